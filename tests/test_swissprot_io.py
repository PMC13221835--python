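"""Flat-file parser and writer: field extraction, dialects, round-trip."""
import io

import pytest

from toxprotkit.swissprot_io import (
    Dataset,
    Feature,
    FeatureKind,
    ParseError,
    ProteinEntry,
    ValidationError,
    extract_family_raw,
    read_dat,
    write_dat,
)

SEQ50 = "MKTLLLTLVVVTIVCLDLGYTLKCNKLVPLFYKTCPAGKNLCYKMFMVAT"

SAMPLE_DAT = f"""\
ID   TOX1_TEST               Reviewed;          50 AA.
AC   P00001; Q99999;
DE   RecName: Full=Alpha-toxin 1;
OS   Test organism.
OC   Eukaryota; Metazoa; Chordata; Squamata; Naja.
OX   NCBI_TaxID=35670;
KW   Toxin; Secreted; Disulfide bond.
CC   -!- TISSUE SPECIFICITY: Expressed by the venom gland.
CC   -!- SIMILARITY: Belongs to the phospholipase A2 family.
CC   -!- TOXIC DOSE: LD(50) is 0.5 mg/kg by intravenous injection into mice.
DR   GO; GO:0005576; C:extracellular region; IEA:Test.
DR   GO; GO:0090729; F:toxin activity; IEA:Test.
PE   1: Evidence at protein level;
FT   SIGNAL          1..22
FT   DISULFID        25..40
FT   MOD_RES         50
FT                   /note="Threonine amide"
SQ   SEQUENCE   50 AA;  0 MW;  0000000000000000 CRC64;
     {SEQ50[:50]}
//
ID   TOX2_TEST               Reviewed;          50 AA.
AC   P00002;
DE   RecName: Full=Beta-toxin fragment;
DE   Flags: Fragment;
OX   NCBI_TaxID=35670;
CC   -!- SIMILARITY: Belongs to the conotoxin-like family. Subgroup two.
CC   -!- SIMILARITY: Belongs to the second family.
PE   2: Evidence at transcript level;
FT   PROPEP          ?..30
FT   CHAIN           31..?50
SQ   SEQUENCE   50 AA;  0 MW;  0000000000000000 CRC64;
     {SEQ50}
//
"""


@pytest.fixture(scope="module")
def sample():
    return read_dat(SAMPLE_DAT, year=2025)


class TestRead:
    def test_fields_read_verbatim(self, sample):
        e = sample.entries[0]
        assert e.accession == "P00001"  # primary accession only
        assert e.entry_name == "TOX1_TEST"
        assert e.protein_name == "Alpha-toxin 1"
        assert "Toxin" in e.keywords
        assert len(e.sequence) == 50
        assert e.taxid == 35670
        assert e.lineage_text[1] == "Metazoa"
        assert e.tissue_specificity == "Expressed by the venom gland."
        assert e.toxic_dose_texts == (
            "LD(50) is 0.5 mg/kg by intravenous injection into mice.",
        )
        assert {(g.go_id, g.aspect) for g in e.go_refs} == {
            ("GO:0005576", "C"), ("GO:0090729", "F"),
        }
        assert e.evidence_level == 1
        assert e.snapshot_year == 2025

    def test_fragment_flag_from_de_block(self, sample):
        assert not sample.entries[0].is_fragment
        assert sample.entries[1].is_fragment

    def test_signal_feature_fully_known(self, sample):
        ft = sample.entries[0].features[0]
        assert ft.kind is FeatureKind.SIGNAL
        assert (ft.start, ft.end) == (1, 22)
        assert ft.fully_known

    def test_single_position_feature_with_note(self, sample):
        ft = sample.entries[0].features[2]
        assert ft.kind is FeatureKind.MOD_RES
        assert (ft.start, ft.end) == (50, 50)
        assert ft.description == "Threonine amide"

    def test_unknown_endpoints_clear_known_flags(self, sample):
        propep, chain = sample.entries[1].features
        assert propep.start is None and not propep.start_known
        assert propep.end == 30 and propep.end_known
        assert chain.end == 50 and not chain.end_known

    def test_family_raw_first_match_kept(self, sample):
        assert extract_family_raw(sample.entries[0]) == "phospholipase A2 family"
        # two SIMILARITY blocks: first match retained, full clause kept
        # (truncation at the first period happens during normalization)
        assert sample.entries[1].family_raw == "conotoxin-like family. Subgroup two"

    def test_no_similarity_comment_gives_absent_family(self):
        text = SAMPLE_DAT.split("//\n")[0].replace(
            "CC   -!- SIMILARITY: Belongs to the phospholipase A2 family.\n", ""
        ) + "//\n"
        ds = read_dat(text)
        assert ds.entries[0].family_raw is None

    def test_terminator_count_equals_entry_count(self, sample):
        assert SAMPLE_DAT.count("//\n") == len(sample)


class TestErrors:
    def test_missing_sq_is_parse_error(self):
        broken = SAMPLE_DAT.split("//\n")[0]
        broken = "\n".join(
            ln for ln in broken.splitlines() if not ln.startswith(("SQ", "     "))
        ) + "\n//\n"
        with pytest.raises(ParseError, match="SQ"):
            read_dat(broken)

    def test_missing_terminator_is_parse_error(self):
        with pytest.raises(ParseError, match="terminator"):
            read_dat(SAMPLE_DAT + "ID   TRAILING_TEST   Reviewed;   10 AA.\n")

    def test_feature_outside_sequence_names_accession(self):
        bad = SAMPLE_DAT.replace("FT   DISULFID        25..40",
                                 "FT   DISULFID        25..90")
        with pytest.raises(ValidationError, match="P00001"):
            read_dat(bad)

    def test_duplicate_accessions_rejected(self):
        block = SAMPLE_DAT.split("//\n")[0] + "//\n"
        with pytest.raises(ValidationError, match="duplicate"):
            read_dat(block * 2)


class TestWrite:
    def test_empty_dataset_empty_text(self):
        assert write_dat(Dataset()) == ""

    def test_roundtrip_identity_on_generated_fixture(self, small_result):
        ds = read_dat(small_result.dat_text, year=small_result.year)
        assert ds.entries == small_result.dataset.entries

    def test_roundtrip_identity_on_series(self, series_result):
        for snap in series_result.snapshots:
            ds = read_dat(snap.dat_text, year=snap.year)
            assert ds.entries == snap.dataset.entries

    def test_unknown_propep_end_roundtrips(self):
        entry = ProteinEntry(
            accession="P12345",
            entry_name="T_TST",
            sequence="A" * 40,
            features=(Feature(FeatureKind.PROPEP, 1, 20, end_known=False),),
        )
        ds = Dataset(year=0, entries=[entry])
        back = read_dat(write_dat(ds))
        assert back.entries == [entry]

    def test_invalid_entry_refused(self):
        entry = ProteinEntry(
            accession="P12345", entry_name="T_TST", sequence="A" * 10,
            features=(Feature(FeatureKind.CHAIN, 1, 99),),
        )
        with pytest.raises(ValidationError):
            write_dat(Dataset(entries=[entry]))


LEGACY_DAT = f"""\
ID   TOX3_TEST               Reviewed;          50 AA.
AC   P00003;
OX   NCBI_TaxID=35670;
PE   1: Evidence at protein level;
FT   SIGNAL        1     22       Or 23.
FT   PROPEP       23     30
FT   CHAIN        31    >50       Mature toxin
FT                                continued here.
SQ   SEQUENCE   50 AA;  0 MW;  0000000000000000 CRC64;
     {SEQ50}
//
"""


def test_legacy_dialect_read_behind_flag():
    ds = read_dat(LEGACY_DAT, legacy_ft=True)
    sig, propep, chain = ds.entries[0].features
    assert (sig.start, sig.end, sig.description) == (1, 22, "Or 23")
    assert (propep.start, propep.end) == (23, 30)
    assert chain.end == 50 and not chain.end_known
    assert chain.description == "Mature toxin continued here"


def test_biopython_crosscheck_on_generated_fixture(small_result):
    """Our writer/parser against the independent Bio.SwissProt parser."""
    SwissProt = pytest.importorskip("Bio.SwissProt")
    ref = list(SwissProt.parse(io.StringIO(small_result.dat_text)))
    ours = small_result.dataset.entries
    assert len(ref) == len(ours)
    for r, e in zip(ref, ours):
        assert r.accessions[0] == e.accession
        assert r.sequence == e.sequence
        assert int(r.taxonomy_id[0]) == e.taxid
        assert set(r.keywords) == set(e.keywords)
        ref_spans = {
            (f.type, int(f.location.start) + 1, int(f.location.end))
            for f in r.features
            if type(f.location.start).__name__ == "ExactPosition"
            and type(f.location.end).__name__ == "ExactPosition"
        }
        our_spans = {
            (ft.kind.value, ft.start, ft.end)
            for ft in e.features
            if ft.fully_known
        }
        assert our_spans <= ref_spans
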