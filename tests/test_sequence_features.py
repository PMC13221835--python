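"""Mature-sequence derivation, length bins, fragments, PTMs, doses, GO."""
import pytest
from hypothesis import given
from hypothesis import strategies as st

from toxprotkit.sequence_features import (
    DerivationError,
    MatureMethod,
    PtmVocabulary,
    Route,
    bin_length,
    derive_mature,
    go_coverage,
    has_ptm_keyword,
    is_fragment,
    parse_toxic_dose,
    ptm_profile,
)
from toxprotkit.swissprot_io import (
    Dataset,
    Feature,
    FeatureKind,
    GoRef,
    STRUCTURAL_KINDS,
    read_dat,
)

from conftest import make_entry

SEQ100 = "ACDEFGHIKLMNPQRSTVWY" * 5


def sig(a, b, **kw):
    return Feature(FeatureKind.SIGNAL, a, b, **kw)


def propep(a, b, **kw):
    return Feature(FeatureKind.PROPEP, a, b, **kw)


def chain(a, b, **kw):
    return Feature(FeatureKind.CHAIN, a, b, **kw)


class TestDeriveMature:
    def test_signal_and_propeptide_removed(self):
        e = make_entry(sequence=SEQ100,
                       features=[sig(1, 20), propep(21, 40)])
        m = derive_mature(e)
        assert m.length == 60
        assert m.sequence == SEQ100[40:]
        assert m.method is MatureMethod.SIGNAL_PROPEP_REMOVED

    def test_chain_annotation_takes_precedence(self):
        e = make_entry(sequence=SEQ100,
                       features=[sig(1, 20), chain(25, 80)])
        m = derive_mature(e)
        assert m.length == 56
        assert m.sequence == SEQ100[24:80]
        assert m.method is MatureMethod.CHAIN_PEPTIDE

    def test_no_annotations_assumed_already_mature(self):
        m = derive_mature(make_entry(sequence=SEQ100))
        assert m.sequence == SEQ100
        assert m.method is MatureMethod.AS_IS

    def test_longest_chain_wins_ties_to_smallest_start(self):
        e = make_entry(sequence=SEQ100,
                       features=[chain(41, 60), chain(11, 30), chain(1, 5)])
        m = derive_mature(e)
        assert m.sequence == SEQ100[10:30]

    def test_incomplete_chain_not_eligible(self):
        e = make_entry(sequence=SEQ100,
                       features=[chain(25, 80, end_known=False), sig(1, 20)])
        assert derive_mature(e).method is MatureMethod.SIGNAL_PROPEP_REMOVED

    def test_total_removal_is_error(self):
        e = make_entry(sequence="A" * 30, features=[sig(1, 30)])
        with pytest.raises(DerivationError):
            derive_mature(e)

    def test_oracle_equivalence_on_1000_fixture_entries(self):
        """Brute-force residue-mask oracle over >= 1000 generated entries."""
        from toxprotkit.synthetic import SyntheticConfig, generate

        res = generate(SyntheticConfig(seed=23, n_entries=1000))

        def oracle(entry):
            spans = [
                (ft.start, ft.end)
                for ft in entry.features
                if ft.kind in (FeatureKind.CHAIN, FeatureKind.PEPTIDE)
                and ft.fully_known
            ]
            if spans:
                best = sorted(spans, key=lambda se: (-(se[1] - se[0]), se[0]))[0]
                return entry.sequence[best[0] - 1 : best[1]]
            mask = [True] * len(entry.sequence)
            removed = False
            for ft in entry.features:
                if ft.kind in (FeatureKind.SIGNAL, FeatureKind.PROPEP) and ft.fully_known:
                    removed = True
                    for i in range(ft.start - 1, ft.end):
                        mask[i] = False
            return "".join(c for c, keep in zip(entry.sequence, mask) if keep)

        assert len(res.dataset) >= 1000
        for entry in res.dataset:
            m = derive_mature(entry)
            assert m.sequence == oracle(entry)
            assert m.length <= len(entry.sequence)


class TestBinLength:
    @pytest.mark.parametrize("length,label", [
        (26, "26-50"), (75, "51-75"), (4, "1-25"), (25, "1-25"), (1384, "1376-1400"),
    ])
    def test_closed_bins_of_width_25(self, length, label):
        assert bin_length(length) == label

    def test_length_below_one_is_error(self):
        with pytest.raises(ValueError):
            bin_length(0)

    @given(st.integers(min_value=1, max_value=2000))
    def test_every_length_in_exactly_one_bin(self, length):
        label = bin_length(length)
        lo, hi = (int(x) for x in label.split("-"))
        assert lo <= length <= hi
        assert hi - lo == 24
        assert (lo - 1) % 25 == 0


class TestFragment:
    def test_description_flag(self):
        assert is_fragment(make_entry(is_fragment=True))

    def test_unknown_signal_start(self):
        e = make_entry(sequence=SEQ100,
                       features=[sig(1, 20, start_known=False)])
        assert is_fragment(e)

    def test_fully_specified_is_not_fragment(self):
        e = make_entry(sequence=SEQ100, features=[sig(1, 20), chain(21, 100)])
        assert not is_fragment(e)

    def test_incomplete_nonstructural_feature_is_not_fragment(self):
        e = make_entry(
            sequence=SEQ100,
            features=[Feature(FeatureKind.DISULFID, 3, 30, end_known=False)],
        )
        assert not is_fragment(e)


class TestPtm:
    def test_three_disulfide_features(self, vocab):
        e = make_entry(sequence=SEQ100, features=[
            Feature(FeatureKind.DISULFID, 1, 10),
            Feature(FeatureKind.DISULFID, 2, 11),
            Feature(FeatureKind.DISULFID, 3, 12),
        ])
        assert ptm_profile(e, vocab).counts == {"Disulfide bond": 3}

    def test_mod_res_mapped_through_vocabulary(self, vocab):
        e = make_entry(sequence=SEQ100, features=[
            Feature(FeatureKind.MOD_RES, 5, 5, description="4-hydroxyproline"),
            Feature(FeatureKind.MOD_RES, 100, 100, description="Leucine amide"),
        ])
        p = ptm_profile(e, vocab)
        assert p.counts["Hydroxylation"] == 1
        assert p.counts["Amidation"] == 1

    def test_vocabulary_miss_counts_as_other(self, vocab, caplog):
        e = make_entry(sequence=SEQ100, features=[
            Feature(FeatureKind.MOD_RES, 5, 5, description="Imaginary residue"),
        ])
        with caplog.at_level("WARNING"):
            assert ptm_profile(e, vocab).counts == {"Other": 1}
        assert "Imaginary residue" in caplog.text

    def test_feature_kind_categories(self, vocab):
        e = make_entry(sequence=SEQ100, features=[
            Feature(FeatureKind.CARBOHYD, 5, 5),
            Feature(FeatureKind.CROSSLNK, 10, 12),
            Feature(FeatureKind.LIPID, 20, 20),
        ])
        assert ptm_profile(e, vocab).counts == {
            "Glycosylation": 1, "Cross-link": 1, "Lipidation": 1,
        }

    def test_profile_total_conserves_feature_count(self, small_result, vocab):
        ptm_kinds = {
            FeatureKind.DISULFID, FeatureKind.CARBOHYD, FeatureKind.MOD_RES,
            FeatureKind.CROSSLNK, FeatureKind.LIPID,
        }
        for entry in small_result.dataset:
            n_ptm_feats = sum(1 for ft in entry.features if ft.kind in ptm_kinds)
            assert ptm_profile(entry, vocab).total == n_ptm_feats

    def test_keyword_accounting_is_independent(self, vocab):
        e = make_entry(keywords={"Disulfide bond"})
        assert has_ptm_keyword(e)
        assert not ptm_profile(e, vocab).has_annotation

    def test_vocabulary_case_insensitive(self):
        v = PtmVocabulary(records={"Leucine Amide": "Amidation"})
        assert v.categorize("leucine amide") == "Amidation"


class TestToxicDose:
    def test_iv_mouse(self):
        (r,) = parse_toxic_dose(
            ["LD(50) is 0.5 mg/kg by intravenous injection into mice"]
        )
        assert r.mouse_tested and r.route is Route.IV

    def test_non_mouse_unstated_route(self):
        (r,) = parse_toxic_dose(["Paralytic dose in crickets"])
        assert not r.mouse_tested and r.route is Route.OTHER

    def test_abbreviated_icv(self):
        (r,) = parse_toxic_dose(["LD(50) is 0.003 nmol/kg i.c.v. in mouse"])
        assert r.route is Route.ICV and r.mouse_tested

    @pytest.mark.parametrize("text,route", [
        ("by intraperitoneal injection", Route.IP),
        ("0.1 mg/kg s.c. into mice", Route.SC),
        ("1 mg/kg i.v. and also i.p.", Route.IV),  # first keyword wins
    ])
    def test_route_keywords(self, text, route):
        (r,) = parse_toxic_dose([text])
        assert r.route is route


class TestGoCoverage:
    def _entry(self, i, aspects):
        return make_entry(
            accession=f"P{i:05d}",
            go_refs=[GoRef("GO:0000001", a, "term") for a in aspects],
        )

    def test_full_none_and_partial_coverage(self):
        entries = [self._entry(i, ["C"]) for i in range(6)]
        entries += [self._entry(i + 6, ["C", "F"]) for i in range(2)]
        ds = Dataset(entries=entries)
        cov = go_coverage(ds)
        assert cov == {"C": 100.0, "P": 0.0, "F": 25.0}

    def test_empty_dataset_is_error(self):
        with pytest.raises(ValueError):
            go_coverage(Dataset())
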