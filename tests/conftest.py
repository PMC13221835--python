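import pytest
from hypothesis import settings

settings.register_profile("suite", derandomize=True, max_examples=100)
settings.load_profile("suite")

from toxprotkit.annotation import FamilyNormalizer, Lineage, TaxonomyTable
from toxprotkit.metrics import UNASSIGNED, AnnotatedEntry
from toxprotkit.annotation import Habitat
from toxprotkit.pipeline import annotate_entries
from toxprotkit.selection import CriterionClass
from toxprotkit.sequence_features import (
    MatureMethod,
    MatureSequence,
    PTMProfile,
    PtmVocabulary,
)
from toxprotkit.swissprot_io import Feature, FeatureKind, ProteinEntry, read_dat
from toxprotkit.synthetic import SyntheticConfig, generate, generate_snapshot_series


@pytest.fixture(scope="session")
def vocab():
    return PtmVocabulary.load_default()


@pytest.fixture(scope="session")
def normalizer():
    return FamilyNormalizer.load_default()


@pytest.fixture(scope="session")
def small_result():
    """One 300-entry snapshot with exact bookkeeping."""
    return generate(SyntheticConfig(seed=11, n_entries=300), year=2025)


@pytest.fixture(scope="session")
def small_records(small_result, normalizer, vocab):
    ds = read_dat(small_result.dat_text, year=2025)
    return annotate_entries(
        ds, small_result.taxonomy, small_result.habitat_table, normalizer, vocab
    )


@pytest.fixture(scope="session")
def series_result():
    """Three snapshots (1x/2x/3x growth) with planted newcomers and one
    planted disappearance."""
    cfg = SyntheticConfig(seed=7, n_entries=200)
    return generate_snapshot_series(
        cfg,
        [2005, 2015, 2025],
        [1, 2, 3],
        introduce_orders={2015: ["Scolopendromorpha"], 2025: ["Myliobatiformes"]},
        introduce_families={
            2015: ["Scoloptoxin-01 family"],
            2025: ["Orpotrin family", "Conotoxin A superfamily"],
        },
        drop_orders={2015: ["Hymenoptera"]},
    )


@pytest.fixture(scope="session")
def series_records(series_result, normalizer, vocab):
    out = {}
    for snap in series_result.snapshots:
        ds = read_dat(snap.dat_text, year=snap.year)
        out[snap.year] = annotate_entries(
            ds, series_result.taxonomy, series_result.habitat_table,
            normalizer, vocab,
        )
    return out


@pytest.fixture(scope="session")
def mini_taxonomy():
    """Hand-built taxonomy: a metazoan chain plus a plant outgroup."""
    t = TaxonomyTable()
    t.add(1, 1, "no rank", "root")
    t.add(33208, 1, "kingdom", "Metazoa")
    t.add(7711, 33208, "phylum", "Chordata")
    t.add(8504, 7711, "class", "Lepidosauria")
    t.add(8509, 8504, "order", "Squamata")
    t.add(8602, 8509, "family", "Elapidae")
    t.add(8656, 8602, "genus", "Naja")
    t.add(35670, 8656, "species", "Naja naja")
    t.add(33090, 1, "kingdom", "Viridiplantae")
    t.add(3702, 33090, "species", "Arabidopsis thaliana")
    t.deprecated_map[999] = 35670
    return t


def make_entry(
    accession="P99999",
    sequence="M" * 50,
    features=(),
    keywords=(),
    tissue=None,
    family_raw=None,
    taxid=35670,
    is_fragment=False,
    doses=(),
    go_refs=(),
    evidence=1,
):
    return ProteinEntry(
        accession=accession,
        entry_name=f"{accession}_TST",
        sequence=sequence,
        taxid=taxid,
        is_fragment=is_fragment,
        keywords=frozenset(keywords),
        tissue_specificity=tissue,
        family_raw=family_raw,
        toxic_dose_texts=tuple(doses),
        go_refs=tuple(go_refs),
        evidence_level=evidence,
        features=tuple(features),
    )


def make_record(
    accession="P99999",
    family="Fam A",
    habitat=Habitat.TERRESTRIAL,
    mature_len=30,
    species_taxid=35670,
    species="Naja naja",
    order="Squamata",
    fragment=False,
    ptm_counts=None,
    doses=(),
    evidence=1,
):
    """Minimal AnnotatedEntry for direct metric tests."""
    from collections import Counter

    entry = make_entry(accession=accession, sequence="A" * mature_len,
                       evidence=evidence)
    lineage = Lineage(
        taxid=species_taxid, phylum="Chordata", class_="Lepidosauria",
        order=order, family=f"{order}idae", genus=species.split()[0],
        species=species, species_taxid=species_taxid,
    )
    return AnnotatedEntry(
        entry=entry,
        lineage=lineage,
        habitat=habitat,
        family=family,
        mature=MatureSequence("A" * mature_len, MatureMethod.AS_IS),
        fragment=fragment,
        ptm=PTMProfile(Counter(ptm_counts or {})),
        ptm_keyword=bool(ptm_counts),
        doses=tuple(doses),
        criterion=CriterionClass.BOTH,
    )
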