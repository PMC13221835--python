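"""Pipeline orchestration: parse -> select -> annotate -> derive features
-> metrics, per snapshot and across snapshots.

`annotate_entries` is the single place where an entry acquires all its
derived attributes, so every metric downstream counts the same way.  Run
functions are deterministic for fixed inputs and configuration, log
stage counts (parsed, excluded per reason, selected), and write CSV/JSON
outputs suitable for diffing across runs.
"""
from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import pandas as pd
import yaml

from .annotation import (
    FamilyNormalizer,
    HabitatTable,
    TaxonomyTable,
    classify_habitat,
    resolve_lineage,
)
from .embedding_eval import KmerEmbedder, SilhouetteReport, compare_variants
from .metrics import (
    UNASSIGNED,
    AnnotatedEntry,
    SnapshotComparison,
    SnapshotSummary,
    compare_snapshots,
    habitat_partition,
    length_histogram,
    rank_families,
    summarize_snapshot,
)
from .selection import CriterionClass, Definition, classify_criteria
from .sequence_features import (
    PtmVocabulary,
    bin_length,
    derive_mature,
    has_ptm_keyword,
    is_fragment,
    parse_toxic_dose,
    ptm_profile,
)
from .swissprot_io import Dataset, read_dat

log = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "ConfigurationError", "annotate_entries",
           "run_snapshot", "run_comparison", "run_embedding_eval"]


class ConfigurationError(ValueError):
    """Invalid or incomplete pipeline configuration."""


@dataclass
class PipelineConfig:
    """Paths, definition choice and knobs for one pipeline run.

    Defaults reproduce the analysis conditions: the venom-tissue
    definition, top-10 family ranking, 25-aa length bins, and a k-mer
    embedding provider scored over the top-10 families (the optional
    2-D projection settings n_neighbors=50, min_dist=0.5 are recorded
    for visualisation tools but play no role in scoring).
    """

    inputs: Dict[int, str] = field(default_factory=dict)  # year -> DAT path
    taxonomy: str = ""
    merged: Optional[str] = None
    habitat_order: Optional[str] = None
    habitat_genus: Optional[str] = None
    ptmlist: Optional[str] = None
    aliases: Optional[str] = None
    definition: Definition = Definition.VENOM_TISSUE
    top_n: int = 10
    bin_width: int = 25
    embedding: Dict = field(
        default_factory=lambda: {"k": 2, "top_n": 10,
                                 "n_neighbors": 50, "min_dist": 0.5}
    )
    outdir: str = "toxprot_out"
    seed: int = 0
    legacy_ft: bool = False

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        cfg = cls()
        for key, value in raw.items():
            if not hasattr(cfg, key):
                raise ConfigurationError(f"unknown configuration key {key!r}")
            setattr(cfg, key, value)
        cfg.inputs = {int(y): str(p) for y, p in (cfg.inputs or {}).items()}
        cfg.definition = Definition(cfg.definition)
        return cfg

    def validate_for(self, years: Sequence[int]) -> None:
        for year in years:
            if year not in self.inputs:
                raise ConfigurationError(f"no input DAT configured for year {year}")
            if not Path(self.inputs[year]).exists():
                raise ConfigurationError(
                    f"input file missing: {self.inputs[year]}"
                )
        if not self.taxonomy or not Path(self.taxonomy).exists():
            raise ConfigurationError(f"taxonomy table missing: {self.taxonomy!r}")
        for label, p in (("habitat_order", self.habitat_order),
                         ("habitat_genus", self.habitat_genus),
                         ("ptmlist", self.ptmlist),
                         ("aliases", self.aliases)):
            if p is not None and not Path(p).exists():
                raise ConfigurationError(f"{label} file missing: {p}")

    # -- resource loading --------------------------------------------------

    def load_taxonomy(self) -> TaxonomyTable:
        return TaxonomyTable.from_tsv(self.taxonomy, self.merged)

    def load_habitats(self) -> HabitatTable:
        if self.habitat_order and self.habitat_genus:
            return HabitatTable.from_tsv(self.habitat_order, self.habitat_genus)
        return HabitatTable.load_default()

    def load_vocab(self) -> PtmVocabulary:
        if self.ptmlist:
            return PtmVocabulary.from_file(self.ptmlist)
        return PtmVocabulary.load_default()

    def load_normalizer(self) -> FamilyNormalizer:
        if self.aliases:
            return FamilyNormalizer.from_tsv(self.aliases)
        return FamilyNormalizer.load_default()


def annotate_entries(
    dataset: Dataset,
    taxonomy: TaxonomyTable,
    habitats: HabitatTable,
    normalizer: FamilyNormalizer,
    vocab: PtmVocabulary,
    definition: Definition = Definition.VENOM_TISSUE,
) -> List[AnnotatedEntry]:
    """Classify, select and fully annotate a parsed dataset.

    Returns one record per entry satisfying the chosen definition, in
    input order; logs how many entries each selection class contributed.
    """
    wanted = {
        Definition.VENOM_TISSUE: {CriterionClass.VENOM_TISSUE_ONLY,
                                  CriterionClass.BOTH},
        Definition.TOXIN_KEYWORD: {CriterionClass.TOXIN_KEYWORD_ONLY,
                                   CriterionClass.BOTH},
        Definition.UNION: {CriterionClass.VENOM_TISSUE_ONLY,
                           CriterionClass.TOXIN_KEYWORD_ONLY,
                           CriterionClass.BOTH},
    }[Definition(definition)]
    records: List[AnnotatedEntry] = []
    n_excluded = 0
    for entry in dataset:
        criterion = classify_criteria(entry, taxonomy)
        if criterion not in wanted:
            n_excluded += 1
            continue
        lineage = resolve_lineage(entry.taxid, taxonomy)
        family = (
            normalizer.normalize(entry.family_raw)
            if entry.family_raw is not None
            else UNASSIGNED
        )
        records.append(
            AnnotatedEntry(
                entry=entry,
                lineage=lineage,
                habitat=classify_habitat(lineage, habitats),
                family=family,
                mature=derive_mature(entry),
                fragment=is_fragment(entry),
                ptm=ptm_profile(entry, vocab),
                ptm_keyword=has_ptm_keyword(entry),
                doses=tuple(parse_toxic_dose(entry.toxic_dose_texts)),
                criterion=criterion,
            )
        )
    log.info(
        "annotated %d/%d entries (%d excluded by definition %s)",
        len(records), len(dataset), n_excluded, Definition(definition).value,
    )
    if len(records) + n_excluded != len(dataset):
        raise AssertionError("stage-count conservation violated")
    return records


def records_to_frame(records: Sequence[AnnotatedEntry]) -> pd.DataFrame:
    """Per-entry CSV table (one row per selected entry)."""
    rows = []
    for r in records:
        row = {
            "accession": r.accession,
            "year": r.entry.snapshot_year,
            "criterion_class": r.criterion.value,
            "phylum": r.lineage.phylum,
            "class": r.lineage.class_,
            "order": r.lineage.order,
            "tax_family": r.lineage.family,
            "genus": r.lineage.genus,
            "species": r.lineage.species,
            "habitat": r.habitat.value,
            "protein_family": r.family,
            "mature_length": r.mature.length,
            "mature_method": r.mature.method.value,
            "length_bin": bin_length(r.mature.length),
            "fragment": r.fragment,
            "ptm_total": r.ptm.total,
            "ptm_keyword": r.ptm_keyword,
            "evidence_level": r.entry.evidence_level,
            "n_toxic_dose": len(r.doses),
            "mouse_tested": any(d.mouse_tested for d in r.doses),
            "routes": ";".join(d.route.value for d in r.doses),
        }
        for cat, count in sorted(r.ptm.as_dict().items()):
            row[f"ptm_{cat.lower().replace(' ', '_')}"] = count
        rows.append(row)
    return pd.DataFrame(rows)


def _load_year(config: PipelineConfig, year: int) -> Dataset:
    with open(config.inputs[year]) as fh:
        dataset = read_dat(fh, year=year, legacy_ft=config.legacy_ft)
    log.info("year %d: parsed %d entries", year, len(dataset))
    return dataset


def _annotate_year(config: PipelineConfig, year: int) -> List[AnnotatedEntry]:
    dataset = _load_year(config, year)
    return annotate_entries(
        dataset,
        config.load_taxonomy(),
        config.load_habitats(),
        config.load_normalizer(),
        config.load_vocab(),
        config.definition,
    )


def run_snapshot(
    config: PipelineConfig, year: int
) -> Tuple[SnapshotSummary, pd.DataFrame]:
    """Run one snapshot end to end and write its outputs.

    Writes ``toxprot_<year>.csv`` (per-entry), ``summary_<year>.json``,
    ``families_<year>.json``, ``habitat_<year>.json`` and
    ``length_histogram_<year>.json`` under the configured outdir.
    """
    config.validate_for([year])
    records = _annotate_year(config, year)
    summary = summarize_snapshot(records, year)
    ranking = rank_families(records, config.top_n)
    partition = habitat_partition(records)
    histogram = length_histogram(records, config.bin_width)
    frame = records_to_frame(records)

    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    frame.to_csv(outdir / f"toxprot_{year}.csv", index=False)
    (outdir / f"summary_{year}.json").write_text(
        json.dumps(summary.as_dict(), indent=2) + "\n"
    )
    (outdir / f"families_{year}.json").write_text(
        json.dumps(ranking.as_dict(), indent=2) + "\n"
    )
    (outdir / f"habitat_{year}.json").write_text(
        json.dumps(partition.as_dict(), indent=2) + "\n"
    )
    (outdir / f"length_histogram_{year}.json").write_text(
        json.dumps(histogram, indent=2) + "\n"
    )
    return summary, frame


def run_comparison(
    config: PipelineConfig, years: Sequence[int]
) -> Dict[Tuple[int, int], SnapshotComparison]:
    """Pairwise comparisons (consecutive plus first-vs-last) over years."""
    if len(years) < 2:
        raise ConfigurationError("comparison needs at least two years")
    years = sorted(years)
    config.validate_for(years)
    annotated = {year: _annotate_year(config, year) for year in years}
    pairs = list(zip(years, years[1:]))
    if len(years) > 2:
        pairs.append((years[0], years[-1]))
    comparisons = {
        (a, b): compare_snapshots(annotated[a], annotated[b], a, b)
        for a, b in pairs
    }
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    payload = {f"{a}-{b}": c.as_dict() for (a, b), c in comparisons.items()}
    (outdir / "comparisons.json").write_text(json.dumps(payload, indent=2) + "\n")
    return comparisons


def run_embedding_eval(
    config: PipelineConfig, year: int
) -> List[SilhouetteReport]:
    """Five-variant silhouette comparison for one snapshot.

    Families are the top-N normalized names; the embedding provider is
    the deterministic k-mer embedder configured under ``embedding.k``.
    Writes silhouette reports and one FASTA per variant.
    """
    config.validate_for([year])
    dataset = _load_year(config, year)
    records = annotate_entries(
        dataset,
        config.load_taxonomy(),
        config.load_habitats(),
        config.load_normalizer(),
        config.load_vocab(),
        config.definition,
    )
    selected = Dataset(year=year, entries=[r.entry for r in records])
    labels = {r.accession: r.family for r in records}
    provider = KmerEmbedder(k=int(config.embedding.get("k", 2)))
    reports = compare_variants(
        selected, labels, provider, top_n=int(config.embedding.get("top_n", 10))
    )
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    (outdir / f"silhouette_{year}.json").write_text(
        json.dumps([r.as_dict() for r in reports], indent=2) + "\n"
    )
    from .embedding_eval import prepare_variant, Variant

    for variant in Variant:
        pairs = prepare_variant(selected, variant)
        with open(outdir / f"sequences_{year}_{variant.value}.fasta", "w") as fh:
            for acc, seq in pairs:
                fh.write(f">{acc}|{variant.value}\n")
                for i in range(0, len(seq), 60):
                    fh.write(seq[i : i + 60] + "\n")
    return reports
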