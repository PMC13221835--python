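"""Snapshot summaries, cross-snapshot comparisons, family rankings,
habitat partitions and mature-length histograms.

All operations work on :class:`AnnotatedEntry` records — one per entry,
carrying the resolved lineage, habitat, normalized family and derived
sequence features — so that the counting conventions live in one place:

* percentages are round-half-away-from-zero to one decimal of
  ``100 * count / total``;
* decade growth is an integer floor of the relative change;
* species are counted by resolved species-rank taxid (name fallback);
* families are counted by post-alias normalized name, with entries
  lacking a family statement pooled as "Unassigned".
"""
from __future__ import annotations

import math
from collections import Counter, defaultdict
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Set, Tuple

from ._rounding import percent, round1_half_up
from .annotation import Habitat, Lineage
from .selection import CriterionClass
from .sequence_features import (
    MatureSequence,
    PTMProfile,
    ToxicDoseRecord,
    bin_length,
)
from .swissprot_io import ProteinEntry

__all__ = [
    "percent",
    "growth_pct_floor",
    "AnnotatedEntry",
    "SnapshotSummary",
    "SnapshotComparison",
    "FamilyCount",
    "FamilyRanking",
    "HabitatPartition",
    "UNASSIGNED",
    "summarize_snapshot",
    "compare_snapshots",
    "rank_families",
    "habitat_partition",
    "length_histogram",
]

UNASSIGNED = "Unassigned"

_COMPARISON_RANKS = ("order", "family", "genus", "species")


def growth_pct_floor(count_a: int, count_b: int) -> int:
    """Integer floor of the percentage growth from ``count_a`` to ``count_b``."""
    if count_a < 1:
        raise ValueError("baseline count must be >= 1")
    return math.floor(100.0 * (count_b - count_a) / count_a)


@dataclass(frozen=True)
class AnnotatedEntry:
    """One selected entry with every derived attribute the metrics need."""

    entry: ProteinEntry
    lineage: Lineage
    habitat: Habitat
    family: str  # normalized name, or UNASSIGNED
    mature: MatureSequence
    fragment: bool
    ptm: PTMProfile
    ptm_keyword: bool
    doses: Tuple[ToxicDoseRecord, ...]
    criterion: CriterionClass

    @property
    def accession(self) -> str:
        return self.entry.accession

    @property
    def species_key(self):
        return self.lineage.species_key


def _species_set(records: Sequence[AnnotatedEntry]) -> Set:
    return {r.species_key for r in records}


def _family_set(records: Sequence[AnnotatedEntry]) -> Set[str]:
    return {r.family for r in records if r.family != UNASSIGNED}


def _rank_names(records: Sequence[AnnotatedEntry], rank: str) -> Set[str]:
    return {
        name
        for r in records
        if (name := r.lineage.rank_name(rank)) is not None
    }


@dataclass
class SnapshotSummary:
    """The per-release metric vector (entry counts, diversity, coverage)."""

    year: int
    total_entries: int
    n_orders: int
    n_species: int
    n_families: int
    n_unassigned: int
    pct_unassigned: float
    n_fragments: int
    pct_fragments: float
    n_ptm_annotated: int
    pct_ptm_annotated: float
    n_ptm_keyword: int
    pct_ptm_keyword: float
    n_toxic_dose: int
    pct_toxic_dose: float
    evidence_distribution: Dict[int, Tuple[int, float]]
    ptm_category_totals: Dict[str, int]

    def as_dict(self) -> dict:
        d = {
            "year": self.year,
            "total_entries": self.total_entries,
            "n_orders": self.n_orders,
            "n_species": self.n_species,
            "n_families": self.n_families,
            "n_unassigned": self.n_unassigned,
            "pct_unassigned": self.pct_unassigned,
            "n_fragments": self.n_fragments,
            "pct_fragments": self.pct_fragments,
            "n_ptm_annotated": self.n_ptm_annotated,
            "pct_ptm_annotated": self.pct_ptm_annotated,
            "n_ptm_keyword": self.n_ptm_keyword,
            "pct_ptm_keyword": self.pct_ptm_keyword,
            "n_toxic_dose": self.n_toxic_dose,
            "pct_toxic_dose": self.pct_toxic_dose,
            "evidence_distribution": {
                str(k): list(v) for k, v in sorted(self.evidence_distribution.items())
            },
            "ptm_category_totals": dict(self.ptm_category_totals),
        }
        return d


def summarize_snapshot(
    records: Sequence[AnnotatedEntry], year: int
) -> SnapshotSummary:
    """Summary-table metrics over one annotated snapshot."""
    n = len(records)
    if n < 1:
        raise ValueError("cannot summarize an empty snapshot")
    n_unassigned = sum(1 for r in records if r.family == UNASSIGNED)
    n_fragments = sum(1 for r in records if r.fragment)
    n_ptm = sum(1 for r in records if r.ptm.has_annotation)
    n_ptm_kw = sum(1 for r in records if r.ptm_keyword)
    n_dose = sum(1 for r in records if r.doses)
    ev = Counter(r.entry.evidence_level for r in records)
    ptm_totals: Counter = Counter()
    for r in records:
        ptm_totals.update(r.ptm.counts)
    return SnapshotSummary(
        year=year,
        total_entries=n,
        n_orders=len(_rank_names(records, "order")),
        n_species=len(_species_set(records)),
        n_families=len(_family_set(records)),
        n_unassigned=n_unassigned,
        pct_unassigned=percent(n_unassigned, n),
        n_fragments=n_fragments,
        pct_fragments=percent(n_fragments, n),
        n_ptm_annotated=n_ptm,
        pct_ptm_annotated=percent(n_ptm, n),
        n_ptm_keyword=n_ptm_kw,
        pct_ptm_keyword=percent(n_ptm_kw, n),
        n_toxic_dose=n_dose,
        pct_toxic_dose=percent(n_dose, n),
        evidence_distribution={
            level: (ev.get(level, 0), percent(ev.get(level, 0), n))
            for level in (1, 2, 3, 4, 5)
        },
        ptm_category_totals=dict(ptm_totals),
    )


@dataclass
class SnapshotComparison:
    """Diffs between two annotated snapshots.

    Species change is reported two ways: the net unique-count change
    (count_b - count_a, which can hide turnover) and the newcomer set
    (names in b but not a); disappeared taxa are tracked per rank as
    well.  Family change refers to protein families (normalized names).
    """

    year_a: int
    year_b: int
    entries_a: int
    entries_b: int
    growth_pct_floor: int
    net_species_change: int
    net_family_change: int
    newcomer_species: Set
    newcomer_taxa_by_rank: Dict[str, Set[str]]
    disappeared_taxa_by_rank: Dict[str, Set[str]]
    newcomer_families: Set[str]
    disappeared_families: Set[str]

    def as_dict(self) -> dict:
        return {
            "year_a": self.year_a,
            "year_b": self.year_b,
            "entries_a": self.entries_a,
            "entries_b": self.entries_b,
            "growth_pct_floor": self.growth_pct_floor,
            "net_species_change": self.net_species_change,
            "net_family_change": self.net_family_change,
            "newcomer_species": sorted(map(str, self.newcomer_species)),
            "newcomer_taxa_by_rank": {
                k: sorted(v) for k, v in self.newcomer_taxa_by_rank.items()
            },
            "disappeared_taxa_by_rank": {
                k: sorted(v) for k, v in self.disappeared_taxa_by_rank.items()
            },
            "newcomer_families": sorted(self.newcomer_families),
            "disappeared_families": sorted(self.disappeared_families),
        }


def compare_snapshots(
    records_a: Sequence[AnnotatedEntry],
    records_b: Sequence[AnnotatedEntry],
    year_a: int,
    year_b: int,
) -> SnapshotComparison:
    species_a, species_b = _species_set(records_a), _species_set(records_b)
    fam_a, fam_b = _family_set(records_a), _family_set(records_b)
    newcomers = {}
    disappeared = {}
    for rank in _COMPARISON_RANKS:
        names_a, names_b = _rank_names(records_a, rank), _rank_names(records_b, rank)
        newcomers[rank] = names_b - names_a
        disappeared[rank] = names_a - names_b
    return SnapshotComparison(
        year_a=year_a,
        year_b=year_b,
        entries_a=len(records_a),
        entries_b=len(records_b),
        growth_pct_floor=growth_pct_floor(len(records_a), len(records_b)),
        net_species_change=len(species_b) - len(species_a),
        net_family_change=len(fam_b) - len(fam_a),
        newcomer_species=species_b - species_a,
        newcomer_taxa_by_rank=newcomers,
        disappeared_taxa_by_rank=disappeared,
        newcomer_families=fam_b - fam_a,
        disappeared_families=fam_a - fam_b,
    )


@dataclass(frozen=True)
class FamilyCount:
    family: str
    count: int
    pct: float


@dataclass
class FamilyRanking:
    top: List[FamilyCount]
    other_count: int
    unassigned_count: int
    total: int

    def as_dict(self) -> dict:
        return {
            "top": [
                {"family": f.family, "count": f.count, "pct": f.pct} for f in self.top
            ],
            "other_count": self.other_count,
            "unassigned_count": self.unassigned_count,
            "total": self.total,
        }


def rank_families(records: Sequence[AnnotatedEntry], top_n: int) -> FamilyRanking:
    """Most-abundant protein families, descending by entry count.

    Ties at the rank boundary break lexicographically; families outside
    the top ``top_n`` aggregate into the "Other" count and Unassigned
    entries are reported separately.
    """
    if top_n < 1:
        raise ValueError("top_n must be >= 1")
    counts = Counter(r.family for r in records if r.family != UNASSIGNED)
    ordered = sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))
    total = len(records)
    top = [
        FamilyCount(name, c, percent(c, total)) for name, c in ordered[:top_n]
    ]
    other = sum(c for _, c in ordered[top_n:])
    unassigned = sum(1 for r in records if r.family == UNASSIGNED)
    return FamilyRanking(
        top=top, other_count=other, unassigned_count=unassigned, total=total
    )


@dataclass
class HabitatPartition:
    """Entries/species/families per habitat and the shared-family set."""

    entries: Dict[Habitat, int]
    species: Dict[Habitat, int]
    families: Dict[Habitat, int]
    shared_families: Set[str]
    shared_family_counts: Dict[str, Dict[Habitat, int]]

    def as_dict(self) -> dict:
        return {
            "entries": {h.value: c for h, c in self.entries.items()},
            "species": {h.value: c for h, c in self.species.items()},
            "families": {h.value: c for h, c in self.families.items()},
            "shared_families": sorted(self.shared_families),
            "shared_family_counts": {
                fam: {h.value: c for h, c in per.items()}
                for fam, per in sorted(self.shared_family_counts.items())
            },
        }


def habitat_partition(records: Sequence[AnnotatedEntry]) -> HabitatPartition:
    """Terrestrial/marine partition of entries, species and families.

    Shared families are the intersection of the two habitats' family
    sets, with per-habitat entry counts retained for each.
    """
    by_habitat: Dict[Habitat, List[AnnotatedEntry]] = {
        Habitat.TERRESTRIAL: [],
        Habitat.MARINE: [],
    }
    for r in records:
        by_habitat[r.habitat].append(r)
    fam_sets = {h: _family_set(rs) for h, rs in by_habitat.items()}
    shared = fam_sets[Habitat.TERRESTRIAL] & fam_sets[Habitat.MARINE]
    shared_counts: Dict[str, Dict[Habitat, int]] = {}
    for fam in shared:
        shared_counts[fam] = {
            h: sum(1 for r in rs if r.family == fam) for h, rs in by_habitat.items()
        }
    return HabitatPartition(
        entries={h: len(rs) for h, rs in by_habitat.items()},
        species={h: len(_species_set(rs)) for h, rs in by_habitat.items()},
        families={h: len(s) for h, s in fam_sets.items()},
        shared_families=shared,
        shared_family_counts=shared_counts,
    )


def length_histogram(
    records: Sequence[AnnotatedEntry], width: int = 25
) -> Dict[str, int]:
    """Mature-length histogram in closed bins of ``width`` residues.

    Bins run contiguously from 1 to the longest observed mature length;
    empty bins are reported as 0, never omitted.
    """
    counts: Counter = Counter(bin_length(r.mature.length, width) for r in records)
    if not records:
        return {}
    max_len = max(r.mature.length for r in records)
    out: Dict[str, int] = {}
    lo = 1
    while lo <= max_len:
        label = f"{lo}-{lo + width - 1}"
        out[label] = counts.get(label, 0)
        lo += width
    return out
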