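"""Per-entry molecular attributes derived from feature annotations.

Covers: mature sequence and length (chain/peptide annotations first, then
signal/propeptide removal, else the precursor as-is), 25-aa length bins,
fragment status (explicit flag or any incomplete processed-subsequence
range), feature- and keyword-based PTM accounting, toxic-dose text flags
(test animal and administration route) and GO annotation coverage.
"""
from __future__ import annotations

import logging
import re
from collections import Counter
from dataclasses import dataclass, field
from enum import Enum
from importlib import resources
from typing import Dict, Iterable, List, Mapping, Optional, Sequence

from ._rounding import percent
from .swissprot_io import Dataset, Feature, FeatureKind, ProteinEntry, STRUCTURAL_KINDS

log = logging.getLogger(__name__)

__all__ = [
    "MatureMethod",
    "MatureSequence",
    "PTMProfile",
    "PtmVocabulary",
    "Route",
    "ToxicDoseRecord",
    "PTM_CATEGORIES",
    "PTM_KEYWORD_CATEGORIES",
    "derive_mature",
    "bin_length",
    "is_fragment",
    "ptm_profile",
    "has_ptm_keyword",
    "parse_toxic_dose",
    "go_coverage",
]


class MatureMethod(str, Enum):
    CHAIN_PEPTIDE = "chain_peptide"
    SIGNAL_PROPEP_REMOVED = "signal_propep_removed"
    AS_IS = "as_is"


@dataclass(frozen=True)
class MatureSequence:
    sequence: str
    method: MatureMethod

    @property
    def length(self) -> int:
        return len(self.sequence)


class DerivationError(ValueError):
    """Mature sequence empty after feature-based processing."""


def derive_mature(entry: ProteinEntry) -> MatureSequence:
    """Mature sequence of one entry.

    Precedence: (1) if at least one CHAIN or PEPTIDE feature with both
    endpoints known exists, the longest such span (ties broken by the
    smallest start) is the mature product; (2) otherwise residues covered
    by fully-known SIGNAL and PROPEP features are removed from the
    precursor; (3) entries without any of these annotations are assumed
    to already be in mature form.
    """
    seq = entry.sequence
    spans = [
        (ft.start, ft.end)
        for ft in entry.features
        if ft.kind in (FeatureKind.CHAIN, FeatureKind.PEPTIDE) and ft.fully_known
    ]
    if spans:
        start, end = max(spans, key=lambda se: (se[1] - se[0], -se[0]))
        mature = seq[start - 1 : end]
        if not mature:
            raise DerivationError(f"{entry.accession}: empty chain/peptide span")
        return MatureSequence(mature, MatureMethod.CHAIN_PEPTIDE)

    removable = [
        ft
        for ft in entry.features
        if ft.kind in (FeatureKind.SIGNAL, FeatureKind.PROPEP) and ft.fully_known
    ]
    if removable:
        keep = [True] * len(seq)
        for ft in removable:
            for i in range(ft.start - 1, ft.end):
                keep[i] = False
        mature = "".join(c for c, k in zip(seq, keep) if k)
        if not mature:
            raise DerivationError(
                f"{entry.accession}: sequence empty after signal/propeptide removal"
            )
        return MatureSequence(mature, MatureMethod.SIGNAL_PROPEP_REMOVED)

    return MatureSequence(seq, MatureMethod.AS_IS)


def bin_length(length: int, width: int = 25) -> str:
    """Closed-range length bin label, e.g. 26 -> "26-50" at width 25."""
    if length < 1:
        raise ValueError(f"length must be >= 1, got {length}")
    lo = ((length - 1) // width) * width + 1
    return f"{lo}-{lo + width - 1}"


def is_fragment(entry: ProteinEntry) -> bool:
    """Fragment = explicit description flag, or any signal peptide,
    propeptide, chain or peptide feature with an incomplete range."""
    if entry.is_fragment:
        return True
    return any(
        ft.kind in STRUCTURAL_KINDS and not ft.fully_known for ft in entry.features
    )


# ---------------------------------------------------------------------------
# PTM accounting

#: categories always present in a profile (counts may be zero)
PTM_CATEGORIES = (
    "Disulfide bond",
    "Amidation",
    "Glycosylation",
    "Hydroxylation",
    "Pyrrolidone carboxylic acid",
    "Gamma-carboxyglutamic acid",
    "Cross-link",
    "Lipidation",
    "Other",
)

_FEATURE_CATEGORY = {
    FeatureKind.DISULFID: "Disulfide bond",
    FeatureKind.CARBOHYD: "Glycosylation",
    FeatureKind.CROSSLNK: "Cross-link",
    FeatureKind.LIPID: "Lipidation",
}

#: PTM-related KW-line keywords -> category (the parallel, coarser
#: keyword-based accounting; the two sources can disagree)
PTM_KEYWORD_CATEGORIES = {
    "Disulfide bond": "Disulfide bond",
    "Amidation": "Amidation",
    "Glycoprotein": "Glycosylation",
    "Hydroxylation": "Hydroxylation",
    "Pyrrolidone carboxylic acid": "Pyrrolidone carboxylic acid",
    "Gamma-carboxyglutamic acid": "Gamma-carboxyglutamic acid",
    "Isopeptide bond": "Cross-link",
    "Lipoprotein": "Lipidation",
}


@dataclass
class PtmVocabulary:
    """Modified-residue description -> category, from a ptmlist-format file.

    Lookup is case-insensitive; unknown descriptions map to "Other" with
    a warning.
    """

    records: Dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.records = {k.lower(): v for k, v in self.records.items()}

    def categorize(self, description: str) -> str:
        key = description.strip().lower()
        cat = self.records.get(key)
        if cat is None:
            log.warning("modified residue %r not in PTM vocabulary; counting as Other",
                        description)
            return "Other"
        return cat

    @classmethod
    def from_ptmlist(cls, text: str) -> "PtmVocabulary":
        records: Dict[str, str] = {}
        current_id: Optional[str] = None
        for line in text.splitlines():
            if line.startswith("ID   "):
                current_id = line[5:].strip()
            elif line.startswith("KW   ") and current_id is not None:
                records[current_id] = line[5:].strip().rstrip(".")
            elif line.startswith("//"):
                current_id = None
        return cls(records=records)

    @classmethod
    def from_file(cls, path) -> "PtmVocabulary":
        with open(path) as fh:
            return cls.from_ptmlist(fh.read())

    @classmethod
    def load_default(cls) -> "PtmVocabulary":
        text = (
            resources.files("toxprotkit.data") / "ptmlist_seed.txt"
        ).read_text()
        return cls.from_ptmlist(text)


@dataclass
class PTMProfile:
    """Per-feature PTM counts by standardized category."""

    counts: Counter = field(default_factory=Counter)

    @property
    def total(self) -> int:
        return sum(self.counts.values())

    @property
    def has_annotation(self) -> bool:
        return self.total > 0

    def as_dict(self) -> Dict[str, int]:
        return {cat: self.counts.get(cat, 0) for cat in PTM_CATEGORIES}


def ptm_profile(entry: ProteinEntry, vocab: PtmVocabulary) -> PTMProfile:
    """Feature-based PTM profile: one count per annotated feature.

    Disulfide bonds count one per DISULFID feature (interchain bonds
    included); CARBOHYD, CROSSLNK and LIPID features map to fixed
    categories; MOD_RES descriptions go through the controlled
    vocabulary.
    """
    counts: Counter = Counter()
    for ft in entry.features:
        if ft.kind in _FEATURE_CATEGORY:
            counts[_FEATURE_CATEGORY[ft.kind]] += 1
        elif ft.kind is FeatureKind.MOD_RES:
            counts[vocab.categorize(ft.description)] += 1
    return PTMProfile(counts=counts)


def has_ptm_keyword(entry: ProteinEntry) -> bool:
    """Keyword-based PTM flag (the parallel KW-line accounting)."""
    return any(kw in PTM_KEYWORD_CATEGORIES for kw in entry.keywords)


# ---------------------------------------------------------------------------
# toxic dose


class Route(str, Enum):
    IV = "intravenous"
    IP = "intraperitoneal"
    SC = "subcutaneous"
    ICV = "intracerebroventricular"
    OTHER = "other_or_unstated"


_ROUTE_PATTERNS = (
    (re.compile(r"intravenous|\bi\.v\.", re.I), Route.IV),
    (re.compile(r"intraperitoneal|\bi\.p\.", re.I), Route.IP),
    (re.compile(r"subcutaneous|\bs\.c\.", re.I), Route.SC),
    (re.compile(r"intracerebroventricular|\bi\.c\.v\.", re.I), Route.ICV),
)

_MOUSE_RE = re.compile(r"mouse|mice", re.I)


@dataclass(frozen=True)
class ToxicDoseRecord:
    raw: str
    mouse_tested: bool
    route: Route


def parse_toxic_dose(texts: Sequence[str]) -> List[ToxicDoseRecord]:
    """Flag each TOXIC DOSE text for mouse testing and administration route.

    The route is the first matching keyword in the order intravenous,
    intraperitoneal, subcutaneous, intracerebroventricular (full words or
    the dotted abbreviations); texts matching none are OTHER/UNSTATED.
    """
    records = []
    for text in texts:
        route = Route.OTHER
        for pattern, r in _ROUTE_PATTERNS:
            if pattern.search(text):
                route = r
                break
        records.append(
            ToxicDoseRecord(
                raw=text, mouse_tested=bool(_MOUSE_RE.search(text)), route=route
            )
        )
    return records


# ---------------------------------------------------------------------------
# GO coverage


def go_coverage(dataset: Dataset) -> Dict[str, float]:
    """Percentage of entries with >= 1 GO term per aspect (F, P, C)."""
    n = len(dataset)
    if n < 1:
        raise ValueError("go_coverage requires a non-empty dataset")
    out = {}
    for aspect in ("F", "P", "C"):
        k = sum(1 for e in dataset if any(g.aspect == aspect for g in e.go_refs))
        out[aspect] = percent(k, n)
    return out
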