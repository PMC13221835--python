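"""Embedding-based evaluation of protein-family separation.

Five sequence-processing variants are compared: the full precursor,
signal peptide removed, signal peptide removed without fragments, signal
and propeptide removed, and signal and propeptide removed without
fragments.  Each variant's sequences are embedded through a pluggable
provider — any deterministic mapping from sequences to fixed-length
vectors — and family separation is scored by the mean silhouette over
family labels (Euclidean distance, computed in the full embedding
space).

The packaged provider is a k-mer composition embedder: deterministic,
download-free and sufficient to rank variants on fixtures with planted
family structure.  An adapter for an external protein language model can
be supplied as any callable with the same signature.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass
from enum import Enum
from itertools import product
from typing import Callable, Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
from sklearn.metrics import silhouette_score

from .metrics import UNASSIGNED
from .sequence_features import is_fragment
from .swissprot_io import Dataset, FeatureKind, ProteinEntry

log = logging.getLogger(__name__)

__all__ = [
    "Variant",
    "EmbeddingMatrix",
    "SilhouetteReport",
    "SilhouetteError",
    "prepare_variant",
    "mock_embed",
    "KmerEmbedder",
    "silhouette_by_family",
    "compare_variants",
]

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"


class Variant(str, Enum):
    """The five sequence-processing variants, in canonical order."""

    FULL = "full"
    SIGNAL_REMOVED = "signal_removed"
    SIGNAL_REMOVED_NOFRAG = "signal_removed_nofrag"
    SIGNAL_PROPEP_REMOVED = "signal_propep_removed"
    SIGNAL_PROPEP_REMOVED_NOFRAG = "signal_propep_removed_nofrag"


_VARIANT_KINDS = {
    Variant.FULL: frozenset(),
    Variant.SIGNAL_REMOVED: frozenset({FeatureKind.SIGNAL}),
    Variant.SIGNAL_REMOVED_NOFRAG: frozenset({FeatureKind.SIGNAL}),
    Variant.SIGNAL_PROPEP_REMOVED: frozenset({FeatureKind.SIGNAL, FeatureKind.PROPEP}),
    Variant.SIGNAL_PROPEP_REMOVED_NOFRAG: frozenset(
        {FeatureKind.SIGNAL, FeatureKind.PROPEP}
    ),
}

_VARIANT_NOFRAG = {
    Variant.SIGNAL_REMOVED_NOFRAG,
    Variant.SIGNAL_PROPEP_REMOVED_NOFRAG,
}


class SilhouetteError(ValueError):
    """Fewer than two eligible families after restriction."""


def _excise(sequence: str, entry: ProteinEntry, kinds: frozenset) -> str:
    if not kinds:
        return sequence
    keep = [True] * len(sequence)
    for ft in entry.features:
        if ft.kind in kinds and ft.fully_known:
            for i in range(ft.start - 1, ft.end):
                keep[i] = False
    return "".join(c for c, k in zip(sequence, keep) if k)


def prepare_variant(
    dataset: Dataset, variant: Variant
) -> List[Tuple[str, str]]:
    """(accession, processed sequence) pairs for one variant.

    Fully-known SIGNAL (and, for the propeptide variants, PROPEP) spans
    are excised from the precursor; the fragment-free variants
    additionally drop fragment entries.  Entries whose processed
    sequence is empty are dropped with a warning.
    """
    variant = Variant(variant)
    kinds = _VARIANT_KINDS[variant]
    nofrag = variant in _VARIANT_NOFRAG
    out: List[Tuple[str, str]] = []
    for entry in dataset:
        if nofrag and is_fragment(entry):
            continue
        seq = _excise(entry.sequence, entry, kinds)
        if not seq:
            log.warning(
                "%s: empty sequence under variant %s; dropped",
                entry.accession,
                variant.value,
            )
            continue
        out.append((entry.accession, seq))
    return out


@dataclass
class EmbeddingMatrix:
    """Ordered accessions and one fixed-length real vector per accession."""

    ids: Tuple[str, ...]
    vectors: np.ndarray  # shape (n, dim)

    def __post_init__(self) -> None:
        self.ids = tuple(self.ids)
        self.vectors = np.asarray(self.vectors, dtype=float)
        if self.vectors.ndim != 2 or len(self.ids) != self.vectors.shape[0]:
            raise ValueError("ids and vectors disagree in length")
        if not np.isfinite(self.vectors).all():
            raise ValueError("embedding matrix contains non-finite values")

    @property
    def dim(self) -> int:
        return int(self.vectors.shape[1])


def mock_embed(sequences: Sequence[Tuple[str, str]], k: int = 2) -> EmbeddingMatrix:
    """Deterministic k-mer composition embedding (dim = 20**k).

    Each vector holds the frequency of every length-k word over the
    standard 20-letter alphabet (counts normalized to sum to 1); k-mers
    containing non-standard letters are skipped.  Sequences shorter than
    k embed as a zero vector with a warning.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if not sequences:
        raise ValueError("no sequences to embed")
    index = {
        "".join(word): i for i, word in enumerate(product(AMINO_ACIDS, repeat=k))
    }
    dim = len(AMINO_ACIDS) ** k
    vectors = np.zeros((len(sequences), dim))
    ids = []
    for row, (acc, seq) in enumerate(sequences):
        ids.append(acc)
        if len(seq) < k:
            log.warning("%s: sequence shorter than k=%d; zero vector", acc, k)
            continue
        total = 0
        for i in range(len(seq) - k + 1):
            j = index.get(seq[i : i + k])
            if j is not None:
                vectors[row, j] += 1
                total += 1
        if total:
            vectors[row] /= total
    return EmbeddingMatrix(ids=tuple(ids), vectors=vectors)


class KmerEmbedder:
    """Provider wrapper fixing ``k`` for :func:`mock_embed`."""

    def __init__(self, k: int = 2):
        self.k = k

    def __call__(self, sequences: Sequence[Tuple[str, str]]) -> EmbeddingMatrix:
        return mock_embed(sequences, k=self.k)


@dataclass
class SilhouetteReport:
    variant: Variant
    mean_silhouette: float
    n_proteins: int
    n_families: int
    selected: bool = False

    def as_dict(self) -> dict:
        return {
            "variant": self.variant.value,
            "mean_silhouette": self.mean_silhouette,
            "n_proteins": self.n_proteins,
            "n_families": self.n_families,
            "selected": self.selected,
        }


def silhouette_by_family(
    matrix: EmbeddingMatrix,
    labels: Mapping[str, Optional[str]],
    top_n: int,
    variant: Variant = Variant.FULL,
) -> SilhouetteReport:
    """Mean silhouette over family labels in the embedding space.

    Points are restricted to the ``top_n`` most populous families
    (unlabeled and Unassigned entries excluded, as are families left
    with fewer than two members).  All points identical is a degenerate
    configuration scored as 0 by convention.
    """
    labelled = [
        (i, labels[acc])
        for i, acc in enumerate(matrix.ids)
        if labels.get(acc) not in (None, UNASSIGNED)
    ]
    counts: Dict[str, int] = {}
    for _, fam in labelled:
        counts[fam] = counts.get(fam, 0) + 1
    top = {
        fam
        for fam, _ in sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))[:top_n]
        if counts[fam] >= 2
    }
    keep = [(i, fam) for i, fam in labelled if fam in top]
    families = {fam for _, fam in keep}
    if len(families) < 2:
        raise SilhouetteError(
            f"need >= 2 families with >= 2 members, found {len(families)}"
        )
    rows = np.array([i for i, _ in keep])
    X = matrix.vectors[rows]
    y = np.array([fam for _, fam in keep])
    if np.allclose(X, X[0]):
        log.warning("all embedded points identical; silhouette defined as 0")
        score = 0.0
    else:
        score = float(silhouette_score(X, y, metric="euclidean"))
    return SilhouetteReport(
        variant=variant,
        mean_silhouette=score,
        n_proteins=len(keep),
        n_families=len(families),
    )


def compare_variants(
    dataset: Dataset,
    labels: Mapping[str, Optional[str]],
    provider: Callable[[Sequence[Tuple[str, str]]], EmbeddingMatrix],
    top_n: int = 10,
) -> List[SilhouetteReport]:
    """Score all five variants, in canonical order, with one provider.

    The highest-scoring variant is flagged ``selected``.
    """
    reports = []
    for variant in Variant:
        pairs = prepare_variant(dataset, variant)
        try:
            matrix = provider(pairs)
        except Exception as exc:
            raise RuntimeError(f"embedding provider failed on variant {variant.value}") from exc
        report = silhouette_by_family(matrix, labels, top_n, variant=variant)
        reports.append(report)
    best = max(range(len(reports)), key=lambda i: reports[i].mean_silhouette)
    reports[best].selected = True
    return reports
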