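"""Dual selection criteria for venom-related entries.

The curated venom dataset is defined by two complementary, non-exclusive
criteria applied within Metazoa (taxid 33208): (i) the TISSUE SPECIFICITY
comment mentions "venom" (venom-tissue definition), and (ii) the entry
carries the "Toxin" controlled-vocabulary keyword (KW-0800).  Every entry
falls into exactly one of four classes: venom-tissue only, toxin-keyword
only, both, or excluded.
"""
from __future__ import annotations

import logging
from collections import Counter
from enum import Enum

from .annotation import LineageError, TaxonomyTable, is_metazoan
from .swissprot_io import Dataset, ProteinEntry

log = logging.getLogger(__name__)

__all__ = ["CriterionClass", "Definition", "classify_criteria", "filter_dataset",
           "class_counts", "TOXIN_KEYWORD"]

#: canonical name of keyword KW-0800 as carried on flat-file KW lines
TOXIN_KEYWORD = "Toxin"


class CriterionClass(str, Enum):
    VENOM_TISSUE_ONLY = "venom_tissue_only"
    TOXIN_KEYWORD_ONLY = "toxin_keyword_only"
    BOTH = "both"
    EXCLUDED = "excluded"


class Definition(str, Enum):
    """Which criterion defines the working dataset."""

    VENOM_TISSUE = "venom_tissue"
    TOXIN_KEYWORD = "toxin_keyword"
    UNION = "union"


_DEFINITION_CLASSES = {
    Definition.VENOM_TISSUE: {CriterionClass.VENOM_TISSUE_ONLY, CriterionClass.BOTH},
    Definition.TOXIN_KEYWORD: {CriterionClass.TOXIN_KEYWORD_ONLY, CriterionClass.BOTH},
    Definition.UNION: {
        CriterionClass.VENOM_TISSUE_ONLY,
        CriterionClass.TOXIN_KEYWORD_ONLY,
        CriterionClass.BOTH,
    },
}


def classify_criteria(entry: ProteinEntry, taxonomy: TaxonomyTable) -> CriterionClass:
    """Classify one entry against the dual criteria.

    Entries outside Metazoa are excluded outright; an unresolvable taxid
    is excluded with a logged warning rather than a hard error.  The
    "venom" match is a case-insensitive substring over the full tissue
    specificity text, so "venom gland" and "venom duct" both match.
    """
    try:
        if not is_metazoan(entry.taxid, taxonomy):
            return CriterionClass.EXCLUDED
    except LineageError:
        log.warning(
            "%s: taxid %d unresolvable; excluding entry", entry.accession, entry.taxid
        )
        return CriterionClass.EXCLUDED
    tissue = (
        entry.tissue_specificity is not None
        and "venom" in entry.tissue_specificity.lower()
    )
    keyword = TOXIN_KEYWORD in entry.keywords
    if tissue and keyword:
        return CriterionClass.BOTH
    if tissue:
        return CriterionClass.VENOM_TISSUE_ONLY
    if keyword:
        return CriterionClass.TOXIN_KEYWORD_ONLY
    return CriterionClass.EXCLUDED


def filter_dataset(
    dataset: Dataset, taxonomy: TaxonomyTable, definition: Definition
) -> Dataset:
    """Sub-dataset satisfying the chosen definition, input order preserved."""
    wanted = _DEFINITION_CLASSES[Definition(definition)]
    kept = [e for e in dataset if classify_criteria(e, taxonomy) in wanted]
    return Dataset(year=dataset.year, entries=kept)


def class_counts(dataset: Dataset, taxonomy: TaxonomyTable) -> Counter:
    """Counter of criterion classes over a dataset (partition check aid)."""
    return Counter(classify_criteria(e, taxonomy) for e in dataset)
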