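"""Taxonomic lineage resolution, habitat classification and protein-family
name normalization.

Lineages are resolved from a local table mirroring the structure of the
NCBI taxonomy dump (taxid, parent taxid, rank, name, plus an optional
merged-id file mapping deprecated identifiers to current ones).  Habitat
is assigned by a two-tier lookup: first by taxonomic order, then by genus
for orders that span both terrestrial and marine habitats (e.g. within
Squamata: Crotalus is terrestrial, Hydrophis is marine).

Family names from the SIMILARITY comment are normalized by truncating at
the first period/comma/semicolon, expanding bare conotoxin superfamily
codes ("I1 superfamily" -> "Conotoxin I1 superfamily"), and applying an
alias map that links families renamed across release years.
"""
from __future__ import annotations

import csv
import logging
import re
from dataclasses import dataclass, field
from enum import Enum
from importlib import resources
from pathlib import Path
from typing import Dict, Mapping, Optional, Tuple

log = logging.getLogger(__name__)

__all__ = [
    "METAZOA_TAXID",
    "Habitat",
    "OrderHabitat",
    "TaxonomyTable",
    "Lineage",
    "HabitatTable",
    "FamilyNormalizer",
    "LineageError",
    "HabitatError",
    "NormalizationError",
    "resolve_lineage",
    "classify_habitat",
    "normalize_family",
]

#: NCBI taxid of the Metazoa (animal kingdom) root used by the selection query
METAZOA_TAXID = 33208

_RANKS = ("phylum", "class", "order", "family", "genus", "species")


class LineageError(KeyError):
    """A taxid cannot be resolved against the taxonomy table."""


class HabitatError(KeyError):
    """A lineage is not covered by the habitat lookup tables."""


class NormalizationError(ValueError):
    """A family string is empty after truncation."""


class Habitat(str, Enum):
    TERRESTRIAL = "terrestrial"
    MARINE = "marine"


class OrderHabitat(str, Enum):
    TERRESTRIAL = "terrestrial"
    MARINE = "marine"
    MIXED = "mixed"


@dataclass
class TaxonomyTable:
    """taxid -> (parent taxid, rank, name), plus deprecated-id remapping."""

    records: Dict[int, Tuple[int, str, str]] = field(default_factory=dict)
    deprecated_map: Dict[int, int] = field(default_factory=dict)

    def add(self, taxid: int, parent: int, rank: str, name: str) -> None:
        self.records[taxid] = (parent, rank, name)

    def current_id(self, taxid: int) -> int:
        return self.deprecated_map.get(taxid, taxid)

    def chain(self, taxid: int):
        """Walk parent links from ``taxid`` to the root, yielding
        (taxid, rank, name) including the start node."""
        tid = self.current_id(taxid)
        seen = set()
        while True:
            if tid in seen:
                raise LineageError(f"cycle in taxonomy at taxid {tid}")
            seen.add(tid)
            if tid not in self.records:
                raise LineageError(f"unknown taxid {tid}")
            parent, rank, name = self.records[tid]
            yield tid, rank, name
            if parent == tid or tid == 1:
                return
            tid = parent

    @classmethod
    def from_tsv(cls, nodes_path, merged_path=None) -> "TaxonomyTable":
        table = cls()
        with open(nodes_path, newline="") as fh:
            for row in csv.reader(fh, delimiter="\t"):
                if not row or row[0].startswith("#"):
                    continue
                taxid, parent, rank, name = row[:4]
                table.add(int(taxid), int(parent), rank, name)
        if merged_path is not None and Path(merged_path).exists():
            with open(merged_path, newline="") as fh:
                for row in csv.reader(fh, delimiter="\t"):
                    if not row or row[0].startswith("#"):
                        continue
                    table.deprecated_map[int(row[0])] = int(row[1])
        return table

    def to_tsv(self, nodes_path, merged_path=None) -> None:
        with open(nodes_path, "w", newline="") as fh:
            w = csv.writer(fh, delimiter="\t", lineterminator="\n")
            for taxid in sorted(self.records):
                parent, rank, name = self.records[taxid]
                w.writerow([taxid, parent, rank, name])
        if merged_path is not None:
            with open(merged_path, "w", newline="") as fh:
                w = csv.writer(fh, delimiter="\t", lineterminator="\n")
                for old in sorted(self.deprecated_map):
                    w.writerow([old, self.deprecated_map[old]])


@dataclass(frozen=True)
class Lineage:
    """The six named ranks collected from a parent-chain walk."""

    taxid: int
    phylum: Optional[str] = None
    class_: Optional[str] = None
    order: Optional[str] = None
    family: Optional[str] = None
    genus: Optional[str] = None
    species: Optional[str] = None
    species_taxid: Optional[int] = None

    def rank_name(self, rank: str) -> Optional[str]:
        return getattr(self, "class_" if rank == "class" else rank)

    @property
    def species_key(self):
        """Identity used for species counting: species-rank taxid when
        resolved, else the species name string."""
        return self.species_taxid if self.species_taxid is not None else self.species


def resolve_lineage(taxid: int, table: TaxonomyTable) -> Lineage:
    """Resolve a taxid (deprecated ids remapped first) to its lineage."""
    current = table.current_id(taxid)
    fields: Dict[str, Optional[str]] = {}
    species_taxid = None
    for tid, rank, name in table.chain(current):
        if rank == "species":
            fields.setdefault("species", name)
            if species_taxid is None:
                species_taxid = tid
        elif rank == "class":
            fields.setdefault("class_", name)
        elif rank in _RANKS:
            fields.setdefault(rank, name)
    return Lineage(taxid=current, species_taxid=species_taxid, **fields)


def is_metazoan(taxid: int, table: TaxonomyTable) -> bool:
    """True if the Metazoa root lies on the taxid's parent chain."""
    return any(tid == METAZOA_TAXID for tid, _, _ in table.chain(taxid))


@dataclass
class HabitatTable:
    """Two-tier habitat lookup: order-level, with genus-level override for
    orders spanning both habitats."""

    order_map: Dict[str, OrderHabitat] = field(default_factory=dict)
    genus_map: Dict[str, Habitat] = field(default_factory=dict)

    @classmethod
    def from_tsv(cls, order_path, genus_path) -> "HabitatTable":
        table = cls()
        with open(order_path, newline="") as fh:
            for row in csv.reader(fh, delimiter="\t"):
                if not row or row[0].startswith("#"):
                    continue
                table.order_map[row[0]] = OrderHabitat(row[1].strip().lower())
        with open(genus_path, newline="") as fh:
            for row in csv.reader(fh, delimiter="\t"):
                if not row or row[0].startswith("#"):
                    continue
                table.genus_map[row[0]] = Habitat(row[1].strip().lower())
        return table

    def to_tsv(self, order_path, genus_path) -> None:
        with open(order_path, "w", newline="") as fh:
            w = csv.writer(fh, delimiter="\t", lineterminator="\n")
            for name in sorted(self.order_map):
                w.writerow([name, self.order_map[name].value])
        with open(genus_path, "w", newline="") as fh:
            w = csv.writer(fh, delimiter="\t", lineterminator="\n")
            for name in sorted(self.genus_map):
                w.writerow([name, self.genus_map[name].value])

    @classmethod
    def load_default(cls) -> "HabitatTable":
        """The packaged seed tables covering documented assignments."""
        base = resources.files("toxprotkit.data")
        with resources.as_file(base / "habitat_order.tsv") as op, resources.as_file(
            base / "habitat_genus.tsv"
        ) as gp:
            return cls.from_tsv(op, gp)


def classify_habitat(lineage: Lineage, table: HabitatTable) -> Habitat:
    """Assign terrestrial/marine habitat via the two-tier lookup.

    Raises :class:`HabitatError` when the order is not in the table, or
    when a mixed-habitat order lacks a genus-level entry — habitat totals
    must partition the dataset, so there is no silent "unknown" bucket.
    """
    if lineage.order is None:
        raise HabitatError(f"taxid {lineage.taxid}: no order rank on lineage")
    oh = table.order_map.get(lineage.order)
    if oh is None:
        raise HabitatError(f"order {lineage.order!r} not in habitat table")
    if oh is not OrderHabitat.MIXED:
        return Habitat(oh.value)
    if lineage.genus is None or lineage.genus not in table.genus_map:
        raise HabitatError(
            f"mixed-habitat order {lineage.order!r}: genus "
            f"{lineage.genus!r} not in genus table"
        )
    return table.genus_map[lineage.genus]


# ---------------------------------------------------------------------------
# family-name normalization

#: a bare 1-3 character superfamily code missing the word "Conotoxin"
_CONOTOXIN_BARE_RE = re.compile(r"^[A-Za-z0-9]{1,3} superfamily$")


@dataclass
class FamilyNormalizer:
    """Normalize SIMILARITY family clauses to canonical cross-year names."""

    alias_map: Dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for target in self.alias_map.values():
            if self.normalize(target) != target:
                raise ValueError(
                    f"alias target {target!r} is not a normalization fixed point"
                )

    def normalize(self, raw: str) -> str:
        s = re.split(r"[.,;]", raw, maxsplit=1)[0].strip()
        if not s:
            raise NormalizationError(f"family name empty after truncation: {raw!r}")
        if _CONOTOXIN_BARE_RE.match(s):
            s = "Conotoxin " + s
        return self.alias_map.get(s, s)

    @classmethod
    def from_tsv(cls, path) -> "FamilyNormalizer":
        alias: Dict[str, str] = {}
        with open(path, newline="") as fh:
            for row in csv.reader(fh, delimiter="\t"):
                if not row or row[0].startswith("#"):
                    continue
                alias[row[0]] = row[1]
        return cls(alias_map=alias)

    @classmethod
    def load_default(cls) -> "FamilyNormalizer":
        base = resources.files("toxprotkit.data")
        with resources.as_file(base / "family_aliases.tsv") as p:
            return cls.from_tsv(p)


def normalize_family(raw: str, normalizer: FamilyNormalizer) -> str:
    """Functional wrapper around :meth:`FamilyNormalizer.normalize`."""
    return normalizer.normalize(raw)
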