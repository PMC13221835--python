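"""Synthetic Swiss-Prot flat-file fixtures with exact ground truth.

The generator emits complete DAT snapshots plus the taxonomy and habitat
tables covering every generated taxon, together with a
:class:`SnapshotTruth` that is pure bookkeeping of what was emitted —
criterion classes, species/order/family sets, fragment status, mature
lengths, PTM category totals, habitat assignments, evidence levels — so
every pipeline stage can be checked for exact recovery without any
downloads.

The default configuration mirrors the gross statistical shape of curated
venom data: a handful of dominant orders (snakes, spiders, cone snails,
scorpions), short disulfide-rich mature peptides (most 26-75 aa) with a
minority enzyme component of several hundred residues, roughly a sixth
of entries flagged as fragments, and about a fifth of entries of marine
origin.  Sequences are built as optional random signal peptide +
optional propeptide + a family-specific mature core (a shared motif per
family with light per-entry mutation), which plants the family structure
that the embedding evaluation is expected to recover once signal
peptides are removed.
"""
from __future__ import annotations

import logging
import math
from collections import Counter
from dataclasses import dataclass, field, replace
from typing import Dict, List, Mapping, Optional, Sequence, Set, Tuple

import numpy as np

from .annotation import Habitat, HabitatTable, OrderHabitat, TaxonomyTable
from .swissprot_io import (
    Dataset,
    Feature,
    FeatureKind,
    GoRef,
    ProteinEntry,
    write_dat,
)

log = logging.getLogger(__name__)

__all__ = [
    "OrderSpec",
    "FamilySpec",
    "SyntheticConfig",
    "SnapshotTruth",
    "ComparisonTruth",
    "GenerationResult",
    "SnapshotSeries",
    "ConfigError",
    "generate",
    "generate_snapshot_series",
    "DEFAULT_ORDERS",
    "DEFAULT_FAMILIES",
]

AA = "ACDEFGHIKLMNPQRSTVWY"

AA_NAMES = {
    "A": "Alanine", "C": "Cysteine", "D": "Aspartate", "E": "Glutamate",
    "F": "Phenylalanine", "G": "Glycine", "H": "Histidine", "I": "Isoleucine",
    "K": "Lysine", "L": "Leucine", "M": "Methionine", "N": "Asparagine",
    "P": "Proline", "Q": "Glutamine", "R": "Arginine", "S": "Serine",
    "T": "Threonine", "V": "Valine", "W": "Tryptophan", "Y": "Tyrosine",
}

_CATEGORY_KEYWORD = {
    "Disulfide bond": "Disulfide bond",
    "Amidation": "Amidation",
    "Glycosylation": "Glycoprotein",
    "Hydroxylation": "Hydroxylation",
    "Pyrrolidone carboxylic acid": "Pyrrolidone carboxylic acid",
    "Gamma-carboxyglutamic acid": "Gamma-carboxyglutamic acid",
    "Cross-link": "Isopeptide bond",
    "Lipidation": "Lipoprotein",
}

_GO_TERMS = {
    "F": (("GO:0090729", "toxin activity"),
          ("GO:0019871", "sodium channel inhibitor activity"),
          ("GO:0015459", "potassium channel regulator activity")),
    "P": (("GO:0006952", "defense response"),
          ("GO:0044179", "hemolysis in another organism")),
    "C": (("GO:0005576", "extracellular region"),
          ("GO:0005615", "extracellular space")),
}

_EPITHETS = ("alpha", "beta", "gamma", "delta", "epsilon", "zeta", "eta", "theta")


class ConfigError(ValueError):
    """Inconsistent synthetic-data configuration."""


@dataclass(frozen=True)
class OrderSpec:
    """One taxonomic order the generator can emit."""

    order: str
    phylum: str
    class_: str
    genera: Tuple[str, ...]
    habitat: str  # terrestrial | marine | mixed
    weight: float
    genus_habitats: Optional[Mapping[str, str]] = None  # required when mixed


@dataclass(frozen=True)
class FamilySpec:
    """One protein family: the raw SIMILARITY text, its canonical
    post-normalization name (bookkeeping, not re-derived), the orders it
    occurs in, and its typical mature length."""

    raw: str
    canonical: str
    weight: float
    orders: Optional[Tuple[str, ...]] = None  # None = any order
    mature_len: int = 40


DEFAULT_ORDERS: Tuple[OrderSpec, ...] = (
    OrderSpec("Squamata", "Chordata", "Lepidosauria",
              ("Crotalus", "Naja", "Hydrophis", "Laticauda"), "mixed", 0.34,
              {"Crotalus": "terrestrial", "Naja": "terrestrial",
               "Hydrophis": "marine", "Laticauda": "marine"}),
    OrderSpec("Araneae", "Arthropoda", "Arachnida",
              ("Latrodectus", "Atrax", "Cyriopagopus"), "terrestrial", 0.20),
    OrderSpec("Neogastropoda", "Mollusca", "Gastropoda",
              ("Conus", "Terebra", "Turris"), "marine", 0.18),
    OrderSpec("Scorpiones", "Arthropoda", "Arachnida",
              ("Androctonus", "Centruroides", "Leiurus"), "terrestrial", 0.14),
    OrderSpec("Hymenoptera", "Arthropoda", "Insecta",
              ("Apis", "Vespa"), "terrestrial", 0.08),
    OrderSpec("Scolopendromorpha", "Arthropoda", "Chilopoda",
              ("Scolopendra",), "terrestrial", 0.04),
    OrderSpec("Myliobatiformes", "Chordata", "Chondrichthyes",
              ("Potamotrygon",), "marine", 0.02),
)

DEFAULT_FAMILIES: Tuple[FamilySpec, ...] = (
    FamilySpec("phospholipase A2 family. Group I subfamily",
               "phospholipase A2 family", 0.15,
               ("Squamata", "Hymenoptera"), 122),
    FamilySpec("Snake toxin family", "Snake three-finger toxin family", 0.14,
               ("Squamata",), 62),
    FamilySpec("Long (4 C-C) scorpion toxin family",
               "Long (4 C-C) scorpion toxin family", 0.10,
               ("Scorpiones",), 64),
    FamilySpec("Short scorpion toxin family", "Short scorpion toxin family",
               0.06, ("Scorpiones",), 36),
    FamilySpec("I1 superfamily", "Conotoxin I1 superfamily", 0.07,
               ("Neogastropoda",), 50),
    FamilySpec("O1 superfamily", "Conotoxin O1 superfamily", 0.07,
               ("Neogastropoda",), 30),
    FamilySpec("Conotoxin A superfamily", "Conotoxin A superfamily", 0.04,
               ("Neogastropoda",), 16),
    FamilySpec("Huwentoxin-1 family", "Neurotoxin 10 (Hwtx-1) family", 0.08,
               ("Araneae",), 35),
    FamilySpec("Venom Kunitz-type family", "Venom Kunitz-type family", 0.06,
               ("Squamata", "Neogastropoda", "Araneae"), 58),
    FamilySpec("Venom metalloproteinase (M12B) family",
               "Venom metalloproteinase (M12B) family", 0.05,
               ("Squamata",), 420),
    FamilySpec("Peptidase S1 family. Snake venom subfamily",
               "Peptidase S1 family", 0.05, ("Squamata",), 236),
    FamilySpec("MCD family", "MCD family", 0.04, ("Hymenoptera",), 22),
    FamilySpec("Scoloptoxin-01 family", "Scoloptoxin-01 family", 0.04,
               ("Scolopendromorpha",), 45),
    FamilySpec("Orpotrin family", "Orpotrin family", 0.02,
               ("Myliobatiformes",), 14),
    FamilySpec("Non-disulfide-bridged peptide (NDBP) superfamily",
               "Non-disulfide-bridged peptide (NDBP) superfamily", 0.02,
               ("Scorpiones",), 28),
)


def _default_ptm_rates() -> Dict[str, float]:
    return {
        "Disulfide bond": 3.5,
        "Amidation": 0.35,
        "Glycosylation": 0.25,
        "Hydroxylation": 0.12,
        "Pyrrolidone carboxylic acid": 0.08,
        "Gamma-carboxyglutamic acid": 0.05,
        "Cross-link": 0.03,
        "Lipidation": 0.02,
    }


@dataclass(frozen=True)
class SyntheticConfig:
    """Study-condition knobs for fixture generation (all defaults are the
    generator's standing conditions; ground truth is bookkeeping, never a
    target)."""

    seed: int = 0
    n_entries: int = 200
    order_spec: Tuple[OrderSpec, ...] = DEFAULT_ORDERS
    family_spec: Tuple[FamilySpec, ...] = DEFAULT_FAMILIES
    fraction_unassigned: float = 0.07
    fraction_fragment: float = 0.17
    fraction_signal: float = 0.70
    fraction_propep: float = 0.30
    fraction_chain: float = 0.50
    ptm_rates: Mapping[str, float] = field(default_factory=_default_ptm_rates)
    ptm_keyword_rate: float = 0.92
    ptm_keyword_only_rate: float = 0.05
    dose_rate: float = 0.08
    mouse_rate: float = 0.40
    route_weights: Mapping[str, float] = field(
        default_factory=lambda: {"iv": 0.33, "ip": 0.25, "sc": 0.18,
                                 "icv": 0.10, "other": 0.14}
    )
    go_rate: Mapping[str, float] = field(
        default_factory=lambda: {"F": 0.90, "P": 0.45, "C": 0.95}
    )
    evidence_probs: Mapping[int, float] = field(
        default_factory=lambda: {1: 0.60, 2: 0.26, 3: 0.12, 4: 0.01, 5: 0.01}
    )
    #: probabilities for (venom-tissue only, toxin-keyword only, both, neither)
    criterion_mix: Tuple[float, float, float, float] = (0.45, 0.15, 0.35, 0.05)
    species_per_genus: int = 3
    deprecated_rate: float = 0.03
    mutation_rate: float = 0.08
    enzyme_weight: float = 0.12  # unassigned-entry length mixture
    signal_len_range: Tuple[int, int] = (15, 30)
    propep_len_range: Tuple[int, int] = (8, 20)

    def validate(self) -> None:
        if self.n_entries < 0:
            raise ConfigError("n_entries must be >= 0")
        if abs(sum(self.criterion_mix) - 1.0) > 1e-9:
            raise ConfigError("criterion_mix must sum to 1")
        for frac in (self.fraction_unassigned, self.fraction_fragment,
                     self.fraction_signal, self.fraction_propep,
                     self.fraction_chain, self.dose_rate, self.mouse_rate):
            if not 0.0 <= frac <= 1.0:
                raise ConfigError(f"fraction {frac} outside [0, 1]")
        orders = {o.order for o in self.order_spec}
        for o in self.order_spec:
            if o.weight <= 0:
                raise ConfigError(f"order {o.order}: non-positive weight")
            if o.habitat == "mixed":
                if not o.genus_habitats:
                    raise ConfigError(
                        f"mixed order {o.order} needs genus_habitats"
                    )
                missing = set(o.genera) - set(o.genus_habitats)
                if missing:
                    raise ConfigError(
                        f"mixed order {o.order}: genera without habitat {missing}"
                    )
        for f in self.family_spec:
            if f.weight <= 0:
                raise ConfigError(f"family {f.raw!r}: non-positive weight")
            if f.orders is not None and not set(f.orders) & orders:
                raise ConfigError(
                    f"family {f.raw!r}: none of its orders are configured"
                )
        for order in orders:
            if not any(f.orders is None or order in f.orders
                       for f in self.family_spec):
                raise ConfigError(f"order {order} has no eligible family")


# ---------------------------------------------------------------------------
# ground truth containers


@dataclass
class SnapshotTruth:
    """Exact bookkeeping of one emitted snapshot.

    Criterion counts cover every parsed entry; all other fields cover the
    venom-tissue selection (the pipeline's default working definition).
    """

    year: int
    n_parsed: int
    criterion_counts: Dict[str, int]
    n_entries: int
    n_orders: int
    n_species: int
    n_families: int
    n_unassigned: int
    n_fragments: int
    n_ptm_annotated: int
    n_ptm_keyword: int
    n_toxic_dose: int
    evidence_distribution: Dict[int, int]
    ptm_category_totals: Dict[str, int]
    habitat_entries: Dict[str, int]
    habitat_species: Dict[str, int]
    habitat_families: Dict[str, int]
    shared_families: Set[str]
    shared_family_counts: Dict[str, Dict[str, int]]
    length_bins: Dict[str, int]
    go_counts: Dict[str, int]
    family_counts: Dict[str, int]
    species_key_set: Set[int]
    rank_sets: Dict[str, Set[str]]
    family_set: Set[str]

    def as_dict(self) -> dict:
        return {
            "year": self.year,
            "n_parsed": self.n_parsed,
            "criterion_counts": dict(self.criterion_counts),
            "n_entries": self.n_entries,
            "n_orders": self.n_orders,
            "n_species": self.n_species,
            "n_families": self.n_families,
            "n_unassigned": self.n_unassigned,
            "n_fragments": self.n_fragments,
            "n_ptm_annotated": self.n_ptm_annotated,
            "n_ptm_keyword": self.n_ptm_keyword,
            "n_toxic_dose": self.n_toxic_dose,
            "evidence_distribution": {str(k): v for k, v in
                                      sorted(self.evidence_distribution.items())},
            "ptm_category_totals": dict(self.ptm_category_totals),
            "habitat_entries": dict(self.habitat_entries),
            "habitat_species": dict(self.habitat_species),
            "habitat_families": dict(self.habitat_families),
            "shared_families": sorted(self.shared_families),
            "shared_family_counts": {k: dict(v) for k, v in
                                     sorted(self.shared_family_counts.items())},
            "length_bins": dict(self.length_bins),
            "go_counts": dict(self.go_counts),
            "family_counts": dict(sorted(self.family_counts.items())),
        }


@dataclass
class ComparisonTruth:
    """Expected cross-snapshot diffs (venom-tissue selection)."""

    year_a: int
    year_b: int
    entries_a: int
    entries_b: int
    growth_pct_floor: int
    net_species_change: int
    net_family_change: int
    newcomer_species: Set[int]
    newcomer_taxa_by_rank: Dict[str, Set[str]]
    disappeared_taxa_by_rank: Dict[str, Set[str]]
    newcomer_families: Set[str]
    disappeared_families: Set[str]


@dataclass
class GenerationResult:
    """One generated snapshot with its files and its bookkeeping."""

    year: int
    dataset: Dataset
    dat_text: str
    taxonomy: TaxonomyTable
    habitat_table: HabitatTable
    truth: SnapshotTruth


@dataclass
class SnapshotSeries:
    snapshots: List[GenerationResult]
    taxonomy: TaxonomyTable
    habitat_table: HabitatTable
    comparisons: Dict[Tuple[int, int], ComparisonTruth]


# ---------------------------------------------------------------------------
# generator internals


class _Taxa:
    """Deterministic taxonomy universe for one configuration."""

    def __init__(self, config: SyntheticConfig):
        self.table = TaxonomyTable()
        t = self.table
        t.add(1, 1, "no rank", "root")
        t.add(2759, 1, "superkingdom", "Eukaryota")
        t.add(33208, 2759, "kingdom", "Metazoa")
        self.habitat = HabitatTable()
        next_id = {"phylum": 101, "class": 201, "order": 301,
                   "family": 401, "genus": 1001, "species": 10001}
        phyla: Dict[str, int] = {}
        classes: Dict[Tuple[str, str], int] = {}
        self.species: Dict[Tuple[str, str, int], dict] = {}
        for spec in config.order_spec:
            if spec.phylum not in phyla:
                phyla[spec.phylum] = next_id["phylum"]
                next_id["phylum"] += 1
                t.add(phyla[spec.phylum], 33208, "phylum", spec.phylum)
            ckey = (spec.phylum, spec.class_)
            if ckey not in classes:
                classes[ckey] = next_id["class"]
                next_id["class"] += 1
                t.add(classes[ckey], phyla[spec.phylum], "class", spec.class_)
            order_id = next_id["order"]
            next_id["order"] += 1
            t.add(order_id, classes[ckey], "order", spec.order)
            self.habitat.order_map[spec.order] = OrderHabitat(spec.habitat)
            for genus in spec.genera:
                family_name = f"{genus}idae"
                family_id = next_id["family"]
                next_id["family"] += 1
                t.add(family_id, order_id, "family", family_name)
                genus_id = next_id["genus"]
                next_id["genus"] += 1
                t.add(genus_id, family_id, "genus", genus)
                if spec.habitat == "mixed":
                    self.habitat.genus_map[genus] = Habitat(
                        spec.genus_habitats[genus]
                    )
                    habitat = spec.genus_habitats[genus]
                else:
                    habitat = spec.habitat
                for i in range(config.species_per_genus):
                    sp_id = next_id["species"]
                    next_id["species"] += 1
                    name = f"{genus} {_EPITHETS[i % len(_EPITHETS)]}"
                    t.add(sp_id, genus_id, "species", name)
                    t.deprecated_map[900000 + sp_id] = sp_id
                    self.species[(spec.order, genus, i)] = {
                        "taxid": sp_id,
                        "old_taxid": 900000 + sp_id,
                        "name": name,
                        "order": spec.order,
                        "genus": genus,
                        "family": family_name,
                        "phylum": spec.phylum,
                        "class": spec.class_,
                        "habitat": habitat,
                    }


def _weighted_choice(rng: np.random.Generator, items: Sequence, weights) -> int:
    w = np.asarray([float(x) for x in weights])
    return int(rng.choice(len(items), p=w / w.sum()))


def _rand_seq(rng: np.random.Generator, n: int) -> str:
    return "".join(AA[i] for i in rng.integers(0, len(AA), size=n))


def _mutate(rng: np.random.Generator, seq: str, rate: float) -> str:
    chars = list(seq)
    for i in range(len(chars)):
        if rng.random() < rate:
            chars[i] = AA[int(rng.integers(0, len(AA)))]
    return "".join(chars)


_DOSE_TEMPLATES = {
    "iv": ("LD(50) is {d} mg/kg by intravenous injection into {animal}.", True),
    "ip": ("LD(50) is {d} mg/kg by intraperitoneal injection into {animal}.", True),
    "sc": ("LD(50) is {d} mg/kg by subcutaneous injection into {animal}.", True),
    "icv": ("LD(50) is {d} ug/kg by intracerebroventricular injection into"
            " {animal}.", True),
    "other": ("Paralytic dose in crickets is {d} nmol/g.", False),
}


def _bin_label(length: int, width: int = 25) -> str:
    lo = ((length - 1) // width) * width + 1
    return f"{lo}-{lo + width - 1}"


class _Generator:
    def __init__(self, config: SyntheticConfig):
        config.validate()
        self.config = config
        self.rng = np.random.default_rng(config.seed)
        self.taxa = _Taxa(config)
        # family motifs drawn once, in family_spec order, before any entry
        self.motifs = {
            spec.raw: _rand_seq(self.rng, spec.mature_len)
            for spec in config.family_spec
        }

    # -- per-entry construction -------------------------------------------

    def build_entry(self, idx: int, allowed_orders: Set[str],
                    allowed_families: Set[str]):
        cfg, rng = self.config, self.rng
        order_specs = [o for o in cfg.order_spec if o.order in allowed_orders]
        ospec = order_specs[
            _weighted_choice(rng, order_specs, [o.weight for o in order_specs])
        ]
        genus = ospec.genera[int(rng.integers(0, len(ospec.genera)))]
        sp_i = int(rng.integers(0, cfg.species_per_genus))
        sp = self.taxa.species[(ospec.order, genus, sp_i)]

        crit_i = _weighted_choice(rng, range(4), cfg.criterion_mix)
        criterion = ("tissue_only", "keyword_only", "both", "neither")[crit_i]

        unassigned = rng.random() < cfg.fraction_unassigned
        fspec = None
        if not unassigned:
            eligible = [
                f for f in cfg.family_spec
                if f.raw in allowed_families
                and (f.orders is None or ospec.order in f.orders)
            ]
            if not eligible:
                unassigned = True
            else:
                fspec = eligible[
                    _weighted_choice(rng, eligible, [f.weight for f in eligible])
                ]

        if fspec is not None:
            core = _mutate(rng, self.motifs[fspec.raw], cfg.mutation_rate)
        else:
            if rng.random() < cfg.enzyme_weight:
                core_len = int(rng.integers(250, 501))
            else:
                core_len = int(rng.integers(20, 91))
            core = _rand_seq(rng, core_len)

        has_signal = rng.random() < cfg.fraction_signal
        has_propep = rng.random() < cfg.fraction_propep
        has_chain = rng.random() < cfg.fraction_chain
        ls = int(rng.integers(*cfg.signal_len_range)) if has_signal else 0
        lp = int(rng.integers(*cfg.propep_len_range)) if has_propep else 0
        signal = _rand_seq(rng, ls)
        propep = _rand_seq(rng, lp)
        seq = signal + propep + core
        L = len(seq)

        features: List[Feature] = []
        struct_idx: List[int] = []
        if has_signal:
            struct_idx.append(len(features))
            features.append(Feature(FeatureKind.SIGNAL, 1, ls))
        if has_propep:
            struct_idx.append(len(features))
            features.append(Feature(FeatureKind.PROPEP, ls + 1, ls + lp))
        if has_chain:
            struct_idx.append(len(features))
            features.append(
                Feature(FeatureKind.CHAIN, ls + lp + 1, L,
                        description=f"Synthetic toxin {idx}")
            )

        is_frag = rng.random() < cfg.fraction_fragment
        frag_flag = False
        broken: Optional[int] = None
        if is_frag:
            if struct_idx and rng.random() < 0.5:
                broken = struct_idx[int(rng.integers(0, len(struct_idx)))]
                ft = features[broken]
                if rng.random() < 0.5:
                    features[broken] = Feature(ft.kind, ft.start, ft.end,
                                               start_known=False,
                                               description=ft.description)
                else:
                    features[broken] = Feature(ft.kind, ft.start, ft.end,
                                               end_known=False,
                                               description=ft.description)
            else:
                frag_flag = True

        chain_ok = has_chain and (broken is None
                                  or features[broken].kind is not FeatureKind.CHAIN)
        signal_ok = has_signal and (broken is None
                                    or features[broken].kind is not FeatureKind.SIGNAL)
        propep_ok = has_propep and (broken is None
                                    or features[broken].kind is not FeatureKind.PROPEP)
        if chain_ok:
            mature_len = L - ls - lp
        elif signal_ok or propep_ok:
            mature_len = L - (ls if signal_ok else 0) - (lp if propep_ok else 0)
        else:
            mature_len = L

        # PTM features
        ptm_counts: Counter = Counter()
        rates = cfg.ptm_rates
        n_ss = int(rng.poisson(rates.get("Disulfide bond", 0.0)))
        n_ss = min(n_ss, L // 2)
        if n_ss:
            pos = sorted(rng.choice(np.arange(1, L + 1), size=2 * n_ss,
                                    replace=False).tolist())
            for b in range(n_ss):
                a, c = pos[2 * b], pos[2 * b + 1]
                features.append(Feature(FeatureKind.DISULFID, int(a), int(c)))
            ptm_counts["Disulfide bond"] = n_ss
        if rng.random() < rates.get("Amidation", 0.0):
            features.append(
                Feature(FeatureKind.MOD_RES, L, L,
                        description=f"{AA_NAMES[seq[-1]]} amide")
            )
            ptm_counts["Amidation"] += 1
        n_gly = int(rng.poisson(rates.get("Glycosylation", 0.0)))
        for _ in range(n_gly):
            p = int(rng.integers(1, L + 1))
            features.append(
                Feature(FeatureKind.CARBOHYD, p, p,
                        description="N-linked (GlcNAc...) asparagine")
            )
        if n_gly:
            ptm_counts["Glycosylation"] = n_gly
        n_hyd = int(rng.poisson(rates.get("Hydroxylation", 0.0)))
        for _ in range(n_hyd):
            p = int(rng.integers(1, L + 1))
            features.append(Feature(FeatureKind.MOD_RES, p, p,
                                    description="4-hydroxyproline"))
        if n_hyd:
            ptm_counts["Hydroxylation"] = n_hyd
        if rng.random() < rates.get("Pyrrolidone carboxylic acid", 0.0):
            features.append(Feature(FeatureKind.MOD_RES, 1, 1,
                                    description="Pyrrolidone carboxylic acid"))
            ptm_counts["Pyrrolidone carboxylic acid"] += 1
        if rng.random() < rates.get("Gamma-carboxyglutamic acid", 0.0):
            p = int(rng.integers(1, L + 1))
            features.append(Feature(FeatureKind.MOD_RES, p, p,
                                    description="4-carboxyglutamate"))
            ptm_counts["Gamma-carboxyglutamic acid"] += 1
        if rng.random() < rates.get("Cross-link", 0.0) and L >= 4:
            p = int(rng.integers(1, L - 2))
            features.append(
                Feature(FeatureKind.CROSSLNK, p, p + 2,
                        description="Isoaspartyl glycine isopeptide (Asn-Gly)")
            )
            ptm_counts["Cross-link"] += 1
        if rng.random() < rates.get("Lipidation", 0.0):
            p = int(rng.integers(1, L + 1))
            features.append(Feature(FeatureKind.LIPID, p, p,
                                    description="GPI-anchor amidated serine"))
            ptm_counts["Lipidation"] += 1

        # keywords
        keywords = {"Secreted"}
        if criterion in ("keyword_only", "both"):
            keywords.add("Toxin")
        has_ptm_kw = False
        if ptm_counts:
            if rng.random() < cfg.ptm_keyword_rate:
                for cat in ptm_counts:
                    keywords.add(_CATEGORY_KEYWORD[cat])
                has_ptm_kw = True
        elif rng.random() < cfg.ptm_keyword_only_rate:
            keywords.add("Disulfide bond")
            has_ptm_kw = True

        # tissue specificity
        if criterion in ("tissue_only", "both"):
            tissue = ("Expressed by the venom gland."
                      if rng.random() < 0.7 else "Expressed by the venom duct.")
        else:
            tissue = ("Expressed in the salivary gland."
                      if rng.random() < 0.3 else None)

        # toxic dose
        doses: List[str] = []
        has_dose = rng.random() < cfg.dose_rate
        if has_dose:
            routes = list(cfg.route_weights)
            route = routes[_weighted_choice(rng, routes,
                                            [cfg.route_weights[r] for r in routes])]
            template, supports_animal = _DOSE_TEMPLATES[route]
            d = round(float(rng.uniform(0.01, 5.0)), 3)
            if supports_animal:
                animal = "mice" if rng.random() < cfg.mouse_rate else "rabbits"
                doses.append(template.format(d=d, animal=animal))
            else:
                doses.append(template.format(d=d))

        # GO refs
        go_refs: List[GoRef] = []
        go_aspects: Set[str] = set()
        for aspect in ("F", "P", "C"):
            if rng.random() < cfg.go_rate.get(aspect, 0.0):
                terms = _GO_TERMS[aspect]
                go_id, label = terms[int(rng.integers(0, len(terms)))]
                go_refs.append(GoRef(go_id, aspect, label))
                go_aspects.add(aspect)

        levels = sorted(cfg.evidence_probs)
        evidence = levels[_weighted_choice(
            rng, levels, [cfg.evidence_probs[l] for l in levels])]

        use_deprecated = rng.random() < cfg.deprecated_rate
        taxid = sp["old_taxid"] if use_deprecated else sp["taxid"]

        entry = ProteinEntry(
            accession=f"P{idx:05d}",
            entry_name=f"TX{idx:05d}_SYN",
            sequence=seq,
            protein_name=f"Synthetic venom protein {idx}",
            is_fragment=frag_flag,
            taxid=taxid,
            lineage_text=("Eukaryota", "Metazoa", sp["phylum"], sp["class"],
                          sp["order"], sp["family"], sp["genus"]),
            keywords=frozenset(keywords),
            tissue_specificity=tissue,
            family_raw=fspec.raw if fspec is not None else None,
            toxic_dose_texts=tuple(doses),
            go_refs=tuple(go_refs),
            evidence_level=evidence,
            features=tuple(features),
        )

        record = {
            "criterion": criterion,
            "selected": criterion in ("tissue_only", "both"),
            "order": sp["order"],
            "taxfamily": sp["family"],
            "genus": sp["genus"],
            "species_name": sp["name"],
            "species_taxid": sp["taxid"],
            "phylum": sp["phylum"],
            "class": sp["class"],
            "habitat": sp["habitat"],
            "family": fspec.canonical if fspec is not None else None,
            "fragment": is_frag,
            "mature_len": mature_len,
            "ptm_counts": ptm_counts,
            "has_ptm_kw": has_ptm_kw,
            "has_dose": has_dose,
            "evidence": evidence,
            "go_aspects": go_aspects,
        }
        return entry, record


def _aggregate(year: int, records: Sequence[dict]) -> SnapshotTruth:
    crit = Counter(r["criterion"] for r in records)
    sel = [r for r in records if r["selected"]]
    species = {r["species_taxid"] for r in sel}
    families = {r["family"] for r in sel if r["family"] is not None}
    rank_sets = {
        "order": {r["order"] for r in sel},
        "family": {r["taxfamily"] for r in sel},
        "genus": {r["genus"] for r in sel},
        "species": {r["species_name"] for r in sel},
    }
    ptm_totals: Counter = Counter()
    for r in sel:
        ptm_totals.update(r["ptm_counts"])
    habitats = ("terrestrial", "marine")
    hab_entries = {h: sum(1 for r in sel if r["habitat"] == h) for h in habitats}
    hab_species = {
        h: len({r["species_taxid"] for r in sel if r["habitat"] == h})
        for h in habitats
    }
    hab_fams = {
        h: {r["family"] for r in sel
            if r["habitat"] == h and r["family"] is not None}
        for h in habitats
    }
    shared = hab_fams["terrestrial"] & hab_fams["marine"]
    shared_counts = {
        fam: {h: sum(1 for r in sel
                     if r["habitat"] == h and r["family"] == fam)
              for h in habitats}
        for fam in shared
    }
    bins: Dict[str, int] = {}
    if sel:
        max_len = max(r["mature_len"] for r in sel)
        bin_counts = Counter(_bin_label(r["mature_len"]) for r in sel)
        lo = 1
        while lo <= max_len:
            label = f"{lo}-{lo + 24}"
            bins[label] = bin_counts.get(label, 0)
            lo += 25
    return SnapshotTruth(
        year=year,
        n_parsed=len(records),
        criterion_counts={
            "tissue_only": crit.get("tissue_only", 0),
            "keyword_only": crit.get("keyword_only", 0),
            "both": crit.get("both", 0),
            "neither": crit.get("neither", 0),
        },
        n_entries=len(sel),
        n_orders=len(rank_sets["order"]),
        n_species=len(species),
        n_families=len(families),
        n_unassigned=sum(1 for r in sel if r["family"] is None),
        n_fragments=sum(1 for r in sel if r["fragment"]),
        n_ptm_annotated=sum(1 for r in sel if r["ptm_counts"]),
        n_ptm_keyword=sum(1 for r in sel if r["has_ptm_kw"]),
        n_toxic_dose=sum(1 for r in sel if r["has_dose"]),
        evidence_distribution={
            lvl: sum(1 for r in sel if r["evidence"] == lvl)
            for lvl in (1, 2, 3, 4, 5)
        },
        ptm_category_totals=dict(ptm_totals),
        habitat_entries=hab_entries,
        habitat_species=hab_species,
        habitat_families={h: len(s) for h, s in hab_fams.items()},
        shared_families=shared,
        shared_family_counts=shared_counts,
        length_bins=bins,
        go_counts={a: sum(1 for r in sel if a in r["go_aspects"])
                   for a in ("F", "P", "C")},
        family_counts=dict(Counter(
            r["family"] for r in sel if r["family"] is not None)),
        species_key_set=species,
        rank_sets=rank_sets,
        family_set=families,
    )


def _compare_truth(a: SnapshotTruth, b: SnapshotTruth) -> ComparisonTruth:
    return ComparisonTruth(
        year_a=a.year,
        year_b=b.year,
        entries_a=a.n_entries,
        entries_b=b.n_entries,
        growth_pct_floor=math.floor(
            100.0 * (b.n_entries - a.n_entries) / a.n_entries
        ),
        net_species_change=b.n_species - a.n_species,
        net_family_change=b.n_families - a.n_families,
        newcomer_species=b.species_key_set - a.species_key_set,
        newcomer_taxa_by_rank={
            rank: b.rank_sets[rank] - a.rank_sets[rank] for rank in a.rank_sets
        },
        disappeared_taxa_by_rank={
            rank: a.rank_sets[rank] - b.rank_sets[rank] for rank in a.rank_sets
        },
        newcomer_families=b.family_set - a.family_set,
        disappeared_families=a.family_set - b.family_set,
    )


# ---------------------------------------------------------------------------
# public API


def generate(config: SyntheticConfig, year: int = 2025) -> GenerationResult:
    """Generate one snapshot: flat-file text, covering taxonomy and
    habitat tables, and exact bookkeeping ground truth.

    Deterministic given ``config.seed``.
    """
    gen = _Generator(config)
    all_orders = {o.order for o in config.order_spec}
    all_families = {f.raw for f in config.family_spec}
    entries, records = [], []
    for i in range(config.n_entries):
        entry, record = gen.build_entry(i, all_orders, all_families)
        entries.append(replace(entry, snapshot_year=year))
        records.append(record)
    dataset = Dataset(year=year, entries=entries)
    return GenerationResult(
        year=year,
        dataset=dataset,
        dat_text=write_dat(dataset),
        taxonomy=gen.taxa.table,
        habitat_table=gen.taxa.habitat,
        truth=_aggregate(year, records),
    )


def generate_snapshot_series(
    config: SyntheticConfig,
    years: Sequence[int],
    growth_factors: Sequence[float],
    introduce_orders: Optional[Mapping[int, Sequence[str]]] = None,
    introduce_families: Optional[Mapping[int, Sequence[str]]] = None,
    drop_orders: Optional[Mapping[int, Sequence[str]]] = None,
) -> SnapshotSeries:
    """Generate a series of release snapshots with planted diffs.

    Later snapshots are supersets of earlier ones plus newcomers: with
    growth factors (1, 2, 3) the snapshot entry counts stand in exactly
    that ratio.  ``introduce_orders`` / ``introduce_families`` plant
    newcomers by making a taxon or family eligible only from a given
    year onward; ``drop_orders`` plants disappearances by excluding an
    order's entries from one snapshot only.  Ground truth includes the
    expected cross-snapshot comparison values for consecutive pairs and
    the first-vs-last pair.
    """
    if len(years) != len(growth_factors):
        raise ConfigError("years and growth_factors must have equal length")
    if list(growth_factors) != sorted(growth_factors):
        raise ConfigError(
            "growth factors must be non-decreasing (snapshots are supersets; "
            "plant disappearances via drop_orders)"
        )
    years = list(years)
    order_years = sorted(years)
    if years != order_years:
        log.info("years %s processed in sorted order", years)
        years = order_years
    introduce_orders = {int(y): set(v) for y, v in (introduce_orders or {}).items()}
    introduce_families = {
        int(y): set(v) for y, v in (introduce_families or {}).items()
    }
    drop_orders = {int(y): set(v) for y, v in (drop_orders or {}).items()}
    known_orders = {o.order for o in config.order_spec}
    known_families = {f.raw for f in config.family_spec}
    for mapping, known, what in (
        (introduce_orders, known_orders, "order"),
        (introduce_families, known_families, "family"),
        (drop_orders, known_orders, "order"),
    ):
        for y, names in mapping.items():
            unknown = names - known
            if unknown:
                raise ConfigError(f"unknown {what}(s) {unknown} for year {y}")

    gen = _Generator(config)
    counts = [int(round(config.n_entries * f)) for f in growth_factors]
    n_max = counts[-1]

    # eligibility per snapshot index (cumulative introductions)
    allowed_orders_at: List[Set[str]] = []
    allowed_families_at: List[Set[str]] = []
    late_orders = set().union(*introduce_orders.values()) if introduce_orders else set()
    late_families = (
        set().union(*introduce_families.values()) if introduce_families else set()
    )
    for j, year in enumerate(years):
        ao = known_orders - late_orders
        af = known_families - late_families
        for y, names in introduce_orders.items():
            if y <= year:
                ao |= names
        for y, names in introduce_families.items():
            if y <= year:
                af |= names
        allowed_orders_at.append(ao)
        allowed_families_at.append(af)

    master: List[Tuple[ProteinEntry, dict]] = []
    for i in range(n_max):
        j_min = next(j for j, c in enumerate(counts) if i < c)
        entry, record = gen.build_entry(
            i, allowed_orders_at[j_min], allowed_families_at[j_min]
        )
        record["first_snapshot"] = j_min
        master.append((entry, record))

    results: List[GenerationResult] = []
    for j, year in enumerate(years):
        dropped = drop_orders.get(year, set())
        snap_entries, snap_records = [], []
        for i in range(counts[j]):
            entry, record = master[i]
            if record["order"] in dropped:
                continue
            snap_entries.append(replace(entry, snapshot_year=year))
            snap_records.append(record)
        dataset = Dataset(year=year, entries=snap_entries)
        results.append(
            GenerationResult(
                year=year,
                dataset=dataset,
                dat_text=write_dat(dataset),
                taxonomy=gen.taxa.table,
                habitat_table=gen.taxa.habitat,
                truth=_aggregate(year, snap_records),
            )
        )

    comparisons: Dict[Tuple[int, int], ComparisonTruth] = {}
    for a, b in zip(results, results[1:]):
        comparisons[(a.year, b.year)] = _compare_truth(a.truth, b.truth)
    if len(results) > 2:
        comparisons[(results[0].year, results[-1].year)] = _compare_truth(
            results[0].truth, results[-1].truth
        )
    return SnapshotSeries(
        snapshots=results,
        taxonomy=gen.taxa.table,
        habitat_table=gen.taxa.habitat,
        comparisons=comparisons,
    )
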