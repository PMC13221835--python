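# toxprotkit

Database metrics for curated animal-venom protein data in
UniProtKB/Swiss-Prot.

Venom proteins and peptides are curated in Swiss-Prot under the Tox-Prot
annotation project. Tracking how that corpus grows and diversifies —
which taxa and protein families dominate, how mature peptide lengths and
post-translational modifications (PTMs) are distributed, how terrestrial
and marine lineages are represented — requires re-deriving the same
metrics consistently across archived release snapshots. `toxprotkit` is
a tested, reusable pipeline for exactly that, for anyone analysing
venom-related Swiss-Prot data: parse flat-file (DAT) releases, select
venom entries, annotate them, derive per-entry sequence features, and
compute snapshot and cross-snapshot metrics, plus an embedding-based
evaluation of protein-family separation.

## What it computes

**Selection.** Venom entries are defined by two complementary criteria
within Metazoa (NCBI taxid 33208), mirroring the UniProt query
`(taxonomy_id:33208) AND ((cc_tissue_specificity:venom) OR
(keyword:KW-0800))`:

* *venom tissue*: the TISSUE SPECIFICITY comment mentions "venom"
  (case-insensitive substring, so "venom gland" and "venom duct" match);
* *toxin keyword*: the entry carries the "Toxin" keyword (KW-0800).

Each entry falls into exactly one class — tissue-only, keyword-only,
both, or excluded — and the working dataset is the venom-tissue
definition by default.

**Annotation.** Taxonomic lineage (phylum → species) is resolved from a
local NCBI-style taxonomy table with deprecated-id remapping; habitat is
a two-tier lookup (order level, then genus level for orders spanning
both habitats, e.g. within Squamata: *Crotalus* → terrestrial,
*Hydrophis* → marine); protein-family names from SIMILARITY comments are
normalized (truncation at the first `.`/`,`/`;`, conotoxin shorthand
expansion "I1 superfamily" → "Conotoxin I1 superfamily", and a
cross-year alias map, e.g. "Snake toxin family" → "Snake three-finger
toxin family").

**Sequence features.** Mature sequence via chain/peptide annotations
(longest fully-known span) or signal/propeptide removal, else the
precursor as-is; 25-aa length bins; fragment status (explicit flag or
any incomplete signal/propeptide/chain/peptide range); feature- and
keyword-based PTM profiles through a ptmlist-format controlled
vocabulary; toxic-dose flags (mouse testing, administration route); GO
coverage per aspect.

**Metrics.** Snapshot summary vectors (entries, orders, species,
families, unassigned/fragment/PTM/toxic-dose counts with one-decimal
percentages, protein-existence evidence distribution), cross-snapshot
diffs (net changes plus newcomer/disappeared sets per rank), family
rankings, habitat partitions with shared-family analysis, and
mature-length histograms. Percentages use round-half-away-from-zero to
one decimal; decade growth uses an integer floor of
`100 * (b - a) / a`.

**Embedding evaluation.** Five sequence-processing variants (full
precursor; signal removed; signal removed, fragment-free; signal +
propeptide removed; signal + propeptide removed, fragment-free) are
embedded by a pluggable provider and scored by the mean silhouette
`s = (b − a) / max(a, b)` over family labels (Euclidean, full embedding
space). The packaged provider is a deterministic k-mer composition
embedder; an external protein language model can be slotted in through
the same provider contract.

**Synthetic data.** A generator emits complete DAT snapshots (plus
taxonomy/habitat tables covering every generated taxon) with exact
bookkeeping of every metric the pipeline reports, so the whole pipeline
is testable end to end without any downloads.

## Worked example

Generate a three-snapshot fixture series and run the full analysis:

```bash
toxprotkit synth --seed 1 --n-entries 120 --years 2005,2015,2025 \
    --growth-factors 1,2,3 --outdir fixtures
toxprotkit report --config config.yaml
toxprotkit compare --config config.yaml --years 2005,2015,2025
toxprotkit embed-eval --config config.yaml --year 2025
```

with `config.yaml` pointing at the generated files (see
`tests/test_pipeline.py` for a complete example). This prints:

```
2005: 91 entries, 39 species, 15 families
2015: 193 entries, 49 species, 15 families
2025: 288 entries, 51 species, 15 families

2005->2015: entries 91->193 (112%), net species +10, net families +0
2015->2025: entries 193->288 (49%), net species +2, net families +0
2005->2025: entries 91->288 (216%), net species +12, net families +0

full: 0.135 (241 proteins, 10 families)
signal_removed: 0.256 (241 proteins, 10 families)
signal_removed_nofrag: 0.260 (197 proteins, 10 families)
signal_propep_removed: 0.298 (241 proteins, 10 families)
signal_propep_removed_nofrag: 0.307 (197 proteins, 10 families) <- selected
```

Reading this: of the 360 synthetic entries in the 2025 snapshot, 288
satisfy the venom-tissue definition; unique species and protein-family
counts grow across snapshots; the growth percentages are integer floors
of the relative entry-count change. In the variant comparison, the mean
silhouette over the top-10 families rises sharply once random signal
peptides are excised (0.135 → 0.256) — family-specific structure lives
in the mature core — and the fragment-free, fully-processed variant
scores highest and is flagged as selected. Per-entry CSVs and JSON
summaries land in the configured output directory.

The same operations are available as a library (`toxprotkit.pipeline`,
`toxprotkit.metrics`, ...) for use in notebooks and scripts.

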