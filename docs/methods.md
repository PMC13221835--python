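# Methods

This note documents the models, conventions and design choices behind
`toxprotkit`, in the order the pipeline applies them.

## Flat-file model and dialects

Entries are parsed from Swiss-Prot flat-file (DAT) text into a dataclass
model carrying exactly the analysed fields: primary accession, entry
name, protein name, fragment flag, taxid, OC lineage text, keywords, the
TISSUE SPECIFICITY / SIMILARITY / TOXIC DOSE comment blocks, GO
cross-references with aspect codes, the protein-existence (PE) level,
the sequence, and the feature table (SIGNAL, PROPEP, CHAIN, PEPTIDE,
DISULFID, CARBOHYD, MOD_RES, CROSSLNK, LIPID; anything else is kept as
OTHER with its original key). Comment topics outside the three analysed
ones are preserved opaquely so writing is lossless for the model.

Two feature-table dialects occur in archived releases. The canonical
dialect here is the modern single-line syntax (`FT   SIGNAL   1..22`,
`/note="..."` continuations); the legacy column-based dialect is
accepted on read behind `legacy_ft=True` and never written. One writer
dialect keeps the round-trip exact: `read_dat(write_dat(d)) == d`
field-for-field on every generated fixture, which the suite asserts and
additionally cross-checks against `Bio.SwissProt` as an independent
reader.

Endpoint qualifiers `?`, `?N`, `<N`, `>N` mark a position as not
reliably known and clear the corresponding `start_known`/`end_known`
flag; a known endpoint must satisfy `1 <= index <= len(sequence)` or the
parser raises naming the accession. The distinction between `<N`, `>N`
and `?N` is deliberately collapsed to "value N, not known": nothing
downstream depends on which qualifier produced the uncertainty, and the
collapse is what makes a single canonical writer form (`?N`)
round-trip exactly. Entries without a PE line (as in the oldest
releases, which predate protein-existence annotation) default to level
5 ("Uncertain").

Multiple SIMILARITY family statements in one entry are not covered by
any stated convention; the first "Belongs to the ..." match is kept and
a warning logged. The extracted `family_raw` is the full clause after
"Belongs to the" with only the final period stripped; truncation at the
first period/comma/semicolon is the normalizer's job (below), so the
two stages compose the documented normalization exactly.

## Selection

The dual criteria replicate the curation query: Metazoa-restricted
(taxid 33208 on the resolved parent chain), then "venom" as a
case-insensitive substring of the TISSUE SPECIFICITY text and/or the
"Toxin" keyword (the flat file carries keyword names, not KW codes).
Substring matching intentionally accepts "venom gland", "venom duct" —
and would accept "venomous"; stemming is not attempted because the
source query is a plain-text field search. An unresolvable taxid
excludes the entry with a warning rather than aborting a whole release.
The four criterion classes partition every dataset, and
`|UNION| = |VT| + |KW| − |BOTH|` is asserted as a property.

## Annotation

*Lineage.* The taxonomy table mirrors the NCBI dump structure
(taxid, parent, rank, name + merged-id file). Resolution remaps
deprecated ids first, then walks the parent chain collecting the six
named ranks, guarding against cycles. Species identity for counting is
the species-rank taxid (name string as fallback), which is robust to
synonym strings in fixtures.

*Habitat.* Two-tier lookup; unknown orders (or a mixed-habitat order
with an unknown genus) raise rather than fall into a silent "unknown"
bucket, because habitat totals must partition the dataset. The shipped
seed tables cover the documented assignments, including the edge cases
(estuarine *Cerberus* and river stingray *Potamotrygon* grouped marine,
freshwater *Pseudoferania* terrestrial). The tables are plain TSV and
intended to be extended for real data.

*Family normalization.* Truncate at the first of `. , ;`, trim, expand
bare conotoxin superfamily codes (a 1–3 character alphanumeric code
followed by "superfamily" without the word "Conotoxin"), then apply the
alias map. Alias targets are validated to be fixed points at load time,
which makes the whole normalizer idempotent — asserted by a property
test over arbitrary text. The shipped alias map contains only
documented renames (e.g. Huwentoxin-1 and two further spider-toxin
families consolidated into "Neurotoxin 10 (Hwtx-1)"); the full
historical mapping is much larger and the file format accepts
extensions.

## Sequence features

*Mature sequence.* Chain/peptide-first precedence: if any CHAIN or
PEPTIDE feature is fully known, the longest such span is the mature
product (ties to the smallest start — the longest span best
approximates the mature chain of a multi-product precursor); otherwise
residues covered by fully-known SIGNAL/PROPEP features are removed;
otherwise the precursor is assumed already mature. Equivalence with a
brute-force residue-mask implementation is asserted on 1000 generated
entries.

*Bins.* Closed integer bins of width 25 (`1-25`, `26-50`, ...); labels
use an ASCII hyphen. Every length falls in exactly one bin and bin
populations sum to the dataset size. Fragment entries stay in the
histograms (a flag exists to drop them downstream), preserving
additivity with the summary counts.

*Fragments.* An entry is a fragment iff the description carries the
Fragment flag or any signal/propeptide/chain/peptide feature has an
incomplete range. Incomplete endpoints on PTM features do not make an
entry a fragment.

*PTMs.* Feature-based accounting: one count per DISULFID (interchain
included), CARBOHYD → Glycosylation, CROSSLNK → Cross-link, LIPID →
Lipidation, MOD_RES through the ptmlist-format controlled vocabulary
(case-insensitive; misses count as "Other" with a warning). The
packaged vocabulary is a synthetic curated seed covering the
descriptions the fixture generator emits (all twenty "X amide" forms,
common hydroxylations, pyroglutamate, carboxyglutamate); for real data,
point the pipeline at a full ptmlist file. A parallel, coarser
keyword-based accounting (Disulfide bond, Amidation, Glycoprotein, ...
on KW lines) is computed separately because the two sources genuinely
disagree in curated data; summaries report both counts.

*Toxic dose.* Mouse testing is flagged by "mouse"/"mice"
(case-insensitive); administration route is the first matching keyword
in the order intravenous, intraperitoneal, subcutaneous,
intracerebroventricular (full words or dotted abbreviations), else
OTHER/UNSTATED. Numeric dose normalization across units is out of
scope: units, test frameworks and incubation regimes vary too much for
the values to be comparable.

*GO coverage.* Percentage of entries with ≥ 1 term per aspect, read
directly from the `F:`/`P:`/`C:` prefix on DR GO lines, so OBO parsing
is unnecessary for coverage (an OBO file can enrich term labels only).

## Metric conventions

* Percentages: round half away from zero to one decimal of
  `100 * count / total` (matches every printed cell of the published
  summary table, e.g. 129/1379 → 9.4, 5222/6012 → 86.9).
* Decade growth: integer floor of `100 * (b − a) / a` (1379 → 6012
  gives 335, where nearest-rounding would give 336; 6012 → 7418 gives
  23). Both conventions were fixed by reverse-engineering the printed
  values and are applied everywhere.
* Species change across snapshots is reported both as the net
  unique-count difference (which can hide turnover) and as newcomer /
  disappeared name sets per rank, because both notions are in common
  use and they differ exactly when taxa drop out between releases.
* Family rankings sort by descending count with lexicographic
  tie-breaks; families beyond the top-N aggregate into "Other";
  entries without a family statement are pooled as "Unassigned" and
  reported separately, never inside the ranking.

## Embedding evaluation

The five processing variants are generated by excising fully-known
SIGNAL (and PROPEP) spans and optionally dropping fragments; empty
results are dropped with a warning. The provider contract is "list of
(id, sequence) in, matrix of finite fixed-length vectors out". The
packaged provider embeds k-mer composition frequencies (default k = 2,
dim 400); it is deterministic and order-independent, which the suite
asserts bit-exactly. Silhouette is computed in the full embedding space
(not a 2-D projection — projections are recorded as optional
visualization settings, n_neighbors = 50, min_dist = 0.5, and play no
role in scoring), restricted to the top-N families after excluding
unlabeled/Unassigned entries and singleton families. The degenerate
all-points-identical configuration is scored 0 by convention. The
implementation is scikit-learn's silhouette; tests check it against an
exhaustive pairwise-distance computation on hand-sized configurations.

External language-model scores are deliberately not asserted anywhere:
the package's claim is the *ordering* behaviour on planted structure
(signal removal improves separation), not any absolute value.

## Synthetic data: what it emulates, what it does not

Each entry is built as optional signal peptide (random residues, 15–29
aa) + optional propeptide (8–19 aa) + a family-specific mature core (a
motif drawn once per family, mutated at 8% of positions per entry).
Because signal peptides are pure noise and cores are family-specific,
removing signals must sharpen family separation under any
composition-sensitive embedder — the planted-structure property the
embedding tests assert.

Defaults mirror the gross shape of curated venom data: seven orders
dominated by snakes, spiders, cone snails and scorpions (≈ 20% of
entries marine), fifteen families whose raw names exercise truncation,
conotoxin expansion and aliasing, mature peptides mostly tens of
residues with two enzyme families of hundreds, disulfide counts
Poisson-distributed around 3.5, ~17% fragments, dual-criterion mix
(45/15/35/5% tissue-only/keyword-only/both/neither), and a
protein-existence distribution concentrated on levels 1–2. These are
standing study conditions, chosen once; ground truth is exact
bookkeeping of what was emitted, never a statistical target.

The generator does **not** emulate real venom biology: no cysteine
scaffolds behind the disulfide counts, no codon- or composition-level
realism, no correlation between family and PTM repertoire beyond what
falls out of length. Passing tests therefore demonstrate that the
pipeline *measures correctly*, not that real venom data has any
particular value of any metric.

Snapshot series are supersets by construction (entry counts follow the
growth factors exactly); newcomers are planted by making an order or
family eligible only from a given year, disappearances by excluding an
order from a single snapshot. Determinism is end to end: one
`numpy.random.Generator` seeded from the config, byte-identical DAT
output across runs.

## Problem sizes and runtime

The suite runs on fixtures of 300 entries (single snapshot), a
200/400/600-entry three-snapshot series, and 1000 entries for the
mature-length oracle — sizes at which every exact-recovery check is
instantaneous while still exercising every code path; the full suite
completes in a few seconds, the acceptance script in about two.

## Known limitations

* The flat-file writer targets the canonical dialect only; it is not a
  general Swiss-Prot emitter (no DT/OS/RN blocks, single-line CC
  blocks, placeholder MW/CRC64 in SQ headers).
* Habitat and alias tables ship as documented seeds, not the full
  curated supplements; real-data runs need extended tables.
* Secondary accessions are ignored; datasets are keyed per snapshot,
  and cross-release accession-history resolution is out of scope.
* Toxic-dose parsing is keyword-level only (no unit normalization).
* The k-mer provider is a deterministic stand-in with the same contract
  as a protein language model, adequate for ordering planted structure
  but not a substitute for learned embeddings on real sequences.
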