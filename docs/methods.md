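# Methods

`pgm-paralogs` re-implements, as a reusable library, a comparative analysis
of the five human α-D-phosphohexomutase paralogs (PGM1, PGM2, PGM2L1, PGM3,
PGM5): cross-paralog residue mapping through a circular-permutation-aware
alignment, active-site motif profiling, knowledge-based transfer of
disease-associated positions to population missense variants, distance-based
phylogenetics under the JTT model, and tissue-expression normalisation.
This note records the models, the defaults and why, and the design choices
made where the design was genuinely open.

## Circular permutation of PGM3

PGM3 carries a circular permutation within domain 1: native residues 54–114
and 115–169 occupy swapped positions in the chain relative to the other
paralogs, while the fold (including the phosphoserine loop) is unchanged.
All alignment work therefore uses the *adjusted* PGM3 sequence
(prefix + 115–169 + 54–114 + suffix); a `CoordinateTranslator` is attached
to the alignment row and every reported position — position maps, variant
anchors, region extractions — is converted back to native numbering.  The
adjusted/native mapping is an exact bijection, tested by round-trip on
random sequences and specs.

## Position mapping and variant transfer

`build_position_map` turns each alignment column into a correspondence group
of `(protein, native position)` pairs.  Mapping is **strict**: a protein
gapped in a column is absent from the group, and no ±k rescue window is
applied, because the catalogued cross-paralog correspondences are exact
residue matches.  For a fixed protein pair the induced mapping is injective.

Population variants are classified with a precedence chain:

1. `confirmed_disease` — the entry itself is a patient variant;
2. `at_disease_position` — a population variant at a position where the
   *same* protein already has a patient variant.  These are tabulated (the
   source catalog shows them in parentheses) but are not counted as *new*
   corresponding variants;
3. `corresponds_to_disease` (category 1) — the position maps onto a patient
   position of another protein in the disease catalog;
4. `functional_region` (category 2) — the position lies inside one of the
   four active-site regions;
5. `unclassified` — everything else.

Categories 2–4 additionally require a *significant physicochemical change*
and *population rarity*.  The `at_disease_position` bucket is an extension
over a plain two-category scheme; without it, same-position substitutions
(e.g. PGM1 Q41E at the patient position Q41R) would inflate the
category-1 count, which by its published definition covers only new
positions.

Counting conventions in `summarize` follow the source study, including its
two inconsistent conclusion groupings: `new_variants_pgm1_pgm3` counts
categories 1+2 restricted to PGM1/PGM3 (16 on the bundled table), while
`new_variants_other_paralogs` counts category 1 only (11).  Both are
reported; no reconciliation is forced.

### Physicochemical significance

The Grantham distance is recomputed at call time from the 1974 formula
`D = 50.723·sqrt(1.833·Δc² + 0.1018·Δp² + 0.000399·Δv²)` with the published
composition/polarity/volume values, rounded to integers.  Spot checks:
G–R = 125, L–I = 5, D–N = 23, R–C = 180; the mean over all pairs is ≈100.
Two extreme pairs (C–W, S–L) round to one unit below the printed historical
table — a rounding artefact of the original publication.

Default threshold τ = 60 (G→R in, L→I out).  The curated variant table
carries an explicit per-entry expert flag that overrides τ, because the
original selection was expert judgment and includes substitutions with
Grantham scores as low as 23 (D→N) and 29 (E→Q, R→H); τ governs only
de-novo screening of new variant tables.  Frequency default: variants pass
when rarer than 1e-3 (the highest frequency class in the catalog);
singletons always pass.

### Domains

PGM1 structural domain boundaries (1–191, 192–304, 305–421, 422–562) are
the only ones taken as given; the other paralogs inherit domains by
comparing their alignment column against the columns of the PGM1 boundary
residues.

## Active-site regions and profiles

The four regions — phosphoserine loop (TASH core), metal-binding loop
(DGDGDR/DPDADR), sugar-binding loop (GEESF / FAFEE / YFEAN), phosphate-
binding loop (paired arginines, SGT/SGS) — are configuration data expressed
as reference-alignment column spans anchored at the motifs, since the
source describes motifs, not coordinates.  Per-subgroup position frequency
matrices use a Jukes-style pseudocount (default 0.5 per residue); the
strict-conservation flag reflects raw counts, so a unanimous column is
strict regardless of pseudocount.  Sub-group classification aligns a query
globally (affine gaps, open 10 / extend 0.5, BLOSUM62) to each reference
row, inherits the best row's column map, and scores
`Σ log(freq/background)` over region columns (uniform background by
default).  Coverage below 80% of the columns the chosen reference row
occupies, or a winning margin under δ = 2.0 nats, yields *unclassified*;
δ is deliberately conservative and configurable.  Queries carrying a
circular permutation should be adjusted (`permute`) before classification —
otherwise the phosphoserine-loop columns cannot align and the query is
rejected for low coverage rather than misassigned.

## Phylogenetics

`complete_deletion` retains exactly the columns with a canonical residue in
every row.  Distances: p-distance, Poisson correction `−ln(1−p)`, or the
maximum-likelihood pairwise time under JTT (bounded 1-D optimisation of the
pair likelihood).  The JTT constants (exchangeabilities and equilibrium
frequencies, Jones et al. 1992) are bundled; the rate matrix is normalised
to one expected substitution per site, and transition matrices come from a
single symmetric eigendecomposition (the model is reversible).

Neighbor joining is the plain Saitou–Nei agglomeration: Q-matrix ties break
toward the lexicographically smallest index pair; negative branch estimates
are clamped to zero with the deficit moved to the sibling; output is
unrooted (trifurcating root).  BioNJ variance weighting and heuristic
maximum-likelihood topology search are out of scope — trees are scored as
given by Felsenstein pruning.  Consequently the published MEGA log-likelihood
(−23090.0265) and its "265 retained positions" are not reproduction targets:
both depend on MEGA internals and on the aligner used for the 85-sequence
dataset.  Property tests substitute: NJ is exact on additive matrices
(checked against an independent topology scan and scikit-bio's NJ), pruning
equals exhaustive enumeration over internal states on four taxa to 1e-9, and
the log-likelihood is invariant under re-rooting to 1e-8.

## Expression

Protein iBAQ matrices are log10-transformed (zeros become missing, with a
warning — an unobserved protein is absence of evidence, not a −∞ signal);
RNA matrices are Z-scored per tissue row with sample standard deviation
(n−1).  Constant rows become all-zero and are flagged; rows with fewer than
two observations are emitted missing.  Tissues with no signal for any
paralog are dropped before analysis, and fluid samples are excluded
upstream by the tissue list.  Heat-map row ordering uses average-linkage
hierarchical clustering on Euclidean distances with a deterministic leaf
order (the subtree containing the alphabetically smallest tissue goes
first); the clustering behind the published figure brackets is unstated, so
this ordering is a documented convention, not a reproduction.

## Synthetic data

Families are simulated under JTT on a known tree (default: the family's
sister-pair backbone `((PGM1,PGM5),(PGM2,PGM2L1),PGM3)` with 0.15/0.25/0.55
branch lengths, 400 residues), sub-group motifs are overwritten after
evolution (a constraint, i.e. a simplification of purifying selection, not
a selection model), and one taxon is circularly permuted.  Variant tables
plant category-1 variants at positions corresponding to a synthetic PGM1
catalog, category-2 variants inside motif regions, and decoys elsewhere,
with frequencies drawn 60/30/10 from the three rare classes; planted
substitutions use Grantham-distant alternates (≥100).  Expression matrices
are lognormal (σ = 0.5) with an 8-fold signature tissue per paralog.
Everything is a pure function of an explicit seed.

What the simulations do **not** emulate: indels (alignments are simulated
gap-free, so position transfer on synthetic data is exact by construction
— classifier recovery there tests the plumbing, not alignment quality),
site-rate heterogeneity, compositional drift, and real population genetics
of allele frequencies.  Passing recovery tests on synthetic data therefore
shows correctness of the machinery, not robustness to real-data alignment
error.

## The bundled reference fixtures

Real sequences cannot be redistributed here, so the package bundles a
*synthetic* reference alignment (so labelled in file names and docstrings)
constructed to satisfy, by design, every structural fact the analysis
depends on: real native lengths; PGM3 in adjusted coordinates; the four
motifs at the catalogued native positions; all cross-paralog rows of the
curated variant table anchored into shared columns; and unconstrained
residues evolved under JTT on the sister-pair topology so that identities
and NJ trees built from the fixture behave qualitatively like the family
(PGM1–PGM5 and PGM2–PGM2L1 most similar, PGM3 most distant).  The curated
variant table itself (patient positions of PGM1/PGM3, retained population
variants with frequency classes) is transcribed data, not simulation.  The
expression fixture is likewise synthetic, built to the qualitative
statements about the tissue panel (e.g. PGM2L1 peaking in prefrontal
cortex; PGM5 RNA in esophagus dwarfing all other tissues).  Copies are
shipped under `pgm_paralogs/data/` and are byte-identical to the generator
output (tested).

## Numerical and determinism notes

- All randomness flows through `numpy.random.default_rng` with explicit
  seeds; the fixture seed is a package constant.
- Transition-matrix exponentials clip tiny negative eigen-round-off to 0.
- The pairwise ML distance is optimised on [1e-8, 50] with `xatol = 1e-8`.
- Newick is written with 10-significant-digit branch lengths; parsing is
  delegated to scikit-bio.
- Test problem sizes (400-residue simulations, 100-replicate recovery runs,
  10-member families) were chosen as the smallest sizes at which the
  stochastic properties are stable.

## Known limitations

- The classifier's query alignment is pairwise-to-best-row; remote queries
  that would need profile alignment may be rejected as low-coverage.
- Domain assignment outside PGM1 is column-based and inherits any local
  alignment error at domain boundaries.
- `polyphen_hook` only consumes externally supplied scores; no structure- or
  service-based validation is performed.
- Fig-5B-style seqinR distances are not reproduced; the identity matrix
  emits 1 − identity/100 as its companion distance without claiming
  equality with that tool.
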