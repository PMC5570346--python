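# pgm-paralogs

Comparative sequence, variant, phylogeny and expression analysis of the
human phosphoglucomutase-1 (PGM1) paralog family.

The human genome encodes five α-D-phosphohexomutase paralogs — PGM1, PGM2,
PGM2L1, PGM3 and PGM5 — that share a four-domain fold and four conserved
active-site regions (the phosphoserine loop, the metal-binding loop, the
sugar-binding loop and the phosphate-binding loop) but differ in substrate
preference and biological role.  PGM1 and PGM3 deficiencies are established
inherited diseases; the other three paralogs have no confirmed patient
variants yet.  This package implements the knowledge-based screen that
transfers disease-associated residue positions across paralogs: if a
population missense variant of PGM2/PGM2L1/PGM5 (or a new PGM1/PGM3
variant) lands on a residue position that is either (1) equivalent, through
a curated alignment, to a confirmed disease position of PGM1 or PGM3, or
(2) inside one of the key active-site regions — and the substitution is a
significant physicochemical change and rare in the population — it is a
candidate for protein dysfunction.

For a variant `v = (P, i, a→b)` of paralog `P` at native position `i`, the
classifier computes

- the alignment column group `G(P, i)` of `(paralog, native position)`
  pairs, via a circular-permutation-aware reference alignment (PGM3 is
  aligned with native residues 54–114 and 115–169 swapped, and every result
  is reported back in native numbering);
- the Grantham distance
  `D(a,b) = 50.723·√(1.833·Δc² + 0.1018·Δp² + 0.000399·Δv²)`
  (significant when `D ≥ τ`, default τ = 60, or when the curated expert
  flag says so);
- a rarity predicate on the ExAC-style frequency class (pass below 1e-3;
  singletons always pass).

Around this core the package provides the rest of the published pipeline:
pairwise identity matrices, per-subgroup position frequency matrices (logo
data) and a log-odds sub-group classifier for the four active-site regions,
complete-deletion gap filtering, p/Poisson/JTT-ML pairwise distances,
Saitou–Nei neighbor joining, Felsenstein-pruning log-likelihoods under the
bundled JTT model, iBAQ log-scaling and per-row Z-scoring of tissue
expression matrices, and seeded synthetic-data generators (families on a
known tree, planted variant tables, planted expression signatures) so that
every stage is testable offline.  All bundled sequence and expression
fixtures are synthetic stand-ins, constructed so that every catalogued
cross-paralog correspondence and motif holds by design (see
`docs/methods.md`); the curated variant table itself is transcribed data.

## Worked example

Classify the bundled variant table against the bundled alignment, catalog
and regions:

```sh
$ pgm-paralogs classify-variants --out classifications.tsv
disease_positions_PGM1: 18
disease_positions_PGM3: 8
disease_positions_total: 26
category1_variants: 18
category2_variants: 29
category2_positions: 27
at_disease_position_variants: 7
new_variants_pgm1_pgm3: 16
new_variants_other_paralogs: 11
predicted_variants_total: 54
```

Reading: PGM1 and PGM3 contribute 18 and 8 confirmed disease positions
(26 total).  Among the retained population variants, 18 fall at positions
corresponding to a disease position of another paralog (category 1), and
29 more — at 27 distinct positions — fall inside the active-site regions
(category 2).  Grouped the way the screen's conclusions group them, that is
16 new candidate variants in PGM1+PGM3 and 11 category-1 candidates in
PGM2/PGM2L1/PGM5.  Seven further variants sit at already-known disease
positions of their own protein and are tabulated separately.

Per-variant output (`classifications.tsv`) carries the category, Grantham
score, rarity, inherited structural domain (1–4) and the anchoring disease
position, e.g. the PGM3 population variant R496W anchors at PGM1 R503
(both phosphate-binding-loop arginines, domain 4).

Position transfer and phylogeny from the same alignment:

```sh
$ pgm-paralogs map-position --from PGM1:503 --to PGM5
PGM1:503 -> PGM5:508
$ pgm-paralogs phylo --out tree.nwk
456 gap-free columns retained
NJ tree (p_distance) -> tree.nwk
$ cat tree.nwk
(PGM3:0.4292763158,(PGM1:0.2532894737,PGM5:0.2423245614):0.1200657895,(PGM2:0.2368421053,PGM2L1:0.2478070175):0.1167763158);
```

The tree shows the family's two sister pairs, (PGM1, PGM5) and
(PGM2, PGM2L1), with PGM3 most distant.  `pgm-paralogs run --out-dir out/`
chains every stage (identities, profiles, phylogeny, variants, expression)
and writes a manifest with checksums; reruns are byte-identical.

Other subcommands: `permute`, `identity-matrix`, `profiles`, `classify`
(sub-group assignment of query FASTA), `expression`, and
`simulate family|variants|expression|bundle` for the seeded generators.

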