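# Methods

## The mediation model

`mirbridge` rests on one biological hypothesis: a lncRNA and a protein
that interact with a common set of miRNAs are more likely to interact
with each other (the miR-21 / PTEN / PTENpg1 regulatory triangle is the
canonical example).  The method therefore needs no training set of
direct lncRNA–protein interactions — only the two indirect interaction
layers — which makes it usable exactly where supervised predictors run
out of labelled data.  The cost of this design is coverage: only
lncRNA–protein pairs connected through at least one shared miRNA can
receive a non-zero score.

### Curation

Both edge lists are restricted to the miRNAs they share; entities left
without an edge are dropped.  Identifier matching is exact string
matching after whitespace trimming — no symbol aliasing is attempted,
so inputs must already use one naming scheme per entity class.  All
identifier lists are sorted lexicographically, making every downstream
matrix reproducible bit-for-bit on identical input.

### Network similarity and K

A miRNA's contribution within one bipartite network is
`c(m) = −ln(deg(m)/Σ deg)` — the self-information of picking one of its
edges at random, so hub miRNAs are discounted and rare interactors
dominate.  Natural logarithms throughout; units are nats.  Pair
similarity sums contributions over shared neighbours.  Two details the
formulas leave open:

* **Diagonal.**  The pair formula applied with `u = v` sums an entity's
  whole neighbourhood.  We compute it that way, but the diagonal is
  overwritten with 1 by normalization, so the choice is inert (stated
  because the oracle tests exercise it).
* **Degree-0 miRNAs** can appear only in non-curated input.  They are
  excluded from the normalizing sum and marked NaN; they have no
  neighbours, so the marker can never propagate into a similarity.

The whole-network correlation K uses the combined degree
`t(m) = |L(m)| + |P(m)|` and couples every lncRNA–protein pair through
their shared miRNAs.  On curated input `t(m) ≥ 2`, so K is finite and
non-negative, and `K(l, p) = 0` exactly when the pair shares no miRNA.

### Normalization and scoring

Row normalization divides each off-diagonal entry by its row's
off-diagonal sum and sets the diagonal to 1: every entity spreads one
unit of similarity mass over its peers, and multiplying a similarity
matrix by any positive constant leaves `Q` — hence `W` — unchanged.
Two deliberate choices:

* A row with no off-diagonal similarity keeps zeros (only the diagonal
  is 1).  Dividing by zero is undefined, and an isolated entity must not
  inject similarity mass it has no evidence for; `Q` stays close to the
  identity for such entities.
* `Q` is generally asymmetric and is left so; no symmetrization.

`W = Q1 K Q2` is a single closed-form product — no propagation,
restarts, or learning.  Prediction uses a strict `>` threshold; the
shipped recommended operating point (2.147) balances TPR and FPR on the
curated-database study and is only meaningful on comparable score
scales — for other datasets use the balanced threshold reported by the
evaluation.

### Sequence similarity

`e(u, v) = w(u, v)/(|u| + |v|)`, with `w` the exact Smith–Waterman
score (no heuristic seeding; the entity counts here are a few hundred,
so all-pairs exact alignment is affordable).  The original description
does not fix a scoring scheme, so the package defaults to community
conventions — nucleotides: match +2, mismatch −1, gap open −5, gap
extend −2; proteins: BLOSUM62, gap open −11, extend −1 — and serializes
the scheme into every output for provenance.  A gap of length `g` costs
`open + (g−1)·extend`.  With match +2 the nucleotide similarity is
bounded in [0, 1] since `w ≤ 2·min(|u|, |v|)`.  Ambiguous residues are
replaced on read by a sentinel scoring −10⁴ against everything, so they
can never support an alignment (a conservative choice; wildcards that
"match anything" would inflate similarity between low-quality
sequences).

### Pseudo-composition features

PseDNC: the 16 dinucleotide frequencies plus λ correlation factors
`θ_j`, each the average over positions of the mean squared property
difference between dinucleotides j apart, combined as
`d_k = f_k/(1 + ω₁Σθ)` and `d_{16+j} = ω₁θ_j/(1 + ω₁Σθ)` — so every
vector sums to 1.  PseAAC is the analogous type-1 construction over the
20 amino acids.  Defaults λ = 10, ω₁ = 0.1, τ = 11, ω₂ = 0.5 follow the
calibration grid search of the study this model reproduces (λ, τ in
10–20; ω₁ in 0.1–1; ω₂ in 0.05–0.5).

Property profiles are packaged as versioned TSVs and z-standardized on
load (each property to mean 0 / SD 1 over its alphabet), following the
practice of the standard pseudo-composition web tools; standardization
makes the features invariant to each scale's original units.  The
dinucleotide table carries the six helical step parameters (Twist,
Tilt, Roll, Shift, Slide, Rise).  The amino-acid table spans eight
standard physicochemical axes — Hopp–Woods hydrophilicity, Jones
hydrophobicity, Zimmerman isoelectric point and bulkiness,
Krigbaum–Komoriya side-chain volume, Grantham polarity, Kyte–Doolittle
hydropathy, and residue mass.  Any table with the same layout can be
substituted via `PropertyTable.from_tsv`.

Feature similarity is `1/‖V(u) − V(v)‖₂`, which is singular for
identical vectors; distances below ε = 10⁻⁸ are capped at 1/ε, which
preserves the ranking while keeping the matrix finite.  Entities whose
(unambiguous) sequence is shorter than the correlation depth are
excluded with a warning and zero similarity rows — "no evidence", never
NaN.

### Evaluation

Negatives are all pairs of the evaluated universe that are not gold
positives; the universe is either every pair of the scored matrix
(default) or only pairs among entities appearing in the gold standard
(`--universe gold-entities`) — the construction consistent with a
highly imbalanced verified-interaction test set.  The threshold sweep
takes one operating point per distinct score, so tied scores move as a
block and contribute diagonal ROC segments; trapezoidal integration
then equals the half-credit Mann–Whitney concordance exactly (a tested
identity).  AUPR uses step-wise, non-interpolated integration
(`Σ ΔR·P`), matching average precision; precision at an empty
prediction set is reported as 1 by logged convention.  The enrichment
test is a Pearson chi-square with 1 df and no continuity correction
(counts are large in the intended regime; a warning is emitted if any
expected cell drops below 1), with the p-value floored at "< 1e-16" for
display.

## Synthetic data generator

The generator emulates the *shape* of the curated interactome study
data: default 331 lncRNAs, 360 miRNAs and 103 proteins with edge
densities matching 1 356 lncRNA–miRNA and 1 156 protein–miRNA edges and
an overall gold-positive rate matching 1 925 verified pairs.  Edges are
i.i.d. Bernoulli draws; a repair pass (fixed scan order, same random
stream) gives every entity and every miRNA at least one edge on each
side, so the emitted networks are already curated and
`curate(generate(...))` is a no-op.  Gold positives are drawn with
probability `p1` for pairs sharing ≥ 1 miRNA and `p0` otherwise, with
`odds(p1)/odds(p0)` equal to the configured enrichment (default 8, a
strong but not overwhelming planted association) and the overall rate
held at the configured value — `p0` is solved by root finding on the
observed share fraction.  Sequences are i.i.d. uniform residues.

What the generator does **not** emulate: the heavy-tailed degree
distributions of real interactomes, sequence homology structure
(uniform random sequences share no evolutionary signal, so sequence and
feature similarities are nearly uninformative on synthetic data — their
ablation rows serve as a null reference), and identifier semantics.
Passing tests on synthetic data therefore demonstrates the pipeline's
correctness and its ability to recover a planted mediation signal, not
field performance on curated databases.

All randomness flows through a single integer-seeded generator with a
documented draw order (adjacency, repairs, gold, sequence child seeds),
so fixtures are stable and every run is bit-reproducible.

## Problem sizes in tests and the acceptance script

Oracle-equivalence checks run on random instances up to 10×10×10
against naive triple-loop implementations (tolerance 1e-10; AUROC vs
concordance at 1e-12).  Calibration of the null enrichment test uses
100 seeds and signal-recovery 20 seeds at the full study-shaped default
size, which the closed-form pipeline handles in milliseconds per seed.
The nine-combination ablation in the acceptance script uses a smaller
sequence-bearing dataset (80×90×40, lncRNAs 150–300 nt, proteins 80–200
aa) so that the all-pairs exact alignment step stays a one-second
computation while still exercising every similarity family.

## Known limitations

* Coverage is limited to pairs reachable through a shared miRNA; the
  score is exactly 0 otherwise (before the Q-mixing, which can move
  small mass onto unshared pairs via similar entities).
* The recommended threshold is scale-dependent and should be
  re-derived (balanced threshold) for any new dataset.
* No identifier mapping: inputs must be pre-harmonised.
* The chi-square enrichment test assumes independent pairs; pairs
  sharing an entity are not independent, so its p-value is a
  descriptive, not exact, quantity on real interactomes.
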