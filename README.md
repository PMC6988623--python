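# mirbridge

`mirbridge` predicts lncRNA–protein interactions **without any prior
knowledge of direct lncRNA–protein interactions**, using miRNAs as
mediators.  It is aimed at computational biologists who have curated
lncRNA–miRNA and protein–miRNA interaction tables (e.g. from an RNA
interactome database) and want a ranked list of candidate lncRNA–protein
pairs plus a full ROC/PR evaluation against any available gold standard.

## Model

Let `G1 = (L, M, E1)` be the bipartite lncRNA–miRNA network over `x`
lncRNAs and `y` miRNAs, and `G2 = (P, M, E2)` the protein–miRNA network
over `z` proteins and the same miRNAs.  After curation, `M` is exactly
the set of miRNAs interacting with both a lncRNA and a protein.

*Network similarity.*  Each miRNA contributes information inversely
related to its commonness: `c(m) = −ln(deg(m) / Σ deg)` within one
network (nats).  Two lncRNAs (or two proteins) are similar when they
share informative miRNAs:

```
n(u, v) = Σ_{m ∈ M(u) ∩ M(v)} c(m)
```

*Sequence similarity.*  `e(u, v) = w(u, v) / (|u| + |v|)` with `w` the
Smith–Waterman local-alignment score (defaults: match +2 / mismatch −1 /
gap −5/−2 for nucleotides; BLOSUM62, gap −11/−1 for proteins).

*Feature similarity.*  lncRNAs are embedded as pseudo dinucleotide
composition vectors (16 + λ dimensions; λ = 10, ω₁ = 0.1) and proteins
as type-1 pseudo amino-acid composition vectors (20 + τ dimensions;
τ = 11, ω₂ = 0.5), both built from standardized physicochemical property
tables shipped with the package; `f(u, v) = 1 / ‖V(u) − V(v)‖₂`.

*Scoring.*  Whichever similarity family is chosen per side, the matrices
`S1` (lncRNA×lncRNA) and `S2` (protein×protein) are row-normalized into
`Q1`, `Q2` (unit diagonal, off-diagonal rows summing to 1).  The
whole-network correlation couples the two networks directly:

```
t(m) = |L(m)| + |P(m)|,   K(l, p) = −Σ_{m ∈ M(l) ∩ M(p)} ln(t(m) / Σ t)
```

and the final score matrix is `W = Q1 · K · Q2`.  Pairs with
`W(l, p)` strictly above a threshold (recommended operating point:
2.147) are predicted to interact.  Evaluation sweeps the threshold over
every distinct score to produce ROC and PR curves, AUROC/AUPR, and the
chi-square test for enrichment of known interactions among pairs
sharing a miRNA.

## Worked example

Generate a small synthetic dataset with a planted mediation signal,
score it with network similarity on both sides, and evaluate:

```sh
mirbridge synth --x 40 --y 30 --z 20 --lnc-density 0.08 \
    --prot-density 0.12 --positive-rate 0.1 --enrichment 10 \
    --seed 7 --out demo/
mirbridge score --lnc-edges demo/lncrna_mirna_edges.tsv \
    --prot-edges demo/protein_mirna_edges.tsv --out demo/score/
mirbridge evaluate --scores demo/score/score_matrix.tsv \
    --gold demo/gold_standard.tsv \
    --lnc-edges demo/lncrna_mirna_edges.tsv \
    --prot-edges demo/protein_mirna_edges.tsv --out demo/eval/
```

The synth step prints the curated profile:

```
{"n_lncrnas": 40, "n_mirnas": 30, "n_proteins": 20, "n_lnc_mirna_edges": 102, "n_prot_mirna_edges": 71}
```

the score step prints `553 pairs predicted above threshold 2.147`, and
the evaluate step prints (values from this exact command sequence):

```
{"auroc": 0.7352731567265989, "aupr": 0.18399826942917463, "balanced_threshold": 5.988250274900473, "balanced_accuracy": 0.74, "enrichment_chi2": 72.15734427567511, "enrichment_p": "< 1e-16"}
```

AUROC ≈ 0.74 on an enrichment-10 planted signal: pairs that share a
miRNA (and are therefore enriched for true interactions) rank above
pairs that do not.  The chi-square confirms the planted association
between miRNA sharing and interaction.  `mirbridge ablate` adds the
3 × 3 table of similarity combinations plus the six single-matrix
configurations in which `Q1` or `Q2` is replaced by the identity.

Real datasets are analysed the same way: point `--lnc-edges`,
`--prot-edges` (and optionally `--lnc-fasta` / `--prot-fasta`,
`--gold`) at your curated tables.

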