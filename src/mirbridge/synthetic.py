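"""Synthetic heterogeneous datasets with a planted mediation signal.

The generator emulates the shape of the curated RAID study data: two
bipartite networks over a shared miRNA set (default 331 lncRNAs, 360
miRNAs, 103 proteins at the curated edge densities), plus a gold
standard in which lncRNA-protein pairs sharing at least one miRNA are
enriched for "true" interactions by a tunable odds ratio.  Random
sequences make the sequence- and feature-similarity paths runnable
without any download.

All randomness flows through one numpy Generator seeded from a single
integer.  Draw order (fixed; documented so later additions do not
silently shift fixtures):
  1. lncRNA-miRNA adjacency Bernoulli draws,
  2. protein-miRNA adjacency Bernoulli draws,
  3. repair edges for empty lncRNA rows, then empty protein rows, then
     miRNA columns missing a lncRNA edge, then missing a protein edge
     (row/column scan order),
  4. gold-standard pair draws,
  5. two child seeds for lncRNA and protein sequence generation.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import brentq

from .dataio import (
    AMINO_ACIDS,
    NUCLEOTIDES,
    Alphabet,
    EdgeList,
    EntityClass,
    HeterogeneousDataset,
    SequenceStore,
    curate,
)
from .evaluation import GoldStandard


@dataclass
class SynthConfig:
    """Study-shaped defaults: sizes, densities and base positive rate
    match the curated-database profile (331/360/103 entities, ~1356 and
    ~1156 edges, ~1925 gold positives)."""

    x: int = 331
    y: int = 360
    z: int = 103
    lnc_density: float = 1356 / (331 * 360)
    prot_density: float = 1156 / (103 * 360)
    positive_rate: float = 1925 / (331 * 103)
    enrichment: float = 8.0  # odds ratio for shared-miRNA pairs
    lnc_length: tuple[int, int] = (200, 1000)
    prot_length: tuple[int, int] = (100, 600)
    with_sequences: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        for d in (self.lnc_density, self.prot_density):
            if not 0 < d <= 1:
                raise ValueError("edge densities must be in (0, 1]")
        if self.enrichment < 1:
            raise ValueError("enrichment odds ratio must be >= 1")
        if not 0 < self.positive_rate < 1:
            raise ValueError("positive_rate must be in (0, 1)")
        if min(self.x, self.y, self.z) < 1:
            raise ValueError("x, y, z must be >= 1")
        # expected number of pairs sharing >= 1 miRNA
        p_share = 1 - (1 - self.lnc_density * self.prot_density) ** self.y
        if p_share * self.x * self.z < 1:
            raise ValueError(
                "infeasible config: expected number of shared-miRNA pairs < 1"
            )


def random_sequences(
    ids: list[str],
    alphabet: Alphabet,
    length_range: tuple[int, int],
    seed: int,
) -> SequenceStore:
    """I.i.d. uniform-residue sequences, deterministic under the seed."""
    rng = np.random.default_rng(seed)
    letters = np.array(
        list(NUCLEOTIDES if Alphabet(alphabet) is Alphabet.NUCLEOTIDE else AMINO_ACIDS)
    )
    lo, hi = length_range
    if lo < 2 or hi < lo:
        raise ValueError("invalid sequence length range")
    sequences = {}
    for name in ids:
        length = int(rng.integers(lo, hi + 1))
        sequences[name] = "".join(rng.choice(letters, size=length))
    return SequenceStore(sequences=sequences, alphabet=Alphabet(alphabet))


def _repair(adj: np.ndarray, rng: np.random.Generator) -> None:
    """Give every row at least one edge (uniform column choice)."""
    for i in np.flatnonzero(adj.sum(axis=1) == 0):
        adj[i, rng.integers(adj.shape[1])] = 1


def _repair_columns(adj: np.ndarray, rng: np.random.Generator) -> None:
    for j in np.flatnonzero(adj.sum(axis=0) == 0):
        adj[rng.integers(adj.shape[0]), j] = 1


def _positive_probs(rate: float, share_frac: float, odds_ratio: float):
    """Solve (p0, p1) with odds(p1) = odds_ratio * odds(p0) and overall
    positive rate share_frac*p1 + (1-share_frac)*p0 = rate."""

    def p1_of(p0: float) -> float:
        return odds_ratio * p0 / (1 - p0 + odds_ratio * p0)

    if odds_ratio == 1.0 or share_frac in (0.0, 1.0):
        return rate, rate

    def f(p0: float) -> float:
        return share_frac * p1_of(p0) + (1 - share_frac) * p0 - rate

    p0 = brentq(f, 1e-12, rate)
    return p0, p1_of(p0)


def generate(cfg: SynthConfig) -> tuple[HeterogeneousDataset, GoldStandard]:
    """Draw a curated dataset and a gold standard with planted signal.

    The emitted networks are already curated (every miRNA has >= 1 edge
    in both networks), so ``curate`` over the emitted edge lists is a
    round-trip no-op.
    """
    rng = np.random.default_rng(cfg.seed)
    lnc_ids = [f"lnc{i:04d}" for i in range(cfg.x)]
    mirna_ids = [f"mir{i:04d}" for i in range(cfg.y)]
    prot_ids = [f"prot{i:04d}" for i in range(cfg.z)]

    al = (rng.random((cfg.x, cfg.y)) < cfg.lnc_density).astype(np.uint8)
    ap = (rng.random((cfg.z, cfg.y)) < cfg.prot_density).astype(np.uint8)
    _repair(al, rng)
    _repair(ap, rng)
    _repair_columns(al, rng)
    _repair_columns(ap, rng)

    lnc_pairs = [
        (lnc_ids[i], mirna_ids[j]) for i, j in zip(*np.nonzero(al))
    ]
    prot_pairs = [
        (prot_ids[i], mirna_ids[j]) for i, j in zip(*np.nonzero(ap))
    ]
    shares = (al.astype(np.int64) @ ap.T.astype(np.int64)) > 0
    share_frac = float(shares.mean())
    p0, p1 = _positive_probs(cfg.positive_rate, share_frac, cfg.enrichment)
    prob = np.where(shares, p1, p0)
    gold_mask = rng.random((cfg.x, cfg.z)) < prob
    if not 0 < gold_mask.sum() < gold_mask.size:
        raise ValueError(
            "degenerate gold standard drawn (all or no pairs positive); "
            "adjust sizes or positive_rate"
        )
    positives = [
        (lnc_ids[i], prot_ids[j]) for i, j in zip(*np.nonzero(gold_mask))
    ]

    lnc_seqs = prot_seqs = None
    if cfg.with_sequences:
        seeds = rng.integers(0, 2**31 - 1, size=2)
        lnc_seqs = random_sequences(
            lnc_ids, Alphabet.NUCLEOTIDE, cfg.lnc_length, int(seeds[0])
        )
        prot_seqs = random_sequences(
            prot_ids, Alphabet.AMINO_ACID, cfg.prot_length, int(seeds[1])
        )

    ds = curate(
        EdgeList(lnc_pairs, EntityClass.LNCRNA),
        EdgeList(prot_pairs, EntityClass.PROTEIN),
        lnc_seqs=lnc_seqs,
        prot_seqs=prot_seqs,
    )
    # repairs guarantee curation keeps everything; ids are zero-padded so
    # sorted order equals generation order
    assert ds.lnc_ids == lnc_ids and ds.prot_ids == prot_ids
    gold = GoldStandard.from_pairs(positives, lnc_ids, prot_ids, universe="all")
    return ds, gold
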