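"""Pseudo-composition features and inverse-distance feature similarity.

lncRNAs are represented by pseudo dinucleotide composition (PseDNC):
the 16 dinucleotide frequencies augmented with lambda sequence-order
correlation factors derived from standardized physicochemical property
profiles.  Proteins use the classic type-1 pseudo amino-acid
composition (PseAAC): 20 residue frequencies plus tau correlation
factors.  Both vectors are normalized to sum to 1.

The feature similarity between two entities is the reciprocal Euclidean
distance between their vectors, capped for identical vectors.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

from .dataio import (
    AMBIGUOUS_SENTINEL,
    AMINO_ACIDS,
    NUCLEOTIDES,
    Alphabet,
    SequenceStore,
)
from .matrices import SimilarityMatrix

log = logging.getLogger(__name__)

#: reciprocal-distance cap for identical feature vectors (1 / epsilon)
ZERO_DISTANCE_EPS = 1e-8

DINUCLEOTIDES = [a + b for a in NUCLEOTIDES for b in NUCLEOTIDES]

# calibration defaults for the pseudo-composition parameters
DEFAULT_LAMBDA = 10
DEFAULT_OMEGA1 = 0.1
DEFAULT_TAU = 11
DEFAULT_OMEGA2 = 0.5


@dataclass
class PropertyTable:
    """Standardized physicochemical property profiles.

    ``values`` has one row per property and one column per alphabet
    item (16 dinucleotides or 20 amino acids); every row is
    z-standardized to mean 0 / SD 1 over the alphabet.
    """

    name: str
    items: list[str]
    property_names: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.property_names), len(self.items)):
            raise ValueError("property table shape mismatch")

    def standardized(self) -> "PropertyTable":
        v = self.values
        mu = v.mean(axis=1, keepdims=True)
        sd = v.std(axis=1, keepdims=True)
        if np.any(sd == 0):
            raise ValueError("constant property row cannot be standardized")
        return PropertyTable(self.name, self.items, self.property_names, (v - mu) / sd)

    @classmethod
    def from_tsv(cls, path: str | Path, name: str | None = None) -> "PropertyTable":
        df = pd.read_csv(path, sep="\t", comment="#", index_col=0)
        return cls(
            name=name or Path(path).stem,
            items=[str(c) for c in df.columns],
            property_names=[str(i) for i in df.index],
            values=df.to_numpy(),
        )


def _load_packaged(filename: str) -> PropertyTable:
    ref = resources.files("mirbridge.data").joinpath(filename)
    with resources.as_file(ref) as path:
        return PropertyTable.from_tsv(path).standardized()


def default_dinucleotide_table() -> PropertyTable:
    """Six standardized DNA step properties (Twist..Rise)."""
    table = _load_packaged("dinucleotide_properties.tsv")
    if table.items != DINUCLEOTIDES:
        raise ValueError("packaged dinucleotide table has unexpected columns")
    return table


def default_amino_acid_table() -> PropertyTable:
    """Eight standardized amino-acid scales (see data file header)."""
    table = _load_packaged("amino_acid_properties.tsv")
    if table.items != list(AMINO_ACIDS_ORDER):
        raise ValueError("packaged amino-acid table has unexpected columns")
    return table


# data file uses the conventional biochemical ordering
AMINO_ACIDS_ORDER = "ARNDCQEGHILKMFPSTWYV"


@dataclass
class PseVector:
    """A unit-sum pseudo-composition vector with its parameters."""

    values: np.ndarray
    params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)


def _correlation_factors(
    codes: np.ndarray, profiles: np.ndarray, max_rank: int
) -> np.ndarray:
    """theta_j, j=1..max_rank: mean over positions of the mean squared
    property difference between items ``j`` apart.

    ``codes`` indexes items along the sequence; ``profiles`` is the
    (n_properties, n_items) standardized table.
    """
    per_item = profiles.T  # (n_items, n_props)
    seq_props = per_item[codes]  # (n_positions, n_props)
    n = len(codes)
    thetas = np.empty(max_rank, dtype=float)
    for j in range(1, max_rank + 1):
        diff = seq_props[:-j] - seq_props[j:]
        thetas[j - 1] = np.mean(np.mean(diff * diff, axis=1))
    return thetas


def _assemble(freqs: np.ndarray, thetas: np.ndarray, omega: float) -> np.ndarray:
    denom = 1.0 + omega * thetas.sum()
    return np.concatenate([freqs / denom, omega * thetas / denom])


def psednc(
    seq: str,
    lam: int = DEFAULT_LAMBDA,
    omega1: float = DEFAULT_OMEGA1,
    props: PropertyTable | None = None,
) -> PseVector:
    """PseDNC vector of dimension 16 + lambda for a nucleotide sequence.

    Ambiguous-residue sentinels are dropped before computation.  The
    sequence must keep at least lambda + 2 unambiguous nucleotides so
    that the deepest correlation tier has one term.
    """
    if lam < 1:
        raise ValueError("lambda must be >= 1")
    if props is None:
        props = default_dinucleotide_table()
    seq = seq.replace(AMBIGUOUS_SENTINEL, "")
    if len(seq) < lam + 2:
        raise ValueError(
            f"sequence has {len(seq)} unambiguous nucleotides; PseDNC with "
            f"lambda={lam} needs at least {lam + 2}"
        )
    base_index = {c: i for i, c in enumerate(NUCLEOTIDES)}
    codes = np.array(
        [4 * base_index[a] + base_index[b] for a, b in zip(seq, seq[1:])]
    )
    freqs = np.bincount(codes, minlength=16).astype(float)
    freqs /= freqs.sum()
    thetas = _correlation_factors(codes, props.values, lam)
    return PseVector(
        values=_assemble(freqs, thetas, omega1),
        params={"kind": "PseDNC", "lambda": lam, "omega": omega1, "table": props.name},
    )


def pseaac(
    seq: str,
    tau: int = DEFAULT_TAU,
    omega2: float = DEFAULT_OMEGA2,
    props: PropertyTable | None = None,
) -> PseVector:
    """Type-1 PseAAC vector of dimension 20 + tau for a protein sequence."""
    if tau < 1:
        raise ValueError("tau must be >= 1")
    if props is None:
        props = default_amino_acid_table()
    seq = seq.replace(AMBIGUOUS_SENTINEL, "")
    if len(seq) < tau + 1:
        raise ValueError(
            f"sequence has {len(seq)} unambiguous residues; PseAAC with "
            f"tau={tau} needs at least {tau + 1}"
        )
    aa_index = {c: i for i, c in enumerate(props.items)}
    codes = np.array([aa_index[c] for c in seq])
    freqs = np.bincount(codes, minlength=20).astype(float)
    freqs /= freqs.sum()
    thetas = _correlation_factors(codes, props.values, tau)
    return PseVector(
        values=_assemble(freqs, thetas, omega2),
        params={"kind": "PseAAC", "tau": tau, "omega": omega2, "table": props.name},
    )


def feature_similarity(vectors: list[PseVector], ids: list[str]) -> SimilarityMatrix:
    """f(u, v) = 1 / ||V(u) - V(v)||_2, capped at 1/eps for zero distance."""
    if len(vectors) != len(ids):
        raise ValueError("one vector per id required")
    dims = {v.values.shape for v in vectors}
    if len(dims) > 1:
        raise ValueError(f"mixed vector dimensions: {sorted(dims)}")
    params = vectors[0].params if vectors else {}
    stack = np.vstack([v.values for v in vectors])
    diff = stack[:, None, :] - stack[None, :, :]
    dist = np.sqrt((diff * diff).sum(axis=2))
    capped = dist < ZERO_DISTANCE_EPS
    n_capped = int(capped.sum()) - len(ids)  # diagonal is always capped
    if n_capped > 0:
        log.info(
            "%d off-diagonal pair(s) at (near-)zero feature distance capped "
            "at 1/%g",
            n_capped // 2,
            ZERO_DISTANCE_EPS,
        )
    values = np.where(capped, 1.0 / ZERO_DISTANCE_EPS, 1.0 / np.where(capped, 1.0, dist))
    values = 0.5 * (values + values.T)
    return SimilarityMatrix(
        ids=list(ids), values=values, method="feature", meta=dict(params)
    )


def feature_similarity_from_store(
    store: SequenceStore,
    ids: list[str],
    lam: int = DEFAULT_LAMBDA,
    omega1: float = DEFAULT_OMEGA1,
    tau: int = DEFAULT_TAU,
    omega2: float = DEFAULT_OMEGA2,
    props: PropertyTable | None = None,
) -> SimilarityMatrix:
    """Compute pseudo-composition vectors for ``ids`` and their similarity.

    Entities whose sequence is too short for the requested correlation
    depth are excluded with a warning; their rows/columns are filled
    with 0 (no evidence), never NaN.
    """
    missing = [i for i in ids if i not in store]
    if missing:
        raise KeyError(f"sequences missing for ids: {missing}")
    nucleotide = store.alphabet is Alphabet.NUCLEOTIDE
    vectors: dict[str, PseVector] = {}
    excluded: list[str] = []
    for name in ids:
        try:
            if nucleotide:
                vectors[name] = psednc(store[name], lam, omega1, props)
            else:
                vectors[name] = pseaac(store[name], tau, omega2, props)
        except ValueError:
            excluded.append(name)
    if excluded:
        log.warning(
            "%d entities too short for pseudo-composition (excluded, "
            "zero similarity rows): %s",
            len(excluded),
            excluded[:10],
        )
    kept = [i for i in ids if i in vectors]
    if not kept:
        raise ValueError("no entity has a sequence long enough for features")
    sub = feature_similarity([vectors[i] for i in kept], kept)
    n = len(ids)
    values = np.zeros((n, n), dtype=float)
    pos = {name: k for k, name in enumerate(ids)}
    idx = np.array([pos[i] for i in kept])
    values[np.ix_(idx, idx)] = sub.values
    return SimilarityMatrix(ids=list(ids), values=values, method="feature", meta=sub.meta)
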