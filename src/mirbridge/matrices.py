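"""Labelled matrix containers shared across the pipeline.

Every matrix carries its identifier ordering explicitly; downstream
operations check orderings for equality and never reorder silently.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd


@dataclass
class SimilarityMatrix:
    """Square symmetric similarity matrix over one entity class.

    ``method`` tags how it was computed: "network", "sequence" or
    "feature".  ``meta`` records parameters (alignment scheme, pseudo
    composition parameters, ...) for provenance.
    """

    ids: list[str]
    values: np.ndarray
    method: str
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.ids)
        if self.values.shape != (n, n):
            raise ValueError(
                f"similarity matrix shape {self.values.shape} does not match "
                f"{n} identifiers"
            )
        if not np.all(np.isfinite(self.values)):
            raise ValueError("similarity matrix contains non-finite entries")
        if not np.allclose(self.values, self.values.T):
            raise ValueError("similarity matrix is not symmetric")
        if np.any(self.values < 0):
            raise ValueError("similarity matrix contains negative entries")

    def to_tsv(self, path: str | Path) -> None:
        pd.DataFrame(self.values, index=self.ids, columns=self.ids).to_csv(
            path, sep="\t"
        )

    @classmethod
    def from_tsv(cls, path: str | Path, method: str = "unknown") -> "SimilarityMatrix":
        df = pd.read_csv(path, sep="\t", index_col=0)
        return cls(ids=[str(i) for i in df.index], values=df.to_numpy(), method=method)


@dataclass
class NormalizedSimilarity:
    """Row-normalized similarity with unit diagonal (generally asymmetric)."""

    ids: list[str]
    values: np.ndarray
    method: str = "unknown"
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.ids)
        if self.values.shape != (n, n):
            raise ValueError("normalized similarity shape mismatch")


@dataclass
class ScoreMatrix:
    """lncRNA-by-protein real matrix; used for both K and W = Q1 K Q2."""

    lnc_ids: list[str]
    prot_ids: list[str]
    values: np.ndarray
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.lnc_ids), len(self.prot_ids)):
            raise ValueError(
                f"score matrix shape {self.values.shape} does not match "
                f"{len(self.lnc_ids)} lncRNAs x {len(self.prot_ids)} proteins"
            )
        if not np.all(np.isfinite(self.values)):
            raise ValueError("score matrix contains non-finite entries")

    def to_tsv(self, path: str | Path) -> None:
        pd.DataFrame(self.values, index=self.lnc_ids, columns=self.prot_ids).to_csv(
            path, sep="\t"
        )

    @classmethod
    def from_tsv(cls, path: str | Path) -> "ScoreMatrix":
        df = pd.read_csv(path, sep="\t", index_col=0)
        return cls(
            lnc_ids=[str(i) for i in df.index],
            prot_ids=[str(c) for c in df.columns],
            values=df.to_numpy(),
        )


def check_same_ids(a: Sequence[str], b: Sequence[str], what: str) -> None:
    """Raise if two identifier orderings are not exactly equal."""
    if list(a) != list(b):
        raise ValueError(
            f"identifier order mismatch in {what}: matrices must share the "
            "same ids in the same order (no silent reordering)"
        )
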