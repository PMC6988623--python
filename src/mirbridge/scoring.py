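"""Row normalization, the final score matrix W = Q1 K Q2, and predictions.

Similarity matrices are normalized row-wise: each off-diagonal entry is
divided by its row's off-diagonal sum and the diagonal is set to 1, so
every entity distributes one unit of similarity mass over its peers.
Rows with no off-diagonal similarity keep zeros off the diagonal ("no
evidence" must not inject mass).  The normalized matrices sandwich the
whole-network correlation K to give the final lncRNA-by-protein score
matrix; pairs scoring above a threshold are predicted to interact.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .matrices import NormalizedSimilarity, ScoreMatrix, SimilarityMatrix, check_same_ids

#: operating point balancing TPR and FPR on the curated-database study
RECOMMENDED_THRESHOLD = 2.147


def normalize(S: SimilarityMatrix) -> NormalizedSimilarity:
    """Row-normalize a similarity matrix (unit diagonal, off-diag sums 1).

    The result is generally asymmetric; no symmetrization is applied.
    """
    v = S.values
    if np.any(v < 0):
        bad = np.argwhere(v < 0)[:5]
        raise ValueError(f"negative similarity entries at indices {bad.tolist()}")
    off = v.copy()
    np.fill_diagonal(off, 0.0)
    row_sums = off.sum(axis=1)
    out = np.zeros_like(off)
    nz = row_sums > 0
    out[nz] = off[nz] / row_sums[nz, None]
    np.fill_diagonal(out, 1.0)
    return NormalizedSimilarity(
        ids=list(S.ids), values=out, method=S.method, meta=dict(S.meta)
    )


def identity_normalized(ids: list[str]) -> NormalizedSimilarity:
    """Identity stand-in used when one similarity matrix is ablated."""
    return NormalizedSimilarity(
        ids=list(ids), values=np.eye(len(ids)), method="identity"
    )


def score(
    Q1: NormalizedSimilarity, K: ScoreMatrix, Q2: NormalizedSimilarity
) -> ScoreMatrix:
    """W = Q1 K Q2 with id-order checks (never a silent reorder)."""
    check_same_ids(Q1.ids, K.lnc_ids, "Q1 vs K rows")
    check_same_ids(Q2.ids, K.prot_ids, "Q2 vs K columns")
    values = Q1.values @ K.values @ Q2.values
    return ScoreMatrix(
        lnc_ids=list(K.lnc_ids),
        prot_ids=list(K.prot_ids),
        values=values,
        provenance={
            "lnc_similarity": Q1.method,
            "prot_similarity": Q2.method,
            "lnc_meta": Q1.meta,
            "prot_meta": Q2.meta,
        },
    )


@dataclass
class PredictionSet:
    """Ranked (lncRNA, protein, score) rows with a predicted flag.

    Sorted by descending score, ties broken by lncRNA id then protein
    id; ``predicted`` is True iff score > threshold (strict).
    """

    table: pd.DataFrame
    threshold: float

    def to_tsv(self, path) -> None:
        out = self.table.copy()
        out["predicted"] = out["predicted"].astype(int)
        out.to_csv(path, sep="\t", index=False)

    @property
    def n_predicted(self) -> int:
        return int(self.table["predicted"].sum())


def predict(W: ScoreMatrix, threshold: float = RECOMMENDED_THRESHOLD) -> PredictionSet:
    """Rank all pairs and flag those scoring strictly above ``threshold``."""
    x, z = W.values.shape
    lnc = np.repeat(W.lnc_ids, z)
    prot = np.tile(W.prot_ids, x)
    scores = W.values.ravel()
    df = pd.DataFrame({"lncrna_id": lnc, "protein_id": prot, "score": scores})
    df = df.sort_values(
        ["score", "lncrna_id", "protein_id"],
        ascending=[False, True, True],
        kind="mergesort",
    ).reset_index(drop=True)
    df["predicted"] = df["score"] > threshold
    return PredictionSet(table=df, threshold=threshold)
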