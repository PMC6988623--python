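"""High-level drivers wiring similarities, K and W into workflows."""
from __future__ import annotations

import logging

import pandas as pd

from . import featsim, netsim, scoring, seqsim
from .dataio import Alphabet, HeterogeneousDataset
from .evaluation import GoldStandard, roc_pr
from .matrices import NormalizedSimilarity, ScoreMatrix, SimilarityMatrix

log = logging.getLogger(__name__)

SIMILARITY_METHODS = ("network", "sequence", "feature")


def similarity(
    ds: HeterogeneousDataset,
    side: str,
    method: str,
    scheme: seqsim.AlignmentScheme | None = None,
    feat_params: dict | None = None,
) -> SimilarityMatrix:
    """One similarity matrix for ``side`` in {"lnc", "prot"}."""
    if side not in {"lnc", "prot"}:
        raise ValueError("side must be 'lnc' or 'prot'")
    if method not in SIMILARITY_METHODS:
        raise ValueError(f"unknown similarity method {method!r}")
    net = ds.lnc_net if side == "lnc" else ds.prot_net
    if method == "network":
        return netsim.network_similarity(net)
    store = ds.lnc_seqs if side == "lnc" else ds.prot_seqs
    if store is None:
        raise ValueError(
            f"{method} similarity for {side} requires sequences, but none "
            "are loaded"
        )
    ids = net.entity_ids
    if method == "sequence":
        return seqsim.sequence_similarity(store, ids, scheme)
    params = feat_params or {}
    return featsim.feature_similarity_from_store(store, ids, **params)


def score_matrix(
    ds: HeterogeneousDataset,
    lnc_method: str = "network",
    prot_method: str = "network",
    drop_q1: bool = False,
    drop_q2: bool = False,
    lnc_scheme: seqsim.AlignmentScheme | None = None,
    prot_scheme: seqsim.AlignmentScheme | None = None,
    feat_params: dict | None = None,
) -> ScoreMatrix:
    """Final score matrix W = Q1 K Q2 (with optional identity ablations)."""
    K = netsim.whole_network_correlation(ds)
    if drop_q1:
        q1: NormalizedSimilarity = scoring.identity_normalized(ds.lnc_ids)
    else:
        q1 = scoring.normalize(similarity(ds, "lnc", lnc_method, lnc_scheme, feat_params))
    if drop_q2:
        q2 = scoring.identity_normalized(ds.prot_ids)
    else:
        q2 = scoring.normalize(similarity(ds, "prot", prot_method, prot_scheme, feat_params))
    return scoring.score(q1, K, q2)


def ablate(
    ds: HeterogeneousDataset,
    gold: GoldStandard,
    include_single: bool = True,
    lnc_scheme: seqsim.AlignmentScheme | None = None,
    prot_scheme: seqsim.AlignmentScheme | None = None,
    feat_params: dict | None = None,
) -> pd.DataFrame:
    """AUROC/AUPR for all nine similarity combinations, plus the six
    single-matrix configurations (Q1 or Q2 replaced by identity)."""
    K = netsim.whole_network_correlation(ds)
    q1s = {
        m: scoring.normalize(similarity(ds, "lnc", m, lnc_scheme, feat_params))
        for m in SIMILARITY_METHODS
    }
    q2s = {
        m: scoring.normalize(similarity(ds, "prot", m, prot_scheme, feat_params))
        for m in SIMILARITY_METHODS
    }
    rows = []

    def add(lnc_tag, prot_tag, q1, q2):
        res = roc_pr(scoring.score(q1, K, q2), gold)
        rows.append(
            {
                "lnc_similarity": lnc_tag,
                "prot_similarity": prot_tag,
                "auroc": res.auroc,
                "aupr": res.aupr,
            }
        )

    for lm in SIMILARITY_METHODS:
        for pm in SIMILARITY_METHODS:
            add(lm, pm, q1s[lm], q2s[pm])
    if include_single:
        ident1 = scoring.identity_normalized(ds.lnc_ids)
        ident2 = scoring.identity_normalized(ds.prot_ids)
        for lm in SIMILARITY_METHODS:
            add(lm, "identity", q1s[lm], ident2)
        for pm in SIMILARITY_METHODS:
            add("identity", pm, ident1, q2s[pm])
    return pd.DataFrame(rows)
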