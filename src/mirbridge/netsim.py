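"""Information-content network similarity and whole-network correlation.

Each miRNA carries a *network contribution* c(m) = -ln(deg(m) / total
edges) within one bipartite network: rare interactors are more
informative.  The network similarity of two lncRNAs (or two proteins) is
the summed contribution of the miRNAs they share.  The whole-network
correlation K couples the two networks: for a lncRNA l and a protein p,
K(l, p) sums -ln(t(m) / sum t) over their shared miRNAs, where
t(m) = deg_lnc(m) + deg_prot(m) is the miRNA's combined degree.

All logs are natural (units: nats).
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .dataio import HeterogeneousDataset, InteractionNetwork
from .matrices import ScoreMatrix, SimilarityMatrix


@dataclass
class ContributionVector:
    """Per-miRNA contribution in one bipartite network, in nats.

    miRNAs with degree 0 (possible only on non-curated input) carry NaN:
    they have no neighbours, so they can never appear in an intersection
    and their marker never propagates into a similarity.
    """

    mirna_ids: list[str]
    values: np.ndarray

    def filled(self) -> np.ndarray:
        """Contributions with the degree-0 NaN markers replaced by 0."""
        return np.nan_to_num(self.values, nan=0.0)


def contribution(net: InteractionNetwork) -> ContributionVector:
    """c(m_k) = -ln(deg(m_k) / sum_k deg(m_k)), per miRNA.

    Degree-0 miRNAs are excluded from the normalizing sum and marked NaN.
    """
    deg = net.mirna_degrees.astype(float)
    total = deg.sum()
    if total < 1:
        raise ValueError("network has no edges; contributions undefined")
    with np.errstate(divide="ignore"):
        vals = -np.log(deg / total)
    vals[deg == 0] = np.nan
    return ContributionVector(mirna_ids=list(net.mirna_ids), values=vals)


def network_similarity(net: InteractionNetwork) -> SimilarityMatrix:
    """Summed shared-miRNA contributions for every entity pair.

    The diagonal applies the same formula with u = v (an entity's
    self-intersection is its whole miRNA neighbourhood); row
    normalization later overwrites it with 1, so the choice is inert.
    """
    c = contribution(net).filled()
    a = net.adjacency.astype(float)
    values = (a * c) @ a.T
    values = 0.5 * (values + values.T)  # exact symmetry against fp jitter
    return SimilarityMatrix(
        ids=list(net.entity_ids),
        values=values,
        method="network",
        meta={"entity_class": net.entity_class.value, "units": "nats"},
    )


def whole_network_correlation(ds: HeterogeneousDataset) -> ScoreMatrix:
    """The lncRNA-by-protein whole-network correlation matrix K.

    K(l_i, p_j) = -sum over shared miRNAs m of ln(t(m) / sum_k t(m_k)),
    with t(m) the miRNA's combined degree across both networks.  On a
    curated dataset every miRNA has t(m) >= 2, so K is finite and
    non-negative, and K(i, j) = 0 iff l_i and p_j share no miRNA.
    """
    t = (ds.lnc_net.mirna_degrees + ds.prot_net.mirna_degrees).astype(float)
    if np.any(t == 0):
        raise ValueError(
            "dataset contains miRNAs with no edges in either network; "
            "curate the input first"
        )
    contrib = -np.log(t / t.sum())
    al = ds.lnc_net.adjacency.astype(float)
    ap = ds.prot_net.adjacency.astype(float)
    values = (al * contrib) @ ap.T
    return ScoreMatrix(
        lnc_ids=list(ds.lnc_ids),
        prot_ids=list(ds.prot_ids),
        values=values,
        provenance={"matrix": "whole_network_correlation", "units": "nats"},
    )
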