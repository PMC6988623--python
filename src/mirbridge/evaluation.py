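"""Confusion metrics, ROC/PR curves and the shared-miRNA enrichment test.

The gold standard is a set of verified lncRNA-protein pairs; every other
ordered pair of the evaluated universe counts as a negative.  Sweeping
the score threshold from the maximum to below the minimum yields one
operating point per distinct score (tied scores move together, giving
diagonal ROC segments, i.e. half-credit concordance).  AUROC is the
trapezoidal area under (FPR, TPR); AUPR uses step-wise (non-
interpolated) precision-recall integration.
"""
from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .dataio import HeterogeneousDataset
from .matrices import ScoreMatrix

log = logging.getLogger(__name__)


@dataclass
class GoldStandard:
    """Verified positive pairs over an explicit pair universe."""

    positives: set[tuple[str, str]]
    lnc_ids: list[str]
    prot_ids: list[str]

    def __post_init__(self) -> None:
        lnc, prot = set(self.lnc_ids), set(self.prot_ids)
        bad = [p for p in self.positives if p[0] not in lnc or p[1] not in prot]
        if bad:
            raise ValueError(
                f"{len(bad)} gold pair(s) reference unknown ids, e.g. {bad[:5]}"
            )

    @property
    def n_universe(self) -> int:
        return len(self.lnc_ids) * len(self.prot_ids)

    def label_matrix(self) -> np.ndarray:
        li = {e: i for i, e in enumerate(self.lnc_ids)}
        pi = {e: i for i, e in enumerate(self.prot_ids)}
        labels = np.zeros((len(self.lnc_ids), len(self.prot_ids)), dtype=bool)
        for l, p in self.positives:
            labels[li[l], pi[p]] = True
        return labels

    @classmethod
    def from_pairs(
        cls,
        pairs: list[tuple[str, str]],
        lnc_ids: list[str],
        prot_ids: list[str],
        universe: str = "all",
    ) -> "GoldStandard":
        """Build a gold standard under one of two universe conventions.

        ``universe="all"`` keeps every lncRNA-protein pair of the scored
        matrix; ``"gold-entities"`` restricts the universe to entities
        that appear in at least one gold pair.
        """
        if universe not in {"all", "gold-entities"}:
            raise ValueError("universe must be 'all' or 'gold-entities'")
        positives = set(pairs)
        if universe == "gold-entities":
            gl = {l for l, _ in positives}
            gp = {p for _, p in positives}
            lnc_ids = [i for i in lnc_ids if i in gl]
            prot_ids = [i for i in prot_ids if i in gp]
        return cls(positives=positives, lnc_ids=lnc_ids, prot_ids=prot_ids)


def read_gold(path, universe_lnc_ids, universe_prot_ids, universe="all") -> GoldStandard:
    """Read a two-column lncRNA/protein TSV into a GoldStandard."""
    df = pd.read_csv(path, sep="\t")
    if df.shape[1] < 2:
        raise ValueError(f"{path}: expected >= 2 columns")
    pairs = list(
        zip(df.iloc[:, 0].astype(str).str.strip(), df.iloc[:, 1].astype(str).str.strip())
    )
    return GoldStandard.from_pairs(pairs, universe_lnc_ids, universe_prot_ids, universe)


def _aligned_scores_labels(W: ScoreMatrix, gold: GoldStandard):
    if set(gold.lnc_ids) - set(W.lnc_ids) or set(gold.prot_ids) - set(W.prot_ids):
        raise ValueError("gold universe references ids absent from the score matrix")
    li = [W.lnc_ids.index(i) for i in gold.lnc_ids]
    pi = [W.prot_ids.index(i) for i in gold.prot_ids]
    sub = W.values[np.ix_(li, pi)]
    return sub.ravel(), gold.label_matrix().ravel()


@dataclass
class ConfusionResult:
    tp: int
    tn: int
    fp: int
    fn: int
    tpr: float
    fpr: float
    precision: float
    recall: float
    accuracy: float


def confusion_at(
    W: ScoreMatrix, gold: GoldStandard, threshold: float
) -> ConfusionResult:
    """Confusion counts and the five rates at one strict (>) threshold.

    Precision is reported as 1 when nothing is predicted (logged
    convention).
    """
    scores, labels = _aligned_scores_labels(W, gold)
    pred = scores > threshold
    tp = int(np.sum(pred & labels))
    fp = int(np.sum(pred & ~labels))
    fn = int(np.sum(~pred & labels))
    tn = int(np.sum(~pred & ~labels))
    if tp + fp == 0:
        log.info("no predictions at threshold %g; precision = 1 by convention", threshold)
        precision = 1.0
    else:
        precision = tp / (tp + fp)
    tpr = tp / (tp + fn) if tp + fn else 0.0
    fpr = fp / (fp + tn) if fp + tn else 0.0
    return ConfusionResult(
        tp=tp,
        tn=tn,
        fp=fp,
        fn=fn,
        tpr=tpr,
        fpr=fpr,
        precision=precision,
        recall=tpr,
        accuracy=(tp + tn) / (tp + tn + fp + fn),
    )


@dataclass
class EvaluationResult:
    """Threshold sweep with per-point confusion counts and curve areas."""

    thresholds: np.ndarray
    tp: np.ndarray
    fp: np.ndarray
    tn: np.ndarray
    fn: np.ndarray
    tpr: np.ndarray
    fpr: np.ndarray
    precision: np.ndarray
    recall: np.ndarray
    accuracy: np.ndarray
    auroc: float
    aupr: float

    @property
    def balanced_index(self) -> int:
        """Index of the operating point maximizing TPR + (1 - FPR)."""
        return int(np.argmax(self.tpr + (1.0 - self.fpr)))

    @property
    def balanced_threshold(self) -> float:
        return float(self.thresholds[self.balanced_index])

    @property
    def balanced_accuracy_point(self) -> float:
        """Accuracy at the balanced (max TPR + 1 - FPR) operating point."""
        return float(self.accuracy[self.balanced_index])

    def points_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "threshold": self.thresholds,
                "tp": self.tp,
                "fp": self.fp,
                "tn": self.tn,
                "fn": self.fn,
                "tpr": self.tpr,
                "fpr": self.fpr,
                "precision": self.precision,
                "recall": self.recall,
                "accuracy": self.accuracy,
            }
        )

    def metrics_dict(self) -> dict:
        return {
            "auroc": self.auroc,
            "aupr": self.aupr,
            "balanced_threshold": self.balanced_threshold,
            "balanced_accuracy": self.balanced_accuracy_point,
        }


def roc_pr(W: ScoreMatrix, gold: GoldStandard) -> EvaluationResult:
    """Full threshold sweep over the score matrix against the gold pairs."""
    scores, labels = _aligned_scores_labels(W, gold)
    n_pos = int(labels.sum())
    n_neg = labels.size - n_pos
    if n_pos == 0 or n_neg == 0:
        raise ValueError(
            f"degenerate gold standard: {n_pos} positives / {n_neg} negatives"
        )
    order = np.argsort(-scores, kind="mergesort")
    s_sorted = scores[order]
    l_sorted = labels[order]
    # last index of every tied-score group
    distinct = np.nonzero(np.diff(s_sorted))[0]
    group_ends = np.r_[distinct, len(s_sorted) - 1]
    cum_tp = np.cumsum(l_sorted)
    cum_fp = np.cumsum(~l_sorted)
    tp = np.r_[0, cum_tp[group_ends]].astype(int)
    fp = np.r_[0, cum_fp[group_ends]].astype(int)
    fn = n_pos - tp
    tn = n_neg - fp
    # thresholds realizing each point under the strict > rule: the first
    # point (nothing predicted) at the maximum score, each group point at
    # the next distinct value, the final all-predicted point below min
    values = s_sorted[group_ends]
    thresholds = np.r_[values, -np.inf]
    tpr = tp / n_pos
    fpr = fp / n_neg
    with np.errstate(invalid="ignore"):
        precision = np.where(tp + fp > 0, tp / np.maximum(tp + fp, 1), 1.0)
    accuracy = (tp + tn) / labels.size
    auroc = float(np.trapezoid(tpr, fpr))
    recall = tpr
    aupr = float(np.sum(np.diff(recall) * precision[1:]))
    return EvaluationResult(
        thresholds=thresholds,
        tp=tp,
        fp=fp,
        tn=tn,
        fn=fn,
        tpr=tpr,
        fpr=fpr,
        precision=precision,
        recall=recall,
        accuracy=accuracy,
        auroc=auroc,
        aupr=aupr,
    )


@dataclass
class EnrichmentResult:
    """Chi-square association between miRNA sharing and interaction."""

    chi2: float
    p_value: float
    table: np.ndarray  # rows: shares / not; cols: interacting / not
    expected: np.ndarray

    @property
    def p_label(self) -> str:
        return "< 1e-16" if self.p_value < 1e-16 else f"{self.p_value:.3g}"


def enrichment_test(ds: HeterogeneousDataset, gold: GoldStandard) -> EnrichmentResult:
    """Pearson chi-square (1 df, no continuity correction) for the
    enrichment of known interactions among pairs sharing >= 1 miRNA."""
    shares = (
        ds.lnc_net.adjacency.astype(np.int64) @ ds.prot_net.adjacency.T.astype(np.int64)
    ) > 0
    li = [ds.lnc_ids.index(i) for i in gold.lnc_ids]
    pi = [ds.prot_ids.index(i) for i in gold.prot_ids]
    shares = shares[np.ix_(li, pi)].ravel()
    labels = gold.label_matrix().ravel()
    table = np.array(
        [
            [np.sum(shares & labels), np.sum(shares & ~labels)],
            [np.sum(~shares & labels), np.sum(~shares & ~labels)],
        ],
        dtype=np.int64,
    )
    chi2, p, _, expected = stats.chi2_contingency(table, correction=False)
    if np.any(expected < 1):
        warnings.warn(
            "chi-square expected cell count < 1; the enrichment test is "
            "unreliable on this dataset",
            stacklevel=2,
        )
    return EnrichmentResult(chi2=float(chi2), p_value=float(p), table=table, expected=expected)
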