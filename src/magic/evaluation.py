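"""Benchmarking of ranked factor predictions against known interactors.

The positive class for a perturbation experiment is the manipulated factor
plus its potential interactors (partners in a STRING-style links table
with combined score strictly greater than a threshold, default 300).  A
ranked factor list from any algorithm becomes a vector of positive /
negative calls with scaled ranks i/m in (0, 1]; from it we compute
precision-recall and ROC curves (no class balancing; PR is the headline
metric for these imbalanced problems), and the rank-cumulative excess
D(r) − r, whose area summarises how early true factors are ranked.
Contiguous runs of positive calls collapse to the rank of the first call
in the block before cumulation.  Metrics can be weighted by the fractional
rank F_R = 1/(integer rank of the manipulated factor).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import (
    average_precision_score,
    precision_recall_curve,
    roc_curve,
)

logger = logging.getLogger(__name__)

DEFAULT_LINK_THRESHOLD = 300.0


@dataclass(frozen=True)
class PositiveClass:
    """The manipulated factor and its potential interactors (upper-cased)."""

    manipulated_factor: str
    interactors: frozenset[str]

    @property
    def members(self) -> frozenset[str]:
        return self.interactors | {self.manipulated_factor}


def read_string_links(path: str | Path) -> pd.DataFrame:
    """Whitespace-delimited links table with protein1/protein2/combined_score."""
    df = pd.read_csv(path, sep=r"\s+")
    required = {"protein1", "protein2", "combined_score"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"links table {path} missing columns {sorted(missing)}")
    return df


def build_positive_class(
    links: pd.DataFrame | str | Path,
    factor: str,
    threshold: float = DEFAULT_LINK_THRESHOLD,
) -> PositiveClass:
    """Partners of ``factor`` with combined score strictly above ``threshold``.

    The links table is treated as undirected; symmetric duplicates count
    once.  A factor absent from the table yields an interactor-free class
    (just the factor itself) with a warning.
    """
    if not isinstance(links, pd.DataFrame):
        links = read_string_links(links)
    fac = factor.upper()
    a = links["protein1"].astype(str).str.upper()
    b = links["protein2"].astype(str).str.upper()
    s = links["combined_score"].astype(float)
    partners = set(b[(a == fac) & (s > threshold)]) | set(a[(b == fac) & (s > threshold)])
    partners.discard(fac)
    if not (a == fac).any() and not (b == fac).any():
        logger.warning("factor %s absent from links table; positives = {%s}", fac, fac)
    return PositiveClass(manipulated_factor=fac, interactors=frozenset(partners))


@dataclass
class CallsVector:
    """Positive/negative labels over a ranked factor list, with scaled ranks.

    Rank i of m maps to i/m; duplicate factor names keep one call per
    ranked entry (multiple ChIP tracks of the same factor each count).
    """

    factors: list[str]
    labels: np.ndarray        # bool, True = positive
    scaled_ranks: np.ndarray  # i/m in (0, 1]

    @property
    def n_positive(self) -> int:
        return int(self.labels.sum())


def calls_vector(ranked: Sequence[str], positives: PositiveClass | set[str]) -> CallsVector:
    """Label each ranked entry positive iff it belongs to the positive class."""
    entries = [str(f).strip() for f in ranked if str(f).strip()]
    if not entries:
        raise ValueError("ranked list is empty")
    members = (
        positives.members if isinstance(positives, PositiveClass)
        else {str(p).upper() for p in positives}
    )
    labels = np.array([f.upper() in members for f in entries])
    if not labels.any():
        logger.warning("no positives found in ranked list (%d entries)", len(entries))
    m = len(entries)
    return CallsVector(
        factors=entries,
        labels=labels,
        scaled_ranks=np.arange(1, m + 1) / m,
    )


@dataclass
class PRROCResult:
    precision: np.ndarray
    recall: np.ndarray
    fpr: np.ndarray
    tpr: np.ndarray
    pr_auc: float
    roc_auc: float


def pr_roc(calls: CallsVector, pr_mode: str = "trapezoid") -> PRROCResult:
    """PR and ROC curves with AUCs for a calls vector.

    The prediction score is 1 − scaled rank (best rank → highest score).
    PR AUC is trapezoidal area over the recall-sorted PR points by default;
    ``pr_mode="average_precision"`` switches to the step-wise estimator.
    No balancing of the classes is performed.
    """
    n_pos = calls.n_positive
    if n_pos == 0:
        raise ValueError("calls vector has no positive calls")
    if n_pos == calls.labels.size:
        raise ValueError("calls vector has no negative calls")
    scores = 1.0 - calls.scaled_ranks
    precision, recall, _ = precision_recall_curve(calls.labels, scores)
    fpr, tpr, _ = roc_curve(calls.labels, scores)
    if pr_mode == "trapezoid":
        # recall is monotone non-increasing in the emitted order; integrating
        # in that order keeps vertical (tied-recall) segments at zero width
        pr_auc = float(-np.trapezoid(precision, recall))
    elif pr_mode == "average_precision":
        pr_auc = float(average_precision_score(calls.labels, scores))
    else:
        raise ValueError(f"unknown pr_mode {pr_mode!r}")
    roc_auc = float(np.trapezoid(tpr, fpr))
    return PRROCResult(precision=precision, recall=recall, fpr=fpr, tpr=tpr,
                       pr_auc=pr_auc, roc_auc=roc_auc)


def block_adjusted_positive_ranks(calls: CallsVector) -> np.ndarray:
    """Scaled ranks of positive calls, contiguous runs collapsed to the first.

    Every call in a block of consecutive positives is assigned the scaled
    rank of the block's first element (the block keeps its multiplicity).
    """
    ranks = []
    block_rank = None
    for lab, r in zip(calls.labels, calls.scaled_ranks):
        if lab:
            if block_rank is None:
                block_rank = r
            ranks.append(block_rank)
        else:
            block_rank = None
    return np.asarray(ranks, dtype=float)


@dataclass
class RankCurve:
    """Cumulative D(r) of positive-call scaled ranks and its excess over r."""

    grid: np.ndarray
    d_of_r: np.ndarray
    excess: np.ndarray        # D(r) - r
    auc: float                # area under excess over [0, 1]
    positive_ranks: np.ndarray = field(repr=False, default=None)


def rank_curve(calls: CallsVector) -> RankCurve:
    """D(r) − r curve for a calls vector, with exact trapezoid-free area.

    D(r) is the ECDF of the block-adjusted positive scaled ranks; a
    rank-uniform spread of positives gives D(r) ≈ r, so the excess
    integrates to ∫D − 1/2 = 1/2 − mean(positive ranks).
    """
    pos = block_adjusted_positive_ranks(calls)
    if pos.size == 0:
        raise ValueError("no positive calls")
    xs = np.unique(np.concatenate(([0.0], pos, [1.0])))
    d = np.searchsorted(np.sort(pos), xs, side="right") / pos.size
    auc = 0.5 - float(pos.mean())
    return RankCurve(grid=xs, d_of_r=d, excess=d - xs, auc=auc, positive_ranks=pos)


def fractional_rank(ranked: Sequence[str], factor: str) -> float:
    """F_R = 1 / integer rank of ``factor`` in the ranked list (best match)."""
    fac = factor.upper()
    for i, f in enumerate(ranked, start=1):
        if str(f).strip().upper() == fac:
            return 1.0 / i
    raise ValueError(f"manipulated factor {factor!r} absent from ranking")


def weighted_metric(value: float | np.ndarray, f_r: float) -> float | np.ndarray:
    """Scale a metric (curve or scalar AUC) by the fractional rank F_R."""
    if not 0.0 < f_r <= 1.0:
        raise ValueError(f"F_R must be in (0, 1], got {f_r}")
    return value * f_r


def compare_distributions(
    curve_a: RankCurve | np.ndarray, curve_b: RankCurve | np.ndarray
) -> tuple[float, float]:
    """Two-sample two-sided KS test between block-adjusted positive rank samples."""
    a = curve_a.positive_ranks if isinstance(curve_a, RankCurve) else np.asarray(curve_a)
    b = curve_b.positive_ranks if isinstance(curve_b, RankCurve) else np.asarray(curve_b)
    if a.size == 0 or b.size == 0:
        raise ValueError("both rank samples must be non-empty")
    res = stats.ks_2samp(a, b)
    return float(res.statistic), float(res.pvalue)


def read_ranked_lists(path: str | Path) -> pd.DataFrame:
    """Ranked-list table: column 1 = interactors of the manipulated factor,
    subsequent columns = best-first factor rankings, one per algorithm."""
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    if df.shape[1] < 2:
        raise ValueError(f"{path}: need an interactor column plus >=1 ranking")
    return df


def evaluate_rankings(
    ranks: pd.DataFrame | str | Path,
    positives: PositiveClass | set[str] | None = None,
    manipulated_factor: str | None = None,
    pr_mode: str = "trapezoid",
) -> pd.DataFrame:
    """Score every ranking column of a table against the positive class.

    When ``positives`` is None, the first column is read as the interactor
    list (requires ``manipulated_factor`` for the weighted metrics).
    Returns one row per algorithm with PR/ROC AUCs, rank-excess AUC, F_R
    and the F_R-weighted variants.
    """
    if not isinstance(ranks, pd.DataFrame):
        ranks = read_ranked_lists(ranks)
    cols = list(ranks.columns)
    if positives is None:
        interactors = frozenset(
            v.strip().upper() for v in ranks[cols[0]] if str(v).strip()
        )
        if manipulated_factor is None:
            raise ValueError("manipulated_factor required with positives-from-column-1")
        positives = PositiveClass(
            manipulated_factor=manipulated_factor.upper(),
            interactors=interactors,
        )
        algo_cols = cols[1:]
    else:
        algo_cols = cols
        if isinstance(positives, PositiveClass) and manipulated_factor is None:
            manipulated_factor = positives.manipulated_factor

    rows = []
    for col in algo_cols:
        ranked = [v for v in ranks[col].tolist() if str(v).strip()]
        if not ranked:
            continue
        calls = calls_vector(ranked, positives)
        if calls.n_positive == 0 or calls.n_positive == calls.labels.size:
            logger.warning("column %r: single-class calls vector; skipped", col)
            continue
        pr = pr_roc(calls, pr_mode=pr_mode)
        rc = rank_curve(calls)
        row = {
            "algorithm": col,
            "n_ranked": calls.labels.size,
            "n_positive": calls.n_positive,
            "pr_auc": pr.pr_auc,
            "roc_auc": pr.roc_auc,
            "rank_excess_auc": rc.auc,
        }
        if manipulated_factor is not None:
            try:
                f_r = fractional_rank(calls.factors, manipulated_factor)
                row["f_r"] = f_r
                row["weighted_pr_auc"] = weighted_metric(pr.pr_auc, f_r)
                row["weighted_rank_excess_auc"] = weighted_metric(rc.auc, f_r)
            except ValueError:
                row["f_r"] = np.nan
        rows.append(row)
    return pd.DataFrame(rows)
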