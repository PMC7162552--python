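"""The MAGIC enrichment statistic.

For each ChIP-seq track the empirical CDF of signals over the background
gene list, B(c), is compared with the ECDF over the query list, Q(c), via

    D_sup = sup_c ( B(c) - Q(c) )

A query enriched for high-signal genes lags the background cumulative, so
D_sup is large; the ChIP value attaining it (arg_Dsup, the "Critical ChIP")
splits the query into target genes (signal > arg_Dsup) and the rest.
Tracks with fewer than five targets are triaged.  A Kolmogorov–Smirnov
p-value is computed from D_sup and the effective sample size, corrected
across non-triaged tracks by Benjamini–Hochberg, and combined with the
tail-enrichment ratio r (mean of the top n = 0.05X query signals over the
top n background signals) into the ranking score

    S = -log10(P_corr) * r
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.special import kolmogorov
from statsmodels.stats.multitest import multipletests

from .matrix_builder import MagicMatrix

logger = logging.getLogger(__name__)

PVALUE_MODES = ("asymptotic", "onesided", "permutation")
DEFAULT_FDR_THRESHOLD = 0.10


class ListsError(ValueError):
    """Raised for malformed or empty gene-list inputs."""


@dataclass
class GeneListSet:
    """Background universe plus named query lists, filtered against a matrix.

    ``background`` is the N accepted background genes; each query is a
    subset of the background of size X.  ``triaged_genes`` records input
    symbols dropped because they are absent from the matrix.
    """

    background: list[str]
    queries: dict[str, list[str]]
    triaged_genes: dict[str, list[str]] = field(default_factory=dict)
    background_name: str = "Background"


def load_lists(path: str | Path, matrix: MagicMatrix) -> GeneListSet:
    """Read a tab-delimited lists file (col 1 = background, cols 2+ = queries).

    Genes absent from the matrix are triaged; query genes absent from the
    accepted background are dropped with a warning; duplicates are
    de-duplicated (first occurrence kept).
    """
    with open(path) as fh:
        header = fh.readline().rstrip("\n")
    if not header.strip():
        raise ListsError(f"{path}: empty file")
    names = [h.strip() for h in header.split("\t")]
    if len(set(names)) != len(names):
        raise ListsError(f"{path}: must have unique names for each column")
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    df.columns = names

    def column(name: str) -> list[str]:
        vals = [v.strip() for v in df[name].tolist() if v and v.strip()]
        seen: set[str] = set()
        out = []
        dups = 0
        for v in vals:
            if v in seen:
                dups += 1
                continue
            seen.add(v)
            out.append(v)
        if dups:
            logger.warning("%s: %d duplicate gene(s) removed from %r", path, dups, name)
        return out

    known = set(matrix.genes)
    triaged: dict[str, list[str]] = {}

    raw_bg = column(names[0])
    background = [g for g in raw_bg if g in known]
    dropped_bg = [g for g in raw_bg if g not in known]
    if dropped_bg:
        triaged[names[0]] = dropped_bg
    if not background:
        raise ListsError(f"{path}: background list empty after matrix filtering")

    bg_set = set(background)
    queries: dict[str, list[str]] = {}
    for name in names[1:]:
        raw = column(name)
        absent = [g for g in raw if g not in known]
        if absent:
            triaged[name] = absent
        kept = [g for g in raw if g in known]
        in_bg = [g for g in kept if g in bg_set]
        if len(in_bg) != len(kept):
            logger.warning(
                "%s: query %r has %d gene(s) outside the background; dropped",
                path, name, len(kept) - len(in_bg),
            )
        if not in_bg:
            raise ListsError(f"{path}: query {name!r} empty after filtering")
        queries[name] = in_bg
    return GeneListSet(
        background=background, queries=queries, triaged_genes=triaged,
        background_name=names[0],
    )


def ecdf_dsup(
    b_values: np.ndarray, q_values: np.ndarray
) -> tuple[float, float]:
    """Supremum of B(c) − Q(c) over the signal grid, and the attaining c.

    The grid is the unique background values, preceded by 0 when every
    background signal is positive (there both cumulatives are 0, so the
    supremum is never negative).  Ties are broken to the smallest
    attaining c, which maximises the resulting target set.
    """
    b = np.sort(np.asarray(b_values, dtype=float))
    q = np.sort(np.asarray(q_values, dtype=float))
    if b.size == 0 or q.size == 0:
        raise ValueError("both background and query must be non-empty")
    grid = np.unique(b)
    if grid[0] > 0:
        grid = np.concatenate(([0.0], grid))
    B = np.searchsorted(b, grid, side="right") / b.size
    Q = np.searchsorted(q, grid, side="right") / q.size
    diff = B - Q
    i = int(np.argmax(diff))  # first occurrence = smallest c
    return float(diff[i]), float(grid[i])


def ks_pvalue(n_background: int, n_query: int, d_sup: float, mode: str = "asymptotic") -> float:
    """KS p-value for observing a sup-difference ≥ ``d_sup`` by chance.

    ``asymptotic`` applies the two-sided Kolmogorov survival function
    2·Σ(−1)^{k−1}·exp(−2k²λ²) at λ = sqrt(N_e)·D with effective size
    N_e = N·X/(N+X); ``onesided`` uses exp(−2·N_e·D²).  For a calibrated
    empirical tail under the nested-sampling null use
    :func:`permutation_pvalue`.
    """
    if not 0.0 <= d_sup <= 1.0:
        raise ValueError(f"d_sup must be in [0, 1], got {d_sup}")
    if n_background < 1 or n_query < 1:
        raise ValueError("sample sizes must be >= 1")
    n_eff = n_background * n_query / (n_background + n_query)
    if mode == "asymptotic":
        return float(min(1.0, kolmogorov(math.sqrt(n_eff) * d_sup)))
    if mode == "onesided":
        return float(min(1.0, math.exp(-2.0 * n_eff * d_sup * d_sup)))
    raise ValueError(f"unknown p-value mode {mode!r}")


def _dsup_of_sorted_queries(b_sorted: np.ndarray, q_sorted_rows: np.ndarray) -> np.ndarray:
    """Vectorised D_sup for many sorted query rows against one background.

    On the segment [q_(j), q_(j+1)) the difference B−Q equals B(c) − j/X,
    maximal just below q_(j+1); hence D_sup = max_j count(b < q_(j))/N −
    (j−1)/X, floored at 0.  Equivalent to the grid scan in ecdf_dsup.
    """
    n = b_sorted.size
    x = q_sorted_rows.shape[1]
    below = np.searchsorted(b_sorted, q_sorted_rows.ravel(), side="left")
    below = below.reshape(q_sorted_rows.shape) / n
    j = np.arange(x) / x
    return np.maximum((below - j).max(axis=1), 0.0)


def permutation_pvalue(
    b_values: np.ndarray,
    n_query: int,
    d_sup: float,
    n_resamples: int = 10_000,
    rng: np.random.Generator | None = None,
) -> float:
    """Empirical tail of D_sup under resampling X genes from the background.

    This is the exact null for MAGIC's nested design (the query is a subset
    of the background), so it is the calibration oracle for the analytic
    modes of :func:`ks_pvalue`.  Add-one estimator: (1 + #{D* ≥ D})/(1 + R).
    """
    rng = np.random.default_rng() if rng is None else rng
    b = np.sort(np.asarray(b_values, dtype=float))
    idx = np.argsort(rng.random((n_resamples, b.size)), axis=1)[:, :n_query]
    samples = np.sort(b[idx], axis=1)
    d_null = _dsup_of_sorted_queries(b, samples)
    hits = int(np.sum(d_null >= d_sup - 1e-12))
    return (1 + hits) / (1 + n_resamples)


@dataclass
class TailStats:
    n_tail: int
    obs_tail_mean: float
    exp_tail_mean: float
    ratio: float


def tail_ratio(b_values: np.ndarray, q_values: np.ndarray) -> TailStats:
    """Ratio r of mean top-n query signals to mean top-n background signals.

    n = 0.05·X rounded up, with a floor of 1 so small queries keep a
    non-empty tail.  A degenerate all-zero background tail gives r = 0.
    """
    b = np.asarray(b_values, dtype=float)
    q = np.asarray(q_values, dtype=float)
    n = max(1, math.ceil(0.05 * q.size))
    obs = float(np.mean(np.sort(q)[-n:]))
    exp = float(np.mean(np.sort(b)[-n:]))
    ratio = obs / exp if exp > 0 else 0.0
    return TailStats(n_tail=n, obs_tail_mean=obs, exp_tail_mean=exp, ratio=ratio)


def bh_correct(raw_p: Sequence[float]) -> np.ndarray:
    """Benjamini–Hochberg step-up correction over one query's non-triaged tracks."""
    p = np.asarray(raw_p, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def score(corrected_p: float, ratio: float) -> float:
    """S = −log10(P_corr) × r; P_corr is floored at the smallest normal float."""
    if corrected_p <= 0.0:
        logger.warning("corrected p of 0 floored at %g before log", np.finfo(float).tiny)
    p = max(float(corrected_p), float(np.finfo(float).tiny))
    return -math.log10(p) * ratio + 0.0  # +0.0 normalises -0.0


def target_genes(
    symbols: Sequence[str], signals: np.ndarray, arg_dsup: float
) -> list[tuple[str, float]]:
    """Query genes with signal strictly greater than the Critical ChIP."""
    return [
        (s, float(v)) for s, v in zip(symbols, signals) if v > arg_dsup
    ]


MIN_TARGETS = 5  # tracks with fewer target genes are triaged


def triage(targets: Sequence[tuple[str, float]], exp_tail_mean: float = 1.0) -> bool:
    """True when a track is dropped from further statistics.

    A track is triaged when fewer than five query genes lie above the
    Critical ChIP, or when the background tail carries no signal at all
    (degenerate track, r undefined).
    """
    return len(targets) < MIN_TARGETS or exp_tail_mean <= 0


@dataclass
class FactorResult:
    """Per-track MAGIC statistics for one query list."""

    factor_name: str
    description: str
    track_id: str
    d_sup: float
    arg_dsup: float
    n_tail: int
    obs_tail_mean: float
    exp_tail_mean: float
    ratio: float
    targets: list[tuple[str, float]]
    triaged: bool
    raw_p: float = math.nan
    corrected_p: float = math.nan
    score: float = math.nan

    def significant(self, threshold: float = DEFAULT_FDR_THRESHOLD) -> bool:
        return not self.triaged and self.corrected_p < threshold


@dataclass
class EnrichmentReport:
    """All per-track results for one query, sorted by Score."""

    query_name: str
    background_name: str
    results: list[FactorResult]          # non-triaged, sorted by score
    triaged_results: list[FactorResult]  # triaged tracks, sorted by d_sup desc
    n_background: int
    n_query: int
    fdr_threshold: float = DEFAULT_FDR_THRESHOLD

    @property
    def all_results(self) -> list[FactorResult]:
        return self.results + self.triaged_results

    def summary(self) -> list[FactorResult]:
        """Best-scoring track per factor name (one row per factor)."""
        best: dict[str, FactorResult] = {}
        for r in self.results:  # already sorted best-first
            best.setdefault(r.factor_name, r)
        return list(best.values())

    def significant_results(self) -> list[FactorResult]:
        return [r for r in self.results if r.significant(self.fdr_threshold)]


def _result_sort_key(r: FactorResult):
    return (-r.score, r.corrected_p, r.track_id)


def run_query(
    matrix: MagicMatrix,
    lists: GeneListSet,
    query_name: str,
    pvalue_mode: str = "asymptotic",
    fdr_threshold: float = DEFAULT_FDR_THRESHOLD,
    n_resamples: int = 10_000,
    rng: np.random.Generator | None = None,
) -> EnrichmentReport:
    """Run the full MAGIC statistic for one query list over every track.

    Per track: ECDF sup-difference and Critical ChIP, target extraction and
    triage, tail-enrichment ratio, KS p-value; then BH correction across
    the non-triaged tracks and Score ranking.
    """
    if pvalue_mode not in PVALUE_MODES:
        raise ValueError(f"pvalue_mode must be one of {PVALUE_MODES}")
    if query_name not in lists.queries:
        raise KeyError(f"unknown query list {query_name!r}")
    background = [g for g in lists.background if g in set(matrix.genes)]
    if not background:
        raise ListsError("background list and matrix share no genes")
    query = [g for g in lists.queries[query_name] if g in set(background)]
    if not query:
        raise ListsError(f"query {query_name!r} empty after filtering")

    sub = matrix.values.loc[background]
    qsub = matrix.values.loc[query]
    results: list[FactorResult] = []
    for meta in matrix.tracks:
        b = sub[meta.track_id].to_numpy()
        q = qsub[meta.track_id].to_numpy()
        d_sup, arg_dsup = ecdf_dsup(b, q)
        tails = tail_ratio(b, q)
        targets = target_genes(query, q, arg_dsup)
        triaged = triage(targets, tails.exp_tail_mean)
        res = FactorResult(
            factor_name=meta.factor_name,
            description=meta.description,
            track_id=meta.track_id,
            d_sup=d_sup,
            arg_dsup=arg_dsup,
            n_tail=tails.n_tail,
            obs_tail_mean=tails.obs_tail_mean,
            exp_tail_mean=tails.exp_tail_mean,
            ratio=tails.ratio,
            targets=targets,
            triaged=triaged,
        )
        if not triaged:
            if pvalue_mode == "permutation":
                res.raw_p = permutation_pvalue(
                    b, len(q), d_sup, n_resamples=n_resamples, rng=rng
                )
            else:
                res.raw_p = ks_pvalue(len(b), len(q), d_sup, mode=pvalue_mode)
        results.append(res)

    kept = [r for r in results if not r.triaged]
    triaged_rows = sorted(
        (r for r in results if r.triaged), key=lambda r: (-r.d_sup, r.track_id)
    )
    if kept:
        corrected = bh_correct([r.raw_p for r in kept])
        for r, pc in zip(kept, corrected):
            r.corrected_p = float(pc)
            r.score = score(r.corrected_p, r.ratio)
        kept.sort(key=_result_sort_key)
    logger.info(
        "query %s: %d tracks, %d triaged, %d significant at FDR<%g",
        query_name, len(results), len(triaged_rows),
        sum(r.significant(fdr_threshold) for r in kept), fdr_threshold,
    )
    return EnrichmentReport(
        query_name=query_name,
        background_name=lists.background_name,
        results=kept,
        triaged_results=triaged_rows,
        n_background=len(background),
        n_query=len(query),
        fdr_threshold=fdr_threshold,
    )
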