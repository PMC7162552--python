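"""Writers for the MAGIC output surface.

A run produces, next to the input lists file: ``Accepted_Lists.txt`` and
``Platform_Matrix.txt`` at the top level, then one directory per query list
containing the Details and Summary tables, a score bar graph, a GSEA-ready
GMX drivers file, a ``CDFs/`` directory of per-factor diagnostic plots, an
``Auxiliary_Files/`` directory (raw results for all tracks including
triaged ones, sub-matrix, triage listings) and a ``Target_Data/`` directory
with per-factor target gene files for every factor at P_corr < 10%.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .enrichment import (
    DEFAULT_FDR_THRESHOLD,
    EnrichmentReport,
    FactorResult,
    GeneListSet,
    run_query,
)
from .matrix_builder import MagicMatrix, write_matrix

logger = logging.getLogger(__name__)

DETAILS_COLUMNS = [
    "Factor",
    "Description",
    "Critical ChIP",
    "Obs Tail Mean",
    "Exp Tail Mean",
    "Tail Enrichment",
    "Raw P",
    "Corrected P",
    "Score",
]


@dataclass
class OutputBundle:
    """Paths of every artifact written by :func:`write_bundle`."""

    root: Path
    accepted_lists: Path
    platform_matrix: Path
    query_dirs: dict[str, Path] = field(default_factory=dict)
    reports: dict[str, EnrichmentReport] = field(default_factory=dict)


def _table_name(stem: str, xls_naming: bool) -> str:
    return f"{stem}.xls" if xls_naming else f"{stem}.txt"


def _details_frame(rows: list[FactorResult], threshold: float, flag: bool = True) -> pd.DataFrame:
    df = pd.DataFrame(
        {
            "Factor": [r.factor_name for r in rows],
            "Description": [r.description for r in rows],
            "Critical ChIP": [r.arg_dsup for r in rows],
            "Obs Tail Mean": [r.obs_tail_mean for r in rows],
            "Exp Tail Mean": [r.exp_tail_mean for r in rows],
            "Tail Enrichment": [r.ratio for r in rows],
            "Raw P": [r.raw_p for r in rows],
            "Corrected P": [r.corrected_p for r in rows],
            "Score": [r.score for r in rows],
        },
        columns=DETAILS_COLUMNS,
    )
    if flag:
        df["Significant"] = [
            "*" if r.significant(threshold) else "" for r in rows
        ]
    return df


def write_details(report: EnrichmentReport, path: str | Path) -> None:
    """Details table: the nine statistic columns for every non-triaged track,
    sorted by Score, plus a plain-text flag column marking P_corr < 10% rows."""
    if not report.results:
        logger.warning("query %s: no non-triaged tracks; header-only Details",
                       report.query_name)
    _details_frame(report.results, report.fdr_threshold).to_csv(
        path, sep="\t", index=False
    )


def write_summary(report: EnrichmentReport, path: str | Path) -> None:
    """Summary table: the best-scoring track per factor, same layout as Details."""
    _details_frame(report.summary(), report.fdr_threshold).to_csv(
        path, sep="\t", index=False
    )


def write_gmx(
    background: list[str],
    query: list[str],
    report: EnrichmentReport,
    path: str | Path,
) -> None:
    """GSEA GMX drivers file (column-oriented gene sets).

    Column 1 is the background list, column 2 the query, then one column of
    target genes per significant factor.  Row 1 holds set names, row 2
    descriptions; shorter columns are padded with empty cells.
    """
    cols: list[tuple[str, str, list[str]]] = [
        (report.background_name, "background list", list(background)),
        (report.query_name, "query list", list(query)),
    ]
    for r in report.significant_results():
        cols.append(
            (r.track_id, f"targets (ChIP > {r.arg_dsup:g})", [g for g, _ in r.targets])
        )
    depth = max(len(c[2]) for c in cols)
    with open(path, "w") as fh:
        fh.write("\t".join(c[0] for c in cols) + "\n")
        fh.write("\t".join(c[1] for c in cols) + "\n")
        for i in range(depth):
            fh.write(
                "\t".join(c[2][i] if i < len(c[2]) else "" for c in cols) + "\n"
            )


def write_raw_results(report: EnrichmentReport, path: str | Path) -> None:
    """Raw results for ALL tracks, comma separated, with the KS D column.

    Triaged tracks carry a negative D; the sign is a triage marker used for
    sorting, not a statement that the difference was negative.
    """
    rows = report.all_results
    df = pd.DataFrame(
        {
            "Factor": [r.factor_name for r in rows],
            "Description": [r.description for r in rows],
            "KS D": [-r.d_sup if r.triaged else r.d_sup for r in rows],
            "Critical ChIP": [r.arg_dsup for r in rows],
            "Obs Tail Mean": [r.obs_tail_mean for r in rows],
            "Exp Tail Mean": [r.exp_tail_mean for r in rows],
            "Tail Enrichment": [r.ratio for r in rows],
            "Raw P": [r.raw_p for r in rows],
            "Corrected P": [r.corrected_p for r in rows],
            "Score": [r.score for r in rows],
            "Triaged": [int(r.triaged) for r in rows],
        }
    )
    df.to_csv(path, index=False)


def write_auxiliary(
    report: EnrichmentReport,
    matrix: MagicMatrix,
    lists: GeneListSet,
    aux_dir: str | Path,
) -> dict[str, Path]:
    """Populate Auxiliary_Files: raw results, sub-matrix, triage listings."""
    aux_dir = Path(aux_dir)
    aux_dir.mkdir(parents=True, exist_ok=True)
    q = report.query_name
    paths = {
        "raw_results": aux_dir / f"{q}_raw_results.csv",
        "sub_matrix": aux_dir / f"{q}_Sub_Matrix.txt",
        "triaged_factors": aux_dir / "Triaged_Factors.txt",
        "triaged_genes": aux_dir / "Triaged_Genes.txt",
    }
    write_raw_results(report, paths["raw_results"])
    query = lists.queries[q]
    sub = MagicMatrix(values=matrix.values.loc[query], tracks=matrix.tracks)
    write_matrix(sub, paths["sub_matrix"])
    with open(paths["triaged_factors"], "w") as fh:
        for r in report.triaged_results:
            fh.write(r.track_id + "\n")
    with open(paths["triaged_genes"], "w") as fh:
        for g in lists.triaged_genes.get(q, []):
            fh.write(g + "\n")
    return paths


def write_target_data(report: EnrichmentReport, target_dir: str | Path) -> list[Path]:
    """One comma-separated (gene, signal) file per factor with P_corr < 10%."""
    target_dir = Path(target_dir)
    target_dir.mkdir(parents=True, exist_ok=True)
    written = []
    for r in report.significant_results():
        p = target_dir / f"{r.track_id}_targets.csv"
        with open(p, "w") as fh:
            fh.write("Gene,ChIP\n")
            for g, v in r.targets:
                fh.write(f"{g},{v:g}\n")
        written.append(p)
    return written


def write_accepted_lists(lists: GeneListSet, path: str | Path) -> None:
    """The input lists file filtered for genes present in the matrix."""
    cols = [(lists.background_name, lists.background)] + [
        (n, q) for n, q in lists.queries.items()
    ]
    depth = max(len(c[1]) for c in cols)
    with open(path, "w") as fh:
        fh.write("\t".join(c[0] for c in cols) + "\n")
        for i in range(depth):
            fh.write("\t".join(c[1][i] if i < len(c[1]) else "" for c in cols) + "\n")


def plot_cdf(
    b_values: np.ndarray,
    q_values: np.ndarray,
    result: FactorResult,
    rank: int,
    out_dir: str | Path,
) -> Path:
    """Diagnostic plot for one non-triaged factor, named ``<rank>_<factor>.pdf``.

    Black: background cumulative; red: query cumulative; blue vertical line
    at the Critical ChIP; gene ticks on the x-axis with lollipop markers on
    the n best-signal query and background genes.
    """
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    b = np.sort(np.asarray(b_values, dtype=float))
    q = np.sort(np.asarray(q_values, dtype=float))
    fig, ax = plt.subplots(figsize=(6, 4.5))
    ax.step(b, np.arange(1, b.size + 1) / b.size, where="post", color="black",
            label="background")
    ax.step(q, np.arange(1, q.size + 1) / q.size, where="post", color="red",
            label="query")
    ax.axvline(result.arg_dsup, color="blue", lw=1,
               label=f"Critical ChIP = {result.arg_dsup:g}")
    ax.plot(b, np.full(b.size, -0.02), "|", color="black", ms=6)
    ax.plot(q, np.full(q.size, -0.05), "|", color="red", ms=6)
    n = result.n_tail
    ax.plot(b[-n:], np.full(n, -0.02), "o", color="black", ms=4, fillstyle="none")
    ax.plot(q[-n:], np.full(n, -0.05), "o", color="red", ms=4, fillstyle="none")
    ax.set_xlabel("ChIP signal")
    ax.set_ylabel("cumulative fraction of genes")
    ax.set_ylim(-0.08, 1.02)
    ax.set_title(f"{result.track_id}  (Score {result.score:.2f})", fontsize=9)
    ax.legend(fontsize=7, loc="lower right")
    out = Path(out_dir) / f"{rank}_{result.factor_name}.pdf"
    fig.savefig(out)
    plt.close(fig)
    return out


def plot_summary_bars(report: EnrichmentReport, path: str | Path) -> None:
    """Bar graph of factor Scores for every factor at P_corr < 10%."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    rows = [r for r in report.summary() if r.significant(report.fdr_threshold)]
    fig, ax = plt.subplots(figsize=(6, max(2.0, 0.3 * len(rows) + 1)))
    if rows:
        names = [r.factor_name for r in rows][::-1]
        scores = [r.score for r in rows][::-1]
        ax.barh(names, scores, color="firebrick")
    ax.set_xlabel("Score")
    ax.set_title(f"{report.query_name}: factors at P_corr < "
                 f"{report.fdr_threshold:.0%}", fontsize=9)
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)


def write_bundle(
    matrix: MagicMatrix,
    lists: GeneListSet,
    out_dir: str | Path,
    pvalue_mode: str = "asymptotic",
    fdr_threshold: float = DEFAULT_FDR_THRESHOLD,
    plots: bool = True,
    xls_naming: bool = False,
    rng: np.random.Generator | None = None,
    n_resamples: int = 10_000,
) -> OutputBundle:
    """Run every query list and write the complete output directory tree."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    accepted = out_dir / "Accepted_Lists.txt"
    write_accepted_lists(lists, accepted)
    platform = out_dir / "Platform_Matrix.txt"
    bg = [g for g in lists.background if g in set(matrix.genes)]
    write_matrix(MagicMatrix(values=matrix.values.loc[bg], tracks=matrix.tracks),
                 platform)
    bundle = OutputBundle(root=out_dir, accepted_lists=accepted,
                          platform_matrix=platform)
    for qname in lists.queries:
        report = run_query(
            matrix, lists, qname, pvalue_mode=pvalue_mode,
            fdr_threshold=fdr_threshold, rng=rng, n_resamples=n_resamples,
        )
        qdir = out_dir / qname
        qdir.mkdir(exist_ok=True)
        write_details(report, qdir / _table_name(f"{qname}_Details", xls_naming))
        write_summary(report, qdir / _table_name(f"{qname}_Summary", xls_naming))
        write_gmx(bg, lists.queries[qname], report, qdir / f"{qname}_Drivers.gmx")
        write_auxiliary(report, matrix, lists, qdir / "Auxiliary_Files")
        write_target_data(report, qdir / "Target_Data")
        if plots:
            plot_summary_bars(report, qdir / f"{qname}_summary.pdf")
            cdf_dir = qdir / "CDFs"
            cdf_dir.mkdir(exist_ok=True)
            sub = matrix.values.loc[bg]
            qsub = matrix.values.loc[lists.queries[qname]]
            for rank, r in enumerate(report.results, start=1):
                plot_cdf(sub[r.track_id].to_numpy(), qsub[r.track_id].to_numpy(),
                         r, rank, cdf_dir)
        bundle.query_dirs[qname] = qdir
        bundle.reports[qname] = report
    return bundle
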