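"""Screen every module x branch cell and report the rewiring candidates.

Each cell runs the full block search; converged cells become one report
row sorted by descending block score, mirroring the study-style summary
table (module, branch, skew, the two pooled team differences, team sizes,
gene counts, member lists).  There is no significance model for a block
score, so the report simply surfaces the high-skew tail; the companion
histogram (two-digit truncation of skew, sliding-window smoothing) shows
where that tail starts.
"""

from __future__ import annotations

import math
from typing import Iterable

import numpy as np
import pandas as pd

from ._precision import round8
from .attrition import DEFAULT_IMPORTANCE_THRESHOLD, find_block
from .data_model import BindingTensor, Block, BranchPartition, GeneModule
from .exceptions import TfrewireError
from .skewness import branch_species_indices, dif_scores

__all__ = [
    "REPORT_COLUMNS",
    "screen",
    "skew_histogram",
    "write_report",
    "write_histogram",
    "plot_skew_histogram",
    "plot_block_profile",
]

REPORT_COLUMNS = [
    "module", "branch", "skew", "dif_m_star", "dif_m",
    "n_t_star", "n_t", "n_genes", "module_size",
    "team_t", "team_t_star", "genes",
]

#: histogram smoothing window (centered moving average, shrinking at edges)
HISTOGRAM_WINDOW = 7

#: gene-set Jaccard similarity above which two rows of one module count as
#: the same event on slightly different branches
DEDUP_JACCARD = 0.8


def _jaccard(a: frozenset, b: frozenset) -> float:
    return len(a & b) / len(a | b)


def screen(tensor: BindingTensor, modules: Iterable[GeneModule],
           branches: Iterable[BranchPartition],
           importance_threshold: float = DEFAULT_IMPORTANCE_THRESHOLD,
           dedup: bool = False, dedup_jaccard: float = DEDUP_JACCARD,
           require_negative_t_star: bool = True):
    """Run the block search over all branches x modules.

    Returns ``(report, failures)``: a DataFrame with one row per cell where
    a reportable block converged, sorted by descending skew, plus a list of
    ``(module_id, branch_label, reason)`` for the cells without one.  With
    ``dedup=True``, rows of one module whose block gene sets overlap above
    ``dedup_jaccard`` are collapsed to the highest-skew row.
    """
    rows = []
    failures = []
    for module in modules:
        for branch in branches:
            try:
                result = find_block(
                    tensor, module, branch,
                    importance_threshold=importance_threshold,
                    require_negative_t_star=require_negative_t_star,
                )
            except TfrewireError as exc:
                failures.append((module.module_id, branch.label, str(exc)))
                continue
            if result.block is None or not result.converged:
                failures.append((module.module_id, branch.label,
                                 result.stop_reason or "no block"))
                continue
            if not result.reportable:
                failures.append((module.module_id, branch.label,
                                 "non-negative skew in T_star"))
                continue
            block = result.block
            dif_m, dif_ms = dif_scores(tensor, block)
            rows.append({
                "module": module.module_id,
                "branch": branch.label,
                "skew": float(round8(block.score)),
                "dif_m_star": float(round8(dif_ms)),
                "dif_m": float(round8(dif_m)),
                "n_t_star": len(block.T_star),
                "n_t": len(block.T),
                "n_genes": len(block.G),
                "module_size": len(module),
                "team_t": ";".join(block.T),
                "team_t_star": ";".join(block.T_star),
                "genes": ";".join(block.G),
            })
    report = pd.DataFrame(rows, columns=REPORT_COLUMNS)
    if len(report):
        report = report.sort_values(
            ["skew", "module", "branch"], ascending=[False, True, True]
        ).reset_index(drop=True)
    if dedup and len(report):
        kept_rows = []
        kept_sets: dict[str, list] = {}
        for _, row in report.iterrows():
            genes = frozenset(row["genes"].split(";"))
            near = [s for s in kept_sets.get(row["module"], [])
                    if _jaccard(genes, s) > dedup_jaccard]
            if near:
                continue
            kept_sets.setdefault(row["module"], []).append(genes)
            kept_rows.append(row)
        report = pd.DataFrame(kept_rows, columns=REPORT_COLUMNS).reset_index(drop=True)
    return report, failures


def skew_histogram(scores) -> pd.DataFrame:
    """Histogram of block scores at two-digit truncation, with smoothing.

    ``scores`` is a sequence of skews or a report DataFrame.  Bins are
    ``floor(skew * 100) / 100`` over the occupied range (empty interior
    bins included); the smoothed series is a centered moving average of
    window :data:`HISTOGRAM_WINDOW`, truncated at the edges.
    """
    if isinstance(scores, pd.DataFrame):
        scores = scores["skew"].tolist()
    scores = [float(s) for s in scores]
    if not scores:
        raise ValueError("need at least one score")
    # scores carry 8 valid decimals; the epsilon guards the float product
    # against e.g. 0.73 * 100 == 72.999...
    keys = [math.floor(s * 100 + 1e-9) for s in scores]
    lo, hi = min(keys), max(keys)
    counts = np.zeros(hi - lo + 1, dtype=int)
    for k in keys:
        counts[k - lo] += 1
    half = HISTOGRAM_WINDOW // 2
    smoothed = np.array([
        counts[max(0, i - half): i + half + 1].mean()
        for i in range(counts.size)
    ])
    return pd.DataFrame({
        "bin": [(lo + i) / 100.0 for i in range(counts.size)],
        "count": counts,
        "smoothed": smoothed,
    })


def write_report(report: pd.DataFrame, path) -> None:
    report.to_csv(path, sep="\t", index=False, float_format="%.8f")


def write_histogram(histogram: pd.DataFrame, path) -> None:
    histogram.to_csv(path, sep="\t", index=False, float_format="%.8f")


def plot_skew_histogram(histogram: pd.DataFrame, path) -> None:
    """Bar histogram of truncated skews with the smoothed curve overlaid."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(7, 4))
    ax.bar(histogram["bin"], histogram["count"], width=0.009, color="tab:blue",
           label="max blocks per bin")
    ax.plot(histogram["bin"], histogram["smoothed"], color="tab:red",
            label=f"moving average (window {HISTOGRAM_WINDOW})")
    ax.set_xlabel("block skew (two-digit truncation)")
    ax.set_ylabel("number of max blocks")
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_block_profile(tensor: BindingTensor, block: Block, path) -> None:
    """Per-species mean binding of the two teams over the block genes.

    One dot per team per species — each an average over team x gene pairs —
    with a vertical line at the branch boundary.
    """
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    idx_m, idx_ms = branch_species_indices(tensor, block.branch)
    order = list(idx_m) + list(idx_ms)
    t_idx = [tensor.tf_index[x] for x in block.T]
    ts_idx = [tensor.tf_index[x] for x in block.T_star]
    g_idx = [tensor.gene_index[g] for g in block.G]
    t_means = [float(np.nanmean(tensor.P[np.ix_(t_idx, g_idx, [s])])) for s in order]
    ts_means = [float(np.nanmean(tensor.P[np.ix_(ts_idx, g_idx, [s])])) for s in order]
    labels = [tensor.species_ids[s] for s in order]

    fig, ax = plt.subplots(figsize=(9, 4))
    x = np.arange(len(order))
    ax.plot(x, t_means, "o-", color="tab:red", label=f"T ({', '.join(block.T[:4])})")
    ax.plot(x, ts_means, "o-", color="tab:blue",
            label=f"T* ({', '.join(block.T_star[:4])})")
    ax.axvline(len(idx_m) - 0.5, linestyle="--", color="grey")
    ax.set_xticks(x, labels, rotation=90, fontsize=7)
    ax.set_ylabel("mean binding probability")
    ax.set_ylim(-0.02, 1.02)
    ax.legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
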