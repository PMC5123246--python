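"""Importance-driven attrition: shrink max blocks one element at a time.

After each ping-pong convergence every block element gets an *importance*
ratio relative to the extreme member of its class:

* x in T:  skew(x, G) / max_{x' in T} skew(x', G)
* y in T*: skew(y, G) / min_{y' in T*} skew(y', G)   (two negatives)
* g in G:  [skew(T, g) − skew(T*, g)] / max over G of the same

The least-important element across all three classes is deleted — one of
(m, m*, mG) drops by 1 — and ping-pong restarts from the current gene set.
Deleting the weakest member of a class can only raise that class's mean, so
the block score never decreases along the trajectory.  Attrition stops when
every importance has reached the threshold (0.5 by default; 0.25 keeps
larger, 0.75 smaller blocks), producing a sequence of max blocks whose
total size shrinks in steps of one.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from ._precision import round8
from .data_model import BindingTensor, Block, BlockShape, BranchPartition, GeneModule
from .exceptions import (
    AttritionStopSignal,
    DegenerateBlockError,
    SignShortageError,
    ValidationError,
)
from .pingpong import DEFAULT_MAX_ITER, _Workspace, run_pingpong
from .skewness import usable_genes

__all__ = [
    "importance_scores",
    "attrition_step",
    "AttritionRound",
    "FindBlockResult",
    "find_block",
    "BlockFinder",
]

DEFAULT_IMPORTANCE_THRESHOLD = 0.5

_CLASS_ORDER = {"T": 0, "T_star": 1, "G": 2}


def importance_scores(tensor: BindingTensor, block: Block) -> pd.DataFrame:
    """Per-element raw scores and importance ratios for a block.

    Returns a DataFrame with columns ``element``, ``cls`` (one of
    ``"T"``, ``"T_star"``, ``"G"``), ``score`` and ``importance``.  The
    top member of each class has importance exactly 1.  Raises
    :class:`DegenerateBlockError` when a class denominator has the wrong
    sign (no positively skewed factor in T, no negatively skewed factor in
    T*, or no positive gene contrast).
    """
    ws = _Workspace(tensor, block.branch, list(block.G))
    t_idx = ws.tf_indices(block.T)
    ts_idx = ws.tf_indices(block.T_star)
    g_idx = ws.gene_indices(block.G)

    tf_scores = round8(ws.S[:, g_idx].mean(axis=1))
    t_scores = tf_scores[t_idx]
    ts_scores = tf_scores[ts_idx]
    g_scores = round8(ws.S[t_idx].mean(axis=0) - ws.S[ts_idx].mean(axis=0))[g_idx]

    max_t = t_scores.max()
    min_ts = ts_scores.min()
    max_g = g_scores.max()
    if max_t <= 0:
        raise DegenerateBlockError("no positively skewed factor in T")
    if min_ts >= 0:
        raise DegenerateBlockError("no negatively skewed factor in T*")
    if max_g <= 0:
        raise DegenerateBlockError("no positive gene contrast in G")

    rows = []
    for i, name in zip(t_idx, ws.tf_names(t_idx)):
        rows.append((name, "T", float(tf_scores[i]), float(tf_scores[i] / max_t)))
    for i, name in zip(ts_idx, ws.tf_names(ts_idx)):
        rows.append((name, "T_star", float(tf_scores[i]), float(tf_scores[i] / min_ts)))
    for k, name in enumerate(ws.gene_names(g_idx)):
        rows.append((name, "G", float(g_scores[k]), float(g_scores[k] / max_g)))
    return pd.DataFrame(rows, columns=["element", "cls", "score", "importance"])


def _least_important(table: pd.DataFrame):
    """Row of the minimal importance; rounded ties resolved alphabetically
    by element name, then by class order T, T*, G."""
    keyed = sorted(
        (float(round8(r.importance)), r.element, _CLASS_ORDER[r.cls], r.cls)
        for r in table.itertuples(index=False)
    )
    imp, element, _, cls = keyed[0]
    return element, cls, imp


def attrition_step(tensor: BindingTensor, module: GeneModule, block: Block):
    """Delete the least-important element of a max block.

    Returns ``(new_shape, removed_element, removed_class)``.  Raises
    :class:`AttritionStopSignal` if the deletion would empty a class.
    """
    table = importance_scores(tensor, block)
    element, cls, _ = _least_important(table)
    shape = block.shape
    m, m_star, m_g = shape.m, shape.m_star, shape.m_g
    if cls == "T":
        m -= 1
    elif cls == "T_star":
        m_star -= 1
    else:
        m_g -= 1
    if min(m, m_star, m_g) < 1:
        raise AttritionStopSignal(
            f"removing {element!r} would empty class {cls}; attrition stops"
        )
    return BlockShape(m, m_star, m_g), element, cls


@dataclass
class AttritionRound:
    """One converged max block along the attrition trajectory.

    ``removed_element``/``removed_class`` name the deletion performed
    *after* this block converged (``None`` on the final round)."""

    shape: BlockShape
    score: float
    removed_element: str | None
    removed_class: str | None
    terminated_early: bool = False


@dataclass
class FindBlockResult:
    """Final block, shrinking-trajectory metadata and the stop reason."""

    block: Block | None
    trajectory: list = field(default_factory=list)
    importances: pd.DataFrame | None = None
    converged: bool = False
    reportable: bool = False
    stop_reason: str = ""


def find_block(tensor: BindingTensor, module: GeneModule,
               branch: BranchPartition,
               importance_threshold: float = DEFAULT_IMPORTANCE_THRESHOLD,
               initial_genes=None,
               require_negative_t_star: bool = True,
               max_iter: int = DEFAULT_MAX_ITER) -> FindBlockResult:
    """Full search: ping-pong plus attrition down to the importance threshold.

    Starts from G0 = all usable module genes (or ``initial_genes``), with
    the initial team sizes given by the sign counts of skew(x, G0) over all
    factors — attrition then shrinks from the full factor set.  Alternates
    :func:`run_pingpong` and :func:`attrition_step` until every importance
    is at least the threshold.  A sign shortage or degenerate block along
    the way returns the best block reached so far, flagged via
    ``converged=False`` and ``stop_reason``.
    """
    if not 0.0 < importance_threshold <= 1.0:
        raise ValidationError("importance_threshold must lie in (0, 1]")
    pool = usable_genes(tensor, branch, sorted(module.genes))
    if not pool:
        raise ValidationError(
            f"module {module.module_id!r} has no usable gene for branch {branch.label!r}"
        )
    if initial_genes is None:
        g0 = sorted(pool)
    else:
        g0 = sorted(set(initial_genes))
        bad = set(g0) - set(pool)
        if bad:
            raise ValidationError(
                f"initial genes not usable for branch {branch.label!r}: {sorted(bad)}"
            )

    ws = _Workspace(tensor, branch, pool)
    m = m_star = len(ws.tfs)  # clamped to the available signs below
    m_g = len(g0)

    trajectory: list[AttritionRound] = []
    block = None
    importances = None
    stop_reason = "importance_threshold"
    converged = False
    while True:
        # Team sizes can never exceed the numbers of positively and
        # negatively skewed factors for the current start set; when a gene
        # deletion flips a near-zero factor's sign, shrink the teams to fit
        # rather than aborting the whole search.
        sx = ws.tf_scores(ws.gene_indices(g0))
        n_pos = int((sx > 0).sum())
        n_neg = int((sx < 0).sum())
        if n_pos == 0 or n_neg == 0:
            stop_reason = "sign_shortage"
            break
        m = min(m, n_pos)
        m_star = min(m_star, n_neg)
        result = run_pingpong(tensor, module, g0, BlockShape(m, m_star, m_g),
                              branch, max_iter=max_iter)
        block = result.block
        if result.terminated_early:
            # a gene set reached mid-run starves one sign; resume from it
            # with teams clamped on the next pass
            trajectory.append(AttritionRound(block.shape, float(round8(block.score)),
                                             None, None, terminated_early=True))
            g0 = list(block.G)
            m_g = len(g0)
            continue
        try:
            table = importance_scores(tensor, block)
        except DegenerateBlockError:
            trajectory.append(AttritionRound(block.shape, float(round8(block.score)),
                                             None, None))
            stop_reason = "degenerate"
            break
        importances = table
        if float(round8(table["importance"]).min()) >= importance_threshold:
            trajectory.append(AttritionRound(block.shape, float(round8(block.score)),
                                             None, None))
            converged = True
            break
        try:
            new_shape, element, cls = attrition_step(tensor, module, block)
        except AttritionStopSignal:
            trajectory.append(AttritionRound(block.shape, float(round8(block.score)),
                                             None, None))
            stop_reason = "shape_floor"
            break
        trajectory.append(AttritionRound(block.shape, float(round8(block.score)),
                                         element, cls))
        m, m_star, m_g = new_shape.as_tuple()
        g0 = [g for g in block.G if not (cls == "G" and g == element)]

    reportable = False
    if block is not None:
        ts_scores = round8(ws.S[ws.tf_indices(block.T_star)]
                           [:, ws.gene_indices(block.G)].mean(axis=1))
        reportable = bool(np.all(ts_scores < 0)) or not require_negative_t_star
    return FindBlockResult(block, trajectory, importances, converged,
                           reportable, stop_reason)


def write_trajectory(result: FindBlockResult, path) -> None:
    """One TSV row per attrition round: shape, score, removed element."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("round\tm\tm_star\tm_g\tscore\tremoved_element\tremoved_class\n")
        for i, r in enumerate(result.trajectory):
            fh.write(
                f"{i}\t{r.shape.m}\t{r.shape.m_star}\t{r.shape.m_g}\t"
                f"{r.score:.8f}\t{r.removed_element or '-'}\t{r.removed_class or '-'}\n"
            )


class BlockFinder(BaseEstimator):
    """Scikit-learn style wrapper around :func:`find_block`.

    Parameters mirror :func:`find_block`; the tensor is passed as ``X`` of
    :meth:`fit`.

    Attributes
    ----------
    block_ : Block or None
    score_ : float or None
    trajectory_ : list of AttritionRound
    importances_ : pandas.DataFrame or None
    converged_ : bool
    reportable_ : bool
    stop_reason_ : str
    """

    def __init__(self, module=None, branch=None,
                 importance_threshold=DEFAULT_IMPORTANCE_THRESHOLD,
                 initial_genes=None, require_negative_t_star=True,
                 max_iter=DEFAULT_MAX_ITER):
        self.module = module
        self.branch = branch
        self.importance_threshold = importance_threshold
        self.initial_genes = initial_genes
        self.require_negative_t_star = require_negative_t_star
        self.max_iter = max_iter

    def fit(self, X: BindingTensor, y=None):
        if self.module is None or self.branch is None:
            raise ValidationError("module and branch must be set before fit")
        result = find_block(
            X, self.module, self.branch,
            importance_threshold=self.importance_threshold,
            initial_genes=self.initial_genes,
            require_negative_t_star=self.require_negative_t_star,
            max_iter=self.max_iter,
        )
        self.result_ = result
        self.block_ = result.block
        self.score_ = None if result.block is None else result.block.score
        self.trajectory_ = result.trajectory
        self.importances_ = result.importances
        self.converged_ = result.converged
        self.reportable_ = result.reportable
        self.stop_reason_ = result.stop_reason
        return self
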