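"""The ping-pong coordinate-ascent search for substitution-maximizing blocks.

At a fixed shape (m, m*, mG) the algorithm alternates two steps:

* **Step TF** — given the current gene set G, score every transcription
  factor by skew(x, G) and take the m highest scorers as team T and the m*
  lowest as T*.  T must consist of positive scores and T* of negative ones;
  if either sign runs short the run terminates.
* **Step G** — given the teams, score every gene of the module by
  skew(T, g) − skew(T*, g) and keep the mG highest.

Both steps replace a set by the best set of the same size, so the block
score never decreases; over the finite block space the loop must stop, and
it stops at a *max block*: no single-element substitution can raise the
score.  Scores are compared after rounding to eight decimal digits, and
rounded ties are broken alphabetically, which makes every run
deterministic.

:func:`verify_max_block` checks the fixed-point property by exhaustive
single substitutions, and :func:`brute_force_best_block` is a tiny-instance
enumeration oracle used in testing — full enumeration is hopeless at real
problem sizes, which is the point of the ascent.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
from sklearn.base import BaseEstimator

from ._precision import round8
from .data_model import BindingTensor, Block, BlockShape, BranchPartition, GeneModule
from .exceptions import (
    EnumerationTooLargeError,
    SignShortageError,
    ValidationError,
)
from .skewness import skew_matrix, usable_genes

__all__ = [
    "PingPongResult",
    "step_tf",
    "step_g",
    "run_pingpong",
    "verify_max_block",
    "brute_force_best_block",
    "PingPongMaximizer",
]

#: hard cap on ping-pong iterations; the monotone score over a finite block
#: space guarantees termination long before this, so exceeding it is a bug
DEFAULT_MAX_ITER = 10_000


class _Workspace:
    """Alphabetically ordered skew matrix for one (tensor, branch, gene pool).

    Rows are transcription factors and columns genes, both sorted by name so
    that "first index" and "first alphabetically" coincide and `lexsort`
    tie-breaking is a plain position key.  Genes whose skew is undefined for
    the branch (no present ortholog on one side) are dropped from the pool
    up front.
    """

    def __init__(self, tensor: BindingTensor, branch: BranchPartition, genes=None):
        self.tensor = tensor
        self.branch = branch
        if genes is None:
            genes = tensor.gene_ids
        else:
            genes = list(genes)
            unknown = [g for g in genes if g not in tensor.gene_index]
            if unknown:
                raise ValidationError(f"genes absent from tensor: {sorted(unknown)}")
        self.genes = sorted(usable_genes(tensor, branch, genes))
        self.tfs = sorted(tensor.tf_ids)
        if not self.genes:
            raise ValidationError(
                f"branch {branch.label!r}: no usable genes in the pool"
            )
        S_tensor_order = skew_matrix(tensor, branch, self.genes)
        rows = [tensor.tf_index[x] for x in self.tfs]
        self.S = S_tensor_order[rows, :]
        self.tf_pos = {n: i for i, n in enumerate(self.tfs)}
        self.gene_pos = {n: i for i, n in enumerate(self.genes)}

    # -- index helpers -------------------------------------------------------
    def tf_indices(self, names) -> np.ndarray:
        try:
            return np.array(sorted(self.tf_pos[n] for n in names), dtype=int)
        except KeyError as exc:
            raise ValidationError(f"unknown transcription factor {exc.args[0]!r}") from exc

    def gene_indices(self, names) -> np.ndarray:
        missing = [g for g in names if g not in self.gene_pos]
        if missing:
            raise ValidationError(
                f"genes not usable for branch {self.branch.label!r}: {sorted(missing)}"
            )
        return np.array(sorted(self.gene_pos[g] for g in names), dtype=int)

    def tf_names(self, idx) -> tuple:
        return tuple(self.tfs[i] for i in idx)

    def gene_names(self, idx) -> tuple:
        return tuple(self.genes[i] for i in idx)

    # -- scores --------------------------------------------------------------
    def tf_scores(self, g_idx) -> np.ndarray:
        """Rounded skew(x, G) for every factor."""
        return round8(self.S[:, g_idx].mean(axis=1))

    def gene_scores(self, t_idx, ts_idx) -> np.ndarray:
        """Rounded skew(T, g) − skew(T*, g) for every pool gene."""
        return round8(self.S[t_idx].mean(axis=0) - self.S[ts_idx].mean(axis=0))

    def score(self, t_idx, ts_idx, g_idx) -> float:
        return float(self.S[np.ix_(t_idx, g_idx)].mean()
                     - self.S[np.ix_(ts_idx, g_idx)].mean())


def _pick_top(scores: np.ndarray, k: int) -> np.ndarray:
    """Indices of the k largest scores, rounded ties going to the lowest
    (alphabetically first) index."""
    order = np.lexsort((np.arange(scores.size), -scores))
    return np.sort(order[:k])


def _pick_bottom(scores: np.ndarray, k: int) -> np.ndarray:
    order = np.lexsort((np.arange(scores.size), scores))
    return np.sort(order[:k])


def _step_tf(ws: _Workspace, g_idx: np.ndarray, m: int, m_star: int):
    sx = ws.tf_scores(g_idx)
    n_pos = int((sx > 0).sum())
    n_neg = int((sx < 0).sum())
    if n_pos < m or n_neg < m_star:
        raise SignShortageError(
            f"need {m} positively and {m_star} negatively skewed factors, "
            f"found {n_pos} and {n_neg}"
        )
    return _pick_top(sx, m), _pick_bottom(sx, m_star)


def _step_g(ws: _Workspace, t_idx, ts_idx, m_g: int) -> np.ndarray:
    if m_g > len(ws.genes):
        raise ValidationError(
            f"mG={m_g} exceeds the {len(ws.genes)} usable genes of the module"
        )
    return _pick_top(ws.gene_scores(t_idx, ts_idx), m_g)


def step_tf(tensor: BindingTensor, G, shape: BlockShape,
            branch: BranchPartition):
    """One Step TF over *all* transcription factors for the gene set G.

    Returns ``(T, T_star)`` as alphabetically sorted name tuples; raises
    :class:`SignShortageError` if the required signs run short.
    """
    if isinstance(shape, tuple):
        shape = BlockShape(*shape)
    G = list(G)
    if not G:
        raise ValidationError("step TF requires a non-empty gene set")
    ws = _Workspace(tensor, branch, G)
    if len(ws.genes) != len(G):
        dropped = set(G) - set(ws.genes)
        raise ValidationError(
            f"genes unusable for branch {branch.label!r}: {sorted(dropped)}"
        )
    t_idx, ts_idx = _step_tf(ws, ws.gene_indices(G), shape.m, shape.m_star)
    return ws.tf_names(t_idx), ws.tf_names(ts_idx)


def step_g(tensor: BindingTensor, T, T_star, module: GeneModule, m_g: int,
           branch: BranchPartition):
    """One Step G over all usable genes of the module, for fixed teams."""
    if not T or not T_star:
        raise ValidationError("step G requires non-empty teams")
    if set(T) & set(T_star):
        raise ValidationError("teams must be disjoint")
    ws = _Workspace(tensor, branch, module.sorted_genes)
    g_idx = _step_g(ws, ws.tf_indices(T), ws.tf_indices(T_star), m_g)
    return ws.gene_names(g_idx)


@dataclass
class PingPongResult:
    """Outcome of one ping-pong run.

    ``score_trace`` holds the rounded block score after every TF and G step
    and is non-decreasing; ``terminated_early`` flags a sign shortage, in
    which case ``block`` is the last valid block reached.
    """

    block: Block
    iterations: int
    terminated_early: bool
    score_trace: list = field(default_factory=list)


def run_pingpong(tensor: BindingTensor, module: GeneModule, G0,
                 shape: BlockShape, branch: BranchPartition,
                 max_iter: int = DEFAULT_MAX_ITER) -> PingPongResult:
    """Iterate Step TF / Step G from the start set G0 until the score stops
    strictly increasing (on rounded values).

    The returned block is a fixed point: re-applying either step reproduces
    it.  If the very first TF step cannot fill the teams a
    :class:`SignShortageError` propagates; a shortage in a later iteration
    ends the run with ``terminated_early=True`` and the last valid block.
    """
    if isinstance(shape, tuple):
        shape = BlockShape(*shape)
    G0 = list(G0)
    if len(set(G0)) != len(G0):
        raise ValidationError("G0 contains duplicate genes")
    if len(G0) != shape.m_g:
        raise ValidationError(f"|G0|={len(G0)} does not match mG={shape.m_g}")
    ws = _Workspace(tensor, branch, module.sorted_genes)
    if shape.m + shape.m_star > len(ws.tfs):
        raise ValidationError("m + m* exceeds the number of transcription factors")
    g_idx = ws.gene_indices(G0)

    trace: list = []
    prev = 0.0
    iterations = 0
    terminated_early = False
    t_idx = ts_idx = None
    while True:
        if iterations >= max_iter:
            raise RuntimeError(
                "ping-pong iteration cap exceeded; the monotone score should "
                "have terminated the loop — this indicates a bug"
            )
        try:
            new_t, new_ts = _step_tf(ws, g_idx, shape.m, shape.m_star)
        except SignShortageError:
            if t_idx is None:
                raise
            terminated_early = True
            break
        t_idx, ts_idx = new_t, new_ts
        trace.append(float(round8(ws.score(t_idx, ts_idx, g_idx))))
        new_g = _step_g(ws, t_idx, ts_idx, shape.m_g)
        score = float(round8(ws.score(t_idx, ts_idx, new_g)))
        trace.append(score)
        iterations += 1
        unchanged = np.array_equal(new_g, g_idx)
        g_idx = new_g
        # `unchanged` means a true fixed point (both steps are functions of
        # the other side's output); otherwise stop on non-increase, as the
        # loop condition `new_score > score` prescribes.
        if unchanged or score <= prev:
            break
        prev = score

    block = Block(
        T=ws.tf_names(t_idx),
        T_star=ws.tf_names(ts_idx),
        G=ws.gene_names(g_idx),
        branch=branch,
        score=ws.score(t_idx, ts_idx, g_idx),
    )
    return PingPongResult(block, iterations, terminated_early, trace)


def verify_max_block(tensor: BindingTensor, module: GeneModule, block: Block):
    """Check the substitution-maximality of a block.

    Tries every single-element substitution — one member of T, T* or G
    replaced by any candidate outside the block (genes drawn from the
    module) — and returns ``(is_max, witnesses)`` where each witness is a
    tuple ``(component, removed, inserted, new_score)`` for an improving
    swap.
    """
    ws = _Workspace(tensor, branch := block.branch, module.sorted_genes)
    t_idx = ws.tf_indices(block.T)
    ts_idx = ws.tf_indices(block.T_star)
    g_idx = ws.gene_indices(block.G)
    m, m_star, m_g = len(t_idx), len(ts_idx), len(g_idx)

    row_sums = ws.S[:, g_idx].sum(axis=1)          # per-factor sum over G
    col_t = ws.S[t_idx].sum(axis=0)                # per-gene sums over teams
    col_ts = ws.S[ts_idx].sum(axis=0)
    sum_t, sum_ts = row_sums[t_idx].sum(), row_sums[ts_idx].sum()
    base = round8(sum_t / (m * m_g) - sum_ts / (m_star * m_g))

    in_block = set(t_idx) | set(ts_idx)
    tf_cands = [i for i in range(len(ws.tfs)) if i not in in_block]
    g_in = set(g_idx)
    g_cands = [j for j in range(len(ws.genes)) if j not in g_in]

    witnesses = []
    for i in t_idx:
        for c in tf_cands:
            s = round8((sum_t - row_sums[i] + row_sums[c]) / (m * m_g)
                       - sum_ts / (m_star * m_g))
            if s > base:
                witnesses.append(("T", ws.tfs[i], ws.tfs[c], float(s)))
    for i in ts_idx:
        for c in tf_cands:
            s = round8(sum_t / (m * m_g)
                       - (sum_ts - row_sums[i] + row_sums[c]) / (m_star * m_g))
            if s > base:
                witnesses.append(("T_star", ws.tfs[i], ws.tfs[c], float(s)))
    col_score = col_t / m - col_ts / m_star
    total = col_score[g_idx].sum()
    for j in g_idx:
        for c in g_cands:
            s = round8((total - col_score[j] + col_score[c]) / m_g)
            if s > base:
                witnesses.append(("G", ws.genes[j], ws.genes[c], float(s)))
    return (not witnesses), witnesses


def brute_force_best_block(tensor: BindingTensor, module: GeneModule,
                           shape: BlockShape, branch: BranchPartition,
                           max_blocks: int = 500_000) -> Block:
    """Globally best block of the given shape by exhaustive enumeration.

    A test oracle for tiny instances only; refuses instances whose block
    count exceeds ``max_blocks``.  Rounded score ties are resolved by the
    lexicographically smallest (T, T*, G) name tuples.
    """
    if isinstance(shape, tuple):
        shape = BlockShape(*shape)
    ws = _Workspace(tensor, branch, module.sorted_genes)
    n_tf, n_g = len(ws.tfs), len(ws.genes)
    if shape.m + shape.m_star > n_tf:
        raise ValidationError("m + m* exceeds the number of transcription factors")
    if shape.m_g > n_g:
        raise ValidationError("mG exceeds the number of usable genes")

    t_combos = list(combinations(range(n_tf), shape.m))
    ts_combos = list(combinations(range(n_tf), shape.m_star))
    g_combos = list(combinations(range(n_g), shape.m_g))
    n_blocks = len(t_combos) * len(ts_combos) * len(g_combos)
    if n_blocks > max_blocks:
        raise EnumerationTooLargeError(
            f"{n_blocks} blocks exceed the enumeration cap of {max_blocks}"
        )

    A = np.zeros((len(t_combos), n_tf))
    for i, c in enumerate(t_combos):
        A[i, list(c)] = 1.0 / shape.m
    B = np.zeros((len(ts_combos), n_tf))
    for i, c in enumerate(ts_combos):
        B[i, list(c)] = 1.0 / shape.m_star
    Gm = np.zeros((len(g_combos), n_g))
    for i, c in enumerate(g_combos):
        Gm[i, list(c)] = 1.0 / shape.m_g

    TG = A @ ws.S @ Gm.T                       # (n_t_combos, n_g_combos)
    TsG = B @ ws.S @ Gm.T
    disjoint = ((A > 0) @ (B > 0).T) == 0      # (n_t_combos, n_ts_combos)
    scores = TG[:, None, :] - TsG[None, :, :]
    scores = np.where(disjoint[:, :, None], scores, -np.inf)
    r = round8(scores)
    best = r.max()
    candidates = np.argwhere(r == best)
    keyed = sorted(
        (ws.tf_names(t_combos[i]), ws.tf_names(ts_combos[j]), ws.gene_names(g_combos[k]))
        for i, j, k in candidates
    )
    T, T_star, G = keyed[0]
    return Block(T=T, T_star=T_star, G=G, branch=branch,
                 score=ws.score(ws.tf_indices(T), ws.tf_indices(T_star),
                                ws.gene_indices(G)))


class PingPongMaximizer(BaseEstimator):
    """Scikit-learn style wrapper around :func:`run_pingpong`.

    Parameters
    ----------
    module : GeneModule
        Candidate regulon supplying the gene pool.
    branch : BranchPartition
        Species split whose contrast is maximised.
    m, m_star, m_g : int
        Fixed block shape.
    initial_genes : sequence of str, optional
        Start set G0 of size ``m_g``; defaults to the alphabetically first
        ``m_g`` usable genes of the module, keeping the default fit
        deterministic.
    max_iter : int
        Safety cap on iterations.

    Attributes
    ----------
    block_ : Block
    score_ : float
    score_trace_ : list of float
    n_iter_ : int
    terminated_early_ : bool
    """

    def __init__(self, module=None, branch=None, m=1, m_star=1, m_g=1,
                 initial_genes=None, max_iter=DEFAULT_MAX_ITER):
        self.module = module
        self.branch = branch
        self.m = m
        self.m_star = m_star
        self.m_g = m_g
        self.initial_genes = initial_genes
        self.max_iter = max_iter

    def fit(self, X: BindingTensor, y=None):
        if self.module is None or self.branch is None:
            raise ValidationError("module and branch must be set before fit")
        g0 = self.initial_genes
        if g0 is None:
            pool = sorted(usable_genes(X, self.branch, self.module.sorted_genes))
            g0 = pool[: self.m_g]
        result = run_pingpong(
            X, self.module, g0, BlockShape(self.m, self.m_star, self.m_g),
            self.branch, max_iter=self.max_iter,
        )
        self.result_ = result
        self.block_ = result.block
        self.score_ = result.block.score
        self.score_trace_ = result.score_trace
        self.n_iter_ = result.iterations
        self.terminated_early_ = result.terminated_early
        return self
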