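"""Skew statistics: branch contrasts of binding probabilities.

For a branch partition (M, M*) the skew of a factor–gene pair is

    skew(x, g) = <P(x, g, s)>_{s in M, ortholog present}
               - <P(x, g, s)>_{s in M*, ortholog present}

an unweighted mean difference over the species that carry an ortholog of
*g*.  Team/gene-set skews are grand means of the pairwise skews, and a
block's score is skew(T, G) − skew(T*, G).  The averaging order does not
matter: averaging first over genes or first over factors gives the same
grand mean.

A gene with no present ortholog on one side has undefined skew for that
branch; callers are expected to drop such genes per branch before any
optimisation (see :func:`usable_genes`).
"""

from __future__ import annotations

import numpy as np

from .data_model import BindingTensor, Block, BranchPartition
from .exceptions import UndefinedSkewError, ValidationError

__all__ = [
    "branch_species_indices",
    "usable_genes",
    "skew_matrix",
    "skew_tf_gene",
    "skew_team_genes",
    "block_skew",
    "block_skew_sets",
    "dif_scores",
]


def branch_species_indices(tensor: BindingTensor, branch: BranchPartition):
    """Column indices of the two partition sides, in species-id order."""
    branch.validate_against(tensor.species_ids)
    idx_m = np.array(sorted(tensor.species_index[s] for s in branch.M), dtype=int)
    idx_ms = np.array(sorted(tensor.species_index[s] for s in branch.M_star), dtype=int)
    return idx_m, idx_ms


def _side_counts(tensor, branch):
    idx_m, idx_ms = branch_species_indices(tensor, branch)
    cm = tensor.present[:, idx_m].sum(axis=1)
    cms = tensor.present[:, idx_ms].sum(axis=1)
    return idx_m, idx_ms, cm, cms


def usable_genes(tensor: BindingTensor, branch: BranchPartition,
                 genes=None) -> list:
    """Genes with at least one present ortholog on *each* side of the branch.

    Order of `genes` is preserved; by default all tensor genes are screened.
    """
    _, _, cm, cms = _side_counts(tensor, branch)
    if genes is None:
        genes = tensor.gene_ids
    out = []
    for g in genes:
        gi = tensor.gene_index[g]
        if cm[gi] > 0 and cms[gi] > 0:
            out.append(g)
    return out


def skew_matrix(tensor: BindingTensor, branch: BranchPartition, genes=None) -> np.ndarray:
    """The (n_tfs, len(genes)) matrix of pairwise skews skew(x, g).

    Raises :class:`UndefinedSkewError` if any requested gene lacks a present
    ortholog on one side of the partition.
    """
    idx_m, idx_ms, cm, cms = _side_counts(tensor, branch)
    if genes is None:
        genes = tensor.gene_ids
    gidx = np.array([tensor.gene_index[g] for g in genes], dtype=int)
    bad = [g for g, gi in zip(genes, gidx) if cm[gi] == 0 or cms[gi] == 0]
    if bad:
        raise UndefinedSkewError(
            f"branch {branch.label!r}: skew undefined for genes {bad} "
            f"(no present ortholog on one side)"
        )
    sum_m = np.nansum(tensor.P[:, gidx][:, :, idx_m], axis=2)
    sum_ms = np.nansum(tensor.P[:, gidx][:, :, idx_ms], axis=2)
    return sum_m / cm[gidx] - sum_ms / cms[gidx]


def skew_tf_gene(tensor: BindingTensor, x: str, g: str,
                 branch: BranchPartition) -> float:
    """skew(x, g, M): mean over present species in M minus mean over M*."""
    if x not in tensor.tf_index:
        raise ValidationError(f"unknown transcription factor {x!r}")
    S = skew_matrix(tensor, branch, genes=[g])
    return float(S[tensor.tf_index[x], 0])


def skew_team_genes(tensor: BindingTensor, T, G, branch: BranchPartition) -> float:
    """skew(T, G): grand mean of skew(x, g) over all pairs in T x G."""
    T, G = list(T), list(G)
    if not T or not G:
        raise ValidationError("skew(T, G) requires non-empty T and G")
    for x in T:
        if x not in tensor.tf_index:
            raise ValidationError(f"unknown transcription factor {x!r}")
    S = skew_matrix(tensor, branch, genes=G)
    rows = [tensor.tf_index[x] for x in T]
    return float(S[rows, :].mean())


def block_skew_sets(tensor: BindingTensor, T, T_star, G,
                    branch: BranchPartition) -> float:
    """skew(T, T*, G) = skew(T, G) − skew(T*, G); range [−2, 2]."""
    if set(T) & set(T_star):
        raise ValidationError("T and T* must be disjoint")
    return skew_team_genes(tensor, T, G, branch) - skew_team_genes(tensor, T_star, G, branch)


def block_skew(tensor: BindingTensor, block: Block) -> float:
    """Recompute a block's score from the tensor."""
    return block_skew_sets(tensor, block.T, block.T_star, block.G, block.branch)


def dif_scores(tensor: BindingTensor, block: Block) -> tuple[float, float]:
    """Pooled team differences (Dif(M), Dif(M*)).

    Dif(M) is the mean of P over all present (x in T, g in G, s in M)
    triples minus the same mean for T*; Dif(M*) is the analogue on the
    complement.  On a complete tensor Dif(M) − Dif(M*) equals the block
    score exactly; with missing orthologs the pooled means weight genes by
    their number of present species, so the identity is only approximate.
    """
    idx_m, idx_ms = branch_species_indices(tensor, block.branch)
    t_idx = [tensor.tf_index[x] for x in block.T]
    ts_idx = [tensor.tf_index[x] for x in block.T_star]
    g_idx = [tensor.gene_index[g] for g in block.G]

    def pooled(rows, cols):
        vals = tensor.P[np.ix_(rows, g_idx, cols)]
        if np.all(np.isnan(vals)):
            raise UndefinedSkewError(
                f"branch {block.branch.label!r}: no present orthologs on one side"
            )
        return float(np.nanmean(vals))

    dif_m = pooled(t_idx, idx_m) - pooled(ts_idx, idx_m)
    dif_ms = pooled(t_idx, idx_ms) - pooled(ts_idx, idx_ms)
    return dif_m, dif_ms
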