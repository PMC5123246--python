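"""Deterministic synthetic data with planted rewiring structure.

The generator emulates the structure of a real rewiring event: inside a
planted block the T team binds strongly on the clade M and weakly on M*,
the T* team does the opposite, and everything else fluctuates around a
neutral background mean.  Probabilities are truncated-normal noise around
those means, so the planted block's expected score has the closed form

    delta = (t_on_m - t_on_m_star) - (t_star_on_m - t_star_on_m_star).

Default dimensions scale the real study down: 20 factors x 40 genes x 23
species, a 10-species clade, and a planted (3, 1, 19)-block with
delta = 1.0 and noise 0.05.  Same seed, same bytes.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import yaml
from scipy.stats import truncnorm

from ._precision import round8
from .data_model import (
    BindingTensor,
    Block,
    BranchPartition,
    GeneModule,
    write_binding_table,
    write_modules,
)
from .binding import PWMatrix, PromoterSet, write_promoters, write_transfac
from .exceptions import ValidationError
from .skewness import block_skew

__all__ = [
    "PlantSpec",
    "PlantResult",
    "plant_tensor",
    "random_tensor",
    "prefix_branch",
    "species_tree_newick",
    "default_branch_config",
    "synthetic_pwms",
    "plant_promoters",
    "module51_fixture",
    "write_dataset",
]


@dataclass(frozen=True)
class PlantSpec:
    """Parameters of a planted-rewiring fixture.

    Means are clipped-truncated-normal centres per cell; the planted block
    occupies the first ``m`` factors (team T), the next ``m_star`` factors
    (team T*) and the first ``m_g`` genes, against the clade of the first
    ``n_clade`` species.
    """

    n_tfs: int = 20
    n_genes: int = 40
    n_species: int = 23
    n_clade: int = 10
    m: int = 3
    m_star: int = 1
    m_g: int = 19
    t_on_m: float = 0.8
    t_on_m_star: float = 0.3
    t_star_on_m: float = 0.3
    t_star_on_m_star: float = 0.8
    background_mean: float = 0.5
    noise: float = 0.05
    missing_rate: float = 0.0
    seed: int = 0
    tf_names: tuple | None = None
    gene_names: tuple | None = None
    species_names: tuple | None = None
    module_id: str = "1"

    def __post_init__(self):
        if self.m + self.m_star > self.n_tfs:
            raise ValidationError("planted teams exceed the number of factors")
        if self.m_g > self.n_genes:
            raise ValidationError("planted gene set exceeds the number of genes")
        if not 1 <= self.n_clade < self.n_species:
            raise ValidationError("clade must be a proper non-empty species subset")
        for name in ("t_on_m", "t_on_m_star", "t_star_on_m", "t_star_on_m_star",
                     "background_mean"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValidationError(f"{name}={v} outside [0, 1]")
        if not 0.0 <= self.missing_rate < 1.0:
            raise ValidationError("missing_rate must lie in [0, 1)")

    @property
    def delta(self) -> float:
        """Closed-form block score of the planted means."""
        return (self.t_on_m - self.t_on_m_star) - (self.t_star_on_m - self.t_star_on_m_star)

    def names(self):
        tfs = self.tf_names or tuple(f"TF{i + 1:03d}" for i in range(self.n_tfs))
        genes = self.gene_names or tuple(f"g{i + 1:03d}" for i in range(self.n_genes))
        species = self.species_names or tuple(f"sp{i + 1:02d}" for i in range(self.n_species))
        if (len(tfs), len(genes), len(species)) != (self.n_tfs, self.n_genes, self.n_species):
            raise ValidationError("name list lengths do not match the fixture dimensions")
        return list(tfs), list(genes), list(species)


@dataclass
class PlantResult:
    """A planted tensor with its ground truth."""

    tensor: BindingTensor
    block: Block | None
    branch: BranchPartition
    module: GeneModule
    spec: PlantSpec


def _truncnorm_around(means: np.ndarray, scale: float, rng) -> np.ndarray:
    if scale == 0:
        return means.copy()
    a = (0.0 - means) / scale
    b = (1.0 - means) / scale
    return truncnorm.rvs(a, b, loc=means, scale=scale, random_state=rng)


def plant_tensor(spec: PlantSpec) -> PlantResult:
    """Generate a tensor with the planted block of `spec` (seeded)."""
    tfs, genes, species = spec.names()
    rng = np.random.default_rng(spec.seed)
    means = np.full((spec.n_tfs, spec.n_genes, spec.n_species), spec.background_mean)
    m_side = np.arange(spec.n_species) < spec.n_clade
    t_rows = np.arange(spec.m)
    ts_rows = np.arange(spec.m, spec.m + spec.m_star)
    g_cols = np.arange(spec.m_g)
    if spec.m and spec.m_g:
        means[np.ix_(t_rows, g_cols, np.where(m_side)[0])] = spec.t_on_m
        means[np.ix_(t_rows, g_cols, np.where(~m_side)[0])] = spec.t_on_m_star
    if spec.m_star and spec.m_g:
        means[np.ix_(ts_rows, g_cols, np.where(m_side)[0])] = spec.t_star_on_m
        means[np.ix_(ts_rows, g_cols, np.where(~m_side)[0])] = spec.t_star_on_m_star
    P = round8(np.clip(_truncnorm_around(means, spec.noise, rng), 0.0, 1.0))
    present = rng.random((spec.n_genes, spec.n_species)) >= spec.missing_rate
    tensor = BindingTensor(tfs, genes, species, P, present)
    branch = BranchPartition.from_members(str(spec.n_clade), species[: spec.n_clade], species)
    module = GeneModule(spec.module_id, frozenset(genes))
    block = None
    if spec.m and spec.m_star and spec.m_g:
        block = Block(
            T=tuple(tfs[i] for i in t_rows),
            T_star=tuple(tfs[i] for i in ts_rows),
            G=tuple(genes[i] for i in g_cols),
            branch=branch,
            score=0.0,
        )
        block = replace(block, score=block_skew(tensor, block))
    return PlantResult(tensor, block, branch, module, spec)


def random_tensor(seed: int, n_tfs: int, n_genes: int, n_species: int,
                  missing_rate: float = 0.0) -> BindingTensor:
    """A uniform-random tensor (no planted structure), for property tests."""
    rng = np.random.default_rng(seed)
    P = round8(rng.random((n_tfs, n_genes, n_species)))
    present = rng.random((n_genes, n_species)) >= missing_rate
    return BindingTensor(
        [f"TF{i + 1:03d}" for i in range(n_tfs)],
        [f"g{i + 1:03d}" for i in range(n_genes)],
        [f"sp{i + 1:02d}" for i in range(n_species)],
        P,
        present,
    )


def prefix_branch(tensor: BindingTensor, k: int, label: str | None = None) -> BranchPartition:
    """Branch whose M is the first k species of the tensor."""
    return BranchPartition.from_members(
        label or str(k), tensor.species_ids[:k], tensor.species_ids
    )


# ---------------------------------------------------------------------------
# Trees
# ---------------------------------------------------------------------------

def _ladder(names) -> str:
    if len(names) == 1:
        return names[0]
    out = f"({names[0]},{names[1]})"
    for n in names[2:]:
        out = f"({out},{n})"
    return out


def species_tree_newick(species, clades=None) -> str:
    """A rooted newick tree over `species` built from left-nested ladders.

    ``clades`` partitions the species list, in order, into sub-ladders;
    every prefix union of clades (and every prefix within the first clade)
    is then a clade of the tree.  Default for 23 species mirrors the
    study's branch structure: sizes 10, 3, 4, 3, 3, so that e.g. the first
    10 species, species 11–13, species 14–17, and the first 20 species are
    all clades.
    """
    species = list(species)
    if clades is None:
        if len(species) == 23:
            sizes = [10, 3, 4, 3, 3]
        else:
            sizes = [max(1, len(species) // 2), len(species) - max(1, len(species) // 2)]
        clades, start = [], 0
        for size in sizes:
            clades.append(species[start:start + size])
            start += size
    flat = [s for c in clades for s in c]
    if flat != species:
        raise ValidationError("clades must partition the species list in order")
    return _ladder([_ladder(c) for c in clades]) + ";"


def default_branch_config(species) -> dict:
    """Branch labels for the default 23-species fixture tree."""
    species = list(species)
    if len(species) != 23:
        return {str(max(1, len(species) // 2)): None}
    return {
        "4": None,
        "10": None,
        "20": None,
        "112": [species[i] for i in range(13, 17)],
        "113": [species[i] for i in range(10, 13)],
    }


# ---------------------------------------------------------------------------
# PWMs and promoters
# ---------------------------------------------------------------------------

def synthetic_pwms(n: int, width: int = 8, seed: int = 0,
                   strength: float = 20.0, names=None) -> list[PWMatrix]:
    """Random strong-consensus PWMs (count `strength` on one base per position)."""
    rng = np.random.default_rng(seed)
    names = list(names) if names is not None else [f"TF{i + 1:03d}" for i in range(n)]
    if len(names) != n:
        raise ValidationError("need one name per PWM")
    out = []
    for name in names:
        counts = np.zeros((width, 4))
        counts[np.arange(width), rng.integers(0, 4, size=width)] = strength
        out.append(PWMatrix(name, counts))
    return out


def plant_promoters(spec: PlantSpec, pwms, length: int = 600,
                    composition=(0.3, 0.2, 0.2, 0.3), copies: int = 2) -> PromoterSet:
    """Promoters with consensus sites implanted to mirror the planted block.

    The first ``spec.m`` PWMs belong to team T and get their consensus
    implanted into the clade-M promoters of the planted genes; the next
    ``spec.m_star`` PWMs are team T* and are implanted on the M* side only.
    The rest of every sequence is i.i.d. background with the given base
    composition.
    """
    pwms = list(pwms)
    if len(pwms) < spec.m + spec.m_star:
        raise ValidationError("need at least m + m* PWMs to plant")
    max_w = max(p.width for p in pwms[: spec.m + spec.m_star]) if pwms else 0
    if length < max_w * copies:
        raise ValidationError("promoter too short for the requested implants")
    _, genes, species = spec.names()
    rng = np.random.default_rng(spec.seed + 1)
    comp = np.asarray(composition, float)
    comp = comp / comp.sum()
    records = {}
    for gi, gene in enumerate(genes):
        for si, sp in enumerate(species):
            seq = rng.choice(list("ACGT"), size=length, p=comp)
            if gi < spec.m_g:
                on_m = si < spec.n_clade
                team = pwms[: spec.m] if on_m else pwms[spec.m: spec.m + spec.m_star]
                for pwm in team:
                    site = pwm.consensus()
                    for _ in range(copies):
                        start = int(rng.integers(0, length - pwm.width + 1))
                        seq[start:start + pwm.width] = list(site)
            records[(sp, gene)] = "".join(seq)
    return PromoterSet(records, max_length=max(length, PromoterSet.max_length))


def module51_fixture(seed: int = 0, noise: float = 0.05) -> PlantResult:
    """A fixture shaped like the study's flagship case.

    Ribosomal-protein-like module of 31 genes on a 23-species tree, branch
    "10": a three-factor team (FHL1, RAP1, SFP1) binds the 19 signal genes
    on the first ten species while the singleton team TBF1 binds them on
    the other thirteen.
    """
    tf_names = ("FHL1", "RAP1", "SFP1", "TBF1") + tuple(
        f"YTF{i:03d}" for i in range(5, 21)
    )
    gene_names = tuple(f"RPL{i:03d}" for i in range(1, 20)) + tuple(
        f"YGL{i:03d}" for i in range(20, 32)
    )
    spec = PlantSpec(
        n_tfs=20, n_genes=31, n_species=23, n_clade=10,
        m=3, m_star=1, m_g=19, noise=noise, seed=seed,
        tf_names=tf_names, gene_names=gene_names, module_id="51",
    )
    return plant_tensor(spec)


# ---------------------------------------------------------------------------
# On-disk fixture bundles
# ---------------------------------------------------------------------------

def write_dataset(result: PlantResult, out_dir, with_promoters: bool = False) -> dict:
    """Write a planted fixture as the package's on-disk formats.

    Produces tensor.tsv, modules.tsv (the planted module plus a decoy
    module of the background genes), tree.nwk, branches.yaml and
    ground_truth.json; optionally pwms.transfac and promoters.fasta for the
    occupancy stage.  Returns the path map.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    spec = result.spec
    tensor = result.tensor
    paths = {
        "tensor": out / "tensor.tsv",
        "modules": out / "modules.tsv",
        "tree": out / "tree.nwk",
        "branches": out / "branches.yaml",
        "ground_truth": out / "ground_truth.json",
    }
    write_binding_table(tensor, paths["tensor"])
    modules = [result.module]
    background_genes = [g for g in tensor.gene_ids
                        if result.block is None or g not in result.block.G]
    if background_genes:
        decoy_id = f"{result.module.module_id}_background"
        modules.append(GeneModule(decoy_id, frozenset(background_genes)))
    write_modules(modules, paths["modules"])
    with open(paths["tree"], "w", encoding="utf-8") as fh:
        fh.write(species_tree_newick(tensor.species_ids) + "\n")
    with open(paths["branches"], "w", encoding="utf-8") as fh:
        yaml.safe_dump({"branches": default_branch_config(tensor.species_ids)}, fh)
    truth = {
        "seed": spec.seed,
        "delta": spec.delta,
        "branch": result.branch.label,
        "module_id": result.module.module_id,
        "block": None,
    }
    if result.block is not None:
        truth["block"] = {
            "T": list(result.block.T),
            "T_star": list(result.block.T_star),
            "G": list(result.block.G),
            "score": result.block.score,
        }
    with open(paths["ground_truth"], "w", encoding="utf-8") as fh:
        json.dump(truth, fh, indent=2, sort_keys=True)
        fh.write("\n")
    if with_promoters:
        pwms = synthetic_pwms(spec.n_tfs, seed=spec.seed,
                              names=tensor.tf_ids)
        promoters = plant_promoters(spec, pwms)
        paths["pwms"] = out / "pwms.transfac"
        paths["promoters"] = out / "promoters.fasta"
        write_transfac(pwms, paths["pwms"])
        write_promoters(promoters, paths["promoters"])
    return paths
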