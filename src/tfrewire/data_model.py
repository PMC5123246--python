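"""Core domain types and readers/writers for the on-disk text formats.

The central container is the :class:`BindingTensor`: the probability
``P(x, g, s)`` that transcription factor *x* binds somewhere in the upstream
promoter region of gene *g* in species *s*, together with an explicit
ortholog-presence mask.  Species without an ortholog of a gene never enter
any average.

All tables are plain tab-separated text; trees are newick; branch partitions
come from a small YAML/dict configuration mapping branch labels to clade
memberships.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from decimal import InvalidOperation
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import dendropy
import numpy as np
import pandas as pd
import yaml

from ._precision import round8, round8_decimal
from .exceptions import ParseError, ValidationError

#: column order of the binding-probability table
BINDING_COLUMNS = ("tf", "gene", "species", "probability")

#: column order of the module membership table
MODULE_COLUMNS = ("module_id", "gene_id")

_SEPARATORS = {"tsv": "\t", "csv": ","}


def _check_unique(names: Sequence[str], what: str) -> None:
    if len(set(names)) != len(names):
        seen, dup = set(), set()
        for n in names:
            if n in seen:
                dup.add(n)
            seen.add(n)
        raise ValidationError(f"duplicate {what}: {sorted(dup)}")


class BindingTensor:
    """Binding probabilities over (transcription factor, gene, species).

    Parameters
    ----------
    tf_ids, gene_ids, species_ids
        Ordered, duplicate-free name lists.
    P
        Array of shape ``(n_tfs, n_genes, n_species)``.  Entries at
        (gene, species) pairs without an ortholog are forced to NaN so they
        can never leak into a sum.
    present
        Boolean ortholog-presence mask of shape ``(n_genes, n_species)``.
        ``None`` means every ortholog is present.

    Every stored probability lies in [0, 1] and is rounded to eight decimal
    digits; the eight-digit precision is what makes score ties rare and
    tie-breaking reproducible.
    """

    def __init__(self, tf_ids, gene_ids, species_ids, P, present=None, *, validate=True):
        self.tf_ids = [str(t) for t in tf_ids]
        self.gene_ids = [str(g) for g in gene_ids]
        self.species_ids = [str(s) for s in species_ids]
        self.P = np.array(P, dtype=float)
        if present is None:
            present = np.ones((len(self.gene_ids), len(self.species_ids)), dtype=bool)
        self.present = np.array(present, dtype=bool)
        # NaN out absent entries so they can never enter an average
        self.P[:, ~self.present] = np.nan
        self.tf_index = {n: i for i, n in enumerate(self.tf_ids)}
        self.gene_index = {n: i for i, n in enumerate(self.gene_ids)}
        self.species_index = {n: i for i, n in enumerate(self.species_ids)}
        if validate:
            self._validate()

    # -- basic introspection -------------------------------------------------
    @property
    def n_tfs(self) -> int:
        return len(self.tf_ids)

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_species(self) -> int:
        return len(self.species_ids)

    @property
    def shape(self):
        return (self.n_tfs, self.n_genes, self.n_species)

    def _validate(self) -> None:
        _check_unique(self.tf_ids, "transcription factor ids")
        _check_unique(self.gene_ids, "gene ids")
        _check_unique(self.species_ids, "species ids")
        expected = (self.n_tfs, self.n_genes, self.n_species)
        if self.P.shape != expected:
            raise ValidationError(f"P has shape {self.P.shape}, expected {expected}")
        if self.present.shape != (self.n_genes, self.n_species):
            raise ValidationError(
                f"present mask has shape {self.present.shape}, "
                f"expected {(self.n_genes, self.n_species)}"
            )
        vals = self.P[:, self.present]
        if vals.size and not np.all(np.isfinite(vals)):
            raise ValidationError("probabilities at present orthologs must be finite")
        if vals.size and (vals.min() < 0.0 or vals.max() > 1.0):
            raise ValidationError("probabilities must lie in [0, 1]")
        if vals.size and np.max(np.abs(vals - round8(vals))) > 1e-12:
            raise ValidationError("probabilities must be rounded to 8 decimal digits")

    # -- element access ------------------------------------------------------
    def is_present(self, gene: str, species: str) -> bool:
        return bool(self.present[self.gene_index[gene], self.species_index[species]])

    def probability(self, tf: str, gene: str, species: str) -> float:
        """Return P(tf, gene, species); error if the ortholog is absent."""
        gi, si = self.gene_index[gene], self.species_index[species]
        if not self.present[gi, si]:
            raise ValidationError(f"gene {gene!r} has no ortholog in species {species!r}")
        return float(self.P[self.tf_index[tf], gi, si])

    # -- DataFrame bridge ----------------------------------------------------
    def to_frame(self) -> pd.DataFrame:
        """Long-format (tf, gene, species, probability) rows, present pairs only."""
        rows = []
        for ti, tf in enumerate(self.tf_ids):
            for gi, g in enumerate(self.gene_ids):
                for si, s in enumerate(self.species_ids):
                    if self.present[gi, si]:
                        rows.append((tf, g, s, float(self.P[ti, gi, si])))
        return pd.DataFrame(rows, columns=list(BINDING_COLUMNS))

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "BindingTensor":
        """Build a tensor from long-format rows (validates like the reader)."""
        entries = {
            (str(r.tf), str(r.gene), str(r.species)): round8_decimal(str(r.probability))
            for r in df.itertuples(index=False)
        }
        if len(entries) != len(df):
            raise ValidationError("duplicate (tf, gene, species) triples")
        return _tensor_from_entries(entries)

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return (
            f"BindingTensor({self.n_tfs} TFs x {self.n_genes} genes x "
            f"{self.n_species} species, {int(self.present.sum())} present pairs)"
        )


def _tensor_from_entries(entries: Mapping[tuple, float]) -> BindingTensor:
    tfs, genes, species = [], [], []
    seen_t, seen_g, seen_s = set(), set(), set()
    for (t, g, s) in entries:
        if t not in seen_t:
            seen_t.add(t)
            tfs.append(t)
        if g not in seen_g:
            seen_g.add(g)
            genes.append(g)
        if s not in seen_s:
            seen_s.add(s)
            species.append(s)
    ti = {n: i for i, n in enumerate(tfs)}
    gi = {n: i for i, n in enumerate(genes)}
    si = {n: i for i, n in enumerate(species)}
    P = np.full((len(tfs), len(genes), len(species)), np.nan)
    counts = np.zeros((len(genes), len(species)), dtype=int)
    for (t, g, s), p in entries.items():
        P[ti[t], gi[g], si[s]] = p
        counts[gi[g], si[s]] += 1
    partial = (counts > 0) & (counts < len(tfs))
    if partial.any():
        g0, s0 = np.argwhere(partial)[0]
        raise ValidationError(
            f"incomplete transcription-factor coverage for (gene {genes[g0]!r}, "
            f"species {species[s0]!r}): a (gene, species) pair must either list "
            f"all {len(tfs)} factors or be absent entirely"
        )
    present = counts == len(tfs)
    return BindingTensor(tfs, genes, species, P, present)


def read_binding_table(path, dialect: str = "tsv") -> BindingTensor:
    """Read a delimited (tf, gene, species, probability) table.

    A (gene, species) pair absent from the file is recorded as a missing
    ortholog (``present=False``); a pair covered by only part of the factor
    set is a validation error.  Probabilities are rounded half-to-even at
    eight decimal digits by exact decimal arithmetic on load.
    """
    sep = _SEPARATORS[dialect]
    path = Path(path)
    entries: dict[tuple, float] = {}
    with open(path, encoding="utf-8") as fh:
        header = fh.readline()
        cols = tuple(c.strip() for c in header.rstrip("\n").split(sep))
        if cols != BINDING_COLUMNS:
            raise ParseError(
                f"{path.name}: line 1: expected header {sep.join(BINDING_COLUMNS)!r}, "
                f"got {header.strip()!r}"
            )
        for lineno, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            parts = [p.strip() for p in line.rstrip("\n").split(sep)]
            if len(parts) != 4:
                raise ParseError(
                    f"{path.name}: line {lineno}: expected 4 fields, got {len(parts)}"
                )
            tf, gene, species, prob_text = parts
            if not (tf and gene and species and prob_text):
                raise ParseError(f"{path.name}: line {lineno}: empty field")
            try:
                prob = round8_decimal(prob_text)
            except (InvalidOperation, ValueError) as exc:
                raise ParseError(
                    f"{path.name}: line {lineno}: bad probability {prob_text!r}"
                ) from exc
            if not 0.0 <= prob <= 1.0:
                raise ValidationError(
                    f"{path.name}: line {lineno}: probability {prob_text} outside [0, 1]"
                )
            key = (tf, gene, species)
            if key in entries:
                raise ValidationError(
                    f"{path.name}: line {lineno}: duplicate triple {key}"
                )
            entries[key] = prob
    if not entries:
        raise ParseError(f"{path.name}: no data rows")
    return _tensor_from_entries(entries)


def write_binding_table(tensor: BindingTensor, path, dialect: str = "tsv") -> None:
    """Write the tensor as a delimited table (absent orthologs are omitted)."""
    sep = _SEPARATORS[dialect]
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(sep.join(BINDING_COLUMNS) + "\n")
        for ti, tf in enumerate(tensor.tf_ids):
            for gi, g in enumerate(tensor.gene_ids):
                for si, s in enumerate(tensor.species_ids):
                    if tensor.present[gi, si]:
                        fh.write(sep.join((tf, g, s, f"{tensor.P[ti, gi, si]:.8f}")) + "\n")


# ---------------------------------------------------------------------------
# Gene modules
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GeneModule:
    """A named candidate regulon: a non-empty set of gene ids."""

    module_id: str
    genes: frozenset

    def __post_init__(self):
        object.__setattr__(self, "genes", frozenset(str(g) for g in self.genes))
        if not self.genes:
            raise ValidationError(f"module {self.module_id!r} is empty")

    @property
    def sorted_genes(self) -> tuple:
        return tuple(sorted(self.genes))

    def __len__(self) -> int:
        return len(self.genes)


def read_modules(path, tensor: BindingTensor | None = None,
                 unknown_genes: str = "warn") -> list[GeneModule]:
    """Read a (module_id, gene_id) table into modules (which may overlap).

    Genes unknown to `tensor` are dropped with a warning, or rejected when
    ``unknown_genes="error"``.
    """
    if unknown_genes not in ("warn", "error"):
        raise ValueError("unknown_genes must be 'warn' or 'error'")
    path = Path(path)
    order: list[str] = []
    members: dict[str, list] = {}
    with open(path, encoding="utf-8") as fh:
        header = fh.readline()
        cols = tuple(c.strip() for c in header.rstrip("\n").split("\t"))
        if cols != MODULE_COLUMNS:
            expected = "\t".join(MODULE_COLUMNS)
            raise ParseError(
                f"{path.name}: line 1: expected header "
                f"{expected!r}, got {header.strip()!r}"
            )
        for lineno, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            parts = [p.strip() for p in line.rstrip("\n").split("\t")]
            if len(parts) != 2 or not parts[0] or not parts[1]:
                raise ParseError(
                    f"{path.name}: line {lineno}: expected non-empty "
                    f"(module_id, gene_id), got {line.strip()!r}"
                )
            mid, gene = parts
            if tensor is not None and gene not in tensor.gene_index:
                msg = f"{path.name}: line {lineno}: gene {gene!r} absent from tensor"
                if unknown_genes == "error":
                    raise ValidationError(msg)
                warnings.warn(msg + "; dropped", stacklevel=2)
                continue
            if mid not in members:
                members[mid] = []
                order.append(mid)
            members[mid].append(gene)
    modules = []
    for mid in order:
        if not members[mid]:
            warnings.warn(f"module {mid!r} lost all genes; dropped", stacklevel=2)
            continue
        modules.append(GeneModule(mid, frozenset(members[mid])))
    if not modules:
        raise ParseError(f"{path.name}: no modules")
    return modules


def write_modules(modules: Iterable[GeneModule], path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("\t".join(MODULE_COLUMNS) + "\n")
        for module in modules:
            for gene in module.sorted_genes:
                fh.write(f"{module.module_id}\t{gene}\n")


# ---------------------------------------------------------------------------
# Branch partitions
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class BranchPartition:
    """A split of the species set into a clade M and its complement M*."""

    label: str
    M: frozenset
    M_star: frozenset

    def __post_init__(self):
        object.__setattr__(self, "M", frozenset(str(s) for s in self.M))
        object.__setattr__(self, "M_star", frozenset(str(s) for s in self.M_star))
        if not self.M or not self.M_star:
            raise ValidationError(f"branch {self.label!r}: both sides must be non-empty")
        if self.M & self.M_star:
            raise ValidationError(
                f"branch {self.label!r}: M and M* overlap: {sorted(self.M & self.M_star)}"
            )

    @property
    def species(self) -> frozenset:
        return self.M | self.M_star

    def validate_against(self, species_ids: Sequence[str]) -> None:
        full = set(species_ids)
        if self.species != full:
            missing = full - self.species
            extra = self.species - full
            raise ValidationError(
                f"branch {self.label!r} does not partition the species set "
                f"(missing={sorted(missing)}, unknown={sorted(extra)})"
            )

    def swapped(self) -> "BranchPartition":
        """The same split with the roles of M and M* exchanged."""
        return BranchPartition(f"{self.label}*", self.M_star, self.M)

    @classmethod
    def from_members(cls, label: str, members: Iterable[str],
                     all_species: Sequence[str]) -> "BranchPartition":
        members = frozenset(str(m) for m in members)
        rest = frozenset(all_species) - members
        return cls(str(label), members, rest)


def read_species_tree(path):
    """Read a newick tree; returns ``(tree, leaf_labels_in_file_order)``."""
    tree = dendropy.Tree.get(path=str(path), schema="newick", preserve_underscores=True)
    tree.is_rooted = True  # clade membership is read off the rooted topology
    leaves = [leaf.taxon.label for leaf in tree.leaf_node_iter()]
    _check_unique(leaves, "tree leaf labels")
    return tree, leaves


def _is_clade(tree, members: set) -> bool:
    try:
        mrca = tree.mrca(taxon_labels=sorted(members))
    except (KeyError, ValueError):
        return False
    if mrca is None:
        return False
    below = {leaf.taxon.label for leaf in mrca.leaf_iter()}
    return below == set(members)


def read_tree_and_branches(tree_path, branch_config, *,
                           check_clades: bool = True) -> list[BranchPartition]:
    """Expand a branch configuration against a species tree.

    ``branch_config`` maps a branch label to either ``None`` (a one- or
    two-digit label *k*, expanded to the first *k* species in tree leaf
    order) or an explicit list of species names.  Each branch must be a
    clade of the tree — or have a clade as its complement, which covers
    splits at the root — unless ``check_clades`` is disabled.
    """
    if isinstance(branch_config, (str, Path)):
        with open(branch_config, encoding="utf-8") as fh:
            branch_config = yaml.safe_load(fh)
    if isinstance(branch_config, dict) and "branches" in branch_config:
        branch_config = branch_config["branches"]
    if not isinstance(branch_config, dict) or not branch_config:
        raise ValidationError("branch config must be a non-empty mapping")

    tree, leaves = read_species_tree(tree_path)
    partitions = []
    for label, value in branch_config.items():
        label = str(label)
        if value is None:
            if not (label.isdigit() and len(label) <= 2):
                raise ValidationError(
                    f"branch {label!r}: only 1- or 2-digit labels expand to a "
                    f"species prefix; give the membership explicitly"
                )
            k = int(label)
            if not 1 <= k < len(leaves):
                raise ValidationError(
                    f"branch {label!r}: prefix size {k} outside 1..{len(leaves) - 1}"
                )
            members = leaves[:k]
        else:
            members = [str(v) for v in value]
            unknown = set(members) - set(leaves)
            if unknown:
                raise ValidationError(
                    f"branch {label!r}: unknown species {sorted(unknown)}"
                )
        part = BranchPartition.from_members(label, members, leaves)
        if check_clades and not (_is_clade(tree, set(part.M))
                                 or _is_clade(tree, set(part.M_star))):
            raise ValidationError(
                f"branch {label!r}: neither {sorted(part.M)} nor its complement "
                f"is a clade of the tree"
            )
        partitions.append(part)
    return partitions


# ---------------------------------------------------------------------------
# Blocks
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class BlockShape:
    """Sizes (m, m*, mG) of the two factor teams and the gene set."""

    m: int
    m_star: int
    m_g: int

    def __post_init__(self):
        for name, v in (("m", self.m), ("m_star", self.m_star), ("m_g", self.m_g)):
            if int(v) != v or v < 1:
                raise ValidationError(f"shape component {name} must be a positive integer")

    @property
    def total(self) -> int:
        return self.m + self.m_star + self.m_g

    def as_tuple(self):
        return (self.m, self.m_star, self.m_g)


@dataclass(frozen=True)
class Block:
    """Two disjoint transcription-factor teams and a gene set, with its score.

    ``score`` is skew(T, G) − skew(T*, G) for the stored branch, recomputable
    from the tensor.  Member tuples are kept alphabetically sorted so equal
    blocks compare equal.
    """

    T: tuple
    T_star: tuple
    G: tuple
    branch: BranchPartition
    score: float

    def __post_init__(self):
        object.__setattr__(self, "T", tuple(sorted(str(x) for x in self.T)))
        object.__setattr__(self, "T_star", tuple(sorted(str(x) for x in self.T_star)))
        object.__setattr__(self, "G", tuple(sorted(str(g) for g in self.G)))
        for name, group in (("T", self.T), ("T_star", self.T_star), ("G", self.G)):
            if not group:
                raise ValidationError(f"block component {name} is empty")
            _check_unique(group, f"block {name} members")
        if set(self.T) & set(self.T_star):
            raise ValidationError(
                f"teams overlap: {sorted(set(self.T) & set(self.T_star))}"
            )

    @property
    def shape(self) -> BlockShape:
        return BlockShape(len(self.T), len(self.T_star), len(self.G))
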