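"""Promoter occupancy probabilities from positional weight matrices.

Each transcription factor is modelled by a PWM of width 6–20 (usually under
10).  For a window *w* of promoter sequence the per-site binding
probability is the posterior of an independent-sites likelihood-ratio
model,

    q(w) = p L(w) / (p L(w) + (1 - p) B(w)),

with L the PWM likelihood (pseudocount-regularised frequencies), B the
background likelihood under the species' promoter base composition, and a
per-window prior p defaulting to 1/600 — one expected site in a full-length
promoter.  The occupancy of a promoter is the probability of at least one
binding event over all windows on both strands,

    occupancy = 1 - prod_w (1 - q(w)).

Windows containing an ambiguous base contribute zero.  The per-window model
lives behind :func:`site_probability` so a different estimator can be
swapped in without touching any caller.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from Bio import SeqIO, motifs
from Bio.Seq import Seq

from ._precision import round8
from .data_model import BindingTensor, _check_unique
from .exceptions import ParseError, ValidationError

__all__ = [
    "PWMatrix",
    "PromoterSet",
    "parse_transfac",
    "write_transfac",
    "read_promoters",
    "write_promoters",
    "base_composition",
    "site_probability",
    "occupancy_probability",
    "build_tensor",
]

BASES = "ACGT"
_BASE_INDEX = {b: i for i, b in enumerate(BASES)}

#: default per-window prior: one expected site per 600-bp promoter
DEFAULT_PRIOR = 1.0 / 600.0
DEFAULT_PSEUDOCOUNT = 0.5
#: promoters are the up-to-600-bp region immediately 5' of the start codon
PROMOTER_LENGTH = 600

UNIFORM_BACKGROUND = np.full(4, 0.25)


@dataclass
class PWMatrix:
    """Position-specific nucleotide count matrix for one factor.

    ``counts`` has shape (width, 4) in A, C, G, T order; counts may be real
    (weighted alignments) but must be non-negative.
    """

    tf_id: str
    counts: np.ndarray

    def __post_init__(self):
        self.counts = np.asarray(self.counts, dtype=float)
        if self.counts.ndim != 2 or self.counts.shape[1] != 4:
            raise ValidationError(
                f"PWM {self.tf_id!r}: counts must have shape (width, 4)"
            )
        if self.width < 1:
            raise ValidationError(f"PWM {self.tf_id!r}: zero width")
        if np.any(self.counts < 0) or not np.all(np.isfinite(self.counts)):
            raise ValidationError(f"PWM {self.tf_id!r}: counts must be finite and >= 0")

    @property
    def width(self) -> int:
        return self.counts.shape[0]

    def frequencies(self, pseudocount: float = DEFAULT_PSEUDOCOUNT) -> np.ndarray:
        """Pseudocount-regularised frequencies; each row sums to 1."""
        c = self.counts + pseudocount
        return c / c.sum(axis=1, keepdims=True)

    def consensus(self) -> str:
        """Highest-count base per position (ties to the first of A,C,G,T)."""
        return "".join(BASES[i] for i in self.counts.argmax(axis=1))


# ---------------------------------------------------------------------------
# TRANSFAC I/O (via Bio.motifs)
# ---------------------------------------------------------------------------

def parse_transfac(path) -> list[PWMatrix]:
    """Parse a TRANSFAC-format matrix file into :class:`PWMatrix` records."""
    path = Path(path)
    try:
        with open(path, encoding="utf-8") as fh:
            records = motifs.parse(fh, "TRANSFAC")
    except Exception as exc:
        raise ParseError(f"{path.name}: not a valid TRANSFAC file: {exc}") from exc
    out = []
    for i, record in enumerate(records):
        name = record.get("ID") or record.get("AC") or record.name or f"motif_{i + 1}"
        counts = np.column_stack([record.counts[b] for b in BASES])
        out.append(PWMatrix(str(name), counts))
    if not out:
        raise ParseError(f"{path.name}: no matrices found")
    _check_unique([p.tf_id for p in out], "PWM ids")
    return out


def write_transfac(pwms, path) -> None:
    """Write matrices in the minimal TRANSFAC layout Bio.motifs reads back."""
    with open(path, "w", encoding="utf-8") as fh:
        for pwm in pwms:
            # the strict Bio.motifs reader wants two spaces after each key
            fh.write(f"ID  {pwm.tf_id}\nBF  undefined\n")
            fh.write("P0      A      C      G      T\n")
            for pos in range(pwm.width):
                a, c, g, t = pwm.counts[pos]
                consensus = BASES[int(pwm.counts[pos].argmax())]
                fh.write(
                    f"{pos + 1:02d}  {a:6.2f} {c:6.2f} {g:6.2f} {t:6.2f}      {consensus}\n"
                )
            fh.write("XX\n//\n")


# ---------------------------------------------------------------------------
# Promoters
# ---------------------------------------------------------------------------

@dataclass
class PromoterSet:
    """Upstream promoter sequences keyed by (species, gene).

    Sequences use the alphabet {A, C, G, T, N} and are at most
    ``max_length`` (600 by default) bases long; shorter records are allowed.
    """

    records: dict
    max_length: int = PROMOTER_LENGTH

    def __post_init__(self):
        clean = {}
        for (species, gene), seq in self.records.items():
            seq = str(seq).upper()
            bad = set(seq) - set("ACGTN")
            if bad:
                raise ValidationError(
                    f"promoter ({species}, {gene}): invalid characters {sorted(bad)}"
                )
            if len(seq) > self.max_length:
                raise ValidationError(
                    f"promoter ({species}, {gene}): length {len(seq)} exceeds "
                    f"{self.max_length}"
                )
            clean[(str(species), str(gene))] = seq
        self.records = clean

    @property
    def species_ids(self) -> list:
        return sorted({s for s, _ in self.records})

    @property
    def gene_ids(self) -> list:
        return sorted({g for _, g in self.records})

    def sequences_for_species(self, species: str) -> list:
        return [seq for (s, _), seq in sorted(self.records.items()) if s == species]

    def __len__(self) -> int:
        return len(self.records)


def read_promoters(path, max_length: int = PROMOTER_LENGTH) -> PromoterSet:
    """Read promoters from FASTA with ``species|gene`` headers."""
    records = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if "|" not in rec.id:
            raise ParseError(
                f"promoter header {rec.id!r} is not of the form 'species|gene'"
            )
        species, gene = rec.id.split("|", 1)
        key = (species, gene)
        if key in records:
            raise ValidationError(f"duplicate promoter record for {key}")
        records[key] = str(rec.seq)
    if not records:
        raise ParseError(f"{Path(path).name}: no FASTA records")
    return PromoterSet(records, max_length=max_length)


def write_promoters(promoters: PromoterSet, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for (species, gene), seq in sorted(promoters.records.items()):
            fh.write(f">{species}|{gene}\n")
            for i in range(0, len(seq), 70):
                fh.write(seq[i:i + 70] + "\n")


def base_composition(sequences) -> np.ndarray:
    """A/C/G/T frequencies pooled over sequences (N ignored; uniform if empty)."""
    counts = np.zeros(4)
    for seq in sequences:
        for ch, i in _BASE_INDEX.items():
            counts[i] += seq.count(ch)
    total = counts.sum()
    if total == 0:
        return UNIFORM_BACKGROUND.copy()
    return counts / total


# ---------------------------------------------------------------------------
# Occupancy model
# ---------------------------------------------------------------------------

def _encode(seq: str) -> np.ndarray:
    arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    out = np.full(arr.size, -1, dtype=np.int64)
    for ch, i in _BASE_INDEX.items():
        out[arr == ord(ch)] = i
    return out


def site_probability(pwm: PWMatrix, window: str, background=None,
                     prior: float = DEFAULT_PRIOR,
                     pseudocount: float = DEFAULT_PSEUDOCOUNT) -> float:
    """Posterior binding probability of a single window.

    Windows containing a base outside {A, C, G, T} contribute 0.
    """
    window = window.upper()
    if len(window) != pwm.width:
        raise ValidationError(
            f"window length {len(window)} does not match PWM width {pwm.width}"
        )
    background = UNIFORM_BACKGROUND if background is None else np.asarray(background, float)
    if any(ch not in _BASE_INDEX for ch in window):
        return 0.0
    freqs = pwm.frequencies(pseudocount)
    ratio = 1.0
    for pos, ch in enumerate(window):
        b = _BASE_INDEX[ch]
        ratio *= freqs[pos, b] / background[b]
    return float(prior * ratio / (prior * ratio + (1.0 - prior)))


def _window_ratios(freqs, background, codes, width):
    """Likelihood ratios of all windows of one strand; NaN-free, N windows 0."""
    n = codes.size - width + 1
    windows = np.lib.stride_tricks.sliding_window_view(codes, width)
    valid = np.all(windows >= 0, axis=1)
    ratios = np.ones(n)
    safe = np.where(windows >= 0, windows, 0)
    F = freqs / background  # (width, 4)
    for j in range(width):
        ratios *= F[j, safe[:, j]]
    ratios[~valid] = 0.0
    return ratios


def occupancy_probability(pwm: PWMatrix, promoter: str, background=None,
                          prior: float = DEFAULT_PRIOR,
                          pseudocount: float = DEFAULT_PSEUDOCOUNT) -> float:
    """Probability of at least one binding event anywhere in the promoter.

    Scans every window on both strands; promoters shorter than the PWM have
    occupancy 0 (with a warning).  Monotone non-decreasing in promoter
    length and invariant under reverse complement.
    """
    promoter = promoter.upper()
    background = UNIFORM_BACKGROUND if background is None else np.asarray(background, float)
    if len(promoter) < pwm.width:
        warnings.warn(
            f"promoter shorter than PWM {pwm.tf_id!r} ({len(promoter)} < {pwm.width}); "
            f"occupancy is 0",
            stacklevel=2,
        )
        return 0.0
    freqs = pwm.frequencies(pseudocount)
    fwd = _encode(promoter)
    rev = _encode(str(Seq(promoter).reverse_complement()))
    no_bind = 1.0
    for codes in (fwd, rev):
        ratios = _window_ratios(freqs, background, codes, pwm.width)
        q = prior * ratios / (prior * ratios + (1.0 - prior))
        no_bind *= float(np.prod(1.0 - q))
    return float(1.0 - no_bind)


def build_tensor(pwms, promoters: PromoterSet, background=None,
                 prior: float = DEFAULT_PRIOR,
                 pseudocount: float = DEFAULT_PSEUDOCOUNT) -> BindingTensor:
    """Occupancy probabilities for every factor x gene x species.

    (gene, species) pairs without a promoter record become missing
    orthologs.  Unless an explicit ``background`` (4-vector) is given, each
    species' background is its own pooled promoter base composition.
    Probabilities are rounded to eight decimal digits on export.
    """
    pwms = list(pwms)
    _check_unique([p.tf_id for p in pwms], "PWM ids")
    species = promoters.species_ids
    genes = promoters.gene_ids
    tf_ids = [p.tf_id for p in pwms]

    backgrounds = {}
    for s in species:
        if background is not None:
            backgrounds[s] = np.asarray(background, float)
        else:
            backgrounds[s] = base_composition(promoters.sequences_for_species(s))

    P = np.full((len(pwms), len(genes), len(species)), np.nan)
    present = np.zeros((len(genes), len(species)), dtype=bool)
    gi = {g: i for i, g in enumerate(genes)}
    si = {s: i for i, s in enumerate(species)}
    for (s, g), seq in promoters.records.items():
        present[gi[g], si[s]] = True
        for ti, pwm in enumerate(pwms):
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                occ = occupancy_probability(pwm, seq, backgrounds[s],
                                            prior=prior, pseudocount=pseudocount)
            P[ti, gi[g], si[s]] = round8(occ)
    return BindingTensor(tf_ids, genes, species, P, present)
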