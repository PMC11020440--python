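"""Evolutionary features computed from a multiple sequence alignment.

This module reads alignments (aligned FASTA or A3M), builds regularized
amino-acid frequency models, and computes the three per-variant
evolutionary scores that do not require a coevolutionary model:

* the Conservation Index (CI) — the Euclidean distance between a
  column's regularized frequency vector and the alignment-wide one,
  taken over the 20 standard amino acids;
* the log-odds ratio (LOR) — the difference of logits between the
  mutant and wild-type regularized column frequencies;
* a PROVEAN-style delta-alignment score (PVS) — the mean change in
  substitution-matrix score of the variant against the aligned
  homologs, reusing the existing pairwise alignments rather than
  realigning per variant.

Frequencies are counted over 21 states (20 amino acids + gap) with a
pseudocount ``theta`` (default 0.01) splitting probability mass evenly
across states; the CI sum runs over the 20 amino acids only.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import NamedTuple

import numpy as np
from Bio import SeqIO
from Bio.Align import substitution_matrices

from .alphabet import (
    ALPHABET,
    AMINO_ACIDS,
    GAP,
    GAP_INDEX,
    N_STATES,
    THREE_TO_ONE,
    decode_sequence,
    encode_char,
    encode_sequence,
    is_standard_aa,
)

__all__ = [
    "MSA",
    "Variant",
    "parse_variant",
    "FrequencyModel",
    "SubstitutionMatrix",
    "FlaggedScore",
    "AlignmentFormatError",
    "read_alignment",
    "write_alignment",
    "regularized_frequencies",
    "conservation_index",
    "conservation_profile",
    "log_odds_ratio",
    "provean_score",
]

DEFAULT_THETA = 0.01


class AlignmentFormatError(ValueError):
    """Raised when an alignment file cannot be parsed into a valid MSA."""


class FlaggedScore(NamedTuple):
    """A score together with a coverage flag.

    ``defined`` is False when the score could not be computed from data
    (e.g. no homolog covers the variant column) and the value defaults
    to 0.0 by convention.
    """

    value: float
    defined: bool


@dataclass(frozen=True)
class Variant:
    """A single amino-acid substitution in 1-based query coordinates."""

    position: int
    wt: str
    mt: str

    def __post_init__(self) -> None:
        if self.position < 1:
            raise ValueError(f"variant position must be >= 1, got {self.position}")
        for label, aa in (("wild-type", self.wt), ("mutant", self.mt)):
            if not is_standard_aa(aa):
                raise ValueError(f"{label} residue {aa!r} is not a standard amino acid")

    def __str__(self) -> str:
        return f"{self.wt}{self.position}{self.mt}"


_VARIANT_SHORT = re.compile(r"^([A-Za-z])(\d+)([A-Za-z])$")
_VARIANT_HGVS = re.compile(r"^(?:p\.)?([A-Z][a-z]{2})(\d+)([A-Z][a-z]{2})$")


def parse_variant(key: str) -> Variant:
    """Parse a variant key such as ``"A123V"`` or ``"p.Ala123Val"``.

    Both styles normalize to the same :class:`Variant`.
    """
    key = key.strip()
    m = _VARIANT_SHORT.match(key)
    if m:
        return Variant(int(m.group(2)), m.group(1).upper(), m.group(3).upper())
    m = _VARIANT_HGVS.match(key)
    if m:
        try:
            wt = THREE_TO_ONE[m.group(1).upper()]
            mt = THREE_TO_ONE[m.group(3).upper()]
        except KeyError as exc:
            raise ValueError(f"unknown residue code in variant key {key!r}") from exc
        return Variant(int(m.group(2)), wt, mt)
    raise ValueError(f"cannot parse variant key {key!r}")


@dataclass(frozen=True)
class MSA:
    """A multiple sequence alignment with the query as row 0.

    Rows are stored as an ``m x N`` int8 matrix over the 21-state
    alphabet.  Nonstandard residues have already been canonicalized to
    the gap state.  Query positions are 1-based indices into the
    *ungapped* query sequence; ``column_of`` maps them to alignment
    columns.
    """

    ids: tuple[str, ...]
    codes: np.ndarray  # shape (m, N), int8 state indices

    def __post_init__(self) -> None:
        codes = np.asarray(self.codes, dtype=np.int8)
        if codes.ndim != 2 or codes.shape[0] < 1 or codes.shape[1] < 1:
            raise AlignmentFormatError("alignment must have at least one row and one column")
        if len(self.ids) != codes.shape[0]:
            raise AlignmentFormatError("number of ids does not match number of rows")
        if codes.min() < 0 or codes.max() >= N_STATES:
            raise AlignmentFormatError("alignment contains out-of-alphabet states")
        object.__setattr__(self, "codes", codes)
        # columns where the query is not a gap, in order
        qcols = np.flatnonzero(codes[0] != GAP_INDEX)
        object.__setattr__(self, "_query_cols", qcols)

    @property
    def m(self) -> int:
        """Alignment depth (number of rows, query included)."""
        return self.codes.shape[0]

    @property
    def N(self) -> int:
        """Alignment length (number of columns)."""
        return self.codes.shape[1]

    @property
    def query_id(self) -> str:
        return self.ids[0]

    @property
    def query_length(self) -> int:
        """Length of the ungapped query sequence."""
        return len(self._query_cols)

    def row(self, k: int) -> str:
        """Aligned row ``k`` as a string."""
        return decode_sequence(self.codes[k])

    @property
    def rows(self) -> list[str]:
        return [self.row(k) for k in range(self.m)]

    @property
    def query_sequence(self) -> str:
        """The ungapped query sequence."""
        return decode_sequence(self.codes[0, self._query_cols])

    def column_of(self, position: int) -> int:
        """Alignment column (0-based) of a 1-based query position."""
        if not 1 <= position <= self.query_length:
            raise IndexError(
                f"query position {position} out of range 1..{self.query_length}"
            )
        return int(self._query_cols[position - 1])

    def check_variant(self, variant: Variant) -> int:
        """Validate ``variant`` against the query and return its column.

        A mismatch between the declared wild-type residue and the query
        sequence is an error: silent coordinate drift is the classic
        variant-annotation bug.
        """
        col = self.column_of(variant.position)
        actual = ALPHABET[int(self.codes[0, col])]
        if actual != variant.wt:
            raise ValueError(
                f"variant {variant} conflicts with query: residue at position "
                f"{variant.position} is {actual!r}, not {variant.wt!r}"
            )
        return col


def _parse_a3m_row(seq: str) -> str:
    """Drop lowercase insertion states from an A3M row."""
    return "".join(c for c in seq if not c.islower())


def read_alignment(path: str | Path, format: str = "aligned-fasta") -> MSA:
    """Read an alignment file into an :class:`MSA`.

    Parameters
    ----------
    path:
        Path to the alignment file.
    format:
        ``"aligned-fasta"`` for a FASTA file whose records are already
        padded to equal length, or ``"a3m"`` for the A3M dialect in
        which lowercase letters mark insertions relative to the query.
        A3M insertion columns are removed so that every row has the
        query's column count; features are defined per query position,
        so insertion states carry no usable signal here.

    Unknown residue codes canonicalize to the gap state.  Row order is
    preserved and row 0 is taken as the query.
    """
    if format not in ("aligned-fasta", "a3m"):
        raise ValueError(f"unknown alignment format {format!r}")
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise AlignmentFormatError(f"no sequences found in {path}")
    ids = tuple(r.id for r in records)
    raw = [str(r.seq) for r in records]
    if format == "a3m":
        raw = [_parse_a3m_row(s) for s in raw]
    lengths = {len(s) for s in raw}
    if len(lengths) != 1:
        raise AlignmentFormatError(
            f"ragged alignment in {path}: row lengths {sorted(lengths)}"
        )
    codes = np.vstack([encode_sequence(s) for s in raw])
    return MSA(ids=ids, codes=codes)


def write_alignment(msa: MSA, path: str | Path, format: str = "aligned-fasta") -> None:
    """Write an :class:`MSA` as aligned FASTA (A3M without insertions
    is identical, so one writer serves both)."""
    with open(path, "w") as fh:
        for name, row in zip(msa.ids, msa.rows):
            fh.write(f">{name}\n{row}\n")


# ---------------------------------------------------------------------------
# Regularized frequencies and frequency-based scores
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class FrequencyModel:
    """Regularized per-column and alignment-wide amino-acid frequencies.

    With raw counts ``c_i(a)`` (column) and ``c(a)`` (whole alignment),
    depth ``m`` and length ``N``::

        f_i(a) = c_i(a)/m       * (1 - theta) + theta/21
        f(a)   = c(a)/(m * N)   * (1 - theta) + theta/21

    The gap is counted as the 21st state; every frequency is at least
    ``theta/21`` and each column's 21 frequencies sum to 1.
    """

    theta: float
    f_col: np.ndarray      # (N, 21)
    f_global: np.ndarray   # (21,)
    c_col: np.ndarray      # (N, 21) raw counts
    c_global: np.ndarray   # (21,)
    msa: MSA = field(repr=False)

    @property
    def N(self) -> int:
        return self.f_col.shape[0]


def regularized_frequencies(msa: MSA, theta: float = DEFAULT_THETA) -> FrequencyModel:
    """Count state occurrences and apply pseudocount regularization."""
    if not 0.0 <= theta <= 1.0:
        raise ValueError(f"theta must lie in [0, 1], got {theta}")
    m, N = msa.m, msa.N
    c_col = np.zeros((N, N_STATES), dtype=np.int64)
    for a in range(N_STATES):
        c_col[:, a] = (msa.codes == a).sum(axis=0)
    c_global = c_col.sum(axis=0)
    f_col = (c_col / m) * (1.0 - theta) + theta / N_STATES
    f_global = (c_global / (m * N)) * (1.0 - theta) + theta / N_STATES
    return FrequencyModel(
        theta=theta, f_col=f_col, f_global=f_global,
        c_col=c_col, c_global=c_global, msa=msa,
    )


def conservation_index(freq: FrequencyModel, column: int) -> float:
    """Conservation Index of one alignment column (0-based index).

    ``CI = sqrt( sum_a (f_i(a) - f(a))^2 )`` over the 20 standard amino
    acids; the gap state is excluded from the sum even though it is
    counted in the frequencies.
    """
    if not 0 <= column < freq.N:
        raise IndexError(f"column {column} out of range 0..{freq.N - 1}")
    d = freq.f_col[column, :GAP_INDEX] - freq.f_global[:GAP_INDEX]
    return float(np.sqrt(np.sum(d * d)))


def conservation_profile(freq: FrequencyModel) -> np.ndarray:
    """Conservation Index for every alignment column at once."""
    d = freq.f_col[:, :GAP_INDEX] - freq.f_global[np.newaxis, :GAP_INDEX]
    return np.sqrt(np.sum(d * d, axis=1))


def log_odds_ratio(freq: FrequencyModel, variant: Variant) -> float:
    """Log-odds ratio of the mutant versus wild-type column frequency.

    ``LOR = logit(f_i(mt)) - logit(f_i(wt))`` with natural-log logits,
    evaluated at the alignment column of the variant's query position.
    Positive values mean the mutant residue is more common at that
    position than the wild-type one.
    """
    col = freq.msa.check_variant(variant)
    f_wt = float(freq.f_col[col, encode_char(variant.wt)])
    f_mt = float(freq.f_col[col, encode_char(variant.mt)])
    for name, f in (("wild-type", f_wt), ("mutant", f_mt)):
        if not 0.0 < f < 1.0:
            raise ValueError(
                f"{name} frequency {f} is degenerate for the logit; "
                "use theta > 0 to regularize"
            )
    return float(np.log(f_mt / (1.0 - f_mt)) - np.log(f_wt / (1.0 - f_wt)))


# ---------------------------------------------------------------------------
# PROVEAN-style delta-alignment score
# ---------------------------------------------------------------------------


class SubstitutionMatrix:
    """A symmetric amino-acid substitution score table (BLOSUM62 by default)."""

    def __init__(self, name: str, scores: np.ndarray):
        scores = np.asarray(scores, dtype=float)
        if scores.shape != (20, 20):
            raise ValueError("substitution matrix must be 20x20 over the standard amino acids")
        if not np.allclose(scores, scores.T):
            raise ValueError("substitution matrix must be symmetric")
        self.name = name
        self._scores = scores

    @classmethod
    def from_name(cls, name: str = "BLOSUM62") -> "SubstitutionMatrix":
        """Load one of the matrices distributed with Biopython."""
        bio = substitution_matrices.load(name)
        return cls._from_biopython(name, bio)

    @classmethod
    def read_ncbi(cls, path: str | Path, name: str | None = None) -> "SubstitutionMatrix":
        """Read a matrix in NCBI text format."""
        with open(path) as fh:
            bio = substitution_matrices.read(fh)
        return cls._from_biopython(name or Path(path).stem, bio)

    @classmethod
    def _from_biopython(cls, name, bio) -> "SubstitutionMatrix":
        scores = np.empty((20, 20))
        for i, a in enumerate(AMINO_ACIDS):
            for j, b in enumerate(AMINO_ACIDS):
                scores[i, j] = bio[a, b]
        return cls(name, scores)

    def score(self, a: str, b: str) -> float:
        """Score of aligning residue ``a`` with residue ``b``."""
        ia, ib = AMINO_ACIDS.index(a), AMINO_ACIDS.index(b)
        return float(self._scores[ia, ib])

    def __repr__(self) -> str:
        return f"SubstitutionMatrix({self.name!r})"


def provean_score(
    msa: MSA,
    variant: Variant,
    matrix: SubstitutionMatrix | None = None,
) -> FlaggedScore:
    """PROVEAN-style delta-alignment score of a variant.

    For each homolog row whose state at the variant column is not a
    gap, the per-homolog delta is ``s(mt, h) - s(wt, h)`` where ``h``
    is the homolog residue at that column; the score is the unweighted
    mean of the deltas.  The pairwise alignments implicit in the MSA
    are reused as-is — variants are never realigned.  Clustering-based
    homolog weighting of the original PROVEAN is deliberately not
    reproduced (a documented simplification).

    When no homolog covers the column the score is 0 with
    ``defined=False``.
    """
    if matrix is None:
        matrix = SubstitutionMatrix.from_name("BLOSUM62")
    col = msa.check_variant(variant)
    deltas = []
    for k in range(1, msa.m):
        state = int(msa.codes[k, col])
        if state == GAP_INDEX:
            continue
        h = ALPHABET[state]
        deltas.append(matrix.score(variant.mt, h) - matrix.score(variant.wt, h))
    if not deltas:
        return FlaggedScore(0.0, False)
    return FlaggedScore(float(np.mean(deltas)), True)
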