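"""Per-column conservation statistics of a multiple sequence alignment.

Three per-position signals feed the range-based contact predictors:

* **VAR** — sequence variability, the number of distinct residue types
  observed in the column (optionally normalised by 20);
* **ENT** — Shannon entropy of the residue frequencies, in bits;
* **KOL** — a Kolmogorov-complexity estimate obtained by running a
  general-purpose lossless compressor over the column string and
  normalising by the compressed size of an equal-length incompressible
  reference, clipped to [0, 1].

Columns dominated by gaps carry little information; any column with fewer
than 50% ungapped symbols is flagged missing (NaN) and excluded from
downstream range selection.
"""

from __future__ import annotations

import lzma
import math
import zlib
from collections import Counter
from dataclasses import dataclass, field

import numpy as np
from Bio import AlignIO

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
GAP_CHARS = frozenset("-.")
UNKNOWN_CHARS = frozenset("XxBZJUO*")

#: fraction of a column that must be ungapped for its scores to be usable
MIN_UNGAPPED_FRACTION = 0.5


@dataclass(frozen=True)
class Alignment:
    """An aligned set of protein sequences (gap '-', unknown 'X')."""

    records: tuple[tuple[str, str], ...]

    def __post_init__(self) -> None:
        if len(self.records) < 2:
            raise ValueError(f"need >=2 sequences, got {len(self.records)}")
        length = len(self.records[0][1])
        if length < 1:
            raise ValueError("alignment has zero columns")
        for name, seq in self.records:
            if len(seq) != length:
                raise ValueError(
                    f"ragged alignment: record {name!r} has length "
                    f"{len(seq)}, expected {length}"
                )

    @property
    def length(self) -> int:
        return len(self.records[0][1])

    @property
    def n_sequences(self) -> int:
        return len(self.records)

    def column(self, pos: int) -> str:
        """Column string at 1-based position ``pos``."""
        if not 1 <= pos <= self.length:
            raise IndexError(f"position {pos} outside 1..{self.length}")
        return "".join(seq[pos - 1] for _, seq in self.records)


@dataclass(frozen=True)
class ColumnProfile:
    """Residue counts of one alignment column, gaps and unknowns excluded."""

    position: int
    counts: dict[str, int]
    n_ungapped: int


@dataclass(frozen=True)
class CompressorConfig:
    """Compressor behind the KOL estimator; recorded in all outputs."""

    name: str = "zlib"
    level: int = 9
    reference_seed: int = 745113

    def compress_len(self, data: bytes) -> int:
        if self.name == "zlib":
            return len(zlib.compress(data, self.level))
        if self.name == "lzma":
            return len(lzma.compress(data, preset=self.level))
        raise ValueError(f"unknown compressor {self.name!r}")

    def describe(self) -> str:
        return f"{self.name}-level{self.level}-refseed{self.reference_seed}"


@dataclass
class ColumnScores:
    """Arrays of per-column scores; NaN marks flagged-missing columns."""

    var: np.ndarray
    ent: np.ndarray
    kol: np.ndarray
    n_ungapped: np.ndarray
    compressor: CompressorConfig = field(default_factory=CompressorConfig)

    def __len__(self) -> int:
        return len(self.ent)


def read_alignment(path) -> Alignment:
    """Read an aligned-FASTA file into an :class:`Alignment`.

    Raises ``ValueError`` on an empty file, fewer than two records or
    ragged record lengths (Biopython raises for the latter; we re-check so
    the offending record is named).
    """
    try:
        msa = AlignIO.read(str(path), "fasta")
    except ValueError as exc:
        # Biopython's error for ragged input is unspecific; re-parse
        # record-by-record to name the culprit.
        from Bio import SeqIO

        records = [(r.id, str(r.seq).upper()) for r in SeqIO.parse(str(path), "fasta")]
        if not records:
            raise ValueError(f"no FASTA records in {path}") from exc
        return Alignment(tuple(records))
    records = tuple((r.id, str(r.seq).upper()) for r in msa)
    return Alignment(records)


def column_profile(aln: Alignment, pos: int) -> ColumnProfile:
    """Count residue occurrences in column ``pos`` (1-based), skipping
    gaps and unknown symbols."""
    col = aln.column(pos)
    counts = Counter(
        c for c in col if c not in GAP_CHARS and c not in UNKNOWN_CHARS
    )
    return ColumnProfile(pos, dict(counts), sum(counts.values()))


def shannon_entropy(profile: ColumnProfile) -> float:
    """Shannon entropy in bits of the column's residue frequencies.

    An all-gap column has no distribution to measure: returns NaN.
    """
    n = profile.n_ungapped
    if n == 0:
        return math.nan
    h = -sum(
        (c / n) * math.log2(c / n) for c in profile.counts.values() if c > 0
    )
    return h + 0.0  # normalise IEEE -0.0 for single-type columns


def variability(profile: ColumnProfile, normalized: bool = False) -> float:
    """Number of distinct residue types in the column.

    With ``normalized=True`` the count is divided by 20 so the score lives
    on [0, 1]. All-gap columns return NaN.
    """
    if profile.n_ungapped == 0:
        return math.nan
    k = len(profile.counts)
    return k / 20.0 if normalized else float(k)


def kolmogorov_score(
    aln: Alignment,
    pos: int,
    compressor: CompressorConfig | None = None,
) -> float:
    """Compressibility of column ``pos``: compressed size of the ungapped
    column string over the compressed size of an equal-length
    incompressible reference, clipped to [0, 1].

    Constant columns compress well and score low; maximally mixed columns
    approach 1. The estimate is deterministic for a fixed
    :class:`CompressorConfig`. Columns with fewer than two ungapped
    symbols are flagged missing (NaN).
    """
    compressor = compressor or CompressorConfig()
    col = aln.column(pos)
    stripped = "".join(
        c for c in col if c not in GAP_CHARS and c not in UNKNOWN_CHARS
    )
    if len(stripped) < 2:
        return math.nan
    size = compressor.compress_len(stripped.encode("ascii"))
    ref = _reference_string(len(stripped), compressor.reference_seed)
    ref_size = compressor.compress_len(ref)
    return min(1.0, max(0.0, size / ref_size))


def _reference_string(n: int, seed: int) -> bytes:
    """Pseudo-random residue string of length ``n``; the incompressible
    yardstick for the KOL ratio."""
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, 20, size=n)
    return bytes(ord(AMINO_ACIDS[i]) for i in idx)


def compute_column_scores(
    aln: Alignment,
    compressor: CompressorConfig | None = None,
    normalized_var: bool = False,
) -> ColumnScores:
    """VAR/ENT/KOL for every column of ``aln``.

    Columns with less than :data:`MIN_UNGAPPED_FRACTION` ungapped symbols
    are NaN across all three scores.
    """
    compressor = compressor or CompressorConfig()
    n_cols = aln.length
    var = np.full(n_cols, np.nan)
    ent = np.full(n_cols, np.nan)
    kol = np.full(n_cols, np.nan)
    n_ungapped = np.zeros(n_cols, dtype=int)
    for i in range(1, n_cols + 1):
        prof = column_profile(aln, i)
        n_ungapped[i - 1] = prof.n_ungapped
        if prof.n_ungapped < MIN_UNGAPPED_FRACTION * aln.n_sequences:
            continue
        var[i - 1] = variability(prof, normalized=normalized_var)
        ent[i - 1] = shannon_entropy(prof)
        kol[i - 1] = kolmogorov_score(aln, i, compressor)
    return ColumnScores(var, ent, kol, n_ungapped, compressor)


def write_column_scores(scores: ColumnScores, path) -> None:
    """TSV dump: one row per column; header records the compressor."""
    with open(path, "w") as fh:
        fh.write(f"# compressor={scores.compressor.describe()}\n")
        fh.write("position\tvar\tent\tkol\tn_ungapped\n")
        for i in range(len(scores)):
            fh.write(
                f"{i + 1}\t{scores.var[i]:.4f}\t{scores.ent[i]:.4f}\t"
                f"{scores.kol[i]:.4f}\t{scores.n_ungapped[i]}\n"
            )
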