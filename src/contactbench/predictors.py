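"""Build candidate contact-pair sets from the available signals.

Three families of predictor are supported:

* range-based (KOL, VRN/ENT): positions whose per-column conservation
  score falls inside a calibrated band [center ± half-width] are declared
  candidate contact participants, and every unordered pair among them is
  predicted — the simplest pairing rule consistent with conserved core
  positions sharing a conservation band;
* matrix-based (SVB): a symmetric 20×20 residue-type-pair likelihood
  matrix thresholded over the target sequence;
* external (CMA-, P2P-style): pair lists produced elsewhere, read from
  plain two/three-column text.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np

from .msa_stats import AMINO_ACIDS

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class ScoreRange:
    """A score band [center - half_width, center + half_width]."""

    center: float
    half_width: float = 0.05

    def __post_init__(self) -> None:
        if self.half_width <= 0:
            raise ValueError("half_width must be positive")

    def __contains__(self, value: float) -> bool:
        return (
            not math.isnan(value)
            and self.center - self.half_width <= value <= self.center + self.half_width
        )


@dataclass(frozen=True)
class PredictionSet:
    """Unordered residue pairs (1-based, i<j) proposed by one method."""

    method: str
    pairs: frozenset[tuple[int, int]]
    provenance: str = ""

    def __len__(self) -> int:
        return len(self.pairs)


class SvbMatrix:
    """Symmetric residue-type-pair contact likelihood matrix."""

    def __init__(self, values: dict[tuple[str, str], float]):
        self._values: dict[tuple[str, str], float] = {}
        for (a, b), v in values.items():
            if not np.isfinite(v):
                raise ValueError(f"non-finite likelihood for pair ({a}, {b})")
            mirror = values.get((b, a))
            if a != b and mirror is not None and mirror != v:
                raise ValueError(
                    f"asymmetric likelihoods for ({a}, {b}): {v} vs {mirror}"
                )
            self._values[(a, b)] = float(v)
            self._values[(b, a)] = float(v)
        missing = [
            (a, b)
            for a in AMINO_ACIDS
            for b in AMINO_ACIDS
            if (a, b) not in self._values
        ]
        if missing:
            raise ValueError(
                f"likelihood matrix incomplete; missing {len(missing)} "
                f"pairs, e.g. {missing[:3]}"
            )

    def __getitem__(self, pair: tuple[str, str]) -> float:
        return self._values[pair]

    @property
    def min(self) -> float:
        return min(self._values.values())

    @property
    def max(self) -> float:
        return max(self._values.values())


def read_svb_matrix(path) -> SvbMatrix:
    """Read a 20×20 likelihood table: header row of residue letters, then
    one row per residue letter."""
    with open(path) as fh:
        lines = [ln.split() for ln in fh if ln.strip() and not ln.startswith("#")]
    header = lines[0]
    values = {}
    for row in lines[1:]:
        a = row[0]
        for b, v in zip(header, row[1:]):
            values[(a.upper(), b.upper())] = float(v)
    return SvbMatrix(values)


def select_positions(scores, score_range: ScoreRange) -> set[int]:
    """1-based positions whose score lies inside the band; NaN (missing)
    scores never match. Accepts a sequence or array of per-column scores."""
    selected = {
        i + 1 for i, s in enumerate(np.asarray(scores, dtype=float)) if s in score_range
    }
    if not selected:
        log.info("range %s selected no positions", score_range)
    return selected


def pairs_from_selection(
    selected: set[int], method: str = "other", provenance: str = ""
) -> PredictionSet:
    """All unordered pairs over the selected positions (C(k,2) pairs)."""
    pairs = frozenset(combinations(sorted(selected), 2))
    return PredictionSet(method, pairs, provenance)


def range_predict(
    scores, score_range: ScoreRange, method: str = "other"
) -> PredictionSet:
    """Range selection followed by all-pairs expansion."""
    sel = select_positions(scores, score_range)
    return pairs_from_selection(
        sel,
        method,
        f"range {score_range.center:g}±{score_range.half_width:g}, "
        f"{len(sel)} positions",
    )


def svb_predict(
    sequence: str, matrix: SvbMatrix, threshold: float, method: str = "SVB"
) -> PredictionSet:
    """Pairs (i, j) whose residue-type likelihood meets the threshold.

    Sequence letters outside the 20 standard types are skipped with a
    warning and can never appear in a predicted pair.
    """
    valid = {}
    for i, aa in enumerate(sequence.upper(), start=1):
        if aa in AMINO_ACIDS:
            valid[i] = aa
        else:
            log.warning("position %d has non-standard residue %r; skipped", i, aa)
    pairs = frozenset(
        (i, j)
        for i, j in combinations(sorted(valid), 2)
        if matrix[valid[i], valid[j]] >= threshold
    )
    return PredictionSet(method, pairs, f"svb threshold {threshold:g}")


def read_external_predictions(path, top_k="all", method: str = "other") -> PredictionSet:
    """Read an externally produced pair list: whitespace/comma-delimited
    lines ``i j [score]`` with 1-based indices.

    Pairs are normalised to i<j and de-duplicated (highest score kept).
    With a numeric ``top_k`` and scores present, only the k best-scoring
    pairs are retained, ties broken by (i, j) lexicographic order.
    Self-pairs are skipped with a warning; a non-integer index is a hard
    error naming the line.
    """
    scored: dict[tuple[int, int], float] = {}
    n_lines = 0
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.replace(",", " ").strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split()
            try:
                i, j = int(fields[0]), int(fields[1])
            except (ValueError, IndexError) as exc:
                raise ValueError(
                    f"{path}:{lineno}: expected 'i j [score]', got {raw!r}"
                ) from exc
            if i == j:
                log.warning("%s:%d: self-pair (%d, %d) skipped", path, lineno, i, j)
                continue
            score = float(fields[2]) if len(fields) > 2 else math.nan
            key = (min(i, j), max(i, j))
            if key not in scored or (
                not math.isnan(score)
                and (math.isnan(scored[key]) or score > scored[key])
            ):
                scored[key] = score
            n_lines += 1
    if top_k != "all":
        k = int(top_k)
        ranked = sorted(
            scored.items(),
            key=lambda kv: (-(kv[1] if not math.isnan(kv[1]) else -math.inf), kv[0]),
        )
        scored = dict(ranked[:k])
    return PredictionSet(
        method,
        frozenset(scored),
        f"read {n_lines} lines from {path}, top_k={top_k}",
    )
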