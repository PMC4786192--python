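"""Score predicted contact pairs against structure-derived contact maps.

For a fixed prediction set evaluated against the contact map at one
cutoff, the confusion counts over the full pair universe (all n(n-1)/2
unordered pairs) give four summary statistics:

    MCC   = (TP·TN − FP·FN) / sqrt((TP+FP)(TP+FN)(TN+FP)(TN+FN))
    ACCY  = (TN − TP) / (TP+FP+FN+TN)        (reported convention)
    PREC  = TP / (TP+FP)
    SENSY = TP / (TP+FN)

ACCY above follows the convention of the benchmark tables this package
reproduces; the standard (TP+TN)/total accuracy is computed alongside as
``accy_std``. A method's *characteristic contact distance* is the cutoff
at which its MCC peaks; scanning the cutoff ladder and extracting that
peak is the central measurement here.

Chance-level signal is removed by subtracting the mean metric of
equally-sized uniformly random prediction sets (the RND correction).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .predictors import PredictionSet, ScoreRange, range_predict
from .structure_contacts import (
    CUTOFF_LADDER,
    ContactMap,
    DistanceMatrix,
    contact_map,
)

log = logging.getLogger(__name__)

METRIC_NAMES = ("mcc", "accy", "accy_std", "prec", "sensy")


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    fn: int
    tn: int

    @property
    def universe(self) -> int:
        return self.tp + self.fp + self.fn + self.tn


def confusion(pred: PredictionSet, cm: ContactMap) -> ConfusionCounts:
    """TP/FP/FN/TN of a prediction set against one contact map.

    Prediction indices must lie within 1..n_residues; out-of-range pairs
    are a hard error (they would silently deflate TN otherwise).
    """
    n = cm.n_residues
    bad = [p for p in pred.pairs if not (1 <= p[0] < p[1] <= n)]
    if bad:
        raise ValueError(
            f"{len(bad)} predicted pairs outside residue range 1..{n}: "
            f"{sorted(bad)[:5]}"
        )
    tp = len(pred.pairs & cm.contacts)
    fp = len(pred.pairs) - tp
    fn = len(cm.contacts) - tp
    tn = cm.universe_size - tp - fp - fn
    return ConfusionCounts(tp, fp, fn, tn)


def mcc(c: ConfusionCounts) -> float:
    """Matthews correlation coefficient; 0 by convention when any
    denominator factor is zero (logged)."""
    den = (
        (c.tp + c.fp) * (c.tp + c.fn) * (c.tn + c.fp) * (c.tn + c.fn)
    )
    if den == 0:
        log.debug("MCC denominator zero for %s; returning 0", c)
        return 0.0
    return (c.tp * c.tn - c.fp * c.fn) / math.sqrt(den)


def accuracy_paper(c: ConfusionCounts) -> float:
    """(TN − TP) / universe — the reported-table accuracy convention."""
    return (c.tn - c.tp) / c.universe


def accuracy_standard(c: ConfusionCounts) -> float:
    """(TP + TN) / universe — the textbook accuracy."""
    return (c.tp + c.tn) / c.universe


def precision(c: ConfusionCounts) -> float:
    """TP/(TP+FP); undefined (no positives predicted) reports 0.0."""
    return c.tp / (c.tp + c.fp) if c.tp + c.fp else 0.0


def sensitivity(c: ConfusionCounts) -> float:
    """TP/(TP+FN); undefined (no actual contacts) reports 0.0."""
    return c.tp / (c.tp + c.fn) if c.tp + c.fn else 0.0


def compute_metrics(c: ConfusionCounts) -> dict[str, float]:
    return {
        "mcc": mcc(c),
        "accy": accuracy_paper(c),
        "accy_std": accuracy_standard(c),
        "prec": precision(c),
        "sensy": sensitivity(c),
    }


def random_baseline(
    cm: ContactMap, k: int, n_reps: int = 100, seed: int = 0
) -> dict[str, float]:
    """Mean metrics of ``n_reps`` uniformly random k-pair prediction sets.

    Each replicate draws k distinct pairs from the universe without
    replacement; TP then follows the hypergeometric law with mean
    k·|contacts|/|universe|. Fully reproducible from ``seed``.
    """
    universe = cm.universe_size
    if not 0 <= k <= universe:
        raise ValueError(f"k={k} outside 0..{universe}")
    if n_reps < 1:
        raise ValueError("n_reps must be >=1")
    rng = np.random.default_rng(seed)
    # linearised upper-triangle index of each contact pair
    n = cm.n_residues
    contact_flags = np.zeros(universe, dtype=bool)
    for i, j in cm.contacts:
        contact_flags[_pair_index(i, j, n)] = True
    n_contacts = int(contact_flags.sum())
    sums = dict.fromkeys(METRIC_NAMES, 0.0)
    for _ in range(n_reps):
        draw = rng.choice(universe, size=k, replace=False)
        tp = int(contact_flags[draw].sum())
        c = ConfusionCounts(tp, k - tp, n_contacts - tp, universe - k - n_contacts + tp)
        for name, value in compute_metrics(c).items():
            sums[name] += value
    return {name: s / n_reps for name, s in sums.items()}


def _pair_index(i: int, j: int, n: int) -> int:
    """Row-major upper-triangle linear index of 1-based pair (i, j)."""
    i0, j0 = i - 1, j - 1
    return i0 * n - i0 * (i0 + 1) // 2 + (j0 - i0 - 1)


def corrected(value: float, baseline_mean: float) -> float:
    """RND correction: metric minus its random-baseline mean."""
    return value - baseline_mean


@dataclass
class MetricRecord:
    """One row of a cutoff scan: counts, metrics and RND-corrected metrics."""

    cutoff: float
    counts: ConfusionCounts
    metrics: dict[str, float]
    baseline: dict[str, float] | None = None
    rnd_meta: dict | None = None

    @property
    def mcc(self) -> float:
        return self.metrics["mcc"]

    @property
    def mcc_corr(self) -> float | None:
        if self.baseline is None:
            return None
        return corrected(self.metrics["mcc"], self.baseline["mcc"])

    def corrected_metrics(self) -> dict[str, float] | None:
        if self.baseline is None:
            return None
        return {
            name: corrected(self.metrics[name], self.baseline[name])
            for name in METRIC_NAMES
        }


@dataclass
class CutoffScan:
    """Metrics of one method across the cutoff ladder."""

    method: str
    records: list[MetricRecord] = field(default_factory=list)

    @property
    def cutoffs(self) -> np.ndarray:
        return np.array([r.cutoff for r in self.records])

    @property
    def mccs(self) -> np.ndarray:
        return np.array([r.mcc for r in self.records])


@dataclass(frozen=True)
class PeakSummary:
    """Characteristic contact distance(s) extracted from an MCC profile."""

    primary_peak: float
    primary_mcc: float
    secondary_peaks: tuple[float, ...]
    erratic: bool


def metric_scan(
    pred: PredictionSet,
    dm: DistanceMatrix,
    ladder: tuple[float, ...] = CUTOFF_LADDER,
    rnd_reps: int = 100,
    seed: int | None = None,
) -> CutoffScan:
    """Evaluate one (fixed) prediction set at every ladder cutoff.

    With ``seed`` given, each record also carries the RND baseline (k
    matched to the prediction's pair count; means over ``rnd_reps``
    replicates) and hence corrected metrics.
    """
    if len(ladder) == 0 or any(b <= a for a, b in zip(ladder, ladder[1:])):
        raise ValueError("ladder must be non-empty and strictly increasing")
    scan = CutoffScan(pred.method)
    for idx, cutoff in enumerate(ladder):
        cm = contact_map(dm, cutoff)
        counts = confusion(pred, cm)
        baseline = rnd_meta = None
        if seed is not None:
            rep_seed = (seed + idx) % 2**31
            baseline = random_baseline(cm, len(pred.pairs), rnd_reps, rep_seed)
            rnd_meta = {"n_reps": rnd_reps, "seed": rep_seed, "k": len(pred.pairs)}
        scan.records.append(
            MetricRecord(cutoff, counts, compute_metrics(counts), baseline, rnd_meta)
        )
    return scan


@dataclass
class CalibrationResult:
    """Outcome of a score-range scan: per-cutoff optima and hit counts."""

    table: pd.DataFrame  # columns: center, hits, mcc_<cutoff>...
    per_cutoff_best: dict[float, float]
    agree: bool
    best_center: float


def calibrate_range(
    scores,
    dm: DistanceMatrix,
    centers,
    half_width: float = 0.05,
    calibration_cutoffs: tuple[float, ...] = (6.0, 10.0),
    method: str = "range",
) -> CalibrationResult:
    """Scan candidate band centers and find the one maximising MCC.

    At each center the band [center ± half_width] selects positions, all
    pairs among them are predicted, and the MCC is computed at each
    calibration cutoff. Reports the per-cutoff optimal centers, whether
    they agree, and the number of hits (predicted pairs) per center.
    Raises when every center selects nothing (grid misses the score
    scale).
    """
    centers = list(centers)
    if not centers:
        raise ValueError("empty center grid")
    maps = {c: contact_map(dm, c) for c in calibration_cutoffs}
    rows = []
    any_nonempty = False
    for center in centers:
        pred = range_predict(scores, ScoreRange(center, half_width), method)
        any_nonempty = any_nonempty or bool(pred.pairs)
        row = {"center": center, "hits": len(pred.pairs)}
        for cutoff, cm in maps.items():
            row[f"mcc_{cutoff:g}"] = mcc(confusion(pred, cm))
        rows.append(row)
    if not any_nonempty:
        raise ValueError(
            "every candidate center selected zero positions; widen the "
            "grid or the half-width to cover the score scale"
        )
    table = pd.DataFrame(rows)
    per_cutoff_best = {
        cutoff: float(table.loc[table[f"mcc_{cutoff:g}"].idxmax(), "center"])
        for cutoff in calibration_cutoffs
    }
    mean_mcc = table[[f"mcc_{c:g}" for c in calibration_cutoffs]].mean(axis=1)
    best_center = float(table.loc[mean_mcc.idxmax(), "center"])
    agree = len(set(per_cutoff_best.values())) == 1
    return CalibrationResult(table, per_cutoff_best, agree, best_center)


def find_peaks(
    scan: CutoffScan,
    erratic_mcc_floor: float = 0.10,
    secondary_fraction: float = 0.5,
) -> PeakSummary:
    """Extract the characteristic contact distance from an MCC profile.

    Primary peak: the cutoff with maximal MCC (ties go to the smaller
    cutoff). Secondary peaks: interior local maxima reaching at least
    ``secondary_fraction`` of the primary MCC. The scan is flagged
    erratic when the primary MCC is below the floor or the maximum sits
    on a ladder boundary — profiles where "characteristic distance" is
    not meaningful.
    """
    return find_peaks_from_values(
        scan.cutoffs, scan.mccs, erratic_mcc_floor, secondary_fraction
    )


def find_peaks_from_values(
    cutoffs,
    mccs,
    erratic_mcc_floor: float = 0.10,
    secondary_fraction: float = 0.5,
) -> PeakSummary:
    cutoffs = np.asarray(cutoffs, dtype=float)
    mccs = np.asarray(mccs, dtype=float)
    if len(cutoffs) != len(mccs) or len(cutoffs) == 0:
        raise ValueError("cutoffs and mccs must be equal-length, non-empty")
    primary_idx = int(np.argmax(mccs))  # argmax takes first of ties
    primary_mcc = float(mccs[primary_idx])
    secondary = tuple(
        float(cutoffs[i])
        for i in range(1, len(mccs) - 1)
        if i != primary_idx
        and mccs[i] >= mccs[i - 1]
        and mccs[i] >= mccs[i + 1]
        and primary_mcc > 0
        and mccs[i] >= secondary_fraction * primary_mcc
    )
    erratic = (
        primary_mcc < erratic_mcc_floor
        or primary_idx in (0, len(mccs) - 1)
    )
    return PeakSummary(float(cutoffs[primary_idx]), primary_mcc, secondary, erratic)


def scan_to_frame(scan: CutoffScan) -> pd.DataFrame:
    """Long-form table of a scan, one row per cutoff (benchmark layout)."""
    rows = []
    for r in scan.records:
        row = {
            "method": scan.method,
            "cutoff": r.cutoff,
            "tp": r.counts.tp,
            "fp": r.counts.fp,
            "fn": r.counts.fn,
            "tn": r.counts.tn,
            "mcc": round(r.metrics["mcc"], 4),
            "accy": round(r.metrics["accy"], 3),
            "accy_std": round(r.metrics["accy_std"], 3),
            "prec": round(r.metrics["prec"], 3),
            "sensy": round(r.metrics["sensy"], 3),
        }
        if r.baseline is not None:
            row["mcc_corr"] = round(r.mcc_corr, 4)
        rows.append(row)
    return pd.DataFrame(rows)


def write_metric_table(scan: CutoffScan, path, provenance: str = "") -> None:
    """TSV mirroring the benchmark table layout, with a provenance header."""
    df = scan_to_frame(scan)
    with open(path, "w") as fh:
        if provenance:
            for line in provenance.splitlines():
                fh.write(f"# {line}\n")
        df.to_csv(fh, sep="\t", index=False)
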