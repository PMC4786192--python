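"""Cross-method comparison: assemble metric profiles and run a PCA.

Observations are (protein, cutoff) cells; variables are the per-method
metric (typically RND-corrected MCC) plus the cutoff itself. A
correlation PCA (centered, unit-scaled — the variables live on different
scales) then shows which methods move together and how each relates to
the distance cutoff: methods whose loading is near-antiparallel to the
cutoff's lose signal as the contact definition loosens; methods
orthogonal to it are indifferent to the contact scale.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .evaluation import CutoffScan

log = logging.getLogger(__name__)


@dataclass
class PcaResult:
    loadings: pd.DataFrame  # component × variable
    scores: np.ndarray  # observation × component
    explained_variance_ratio: np.ndarray
    dropped: tuple[str, ...] = ()


def assemble_profiles(
    scans: dict[str, dict[str, CutoffScan]],
    metric: str = "mcc_corr",
) -> pd.DataFrame:
    """Long-format profile matrix from per-method, per-protein scans.

    ``scans[method][protein]`` is a :class:`CutoffScan`; all methods must
    share the cutoff ladder (hard error otherwise). Rows with any missing
    cell are dropped with a warning. Columns: one per method, plus
    ``cutoff``; index: (protein, cutoff).
    """
    methods = sorted(scans)
    if not methods:
        raise ValueError("no scans given")
    ladders = {
        m: tuple(scan.cutoffs.tolist())
        for m, per_protein in scans.items()
        for scan in per_protein.values()
    }
    if len(set(ladders.values())) > 1:
        raise ValueError(f"cutoff ladders differ across methods: {ladders}")
    cells: dict[tuple[str, float], dict[str, float]] = {}
    for m in methods:
        for protein, scan in scans[m].items():
            for r in scan.records:
                value = r.mcc_corr if metric == "mcc_corr" else r.metrics[metric]
                if value is None:
                    continue
                cells.setdefault((protein, r.cutoff), {})[m] = value
    rows = []
    for (protein, cutoff), values in sorted(cells.items()):
        if len(values) < len(methods):
            log.warning(
                "dropping (%s, %g): missing %s",
                protein,
                cutoff,
                sorted(set(methods) - set(values)),
            )
            continue
        rows.append({"protein": protein, "cutoff": cutoff, **values})
    df = pd.DataFrame(rows)
    return df.set_index("protein")[methods + ["cutoff"]].reset_index()


def pca(
    profiles: pd.DataFrame,
    n_components: int | None = None,
    scale: bool = True,
) -> PcaResult:
    """PCA of the profile matrix via SVD of the centered (and, by
    default, unit-scaled) data.

    Zero-variance columns are dropped with a warning. The sign of each
    component is fixed by forcing its largest-magnitude loading positive,
    making results deterministic.
    """
    numeric = profiles.select_dtypes(include=[np.number])
    std = numeric.std(ddof=1)
    dropped = tuple(std.index[std == 0])
    if dropped:
        log.warning("dropping zero-variance columns: %s", dropped)
        numeric = numeric.drop(columns=list(dropped))
        std = std.drop(list(dropped))
    x = numeric.to_numpy(dtype=float)
    x = x - x.mean(axis=0)
    if scale:
        x = x / std.to_numpy()
    u, s, vt = np.linalg.svd(x, full_matrices=False)
    # sign convention: largest-|loading| entry of each component positive
    for k in range(vt.shape[0]):
        j = int(np.argmax(np.abs(vt[k])))
        if vt[k, j] < 0:
            vt[k] *= -1
            u[:, k] *= -1
    evr = s**2 / (s**2).sum()
    if n_components is not None:
        u, s, vt, evr_out = u[:, :n_components], s[:n_components], vt[:n_components], evr[:n_components]
    else:
        evr_out = evr
    loadings = pd.DataFrame(
        vt,
        index=[f"PC{k + 1}" for k in range(vt.shape[0])],
        columns=numeric.columns,
    )
    return PcaResult(loadings, u * s, evr_out, dropped)


def loading_angle(result: PcaResult, var_a: str, var_b: str, n_components: int = 2) -> float:
    """Angle (degrees, in [0, 180]) between two variables' loading
    vectors in the leading-component plane."""
    a = result.loadings[var_a].to_numpy()[:n_components]
    b = result.loadings[var_b].to_numpy()[:n_components]
    cosang = float(a @ b / (np.linalg.norm(a) * np.linalg.norm(b)))
    return math_degrees(cosang)


def math_degrees(cosang: float) -> float:
    return float(np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0))))


def write_pca_tables(result: PcaResult, prefix) -> None:
    """TSV exports: loadings, scores, explained variance."""
    result.loadings.to_csv(f"{prefix}_loadings.tsv", sep="\t")
    pd.DataFrame(
        result.scores,
        columns=[f"PC{k + 1}" for k in range(result.scores.shape[1])],
    ).to_csv(f"{prefix}_scores.tsv", sep="\t", index=False)
    pd.DataFrame(
        {"component": [f"PC{k + 1}" for k in range(len(result.explained_variance_ratio))],
         "explained_variance_ratio": result.explained_variance_ratio}
    ).to_csv(f"{prefix}_variance.tsv", sep="\t", index=False)
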