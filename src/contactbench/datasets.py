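"""Bundled reference data.

The package ships the published benchmark grid for the α-lactalbumin
domain (PDB 1a4v, 123 residues): confusion counts and reported metrics
for five contact predictors (SVB, P2P, KOL, VRN, CMA) at nine CA–CA
cutoffs from 4 to 20 Å. It is the regression anchor for the metric
formulas and the peak-extraction rule.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

#: residue count of the 1a4v benchmark domain (universe = C(123, 2) = 7503)
BENCHMARK_N_RESIDUES = 123

BENCHMARK_METHODS = ("SVB", "P2P", "KOL", "VRN", "CMA")


def load_benchmark_1a4v() -> pd.DataFrame:
    """The 45-row benchmark grid: method, cutoff, tp/fp/fn/tn and the
    reported mcc/accy/prec/sensy/mcc_corr values."""
    ref = resources.files("contactbench").joinpath("data/benchmark_1a4v.tsv")
    with resources.as_file(ref) as path:
        return pd.read_csv(path, sep="\t")
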