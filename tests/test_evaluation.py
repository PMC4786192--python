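"""Confusion counts, metrics, RND correction, calibration and peaks."""

from itertools import combinations

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import contactbench as cb
from contactbench.evaluation import ConfusionCounts, scan_to_frame


def toy_map(n=20, cutoff=8.0, seed=3):
    rng = np.random.default_rng(seed)
    pts = rng.normal(scale=7, size=(n, 3))
    dm = cb.distance_matrix(cb.CoordinateSet(pts, tuple(range(1, n + 1))))
    return dm, cb.contact_map(dm, cutoff)


class TestConfusion:
    def test_perfect_predictor(self):
        _, cm = toy_map()
        pred = cb.PredictionSet("p", cm.contacts)
        c = cb.confusion(pred, cm)
        assert (c.fp, c.fn) == (0, 0) and c.tp == len(cm.contacts)

    def test_empty_predictor(self):
        _, cm = toy_map()
        c = cb.confusion(cb.PredictionSet("p", frozenset()), cm)
        assert (c.tp, c.fp) == (0, 0)
        assert c.fn == len(cm.contacts)
        assert c.tn == cm.universe_size - c.fn

    def test_matches_exhaustive_enumeration(self):
        """Counts equal a double loop over all 190 pairs of a 20-residue toy."""
        dm, cm = toy_map()
        rng = np.random.default_rng(9)
        pairs = frozenset(
            (i, j)
            for i, j in combinations(range(1, 21), 2)
            if rng.random() < 0.3
        )
        c = cb.confusion(cb.PredictionSet("p", pairs), cm)
        tp = fp = fn = tn = 0
        for i, j in combinations(range(1, 21), 2):
            predicted = (i, j) in pairs
            actual = dm.d[i - 1, j - 1] <= cm.cutoff
            tp += predicted and actual
            fp += predicted and not actual
            fn += actual and not predicted
            tn += not predicted and not actual
        assert (c.tp, c.fp, c.fn, c.tn) == (tp, fp, fn, tn)

    def test_out_of_range_pairs_rejected(self):
        _, cm = toy_map()
        with pytest.raises(ValueError, match="outside"):
            cb.confusion(cb.PredictionSet("p", frozenset({(1, 99)})), cm)


class TestMetrics:
    """Spot checks against the published 1a4v benchmark values."""

    def test_mcc_kol_10A(self):
        assert cb.mcc(ConfusionCounts(102, 487, 109, 6805)) == pytest.approx(
            0.2561, abs=5e-5
        )

    def test_mcc_svb_14A(self):
        assert cb.mcc(ConfusionCounts(146, 1123, 130, 6104)) == pytest.approx(
            0.1876, abs=5e-5
        )

    def test_mcc_perfect_prediction(self):
        assert cb.mcc(ConfusionCounts(10, 0, 0, 100)) == pytest.approx(1.0)

    def test_mcc_zero_denominator_convention(self):
        assert cb.mcc(ConfusionCounts(0, 0, 5, 10)) == 0.0

    def test_accuracy_reported_convention(self):
        # (TN - TP) / universe, the convention the benchmark table follows
        c = ConfusionCounts(102, 487, 109, 6805)
        assert cb.accuracy_paper(c) == pytest.approx(0.893, abs=5e-4)
        assert cb.accuracy_standard(c) == pytest.approx((102 + 6805) / 7503)
        c2 = ConfusionCounts(7, 54, 938, 6504)
        assert cb.accuracy_paper(c2) == pytest.approx(0.866, abs=5e-4)

    def test_accuracy_zero_when_tp_equals_tn(self):
        assert cb.accuracy_paper(ConfusionCounts(5, 1, 1, 5)) == 0.0

    def test_precision_sensitivity(self):
        c = ConfusionCounts(120, 501, 66, 6816)
        assert cb.precision(c) == pytest.approx(0.193, abs=5e-4)
        assert cb.sensitivity(c) == pytest.approx(0.645, abs=5e-4)
        assert cb.sensitivity(ConfusionCounts(7, 61, 23, 7412)) == pytest.approx(
            0.233, abs=5e-4
        )

    def test_undefined_precision_reports_zero(self):
        assert cb.precision(ConfusionCounts(0, 0, 88, 7415)) == 0.0


class TestRandomBaseline:
    def test_k_zero_degenerate(self):
        _, cm = toy_map()
        base = cb.random_baseline(cm, k=0, n_reps=5, seed=1)
        assert base["mcc"] == 0.0 and base["prec"] == 0.0

    def test_k_equals_universe(self):
        _, cm = toy_map()
        base = cb.random_baseline(cm, k=cm.universe_size, n_reps=3, seed=1)
        assert base["sensy"] == pytest.approx(1.0)

    def test_k_too_large_rejected(self):
        _, cm = toy_map()
        with pytest.raises(ValueError):
            cb.random_baseline(cm, k=cm.universe_size + 1, n_reps=1, seed=1)

    def test_reproducible_from_seed(self):
        _, cm = toy_map()
        a = cb.random_baseline(cm, 30, n_reps=20, seed=5)
        b = cb.random_baseline(cm, 30, n_reps=20, seed=5)
        assert a == b

    def test_hypergeometric_sensitivity_mean(self):
        """E(TP) = k·|contacts|/|universe|, so the sensitivity baseline
        converges on k/|universe|."""
        _, cm = toy_map()
        k = 30
        base = cb.random_baseline(cm, k, n_reps=500, seed=2)
        assert base["sensy"] == pytest.approx(k / cm.universe_size, abs=0.02)


class TestCorrected:
    def test_subtraction(self):
        assert cb.corrected(0.30, 0.00) == pytest.approx(0.30)
        assert cb.corrected(0.30, 0.05) == pytest.approx(0.25)

    def test_random_predictor_corrects_to_zero(self):
        _, cm = toy_map()
        rng = np.random.default_rng(4)
        pairs = frozenset(
            p for p in combinations(range(1, 21), 2) if rng.random() < 0.2
        )
        value = cb.mcc(cb.confusion(cb.PredictionSet("r", pairs), cm))
        base = cb.random_baseline(cm, len(pairs), n_reps=500, seed=6)
        assert abs(cb.corrected(value, base["mcc"])) < 0.15  # Monte-Carlo noise


class TestMetricScan:
    def test_perfect_predictor_peaks_at_its_cutoff(self, small_protein):
        dm = cb.distance_matrix(small_protein.coords)
        cm = cb.contact_map(dm, 8.0)
        scan = cb.metric_scan(cb.PredictionSet("p", cm.contacts), dm)
        by_cutoff = {r.cutoff: r.mcc for r in scan.records}
        assert by_cutoff[8.0] == pytest.approx(1.0)
        assert all(v <= 1.0 for v in by_cutoff.values())
        assert cb.find_peaks(scan).primary_peak == 8.0

    def test_empty_predictor_all_zero(self, small_protein):
        dm = cb.distance_matrix(small_protein.coords)
        scan = cb.metric_scan(cb.PredictionSet("p", frozenset()), dm)
        assert all(r.mcc == 0.0 for r in scan.records)

    def test_scan_equals_independent_recomputation(self, small_protein):
        """No hidden caching: the scan matches per-cutoff recomputation."""
        dm = cb.distance_matrix(small_protein.coords)
        rng = np.random.default_rng(8)
        pairs = frozenset(
            p
            for p in combinations(range(1, len(small_protein.coords) + 1), 2)
            if rng.random() < 0.1
        )
        pred = cb.PredictionSet("p", pairs)
        scan = cb.metric_scan(pred, dm)
        for r in scan.records:
            c = cb.confusion(pred, cb.contact_map(dm, r.cutoff))
            assert cb.compute_metrics(c) == r.metrics

    def test_universe_conservation_and_nested_positives(self, small_protein):
        dm = cb.distance_matrix(small_protein.coords)
        n = len(small_protein.coords)
        pred = cb.PredictionSet("p", frozenset({(1, 2), (3, 9)}))
        scan = cb.metric_scan(pred, dm)
        universe = n * (n - 1) // 2
        positives = []
        for r in scan.records:
            c = r.counts
            assert c.tp + c.fp + c.fn + c.tn == universe
            positives.append(c.tp + c.fn)
        assert positives == sorted(positives)

    def test_bad_ladder_rejected(self, small_protein):
        dm = cb.distance_matrix(small_protein.coords)
        with pytest.raises(ValueError):
            cb.metric_scan(cb.PredictionSet("p", frozenset()), dm, ladder=(8.0, 4.0))


class TestCalibrateRange:
    def test_planted_optimum_recovered_at_every_cutoff(self):
        # positions 1-5 form a tight cluster and share score 0.30
        pts = np.vstack(
            [np.random.default_rng(1).normal(scale=2.0, size=(5, 3)),
             np.random.default_rng(2).normal(scale=2.0, size=(5, 3)) + 60.0]
        )
        dm = cb.distance_matrix(cb.CoordinateSet(pts, tuple(range(1, 11))))
        scores = [0.30] * 5 + [0.90] * 5
        cal = cb.calibrate_range(scores, dm, centers=[0.1, 0.3, 0.5, 0.9])
        assert cal.best_center == pytest.approx(0.3)
        assert all(c == pytest.approx(0.3) for c in cal.per_cutoff_best.values())
        assert cal.agree

    def test_single_center_grid(self, small_protein):
        dm = cb.distance_matrix(small_protein.coords)
        scores = cb.compute_column_scores(small_protein.aln)
        cal = cb.calibrate_range(scores.ent, dm, centers=[0.5], half_width=0.5)
        assert cal.best_center == 0.5

    def test_all_empty_selection_raises(self, small_protein):
        dm = cb.distance_matrix(small_protein.coords)
        with pytest.raises(ValueError, match="zero positions"):
            cb.calibrate_range([10.0] * len(small_protein.coords), dm, [0.0, 0.1])

    def test_recovers_planted_conservation_band(self, default_protein):
        """The argmax center lands within one grid step of the core
        columns' median entropy (the planted band)."""
        dm = cb.distance_matrix(default_protein.coords)
        scores = cb.compute_column_scores(default_protein.aln)
        grid = np.arange(0.0, 3.01, 0.25)
        cal = cb.calibrate_range(scores.ent, dm, grid, half_width=0.25)
        planted = np.nanmedian(scores.ent[default_protein.is_core])
        assert abs(cal.best_center - planted) <= 0.25 + 1e-9
        assert (cal.table["hits"] >= 0).all()


class TestFindPeaks:
    def test_benchmark_primary_peaks(self, benchmark):
        expected = {"SVB": 14.0, "CMA": 6.0, "KOL": 10.0}
        for method, peak in expected.items():
            block = benchmark[benchmark["method"] == method]
            summary = cb.find_peaks_from_values(block["cutoff"], block["mcc"])
            assert summary.primary_peak == peak, method

    def test_monotone_profile_flags_boundary_erratic(self):
        summary = cb.find_peaks_from_values([4, 6, 8, 10], [0.1, 0.2, 0.3, 0.4])
        assert summary.primary_peak == 10 and summary.erratic

    def test_low_mcc_flags_erratic(self):
        summary = cb.find_peaks_from_values([4, 6, 8], [0.01, 0.05, 0.02])
        assert summary.erratic

    def test_tie_goes_to_smaller_cutoff(self):
        summary = cb.find_peaks_from_values([4, 6, 8, 10], [0.1, 0.3, 0.3, 0.1])
        assert summary.primary_peak == 6

    def test_secondary_peaks_are_interior_local_maxima(self):
        cutoffs = [4, 6, 8, 10, 12, 14]
        mccs = [0.1, 0.25, 0.1, 0.4, 0.1, 0.05]
        summary = cb.find_peaks_from_values(cutoffs, mccs)
        assert summary.primary_peak == 10
        assert summary.secondary_peaks == (6,)


@given(seed=st.integers(0, 2**16), density=st.floats(0.0, 1.0))
@settings(deadline=None, max_examples=25)
def test_confusion_counts_always_sum_to_universe(seed, density):
    dm, cm = toy_map(n=15, seed=seed % 100)
    rng = np.random.default_rng(seed)
    pairs = frozenset(
        p for p in combinations(range(1, 16), 2) if rng.random() < density
    )
    c = cb.confusion(cb.PredictionSet("p", pairs), cm)
    assert c.tp + c.fp + c.fn + c.tn == 105  # C(15, 2)
    assert min(c.tp, c.fp, c.fn, c.tn) >= 0


def test_metric_table_layout(tmp_path, small_protein):
    dm = cb.distance_matrix(small_protein.coords)
    pred = cb.PredictionSet("KOL", frozenset({(1, 5), (2, 9)}))
    scan = cb.metric_scan(pred, dm, rnd_reps=10, seed=1)
    frame = scan_to_frame(scan)
    assert list(frame.columns[:6]) == ["method", "cutoff", "tp", "fp", "fn", "tn"]
    assert "mcc_corr" in frame.columns
    out = tmp_path / "t.tsv"
    cb.evaluation.write_metric_table(scan, out, provenance="seed=1")
    text = out.read_text()
    assert text.startswith("# seed=1\n")
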