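import numpy as np
import pytest
from scipy.stats import spearmanr

from elemtraj.core import AnalysisConfig
from elemtraj.synthetic import generate, preset
from elemtraj.trajectory import (
    compute_metrics,
    directionality,
    make_windows,
    speed,
    turnover,
    turnover_ci,
    window_width,
)
from elemtraj.transform import sqrt_minmax
from tests.conftest import make_trec


def window_of(trec, members, width=10.0):
    from elemtraj.trajectory import Window

    members = tuple(members)
    return Window(
        center_index=members[0],
        center_age=float(trec.ages[members[0]]),
        width=width,
        members=members,
        sufficient=True,
    )


class TestWindowWidth:
    @pytest.mark.parametrize(
        "span,fraction,expected",
        [
            ((774.0, 2009.0), 0.30, 370),  # Lake Funda
            ((1311.0, 1960.0), 0.30, 194),  # Lake Azul
            ((0.0, 100.0), 1.0, 100),
            ((0.0, 99.9), 0.30, 29),  # floor, whole years
        ],
    )
    def test_floor_rule(self, span, fraction, expected):
        assert window_width(span, fraction) == expected

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            window_width((100.0, 100.0), 0.3)
        with pytest.raises(ValueError):
            window_width((0.0, 10.0), 0.0)


class TestMakeWindows:
    def test_interior_membership(self):
        trec = make_trec(np.linspace(0, 1, 10)[:, None], ages=np.arange(10) * 10.0)
        cfg = AnalysisConfig(window_fraction=25 / 90, min_window_n=3)
        wins = make_windows(trec, cfg)
        assert wins[0].width == 25.0
        # interior window: center +- 12.5 years covers 3 samples
        assert wins[5].members == (4, 5, 6)
        assert wins[5].n == 3

    def test_full_fraction_central_window_spans_record(self):
        trec = make_trec(np.linspace(0, 1, 6)[:, None], ages=np.arange(6) * 10.0)
        wins = make_windows(trec, AnalysisConfig(window_fraction=1.0))
        # W equals the span: every sample within +-25 y of the center joins
        assert wins[2].members == (0, 1, 2, 3, 4)
        assert wins[3].members == (1, 2, 3, 4, 5)
        # edge windows keep the nominal width but are truncated by availability
        assert wins[0].width == 50.0 and wins[0].members == (0, 1, 2)

    def test_edge_truncation(self):
        trec = make_trec(np.linspace(0, 1, 10)[:, None], ages=np.arange(10) * 10.0)
        wins = make_windows(trec, AnalysisConfig(window_fraction=0.5))
        assert min(trec.ages[list(wins[0].members)]) == trec.ages[0]
        assert wins[0].members[0] == 0

    def test_insufficient_flagging(self):
        trec = make_trec(np.linspace(0, 1, 4)[:, None], ages=[0.0, 10.0, 80.0, 90.0])
        wins = make_windows(trec, AnalysisConfig(window_fraction=0.3, min_window_n=3))
        assert not wins[0].sufficient  # only samples 0,1 within +-13.5 y
        assert wins[0].n == 2


class TestTurnover:
    def test_two_sample_closed_form(self):
        trec = make_trec([[0.0, 0.0], [1.0, 1.0]])
        win = window_of(trec, [0, 1])
        # d^2 = 2; sum_{i<j} d^2 / (n(n-1)) = 2/2 = 1; SS route: 1/(2-1) = 1
        assert turnover(win, trec) == pytest.approx(1.0)

    def test_identical_samples_zero(self):
        trec = make_trec(np.full((5, 3), 0.3))
        assert turnover(window_of(trec, range(5)), trec) == 0.0

    def test_ss_equals_pairwise_identity(self):
        rng = np.random.default_rng(41)
        for _ in range(50):
            X = rng.uniform(0, 1, size=(6, 4))
            trec = make_trec(X)
            win = window_of(trec, range(6))
            bd = turnover(win, trec)
            D2 = ((X[:, None] - X[None, :]) ** 2).sum(-1)
            pairwise = D2[np.triu_indices(6, 1)].sum() / (6 * 5)
            assert bd == pytest.approx(pairwise, abs=1e-12)

    def test_order_invariance(self):
        rng = np.random.default_rng(43)
        X = rng.uniform(0, 1, size=(7, 3))
        t1 = turnover(window_of(make_trec(X), range(7)), make_trec(X))
        perm = rng.permutation(7)
        t2 = turnover(window_of(make_trec(X[perm]), range(7)), make_trec(X[perm]))
        assert t1 == pytest.approx(t2, rel=1e-12)

    def test_undefined_below_two(self):
        trec = make_trec([[0.1, 0.2]])
        assert np.isnan(turnover(window_of(trec, [0]), trec))


class TestTurnoverCI:
    def test_identical_samples_degenerate_ci(self):
        trec = make_trec(np.full((6, 2), 0.5))
        win = window_of(trec, range(6))
        cfg = AnalysisConfig(rng_seed=1)
        assert turnover_ci(win, trec, cfg, np.random.default_rng(1)) == (0.0, 0.0)

    def test_bit_exact_reproducibility(self):
        rng = np.random.default_rng(47)
        trec = make_trec(rng.uniform(0, 1, size=(8, 3)))
        win = window_of(trec, range(8))
        cfg = AnalysisConfig(rng_seed=123)
        a = turnover_ci(win, trec, cfg, np.random.default_rng(cfg.rng_seed))
        b = turnover_ci(win, trec, cfg, np.random.default_rng(cfg.rng_seed))
        assert a == b

    def test_ci_covers_point_estimate(self):
        """Percentile CI of the window turnover contains the point estimate
        for the vast majority of Gaussian windows (small-scale check; the
        200-window experiment runs in the acceptance suite)."""
        rng = np.random.default_rng(49)
        cfg = AnalysisConfig(bootstrap_reps=199)
        hits = 0
        for _ in range(40):
            X = np.clip(rng.normal(0.5, 0.15, size=(8, 3)), 0, 1)
            trec = make_trec(X)
            win = window_of(trec, range(8))
            bd = turnover(win, trec)
            lo, hi = turnover_ci(win, trec, cfg, rng)
            hits += lo <= bd <= hi
        assert hits >= 38


class TestDirectionality:
    def test_collinear_path_is_one(self):
        trec = make_trec([[0.0, 0.0], [0.5, 0.0], [1.0, 0.0]])
        assert directionality(window_of(trec, range(3)), trec) == pytest.approx(1.0)

    def test_reversal_is_zero(self):
        trec = make_trec([[0.0, 0.0], [1.0, 0.0], [0.0, 0.0]])
        assert directionality(window_of(trec, range(3)), trec) == pytest.approx(0.0)

    def test_right_angle_is_half(self):
        trec = make_trec([[0.0, 0.0], [1.0, 0.0], [1.0, 1.0]])
        assert directionality(window_of(trec, range(3)), trec) == pytest.approx(0.5)

    def test_degenerate_triplets_skipped(self):
        # duplicate middle point: triplets with a zero-length segment are
        # dropped, leaving the single well-defined straight-line triplet
        trec = make_trec([[0.0, 0.0], [0.5, 0.0], [0.5, 0.0], [1.0, 0.0]])
        val = directionality(window_of(trec, range(4)), trec)
        assert val == pytest.approx(1.0)

    def test_undefined_below_three(self):
        trec = make_trec([[0.0, 0.0], [1.0, 1.0]])
        assert np.isnan(directionality(window_of(trec, [0, 1]), trec))

    def test_noise_degrades_directionality(self):
        """Directionality of a monotone drift decreases as noise grows
        (Spearman rho < 0 across noise levels)."""
        levels = [0.0, 0.02, 0.05, 0.1, 0.2]
        vals = []
        rng = np.random.default_rng(53)
        base = np.linspace(0.1, 0.9, 12)[:, None] @ np.ones((1, 3))
        for sd in levels:
            noisy = np.clip(base + rng.normal(0, sd, size=base.shape), 0, 1)
            trec = make_trec(noisy)
            vals.append(directionality(window_of(trec, range(12)), trec))
        rho, _ = spearmanr(levels, vals)
        assert rho < 0


class TestSpeed:
    def test_single_segment_all_modes(self):
        trec = make_trec([[0.0, 0.0], [0.3, 0.4]], ages=[0.0, 10.0])
        win = window_of(trec, [0, 1], width=10.0)
        for mode in ("path", "net", "mean_segment"):
            cfg = AnalysisConfig(speed_mode=mode)
            age, val = speed(win, trec, cfg)
            assert val == pytest.approx(0.05)  # d = 0.5 over W = 10
            assert age == pytest.approx(5.0)  # mean member year

    def test_collinear_multi_segment_modes(self):
        X = np.array([[0.0], [0.1], [0.2], [0.3], [0.4]])
        trec = make_trec(X, ages=[0.0, 2.0, 4.0, 6.0, 8.0])
        win = window_of(trec, range(5), width=10.0)
        results = {
            mode: speed(win, trec, AnalysisConfig(speed_mode=mode))[1]
            for mode in ("path", "net", "mean_segment")
        }
        assert results["path"] == pytest.approx(0.4 / 10)
        assert results["net"] == pytest.approx(0.4 / 10)
        assert results["mean_segment"] == pytest.approx(0.1 / 10)

    def test_path_dominates_net(self):
        """Triangle inequality: traversed path >= net displacement, any window."""
        rng = np.random.default_rng(59)
        for _ in range(200):
            n = rng.integers(2, 9)
            trec = make_trec(rng.uniform(0, 1, size=(n, 3)),
                             ages=np.sort(rng.choice(1000, size=n, replace=False)).astype(float))
            win = window_of(trec, range(n), width=50.0)
            p = speed(win, trec, AnalysisConfig(speed_mode="path"))[1]
            nt = speed(win, trec, AnalysisConfig(speed_mode="net"))[1]
            assert p >= nt - 1e-12

    def test_doubling_ages_halves_speed(self):
        rng = np.random.default_rng(61)
        X = rng.uniform(0, 1, size=(8, 3))
        ages = np.sort(rng.choice(500, size=8, replace=False)).astype(float)
        for mode in ("path", "net", "mean_segment"):
            cfg = AnalysisConfig(speed_mode=mode)
            t1 = make_trec(X, ages=ages)
            t2 = make_trec(X, ages=2 * ages)
            v1 = speed(window_of(t1, range(8), width=100.0), t1, cfg)[1]
            v2 = speed(window_of(t2, range(8), width=200.0), t2, cfg)[1]
            assert v2 == pytest.approx(v1 / 2)


class TestComputeMetrics:
    def test_series_shapes_and_flags(self):
        record, _ = generate(preset("shallow_small"))
        trec = sqrt_minmax(record)
        cfg = AnalysisConfig(bootstrap_reps=49, rng_seed=5)
        series = compute_metrics(trec, cfg)
        for name in ("turnover", "directionality", "speed"):
            rows = series[name].rows
            assert len(rows) == trec.n_samples
            assert rows["center_age"].is_monotonic_increasing
            finite = rows["value"].dropna()
            assert (finite >= 0).all()
        assert (series["directionality"].rows["value"].dropna() <= 1).all()

    def test_turnover_peaks_at_breakpoints(self):
        """Windows spanning an abrupt regime shift show higher mean turnover
        than windows fully inside a zone."""
        record, truth = generate(preset("shallow_small"))
        trec = sqrt_minmax(record)
        cfg = AnalysisConfig(rng_seed=2)
        series = compute_metrics(trec, cfg, metrics=("turnover",), with_ci=False)
        rows = series["turnover"].rows
        W = series["turnover"].window_width
        spans_break = np.array([
            any(abs(a - b) <= W / 2 for b in truth.breakpoint_ages)
            for a in rows["center_age"]
        ])
        vals = rows["value"].to_numpy()
        assert np.nanmean(vals[spans_break]) > np.nanmean(vals[~spans_break])

    def test_rerun_is_deterministic(self):
        record, _ = generate(preset("deep_large"))
        trec = sqrt_minmax(record)
        cfg = AnalysisConfig(bootstrap_reps=99, rng_seed=11)
        a = compute_metrics(trec, cfg)["turnover"].rows
        b = compute_metrics(trec, cfg)["turnover"].rows
        assert a.equals(b)
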