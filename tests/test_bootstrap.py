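"""Smooth/case resampling, bootstrap runs, summaries and the baseline
noise diagnostic."""

import numpy as np
import pytest

from curveboot import (
    ConcRespSeries,
    baseline_noise_diagnostic,
    case_resample,
    compute_bmad,
    fit_curve,
    run_bootstrap,
    smooth_resample,
    summarize_bootstrap,
)
from curveboot.bootstrap import MODEL_CODES, BootstrapRun, PARAM_NAMES
from curveboot.synthetic import TruthSpec, make_design, simulate_series

from conftest import make_series


def _rng(seed=0):
    return np.random.default_rng(seed)


class TestSmoothResample:
    def test_identity_with_single_replicates_and_zero_noise(self):
        s = make_series(np.linspace(-2, 2, 9), np.arange(9.0))
        draw = smooth_resample(s, 0.0, _rng())
        np.testing.assert_array_equal(draw.series_star.resp, s.resp)
        np.testing.assert_array_equal(draw.series_star.conc, s.conc)

    def test_concentrations_never_altered(self, noisy_hill_series):
        for seed in range(10):
            draw = smooth_resample(noisy_hill_series, 5.0, _rng(seed))
            np.testing.assert_array_equal(draw.series_star.conc,
                                          noisy_hill_series.conc)

    def test_noise_sd_equals_bmad(self):
        # Monte-Carlo check of the stated noise law on a one-point series
        s = make_series([0.0], [10.0])
        rng = _rng(42)
        diffs = np.array([
            smooth_resample(s, 2.0, rng).series_star.resp[0] - 10.0
            for _ in range(10_000)
        ])
        assert 1.96 <= diffs.std(ddof=1) <= 2.04

    def test_resampled_values_come_from_same_concentration(self):
        s = make_series([0, 0, 0, 1, 1, 1], [1.0, 2.0, 3.0, 10.0, 20.0, 30.0])
        for seed in range(20):
            draw = smooth_resample(s, 0.0, _rng(seed))
            assert set(draw.series_star.resp[:3]) <= {1.0, 2.0, 3.0}
            assert set(draw.series_star.resp[3:]) <= {10.0, 20.0, 30.0}


class TestCaseResample:
    def test_values_are_originals(self):
        s = make_series([0, 0, 0, 1, 1, 1], [1.0, 2.0, 3.0, 10.0, 20.0, 30.0])
        draw = case_resample(s, _rng(1))
        for v, orig in zip(draw.series_star.resp,
                           [{1.0, 2.0, 3.0}] * 3 + [{10.0, 20.0, 30.0}] * 3):
            assert v in orig

    def test_rejects_single_replicate_designs(self):
        s = make_series(np.linspace(-2, 2, 9), np.arange(9.0))
        with pytest.raises(ValueError, match="single-replicate"):
            case_resample(s, _rng())

    def test_equals_smooth_resample_without_noise(self):
        s = make_series([0, 0, 1, 1], [1.0, 2.0, 3.0, 4.0])
        a = case_resample(s, _rng(7)).series_star.resp
        b = smooth_resample(s, 0.0, _rng(7)).series_star.resp
        np.testing.assert_array_equal(a, b)


class TestRunBootstrap:
    def test_reproducible_given_seed(self, noisy_hill_series, noisy_hill_fit):
        kw = dict(B=25, seed=123, point_result=noisy_hill_fit)
        r1 = run_bootstrap(noisy_hill_series, 5.0, 15.0, **kw)
        r2 = run_bootstrap(noisy_hill_series, 5.0, 15.0, **kw)
        np.testing.assert_array_equal(r1.winner, r2.winner)
        np.testing.assert_array_equal(r1.hitc, r2.hitc)
        for name in PARAM_NAMES:
            np.testing.assert_array_equal(r1.params[name], r2.params[name])

    def test_extending_B_preserves_early_samples(self, noisy_hill_series,
                                                 noisy_hill_fit):
        short = run_bootstrap(noisy_hill_series, 5.0, 15.0, B=10, seed=9,
                              point_result=noisy_hill_fit)
        long = run_bootstrap(noisy_hill_series, 5.0, 15.0, B=20, seed=9,
                             point_result=noisy_hill_fit)
        np.testing.assert_array_equal(short.hitc, long.hitc[:10])
        np.testing.assert_array_equal(short.params["ga"],
                                      long.params["ga"][:10])

    def test_degenerate_resampling_reproduces_point_estimate(self):
        # single replicate + bmad 0: every resample is the original series
        conc = np.linspace(-2, 2, 9)
        resp = 50.0 / (1 + 10.0 ** ((0.0 - conc) * 1.5))
        s = make_series(conc, resp)
        point = fit_curve(s, 0.0, 5.0)
        run = run_bootstrap(s, 0.0, 5.0, B=12, seed=1, point_result=point)
        assert set(run.hitc) == {point.hitc}
        assert len(set(run.params["ga"])) == 1
        summ = summarize_bootstrap(run)
        assert summ.hit_probability in (0.0, 1.0)

    def test_hits_imply_nonconstant_winner(self, noisy_hill_series,
                                           noisy_hill_fit):
        run = run_bootstrap(noisy_hill_series, 5.0, 15.0, B=50, seed=2,
                            point_result=noisy_hill_fit)
        summ = summarize_bootstrap(run)
        assert (summ.model_freq["hill"] + summ.model_freq["gnls"]
                >= summ.hit_probability)


class TestSummarize:
    def _toy_run(self, winners, hitcs, ga=None):
        B = len(winners)
        params = {n: np.full(B, np.nan) for n in PARAM_NAMES}
        if ga is not None:
            params["ga"] = np.asarray(ga, dtype=float)
        return BootstrapRun(
            series=make_series([0, 1], [0.0, 1.0]), bmad=1.0, cutoff=3.0,
            B=B, seed=0,
            winner=np.array([MODEL_CODES[w] for w in winners], dtype=np.int8),
            hitc=np.asarray(hitcs, dtype=np.int8),
            params=params,
            aic={m: np.full(B, np.nan) for m in ("cnst", "hill", "gnls")},
        )

    def test_half_hits_give_probability_half(self):
        run = self._toy_run(["hill"] * 1000, [1] * 500 + [0] * 500)
        assert summarize_bootstrap(run).hit_probability == 0.5

    def test_model_freq_sums_to_one(self):
        run = self._toy_run(["cnst", "hill", "gnls", "hill"], [0, 1, 1, 0])
        freq = summarize_bootstrap(run).model_freq
        assert sum(freq.values()) == pytest.approx(1.0)

    def test_cnst_samples_excluded_from_parameter_pool(self):
        run = self._toy_run(["cnst", "hill", "hill"], [0, 1, 1],
                            ga=[np.nan, -1.0, 1.0])
        summ = summarize_bootstrap(run)
        assert summ.n_param_samples == 2
        q = summ.param_quantiles["ga"]
        # type-7: q0.025 of {-1, 1} is -1 + 0.025 * 2
        assert q[0] == pytest.approx(-0.95)
        assert q[1] == pytest.approx(0.0)

    def test_no_nonconstant_winners_reports_none(self):
        run = self._toy_run(["cnst", "cnst"], [0, 0])
        summ = summarize_bootstrap(run)
        assert summ.param_quantiles["tp"] is None
        assert summ.param_quantiles["la"] is None

    def test_identical_samples_zero_width_ci(self):
        run = self._toy_run(["hill"] * 8, [1] * 8, ga=[0.5] * 8)
        q = summarize_bootstrap(run).param_quantiles["ga"]
        assert q[0] == q[2] == 0.5

    def test_quantiles_ordered(self, noisy_hill_series, noisy_hill_fit):
        run = run_bootstrap(noisy_hill_series, 5.0, 15.0, B=40, seed=4,
                            point_result=noisy_hill_fit)
        for q in summarize_bootstrap(run).param_quantiles.values():
            if q is not None:
                assert q[0] <= q[1] <= q[2]


class TestBaselineDiagnostic:
    def _collection(self, n_series, rng, contaminate=0.0):
        out = []
        for i in range(n_series):
            conc = np.repeat(np.linspace(-2, 2, 5), 2)
            resp = rng.normal(0.0, 3.0, conc.size)
            if contaminate and rng.random() < contaminate:
                resp[:4] += 30.0  # potent responder active at baseline
            out.append(make_series(conc, resp, chem=f"c{i}"))
        return out

    def test_normal_baseline_small_ks(self):
        coll = self._collection(500, _rng(0))  # 2000 pooled baseline points
        bmad = compute_bmad(coll).value
        diag = baseline_noise_diagnostic(coll, bmad)
        assert diag.n >= 2000
        assert diag.ks_distance < 0.05

    def test_contaminated_baseline_deviates_in_upper_tail(self):
        rng = _rng(1)
        coll = self._collection(500, rng, contaminate=0.05)
        bmad = compute_bmad(coll).value
        diag = baseline_noise_diagnostic(coll, bmad)
        gaps = diag.ecdf_p - diag.normal_cdf
        upper = diag.ecdf_x > np.quantile(diag.ecdf_x, 0.75)
        assert np.abs(gaps[upper]).max() > np.abs(gaps[~upper]).max()

    def test_ecdf_nondecreasing_zero_to_one(self):
        coll = self._collection(10, _rng(2))
        diag = baseline_noise_diagnostic(coll, compute_bmad(coll).value)
        assert np.all(np.diff(diag.ecdf_p) >= 0)
        assert diag.ecdf_p[0] > 0 and diag.ecdf_p[-1] == pytest.approx(1.0)

    def test_too_few_points_rejected(self):
        coll = self._collection(2, _rng(3))
        with pytest.raises(ValueError, match=">= 20"):
            baseline_noise_diagnostic(coll, 1.0)


class TestResultsApi:
    def test_bootstrap_results_object(self, noisy_hill_series):
        from curveboot import ConcRespModel

        res = ConcRespModel(noisy_hill_series, 5.0, 15.0).fit()
        boot = res.bootstrap(B=30, seed=5)
        assert boot.B == 30
        assert 0.0 <= boot.hit_probability <= 1.0
        lo, hi = boot.conf_int("ga")
        assert lo <= hi
        df = boot.to_dataframe()
        assert len(df) == 30
        assert "hit probability" in boot.summary()
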