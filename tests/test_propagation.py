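"""Index-paired propagation, the AUC aggregator, decision bands and
uncertainty-driver ranking."""

import numpy as np
import pytest

from curveboot import (
    AggregatorSpec,
    ScorePanel,
    aggregate_score,
    classify_score,
    fit_curve,
    propagate,
    rank_uncertainty_drivers,
    winner_response,
)
from curveboot.bootstrap import MODEL_CODES, PARAM_NAMES, BootstrapRun
from curveboot.fitting import CnstFit, CurveResult, HillFit
from curveboot.propagation import PanelBootstrap, default_grid
from curveboot.curves import hill_response, gnls_response

from conftest import make_series

GRID = np.linspace(-3, 2, 50)


def _hill_result(tp=50.0, ga=0.0, gw=1.5, hitc=1):
    s = make_series([-2, -1, 0, 1], [0, 10, 40, 50])
    fits = {
        "cnst": CnstFit(er=0.0, loglik=-50.0, aic=102.0),
        "hill": HillFit(tp=tp, ga=ga, gw=gw, er=0.0, loglik=-10.0, aic=28.0),
    }
    return CurveResult(series=s, fits=fits, winner="hill", hitc=hitc,
                       cutoff=5.0, max_median=50.0, bmad=1.0,
                       fitted_nonconstant=True)


def _cnst_result():
    s = make_series([-2, -1, 0, 1], [0.0, 0.0, 0.0, 0.0])
    fits = {"cnst": CnstFit(er=0.0, loglik=-5.0, aic=12.0)}
    return CurveResult(series=s, fits=fits, winner="cnst", hitc=0,
                       cutoff=5.0, max_median=0.0, bmad=1.0,
                       fitted_nonconstant=False)


def _run_from_records(records):
    """records: list of (winner, hitc, params dict)."""
    B = len(records)
    params = {n: np.full(B, np.nan) for n in PARAM_NAMES}
    winner = np.zeros(B, dtype=np.int8)
    hitc = np.zeros(B, dtype=np.int8)
    for b, (w, h, p) in enumerate(records):
        winner[b] = MODEL_CODES[w]
        hitc[b] = h
        for k, v in p.items():
            params[k][b] = v
    return BootstrapRun(
        series=make_series([0, 1], [0.0, 1.0]), bmad=1.0, cutoff=5.0,
        B=B, seed=0, winner=winner, hitc=hitc, params=params,
        aic={m: np.full(B, np.nan) for m in ("cnst", "hill", "gnls")},
    )


def _constant_run(result, B):
    fit = result.fits.get("hill")
    rec = (("hill", result.hitc,
            {"tp": fit.tp, "ga": fit.ga, "gw": fit.gw})
           if fit is not None else ("cnst", 0, {}))
    return _run_from_records([rec] * B)


class TestWinnerResponse:
    def test_non_hit_contributes_zero(self):
        r = _hill_result(hitc=0)
        np.testing.assert_array_equal(winner_response(r, GRID),
                                      np.zeros_like(GRID))

    def test_gnls_gain_only_equals_hill(self):
        from curveboot.fitting import GnlsFit

        s = make_series([-2, -1, 0, 1], [0, 10, 40, 30])
        g = GnlsFit(tp=40.0, ga=-0.5, gw=2.0, la=1.5, lw=4.0, er=0.0,
                    loglik=-8.0, aic=28.0)
        r = CurveResult(series=s, fits={"cnst": CnstFit(0, -50, 102),
                                        "gnls": g},
                        winner="gnls", hitc=1, cutoff=5.0, max_median=40.0,
                        bmad=1.0, fitted_nonconstant=True)
        np.testing.assert_allclose(
            winner_response(r, GRID, gain_only=True),
            hill_response(40.0, -0.5, 2.0, GRID))
        np.testing.assert_allclose(
            winner_response(r, GRID, gain_only=False),
            gnls_response(40.0, -0.5, 2.0, 1.5, 4.0, GRID))

    def test_hill_response_within_top(self):
        resp = winner_response(_hill_result(), GRID)
        assert np.all(resp >= 0) and np.all(resp <= 50.0)


class TestAggregateScore:
    def test_all_non_hits_score_zero(self):
        spec = AggregatorSpec(grid=GRID)
        assert aggregate_score([np.zeros_like(GRID)] * 4, spec) == 0.0

    def test_constant_response_self_scales_to_one(self):
        const = np.full_like(GRID, 7.0)
        ref_score = aggregate_score([const], AggregatorSpec(grid=GRID))
        spec = AggregatorSpec(grid=GRID, reference_score=ref_score)
        assert aggregate_score([const], spec) == pytest.approx(1.0)

    def test_linearity_in_response(self):
        rng = np.random.default_rng(0)
        resp = rng.uniform(0, 10, GRID.size)
        spec = AggregatorSpec(grid=GRID)
        assert aggregate_score([2 * resp], spec) == pytest.approx(
            2 * aggregate_score([resp], spec))

    def test_assay_order_invariant(self):
        rng = np.random.default_rng(1)
        rs = [rng.uniform(0, 10, GRID.size) for _ in range(5)]
        spec = AggregatorSpec(grid=GRID)
        assert aggregate_score(rs, spec) == pytest.approx(
            aggregate_score(rs[::-1], spec))

    def test_grid_mismatch_rejected(self):
        spec = AggregatorSpec(grid=GRID)
        with pytest.raises(ValueError, match="grid"):
            aggregate_score([np.zeros(10)], spec)


class TestPropagate:
    def test_frozen_ensembles_give_zero_width_ci(self):
        results = {"a1": _hill_result(), "a2": _hill_result(tp=30.0)}
        runs = {a: _constant_run(r, 20) for a, r in results.items()}
        panel = PanelBootstrap("chem", runs, results)
        dist = propagate(panel, AggregatorSpec(grid=GRID))
        assert dist.ci[0] == pytest.approx(dist.ci[1])
        assert dist.ci[0] == pytest.approx(dist.point_score)

    def test_two_assay_hit_split_enumeration(self):
        # assay 1 alternates hit/non-hit; assay 2 constant: exactly two
        # score values with frequencies matching the alternation
        hit = {"tp": 40.0, "ga": 0.0, "gw": 2.0}
        recs = [("hill", 1, hit) if b % 2 == 0 else ("cnst", 0, {})
                for b in range(10)]
        runs = {"a1": _run_from_records(recs),
                "a2": _constant_run(_hill_result(), 10)}
        results = {"a1": _hill_result(tp=40.0, gw=2.0), "a2": _hill_result()}
        panel = PanelBootstrap("chem", runs, results)
        spec = AggregatorSpec(grid=GRID)
        dist = propagate(panel, spec)
        values = np.unique(np.round(dist.samples, 12))
        assert values.size == 2
        # hand enumeration of the two outcomes
        resp_a2 = hill_response(50.0, 0.0, 1.5, GRID)
        resp_a1 = hill_response(40.0, 0.0, 2.0, GRID)
        lo = aggregate_score([np.zeros_like(GRID), resp_a2], spec)
        hi = aggregate_score([resp_a1, resp_a2], spec)
        np.testing.assert_allclose(sorted(values), sorted([lo, hi]))
        assert np.mean(dist.samples == hi) == 0.5

    def test_single_assay_hit_fraction_matches_hit_probability(self):
        hit = {"tp": 40.0, "ga": 0.0, "gw": 2.0}
        recs = ([("hill", 1, hit)] * 7 + [("cnst", 0, {})] * 3)
        panel = PanelBootstrap("chem", {"a": _run_from_records(recs)},
                               {"a": _hill_result(tp=40.0, gw=2.0)})
        dist = propagate(panel, AggregatorSpec(grid=GRID))
        assert np.mean(dist.samples > 0) == pytest.approx(0.7)

    def test_mismatched_B_rejected(self):
        runs = {"a1": _constant_run(_hill_result(), 10),
                "a2": _constant_run(_hill_result(), 20)}
        with pytest.raises(ValueError, match="share B"):
            PanelBootstrap("chem", runs, {"a1": _hill_result(),
                                          "a2": _hill_result()})


class TestClassify:
    def test_positive_no_crossing(self):
        flags = classify_score(0.5, (0.4, 0.6))
        assert flags["positive"] and not flags["ci_crosses_cutoff"]

    def test_ci_crossing_cutoff_flagged(self):
        flags = classify_score(0.08, (0.05, 0.2))
        assert flags["inconclusive"] and flags["ci_crosses_cutoff"]

    def test_tiny_score_negative(self):
        assert classify_score(0.0005, (0.0, 0.001))["negative"]

    def test_invalid_bands_rejected(self):
        with pytest.raises(ValueError):
            classify_score(0.5, (0.4, 0.6), positive_cutoff=0.1,
                           inconclusive_floor=0.2)


class TestDrivers:
    def test_single_varying_assay_accounts_for_all_variance(self):
        hit = {"tp": 40.0, "ga": 0.0, "gw": 2.0}
        varying = _run_from_records(
            [("hill", 1, hit) if b % 2 else ("cnst", 0, {})
             for b in range(20)])
        runs = {"varying": varying,
                "steady": _constant_run(_hill_result(), 20)}
        results = {"varying": _hill_result(tp=40.0, gw=2.0),
                   "steady": _hill_result()}
        panel = PanelBootstrap("chem", runs, results)
        spec = AggregatorSpec(grid=GRID)
        table = rank_uncertainty_drivers(panel, spec)
        assert table[0]["assay_id"] == "varying"
        assert table[0]["variance_fraction"] == pytest.approx(1.0)
        assert table[1]["variance_fraction"] == pytest.approx(0.0, abs=1e-12)

    def test_all_frozen_zero_variance(self):
        runs = {"a": _constant_run(_hill_result(), 10)}
        panel = PanelBootstrap("chem", runs, {"a": _hill_result()})
        dist = propagate(panel, AggregatorSpec(grid=GRID))
        assert np.var(dist.samples) == 0.0


class TestEndToEndPanel:
    def test_simulated_panel_through_score(self):
        from curveboot import run_bootstrap
        from curveboot.synthetic import simulate_panel

        panel_series = simulate_panel(n_assays=3, ga=0.0, tps=50.0,
                                      noise_sds=5.0, seed=21)
        runs, points = {}, {}
        for assay, s in panel_series.items():
            points[assay] = fit_curve(s, 5.0, 15.0)
            runs[assay] = run_bootstrap(s, 5.0, 15.0, B=25, seed=77,
                                        point_result=points[assay])
        grid = default_grid(panel_series.values())
        sp = ScorePanel("chem", runs, points, AggregatorSpec(grid=grid))
        dist = sp.propagate()
        assert dist.ci[0] <= np.median(dist.samples) <= dist.ci[1]
        assert dist.point_score > 0
        drivers = sp.rank_uncertainty_drivers()
        assert len(drivers) == 3
        assert "score" in sp.summary()
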