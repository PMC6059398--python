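"""Smooth nonparametric bootstrap for concentration-response fits.

One resample: at each distinct concentration draw j(i) responses with
replacement from that concentration's observed responses, then add i.i.d.
Normal(0, bmad) smoothing noise to every drawn value, keeping the
concentrations fixed. The resampled curve is refit to the three candidate
models, giving a winner, parameters and a hit call per resample; repeating
B times (1000 by default) yields hit probabilities, model-selection
frequencies and winner-pooled parameter confidence intervals.

The smoothing scale is the assay's own bmad: too little noise collapses the
resamples into discrete bins for sparse designs (plain case resampling),
too much inflates the uncertainty, and bmad is precisely the pipeline's
estimate of baseline noise. :func:`baseline_noise_diagnostic` checks that
assumption by comparing the pooled baseline responses against
Normal(0, bmad).

RNG discipline: one master seed per curve; resample b draws from the child
stream ``SeedSequence(seed, spawn_key=(b,))`` so enlarging B extends a run
without reshuffling earlier samples.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy import stats

from .data import ConcRespSeries, compute_bmad
from .fitting import CurveResult, CnstFit, fit_curve, _fit_cnst
from .curves import compute_aic

__all__ = [
    "ResampleDraw",
    "BootstrapRun",
    "BootstrapSummary",
    "BootstrapResults",
    "smooth_resample",
    "case_resample",
    "run_bootstrap",
    "summarize_bootstrap",
    "baseline_noise_diagnostic",
]

MODEL_CODES = {"cnst": 0, "hill": 1, "gnls": 2}
MODEL_NAMES = {v: k for k, v in MODEL_CODES.items()}

#: winner parameters recorded per resample (NaN where the winner does not
#: define them)
PARAM_NAMES = ("tp", "ga", "gw", "la", "lw", "er")


@dataclass(frozen=True)
class ResampleDraw:
    """One smooth-bootstrap resample of a series."""

    series_star: ConcRespSeries
    noise: np.ndarray
    replicate_indices: np.ndarray


def _resample(series: ConcRespSeries, bmad: float, rng) -> ResampleDraw:
    inverse = series.group_index
    picked = np.empty(series.n_points, dtype=np.int64)
    for g in range(series.n_conc):
        members = np.nonzero(inverse == g)[0]
        j = members.shape[0]
        # positions of this concentration's replicates keep their slots;
        # each slot copies a uniformly drawn replicate from the same group
        picked[members] = members[rng.integers(0, j, size=j)]
    noise = (rng.normal(0.0, bmad, size=series.n_points) if bmad > 0
             else np.zeros(series.n_points))
    star = series.with_resp(series.resp[picked] + noise)
    return ResampleDraw(series_star=star, noise=noise,
                        replicate_indices=picked)


def smooth_resample(series: ConcRespSeries, bmad: float, rng) -> ResampleDraw:
    """Resample within concentration with replacement + Normal(0, bmad) noise.

    Concentrations are never altered; with bmad = 0 and a single replicate
    per concentration the draw is the identity.
    """
    if bmad < 0:
        raise ValueError("bmad must be >= 0")
    return _resample(series, float(bmad), rng)


def case_resample(series: ConcRespSeries, rng) -> ResampleDraw:
    """Plain (non-smoothed) case bootstrap: resampling only, no noise.

    Only defined for multi-replicate designs: with a single measurement per
    concentration, resampling with replacement returns the original point
    every time and the bootstrap distribution is degenerate.
    """
    counts = series.replicate_counts()
    if counts.min() < 2:
        raise ValueError(
            "case_resample requires >= 2 replicates at every concentration; "
            f"series {series.chemical_id}/{series.assay_id} has a "
            "single-replicate concentration (use the smooth bootstrap)"
        )
    return _resample(series, 0.0, rng)


@dataclass
class BootstrapRun:
    """B resample-and-refit records for one series."""

    series: ConcRespSeries
    bmad: float
    cutoff: float
    B: int
    seed: int
    winner: np.ndarray        # int codes, see MODEL_CODES
    hitc: np.ndarray          # 0/1
    params: dict              # name -> array(B), NaN where undefined
    aic: dict                 # model -> array(B), NaN where not fit
    n_fallback: int = 0       # samples that fell back to cnst on failure

    def winner_labels(self) -> np.ndarray:
        return np.array([MODEL_NAMES[c] for c in self.winner])

    def to_dataframe(self):
        import pandas as pd

        data = {
            "sample": np.arange(self.B),
            "winner": self.winner_labels(),
            "hitc": self.hitc,
        }
        for name in PARAM_NAMES:
            data[name] = self.params[name]
        for m in ("cnst", "hill", "gnls"):
            data[f"aic_{m}"] = self.aic[m]
        return pd.DataFrame(data)


def _record_sample(run: BootstrapRun, b: int, res: CurveResult):
    run.winner[b] = MODEL_CODES[res.winner]
    run.hitc[b] = res.hitc
    fit = res.winner_fit
    for name in PARAM_NAMES:
        run.params[name][b] = getattr(fit, name, np.nan)
    for m in ("cnst", "hill", "gnls"):
        f = res.fits.get(m)
        run.aic[m][b] = f.aic if f is not None and f.converged else np.nan


def run_bootstrap(series: ConcRespSeries, bmad: float, cutoff: float,
                  B: int = 1000, seed: Optional[int] = None, *,
                  point_result: Optional[CurveResult] = None) -> BootstrapRun:
    """Run the smooth bootstrap: B resample -> refit cycles.

    Deterministic given ``seed``. Refits warm-start from the point-estimate
    parameters (computed here when ``point_result`` is not supplied). A
    per-sample fit failure falls back to a cnst-only result so B stays
    fixed and the hit probability stays well defined.
    """
    if B < 1:
        raise ValueError("B must be >= 1")
    if seed is None:
        seed = int(np.random.SeedSequence().entropy % (2 ** 31))
    seed = int(seed)
    if point_result is None:
        point_result = fit_curve(series, bmad, cutoff)
    warm = {}
    h = point_result.fits.get("hill")
    if h is not None and h.converged:
        warm["hill"] = np.array([h.tp, h.ga, h.gw, h.er])
    g = point_result.fits.get("gnls")
    if g is not None and g.converged:
        warm["gnls"] = np.array([g.tp, g.ga, g.gw, g.la, g.lw, g.er])

    run = BootstrapRun(
        series=series, bmad=float(bmad), cutoff=float(cutoff), B=B, seed=seed,
        winner=np.zeros(B, dtype=np.int8), hitc=np.zeros(B, dtype=np.int8),
        params={n: np.full(B, np.nan) for n in PARAM_NAMES},
        aic={m: np.full(B, np.nan) for m in ("cnst", "hill", "gnls")},
    )
    for b in range(B):
        rng = np.random.default_rng(
            np.random.SeedSequence(entropy=seed, spawn_key=(b,)))
        draw = smooth_resample(series, bmad, rng)
        try:
            # warm-started refits tolerate a slightly looser simplex
            # collapse; parameter error ~1e-4 is negligible against the
            # bootstrap spread itself
            res = fit_curve(draw.series_star, bmad, cutoff,
                            refine_grid=False, warm_starts=warm,
                            maxfev=4000, xatol=1e-4, fatol=1e-7)
        except Exception:
            cn = _fit_cnst(draw.series_star, bmad)
            res = CurveResult(series=draw.series_star, fits={"cnst": cn},
                              winner="cnst", hitc=0, cutoff=cutoff,
                              max_median=float(np.nan), bmad=bmad,
                              fitted_nonconstant=False)
            run.n_fallback += 1
        _record_sample(run, b, res)
    return run


@dataclass(frozen=True)
class BootstrapSummary:
    """Hit probability, model frequencies and winner-pooled parameter CIs."""

    B: int
    seed: int
    hit_probability: float
    model_freq: dict               # model -> fraction of resamples won
    hit_model_freq: dict           # (model, hitc) split of resamples
    param_quantiles: dict          # name -> (q025, q50, q975) or None
    n_param_samples: int           # nonconstant winners pooled for tp/ga/gw
    n_gnls_samples: int            # gnls winners pooled for la/lw


def summarize_bootstrap(run: BootstrapRun,
                        quantiles=(0.025, 0.5, 0.975)) -> BootstrapSummary:
    """Summarize a run; parameter quantiles pool winning-model values only.

    tp/ga/gw quantiles pool resamples whose winner is hill or gnls; la/lw
    pool gnls winners only. Quantiles use linear interpolation between
    order statistics. A parameter with no contributing samples reports
    ``None`` rather than 0.
    """
    if run.B < 1:
        raise ValueError("empty bootstrap run")
    labels = run.winner
    freq = {m: float(np.mean(labels == c)) for m, c in MODEL_CODES.items()}
    hit_split = {}
    for m, c in MODEL_CODES.items():
        for h in (0, 1):
            hit_split[(m, h)] = float(np.mean((labels == c) & (run.hitc == h)))
    nonconst = labels != MODEL_CODES["cnst"]
    gnls_mask = labels == MODEL_CODES["gnls"]
    pq = {}
    for name in ("tp", "ga", "gw"):
        vals = run.params[name][nonconst]
        pq[name] = (tuple(np.quantile(vals, quantiles)) if vals.size else None)
    for name in ("la", "lw"):
        vals = run.params[name][gnls_mask]
        pq[name] = (tuple(np.quantile(vals, quantiles)) if vals.size else None)
    return BootstrapSummary(
        B=run.B, seed=run.seed,
        hit_probability=float(np.mean(run.hitc == 1)),
        model_freq=freq, hit_model_freq=hit_split, param_quantiles=pq,
        n_param_samples=int(nonconst.sum()),
        n_gnls_samples=int(gnls_mask.sum()),
    )


@dataclass(frozen=True)
class BaselineDiagnostic:
    """Fig-1-style comparison of pooled baseline noise to Normal(0, bmad)."""

    ks_distance: float
    n: int
    bmad: float
    ecdf_x: np.ndarray     # sorted centered baseline responses
    ecdf_p: np.ndarray     # empirical CDF at ecdf_x
    normal_cdf: np.ndarray  # Normal(0, bmad) CDF at ecdf_x


def baseline_noise_diagnostic(series_collection, bmad: float,
                              min_points: int = 20) -> BaselineDiagnostic:
    """KS distance between pooled, median-centered baseline responses and
    Normal(0, bmad), plus the ecdf table for plotting.

    Deviations in the upper tail flag highly potent chemicals already
    active at the lowest tested concentrations.
    """
    series_collection = list(series_collection)
    if not series_collection:
        raise ValueError("empty series collection")
    pool = np.concatenate([s.baseline_responses() for s in series_collection])
    if pool.shape[0] < min_points:
        raise ValueError(
            f"baseline diagnostic needs >= {min_points} pooled points, "
            f"got {pool.shape[0]}"
        )
    centered = np.sort(pool - np.median(pool))
    ks = stats.kstest(centered, "norm", args=(0.0, bmad))
    n = centered.shape[0]
    return BaselineDiagnostic(
        ks_distance=float(ks.statistic), n=n, bmad=float(bmad),
        ecdf_x=centered, ecdf_p=np.arange(1, n + 1) / n,
        normal_cdf=stats.norm.cdf(centered, 0.0, bmad),
    )


class BootstrapResults:
    """Results object for a curve's bootstrap: run + summary + plotting."""

    def __init__(self, fit_results, run: BootstrapRun):
        self.fit_results = fit_results
        self.run = run
        self._summary = summarize_bootstrap(run)

    @property
    def B(self):
        return self.run.B

    @property
    def hit_probability(self):
        return self._summary.hit_probability

    @property
    def model_freq(self):
        return self._summary.model_freq

    @property
    def param_quantiles(self):
        return self._summary.param_quantiles

    @property
    def n_param_samples(self):
        return self._summary.n_param_samples

    def conf_int(self, param: str):
        """(0.025, 0.975) winner-pooled interval for ``param`` (None if no
        contributing resamples)."""
        q = self._summary.param_quantiles.get(param)
        return None if q is None else (q[0], q[2])

    def to_dataframe(self):
        return self.run.to_dataframe()

    def summary(self) -> str:
        s = self._summary
        lines = [
            "Smooth bootstrap summary",
            "=" * 60,
            f"B: {s.B}    seed: {s.seed}",
            f"hit probability: {s.hit_probability:.4f}",
            "model frequencies: "
            + "  ".join(f"{m}={s.model_freq[m]:.3f}"
                        for m in ("cnst", "hill", "gnls")),
            f"winner-pooled samples: {s.n_param_samples} nonconstant "
            f"({s.n_gnls_samples} gnls)",
            "-" * 60,
            f"{'param':<6}{'q0.025':>12}{'median':>12}{'q0.975':>12}",
        ]
        for name in PARAM_NAMES[:-1]:
            q = s.param_quantiles.get(name)
            if q is None:
                lines.append(f"{name:<6}{'(no samples)':>36}")
            else:
                lines.append(f"{name:<6}{q[0]:>12.4f}{q[1]:>12.4f}{q[2]:>12.4f}")
        return "\n".join(lines)

    def plot(self, ax=None, max_curves: int = 50):
        """Data, point-estimate curve, and a subset of resampled fits."""
        import matplotlib.pyplot as plt

        ax = self.fit_results.plot(ax=ax)
        s = self.run.series
        xs = np.linspace(s.conc.min(), s.conc.max(), 200)
        from .curves import hill_response, gnls_response

        shown = 0
        for b in range(self.run.B):
            if shown >= max_curves:
                break
            code = self.run.winner[b]
            p = {n: self.run.params[n][b] for n in PARAM_NAMES}
            if code == MODEL_CODES["hill"]:
                ax.plot(xs, hill_response(p["tp"], p["ga"], p["gw"], xs),
                        color="C0", alpha=0.15, lw=0.8)
            elif code == MODEL_CODES["gnls"]:
                ax.plot(xs, gnls_response(p["tp"], p["ga"], p["gw"],
                                          p["la"], p["lw"], xs),
                        color="C2", alpha=0.15, lw=0.8)
            shown += 1
        return ax
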