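"""Constrained maximum-likelihood curve fitting, AIC selection, hit calls.

The point-estimate pipeline: fit the cnst, hill and gnls models to one
:class:`~curveboot.data.ConcRespSeries` by maximizing the t(4) likelihood
with Nelder-Mead inside per-series constraint boxes, pick the winner by
minimum AIC, and call the curve a hit when the winner is nonconstant, its
top asymptote exceeds the activity cutoff, and some concentration's median
response exceeds the cutoff.

Constraint boxes (computed from the series being fit, never assay-wide):

======  ==========================  =============================
model   parameter                   box
======  ==========================  =============================
hill    tp                          [0, 1.2 * max(resp)]
hill    ga                          [min(conc) - 2, max(conc) + 0.5]
hill    gw                          [0.3, 8]
gnls    ga                          [min(conc) - 2, max(conc)]
gnls    la                          [min(conc) - 2, max(conc) + 2]
gnls    lw                          [0.3, 18]
gnls    la - ga                     > 0.25
======  ==========================  =============================

The boxes let the AC50 fall below the tested range (potent reference
chemicals may saturate at the lowest tested concentration) and keep the
slopes away from the 0 / infinity maximum-likelihood degeneracies that flat
or single-point-elevated data produce.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from . import _nm
from .curves import compute_aic, gnls_response, hill_response
from .data import (
    BMAD_SCALE,
    ConcRespSeries,
    compute_bmad,
    max_median,
    should_fit_models,
)

__all__ = [
    "FitBounds",
    "CnstFit",
    "HillFit",
    "GnlsFit",
    "CurveResult",
    "fit_curve",
    "select_winner",
    "ConcRespModel",
    "CurveFitResults",
    "K_PARAMS",
    "MODEL_ORDER",
]

K_PARAMS = {"cnst": 1, "hill": 4, "gnls": 6}
#: parsimony order used to break exact AIC ties
MODEL_ORDER = ("cnst", "hill", "gnls")

# numerical guards on the log error scale: exp(-18.4) ~ 1e-8 keeps the
# objective finite on noiseless fixtures where the ML scale diverges to 0
_ER_LB = -18.4
_ER_UB = 30.0

_MIN_CONC_FOR_NONCONST = 4  # identifiability floor for 4/6-parameter models


@dataclass(frozen=True)
class FitBounds:
    """Per-series constraint boxes for the hill and gnls fits."""

    max_resp: float
    min_conc: float
    max_conc: float

    @classmethod
    def from_series(cls, series: ConcRespSeries) -> "FitBounds":
        return cls(
            max_resp=float(series.resp.max()),
            min_conc=float(series.conc.min()),
            max_conc=float(series.conc.max()),
        )

    @property
    def tp_max(self) -> float:
        # max_resp <= 0 only occurs for series the 3*bmad gate already
        # excludes; keep the box nonempty regardless
        return 1.2 * self.max_resp if self.max_resp > 0 else 1e-6

    def hill_box(self):
        lb = np.array([0.0, self.min_conc - 2.0, 0.3, _ER_LB])
        ub = np.array([self.tp_max, self.max_conc + 0.5, 8.0, _ER_UB])
        return lb, ub

    def gnls_box(self):
        lb = np.array([0.0, self.min_conc - 2.0, 0.3, self.min_conc - 2.0, 0.3, _ER_LB])
        ub = np.array([self.tp_max, self.max_conc, 8.0, self.max_conc + 2.0, 18.0, _ER_UB])
        return lb, ub


@dataclass(frozen=True)
class CnstFit:
    er: float
    loglik: float
    aic: float
    k: int = 1
    converged: bool = True


@dataclass(frozen=True)
class HillFit:
    tp: float
    ga: float
    gw: float
    er: float
    loglik: float
    aic: float
    k: int = 4
    converged: bool = True
    degenerate_gw: bool = False


@dataclass(frozen=True)
class GnlsFit:
    tp: float
    ga: float
    gw: float
    la: float
    lw: float
    er: float
    loglik: float
    aic: float
    k: int = 6
    converged: bool = True
    degenerate_gw: bool = False


@dataclass(frozen=True)
class CurveResult:
    """Winner selection, hit call and cutoff context for one series."""

    series: ConcRespSeries
    fits: dict
    winner: str
    hitc: int
    cutoff: float
    max_median: float
    bmad: float
    fitted_nonconstant: bool

    @property
    def winner_fit(self):
        return self.fits[self.winner]


# ----------------------------------------------------------------------
# starting values


def _robust_scale(resp: np.ndarray) -> float:
    return BMAD_SCALE * float(np.median(np.abs(resp - np.median(resp))))


def _er_start(series: ConcRespSeries, bmad: float) -> float:
    return float(np.log(max(bmad, _robust_scale(series.resp), 1e-3)))


def _hill_start(series, bmad, lb, ub):
    medians = series.median_responses()
    uniq = series.unique_conc
    tp0 = float(np.clip(max_median(series), 1e-3, ub[0]))
    above = np.nonzero(medians > tp0 / 2.0)[0]
    if above.size:
        ga0 = float(uniq[above[0]])
    else:
        ga0 = 0.5 * (uniq[0] + uniq[-1])
    ga0 = float(np.clip(ga0, lb[1] + 1e-6, ub[1] - 1e-6))
    return np.array([tp0, ga0, 1.2, _er_start(series, bmad)])


def _gnls_start(series, bmad, lb, ub):
    h = _hill_start(series, bmad, lb[[0, 1, 2, 5]], ub[[0, 1, 2, 5]])
    ga0 = float(np.clip(h[1], lb[1] + 1e-6, ub[1] - 1e-6))
    la0 = float(np.clip(ga0 + 1.0, lb[3] + 1e-6, ub[3] - 1e-6))
    if la0 - ga0 <= 0.3:
        la0 = min(ga0 + 0.35, ub[3] - 1e-6)
    return np.array([h[0], ga0, h[2], la0, 5.0, h[3]])


# ----------------------------------------------------------------------
# per-model fits


def _run_nm(model, start, x, y, lb, ub, maxfev, xatol=1e-6, fatol=1e-9):
    p, f, nfev, conv = _nm.nelder_mead(
        model, start, x, y, lb, ub, maxfev, xatol, fatol
    )
    return p, f, conv


def _grid_polish(model, x, y, lb, ub, er0, best_p, best_f, conv, maxfev):
    """Grid-restarted refinement: factorial scan of the box, simplex polish
    from the grid winner, repeated until the scan stops improving.

    The gnls surface is multimodal (the loss term can chase local dips), so
    its scan runs at the current fitted error scale and iterates; the hill
    scan covers the error scale as an extra grid dimension in one pass.
    """
    for _ in range(3):
        if model == _nm.HILL:
            grids = [
                np.linspace(lb[0], ub[0], 8),
                np.linspace(lb[1], ub[1], 8),
                np.linspace(lb[2], ub[2], 8),
                np.linspace(er0 - 2.0, er0 + 3.0, 5),
            ]
        else:
            er_now = best_p[5] if np.isfinite(best_f) else er0
            grids = [
                np.linspace(lb[0], ub[0], 12),
                np.linspace(lb[1], ub[1], 12),
                np.linspace(lb[2], ub[2], 12),
                np.linspace(lb[3], ub[3], 12),
                np.linspace(lb[4], ub[4], 12),
                np.array([er_now]),
            ]
        flat = np.concatenate(grids)
        sizes = np.array([g.shape[0] for g in grids], dtype=np.int64)
        gf, gp = _nm.grid_best(model, x, y, flat, sizes)
        if gf >= best_f - 1e-9:
            break
        p2, f2, conv2 = _run_nm(model, gp, x, y, lb, ub, maxfev)
        if f2 < best_f:
            best_p, best_f, conv = p2, f2, conv2
        else:
            break
        if model == _nm.HILL:
            break  # single pass: the hill scan already covers er
    return best_p, best_f, conv


def _fit_cnst(series, bmad, maxfev=500, xatol=1e-6, fatol=1e-9):
    x, y = series.conc, series.resp
    lb = np.array([_ER_LB])
    ub = np.array([_ER_UB])
    start = np.array([_er_start(series, bmad)])
    p, f, conv = _run_nm(_nm.CNST, start, x, y, lb, ub, maxfev, xatol, fatol)
    loglik = -f
    return CnstFit(er=float(p[0]), loglik=loglik, aic=compute_aic(loglik, 1),
                   converged=bool(conv))


def _degenerate_gw(series, bmad, ga_fit) -> bool:
    """Flat-elevated degeneracy: every concentration's median is elevated
    above the 3*bmad gate and the fitted AC50 falls below the tested range,
    i.e. all non-control responses sit at about the same level because the
    dose-response occurred entirely below the lowest tested concentration.
    Only the saturated top of the curve is observed, the slope's ML limit
    is 0 (unreachable inside the box), and 0.3 is reported instead."""
    if ga_fit >= float(series.conc.min()):
        return False
    return bool(series.median_responses().min() > 3.0 * bmad)


def _fit_one(model_code, series, bmad, bounds, warm=None, refine_grid=True,
             maxfev=8000, xatol=1e-6, fatol=1e-9):
    x, y = series.conc, series.resp
    if model_code == _nm.HILL:
        lb, ub = bounds.hill_box()
        make_start = lambda: _hill_start(series, bmad, lb, ub)  # noqa: E731
    else:
        lb, ub = bounds.gnls_box()
        make_start = lambda: _gnls_start(series, bmad, lb, ub)  # noqa: E731

    start = None
    if warm is not None:
        w = np.clip(np.asarray(warm, dtype=float), lb + 1e-9, ub - 1e-9)
        if model_code == _nm.GNLS and w[3] - w[1] <= 0.25:
            w[3] = min(w[1] + 0.3, ub[3] - 1e-9)
        p, f, conv = _run_nm(model_code, w, x, y, lb, ub, maxfev, xatol, fatol)
        if not conv:
            start = make_start()
            p2, f2, conv2 = _run_nm(model_code, start, x, y, lb, ub, maxfev,
                                    xatol, fatol)
            if f2 < f:
                p, f, conv = p2, f2, conv2
    else:
        start = make_start()
        p, f, conv = _run_nm(model_code, start, x, y, lb, ub, maxfev, xatol,
                             fatol)
        if not conv:
            start2 = start.copy()
            start2[1] = min(start2[1] + 1.0, ub[1] - 1e-6)
            p2, f2, conv2 = _run_nm(model_code, start2, x, y, lb, ub, maxfev,
                                    xatol, fatol)
            if f2 < f:
                p, f, conv = p2, f2, conv2
    if refine_grid:
        if start is None:
            start = make_start()
        p, f, conv = _grid_polish(model_code, x, y, lb, ub, start[-1], p, f,
                                  conv, maxfev)
    loglik = -f
    if not np.isfinite(loglik) or loglik <= -_nm.PENALTY / 2:
        conv = False
    degen = _degenerate_gw(series, bmad, p[1])
    if model_code == _nm.HILL:
        return HillFit(
            tp=float(p[0]), ga=float(p[1]), gw=0.3 if degen else float(p[2]),
            er=float(p[3]), loglik=loglik, aic=compute_aic(loglik, 4),
            converged=bool(conv), degenerate_gw=degen,
        )
    return GnlsFit(
        tp=float(p[0]), ga=float(p[1]), gw=0.3 if degen else float(p[2]),
        la=float(p[3]), lw=float(p[4]), er=float(p[5]), loglik=loglik,
        aic=compute_aic(loglik, 6), converged=bool(conv), degenerate_gw=degen,
    )


def select_winner(fits: dict) -> str:
    """Label of the minimum-AIC fit; exact ties go to fewer parameters."""
    if "cnst" not in fits:
        raise ValueError("select_winner: the cnst fit must be present")
    winner, best = None, np.inf
    for name in MODEL_ORDER:
        fit = fits.get(name)
        if fit is None or not fit.converged or not np.isfinite(fit.aic):
            continue
        if fit.aic < best:  # strict: earlier (fewer-parameter) model keeps ties
            winner, best = name, fit.aic
    if winner is None:
        winner = "cnst"
    return winner


def fit_curve(series: ConcRespSeries, bmad: float, cutoff: float, *,
              refine_grid: bool = True, warm_starts: Optional[dict] = None,
              maxfev: int = 8000, xatol: float = 1e-6,
              fatol: float = 1e-9) -> CurveResult:
    """Fit the three candidate models to one series and call the hit.

    The cnst model is always fit (a closed 1-D search over the error
    scale). The hill and gnls models are fit only when the series passes
    the 3*bmad gate and offers at least 4 distinct concentrations.
    Nonconverged models are excluded from winner selection.

    Parameters
    ----------
    series : ConcRespSeries
    bmad : float
        Assay baseline noise scale (response units).
    cutoff : float
        Activity cutoff (response units), >= 0.
    refine_grid : bool
        Add a coarse grid pre-scan + second polish to each nonconstant fit
        (default for point estimates; the bootstrap disables it and warm-
        starts from the point estimate instead).
    warm_starts : dict, optional
        ``{"hill": array(4), "gnls": array(6)}`` starting vectors.
    """
    bmad = float(bmad)
    cutoff = float(cutoff)
    if cutoff < 0:
        raise ValueError("cutoff must be >= 0")
    bounds = FitBounds.from_series(series)
    fits = {"cnst": _fit_cnst(series, bmad, xatol=xatol, fatol=fatol)}
    gate = should_fit_models(series, bmad)
    fit_nonconst = gate and series.n_conc >= _MIN_CONC_FOR_NONCONST
    if fit_nonconst:
        warm = warm_starts or {}
        fits["hill"] = _fit_one(_nm.HILL, series, bmad, bounds,
                                warm=warm.get("hill"),
                                refine_grid=refine_grid, maxfev=maxfev,
                                xatol=xatol, fatol=fatol)
        fits["gnls"] = _fit_one(_nm.GNLS, series, bmad, bounds,
                                warm=warm.get("gnls"),
                                refine_grid=refine_grid, maxfev=maxfev,
                                xatol=xatol, fatol=fatol)
    winner = select_winner(fits)
    mm = max_median(series)
    hitc = int(
        winner != "cnst"
        and fits[winner].tp > cutoff
        and mm > cutoff
    )
    return CurveResult(
        series=series, fits=fits, winner=winner, hitc=hitc, cutoff=cutoff,
        max_median=mm, bmad=bmad, fitted_nonconstant=fit_nonconst,
    )


# ----------------------------------------------------------------------
# Model / Results front end


class ConcRespModel:
    """Concentration-response model for one chemical x assay series.

    Parameters
    ----------
    series : ConcRespSeries
    bmad : float
        Assay noise scale; estimate it with
        :func:`curveboot.data.compute_bmad` over the assay's series.
    cutoff : float
        Activity cutoff in response units (commonly 3, 6 or 10 x bmad).

    Examples
    --------
    >>> model = ConcRespModel(series, bmad=5.0, cutoff=15.0)
    >>> res = model.fit()
    >>> res.winner, res.hitc
    ('hill', 1)
    >>> boot = res.bootstrap(B=1000, seed=7)
    >>> boot.hit_probability
    0.98...
    """

    def __init__(self, series: ConcRespSeries, bmad: float, cutoff: float):
        self.series = series
        self.bmad = float(bmad)
        self.cutoff = float(cutoff)

    @classmethod
    def from_dataframe(cls, df, bmad=None, cutoff="3*bmad",
                       chemical_id=None, assay_id=None):
        """Build from a long-format frame with columns logc and resp.

        ``bmad=None`` estimates it from this series' own baseline; cutoff
        strings of the form ``"k*bmad"`` are resolved against it.
        """
        chem = chemical_id or (str(df["chemical_id"].iloc[0])
                               if "chemical_id" in df else "chem")
        assay = assay_id or (str(df["assay_id"].iloc[0])
                             if "assay_id" in df else "assay")
        series = ConcRespSeries(chem, assay,
                                df["logc"].to_numpy(float),
                                df["resp"].to_numpy(float))
        if bmad is None:
            bmad = compute_bmad([series]).value
        if isinstance(cutoff, str):
            from .io import resolve_cutoff
            cutoff = resolve_cutoff(cutoff, bmad)
        return cls(series, bmad=bmad, cutoff=cutoff)

    def fit(self, **kwargs) -> "CurveFitResults":
        return CurveFitResults(self, fit_curve(self.series, self.bmad,
                                               self.cutoff, **kwargs))


class CurveFitResults:
    """Fitted curve results: per-model fits, AIC winner, hit call."""

    def __init__(self, model: ConcRespModel, result: CurveResult):
        self.model = model
        self.result = result

    # convenience pass-throughs
    @property
    def fits(self):
        return self.result.fits

    @property
    def winner(self):
        return self.result.winner

    @property
    def winner_fit(self):
        return self.result.winner_fit

    @property
    def hitc(self):
        return self.result.hitc

    def predict(self, x) -> np.ndarray:
        """Winning-model response at log10 concentrations ``x``."""
        fit = self.winner_fit
        x = np.asarray(x, dtype=float)
        if self.winner == "cnst":
            return np.zeros_like(x)
        if self.winner == "hill":
            return hill_response(fit.tp, fit.ga, fit.gw, x)
        return gnls_response(fit.tp, fit.ga, fit.gw, fit.la, fit.lw, x)

    def bootstrap(self, B: int = 1000, seed: Optional[int] = None,
                  **kwargs):
        """Smooth-bootstrap uncertainty for this curve (see
        :func:`curveboot.bootstrap.run_bootstrap`)."""
        from .bootstrap import run_bootstrap, BootstrapResults

        run = run_bootstrap(self.model.series, self.model.bmad,
                            self.model.cutoff, B=B, seed=seed,
                            point_result=self.result, **kwargs)
        return BootstrapResults(self, run)

    def summary(self) -> str:
        r = self.result
        s = r.series
        lines = [
            "Concentration-response fit",
            "=" * 60,
            f"series:        {s.chemical_id} / {s.assay_id}"
            f"  (N={s.n_points}, {s.n_conc} concentrations)",
            f"bmad:          {r.bmad:.6g}    cutoff: {r.cutoff:.6g}",
            f"max median:    {r.max_median:.6g}",
            f"3*bmad gate:   {'passed' if r.fitted_nonconstant else 'not passed'}",
            f"winner:        {r.winner}    hit call: {r.hitc}",
            "-" * 60,
            f"{'model':<6}{'loglik':>12}{'AIC':>12}{'conv':>6}  parameters",
        ]
        for name in MODEL_ORDER:
            fit = r.fits.get(name)
            if fit is None:
                lines.append(f"{name:<6}{'not fit (gate)':>24}")
                continue
            if name == "cnst":
                pars = f"er={fit.er:.4g}"
            elif name == "hill":
                pars = (f"tp={fit.tp:.4g} ga={fit.ga:.4g} gw={fit.gw:.4g} "
                        f"er={fit.er:.4g}")
                if fit.degenerate_gw:
                    pars += " [gw degenerate]"
            else:
                pars = (f"tp={fit.tp:.4g} ga={fit.ga:.4g} gw={fit.gw:.4g} "
                        f"la={fit.la:.4g} lw={fit.lw:.4g} er={fit.er:.4g}")
            lines.append(
                f"{name:<6}{fit.loglik:>12.4f}{fit.aic:>12.4f}"
                f"{'yes' if fit.converged else 'no':>6}  {pars}"
            )
        return "\n".join(lines)

    def plot(self, ax=None, grid_points: int = 200):
        """Data points plus the winning-model curve."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        s = self.result.series
        ax.scatter(s.conc, s.resp, s=18, color="k", zorder=3, label="data")
        xs = np.linspace(s.conc.min(), s.conc.max(), grid_points)
        ax.plot(xs, self.predict(xs), color="C3",
                label=f"winner: {self.winner}")
        ax.axhline(self.result.cutoff, ls="-", color="gray", lw=0.8)
        ax.axhline(3 * self.result.bmad, ls="--", color="gray", lw=0.8)
        ax.set_xlabel("log10 concentration (µM)")
        ax.set_ylabel("response")
        ax.legend()
        return ax
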