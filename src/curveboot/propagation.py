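"""Index-paired propagation of bootstrap ensembles through an aggregate score.

A chemical screened across an assay panel gets one aggregate activity score
combining the winning fitted curves of all assays; this module propagates
each assay's bootstrap ensemble through that score by pairing resample
indices — sample i of the aggregate uses sample i of every assay, never a
re-randomized combination — so cross-assay structure within a resample is
preserved.

The aggregator here is a simple agonist-style AUC: each hit assay
contributes the area under its winning-model response over a shared log10
concentration grid (gain component only for gnls winners; non-hits
contribute zero), assays are averaged equally, and the result is scaled so
a designated reference agonist scores 1. The aggregator is a plug-in: a
richer pathway model consuming the same per-sample winner parameters can be
substituted without touching the pairing, quantile or driver-ranking
machinery.

Decision bands on the scaled score: >= 0.1 positive, (0.001, 0.1)
inconclusive, otherwise negative; a 95% CI crossing 0.1 flags a chemical
whose activity call is itself uncertain.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .bootstrap import MODEL_CODES, BootstrapRun
from .curves import gnls_response, hill_response
from .fitting import CurveResult

__all__ = [
    "AggregatorSpec",
    "PanelBootstrap",
    "ScoreDistribution",
    "ScorePanel",
    "winner_response",
    "aggregate_score",
    "propagate",
    "classify_score",
    "rank_uncertainty_drivers",
    "default_grid",
]

POSITIVE_CUTOFF = 0.1
INCONCLUSIVE_FLOOR = 0.001


@dataclass(frozen=True)
class AggregatorSpec:
    """Shared evaluation grid, reference scaling and gnls handling."""

    grid: np.ndarray              # log10 µM, strictly increasing
    reference_score: float = 1.0  # unscaled score of the reference agonist
    gain_only: bool = True        # use only the gain component of gnls fits

    def __post_init__(self):
        grid = np.asarray(self.grid, dtype=float)
        if grid.ndim != 1 or grid.shape[0] < 2:
            raise ValueError("grid must be a 1-D vector with >= 2 points")
        if not np.all(np.diff(grid) > 0):
            raise ValueError("grid must be strictly increasing")
        if self.reference_score <= 0:
            raise ValueError("reference score must be > 0")
        object.__setattr__(self, "grid", grid)


def default_grid(series_collection, n_points: int = 50) -> np.ndarray:
    """Log-spaced grid spanning the union of tested ranges across a panel."""
    lo = min(float(s.conc.min()) for s in series_collection)
    hi = max(float(s.conc.max()) for s in series_collection)
    return np.linspace(lo, hi, n_points)


def winner_response(curve: CurveResult, grid, gain_only: bool = True):
    """Winning-model response on the grid; zero for non-hits.

    gnls winners contribute only their gain component when ``gain_only``
    (half-max ``ga``, slope ``gw``, top ``tp`` evaluated as a Hill curve).
    """
    grid = np.asarray(grid, dtype=float)
    if grid.size == 0:
        raise ValueError("grid must be nonempty")
    if curve.hitc == 0:
        return np.zeros_like(grid)
    fit = curve.winner_fit
    if curve.winner == "hill" or (curve.winner == "gnls" and gain_only):
        return hill_response(fit.tp, fit.ga, fit.gw, grid)
    if curve.winner == "gnls":
        return gnls_response(fit.tp, fit.ga, fit.gw, fit.la, fit.lw, grid)
    return np.zeros_like(grid)


def _sample_response(run: BootstrapRun, b: int, grid, gain_only: bool):
    if run.hitc[b] == 0:
        return np.zeros_like(grid)
    code = run.winner[b]
    tp = run.params["tp"][b]
    ga = run.params["ga"][b]
    gw = run.params["gw"][b]
    if code == MODEL_CODES["hill"] or gain_only:
        return hill_response(tp, ga, gw, grid)
    return gnls_response(tp, ga, gw, run.params["la"][b],
                         run.params["lw"][b], grid)


def aggregate_score(responses, spec: AggregatorSpec) -> float:
    """Equal-weight normalized AUC over assays, scaled by the reference.

    Mean over assays of trapezoid area under each response curve divided by
    the grid span, then divided by the reference score. Zero when every
    assay contributes zero response.
    """
    grid = spec.grid
    responses = [np.asarray(r, dtype=float) for r in responses]
    if not responses:
        raise ValueError("no assay responses supplied")
    for r in responses:
        if r.shape != grid.shape:
            raise ValueError("response vector does not match the grid")
    span = grid[-1] - grid[0]
    areas = [np.trapezoid(r, grid) / span for r in responses]
    return float(np.mean(areas) / spec.reference_score)


@dataclass
class PanelBootstrap:
    """One chemical's per-assay bootstrap runs plus point estimates."""

    chemical_id: str
    runs: dict                 # assay_id -> BootstrapRun
    point_results: dict        # assay_id -> CurveResult

    def __post_init__(self):
        if not self.runs:
            raise ValueError("panel has no assays")
        if set(self.runs) != set(self.point_results):
            raise ValueError("runs and point_results must cover the same assays")
        sizes = {run.B for run in self.runs.values()}
        if len(sizes) != 1:
            raise ValueError(
                f"all assays must share B; got B values {sorted(sizes)}")

    @property
    def B(self) -> int:
        return next(iter(self.runs.values())).B

    @property
    def assay_ids(self):
        return sorted(self.runs)


@dataclass(frozen=True)
class ScoreDistribution:
    """Aggregate-score ensemble with CI and decision-band flags."""

    chemical_id: str
    point_score: float
    samples: np.ndarray
    ci: tuple
    flags: dict

    @property
    def q025(self):
        return self.ci[0]

    @property
    def q975(self):
        return self.ci[1]


def classify_score(point_score: float, ci,
                   positive_cutoff: float = POSITIVE_CUTOFF,
                   inconclusive_floor: float = INCONCLUSIVE_FLOOR) -> dict:
    """Decision-band flags for a scaled score and its 95% CI."""
    if positive_cutoff <= 0 or inconclusive_floor <= 0:
        raise ValueError("cutoffs must be positive")
    if inconclusive_floor >= positive_cutoff:
        raise ValueError("inconclusive floor must be below the positive cutoff")
    positive = point_score >= positive_cutoff
    inconclusive = inconclusive_floor < point_score < positive_cutoff
    return {
        "positive": bool(positive),
        "inconclusive": bool(inconclusive),
        "negative": bool(not positive and not inconclusive),
        "ci_crosses_cutoff": bool(ci[0] < positive_cutoff < ci[1]),
    }


def _score_samples(panel: PanelBootstrap, spec: AggregatorSpec,
                   frozen=()) -> np.ndarray:
    """Index-paired score samples; assays in ``frozen`` are pinned at their
    point-estimate response."""
    grid = spec.grid
    frozen = set(frozen)
    fixed = {a: winner_response(panel.point_results[a], grid, spec.gain_only)
             for a in frozen}
    scores = np.empty(panel.B)
    for b in range(panel.B):
        responses = []
        for a in panel.assay_ids:
            if a in frozen:
                responses.append(fixed[a])
            else:
                responses.append(_sample_response(panel.runs[a], b, grid,
                                                  spec.gain_only))
        scores[b] = aggregate_score(responses, spec)
    return scores


def propagate(panel: PanelBootstrap, spec: AggregatorSpec,
              quantiles=(0.025, 0.975)) -> ScoreDistribution:
    """Build the chemical's score distribution by pairing resample indices.

    Sample i of the score combines sample i of every assay's run; the point
    score combines the point-estimate fits. The CI is the percentile
    interval of the actually-computed samples.
    """
    point = aggregate_score(
        [winner_response(panel.point_results[a], spec.grid, spec.gain_only)
         for a in panel.assay_ids], spec)
    samples = _score_samples(panel, spec)
    ci = tuple(np.quantile(samples, quantiles))
    return ScoreDistribution(
        chemical_id=panel.chemical_id, point_score=point, samples=samples,
        ci=ci, flags=classify_score(point, ci),
    )


def rank_uncertainty_drivers(panel: PanelBootstrap, spec: AggregatorSpec,
                             dist: Optional[ScoreDistribution] = None):
    """Which assay drives the score uncertainty?

    For each assay, recompute the score samples with that assay pinned at
    its point estimate; the drop in sample variance is that assay's
    contribution. Returns rows sorted by variance reduction (largest
    first), each with the assay's own hit probability.
    """
    if dist is None:
        dist = propagate(panel, spec)
    total_var = float(np.var(dist.samples))
    rows = []
    for a in panel.assay_ids:
        frozen_samples = _score_samples(panel, spec, frozen=(a,))
        reduction = total_var - float(np.var(frozen_samples))
        rows.append({
            "assay_id": a,
            "variance_reduction": reduction,
            "variance_fraction": (reduction / total_var if total_var > 0
                                  else 0.0),
            "hit_probability": float(np.mean(panel.runs[a].hitc == 1)),
        })
    rows.sort(key=lambda r: r["variance_reduction"], reverse=True)
    return rows


class ScorePanel:
    """Model-style front end: panel in, score distribution out.

    Examples
    --------
    >>> panel = ScorePanel(chemical_id, runs, point_results, spec)
    >>> dist = panel.propagate()
    >>> dist.point_score, dist.ci
    (0.42, (0.31, 0.55))
    >>> panel.rank_uncertainty_drivers()[0]["assay_id"]
    'assay03'
    """

    def __init__(self, chemical_id, runs, point_results,
                 spec: AggregatorSpec):
        self.panel = PanelBootstrap(chemical_id, dict(runs),
                                    dict(point_results))
        self.spec = spec
        self._dist = None

    def propagate(self) -> ScoreDistribution:
        self._dist = propagate(self.panel, self.spec)
        return self._dist

    def rank_uncertainty_drivers(self):
        if self._dist is None:
            self.propagate()
        return rank_uncertainty_drivers(self.panel, self.spec, self._dist)

    def summary(self) -> str:
        dist = self._dist or self.propagate()
        flag = [k for k in ("positive", "inconclusive", "negative")
                if dist.flags[k]][0]
        lines = [
            f"Aggregate activity score: {self.panel.chemical_id}",
            "=" * 60,
            f"assays: {len(self.panel.assay_ids)}    B: {self.panel.B}",
            f"point score: {dist.point_score:.4f}   "
            f"95% CI: ({dist.ci[0]:.4f}, {dist.ci[1]:.4f})",
            f"call: {flag}"
            + ("  [CI crosses 0.1]" if dist.flags["ci_crosses_cutoff"] else ""),
        ]
        return "\n".join(lines)
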