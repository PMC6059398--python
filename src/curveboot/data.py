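"""Concentration-response series container and baseline-noise statistics.

A :class:`ConcRespSeries` holds one chemical x assay dataset: log10
concentrations (µM) and normalized responses, one entry per measurement.
Replicates are rows sharing an exactly-equal concentration value; no
concentration binning is performed.

The assay noise scale is the baseline median absolute deviation (bmad):
the scaled MAD of the responses pooled from each chemical's two lowest
tested concentrations. It drives three things downstream: the 3*bmad gate
deciding whether nonconstant models are fit at all, activity cutoffs
expressed as multiples of bmad, and the standard deviation of the
smoothing noise in the bootstrap.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "BMAD_SCALE",
    "ConcRespSeries",
    "BmadEstimate",
    "compute_bmad",
    "max_median",
    "should_fit_models",
]

#: MAD -> standard-deviation scale factor for Gaussian noise, as used by
#: the screening pipeline's bmad definition.
BMAD_SCALE = 1.4826


@dataclass(frozen=True)
class ConcRespSeries:
    """One chemical x assay concentration-response dataset.

    Parameters
    ----------
    chemical_id, assay_id : str
        Opaque identifiers.
    conc : ndarray
        log10(concentration in µM), one value per measurement.
    resp : ndarray
        Normalized response, same length as ``conc``.
    """

    chemical_id: str
    assay_id: str
    conc: np.ndarray
    resp: np.ndarray
    _groups: tuple = field(init=False, repr=False, compare=False, default=None)

    def __post_init__(self):
        conc = np.asarray(self.conc, dtype=float)
        resp = np.asarray(self.resp, dtype=float)
        if conc.ndim != 1 or resp.ndim != 1:
            raise ValueError("conc and resp must be 1-D arrays")
        if conc.shape[0] != resp.shape[0]:
            raise ValueError(
                f"series {self.chemical_id}/{self.assay_id}: "
                f"len(conc)={conc.shape[0]} != len(resp)={resp.shape[0]}"
            )
        if conc.shape[0] < 1:
            raise ValueError(f"series {self.chemical_id}/{self.assay_id}: empty")
        if not (np.isfinite(conc).all() and np.isfinite(resp).all()):
            raise ValueError(
                f"series {self.chemical_id}/{self.assay_id}: non-finite values"
            )
        object.__setattr__(self, "conc", conc)
        object.__setattr__(self, "resp", resp)
        uniq, inverse = np.unique(conc, return_inverse=True)
        object.__setattr__(self, "_groups", (uniq, inverse))

    # -- design structure ------------------------------------------------

    @property
    def n_points(self) -> int:
        """Total number of measurements N."""
        return self.conc.shape[0]

    @property
    def unique_conc(self) -> np.ndarray:
        """Distinct tested concentrations, ascending (log10 µM)."""
        return self._groups[0]

    @property
    def group_index(self) -> np.ndarray:
        """Index into :attr:`unique_conc` for each measurement."""
        return self._groups[1]

    @property
    def n_conc(self) -> int:
        return self.unique_conc.shape[0]

    def replicate_counts(self) -> np.ndarray:
        """j(i): number of replicates at each distinct concentration."""
        return np.bincount(self.group_index, minlength=self.n_conc)

    def median_responses(self) -> np.ndarray:
        """Median replicate response at each distinct concentration."""
        cached = getattr(self, "_medians", None)
        if cached is None:
            from ._nm import group_medians

            uniq, inverse = self._groups
            cached = group_medians(self.resp, inverse, uniq.shape[0])
            object.__setattr__(self, "_medians", cached)
        return cached

    def baseline_responses(self) -> np.ndarray:
        """Responses observed at the two lowest tested concentrations."""
        if self.n_conc < 2:
            raise ValueError(
                f"series {self.chemical_id}/{self.assay_id}: needs >= 2 distinct "
                "concentrations to define a baseline"
            )
        return self.resp[self.group_index <= 1]

    def with_resp(self, resp: np.ndarray) -> "ConcRespSeries":
        """Copy of this series with responses replaced (same concentrations).

        Reuses this series' concentration-group structure instead of
        rederiving it, which keeps bootstrap resampling cheap.
        """
        new = object.__new__(ConcRespSeries)
        object.__setattr__(new, "chemical_id", self.chemical_id)
        object.__setattr__(new, "assay_id", self.assay_id)
        object.__setattr__(new, "conc", self.conc)
        object.__setattr__(new, "resp", np.asarray(resp, dtype=float))
        object.__setattr__(new, "_groups", self._groups)
        return new


@dataclass(frozen=True)
class BmadEstimate:
    """Baseline median absolute deviation for one assay.

    ``value`` is 1.4826 * median(|X_i - median(X)|) over the pooled baseline
    responses X; ``n_baseline`` counts the pooled values.
    """

    value: float
    n_baseline: int

    def __post_init__(self):
        if self.value < 0:
            raise ValueError("bmad must be >= 0")

    def __float__(self) -> float:
        return float(self.value)


def compute_bmad(series_collection) -> BmadEstimate:
    """Estimate the assay noise scale from pooled baseline responses.

    Pools the responses at each series' two lowest tested concentrations and
    returns the scaled median absolute deviation
    ``1.4826 * median(|X_i - median(X)|)``. Median-based statistics keep a
    small number of highly potent chemicals (active already at the lowest
    concentrations) from inflating the noise estimate.
    """
    series_collection = list(series_collection)
    if not series_collection:
        raise ValueError("compute_bmad: empty series collection")
    pool = np.concatenate([s.baseline_responses() for s in series_collection])
    med = np.median(pool)
    value = BMAD_SCALE * float(np.median(np.abs(pool - med)))
    return BmadEstimate(value=value, n_baseline=pool.shape[0])


def max_median(series: ConcRespSeries) -> float:
    """Maximum over distinct concentrations of the median replicate response."""
    return float(series.median_responses().max())


def should_fit_models(series: ConcRespSeries, bmad: float) -> bool:
    """3*bmad gate: fit nonconstant models only to series showing signal.

    True iff some concentration's median response exceeds 3*bmad (strict).
    """
    bmad = float(bmad)
    if bmad < 0:
        raise ValueError("bmad must be >= 0")
    return max_median(series) > 3.0 * bmad
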