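"""Seeded synthetic concentration-response data.

Emulates the three assay designs the screening programs use — 9
concentrations x 1 replicate (transcription-factor panels), 4 x 3
(protein-complementation panels, clustered at higher concentrations), and
15 x 3 (the quantitative HTS panels, tested >100-fold lower) — with Hill,
gain-loss or null ground truth plus additive baseline noise. Everything is
reproducible from a seed, so the fitting and bootstrap machinery is
testable without any database access.

Noise families: ``normal`` (the baseline model the bmad diagnostic
assumes) and ``t4-scaled`` (Student-t(4) scaled to the same standard
deviation, heavier-tailed, for robustness checks of the t(4) likelihood).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np

from .curves import gnls_response, hill_response
from .data import ConcRespSeries

__all__ = ["DesignSpec", "TruthSpec", "make_design", "simulate_series",
           "simulate_panel", "DESIGNS"]


@dataclass(frozen=True)
class DesignSpec:
    """Assay plate design: concentration grid shape and replication."""

    name: str
    n_conc: int
    n_reps: int
    min_logc: float   # log10 µM
    max_logc: float

    def __post_init__(self):
        if self.n_conc < 1 or self.n_reps < 1:
            raise ValueError("n_conc and n_reps must be >= 1")
        if not self.min_logc < self.max_logc:
            raise ValueError("min_logc must be < max_logc")

    @property
    def n_points(self) -> int:
        return self.n_conc * self.n_reps

    def concentrations(self) -> np.ndarray:
        """Distinct log10 concentrations, evenly log-spaced, ascending."""
        return np.linspace(self.min_logc, self.max_logc, self.n_conc)


# The qHTS panel tested >100-fold lower than the others, hence the >= 2
# log10-unit lower floor.
DESIGNS = {
    "ATG-like": DesignSpec("ATG-like", 9, 1, -1.7, 2.0),
    "OT-like": DesignSpec("OT-like", 4, 3, -1.7, 2.0),
    "TOX21-like": DesignSpec("TOX21-like", 15, 3, -3.7, 2.0),
}


def make_design(name: str, **overrides) -> DesignSpec:
    """Named design (``ATG-like``, ``OT-like``, ``TOX21-like``) or
    ``custom`` with explicit n_conc/n_reps/min_logc/max_logc."""
    key = name if name in DESIGNS else name.upper() + "-like"
    if name.lower() == "custom":
        required = {"n_conc", "n_reps", "min_logc", "max_logc"}
        missing = required - set(overrides)
        if missing:
            raise ValueError(f"custom design requires {sorted(missing)}")
        return DesignSpec("custom", **{k: overrides[k] for k in required})
    for cand in (name, key):
        if cand in DESIGNS:
            base = DESIGNS[cand]
            return replace(base, **overrides) if overrides else base
    raise ValueError(
        f"unknown design {name!r}; choose from {sorted(DESIGNS)} or 'custom'")


@dataclass(frozen=True)
class TruthSpec:
    """Ground truth for a simulated series."""

    model: str                 # null | hill | gnls
    tp: float = 0.0
    ga: float = 0.0
    gw: float = 1.0
    la: float = 1.0
    lw: float = 5.0
    noise_sd: float = 0.0
    noise_family: str = "normal"   # normal | t4-scaled

    def __post_init__(self):
        if self.model not in ("null", "hill", "gnls"):
            raise ValueError(f"unknown truth model {self.model!r}")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.noise_family not in ("normal", "t4-scaled"):
            raise ValueError(f"unknown noise family {self.noise_family!r}")

    def mean_response(self, x) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        if self.model == "null":
            return np.zeros_like(x)
        if self.model == "hill":
            return hill_response(self.tp, self.ga, self.gw, x)
        return gnls_response(self.tp, self.ga, self.gw, self.la, self.lw, x)


def _draw_noise(truth: TruthSpec, size: int, rng) -> np.ndarray:
    if truth.noise_sd == 0:
        return np.zeros(size)
    if truth.noise_family == "normal":
        return rng.normal(0.0, truth.noise_sd, size)
    # t(4) has variance df/(df-2) = 2; rescale to match the stated sd
    return rng.standard_t(4, size) * truth.noise_sd / math.sqrt(2.0)


def simulate_series(design: DesignSpec, truth: TruthSpec, seed,
                    chemical_id: str = "chem", assay_id: str = "assay",
                    ) -> ConcRespSeries:
    """Simulate one series: truth mean on the design grid + i.i.d. noise."""
    rng = np.random.default_rng(seed)
    conc = np.repeat(design.concentrations(), design.n_reps)
    resp = truth.mean_response(conc) + _draw_noise(truth, conc.shape[0], rng)
    return ConcRespSeries(chemical_id, assay_id, conc, resp)


def simulate_panel(n_assays: int, ga: float, tps, noise_sds, seed,
                   designs=None, gw: float = 1.2,
                   chemical_id: str = "chem") -> dict:
    """Simulate one chemical across a panel of assays.

    Shared potency ``ga`` (and slope ``gw``) with per-assay efficacy and
    noise, mirroring how a receptor-panel chemical shows one underlying
    potency but assay-specific response scales. ``tps`` and ``noise_sds``
    are scalars or per-assay sequences; ``designs`` likewise (default
    TOX21-like for all). Returns ``{assay_id: ConcRespSeries}``.
    """
    if n_assays < 1:
        raise ValueError("n_assays must be >= 1")

    def per_assay(value, caster):
        if np.isscalar(value) or isinstance(value, (DesignSpec, str)):
            return [caster(value)] * n_assays
        out = list(value)
        if len(out) != n_assays:
            raise ValueError("per-assay list length must equal n_assays")
        return [caster(v) for v in out]

    tps = per_assay(tps, float)
    noise_sds = per_assay(noise_sds, float)
    if designs is None:
        designs = DESIGNS["TOX21-like"]
    designs = per_assay(
        designs, lambda d: d if isinstance(d, DesignSpec) else make_design(d))

    root = np.random.SeedSequence(seed)
    panel = {}
    for a in range(n_assays):
        assay_id = f"assay{a:02d}"
        truth = TruthSpec(model="hill" if tps[a] > 0 else "null",
                          tp=tps[a], ga=ga, gw=gw, noise_sd=noise_sds[a])
        child = np.random.SeedSequence(entropy=root.entropy, spawn_key=(a,))
        panel[assay_id] = simulate_series(
            designs[a], truth, child, chemical_id=chemical_id,
            assay_id=assay_id)
    return panel
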