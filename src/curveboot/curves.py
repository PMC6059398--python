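"""Model equations and robust likelihood for concentration-response curves.

Three candidate mean models, all in the "up" (gain) direction with the
bottom asymptote pinned at zero:

* ``cnst``  — zero response everywhere (the null model).
* ``hill``  — tp / (1 + 10^((ga - x) * gw)), a log10-concentration Hill
  curve with top asymptote ``tp``, half-max log-concentration ``ga``
  (the AC50, log10 µM) and gain coefficient ``gw``.
* ``gnls``  — hill gain term times a loss-direction Hill term
  1 / (1 + 10^((x - la) * lw)) sharing the top asymptote; models responses
  that rise and then fall (e.g. cytotoxicity at high concentration).

Residuals are scored with a Student-t likelihood with 4 degrees of freedom,
a long-tailed error model that keeps occasional wild points from dominating
the fit. The scale enters on the log scale (``er``) so it stays positive.
"""

from __future__ import annotations

import math

import numpy as np

__all__ = ["hill_response", "gnls_response", "t4_loglik", "compute_aic"]

# log density of the standard t(4) at zero: Gamma(2.5)/(Gamma(2)*sqrt(4*pi)) = 3/8
_LOG_T4_NORM = math.log(0.375)

# cap on the base-10 exponent; beyond this the logistic term is 0/1 to
# double precision and 10**e would overflow
_EXP_CAP = 300.0


def _check_finite(**kwargs):
    for name, value in kwargs.items():
        if not np.all(np.isfinite(value)):
            raise ValueError(f"{name} must be finite")


def hill_response(tp, ga, gw, x):
    """Evaluate the gain-direction Hill curve tp / (1 + 10^((ga - x) * gw)).

    Parameters
    ----------
    tp : float
        Top asymptote (response units).
    ga : float
        Half-max log10 concentration (log10 µM).
    gw : float
        Gain coefficient, > 0.
    x : array_like
        log10 concentrations to evaluate at.

    Returns
    -------
    ndarray or float
        Response, monotone nondecreasing in ``x`` for tp >= 0.
    """
    x = np.asarray(x, dtype=float)
    _check_finite(tp=tp, ga=ga, gw=gw, x=x)
    if gw <= 0:
        raise ValueError("gw must be > 0")
    e = np.clip((ga - x) * gw, -_EXP_CAP, _EXP_CAP)
    out = tp / (1.0 + 10.0 ** e)
    return out if out.ndim else float(out)


def gnls_response(tp, ga, gw, la, lw, x):
    """Evaluate the gain-loss curve: Hill gain term times a loss-direction term.

    ``tp * gain(x; ga, gw) * loss(x; la, lw)`` with
    ``loss(x) = 1 / (1 + 10^((x - la) * lw))``. As ``la`` moves far above the
    tested range the loss term tends to 1 and the curve reduces to the Hill
    model.
    """
    x = np.asarray(x, dtype=float)
    _check_finite(tp=tp, ga=ga, gw=gw, la=la, lw=lw, x=x)
    if gw <= 0 or lw <= 0:
        raise ValueError("gw and lw must be > 0")
    eg = np.clip((ga - x) * gw, -_EXP_CAP, _EXP_CAP)
    el = np.clip((x - la) * lw, -_EXP_CAP, _EXP_CAP)
    out = tp / ((1.0 + 10.0 ** eg) * (1.0 + 10.0 ** el))
    return out if out.ndim else float(out)


def t4_loglik(resp, mu, er):
    """Log-likelihood of responses under t(4) errors around the model mean.

    Sum over points of the log density of a location-scale Student-t with
    4 degrees of freedom: location ``mu``, scale ``exp(er)``. Includes the
    ``-er`` (log-scale Jacobian) term per point.

    Parameters
    ----------
    resp, mu : array_like
        Observed responses and model means, equal length.
    er : float
        Log of the t scale parameter.

    Returns
    -------
    float
        Log-likelihood in nats.
    """
    resp = np.asarray(resp, dtype=float)
    mu = np.asarray(mu, dtype=float)
    if resp.shape != mu.shape:
        raise ValueError(f"resp shape {resp.shape} != mu shape {mu.shape}")
    scale = math.exp(er)
    z = (resp - mu) / scale
    return float(np.sum(_LOG_T4_NORM - 2.5 * np.log1p(0.25 * z * z) - er))


def compute_aic(loglik: float, k: int) -> float:
    """Akaike information criterion, 2k - 2*loglik.

    ``k`` counts all estimated parameters including the error scale:
    1 (cnst), 4 (hill), 6 (gnls).
    """
    return 2.0 * k - 2.0 * loglik
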