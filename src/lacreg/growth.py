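"""Modified Gompertz growth-curve fitting and lag-time extraction.

Cultures switched from glucose to lactose show a lag whose length depends
on how quickly the lac genes are induced.  The modified Gompertz model
(Zwietering parameterization)

    y(t) = baseline + A_max * exp(-exp((mu_max * e / A_max) * (lag - t) + 1))

encodes the lag directly: the tangent at the inflection point has slope
mu_max and crosses y = baseline at t = lag.  Per-well fits are combined
into a per-strain lag as an inverse-RMSE^2 weighted mean.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
from scipy.optimize import least_squares

logger = logging.getLogger(__name__)

__all__ = ["GrowthCurve", "GompertzFit", "GrowthFitConfig",
           "gompertz", "fit_growth", "aggregate_lag"]

_E = math.e


class GrowthError(ValueError):
    pass


@dataclass
class GrowthCurve:
    """OD450 time series for one well; times in minutes, strictly increasing."""

    well_id: str
    strain_id: str
    times: np.ndarray
    od: np.ndarray

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.od = np.asarray(self.od, dtype=float)
        if self.times.shape != self.od.shape or self.times.ndim != 1:
            raise GrowthError("times and od must be equal-length vectors")
        if self.times.size < 10:
            raise GrowthError("need at least 10 time points")
        if np.any(np.diff(self.times) <= 0):
            raise GrowthError("times must be strictly increasing")
        if not np.all(np.isfinite(self.od)):
            raise GrowthError("od must be finite")


@dataclass
class GompertzFit:
    """Fit of one growth curve; ``accepted`` False flags a no-growth well."""

    well_id: str
    strain_id: str
    A_max: float
    mu_max: float
    lag_lambda: float
    baseline: float
    rmse: float
    weight: float
    accepted: bool = True

    def to_dict(self) -> dict:
        return {"well": self.well_id, "strain": self.strain_id,
                "A_max": self.A_max, "mu_max": self.mu_max,
                "lag_lambda": self.lag_lambda, "baseline": self.baseline,
                "rmse": self.rmse, "weight": self.weight,
                "accepted": self.accepted}


@dataclass
class GrowthFitConfig:
    min_od_range: float = 0.02     # below this the well is called no-growth
    n_starts: int = 4              # perturbed restarts around the heuristic
    seed: int = 0


def gompertz(t, A_max: float, mu_max: float, lag_lambda: float,
             baseline: float):
    """Modified Gompertz OD at time t (minutes)."""
    if not (A_max > 0 and mu_max > 0):
        raise GrowthError("A_max and mu_max must be > 0")
    t = np.asarray(t, dtype=float)
    inner = (mu_max * _E / A_max) * (lag_lambda - t) + 1.0
    out = baseline + A_max * np.exp(-np.exp(np.clip(inner, -700, 700)))
    return out if out.ndim else float(out)


def _residuals(p: np.ndarray, t: np.ndarray, od: np.ndarray) -> np.ndarray:
    A, mu, lag, base = p
    inner = (mu * _E / A) * (lag - t) + 1.0
    return base + A * np.exp(-np.exp(np.clip(inner, -700, 700))) - od


def _heuristic_p0(t: np.ndarray, od: np.ndarray) -> np.ndarray:
    base = float(np.percentile(od, 5))
    A = max(float(np.max(od) - base), 1e-3)
    # max slope over a smoothed difference quotient
    k = max(len(t) // 50, 1)
    slopes = (od[k:] - od[:-k]) / (t[k:] - t[:-k])
    i = int(np.argmax(slopes))
    mu = max(float(slopes[i]), 1e-6)
    t_inf = 0.5 * (t[i] + t[i + k])
    y_inf = 0.5 * (od[i] + od[i + k])
    lag = max(t_inf - (y_inf - base) / mu, 0.0)
    return np.array([A, mu, lag, base])


def fit_growth(curve: GrowthCurve,
               config: GrowthFitConfig | None = None) -> GompertzFit:
    """Least-squares Gompertz fit of one well with multistart.

    A flat curve (OD range below ``min_od_range``) is returned with
    ``accepted=False`` rather than raising.
    """
    config = config or GrowthFitConfig()
    t, od = curve.times, curve.od
    od_range = float(np.max(od) - np.min(od))
    if od_range < config.min_od_range:
        logger.info("well %s (%s): no growth (OD range %.4f)",
                    curve.well_id, curve.strain_id, od_range)
        return GompertzFit(curve.well_id, curve.strain_id,
                           A_max=np.nan, mu_max=np.nan, lag_lambda=np.nan,
                           baseline=float(np.mean(od)), rmse=np.nan,
                           weight=0.0, accepted=False)

    p0 = _heuristic_p0(t, od)
    rng = np.random.default_rng(config.seed)
    starts = [p0]
    for _ in range(config.n_starts - 1):
        starts.append(np.array([p0[0] * rng.uniform(0.7, 1.4),
                                p0[1] * rng.uniform(0.5, 2.0),
                                max(p0[2] * rng.uniform(0.5, 1.5), 1.0),
                                p0[3]]))
    lb = np.array([1e-6, 1e-9, 0.0, -np.inf])
    ub = np.array([np.inf, np.inf, float(t[-1]) * 2.0, np.inf])
    best = None
    for s in starts:
        try:
            res = least_squares(_residuals, np.clip(s, lb, ub), args=(t, od),
                                bounds=(lb, ub), xtol=1e-15, ftol=1e-15,
                                gtol=1e-15, max_nfev=2000)
        except Exception:  # singular step on a pathological start
            continue
        if best is None or res.cost < best.cost:
            best = res
    if best is None:
        return GompertzFit(curve.well_id, curve.strain_id, np.nan, np.nan,
                           np.nan, float(np.mean(od)), np.nan, 0.0,
                           accepted=False)
    A, mu, lag, base = best.x
    rmse = float(np.sqrt(np.mean(best.fun ** 2)))
    weight = 1.0 / max(rmse, 1e-12) ** 2
    return GompertzFit(curve.well_id, curve.strain_id, float(A), float(mu),
                       float(lag), float(base), rmse, weight, accepted=True)


def aggregate_lag(fits: list[GompertzFit]) -> tuple[float, float]:
    """Weighted mean lag across a strain's replicate fits.

    Weights are 1/rmse^2; returns (lag, weighted standard error).  With no
    accepted fit, both values are NaN (a missing-value result, not an
    error).
    """
    acc = [f for f in fits if f.accepted]
    if not acc:
        return (float("nan"), float("nan"))
    lags = np.array([f.lag_lambda for f in acc])
    w = np.array([f.weight for f in acc])
    w = w / w.sum()
    mean = float(np.sum(w * lags))
    if len(acc) == 1:
        return (mean, 0.0)
    var = float(np.sum(w * (lags - mean) ** 2) / max(1.0 - np.sum(w ** 2), 1e-12))
    se = math.sqrt(var * float(np.sum(w ** 2)))
    return (mean, se)
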