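"""Input-output characterisation of motor units.

Each tracked unit's relation between instantaneous firing rate and force
during the ramp phases is fitted with three candidate models,

    linear:             f(F) = a F + b                 (p = 2)
    rising exponential: f(F) = a (1 - e^(-F/b)) + c    (p = 3)
    natural logarithm:  f(F) = a ln(F) + b             (p = 2)

and the best model is selected by the Bayesian information criterion
BIC = n ln(sse/n) + p ln(n). From the logarithmic fit, the initial
acceleration of firing rate is the derivative a/F evaluated at the
recruitment threshold (per %MVC, and per second after scaling by the
ramp rate). The second, linear stage of rate coding is characterised by
the mean plateau firing rate at each level and its increment per 10 %MVC
step; hysteresis is the difference between recruitment and derecruitment
thresholds.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, stats

NOT_COMPUTABLE = float("nan")

MODELS = ("linear", "rising_exponential", "natural_log")
N_PARAMS = {"linear": 2, "rising_exponential": 3, "natural_log": 2}

#: recruitment-threshold group boundaries, %MVC
GROUP_BOUNDS = {"low": (0.0, 25.0), "medium": (25.0, 50.0), "high": (50.0, 75.0)}


def threshold_group(rt: float) -> str:
    """low (0-25), medium (25-50) or high (50-75 %MVC) threshold group."""
    if rt <= GROUP_BOUNDS["low"][1]:
        return "low"
    if rt <= GROUP_BOUNDS["medium"][1]:
        return "medium"
    return "high"


def instantaneous_rates(spikes: np.ndarray, fs: float) -> tuple[np.ndarray, np.ndarray]:
    """(time index, rate) series; the rate over each inter-spike interval is
    assigned to the later discharge."""
    spikes = np.asarray(spikes, dtype=np.int64)
    if spikes.size < 2:
        return np.array([], dtype=np.int64), np.array([])
    isi = np.diff(spikes).astype(float)
    return spikes[1:], fs / isi


@dataclass
class RampObservation:
    """Pooled (force, rate) pairs over the ramps where a unit was tracked."""

    force: np.ndarray  # %MVC
    rate: np.ndarray  # pps
    phase: str = "up"  # "up" or "down"

    @property
    def n(self) -> int:
        return self.force.size


def ramp_observation(
    spikes: np.ndarray,
    force: np.ndarray,
    fs: float,
    ramp_window: tuple[int, int],
    phase: str = "up",
) -> RampObservation:
    """(force, instantaneous rate) pairs for discharges inside one ramp."""
    t, r = instantaneous_rates(spikes, fs)
    keep = (t >= ramp_window[0]) & (t < ramp_window[1])
    return RampObservation(force=force[t[keep]], rate=r[keep], phase=phase)


def pool_ramp_observations(obs: list[RampObservation]) -> RampObservation:
    if not obs:
        return RampObservation(force=np.array([]), rate=np.array([]))
    return RampObservation(
        force=np.concatenate([o.force for o in obs]),
        rate=np.concatenate([o.rate for o in obs]),
        phase=obs[0].phase,
    )


def bic(sse: float, n: int, p: int) -> float:
    """Bayesian information criterion: n*ln(sse/n) + p*ln(n).

    An exact fit (sse = 0) returns -inf: such a model is preferred over
    any model with positive error.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if sse < 0:
        raise ValueError("sse must be non-negative")
    if sse == 0:
        return float("-inf")
    return n * math.log(sse / n) + p * math.log(n)


@dataclass
class ModelFit:
    model: str
    params: tuple[float, ...]
    sse: float
    n: int
    p: int
    converged: bool
    bic: float = field(init=False)

    def __post_init__(self) -> None:
        self.bic = bic(self.sse, self.n, self.p) if self.converged else float("inf")

    def predict(self, force: np.ndarray) -> np.ndarray:
        return predict(self.model, self.params, force)


def predict(model: str, params: tuple[float, ...], force: np.ndarray) -> np.ndarray:
    f = np.asarray(force, dtype=float)
    if model == "linear":
        a, b = params
        return a * f + b
    if model == "rising_exponential":
        a, b, c = params
        return a * (1.0 - np.exp(-f / b)) + c
    if model == "natural_log":
        a, b = params
        return a * np.log(f) + b
    raise ValueError(f"unknown model {model!r}")


def fit_candidates(obs: RampObservation, maxfev: int = 1000) -> dict[str, ModelFit]:
    """Least-squares fits of the three candidate models on the same points.

    The linear and logarithmic models are linear in their parameters and
    solved directly; the rising exponential uses a bounded nonlinear
    solver (iteration cap 1000) started from the data range. A model
    that fails to converge is flagged and excluded from selection.
    """
    f = np.asarray(obs.force, dtype=float)
    r = np.asarray(obs.rate, dtype=float)
    n = f.size
    if n < 5 or np.any(f <= 0):
        raise ValueError("need >= 5 observations with strictly positive forces")
    fits: dict[str, ModelFit] = {}

    def lsq(design: np.ndarray) -> tuple[np.ndarray, float]:
        coef, *_ = np.linalg.lstsq(design, r, rcond=None)
        return coef, float(np.sum((design @ coef - r) ** 2))

    coef, sse = lsq(np.column_stack([f, np.ones(n)]))
    fits["linear"] = ModelFit("linear", (float(coef[0]), float(coef[1])), sse, n, 2, True)

    coef, sse = lsq(np.column_stack([np.log(f), np.ones(n)]))
    fits["natural_log"] = ModelFit(
        "natural_log", (float(coef[0]), float(coef[1])), sse, n, 2, True
    )

    p0 = (max(np.ptp(r), 1.0), max(np.median(f), 1.0), float(np.min(r)))
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            popt, _ = optimize.curve_fit(
                lambda x, a, b, c: a * (1.0 - np.exp(-x / b)) + c,
                f,
                r,
                p0=p0,
                maxfev=maxfev,
                bounds=([-np.inf, 1e-6, -np.inf], [np.inf, np.inf, np.inf]),
            )
        resid = predict("rising_exponential", tuple(popt), f) - r
        fits["rising_exponential"] = ModelFit(
            "rising_exponential", tuple(float(v) for v in popt), float(np.sum(resid**2)),
            n, 3, True,
        )
    except (RuntimeError, ValueError):
        fits["rising_exponential"] = ModelFit(
            "rising_exponential", (NOT_COMPUTABLE,) * 3, float("inf"), n, 3, False
        )
    return fits


def select_best(fits: dict[str, ModelFit]) -> str | None:
    """Model with the lowest BIC; ties go to fewer parameters, then to the
    logarithmic model. None when no fit converged."""
    converged = [f for f in fits.values() if f.converged]
    if not converged:
        return None
    order = {m: i for i, m in enumerate(("natural_log", "linear", "rising_exponential"))}
    best = min(converged, key=lambda f: (f.bic, f.p, order[f.model]))
    return best.model


def initial_acceleration(
    log_fit: ModelFit, rt: float, ramp_rate: float = 5.0
) -> tuple[float, float]:
    """Derivative a/F of the logarithmic fit at the recruitment threshold.

    Returns (pps per %MVC, pps per second); the time-domain value scales
    the force-domain derivative by the ramp rate (5 %MVC/s).
    """
    if log_fit.model != "natural_log":
        raise ValueError("initial acceleration is defined on the natural-log fit")
    if rt <= 0:
        raise ValueError("recruitment threshold must be positive")
    a = log_fit.params[0]
    force_domain = a / rt
    return force_domain, force_domain * ramp_rate


def thresholds(
    spikes: np.ndarray,
    force: np.ndarray,
    target: float | None = None,
) -> tuple[float, float]:
    """Recruitment and derecruitment thresholds for one contraction.

    RT is the force at the unit's first discharge, provided it falls in
    the ramp-up phase; DRT the force at the last discharge, in the
    ramp-down. A unit firing only during the plateau is not assessable
    (NaN, NaN).
    """
    spikes = np.asarray(spikes, dtype=np.int64)
    if spikes.size == 0:
        return NOT_COMPUTABLE, NOT_COMPUTABLE
    if target is None:
        target = float(np.max(force))
    on = np.flatnonzero(force >= target - 1e-9)
    plateau_start, plateau_stop = (int(on[0]), int(on[-1]) + 1) if on.size else (0, force.size)
    rt = float(force[spikes[0]]) if spikes[0] < plateau_start else NOT_COMPUTABLE
    drt = float(force[spikes[-1]]) if spikes[-1] >= plateau_stop else NOT_COMPUTABLE
    return rt, drt


def pooled_thresholds(
    per_contraction: list[tuple[float, float]],
) -> tuple[float, float, float]:
    """Mean RT, mean DRT and hysteresis (RT - DRT) across contractions.

    Only contractions where a threshold was assessable contribute to its
    mean. The sign convention follows the printed difference RT - DRT:
    negative values indicate prolonged firing on the ramp-down (a
    hysteresis); positive values the reverse.
    """
    rts = [rt for rt, _ in per_contraction if np.isfinite(rt)]
    drts = [drt for _, drt in per_contraction if np.isfinite(drt)]
    rt = float(np.mean(rts)) if rts else NOT_COMPUTABLE
    drt = float(np.mean(drts)) if drts else NOT_COMPUTABLE
    return rt, drt, rt - drt


def plateau_mean_rate(
    spikes: np.ndarray, fs: float, plateau: tuple[int, int]
) -> float:
    """Mean instantaneous rate over discharges inside the plateau window."""
    t, r = instantaneous_rates(spikes, fs)
    keep = (t >= plateau[0]) & (t < plateau[1])
    if np.sum(keep) < 1:
        return NOT_COMPUTABLE
    return float(np.mean(r[keep]))


def rate_increments(
    plateau_rates: dict[float, float], step: float = 10.0
) -> tuple[list[tuple[float, float]], float]:
    """Plateau-rate change per consecutive 10 %MVC level step.

    Only truly consecutive tracked levels (separated by ``step``)
    contribute. Returns ([(level step midpoint force delta, rate delta)],
    mean delta) — the mean is NaN when no consecutive pair exists.
    """
    levels = sorted(k for k, v in plateau_rates.items() if np.isfinite(v))
    increments = []
    for lo, hi in zip(levels[:-1], levels[1:]):
        if abs((hi - lo) - step) < 1e-9:
            increments.append((step, plateau_rates[hi] - plateau_rates[lo]))
    mean = float(np.mean([d for _, d in increments])) if increments else NOT_COMPUTABLE
    return increments, mean


@dataclass
class RateCodingProfile:
    """Everything measured about one tracked unit."""

    unit_id: int
    rt: float
    drt: float
    hysteresis: float
    group: str
    best_model_up: str | None
    best_model_down: str | None
    fits_up: dict[str, ModelFit]
    init_accel_force: float  # pps per %MVC
    init_accel_time: float  # pps per s at the 5 %MVC/s ramp
    plateau_rates: dict[float, float]
    increments: list[tuple[float, float]]
    mean_increment: float


def _adjusted_r2(y: np.ndarray, yhat: np.ndarray, p: int) -> float:
    n = y.size
    ss_res = float(np.sum((y - yhat) ** 2))
    ss_tot = float(np.sum((y - np.mean(y)) ** 2))
    if ss_tot == 0 or n - p - 1 <= 0:
        return NOT_COMPUTABLE
    return 1.0 - (ss_res / ss_tot) * (n - 1) / (n - p - 1)


@dataclass
class PoolRegressions:
    accel_vs_rt: dict
    increment_vs_rt: dict
    rt_vs_drt: dict
    n_units: int
    skipped: bool = False


def pool_regressions(profiles: list[RateCodingProfile], min_units: int = 20) -> PoolRegressions:
    """Pool-level relations across units.

    - initial acceleration vs RT: nonlinear fit c/RT with adjusted R^2
      (the form implied by the derivative of the logarithmic model);
    - plateau-rate increment vs RT: linear fit with Pearson r and p;
    - RT vs DRT: linear and quadratic fits compared by BIC.
    Pools smaller than ``min_units`` are flagged and skipped.
    """
    if len(profiles) < min_units:
        return PoolRegressions({}, {}, {}, len(profiles), skipped=True)
    rt = np.array([p.rt for p in profiles])
    accel = np.array([p.init_accel_time for p in profiles])
    ok = np.isfinite(rt) & np.isfinite(accel) & (rt > 0)
    popt, _ = optimize.curve_fit(lambda x, c: c / x, rt[ok], accel[ok], p0=(1.0,), maxfev=1000)
    accel_fit = {
        "c": float(popt[0]),
        "adjusted_r2": _adjusted_r2(accel[ok], popt[0] / rt[ok], 1),
        "n": int(ok.sum()),
    }

    inc = np.array([p.mean_increment for p in profiles])
    ok = np.isfinite(rt) & np.isfinite(inc)
    if ok.sum() >= 3:
        slope, intercept, r, pval, _ = stats.linregress(rt[ok], inc[ok])
        inc_fit = {
            "slope": float(slope),
            "intercept": float(intercept),
            "pearson_r": float(r),
            "p_value": float(pval),
            "n": int(ok.sum()),
        }
    else:
        inc_fit = {"n": int(ok.sum())}

    drt = np.array([p.drt for p in profiles])
    ok = np.isfinite(rt) & np.isfinite(drt)
    rt_drt: dict = {"n": int(ok.sum())}
    if ok.sum() >= 4:
        x, y = rt[ok], drt[ok]
        lin = np.polyfit(x, y, 1)
        sse_lin = float(np.sum((np.polyval(lin, x) - y) ** 2))
        quad = np.polyfit(x, y, 2)
        sse_quad = float(np.sum((np.polyval(quad, x) - y) ** 2))
        bic_lin = bic(sse_lin, x.size, 2)
        bic_quad = bic(sse_quad, x.size, 3)
        rt_drt.update(
            linear=[float(v) for v in lin],
            quadratic=[float(v) for v in quad],
            bic_linear=bic_lin,
            bic_nonlinear=bic_quad,
            best="linear" if bic_lin <= bic_quad else "nonlinear",
            adjusted_r2_best=_adjusted_r2(
                y,
                np.polyval(lin if bic_lin <= bic_quad else quad, x),
                2 if bic_lin <= bic_quad else 3,
            ),
        )
    return PoolRegressions(accel_fit, inc_fit, rt_drt, len(profiles))
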