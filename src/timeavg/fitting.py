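"""Offline maximum-likelihood psychometric fitting.

Fits binary comparison data with a logistic psychometric function,
optionally extended by a lapse rate or by a non-temporal response
mixture (a gamma- or logistic-based temporal component mixed with a
truncated-exponential non-temporal component), and compares variants
by AIC.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.special import expit, logit
from scipy.stats import gamma as gamma_dist

__all__ = [
    "VARIANTS",
    "PsychometricFit",
    "DegenerateDataError",
    "FitFailureError",
    "fit_psychometric",
    "pse_of",
    "jnd_of",
    "compare_variants",
    "fit_observers",
]

VARIANTS = ("logistic", "logistic+lapse", "gamma+nontemporal", "logistic+nontemporal")

_LN3 = float(np.log(3.0))
_EPS = 1e-9
_LOG_BETA_BOUNDS = (np.log(1e-4), np.log(5.0))
_LAM_MAX = 0.3
_PNT_MAX = 0.5


class DegenerateDataError(ValueError):
    """Trial data cannot constrain a psychometric function."""


class FitFailureError(RuntimeError):
    """Optimization failed to converge; carries per-start diagnostics."""

    def __init__(self, message: str, diagnostics=None):
        super().__init__(message)
        self.diagnostics = diagnostics or []


@dataclass
class PsychometricFit:
    """A converged psychometric fit with derived PSE/JND and AIC."""

    model_variant: str
    params: dict[str, float]
    loglik: float
    aic: float
    pse: float
    jnd: float
    n_trials: int
    flags: tuple[str, ...] = ()


def _as_arrays(trials: Iterable) -> tuple[np.ndarray, np.ndarray]:
    pairs = np.asarray([(float(x), int(r)) for x, r in trials])
    if pairs.size == 0:
        raise DegenerateDataError("no trials")
    x, r = pairs[:, 0], pairs[:, 1].astype(int)
    if x.size < 10:
        raise DegenerateDataError("need at least 10 trials")
    if r.min() == r.max():
        raise DegenerateDataError("responses contain a single category")
    return x, r


def _nt_prob(x: np.ndarray, rate: float, lo: float, hi: float) -> np.ndarray:
    """Non-temporal "longer" probability: truncated-exponential CDF on [lo, hi]."""
    z = np.clip((x - lo) / (hi - lo), 0.0, 1.0)
    if abs(rate) < 1e-12:
        return z
    return -np.expm1(-rate * z) / -np.expm1(-rate)


class _Variant:
    """Parameter transform + response model for one fit variant."""

    def __init__(self, name: str, x: np.ndarray):
        self.name = name
        self.lo, self.hi = float(x.min()), float(x.max())
        span = max(self.hi - self.lo, 1.0)
        self.alpha_bounds = (self.lo - 0.5 * span, self.hi + 0.5 * span)

    @property
    def k(self) -> int:
        return {
            "logistic": 2,
            "logistic+lapse": 3,
            "gamma+nontemporal": 4,
            "logistic+nontemporal": 4,
        }[self.name]

    def initial(self, x: np.ndarray, r: np.ndarray) -> np.ndarray:
        alpha0 = float(np.median(x))
        beta0 = 4.0 / max(float(np.std(x)), 1.0)
        beta0 = float(np.clip(beta0, np.exp(_LOG_BETA_BOUNDS[0]) * 2, np.exp(_LOG_BETA_BOUNDS[1]) / 2))
        if self.name == "logistic":
            return np.array([alpha0, np.log(beta0)])
        if self.name == "logistic+lapse":
            return np.array([alpha0, np.log(beta0), logit(0.05 / _LAM_MAX)])
        if self.name == "logistic+nontemporal":
            return np.array([alpha0, np.log(beta0), logit(0.1 / _PNT_MAX), 0.0])
        # gamma+nontemporal: match median and a moderate spread
        shape0 = 16.0
        scale0 = alpha0 / gamma_dist.ppf(0.5, shape0)
        return np.array([np.log(shape0), np.log(scale0), logit(0.1 / _PNT_MAX), 0.0])

    def bounds(self) -> list[tuple[float, float]]:
        lb, ub = _LOG_BETA_BOUNDS
        if self.name == "logistic":
            return [self.alpha_bounds, (lb, ub)]
        if self.name == "logistic+lapse":
            return [self.alpha_bounds, (lb, ub), (-7.0, 7.0)]
        if self.name == "logistic+nontemporal":
            return [self.alpha_bounds, (lb, ub), (-7.0, 7.0), (-2.0, 2.0)]
        return [(np.log(1.1), np.log(400.0)), (np.log(1e-2), np.log(1e3)), (-7.0, 7.0), (-2.0, 2.0)]

    def prob(self, theta: np.ndarray, x: np.ndarray) -> np.ndarray:
        if self.name == "logistic":
            alpha, logb = theta
            return expit((x - alpha) * np.exp(logb))
        if self.name == "logistic+lapse":
            alpha, logb, tl = theta
            lam = _LAM_MAX * expit(tl)
            return lam / 2.0 + (1.0 - lam) * expit((x - alpha) * np.exp(logb))
        if self.name == "logistic+nontemporal":
            alpha, logb, tp, lograte = theta
            p_nt = _PNT_MAX * expit(tp)
            f = expit((x - alpha) * np.exp(logb))
            return p_nt * _nt_prob(x, np.exp(lograte), self.lo, self.hi) + (1 - p_nt) * f
        logk, logs, tp, lograte = theta
        p_nt = _PNT_MAX * expit(tp)
        f = gamma_dist.cdf(x, np.exp(logk), scale=np.exp(logs))
        return p_nt * _nt_prob(x, np.exp(lograte), self.lo, self.hi) + (1 - p_nt) * f

    def unpack(self, theta: np.ndarray) -> dict[str, float]:
        if self.name == "logistic":
            return {"alpha": theta[0], "beta": float(np.exp(theta[1]))}
        if self.name == "logistic+lapse":
            return {
                "alpha": theta[0],
                "beta": float(np.exp(theta[1])),
                "lam": float(_LAM_MAX * expit(theta[2])),
            }
        if self.name == "logistic+nontemporal":
            return {
                "alpha": theta[0],
                "beta": float(np.exp(theta[1])),
                "p_nt": float(_PNT_MAX * expit(theta[2])),
                "nt_rate": float(np.exp(theta[3])),
            }
        return {
            "gamma_shape": float(np.exp(theta[0])),
            "gamma_scale": float(np.exp(theta[1])),
            "p_nt": float(_PNT_MAX * expit(theta[2])),
            "nt_rate": float(np.exp(theta[3])),
        }


def _neg_loglik(theta, variant: _Variant, x, r) -> float:
    p = np.clip(variant.prob(theta, x), _EPS, 1.0 - _EPS)
    return -float(np.sum(np.where(r == 1, np.log(p), np.log1p(-p))))


def fit_psychometric(
    trials: Iterable,
    variant: str = "logistic",
    n_starts: int = 5,
    seed: int = 0,
) -> PsychometricFit:
    """Maximum-likelihood fit of one psychometric variant.

    Multi-start quasi-Newton optimization on transformed parameters
    (log slope, logit lapse/mixture weight).  Trial order does not
    matter.  Raises :class:`DegenerateDataError` for unusable data and
    :class:`FitFailureError` when no start converges.
    """
    if variant not in VARIANTS:
        raise ValueError(f"unknown variant {variant!r}; expected one of {VARIANTS}")
    x, r = _as_arrays(trials)
    v = _Variant(variant, x)
    theta0 = v.initial(x, r)
    bounds = v.bounds()
    rng = np.random.default_rng(seed)

    best = None
    diagnostics = []
    for start in range(max(n_starts, 1)):
        t0 = theta0.copy()
        if start > 0:
            scale = np.full(t0.size, 0.5)
            if variant.startswith("logistic"):
                scale[0] = 0.15 * max(v.hi - v.lo, 1.0)  # alpha jitter in ms
            t0 = t0 + rng.normal(0.0, 1.0, size=t0.size) * scale
            t0 = np.clip(t0, [b[0] for b in bounds], [b[1] for b in bounds])
        res = minimize(
            _neg_loglik, t0, args=(v, x, r), method="L-BFGS-B", bounds=bounds
        )
        diagnostics.append({"start": start, "success": bool(res.success), "message": str(res.message)})
        if res.success and (best is None or res.fun < best.fun):
            best = res
    if best is None:
        raise FitFailureError(f"no converged fit for variant {variant!r}", diagnostics)

    params = v.unpack(best.x)
    flags: list[str] = []
    if "beta" in params and params["beta"] >= np.exp(_LOG_BETA_BOUNDS[1]) * (1 - 1e-6):
        flags.append("slope-at-bound")  # separation degeneracy

    loglik = -float(best.fun)
    aic = 2 * v.k - 2 * loglik
    fit = PsychometricFit(
        model_variant=variant,
        params=params,
        loglik=loglik,
        aic=aic,
        pse=np.nan,
        jnd=np.nan,
        n_trials=int(x.size),
        flags=tuple(flags),
    )
    fit.pse = pse_of(fit)
    fit.jnd = jnd_of(fit)
    return fit


def pse_of(fit: PsychometricFit) -> float:
    """Stimulus at which the temporal component crosses 0.5, in ms.

    The threshold alpha for logistic variants (the symmetric lapse or
    mixture leaves the temporal midpoint unchanged); the gamma median
    for the gamma variant.
    """
    if "alpha" in fit.params:
        return float(fit.params["alpha"])
    return float(
        gamma_dist.ppf(0.5, fit.params["gamma_shape"], scale=fit.params["gamma_scale"])
    )


def jnd_of(fit: PsychometricFit) -> float:
    """Difference between the temporal component's 75% and 50% points, in ms."""
    if "beta" in fit.params:
        return _LN3 / float(fit.params["beta"])
    k, s = fit.params["gamma_shape"], fit.params["gamma_scale"]
    return float(gamma_dist.ppf(0.75, k, scale=s) - gamma_dist.ppf(0.5, k, scale=s))


def compare_variants(
    trials: Iterable,
    variants: Sequence[str] = VARIANTS,
    n_starts: int = 5,
    seed: int = 0,
) -> pd.DataFrame:
    """Fit each variant to the same trials and rank them by AIC.

    One row per variant: parameters, loglik, aic, delta_aic against the
    best converged fit, pse and jnd.  Per-variant failures are reported
    in the ``error`` column without aborting the others.  Deterministic
    for fixed ``seed``.
    """
    trials = list(trials)
    rows = []
    for variant in variants:
        try:
            fit = fit_psychometric(trials, variant=variant, n_starts=n_starts, seed=seed)
            rows.append(
                {
                    "model_variant": variant,
                    "loglik": fit.loglik,
                    "aic": fit.aic,
                    "pse": fit.pse,
                    "jnd": fit.jnd,
                    "params": dict(fit.params),
                    "flags": ";".join(fit.flags),
                    "error": None,
                }
            )
        except (DegenerateDataError, FitFailureError) as exc:
            rows.append(
                {
                    "model_variant": variant,
                    "loglik": np.nan,
                    "aic": np.nan,
                    "pse": np.nan,
                    "jnd": np.nan,
                    "params": {},
                    "flags": "",
                    "error": f"{type(exc).__name__}: {exc}",
                }
            )
    df = pd.DataFrame(rows)
    df = df.sort_values("aic", na_position="last", kind="mergesort").reset_index(drop=True)
    best = df["aic"].min()
    df["delta_aic"] = df["aic"] - best
    return df


def fit_observers(
    trials: pd.DataFrame, variant: str = "logistic", n_starts: int = 5, seed: int = 0
) -> pd.DataFrame:
    """Fit one psychometric function per observer x set of a trial table.

    Returns a tidy frame with columns observer_id, set_id, alpha, beta,
    lam, p_nt, loglik, aic, pse, jnd, error.  Groups whose fit fails
    carry the error message and NaN estimates.
    """
    rows = []
    for (obs_id, set_id), g in trials.groupby(["observer_id", "set_id"], sort=True):
        pairs = list(zip(g["comparison_ms"], g["response"]))
        row = {"observer_id": obs_id, "set_id": set_id, "model_variant": variant}
        try:
            fit = fit_psychometric(pairs, variant=variant, n_starts=n_starts, seed=seed)
            row.update(
                alpha=fit.params.get("alpha", np.nan),
                beta=fit.params.get("beta", np.nan),
                lam=fit.params.get("lam", np.nan),
                p_nt=fit.params.get("p_nt", np.nan),
                loglik=fit.loglik,
                aic=fit.aic,
                pse=fit.pse,
                jnd=fit.jnd,
                error=None,
            )
        except (DegenerateDataError, FitFailureError) as exc:
            row.update(
                alpha=np.nan, beta=np.nan, lam=np.nan, p_nt=np.nan,
                loglik=np.nan, aic=np.nan, pse=np.nan, jnd=np.nan,
                error=f"{type(exc).__name__}: {exc}",
            )
        rows.append(row)
    return pd.DataFrame(rows)
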