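"""Ensemble-averaging schemes for interval durations.

Four candidate schemes for how an observer might average a set of time
intervals — arithmetic, geometric, weighted (duration-proportional
weights) and harmonic — together with their noisy generative versions
under scalar timing noise, and model-predicted points of subjective
equality (PSE).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np

__all__ = [
    "SCHEMES",
    "IntervalSet",
    "ObserverParams",
    "ModelPrediction",
    "SET1",
    "SET2",
    "SET3",
    "BUILTIN_SETS",
    "arithmetic_mean",
    "geometric_mean",
    "harmonic_mean",
    "weighted_mean",
    "scheme_mean",
    "sample_ensemble_average",
    "sample_ensemble_averages",
    "noise_free_prediction",
    "predict_pse",
]

SCHEMES = ("arithmetic", "geometric", "weighted", "harmonic")


@dataclass(frozen=True)
class IntervalSet:
    """A named stimulus ensemble of base durations in milliseconds."""

    set_id: str
    intervals: tuple[float, ...]

    def __post_init__(self) -> None:
        ivals = tuple(float(v) for v in self.intervals)
        if len(ivals) < 2:
            raise ValueError("an interval set needs at least 2 durations")
        if any(v <= 0 or not np.isfinite(v) for v in ivals):
            raise ValueError("all durations must be strictly positive and finite")
        object.__setattr__(self, "intervals", ivals)

    def __len__(self) -> int:
        return len(self.intervals)


SET1 = IntervalSet("set1", (300, 550, 800, 1050, 1300))
SET2 = IntervalSet("set2", (600, 700, 800, 900, 1000))
SET3 = IntervalSet("set3", (500, 610, 730, 840, 950))

#: The three stimulus ensembles used throughout, keyed by id.
BUILTIN_SETS: Mapping[str, IntervalSet] = {s.set_id: s for s in (SET1, SET2, SET3)}


@dataclass(frozen=True)
class ObserverParams:
    """Generative parameters of a virtual observer.

    Parameters
    ----------
    scheme :
        Averaging scheme, one of ``SCHEMES``.
    weber_fraction :
        Scalar-noise coefficient ``w_f`` for the linear-scale schemes:
        each interval is perceived as ``T_i ~ N(mu_i, mu_i * w_f)``.
        Ignored by the geometric scheme.
    log_noise_sd :
        Log-scale noise SD ``sigma_t`` for the geometric scheme:
        ``log T_i ~ N(log mu_i, sigma_t)``.  Ignored otherwise.
    bias_mean, bias_sd :
        Mean and SD of the additive bias ``B ~ N(bias_mean, bias_sd)``.
        For the geometric scheme the bias lives in log-units (added to
        the mean log before exponentiation); for the others it is in ms.
    lapse_rate :
        Probability of a stimulus-independent coin-flip response.
    rng_seed :
        Optional seed recorded with the observer; simulation code may
        use it to derive a per-observer generator.
    """

    scheme: str
    weber_fraction: float = 0.0
    log_noise_sd: float = 0.0
    bias_mean: float = 0.0
    bias_sd: float = 0.0
    lapse_rate: float = 0.0
    rng_seed: Optional[int] = None

    def __post_init__(self) -> None:
        if self.scheme not in SCHEMES:
            raise ValueError(f"unknown scheme {self.scheme!r}; expected one of {SCHEMES}")
        for name in ("weber_fraction", "log_noise_sd", "bias_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if not 0.0 <= self.lapse_rate < 0.5:
            raise ValueError("lapse_rate must lie in [0, 0.5)")

    @property
    def scheme_noise(self) -> float:
        """The noise parameter relevant to this observer's scheme."""
        return self.log_noise_sd if self.scheme == "geometric" else self.weber_fraction


@dataclass
class ModelPrediction:
    """A fitted averaging model: per-set predicted PSEs, bias and SSE."""

    scheme: str
    per_set_pse: dict[str, float]
    fitted_bias: float
    sse: float
    extra_params: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if any(v <= 0 for v in self.per_set_pse.values()):
            raise ValueError("predicted PSEs must be strictly positive")
        if self.sse < 0:
            raise ValueError("sse must be non-negative")


def _check_values(values: Sequence[float]) -> np.ndarray:
    arr = np.asarray(values, dtype=float)
    if arr.size == 0:
        raise ValueError("empty input")
    if np.any(arr <= 0) or not np.all(np.isfinite(arr)):
        raise ValueError("all values must be strictly positive and finite")
    return arr


def arithmetic_mean(values: Sequence[float]) -> float:
    """Plain average: sum of the values divided by their count."""
    return float(np.mean(_check_values(values)))


def geometric_mean(values: Sequence[float]) -> float:
    """Exponential of the mean of the natural logs."""
    return float(np.exp(np.mean(np.log(_check_values(values)))))


def harmonic_mean(values: Sequence[float]) -> float:
    """Reciprocal of the arithmetic mean of the reciprocals."""
    arr = _check_values(values)
    return float(arr.size / np.sum(1.0 / arr))


def weighted_mean(values: Sequence[float]) -> float:
    """Duration-weighted average with normalized weights ``w_i = x_i / sum(x)``.

    Equals ``sum(x_i^2) / sum(x_i)`` and is never smaller than the
    arithmetic mean (equality only for constant inputs).
    """
    arr = _check_values(values)
    return float(np.sum(arr * arr) / np.sum(arr))


_SCHEME_FUNCS = {
    "arithmetic": arithmetic_mean,
    "geometric": geometric_mean,
    "weighted": weighted_mean,
    "harmonic": harmonic_mean,
}


def scheme_mean(scheme: str, values: Sequence[float]) -> float:
    """Apply the named averaging scheme to ``values``."""
    try:
        fn = _SCHEME_FUNCS[scheme]
    except KeyError:
        raise ValueError(f"unknown scheme {scheme!r}") from None
    return fn(values)


def sample_ensemble_averages(
    interval_set: IntervalSet,
    obs: ObserverParams,
    rng: np.random.Generator,
    size: int,
) -> np.ndarray:
    """Draw ``size`` internal ensemble averages for one observer.

    Linear-scale schemes perceive each base duration ``mu_i`` as
    ``T_i ~ N(mu_i, mu_i * w_f)`` (non-positive draws are resampled:
    durations are physical), average the ``T_i`` per the scheme and add
    an additive ms bias draw.  The geometric scheme averages log-scale
    draws, adds the bias in log-space and exponentiates back.
    """
    mu = np.asarray(interval_set.intervals)
    if obs.scheme == "geometric":
        logs = rng.normal(np.log(mu), obs.log_noise_sd, size=(size, mu.size))
        bias = rng.normal(obs.bias_mean, obs.bias_sd, size=size)
        return np.exp(logs.mean(axis=1) + bias)

    sd = mu * obs.weber_fraction
    t = rng.normal(mu, sd, size=(size, mu.size))
    if obs.weber_fraction > 0:
        bad = t <= 0
        while bad.any():  # negligible for w_f <= 0.3 at these durations
            mu_b = np.broadcast_to(mu, t.shape)[bad]
            sd_b = np.broadcast_to(sd, t.shape)[bad]
            t[bad] = rng.normal(mu_b, sd_b)
            bad = t <= 0

    if obs.scheme == "arithmetic":
        avg = t.mean(axis=1)
    elif obs.scheme == "harmonic":
        avg = mu.size / np.sum(1.0 / t, axis=1)
    else:  # weighted: weights fixed by the physical durations
        avg = t @ (mu / mu.sum())
    return avg + rng.normal(obs.bias_mean, obs.bias_sd, size=size)


def sample_ensemble_average(
    interval_set: IntervalSet, obs: ObserverParams, rng: np.random.Generator
) -> float:
    """One draw of the observer's internal ensemble average, in ms."""
    return float(sample_ensemble_averages(interval_set, obs, rng, 1)[0])


def noise_free_prediction(interval_set: IntervalSet, obs: ObserverParams) -> float:
    """Closed-form prediction with all noise switched off.

    Scheme mean plus bias in ms, or ``GM * exp(bias)`` for the
    geometric scheme.
    """
    m = scheme_mean(obs.scheme, interval_set.intervals)
    if obs.scheme == "geometric":
        return m * float(np.exp(obs.bias_mean))
    return m + obs.bias_mean


def predict_pse(
    interval_set: IntervalSet,
    obs: ObserverParams,
    n_sim: int = 100_000,
    rng: Optional[np.random.Generator] = None,
) -> float:
    """Model-predicted PSE: the median of ``n_sim`` internal averages.

    The median is the stimulus value at which the ensemble average is
    equally likely to fall above or below, i.e. the 50% point of the
    induced response curve.  When the scheme's own noise parameter is
    zero the internal average is the scheme mean plus a symmetric bias
    draw, so the median equals the noise-free closed form and no
    simulation is run.
    """
    if n_sim < 1:
        raise ValueError("n_sim must be >= 1")
    if obs.scheme_noise == 0.0:
        return noise_free_prediction(interval_set, obs)
    if rng is None:
        rng = np.random.default_rng(obs.rng_seed)
    return float(np.median(sample_ensemble_averages(interval_set, obs, rng, n_sim)))
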