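"""Updated maximum-likelihood (UML) adaptive procedure.

Maintains a discretized Bayesian posterior over the threshold, slope
and lapse rate of a logistic psychometric function and places each
comparison stimulus to minimize the expected posterior variance of the
threshold.  Functional reimplementation; not a bit-exact port of any
particular toolbox.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy.special import expit, logsumexp

__all__ = [
    "PosteriorGrid",
    "TrackState",
    "NumericalError",
    "psychometric_probability",
    "update_posterior",
    "select_next_stimulus",
    "estimate_parameters",
    "track_to_json",
    "track_from_json",
]


class NumericalError(RuntimeError):
    """Posterior update produced a degenerate (all-zero) distribution."""


def psychometric_probability(x, alpha, beta, lam):
    """Lapse-attenuated logistic: ``lam/2 + (1 - lam) / (1 + exp(-(x - alpha) * beta))``.

    Strictly increasing in ``x``, bounded in ``[lam/2, 1 - lam/2]``.
    Arguments broadcast like NumPy ufuncs; scalars in give a scalar out.
    """
    beta_arr = np.asarray(beta, dtype=float)
    lam_arr = np.asarray(lam, dtype=float)
    if np.any(beta_arr <= 0):
        raise ValueError("beta must be strictly positive")
    if np.any(lam_arr < 0) or np.any(lam_arr >= 0.5):
        raise ValueError("lam must lie in [0, 0.5)")
    p = lam_arr / 2.0 + (1.0 - lam_arr) * expit((np.asarray(x, dtype=float) - alpha) * beta_arr)
    return float(p) if np.isscalar(x) and p.ndim == 0 else p


@dataclass
class PosteriorGrid:
    """Discretized joint posterior over (alpha, beta, lambda).

    ``log_posterior`` has shape ``(len(alpha), len(beta), len(lam))``
    and, exponentiated, sums to 1.
    """

    alpha: np.ndarray
    beta: np.ndarray
    lam: np.ndarray
    log_posterior: np.ndarray

    def __post_init__(self) -> None:
        for name in ("alpha", "beta", "lam"):
            g = np.asarray(getattr(self, name), dtype=float)
            if g.ndim != 1 or (g.size > 1 and np.any(np.diff(g) <= 0)):
                raise ValueError(f"{name} grid must be 1-D and strictly increasing")
            setattr(self, name, g)
        shape = (self.alpha.size, self.beta.size, self.lam.size)
        self.log_posterior = np.asarray(self.log_posterior, dtype=float).reshape(shape)

    @classmethod
    def default(
        cls,
        alpha_range: tuple[float, float] = (200.0, 1400.0),
        n_alpha: int = 61,
        beta_range: tuple[float, float] = (0.002, 0.2),
        n_beta: int = 41,
        lam_max: float = 0.2,
        n_lam: int = 11,
    ) -> "PosteriorGrid":
        """Flat prior on a linear alpha / log-spaced beta / linear lambda grid.

        Defaults span all three set means and plausible Weber fractions.
        """
        alpha = np.linspace(*alpha_range, n_alpha)
        beta = np.geomspace(*beta_range, n_beta)
        lam = np.linspace(0.0, lam_max, n_lam)
        n = alpha.size * beta.size * lam.size
        logp = np.full((alpha.size, beta.size, lam.size), -np.log(n))
        return cls(alpha, beta, lam, logp)

    @property
    def total_mass(self) -> float:
        return float(np.exp(logsumexp(self.log_posterior)))


@dataclass
class TrackState:
    """One adaptive track: posterior grid, response history, stimulus policy."""

    grid: PosteriorGrid
    history: list[tuple[float, int]] = field(default_factory=list)
    stimulus_range: tuple[float, float] = (100.0, 2000.0)
    initial_stimulus_ms: float = 500.0
    candidates: Optional[np.ndarray] = None
    # caches, derived from the grid
    _nodes: Optional[tuple[np.ndarray, np.ndarray, np.ndarray]] = field(
        default=None, repr=False, compare=False
    )
    _prob_cache: dict = field(default_factory=dict, repr=False, compare=False)

    def __post_init__(self) -> None:
        if self.candidates is None:
            self.candidates = np.clip(self.grid.alpha, *self.stimulus_range)
        self.candidates = np.unique(np.asarray(self.candidates, dtype=float))

    def node_params(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Flattened (alpha, beta, lam) value per posterior node."""
        if self._nodes is None:
            a, b, l = np.meshgrid(
                self.grid.alpha, self.grid.beta, self.grid.lam, indexing="ij"
            )
            self._nodes = (a.ravel(), b.ravel(), l.ravel())
        return self._nodes

    def prob_at(self, stimulus_ms: float) -> np.ndarray:
        """P(response = 1 | stimulus) at every grid node (cached)."""
        key = float(stimulus_ms)
        p = self._prob_cache.get(key)
        if p is None:
            a, b, l = self.node_params()
            p = psychometric_probability(key, a, b, l)
            self._prob_cache[key] = p
        return p

    def posterior_weights(self) -> np.ndarray:
        return np.exp(self.grid.log_posterior.ravel())


def update_posterior(track: TrackState, stimulus_ms: float, response: int) -> TrackState:
    """Bayes update of the track's posterior for one observed response.

    Multiplies the prior by the Bernoulli likelihood at every node and
    renormalizes (all in log-space); the trial is appended to the
    history.  Mutates and returns ``track``.
    """
    if response not in (0, 1):
        raise ValueError("response must be 0 or 1")
    p = np.clip(track.prob_at(stimulus_ms), 1e-12, 1.0 - 1e-12)
    loglik = np.log(p) if response == 1 else np.log1p(-p)
    logpost = track.grid.log_posterior.ravel() + loglik
    norm = logsumexp(logpost)
    if not np.isfinite(norm):
        raise NumericalError("posterior collapsed to zero mass")
    track.grid.log_posterior = (logpost - norm).reshape(track.grid.log_posterior.shape)
    track.history.append((float(stimulus_ms), int(response)))
    return track


def _alpha_marginal(track: TrackState) -> np.ndarray:
    lp = track.grid.log_posterior
    return np.exp(logsumexp(lp, axis=(1, 2)))


def _weighted_quantile(values: np.ndarray, weights: np.ndarray, q: float) -> float:
    cdf = np.cumsum(weights)
    cdf /= cdf[-1]
    return float(values[np.searchsorted(cdf, q, side="left").clip(0, values.size - 1)])


_SWEEP_LEVELS = (0.1, 0.3, 0.5, 0.7, 0.9)


def select_next_stimulus(track: TrackState, mode: str = "variance-min") -> float:
    """Choose the next comparison stimulus for this track, in ms.

    ``variance-min`` minimizes the one-step-ahead expected posterior
    variance of the threshold, taking the expectation over the two
    possible responses; ties go to the smallest candidate. ``sweep``
    cycles through fixed quantiles of the current threshold marginal.
    A fresh track always starts at ``initial_stimulus_ms``.
    """
    lo, hi = track.stimulus_range
    if not track.history:
        return float(np.clip(track.initial_stimulus_ms, lo, hi))
    cand = track.candidates
    if cand.size == 1:
        return float(cand[0])

    if mode == "sweep":
        q = _SWEEP_LEVELS[len(track.history) % len(_SWEEP_LEVELS)]
        target = _weighted_quantile(track.grid.alpha, _alpha_marginal(track), q)
        return float(cand[np.argmin(np.abs(cand - target))])
    if mode != "variance-min":
        raise ValueError(f"unknown mode {mode!r}")

    w = track.posterior_weights()
    a, _, _ = track.node_params()
    # P[c, n] = response probability at candidate c under node n
    P = np.stack([track.prob_at(x) for x in cand])
    wa = w * a
    wa2 = wa * a
    s0 = np.clip(P @ w, 1e-12, 1 - 1e-12)  # predictive P(response = 1)
    s1 = P @ wa
    s2 = P @ wa2
    t1, t2 = wa.sum(), wa2.sum()
    var1 = s2 / s0 - (s1 / s0) ** 2
    var0 = (t2 - s2) / (1 - s0) - ((t1 - s1) / (1 - s0)) ** 2
    expected_var = s0 * var1 + (1 - s0) * var0
    return float(cand[int(np.argmin(expected_var))])  # candidates sorted ascending


def estimate_parameters(track: TrackState) -> tuple[float, float, float]:
    """Posterior means of (alpha, beta, lambda); beta averaged in log-space."""
    w = track.posterior_weights()
    a, b, l = track.node_params()
    alpha_hat = float(w @ a)
    beta_hat = float(np.exp(w @ np.log(b)))
    lambda_hat = float(w @ l)
    return alpha_hat, beta_hat, lambda_hat


def track_to_json(track: TrackState) -> str:
    """Serialize a track (grids, posterior, history) for checkpoint/resume."""
    return json.dumps(
        {
            "alpha": track.grid.alpha.tolist(),
            "beta": track.grid.beta.tolist(),
            "lam": track.grid.lam.tolist(),
            "log_posterior": track.grid.log_posterior.ravel().tolist(),
            "history": [[x, r] for x, r in track.history],
            "stimulus_range": list(track.stimulus_range),
            "initial_stimulus_ms": track.initial_stimulus_ms,
            "candidates": track.candidates.tolist(),
        }
    )


def track_from_json(payload: str) -> TrackState:
    d = json.loads(payload)
    grid = PosteriorGrid(
        np.asarray(d["alpha"]),
        np.asarray(d["beta"]),
        np.asarray(d["lam"]),
        np.asarray(d["log_posterior"]),
    )
    return TrackState(
        grid=grid,
        history=[(float(x), int(r)) for x, r in d["history"]],
        stimulus_range=tuple(d["stimulus_range"]),
        initial_stimulus_ms=float(d["initial_stimulus_ms"]),
        candidates=np.asarray(d["candidates"]),
    )
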