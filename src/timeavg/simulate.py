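"""Synthetic observers and sessions.

Simulates complete two-phase comparison sessions: on every trial a
random permutation of one set's intervals is internally encoded with
scalar noise, averaged under the observer's scheme, biased, and
compared against an adaptively chosen comparison interval.  Three
adaptive tracks (one per set) run concurrently, randomly interleaved.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .adaptive import PosteriorGrid, TrackState, select_next_stimulus, update_posterior
from .models import (
    SCHEMES,
    SET1,
    SET2,
    SET3,
    IntervalSet,
    ObserverParams,
    sample_ensemble_average,
)

__all__ = [
    "TrialRecord",
    "SessionDesign",
    "CohortRanges",
    "simulate_response",
    "simulate_session",
    "generate_cohort",
    "trials_to_frame",
    "frame_to_trials",
    "write_trials_csv",
    "read_trials_csv",
    "write_truth_csv",
]


@dataclass(frozen=True)
class TrialRecord:
    """One comparison trial of a simulated session."""

    observer_id: str
    trial_index: int  # 1-based, in presentation order
    set_id: str
    presented_order: tuple[float, ...]
    comparison_ms: float
    response: int  # 1 = "comparison longer", 0 = "comparison shorter"
    internal_average_ms: float  # latent; retained for testing only

    def __post_init__(self) -> None:
        if self.comparison_ms <= 0:
            raise ValueError("comparison_ms must be positive")
        if self.response not in (0, 1):
            raise ValueError("response must be 0 or 1")


@dataclass(frozen=True)
class SessionDesign:
    """Session layout: which sets, how many trials each, starting stimulus."""

    sets: tuple[IntervalSet, ...] = (SET1, SET2, SET3)
    trials_per_set: int = 80
    initial_comparison_ms: float = 500.0

    def __post_init__(self) -> None:
        if self.trials_per_set < 1:
            raise ValueError("trials_per_set must be >= 1")
        ids = [s.set_id for s in self.sets]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate set_id in design")

    @property
    def n_trials(self) -> int:
        return self.trials_per_set * len(self.sets)


def _simulate_response_latent(
    interval_set: IntervalSet,
    comparison_ms: float,
    obs: ObserverParams,
    rng: np.random.Generator,
) -> tuple[int, float]:
    if comparison_ms <= 0:
        raise ValueError("comparison_ms must be positive")
    internal = sample_ensemble_average(interval_set, obs, rng)
    if obs.lapse_rate > 0 and rng.random() < obs.lapse_rate:
        return int(rng.random() < 0.5), internal
    return int(comparison_ms > internal), internal


def simulate_response(
    interval_set: IntervalSet,
    comparison_ms: float,
    obs: ObserverParams,
    rng: np.random.Generator,
) -> int:
    """Binary judgement "comparison longer" (1) vs "shorter" (0).

    With probability ``lapse_rate`` the response is a fair coin flip;
    otherwise it is 1 iff the comparison exceeds a fresh draw of the
    observer's internal ensemble average.
    """
    return _simulate_response_latent(interval_set, comparison_ms, obs, rng)[0]


def simulate_session(
    obs: ObserverParams,
    design: SessionDesign,
    rng: np.random.Generator,
    observer_id: str = "obs",
    grid: Optional[PosteriorGrid] = None,
    mode: str = "variance-min",
) -> list[TrialRecord]:
    """Run one full session and return its trials in presentation order.

    One adaptive track per set, interleaved via a uniformly random
    shuffle of the per-set trial budget so that all tracks finish
    together.  Each trial presents a fresh random permutation of its
    set's intervals.  Fully reproducible given ``rng``.
    """
    if grid is None:
        grid = PosteriorGrid.default()
    tracks: dict[str, TrackState] = {}
    for s in design.sets:
        g = PosteriorGrid(
            grid.alpha.copy(), grid.beta.copy(), grid.lam.copy(), grid.log_posterior.copy()
        )
        tracks[s.set_id] = TrackState(grid=g, initial_stimulus_ms=design.initial_comparison_ms)

    order = np.repeat(np.arange(len(design.sets)), design.trials_per_set)
    order = rng.permutation(order)

    records: list[TrialRecord] = []
    for trial_index, set_idx in enumerate(order, start=1):
        iset = design.sets[set_idx]
        track = tracks[iset.set_id]
        comparison = select_next_stimulus(track, mode=mode)
        presented = tuple(float(v) for v in rng.permutation(iset.intervals))
        response, internal = _simulate_response_latent(iset, comparison, obs, rng)
        update_posterior(track, comparison, response)
        records.append(
            TrialRecord(
                observer_id=observer_id,
                trial_index=trial_index,
                set_id=iset.set_id,
                presented_order=presented,
                comparison_ms=comparison,
                response=response,
                internal_average_ms=internal,
            )
        )
    return records


@dataclass(frozen=True)
class CohortRanges:
    """Uniform sampling ranges for cohort observer parameters.

    Log-unit fields apply to geometric observers, ms fields to the
    linear-scale schemes.
    """

    weber_fraction: tuple[float, float] = (0.05, 0.2)
    log_noise_sd: tuple[float, float] = (0.05, 0.2)
    bias_mean_ms: tuple[float, float] = (-80.0, 0.0)
    bias_mean_log: tuple[float, float] = (-0.1, 0.0)
    bias_sd_ms: tuple[float, float] = (0.0, 20.0)
    bias_sd_log: tuple[float, float] = (0.0, 0.03)
    lapse_rate: tuple[float, float] = (0.0, 0.05)

    def sample(self, scheme: str, rng: np.random.Generator, seed: int) -> ObserverParams:
        u = lambda lo_hi: float(rng.uniform(*lo_hi))
        if scheme == "geometric":
            return ObserverParams(
                scheme=scheme,
                log_noise_sd=u(self.log_noise_sd),
                bias_mean=u(self.bias_mean_log),
                bias_sd=u(self.bias_sd_log),
                lapse_rate=u(self.lapse_rate),
                rng_seed=seed,
            )
        return ObserverParams(
            scheme=scheme,
            weber_fraction=u(self.weber_fraction),
            bias_mean=u(self.bias_mean_ms),
            bias_sd=u(self.bias_sd_ms),
            lapse_rate=u(self.lapse_rate),
            rng_seed=seed,
        )


def _allocate_counts(n: int, scheme_mix: Mapping[str, float]) -> dict[str, int]:
    # largest-remainder apportionment; deterministic tie-break by name
    items = sorted(scheme_mix.items())
    if any(p < 0 for _, p in items) or abs(sum(p for _, p in items) - 1.0) > 1e-9:
        raise ValueError("scheme_mix proportions must be non-negative and sum to 1")
    for scheme, _ in items:
        if scheme not in SCHEMES:
            raise ValueError(f"unknown scheme {scheme!r}")
    raw = {s: n * p for s, p in items}
    counts = {s: int(np.floor(r)) for s, r in raw.items()}
    leftover = n - sum(counts.values())
    by_remainder = sorted(items, key=lambda kv: (-(raw[kv[0]] - counts[kv[0]]), kv[0]))
    for s, _ in by_remainder[:leftover]:
        counts[s] += 1
    return counts


def generate_cohort(
    n_observers: int,
    scheme_mix: Mapping[str, float],
    param_ranges: Optional[CohortRanges] = None,
    rng: Optional[np.random.Generator] = None,
    design: Optional[SessionDesign] = None,
    grid: Optional[PosteriorGrid] = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate a cohort of virtual observers.

    Returns ``(trials, truth)``: the concatenated trial table and a
    sidecar of ground-truth observer parameters keyed by observer_id.
    Scheme counts follow ``scheme_mix`` by largest-remainder rounding.
    """
    if n_observers < 0:
        raise ValueError("n_observers must be non-negative")
    if rng is None:
        rng = np.random.default_rng()
    if param_ranges is None:
        param_ranges = CohortRanges()
    if design is None:
        design = SessionDesign()

    counts = _allocate_counts(n_observers, scheme_mix)
    schemes = [s for s in sorted(counts) for _ in range(counts[s])]

    all_records: list[TrialRecord] = []
    truth_rows = []
    for i, scheme in enumerate(schemes):
        obs_id = f"obs{i + 1:03d}"
        seed = int(rng.integers(0, 2**31 - 1))
        obs = param_ranges.sample(scheme, rng, seed)
        session_rng = np.random.default_rng(seed)
        all_records.extend(
            simulate_session(obs, design, session_rng, observer_id=obs_id, grid=grid)
        )
        truth_rows.append(
            {
                "observer_id": obs_id,
                "scheme": obs.scheme,
                "weber_fraction": obs.weber_fraction,
                "log_noise_sd": obs.log_noise_sd,
                "bias_mean": obs.bias_mean,
                "bias_sd": obs.bias_sd,
                "lapse_rate": obs.lapse_rate,
                "rng_seed": obs.rng_seed,
            }
        )

    truth_cols = [
        "observer_id", "scheme", "weber_fraction", "log_noise_sd",
        "bias_mean", "bias_sd", "lapse_rate", "rng_seed",
    ]
    return trials_to_frame(all_records), pd.DataFrame(truth_rows, columns=truth_cols)


_TRIAL_COLUMNS = [
    "observer_id", "trial_index", "set_id",
    "i1", "i2", "i3", "i4", "i5",
    "comparison_ms", "response",
]


def trials_to_frame(records: Sequence[TrialRecord], include_latent: bool = True) -> pd.DataFrame:
    """Flatten trial records into the canonical trial table."""
    rows = []
    for r in records:
        row = {
            "observer_id": r.observer_id,
            "trial_index": r.trial_index,
            "set_id": r.set_id,
        }
        row.update({f"i{k + 1}": v for k, v in enumerate(r.presented_order)})
        row["comparison_ms"] = r.comparison_ms
        row["response"] = r.response
        if include_latent:
            row["internal_average_ms"] = r.internal_average_ms
        rows.append(row)
    cols = _TRIAL_COLUMNS + (["internal_average_ms"] if include_latent else [])
    return pd.DataFrame(rows, columns=cols)


def frame_to_trials(df: pd.DataFrame) -> list[TrialRecord]:
    records = []
    for row in df.itertuples(index=False):
        presented = tuple(
            float(getattr(row, f"i{k}")) for k in range(1, 6) if hasattr(row, f"i{k}")
        )
        records.append(
            TrialRecord(
                observer_id=str(row.observer_id),
                trial_index=int(row.trial_index),
                set_id=str(row.set_id),
                presented_order=presented,
                comparison_ms=float(row.comparison_ms),
                response=int(row.response),
                internal_average_ms=float(getattr(row, "internal_average_ms", np.nan)),
            )
        )
    return records


def write_trials_csv(df: pd.DataFrame, path, include_latent: bool = False) -> None:
    """Write the trial table; the latent column is dropped by default."""
    out = df if include_latent else df[[c for c in df.columns if c != "internal_average_ms"]]
    out.to_csv(path, index=False)


def read_trials_csv(path) -> pd.DataFrame:
    return pd.read_csv(path)


def write_truth_csv(truth: pd.DataFrame, path) -> None:
    truth.to_csv(path, index=False)
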