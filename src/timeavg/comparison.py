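"""Averaging-model fits to observed PSEs and observer classification.

Given per-observer, per-set PSEs, fits each averaging scheme's bias to
the grand-mean PSEs (closed form for the linear schemes and the
geometric scheme, grid search for the noisy harmonic model), classifies
individual observers in the (PSE1 - PSE2, PSE1 - PSE3) difference
plane, and assembles the full end-to-end analysis report.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from . import fitting
from .models import (
    BUILTIN_SETS,
    IntervalSet,
    ModelPrediction,
    ObserverParams,
    arithmetic_mean,
    geometric_mean,
    harmonic_mean,
    noise_free_prediction,
    sample_ensemble_averages,
    scheme_mean,
    weighted_mean,
)

__all__ = [
    "ClassificationResult",
    "AnalysisError",
    "grand_means",
    "ideal_points",
    "classify_observer",
    "classify_all",
    "fit_bias",
    "grid_search_harmonic",
    "default_harmonic_grid",
    "run_full_analysis",
]

GEOMETRIC_LABEL = "geometric-oriented"
ARITHMETIC_LABEL = "arithmetic-oriented"


class AnalysisError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


@dataclass(frozen=True)
class ClassificationResult:
    observer_id: str
    delta_12: float
    delta_13: float
    label: str


def grand_means(pse_table: pd.DataFrame) -> pd.DataFrame:
    """Per-set grand mean PSE/JND with standard errors."""
    g = pse_table.groupby("set_id")
    out = pd.DataFrame(
        {
            "pse_mean": g["pse"].mean(),
            "pse_sem": g["pse"].sem(),
            "jnd_mean": g["jnd"].mean(),
            "jnd_sem": g["jnd"].sem(),
            "n": g["pse"].count(),
        }
    )
    return out.reset_index()


def ideal_points(
    sets: Sequence[IntervalSet],
) -> tuple[tuple[float, float], tuple[float, float]]:
    """Ideal (delta_12, delta_13) locations of pure arithmetic and geometric averaging."""
    if len(sets) != 3:
        raise ValueError("exactly three interval sets are required")
    ams = [arithmetic_mean(s.intervals) for s in sets]
    gms = [geometric_mean(s.intervals) for s in sets]
    arith = (ams[0] - ams[1], ams[0] - ams[2])
    geo = (gms[0] - gms[1], gms[0] - gms[2])
    return arith, geo


def classify_observer(
    delta_12: float,
    delta_13: float,
    ideal: tuple[tuple[float, float], tuple[float, float]],
) -> str:
    """Label an observer by the nearer ideal point in the difference plane.

    Equivalent to the side of the perpendicular bisector of the segment
    joining the two ideal points; exact ties go to arithmetic-oriented.
    """
    (ax, ay), (gx, gy) = ideal
    d_arith = (delta_12 - ax) ** 2 + (delta_13 - ay) ** 2
    d_geo = (delta_12 - gx) ** 2 + (delta_13 - gy) ** 2
    return GEOMETRIC_LABEL if d_geo < d_arith else ARITHMETIC_LABEL


def classify_all(pse_table: pd.DataFrame, sets: Sequence[IntervalSet]) -> pd.DataFrame:
    """Classify every observer with PSEs for all three sets."""
    ideal = ideal_points(sets)
    id1, id2, id3 = (s.set_id for s in sets)
    wide = pse_table.pivot(index="observer_id", columns="set_id", values="pse")
    rows = []
    for obs_id, row in wide.iterrows():
        if row[[id1, id2, id3]].isna().any():
            continue
        d12 = float(row[id1] - row[id2])
        d13 = float(row[id1] - row[id3])
        rows.append(
            {
                "observer_id": obs_id,
                "delta_12": d12,
                "delta_13": d13,
                "label": classify_observer(d12, d13, ideal),
            }
        )
    return pd.DataFrame(rows, columns=["observer_id", "delta_12", "delta_13", "label"])


def fit_bias(
    scheme: str,
    observed: Mapping[str, float],
    sets: Sequence[IntervalSet],
) -> ModelPrediction:
    """Closed-form bias fit of a noise-free averaging model to observed PSEs.

    Minimizes the sum of squared errors over the constant bias: the
    mean residual in ms for the linear-scale schemes, and the mean log
    residual for the geometric scheme (whose bias is multiplicative).
    """
    missing = [s.set_id for s in sets if s.set_id not in observed]
    if missing:
        raise ValueError(f"observed PSEs missing for sets: {missing}")
    obs = np.array([float(observed[s.set_id]) for s in sets])
    base = np.array([scheme_mean(scheme, s.intervals) for s in sets])
    if scheme == "geometric":
        mu_b = float(np.mean(np.log(obs) - np.log(base)))
        pred = base * np.exp(mu_b)
    else:
        mu_b = float(np.mean(obs - base))
        pred = base + mu_b
    sse = float(np.sum((pred - obs) ** 2))
    return ModelPrediction(
        scheme=scheme,
        per_set_pse={s.set_id: float(p) for s, p in zip(sets, pred)},
        fitted_bias=mu_b,
        sse=sse,
    )


def default_harmonic_grid(
    wf_step: float = 0.025, mub_step: float = 5.0, sigma_step: float = 10.0
) -> dict[str, np.ndarray]:
    """Default harmonic-model search grid over (w_f, mu_b, sigma)."""
    return {
        "weber_fraction": np.arange(0.0, 0.3 + 1e-9, wf_step),
        "bias_mean": np.arange(-200.0, 50.0 + 1e-9, mub_step),
        "bias_sd": np.arange(0.0, 60.0 + 1e-9, sigma_step),
    }


def grid_search_harmonic(
    observed: Mapping[str, float],
    sets: Sequence[IntervalSet],
    grid: Optional[Mapping[str, Sequence[float]]] = None,
    n_sim: int = 20_000,
    seed: int = 0,
) -> ModelPrediction:
    """Fit the noisy harmonic model by exhaustive grid search.

    The harmonic average is a non-linear reduction, so its predicted
    median shifts with the scalar noise; every grid node is therefore
    evaluated by Monte Carlo.  All nodes reuse the same random numbers
    (a fresh generator seeded identically per node), which stabilizes
    the argmin; ties break toward the lexicographically smallest
    parameter tuple.  Deterministic given ``seed`` and the grid.
    """
    if grid is None:
        grid = default_harmonic_grid()
    wf_grid = np.sort(np.asarray(grid["weber_fraction"], dtype=float))
    mub_grid = np.sort(np.asarray(grid["bias_mean"], dtype=float))
    sd_grid = np.sort(np.asarray(grid["bias_sd"], dtype=float))
    if wf_grid.size == 0 or mub_grid.size == 0 or sd_grid.size == 0:
        raise ValueError("empty grid")
    missing = [s.set_id for s in sets if s.set_id not in observed]
    if missing:
        raise ValueError(f"observed PSEs missing for sets: {missing}")
    obs = np.array([float(observed[s.set_id]) for s in sets])

    # The constant part of the bias shifts every draw by mu_b exactly, so
    # the Monte Carlo only needs to run once per (w_f, bias_sd, set); the
    # mu_b axis is then a deterministic shift of the cached medians.
    bias_rng = np.random.default_rng(seed)
    z_bias = bias_rng.standard_normal(n_sim)
    base_median = np.empty((wf_grid.size, sd_grid.size, len(sets)))
    for i, wf in enumerate(wf_grid):
        for j, s in enumerate(sets):
            params = ObserverParams(scheme="harmonic", weber_fraction=float(wf))
            rng = np.random.default_rng(seed)  # common random numbers across nodes
            draws = (
                sample_ensemble_averages(s, params, rng, n_sim)
                if wf > 0
                else np.full(n_sim, noise_free_prediction(s, params))
            )
            for k, sd in enumerate(sd_grid):
                base_median[i, k, j] = float(np.median(draws + sd * z_bias))

    best = None
    for i, wf in enumerate(wf_grid):
        for k, sd in enumerate(sd_grid):
            for mu_b in mub_grid:
                pred = base_median[i, k] + mu_b
                if np.any(pred <= 0):
                    continue
                sse = float(np.sum((pred - obs) ** 2))
                key = (sse, float(wf), float(mu_b), float(sd))
                if best is None or key < best[0]:
                    best = (key, pred, float(wf), float(mu_b), float(sd))
    if best is None:
        raise ValueError("no admissible grid node (all predictions non-positive)")
    (sse, *_), pred, wf, mu_b, sd = best
    return ModelPrediction(
        scheme="harmonic",
        per_set_pse={s.set_id: float(p) for s, p in zip(sets, pred)},
        fitted_bias=mu_b,
        sse=sse,
        extra_params={"weber_fraction": wf, "bias_sd": sd},
    )


def _noise_free_pattern(sets: Sequence[IntervalSet]) -> dict[str, dict[str, float]]:
    fns = {
        "arithmetic": arithmetic_mean,
        "geometric": geometric_mean,
        "harmonic": harmonic_mean,
        "weighted": weighted_mean,
    }
    return {
        scheme: {s.set_id: float(fn(s.intervals)) for s in sets} for scheme, fn in fns.items()
    }


def run_full_analysis(
    trials: pd.DataFrame,
    sets: Optional[Sequence[IntervalSet]] = None,
    variant: str = "logistic",
    harmonic_grid: Optional[Mapping[str, Sequence[float]]] = None,
    harmonic_n_sim: int = 20_000,
    n_starts: int = 5,
    seed: int = 0,
) -> dict:
    """End-to-end analysis of a trial table.

    Stages: psychometric fits per observer x set -> PSE/JND table ->
    per-model bias fits and SSEs -> difference-plane classification ->
    JSON-serializable report.  Raises :class:`AnalysisError` with a
    stage tag on failure; an empty trial table is rejected outright.
    """
    if trials is None or len(trials) == 0:
        raise AnalysisError("input: empty trial table")
    if sets is None:
        sets = [BUILTIN_SETS[sid] for sid in sorted(trials["set_id"].unique())]

    try:
        fits = fitting.fit_observers(trials, variant=variant, n_starts=n_starts, seed=seed)
    except Exception as exc:  # pragma: no cover - defensive
        raise AnalysisError(f"psychometric-fitting: {exc}") from exc
    ok = fits[fits["error"].isna()]
    if ok.empty:
        raise AnalysisError("psychometric-fitting: no observer x set fit converged")
    pse_table = ok[["observer_id", "set_id", "pse", "jnd"]].reset_index(drop=True)

    try:
        grand = grand_means(pse_table)
        observed = dict(zip(grand["set_id"], grand["pse_mean"]))
        predictions = {
            scheme: fit_bias(scheme, observed, sets)
            for scheme in ("arithmetic", "geometric", "weighted")
        }
        predictions["harmonic"] = grid_search_harmonic(
            observed, sets, grid=harmonic_grid, n_sim=harmonic_n_sim, seed=seed
        )
    except Exception as exc:
        raise AnalysisError(f"model-fitting: {exc}") from exc
    best_model = min(sorted(predictions), key=lambda k: predictions[k].sse)

    try:
        classes = classify_all(pse_table, sets)
    except Exception as exc:
        raise AnalysisError(f"classification: {exc}") from exc
    n_geo = int((classes["label"] == GEOMETRIC_LABEL).sum())
    n_ari = int((classes["label"] == ARITHMETIC_LABEL).sum())

    arith_pt, geo_pt = ideal_points(sets)
    return {
        "n_observers": int(trials["observer_id"].nunique()),
        "n_trials": int(len(trials)),
        "psychometric_variant": variant,
        "pse_table": pse_table.to_dict(orient="records"),
        "grand_means": grand.to_dict(orient="records"),
        "set_statistics": _noise_free_pattern(sets),
        "ideal_points": {"arithmetic": list(arith_pt), "geometric": list(geo_pt)},
        "model_fits": {
            scheme: {
                "per_set_pse": pred.per_set_pse,
                "fitted_bias": pred.fitted_bias,
                "sse": pred.sse,
                "extra_params": pred.extra_params,
            }
            for scheme, pred in predictions.items()
        },
        "best_model": best_model,
        "classification": classes.to_dict(orient="records"),
        "classification_counts": {GEOMETRIC_LABEL: n_geo, ARITHMETIC_LABEL: n_ari},
    }
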