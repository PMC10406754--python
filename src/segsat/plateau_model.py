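"""Exponential-plateau learning-curve model and dataset-size plateau estimation.

Test segmentation performance as a function of training-set size is modelled
by the three-parameter exponential-plateau law

    D(x) = D_max - (D_max - D_0) * exp(-k * x)

where ``x`` is the number of training+validation images, ``D_max`` is the
maximum achievable Dice, ``D_0`` the minimum Dice (the x=0 intercept) and
``k`` the exponential rate constant.  The *plateau point* is the smallest
integer dataset size at which the fitted curve comes within a tolerance
(default 0.01 Dice) of ``D_max``; it has the closed form

    plateau_x = ceil( ln((D_max - D_0) / tol) / k )

whenever ``D_max - D_0 > tol``, else 1.

Parameters are fit by bounded nonlinear least squares.  Because Dice is
bounded, the fit is constrained to 0 <= D_0, D_max <= 1 and k in (0, 1];
an unconstrained fit can extrapolate past Dice 1.  A plateau point beyond
the largest observed size is flagged ``extrapolated`` — the estimate then
rests on the model shape, not on data, and deserves less confidence.

Stability of the plateau estimate is probed by refitting after progressively
dropping all observations at the largest remaining size: large jumps in
``D_max`` between successive fits mean the curve has not yet stabilised.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

__all__ = [
    "CurveObservation",
    "PlateauFit",
    "StabilityStep",
    "StabilityReport",
    "predict_dice",
    "fit_plateau",
    "plateau_point",
    "stability_analysis",
    "quartile_curve_analysis",
    "read_curve_csv",
    "write_curve_csv",
    "DEFAULT_TOLERANCE",
    "DEFAULT_GAP_THRESHOLD",
    "K_BOUNDS",
]

DEFAULT_TOLERANCE = 0.01
#: Largest |Delta D_max| between successive dropout fits still called stable.
DEFAULT_GAP_THRESHOLD = 0.02
#: Box bounds on the rate constant (per image).
K_BOUNDS = (1e-6, 1.0)

CURVE_CSV_COLUMNS = ["x", "dice", "kind", "fold_id"]


@dataclass(frozen=True)
class CurveObservation:
    """One (dataset size, Dice) point of a learning curve.

    ``kind`` distinguishes the fused five-fold ensemble score at a size
    (``"ensemble"``) from an individual fold's score (``"fold"``).
    """

    x: int
    dice: float
    kind: Literal["ensemble", "fold"] = "ensemble"
    fold_id: int | None = None

    def __post_init__(self) -> None:
        if self.x < 1:
            raise ValueError(f"dataset size must be >= 1, got {self.x}")
        if not 0.0 <= self.dice <= 1.0:
            raise ValueError(f"dice must be in [0, 1], got {self.dice}")
        if self.kind not in ("ensemble", "fold"):
            raise ValueError(f"kind must be 'ensemble' or 'fold', got {self.kind!r}")


@dataclass(frozen=True)
class PlateauFit:
    """Fitted exponential-plateau parameters plus the derived plateau point."""

    d_max: float
    d_zero: float
    k: float
    tolerance: float = DEFAULT_TOLERANCE
    plateau_x: int = 1
    residual_sum_squares: float = 0.0
    n_points: int = 0
    converged: bool = True
    flat_curve: bool = False
    extrapolated: bool = False
    max_observed_x: int | None = None

    def to_dict(self) -> dict:
        return {
            "d_max": self.d_max,
            "d_zero": self.d_zero,
            "k": self.k,
            "tolerance": self.tolerance,
            "plateau_x": self.plateau_x,
            "rss": self.residual_sum_squares,
            "n_points": self.n_points,
            "converged": self.converged,
            "flat_curve": self.flat_curve,
            "extrapolated": self.extrapolated,
            "max_observed_x": self.max_observed_x,
        }


@dataclass(frozen=True)
class StabilityStep:
    dropped_sizes: tuple[int, ...]
    fit: PlateauFit


@dataclass(frozen=True)
class StabilityReport:
    """Successive plateau fits under dropout of the largest dataset sizes."""

    steps: tuple[StabilityStep, ...]
    max_dmax_gap: float
    gap_threshold: float
    stable: bool

    def to_dict(self) -> dict:
        return {
            "steps": [
                {"dropped_sizes": list(s.dropped_sizes), **s.fit.to_dict()}
                for s in self.steps
            ],
            "max_dmax_gap": self.max_dmax_gap,
            "gap_threshold": self.gap_threshold,
            "stable": self.stable,
        }


def predict_dice(fit: PlateauFit, x) -> float | np.ndarray:
    """Evaluate the fitted curve D(x) = D_max - (D_max - D_0)·e^(-kx).

    Strictly increasing in x when ``d_max > d_zero`` and bounded in
    ``[d_zero, d_max]``.  Accepts scalars or arrays, x >= 0.
    """
    x = np.asarray(x, dtype=float)
    out = fit.d_max - (fit.d_max - fit.d_zero) * np.exp(-fit.k * x)
    return float(out) if out.ndim == 0 else out


def _curve(x, d_max, d_zero, k):
    return d_max - (d_max - d_zero) * np.exp(-k * x)


def _closed_form_plateau(d_max: float, d_zero: float, k: float, tolerance: float) -> int:
    gap = d_max - d_zero
    if gap <= tolerance:
        return 1
    return max(1, math.ceil(math.log(gap / tolerance) / k))


def _initial_guess(x: np.ndarray, y: np.ndarray) -> tuple[float, float, float]:
    """Deterministic starting point: asymptote from the best observed Dice,
    intercept from the smallest size, rate from a log-linear regression of
    the residual gap ln(d_max0 + 1e-3 - dice) on x."""
    d_max0 = min(float(y.max()), 1.0)
    d_zero0 = float(y[np.argmin(x)])
    resid = np.log(np.maximum(d_max0 + 1e-3 - y, 1e-12))
    slope = np.polyfit(x, resid, 1)[0] if len(np.unique(x)) > 1 else -0.01
    k0 = float(np.clip(-slope, K_BOUNDS[0] * 10, K_BOUNDS[1]))
    return d_max0, min(d_zero0, d_max0), k0


def fit_plateau(
    observations: Sequence[CurveObservation],
    tolerance: float = DEFAULT_TOLERANCE,
    use: Literal["ensemble_only", "all_points"] = "ensemble_only",
) -> PlateauFit:
    """Fit (D_max, D_0, k) to learning-curve observations by least squares.

    Parameters
    ----------
    observations
        Curve points; by default only ``kind == "ensemble"`` points enter the
        fit (``use="all_points"`` includes fold points, unweighted).
    tolerance
        Dice tolerance defining the plateau point.
    use
        Which observation kinds to fit on.

    Requires at least 3 observations at 3 distinct sizes (three free
    parameters).  If every Dice value is identical, the flat-curve degenerate
    fit ``d_max = d_zero`` is returned with ``plateau_x = 1`` and
    ``flat_curve=True`` instead of invoking the optimiser.
    """
    if use not in ("ensemble_only", "all_points"):
        raise ValueError(f"use must be 'ensemble_only' or 'all_points', got {use!r}")
    if use == "ensemble_only":
        selected = [o for o in observations if o.kind == "ensemble"]
        # fall back to every point when no ensemble observations are tagged
        if not selected:
            selected = list(observations)
    else:
        selected = list(observations)
    if not selected:
        raise ValueError("no observations to fit")
    x = np.array([o.x for o in selected], dtype=float)
    y = np.array([o.dice for o in selected], dtype=float)
    n_distinct = len(np.unique(x))
    if n_distinct < 3:
        raise ValueError(
            f"need observations at >= 3 distinct dataset sizes, got {n_distinct}"
        )
    max_x = int(x.max())

    if np.ptp(y) < 1e-12:
        level = float(y[0])
        return PlateauFit(
            d_max=level,
            d_zero=level,
            k=K_BOUNDS[0],
            tolerance=tolerance,
            plateau_x=1,
            residual_sum_squares=0.0,
            n_points=len(selected),
            converged=True,
            flat_curve=True,
            extrapolated=False,
            max_observed_x=max_x,
        )

    p0 = _initial_guess(x, y)
    lower = [0.0, 0.0, K_BOUNDS[0]]
    upper = [1.0, 1.0, K_BOUNDS[1]]
    p0 = tuple(np.clip(p0, lower, upper))
    converged = True
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            popt, _ = curve_fit(
                _curve, x, y, p0=p0, bounds=(lower, upper), maxfev=20000,
                xtol=1e-12, ftol=1e-12, gtol=1e-12,
            )
    except RuntimeError:
        converged = False
        popt = np.asarray(p0)
    d_max, d_zero, k = (float(v) for v in popt)
    if d_zero > d_max:
        # decreasing curve: not a learning curve under this model
        converged = False
    rss = float(np.sum((y - _curve(x, d_max, d_zero, k)) ** 2))
    plateau_x = _closed_form_plateau(d_max, d_zero, k, tolerance)
    return PlateauFit(
        d_max=d_max,
        d_zero=d_zero,
        k=k,
        tolerance=tolerance,
        plateau_x=plateau_x,
        residual_sum_squares=rss,
        n_points=len(selected),
        converged=converged,
        flat_curve=False,
        extrapolated=plateau_x > max_x,
        max_observed_x=max_x,
    )


def plateau_point(fit: PlateauFit, tolerance: float | None = None) -> int:
    """Smallest positive integer x with ``d_max - D(x) <= tolerance``.

    Uses the closed form ``ceil(ln((d_max - d_zero)/tol)/k)``; flat curves
    return 1.  Passing ``tolerance`` overrides the fit's stored value.
    """
    tol = fit.tolerance if tolerance is None else tolerance
    if tol <= 0:
        raise ValueError("tolerance must be positive")
    return _closed_form_plateau(fit.d_max, fit.d_zero, fit.k, tol)


def stability_analysis(
    observations: Sequence[CurveObservation],
    max_drops: int = 2,
    tolerance: float = DEFAULT_TOLERANCE,
    gap_threshold: float = DEFAULT_GAP_THRESHOLD,
    use: Literal["ensemble_only", "all_points"] = "ensemble_only",
) -> StabilityReport:
    """Refit the plateau model while progressively dropping the largest sizes.

    Fit 0 uses all observations; fit i+1 removes every observation at the
    largest size remaining after fit i, up to ``max_drops`` times.  The report
    carries each fit, the largest |Delta d_max| between successive fits, and a
    ``stable`` verdict under ``gap_threshold``.
    """
    if max_drops < 0:
        raise ValueError("max_drops must be >= 0")
    remaining = list(observations)
    dropped: list[int] = []
    steps: list[StabilityStep] = []
    for _ in range(max_drops + 1):
        fit = fit_plateau(remaining, tolerance=tolerance, use=use)
        steps.append(StabilityStep(dropped_sizes=tuple(dropped), fit=fit))
        if len(steps) == max_drops + 1:
            break
        largest = max(o.x for o in remaining)
        remaining = [o for o in remaining if o.x != largest]
        dropped = dropped + [largest]
        if len({o.x for o in remaining}) < 3:
            raise ValueError(
                f"dropping size {largest} leaves fewer than 3 distinct sizes"
            )
    gaps = [
        abs(steps[i + 1].fit.d_max - steps[i].fit.d_max)
        for i in range(len(steps) - 1)
    ]
    max_gap = max(gaps) if gaps else 0.0
    return StabilityReport(
        steps=tuple(steps),
        max_dmax_gap=max_gap,
        gap_threshold=gap_threshold,
        stable=max_gap <= gap_threshold,
    )


def quartile_curve_analysis(
    case_table: pd.DataFrame,
    volume_key: str = "ref_volume_ml",
    x_key: str = "x",
    dice_key: str = "dice",
    case_key: str = "case_id",
    tolerance: float = DEFAULT_TOLERANCE,
) -> dict[int, dict]:
    """Per-quartile learning curves by reference structure volume.

    Test cases are ranked by their reference volume (ties broken
    deterministically by case id) and split into four near-equal groups;
    quartile 1 holds the smallest structures.  Within each quartile the mean
    Dice per dataset size gives one learning curve, which is then fit with
    the plateau model.  Small structures typically plateau lower and later.

    ``case_table`` needs one row per (case, dataset size) with the case's
    Dice at that size and its reference volume (constant across sizes for a
    fixed test set).

    Returns ``{quartile: {"cases": [...], "observations": [...], "fit": PlateauFit}}``.
    """
    required = {volume_key, x_key, dice_key, case_key}
    missing = required - set(case_table.columns)
    if missing:
        raise ValueError(f"case table missing columns {sorted(missing)}")
    per_case = (
        case_table.groupby(case_key, sort=True)[volume_key].first().reset_index()
    )
    per_case = per_case.sort_values(
        [volume_key, case_key], kind="mergesort"
    ).reset_index(drop=True)
    quartile_groups = np.array_split(per_case[case_key].to_numpy(), 4)

    results: dict[int, dict] = {}
    for q, cases in enumerate(quartile_groups, start=1):
        sub = case_table[case_table[case_key].isin(cases)]
        means = sub.groupby(x_key)[dice_key].mean().reset_index()
        obs = [
            CurveObservation(x=int(row[x_key]), dice=float(row[dice_key]))
            for _, row in means.iterrows()
        ]
        if len(obs) < 3:
            raise ValueError(
                f"quartile {q} has observations at only {len(obs)} sizes; need >= 3"
            )
        results[q] = {
            "cases": list(cases),
            "observations": obs,
            "fit": fit_plateau(obs, tolerance=tolerance),
        }
    return results


def read_curve_csv(path: str | Path) -> list[CurveObservation]:
    """Read learning-curve observations from CSV (columns x,dice,kind,fold_id)."""
    frame = pd.read_csv(path)
    missing = {"x", "dice"} - set(frame.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    obs = []
    for i, row in frame.iterrows():
        try:
            obs.append(
                CurveObservation(
                    x=int(row["x"]),
                    dice=float(row["dice"]),
                    kind=str(row.get("kind", "ensemble"))
                    if "kind" in frame.columns and pd.notna(row.get("kind"))
                    else "ensemble",
                    fold_id=int(row["fold_id"])
                    if "fold_id" in frame.columns and pd.notna(row.get("fold_id"))
                    else None,
                )
            )
        except (ValueError, TypeError) as exc:
            raise ValueError(f"{path}: bad observation at row {i + 2}: {exc}") from exc
    return obs


def write_curve_csv(observations: Sequence[CurveObservation], path: str | Path) -> None:
    frame = pd.DataFrame(
        [
            {"x": o.x, "dice": o.dice, "kind": o.kind, "fold_id": o.fold_id}
            for o in observations
        ],
        columns=CURVE_CSV_COLUMNS,
    )
    frame.to_csv(path, index=False)
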