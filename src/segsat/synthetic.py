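"""Seeded generators for every input the toolkit consumes.

Three families of synthetic data, all fully deterministic under a fixed seed:

* 3D kidney/tumor label phantoms — two kidney ellipsoids plus a tumor sphere
  whose label takes precedence where it carves into parenchyma (the
  exophytic/endophytic situation);
* controllably degraded predictions — copies of a phantom whose Dice against
  the original hits a requested target, by boundary flipping, erosion,
  dilation, or outright deletion of the structure (the missed-tumor case);
* learning-curve observations drawn from a known exponential-plateau law with
  additive truncated-Gaussian fold noise, the forward model of the fitting
  code.

The phantoms are label volumes only (no intensities): every downstream
operation — metrics, ensembling, curve fitting — consumes labels, so
intensity realism would buy nothing here.  Geometry is specified in
millimetres; voxel centres sit at index × spacing.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import ndimage

from .label_volumes import LabelVolume
from .plateau_model import CurveObservation
from .seg_metrics import binary_counts, dice as dice_score

__all__ = [
    "PhantomSpec",
    "CurveSimSpec",
    "make_phantom",
    "degrade",
    "simulate_folds",
    "simulate_learning_curve",
    "DEGRADE_MODES",
    "DEGRADE_TOLERANCE",
]

DEGRADE_MODES = ("boundary_flip", "erode", "dilate", "delete_component")

#: Acceptable |achieved − target| Dice after degradation; discrete voxel
#: flips cannot hit arbitrary real targets exactly.
DEGRADE_TOLERANCE = 0.05

_FACE = ndimage.generate_binary_structure(3, 1)


@dataclass(frozen=True)
class PhantomSpec:
    """Geometry of a two-kidney + tumor phantom, in mm.

    Defaults give a pair of ellipsoidal kidneys with a tumor sphere embedded
    in the right one, on a 64x64x32 isotropic 1 mm grid — big enough for
    meaningful surface metrics, small enough to evaluate in milliseconds.
    """

    shape: tuple[int, int, int] = (64, 64, 32)
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    kidney_centers: tuple[tuple[float, float, float], tuple[float, float, float]] = (
        (18.0, 32.0, 16.0),
        (46.0, 32.0, 16.0),
    )
    kidney_semiaxes: tuple[tuple[float, float, float], tuple[float, float, float]] = (
        (10.0, 8.0, 9.0),
        (10.0, 8.0, 9.0),
    )
    tumor_center: tuple[float, float, float] = (48.0, 36.0, 16.0)
    tumor_radius: float = 6.0
    kidney_label: int = 1
    tumor_label: int = 2
    seed: int = 0

    def __post_init__(self) -> None:
        extent = tuple((n - 1) * s for n, s in zip(self.shape, self.spacing))
        for center, semi in zip(self.kidney_centers, self.kidney_semiaxes):
            for axis in range(3):
                if center[axis] - semi[axis] < 0 or center[axis] + semi[axis] > extent[axis]:
                    raise ValueError(
                        f"kidney ellipsoid exceeds grid on axis {axis + 1}"
                    )
        if self.tumor_radius < 0:
            raise ValueError("tumor radius must be >= 0")
        for axis in range(3):
            if (
                self.tumor_center[axis] - self.tumor_radius < 0
                or self.tumor_center[axis] + self.tumor_radius > extent[axis]
            ):
                raise ValueError(f"tumor sphere exceeds grid on axis {axis + 1}")


@dataclass(frozen=True)
class CurveSimSpec:
    """Ground truth and noise model for simulated learning curves.

    Defaults mirror a tumor-segmentation experiment design: sizes 50..300 in
    steps of 50, five cross-validation folds per size, fold noise SD 0.02
    Dice, and a generating curve rising from 0.40 toward a 0.85 asymptote.
    """

    d_max: float = 0.85
    d_zero: float = 0.40
    k: float = 0.02
    sizes: tuple[int, ...] = (50, 100, 150, 200, 250, 300)
    folds_per_size: int = 5
    noise_sd: float = 0.02
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.d_zero <= self.d_max <= 1.0:
            raise ValueError("need 0 <= d_zero <= d_max <= 1")
        if self.k <= 0:
            raise ValueError("rate constant k must be positive")
        if any(x < 1 for x in self.sizes):
            raise ValueError("dataset sizes must be >= 1")
        if self.folds_per_size < 1:
            raise ValueError("need >= 1 fold per size")
        if self.noise_sd < 0:
            raise ValueError("noise SD must be >= 0")


def make_phantom(spec: PhantomSpec | None = None) -> LabelVolume:
    """Rasterise the phantom: kidney ellipsoids, tumor sphere on top."""
    if spec is None:
        spec = PhantomSpec()
    coords = [
        np.arange(n) * s for n, s in zip(spec.shape, spec.spacing)
    ]
    gx, gy, gz = np.meshgrid(*coords, indexing="ij")
    voxels = np.zeros(spec.shape, dtype=np.int32)
    for center, semi in zip(spec.kidney_centers, spec.kidney_semiaxes):
        inside = (
            ((gx - center[0]) / semi[0]) ** 2
            + ((gy - center[1]) / semi[1]) ** 2
            + ((gz - center[2]) / semi[2]) ** 2
        ) <= 1.0
        voxels[inside] = spec.kidney_label
    if spec.tumor_radius > 0:
        c = spec.tumor_center
        inside = (
            (gx - c[0]) ** 2 + (gy - c[1]) ** 2 + (gz - c[2]) ** 2
        ) <= spec.tumor_radius**2
        voxels[inside] = spec.tumor_label  # tumor precedence over kidney
    return LabelVolume(voxels=voxels, spacing=spec.spacing, source_id="phantom")


def _measure_dice(original: LabelVolume, modified: LabelVolume, label: int) -> float:
    return dice_score(*binary_counts(original, modified, label))


def _boundary_flip(
    voxels: np.ndarray,
    original_mask: np.ndarray,
    background: int,
    label: int,
    target_dice: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Flip f mask voxels near the boundary to background and f nearby
    background voxels to the label.

    With equal removals and additions the Dice against the original is
    exactly (n - f)/n, so f = round(n·(1 - target)) lands on target to
    within one voxel's worth of Dice.  Flips are sampled at random from a
    boundary band just deep enough to contain f candidates, so independent
    seeds produce largely independent error patterns (which is what lets
    majority voting of simulated folds recover the truth).
    """
    n = int(original_mask.sum())
    f = int(round(n * (1.0 - target_dice)))
    out = voxels.copy()

    def band_sample(candidate_mask: np.ndarray, depth_map: np.ndarray, count: int):
        """Random voxels from a boundary band holding >= 4x count candidates.

        Oversampling the band keeps per-voxel flip probability low, so flips
        under different seeds overlap little.
        """
        for depth in range(1, max(voxels.shape) + 1):
            band = np.argwhere(candidate_mask & (depth_map <= depth))
            if len(band) >= 4 * count:
                break
        take = min(count, len(band))
        return band[rng.choice(len(band), size=take, replace=False)]

    # removals: mask voxels close to the outside
    depth_in = ndimage.distance_transform_edt(original_mask)
    pick = band_sample(original_mask, depth_in, f)
    out[tuple(pick.T)] = background
    # additions: original-background voxels close to the mask
    growable = voxels == background
    depth_out = ndimage.distance_transform_edt(~original_mask)
    pick = band_sample(growable, depth_out, f)
    out[tuple(pick.T)] = label
    return out


def _morph_to_target(
    voxels: np.ndarray,
    original: LabelVolume,
    label: int,
    background: int,
    target_dice: float,
    mode: str,
) -> tuple[np.ndarray, float]:
    """Erode or dilate the label mask one step at a time toward the target."""
    mask = voxels == label
    growable = voxels == background
    best_vox, best_dice = voxels.copy(), 1.0
    current = mask.copy()
    for _ in range(200):
        if mode == "erode":
            nxt = ndimage.binary_erosion(current, structure=_FACE, border_value=0)
        else:
            nxt = current | (
                ndimage.binary_dilation(current, structure=_FACE) & growable
            )
        if nxt.sum() == current.sum():
            break
        current = nxt
        cand = voxels.copy()
        cand[mask] = background
        cand[mask & current] = label
        if mode == "dilate":
            cand = voxels.copy()
            cand[current & growable] = label
        trial = LabelVolume(cand, original.spacing)
        d = _measure_dice(original, trial, label)
        if abs(d - target_dice) < abs(best_dice - target_dice):
            best_vox, best_dice = cand, d
        if d <= target_dice:  # dice falls monotonically either way; stop past target
            break
    return best_vox, best_dice


def degrade(
    volume: LabelVolume,
    label: int,
    target_dice: float,
    mode: str = "boundary_flip",
    seed: int = 0,
) -> LabelVolume:
    """Return a copy whose Dice against ``volume`` for ``label`` hits a target.

    Only voxels of ``label`` and of the background are ever touched; other
    labels are preserved exactly.  ``delete_component`` ignores the target
    and empties the structure entirely (Dice 0) — the model-missed-the-tumor
    scenario.  Raises if the achieved Dice cannot come within
    ``DEGRADE_TOLERANCE`` of the target, reporting the achieved value.
    """
    if mode not in DEGRADE_MODES:
        raise ValueError(f"mode must be one of {DEGRADE_MODES}, got {mode!r}")
    if not 0.0 < target_dice <= 1.0:
        raise ValueError(f"target_dice must be in (0, 1], got {target_dice}")
    mask = volume.mask(label)
    if not mask.any():
        raise ValueError(f"label {label} not present in volume")
    background = 0

    if mode == "delete_component":
        out = volume.voxels.copy()
        out[mask] = background
        return LabelVolume(out, volume.spacing, volume.source_id)
    if target_dice == 1.0:
        return LabelVolume(volume.voxels.copy(), volume.spacing, volume.source_id)

    rng = np.random.default_rng(seed)
    if mode == "boundary_flip":
        out = _boundary_flip(
            volume.voxels, mask, background, label, target_dice, rng
        )
        achieved = _measure_dice(
            volume, LabelVolume(out, volume.spacing), label
        )
    else:
        out, achieved = _morph_to_target(
            volume.voxels, volume, label, background, target_dice, mode
        )
    if abs(achieved - target_dice) > DEGRADE_TOLERANCE:
        raise ValueError(
            f"cannot reach Dice {target_dice:.3f} with mode {mode!r}; "
            f"achieved {achieved:.3f}"
        )
    return LabelVolume(out, volume.spacing, volume.source_id)


def simulate_folds(
    volume: LabelVolume,
    label: int,
    K: int = 5,
    quality_spread: tuple[float, float] = (0.85, 0.05),
    seed: int = 0,
) -> list[LabelVolume]:
    """K independent degradations emulating cross-validation fold models.

    Each fold's Dice target is drawn from a Gaussian centred on
    ``quality_spread[0]`` with SD ``quality_spread[1]``, clipped to
    (0.5, 1.0].  A degenerate spread at (1.0, 0.0) returns K exact copies.
    """
    if K < 1:
        raise ValueError("need K >= 1 folds")
    mean_q, sd_q = quality_spread
    seeds = np.random.SeedSequence(seed).spawn(K)
    folds = []
    for i, sub in enumerate(seeds):
        rng = np.random.default_rng(sub)
        target = float(np.clip(rng.normal(mean_q, sd_q), 0.5, 1.0)) if sd_q > 0 else mean_q
        fold = degrade(
            volume, label, target, mode="boundary_flip",
            seed=int(rng.integers(2**31)),
        )
        folds.append(
            LabelVolume(fold.voxels, fold.spacing, f"{volume.source_id}_fold{i}")
        )
    return folds


def simulate_learning_curve(spec: CurveSimSpec | None = None) -> list[CurveObservation]:
    """Draw fold and ensemble observations from a known plateau law.

    For every size x and fold, dice = clip(D(x) + eps, 0, 1) with
    eps ~ N(0, noise_sd); the ensemble observation at x is the mean of its
    folds.  Returns fold observations followed by ensemble observations,
    all reproducible from ``spec.seed``.
    """
    if spec is None:
        spec = CurveSimSpec()
    rng = np.random.default_rng(spec.seed)
    observations: list[CurveObservation] = []
    for x in spec.sizes:
        true = spec.d_max - (spec.d_max - spec.d_zero) * np.exp(-spec.k * x)
        fold_dice = np.clip(
            true + rng.normal(0.0, spec.noise_sd, size=spec.folds_per_size)
            if spec.noise_sd > 0
            else np.full(spec.folds_per_size, true),
            0.0,
            1.0,
        )
        for fold_id, d in enumerate(fold_dice):
            observations.append(
                CurveObservation(x=x, dice=float(d), kind="fold", fold_id=fold_id)
            )
        observations.append(
            CurveObservation(x=x, dice=float(fold_dice.mean()), kind="ensemble")
        )
    return observations
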