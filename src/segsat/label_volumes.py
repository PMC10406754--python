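"""Data model and NIfTI I/O for 3D multi-label segmentation volumes.

A :class:`LabelVolume` is a 3D grid of non-negative integer labels plus the
physical voxel spacing in millimetres.  Volumes are kept in the file's native
array order; no reorientation is performed, because every downstream metric
(overlap, surface distance, volume) is invariant to axis permutation as long
as the per-axis spacing travels with the array.  Rotation/flip content of the
NIfTI affine beyond the voxel size is deliberately ignored — see the package
methods note for the rationale and limitation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import nibabel as nib
import numpy as np

__all__ = [
    "LabelVolume",
    "LabelMap",
    "read_label_volume",
    "write_label_volume",
    "check_comparable",
    "SPACING_RTOL",
    "LABEL_ROUND_TOL",
]

#: Relative tolerance under which two voxel spacings count as identical.
SPACING_RTOL = 1e-6

#: Absolute tolerance for accepting a float-stored voxel value as an integer.
LABEL_ROUND_TOL = 1e-6


@dataclass(frozen=True)
class LabelVolume:
    """A 3D integer label grid with physical voxel spacing.

    Parameters
    ----------
    voxels
        3D array of non-negative integer labels (background is conventionally 0).
    spacing
        Per-axis physical voxel size in mm, one positive value per stored axis.
    source_id
        Opaque case identifier, usually the file stem.
    """

    voxels: np.ndarray
    spacing: tuple[float, float, float]
    source_id: str = ""

    def __post_init__(self) -> None:
        vox = np.asarray(self.voxels)
        if vox.ndim != 3:
            raise ValueError(f"label volume must be 3D, got {vox.ndim}D")
        if not np.issubdtype(vox.dtype, np.integer):
            raise ValueError(f"voxels must be integer-typed, got dtype {vox.dtype}")
        if vox.size and vox.min() < 0:
            raise ValueError("voxel labels must be non-negative")
        spacing = tuple(float(s) for s in self.spacing)
        if len(spacing) != 3:
            raise ValueError("spacing must have exactly three components")
        for axis, s in enumerate(spacing):
            if not np.isfinite(s) or s <= 0:
                raise ValueError(f"spacing[{axis}] must be positive and finite, got {s}")
        object.__setattr__(self, "voxels", vox)
        object.__setattr__(self, "spacing", spacing)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.voxels.shape  # type: ignore[return-value]

    @property
    def voxel_volume_mm3(self) -> float:
        """Physical volume of one voxel in mm^3."""
        return float(np.prod(self.spacing))

    def labels(self) -> np.ndarray:
        """Sorted array of distinct label values present in the volume."""
        return np.unique(self.voxels)

    def mask(self, label: int) -> np.ndarray:
        """Boolean mask of voxels carrying ``label``."""
        return self.voxels == label


@dataclass(frozen=True)
class LabelMap:
    """Mapping of structure names to integer label values.

    The default matches the kidney-tumor scheme: background 0, kidney 1,
    tumor 2.  Label values must be distinct and must not include the
    background value.
    """

    names: Mapping[str, int] = field(
        default_factory=lambda: {"kidney": 1, "tumor": 2}
    )
    background: int = 0

    def __post_init__(self) -> None:
        values = list(self.names.values())
        if len(set(values)) != len(values):
            raise ValueError(f"label values must be distinct, got {dict(self.names)}")
        if self.background in values:
            raise ValueError(
                f"background value {self.background} collides with a named label"
            )
        object.__setattr__(self, "names", dict(self.names))

    def items(self):
        return self.names.items()

    @classmethod
    def parse(cls, text: str, background: int = 0) -> "LabelMap":
        """Parse ``"kidney=1,tumor=2"`` style CLI syntax."""
        names: dict[str, int] = {}
        for chunk in text.split(","):
            chunk = chunk.strip()
            if not chunk:
                continue
            name, _, value = chunk.partition("=")
            if not value:
                raise ValueError(f"bad label spec {chunk!r}; expected name=value")
            names[name.strip()] = int(value)
        if not names:
            raise ValueError("empty label map")
        return cls(names=names, background=background)


def read_label_volume(path: str | Path) -> LabelVolume:
    """Read a NIfTI-1 label volume.

    Voxel spacing is taken from the header zooms.  Stored values within
    ``LABEL_ROUND_TOL`` of an integer are rounded; anything else raises,
    because silently rounding e.g. 1.5 would corrupt a label mask.

    Raises
    ------
    FileNotFoundError
        If ``path`` does not exist.
    ValueError
        For non-3D images or non-integer voxel values beyond tolerance.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such file: {path}")
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    # tolerate trailing singleton dims some writers emit, reject real 4D
    data = np.squeeze(data)
    if data.ndim != 3:
        raise ValueError(f"{path}: expected a 3D label image, got shape {data.shape}")
    if not np.issubdtype(data.dtype, np.integer):
        rounded = np.rint(data)
        if not np.allclose(data, rounded, rtol=0, atol=LABEL_ROUND_TOL):
            bad = np.abs(data - rounded).max()
            raise ValueError(
                f"{path}: non-integer labels (max deviation {bad:g} exceeds "
                f"{LABEL_ROUND_TOL:g})"
            )
        data = rounded
    data = data.astype(np.int32)
    spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
    return LabelVolume(voxels=data, spacing=spacing, source_id=path.name.split(".")[0])


def write_label_volume(volume: LabelVolume, path: str | Path) -> None:
    """Write a :class:`LabelVolume` as NIfTI-1 with integer data.

    The affine is a diagonal scaling by the voxel spacing, so
    ``read_label_volume(write_label_volume(v)) == v`` on voxels and spacing.
    """
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    affine = np.diag(list(volume.spacing) + [1.0])
    img = nib.Nifti1Image(volume.voxels.astype(np.int32), affine)
    img.header.set_zooms(volume.spacing)
    nib.save(img, str(path))


def check_comparable(reference: LabelVolume, prediction: LabelVolume) -> None:
    """Raise unless the two volumes live on the same grid.

    Comparable means identical shapes and per-axis spacing agreeing within
    ``SPACING_RTOL`` relative tolerance.  Error messages name the first
    offending axis (1-based, matching how imaging people count axes).
    """
    for axis, (a, b) in enumerate(zip(reference.shape, prediction.shape), start=1):
        if a != b:
            raise ValueError(
                f"shape mismatch on axis {axis}: reference {reference.shape} "
                f"vs prediction {prediction.shape}"
            )
    for axis, (a, b) in enumerate(zip(reference.spacing, prediction.spacing), start=1):
        if abs(a - b) > SPACING_RTOL * max(abs(a), abs(b)):
            raise ValueError(
                f"spacing mismatch on axis {axis}: reference {reference.spacing} "
                f"vs prediction {prediction.spacing}"
            )
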