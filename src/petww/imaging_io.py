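"""Imaging containers, NIfTI and table I/O, and the pipeline entry point.

Coordinate convention: voxel indices are 0-based, axis order (x, y, z) as
stored, and world coordinates (mm) are ``origin + index * spacing``.  All
volumes passed between modules share this convention; the NIfTI reader
normalises to it and records the fact on the object.
"""

from __future__ import annotations

import dataclasses
import logging
from pathlib import Path
from typing import Sequence

import nibabel as nib
import numpy as np
import pandas as pd

log = logging.getLogger("petww")

AXIS_CONVENTION = "index-0-based:(x,y,z):world=origin+index*spacing"

#: Non-feature columns every feature table carries.
TABLE_ID_COLUMNS = ("subject_id", "scanner")


class FormatError(ValueError):
    """Raised when an on-disk object does not match the expected format."""


@dataclasses.dataclass
class SuvVolume:
    """A 3D grid of standardized uptake values with anisotropic spacing.

    Parameters
    ----------
    values : ndarray, shape (nx, ny, nz)
        SUV at each voxel; must be finite.
    spacing : 3 floats
        Voxel edge length per axis, mm; strictly positive.
    origin : 3 floats
        World coordinate (mm) of the centre of voxel (0, 0, 0).
    """

    values: np.ndarray
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)
    axis_convention: str = AXIS_CONVENTION

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 3:
            raise FormatError(
                f"SUV volume must be 3D, got {self.values.ndim}D"
            )
        if not np.all(np.isfinite(self.values)):
            raise FormatError("SUV volume contains non-finite values")
        self.spacing = tuple(float(s) for s in self.spacing)
        self.origin = tuple(float(o) for o in self.origin)
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise FormatError(f"spacing must be 3 positive floats, got {self.spacing}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.spacing))

    def world_coordinates(self, indices: np.ndarray) -> np.ndarray:
        """Map an (n, 3) array of voxel indices to world mm coordinates."""
        return np.asarray(self.origin) + np.asarray(indices) * np.asarray(self.spacing)


@dataclasses.dataclass
class Mask:
    """A binary VOI on the same grid as its parent :class:`SuvVolume`."""

    values: np.ndarray
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values).astype(bool)
        if self.values.ndim != 3:
            raise FormatError(f"mask must be 3D, got {self.values.ndim}D")
        self.spacing = tuple(float(s) for s in self.spacing)
        self.origin = tuple(float(o) for o in self.origin)

    @property
    def voxel_count(self) -> int:
        return int(self.values.sum())

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.spacing))

    def same_grid_as(self, other: "SuvVolume | Mask") -> bool:
        return (
            self.values.shape == other.values.shape
            and np.allclose(self.spacing, other.spacing)
            and np.allclose(self.origin, other.origin)
        )


def _affine(spacing: Sequence[float], origin: Sequence[float]) -> np.ndarray:
    aff = np.diag(list(spacing) + [1.0])
    aff[:3, 3] = origin
    return aff


def write_volume(volume: SuvVolume | Mask, path: str | Path) -> None:
    """Write a volume or mask as NIfTI-1 with spacing/origin in the affine."""
    data = volume.values
    if data.dtype == bool:
        data = data.astype(np.uint8)
    img = nib.Nifti1Image(data, _affine(volume.spacing, volume.origin))
    img.header.set_zooms(volume.spacing)
    nib.save(img, str(path))


def read_volume(path: str | Path) -> SuvVolume:
    """Read a NIfTI-1 SUV volume.

    The grid is kept in stored (x, y, z) order; spacing comes from the
    header zooms and the origin from the affine translation.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    img = nib.load(str(path))
    if len(img.shape) != 3:
        raise FormatError(f"expected a 3D image, got {len(img.shape)}D: {path}")
    zooms = img.header.get_zooms()[:3]
    if any(not np.isfinite(z) or z <= 0 for z in zooms):
        raise FormatError(f"missing or invalid voxel spacing in {path}")
    data = np.asarray(img.dataobj, dtype=np.float64)
    origin = tuple(float(v) for v in np.asarray(img.affine)[:3, 3])
    return SuvVolume(values=data, spacing=tuple(float(z) for z in zooms), origin=origin)


def read_mask(path: str | Path) -> Mask:
    vol = read_volume(path)
    return Mask(values=vol.values > 0.5, spacing=vol.spacing, origin=vol.origin)


# ---------------------------------------------------------------------------
# Feature tables
# ---------------------------------------------------------------------------


@dataclasses.dataclass
class FeatureTable:
    """Subjects x radiomic features with scanner labels.

    ``data`` holds one row per subject with columns ``subject_id``,
    ``scanner`` and then the feature columns (by default the canonical
    81-column registry from :mod:`petww.radiomics`).
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.data
        for col in TABLE_ID_COLUMNS:
            if col not in df.columns:
                raise FormatError(f"feature table missing required column {col!r}")
        if df["subject_id"].duplicated().any():
            dup = df.loc[df["subject_id"].duplicated(), "subject_id"].iloc[0]
            raise FormatError(f"duplicate subject id {dup!r}")
        self.data = df.reset_index(drop=True)

    @property
    def feature_columns(self) -> list[str]:
        return [c for c in self.data.columns if c not in TABLE_ID_COLUMNS]

    @property
    def n_subjects(self) -> int:
        return len(self.data)

    def features(self) -> pd.DataFrame:
        """Feature values indexed by subject_id."""
        return self.data.set_index("subject_id")[self.feature_columns]

    @property
    def scanner(self) -> pd.Series:
        return self.data.set_index("subject_id")["scanner"]

    def with_features(self, feats: pd.DataFrame) -> "FeatureTable":
        """Return a copy with feature values replaced (ids/scanners kept)."""
        out = self.data[list(TABLE_ID_COLUMNS)].copy()
        feats = feats.reindex(self.data["subject_id"].to_numpy())
        for c in feats.columns:
            out[c] = feats[c].to_numpy()
        return FeatureTable(out)

    def validate_layout(self, expected_columns: Sequence[str]) -> None:
        got, want = list(self.feature_columns), list(expected_columns)
        if got != want:
            missing = sorted(set(want) - set(got))
            extra = sorted(set(got) - set(want))
            raise FormatError(
                f"feature table layout mismatch: missing={missing[:5]} extra={extra[:5]}"
            )


def write_feature_table(table: FeatureTable, path: str | Path) -> None:
    """Write a feature table as CSV at full float precision."""
    table.data.to_csv(path, index=False, float_format="%.17g")


def read_feature_table(path: str | Path) -> FeatureTable:
    df = pd.read_csv(path)
    return FeatureTable(df)


def run_pipeline(config, out_dir: str | Path):
    """Run the full analysis (segment -> extract -> harmonize -> model ->
    survival) from a configuration; see :func:`petww.pipeline.run_pipeline`."""
    from .pipeline import run_pipeline as _run

    return _run(config, out_dir)
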