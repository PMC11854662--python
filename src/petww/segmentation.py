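"""Liver-referenced PERCIST segmentation of FDG-avid lesions.

A 2 cm-diameter spherical reference VOI on healthy liver yields the
background threshold ``1.5 * liver mean + 2 * liver SD`` (the PERCIST
convention); voxels at or above it, outside the liver VOI and any caller
supplied exclusion regions, are grouped into 26-connected components.
Each surviving component is one lesion with its metabolic tumour volume
(MTV), SUVmax and SUVmean; TMTV is the sum of MTVs.

Conventions (the clinical literature does not fix them): threshold
comparison is closed (``>=``), connectivity is 26-neighbour, components
smaller than ``min_lesion_voxels`` (default 3) are dropped as noise, and
the liver SD is the sample standard deviation (ddof=1).
"""

from __future__ import annotations

import dataclasses
import logging

import numpy as np
from scipy import ndimage

from .imaging_io import Mask, SuvVolume

log = logging.getLogger("petww")

LIVER_VOI_DIAMETER_MM = 20.0


@dataclasses.dataclass
class LiverStats:
    """First moments of the liver reference VOI."""

    mean: float
    sd: float
    min: float
    voxel_count: int

    def __post_init__(self) -> None:
        if self.voxel_count <= 0:
            raise ValueError("liver VOI is empty")
        if self.sd < 0:
            raise ValueError("negative SD")


@dataclasses.dataclass
class Lesion:
    label: int
    mask: Mask
    mtv_cm3: float
    suvmax: float
    suvmean: float


@dataclasses.dataclass
class LesionSet:
    """Disjoint lesion masks plus the liver reference VOI and threshold."""

    lesions: list[Lesion]
    liver_voi: Mask | None
    threshold: float
    tmtv_cm3: float

    @property
    def n_lesions(self) -> int:
        return len(self.lesions)

    def suvmax_lesion(self) -> Lesion:
        """The lesion containing the global SUVmax.

        Ties across lesions go to the larger MTV, then the lowest label.
        """
        if not self.lesions:
            raise ValueError("empty lesion set")
        return max(self.lesions, key=lambda l: (l.suvmax, l.mtv_cm3, -l.label))


def place_liver_voi(volume: SuvVolume, center_mm) -> Mask:
    """Spherical 2 cm reference VOI: voxels whose centres lie within 10 mm.

    Raises if the sphere would be clipped by the grid boundary — a
    truncated reference VOI would bias the background statistics.
    """
    center = np.asarray(center_mm, dtype=float)
    radius = LIVER_VOI_DIAMETER_MM / 2.0
    origin = np.asarray(volume.origin)
    spacing = np.asarray(volume.spacing)
    shape = np.asarray(volume.shape)
    hi = origin + (shape - 1) * spacing
    if np.any(center - radius < origin) or np.any(center + radius > hi):
        raise ValueError(
            f"liver VOI (radius {radius} mm) at {tuple(center)} is clipped by "
            f"the grid (extent {tuple(origin)}..{tuple(hi)} mm)"
        )
    # restrict to the bounding box around the sphere
    lo_idx = np.floor((center - radius - origin) / spacing).astype(int)
    hi_idx = np.ceil((center + radius - origin) / spacing).astype(int) + 1
    lo_idx = np.maximum(lo_idx, 0)
    hi_idx = np.minimum(hi_idx, shape)
    grids = np.meshgrid(
        *[np.arange(lo_idx[a], hi_idx[a]) for a in range(3)], indexing="ij"
    )
    idx = np.stack([g.ravel() for g in grids], axis=1)
    world = origin + idx * spacing
    inside = np.sum((world - center) ** 2, axis=1) <= radius**2
    mask = np.zeros(volume.shape, dtype=bool)
    mask[tuple(idx[inside].T)] = True
    return Mask(values=mask, spacing=volume.spacing, origin=volume.origin)


def liver_statistics(volume: SuvVolume, liver_voi: Mask) -> LiverStats:
    vals = volume.values[liver_voi.values]
    if vals.size == 0:
        raise ValueError("liver VOI is empty")
    sd = float(np.std(vals, ddof=1)) if vals.size > 1 else 0.0
    return LiverStats(
        mean=float(np.mean(vals)),
        sd=sd,
        min=float(np.min(vals)),
        voxel_count=int(vals.size),
    )


def percist_threshold(stats: LiverStats) -> float:
    """PERCIST background threshold: 1.5 x liver mean + 2 x liver SD."""
    return 1.5 * stats.mean + 2.0 * stats.sd


# 26-neighbourhood in 3D
_STRUCTURE_26 = np.ones((3, 3, 3), dtype=bool)


def extract_lesions(
    volume: SuvVolume,
    threshold: float,
    liver_voi: Mask | None = None,
    exclusion_masks: list[Mask] | None = None,
    min_lesion_voxels: int = 3,
) -> LesionSet:
    """Connected-component lesion extraction above the PERCIST threshold.

    ``exclusion_masks`` is the programmatic stand-in for the physician's
    rejection of physiological/false-positive uptake: any supra-threshold
    voxel inside one is discarded before labelling.
    """
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    hot = volume.values >= threshold
    if liver_voi is not None:
        hot &= ~liver_voi.values
    for m in exclusion_masks or []:
        hot &= ~m.values
    labels, n = ndimage.label(hot, structure=_STRUCTURE_26)
    voxel_vol_cm3 = volume.voxel_volume_mm3 / 1000.0
    lesions: list[Lesion] = []
    if n:
        counts = np.bincount(labels.ravel())
        for lab in range(1, n + 1):
            if counts[lab] < min_lesion_voxels:
                continue
            mvals = labels == lab
            suvs = volume.values[mvals]
            lesions.append(
                Lesion(
                    label=len(lesions) + 1,
                    mask=Mask(values=mvals, spacing=volume.spacing, origin=volume.origin),
                    mtv_cm3=float(counts[lab]) * voxel_vol_cm3,
                    suvmax=float(suvs.max()),
                    suvmean=float(suvs.mean()),
                )
            )
    tmtv = float(sum(l.mtv_cm3 for l in lesions))
    if not lesions:
        log.warning("no lesion survives threshold %.3f; empty lesion set", threshold)
    return LesionSet(lesions=lesions, liver_voi=liver_voi, threshold=threshold, tmtv_cm3=tmtv)


def segment_subject(
    volume: SuvVolume,
    liver_center_mm,
    exclusion_masks: list[Mask] | None = None,
    min_lesion_voxels: int = 3,
) -> tuple[LesionSet, LiverStats]:
    """Full per-subject segmentation: liver VOI -> threshold -> lesions."""
    voi = place_liver_voi(volume, liver_center_mm)
    stats = liver_statistics(volume, voi)
    thr = percist_threshold(stats)
    lesions = extract_lesions(
        volume, thr, liver_voi=voi, exclusion_masks=exclusion_masks,
        min_lesion_voxels=min_lesion_voxels,
    )
    return lesions, stats


def write_label_map(lesions: LesionSet, path) -> None:
    """Write lesions as a NIfTI label map (1..n lesions, 255 liver VOI)."""
    from .imaging_io import write_volume

    ref = lesions.liver_voi if lesions.liver_voi is not None else lesions.lesions[0].mask
    out = np.zeros(ref.values.shape, dtype=np.float64)
    for les in lesions.lesions:
        out[les.mask.values] = les.label
    if lesions.liver_voi is not None:
        out[lesions.liver_voi.values] = 255
    write_volume(SuvVolume(values=out, spacing=ref.spacing, origin=ref.origin), path)
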