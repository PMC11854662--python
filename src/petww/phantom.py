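"""Synthetic FDG-PET phantom cohorts with known ground truth.

Each subject is a 3D SUV grid containing quasi-spherical FDG-avid
lesions on a low-uptake background plus a homogeneous ellipsoidal
healthy-liver region.  Lesions are spheres in continuous space (so their
true sphericity and volume are analytic), rasterised to the grid and
blurred by an isotropic Gaussian point-spread function whose amplitude is
rescaled so each lesion's post-blur peak equals its drawn peak SUV.
Gaussian background noise is added and the liver region is painted with
independent draws of the stated mean/SD, giving exact control over the
reference-region statistics that drive the PERCIST threshold.

Cohorts add: a two-scanner split with location/scale batch effects
applied in *image space* (gain and offset on voxel intensities, so the
perturbation propagates through the full segmentation/extraction path
the way real scanner differences would); and a time-to-treatment outcome
generated as a linear combination of designated ground-truth feature
values (computed on the noiseless masks, so outcome-model recovery is
not confounded by segmentation error) plus Gaussian noise, clamped at 1
month.  Default sizes mirror the clinical setting emulated here: 38
subjects, 16/22 scanner split, ~7 lesions per subject with peak SUV
7-14, ~32% of subjects never treated (censored).
"""

from __future__ import annotations

import dataclasses
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter

from .imaging_io import FeatureTable, Mask, SuvVolume, write_volume
from .modelling import OutcomeRecord
from .radiomics import FEATURE_COLUMNS, assemble_feature_vector
from .segmentation import Lesion, LesionSet, place_liver_voi

log = logging.getLogger("petww")

#: Semi-axes (mm) of the ellipsoidal liver region, large enough to hold
#: the 2 cm spherical reference VOI with margin.
LIVER_SEMI_AXES_MM = (20.0, 16.0, 14.0)
_PLACEMENT_RETRIES = 200


@dataclasses.dataclass
class PhantomSpec:
    """Geometry and intensity parameters of one synthetic PET volume."""

    grid_shape: tuple[int, int, int] = (64, 64, 64)
    voxel_spacing: tuple[float, float, float] = (3.0, 3.0, 3.0)
    n_lesions: int = 7
    lesion_radius_range: tuple[float, float] = (6.0, 14.0)     # mm
    lesion_peak_suv_range: tuple[float, float] = (7.0, 14.0)   # SUV
    background_suv: float = 1.0
    background_noise_sd: float = 0.15
    liver_center: tuple[int, int, int] = (14, 14, 14)          # voxel coords
    liver_mean_suv: float = 2.2
    liver_sd_suv: float = 0.25
    psf_sigma_mm: float = 2.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_lesions < 1:
            raise ValueError("n_lesions must be >= 1")
        if not self.lesion_peak_suv_range[0] > self.background_suv:
            raise ValueError("lesion peaks must exceed the background SUV")
        if self.lesion_radius_range[0] <= 0:
            raise ValueError("lesion radii must be positive")
        if self.background_noise_sd < 0 or self.liver_sd_suv < 0:
            raise ValueError("noise SDs must be nonnegative")

    @property
    def liver_center_mm(self) -> np.ndarray:
        return np.asarray(self.liver_center) * np.asarray(self.voxel_spacing)

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=2)


@dataclasses.dataclass
class GroundTruth:
    """What the generator knows: true masks, metrics and features."""

    lesion_set: LesionSet          # masks + MTV/SUV metrics on the noiseless volume
    liver_center_mm: tuple[float, float, float]
    noiseless: SuvVolume           # pre-noise, pre-batch-effect volume
    features: dict[str, float]     # 81-feature vector on the true masks


def _voxel_center_grid(shape, spacing):
    axes = [np.arange(n) * s for n, s in zip(shape, spacing)]
    return np.meshgrid(*axes, indexing="ij")


def _sphere_mask(shape, spacing, center_mm, radius_mm) -> np.ndarray:
    lo = np.maximum(np.floor((center_mm - radius_mm) / spacing).astype(int), 0)
    hi = np.minimum(np.ceil((center_mm + radius_mm) / spacing).astype(int) + 1, shape)
    mask = np.zeros(shape, dtype=bool)
    sub_axes = [np.arange(lo[a], hi[a]) * spacing[a] for a in range(3)]
    gx, gy, gz = np.meshgrid(*sub_axes, indexing="ij")
    d2 = (gx - center_mm[0]) ** 2 + (gy - center_mm[1]) ** 2 + (gz - center_mm[2]) ** 2
    mask[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]] = d2 <= radius_mm**2
    return mask


def _ellipsoid_mask(shape, spacing, center_mm, semi_axes_mm) -> np.ndarray:
    center_mm = np.asarray(center_mm, dtype=float)
    semi = np.asarray(semi_axes_mm, dtype=float)
    lo = np.maximum(np.floor((center_mm - semi) / spacing).astype(int), 0)
    hi = np.minimum(np.ceil((center_mm + semi) / spacing).astype(int) + 1, shape)
    sub_axes = [np.arange(lo[a], hi[a]) * spacing[a] for a in range(3)]
    gx, gy, gz = np.meshgrid(*sub_axes, indexing="ij")
    q = (
        ((gx - center_mm[0]) / semi[0]) ** 2
        + ((gy - center_mm[1]) / semi[1]) ** 2
        + ((gz - center_mm[2]) / semi[2]) ** 2
    )
    mask = np.zeros(tuple(shape), dtype=bool)
    mask[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]] = q <= 1.0
    return mask


def generate_phantom(spec: PhantomSpec, rng=None) -> tuple[SuvVolume, GroundTruth]:
    """Generate one phantom volume and its ground truth.

    Raises if a lesion cannot be placed after bounded retries (the grid
    is too small for the requested lesion count/size/separation).
    """
    rng = np.random.default_rng(spec.seed if rng is None else rng)
    shape = np.asarray(spec.grid_shape)
    spacing = np.asarray(spec.voxel_spacing, dtype=float)
    extent = (shape - 1) * spacing
    liver_c = spec.liver_center_mm.astype(float)
    semi = np.asarray(LIVER_SEMI_AXES_MM)
    if np.any(liver_c - semi < 0) or np.any(liver_c + semi > extent):
        raise ValueError("liver ellipsoid does not fit inside the grid")

    sigma_mm = float(spec.psf_sigma_mm)
    margin = sigma_mm * 2.0
    sep_gap = max(2.0 * sigma_mm, 6.0)
    liver_clear = float(semi.max()) + sep_gap

    centers, radii, peaks = [], [], []
    for i in range(spec.n_lesions):
        r = rng.uniform(*spec.lesion_radius_range)
        peak = rng.uniform(*spec.lesion_peak_suv_range)
        lo = r + margin
        hi = extent - (r + margin)
        if np.any(hi <= lo):
            raise ValueError(
                f"grid too small: lesion radius {r:.1f} mm + PSF margin exceeds extent {extent}"
            )
        for attempt in range(_PLACEMENT_RETRIES):
            c = rng.uniform(lo, hi)
            if np.linalg.norm(c - liver_c) < r + liver_clear:
                continue
            if any(
                np.linalg.norm(c - c2) < r + r2 + sep_gap
                for c2, r2 in zip(centers, radii)
            ):
                continue
            break
        else:
            raise ValueError(
                f"could not place lesion {i + 1}/{spec.n_lesions} after "
                f"{_PLACEMENT_RETRIES} tries: grid {tuple(shape)} too crowded for "
                f"radius {r:.1f} mm with separation {sep_gap:.1f} mm"
            )
        centers.append(c)
        radii.append(r)
        peaks.append(peak)

    # rasterise each lesion, blur within a cropped window, rescale to peak
    values = np.full(tuple(shape), float(spec.background_suv))
    gt_masks = []
    sigma_vox = sigma_mm / spacing
    pad = np.ceil(4 * sigma_vox).astype(int)
    for c, r, peak in zip(centers, radii, peaks):
        mask = _sphere_mask(tuple(shape), spacing, c, r)
        gt_masks.append(mask)
        idx = np.argwhere(mask)
        lo_i = np.maximum(idx.min(axis=0) - pad, 0)
        hi_i = np.minimum(idx.max(axis=0) + 1 + pad, shape)
        sl = tuple(slice(lo_i[a], hi_i[a]) for a in range(3))
        field = gaussian_filter(mask[sl].astype(float), sigma=sigma_vox, mode="constant")
        fmax = field.max()
        if fmax > 0:
            values[sl] += field * ((peak - spec.background_suv) / fmax)

    liver_mask = _ellipsoid_mask(tuple(shape), spacing, liver_c, semi)
    noiseless_values = values.copy()
    noiseless_values[liver_mask] = spec.liver_mean_suv
    noiseless = SuvVolume(values=np.clip(noiseless_values, 0, None), spacing=tuple(spacing))

    values = values + rng.normal(0.0, spec.background_noise_sd, size=tuple(shape))
    values[liver_mask] = rng.normal(
        spec.liver_mean_suv, spec.liver_sd_suv, size=int(liver_mask.sum())
    )
    volume = SuvVolume(values=np.clip(values, 0, None), spacing=tuple(spacing))

    lesions = []
    for lab, mask in enumerate(gt_masks, start=1):
        suvs = noiseless.values[mask]
        lesions.append(
            Lesion(
                label=lab,
                mask=Mask(values=mask, spacing=tuple(spacing)),
                mtv_cm3=float(mask.sum()) * volume.voxel_volume_mm3 / 1000.0,
                suvmax=float(suvs.max()),
                suvmean=float(suvs.mean()),
            )
        )
    liver_voi = place_liver_voi(noiseless, liver_c)
    gt_set = LesionSet(
        lesions=lesions,
        liver_voi=liver_voi,
        threshold=float("nan"),
        tmtv_cm3=float(sum(l.mtv_cm3 for l in lesions)),
    )
    gt = GroundTruth(
        lesion_set=gt_set,
        liver_center_mm=tuple(liver_c),
        noiseless=noiseless,
        features=assemble_feature_vector(gt_set, noiseless),
    )
    return volume, gt


@dataclasses.dataclass
class CohortSpec:
    """Study-level parameters of a synthetic two-scanner cohort."""

    n_subjects: int = 38
    scanner_assignment: float = 16.0 / 38.0   # fraction on scanner A
    batch_location_effect: tuple[float, float] = (0.0, 0.0)  # additive SUV per scanner
    batch_scale_effect: tuple[float, float] = (1.0, 1.0)     # multiplicative gain
    informative_features: tuple[str, ...] = ("tmtv_cm3", "n_lesions", "F_stat.kurt")
    outcome_coefficients: tuple[float, ...] = (-1.5, -6.0, 7.0)
    outcome_intercept: float = 87.0
    outcome_noise_sd: float = 10.0            # months
    censor_fraction: float = 12.0 / 38.0
    lesion_count_jitter: int = 3              # n_lesions varies +/- this per subject
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subjects < 1:
            raise ValueError("n_subjects must be >= 1")
        if not 0.0 < self.scanner_assignment < 1.0:
            raise ValueError("scanner_assignment must be strictly between 0 and 1")
        if not self.outcome_noise_sd > 0:
            raise ValueError("outcome_noise_sd must be positive")
        if len(self.informative_features) != len(self.outcome_coefficients):
            raise ValueError("one coefficient per informative feature required")
        unknown = [f for f in self.informative_features if f not in FEATURE_COLUMNS]
        if unknown:
            raise ValueError(
                f"unknown informative feature(s) {unknown}; valid names are the "
                f"81-feature registry, e.g. {FEATURE_COLUMNS[:4]}... see "
                "petww.radiomics.FEATURE_COLUMNS"
            )
        if not 0.0 <= self.censor_fraction < 1.0:
            raise ValueError("censor_fraction must be in [0, 1)")

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=2)


@dataclasses.dataclass
class Cohort:
    volumes: list[SuvVolume]
    scanner: list[str]
    outcomes: list[OutcomeRecord]
    ground_truth: list[GroundTruth]
    gt_features: FeatureTable      # 81 ground-truth features per subject
    liver_center_mm: tuple[float, float, float]

    @property
    def subject_ids(self) -> list[str]:
        return [o.subject_id for o in self.outcomes]


def generate_cohort(cspec: CohortSpec, pspec_template: PhantomSpec | None = None) -> Cohort:
    """Generate a full synthetic cohort with scanner effects and outcomes.

    Per-subject phantoms vary lesion count (within ``lesion_count_jitter``
    of the template), positions, radii and peaks.  TTT is
    ``intercept + sum(coef * ground-truth feature) + N(0, noise_sd)``,
    clamped at 1 month; a ``censor_fraction`` of subjects never start
    treatment and carry a follow-up time instead.
    """
    pspec = pspec_template if pspec_template is not None else PhantomSpec()
    ss = np.random.SeedSequence(cspec.seed)
    subject_seeds = ss.spawn(cspec.n_subjects)
    cohort_rng = np.random.default_rng(ss.spawn(1)[0])

    n = cspec.n_subjects
    n_a = int(round(cspec.scanner_assignment * n))
    n_a = min(max(n_a, 1), n - 1) if n > 1 else n_a
    scanner = np.array(["A"] * n_a + ["B"] * (n - n_a))
    cohort_rng.shuffle(scanner)

    volumes, gts, rows = [], [], []
    lo_n = max(1, pspec.n_lesions - cspec.lesion_count_jitter)
    hi_n = pspec.n_lesions + cspec.lesion_count_jitter
    for i in range(n):
        srng = np.random.default_rng(subject_seeds[i])
        n_les = int(srng.integers(lo_n, hi_n + 1))
        spec_i = dataclasses.replace(pspec, n_lesions=n_les)
        vol, gt = generate_phantom(spec_i, rng=srng)
        s = 0 if scanner[i] == "A" else 1
        gain = cspec.batch_scale_effect[s]
        offset = cspec.batch_location_effect[s]
        vol = SuvVolume(
            values=np.clip(gain * vol.values + offset, 0, None),
            spacing=vol.spacing,
            origin=vol.origin,
        )
        volumes.append(vol)
        gts.append(gt)
        rows.append({"subject_id": f"S{i + 1:03d}", "scanner": scanner[i], **gt.features})

    gt_table = FeatureTable(pd.DataFrame(rows))

    feats = gt_table.features()
    signal = np.full(n, float(cspec.outcome_intercept))
    for name, coef in zip(cspec.informative_features, cspec.outcome_coefficients):
        signal += coef * feats[name].to_numpy()
    ttt = signal + cohort_rng.normal(0.0, cspec.outcome_noise_sd, size=n)
    ttt = np.maximum(ttt, 1.0)

    n_cens = int(round(cspec.censor_fraction * n))
    censored = np.zeros(n, dtype=bool)
    if n_cens:
        censored[cohort_rng.choice(n, size=n_cens, replace=False)] = True
    followup = cohort_rng.uniform(24.0, 120.0, size=n)

    outcomes = [
        OutcomeRecord(
            subject_id=f"S{i + 1:03d}",
            ttt_months=float(followup[i] if censored[i] else ttt[i]),
            event=bool(not censored[i]),
        )
        for i in range(n)
    ]
    return Cohort(
        volumes=volumes,
        scanner=list(scanner),
        outcomes=outcomes,
        ground_truth=gts,
        gt_features=gt_table,
        liver_center_mm=tuple(pspec.liver_center_mm),
    )


def write_cohort(cohort: Cohort, out_dir: str | Path) -> Path:
    """Write volumes as NIfTI-1 plus a manifest CSV; returns the manifest path."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rows = []
    cx, cy, cz = cohort.liver_center_mm
    for vol, sid, scan, rec in zip(
        cohort.volumes, cohort.subject_ids, cohort.scanner, cohort.outcomes
    ):
        path = out / f"{sid}.nii.gz"
        write_volume(vol, path)
        rows.append(
            {
                "subject_id": sid, "scanner": scan,
                "ttt_months": rec.ttt_months, "event": rec.event,
                "liver_center_x": cx, "liver_center_y": cy, "liver_center_z": cz,
                "volume": path.name,
            }
        )
    manifest = out / "manifest.csv"
    pd.DataFrame(rows).to_csv(manifest, index=False, float_format="%.17g")
    return manifest


def synthetic_feature_table(
    n_subjects: int,
    n_features: int = 81,
    frac_a: float = 0.5,
    location_shift_sd: float = 0.0,
    scale_factor: float = 1.0,
    seed: int = 0,
) -> FeatureTable:
    """Feature-space batch-effect table (no images) for harmonization studies.

    Scanner-B values are drawn as
    ``mu + scale_factor * sigma * z + location_shift_sd * sigma`` so the
    injected group-mean difference is ``location_shift_sd`` per-feature SDs
    and the variance ratio is ``scale_factor**2``.
    """
    rng = np.random.default_rng(seed)
    cols = list(FEATURE_COLUMNS[:n_features])
    n_a = int(round(frac_a * n_subjects))
    mu = rng.uniform(-5, 5, size=n_features)
    sigma = rng.uniform(0.5, 3.0, size=n_features)
    z = rng.standard_normal((n_subjects, n_features))
    X = mu + sigma * z
    X[n_a:] = mu + scale_factor * sigma * z[n_a:] + location_shift_sd * sigma
    df = pd.DataFrame(X, columns=cols)
    df.insert(0, "scanner", ["A"] * n_a + ["B"] * (n_subjects - n_a))
    df.insert(0, "subject_id", [f"S{i + 1:03d}" for i in range(n_subjects)])
    return FeatureTable(df)
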