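"""Synthetic longitudinal PET phantom cohort with a planted covariance
pattern.

The study design being emulated: 18 rats (10 disease, 8 control) scanned at
baseline and at weeks 3, 4, 6 and 9 after a unilateral nigral lesion, with
cylinder-test motor scores (percent impaired-forelimb use) recorded at each
session.  The phantom is an ellipsoidal "brain" partitioned into contiguous
parcels; the disease signal is a regional multiplicative modulation of
uptake whose amplitude follows a monotone schedule — zero before week 4,
ramping up, and near-complete and stable by weeks 6-9.

Because the analysis normalizes each scan to zero mean and unit L2 norm,
only relative regional uptake is identifiable; the generator therefore
plants a *multiplicative* regional effect (relative hyper-/hypometabolism)
rather than an additive one, and adds a global per-subject scale factor
that the normalization must (and does) cancel.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .preprocess import smooth_gaussian

__all__ = [
    "TIMEPOINTS",
    "AtlasVolume",
    "EffectSchedule",
    "SubjectScan",
    "MotorParams",
    "build_phantom_atlas",
    "make_ground_truth_pattern",
    "generate_cohort",
    "default_region_effects",
    "default_phantom",
    "write_cohort",
]

TIMEPOINTS = ("baseline", "w3", "w4", "w6", "w9")

#: parcel names loosely following the regions summarized in small-animal
#: FDG-PET atlases; purely a naming convenience for the synthetic parcels
_REGION_NAMES = [
    "striatum",
    "motor cortex",
    "somatosensory cortex",
    "cingulate cortex",
    "medial prefrontal cortex",
    "orbitofrontal cortex",
    "visual cortex",
    "entorhinal cortex",
    "insular cortex",
    "thalamus",
    "hippocampus",
    "cerebellum",
    "midbrain",
    "pons",
    "medulla",
]


@dataclass
class AtlasVolume:
    """Integer parcellation of the phantom brain.

    ``labels`` is a 3-D integer grid (0 = background); every nonzero label
    appears in ``label_table`` and labels only voxels inside the brain mask.
    """

    labels: np.ndarray
    label_table: dict[int, str]
    voxel_size: tuple[float, float, float] = (1.0, 1.0, 1.0)

    def validate(self, mask: np.ndarray | None = None) -> None:
        ids = np.unique(self.labels)
        ids = ids[ids != 0]
        for rid in ids:
            if int(rid) not in self.label_table:
                raise ValueError(f"label {rid} missing from label table")
            if (self.labels == rid).sum() == 0:  # pragma: no cover
                raise ValueError(f"region {rid} is empty")
        if mask is not None and np.any((self.labels > 0) & ~np.asarray(mask, bool)):
            raise ValueError("labeled voxels extend outside the brain mask")


@dataclass
class EffectSchedule:
    """Per-timepoint multiplier on the planted pattern amplitude.

    The baseline multiplier must be 0 and multipliers must be non-decreasing
    over time; the final multiplier must be 1 (complete expression) unless
    the schedule is identically zero (null schedule, used for calibration).
    """

    multipliers: dict[str, float]

    def __post_init__(self) -> None:
        vals = [self.multipliers[tp] for tp in self.multipliers]
        if "baseline" in self.multipliers and self.multipliers["baseline"] != 0.0:
            raise ValueError("baseline multiplier must be 0")
        if any(b < a for a, b in zip(vals, vals[1:])):
            raise ValueError("multipliers must be non-decreasing over time")
        if any(v != 0.0 for v in vals) and vals[-1] != 1.0:
            raise ValueError("final multiplier must be 1 (or all zero)")

    def __getitem__(self, tp: str) -> float:
        return self.multipliers[tp]

    @classmethod
    def default(cls) -> "EffectSchedule":
        return cls({"baseline": 0.0, "w3": 0.0, "w4": 0.6, "w6": 0.9, "w9": 1.0})

    @classmethod
    def null(cls) -> "EffectSchedule":
        return cls({tp: 0.0 for tp in TIMEPOINTS})


@dataclass
class SubjectScan:
    subject_id: str
    group: str  # "PD" or "control"
    timepoint: str
    image: np.ndarray
    motor_score: float

    def __post_init__(self) -> None:
        if not np.isfinite(self.motor_score):
            raise ValueError("motor score must be finite")


@dataclass
class MotorParams:
    """Cylinder-test score model.

    Controls use both forelimbs symmetrically (about 50% impaired-side use);
    lesioned animals drop by ``slope`` percentage points at full pattern
    expression.  Noise is Gaussian, truncated to [0, 100] by clipping.
    """

    control_mean: float = 50.0
    slope: float = 35.0
    noise_sd: float = 6.0


def build_phantom_atlas(
    grid_dims: tuple[int, int, int] = (32, 32, 32),
    n_regions: int = 15,
    seed: int = 0,
    voxel_size: tuple[float, float, float] = (1.0, 1.0, 1.0),
) -> tuple[AtlasVolume, np.ndarray]:
    """Ellipsoidal brain mask partitioned into contiguous parcels.

    The mask is an axis-aligned ellipsoid with semi-axes 0.4 x grid size;
    parcels are the nearest-seed-point (Voronoi) partition of mask voxels
    for ``n_regions`` seed points drawn inside the mask.  Deterministic for
    a fixed seed.
    """
    dims = tuple(int(d) for d in grid_dims)
    if any(d < 16 for d in dims):
        raise ValueError("grid dimensions must each be at least 16")
    if not 2 <= n_regions <= 30:
        raise ValueError("n_regions must be between 2 and 30")
    centre = (np.asarray(dims) - 1) / 2.0
    semi = 0.4 * np.asarray(dims)
    grid = np.indices(dims).reshape(3, -1).T
    inside = (((grid - centre) / semi) ** 2).sum(axis=1) <= 1.0
    mask = inside.reshape(dims)
    mask_vox = grid[inside]
    if mask_vox.shape[0] < n_regions:
        raise ValueError(
            f"mask has {mask_vox.shape[0]} voxels, cannot host {n_regions} parcels"
        )
    rng = np.random.default_rng(seed)
    seeds = mask_vox[rng.choice(mask_vox.shape[0], size=n_regions, replace=False)]
    d2 = ((mask_vox[:, None, :] - seeds[None, :, :]) ** 2).sum(axis=2)
    assign = np.argmin(d2, axis=1) + 1  # ties -> lowest region id
    labels = np.zeros(dims, dtype=np.int32)
    labels[tuple(mask_vox.T)] = assign
    names = {
        i + 1: (_REGION_NAMES[i] if i < len(_REGION_NAMES) else f"parcel {i + 1}")
        for i in range(n_regions)
    }
    atlas = AtlasVolume(labels=labels, label_table=names, voxel_size=voxel_size)
    atlas.validate(mask)
    return atlas, mask


def make_ground_truth_pattern(
    atlas: AtlasVolume, region_effects: dict[int, float]
) -> tuple[np.ndarray, np.ndarray]:
    """Voxel map of planted signed amplitudes.

    Every voxel receives the amplitude of its region (0 if the region is
    unlisted).  Returns the 3-D map and the masked vector (raster order over
    labeled voxels) for recovery tests.
    """
    for rid in region_effects:
        if int(rid) not in atlas.label_table:
            raise ValueError(f"unknown region id {rid}")
    vol = np.zeros(atlas.labels.shape, dtype=float)
    for rid, amp in region_effects.items():
        vol[atlas.labels == rid] = amp
    masked = vol[atlas.labels > 0]
    return vol, masked


def default_region_effects(
    atlas: AtlasVolume, amplitude: float = 0.1
) -> dict[int, float]:
    """Balanced default: first third of regions hyper (+amp), second third
    hypo (-amp), rest neutral — so the planted map is near zero-mean over
    the brain, mirroring the relative hyper/hypometabolism the normalized
    analysis can recover."""
    ids = sorted(atlas.label_table)
    k = len(ids) // 3
    effects = {rid: amplitude for rid in ids[:k]}
    effects.update({rid: -amplitude for rid in ids[k : 2 * k]})
    return effects


def generate_cohort(
    atlas: AtlasVolume,
    truth_pattern: np.ndarray,
    n_pd: int = 10,
    n_control: int = 8,
    schedule: EffectSchedule | None = None,
    baseline_mean: float = 100.0,
    subject_sd: float = 0.1,
    voxel_noise_sd: float = 5.0,
    motor_params: MotorParams | None = None,
    seed: int = 0,
    psf_fwhm: float = 1.35,
    timepoints: tuple[str, ...] = TIMEPOINTS,
    mask: np.ndarray | None = None,
) -> list[SubjectScan]:
    """Simulate the longitudinal cohort.

    Control uptake inside the brain is ``baseline_mean * (1 + subject
    scale)`` plus i.i.d. voxel noise, blurred by the scanner-resolution PSF
    (FWHM ``psf_fwhm`` mm).  Disease scans are additionally modulated
    voxelwise by ``(1 + schedule[t] * truth_pattern)``.  Motor scores:
    controls near 50% symmetric use; disease scores drop by ``slope *
    schedule[t]`` with truncated Gaussian noise.  Fully reproducible for a
    fixed seed.
    """
    if n_pd < 1 or n_control < 1:
        raise ValueError("both groups need at least one subject")
    if baseline_mean <= 0 or subject_sd <= 0 or voxel_noise_sd <= 0:
        raise ValueError("scale parameters must be positive")
    schedule = schedule or EffectSchedule.default()
    for tp in timepoints:
        if tp not in schedule.multipliers:
            raise ValueError(f"schedule does not cover timepoint {tp!r}")
    motor_params = motor_params or MotorParams()
    if mask is None:
        mask = atlas.labels > 0
    mask = np.asarray(mask, dtype=bool)
    truth = np.asarray(truth_pattern, dtype=float)
    if truth.shape != atlas.labels.shape:
        raise ValueError("truth pattern shape does not match atlas")
    rng = np.random.default_rng(seed)
    subjects = [("PD", f"pd{i:02d}") for i in range(n_pd)] + [
        ("control", f"ct{i:02d}") for i in range(n_control)
    ]
    subj_scale = rng.normal(0.0, subject_sd, size=len(subjects)).clip(min=-0.9)
    scans = []
    for (group, sid), scale in zip(subjects, subj_scale):
        for tp in timepoints:
            s = schedule[tp]
            base = baseline_mean * (1.0 + scale) * mask.astype(float)
            if group == "PD":
                base = base * (1.0 + s * truth)
            img = base + rng.normal(0.0, voxel_noise_sd, size=mask.shape)
            img = smooth_gaussian(img, psf_fwhm, atlas.voxel_size)
            if group == "PD":
                score = motor_params.control_mean - motor_params.slope * s
            else:
                score = motor_params.control_mean
            score = float(
                np.clip(score + rng.normal(0.0, motor_params.noise_sd), 0.0, 100.0)
            )
            scans.append(
                SubjectScan(
                    subject_id=sid, group=group, timepoint=tp, image=img, motor_score=score
                )
            )
    return scans


def default_phantom(seed: int = 0, amplitude: float = 0.1, null: bool = False):
    """The package's standard demo phantom: 32^3 grid, 15 parcels, 10 PD /
    8 controls over 5 timepoints with the default expression schedule.

    Returns (atlas, mask, truth_volume, truth_vector, scans).  With
    ``null=True`` the planted amplitude is zero everywhere (calibration
    phantom); the atlas geometry is kept fixed across seeds so that only
    the cohort realization varies.
    """
    atlas, mask = build_phantom_atlas((32, 32, 32), 15, seed=12345)
    effects = default_region_effects(atlas, 0.0 if null else amplitude)
    truth_vol, truth_vec = make_ground_truth_pattern(atlas, effects)
    scans = generate_cohort(atlas, truth_vol, seed=seed, mask=mask)
    return atlas, mask, truth_vol, truth_vec, scans


def write_cohort(
    scans: list[SubjectScan],
    atlas: AtlasVolume,
    mask: np.ndarray,
    out_dir,
    seed: int | None = None,
    params: dict | None = None,
) -> None:
    """Write the cohort as NIfTI volumes + atlas TSV + subject CSV + manifest."""
    import nibabel as nib

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    affine = np.diag(list(atlas.voxel_size) + [1.0])
    nib.save(nib.Nifti1Image(mask.astype(np.uint8), affine), out / "mask.nii.gz")
    nib.save(nib.Nifti1Image(atlas.labels.astype(np.int16), affine), out / "atlas.nii.gz")
    pd.DataFrame(
        [{"region_id": rid, "region_name": name} for rid, name in sorted(atlas.label_table.items())]
    ).to_csv(out / "atlas_labels.tsv", sep="\t", index=False)
    rows = []
    for scan in scans:
        fname = f"{scan.subject_id}_{scan.timepoint}.nii.gz"
        nib.save(nib.Nifti1Image(scan.image.astype(np.float32), affine), out / fname)
        rows.append(
            {
                "subject_id": scan.subject_id,
                "group": scan.group,
                "timepoint": scan.timepoint,
                "motor_score": scan.motor_score,
                "image": fname,
            }
        )
    pd.DataFrame(rows).to_csv(out / "subjects.csv", index=False)
    manifest = {"seed": seed, "n_scans": len(scans), "params": params or {}}
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
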