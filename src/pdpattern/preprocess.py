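"""Scan-level preprocessing: smoothing, masking, vectorization, normalization.

Every scan enters the multivariate analysis as a masked voxel vector that is
spatially demeaned and scaled to unit L2 norm.  Only the *relative* spatial
distribution of tracer uptake then carries information: multiplying a scan by
any positive constant (injected dose, global metabolic rate, scanner
calibration) leaves its feature vector unchanged.

The fixed order of operations is smooth -> mask -> vectorize -> demean ->
L2-normalize.  The demean is taken over masked voxels only, since voxels
outside the brain carry no uptake signal.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import ndimage

__all__ = [
    "SIGMA_PER_FWHM",
    "FeatureVector",
    "DataMatrix",
    "smooth_gaussian",
    "vectorize",
    "devectorize",
    "normalize",
    "build_data_matrix",
    "save_data_matrix",
    "load_data_matrix",
]

#: sigma = FWHM * SIGMA_PER_FWHM for a Gaussian kernel
SIGMA_PER_FWHM = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))

_MEAN_TOL = 1e-10
_NORM_TOL = 1e-10


@dataclass
class FeatureVector:
    """A masked, demeaned, unit-L2-norm voxel vector.

    Attributes
    ----------
    values : (D,) float array with ``sum(values) == 0`` and
        ``sum(values**2) == 1`` to within 1e-10.
    mask_index : (D, 3) int array mapping vector position -> voxel coordinate,
        or None when the vector was built without spatial context.
    """

    values: np.ndarray
    mask_index: np.ndarray | None = None

    @property
    def d(self) -> int:
        return self.values.shape[0]

    def validate(self) -> None:
        v = self.values
        if abs(float(v.mean())) > _MEAN_TOL:
            raise ValueError("feature vector mean exceeds tolerance")
        if abs(float(v @ v) - 1.0) > _NORM_TOL:
            raise ValueError("feature vector sum of squares differs from one")


@dataclass
class DataMatrix:
    """N preprocessed scans sharing one mask, with row-aligned metadata.

    ``X`` is (N, D); every row satisfies the :class:`FeatureVector`
    invariants.  ``meta`` carries subject_id, group, timepoint and
    motor_score aligned with the rows.
    """

    X: np.ndarray
    mask_index: np.ndarray
    meta: pd.DataFrame
    shape: tuple[int, int, int] | None = None

    @property
    def n(self) -> int:
        return self.X.shape[0]

    @property
    def d(self) -> int:
        return self.X.shape[1]

    def labels(self, positive_group: str = "PD") -> np.ndarray:
        """Class targets: +1 for the positive (disease) group, -1 otherwise."""
        return np.where(self.meta["group"].to_numpy() == positive_group, 1.0, -1.0)

    def motor_scores(self) -> np.ndarray:
        return self.meta["motor_score"].to_numpy(dtype=float)

    def subset(self, rows: Sequence[int]) -> "DataMatrix":
        rows = np.asarray(rows, dtype=int)
        return DataMatrix(
            X=self.X[rows],
            mask_index=self.mask_index,
            meta=self.meta.iloc[rows].reset_index(drop=True),
            shape=self.shape,
        )

    def validate(self) -> None:
        if self.n < 2:
            raise ValueError("a data matrix needs at least two scans")
        means = self.X.mean(axis=1)
        sq = np.einsum("ij,ij->i", self.X, self.X)
        if np.abs(means).max() > _MEAN_TOL or np.abs(sq - 1.0).max() > _NORM_TOL:
            raise ValueError("row invariants violated (mean 0 / unit sum of squares)")


def smooth_gaussian(
    image: np.ndarray,
    fwhm: float,
    voxel_size: float | Sequence[float] = 1.0,
) -> np.ndarray:
    """Isotropic Gaussian smoothing specified in millimetres of FWHM.

    Per-axis sigma in voxels is ``fwhm * SIGMA_PER_FWHM / voxel_size``.
    Boundaries use renormalized (mass-conserving) convolution: the image is
    convolved with zero padding and divided by the identically convolved
    indicator of the domain, so constants are preserved exactly and interior
    mass is conserved.
    """
    if fwhm <= 0:
        raise ValueError("fwhm must be positive")
    image = np.asarray(image, dtype=float)
    vs = np.broadcast_to(np.asarray(voxel_size, dtype=float), (image.ndim,))
    if np.any(vs <= 0):
        raise ValueError("voxel sizes must be positive")
    sigma = fwhm * SIGMA_PER_FWHM / vs
    num = ndimage.gaussian_filter(image, sigma, mode="constant", cval=0.0)
    den = ndimage.gaussian_filter(np.ones_like(image), sigma, mode="constant", cval=0.0)
    return num / den


def vectorize(image: np.ndarray, mask: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Extract masked voxels in a fixed raster order.

    Returns ``(raw, mask_index)`` where ``mask_index`` is the (D, 3) array of
    voxel coordinates in C-order raster scan (last axis fastest).  The
    operation is invertible via :func:`devectorize`.
    """
    image = np.asarray(image)
    mask = np.asarray(mask, dtype=bool)
    if image.shape != mask.shape:
        raise ValueError(f"image shape {image.shape} != mask shape {mask.shape}")
    if not mask.any():
        raise ValueError("mask is empty")
    mask_index = np.argwhere(mask)
    raw = image[mask]
    return raw.astype(float), mask_index


def devectorize(
    values: np.ndarray, mask_index: np.ndarray, shape: Sequence[int], fill: float = 0.0
) -> np.ndarray:
    """Inverse of :func:`vectorize`: scatter a masked vector back to a volume."""
    vol = np.full(tuple(shape), fill, dtype=float)
    vol[tuple(mask_index.T)] = values
    return vol


def normalize(raw: np.ndarray, mask_index: np.ndarray | None = None) -> FeatureVector:
    """Demean and scale to unit L2 norm: ``(raw - mean) / ||raw - mean||``.

    A constant (zero-variance) input signals a degenerate scan and raises.
    """
    raw = np.asarray(raw, dtype=float)
    if raw.ndim != 1 or raw.size < 2:
        raise ValueError("normalize expects a 1-D vector of length >= 2")
    centred = raw - raw.mean()
    norm = float(np.linalg.norm(centred))
    if norm == 0.0:
        raise ValueError("zero-variance scan: all masked voxels identical")
    return FeatureVector(values=centred / norm, mask_index=mask_index)


def build_data_matrix(
    scans: Iterable,
    mask: np.ndarray,
    fwhm: float,
    voxel_size: float | Sequence[float] = 1.0,
) -> DataMatrix:
    """Preprocess a set of co-registered scans into one DataMatrix.

    ``scans`` are objects with subject_id, group, timepoint, motor_score and
    a 3-D ``image`` (see :class:`pdpattern.phantom.SubjectScan`).  Rows are
    ordered by (group, subject_id); smoothing is applied before masking.
    """
    mask = np.asarray(mask, dtype=bool)
    scans = sorted(scans, key=lambda s: (s.group, s.subject_id))
    if not scans:
        raise ValueError("no scans given")
    rows = []
    meta_rows = []
    mask_index = None
    for scan in scans:
        img = np.asarray(scan.image, dtype=float)
        if img.shape != mask.shape:
            raise ValueError(
                f"scan {scan.subject_id}: shape {img.shape} != mask {mask.shape}"
            )
        smoothed = smooth_gaussian(img, fwhm, voxel_size)
        raw, mask_index = vectorize(smoothed, mask)
        fv = normalize(raw, mask_index)
        rows.append(fv.values)
        meta_rows.append(
            {
                "subject_id": scan.subject_id,
                "group": scan.group,
                "timepoint": scan.timepoint,
                "motor_score": scan.motor_score,
            }
        )
    return DataMatrix(
        X=np.vstack(rows),
        mask_index=mask_index,
        meta=pd.DataFrame(meta_rows),
        shape=mask.shape,
    )


def save_data_matrix(dm: DataMatrix, path) -> None:
    """Serialize to a single ``.npz`` archive (exact float64 round-trip)."""
    np.savez(
        path,
        X=dm.X,
        mask_index=dm.mask_index,
        shape=np.asarray(dm.shape if dm.shape else (), dtype=int),
        subject_id=dm.meta["subject_id"].to_numpy(dtype="U64"),
        group=dm.meta["group"].to_numpy(dtype="U16"),
        timepoint=dm.meta["timepoint"].to_numpy(dtype="U16"),
        motor_score=dm.meta["motor_score"].to_numpy(dtype=float),
    )


def load_data_matrix(path) -> DataMatrix:
    with np.load(path, allow_pickle=False) as z:
        meta = pd.DataFrame(
            {
                "subject_id": z["subject_id"],
                "group": z["group"],
                "timepoint": z["timepoint"],
                "motor_score": z["motor_score"],
            }
        )
        shape = tuple(int(s) for s in z["shape"]) or None
        return DataMatrix(X=z["X"], mask_index=z["mask_index"], meta=meta, shape=shape)
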