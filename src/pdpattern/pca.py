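"""Subject-space principal component analysis for N << D imaging data.

With N scans of D masked voxels (N around 18, D around 1e4-1e5) the D x D
voxel covariance matrix is never formed.  Eigenvectors are obtained from the
N x N Gram matrix of subject-centred rows and mapped back to voxel space;
the nonzero eigenvalues of the two problems coincide.  All components with
nonzero variance are retained — component weighting is left entirely to the
downstream SVM rather than to a variance cutoff.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .preprocess import DataMatrix

__all__ = ["PCABasis", "fit_pca", "transform", "inverse_transform", "save_basis", "load_basis"]

#: relative eigenvalue cutoff for "nonzero variance"
EIGENVALUE_RTOL = 1e-10


@dataclass
class PCABasis:
    """Orthonormal feature transform.

    ``components`` is the K x D matrix A whose rows are principal components
    of the training data (unit norm, mutually orthogonal); ``training_mean``
    is the voxel-wise mean across training subjects, subtracted before any
    projection; ``eigenvalues`` are the sample-covariance eigenvalues
    (denominator N-1), sorted non-increasing.
    """

    components: np.ndarray
    training_mean: np.ndarray
    eigenvalues: np.ndarray
    mask_index: np.ndarray | None = None

    @property
    def k(self) -> int:
        return self.components.shape[0]

    @property
    def d(self) -> int:
        return self.components.shape[1]


def fit_pca(data: DataMatrix | np.ndarray) -> PCABasis:
    """Fit the PCA transform on the full training set (both groups pooled).

    Centering is across subjects (voxel-wise mean), which is distinct from
    the per-scan spatial demean applied during preprocessing.  Eigenvectors
    come from the N x N Gram matrix; the per-component sign is fixed by
    making the largest-magnitude voxel loading positive.
    """
    if isinstance(data, DataMatrix):
        X = data.X
        mask_index = data.mask_index
    else:
        X = np.asarray(data, dtype=float)
        mask_index = None
    if X.ndim != 2:
        raise ValueError("expected a 2-D data matrix")
    n, d = X.shape
    if n < 3:
        raise ValueError(f"PCA needs at least 3 subjects, got {n}")
    mean = X.mean(axis=0)
    Xc = X - mean
    gram = (Xc @ Xc.T) / (n - 1)
    evals, evecs = np.linalg.eigh(gram)
    order = np.argsort(evals)[::-1]
    evals = evals[order]
    evecs = evecs[:, order]
    cutoff = EIGENVALUE_RTOL * max(float(evals[0]), 0.0)
    keep = evals > cutoff
    if not keep.any():
        raise ValueError("no variance in training data (all rows identical)")
    evals = evals[keep]
    evecs = evecs[:, keep]
    # voxel-space components: v_k = Xc^T u_k / sqrt((n-1) * lambda_k)
    comps = (Xc.T @ evecs) / np.sqrt((n - 1) * evals)
    comps = comps.T  # K x D
    for row in comps:
        if row[np.argmax(np.abs(row))] < 0:
            row *= -1.0
    return PCABasis(
        components=comps,
        training_mean=mean,
        eigenvalues=evals,
        mask_index=mask_index,
    )


def transform(basis: PCABasis, x: np.ndarray) -> np.ndarray:
    """Project voxel-space vector(s) to component coordinates A(x - mean)."""
    x = np.asarray(x, dtype=float)
    if x.shape[-1] != basis.d:
        raise ValueError(f"dimension mismatch: x has {x.shape[-1]} voxels, basis {basis.d}")
    return (x - basis.training_mean) @ basis.components.T


def inverse_transform(basis: PCABasis, coords: np.ndarray) -> np.ndarray:
    """Map component coordinates back to voxel space (adds the mean)."""
    coords = np.asarray(coords, dtype=float)
    return coords @ basis.components + basis.training_mean


def save_basis(basis: PCABasis, path) -> None:
    """Single-archive serialization with bit-exact round-trip."""
    np.savez(
        path,
        components=basis.components,
        training_mean=basis.training_mean,
        eigenvalues=basis.eigenvalues,
        mask_index=basis.mask_index if basis.mask_index is not None else np.empty((0, 3), int),
    )


def load_basis(path) -> PCABasis:
    with np.load(path, allow_pickle=False) as z:
        mi = z["mask_index"]
        return PCABasis(
            components=z["components"],
            training_mean=z["training_mean"],
            eigenvalues=z["eigenvalues"],
            mask_index=mi if mi.size else None,
        )
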