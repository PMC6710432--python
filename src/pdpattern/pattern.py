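"""Voxel-space metabolic brain patterns and expression scores.

A trained linear SVM with weight vector w in component space, together with
the orthonormal PCA transform A, defines a voxel-space pattern p = A^T w
(divided by the kernel scale used at training).  Projecting any preprocessed
scan onto p — the inner product <p, x - training_mean> — yields its raw
pattern-expression score; standardizing against the pooled control scans
from all timepoints yields the Z-value reported per subject.

The sign convention is that the disease (PD) training group has positive
mean raw score, so positive pattern weights read as relative
hypermetabolism and negative weights as hypometabolism.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .pca import PCABasis
from .preprocess import DataMatrix, devectorize
from .svm import SVMSolution

__all__ = [
    "MetabolicPattern",
    "derive_pattern",
    "expression_scores",
    "zscore",
    "score_table",
    "save_pattern",
    "load_pattern",
]


@dataclass
class MetabolicPattern:
    """A voxel-space pattern p = A^T w with its mask bookkeeping.

    ``training_mean`` is the PCA training mean, kept with the pattern so
    that expression scores are always computed against the same centering
    the pattern was derived with.
    """

    p: np.ndarray
    mask_index: np.ndarray | None
    training_mean: np.ndarray
    provenance: dict = field(default_factory=dict)

    @property
    def d(self) -> int:
        return self.p.shape[0]

    def to_volume(self, shape) -> np.ndarray:
        if self.mask_index is None:
            raise ValueError("pattern has no mask index")
        return devectorize(self.p, self.mask_index, shape)


def derive_pattern(
    basis: PCABasis,
    model: SVMSolution,
    training_data: DataMatrix | None = None,
    positive_group: str = "PD",
    timepoint: str | None = None,
) -> MetabolicPattern:
    """Reconstruct the voxel-space pattern p = A^T (w / s).

    If ``training_data`` (with group metadata) is given, the sign convention
    is enforced: the positive (disease) group must have positive mean raw
    score; otherwise p is flipped and the flip recorded in provenance.
    """
    if model.w.shape[0] != basis.k:
        raise ValueError(
            f"dimension mismatch: model has {model.w.shape[0]} weights, basis {basis.k} components"
        )
    p = basis.components.T @ (model.w / model.kernel_scale)
    if not np.any(p):
        raise ValueError("derived pattern is all-zero")
    flipped = False
    if training_data is not None:
        raw = (training_data.X - basis.training_mean) @ p
        pos = training_data.meta["group"].to_numpy() == positive_group
        if not pos.any():
            raise ValueError(f"no {positive_group!r} subjects in training data")
        if float(raw[pos].mean()) < 0:
            p = -p
            flipped = True
    prov = {
        "mode": model.mode,
        "C": model.C,
        "kernel_scale": model.kernel_scale,
        "epsilon": model.epsilon,
        "timepoint": timepoint,
        "sign_flipped": flipped,
        "bias_b": model.b,
        "centering": "training_mean",
    }
    return MetabolicPattern(
        p=p,
        mask_index=basis.mask_index,
        training_mean=basis.training_mean,
        provenance=prov,
    )


def _check_mask(pattern: MetabolicPattern, data: DataMatrix) -> None:
    if data.X.shape[1] != pattern.d:
        raise ValueError("mask mismatch: voxel counts differ")
    if (
        pattern.mask_index is not None
        and data.mask_index is not None
        and not np.array_equal(pattern.mask_index, data.mask_index)
    ):
        raise ValueError("mask mismatch: voxel orderings differ")


def expression_scores(
    pattern: MetabolicPattern, data: DataMatrix | np.ndarray, centering: bool = True
) -> np.ndarray:
    """Raw pattern-expression scores <p, x - training_mean> per scan.

    The SVM bias b is deliberately excluded: the score measures pattern
    expression, not a class prediction, and the subsequent Z-standardization
    absorbs any constant offset.
    """
    if isinstance(data, DataMatrix):
        _check_mask(pattern, data)
        X = data.X
    else:
        X = np.atleast_2d(np.asarray(data, dtype=float))
        if X.shape[1] != pattern.d:
            raise ValueError("mask mismatch: voxel counts differ")
    if centering:
        return (X - pattern.training_mean) @ pattern.p
    return X @ pattern.p


def zscore(
    raw_scores: np.ndarray, control_reference: np.ndarray
) -> tuple[np.ndarray, float, float]:
    """Standardize raw scores against the control-scan reference.

    The reference is the raw scores of all control scans pooled across every
    timepoint; sigma uses the N-1 denominator.  Returns (z, mu, sigma).
    """
    ref = np.asarray(control_reference, dtype=float)
    if ref.size < 2:
        raise ValueError("need at least 2 control scores for standardization")
    mu = float(ref.mean())
    sigma = float(ref.std(ddof=1))
    if sigma <= 0:
        raise ValueError("zero variance in control reference scores")
    return (np.asarray(raw_scores, dtype=float) - mu) / sigma, mu, sigma


def score_table(
    pattern: MetabolicPattern,
    data: DataMatrix,
    control_reference: np.ndarray,
    centering: bool = True,
) -> pd.DataFrame:
    """Per-subject score table: subject_id, group, timepoint, raw, z."""
    raw = expression_scores(pattern, data, centering=centering)
    z, mu, sigma = zscore(raw, control_reference)
    out = data.meta[["subject_id", "group", "timepoint"]].copy()
    out["raw"] = raw
    out["z"] = z
    out.attrs["control_mu"] = mu
    out.attrs["control_sigma"] = sigma
    return out


def save_pattern(pattern: MetabolicPattern, path) -> None:
    np.savez(
        path,
        p=pattern.p,
        training_mean=pattern.training_mean,
        mask_index=pattern.mask_index
        if pattern.mask_index is not None
        else np.empty((0, 3), int),
        provenance=np.frombuffer(
            json.dumps(pattern.provenance).encode(), dtype=np.uint8
        ),
    )


def load_pattern(path) -> MetabolicPattern:
    with np.load(path, allow_pickle=False) as z:
        mi = z["mask_index"]
        prov = json.loads(bytes(z["provenance"]).decode())
        return MetabolicPattern(
            p=z["p"],
            mask_index=mi if mi.size else None,
            training_mean=z["training_mean"],
            provenance=prov,
        )
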