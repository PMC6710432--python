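"""Atlas-based regional summaries of voxel patterns.

Two views of a pattern are produced: (i) per-region positive/negative
weighting percentages relative to the whole pattern, with a predominance
call (hyper- vs hypometabolic vs mixed), and (ii) region-wise Pearson
correlation between two patterns (e.g. the disease-specific and the
motor-related pattern).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "RegionWeighting",
    "region_weighting",
    "weighting_table",
    "pattern_region_correlation",
    "score_correlation",
]

DEFAULT_PREDOMINANCE_RATIO = 2.0


@dataclass
class RegionWeighting:
    region_id: int
    region_name: str
    pos_pct: float
    neg_pct: float
    predominance: str  # "+", "-" or "/"


def _atlas_labels_on_mask(atlas, mask_index: np.ndarray) -> np.ndarray:
    return np.asarray(atlas.labels)[tuple(np.asarray(mask_index).T)]


def region_weighting(
    pattern,
    atlas,
    predominance_ratio: float = DEFAULT_PREDOMINANCE_RATIO,
) -> list[RegionWeighting]:
    """Positive/negative weighting mass per atlas region.

    pos_pct(r) = 100 * sum of positive pattern weights in r / sum |p| over
    the whole mask, and symmetrically for neg_pct, so that across regions
    covering the mask the percentages total 100.  A region is called "+"
    (predominantly positive / hypermetabolic) when pos >= ratio * neg, "-"
    when neg >= ratio * pos, "/" otherwise.
    """
    if predominance_ratio <= 0:
        raise ValueError("predominance_ratio must be positive")
    p = np.asarray(pattern.p, dtype=float)
    total = float(np.abs(p).sum())
    if total == 0:
        raise ValueError("all-zero pattern has no regional weighting")
    labels = _atlas_labels_on_mask(atlas, pattern.mask_index)
    out = []
    for rid, name in sorted(atlas.label_table.items()):
        sel = labels == rid
        if not sel.any():
            warnings.warn(f"region {rid} ({name}) is empty on the pattern mask")
            out.append(RegionWeighting(rid, name, 0.0, 0.0, "/"))
            continue
        pr = p[sel]
        pos = 100.0 * float(pr[pr > 0].sum()) / total
        neg = 100.0 * float(-pr[pr < 0].sum()) / total
        if pos == 0.0 and neg == 0.0:
            call = "/"
        elif pos >= predominance_ratio * neg:
            call = "+"
        elif neg >= predominance_ratio * pos:
            call = "-"
        else:
            call = "/"
        out.append(RegionWeighting(rid, name, pos, neg, call))
    return out


def weighting_table(weightings: list[RegionWeighting]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "region_id": w.region_id,
                "region_name": w.region_name,
                "pos_pct": w.pos_pct,
                "neg_pct": w.neg_pct,
                "predominance": w.predominance,
            }
            for w in weightings
        ]
    )


def pattern_region_correlation(p1, p2, atlas, min_voxels: int = 3) -> dict[int, float]:
    """Per-region Pearson correlation of two patterns' voxel weights.

    Regions with fewer than ``min_voxels`` voxels or zero variance in either
    pattern are reported as NaN (undefined).
    """
    a = np.asarray(p1.p, dtype=float)
    b = np.asarray(p2.p, dtype=float)
    if a.shape != b.shape:
        raise ValueError("patterns do not share a mask")
    if p1.mask_index is not None and p2.mask_index is not None:
        if not np.array_equal(p1.mask_index, p2.mask_index):
            raise ValueError("patterns do not share a mask")
    labels = _atlas_labels_on_mask(atlas, p1.mask_index)
    out: dict[int, float] = {}
    for rid in sorted(atlas.label_table):
        sel = labels == rid
        if sel.sum() < min_voxels or a[sel].std() == 0 or b[sel].std() == 0:
            out[rid] = float("nan")
            continue
        out[rid] = float(stats.pearsonr(a[sel], b[sel]).statistic)
    return out


def score_correlation(scores_a, scores_b) -> float:
    """Pooled Pearson correlation between two aligned score lists.

    Affine-invariant, so raw scores and Z-values give the identical r.
    """
    a = np.asarray(scores_a, dtype=float)
    b = np.asarray(scores_b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("score lists must be 1-D and aligned")
    if a.size < 3:
        raise ValueError("need at least 3 score pairs")
    if a.std() == 0 or b.std() == 0:
        raise ValueError("zero variance in scores")
    return float(stats.pearsonr(a, b).statistic)
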