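"""Longitudinal group statistics: week-9 LOOCV and per-timepoint tests.

The pattern is derived at the final timepoint, where degeneration in the
disease model is near-complete and stable.  Classifier accuracy at that
timepoint is estimated by leave-one-out cross-validation in which the PCA
transform, the SVM and the pattern sign convention are all refit on the
N-1 retained subjects — the held-out scan influences nothing in the fold
model.  Earlier timepoints are scored with the full final-timepoint
pattern, and PD-vs-control differences are evaluated per timepoint with a
two-sided Wilcoxon rank-sum test.

The rank-sum test uses the exact null distribution (dynamic programming
over rank subsets, equivalent to full enumeration) for tie-free samples of
combined size <= 25, and a normal approximation with midranks, tie
correction and continuity correction otherwise.  Two-sided p doubles the
smaller tail, capped at 1.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .pca import fit_pca, transform
from .pattern import MetabolicPattern, derive_pattern, expression_scores, zscore
from .preprocess import DataMatrix
from .svm import classify, train_svc, train_svr

__all__ = [
    "TimepointResult",
    "LoocvReport",
    "LongitudinalReport",
    "wilcoxon_rank_sum",
    "loocv_scores",
    "loocv_week9",
    "longitudinal_projection",
]

EXACT_LIMIT = 25


def _exact_ranksum_p(w_obs: float, n_a: int, n_b: int) -> float:
    """Exact two-sided p for the rank-sum W of group a (no ties).

    Counts, for every achievable sum w, the number of n_a-subsets of ranks
    {1..n} with that sum — the full enumeration distribution — via DP.
    """
    n = n_a + n_b
    max_sum = n * (n + 1) // 2
    # counts[k, w] = number of k-subsets of {1..r} summing to w
    counts = np.zeros((n_a + 1, max_sum + 1))
    counts[0, 0] = 1.0
    for r in range(1, n + 1):
        kmax = min(r, n_a)
        for k in range(kmax, 0, -1):
            counts[k, r:] += counts[k - 1, : max_sum + 1 - r]
    dist = counts[n_a]
    total = dist.sum()
    w = int(round(w_obs))
    p_low = dist[: w + 1].sum() / total
    p_high = dist[w:].sum() / total
    return float(min(1.0, 2.0 * min(p_low, p_high)))


def wilcoxon_rank_sum(a, b) -> tuple[float, float]:
    """Two-sided Wilcoxon rank-sum test; returns (rank-sum of a, p)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be nonempty")
    pooled = np.concatenate([a, b])
    ranks = stats.rankdata(pooled)  # midranks for ties
    w = float(ranks[: a.size].sum())
    n_a, n_b, n = a.size, b.size, pooled.size
    has_ties = np.unique(pooled).size < n
    if not has_ties and n <= EXACT_LIMIT:
        return w, _exact_ranksum_p(w, n_a, n_b)
    mean = n_a * (n + 1) / 2.0
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = float(((tie_counts**3 - tie_counts).sum())) / (n * (n - 1))
    var = n_a * n_b / 12.0 * ((n + 1) - tie_term)
    if var <= 0:
        return w, 1.0
    diff = w - mean
    # continuity correction toward the mean
    cc = np.sign(diff) * 0.5 if abs(diff) > 0.5 else diff
    z = (diff - cc) / np.sqrt(var)
    p = float(min(1.0, 2.0 * stats.norm.sf(abs(z))))
    return w, p


@dataclass
class TimepointResult:
    timepoint: str
    z_scores: pd.DataFrame  # subject_id, group, raw, z
    wilcoxon_stat: float
    wilcoxon_p: float
    alpha: float = 0.05

    @property
    def significant(self) -> bool:
        return self.wilcoxon_p < self.alpha


@dataclass
class LoocvReport:
    """Held-out label and raw score per subject, plus per-group accuracies."""

    records: pd.DataFrame  # subject_id, group, true_label, pred_label, raw
    accuracy_pd: float
    accuracy_control: float

    @property
    def accuracy(self) -> float:
        return float((self.records["pred_label"] == self.records["true_label"]).mean())


def loocv_scores(
    data: DataMatrix,
    mode: str,
    C: float,
    kernel_scale: float = 1.0,
    epsilon: float | None = None,
    tol: float = 1e-3,
    positive_group: str = "PD",
) -> pd.DataFrame:
    """Held-out raw expression scores (and labels, for the classifier).

    Each fold refits PCA and the SVM on the remaining N-1 subjects (the
    feature transform is part of the model, so it must be refit to avoid
    leakage), and scores the held-out scan with that fold's sign-corrected
    pattern.  Applied to the final timepoint for both the classification
    and the regression pattern.
    """
    groups = data.meta["group"].to_numpy()
    labels = data.labels(positive_group)
    for g in np.unique(groups):
        if (groups == g).sum() < 2:
            raise ValueError(f"group {g!r} has fewer than 2 subjects")
    targets = labels if mode == "classify" else data.motor_scores()
    n = data.n
    rows = []
    for i in range(n):
        tr = [j for j in range(n) if j != i]
        fold = data.subset(tr)
        if np.unique(fold.meta["group"]).size < 2:
            raise ValueError("training fold contains a single class")
        basis = fit_pca(fold)
        coords = transform(basis, fold.X)
        if mode == "classify":
            model = train_svc(coords, targets[tr], C, kernel_scale, tol=tol)
            pred = int(classify(model, transform(basis, data.X[i])))
        elif mode == "regress":
            model = train_svr(coords, targets[tr], C, epsilon=epsilon,
                              kernel_scale=kernel_scale, tol=tol)
            pred = None
        else:
            raise ValueError(f"unknown mode {mode!r}")
        pat = derive_pattern(basis, model, training_data=fold, positive_group=positive_group)
        raw = float(expression_scores(pat, data.X[i][None, :])[0])
        rows.append(
            {
                "subject_id": data.meta["subject_id"].iloc[i],
                "group": groups[i],
                "true_label": int(labels[i]),
                "pred_label": pred,
                "raw": raw,
            }
        )
    return pd.DataFrame(rows)


def loocv_week9(
    data: DataMatrix,
    C: float,
    kernel_scale: float = 1.0,
    tol: float = 1e-3,
    positive_group: str = "PD",
) -> LoocvReport:
    """Leave-one-out cross-validation of the final-timepoint classifier."""
    rec = loocv_scores(
        data, "classify", C, kernel_scale=kernel_scale, tol=tol,
        positive_group=positive_group,
    )
    pd_mask = rec["group"] == positive_group
    acc_pd = float((rec.loc[pd_mask, "pred_label"] == rec.loc[pd_mask, "true_label"]).mean())
    acc_ct = float(
        (rec.loc[~pd_mask, "pred_label"] == rec.loc[~pd_mask, "true_label"]).mean()
    )
    return LoocvReport(records=rec, accuracy_pd=acc_pd, accuracy_control=acc_ct)


@dataclass
class LongitudinalReport:
    results: dict[str, TimepointResult]
    control_mu: float
    control_sigma: float
    scores: pd.DataFrame = field(repr=False, default=None)

    def summary_dict(self) -> dict:
        return {
            tp: {"p": r.wilcoxon_p, "significant": bool(r.significant)}
            for tp, r in self.results.items()
        }

    def plot(self, ax=None):
        """Box plots of Z-scores per timepoint and group (PD vs control)."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(7, 4))
        tps = list(self.results)
        data, positions, colors = [], [], []
        for k, tp in enumerate(tps):
            df = self.results[tp].z_scores
            for off, (grp, col) in enumerate([("PD", "tab:red"), ("control", "tab:blue")]):
                data.append(df.loc[df["group"] == grp, "z"].to_numpy())
                positions.append(2.5 * k + off)
                colors.append(col)
        bp = ax.boxplot(data, positions=positions, widths=0.8, patch_artist=True)
        for patch, col in zip(bp["boxes"], colors):
            patch.set_facecolor(col)
            patch.set_alpha(0.5)
        ax.set_xticks([2.5 * k + 0.5 for k in range(len(tps))])
        ax.set_xticklabels(
            [f"{tp}\np={self.results[tp].wilcoxon_p:.2g}" for tp in tps], fontsize=8
        )
        ax.set_ylabel("pattern expression (Z)")
        return ax


def longitudinal_projection(
    pattern: MetabolicPattern,
    matrices: dict[str, DataMatrix],
    loocv: LoocvReport | None = None,
    final_timepoint: str = "w9",
    alpha: float = 0.05,
    positive_group: str = "PD",
    control_group: str = "control",
) -> LongitudinalReport:
    """Project every timepoint onto the final-timepoint pattern and test.

    The Z reference is the mean/SD of the raw scores of all control scans
    across all timepoints (scored with the full pattern).  At the final
    timepoint, if a LOOCV report is given, each subject's raw score is the
    held-out score from its LOOCV fold, standardized against the same
    control reference.
    """
    raw_by_tp = {
        tp: expression_scores(pattern, dm) for tp, dm in matrices.items()
    }
    ctrl_scores = np.concatenate(
        [
            raw_by_tp[tp][matrices[tp].meta["group"].to_numpy() == control_group]
            for tp in matrices
        ]
    )
    _, mu, sigma = zscore(np.zeros(1), ctrl_scores)
    results: dict[str, TimepointResult] = {}
    all_rows = []
    for tp, dm in matrices.items():
        raw = raw_by_tp[tp].copy()
        if loocv is not None and tp == final_timepoint:
            rec = loocv.records if isinstance(loocv, LoocvReport) else loocv
            lut = dict(zip(rec["subject_id"], rec["raw"]))
            raw = np.array([lut[s] for s in dm.meta["subject_id"]])
        z = (raw - mu) / sigma
        df = dm.meta[["subject_id", "group"]].copy()
        df["timepoint"] = tp
        df["raw"] = raw
        df["z"] = z
        grp = dm.meta["group"].to_numpy()
        stat, p = wilcoxon_rank_sum(z[grp == positive_group], z[grp == control_group])
        results[tp] = TimepointResult(
            timepoint=tp, z_scores=df, wilcoxon_stat=stat, wilcoxon_p=p, alpha=alpha
        )
        all_rows.append(df)
    return LongitudinalReport(
        results=results,
        control_mu=mu,
        control_sigma=sigma,
        scores=pd.concat(all_rows, ignore_index=True),
    )
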