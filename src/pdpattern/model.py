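"""Model/Results facade over the pattern-derivation pipeline.

``BrainPatternModel`` is constructed from a preprocessed final-timepoint
:class:`~pdpattern.preprocess.DataMatrix`; ``fit()`` runs PCA, (optionally)
grid-search hyperparameter selection under nested k-fold CV, SMO training,
and voxel-pattern reconstruction, returning a ``BrainPatternResults`` that
carries the pattern and exposes expression scoring, LOOCV, longitudinal
projection and regional summaries.

``run_study`` orchestrates the full analysis of a (phantom or real) cohort:
both the disease-specific pattern (classification, PDSP) and the
motor-score pattern (regression, PDMP) are derived at the final timepoint
and every earlier timepoint is projected onto them.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import longitudinal as lg
from . import pattern as pt
from . import pca as _pca
from . import regional as rg
from . import svm as _svm
from .preprocess import DataMatrix, build_data_matrix

__all__ = ["BrainPatternModel", "BrainPatternResults", "StudyReport", "run_study"]

DEFAULT_C_GRID = tuple(10.0**k for k in range(-3, 4))
DEFAULT_SCALE_GRID = tuple(2.0**k for k in range(-3, 4))


class BrainPatternModel:
    """Covariance-pattern model: PCA feature transform + linear SVM.

    Parameters
    ----------
    data : DataMatrix
        Preprocessed scans of the training timepoint (typically the final
        one, where the disease signal is stable).
    mode : {"classify", "regress"}
        "classify" separates the disease group from controls (disease-
        specific pattern); "regress" predicts motor scores (motor pattern).
    targets : array-like, optional
        Training targets; defaults to +/-1 group labels (classify) or the
        motor scores carried in the metadata (regress).
    """

    def __init__(self, data: DataMatrix, mode: str = "classify", targets=None,
                 positive_group: str = "PD"):
        if mode not in ("classify", "regress"):
            raise ValueError(f"unknown mode {mode!r}")
        data.validate()
        self.data = data
        self.mode = mode
        self.positive_group = positive_group
        if targets is not None:
            self.targets = np.asarray(targets, dtype=float)
        elif mode == "classify":
            self.targets = data.labels(positive_group)
        else:
            self.targets = data.motor_scores()

    @classmethod
    def from_cohort(cls, scans, mask, fwhm: float = 1.6, voxel_size=1.0,
                    timepoint: str = "w9", mode: str = "classify", **kw):
        """Build directly from raw scans of one timepoint."""
        tp_scans = [s for s in scans if s.timepoint == timepoint]
        dm = build_data_matrix(tp_scans, mask, fwhm, voxel_size)
        return cls(dm, mode=mode, **kw)

    def fit(
        self,
        C: float | None = None,
        kernel_scale: float | None = None,
        epsilon: float | None = None,
        C_grid=DEFAULT_C_GRID,
        scale_grid=DEFAULT_SCALE_GRID,
        cv_folds: int = 10,
        seed: int = 0,
        tol: float = 1e-3,
        timepoint: str | None = None,
    ) -> "BrainPatternResults":
        """Fit the transform and the SVM; derive the voxel pattern.

        If C or kernel_scale is None, both are selected by grid search with
        seeded nested k-fold CV (stratified for classification, with the
        fold count lowered to the smallest class size when needed).
        """
        basis = _pca.fit_pca(self.data)
        coords = _pca.transform(basis, self.data.X)
        grid_result = None
        if C is None or kernel_scale is None:
            k = cv_folds
            if self.mode == "classify":
                counts = self.data.meta["group"].value_counts()
                k = min(k, int(counts.min()))
            k = min(k, self.data.n)
            grid_result = _svm.grid_search_nested_cv(
                coords, self.targets, C_grid, scale_grid, k=k, seed=seed,
                mode=self.mode, tol=tol,
            )
            C = grid_result.C if C is None else C
            kernel_scale = grid_result.kernel_scale if kernel_scale is None else kernel_scale
        if self.mode == "classify":
            solution = _svm.train_svc(coords, self.targets, C, kernel_scale, tol=tol)
        else:
            solution = _svm.train_svr(
                coords, self.targets, C, epsilon=epsilon, kernel_scale=kernel_scale, tol=tol
            )
        pattern = pt.derive_pattern(
            basis, solution, training_data=self.data,
            positive_group=self.positive_group, timepoint=timepoint,
        )
        return BrainPatternResults(
            model=self, basis=basis, svm=solution, pattern=pattern,
            grid_result=grid_result,
        )


@dataclass
class BrainPatternResults:
    """Fit results: PCA basis, SVM solution and the voxel pattern."""

    model: BrainPatternModel
    basis: _pca.PCABasis
    svm: _svm.SVMSolution
    pattern: pt.MetabolicPattern
    grid_result: _svm.GridSearchResult | None = None

    # -- scoring ----------------------------------------------------------
    def expression_scores(self, data, centering: bool = True) -> np.ndarray:
        return pt.expression_scores(self.pattern, data, centering=centering)

    def loocv(self, tol: float = 1e-3) -> lg.LoocvReport:
        if self.model.mode != "classify":
            raise ValueError("LOOCV accuracy is defined for the classifier")
        return lg.loocv_week9(
            self.model.data, C=self.svm.C, kernel_scale=self.svm.kernel_scale,
            tol=tol, positive_group=self.model.positive_group,
        )

    def project(self, matrices: dict[str, DataMatrix], loocv=None,
                final_timepoint: str = "w9", alpha: float = 0.05) -> lg.LongitudinalReport:
        return lg.longitudinal_projection(
            self.pattern, matrices, loocv=loocv, final_timepoint=final_timepoint,
            alpha=alpha, positive_group=self.model.positive_group,
        )

    def region_weighting(self, atlas, predominance_ratio: float = 2.0) -> pd.DataFrame:
        return rg.weighting_table(
            rg.region_weighting(self.pattern, atlas, predominance_ratio)
        )

    # -- reporting --------------------------------------------------------
    def summary(self) -> str:
        m = self.model
        s = self.svm
        lines = [
            "Covariance brain-pattern model",
            "=" * 46,
            f"mode:            {m.mode}"
            + ("  (disease-specific pattern)" if m.mode == "classify" else "  (motor pattern)"),
            f"subjects:        {m.data.n}  (D = {m.data.d} masked voxels)",
            f"components:      {self.basis.k}",
            f"C:               {s.C:g}",
            f"kernel scale:    {s.kernel_scale:g}",
        ]
        if s.epsilon is not None:
            lines.append(f"epsilon:         {s.epsilon:g}")
        if self.grid_result is not None:
            lines.append(f"grid-search CV loss: {self.grid_result.cv_loss:.4f}")
        lines += [
            f"support vectors: {len(s.support_)} / {len(s.alphas)}",
            f"bias b:          {s.b:+.4f}",
            f"sign flipped:    {self.pattern.provenance['sign_flipped']}",
        ]
        if m.mode == "classify":
            pred = _svm.classify(self.svm, _pca.transform(self.basis, m.data.X))
            acc = float(np.mean(pred == m.targets))
            lines.append(f"training accuracy: {acc:.3f}")
        else:
            pred = _svm.decision_value(self.svm, _pca.transform(self.basis, m.data.X))
            mae = float(np.mean(np.abs(pred - m.targets)))
            lines.append(f"training MAE:    {mae:.3f}")
        return "\n".join(lines)


@dataclass
class StudyReport:
    """Full-cohort analysis: both patterns with their longitudinal reports."""

    results: dict[str, BrainPatternResults]          # "pdsp" / "pdmp"
    loocv: lg.LoocvReport | None
    projections: dict[str, lg.LongitudinalReport]
    matrices: dict[str, DataMatrix] = field(repr=False, default=None)

    def score_correlations(self) -> dict[str, float]:
        """Pooled PDSP-PDMP expression-score Pearson r per timepoint."""
        if not {"pdsp", "pdmp"} <= set(self.projections):
            raise ValueError("both patterns are needed for score correlations")
        out = {}
        a = self.projections["pdsp"]
        b = self.projections["pdmp"]
        for tp in a.results:
            out[tp] = rg.score_correlation(
                a.results[tp].z_scores["raw"].to_numpy(),
                b.results[tp].z_scores["raw"].to_numpy(),
            )
        return out


def run_study(
    scans,
    mask,
    fwhm: float = 1.6,
    voxel_size=1.0,
    final_timepoint: str = "w9",
    modes: tuple[str, ...] = ("pdsp", "pdmp"),
    hyperparams: dict | None = None,
    grid_cv_folds: int = 10,
    seed: int = 0,
    tol: float = 1e-3,
    alpha: float = 0.05,
) -> StudyReport:
    """End-to-end analysis of a longitudinal cohort.

    ``hyperparams`` may fix {"C": ..., "kernel_scale": ...} to skip the grid
    search (used for large calibration sweeps); otherwise both are selected
    by nested CV at the final timepoint.
    """
    timepoints = sorted({s.timepoint for s in scans},
                        key=lambda t: (t != "baseline", t))
    matrices = {
        tp: build_data_matrix([s for s in scans if s.timepoint == tp],
                              mask, fwhm, voxel_size)
        for tp in timepoints
    }
    hp = hyperparams or {}
    results: dict[str, BrainPatternResults] = {}
    projections: dict[str, lg.LongitudinalReport] = {}
    loocv = None
    for name in modes:
        mode = "classify" if name == "pdsp" else "regress"
        model = BrainPatternModel(matrices[final_timepoint], mode=mode)
        res = model.fit(
            C=hp.get("C"), kernel_scale=hp.get("kernel_scale"),
            epsilon=hp.get("epsilon"), cv_folds=grid_cv_folds, seed=seed,
            tol=tol, timepoint=final_timepoint,
        )
        results[name] = res
        # final-timepoint scores are always held out (fold-refit PCA + SVM)
        if mode == "classify":
            loocv = res.loocv(tol=tol)
            holdout = loocv
        else:
            holdout = lg.loocv_scores(
                matrices[final_timepoint], "regress", C=res.svm.C,
                kernel_scale=res.svm.kernel_scale, epsilon=res.svm.epsilon, tol=tol,
            )
        projections[name] = res.project(
            matrices,
            loocv=holdout,
            final_timepoint=final_timepoint,
            alpha=alpha,
        )
    return StudyReport(results=results, loocv=loocv, projections=projections,
                       matrices=matrices)
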