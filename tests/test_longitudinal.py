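import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from pdpattern.longitudinal import (
    longitudinal_projection,
    loocv_scores,
    loocv_week9,
    wilcoxon_rank_sum,
)
from pdpattern.pattern import MetabolicPattern
from pdpattern.preprocess import DataMatrix, build_data_matrix

from _oracles import wilcoxon_enumeration_p
from conftest import make_matrix


class TestWilcoxon:
    def test_two_vs_two_extreme(self):
        """a={1,2} vs b={3,4}: W=3 is the minimum; exact two-sided p=2/6."""
        w, p = wilcoxon_rank_sum([1, 2], [3, 4])
        assert w == 3.0
        assert p == pytest.approx(1 / 3)

    def test_identical_groups_give_p_one(self):
        _, p = wilcoxon_rank_sum([1, 2, 3], [1, 2, 3])
        assert p == 1.0

    def test_exact_branch_matches_enumeration_oracle(self):
        rng = np.random.default_rng(0)
        for n_a, n_b in itertools.product(range(1, 7), range(1, 7)):
            a = rng.normal(size=n_a)
            b = rng.normal(size=n_b)
            _, p = wilcoxon_rank_sum(a, b)
            assert p == pytest.approx(wilcoxon_enumeration_p(a, b), abs=1e-12)

    def test_exact_branch_matches_scipy_exact(self):
        rng = np.random.default_rng(1)
        for _ in range(20):
            a = rng.normal(size=int(rng.integers(3, 11)))
            b = rng.normal(size=int(rng.integers(3, 11)))
            _, p = wilcoxon_rank_sum(a, b)
            ref = stats.mannwhitneyu(a, b, alternative="two-sided", method="exact").pvalue
            assert p == pytest.approx(ref, abs=1e-10)

    def test_large_sample_approximation_tracks_scipy(self):
        rng = np.random.default_rng(2)
        a = rng.normal(0.3, 1, size=20)
        b = rng.normal(0, 1, size=18)
        _, p = wilcoxon_rank_sum(a, b)
        ref = stats.mannwhitneyu(a, b, alternative="two-sided", method="asymptotic").pvalue
        assert p == pytest.approx(ref, rel=0.05)

    def test_tied_data_uses_midranks(self):
        a = [1.0, 2.0, 2.0, 5.0]
        b = [2.0, 3.0, 4.0, 6.0]
        w, p = wilcoxon_rank_sum(a, b)
        assert 0 < p <= 1.0

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            wilcoxon_rank_sum([], [1.0])


class TestLoocv:
    def test_perfectly_separated_cohort_classified_exactly(self, small_w9):
        report = loocv_week9(small_w9, C=100.0)
        assert report.accuracy_pd == 1.0
        assert report.accuracy_control == 1.0
        assert len(report.records) == small_w9.n

    def test_fold_training_sizes(self, small_w9):
        rec = loocv_scores(small_w9, "classify", C=1.0)
        # every subject held out exactly once
        assert sorted(rec["subject_id"]) == sorted(small_w9.meta["subject_id"])

    def test_no_leakage_from_held_out_scan(self, small_w9):
        """The held-out subject's scan influences nothing in its fold model:
        its LOOCV score with a perturbed scan equals scoring the perturbed
        scan against the fold model fit without it."""
        from pdpattern.pca import fit_pca, transform
        from pdpattern.pattern import derive_pattern, expression_scores
        from pdpattern.svm import train_svc

        # fold model for subject 0, fit manually on the other rows
        fold = small_w9.subset(range(1, small_w9.n))
        basis = fit_pca(fold)
        model = train_svc(
            transform(basis, fold.X), fold.labels(), C=100.0, tol=1e-3
        )
        pat = derive_pattern(basis, model, training_data=fold)

        X = small_w9.X.copy()
        X[0] = np.roll(X[0], 17)  # perturb held-out scan; row invariants kept
        perturbed = DataMatrix(
            X=X, mask_index=small_w9.mask_index, meta=small_w9.meta, shape=small_w9.shape
        )
        rec = loocv_scores(perturbed, "classify", C=100.0)
        expected = float(expression_scores(pat, X[0][None, :])[0])
        assert rec["raw"].iloc[0] == expected

    def test_regression_mode_scores_every_subject(self, small_w9):
        rec = loocv_scores(small_w9, "regress", C=1.0)
        assert rec["pred_label"].isna().all()
        assert np.isfinite(rec["raw"]).all()

    def test_single_member_group_rejected(self):
        rng = np.random.default_rng(3)
        dm = make_matrix(
            rng.normal(size=(4, 6)) + np.linspace(0, 1, 6),
            groups=["PD", "control", "control", "control"],
        )
        dm.X = dm.X - dm.X.mean(1, keepdims=True)
        dm.X = dm.X / np.linalg.norm(dm.X, axis=1, keepdims=True)
        with pytest.raises(ValueError):
            loocv_week9(dm, C=1.0)


class TestProjection:
    def test_signal_cohort_significant_only_after_onset(self, small_cohort):
        atlas, mask, truth, truth_vec, scans = small_cohort
        mats = {
            tp: build_data_matrix([s for s in scans if s.timepoint == tp], mask, 1.6)
            for tp in ("baseline", "w9")
        }
        from pdpattern.model import BrainPatternModel

        res = BrainPatternModel(mats["w9"]).fit(C=1.0, kernel_scale=1.0)
        loocv = loocv_week9(mats["w9"], C=1.0)
        report = longitudinal_projection(res.pattern, mats, loocv=loocv)
        assert not report.results["baseline"].significant
        assert report.results["w9"].significant
        assert report.results["w9"].wilcoxon_p > 0

    def test_all_control_scores_self_standardize(self):
        """Projecting a control-only cohort: pooled z has mean 0, sd 1."""
        rng = np.random.default_rng(5)
        d = 30
        pat = MetabolicPattern(
            p=rng.normal(size=d), mask_index=None, training_mean=np.zeros(d)
        )
        mats = {}
        for tp in ("baseline", "w9"):
            X = rng.normal(size=(6, d))
            mats[tp] = make_matrix(X, groups=["control"] * 6)
        # wilcoxon needs both groups; relabel one subject per timepoint as PD
        for tp in mats:
            mats[tp].meta.loc[0, "group"] = "PD"
        report = longitudinal_projection(pat, mats)
        ctrl_z = report.scores[report.scores["group"] == "control"]["z"]
        pd_z = report.scores[report.scores["group"] == "PD"]["z"]
        all_ctrl_raw = report.scores[report.scores["group"] == "control"]["raw"]
        z_of_ref = (all_ctrl_raw - report.control_mu) / report.control_sigma
        assert z_of_ref.mean() == pytest.approx(0.0, abs=1e-12)
        assert z_of_ref.std(ddof=1) == pytest.approx(1.0, abs=1e-12)

    def test_missing_timepoint_simply_absent(self, small_cohort):
        atlas, mask, truth, truth_vec, scans = small_cohort
        mats = {
            "w9": build_data_matrix(
                [s for s in scans if s.timepoint == "w9"], mask, 1.6
            )
        }
        rng = np.random.default_rng(0)
        from pdpattern.model import BrainPatternModel

        res = BrainPatternModel(mats["w9"]).fit(C=1.0, kernel_scale=1.0)
        report = longitudinal_projection(res.pattern, mats)
        assert set(report.results) == {"w9"}
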