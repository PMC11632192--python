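"""Statistics: LMM, contrasts, Bayesian shrinkage, WAIC/LOO, rmcorr."""

import numpy as np
import pandas as pd
import pytest

from mwtbio.simstudy import CohortSpec, StudyDesign, simulate_study
from mwtbio.stats import (
    ModelDesign,
    PriorSpec,
    contrasts_change_from_baseline,
    fit_bayes_shrunk,
    fit_lmm,
    rmcorr,
    score_model,
    sweep_hyperparameter,
)
from mwtbio.stats._lmm import build_design_matrix


def model_dgp_table(frame, siesta=0.05, subject_sd=0.02, noise_sd=0.01, seed=0):
    """A StudyTable drawn from the LMM's own data-generating process."""
    rng = np.random.default_rng(seed)
    tab = frame.copy()
    subjects = tab.participant.unique()
    u = dict(zip(subjects, rng.normal(0, subject_sd, len(subjects))))
    tab["y"] = (
        0.1
        + siesta * tab.isSiesta
        + tab.participant.map(u)
        + rng.normal(0, noise_sd, len(tab))
    )
    return tab


@pytest.fixture(scope="module")
def design_frame(small_study):
    return small_study.design


class TestDesignMatrix:
    def test_columns_and_reference_levels(self, small_endpoints):
        X, info = build_design_matrix(
            small_endpoints, ModelDesign(response="sleepiness_slope")
        )
        assert info["reference_treatment"] == "placebo"
        assert info["days"][0] == "baseline"
        assert "day[day1]:treatment[drug]" in X.columns

    def test_rank_deficiency_names_aliased_columns(self, small_endpoints):
        tab = small_endpoints.copy()
        tab["treatment"] = np.where(tab.day == "baseline", "placebo", "drug")
        # treatment now a function of day -> interaction aliased
        with pytest.raises(ValueError, match="aliased"):
            build_design_matrix(tab, ModelDesign(response="sleepiness_slope"))


class TestLMM:
    def test_recovers_effects_under_model_dgp(self, design_frame):
        tab = model_dgp_table(design_frame, siesta=0.05, seed=1)
        fit = fit_lmm(tab, ModelDesign(response="y"))
        assert fit.converged
        assert fit.params["isSiesta"] == pytest.approx(0.05, abs=0.01)
        assert fit.participant_sd == pytest.approx(0.02, rel=0.6)

    def test_zero_participant_variance_boundary(self, design_frame):
        tab = model_dgp_table(design_frame, subject_sd=0.0, seed=2)
        fit = fit_lmm(tab, ModelDesign(response="y"))
        assert fit.participant_sd == pytest.approx(0.0, abs=2e-3)
        assert fit.converged

    def test_mean_estimate_tracks_true_siesta_through_pipeline(self):
        """Full-pipeline siesta estimate within 10% of truth on average."""
        from mwtbio.session_metrics import compile_endpoints

        design = StudyDesign(
            cohorts=(
                CohortSpec(
                    "P", 6, {"baseline": 0.12, "day1": 0.12, "day7": 0.12},
                    treatment="placebo",
                ),
                CohortSpec(
                    "A", 6, {"baseline": 0.12, "day1": 0.12, "day7": 0.12},
                    treatment="drug",
                ),
            ),
            siesta_slope_bump=0.05,
        )
        md = ModelDesign(response="sleepiness_slope")
        ests = []
        for r in range(30):
            study = simulate_study(design, seed=9000 + r)
            fit = fit_lmm(compile_endpoints(study), md)
            ests.append(fit.params["isSiesta"])
        assert np.mean(ests) == pytest.approx(0.05, rel=0.10)

    def test_too_few_subjects_rejected(self, design_frame):
        tab = model_dgp_table(design_frame, seed=3)
        tab = tab[tab.participant == tab.participant.iloc[0]]
        with pytest.raises(ValueError, match="subjects"):
            fit_lmm(tab, ModelDesign(response="y"))


class TestContrasts:
    def test_treatment_effect_detected_with_power(self, small_study):
        """Drug halves the slope on day 1: strongly negative contrast."""
        from mwtbio.session_metrics import compile_endpoints

        tab = compile_endpoints(small_study)
        md = ModelDesign(response="sleepiness_slope")
        fit = fit_lmm(tab, md)
        ct = contrasts_change_from_baseline(fit, md)
        drug_day1 = ct[(ct.treatment == "drug") & (ct.day == "day1")].iloc[0]
        assert drug_day1.estimate < 0
        assert abs(drug_day1.z) > 2

    def test_null_arm_contrast_centered_at_zero(self, design_frame):
        md = ModelDesign(response="y")
        ests = []
        for r in range(25):
            tab = model_dgp_table(design_frame, siesta=0.0, seed=100 + r)
            fit = fit_lmm(tab, md)
            ct = contrasts_change_from_baseline(fit, md)
            ests.extend(ct[ct.treatment == "placebo"].estimate)
        assert np.mean(ests) == pytest.approx(0.0, abs=3 * np.std(ests) / np.sqrt(len(ests)) + 1e-4)

    def test_contrast_invariant_to_constant_shifts(self, design_frame):
        """The day-difference contrast ignores intercept-level shifts."""
        md = ModelDesign(response="y")
        tab = model_dgp_table(design_frame, seed=7)
        ct1 = contrasts_change_from_baseline(fit_lmm(tab, md), md)
        tab2 = tab.assign(y=tab.y + 123.0)
        ct2 = contrasts_change_from_baseline(fit_lmm(tab2, md), md)
        assert np.allclose(ct1.estimate, ct2.estimate, atol=1e-6)

    def test_missing_level_rejected(self, design_frame):
        md = ModelDesign(response="y", baseline_day="day99")
        with pytest.raises(ValueError, match="day99"):
            fit_lmm(model_dgp_table(design_frame), md)


class TestBayesShrunk:
    def test_tiny_t_shrinks_everything_to_zero(self, design_frame):
        tab = model_dgp_table(design_frame, siesta=0.05, seed=4)
        post = fit_bayes_shrunk(
            tab, ModelDesign(response="y"), PriorSpec(1e-4), chains=2, iters=600, seed=0
        )
        assert post.posterior_mean().drop("Intercept").abs().max() < 1e-2

    def test_large_t_matches_reml_on_identified_effects(self, small_endpoints):
        md = ModelDesign(response="sleepiness_slope")
        reml = fit_lmm(small_endpoints, md)
        post = fit_bayes_shrunk(
            small_endpoints, md, PriorSpec(100.0), chains=2, iters=1500, seed=1
        )
        pm = post.posterior_mean()
        for name in reml.params.index:
            if abs(reml.params[name]) > 2 * reml.bse[name]:
                assert pm[name] == pytest.approx(reml.params[name], rel=0.05)

    def test_identically_zero_cell_stays_finite(self, small_endpoints):
        tab = small_endpoints.copy()
        cell = (tab.treatment == "drug") & (tab.day == "day1")
        tab.loc[cell, "microsleep_rate"] = 0.0
        post = fit_bayes_shrunk(
            tab,
            ModelDesign(response="microsleep_rate"),
            PriorSpec(3.0),
            chains=2,
            iters=800,
            seed=2,
        )
        assert np.isfinite(post.posterior_mean()).all()
        assert np.isfinite(post.posterior_sd()).all()
        assert (post.posterior_sd() > 0).all()

    def test_shrinkage_monotone_in_t(self, small_endpoints):
        """Tighter priors shrink the coefficient vector.

        The L2 norm of the non-intercept posterior means is nondecreasing
        in t (the ridge-path norm property); the balanced, orthogonal
        isSiesta coordinate is itself monotone.  Per-coordinate
        monotonicity cannot hold in general: correlated day x treatment
        columns trade signal as the prior tightens.
        """
        md = ModelDesign(response="sleepiness_slope")
        fits = [
            fit_bayes_shrunk(
                small_endpoints, md, PriorSpec(t), chains=2, iters=2000, seed=3
            )
            for t in (0.005, 0.02, 0.1, 1.0)
        ]
        means = [f.posterior_mean().drop("Intercept") for f in fits]
        sds = [f.posterior_sd().drop("Intercept") for f in fits]
        for m1, m2, s2 in zip(means, means[1:], sds[1:]):
            assert np.linalg.norm(m1) <= np.linalg.norm(m2) + 0.02 * np.linalg.norm(s2)
            assert abs(m1["isSiesta"]) <= abs(m2["isSiesta"]) + 0.02 * s2["isSiesta"]

    def test_fixed_seed_reproducible(self, design_frame):
        tab = model_dgp_table(design_frame, seed=5)
        md = ModelDesign(response="y")
        a = fit_bayes_shrunk(tab, md, PriorSpec(1.0), chains=2, iters=400, seed=11)
        b = fit_bayes_shrunk(tab, md, PriorSpec(1.0), chains=2, iters=400, seed=11)
        assert np.array_equal(a.beta, b.beta)

    def test_rhat_reported_for_every_parameter(self, design_frame):
        tab = model_dgp_table(design_frame, seed=6)
        post = fit_bayes_shrunk(
            tab, ModelDesign(response="y"), PriorSpec(1.0), chains=2, iters=400, seed=0
        )
        assert set(post.beta_names) <= set(post.rhat.index)
        assert {"sigma_e", "sigma_u"} <= set(post.rhat.index)


class TestModelScore:
    def test_too_few_draws_rejected(self, design_frame):
        tab = model_dgp_table(design_frame, seed=7)
        post = fit_bayes_shrunk(
            tab, ModelDesign(response="y"), PriorSpec(1.0), chains=1, iters=100, seed=0
        )
        with pytest.raises(ValueError, match="100"):
            score_model(post)

    def test_duplicated_rows_double_waic(self, design_frame):
        tab = model_dgp_table(design_frame, seed=8)
        md = ModelDesign(response="y")
        s1 = score_model(
            fit_bayes_shrunk(tab, md, PriorSpec(1.0), chains=2, iters=800, seed=0),
            refit=False,
        )
        doubled = pd.concat([tab, tab], ignore_index=True)
        s2 = score_model(
            fit_bayes_shrunk(doubled, md, PriorSpec(1.0), chains=2, iters=800, seed=0),
            refit=False,
        )
        assert s2.waic == pytest.approx(2 * s1.waic, rel=0.10)

    def test_loo_prefers_generating_model(self, small_endpoints):
        md_full = ModelDesign(response="sleepiness_slope")
        md_red = ModelDesign(response="sleepiness_slope", include_interaction=False)
        sf = score_model(
            fit_bayes_shrunk(
                small_endpoints, md_full, PriorSpec(3.0), chains=2, iters=800, seed=0
            ),
            refit=False,
        )
        sr = score_model(
            fit_bayes_shrunk(
                small_endpoints, md_red, PriorSpec(3.0), chains=2, iters=800, seed=0
            ),
            refit=False,
        )
        assert sf.loo < sr.loo  # deviance scale: lower is better


class TestSweep:
    def test_grid_validation(self, design_frame):
        tab = model_dgp_table(design_frame, seed=9)
        md = ModelDesign(response="y")
        with pytest.raises(ValueError, match="at least 5"):
            sweep_hyperparameter(tab, md, [0.1, 1.0, 10.0])
        with pytest.raises(ValueError, match="increasing"):
            sweep_hyperparameter(tab, md, [1.0, 0.5, 2.0, 3.0, 4.0])
        with pytest.raises(ValueError, match="positive"):
            sweep_hyperparameter(tab, md, [-1.0, 0.5, 1.0, 2.0, 3.0])

    def test_strong_effects_reject_full_shrinkage(self, small_endpoints):
        md = ModelDesign(response="sleepiness_slope")
        sweep = sweep_hyperparameter(
            small_endpoints, md, [0.001, 0.01, 0.1, 1.0, 10.0],
            seed=0, chains=2, iters=600,
        )
        assert sweep.t_star > sweep.table.t.iloc[0]
        assert not sweep.weak_inflection

    def test_pure_noise_flags_weak_inflection(self, design_frame):
        rng = np.random.default_rng(0)
        tab = design_frame.copy()
        tab["y"] = rng.normal(0, 1.0, len(tab))
        sweep = sweep_hyperparameter(
            tab, ModelDesign(response="y"), [0.01, 0.1, 1.0, 10.0, 100.0],
            seed=0, chains=2, iters=600,
        )
        assert sweep.weak_inflection


class TestRmCorr:
    def test_perfect_offset_data(self):
        rows = []
        for s, off in zip("abc", (0.0, 5.0, -2.0)):
            for x in range(4):
                rows.append({"participant": s, "x": float(x), "y": x + off})
        res = rmcorr(pd.DataFrame(rows), "x", "y")
        assert res.r == pytest.approx(1.0)
        assert res.df == 12 - 3 - 1

    def test_constant_y_within_subject(self):
        rows = []
        for s, off in zip("abc", (1.0, 2.0, 3.0)):
            for x in range(4):
                rows.append({"participant": s, "x": float(x), "y": off})
        res = rmcorr(pd.DataFrame(rows), "x", "y")
        assert res.r == pytest.approx(0.0, abs=1e-12)

    def test_matches_ancova_oracle(self):
        """Mixed-slope table vs an explicit dummy-coded ANCOVA via lstsq."""
        rng = np.random.default_rng(13)
        rows = []
        for si, s in enumerate("abc"):
            for _ in range(4):
                x = rng.normal()
                rows.append(
                    {
                        "participant": s,
                        "x": x,
                        "y": (0.8 - 0.3 * si) * x + si + rng.normal(0, 0.3),
                    }
                )
        tab = pd.DataFrame(rows)
        res = rmcorr(tab, "x", "y")
        # oracle: full design matrix [subject dummies | x], SS decomposition
        D = pd.get_dummies(tab.participant).to_numpy(dtype=float)
        X_full = np.column_stack([D, tab.x.to_numpy()])
        y = tab.y.to_numpy()
        beta_full, *_ = np.linalg.lstsq(X_full, y, rcond=None)
        ss_err = float(np.sum((y - X_full @ beta_full) ** 2))
        beta_sub, *_ = np.linalg.lstsq(D, y, rcond=None)
        ss_sub = float(np.sum((y - D @ beta_sub) ** 2))
        ss_x = ss_sub - ss_err
        r_oracle = np.sign(beta_full[-1]) * np.sqrt(ss_x / (ss_x + ss_err))
        assert res.r == pytest.approx(r_oracle, abs=1e-10)
        assert res.slope == pytest.approx(beta_full[-1], abs=1e-10)

    def test_matches_pingouin(self):
        pingouin = pytest.importorskip("pingouin")
        rng = np.random.default_rng(21)
        rows = []
        for s in "abcde":
            for _ in range(6):
                x = rng.normal()
                rows.append(
                    {"participant": s, "x": x, "y": 0.6 * x + rng.normal(0, 0.5)}
                )
        tab = pd.DataFrame(rows)
        res = rmcorr(tab, "x", "y")
        ref = pingouin.rm_corr(data=tab, x="x", y="y", subject="participant")
        assert res.r == pytest.approx(float(ref.r.iloc[0]), abs=1e-10)
        assert res.df == int(ref.dof.iloc[0])
        assert res.p == pytest.approx(float(ref.pval.iloc[0]), rel=1e-6)

    def test_small_subjects_dropped_with_warning(self):
        rows = [
            {"participant": "a", "x": 1.0, "y": 1.0},
            {"participant": "b", "x": 0.0, "y": 0.0},
            {"participant": "b", "x": 1.0, "y": 1.0},
            {"participant": "c", "x": 0.0, "y": 0.5},
            {"participant": "c", "x": 1.0, "y": 1.5},
            {"participant": "c", "x": 2.0, "y": 2.5},
        ]
        with pytest.warns(UserWarning, match="dropping"):
            res = rmcorr(pd.DataFrame(rows), "x", "y")
        assert res.n_subjects == 2

    def test_too_few_subjects_rejected(self):
        rows = [
            {"participant": "a", "x": 0.0, "y": 0.0},
            {"participant": "a", "x": 1.0, "y": 1.0},
        ]
        with pytest.raises(ValueError, match="2 subjects"):
            rmcorr(pd.DataFrame(rows), "x", "y")
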