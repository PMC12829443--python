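import numpy as np
import pandas as pd
import pytest
from scipy import stats

import fearcond as fc
from fearcond import associations as assoc
from fearcond.associations import (
    AssociationError,
    association_battery,
    residualize,
    spearman_bootstrap,
    steiger_compare,
)


class TestSpearmanBootstrap:
    def test_monotone_relationship_is_perfect(self):
        x = np.linspace(0, 5, 20)
        res = spearman_bootstrap(x, np.exp(x), n_boot=100, seed=0)
        assert res.rho == pytest.approx(1.0)
        res_rev = spearman_bootstrap(x, -np.exp(x), n_boot=100, seed=0)
        assert res_rev.rho == pytest.approx(-1.0)

    def test_invariant_under_monotone_transforms(self):
        rng = np.random.default_rng(1)
        x = rng.normal(size=50)
        y = 0.5 * x + rng.normal(size=50)
        r1 = spearman_bootstrap(x, y, n_boot=10, seed=0).rho
        r2 = spearman_bootstrap(np.exp(x), y**3, n_boot=10, seed=0).rho
        assert r1 == pytest.approx(r2)

    def test_tie_fixture_matches_rank_then_pearson_oracle(self):
        x = np.array([1.0, 2, 2, 3, 4, 5, 5, 5, 6, 7])
        y = np.array([2.0, 1, 3, 3, 5, 4, 6, 7, 7, 9])
        res = spearman_bootstrap(x, y, n_boot=10, seed=0)
        oracle = np.corrcoef(stats.rankdata(x), stats.rankdata(y))[0, 1]
        assert res.rho == pytest.approx(oracle, abs=1e-12)

    def test_ci_brackets_point_estimate(self):
        rng = np.random.default_rng(2)
        x = rng.normal(size=80)
        y = 0.6 * x + rng.normal(size=80)
        res = spearman_bootstrap(x, y, n_boot=2000, seed=3)
        assert -1 <= res.ci_lo <= res.rho <= res.ci_hi <= 1
        assert res.p < 0.01

    def test_zero_variance_rejected(self):
        with pytest.raises(AssociationError):
            spearman_bootstrap(np.ones(10), np.arange(10.0), n_boot=10, seed=0)

    def test_bootstrap_ci_coverage_near_nominal(self):
        """Percentile-bootstrap 95% CI coverage for rho on a known bivariate
        normal (rho_s = (6/pi) asin(r/2)) stays near 95%."""
        r = 0.5
        true_rho_s = 6 / np.pi * np.arcsin(r / 2)
        rng = np.random.default_rng(4)
        hits = 0
        reps = 300
        for _ in range(reps):
            x = rng.standard_normal(100)
            y = r * x + np.sqrt(1 - r * r) * rng.standard_normal(100)
            res = spearman_bootstrap(x, y, n_boot=400, seed=rng)
            hits += res.ci_lo <= true_rho_s <= res.ci_hi
        coverage = hits / reps
        assert 0.90 <= coverage <= 0.99

    def test_exact_permutation_p_close_to_t_approximation(self):
        rng = np.random.default_rng(5)
        x = rng.normal(size=20)
        y = 0.7 * x + rng.normal(size=20)
        approx = spearman_bootstrap(x, y, n_boot=10, seed=0).p
        exact = spearman_bootstrap(x, y, n_boot=10, seed=0, exact_p=True).p
        assert exact == pytest.approx(approx, abs=0.02)


class TestResidualize:
    def test_identical_scores_leave_no_residual(self):
        v = np.array([1.0, 4, 2, 8, 5, 7])
        res = residualize(v, v)
        assert np.allclose(res.gad_residual, 0, atol=1e-10)
        assert np.allclose(res.phq_residual, 0, atol=1e-10)
        z = (v - v.mean()) / v.std()
        assert np.allclose(res.shared, z)

    def test_orthogonal_scores_keep_centred_originals(self):
        gad = np.array([1.0, 2, 3, 4, 5, 6, 7, 8])
        phq = np.array([1.0, -1, -1, 1, 1, -1, -1, 1])  # r = 0 with gad
        assert abs(np.corrcoef(gad, phq)[0, 1]) < 1e-12
        res = residualize(gad, phq)
        assert np.allclose(res.gad_residual, gad - gad.mean())
        assert np.allclose(res.phq_residual, phq - phq.mean())

    def test_matches_normal_equations_oracle(self):
        gad = np.array([3.0, 7, 1, 9, 4, 6, 2, 8])
        phq = np.array([2.0, 5, 2, 8, 5, 5, 1, 9])
        res = residualize(gad, phq)
        X = np.column_stack([np.ones(8), phq])
        beta = np.linalg.solve(X.T @ X, X.T @ gad)
        assert np.allclose(res.gad_residual, gad - X @ beta, atol=1e-10)

    def test_residuals_orthogonal_to_regressor(self):
        rng = np.random.default_rng(6)
        gad = rng.integers(0, 22, 60).astype(float)
        phq = np.clip(gad + rng.integers(-4, 5, 60), 0, 24).astype(float)
        res = residualize(gad, phq)
        assert abs(np.dot(res.gad_residual, phq - phq.mean())) < 1e-8
        assert abs(np.dot(res.phq_residual, gad - gad.mean())) < 1e-8

    def test_constant_regressor_rejected(self):
        with pytest.raises(AssociationError):
            residualize(np.arange(5.0), np.ones(5))


class TestSteiger:
    def test_equal_absolute_correlations_give_null(self):
        res = steiger_compare(0.4, -0.4, 0.2, 50)
        assert res.t == 0.0
        assert res.p == pytest.approx(1.0)

    def test_sign_invariance(self):
        base = steiger_compare(0.5, 0.3, 0.4, 100)
        for r1, r2 in ((-0.5, 0.3), (0.5, -0.3), (-0.5, -0.3)):
            res = steiger_compare(r1, r2, 0.4, 100)
            assert res.t == pytest.approx(base.t)
            assert res.p == pytest.approx(base.p)

    def test_matches_published_formula_oracle(self):
        # independent literal evaluation of Steiger's (1980) Z with |r|
        r1, r2, r12, n = 0.5, 0.3, 0.4, 100
        z1, z2 = np.arctanh(r1), np.arctanh(r2)
        rbar = (r1 + r2) / 2
        s = (r12 * (1 - 2 * rbar**2) - 0.5 * rbar**2 * (1 - 2 * rbar**2 - r12**2)) / (
            1 - rbar**2
        ) ** 2
        t_expected = (z1 - z2) * np.sqrt((n - 3) / (2 * (1 - s)))
        res = steiger_compare(r1, r2, r12, n)
        assert res.t == pytest.approx(t_expected, abs=1e-12)
        assert res.t == pytest.approx(2.0349, abs=1e-4)
        assert res.p == pytest.approx(2 * stats.norm.sf(t_expected), abs=1e-12)

    def test_domain_errors(self):
        with pytest.raises(AssociationError):
            steiger_compare(1.0, 0.3, 0.4, 100)
        with pytest.raises(AssociationError):
            steiger_compare(0.5, 0.3, 1.0, 100)
        with pytest.raises(AssociationError):
            steiger_compare(0.5, 0.3, 0.4, 3)


class TestBattery:
    def _inputs(self, n=60, seed=0):
        rng = np.random.default_rng(seed)
        sids = [f"S{i}" for i in range(n)]
        params = pd.DataFrame(
            {
                "subject_id": sids,
                "lr_cs_plus_ext": rng.beta(2, 2, n),
                "lr_cs_minus_acq": rng.beta(2, 2, n),
                "lapse": rng.gamma(5, 1, n),
            }
        )
        measures = pd.DataFrame({"subject_id": sids})
        for col in (
            "acq_csp_mean", "acq_csm_mean", "acq_discrimination",
            "ext_csp_mean", "ext_csm_mean", "ext_discrimination",
        ):
            measures[col] = rng.uniform(1, 9, n)
        questionnaires = pd.DataFrame(
            {
                "subject_id": sids,
                "gad7": rng.integers(0, 22, n),
                "phq8": rng.integers(0, 25, n),
            }
        )
        return params, measures, questionnaires

    def test_grid_is_complete(self):
        params, measures, questionnaires = self._inputs()
        bat = association_battery(params, measures, questionnaires, n_boot=50, seed=0)
        n_vars = 3 + 6  # parameters + descriptive measures
        assert len(bat.correlations) == n_vars * 5
        assert set(bat.correlations["score"]) == set(assoc.SCORE_COLUMNS)
        # Steiger rows: each learning rate against its matching mean
        assert set(bat.steiger["parameter"]) == {"lr_cs_plus_ext", "lr_cs_minus_acq"}
        assert (bat.steiger["ci_lo"] <= bat.steiger["ci_hi"]).all()

    def test_orthogonal_scales_make_residuals_match_raw(self):
        params, measures, questionnaires = self._inputs(n=80, seed=1)
        rng = np.random.default_rng(2)
        gad = rng.normal(size=80)
        phq = rng.normal(size=80)
        phq -= np.polyval(np.polyfit(gad, phq, 1), gad)  # exactly orthogonal
        questionnaires["gad7"] = gad
        questionnaires["phq8"] = phq
        bat = association_battery(params, measures, questionnaires, n_boot=20, seed=3)
        sub = bat.correlations[bat.correlations["variable"] == "lr_cs_plus_ext"]
        raw = sub.loc[sub["score"] == "gad7", "rho"].iloc[0]
        resid = sub.loc[sub["score"] == "gad_residual", "rho"].iloc[0]
        assert resid == pytest.approx(raw, abs=0.02)

    def test_misaligned_subjects_rejected(self):
        params, measures, questionnaires = self._inputs()
        with pytest.raises(AssociationError):
            association_battery(params.iloc[:-5], measures, questionnaires, n_boot=10, seed=0)

    def test_recovers_generator_target_correlation(self):
        cohort = fc.generate_cohort(
            fc.CohortConfig(
                n_subjects=2000, target_assoc={"cs_plus_ext": -0.25}, missing_rate=0.0, seed=4
            )
        )
        params = cohort.true_parameters[["subject_id", "lr_cs_plus_ext"]]
        from fearcond.descriptives import descriptive_measures

        bat = association_battery(
            params, descriptive_measures(cohort.responses), cohort.questionnaires,
            n_boot=200, seed=5,
        )
        row = bat.correlations[
            (bat.correlations["variable"] == "lr_cs_plus_ext")
            & (bat.correlations["score"] == "gad7")
        ].iloc[0]
        assert row["rho"] == pytest.approx(-0.25, abs=0.05)
        assert row["ci_lo"] <= -0.25 <= row["ci_hi"]


def test_learning_rate_sign_convention_by_simulation(schedule):
    """Faster CS+ learning raises the CS+ whole-phase mean; faster CS-
    learning lowers the CS- whole-phase mean (responding moves toward the
    cue's asymptote more quickly)."""
    from fearcond import models
    from fearcond.descriptives import descriptive_measures

    spec = fc.get_model("2a")
    rng = np.random.default_rng(8)
    rows = {}
    for label, (lrp, lrm) in {
        "slow": (0.05, 0.05), "fast": (0.9, 0.9),
    }.items():
        ratings = {
            f"{label}{i}": models.simulate_ratings(
                spec,
                models.SubjectParameters({"cs_plus": lrp, "cs_minus": lrm}, lapse=30.0),
                schedule,
                rng,
            )
            for i in range(40)
        }
        resp = models.responses_frame(schedule, ratings)
        rows[label] = descriptive_measures(resp).mean(numeric_only=True)
    assert rows["fast"]["acq_csp_mean"] > rows["slow"]["acq_csp_mean"]
    assert rows["fast"]["acq_csm_mean"] < rows["slow"]["acq_csm_mean"]
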