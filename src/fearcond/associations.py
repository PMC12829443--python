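"""Associations between learning parameters and anxiety/depression severity.

All associations use Spearman's rho (the questionnaire totals are
zero-inflated and ordinal) with percentile-bootstrap 95% confidence
intervals over subject resampling and t-approximation p-values.  Because
GAD-7 and PHQ-8 are highly correlated, trait-specific effects are probed
with residualised scores (each scale regressed on the other by OLS) and a
shared-variance score; competing dependent correlations (a learning rate
vs its matching whole-phase mean, both correlated with the same anxiety
score) are compared with a Steiger Z test on absolute correlation values —
absolute because the sign of the learning-rate/responding relationship is
contingent on the cue.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .descriptives import MEASURE_COLUMNS

DEFAULT_BOOTSTRAP = 10_000


class AssociationError(ValueError):
    pass


@dataclass
class AssociationResult:
    rho: float
    ci_lo: float
    ci_hi: float
    p: float
    n: int


def spearman_bootstrap(
    x,
    y,
    n_boot: int = DEFAULT_BOOTSTRAP,
    seed: int | np.random.Generator = 0,
    exact_p: bool = False,
) -> AssociationResult:
    """Spearman's rho with a percentile-bootstrap 95% CI.

    rho uses average ranks (tie-corrected); the p-value is the
    t-approximation unless ``exact_p`` requests a permutation test (small
    samples only).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or len(x) < 4:
        raise AssociationError("spearman_bootstrap needs equal-length samples, n >= 4")
    if n_boot < 1:
        raise AssociationError("n_boot must be >= 1")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise AssociationError("correlation undefined for zero-variance input")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n = len(x)
    res = stats.spearmanr(x, y)
    rho = float(res.statistic)
    if exact_p:
        perm = stats.permutation_test(
            (x,),
            lambda xs: stats.spearmanr(xs, y).statistic,
            permutation_type="pairings",
            n_resamples=9999,
            rng=np.random.default_rng(rng.integers(2**31)),
        )
        p = float(perm.pvalue)
    else:
        p = float(res.pvalue)
    boots = np.empty(n_boot)
    for b in range(n_boot):
        idx = rng.integers(0, n, n)
        xb, yb = x[idx], y[idx]
        if np.ptp(xb) == 0 or np.ptp(yb) == 0:
            boots[b] = np.nan
            continue
        boots[b] = stats.spearmanr(xb, yb).statistic
    lo, hi = np.nanpercentile(boots, [2.5, 97.5])
    return AssociationResult(rho=rho, ci_lo=float(lo), ci_hi=float(hi), p=p, n=n)


@dataclass
class ResidualScores:
    """Trait-specific and shared components of the two severity scales."""

    gad_residual: np.ndarray  # GAD-7 regressed on PHQ-8
    phq_residual: np.ndarray  # PHQ-8 regressed on GAD-7
    shared: np.ndarray        # mean of the two standardised scale scores


def residualize(gad, phq) -> ResidualScores:
    """OLS residualisation in both directions plus a shared-variance score.

    The shared score is the per-subject mean of the two standardised scale
    totals (OLS residuals are orthogonal to their regressor but have no
    shared component by construction, so the common factor is summarised by
    the standardised-score mean).
    """
    gad = np.asarray(gad, dtype=float)
    phq = np.asarray(phq, dtype=float)
    if gad.shape != phq.shape or gad.ndim != 1 or len(gad) < 3:
        raise AssociationError("residualize needs equal-length samples, n >= 3")
    if np.ptp(gad) == 0 or np.ptp(phq) == 0:
        raise AssociationError("residualize needs non-constant scores")
    gad_on_phq = sm.OLS(gad, sm.add_constant(phq)).fit()
    phq_on_gad = sm.OLS(phq, sm.add_constant(gad)).fit()
    z = lambda v: (v - v.mean()) / v.std(ddof=0)
    return ResidualScores(
        gad_residual=np.asarray(gad_on_phq.resid),
        phq_residual=np.asarray(phq_on_gad.resid),
        shared=(z(gad) + z(phq)) / 2.0,
    )


@dataclass
class SteigerResult:
    t: float
    p: float
    r1_abs: float
    r2_abs: float
    r12: float
    n: int


def steiger_compare(r1: float, r2: float, r12: float, n: int) -> SteigerResult:
    """Steiger's Z for two dependent correlations sharing one variable,
    on absolute correlation values.

    ``r1`` and ``r2`` are the two correlations with the shared (anxiety)
    variable; ``r12`` is the correlation between the two competing
    predictors.  Uses Fisher-z transformed |r1|, |r2| scaled by the
    dependent-correlation covariance term; two-sided normal p.
    """
    for r, name in ((r1, "r1"), (r2, "r2")):
        if not -1.0 < r < 1.0:
            raise AssociationError(f"{name} must lie in (-1, 1)")
    if not -1.0 < r12 < 1.0:
        raise AssociationError("r12 must lie strictly inside (-1, 1)")
    if n <= 3:
        raise AssociationError("Steiger's Z requires n > 3")
    a1, a2 = abs(r1), abs(r2)
    z1, z2 = np.arctanh(a1), np.arctanh(a2)
    rbar = 0.5 * (a1 + a2)
    rb2 = rbar * rbar
    # covariance of the two dependent correlations (shared-variable form)
    s = (r12 * (1.0 - 2.0 * rb2) - 0.5 * rb2 * (1.0 - 2.0 * rb2 - r12 * r12)) / (
        (1.0 - rb2) ** 2
    )
    t = (z1 - z2) * np.sqrt((n - 3.0) / (2.0 * (1.0 - s)))
    p = 2.0 * stats.norm.sf(abs(t))
    return SteigerResult(float(t), float(p), a1, a2, float(r12), int(n))


#: Learning-rate role -> matching whole-phase-mean column for the Steiger
#: comparison of model-based vs descriptive associations.
ROLE_TO_MEASURE = {
    "cs_plus_acq_us_plus": "acq_csp_mean",
    "cs_plus_acq_us_minus": "acq_csp_mean",
    "cs_plus_acq": "acq_csp_mean",
    "cs_minus_acq": "acq_csm_mean",
    "cs_plus_ext": "ext_csp_mean",
    "cs_minus_ext": "ext_csm_mean",
}

SCORE_COLUMNS = ["gad7", "phq8", "gad_residual", "phq_residual", "shared"]


@dataclass
class AssociationBattery:
    """The full association grid plus Steiger comparisons."""

    correlations: pd.DataFrame
    steiger: pd.DataFrame
    n: int


def association_battery(
    parameter_estimates: pd.DataFrame,
    measures: pd.DataFrame,
    questionnaires: pd.DataFrame,
    n_boot: int = DEFAULT_BOOTSTRAP,
    seed: int = 0,
) -> AssociationBattery:
    """Correlate every model parameter and descriptive measure with the five
    severity scores, and compare each learning rate against its matching
    whole-phase mean with Steiger's Z.

    Inputs must share ``subject_id``; rows are inner-joined and order-aligned
    before analysis.
    """
    for frame, name in (
        (parameter_estimates, "parameter_estimates"),
        (measures, "measures"),
        (questionnaires, "questionnaires"),
    ):
        if "subject_id" not in frame.columns:
            raise AssociationError(f"{name} lacks a subject_id column")
    merged = questionnaires.merge(measures, on="subject_id").merge(
        parameter_estimates, on="subject_id"
    )
    if len(merged) != len(parameter_estimates) or len(merged) != len(questionnaires):
        raise AssociationError("subjects are misaligned across inputs")
    rng = np.random.default_rng(seed)

    res = residualize(merged["gad7"], merged["phq8"])
    scores = {
        "gad7": merged["gad7"].to_numpy(dtype=float),
        "phq8": merged["phq8"].to_numpy(dtype=float),
        "gad_residual": res.gad_residual,
        "phq_residual": res.phq_residual,
        "shared": res.shared,
    }

    param_cols = [c for c in parameter_estimates.columns if c != "subject_id"]
    measure_cols = [c for c in MEASURE_COLUMNS if c in measures.columns]
    rows = []
    for kind, cols in (("parameter", param_cols), ("descriptive", measure_cols)):
        for col in cols:
            vals = merged[col].to_numpy(dtype=float)
            for score_name in SCORE_COLUMNS:
                r = spearman_bootstrap(
                    vals, scores[score_name], n_boot=n_boot,
                    seed=np.random.default_rng(rng.integers(2**31)),
                )
                rows.append(
                    {
                        "variable": col,
                        "kind": kind,
                        "score": score_name,
                        "rho": r.rho,
                        "ci_lo": r.ci_lo,
                        "ci_hi": r.ci_hi,
                        "p": r.p,
                        "n": r.n,
                    }
                )
    correlations = pd.DataFrame(rows)

    steiger_rows = []
    gad = scores["gad7"]
    for col in param_cols:
        role = col[3:] if col.startswith("lr_") else None
        measure_col = ROLE_TO_MEASURE.get(role) if role else None
        if measure_col is None or measure_col not in merged.columns:
            continue
        lr_vals = merged[col].to_numpy(dtype=float)
        m_vals = merged[measure_col].to_numpy(dtype=float)
        r1 = stats.spearmanr(lr_vals, gad).statistic
        r2 = stats.spearmanr(m_vals, gad).statistic
        r12 = stats.spearmanr(lr_vals, m_vals).statistic
        result = steiger_compare(r1, r2, r12, len(merged))
        boots = np.empty(n_boot)
        for b in range(n_boot):
            idx = rng.integers(0, len(merged), len(merged))
            try:
                rb1 = stats.spearmanr(lr_vals[idx], gad[idx]).statistic
                rb2 = stats.spearmanr(m_vals[idx], gad[idx]).statistic
                rb12 = np.clip(stats.spearmanr(lr_vals[idx], m_vals[idx]).statistic, -0.999, 0.999)
                boots[b] = steiger_compare(rb1, rb2, rb12, len(merged)).t
            except (AssociationError, ValueError):
                boots[b] = np.nan
        lo, hi = np.nanpercentile(boots, [2.5, 97.5])
        steiger_rows.append(
            {
                "parameter": col,
                "measure": measure_col,
                "t": result.t,
                "ci_lo": float(lo),
                "ci_hi": float(hi),
                "p": result.p,
                "r_lr_gad": float(r1),
                "r_measure_gad": float(r2),
                "r12": float(r12),
                "n": result.n,
            }
        )
    return AssociationBattery(
        correlations=correlations, steiger=pd.DataFrame(steiger_rows), n=len(merged)
    )
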