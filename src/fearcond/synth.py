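"""Synthetic study cohorts.

The original participant data are not deposited, so every downstream stage
of the pipeline is exercised on synthetic cohorts whose statistical
structure mirrors the study design: per-subject Rescorla-Wagner parameters
drawn from group-level beta/gamma laws, trial-by-trial expectancy ratings
simulated from the generative model itself, zero-inflated ordinal GAD-7 and
PHQ-8 questionnaire totals, and post-experiment compliance metadata that
supports medium/strict exclusion filtering.

Cross-variable dependence is induced through a one-factor Gaussian copula:
a latent "distress" factor drives the GAD-7 latent directly, the PHQ-8
latent at a calibrated loading, and (optionally) selected learning-rate
latents at calibrated negative loadings.  Because discretisation attenuates
rank correlations, the latent loadings are calibrated numerically (Monte
Carlo inversion against the actual marginal transforms) so that the
*observed* Spearman correlations hit their targets.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from functools import lru_cache
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from . import models
from .schedule import ScheduleConfig, TrialSchedule, build_schedule

GAD7_MAX = 21
PHQ8_MAX = 24


class CohortConfigError(ValueError):
    """Raised for infeasible cohort configurations."""


# ---------------------------------------------------------------------------
# group-level hyperparameters


@dataclass(frozen=True)
class GroupHyperparameters:
    """Group-level (shape) hyperparameters.

    Subject learning rates, start values and the jump follow
    ``Beta(shape1 + 1, shape2 + 1)``; the subject lapse follows
    ``Gamma(lapse_shape, lapse_inv_scale)`` (shape/rate parameterisation).
    ``lr`` may be a single (shape1, shape2) pair applied to every
    learning-rate role, or a mapping from role name to pair.
    """

    lr: tuple | dict = (0.5, 0.5)
    lapse_shape: float = 5.0
    lapse_inv_scale: float = 5.0
    start: tuple = (0.5, 0.5)
    jump: tuple = (0.5, 0.5)

    def lr_for(self, role: str) -> tuple[float, float]:
        pair = self.lr[role] if isinstance(self.lr, dict) else self.lr
        return float(pair[0]), float(pair[1])

    def validate(self, roles=()) -> None:
        pairs = [self.lr_for(r) for r in roles] if roles else (
            list(self.lr.values()) if isinstance(self.lr, dict) else [self.lr]
        )
        for pair in [*pairs, self.start, self.jump]:
            if pair[0] <= 0 or pair[1] <= 0:
                raise CohortConfigError("hyperparameters must be positive")
        if self.lapse_shape <= 0 or self.lapse_inv_scale <= 0:
            raise CohortConfigError("lapse hyperparameters must be positive")

    @classmethod
    def prior_means(cls) -> "GroupHyperparameters":
        """Hyperparameters fixed at the means of their hyperpriors
        (Gamma(0.5, 1) for beta shapes, Gamma(5, 1) for the lapse pair)."""
        return cls(lr=(0.5, 0.5), lapse_shape=5.0, lapse_inv_scale=5.0,
                   start=(0.5, 0.5), jump=(0.5, 0.5))

    @classmethod
    def reference(cls) -> "GroupHyperparameters":
        """Reference simulation values: mid-range Beta(2, 2) learning rates
        and a decisive mean lapse of 5 (choice probabilities clearly peaked,
        so learning rates are identifiable from 60 trials)."""
        return cls(lr=(1.0, 1.0), lapse_shape=5.0, lapse_inv_scale=1.0,
                   start=(1.0, 1.0), jump=(1.0, 1.0))


def draw_subject_parameters(
    hyper: GroupHyperparameters,
    n: int,
    seed: int | np.random.Generator = 0,
    spec: models.ModelSpec | None = None,
) -> list[models.SubjectParameters]:
    """Draw independent subject parameter sets from the group-level laws."""
    spec = spec or models.get_model("7d")
    hyper.validate(spec.roles)
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    out = []
    for _ in range(n):
        lrs = {}
        for role in spec.roles:
            s1, s2 = hyper.lr_for(role)
            lrs[role] = float(rng.beta(s1 + 1.0, s2 + 1.0))
        lapse = float(rng.gamma(hyper.lapse_shape, 1.0 / hyper.lapse_inv_scale))
        v0p = v0m = 0.5
        jump = 0.0
        if spec.free_start_values:
            v0p = float(rng.beta(hyper.start[0] + 1.0, hyper.start[1] + 1.0))
            v0m = float(rng.beta(hyper.start[0] + 1.0, hyper.start[1] + 1.0))
        if spec.free_jump:
            jump = float(rng.beta(hyper.jump[0] + 1.0, hyper.jump[1] + 1.0))
        out.append(models.SubjectParameters(lrs, lapse, v0p, v0m, jump))
    return out


# ---------------------------------------------------------------------------
# questionnaire marginals

def _zinb_pmf(pi0: float, r: float, mean: float, maximum: int) -> np.ndarray:
    """Zero-inflated negative-binomial pmf with the upper tail lumped at the
    scale maximum (totals are bounded)."""
    p = r / (r + mean)
    ks = np.arange(maximum + 1)
    pmf = (1.0 - pi0) * stats.nbinom.pmf(ks, r, p)
    pmf[0] += pi0
    pmf[maximum] += (1.0 - pi0) * stats.nbinom.sf(maximum, r, p)
    return pmf / pmf.sum()


#: Marginal total-score distributions (zero-inflated, ordinal, bounded),
#: matched to the pooled sample's mean ~6 and SD ~5 on both scales.
GAD7_PMF = _zinb_pmf(pi0=0.10, r=1.9, mean=6.0, maximum=GAD7_MAX)
PHQ8_PMF = _zinb_pmf(pi0=0.08, r=2.2, mean=6.0, maximum=PHQ8_MAX)


def _quantile_from_pmf(pmf: np.ndarray, u: np.ndarray) -> np.ndarray:
    cdf = np.cumsum(pmf)
    cdf[-1] = 1.0
    return np.searchsorted(cdf, u, side="left").astype(np.int64)


def questionnaire_quantile(scale: str, u) -> np.ndarray:
    """Inverse CDF of a questionnaire total-score marginal ('gad7'/'phq8')."""
    pmf = GAD7_PMF if scale == "gad7" else PHQ8_PMF
    return _quantile_from_pmf(pmf, np.atleast_1d(np.asarray(u, dtype=float)))


# ---------------------------------------------------------------------------
# copula calibration

_CAL_N = 120_000
_CAL_SEED = 987654321


def _marginal_transform(kind: tuple, z: np.ndarray) -> np.ndarray:
    """Map standard-normal latents through a marginal quantile function."""
    u = stats.norm.cdf(z)
    if kind[0] == "gad7" or kind[0] == "phq8":
        return _quantile_from_pmf(GAD7_PMF if kind[0] == "gad7" else PHQ8_PMF, u).astype(float)
    if kind[0] == "beta":
        return stats.beta.ppf(u, kind[1], kind[2])
    raise CohortConfigError(f"unknown marginal {kind!r}")


@lru_cache(maxsize=64)
def calibrate_latent_rho(target: float, kind_x: tuple, kind_y: tuple) -> float:
    """Latent normal correlation that yields the target Spearman correlation
    between the two (possibly discretised) margins.

    Solved by bisection on a common-random-number Monte Carlo estimate of
    Spearman's rho as a monotone function of the latent correlation.
    """
    if not -1.0 < target < 1.0:
        raise CohortConfigError(f"target correlation {target} outside (-1, 1)")
    if target == 0.0:
        return 0.0
    rng = np.random.default_rng(_CAL_SEED)
    z1 = rng.standard_normal(_CAL_N)
    z2 = rng.standard_normal(_CAL_N)
    x = _marginal_transform(kind_x, z1)

    def spearman_at(rho: float) -> float:
        y = _marginal_transform(kind_y, rho * z1 + math_sqrt1m(rho) * z2)
        return stats.spearmanr(x, y).statistic

    lo, hi = (0.0, 0.999) if target > 0 else (-0.999, 0.0)
    f_lo, f_hi = spearman_at(lo), spearman_at(hi)
    if not (min(f_lo, f_hi) <= target <= max(f_lo, f_hi)):
        raise CohortConfigError(
            f"target Spearman {target} unreachable for these margins "
            f"(attainable range about [{min(f_lo, f_hi):.3f}, {max(f_lo, f_hi):.3f}])"
        )
    for _ in range(30):
        mid = 0.5 * (lo + hi)
        if (spearman_at(mid) - target) * (f_lo - target) <= 0:
            hi = mid
        else:
            lo, f_lo = mid, spearman_at(mid)
    return 0.5 * (lo + hi)


def math_sqrt1m(rho: float) -> float:
    return float(np.sqrt(max(0.0, 1.0 - rho * rho)))


def generate_questionnaires(
    latent: np.ndarray,
    rho_gp: float = 0.71,
    seed: int | np.random.Generator = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """GAD-7 / PHQ-8 totals from per-subject latent distress scores.

    GAD-7 is the discretised latent itself; PHQ-8 shares the latent at a
    loading calibrated so the totals' Spearman correlation approaches
    ``rho_gp``.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    latent = np.asarray(latent, dtype=float)
    gad = _quantile_from_pmf(GAD7_PMF, stats.norm.cdf(latent))
    if rho_gp == 0.0:
        phq_z = rng.standard_normal(len(latent))
    else:
        rho = calibrate_latent_rho(rho_gp, ("gad7",), ("phq8",))
        phq_z = rho * latent + math_sqrt1m(rho) * rng.standard_normal(len(latent))
    phq = _quantile_from_pmf(PHQ8_PMF, stats.norm.cdf(phq_z))
    return gad, phq


# ---------------------------------------------------------------------------
# compliance metadata


@dataclass(frozen=True)
class ExclusionRates:
    """Per-criterion probabilities for the compliance generator.

    Defaults approximate the study's attrition (about 62% surviving the
    medium filter and 61% of those surviving the strict filter).
    """

    removed_headphones: float = 0.08
    low_volume: float = 0.12        # volume dropped below 80%
    partial_volume: float = 0.20    # volume in [80%, 100%)
    restarted_app: float = 0.08
    low_unpleasantness: float = 0.15  # US rated < 5 of 10
    unaware: float = 0.20           # no contingency awareness

    def validate(self) -> None:
        for name, v in self.__dict__.items():
            if not 0.0 <= v <= 1.0:
                raise CohortConfigError(f"exclusion rate {name}={v} outside [0, 1]")
        if self.low_volume + self.partial_volume > 1.0:
            raise CohortConfigError("volume category probabilities exceed 1")

    @classmethod
    def none(cls) -> "ExclusionRates":
        return cls(0.0, 0.0, 0.0, 0.0, 0.0, 0.0)


def _generate_compliance(rates: ExclusionRates, n: int, rng: np.random.Generator) -> pd.DataFrame:
    rates.validate()
    cat = rng.random(n)
    volume = np.ones(n)
    low = cat < rates.low_volume
    partial = (cat >= rates.low_volume) & (cat < rates.low_volume + rates.partial_volume)
    volume[low] = rng.uniform(0.4, 0.8, low.sum())
    volume[partial] = rng.uniform(0.8, 1.0 - 1e-9, partial.sum())
    low_unp = rng.random(n) < rates.low_unpleasantness
    unpleasantness = np.where(low_unp, rng.integers(1, 5, n), rng.integers(5, 11, n))
    return pd.DataFrame(
        {
            "removed_headphones": rng.random(n) < rates.removed_headphones,
            "min_volume_fraction": volume,
            "restarted_app": rng.random(n) < rates.restarted_app,
            "us_unpleasantness": unpleasantness.astype(int),
            "contingency_aware": rng.random(n) >= rates.unaware,
        }
    )


# ---------------------------------------------------------------------------
# whole-cohort generation


@dataclass(frozen=True)
class CohortConfig:
    """Study conditions for a synthetic cohort.

    Defaults follow the study: model 7d as the generating model, the
    GAD-7/PHQ-8 rank correlation at 0.71, and the two learning rates the
    study found anxiety-linked (safety learning and threat extinction) rank
    correlated with the anxiety score at -0.21 / -0.22.
    """

    n_subjects: int = 145
    generating_model: models.ModelSpec = field(default_factory=lambda: models.get_model("7d"))
    hyperparameters: GroupHyperparameters = field(default_factory=GroupHyperparameters.reference)
    target_assoc: dict = field(
        default_factory=lambda: {"cs_plus_ext": -0.22, "cs_minus_acq": -0.21}
    )
    gad_phq_rho: float = 0.71
    missing_rate: float = 0.02
    exclusion_rates: ExclusionRates = field(default_factory=ExclusionRates)
    schedule_config: ScheduleConfig = field(default_factory=ScheduleConfig)
    seed: int = 0

    def validate(self) -> None:
        if self.n_subjects < 1:
            raise CohortConfigError("n_subjects must be positive")
        if not 0.0 <= self.missing_rate <= 1.0:
            raise CohortConfigError("missing_rate must lie in [0, 1]")
        if not -1.0 <= self.gad_phq_rho <= 1.0:
            raise CohortConfigError("gad_phq_rho must lie in [-1, 1]")
        roles = self.generating_model.roles
        for role, rho in self.target_assoc.items():
            if role not in roles:
                raise CohortConfigError(
                    f"target role {role!r} not in model {self.generating_model.label}"
                )
            if not -1.0 <= rho <= 1.0:
                raise CohortConfigError("target correlations must lie in [-1, 1]")
        self.exclusion_rates.validate()


@dataclass
class CohortDataset:
    """A complete synthetic study dataset."""

    responses: pd.DataFrame
    questionnaires: pd.DataFrame
    compliance: pd.DataFrame
    true_parameters: pd.DataFrame | None
    schedule: TrialSchedule
    config: CohortConfig | None = None

    @property
    def subject_ids(self) -> list:
        return list(self.questionnaires["subject_id"])

    @property
    def n_subjects(self) -> int:
        return len(self.questionnaires)

    def select_subjects(self, keep_ids) -> "CohortDataset":
        keep = set(keep_ids)
        return CohortDataset(
            responses=self.responses[self.responses["subject_id"].isin(keep)].reset_index(drop=True),
            questionnaires=self.questionnaires[
                self.questionnaires["subject_id"].isin(keep)
            ].reset_index(drop=True),
            compliance=self.compliance[self.compliance["subject_id"].isin(keep)].reset_index(drop=True),
            true_parameters=None
            if self.true_parameters is None
            else self.true_parameters[self.true_parameters["subject_id"].isin(keep)].reset_index(drop=True),
            schedule=self.schedule,
            config=self.config,
        )

    def to_csvs(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        models.write_responses_csv(self.responses, outdir / "responses.csv")
        self.questionnaires.to_csv(outdir / "questionnaires.csv", index=False)
        self.compliance.to_csv(outdir / "compliance.csv", index=False)
        if self.true_parameters is not None:
            self.true_parameters.to_csv(outdir / "true_parameters.csv", index=False)
        from .schedule import write_schedule_csv

        write_schedule_csv(self.schedule, outdir / "schedule.csv")

    @classmethod
    def from_csvs(cls, outdir: str | Path) -> "CohortDataset":
        outdir = Path(outdir)
        from .schedule import read_schedule_csv

        tp = outdir / "true_parameters.csv"
        return cls(
            responses=models.read_responses_csv(outdir / "responses.csv"),
            questionnaires=pd.read_csv(outdir / "questionnaires.csv"),
            compliance=pd.read_csv(outdir / "compliance.csv"),
            true_parameters=pd.read_csv(tp) if tp.exists() else None,
            schedule=read_schedule_csv(outdir / "schedule.csv"),
        )


def generate_cohort(config: CohortConfig | None = None, seed: int | None = None) -> CohortDataset:
    """Generate a complete synthetic cohort.

    Ratings are simulated from the generating model with each subject's true
    parameters; targeted learning-rate roles are coupled to the latent
    distress factor through the calibrated Gaussian copula; missing ratings
    are missing completely at random.
    """
    config = config or CohortConfig()
    if seed is not None:
        config = replace(config, seed=seed)
    config.validate()
    spec = config.generating_model
    hyper = config.hyperparameters
    hyper.validate(spec.roles)
    rng = np.random.default_rng(config.seed)
    n = config.n_subjects

    schedule = build_schedule(config.schedule_config, seed=int(rng.integers(2**31)))

    # latent distress factor and questionnaire totals
    latent = rng.standard_normal(n)
    gad, phq = generate_questionnaires(latent, config.gad_phq_rho, rng)

    # subject parameters; targeted LR roles share the latent factor
    lr_draws: dict[str, np.ndarray] = {}
    for role in spec.roles:
        s1, s2 = hyper.lr_for(role)
        if role in config.target_assoc:
            rho = calibrate_latent_rho(
                float(config.target_assoc[role]), ("gad7",), ("beta", s1 + 1.0, s2 + 1.0)
            )
            z = rho * latent + math_sqrt1m(rho) * rng.standard_normal(n)
            lr_draws[role] = stats.beta.ppf(stats.norm.cdf(z), s1 + 1.0, s2 + 1.0)
        else:
            lr_draws[role] = rng.beta(s1 + 1.0, s2 + 1.0, n)

    lapse = rng.gamma(hyper.lapse_shape, 1.0 / hyper.lapse_inv_scale, n)
    v0p = rng.beta(hyper.start[0] + 1.0, hyper.start[1] + 1.0, n) if spec.free_start_values else np.full(n, 0.5)
    v0m = rng.beta(hyper.start[0] + 1.0, hyper.start[1] + 1.0, n) if spec.free_start_values else np.full(n, 0.5)
    jump = rng.beta(hyper.jump[0] + 1.0, hyper.jump[1] + 1.0, n) if spec.free_jump else np.zeros(n)

    subject_ids = [f"S{i + 1:04d}" for i in range(n)]
    ratings_by_subject = {}
    records = []
    for i, sid in enumerate(subject_ids):
        params = models.SubjectParameters(
            {r: float(lr_draws[r][i]) for r in spec.roles},
            float(lapse[i]), float(v0p[i]), float(v0m[i]), float(jump[i]),
        )
        ratings = simulate_with_missing(
            spec, params, schedule, rng, config.missing_rate
        )
        ratings_by_subject[sid] = ratings
        rec = {"subject_id": sid}
        rec.update({f"lr_{r}": params.learning_rates[r] for r in spec.roles})
        rec["lapse"] = params.lapse
        if spec.free_start_values:
            rec["v0_cs_plus"] = params.start_value_cs_plus
            rec["v0_cs_minus"] = params.start_value_cs_minus
        if spec.free_jump:
            rec["jump"] = params.jump
        records.append(rec)

    responses = models.responses_frame(schedule, ratings_by_subject)
    questionnaires = pd.DataFrame(
        {"subject_id": subject_ids, "gad7": gad.astype(int), "phq8": phq.astype(int)}
    )
    compliance = _generate_compliance(config.exclusion_rates, n, rng)
    compliance.insert(0, "subject_id", subject_ids)
    return CohortDataset(
        responses=responses,
        questionnaires=questionnaires,
        compliance=compliance,
        true_parameters=pd.DataFrame(records),
        schedule=schedule,
        config=config,
    )


def simulate_with_missing(
    spec: models.ModelSpec,
    params: models.SubjectParameters,
    schedule: TrialSchedule,
    rng: np.random.Generator,
    missing_rate: float,
) -> np.ndarray:
    """Simulate a rating sequence and blank trials MCAR at ``missing_rate``."""
    ratings = models.simulate_ratings(spec, params, schedule, rng).astype(float)
    if missing_rate > 0:
        ratings[rng.random(len(ratings)) < missing_rate] = np.nan
    return ratings
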