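"""Hierarchical Bayesian estimation of the model family.

Subject-level parameters (learning rates, lapse, optional start values and
jump) are constrained to their supports through beta/gamma population laws
whose shape hyperparameters carry gamma hyperpriors:

    LR_shape1, LR_shape2          ~ Gamma(0.5, 1)
    LR_subject                    ~ Beta(LR_shape1 + 1, LR_shape2 + 1)
    Lapse_shape, Lapse_inv_scale  ~ Gamma(5, 1)
    Lapse_subject                 ~ Gamma(Lapse_shape, Lapse_inv_scale)

(the +1 on the beta shapes keeps the population law from inverting; start
values and the jump reuse the learning-rate scheme).  Gamma distributions
are shape/rate parameterised throughout.

Sampling uses adaptive Metropolis-within-Gibbs (see ``_sampler``) with
multiple chains; convergence is summarised by split-chain rank-normalised
R-hat and effective sample sizes via arviz.  Posterior point estimates are
medians with equal-tailed 95% credible intervals.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import arviz as az
import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from . import models, synth
from ._sampler import _log_joint, _pointwise_loglik_matrix, _run_chain
from .models import ModelSpec, _LOG_1MQ, _LOG_Q
from .schedule import ACQUISITION, CS_PLUS, TrialSchedule, build_schedule
from .synth import GroupHyperparameters

RHAT_THRESHOLD = 1.01


class FittingError(RuntimeError):
    """Raised when sampling cannot proceed (bad configuration or data)."""


@dataclass(frozen=True)
class SamplerConfig:
    """MCMC run configuration.

    One iteration retains one draw; internally each iteration performs
    ``subject_scans`` full componentwise sweeps over subject-level
    parameters and ``hyper_scans`` sweeps over the (cheap) group-level
    conditionals, so the per-iteration information content is comparable to
    a gradient-based sampler's multi-step transitions.
    """

    chains: int = 4
    warmup: int = 500
    samples: int = 500
    seed: int = 0
    target_acceptance: float = 0.44
    subject_scans: int = 6
    hyper_scans: int = 60

    def validate(self) -> None:
        if self.chains < 1:
            raise FittingError("at least one chain is required")
        if self.warmup < 0 or self.samples < 1:
            raise FittingError("warmup must be >= 0 and samples >= 1")
        if not 0.0 < self.target_acceptance < 1.0:
            raise FittingError("target_acceptance must lie in (0, 1)")


def hyper_names(spec: ModelSpec) -> list[str]:
    names = []
    for pname in spec.subject_parameter_names:
        if pname == "lapse":
            names += ["lapse_shape", "lapse_inv_scale"]
        else:
            names += [f"{pname}_shape1", f"{pname}_shape2"]
    return names


def _prepare_responses(X) -> dict:
    """Long-format responses -> dense per-subject trial arrays."""
    if isinstance(X, synth.CohortDataset):
        frame = X.responses
    else:
        frame = X
    required = {"subject_id", "phase", "index", "cue", "reinforced", "rating"}
    missing = required - set(frame.columns)
    if missing:
        raise FittingError(f"responses table missing columns {sorted(missing)}")
    frame = frame.copy()
    frame["_phase_ord"] = (frame["phase"] != ACQUISITION).astype(int)
    frame = frame.sort_values(["subject_id", "_phase_ord", "index"], kind="stable")
    sids = list(dict.fromkeys(frame["subject_id"]))
    n_trials = frame.groupby("subject_id").size()
    if n_trials.nunique() != 1:
        raise FittingError("all subjects must share the trial count")
    T = int(n_trials.iloc[0])
    N = len(sids)

    cue = np.empty((N, T), dtype=np.int8)
    us = np.empty((N, T), dtype=np.float64)
    rating = np.empty((N, T), dtype=np.int64)
    ext_start = np.empty(N, dtype=np.int64)
    meta_phase = np.empty((N, T), dtype=object)
    meta_cue = np.empty((N, T), dtype=object)
    for i, sid in enumerate(sids):
        sub = frame[frame["subject_id"] == sid]
        cue[i] = (sub["cue"] == CS_PLUS).to_numpy(dtype=np.int8)
        us[i] = sub["reinforced"].to_numpy(dtype=float)
        r = pd.to_numeric(sub["rating"], errors="coerce").to_numpy(dtype=float)
        bad = r[~np.isnan(r)]
        if len(bad) and ((bad < 1) | (bad > 9)).any():
            raise FittingError("ratings must lie in 1..9")
        rating[i] = np.where(np.isnan(r), 0, r).astype(np.int64)
        acq_mask = (sub["phase"] == ACQUISITION).to_numpy()
        ext_start[i] = int(acq_mask.sum())
        meta_phase[i] = sub["phase"].to_numpy()
        meta_cue[i] = sub["cue"].to_numpy()
    return {
        "subject_ids": sids,
        "cue": cue,
        "us": us,
        "rating": rating,
        "ext_start": ext_start,
        "phase": meta_phase,
        "cue_label": meta_cue,
    }


def _role_matrix(spec: ModelSpec, data: dict) -> np.ndarray:
    lookup = {r: i for i, r in enumerate(spec.roles)}
    N, T = data["cue"].shape
    role = np.empty((N, T), dtype=np.int64)
    for i in range(N):
        for t in range(T):
            role[i, t] = lookup[
                models.trial_role(
                    spec.lr_structure,
                    data["phase"][i][t],
                    data["cue_label"][i][t],
                    bool(data["us"][i, t] > 0),
                )
            ]
    return role


@dataclass
class PosteriorDraws:
    """Multi-chain posterior draws on the constrained scale."""

    subject: np.ndarray  # (chains, samples, n_subjects, n_subject_params)
    hyper: np.ndarray    # (chains, samples, n_hypers)
    subject_param_names: tuple
    hyper_names: tuple
    subject_ids: list
    spec: ModelSpec
    data: dict
    accept_subject: float
    accept_hyper: float
    divergences: int = 0
    update_on_missing: bool = False

    def to_inferencedata(self) -> az.InferenceData:
        post = {}
        for h, name in enumerate(self.hyper_names):
            post[name] = self.hyper[:, :, h]
        for j, name in enumerate(self.subject_param_names):
            post[name] = self.subject[:, :, :, j]
        return az.from_dict(
            posterior=post, coords={"subject": self.subject_ids},
            dims={name: ["subject"] for name in self.subject_param_names},
        )

    def pointwise_loglik(self) -> np.ndarray:
        """(chains, samples, n_points) log-likelihood matrix over non-missing
        subject x trial datapoints (subject-major order)."""
        C, S, N, P = self.subject.shape
        flat = self.subject.reshape(C * S, N, P)
        mat = _pointwise_loglik_matrix(
            flat,
            len(self.spec.roles),
            self.spec.free_start_values,
            self.spec.free_jump,
            self.data["cue"],
            self.data["us"],
            self.data["role"],
            self.data["rating"],
            self.data["ext_start"],
            _LOG_Q,
            _LOG_1MQ,
            self.update_on_missing,
        )
        return mat.reshape(C, S, -1)

    def point_meta(self) -> pd.DataFrame:
        rows = []
        N, T = self.data["rating"].shape
        for i in range(N):
            for t in range(T):
                if self.data["rating"][i, t] > 0:
                    rows.append(
                        {
                            "subject_id": self.subject_ids[i],
                            "trial": t,
                            "phase": self.data["phase"][i][t],
                            "cue": self.data["cue_label"][i][t],
                        }
                    )
        return pd.DataFrame(rows)


def summarize_posterior(draws: PosteriorDraws) -> pd.DataFrame:
    """Median, equal-tailed 95% credible interval, split-chain
    rank-normalised R-hat and effective sample size per parameter.

    R-hat requires at least two chains; with a single chain it is reported
    as NaN (flagged in the ``rhat_available`` attribute).
    """
    idata = draws.to_inferencedata()
    multi = draws.hyper.shape[0] >= 2
    rhat = az.rhat(idata) if multi else None
    ess = az.ess(idata)

    rows = []

    def _row(name, samples_2d, sid, rh, es):
        if np.ptp(samples_2d) == 0:
            # zero between- and within-chain variance: converged by convention
            rh = 1.0 if rhat is not None else rh
        lo, med, hi = np.percentile(samples_2d, [2.5, 50.0, 97.5])
        rows.append(
            {
                "parameter": name,
                "subject_id": sid,
                "level": "group" if sid is None else "subject",
                "median": med,
                "ci_lo": lo,
                "ci_hi": hi,
                "rhat": rh,
                "ess": es,
            }
        )

    for h, name in enumerate(draws.hyper_names):
        _row(
            name,
            draws.hyper[:, :, h],
            None,
            float(rhat[name].values) if multi else np.nan,
            float(ess[name].values),
        )
    for j, name in enumerate(draws.subject_param_names):
        rh = rhat[name].values if multi else None
        es = ess[name].values
        for i, sid in enumerate(draws.subject_ids):
            _row(
                name,
                draws.subject[:, :, i, j],
                sid,
                float(rh[i]) if multi else np.nan,
                float(es[i]),
            )
    frame = pd.DataFrame(rows)
    frame.attrs["divergences"] = draws.divergences
    frame.attrs["rhat_available"] = multi
    return frame


class HierarchicalRescorlaWagner(BaseEstimator):
    """Hierarchical Bayesian Rescorla-Wagner estimator.

    Fits one member of the 28-model family to a long-format response table
    (columns ``subject_id, phase, index, cue, reinforced, rating``; empty
    rating = missing).  Follows the scikit-learn estimator protocol: all
    configuration lives in ``__init__``; ``fit`` populates trailing
    underscore attributes.

    Attributes (after fit)
    ----------------------
    draws_ : PosteriorDraws
    summary_ : DataFrame of medians, 95% CIs, R-hat, ESS
    rhat_max_ : max R-hat over group-level hyperparameters
    divergences_ : always 0 for this sampler (no divergence notion)
    """

    def __init__(
        self,
        lr_structure: int = 7,
        fit_variant: str = "d",
        chains: int = 4,
        warmup: int = 500,
        samples: int = 500,
        subject_scans: int = 6,
        hyper_scans: int = 60,
        target_acceptance: float = 0.44,
        update_on_missing: bool = False,
        random_state: int = 0,
    ):
        self.lr_structure = lr_structure
        self.fit_variant = fit_variant
        self.chains = chains
        self.warmup = warmup
        self.samples = samples
        self.subject_scans = subject_scans
        self.hyper_scans = hyper_scans
        self.target_acceptance = target_acceptance
        self.update_on_missing = update_on_missing
        self.random_state = random_state

    @property
    def spec(self) -> ModelSpec:
        return ModelSpec(self.lr_structure, self.fit_variant)

    def _sampler_config(self) -> SamplerConfig:
        return SamplerConfig(
            chains=self.chains,
            warmup=self.warmup,
            samples=self.samples,
            seed=self.random_state,
            target_acceptance=self.target_acceptance,
            subject_scans=self.subject_scans,
            hyper_scans=self.hyper_scans,
        )

    def fit(self, X, y=None):
        cfg = self._sampler_config()
        cfg.validate()
        spec = self.spec
        data = _prepare_responses(X)
        data["role"] = _role_matrix(spec, data)
        if (data["rating"] > 0).sum() == 0:
            raise FittingError("no observed ratings to fit")

        sub_chains, hyp_chains = [], []
        acc_s = acc_h = 0.0
        for c in range(cfg.chains):
            chain_seed = (cfg.seed * 100003 + 17 * c + 1) % (2**31)
            ds, dh, a_s, a_h = _run_chain(
                data["cue"],
                data["us"],
                data["role"],
                data["rating"],
                data["ext_start"],
                len(spec.roles),
                spec.free_start_values,
                spec.free_jump,
                0.5,
                1.0,
                5.0,
                1.0,
                cfg.warmup,
                cfg.samples,
                cfg.subject_scans,
                cfg.hyper_scans,
                cfg.target_acceptance,
                chain_seed,
                _LOG_Q,
                _LOG_1MQ,
                self.update_on_missing,
            )
            sub_chains.append(ds)
            hyp_chains.append(dh)
            acc_s += a_s
            acc_h += a_h

        self.n_subjects_ = len(data["subject_ids"])
        self.draws_ = PosteriorDraws(
            subject=np.stack(sub_chains),
            hyper=np.stack(hyp_chains),
            subject_param_names=spec.subject_parameter_names,
            hyper_names=tuple(hyper_names(spec)),
            subject_ids=data["subject_ids"],
            spec=spec,
            data=data,
            accept_subject=acc_s / cfg.chains,
            accept_hyper=acc_h / cfg.chains,
            update_on_missing=self.update_on_missing,
        )
        self.summary_ = summarize_posterior(self.draws_)
        group = self.summary_[self.summary_["level"] == "group"]
        self.rhat_max_ = float(group["rhat"].max())
        self.divergences_ = 0
        return self

    def subject_medians(self) -> pd.DataFrame:
        """Per-subject posterior medians, one column per parameter."""
        sub = self.summary_[self.summary_["level"] == "subject"]
        return sub.pivot(index="subject_id", columns="parameter", values="median").loc[
            self.draws_.subject_ids
        ]

    def pointwise_loglik_draws(self) -> np.ndarray:
        return self.draws_.pointwise_loglik()

    def score(self, X=None, y=None) -> float:
        """Pseudo-r2 of the fit (posterior-mean pointwise log-likelihood
        against the chance log-likelihood)."""
        from .compare import pseudo_r2

        ll = self.pointwise_loglik_draws()
        pointwise_mean = ll.mean(axis=(0, 1))
        return pseudo_r2(float(pointwise_mean.sum()), pointwise_mean.size)


def fit_model(
    spec: ModelSpec,
    dataset,
    sampler: SamplerConfig | None = None,
    update_on_missing: bool = False,
) -> HierarchicalRescorlaWagner:
    """Fit one model of the registry; returns the fitted estimator."""
    sampler = sampler or SamplerConfig()
    est = HierarchicalRescorlaWagner(
        lr_structure=spec.lr_structure,
        fit_variant=spec.fit_variant,
        chains=sampler.chains,
        warmup=sampler.warmup,
        samples=sampler.samples,
        subject_scans=sampler.subject_scans,
        hyper_scans=sampler.hyper_scans,
        target_acceptance=sampler.target_acceptance,
        update_on_missing=update_on_missing,
        random_state=sampler.seed,
    )
    return est.fit(dataset)


def log_joint(
    spec: ModelSpec,
    data: dict,
    subject_params: np.ndarray,
    hypers: np.ndarray,
    update_on_missing: bool = False,
) -> float:
    """Joint log-density (likelihood + all priors) at a fixed point, on the
    constrained scale.  This is the sampler's target (up to the
    transform Jacobians it adds for unconstrained-scale moves)."""
    return float(
        _log_joint(
            np.ascontiguousarray(subject_params, dtype=float),
            np.ascontiguousarray(hypers, dtype=float),
            len(spec.roles),
            spec.free_start_values,
            spec.free_jump,
            data["cue"],
            data["us"],
            data["role"],
            data["rating"],
            data["ext_start"],
            0.5,
            1.0,
            5.0,
            1.0,
            _LOG_Q,
            _LOG_1MQ,
            update_on_missing,
        )
    )


# ---------------------------------------------------------------------------
# predictive checks


@dataclass
class PPCReport:
    """Group-level predictive check.

    ``trajectory`` holds, per trial position, the median generated group-mean
    rating with its 50% highest-density interval and the observed group
    mean.  ``phase_cue_corr`` is the 4x4 correlation matrix between
    generated and observed per-subject whole-phase means (rows = generated,
    columns = observed; order acquisition CS+, acquisition CS-, extinction
    CS+, extinction CS-).
    """

    trajectory: pd.DataFrame
    coverage: float
    phase_cue_corr: pd.DataFrame
    mode: str
    generated_ratings_range: tuple


_PC_ORDER = [("acquisition", "CS+"), ("acquisition", "CS-"), ("extinction", "CS+"), ("extinction", "CS-")]


def _whole_phase_means(ratings: np.ndarray, phase, cue) -> np.ndarray:
    out = np.empty(4)
    for k, (ph, cu) in enumerate(_PC_ORDER):
        mask = (phase == ph) & (cue == cu)
        vals = ratings[mask]
        vals = vals[~np.isnan(vals)]
        out[k] = vals.mean() if len(vals) else np.nan
    return out


def predictive_check(
    spec: ModelSpec,
    draws_or_hyper,
    dataset,
    mode: str = "posterior",
    seed: int = 0,
    n_reps: int = 500,
) -> PPCReport:
    """Prior or posterior predictive check against a dataset.

    In posterior mode each replicate simulates every subject's ratings from
    one randomly chosen posterior draw of that subject's parameters; in
    prior mode hyperparameters are drawn from the hyperpriors and subjects
    from the population laws.
    """
    rng = np.random.default_rng(seed)
    if isinstance(dataset, synth.CohortDataset):
        data = _prepare_responses(dataset.responses)
        schedule = dataset.schedule
    else:
        data = _prepare_responses(dataset)
        schedule = None
    N, T = data["rating"].shape
    phase0 = np.asarray(data["phase"][0])
    cue0 = np.asarray(data["cue_label"][0])
    if schedule is None:
        schedule = _schedule_from_arrays(data)

    obs = np.where(data["rating"] > 0, data["rating"], np.nan).astype(float)
    obs_traj = np.nanmean(obs, axis=0)
    obs_pc = np.vstack([_whole_phase_means(obs[i], phase0, cue0) for i in range(N)])

    gen_traj = np.empty((n_reps, T))
    gen_pc_accum = np.zeros((N, 4))
    lo = np.inf
    hi = -np.inf
    for rep in range(n_reps):
        sim = np.empty((N, T))
        for i in range(N):
            params = _draw_params(spec, draws_or_hyper, mode, i, rng)
            sim[i] = models.simulate_ratings(spec, params, schedule, rng)
        gen_traj[rep] = sim.mean(axis=0)
        lo = min(lo, sim.min())
        hi = max(hi, sim.max())
        for i in range(N):
            gen_pc_accum[i] += _whole_phase_means(sim[i], phase0, cue0)
    gen_pc = gen_pc_accum / n_reps

    hdi = az.hdi(gen_traj[np.newaxis], hdi_prob=0.5)
    traj = pd.DataFrame(
        {
            "trial": np.arange(T),
            "phase": phase0,
            "cue": cue0,
            "median_generated": np.median(gen_traj, axis=0),
            "hdi_lo": hdi[:, 0],
            "hdi_hi": hdi[:, 1],
            "observed": obs_traj,
        }
    )
    inside = (obs_traj >= hdi[:, 0]) & (obs_traj <= hdi[:, 1])
    corr = np.full((4, 4), np.nan)
    for a in range(4):
        for b in range(4):
            ga, ob = gen_pc[:, a], obs_pc[:, b]
            ok = ~(np.isnan(ga) | np.isnan(ob))
            if ok.sum() > 2:
                corr[a, b] = np.corrcoef(ga[ok], ob[ok])[0, 1]
    labels = [f"{p} {c}" for p, c in _PC_ORDER]
    return PPCReport(
        trajectory=traj,
        coverage=float(inside.mean()),
        phase_cue_corr=pd.DataFrame(corr, index=labels, columns=labels),
        mode=mode,
        generated_ratings_range=(float(lo), float(hi)),
    )


def _schedule_from_arrays(data) -> TrialSchedule:
    """Reconstruct a TrialSchedule equivalent from prepared arrays (first
    subject; shared schedules assumed)."""
    from .schedule import EXTINCTION, TrialSpec, ScheduleConfig

    trials = []
    idx_acq = idx_ext = 0
    for t in range(data["cue"].shape[1]):
        ph = data["phase"][0][t]
        if ph == ACQUISITION:
            idx_acq += 1
            idx = idx_acq
        else:
            idx_ext += 1
            idx = idx_ext
        trials.append(
            TrialSpec(ph, idx, data["cue_label"][0][t], bool(data["us"][0, t] > 0), 1)
        )
    return TrialSchedule(tuple(trials), ScheduleConfig(), seed=-1)


def _draw_params(spec, draws_or_hyper, mode, subject_index, rng) -> models.SubjectParameters:
    if mode == "posterior":
        draws: PosteriorDraws = draws_or_hyper
        C, S = draws.subject.shape[:2]
        c = int(rng.integers(C))
        s = int(rng.integers(S))
        return models.SubjectParameters.from_vector(spec, draws.subject[c, s, subject_index])
    if mode == "prior":
        s1 = rng.gamma(0.5, 1.0)
        s2 = rng.gamma(0.5, 1.0)
        hyper = GroupHyperparameters(
            lr=(max(s1, 1e-6), max(s2, 1e-6)),
            lapse_shape=max(rng.gamma(5.0, 1.0), 1e-6),
            lapse_inv_scale=max(rng.gamma(5.0, 1.0), 1e-6),
            start=(max(rng.gamma(0.5, 1.0), 1e-6), max(rng.gamma(0.5, 1.0), 1e-6)),
            jump=(max(rng.gamma(0.5, 1.0), 1e-6), max(rng.gamma(0.5, 1.0), 1e-6)),
        )
        return synth.draw_subject_parameters(hyper, 1, rng, spec)[0]
    raise FittingError(f"unknown predictive-check mode {mode!r}")


# ---------------------------------------------------------------------------
# parameter recovery


@dataclass
class RecoveryReport:
    """Coverage of true parameter values by posterior 95% CIs."""

    table: pd.DataFrame
    spec: ModelSpec

    @property
    def coverage(self) -> float:
        return float(self.table["covered"].mean())

    def coverage_by_parameter(self) -> pd.Series:
        return self.table.groupby("parameter")["covered"].mean()

    def rank_correlation(self, parameter: str) -> float:
        from scipy.stats import spearmanr

        sub = self.table[
            (self.table["parameter"] == parameter) & (self.table["level"] == "subject")
        ]
        return float(spearmanr(sub["truth"], sub["median"]).statistic)


def _hyper_truths(spec: ModelSpec, hyper: GroupHyperparameters) -> dict:
    out = {}
    for pname in spec.subject_parameter_names:
        if pname.startswith("lr_"):
            s1, s2 = hyper.lr_for(pname[3:])
            out[f"{pname}_shape1"] = s1
            out[f"{pname}_shape2"] = s2
        elif pname == "lapse":
            out["lapse_shape"] = hyper.lapse_shape
            out["lapse_inv_scale"] = hyper.lapse_inv_scale
        elif pname.startswith("v0_"):
            out[f"{pname}_shape1"] = hyper.start[0]
            out[f"{pname}_shape2"] = hyper.start[1]
        elif pname == "jump":
            out["jump_shape1"] = hyper.jump[0]
            out["jump_shape2"] = hyper.jump[1]
    return out


def parameter_recovery_study(
    spec: ModelSpec,
    fixed_hyperparameters: GroupHyperparameters | None = None,
    n_subjects: int = 30,
    sampler: SamplerConfig | None = None,
    seed: int = 0,
    missing_rate: float = 0.0,
) -> RecoveryReport:
    """Simulate -> fit -> check that posterior 95% CIs contain the truth.

    Data are simulated from fixed, predefined hyperparameters; recovery of a
    parameter is deemed successful when its 95% credible interval contains
    the true value (closed intervals, so endpoint hits count as covered).
    """
    hyper = fixed_hyperparameters or GroupHyperparameters.reference()
    sampler = sampler or SamplerConfig(seed=seed)
    rng = np.random.default_rng(seed)
    schedule = build_schedule(seed=int(rng.integers(2**31)))
    truths = synth.draw_subject_parameters(hyper, n_subjects, rng, spec)
    sids = [f"S{i + 1:04d}" for i in range(n_subjects)]
    ratings = {
        sid: synth.simulate_with_missing(spec, p, schedule, rng, missing_rate)
        for sid, p in zip(sids, truths)
    }
    responses = models.responses_frame(schedule, ratings)
    fit = fit_model(spec, responses, dataclasses.replace(sampler, seed=seed))

    truth_lookup = {}
    for sid, p in zip(sids, truths):
        vec = p.as_vector(spec)
        for name, val in zip(spec.subject_parameter_names, vec):
            truth_lookup[(name, sid)] = val
    hyper_truth = _hyper_truths(spec, hyper)

    table = fit.summary_.copy()
    truths_col = []
    for _, row in table.iterrows():
        if row["level"] == "subject":
            truths_col.append(truth_lookup[(row["parameter"], row["subject_id"])])
        else:
            truths_col.append(hyper_truth[row["parameter"]])
    table["truth"] = truths_col
    table["covered"] = (table["ci_lo"] <= table["truth"]) & (table["truth"] <= table["ci_hi"])
    return RecoveryReport(table=table, spec=spec)
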