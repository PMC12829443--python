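"""The Rescorla-Wagner model family with an ordinal beta-link choice rule.

Each cue (CS+, CS-) carries an associative value V in [0, 1], updated after
every outcome by a prediction-error rule

    V_{t+1} = V_t + (US - V_t) * LR,

where US is 1 on reinforced trials and 0 otherwise, and LR is a learning
rate in [0, 1].  The 1-9 expectancy rating is generated by treating V as
the mean of a beta distribution with fixed precision phi = 10, evaluating
the beta kernel on a nine-point grid over [0, 1], normalising to a
probability vector P, and passing P * lapse through a softmax to obtain the
categorical choice probabilities theta.  Low lapse values flatten theta
toward a uniform distribution over the nine ratings.

The family crosses seven learning-rate structures (which trials share a
learning rate) with four fitting variants:

    a: fixed start values (0.5), no jump
    b: free per-cue start values, no jump
    c: fixed start values, free CS- jump at the extinction boundary
    d: free start values and free jump

giving 28 models, labelled ``1a`` .. ``7d``.  The "jump" is added to the
CS- value immediately before the first extinction trial (clamped at 1),
capturing threat generalisation at the phase change.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .schedule import ACQUISITION, CS_MINUS, CS_PLUS, EXTINCTION, TrialSchedule

PHI = 10.0
N_RATINGS = 9
GRID_EPS = 1e-6
V_EPS = 1e-6

#: Nine equally spaced rating anchors on [0, 1]; the endpoints are guarded
#: so the beta kernel stays finite when a shape parameter falls below 1.
RATING_GRID = np.clip(np.linspace(0.0, 1.0, N_RATINGS), GRID_EPS, 1.0 - GRID_EPS)
_LOG_Q = np.log(RATING_GRID)
_LOG_1MQ = np.log1p(-RATING_GRID)

# Learning-rate roles per structure.  A role names the set of trials that
# share a learning rate.
STRUCTURE_ROLES: dict[int, tuple[str, ...]] = {
    1: ("all",),
    2: ("cs_plus", "cs_minus"),
    3: ("cs_minus", "cs_plus_acq", "cs_plus_ext"),
    4: ("cs_plus_acq", "cs_plus_ext", "cs_minus_acq", "cs_minus_ext"),
    5: ("aversive", "nonaversive"),
    6: ("cs_minus", "cs_plus_us_plus", "cs_plus_us_minus"),
    7: (
        "cs_minus_acq",
        "cs_minus_ext",
        "cs_plus_acq_us_plus",
        "cs_plus_acq_us_minus",
        "cs_plus_ext",
    ),
}

FIT_VARIANTS = ("a", "b", "c", "d")


class ModelError(ValueError):
    """Raised for out-of-domain arguments or spec/parameter mismatches."""


@dataclass(frozen=True)
class ModelSpec:
    """One member of the 28-model family."""

    lr_structure: int
    fit_variant: str

    def __post_init__(self) -> None:
        if self.lr_structure not in STRUCTURE_ROLES:
            raise ModelError(f"unknown learning-rate structure {self.lr_structure}")
        if self.fit_variant not in FIT_VARIANTS:
            raise ModelError(f"unknown fitting variant {self.fit_variant!r}")

    @property
    def label(self) -> str:
        return f"{self.lr_structure}{self.fit_variant}"

    @property
    def roles(self) -> tuple[str, ...]:
        return STRUCTURE_ROLES[self.lr_structure]

    @property
    def free_start_values(self) -> bool:
        return self.fit_variant in ("b", "d")

    @property
    def free_jump(self) -> bool:
        return self.fit_variant in ("c", "d")

    @property
    def subject_parameter_names(self) -> tuple[str, ...]:
        names = [f"lr_{r}" for r in self.roles] + ["lapse"]
        if self.free_start_values:
            names += ["v0_cs_plus", "v0_cs_minus"]
        if self.free_jump:
            names += ["jump"]
        return tuple(names)


def enumerate_models() -> list[ModelSpec]:
    """All 28 (learning-rate structure, fitting variant) combinations."""
    return [ModelSpec(s, v) for s in sorted(STRUCTURE_ROLES) for v in FIT_VARIANTS]


def get_model(label: str) -> ModelSpec:
    """Look a model up by its label, e.g. ``"7d"``."""
    label = label.strip().lower()
    return ModelSpec(int(label[:-1]), label[-1])


def trial_role(lr_structure: int, phase: str, cue: str, reinforced: bool) -> str:
    """Which learning-rate role governs a trial's value update.

    For the outcome-contingent structures (5, 6, 7) the "non-aversive"
    roles cover every trial on which no US is delivered: unreinforced CS+
    acquisition trials, all extinction CS+ trials, and (structure 5) all
    CS- trials.
    """
    plus = cue == CS_PLUS
    acq = phase == ACQUISITION
    if lr_structure == 1:
        return "all"
    if lr_structure == 2:
        return "cs_plus" if plus else "cs_minus"
    if lr_structure == 3:
        if not plus:
            return "cs_minus"
        return "cs_plus_acq" if acq else "cs_plus_ext"
    if lr_structure == 4:
        return f"{'cs_plus' if plus else 'cs_minus'}_{'acq' if acq else 'ext'}"
    if lr_structure == 5:
        return "aversive" if reinforced else "nonaversive"
    if lr_structure == 6:
        if not plus:
            return "cs_minus"
        return "cs_plus_us_plus" if reinforced else "cs_plus_us_minus"
    if lr_structure == 7:
        if not plus:
            return "cs_minus_acq" if acq else "cs_minus_ext"
        if acq:
            return "cs_plus_acq_us_plus" if reinforced else "cs_plus_acq_us_minus"
        return "cs_plus_ext"
    raise ModelError(f"unknown structure {lr_structure}")


def role_indices(spec: ModelSpec, schedule: TrialSchedule) -> np.ndarray:
    """Integer role index (into ``spec.roles``) for every trial."""
    lookup = {r: i for i, r in enumerate(spec.roles)}
    return np.array(
        [lookup[trial_role(spec.lr_structure, t.phase, t.cue, t.reinforced)] for t in schedule.trials],
        dtype=np.int64,
    )


@dataclass
class SubjectParameters:
    """Free parameters for one subject under a given model."""

    learning_rates: dict[str, float]
    lapse: float
    start_value_cs_plus: float = 0.5
    start_value_cs_minus: float = 0.5
    jump: float = 0.0

    def validate(self, spec: ModelSpec | None = None) -> None:
        for role, lr in self.learning_rates.items():
            if not 0.0 <= lr <= 1.0:
                raise ModelError(f"learning rate {role}={lr} outside [0, 1]")
        if not self.lapse > 0.0:
            raise ModelError("lapse must be positive")
        for v in (self.start_value_cs_plus, self.start_value_cs_minus):
            if not 0.0 <= v <= 1.0:
                raise ModelError("start values must lie in [0, 1]")
        if not 0.0 <= self.jump <= 1.0:
            raise ModelError("jump must lie in [0, 1]")
        if spec is not None:
            missing = set(spec.roles) - set(self.learning_rates)
            if missing:
                raise ModelError(f"missing learning rates for roles {sorted(missing)}")
            if not spec.free_start_values and (
                self.start_value_cs_plus != 0.5 or self.start_value_cs_minus != 0.5
            ):
                raise ModelError(f"variant {spec.fit_variant} fixes start values at 0.5")
            if not spec.free_jump and self.jump != 0.0:
                raise ModelError(f"variant {spec.fit_variant} fixes jump at 0")

    def as_vector(self, spec: ModelSpec) -> np.ndarray:
        vec = [self.learning_rates[r] for r in spec.roles] + [self.lapse]
        if spec.free_start_values:
            vec += [self.start_value_cs_plus, self.start_value_cs_minus]
        if spec.free_jump:
            vec += [self.jump]
        return np.asarray(vec, dtype=float)

    @classmethod
    def from_vector(cls, spec: ModelSpec, vec: np.ndarray) -> "SubjectParameters":
        vec = np.asarray(vec, dtype=float)
        n = len(spec.roles)
        lrs = dict(zip(spec.roles, vec[:n]))
        lapse = float(vec[n])
        i = n + 1
        v0p = v0m = 0.5
        jump = 0.0
        if spec.free_start_values:
            v0p, v0m = float(vec[i]), float(vec[i + 1])
            i += 2
        if spec.free_jump:
            jump = float(vec[i])
        return cls(lrs, lapse, v0p, v0m, jump)


@dataclass
class LatentTrace:
    """Per-trial associative values (pre-update, i.e. at rating time) and
    prediction errors (NaN where no update occurred)."""

    v_cs_plus: np.ndarray
    v_cs_minus: np.ndarray
    prediction_error: np.ndarray


# ---------------------------------------------------------------------------
# Elementary operations

def rw_update(v: float, us: float, lr: float) -> float:
    """One Rescorla-Wagner value update: ``v + (us - v) * lr``."""
    if not 0.0 <= v <= 1.0:
        raise ModelError(f"value {v} outside [0, 1]")
    if us not in (0, 1, 0.0, 1.0):
        raise ModelError(f"outcome {us} must be 0 or 1")
    if not 0.0 <= lr <= 1.0:
        raise ModelError(f"learning rate {lr} outside [0, 1]")
    return v + (us - v) * lr


def beta_shapes(v: float, phi: float = PHI) -> tuple[float, float]:
    """Mean/precision to shape reparameterisation: alpha = v*phi, beta = phi - v*phi.

    At v in {0, 1} one shape is exactly zero, which is degenerate for a beta
    law; callers clamp v to [V_EPS, 1 - V_EPS] first (see
    :func:`ordinal_probs`).
    """
    if not phi > 0:
        raise ModelError("phi must be positive")
    if not 0.0 <= v <= 1.0:
        raise ModelError(f"value {v} outside [0, 1]")
    alpha = v * phi
    return alpha, phi - alpha


def ordinal_probs(alpha: float, beta: float) -> np.ndarray:
    """Discretise the beta kernel on the nine-point rating grid.

    Returns the probability vector P with
    ``P_i ∝ Q_i^(alpha-1) * (1-Q_i)^(beta-1)`` on the guarded grid.
    """
    logw = (alpha - 1.0) * _LOG_Q + (beta - 1.0) * _LOG_1MQ
    logw -= logw.max()
    w = np.exp(logw)
    return w / w.sum()


def choice_probs(p: np.ndarray, lapse: float) -> np.ndarray:
    """Lapse-scaled softmax over the ordinal probabilities.

    theta = softmax(p * lapse).  As lapse -> 0 theta becomes uniform; the
    mode of theta always coincides with the mode of p.
    """
    if not lapse > 0:
        raise ModelError("lapse must be positive")
    z = np.asarray(p, dtype=float) * lapse
    z = z - z.max()
    e = np.exp(z)
    return e / e.sum()


def rating_distribution(v: float, lapse: float) -> np.ndarray:
    """theta for a given associative value: the composed choice rule."""
    vc = min(max(v, V_EPS), 1.0 - V_EPS)
    a, b = beta_shapes(vc)
    return choice_probs(ordinal_probs(a, b), lapse)


# ---------------------------------------------------------------------------
# Trial-sequence operations

def _schedule_arrays(schedule: TrialSchedule):
    cue_plus = np.array([t.cue == CS_PLUS for t in schedule.trials])
    us = np.array([1.0 if t.reinforced else 0.0 for t in schedule.trials])
    phases = [t.phase for t in schedule.trials]
    ext_start = phases.index(EXTINCTION) if EXTINCTION in phases else len(phases)
    return cue_plus, us, ext_start


def _coerce_ratings(ratings, n: int) -> np.ndarray:
    if ratings is None:
        return np.full(n, np.nan)
    arr = np.asarray(
        [np.nan if r is None else float(r) for r in ratings], dtype=float
    )
    if arr.shape != (n,):
        raise ModelError(f"ratings length {arr.shape} does not match {n} trials")
    present = arr[~np.isnan(arr)]
    if len(present) and (
        (present < 1).any() or (present > 9).any() or (present != np.round(present)).any()
    ):
        raise ModelError("ratings must be integers in 1..9 or missing")
    return arr


def run_latent(
    spec: ModelSpec,
    params: SubjectParameters,
    schedule: TrialSchedule,
    ratings=None,
    update_on_missing: bool = False,
) -> LatentTrace:
    """Run the value recursion over a schedule.

    Returns the pre-update (rating-time) values for both cues at every
    trial.  Trials with a missing rating are skipped entirely by default:
    they contribute neither a likelihood term nor a value update, the update
    instead occurring at the next trial with data.  Set
    ``update_on_missing=True`` to apply value updates on missing trials
    anyway.
    """
    params.validate(spec)
    cue_plus, us, ext_start = _schedule_arrays(schedule)
    # No rating sequence means every trial is observed (pure forward run).
    observed_mask = (
        np.ones(len(schedule), dtype=bool)
        if ratings is None
        else ~np.isnan(_coerce_ratings(ratings, len(schedule)))
    )
    roles = role_indices(spec, schedule)
    lrs = np.array([params.learning_rates[r] for r in spec.roles])

    vp = params.start_value_cs_plus
    vm = params.start_value_cs_minus
    v_plus = np.empty(len(schedule))
    v_minus = np.empty(len(schedule))
    pe = np.full(len(schedule), np.nan)
    for t in range(len(schedule)):
        if t == ext_start:
            vm = min(vm + params.jump, 1.0)
        v_plus[t] = vp
        v_minus[t] = vm
        if observed_mask[t] or update_on_missing:
            v = vp if cue_plus[t] else vm
            pe[t] = us[t] - v
            v_new = v + pe[t] * lrs[roles[t]]
            if cue_plus[t]:
                vp = v_new
            else:
                vm = v_new
    return LatentTrace(v_plus, v_minus, pe)


def simulate_ratings(
    spec: ModelSpec,
    params: SubjectParameters,
    schedule: TrialSchedule,
    seed: int | np.random.Generator = 0,
) -> np.ndarray:
    """Draw a rating sequence from the generative model.

    The rating at each trial is drawn from Categorical(theta) computed from
    the pre-update value of the presented cue (ratings are elicited before
    the US is delivered), after which the value update is applied.
    """
    params.validate(spec)
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    cue_plus, us, ext_start = _schedule_arrays(schedule)
    roles = role_indices(spec, schedule)
    lrs = np.array([params.learning_rates[r] for r in spec.roles])

    vp = params.start_value_cs_plus
    vm = params.start_value_cs_minus
    out = np.empty(len(schedule), dtype=np.int64)
    for t in range(len(schedule)):
        if t == ext_start:
            vm = min(vm + params.jump, 1.0)
        v = vp if cue_plus[t] else vm
        theta = rating_distribution(v, params.lapse)
        out[t] = int(np.searchsorted(np.cumsum(theta), rng.random() * theta.sum())) + 1
        v_new = v + (us[t] - v) * lrs[roles[t]]
        if cue_plus[t]:
            vp = v_new
        else:
            vm = v_new
    return out


def pointwise_loglik(
    spec: ModelSpec,
    params: SubjectParameters,
    schedule: TrialSchedule,
    ratings,
    update_on_missing: bool = False,
) -> pd.Series:
    """Per-trial log-likelihood of the observed ratings.

    Returns a Series indexed by (0-based) trial position containing one
    finite entry per non-missing trial; missing trials are absent.  The sum
    equals the subject's total log-likelihood, and the index allows
    phase-by-cue decompositions.
    """
    ratings = _coerce_ratings(ratings, len(schedule))
    trace = run_latent(spec, params, schedule, ratings, update_on_missing)
    cue_plus, _, _ = _schedule_arrays(schedule)
    idx, vals = [], []
    for t in range(len(schedule)):
        if np.isnan(ratings[t]):
            continue
        v = trace.v_cs_plus[t] if cue_plus[t] else trace.v_cs_minus[t]
        theta = rating_distribution(v, params.lapse)
        idx.append(t)
        vals.append(np.log(theta[int(ratings[t]) - 1]))
    return pd.Series(vals, index=pd.Index(idx, name="trial"), name="loglik")


# ---------------------------------------------------------------------------
# Long-format response table IO

RESPONSE_COLUMNS = ["subject_id", "phase", "index", "cue", "reinforced", "rating"]


def responses_frame(schedule: TrialSchedule, ratings_by_subject: dict) -> pd.DataFrame:
    """Assemble a long-format response table (one row per subject x trial)."""
    base = schedule.to_frame()[["phase", "index", "cue", "reinforced"]]
    frames = []
    for sid, ratings in ratings_by_subject.items():
        f = base.copy()
        f.insert(0, "subject_id", sid)
        f["rating"] = _coerce_ratings(ratings, len(schedule))
        frames.append(f)
    return pd.concat(frames, ignore_index=True)


def write_responses_csv(frame: pd.DataFrame, path: str | Path) -> None:
    out = frame.copy()
    out["rating"] = out["rating"].map(lambda r: "" if pd.isna(r) else str(int(r)))
    out.to_csv(path, index=False)


def read_responses_csv(path: str | Path) -> pd.DataFrame:
    frame = pd.read_csv(path)
    frame["rating"] = pd.to_numeric(frame["rating"], errors="coerce")
    frame["reinforced"] = frame["reinforced"].astype(bool)
    return frame
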