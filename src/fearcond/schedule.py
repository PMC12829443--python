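"""Fear-conditioning trial schedules.

The task is a differential fear-conditioning paradigm with two visual cues:
a threat cue (CS+) that is paired with an aversive loud noise (the
unconditional stimulus, US) on a fixed proportion of acquisition trials, and
a safety cue (CS-) that is never reinforced.  Acquisition presents 12 trials
of each cue in a pseudorandom interleaving with 75% CS+ reinforcement
(9 of 12 trials); extinction presents 18 trials of each cue, none
reinforced.  Trials are separated by a 1-3 s inter-trial interval.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

ACQUISITION = "acquisition"
EXTINCTION = "extinction"
CS_PLUS = "CS+"
CS_MINUS = "CS-"

_PHASES = (ACQUISITION, EXTINCTION)
_CUES = (CS_PLUS, CS_MINUS)
_ITI_CHOICES = (1, 2, 3)


class ScheduleConfigError(ValueError):
    """Raised for inconsistent schedule configurations."""


@dataclass(frozen=True)
class TrialSpec:
    """One trial of the paradigm.

    ``index`` is the 1-based position of the trial within its phase.
    ``reinforced`` means the US is delivered after the expectancy rating,
    which is only possible for CS+ trials in acquisition.
    """

    phase: str
    index: int
    cue: str
    reinforced: bool
    iti_seconds: int

    def __post_init__(self) -> None:
        if self.phase not in _PHASES:
            raise ScheduleConfigError(f"unknown phase {self.phase!r}")
        if self.cue not in _CUES:
            raise ScheduleConfigError(f"unknown cue {self.cue!r}")
        if self.reinforced and not (self.cue == CS_PLUS and self.phase == ACQUISITION):
            raise ScheduleConfigError("only acquisition CS+ trials may be reinforced")
        if self.iti_seconds not in _ITI_CHOICES:
            raise ScheduleConfigError("iti_seconds must be 1, 2 or 3")


@dataclass(frozen=True)
class ScheduleConfig:
    """Counts and constraints defining the task schedule."""

    n_acq_per_cue: int = 12
    n_ext_per_cue: int = 18
    reinforcement_rate: float = 0.75
    max_cue_run: int = 2
    max_unreinforced_run: int = 2
    seed: int = 0

    @property
    def n_reinforced(self) -> int:
        n = self.reinforcement_rate * self.n_acq_per_cue
        if abs(n - round(n)) > 1e-9:
            raise ScheduleConfigError(
                f"reinforcement_rate * n_acq_per_cue = {n} is not an integer"
            )
        return int(round(n))

    def validate(self) -> None:
        if self.n_acq_per_cue < 1 or self.n_ext_per_cue < 1:
            raise ScheduleConfigError("per-cue trial counts must be positive")
        if not 0.0 <= self.reinforcement_rate <= 1.0:
            raise ScheduleConfigError("reinforcement_rate must lie in [0, 1]")
        if self.max_cue_run < 1:
            raise ScheduleConfigError("max_cue_run must be at least 1")
        self.n_reinforced  # raises if non-integer


@dataclass(frozen=True)
class TrialSchedule:
    """An ordered sequence of trials (acquisition followed by extinction)."""

    trials: tuple[TrialSpec, ...]
    config: ScheduleConfig
    seed: int

    def __len__(self) -> int:
        return len(self.trials)

    @property
    def n_acquisition(self) -> int:
        return sum(t.phase == ACQUISITION for t in self.trials)

    @property
    def n_extinction(self) -> int:
        return sum(t.phase == EXTINCTION for t in self.trials)

    @property
    def n_reinforced(self) -> int:
        return sum(t.reinforced for t in self.trials)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "phase": [t.phase for t in self.trials],
                "index": [t.index for t in self.trials],
                "cue": [t.cue for t in self.trials],
                "reinforced": [t.reinforced for t in self.trials],
                "iti_seconds": [t.iti_seconds for t in self.trials],
            }
        )


@dataclass
class ValidationReport:
    """Report-only list of schedule invariant violations."""

    violations: list[str] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.violations


def _interleave_cues(rng: np.random.Generator, n_per_cue: int, max_run: int) -> list[str]:
    """Uniform random interleaving, rejected and resampled until no cue run
    exceeds ``max_run``."""
    base = np.array([CS_PLUS] * n_per_cue + [CS_MINUS] * n_per_cue)
    for _ in range(100_000):
        order = rng.permutation(base)
        if _max_run_length(order) <= max_run:
            return list(order)
    raise ScheduleConfigError("could not satisfy max_cue_run constraint")


def _max_run_length(seq) -> int:
    best = run = 1
    for a, b in zip(seq[:-1], seq[1:]):
        run = run + 1 if a == b else 1
        best = max(best, run)
    return best


def _reinforcement_pattern(
    rng: np.random.Generator, n_cs_plus: int, n_reinforced: int, max_unreinforced_run: int
) -> np.ndarray:
    """Choose which CS+ trials carry the US, avoiding long unreinforced runs."""
    pattern = np.zeros(n_cs_plus, dtype=bool)
    if n_reinforced == 0:
        return pattern
    for _ in range(100_000):
        pattern[:] = False
        idx = rng.choice(n_cs_plus, size=n_reinforced, replace=False)
        pattern[idx] = True
        if _max_false_run(pattern) <= max_unreinforced_run:
            return pattern.copy()
    raise ScheduleConfigError("could not satisfy reinforcement-run constraint")


def _max_false_run(pattern: np.ndarray) -> int:
    best = run = 0
    for p in pattern:
        run = 0 if p else run + 1
        best = max(best, run)
    return best


def build_schedule(config: ScheduleConfig | None = None, seed: int | None = None) -> TrialSchedule:
    """Build a pseudorandomised trial schedule.

    Deterministic for a given seed.  The acquisition cue order and the
    reinforcement pattern are drawn uniformly subject to run-length
    constraints (no more than ``max_cue_run`` consecutive same-cue trials,
    no more than ``max_unreinforced_run`` consecutive unreinforced CS+
    trials).
    """
    config = config or ScheduleConfig()
    config.validate()
    if seed is None:
        seed = config.seed
    rng = np.random.default_rng(seed)

    trials: list[TrialSpec] = []
    acq_cues = _interleave_cues(rng, config.n_acq_per_cue, config.max_cue_run)
    reinforce = _reinforcement_pattern(
        rng, config.n_acq_per_cue, config.n_reinforced, config.max_unreinforced_run
    )
    plus_counter = 0
    for i, cue in enumerate(acq_cues):
        reinforced = False
        if cue == CS_PLUS:
            reinforced = bool(reinforce[plus_counter])
            plus_counter += 1
        trials.append(
            TrialSpec(ACQUISITION, i + 1, cue, reinforced, int(rng.choice(_ITI_CHOICES)))
        )
    ext_cues = _interleave_cues(rng, config.n_ext_per_cue, config.max_cue_run)
    for i, cue in enumerate(ext_cues):
        trials.append(
            TrialSpec(EXTINCTION, i + 1, cue, False, int(rng.choice(_ITI_CHOICES)))
        )
    return TrialSchedule(tuple(trials), replace(config, seed=seed), seed)


def validate_schedule(schedule: TrialSchedule) -> ValidationReport:
    """Check every schedule invariant; returns a report rather than raising."""
    report = ValidationReport()
    cfg = schedule.config
    frame = schedule.to_frame()

    for phase, n_expected in ((ACQUISITION, cfg.n_acq_per_cue), (EXTINCTION, cfg.n_ext_per_cue)):
        sub = frame[frame["phase"] == phase]
        for cue in _CUES:
            n = int((sub["cue"] == cue).sum())
            if n != n_expected:
                report.violations.append(
                    f"{phase} has {n} {cue} trials, expected {n_expected}"
                )
    n_reinforced = int(frame["reinforced"].sum())
    try:
        expected = cfg.n_reinforced
    except ScheduleConfigError as exc:
        report.violations.append(str(exc))
        expected = None
    if expected is not None and n_reinforced != expected:
        report.violations.append(
            f"{n_reinforced} reinforced trials, expected {expected}"
        )
    bad = frame[frame["reinforced"] & ((frame["phase"] != ACQUISITION) | (frame["cue"] != CS_PLUS))]
    if len(bad):
        report.violations.append("reinforced trials outside acquisition CS+")
    if not frame["iti_seconds"].isin(_ITI_CHOICES).all():
        report.violations.append("iti_seconds outside {1, 2, 3}")
    for phase in _PHASES:
        cues = frame.loc[frame["phase"] == phase, "cue"].tolist()
        if cues and _max_run_length(cues) > cfg.max_cue_run:
            report.violations.append(f"{phase} cue run exceeds {cfg.max_cue_run}")
    return report


def write_schedule_csv(schedule: TrialSchedule, path: str | Path) -> None:
    schedule.to_frame().to_csv(path, index=False)


def read_schedule_csv(path: str | Path, config: ScheduleConfig | None = None) -> TrialSchedule:
    frame = pd.read_csv(path)
    trials = tuple(
        TrialSpec(
            phase=row.phase,
            index=int(row.index_),
            cue=row.cue,
            reinforced=bool(row.reinforced),
            iti_seconds=int(row.iti_seconds),
        )
        for row in frame.rename(columns={"index": "index_"}).itertuples()
    )
    return TrialSchedule(trials, config or ScheduleConfig(), seed=-1)
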