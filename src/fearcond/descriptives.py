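"""Exclusion filtering and conventional fear-conditioning measures.

Two nested compliance filters are applied before analysis.  The medium
filter removes participants who removed their headphones, reduced volume
below 80% of maximum, restarted the app, or rated the aversive noise below
5 of 10.  The strict filter additionally removes anyone whose volume
dropped below 100% or who did not report contingency awareness — i.e. only
participants who did the task exactly as intended.

The conventional measures the model-based learning rates are benchmarked
against are (1) end-phase CS discrimination: the difference between the
final CS+ and final CS- expectancy rating within a phase, and (2) the
whole-phase mean rating per cue and phase.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum

import numpy as np
import pandas as pd
from scipy import stats

from .schedule import ACQUISITION, CS_MINUS, CS_PLUS, EXTINCTION
from .synth import CohortDataset

MEASURE_COLUMNS = [
    "acq_csp_mean",
    "acq_csm_mean",
    "acq_discrimination",
    "ext_csp_mean",
    "ext_csm_mean",
    "ext_discrimination",
]

COMPLIANCE_COLUMNS = [
    "removed_headphones",
    "min_volume_fraction",
    "restarted_app",
    "us_unpleasantness",
    "contingency_aware",
]


class ExclusionLevel(str, Enum):
    NONE = "none"
    MEDIUM = "medium"
    STRICT = "strict"


class DataError(ValueError):
    pass


def survivor_mask(compliance: pd.DataFrame, level: ExclusionLevel | str) -> pd.Series:
    """Boolean mask of subjects surviving the exclusion filter.

    Volume thresholds are strict inequalities ("below 80%", "below 100%");
    unpleasantness "less than five" keeps a rating of exactly 5.
    """
    level = ExclusionLevel(level)
    missing = set(COMPLIANCE_COLUMNS) - set(compliance.columns)
    if missing:
        raise DataError(f"compliance table missing columns {sorted(missing)}")
    keep = pd.Series(True, index=compliance.index)
    if level == ExclusionLevel.NONE:
        return keep
    keep &= ~compliance["removed_headphones"].astype(bool)
    keep &= compliance["min_volume_fraction"] >= 0.80
    keep &= ~compliance["restarted_app"].astype(bool)
    keep &= compliance["us_unpleasantness"] >= 5
    if level == ExclusionLevel.STRICT:
        keep &= compliance["min_volume_fraction"] >= 1.0
        keep &= compliance["contingency_aware"].astype(bool)
    return keep


def apply_exclusions(cohort: CohortDataset, level: ExclusionLevel | str) -> CohortDataset:
    """Drop non-compliant subjects; survivors are otherwise untouched.

    Strict survivors are always a subset of medium survivors.
    """
    keep = survivor_mask(cohort.compliance, level)
    ids = cohort.compliance.loc[keep, "subject_id"]
    return cohort.select_subjects(ids)


def descriptive_measures(responses: pd.DataFrame) -> pd.DataFrame:
    """Per-subject whole-phase means and end-phase CS discrimination.

    Whole-phase means ignore missing trials.  End-phase discrimination uses
    the last non-missing rating per cue within the phase (a missing final
    trial falls back to the preceding rated trial); a cue with no rated
    trials in a phase yields NaN for the affected measures.
    """
    rows = []
    for sid, sub in responses.groupby("subject_id", sort=False):
        rec = {"subject_id": sid}
        for phase, prefix in ((ACQUISITION, "acq"), (EXTINCTION, "ext")):
            ph = sub[sub["phase"] == phase].sort_values("index")
            finals = {}
            for cue, tag in ((CS_PLUS, "csp"), (CS_MINUS, "csm")):
                vals = pd.to_numeric(ph.loc[ph["cue"] == cue, "rating"], errors="coerce").dropna()
                rec[f"{prefix}_{tag}_mean"] = vals.mean() if len(vals) else np.nan
                finals[tag] = vals.iloc[-1] if len(vals) else np.nan
            rec[f"{prefix}_discrimination"] = finals["csp"] - finals["csm"]
        rows.append(rec)
    return pd.DataFrame(rows, columns=["subject_id", *MEASURE_COLUMNS])


@dataclass
class SignedRankResult:
    statistic: float
    p: float
    n: int
    degenerate: bool = False


def signed_rank_test(paired_a, paired_b) -> SignedRankResult:
    """Two-sided Wilcoxon signed-rank test on paired samples.

    Uses the exact null distribution for n <= 25 without ties or zero
    differences, otherwise the tie-corrected normal approximation.  All-zero
    differences are degenerate and flagged rather than tested.
    """
    a = np.asarray(paired_a, dtype=float)
    b = np.asarray(paired_b, dtype=float)
    if a.shape != b.shape or a.ndim != 1 or len(a) < 1:
        raise DataError("signed_rank_test needs two equal-length 1-d samples")
    diffs = a - b
    if np.allclose(diffs, 0.0):
        return SignedRankResult(np.nan, np.nan, len(a), degenerate=True)
    res = stats.wilcoxon(a, b, alternative="two-sided", method="auto", zero_method="wilcox")
    return SignedRankResult(float(res.statistic), float(res.pvalue), len(a), False)


def measures_with_tests(responses: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Descriptive measures plus signed-rank tests of CS discrimination
    (paired CS+ vs CS- whole-phase means within each phase)."""
    measures = descriptive_measures(responses)
    tests = []
    for phase, prefix in ((ACQUISITION, "acq"), (EXTINCTION, "ext")):
        sub = measures[[f"{prefix}_csp_mean", f"{prefix}_csm_mean"]].dropna()
        res = signed_rank_test(sub.iloc[:, 0], sub.iloc[:, 1])
        tests.append(
            {
                "phase": phase,
                "comparison": "CS+ vs CS- whole-phase mean",
                "statistic": res.statistic,
                "p": res.p,
                "n": res.n,
                "degenerate": res.degenerate,
            }
        )
    return measures, pd.DataFrame(tests)
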