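"""Model-fit metrics and Bayesian model selection.

Fit quality is summarised by the expected log pointwise predictive density
(ELPD) estimated by Pareto-smoothed importance-sampling leave-one-out
cross-validation (PSIS-LOO), together with LOOIC (= -2 ELPD), WAIC, and a
pseudo-r2 relating the model's log-likelihood L to the chance
log-likelihood C of uniform guessing over the nine rating categories:

    pseudo-r2 = 1 - L / C,   C = T * log(1/9).

Selection keeps the ELPD-maximising model; any model whose ELPD deficit is
within five times the standard error of the pairwise ELPD difference is
recorded as tied, with the globally best model retained among ties.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import arviz as az
import numpy as np
import pandas as pd

CHANCE_LOG_PROB = math.log(1.0 / 9.0)
TIE_SE_MULTIPLIER = 5.0


class ComparisonError(ValueError):
    pass


def pseudo_r2(total_loglik: float, n_trials: int) -> float:
    """1 - L/C with C the chance (uniform-over-nine) log-likelihood."""
    if n_trials < 1:
        raise ComparisonError("pseudo_r2 requires at least one trial")
    if total_loglik > 1e-9:
        raise ComparisonError("total log-likelihood must be <= 0")
    return 1.0 - total_loglik / (n_trials * CHANCE_LOG_PROB)


@dataclass
class FitMetrics:
    """ELPD/LOOIC/WAIC summary for one model fit."""

    elpd_loo: float
    elpd_se: float
    looic: float
    p_loo: float
    elpd_waic: float
    waic: float
    pseudo_r2: float
    n_points: int
    loo_pointwise: np.ndarray
    pareto_k: np.ndarray
    by_phase_cue: dict = field(default_factory=dict)

    @property
    def high_pareto_points(self) -> np.ndarray:
        """Indices of datapoints with unreliable importance weights (k > 0.7);
        flagged, not fatal."""
        return np.flatnonzero(self.pareto_k > 0.7)


def elpd_estimates(loglik_draws: np.ndarray, point_meta: pd.DataFrame | None = None) -> FitMetrics:
    """PSIS-LOO / WAIC estimates from a pointwise log-likelihood array.

    ``loglik_draws`` has shape (chains, draws, points) or (draws, points).
    When ``point_meta`` (columns ``phase`` and ``cue``) is given, the ELPD
    and pseudo-r2 are additionally decomposed over phase x cue subsets by
    restricting the pointwise matrix.
    """
    ll = np.asarray(loglik_draws, dtype=float)
    if ll.ndim == 2:
        ll = ll[np.newaxis]
    if ll.ndim != 3:
        raise ComparisonError("log-likelihood draws must be 2- or 3-dimensional")
    if not np.isfinite(ll).all():
        raise ComparisonError("log-likelihood draws contain non-finite entries")

    idata = az.from_dict(log_likelihood={"rating": ll})
    # relative MCMC efficiency of the pointwise log-likelihood (1 for a
    # single chain or degenerate draws)
    n_draws = ll.shape[0] * ll.shape[1]
    if ll.shape[0] >= 2 and np.ptp(ll, axis=(0, 1)).max() > 0:
        ess = az.ess(az.convert_to_dataset(ll, group="log_likelihood"))
        reff = float(np.nanmean(ess.to_array().values)) / n_draws
        if not np.isfinite(reff) or reff <= 0:
            reff = 1.0
    else:
        reff = 1.0
    loo = az.loo(idata, pointwise=True, reff=reff)
    waic = az.waic(idata)

    pointwise_mean = ll.mean(axis=(0, 1))
    n_points = pointwise_mean.size
    metrics = FitMetrics(
        elpd_loo=float(loo.elpd_loo),
        elpd_se=float(loo.se),
        looic=-2.0 * float(loo.elpd_loo),
        p_loo=float(loo.p_loo),
        elpd_waic=float(waic.elpd_waic),
        waic=-2.0 * float(waic.elpd_waic),
        pseudo_r2=pseudo_r2(float(pointwise_mean.sum()), n_points),
        n_points=n_points,
        loo_pointwise=np.asarray(loo.loo_i.values, dtype=float),
        pareto_k=np.asarray(loo.pareto_k.values, dtype=float),
    )
    if point_meta is not None:
        if len(point_meta) != n_points:
            raise ComparisonError("point metadata does not match the pointwise matrix")
        for (phase, cue), idx in point_meta.groupby(["phase", "cue"]).groups.items():
            cols = np.asarray(idx, dtype=int)
            sub = ll[:, :, cols]
            sub_idata = az.from_dict(log_likelihood={"rating": sub})
            sub_loo = az.loo(sub_idata, pointwise=False, reff=reff)
            sub_mean = sub.mean(axis=(0, 1))
            metrics.by_phase_cue[(phase, cue)] = {
                "elpd_loo": float(sub_loo.elpd_loo),
                "elpd_se": float(sub_loo.se),
                "pseudo_r2": pseudo_r2(float(sub_mean.sum()), sub_mean.size),
                "n_points": int(sub_mean.size),
            }
    return metrics


@dataclass
class ComparisonTable:
    """Ranked model comparison with the 5-SE tie rule applied."""

    table: pd.DataFrame
    selected: str
    ties: list = field(default_factory=list)


def select_model(metrics_by_label: dict[str, FitMetrics]) -> ComparisonTable:
    """Select the ELPD-maximising model.

    Any model whose pairwise ELPD difference from the top model is within
    five times the (paired, pointwise) standard error of that difference is
    recorded as a tie; the globally best model is retained regardless.
    """
    if len(metrics_by_label) < 2:
        raise ComparisonError("model selection needs at least two fitted models")
    labels = list(metrics_by_label)
    elpds = {lab: metrics_by_label[lab].elpd_loo for lab in labels}
    best = max(elpds, key=elpds.get)
    best_pw = metrics_by_label[best].loo_pointwise

    rows = []
    ties = []
    for lab in sorted(labels, key=lambda l: -elpds[l]):
        m = metrics_by_label[lab]
        if lab == best:
            d_elpd, d_se, tied = 0.0, 0.0, False
        else:
            if len(m.loo_pointwise) != len(best_pw):
                raise ComparisonError("models were fitted to different datapoints")
            diff = best_pw - m.loo_pointwise
            d_elpd = float(diff.sum())
            d_se = float(np.sqrt(len(diff) * diff.var(ddof=0)))
            tied = d_elpd <= TIE_SE_MULTIPLIER * d_se
            if tied:
                ties.append(lab)
        rows.append(
            {
                "model": lab,
                "elpd_loo": m.elpd_loo,
                "elpd_se": m.elpd_se,
                "looic": m.looic,
                "waic": m.waic,
                "pseudo_r2": m.pseudo_r2,
                "d_elpd": d_elpd,
                "d_se": d_se,
                "tied_with_best": tied,
            }
        )
    return ComparisonTable(table=pd.DataFrame(rows), selected=best, ties=ties)


def comparison_csv(table: ComparisonTable, path) -> None:
    table.table.to_csv(path, index=False)
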