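"""Patient-level drug-resistance scoring and survival stratification.

The resistance score of a patient is the intercept-free linear
combination sum_i beta_i * Exp_i over the trained model's genes (or the
forest prediction for the forest model).  Scores are dichotomized at the
maximally selected rank-statistic cutpoint: among all candidate splits
leaving at least ``minprop`` of the cohort on each side, the one whose
two-group standardized log-rank statistic is largest in absolute value.
Samples at or above the cutpoint form the resistant group.  Group
survival is compared by Kaplan-Meier curves and the two-sample log-rank
test.

The log-rank p at the maxstat-selected split is reported raw; because
the cutpoint is chosen to maximize the statistic, this p is optimistic
under the null (the inflation is quantified in the test suite).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter

from .io import ExpressionDataset

__all__ = [
    "RESISTANT",
    "SENSITIVE",
    "ScoreTable",
    "SurvivalComparison",
    "drug_resistance_score",
    "maxstat_cutpoint",
    "dichotomize",
    "km_estimate",
    "logrank_statistic",
    "logrank_test",
    "validate_cohort",
]

RESISTANT = "resistant"
SENSITIVE = "sensitive"


@dataclass
class ScoreTable:
    """Per-sample scores, the shared cutpoint and the induced groups."""

    table: pd.DataFrame  # columns: score, group; index: sample_id
    cutpoint: float

    @property
    def scores(self) -> pd.Series:
        return self.table["score"]

    @property
    def groups(self) -> pd.Series:
        return self.table["group"]


@dataclass
class SurvivalComparison:
    chi_square: float
    p_value: float
    degrees_of_freedom: int
    group_sizes: dict[str, int]
    km_curves: dict[str, pd.DataFrame]  # group -> (time, survival, at_risk)
    metadata: dict = field(default_factory=dict)


def drug_resistance_score(model, expr: ExpressionDataset) -> pd.Series:
    """Score = sum_i beta_i * Exp_i over the model's genes (no intercept)
    for linear model kinds; forest models score by predicted value.
    Missing model genes raise with the genes listed."""
    missing = [g for g in model.selected_genes if g not in set(expr.gene_ids)]
    if missing:
        raise KeyError(f"model gene(s) absent from expression data: {missing}")
    sub = expr.subset_genes(model.selected_genes)
    if not np.all(np.isfinite(sub.values)):
        raise ValueError("non-finite expression values")
    if model.kind == "rf":
        values = model.forest.predict(sub.values.T)
    else:
        values = sub.values.T @ np.asarray(model.coefficients, dtype=float)
    return pd.Series(values, index=expr.sample_ids, name="score")


def logrank_statistic(
    groups: np.ndarray, times: np.ndarray, events: np.ndarray
) -> tuple[float, float]:
    """Two-sample log-rank: returns (Z, chi_square) where Z is the
    standardized observed-minus-expected event count of group 1 and
    chi_square = Z**2.  Uses the hypergeometric variance with ties."""
    groups = np.asarray(groups, dtype=bool)
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    order = np.argsort(times, kind="stable")
    times, events, groups = times[order], events[order], groups[order]
    uniq, start = np.unique(times, return_index=True)
    n = len(times)
    o_minus_e = 0.0
    var = 0.0
    # censored subjects at t remain at risk for events at t
    at_risk_total = n
    at_risk_g1 = int(groups.sum())
    bounds = list(start) + [n]
    for i in range(len(uniq)):
        sl = slice(bounds[i], bounds[i + 1])
        d = int(events[sl].sum())
        if d > 0:
            n_t, n1_t = at_risk_total, at_risk_g1
            d1 = int(events[sl][groups[sl]].sum())
            e1 = d * n1_t / n_t
            o_minus_e += d1 - e1
            if n_t > 1:
                var += d * (n1_t / n_t) * (1 - n1_t / n_t) * (n_t - d) / (n_t - 1)
        at_risk_total -= sl.stop - sl.start
        at_risk_g1 -= int(groups[sl].sum())
    if var <= 0:
        return 0.0, 0.0
    z = o_minus_e / math.sqrt(var)
    return float(z), float(z * z)


def logrank_test(
    groups: pd.Series | np.ndarray,
    times: np.ndarray,
    events: np.ndarray,
) -> SurvivalComparison:
    """Two-sample log-rank test (1 df) with per-group Kaplan-Meier curves."""
    groups = pd.Series(np.asarray(groups))
    labels = sorted(groups.unique())
    if len(labels) != 2:
        raise ValueError(f"need exactly 2 groups, found {len(labels)}: {labels}")
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    if events.sum() < 1:
        raise ValueError("no events observed")
    indicator = (groups == labels[1]).to_numpy()
    _z, chi2 = logrank_statistic(indicator, times, events)
    from scipy.stats import chi2 as chi2_dist

    p = float(chi2_dist.sf(chi2, df=1)) if chi2 > 0 else 1.0
    curves = {
        str(lab): km_estimate(times[(groups == lab).to_numpy()], events[(groups == lab).to_numpy()])
        for lab in labels
    }
    sizes = {str(lab): int((groups == lab).sum()) for lab in labels}
    return SurvivalComparison(
        chi_square=chi2, p_value=p, degrees_of_freedom=1,
        group_sizes=sizes, km_curves=curves,
    )


def km_estimate(times: np.ndarray, events: np.ndarray) -> pd.DataFrame:
    """Kaplan-Meier product-limit curve (lifelines) with at-risk counts at
    the distinct event times; censored subjects at an event time remain at
    risk for that event."""
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    if len(times) == 0:
        raise ValueError("empty input")
    if (times <= 0).any():
        raise ValueError("times must be positive")
    kmf = KaplanMeierFitter()
    kmf.fit(times, events)
    event_times = np.unique(times[events == 1])
    if event_times.size == 0:
        return pd.DataFrame({"time": [], "survival": [], "at_risk": []})
    surv = kmf.survival_function_at_times(event_times).to_numpy()
    at_risk = np.array([(times >= t).sum() for t in event_times])
    return pd.DataFrame({"time": event_times, "survival": surv, "at_risk": at_risk})


def maxstat_cutpoint(
    scores: np.ndarray,
    times: np.ndarray,
    events: np.ndarray,
    minprop: float = 0.1,
) -> tuple[float, float]:
    """Maximally selected rank statistic: over candidate cutpoints
    (midpoints between consecutive distinct scores whose split keeps at
    least ``minprop`` of the cohort on each side), return the cutpoint
    maximizing |standardized log-rank statistic| and that maximum.
    Ties go to the smallest cutpoint."""
    scores = np.asarray(scores, dtype=float)
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    n = len(scores)
    if n < 10:
        raise ValueError("need at least 10 samples")
    if events.sum() < 2:
        raise ValueError("need at least 2 events")
    if not (0 < minprop < 0.5):
        raise ValueError("minprop must be in (0, 0.5)")
    distinct = np.unique(scores)
    candidates = (distinct[:-1] + distinct[1:]) / 2.0
    best_cut = math.nan
    best_stat = -math.inf
    for cut in candidates:
        high = scores >= cut
        n_high = int(high.sum())
        if min(n_high, n - n_high) < minprop * n:
            continue
        z, _chi2 = logrank_statistic(high, times, events)
        stat = abs(z)
        if stat > best_stat + 1e-12:
            best_stat = stat
            best_cut = float(cut)
    if not math.isfinite(best_cut):
        raise ValueError("no candidate cutpoint satisfies the minprop constraint")
    return best_cut, float(best_stat)


def dichotomize(scores: pd.Series, cutpoint: float) -> pd.Series:
    """Resistant iff score >= cutpoint (boundary resistant)."""
    if not math.isfinite(cutpoint):
        raise ValueError("cutpoint must be finite")
    return pd.Series(
        np.where(scores.to_numpy() >= cutpoint, RESISTANT, SENSITIVE),
        index=scores.index, name="group",
    )


def validate_cohort(
    model,
    expr: ExpressionDataset,
    phenotype: pd.DataFrame,
    minprop: float = 0.1,
) -> tuple[SurvivalComparison, ScoreTable]:
    """Score a cohort, estimate its maxstat cutpoint on overall survival,
    dichotomize, and compare group survival (KM + log-rank).  The
    cutpoint is re-estimated per cohort."""
    scores = drug_resistance_score(model, expr)
    samples = [s for s in scores.index if s in phenotype.index]
    if not samples:
        raise ValueError("no scored sample has phenotype data")
    scores = scores.loc[samples]
    times = phenotype.loc[samples, "os_time"].to_numpy(dtype=float)
    events = phenotype.loc[samples, "os_event"].to_numpy(dtype=int)
    cut, stat = maxstat_cutpoint(scores.to_numpy(), times, events, minprop=minprop)
    groups = dichotomize(scores, cut)
    comparison = logrank_test(groups, times, events)
    comparison.metadata = {
        "model_kind": model.kind,
        "n_model_genes": len(model.selected_genes),
        "cutpoint": cut,
        "maxstat_statistic": stat,
        "seed": getattr(model, "metadata", {}).get("seed"),
    }
    table = pd.DataFrame({"score": scores, "group": groups})
    return comparison, ScoreTable(table=table, cutpoint=cut)
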