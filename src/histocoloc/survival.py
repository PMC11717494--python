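"""Survival stratification and association testing.

Patients are dichotomised into high/low groups on a spatial metric
(default: cohort median, ties at the cutpoint going low), compared with a
two-sided log-rank test, and — for metrics that warrant it — tested in a
multivariate Cox proportional-hazards model with clinical covariates.

The log-rank statistic and the Kaplan–Meier product-limit estimator are
implemented directly (they are part of the reported analysis surface and
are oracle-tested against hand computations); the Cox partial-likelihood
fit is delegated to lifelines with the Efron tie correction.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)


class FitError(RuntimeError):
    """Raised when the proportional-hazards fit fails to converge."""


@dataclass(frozen=True)
class StratifiedCohort:
    """Per-patient high/low labels for a metric, with the cutpoint used."""

    labels: pd.Series  # index: patient id; values: "high"/"low"
    cutpoint: float
    metric_name: str

    def __post_init__(self) -> None:
        groups = set(self.labels.unique())
        if groups != {"high", "low"}:
            raise ValueError(f"expected exactly the groups high/low, got {sorted(groups)}")


@dataclass
class AssociationResult:
    """Log-rank test plus (optionally) an adjusted hazards fit.

    ``hazard_table`` has one row per model term with columns
    term, hr, ci_low, ci_high, p, log_hr, se.
    """

    logrank_stat: float | None = None
    logrank_p: float | None = None
    hazard_table: pd.DataFrame | None = None
    n_patients: int = 0
    n_events: int = 0
    n_dropped: int = 0

    def hr(self, term: str) -> float:
        return float(self.hazard_table.set_index("term").loc[term, "hr"])

    def ci(self, term: str) -> tuple[float, float]:
        row = self.hazard_table.set_index("term").loc[term]
        return float(row.ci_low), float(row.ci_high)


# ---------------------------------------------------------------------------
# stratification
# ---------------------------------------------------------------------------


def dichotomise(values: pd.Series, method: str = "median") -> StratifiedCohort:
    """Split patients into high/low groups on a metric.

    The default cutpoint is the cohort median; values strictly above it
    are "high", ties at the cutpoint go "low".  The cutpoint is recorded
    so alternative rules remain auditable.
    """
    v = pd.Series(values).astype(float)
    if len(v) < 2:
        raise ValueError("need >= 2 patients")
    if not np.isfinite(v).all():
        raise ValueError("metric values must be finite")
    if v.nunique() == 1:
        raise ValueError("all metric values identical: stratification degenerate")
    if method != "median":
        raise ValueError(f"unknown dichotomisation method {method!r}")
    cut = float(v.median())
    labels = pd.Series(np.where(v > cut, "high", "low"), index=v.index, name="group")
    if labels.nunique() == 1:
        raise ValueError("degenerate stratification: median split left one group empty")
    return StratifiedCohort(labels=labels, cutpoint=cut, metric_name=str(values.name or "metric"))


# ---------------------------------------------------------------------------
# log-rank test (direct implementation)
# ---------------------------------------------------------------------------


def logrank_test(
    time: np.ndarray, event: np.ndarray, group: np.ndarray
) -> tuple[float, float]:
    """Two-group, two-sided log-rank test.

    At each distinct event time the observed number of events in group 1
    is compared with its hypergeometric expectation given the risk sets;
    the chi-square statistic (1 df) is ``(sum O - sum E)^2 / sum V``.
    Returns ``(statistic, p)``.
    """
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=bool)
    group = np.asarray(group)
    names = np.unique(group)
    if len(names) != 2:
        raise ValueError(f"log-rank test needs exactly two groups, got {len(names)}")
    if not event.any():
        raise ValueError("log-rank test needs at least one event")
    g1 = group == names[0]

    o_minus_e, var = 0.0, 0.0
    for t in np.unique(time[event]):
        at_risk = time >= t
        n = at_risk.sum()
        n1 = (at_risk & g1).sum()
        d = (event & (time == t)).sum()
        d1 = (event & (time == t) & g1).sum()
        o_minus_e += d1 - d * n1 / n
        if n > 1:
            var += d * (n1 / n) * (1 - n1 / n) * (n - d) / (n - 1)
    if var == 0:
        return 0.0, 1.0
    stat = o_minus_e**2 / var
    return float(stat), float(stats.chi2.sf(stat, df=1))


# ---------------------------------------------------------------------------
# Kaplan–Meier product-limit estimator (direct implementation)
# ---------------------------------------------------------------------------


def km_curve(time: np.ndarray, event: np.ndarray) -> pd.DataFrame:
    """Product-limit survival estimate for one group.

    Returns a step table with one row per distinct event time: columns
    time, n_at_risk, n_events, survival.  The curve starts at S(0) = 1
    and steps only at event times.
    """
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=bool)
    rows = [{"time": 0.0, "n_at_risk": int(len(time)), "n_events": 0, "survival": 1.0}]
    s = 1.0
    for t in np.unique(time[event]):
        n = int((time >= t).sum())
        d = int((event & (time == t)).sum())
        s *= 1.0 - d / n
        rows.append({"time": float(t), "n_at_risk": n, "n_events": d, "survival": s})
    return pd.DataFrame(rows)


def km_curves(
    records: pd.DataFrame, cohort: StratifiedCohort, at_risk_times: np.ndarray | None = None
) -> dict[str, pd.DataFrame]:
    """Per-group Kaplan–Meier step tables (+ numbers at risk on a grid).

    ``records`` needs columns patient_id, pfs_months, event; group labels
    come from ``cohort.labels`` indexed by patient id.
    """
    merged = (
        records.drop(columns=["group"], errors="ignore")
        .set_index("patient_id")
        .join(cohort.labels, how="inner")
    )
    out = {}
    for g, grp in merged.groupby("group"):
        tab = km_curve(grp.pfs_months.to_numpy(), grp.event.to_numpy())
        if at_risk_times is not None:
            t = grp.pfs_months.to_numpy()
            nar = pd.DataFrame(
                {"time": at_risk_times, "n_at_risk": [(t >= u).sum() for u in at_risk_times]}
            )
            tab.attrs["numbers_at_risk"] = nar
        out[str(g)] = tab
    return out


# ---------------------------------------------------------------------------
# adjusted proportional hazards (lifelines, Efron ties)
# ---------------------------------------------------------------------------


def fit_adjusted_hazards(
    records: pd.DataFrame,
    metric_term: str,
    covariates: list[str] | None = None,
    duration_col: str = "pfs_months",
    event_col: str = "event",
) -> AssociationResult:
    """Multivariate Cox proportional-hazards fit.

    ``records`` holds one row per patient with the duration/event columns,
    the metric term (numeric or a high/low label, encoded 1/0) and any
    clinical covariates.  Patients missing any model column are dropped
    listwise (logged).  Raises :class:`FitError` on non-convergence.
    """
    from lifelines import CoxPHFitter
    from lifelines.exceptions import ConvergenceError

    covariates = list(covariates or [])
    terms = [metric_term] + covariates
    cols = [duration_col, event_col] + terms
    missing = [c for c in cols if c not in records.columns]
    if missing:
        raise ValueError(f"missing columns: {missing}")

    df = records[cols].copy()
    if df[metric_term].dtype == object:
        df[metric_term] = (df[metric_term] == "high").astype(float)
    n0 = len(df)
    df = df.dropna()
    n_dropped = n0 - len(df)
    if n_dropped:
        logger.info("dropped %d of %d patients with missing covariates", n_dropped, n0)

    for term in terms:
        if df[term].nunique() <= 1:
            raise ValueError(f"covariate {term!r} is constant after listwise deletion")
    n_events = int(df[event_col].sum())
    if n_events < len(terms):
        raise ValueError(f"{n_events} events for {len(terms)} parameters: model unidentifiable")

    cph = CoxPHFitter()
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            cph.fit(df, duration_col=duration_col, event_col=event_col)
    except (ConvergenceError, np.linalg.LinAlgError) as exc:
        raise FitError(f"proportional-hazards fit did not converge: {exc}") from exc

    summ = cph.summary
    table = pd.DataFrame(
        {
            "term": summ.index,
            "hr": summ["exp(coef)"].to_numpy(),
            "ci_low": summ["exp(coef) lower 95%"].to_numpy(),
            "ci_high": summ["exp(coef) upper 95%"].to_numpy(),
            "p": summ["p"].to_numpy(),
            "log_hr": summ["coef"].to_numpy(),
            "se": summ["se(coef)"].to_numpy(),
        }
    ).reset_index(drop=True)
    return AssociationResult(
        hazard_table=table, n_patients=len(df), n_events=n_events, n_dropped=n_dropped
    )


# ---------------------------------------------------------------------------
# composed analyses
# ---------------------------------------------------------------------------


def associate(
    records: pd.DataFrame,
    cohort: StratifiedCohort,
    covariates: list[str] | None = None,
) -> AssociationResult:
    """Univariate log-rank test plus covariate-adjusted hazards fit for a
    stratified cohort.  ``records`` must carry patient_id."""
    merged = (
        records.drop(columns=["group"], errors="ignore")
        .set_index("patient_id")
        .join(cohort.labels, how="inner")
        .reset_index()
    )
    stat, p = logrank_test(
        merged.pfs_months.to_numpy(), merged.event.to_numpy(), merged.group.to_numpy()
    )
    res = fit_adjusted_hazards(merged, "group", covariates)
    res.logrank_stat, res.logrank_p = stat, p
    return res


def subgroup_analysis(
    records: pd.DataFrame,
    cohort: StratifiedCohort,
    stratifier: str,
    covariates: list[str] | None = None,
) -> dict[str, AssociationResult]:
    """Repeat the association analysis within each stratum of a covariate.

    Strata with fewer than 2 patients or no events are skipped with a
    warning.  Returns stratum value -> AssociationResult.
    """
    if stratifier not in records.columns:
        raise ValueError(f"stratifier {stratifier!r} not in records")
    if records[stratifier].isna().any():
        raise ValueError(f"stratifier {stratifier!r} missing for some patients")
    out: dict[str, AssociationResult] = {}
    for value, grp in records.groupby(stratifier):
        if len(grp) < 2 or grp.event.sum() == 0:
            logger.warning("skipping stratum %s=%r: too few patients or no events",
                           stratifier, value)
            continue
        sub_labels = cohort.labels.loc[cohort.labels.index.intersection(grp.patient_id)]
        if sub_labels.nunique() < 2:
            logger.warning("skipping stratum %s=%r: single group", stratifier, value)
            continue
        sub_cohort = StratifiedCohort(sub_labels, cohort.cutpoint, cohort.metric_name)
        try:
            out[str(value)] = associate(grp, sub_cohort, covariates)
        except (ValueError, FitError) as exc:
            logger.warning("skipping stratum %s=%r: %s", stratifier, value, exc)
    return out
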