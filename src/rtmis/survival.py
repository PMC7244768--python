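"""Outcome analyses: Kaplan-Meier, log-rank, threshold scans, Cox models.

Follow-up is administratively right-censored at 60 months: any record with
a longer time is stored at 60 months with its event removed.  Survival
curves use the Kaplan-Meier product-limit estimator with exponential
Greenwood (log(-log)) 95% confidence intervals; group comparisons use the
two-sided log-rank test.

Expression-based risk groups (e.g. MYC-high, BCL2-high) are derived by
scanning dichotomisation thresholds over a grid of expression quantiles
(0.10-0.90 in steps of 0.05) and keeping the split with the smallest
log-rank p.  The scan is exploratory: the minimum p is not corrected for
the number of thresholds tried, and the full p-vector is returned so users
can correct.  The double-expressor group is MYC > threshold AND BCL2 >
threshold.  Multivariable analysis uses a Cox proportional-hazards model
(Efron handling of ties) with Wald confidence intervals.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.statistics import logrank_test

CENSOR_HORIZON_MONTHS = 60.0
DEFAULT_SCAN_QUANTILES = np.round(np.arange(0.10, 0.901, 0.05), 2)


class SurvivalError(ValueError):
    pass


def apply_censoring_cap(records: pd.DataFrame,
                        horizon: float = CENSOR_HORIZON_MONTHS
                        ) -> pd.DataFrame:
    """Administrative right-censoring: cap times and drop capped events."""
    out = records.copy()
    over = out["time"] > horizon
    out.loc[over, "time"] = horizon
    out.loc[over, "event"] = False
    out["event"] = out["event"].astype(bool)
    if (out["time"] < 0).any():
        raise SurvivalError("negative survival time")
    return out


def load_clinical(path, horizon: float = CENSOR_HORIZON_MONTHS
                  ) -> pd.DataFrame:
    """Read a clinical CSV (sample_id, time_months, event[, ipi_score]).

    Applies the censoring cap and derives ``ipi_high`` (score 3-5) when an
    IPI score column is present.
    """
    df = pd.read_csv(path)
    records = pd.DataFrame({
        "time": df["time_months"].astype(float).to_numpy(),
        "event": df["event"].astype(bool).to_numpy(),
    }, index=pd.Index(df["sample_id"], name="sample_id"))
    if "ipi_score" in df.columns:
        records["ipi_high"] = (df["ipi_score"].astype(int).to_numpy() >= 3)
    return apply_censoring_cap(records, horizon)


def km_estimate(records: pd.DataFrame, alpha: float = 0.05) -> pd.DataFrame:
    """Kaplan-Meier product-limit estimate with 95% CI.

    Returns a step-function table indexed by time with columns
    ``survival``, ``ci_lower``, ``ci_upper`` (exponential Greenwood
    intervals, clipped to [0, 1]).
    """
    if len(records) == 0:
        raise SurvivalError("no records")
    kmf = KaplanMeierFitter(alpha=alpha)
    kmf.fit(records["time"], records["event"])
    out = kmf.survival_function_.copy()
    out.columns = ["survival"]
    ci = kmf.confidence_interval_
    out["ci_lower"] = ci.iloc[:, 0].clip(0.0, 1.0).to_numpy()
    out["ci_upper"] = ci.iloc[:, 1].clip(0.0, 1.0).to_numpy()
    return out


def logrank(records: pd.DataFrame,
            group: pd.Series | np.ndarray) -> tuple[float, float]:
    """Two-sided log-rank test between two groups: (chi2 statistic, p)."""
    group = np.asarray(group)
    values = pd.unique(group)
    if len(values) != 2:
        raise SurvivalError(f"log-rank needs two groups, got {len(values)}")
    in_a = group == values[0]
    res = logrank_test(records["time"][in_a], records["time"][~in_a],
                       records["event"][in_a], records["event"][~in_a])
    return float(res.test_statistic), float(res.p_value)


@dataclass
class ThresholdScanResult:
    """Exploratory log-rank threshold scan (selection not corrected)."""

    gene: str
    quantiles: np.ndarray
    thresholds: np.ndarray
    logrank_p: np.ndarray       # nan where the split is degenerate
    chosen_quantile: float
    chosen_threshold: float

    @property
    def chosen_p(self) -> float:
        return float(np.nanmin(self.logrank_p))


def threshold_scan(expr: pd.DataFrame, gene: str, records: pd.DataFrame,
                   quantiles: np.ndarray = DEFAULT_SCAN_QUANTILES
                   ) -> ThresholdScanResult:
    """Scan expression quantiles for the most significant dichotomisation.

    Ties in p resolve to the lowest quantile.  Raises on constant
    expression (degenerate grid).  Requires expression for every record.
    """
    values = expr.loc[records.index, gene].astype(float)
    if values.isna().any():
        raise SurvivalError(f"missing expression for {gene}")
    if np.ptp(values.to_numpy()) == 0:
        raise SurvivalError(f"degenerate grid: {gene} expression is constant")
    quantiles = np.asarray(quantiles, dtype=float)
    thresholds = np.quantile(values.to_numpy(), quantiles)
    pvals = np.full(len(quantiles), np.nan)
    for i, thr in enumerate(thresholds):
        high = values.to_numpy() > thr
        if high.all() or not high.any():
            continue
        _, pvals[i] = logrank(records, high)
    if np.isnan(pvals).all():
        raise SurvivalError(f"degenerate grid: no threshold splits {gene}")
    best = int(np.nanargmin(pvals))
    return ThresholdScanResult(
        gene=gene, quantiles=quantiles, thresholds=thresholds,
        logrank_p=pvals, chosen_quantile=float(quantiles[best]),
        chosen_threshold=float(thresholds[best]))


def double_expressor(expr: pd.DataFrame, records: pd.DataFrame,
                     myc_threshold: float, bcl2_threshold: float,
                     myc_gene: str = "MYC",
                     bcl2_gene: str = "BCL2") -> pd.Series:
    """Flag samples with both MYC and BCL2 above their thresholds."""
    sub = expr.loc[records.index]
    flag = ((sub[myc_gene] > myc_threshold)
            & (sub[bcl2_gene] > bcl2_threshold))
    return flag.rename("double_expressor")


def cox_multivariate(records: pd.DataFrame,
                     covariates: list[str] | None = None) -> pd.DataFrame:
    """Cox proportional-hazards fit (Efron ties) over boolean covariates.

    Returns a DataFrame indexed by covariate with columns ``hr``,
    ``ci_lower``, ``ci_upper`` (Wald 95%), ``p`` and ``coef``.  Warns when
    there are fewer than 10 events per covariate.
    """
    if covariates is None:
        covariates = [c for c in records.columns
                      if c not in ("time", "event")]
    if not covariates:
        raise SurvivalError("no covariates")
    for c in covariates:
        if records[c].nunique() < 2:
            raise SurvivalError(f"non-identifiable covariate: {c!r} is "
                                "constant across the cohort")
    n_events = int(records["event"].sum())
    if n_events < 10 * len(covariates):
        warnings.warn(
            f"only {n_events} events for {len(covariates)} covariates "
            "(< 10 per covariate); estimates may be unstable", stacklevel=2)
    df = records[["time", "event"] + covariates].astype(float)
    cph = CoxPHFitter()
    cph.fit(df, duration_col="time", event_col="event")
    summ = cph.summary
    out = pd.DataFrame({
        "coef": summ["coef"],
        "hr": summ["exp(coef)"],
        "ci_lower": summ["exp(coef) lower 95%"],
        "ci_upper": summ["exp(coef) upper 95%"],
        "p": summ["p"],
    })
    out.index.name = "covariate"
    return out.loc[covariates]
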