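"""Survival-analysis layer: Kaplan–Meier, log-rank, Cox regression,
Harrell's concordance, time-dependent AUC, and subgroup forest tables.

All functions accept a tidy patient table (``pandas.DataFrame``) with
``time`` (months, > 0) and ``event`` (0/1) columns, the shape the cohort
generator writes to ``patients.csv``.  Tests are two-sided with alpha 0.05.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.statistics import multivariate_logrank_test
from lifelines.utils import concordance_index as _lifelines_cindex

ALPHA = 0.05

__all__ = [
    "SurvivalRecord", "KMCurve", "CoxFit", "LogrankResult",
    "records_to_frame", "check_survival_frame",
    "km_curve", "km_rate_at", "logrank_test", "cox_fit",
    "concordance_index", "time_dependent_auc", "subgroup_forest",
]


@dataclass(frozen=True)
class SurvivalRecord:
    """One patient's endpoint: time in months, event indicator, covariates."""

    patient_id: str
    time: float
    event: int
    endpoint: str = "DFS"
    covariates: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.time <= 0:
            raise ValueError(f"time must be > 0, got {self.time}")
        if self.event not in (0, 1):
            raise ValueError(f"event must be 0 or 1, got {self.event}")


def records_to_frame(records: list[SurvivalRecord]) -> pd.DataFrame:
    rows = []
    for r in records:
        row = {"patient_id": r.patient_id, "time": r.time, "event": r.event,
               "endpoint": r.endpoint}
        row.update(r.covariates)
        rows.append(row)
    return pd.DataFrame(rows)


def check_survival_frame(df: pd.DataFrame) -> pd.DataFrame:
    if not {"time", "event"} <= set(df.columns):
        raise ValueError("survival frame needs 'time' and 'event' columns")
    if (df["time"] <= 0).any():
        raise ValueError("all times must be > 0")
    if not df["event"].isin([0, 1]).all():
        raise ValueError("event must be binary 0/1")
    return df


# ---------------------------------------------------------------------------
# Kaplan–Meier
# ---------------------------------------------------------------------------

@dataclass
class KMCurve:
    """Product-limit estimate: right-continuous step function."""

    times: np.ndarray          # step grid, starts at 0
    survival: np.ndarray       # S(t) at each grid time
    at_risk: np.ndarray        # number at risk just before each grid time
    censor_times: np.ndarray   # times of censored observations

    def rate_at(self, t: float) -> float:
        return km_rate_at(self, t)


def km_curve(df: pd.DataFrame) -> KMCurve:
    check_survival_frame(df)
    if len(df) == 0:
        raise ValueError("need at least one record")
    kmf = KaplanMeierFitter()
    kmf.fit(df["time"], df["event"])
    grid = kmf.survival_function_.index.to_numpy(dtype=float)
    surv = kmf.survival_function_["KM_estimate"].to_numpy(dtype=float)
    at_risk = kmf.event_table["at_risk"].reindex(grid).to_numpy(dtype=float)
    cens = np.sort(df.loc[df["event"] == 0, "time"].to_numpy(dtype=float))
    return KMCurve(grid, surv, at_risk, cens)


def km_rate_at(curve: KMCurve, t: float) -> float:
    """S(t) from the right-continuous step function."""
    if t < 0:
        raise ValueError("t must be >= 0")
    idx = np.searchsorted(curve.times, t, side="right") - 1
    return float(curve.survival[idx]) if idx >= 0 else 1.0


# ---------------------------------------------------------------------------
# Log-rank
# ---------------------------------------------------------------------------

@dataclass
class LogrankResult:
    statistic: float
    p_value: float
    df: int
    significant: bool


def logrank_test(df: pd.DataFrame, group_col: str = "group") -> LogrankResult:
    """k-sample log-rank test (chi-square with k-1 df)."""
    check_survival_frame(df)
    groups = df[group_col]
    k = groups.nunique()
    if k < 2 or df.groupby(group_col).size().min() == 0:
        raise ValueError("need >= 2 non-empty groups")
    if int(df["event"].sum()) == 0:
        raise ValueError("log-rank undefined: no events in any group")
    res = multivariate_logrank_test(df["time"], groups, df["event"])
    return LogrankResult(float(res.test_statistic), float(res.p_value),
                         k - 1, bool(res.p_value < ALPHA))


# ---------------------------------------------------------------------------
# Cox proportional hazards
# ---------------------------------------------------------------------------

@dataclass
class CoxFit:
    """Per-covariate estimates from a Cox proportional-hazards fit."""

    table: pd.DataFrame        # index = covariates; beta, se, hr, ci, p
    log_likelihood: float
    converged: bool
    n: int
    n_events: int

    def hr(self, name: str) -> float:
        return float(self.table.loc[name, "hr"])

    def summary(self) -> str:
        lines = [f"Cox PH fit: n={self.n}, events={self.n_events}, "
                 f"log PL={self.log_likelihood:.4f}, converged={self.converged}"]
        for name, row in self.table.iterrows():
            lines.append(
                f"  {name}: HR {row['hr']:.3f} "
                f"(95% CI {row['ci_lower']:.3f}-{row['ci_upper']:.3f}), "
                f"beta {row['beta']:.4f} +/- {row['se']:.4f}, p={row['p']:.3g}"
            )
        return "\n".join(lines)


def cox_fit(df: pd.DataFrame, covariates: list[str],
            ties: str = "breslow", penalizer: float = 0.0) -> CoxFit:
    """Uni- or multivariable Cox regression (Breslow ties by default).

    ``penalizer`` adds a small ridge penalty; useful when covariates are
    strongly correlated.
    """
    check_survival_frame(df)
    n_events = int(df["event"].sum())
    if n_events < len(covariates) + 1:
        raise ValueError(
            f"{n_events} events cannot support {len(covariates)} covariates"
        )
    for c in covariates:
        x = df[c].to_numpy(dtype=float)
        if not np.all(np.isfinite(x)):
            raise ValueError(f"covariate {c!r} has non-finite values")
        if np.ptp(x) == 0:
            raise ValueError(f"covariate {c!r} is constant")
    cph = CoxPHFitter(penalizer=penalizer)
    converged = True
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")
        cph.fit(df[["time", "event", *covariates]], duration_col="time",
                event_col="event")
        if any("converg" in str(w.message).lower()
               or "complete separation" in str(w.message).lower()
               for w in caught):
            converged = False
    s = cph.summary
    table = pd.DataFrame({
        "beta": s["coef"],
        "se": s["se(coef)"],
        "hr": np.exp(s["coef"]),
        "ci_lower": np.exp(s["coef"] - 1.96 * s["se(coef)"]),
        "ci_upper": np.exp(s["coef"] + 1.96 * s["se(coef)"]),
        "p": s["p"],
    })
    table.index.name = "covariate"
    return CoxFit(table, float(cph.log_likelihood_), converged,
                  len(df), n_events)


# ---------------------------------------------------------------------------
# Discrimination metrics
# ---------------------------------------------------------------------------

def concordance_index(df: pd.DataFrame, risks: np.ndarray) -> float:
    """Harrell's c-index; higher risk should mean shorter survival.

    Score ties in usable pairs count 0.5.  Raises if no pair is orderable
    under the censoring pattern.
    """
    check_survival_frame(df)
    risks = np.asarray(risks, dtype=float)
    if not np.all(np.isfinite(risks)):
        raise ValueError("risk scores must be finite")
    try:
        # lifelines scores "higher = longer survival", so negate
        return float(_lifelines_cindex(df["time"], -risks, df["event"]))
    except ZeroDivisionError as exc:
        raise ValueError("no usable (orderable) pairs under censoring") from exc


def time_dependent_auc(df: pd.DataFrame, risks: np.ndarray,
                       horizons=(12.0, 24.0, 60.0),
                       train_df: pd.DataFrame | None = None) -> dict[float, float]:
    """Cumulative-case / dynamic-control AUC at each horizon, IPCW-weighted.

    Censoring weights come from ``train_df`` when given (e.g. the training
    cohort), else from ``df`` itself.  Horizons past the last observed
    follow-up are returned as NaN.
    """
    from sksurv.metrics import cumulative_dynamic_auc
    from sksurv.util import Surv

    check_survival_frame(df)
    risks = np.asarray(risks, dtype=float)
    ref = df if train_df is None else check_survival_frame(train_df)
    y_train = Surv.from_arrays(ref["event"].astype(bool), ref["time"])
    y_test = Surv.from_arrays(df["event"].astype(bool), df["time"])
    out: dict[float, float] = {}
    tmax = float(df["time"].max())
    for h in horizons:
        if h >= tmax:
            out[float(h)] = float("nan")
            continue
        n_cases = int(((df["time"] <= h) & (df["event"] == 1)).sum())
        n_controls = int((df["time"] > h).sum())
        if n_cases == 0 or n_controls == 0:
            out[float(h)] = float("nan")
            continue
        auc, _ = cumulative_dynamic_auc(y_train, y_test, risks, [h])
        out[float(h)] = float(auc[0])
    return out


# ---------------------------------------------------------------------------
# Subgroup forest
# ---------------------------------------------------------------------------

def subgroup_forest(df: pd.DataFrame, risk_col: str,
                    subgroup_cols: list[str]) -> pd.DataFrame:
    """Univariable Cox fit of `risk_col` inside every subgroup level.

    Degenerate levels (<2 events, constant risk, or <2 patients) are kept in
    the table with NaN estimates and a reason in ``note``.
    """
    check_survival_frame(df)
    rows = []
    for col in subgroup_cols:
        for level in sorted(df[col].dropna().unique(), key=str):
            sub = df[df[col] == level]
            row = {"subgroup": col, "level": level, "n": len(sub),
                   "n_events": int(sub["event"].sum()),
                   "hr": np.nan, "ci_lower": np.nan, "ci_upper": np.nan,
                   "p": np.nan, "note": ""}
            if len(sub) < 2 or row["n_events"] < 2:
                row["note"] = "skipped: fewer than 2 events"
            elif np.ptp(sub[risk_col].to_numpy(dtype=float)) == 0:
                row["note"] = "skipped: constant risk in subgroup"
            else:
                fit = cox_fit(sub, [risk_col])
                r = fit.table.loc[risk_col]
                row.update(hr=r["hr"], ci_lower=r["ci_lower"],
                           ci_upper=r["ci_upper"], p=r["p"])
                if not fit.converged:
                    row["note"] = "did not converge"
            rows.append(row)
    return pd.DataFrame(rows)
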