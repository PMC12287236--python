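"""Hybrid Deep Score: SNN fusion of the three views and risk stratification.

The per-patient MM, CL and DG features are concatenated, standardized with
training-cohort statistics (frozen at fit time), passed through a small
self-normalizing network (SELU activations, alpha-dropout, LeCun-normal
init) and trained with the Cox partial-likelihood objective on DFS.  The
resulting scalar is the Hybrid Deep Score; patients are dichotomized at the
training-cohort median (strictly greater = high risk), and the score is
used to refine clinical staging strata.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._autograd import Adam, Tensor
from ._nn import Dense, alpha_dropout, cox_ph_loss
from .survstats import (KMCurve, check_survival_frame, concordance_index,
                        cox_fit, km_curve, logrank_test, time_dependent_auc)


@dataclass
class HDSConfig:
    hidden: tuple[int, ...] = (32, 16)
    dropout: float = 0.1           # alpha-dropout rate during training
    lr: float = 1e-2
    epochs: int = 80
    seed: int = 0


def snn_forward(layers: list[Dense], x: Tensor, dropout: float = 0.0,
                rng: np.random.Generator | None = None) -> Tensor:
    """SELU network forward; the last layer is the linear risk head."""
    h = x
    for layer in layers[:-1]:
        h = layer(h).selu()
        if dropout > 0.0 and rng is not None:
            h = alpha_dropout(h, dropout, rng)
    return layers[-1](h)


def build_snn(rng: np.random.Generator, n_in: int,
              hidden: tuple[int, ...]) -> list[Dense]:
    dims = [n_in, *hidden, 1]
    return [Dense(rng, dims[i], dims[i + 1]) for i in range(len(dims) - 1)]


class HDSModel:
    """SNN fusion model over a per-patient multi-view feature table."""

    def __init__(self, features: pd.DataFrame, survival: pd.DataFrame,
                 config: HDSConfig | None = None,
                 feature_cols: list[str] | None = None):
        self.config = config or HDSConfig()
        if feature_cols is None:
            feature_cols = [c for c in features.columns
                            if c.split("_")[0] in ("mm", "cl", "dg")]
        if not feature_cols:
            raise ValueError("no mm_/cl_/dg_ feature columns found")
        missing = [c for c in feature_cols if c not in features.columns]
        if missing:
            raise ValueError(f"feature columns missing: {missing}")
        self.feature_cols = list(feature_cols)
        self.features = features.reset_index(drop=True)
        self.survival = check_survival_frame(survival.reset_index(drop=True))
        if len(self.features) != len(self.survival):
            raise ValueError("features and survival must align row-wise")
        if int(self.survival["event"].sum()) < 2:
            raise ValueError("partial likelihood undefined: fewer than 2 events")

    def fit(self, verbose: bool = False) -> "HDSResults":
        cfg = self.config
        x = self.features[self.feature_cols].to_numpy(float)
        if not np.all(np.isfinite(x)):
            raise ValueError("non-finite feature values")
        mean = x.mean(axis=0)
        sd = x.std(axis=0)
        sd[sd == 0] = 1.0
        xz = (x - mean) / sd
        rng = np.random.default_rng(cfg.seed)
        layers = build_snn(rng, xz.shape[1], cfg.hidden)
        params = [p for layer in layers for p in layer.params]
        opt = Adam(params, lr=cfg.lr)
        times = self.survival["time"].to_numpy(float)
        events = self.survival["event"].to_numpy(int)
        xt = Tensor(xz)
        drop_rng = np.random.default_rng(cfg.seed + 1)
        history = []
        for epoch in range(cfg.epochs):
            risks = snn_forward(layers, xt, cfg.dropout, drop_rng).reshape(-1)
            loss = cox_ph_loss(risks, times, events)
            opt.zero_grad()
            loss.backward()
            opt.step()
            history.append(float(loss.data))
            if verbose:
                print(f"epoch {epoch}: loss {loss.data:.4f}")
        return HDSResults(cfg, list(self.feature_cols), mean, sd, layers,
                          history)


@dataclass
class HDSResults:
    """Fitted HDS network with frozen standardization statistics."""

    config: HDSConfig
    feature_cols: list[str]
    mean: np.ndarray
    sd: np.ndarray
    layers: list = field(repr=False)
    train_history: list[float] = field(default_factory=list)

    def score(self, features: pd.DataFrame) -> np.ndarray:
        """Hybrid Deep Score per patient (higher = worse prognosis)."""
        missing = [c for c in self.feature_cols if c not in features.columns]
        if missing:
            raise ValueError(f"feature columns missing at scoring: {missing}")
        x = features[self.feature_cols].to_numpy(float)
        xz = (x - self.mean) / self.sd
        return snn_forward(self.layers, Tensor(xz)).data.reshape(-1).copy()

    def summary(self) -> str:
        return (f"HDS SNN {tuple(self.config.hidden)} on "
                f"{len(self.feature_cols)} features; "
                f"{len(self.train_history)} epochs, "
                f"final Cox loss {self.train_history[-1]:.4f}")


# ---------------------------------------------------------------------------
# single-view Cox reduction (for ablations and independence tests)
# ---------------------------------------------------------------------------

def fit_view_cox(features: pd.DataFrame, survival: pd.DataFrame,
                 columns: list[str], penalizer: float = 0.1):
    """Reduce one feature view to its Cox linear predictor.

    Constant columns are dropped; a ridge penalty stabilizes the fit on
    correlated morphology columns.  Returns ``(score_fn, fitter)`` where
    ``score_fn(features_df) -> lp array``.
    """
    from lifelines import CoxPHFitter

    check_survival_frame(survival)
    x = features[columns].to_numpy(float)
    keep = [c for c, col in zip(columns, x.T) if np.ptp(col) > 0]
    if not keep:
        raise ValueError("all view columns constant")
    df = features[keep].reset_index(drop=True).copy()
    df["time"] = survival["time"].to_numpy(float)
    df["event"] = survival["event"].to_numpy(int)
    cph = CoxPHFitter(penalizer=penalizer)
    cph.fit(df, duration_col="time", event_col="event")
    beta = cph.params_.reindex(keep).to_numpy(float)
    means = df[keep].mean().to_numpy(float)

    def score_fn(f: pd.DataFrame) -> np.ndarray:
        return (f[keep].to_numpy(float) - means) @ beta

    return score_fn, cph


# ---------------------------------------------------------------------------
# stratification
# ---------------------------------------------------------------------------

@dataclass
class RiskStratification:
    """Median-cutoff dichotomization of a continuous risk score."""

    table: pd.DataFrame   # patient_id (if known), hds, group
    cutoff: float


def stratify_by_median(train_scores: np.ndarray, scores: np.ndarray,
                       patient_ids=None) -> RiskStratification:
    """Cutoff = median of the training scores; strictly greater = high."""
    train_scores = np.asarray(train_scores, dtype=float)
    if train_scores.size == 0:
        raise ValueError("train_scores must be non-empty")
    scores = np.asarray(scores, dtype=float)
    cutoff = float(np.median(train_scores))
    group = np.where(scores > cutoff, "high", "low")
    table = pd.DataFrame({"hds": scores, "group": group})
    if patient_ids is not None:
        table.insert(0, "patient_id", list(patient_ids))
    return RiskStratification(table, cutoff)


@dataclass
class RefinedStratification:
    strata: pd.Series                  # per-patient refined stratum label
    km: dict[str, KMCurve]             # per usable stratum
    pairwise: pd.DataFrame             # stratum pair, statistic, p
    excluded: list[str]                # strata with < 2 patients


def refine_staging(df: pd.DataFrame, stage_col: str, group_col: str,
                   low_risk_stages: tuple[str, ...]) -> RefinedStratification:
    """Split designated low-risk clinical stages by the HDS group.

    Patients in a low-risk stage get stratum "<stage>/<group>"; other stages
    keep their stage label.  Returns per-stratum KM curves and unadjusted
    pairwise log-rank p values (strata with < 2 patients are excluded from
    testing and listed).
    """
    check_survival_frame(df)
    stage = df[stage_col].astype(str)
    refined = np.where(stage.isin(low_risk_stages),
                       stage + "/" + df[group_col].astype(str), stage)
    strata = pd.Series(refined, index=df.index, name="refined_stratum")
    km, excluded = {}, []
    for s in sorted(strata.unique()):
        sub = df[strata == s]
        if len(sub) < 2:
            excluded.append(s)
            continue
        km[s] = km_curve(sub)
    usable = sorted(km)
    rows = []
    for i in range(len(usable)):
        for j in range(i + 1, len(usable)):
            a, b = usable[i], usable[j]
            pair = df[strata.isin([a, b])].copy()
            pair["_stratum"] = strata[strata.isin([a, b])]
            if int(pair["event"].sum()) == 0:
                rows.append({"stratum_a": a, "stratum_b": b,
                             "statistic": np.nan, "p": np.nan})
                continue
            res = logrank_test(pair, "_stratum")
            rows.append({"stratum_a": a, "stratum_b": b,
                         "statistic": res.statistic, "p": res.p_value})
    return RefinedStratification(strata, km, pd.DataFrame(rows), excluded)


# ---------------------------------------------------------------------------
# HDS + clinical staging combination
# ---------------------------------------------------------------------------

@dataclass
class CombinedStagingFit:
    cox: object                 # CoxFit over (hds, stage)
    linear_predictor: np.ndarray
    c_index: float
    auc: dict[float, float]
    collinearity_warning: bool


def combine_with_staging(hds: np.ndarray, stage_ordinal: np.ndarray,
                         survival: pd.DataFrame,
                         horizons=(12.0, 24.0, 60.0)) -> CombinedStagingFit:
    """Two-covariate Cox fit of the HDS and an ordinal stage code.

    The fitted linear combination is evaluated with the c-index and
    time-dependent AUCs.  Zero-variance stage raises; near-collinear inputs
    are flagged.
    """
    df = check_survival_frame(survival.reset_index(drop=True)).copy()
    hds = np.asarray(hds, dtype=float)
    stage = np.asarray(stage_ordinal, dtype=float)
    if np.ptp(stage) == 0:
        raise ValueError("stage has zero variance")
    x = np.column_stack([hds, stage])
    cond = np.linalg.cond(np.corrcoef(x, rowvar=False))
    warn = bool(cond > 1e6)
    df["hds"] = hds
    df["stage_ordinal"] = stage
    # near-collinear predictors are unidentifiable without a ridge penalty
    fit = cox_fit(df, ["hds", "stage_ordinal"],
                  penalizer=0.01 if warn else 0.0)
    beta = fit.table["beta"].to_numpy(float)
    lp = x @ beta
    return CombinedStagingFit(
        cox=fit,
        linear_predictor=lp,
        c_index=concordance_index(df, lp),
        auc=time_dependent_auc(df, lp, horizons),
        collinearity_warning=warn,
    )
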