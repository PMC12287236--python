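"""End-to-end orchestration on a synthetic cohort.

Runs every stage in order: cohort generation, event-stratified 8:2 split,
patch-classifier check, ATAT training, global-encoder training, the
three-view feature table, HDS fusion, median-cutoff stratification,
survival statistics (KM/log-rank/Cox/c-index/time-dependent AUC), view
ablation and independence, stage refinement, and the subgroup forest.
All outputs are written as deterministic text files derived only from the
seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .atat import ATATConfig, ATATModel, attention_heatmap
from .cohort import Cohort, CohortConfig, make_cohort, train_val_split, write_cohort
from .features import (GlobalEncoderConfig, GlobalEncoderModel,
                       multiview_table, view_columns, view_independence_tests)
from .hds import (HDSConfig, HDSModel, combine_with_staging, fit_view_cox,
                  refine_staging, stratify_by_median)
from .patchclf import PatchDataset, evaluate_patch_classifier, fit_patch_classifier
from .survstats import concordance_index, cox_fit, logrank_test, subgroup_forest, time_dependent_auc
from .tilemap import CATEGORIES, write_value_grid

KEY_CATEGORIES = ("Tumor", "Necrosis", "Lymphocyte")


@dataclass
class PipelineResult:
    cohort: Cohort
    train_idx: np.ndarray
    val_idx: np.ndarray
    features: pd.DataFrame
    scores: pd.DataFrame          # per-patient ATAT risk, HDS, group
    cutoff: float
    stats: dict                   # nested summary of every evaluation
    forest: pd.DataFrame
    atat_results: object
    encoder_results: object
    hds_results: object


def _patch_dataset(cohort: Cohort, idx: np.ndarray, per_slide: int,
                   rng: np.random.Generator) -> PatchDataset:
    xs, ys = [], []
    for i in idx:
        bag = cohort.bags[i]
        for k, cat in enumerate(CATEGORIES):
            if cat not in bag.instances:
                continue
            arr = bag.instances[cat]
            take = min(per_slide, len(arr))
            sel = rng.choice(len(arr), size=take, replace=False)
            xs.append(arr[sel])
            ys.append(np.full(take, k))
    return PatchDataset(np.vstack(xs), np.concatenate(ys))


def run_pipeline(config: CohortConfig | None = None, seed: int = 0,
                 atat_config: ATATConfig | None = None,
                 encoder_config: GlobalEncoderConfig | None = None,
                 hds_config: HDSConfig | None = None,
                 n_perm: int = 200, verbose: bool = False) -> PipelineResult:
    config = config or CohortConfig(seed=seed)
    if config.seed != seed:
        config = CohortConfig(**{**config.__dict__, "seed": seed})
    cohort = make_cohort(config)
    surv = cohort.survival_frame()
    train_idx, val_idx = train_val_split(cohort.patients, 0.8, seed=seed)
    tr = surv.iloc[train_idx].reset_index(drop=True)
    va = surv.iloc[val_idx].reset_index(drop=True)
    tr_bags = [cohort.bags[i] for i in train_idx]
    va_bags = [cohort.bags[i] for i in val_idx]

    # --- patch classification stage -------------------------------------
    rng = np.random.default_rng(seed + 17)
    clf = fit_patch_classifier(
        _patch_dataset(cohort, train_idx[:40], 8, rng), seed=seed)
    clf_report = evaluate_patch_classifier(
        clf, _patch_dataset(cohort, val_idx[:40], 8, rng))

    # --- ATAT ------------------------------------------------------------
    atat_config = atat_config or ATATConfig(seed=seed)
    atat = ATATModel(tr_bags, tr, atat_config).fit(verbose=verbose)
    atat_val_risk = atat.risks(va_bags)
    atat_all_risk = atat.risks(cohort.bags)

    # attention mass on the key categories, per validation slide
    masses = []
    for i in val_idx:
        att = atat.attention(cohort.bags[i])
        masses.append(sum(att.category_importance.get(c, 0.0)
                          for c in KEY_CATEGORIES))
    att_mass = pd.DataFrame({
        "patient_id": cohort.patients["patient_id"].iloc[val_idx].to_numpy(),
        "key_category_mass": masses,
    })

    # --- global encoder + feature table ----------------------------------
    encoder_config = encoder_config or GlobalEncoderConfig(seed=seed)
    encoder = GlobalEncoderModel(tr_bags, tr, encoder_config).fit(verbose=verbose)
    features = multiview_table(cohort.maps, cohort.bags, encoder,
                               n_perm=n_perm, seed=seed)
    f_tr = features.iloc[train_idx].reset_index(drop=True)
    f_va = features.iloc[val_idx].reset_index(drop=True)

    # --- HDS fusion -------------------------------------------------------
    hds_config = hds_config or HDSConfig(seed=seed)
    hds = HDSModel(f_tr, tr, hds_config).fit(verbose=verbose)
    hds_train = hds.score(f_tr)
    hds_val = hds.score(f_va)
    hds_all = hds.score(features)

    strat = stratify_by_median(hds_train, hds_all,
                               cohort.patients["patient_id"])
    scores = strat.table.copy()
    scores["atat_risk"] = atat_all_risk
    scores["split"] = "train"
    scores.loc[val_idx, "split"] = "val"

    # --- evaluation -------------------------------------------------------
    view_cidx: dict[str, float] = {}
    view_scores_val: dict[str, np.ndarray] = {}
    for view in ("mm", "cl", "dg"):
        fn, _ = fit_view_cox(f_tr, tr, view_columns(features, view))
        view_scores_val[view] = fn(f_va)
        view_cidx[view] = concordance_index(va, view_scores_val[view])
    independence = view_independence_tests(view_scores_val)

    df_all = surv.copy()
    df_all["group"] = scores["group"].to_numpy()
    df_all["hds"] = hds_all
    lr = logrank_test(df_all, "group")

    refined = refine_staging(df_all.assign(stage=cohort.patients["stage"]),
                             "stage", "group", low_risk_stages=("early",))
    within = refined.pairwise
    within_stage_p = within.loc[
        (within["stratum_a"] == "early/high") &
        (within["stratum_b"] == "early/low"), "p"]

    stage_ord = (cohort.patients["stage"] == "late").astype(int).to_numpy()
    combined = combine_with_staging(hds_all, stage_ord, surv)

    forest = subgroup_forest(df_all.assign(sex=cohort.patients["sex"],
                                           age_group=cohort.patients["age_group"]),
                             "hds", ["sex", "age_group"])

    # permuted-label negative control: permute (time, event) cohort-wide
    # before the split, retrain, evaluate against the permuted val labels
    perm_rng = np.random.default_rng(seed + 23)
    order = perm_rng.permutation(len(surv))
    surv_perm = surv.copy()
    surv_perm[["time", "event"]] = surv[["time", "event"]].to_numpy()[order]
    tr_perm = surv_perm.iloc[train_idx].reset_index(drop=True)
    va_perm = surv_perm.iloc[val_idx].reset_index(drop=True)
    hds_perm = HDSModel(f_tr, tr_perm, hds_config).fit()
    perm_cidx = concordance_index(va_perm, hds_perm.score(f_va))

    stats = {
        "n_patients": int(config.n_patients),
        "n_train": int(len(train_idx)),
        "n_val": int(len(val_idx)),
        "event_fraction": float(surv["event"].mean()),
        "patch_classifier": {
            "macro_auc": clf_report.macro_auc,
            "per_class_auc": clf_report.per_class_auc,
        },
        "c_index": {
            "atat_val": concordance_index(va, atat_val_risk),
            "hds_val": concordance_index(va, hds_val),
            "hds_train": concordance_index(tr, hds_train),
            "views_val": view_cidx,
            "hds_permuted_labels_val": perm_cidx,
            "combined_staging": combined.c_index,
        },
        "attention": {
            "mean_key_category_mass_val": float(att_mass["key_category_mass"].mean()),
        },
        "logrank_median_split": {"statistic": lr.statistic, "p": lr.p_value},
        "refined_staging": {
            "within_low_stage_p": (float(within_stage_p.iloc[0])
                                   if len(within_stage_p) else None),
            "excluded_strata": refined.excluded,
        },
        "time_dependent_auc_val": time_dependent_auc(va, hds_val, train_df=tr),
        "view_independence": independence.drop(columns="note").to_dict("records"),
        "cutoff": strat.cutoff,
    }
    return PipelineResult(cohort, train_idx, val_idx, features, scores,
                          strat.cutoff, stats, forest, atat, encoder, hds)


def write_pipeline_outputs(result: PipelineResult, outdir) -> None:
    """Write every stage output as deterministic text files."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_cohort(result.cohort, outdir)
    result.features.to_csv(outdir / "features.csv", index=False)
    result.scores.to_csv(outdir / "scores.csv", index=False)
    result.forest.to_csv(outdir / "forest.csv", index=False)
    with open(outdir / "stats.json", "w") as fh:
        json.dump(result.stats, fh, indent=2, sort_keys=True, allow_nan=True,
                  default=float)
    # one attention heatmap for the first validation slide, as a 4x4-block grid
    i = int(result.val_idx[0])
    att = result.atat_results.attention(result.cohort.bags[i])
    grid = attention_heatmap(att, result.cohort.maps[i], block=4)
    write_value_grid(grid, outdir / f"heatmap_{grid.slide_id}.tsv")
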