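"""Seeded synthetic cohorts with known ground truth.

The generator emulates the three data layers the real study uses:

1. tissue-label grids with planted spatial structure — high-risk-style
   slides carry tumor blobs with necrotic cores and lymphocyte rims (the
   morphology attention models flag in poor-prognosis patients), low-risk
   slides carry bland tumor blobs without them;
2. class-conditional patch embeddings (centroid per tissue category plus
   isotropic Gaussian noise), standing in for a pretrained CNN extractor;
3. survival outcomes from a proportional-hazards model whose linear
   predictor loads on the TRUE morphology/co-localization values of the
   generated maps, with independent exponential censoring.

Everything is deterministic given the config seed; the planted truth is
stored alongside the cohort for recovery tests and never read by any
model-fitting code.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .bags import SlideBag, load_bag, save_bag
from .features import colocalization_scores, morphological_features
from .tilemap import (BLANK, CATEGORIES, TissueMap, read_tissue_map,
                      write_tissue_map)

#: covariate names the survival model loads on, and their default weights
DEFAULT_TRUE_BETAS: dict[str, float] = {
    "cl_J_necrosis_tumor": 1.5,
    "cl_J_lymphocyte_tumor": 1.0,
    "mm_necrosis_area_fraction": 0.5,
}


def default_class_means(dim: int, separation: float = 3.0) -> dict[str, np.ndarray]:
    """One centroid per tissue category: `separation` on its own axis."""
    if dim < len(CATEGORIES):
        raise ValueError(f"feature dim must be >= {len(CATEGORIES)}")
    means = {}
    for i, cat in enumerate(CATEGORIES):
        v = np.zeros(dim)
        v[i] = separation
        means[cat] = v
    return means


@dataclass
class CohortConfig:
    n_patients: int = 400
    grid_shape: tuple[int, int] = (16, 16)
    risk_mix: float = 0.5                 # fraction of high-risk-style slides
    class_feature_dim: int = 16
    class_means: dict[str, np.ndarray] | None = None
    feature_noise_sd: float = 1.0
    true_betas: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_TRUE_BETAS))
    baseline_hazard: float = 0.02          # events per month at lp = 0
    censoring_rate: float = 0.01           # independent exponential censoring
    patch_size: int = 150
    seed: int = 0

    def __post_init__(self):
        if not 0.0 <= self.risk_mix <= 1.0:
            raise ValueError("risk_mix must lie in [0, 1]")
        if self.baseline_hazard <= 0 or self.censoring_rate <= 0:
            raise ValueError("hazard rates must be > 0")
        if self.class_means is None:
            self.class_means = default_class_means(self.class_feature_dim)


# ---------------------------------------------------------------------------
# tissue maps with planted structure
# ---------------------------------------------------------------------------

def _as_rng(seed) -> np.random.Generator:
    return seed if isinstance(seed, np.random.Generator) \
        else np.random.default_rng(seed)


def _grow_blob(rng, shape, target: int, allowed: np.ndarray) -> np.ndarray:
    """Connected random-walk blob of ~`target` cells inside `allowed`."""
    nr, nc = shape
    free = np.argwhere(allowed)
    start = tuple(free[rng.integers(len(free))])
    blob = {start}
    pos = start
    steps = 0
    while len(blob) < target and steps < 60 * target:
        dr, dc = ((-1, 0), (1, 0), (0, -1), (0, 1))[rng.integers(4)]
        cand = (pos[0] + dr, pos[1] + dc)
        if 0 <= cand[0] < nr and 0 <= cand[1] < nc and allowed[cand]:
            pos = cand
            blob.add(pos)
        steps += 1
    # 4-neighbor dilation fallback so the target size is always reached
    while len(blob) < target:
        frontier = []
        for (r, c) in blob:
            for dr, dc in ((-1, 0), (1, 0), (0, -1), (0, 1)):
                cand = (r + dr, c + dc)
                if (0 <= cand[0] < nr and 0 <= cand[1] < nc
                        and allowed[cand] and cand not in blob):
                    frontier.append(cand)
        if not frontier:
            break
        blob.add(frontier[rng.integers(len(frontier))])
    mask = np.zeros(shape, dtype=bool)
    for cell in blob:
        mask[cell] = True
    return mask


def simulate_tissue_map(grid_shape: tuple[int, int], style: str, seed,
                        slide_id: str = "slide",
                        patch_size: int = 150) -> TissueMap:
    """Generate one tissue-label grid in the given risk style.

    ``high_risk``: tumor blobs with necrotic cores and a lymphocyte band on
    the blob perimeter.  ``low_risk``: tumor blobs only, no necrosis and at
    most 1% lymphocyte cells.  A small Blank corner mimics slide background.
    """
    if style not in ("high_risk", "low_risk"):
        raise ValueError(f"style must be high_risk or low_risk, got {style!r}")
    nr, nc = grid_shape
    if nr < 8 or nc < 8:
        raise ValueError(f"grid {nr}x{nc} too small to grow a tumor blob "
                         "(need at least 8x8)")
    rng = _as_rng(seed)
    labels = np.full(grid_shape, "", dtype=object)

    # blank corner wedge (slide background), at most ~5% of cells
    blank = np.zeros(grid_shape, dtype=bool)
    wedge = int(rng.integers(0, max(nr, nc) // 3 + 1))
    for r in range(min(wedge, nr)):
        blank[r, :max(0, wedge - r)] = True
    labels[blank] = BLANK
    tissue = ~blank
    n_tissue = int(tissue.sum())

    # tumor blobs
    frac = rng.uniform(0.25, 0.40) if style == "high_risk" else rng.uniform(0.15, 0.30)
    n_blobs = int(rng.integers(1, 4))
    tumor = np.zeros(grid_shape, dtype=bool)
    per_blob = max(4, int(frac * n_tissue) // n_blobs)
    for _ in range(n_blobs):
        tumor |= _grow_blob(rng, grid_shape, per_blob, tissue & ~tumor)
    labels[tumor] = "Tumor"

    necrosis = np.zeros(grid_shape, dtype=bool)
    lymph = np.zeros(grid_shape, dtype=bool)
    if style == "high_risk":
        # necrotic core inside the tumor mass
        core_target = max(2, int(rng.uniform(0.20, 0.40) * int(tumor.sum())))
        necrosis = _grow_blob(rng, grid_shape, core_target, tumor)
        labels[necrosis] = "Necrosis"
        # lymphocyte band on the tumor perimeter (outside the blob)
        rim = np.zeros(grid_shape, dtype=bool)
        t = tumor
        rim[1:, :] |= t[:-1, :]
        rim[:-1, :] |= t[1:, :]
        rim[:, 1:] |= t[:, :-1]
        rim[:, :-1] |= t[:, 1:]
        rim &= tissue & ~tumor
        for cell in np.argwhere(rim):
            if rng.random() < 0.8:
                lymph[tuple(cell)] = True
        labels[lymph] = "Lymphocyte"
    else:
        # at most 1% scattered lymphocytes, no necrosis
        budget = int(rng.integers(0, n_tissue // 100 + 1))
        free = np.argwhere(tissue & ~tumor)
        if budget and len(free):
            for i in rng.choice(len(free), size=min(budget, len(free)),
                                replace=False):
                lymph[tuple(free[i])] = True
            labels[lymph] = "Lymphocyte"

    # background: fibrosis / normal liver / other
    bg = tissue & ~(tumor | necrosis | lymph)
    bg_cells = np.argwhere(bg)
    choices = rng.choice(["Fibrosis", "NormalLiver", "Other"],
                         size=len(bg_cells), p=[0.35, 0.45, 0.20])
    for cell, lab in zip(bg_cells, choices):
        labels[tuple(cell)] = lab
    return TissueMap(slide_id, labels, patch_size)


# ---------------------------------------------------------------------------
# class-conditional patch embeddings
# ---------------------------------------------------------------------------

def simulate_patch_features(tmap: TissueMap, config: CohortConfig,
                            seed) -> SlideBag:
    """centroid(label) + isotropic Gaussian noise per non-Blank patch."""
    rng = _as_rng(seed)
    present = sorted(set(tmap.labels.ravel()) - {BLANK})
    missing = [c for c in present if c not in config.class_means]
    if missing:
        raise ValueError(f"no class centroid for categories {missing}")
    instances: dict[str, np.ndarray] = {}
    cells: dict[str, np.ndarray] = {}
    for cat in CATEGORIES:
        pos = np.argwhere(tmap.labels == cat)
        if len(pos) == 0:
            continue
        noise = rng.normal(0.0, config.feature_noise_sd,
                           size=(len(pos), config.class_feature_dim))
        instances[cat] = config.class_means[cat][None, :] + noise
        cells[cat] = pos
    return SlideBag(tmap.slide_id, instances, cells)


# ---------------------------------------------------------------------------
# survival outcomes
# ---------------------------------------------------------------------------

def simulate_survival(covariates: np.ndarray, true_betas: np.ndarray,
                      baseline_hazard: float, censoring_rate: float,
                      seed) -> pd.DataFrame:
    """Exponential PH event times with independent exponential censoring.

    T ~ Exp(rate = baseline_hazard * exp(beta' x)), C ~ Exp(censoring_rate);
    observed time = min(T, C), event = 1[T <= C].
    """
    rng = _as_rng(seed)
    x = np.atleast_2d(np.asarray(covariates, dtype=float))
    lp = x @ np.asarray(true_betas, dtype=float)
    if not np.all(np.isfinite(lp)):
        raise ValueError("non-finite linear predictor")
    t_event = rng.exponential(1.0 / (baseline_hazard * np.exp(lp)))
    t_cens = rng.exponential(1.0 / censoring_rate, size=len(lp))
    return pd.DataFrame({
        "time": np.minimum(t_event, t_cens),
        "event": (t_event <= t_cens).astype(int),
        "linear_predictor": lp,
    })


# ---------------------------------------------------------------------------
# full cohort
# ---------------------------------------------------------------------------

@dataclass
class Cohort:
    config: CohortConfig
    maps: list[TissueMap]
    bags: list[SlideBag]
    patients: pd.DataFrame   # patient_id, slide_id, time_months, event, stage, ...
    truth: pd.DataFrame      # planted covariates + true lp + style; tests only

    def survival_frame(self) -> pd.DataFrame:
        df = self.patients.rename(columns={"time_months": "time"})
        return df


def make_cohort(config: CohortConfig | None = None) -> Cohort:
    config = config or CohortConfig()
    if config.n_patients < 10:
        raise ValueError("need at least 10 patients")
    rng = np.random.default_rng(config.seed)
    n = config.n_patients
    n_high = int(round(config.risk_mix * n))
    styles = np.array(["high_risk"] * n_high + ["low_risk"] * (n - n_high))
    rng.shuffle(styles)

    maps, bags, planted = [], [], []
    for i in range(n):
        slide_id = f"S{i:04d}"
        tmap = simulate_tissue_map(config.grid_shape, styles[i], rng,
                                   slide_id, config.patch_size)
        maps.append(tmap)
        bags.append(simulate_patch_features(tmap, config, rng))
        mm = morphological_features(tmap)
        # planted co-localization uses the deterministic J scores only
        cl = colocalization_scores(tmap, n_perm=10, seed=0)
        planted.append({name: (mm.get(name) if name.startswith("mm_")
                               else cl.get(name))
                        for name in config.true_betas})

    truth = pd.DataFrame(planted)
    z = (truth - truth.mean()) / truth.std(ddof=0).replace(0.0, 1.0)
    betas = np.array([config.true_betas[c] for c in truth.columns])
    surv = simulate_survival(z.to_numpy(), betas, config.baseline_hazard,
                             config.censoring_rate, rng)

    patients = pd.DataFrame({
        "patient_id": [f"P{i:04d}" for i in range(n)],
        "slide_id": [m.slide_id for m in maps],
        "time_months": surv["time"],
        "event": surv["event"],
        # stage and subgroups assigned independently of the planted signal
        "stage": rng.choice(["early", "late"], size=n, p=[0.6, 0.4]),
        "sex": rng.choice(["F", "M"], size=n),
        "age_group": rng.choice(["<60", ">=60"], size=n),
    })
    truth = truth.assign(
        patient_id=patients["patient_id"],
        style=styles,
        true_linear_predictor=surv["linear_predictor"],
        true_risk_group=np.where(
            surv["linear_predictor"] > np.median(surv["linear_predictor"]),
            "high", "low"),
    )
    return Cohort(config, maps, bags, patients, truth)


def train_val_split(patients: pd.DataFrame, ratio: float = 0.8,
                    seed: int = 0) -> tuple[np.ndarray, np.ndarray]:
    """Event-stratified train/validation index split (default 8:2)."""
    if not 0.0 < ratio < 1.0:
        raise ValueError("ratio must lie in (0, 1)")
    rng = np.random.default_rng(seed)
    n = len(patients)
    n_train = int(round(ratio * n))
    idx_by_event = {e: rng.permutation(np.flatnonzero(
        patients["event"].to_numpy() == e)) for e in (0, 1)}
    takes = {e: int(round(ratio * len(v))) for e, v in idx_by_event.items()}
    # largest-remainder adjustment so totals match exactly
    while sum(takes.values()) > n_train:
        e = max(takes, key=lambda k: takes[k])
        takes[e] -= 1
    while sum(takes.values()) < n_train:
        e = min(takes, key=lambda k: takes[k] - len(idx_by_event[k]))
        takes[e] += 1
    train = np.sort(np.concatenate(
        [idx_by_event[e][:takes[e]] for e in (0, 1)]))
    val = np.sort(np.setdiff1d(np.arange(n), train))
    return train, val


# ---------------------------------------------------------------------------
# on-disk layout
# ---------------------------------------------------------------------------

def write_cohort(cohort: Cohort, outdir) -> None:
    outdir = Path(outdir)
    (outdir / "maps").mkdir(parents=True, exist_ok=True)
    (outdir / "bags").mkdir(parents=True, exist_ok=True)
    for tmap in cohort.maps:
        write_tissue_map(tmap, outdir / "maps" / f"{tmap.slide_id}.tsv")
    for bag in cohort.bags:
        save_bag(bag, outdir / "bags" / f"{bag.slide_id}.npz")
    cohort.patients.to_csv(outdir / "patients.csv", index=False)
    cohort.truth.to_csv(outdir / "truth.csv", index=False)


def load_cohort(indir, config: CohortConfig | None = None) -> Cohort:
    indir = Path(indir)
    patients = pd.read_csv(indir / "patients.csv")
    truth_path = indir / "truth.csv"
    truth = pd.read_csv(truth_path) if truth_path.exists() else pd.DataFrame()
    maps = [read_tissue_map(indir / "maps" / f"{sid}.tsv")
            for sid in patients["slide_id"]]
    bags = [load_bag(indir / "bags" / f"{sid}.npz")
            for sid in patients["slide_id"]]
    return Cohort(config or CohortConfig(), maps, bags, patients, truth)
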