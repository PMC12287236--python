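"""The three feature views computed per slide.

* MM — microscopic morphological features of Tumor, Necrosis and Lymphocyte
  regions on the tissue-label grid (area fraction, 4-connected component
  count, largest-component fraction, boundary-to-area ratio).
* CL — co-localization scores: junction statistics between lymphocytes,
  necrosis and tumor (adjacency J scores, triple-junction density, and
  permutation-null enrichment z per pair).
* DG — deep global features: the class-token embedding of a small
  transformer MIL encoder trained with a Cox survival objective.

MM and CL are deterministic functions of the label map; DG is learned.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage, stats

from ._autograd import Adam, Tensor, concat, softmax
from ._nn import cox_ph_loss, lecun_normal
from .bags import SlideBag
from .tilemap import BLANK, TissueMap

MM_CLASSES = ("Tumor", "Necrosis", "Lymphocyte")
CL_PAIRS = (("Necrosis", "Tumor"), ("Lymphocyte", "Tumor"),
            ("Necrosis", "Lymphocyte"))


# ---------------------------------------------------------------------------
# MM: morphology on the label grid
# ---------------------------------------------------------------------------

def morphological_features(tmap: TissueMap) -> dict[str, float]:
    """Area, connectedness and boundary statistics for the three classes.

    Edges to Blank cells are not counted as boundary (Blank is excluded from
    every feature computation); absent classes contribute all-zero features.
    """
    non_blank = tmap.non_blank
    n_tissue = int(non_blank.sum())
    if n_tissue == 0:
        raise ValueError("tissue map is entirely Blank")
    out: dict[str, float] = {}
    for cls in MM_CLASSES:
        mask = tmap.mask(cls)
        n = int(mask.sum())
        prefix = f"mm_{cls.lower()}"
        if n == 0:
            out[f"{prefix}_area_fraction"] = 0.0
            out[f"{prefix}_component_count"] = 0.0
            out[f"{prefix}_largest_component_fraction"] = 0.0
            out[f"{prefix}_boundary_to_area"] = 0.0
            continue
        labeled, n_comp = ndimage.label(mask)  # default structure = 4-conn
        sizes = ndimage.sum_labels(mask, labeled, range(1, n_comp + 1))
        boundary = 0
        other = non_blank & ~mask
        boundary += int(np.sum(mask[:-1, :] & other[1:, :]))
        boundary += int(np.sum(mask[1:, :] & other[:-1, :]))
        boundary += int(np.sum(mask[:, :-1] & other[:, 1:]))
        boundary += int(np.sum(mask[:, 1:] & other[:, :-1]))
        out[f"{prefix}_area_fraction"] = n / n_tissue
        out[f"{prefix}_component_count"] = float(n_comp)
        out[f"{prefix}_largest_component_fraction"] = float(sizes.max()) / n
        out[f"{prefix}_boundary_to_area"] = boundary / n
    return out


# ---------------------------------------------------------------------------
# CL: co-localization / junction statistics
# ---------------------------------------------------------------------------

def _adjacency_edges(labels: np.ndarray) -> np.ndarray:
    """Unordered 4-neighbor label pairs among non-Blank cells, (m, 2)."""
    pairs = []
    a, b = labels[:-1, :], labels[1:, :]
    keep = (a != BLANK) & (b != BLANK)
    pairs.append(np.stack([a[keep], b[keep]], axis=1))
    a, b = labels[:, :-1], labels[:, 1:]
    keep = (a != BLANK) & (b != BLANK)
    pairs.append(np.stack([a[keep], b[keep]], axis=1))
    return np.concatenate(pairs, axis=0) if pairs else np.empty((0, 2), object)


def _j_score(edges: np.ndarray, a: str, b: str) -> float:
    """J(A->B): A-B adjacencies over all adjacencies incident to an A cell."""
    if len(edges) == 0:
        return 0.0
    inc_a = (edges[:, 0] == a) | (edges[:, 1] == a)
    denom = int(inc_a.sum())
    if denom == 0:
        return 0.0
    cross = ((edges[:, 0] == a) & (edges[:, 1] == b)) | \
            ((edges[:, 0] == b) & (edges[:, 1] == a))
    return float(cross.sum()) / denom


def triple_junction_density(tmap: TissueMap) -> float:
    """Fraction of 2x2 windows containing Tumor, Necrosis and Lymphocyte."""
    lab = tmap.labels
    nr, nc = lab.shape
    if nr < 2 or nc < 2:
        return 0.0
    windows = np.stack([lab[:-1, :-1], lab[:-1, 1:], lab[1:, :-1], lab[1:, 1:]])
    present = [np.any(windows == cls, axis=0) for cls in MM_CLASSES]
    return float(np.mean(present[0] & present[1] & present[2]))


def colocalization_scores(tmap: TissueMap, n_perm: int = 200,
                          seed: int = 0) -> dict[str, float]:
    """Junction J scores, triple-junction density, and enrichment z values.

    The z for each pair compares the observed J against `n_perm` random
    relabelings of the non-Blank cells (spatial structure destroyed, class
    abundances kept).
    """
    if n_perm < 10:
        raise ValueError("n_perm must be >= 10 for a usable null")
    non_blank = tmap.non_blank
    if int(non_blank.sum()) < 2:
        raise ValueError("need at least 2 non-Blank cells")
    edges = _adjacency_edges(tmap.labels)
    out: dict[str, float] = {}
    for a, b in CL_PAIRS:
        out[f"cl_J_{a.lower()}_{b.lower()}"] = _j_score(edges, a, b)
    out["cl_triple_junction_density"] = triple_junction_density(tmap)

    rng = np.random.default_rng(seed)
    tissue_labels = tmap.labels[non_blank]
    null = {pair: np.empty(n_perm) for pair in CL_PAIRS}
    shuffled = tmap.labels.copy()
    for i in range(n_perm):
        perm = rng.permutation(len(tissue_labels))
        shuffled[non_blank] = tissue_labels[perm]
        perm_edges = _adjacency_edges(shuffled)
        for pair in CL_PAIRS:
            null[pair][i] = _j_score(perm_edges, *pair)
    for a, b in CL_PAIRS:
        obs = out[f"cl_J_{a.lower()}_{b.lower()}"]
        mu, sd = null[(a, b)].mean(), null[(a, b)].std(ddof=1)
        out[f"cl_z_{a.lower()}_{b.lower()}"] = (obs - mu) / sd if sd > 0 else 0.0
    return out


# ---------------------------------------------------------------------------
# DG: transformer MIL global encoder
# ---------------------------------------------------------------------------

@dataclass
class GlobalEncoderConfig:
    embed_dim: int = 16          # model width = dg feature width
    max_tokens: int = 128        # seeded per-slide token cap
    lr: float = 5e-3
    epochs: int = 40
    seed: int = 0

    def __post_init__(self):
        if self.embed_dim < 1 or self.max_tokens < 1:
            raise ValueError("dims must be >= 1")


def _slide_rng(seed: int, slide_id: str) -> np.random.Generator:
    return np.random.default_rng((seed, zlib.crc32(slide_id.encode())))


def _canonical_tokens(bag: SlideBag, max_tokens: int, seed: int) -> np.ndarray:
    """Unique instance rows, lexicographically sorted, then seeded subsample.

    The unique+sort canonicalization makes the token set invariant to both
    instance order and instance duplication.
    """
    x = np.unique(bag.all_instances(), axis=0)
    if x.shape[0] > max_tokens:
        idx = _slide_rng(seed, bag.slide_id).choice(
            x.shape[0], size=max_tokens, replace=False)
        x = x[np.sort(idx)]
    return x


class GlobalEncoderModel:
    """Transformer-style MIL encoder trained on a Cox survival objective.

    A learned class token attends over (up to ``max_tokens``) patch
    embeddings through one self-attention layer; its output embedding is the
    slide's deep-global (DG) feature vector, and a linear head on it is the
    training-time risk.
    """

    def __init__(self, bags: list[SlideBag], survival: pd.DataFrame,
                 config: GlobalEncoderConfig | None = None):
        self.config = config or GlobalEncoderConfig()
        self.bags = list(bags)
        self.survival = survival.reset_index(drop=True)
        if len(self.bags) != len(self.survival):
            raise ValueError("one bag per survival record required")
        if int(self.survival["event"].sum()) == 0:
            raise ValueError("partial likelihood undefined: no events")

    def fit(self, verbose: bool = False) -> "GlobalEncoderResults":
        cfg = self.config
        rng = np.random.default_rng(cfg.seed)
        d = self.bags[0].dim
        m = cfg.embed_dim
        params = {
            "W_in": Tensor(lecun_normal(rng, d, (d, m)), requires_grad=True),
            "cls": Tensor(lecun_normal(rng, m, (1, m)), requires_grad=True),
            "Wq": Tensor(lecun_normal(rng, m, (m, m)), requires_grad=True),
            "Wk": Tensor(lecun_normal(rng, m, (m, m)), requires_grad=True),
            "Wv": Tensor(lecun_normal(rng, m, (m, m)), requires_grad=True),
            "w_out": Tensor(lecun_normal(rng, m, (m,)), requires_grad=True),
            "b_out": Tensor(np.zeros(()), requires_grad=True),
        }
        token_sets = [_canonical_tokens(b, cfg.max_tokens, cfg.seed)
                      for b in self.bags]
        times = self.survival["time"].to_numpy(float)
        events = self.survival["event"].to_numpy(int)
        opt = Adam(list(params.values()), lr=cfg.lr)
        history = []
        for epoch in range(cfg.epochs):
            risks = concat([_encoder_forward(params, x)[1].reshape(1)
                            for x in token_sets])
            loss = cox_ph_loss(risks, times, events)
            opt.zero_grad()
            loss.backward()
            opt.step()
            history.append(float(loss.data))
            if verbose:
                print(f"epoch {epoch}: loss {loss.data:.4f}")
        return GlobalEncoderResults(self.config, params, history)


def _encoder_forward(params: dict, tokens_np: np.ndarray):
    """Returns (class-token embedding, risk scalar) for one token set."""
    m = params["W_in"].shape[1]
    x = Tensor(tokens_np) @ params["W_in"]
    t = concat([params["cls"], x], axis=0)
    q = t @ params["Wq"]
    k = t @ params["Wk"]
    v = t @ params["Wv"]
    att = softmax(q @ k.T * (1.0 / np.sqrt(m)), axis=-1)
    h = att @ v + t  # residual
    dg = h[0]
    risk = dg @ params["w_out"] + params["b_out"]
    return dg, risk


@dataclass
class GlobalEncoderResults:
    config: GlobalEncoderConfig
    params: dict = field(repr=False)
    train_history: list[float] = field(default_factory=list)

    def embed(self, bag: SlideBag) -> np.ndarray:
        """Deep-global (DG) feature vector of one slide."""
        tokens = _canonical_tokens(bag, self.config.max_tokens, self.config.seed)
        dg, _ = _encoder_forward(self.params, tokens)
        return dg.data.copy()

    def risk(self, bag: SlideBag) -> float:
        tokens = _canonical_tokens(bag, self.config.max_tokens, self.config.seed)
        _, r = _encoder_forward(self.params, tokens)
        return float(r.data)

    def risks(self, bags: list[SlideBag]) -> np.ndarray:
        return np.array([self.risk(b) for b in bags])

    def summary(self) -> str:
        return (f"GlobalEncoder(dim={self.config.embed_dim}, "
                f"tokens<={self.config.max_tokens}); "
                f"{len(self.train_history)} epochs, "
                f"final Cox loss {self.train_history[-1]:.4f}")


def extract_global_features(results: GlobalEncoderResults,
                            bag: SlideBag) -> np.ndarray:
    return results.embed(bag)


# ---------------------------------------------------------------------------
# assembling the per-patient feature table
# ---------------------------------------------------------------------------

def multiview_table(maps: list[TissueMap], bags: list[SlideBag],
                    encoder: GlobalEncoderResults, n_perm: int = 200,
                    seed: int = 0) -> pd.DataFrame:
    """One row per slide with namespaced mm_*, cl_* and dg_* columns."""
    rows = []
    for tmap, bag in zip(maps, bags):
        if tmap.slide_id != bag.slide_id:
            raise ValueError("maps and bags must align by slide_id")
        row: dict = {"slide_id": tmap.slide_id}
        row.update(morphological_features(tmap))
        row.update(colocalization_scores(tmap, n_perm=n_perm, seed=seed))
        dg = encoder.embed(bag)
        row.update({f"dg_{i}": v for i, v in enumerate(dg)})
        rows.append(row)
    return pd.DataFrame(rows)


def view_columns(df: pd.DataFrame, view: str) -> list[str]:
    cols = [c for c in df.columns if c.startswith(f"{view}_")]
    if not cols:
        raise ValueError(f"no columns for view {view!r}")
    return cols


# ---------------------------------------------------------------------------
# view independence
# ---------------------------------------------------------------------------

def view_independence_tests(view_scores: dict[str, np.ndarray]) -> pd.DataFrame:
    """Pairwise chi-square tests between median-dichotomized view risks.

    Each view's scalar risk is dichotomized at its own median; a 2x2
    chi-square (Yates-uncorrected) is computed per pair.  p > 0.05 is
    reported as consistent with independence.
    """
    names = list(view_scores)
    groups = {}
    for name in names:
        s = np.asarray(view_scores[name], dtype=float)
        groups[name] = (s > np.median(s)).astype(int)
    rows = []
    for i in range(len(names)):
        for j in range(i + 1, len(names)):
            a, b = groups[names[i]], groups[names[j]]
            table = np.array([[np.sum((a == 0) & (b == 0)),
                               np.sum((a == 0) & (b == 1))],
                              [np.sum((a == 1) & (b == 0)),
                               np.sum((a == 1) & (b == 1))]])
            row = {"view_a": names[i], "view_b": names[j],
                   "chi2": np.nan, "p": np.nan, "independent": None,
                   "note": ""}
            if np.any(table.sum(axis=0) == 0) or np.any(table.sum(axis=1) == 0):
                row["note"] = "degenerate margin: test undefined"
            else:
                chi2, p, _, _ = stats.chi2_contingency(table, correction=False)
                row.update(chi2=float(chi2), p=float(p),
                           independent=bool(p > 0.05))
            rows.append(row)
    return pd.DataFrame(rows)
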