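"""Attention Activator: category-grouped attention MIL for survival.

Each slide is a bag of patch embeddings grouped by tissue category.  The
model pools within each category with gated attention (intra-class
variability), relates the pooled category embeddings with one
self-attention layer (inter-class relationships), collapses them with a
learned category-importance softmax, and maps the slide embedding to a
scalar risk.  Training minimizes the negative Cox partial log-likelihood
(Breslow ties) of the slide risks against DFS time and status, with
full-cohort risk sets at every step.

The per-patch attention weights and the category-importance weights are the
model's interpretability output: they indicate which tissue regions and
which tissue classes drive the predicted risk.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._autograd import Adam, Tensor, concat, softmax, stack
from ._nn import cox_ph_loss, lecun_normal
from .bags import SlideBag
from .tilemap import CATEGORIES, TissueMap, ValueGrid, grid_aggregate


@dataclass
class ATATConfig:
    attention_hidden: int = 32   # width of the gated-attention projection
    inter_dim: int = 16          # width of the inter-class attention space
    lr: float = 5e-3
    epochs: int = 30
    seed: int = 0

    def __post_init__(self):
        if self.attention_hidden < 1 or self.inter_dim < 1:
            raise ValueError("dims must be >= 1")


@dataclass
class AttentionResult:
    """Per-patch and per-category attention for one slide, plus its risk."""

    slide_id: str
    patch_attention: dict[str, np.ndarray]      # softmax within category
    category_importance: dict[str, float]       # softmax over present cats
    risk: float
    cells: dict[str, np.ndarray]                # (row, col) per instance


def _init_params(rng: np.random.Generator, d: int,
                 cfg: ATATConfig) -> dict[str, Tensor]:
    m, k = cfg.attention_hidden, cfg.inter_dim
    params: dict[str, Tensor] = {}
    for cat in CATEGORIES:
        params[f"V_{cat}"] = Tensor(lecun_normal(rng, d, (d, m)), requires_grad=True)
        params[f"U_{cat}"] = Tensor(lecun_normal(rng, d, (d, m)), requires_grad=True)
        params[f"w_{cat}"] = Tensor(lecun_normal(rng, m, (m,)), requires_grad=True)
    for name in ("Wq", "Wk", "Wv"):
        params[name] = Tensor(lecun_normal(rng, d, (d, k)), requires_grad=True)
    params["u_imp"] = Tensor(lecun_normal(rng, k, (k,)), requires_grad=True)
    params["w_out"] = Tensor(lecun_normal(rng, d, (d,)), requires_grad=True)
    params["b_out"] = Tensor(np.zeros(()), requires_grad=True)
    return params


def _forward(params: dict[str, Tensor], bag: SlideBag):
    """Forward pass; returns (risk, per-cat attention, importance, cats)."""
    cats = bag.categories
    if not cats:
        raise ValueError(f"bag {bag.slide_id} is empty")
    pooled = []
    attentions = []
    for cat in cats:
        x = Tensor(bag.instances[cat])
        gate = (x @ params[f"V_{cat}"]).tanh() * (x @ params[f"U_{cat}"]).sigmoid()
        a = softmax(gate @ params[f"w_{cat}"], axis=0)
        attentions.append(a)
        pooled.append(a @ x)  # attention-weighted category embedding
    z = stack(pooled, axis=0)  # (k_present, d)
    q = z @ params["Wq"]
    k = z @ params["Wk"]
    v = z @ params["Wv"]
    scale = 1.0 / np.sqrt(params["Wq"].shape[1])
    ctx = softmax(q @ k.T * scale, axis=-1) @ v  # inter-class context
    # the inter-class module yields the importance weights; the slide
    # embedding is the importance-weighted sum of the category embeddings
    gamma = softmax(ctx @ params["u_imp"], axis=0)
    slide_vec = gamma @ z
    risk = slide_vec @ params["w_out"] + params["b_out"]
    return risk, attentions, gamma, cats


class ATATModel:
    """Model object: bags + survival labels; ``fit()`` returns results."""

    def __init__(self, bags: list[SlideBag], survival: pd.DataFrame,
                 config: ATATConfig | None = None):
        self.config = config or ATATConfig()
        self.bags = list(bags)
        self.survival = survival.reset_index(drop=True)
        if len(self.bags) != len(self.survival):
            raise ValueError("one bag per survival record required")
        if "slide_id" in self.survival.columns:
            mismatched = [b.slide_id for b, s in
                          zip(self.bags, self.survival["slide_id"])
                          if b.slide_id != s]
            if mismatched:
                raise ValueError(f"unmatched slide ids: {mismatched[:5]}")
        if int(self.survival["event"].sum()) < 2:
            raise ValueError("partial likelihood undefined: fewer than 2 events")

    def fit(self, verbose: bool = False) -> "ATATResults":
        cfg = self.config
        rng = np.random.default_rng(cfg.seed)
        d = self.bags[0].dim
        params = _init_params(rng, d, cfg)
        times = self.survival["time"].to_numpy(float)
        events = self.survival["event"].to_numpy(int)
        opt = Adam(list(params.values()), lr=cfg.lr)
        history = []
        for epoch in range(cfg.epochs):
            risks = concat([_forward(params, b)[0].reshape(1)
                            for b in self.bags])
            loss = cox_ph_loss(risks, times, events)
            opt.zero_grad()
            loss.backward()
            opt.step()
            history.append(float(loss.data))
            if verbose:
                print(f"epoch {epoch}: loss {loss.data:.4f}")
        return ATATResults(cfg, params, history)


@dataclass
class ATATResults:
    config: ATATConfig
    params: dict = field(repr=False)
    train_history: list[float] = field(default_factory=list)

    def attention(self, bag: SlideBag) -> AttentionResult:
        risk, atts, gamma, cats = _forward(self.params, bag)
        return AttentionResult(
            slide_id=bag.slide_id,
            patch_attention={c: a.data.copy() for c, a in zip(cats, atts)},
            category_importance={c: float(g) for c, g in zip(cats, gamma.data)},
            risk=float(risk.data),
            cells={c: bag.cells[c].copy() for c in cats if c in bag.cells},
        )

    def risk(self, bag: SlideBag) -> float:
        return float(_forward(self.params, bag)[0].data)

    def risks(self, bags: list[SlideBag]) -> np.ndarray:
        return np.array([self.risk(b) for b in bags])

    def summary(self) -> str:
        cfg = self.config
        return ("ATAT(gated attention per category -> inter-class "
                f"self-attention; hidden={cfg.attention_hidden}, "
                f"inter={cfg.inter_dim}); {len(self.train_history)} epochs, "
                f"final Cox loss {self.train_history[-1]:.4f}")


def attention_heatmap(result: AttentionResult, tmap: TissueMap,
                      block: int = 4) -> ValueGrid:
    """Patch-level saliency (importance x within-category attention)
    aggregated onto a coarse grid; Blank cells stay missing."""
    values = np.full((tmap.n_rows, tmap.n_cols), np.nan)
    for cat, weights in result.patch_attention.items():
        if cat not in result.cells:
            continue
        gamma = result.category_importance[cat]
        for (r, c), w in zip(result.cells[cat], weights):
            if not (0 <= r < tmap.n_rows and 0 <= c < tmap.n_cols):
                raise ValueError(f"patch ({r},{c}) outside {tmap.n_rows}x"
                                 f"{tmap.n_cols} grid")
            values[r, c] = gamma * w
    return grid_aggregate(ValueGrid(tmap.slide_id, values), block)
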