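"""Shared neural building blocks: layers, initialisation, and the Cox loss.

The negative Cox partial log-likelihood with Breslow tie handling is the
training objective of every survival network in the package; higher network
output means higher hazard.
"""

from __future__ import annotations

import numpy as np

from ._autograd import Tensor

__all__ = ["lecun_normal", "Dense", "alpha_dropout", "cox_ph_loss",
           "breslow_loglik"]


def lecun_normal(rng: np.random.Generator, fan_in: int, shape) -> np.ndarray:
    """LeCun-normal init, the standard choice for self-normalizing nets."""
    return rng.normal(0.0, 1.0 / np.sqrt(fan_in), size=shape)


class Dense:
    def __init__(self, rng: np.random.Generator, n_in: int, n_out: int):
        self.W = Tensor(lecun_normal(rng, n_in, (n_in, n_out)), requires_grad=True)
        self.b = Tensor(np.zeros(n_out), requires_grad=True)

    def __call__(self, x: Tensor) -> Tensor:
        return x @ self.W + self.b

    @property
    def params(self) -> list[Tensor]:
        return [self.W, self.b]


# Alpha-dropout keeps the SELU self-normalizing property: dropped units are
# set to the SELU negative saturation value and the layer is affinely
# rescaled so mean/variance are preserved in expectation.
_SELU_LAMBDA = 1.0507009873554805
_SELU_ALPHA = 1.6732632423543772
_ALPHA_PRIME = -_SELU_LAMBDA * _SELU_ALPHA


def alpha_dropout(x: Tensor, rate: float, rng: np.random.Generator) -> Tensor:
    if rate <= 0.0:
        return x
    q = 1.0 - rate
    mask = (rng.random(x.shape) < q).astype(float)
    a = (q + _ALPHA_PRIME**2 * q * (1 - q)) ** -0.5
    b = -a * (1 - q) * _ALPHA_PRIME
    return (x * Tensor(mask) + Tensor((1 - mask) * _ALPHA_PRIME)) * a + b


def _risk_set_mask(times: np.ndarray, events: np.ndarray) -> np.ndarray:
    """Rows = events (in input order), cols = cohort; 1 where t_j >= t_i."""
    ev_idx = np.flatnonzero(events == 1)
    return (times[None, :] >= times[ev_idx, None]).astype(float)


def cox_ph_loss(risks: Tensor, times: np.ndarray, events: np.ndarray) -> Tensor:
    """Mean negative Cox partial log-likelihood (Breslow ties).

    ``risks`` is the model's linear predictor for every subject, shape (n,).
    """
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    n_events = int(events.sum())
    if n_events == 0:
        raise ValueError("partial likelihood undefined: no events")
    mask = Tensor(_risk_set_mask(times, events))
    ev_idx = np.flatnonzero(events == 1)
    # numerically centre the risks (a constant shift leaves the loss invariant)
    shift = Tensor(np.max(risks.data))
    e = (risks - shift).exp()
    denom = (mask @ e).log()  # log sum_{j in risk set i} exp(r_j - shift)
    num = risks[ev_idx] - shift
    return (denom - num).sum() * (1.0 / n_events)


def breslow_loglik(risks: np.ndarray, times: np.ndarray, events: np.ndarray) -> float:
    """Plain-numpy Breslow partial log-likelihood (not the per-event mean)."""
    risks = np.asarray(risks, dtype=float)
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    ll = 0.0
    for i in np.flatnonzero(events == 1):
        in_set = times >= times[i]
        ll += risks[i] - np.log(np.sum(np.exp(risks[in_set])))
    return float(ll)
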