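"""The continuous resilient (CoRe) parameter update and learning-rate decay.

CoRe is an adaptive first-order optimizer in the Adam family: it keeps
bias-corrected first and second gradient moments, but the first-moment
coefficient decays along the run from beta1a to beta1b through a Gaussian
window of width beta1c steps,

    beta1(t) = beta1b + (beta1a - beta1b) * exp(-((t - 1)/beta1c)^2),

so early iterations use heavy momentum (0.9) and late iterations a lighter
one (0.5).  The parameter increment at step t is

    -eta(t) * [g_t / (1 - beta1(t)^t)] / (sqrt(h_t / (1 - beta2^t)) + eps)

with g/h the exponential moving averages of F and F^2.  On top of this an
exponential learning-rate schedule eta(t) = eta0 * r^(t/T) decays the rate
from eta0 to r * eta0 over the step budget T.

Defaults: eta0 = 0.05, beta1a = 0.9, beta1b = 0.5, beta1c = 100,
beta2 = 0.99, eps = 1e-8.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["CoReHyper", "CoReState", "core_update", "learning_rate", "beta1_schedule"]


@dataclass(frozen=True)
class CoReHyper:
    """CoRe hyperparameters plus the learning-rate schedule."""

    eta0: float = 0.05
    beta1a: float = 0.9
    beta1b: float = 0.5
    beta1c: float = 100.0
    beta2: float = 0.99
    eps: float = 1e-8
    decay_rate: float = 0.1
    total_steps: int = 1000


@dataclass
class CoReState:
    """Moment accumulators; ``t`` counts completed updates."""

    g: np.ndarray
    h2: np.ndarray
    t: int = 0
    hyper: CoReHyper = field(default_factory=CoReHyper)

    @classmethod
    def zeros(cls, n_params: int, hyper: CoReHyper | None = None) -> "CoReState":
        return cls(g=np.zeros(n_params), h2=np.zeros(n_params),
                   hyper=hyper or CoReHyper())


def beta1_schedule(t: int, hyper: CoReHyper) -> float:
    """Gaussian-decaying momentum coefficient beta1(t)."""
    return hyper.beta1b + (hyper.beta1a - hyper.beta1b) * np.exp(-((t - 1) / hyper.beta1c) ** 2)


def learning_rate(t: int, total_steps: int, decay_rate: float, eta0: float) -> float:
    """Exponentially decaying rate: eta0 at t=0, decay_rate * eta0 at t=T."""
    if decay_rate <= 0:
        raise ValueError("decay rate must be positive")
    if total_steps < 1:
        raise ValueError("total step count must be >= 1")
    return float(eta0 * decay_rate ** (t / total_steps))


def core_update(state: CoReState, grad: np.ndarray, eta: float | None = None):
    """One CoRe step; returns ``(new_state, parameter_increment)``.

    ``eta`` overrides the scheduled learning rate (the caller normally
    passes :func:`learning_rate` of the current step).
    """
    grad = np.asarray(grad, dtype=float)
    if not np.all(np.isfinite(grad)):
        raise FloatingPointError("non-finite gradient passed to the optimizer")
    hp = state.hyper
    t = state.t + 1
    b1 = beta1_schedule(t, hp)
    g = b1 * state.g + (1.0 - b1) * grad
    h2 = hp.beta2 * state.h2 + (1.0 - hp.beta2) * grad ** 2
    g_hat = g / (1.0 - b1 ** t)
    h_hat = h2 / (1.0 - hp.beta2 ** t)
    scaled = g_hat / (np.sqrt(h_hat) + hp.eps)
    if eta is None:
        eta = learning_rate(t - 1, hp.total_steps, hp.decay_rate, hp.eta0)
    new_state = CoReState(g=g, h2=h2, t=t, hyper=hp)
    return new_state, -float(eta) * scaled
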