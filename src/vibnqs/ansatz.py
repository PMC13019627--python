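"""Amplitude functions: modal products, the modal-backflow network, and a
plain feedforward baseline.

A *modal* is a single-mode wavefunction, a superposition of that mode's
Fock states.  A modal-product (MP, Hartree-product) state assigns one fixed
modal per mode, so the amplitude of an ONV is the product of the selected
modal coefficients, ``Psi(n) = prod_i phi_{i, n_i}``.  The modal-backflow
(MBF) ansatz makes the modal coefficients depend on the whole ONV through a
shallow fully connected network,

    h = tanh(W0 n + b0),    o = tanh(W1 h + b1),

with ``o`` reshaped to an L x Nmodal correction ``delta(n)`` added to a
fixed modal matrix: ``phi(n) = phi0 + delta(n)``.  With all weights and
biases zero the MBF state reduces exactly to the MP state ``phi0``, which
is what makes mean-field (VSCF) pretraining a special case of the same
machinery.  The FNN baseline uses the same two-layer body with a scalar
head that outputs the amplitude directly.

All amplitudes are real; parameter derivatives of log Psi are exact
(chain rule), not autodiff.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "ModalMatrix",
    "MBFAnsatz",
    "FNNAnsatz",
    "init_mbf",
    "init_fnn",
    "hidden_count",
]


def hidden_count(alpha: float, L: int) -> int:
    """Number of hidden neurons for hidden density alpha = Nhidden / L."""
    nh = int(round(alpha * L))
    if nh < 1:
        raise ValueError(f"alpha={alpha} gives no hidden neurons for L={L}")
    return nh


@dataclass
class ModalMatrix:
    """The fixed part phi0 of the modal functions, shape (L, Nmodal)."""

    phi0: np.ndarray

    def __post_init__(self):
        phi0 = np.asarray(self.phi0, dtype=float)
        if phi0.ndim != 2:
            raise ValueError("phi0 must be a 2-d (L, Nmodal) array")
        if not np.all(np.isfinite(phi0)):
            raise ValueError("phi0 entries must be finite")
        if np.any(np.all(phi0 == 0.0, axis=1)):
            raise ValueError("every mode needs a nonvanishing modal function")
        self.phi0 = phi0

    @classmethod
    def one_hot(cls, onv, nmodal: int) -> "ModalMatrix":
        """Modal matrix of the harmonic product state |onv>."""
        onv = np.asarray(onv, dtype=int)
        phi0 = np.zeros((onv.size, nmodal))
        phi0[np.arange(onv.size), onv] = 1.0
        return cls(phi0)

    @property
    def L(self) -> int:
        return self.phi0.shape[0]

    @property
    def nmodal(self) -> int:
        return self.phi0.shape[1]


class MBFAnsatz:
    """MBF state with exact log-derivatives.

    ``train_phi0`` selects mean-field (VSCF) mode: the network weights are
    frozen (typically at zero) and the fixed modal matrix itself is the
    trainable parameter set.  In the default backflow mode phi0 is frozen
    and the four network blocks (W0, b0, W1, b1) are trainable.
    """

    def __init__(self, phi0: ModalMatrix, w0, b0, w1, b1, alpha: float,
                 train_phi0: bool = False, train_weights: bool = True):
        self.phi0 = phi0
        self.w0 = np.asarray(w0, dtype=float)
        self.b0 = np.asarray(b0, dtype=float)
        self.w1 = np.asarray(w1, dtype=float)
        self.b1 = np.asarray(b1, dtype=float)
        self.alpha = float(alpha)
        self.train_phi0 = bool(train_phi0)
        self.train_weights = bool(train_weights)
        L, nmodal = phi0.L, phi0.nmodal
        nh = self.w0.shape[0]
        if self.w0.shape != (nh, L) or self.b0.shape != (nh,):
            raise ValueError("inconsistent first-layer shapes")
        if self.w1.shape != (L * nmodal, nh) or self.b1.shape != (L * nmodal,):
            raise ValueError("inconsistent second-layer shapes")

    @property
    def L(self) -> int:
        return self.phi0.L

    @property
    def nmodal(self) -> int:
        return self.phi0.nmodal

    @property
    def n_hidden(self) -> int:
        return self.w0.shape[0]

    # -- forward ---------------------------------------------------------

    def forward(self, onvs: np.ndarray):
        """Hidden activations and modal corrections for a batch of ONVs.

        Returns ``(h, delta)`` with shapes (m, Nhidden) and (m, L, Nmodal).
        """
        onvs = np.atleast_2d(np.asarray(onvs, dtype=float))
        if onvs.shape[1] != self.L:
            raise ValueError(f"ONV batch has {onvs.shape[1]} modes, expected {self.L}")
        h = np.tanh(onvs @ self.w0.T + self.b0)
        o = np.tanh(h @ self.w1.T + self.b1)
        return h, o.reshape(-1, self.L, self.nmodal)

    def modal_functions(self, onvs: np.ndarray) -> np.ndarray:
        """ONV-dependent modal matrices phi(n) = phi0 + delta(n)."""
        _, delta = self.forward(onvs)
        return self.phi0.phi0[None, :, :] + delta

    def amplitudes(self, onvs: np.ndarray) -> np.ndarray:
        onvs = np.atleast_2d(np.asarray(onvs, dtype=int))
        phi = self.modal_functions(onvs)
        sel = np.take_along_axis(phi, onvs[:, :, None], axis=2)[:, :, 0]
        return np.prod(sel, axis=1)

    # -- parameters ------------------------------------------------------

    @property
    def n_params(self) -> int:
        n = 0
        if self.train_weights:
            n += self.w0.size + self.b0.size + self.w1.size + self.b1.size
        if self.train_phi0:
            n += self.phi0.phi0.size
        return n

    def get_params(self) -> np.ndarray:
        parts = []
        if self.train_weights:
            parts += [self.w0.ravel(), self.b0.ravel(), self.w1.ravel(), self.b1.ravel()]
        if self.train_phi0:
            parts.append(self.phi0.phi0.ravel())
        return np.concatenate(parts)

    def set_params(self, vec: np.ndarray) -> None:
        vec = np.asarray(vec, dtype=float)
        pos = 0

        def take(arr):
            nonlocal pos
            out = vec[pos:pos + arr.size].reshape(arr.shape)
            pos += arr.size
            return out

        if self.train_weights:
            self.w0 = take(self.w0)
            self.b0 = take(self.b0)
            self.w1 = take(self.w1)
            self.b1 = take(self.b1)
        if self.train_phi0:
            self.phi0 = ModalMatrix(take(self.phi0.phi0))
        if pos != vec.size:
            raise ValueError("parameter vector length mismatch")

    # -- derivatives -----------------------------------------------------

    def log_derivatives(self, onvs: np.ndarray) -> np.ndarray:
        """D_m(n) = (1/Psi) dPsi/dtheta_m for the trainable blocks.

        Shape (m, n_params).  Rows for configurations with a vanishing
        selected coefficient contain non-finite entries; callers apply the
        amplitude floor before using them.
        """
        onvs = np.atleast_2d(np.asarray(onvs, dtype=int))
        m, L, nm = onvs.shape[0], self.L, self.nmodal
        x = onvs.astype(float)
        h = np.tanh(x @ self.w0.T + self.b0)
        o = np.tanh(h @ self.w1.T + self.b1)
        delta = o.reshape(m, L, nm)
        phi = self.phi0.phi0[None, :, :] + delta
        sel = np.take_along_axis(phi, onvs[:, :, None], axis=2)[:, :, 0]  # (m, L)
        with np.errstate(divide="ignore", invalid="ignore"):
            inv_sel = 1.0 / sel

        blocks = []
        if self.train_weights:
            # d log Psi / d z1 is nonzero only at the selected outputs
            flat_pos = np.arange(L)[None, :] * nm + onvs  # (m, L)
            gz1 = np.zeros((m, L * nm))
            rows = np.repeat(np.arange(m), L)
            o_sel = np.take_along_axis(o, flat_pos, axis=1)
            gz1[rows, flat_pos.ravel()] = ((1.0 - o_sel ** 2) * inv_sel).ravel()
            gh = gz1 @ self.w1  # (m, Nh)
            gz0 = gh * (1.0 - h ** 2)
            d_w0 = gz0[:, :, None] * x[:, None, :]
            d_w1 = gz1[:, :, None] * h[:, None, :]
            blocks += [d_w0.reshape(m, -1), gz0, d_w1.reshape(m, -1), gz1]
        if self.train_phi0:
            d_phi0 = np.zeros((m, L, nm))
            np.put_along_axis(d_phi0, onvs[:, :, None], inv_sel[:, :, None], axis=2)
            blocks.append(d_phi0.reshape(m, -1))
        return np.concatenate(blocks, axis=1)


class FNNAnsatz:
    """Two-layer feedforward baseline with a scalar amplitude head.

    The body is the same tanh layer as the MBF network; the head is
    *linear*, ``Psi(n) = w1 . h + b1``.  A bounded (tanh) head turns out to
    be unusable as a direct amplitude model: once the optimizer saturates
    it, every selected configuration sits at |Psi| ~ 1 with a vanishing
    log-derivative, and the state can no longer concentrate weight on the
    dominant configuration.  The linear head keeps the amplitude scale
    free (the estimator only uses normalized quantities).
    """

    def __init__(self, L: int, w0, b0, w1, b1, alpha: float):
        self.L = int(L)
        self.w0 = np.asarray(w0, dtype=float)
        self.b0 = np.asarray(b0, dtype=float)
        self.w1 = np.asarray(w1, dtype=float)
        self.b1 = float(b1)
        self.alpha = float(alpha)
        nh = self.w0.shape[0]
        if self.w0.shape != (nh, self.L) or self.b0.shape != (nh,) or self.w1.shape != (nh,):
            raise ValueError("inconsistent FNN shapes")

    @property
    def n_hidden(self) -> int:
        return self.w0.shape[0]

    @property
    def n_params(self) -> int:
        return self.w0.size + self.b0.size + self.w1.size + 1

    def amplitudes(self, onvs: np.ndarray) -> np.ndarray:
        onvs = np.atleast_2d(np.asarray(onvs, dtype=float))
        h = np.tanh(onvs @ self.w0.T + self.b0)
        return h @ self.w1 + self.b1

    def get_params(self) -> np.ndarray:
        return np.concatenate([self.w0.ravel(), self.b0, self.w1, [self.b1]])

    def set_params(self, vec: np.ndarray) -> None:
        vec = np.asarray(vec, dtype=float)
        n0 = self.w0.size
        nh = self.n_hidden
        self.w0 = vec[:n0].reshape(self.w0.shape)
        self.b0 = vec[n0:n0 + nh]
        self.w1 = vec[n0 + nh:n0 + 2 * nh]
        self.b1 = float(vec[-1])

    def log_derivatives(self, onvs: np.ndarray) -> np.ndarray:
        onvs = np.atleast_2d(np.asarray(onvs, dtype=float))
        m = onvs.shape[0]
        h = np.tanh(onvs @ self.w0.T + self.b0)
        psi = h @ self.w1 + self.b1
        with np.errstate(divide="ignore", invalid="ignore"):
            gz1 = 1.0 / psi  # (m,)
        gh = gz1[:, None] * self.w1[None, :]
        gz0 = gh * (1.0 - h ** 2)
        d_w0 = gz0[:, :, None] * onvs[:, None, :]
        d_w1 = gz1[:, None] * h
        return np.concatenate([d_w0.reshape(m, -1), gz0, d_w1, gz1[:, None]], axis=1)


def init_mbf(phi0: ModalMatrix, alpha: float, sigma: float, seed: int,
             train_phi0: bool = False, train_weights: bool = True) -> MBFAnsatz:
    """MBF ansatz with weights/biases drawn from N(0, sigma^2).

    ``sigma = 0`` reproduces the modal-product state phi0 exactly.
    """
    if sigma < 0:
        raise ValueError("sigma must be >= 0")
    L, nm = phi0.L, phi0.nmodal
    nh = hidden_count(alpha, L)
    rng = np.random.default_rng(seed)
    w0 = rng.normal(0.0, sigma, size=(nh, L))
    b0 = rng.normal(0.0, sigma, size=nh)
    w1 = rng.normal(0.0, sigma, size=(L * nm, nh))
    b1 = rng.normal(0.0, sigma, size=L * nm)
    return MBFAnsatz(phi0, w0, b0, w1, b1, alpha,
                     train_phi0=train_phi0, train_weights=train_weights)


def init_fnn(L: int, alpha: float, sigma: float, seed: int) -> FNNAnsatz:
    """FNN baseline with weights/biases drawn from N(0, sigma^2)."""
    if sigma < 0:
        raise ValueError("sigma must be >= 0")
    nh = hidden_count(alpha, L)
    rng = np.random.default_rng(seed)
    w0 = rng.normal(0.0, sigma, size=(nh, L))
    b0 = rng.normal(0.0, sigma, size=nh)
    w1 = rng.normal(0.0, sigma, size=nh)
    b1 = rng.normal(0.0, sigma)
    return FNNAnsatz(L, w0, b0, w1, b1, alpha)
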