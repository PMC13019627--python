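"""Second-quantized Watson Hamiltonians on truncated bosonic Fock spaces.

The vibrational Hamiltonian in dimensionless normal coordinates contains a
harmonic part, anharmonic potential terms of order 3-6 built from reduced
force constants, and (optionally) Coriolis rovibrational couplings.  After
substituting ``q = (b^dag + b)/sqrt(2)`` and ``p = (b^dag - b)/sqrt(2)`` the
operator becomes a sum of ladder-operator strings acting on occupation
number vectors (ONVs).  Each mode's local Fock space is truncated at
``Nmax`` quanta (``Nmodal = Nmax + 1`` basis states), so every ladder
factor is applied sequentially *inside* the truncated space: creation on a
mode already at ``Nmax`` annihilates the state.

All coefficients are stored and returned in cm^-1.
"""

from __future__ import annotations

import itertools
import math
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import scipy.sparse as sp

__all__ = [
    "ForceField",
    "Coriolis",
    "WatsonOperator",
    "ladder_apply",
    "build_operator",
    "connections",
    "to_matrix",
    "reduce_constants",
    "onv_to_index",
    "index_to_onv",
]

#: Orders of potential-energy force constants supported.
SUPPORTED_ORDERS = (3, 4, 5, 6)

#: Default cap on the enumerable Fock-space dimension for dense assembly.
SIZE_GUARD = 2_000_000


class ValidationError(ValueError):
    """Raised when a force field or operator request is inconsistent."""


@dataclass(frozen=True)
class Coriolis:
    """Rotational constants and Coriolis coupling matrices.

    Parameters
    ----------
    b
        Three rotational constants ``B^tau`` (tau = x, y, z) in cm^-1.
    xi
        Three L x L dimensionless antisymmetric coupling matrices
        ``xi^tau``, stacked as shape ``(3, L, L)``.
    """

    b: np.ndarray
    xi: np.ndarray

    def __post_init__(self):
        b = np.asarray(self.b, dtype=float)
        xi = np.asarray(self.xi, dtype=float)
        object.__setattr__(self, "b", b)
        object.__setattr__(self, "xi", xi)
        if b.shape != (3,):
            raise ValidationError(f"expected 3 rotational constants, got shape {b.shape}")
        if xi.ndim != 3 or xi.shape[0] != 3 or xi.shape[1] != xi.shape[2]:
            raise ValidationError(f"xi must have shape (3, L, L), got {xi.shape}")
        if not np.allclose(xi, -np.transpose(xi, (0, 2, 1)), atol=1e-12):
            raise ValidationError("Coriolis xi matrices must be antisymmetric (xi_ij = -xi_ji)")


@dataclass(frozen=True)
class ForceField:
    """Harmonic frequencies plus reduced anharmonic force constants.

    Parameters
    ----------
    w
        Harmonic frequencies of the L normal modes, cm^-1, all positive.
    phi
        Mapping ``order -> {sorted index tuple: reduced constant}`` with the
        reduced constants ``Phi`` in cm^-1.  Only canonically sorted index
        tuples are stored; the full symmetric tensor is implied.
    coriolis
        Optional Coriolis data.
    """

    w: np.ndarray
    phi: Mapping[int, Mapping[tuple, float]] = field(default_factory=dict)
    coriolis: Coriolis | None = None

    def __post_init__(self):
        w = np.atleast_1d(np.asarray(self.w, dtype=float))
        object.__setattr__(self, "w", w)
        if w.ndim != 1 or w.size < 1:
            raise ValidationError("frequencies must form a non-empty 1-d array")
        if np.any(w <= 0):
            raise ValidationError("all harmonic frequencies must be strictly positive")
        L = w.size
        clean: dict[int, dict[tuple, float]] = {}
        for order, entries in dict(self.phi).items():
            order = int(order)
            if order not in SUPPORTED_ORDERS:
                raise ValidationError(f"unsupported force-constant order {order}")
            table: dict[tuple, float] = {}
            for idx, val in dict(entries).items():
                idx = tuple(int(i) for i in idx)
                if len(idx) != order:
                    raise ValidationError(f"index tuple {idx} does not match order {order}")
                if any(i < 0 or i >= L for i in idx):
                    raise ValidationError(f"tensor index {idx} out of range for L={L}")
                key = tuple(sorted(idx))
                if key in table:
                    raise ValidationError(f"duplicate index tuple {key} at order {order}")
                table[key] = float(val)
            clean[order] = table
        object.__setattr__(self, "phi", clean)
        if self.coriolis is not None and self.coriolis.xi.shape[1] != L:
            raise ValidationError("Coriolis xi dimension does not match the number of modes")

    @property
    def L(self) -> int:
        return int(self.w.size)

    def harmonic_zpe(self) -> float:
        """Zero-point energy of the harmonic part, ``sum_i w_i / 2``."""
        return float(self.w.sum() / 2.0)


def reduce_constants(kappa: Mapping[tuple, float], w: Sequence[float]) -> dict[tuple, float]:
    """Reduce raw PES derivatives by the frequency product root.

    ``Phi_{i1..inu} = kappa_{i1..inu} / sqrt(w_{i1} ... w_{inu})`` with the
    frequencies and derivatives in consistent units (the result carries the
    units of kappa divided by those of w^(nu/2)).
    """
    w = np.asarray(w, dtype=float)
    if np.any(w <= 0):
        raise ValidationError("frequencies must be strictly positive to reduce constants")
    out: dict[tuple, float] = {}
    for idx, val in kappa.items():
        idx = tuple(int(i) for i in idx)
        if len(idx) not in SUPPORTED_ORDERS:
            raise ValidationError(f"index arity {len(idx)} outside supported orders {SUPPORTED_ORDERS}")
        out[idx] = float(val) / math.sqrt(float(np.prod(w[list(idx)])))
    return out


def unreduce_constants(phi: Mapping[tuple, float], w: Sequence[float]) -> dict[tuple, float]:
    """Inverse of :func:`reduce_constants`."""
    w = np.asarray(w, dtype=float)
    return {tuple(idx): float(v) * math.sqrt(float(np.prod(w[list(idx)]))) for idx, v in phi.items()}


def ladder_apply(n: Sequence[int], mode: int, kind: str, nmax: int | None = None):
    """Apply one ladder operator to an ONV inside the truncated space.

    Annihilation acts as ``b|..k..> = sqrt(k)|..k-1..>`` and creation as
    ``b^dag|..k..> = sqrt(k+1)|..k+1..>``.  Returns ``(new_onv, amplitude)``
    or ``None`` when the result leaves the space: annihilation on 0 quanta,
    or creation on a mode already at ``nmax`` (the truncation projects the
    result out).  With ``nmax=None`` creation is unbounded.
    """
    n = tuple(int(x) for x in n)
    if mode < 0 or mode >= len(n):
        raise IndexError(f"mode {mode} out of range for {len(n)} modes")
    k = n[mode]
    if kind == "annihilate":
        if k == 0:
            return None
        return n[:mode] + (k - 1,) + n[mode + 1:], math.sqrt(k)
    if kind == "create":
        if nmax is not None and k >= nmax:
            return None
        return n[:mode] + (k + 1,) + n[mode + 1:], math.sqrt(k + 1)
    raise ValueError(f"kind must be 'create' or 'annihilate', got {kind!r}")


def _ladder_matrices(nmodal: int):
    """Truncated X = b^dag + b, P = b^dag - b and the number operator."""
    root = np.sqrt(np.arange(1, nmodal))
    x = np.zeros((nmodal, nmodal))
    x[np.arange(1, nmodal), np.arange(nmodal - 1)] = root  # b^dag
    x[np.arange(nmodal - 1), np.arange(1, nmodal)] = root  # b
    p = np.zeros((nmodal, nmodal))
    p[np.arange(1, nmodal), np.arange(nmodal - 1)] = root
    p[np.arange(nmodal - 1), np.arange(1, nmodal)] = -root
    num = np.diag(np.arange(nmodal, dtype=float))
    return x, p, num


@dataclass
class WatsonOperator:
    """Assembled term table of a Watson Hamiltonian on the truncated space.

    ``terms`` is a flat list of ``(coefficient, ((mode, matrix), ...))``
    entries: the matrix element ``<n'|term|n>`` is the coefficient times the
    product over the listed modes of ``matrix[n'_mode, n_mode]`` with all
    unlisted modes unchanged.  ``diag_shift`` collects purely scalar terms.
    The table is Hermitized term-by-term, so ``<n'|H|n> = <n|H|n'>``.
    """

    ff: ForceField
    nmax: int
    terms: list
    diag_shift: float
    xpow: list
    pmat: np.ndarray

    @property
    def L(self) -> int:
        return self.ff.L

    @property
    def nmodal(self) -> int:
        return self.nmax + 1

    @property
    def dim(self) -> int:
        return self.nmodal ** self.L


def _symmetrized_terms(coeff: float, factors: tuple):
    """Emit a term as its symmetric (Hermitized) part.

    Potential strings are built from symmetric matrices and are already
    Hermitian; Coriolis strings with same-mode q/p mixes are not, so the
    transpose partner is added at half weight.
    """
    if all(np.array_equal(m, m.T) for _, m in factors):
        return [(coeff, factors)]
    t_factors = tuple((mode, m.T.copy()) for mode, m in factors)
    return [(0.5 * coeff, factors), (0.5 * coeff, t_factors)]


def build_operator(ff: ForceField, nmax: int) -> WatsonOperator:
    """Assemble the second-quantized Watson operator at truncation ``nmax``.

    The harmonic part contributes ``sum_i w_i (b_i^dag b_i + 1/2)``; each
    order-``nu`` reduced constant contributes with prefactor
    ``1/(nu! * 2^(nu/2))`` times the product of ``(b^dag + b)`` factors; the
    Coriolis part contributes ``(1/4) B^tau xi_ij xi_kl
    sqrt(w_j w_l / (w_i w_k))`` times ``X_i P_j X_k P_l``.  Powers of ladder
    strings are powers of the *truncated* single-mode matrices.
    """
    if nmax < 1:
        raise ValidationError("nmax must be >= 1")
    nmodal = nmax + 1
    x, p, num = _ladder_matrices(nmodal)
    max_pow = max(SUPPORTED_ORDERS) + 1
    xpow = [np.linalg.matrix_power(x, k) for k in range(max_pow)]

    terms: list = []
    diag_shift = float(ff.w.sum() / 2.0)
    for i, wi in enumerate(ff.w):
        terms.append((float(wi), ((i, num),)))

    for order, table in ff.phi.items():
        pref = 1.0 / (math.factorial(order) * 2.0 ** (order / 2.0))
        for idx, val in table.items():
            counts = Counter(idx)
            mult = math.factorial(order)
            for c in counts.values():
                mult //= math.factorial(c)
            coeff = pref * val * mult
            factors = tuple((mode, xpow[k]) for mode, k in sorted(counts.items()))
            terms.extend(_symmetrized_terms(coeff, factors))

    if ff.coriolis is not None:
        L = ff.L
        w = ff.w
        for tau in range(3):
            xi = ff.coriolis.xi[tau]
            btau = float(ff.coriolis.b[tau])
            if btau == 0.0 or not np.any(xi):
                continue
            pairs = [(i, j) for i in range(L) for j in range(L) if xi[i, j] != 0.0]
            for (i, j) in pairs:
                for (k, l) in pairs:
                    coeff = 0.25 * btau * xi[i, j] * xi[k, l] * math.sqrt(w[j] * w[l] / (w[i] * w[k]))
                    # written operator order X_i P_j X_k P_l; same-mode factors
                    # compose by matrix product in that order
                    per_mode: dict[int, np.ndarray] = {}
                    for mode, mat in ((i, x), (j, p), (k, x), (l, p)):
                        per_mode[mode] = per_mode[mode] @ mat if mode in per_mode else mat
                    factors = tuple(sorted(per_mode.items()))
                    terms.extend(_symmetrized_terms(coeff, factors))

    return WatsonOperator(ff=ff, nmax=nmax, terms=terms, diag_shift=diag_shift, xpow=xpow, pmat=p)


def connections(H: WatsonOperator, n: Sequence[int]) -> list[tuple[tuple, float]]:
    """All ONVs ``n'`` with nonzero ``<n'|H|n>``, including the diagonal.

    Duplicate contributions from different terms are merged.  The returned
    matrix elements agree with the rows of :func:`to_matrix`.
    """
    n = tuple(int(x) for x in n)
    if len(n) != H.L:
        raise ValidationError(f"ONV has {len(n)} modes, operator expects {H.L}")
    if any(x < 0 or x > H.nmax for x in n):
        raise ValidationError(f"ONV {n} outside truncation Nmax={H.nmax}")
    acc: dict[tuple, float] = {n: H.diag_shift}
    for coeff, factors in H.terms:
        per_mode_rows = []
        for mode, mat in factors:
            col = mat[:, n[mode]]
            rows = np.nonzero(col)[0]
            per_mode_rows.append((mode, rows, col))
        for combo in itertools.product(*(range(len(r)) for _, r, _ in per_mode_rows)):
            amp = coeff
            new = list(n)
            for (mode, rows, col), sel in zip(per_mode_rows, combo):
                r = rows[sel]
                amp *= col[r]
                new[mode] = int(r)
            key = tuple(new)
            acc[key] = acc.get(key, 0.0) + amp
    return [(k, v) for k, v in acc.items() if v != 0.0]


def to_matrix(H: WatsonOperator, size_guard: int = SIZE_GUARD) -> sp.csr_matrix:
    """Assemble the full sparse symmetric matrix over the enumerated basis.

    Basis ordering is mixed-radix little-endian: mode 0 varies fastest,
    ``index = sum_i n_i * Nmodal^i``.
    """
    dim = H.dim
    if dim > size_guard:
        raise ValidationError(f"Fock space dimension {dim} exceeds the size guard {size_guard}")
    nm = H.nmodal
    eye = sp.identity(nm, format="csr")
    mat = sp.identity(dim, format="csr") * H.diag_shift
    for coeff, factors in H.terms:
        fac = {mode: m for mode, m in factors}
        acc = None
        # little-endian: index = sum n_i nm^i  ->  kron(M_{L-1}, ..., M_0)
        for mode in range(H.L - 1, -1, -1):
            m = sp.csr_matrix(fac[mode]) if mode in fac else eye
            acc = m if acc is None else sp.kron(acc, m, format="csr")
        mat = mat + coeff * acc
    mat = (mat + mat.T) * 0.5
    mat.eliminate_zeros()
    return sp.csr_matrix(mat)


def onv_to_index(n: np.ndarray, nmodal: int) -> np.ndarray:
    """Map ONVs (..., L) to basis indices (mode 0 fastest)."""
    n = np.asarray(n, dtype=np.int64)
    L = n.shape[-1]
    radix = nmodal ** np.arange(L, dtype=np.int64)
    return n @ radix


def index_to_onv(idx: np.ndarray, L: int, nmodal: int) -> np.ndarray:
    """Inverse of :func:`onv_to_index`; returns shape (..., L)."""
    idx = np.asarray(idx, dtype=np.int64)
    out = np.empty(idx.shape + (L,), dtype=np.int64)
    rem = idx
    for i in range(L):
        out[..., i] = rem % nmodal
        rem = rem // nmodal
    return out


def enumerate_basis(L: int, nmodal: int) -> np.ndarray:
    """All ONVs of the truncated space in basis order, shape (dim, L)."""
    return index_to_onv(np.arange(nmodal ** L, dtype=np.int64), L, nmodal)
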