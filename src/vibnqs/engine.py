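"""Selected-configuration evaluation of energies and gradients.

Instead of Markov-chain sampling, expectation values are restricted to a
small set W of configurations with the largest amplitudes.  The estimator
is the asymmetric quotient

    <H>_W = sum_{n in W} P_W(n) E_loc(n) = <Psi_W|H|Psi> / <Psi_W|Psi_W>,

where ``E_loc(n) = sum_{n'} <n|H|n'> Psi(n')/Psi(n)`` runs over the *full*
connected set of n (not only W) and ``P_W`` is the amplitude-squared
distribution normalized over W.  Parameter gradients use the covariance
form ``F_m = 2 sum_W P_W(n) D_m(n) (E_loc(n) - <H>_W)`` with
``D_m = d log Psi / d theta_m``.  The set W is refreshed by pooling W with
at most ``K * Ns`` configurations sampled uniformly from the
Hamiltonian-connected frontier and keeping the Ns largest amplitudes.

For enumerable spaces the Hamiltonian rows come from a cached sparse
matrix; otherwise connections are generated on demand and memoized.
Configurations whose amplitude falls below a relative floor are dropped
from the probability normalization and from the gradient.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import scipy.sparse as sp

from .hamiltonian import (
    WatsonOperator,
    connections,
    index_to_onv,
    onv_to_index,
    to_matrix,
)

__all__ = [
    "SelectedSpace",
    "OperatorCache",
    "PenaltyOperator",
    "local_energy",
    "local_energies",
    "expectation_w",
    "gradient_w",
    "extend_and_select",
    "evaluate",
    "AMP_FLOOR_REL",
]

#: Relative amplitude floor: configurations with |Psi| below this fraction
#: of the largest amplitude in W are excluded from P and D.
AMP_FLOOR_REL = 1e-12

#: Spaces up to this dimension use the cached sparse-matrix fast path.
MATRIX_GUARD = 200_000


@dataclass
class SelectedSpace:
    """Ordered set W of selected ONVs with amplitudes cached at selection."""

    onvs: np.ndarray          # (m, L) int
    amps: np.ndarray          # (m,)
    ns: int
    k: int

    def __post_init__(self):
        self.onvs = np.atleast_2d(np.asarray(self.onvs, dtype=np.int64))
        self.amps = np.atleast_1d(np.asarray(self.amps, dtype=float))
        if self.onvs.shape[0] != self.amps.shape[0]:
            raise ValueError("amplitude cache does not match member count")

    def __len__(self) -> int:
        return self.onvs.shape[0]

    @classmethod
    def seeded(cls, onv: Sequence[int], psi, ns: int, k: int) -> "SelectedSpace":
        onvs = np.atleast_2d(np.asarray(onv, dtype=np.int64))
        return cls(onvs=onvs, amps=psi.amplitudes(onvs), ns=int(ns), k=int(k))


@dataclass
class PenaltyOperator:
    """A Watson operator plus projector penalties and a scalar shift.

    ``H + z * sum_j |Psi_j><Psi_j| / <Psi_j|Psi_j> + shift``; each prior
    state j is known on a finite support (ONVs and amplitudes), and all
    overlaps are evaluated on those supports only.
    """

    base: WatsonOperator
    supports: list = field(default_factory=list)   # [(onvs (s, L), amps (s,)), ...]
    z: float = 0.0
    shift: float = 0.0

    @property
    def L(self) -> int:
        return self.base.L

    @property
    def nmodal(self) -> int:
        return self.base.nmodal

    @property
    def dim(self) -> int:
        return self.base.dim


class OperatorCache:
    """Row access to a (possibly penalty-shifted) Hamiltonian.

    On enumerable spaces (dimension <= ``matrix_guard``) the full sparse
    matrix of the base operator is assembled once and rows are sliced from
    it; otherwise per-ONV connections are generated and memoized.
    """

    def __init__(self, op, matrix_guard: int = MATRIX_GUARD):
        if isinstance(op, PenaltyOperator):
            self.base = op.base
            self.penalty = op
        elif isinstance(op, WatsonOperator):
            self.base = op
            self.penalty = None
        else:
            raise TypeError(f"unsupported operator type {type(op).__name__}")
        self.L = self.base.L
        self.nmodal = self.base.nmodal
        self.dim = self.base.dim
        self.use_matrix = self.dim <= matrix_guard
        self._csr: sp.csr_matrix | None = None
        self._conn_memo: dict = {}

    @property
    def csr(self) -> sp.csr_matrix:
        if self._csr is None:
            self._csr = to_matrix(self.base)
        return self._csr

    # -- row structure ---------------------------------------------------

    def _rows_matrix(self, onvs: np.ndarray):
        idx = onv_to_index(onvs, self.nmodal)
        csr = self.csr
        starts, stops = csr.indptr[idx], csr.indptr[idx + 1]
        counts = stops - starts
        gather = np.concatenate([np.arange(s, e) for s, e in zip(starts, stops)]) \
            if len(starts) else np.empty(0, dtype=np.int64)
        nbr_idx = csr.indices[gather]
        elems = csr.data[gather]
        splits = np.concatenate([[0], np.cumsum(counts)])
        return nbr_idx, elems, splits

    def _row_generic(self, onv: tuple):
        if onv not in self._conn_memo:
            conn = connections(self.base, onv)
            nbrs = np.asarray([c[0] for c in conn], dtype=np.int64)
            vals = np.asarray([c[1] for c in conn], dtype=float)
            self._conn_memo[onv] = (nbrs, vals)
        return self._conn_memo[onv]

    def connected_union(self, onvs: np.ndarray) -> np.ndarray:
        """Deduplicated union of the connected sets of a batch of ONVs
        (members included), plus any penalty supports."""
        onvs = np.atleast_2d(np.asarray(onvs, dtype=np.int64))
        if self.use_matrix:
            nbr_idx, _, _ = self._rows_matrix(onvs)
            idx = np.unique(nbr_idx)
            out = index_to_onv(idx, self.L, self.nmodal)
        else:
            seen = {}
            for row in onvs:
                nbrs, _ = self._row_generic(tuple(int(v) for v in row))
                for nb in nbrs:
                    seen[tuple(int(v) for v in nb)] = None
            out = np.asarray(sorted(seen), dtype=np.int64).reshape(-1, self.L)
        if self.penalty is not None and self.penalty.supports:
            sup = np.concatenate([s[0] for s in self.penalty.supports], axis=0)
            out = np.unique(np.concatenate([out, sup], axis=0), axis=0)
        return out

    # -- local energies --------------------------------------------------

    def local_energies(self, psi, onvs: np.ndarray, amps: np.ndarray | None = None) -> np.ndarray:
        """E_loc over a batch; one amplitude evaluation per distinct ONV."""
        onvs = np.atleast_2d(np.asarray(onvs, dtype=np.int64))
        if amps is None:
            amps = psi.amplitudes(onvs)
        if self.use_matrix:
            nbr_idx, elems, splits = self._rows_matrix(onvs)
            uniq, inv = np.unique(nbr_idx, return_inverse=True)
            nbr_amps = psi.amplitudes(index_to_onv(uniq, self.L, self.nmodal))[inv]
        else:
            rows = [self._row_generic(tuple(int(v) for v in row)) for row in onvs]
            counts = [r[0].shape[0] for r in rows]
            splits = np.concatenate([[0], np.cumsum(counts)])
            all_nbrs = np.concatenate([r[0] for r in rows], axis=0)
            elems = np.concatenate([r[1] for r in rows])
            uniq, inv = np.unique(all_nbrs, axis=0, return_inverse=True)
            nbr_amps = psi.amplitudes(uniq)[inv]
        weighted = elems * nbr_amps
        sums = np.add.reduceat(weighted, splits[:-1]) if weighted.size else np.zeros(len(onvs))
        sums = np.where(splits[:-1] == splits[1:], 0.0, sums)  # empty rows
        with np.errstate(divide="ignore", invalid="ignore"):
            eloc = sums / amps
        if self.penalty is not None:
            pen = self.penalty
            extra = np.zeros(len(onvs))
            for sup_onvs, sup_amps in pen.supports:
                norm = float(sup_amps @ sup_amps)
                overlap = float(sup_amps @ psi.amplitudes(sup_onvs))
                psi_j_here = _amplitudes_on(sup_onvs, sup_amps, onvs)
                extra += pen.z * overlap * psi_j_here / norm
            with np.errstate(divide="ignore", invalid="ignore"):
                eloc = eloc + extra / amps
            eloc = eloc + pen.shift
        return eloc


def _amplitudes_on(sup_onvs: np.ndarray, sup_amps: np.ndarray, onvs: np.ndarray) -> np.ndarray:
    """Amplitudes of a support-backed state evaluated on a batch (0 off support)."""
    table = {tuple(int(v) for v in row): float(a) for row, a in zip(sup_onvs, sup_amps)}
    return np.asarray([table.get(tuple(int(v) for v in row), 0.0) for row in onvs])


def penalized_cache(cache: OperatorCache, supports, z: float, shift: float) -> OperatorCache:
    """Cache for ``base + z * sum projectors + shift`` reusing the base rows."""
    pen = PenaltyOperator(base=cache.base, supports=list(supports), z=float(z), shift=float(shift))
    out = OperatorCache.__new__(OperatorCache)
    out.base = cache.base
    out.penalty = pen
    out.L, out.nmodal, out.dim = cache.L, cache.nmodal, cache.dim
    out.use_matrix = cache.use_matrix
    out._csr = cache._csr
    out._conn_memo = cache._conn_memo
    return out


def penalty_matrix(pen: PenaltyOperator) -> np.ndarray:
    """Dense matrix of a penalty operator on the enumerated basis (tests)."""
    mat = to_matrix(pen.base).toarray()
    dim = mat.shape[0]
    for sup_onvs, sup_amps in pen.supports:
        v = np.zeros(dim)
        v[onv_to_index(sup_onvs, pen.nmodal)] = sup_amps
        mat += pen.z * np.outer(v, v) / float(v @ v)
    mat += pen.shift * np.eye(dim)
    return mat


def _as_cache(H) -> OperatorCache:
    return H if isinstance(H, OperatorCache) else OperatorCache(H)


def local_energy(H, psi, n: Sequence[int]) -> float:
    """Local energy of one configuration, cm^-1."""
    cache = _as_cache(H)
    return float(cache.local_energies(psi, np.atleast_2d(np.asarray(n, dtype=np.int64)))[0])


def local_energies(H, psi, onvs: np.ndarray, amps: np.ndarray | None = None) -> np.ndarray:
    return _as_cache(H).local_energies(psi, onvs, amps)


def _floor_mask(amps: np.ndarray, floor_rel: float) -> np.ndarray:
    cap = np.max(np.abs(amps)) if amps.size else 0.0
    if cap == 0.0:
        raise ValueError("all amplitudes vanish on the selected space")
    return np.abs(amps) >= floor_rel * cap


def expectation_w(H, psi, W: SelectedSpace, floor_rel: float = AMP_FLOOR_REL) -> float:
    """<H>_W with P normalized over the (unfloored) members of W."""
    e, _, _ = _weights_and_locals(_as_cache(H), psi, W, floor_rel)
    return e


def _weights_and_locals(cache: OperatorCache, psi, W: SelectedSpace, floor_rel: float):
    if len(W) == 0:
        raise ValueError("selected space is empty")
    amps = W.amps
    mask = _floor_mask(amps, floor_rel)
    onvs, amps = W.onvs[mask], amps[mask]
    p = amps ** 2
    p = p / p.sum()
    eloc = cache.local_energies(psi, onvs, amps)
    energy = float(p @ eloc)
    return energy, (onvs, amps, p, eloc), mask


def gradient_w(H, psi, W: SelectedSpace, floor_rel: float = AMP_FLOOR_REL) -> np.ndarray:
    """Gradient F of <H>_W with respect to the trainable parameters."""
    _, grad, _ = evaluate(H, psi, W, floor_rel)
    return grad


def evaluate(H, psi, W: SelectedSpace, floor_rel: float = AMP_FLOOR_REL):
    """Energy, gradient and diagnostics in one pass over W.

    Returns ``(energy, gradient, info)`` where info carries the floored
    member count and the local-energy variance.
    """
    cache = _as_cache(H)
    energy, (onvs, amps, p, eloc), mask = _weights_and_locals(cache, psi, W, floor_rel)
    d = psi.log_derivatives(onvs)
    resid = eloc - energy
    grad = 2.0 * ((p * resid) @ d)
    info = {
        "n_floored": int((~mask).sum()),
        "eloc_var": float(p @ resid ** 2),
    }
    return energy, grad, info


def extend_and_select(H, psi, W: SelectedSpace, ns: int | None = None,
                      k: int | None = None, rng=None) -> SelectedSpace:
    """Extend W through the Hamiltonian and keep the Ns largest amplitudes.

    The candidate pool is W itself plus at most ``K * Ns`` configurations
    sampled uniformly without replacement from the deduplicated connected
    frontier (connections of W minus W).  Ties in |Psi| break by ONV
    lexicographic order; with a fixed rng the update is deterministic.
    """
    cache = _as_cache(H)
    ns = int(ns if ns is not None else W.ns)
    k = int(k if k is not None else W.k)
    if ns < 1 or k < 1:
        raise ValueError("Ns and K must be >= 1")
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng

    union = cache.connected_union(W.onvs)
    # frontier = union minus current members, via basis indices when possible
    if cache.use_matrix:
        u_idx = onv_to_index(union, cache.nmodal)
        w_idx = onv_to_index(W.onvs, cache.nmodal)
        frontier = union[~np.isin(u_idx, w_idx)]
    else:
        w_set = {tuple(int(v) for v in row) for row in W.onvs}
        keep = [i for i, row in enumerate(union) if tuple(int(v) for v in row) not in w_set]
        frontier = union[keep]

    n_draw = min(k * ns, frontier.shape[0])
    if n_draw > 0:
        picks = rng.choice(frontier.shape[0], size=n_draw, replace=False)
        cand = np.concatenate([W.onvs, frontier[picks]], axis=0)
    else:
        cand = W.onvs
    # lexicographic pre-sort, then stable sort by descending |Psi|
    order = np.lexsort(cand.T[::-1])
    cand = cand[order]
    amps = psi.amplitudes(cand)
    sel = np.argsort(-np.abs(amps), kind="stable")[:ns]
    sel.sort()  # keep lexicographic order inside W
    return SelectedSpace(onvs=cand[sel], amps=amps[sel], ns=ns, k=k)
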