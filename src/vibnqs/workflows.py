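"""End-to-end optimization procedures.

The full pipeline for one vibrational state is

1. *Mean-field (VSCF) stage*: optimize a modal-product state (an MBF
   network with all weights and biases frozen at zero, the fixed modal
   matrix trainable), seeded with a harmonic configuration.
2. *Backflow stage*: freeze the optimized modal matrix as the fixed part,
   switch on the network weights (small random initialization) and optimize
   the ONV-dependent corrections with the same selected-configuration loop.
3. *Excited states*: repeat on a penalty-shifted Hamiltonian
   ``H + z * sum_j projector(Psi_j) - ZPE`` whose ground state is the next
   excited state.  The level-dependent shift z is estimated from the VSCF
   energy of the penalty Hamiltonian itself, which bounds the target
   transition from above, and is then enlarged by a safety margin.

Convergence is by a fixed step budget over a (possibly staged) schedule of
selected-space sizes Ns; the per-iteration log allows post-hoc checks.
"""

from __future__ import annotations

import heapq
import math
from dataclasses import dataclass, field, replace

import numpy as np

from . import engine
from .ansatz import ModalMatrix, init_mbf
from .core_optimizer import CoReHyper, CoReState, core_update, learning_rate
from .engine import OperatorCache, SelectedSpace, penalized_cache

__all__ = [
    "TrainingConfig",
    "StateRecord",
    "IterationLog",
    "run_vscf",
    "run_ground",
    "estimate_shift",
    "run_excited_ladder",
    "lowest_harmonic_onvs",
]

LOG_COLUMNS = ("step", "ns", "energy", "n_selected", "grad_norm", "eta", "eloc_var")

#: Converged states are flagged when their mutual overlap exceeds this.
OVERLAP_TOL = 1e-2


@dataclass(frozen=True)
class TrainingConfig:
    """Settings for the selected-configuration optimization.

    ``ns_schedule`` is a list of ``(Ns, steps)`` stages with non-decreasing
    Ns.  ``z_prime`` is the initial shift guess for excited-state targeting
    (default: four times the largest harmonic frequency).
    """

    nmax: int
    ns_schedule: tuple = ((128, 1000),)
    k: int = 1
    alpha: float = 1.0
    eta0: float = 0.05
    decay_rate: float = 0.1
    seed: int = 0
    pretrain: bool = True
    vscf_steps: int = 300
    vscf_decay: float = 0.01
    vscf_noise: float = 0.01
    init_sigma: float = 1e-3
    floor_rel: float = engine.AMP_FLOOR_REL
    z_prime: float | None = None
    shift_margin: float = 1.1

    def __post_init__(self):
        sched = tuple((int(ns), int(steps)) for ns, steps in self.ns_schedule)
        object.__setattr__(self, "ns_schedule", sched)
        if not sched:
            raise ValueError("the Ns schedule must not be empty")
        ns_vals = [ns for ns, _ in sched]
        if any(ns < 1 for ns in ns_vals) or any(b < a for a, b in zip(ns_vals, ns_vals[1:])):
            raise ValueError("Ns values must be positive and non-decreasing")

    @property
    def total_steps(self) -> int:
        return sum(steps for _, steps in self.ns_schedule)


@dataclass
class StateRecord:
    """A converged state: support, unit-norm amplitudes, energy, level."""

    support: np.ndarray       # (s, L) int
    amplitudes: np.ndarray    # (s,) unit norm
    energy: float
    level: int
    warnings: list = field(default_factory=list)

    def __post_init__(self):
        self.support = np.atleast_2d(np.asarray(self.support, dtype=np.int64))
        amps = np.asarray(self.amplitudes, dtype=float)
        norm = np.linalg.norm(amps)
        if norm == 0:
            raise ValueError("state record needs a nonvanishing amplitude vector")
        self.amplitudes = amps / norm


class IterationLog:
    """Per-iteration record of the optimization loop."""

    def __init__(self):
        self.rows: list[tuple] = []

    def append(self, *row):
        self.rows.append(tuple(row))

    @property
    def energies(self) -> np.ndarray:
        return np.asarray([r[2] for r in self.rows])

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("\t".join(LOG_COLUMNS) + "\n")
            for row in self.rows:
                fh.write("\t".join(repr(v) for v in row) + "\n")


def _optimize(cache: OperatorCache, psi, seed_onv, cfg: TrainingConfig,
              schedule, eta0: float, decay_rate: float, rng) -> tuple[float, SelectedSpace, IterationLog]:
    """Generic extend/select -> gradient -> CoRe loop over an Ns schedule."""
    total = sum(steps for _, steps in schedule)
    hyper = CoReHyper(eta0=eta0, decay_rate=decay_rate, total_steps=total)
    state = CoReState.zeros(psi.n_params, hyper)
    log = IterationLog()
    W = SelectedSpace.seeded(seed_onv, psi, schedule[0][0], cfg.k)
    t = 0
    for ns, steps in schedule:
        for _ in range(steps):
            W = engine.extend_and_select(cache, psi, W, ns, cfg.k, rng)
            energy, grad, info = engine.evaluate(cache, psi, W, cfg.floor_rel)
            if not math.isfinite(energy):
                raise FloatingPointError(
                    f"optimization diverged at step {t}: energy={energy!r}")
            eta = learning_rate(t, total, decay_rate, eta0)
            state, inc = core_update(state, grad, eta)
            psi.set_params(psi.get_params() + inc)
            log.append(t, ns, energy, len(W), float(np.linalg.norm(grad)), eta,
                       info["eloc_var"])
            t += 1
    # final refresh + evaluation with the converged parameters (no update)
    W = engine.extend_and_select(cache, psi, W, schedule[-1][0], cfg.k, rng)
    energy = engine.expectation_w(cache, psi, W, cfg.floor_rel)
    log.append(t, schedule[-1][0], energy, len(W), 0.0, 0.0, 0.0)
    return energy, W, log


def _vacuum(L: int) -> np.ndarray:
    return np.zeros(L, dtype=np.int64)


def _vscf_phi0(seed_onv, nmodal: int, noise: float, rng) -> ModalMatrix:
    onv = np.asarray(seed_onv, dtype=int)
    phi0 = ModalMatrix.one_hot(onv, nmodal).phi0
    phi0 = phi0 + rng.normal(0.0, noise, size=phi0.shape) if noise > 0 else phi0
    return ModalMatrix(phi0)


def _normalize_rows(phi0: np.ndarray) -> np.ndarray:
    out = phi0 / np.linalg.norm(phi0, axis=1, keepdims=True)
    # gauge: dominant coefficient positive
    sign = np.sign(out[np.arange(out.shape[0]), np.argmax(np.abs(out), axis=1)])
    return out * sign[:, None]


def run_vscf(H, seed_onv=None, cfg: TrainingConfig | None = None):
    """Mean-field stage: optimize the modal-product state.

    Returns ``(ModalMatrix, energy, log)`` where the energy is the
    selected-configuration estimate on the final W.
    """
    cache = engine._as_cache(H)
    if cfg is None:
        cfg = TrainingConfig(nmax=cache.nmodal - 1)
    if seed_onv is None:
        seed_onv = _vacuum(cache.L)
    rng = np.random.default_rng(np.random.SeedSequence([int(cfg.seed), 101]))
    phi0 = _vscf_phi0(seed_onv, cache.nmodal, cfg.vscf_noise, rng)
    psi = init_mbf(phi0, cfg.alpha, 0.0, cfg.seed, train_phi0=True, train_weights=False)
    schedule = ((cfg.ns_schedule[0][0], cfg.vscf_steps),)
    energy, _, log = _optimize(cache, psi, seed_onv, cfg, schedule,
                               cfg.eta0, cfg.vscf_decay, rng)
    return ModalMatrix(_normalize_rows(psi.phi0.phi0)), energy, log


def run_ground(H, cfg: TrainingConfig, seed_onv=None, phi0: ModalMatrix | None = None):
    """Ground-state pipeline: optional VSCF pretraining, then MBF training.

    A precomputed ``phi0`` (e.g. a shared VSCF solution) bypasses the
    pretraining stage.  Returns ``(ansatz, StateRecord, log)``.
    """
    cache = engine._as_cache(H)
    if seed_onv is None:
        seed_onv = _vacuum(cache.L)
    if phi0 is not None:
        pass
    elif cfg.pretrain:
        phi0, _, _ = run_vscf(cache, seed_onv, cfg)
    else:
        phi0 = ModalMatrix.one_hot(np.asarray(seed_onv, dtype=int), cache.nmodal)
    psi = init_mbf(phi0, cfg.alpha, cfg.init_sigma, cfg.seed)
    rng = np.random.default_rng(np.random.SeedSequence([int(cfg.seed), 202]))
    energy, W, log = _optimize(cache, psi, seed_onv, cfg, cfg.ns_schedule,
                               cfg.eta0, cfg.decay_rate, rng)
    record = StateRecord(support=W.onvs, amplitudes=W.amps, energy=energy, level=0)
    return psi, record, log


def estimate_shift(H, priors, z_prime: float, cfg: TrainingConfig, zpe: float,
                   seed_onv=None):
    """Level shift from the mean-field solution of the penalty Hamiltonian.

    Runs VSCF on ``H + z' * sum_j projector(Psi_j) - ZPE`` and returns its
    energy ``z_n``, which (variationally) bounds the target transition
    ``E_n - ZPE`` from above, together with the optimized modal matrix for
    reuse as the pretrained fixed part.
    """
    cache = engine._as_cache(H)
    supports = [(p.support, p.amplitudes) for p in priors]
    pen = penalized_cache(cache, supports, z_prime, -zpe)
    phi0, energy, _ = run_vscf(pen, seed_onv, cfg)
    return float(energy), phi0


def lowest_harmonic_onvs(w, nmax: int, count: int) -> np.ndarray:
    """The ``count`` harmonically lowest ONVs, energy- then lex-ordered."""
    w = np.asarray(w, dtype=float)
    L = w.size
    start = tuple(0 for _ in range(L))
    heap = [(0.0, start)]
    seen = {start}
    out = []
    while heap and len(out) < count:
        e, onv = heapq.heappop(heap)
        out.append(onv)
        for i in range(L):
            if onv[i] < nmax:
                nxt = onv[:i] + (onv[i] + 1,) + onv[i + 1:]
                if nxt not in seen:
                    seen.add(nxt)
                    heapq.heappush(heap, (e + float(w[i]), nxt))
    return np.asarray(out, dtype=np.int64)


def run_excited_ladder(H, n_states: int, cfg: TrainingConfig):
    """Solve the lowest ``n_states`` levels sequentially.

    Level 0 is the plain ground-state run; each higher level optimizes the
    penalty Hamiltonian built from all previously converged states, seeded
    at the corresponding harmonic configuration.  Energies of levels >= 1
    are recorded as absolute values; their transitions are the difference
    to the converged level-0 energy.
    """
    if n_states < 1:
        raise ValueError("n_states must be >= 1")
    cache = engine._as_cache(H)
    seeds = lowest_harmonic_onvs(cache.base.ff.w, cfg.nmax, n_states)
    _, record0, _ = run_ground(cache, cfg, seed_onv=seeds[0])
    records = [record0]
    zpe = record0.energy
    z_prime = cfg.z_prime if cfg.z_prime is not None else 4.0 * float(np.max(cache.base.ff.w))
    for level in range(1, n_states):
        lcfg = replace(cfg, seed=cfg.seed + 7919 * level)
        seed_onv = seeds[level]
        z_n, phi0 = estimate_shift(cache, records, z_prime, lcfg, zpe, seed_onv)
        z_opt = cfg.shift_margin * z_n if z_n > 0 else z_prime
        supports = [(p.support, p.amplitudes) for p in records]
        pen = penalized_cache(cache, supports, z_opt, -zpe)
        if cfg.pretrain:
            start = ModalMatrix(phi0.phi0)
        else:
            start = ModalMatrix.one_hot(seed_onv, cache.nmodal)
        psi = init_mbf(start, cfg.alpha, cfg.init_sigma, lcfg.seed)
        rng = np.random.default_rng(np.random.SeedSequence([int(lcfg.seed), 202]))
        _, W, _ = _optimize(pen, psi, seed_onv, lcfg, lcfg.ns_schedule,
                            lcfg.eta0, lcfg.decay_rate, rng)
        # report the bare-Hamiltonian energy of the converged state
        energy = engine.expectation_w(cache, psi, W, cfg.floor_rel)
        record = StateRecord(support=W.onvs, amplitudes=W.amps, energy=energy,
                             level=level)
        for prior in records:
            ov = _support_overlap(prior, record)
            if abs(ov) > OVERLAP_TOL:
                record.warnings.append(
                    f"overlap {ov:.3e} with level {prior.level} exceeds {OVERLAP_TOL}")
        records.append(record)
    return records


def _support_overlap(a: StateRecord, b: StateRecord) -> float:
    """<a|b> evaluated on the union of the stored supports."""
    ta = {tuple(int(v) for v in row): amp for row, amp in zip(a.support, a.amplitudes)}
    tb = {tuple(int(v) for v in row): amp for row, amp in zip(b.support, b.amplitudes)}
    return float(sum(amp * tb[key] for key, amp in ta.items() if key in tb))
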