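"""Random anharmonic force fields at controlled anharmonicity.

The benchmark distribution draws harmonic frequencies uniformly from
[1500, 3000] cm^-1 and cubic/quartic PES derivatives with magnitudes from
``N(lambda_nu, lambda_nu/5)`` in atomic units, where
``lambda_nu = base_au * wbar_au^(nu/2)`` and ``wbar`` is the midpoint
frequency 2250 cm^-1.  The base scale sets the anharmonicity regime:
50 cm^-1 (weak), 150 cm^-1 (moderate), 500 cm^-1 (strong).  Tensor entries
are damped by an off-diagonal decay factor of 1 / 0.1 / 0.01 for fully-,
semi- and off-diagonal index tuples.  Quartic entries are kept positive
(a bounded-below well along each diagonal), cubic entries get independent
random signs.  Sampled derivatives are reduced by the frequency product
root and stored in cm^-1; no Coriolis constants are sampled.

This module is the only place where the cm^-1 <-> Hartree conversion
appears; everything downstream works in cm^-1.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np

from .hamiltonian import ForceField
from .exactref import anharmonic_correction_exact

__all__ = [
    "CM1_TO_HARTREE",
    "AnharmonicityRegime",
    "REGIMES",
    "sample_force_field",
    "anharmonic_correction",
]

#: 1 cm^-1 in Hartree atomic units (hc-based conversion).
CM1_TO_HARTREE = 4.556335e-6

FREQ_LOW = 1500.0
FREQ_HIGH = 3000.0
WBAR_CM1 = 0.5 * (FREQ_LOW + FREQ_HIGH)

#: Decay factors: all indices identical / some identical / all distinct.
DECAY_FULL, DECAY_SEMI, DECAY_OFF = 1.0, 0.1, 0.01


@dataclass(frozen=True)
class AnharmonicityRegime:
    """A named anharmonicity scale: ``base`` in cm^-1."""

    label: str
    base: float

    def lam(self, order: int) -> float:
        """Mean magnitude ``lambda_nu`` of order-``order`` derivatives, a.u."""
        wbar_au = WBAR_CM1 * CM1_TO_HARTREE
        return self.base * CM1_TO_HARTREE * wbar_au ** (order / 2.0)


REGIMES: dict[str, AnharmonicityRegime] = {
    "weak": AnharmonicityRegime("weak", 50.0),
    "moderate": AnharmonicityRegime("moderate", 150.0),
    "strong": AnharmonicityRegime("strong", 500.0),
}


def _regime(r) -> AnharmonicityRegime:
    if isinstance(r, AnharmonicityRegime):
        return r
    try:
        return REGIMES[str(r)]
    except KeyError:
        raise ValueError(f"unknown anharmonicity regime {r!r}; choose from {sorted(REGIMES)}") from None


def _decay(idx: tuple) -> float:
    distinct = len(set(idx))
    if distinct == 1:
        return DECAY_FULL
    if distinct == len(idx):
        return DECAY_OFF
    return DECAY_SEMI


def sample_force_field(L: int, regime3, regime4, seed: int) -> ForceField:
    """Draw one random force field with cubic and quartic constants.

    A pure function of ``(L, regime3, regime4, seed)``.  Draw order is
    fixed: frequencies first, then cubic magnitudes and signs, then quartic
    magnitudes, each over the canonically sorted index tuples in
    lexicographic order.
    """
    if L < 2:
        raise ValueError("need at least two modes")
    r3, r4 = _regime(regime3), _regime(regime4)
    rng = np.random.default_rng(seed)
    w = rng.uniform(FREQ_LOW, FREQ_HIGH, size=L)
    w_au = w * CM1_TO_HARTREE

    phi: dict[int, dict[tuple, float]] = {}
    for order, reg in ((3, r3), (4, r4)):
        lam = reg.lam(order)
        tuples = list(itertools.combinations_with_replacement(range(L), order))
        mags = np.clip(rng.normal(lam, lam / 5.0, size=len(tuples)), 0.0, None)
        if order == 3:
            signs = rng.choice([-1.0, 1.0], size=len(tuples))
        else:
            signs = np.ones(len(tuples))
        table: dict[tuple, float] = {}
        for idx, mag, sign in zip(tuples, mags, signs):
            kappa_au = sign * mag * _decay(idx)
            phi_au = kappa_au / np.sqrt(np.prod(w_au[list(idx)]))
            table[idx] = float(phi_au / CM1_TO_HARTREE)
        phi[order] = table
    return ForceField(w=w, phi=phi)


def anharmonic_correction(ff: ForceField, nmax: int) -> float:
    """Exact ZPE of the full Hamiltonian minus the harmonic ZPE, cm^-1."""
    return anharmonic_correction_exact(ff, nmax)
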