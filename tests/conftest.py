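"""Shared fixtures and independent oracles.

The brute-force Watson matrix below expands every ladder string explicitly
(all index permutations of each force-constant entry, all 2^nu
creation/annihilation choices, applied ket-by-ket inside the truncated
space, then symmetrized).  It shares no code with the term-table assembly
in the package and serves as the matrix-element oracle.
"""

from __future__ import annotations

import itertools
import math

import numpy as np
import pytest

from vibnqs.hamiltonian import ForceField, enumerate_basis, onv_to_index


def apply_string(ket: tuple, amp: float, ops, nmax: int):
    """Apply ladder ops right-to-left; returns (ket, amp) or None.

    ``ops`` is a sequence of (mode, kind, sign) in *written* operator order.
    """
    for mode, kind, sign in reversed(ops):
        k = ket[mode]
        if kind == "create":
            if k >= nmax:
                return None
            ket = ket[:mode] + (k + 1,) + ket[mode + 1:]
            amp *= sign * math.sqrt(k + 1)
        else:
            if k == 0:
                return None
            ket = ket[:mode] + (k - 1,) + ket[mode + 1:]
            amp *= sign * math.sqrt(k)
    return ket, amp


def brute_force_matrix(ff: ForceField, nmax: int) -> np.ndarray:
    """Dense Watson matrix via explicit ladder-string expansion."""
    L, nmodal = ff.L, nmax + 1
    basis = enumerate_basis(L, nmodal)
    dim = basis.shape[0]
    mat = np.zeros((dim, dim))
    # harmonic part: diagonal sum_i w_i (n_i + 1/2)
    for b, ket in enumerate(map(tuple, basis)):
        mat[b, b] += float(sum(w * (n + 0.5) for w, n in zip(ff.w, ket)))

    def add_string(coeff, ops):
        for b, ket in enumerate(map(tuple, basis)):
            res = apply_string(ket, coeff, ops, nmax)
            if res is not None:
                new, amp = res
                r = int(onv_to_index(np.asarray(new), nmodal))
                mat[r, b] += amp

    for order, table in ff.phi.items():
        pref = 1.0 / (math.factorial(order) * 2.0 ** (order / 2.0))
        for idx, val in table.items():
            for perm in set(itertools.permutations(idx)):
                for kinds in itertools.product(("create", "annihilate"), repeat=order):
                    ops = [(m, k, 1.0) for m, k in zip(perm, kinds)]
                    add_string(pref * val, ops)

    if ff.coriolis is not None:
        for tau in range(3):
            xi, btau = ff.coriolis.xi[tau], float(ff.coriolis.b[tau])
            for i, j, k, l in itertools.product(range(L), repeat=4):
                if xi[i, j] == 0.0 or xi[k, l] == 0.0:
                    continue
                coeff = 0.25 * btau * xi[i, j] * xi[k, l] * math.sqrt(
                    ff.w[j] * ff.w[l] / (ff.w[i] * ff.w[k]))
                # X = b^dag + b, P = b^dag - b
                for s1 in (("create", 1.0), ("annihilate", 1.0)):
                    for s2 in (("create", 1.0), ("annihilate", -1.0)):
                        for s3 in (("create", 1.0), ("annihilate", 1.0)):
                            for s4 in (("create", 1.0), ("annihilate", -1.0)):
                                ops = [(i, *s1), (j, *s2), (k, *s3), (l, *s4)]
                                add_string(coeff, ops)
    return 0.5 * (mat + mat.T)


@pytest.fixture(scope="session")
def harmonic_ff3():
    return ForceField(w=[1600.0, 2100.0, 2900.0])


@pytest.fixture(scope="session")
def anharmonic_ff2():
    """Small 2-mode force field with cubic + quartic couplings."""
    return ForceField(
        w=[1700.0, 2400.0],
        phi={3: {(0, 0, 0): -40.0, (0, 0, 1): 12.0, (0, 1, 1): -6.0, (1, 1, 1): 25.0},
             4: {(0, 0, 0, 0): 30.0, (0, 0, 1, 1): 8.0, (1, 1, 1, 1): 18.0}},
    )
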