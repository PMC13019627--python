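# Methods

## Model

The package solves the vibrational Schrödinger equation for a Watson
Hamiltonian in dimensionless normal coordinates.  The operator is assembled
in second quantization from

* harmonic frequencies `w_i` (cm⁻¹),
* reduced force constants `Phi^(nu)` of orders 3–6 (cm⁻¹), related to raw
  PES derivatives by `Phi = kappa / sqrt(w_{i1} ... w_{inu})`,
* optional Coriolis terms `(1/4) B^tau xi_ij xi_kl sqrt(w_j w_l / (w_i w_k))
  X_i P_j X_k P_l` with `X = b† + b`, `P = b† − b`, three rotational
  constants `B^tau` and antisymmetric coupling matrices `xi^tau`.

The order-`nu` potential prefactor is `1/(nu! 2^(nu/2))` for every order —
the `nu = 3, 4` cases give the familiar `1/(12 sqrt 2)` and `1/96`, and the
same rule is continued to orders 5 and 6.

All Hamiltonian coefficients live in cm⁻¹.  The single cm⁻¹ ↔ Hartree
conversion (1 cm⁻¹ = 4.556335e-6 E_h) appears only in the random sampler,
whose scale parameters are specified in atomic units.

### Truncation conventions

Each mode keeps `Nmodal = Nmax + 1` Fock states.  Every ladder factor is
applied sequentially *inside* the truncated space (creation on a mode at
`Nmax` annihilates the state), so `(b†+b)^k` is the k-th power of the
truncated one-mode matrix, not the truncation of the untruncated power.
Sequential truncation of Coriolis strings with repeated modes can break
Hermiticity at the truncation boundary; since the untruncated operator is
Hermitian, the assembled operator is symmetrized term-by-term,
`H -> (A + Aᵀ)/2`.  Same-mode factors in a Coriolis string compose by
matrix product in the written operator order (i, j, k, l right-to-left
onto the ket).  Only canonically sorted index tuples of the symmetric
`Phi` tensors are stored; permutation multiplicity is folded into the term
coefficients as a multinomial factor.

The matrix-element path is verified against a brute-force oracle that
expands every ladder string explicitly (all index permutations, all 2^nu
creation/annihilation choices) — agreement to 1e-10 cm⁻¹ on small spaces.

## Ansätze

**Modal product (MP) / VSCF.**  `Psi(n) = prod_i phi0[i, n_i]`.  The VSCF
state is the energy-optimal MP state; here it is represented as a
modal-backflow network with all weights frozen at zero and the fixed modal
matrix trainable, so the mean-field stage runs through exactly the same
estimator and optimizer as the correlated stage.

**Modal backflow (MBF).**  `phi(n) = phi0 + delta(n)` with
`delta = tanh(W1 tanh(W0 n + b0) + b1)` reshaped to `L x Nmodal`; the
amplitude multiplies one coefficient per mode selected by that mode's
occupation.  Occupations are fed to the network as raw integers.  The
hidden width is `alpha * L` (hidden density `alpha`).  During backflow
training `phi0` is frozen — it is the fixed, mean-field part; the network
learns only the ONV-dependent correction.  All amplitudes are real: the
Hamiltonian is real symmetric and the targeted states can be chosen real.

**FNN baseline.**  The same one-hidden-layer body with a *linear* scalar
head `Psi(n) = w1 · h + b1`, used for architecture comparisons.  A bounded
(tanh) head was tried first and is unusable in practice: the optimizer
drives every selected configuration to |Psi| ≈ 1, where the
log-derivative `(1 − Psi²)/Psi` vanishes and the state can no longer
concentrate weight on the dominant configuration (runs stall hundreds of
cm⁻¹ above the ground state).  The linear head leaves the overall scale
free, which is immaterial since all estimators use normalized quantities.

Parameter derivatives of `log Psi` are exact chain-rule expressions
(product rule over modes, two tanh layers), checked against central finite
differences to ~1e-8 relative.

## Estimators

With a selected set `W` of configurations and amplitude cache `Psi(n)`:

* local energy `E_loc(n) = sum_{n'} <n|H|n'> Psi(n')/Psi(n)` over the
  *full* connected set of `n`;
* energy `<H>_W = sum_{n in W} P_W(n) E_loc(n)`, the asymmetric quotient
  `<Psi_W|H|Psi> / <Psi_W|Psi_W>`, with `P_W` the amplitude-squared
  distribution normalized over `W` (normalizing over anything larger is
  not computable and not self-consistent);
* gradient `F_m = 2 sum_W P_W(n) D_m(n) (E_loc(n) − <H>_W)` with
  `D = d log Psi / d theta`.

On the full space this is the exact Rayleigh quotient and its exact
gradient; on a subset it is the estimator used throughout.  It is not
strictly variational, but stays near-variational whenever `W` captures the
dominant amplitudes (asserted in tests against dense references).

**Selection update.**  The candidate pool is `W` itself plus at most
`K × Ns` configurations drawn uniformly without replacement from the
deduplicated connected frontier of `W`; the new `W` keeps the `Ns`
candidates of largest |Psi|.  Keeping `W` in the pool means selection can
only improve the represented weight.  Ties break by ONV lexicographic
order, and the sampling generator is part of the run configuration, so
whole runs are bit-reproducible.

**Amplitude floor.**  Configurations with |Psi| below 1e-12 of the largest
amplitude in `W` are dropped from `P_W` and from the gradient; they would
otherwise contribute unbounded `1/Psi` factors.

**Row caching.**  On enumerable spaces (dimension ≤ 2×10⁵ by default) the
sparse operator matrix is assembled once and Hamiltonian rows are sliced
from it; larger spaces fall back to per-ONV connection generation with
memoization.  Both paths are tested against each other.  Amplitudes are
evaluated once per distinct ONV per iteration.

## Optimizer

CoRe update (Adam family): bias-corrected first/second moments with a
Gaussian-decaying momentum coefficient
`beta1(t) = 0.5 + 0.4 exp(−((t−1)/100)²)`; defaults `eta0 = 0.05`,
`beta2 = 0.99`, `eps = 1e-8` (the regularizer is not specified anywhere
authoritative; 1e-8 is the Adam convention).  The bias correction raises
the *time-dependent* `beta1(t)` to the power `t`, as the update is usually
written; a running-product correction would differ only transiently.  On
top sits an exponential learning-rate schedule `eta(t) = eta0 · r^(t/T)`
(decay rate `r`, total budget `T`): written with a negative exponent the
schedule would grow for `r < 1`, so the decaying sign convention is used.
Convergence is by fixed step budget; the per-iteration TSV log (energy,
|W|, gradient norm, rate) supports post-hoc convergence checks.

The scale-free Adam-type step is what makes a *schedule* necessary: near a
minimum the normalized step approaches ±eta per parameter regardless of
gradient size, so the final learning rate bounds the attainable accuracy.
For harmonic-limit tests demanding 1e-6 cm⁻¹, a gentler `eta0 = 0.01` with
a strong decay (`r ~ 1e-6`) converges to machine precision; production
anharmonic runs use the default `eta0 = 0.05`, `r = 0.1`.

## Workflows

**Ground state.**  VSCF pretraining (optional) seeds `phi0`; the network
weights are initialized from `N(0, sigma²)` with `sigma = 1e-3`.  The
initialization noise must be small relative to the smallest meaningful
modal coefficients (often ~1e-3), otherwise the pretrained state is
audibly perturbed — at `sigma = 0.01` the iteration-0 energy sits several
cm⁻¹ off the VSCF energy on weak-anharmonicity systems, at `sigma = 1e-3`
within ~0.1 cm⁻¹, with no loss in final accuracy in either regime.
VSCF itself starts from a one-hot harmonic configuration plus `1e-2`
exploration noise (without it, the initial state has exactly zero
amplitude everywhere else and selection cannot grow).

**Excited states.**  Level `n` minimizes the penalty operator
`H + z_opt sum_{j<n} |Psi_j><Psi_j| − ZPE` over all previously converged
states.  The shift is estimated as the VSCF energy `z_n` of the penalty
operator with an initial guess `z'` (default `4 max_i w_i`), which bounds
the target transition from above; the optimization then uses
`z_opt = 1.1 z_n` — the 10 % margin keeps the penalty above the target
despite residual VSCF bias.  Prior states are known only on their stored
supports, so all overlaps `<Psi_j|Psi>` are evaluated on those supports.
Seed configurations for level `n` are the harmonically `n`-th lowest ONVs
(ties in harmonic energy broken lexicographically).  The reported energy
of a converged level is the *bare*-Hamiltonian expectation on its final
`W`; transitions subtract the pipeline's own converged level-0 energy.
Pairwise support overlaps above 1e-2 are flagged in the state record
rather than raised.

**Sequential Ns schedules.**  `TrainingConfig.ns_schedule` is a list of
`(Ns, steps)` stages with non-decreasing `Ns`, matching the practice of
growing the selected space as the state sharpens.

## Random Hamiltonian sampler

The benchmark generator draws, per Hamiltonian:

* `w_i ~ Uniform[1500, 3000]` cm⁻¹ (4 modes by default);
* cubic and quartic derivative magnitudes
  `|kappa| ~ N(lambda_nu, lambda_nu/5)` in atomic units, with
  `lambda_nu = base_au · wbar_au^(nu/2)`, `wbar = 2250` cm⁻¹, and base
  50 / 150 / 500 cm⁻¹ for the weak / moderate / strong regimes
  (equivalently: diagonal reduced constants of mean 50 / 150 / 500 cm⁻¹);
* an off-diagonal decay factor 1 / 0.1 / 0.01 for tuples with all / some /
  no repeated indices;
* quartic entries kept positive (each diagonal direction bounded below);
  cubic magnitudes get an independent uniform ±1 sign per unique tuple —
  only the magnitudes are constrained by the recipe, and random signs
  avoid a systematic tilt of the well.  Normal draws are clamped at zero
  (probability ~3e-7 per draw) rather than redrawn, to keep the stream a
  pure function of the seed.

No Coriolis constants and no orders above 4 are sampled.  The three
regimes produce anharmonic ZPE corrections in distinct ranges (medians
ordered weak < moderate < strong, the strong tail reaching the 10² cm⁻¹
scale), which is what makes the regime grid a meaningful difficulty axis.

What the sampler does *not* emulate: resonance structure of real
molecules (Fermi resonances arise only by chance), Coriolis couplings,
sextic terms, and mode counts beyond the enumerable range.  Passing the
grid therefore demonstrates correct optimization across anharmonicity
strengths, not transferability to large ab initio systems — those enter
through transcribed force-field files instead.

## Exact reference

Spaces up to a guard of 2×10⁶ states are enumerated (mixed-radix
little-endian, mode 0 fastest; the ordering is recorded with every
spectrum so eigenvectors are portable).  Small spaces (≤ 800) use dense
`eigh`; larger ones Lanczos (`eigsh`) with a seeded start vector.
Eigenvectors wrap into table-backed amplitude functions for zero-variance
tests: on an exact eigenvector the local energy is constant and the
gradient vanishes identically.

## Problem sizes used in the shipped checks

Test-suite and acceptance-script runs use 4-mode spaces at `Nmax = 6`
(2401 states), 5 samples per regime cell, and step budgets of 1000–2000 —
small enough to re-run routinely, large enough that the moderate-regime
ground-state error reaches the 0.01–0.1 cm⁻¹ scale and the regime-grid
mean stays well under 1 cm⁻¹.  The excited-state machinery is exercised
on 2–3-mode systems, including a synthetic sextic-plus-Coriolis field.

## Known limitations

* The asymmetric estimator's gradient is the standard covariance formula;
  off the full space it is an estimator of, not identically equal to, the
  derivative of `<H>_W` under selection updates.  At exact eigenstates both
  vanish; in practice the residual bias is far below the optimization
  floor.
* Penalty overlaps are support-restricted; states whose true overlap mass
  lies outside the stored supports could evade the penalty.  The overlap
  flag in the state record is the guard.
* Adam-type normalization bounds the attainable energy floor by the final
  learning rate; spectroscopic accuracy is comfortable, machine precision
  requires the gentle schedules noted above.
* No symmetry labels: degenerate or near-degenerate levels are resolved
  only as well as the penalty shifts separate them (ordering is asserted
  and flagged, not enforced).
* Mode counts are limited by the enumerable-reference philosophy of the
  test battery, not by the ansatz; the generic connection path exists but
  large-`L` production runs are out of the shipped scope.
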