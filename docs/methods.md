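# Methods

This note documents the models, conventions and numerical choices behind
`fedimer`, in the package's own terms. It states no empirical result that
the test suite or `scripts/acceptance.py` does not itself compute.

## Scope and data model

The package analyses *tabulated* electronic energies; it runs no
electronic-structure calculations. Every energy is an `EnergyRecord`
keyed by (structure, method, qualifier, basis, spin state, component,
relativistic flag); key uniqueness is enforced on every insertion. The
internal unit is hartree; reports are kJ/mol at one decimal and
couplings cm⁻¹ at one decimal. Conversion constants are fixed once:
1 hartree = 2625.4996395 kJ/mol = 219474.6314 cm⁻¹ (CODATA), so
1 cm⁻¹ = 0.01196266 kJ/mol; all round trips are identities to better
than 1e-12 relative.

The packaged benchmark tables print *relative* energies (against the HC
structure) or deviations from a cross-structure average. Every operation
that consumes them — relative energies, CBS extrapolation, basis-set and
multireference corrections — is linear and invariant under
structure-independent shifts, which is what makes shifted fixtures valid
inputs; this invariance is asserted by property tests.

## Yamaguchi spin projection

For a same-structure broken-symmetry/high-spin pair,

J = (E_BS − E_HS) / (⟨S²⟩_HS − ⟨S²⟩_BS),
E_PS = E_BS + (⟨S²⟩_BS − ⟨S²⟩_PS)·J.

J is defined operationally by this quotient; no −2J spin-Hamiltonian
prefactor is asserted, because this is the unique convention under which
the tabulated couplings and pure-spin corrections are mutually
consistent (the identity `ps_correction = J·⟨S²⟩_BS` for a singlet
target is checked to 1e-9 kJ/mol on every result). ⟨S²⟩ values measured
at the CCSD level are conventionally reused for CCSD(T) projections; the
API takes them explicitly so other choices are possible. Per-structure
J cannot be formed from relative-only energies, so `SpinPair` requires
same-structure pairs; the fixture path instead carries tabulated J plus
⟨S²⟩ and uses `ps_correction_from_coupling`.

The composite energy deliberately does **not** add the pure-spin
correction: the DMRG energies entering the multireference correction are
already pure-spin singlet energies, and stacking both would double-count
spin recoupling. The spin-projection table is reported alongside for
diagnosis only.

## CBS extrapolation

Correlation components follow E_X = E_∞ + A·X^(−β) with β = 2.4 by
default (configurable). The two-point formula
E_∞ = (Y^β·E_Y − X^β·E_X)/(Y^β − X^β) inverts this exactly, a property
tested to machine precision over random (E_∞, A, β). Mean-field energies
are never extrapolated: the limit is the value at the largest cardinal
(QZ here), and total energies are never extrapolated directly — the
pipeline enforces the mean-field/correlation split.

The basis-set correction to relative CCSD(T) energies is
Δ[CBS total − TZ total] per structure, with
CBS total = mean-field(QZ) + CBS(CCSD corr, DZ/TZ) + CBS((T), DZ/TZ).

The extrapolation uncertainty uses MP2 ladders at DZ/TZ/QZ: per
structure, the discrepancy d = E^(DZ/TZ→∞) − E^(TZ/QZ→∞); for a pair of
structures δ = |d_i − d_j|/2, reported rounded to whole kJ/mol. When no
pair is specified the pair maximising δ is selected automatically — the
most conservative choice, and the one consistent with picking the
structures whose extrapolated MP2 energies disagree most.

**Tolerances.** Quantities recomputed by extrapolation from one-decimal
printed inputs are compared at ±0.2 kJ/mol: the DZ/TZ weights
(≈ +1.61 / −0.61) amplify input rounding by up to ≈2.2×. Pure sums and
differences of printed values are asserted exactly (float noise only).
Machine-precision assertions are reserved for synthetic inputs.

## DMRG extrapolation and the multireference correction

DMRG energies from a reverse schedule are modelled as linear in the
discarded weight; the zero-weight limit is the intercept of an ordinary
least-squares fit (numpy polyfit, cross-checked against a closed-form
three-point least squares in the tests). Linear-in-discarded-weight is
the standard convergence model that the one-fifth error rule
presupposes; the fit residual is exposed so a future quadratic variant
can be compared. The error estimate is |E(max M) − E_extrap|/5, an
identity enforced on every `ExtrapolatedDMRG`. Series without discarded
weights (bond dimensions only) are refused rather than mapped through an
invented proxy. For noiseless variational input the intercept lies at or
below every input energy; with noise this may fail and is not asserted.

The multireference correction is ΔE = E_DMRG-act − E_CCSD(T)-act per
structure in a common active space, then referenced to the reference
structure. Offsets tabulated against a per-structure CCSD baseline are
equally valid inputs (the baseline cancels in the difference).
Extrapolation errors propagate onto relative corrections additively —
a conservative design choice, not a prescription. The uncertainty
attached to the whole correction is half its largest-magnitude relative
value (the largest error still compatible with the correction improving
the result), rounded to whole kJ/mol for reporting.

## Active-space diagnostics

"Furthest from 0 or 2" is read as maximising d(n) = min(n, 2 − n), which
ranks singly occupied orbitals (n ≈ 1) highest — consistent with
including all open-shell Fe orbitals. Ties break by ascending orbital
index, making selection deterministic and enlargement monotone (supersets).
The electron count of a selection is the rounded occupancy sum; it is not
pinned to the full-vector count, since different selections legitimately
carry different counts. `OccupancyVector.electron_count` is optional and
validated (sum within 1e-6) only when supplied, so unnormalised
diagnostic vectors remain usable.

The fractional census counts occupancies in [0.2, 0.8] ∪ [1.2, 1.8],
edges inclusive (occupancies exactly at an edge are measure-zero in
practice); the band is particle-hole symmetric and excludes n ≈ 1 by
construction.

## Composite assembly and uncertainties

total = uncorrected_TZ + mr_correction + basis_correction, exactly — no
rounding inside the sum; rounding (half-even) happens only at render
time. Reference-structure components must be identically zero. Ranking
is ascending by total with exact ties reported as tie groups. DFT
deviation statistics (mean and max absolute deviation from the
composite) are taken over the non-reference structures only; including
the reference, whose deviation is identically zero, would dilute the
mean and is inconsistent with the benchmark convention.

The two uncertainty components are added linearly ("adding" the
uncertainties), treating them as fully correlated; quadrature is
available but off by default. In `paper` mode each component is rounded
to whole kJ/mol before summation (matching the ±N reporting convention:
9.6 → 10, 7.9 → 8, total 18); `exact` mode keeps full precision.

## Synthetic data

The generator emulates only the statistical/functional forms the
analysis assumes — power-law basis ladders, Yamaguchi-consistent BS/HS
pairs, DMRG series linear in discarded weight, occupancy vectors with a
planted number of band-fractional orbitals — no Hamiltonians, orbitals
or solvation. Each generator is the exact inverse of its analysis
operation in the noiseless limit; `gen_study` emits a full bundle plus
an analytic answer key (true composite totals, ranking, DFT deviation
stats) computed in closed form from the planted truth, the central test
architecture of the repository. Defaults mirror the magnitudes of the
real system: mean-field deviations of ±150–250 kJ/mol converging at QZ,
multireference offsets of −9 to −28 kJ/mol, basis corrections up to
~26 kJ/mol, couplings of −94 to −389 cm⁻¹ with ⟨S²⟩_BS ≈ 3.8–4.6 and
⟨S²⟩_HS ≈ 20. Noise is independent zero-mean Gaussian per energy and off
by default — the emulated calculations are deterministic; it exists only
to test estimator robustness (unbiasedness of the noisy-ladder
extrapolation is checked by Monte Carlo over 200 draws). Passing tests
on synthetic bundles demonstrate algebraic correctness of the pipeline,
not the physical adequacy of power-law or linear convergence models for
any particular system.

## Problem sizes

Everything operates on four-structure tables, three- or four-point
ladders and ≤ 5-point DMRG series; the full suite and the acceptance
script each run in a few seconds on one CPU.

## Known limitations

- Only the two-state Yamaguchi scheme; no spin-adapted CC or multi-state
  projection.
- Only the power-law two-point CBS family and the largest-basis
  mean-field rule; no exponential or three-point schemes.
- The DMRG extrapolation is linear OLS; sweep-level detail (schedules,
  point selection) is out of scope, so printed extrapolation-error
  magnitudes are reproduced in order, not bit-exactly.
- Relativistic (X2C) corrections, solvation shifts and largest-CSF
  weights are carried as data/metadata only; no operation computes them.
- No thermochemical corrections (ZPE, thermal, solvation) are applied.
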