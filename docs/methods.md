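# Methods

## Scope and model

The package solves the active-space electronic Schrödinger equation for a
noncovalent dimer by sample-based quantum diagonalization (SQD), entirely
classically.  The physical model is the second-quantized active-space
Hamiltonian (E₀, h_pr, (pr|qs) in chemist notation with 8-fold permutational
symmetry), defined over M spatial orbitals with fixed electron counts
(N_α, N_β).  Determinants are 2M-bit configurations, alpha block first,
orbital 1 at bit 0.  Internal units are Hartree and Ångström; the single
conversion constant 627.509474 kcal/mol per Hartree lives in
`sqd_binder.units`.

Binding energies use the supramolecular bound/unbound protocol: one energy
for the interacting dimer, one for the same dimer with the monomers rigidly
translated to 48.000 Å anchor separation, both in the *same* active-space
definition, so that active-space truncation errors largely cancel in the
difference.  The unbound reference is computed once per system and shared
across the distance grid.  Potential-energy-surface geometries are generated
by rigid translation of monomer B along the anchor A→B axis; monomers are
not relaxed along the scan (an open choice — the translation preserves every
intra-monomer distance exactly, which the tests assert to 1e-10 Å).

## CI engine

Slater–Condon matrix elements are assembled with antisymmetry phases
computed by sequential application of creation/annihilation operators on the
occupation bitmasks; with all-alpha-then-all-beta spin-orbital ordering and
per-sector number conservation, phases factorize per sector.  The engine is
validated entrywise (1e-12) against a brute-force Jordan–Wigner operator
matrix built in the test suite — an oracle that shares no code with the
engine.

Subspaces are Cartesian products A×B of unique alpha and beta occupation
strings.  This product closure is the only reading consistent with the
production run settings (10·10³ raw samples per batch yielding the full
245,025 = C(12,8)² determinant space for the water dimer).  The projected
Hamiltonian is built sparsely by enumerating single/double excitations of
each support determinant and keeping those inside S.

The lowest eigenpair comes from a Davidson iteration: diagonal
preconditioner, start vector at the lowest-diagonal determinant, search
space capped at 25 vectors with restart, residual threshold 1e-8 Hartree
(the production threshold is not published; this default is configurable).
Spaces of dimension ≤ 64 are diagonalized densely.  Cross-checks against
`numpy.linalg.eigh` and ARPACK (`scipy.sparse.linalg.eigsh`) are part of the
suite.

The Hamiltonian variance ΔH = ⟨Ĥ²⟩ − ⟨Ĥ⟩² is evaluated with the full,
unprojected Hamiltonian action by exact enumeration of all single/double
excitations of the support (no stochastic estimation), since the
extrapolation treats ΔH as exact.  Values in [−1e-10, 0] are clipped to 0.

## LUCJ ansatz

The ansatz is the truncated local unitary cluster Jastrow state
|Ψ⟩ = e^{−K̂₂} e^{K̂₁} e^{iĴ₁} e^{−K̂₁} |x_RHF⟩.  Parameterization from
closed-shell doubles amplitudes proceeds by double factorization: the
symmetric matrix t2[(ia),(jb)] is eigendecomposed; writing the rank-1
excitation operator of eigenpair k as Â and S = A + Aᵀ, D = A − Aᵀ, the
operator identity Â² − (Â†)² = (i/2)[(X₊)² − (X₋)²] with X± = S ∓ iD turns
e^{T̂₂−T̂₂†} into a product of rotated diagonal-Coulomb factors
U e^{iĴ} U†, J = ±(λ/8) w wᵀ, with U and w from the eigendecomposition of
the complex Hermitian X±.  The untruncated factor product is verified in the
tests against the brute-force Fock-space e^{T̂₂−T̂₂†}|RHF⟩ (residual decays
as the cube of the amplitude scale).

Truncation at "1.5 layers": the dominant factor supplies K₁ (anti-Hermitian,
complex in general) and J₁; the trailing half-layer rotation e^{−K̂₂}
carries the unitarized singles amplitudes e^{T̂₁−T̂₁†} when t1 is supplied
and is zero otherwise.  Singles are ignored by default.  Reading the
half layer instead as the *entering rotation of the dropped second factor*
was implemented and rejected: that rotation is O(1) even for vanishing
amplitudes, so the truncated state would not reduce to the reference in the
weak-correlation limit.  No variational re-optimization of the parameters is
performed.

The locality mask `line_heavyhex` zeroes J₁ couplings except same-spin
nearest neighbours (|p−r| ≤ 1) and opposite-spin same-orbital pairs,
emulating the heavy-hex connectivity constraint; `dense` allows all pairs.
The mask is applied after construction.

The state is evaluated exactly over the full CAS determinant basis: orbital
rotations by Krylov propagation (`scipy.sparse.linalg.expm_multiply`) of the
one-body generator in CI space — one CI vector in memory, no explicit
operator exponential — and the Jastrow layer as the diagonal phase
exp(i xᵀJx) per determinant (full double sum over spin-orbital pairs, the
idempotency n̂² = n̂ handling the diagonal).  Amplitudes stay complex
end-to-end; sampling uses |amplitude|².  When no coupled-cluster engine is
available, `mp2_amplitudes` provides perturbative doubles from the
active-space integrals with orbital energies taken from the diagonal of the
active-space Fock matrix (off-diagonal Fock elements are neglected — a
deliberate, documented approximation adequate for initializing an ansatz).

## Synthetic device

Measurement is emulated by i.i.d. multinomial sampling from |⟨x|Ψ⟩|², then
independent per-bit flips with probability ε (default 0.01; production
shot counts 200·10³/300·10³ are presets per system).  This reproduces the
one device property the recovery algorithm relies on — broken
particle-number conservation — and deliberately omits correlated errors,
readout-error matrices and calibration data; conclusions about real hardware
noise beyond number breakage are outside what passing tests show.  The
actual device noise level is not published; ε is a package choice.  Sample
sets are multisets (counts), serialized as `bitstring count` rows under a
JSON metadata header so hardware dumps could be ingested.

## Configuration recovery

Occupations are initialized from the correct-particle-number outcomes.  Each
corrupted shot is repaired per spin sector, inserting electrons at empty
orbitals with probability ∝ n_p (removing with ∝ 1 − n_p), one at a time
without replacement, with a uniform fallback when all weights vanish.  The
exact repair law used on hardware data is not printed in the literature this
emulates; the proportional scheme implements its stated intent and is kept
behind a single function so alternatives can be swapped.  Raw shots are
re-recovered from scratch each iteration; K batches are drawn with
replacement (independent multinomial subsampling — "subsets" without
assuming disjointness); occupations update as the uniform (unweighted)
average over the K batch eigenstates, per the printed formula.  Fixed step
counts (10/10/5 per production system) plus an optional 1e-6 Hartree
early-stop are the defaults.

## Extrapolation and binding curves

Zero-variance extrapolation fits E against x = ΔH/E² by unweighted ordinary
least squares (no weighting is published); the intercept estimates the
eigenstate energy and the intercept standard error is the reported
uncertainty.  Production ladders use batch sizes 9/11/14·10³ (three points)
or 5.5/6.5/7.5/8.5·10³ (four points); both bound and unbound energies are
extrapolated with identical ladders.  Curve minima are reported at the grid
arg-min, without interpolation.

## Synthetic data and what passing tests show

`random_hamiltonian` draws a symmetrized Gaussian h and an 8-fold
symmetrized Gaussian eri (reproducible, no physical structure);
`single_reference_hamiltonian` adds well-separated orbital energies and
scales down the two-body terms to mimic a weakly correlated molecule.  The
toy study conditions are: (4e,4o) and (4e,5o) systems, doubles amplitudes of
scale 0.5, the heavy-hex locality mask, 10⁴ shots, K = 4 batches of 2,500,
ε ∈ {0, 0.02}; extrapolation calibration uses nested product subspaces of
sizes 6–9 strings per sector of the (4e,5o) toy, ranked by ground-state
marginal weight — the near-eigenstate regime where the linear
energy-variance relation actually holds (on strongly random Hamiltonians at
coarse truncation it does not, and the package makes no claim there).
These sizes keep the full suite and the acceptance script in the seconds
range.  Passing them shows the algorithmic chain is exact where it should be
and statistically calibrated where it is stochastic; it does not validate
basis-set or active-space choices for real molecules, which enter through
FCIDUMP inputs produced by an external engine.

## Known limitations

- `prepare_active_space` needs pyscf; without it the package is
  FCIDUMP-only by design.
- The CI engine is pure Python/scipy; practical subspace dimensions are
  ~10⁴–10⁵, well below the 10⁸-determinant production runs of the original
  hardware study.
- Excited states, spin adaptation, S² purification and perturbative
  corrections are out of scope.
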