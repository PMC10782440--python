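# Methods

`evbkit` implements a desk-scale version of the empirical valence bond (EVB)
free-energy workflow used to obtain thermodynamic activation parameters of a
two-state chemical reaction — the kind of campaign run for the chorismate →
prephenate rearrangement in water and in chorismate-mutase enzymes — with
toy systems small enough that every stage can be validated against analytic
or quadrature oracles.

## The model

Two *diabatic* states describe the reaction: state 1 is an ordinary force
field with the reactant bonding pattern (the breaking ether-like bond
present as a Morse term), state 2 the product pattern (the forming
carbon–carbon bond present instead).  Both act on the same atoms.  The
reactive surface is the lower eigenvalue of

    H = [[eps1,  H12],
         [H12,   eps2 + delta_alpha]]

`delta_alpha` (the gas-phase shift of the product state) and `H12` (a
constant off-diagonal coupling) are the only free parameters.  The constant
form of `H12` is assumed deliberately: the two-parameter calibration below
determines exactly one (delta_alpha, H12) pair, which would be
under-determined if H12 carried a coordinate dependence.

Force-field terms: Morse bonds `D(1-exp(-a(r-r0)))^2`, harmonic angles
`k/2 (theta-theta0)^2`, periodic torsions `k(1+cos(n phi - delta))`,
harmonic impropers, Coulomb (`332.0636 kcal·Å/(mol·e²)`) and
Lennard-Jones 12-6 with geometric-mean combination and 0.5 scaling of 1-4
electrostatics and LJ (OPLS convention).  `kB = 0.0019872041 kcal/(mol·K)`.
No nonbonded cutoff is used anywhere — toy systems are small, and the
reacting fragment must in any case interact with its full surroundings.
Every evaluation returns the six-term breakdown partitioned into
reacting–reacting (rr), reacting–surrounding (rs) and
surrounding–surrounding (ss) groups; the two group-sum identities
(rr+rs+ss per term, terms summing to the total) hold by construction and
are asserted to 1e-9 in the tests.

One bookkeeping choice the two-topology setup forces: the 1-2/1-3
exclusion sets of the two states are *unioned* and applied to both
topologies.  Without this, the pair across the broken bond sees a bare
Coulomb interaction in the product state and collapses into a spurious
tight ion pair.

## Sampling

Configurations are Boltzmann-sampled on the mapping potentials
`eps_m = (1-λ) eps1 + λ (eps2 + delta_alpha)` with BAOAB-discretized
Langevin dynamics.  A weak-coupling bath was the historical choice for this
protocol, but it does not sample the canonical ensemble, which the
free-energy estimators require; Langevin friction replaces it, with the
six-stage heat-up schedule retained for protocol fidelity (stage
temperatures interpolate linearly from 1 K to the target; stage relaxation
times of 10 fs for the first five stages and 100 fs for the last map to
friction as γ = 1/τ).  The trailing-window kinetic-temperature check
accepts a deviation of 10% of the target, widened to 3 statistical standard
errors when the trailing average has too few effective samples to resolve
10% (unavoidable for few-particle systems).

Windows are visited in λ order; each starts from the previous window's
final configuration, runs a discarded re-equilibration, then production.
Seeds: `master + 10000·replicate + window_index` per window, with the slot
9999 reserved for the heat-up, so every protocol is bit-reproducible from
its master seed.  A window failure aborts that replicate and the rest
continue.

Desk-scale protocol sizes (package defaults, chosen once):

| system | windows | timestep | window production | replicates |
|---|---|---|---|---|
| 1D reference | 51 (Δλ = 0.02) | 1 fs | 3 ps (+0.3 ps equil) | 10 |
| 3D toys | 51 | 0.5 fs | 1.3 ps (+0.2 ps equil) | 3 |

The full-scale campaign this emulates used 100 replicates of 100 ps
windows; the desk protocol keeps the window count and replicate design and
shortens the dynamics, which the oracle comparisons below show is
sufficient for the 1D reference to ~0.1 kcal/mol.

## Free-energy estimators

Adjacent-window free-energy differences use the Zwanzig exponential
average, computed in both directions and averaged
(`ΔG = ½(ΔG_fwd − ΔG_bwd)`), which cancels the leading-order bias on
overlapped windows; an effective-sample-size warning fires below 5%
overlap.  The profile along the energy gap `Δε = eps1 − eps2'` applies the
umbrella correction

    dg(Δε_n) = ΔG(λ_m) − kT ln ⟨δ(Δε − Δε_n) exp(−β(Eg − eps_m))⟩_m

per window and combines windows per bin by count-weighted averaging.
Numerical choices: 101 bins over the sampled gap span by default (41 for
the 3D toys, whose span is ~800 kcal/mol wide); bins with fewer than 10
frames masked; exponentials via log-sum-exp.  RS/TS/PS landmarks are found
by locating the interior maximum with the largest *prominence* over its
flanking minima (robust against small noise dips in the basin tails —
picking the two lowest minima naively can pair the global minimum with a
noise dip), then RS/PS are the lowest bins on either side and ties break
toward lower Δε.  The TS is the raw bin maximum; no spline refinement.
ΔG‡ ≥ 0 and the profile is normalized to dg(RS) = 0.  A masked region that
separates the two basins raises a sampling-gap error rather than returning
a profile that silently spans it.

Replicates are analyzed independently (one profile each; mean ± SEM of
ΔG‡/ΔG0 across replicates is the reported statistic).  For plotting and
oracle comparison, replicate profiles on shared bin edges are combined by
count-weighted averaging, masking bins supported by fewer than half the
replicates; profile accuracy is assessed between the RS and PS minima —
the basin walls beyond the minima are sparse-tail artifacts with no
bearing on the extracted thermodynamics.

## Calibration

`calibrate_evb` fits (delta_alpha, H12) to target activation and reaction
free energies by a damped two-dimensional secant (Broyden) iteration on
the residual vector, damping 0.7, max 25 iterations, initial Jacobian
reflecting the near-separation of effects (delta_alpha moves ΔG0 ≈ 1:1 and
the barrier by ≈ 0.5; H12 lowers the barrier ≈ 1:1).  Barrierless iterates
halve H12 and retry.  The evaluator is pluggable: quadrature (deterministic,
1D) or full re-simulation with fresh per-iterate seeds, where the
stochastic tolerance is `max(stated tolerance, 2× replicate SEM)`.  The
fitted pair is then *frozen* and reused unchanged for catalyst variants —
transferability of reference-reaction parameters is the method's modeling
contract.

The shipped 1D reference calibrates to ΔG‡ = 24.5, ΔG0 = −12.8 kcal/mol at
298 K with quadrature residuals < 1e-3 in ~9 iterations
(delta_alpha ≈ −12.86, H12 ≈ 7.22 kcal/mol for the shipped well
parameters).  The reaction free-energy reference value carries a known
ambiguity in the source energetics (−12.8 vs −13.2 kcal/mol from different
estimates); both are accepted inputs and −12.8 is the shipped default.

## Arrhenius decomposition

Over a 25 K span, ΔG‡(T) = ΔH‡ − TΔS‡ is treated as linear (temperature-
independent ΔH‡/ΔS‡; no heat-capacity term).  Ordinary least squares of
mean ΔG‡(T)/T against 1/T — on per-temperature replicate means, matching
how such campaigns report mean ± SEM — gives ΔH‡ as the slope and −ΔS‡ as
the intercept.  Parameter standard errors come from a nonparametric
bootstrap over replicates within each temperature (1000 seeded resamples);
published SEMs for such fits are not always internally consistent (one
source table prints an activation free energy SEM of ±12.1 alongside
sub-kcal errors elsewhere, evidently a typo), so the package always
reports its own bootstrap errors.  The default ladder is six temperatures,
288–313 K in 5 K steps; the source protocol's equilibration text cites a
slightly different range (283–308 K) than its production ladder — one
ladder (288–313 K) is used for everything here.

## Activation-enthalpy decomposition

Neglecting the pressure–volume term, ΔH‡ is approximated by TS−RS
differences of ensemble-averaged potential energy.  Only terms involving
the reacting fragment are computed: ΔU_rr (within the fragment) and ΔU_rs
(fragment–surroundings), with the fragment total split into bonded
(bond/angle/torsion/improper) and nonbonded (elec/vdW) parts.  The
surroundings self-energy term ΔU_ss is *never* computed — it involves
numerically very large bath energies — and the result type has no field
for it.  Per-frame state mixing uses the ground-state eigenvector weights
(w1, w2), since the ground surface is the physical one.  The constant
delta_alpha shift is not part of any force-field term and is excluded from
the decomposition.

Ensembles are selected by gap bin: frames within ±1 bin of the RS (TS)
landmark, pooled across windows and replicates (whether the original
analysis selected frames at fixed λ or by gap bin is not documented;
gap-binned is the choice here).  Note that under λ-pooled sampling the TS
ensemble is typically the *larger* one — the mapping potential exists
precisely to over-sample the barrier — and the ±1 vs ±2 bin sensitivity is
systematic at desk-scale bin widths (~4% of ΔU_tot,r for the shipped toy),
which the tests bound in relative terms.

Geometric observables (the breaking- and forming-bond distances and three
backbone torsions of the fragment, the analogs of the C5–O7/C1–C9
distances and ring torsions tracked for chorismate) are measured per frame
with means ± SEM; torsions are reported in degrees in (−180, 180] and
collinear quadruples raise an error.

## Synthetic systems: what they emulate, and what they do not

**1D oracle** — a single particle on two displaced equal-force-constant
harmonic diabats.  Equal curvature makes the gap *linear* in the
coordinate, so gap bins map to exact intervals and the profile can be
computed by Gauss–Legendre quadrature to machine accuracy: the independent
oracle for every sampled estimator.  The `reference` preset
(k = 300 kcal/mol/Å², minima 1 Å apart → reorganization energy
≈ 150 kcal/mol) is sized so calibration to (24.5, −12.8) succeeds with a
physically sensible H12 ≈ 7 kcal/mol.

**3D toy reaction** — a six-atom chain whose state-1 topology holds a
breaking bond (atoms 2–3) and whose state-2 topology closes the ring with
a forming bond (atoms 0–5), emulating the pericyclic rearrangement's
geometry change; state-dependent charges grow the negative charge on the
ether-oxygen analog (atom 3) in the product state.  Ten uncharged LJ
particles in a flat-bottom restraining sphere emulate a solvent droplet
(no constraint algorithm is needed because the bath is monoatomic).  Two
toy-specific choices matter and were tuned for sampling physics, not for
any target number:

* the reacting Morse wells are *wide* (a = 0.6 Å⁻¹): with narrow wells the
  mapping potential snaps first-order-like through ring closure and leaves
  an unbridgeable hole in the gap histogram; wide wells give partially
  formed bonds intermediate energies so the window minima sweep the gap
  continuously;
* flat-bottom distance tethers (active beyond 4.2 Å) on both reacting
  pairs emulate a binding pocket: without them the open-chain end-to-end
  distance diffuses freely in the end states, making the basins along the
  gap unboundedly broad and the replicate estimates hysteretic.  Applied
  as system restraints, identical in both states, they cancel exactly in
  the gap coordinate.

The `catalyst` variant adds a fixed +0.9 e charge 2.8 Å from atom 3 (with
the −0.9 e counter-charge 9 Å away on the opposite side, both on
effectively immobile carrier particles), stabilizing the product-like
charge distribution at the transition state.  With the calibrated
Hamiltonian frozen, this lowers the sampled ΔG‡ by ≈ 3 kcal/mol and
makes the fragment–surroundings electrostatic activation term negative
(≈ −7 kcal/mol vs exactly 0 for the uncharged-surroundings reference) —
the qualitative electrostatic transition-state stabilization signal that
distinguishes enzyme from water environments in the real campaign.

What passing these tests does *not* show: the toys have no protein, no
explicit water, no long-range electrostatics beyond direct sums, and
six-atom "chemistry"; quantitative enzyme numbers (ΔH‡ of the two enzymes,
their decomposition magnitudes) are outside what any desk-scale surrogate
can reproduce.  The pipeline is validated on (i) exact/quadrature closures
and (ii) sign-level catalysis contrasts.

**Arrhenius fixtures** — `ΔG‡(T) = ΔH − TΔS + noise`, seeded, noiseless
when σ = 0; used to verify exact recovery, unbiasedness, and bootstrap
scaling of the regression.

## Degenerate inputs and failure modes

Nonpositive Morse distances, overlapping atoms (pair distance < 1e-6 Å),
mismatched coordinate shapes, λ outside [0, 1], collinear dihedrals,
windows with < 10 frames, profiles with no interior maximum
(barrierless), unsampled regions separating basins, < 3 temperatures, and
non-finite forces during integration all raise typed errors; the CLI maps
them to exit codes (2 usage, 3 data, 4 numerical).

## Known limitations

* Count-weighted window combination, not MBAR/WHAM; fine at these overlap
  levels, but the estimator is not variance-optimal.
* H12 constant; no distance dependence.
* The 3D toy's λ-dragging leaves a small hysteresis contribution in the
  replicate scatter (visible as ~0.3–0.9 kcal/mol SEMs at desk scale).
* Single-temperature ΔH‡/ΔS‡ linearity; no ΔCp‡.
* Bootstrap SEs understate errors when replicate counts are very small
  (< 3 per temperature).
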