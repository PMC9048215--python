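# Methods

## Scope and model

`atsf` predicts conformational-adaptive (CA) partial charges for methyl
pentofuranosides. The model chain is: pseudorotation-driven conformer
generation → categorized atom-centered symmetry-function descriptors →
per-element random-forest regression → charge-neutrality correction →
electrostatic evaluation (per-atom correlations, linear fits, point-charge
dipoles). Quantum-chemical reference charges are out of scope; a synthetic
oracle (below) or user-supplied charge tables play that role.

## Pseudorotation and conformer embedding

A five-membered ring conformation is parameterized by phase P and amplitude
τₘ through the cosine law θⱼ = τₘ·cos(P + 144°·j) over the five endo-cyclic
torsions (θ₀ = C1–C2–C3–C4, …, θ₄ = O4–C1–C2–C3). The inverse uses the
discrete Fourier projections τₘcos P = (2/5)Σθⱼcos(144°j),
τₘsin P = −(2/5)Σθⱼsin(144°j), which are algebraically exact on cosine-law
torsion sets; the pair (forward, inverse) round-trips to 1e-9 on the whole
sampling grid. The phase of a planar ring (τₘ → 0) is mathematically
undefined; requesting it raises an error, and embedding tolerances widen
below τₘ = 9° where the phase becomes ill-conditioned.

The sampling grid runs τₘ = 3°…45° in 3° steps and P = 0°…354° in 6° steps,
τₘ-major. The 360° phase endpoint is excluded as identical to 0°, giving
60 × 15 = 900 ring conformations. Exo-cyclic torsions are drawn i.i.d.
uniform on [0°, 360°); rotamer-well sampling was deliberately not imposed —
uniform coverage stresses the descriptors over the whole torsion circle.

Cosine-law torsions with a single amplitude are not exactly realizable by a
closed ring with fixed bond lengths; the ring is therefore embedded by
nonlinear least squares over internal coordinates (three free ring bond
angles plus two trial torsions; bonds hard at C–C 1.526 Å, C–O 1.410 Å; a
weak 104.5° angle restraint selects the chemically sensible branch). The
residual inconsistency lands almost entirely outside the pseudorotation
subspace: re-measured (P, τₘ) agree with the target to better than 0.05°
across the grid, far inside the (2°, 1°) acceptance tolerance. All other
atoms are rebuilt by Z-matrix extension reusing the molecule's own internal
coordinates, after which each named exo-cyclic torsion is driven rigidly to
its target (hit to < 0.1°). Embedding is deterministic given the target
specification and independent of the input frame.

### Fixtures

The eight packaged methyl D-pentofuranosides (ara/lyx/rib/xyl × α/β) use
idealized internal coordinates (tetrahedral angles, C–H 1.09 Å, O–H 0.96 Å)
with Haworth-style face assignments at C1/C2/C3 and the D-configuration at
C4. They are stand-ins with correct topology, typing and stereochemical
distinctness — no claim is made that they match quantum-optimized
geometries.

## Descriptors

Radial and angular symmetry-function components use the cosine cutoff
fc(R) = 0.5(cos(πR/R_c) + 1) with R_c = 99 Å (effectively no cutoff at this
molecular size), R_s = 1.0 Å, η = 1.0 Å⁻², λ = +1, ζ = 1. The angular
three-body Gaussian width η_ang defaults to 0: reusing η = 1.0 Å⁻² there
would weight every bonded triple by ~e⁻⁷ and erase the angular signal, so
the width is exposed as a separate parameter instead. Angular sums count
each unordered atom pair once (an ordered convention would only rescale by
2 at ζ = 1).

Layouts are occupancy-driven: a radial slot per category with ≥ 1 atom, an
angular slot for {J, K}, J ≠ K, when both categories are occupied, and for
{J, J} when the category holds ≥ 2 atoms. This is the unique rule consistent
with all three component counts on a 23-atom furanoside: 3 + 6 = 9
(element), 8 + (28 + 5) = 41 (atom type; three singleton types Of, Os, H2
contribute no same-type pair), 23 + 253 = 276 (atom name). Slots are ordered
lexicographically and named (`rad:Cf`, `ang:Cf|Oh`, …) for serialization.

A naive triple-loop implementation of each component is kept as the test
oracle; the vectorized path must agree to 1e-12, and rigid-motion
invariance is verified to 1e-10.

## Synthetic charge oracle

The oracle emulates the properties that matter about conformation-dependent
fitted charges without any electronic-structure content:

    q_i = base(tᵢ) + α · s(tᵢ) · Σⱼ s(tⱼ) · exp(−R_ij / ρ)

over force-field atom types t, followed by clamping aliphatic hydrogens
(types H1, H2) to exactly 0 and removing the residual net charge by a
uniform shift over the remaining atoms. It is deterministic, smooth,
invariant under rigid motion (distances only), and exactly neutral.

Constants are packaged artifact values, chosen once and frozen: base charges
on carbohydrate force-field scales (e.g. Oh −0.66 e, Ho +0.43 e), decay
ρ = 1.25 Å, coupling α = 0.35 with sensitivities concentrated on
oxygen-bearing types (O types −0.5…−0.6, Ho 0.55, C types 0.05, aliphatic H
0.03). Two considerations fixed this pattern during design: conformational
variation must sit on the ~0.01–0.1 e scale of real fitted-charge
intercepts, and the signal must live mainly on hydroxyl/ring-oxygen
distances so that a depth-6 forest over the 41 atom-type components can
recover it (the oracle's design contract) while every element still varies
with conformation. What passing the recovery test shows is that the
descriptors resolve distance-mediated conformational signal; it does not
show that real RESP charge surfaces, which contain through-bond polarization
and charge transfer, are equally learnable.

## Regression and neutrality correction

One `RandomForestRegressor` per element (C, O, H) with 200 trees, max depth
6, minimum 6 samples per split and per leaf, seeded for bit reproducibility.
The hydrogen model trains only on hydroxyl hydrogens by default: aliphatic-H
targets are identically zero under the charge convention and would only add
degenerate rows (a configuration flag restores them). Predictions report the
across-tree mean (raw charge) and standard deviation σᵢ; clamped atoms get
raw 0, σ 0.

The neutrality correction spreads Δ = Σq_raw − q_net as
qᵢ ← qᵢ − Δ·σᵢ/Σσ. σ-weights (rather than σ²) are the default — the
correction lands preferentially on atoms the ensemble disagrees about — with
σ² behind a switch; when every σ is zero the limit of equal uncertainty
(uniform spread over non-clamped atoms) applies. The corrected sum is exact
to 1e-12 and clamped atoms never move.

Models are pooled across all eight furanosides; per-molecule training is a
caller choice (pass fewer molecules).

## Evaluation

Per-atom-name Pearson r and OLS fits y = a·x + b (x = reference,
y = predicted) over all test conformers; zero-variance series are flagged
explicitly rather than returned as NaN. Dipoles use μ = k·Σqᵢrᵢ with
k = 4.80320 D/(e·Å) fixed to six significant figures. The scalar
"dipole difference" statistic is | |μ_A| − |μ_B| | by default (magnitude
convention, recorded in the report); a vector-difference-norm mode is
provided since either reading of the scalar is defensible.

## Problem sizes

The packaged demonstration and the acceptance property run the pipeline at a
reduced grid — τₘ ∈ {15°, 30°, 45°}, P in 30° steps (36 ring
conformations), 10 exo-cyclic combinations, 8/2 split, all eight molecules —
chosen as the smallest sampling that still exercises every stage and leaves
enough test conformers (576) for stable per-atom statistics. The full
900 × 30 protocol runs through the same code paths (the split logic is
exercised at full scale in the tests) and takes proportionally longer.

## Known limitations

- Fixture geometries are idealized; bond lengths/angles are not
  quantum-optimized, so absolute descriptor values differ from those any
  specific published geometry would give (all counting and invariance
  properties are geometry-independent).
- The ring-closure least squares distributes the cosine-law inconsistency
  over all five torsions; worst-case torsion residuals reach ~2° at large
  τₘ even though the recovered (P, τₘ) is accurate to < 0.05°.
- The synthetic oracle is pairwise and distance-mediated; it cannot emulate
  anisotropic or through-bond electrostatic effects.
- Only {C, H, O} molecules with a single five-membered ring are supported;
  hexoses, protonation states, and general force-field typing are out of
  scope.
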