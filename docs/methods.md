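# Methods

This note records the models implemented in `tensiofit`, the numerical
and design choices behind them, what the synthetic-data generators do and
do not emulate, and the known limitations — in particular the statistical
identifiability of the two fitted models.

## Adsorption: the two-state reorientation equation of state

The isotherm module implements the reorientation (two-orientation) model
for a soluble surfactant at a fluid interface. A molecule adsorbs either
flat, occupying the maximum molar area ω₁, or upright, occupying the
minimum area ω₂; the exponent α weights the flat state. With
Π = γ₀ − γ the implemented equation of state is

    b·c = (1 − e^{−Πω/RT}) / [ (ω₁/ω₂)^α e^{−Πω₁/RT} + e^{−Πω₂/RT} ],
    ω   = (ω₁X + ω₂)/(1 + X),   X = (ω₁/ω₂)^α e^{−Π(ω₁−ω₂)/RT}.

The typeset forms of these equations in the surfactant literature are
easy to mis-parse, so the parse adopted here is pinned by reduction
checks that the test suite asserts:

- ω(0) → (ω₁+ω₂)/2 when α = 0, ω(Π→∞) → ω₂ (full compression);
- the Henry (dilute) limit c ≈ Π·ω(0) / (b·RT·[(ω₁/ω₂)^α + 1]) agrees
  with the full expression to better than 1% at Π = 10⁻⁵ N/m;
- c(Π) is strictly increasing on [0, γ₀], giving a unique inverse.

**Coverage bridge.** The model family identifies θ = 1 − e^{−Πω/RT} and
Γ = θ/ω. These are adopted here as the coverage/adsorption bridge even
though equation-of-state papers rarely write them explicitly. One
consequence worth knowing: θ(Π) is *not* globally monotone. Because
ω(Π) falls steeply while the layer reorients, the product Πω can dip
slightly once θ exceeds ≈0.99 (for the saponin/MCT parameter sets the
maximum sits just below the plateau pressure). The tests therefore
assert monotonicity only in the rising, physically-informative regime.

**Units.** All internal computation is SI (N/m, m²/mol, mol/m³, K);
mN/m and g/L appear only at I/O boundaries. The exponent arguments
Πω/RT are order one only in SI, which is the reason for the hard
convention. Mass→molar conversion assumes an average molar mass of
1650 g/mol for the saponin extract (configurable per
`InterfaceSystem`). The default temperature is 293.15 K (20 °C, the
tensiometry condition) and the default pure-interface tension
25.4 mN/m (water–MCT).

**Numerics.** Exponent arguments are clamped at |x| ≤ 700 so that limit
evaluations saturate instead of overflowing. The public inverse
`equilibrium_pressure` uses Brent's method on the guaranteed bracket
[0, γ₀] with a 10⁻¹⁰ N/m tolerance followed by a short Newton polish;
the round-trip c → Π → c is identity to 10⁻⁸ relative. Inside the
least-squares objective a vectorized 60-step bisection is used instead
(≈10⁻²⁰ N/m bracket width), which is an order of magnitude faster for
whole datasets.

**Fitting.** `fit_isotherm` minimizes the unweighted SSE in tension
(mN/m). Positivity and the ordering ω₁ > ω₂ are enforced by optimizing
log ω₂, log δ (with ω₁ = ω₂(1+δ)), α ≥ 0 and log b. When requested (the
default), a detected cmc trims the data to c ≤ cmc, since the equation
of state describes sub-micellar adsorption only. Concentrations the
trial model cannot reach are clipped to the γ→0 boundary so the
objective stays finite during exploration. The optimizer is SciPy's
trust-region reflective least squares (through lmfit) capped at 2000
function evaluations — on noise-free data convergence to the generating
parameters is exact well before the cap; on noisy data the cap stops
unproductive wandering along the sloppy valley described below. A
dataset whose tensions all equal γ₀ carries no adsorption signal and is
reported as a failed fit rather than pushed to a b → 0 boundary.

**cmc detection.** The estimator mirrors the visual convention of the
surfactant literature: in (ln c, γ) coordinates, fit a descending line
to the pre-break points and a horizontal plateau to the post-break
points for every admissible split, keep the split with minimal total
SSE, and intersect the two segments. A plateau is accepted only when
the descending slope is negative, the two-segment SSE is at most half
that of a single global line (monotone data therefore return "no cmc"),
and the intersection lies inside the sampled range. On noise-free
piecewise data the breakpoint is recovered exactly; at 0.2 mN/m
Gaussian noise it is recovered to within ~15%.

**Identifiability.** Over an experimentally accessible sub-cmc range
the tension curve is nearly linear in ln c, and the equation of state
is then sensitive mainly to ω₁ (the slope) and to the *product*
b·(ω₁/ω₂)^α (the position). For the saponin-in-acetic-acid parameter
set, the denominator term containing ω₂ only starts to dominate at
γ ≈ 2 mN/m — below the physical plateau at 5.3 mN/m — so ω₂ and b are
individually constrained only by weak curvature. In consequence,
noise-free refits recover all four parameters exactly, while at
percent-level multiplicative tension noise the maximum-likelihood
estimates of ω₂ and b wander along the sloppy valley by large factors
(the acceptance script quantifies this honestly). This is a property
of the model-plus-design information content, not of the optimizer:
practitioners who need sharp ω₂/b values must either extend the design
into the dilute knee with very low noise or fix parameters from
independent evidence.

**Open point: plateau adsorption.** Evaluating Γ = θ/ω at the plateau
pressure with the published water/MCT parameters gives ≈1.66 μmol/m²
(the acetic row gives ≈1.02), whereas the corresponding published
maximum-adsorption figures are 1.2 ± 0.1 and 0.9 ± 0.1 μmol/m². The
discrepancy is expected if the published values were obtained from a
Gibbs-slope analysis of the data rather than from the model bridge;
both numbers are reported by the acceptance script and no agreement is
forced.

## Dilational rheology

`E_lvdt` and `E_extended` implement the classical and extended
Lucassen–van den Tempel moduli with ξ = √(ν_D/2ν) and λ = √(ν_k/ν).
The square roots are part of the definitions (typeset sources often
drop them); the parse is validated by the classical half-power point
|E(ξ=1)| = E₀/√5 and by the monotone rise of |E| towards E₀. E₀ is the
Gibbs elasticity |dγ/d ln Γ| — only magnitudes are fitted, consistent
with modulus-only data. ν_k = ∞ (`math.inf`) is an explicit sentinel
selecting the classical model rather than a huge float.

The extended form reduces to the classical one as ν_k → ∞. Note the
convergence rate differs between representations: the modulus converges
as ν_k⁻¹ while the residual imaginary part decays only as ν_k^(−1/2),
so limit checks are asserted on |E| (the measured quantity) — at
ν_k = 10⁶ Hz the modulus matches the classical curve to 3×10⁻⁷
relative over the 0.005–0.2 Hz instrument band.

**Fitting.** `fit_viscoelasticity` fits |E|(ν) with unweighted SSE
(phase, when present, is ignored), log-parameters for positivity, and
five restarts from log-normally jittered initials (deterministic for a
given seed) to mitigate local minima of the 4-parameter surface.
ν_k is bounded above by 10³ Hz. Two degenerate outcomes are detected
and reported as a recommendation to use the classical model: ν_k
pushed within a decade of its bound, and — more commonly — a nested
model comparison in which the 2-parameter classical fit matches the
extended SSE to within 1% (when E₁ → E₀ the kinetic factor cancels and
ν_k becomes arbitrary, so the bound criterion alone is not reliable).

The same sloppiness caveat applies as for the isotherm: with ten
modulus points on 0.005–0.2 Hz, noise-free sweeps are recovered
exactly, but at 1% modulus noise E₀ and ν_D trade off against E₁ and
ν_k along flat likelihood directions and individual estimates spread by
tens of percent. The fitted curve itself remains within the noise
scale (asserted in the tests).

**Isotherm link.** `nuD_from_isotherm` evaluates ν_D = D(∂c/∂Γ)² along
the isotherm, with ∂c/∂Γ = (dc/dΠ)/(dΓ/dΠ) by central finite
differences (relative step 10⁻⁶, validated against a dense secant to
0.1%). ν_D is linear in D and rises steeply with concentration over the
dilute-to-moderate band; very close to the plateau the derivative ratio
turns over, so the qualitative "increases with concentration" trend is
asserted only below that region. Pressures where dΓ/dΠ vanishes are
rejected.

## Aggregation statistics

The dwell criterion is applied to the raw per-frame minimum distance
(sampled every 0.05 ns in the reference protocol): a frame is
aggregated iff it belongs to a maximal run of frames with distance
strictly below the 0.25 nm cutoff whose observed duration is at least
5 ns (inclusive). Runs truncated by the start or end of the trajectory
are judged by their observed duration. The aggregation probability is
the aggregated-frame fraction (equivalently time fraction, since dt is
uniform); the hydrogen-bond energy is averaged over aggregated frames
and reported as absent when there are none; "hydrophobic bonding" is
flagged when the trajectory-average hydrophobic score reaches 5
(inclusive at the boundary). Block averaging over 5 ns windows is
non-overlapping and reporting-only — it never feeds the dwell
criterion, whose definition refers to the monitored distance itself.
Replicate runs (three starting configurations in the reference
protocol) are summarized by the mean probability and its half-range.

Both monotonicity properties — probability non-increasing in the dwell
minimum and in a lowered cutoff — are asserted over random
trajectories, and the labeling is checked frame-exactly against an
independent run-length-scan oracle.

## Emulsion stability

V_rel = V_emul/V_tot with validation that the first sample is fully
emulsified (V_rel = 1 at formation, as the double-syringe protocol
guarantees). `time_to_fraction` interpolates the first downward
crossing linearly between samples and returns "absent" when the
fraction is never reached within the observation window. Scan profiles
use heights in mm with 0 at the cell bottom, increasing upward (oil
creams upward in oil-in-water emulsions; the instrument's native
convention is unstated, so this one is fixed and documented), cell
height 56 mm. Opaque bands are maximal runs with transmission at or
below a 1% threshold; the tracked boundary is the lower edge of the
uppermost band. The 0.5 mm ruler resolution of the volume logs is
metadata, not an enforced grid. No kinetic model (exponential or
stretched) is fitted to V_rel(t): the reference data are raw curves.

## Synthetic data

The generators emulate the study conditions, not the physics of
measurement:

- **Isotherms** — 12 log-spaced concentrations from 10⁻³ g/L up to the
  preset cmc (0.79 g/L for saponin in water, 0.14 g/L in acetic acid,
  against γ₀ = 25.4 mN/m at 293.15 K), tensions from the equation of
  state times (1 + σ·N(0,1)). Multiplicative Gaussian noise is used for
  tensions and moduli because drop-shape instrument errors scale with
  the signal.
- **Sweeps** — log-spaced frequencies over the 0.005–0.2 Hz
  oscillating-drop band; moduli from the extended model.
- **Trajectories** — alternating exponential on/off dwells (a two-state
  renewal process), 200 ns at 0.05 ns sampling by default, with
  distances drawn uniformly inside (0.10–0.24 nm) or outside
  (0.30–3.0 nm) the contact cutoff, hydrogen bonds only in the
  aggregated state (energies ~N(20, 3) kJ/mol), and hydrophobic scores
  near 2 (below the bonding threshold, as for the chitosan–saponin
  system). The true pre-filtering occupancy is recorded in metadata.
- **Creaming** — an ideal opaque emulsion column whose lower (serum)
  boundary rises at a constant speed inside the 56 mm cell, with the
  paired V_rel curve consistent with the cleared height fraction.

What they deliberately do *not* emulate: surfactant partitioning into
the oil, adsorption kinetics (only equilibrium tensions are generated),
correlated or heteroscedastic instrument drift, force-field physics or
distance autocorrelation within dwell states, droplet-size evolution
and backscattering structure. Passing recovery tests therefore
demonstrates correctness of the estimators under the stated noise
model, not robustness to every artifact of real measurements.

Determinism: a fixed seed makes every generator byte-reproducible;
different seeds change only the noise realization, never the recorded
truth.

## Problem sizes

The test suite and the acceptance script use the study-scale problem
sizes throughout: 12-point isotherms, 10-point frequency sweeps,
200 ns / 4000-frame trajectories (with one 50 μs trajectory as a
long-run oracle and 2 μs trajectories for the consistency check), a
10⁶-point pressure grid for the brute-force inversion oracle, and
10–20 replicate noisy datasets for the recovery studies.

## Known limitations

- The noisy-data recovery of (ω₂, b) and of (E₀, ν_D) is limited by the
  information content of the designs, as discussed above; the package
  reports what the data support rather than regularizing towards
  expected values.
- The cmc estimator assumes a single break between a log-linear descent
  and a flat plateau; pre-micellar aggregation or slow drift produce
  softer breaks it will localize less well.
- Electrostatic (Davies-type) corrections, multi-mode reorientation
  models and surfactant partitioning are out of scope.
- The aggregation module consumes pre-extracted observables; it does
  not parse MD engine trajectory formats or detect hydrogen bonds from
  coordinates.
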