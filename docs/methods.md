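# Methods

## The model family

Nine nested ODE models describe the digestion of a short fluorogenic
peptide (substrate S, cleaved once into product P) by the 20S
proteasome at bulk concentration `E0` (µM). Concentrations are in µM
and time in minutes throughout; `E0` is derived from the assay mass via
a configurable molar mass (default 700 kDa) and reaction volume
(default 100 µl), so 0.125 µg/100 µl ≈ 1.79 nM.

**M1** is Michaelis–Menten (`vmax`, `KM`). **M2** replaces it with a
two-site-modifier scheme in which substrate and product each bind a
catalytic site (affinity constants `KaS`, `KaP`, Hill coefficient `na`)
and a non-catalytic modifier site (`KiS`, `KiP`, `ni`); site
interaction is parameterised by `α > 0` and the catalytic activity of
modifier-bound enzyme by `β ∈ (0, 1]`. Intermediate enzyme complexes
are treated in quasi-steady state, which gives the closed-form rate

    v_hydr = na·kp·E0·(S^na/KaS)·(1 + β·S^ni/(α·KiS) + β·P^ni/(α·KiP))/x
    x = 1 + A + B + A·B/α,  A = S^na/KaS + P^na/KaP,  B = S^ni/KiS + P^ni/KiP

The nine-term partition denominator factors exactly as `1 + A + B +
A·B/α`; the engine uses the factored form. The leading factor is `na`
as the rate law is stated; a different convention (e.g. number of
catalytic-site copies) is absorbed by rescaling `kp`. **M3/M4** add a
positive feedback of product on catalytic binding or on the hydrolysis
rate; the feedback form is the simplest saturating choice, multiplying
`KaS⁻¹` (M3) or `kp` (M4) by `1 + ε·P/(Kf + P)`. These two variants
exist to be rejected by model selection, so the exact saturation form
is not critical.

**M5–M9** add the compartment structure: an outer gate site G1 binds
external peptide (`kon`, `koff`), gate-bound peptide enters the chamber
(`v_in`), inner peptide reaches an inner gate site G2 by translocation
(`τ·f_in·G2/E0`, with the printed 1/E0 normalisation of all
inner-site binding terms) and exits (`v_out`). The chamber holds at
most `C` molecules per proteasome; influx carries the saturating factor
`tanh(max(0, E0·C − S − P))`, a heuristic that shuts the gate as the
chamber fills. The argument is clamped at zero — an over-full chamber
must not produce reverse flux — and is treated as dimensionless with an
implicit 1 µM scale. Efflux carries no capacity term. Regulation
multiplies both transport rates by
`(1 + Xenh·occ_E/E0) / (1 + Yinh·occ_I/I0)`, where `occ_E` is the
occupancy of a transport-enhancing site (M6: on the outer surface,
binding outer peptide; M7–M9: inside, binding inner peptide) and
`occ_I` of a transport-inhibiting site (M8: inside; M9: outside,
binding `h` outer peptide molecules per site at rate
`Ion·f_out^h·Ifree` — the Hill exponent `h` also enters the peptide
bookkeeping, each occupied site holding `h` molecules). A free-diffusion
variant of M5 (symmetric first-order exchange instead of gate binding)
is available behind a flag but is not part of the selection ladder.

Site totals default to one effective site of each class per proteasome
(`G1_tot = G2_tot = Ereg_tot = I0 = E0`) and are configurable.

The equation system as typeset in the source material contains sign
inconsistencies (the inner-gate and inhibitor-site balances); signs
here are fixed by requiring that the four site totals and the total
peptide moiety `Sout + Pout + G1Sout + G1Pout + S + P + G2S + G2P +
EregS + EregP + h·(IS + IP)` are exactly conserved, which the test
suite verifies to machine precision and along full trajectories to
better than 1e-6 relative at solver tolerances rtol 1e-8 / atol 1e-10.

### One engine, many models

S and P are two species of a generic multi-peptide compartment engine:
`n` peptide species share the gates, the capacity (the inner load is
volume-weighted via per-species capacities, `load_k = Σ_j (C_k/C_j)
f_in,j`), the regulatory sites and the active-site partition
denominator (`A` and `B` summed over species). Cleavage channels map a
substrate species to its products with a relative rate. The same engine
therefore powers the single-substrate models (one channel S→P), the
co-substrate protocol (four species, two channels, competitive active
sites through the joint denominator) and the polypeptide extension
(six species, four channels). The engine kernel is numba-compiled;
integration uses LSODA (`scipy.integrate.odeint`) with defaults
rtol 1e-8 / atol 1e-10 (1e-6 / 1e-9 inside ABC loops, where the
distance is noise-dominated). Species are clamped at zero inside rate
evaluations to protect fractional powers against integrator
undershoot; trajectories are rejected if any species drops below
−1e-6 µM or a conserved total drifts.

### Observable

The fluorogenic readout counts every cleaved bond regardless of where
the product resides, so the default product observable is the total
product moiety `Pout + G1Pout + P + G2P + EregP + h·IP` — identically
the time-integral of the hydrolysis flux. An "outer product only" mode
is available. Initial velocities are least-squares slopes over the
15/30/45/60 min samples, matching the standard assay analysis.

## Synthetic data and fixtures

`proteokin.synthetic` emulates the assay designs: mouse digestions at
80–480 µM (LLVY-like) and 160–640 µM (LLE-like), human six-point
designs from 20 to 640 µM for all three substrates, duplicate
replicates, and multiplicative log-normal measurement noise
`exp(σ·Z)` with default σ = 0.05 (fluorescence errors scale with
signal; an additive option exists). The default σ is a fixture choice —
the real assay's noise magnitude is not modelled mechanistically.

The per-substrate fixture parameter sets are synthetic, chosen once so
that each substrate class displays its characteristic signature at
realistic magnitudes (velocities of a few to tens of nM/min, capacities
of hundreds of molecules):

* **LLVY-like** — transport-limited and enhancer-dominated: the
  external inhibitor equilibrates within minutes and suppresses the
  early velocity; inner product accumulating on the enhancer site then
  raises the velocity over the first ~90–120 min.
* **LLE-like** — fast transport, rapid chamber filling to near
  capacity, strong external substrate inhibition (`Yinh = 10`,
  half-saturating near 150 µM) and inefficient catalysis (β = 0.01);
  its dose–response has an interior maximum.
* **VGR-like** — intermediate; immuno-isoform variants scale transport
  and active-site constants while sharing the chamber capacity.

What the generator does *not* emulate: fluorescence-unit calibration,
plate-reader drift, inner-filter effects, pipetting error correlation
across wells, and enzyme inactivation. Passing the recovery tests
therefore demonstrates the estimator's correctness under the stated
noise model, not robustness to real-world systematics.

## ABC-SMC

The sampler is a standard sequential ABC: population 0 samples the
prior; each subsequent population draws a particle from the previous
weighted population, perturbs it with a component-wise uniform kernel
(half-width 0.5× the previous population's range per parameter, in
log10 space for log-scale parameters), and accepts when the distance is
below ε, set adaptively as the 0.3 quantile of the previous
population's distances. Importance weights are `prior(θ) / Σ_j w_j
K(θ|θ_j)`. A proposal budget (50× the population size) bounds each
population; degenerate populations (effective sample size < 1.5) stop
the run with a warning. Runs are bit-reproducible from the seed.

The distance between datasets is the root-mean-square of per-cell
differences of replicate-mean product, each cell normalised by the
maximum observed product of its concentration series, so all
concentration series contribute comparably. Fitting targets the
replicate mean.

Model selection samples a model indicator jointly with parameters: the
proposal resamples a model from the previous population's marginal,
switches to another model with probability 0.25, then perturbs a
particle of that model; weights carry the model-kernel and
parameter-kernel mixture densities. The prior model probability is
uniform — 0.5 for pairwise comparisons, 0.25 for the joint comparison
of the four non-compartmental models. The staged scheme compares M1–M4
jointly, advances the winner through pairwise comparisons against
M5…M9 in order of increasing complexity, and finally re-tests the
overall winner against all other models.

Default priors are log-uniform over four orders of magnitude around the
fixture values; the capacity `C` has a uniform prior on [10, 1000]
molecules.

## Scaled-down study sizes

The quantitative studies are deliberately small so a full pass runs on
one CPU in minutes: selection experiments use 100 particles, three
concentrations (40/160/640 µM) and six time points; the recovery study
fits the six-concentration human-style design (six time points, 5%
noise, 200 particles, up to six populations) with `v_in`, `kp` and `C`
free and all other parameters fixed at their generating values — a
deliberate reduction that makes the 200-particle budget meaningful and
focuses the check on the transport/capacity parameters the analysis
turns on. The recovery fixture is LLE-like because its chamber fills to
near capacity within the time course; the capacity then shapes the
curvature of the kinetics and `C` is identifiable separately from
`v_in` (in a far-from-capacity regime the two are confounded through
`v_in·tanh(E0·C)`). `kp` is weakly identified in this transport-limited
regime, and its posterior stays broad — the recovery criterion for it
is interval coverage, not precision.

## Sensitivity analysis and capacity checks

Rate-limiting steps are probed by scaling one reaction class at a time
— gate affinity (`kon`×f, or `koff`÷f as an alternative), influx,
hydrolysis, translocation, efflux, or gate size (`v_in` and `v_out`
jointly) — and measuring the product fold change after 60 min at
320 µM. The perturbation factor defaults to 2 (large enough to beat
solver noise, small enough to read as a local probe) and is recorded in
every output. Over a posterior the analysis reports the weighted
distribution, with both mean and median summaries. Chamber occupancy
counts free inner peptide, inner-gate-bound and (for an inside
enhancer) enhancer-bound peptide per proteasome; the product fraction
is undefined (NaN) while the chamber is empty. Capacity consistency
reports pairwise ratios of fitted `C` values against inverse
molecular-volume ratios, unrounded, with agreement scores
`min/max`.

## Polypeptide extension

A hypothetical 23-residue substrate carries cleavage sites after
residues 8 and 15 (configurable). The six species (S, A, B, C, AB, BC)
each have their own transport scale; capacities scale inversely with
residue count (volume ∝ length). The active site is simplified: one
shared two-site-modifier denominator over species-summed occupancies
with common `KaS, KiS, KiP, na, ni, α, β, kp` and per-site relative
rates. Cleavable species (S, AB, BC) bind catalytically via `KaS` and
modulate via `KiS`; terminal products via `KiP` only. Default
affinities sit at the inner-concentration scale (~`E0·C` ≈ 0.2 µM)
so modifier occupancy actually engages during a digestion — with
µM-scale affinities the inner pools, bounded by the chamber capacity,
would never activate the nonlinearity and site usage could not drift.

Cleavage-site usage is the per-site hydrolysis flux (the model analogue
of the experimentally measured site-specific cleavage strength, SCS).
Two normalisations are reported: share-of-total (sums to 1 across
sites) and per-site fold change relative to the first sample. Behaviour
classification fits a slope to each site's fold-change curve and labels
the pair flat / both_decrease / both_increase / divergent, with a
dead-band of 0.15 total relative change below which a trend counts as
flat; one flat and one moving site classify by the moving site's sign.
Relative usage drifts over time even with product re-entry disabled
(product `kon` = 0), because partially processed fragments retained
inside the chamber are re-cleaved at site-specific rates that shift as
the partition denominator grows — re-entry is not needed to explain
usage variation.

## SBML

Compartmental models export to SBML Level 3 as species, parameters and
one rate rule per species; the MathML (including `tanh` and `max`) is
generated from a symbolic reconstruction of the rate equations that the
test suite checks against the numerical engine. Import restores the
parameter values exactly and rebuilds the model from an embedded
annotation. A structural validator (namespace, species/compartment
references, per-rule MathML) guards the documents.

## Known limitations

* The ABC perturbation kernel is uniform and component-wise; correlated
  posteriors mix more slowly than with a covariance-adapted kernel.
* The co-substrate model shares topology-level constants (Hill
  coefficients, α, β, enhancement/inhibition factors, `h`) from species
  A; only species-level constants differ between the two peptides.
* The `tanh` capacity heuristic fixes the crossover softness at 1 µM;
  capacity estimates are interpretable relative to that convention.
* Fixture parameter sets are synthetic and qualitative: they reproduce
  the class of each substrate's kinetic signature, not experimental
  posterior values.
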