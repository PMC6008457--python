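# Methods

## Model formalism

A `KineticModel` is a compartmental reaction network.  Internal species
obey first-order kinetics, `dc_i/dt = (1/f_i) Σ_r S_ir v_r`, with `f_i`
the volume fraction of the species' compartment (so a flux expressed per
gram of tissue produces the correct concentration change in a small
compartment).  External species are boundary conditions: they are clamped
to a `BoundaryProfile` and never integrated, which makes the plasma the
sole source and sink of carbon and nitrogen — there are no implicit
sources on internal species.  Units are fixed throughout: mM for
concentrations, µmol/g/h for fluxes, hours for time, mV for membrane
potential.

Rate laws come from a closed constructor set:

* `mass_action` — k·(ΠS − ΠP/Keq); exactly zero at equilibrium.
* `reversible_mm` — generalized Michaelis–Menten whose numerator
  (ΠS − ΠP/Keq)/ΠKmS vanishes exactly when the mass-action ratio equals
  Keq (Haldane consistency), with the standard
  Π(1+S/Km) + Π(1+P/Km) − 1 denominator.  With no products this is
  irreversible MM.
* `hill` — Vmax·Sⁿ/(Kⁿ+Sⁿ) for cooperative enzymes.
* `with_modifiers` — multiplies a core law by saturating activation
  E^h/(K^h+E^h) or inhibition K^h/(K^h+E^h) terms, or substitutes
  KM → KM·(1+I/Ki) for a competitive inhibitor.
* `ghk_ion` — Goldman–Hodgkin–Katz constant-field electrodiffusion.  The
  singularity at zero potential is removed by a series branch for
  |zV/φ| < 1e-4 (φ = RT/F ≈ 26.73 mV at 310 K), so the expression is
  continuous and finite everywhere, and the flux is exactly zero at the
  ion's Nernst potential.
* `phospho_interpolated` — v = γ·v_P + (1−γ)·v_D between the
  phosphorylated and dephosphorylated enzyme states, each with its own
  maximal activity and kinetic constants.  γ(glc) is a Hill sigmoid of
  *plasma glucose* (the phenomenological stand-in for the insulin/glucagon
  signaling chain): γ = 0.5 at the half-saturation glucose, monotone,
  bounded in [0,1].  The functional form of the physiological signaling
  cascade is not observable at this level of description; the sigmoid
  family is an explicit modeling choice.
* `custom` — an arbitrary expression string (parsed with a clean symbol
  namespace so ids like `S`, `E`, `N` never collide with library names).

Maximal activities always enter as multiplicative pre-factors.  This is
load-bearing: the scaled elasticity of any constructed rate with respect
to its Vmax is identically 1, which the randomized acceptance suite
verifies along both the symbolic and the numeric differentiation path.

The inner mitochondrial membrane carries a lumped potential Δψ (mV,
positive outside) integrated as dΔψ/dt = (1/C)·Σ_r z_r v_r, where `z_r`
is the charge each reaction moves outward per unit flux and `C` a
capacitance parameter (µmol charge·g⁻¹·mV⁻¹).  This collapses the full
electrophysiology (individual ion gradients, pH component of the
proton-motive force) into one state; the GHK proton leak and the
potential-dependence of the pumps and the ATP synthase act on this state.

## Numerics

* Integration: `scipy.integrate.solve_ivp` with LSODA, rtol 1e-6,
  atol 1e-9 mM (configurable).  The membrane potential and the small
  redox pools make the system stiff; LSODA's automatic switching handles
  the diurnal forcing without restarts because periodic profiles are
  interpolated with a periodic cubic spline (aperiodic overlays — boluses,
  drug profiles — use linear interpolation).
* Rate evaluation: every model structure is compiled once with
  `sympy.lambdify`; parameters remain run-time arguments, so Vmax-
  perturbation studies (control analysis, Monte-Carlo, proteome scaling)
  re-use a single compilation.
* Steady states: long stiff relaxation in doubling time chunks, then a
  damped least-squares Newton polish in log-concentration coordinates
  with the conserved-moiety totals of the starting state appended as
  constraints (the raw Jacobian is singular along conservation
  relations).  Convergence requires ‖S·v‖∞ ≤ 1e-9·max(1, ‖c‖); a
  residual that stops shrinking without reaching tolerance (e.g., an
  oscillatory attractor) raises an explicit error rather than returning a
  partial answer.
* Conserved moieties are computed exactly over the rationals (sympy
  nullspace of Sᵀ restricted to internal species) and checked on every
  bundled scenario to drift < 1e-6 relative.
* Determinism: identical model + boundary + options give bitwise-identical
  trajectories; all stochastic procedures consume a single seeded
  `numpy.random.default_rng`.

## Calibration

Only maximal activities are treated as free parameters — they absorb
variable enzyme expression, while Km/Ka/Hill constants are enzyme
properties.  The objective sums, per experiment group α, a data term
normalized by the squared group-mean observation (making groups with
different units and magnitudes commensurable) and a penalty term
(1/M̄)²·ΣΣH(M) pushing internal metabolites back into their
physiological ranges; M̄ = 1.48 mM is the mean metabolite scale.  H is
one-sided quadratic, continuous with continuous first derivative at both
range boundaries.  The penalty is evaluated at each experiment's
observation times — a deliberate interpretation (a dense-grid alternative
would only strengthen the constraint).

The optimizer is derivative-free (Nelder–Mead) over log-Vmax with seeded
multistart: a cheap, loosely converged exploration run from every random
start, then one thorough polish from the best exploration result.  The
objective is piecewise-smooth and cheap on the bundled problems, and
log-space keeps activities positive without explicit constraints.  Simulation failures yield a documented large finite value
(1e9) plus a failure flag, never a silently dropped experiment.
Diagnostics include per-experiment residuals, bound violations, the
evaluation trace, and *flat directions*: eigenvectors of the numeric
log-space Hessian whose curvature is below 1 % of the dominant one — a
local, profile-likelihood-style detector of practically unidentifiable
parameter combinations (it found, e.g., the compensating direction of two
parallel transporters in the test suite).

## Sensitivity and control analysis

π-elasticities are computed symbolically (exact differentiation of the
rate law) with a central-finite-difference cross-check; a reaction with
zero reference rate has no defined elasticity and raises.  Response
coefficients use the λ-form R = (Y(λp)/Y(p)−1)/(λ−1) on steady states at
the 24 h-mean boundary clamp, warm-started from the reference state; the
infinitesimal coefficient combines central differences at λ = 1±h and
1±h/2 with one Richardson step (h = 0.01 default).  Undefined
coefficients (reference value below 1e-12) are first-class tagged records
carrying the absolute change, never NaNs silently entering aggregates.

Dynamic control analysis reduces each enzyme's maximal activity by 10 %
(both phospho-state activities together — the perturbation models reduced
enzyme abundance) and scores the mean effect on the 24 h course of the 24
metabolic functions with ⟨R⟩_T (trapezoidal quadrature, T = 24 h).  The
sign is the sign of the time-averaged deviation ∫(Y_pert−Y_ref)dt — a
documented choice, since a scalar score of a time-course perturbation has
no canonical sign.  Normalization maps positive entries by the global
maximum positive value and negative entries by the magnitude of the
global minimum into [−1, +1]; a per-function scaling is available as an
option.  The reference trajectory discards run-in forcing cycles before
the analyzed window so transients of the initial state have decayed; the
package default is 3 run-in days, and the test suite uses 1 run-in day at
0.5 h output resolution for the demo-scale analyses (the demo model's
fast pools settle within a day; glycogen and triglyceride enter the
analysis as deviations between matched runs, which cancels most of the
residual drift).

Monte-Carlo envelopes draw an independent uniform factor from
[0.9, 1.1] for every enzyme's Vmax per replicate (the magnitude of
reported inter-individual liver proteome variation), re-simulate the
forced cycle, and take pointwise empirical 2.5/97.5 % quantiles over 100
replicates.  Failed replicates are dropped and counted.

## The bundled demo model

The demo hepatocyte instantiates the classic liver pathway map at coarse
granularity: 4 compartments (extracellular space, cytosol, mitochondrial
matrix, inner-membrane space), ~60 reactions, with multi-step pathways
lumped into single reactions (lower glycolysis, gluconeogenesis, TCA
cycle, β-oxidation behind the malonyl-CoA-inhibited carnitine shuttle,
fatty-acid synthesis, respiratory complexes I+III and IV with cytochrome
c in the inter-membrane space, the urea cycle behind its
N-acetylglutamate activator, the Leloir pathway with aldose-reductase and
galactose-dehydrogenase branches, ADH/ALDH ethanol oxidation, and lumped
alanine/serine/glutamine/ammonia nitrogen feeds).  Regulatory motifs are
explicit: glucose-driven phospho-switching of glycogen synthase and
phosphorylase, lower glycolysis, gluconeogenesis and acetyl-CoA
carboxylase; allosteric fatty-acid inhibition of ACC; insulin suppression
of VLDL export; O₂ limitation of complex IV; ATP-gating (Hill) of the
ATP-consuming anabolic lumps, which is what collapses gluconeogenesis and
ureagenesis under hypoxia.

**Every kinetic constant is synthetic.**  Values were chosen once so that
the network reproduces the qualitative fed/fast physiology a hepatologist
would demand of a liver model — net glucose uptake when plasma glucose
and insulin are high and net release overnight; deep (> 50 %) overnight
glycogen depletion with a mid-afternoon peak; triglyceride stores varying
by < 10 % over a normal day; de-novo lipogenesis anticorrelated with
fatty-acid uptake; gross glucose production (glucose-6-phosphatase flux)
and urea production collapsing monotonically below 20 % of normoxia with
a transition centered near 10–15 mmHg pO₂; full reversibility of an
ethanol bolus within ~6 h of its end; GALT deficiency accumulating by far
the largest galactose-1-phosphate burden among the Leloir variants — and
each parameter carries a provenance note saying it is synthetic.  The
hypoxia scan reports *gross* glucose production (G6Pase flux) rather than
net glucose exchange because the net flux changes sign when uptake
continues while production fails, which makes a ratio to the reference
meaningless.

The diurnal generator synthesizes 24 h-periodic plasma profiles for the
15 drivers (glucose, lactate, pyruvate, glycerol, free fatty acids,
acetoacetate, β-hydroxybutyrate, O₂, ammonia, glutamine, glutamate,
serine, alanine, insulin, glucagon) as one- or two-harmonic cosines with
per-species mean, amplitude and peak time; defaults phase glucose and
insulin mid-day and fatty acids, ketone bodies and glucagon overnight.
Amplitudes must stay below means (profiles are strictly positive), and an
optional seeded log-normal jitter of the means emulates inter-individual
variability.  Scenario species (ethanol, acetate, galactose, urea) ride
along as constants.

What the generator does *not* emulate: meal-shaped (non-sinusoidal)
excursions, correlated noise between species, day-to-day variability, and
measured rat plasma curves.  Passing the property suite therefore shows
that the engine and analysis machinery behave correctly on a liver-like
network under liver-like forcing — not that the demo model is
quantitatively predictive for any real liver.

## Scenarios

Scenarios are pure functions of (model, boundary, configuration, seed).
For ethanol and galactose challenges the plasma species is converted from
a clamped boundary into a one-pool state in the extracellular compartment
(volume fraction 15 — the distribution volume per gram of liver tissue),
fed by an infusion forcing series (µmol/g/h) and cleared only by the
hepatocyte's own exchange reactions.  The galactose challenge uses a
gamma-shaped appearance curve (shape 2.5, scale 0.8 h, start 2 h) as the
delay between oral intake and plasma appearance.  Valproate rides a
fixture plasma profile (bolus at 2 h, 0.5 h absorption, 3 h half-life;
its microsomal clearance is exogenous input, not modeled) and acts
competitively on the carnitine shuttle's fatty-acid KM (Ki 0.40 mM) and
on N-acetylglutamate synthesis (Ki 1.0 mM); inhibition constants were set
so the urea suppression during exposure is mild enough for daily nitrogen
balance to restore the 24 h mean within ~2 %, mirroring the clinical
picture of transient, not cumulative, urea-cycle impairment.  Drug
washout restores rate evaluations bitwise because the competitive factor
(1+[drug]/Ki) collapses to exactly 1 at zero drug.  Proteome scaling
multiplies each mapped enzyme's maximal activities by its tumor/normal
abundance ratio and reports coverage; unknown ids are skipped and
recorded.

Unit helpers use molar masses 46.07 g/mol (ethanol) and 180.16 g/mol
(glucose), an O₂ solubility of 1.3 µM/mmHg, and a standard 15 L
extracellular distribution volume for the bolus-dilution example.

## Interchange

The native structured-text (JSON) format is the source of truth;
re-serialization after a read is byte-identical.  SBML Level 3 export
writes genuine kinetic-law math (including the piecewise GHK branch) plus
package annotations carrying parameter categories, canonical expression
strings, charge transfers and phospho-function metadata; the membrane
potential becomes a non-constant parameter with a rate rule over reaction
symbols.  Importing package-annotated SBML reproduces simulations
exactly; foreign SBML imports the standard subset (no piecewise laws
without annotations) and rejects undefined references with the offending
names.  All file writes are atomic (temp file + rename).

## Known limitations

* The demo model is a caricature: lumped stoichiometries are not
  carbon-balanced through CO₂, the pentose shunt and cholesterol branches
  are single reactions, and amino-acid metabolism is reduced to four
  nitrogen feeds.
* γ(glc) ties phospho-regulation to glucose only; glucagon and insulin
  enter the kinetics solely through the VLDL inhibition term and the
  waveform phasing.
* The membrane potential is one lumped state; pH gradients and individual
  ion species are out of scope.
* Gene expression, protein turnover and signaling beyond the
  phospho-sigmoid are not modeled; proteome scaling is the supported way
  to impose expression differences.
* Steady-state search assumes a point attractor; sustained oscillations
  are detected and reported, not analyzed.
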