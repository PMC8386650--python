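# Methods

This note documents the models implemented in `neurobias`, the defaults and
why they were chosen, what the synthetic-data generators do and do not
emulate, and the numerical choices that affect results.

## Concentration–response model and fitting

Curves are fit with the variable-slope sigmoid
`Y(c) = basal + top/(1 + 10^(n(−pEC50 − log10 c)))` on the
log10-concentration axis.  `top` is the span above `basal` (the curve's
Emax); concentrations are molar throughout and zero concentrations are
disallowed in fits (baselines are handled by explicit subtraction, by default
the mean response at the lowest assayed concentration per curve).

Fitting is unweighted least squares (no replicate weighting), with a
deterministic multi-start scheme: pEC50 starts on a fixed 5-point grid
spanning the assayed window, Hill-slope starts at {0.5, 1, 2}, best residual
sum of squares wins, ties resolved toward the lowest pEC50 start.  This
removes optimizer-heuristic nondeterminism: the fit is a pure function of the
data (invariant to row order and to duplicating all rows).  The Hill slope is
bounded to (0.1, 10) to exclude degenerate step fits, and pEC50 to the data
window ±3 log units, with a separate `extrapolated` flag beyond ±1.
Non-convergence (e.g. a flat curve) is reported via a flag with diagnostics,
not an exception.  Hill slopes are fit per curve; no slope sharing across
curves is attempted.

## AUC coupling ratios

The AUC integrates the *fitted*, baseline-free curve
(`top/(1 + 10^(n(−pEC50 − x)))`) over the assayed log10-concentration window
by composite trapezoid on a 2001-point grid (≤1e−4 relative error vs the
analytic integral for unit slope).  Integrating the fitted model rather than
raw-point trapezoids makes the AUC capture potency, efficacy and slope
jointly and keeps it noise-robust.  Using one common window for all pathways
of a ligand makes the window cancel in ratios.  Pairwise pathway ratios are
then normalized element-wise by the reference agonist's ratio matrix, which
cancels assay-scale (biosensor) differences; the reference's normalized
matrix is all ones exactly.

## Operational model

The Black–Leff operational model is implemented in the τ-explicit form
`E = Basal + (Em − Basal)τⁿ[A]ⁿ/(([A]+K_A)ⁿ + τⁿ[A]ⁿ)` with
`τ = 10^(logR + logK_A)`, evaluated as a logistic in log space for overflow
safety.  Per pathway, Em, Basal and n are shared across all agonists; full
agonists have log K_A fixed at 0 and partial agonists have it estimated.  An
agonist is classed full when its fitted Hill top reaches ≥90% of the
reference agonist's top in that pathway (the threshold is a package choice;
the reference is always full).  Starts for logR come from per-curve Hill
pEC50s — for a full agonist with K_A = 1 M and [A] ≪ K_A the half-max sits at
[A] = 1/R — with the same deterministic multi-start over n.

Bias is `ΔΔlog(τ/K_A)` between two pathways after normalizing each pathway's
log R to the reference agonist, reported as the fold factor `10^ΔΔ` together
with the ordered pathway pair (sign convention: pathway_a − pathway_b).
Confidence intervals use a parametric residual-resampling bootstrap
(default 1000 refits, percentile method, seed-controlled): residuals of the
global fit are resampled with replacement onto the fitted curves and the
model refit from the original solution.  This replaces closed-form SE
propagation and makes the CIs exactly reproducible.  Reference-agonist
identities (Δ = 0, factor = 1) hold exactly; reciprocity
bias(a,b)·bias(b,a) = 1 holds to one ulp in floating point.

## GIRK desensitization

Traces are peak-normalized (after subtracting an agonist-independent baseline
when provided).  The residual current at t_end (415 s in the reference
protocol) is the mean of the normalized current over the terminal **5 s**
window — a package choice for noise robustness at the 156 Hz sampling rate.
Decay is quantified by least squares of
`plateau + (1 − plateau)·e^(−(t−t_peak)/τ)` on the post-peak segment; a flat
segment or a τ pinned at its bound is flagged unidentifiable rather than
reported.  Note that a decay constant much longer than the application window
is intrinsically weakly identified.  Group comparison is standard one-way
ANOVA plus two-sided pairwise t-tests with Bonferroni correction
(p × number of pairs, capped at 1).

## Metadynamics engine

Dynamics are **overdamped (position) Langevin** integrated by Euler–Maruyama:
`ds = −U′(s)/ζ dt + sqrt(2 k_B T dt/ζ) ξ`.  Only the CV-space statistics
matter for validating the bias/reconstruction chain, so inertial dynamics add
nothing at this scale.  Defaults: friction ζ = 5 kcal·ps/mol/Å² (diffusion
≈ 0.12 Å²/ps at 300 K) and dt = 0.01 ps.  A documented stability check
requires `dt·max|U″|/ζ ≤ 0.5` over the thermally reachable region
(U − min U ≤ 15 kcal/mol), including the wall stiffness only where the wall
is actually reachable.  k_B T = 0.596 kcal/mol at 300 K.

Bias parameters default to: hill height 0.1 kcal/mol, width 0.1 Å, one hill
per 4 ps, well-tempered bias factor γ = 10, κ = 100 kcal/mol/Å² harmonic wall
at 12 Å, 6 walkers sharing bias every 20 ps, 300 K.  Deposited heights follow
`w0·exp(−V_bias/((γ−1)k_B T))` with V_bias evaluated as the depositing walker
currently sees it; each walker sees its own hills immediately and everyone
else's at the next synchronisation.  Toy potentials live on the full line, so
the one-sided wall is applied symmetrically at ±12 Å (exponent 2, the common
default for such restraints).  The shared bias is kept on a grid of spacing
σ/5 with analytic Gaussian derivatives; forces are linearly interpolated.
Both `MetadParams` and `ToyPotential` carry a temperature; the runner uses
`MetadParams.temperature` for the thermostat and the well-tempered decay.

The FES estimator is the standard rescaled-bias form
`F(s) = −(γ/(γ−1))·V_bias(s)`, shifted so the global minimum is 0 (energy
plots are relative).  Convergence is monitored by recomputing the profile
after every block of N deposited Gaussians (hills in deposition-time order,
merged across walkers); the final profile always uses all hills.  Wells are
local minima with ≥0.5 kcal/mol prominence (boundary minima included);
barrier(i→j) is the maximum F between the two minima minus F(well i).

**Problem sizes.** Test and example runs use 4–5×10⁵ steps (6 walkers,
6 000–7 500 hills) on double wells with a 1.3 kcal/mol barrier, which
reproduces U − min U with RMS ≈ 0.1–0.2 kcal/mol over the thermally
accessible region (defined as U − min U ≤ 2 kcal/mol, i.e. wells plus barrier
top with margin) and recovers the planted barrier well within
±0.3 kcal/mol.  These sizes were chosen as the smallest that are clearly
converged; longer runs only tighten the numbers.  The Boltzmann sanity check
(zero hill height, harmonic well) uses ~3×10³ effectively independent samples
from 50 thinned walkers; at much larger sample counts a Kolmogorov–Smirnov
test would resolve the O(dt) Euler–Maruyama discretization bias itself, which
is not what the check is for.

## Contact analysis

Input is a per-frame coordinate table (frame, atom_id, role, x, y, z in Å) —
deliberately not a binary trajectory format.  A pair is in direct contact
when the Euclidean distance is ≤ cutoff (closed interval at the boundary);
default cutoff 3.5 Å, a standard heavy-atom donor–acceptor criterion (no
hydrogen-bond angle term).  A water mediates a contact when one water atom is
within the cutoff of both partners.  A frame counts once per pair regardless
of route; reported frequencies split into direct and water-only components
that sum to the total.  Frequencies are invariant under rigid-body motion of
each frame and monotone non-decreasing in the cutoff.

## Synthetic data: what it emulates and what it does not

Generators produce: (a) long-format BRET-style concentration–response tables
from Hill or operational-model truths, with i.i.d. Gaussian noise on the
response (no heteroscedasticity, plate effects or outliers — replicate-level
variance for the real assays is not published, so `noise_sd` defaults are
fixture choices, 0.05 response units ≈ 5% of a typical span); (b) GIRK traces
as exponential onset × exponential decay toward a baseline, sampled at 156 Hz
over 415 s (64 740 samples) — no leak currents, capacitance transients or
voltage-protocol artifacts; (c) coordinate tables with Bernoulli-planted
contact frequencies, optionally realised through bridging waters — geometry
is schematic, not physical; (d) analytic toy potentials standing in for the
receptor-ligand distance CVs.  The default concentration grid is 9 log-spaced
points from 1 pM to 100 μM, spanning all printed potencies (pEC50 4.06–7.94).
BRET photophysics is not modeled; responses are abstract uBRET numbers.

Passing round-trips on these fixtures demonstrates that the *estimators* are
correct and unbiased under their own assumptions; they cannot certify
behaviour under real-data pathologies (heteroscedastic noise, partial
solubility, receptor reserve differences between batches).

All randomness flows through explicit integer seeds (`numpy.random.default_rng`);
no global RNG state is touched, and a fixed seed gives byte-identical output.

## Known limitations

- No biphasic/two-site dose–response models and no robust regression.
- Operational fits with *only* partial agonists leave Em weakly identified;
  this is flagged, not resolved.
- The metadynamics engine is 1D and overdamped by design; no multi-dimensional
  CVs, replica exchange beyond shared-bias walkers, or reweighting estimators.
- Contact analysis has no angle criteria and no trajectory-format parsing.
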