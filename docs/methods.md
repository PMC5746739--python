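# Methods

`hetflux` is a steady-state ¹³C metabolic flux analysis (MFA) toolkit built
around one question: when a tissue mixes cell types with different flux
distributions, what does fitting a single network to the *averaged*
labelling data actually estimate?  This note records the models, the
numerical choices, and the limits of what the synthetic data can show.

## Networks and the flux space

An atom-transition network lists metabolites (substrate, internal, or sink)
and reactions whose atom maps carry every reactant carbon to a product
carbon (a bijection, checked for every reaction at parse time).  Symmetric
intermediates (succinate, fumarate) are handled by giving the reaction two
alternative atom maps separated by `|`; each alternative carries half the
reaction's flux.  This is mathematically identical to duplicating the
consuming reaction at half flux without introducing a second flux variable.

Steady-state net fluxes satisfy S·v = 0 over the internal metabolites.
Stoichiometric coefficients and constraint coefficients are kept rational
and the null space is solved exactly with sympy, so `free_flux_basis`
returns an exact affine map v = A·f + b from the designated free fluxes;
under- and over-determination are rejected with the rank deficit.  Floats
enter only at the flux-value level.  Reversible reactions carry an exchange
flux stored on the compactified scale xch01 ∈ [0, 1): the raw bidirectional
rate is e = xch01/(1 − xch01), forward = max(net, 0) + e, backward =
max(−net, 0) + e.  The compactified scale makes "0.99" a meaningful
near-equilibrium setting and keeps optimizer boxes finite.

## Label simulation

The production simulator decomposes the requested fragments into elementary
metabolite units (EMUs): carbon subsets whose mass-isotopomer distributions
(MIDs) close under the atom maps.  Walking the maps backwards from each
target yields, per EMU, the producing flux terms; sources that split across
several reactant molecules convolve MIDs of strictly smaller EMUs, so the
system solves as a cascade of linear systems ordered by EMU size (dense
`numpy.linalg.solve` per size block; the canonical panel needs ~180 EMUs and
solves in about a millisecond).  Pools with total throughput below 1e−12
are pruned to unlabelled with a warning rather than dividing by zero.
Positional-isotopomer distributions are recovered from the EMU solution by
Möbius inversion over the carbon-subset lattice (the top mass of each
subset's MID is the cumulative "all labelled" fraction), capped at 12
carbons per metabolite.

The validation oracle solves the *full* positional-isotopomer balance by
fixed-point iteration, with no EMU reduction, on networks of at most 16
total carbons.  The balance is bilinear in the unknown distributions where
condensation reactions appear, and the raw functional iteration is unstable
once exchange fluxes exceed the net flux (probability mass decays toward a
spurious fixed point).  The iterate is therefore renormalized to the
simplex every sweep — where the map contracts — and the converged solution
is verified against the un-normalized balances (residual ≤ 1e−9); an
unbalanced "solution" raises rather than returning.  Tests require
|EMU − oracle| ≤ 1e−8 across >100 random feasible flux states.

Tracers assign each substrate a mixture of binary labelling patterns;
positions not set by the pattern are ¹³C with the natural-abundance
probability (0 for pure simulations, 0.011 when emulating experiments), so
natural abundance enters at the substrate definition and the correction
machinery can be tested independently of the simulator.

## The bundled models

**Branch-point toy.**  S (2 carbons, labelled in position 1) → A; A → B + C
by two irreversible routes that send carbon 1 to B or to C.  With exchange
off, the labelled fraction of B equals the branch flux — the linear case.
Making the first route reversible (condensation B + C → A) adds one
exchange degree of freedom and makes the steady state non-linear:
x_B = (n + 2e − ne)/(1 + 3e − 2ne) for net flux n and raw exchange e, which
the tests verify against both simulators, together with the structural
identities x_B + x_C = 1 and abundance(00) = abundance(11) in A (00/11
arise only by recombination).

**Canonical core network.**  An uncompartmented network of primary carbon
metabolism — EMP glycolysis, oxidative PPP (G6PDH + 6PGDH lumped, releasing
carbon 1 of G6P), non-oxidative PPP with canonical transketolase /
transaldolase maps, full TCA cycle with succinate and fumarate scrambling,
glyoxylate bypass (isocitrate lyase + malate synthase), PEP carboxylase,
malic enzyme, and biomass drains from ten precursors (G6P, F6P, R5P, E4P,
3PG, PEP, pyruvate, AcCoA, AKG, OAA) tied to a single biomass flux with
E. coli-style precursor coefficients (mmol per unit biomass).  CO2 is a
carbon-carrying internal metabolite — decarboxylations feed it, PEPCase
consumes it, the remainder exits — so refixation is label-correct.  Net
fluxes are completely determined by five frees: glucose uptake, biomass,
G6PDH, PEPCase, ICL.  Malic enzyme is required for that count: without a
cataplerotic step the OAA-family balance ties PEPCase to the biomass
drains.  Malate dehydrogenase is deliberately irreversible (MAL → OAA):
in the reversed regime the PEPCase/malic-enzyme loop becomes exactly
label-transparent (OAA's only source degenerates to PEP + CO2 and the PEP
rerouted through OAA → MAL → pyruvate replaces, one for one, the PEP lost
from pyruvate kinase), making PEPCase structurally non-identifiable.  The
reference flux state (uptake 100, biomass 7.56, G6PDH 50, PEPCase 80, ICL
25) is feasible with every irreversible flux positive.  The atom maps and
biomass coefficients are a reconstruction in the style of standard E. coli
core models, not a published model; aggregate physiology (CO2 ≈ 281 per
100 glucose at the reference state) depends on the drain coefficients.

**Fragment panel.**  27 tBDMS-derivatized GC-MS fragments of 12
proteinogenic amino acids: [M−57] (all backbone carbons) and [M−159]
(loses carbon 1) for each, plus the common m/z-302 ion (carbons 1–2) for
Ala, Ser, Asp.  Amino-acid MIDs are computed as convolutions of their
biosynthetic precursor EMUs (Ala ← pyruvate; Ser/Gly ← 3PG; Asp/Thr ← OAA;
Glu/Pro ← AKG; Phe/Tyr ← 2 PEP + E4P; Val ← 2 pyruvate − CO2; Leu ← 2
pyruvate + AcCoA − 2 CO2; Ile ← OAA + pyruvate − CO2), which keeps the
flux space at five frees instead of adding synthesis reactions.  Ion
elemental compositions derive from the amino-acid formula plus
n·(C₆H₁₄Si) per tBDMS group minus C₄H₉ for [M−57] (checked against the
known Ala [M−57] composition C₁₁H₂₆NO₂Si₂, m/z 260); [M−159] additionally
loses the derivatized carboxyl (CO₂ + C₆H₁₅Si).  The m/z-302 composition
is a documented reconstruction.  Which 27 fragments the original panel
used is not published; this panel is the package's own choice.

## Mass-isotopomer processing

The correction matrix for a fragment is the convolution of the
natural-abundance mass-shift distributions of every atom that is not a
backbone carbon (¹³C 0.01109, ²H 0.000115, ¹⁵N 0.00364, ¹⁷O/¹⁸O
0.00038/0.00205, ²⁹Si/³⁰Si 0.04685/0.03092, ³³S/³⁴S 0.0075/0.0425),
truncated to the n+1 recorded masses.  Correction solves the truncated
system by least squares and renormalizes; negative corrected abundances
are *retained* by default because they carry the statistical signature of
baseline-corrected weak signals (a `clamp` option switches to bounded
least squares on [0, 1]).  Condition numbers above 1e8 raise a warning.
Fractional enrichment is Σ i·Mᵢ/n, returned unclamped.  The ion-count QC
rule drops fragments below a threshold (default 1e5 counts).

Datasets travel as long-format tables (fragment, mass index or isotopomer
pattern, value, SD, ion count).  Direct rate measurements (e.g. glucose
uptake) ride along as sentinel rows: labelling patterns constrain only
flux *ratios*, so at least one measured rate is needed to pin the absolute
scale — mirroring practice, where uptake or growth rates accompany MID
data.

## Fitting, Monte Carlo, confidence intervals

The objective is the variance-weighted SSR Σ((sim − meas)/sd)².  Fits run
bounded trust-region least squares (`scipy.optimize.least_squares`,
finite-difference Jacobians) from Latin-hypercube multistarts (default 20)
over the free-flux box; interior infeasibility (an irreversible net flux
driven negative by the affine basis) returns a smooth penalty pointing back
toward feasibility.  Distinct optima within ΔSSR ≤ 1e−6 are all kept and
flagged as multimodal rather than silently choosing one.

Monte Carlo reliability follows the replicate protocol exactly: 100
replicates per dataset, each measurement redrawn with sd = max(1% of value,
0.001), refit from the base optimum, per-flux mean and SD reported, fully
reproducible under a fixed seed; isolated replicate failures are counted
and tolerated up to 10%.  The noise rule governs the *draw*; the dataset's
declared weighting is left untouched, so replicate optima scatter around
the base estimate.

Confidence intervals use parameter continuation: one flux is stepped away
from the optimum (initial step 2% of its box, growing 1.6× while the
profile stays flat, halving on gross overshoot) with all other fluxes
re-optimized, until the SSR crosses SSR_min + χ²(1, level) (3.84 at 95%).
The crossing is refined by interpolating on √(SSR − SSR_min), exact for a
locally quadratic profile (validated against the closed-form interval of
the linear toy model to 1%).  Labelling rows are re-weighted to a nominal
absolute error of 0.001 for the profile, per the reference protocol; rate
rows keep their own uncertainty.  A profile still below threshold at a
bound is reported as an open interval side.  Mixture-experiment fits use
the same nominal weighting so the reported estimate always lies inside its
own interval.

## Mixture experiments

A `MixtureScenario` holds flux states with protein-pool weights.  The
measured dataset of a mixture is the weighted average of member datasets —
never the dataset of the averaged fluxes; the gap between those two is the
phenomenon under study.  `run_mixture_experiment` fits the averaged data
and tabulates estimate, 95% CI, and percent-of-expected against the true
weighted fluxes, plus physiology: CO2 efflux, O2 uptake from the electron
balance (½ O2 per NADH or FADH2, with NADPH assumed consumed by
biosynthesis — configurable in the cofactor table), respiratory quotient,
and carbon conversion efficiency (1 − CO2/carbon imported).  Physiology is
linear in the flux state, so the weighted-average state gives the true
aggregate physiology to compare against.  Physiology CIs come from the
Monte Carlo replicate distribution (2.5/97.5 percentiles), flux CIs from
continuation.  A helper constructs two-member scenarios whose weighted
mean equals a reference state by solving member₂ = (ref − w₁·member₁)/w₂
and validating feasibility.  Weights default to 0.5/0.5 and are read as
each cell type's contribution to the measured protein pool.

The analysis drivers choose member contrasts of ±(20, 8, 8) on
(G6PDH, PEPCase, ICL) and ±0.6 on biomass.  The modest biomass contrast is
a constraint of the reconstruction: the acetyl-CoA drain coefficient is
large, so biomass swings beyond ~±0.8 drive malate dehydrogenase negative.
The published mixture tables came from different (unavailable) member
definitions, so numeric flux estimates are not comparable row-by-row; the
qualitative findings — seemingly precise but wrong estimates, errors in
both directions, distorted physiology — reproduce.

## Synthetic measurement noise

GC-MS noise is additive Gaussian on abundances with sd = a/√(ion count) + b
(defaults a = 3.0, b = 1e−4), unbiased, seeded, and not renormalized across
an envelope — emulating independently baseline-corrected mass traces that
can go negative at low counts.  The defaults are calibrated so enrichment
SD is ≈0.01 at 1e5 counts, which makes the empirical reliability threshold
emerge at ~1e5 counts: above it, |measured − true enrichment| ≤ 0.02 in
≥95% of draws; below 1e4 counts negative enrichments are common.  This is
an emulation of the statistical *effect* of baseline correction, not an
instrument model: there is no chromatography, no peak integration, no
correlated within-envelope noise, and no heavy-tailed contamination.
Passing tests therefore show the processing rules behave correctly under
the stated noise structure, not that the thresholds are optimal for any
particular instrument.  Reporter-vs-total-protein null datasets are two
independent noisy realizations of one truth; equivalence is assessed by
OLS regression over all shared isotopomer abundances plus a paired t-test
(df = pairs − 1; identical inputs return t = 0, p = 1 rather than 0/0).

## Problem sizes and defaults

Default problem sizes are chosen to keep every analysis interactive on one
core: toy fits take milliseconds; a canonical 5-flux fit with 20
multistarts ≈ 2 s; 100 Monte Carlo replicates ≈ 10 s; a full canonical
continuation ≈ 5 s.  The oracle cross-validation uses 100 random states on
≤16-carbon networks.  Seeds default to small fixed integers and every
stochastic entry point accepts one.

## Known limitations

* Atom maps, biomass composition, fragment list and mixture definitions are
  reconstructions; absolute flux estimates and gas-exchange values are
  composition-dependent.
* No subcellular compartmentation, no isotopically non-stationary
  simulation, no multi-element (²H/¹⁵N) tracers.
* The brute-force oracle is limited to 16 carbons; the canonical network is
  validated only through the EMU route's internal invariants (balance,
  normalization, enrichment conservation) and toy-network agreement.
* Exchange fluxes of the canonical network default to zero rather than
  being fitted; only the five net frees are estimated.
* The equivalence test treats isotopomer abundances as independent pairs;
  within-fragment correlations are ignored, as in the matched-pairs
  treatment it mirrors.
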