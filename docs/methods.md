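# Methods

This note documents the models, estimators and design choices behind
`woodfrac`, in the spirit of a package vignette: what each stage assumes,
which parameters matter, and what the synthetic validation does and does not
demonstrate.

## Study design encoded in the fixtures

The packaged CSVs transcribe, cell by cell, the species-level tables of a
field campaign on 16 Australian evergreen tree species (8 on nutrient-poor
sandstone plateau soil, 8 on nutrient-rich gully soil; 14 genera, 8
families; 5 mature individuals per species, n = 80). Values are stored as
the printed strings so serialisation round-trips bit-exactly; loaders
validate counts, grid completeness and positivity and fail naming file and
row. Tissue nutrients are N in mg g⁻¹ and P in mg kg⁻¹ for six
compartments: fresh leaves, senescent leaves, twig wood, outer sapwood,
inner wood, bark. Note one transcription hazard preserved deliberately: the
structural-trait table as printed swaps the abbreviations of *Syncarpia
glomulifera* and *Synoum glandulosum* relative to the nutrient table, so
all joins are keyed on the full species name.

## Stereology

Tissue fractions are estimated by classifying the nodes of a regular point
lattice laid over a categorical raster (point counting). With the grid
offset drawn uniformly from [0, spacing)², every pixel has identical hit
probability, making the per-category hit fraction an unbiased estimator of
areal fraction with binomial standard error √(f(1−f)/n). Defaults: stem
spacing 130 µm, twig 60 µm (midpoints of the 120–140 µm and 40–80 µm
working ranges); a minimum of 300 intersections is enforced by repeatedly
halving the spacing (logged), and the run fails if that would push spacing
below twice the pixel pitch. Conventions chosen where the procedure is
underdetermined: grid offsets are seeded-random rather than corner-anchored
(avoids aliasing with periodic structures); a node on a pixel boundary
belongs to the pixel given by the floor of its coordinate (half-open
pixels, origin top-left); category "other" is included in the denominator
by default, with a flag to exclude it.

## Synthetic sections

The scene generator renders the five-category tissue map (codes: 0 outside,
1 conduit, 2 axial parenchyma, 3 ray parenchyma, 4 fiber including walls
and septate fibers, 5 other) as geometry, not histology: non-overlapping
elliptical conduit lumina with lognormal equivalent diameters (default
median 60 µm, σ_log 0.3, axis ratio ≥ 0.7), paratracheal sheaths obtained
by dilating the conduit mask (default 10 µm) with optional tangential bands
to reach an axial target, radial rays as vertical bands (default 30 µm
wide), and a fiber matrix filling the rest. Conflicts resolve by claim
order conduit → sheath → ray → other, each stage claiming only unclaimed
fiber pixels; ray-band coverage is inflated by the already-claimed fraction
so achieved fractions land on their targets (default tolerance ±0.02, else
the generator fails reporting achieved vs requested). Conduits are placed
on a canvas padded by the largest admissible radius and clipped to the
analysis window, exactly as vessels are clipped at the edge of a real
analysed rectangle; without this the window edges are conduit-free and the
varying lattice size correlates with edge composition, biasing point-count
fractions by about one percentage point. The unclipped mode
(`clip_at_edges=False`) is retained because only there do the recorded
ellipse areas Σπab match the rasterised lumen fraction exactly (used as a
cross-check, agreement within 1 pp). Ground-truth fractions are exact
pixel counts; identical parameters and seed give identical rasters.

What passing these tests shows: the point-count estimator and its error
model behave correctly on scenes whose truth is known. What it does not
show: performance on real stained micrographs, where classification error,
staining variability and section damage dominate — image classification is
out of scope.

## Vessel morphometrics and hydraulics

Per-vessel ellipse measurements use major/minor *radii* a, b in µm
(verified by the circle identity d = 2r). Equivalent diameter
d = (32(ab)³/(a²+b²))^¼. The hydraulically weighted mean is implemented as
d_h = Σd⁵/Σd⁴ — the flow-weighted convention that reduces to d for uniform
populations and always lies in [min d, max d]; the compact form sometimes
printed as "Σd⁴/d⁵" is dimensionally inconsistent and is not used.
Hagen–Poiseuille conductivity K_h = (π Σr⁴ / 8η)ρ with water at 20 °C
(η = 1.002×10⁻³ Pa s, ρ = 998.2 kg m⁻³), r = d/2 in metres; K_S = K_h
divided by the analysed cross-sectional area (bark and pith excluded),
expressed in kg m⁻¹ MPa⁻¹ s⁻¹ (explicit 10⁶ Pa→MPa factor) to match the
trait table's units. Vessel density is reported per mm² (the printed unit
"n mm⁻¹" is read as an areal density). The synthetic vessel generator
draws lognormal diameters; the target-calibrated variant inverts
E[d⁵]/E[d⁴] = exp(μ + 4.5σ²) for the median and sets the count from the
lumen-area target, which reproduces published per-species d_h and K_S
magnitudes (sample d_h sits a few percent below the population value
because the d⁴-weighted ratio is tail-dominated at finite n).

## Nutrient budgets

Recycling (resorption) efficiency is 1 − conc_senescent/conc_fresh, with
the wood analogue using outer sapwood as the "fresh" pool and inner wood as
the "senescent" pool. Negative efficiencies are preserved — they are a
finding (heartwood nutrient deposition), not an error. Proficiency is the
senescent-tissue concentration, so proficiency = conc_fresh·(1 − NRE)
holds identically. Sub-detection values are replaced by
(detection limit − blank), default limit 0.01 ppm for P and blank 0, and
every derived efficiency carries a `substituted` flag marking it a lower
bound. The senescence mass-loss correction multiplies the senescent
concentration by sla_fresh/sla_senescent (the ratio of area-specific
masses) before the efficiency formula; equal SLAs recover the uncorrected
value. Species-level efficiencies in the packaged summaries are ratios of
printed species means; with per-individual data the package computes per
individual and averages, and both error estimators (SD of individual
efficiencies; propagation from concentration SEs) are available since the
reporting convention is ambiguous. The glasshouse dose helper converts a
pellet application rate and P mass fraction to µg P per g soil
(3.2 g kg⁻¹ × 4.8 % = 153.6 µg/g).

## Traits

SLA = area/dry mass (cm² g⁻¹); Huber value = sapwood area / distal leaf
area with bark and pith excluded from sapwood; wood density = dry mass /
fresh volume with the fresh volume optionally derived from the displaced
water mass at 20 °C (0.9982 g cm⁻³); densities outside 0.1–1.4 g cm⁻³ are
logged as implausible. Relative BAI converts diameters to basal areas
(πd²/4) and annualises the relative increment by 365.25/elapsed-days. Leaf
lifespan is demographic: mean standing leaf count divided by the
annualised birth flux and by the shedding flux, averaged — at steady state
both equal the mean residence time; "mean of the two variables" is read as
the mean of the two lifespan estimates (the flux-ratio reading is also
emitted). A stochastic steady-state census simulation (10 twigs, 3
censuses) recovers a 3.21-year lifespan within 10 %.

## Mixed models and inference

All models are random-intercept LMMs, y = Xβ + b_species + e. Because the
single-variance-ratio structure admits an exact 1-D profiled (restricted)
likelihood — the group correlation matrix I + λJ has symmetric inverse
square root I − (c/m)J with c = 1 − 1/√(1+λm) — the package ships its own
fitter: each likelihood evaluation is an OLS on whitened data, the fit is a
bounded scalar optimisation, and bootstrap refits vectorise across response
columns (a 199-replicate parametric bootstrap takes well under 0.1 s at
n = 80). The engine agrees with statsmodels MixedLM to optimiser tolerance;
statsmodels remains the independent oracle in the tests, never the
implementation. σ²_f for R²_marginal is the population variance of the
fixed-effect linear predictor; R²_conditional adds the intercept variance.
λ̂ = 0 fits are reported as singular, not hidden. Responses log-transform
only for vessel sizes and K_S. Parametric bootstrap p-values simulate the
response from the ML fit of the reduced model, refit both models by ML
through the same vectorised grid-plus-parabolic-refinement path as the
observed statistic (so refinement error cancels in the comparison), and use
p = (1 + #{LR* ≥ LR_obs})/(reps + 1); default 999 replicates, 199 in the
large calibration studies. Measured type-I error at α = 0.05 over 500 null
datasets × 199 replicates: within [0.02, 0.08].

ANOVA variance partitioning uses method-of-moments components
(σ̂²_sp = (MS_between − MS_within)/n₀, truncated at zero) and reports
percent shares. For recovery studies across replicate simulations the
share is formed from replicate-pooled components rather than by averaging
per-replicate shares: the per-replicate percentage is a ratio of noisy
components and carries a Jensen bias of about −2 pp at a 71 % share with
16 groups, while pooled components are unbiased (recovery of a simulated
71.3 % share over 200 replicates: ~72 %). At a true share of zero the
truncation leaves a small positive floor (~3 pp) that no aggregation
removes. Soil-class comparisons use Welch's t on per-species means,
low-minus-high by convention (higher recycling on poor soils gives
positive t); PCA standardises variables to unit variance since traits mix
units; stepwise backward selection drops, at each step, the predictor whose
removal lowers ML-based AIC the most.

## Field-dataset generator

Each trait is species mean + individual noise with configurable variance
components; defaults mirror the study conditions — 16 species × 5
individuals, species identity explaining 71.3 % (stem) and 69.4 % (twig) of
parenchyma-fraction variance, parenchyma fractions centred at 0.28 with a
between-species SD of 0.08 (matching the published 14.6–44.9 % range), and
trait magnitudes at the published species-mean scale. An optional linear
link generates sapwood N = α + β·(stem parenchyma fraction) + effects
(defaults α = 0.9 mg g⁻¹, β = 2.0 mg g⁻¹ per unit fraction), and
concentration-like responses can be floored at a tiny positive value; the
floor is off for zero-mean calibration responses, where it would truncate
the distribution. Generating parameters are stored as ground truth. The
generator emulates balanced Gaussian variance components only — no
phylogenetic structure, spatial autocorrelation, missingness or
measurement-error correlation — so statistical recovery results certify the
estimators, not robustness to those real-data features.

## Pipeline and problem sizes

`run_pipeline` chains synthesis → stereology → vessel summaries → nutrient
budget → field simulation → statistics, writing CSVs with fixed float
formatting so identical config + seed give byte-identical tables. Every
stage derives its seed as SHA-256(master seed, stage name) mod 2³¹, so
adding a stage never perturbs earlier streams. Default problem sizes keep
the whole suite interactive: scenes of 1.5–6 mm² at 2 µm px⁻¹, 200-offset
stereology replications, 200-replicate variance-partition studies, 500 × 199
bootstrap calibration; all scale linearly if larger studies are wanted.

## Known limitations

Scene geometry is a caricature (straight rays, axis-aligned bands, no
growth rings, vessel multiples or heartwood gradients). Efficiencies from
species means are not individual-mean efficiencies; both are exposed. The
published per-individual regression, PCA and t statistics are not
reproducible from printed species-level tables, so the statistical stage is
validated by parameter recovery on synthetic data instead. The stepwise
procedure reproduces the selection algorithm, not the study's specific
selected coefficients.
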