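# woodfrac

Wood of evergreen trees is far from dead: interwoven networks of living axial
and ray parenchyma can make up 15–45 % of xylem volume, and how that abundance
relates to a tree's nutrient economy is an open question. `woodfrac`
re-implements, as a tested analysis pipeline, the quantitative chain used to
study this in 16 co-occurring Australian evergreen species growing on
nutrient-poor sandstone versus nutrient-rich gully soils:

- **Stereology** — grid-based point counting of tissue fractions (conduit,
  axial parenchyma, ray parenchyma, fiber, other) on categorical
  cross-section rasters, with binomial sampling errors
  `se = sqrt(f(1−f)/n)` and a ≥300-intersection rule enforced by spacing
  halving.
- **Vessel morphometrics** — equivalent diameter
  `d = (32(ab)³/(a²+b²))^¼` from ellipse radii *a, b*; hydraulically
  weighted mean `d_h = Σd⁵/Σd⁴`; vessel density; lumen fraction; and
  Hagen–Poiseuille theoretical conductivity
  `K_h = (π Σr⁴ / 8η) ρ`, reported per analysed area as `K_S`
  (kg m⁻¹ MPa⁻¹ s⁻¹).
- **Nutrient recycling** — resorption efficiency
  `NRE = 1 − conc_senescent / conc_fresh` for leaves (fresh → senescent) and
  stem wood (outer sapwood → inner wood, where negative values mean
  heartwood enrichment), proficiency, senescence mass-loss correction via
  fresh/senescent SLA, and detection-limit substitution (limit − blank).
- **Traits** — SLA, Huber value, wood density (Archimedes displacement),
  relative basal area increment, demographic leaf lifespan.
- **Statistics** — species-random-intercept linear mixed models with
  `R²_marginal = σ²_f / (σ²_f + σ²_b + σ²_e)` and
  `R²_conditional = (σ²_f + σ²_b) / (σ²_f + σ²_b + σ²_e)`, parametric
  bootstrap p-values for nested model comparisons, ANOVA variance
  partitioning (`σ²_effect/σ²_total × 100`), Welch soil-class tests,
  Kruskal–Wallis, standardized-variable PCA, and stepwise backward AIC.

Because the study's per-individual raw data are unpublished, the package
ships (a) the printed species-level tables as exact CSV fixtures and (b)
synthetic-data generators with known ground truth — labelled section rasters
with exact pixel-count fractions, lognormal vessel populations, and
species × individual field datasets with specified variance components — so
every estimator can be validated against what it is supposed to recover.

## Worked example

Recycling efficiencies from the packaged tissue-nutrient table
(`analysis/05_nutrient_recycling.py`):

```
leaf recycling efficiency ranges (species means):
  P: 0.194 - 0.775 (max in Cry_mac)
  N: 0.176 - 0.560 (max in Ban_eri)
negative stem-wood recycling in 6 species: ['Ban_eri', 'Euc_pip', 'Lep_pol', 'Per_lin', 'Pit_und', 'Slo_aus']
  low vs high soil, leaf      P: t = +2.59, p = 0.031 *
  low vs high soil, leaf      N: t = +1.36, p = 0.195
glasshouse fertilizer treatment adds 153.6 ug P per g soil
```

Phosphorus is withdrawn from senescing leaves far more completely (up to
77.5 % of the pool) than nitrogen (up to 56 %), species on the poor soils
resorb leaf P significantly more efficiently than species on rich soils
(positive t under the low-minus-high convention), and several species show
*negative* wood recycling — inner wood richer than sapwood, consistent with
nutrient deposition during heartwood formation.

The statistics stage on a simulated field campaign
(`analysis/06_trait_statistics.py --seed 0`):

```
  parenchyma_fraction_stem   species share  78.0 %
  parenchyma_fraction_twig   species share  69.1 %
sapwood N ~ parenchyma + (1|species): beta = 1.66, R2m = 0.15, R2c = 0.60, p_boot = 0.0070 (999 reps)
PCA: first two axes explain 50.5 % of trait variance
stepwise backward AIC keeps: ['parenchyma_fraction_stem']
variance-partition recovery of a 71.3 % species share over 200 replicates: 72.06 %
```

Species identity dominates trait variance (the generator's defaults place
~70 % of variance between species, as observed in the field study), the
mixed model detects the simulated parenchyma → sapwood-N link, and the
ANOVA partition recovers the simulated species share.

The full chain can also be run as one reproducible pipeline
(`woodfrac run --seed 1 --out-dir results/run`) or stage by stage through
the `woodfrac` CLI (`synthesize`, `count`, `vessels`, `recycle`, `traits`,
`stats`, `run`, `validate`); identical config and seed give byte-identical
output tables.

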