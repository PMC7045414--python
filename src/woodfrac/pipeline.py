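"""Pipeline orchestration: one reproducible run over all analysis stages.

A run synthesises labelled sections and vessel populations, point-counts the
sections, summarises vessel hydraulics, computes recycling efficiencies from
the packaged tissue-nutrient table, simulates the field dataset, and runs the
statistics stage (variance partition, mixed model, PCA), writing versioned CSV
tables, a line-oriented log and a short report. Every stochastic stage
receives a seed derived deterministically from the master seed via a stable
per-stage hash, so adding a stage never perturbs earlier streams and the same
config + seed yields byte-identical tables.
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import fixtures, nutrients, stats, stereology, synthesis, vessels

log = logging.getLogger("woodfrac.pipeline")

__all__ = ["RunConfig", "run_pipeline", "validate_against_fixtures",
           "stage_seed"]


def stage_seed(master_seed: int, stage: str) -> int:
    """Deterministic per-stage seed below 2**31, stable across code changes."""
    digest = hashlib.sha256(f"{master_seed}:{stage}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)


@dataclass
class RunConfig:
    """Settings for one end-to-end run."""

    out_dir: str = "results/run"
    seed: int = 0
    n_scene_species: int = 4  # sections synthesised (keeps the demo quick)
    scene: synthesis.SceneParams = field(default_factory=synthesis.SceneParams)
    grid_spacing_um: float = stereology.DEFAULT_SPACING_UM["stem"]
    min_intersections: int = 300
    hydraulics: vessels.HydraulicConstants = field(
        default_factory=vessels.HydraulicConstants)
    detection: nutrients.DetectionLimitPolicy = field(
        default_factory=nutrients.DetectionLimitPolicy)
    n_species: int = 16
    n_individuals: int = 5
    bootstrap_reps: int = 199

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "scene" in raw:
            raw["scene"] = synthesis.SceneParams(**raw["scene"])
        if "hydraulics" in raw:
            raw["hydraulics"] = vessels.HydraulicConstants(**raw["hydraulics"])
        if "detection" in raw:
            raw["detection"] = nutrients.DetectionLimitPolicy(**raw["detection"])
        return cls(**raw)


def _write(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, index=False, float_format="%.6g", lineterminator="\n")


def run_pipeline(config: RunConfig) -> dict[str, Path]:
    """Execute all stages; returns the mapping of artifact name -> path."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(out / "run.log", mode="w")
    handler.setFormatter(logging.Formatter("%(levelname)s %(name)s %(message)s"))
    root = logging.getLogger("woodfrac")
    root.addHandler(handler)
    root.setLevel(logging.INFO)
    artifacts: dict[str, Path] = {}
    stage = "startup"
    try:
        log.info("run start seed=%d out=%s", config.seed, out)

        stage = "fixtures"
        _, species, nutrient_table, trait_table = fixtures.load_packaged_tables()

        stage = "synthesize+stereology"
        rows = []
        for i, sp in enumerate(species[: config.n_scene_species]):
            seed = stage_seed(config.seed, f"scene:{sp.abbreviation}")
            scene = synthesis.generate_section_scene(config.scene, seed=seed)
            spec = stereology.GridSpec(spacing_um=config.grid_spacing_um,
                                       offset_um=None)
            res = stereology.point_count(
                scene.label_map, spec,
                min_intersections=config.min_intersections,
                seed=stage_seed(config.seed, f"grid:{sp.abbreviation}"))
            log.info("scene %s: n_total=%d spacing=%.1f", sp.abbreviation,
                     res.n_total, res.spacing_used_um)
            for cat, frac in res.fractions.items():
                rows.append({"species": sp.abbreviation, "category": cat,
                             "count": res.counts[cat], "fraction": frac,
                             "se": res.se[cat],
                             "true_fraction": scene.true_fractions[cat],
                             "n_total": res.n_total,
                             "spacing_used_um": res.spacing_used_um})
        tissue_df = pd.DataFrame(rows)
        _write(tissue_df, out / "tissue_fractions.csv")
        artifacts["tissue_fractions"] = out / "tissue_fractions.csv"

        stage = "vessels"
        vrows = []
        stem_traits = trait_table[trait_table.organ == "stem"]
        for sp in species[: config.n_scene_species]:
            sel = stem_traits[stem_traits.species_name == sp.species_name]
            dh = float(sel[sel.trait == "dh_mean_um"]["mean"].iloc[0])
            a_lumen = float(sel[sel.trait == "A_lumen_pct"]["mean"].iloc[0])
            pop = synthesis.vessel_population_for_targets(
                d_h_um=dh, a_lumen_pct=a_lumen, analyzed_area_mm2=10.0,
                organ="stem",
                seed=stage_seed(config.seed, f"vessels:{sp.abbreviation}"))
            s = vessels.population_summary(pop, config.hydraulics)
            vrows.append({"species": sp.abbreviation, "n_vessels": s.n_vessels,
                          "VD_per_mm2": s.vd_per_mm2, "d_max_um": s.d_max_um,
                          "d_h_um": s.d_h_um,
                          "A_lumen_pct": s.lumen_fraction_pct, "K_S": s.k_s})
        _write(pd.DataFrame(vrows), out / "vessel_summaries.csv")
        artifacts["vessel_summaries"] = out / "vessel_summaries.csv"

        stage = "nutrient_budget"
        summary = nutrients.group_recycling_summary(nutrient_table, species)
        _write(summary.per_species, out / "recycling_per_species.csv")
        _write(summary.by_soil_class, out / "recycling_by_soil_class.csv")
        artifacts["recycling_per_species"] = out / "recycling_per_species.csv"
        artifacts["recycling_by_soil_class"] = out / "recycling_by_soil_class.csv"

        stage = "field_dataset"
        ds = synthesis.generate_field_dataset(
            n_species=config.n_species, n_individuals=config.n_individuals,
            seed=stage_seed(config.seed, "field_dataset"))
        _write(ds.data, out / "field_dataset.csv")
        artifacts["field_dataset"] = out / "field_dataset.csv"

        stage = "stats"
        vp = stats.variance_partition(ds, "parenchyma_fraction_stem")
        full = stats.MixedModelSpec(response="sapwood_N_mg_g",
                                    predictors=("parenchyma_fraction_stem",))
        reduced = full.with_predictors(())
        fit = stats.fit_mixed_model(ds, full)
        p_boot = stats.parametric_bootstrap_p(
            full, reduced, ds, reps=config.bootstrap_reps,
            seed=stage_seed(config.seed, "bootstrap"))
        pca = stats.pca_summary(ds, ["parenchyma_fraction_stem",
                                     "parenchyma_fraction_twig", "SLA_cm2_g",
                                     "wood_density_g_cm3", "sapwood_N_mg_g"])
        stats_df = pd.DataFrame([
            {"quantity": "variance_partition_species_pct",
             "value": vp.percent["species"]},
            {"quantity": "lmm_beta_parenchyma",
             "value": fit.coefficients["parenchyma_fraction_stem"]},
            {"quantity": "lmm_R2_marginal", "value": fit.r2_marginal},
            {"quantity": "lmm_R2_conditional", "value": fit.r2_conditional},
            {"quantity": "lmm_p_boot", "value": p_boot},
            {"quantity": "pca_pc1_pc2_pct",
             "value": 100.0 * float(pca.explained_variance_ratio[:2].sum())},
        ])
        _write(stats_df, out / "stats_summary.csv")
        artifacts["stats_summary"] = out / "stats_summary.csv"

        stage = "report"
        maxima = summary.per_species.groupby(["organ", "element"])["efficiency"].max()
        report = [
            "# woodfrac run report",
            f"seed: {config.seed}",
            f"species analysed: {config.n_scene_species} scenes, "
            f"{config.n_species} x {config.n_individuals} field records",
            "",
            "## Recycling maxima (ratio of species-mean concentrations)",
            f"max leaf P efficiency: {maxima[('leaf', 'P')]:.3f}",
            f"max leaf N efficiency: {maxima[('leaf', 'N')]:.3f}",
            f"max stem-wood P efficiency: {maxima[('stem_wood', 'P')]:.3f}",
            "",
            "## Statistics",
            *(f"{r.quantity}: {r.value:.4f}" for r in stats_df.itertuples()),
        ]
        (out / "report.md").write_text("\n".join(report) + "\n")
        artifacts["report"] = out / "report.md"
        log.info("run complete: %d artifacts", len(artifacts))
    except Exception as exc:
        raise RuntimeError(f"pipeline failed in stage {stage!r}: {exc}") from exc
    finally:
        root.removeHandler(handler)
        handler.close()
    return artifacts


# ---------------------------------------------------------------- validation
@dataclass(frozen=True)
class ValidationCheck:
    name: str
    computed: float
    expected: float
    tolerance: float
    one_sided_ge: bool = False  # pass iff computed >= expected

    @property
    def passed(self) -> bool:
        if self.one_sided_ge:
            return self.computed >= self.expected
        return abs(self.computed - self.expected) <= self.tolerance


def validate_against_fixtures() -> list[ValidationCheck]:
    """Recompute the desk-scale published quantities from the fixtures.

    Failures are reported in the returned list, not raised.
    """
    checks: list[ValidationCheck] = []
    _, species, table, _ = fixtures.load_packaged_tables()
    checks.append(ValidationCheck(
        "n_species", len(species), 16, 0))
    checks.append(ValidationCheck(
        "n_genera", len({s.genus for s in species}), 14, 0))
    checks.append(ValidationCheck(
        "n_families", len({s.family for s in species}), 8, 0))
    checks.append(ValidationCheck(
        "tissue_table_Euc_pip_fresh_N",
        fixtures.tissue_nutrient_lookup(table, "Eucalyptus piperita",
                                        "fresh_leaves", "N"), 15.73, 0))

    summary = nutrients.group_recycling_summary(table, species)
    leaf = summary.per_species[summary.per_species.organ == "leaf"]
    leaf_p_max = leaf[leaf.element == "P"]["efficiency"].max()
    low_n = leaf[(leaf.element == "N") & (leaf.soil_class == "low")]["efficiency"]
    checks.append(ValidationCheck("max_leaf_P_efficiency", leaf_p_max, 0.77, 0.01))
    checks.append(ValidationCheck("max_leaf_N_efficiency_low_soil",
                                  low_n.max(), 0.56, 0.005))
    checks.append(ValidationCheck("min_leaf_N_efficiency_low_soil",
                                  low_n.min(), 0.17, 0.0, one_sided_ge=True))
    checks.append(ValidationCheck(
        "greenhouse_P_dose_ug_g", nutrients.fertilizer_p_addition(), 150.0,
        150.0 * 0.05))
    checks.append(ValidationCheck(
        "circle_equivalent_diameter", vessels.equivalent_diameter(25.0, 25.0),
        50.0, 1e-9))
    checks.append(ValidationCheck(
        "uniform_dh", vessels.hydraulically_weighted_diameter([50.0] * 3),
        50.0, 1e-9))
    single = vessels.VesselPopulation(
        vessels=(vessels.VesselMeasure(25.0, 25.0),), analyzed_area_mm2=1.0)
    _, k_s = vessels.theoretical_conductivity(single)
    checks.append(ValidationCheck("single_vessel_K_S", k_s, 0.1528, 0.0005))

    ds = synthesis.generate_field_dataset(seed=0)
    checks.append(ValidationCheck("n_field_records", ds.n_records, 80, 0))
    return checks
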