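"""Vessel morphometrics: diameter formulas, hydraulic conductivity, summaries."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from woodfrac.synthesis import SceneParams, generate_section_scene, \
    generate_vessel_population
from woodfrac.vessels import (HydraulicConstants, VesselMeasure,
                              VesselPopulation, equivalent_diameter,
                              hydraulically_weighted_diameter,
                              population_summary, theoretical_conductivity)


class TestEquivalentDiameter:
    def test_circle_identity(self):
        assert equivalent_diameter(25.0, 25.0) == pytest.approx(50.0, abs=1e-12)

    def test_ellipse_value(self):
        # direct evaluation of (32 (ab)^3 / (a^2+b^2))^(1/4)
        assert equivalent_diameter(30.0, 20.0) == pytest.approx(48.02, abs=0.01)

    def test_shrinks_to_zero_with_minor_radius(self):
        ds = [equivalent_diameter(30.0, b) for b in (10.0, 1.0, 0.01, 1e-4)]
        assert all(x > y for x, y in zip(ds, ds[1:]))
        assert ds[-1] < 0.01  # d ~ (32 a b^3)^(1/4) -> 0 as b -> 0

    def test_rejects_nonpositive(self):
        with pytest.raises(ValueError):
            equivalent_diameter(0.0, 10.0)


class TestHydraulicMean:
    def test_uniform_population(self):
        assert hydraulically_weighted_diameter([50.0, 50.0, 50.0]) == 50.0

    def test_two_sizes(self):
        # brute force: (40^5 + 60^5) / (40^4 + 60^4)
        assert hydraulically_weighted_diameter([40.0, 60.0]) == pytest.approx(
            56.70, abs=0.01)

    def test_single_vessel(self):
        assert hydraulically_weighted_diameter([37.2]) == pytest.approx(37.2)

    def test_empty_raises(self):
        with pytest.raises(ValueError):
            hydraulically_weighted_diameter([])

    @settings(derandomize=True, max_examples=50)
    @given(st.lists(st.floats(1.0, 300.0), min_size=1, max_size=60))
    def test_bounds_and_mean_ordering(self, diameters):
        dh = hydraulically_weighted_diameter(diameters)
        assert min(diameters) - 1e-9 <= dh <= max(diameters) + 1e-9
        assert dh >= np.mean(diameters) - 1e-9  # weighting favors wide vessels


def _pop(radii_um, area_mm2=1.0):
    return VesselPopulation(
        vessels=tuple(VesselMeasure(r, r) for r in radii_um),
        analyzed_area_mm2=area_mm2)


class TestConductivity:
    def test_empty_population_is_zero(self):
        pop = VesselPopulation(vessels=(), analyzed_area_mm2=1.0)
        assert theoretical_conductivity(pop) == (0.0, 0.0)

    def test_single_vessel_unit_tracked(self):
        # independent unit-tracked oracle: r = 25 um in 1 mm^2
        r = 25e-6
        eta, rho = 1.002e-3, 998.2
        k_h_si = np.pi * r**4 / (8 * eta) * rho      # kg m Pa^-1 s^-1
        expect = k_h_si / 1e-6 * 1e6                 # per MPa, per m^2
        _, k_s = theoretical_conductivity(_pop([25.0]))
        assert k_s == pytest.approx(expect, rel=1e-12)
        assert k_s == pytest.approx(0.1528, rel=5e-3)

    def test_r4_scaling(self):
        k1, _ = theoretical_conductivity(_pop([10.0, 20.0, 30.0]))
        k2, _ = theoretical_conductivity(_pop([20.0, 40.0, 60.0]))
        assert k2 == pytest.approx(16.0 * k1, rel=1e-12)

    def test_additive_over_partitions(self):
        radii = [12.0, 25.0, 31.0, 44.0]
        k_all, _ = theoretical_conductivity(_pop(radii))
        k_a, _ = theoretical_conductivity(_pop(radii[:2]))
        k_b, _ = theoretical_conductivity(_pop(radii[2:]))
        assert k_all == pytest.approx(k_a + k_b, rel=1e-12)

    def test_order_invariance(self):
        radii = [12.0, 25.0, 31.0, 44.0]
        k1, _ = theoretical_conductivity(_pop(radii))
        k2, _ = theoretical_conductivity(_pop(radii[::-1]))
        assert k1 == pytest.approx(k2, rel=1e-14)


class TestPopulationSummary:
    def test_arithmetic_oracle(self):
        s = population_summary(_pop([25.0] * 100, area_mm2=10.0))
        assert s.vd_per_mm2 == pytest.approx(10.0)
        assert s.lumen_fraction_pct == pytest.approx(
            100 * 100 * np.pi * 625 / 1e7, rel=1e-12)
        assert s.lumen_fraction_pct == pytest.approx(1.963, abs=0.001)

    def test_single_vessel_degenerate(self):
        s = population_summary(_pop([25.0]))
        assert s.d_max_um == s.d_h_um == pytest.approx(50.0)

    def test_empty_population_warns(self):
        pop = VesselPopulation(vessels=(), analyzed_area_mm2=1.0)
        with pytest.warns(UserWarning):
            s = population_summary(pop)
        assert s.n_vessels == 0 and s.k_s == 0.0

    def test_stem_ks_in_published_span(self):
        """A lognormal population at stem-wood magnitudes lands inside the
        printed species range of K_S (5.72-209.74 kg m^-1 MPa^-1 s^-1)."""
        pop = generate_vessel_population(n_vessels=300, d_median_um=100.0,
                                         d_sigma=0.25, analyzed_area_mm2=10.0,
                                         seed=2)
        s = population_summary(pop)
        assert 5.72 <= s.k_s <= 209.74

    def test_calibrated_population_hits_targets(self):
        """The target-calibrated generator reproduces a species' published
        d_h and lumen-area percentage and yields a K_S in the printed span."""
        from woodfrac.synthesis import vessel_population_for_targets

        # E. haemastoma stem targets: d_h 195.73 um, A_lumen 19.97 %
        pop = vessel_population_for_targets(d_h_um=195.73, a_lumen_pct=19.97,
                                            analyzed_area_mm2=15.0, seed=1)
        s = population_summary(pop)
        # finite-sample tail weighting pulls sample d_h a few % below the
        # population value exp(mu + 4.5 sigma^2) the calibration inverts
        assert s.d_h_um == pytest.approx(195.73, rel=0.10)
        assert s.lumen_fraction_pct == pytest.approx(19.97, rel=0.10)
        assert 5.72 <= s.k_s <= 209.74  # published stem K_S span


def test_lumen_fraction_matches_raster():
    """Sum of ellipse areas agrees with the rasterised conduit fraction
    within rasterisation error (<= 1 percentage point); conduits must be
    whole (unclipped) for the ellipse areas to be exact."""
    sc = generate_section_scene(SceneParams(clip_at_edges=False), seed=7)
    area_um2 = sum(np.pi * a * b for a, b in sc.conduit_ellipses)
    total_um2 = sc.label_map.width_um * sc.label_map.height_um
    assert abs(area_um2 / total_um2 - sc.true_fractions["conduit"]) < 0.01
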