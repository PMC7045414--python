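"""Grid construction and point-count estimation on labelled rasters."""

import numpy as np
import pytest

from woodfrac.stereology import (GridSpec, PointCountResult, StereologyError,
                                 TissueLabelMap, build_grid, point_count,
                                 total_parenchyma)
from woodfrac.synthesis import CATEGORY_CODES, SceneParams, \
    generate_section_scene


def _uniform_map(code=4, shape=(500, 500), um_per_pixel=4.0):
    return TissueLabelMap(raster=np.full(shape, code, dtype=np.uint8),
                          um_per_pixel=um_per_pixel)


class TestBuildGrid:
    def test_lattice_count_rectangle(self):
        # 2 mm x 3 mm at 140 um spacing, zero offset: 15 x 22 nodes
        lmap = TissueLabelMap(np.full((750, 500), 4, np.uint8), 4.0)
        pts = build_grid(lmap, GridSpec(spacing_um=140.0))
        assert len(pts) == 15 * 22

    def test_spacing_larger_than_image(self):
        lmap = _uniform_map(shape=(100, 100))
        pts = build_grid(lmap, GridSpec(spacing_um=10_000.0))
        assert len(pts) == 1 and tuple(pts[0]) == (0.0, 0.0)

    def test_full_mask_equals_no_mask(self):
        raster = np.full((200, 300), 4, np.uint8)
        a = build_grid(TissueLabelMap(raster, 4.0), GridSpec(130.0))
        b = build_grid(TissueLabelMap(raster, 4.0,
                                      region_mask=np.ones_like(raster, bool)),
                       GridSpec(130.0))
        assert np.array_equal(a, b)

    def test_spacing_below_pixel_pitch_rejected(self):
        with pytest.raises(StereologyError):
            build_grid(_uniform_map(), GridSpec(spacing_um=5.0))


class TestPointCount:
    def test_pure_fiber_raster(self):
        res = point_count(_uniform_map(code=CATEGORY_CODES["fiber"]),
                          GridSpec(130.0))
        assert res.fractions["fiber"] == 1.0
        assert all(v == 0.0 for k, v in res.fractions.items() if k != "fiber")
        assert sum(res.counts.values()) == res.n_total

    def test_spacing_halved_until_minimum(self):
        lmap = _uniform_map(shape=(250, 250))  # 1 mm x 1 mm
        res = point_count(lmap, GridSpec(130.0), min_intersections=300)
        assert res.n_total >= 300
        assert res.spacing_used_um < 130.0

    def test_region_too_small_fails(self):
        lmap = _uniform_map(shape=(20, 20))  # 80 um x 80 um
        with pytest.raises(StereologyError):
            point_count(lmap, GridSpec(60.0), min_intersections=10_000)

    def test_stem_region_6mm2_meets_minimum(self):
        """A 2 x 3 mm stem region at the default 130 um spacing clears the
        300-intersection floor without halving."""
        lmap = TissueLabelMap(np.full((750, 500), 4, np.uint8), 4.0)
        res = point_count(lmap, GridSpec.default("stem"))
        assert res.n_total >= 300
        assert res.spacing_used_um == 130.0

    def test_estimate_within_three_se(self):
        """On a scene with true conduit fraction 0.30 and ~1000 nodes the
        point-count estimate lies within 3 binomial SE of the truth."""
        params = SceneParams(conduit_fraction=0.30, ray_fraction=0.10,
                             sheath_thickness_um=0.0,
                             width_um=2000.0, height_um=2000.0)
        scene = generate_section_scene(params, seed=21)
        res = point_count(scene.label_map, GridSpec(62.0, offset_um=None),
                          seed=5)
        assert res.n_total == pytest.approx(1000, rel=0.1)
        truth = scene.true_fractions["conduit"]
        assert abs(res.fractions["conduit"] - truth) <= 3 * res.se["conduit"]

    def test_category_relabel_permutes_counts(self):
        scene = generate_section_scene(SceneParams(), seed=3)
        res = point_count(scene.label_map, GridSpec(130.0), seed=9)
        # swap conduit (1) and fiber (4) codes
        swapped = scene.label_map.raster.copy()
        swapped[scene.label_map.raster == 1] = 4
        swapped[scene.label_map.raster == 4] = 1
        res2 = point_count(TissueLabelMap(swapped, 2.0), GridSpec(130.0),
                           seed=9)
        assert res2.counts["fiber"] == res.counts["conduit"]
        assert res2.counts["conduit"] == res.counts["fiber"]
        assert res2.counts["ray_parenchyma"] == res.counts["ray_parenchyma"]

    def test_exclude_other_renormalises(self):
        params = SceneParams(other_fraction=0.05)
        scene = generate_section_scene(params, seed=13)
        incl = point_count(scene.label_map, GridSpec(130.0), seed=1)
        excl = point_count(scene.label_map, GridSpec(130.0), seed=1,
                           include_other=False)
        assert "other" not in excl.fractions
        assert sum(excl.fractions.values()) == pytest.approx(1.0)
        assert excl.fractions["fiber"] >= incl.fractions["fiber"]

    def test_se_shrinks_as_inverse_sqrt_n(self, default_scene):
        """Halving the spacing quadruples n and halves the binomial SE."""
        coarse = point_count(default_scene.label_map, GridSpec(120.0), seed=2)
        fine = point_count(default_scene.label_map, GridSpec(60.0), seed=2)
        ratio = coarse.se["ray_parenchyma"] / fine.se["ray_parenchyma"]
        n_ratio = np.sqrt(fine.n_total / coarse.n_total)
        assert ratio == pytest.approx(n_ratio, rel=0.15)


def test_total_parenchyma_sums_axial_and_ray():
    res = PointCountResult(
        counts={"axial_parenchyma": 10, "ray_parenchyma": 15, "fiber": 75},
        n_total=100,
        fractions={"axial_parenchyma": 0.10, "ray_parenchyma": 0.15,
                   "fiber": 0.75},
        se={}, spacing_used_um=130.0, offset_um=(0.0, 0.0))
    assert total_parenchyma(res) == pytest.approx(0.25)


def test_offset_randomisation_is_seeded(default_scene):
    a = point_count(default_scene.label_map, GridSpec(130.0, offset_um=None),
                    seed=17)
    b = point_count(default_scene.label_map, GridSpec(130.0, offset_um=None),
                    seed=17)
    assert a.offset_um == b.offset_um and a.counts == b.counts


def test_unbiasedness_over_random_offsets(default_scene):
    """Mean point-count fraction over 60 random grid offsets tracks the
    pixel truth within a small multiple of the SE of the mean."""
    scene = default_scene
    estimates, ses = [], []
    for seed in range(60):
        res = point_count(scene.label_map, GridSpec(130.0, offset_um=None),
                          seed=seed)
        estimates.append(res.fractions["conduit"])
        ses.append(res.se["conduit"])
    pooled_se = float(np.sqrt(np.mean(np.square(ses))))
    bias = abs(np.mean(estimates) - scene.true_fractions["conduit"])
    assert bias <= pooled_se
    assert bias <= 3 * np.std(estimates, ddof=1) / np.sqrt(len(estimates))
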