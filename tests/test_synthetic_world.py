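"""Scene construction, trunk viewpoints, the renderer and angular fixtures."""

import dataclasses

import numpy as np
import pytest

import trunknav as tn
from trunknav.panorama_ops import ELEV_TOP_DEG
from trunknav.synthetic_world import (
    Scene,
    Tree,
    build_scene,
    default_scene_config,
    nest_tree_scene_config,
    render_panorama,
    sample_angles,
    trunk_viewpoint,
)

TRUNK = dict(trunk_radius=0.15, trunk_height=6.0, canopy_radius=1.8,
             canopy_center_height=5.0)


def minimal_config(**over):
    cfg = {
        "trees": [dict(name="foraging", x=0.0, y=0.0, **TRUNK),
                  dict(name="nest_tree", x=0.0, y=3.25, **TRUNK)],
        "nest": {"x": 0.0, "y": 3.0, "tree": "nest_tree"},
        "texture": {"amplitude": 0.0, "seed": 0},
    }
    cfg.update(over)
    return cfg


class TestBuildScene:
    def test_screen_extents_from_config(self):
        scene = build_scene(default_scene_config(include_screen=True))
        s = scene.screen
        assert s is not None
        assert 2 * s.half_width == pytest.approx(1.5)
        assert (s.z_min, s.z_max) == (0.05, 2.0)

    def test_minimal_scene_has_exactly_named_trees(self):
        scene = build_scene(minimal_config())
        assert [t.name for t in scene.trees] == ["foraging", "nest_tree"]
        assert scene.screen is None

    def test_deterministic(self):
        assert build_scene(default_scene_config()) == build_scene(
            default_scene_config()
        )

    def test_rejects_overlapping_trunks(self):
        cfg = minimal_config()
        cfg["trees"][1].update(x=0.0, y=0.2)
        with pytest.raises(ValueError, match="overlap"):
            build_scene(cfg)

    def test_rejects_nest_inside_trunk(self):
        cfg = minimal_config()
        cfg["nest"] = {"x": 0.0, "y": 0.05, "tree": "nest_tree"}
        with pytest.raises(ValueError, match="nest"):
            build_scene(cfg)

    def test_rejects_bad_intensity_and_empty_screen(self):
        with pytest.raises(ValueError):
            build_scene(minimal_config(ground_intensity=300.0))
        cfg = minimal_config()
        cfg["screen"] = dict(center_x=0, center_y=0, half_width=0.75,
                             z_min=1.0, z_max=1.0)
        with pytest.raises(ValueError, match="height range"):
            build_scene(cfg)

    def test_nest_bearing_is_zero_for_focal_tree(self):
        for cfg, tree in ((default_scene_config(), "foraging"),
                          (nest_tree_scene_config(), "nest_tree")):
            assert build_scene(cfg).nest_bearing(tree) == pytest.approx(0.0)


class TestTrunkViewpoint:
    def test_nest_side_at_ground(self):
        scene = build_scene(minimal_config())
        vp = trunk_viewpoint(scene, "foraging", 0.0, 0.0, offset=0.02)
        assert (vp.x, vp.y, vp.z) == pytest.approx((0.0, 0.17, 0.0))

    def test_opposite_side_at_two_metres(self):
        scene = build_scene(minimal_config())
        vp = trunk_viewpoint(scene, "foraging", 180.0, 2.0, offset=0.02)
        assert (vp.x, vp.y, vp.z) == pytest.approx((0.0, -0.17, 2.0), abs=1e-12)
        assert np.hypot(vp.x, vp.y) == pytest.approx(0.17)

    def test_90_degrees_against_trig_oracle(self, foraging_scene):
        tree = foraging_scene.tree("foraging")
        vp = trunk_viewpoint(foraging_scene, "foraging", 90.0, 1.0, offset=0.02)
        # independent 2-D trigonometry: nest is due +y, so 90 deg clockwise
        # from the nest side is due +x of the trunk axis
        rad = tree.trunk_radius + 0.02
        assert vp.x == pytest.approx(tree.x + rad * np.sin(np.pi / 2))
        assert vp.y == pytest.approx(tree.y + rad * np.cos(np.pi / 2), abs=1e-12)
        bearing = np.rad2deg(np.arctan2(vp.x - tree.x, vp.y - tree.y)) % 360
        assert bearing == pytest.approx(90.0)

    def test_errors(self, foraging_scene):
        with pytest.raises(KeyError):
            trunk_viewpoint(foraging_scene, "oak", 0, 0)
        with pytest.raises(ValueError):
            trunk_viewpoint(foraging_scene, "foraging", 0, 99.0)
        with pytest.raises(ValueError):
            trunk_viewpoint(foraging_scene, "foraging", 0, 1.0, offset=0.0)


def rotated_scene(scene: Scene, vp, k_deg: float) -> Scene:
    """Rotate every tree clockwise by k about the viewpoint's vertical axis."""
    kr = np.deg2rad(k_deg)
    trees = []
    for t in scene.trees:
        dx, dy = t.x - vp.x, t.y - vp.y
        rho, b = np.hypot(dx, dy), np.arctan2(dx, dy)
        trees.append(
            dataclasses.replace(
                t, x=vp.x + rho * np.sin(b + kr), y=vp.y + rho * np.cos(b + kr)
            )
        )
    return dataclasses.replace(scene, trees=tuple(trees))


class TestRender:
    def test_empty_scene_sky_above_ground_below(self):
        scene = Scene(trees=(), nest_x=0, nest_y=3, nest_tree="",
                      ground_intensity=40.0, sky_intensity=255.0)
        p = render_panorama(scene, tn.Viewpoint(0, 0, 1.0), texture=False)
        elev = ELEV_TOP_DEG - np.arange(117)
        assert np.all(p.grid[elev > 0, :] == 255.0)
        assert np.all(p.grid[elev < 0, :] == 40.0)

    def test_single_distant_trunk_angular_width(self):
        d, r = 5.0, 0.5
        tree = Tree("t", d * np.sin(np.pi / 2), d * np.cos(np.pi / 2),
                    r, 10.0, 0.5, 10.5)
        scene = Scene(trees=(tree,), nest_x=0, nest_y=3, nest_tree="t")
        p = render_panorama(scene, tn.Viewpoint(0, 0, 1.0), texture=False)
        row = int(ELEV_TOP_DEG - 30)  # +30 deg elevation: trunk or sky only
        dark = p.grid[row] == tree.trunk_intensity
        half = np.rad2deg(np.arcsin(r / d))
        for c in range(360):
            az = c + 0.5
            inside = abs(az - 90.0) < half  # oracle: ray-circle intersection
            assert dark[c] == inside, f"column {c}"
        assert dark.sum() == pytest.approx(2 * half, abs=1.0)

    def test_self_occlusion_by_own_trunk(self):
        cfg = minimal_config()
        cfg["trees"][1]["trunk_intensity"] = 80.0  # distinguish the two trunks
        scene = build_scene(cfg).without_texture()
        vp = trunk_viewpoint(scene, "foraging", 180.0, 1.0, offset=0.02)
        p = render_panorama(scene, vp, texture=False)
        row = int(ELEV_TOP_DEG - 10)  # +10 deg elevation, azimuth 0 column
        assert p.grid[row, 0] == scene.tree("foraging").trunk_intensity
        # without the focal tree the same ray reaches past the nest tree to sky
        bare = dataclasses.replace(
            scene, trees=tuple(t for t in scene.trees if t.name != "foraging")
        )
        q = render_panorama(bare, vp, texture=False)
        assert q.grid[row, 0] != scene.tree("foraging").trunk_intensity

    @pytest.mark.parametrize("k", [0, 37, 90, 180])
    def test_scene_rotation_equals_column_shift(self, k):
        scene = build_scene(default_scene_config()).without_texture()
        vp = trunk_viewpoint(scene, "foraging", 45.0, 1.2)
        base = render_panorama(scene, vp, texture=False)
        rot = render_panorama(rotated_scene(scene, vp, k), vp, texture=False)
        assert np.array_equal(rot.grid, np.roll(base.grid, k, axis=1))

    def test_raising_viewpoint_lowers_object_top(self):
        tree = Tree("t", 0.0, 4.0, 0.3, 2.5, 0.3, 2.9)
        scene = Scene(trees=(tree,), nest_x=0, nest_y=1, nest_tree="t")
        col = 0  # tree due +y of the viewer at azimuth ~0.5 deg
        tops = []
        for z in (0.0, 1.0, 1.75):
            p = render_panorama(scene, tn.Viewpoint(0, 0, z), texture=False)
            rows = np.flatnonzero(p.grid[:, col] == tree.trunk_intensity)
            tops.append(ELEV_TOP_DEG - rows.min())  # apparent top elevation
        assert tops[0] > tops[1] > tops[2]

    def test_screen_blocks_outside_world_below_top(self):
        cfg = nest_tree_scene_config(include_screen=True)
        for t in cfg["trees"]:
            if t["name"] != "nest_tree":
                t["trunk_intensity"] = 200.0  # marker intensity
        cfg["texture"]["amplitude"] = 0.0
        scene = build_scene(cfg)
        vp = trunk_viewpoint(scene, "nest_tree", 90.0, 1.0)
        p = render_panorama(scene, vp, texture=False)
        elev = ELEV_TOP_DEG - np.arange(117)
        # farthest wall corner is ~1.2 m away, screen top 1 m above the eye:
        # nothing beyond the screen is visible below 35 deg elevation
        assert not np.any(p.grid[elev < 35.0, :] == 200.0)
        unscreened = render_panorama(scene.without_screen(), vp, texture=False)
        assert np.any(unscreened.grid[elev < 35.0, :] == 200.0)

    def test_deterministic_rendering(self, foraging_scene):
        vp = trunk_viewpoint(foraging_scene, "foraging", 30.0, 0.8)
        a = render_panorama(foraging_scene, vp)
        b = render_panorama(foraging_scene, vp)
        assert np.array_equal(a.grid, b.grid)

    def test_errors(self, foraging_scene):
        inside = tn.Viewpoint(0.0, 0.0, 1.0)  # trunk axis of the focal tree
        with pytest.raises(ValueError, match="inside"):
            render_panorama(foraging_scene, inside)
        vp = trunk_viewpoint(foraging_scene, "foraging", 0, 1.0)
        with pytest.raises(ValueError):
            render_panorama(foraging_scene, vp, width=100)
        with pytest.raises(ValueError):
            render_panorama(foraging_scene, vp, height=0)


class TestSampleAngles:
    def test_concentration_limit(self):
        s = sample_angles("vonmises", 5, seed=1, mu=0.0, kappa=1e6)
        wrapped = (s.angles + 180) % 360 - 180
        assert np.all(np.abs(wrapped) < 0.5)

    def test_uniform_resultant_small(self):
        s = sample_angles("uniform", 10_000, seed=2)
        _, r = tn.circ_mean(s.angles)
        assert r < 0.05

    def test_determinism(self):
        a = sample_angles("vonmises", 50, seed=3, mu=10, kappa=2)
        b = sample_angles("vonmises", 50, seed=3, mu=10, kappa=2)
        assert np.array_equal(a.angles, b.angles)

    def test_kappa_zero_is_uniform(self):
        s = sample_angles("vonmises", 10_000, seed=4, mu=0, kappa=0.0)
        _, r = tn.circ_mean(s.angles)
        assert r < 0.05

    def test_rejects_bad_arguments(self):
        with pytest.raises(ValueError):
            sample_angles("vonmises", 5, seed=0, kappa=-1.0)
        with pytest.raises(ValueError):
            sample_angles("uniform", 0, seed=0)
        with pytest.raises(ValueError):
            sample_angles("gaussian", 5, seed=0)

    def test_frame_columns(self):
        df = sample_angles("uniform", 5, seed=0).to_frame("cond", 1.0)
        assert list(df.columns) == ["angle_deg", "condition", "height_m", "replicate"]
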