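"""Synthetic 3-D scenes and an equirectangular panorama renderer.

The world emulates the visual structure that matters for trunk-descending
ants in an open eucalypt stand: a bright uniform sky, dark tree trunks
(vertical cylinders) topped by canopies (spheres), a flat ground plane, and
optionally an opaque screen (four vertical rectangles, suspended a few
centimetres off the ground) boxing in the nest tree.  A deterministic
procedural texture anchored in world coordinates adds bark/foliage/ground
variation so that symmetric scenes do not produce degenerate all-equal
mismatch curves.

The renderer casts one ray per pixel from a viewpoint just off the bark and
returns the canonical world-aligned 360 x 117 panorama (see
:mod:`trunknav.panorama_ops`): column 0 is world azimuth 0 deg -- the nest
direction, by construction of the scene presets -- increasing clockwise,
rows span +66..-50 deg elevation.  Occlusion is respected, including
self-occlusion by the trunk the viewer stands beside, which covers well
over 100 deg of azimuth at a 2 cm eye offset.

Angular behavioural fixtures (von Mises or uniform direction samples) live
here too, so every downstream stage is testable without field data.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from trunknav.panorama_ops import ELEV_TOP_DEG, PANO_HEIGHT, PANO_WIDTH, Panorama

_EPS = 1e-9
#: minimum eye height above the ground plane used when rendering, metres.
#: An eye exactly in the plane of the ground would see it edge-on.
MIN_EYE_HEIGHT = 0.01
#: default camera offset from the bark surface, metres (ant eye height).
DEFAULT_EYE_OFFSET = 0.02
#: offset of the panoramic camera used for the ground-level reference view
#: at the tree base, metres: a camera on its mount next to the trunk sits
#: well proud of the bark, unlike an ant pressed against it.
BASE_CAMERA_OFFSET = 0.25


@dataclass(frozen=True)
class Tree:
    """A trunk (finite vertical cylinder) plus a canopy (sphere)."""

    name: str
    x: float
    y: float
    trunk_radius: float
    trunk_height: float
    canopy_radius: float
    canopy_center_height: float
    trunk_intensity: float = 60.0
    canopy_intensity: float = 85.0


@dataclass(frozen=True)
class Screen:
    """Opaque square enclosure: four vertical walls around (center_x, center_y).

    The walls span ``z_min``..``z_max``; the default 5 cm gap at the bottom
    mirrors a screen suspended just off the ground so ants can pass under.
    """

    center_x: float
    center_y: float
    half_width: float
    z_min: float = 0.05
    z_max: float = 2.0
    intensity: float = 120.0


@dataclass(frozen=True)
class TextureNoise:
    """Additive, deterministic, world-anchored intensity texture.

    The field is anisotropic: variation is strong in the horizontal plane
    and weak vertically (``z_scale``), emulating the vertically streaked
    bark of eucalypts -- a trunk looks different from different compass
    sides but much the same at different heights on the same side.
    """

    amplitude: float = 70.0
    seed: int = 0
    z_scale: float = 0.03


@dataclass(frozen=True)
class Viewpoint:
    """Camera position in metres; panoramas rendered from here are
    world-aligned (column 0 = world azimuth 0 = nest direction)."""

    x: float
    y: float
    z: float


@dataclass(frozen=True)
class Scene:
    trees: tuple[Tree, ...]
    nest_x: float
    nest_y: float
    nest_tree: str
    ground_intensity: float = 40.0
    sky_intensity: float = 255.0
    screen: Screen | None = None
    texture: TextureNoise = field(default_factory=TextureNoise)

    def tree(self, name: str) -> Tree:
        for t in self.trees:
            if t.name == name:
                return t
        raise KeyError(f"unknown tree {name!r}")

    def nest_bearing(self, tree_id: str) -> float:
        """World bearing (deg clockwise from +y) from a trunk axis to the nest."""
        t = self.tree(tree_id)
        return float(
            np.rad2deg(np.arctan2(self.nest_x - t.x, self.nest_y - t.y)) % 360.0
        )

    def with_screen(self, screen: Screen) -> "Scene":
        return replace(self, screen=screen)

    def without_screen(self) -> "Scene":
        return replace(self, screen=None)

    def without_texture(self) -> "Scene":
        return replace(self, texture=TextureNoise(amplitude=0.0, seed=self.texture.seed))


def build_scene(config) -> Scene:
    """Validate a scene configuration (dict, YAML or JSON path) into a Scene.

    Rejects overlapping trunk cross-sections and a nest placed inside a
    trunk; all intensities must lie in [0, 255] and a screen's height range
    must be non-empty.
    """
    if isinstance(config, (str, Path)):
        config = load_config(config)
    trees = []
    for spec in config["trees"]:
        trees.append(Tree(**spec))
    if not trees:
        raise ValueError("scene needs at least one tree")
    names = [t.name for t in trees]
    if len(set(names)) != len(names):
        raise ValueError("tree names must be unique")
    for t in trees:
        if t.trunk_radius <= 0:
            raise ValueError(f"tree {t.name!r}: trunk radius must be > 0")
        if t.trunk_height <= 0 or t.canopy_radius <= 0:
            raise ValueError(f"tree {t.name!r}: non-positive dimensions")
        for v in (t.trunk_intensity, t.canopy_intensity):
            if not 0.0 <= v <= 255.0:
                raise ValueError(f"tree {t.name!r}: intensity outside [0, 255]")
    for i, a in enumerate(trees):
        for b in trees[i + 1 :]:
            if np.hypot(a.x - b.x, a.y - b.y) <= a.trunk_radius + b.trunk_radius:
                raise ValueError(
                    f"overlapping trunk cross-sections: {a.name!r} and {b.name!r}"
                )
    nest = config["nest"]
    nx, ny, nest_tree = float(nest["x"]), float(nest["y"]), nest["tree"]
    if nest_tree not in names:
        raise ValueError(f"nest abuts unknown tree {nest_tree!r}")
    for t in trees:
        if np.hypot(nx - t.x, ny - t.y) <= t.trunk_radius:
            raise ValueError(f"nest lies inside trunk of {t.name!r}")
    ground = float(config.get("ground_intensity", 40.0))
    sky = float(config.get("sky_intensity", 255.0))
    for v in (ground, sky):
        if not 0.0 <= v <= 255.0:
            raise ValueError("ground/sky intensity outside [0, 255]")
    screen = None
    if config.get("screen") is not None:
        screen = Screen(**config["screen"])
        if screen.z_max <= screen.z_min:
            raise ValueError("screen height range is empty")
        if screen.half_width <= 0:
            raise ValueError("screen half-width must be > 0")
        if not 0.0 <= screen.intensity <= 255.0:
            raise ValueError("screen intensity outside [0, 255]")
    tex = TextureNoise(**config.get("texture", {}))
    if tex.amplitude < 0:
        raise ValueError("texture amplitude must be >= 0")
    return Scene(
        trees=tuple(trees),
        nest_x=nx,
        nest_y=ny,
        nest_tree=nest_tree,
        ground_intensity=ground,
        sky_intensity=sky,
        screen=screen,
        texture=tex,
    )


# ---------------------------------------------------------------------------
# scene presets
#
# The two presets mirror the two experimental geometries: (a) a foraging
# tree 3 m from the nest, with the nest tree just behind the nest, and (b)
# the nest tree itself with the nest 10 cm from its bark, optionally boxed
# in by a 1.5 x 1.5 m screen 2 m high with a 5 cm ground gap.  In both, the
# world frame is chosen so that azimuth 0 (the +y axis) is the nest
# direction as seen from the focal tree.  Distractor trees are hand-placed
# at mixed bearings and distances (2.5-7 m) with varied sizes and slightly
# varied bark/foliage intensities, so the skyline height varies with
# azimuth and the scene has no mirror symmetry.


def _distractors(entries):
    keys = (
        "name", "x", "y", "trunk_radius", "trunk_height",
        "canopy_radius", "canopy_center_height", "trunk_intensity",
        "canopy_intensity",
    )
    return [dict(zip(keys, e)) for e in entries]


def default_scene_config(include_screen: bool = False, texture_seed: int = 0) -> dict:
    """Foraging-tree layout: focal tree at the origin, nest 3 m away at azimuth 0."""
    trees = [
        dict(name="foraging", x=0.0, y=0.0, trunk_radius=0.15, trunk_height=6.0,
             canopy_radius=1.8, canopy_center_height=5.0),
        # nest tree just behind the nest (bark 10 cm from the nest entrance)
        dict(name="nest_tree", x=0.0, y=3.25, trunk_radius=0.15, trunk_height=6.0,
             canopy_radius=1.8, canopy_center_height=5.0),
    ] + _distractors([
        ("d1", 2.6, 4.4, 0.22, 7.0, 2.2, 6.0, 55.0, 80.0),
        ("d2", -3.4, 2.0, 0.18, 5.5, 1.9, 4.6, 65.0, 92.0),
        ("d3", 4.2, -0.8, 0.28, 8.0, 2.6, 6.6, 58.0, 83.0),
        ("d4", -2.3, -3.6, 0.14, 4.5, 1.5, 3.8, 70.0, 88.0),
        ("d5", 0.9, -5.2, 0.20, 6.5, 2.0, 5.4, 62.0, 78.0),
    ])
    cfg = {
        "trees": trees,
        "nest": {"x": 0.0, "y": 3.0, "tree": "nest_tree"},
        "ground_intensity": 40.0,
        "sky_intensity": 255.0,
        "texture": {"amplitude": 70.0, "seed": texture_seed},
    }
    if include_screen:
        cfg["screen"] = dict(center_x=0.0, center_y=3.25, half_width=0.75,
                             z_min=0.05, z_max=2.0, intensity=120.0)
    return cfg


def nest_tree_scene_config(include_screen: bool = False, texture_seed: int = 0) -> dict:
    """Nest-tree layout: focal tree at the origin, nest 10 cm from its bark.

    ``include_screen`` adds the blocking enclosure (1.5 x 1.5 m square,
    walls from 5 cm to 2 m) centred on the nest tree; the nest entrance
    lies inside the enclosure, as in the blocking experiment.
    """
    trees = [
        dict(name="nest_tree", x=0.0, y=0.0, trunk_radius=0.15, trunk_height=6.0,
             canopy_radius=1.8, canopy_center_height=5.0),
        dict(name="foraging", x=1.2, y=-3.8, trunk_radius=0.17, trunk_height=6.5,
             canopy_radius=2.0, canopy_center_height=5.5),
    ] + _distractors([
        ("d1", 2.4, 3.9, 0.22, 7.0, 2.2, 6.0, 55.0, 80.0),
        ("d2", -3.1, 1.4, 0.18, 5.5, 1.9, 4.6, 65.0, 92.0),
        ("d3", 4.4, -0.5, 0.28, 8.0, 2.6, 6.6, 58.0, 83.0),
        ("d4", -2.6, -3.2, 0.14, 4.5, 1.5, 3.8, 70.0, 88.0),
        ("d5", -1.3, 5.6, 0.20, 6.5, 2.0, 5.4, 62.0, 78.0),
    ])
    cfg = {
        "trees": trees,
        "nest": {"x": 0.0, "y": 0.25, "tree": "nest_tree"},
        "ground_intensity": 40.0,
        "sky_intensity": 255.0,
        "texture": {"amplitude": 70.0, "seed": texture_seed},
    }
    if include_screen:
        cfg["screen"] = dict(center_x=0.0, center_y=0.0, half_width=0.75,
                             z_min=0.05, z_max=2.0, intensity=120.0)
    return cfg


def load_config(path) -> dict:
    path = Path(path)
    text = path.read_text()
    if path.suffix.lower() == ".json":
        return json.loads(text)
    return yaml.safe_load(text)


def save_config(config: dict, path) -> Path:
    path = Path(path)
    if path.suffix.lower() == ".json":
        path.write_text(json.dumps(config, indent=2))
    else:
        path.write_text(yaml.safe_dump(config, sort_keys=False))
    return path


# ---------------------------------------------------------------------------
# viewpoints


def trunk_viewpoint(
    scene: Scene,
    tree_id: str,
    azimuth: float,
    height: float,
    offset: float = DEFAULT_EYE_OFFSET,
) -> Viewpoint:
    """Camera position on a trunk surface.

    ``azimuth`` is measured from the tree's nest-facing side (0 deg),
    increasing clockwise; the camera sits ``offset`` metres outside the
    bark at the given height.
    """
    tree = scene.tree(tree_id)  # KeyError for unknown id
    if offset <= 0:
        raise ValueError("offset must be > 0 (camera sits just outside the bark)")
    if height < 0 or height > tree.trunk_height:
        raise ValueError(
            f"height {height} outside trunk range [0, {tree.trunk_height}]"
        )
    bearing = np.deg2rad(scene.nest_bearing(tree_id) + azimuth)
    rad = tree.trunk_radius + offset
    return Viewpoint(
        x=tree.x + rad * np.sin(bearing),
        y=tree.y + rad * np.cos(bearing),
        z=height,
    )


def _assert_viewpoint_free(scene: Scene, vp: Viewpoint) -> None:
    if vp.z < 0:
        raise ValueError("viewpoint below the ground plane")
    for t in scene.trees:
        if (
            np.hypot(vp.x - t.x, vp.y - t.y) < t.trunk_radius - _EPS
            and 0.0 <= vp.z <= t.trunk_height
        ):
            raise ValueError(f"viewpoint inside trunk of {t.name!r}")
        d = np.sqrt(
            (vp.x - t.x) ** 2 + (vp.y - t.y) ** 2 + (vp.z - t.canopy_center_height) ** 2
        )
        if d < t.canopy_radius - _EPS:
            raise ValueError(f"viewpoint inside canopy of {t.name!r}")


def _texture_offsets(points: np.ndarray, texture: TextureNoise) -> np.ndarray:
    """Smooth value noise in [-1, 1] as a function of world position.

    A small sum of sinusoidal plane waves with seeded random wave vectors
    and phases: deterministic, view-consistent (the same surface point gets
    the same offset from every viewpoint) and cheap to evaluate.
    """
    rng = np.random.default_rng(texture.seed)
    k = 24
    freqs = rng.uniform(0.8, 8.0, k)
    dirs = rng.normal(size=(k, 3))
    dirs[:, 2] *= texture.z_scale
    dirs /= np.linalg.norm(dirs, axis=1, keepdims=True)
    phases = rng.uniform(0.0, 2.0 * np.pi, k)
    acc = np.zeros(points.shape[0])
    for i in range(k):
        acc += np.sin(2.0 * np.pi * freqs[i] * (points @ dirs[i]) + phases[i])
    return acc * (0.25 / np.sqrt(k / 2.0))


def render_panorama(
    scene: Scene,
    viewpoint: Viewpoint,
    width: int = PANO_WIDTH,
    height: int = PANO_HEIGHT,
    texture: bool = True,
) -> Panorama:
    """Ray-cast an equirectangular panorama from a viewpoint.

    One ray per pixel: azimuth ``(column + 0.5) * (360 / width)`` degrees
    clockwise from the nest direction, elevation on integer degrees from
    +66 (top row) down.  Each pixel takes the intensity of the nearest
    intersected primitive (trunk, canopy, screen wall, ground) plus the
    scene texture, or the sky intensity when nothing is hit.
    """
    if width <= 0 or height <= 0:
        raise ValueError("non-positive panorama dimensions")
    if 360 % width != 0:
        raise ValueError("width must divide 360 into whole-degree bins")
    _assert_viewpoint_free(scene, viewpoint)

    az = np.deg2rad((np.arange(width) + 0.5) * (360.0 / width))
    elev = np.deg2rad(ELEV_TOP_DEG - np.arange(height))
    aa, ee = np.meshgrid(az, elev)
    ce = np.cos(ee)
    d = np.stack(
        [ce * np.sin(aa), ce * np.cos(aa), np.sin(ee)], axis=-1
    ).reshape(-1, 3)
    o = np.array([viewpoint.x, viewpoint.y, max(viewpoint.z, MIN_EYE_HEIGHT)])

    n = d.shape[0]
    t_best = np.full(n, np.inf)
    val = np.full(n, float(scene.sky_intensity))
    hit = np.zeros(n, dtype=bool)

    def consider(t, intensity):
        closer = t < t_best
        t_best[closer] = t[closer]
        val[closer] = intensity
        hit[closer] = True

    dz = d[:, 2]
    with np.errstate(divide="ignore", invalid="ignore"):
        tg = np.where(dz < 0.0, -o[2] / dz, np.inf)
    consider(np.where(tg > _EPS, tg, np.inf), scene.ground_intensity)

    for tree in scene.trees:
        # trunk: finite vertical cylinder
        ox, oy = o[0] - tree.x, o[1] - tree.y
        dx, dy = d[:, 0], d[:, 1]
        a = dx * dx + dy * dy
        b = 2.0 * (ox * dx + oy * dy)
        c = ox * ox + oy * oy - tree.trunk_radius**2
        disc = b * b - 4.0 * a * c
        ok = (disc >= 0.0) & (a > 1e-14)
        sq = np.sqrt(np.where(ok, disc, 0.0))
        with np.errstate(divide="ignore", invalid="ignore"):
            for sign in (-1.0, 1.0):
                t = np.where(ok, (-b + sign * sq) / (2.0 * a), np.inf)
                z = o[2] + t * dz
                valid = ok & (t > _EPS) & (z >= 0.0) & (z <= tree.trunk_height)
                consider(np.where(valid, t, np.inf), tree.trunk_intensity)
        # canopy: sphere (ray directions are unit vectors, so a = 1)
        oc = o - np.array([tree.x, tree.y, tree.canopy_center_height])
        b = 2.0 * (d @ oc)
        c = float(oc @ oc) - tree.canopy_radius**2
        disc = b * b - 4.0 * c
        ok = disc >= 0.0
        sq = np.sqrt(np.where(ok, disc, 0.0))
        for sign in (-1.0, 1.0):
            t = np.where(ok, (-b + sign * sq) / 2.0, np.inf)
            consider(np.where(ok & (t > _EPS), t, np.inf), tree.canopy_intensity)

    if scene.screen is not None:
        s = scene.screen
        center = (s.center_x, s.center_y)
        for axis in (0, 1):
            other = 1 - axis
            for side in (-1.0, 1.0):
                coord = center[axis] + side * s.half_width
                da = d[:, axis]
                with np.errstate(divide="ignore", invalid="ignore"):
                    t = (coord - o[axis]) / da
                p_other = o[other] + t * d[:, other]
                z = o[2] + t * dz
                valid = (
                    np.isfinite(t)
                    & (t > _EPS)
                    & (np.abs(p_other - center[other]) <= s.half_width)
                    & (z >= s.z_min)
                    & (z <= s.z_max)
                )
                consider(np.where(valid, t, np.inf), s.intensity)

    if texture and scene.texture.amplitude > 0.0 and hit.any():
        pts = o[None, :] + t_best[hit, None] * d[hit]
        val[hit] = val[hit] + scene.texture.amplitude * _texture_offsets(
            pts, scene.texture
        )

    img = np.rint(np.clip(val, 0.0, 255.0)).reshape(height, width)
    return Panorama(img)


# ---------------------------------------------------------------------------
# angular behavioural fixtures


@dataclass(frozen=True)
class AngularSample:
    """A seeded sample of directions in degrees [0, 360)."""

    angles: np.ndarray
    distribution: str
    params: dict
    seed: int

    def to_frame(
        self, condition: str = "", height_m: float = np.nan
    ) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "angle_deg": self.angles,
                "condition": condition,
                "height_m": height_m,
                "replicate": np.arange(self.angles.size),
            }
        )


def sample_angles(
    distribution: str,
    n: int,
    seed: int,
    mu: float = 0.0,
    kappa: float = 0.0,
) -> AngularSample:
    """Draw ``n`` directions from a von Mises(mu, kappa) or uniform distribution.

    kappa = 0 reduces the von Mises to the circular uniform; kappa < 0 and
    n < 1 are rejected.  Reproducible given the seed.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    if distribution == "uniform":
        a = rng.uniform(0.0, 360.0, n)
        params = {}
    elif distribution == "vonmises":
        if kappa < 0:
            raise ValueError("kappa must be >= 0")
        a = np.rad2deg(rng.vonmises(np.deg2rad(mu), kappa, n)) % 360.0
        params = {"mu": float(mu), "kappa": float(kappa)}
    else:
        raise ValueError(f"unknown distribution {distribution!r}")
    return AngularSample(a, distribution, params, seed)
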