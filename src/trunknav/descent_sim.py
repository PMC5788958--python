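"""View-matching agents descending a cylindrical trunk.

Agents hold one or more panoramic memories acquired at the base of the
focal tree (nest side) and descend in fixed height steps, choosing lateral
(around-the-trunk) moves from the rotIDF between the current view and the
memory.  Two minimal motor policies are implemented, matching the two
candidate strategies for the real ants:

* ``gradient`` -- a gradient of familiarity: probe the mismatch at a few
  azimuth offsets at the current height and sidestep toward the best
  (lowest-mismatch) probe;
* ``compass`` -- a visual compass: read the rotation that best aligns the
  current view with memory and sidestep in the direction that shrinks the
  magnitude of that rotation.

Neither is claimed to be the ants' mechanism; they are the simplest motor
rules consistent with each reading of the view-matching signal.

In the landmark-blocked condition (screen around the nest tree) the agent
may find no usable signal: every probe's mismatch exceeds a per-scene
no-signal threshold.  It then wanders: the lateral move is drawn uniformly
around the trunk, the uninformed-search null that mirrors the looping
paths of real screened-in foragers.  In addition, with probability
``p_escape`` (default 0.5, matching the roughly half of real foragers that
climbed above the screen) it first climbs above the screen top, re-orients
there, and only then resumes its descent.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from trunknav import circular_stats
from trunknav.panorama_ops import Panorama, rotidf, wrap_signed
from trunknav.synthetic_world import (
    DEFAULT_EYE_OFFSET,
    Scene,
    render_panorama,
    trunk_viewpoint,
)

_NO_THRESHOLD = np.inf


@dataclass(frozen=True)
class TrunkPosition:
    """A point on a trunk surface: azimuth (deg, clockwise from the nest
    side at 0) and height above ground (m).

    The azimuth is stored unwrapped so that paths can be plotted and
    interpolated continuously; :attr:`azimuth_wrapped` reports it in
    (-180, 180], the convention used for unwrapped path plots where +180
    and -180 are the same position.
    """

    azimuth: float
    height: float

    def __post_init__(self):
        if self.height < 0:
            raise ValueError("height must be >= 0")

    @property
    def azimuth_wrapped(self) -> float:
        return wrap_signed(self.azimuth)


@dataclass(frozen=True)
class MemoryView:
    panorama: Panorama
    position: TrunkPosition


@dataclass(frozen=True)
class AgentPolicy:
    """Motor policy of a descending view-matching agent.

    ``scan_offsets`` (deg, symmetric about 0) are the azimuth probes of the
    gradient strategy, emulating a horizontal scan.  ``noise_kappa`` is the
    von Mises concentration of per-step motor noise on the lateral
    component; ``None`` disables noise.
    """

    strategy: str
    memory: tuple[MemoryView, ...]
    scan_offsets: tuple[float, ...] = (-40.0, -20.0, 0.0, 20.0, 40.0)
    step_down: float = 0.10
    lateral_step: float = 30.0
    noise_kappa: float | None = 10.0

    def __post_init__(self):
        if self.strategy not in ("gradient", "compass"):
            raise ValueError(f"unknown strategy {self.strategy!r}")
        if self.step_down <= 0:
            raise ValueError("step_down must be > 0")
        if self.lateral_step <= 0:
            raise ValueError("lateral_step must be > 0")
        offs = sorted(self.scan_offsets)
        if sorted(-o for o in offs) != offs:
            raise ValueError("scan_offsets must be symmetric about 0")
        object.__setattr__(self, "memory", tuple(self.memory))
        object.__setattr__(self, "scan_offsets", tuple(self.scan_offsets))


def acquire_memory(
    scene: Scene,
    tree_id: str,
    heights=(0.0,),
    azimuth: float = 0.0,
    offset: float = DEFAULT_EYE_OFFSET,
    n_views: int | None = None,
) -> tuple[MemoryView, ...]:
    """Render the agent's reference views on the focal trunk.

    The default is the single view the image analysis uses: the nest-facing
    side (azimuth 0) at the base of the tree.  Duplicate heights are
    deduplicated with a warning.
    """
    uniq = []
    for h in heights:
        if h in uniq:
            warnings.warn(f"duplicate memory height {h} ignored", stacklevel=2)
        else:
            uniq.append(h)
    if n_views is not None and n_views != len(uniq):
        raise ValueError(
            f"n_views={n_views} inconsistent with {len(uniq)} distinct heights"
        )
    views = []
    for h in uniq:
        vp = trunk_viewpoint(scene, tree_id, azimuth, h, offset)
        views.append(
            MemoryView(render_panorama(scene, vp), TrunkPosition(azimuth, h))
        )
    return tuple(views)


def familiarity(scene, viewpoint, memory, metric: str = "sad") -> float:
    """Scalar mismatch of the current view against memory (lower = more familiar).

    The minimum over memory views of the rotIDF best mismatch.  Because
    panoramas are world-aligned and the rotIDF scans all rotations, the
    value does not depend on any notion of agent heading.
    """
    if not memory:
        raise ValueError("memory is empty")
    cur = render_panorama(scene, viewpoint)
    return min(rotidf(m.panorama, cur, metric).best_mismatch for m in memory)


class ProbeCache:
    """Memoised view-matching probes on a trunk surface.

    Probe positions are quantised to 1 deg of azimuth and 1 cm of height --
    the renderer's azimuth resolution and a tenth of the default descent
    step -- so that agents revisiting the same region of trunk reuse
    renders and rotIDF curves.  Each cache is bound to one (scene, tree,
    memory, metric) combination.
    """

    def __init__(
        self,
        scene: Scene,
        tree_id: str,
        memory,
        metric: str = "sad",
        offset: float = DEFAULT_EYE_OFFSET,
    ):
        if not memory:
            raise ValueError("memory is empty")
        self.scene = scene
        self.tree_id = tree_id
        self.memory = tuple(memory)
        self.metric = metric
        self.offset = offset
        self._max_h = scene.tree(tree_id).trunk_height
        self._store: dict[tuple[int, int], tuple[float, float]] = {}

    def probe(self, azimuth: float, height: float) -> tuple[float, float]:
        """(best mismatch, signed best rotation in deg) at a trunk position."""
        key = (
            int(round(azimuth)) % 360,
            int(round(min(max(height, 0.0), self._max_h) * 100)),
        )
        if key not in self._store:
            vp = trunk_viewpoint(
                self.scene, self.tree_id, key[0], key[1] / 100.0, self.offset
            )
            cur = render_panorama(self.scene, vp)
            curves = [rotidf(m.panorama, cur, self.metric) for m in self.memory]
            best = min(curves, key=lambda c: c.best_mismatch)
            self._store[key] = (best.best_mismatch, best.best_rotation_signed)
        return self._store[key]

    def __len__(self) -> int:
        return len(self._store)


def no_signal_threshold(
    cache: ProbeCache,
    azimuths=(0.0, 45.0, 90.0, 135.0, 180.0, 225.0, 270.0, 315.0),
    heights=(0.1, 0.25, 0.5, 1.0, 1.5),
    factor: float = 0.9,
) -> float:
    """Mismatch level above which the agent treats the view as uninformative.

    Calibrated per scene as ``factor`` times the lowest mismatch found on a
    small grid of screened-in probe positions: inside the screen every view
    is dominated by the blank walls, so the grid minimum estimates the
    no-signal floor and any probe above ``factor`` x that floor carries no
    usable panorama information.
    """
    return factor * min(cache.probe(a, h)[0] for a in azimuths for h in heights)


def _lateral_decision(policy, cache, azimuth, height, threshold):
    """Informed lateral move in degrees, or (None, False) when no signal.

    Returns ``(delta, signal)``.  Gradient: sidestep ``lateral_step``
    toward the lowest-mismatch scan probe (exact tie -> stay).  Compass:
    compare |best rotation| at the current azimuth and one lateral step to
    either side; move to the strict minimiser (tie -> stay).
    """
    if policy.strategy == "gradient":
        fams = [cache.probe(azimuth + off, height)[0] for off in policy.scan_offsets]
        if min(fams) > threshold:
            return None, False
        fmin = min(fams)
        best = [off for off, f in zip(policy.scan_offsets, fams) if f == fmin]
        if len(best) > 1 or best[0] == 0.0:
            return 0.0, True
        return float(np.copysign(policy.lateral_step, best[0])), True
    # compass
    probes = {
        d: cache.probe(azimuth + d * policy.lateral_step, height)
        for d in (-1.0, 0.0, 1.0)
    }
    if min(p[0] for p in probes.values()) > threshold:
        return None, False
    scores = {d: abs(p[1]) for d, p in probes.items()}
    smin = min(scores.values())
    best = [d for d, s in scores.items() if s == smin]
    if len(best) > 1:
        return 0.0, True
    return best[0] * policy.lateral_step, True


def _motor_noise(policy, rng) -> float:
    if policy.noise_kappa is None:
        return 0.0
    return float(np.rad2deg(rng.vonmises(0.0, policy.noise_kappa)))


def step(
    state: TrunkPosition,
    policy: AgentPolicy,
    scene: Scene,
    tree_id: str,
    rng=None,
    cache: ProbeCache | None = None,
    threshold: float = _NO_THRESHOLD,
) -> TrunkPosition:
    """One descent step: choose a lateral move, add motor noise, step down.

    With an empty memory the policy degenerates to a uniform-random lateral
    walk (used to confirm that orientation in the full model comes from
    view matching, not trunk geometry).  Height never increases here; the
    blocked-condition escape climb lives in :func:`run_condition`.
    """
    if state.height <= 0:
        raise ValueError("agent already on the ground")
    if rng is None:
        rng = np.random.default_rng()
    if policy.memory:
        if cache is None:
            cache = ProbeCache(scene, tree_id, policy.memory)
        delta, signal = _lateral_decision(
            policy, cache, state.azimuth, state.height, threshold
        )
    else:
        delta, signal = None, False
    if delta is None:
        delta = float(rng.uniform(-180.0, 180.0))
    else:
        delta += _motor_noise(policy, rng)
    return TrunkPosition(
        state.azimuth + delta, max(state.height - policy.step_down, 0.0)
    )


@dataclass
class DescentResult:
    """Paths and height-crossing angles from one simulated condition."""

    paths: list  # raw per-agent paths, lists of TrunkPosition
    descents: list  # final-descent-filtered paths
    crossings: dict  # height (m) -> ndarray of azimuths, deg in [0, 360)
    escaped: list  # per-agent flag: climbed above the screen
    threshold: float
    cache: ProbeCache

    def crossings_frame(self, condition: str = "") -> pd.DataFrame:
        rows = []
        for h, az in sorted(self.crossings.items(), reverse=True):
            for i, a in enumerate(az):
                rows.append(
                    {
                        "condition": condition,
                        "height_m": h,
                        "agent": i,
                        "angle_deg": a,
                    }
                )
        return pd.DataFrame(rows)

    def paths_frame(self, condition: str = "") -> pd.DataFrame:
        rows = []
        for i, path in enumerate(self.paths):
            for k, p in enumerate(path):
                rows.append(
                    {
                        "condition": condition,
                        "agent": i,
                        "step": k,
                        "azimuth_deg_wrapped": p.azimuth_wrapped,
                        "height_m": p.height,
                    }
                )
        return pd.DataFrame(rows)


def _crossing_azimuth(path, target: float) -> float | None:
    """Azimuth at the first time the (filtered) path reaches ``target`` height,
    linearly interpolated between the bracketing steps."""
    for k, p in enumerate(path):
        if p.height <= target:
            if k == 0:
                return path[0].azimuth
            prev = path[k - 1]
            if prev.height == p.height:
                return p.azimuth
            frac = (prev.height - target) / (prev.height - p.height)
            return prev.azimuth + frac * (p.azimuth - prev.azimuth)
    return None


def run_condition(
    scene: Scene,
    policy: AgentPolicy,
    release: TrunkPosition,
    n_agents: int,
    *,
    tree_id: str,
    blocked: bool = False,
    seed: int = 0,
    crossing_heights=(1.0, 0.0),
    p_escape: float = 0.5,
    escape_margin: float = 0.5,
    max_reposition_steps: int = 40,
    max_steps: int = 400,
    cache: ProbeCache | None = None,
    metric: str = "sad",
) -> DescentResult:
    """Simulate ``n_agents`` independent seeded descents of one condition.

    ``blocked`` requires the scene to contain the screen; the agent's
    memory (in ``policy``) should have been acquired in the unscreened
    scene, as the real foragers' memories predate the screen.  Each agent's
    path is recorded at every step, passed through the final-descent
    filter, and reduced to azimuth crossings at the requested heights.
    """
    if n_agents < 1:
        raise ValueError("n_agents must be >= 1")
    tree = scene.tree(tree_id)
    if release.height > tree.trunk_height:
        raise ValueError("release above trunk top")
    if blocked:
        if scene.screen is None:
            raise ValueError("blocked condition requires a scene with a screen")
        if tree.trunk_radius + DEFAULT_EYE_OFFSET >= scene.screen.half_width:
            raise ValueError("release position lies inside the screen wall")
    if policy.memory and cache is None:
        cache = ProbeCache(scene, tree_id, policy.memory, metric=metric)
    threshold = _NO_THRESHOLD
    if blocked and cache is not None:
        threshold = no_signal_threshold(cache)
    screen_top = scene.screen.z_max if scene.screen is not None else np.inf

    paths, descents, escaped_flags = [], [], []
    for child in np.random.SeedSequence(seed).spawn(n_agents):
        rng = np.random.default_rng(child)
        pos = release
        path = [pos]
        mode = "descend"
        escape_decided = False
        escaped = False
        repositioned = 0
        for _ in range(max_steps):
            if pos.height <= 0:
                break
            if mode == "ascend":
                if pos.height < screen_top + escape_margin:
                    pos = TrunkPosition(pos.azimuth, pos.height + policy.step_down)
                    path.append(pos)
                    continue
                mode = "reposition"
            if mode == "reposition":
                delta, signal = (None, False)
                if cache is not None:
                    delta, signal = _lateral_decision(
                        policy, cache, pos.azimuth, pos.height, threshold
                    )
                if (
                    not signal
                    or delta == 0.0
                    or repositioned >= max_reposition_steps
                ):
                    mode = "descend"  # fall through: descend from here
                else:
                    pos = TrunkPosition(
                        pos.azimuth + delta + _motor_noise(policy, rng), pos.height
                    )
                    path.append(pos)
                    repositioned += 1
                    continue
            # descending
            delta, signal = (None, False)
            if cache is not None:
                delta, signal = _lateral_decision(
                    policy, cache, pos.azimuth, pos.height, threshold
                )
            if not signal and blocked and not escape_decided:
                escape_decided = True
                if rng.random() < p_escape:
                    escaped = True
                    mode = "ascend"
                    continue
            if delta is None:
                delta = float(rng.uniform(-180.0, 180.0))
            else:
                delta += _motor_noise(policy, rng)
            pos = TrunkPosition(
                pos.azimuth + delta, max(pos.height - policy.step_down, 0.0)
            )
            path.append(pos)
        paths.append(path)
        descents.append(circular_stats.final_descent_filter(path))
        escaped_flags.append(escaped)

    crossings = {}
    for h in crossing_heights:
        vals = [_crossing_azimuth(p, h) for p in descents]
        crossings[h] = np.array([v % 360.0 for v in vals if v is not None])
    return DescentResult(paths, descents, crossings, escaped_flags, threshold, cache)


def condition_report(result: DescentResult, condition: str = "", mu0: float = 0.0):
    """Table-style circular-statistics report for one simulated condition."""
    return circular_stats.summary_table(
        result.crossings_frame(condition), mu0=mu0
    )
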