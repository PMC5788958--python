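"""Panoramic image preprocessing and rotational image difference functions.

A panorama here is an equirectangular grid of grayscale intensities: one
column per degree of azimuth (360 columns) and one row per degree of
elevation, spanning +66 deg (top row) to -50 deg (bottom row), i.e. 117
rows.  Intensities are on the usual 8-bit scale [0, 255].  Panoramas are
stored *world-aligned*: column 0 always corresponds to world azimuth 0 deg
(the nest direction), with azimuth increasing clockwise.  "Rotating" a view
therefore means circularly shifting its columns.

The rotational image difference function (rotIDF) compares a reference
panorama with a test panorama at every relative rotation of the test image
in one-degree steps.  The mismatch at rotation ``r`` is either the sum of
absolute pixel differences (SAD, the default) or the root-mean-square pixel
difference (RMS).  A low, sharply localised minimum of the curve indicates
that the test view can be aligned with the stored reference -- the basis of
both the visual-compass reading (take the argmin as a heading) and the
familiarity reading (take the min as a scalar goodness-of-match).
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from numbers import Integral
from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image
from skimage.transform import downscale_local_mean

#: canonical panorama shape: 1 pixel per degree of azimuth and elevation
PANO_WIDTH = 360
PANO_HEIGHT = 117
#: elevation of the centre of the top / bottom pixel row, degrees.
#: 67 rows at or above the horizon and 50 below, so +66 .. -50 inclusive.
ELEV_TOP_DEG = 66.0
ELEV_BOTTOM_DEG = -50.0

#: default "clear minimum" criterion: valley depth threshold and the arc
#: (in degrees around the argmin) within which every near-minimal rotation
#: must fall for the minimum to count as unique.
DEFAULT_DEPTH_THRESHOLD = 0.15
DEFAULT_PLATEAU_DEG = 5.0
#: rotations within this fraction of the curve's range above the minimum
#: are treated as part of the minimum's plateau.
DEFAULT_NEAR_FRACTION = 0.01

_EPS = 1e-12

ORIENTATION_NOTE = (
    "column 0 = world azimuth 0 deg (nest direction), azimuth increases "
    "clockwise at 1 deg/column; elevation spans +66 deg (top row) to "
    "-50 deg (bottom row) at 1 deg/row"
)


def wrap_signed(angle):
    """Wrap an angle (or array of angles) in degrees to (-180, 180]."""
    a = np.asarray(angle, dtype=float) % 360.0
    out = np.where(a > 180.0, a - 360.0, a)
    if np.ndim(angle) == 0:
        return float(out)
    return out


@dataclass(frozen=True)
class Panorama:
    """An equirectangular grayscale panorama with a fixed world orientation.

    Parameters
    ----------
    grid : ndarray, shape (rows, 360)
        Intensity values in [0, 255]; row 0 is the top (highest elevation).
    orientation : float
        World azimuth of column 0 in degrees clockwise from the nest
        direction.  The renderer always produces 0.
    """

    grid: np.ndarray
    orientation: float = 0.0

    def __post_init__(self):
        g = np.asarray(self.grid, dtype=float)
        if g.ndim != 2:
            raise ValueError("panorama grid must be 2-D (rows x columns)")
        if g.shape[1] != PANO_WIDTH:
            raise ValueError(
                f"panorama must have exactly {PANO_WIDTH} columns "
                f"(1 per degree of azimuth), got {g.shape[1]}"
            )
        if g.size and (g.min() < 0.0 or g.max() > 255.0):
            raise ValueError("panorama intensities must lie in [0, 255]")
        if not 0.0 <= float(self.orientation) < 360.0:
            raise ValueError("orientation must lie in [0, 360)")
        object.__setattr__(self, "grid", g)
        object.__setattr__(self, "orientation", float(self.orientation))

    @property
    def width(self) -> int:
        return self.grid.shape[1]

    @property
    def height(self) -> int:
        return self.grid.shape[0]


def preprocess(image, width: int = PANO_WIDTH, height: int = PANO_HEIGHT) -> Panorama:
    """Convert a raw panoramic raster to the canonical 360 x 117 grayscale grid.

    If the input has colour channels only the blue channel is kept: blue
    preserves the high contrast between dark terrestrial objects and the
    bright sky while discarding cloud/blue-sky differences.  The image is
    then block-averaged down to 1 pixel per degree, which requires the input
    dimensions to be integer multiples of the target dimensions.

    Parameters
    ----------
    image : array-like
        ``(H, W)`` grayscale or ``(H, W, 3+)`` RGB(A) raster covering the
        full 360 deg of azimuth.
    """
    arr = np.asarray(image, dtype=float)
    if arr.ndim == 3:
        if arr.shape[2] < 3:
            raise ValueError("colour input must have at least 3 channels (RGB)")
        arr = arr[:, :, 2]  # blue channel
    if arr.ndim != 2:
        raise ValueError("input must be a 2-D grayscale or 3-D colour raster")
    h, w = arr.shape
    if w < width:
        raise ValueError(f"input width {w} is narrower than target {width}")
    if w % width != 0 or h % height != 0:
        raise ValueError(
            "input dimensions must be integer multiples of the target "
            f"({width} x {height}) for block averaging; got {w} x {h}"
        )
    fy, fx = h // height, w // width
    if (fy, fx) != (1, 1):
        arr = downscale_local_mean(arr, (fy, fx))
    return Panorama(arr)


def rotate_panorama(p: Panorama, r) -> Panorama:
    """Return ``p`` as it would appear after rotating the view ``r`` degrees clockwise.

    ``r`` must be an integer number of degrees (the rotIDF works in
    one-degree steps).  Column ``c`` of the result equals column
    ``(c + r) mod 360`` of the input; rotating by 0 or 360 is the identity.
    """
    if isinstance(r, bool) or not isinstance(r, (Integral, np.integer)):
        if isinstance(r, float) and float(r).is_integer():
            r = int(r)
        else:
            raise ValueError(f"rotation must be an integer number of degrees, got {r!r}")
    return Panorama(np.roll(p.grid, -int(r), axis=1), p.orientation)


def mismatch_curve(ref, test, metric: str = "sad") -> np.ndarray:
    """rotIDF mismatch at every column shift, on bare grids of any width.

    ``out[r]`` compares ``ref`` against ``test`` rotated ``r`` columns
    clockwise (i.e. ``test[:, (c + r) % W]``).  SAD on integer-valued grids
    is computed in integer arithmetic and is exact.
    """
    ref = np.asarray(ref, dtype=float)
    test = np.asarray(test, dtype=float)
    if ref.shape != test.shape:
        raise ValueError(f"shape mismatch: {ref.shape} vs {test.shape}")
    if metric not in ("sad", "rms"):
        raise ValueError(f"metric must be 'sad' or 'rms', got {metric!r}")
    w = ref.shape[1]
    out = np.empty(w)
    integral = np.array_equal(ref, np.rint(ref)) and np.array_equal(test, np.rint(test))
    if metric == "sad" and integral:
        refi = ref.astype(np.int16)
        tiled = np.concatenate([test, test], axis=1).astype(np.int16)
        buf = np.empty_like(refi)
        for r in range(w):
            np.subtract(tiled[:, r : r + w], refi, out=buf)
            np.abs(buf, out=buf)
            out[r] = float(buf.sum(dtype=np.int64))
    else:
        tiled = np.concatenate([test, test], axis=1)
        buf = np.empty_like(ref)
        for r in range(w):
            np.subtract(tiled[:, r : r + w], ref, out=buf)
            if metric == "sad":
                np.abs(buf, out=buf)
                out[r] = buf.sum()
            else:
                np.square(buf, out=buf)
                out[r] = np.sqrt(buf.mean())
    return out


@dataclass(frozen=True)
class RotIDFCurve:
    """Mismatch per rotation, plus best-match and valley-depth summaries.

    ``mismatch[r]`` is the mismatch with the test view rotated ``r`` steps
    clockwise; for canonical panoramas one step is one degree.
    """

    mismatch: np.ndarray
    metric: str = "sad"

    def __post_init__(self):
        m = np.asarray(self.mismatch, dtype=float)
        if m.ndim != 1 or m.size < 1:
            raise ValueError("mismatch must be a non-empty 1-D array")
        if m.min() < 0:
            raise ValueError("mismatch values must be non-negative")
        object.__setattr__(self, "mismatch", m)

    @property
    def n_rotations(self) -> int:
        return self.mismatch.size

    @property
    def rotation_step(self) -> float:
        """Degrees per rotation index (1.0 for canonical panoramas)."""
        return 360.0 / self.mismatch.size

    @property
    def best_mismatch(self) -> float:
        return float(self.mismatch.min())

    @property
    def best_rotation(self) -> float:
        """Argmin rotation in degrees, in [0, 360).

        Ties are broken toward the smallest absolute signed rotation
        (wrapped to (-180, 180]); residual ties break toward the positive
        (clockwise) rotation, i.e. "no turn" is favoured and then a
        clockwise turn.
        """
        m = self.mismatch
        cand = np.flatnonzero(m == m.min())
        rots = cand * self.rotation_step
        wrapped = np.atleast_1d(wrap_signed(rots))
        # sort key: |wrapped| first, then prefer positive over negative
        order = sorted(range(len(cand)), key=lambda i: (abs(wrapped[i]), wrapped[i] < 0))
        return float(rots[order[0]] % 360.0)

    @property
    def best_rotation_signed(self) -> float:
        """Best rotation wrapped to (-180, 180]."""
        return wrap_signed(self.best_rotation)


def rotidf(reference: Panorama, test: Panorama, metric: str = "sad") -> RotIDFCurve:
    """Rotational image difference function between two canonical panoramas.

    Both panoramas must share the 360 x 117 shape and the 8-bit intensity
    scale.  The returned curve has one entry per one-degree rotation of the
    test image.
    """
    if reference.grid.shape != test.grid.shape:
        raise ValueError(
            f"shape mismatch: {reference.grid.shape} vs {test.grid.shape}"
        )
    return RotIDFCurve(mismatch_curve(reference.grid, test.grid, metric), metric)


def valley_depth(curve: RotIDFCurve) -> float:
    """Relative depth of the curve's minimum: ``1 - min/mean`` in [0, 1].

    A flat curve has depth 0; a curve whose minimum reaches 0 (e.g. a
    self-comparison) has depth 1.  An all-zero curve is defined to have
    depth 0.
    """
    m = curve.mismatch
    mean = m.mean()
    if mean <= _EPS:
        return 0.0
    return float(1.0 - m.min() / mean)


def has_clear_minimum(
    curve: RotIDFCurve,
    depth_threshold: float = DEFAULT_DEPTH_THRESHOLD,
    plateau_deg: float = DEFAULT_PLATEAU_DEG,
    near_fraction: float = DEFAULT_NEAR_FRACTION,
) -> bool:
    """Whether the curve shows a distinct, unique valley of minimum mismatch.

    The curve counts as having a clear minimum when its valley depth is at
    least ``depth_threshold`` *and* the minimum is unique up to a plateau:
    every rotation whose mismatch lies within ``near_fraction`` of the
    curve's range above the minimum must fall within ``plateau_deg`` degrees
    of the argmin.  The thresholds are reported alongside results rather
    than baked into any conclusion.
    """
    if valley_depth(curve) < depth_threshold:
        return False
    m = curve.mismatch
    span = m.max() - m.min()
    if span <= _EPS:
        return False
    near = np.flatnonzero(m <= m.min() + near_fraction * span)
    dist = np.abs(wrap_signed(near * curve.rotation_step - curve.best_rotation))
    return bool(np.all(dist <= plateau_deg))


def curve_summary(
    curve: RotIDFCurve,
    depth_threshold: float = DEFAULT_DEPTH_THRESHOLD,
    plateau_deg: float = DEFAULT_PLATEAU_DEG,
) -> dict:
    """JSON-ready summary of a rotIDF curve."""
    return {
        "metric": curve.metric,
        "best_rotation_deg": curve.best_rotation,
        "best_rotation_signed_deg": curve.best_rotation_signed,
        "best_mismatch": curve.best_mismatch,
        "valley_depth": valley_depth(curve),
        "clear_minimum": has_clear_minimum(curve, depth_threshold, plateau_deg),
        "depth_threshold": depth_threshold,
        "plateau_deg": plateau_deg,
    }


def curve_to_frame(curve: RotIDFCurve, label: str | None = None) -> pd.DataFrame:
    """rotIDF curve as a tidy DataFrame (rotation_deg, mismatch[, label])."""
    df = pd.DataFrame(
        {
            "rotation_deg": np.arange(curve.n_rotations) * curve.rotation_step,
            "mismatch": curve.mismatch,
        }
    )
    if label is not None:
        df.insert(0, "label", label)
    return df


# ---------------------------------------------------------------------------
# image I/O


def save_panorama(p: Panorama, path, metadata: dict | None = None) -> Path:
    """Write a panorama as an 8-bit grayscale PNG/TIFF plus a JSON sidecar.

    The sidecar records the orientation convention and any extra metadata
    (e.g. the rendering viewpoint) so a saved panorama is self-describing.
    """
    path = Path(path)
    img = np.rint(np.clip(p.grid, 0, 255)).astype(np.uint8)
    Image.fromarray(img, mode="L").save(path)
    sidecar = {
        "orientation_deg": p.orientation,
        "width": p.width,
        "height": p.height,
        "convention": ORIENTATION_NOTE,
    }
    if metadata:
        sidecar.update(metadata)
    path.with_suffix(path.suffix + ".json").write_text(json.dumps(sidecar, indent=2))
    return path


def load_panorama(path) -> Panorama:
    """Read a panorama image (PNG/TIFF); keeps only blue if it has colour.

    If a ``<name>.<ext>.json`` sidecar exists its ``orientation_deg`` is
    honoured.
    """
    path = Path(path)
    arr = np.asarray(Image.open(path), dtype=float)
    if arr.ndim == 3:
        arr = arr[:, :, 2]
    orientation = 0.0
    sidecar = path.with_suffix(path.suffix + ".json")
    if sidecar.exists():
        orientation = float(json.loads(sidecar.read_text()).get("orientation_deg", 0.0))
    return Panorama(arr, orientation)
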