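# Methods

`trunknav` models how a nocturnal arboreal ant, descending a tree trunk with
its body perpendicular to the ground, can find the side of the trunk that
faces its nest using nothing but the surrounding terrestrial panorama and a
view memorised at the tree base.  This note describes the model, its
parameters and defaults, what the synthetic world does and does not emulate,
and the numerical choices behind the statistics.

## The view-matching signal

All visual processing operates on equirectangular grayscale panoramas of
360 x 117 pixels at 1 pixel/degree of azimuth and elevation, spanning +66
deg (top row) to -50 deg (bottom row) -- 67 rows at or above the horizon and
50 below, the horizon falling between rows.  Colour input keeps only the
blue channel, which preserves the contrast between dark terrestrial objects
and the bright sky while suppressing cloud/blue-sky differences; higher-
resolution input is block-averaged down, which requires integer size
multiples.  Panoramas are stored *world-aligned*: column 0 is always world
azimuth 0 deg, defined as the nest direction seen from the focal tree, with
azimuth increasing clockwise.  Plots that centre the nest are a display
choice, not a storage convention.

The rotational image difference function (rotIDF) between a reference and a
test panorama evaluates, for every one-degree rotation `r` of the test
view, either the sum of absolute pixel differences (SAD, default; computed
in integer arithmetic, hence exact) or the root-mean-square difference
(RMS).  Rotation means rotating the *viewer*: `rotate(p, r)[c] = p[(c + r)
mod 360]`, so the best rotation reads directly as the heading offset that
aligns the test view to the reference.  Ties at the minimum break toward
the smallest absolute signed rotation and then clockwise ("no turn" is
favoured).  Two summaries matter downstream:

* **valley depth** `1 - min/mean` in [0, 1] (an all-zero curve is assigned
  depth 0);
* **clear minimum**: depth >= 0.15 *and* every rotation whose mismatch lies
  within 1% of the curve's range above the minimum falls within +-5 deg of
  the argmin.  The 0.15 threshold and the +-5 deg plateau window are
  configuration, reported with every summary and baked into no conclusion;
  "clear" is inherently a qualitative judgement and these defaults simply
  make it reproducible.

## The synthetic world

The scene generator emulates an open eucalypt stand with a nest at a tree
base: trunks are finite vertical cylinders, canopies spheres, the ground a
plane, the sky a uniform bright field (255) against terrain at 40-95.  The
two presets mirror the two experimental geometries: a foraging tree 3 m
from the nest (with the nest tree just behind the nest and five distractor
trees at mixed bearings, 3.9-5.3 m, with varied sizes so the skyline height
varies with azimuth and the scene has no mirror symmetry), and the nest
tree itself with the nest 10 cm from its bark.  The blocking enclosure is
four opaque walls forming a 1.5 x 1.5 m square, 0.75 m from the trunk,
spanning 0.05-2.0 m height -- suspended a few centimetres off the ground,
with the nest inside the square.

Rendering casts one ray per pixel and takes the nearest intersected
primitive's intensity, respecting occlusion -- including self-occlusion by
the trunk the viewer stands beside, which at the 2 cm default eye offset
covers ~124 deg of azimuth.  Rendering is deterministic given scene and
viewpoint.

**Surface texture.**  A deterministic world-anchored texture (a seeded sum
of 24 sinusoidal plane waves, wavelengths 0.125-1.25 m, nominal amplitude
70 on the 8-bit scale, effective standard deviation amplitude/4) is added
to every surface hit.  Many superposed waves make the field noise-like: a
small number of components leaves the bark pattern quasi-periodic around
the trunk circumference, and its rotational self-similarity then fabricates
false familiarity basins on the far side of the trunk.  The field is also
anisotropic: wave-vector z-components are scaled by 0.03, so variation is
strong around a trunk's circumference but very weak along its height -- the
visual structure of vertically streaked eucalypt bark.  This anisotropy is
load-bearing.  A
view from the same trunk side at a different height sees nearly the same
bark (plus parallax on the surroundings), so the base memory still matches
at 1-1.75 m; a view from a different side sees different bark over the
~124 deg the trunk occupies, so views from the far sides of the trunk
cannot be brought into registration with the base view at any rotation.
With weak or isotropic texture the model instead produces a spurious deep
rotIDF valley at whatever rotation aligns the two trunk silhouettes, for
every release side -- qualitatively wrong.

**Camera offsets.**  On-trunk views use a 2 cm eye offset (an ant pressed
to the bark; small enough to preserve self-occlusion, non-zero to avoid
coincident-surface rays).  The ground-level *reference* panorama at the
tree base is rendered 25 cm from the bark, where a panoramic camera on its
mount would sit.  The asymmetry matters: the base reference has a narrow
(~44 deg) trunk silhouette, so on-tree views 90/180/270 deg around the
trunk can neither align their wide occluder with it (little overlap to
cancel) nor align the scenery (each view hides a different ~120 deg of the
world), and their rotIDFs stay flat.

**What the synthetic world does not emulate:** twilight spectra and
lighting, leaf-level canopy structure, wind, clouds, camera exposure and
lens distortion, terrain relief, and any non-visual cue.  Tests passing on
this world show that the pipeline recovers the information the geometry and
contrast structure make available; they do not show that real panoramas at
a real site carry that information.

## Descent agents

An agent is released on the trunk at a given azimuth (0 = nest side,
clockwise positive) and height, holds a memory of one panorama rendered at
the base of its tree on the nest side (2 cm offset), and alternates a
lateral decision with a fixed 0.10 m descent step (the spacing of the path
markers in on-tree displacement experiments).  Two minimal motor rules
implement the two candidate strategies; neither is claimed to be the
ants' mechanism:

* **gradient of familiarity** -- probe the rotIDF best-mismatch at
  +-20 and +-40 deg around the current azimuth (the width of a slow
  horizontal scan) and sidestep 30 deg toward the best probe; exact ties
  hold position.  Narrower scan arcs (+-10/20 deg) leave agents released
  opposite the nest stranded on the locally flat far side of the
  familiarity landscape.
* **visual compass** -- read the signed best rotation against memory at the
  current azimuth and one sidestep to either side, and move to whichever
  minimises its magnitude.  On the trunk this signal is globally
  informative: the best rotation tracks the angular offset between the
  current and memorised trunk sides.

Per-step motor noise is von Mises with kappa = 10 (circular s.d. ~18 deg)
on the lateral component.  Probes are memoised on a 1 deg x 1 cm grid --
the renderer's azimuth resolution and a tenth of the descent step -- so
repeated visits reuse renders.

**No signal and the blocked condition.**  Every probe is compared against a
per-scene no-signal threshold: 0.9 times the minimum familiarity over a
calibration grid of screened-in positions (8 azimuths x 5 heights from 0.1
to 1.5 m).  The grid must extend near the ground: bark and in-square ground
matching otherwise leaves sub-threshold pockets on the nest side that let
"blocked" agents orient anyway.  When no probe beats the threshold the
agent's lateral move is drawn uniformly around the trunk -- the uninformed-
search null, mirroring the looping paths of screened-in foragers.  In the
blocked condition an agent that first finds itself without signal escapes
with probability 0.5 (the observed fraction): it climbs until 0.5 m above
the screen top, where the walls no longer dominate the lower visual field,
re-orients laterally while the signal lasts, and then resumes its descent,
losing the signal again once back inside the enclosure.  A 0.1 m climb
margin is not enough -- at eye level just above the wall top the screen
still blocks nearly all of the below-horizon field.

Analysis applies the final-descent filter (keep the path suffix from the
last local height maximum; ties extend the run) before extracting the
azimuth at which each path first reaches a crossing height (1.4/1/0 m),
linearly interpolated between bracketing steps on the unwrapped azimuth.

Default condition sizes mirror the displacement experiments: 15
agents/condition for the four-way foraging-tree releases at 2 m, 20 for the
nest-tree releases at 1.5 m (blocked and unblocked); these sizes also keep
the full simulated experiment within a few CPU-minutes.

## Circular statistics

Angles are degrees at the API, radians internally.  The mean direction mu
and resultant length R come from the unit-vector mean; R numerically zero
yields an explicit "undefined mu", never NaN.

* **Rayleigh test** (uniformity): Z = nR^2.  For n <= 30 the p-value is
  exact -- Kluyver's random-walk integral P(S < s) = s Int J1(st) J0(t)^n dt
  -- because the usual series approximation misstates deep-tail
  probabilities at small n; the series is used above n = 30 where it is
  accurate.
* **V-test** (clustering around a pre-declared direction, the nest at 0
  deg): V = R cos(mu - mu0), u = V sqrt(2n), one-tailed p from the normal
  upper tail with a one-term Edgeworth correction for the kurtosis of cos
  under the null (-3/2): p = 1 - Phi(u) - phi(u)(u^3 - 3u)/(16n).  A
  simulation method (uniform-null resampling with the +1 correction) is
  available for audit.
* **Mean-direction CI**: circular-dispersion method with a Student-t
  quantile (n - 1 df); half-width asin(t sqrt(delta/n)) with delta =
  (1 - rho2)/(2R^2).  The normal quantile undercovers (~0.92-0.935 at
  kappa = 2, n = 15); the t quantile calibrates to ~0.95.  Intervals that
  do not exist (dispersed samples, asin argument >= 1) are returned as an
  explicit undefined result.  Membership of a direction in a CI is decided
  on the wrapped arc, so intervals crossing 0 deg behave correctly.

All three are validated in the test suite against large simulated nulls
(10^5-replicate p-value agreement within 3 Monte-Carlo standard errors,
type-I error in [0.04, 0.06] at alpha = 0.05, CI coverage in [0.93, 0.97]),
so correctness rests on simulation, not on matching any particular
commercial implementation.  Alpha is 0.05 throughout and no
multiple-testing correction is applied, matching standard practice in this
literature.

## Known limitations

* The renderer's primitives (cylinders, spheres, a plane, uniform sky) and
  the sinusoidal texture are caricatures; absolute mismatch values have no
  physical unit and only orderings and curve shapes are meaningful.
* The on-nest/off-nest split sits within ~0.05-0.1 of the 0.15
  clear-minimum threshold.  On the default study scene (texture seed 0) the
  classification is deterministic and holds with margin, but under other
  texture seeds individual off-nest views can graze the threshold; the
  binary "clear minimum" label is a convenience, and the valley-depth
  ordering (nest-side views always deeper than far-side views) is the
  robust quantity.
* The motor rules are deliberately minimal: no pauses, no information
  accumulation across scans, no biomechanics of vertical walking; the
  escape rule is a stand-in for a behaviour whose trigger is unknown.
* The no-signal threshold is a modelling device calibrated per scene; real
  ants presumably grade their confidence continuously.
* With n = 15-20 samples per condition, the uniformity checks on blocked
  descents inherit the usual ~5% false-positive rate of any single test at
  alpha = 0.05; conclusions should rest on the pattern across heights and
  conditions, as they do in the field data.
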