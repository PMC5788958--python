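#!/usr/bin/env python
"""Render the image-analysis panorama grid for the default synthetic site.

Writes the ground-level base reference (nest side, camera offset) and the
4 directions x 2 heights on-tree views for the foraging tree, as PNGs with
JSON sidecars, under results/panoramas/.
"""

import dataclasses
from pathlib import Path

import trunknav as tn
from trunknav.panorama_ops import save_panorama
from trunknav.synthetic_world import BASE_CAMERA_OFFSET, DEFAULT_EYE_OFFSET

OUT = Path("results/panoramas")


def main():
    OUT.mkdir(parents=True, exist_ok=True)
    scene = tn.build_scene(tn.default_scene_config())
    grid = [("base", 0.0, 0.0, BASE_CAMERA_OFFSET)] + [
        (f"az{az:.0f}_h{h}", az, h, DEFAULT_EYE_OFFSET)
        for az in (0.0, 90.0, 180.0, 270.0)
        for h in (1.0, 1.75)
    ]
    for label, az, h, off in grid:
        vp = tn.trunk_viewpoint(scene, "foraging", az, h, offset=off)
        pano = tn.render_panorama(scene, vp)
        save_panorama(
            pano, OUT / f"foraging_{label}.png",
            metadata={"tree": "foraging", "azimuth_deg": az, "height_m": h,
                      "offset_m": off, "viewpoint": dataclasses.asdict(vp)},
        )
        print(f"rendered {label:12s} mean intensity {pano.grid.mean():6.1f}")
    print(f"{len(grid)} panoramas -> {OUT}")


if __name__ == "__main__":
    main()
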