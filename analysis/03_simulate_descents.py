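#!/usr/bin/env python
"""Simulate the displacement experiments with view-matching agents.

Conditions (both motor strategies):
  * foraging tree, unblocked: releases at 0/90/180/270 deg, 2 m, n = 15;
  * nest tree, unblocked:  release at 180 deg, 1.5 m, n = 20;
  * nest tree, blocked (screen): release at 180 deg, 1.5 m, n = 20.

Writes per-agent paths and height-crossing angles under
results/simulation/ and prints a one-line summary per condition.
"""

from pathlib import Path

import numpy as np
import pandas as pd

import trunknav as tn
from trunknav import circular_stats as cs
from trunknav import descent_sim as ds

OUT = Path("results/simulation")
SEED = 20_18


def main():
    OUT.mkdir(parents=True, exist_ok=True)
    foraging = tn.build_scene(tn.default_scene_config())
    nest_blocked = tn.build_scene(tn.nest_tree_scene_config(include_screen=True))
    setups = {
        "foraging": (foraging, "foraging", ds.acquire_memory(foraging, "foraging")),
        "nest": (nest_blocked, "nest_tree",
                 ds.acquire_memory(nest_blocked.without_screen(), "nest_tree")),
    }
    caches = {}
    conditions = (
        [("foraging", az, 2.0, 15, False) for az in (0.0, 90.0, 180.0, 270.0)]
        + [("nest", 180.0, 1.5, 20, False), ("nest", 180.0, 1.5, 20, True)]
    )
    seeds = iter(np.random.SeedSequence(SEED).generate_state(64))
    paths, crossings = [], []
    for strategy in ("gradient", "compass"):
        for scene_key, az, h0, n, blocked in conditions:
            scene, tree, memory = setups[scene_key]
            sim_scene = scene if blocked else scene.without_screen()
            cache = caches.setdefault(
                (scene_key, blocked), ds.ProbeCache(sim_scene, tree, memory)
            )
            res = ds.run_condition(
                sim_scene, ds.AgentPolicy(strategy, memory),
                ds.TrunkPosition(az, h0), n, tree_id=tree, blocked=blocked,
                seed=int(next(seeds) % 2**31),
                crossing_heights=(1.4, 1.0, 0.0) if scene_key == "nest" else (1.0, 0.0),
                cache=cache,
            )
            name = f"{strategy}_{scene_key}_az{az:.0f}" + ("_blocked" if blocked else "")
            paths.append(res.paths_frame(name))
            crossings.append(res.crossings_frame(name))
            ground = res.crossings[0.0]
            ray = cs.rayleigh_test(ground)
            vt = cs.v_test(ground)
            esc = f" escaped {sum(res.escaped)}/{n}" if blocked else ""
            print(f"{name:34s} ground: mu {tn.circ_mean(ground)[0]:6.1f}  "
                  f"Rayleigh p {ray.p:.4f}  V p {vt.p:.4f}{esc}")
    pd.concat(paths).to_csv(OUT / "paths.csv", index=False)
    pd.concat(crossings).to_csv(OUT / "crossings.csv", index=False)
    print(f"paths + crossings -> {OUT}")


if __name__ == "__main__":
    main()
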