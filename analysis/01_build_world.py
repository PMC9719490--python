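"""Build the default desk-scale study world and commute trajectory.

Writes the world (YAML) and trajectory (CSV waypoints) plus the angular
light profile around the origin — the azimuthal distribution of light mass
within 15 km of the "cave" — which shows the dominant off-goal city that
the phototaxis null steers into.
"""

from pathlib import Path

import numpy as np
import pandas as pd

from batnav import angular_light_profile, bearing_to_target
from batnav import experiments as ex
from batnav.pipeline import child_seed
from batnav.trajectory import save_trajectory
from batnav.world import save_world

SEED = 1
RESULTS = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    RESULTS.mkdir(exist_ok=True)
    world = ex.default_world(child_seed(SEED, "world"))
    trajectory = ex.default_trajectory(world, child_seed(SEED, "trajectory"))
    save_world(world, RESULTS / "world.yaml")
    save_trajectory(trajectory, RESULTS / "trajectory.csv")

    profile = angular_light_profile(world, world.origin, radius_m=15_000.0, n_bins=36)
    goal_bearing = world.goal_bearing
    pd.DataFrame(
        {
            "azimuth_deg": profile.bin_centers_deg,
            "azimuth_rel_goal_deg": (profile.bin_centers_deg - goal_bearing) % 360.0,
            "fraction_of_light": profile.fraction_of_total,
        }
    ).to_csv(RESULTS / "light_profile.csv", index=False)

    dom = world.dominant_source
    dom_az = bearing_to_target(world.origin, dom.position)
    print(f"world: {len(world.light_sources)} light sources, origin->goal "
          f"{world.goal_distance:.0f} m at bearing {goal_bearing:.0f} deg")
    print(f"trajectory: {len(trajectory.waypoints)} waypoints, arc length {trajectory.length:.0f} m")
    print(f"dominant city: radiance {dom.peak_radiance:.1f} "
          f"(median source {np.median([s.peak_radiance for s in world.light_sources]):.2f}), "
          f"azimuth {dom_az:.0f} deg from origin vs goal at {goal_bearing:.0f} deg -> "
          f"brightest direction is {abs((dom_az - goal_bearing + 180) % 360 - 180):.0f} deg off-goal")
    peak_bin = profile.bin_centers_deg[np.argmax(profile.fraction_of_total)]
    print(f"light profile: brightest azimuth bin {peak_bin:.0f} deg holds "
          f"{100 * profile.fraction_of_total.max():.1f}% of the light mass within 15 km")


if __name__ == "__main__":
    main()
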