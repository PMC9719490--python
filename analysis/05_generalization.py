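"""Spatial and temporal generalisation of the navigation network.

Two probes of generalisation:

1. Excluded-segment split: retrain with a contiguous ~23% arc window of the
   route withheld and test only on views >= 1 km inside the gap.
2. Off-route, drifted-world probes: evaluate the full-route network (from
   03) at 9 points 2-5 km off the route, on a world one year of scene
   drift later, asking over which gaze sectors it still points to within
   15 deg of the goal ("green sectors").
"""

import json
from pathlib import Path

import pandas as pd

from batnav import DriftConfig, green_sectors, perturb_world, sample_offroute_probes
from batnav import experiments as ex
from batnav.acquisition import load_dataset
from batnav.navnet import load_model
from batnav.pipeline import child_seed

SEED = 1
ROOT = Path(__file__).resolve().parents[1]
RESULTS = ROOT / "results"
SCRATCH = ROOT / "scratch"


def main() -> None:
    RESULTS.mkdir(exist_ok=True)
    world = ex.default_world(child_seed(SEED, "world"))
    trajectory = ex.default_trajectory(world, child_seed(SEED, "trajectory"))
    cache = SCRATCH / "route_views.h5"
    dataset = load_dataset(cache) if cache.exists() else ex.make_route_dataset(
        world, trajectory, child_seed(SEED, "acquire")
    )

    _, gap_summary = ex.experiment_generalization(SEED, world, trajectory, dataset)
    exclude, test_range = ex.default_exclusion_ranges(trajectory)
    print(f"excluded-segment split: window [{exclude[0]:.0f}, {exclude[1]:.0f}] m "
          f"({100 * (exclude[1] - exclude[0]) / trajectory.length:.0f}% of the arc), "
          f"tested on [{test_range[0]:.0f}, {test_range[1]:.0f}] m")
    print(f"gap sector error: {gap_summary.mean_abs_error_deg:.2f} deg "
          f"(SD {gap_summary.sd_deg:.1f}, n={gap_summary.n})")

    # off-route probes on the drifted world, evaluated with the full-route net
    model = load_model(SCRATCH / "navnet_full.npz")
    drifted = perturb_world(world, DriftConfig(fraction=0.2), seed=child_seed(SEED, "drift"))
    probes = sample_offroute_probes(
        drifted, trajectory, n_points=9, distance_range_m=(2_000.0, 5_000.0),
        seed=child_seed(SEED, "probes"),
    )
    report = green_sectors(model, probes, threshold_deg=15.0)
    rows = []
    for probe, intervals, width in zip(probes, report.per_probe, report.total_width_deg):
        rows.append(
            {
                "x_m": probe.center_position[0],
                "y_m": probe.center_position[1],
                "route_distance_m": probe.min_route_distance_m,
                "green_width_deg": width,
                "n_sectors": len(intervals),
            }
        )
    pd.DataFrame(rows).to_csv(RESULTS / "green_sectors.csv", index=False)

    summary = {
        "gap_sector_error_deg": gap_summary.mean_abs_error_deg,
        "gap_sector_sd_deg": gap_summary.sd_deg,
        "gap_n": gap_summary.n,
        "green_mean_total_width_deg": report.mean_total_width_deg,
        "green_sd_total_width_deg": report.sd_total_width_deg,
        "probes_with_empty_sectors": int(sum(w == 0.0 for w in report.total_width_deg)),
    }
    with open(RESULTS / "generalization.json", "w") as fh:
        json.dump(summary, fh, indent=2)

    print(f"green sectors (<15 deg error) at 9 off-route points on the drifted world: "
          f"mean total width {report.mean_total_width_deg:.1f} deg "
          f"(SD {report.sd_total_width_deg:.1f}); "
          f"{summary['probes_with_empty_sectors']} probes with no green sector")


if __name__ == "__main__":
    main()
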