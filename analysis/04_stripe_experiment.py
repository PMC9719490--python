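"""Which horizontal band of the view carries the navigation signal?

Retrains the network three times on copies of a compact route dataset with
the top, middle, or bottom third of every image (train and test) zeroed
out, and compares goal-sector errors.  By the scene design the horizon
band (middle third) carries the light-source geometry, so its removal
should be the damaging one.  Run at a reduced scale (2.5 km world, 48x48
views) to keep three trainings cheap.
"""

import json
from pathlib import Path

import batnav
from batnav import experiments as ex

ROOT = Path(__file__).resolve().parents[1]
RESULTS = ROOT / "results"


def main() -> None:
    RESULTS.mkdir(exist_ok=True)
    cfg = batnav.WorldConfig(
        goal_distance_m=2_500.0,
        n_light_sources=8,
        scatter_lateral_range_m=(300.0, 2_000.0),
        forward_along_range_m=(-300.0, 1_500.0),
        forward_lateral_m=1_000.0,
        city_lateral_m=-1_200.0,
        city_extent_m=300.0,
        min_city_axis_offset_m=500.0,
    )
    world = batnav.build_world(cfg, seed=2)
    trajectory = batnav.make_trajectory(world, batnav.TrajectoryConfig(lateral_amplitude_m=80.0), seed=2)
    protocol = batnav.ProtocolConfig(rotation_step_deg=12.0, resolution=48, zigzag_amplitude_m=40.0)
    dataset = batnav.sample_route_views(world, trajectory, protocol, seed=3)
    test = ex.fresh_test_views(world, trajectory, n=250, seed=4, protocol=protocol)
    arch = batnav.ArchConfig(conv_blocks=((6, 3, 2), (12, 3, 2)), fc_sizes=(48, 24, 12), input_hw=(48, 48))
    hyper = batnav.Hyperparams(epochs=14, seed=5, lr_decay_epochs=(8, 11))

    results = batnav.stripe_experiment(arch, dataset, test, hyper)
    report = {
        which: {"mean_abs_error_deg": s.mean_abs_error_deg, "sd_deg": s.sd_deg, "n": s.n}
        for which, s in results.items()
    }
    with open(RESULTS / "stripe_experiment.json", "w") as fh:
        json.dump(report, fh, indent=2)

    for which in ("top", "middle", "bottom"):
        s = results[which]
        print(f"{which:>6}-removed: sector error {s.mean_abs_error_deg:6.1f} deg (SD {s.sd_deg:.1f})")
    worst = max(results, key=lambda k: results[k].mean_abs_error_deg)
    print(f"removing the {worst} band hurts most "
          f"({'horizon information, as designed' if worst == 'middle' else 'unexpected'})")


if __name__ == "__main__":
    main()
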