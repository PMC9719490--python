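"""Closed-loop homing: can single-view azimuth estimates steer a flight?

Three estimator conditions on the default world:

* two noisy oracles calibrated to the sector errors of the two reference
  networks (mean |error| 22.2 and 25.4 deg), 50 runs each — the headline
  success-rate condition;
* the trained full-route network reading freshly rendered views (10 runs;
  slower because every step renders);
* the phototaxis null (steer at the brightest column), 50 runs — expected
  to fail completely because the dominant city is off-goal.
"""

import json
from pathlib import Path

import pandas as pd

from batnav import SimConfig, make_model_estimator, make_phototaxis_estimator, run_batch, simulate
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

    batch = ex.experiment_sim_success(seed=SEED)
    print(f"noisy oracles ({ex.REFERENCE_MEAN_ERRORS} deg mean error): "
          f"{batch.successes} successes of {batch.runs} -> pooled {100 * batch.pooled_rate:.0f}%")

    model = load_model(SCRATCH / "navnet_full.npz")
    dataset = load_dataset(SCRATCH / "route_views.h5")
    lookup_est = make_model_estimator(model, dataset, lookup_mode="nearest_view")
    lookup_batch = run_batch(world, trajectory, [lookup_est], runs_per_estimator=50,
                             config=SimConfig(), seed=child_seed(SEED, "lookup_sim"))
    print(f"trained network (nearest-view lookup): {lookup_batch.reached[0]}/50 runs reach the "
          f"goal radius; {lookup_batch.successes[0]}/50 also satisfy capture-then-orbit "
          f"(past the route end there are no stored views with return headings)")

    net_est = make_model_estimator(model, world, lookup_mode="render_exact")
    net_batch = run_batch(world, trajectory, [net_est], runs_per_estimator=10,
                          config=SimConfig(), seed=child_seed(SEED, "net_sim"))
    print(f"trained network (render-exact): {net_batch.reached[0]}/10 reach the goal radius, "
          f"{net_batch.successes[0]}/10 capture-then-orbit")

    photo = make_phototaxis_estimator(world)
    photo_batch = run_batch(world, trajectory, [photo], runs_per_estimator=50,
                            config=SimConfig(), seed=child_seed(SEED, "photo_sim"))
    print(f"phototaxis null: {photo_batch.successes[0]}/50 successes")

    example = simulate(world, trajectory, lookup_est, SimConfig(), seed=child_seed(SEED, "example"))
    pd.DataFrame(
        {
            "step": range(len(example.positions)),
            "x_m": example.positions[:, 0],
            "y_m": example.positions[:, 1],
            "heading_deg": example.headings,
            "distance_to_goal_m": example.distances,
        }
    ).to_csv(RESULTS / "example_flight.csv", index=False)

    report = {
        "noisy_oracle": {"successes": batch.successes, "runs": batch.runs,
                         "pooled_rate_pct": 100 * batch.pooled_rate,
                         "mean_steps": batch.mean_steps},
        "trained_network_nearest_view": {"successes": lookup_batch.successes,
                                         "reached_goal_radius": lookup_batch.reached,
                                         "runs": lookup_batch.runs,
                                         "mean_steps": lookup_batch.mean_steps},
        "trained_network_render_exact": {"successes": net_batch.successes,
                                         "reached_goal_radius": net_batch.reached,
                                         "runs": net_batch.runs,
                                         "mean_steps": net_batch.mean_steps},
        "phototaxis": {"successes": photo_batch.successes, "runs": photo_batch.runs},
        "example_flight_success": example.success,
        "example_flight_steps": example.steps_used,
    }
    with open(RESULTS / "simulation.json", "w") as fh:
        json.dump(report, fh, indent=2)


if __name__ == "__main__":
    main()
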