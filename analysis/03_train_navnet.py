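"""Train the navigation network on the full route and evaluate it.

Loads the acquired dataset (or rebuilds it), trains the compact azimuth
regressor with the wrap-aware squared loss, and reports the goal-sector
error plus the polar profile of error versus gaze angle relative to the
goal.  The checkpoint goes to scratch/; history and evaluation tables to
results/.
"""

import json
from pathlib import Path

import numpy as np
import pandas as pd

from batnav import error_profile, sector_error
from batnav import experiments as ex
from batnav.acquisition import load_dataset
from batnav.navnet import save_model
from batnav.pipeline import child_seed

SEED = 1
ROOT = Path(__file__).resolve().parents[1]
RESULTS = ROOT / "results"
SCRATCH = ROOT / "scratch"


def main() -> None:
    RESULTS.mkdir(exist_ok=True)
    SCRATCH.mkdir(exist_ok=True)
    world = ex.default_world(child_seed(SEED, "world"))
    trajectory = ex.default_trajectory(world, child_seed(SEED, "trajectory"))
    cache = SCRATCH / "route_views.h5"
    dataset = load_dataset(cache) if cache.exists() else ex.make_route_dataset(
        world, trajectory, child_seed(SEED, "acquire")
    )

    model, summary, test = ex.experiment_full_route(SEED, world, trajectory, dataset)
    save_model(model, SCRATCH / "navnet_full.npz")
    pd.DataFrame(model.training_history).to_csv(RESULTS / "training_history.csv", index=False)

    centers, means, counts = error_profile(model, test, bin_deg=30.0)
    pd.DataFrame(
        {"label_bin_center_deg": centers, "mean_abs_error_deg": means, "n": counts}
    ).to_csv(RESULTS / "error_profile.csv", index=False)

    report = {
        "sector_error_deg": summary.mean_abs_error_deg,
        "sector_sd_deg": summary.sd_deg,
        "sector_n": summary.n,
        "final_training_error_deg": model.training_history[-1]["mean_abs_error_deg"],
        "epochs": len(model.training_history),
    }
    with open(RESULTS / "full_route_evaluation.json", "w") as fh:
        json.dump(report, fh, indent=2)

    print(f"trained {len(model.training_history)} epochs; final training |error| "
          f"{report['final_training_error_deg']:.1f} deg")
    print(f"goal-sector (+-45 deg) test error: {summary.mean_abs_error_deg:.2f} deg "
          f"(SD {summary.sd_deg:.1f}, n={summary.n})")
    in_sector = ~np.isnan(means)
    print("polar profile (bin centre -> mean |error|): "
          + ", ".join(f"{c:.0f}:{m:.0f}" for c, m in zip(centers[in_sector], means[in_sector])))


if __name__ == "__main__":
    main()
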