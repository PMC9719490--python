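"""Goal-direction tuning of the trained network's fully-connected units.

Feeds the full-route network with all-around views from several locations,
averages each unit's activation as a function of gaze-relative-to-goal,
and classifies every unit of the three fc layers as unimodal / bimodal /
multimodal / non-directional, with peak azimuths and half-height widths.
"""

import json
from pathlib import Path

import pandas as pd

from batnav import classify_unit, layer_summary, probe_activations, sample_offroute_probes
from batnav import experiments as ex
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
    model = load_model(SCRATCH / "navnet_full.npz")

    # all-around probes near the route (the network's operating regime)
    probes = sample_offroute_probes(
        world, trajectory, n_points=5, distance_range_m=(100.0, 600.0),
        seed=child_seed(SEED, "unit_probes"),
    )
    profiles = probe_activations(model, probes)
    tunings = [classify_unit(p) for p in profiles]

    rows = []
    for t in tunings:
        rows.append(
            {
                "layer": t.unit_id[0],
                "unit": t.unit_id[1],
                "modality": t.modality,
                "rayleigh_p": t.rayleigh_p,
                "peak_az_deg": t.peaks[0][0] if t.peaks and t.directional else None,
                "width_deg": t.widths_deg[0] if t.widths_deg else None,
            }
        )
    pd.DataFrame(rows).to_csv(RESULTS / "unit_tuning.csv", index=False)

    summaries = {}
    for layer in (1, 2, 3):
        ts = [t for t in tunings if t.unit_id[0] == layer]
        s = layer_summary(ts, layer=layer)
        summaries[f"layer{layer}"] = {
            "n_units": s.n_units,
            "class_fractions": s.class_fractions,
            "modal_peak_bin_center_deg": s.modal_bin_center_deg,
        }
        fr = s.class_fractions
        print(f"layer {layer} ({s.n_units} units): "
              f"uni {100 * fr['unimodal']:.0f}%, bi {100 * fr['bimodal']:.0f}%, "
              f"multi {100 * fr['multimodal']:.0f}%, non-dir {100 * fr['non_directional']:.0f}%"
              + (f"; modal unimodal peak bin {s.modal_bin_center_deg:.0f} deg"
                 if s.modal_bin_center_deg is not None else ""))
    with open(RESULTS / "unit_tuning_summary.json", "w") as fh:
        json.dump(summaries, fh, indent=2)


if __name__ == "__main__":
    main()
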