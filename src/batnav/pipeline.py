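"""End-to-end orchestration: seeds, presets, the pipeline runner and the
fixture generator used by the test suite.

Every stochastic stage derives its seed from the single global seed by a
stable hash of the stage name, so one knob reproduces the whole run while
stages stay independently re-runnable.
"""

from __future__ import annotations

import json
import time
import zlib
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np

from .acquisition import ProtocolConfig, sample_route_views
from .navnet import ArchConfig, Hyperparams, build_model, sector_error, train_model
from .simulator import SimConfig, make_noisy_oracle, run_batch, sd_for_mean_abs_error
from .trajectory import TrajectoryConfig, make_trajectory, save_trajectory
from .world import WorldConfig, build_world, save_world

__all__ = ["RunConfig", "child_seed", "run_pipeline", "make_fixtures"]


def child_seed(global_seed: int, stage: str) -> int:
    """Stable per-stage seed: crc32 of "<seed>:<stage>", below 2**31."""
    return zlib.crc32(f"{global_seed}:{stage}".encode()) % (2**31)


@dataclass
class RunConfig:
    """Nested configuration of a full run.

    ``scale`` selects a preset: ``desk`` (64x64 images, compact network) or
    ``paper_faithful`` (160x160, fc sizes 4096/1024/256, batch 32, lr 0.01).
    """

    seed: int = 0
    scale: str = "desk"
    out_dir: str = "pipeline_out"
    world: WorldConfig = field(default_factory=WorldConfig)
    trajectory: TrajectoryConfig = field(default_factory=TrajectoryConfig)
    protocol: ProtocolConfig = field(default_factory=ProtocolConfig)
    arch: ArchConfig = field(default_factory=ArchConfig)
    hyper: Hyperparams = field(default_factory=Hyperparams)
    sim: SimConfig = field(default_factory=SimConfig)
    n_test_views: int = 600
    noisy_oracle_mean_errors: tuple[float, float] = (22.2, 25.4)
    sim_runs_per_estimator: int = 50

    @classmethod
    def preset(cls, scale: str = "desk", seed: int = 0, out_dir: str = "pipeline_out") -> "RunConfig":
        if scale == "desk":
            return cls(seed=seed, scale=scale, out_dir=out_dir)
        if scale == "paper_faithful":
            return cls(
                seed=seed,
                scale=scale,
                out_dir=out_dir,
                protocol=ProtocolConfig(resolution=160),
                arch=ArchConfig(
                    conv_blocks=((16, 3, 2), (32, 3, 2), (64, 3, 2), (128, 3, 2)),
                    fc_sizes=(4096, 1024, 256),
                    input_hw=(160, 160),
                ),
                hyper=Hyperparams(learning_rate=0.01, batch_size=32, l2_weight=1e-4, epochs=30),
            )
        if scale == "micro":  # sub-minute smoke scale for tests
            return cls(
                seed=seed,
                scale=scale,
                out_dir=out_dir,
                world=WorldConfig(
                    goal_distance_m=2_000.0,
                    n_light_sources=6,
                    scatter_lateral_range_m=(300.0, 1_500.0),
                    forward_along_range_m=(-300.0, 1_200.0),
                    forward_lateral_m=800.0,
                    city_lateral_m=-900.0,
                    city_extent_m=300.0,
                    min_city_axis_offset_m=500.0,
                ),
                trajectory=TrajectoryConfig(lateral_amplitude_m=50.0, lateral_periods=1.5),
                protocol=ProtocolConfig(
                    rotation_step_deg=30.0, resolution=32, zigzag_amplitude_m=30.0, position_jitter_m=5.0
                ),
                arch=ArchConfig(conv_blocks=((6, 3, 2), (12, 3, 2)), fc_sizes=(32, 16, 8), input_hw=(32, 32)),
                hyper=Hyperparams(epochs=1),
                sim=SimConfig(start_zone_m=(0.0, 500.0), max_steps=30, success_radius_m=350.0),
                n_test_views=60,
                sim_runs_per_estimator=5,
            )
        raise ValueError(f"unknown scale preset {scale!r}")

    @classmethod
    def from_dict(cls, doc: dict) -> "RunConfig":
        """Strict construction: unknown keys raise, naming the key."""
        base = cls.preset(doc.get("scale", "desk"), seed=doc.get("seed", 0), out_dir=doc.get("out_dir", "pipeline_out"))
        nested = {
            "world": WorldConfig, "trajectory": TrajectoryConfig, "protocol": ProtocolConfig,
            "arch": ArchConfig, "hyper": Hyperparams, "sim": SimConfig,
        }
        known = set(vars(base))
        for key, value in doc.items():
            if key not in known:
                raise ValueError(f"unknown configuration key: {key!r}")
            if key in nested and isinstance(value, dict):
                sub_cls = nested[key]
                defaults = vars(getattr(base, key))
                for sub in value:
                    if sub not in defaults:
                        raise ValueError(f"unknown configuration key: {key}.{sub!r}")
                merged = {
                    k: (tuple(v) if isinstance(defaults[k], tuple) and isinstance(v, (list, tuple)) else v)
                    for k, v in value.items()
                }
                setattr(base, key, sub_cls(**(defaults | merged)))
            else:
                setattr(base, key, value)
        return base


def run_pipeline(config: RunConfig) -> dict:
    """Execute world -> acquisition -> training -> evaluation -> simulation
    in order; returns (and writes) a manifest of artifacts and stage
    wall-times.  Any stage failure propagates with its stage named."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"seed": config.seed, "scale": config.scale, "stages": {}, "artifacts": {}, "reports": {}}
    log_path = out / "run.log"
    log_fh = open(log_path, "w")

    def stage(name):
        def wrap(fn):
            t0 = time.perf_counter()
            try:
                result = fn()
            except Exception as exc:
                log_fh.write(json.dumps({"stage": name, "status": "failed", "error": str(exc)}) + "\n")
                log_fh.close()
                raise RuntimeError(f"pipeline stage {name!r} failed: {exc}") from exc
            dt = time.perf_counter() - t0
            manifest["stages"][name] = {"wall_time_s": round(dt, 3), "seed": child_seed(config.seed, name)}
            log_fh.write(json.dumps({"stage": name, "status": "ok", "wall_time_s": round(dt, 3)}) + "\n")
            log_fh.flush()
            return result

        return wrap

    world = stage("world")(lambda: build_world(config.world, child_seed(config.seed, "world")))
    save_world(world, out / "world.yaml")
    manifest["artifacts"]["world"] = str(out / "world.yaml")

    traj = stage("trajectory")(lambda: make_trajectory(world, config.trajectory, child_seed(config.seed, "trajectory")))
    save_trajectory(traj, out / "trajectory.csv")
    manifest["artifacts"]["trajectory"] = str(out / "trajectory.csv")

    dataset = stage("acquire")(
        lambda: sample_route_views(world, traj, config.protocol, child_seed(config.seed, "acquire"))
    )
    manifest["reports"]["n_views"] = len(dataset)

    model = stage("train")(
        lambda: train_model(
            build_model(config.arch, child_seed(config.seed, "init")),
            dataset,
            config.hyper.__class__(**(vars(config.hyper) | {"seed": child_seed(config.seed, "train")})),
        )
    )

    def _evaluate():
        from . import experiments  # deferred: experiments also uses child_seed

        test = experiments.fresh_test_views(
            world, traj, config.n_test_views, child_seed(config.seed, "test_views"), protocol=config.protocol
        )
        return sector_error(model, test)

    summary = stage("evaluate")(_evaluate)
    manifest["reports"]["sector_error"] = asdict(summary)

    def _simulate():
        estimators = [
            make_noisy_oracle(world, sd_for_mean_abs_error(m), seed=child_seed(config.seed, f"oracle{i}"))
            for i, m in enumerate(config.noisy_oracle_mean_errors)
        ]
        return run_batch(world, traj, estimators, config.sim_runs_per_estimator, config.sim,
                         seed=child_seed(config.seed, "simulate"))

    batch = stage("simulate")(_simulate)
    manifest["reports"]["sim_success"] = {
        "pooled_rate": batch.pooled_rate, "successes": batch.successes, "runs": batch.runs,
    }

    manifest["history"] = model.training_history
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)
    log_fh.close()
    manifest["artifacts"]["manifest"] = str(out / "manifest.json")
    return manifest


def make_fixtures(seed: int = 0) -> dict:
    """Small, sub-second, bit-reproducible objects for tests.

    Returns a dict with a tiny world and trajectory, a small labelled view
    dataset, a stub model whose fc-layer units are von Mises tuning curves
    with recorded ground truth, and the truth table itself.
    """
    cfg = RunConfig.preset("micro", seed=seed)
    world = build_world(cfg.world, child_seed(seed, "fixture_world"))
    traj = make_trajectory(world, cfg.trajectory, child_seed(seed, "fixture_traj"))
    protocol = ProtocolConfig(
        rotation_step_deg=30.0, resolution=32, supersample=2,
        zigzag_amplitude_m=30.0, position_jitter_m=5.0, views_per_between=1,
    )
    dataset = sample_route_views(world, traj, protocol, child_seed(seed, "fixture_views"))
    stub, truth = _von_mises_stub(child_seed(seed, "fixture_stub"))
    return {
        "world": world,
        "trajectory": traj,
        "protocol": protocol,
        "dataset": dataset,
        "stub_model": stub,
        "stub_truth": truth,
    }


class VonMisesStubModel:
    """A fake probed network whose units have known azimuth tuning.

    ``unit_responses`` evaluates each unit's tuning curve at the probe
    views' relative gazes, so the tuning recovery pipeline can be validated
    against ground truth.  Peak weights of multi-peak units are dominated
    (unequal) so that the profiles carry a nonzero circular resultant;
    balanced symmetric profiles would be Rayleigh-invisible by construction.
    """

    def __init__(self, units_per_layer: dict[str, list[dict]]):
        self.units_per_layer = units_per_layer

    def unit_responses(self, probe) -> dict[str, np.ndarray]:
        rel = np.radians(np.asarray(probe.labels, dtype=float))
        out = {}
        for name, units in self.units_per_layer.items():
            resp = np.empty((len(rel), len(units)))
            for j, unit in enumerate(units):
                acc = np.full(len(rel), unit.get("baseline", 0.0))
                for mu, kappa, amp in unit["components"]:
                    acc = acc + amp * np.exp(kappa * (np.cos(rel - np.radians(mu)) - 1.0))
                resp[:, j] = acc
            out[name] = resp
        return out


def _von_mises_stub(seed: int) -> tuple[VonMisesStubModel, list[dict]]:
    rng = np.random.default_rng(seed)
    truth: list[dict] = []
    units: list[dict] = []

    def add(modality, components):
        units.append({"components": components, "baseline": 0.05})
        truth.append({"modality": modality, "peaks": sorted(mu for mu, _, _ in components)})

    for _ in range(30):  # unimodal
        mu = float(rng.uniform(0.0, 360.0))
        add("unimodal", [(mu, float(rng.uniform(4.0, 8.0)), 1.0)])
    for _ in range(15):  # bimodal: near-antipodal second peak (resolvable at 30 deg bins)
        mu = float(rng.uniform(0.0, 360.0))
        sep = float(rng.uniform(140.0, 180.0))
        add("bimodal", [(mu, 6.0, 1.0), ((mu + sep) % 360.0, 6.0, float(rng.uniform(0.7, 0.95)))])
    for _ in range(10):  # multimodal: dominant peak plus two flankers
        mu = float(rng.uniform(0.0, 360.0))
        off = float(rng.uniform(110.0, 125.0))
        kappa = float(rng.uniform(8.0, 12.0))
        add(
            "multimodal",
            [(mu, kappa, 1.0), ((mu + off) % 360.0, kappa, 0.65), ((mu - off) % 360.0, kappa, 0.55)],
        )
    for _ in range(5):  # flat units
        units.append({"components": [], "baseline": 0.3})
        truth.append({"modality": "non_directional", "peaks": []})

    order = rng.permutation(len(units))
    units = [units[i] for i in order]
    truth = [truth[i] for i in order]
    return VonMisesStubModel({"fc1": units}), truth
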