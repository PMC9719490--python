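"""The azimuth-regression network ("navigation net") and its evaluations.

A compact VGG-style convolutional stack (conv-ReLU-maxpool blocks) followed
by three fully-connected probe layers and a single bounded scalar head
predicts the signed angle of the current gaze relative to the goal bearing,
in degrees in [-180, 180].  The loss is the wrap-aware squared angular
difference: per batch,

    loss = sum_i angdiff(pred_i, label_i)^2 / (2 * 32) + 1e-4 * reg_sum

where angdiff is the shorter-arc magnitude.  The fixed divisor 2*32 (the
nominal batch normaliser) is kept regardless of the actual batch size by
default; a flag switches to normalising by the actual batch.  The gradient
is taken through the equivalent wrapped-difference form, which equals the
min-form value and is differentiable except on the measure-zero 180-degree
antipode.

Evaluation utilities cover the goal-sector error summary, the polar error
profile, the stripe-occlusion experiment, and the "green sector" analysis
of where around a probe point the prediction errs below a threshold.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, replace

import numpy as np

from . import nn
from .acquisition import Dataset, ProbeSet, stripe_occlude
from .angles import angular_difference, wrap_signed
from .errors import TrainingError

__all__ = [
    "ArchConfig",
    "Hyperparams",
    "TrainedModel",
    "ErrorSummary",
    "GreenSectorReport",
    "batch_loss",
    "build_model",
    "train_model",
    "sector_error",
    "error_profile",
    "stripe_experiment",
    "green_sectors",
    "save_model",
    "load_model",
]

PROBE_NAMES = ("fc1", "fc2", "fc3")


@dataclass(frozen=True)
class ArchConfig:
    """Network topology.  ``conv_blocks`` is a tuple of (filters, kernel,
    pool) per block; ``fc_sizes`` are the three fully-connected probe layers
    (desk default 256/64/32; full-scale 4096/1024/256)."""

    conv_blocks: tuple[tuple[int, int, int], ...] = ((8, 3, 2), (16, 3, 2), (32, 3, 2))
    fc_sizes: tuple[int, int, int] = (256, 64, 32)
    input_hw: tuple[int, int] = (64, 64)
    in_channels: int = 2
    head_scale: float = 180.0
    head_temperature: float = 180.0

    def __post_init__(self):
        if len(self.fc_sizes) != 3:
            raise ValueError("fc_sizes must name exactly three probe layers")


@dataclass(frozen=True)
class Hyperparams:
    learning_rate: float = 0.01
    batch_size: int = 32
    l2_weight: float = 1e-4
    epochs: int = 10
    optimizer_name: str = "sgd-momentum"
    momentum: float = 0.9
    clip_norm: float = 10.0
    input_noise_sd: float = 0.01   # sensor-noise emulation on training images
    average_tail_epochs: int = 3   # Polyak-style weight average over the last epochs
    lr_decay_epochs: tuple[int, ...] = ()   # epochs at which lr is halved
    fixed_loss_divisor: bool = True
    seed: int = 0

    def __post_init__(self):
        if self.batch_size <= 0:
            raise ValueError("batch_size must be positive")
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")


@dataclass
class ErrorSummary:
    """Mean/SD of |angular error| over views within a gaze sector."""

    mean_abs_error_deg: float
    sd_deg: float
    n: int
    sector_deg: float


@dataclass
class GreenSectorReport:
    """Contiguous gaze intervals with error below threshold, per probe."""

    per_probe: list[list[tuple[float, float]]]  # [start_deg, end_deg) intervals
    total_width_deg: list[float]
    mean_total_width_deg: float
    sd_total_width_deg: float
    threshold_deg: float


class TrainedModel:
    """The regression network plus named taps on its three fc layers."""

    def __init__(self, net: nn.Sequential, arch: ArchConfig):
        self.net = net
        self.arch = arch
        self.training_history: list[dict] = []

    @property
    def probe_sizes(self) -> tuple[int, int, int]:
        return self.arch.fc_sizes

    def predict(self, images: np.ndarray, batch: int = 256) -> np.ndarray:
        """Predicted relative goal angles in degrees, shape (N,)."""
        images = np.asarray(images, dtype=np.float32)
        out = np.empty(len(images), dtype=np.float64)
        for i in range(0, len(images), batch):
            out[i : i + batch] = self.net.forward(images[i : i + batch]).ravel()
        return out

    def unit_responses(self, probe, batch: int = 256) -> dict[str, np.ndarray]:
        """Post-activation outputs of the three fc probe layers.

        ``probe`` is anything with an ``images`` attribute (or a bare image
        array).  Returns ``{"fc1": (N, n1), ...}``.
        """
        images = np.asarray(getattr(probe, "images", probe), dtype=np.float32)
        chunks: dict[str, list[np.ndarray]] = {name: [] for name in PROBE_NAMES}
        for i in range(0, len(images), batch):
            _, taps = self.net.forward(images[i : i + batch], collect=PROBE_NAMES)
            for name in PROBE_NAMES:
                chunks[name].append(taps[name])
        return {name: np.concatenate(chunks[name]) for name in PROBE_NAMES}


def batch_loss(predictions, labels, regularization_sum: float = 0.0,
               fixed_divisor: bool = True) -> float:
    """The wrap-aware squared-error batch loss (see module docstring)."""
    predictions = np.asarray(predictions, dtype=float)
    labels = np.asarray(labels, dtype=float)
    if predictions.shape != labels.shape:
        raise ValueError("predictions and labels must have the same length")
    divisor = 64.0 if fixed_divisor else 2.0 * len(predictions)
    diffs = angular_difference(predictions, labels)
    return float(np.sum(np.asarray(diffs) ** 2) / divisor + 1e-4 * regularization_sum)


def build_model(arch: ArchConfig | None = None, seed: int = 0) -> TrainedModel:
    """Construct an untrained model with seeded parameter initialisation."""
    arch = arch or ArchConfig()
    rng = np.random.default_rng(seed)
    layers: list[tuple[str, nn.Layer]] = []
    c_in = arch.in_channels
    h, w = arch.input_hw
    for i, (filters, kernel, pool) in enumerate(arch.conv_blocks):
        layers.append((f"conv{i + 1}", nn.Conv2D(c_in, filters, kernel, rng)))
        layers.append((f"relu_c{i + 1}", nn.ReLU()))
        if pool > 1:
            layers.append((f"pool{i + 1}", nn.MaxPool2()))
            h, w = h // 2, w // 2
        c_in = filters
    layers.append(("flatten", nn.Flatten()))
    n_in = h * w * c_in
    for j, size in enumerate(arch.fc_sizes):
        layers.append((f"fc{j + 1}_dense", nn.Dense(n_in, size, rng)))
        layers.append((PROBE_NAMES[j], nn.ReLU()))
        n_in = size
    layers.append(("out", nn.Dense(n_in, 1, rng)))
    layers.append(("head", nn.BoundedHead(arch.head_scale, arch.head_temperature)))
    return TrainedModel(nn.Sequential(layers), arch)


def train_model(model: TrainedModel, train_dataset: Dataset, hyper: Hyperparams | None = None) -> TrainedModel:
    """Train in place with seeded minibatch SGD; returns the same model.

    The per-epoch history records the mean training |angular error| and mean
    loss (computed from the pre-update forward pass of each batch).  Raises
    TrainingError with the epoch index if the loss becomes non-finite.
    """
    hyper = hyper or Hyperparams()
    if len(train_dataset) == 0:
        raise TrainingError("training set is empty")
    images = np.asarray(train_dataset.images, dtype=np.float32)
    labels = np.asarray(train_dataset.labels, dtype=np.float64)
    opt = nn.SGD(
        model.net.params(),
        lr=hyper.learning_rate,
        momentum=hyper.momentum,
        l2=hyper.l2_weight,
        clip_norm=hyper.clip_norm,
        rmsprop=hyper.optimizer_name == "rmsprop-momentum",
    )
    rng = np.random.default_rng(hyper.seed)
    B = hyper.batch_size
    tail_sum = None
    tail_count = 0
    for epoch in range(hyper.epochs):
        if epoch in hyper.lr_decay_epochs:
            opt.lr *= 0.5
        order = rng.permutation(len(images))
        abs_errs, losses = [], []
        for start in range(0, len(order), B):
            idx = order[start : start + B]
            x = images[idx]
            y = labels[idx]
            if hyper.input_noise_sd > 0:
                x = x + rng.normal(0.0, hyper.input_noise_sd, size=x.shape).astype(np.float32)
            pred = model.net.forward(x).ravel()
            wrapped = wrap_signed(pred - y)
            divisor = 64.0 if hyper.fixed_loss_divisor else 2.0 * len(idx)
            loss = float(np.sum(wrapped**2) / divisor)
            if not np.isfinite(loss):
                raise TrainingError(f"training diverged at epoch {epoch}", epoch=epoch)
            abs_errs.append(np.abs(wrapped))
            losses.append(loss)
            dpred = (2.0 * wrapped / divisor).astype(np.float32)
            model.net.backward(dpred[:, None])
            opt.step()
        model.training_history.append(
            {
                "epoch": epoch,
                "mean_abs_error_deg": float(np.mean(np.concatenate(abs_errs))),
                "mean_batch_loss": float(np.mean(losses)),
                "lr": opt.lr,
            }
        )
        if hyper.average_tail_epochs > 0 and epoch >= hyper.epochs - hyper.average_tail_epochs:
            if tail_sum is None:
                tail_sum = [p.value.astype(np.float64).copy() for p in model.net.params()]
            else:
                for acc, p in zip(tail_sum, model.net.params()):
                    acc += p.value
            tail_count += 1
    if tail_sum is not None and tail_count > 1:
        for acc, p in zip(tail_sum, model.net.params()):
            p.value[...] = (acc / tail_count).astype(p.value.dtype)
    return model


def _predictions(model, dataset: Dataset) -> np.ndarray:
    if hasattr(model, "predict"):
        return np.asarray(model.predict(dataset.images))
    return np.asarray(model(dataset))  # callable fallback (oracles, stubs)


def sector_error(model, test_set: Dataset, sector_halfwidth_deg: float = 45.0) -> ErrorSummary:
    """Mean and SD of |angular error| over views gazing within
    ``sector_halfwidth_deg`` of the goal direction."""
    mask = np.abs(test_set.labels) <= sector_halfwidth_deg
    if not np.any(mask):
        raise ValueError(f"no test samples with |label| <= {sector_halfwidth_deg} deg")
    preds = _predictions(model, test_set)
    errs = np.asarray(angular_difference(preds[mask], test_set.labels[mask]))
    return ErrorSummary(
        mean_abs_error_deg=float(errs.mean()),
        sd_deg=float(errs.std()),
        n=int(mask.sum()),
        sector_deg=float(sector_halfwidth_deg),
    )


def error_profile(model, test_set: Dataset, bin_deg: float = 30.0):
    """Polar profile: per-label-bin mean |angular error| and counts.

    Returns (bin_centers, mean_abs_error, counts); empty bins carry NaN.
    """
    if abs(360.0 / bin_deg - round(360.0 / bin_deg)) > 1e-9:
        raise ValueError("bin_deg must divide 360")
    n_bins = int(round(360.0 / bin_deg))
    preds = _predictions(model, test_set)
    errs = np.asarray(angular_difference(preds, test_set.labels))
    idx = np.floor((test_set.labels + 180.0) / bin_deg).astype(int) % n_bins
    counts = np.bincount(idx, minlength=n_bins)
    sums = np.bincount(idx, weights=errs, minlength=n_bins)
    means = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
    centers = -180.0 + (np.arange(n_bins) + 0.5) * bin_deg
    return centers, means, counts


def _occlude_dataset(dataset: Dataset, which: str) -> Dataset:
    images = np.stack([stripe_occlude(im, which) for im in dataset.images])
    out = Dataset(
        images=images,
        positions=dataset.positions,
        gazes=dataset.gazes,
        labels=dataset.labels,
        arc_m=dataset.arc_m,
        split=dataset.split,
        provenance=dict(dataset.provenance) | {"occluded": which},
    )
    return out


def stripe_experiment(
    arch: ArchConfig,
    train_set: Dataset,
    test_set: Dataset,
    hyper: Hyperparams | None = None,
    sector_halfwidth_deg: float = 45.0,
) -> dict[str, ErrorSummary]:
    """Train one model per occluded horizontal third (occlusion applied to
    both training and test images) and evaluate each in the goal sector."""
    hyper = hyper or Hyperparams()
    results: dict[str, ErrorSummary] = {}
    for which in ("top", "middle", "bottom"):
        occ_train = _occlude_dataset(train_set, which)
        occ_test = _occlude_dataset(test_set, which)
        occ_arch = replace(arch, input_hw=occ_train.images.shape[1:3])
        model = build_model(occ_arch, seed=hyper.seed)
        train_model(model, occ_train, hyper)
        results[which] = sector_error(model, occ_test, sector_halfwidth_deg)
    return results


def green_sectors(predict, probes: list[ProbeSet], threshold_deg: float = 15.0) -> GreenSectorReport:
    """Find, per probe, the contiguous (circular) gaze intervals where the
    predicted goal direction errs by less than ``threshold_deg``.

    ``predict`` is either a model with ``.predict(images)`` or a callable
    mapping a ProbeSet to an array of predicted relative angles aligned with
    ``probe.gazes``.
    """
    if not probes:
        raise ValueError("probes must be non-empty")
    per_probe: list[list[tuple[float, float]]] = []
    totals: list[float] = []
    for probe in probes:
        if hasattr(predict, "predict"):
            preds = np.asarray(predict.predict(probe.images))
        else:
            preds = np.asarray(predict(probe))
        errs = np.asarray(angular_difference(preds, probe.labels))
        ok = errs < threshold_deg
        spacing = 360.0 / len(probe.gazes)
        intervals = _circular_runs(ok, probe.gazes, spacing)
        per_probe.append(intervals)
        totals.append(sum(b - a if b > a else b - a + 360.0 for a, b in intervals))
    return GreenSectorReport(
        per_probe=per_probe,
        total_width_deg=totals,
        mean_total_width_deg=float(np.mean(totals)),
        sd_total_width_deg=float(np.std(totals)),
        threshold_deg=float(threshold_deg),
    )


def _circular_runs(ok: np.ndarray, gazes: np.ndarray, spacing: float) -> list[tuple[float, float]]:
    """Maximal runs of True on a circle -> [start_deg, end_deg) intervals."""
    n = len(ok)
    if ok.all():
        return [(0.0, 360.0)]
    if not ok.any():
        return []
    edges = np.flatnonzero(ok & ~np.roll(ok, 1))  # run starts
    intervals = []
    for e in edges:
        length = 0
        while ok[(e + length) % n]:
            length += 1
        start = float(gazes[e])
        end = (start + length * spacing) % 360.0
        intervals.append((start, end if end != start else 360.0))
    return intervals


# ---------------------------------------------------------------------------
# checkpoints

def save_model(model: TrainedModel, path) -> None:
    """Single-file checkpoint with the architecture embedded."""
    meta = {
        "arch": {k: v for k, v in vars(model.arch).items()},
        "history": model.training_history,
    }
    arrays = model.net.state_arrays()
    with open(path, "wb") as fh:
        np.savez(fh, __meta__=np.frombuffer(json.dumps(meta, default=list).encode(), dtype=np.uint8), **arrays)


def load_model(path) -> TrainedModel:
    with np.load(path) as data:
        meta = json.loads(bytes(data["__meta__"]).decode())
        arch_raw = meta["arch"]
        arch = ArchConfig(
            conv_blocks=tuple(tuple(b) for b in arch_raw["conv_blocks"]),
            fc_sizes=tuple(arch_raw["fc_sizes"]),
            input_hw=tuple(arch_raw["input_hw"]),
            in_channels=arch_raw["in_channels"],
            head_scale=arch_raw["head_scale"],
            head_temperature=arch_raw["head_temperature"],
        )
        model = build_model(arch, seed=0)
        model.net.load_state_arrays({k: data[k] for k in data.files if k != "__meta__"})
        model.training_history = meta["history"]
    return model
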