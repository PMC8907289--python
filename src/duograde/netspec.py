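"""Architecture description and forward-evaluation contract.

The network has two encoding paths (one per MR channel) with a shared 3x3x3
kernel but unequal filter budgets — asymmetric default 18:2, symmetric variant
10:10 — each path being ``levels`` blocks of
conv -> ReLU -> dropout(0.3) -> conv -> ReLU -> 2x2x2 max-pool with the filter
count doubling per level.  The paths' final feature blocks are flattened,
concatenated and fed through three fully connected layers ending in a softmax
over two classes.  Single-path baselines reuse the same block structure on
one or both input channels.

Choices the source architecture leaves open (encoder depth, FC widths,
same-padding, fusion by concatenation, +/-2 SD truncation of the initializer)
are fixed here as documented defaults and remain configurable.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .imgio import RoiTensor
from .network import DualPathNet, glorot_std  # re-exported: glorot_std

__all__ = [
    "NetConfig",
    "LayerSpec",
    "NetConfigError",
    "filter_allocation",
    "build_network",
    "glorot_std",
    "init_model",
    "predict",
    "architecture_summary",
]

SINGLE_PATH_CHANNELS = ("T1CE", "FLAIR", "both")


class NetConfigError(ValueError):
    pass


@dataclass
class NetConfig:
    """Full architecture description.

    In ``single_path`` mode the encoder's first-level filter count is
    ``sum(path_filters)`` (default 20), keeping first-level capacity equal to
    the dual-path variants.
    """

    path_filters: tuple[int, int] = (18, 2)
    levels: int = 3
    dropout_rate: float = 0.3
    fc_widths: tuple[int, ...] = (256, 64, 2)
    input_shape: tuple[int, int, int] = (64, 64, 64)
    n_classes: int = 2
    mode: str = "dual_path"
    single_path_channels: str = "both"

    kernel = (3, 3, 3)  # fixed
    pool = (2, 2, 2)  # fixed

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if self.mode not in ("dual_path", "single_path"):
            raise NetConfigError(f"mode must be dual_path or single_path, got {self.mode!r}")
        if self.mode == "dual_path":
            if len(self.path_filters) != 2 or any(f < 1 for f in self.path_filters):
                raise NetConfigError(
                    f"dual_path requires two filter counts >= 1, got {self.path_filters}"
                )
        if self.mode == "single_path" and self.single_path_channels not in SINGLE_PATH_CHANNELS:
            raise NetConfigError(
                f"single_path_channels must be in {SINGLE_PATH_CHANNELS}"
            )
        if self.levels < 1:
            raise NetConfigError("levels must be >= 1")
        if not 0 <= self.dropout_rate < 1:
            raise NetConfigError("dropout_rate must be in [0, 1)")
        if len(self.fc_widths) < 1 or self.fc_widths[-1] != self.n_classes:
            raise NetConfigError(
                f"last FC width must equal n_classes={self.n_classes}, got {self.fc_widths}"
            )
        div = 2**self.levels
        if any(int(s) % div != 0 or int(s) // div < 1 for s in self.input_shape):
            raise NetConfigError(
                f"input_shape {self.input_shape} must be divisible by 2^levels={div} "
                "with at least one voxel remaining"
            )

    # -- derived quantities -------------------------------------------------
    @property
    def path_names(self) -> tuple[str, ...]:
        return ("t1ce", "flair") if self.mode == "dual_path" else ("single",)

    @property
    def in_channels_per_path(self) -> tuple[int, ...]:
        if self.mode == "dual_path":
            return (1, 1)
        return (2,) if self.single_path_channels == "both" else (1,)

    @property
    def first_level_filters(self) -> tuple[int, ...]:
        if self.mode == "dual_path":
            return tuple(self.path_filters)
        return (sum(self.path_filters),)


@dataclass
class LayerSpec:
    """One layer of the unrolled architecture, with shape bookkeeping."""

    name: str
    kind: str  # conv3d | relu | dropout | maxpool3d | flatten | concat | dense | softmax
    path: str  # t1ce | flair | single | merged
    in_channels: int = 0
    out_channels: int = 0
    out_spatial: tuple[int, int, int] | None = None
    fan_in: int = 0
    fan_out: int = 0
    n_params: int = 0

    def __post_init__(self) -> None:
        if self.kind in ("conv3d", "dense") and (self.fan_in <= 0 or self.fan_out <= 0):
            raise NetConfigError(f"weighted layer {self.name} requires positive fans")


def filter_allocation(config: NetConfig) -> dict[str, list[int]]:
    """Per-level filter counts for each path: level l gets first-level x 2^l."""
    config.validate()
    return {
        path: [first * (2**lvl) for lvl in range(config.levels)]
        for path, first in zip(config.path_names, config.first_level_filters)
    }


def build_network(config: NetConfig) -> list[LayerSpec]:
    """Unroll the config into an ordered, shape-checked LayerSpec list."""
    config.validate()
    alloc = filter_allocation(config)
    specs: list[LayerSpec] = []
    kernel_volume = 27
    final_channels: dict[str, int] = {}
    spatial = tuple(int(s) for s in config.input_shape)

    for path, in_ch in zip(config.path_names, config.in_channels_per_path):
        c = in_ch
        spatial = tuple(int(s) for s in config.input_shape)
        for lvl, f in enumerate(alloc[path]):
            for conv_i in (1, 2):
                cin = c if conv_i == 1 else f
                specs.append(
                    LayerSpec(
                        name=f"{path}_l{lvl}_conv{conv_i}",
                        kind="conv3d",
                        path=path,
                        in_channels=cin,
                        out_channels=f,
                        out_spatial=spatial,
                        fan_in=cin * kernel_volume,
                        fan_out=f * kernel_volume,
                        n_params=f * cin * kernel_volume + f,
                    )
                )
                specs.append(
                    LayerSpec(f"{path}_l{lvl}_relu{conv_i}", "relu", path,
                              f, f, spatial)
                )
                if conv_i == 1:
                    specs.append(
                        LayerSpec(f"{path}_l{lvl}_dropout", "dropout", path,
                                  f, f, spatial)
                    )
            if any(s < 2 for s in spatial):
                raise NetConfigError(
                    f"cannot pool {spatial} at level {lvl}: spatial underflow"
                )
            spatial = tuple(s // 2 for s in spatial)
            specs.append(
                LayerSpec(f"{path}_l{lvl}_pool", "maxpool3d", path, f, f, spatial)
            )
            c = f
        specs.append(LayerSpec(f"{path}_flatten", "flatten", path, c, c, spatial))
        final_channels[path] = c

    voxels = int(np.prod(spatial))
    feat = voxels * sum(final_channels.values())
    if config.mode == "dual_path":
        specs.append(LayerSpec("concat", "concat", "merged", feat, feat, spatial))
    widths = (feat, *config.fc_widths)
    for i in range(len(config.fc_widths)):
        specs.append(
            LayerSpec(
                name=f"fc{i + 1}",
                kind="dense",
                path="merged",
                in_channels=widths[i],
                out_channels=widths[i + 1],
                fan_in=widths[i],
                fan_out=widths[i + 1],
                n_params=widths[i] * widths[i + 1] + widths[i + 1],
            )
        )
        if i < len(config.fc_widths) - 1:
            specs.append(
                LayerSpec(f"fc{i + 1}_dropout", "dropout", "merged",
                          widths[i + 1], widths[i + 1])
            )
    specs.append(LayerSpec("softmax", "softmax", "merged",
                           config.n_classes, config.n_classes))
    _check_chaining(specs)
    return specs


def _check_chaining(specs: list[LayerSpec]) -> None:
    """Consecutive layers within a path must have compatible channel chaining."""
    last_out: dict[str, int] = {}
    for spec in specs:
        prev = last_out.get(spec.path)
        if spec.kind in ("conv3d", "dense") and prev is not None and spec.in_channels != prev:
            raise NetConfigError(
                f"layer {spec.name}: in_channels {spec.in_channels} != "
                f"previous out_channels {prev}"
            )
        last_out[spec.path] = spec.out_channels


def init_model(config: NetConfig, seed: int = 0) -> DualPathNet:
    """Instantiate the network with Glorot truncated-normal weights."""
    alloc = filter_allocation(config)
    rng = np.random.default_rng(seed)
    return DualPathNet(
        mode=config.mode,
        in_channels_per_path=list(config.in_channels_per_path),
        filters_per_path=[alloc[p] for p in config.path_names],
        fc_widths=tuple(config.fc_widths),
        dropout_rate=config.dropout_rate,
        input_shape=tuple(int(s) for s in config.input_shape),
        rng=rng,
    )


def _roi_array(roi) -> np.ndarray:
    if isinstance(roi, RoiTensor):
        return roi.values
    return np.asarray(roi)


def select_channels(x: np.ndarray, config: NetConfig) -> np.ndarray:
    """Slice a (N, 2, ...) batch down to the channels the variant consumes."""
    if config.mode == "dual_path" or config.single_path_channels == "both":
        return x
    idx = 0 if config.single_path_channels == "T1CE" else 1
    return x[:, idx : idx + 1]


def predict(model_state: DualPathNet, roi, config: NetConfig | None = None) -> np.ndarray:
    """Class probabilities (index 1 = Grade II) for one ROI tensor.

    Inference is deterministic: dropout is inactive outside training.
    """
    x = _roi_array(roi)
    if x.ndim == 4:
        x = x[np.newaxis]
    if tuple(x.shape[2:]) != model_state.input_shape:
        raise ValueError(
            f"ROI shape {x.shape[2:]} does not match model input {model_state.input_shape}"
        )
    if config is not None:
        x = select_channels(x, config)
    probs = model_state.predict_proba(x)
    return probs[0] if probs.shape[0] == 1 else probs


def architecture_summary(config: NetConfig) -> str:
    """Human-readable layer table (name, kind, shapes, parameter counts)."""
    specs = build_network(config)
    lines = [
        f"{'layer':<22}{'kind':<10}{'path':<8}{'in':>6}{'out':>6}  {'spatial':<14}{'params':>10}",
        "-" * 78,
    ]
    total = 0
    for s in specs:
        spatial = "x".join(str(v) for v in s.out_spatial) if s.out_spatial else "-"
        lines.append(
            f"{s.name:<22}{s.kind:<10}{s.path:<8}{s.in_channels:>6}{s.out_channels:>6}"
            f"  {spatial:<14}{s.n_params:>10}"
        )
        total += s.n_params
    lines.append("-" * 78)
    lines.append(f"total parameters: {total}")
    return "\n".join(lines)
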