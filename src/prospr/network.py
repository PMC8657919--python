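"""The dilated residual distogram network.

The default configuration matches the published architecture: an initial
BatchNorm and 1x1 convolution on the 547-channel input, 220 pre-activation
residual blocks whose 3x3 convolutions cycle through dilations 1, 2, 4, 8
(the first 28 blocks at 256 channels, the remaining 192 at 128), then a
1x1 convolution down to the 10 distance classes plus full-row/full-column
convolutions for the per-residue auxiliary heads (secondary structure,
phi, psi, relative ASA).  The network operates on c x c crops of the
pairwise map (c = 64 by default).
"""

from __future__ import annotations

import dataclasses
import io
import json
from pathlib import Path

import numpy as np

from . import nn

AUX_HEAD_SIZES = {"ss": 9, "phi": 37, "psi": 37, "asa": 11}
N_AUX_CHANNELS = sum(AUX_HEAD_SIZES.values())  # 94
N_DIST_CLASSES = 10


@dataclasses.dataclass
class NetworkConfig:
    in_channels: int = 547
    n_blocks: int = 220
    wide_blocks: int = 28
    wide_channels: int = 256
    narrow_channels: int = 128
    dilation_cycle: tuple[int, ...] = (1, 2, 4, 8)
    crop_size: int = 64
    dropout_rate: float = 0.15
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_blocks < self.wide_blocks or self.wide_blocks < 0:
            raise ValueError("need 0 <= wide_blocks <= n_blocks")
        for field in ("in_channels", "n_blocks", "wide_channels",
                      "narrow_channels", "crop_size"):
            if getattr(self, field) <= 0:
                raise ValueError(f"{field} must be positive")
        if not self.dilation_cycle:
            raise ValueError("dilation_cycle must be non-empty")
        self.dilation_cycle = tuple(int(d) for d in self.dilation_cycle)

    @property
    def narrow_blocks(self) -> int:
        return self.n_blocks - self.wide_blocks

    def block_width(self, k: int) -> int:
        return self.wide_channels if k < self.wide_blocks else self.narrow_channels

    def block_dilation(self, k: int) -> int:
        return self.dilation_cycle[k % len(self.dilation_cycle)]

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["dilation_cycle"] = list(self.dilation_cycle)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "NetworkConfig":
        d = dict(d)
        if "dilation_cycle" in d:
            d["dilation_cycle"] = tuple(d["dilation_cycle"])
        return cls(**d)


def tiny_config(**overrides) -> NetworkConfig:
    """A desk-scale configuration for tests and smoke runs."""
    base = dict(in_channels=547, n_blocks=8, wide_blocks=2, wide_channels=16,
                narrow_channels=8, crop_size=16, dropout_rate=0.1)
    base.update(overrides)
    return NetworkConfig(**base)


@dataclasses.dataclass
class CropPrediction:
    """Per-crop output: distance distogram plus row/column auxiliary heads.

    ``dist`` is (c, c, 10) with each cell a probability vector; ``aux_i``
    and ``aux_j`` are (c, 94) with each head's slice separately normalized.
    ``origin`` locates the crop in 0-based full-sequence coordinates.
    """

    dist: np.ndarray
    aux_i: np.ndarray
    aux_j: np.ndarray
    origin: tuple[int, int] = (0, 0)

    def aux_head(self, which: str, axis: str = "i") -> np.ndarray:
        start = 0
        for name, size in AUX_HEAD_SIZES.items():
            if name == which:
                arr = self.aux_i if axis == "i" else self.aux_j
                return arr[:, start:start + size]
            start += size
        raise KeyError(which)


class DistogramNetwork:
    """Configurable dilated residual network over pairwise crops."""

    def __init__(self, cfg: NetworkConfig):
        self.cfg = cfg
        rng = np.random.default_rng(cfg.seed)
        self.dropout_rng = np.random.default_rng(
            np.random.SeedSequence(cfg.seed).spawn(1)[0])
        width0 = cfg.block_width(0)
        self.stem = nn.Sequential(
            nn.BatchNorm2d(cfg.in_channels),
            nn.Conv2d(cfg.in_channels, width0, 1, rng=rng),
        )
        self.blocks: list[nn.ResidualBlock] = []
        in_ch = width0
        for k in range(cfg.n_blocks):
            out_ch = cfg.block_width(k)
            block = nn.ResidualBlock(in_ch, out_ch, cfg.block_dilation(k),
                                     dropout_rate=cfg.dropout_rate, rng=rng)
            self.blocks.append(block)
            in_ch = out_ch
        final = cfg.block_width(cfg.n_blocks - 1)
        self.trunk_norm = nn.Sequential(nn.BatchNorm2d(final), nn.ELU())
        self.dist_head = nn.Conv2d(final, N_DIST_CLASSES, 1, rng=rng)
        c = cfg.crop_size
        self.aux_i_heads = {
            name: nn.CollapseConv(final, size, c, collapse_axis=3, rng=rng)
            for name, size in AUX_HEAD_SIZES.items()
        }
        self.aux_j_heads = {
            name: nn.CollapseConv(final, size, c, collapse_axis=2, rng=rng)
            for name, size in AUX_HEAD_SIZES.items()
        }
        for layer in self._all_layers():
            for sub in nn.iter_layers(layer):
                if isinstance(sub, nn.SpatialDropout):
                    sub.rng = self.dropout_rng
        self.train(False)

    # -- structure ---------------------------------------------------------

    def _all_layers(self) -> list[nn.Layer]:
        return ([self.stem] + list(self.blocks) + [self.trunk_norm,
                self.dist_head] + list(self.aux_i_heads.values())
                + list(self.aux_j_heads.values()))

    def params(self) -> list[nn.Param]:
        return [p for l in self._all_layers() for p in l.params()]

    def param_count(self) -> int:
        return int(sum(p.value.size for p in self.params()))

    def train(self, mode: bool = True) -> None:
        for l in self._all_layers():
            nn.set_training(l, mode)
        self.training = mode

    # -- forward / backward --------------------------------------------------

    def forward_logits(self, x: np.ndarray) -> dict[str, np.ndarray]:
        """Raw head logits for a batch.

        ``x``: (B, c, c, in_channels) or a single (c, c, in_channels) crop.
        Returns dist logits (B, 10, c, c) and per-head aux logits
        (B, size, c).
        """
        if x.ndim == 3:
            x = x[None]
        B, H, W, C = x.shape
        cfg = self.cfg
        if C != cfg.in_channels:
            raise ValueError(
                f"input has {C} channels, expected {cfg.in_channels}"
            )
        if H != cfg.crop_size or W != cfg.crop_size:
            raise ValueError(
                f"spatial size {(H, W)} does not match crop_size {cfg.crop_size}"
            )
        h = np.ascontiguousarray(x.transpose(0, 3, 1, 2), dtype=np.float32)
        h = self.stem.forward(h)
        for block in self.blocks:
            h = block.forward(h)
        h = self.trunk_norm.forward(h)
        self._trunk_out_shape = h.shape
        out = {"dist": self.dist_head.forward(h)}
        for name, head in self.aux_i_heads.items():
            out[f"{name}_i"] = head.forward(h)
        for name, head in self.aux_j_heads.items():
            out[f"{name}_j"] = head.forward(h)
        return out

    def backward(self, grads: dict[str, np.ndarray]) -> np.ndarray:
        """Backpropagate head gradients; returns d(loss)/d(input) in
        (B, C, H, W) layout."""
        g = self.dist_head.backward(grads["dist"])
        for name, head in self.aux_i_heads.items():
            key = f"{name}_i"
            if key in grads:
                g = g + head.backward(grads[key])
        for name, head in self.aux_j_heads.items():
            key = f"{name}_j"
            if key in grads:
                g = g + head.backward(grads[key])
        g = self.trunk_norm.backward(g)
        for block in reversed(self.blocks):
            g = block.backward(g)
        return self.stem.backward(g)

    def predict_crop(self, x: np.ndarray,
                     origin: tuple[int, int] = (0, 0)) -> CropPrediction:
        """Evaluation-mode forward pass returning normalized probabilities."""
        was_training = self.training
        self.train(False)
        logits = self.forward_logits(x)
        if was_training:
            self.train(True)
        dist = nn.softmax(logits["dist"][0].transpose(1, 2, 0), axis=-1)
        aux = {}
        for axis in ("i", "j"):
            parts = [nn.softmax(logits[f"{name}_{axis}"][0].T, axis=-1)
                     for name in AUX_HEAD_SIZES]
            aux[axis] = np.concatenate(parts, axis=1)
        return CropPrediction(dist=dist, aux_i=aux["i"], aux_j=aux["j"],
                              origin=origin)

    # -- persistence ---------------------------------------------------------

    def state_arrays(self) -> dict[str, np.ndarray]:
        state: dict[str, np.ndarray] = {}
        for k, p in enumerate(self.params()):
            state[f"param_{k}"] = p.value
        bn = 0
        for layer in self._all_layers():
            for sub in nn.iter_layers(layer):
                if isinstance(sub, nn.BatchNorm2d):
                    state[f"bn_{bn}_mean"] = sub.running_mean
                    state[f"bn_{bn}_var"] = sub.running_var
                    bn += 1
        return state

    def load_state_arrays(self, state: dict[str, np.ndarray]) -> None:
        for k, p in enumerate(self.params()):
            p.value[...] = state[f"param_{k}"]
        bn = 0
        for layer in self._all_layers():
            for sub in nn.iter_layers(layer):
                if isinstance(sub, nn.BatchNorm2d):
                    sub.running_mean[...] = state[f"bn_{bn}_mean"]
                    sub.running_var[...] = state[f"bn_{bn}_var"]
                    bn += 1

    def save(self, path: str | Path) -> None:
        """Checkpoint with the config embedded."""
        buf = io.BytesIO()
        np.savez(buf, __config__=np.frombuffer(
            json.dumps(self.cfg.to_dict()).encode(), dtype=np.uint8),
            **self.state_arrays())
        Path(path).write_bytes(buf.getvalue())

    @classmethod
    def load(cls, path: str | Path) -> "DistogramNetwork":
        with np.load(path) as data:
            cfg = NetworkConfig.from_dict(
                json.loads(bytes(data["__config__"]).decode()))
            model = cls(cfg)
            model.load_state_arrays({k: data[k] for k in data.files
                                     if k != "__config__"})
        return model


def build_model(cfg: NetworkConfig) -> DistogramNetwork:
    return DistogramNetwork(cfg)


def forward(model: DistogramNetwork, x: np.ndarray,
            origin: tuple[int, int] = (0, 0)) -> CropPrediction:
    return model.predict_crop(x, origin)


def receptive_field(cfg: NetworkConfig) -> int:
    """Analytic receptive field: each 3x3 convolution at dilation d widens
    the field by 2d; 1x1 layers add nothing."""
    return 1 + 2 * sum(cfg.block_dilation(k) for k in range(cfg.n_blocks))


def expected_param_count(cfg: NetworkConfig) -> int:
    """Closed-form parameter count for a configuration (weights + biases +
    BatchNorm affine pairs, skip projections included)."""
    def conv(cin, cout, k):
        return cout * cin * k * k + cout

    def bn(ch):
        return 2 * ch

    total = bn(cfg.in_channels) + conv(cfg.in_channels, cfg.block_width(0), 1)
    in_ch = cfg.block_width(0)
    for k in range(cfg.n_blocks):
        out_ch = cfg.block_width(k)
        mid = max(out_ch // 2, 1)
        total += bn(in_ch) + conv(in_ch, mid, 1)
        total += bn(mid) + conv(mid, mid, 3)
        total += bn(mid) + conv(mid, out_ch, 1)
        if in_ch != out_ch:
            total += conv(in_ch, out_ch, 1)
        in_ch = out_ch
    final = cfg.block_width(cfg.n_blocks - 1)
    total += bn(final)
    total += conv(final, N_DIST_CLASSES, 1)
    for size in AUX_HEAD_SIZES.values():
        total += 2 * (size * final * cfg.crop_size + size)
    return total
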