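"""The 3D nested U-Net voxel classifier.

The network is a grid of convolution-block nodes X(i, j), i = pyramid
level (0 = full resolution), j = position along the skip pathway, with
0 <= i + j <= depth.  Encoder nodes X(i, 0) follow 2x max pooling of
X(i-1, 0); every nested node X(i, j) consumes the concatenation of all
shallower same-level nodes X(i, 0..j-1) with the 2x trilinearly upsampled
deeper node X(i+1, j-1) -- the dense skip pathways that distinguish the
nested variant from a plain U-Net.  The top-level decoder outputs
X(0, 1..depth) are concatenated and a 1x1x1 convolution maps them to three
class channels (helix, sheet, coil probability after softmax).  The model
is fully convolutional: any input whose spatial dims are divisible by
2^depth yields an output of identical spatial size.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass

import numpy as np

from .nn import Conv3d, ConvBlock, MaxPool3d, Param, Upsample3d, softmax_channels

N_CLASSES = 3


class ConfigError(ValueError):
    pass


@dataclass
class ModelConfig:
    """Architecture hyperparameters.

    depth : number of downsamplings L (default 4).
    channels : L+1 channel counts, shallow to deep (default doubling 16..256).
    deep_supervision_heads : add auxiliary 1x1x1 heads on each X(0, j).
    """

    depth: int = 4
    channels: tuple[int, ...] = (16, 32, 64, 128, 256)
    n_classes: int = N_CLASSES
    deep_supervision_heads: bool = False

    def __post_init__(self) -> None:
        self.channels = tuple(int(c) for c in self.channels)
        if len(self.channels) != self.depth + 1:
            raise ConfigError(
                f"channels must have depth+1={self.depth + 1} entries, "
                f"got {len(self.channels)}"
            )
        if any(c < 1 for c in self.channels):
            raise ConfigError(f"channels must be >= 1, got {self.channels}")
        if self.depth < 1:
            raise ConfigError("depth must be >= 1")

    def to_dict(self) -> dict:
        return {
            "depth": self.depth,
            "channels": list(self.channels),
            "n_classes": self.n_classes,
            "deep_supervision_heads": self.deep_supervision_heads,
        }


class ShapeError(ValueError):
    pass


class VoxelClassifier:
    """Nested U-Net over density chunks; see module docstring.

    Use :func:`build_model` for seeded construction.
    """

    def __init__(self, config: ModelConfig, rng: np.random.Generator,
                 dtype=np.float32):
        self.config = config
        self.dtype = dtype
        L = config.depth
        ch = config.channels
        self.blocks: dict[tuple[int, int], ConvBlock] = {}
        for i in range(L + 1):
            cin = 1 if i == 0 else ch[i - 1]
            self.blocks[(i, 0)] = ConvBlock(cin, ch[i], rng, dtype)
        for j in range(1, L + 1):
            for i in range(0, L - j + 1):
                cin = j * ch[i] + ch[i + 1]
                self.blocks[(i, j)] = ConvBlock(cin, ch[i], rng, dtype)
        self.head = Conv3d(L * ch[0], config.n_classes, 1, rng, dtype)
        self.aux_heads: dict[int, Conv3d] = {}
        if config.deep_supervision_heads:
            for j in range(1, L + 1):
                self.aux_heads[j] = Conv3d(ch[0], config.n_classes, 1, rng, dtype)
        self.pools = {i: MaxPool3d() for i in range(1, L + 1)}
        self.ups = {key: Upsample3d() for key in self.blocks if key[1] >= 1}

    # -- parameters ---------------------------------------------------------
    def params(self) -> list[Param]:
        out = []
        for key in sorted(self.blocks):
            out.extend(self.blocks[key].params())
        out.extend(self.head.params())
        for j in sorted(self.aux_heads):
            out.extend(self.aux_heads[j].params())
        return out

    def n_parameters(self) -> int:
        return int(sum(p.data.size for p in self.params()))

    def zero_grad(self) -> None:
        for p in self.params():
            p.grad[...] = 0.0

    # -- forward / backward -------------------------------------------------
    def _check_dims(self, shape: tuple[int, ...]) -> None:
        step = 2**self.config.depth
        for axis, d in enumerate(shape):
            if d % step:
                raise ShapeError(
                    f"axis {axis} has size {d}, not divisible by 2^depth={step}"
                )

    def forward_logits(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        """Logits (N, n_classes, D, H, W) for input (N, 1, D, H, W)."""
        self._check_dims(x.shape[2:])
        L = self.config.depth
        outs: dict[tuple[int, int], np.ndarray] = {}
        outs[(0, 0)] = self.blocks[(0, 0)].forward(x, training)
        for i in range(1, L + 1):
            pooled = self.pools[i].forward(outs[(i - 1, 0)])
            outs[(i, 0)] = self.blocks[(i, 0)].forward(pooled, training)
        for j in range(1, L + 1):
            for i in range(0, L - j + 1):
                up = self.ups[(i, j)].forward(outs[(i + 1, j - 1)])
                cat = np.concatenate(
                    [outs[(i, jj)] for jj in range(j)] + [up], axis=1
                )
                outs[(i, j)] = self.blocks[(i, j)].forward(cat, training)
        head_in = np.concatenate([outs[(0, j)] for j in range(1, L + 1)], axis=1)
        self._outs = outs
        return self.head.forward(head_in)

    def forward_aux_logits(self) -> dict[int, np.ndarray]:
        """Auxiliary head logits from the last forward pass (deep supervision)."""
        return {
            j: head.forward(self._outs[(0, j)]) for j, head in self.aux_heads.items()
        }

    def backward(self, dlogits: np.ndarray,
                 d_aux: dict[int, np.ndarray] | None = None) -> None:
        """Accumulate parameter gradients from the loss gradient on logits."""
        L = self.config.depth
        ch = self.config.channels
        dhead_in = self.head.backward(dlogits)
        grads: dict[tuple[int, int], np.ndarray] = {}
        for j in range(1, L + 1):
            g = dhead_in[:, (j - 1) * ch[0] : j * ch[0]]
            grads[(0, j)] = np.ascontiguousarray(g)
        if d_aux:
            for j, g_aux in d_aux.items():
                grads[(0, j)] = grads[(0, j)] + self.aux_heads[j].backward(g_aux)
        for j in range(L, 0, -1):
            for i in range(L - j, -1, -1):
                dcat = self.blocks[(i, j)].backward(grads.pop((i, j)))
                off = 0
                for jj in range(j):
                    piece = np.ascontiguousarray(dcat[:, off : off + ch[i]])
                    if (i, jj) in grads:
                        grads[(i, jj)] = grads[(i, jj)] + piece
                    else:
                        grads[(i, jj)] = piece
                    off += ch[i]
                dup = self.ups[(i, j)].backward(
                    np.ascontiguousarray(dcat[:, off:])
                )
                key = (i + 1, j - 1)
                grads[key] = grads[key] + dup if key in grads else dup
        for i in range(L, 0, -1):
            dpooled = self.blocks[(i, 0)].backward(grads.pop((i, 0)))
            dprev = self.pools[i].backward(dpooled)
            key = (i - 1, 0)
            grads[key] = grads[key] + dprev if key in grads else dprev
        self.blocks[(0, 0)].backward(grads.pop((0, 0)))

    def batchnorms(self):
        for key in sorted(self.blocks):
            blk = self.blocks[key]
            yield blk.bn1
            yield blk.bn2

    # -- batchnorm buffers (not trained, but part of a checkpoint) ---------
    def _bn_buffers(self) -> dict[str, np.ndarray]:
        out = {}
        for key in sorted(self.blocks):
            blk = self.blocks[key]
            tag = f"block{key[0]}_{key[1]}"
            for name, bn in (("bn1", blk.bn1), ("bn2", blk.bn2)):
                out[f"{tag}.{name}.running_mean"] = bn.running_mean
                out[f"{tag}.{name}.running_var"] = bn.running_var
        return out


def calibrate_batchnorm(
    model: VoxelClassifier, density_batches: list[np.ndarray]
) -> None:
    """Recompute batch-norm running statistics as the exact average of the
    batch statistics over the given chunk batches (each (N, D, H, W)).

    Exponential running averages lag badly when only a handful of optimizer
    steps separate large weight updates, which makes eval-mode inference
    inconsistent with training; averaging fresh statistics over a fixed
    sample of training chunks removes that lag.
    """
    for bn in model.batchnorms():
        bn.begin_calibration()
    try:
        for batch in density_batches:
            x = np.asarray(batch, dtype=model.dtype)[:, None]
            model.forward_logits(x, training=True)
    finally:
        for bn in model.batchnorms():
            bn.end_calibration()


def build_model(config: ModelConfig, seed: int, dtype=np.float32) -> VoxelClassifier:
    """Deterministically initialized classifier (same seed, same weights)."""
    rng = np.random.default_rng(seed)
    return VoxelClassifier(config, rng, dtype)


def forward(model: VoxelClassifier, density: np.ndarray) -> np.ndarray:
    """Per-voxel class probabilities (n_classes, D, H, W) for one chunk.

    ``density`` is a 3D array (typically 40^3, values in [0, 1]); any shape
    with axes divisible by 2^depth works.  Channels sum to 1 per voxel.
    """
    x = np.asarray(density, dtype=model.dtype)[None, None]
    logits = model.forward_logits(x, training=False)
    return softmax_channels(logits)[0]


def forward_batch(model: VoxelClassifier, densities: np.ndarray) -> np.ndarray:
    """Probabilities (N, n_classes, D, H, W) for a batch of chunks."""
    x = np.asarray(densities, dtype=model.dtype)[:, None]
    return softmax_channels(model.forward_logits(x, training=False))


CHECKPOINT_FORMAT = "cryoss-checkpoint-1"


def save_checkpoint(model: VoxelClassifier, path: str | os.PathLike) -> None:
    """Parameter archive (.npz) with the embedded config and format tag."""
    arrays = {f"param_{i}": p.data for i, p in enumerate(model.params())}
    arrays.update(model._bn_buffers())
    meta = json.dumps({"format": CHECKPOINT_FORMAT, "config": model.config.to_dict()})
    np.savez(os.fspath(path), __meta__=np.frombuffer(meta.encode(), dtype=np.uint8),
             **arrays)


def load_checkpoint(path: str | os.PathLike) -> VoxelClassifier:
    with np.load(os.fspath(path)) as data:
        meta = json.loads(bytes(data["__meta__"]).decode())
        if meta.get("format") != CHECKPOINT_FORMAT:
            raise ValueError(f"not a recognized checkpoint: {path!r}")
        cfg_d = meta["config"]
        config = ModelConfig(
            depth=cfg_d["depth"],
            channels=tuple(cfg_d["channels"]),
            n_classes=cfg_d["n_classes"],
            deep_supervision_heads=cfg_d["deep_supervision_heads"],
        )
        model = build_model(config, seed=0)
        for i, p in enumerate(model.params()):
            p.data = data[f"param_{i}"].copy()
            p.grad = np.zeros_like(p.data)
        buffers = model._bn_buffers()
        for name, arr in buffers.items():
            arr[...] = data[name]
    return model


def clone_parameters(model: VoxelClassifier) -> list[np.ndarray]:
    return [p.data.copy() for p in model.params()] + [
        b.copy() for b in model._bn_buffers().values()
    ]


def restore_parameters(model: VoxelClassifier, snapshot: list[np.ndarray]) -> None:
    params = model.params()
    for p, saved in zip(params, snapshot):
        p.data = saved.copy()
    for buf, saved in zip(model._bn_buffers().values(), snapshot[len(params):]):
        buf[...] = saved
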