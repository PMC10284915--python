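"""Dual-encoder / dual-decoder 2D translation network.

Two structurally identical U-Net-style contracting paths (separate weights)
consume the primary inputs (the three Z-scored global-regression maps:
beta0, beta1, BAT) and the supplementary inputs (the per-ROI residual
correlation maps).  Their bottleneck representations are concatenated and
fed to two identical expanding paths — one synthesizing the CVR map, one
the BAT map — each ending in a 1x1 convolution and a 5*tanh head that
bounds the output to [-5, 5], the range of the clipped hypercapnic labels.

Each encoder block is conv-ReLU-BN-conv-ReLU-BN followed by 2x2 max pooling
(channels double, spatial dims halve); the deepest block skips the pooling
and acts as the bottleneck, so the four up-sampling decoder blocks restore
the input resolution exactly.  Skip connections are taken from the primary
encoder (from the supplementary encoder when the primary is ablated).
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np

from ..core import ConfigurationError
from .layers import (DTYPE, BatchNorm2d, Conv2d, ConvTranspose2d, Layer,
                     MaxPool2d, Param, ReLU, ScaledTanh, Sequential)


@dataclass(frozen=True)
class NetworkConfig:
    primary_in_channels: int = 3
    supplementary_in_channels: int = 133
    base_channels: int = 32
    depth: int = 5                    # encoder blocks
    decoder_blocks: int = 4           # = number of down-samplings
    output_activation_scale: float = 5.0
    use_primary_encoder: bool = True
    use_supplementary_encoder: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.depth != self.decoder_blocks + 1:
            raise ConfigurationError(
                f"depth ({self.depth}) must equal decoder_blocks + 1 "
                f"({self.decoder_blocks + 1})"
            )
        if not (self.use_primary_encoder or self.use_supplementary_encoder):
            raise ConfigurationError("at least one encoder must be enabled")

    @property
    def n_encoders(self) -> int:
        return int(self.use_primary_encoder) + int(self.use_supplementary_encoder)


def _conv_pair(in_ch: int, out_ch: int, rng: np.random.Generator) -> Sequential:
    return Sequential([
        Conv2d(in_ch, out_ch, 3, rng), ReLU(), BatchNorm2d(out_ch),
        Conv2d(out_ch, out_ch, 3, rng), ReLU(), BatchNorm2d(out_ch),
    ])


class EncoderBlock:
    def __init__(self, in_ch: int, out_ch: int, pool: bool,
                 rng: np.random.Generator):
        self.convs = _conv_pair(in_ch, out_ch, rng)
        self.pool = MaxPool2d() if pool else None

    def params(self) -> list[Param]:
        return self.convs.params()

    def forward(self, x: np.ndarray, training: bool) -> tuple[np.ndarray, np.ndarray]:
        feat = self.convs.forward(x, training)
        out = self.pool.forward(feat, training) if self.pool else feat
        return out, feat

    def backward(self, grad_out: np.ndarray,
                 grad_skip: np.ndarray | None) -> np.ndarray:
        g = self.pool.backward(grad_out) if self.pool else grad_out
        if grad_skip is not None:
            g = g + grad_skip
        return self.convs.backward(g)


class Encoder:
    """depth blocks; pooling after all but the last (bottleneck) block."""

    def __init__(self, in_ch: int, base: int, depth: int,
                 rng: np.random.Generator):
        self.blocks = []
        ch_in = in_ch
        for i in range(depth):
            ch_out = base * 2 ** i
            self.blocks.append(EncoderBlock(ch_in, ch_out, pool=i < depth - 1,
                                            rng=rng))
            ch_in = ch_out

    def params(self) -> list[Param]:
        return [p for b in self.blocks for p in b.params()]

    def forward(self, x: np.ndarray, training: bool) -> tuple[np.ndarray, list[np.ndarray]]:
        skips = []
        for i, block in enumerate(self.blocks):
            x, feat = block.forward(x, training)
            if block.pool is not None:
                skips.append(feat)
        return x, skips

    def backward(self, grad_bottleneck: np.ndarray,
                 skip_grads: list[np.ndarray] | None) -> np.ndarray:
        g = self.blocks[-1].backward(grad_bottleneck, None)
        for i in range(len(self.blocks) - 2, -1, -1):
            gs = skip_grads[i] if skip_grads is not None else None
            g = self.blocks[i].backward(g, gs)
        return g


class DecoderBlock:
    """Transpose conv, concatenate skip, then conv-ReLU-BN twice."""

    def __init__(self, in_ch: int, out_ch: int, skip_ch: int,
                 rng: np.random.Generator):
        self.up = ConvTranspose2d(in_ch, out_ch, rng)
        self.convs = _conv_pair(out_ch + skip_ch, out_ch, rng)
        self._split = out_ch

    def params(self) -> list[Param]:
        return self.up.params() + self.convs.params()

    def forward(self, x: np.ndarray, skip: np.ndarray,
                training: bool) -> np.ndarray:
        u = self.up.forward(x, training)
        cat = np.concatenate([u, skip], axis=1)
        return self.convs.forward(cat, training)

    def backward(self, grad: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        gcat = self.convs.backward(grad)
        gu, gskip = gcat[:, :self._split], gcat[:, self._split:]
        return self.up.backward(np.ascontiguousarray(gu)), gskip


class Decoder:
    def __init__(self, fused_ch: int, base: int, n_blocks: int, scale: float,
                 rng: np.random.Generator):
        self.blocks = []
        ch_in = fused_ch
        for j in range(1, n_blocks + 1):
            ch_out = base * 2 ** (n_blocks - j)
            self.blocks.append(DecoderBlock(ch_in, ch_out, skip_ch=ch_out,
                                            rng=rng))
            ch_in = ch_out
        self.head = Sequential([Conv2d(ch_in, 1, 1, rng), ScaledTanh(scale)])

    def params(self) -> list[Param]:
        return [p for b in self.blocks for p in b.params()] + self.head.params()

    def forward(self, x: np.ndarray, skips: list[np.ndarray],
                training: bool) -> np.ndarray:
        for j, block in enumerate(self.blocks):
            x = block.forward(x, skips[-(j + 1)], training)
        return self.head.forward(x, training)

    def backward(self, grad: np.ndarray) -> tuple[np.ndarray, list[np.ndarray]]:
        g = self.head.backward(grad)
        skip_grads: list[np.ndarray] = [None] * len(self.blocks)  # type: ignore
        for j in range(len(self.blocks) - 1, -1, -1):
            g, gskip = self.blocks[j].backward(g)
            skip_grads[len(self.blocks) - 1 - j] = gskip
        return g, skip_grads


class DualEncoderDecoder:
    """The full network.  ``forward`` returns a (B, 2, H, W) stack with
    channel 0 = CVR and channel 1 = BAT, both bounded by the tanh head."""

    def __init__(self, config: NetworkConfig):
        self.config = config
        rng = np.random.default_rng(config.seed)
        base, depth = config.base_channels, config.depth
        self.primary = (Encoder(config.primary_in_channels, base, depth, rng)
                        if config.use_primary_encoder else None)
        self.supplementary = (
            Encoder(config.supplementary_in_channels, base, depth, rng)
            if config.use_supplementary_encoder else None)
        bottleneck_ch = base * 2 ** (depth - 1)
        fused_ch = bottleneck_ch * config.n_encoders
        self.decoders = {
            name: Decoder(fused_ch, base, config.decoder_blocks,
                          config.output_activation_scale, rng)
            for name in ("cvr", "bat")
        }
        self._bottleneck_ch = bottleneck_ch

    # -- parameters ------------------------------------------------------
    def params(self) -> list[Param]:
        out = []
        for enc in (self.primary, self.supplementary):
            if enc is not None:
                out.extend(enc.params())
        for dec in self.decoders.values():
            out.extend(dec.params())
        return out

    def n_parameters(self) -> int:
        return sum(p.size for p in self.params())

    def zero_grad(self) -> None:
        for p in self.params():
            p.grad[:] = 0

    # -- forward / backward ---------------------------------------------
    def _check_dims(self, x: np.ndarray) -> None:
        m = 2 ** self.config.decoder_blocks
        if x.shape[2] % m or x.shape[3] % m:
            raise ConfigurationError(
                f"in-plane dims {x.shape[2:]} must divide by {m}; "
                "pad inputs with preprocess.pad_volume first"
            )

    def forward(self, primary_x: np.ndarray | None,
                supp_x: np.ndarray | None, training: bool = False) -> np.ndarray:
        bottlenecks, skips = [], None
        if self.primary is not None:
            x = np.ascontiguousarray(primary_x, dtype=DTYPE)
            self._check_dims(x)
            b, s = self.primary.forward(x, training)
            bottlenecks.append(b)
            skips = s
        if self.supplementary is not None:
            x = np.ascontiguousarray(supp_x, dtype=DTYPE)
            self._check_dims(x)
            b, s = self.supplementary.forward(x, training)
            bottlenecks.append(b)
            if skips is None:  # primary ablated: skips from supplementary
                skips = s
        fused = (np.concatenate(bottlenecks, axis=1)
                 if len(bottlenecks) > 1 else bottlenecks[0])
        outs = [self.decoders[name].forward(fused, skips, training)
                for name in ("cvr", "bat")]
        return np.concatenate(outs, axis=1)

    def backward(self, grad: np.ndarray) -> None:
        """Accumulate parameter gradients from d(loss)/d(output)."""
        fused_grad = None
        skip_grads = None
        for ch, name in enumerate(("cvr", "bat")):
            g = np.ascontiguousarray(grad[:, ch:ch + 1], dtype=DTYPE)
            gf, gs = self.decoders[name].backward(g)
            fused_grad = gf if fused_grad is None else fused_grad + gf
            if skip_grads is None:
                skip_grads = gs
            else:
                skip_grads = [a + b for a, b in zip(skip_grads, gs)]
        skip_list = skip_grads  # ordered shallow-first, as the encoder expects
        nb = self._bottleneck_ch
        idx = 0
        if self.primary is not None:
            self.primary.backward(
                np.ascontiguousarray(fused_grad[:, idx * nb:(idx + 1) * nb]),
                skip_list)
            idx += 1
            skip_list = None  # supplementary got no skip wiring
        if self.supplementary is not None:
            self.supplementary.backward(
                np.ascontiguousarray(fused_grad[:, idx * nb:(idx + 1) * nb]),
                skip_list)

    def predict(self, primary_x: np.ndarray | None,
                supp_x: np.ndarray | None) -> np.ndarray:
        return self.forward(primary_x, supp_x, training=False)

    # -- persistence -----------------------------------------------------
    def save(self, path: str | Path) -> None:
        path = Path(path)
        arrays = {f"p{i}": p.value for i, p in enumerate(self.params())}
        bn_state = {}
        for i, bn in enumerate(self._batchnorms()):
            bn_state[f"bn{i}_mean"] = bn.running_mean
            bn_state[f"bn{i}_var"] = bn.running_var
        np.savez(path, **arrays, **bn_state)
        sidecar = path.with_suffix(path.suffix + ".json")
        sidecar.write_text(json.dumps(asdict(self.config), indent=2))

    def _batchnorms(self) -> list[BatchNorm2d]:
        found = []

        def walk(obj):
            if isinstance(obj, BatchNorm2d):
                found.append(obj)
            elif isinstance(obj, Sequential):
                for layer in obj.layers:
                    walk(layer)
            elif isinstance(obj, (EncoderBlock,)):
                walk(obj.convs)
            elif isinstance(obj, DecoderBlock):
                walk(obj.convs)
            elif isinstance(obj, Encoder):
                for b in obj.blocks:
                    walk(b)
            elif isinstance(obj, Decoder):
                for b in obj.blocks:
                    walk(b)
                walk(obj.head)

        for enc in (self.primary, self.supplementary):
            if enc is not None:
                walk(enc)
        for dec in self.decoders.values():
            walk(dec)
        return found

    @classmethod
    def load(cls, path: str | Path) -> "DualEncoderDecoder":
        path = Path(path)
        sidecar = path.with_suffix(path.suffix + ".json")
        config = NetworkConfig(**json.loads(sidecar.read_text()))
        model = cls(config)
        data = np.load(path)
        for i, p in enumerate(model.params()):
            p.value = data[f"p{i}"].astype(DTYPE)
        for i, bn in enumerate(model._batchnorms()):
            bn.running_mean = data[f"bn{i}_mean"].astype(DTYPE)
            bn.running_var = data[f"bn{i}_var"].astype(DTYPE)
        return model


def build_model(config: NetworkConfig) -> DualEncoderDecoder:
    """Instantiate the network with seeded weight initialization."""
    return DualEncoderDecoder(config)
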