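"""Residual SELU encoder-decoder for 3D muscle segmentation.

The topology is a U-Net/V-Net hybrid: an initial block, three
down-sampling blocks, a bottom block, three mirrored up-sampling blocks
and a final head, every block carrying a residual connection from its
input to its output and long skip connections joining contraction and
expansion at equal resolution.  Four stride-2 resamplings mean every
spatial input dimension must be divisible by 16.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple

import numpy as np

from ..core import MuscleCrop, MuscleMask
from .layers import Adam, Conv3d, ConvStack, DownConv, SELU, Sigmoid, UpConv


@dataclass
class NetworkSpec:
    """Architecture hyper-parameters.

    Defaults reproduce the published topology: initial 5x5x5 conv with 8
    filters and a stride-2 stem to 16, down blocks (2,32), (3,64),
    (3,128), a (3,128) bottom block, mirrored up blocks and a 16-filter
    final block ending in a 1x1x1 conv + sigmoid.  ``width_multiplier``
    scales every channel count so the identical topology runs at desk
    scale on a CPU.
    """

    init_filters: int = 8
    stem_filters: int = 16
    down_blocks: Sequence[Tuple[int, int]] = ((2, 32), (3, 64), (3, 128))
    bottleneck: Tuple[int, int] = (3, 128)
    final_filters: int = 16
    conv_kernel: int = 5
    width_multiplier: float = 1.0
    skip_mode: str = "add"  # "add" or "concat"
    threshold: float = 0.5

    def __post_init__(self):
        if self.skip_mode not in ("add", "concat"):
            raise ValueError("skip_mode must be 'add' or 'concat'")
        if self.conv_kernel % 2 == 0:
            raise ValueError("conv_kernel must be odd")
        if self.width_multiplier <= 0:
            raise ValueError("width_multiplier must be positive")
        if len(self.down_blocks) != 3:
            raise ValueError("expected three down blocks")

    def width(self, c: int) -> int:
        return max(1, int(round(c * self.width_multiplier)))

    @property
    def n_downsamplings(self) -> int:
        return 1 + len(self.down_blocks)

    @property
    def divisor(self) -> int:
        return 2 ** self.n_downsamplings

    def to_dict(self) -> dict:
        return {
            "init_filters": self.init_filters,
            "stem_filters": self.stem_filters,
            "down_blocks": [list(b) for b in self.down_blocks],
            "bottleneck": list(self.bottleneck),
            "final_filters": self.final_filters,
            "conv_kernel": self.conv_kernel,
            "width_multiplier": self.width_multiplier,
            "skip_mode": self.skip_mode,
            "threshold": self.threshold,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "NetworkSpec":
        d = dict(d)
        d["down_blocks"] = tuple(tuple(b) for b in d["down_blocks"])
        d["bottleneck"] = tuple(d["bottleneck"])
        return cls(**d)


class _Merge:
    """Long skip join: element-wise add (with 1x1x1 projection when the
    channel counts differ) or channel concatenation."""

    def __init__(self, mode, c_up, c_skip, rng):
        self.mode = mode
        self.proj = None
        if mode == "add":
            self.c_out = c_up
            if c_skip != c_up:
                self.proj = Conv3d(c_skip, c_up, 1, rng)
        else:
            self.c_out = c_up + c_skip
            self._c_up = c_up

    def params(self):
        return self.proj.params() if self.proj is not None else []

    def forward(self, up, skip):
        if self.mode == "add":
            s = skip if self.proj is None else self.proj.forward(skip)
            return up + s
        return np.concatenate([up, skip], axis=1)

    def backward(self, dy):
        if self.mode == "add":
            dskip = dy if self.proj is None else self.proj.backward(dy)
            return dy, dskip
        return dy[:, : self._c_up], dy[:, self._c_up:]


class SegmentationNet:
    """The assembled network; built via :func:`build_network`."""

    def __init__(self, spec: NetworkSpec, rng: np.random.Generator):
        self.spec = spec
        k = spec.conv_kernel
        w = spec.width

        self.init_stack = ConvStack(1, 1, w(spec.init_filters), k, rng)
        self.stem = DownConv(w(spec.init_filters), w(spec.stem_filters), rng)
        self.stem_act = SELU()

        # encoder
        self.enc_stacks: List[ConvStack] = []
        self.downs: List[DownConv] = []
        self.down_acts: List[SELU] = []
        c = w(spec.stem_filters)
        enc_channels = []
        for i, (n_convs, m) in enumerate(spec.down_blocks):
            stack = ConvStack(n_convs, c, w(m), k, rng)
            enc_channels.append(w(m))
            nxt = (
                w(spec.down_blocks[i + 1][1])
                if i + 1 < len(spec.down_blocks)
                else w(spec.bottleneck[1])
            )
            self.enc_stacks.append(stack)
            self.downs.append(DownConv(w(m), nxt, rng))
            self.down_acts.append(SELU())
            c = nxt

        n_b, m_b = spec.bottleneck
        self.bottom = ConvStack(n_b, c, w(m_b), k, rng)
        c = w(m_b)

        # decoder mirrors the encoder; each transpose conv halves channels
        self.ups: List[UpConv] = []
        self.up_acts: List[SELU] = []
        self.merges: List[_Merge] = []
        self.dec_stacks: List[ConvStack] = []
        for i, (n_convs, m) in enumerate(reversed(spec.down_blocks)):
            c_up = max(1, w(m_b) // 2) if i == 0 else c_up_next
            self.ups.append(UpConv(c, c_up, rng))
            self.up_acts.append(SELU())
            c_skip = enc_channels[len(spec.down_blocks) - 1 - i]
            merge = _Merge(spec.skip_mode, c_up, c_skip, rng)
            self.merges.append(merge)
            self.dec_stacks.append(ConvStack(n_convs, merge.c_out, w(m), k, rng))
            c = w(m)
            c_up_next = max(1, w(m) // 2)

        # final level: up to stem width, merge with the init features
        self.final_up = UpConv(c, w(spec.stem_filters), rng)
        self.final_up_act = SELU()
        self.final_merge = _Merge(
            spec.skip_mode, w(spec.stem_filters), w(spec.init_filters), rng
        )
        self.final_stack = ConvStack(
            1, self.final_merge.c_out, w(spec.final_filters), k, rng
        )
        self.head = Conv3d(w(spec.final_filters), 1, 1, rng)
        self.out_act = Sigmoid()

    # -- plumbing -----------------------------------------------------
    def _layers(self):
        yield self.init_stack
        yield self.stem
        for s, d in zip(self.enc_stacks, self.downs):
            yield s
            yield d
        yield self.bottom
        for u, m, s in zip(self.ups, self.merges, self.dec_stacks):
            yield u
            yield m
            yield s
        yield self.final_up
        yield self.final_merge
        yield self.final_stack
        yield self.head

    def parameters(self):
        out = []
        for layer in self._layers():
            out.extend(layer.params())
        return out

    def check_input_shape(self, shape) -> None:
        d = self.spec.divisor
        if any(s % d for s in shape):
            raise ValueError(
                f"spatial shape {tuple(shape)} not divisible by {d}"
            )

    # -- forward / backward -------------------------------------------
    def forward(self, x: np.ndarray) -> np.ndarray:
        """Map ``(N, 1, D, H, W)`` intensities to probabilities of the
        same shape."""
        self.check_input_shape(x.shape[2:])
        x = np.ascontiguousarray(x, dtype=np.float32)
        f0 = self.init_stack.forward(x)
        h = self.stem_act.forward(self.stem.forward(f0))
        skips = []
        for stack, down, act in zip(self.enc_stacks, self.downs, self.down_acts):
            f = stack.forward(h)
            skips.append(f)
            h = act.forward(down.forward(f))
        h = self.bottom.forward(h)
        self.last_bottleneck_shape = tuple(h.shape[2:])
        for up, act, merge, stack in zip(
            self.ups, self.up_acts, self.merges, self.dec_stacks
        ):
            h = act.forward(up.forward(h))
            h = merge.forward(h, skips.pop())
            h = stack.forward(h)
        h = self.final_up_act.forward(self.final_up.forward(h))
        h = self.final_merge.forward(h, f0)
        h = self.final_stack.forward(h)
        return self.out_act.forward(self.head.forward(h))

    def backward(self, dprob: np.ndarray) -> None:
        dh = self.head.backward(self.out_act.backward(dprob))
        dh = self.final_stack.backward(dh)
        dh, df0 = self.final_merge.backward(dh)
        dh = self.final_up.backward(self.final_up_act.backward(dh))
        dskips = []
        for up, act, merge, stack in zip(
            reversed(self.ups),
            reversed(self.up_acts),
            reversed(self.merges),
            reversed(self.dec_stacks),
        ):
            dh = stack.backward(dh)
            dh, dskip = merge.backward(dh)
            dskips.append(dskip)
            dh = up.backward(act.backward(dh))
        dh = self.bottom.backward(dh)
        for stack, down, act, dskip in zip(
            reversed(self.enc_stacks),
            reversed(self.downs),
            reversed(self.down_acts),
            reversed(dskips),
        ):
            dh = down.backward(act.backward(dh))
            dh = stack.backward(dh + dskip)
        df0 = df0 + self.stem.backward(self.stem_act.backward(dh))
        self.init_stack.backward(df0)

    # -- (de)serialization --------------------------------------------
    def get_weights(self) -> List[np.ndarray]:
        return [p.copy() for p, _ in self.parameters()]

    def set_weights(self, weights: Sequence[np.ndarray]) -> None:
        params = self.parameters()
        if len(weights) != len(params):
            raise ValueError("weight list length mismatch")
        for (p, _), w_new in zip(params, weights):
            if p.shape != w_new.shape:
                raise ValueError("weight shape mismatch")
            p[...] = w_new


def build_network(spec: NetworkSpec, seed: int = 0) -> SegmentationNet:
    """Construct the network with SELU-appropriate (fan-in) init."""
    return SegmentationNet(spec, np.random.default_rng(seed))


def count_parameters(net: SegmentationNet) -> int:
    """Total number of trainable scalars."""
    return int(sum(p.size for p, _ in net.parameters()))


def predict_probabilities(net: SegmentationNet, intensities: np.ndarray) -> np.ndarray:
    x = np.asarray(intensities, dtype=np.float32)[None, None]
    return net.forward(x)[0, 0]


def predict_mask(
    net: SegmentationNet, crop: MuscleCrop, threshold: float = 0.5
):
    """Segment one crop; returns ``(MuscleMask, probability field)``.

    The mask lives in crop coordinates; ``crop.source_offset`` (carried
    by the caller) re-embeds it into the parent volume.
    """
    probs = predict_probabilities(net, crop.intensities)
    mask = MuscleMask((probs >= threshold).astype(np.uint8), crop.voxel_mm)
    return mask, probs


def save_weights(net: SegmentationNet, path) -> None:
    """Checkpoint as .npz with a JSON architecture sidecar."""
    import json
    from pathlib import Path

    path = Path(path)
    np.savez(path, *[p for p, _ in net.parameters()])
    sidecar = path.with_suffix(".json")
    sidecar.write_text(json.dumps(net.spec.to_dict(), indent=2))


def load_weights(path) -> SegmentationNet:
    import json
    from pathlib import Path

    path = Path(path)
    spec = NetworkSpec.from_dict(json.loads(path.with_suffix(".json").read_text()))
    net = build_network(spec)
    with np.load(path if path.suffix == ".npz" else f"{path}.npz") as data:
        net.set_weights([data[k] for k in data.files])
    return net
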