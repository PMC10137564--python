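"""Residual-encoder U-Net for heart/lung semantic segmentation.

The architecture follows the AlbuNet-34 shape: a ResNet-34-style encoder
(stem + four residual stages with block counts 3/4/6/3) whose stage-4
output is max-pooled once more, so the input is downsampled six times and
the bottleneck feature map is 1/64 of the input resolution.  The decoder
upsamples six times with U-Net concatenation skip connections
(nearest-neighbour upsample + 3x3 convolution per block), and the head is
a 3x3 convolution with one filter per class followed by a per-pixel
softmax, giving mutually exclusive background/lung/heart probabilities.

``base_width`` scales every channel count, so the same architecture runs
at desk scale (e.g. 64x64 input, base_width 8) on a single CPU.  Grayscale
input is replicated to three channels so externally pretrained encoder
weights remain loadable; pretraining itself is out of scope and the
default initialisation is He-normal from a seeded generator.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from . import nn
from .errors import ConfigurationError


@dataclass(frozen=True)
class ModelConfig:
    n_classes: int = 3
    input_size_px: int = 512
    encoder_depth: tuple = (3, 4, 6, 3)
    base_width: int = 64
    extra_pool: bool = True
    skip_mode: str = "concatenate"

    def __post_init__(self):
        if self.n_classes < 2:
            raise ConfigurationError("n_classes must be >= 2")
        if self.skip_mode != "concatenate":
            raise ConfigurationError("only 'concatenate' skip connections supported")
        if len(self.encoder_depth) != 4 or any(d < 1 for d in self.encoder_depth):
            raise ConfigurationError("encoder_depth must be 4 positive block counts")
        factor = 64 if self.extra_pool else 32
        if self.input_size_px <= 0 or self.input_size_px % factor:
            raise ConfigurationError(
                f"input_size_px must be a positive multiple of {factor} "
                f"(got {self.input_size_px})"
            )

    @property
    def n_downsamplings(self) -> int:
        return 6 if self.extra_pool else 5

    @property
    def bottleneck_size(self) -> int:
        return self.input_size_px // (2 ** self.n_downsamplings)


class _BasicBlock(nn.Layer):
    """Two 3x3 convs with identity (or 1x1-projection) shortcut."""

    def __init__(self, cin, cout, stride, rng):
        self.conv1 = nn.Conv2d(cin, cout, 3, stride=stride, bias=False, rng=rng)
        self.bn1 = nn.BatchNorm2d(cout)
        self.relu1 = nn.ReLU()
        self.conv2 = nn.Conv2d(cout, cout, 3, bias=False, rng=rng)
        self.bn2 = nn.BatchNorm2d(cout)
        self.relu_out = nn.ReLU()
        if stride != 1 or cin != cout:
            self.proj = nn.Conv2d(cin, cout, 1, stride=stride, pad=0, bias=False, rng=rng)
            self.proj_bn = nn.BatchNorm2d(cout)
        else:
            self.proj = self.proj_bn = None

    def _layers(self):
        out = [self.conv1, self.bn1, self.conv2, self.bn2]
        if self.proj is not None:
            out += [self.proj, self.proj_bn]
        return out

    def params(self):
        return [p for l in self._layers() for p in l.params()]

    def buffers(self):
        return [b for l in self._layers() for b in l.buffers()]

    def forward(self, x, train=True):
        h = self.relu1.forward(self.bn1.forward(self.conv1.forward(x, train), train))
        h = self.bn2.forward(self.conv2.forward(h, train), train)
        if self.proj is not None:
            s = self.proj_bn.forward(self.proj.forward(x, train), train)
        else:
            s = x
        return self.relu_out.forward(h + s)

    def backward(self, g):
        g = self.relu_out.backward(g)
        gh = self.bn2.backward(g)
        gh = self.conv2.backward(gh)
        gh = self.relu1.backward(gh)
        gh = self.bn1.backward(gh)
        gx = self.conv1.backward(gh)
        if self.proj is not None:
            gx = gx + self.proj.backward(self.proj_bn.backward(g))
        else:
            gx = gx + g
        return gx


class _ConvBNReLU(nn.Layer):
    def __init__(self, cin, cout, k, stride, rng, pad=None):
        self.conv = nn.Conv2d(cin, cout, k, stride=stride, pad=pad, bias=False, rng=rng)
        self.bn = nn.BatchNorm2d(cout)
        self.relu = nn.ReLU()

    def params(self):
        return self.conv.params() + self.bn.params()

    def buffers(self):
        return self.bn.buffers()

    def forward(self, x, train=True):
        return self.relu.forward(self.bn.forward(self.conv.forward(x, train), train))

    def backward(self, g):
        return self.conv.backward(self.bn.backward(self.relu.backward(g)))


class AlbuNet:
    """Encoder-decoder segmentation network (see module docstring)."""

    def __init__(self, cfg: ModelConfig, seed: int = 0):
        self.cfg = cfg
        rng = np.random.default_rng(seed)
        bw = cfg.base_width
        self.stem = _ConvBNReLU(3, bw, 7, 2, rng)
        self.stem_pool = nn.MaxPool2()

        widths = [bw, 2 * bw, 4 * bw, 8 * bw]
        self.stages: list[list[_BasicBlock]] = []
        cin = bw
        for si, (w, depth) in enumerate(zip(widths, cfg.encoder_depth)):
            blocks = []
            for bi in range(depth):
                stride = 2 if (bi == 0 and si > 0) else 1
                blocks.append(_BasicBlock(cin, w, stride, rng))
                cin = w
            self.stages.append(blocks)
        self.extra_pool = nn.MaxPool2() if cfg.extra_pool else None

        # decoder: one up+conv block per downsampling, skips mirror the
        # encoder widths; the final block has no skip (full resolution)
        skip_ch = [8 * bw, 4 * bw, 2 * bw, bw, bw][: cfg.n_downsamplings - 1] \
            if cfg.extra_pool else [4 * bw, 2 * bw, bw, bw]
        out_ch = ([8 * bw, 4 * bw, 2 * bw, bw, bw] if cfg.extra_pool
                  else [4 * bw, 2 * bw, bw, bw])
        self.dec_ups: list[nn.Upsample2] = []
        self.dec_convs: list[_ConvBNReLU] = []
        self._dec_in_ch: list[int] = []
        self._dec_skip_ch = list(skip_ch)
        cin = 8 * bw
        for sc, oc in zip(skip_ch, out_ch):
            self.dec_ups.append(nn.Upsample2())
            self.dec_convs.append(_ConvBNReLU(cin + sc, oc, 3, 1, rng))
            self._dec_in_ch.append(cin)
            cin = oc
        self.dec_ups.append(nn.Upsample2())
        self.dec_convs.append(_ConvBNReLU(cin, bw, 3, 1, rng))
        self.head = nn.Conv2d(bw, cfg.n_classes, 3, rng=rng)
        self.last_bottleneck_hw: tuple[int, int] | None = None

    # -- plumbing ---------------------------------------------------------
    def _modules(self):
        mods = [self.stem]
        for st in self.stages:
            mods.extend(st)
        mods.extend(self.dec_convs)
        mods.append(self.head)
        return mods

    def params(self) -> list[nn.Param]:
        return [p for m in self._modules() for p in m.params()]

    def n_parameters(self) -> int:
        return int(sum(p.data.size for p in self.params()))

    def buffers(self):
        return [b for m in self._modules() for b in m.buffers()]

    # -- forward/backward -------------------------------------------------
    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        """Input (N, 1 or 3, S, S) -> per-pixel class probabilities."""
        x = np.ascontiguousarray(x, dtype=nn.DTYPE)
        if x.ndim != 4:
            raise ValueError(f"expected NCHW input, got shape {x.shape}")
        if x.shape[2] != self.cfg.input_size_px or x.shape[3] != self.cfg.input_size_px:
            raise ValueError(
                f"input spatial size {x.shape[2:]} does not match configured "
                f"{self.cfg.input_size_px}; resize before forward"
            )
        if x.shape[1] == 1:
            x = np.repeat(x, 3, axis=1)
        h = self.stem.forward(x, train)
        f_stem = h
        h = self.stem_pool.forward(h)
        feats = []
        for st in self.stages:
            for blk in st:
                h = blk.forward(h, train)
            feats.append(h)
        if self.extra_pool is not None:
            h = self.extra_pool.forward(h)
        self.last_bottleneck_hw = h.shape[2:]

        skips = ([feats[3], feats[2], feats[1], feats[0], f_stem]
                 if self.cfg.extra_pool else [feats[2], feats[1], feats[0], f_stem])
        self._n_skips = len(skips)
        for up, conv, skip in zip(self.dec_ups, self.dec_convs, skips):
            h = up.forward(h)
            h = conv.forward(np.concatenate([h, skip], axis=1), train)
        h = self.dec_ups[-1].forward(h)
        h = self.dec_convs[-1].forward(h, train)
        logits = self.head.forward(h, train)
        self._probs = nn.softmax(logits)
        return self._probs

    def backward(self, dprobs: np.ndarray) -> None:
        """Backprop dL/dprobabilities through softmax and the whole net."""
        g = nn.softmax_backward(self._probs, dprobs)
        g = self.head.backward(g)
        g = self.dec_convs[-1].backward(g)
        g = self.dec_ups[-1].backward(g)
        # walk the skip-consuming decoder blocks in reverse; collect the
        # gradient flowing into each skip connection
        skip_grads = {}  # skip index (0 = deepest) -> gradient
        for i in range(len(self._dec_in_ch) - 1, -1, -1):
            g = self.dec_convs[i].backward(g)
            cin = self._dec_in_ch[i]
            skip_grads[i] = g[:, cin:]
            g = self.dec_ups[i].backward(np.ascontiguousarray(g[:, :cin]))
        if self.extra_pool is not None:
            g = self.extra_pool.backward(g)
            g = g + skip_grads.pop(0)  # deepest skip taps the stage-4 output
        # remaining skips (deepest-first) tap stage3, stage2, stage1, stem
        remaining = [skip_grads[i] for i in sorted(skip_grads)]
        for stage_idx in (3, 2, 1, 0):
            for blk in reversed(self.stages[stage_idx]):
                g = blk.backward(g)
            if stage_idx > 0:
                g = g + remaining.pop(0)
        g = self.stem_pool.backward(g)
        g = g + remaining.pop(0)
        self.stem.backward(g)

    # -- checkpointing ----------------------------------------------------
    def get_state(self) -> list[np.ndarray]:
        return [p.data for p in self.params()] + list(self.buffers())

    def set_state(self, arrays: list[np.ndarray]) -> None:
        params = self.params()
        n = len(params)
        if len(arrays) != n + len(self.buffers()):
            raise ConfigurationError("checkpoint state does not match architecture")
        for p, a in zip(params, arrays[:n]):
            if p.data.shape != a.shape:
                raise ConfigurationError(
                    f"checkpoint shape {a.shape} != model shape {p.data.shape}"
                )
            p.data[...] = a
        # buffers live inside BN layers; re-distribute in order
        bufs = arrays[n:]
        i = 0
        for m in self._modules():
            own = m.buffers()
            if own:
                m.set_buffers(bufs[i:i + len(own)])
                i += len(own)


def build_model(cfg: ModelConfig, seed: int = 0) -> AlbuNet:
    """Construct the network with He-normal initialisation from ``seed``."""
    return AlbuNet(cfg, seed=seed)


def save_checkpoint(model: AlbuNet, path, training_meta: dict | None = None) -> Path:
    """Serialise weights + config + training metadata into one .npz file."""
    path = Path(path)
    if path.suffix != ".npz":
        path = path.with_suffix(path.suffix + ".npz")
    np.savez(
        path,
        *model.get_state(),
        _config=np.frombuffer(
            json.dumps(asdict(model.cfg)).encode(), dtype=np.uint8
        ),
        _meta=np.frombuffer(
            json.dumps(dict(training_meta or {})).encode(), dtype=np.uint8
        ),
    )
    return path


def load_checkpoint(path) -> tuple[AlbuNet, dict]:
    """Rebuild a model from a checkpoint; forward outputs are reproduced."""
    with np.load(Path(path)) as z:
        cfg_d = json.loads(bytes(z["_config"]).decode())
        meta = json.loads(bytes(z["_meta"]).decode())
        cfg_d["encoder_depth"] = tuple(cfg_d["encoder_depth"])
        cfg = ModelConfig(**cfg_d)
        arrays = [z[f"arr_{i}"] for i in range(len(z.files) - 2)]
    model = AlbuNet(cfg, seed=0)
    model.set_state(arrays)
    return model, meta
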