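"""Asymmetric encoder-decoder with feature-global-delivery channel gating.

The network maps a ``2N x 2N x 3`` patch to an ``N x N`` nucleus-probability
map.  It has *no* skip concatenations between encoder and decoder.  Instead,
every level carries a per-channel state vector ``S_l`` (the feature-global
delivery connection, FGDC) computed from two sigmoid branches:

    AP_l = spatial mean of the level's input features, per channel
    i_l  = sigmoid(1x1 conv of AP_l)                # local-layer information
    g_l  = sigmoid(1x1 conv of S_{l-1})             # gate from previous layer
    S_l  = g_l * i_l                                # elementwise, in (0,1)

The gate's output width follows the channel ladder: 2*C_{l-1} on the encoding
path (channels double per level) and C_{l-1}/2 on the decoding path (channels
halve).  The first level has no predecessor; there ``S_1 = i_1``.

Each level applies gated residual blocks:

    F_hat = K2 * ReLU(K1 * F + b1) + b2
    F_out = ReLU(F_hat * S + F)          # S broadcast over space

so the residual branch is scaled per channel by the delivery state before the
identity addition.  Levels are connected by 2x2 max-pooling plus a 1x1
channel-doubling convolution (encoder) and 2x2 stride-2 transposed
convolutions (decoder).  The head is a 1x1 convolution + sigmoid at full
2N x 2N resolution, center-cropped to N x N: only the central region is ever
supervised, which widens the receptive field around the labeled area.
"""

from __future__ import annotations

import dataclasses
import io as _io
import json
from pathlib import Path
from typing import List, Optional, Tuple

import numpy as np

from . import nn

__all__ = [
    "NetworkConfig",
    "FGDCNet",
    "channel_average_pool",
    "layer_input_info",
    "gate_from_previous",
    "fgdc_state",
    "resblock_apply",
]

PIPELINE_VERSION = "nucseg-0.1.0"


# ---------------------------------------------------------------------------
# Functional forms of the gating arithmetic (used directly by tests and docs;
# the layer classes below implement the same math with backward passes).
# ---------------------------------------------------------------------------

def _sigmoid(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-x))


def channel_average_pool(feature_map: np.ndarray) -> np.ndarray:
    """Per-channel spatial mean of an (H, W, C) or (B, H, W, C) feature map."""
    feature_map = np.asarray(feature_map)
    if feature_map.ndim == 3:
        return feature_map.mean(axis=(0, 1))
    if feature_map.ndim == 4:
        return feature_map.mean(axis=(1, 2))
    raise ValueError(f"expected 3-D or 4-D feature map, got shape {feature_map.shape}")


def layer_input_info(ap: np.ndarray, weight: np.ndarray, bias: np.ndarray) -> np.ndarray:
    """i_l = sigmoid(1x1 conv of the pooled channel vector); entries in (0,1)."""
    ap = np.asarray(ap)
    weight = np.asarray(weight)
    if weight.shape[0] != ap.shape[-1]:
        raise ValueError(
            f"info kernel expects {weight.shape[0]} input channels, got {ap.shape[-1]}"
        )
    return _sigmoid(ap @ weight + bias)


def gate_from_previous(
    s_prev: np.ndarray, weight: np.ndarray, bias: np.ndarray, path: str
) -> np.ndarray:
    """g_l = sigmoid(1x1 conv of S_{l-1}); output width 2*C (encoding) or C/2."""
    s_prev = np.asarray(s_prev)
    weight = np.asarray(weight)
    c_prev = s_prev.shape[-1]
    if path == "encoding":
        d = 2 * c_prev
    elif path == "decoding":
        if c_prev % 2:
            raise ValueError(f"decoding gate needs an even channel count, got {c_prev}")
        d = c_prev // 2
    else:
        raise ValueError(f"path must be 'encoding' or 'decoding', got {path!r}")
    if weight.shape != (c_prev, d):
        raise ValueError(
            f"gate kernel for {path} path must map {c_prev} -> {d} channels, "
            f"got weight shape {weight.shape}"
        )
    return _sigmoid(s_prev @ weight + bias)


def fgdc_state(g: np.ndarray, i: np.ndarray) -> np.ndarray:
    """S_l = g_l * i_l elementwise; both factors in (0,1) so S_l is too."""
    g = np.asarray(g)
    i = np.asarray(i)
    if g.shape != i.shape:
        raise ValueError(f"gate/info length mismatch: {g.shape} vs {i.shape}")
    return g * i


def resblock_apply(
    feature_map: np.ndarray,
    state: np.ndarray,
    k1: np.ndarray,
    b1: np.ndarray,
    k2: np.ndarray,
    b2: np.ndarray,
) -> np.ndarray:
    """Functional gated residual block on a single (H, W, C) feature map."""
    x = np.asarray(feature_map)[None]
    a, _ = nn._conv_same(x, k1, b1)
    fhat, _ = nn._conv_same(np.where(a > 0, a, 0), k2, b2)
    out = fhat * np.asarray(state).reshape(1, 1, 1, -1) + x
    return np.where(out > 0, out, 0)[0]


# ---------------------------------------------------------------------------
# Layer classes with backward passes
# ---------------------------------------------------------------------------

class FGDCGate:
    """Produces the channel state S_l from the level input and S_{l-1}."""

    def __init__(
        self,
        c: int,
        c_prev: Optional[int],
        rng: np.random.Generator,
        dtype,
        name: str,
    ) -> None:
        self.info = nn.Dense(c, c, rng, dtype, f"{name}.info")
        self.gate = None if c_prev is None else nn.Dense(c_prev, c, rng, dtype, f"{name}.gate")
        self._cache = None

    def params(self) -> List[nn.Param]:
        ps = self.info.params()
        if self.gate is not None:
            ps += self.gate.params()
        return ps

    def forward(self, f: np.ndarray, s_prev: Optional[np.ndarray]) -> np.ndarray:
        ap = f.mean(axis=(1, 2))
        i = _sigmoid(self.info.forward(ap))
        if self.gate is None:
            g = None
            s = i
        else:
            g = _sigmoid(self.gate.forward(s_prev))
            s = g * i
        self._cache = (f.shape, i, g)
        return s

    def backward(self, ds: np.ndarray) -> Tuple[np.ndarray, Optional[np.ndarray]]:
        fshape, i, g = self._cache
        if self.gate is None:
            di = ds
            ds_prev = None
        else:
            di = ds * g
            dg = ds * i
            ds_prev = self.gate.backward(dg * g * (1.0 - g))
        dap = self.info.backward(di * i * (1.0 - i))
        _, h, w, c = fshape
        df = np.broadcast_to(
            (dap / (h * w))[:, None, None, :], fshape
        ).astype(dap.dtype)
        self._cache = None
        return df, ds_prev


class GatedResBlock:
    """Residual 3x3 conv pair whose residual branch is channel-gated by S_l."""

    def __init__(self, c: int, rng: np.random.Generator, dtype, name: str) -> None:
        self.conv1 = nn.Conv2d(c, c, 3, rng, dtype, f"{name}.conv1")
        self.conv2 = nn.Conv2d(c, c, 3, rng, dtype, f"{name}.conv2")
        self._cache = None

    def params(self) -> List[nn.Param]:
        return self.conv1.params() + self.conv2.params()

    def forward(self, f: np.ndarray, s: np.ndarray) -> np.ndarray:
        a = self.conv1.forward(f)
        r = np.where(a > 0, a, 0)
        fhat = self.conv2.forward(r)
        pre = fhat * s[:, None, None, :] + f
        self._cache = (a > 0, fhat, s, pre > 0)
        return np.where(pre > 0, pre, 0)

    def backward(self, dout: np.ndarray) -> Tuple[np.ndarray, np.ndarray]:
        relu1_mask, fhat, s, relu2_mask = self._cache
        dpre = np.where(relu2_mask, dout, 0)
        dfhat = dpre * s[:, None, None, :]
        ds = (dpre * fhat).sum(axis=(1, 2))
        dr = self.conv2.backward(dfhat)
        da = np.where(relu1_mask, dr, 0)
        df = dpre + self.conv1.backward(da)
        self._cache = None
        return df, ds


@dataclasses.dataclass(frozen=True)
class NetworkConfig:
    """Architecture knobs.

    ``depth`` counts resolution levels (the ablation axis: a 3-level and a
    4-level variant).  Channels follow base * 2^(level-1).  ``label_size`` N
    fixes the 2N input side; 2N must be divisible by 2^(depth-1) so pooling
    stays exact.
    """

    depth: int = 4
    base_channels: int = 32
    label_size: int = 48
    blocks_per_level: int = 2
    seed: int = 0
    dtype: str = "float32"

    def __post_init__(self) -> None:
        if self.depth < 1:
            raise ValueError(f"depth must be >= 1, got {self.depth}")
        if self.label_size % 2:
            raise ValueError(f"label_size must be even, got {self.label_size}")
        side = 2 * self.label_size
        if side % (2 ** (self.depth - 1)):
            raise ValueError(
                f"input side {side} not divisible by 2^(depth-1) = {2 ** (self.depth - 1)}"
            )
        if self.blocks_per_level < 1:
            raise ValueError("blocks_per_level must be >= 1")

    @property
    def np_dtype(self):
        return np.dtype(self.dtype).type


class FGDCNet:
    """The gated no-skip encoder-decoder (see module docstring)."""

    def __init__(self, config: NetworkConfig) -> None:
        self.config = config
        dtype = config.np_dtype
        rng = np.random.default_rng(config.seed)
        d = config.depth
        chans = [config.base_channels * 2 ** l for l in range(d)]

        self.stem = nn.Conv2d(3, chans[0], 3, rng, dtype, "stem")
        self.enc_gates: List[FGDCGate] = []
        self.enc_blocks: List[List[GatedResBlock]] = []
        self.downs: List[nn.Conv2d] = []
        self.pools: List[nn.MaxPool2x2] = []
        for l in range(d):
            c_prev = None if l == 0 else chans[l - 1]
            self.enc_gates.append(FGDCGate(chans[l], c_prev, rng, dtype, f"enc{l}"))
            self.enc_blocks.append(
                [GatedResBlock(chans[l], rng, dtype, f"enc{l}.rb{b}")
                 for b in range(config.blocks_per_level)]
            )
            if l < d - 1:
                self.pools.append(nn.MaxPool2x2())
                self.downs.append(nn.Conv2d(chans[l], chans[l + 1], 1, rng, dtype, f"down{l}"))

        self.ups: List[nn.ConvTranspose2x2] = []
        self.dec_gates: List[FGDCGate] = []
        self.dec_blocks: List[List[GatedResBlock]] = []
        for l in range(d - 2, -1, -1):  # decoder levels, deepest first
            self.ups.append(nn.ConvTranspose2x2(chans[l + 1], chans[l], rng, dtype, f"up{l}"))
            self.dec_gates.append(FGDCGate(chans[l], chans[l + 1], rng, dtype, f"dec{l}"))
            self.dec_blocks.append(
                [GatedResBlock(chans[l], rng, dtype, f"dec{l}.rb{b}")
                 for b in range(config.blocks_per_level)]
            )

        self.head = nn.Conv2d(chans[0], 1, 1, rng, dtype, "head")
        self._cache = None

    # -- parameter plumbing -------------------------------------------------

    def params(self) -> List[nn.Param]:
        ps = self.stem.params()
        for gate, blocks in zip(self.enc_gates, self.enc_blocks):
            ps += gate.params()
            for b in blocks:
                ps += b.params()
        for down in self.downs:
            ps += down.params()
        for up, gate, blocks in zip(self.ups, self.dec_gates, self.dec_blocks):
            ps += up.params()
            ps += gate.params()
            for b in blocks:
                ps += b.params()
        ps += self.head.params()
        return ps

    def num_params(self) -> int:
        return sum(p.size for p in self.params())

    def summary(self) -> str:
        lines = [
            f"FGDCNet(depth={self.config.depth}, base_channels={self.config.base_channels}, "
            f"label_size={self.config.label_size}, blocks_per_level={self.config.blocks_per_level})",
        ]
        for p in self.params():
            lines.append(f"  {p.name:24s} {str(p.value.shape):20s} {p.size}")
        lines.append(f"total parameters: {self.num_params()}")
        return "\n".join(lines)

    # -- forward / backward -------------------------------------------------

    def forward(
        self, x: np.ndarray, state_override: Optional[float] = None
    ) -> np.ndarray:
        """Map a (B, 2N, 2N, 3) batch to (B, N, N) nucleus probabilities.

        ``state_override`` replaces every channel state by a constant (used to
        ablate the delivery connections: 0.0 reduces each gated block to
        ReLU(F)); it disables backward.
        """
        n = self.config.label_size
        x = np.asarray(x, dtype=self.config.np_dtype)
        if x.ndim != 4 or x.shape[1] != 2 * n or x.shape[2] != 2 * n or x.shape[3] != 3:
            raise ValueError(
                f"expected input of shape (B, {2 * n}, {2 * n}, 3), got {x.shape}"
            )
        states: List[np.ndarray] = []
        f = self.stem.forward(x)
        s_prev: Optional[np.ndarray] = None
        for l in range(self.config.depth):
            s = self.enc_gates[l].forward(f, s_prev)
            if state_override is not None:
                s = np.full_like(s, state_override)
            states.append(s)
            for block in self.enc_blocks[l]:
                f = block.forward(f, s)
            if l < self.config.depth - 1:
                f = self.pools[l].forward(f)
                f = self.downs[l].forward(f)
            s_prev = s
        for idx in range(len(self.ups)):
            f = self.ups[idx].forward(f)
            s = self.dec_gates[idx].forward(f, s_prev)
            if state_override is not None:
                s = np.full_like(s, state_override)
            states.append(s)
            for block in self.dec_blocks[idx]:
                f = block.forward(f, s)
            s_prev = s
        logits = self.head.forward(f)[..., 0]
        probs = _sigmoid(logits)
        half = n // 2
        out = probs[:, half : half + n, half : half + n]
        self._cache = (probs, half) if state_override is None else None
        self.last_states = states
        return out

    def backward(self, dout: np.ndarray) -> None:
        """Accumulate parameter gradients given dLoss/dOutput (B, N, N)."""
        if self._cache is None:
            raise RuntimeError("backward requires a prior forward without state_override")
        probs, half = self._cache
        n = self.config.label_size
        dprobs = np.zeros_like(probs)
        dprobs[:, half : half + n, half : half + n] = dout.astype(probs.dtype)
        dlogits = dprobs * probs * (1.0 - probs)
        df = self.head.backward(dlogits[..., None])

        ds_carry: Optional[np.ndarray] = None  # gradient flowing into S of the previous level
        # decoder levels in reverse
        for idx in range(len(self.ups) - 1, -1, -1):
            ds_total = np.zeros_like(self.last_states[self.config.depth + idx])
            if ds_carry is not None:
                ds_total += ds_carry
            for block in reversed(self.dec_blocks[idx]):
                df, ds = block.backward(df)
                ds_total += ds
            df_gate, ds_carry = self.dec_gates[idx].backward(ds_total)
            df = df + df_gate
            df = self.ups[idx].backward(df)
        # encoder levels in reverse
        for l in range(self.config.depth - 1, -1, -1):
            if l < self.config.depth - 1:
                df = self.downs[l].backward(df)
                df = self.pools[l].backward(df)
            ds_total = np.zeros_like(self.last_states[l])
            if ds_carry is not None:
                ds_total += ds_carry
            for block in reversed(self.enc_blocks[l]):
                df, ds = block.backward(df)
                ds_total += ds
            df_gate, ds_carry = self.enc_gates[l].backward(ds_total)
            df = df + df_gate
        self.stem.backward(df)
        self._cache = None

    def predict(self, x: np.ndarray, batch_size: int = 16) -> np.ndarray:
        """Forward in inference mode, batched to bound memory."""
        outs = []
        for i in range(0, x.shape[0], batch_size):
            outs.append(self.forward(x[i : i + batch_size]))
            self._cache = None
        return np.concatenate(outs, axis=0)

    # -- checkpointing ------------------------------------------------------

    def save(self, path: str | Path) -> None:
        """Write weights + config + version into a single .npz archive."""
        arrays = {f"param_{i}": p.value for i, p in enumerate(self.params())}
        meta = {
            "config": dataclasses.asdict(self.config),
            "version": PIPELINE_VERSION,
        }
        np.savez(path, meta=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8), **arrays)

    @classmethod
    def load(cls, path: str | Path) -> "FGDCNet":
        with np.load(path) as data:
            meta = json.loads(bytes(data["meta"]).decode())
            model = cls(NetworkConfig(**meta["config"]))
            for i, p in enumerate(model.params()):
                value = data[f"param_{i}"]
                if value.shape != p.value.shape:
                    raise ValueError(
                        f"checkpoint parameter {i} has shape {value.shape}, "
                        f"expected {p.value.shape}"
                    )
                p.value = value.astype(model.config.np_dtype)
        return model
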