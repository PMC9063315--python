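"""Attention building blocks for the segmentation network.

Three pieces:

* :class:`DsSE` — dual-scale semantic enhancement. Reconstructs a skip
  connection by non-local attention: the next-deeper encoder map (2C
  channels, half resolution) is channel-mapped and bilinearly upsampled,
  then forms the queries; the current map forms keys and values. The
  row-softmaxed query-key similarity re-weights the value vectors and the
  result is added residually to the current map.
* :class:`AM` — a squeeze-style gate (1x1 conv -> ReLU -> 1x1 conv ->
  sigmoid) producing a per-element confidence map P and gated feature
  Y = P * X.
* :class:`MsFF` — multiscale feature fusion at the top of the encoder:
  stage-3/4 maps are max-pool downsampled to stage-5 size, each stage
  passes through its own AM, the shallow gated maps are projected to the
  deep width, and the fusion is X5 + Y5 + (1 - P5) * (Y3' + Y4').

Each forward path has a brute-force, loop-written reference
(:func:`dsse_reference`, :func:`am_reference`, :func:`msff_reference`)
used by the test suite as an independent oracle.

Queries/keys are computed at a compressed width ``max(C // r, 1)`` with
compression ratio ``r = 16`` by default.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from . import nn
from .nn import functional as F
from .nn.tensor import Tensor, as_tensor

__all__ = [
    "DEFAULT_COMPRESSION_RATIO",
    "FeatureMap",
    "ConfidenceMap",
    "AttentionInternals",
    "DsSE",
    "AM",
    "MsFF",
    "dsse_forward",
    "am_forward",
    "msff_forward",
    "dsse_reference",
    "am_reference",
    "msff_reference",
]

logger = logging.getLogger(__name__)

DEFAULT_COMPRESSION_RATIO = 16

_clamp_logged: set = set()


def compressed_width(channels: int, r: int) -> int:
    """Effective query/key width ``max(C // r, 1)``; the clamp is logged once."""
    w = channels // r
    if w < 1:
        if (channels, r) not in _clamp_logged:
            logger.info("compression ratio %d exceeds channel count %d; width clamped to 1", r, channels)
            _clamp_logged.add((channels, r))
        return 1
    return w


# ---------------------------------------------------------------------------
# domain types


@dataclass
class FeatureMap:
    """A (C, H, W) activation tensor at one encoder/decoder stage (1..5)."""

    data: np.ndarray
    stage: int = 1

    def __post_init__(self):
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError(f"FeatureMap expects (C, H, W); got shape {self.data.shape}")
        if min(self.data.shape) < 1:
            raise ValueError("FeatureMap axes must be >= 1")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("FeatureMap entries must be finite")
        if not 1 <= int(self.stage) <= 5:
            raise ValueError(f"stage must be in 1..5, got {self.stage}")

    @property
    def channels(self) -> int:
        return self.data.shape[0]

    @property
    def spatial(self) -> tuple:
        return self.data.shape[1:]


@dataclass
class ConfidenceMap:
    """Sigmoid-valued (C, H, W) map; every entry strictly inside (0, 1)."""

    data: np.ndarray

    def __post_init__(self):
        self.data = np.asarray(self.data)
        if not (np.all(self.data > 0.0) and np.all(self.data < 1.0)):
            raise ValueError("ConfidenceMap entries must lie strictly in (0, 1)")


@dataclass
class AttentionInternals:
    """Intermediate tensors of one DsSE application (batch axis dropped)."""

    query: np.ndarray  # (H*W, C/r)
    key: np.ndarray  # (C/r, H*W)
    value: np.ndarray  # (C, H*W)
    similarity: np.ndarray  # (H*W, H*W), rows sum to 1
    compression_ratio: int = DEFAULT_COMPRESSION_RATIO


def _check_adjacent(f_shape: tuple, n_shape: tuple) -> None:
    cf, hf, wf = f_shape
    cn, hn, wn = n_shape
    if cn != 2 * cf or hn * 2 != hf or wn * 2 != wf:
        raise ValueError(
            "DsSE expects the deeper map to have 2x channels and half the "
            f"spatial extent of the current map; got F{f_shape} vs N{n_shape} "
            "(mis-wired skip connection?)"
        )


# ---------------------------------------------------------------------------
# modules


class DsSE(nn.Module):
    """Skip-connection reconstruction by dual-scale non-local attention.

    Parameters
    ----------
    channels : width C of the current (shallower) map; the deeper map must
        arrive with 2C channels at half resolution.
    r : compression ratio for the query/key width (default 16).
    """

    def __init__(self, channels: int, r: int = DEFAULT_COMPRESSION_RATIO):
        super().__init__()
        if r < 1:
            raise ValueError("compression ratio r must be >= 1")
        self.channels, self.r = channels, r
        cq = compressed_width(channels, r)
        self.map_n = nn.Conv2d(2 * channels, channels, 1)
        self.to_q = nn.Conv2d(channels, cq, 1)
        self.to_k = nn.Conv2d(channels, cq, 1)
        self.to_v = nn.Conv2d(channels, channels, 1)

    def forward(self, f, n, return_internals: bool = False):
        f, n = as_tensor(f), as_tensor(n)
        _check_adjacent(f.shape[1:], n.shape[1:])
        nb, c, h, w = f.shape
        n_up = F.bilinear_resize(self.map_n(n), (h, w))
        q = self.to_q(n_up).reshape(nb, -1, h * w).transpose(0, 2, 1)  # (N, HW, Cq)
        k = self.to_k(f).reshape(nb, -1, h * w)  # (N, Cq, HW)
        v = self.to_v(f).reshape(nb, c, h * w)  # (N, C, HW)
        e = (q @ k).softmax(axis=-1)  # (N, HW, HW): rows are convex weights
        t = (v @ e.transpose(0, 2, 1)).reshape(nb, c, h, w)
        m = f + t
        if return_internals:
            internals = AttentionInternals(
                query=q.data[0], key=k.data[0], value=v.data[0],
                similarity=e.data[0], compression_ratio=self.r,
            )
            return m, internals
        return m


class AM(nn.Module):
    """Confidence-gating attention: P = sigmoid(conv(relu(conv(X)))), Y = P*X."""

    def __init__(self, channels: int, r: int = DEFAULT_COMPRESSION_RATIO):
        super().__init__()
        if r < 1:
            raise ValueError("compression ratio r must be >= 1")
        self.channels, self.r = channels, r
        cq = compressed_width(channels, r)
        self.squeeze = nn.Conv2d(channels, cq, 1)
        self.expand = nn.Conv2d(cq, channels, 1)

    def forward(self, x):
        x = as_tensor(x)
        p = self.expand(self.squeeze(x).relu()).sigmoid()
        return p * x, p


class MsFF(nn.Module):
    """Top-of-encoder fusion of the three deepest stages.

    The stage-3/4 maps are parameter-free max-pool downsampled (factors 4
    and 2) to stage-5 size, gated by their own AM, projected to the
    stage-5 width by biased 1x1 convolutions, and fused as
    ``X5 + Y5 + (1 - P5) * (Y3' + Y4')``.
    """

    def __init__(self, c3: int, c4: int, c5: int, r: int = DEFAULT_COMPRESSION_RATIO):
        super().__init__()
        self.am3, self.am4, self.am5 = AM(c3, r), AM(c4, r), AM(c5, r)
        self.proj3 = nn.Conv2d(c3, c5, 1)
        self.proj4 = nn.Conv2d(c4, c5, 1)

    def forward(self, x3, x4, x5):
        x3, x4, x5 = as_tensor(x3), as_tensor(x4), as_tensor(x5)
        h5, w5 = x5.shape[2:]
        if x3.shape[2:] != (4 * h5, 4 * w5) or x4.shape[2:] != (2 * h5, 2 * w5):
            raise ValueError(
                "MsFF expects stage-3/4 maps at 4x/2x the stage-5 spatial size; "
                f"got {x3.shape[2:]}, {x4.shape[2:]} vs {x5.shape[2:]} "
                "(wrong stage wiring?)"
            )
        d3 = F.max_pool2d(x3, 4)
        d4 = F.max_pool2d(x4, 2)
        y3, _ = self.am3(d3)
        y4, _ = self.am4(d4)
        y5, p5 = self.am5(x5)
        return x5 + y5 + (1.0 - p5) * (self.proj3(y3) + self.proj4(y4))


# ---------------------------------------------------------------------------
# FeatureMap-level functional wrappers


def _batched(fm: FeatureMap) -> Tensor:
    return Tensor(fm.data[None])


def dsse_forward(f: FeatureMap, n: FeatureMap, r: int = DEFAULT_COMPRESSION_RATIO,
                 module: DsSE | None = None, seed: int = 0) -> FeatureMap:
    """Apply DsSE to a (current, next-deeper) feature-map pair.

    If no pre-built module is supplied, one is constructed with seeded
    random weights (useful for smoke checks; inside the network the
    trained module instance is passed).
    """
    if n.stage != f.stage + 1:
        raise ValueError(f"deeper map must be the next stage: F.stage={f.stage}, N.stage={n.stage}")
    _check_adjacent(f.data.shape, n.data.shape)
    if module is None:
        nn.manual_seed(seed)
        module = DsSE(f.channels, r)
    with nn.no_grad():
        out = module.eval()(_batched(f), _batched(n))
    return FeatureMap(out.data[0], stage=f.stage)


def am_forward(x: FeatureMap, r: int = DEFAULT_COMPRESSION_RATIO,
               module: AM | None = None, seed: int = 0):
    """Apply the confidence gate; returns the gated map and its ConfidenceMap."""
    if module is None:
        nn.manual_seed(seed)
        module = AM(x.channels, r)
    with nn.no_grad():
        y, p = module.eval()(_batched(x))
    return FeatureMap(y.data[0], stage=x.stage), ConfidenceMap(p.data[0])


def msff_forward(x3: FeatureMap, x4: FeatureMap, x5: FeatureMap,
                 r: int = DEFAULT_COMPRESSION_RATIO, module: MsFF | None = None,
                 seed: int = 0) -> FeatureMap:
    """Fuse the three deepest encoder maps into a stage-5-shaped output."""
    if module is None:
        nn.manual_seed(seed)
        module = MsFF(x3.channels, x4.channels, x5.channels, r)
    with nn.no_grad():
        out = module.eval()(_batched(x3), _batched(x4), _batched(x5))
    return FeatureMap(out.data[0], stage=x5.stage)


# ---------------------------------------------------------------------------
# brute-force reference oracles (float64, explicit loops; testing only)


def _conv1x1_loops(x: np.ndarray, w: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Per-pixel 1x1 convolution written as nested loops."""
    cout = w.shape[0]
    _, h, wd = x.shape
    out = np.zeros((cout, h, wd))
    for co in range(cout):
        for i in range(h):
            for j in range(wd):
                out[co, i, j] = float(w[co, :, 0, 0] @ x[:, i, j]) + float(b[co])
    return out


def _upsample2x_loops(x: np.ndarray) -> np.ndarray:
    """Bilinear 2x upsampling with half-pixel centers, per output pixel."""
    c, h, w = x.shape
    out = np.zeros((c, 2 * h, 2 * w))
    for i in range(2 * h):
        for j in range(2 * w):
            ry = min(max((i + 0.5) / 2.0 - 0.5, 0.0), h - 1.0)
            rx = min(max((j + 0.5) / 2.0 - 0.5, 0.0), w - 1.0)
            y0, x0 = int(np.floor(ry)), int(np.floor(rx))
            y1, x1 = min(y0 + 1, h - 1), min(x0 + 1, w - 1)
            ty, tx = ry - y0, rx - x0
            out[:, i, j] = (
                (1 - ty) * (1 - tx) * x[:, y0, x0]
                + (1 - ty) * tx * x[:, y0, x1]
                + ty * (1 - tx) * x[:, y1, x0]
                + ty * tx * x[:, y1, x1]
            )
    return out


def dsse_reference(module: DsSE, f: np.ndarray, n: np.ndarray) -> np.ndarray:
    """Loop transcription of the DsSE forward pass using ``module``'s weights.

    For every output pixel the attention response is accumulated as an
    explicit softmax-weighted sum over all H*W value vectors.
    """
    w = {k: v.astype(np.float64) for k, v in module.state_dict().items()}
    c, h, wd = f.shape
    n_up = _upsample2x_loops(_conv1x1_loops(n, w["map_n.weight"], w["map_n.bias"]))
    q = _conv1x1_loops(n_up, w["to_q.weight"], w["to_q.bias"]).reshape(-1, h * wd).T
    k = _conv1x1_loops(f, w["to_k.weight"], w["to_k.bias"]).reshape(-1, h * wd)
    v = _conv1x1_loops(f, w["to_v.weight"], w["to_v.bias"]).reshape(c, h * wd)
    t = np.zeros((c, h * wd))
    for p in range(h * wd):  # each output position
        logits = np.array([q[p] @ k[:, u] for u in range(h * wd)])
        weights = np.exp(logits - logits.max())
        weights /= weights.sum()
        for u in range(h * wd):  # weighted sum over all value vectors
            t[:, p] += weights[u] * v[:, u]
    return f + t.reshape(c, h, wd)


def am_reference(module: AM, x: np.ndarray) -> np.ndarray:
    """Element-wise loop transcription of the AM gate."""
    w = {k: v.astype(np.float64) for k, v in module.state_dict().items()}
    hidden = _conv1x1_loops(x, w["squeeze.weight"], w["squeeze.bias"])
    hidden = np.maximum(hidden, 0.0)
    logits = _conv1x1_loops(hidden, w["expand.weight"], w["expand.bias"])
    c, h, wd = x.shape
    y = np.zeros_like(x, dtype=np.float64)
    for ci in range(c):
        for i in range(h):
            for j in range(wd):
                p = 1.0 / (1.0 + np.exp(-logits[ci, i, j]))
                y[ci, i, j] = p * x[ci, i, j]
    return y


def _maxpool_loops(x: np.ndarray, k: int) -> np.ndarray:
    c, h, w = x.shape
    out = np.zeros((c, h // k, w // k))
    for ci in range(c):
        for i in range(h // k):
            for j in range(w // k):
                out[ci, i, j] = x[ci, i * k : (i + 1) * k, j * k : (j + 1) * k].max()
    return out


def msff_reference(module: MsFF, x3: np.ndarray, x4: np.ndarray, x5: np.ndarray) -> np.ndarray:
    """Straight-line recomputation of the fusion rule without the module graph."""
    w = {k: v.astype(np.float64) for k, v in module.state_dict().items()}

    def am(prefix, x):
        hidden = np.maximum(_conv1x1_loops(x, w[f"{prefix}.squeeze.weight"], w[f"{prefix}.squeeze.bias"]), 0.0)
        logits = _conv1x1_loops(hidden, w[f"{prefix}.expand.weight"], w[f"{prefix}.expand.bias"])
        p = 1.0 / (1.0 + np.exp(-logits))
        return p * x, p

    y3, _ = am("am3", _maxpool_loops(x3, 4))
    y4, _ = am("am4", _maxpool_loops(x4, 2))
    y5, p5 = am("am5", np.asarray(x5, dtype=np.float64))
    y3p = _conv1x1_loops(y3, w["proj3.weight"], w["proj3.bias"])
    y4p = _conv1x1_loops(y4, w["proj4.weight"], w["proj4.bias"])
    return x5 + y5 + (1.0 - p5) * (y3p + y4p)
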