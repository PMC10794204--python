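"""The regressive vision transformer (RVT) for VHS keypoint prediction.

Architecture, in the order a forward pass runs:

1. **Pyramid encoder with spatial-reduction attention (SRA).**  Each stage
   embeds non-overlapping patches, adds a learnable position embedding,
   and applies transformer blocks of ``LN -> SRA -> residual -> LN ->
   2-layer GELU MLP -> residual``.  SRA computes queries from the full
   token grid but keys/values from a spatially reduced copy: ``R x R``
   neighborhoods are concatenated, linearly projected back to the stage
   width, and layer-normalized, shrinking attention cost by ``R^2``.
   Attention is ``softmax(Q K^T / sqrt(d) + B) V`` with an optional
   learned per-head relative-position bias ``B``.

2. **Feature fusion.**  A texture-level (early-stage) and a shape-level
   (later-stage) feature map each pass through a 3x3 convolutional unit
   projecting to a common width; the coarse map is bilinearly upsampled
   to the fine map's grid and the two are concatenated along channels.

3. **Heads.**  Global average pooling feeds a fully connected regression
   head whose twelve sigmoid outputs are the six keypoints in normalized
   [0, 1] coordinates, and a classification path for the three cardiac
   size classes.

4. **Orthogonal layer.**  The final differentiable layer replaces the
   short-axis endpoint D's ordinate with ``y4_hat = s (x4 - x3) + y3``,
   ``s = -(x1 - x2)/(y1 - y2)``, so the predicted short axis is exactly
   perpendicular to the long axis; gradients flow through ``s`` to all
   contributing coordinates.

At inference the reported class label is always derived from the
predicted keypoints via the VHS thresholds, so geometry and diagnosis can
never disagree; the classification logits exist for the training
objective and for probabilistic metrics such as AUC.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict, field, replace

import numpy as np

from . import autodiff as ad
from .autodiff import Parameter, Tensor
from .errors import ConfigError, FormatError, ShapeError
from .geometry import KeyPointSet, VhsThresholds, classify_vhs_array
from .annotations import denormalize_keypoints

CHECKPOINT_FORMAT_VERSION = 1

#: Rough anatomical layout of the six landmarks in normalized coordinates
#: (carina, apex, short-axis endpoints, T4, ninth vertebra).  Used only to
#: initialize the regression head's bias: starting from a spread, oblique
#: long axis keeps the orthogonal layer's slope well conditioned from the
#: first step (at an uninformed init all sigmoid outputs sit at 0.5, where
#: the slope denominator y1 - y2 vanishes).
KEYPOINT_PRIOR = np.array([0.50, 0.42, 0.58, 0.68, 0.44, 0.52, 0.62, 0.46,
                           0.33, 0.22, 0.66, 0.26])


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ModelConfig:
    """Shape of the RVT encoder and heads.

    ``dims``, ``heads``, ``sr_ratios``, ``depths`` and ``patch_sizes`` are
    per-stage tuples.  ``low_stage``/``high_stage`` are 1-based stage
    numbers feeding the fusion module.  ``head_mode`` selects how class
    logits are produced: ``aux_head`` (a parallel linear head on pooled
    features, the default) or ``soft_vhs`` (logits derived from the
    predicted VHS as negative squared distances to class-interval
    midpoints over a temperature, making classification fully geometric).
    """

    input_size: int = 96
    num_stages: int = 2
    patch_sizes: tuple = (6, 2)
    dims: tuple = (32, 64)
    heads: tuple = (1, 2)
    sr_ratios: tuple = (4, 2)
    depths: tuple = (2, 2)
    mlp_ratio: float = 2.0
    low_stage: int = 1
    high_stage: int = 2
    fusion_channels: int = 64
    head_mode: str = "aux_head"
    use_orthogonal_layer: bool = True
    use_feature_fusion: bool = True
    use_rel_bias: bool = True
    soft_vhs_mids: tuple = (7.2, 9.1, 11.5)
    soft_vhs_temperature: float = 0.5
    thresholds: VhsThresholds = field(default_factory=VhsThresholds)

    def __post_init__(self) -> None:
        per_stage = (self.patch_sizes, self.dims, self.heads, self.sr_ratios, self.depths)
        if any(len(t) != self.num_stages for t in per_stage):
            raise ConfigError("patch_sizes, dims, heads, sr_ratios and depths must all have "
                              f"num_stages={self.num_stages} entries")
        for c, h in zip(self.dims, self.heads):
            if c % h:
                raise ConfigError(f"stage width {c} not divisible by its head count {h}")
        size = self.input_size
        for i, (p, r) in enumerate(zip(self.patch_sizes, self.sr_ratios)):
            if size % p:
                raise ConfigError(f"spatial size {size} at stage {i + 1} not divisible by patch {p}")
            size //= p
            if size % r:
                raise ConfigError(f"token grid {size}x{size} at stage {i + 1} not divisible by R={r}")
        if self.head_mode not in ("aux_head", "soft_vhs"):
            raise ConfigError(f"unknown head_mode {self.head_mode!r}")
        if not (1 <= self.low_stage < self.high_stage <= self.num_stages):
            raise ConfigError(f"need 1 <= low_stage < high_stage <= num_stages, got "
                              f"{self.low_stage}, {self.high_stage}")

    @classmethod
    def desk(cls, **overrides) -> "ModelConfig":
        """CPU-scale preset: 96 px input, two stages of widths 32/64."""
        return cls(**overrides)

    @classmethod
    def full(cls, **overrides) -> "ModelConfig":
        """Full-scale preset mirroring the 512 px four-stage pyramid."""
        defaults = dict(input_size=512, num_stages=4, patch_sizes=(4, 2, 2, 2),
                        dims=(64, 128, 320, 512), heads=(1, 2, 5, 8),
                        sr_ratios=(8, 4, 2, 1), depths=(2, 2, 2, 2), mlp_ratio=4.0,
                        fusion_channels=128, low_stage=1, high_stage=2)
        defaults.update(overrides)
        return cls(**defaults)

    def grid_sizes(self) -> list[int]:
        sizes, size = [], self.input_size
        for p in self.patch_sizes:
            size //= p
            sizes.append(size)
        return sizes

    def to_dict(self) -> dict:
        d = asdict(self)
        d["thresholds"] = {"low": self.thresholds.low, "high": self.thresholds.high}
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "ModelConfig":
        d = dict(d)
        th = d.pop("thresholds", None)
        for key in ("patch_sizes", "dims", "heads", "sr_ratios", "depths", "soft_vhs_mids"):
            if key in d:
                d[key] = tuple(d[key])
        cfg = cls(**d)
        if th is not None:
            cfg = replace(cfg, thresholds=VhsThresholds(**th))
        return cfg


# ---------------------------------------------------------------------------
# layers
# ---------------------------------------------------------------------------

def _xavier(rng: np.random.Generator, fan_in: int, fan_out: int, dtype) -> np.ndarray:
    std = np.sqrt(2.0 / (fan_in + fan_out))
    return rng.normal(0.0, std, size=(fan_in, fan_out)).astype(dtype)


class Linear:
    def __init__(self, rng, fan_in: int, fan_out: int, dtype=np.float32, bias: bool = True,
                 init_std: float | None = None):
        if init_std is None:
            self.w = Parameter(_xavier(rng, fan_in, fan_out, dtype))
        else:
            self.w = Parameter(rng.normal(0.0, init_std, size=(fan_in, fan_out)).astype(dtype))
        self.b = Parameter(np.zeros(fan_out, dtype=dtype)) if bias else None

    def __call__(self, x: Tensor) -> Tensor:
        y = ad.matmul(x, self.w)
        return y + self.b if self.b is not None else y

    def named_parameters(self, prefix: str):
        yield f"{prefix}.w", self.w
        if self.b is not None:
            yield f"{prefix}.b", self.b


class LayerNorm:
    def __init__(self, dim: int, dtype=np.float32):
        self.g = Parameter(np.ones(dim, dtype=dtype))
        self.b = Parameter(np.zeros(dim, dtype=dtype))

    def __call__(self, x: Tensor) -> Tensor:
        return ad.layer_norm(x, self.g, self.b)

    def named_parameters(self, prefix: str):
        yield f"{prefix}.g", self.g
        yield f"{prefix}.b", self.b


def scaled_dot_attention(q: Tensor, k: Tensor, v: Tensor, d: int,
                         bias: Tensor | None = None) -> tuple[Tensor, Tensor]:
    """``softmax(q k^T / sqrt(d) + bias) v``; returns (output, weights)."""
    scores = ad.matmul(q, k.swapaxes(-1, -2)) * (1.0 / np.sqrt(float(d)))
    if bias is not None:
        scores = scores + bias
    weights = ad.softmax(scores, axis=-1)
    return ad.matmul(weights, v), weights


def _relative_bias_index(H: int, W: int, R: int) -> np.ndarray:
    """Flat table index (N_q*N_k,) of quantized query-to-key offsets.

    Keys live on the reduced grid; each key cell is anchored at its center
    in query coordinates.  Offsets index a ``(2M-1)^2`` table, ``M = H``.
    """
    M = H
    qi, qj = np.mgrid[0:H, 0:W]
    ki, kj = np.mgrid[0:H // R, 0:W // R]
    kci = ki * R + (R - 1) / 2.0
    kcj = kj * R + (R - 1) / 2.0
    di = np.floor(qi.ravel()[:, None] - kci.ravel()[None, :] + 0.5).astype(int)
    dj = np.floor(qj.ravel()[:, None] - kcj.ravel()[None, :] + 0.5).astype(int)
    return ((di + M - 1) * (2 * M - 1) + (dj + M - 1)).ravel()


class SpatialReduction:
    """Token-sequence downsampling: R x R neighborhoods -> one projected token."""

    def __init__(self, rng, dim: int, R: int, dtype=np.float32):
        self.R = R
        self.proj = Linear(rng, R * R * dim, dim, dtype)
        self.norm = LayerNorm(dim, dtype)

    def __call__(self, x: Tensor, H: int, W: int) -> Tensor:
        B, N, C = x.shape
        R = self.R
        if N != H * W:
            raise ShapeError(f"token count {N} does not match grid {H}x{W}")
        if H % R or W % R:
            raise ShapeError(f"spatial size H={H}, W={W} not divisible by reduction ratio R={R}")
        if R > 1:
            x = (x.reshape(B, H // R, R, W // R, R, C)
                  .transpose((0, 1, 3, 2, 4, 5))
                  .reshape(B, (H // R) * (W // R), R * R * C))
        return self.norm(self.proj(x))

    def named_parameters(self, prefix: str):
        yield from self.proj.named_parameters(f"{prefix}.proj")
        yield from self.norm.named_parameters(f"{prefix}.norm")


class SRAttention:
    """Multi-head spatial-reduction attention for one pyramid stage."""

    def __init__(self, rng, dim: int, heads: int, R: int, H: int, W: int,
                 use_rel_bias: bool, dtype=np.float32):
        self.heads = heads
        self.d = dim // heads
        self.H, self.W, self.R = H, W, R
        self.wq = Linear(rng, dim, dim, dtype)
        self.wk = Linear(rng, dim, dim, dtype)
        self.wv = Linear(rng, dim, dim, dtype)
        self.wo = Linear(rng, dim, dim, dtype)
        self.sr = SpatialReduction(rng, dim, R, dtype)
        self.bias_table = None
        self._bias_index = None
        if use_rel_bias:
            M = H
            self.bias_table = Parameter(np.zeros((heads, (2 * M - 1) ** 2), dtype=dtype))
            self._bias_index = _relative_bias_index(H, W, R)

    def __call__(self, x: Tensor, return_weights: bool = False):
        B, N, C = x.shape
        h, d = self.heads, self.d
        q = self.wq(x).reshape(B, N, h, d).transpose((0, 2, 1, 3))
        kv = self.sr(x, self.H, self.W)
        Nk = kv.shape[1]
        k = self.wk(kv).reshape(B, Nk, h, d).transpose((0, 2, 1, 3))
        v = self.wv(kv).reshape(B, Nk, h, d).transpose((0, 2, 1, 3))
        bias = None
        if self.bias_table is not None:
            bias = self.bias_table[:, self._bias_index].reshape(1, h, N, Nk)
        out, weights = scaled_dot_attention(q, k, v, d, bias)
        out = out.transpose((0, 2, 1, 3)).reshape(B, N, h * d)
        out = self.wo(out)
        return (out, weights) if return_weights else out

    def named_parameters(self, prefix: str):
        for name, lin in (("wq", self.wq), ("wk", self.wk), ("wv", self.wv), ("wo", self.wo)):
            yield from lin.named_parameters(f"{prefix}.{name}")
        yield from self.sr.named_parameters(f"{prefix}.sr")
        if self.bias_table is not None:
            yield f"{prefix}.bias_table", self.bias_table


class Block:
    """Pre-norm transformer block: LN -> SRA -> +x, LN -> MLP(GELU) -> +x."""

    def __init__(self, rng, dim: int, heads: int, R: int, H: int, W: int,
                 mlp_ratio: float, use_rel_bias: bool, dtype=np.float32):
        hidden = int(round(dim * mlp_ratio))
        self.norm1 = LayerNorm(dim, dtype)
        self.attn = SRAttention(rng, dim, heads, R, H, W, use_rel_bias, dtype)
        self.norm2 = LayerNorm(dim, dtype)
        self.fc1 = Linear(rng, dim, hidden, dtype)
        self.fc2 = Linear(rng, hidden, dim, dtype)

    def __call__(self, x: Tensor) -> Tensor:
        x = x + self.attn(self.norm1(x))
        return x + self.fc2(ad.gelu(self.fc1(self.norm2(x))))

    def named_parameters(self, prefix: str):
        yield from self.norm1.named_parameters(f"{prefix}.norm1")
        yield from self.attn.named_parameters(f"{prefix}.attn")
        yield from self.norm2.named_parameters(f"{prefix}.norm2")
        yield from self.fc1.named_parameters(f"{prefix}.fc1")
        yield from self.fc2.named_parameters(f"{prefix}.fc2")


class PatchEmbed:
    """Non-overlapping patch embedding + learnable position embedding."""

    def __init__(self, rng, in_ch: int, dim: int, patch: int, grid: int, dtype=np.float32):
        self.patch = patch
        self.grid = grid
        self.proj = Linear(rng, patch * patch * in_ch, dim, dtype)
        self.norm = LayerNorm(dim, dtype)
        self.pos = Parameter(rng.normal(0.0, 0.02, size=(1, grid * grid, dim)).astype(dtype))

    def __call__(self, x: Tensor) -> Tensor:
        """(B, H, W, C) image/feature grid -> (B, N, dim) tokens."""
        B, H, W, C = x.shape
        p, g = self.patch, self.grid
        if H != g * p or W != g * p:
            raise ShapeError(f"expected {g * p}x{g * p} input grid, got {H}x{W}")
        tokens = ad.unfold(x, p, p, 0).reshape(B, g * g, p * p * C)
        return self.norm(self.proj(tokens)) + self.pos

    def named_parameters(self, prefix: str):
        yield from self.proj.named_parameters(f"{prefix}.proj")
        yield from self.norm.named_parameters(f"{prefix}.norm")
        yield f"{prefix}.pos", self.pos


class ConvUnit:
    """3x3 convolution (stride 1, pad 1) + GELU, via im2col."""

    def __init__(self, rng, in_ch: int, out_ch: int, dtype=np.float32):
        self.lin = Linear(rng, 9 * in_ch, out_ch, dtype)

    def __call__(self, x: Tensor) -> Tensor:
        return ad.gelu(self.lin(ad.unfold(x, 3, 1, 1)))

    def named_parameters(self, prefix: str):
        yield from self.lin.named_parameters(f"{prefix}.lin")


def _bilinear_matrix(n_out: int, n_in: int, dtype=np.float32) -> np.ndarray:
    """Dense 1-D bilinear interpolation matrix (half-pixel centers)."""
    m = np.zeros((n_out, n_in), dtype=dtype)
    scale = n_in / n_out
    for o in range(n_out):
        src = (o + 0.5) * scale - 0.5
        i0 = int(np.floor(src))
        frac = src - i0
        i0c = min(max(i0, 0), n_in - 1)
        i1c = min(max(i0 + 1, 0), n_in - 1)
        m[o, i0c] += 1.0 - frac
        m[o, i1c] += frac
    return m


def upsample_bilinear(x: Tensor, out_h: int, out_w: int) -> Tensor:
    """(B, H, W, C) -> (B, out_h, out_w, C) bilinear resize."""
    B, H, W, C = x.shape
    mh = Tensor(_bilinear_matrix(out_h, H, x.data.dtype))
    mw = Tensor(_bilinear_matrix(out_w, W, x.data.dtype))
    y = ad.matmul(mh, x.transpose((0, 2, 1, 3)))          # (B, W, out_h, C)
    y = ad.matmul(mw, y.transpose((0, 2, 1, 3)))          # (B, out_h, out_w, C)
    return y


# ---------------------------------------------------------------------------
# orthogonal layer
# ---------------------------------------------------------------------------

def orthogonal_layer(flat, eps: float = 1e-6):
    """Differentiable perpendicularity projection on flat 12-vectors.

    Accepts a :class:`Tensor` or ndarray of shape (..., 12) in the order
    (Ax, Ay, Bx, By, Cx, Cy, Dx, Dy, Ex, Ey, Fx, Fy); only the D slots can
    change.  Matches :func:`vhsnet.geometry.orthogonalize` exactly,
    including the degenerate branch (AB horizontal within ``eps``: D's
    abscissa is replaced by C's instead).
    """
    is_array = not isinstance(flat, Tensor)
    t = Tensor(np.asarray(flat, dtype=float)) if is_array else flat
    if t.shape[-1] != 12:
        raise FormatError(f"orthogonal layer expects (..., 12) inputs, got {t.shape}")
    x1, y1 = t[..., 0:1], t[..., 1:2]
    x2, y2 = t[..., 2:3], t[..., 3:4]
    x3, y3 = t[..., 4:5], t[..., 5:6]
    x4, y4 = t[..., 6:7], t[..., 7:8]
    dy = y1 - y2
    mask = np.abs(dy.data) < eps
    denom = ad.where(mask, Tensor(np.ones_like(dy.data)), dy)
    s = -(x1 - x2) / denom
    y4_hat = s * (x4 - x3) + y3
    new_x4 = ad.where(mask, x3, x4)
    new_y4 = ad.where(mask, y4, y4_hat)
    out = ad.concat([t[..., 0:6], new_x4, new_y4, t[..., 8:12]], axis=-1)
    return out.data if is_array else out


def vhs_from_flat(flat: np.ndarray, span: float = 6.0, ef_floor: float = 1e-6) -> np.ndarray:
    """Vectorized ``span * (|AB| + |CD|) / |EF|`` on (..., 12) arrays.

    ``|EF|`` is floored at ``ef_floor`` so early-training predictions with
    collapsed vertebral points yield large-but-finite scores rather than
    infinities (the strict scalar path in :mod:`vhsnet.geometry` raises).
    """
    f = np.asarray(flat, dtype=float)
    ab = np.hypot(f[..., 0] - f[..., 2], f[..., 1] - f[..., 3])
    cd = np.hypot(f[..., 4] - f[..., 6], f[..., 5] - f[..., 7])
    ef = np.hypot(f[..., 8] - f[..., 10], f[..., 9] - f[..., 11])
    return span * (ab + cd) / np.maximum(ef, ef_floor)


# ---------------------------------------------------------------------------
# the model
# ---------------------------------------------------------------------------

@dataclass
class Prediction:
    """One image's regressed keypoints and derived diagnosis."""

    keypoints_norm: np.ndarray      # (12,) in [0, 1]
    keypoints_px: KeyPointSet       # in source-image pixels
    vhs: float
    class_logits: np.ndarray        # (3,)
    class_probs: np.ndarray         # (3,) softmax of logits
    class_label: int                # from classify_vhs(vhs) — geometric


class RVTModel:
    """Pyramid SRA encoder + feature fusion + regression/aux heads."""

    def __init__(self, cfg: ModelConfig, seed: int = 0, dtype=np.float32):
        self.cfg = cfg
        self.dtype = dtype
        rng = np.random.default_rng(seed)
        grids = cfg.grid_sizes()
        self.grids = grids

        self.embeds: list[PatchEmbed] = []
        self.stages: list[list[Block]] = []
        in_ch = 3
        for i in range(cfg.num_stages):
            self.embeds.append(PatchEmbed(rng, in_ch, cfg.dims[i], cfg.patch_sizes[i], grids[i], dtype))
            blocks = [Block(rng, cfg.dims[i], cfg.heads[i], cfg.sr_ratios[i], grids[i], grids[i],
                            cfg.mlp_ratio, cfg.use_rel_bias, dtype)
                      for _ in range(cfg.depths[i])]
            self.stages.append(blocks)
            in_ch = cfg.dims[i]

        lo, hi = cfg.low_stage - 1, cfg.high_stage - 1
        self._lo, self._hi = lo, hi
        if cfg.use_feature_fusion:
            self.conv_low = ConvUnit(rng, cfg.dims[lo], cfg.fusion_channels, dtype)
            self.conv_high = ConvUnit(rng, cfg.dims[hi], cfg.fusion_channels, dtype)
            head_in = 2 * cfg.fusion_channels
        else:
            self.conv_low = self.conv_high = None
            head_in = cfg.dims[hi]
        self.head_norm = LayerNorm(head_in, dtype)
        # near-zero weight init + anatomical-prior bias: the decoded points
        # start at the prior layout, keeping the orthogonal layer's slope
        # well conditioned during early training
        self.reg_head = Linear(rng, head_in, 12, dtype, init_std=1e-3)
        self.reg_head.b.data = np.log(KEYPOINT_PRIOR / (1.0 - KEYPOINT_PRIOR)).astype(dtype)
        # the aux head likewise starts near zero: uniform class logits at
        # init, so early CE gradients grow gently instead of distorting the
        # shared trunk before coordinate learning starts
        self.aux_head = (Linear(rng, head_in, 3, dtype, init_std=1e-3)
                         if cfg.head_mode == "aux_head" else None)

        self._params = dict(self._named_parameters())

    # -- parameter plumbing ----------------------------------------------
    def _named_parameters(self):
        for i, emb in enumerate(self.embeds):
            yield from emb.named_parameters(f"stage{i}.embed")
            for j, blk in enumerate(self.stages[i]):
                yield from blk.named_parameters(f"stage{i}.block{j}")
        if self.conv_low is not None:
            yield from self.conv_low.named_parameters("fusion.low")
            yield from self.conv_high.named_parameters("fusion.high")
        yield from self.head_norm.named_parameters("head.norm")
        yield from self.reg_head.named_parameters("head.reg")
        if self.aux_head is not None:
            yield from self.aux_head.named_parameters("head.aux")

    def parameters(self) -> list[Parameter]:
        return list(self._params.values())

    def n_parameters(self) -> int:
        return sum(p.data.size for p in self.parameters())

    def state_dict(self) -> dict:
        return {k: p.data.copy() for k, p in self._params.items()}

    def load_state_dict(self, state: dict) -> None:
        missing = set(self._params) - set(state)
        if missing:
            raise FormatError(f"checkpoint is missing parameters: {sorted(missing)[:5]}")
        for k, p in self._params.items():
            arr = np.asarray(state[k], dtype=p.data.dtype)
            if arr.shape != p.data.shape:
                raise FormatError(f"parameter {k!r}: checkpoint shape {arr.shape} != model {p.data.shape}")
            p.data = arr.copy()

    # -- forward ----------------------------------------------------------
    def encode(self, x: Tensor) -> list[tuple[Tensor, int]]:
        """Image batch (B, S, S, 3) -> per-stage token maps [(tokens, grid)]."""
        B, H, W, C = x.shape
        S = self.cfg.input_size
        if H != S or W != S or C != 3:
            raise ShapeError(f"expected (B, {S}, {S}, 3) input, got {x.shape}")
        feats = []
        cur = x
        for i in range(self.cfg.num_stages):
            g = self.grids[i]
            tokens = self.embeds[i](cur)
            for blk in self.stages[i]:
                tokens = blk(tokens)
            feats.append((tokens, g))
            cur = tokens.reshape(B, g, g, self.cfg.dims[i])
        return feats

    def fuse(self, feats: list[tuple[Tensor, int]]) -> Tensor:
        """Fusion of the low/high stage maps -> (B, g_low, g_low, channels)."""
        t_lo, g_lo = feats[self._lo]
        t_hi, g_hi = feats[self._hi]
        B = t_lo.shape[0]
        f_hi = t_hi.reshape(B, g_hi, g_hi, self.cfg.dims[self._hi])
        if not self.cfg.use_feature_fusion:
            return f_hi
        f_lo = t_lo.reshape(B, g_lo, g_lo, self.cfg.dims[self._lo])
        a = self.conv_low(f_lo)
        b = upsample_bilinear(self.conv_high(f_hi), g_lo, g_lo)
        return ad.concat([a, b], axis=-1)

    def forward(self, images) -> tuple[Tensor, Tensor]:
        """Returns (normalized 12-vector coords, class logits), both Tensors."""
        x = images if isinstance(images, Tensor) else Tensor(np.asarray(images, dtype=self.dtype))
        fused = self.fuse(self.encode(x))
        pooled = self.head_norm(fused.mean(axis=(1, 2)))
        coords = ad.sigmoid(self.reg_head(pooled))
        if self.cfg.use_orthogonal_layer:
            coords = orthogonal_layer(coords)
        if self.cfg.head_mode == "aux_head":
            logits = self.aux_head(pooled)
        else:
            logits = self._soft_vhs_logits(coords)
        return coords, logits

    def _soft_vhs_logits(self, coords: Tensor) -> Tensor:
        ab = ((coords[:, 0:1] - coords[:, 2:3]) ** 2.0 + (coords[:, 1:2] - coords[:, 3:4]) ** 2.0).sqrt()
        cd = ((coords[:, 4:5] - coords[:, 6:7]) ** 2.0 + (coords[:, 5:6] - coords[:, 7:8]) ** 2.0).sqrt()
        ef2 = (coords[:, 8:9] - coords[:, 10:11]) ** 2.0 + (coords[:, 9:10] - coords[:, 11:12]) ** 2.0
        ef = ad.where(ef2.data < 1e-12, Tensor(np.full_like(ef2.data, 1e-12)), ef2).sqrt()
        vhs = 6.0 * (ab + cd) / ef
        mids = Tensor(np.asarray(self.cfg.soft_vhs_mids, dtype=vhs.data.dtype)[None, :])
        diff = vhs - mids
        return -(diff * diff) * (1.0 / self.cfg.soft_vhs_temperature)

    # -- inference --------------------------------------------------------
    def predict(self, images: np.ndarray, orig_sizes=None, batch_size: int = 64) -> list[Prediction]:
        """Run the model on (N, S, S, 3) images (or one (S, S, 3) image).

        ``orig_sizes`` is an optional list of per-image (width, height) of
        the source images; keypoints_px are scaled back into that frame.
        VHS and the class label are computed in the square model frame,
        where the orthogonality guarantee holds.
        """
        arr = np.asarray(images, dtype=self.dtype)
        single = arr.ndim == 3
        if single:
            arr = arr[None]
        preds: list[Prediction] = []
        with ad.no_grad():
            for start in range(0, len(arr), batch_size):
                chunk = arr[start:start + batch_size]
                coords_t, logits_t = self.forward(chunk)
                coords = coords_t.data.astype(float)
                logits = logits_t.data.astype(float)
                e = np.exp(logits - logits.max(axis=1, keepdims=True))
                probs = e / e.sum(axis=1, keepdims=True)
                vhs = vhs_from_flat(coords)
                labels = classify_vhs_array(vhs, self.cfg.thresholds)
                for i in range(len(chunk)):
                    w, h = (orig_sizes[start + i] if orig_sizes is not None
                            else (self.cfg.input_size, self.cfg.input_size))
                    preds.append(Prediction(
                        keypoints_norm=coords[i],
                        keypoints_px=denormalize_keypoints(coords[i], w, h),
                        vhs=float(vhs[i]),
                        class_logits=logits[i], class_probs=probs[i],
                        class_label=int(labels[i])))
        return preds


# ---------------------------------------------------------------------------
# checkpoints
# ---------------------------------------------------------------------------

def save_checkpoint(model: RVTModel, path) -> None:
    """Single-file .npz checkpoint with a versioned JSON header."""
    header = json.dumps({"format_version": CHECKPOINT_FORMAT_VERSION,
                         "config": model.cfg.to_dict()})
    np.savez(path, __header__=np.frombuffer(header.encode(), dtype=np.uint8),
             **model.state_dict())


def load_checkpoint(path) -> RVTModel:
    with np.load(path) as data:
        header = json.loads(bytes(data["__header__"]).decode())
        if header.get("format_version") != CHECKPOINT_FORMAT_VERSION:
            raise FormatError(f"unsupported checkpoint format {header.get('format_version')!r}")
        cfg = ModelConfig.from_dict(header["config"])
        model = RVTModel(cfg)
        model.load_state_dict({k: data[k] for k in data.files if k != "__header__"})
    return model
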