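"""Lightweight 3D convolution/Transformer encoder-decoder for phase maps.

The network maps a 4D perfusion series, with the 40 time points as input
channels, onto the five collateral phase maps.  The encoder has four
groups: (1) a 1x3x3 convolution stem with spatial stride 2; (2) two sets
of [two stride-1 inverted-residual (MV2) blocks + one stride-2 MV2
block]; (3) two sets of [a hybrid conv/Transformer (MViT) block + a
stride-2 MV2 block], with 2 and 4 Transformer layers respectively;
(4) pointwise conv -> slice-wise ViT block -> pointwise conv to the
512-channel bottleneck.  All striding is spatial-only, so the 20-slice
depth axis survives to the 512 x 20 x 6 x 6 bottleneck (for 224 input).
The decoder mirrors the encoder with five sets of [3x3x3 transposed
convolution + residual block], skip concatenation at the four encoder
resolutions, and a 1x1x1 head with Tanh producing five channels in
(-1, 1).

Resolution ladder for 224 input: 224 -> 112 -> 56 -> 28 -> 14 -> 6; the
final encoder downsampling is unpadded ((14 - 3)/2 + 1 = 6) and the first
decoder stage inverts it exactly ((6 - 1)*2 + 3 + 1 = 14).  For inputs
whose ladder stays even (e.g. 64 -> ... -> 2) every stage uses "same"
padding instead; this is the ``last_stage_valid`` switch.

Stage channel widths and the ViT depth L_V are free design parameters;
the named reference configuration is calibrated so that the trainable
parameter count and static FLOP count land on the published complexity
budget (26.736 M parameters, 7.140e11 FLOPs at 40 x 20 x 224 x 224 under
the 2-FLOPs-per-MAC convention, counting convolution/linear/attention
matmuls and ignoring normalisation, bias and activation terms).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import nn

__all__ = [
    "ModelConfig",
    "MoReT3D",
    "MV2Block",
    "MViTBlock",
    "ViTBlock",
    "DeconvLayer",
    "ResidualBlock",
    "build_model",
    "unfold_volumes",
    "fold_volumes",
    "unfold_slices",
    "fold_slices",
    "count_parameters",
    "count_flops",
    "profile_model",
    "FLOP_CONVENTION",
]

FLOP_CONVENTION = ("2 FLOPs per multiply-accumulate; convolution, linear and "
                   "attention matrix products counted; normalisation, bias and "
                   "activation terms ignored")


# ---------------------------------------------------------------------------
# unfolding
# ---------------------------------------------------------------------------


def unfold_volumes(x: np.ndarray, p: int) -> np.ndarray:
    """Partition (..., C, D, H, W) into N non-overlapping p^3 volumes.

    Returns (..., C, N, P) with N = D*H*W / p^3 and P = p^3; inverted
    exactly by :func:`fold_volumes`.
    """
    *lead, C, D, H, W = x.shape
    if D % p or H % p or W % p:
        raise ValueError(f"(D, H, W) = {(D, H, W)} not divisible by p = {p}")
    dn, hn, wn = D // p, H // p, W // p
    y = x.reshape(*lead, C, dn, p, hn, p, wn, p)
    # bring the block indices together, then the within-block offsets
    y = np.moveaxis(y, (-5, -3, -1), (-3, -2, -1))
    return np.ascontiguousarray(y).reshape(*lead, C, dn * hn * wn, p ** 3)


def fold_volumes(xu: np.ndarray, p: int, dhw: tuple[int, int, int]) -> np.ndarray:
    """Inverse of :func:`unfold_volumes` for the given (D, H, W)."""
    D, H, W = dhw
    *lead, C, N, P = xu.shape
    if P != p ** 3 or N * P != D * H * W:
        raise ValueError("token shape inconsistent with (D, H, W) and p")
    dn, hn, wn = D // p, H // p, W // p
    y = xu.reshape(*lead, C, dn, hn, wn, p, p, p)
    y = np.moveaxis(y, (-3, -2, -1), (-5, -3, -1))
    return np.ascontiguousarray(y).reshape(*lead, C, D, H, W)


def unfold_slices(x: np.ndarray) -> np.ndarray:
    """Slice-wise unfolding: (..., C, D, H, W) -> (..., C, N=D, P=H*W)."""
    *lead, C, D, H, W = x.shape
    return x.reshape(*lead, C, D, H * W)


def fold_slices(xu: np.ndarray, hw: tuple[int, int]) -> np.ndarray:
    H, W = hw
    *lead, C, N, P = xu.shape
    if P != H * W:
        raise ValueError("token shape inconsistent with (H, W)")
    return xu.reshape(*lead, C, N, H, W)


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ModelConfig:
    """Architecture hyperparameters.

    ``stage_widths`` are the channel counts after the stem and after each
    of the four downsampling stages; ``vit_dim`` is the embedding width of
    the slice-wise ViT block; ``decoder_widths`` are the five decoder
    stage widths (bottleneck side first).
    """

    in_channels: int = 40
    out_phases: int = 5
    depth: int = 20
    stage_widths: tuple[int, int, int, int, int] = (32, 64, 104, 160, 208)
    vit_dim: int = 384
    bottleneck_channels: int = 512
    decoder_widths: tuple[int, int, int, int, int] = (416, 256, 160, 96, 32)
    L_M: tuple[int, int] = (2, 4)
    L_V: int = 4
    patch_p: int = 2
    heads: int = 4
    mv2_expansion: int = 4
    mlp_ratio: float = 2.0
    last_stage_valid: bool = True
    bn_momentum: float = 0.1
    head_bias: float = 0.0
    residual_gamma: float = 1.0  # initial BN scale on residual branches
    transformer_out_scale: float = 1.0  # init scale of attn/MLP output weights

    def __post_init__(self) -> None:
        for w in (*self.stage_widths[2:4], self.vit_dim):
            if w % self.heads:
                raise ValueError(f"heads ({self.heads}) must divide width {w}")
        if len(self.stage_widths) != 5 or len(self.decoder_widths) != 5:
            raise ValueError("expected 5 encoder and 5 decoder widths")

    @classmethod
    def reference(cls) -> "ModelConfig":
        """Calibrated full-size configuration (224 input, 6x6 bottleneck)."""
        return cls()

    @classmethod
    def reduced(cls) -> "ModelConfig":
        """Small configuration for CPU-scale experiments (64 input)."""
        return cls(stage_widths=(8, 12, 16, 24, 32), vit_dim=48,
                   bottleneck_channels=64, decoder_widths=(80, 56, 40, 28, 20),
                   L_V=1, last_stage_valid=False, bn_momentum=0.3,
                   head_bias=-1.0, residual_gamma=0.1,
                   transformer_out_scale=0.3)

    def encoder_ladder(self, hw: int) -> list[int]:
        """Spatial sizes after the stem and each downsampling stage."""
        sizes = [hw // 2]
        for _ in range(3):
            sizes.append(sizes[-1] // 2)
        if self.last_stage_valid:
            sizes.append((sizes[-1] - 3) // 2 + 1)
        else:
            sizes.append(sizes[-1] // 2)
        return sizes


# ---------------------------------------------------------------------------
# building blocks
# ---------------------------------------------------------------------------


def _conv_flops(cin: int, cout: int, kernel, n_out: int) -> int:
    return 2 * cin * cout * int(np.prod(kernel)) * n_out


class ConvBNAct(nn.Layer):
    def __init__(self, cin, cout, kernel, stride=(1, 1, 1), padding=(0, 0, 0),
                 act: bool = True, *, rng):
        super().__init__()
        self.conv = nn.Conv3d(cin, cout, kernel, stride, padding, bias=False, rng=rng)
        self.bn = nn.BatchNorm3d(cout)
        self.act = nn.SiLU() if act else None

    def forward(self, x):
        y = self.bn(self.conv(x))
        return self.act(y) if self.act is not None else y

    def backward(self, dy):
        if self.act is not None:
            dy = self.act.backward(dy)
        return self.conv.backward(self.bn.backward(dy))

    def profile(self, shape):
        C, D, H, W = shape
        k, s, p = self.conv.kernel, self.conv.stride, self.conv.padding
        Do = (D + 2 * p[0] - k[0]) // s[0] + 1
        Ho = (H + 2 * p[1] - k[1]) // s[1] + 1
        Wo = (W + 2 * p[2] - k[2]) // s[2] + 1
        out = (self.conv.cout, Do, Ho, Wo)
        return out, _conv_flops(C, self.conv.cout, k, Do * Ho * Wo)


class MV2Block(nn.Layer):
    """Inverted residual: pointwise expand -> depthwise 3x3x3 -> project.

    Striding is spatial-only; ``spatial_padding=0`` gives the unpadded
    final downsampling of the reference ladder (14 -> 6).
    """

    def __init__(self, cin, cout, stride=1, expansion=4, spatial_padding=1, *, rng):
        super().__init__()
        hidden = cin * expansion
        self.pw1 = ConvBNAct(cin, hidden, 1, rng=rng)
        self.dw = nn.DepthwiseConv3d(hidden, 3, stride=(1, stride, stride),
                                     padding=(1, spatial_padding, spatial_padding),
                                     bias=False, rng=rng)
        self.dw_bn = nn.BatchNorm3d(hidden)
        self.dw_act = nn.SiLU()
        self.pw2 = ConvBNAct(hidden, cout, 1, act=False, rng=rng)
        self.use_res = stride == 1 and cin == cout and spatial_padding == 1

    def forward(self, x):
        y = self.pw1(x)
        y = self.dw_act(self.dw_bn(self.dw(y)))
        y = self.pw2(y)
        return y + x if self.use_res else y

    def backward(self, dy):
        d = self.pw2.backward(dy)
        d = self.dw.backward(self.dw_bn.backward(self.dw_act.backward(d)))
        d = self.pw1.backward(d)
        return d + dy if self.use_res else d

    def profile(self, shape):
        (C1, D1, H1, W1), f1 = self.pw1.profile(shape)
        s, p = self.dw.stride, self.dw.padding
        Do = (D1 + 2 * p[0] - 3) // s[0] + 1
        Ho = (H1 + 2 * p[1] - 3) // s[1] + 1
        Wo = (W1 + 2 * p[2] - 3) // s[2] + 1
        f_dw = 2 * C1 * 27 * Do * Ho * Wo
        (C2, *_), f2 = self.pw2.profile((C1, Do, Ho, Wo))
        return (C2, Do, Ho, Wo), f1 + f_dw + f2


class _TransformerStack(nn.Layer):
    """L pre-norm Transformer layers with one global residual around them."""

    def __init__(self, dim, L, heads, mlp_ratio, *, rng):
        super().__init__()
        self.layers = [nn.TransformerLayer(dim, heads, mlp_ratio, rng=rng)
                       for _ in range(L)]

    def forward(self, tok):
        t = tok
        for layer in self.layers:
            t = layer(t)
        return t + tok

    def backward(self, dt):
        d = dt
        for layer in reversed(self.layers):
            d = layer.backward(d)
        return d + dt

    def profile(self, S, N, C):
        flops = 0
        for layer in self.layers:
            hidden = layer.fc1.cout
            flops += 2 * C * 3 * C * S * N          # qkv
            flops += 2 * C * C * S * N              # output projection
            flops += 2 * (C * hidden + hidden * C) * S * N  # MLP
            flops += 2 * 2 * N * N * C * S          # scores + attn @ V
        return flops


class MViTBlock(nn.Layer):
    """Hybrid block: local depthwise/pointwise convs, then Transformer
    layers over unfolded p^3 volumes (attention across the N volume axis,
    independently at each of the P = p^3 within-volume positions), folded
    back, projected, concatenated with the block input and fused."""

    def __init__(self, ch, L, p=2, heads=4, mlp_ratio=2.0, *, rng):
        super().__init__()
        self.ch, self.p = ch, p
        self.dw = nn.DepthwiseConv3d(ch, 3, padding=(1, 1, 1), bias=False, rng=rng)
        self.dw_bn = nn.BatchNorm3d(ch)
        self.dw_act = nn.SiLU()
        self.pw1 = ConvBNAct(ch, ch, 1, rng=rng)
        self.transformer = _TransformerStack(ch, L, heads, mlp_ratio, rng=rng)
        self.pw2 = ConvBNAct(ch, ch, 1, rng=rng)
        self.fusion = ConvBNAct(2 * ch, ch, 1, rng=rng)

    def _to_tokens(self, y):
        # (B, C, D, H, W) -> (B*P, N, C)
        B, C, D, H, W = y.shape
        self._dhw = (D, H, W)
        xu = unfold_volumes(y, self.p)          # (B, C, N, P)
        tok = np.ascontiguousarray(xu.transpose(0, 3, 2, 1))  # (B, P, N, C)
        P = self.p ** 3
        return tok.reshape(B * P, -1, C)

    def _from_tokens(self, tok, B):
        P = self.p ** 3
        S, N, C = tok.shape
        t = tok.reshape(B, P, N, C).transpose(0, 3, 2, 1)     # (B, C, N, P)
        return fold_volumes(np.ascontiguousarray(t), self.p, self._dhw)

    def forward(self, x):
        B = x.shape[0]
        y = self.dw_act(self.dw_bn(self.dw(x)))
        y = self.pw1(y)
        tok = self._to_tokens(y)
        tok = self.transformer(tok)
        y = self._from_tokens(tok, B)
        y = self.pw2(y)
        cat = np.concatenate([x, y], axis=1)
        return self.fusion(cat)

    def backward(self, dy):
        dcat = self.fusion.backward(dy)
        dx0, dyb = dcat[:, :self.ch], dcat[:, self.ch:]
        d = self.pw2.backward(np.ascontiguousarray(dyb))
        B = d.shape[0]
        dtok = self._to_tokens(d)  # same reshape path (linear, self-inverse pair)
        dtok = self.transformer.backward(dtok)
        d = self._from_tokens(dtok, B)
        d = self.pw1.backward(d)
        d = self.dw.backward(self.dw_bn.backward(self.dw_act.backward(d)))
        return d + np.ascontiguousarray(dx0)

    def profile(self, shape):
        C, D, H, W = shape
        n_vox = D * H * W
        flops = 2 * C * 27 * n_vox                      # depthwise
        _, f = self.pw1.profile(shape); flops += f
        P = self.p ** 3
        N = n_vox // P
        flops += self.transformer.profile(P, N, C)
        _, f = self.pw2.profile(shape); flops += f
        _, f = self.fusion.profile((2 * C,) + shape[1:]); flops += f
        return shape, flops


class ViTBlock(nn.Layer):
    """Slice-wise Transformer: one token per depth slice at each spatial
    location, with a learned per-slice position embedding."""

    def __init__(self, ch, L, depth, heads=4, mlp_ratio=2.0, *, rng):
        super().__init__()
        self.ch, self.depth = ch, depth
        self.pos = nn.Param(
            (0.02 * rng.standard_normal((1, 1, depth, ch))).astype(np.float32))
        self.transformer = _TransformerStack(ch, L, heads, mlp_ratio, rng=rng)

    def forward(self, x):
        B, C, D, H, W = x.shape
        if D != self.depth:
            raise ValueError(f"ViT block built for depth {self.depth}, got {D}")
        self._hw = (H, W)
        xu = unfold_slices(x)                              # (B, C, N=D, P)
        tok = np.ascontiguousarray(xu.transpose(0, 3, 2, 1))  # (B, P, N, C)
        tok = tok + self.pos.data
        self._shape = tok.shape
        tok = tok.reshape(B * H * W, D, C)
        out = self.transformer(tok)
        out = out.reshape(B, H * W, D, C).transpose(0, 3, 2, 1)
        return fold_slices(np.ascontiguousarray(out), self._hw)

    def backward(self, dy):
        B, C, D, H, W = dy.shape
        du = unfold_slices(dy)
        dtok = np.ascontiguousarray(du.transpose(0, 3, 2, 1)).reshape(B * H * W, D, C)
        dtok = self.transformer.backward(dtok)
        dtok = dtok.reshape(B, H * W, D, C)
        self.pos.grad += dtok.sum(axis=(0, 1), keepdims=True)
        dx = dtok.transpose(0, 3, 2, 1)
        return fold_slices(np.ascontiguousarray(dx), self._hw)

    def profile(self, shape):
        C, D, H, W = shape
        return shape, self.transformer.profile(H * W, D, C)


class ResidualBlock(nn.Layer):
    """3x1x1 -> 3x3x3 -> 3x1x1 conv path with a short connection; the
    shortcut is identity when channel counts match, else a 1x1x1
    projection."""

    def __init__(self, cin, cout, *, rng):
        super().__init__()
        self.conv1 = ConvBNAct(cin, cout, (3, 1, 1), padding=(1, 0, 0), rng=rng)
        self.conv2 = ConvBNAct(cout, cout, 3, padding=(1, 1, 1), rng=rng)
        self.conv3 = ConvBNAct(cout, cout, (3, 1, 1), padding=(1, 0, 0),
                               act=False, rng=rng)
        self.short = None if cin == cout else ConvBNAct(cin, cout, 1, act=False, rng=rng)
        self.out_act = nn.SiLU()

    def forward(self, x):
        y = self.conv3(self.conv2(self.conv1(x)))
        s = x if self.short is None else self.short(x)
        return self.out_act(y + s)

    def backward(self, dy):
        d = self.out_act.backward(dy)
        dpath = self.conv1.backward(self.conv2.backward(self.conv3.backward(d)))
        dshort = d if self.short is None else self.short.backward(d)
        return dpath + dshort

    def profile(self, shape):
        s1, f1 = self.conv1.profile(shape)
        s2, f2 = self.conv2.profile(s1)
        s3, f3 = self.conv3.profile(s2)
        f = f1 + f2 + f3
        if self.short is not None:
            _, fs = self.short.profile(shape)
            f += fs
        return s3, f


class DeconvLayer(nn.Layer):
    def __init__(self, cin, cout, spatial_padding=1, spatial_output_padding=1, *, rng):
        super().__init__()
        self.deconv = nn.ConvTranspose3d(
            cin, cout, 3, stride=(1, 2, 2),
            padding=(1, spatial_padding, spatial_padding),
            output_padding=(0, spatial_output_padding, spatial_output_padding),
            bias=False, rng=rng)
        self.bn = nn.BatchNorm3d(cout)
        self.act = nn.SiLU()

    def forward(self, x):
        return self.act(self.bn(self.deconv(x)))

    def backward(self, dy):
        return self.deconv.backward(self.bn.backward(self.act.backward(dy)))

    def profile(self, shape):
        C, D, H, W = shape
        Do, Ho, Wo = self.deconv.output_shape(D, H, W)
        return ((self.deconv.cout, Do, Ho, Wo),
                2 * C * self.deconv.cout * 27 * D * H * W)


# ---------------------------------------------------------------------------
# the model
# ---------------------------------------------------------------------------


class MoReT3D(nn.Layer):
    """Four-group encoder, slice-wise ViT bottleneck, five-stage decoder."""

    def __init__(self, cfg: ModelConfig = ModelConfig(), seed: int = 0):
        super().__init__()
        self.cfg = cfg
        rng = np.random.default_rng(seed)
        c1, c2, c3, c4, c5 = cfg.stage_widths
        d1, d2, d3, d4, d5 = cfg.decoder_widths
        e = cfg.mv2_expansion
        # group 1: conv stem, spatial stride 2
        self.stem = ConvBNAct(cfg.in_channels, c1, (1, 3, 3), stride=(1, 2, 2),
                              padding=(0, 1, 1), rng=rng)
        # group 2: two sets of [2 x MV2(s1), MV2(s2)]
        self.g2 = [
            MV2Block(c1, c1, 1, e, rng=rng), MV2Block(c1, c1, 1, e, rng=rng),
            MV2Block(c1, c2, 2, e, rng=rng),
            MV2Block(c2, c2, 1, e, rng=rng), MV2Block(c2, c2, 1, e, rng=rng),
            MV2Block(c2, c3, 2, e, rng=rng),
        ]
        # group 3: two sets of [MViT, MV2(s2)]
        last_pad = 0 if cfg.last_stage_valid else 1
        self.mvit1 = MViTBlock(c3, cfg.L_M[0], cfg.patch_p, cfg.heads,
                               cfg.mlp_ratio, rng=rng)
        self.down3 = MV2Block(c3, c4, 2, e, rng=rng)
        self.mvit2 = MViTBlock(c4, cfg.L_M[1], cfg.patch_p, cfg.heads,
                               cfg.mlp_ratio, rng=rng)
        self.down4 = MV2Block(c4, c5, 2, e, spatial_padding=last_pad, rng=rng)
        # group 4: pointwise -> slice-wise ViT -> pointwise to bottleneck
        self.pre_vit = ConvBNAct(c5, cfg.vit_dim, 1, rng=rng)
        self.vit = ViTBlock(cfg.vit_dim, cfg.L_V, cfg.depth, cfg.heads,
                            cfg.mlp_ratio, rng=rng)
        self.post_vit = ConvBNAct(cfg.vit_dim, cfg.bottleneck_channels, 1, rng=rng)
        # decoder
        sp, sop = (0, 1) if cfg.last_stage_valid else (1, 1)
        self.deconv1 = DeconvLayer(cfg.bottleneck_channels, d1, sp, sop, rng=rng)
        self.res1 = ResidualBlock(d1 + c4, d1, rng=rng)
        self.deconv2 = DeconvLayer(d1, d2, rng=rng)
        self.res2 = ResidualBlock(d2 + c3, d2, rng=rng)
        self.deconv3 = DeconvLayer(d2, d3, rng=rng)
        self.res3 = ResidualBlock(d3 + c2, d3, rng=rng)
        self.deconv4 = DeconvLayer(d3, d4, rng=rng)
        self.res4 = ResidualBlock(d4 + c1, d4, rng=rng)
        self.deconv5 = DeconvLayer(d4, d5, rng=rng)
        self.res5 = ResidualBlock(d5, d5, rng=rng)
        self.head = nn.Conv3d(d5, cfg.out_phases, 1, rng=rng,
                              weight_scale=float(np.sqrt(1.0 / d5)))
        if cfg.head_bias != 0.0 and self.head.bias is not None:
            self.head.bias.data[...] = cfg.head_bias
        self.tanh = nn.Tanh()
        self._skip_ch = (c1, c2, c3, c4)
        if cfg.bn_momentum != 0.1:
            for bn in self._iter_batchnorms(self):
                bn.momentum = cfg.bn_momentum
        if cfg.transformer_out_scale != 1.0:
            # damp the transformer residual branches at init (skip-init
            # style): the stack starts close to identity, which conditions
            # short CPU-scale training runs
            for blk in (self.mvit1, self.mvit2, self.vit):
                for layer in blk.transformer.layers:
                    layer.attn.proj.weight.data *= cfg.transformer_out_scale
                    layer.fc2.weight.data *= cfg.transformer_out_scale
        if cfg.residual_gamma != 1.0:
            # start residual branches near identity: speeds up early
            # optimisation of the deep stack (kept nonzero so gradients
            # reach every branch from the first step)
            for blk in (*self.g2, self.down3, self.down4):
                if blk.use_res:
                    blk.pw2.bn.gamma.data[...] = cfg.residual_gamma
            for res in (self.res1, self.res2, self.res3, self.res4, self.res5):
                res.conv3.bn.gamma.data[...] = cfg.residual_gamma

    @classmethod
    def _iter_batchnorms(cls, layer):
        for v in vars(layer).values():
            if isinstance(v, nn.BatchNorm3d):
                yield v
            elif isinstance(v, nn.Layer):
                yield from cls._iter_batchnorms(v)
            elif isinstance(v, (list, tuple)):
                for item in v:
                    if isinstance(item, nn.Layer):
                        yield from cls._iter_batchnorms(item)

    # -- forward / backward --------------------------------------------
    def forward(self, x: np.ndarray) -> np.ndarray:
        s1 = self.stem(x)
        y = s1
        for blk in self.g2[:3]:
            y = blk(y)
        s2 = y
        for blk in self.g2[3:]:
            y = blk(y)
        s3 = y
        y = self.down3(self.mvit1(y))
        s4 = y
        y = self.down4(self.mvit2(y))
        y = self.post_vit(self.vit(self.pre_vit(y)))
        self._bottleneck_shape = y.shape[1:]
        y = self.res1(np.concatenate([self.deconv1(y), s4], axis=1))
        y = self.res2(np.concatenate([self.deconv2(y), s3], axis=1))
        y = self.res3(np.concatenate([self.deconv3(y), s2], axis=1))
        y = self.res4(np.concatenate([self.deconv4(y), s1], axis=1))
        y = self.res5(self.deconv5(y))
        return self.tanh(self.head(y))

    def _split_skip(self, d, width):
        return (np.ascontiguousarray(d[:, :width]),
                np.ascontiguousarray(d[:, width:]))

    def backward(self, dy: np.ndarray) -> np.ndarray:
        # skip tensors s1..s4 each receive gradient from two paths: the
        # encoder main path and the decoder concat; the additions below
        # merge them at the point where each skip was taken.
        d = self.head.backward(self.tanh.backward(dy))
        d = self.deconv5.backward(self.res5.backward(d))
        d, ds1 = self._split_skip(self.res4.backward(d), self.cfg.decoder_widths[3])
        d = self.deconv4.backward(d)
        d, ds2 = self._split_skip(self.res3.backward(d), self.cfg.decoder_widths[2])
        d = self.deconv3.backward(d)
        d, ds3 = self._split_skip(self.res2.backward(d), self.cfg.decoder_widths[1])
        d = self.deconv2.backward(d)
        d, ds4 = self._split_skip(self.res1.backward(d), self.cfg.decoder_widths[0])
        d = self.deconv1.backward(d)
        d = self.pre_vit.backward(self.vit.backward(self.post_vit.backward(d)))
        d = self.mvit2.backward(self.down4.backward(d))
        d = d + ds4                      # at s4 (after first group-3 set)
        d = self.mvit1.backward(self.down3.backward(d))
        d = d + ds3                      # at s3 (after second group-2 set)
        for blk in reversed(self.g2[3:]):
            d = blk.backward(d)
        d = d + ds2                      # at s2 (after first group-2 set)
        for blk in reversed(self.g2[:3]):
            d = blk.backward(d)
        d = d + ds1                      # at s1 (stem output)
        return self.stem.backward(d)

    # -- profiling ------------------------------------------------------
    def profile(self, input_shape: tuple[int, int, int, int]) -> dict:
        """Static shape/FLOP walk at ``input_shape = (T, D, H, W)``."""
        T, D, H, W = input_shape
        if T != self.cfg.in_channels:
            raise ValueError(f"model expects {self.cfg.in_channels} time channels")
        flops = 0
        shape, f = self.stem.profile((T, D, H, W)); flops += f
        s1 = shape
        for blk in self.g2[:3]:
            shape, f = blk.profile(shape); flops += f
        s2 = shape
        for blk in self.g2[3:]:
            shape, f = blk.profile(shape); flops += f
        s3 = shape
        shape, f = self.mvit1.profile(shape); flops += f
        shape, f = self.down3.profile(shape); flops += f
        s4 = shape
        shape, f = self.mvit2.profile(shape); flops += f
        shape, f = self.down4.profile(shape); flops += f
        shape, f = self.pre_vit.profile(shape); flops += f
        shape, f = self.vit.profile(shape); flops += f
        shape, f = self.post_vit.profile(shape); flops += f
        bottleneck = shape
        for deconv, res, skip in (
                (self.deconv1, self.res1, s4), (self.deconv2, self.res2, s3),
                (self.deconv3, self.res3, s2), (self.deconv4, self.res4, s1),
                (self.deconv5, self.res5, None)):
            shape, f = deconv.profile(shape); flops += f
            if skip is not None:
                if shape[1:] != skip[1:]:
                    raise ValueError(
                        f"skip resolution mismatch: {shape[1:]} vs {skip[1:]}")
                shape = (shape[0] + skip[0],) + shape[1:]
            shape, f = res.profile(shape); flops += f
        n_out = shape[1] * shape[2] * shape[3]
        flops += 2 * shape[0] * self.cfg.out_phases * n_out
        out_shape = (self.cfg.out_phases,) + shape[1:]
        return {
            "input_shape": tuple(input_shape),
            "bottleneck_shape": tuple(bottleneck),
            "output_shape": out_shape,
            "parameters": self.num_parameters(),
            "flops": int(flops),
            "flop_convention": FLOP_CONVENTION,
        }

    def predict_array(self, x: np.ndarray) -> np.ndarray:
        """Inference forward pass (no gradient caching), batch handled."""
        squeeze = x.ndim == 4
        if squeeze:
            x = x[None]
        was_training = self.training
        self.eval()
        with nn.no_grad():
            y = self.forward(np.ascontiguousarray(x, dtype=np.float32))
        if was_training:
            self.train(True)
        return y[0] if squeeze else y


def build_model(cfg: ModelConfig = ModelConfig(), seed: int = 0) -> MoReT3D:
    return MoReT3D(cfg, seed=seed)


def count_parameters(model: MoReT3D) -> int:
    """Total number of trainable scalars."""
    return model.num_parameters()


def count_flops(model: MoReT3D, input_shape: tuple[int, int, int, int]) -> int:
    """Static FLOP count at the given (T, D, H, W) input shape."""
    return model.profile(input_shape)["flops"]


def profile_model(cfg: ModelConfig, input_shape: tuple[int, int, int, int],
                  seed: int = 0) -> dict:
    return MoReT3D(cfg, seed=seed).profile(input_shape)
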