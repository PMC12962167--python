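"""The heartbeat-probability network: a skip-connected 3D encoder-decoder
attention module followed by a convolutional prediction head.

Architecture
------------
The *attention enhancement module* (AEM) is a four-stage 3D convolutional
encoder (max-pooled to 1/16 of the spatial resolution, 1/4 of the temporal
length) mirrored by a transposed-convolution decoder with skip concatenation
at every scale.  Its final stage ends in a sigmoid and produces a 3-channel
spatiotemporal attention map ``A_st`` the same size as the input clip; the
enhanced clip is the elementwise product ``X* = X * A_st``.  The prediction
head compresses ``X*`` spatially with strided convolutions, projects to one
channel, averages over space, and applies a sigmoid, yielding one heartbeat
probability per frame.

Kernel sizes are not dictated by the stage widths; the defaults here use
spatially large kernels where the resolution is high (5x5 windows capture
skin-region context) and compact 3x3x3 kernels in the low-resolution core.
With these defaults the network has 536,392 learnable parameters (0.536 M)
and 43.270 G multiply-accumulates for a 3x128x128x128 clip — see
``count_parameters`` / ``count_macs``, which derive both numbers from the
configuration alone.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict

import numpy as np

from .layers import (BatchNorm3d, Conv3d, ConvTranspose3d, Layer, MaxPool3d,
                     Param, Sigmoid, SpatialGlobalAvgPool)

__all__ = ["NetConfig", "HbpNet", "build_model", "apply_attention",
           "count_parameters", "count_macs", "layer_table", "summary"]


@dataclass(frozen=True)
class NetConfig:
    """Structural description of the network; all counting derives from it."""

    in_channels: int = 3
    stage_widths: tuple[int, ...] = (12, 24, 48, 96)
    pool_schedule: tuple[tuple[int, int, int], ...] = (
        (1, 2, 2), (2, 2, 2), (2, 2, 2), (1, 2, 2))
    head_widths: tuple[int, ...] = (12, 24, 48, 24, 1)
    input_dims: tuple[int, int, int] = (160, 128, 128)  # (T, H, W)
    final_sigmoid: bool = True
    # kernels, high resolution to low: stem, then one per deeper encoder stage
    stem_kernel: tuple[int, int, int] = (3, 5, 5)
    encoder_kernel: tuple[int, int, int] = (3, 3, 3)
    # decoder conv kernels, low resolution to high (dec4, dec3, dec2, dec1)
    decoder_kernels: tuple[tuple[int, int, int], ...] = (
        (3, 3, 3), (3, 5, 5), (5, 5, 5), (1, 5, 5))
    # transposed-conv kernels, low to high (up4, up3, up2, up1)
    upsample_kernels: tuple[tuple[int, int, int], ...] = (
        (1, 2, 2), (3, 3, 3), (2, 2, 2), (1, 2, 2))
    # head: three strided stages then two projection convs
    head_kernels: tuple[tuple[int, int, int], ...] = (
        (1, 5, 5), (1, 5, 5), (3, 3, 3), (3, 3, 3), (1, 1, 1))

    def __post_init__(self) -> None:
        if len(self.stage_widths) != len(self.pool_schedule):
            raise ValueError("one pool per encoder stage required")
        if any(w <= 0 for w in self.stage_widths + self.head_widths):
            raise ValueError("widths must be positive")
        if self.head_widths[-1] != 1:
            raise ValueError("head must end in a single channel")
        t_factor = int(np.prod([p[0] for p in self.pool_schedule]))
        T, H, W = self.input_dims
        if T % t_factor:
            raise ValueError(
                f"temporal length {T} must be divisible by {t_factor}")
        s_factor = int(np.prod([p[1] for p in self.pool_schedule]))
        if H % s_factor or W % s_factor:
            raise ValueError(
                f"spatial dims {H}x{W} must be divisible by {s_factor}")

    @staticmethod
    def reduced(T: int = 64, H: int = 32, W: int = 32) -> "NetConfig":
        """Desk-scale variant (widths 4/8/16/32) for CPU experiments."""
        return NetConfig(stage_widths=(4, 8, 16, 32),
                         head_widths=(4, 8, 16, 8, 1),
                         input_dims=(T, H, W))


def _upsample_geometry(kernel, pool):
    """stride/padding/output_padding so a transposed conv inverts ``pool``."""
    stride = pool
    padding, out_pad = [], []
    for k, s in zip(kernel, pool):
        if k == s:            # exact unpooling tile
            padding.append(0)
            out_pad.append(0)
        elif k == 3 and s == 2:
            padding.append(1)
            out_pad.append(1)
        elif k == 3 and s == 1:
            padding.append(1)
            out_pad.append(0)
        elif k == 1 and s == 1:
            padding.append(0)
            out_pad.append(0)
        else:
            raise ValueError(f"unsupported upsample kernel/stride ({k}, {s})")
    return stride, tuple(padding), tuple(out_pad)


# --------------------------------------------------------------------------
# analytic accounting
# --------------------------------------------------------------------------

def layer_table(config: NetConfig, input_dims=None) -> list[dict]:
    """Per-layer listing with output dims, parameter and MAC counts.

    MACs follow the usual profiler convention: one multiply-accumulate per
    kernel tap per output element for convolutions and, symmetrically, per
    kernel tap per *input* element for transposed convolutions; pooling,
    normalization and activations are free.  Normalization parameters
    (scale + offset per channel) and biases are included in the parameter
    count.  Batch size does not enter (counts are per clip).
    """
    T, H, W = input_dims if input_dims is not None else config.input_dims
    rows: list[dict] = []

    def conv_row(name, cin, cout, kernel, dims, stride=(1, 1, 1), bn=True,
                 bias=None):
        if bias is None:
            bias = not bn
        out = tuple((d + 2 * (k // 2) - k) // s + 1
                    for d, k, s in zip(dims, kernel, stride))
        kvol = int(np.prod(kernel))
        params = cin * cout * kvol + (cout if bias else 0) + (2 * cout if bn else 0)
        macs = int(np.prod(out)) * cout * cin * kvol
        rows.append(dict(name=name, kind="conv", cin=cin, cout=cout,
                         kernel=kernel, stride=stride, out_dims=out,
                         params=params, macs=macs, bn=bn))
        return out

    def convt_row(name, cin, cout, kernel, pool, dims):
        out = tuple(d * s for d, s in zip(dims, pool))
        kvol = int(np.prod(kernel))
        params = cin * cout * kvol + cout
        macs = int(np.prod(dims)) * cin * cout * kvol  # input-element convention
        rows.append(dict(name=name, kind="convT", cin=cin, cout=cout,
                         kernel=kernel, stride=pool, out_dims=out,
                         params=params, macs=macs, bn=False))
        return out

    widths = config.stage_widths
    dims = (T, H, W)
    enc_dims = []
    cin = config.in_channels
    for i, (w, pool) in enumerate(zip(widths, config.pool_schedule)):
        kernel = config.stem_kernel if i == 0 else config.encoder_kernel
        dims = conv_row(f"enc{i + 1}", cin, w, kernel, dims)
        dims = tuple(d // p for d, p in zip(dims, pool))
        rows.append(dict(name=f"pool{i + 1}", kind="pool", cin=w, cout=w,
                         kernel=pool, stride=pool, out_dims=dims, params=0,
                         macs=0, bn=False))
        enc_dims.append(dims)
        cin = w

    # decoder: up4..up1 / dec4..dec1
    n = len(widths)
    for j in range(n - 1):
        level = n - 1 - j                    # 3, 2, 1 for the default depth
        up_k = config.upsample_kernels[j]
        pool = config.pool_schedule[level]
        dims = convt_row(f"up{level + 1}", widths[level], widths[level - 1],
                         up_k, pool, dims)
        dims = conv_row(f"dec{level + 1}", 2 * widths[level - 1],
                        widths[level - 1], config.decoder_kernels[j], dims)
    dims = convt_row("up1", widths[0], config.in_channels,
                     config.upsample_kernels[-1], config.pool_schedule[0], dims)
    dims = conv_row("dec1", 2 * config.in_channels, config.in_channels,
                    config.decoder_kernels[-1], dims)

    # head on X* (attention-weighted input)
    hw = config.head_widths
    dims = (T, H, W)
    cin = config.in_channels
    for i in range(3):
        dims = conv_row(f"head{i + 1}", cin, hw[i], config.head_kernels[i],
                        dims, stride=(1, 2, 2))
        cin = hw[i]
    dims = conv_row("tail1", cin, hw[3], config.head_kernels[3], dims,
                    bn=False, bias=True)
    dims = conv_row("tail2", hw[3], hw[4], config.head_kernels[4], dims,
                    bn=False, bias=True)
    rows.append(dict(name="gap", kind="pool", cin=1, cout=1,
                     kernel=(1, dims[1], dims[2]), stride=(1, 1, 1),
                     out_dims=(dims[0], 1, 1), params=0, macs=0, bn=False))
    return rows


def count_parameters(config: NetConfig) -> int:
    """Total learnable parameters, from the configuration alone."""
    return sum(r["params"] for r in layer_table(config))


def count_macs(config: NetConfig, input_dims=None) -> int:
    """Per-clip multiply-accumulate count for the given input dims."""
    return sum(r["macs"] for r in layer_table(config, input_dims))


def summary(config: NetConfig, input_dims=None) -> str:
    """Printable stage table with shapes, parameters and MACs."""
    rows = layer_table(config, input_dims)
    lines = [f"{'layer':<8}{'kind':<7}{'c_in':>5}{'c_out':>6}{'kernel':>12}"
             f"{'out (T,H,W)':>18}{'params':>10}{'MACs':>15}"]
    for r in rows:
        lines.append(f"{r['name']:<8}{r['kind']:<7}{r['cin']:>5}{r['cout']:>6}"
                     f"{str(r['kernel']):>12}{str(r['out_dims']):>18}"
                     f"{r['params']:>10}{r['macs']:>15}")
    total_p = sum(r["params"] for r in rows)
    total_m = sum(r["macs"] for r in rows)
    lines.append(f"{'total':<38}{total_p:>10}{total_m:>15}"
                 f"   ({total_p / 1e6:.3f} M params, {total_m / 1e9:.3f} G MACs)")
    return "\n".join(lines)


# --------------------------------------------------------------------------
# the network
# --------------------------------------------------------------------------

def apply_attention(x: np.ndarray, a: np.ndarray) -> np.ndarray:
    """Elementwise attention weighting ``X* = X * A_st``."""
    if x.shape != a.shape:
        raise ValueError(f"shape mismatch {x.shape} vs {a.shape}")
    return x * a


class HbpNet:
    """Numpy implementation of the heartbeat-probability network."""

    def __init__(self, config: NetConfig, seed: int = 0):
        self.config = config
        widths = config.stage_widths
        cin = config.in_channels

        self.enc_convs: list[Conv3d] = []
        self.enc_bns: list[BatchNorm3d] = []
        self.enc_pools: list[MaxPool3d] = []
        for i, (w, pool) in enumerate(zip(widths, config.pool_schedule)):
            kernel = config.stem_kernel if i == 0 else config.encoder_kernel
            self.enc_convs.append(Conv3d(cin, w, kernel, name=f"enc{i + 1}"))
            self.enc_bns.append(BatchNorm3d(w, name=f"enc{i + 1}.bn"))
            self.enc_pools.append(MaxPool3d(pool, name=f"pool{i + 1}"))
            cin = w

        n = len(widths)
        self.ups: list[ConvTranspose3d] = []
        self.dec_convs: list[Conv3d] = []
        self.dec_bns: list[BatchNorm3d] = []
        for j in range(n - 1):
            level = n - 1 - j
            kernel = config.upsample_kernels[j]
            pool = config.pool_schedule[level]
            stride, pad, opad = _upsample_geometry(kernel, pool)
            self.ups.append(ConvTranspose3d(widths[level], widths[level - 1],
                                            kernel, stride, pad, opad,
                                            name=f"up{level + 1}"))
            self.dec_convs.append(Conv3d(2 * widths[level - 1],
                                         widths[level - 1],
                                         config.decoder_kernels[j],
                                         name=f"dec{level + 1}"))
            self.dec_bns.append(BatchNorm3d(widths[level - 1],
                                            name=f"dec{level + 1}.bn"))
        stride, pad, opad = _upsample_geometry(config.upsample_kernels[-1],
                                               config.pool_schedule[0])
        self.ups.append(ConvTranspose3d(widths[0], config.in_channels,
                                        config.upsample_kernels[-1], stride,
                                        pad, opad, name="up1"))
        self.dec_convs.append(Conv3d(2 * config.in_channels,
                                     config.in_channels,
                                     config.decoder_kernels[-1], name="dec1"))
        self.dec_bns.append(BatchNorm3d(config.in_channels, name="dec1.bn"))
        self.att_sigmoid = Sigmoid("att.sigmoid")

        hw = config.head_widths
        cin = config.in_channels
        self.head_convs: list[Conv3d] = []
        self.head_bns: list[BatchNorm3d] = []
        for i in range(3):
            self.head_convs.append(Conv3d(cin, hw[i], config.head_kernels[i],
                                          stride=(1, 2, 2), name=f"head{i + 1}"))
            self.head_bns.append(BatchNorm3d(hw[i], name=f"head{i + 1}.bn"))
            cin = hw[i]
        self.tail1 = Conv3d(cin, hw[3], config.head_kernels[3], bias=True,
                            name="tail1")
        self.tail2 = Conv3d(hw[3], hw[4], config.head_kernels[4], bias=True,
                            name="tail2")
        self.gap = SpatialGlobalAvgPool()
        self.out_sigmoid = Sigmoid("out.sigmoid")

        self._relu_cache: dict[str, np.ndarray] = {}
        self.initialize(seed)

    # -- parameter plumbing -------------------------------------------------
    def _layers_with_params(self) -> list[Layer]:
        out: list[Layer] = []
        for c, b in zip(self.enc_convs, self.enc_bns):
            out += [c, b]
        for u, c, b in zip(self.ups, self.dec_convs, self.dec_bns):
            out += [u, c, b]
        out += self.head_convs[:1] + [self.head_bns[0]]
        out += [self.head_convs[1], self.head_bns[1],
                self.head_convs[2], self.head_bns[2], self.tail1, self.tail2]
        return out

    def params(self) -> list[Param]:
        ps: list[Param] = []
        for layer in self._layers_with_params():
            ps.extend(layer.params())
        return ps

    def n_parameters(self) -> int:
        return sum(p.size for p in self.params())

    def initialize(self, seed: int) -> None:
        rng = np.random.default_rng(seed)
        for layer in self._layers_with_params():
            layer.init(rng)

    def zero_grad(self) -> None:
        for p in self.params():
            p.grad[...] = 0.0

    def state_dict(self) -> dict[str, np.ndarray]:
        state = {p.name: p.value.copy() for p in self.params()}
        for b in self.enc_bns + self.dec_bns + self.head_bns:
            state[f"{b.name}.running_mean"] = b.running_mean.copy()
            state[f"{b.name}.running_var"] = b.running_var.copy()
        return state

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        for p in self.params():
            p.value[...] = state[p.name]
        for b in self.enc_bns + self.dec_bns + self.head_bns:
            b.running_mean[...] = state[f"{b.name}.running_mean"]
            b.running_var[...] = state[f"{b.name}.running_var"]

    def save(self, path) -> None:
        state = self.state_dict()
        state["__config__"] = np.frombuffer(
            json.dumps(asdict(self.config)).encode(), dtype=np.uint8)
        np.savez(path, **state)

    @classmethod
    def load(cls, path) -> "HbpNet":
        with np.load(path) as data:
            cfg_raw = json.loads(bytes(data["__config__"]).decode())
            for k in ("stage_widths", "head_widths", "input_dims"):
                cfg_raw[k] = tuple(cfg_raw[k])
            for k in ("pool_schedule", "decoder_kernels", "upsample_kernels",
                      "head_kernels"):
                cfg_raw[k] = tuple(tuple(v) for v in cfg_raw[k])
            cfg_raw["stem_kernel"] = tuple(cfg_raw["stem_kernel"])
            cfg_raw["encoder_kernel"] = tuple(cfg_raw["encoder_kernel"])
            model = cls(NetConfig(**cfg_raw))
            model.load_state_dict({k: data[k] for k in data.files
                                   if k != "__config__"})
        return model

    # -- forward / backward -------------------------------------------------
    def _check_input(self, x: np.ndarray) -> None:
        T, H, W = self.config.input_dims
        expect = (self.config.in_channels, T, H, W)
        if x.ndim != 5 or x.shape[1:] != expect:
            raise ValueError(
                f"input: clip of shape {x.shape[1:] if x.ndim == 5 else x.shape}"
                f" does not match configured {expect}")

    def forward(self, x: np.ndarray, training: bool = False,
                return_stages: bool = False):
        """Run the network.

        Returns ``(hbp, attention)`` where ``hbp`` is (B, T) in [0, 1] and
        ``attention`` is the (B, C, T, H, W) map ``A_st``.  With
        ``return_stages`` a dict of named intermediate shapes is added.
        """
        x = np.ascontiguousarray(x, dtype=np.float32)
        self._check_input(x)
        tr = training
        stages: dict[str, tuple] = {}
        relus = self._relu_cache = {}

        skips = []
        h = x
        for i, (conv, bn, pool) in enumerate(zip(self.enc_convs, self.enc_bns,
                                                 self.enc_pools)):
            h = bn.forward(conv.forward(h, tr), tr)
            if tr:
                relus[conv.name] = h > 0
            h = np.maximum(h, 0.0)
            h = pool.forward(h, tr)
            skips.append(h)
            stages[f"Enc{i + 1}"] = h.shape[1:]

        n = len(self.enc_convs)
        for j in range(n - 1):
            up, conv, bn = self.ups[j], self.dec_convs[j], self.dec_bns[j]
            h = up.forward(h, tr)
            h = np.concatenate([h, skips[n - 2 - j]], axis=1)
            h = bn.forward(conv.forward(h, tr), tr)
            if tr:
                relus[conv.name] = h > 0
            h = np.maximum(h, 0.0)
            stages[f"Dec{n - j}"] = h.shape[1:]
        h = self.ups[-1].forward(h, tr)
        h = np.concatenate([h, x], axis=1)
        h = self.dec_bns[-1].forward(self.dec_convs[-1].forward(h, tr), tr)
        a_st = self.att_sigmoid.forward(h, tr)
        stages["Dec1"] = a_st.shape[1:]

        x_star = x * a_st
        if tr:
            self._att_inputs = (x, a_st)

        h = x_star
        for i, (conv, bn) in enumerate(zip(self.head_convs, self.head_bns)):
            h = bn.forward(conv.forward(h, tr), tr)
            if tr:
                relus[conv.name] = h > 0
            h = np.maximum(h, 0.0)
            stages[("Head1", "Out2", "Head3")[i]] = h.shape[1:]
        h = self.tail1.forward(h, tr)
        h = self.tail2.forward(h, tr)
        stages["Out1"] = h.shape[1:]
        h = self.gap.forward(h, tr)
        hbp = h[:, 0, :, 0, 0]
        if self.config.final_sigmoid:
            hbp = self.out_sigmoid.forward(hbp, tr)
        stages["Out"] = hbp.shape[1:]

        if return_stages:
            return hbp, a_st, stages
        return hbp, a_st

    def backward(self, dhbp: np.ndarray) -> None:
        """Accumulate parameter gradients from d(loss)/d(hbp), shape (B, T)."""
        relus = self._relu_cache
        g = dhbp.astype(np.float32)
        if self.config.final_sigmoid:
            g = self.out_sigmoid.backward(g)
        g = self.gap.backward(g[:, None, :, None, None])
        g = self.tail2.backward(g)
        g = self.tail1.backward(g)
        for conv, bn in zip(reversed(self.head_convs), reversed(self.head_bns)):
            g = g * relus[conv.name]
            g = conv.backward(bn.backward(g))

        x, a_st = self._att_inputs
        dx_total = g * a_st          # gradient into the raw clip via X*
        g = g * x                    # gradient into the attention map

        g = self.att_sigmoid.backward(g)
        g = self.dec_convs[-1].backward(self.dec_bns[-1].backward(g))
        cin = self.config.in_channels
        g, dx_skip = g[:, :cin], g[:, cin:]
        dx_total = dx_total + dx_skip
        g = self.ups[-1].backward(g)

        n = len(self.enc_convs)
        skip_grads: list[np.ndarray | None] = [None] * n
        for j in range(n - 2, -1, -1):
            up, conv, bn = self.ups[j], self.dec_convs[j], self.dec_bns[j]
            g = g * relus[conv.name]
            g = conv.backward(bn.backward(g))
            w = self.config.stage_widths[n - 2 - j]
            g, skip = g[:, :w], g[:, w:]
            skip_grads[n - 2 - j] = skip
            g = up.backward(g)

        # top of the decoder feeds the deepest pooled encoder output
        for i in range(n - 1, -1, -1):
            conv, bn, pool = self.enc_convs[i], self.enc_bns[i], self.enc_pools[i]
            if i < n - 1 and skip_grads[i] is not None:
                g = g + skip_grads[i]
            g = pool.backward(g)
            g = g * relus[conv.name]
            g = conv.backward(bn.backward(g))
        # g is now the gradient w.r.t. the input clip through the encoder;
        # dx_total carries the multiplicative and skip paths (unused further).
        self._relu_cache = {}


def build_model(config: NetConfig, seed: int = 0) -> HbpNet:
    """Instantiate the network with seeded, deterministic initialization."""
    return HbpNet(config, seed)
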