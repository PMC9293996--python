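"""The anisotropic U-Net: construction, shape propagation, tiled inference.

The architecture is an encoder-decoder with five resolution levels (default)
and valid convolutions only. In-plane convolutions are 3x3x1; at the three
lowest-resolution levels each in-plane convolution is followed by two
through-plane 1x1x3 convolutions. Downsampling is 2x2x1 max pooling,
upsampling 2x2x1 transposed convolution, so the slice axis is never
resampled. Skip connections center-crop the encoder feature map to the
decoder extent before concatenation. Each convolution except the final 1x1x1
output convolution is followed by batch normalization and ReLU; dropout sits
after the bottleneck block. The final activation is a single-channel sigmoid
(foreground probability).

Because every convolution is valid, the output patch is smaller than the
input patch by a fixed symmetric margin: with the default configuration an
input of 236x236x72 voxels yields a 52x52x32 output, i.e. a margin of
92x92x20 per side. The margin is a property of the architecture alone and
identical for every admissible input extent. Through-plane budget of the
default net: the bottleneck path crosses five blocks with through-plane
convolutions (encoder levels 3 and 4, the bottleneck, decoder levels 4 and
3), each carrying 2 convs x 2 stacked 1x1x3 = 4 slice-reducing convolutions,
20 in total -- exactly the 20-slice margin.
"""

from __future__ import annotations

import io
import json
import zipfile
from dataclasses import dataclass

import numpy as np

from ..config import NetworkConfig
from ..volume import MaskVolume, Volume
from .layers import (BatchNormReLU, Conv3d, ConvTranspose221, Dropout,
                     GeometryError, Layer, MaxPool221, Param, center_crop, sigmoid)

__all__ = [
    "PatchGeometry", "AUNet", "build_network", "compute_patch_geometry",
    "count_parameters", "predict_volume", "reflect_pad", "GeometryError",
]


@dataclass(frozen=True)
class PatchGeometry:
    """Input/output patch extents and the symmetric margin between them."""

    input_extent: tuple[int, int, int]
    output_extent: tuple[int, int, int]
    margin: tuple[int, int, int]

    def __post_init__(self) -> None:
        for i, o, m in zip(self.input_extent, self.output_extent, self.margin):
            if i != o + 2 * m or o < 1:
                raise ValueError(
                    f"inconsistent geometry: input {self.input_extent}, "
                    f"output {self.output_extent}, margin {self.margin}")


def _block_kernels(cfg: NetworkConfig, level: int, full3d: bool) -> list[tuple[int, int, int]]:
    """Kernel sequence of one convolution block at a 1-based level."""
    inplane = (3, 3, 3) if full3d else (3, 3, 1)
    kernels: list[tuple[int, int, int]] = []
    with_z = (not full3d) and level in cfg.zconv_levels
    for _ in range(2):
        kernels.append(inplane)
        if with_z:
            kernels.extend([(1, 1, 3)] * cfg.zconvs_per_conv)
    return kernels


class _Block:
    """A convolution block: sequence of (conv, BN, ReLU) units."""

    def __init__(self, cfg: NetworkConfig, level: int, cin: int, cout: int,
                 rng: np.random.Generator, name: str) -> None:
        self.layers: list[Layer] = []
        c = cin
        for i, kernel in enumerate(_block_kernels(cfg, level, full3d=False)):
            self.layers.append(Conv3d(c, cout, kernel, rng, name=f"{name}.conv{i}"))
            self.layers.append(BatchNormReLU(cout, name=f"{name}.bn{i}"))
            c = cout

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x, training)
        return x

    def backward(self, gy: np.ndarray) -> np.ndarray:
        for layer in reversed(self.layers):
            gy = layer.backward(gy)
        return gy

    def params(self) -> list[Param]:
        return [p for layer in self.layers for p in layer.params()]


class AUNet:
    """Anisotropic U-Net with explicit forward and backward passes."""

    def __init__(self, cfg: NetworkConfig, seed: int = 0) -> None:
        self.cfg = cfg
        self.seed = seed
        rng = np.random.default_rng(seed)
        self._dropout_rng = np.random.default_rng(
            np.random.SeedSequence([seed, 0x0D0]))
        L = cfg.levels
        self.enc_blocks: list[_Block] = []
        self.pools: list[MaxPool221] = []
        cin = 1
        for l in range(L):
            cout = cfg.features(l + 1)
            self.enc_blocks.append(_Block(cfg, l + 1, cin, cout, rng, f"enc{l + 1}"))
            if l < L - 1:
                self.pools.append(MaxPool221(name=f"pool{l + 1}"))
            cin = cout
        self.dropout = Dropout(cfg.dropout, self._dropout_rng, name="dropout")
        self.ups: list[ConvTranspose221] = []
        self.dec_blocks: list[_Block] = []
        for l in range(L - 2, -1, -1):
            cout = cfg.features(l + 1)
            self.ups.append(ConvTranspose221(cfg.features(l + 2), cout, rng,
                                             name=f"up{l + 1}"))
            self.dec_blocks.append(_Block(cfg, l + 1, 2 * cout, cout, rng,
                                          f"dec{l + 1}"))
        self.final = Conv3d(cfg.features(1), 1, (1, 1, 1), rng, name="final")
        self.enc_blocks[0].layers[0].needs_input_grad = False
        self._cache: dict | None = None

    # ------------------------------------------------------------------ api

    def params(self) -> list[Param]:
        out: list[Param] = []
        for b in self.enc_blocks:
            out += b.params()
        for up, b in zip(self.ups, self.dec_blocks):
            out += up.params() + b.params()
        out += self.final.params()
        return out

    def zero_grad(self) -> None:
        for p in self.params():
            p.zero_grad()

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        """Map an input patch batch (N,1,X,Y,Z) to foreground probabilities."""
        L = self.cfg.levels
        skips: list[np.ndarray] = []
        h = np.ascontiguousarray(x, dtype=np.float32)
        for l in range(L - 1):
            h = self.enc_blocks[l].forward(h, training)
            skips.append(h)
            h = self.pools[l].forward(h, training)
        h = self.enc_blocks[L - 1].forward(h, training)
        h = self.dropout.forward(h, training)
        crop_info: list[tuple[tuple[int, ...], tuple[slice, ...]]] = []
        for i, l in enumerate(range(L - 2, -1, -1)):
            h = self.ups[i].forward(h, training)
            skip = skips[l]
            target = h.shape[2:]
            slices = [slice(None), slice(None)]
            for axis, (have, want) in enumerate(zip(skip.shape[2:], target)):
                diff = have - want
                if diff < 0 or diff % 2:
                    raise GeometryError(
                        f"skip{l + 1}", f"cannot crop {have} to {want} on axis {axis}")
                slices.append(slice(diff // 2, diff // 2 + want))
            crop_info.append((skip.shape, tuple(slices)))
            h = np.concatenate([skip[tuple(slices)], h], axis=1)
            h = self.dec_blocks[i].forward(h, training)
        z = self.final.forward(h, training)
        p = sigmoid(z)
        if training:
            self._cache = {"p": p, "crop_info": crop_info}
        return p

    def backward(self, gp: np.ndarray) -> None:
        """Backpropagate dLoss/dProbability; accumulates parameter gradients."""
        assert self._cache is not None, "backward requires a training-mode forward"
        p = self._cache["p"]
        crop_info = self._cache["crop_info"]
        L = self.cfg.levels
        gz = (gp * p * (1.0 - p)).astype(np.float32)
        g = self.final.backward(gz)
        skip_grads: dict[int, np.ndarray] = {}
        for i in range(L - 2, -1, -1):
            l = L - 2 - i           # encoder level index fed by this skip
            g = self.dec_blocks[i].backward(g)
            skip_ch = self.dec_blocks[i].layers[0].cin // 2  # type: ignore[attr-defined]
            gskip, gh = g[:, :skip_ch], g[:, skip_ch:]
            shape, slices = crop_info[i]
            full = np.zeros(shape, np.float32)
            full[slices] = gskip
            skip_grads[l] = full
            g = self.ups[i].backward(np.ascontiguousarray(gh))
        g = self.dropout.backward(g)
        g = self.enc_blocks[L - 1].backward(g)
        for l in range(L - 2, -1, -1):
            g = self.pools[l].backward(g)
            g = g + skip_grads[l]
            g = self.enc_blocks[l].backward(g)
        self._cache = None

    # ----------------------------------------------------------- persistence

    def state_dict(self) -> dict[str, np.ndarray]:
        state = {p.name: p.value for p in self.params()}
        for b in self.enc_blocks + self.dec_blocks:
            for layer in b.layers:
                if isinstance(layer, BatchNormReLU):
                    state[f"{layer.name}.running_mean"] = layer.running_mean
                    state[f"{layer.name}.running_var"] = layer.running_var
        return state

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        for p in self.params():
            p.value[...] = state[p.name]
        for b in self.enc_blocks + self.dec_blocks:
            for layer in b.layers:
                if isinstance(layer, BatchNormReLU):
                    layer.running_mean[...] = state[f"{layer.name}.running_mean"]
                    layer.running_var[...] = state[f"{layer.name}.running_var"]


def build_network(cfg: NetworkConfig, seed: int = 0) -> AUNet:
    """Construct a randomly initialized anisotropic U-Net."""
    return AUNet(cfg, seed=seed)


# ------------------------------------------------------------------ geometry

def _trace(cfg: NetworkConfig, extent: tuple[int, int, int]) -> tuple[int, int, int]:
    """Propagate a spatial extent symbolically through every layer."""

    def conv(e: tuple[int, int, int], k: tuple[int, int, int], name: str):
        out = tuple(a - b + 1 for a, b in zip(e, k))
        if any(o < 1 for o in out):
            raise GeometryError(name, f"extent {e} too small for kernel {k}")
        return out

    L = cfg.levels
    e = tuple(int(v) for v in extent)
    if len(e) != 3 or any(v < 1 for v in e):
        raise GeometryError("input", f"invalid input extent {extent}")
    skips: list[tuple[int, int, int]] = []
    for l in range(L):
        for i, k in enumerate(_block_kernels(cfg, l + 1, full3d=False)):
            e = conv(e, k, f"enc{l + 1}.conv{i}")
        if l < L - 1:
            skips.append(e)
            if e[0] % 2 or e[1] % 2:
                raise GeometryError(f"pool{l + 1}", f"in-plane extent {e[:2]} must be even")
            e = (e[0] // 2, e[1] // 2, e[2])
    for i, l in enumerate(range(L - 2, -1, -1)):
        e = (2 * e[0], 2 * e[1], e[2])
        skip = skips[l]
        for axis in range(3):
            diff = skip[axis] - e[axis]
            if diff < 0 or diff % 2:
                raise GeometryError(
                    f"skip{l + 1}", f"cannot center-crop {skip[axis]} to {e[axis]} on axis {axis}")
        for j, k in enumerate(_block_kernels(cfg, l + 1, full3d=False)):
            e = conv(e, k, f"dec{l + 1}.conv{j}")
    return e  # final 1x1x1 conv leaves the extent unchanged


def compute_patch_geometry(cfg: NetworkConfig,
                           input_extent: tuple[int, int, int]) -> PatchGeometry:
    """Exact output extent and symmetric margin for a given input extent.

    Raises :class:`GeometryError` (naming the offending layer) if the extent
    is not admissible. The margin is identical for all admissible extents --
    a consequence of using only valid convolutions.
    """
    out = _trace(cfg, input_extent)
    margin = tuple((i - o) // 2 for i, o in zip(input_extent, out))
    return PatchGeometry(tuple(int(v) for v in input_extent), out, margin)  # type: ignore[arg-type]


def count_parameters(cfg: NetworkConfig, full3d: bool = False) -> int:
    """Number of trainable parameters, computed symbolically.

    With ``full3d=True`` every convolution is counted as an isotropic 3x3x3
    convolution (the through-plane 1x1x3 convolutions are absorbed), i.e. the
    corresponding full 3D U-Net. The anisotropic net is strictly smaller.
    """
    total = 0

    def add_conv(cin: int, cout: int, k: tuple[int, int, int]) -> None:
        nonlocal total
        total += cout * cin * int(np.prod(k)) + cout   # weights + bias
        total += 2 * cout                              # batch-norm gamma/beta

    L = cfg.levels
    cin = 1
    for l in range(L):
        cout = cfg.features(l + 1)
        c = cin
        for k in _block_kernels(cfg, l + 1, full3d):
            add_conv(c, cout, k)
            c = cout
        cin = cout
    for l in range(L - 2, -1, -1):
        cout = cfg.features(l + 1)
        total += cfg.features(l + 2) * cout * 4 + cout  # transposed conv
        c = 2 * cout
        for k in _block_kernels(cfg, l + 1, full3d):
            add_conv(c, cout, k)
            c = cout
    total += cfg.features(1) * 1 * 1 + 1                # final conv, no BN
    return total


# ----------------------------------------------------------------- inference

def reflect_pad(data: np.ndarray, pad: tuple[int, int, int]) -> np.ndarray:
    """Mirror-pad by an arbitrary amount (larger than the array if needed)."""
    out = data
    remaining = [int(p) for p in pad]
    while any(r > 0 for r in remaining):
        step = [min(r, out.shape[ax] - 1) for ax, r in enumerate(remaining)]
        if any(s <= 0 < r for s, r in zip(step, remaining)):
            raise ValueError("cannot mirror-pad a singleton axis")
        out = np.pad(out, [(s, s) for s in step], mode="reflect")
        remaining = [r - s for r, s in zip(remaining, step)]
    return out


def predict_volume(net: AUNet, v: Volume, liver: MaskVolume,
                   geometry: PatchGeometry) -> Volume:
    """Tile the liver bounding box with output windows and run inference.

    Each output window's input window (expanded by the symmetric margin) is
    read with mirror padding where it exceeds the volume. Tiles do not
    overlap, and because the network is purely valid-convolutional the
    result is independent of tile traversal order. Voxels outside all tiles
    are 0.
    """
    v.check_same_grid(liver)
    out = np.zeros(v.shape, np.float32)
    fg = np.argwhere(liver.data > 0)
    if fg.size == 0:
        return Volume(out, v.spacing, v.origin)
    lo = fg.min(axis=0)
    hi = fg.max(axis=0) + 1
    oext = geometry.output_extent
    margin = geometry.margin
    pad = tuple(m + o for m, o in zip(margin, oext))
    padded = reflect_pad(np.ascontiguousarray(v.data, dtype=np.float32), pad)
    for ox in range(lo[0], hi[0], oext[0]):
        for oy in range(lo[1], hi[1], oext[1]):
            for oz in range(lo[2], hi[2], oext[2]):
                origin = (ox, oy, oz)
                start = [o + p - m for o, p, m in zip(origin, pad, margin)]
                stop = [s + e + 2 * m for s, e, m in zip(start, oext, margin)]
                win = padded[start[0]:stop[0], start[1]:stop[1], start[2]:stop[2]]
                prob = net.forward(win[None, None], training=False)[0, 0]
                keep = [min(e, s - o) for e, s, o in zip(oext, v.shape, origin)]
                out[ox:ox + keep[0], oy:oy + keep[1], oz:oz + keep[2]] = \
                    prob[:keep[0], :keep[1], :keep[2]]
    return Volume(out, v.spacing, v.origin)


# --------------------------------------------------------------- checkpoints

CHECKPOINT_VERSION = 1


def save_checkpoint(path: str, net: AUNet, iteration: int,
                    extra: dict | None = None) -> None:
    """Write weights + NetworkConfig + iteration to a single .npz-style file."""
    from dataclasses import asdict

    meta = {
        "version": CHECKPOINT_VERSION,
        "config": asdict(net.cfg),
        "seed": net.seed,
        "iteration": int(iteration),
        "extra": extra or {},
    }
    arrays = dict(net.state_dict())
    buf = io.BytesIO()
    np.savez(buf, **arrays)
    with zipfile.ZipFile(path, "w") as zf:
        zf.writestr("meta.json", json.dumps(meta))
        zf.writestr("arrays.npz", buf.getvalue())


def load_checkpoint(path: str) -> tuple[AUNet, int, dict]:
    """Rebuild a network from a checkpoint; returns (net, iteration, extra)."""
    with zipfile.ZipFile(path) as zf:
        meta = json.loads(zf.read("meta.json"))
        if meta["version"] != CHECKPOINT_VERSION:
            raise ValueError(f"unsupported checkpoint version {meta['version']}")
        with zf.open("arrays.npz") as fh:
            arrays = dict(np.load(io.BytesIO(fh.read())))
    cfg_dict = meta["config"]
    cfg_dict["zconv_levels"] = tuple(cfg_dict["zconv_levels"])
    cfg = NetworkConfig(**cfg_dict)
    net = AUNet(cfg, seed=meta["seed"])
    net.load_state_dict(arrays)
    return net, meta["iteration"], meta["extra"]
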