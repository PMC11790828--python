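"""Framework-agnostic forward semantics of the SPPMC and UECA blocks.

Feature maps are plain ``(C, H, W)`` numpy arrays.  The module provides

* :func:`receptive_field` — the classical receptive-field recurrence
  ``R_1 = k_1``, ``R_n = R_{n-1} + (k_n - 1) * prod(s_i, i < n)``;
* :func:`max_pool_same` — stride-1, shape-preserving sliding-window
  maximum (padding never wins: pad values act as ``-inf``);
* SPPMC — a six-branch CSP-style spatial-pyramid-pooling block whose
  pre-fusion branches realize receptive fields {1, 5, 7, 11, 15, 19}
  with the default pooling-kernel ladder 5, 9, 13, 17;
* UECA — a joint attention block running a squeeze-excitation channel
  gate and a coordinate-attention spatial gate in parallel and summing
  the two gated copies of the input.

All forward passes are deterministic given weights; the module is
inference-semantics only (no optimizer, no training).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view
from scipy.ndimage import maximum_filter

__all__ = [
    "LayerSpec",
    "SPPMCSpec",
    "UECAParams",
    "AttentionMaps",
    "receptive_field",
    "max_pool_same",
    "conv2d_same",
    "sppmc_branch_layers",
    "sppmc_branch_receptive_fields",
    "init_sppmc_params",
    "identity_sppmc_params",
    "sppmc_forward",
    "ueca_gates",
    "ueca_forward",
    "save_params",
    "load_params",
]


# ---------------------------------------------------------------------------
# activations
# ---------------------------------------------------------------------------

def silu(x: np.ndarray) -> np.ndarray:
    return x / (1.0 + np.exp(-x))


def relu(x: np.ndarray) -> np.ndarray:
    return np.maximum(x, 0.0)


def sigmoid(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-x))


_ACTIVATIONS = {"silu": silu, "relu": relu, "identity": lambda x: x}


def _check_feature_tensor(x: np.ndarray) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    if x.ndim != 3:
        raise ValueError(f"feature tensor must be rank-3 (C, H, W), got shape {x.shape}")
    if x.size == 0:
        raise ValueError("feature tensor dimensions must all be >= 1")
    if not np.all(np.isfinite(x)):
        raise ValueError("feature tensor entries must be finite")
    return x


# ---------------------------------------------------------------------------
# receptive field
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class LayerSpec:
    """Kernel size and stride of one convolution/pooling layer."""

    kernel: int
    stride: int = 1

    def __post_init__(self) -> None:
        if self.kernel < 1 or self.stride < 1:
            raise ValueError(
                f"kernel and stride must be >= 1, got k={self.kernel}, s={self.stride}"
            )


def receptive_field(layers: list[LayerSpec]) -> int:
    """Fold a layer stack through the receptive-field recurrence.

    ``R_1 = k_1`` and ``R_n = R_{n-1} + (k_n - 1) * prod(strides of
    layers 1..n-1)``.  For all-stride-1 stacks this is a sum, hence
    order-independent.
    """
    if not layers:
        raise ValueError("layer list must be non-empty")
    r = layers[0].kernel
    jump = layers[0].stride
    for layer in layers[1:]:
        r += (layer.kernel - 1) * jump
        jump *= layer.stride
    return r


# ---------------------------------------------------------------------------
# pooling and convolution primitives
# ---------------------------------------------------------------------------

def max_pool_same(x: np.ndarray, kernel: int) -> np.ndarray:
    """Stride-1, shape-preserving max pool over each channel.

    The window is ``kernel x kernel`` (kernel must be odd so the output
    aligns with the input); outside the image the pool sees ``-inf``,
    i.e. padding never wins.
    """
    x = _check_feature_tensor(x)
    if kernel < 1 or kernel % 2 == 0:
        raise ValueError(f"pool kernel must be a positive odd integer, got {kernel}")
    if kernel == 1:
        return x.copy()
    return maximum_filter(
        x, size=(1, kernel, kernel), mode="constant", cval=-np.inf
    )


def conv2d_same(x: np.ndarray, weight: np.ndarray, bias: np.ndarray | None = None) -> np.ndarray:
    """Stride-1 zero-padded cross-correlation: ``(C,H,W) -> (O,H,W)``.

    ``weight`` has shape ``(O, C, k, k)`` with odd ``k``.
    """
    x = _check_feature_tensor(x)
    weight = np.asarray(weight, dtype=float)
    if weight.ndim != 4 or weight.shape[2] != weight.shape[3]:
        raise ValueError(f"weight must have shape (O, C, k, k), got {weight.shape}")
    o, c, k, _ = weight.shape
    if c != x.shape[0]:
        raise ValueError(f"weight expects {c} input channels, tensor has {x.shape[0]}")
    if k % 2 == 0:
        raise ValueError(f"conv kernel must be odd, got {k}")
    p = (k - 1) // 2
    xp = np.pad(x, ((0, 0), (p, p), (p, p)))
    win = sliding_window_view(xp, (k, k), axis=(1, 2))  # (C, H, W, k, k)
    out = np.einsum("chwkl,ockl->ohw", win, weight, optimize=True)
    if bias is not None:
        out += np.asarray(bias, dtype=float)[:, None, None]
    return out


# ---------------------------------------------------------------------------
# SPPMC
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SPPMCSpec:
    """Shape and wiring parameters of the SPPMC block.

    The default pooling-kernel ladder 5, 9, 13, 17 is an arithmetic
    progression (common difference 4) so the pooled branches sweep the
    receptive-field ladder 7, 11, 15, 19 uniformly.  ``activation``
    names the nonlinearity applied after every convolution; the block's
    semantics use SILU, while ``"identity"`` is available for wiring
    diagnostics.
    """

    in_channels: int
    hidden_channels: int | None = None
    pool_kernels: tuple[int, ...] = (5, 9, 13, 17)
    activation: str = "silu"

    def __post_init__(self) -> None:
        if self.in_channels < 1:
            raise ValueError("in_channels must be >= 1")
        if self.hidden_channels is None:
            # default hidden width: half the input channels, at least 1
            object.__setattr__(
                self, "hidden_channels", max(1, self.in_channels // 2)
            )
        if self.hidden_channels < 1:
            raise ValueError("hidden_channels must be >= 1")
        ks = self.pool_kernels
        if not ks or any(k < 1 or k % 2 == 0 for k in ks):
            raise ValueError(f"pool kernels must be positive odd integers, got {ks}")
        if any(b <= a for a, b in zip(ks, ks[1:])):
            raise ValueError(f"pool kernels must be strictly increasing, got {ks}")
        if self.activation not in _ACTIVATIONS:
            raise ValueError(
                f"activation must be one of {sorted(_ACTIVATIONS)}, got {self.activation!r}"
            )


def sppmc_branch_layers(spec: SPPMCSpec) -> dict[str, list[LayerSpec]]:
    """Per-branch layer stacks of the block, for receptive-field analysis.

    Six pre-fusion branches: the 1x1 shortcut, the local 1x1-3x3-3x3
    convolution path, and the 1x1-3x3-1x1 stem followed by each pooling
    kernel.
    """
    stem = [LayerSpec(1), LayerSpec(3), LayerSpec(1)]
    branches = {
        "shortcut": [LayerSpec(1)],
        "local": [LayerSpec(1), LayerSpec(3), LayerSpec(3)],
    }
    for k in spec.pool_kernels:
        branches[f"pool{k}"] = stem + [LayerSpec(k)]
    return branches


def sppmc_branch_receptive_fields(spec: SPPMCSpec | None = None) -> dict[str, int]:
    """Receptive field of each pre-fusion branch (default: {1,5,7,11,15,19})."""
    spec = spec or SPPMCSpec(in_channels=1)
    return {
        name: receptive_field(layers)
        for name, layers in sppmc_branch_layers(spec).items()
    }


# weight key schema (all convs stride 1, zero-padded 'same'):
#   shortcut.w/.b      : 1x1, C  -> hid
#   local.{0,1,2}.w/.b : 1x1, 3x3, 3x3, C -> hid -> hid -> hid
#   stem.{0,1,2}.w/.b  : 1x1, 3x3, 1x1, C -> hid -> hid -> hid
#   fuse.{0,1}.w/.b    : 1x1 (5*hid -> hid), 3x3 (hid -> hid)
#   final.w/.b         : 1x1, 2*hid -> C
def _sppmc_shapes(spec: SPPMCSpec) -> dict[str, tuple[int, ...]]:
    c, hid = spec.in_channels, spec.hidden_channels
    n_pool = len(spec.pool_kernels)
    shapes: dict[str, tuple[int, ...]] = {
        "shortcut.w": (hid, c, 1, 1),
        "local.0.w": (hid, c, 1, 1),
        "local.1.w": (hid, hid, 3, 3),
        "local.2.w": (hid, hid, 3, 3),
        "stem.0.w": (hid, c, 1, 1),
        "stem.1.w": (hid, hid, 3, 3),
        "stem.2.w": (hid, hid, 1, 1),
        "fuse.0.w": (hid, (1 + n_pool) * hid, 1, 1),
        "fuse.1.w": (hid, hid, 3, 3),
        "final.w": (c, 2 * hid, 1, 1),
    }
    for key in list(shapes):
        shapes[key.replace(".w", ".b")] = (shapes[key][0],)
    return shapes


def init_sppmc_params(
    spec: SPPMCSpec, rng: np.random.Generator | int | None = 0
) -> dict[str, np.ndarray]:
    """Seeded uniform weight initialization (fan-in scaled, zero biases)."""
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    params: dict[str, np.ndarray] = {}
    for key, shape in _sppmc_shapes(spec).items():
        if key.endswith(".b"):
            params[key] = np.zeros(shape)
        else:
            fan_in = shape[1] * shape[2] * shape[3]
            bound = 1.0 / np.sqrt(fan_in)
            params[key] = rng.uniform(-bound, bound, size=shape)
    return params


def _identity_kernel(channels: int, k: int) -> np.ndarray:
    w = np.zeros((channels, channels, k, k))
    mid = (k - 1) // 2
    for c in range(channels):
        w[c, c, mid, mid] = 1.0
    return w


def identity_sppmc_params(spec: SPPMCSpec) -> dict[str, np.ndarray]:
    """Pass-through weights for wiring diagnostics.

    Every square convolution becomes a Dirac kernel; the fusion and
    final projections average their input groups so each branch's
    signal survives unscaled mixing.  Requires ``hidden_channels ==
    in_channels``.
    """
    if spec.hidden_channels != spec.in_channels:
        raise ValueError(
            "identity pass-through requires hidden_channels == in_channels"
        )
    c = spec.in_channels
    n_pool = len(spec.pool_kernels)
    params = {key: np.zeros(shape) for key, shape in _sppmc_shapes(spec).items()}
    for key in ("shortcut.w", "local.0.w", "stem.0.w", "stem.2.w"):
        params[key] = _identity_kernel(c, 1)
    for key in ("local.1.w", "local.2.w", "stem.1.w", "fuse.1.w"):
        params[key] = _identity_kernel(c, 3)
    # group-averaging 1x1 projections
    fuse0 = np.zeros((c, (1 + n_pool) * c, 1, 1))
    for g in range(1 + n_pool):
        for ch in range(c):
            fuse0[ch, g * c + ch, 0, 0] = 1.0 / (1 + n_pool)
    params["fuse.0.w"] = fuse0
    final = np.zeros((c, 2 * c, 1, 1))
    for g in range(2):
        for ch in range(c):
            final[ch, g * c + ch, 0, 0] = 0.5
    params["final.w"] = final
    return params


def sppmc_forward(
    x: np.ndarray,
    spec: SPPMCSpec,
    params: dict[str, np.ndarray],
    return_branches: bool = False,
):
    """Forward pass of the SPPMC block; output shape ``(C, H, W)``.

    Branch outputs (local path and the four pooled views of the stem)
    are concatenated on the channel axis, fused by 1x1 and 3x3
    convolutions, concatenated with the 1x1 shortcut, and projected back
    to ``in_channels`` by a final 1x1 convolution.  The configured
    activation follows every convolution.
    """
    x = _check_feature_tensor(x)
    if x.shape[0] != spec.in_channels:
        raise ValueError(
            f"input has {x.shape[0]} channels, spec expects {spec.in_channels}"
        )
    act = _ACTIVATIONS[spec.activation]

    def conv(name: str, t: np.ndarray) -> np.ndarray:
        return act(conv2d_same(t, params[f"{name}.w"], params[f"{name}.b"]))

    shortcut = conv("shortcut", x)
    local = conv("local.2", conv("local.1", conv("local.0", x)))
    stem = conv("stem.2", conv("stem.1", conv("stem.0", x)))
    pooled = {f"pool{k}": max_pool_same(stem, k) for k in spec.pool_kernels}

    fused = np.concatenate([local, *pooled.values()], axis=0)
    fused = conv("fuse.1", conv("fuse.0", fused))
    out = conv("final", np.concatenate([fused, shortcut], axis=0))
    if return_branches:
        return out, {"shortcut": shortcut, "local": local, **pooled}
    return out


# ---------------------------------------------------------------------------
# UECA
# ---------------------------------------------------------------------------

@dataclass
class UECAParams:
    """Weights of the UECA block's two branches.

    Squeeze-excitation branch: ``M2`` reduces the channel descriptor
    ``C -> C/r_se`` and ``M1`` restores ``C/r_se -> C``.  Coordinate
    branch: the 1x1 kernel ``F1`` reduces ``C -> C/r_ca`` on the
    concatenated directional descriptors, and ``Fh``/``Fw`` restore
    ``C`` per direction.  All transforms are bias-free.
    """

    M1: np.ndarray
    M2: np.ndarray
    F1: np.ndarray
    Fh: np.ndarray
    Fw: np.ndarray
    r_se: int = field(default=16)
    r_ca: int = field(default=32)

    def __post_init__(self) -> None:
        self.M1 = np.asarray(self.M1, dtype=float)
        self.M2 = np.asarray(self.M2, dtype=float)
        self.F1 = np.asarray(self.F1, dtype=float)
        self.Fh = np.asarray(self.Fh, dtype=float)
        self.Fw = np.asarray(self.Fw, dtype=float)
        c = self.channels
        if self.M2.shape != (self.M1.shape[1], c) or self.M1.shape[0] != c:
            raise ValueError(
                f"SE weights must compose C->C/r->C; got M1 {self.M1.shape}, M2 {self.M2.shape}"
            )
        cr = self.F1.shape[0]
        if self.F1.shape != (cr, c) or self.Fh.shape != (c, cr) or self.Fw.shape != (c, cr):
            raise ValueError(
                f"CA weights must compose C->C/r and back; got F1 {self.F1.shape}, "
                f"Fh {self.Fh.shape}, Fw {self.Fw.shape}"
            )

    @property
    def channels(self) -> int:
        return self.M1.shape[0]

    @classmethod
    def random(
        cls,
        channels: int,
        r_se: int = 16,
        r_ca: int = 32,
        rng: np.random.Generator | int | None = 0,
    ) -> "UECAParams":
        """Seeded uniform initialization; the reduction ratios must divide C."""
        for name, r in (("r_se", r_se), ("r_ca", r_ca)):
            if r < 1 or channels % r:
                raise ValueError(
                    f"{name}={r} must be a positive divisor of channels={channels}"
                )
        rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng

        def u(rows: int, cols: int) -> np.ndarray:
            bound = 1.0 / np.sqrt(cols)
            return rng.uniform(-bound, bound, size=(rows, cols))

        cse, cca = channels // r_se, channels // r_ca
        return cls(
            M1=u(channels, cse),
            M2=u(cse, channels),
            F1=u(cca, channels),
            Fh=u(channels, cca),
            Fw=u(channels, cca),
            r_se=r_se,
            r_ca=r_ca,
        )


@dataclass(frozen=True)
class AttentionMaps:
    """Gate maps produced by UECA: all entries strictly in (0, 1).

    ``s1`` is the per-channel squeeze-excitation gate ``(C,)``; ``gh``
    and ``gw`` are the directional coordinate gates ``(C, H)`` and
    ``(C, W)``; ``s2`` is their broadcast product ``(C, H, W)``.
    """

    s1: np.ndarray
    gh: np.ndarray
    gw: np.ndarray

    @property
    def s2(self) -> np.ndarray:
        return self.gh[:, :, None] * self.gw[:, None, :]


def ueca_gates(x: np.ndarray, params: UECAParams) -> AttentionMaps:
    """Compute the SE and coordinate attention gates for a feature map.

    SE branch: global average per channel, squeezed through
    ``sigmoid(M1 @ relu(M2 @ z))``.  Coordinate branch: row/column mean
    descriptors, concatenated and reduced by ``relu(F1 @ .)``, split
    back per direction, and gated through ``sigmoid(Fh @ .)`` /
    ``sigmoid(Fw @ .)``.
    """
    x = _check_feature_tensor(x)
    c, h, w = x.shape
    if c != params.channels:
        raise ValueError(f"input has {c} channels, params expect {params.channels}")

    # squeeze-excitation branch
    z = x.mean(axis=(1, 2))  # (C,)
    s1 = sigmoid(params.M1 @ relu(params.M2 @ z))

    # coordinate branch
    zh = x.mean(axis=2)  # (C, H): mean over columns
    zw = x.mean(axis=1)  # (C, W): mean over rows
    v = relu(params.F1 @ np.concatenate([zh, zw], axis=1))  # (C/r, H+W)
    vh, vw = v[:, :h], v[:, h:]
    gh = sigmoid(params.Fh @ vh)  # (C, H)
    gw = sigmoid(params.Fw @ vw)  # (C, W)
    return AttentionMaps(s1=s1, gh=gh, gw=gw)


def ueca_forward(
    x: np.ndarray, params: UECAParams, combine: str = "sum"
) -> np.ndarray:
    """Apply UECA attention to a feature map; output shape equals input.

    ``combine="sum"`` (default) returns the attention-gated sum
    ``Y = X*s1 + X*s2``; ``combine="product"`` returns the literal
    cascaded reading ``Y = X*(X*s1 + X*s2)``.
    """
    x = _check_feature_tensor(x)
    maps = ueca_gates(x, params)
    gated = x * maps.s1[:, None, None] + x * maps.s2
    if combine == "sum":
        return gated
    if combine == "product":
        return x * gated
    raise ValueError(f"combine must be 'sum' or 'product', got {combine!r}")


# ---------------------------------------------------------------------------
# flat named-array weight archives
# ---------------------------------------------------------------------------

def save_params(path, params: dict[str, np.ndarray]) -> None:
    """Save a flat name->array weight mapping (numpy .npz archive)."""
    np.savez(path, **params)


def load_params(path) -> dict[str, np.ndarray]:
    with np.load(path) as archive:
        return {key: archive[key] for key in archive.files}
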