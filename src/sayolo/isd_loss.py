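"""The iSD-IoU bounding-box regression loss and reference baselines.

The loss combines three scale-free terms::

    L = (1 - IoU_in) + Delta + Omega

* ``IoU_in`` — IoU of *inner* auxiliary boxes: both boxes keep their
  centers and have their sides scaled by a ratio ``r`` in [0.5, 1.5].
  At ``r = 1`` the inner IoU reduces exactly to the plain IoU.
* ``Delta`` — an exponential penalty on the center offset, normalized
  per axis by the enclosing box's width/height and weighted by shape
  weights derived from the ground-truth aspect ratio:
  ``Delta = k * sum_{t in {x,y}} (1 - exp(-rho_t))`` with
  ``rho_x = w1 * ((cx - cx_gt) / wc)^2`` and analogously for y.
* ``Omega`` — an exponential penalty on relative width/height mismatch,
  raised to an exponent ``Theta`` in [2, 6]:
  ``Omega = 1/2 * sum_{t in {w,h}} (1 - exp(-w_t))^Theta``.

The shape weights are ``w1 = 2 (w_gt)^s / ((w_gt)^s + (h_gt)^s)`` and
``h1 = 2 - w1``; as printed, the mismatch terms are *cross*-paired
(``w_w`` uses ``h1`` and ``w_h`` uses ``w1``).  A ``shape_weight_pairing``
switch keeps the direct pairing available because the crossed form is
unusual; the default follows the printed equations.

Reference losses (IoU, DIoU, CIoU) are provided for the convergence
comparison in :mod:`sayolo.simulate`.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .boxgeom import Box, BoxPair, enclosing_wh_xywh, iou_xywh

__all__ = [
    "ConfigError",
    "ISDConfig",
    "LossBreakdown",
    "ShapeWeights",
    "inner_iou",
    "shape_weights",
    "distance_term",
    "shape_term",
    "isd_iou_loss",
    "reference_loss",
    "REFERENCE_LOSSES",
]


class ConfigError(ValueError):
    """Raised when a loss hyperparameter is outside its admissible range."""


@dataclass(frozen=True)
class ISDConfig:
    """Hyperparameters of the iSD-IoU loss.

    Parameters
    ----------
    ratio:
        Inner-box side scaling factor ``r``; admissible range [0.5, 1.5].
        Values below 1 shrink the auxiliary boxes (sharper gradients for
        high-IoU pairs), values above 1 grow them (non-zero gradients for
        barely-overlapping pairs).  Default 1.0, which makes the inner
        IoU coincide with the plain IoU.
    k:
        Weight of the distance term; admissible range (0, 1].  Default 0.5.
    theta:
        Shape-term exponent ``Theta``; admissible range [2, 6].  Larger
        values damp small shape mismatches.  Default 4, the range midpoint.
    s:
        Scale exponent of the shape weights; ``s = 0`` makes both weights
        1 regardless of the ground-truth aspect ratio.  Default 1.0.
    shape_weight_pairing:
        ``"crossed"`` (default, as printed: width mismatch weighted by
        ``h1``, height mismatch by ``w1``) or ``"direct"``.
    """

    ratio: float = 1.0
    k: float = 0.5
    theta: float = 4.0
    s: float = 1.0
    shape_weight_pairing: str = "crossed"

    def __post_init__(self) -> None:
        if not 0.5 <= self.ratio <= 1.5:
            raise ConfigError(
                f"ratio must be within [0.5, 1.5], got {self.ratio}"
            )
        if not 0.0 < self.k <= 1.0:
            raise ConfigError(f"k must be within (0, 1], got {self.k}")
        if not 2.0 <= self.theta <= 6.0:
            raise ConfigError(f"theta must be within [2, 6], got {self.theta}")
        if self.s < 0:
            raise ConfigError(f"s must be >= 0, got {self.s}")
        if self.shape_weight_pairing not in ("crossed", "direct"):
            raise ConfigError(
                "shape_weight_pairing must be 'crossed' or 'direct', "
                f"got {self.shape_weight_pairing!r}"
            )


@dataclass(frozen=True)
class LossBreakdown:
    """Per-pair decomposition of the iSD-IoU loss.

    ``total`` is exactly ``(1 - iou_in) + delta + omega``; no hidden
    reweighting is applied.
    """

    iou_in: float
    delta: float
    omega: float

    @property
    def total(self) -> float:
        return (1.0 - self.iou_in) + self.delta + self.omega


@dataclass(frozen=True)
class ShapeWeights:
    """Directional weights derived from the ground-truth box shape.

    They always sum to 2; a square ground truth gives ``w1 = h1 = 1``
    for any scale exponent.
    """

    w1: float
    h1: float


# ---------------------------------------------------------------------------
# vectorized core on (..., 4) arrays
# ---------------------------------------------------------------------------

def inner_iou_xywh(pred: np.ndarray, gt: np.ndarray, ratio: float) -> np.ndarray:
    """Inner-box IoU on arrays: centers kept, sides scaled by ``ratio``."""
    pred = np.asarray(pred, dtype=float)
    gt = np.asarray(gt, dtype=float)
    scale = np.array([1.0, 1.0, ratio, ratio])
    return iou_xywh(pred * scale, gt * scale)


def shape_weights_xywh(gt: np.ndarray, s: float) -> tuple[np.ndarray, np.ndarray]:
    gt = np.asarray(gt, dtype=float)
    ws = gt[..., 2] ** s
    hs = gt[..., 3] ** s
    w1 = 2.0 * ws / (ws + hs)
    return w1, 2.0 - w1


def isd_components_xywh(
    pred: np.ndarray, gt: np.ndarray, cfg: ISDConfig
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Return ``(iou_in, delta, omega)`` arrays for broadcastable pairs."""
    pred = np.asarray(pred, dtype=float)
    gt = np.asarray(gt, dtype=float)
    iou_in = inner_iou_xywh(pred, gt, cfg.ratio)

    w1, h1 = shape_weights_xywh(gt, cfg.s)
    wc, hc = enclosing_wh_xywh(pred, gt)
    rho_x = w1 * ((pred[..., 0] - gt[..., 0]) / wc) ** 2
    rho_y = h1 * ((pred[..., 1] - gt[..., 1]) / hc) ** 2
    delta = cfg.k * ((1.0 - np.exp(-rho_x)) + (1.0 - np.exp(-rho_y)))

    dw = np.abs(pred[..., 2] - gt[..., 2]) / np.maximum(pred[..., 2], gt[..., 2])
    dh = np.abs(pred[..., 3] - gt[..., 3]) / np.maximum(pred[..., 3], gt[..., 3])
    if cfg.shape_weight_pairing == "crossed":
        w_w, w_h = h1 * dw, w1 * dh
    else:
        w_w, w_h = w1 * dw, h1 * dh
    omega = 0.5 * (
        (1.0 - np.exp(-w_w)) ** cfg.theta + (1.0 - np.exp(-w_h)) ** cfg.theta
    )
    return iou_in, delta, omega


def isd_loss_xywh(pred: np.ndarray, gt: np.ndarray, cfg: ISDConfig) -> np.ndarray:
    iou_in, delta, omega = isd_components_xywh(pred, gt, cfg)
    return (1.0 - iou_in) + delta + omega


def reference_loss_xywh(pred: np.ndarray, gt: np.ndarray, which: str) -> np.ndarray:
    """IoU/DIoU/CIoU losses on arrays, with the standard definitions."""
    pred = np.asarray(pred, dtype=float)
    gt = np.asarray(gt, dtype=float)
    i = iou_xywh(pred, gt)
    if which == "iou":
        return 1.0 - i
    wc, hc = enclosing_wh_xywh(pred, gt)
    d2 = (pred[..., 0] - gt[..., 0]) ** 2 + (pred[..., 1] - gt[..., 1]) ** 2
    c2 = wc**2 + hc**2
    diou = 1.0 - i + d2 / c2
    if which == "diou":
        return diou
    if which == "ciou":
        v = (4.0 / np.pi**2) * (
            np.arctan(gt[..., 2] / gt[..., 3]) - np.arctan(pred[..., 2] / pred[..., 3])
        ) ** 2
        # alpha is the standard trade-off v / ((1 - IoU) + v); 0/0 -> 0
        with np.errstate(invalid="ignore"):
            alpha = np.where(v > 0, v / ((1.0 - i) + v), 0.0)
        return diou + alpha * v
    raise ValueError(f"unknown reference loss {which!r}; expected iou, diou or ciou")


REFERENCE_LOSSES = ("iou", "diou", "ciou")


# ---------------------------------------------------------------------------
# scalar API
# ---------------------------------------------------------------------------

def inner_iou(pair: BoxPair, ratio: float) -> float:
    """IoU of the auxiliary inner boxes (centers kept, sides scaled)."""
    if not 0.5 <= ratio <= 1.5:
        raise ConfigError(f"ratio must be within [0.5, 1.5], got {ratio}")
    a, b = pair.as_arrays()
    return float(inner_iou_xywh(a, b, ratio))


def shape_weights(gt: Box, s: float) -> ShapeWeights:
    """Directional weights ``(w1, h1)`` from the ground-truth box shape."""
    if s < 0:
        raise ConfigError(f"s must be >= 0, got {s}")
    w1, h1 = shape_weights_xywh(gt.as_array(), s)
    return ShapeWeights(w1=float(w1), h1=float(h1))


def distance_term(pair: BoxPair, cfg: ISDConfig) -> float:
    """The exponential center-distance penalty ``Delta``; bounded by ``2k``."""
    a, b = pair.as_arrays()
    return float(isd_components_xywh(a, b, cfg)[1])


def shape_term(pair: BoxPair, cfg: ISDConfig) -> float:
    """The exponential shape-mismatch penalty ``Omega``; bounded by 1."""
    a, b = pair.as_arrays()
    return float(isd_components_xywh(a, b, cfg)[2])


def isd_iou_loss(pair: BoxPair, cfg: ISDConfig | None = None) -> LossBreakdown:
    """Full iSD-IoU loss decomposition for one pair."""
    cfg = cfg or ISDConfig()
    a, b = pair.as_arrays()
    iou_in, delta, omega = isd_components_xywh(a, b, cfg)
    return LossBreakdown(iou_in=float(iou_in), delta=float(delta), omega=float(omega))


def reference_loss(pair: BoxPair, which: str) -> float:
    """One of the baseline losses: ``iou``, ``diou`` or ``ciou``."""
    a, b = pair.as_arrays()
    return float(reference_loss_xywh(a, b, which))
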