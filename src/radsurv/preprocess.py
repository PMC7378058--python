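"""Crop-and-pad preprocessing of tumor patches into fixed-size 3-channel
network inputs.

Convention: all boxes are 0-based and half-open. Default canvases are 80 px
(CT) and 28 px (PET), sized after the largest tumor each modality must hold;
padding pixels are exactly zero. The three channels are either the three
neighboring axial slices (``channel_mode='slices'``) or three concentric
crops of the middle slice at per-side margins 0/10/20 px resized to the
base canvas (``channel_mode='scales'``).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage.transform import resize

DEFAULT_CANVAS_CT = 80
DEFAULT_CANVAS_PET = 28
DEFAULT_MARGINS = (0, 10, 20)

__all__ = [
    "DEFAULT_CANVAS_CT",
    "DEFAULT_CANVAS_PET",
    "DEFAULT_MARGINS",
    "VolumeStack",
    "mask_bbox",
    "crop_to_bbox",
    "pad_to_canvas",
    "stack_slices",
    "multiscale_stack",
    "fit_intensity_range",
    "apply_intensity_range",
]


@dataclass
class VolumeStack:
    """A side x side x 3 network input."""

    pixels: np.ndarray
    modality: str          # "CT" | "PET"
    channel_mode: str      # "slices" | "scales"

    def __post_init__(self):
        p = self.pixels
        if p.ndim != 3 or p.shape[2] != 3 or p.shape[0] != p.shape[1]:
            raise ValueError("pixels must be side x side x 3")
        if self.modality not in ("CT", "PET"):
            raise ValueError("modality must be CT or PET")
        if self.channel_mode not in ("slices", "scales"):
            raise ValueError("channel_mode must be slices or scales")

    @property
    def side(self) -> int:
        return self.pixels.shape[0]


def mask_bbox(roi_mask):
    """Tight bounding box (r0, r1, c0, c1) of a mask, half-open."""
    roi_mask = np.asarray(roi_mask, dtype=bool)
    if not roi_mask.any():
        raise ValueError("ROI mask is empty")
    rows = np.flatnonzero(roi_mask.any(axis=1))
    cols = np.flatnonzero(roi_mask.any(axis=0))
    return int(rows[0]), int(rows[-1]) + 1, int(cols[0]), int(cols[-1]) + 1


def crop_to_bbox(image, roi_mask):
    """Crop an image to the tight bounding box of the ROI mask."""
    image = np.asarray(image)
    roi_mask = np.asarray(roi_mask, dtype=bool)
    if image.shape[:2] != roi_mask.shape:
        raise ValueError("image and mask shapes disagree")
    r0, r1, c0, c1 = mask_bbox(roi_mask)
    return image[r0:r1, c0:c1]


def pad_to_canvas(patch, canvas_side):
    """Center a patch on a square zero canvas.

    Odd leftover pixels go to the bottom/right, i.e. the patch is biased one
    half-pixel toward the top-left corner.
    """
    patch = np.asarray(patch)
    h, w = patch.shape[:2]
    if h > canvas_side or w > canvas_side:
        raise ValueError(
            f"patch {h}x{w} exceeds canvas {canvas_side} "
            "(the canvas must fit the largest tumor)")
    top = (canvas_side - h) // 2
    left = (canvas_side - w) // 2
    out_shape = (canvas_side, canvas_side) + patch.shape[2:]
    out = np.zeros(out_shape, dtype=patch.dtype)
    out[top : top + h, left : left + w] = patch
    return out


def stack_slices(middle, below, above, modality="CT"):
    """Stack three same-shape padded slices as channels (below, middle, above)."""
    below, middle, above = (np.asarray(a) for a in (below, middle, above))
    if not (below.shape == middle.shape == above.shape):
        raise ValueError("the three slices must share a shape")
    if middle.ndim != 2 or middle.shape[0] != middle.shape[1]:
        raise ValueError("slices must be square 2-D arrays")
    return VolumeStack(pixels=np.stack([below, middle, above], axis=-1),
                       modality=modality, channel_mode="slices")


def multiscale_stack(image, roi_mask, canvas_side, margins=DEFAULT_MARGINS,
                     modality="CT"):
    """Three concentric crops of one slice at growing per-side margins.

    The margin-0 channel is the tight bounding-box crop; larger margins are
    clipped at the image border. Each crop is padded (when it fits) or
    bilinearly resized to the base canvas, then stacked; channel order
    follows ``margins``.
    """
    image = np.asarray(image, dtype=float)
    roi_mask = np.asarray(roi_mask, dtype=bool)
    if image.shape[:2] != roi_mask.shape:
        raise ValueError("image and mask shapes disagree")
    r0, r1, c0, c1 = mask_bbox(roi_mask)
    H, W = roi_mask.shape
    channels = []
    for m in margins:
        rr0, rr1 = max(r0 - m, 0), min(r1 + m, H)
        cc0, cc1 = max(c0 - m, 0), min(c1 + m, W)
        crop = image[rr0:rr1, cc0:cc1]
        if crop.shape[0] <= canvas_side and crop.shape[1] <= canvas_side:
            chan = pad_to_canvas(crop, canvas_side)
        else:
            chan = resize(crop, (canvas_side, canvas_side), order=1,
                          preserve_range=True, anti_aliasing=False)
        channels.append(np.asarray(chan, dtype=image.dtype))
    return VolumeStack(pixels=np.stack(channels, axis=-1),
                       modality=modality, channel_mode="scales")


def preprocess_tumor(tumor_stack, roi_mask, canvas_side, channel_mode="slices",
                     margins=DEFAULT_MARGINS, modality="CT"):
    """Full crop->pad->stack path for one tumor.

    ``tumor_stack`` is H x W x 3 (three raw neighboring slices); in
    ``slices`` mode each slice is cropped to the middle-slice ROI bbox and
    centered on the canvas, in ``scales`` mode only the middle slice is used
    at margins 0/10/20.
    """
    tumor_stack = np.asarray(tumor_stack)
    if channel_mode == "scales":
        return multiscale_stack(tumor_stack[..., 1], roi_mask, canvas_side,
                                margins=margins, modality=modality)
    channels = [pad_to_canvas(crop_to_bbox(tumor_stack[..., k], roi_mask),
                              canvas_side)
                for k in range(3)]
    return stack_slices(channels[1], channels[0], channels[2],
                        modality=modality)


# ---------------------------------------------------------------------------
# intensity normalization (fit on training data only)
# ---------------------------------------------------------------------------

def fit_intensity_range(stacks):
    """Min/max over a training set of stacks, for [0, 1] scaling."""
    lo = min(float(np.min(s)) for s in stacks)
    hi = max(float(np.max(s)) for s in stacks)
    if hi <= lo:
        hi = lo + 1.0
    return lo, hi


def apply_intensity_range(stack, lo, hi):
    return np.clip((np.asarray(stack, dtype=np.float32) - lo) / (hi - lo), 0.0, 1.0)
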