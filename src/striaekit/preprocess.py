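"""Photo preprocessing: skin segmentation, navel-centered cropping, binarization.

The objective severity features are all computed inside the *striae
gravidarum region* (SGR): the largest square window centered on the navel
that fits the segmented skin region.  This module produces that window and
its two-class partition:

``R_S``
    pixels whose gray level is similar to the surrounding skin,
``R_SG``
    the striae region — pixels that deviate from the local skin tone.

Binarization is an adaptive (local-mean) threshold with a symmetric
dead-zone: a pixel is a striae *candidate* only when its (lightly smoothed)
gray level deviates from the local mean by more than ``deadzone`` gray
levels.  Candidates below and above the local mean form two classes; the
class whose mean gray lies farther from the overall SGR mean becomes R_SG.
The striae/skin boundary is then refined by a two-means iteration on the
deviation image (the threshold converges to the midpoint of the two class
means), which places the cut at the half-amplitude point of a smoothed
stripe edge and so keeps pixel counts unbiased.  The whole rule is symmetric
under gray inversion — stripes brighter than skin are found exactly as well
as darker ones — and a perfectly uniform window degenerates to an empty
R_SG.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage.filters import threshold_local

from .config import PipelineParams

__all__ = [
    "SkinMask",
    "SgrWindow",
    "RegionPartition",
    "NoSkinError",
    "rgb_to_ycbcr",
    "rgb_to_gray",
    "detect_skin",
    "extract_sgr",
    "binarize_partition",
]

#: ITU-R 601 luma weights, also the Y row of the YCbCr matrix.
_LUMA = np.array([0.299, 0.587, 0.114])


class NoSkinError(ValueError):
    """Raised when no skin-colored pixels are found in a photo."""


@dataclass(frozen=True)
class SkinMask:
    """Binary skin mask aligned to the input photo."""

    mask: np.ndarray

    @property
    def bbox(self) -> tuple[int, int, int, int]:
        """Inclusive bounding box (y0, y1, x0, x1) of the mask."""
        ys, xs = np.nonzero(self.mask)
        return int(ys.min()), int(ys.max()), int(xs.min()), int(xs.max())


@dataclass(frozen=True)
class SgrWindow:
    """Square, navel-centered gray window in which all features are computed."""

    gray: np.ndarray
    origin: tuple[int, int]  # (x, y) of the window's top-left pixel
    side: int
    navel_local: tuple[int, int]  # (x, y) within the window


@dataclass(frozen=True)
class RegionPartition:
    """Two-class partition of an SGR window into skin-like and striae pixels."""

    gray: np.ndarray
    r_s_mask: np.ndarray
    r_sg_mask: np.ndarray
    g_s: float
    g_sg: float
    navel_local: tuple[int, int]

    @property
    def n_s(self) -> int:
        return int(np.count_nonzero(self.r_s_mask))

    @property
    def n_sg(self) -> int:
        return int(np.count_nonzero(self.r_sg_mask))


def rgb_to_ycbcr(rgb: np.ndarray) -> np.ndarray:
    """Full-range (JPEG) YCbCr from an 8-bit RGB raster, float output."""
    rgb = np.asarray(rgb, dtype=float)
    r, g, b = rgb[..., 0], rgb[..., 1], rgb[..., 2]
    y = 0.299 * r + 0.587 * g + 0.114 * b
    cb = 128.0 - 0.168736 * r - 0.331264 * g + 0.5 * b
    cr = 128.0 + 0.5 * r - 0.418688 * g - 0.081312 * b
    return np.stack([y, cb, cr], axis=-1)


def rgb_to_gray(rgb: np.ndarray) -> np.ndarray:
    """ITU-R 601 luma, float in [0, 255]."""
    return np.asarray(rgb, dtype=float) @ _LUMA


def detect_skin(photo: np.ndarray, params: PipelineParams = PipelineParams()) -> SkinMask:
    """Segment skin-colored pixels of an 8-bit RGB photo.

    A pixel is skin-colored when its chroma falls inside the configured
    Cb/Cr box.  The largest connected component is kept and its holes
    (navel, specular spots) are filled.

    Raises
    ------
    NoSkinError
        If no pixel passes the chroma rule.
    """
    photo = np.asarray(photo)
    if photo.ndim != 3 or photo.shape[-1] != 3:
        raise ValueError("photo must be an RGB raster (H, W, 3)")
    ycbcr = rgb_to_ycbcr(photo)
    cb, cr = ycbcr[..., 1], ycbcr[..., 2]
    lo_cb, hi_cb = params.skin_cb_range
    lo_cr, hi_cr = params.skin_cr_range
    raw = (cb >= lo_cb) & (cb <= hi_cb) & (cr >= lo_cr) & (cr <= hi_cr)
    if not raw.any():
        raise NoSkinError("no skin detected")
    labels, n = ndimage.label(raw)
    if n > 1:
        sizes = ndimage.sum_labels(raw, labels, index=np.arange(1, n + 1))
        raw = labels == (int(np.argmax(sizes)) + 1)
    return SkinMask(mask=ndimage.binary_fill_holes(raw))


def extract_sgr(
    photo: np.ndarray,
    skin: SkinMask,
    navel_xy: tuple[int, int],
) -> SgrWindow:
    """Crop the largest navel-centered square inside the skin bounding box.

    The side is even by convention and the navel sits at local index
    ``(side/2 - 1, side/2 - 1)`` (0-based, x rightward, y downward).  The
    window is converted to gray with ITU-R 601 luma weights.

    Raises
    ------
    ValueError
        If the navel lies outside the skin mask, or so close to the skin
        boundary that no square fits.
    """
    nx, ny = int(navel_xy[0]), int(navel_xy[1])
    mask = skin.mask
    if not (0 <= ny < mask.shape[0] and 0 <= nx < mask.shape[1]) or not mask[ny, nx]:
        raise ValueError(f"navel {navel_xy} lies outside the skin mask")
    y0, y1, x0, x1 = skin.bbox
    half = min(nx - x0 + 1, x1 - nx, ny - y0 + 1, y1 - ny)
    if half <= 0:
        raise ValueError("navel is on the skin boundary; no centered square fits")
    side = 2 * half
    sx, sy = nx - (half - 1), ny - (half - 1)
    gray = rgb_to_gray(photo)[sy : sy + side, sx : sx + side]
    return SgrWindow(
        gray=gray, origin=(sx, sy), side=side, navel_local=(half - 1, half - 1)
    )


def _local_mean_block(side: int, params: PipelineParams) -> int:
    block = max(params.block_min, side // params.block_divisor)
    return block | 1  # threshold_local requires an odd block size


def binarize_partition(
    sgr: SgrWindow, params: PipelineParams = PipelineParams()
) -> RegionPartition:
    """Split an SGR window into skin-like (R_S) and striae (R_SG) pixels.

    Pixels within ``params.deadzone`` gray levels of the local mean are
    skin-like candidates.  The pixels outside the dead zone form a below-mean
    and an above-mean class; whichever class has its mean gray farther from
    the overall window mean picks the striae side.  On that side a two-means
    iteration then refines the deviation threshold to the midpoint of the
    striae and skin class means (half-amplitude boundary).  When no pixel
    leaves the dead zone (uniform window) R_SG is empty and ``g_sg`` is
    defined equal to ``g_s`` so that downstream color difference and density
    are 0.
    """
    gray = np.asarray(sgr.gray, dtype=float)
    if gray.size == 0:
        raise ValueError("empty SGR window")
    smooth = ndimage.gaussian_filter(gray, params.presmooth_sigma)
    block = _local_mean_block(min(gray.shape), params)
    local_mean = threshold_local(smooth, block_size=block, method="mean", offset=0.0)
    dev = smooth - local_mean
    low = dev < -params.deadzone
    high = dev > params.deadzone
    overall = gray.mean()

    candidates = []
    for sign, cls in ((-1.0, low), (1.0, high)):
        k = int(np.count_nonzero(cls))
        if k:
            candidates.append((abs(float(gray[cls].mean()) - overall), -k, sign))
    if candidates:
        # farther-from-mean class wins; on an exact distance tie the smaller
        # class is taken as striae (striae are the minority pattern)
        _, _, sign = max(candidates, key=lambda t: (t[0], t[1]))
        sdev = sign * dev  # striae side is positive deviation
        thr = params.deadzone
        for _ in range(30):
            r = sdev > thr
            if not r.any() or r.all():
                break
            new_thr = 0.5 * (float(sdev[r].mean()) + float(sdev[~r].mean()))
            converged = abs(new_thr - thr) < 1e-3
            thr = new_thr
            if converged:
                break
        r_sg = sdev > thr
    else:
        r_sg = np.zeros_like(low)
    r_s = ~r_sg
    g_s = float(gray[r_s].mean()) if r_s.any() else float(overall)
    g_sg = float(gray[r_sg].mean()) if r_sg.any() else g_s
    return RegionPartition(
        gray=gray,
        r_s_mask=r_s,
        r_sg_mask=r_sg,
        g_s=g_s,
        g_sg=g_sg,
        navel_local=sgr.navel_local,
    )
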