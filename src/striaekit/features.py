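"""Objective severity parameters of striae gravidarum photographs.

Five image-derived observation parameters summarise a navel-centered skin
window (the SGR) and its skin/striae partition:

``C``  color difference, ``|G_SG - G_S| / 255`` — normalized gray contrast
       between the striae region and the surrounding skin;
``D``  average density, ``N_SG / (N_SG + N_S)`` — the striae pixel fraction;
``W``  average width, ``2 * N_SG / N_e`` — area over half-perimeter, with
       ``N_e`` the Canny edge-pixel count, approximating mean stripe width
       in pixels;
``A``  distribution area, ``0.25 * #{quadrants with density > 0.4}`` over
       the four navel-centered quadrants;
``E``  average elasticity — the Cutometer R2 total-elasticity index (closer
       to 1 means healthier skin), taken from a 10-value R0..R9 record.

``E`` is optional: when no elasticity record exists the feature is flagged
missing, never imputed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage.feature import canny

from .config import PipelineParams
from .preprocess import RegionPartition, binarize_partition, detect_skin, extract_sgr

__all__ = [
    "FeatureVector",
    "QuadrantDensities",
    "quadrant_slices",
    "color_difference",
    "average_density",
    "average_width",
    "distribution_area",
    "read_elasticity",
    "read_elasticity_table",
    "extract_features",
    "normalize_to_score",
    "FEATURE_COLUMNS",
]

FEATURE_COLUMNS = ("C", "D", "W", "A", "E")


@dataclass(frozen=True)
class FeatureVector:
    """The (C, D, W, A, E) observation vector of one photo; E may be missing."""

    c: float
    d: float
    w: float
    a: float
    e: float | None = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.c <= 1.0:
            raise ValueError(f"C out of range [0,1]: {self.c}")
        if not 0.0 <= self.d <= 1.0:
            raise ValueError(f"D out of range [0,1]: {self.d}")
        if self.w < 0.0:
            raise ValueError(f"W must be >= 0: {self.w}")
        if self.a not in (0.0, 0.25, 0.5, 0.75, 1.0):
            raise ValueError(f"A must be a multiple of 0.25 in [0,1]: {self.a}")

    @property
    def has_elasticity(self) -> bool:
        return self.e is not None

    def as_row(self) -> dict[str, float]:
        return {
            "C": self.c,
            "D": self.d,
            "W": self.w,
            "A": self.a,
            "E": np.nan if self.e is None else self.e,
        }


@dataclass(frozen=True)
class QuadrantDensities:
    """Striae density of the four navel-centered quadrants."""

    d1: float
    d2: float
    d3: float
    d4: float
    threshold: float = 0.4

    def as_tuple(self) -> tuple[float, float, float, float]:
        return (self.d1, self.d2, self.d3, self.d4)

    @property
    def n_exceeding(self) -> int:
        return sum(d > self.threshold for d in self.as_tuple())


def quadrant_slices(
    shape: tuple[int, int], navel_xy: tuple[int, int]
) -> list[tuple[slice, slice]]:
    """Navel-centered quadrants of a raster, in order TL, TR, BL, BR.

    The navel row and column belong to the lower/right quadrants (fixed
    convention).  ``navel_xy`` is (x, y).
    """
    h, w = shape
    nx, ny = navel_xy
    return [
        (slice(0, ny), slice(0, nx)),
        (slice(0, ny), slice(nx, w)),
        (slice(ny, h), slice(0, nx)),
        (slice(ny, h), slice(nx, w)),
    ]


def color_difference(part: RegionPartition) -> float:
    """Normalized gray contrast C = |G_SG - G_S| / 255."""
    return abs(part.g_sg - part.g_s) / 255.0


def average_density(part: RegionPartition) -> float:
    """Striae pixel fraction D = N_SG / (N_SG + N_S)."""
    total = part.n_sg + part.n_s
    return part.n_sg / total if total else 0.0


def count_canny_edges(gray: np.ndarray, params: PipelineParams = PipelineParams()) -> int:
    """Canny edge-pixel count N_e of a gray raster.

    Hysteresis thresholds are set relative to a robust upper gradient scale
    (the 99.5th percentile of the gradient magnitude of the Gaussian-smoothed
    image — robust so that a few very strong gradients, e.g. around the navel,
    cannot mask faint stripe edges), but never below a noise floor taken from
    the 20th gradient percentile under a Rayleigh model of the sensor-noise
    gradient response.  The gradient is computed exactly as the Canny detector
    computes it internally (unnormalized Sobel on the smoothed image) so the
    thresholds live on the right scale.  A gradient-free (uniform) raster has
    no edges.
    """
    img = np.asarray(gray, dtype=float) / 255.0
    smoothed = ndimage.gaussian_filter(img, params.canny_sigma, mode="nearest")
    mag = np.hypot(ndimage.sobel(smoothed, axis=0), ndimage.sobel(smoothed, axis=1))
    gmax = float(mag.max())
    if gmax <= 0.0:
        return 0
    scale = float(np.quantile(mag, 0.995))
    # Rayleigh noise scale from the 20th percentile: q20 = sigma*sqrt(2 ln 1.25)
    floor = float(np.quantile(mag, 0.2)) / 0.668
    low = max(params.canny_low_frac * scale, params.canny_noise_mult * floor)
    high = max(params.canny_high_frac * scale, 2.0 * params.canny_noise_mult * floor)
    if high >= gmax:  # nothing rises above the noise floor
        return 0
    edges = canny(
        img, sigma=params.canny_sigma, low_threshold=low, high_threshold=high
    )
    return int(np.count_nonzero(edges))


def average_width(
    part: RegionPartition, params: PipelineParams = PipelineParams()
) -> tuple[float, int]:
    """Average stripe width W = 2 * N_SG / N_e and the edge count N_e.

    For a band, area divided by half its perimeter is its width, so counting
    Canny edge pixels as the perimeter makes W a mean stripe width in pixels.
    W is 0 when no edges are found.
    """
    n_e = count_canny_edges(part.gray, params)
    if n_e == 0:
        return 0.0, 0
    return 2.0 * part.n_sg / n_e, n_e


def distribution_area(
    striae_mask: np.ndarray,
    navel_xy: tuple[int, int],
    threshold: float = 0.4,
) -> tuple[float, QuadrantDensities]:
    """Distribution area A = 0.25 * #{quadrants with striae density > threshold}.

    The comparison is strict: a quadrant at exactly the threshold does not
    count.  Degenerate (empty) quadrants have density 0.
    """
    mask = np.asarray(striae_mask, dtype=bool)
    nx, ny = int(navel_xy[0]), int(navel_xy[1])
    if not (0 <= ny < mask.shape[0] and 0 <= nx < mask.shape[1]):
        raise ValueError(f"navel {navel_xy} outside the mask raster")
    dens = []
    for ysl, xsl in quadrant_slices(mask.shape, (nx, ny)):
        quad = mask[ysl, xsl]
        dens.append(float(np.count_nonzero(quad)) / quad.size if quad.size else 0.0)
    quads = QuadrantDensities(*dens, threshold=threshold)
    return 0.25 * quads.n_exceeding, quads


def read_elasticity(record: Sequence[float]) -> float:
    """Average elasticity E from a 10-value Cutometer record R0..R9.

    E is the total elasticity index R2 (0-based index 2).  Values outside
    [0, 1] are passed through with a warning.
    """
    values = [float(v) for v in record]
    if len(values) != 10:
        raise ValueError(f"elasticity record must have 10 values R0..R9, got {len(values)}")
    e = values[2]
    if not 0.0 <= e <= 1.0:
        warnings.warn(f"elasticity R2={e} outside [0, 1]", stacklevel=2)
    return e


def read_elasticity_table(path) -> dict[str, float]:
    """Map photo_id -> E from a CSV with columns photo_id,R0,...,R9."""
    df = pd.read_csv(path, dtype={"photo_id": str})
    expected = [f"R{i}" for i in range(10)]
    missing = [c for c in expected if c not in df.columns]
    if missing:
        raise ValueError(f"elasticity CSV missing columns: {missing}")
    return {
        str(row["photo_id"]): read_elasticity([row[c] for c in expected])
        for _, row in df.iterrows()
    }


def extract_features(
    photo: np.ndarray,
    navel_xy: tuple[int, int],
    elasticity_record: Sequence[float] | None = None,
    *,
    elasticity: float | None = None,
    params: PipelineParams = PipelineParams(),
) -> FeatureVector:
    """Full objective pipeline: photo -> (C, D, W, A, E).

    Segments the skin, crops the navel-centered SGR, binarizes it and applies
    the four image operators; attaches E from a 10-value record (or a
    pre-parsed ``elasticity`` value) when supplied.
    """
    skin = detect_skin(photo, params)
    sgr = extract_sgr(photo, skin, navel_xy)
    part = binarize_partition(sgr, params)
    c = color_difference(part)
    d = average_density(part)
    w, _ = average_width(part, params)
    a, _ = distribution_area(
        part.r_sg_mask, part.navel_local, threshold=params.quadrant_threshold
    )
    if elasticity_record is not None:
        elasticity = read_elasticity(elasticity_record)
    return FeatureVector(c=c, d=d, w=w, a=a, e=elasticity)


def normalize_to_score(series: pd.DataFrame) -> tuple[pd.DataFrame, pd.Series, float]:
    """Scale a patient's feature time series to 0-3 severity scores.

    Each available parameter is min-max normalized over the series and scaled
    to [0, 3]; elasticity is inverted first (higher elasticity means healthier
    skin, hence a lower severity contribution).  A parameter that is constant
    over the series carries no information and contributes 0.  Returns the
    per-photo score table, the per-photo score sums, and the average of the
    sums over the series.
    """
    present = [c for c in FEATURE_COLUMNS if c in series.columns]
    if not present:
        raise ValueError(f"series has none of the feature columns {FEATURE_COLUMNS}")
    if len(series) < 2:
        raise ValueError("need at least two time points to normalize a series")
    scores = pd.DataFrame(index=series.index)
    for col in present:
        x = series[col].astype(float)
        if x.isna().any():
            if x.isna().all():
                continue
            raise ValueError(f"column {col} mixes present and missing values")
        span = x.max() - x.min()
        if span == 0:
            scores[col] = 0.0
        elif col == "E":
            scores[col] = 3.0 * (x.max() - x) / span
        else:
            scores[col] = 3.0 * (x - x.min()) / span
    sums = scores.sum(axis=1)
    return scores, sums, float(sums.mean())
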