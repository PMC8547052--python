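"""Synthetic abdominal-skin photographs with known striae ground truth.

No clinical striae gravidarum photo collection is publicly deposited, so the
test bed for the grading pipeline is synthetic: pale skin of a fixed hue with
darker, roughly parallel, slightly wavy stripes of controllable count, pixel
width, gray-level contrast and per-quadrant occupancy around a designated
navel point.  Stripes are rendered as hard-edged bands (no anti-aliasing) so
that coverage, per-quadrant density and mean stripe width can be measured
exactly by pixel counting on the ground-truth mask.

The skin hue is a fixed chroma (full-range YCbCr Cb=110, Cr=150) placed well
inside the default skin-detection box; only the luma channel varies, so the
luma of a rendered pixel equals its designed gray level.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from PIL import Image

from .features import quadrant_slices

__all__ = [
    "StriaeSpec",
    "TruthFeatures",
    "SyntheticPhoto",
    "SeverityProfile",
    "CohortItem",
    "DEFAULT_PROFILES",
    "SEVERITY_ORDER",
    "SKIN_CB",
    "SKIN_CR",
    "generate_photo",
    "generate_band_photo",
    "generate_cohort",
    "write_elasticity_record",
    "write_cohort",
    "uniform_skin_image",
]

SKIN_CB = 110.0
SKIN_CR = 150.0
SEVERITY_ORDER = ("mild", "moderate", "severe")

_NAVEL_GRAY = 60.0
_NAVEL_RADIUS = 3


@dataclass(frozen=True)
class StriaeSpec:
    """Generative parameters of one synthetic photo.

    ``quadrant_occupancy`` holds one weight in [0, 1] per navel-centered
    quadrant (TL, TR, BL, BR); stripes are distributed over the quadrants in
    proportion to these weights and rendered only where the weight is
    nonzero.  ``n_stripes`` is the total stripe budget.
    """

    image_size: int = 256
    skin_gray: float = 190.0
    skin_noise_sd: float = 3.0
    n_stripes: int = 8
    stripe_width_px: float = 6.0
    width_jitter: float = 0.1
    stripe_contrast: float = 40.0
    quadrant_occupancy: tuple[float, float, float, float] = (1.0, 1.0, 1.0, 1.0)
    waviness: float = 2.0
    wave_period: float = 64.0
    navel_xy: tuple[int, int] | None = None
    navel_disc: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.image_size <= 0:
            raise ValueError("image_size must be positive")
        if self.n_stripes < 0:
            raise ValueError("n_stripes must be >= 0")
        if self.stripe_width_px < 1:
            raise ValueError("stripe_width_px must be >= 1")
        if self.skin_gray - self.stripe_contrast < 0:
            raise ValueError("stripe_contrast may not exceed skin_gray")
        if any(not 0.0 <= f <= 1.0 for f in self.quadrant_occupancy):
            raise ValueError("quadrant occupancies must lie in [0, 1]")

    @property
    def navel(self) -> tuple[int, int]:
        if self.navel_xy is not None:
            return self.navel_xy
        c = self.image_size // 2 - 1
        return (c, c)


@dataclass(frozen=True)
class TruthFeatures:
    """Ground truth measured on the rendered mask/image, not spec nominals."""

    coverage: float
    quadrant_coverage: tuple[float, float, float, float]
    mean_width: float
    contrast: float


@dataclass(frozen=True)
class SyntheticPhoto:
    image: np.ndarray  # uint8 RGB
    truth_mask: np.ndarray  # bool, same H/W
    truth: TruthFeatures
    spec: StriaeSpec


def _ycbcr_to_rgb(y: np.ndarray, cb: float, cr: float) -> np.ndarray:
    r = y + 1.402 * (cr - 128.0)
    g = y - 0.344136 * (cb - 128.0) - 0.714136 * (cr - 128.0)
    b = y + 1.772 * (cb - 128.0)
    rgb = np.stack([r, g, b], axis=-1)
    return np.clip(np.round(rgb), 0, 255).astype(np.uint8)


def uniform_skin_image(size: int, gray: float = 190.0) -> np.ndarray:
    """A perfectly uniform skin-colored RGB raster (degenerate fixture)."""
    return _ycbcr_to_rgb(np.full((size, size), float(gray)), SKIN_CB, SKIN_CR)


def _allocate_stripes(total: int, weights: np.ndarray) -> np.ndarray:
    """Largest-remainder apportionment of the stripe budget over quadrants."""
    w = np.asarray(weights, dtype=float)
    if total == 0 or w.sum() == 0:
        return np.zeros(4, dtype=int)
    target = total * w / w.sum()
    counts = np.floor(target).astype(int)
    rem = target - counts
    for i in np.argsort(-rem)[: total - counts.sum()]:
        counts[i] += 1
    return counts


def _render_stripes(
    mask: np.ndarray,
    box: tuple[slice, slice],
    n: int,
    spec: StriaeSpec,
    rng: np.random.Generator,
) -> None:
    ysl, xsl = box
    y0, y1 = ysl.start, ysl.stop
    x0, x1 = xsl.start, xsl.stop
    if n == 0 or y1 - y0 < 1 or x1 - x0 < 1:
        return
    slots = np.linspace(x0, x1, n + 1)
    cols = np.arange(x0, x1)
    ys = np.arange(y0, y1)
    for k in range(n):
        w_k = max(1, int(round(spec.stripe_width_px * (1.0 + spec.width_jitter * rng.standard_normal()))))
        slot_w = slots[k + 1] - slots[k]
        cx = 0.5 * (slots[k] + slots[k + 1]) + rng.uniform(-0.15, 0.15) * slot_w
        phase = rng.uniform(0.0, 2.0 * np.pi)
        centers = cx + spec.waviness * np.sin(2.0 * np.pi * ys / spec.wave_period + phase)
        left = np.round(centers - w_k / 2.0).astype(int)
        band = (cols[None, :] >= left[:, None]) & (cols[None, :] < (left[:, None] + w_k))
        mask[y0:y1, x0:x1] |= band


def _mean_run_width(mask: np.ndarray) -> float:
    """Mean horizontal run length of a mask — the pixel-counted stripe width."""
    m = mask.astype(np.int8)
    starts = int(m[:, 0].sum()) + int(np.count_nonzero(np.diff(m, axis=1) == 1))
    return float(mask.sum()) / starts if starts else 0.0


def generate_photo(spec: StriaeSpec) -> SyntheticPhoto:
    """Render a synthetic striae photo; deterministic for a fixed spec+seed."""
    rng = np.random.default_rng(spec.seed)
    size = spec.image_size
    navel = spec.navel
    mask = np.zeros((size, size), dtype=bool)
    boxes = quadrant_slices((size, size), navel)
    counts = _allocate_stripes(spec.n_stripes, np.asarray(spec.quadrant_occupancy))
    for box, n in zip(boxes, counts):
        _render_stripes(mask, box, int(n), spec, rng)

    gray = np.full((size, size), float(spec.skin_gray))
    gray[mask] -= spec.stripe_contrast
    contrast = float((spec.skin_gray - gray[mask]).mean()) if mask.any() else 0.0

    quad_cov = []
    for ysl, xsl in boxes:
        quad = mask[ysl, xsl]
        quad_cov.append(float(np.count_nonzero(quad)) / quad.size if quad.size else 0.0)
    truth = TruthFeatures(
        coverage=float(np.count_nonzero(mask)) / mask.size,
        quadrant_coverage=tuple(quad_cov),
        mean_width=_mean_run_width(mask),
        contrast=contrast,
    )

    if spec.skin_noise_sd > 0:
        gray = gray + rng.normal(0.0, spec.skin_noise_sd, gray.shape)
    if spec.navel_disc:
        yy, xx = np.ogrid[:size, :size]
        disc = (xx - navel[0]) ** 2 + (yy - navel[1]) ** 2 <= _NAVEL_RADIUS**2
        gray[disc] = _NAVEL_GRAY
    image = _ycbcr_to_rgb(np.clip(gray, 0, 255), SKIN_CB, SKIN_CR)
    return SyntheticPhoto(image=image, truth_mask=mask, truth=truth, spec=spec)


def generate_band_photo(
    width_px: int,
    n_bands: int = 2,
    size: int = 256,
    contrast: float = 60.0,
    skin_gray: float = 190.0,
    noise_sd: float = 2.0,
    seed: int = 0,
) -> SyntheticPhoto:
    """Full-height straight vertical bands of exactly known width.

    A calibration fixture for the average-width estimator: the bands span the
    whole image so their perimeter is purely their two vertical sides.
    """
    rng = np.random.default_rng(seed)
    mask = np.zeros((size, size), dtype=bool)
    slots = np.linspace(0, size, n_bands + 1)
    for k in range(n_bands):
        cx = int(round(0.5 * (slots[k] + slots[k + 1])))
        left = cx - width_px // 2
        mask[:, left : left + width_px] = True
    gray = np.full((size, size), float(skin_gray))
    gray[mask] -= contrast
    truth = TruthFeatures(
        coverage=float(mask.sum()) / mask.size,
        quadrant_coverage=(np.nan,) * 4,
        mean_width=_mean_run_width(mask),
        contrast=contrast,
    )
    if noise_sd > 0:
        gray = gray + rng.normal(0.0, noise_sd, gray.shape)
    image = _ycbcr_to_rgb(np.clip(gray, 0, 255), SKIN_CB, SKIN_CR)
    spec = StriaeSpec(
        image_size=size,
        skin_gray=skin_gray,
        skin_noise_sd=noise_sd,
        n_stripes=n_bands,
        stripe_width_px=width_px,
        width_jitter=0.0,
        stripe_contrast=contrast,
        waviness=0.0,
        navel_disc=False,
        seed=seed,
    )
    return SyntheticPhoto(image=image, truth_mask=mask, truth=truth, spec=spec)


@dataclass(frozen=True)
class SeverityProfile:
    """Per-class distribution from which photo specs are drawn.

    Ranges are uniform-draw bounds; ``elasticity`` is (mean, SD) of the
    Cutometer R2 index.  ``n_quadrants`` bounds how many navel-centered
    quadrants carry stripes; ``occupancy`` is the target striae coverage of
    each active quadrant, which fixes the stripe budget given the width.
    """

    n_quadrants: tuple[int, int]
    occupancy: tuple[float, float]
    width_px: tuple[float, float]
    contrast: tuple[float, float]
    elasticity: tuple[float, float]

    def sample_spec(self, rng: np.random.Generator, image_size: int = 256) -> StriaeSpec:
        nq = int(rng.integers(self.n_quadrants[0], self.n_quadrants[1] + 1))
        quads = rng.choice(4, size=nq, replace=False)
        occ = np.zeros(4)
        occ[quads] = rng.uniform(*self.occupancy, size=nq)
        width = float(rng.uniform(*self.width_px))
        contrast = float(rng.uniform(*self.contrast))
        # each stripe covers ~width/(image_size/2) of its quadrant
        n_stripes = max(nq, int(round(occ.sum() * (image_size / 2.0) / width)))
        return StriaeSpec(
            image_size=image_size,
            n_stripes=n_stripes,
            stripe_width_px=width,
            stripe_contrast=contrast,
            quadrant_occupancy=tuple(occ),
            seed=int(rng.integers(2**31)),
        )

    def sample_elasticity(self, rng: np.random.Generator) -> tuple[float, ...]:
        r = rng.uniform(0.2, 0.95, size=10)
        r[2] = float(np.clip(rng.normal(*self.elasticity), 0.0, 1.0))
        return tuple(float(v) for v in r)


#: Study-like class conditions: mild photos carry a few faint narrow stripes
#: in one or two quadrants, severe photos many wide high-contrast stripes in
#: three or four.  Adjacent classes overlap in every single feature (no one
#: parameter classifies alone, matching the observation that single objective
#: parameters cannot separate the groups) while the classes stay well
#: separated in the joint feature space.  Elasticity means follow the
#: per-group averages reported for the Cutometer R2 index.
DEFAULT_PROFILES: dict[str, SeverityProfile] = {
    "mild": SeverityProfile(
        n_quadrants=(1, 2),
        occupancy=(0.20, 0.42),
        width_px=(3.0, 6.0),
        contrast=(10.0, 26.0),
        elasticity=(0.86, 0.008),
    ),
    "moderate": SeverityProfile(
        n_quadrants=(2, 3),
        occupancy=(0.36, 0.50),
        width_px=(5.0, 9.0),
        contrast=(22.0, 42.0),
        elasticity=(0.81, 0.008),
    ),
    "severe": SeverityProfile(
        n_quadrants=(3, 4),
        occupancy=(0.42, 0.49),
        width_px=(8.0, 12.0),
        contrast=(38.0, 62.0),
        elasticity=(0.79, 0.008),
    ),
}


@dataclass(frozen=True)
class CohortItem:
    photo_id: str
    photo: SyntheticPhoto
    label: str
    elasticity_record: tuple[float, ...]


def generate_cohort(
    n_per_class: int | Sequence[int] | Mapping[str, int],
    seed: int = 0,
    profiles: Mapping[str, SeverityProfile] = DEFAULT_PROFILES,
    image_size: int = 256,
) -> list[CohortItem]:
    """Draw a labeled synthetic cohort; reproducible under ``seed``.

    ``n_per_class`` may be a single count, a sequence ordered like
    ``SEVERITY_ORDER``, or a mapping label -> count.
    """
    labels = [lbl for lbl in SEVERITY_ORDER if lbl in profiles]
    extra = [lbl for lbl in profiles if lbl not in labels]
    labels += sorted(extra)
    if isinstance(n_per_class, Mapping):
        unknown = set(n_per_class) - set(labels)
        if unknown:
            raise ValueError(f"unknown severity labels: {sorted(unknown)}")
        counts = {lbl: int(n_per_class.get(lbl, 0)) for lbl in labels}
    elif isinstance(n_per_class, (int, np.integer)):
        counts = {lbl: int(n_per_class) for lbl in labels}
    else:
        if len(n_per_class) != len(labels):
            raise ValueError(f"expected {len(labels)} class counts, got {len(n_per_class)}")
        counts = dict(zip(labels, (int(n) for n in n_per_class)))
    if any(c < 1 for c in counts.values()):
        raise ValueError("n_per_class must be >= 1 for every class")

    rng = np.random.default_rng(seed)
    items: list[CohortItem] = []
    for lbl in labels:
        profile = profiles[lbl]
        for i in range(counts[lbl]):
            spec = profile.sample_spec(rng, image_size=image_size)
            items.append(
                CohortItem(
                    photo_id=f"{lbl}_{i:03d}",
                    photo=generate_photo(spec),
                    label=lbl,
                    elasticity_record=profile.sample_elasticity(rng),
                )
            )
    return items


def write_elasticity_record(photo_id: str, r_values: Sequence[float], path) -> None:
    """Append one photo's 10-value Cutometer record R0..R9 to a CSV file."""
    values = [float(v) for v in r_values]
    if len(values) != 10:
        raise ValueError(f"expected 10 values R0..R9, got {len(values)}")
    path = Path(path)
    new = not path.exists()
    with path.open("a", newline="") as fh:
        writer = csv.writer(fh)
        if new:
            writer.writerow(["photo_id"] + [f"R{i}" for i in range(10)])
        writer.writerow([photo_id] + [f"{v:.6g}" for v in values])


def write_cohort(items: Sequence[CohortItem], outdir) -> pd.DataFrame:
    """Write PNG images, manifest, truth table and elasticity CSV; return the manifest."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    (outdir / "images").mkdir(exist_ok=True)
    elastic_path = outdir / "elasticity.csv"
    if elastic_path.exists():
        elastic_path.unlink()
    manifest_rows, truth_rows = [], []
    for item in items:
        rel = f"images/{item.photo_id}.png"
        Image.fromarray(item.photo.image).save(outdir / rel)
        nx, ny = item.photo.spec.navel
        manifest_rows.append(
            {"photo_id": item.photo_id, "path": rel, "label": item.label,
             "navel_x": nx, "navel_y": ny}
        )
        t = item.photo.truth
        truth_rows.append(
            {"photo_id": item.photo_id, "coverage": t.coverage,
             "mean_width": t.mean_width, "contrast": t.contrast,
             **{f"quadrant_coverage_{i+1}": q for i, q in enumerate(t.quadrant_coverage)}}
        )
        write_elasticity_record(item.photo_id, item.elasticity_record, elastic_path)
    manifest = pd.DataFrame(manifest_rows)
    manifest.to_csv(outdir / "manifest.csv", index=False)
    pd.DataFrame(truth_rows).to_csv(outdir / "truth.csv", index=False)
    return manifest
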