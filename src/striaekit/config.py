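"""Pipeline configuration.

Two parameter bundles cover the tunables of the grading pipeline:
:class:`PipelineParams` for image preprocessing and feature extraction,
:class:`ClassifierParams` for the severity classifier and its evaluation
harness.  Both are frozen dataclasses so a configuration can be hashed and
logged for provenance.  YAML files may override any field; unknown keys are
rejected so typos fail loudly.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass
from pathlib import Path
from typing import Any, Mapping

import yaml

__all__ = [
    "PipelineParams",
    "ClassifierParams",
    "load_params",
    "config_hash",
]


@dataclass(frozen=True)
class PipelineParams:
    """Preprocessing and feature-extraction parameters.

    Attributes
    ----------
    skin_cb_range, skin_cr_range:
        Inclusive chroma bounds (full-range YCbCr) of the skin-color rule.
        The defaults are the classic Cb/Cr skin box.
    block_min, block_divisor:
        The adaptive-threshold neighbourhood is a square local-mean window of
        side ``max(block_min, sgr_side // block_divisor)`` (forced odd), so the
        neighbourhood scales with image resolution.
    deadzone:
        Gray-level half-width of the "similar to skin" band around the local
        mean; pixels within ``deadzone`` of the local mean are always
        skin-like.  Units: 8-bit gray levels.
    presmooth_sigma:
        Gaussian sigma (pixels) applied before adaptive thresholding to keep
        sensor-like pixel noise out of the striae class.
    canny_sigma:
        Gaussian sigma of the Canny detector used for the edge-pixel count.
    canny_low_frac, canny_high_frac:
        Hysteresis thresholds as fractions of the maximum gradient magnitude.
    canny_noise_mult:
        Lower bound on the hysteresis thresholds, as a multiple of the
        median-based robust gradient noise scale; keeps sensor noise from
        seeding edges on low-contrast photos.
    quadrant_threshold:
        Empirical per-quadrant density cut-off for the distribution area; a
        quadrant counts only when its striae density strictly exceeds it.
    """

    skin_cb_range: tuple[float, float] = (77.0, 127.0)
    skin_cr_range: tuple[float, float] = (133.0, 173.0)
    block_min: int = 15
    block_divisor: int = 8
    deadzone: float = 4.0
    presmooth_sigma: float = 1.0
    canny_sigma: float = 1.4
    canny_low_frac: float = 0.1
    canny_high_frac: float = 0.2
    canny_noise_mult: float = 4.0
    quadrant_threshold: float = 0.4


@dataclass(frozen=True)
class ClassifierParams:
    """Severity-classifier parameters.

    ``reg_bound`` is the soft-margin box constraint C of the dual problem
    (hard margin in the large-C limit).  Features are standardized to
    train-set mean/SD by default because the raw features mix scales
    (width in pixels against ratios in [0, 1]).
    """

    reg_bound: float = 1.0
    train_fraction: float = 0.8
    n_repeats: int = 40
    standardize: bool = True

    def __post_init__(self) -> None:
        if not self.reg_bound > 0:
            raise ValueError("reg_bound must be positive")
        if not 0.0 < self.train_fraction < 1.0:
            raise ValueError("train_fraction must be in (0, 1)")
        if self.n_repeats < 1:
            raise ValueError("n_repeats must be >= 1")


def _build(cls, mapping: Mapping[str, Any]):
    allowed = {f.name for f in dataclasses.fields(cls)}
    unknown = set(mapping) - allowed
    if unknown:
        raise KeyError(f"unknown {cls.__name__} keys: {sorted(unknown)}")
    kwargs = {
        k: tuple(v) if isinstance(v, list) else v for k, v in mapping.items()
    }
    return cls(**kwargs)


def load_params(path: str | Path | None) -> tuple[PipelineParams, ClassifierParams]:
    """Load parameter bundles from a YAML file.

    The file may contain top-level ``pipeline:`` and ``classifier:`` mappings;
    either may be omitted, in which case defaults apply.  ``path=None`` returns
    all defaults.
    """
    if path is None:
        return PipelineParams(), ClassifierParams()
    raw = yaml.safe_load(Path(path).read_text()) or {}
    if not isinstance(raw, dict):
        raise ValueError(f"config root must be a mapping: {path}")
    pipe = _build(PipelineParams, raw.get("pipeline", {}))
    clf = _build(ClassifierParams, raw.get("classifier", {}))
    return pipe, clf


def config_hash(*bundles) -> str:
    """Short stable hash of one or more parameter dataclasses, for run logs."""
    payload = json.dumps(
        [dataclasses.asdict(b) for b in bundles], sort_keys=True, default=str
    )
    return hashlib.sha256(payload.encode()).hexdigest()[:12]
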