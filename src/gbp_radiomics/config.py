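"""Pipeline configuration: every frozen parameter in one serializable place.

A single master seed fans out to stage-specific child seeds through a
deterministic SHA-256 derivation (`derive_seed`), so one knob reproduces the
whole run bit-for-bit.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Dict, List

import yaml

from .synthdata import DEFAULT_CLASS_PARAMS, ClassParams, CohortSpec


def derive_seed(master_seed: int, tag: str) -> int:
    """Deterministic child seed (< 2**31) for a named pipeline stage."""
    digest = hashlib.sha256(f"{master_seed}:{tag}".encode()).digest()
    return int.from_bytes(digest[:4], "little") % (2**31 - 1)


@dataclass
class PipelineConfig:
    # cohort
    n_lesions: int = 100
    n_neoplastic: int = 29
    image_size: int = 256
    pixel_spacing: float = 0.2
    jitter_px: float = 1.5
    # preprocess
    reference_margin_px: int = 10
    # features
    glcm_levels: int = 32
    glcm_max_offset: int = 15
    histogram_bins: int = 32
    # selection
    icc_threshold: float = 0.6
    lasso_n_lambdas: int = 100
    lasso_decades: float = 4.0
    lasso_cv_folds: int = 5
    selection_scope: str = "train"  # "train" (leakage-free) or "all"
    # classification
    train_ratio: float = 0.8
    n_repeats: int = 5
    svm_cv_folds: int = 5
    svm_c_exponents: List[int] = field(default_factory=lambda: list(range(-5, 16, 4)))
    svm_gamma_exponents: List[int] = field(
        default_factory=lambda: [-15, -11, -7, -3, 1, 3]
    )
    # stats
    normality_alpha: float = 0.05
    # seeding
    master_seed: int = 0

    def cohort_spec(self, class_params: Dict[str, ClassParams] | None = None) -> CohortSpec:
        return CohortSpec(
            n_lesions=self.n_lesions,
            n_neoplastic=self.n_neoplastic,
            seed=derive_seed(self.master_seed, "cohort"),
            image_size=self.image_size,
            pixel_spacing=self.pixel_spacing,
            class_params=class_params or dict(DEFAULT_CLASS_PARAMS),
            jitter_px=self.jitter_px,
        )

    def to_json(self) -> str:
        return json.dumps(asdict(self), sort_keys=True, indent=2)

    def config_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(asdict(self), sort_keys=True).encode()
        ).hexdigest()

    @classmethod
    def from_file(cls, path: str | Path) -> "PipelineConfig":
        text = Path(path).read_text()
        data = yaml.safe_load(text) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config fields: {sorted(unknown)}")
        return cls(**data)
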