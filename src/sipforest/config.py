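"""Pipeline configuration: validated settings and a stable config hash.

Every artifact the CLI writes embeds ``hash`` so that downstream stages
can refuse to mix features and models produced under different settings.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, fields, replace
from pathlib import Path

import yaml

__all__ = ["PipelineConfig", "config_hash", "load_config"]


@dataclass(frozen=True)
class PipelineConfig:
    """All tunable settings of the pipeline, with their defaults.

    Feature stage: ``wavelet`` family / ``wavelet_level`` /
    ``wavelet_mode`` control the 2-D transform; ``pca`` toggles the
    400 -> ``pca_components`` reduction and ``pca_scope`` decides whether
    the projection is fitted per training fold (no leakage) or once
    globally.  Classifier stage: ``window`` / ``stride`` for scanning,
    ``trees`` per forest, ``cascade_cv_folds`` for out-of-fold class
    vectors, ``tolerance`` (accuracy percentage points required to grow a
    level) and ``max_levels``.  Evaluation: ``folds`` and the RBF-SVM
    baseline parameters ``svm_c`` / ``svm_g``.
    """

    wavelet: str = "haar"
    wavelet_level: int = 1
    wavelet_mode: str = "periodization"
    encoder: str = "wavelet"
    pca: bool = True
    pca_components: int = 300
    pca_scope: str = "train_only"
    window: int = 100
    stride: int = 1
    trees: int = 500
    cascade_cv_folds: int = 3
    tolerance: float = 5.0
    max_levels: int = 5
    folds: int = 5
    svm_c: float = 0.3
    svm_g: float = 1000.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.wavelet_level < 1:
            raise ValueError("wavelet_level must be >= 1")
        if self.pca_scope not in ("train_only", "global"):
            raise ValueError("pca_scope must be 'train_only' or 'global'")
        if self.encoder not in ("wavelet", "eigenvalue"):
            raise ValueError("encoder must be 'wavelet' or 'eigenvalue'")
        for name in ("pca_components", "window", "stride", "trees", "max_levels"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if self.cascade_cv_folds < 2 or self.folds < 2:
            raise ValueError("fold counts must be >= 2")
        if self.tolerance < 0 or self.svm_c <= 0 or self.svm_g <= 0:
            raise ValueError("tolerance must be >= 0 and SVM parameters positive")

    @property
    def hash(self) -> str:
        return config_hash(asdict(self))

    def updated(self, **kwargs) -> "PipelineConfig":
        return replace(self, **kwargs)


def config_hash(payload: dict) -> str:
    """Stable short hash of a JSON-serializable settings mapping."""
    canonical = json.dumps(payload, sort_keys=True, default=str)
    return hashlib.sha256(canonical.encode()).hexdigest()[:12]


def load_config(path: str | Path) -> PipelineConfig:
    """Load a YAML or JSON config file; unknown keys are rejected."""
    raw = yaml.safe_load(Path(path).read_text()) or {}
    if not isinstance(raw, dict):
        raise ValueError(f"config file {path} must contain a mapping")
    known = {f.name for f in fields(PipelineConfig)}
    unknown = set(raw) - known
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    return PipelineConfig(**raw)
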