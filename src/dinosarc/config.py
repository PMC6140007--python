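"""Layered pipeline configuration with provenance tracking.

Every tunable of the pipeline lives in :class:`PipelineConfig`.  Defaults
that come from the published DINOSARC methodology (e.g. the 10 x 10
detector window, the 500-700-word vocabulary range) are flagged
``method``; values the methodology leaves open and this package chose are
flagged ``package``, so a manifest always records which is which.  The
config round-trips losslessly through YAML; unknown keys are rejected.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass
from pathlib import Path
from typing import Optional

import yaml

from .errors import ParameterError

__all__ = ["PipelineConfig", "PARAM_PROVENANCE"]

#: Where each default comes from: the methodology itself or this package.
PARAM_PROVENANCE = {
    "fov": "package",
    "fov_threshold": "package",
    "bin_width": "package",
    "smoothing_radius": "package",
    "nonmax_window_n": "package",
    "window_s": "method",
    "saliency_tau": "package",
    "k_sp": "package",
    "m_sp": "package",
    "k_vocab": "method",
    "vocab_seed": "package",
    "folds": "method",
    "cv_seed": "package",
    "standardize": "package",
    "synth_seed": "package",
}


@dataclass
class PipelineConfig:
    """All pipeline tunables, with serialization helpers."""

    fov: bool = True
    fov_threshold: int = 10
    bin_width: float = 1.0
    smoothing_radius: int = 2
    nonmax_window_n: int = 5
    window_s: int = 10
    saliency_tau: Optional[float] = None  # None = AUTO (per-image mean)
    k_sp: int = 200
    m_sp: float = 10.0
    k_vocab: int = 600
    vocab_seed: int = 7
    folds: int = 10
    cv_seed: int = 7
    standardize: bool = False
    synth_seed: int = 7

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, data: dict) -> "PipelineConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ParameterError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        if not isinstance(data, dict):
            raise ParameterError("config file must contain a mapping")
        return cls.from_dict(data)

    def config_hash(self) -> str:
        """Stable hash of the canonical serialized form (for manifests)."""
        canon = json.dumps(self.to_dict(), sort_keys=True)
        return hashlib.sha256(canon.encode()).hexdigest()[:16]

    def provenance(self) -> dict[str, str]:
        return dict(PARAM_PROVENANCE)
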