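"""YAML run configuration with strict key checking.

A config file has up to five sections mirroring the pipeline stages plus a
global seed; every stage seed defaults deterministically to the global one.
Unknown sections or keys are rejected so typos cannot silently fall back to
defaults.
"""

from __future__ import annotations

import dataclasses
import hashlib
from dataclasses import dataclass, field

import yaml

from .errors import ValidationError

_ALLOWED: dict[str, set[str]] = {
    "simulate": {
        "mode", "n_rows", "n_cols", "frame_rate", "n_stimuli", "n_trials",
        "stim_duration_s", "blank_duration_s", "resting_duration_s",
        "sigma_area", "sigma_global", "sigma_noise", "kernel_amplitude",
        "spatial_smooth_px", "per_area_counts", "seed",
    },
    "features": {"n_pcs", "max_pcs", "use_lda", "zscore"},
    "classifiers": {"name", "n_components", "C", "kernel", "epochs", "lr"},
    "semisup": {
        "n_components_ubm", "relevance", "cell_px", "schedule_start",
        "schedule_end", "smooth_train_frac", "n_repeats",
    },
    "evaluate": {
        "mode", "train_fraction", "sample_radius_frac", "n_repeats",
        "stimuli", "resting", "durations_s", "conditions",
    },
}


@dataclass
class RunConfig:
    """Validated configuration for one pipeline run."""

    seed: int = 0
    simulate: dict = field(default_factory=dict)
    features: dict = field(default_factory=dict)
    classifiers: dict = field(default_factory=dict)
    semisup: dict = field(default_factory=dict)
    evaluate: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        for section, allowed in _ALLOWED.items():
            payload = getattr(self, section)
            if not isinstance(payload, dict):
                raise ValidationError(f"section {section!r} must be a mapping")
            unknown = set(payload) - allowed
            if unknown:
                raise ValidationError(
                    f"unknown keys in section {section!r}: {sorted(unknown)}"
                )

    def section_seed(self, section: str) -> int:
        """Deterministic per-section seed derived from the global seed."""
        payload = getattr(self, section, {})
        if isinstance(payload, dict) and payload.get("seed") is not None:
            return int(payload["seed"])
        offset = {"simulate": 0, "features": 1, "classifiers": 2, "semisup": 3,
                  "evaluate": 4}.get(section, 9)
        return (int(self.seed) * 13 + offset) % (2**31 - 1)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def config_hash(self) -> str:
        canonical = yaml.safe_dump(self.to_dict(), sort_keys=True)
        return hashlib.sha256(canonical.encode()).hexdigest()[:12]


def load_config(path) -> RunConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise ValidationError("config root must be a mapping")
    unknown = set(raw) - (set(_ALLOWED) | {"seed"})
    if unknown:
        raise ValidationError(f"unknown top-level config keys: {sorted(unknown)}")
    return RunConfig(**raw)
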