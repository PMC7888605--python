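"""Core domain containers: area maps, simulation parameters, recordings.

The six classification targets are the retinotopically defined core visual
areas of mouse cortex -- V1 (primary visual cortex), LM (lateromedial), AL
(anterolateral), RL (rostrolateral), AM (anteromedial) and PM
(posteromedial) -- encoded as integer codes 1..6 with 0 reserved for
background (non-visual / outside the imaging window).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import NamedTuple

import numpy as np
from skimage import measure

from .errors import ValidationError

#: canonical area code -> name mapping
AREA_NAMES: dict[int, str] = {1: "V1", 2: "LM", 3: "AL", 4: "RL", 5: "AM", 6: "PM"}
AREA_CODES: tuple[int, ...] = tuple(AREA_NAMES)
N_AREAS: int = len(AREA_NAMES)


class Trial(NamedTuple):
    """One stimulus presentation: half-open frame window [onset, onset + n_frames)."""

    stimulus_id: int
    onset_frame: int
    n_frames: int


@dataclass
class AreaMap:
    """2-D integer raster assigning each pixel to one of six areas or background.

    Parameters
    ----------
    labels
        ``(rows, cols)`` integer array with values in ``{0} | AREA_CODES``;
        0 marks background pixels excluded from all analyses.
    area_names
        Code -> name map; defaults to the canonical six-area naming.
    pixel_size
        Physical pixel pitch in mm/pixel (informational only).
    """

    labels: np.ndarray
    area_names: dict[int, str] = field(default_factory=lambda: dict(AREA_NAMES))
    pixel_size: float = 0.05

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 2:
            raise ValidationError("AreaMap labels must be a 2-D raster")
        if not np.issubdtype(self.labels.dtype, np.integer):
            raise ValidationError("AreaMap labels must be integer-valued")

    @property
    def shape(self) -> tuple[int, int]:
        return self.labels.shape  # type: ignore[return-value]

    @property
    def codes(self) -> np.ndarray:
        """Sorted nonzero area codes present in the raster."""
        vals = np.unique(self.labels)
        return vals[vals > 0]

    def mask(self, code: int) -> np.ndarray:
        return self.labels == code

    @property
    def in_map(self) -> np.ndarray:
        """Boolean mask of pixels belonging to any area."""
        return self.labels > 0

    def pixel_counts(self) -> dict[int, int]:
        return {int(c): int((self.labels == c).sum()) for c in self.codes}

    def validate(self) -> None:
        """Check contiguity of every nonzero label (4-connectivity)."""
        for code in self.codes:
            n_comp = measure.label(self.mask(int(code)), connectivity=1).max()
            if n_comp != 1:
                raise ValidationError(
                    f"area {code} ({self.area_names.get(int(code), '?')}) is not "
                    f"4-connected ({n_comp} components)"
                )


@dataclass
class SimulationParams:
    """Knobs of the synthetic calcium-imaging generator.

    Signal model per pixel/neuron (all in dF/F units): a shared global
    fluctuation, an area-specific latent, stimulus-locked area-specific
    response kernels during trial windows, and private noise. The trial
    design is a block design: every stimulus appears once per block in a
    random order, repeated ``n_trials`` times, matching a 10-repeat block
    protocol with 2 s stimuli and 2 s blanks; an untrialed resting-state
    segment follows the trial blocks.
    """

    n_rows: int = 64
    n_cols: int = 64
    frame_rate: float = 10.0
    n_stimuli: int = 8
    n_trials: int = 10
    stim_duration_s: float = 2.0
    blank_duration_s: float = 2.0
    resting_duration_s: float = 120.0
    sigma_area: float = 1.0
    sigma_global: float = 1.0
    sigma_noise: float = 1.0
    kernel_amplitude: float = 1.0
    spatial_smooth_px: float = 1.0
    seed: int = 0
    per_area_counts: dict[int, int] | None = None

    def __post_init__(self) -> None:
        for name in ("sigma_area", "sigma_global", "sigma_noise", "kernel_amplitude"):
            if getattr(self, name) < 0:
                raise ValidationError(f"{name} must be >= 0")
        if self.n_trials < 1:
            raise ValidationError("n_trials must be >= 1")
        if self.n_stimuli < 0:
            raise ValidationError("n_stimuli must be >= 0")
        if self.frame_rate <= 0:
            raise ValidationError("frame_rate must be positive")
        if self.spatial_smooth_px < 0:
            raise ValidationError("spatial_smooth_px must be >= 0")
        if self.per_area_counts is not None:
            if len(self.per_area_counts) == 0:
                raise ValidationError("per_area_counts must not be empty")
            if any(n < 1 for n in self.per_area_counts.values()):
                raise ValidationError("per_area_counts must be >= 1 per area")

    @property
    def stim_frames(self) -> int:
        return int(round(self.stim_duration_s * self.frame_rate))

    @property
    def blank_frames(self) -> int:
        return int(round(self.blank_duration_s * self.frame_rate))

    @property
    def resting_frames(self) -> int:
        return int(round(self.resting_duration_s * self.frame_rate))

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        if d["per_area_counts"] is not None:
            d["per_area_counts"] = {int(k): int(v) for k, v in d["per_area_counts"].items()}
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SimulationParams":
        d = dict(d)
        if d.get("per_area_counts") is not None:
            d["per_area_counts"] = {int(k): int(v) for k, v in d["per_area_counts"].items()}
        return cls(**d)


@dataclass
class Recording:
    """A units x timepoints dF/F matrix with metadata.

    ``mode`` is ``"widefield"`` (units are pixels, with coordinates) or
    ``"twophoton"`` (units are neurons, no coordinates). Trial windows are
    half-open 0-based frame ranges; frames after the last trial window form
    the untrialed (resting-state) segment.
    """

    responses: np.ndarray
    unit_labels: np.ndarray
    trials: list[Trial]
    frame_rate: float
    mode: str
    unit_coords: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.responses = np.asarray(self.responses)
        self.unit_labels = np.asarray(self.unit_labels)
        self.trials = [Trial(*t) for t in self.trials]

    @property
    def n_units(self) -> int:
        return self.responses.shape[0]

    @property
    def n_frames(self) -> int:
        return self.responses.shape[1]

    @property
    def trial_end(self) -> int:
        """First frame after the last trial window (0 if untrialed)."""
        if not self.trials:
            return 0
        return max(t.onset_frame + t.n_frames for t in self.trials)

    def stimulus_ids(self) -> np.ndarray:
        return np.unique([t.stimulus_id for t in self.trials])

    def validate(self, area_map: AreaMap | None = None) -> None:
        if self.responses.ndim != 2:
            raise ValidationError("responses must be units x timepoints")
        if self.unit_labels.shape != (self.n_units,):
            raise ValidationError("unit_labels length must match responses rows")
        for t in self.trials:
            if t.onset_frame < 0 or t.onset_frame + t.n_frames > self.n_frames:
                raise ValidationError(f"trial window {t} exceeds recording length")
        if self.mode not in ("widefield", "twophoton"):
            raise ValidationError(f"unknown mode {self.mode!r}")
        if self.mode == "widefield":
            if self.unit_coords is None:
                raise ValidationError("widefield recording requires unit_coords")
            if self.unit_coords.shape != (self.n_units, 2):
                raise ValidationError("unit_coords must be units x 2")
            uniq = np.unique(self.unit_coords, axis=0)
            if uniq.shape[0] != self.n_units:
                raise ValidationError("unit_coords must be unique")
            if area_map is not None:
                r, c = self.unit_coords.T
                rows, cols = area_map.shape
                if (r < 0).any() or (r >= rows).any() or (c < 0).any() or (c >= cols).any():
                    raise ValidationError("unit_coords fall outside the area map")
                if not np.array_equal(area_map.labels[r, c], self.unit_labels):
                    raise ValidationError("unit_labels disagree with the area map")
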