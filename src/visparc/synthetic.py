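"""Synthetic wide-field sheets and two-photon unit collections.

The generator stands in for raw calcium-imaging data while preserving the
statistical structure the downstream analyses rely on:

* a 2-D cortical sheet partitioned into six 4-connected areas, with V1
  holding at least as many pixels as any other area (the size imbalance
  that drives the size-biased chance level);
* each unit's trace is a sum of a shared global fluctuation, an
  area-specific latent, stimulus-locked area-specific response kernels
  during trial windows, and private noise -- so intra-area correlation
  exceeds inter-area correlation, trial averaging raises SNR, and the
  closed-form correlation means are known exactly;
* a block trial design (every stimulus once per block, random order per
  block) followed by an untrialed resting-state segment.

All generators are deterministic for a fixed seed.
"""

from __future__ import annotations

import heapq

import numpy as np
from scipy.ndimage import gaussian_filter

from .errors import DegenerateSignalError, SizingError, ValidationError
from .types import AREA_CODES, AREA_NAMES, AreaMap, Recording, SimulationParams, Trial

# Canonical seed placement (fractions of rows/cols; row 0 = anterior edge).
# V1 sits posterior-central, ringed by the five higher areas, echoing the
# anatomical arrangement of mouse visual cortex.
_SEED_FRACTIONS: dict[int, tuple[float, float]] = {
    1: (0.66, 0.50),  # V1
    2: (0.48, 0.20),  # LM
    3: (0.26, 0.30),  # AL
    4: (0.16, 0.54),  # RL
    5: (0.28, 0.76),  # AM
    6: (0.50, 0.82),  # PM
}
_MIN_AREA_PX = 25


def _ellipse_mask(n_rows: int, n_cols: int) -> np.ndarray:
    r0, c0 = (n_rows - 1) / 2.0, (n_cols - 1) / 2.0
    ar, ac = 0.49 * n_rows, 0.49 * n_cols
    rr, cc = np.mgrid[0:n_rows, 0:n_cols]
    return ((rr - r0) / ar) ** 2 + ((cc - c0) / ac) ** 2 <= 1.0


def _grow_regions(
    mask: np.ndarray, seeds: dict[int, tuple[int, int]], speeds: dict[int, float]
) -> np.ndarray:
    """Competitive wavefront growth (multi-label Dijkstra, 4-neighborhood).

    Each region expands from its seed through its own claimed territory at a
    per-region speed, which guarantees 4-connectivity by construction; faster
    regions claim proportionally more pixels.
    """
    labels = np.zeros(mask.shape, dtype=np.int16)
    arrival = np.full(mask.shape, np.inf)
    heap: list[tuple[float, int, int, int]] = []
    for code, (r, c) in seeds.items():
        labels[r, c] = code
        arrival[r, c] = 0.0
        heapq.heappush(heap, (0.0, code, r, c))
    while heap:
        t, code, r, c = heapq.heappop(heap)
        if t > arrival[r, c] or labels[r, c] != code:
            continue
        step = 1.0 / speeds[code]
        for dr, dc in ((-1, 0), (1, 0), (0, -1), (0, 1)):
            nr, nc = r + dr, c + dc
            if 0 <= nr < mask.shape[0] and 0 <= nc < mask.shape[1] and mask[nr, nc]:
                nt = t + step
                if nt < arrival[nr, nc]:
                    arrival[nr, nc] = nt
                    labels[nr, nc] = code
                    heapq.heappush(heap, (nt, code, nr, nc))
    return labels


def generate_area_map(n_rows: int, n_cols: int, seed: int = 0) -> AreaMap:
    """Generate a six-area cortical sheet with a dominant V1.

    An elliptical imaging window is partitioned by seeded competitive growth;
    the V1 seed expands faster (about a 2x pixel budget), so V1 ends up at
    least as large as every other area. Pixels outside the ellipse are
    background (label 0).

    Raises
    ------
    SizingError
        If the raster cannot host six contiguous regions of >= 25 pixels.
    """
    if n_rows < 32 or n_cols < 32:
        raise SizingError("raster must be at least 32 x 32 to host 6 areas")
    mask = _ellipse_mask(n_rows, n_cols)
    if int(mask.sum()) < 6 * _MIN_AREA_PX:
        raise SizingError("raster too small for 6 areas of >= 25 pixels")
    rng = np.random.default_rng(seed)

    seeds: dict[int, tuple[int, int]] = {}
    in_rows, in_cols = np.nonzero(mask)
    for code in AREA_CODES:
        fr, fc = _SEED_FRACTIONS[code]
        r = (fr + rng.uniform(-0.03, 0.03)) * (n_rows - 1)
        c = (fc + rng.uniform(-0.03, 0.03)) * (n_cols - 1)
        # snap to the nearest in-window pixel not already used as a seed
        d2 = (in_rows - r) ** 2 + (in_cols - c) ** 2
        for idx in np.argsort(d2):
            cand = (int(in_rows[idx]), int(in_cols[idx]))
            if cand not in seeds.values():
                seeds[code] = cand
                break

    v1_speed = np.sqrt(2.0)  # area grows ~ speed^2 in 2-D -> ~2x budget
    for _ in range(6):
        speeds = {c: (v1_speed if c == 1 else 1.0) for c in AREA_CODES}
        labels = _grow_regions(mask, seeds, speeds)
        counts = {c: int((labels == c).sum()) for c in AREA_CODES}
        if counts[1] >= max(counts[c] for c in AREA_CODES if c != 1):
            break
        v1_speed *= 1.2  # crowding starved V1; give it more headway
    if min(counts.values()) < _MIN_AREA_PX:
        raise SizingError(f"smallest area below {_MIN_AREA_PX} pixels: {counts}")

    amap = AreaMap(labels=labels, area_names=dict(AREA_NAMES))
    amap.validate()
    return amap


def _trial_schedule(params: SimulationParams, rng: np.random.Generator) -> list[Trial]:
    """Block design: every stimulus once per block, random order per block."""
    trials: list[Trial] = []
    cursor = 0
    for _ in range(params.n_trials):
        order = rng.permutation(params.n_stimuli)
        for s in order:
            trials.append(Trial(int(s), cursor, params.stim_frames))
            cursor += params.stim_frames + params.blank_frames
    return trials


def _latents_and_kernels(params: SimulationParams, n_frames: int, rng: np.random.Generator):
    g = rng.standard_normal(n_frames)
    area_latents = {c: rng.standard_normal(n_frames) for c in AREA_CODES}
    kernels = {
        (c, s): params.kernel_amplitude * rng.standard_normal(params.stim_frames)
        for c in AREA_CODES
        for s in range(params.n_stimuli)
    }
    return g, area_latents, kernels


def _check_nondegenerate(params: SimulationParams) -> None:
    stim_power = params.kernel_amplitude if params.n_stimuli > 0 else 0.0
    if (
        params.sigma_area == 0
        and params.sigma_global == 0
        and params.sigma_noise == 0
        and stim_power == 0
    ):
        raise DegenerateSignalError(
            "all signal amplitudes are zero: every trace would be identically 0"
        )


def simulate_widefield(area_map: AreaMap, params: SimulationParams) -> Recording:
    """Simulate a wide-field recording over an area map.

    Every raster pixel is a unit (background pixels receive only the global
    fluctuation and noise and carry label 0). The per-pixel noise field is
    spatially Gaussian-smoothed with radius ``spatial_smooth_px``, mimicking
    the optical blur that correlates neighboring wide-field pixels; smoothing
    is applied after amplitude scaling, so nonzero smoothing shrinks the
    noise variance (the closed-form correlation means assume no smoothing).
    """
    _check_nondegenerate(params)
    if area_map.codes.size == 0:
        raise ValidationError("area map has no areas")
    n_rows, n_cols = area_map.shape
    rng = np.random.default_rng(params.seed)
    trials = _trial_schedule(params, rng)
    trial_frames = max((t.onset_frame + t.n_frames for t in trials), default=0)
    if trials:
        trial_frames += params.blank_frames  # trailing blank of the last trial
    n_frames = trial_frames + params.resting_frames
    if n_frames == 0:
        raise DegenerateSignalError("simulation would contain zero frames")
    g, area_latents, kernels = _latents_and_kernels(params, n_frames, rng)

    field = rng.standard_normal((n_frames, n_rows, n_cols)).astype(np.float32)
    field *= params.sigma_noise
    if params.spatial_smooth_px > 0 and params.sigma_noise > 0:
        field = gaussian_filter(
            field, sigma=(0.0, params.spatial_smooth_px, params.spatial_smooth_px)
        )
    field += (params.sigma_global * g)[:, None, None].astype(np.float32)
    for code in area_map.codes:
        m = area_map.mask(int(code))
        field[:, m] += (params.sigma_area * area_latents[int(code)])[:, None].astype(
            np.float32
        )
        for t in trials:
            k = kernels[(int(code), t.stimulus_id)]
            field[t.onset_frame : t.onset_frame + t.n_frames, m] += k[:, None].astype(
                np.float32
            )

    coords = np.argwhere(np.ones((n_rows, n_cols), dtype=bool)).astype(np.int32)
    labels = area_map.labels[coords[:, 0], coords[:, 1]].astype(np.int16)
    responses = field.reshape(n_frames, n_rows * n_cols).T
    rec = Recording(
        responses=responses,
        unit_labels=labels,
        trials=trials,
        frame_rate=params.frame_rate,
        mode="widefield",
        unit_coords=coords,
    )
    rec.validate(area_map)
    return rec


def simulate_twophoton(
    per_area_counts: dict[int, int], params: SimulationParams
) -> Recording:
    """Simulate a two-photon-style collection of independent units per area.

    Same latent model as :func:`simulate_widefield` but with no spatial
    structure: units are exchangeable within an area, and the per-area unit
    counts are exactly as requested (e.g. the unbalanced counts of a public
    cellular-resolution survey).
    """
    if not per_area_counts:
        raise ValidationError("per_area_counts must not be empty")
    if any(n < 1 for n in per_area_counts.values()):
        raise ValidationError("per-area counts must be >= 1")
    if not set(per_area_counts) <= set(AREA_CODES):
        raise ValidationError(f"area codes must be within {AREA_CODES}")
    _check_nondegenerate(params)
    rng = np.random.default_rng(params.seed)
    trials = _trial_schedule(params, rng)
    trial_frames = max((t.onset_frame + t.n_frames for t in trials), default=0)
    if trials:
        trial_frames += params.blank_frames
    n_frames = trial_frames + params.resting_frames
    if n_frames == 0:
        raise DegenerateSignalError("simulation would contain zero frames")
    g, area_latents, kernels = _latents_and_kernels(params, n_frames, rng)

    codes = sorted(per_area_counts)
    n_units = sum(per_area_counts[c] for c in codes)
    responses = np.empty((n_units, n_frames), dtype=np.float32)
    labels = np.empty(n_units, dtype=np.int16)
    row = 0
    for code in codes:
        n = per_area_counts[code]
        block = params.sigma_noise * rng.standard_normal((n, n_frames))
        block += params.sigma_global * g
        block += params.sigma_area * area_latents[code]
        for t in trials:
            k = kernels[(code, t.stimulus_id)]
            block[:, t.onset_frame : t.onset_frame + t.n_frames] += k
        responses[row : row + n] = block
        labels[row : row + n] = code
        row += n
    rec = Recording(
        responses=responses,
        unit_labels=labels,
        trials=trials,
        frame_rate=params.frame_rate,
        mode="twophoton",
    )
    rec.validate()
    return rec
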