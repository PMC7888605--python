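"""Semi-supervised parcellation: UBM, MAP adaptation, merge scoring, growth.

The only supervision is one labeled grid cell at the interior pole of each
area. A universal background model (UBM) -- a large Gaussian mixture
trained on the PCA features of every cortical pixel, label-free -- serves
as a prior; cluster-specific models are obtained by maximum-a-posteriori
(MAP) adaptation of the UBM *means* toward a cell's data, with a relevance
factor controlling the prior/data balance. The merge score between two
neighboring cells,

    S(a, b) = log p(D | lam) - [log p(D_a | lam_a) + log p(D_b | lam_b)],

with each model MAP-adapted to its data (D = D_a u D_b), measures the
likelihood gain from modeling the cells jointly: a modified Bayesian
information criterion whose penalty term is replaced by an adaptive
per-iteration threshold. Labeled regions grow by merging the top x% of
frontier scores per iteration, x shrinking linearly from 80 to 20 as cells
acquire labels; a final supervised classifier trained on samples from the
grown clusters smooths the pixel-level boundaries.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage

from ._gmm import GaussianMixture, fit_gaussian_mixture
from .classifiers import fit_gmm
from .errors import CapacityError, ValidationError
from .features import fit_pca, project_pca, trial_average, zscore_rows
from .types import AreaMap, Recording

logger = logging.getLogger(__name__)

DEFAULT_RELEVANCE = 16.0
DEFAULT_M_UBM = 64
DEFAULT_CELL_PX = 4


@dataclass
class UBM:
    """Universal background model: one large label-free mixture over all pixels."""

    gmm: GaussianMixture
    n_components: int
    seed: int


def train_ubm(
    features: np.ndarray,
    n_components: int = DEFAULT_M_UBM,
    seed: int = 0,
    cov_type: str = "diag",
) -> UBM:
    """EM-train the UBM on all in-map pixel features (no labels used).

    Diagonal covariances are the convention for large background mixtures;
    modeling the whole sheet needs many more components than a per-area
    model, hence the large default.
    """
    X = np.asarray(features, dtype=np.float64)
    if X.shape[0] < n_components:
        raise CapacityError(
            f"{n_components} UBM components exceed {X.shape[0]} samples"
        )
    gmm = fit_gaussian_mixture(X, n_components, seed=seed, cov_type=cov_type)
    return UBM(gmm=gmm, n_components=n_components, seed=seed)


# ---------------------------------------------------------------------------
# grid partition


@dataclass
class ClusterState:
    """Grid partition of the in-map pixels with a per-cell label assignment.

    ``cells[i]`` holds the flat (row-major) raster indices of cell ``i``'s
    pixels; ``labels[i]`` is an area code or 0 while unlabeled;
    ``cell_raster`` maps each pixel to its cell id (-1 for background).
    """

    cells: list[np.ndarray]
    labels: np.ndarray
    adjacency: dict[int, set[int]]
    cell_raster: np.ndarray
    iteration: int = 0
    merge_log: list[dict] = field(default_factory=list)

    @property
    def n_cells(self) -> int:
        return len(self.cells)

    @property
    def n_unlabeled(self) -> int:
        return int((self.labels == 0).sum())

    def pixel_labels(self) -> np.ndarray:
        """Per-pixel labels implied by the current cell labels (raster)."""
        out = np.zeros(self.cell_raster.shape, dtype=np.int16)
        flat = out.ravel()
        for i, px in enumerate(self.cells):
            flat[px] = self.labels[i]
        return out


def _adjacency_from_raster(cell_raster: np.ndarray, n_cells: int) -> dict[int, set[int]]:
    adj: dict[int, set[int]] = {i: set() for i in range(n_cells)}
    for shift in (np.s_[:, :-1], np.s_[:-1, :]):
        if shift == np.s_[:, :-1]:
            a, b = cell_raster[:, :-1], cell_raster[:, 1:]
        else:
            a, b = cell_raster[:-1, :], cell_raster[1:, :]
        both = (a >= 0) & (b >= 0) & (a != b)
        for x, y in zip(a[both].ravel(), b[both].ravel()):
            adj[int(x)].add(int(y))
            adj[int(y)].add(int(x))
    return adj


def partition_grid(area_map: AreaMap, cell_px: int = DEFAULT_CELL_PX) -> ClusterState:
    """Tile the in-map pixels with square cells of ``cell_px`` pixels.

    Edge cells smaller than a quarter of the full cell area are merged into
    the adjacent cell that shares the most pixel boundary. Every in-map
    pixel ends up in exactly one cell.
    """
    if cell_px < 2:
        raise ValidationError("cell_px must be >= 2")
    rows, cols = area_map.shape
    if cell_px > min(rows, cols):
        logger.warning("cell_px %d exceeds the raster extent; one giant cell", cell_px)
    in_map = area_map.in_map
    cell_raster = np.full((rows, cols), -1, dtype=np.int64)
    cells: list[np.ndarray] = []
    for r0 in range(0, rows, cell_px):
        for c0 in range(0, cols, cell_px):
            block = np.zeros((rows, cols), dtype=bool)
            block[r0 : r0 + cell_px, c0 : c0 + cell_px] = True
            px = np.flatnonzero((block & in_map).ravel())
            if px.size == 0:
                continue
            cell_raster.ravel()[px] = len(cells)
            cells.append(px)

    # fold undersized edge cells into their best-connected neighbor
    min_px = max(1, cell_px * cell_px // 4)
    adj = _adjacency_from_raster(cell_raster, len(cells))
    order = np.argsort([c.size for c in cells])
    merged_into: dict[int, int] = {}

    def resolve(i: int) -> int:
        while i in merged_into:
            i = merged_into[i]
        return i

    for i in order:
        i = int(i)
        if i in merged_into or cells[i].size >= min_px:
            continue
        neighbors = {resolve(j) for j in adj[i]} - {i}
        if not neighbors:
            continue  # isolated fragment; keep as its own cell
        # most shared boundary, ties to the lowest id
        best, best_shared = None, -1
        ri, ci = np.unravel_index(cells[i], (rows, cols))
        for j in sorted(neighbors):
            rj, cj = np.unravel_index(cells[j], (rows, cols))
            shared = 0
            pix_j = set(zip(rj.tolist(), cj.tolist()))
            for r, c in zip(ri.tolist(), ci.tolist()):
                shared += sum(
                    (r + dr, c + dc) in pix_j
                    for dr, dc in ((-1, 0), (1, 0), (0, -1), (0, 1))
                )
            if shared > best_shared:
                best, best_shared = j, shared
        cells[best] = np.sort(np.concatenate([cells[best], cells[i]]))
        merged_into[i] = best

    keep = [i for i in range(len(cells)) if i not in merged_into]
    final_cells = [cells[i] for i in keep]
    cell_raster = np.full((rows, cols), -1, dtype=np.int64)
    for new_id, px in enumerate(final_cells):
        cell_raster.ravel()[px] = new_id
    adjacency = _adjacency_from_raster(cell_raster, len(final_cells))
    return ClusterState(
        cells=final_cells,
        labels=np.zeros(len(final_cells), dtype=np.int16),
        adjacency=adjacency,
        cell_raster=cell_raster,
    )


def seed_centers(state: ClusterState, area_map: AreaMap) -> ClusterState:
    """Label the cell at each area's interior pole; all other cells stay unlabeled.

    The interior pole is the pixel maximizing the within-area distance
    transform (well-defined even for concave areas, unlike the centroid).
    Larger areas claim first; a smaller area whose pole cell is taken
    re-seeds at its next-deepest pixel.
    """
    codes = sorted(
        (int(c) for c in area_map.codes),
        key=lambda c: -int((area_map.labels == c).sum()),
    )
    labels = state.labels.copy()
    for code in codes:
        dist = ndimage.distance_transform_edt(area_map.mask(code))
        order = np.argsort(dist.ravel())[::-1]
        placed = False
        for flat in order:
            if dist.ravel()[flat] <= 0:
                break
            cell = state.cell_raster.ravel()[flat]
            if cell >= 0 and labels[cell] == 0:
                labels[cell] = code
                placed = True
                break
        if not placed:
            raise ValidationError(f"could not seed area {code}: no free cell")
    new = ClusterState(
        cells=state.cells,
        labels=labels,
        adjacency=state.adjacency,
        cell_raster=state.cell_raster,
    )
    return new


# ---------------------------------------------------------------------------
# MAP adaptation and merge scoring


def map_adapt(ubm: UBM, data: np.ndarray, relevance: float = DEFAULT_RELEVANCE) -> GaussianMixture:
    """Adapt the UBM means toward ``data``; weights and covariances are kept.

    Per component k: responsibilities gamma over the data give occupancy
    n_k and the weighted data mean E_k; the adapted mean is
    alpha_k E_k + (1 - alpha_k) mu_k with alpha_k = n_k / (n_k + relevance).
    ``relevance=inf`` returns the UBM unchanged; ``relevance -> 0`` lets the
    data dominate wherever it lands.
    """
    data = np.atleast_2d(np.asarray(data, dtype=np.float64))
    if data.shape[0] == 0:
        raise ValidationError("cannot adapt to an empty cell")
    if not relevance > 0:
        raise ValidationError("relevance must be positive")
    resp, _ = ubm.gmm.responsibilities(data)
    n_k = resp.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        E_k = (resp.T @ data) / n_k[:, None]
    E_k[n_k <= 0] = ubm.gmm.means[n_k <= 0]
    alpha = n_k / (n_k + relevance)
    means = alpha[:, None] * E_k + (1.0 - alpha[:, None]) * ubm.gmm.means
    return GaussianMixture(
        weights=ubm.gmm.weights,
        means=means,
        covariances=ubm.gmm.covariances,
        cov_type=ubm.gmm.cov_type,
    )


def merge_score(
    ubm: UBM,
    data_a: np.ndarray,
    data_b: np.ndarray,
    relevance: float = DEFAULT_RELEVANCE,
) -> float:
    """Likelihood gain from modeling two cells jointly (symmetric in a, b)."""
    data_a = np.atleast_2d(np.asarray(data_a, dtype=np.float64))
    data_b = np.atleast_2d(np.asarray(data_b, dtype=np.float64))
    # canonical order makes the score exactly symmetric under argument swap
    if data_b.tobytes() < data_a.tobytes():
        data_a, data_b = data_b, data_a
    lam_a = map_adapt(ubm, data_a, relevance)
    lam_b = map_adapt(ubm, data_b, relevance)
    joint = np.concatenate([data_a, data_b], axis=0)
    lam = map_adapt(ubm, joint, relevance)
    return float(
        lam.log_density(joint).sum()
        - lam_a.log_density(data_a).sum()
        - lam_b.log_density(data_b).sum()
    )


# ---------------------------------------------------------------------------
# region growing


def region_grow(
    state: ClusterState,
    ubm: UBM,
    features: np.ndarray,
    schedule: tuple[float, float] = (0.8, 0.2),
    relevance: float = DEFAULT_RELEVANCE,
    pooled: bool = False,
) -> ClusterState:
    """Grow the seeded regions until every cell is labeled.

    Each iteration scores every (labeled cell, unlabeled 4-neighbor) pair
    and merges the top x% of pairs, x interpolating linearly from
    ``schedule[0]`` to ``schedule[1]`` as the labeled cell fraction goes
    from 0 to 1 (at least one merge per iteration guarantees termination).
    An unlabeled cell contested within an iteration joins the
    higher-scoring region (ties: lower area code, then lower cell id).
    ``features`` rows are indexed by flat raster pixel index. With
    ``pooled=True`` the labeled side of each pair is the entire region's
    data rather than the single frontier cell.
    """
    if not (state.labels > 0).any():
        raise ValidationError("state must be seeded before growing")
    labels = state.labels.copy()
    log_rows = list(state.merge_log)
    iteration = state.iteration
    n_cells = state.n_cells
    while (labels == 0).any():
        iteration += 1
        pairs = [
            (a, b)
            for a in np.flatnonzero(labels > 0)
            for b in state.adjacency[int(a)]
            if labels[b] == 0
        ]
        if not pairs:
            _assign_disconnected(state, labels)
            break
        def _labeled_data(a: int) -> np.ndarray:
            if not pooled:
                return features[state.cells[a]]
            region = np.flatnonzero(labels == labels[a])
            return features[np.concatenate([state.cells[i] for i in region])]

        scored = [
            (merge_score(ubm, _labeled_data(a), features[state.cells[b]], relevance), a, b)
            for a, b in pairs
        ]
        frac_labeled = float((labels > 0).sum()) / n_cells
        x = schedule[0] + (schedule[1] - schedule[0]) * frac_labeled
        n_merge = max(1, int(np.floor(x * len(scored))))
        scored.sort(key=lambda t: (-t[0], labels[t[1]], t[1], t[2]))
        merged = 0
        for score, a, b in scored:
            action = "not_reached"
            if merged < n_merge:
                if labels[b] == 0:
                    labels[b] = labels[a]
                    merged += 1
                    action = "merged"
                else:
                    action = "already_labeled"
            log_rows.append(
                {
                    "iteration": iteration,
                    "cell_a": int(a),
                    "cell_b": int(b),
                    "score": float(score),
                    "threshold_pct": 100.0 * x,
                    "action": action,
                }
            )
    return ClusterState(
        cells=state.cells,
        labels=labels,
        adjacency=state.adjacency,
        cell_raster=state.cell_raster,
        iteration=iteration,
        merge_log=log_rows,
    )


def _assign_disconnected(state: ClusterState, labels: np.ndarray) -> None:
    """Label cells unreachable from any seed by the nearest labeled cell."""
    rows, cols = state.cell_raster.shape
    centers = np.array(
        [np.mean(np.unravel_index(px, (rows, cols)), axis=1) for px in state.cells]
    )
    labeled = np.flatnonzero(labels > 0)
    for i in np.flatnonzero(labels == 0):
        d = np.linalg.norm(centers[labeled] - centers[i], axis=1)
        nearest = labeled[int(np.argmin(d))]
        labels[i] = labels[nearest]
        logger.warning(
            "cell %d unreachable from any seed; labeled %d via nearest labeled cell",
            i,
            int(labels[i]),
        )


def smooth_boundaries(
    state: ClusterState,
    features: np.ndarray,
    train_frac: float = 0.05,
    seed: int = 0,
    n_components: int = 4,
    min_per_label: int = 25,
) -> np.ndarray:
    """Pixel-level boundary smoothing via a supervised mixture classifier.

    Samples ``train_frac`` of pixels per grown cluster label, fits the
    per-area GMM classifier on them, and reclassifies every in-map pixel.
    Returns the final parcellation raster (0 = background).
    """
    if (state.labels == 0).any():
        raise ValidationError("all cells must be labeled before smoothing")
    rng = np.random.default_rng(seed)
    cell_labels = state.pixel_labels()
    flat = cell_labels.ravel()
    in_map_px = np.flatnonzero(state.cell_raster.ravel() >= 0)
    train_px, train_y = [], []
    for code in np.unique(state.labels):
        px = np.flatnonzero(flat == code)
        n = int(np.clip(round(train_frac * px.size), min(min_per_label, px.size), px.size))
        chosen = rng.choice(px, size=n, replace=False)
        train_px.append(chosen)
        train_y.append(np.full(n, code))
    train_px = np.concatenate(train_px)
    train_y = np.concatenate(train_y)
    counts = [int((train_y == c).sum()) for c in np.unique(train_y)]
    m = max(1, min(n_components, min(counts)))
    clf = fit_gmm(features[train_px], train_y, n_components=m, seed=seed)
    pred = clf.predict(features[in_map_px])
    out = np.zeros(state.cell_raster.shape, dtype=np.int16)
    out.ravel()[in_map_px] = pred
    return out


# ---------------------------------------------------------------------------
# orchestration


@dataclass
class ParcellationResult:
    """Final per-pixel parcellation plus intermediate state and diagnostics."""

    pixel_labels: np.ndarray
    cell_state: ClusterState
    merge_log: pd.DataFrame
    accuracy: float
    cell_accuracy: float
    ubm: UBM


def run_semisupervised(
    rec: Recording,
    area_map: AreaMap,
    stimuli=None,
    resting: tuple[float, float, float | None] | None = None,
    n_components_ubm: int = DEFAULT_M_UBM,
    relevance: float = DEFAULT_RELEVANCE,
    cell_px: int = DEFAULT_CELL_PX,
    schedule: tuple[float, float] = (0.8, 0.2),
    seed: int = 0,
    n_pcs: int | float = 0.95,
    max_pcs: int = 50,
    smooth_train_frac: float = 0.05,
) -> ParcellationResult:
    """End-to-end semi-supervised parcellation of a wide-field recording.

    Features are per-unit z-score + PCA only (no labels enter the front
    end); the only supervision is the seeded center cell of each area.
    Accuracy compares the final raster with the ground-truth map over
    in-map pixels; ``cell_accuracy`` does the same for the raw (unsmoothed)
    cell labels.
    """
    if rec.mode != "widefield":
        raise ValidationError("semi-supervised parcellation requires a wide-field recording")
    if rec.n_units != area_map.labels.size:
        raise ValidationError(
            "recording units must cover every raster pixel in row-major order"
        )
    from .features import take_resting

    if resting is not None:
        X = take_resting(rec, *resting)
    else:
        X = trial_average(rec, stimuli)
    in_map_units = np.flatnonzero(rec.unit_labels > 0)
    Z = zscore_rows(X)
    pca = fit_pca(Z[in_map_units], n_kept=n_pcs, max_components=max_pcs)
    feats = project_pca(pca, Z)  # rows align with flat raster order

    ubm = train_ubm(feats[in_map_units], n_components=n_components_ubm, seed=seed)
    state = partition_grid(area_map, cell_px=cell_px)
    state = seed_centers(state, area_map)
    state = region_grow(state, ubm, feats, schedule=schedule, relevance=relevance)
    final = smooth_boundaries(state, feats, train_frac=smooth_train_frac, seed=seed)

    truth = area_map.labels
    in_map = area_map.in_map
    acc = 100.0 * float(np.mean(final[in_map] == truth[in_map]))
    cell_acc = 100.0 * float(np.mean(state.pixel_labels()[in_map] == truth[in_map]))
    return ParcellationResult(
        pixel_labels=final,
        cell_state=state,
        merge_log=pd.DataFrame(state.merge_log),
        accuracy=acc,
        cell_accuracy=cell_acc,
        ubm=ubm,
    )
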