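"""Unsupervised structure detection with PCA and emergent self-organizing maps.

The four z-standardized DAS28-CRP components are projected with classical
PCA (correlation-matrix eigendecomposition) and, independently, the
[0,100]-scaled components are projected onto a large toroidal self-organizing
map (an *emergent* SOM: far more neurons than expected clusters).  Three
per-neuron structure matrices are derived from the trained map:

* **U-matrix** — the mean high-dimensional distance of each prototype to its
  immediately neighboring prototypes; valleys indicate clusters, ridges
  indicate boundaries.
* **P-matrix** — the number of data points within a hypersphere of radius
  *r* around each prototype, a density estimate whose bandwidth defaults to
  the 20th percentile of the nonzero pairwise data distances (Pareto radius).
* **U\\*-matrix** — the U-matrix rescaled by local density, suppressing
  spurious boundaries inside dense regions and amplifying sparse ones.

Clusters and outliers are read off the U*-matrix by thresholding its heights
and flood-filling connected low-height basins on the torus; patients inherit
the basin of their best-matching unit (BMU).  Small basins (fewer members
than ``min_cluster_size``) are reported as outlier groups.  The published
toolchains delineate these basins visually on a topographic rendering; the
percentile threshold and flood fill used here are an automated, configurable
surrogate for that step.
"""

from __future__ import annotations

import warnings
from collections import deque
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist, pdist
from scipy.stats import chi2_contingency

__all__ = [
    "ClusterAssignment",
    "ESOMConfig",
    "ESOMModel",
    "PCAResult",
    "StructureMatrices",
    "assign_bmu",
    "assign_bmus",
    "cluster_stage_association",
    "extract_clusters",
    "p_matrix",
    "pareto_radius",
    "pca_project",
    "scale_0_100",
    "train_esom",
    "u_matrix",
    "u_star_matrix",
    "unscale_0_100",
]


class DegenerateInputError(ValueError):
    """The input admits no meaningful decomposition (e.g. a constant column)."""


# ---------------------------------------------------------------------------
# PCA


@dataclass(frozen=True)
class PCAResult:
    """Correlation-matrix PCA: eigenvalues, scores and variable contributions."""

    eigenvalues: np.ndarray  # (d,), nonincreasing
    loadings: np.ndarray  # (d, d), columns are unit eigenvectors
    scores: np.ndarray  # (n, d)
    contributions: np.ndarray  # (d, d) percent; column k sums to 100

    @property
    def explained_variance_ratio(self) -> np.ndarray:
        return self.eigenvalues / self.eigenvalues.sum()


def pca_project(matrix: np.ndarray) -> PCAResult:
    """PCA of the z-standardized columns of ``matrix`` (n x d).

    Eigendecomposition of the correlation matrix; the contribution of
    variable j to component k is ``100 * loading[j,k]**2`` (unit
    eigenvectors, so each component's contributions sum to 100).
    """
    X = np.asarray(matrix, dtype=float)
    if X.ndim != 2 or X.shape[0] < 2:
        raise DegenerateInputError("pca_project needs an n x d matrix with n >= 2")
    sd = X.std(axis=0, ddof=1)
    if np.any(sd == 0):
        bad = np.flatnonzero(sd == 0).tolist()
        raise DegenerateInputError(f"constant column(s) {bad} cannot be z-standardized")
    Z = (X - X.mean(axis=0)) / sd
    corr = (Z.T @ Z) / (X.shape[0] - 1)
    eigval, eigvec = np.linalg.eigh(corr)
    order = np.argsort(eigval)[::-1]
    eigval, eigvec = eigval[order], eigvec[:, order]
    return PCAResult(
        eigenvalues=eigval,
        loadings=eigvec,
        scores=Z @ eigvec,
        contributions=100.0 * eigvec**2,
    )


# ---------------------------------------------------------------------------
# scaling


def scale_0_100(matrix: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Rescale each column linearly to [0, 100]; constant columns map to 0.

    Returns the scaled matrix and the per-variable ``(min, max)`` pairs
    (shape ``(d, 2)``) needed to invert the map.
    """
    X = np.asarray(matrix, dtype=float)
    if X.ndim != 2 or X.shape[0] < 1:
        raise DegenerateInputError("scale_0_100 needs an n x d matrix with n >= 1")
    lo, hi = X.min(axis=0), X.max(axis=0)
    span = hi - lo
    scaled = np.zeros_like(X)
    nonconst = span > 0
    scaled[:, nonconst] = 100.0 * (X[:, nonconst] - lo[nonconst]) / span[nonconst]
    return scaled, np.column_stack([lo, hi])


def unscale_0_100(scaled: np.ndarray, min_max: np.ndarray) -> np.ndarray:
    """Invert :func:`scale_0_100` with the stored per-variable ranges."""
    lo, hi = min_max[:, 0], min_max[:, 1]
    return lo + np.asarray(scaled, dtype=float) / 100.0 * (hi - lo)


# ---------------------------------------------------------------------------
# ESOM


@dataclass(frozen=True)
class ESOMConfig:
    """Training configuration of the emergent SOM.

    Defaults: 50 x 80 toroidal grid (4,000 neurons), 20 epochs of online
    updates with the learning rate decaying linearly from 0.3 to 0.05 and a
    Gaussian neighborhood whose radius shrinks linearly from
    ``max(rows, cols) / 2`` to 1.
    """

    rows: int = 50
    cols: int = 80
    toroidal: bool = True
    epochs: int = 20
    lr_start: float = 0.3
    lr_end: float = 0.05
    radius_start: float | None = None  # None -> max(rows, cols) / 2
    radius_end: float = 1.0
    seed: int = 0

    def validate(self) -> None:
        if self.rows < 1 or self.cols < 1:
            raise DegenerateInputError("grid must have rows >= 1 and cols >= 1")
        if not 0 < self.lr_end <= self.lr_start:
            raise DegenerateInputError("need 0 < lr_end <= lr_start")
        if self.epochs < 1:
            raise DegenerateInputError("epochs must be >= 1")

    @property
    def n_neurons(self) -> int:
        return self.rows * self.cols


@dataclass
class ESOMModel:
    """A trained map: per-neuron prototype vectors plus the training config.

    ``weights`` has shape ``(rows * cols, d)``; the grid is indexed row-major
    and 0-based, so neuron ``(r, c)`` is row ``r * cols + c``.
    ``input_scaling`` records the per-variable (min, max) of the [0,100]
    rescaling applied to the training data.
    """

    weights: np.ndarray
    config: ESOMConfig
    input_scaling: np.ndarray | None = None

    @property
    def d(self) -> int:
        return self.weights.shape[1]

    def grid_positions(self) -> np.ndarray:
        """(n_neurons, 2) array of (row, col) per neuron, row-major order."""
        rr, cc = np.divmod(np.arange(self.config.n_neurons), self.config.cols)
        return np.column_stack([rr, cc])


def _grid_distance2(config: ESOMConfig, positions: np.ndarray, pos: np.ndarray) -> np.ndarray:
    """Squared grid distance from every neuron to ``pos`` (toroidal if set)."""
    delta = np.abs(positions - pos)
    if config.toroidal:
        delta[:, 0] = np.minimum(delta[:, 0], config.rows - delta[:, 0])
        delta[:, 1] = np.minimum(delta[:, 1], config.cols - delta[:, 1])
    return (delta**2).sum(axis=1).astype(float)


def train_esom(
    data: np.ndarray,
    config: ESOMConfig | None = None,
    init_weights: np.ndarray | None = None,
    epoch_callback=None,
) -> ESOMModel:
    """Train an emergent SOM with online (per-sample) updates.

    Learning rate and Gaussian neighborhood radius interpolate linearly from
    their start to end values over the full training run; sample order is
    reshuffled every epoch.  Deterministic given ``config.seed``.

    Prototypes initialize uniformly over the per-variable data range unless
    ``init_weights`` (n_neurons x d) is given.  ``epoch_callback(epoch,
    weights)``, if set, is invoked after every epoch (monitoring hook).
    """
    config = config or ESOMConfig()
    config.validate()
    X = np.atleast_2d(np.asarray(data, dtype=float))
    if X.shape[0] < 1 or X.shape[1] < 1:
        raise DegenerateInputError("train_esom needs nonempty n x d data")
    n, d = X.shape
    rng = np.random.default_rng(config.seed)
    if init_weights is not None:
        weights = np.array(init_weights, dtype=float)
        if weights.shape != (config.n_neurons, d):
            raise DegenerateInputError(
                f"init_weights must have shape {(config.n_neurons, d)}"
            )
    else:
        lo, hi = X.min(axis=0), X.max(axis=0)
        weights = rng.uniform(lo, hi, size=(config.n_neurons, d))
    positions = np.column_stack(np.divmod(np.arange(config.n_neurons), config.cols)).astype(int)
    r0 = config.radius_start if config.radius_start is not None else max(config.rows, config.cols) / 2.0
    total_steps = config.epochs * n
    step = 0
    for epoch in range(config.epochs):
        for i in rng.permutation(n):
            frac = step / max(total_steps - 1, 1)
            lr = config.lr_start + frac * (config.lr_end - config.lr_start)
            radius = r0 + frac * (config.radius_end - r0)
            x = X[i]
            bmu = int(np.argmin(((weights - x) ** 2).sum(axis=1)))
            g2 = _grid_distance2(config, positions, positions[bmu])
            h = np.exp(-g2 / (2.0 * radius * radius))
            weights += (lr * h)[:, None] * (x - weights)
            step += 1
        if epoch_callback is not None:
            epoch_callback(epoch, weights)
    return ESOMModel(weights=weights, config=config)


def assign_bmu(model: ESOMModel, x: np.ndarray) -> tuple[int, int]:
    """Best-matching unit of ``x``: the neuron with the closest prototype.

    Ties break toward the lowest row-major index.
    """
    x = np.asarray(x, dtype=float)
    if x.shape != (model.d,):
        raise DegenerateInputError(f"input has shape {x.shape}, expected ({model.d},)")
    idx = int(np.argmin(((model.weights - x) ** 2).sum(axis=1)))
    return divmod(idx, model.config.cols)


def assign_bmus(model: ESOMModel, data: np.ndarray) -> np.ndarray:
    """Row-major BMU index for every row of ``data`` (shape (n,))."""
    X = np.atleast_2d(np.asarray(data, dtype=float))
    if X.shape[1] != model.d:
        raise DegenerateInputError(f"data has dimension {X.shape[1]}, expected {model.d}")
    return cdist(X, model.weights, "sqeuclidean").argmin(axis=1)


# ---------------------------------------------------------------------------
# structure matrices


@dataclass(frozen=True)
class StructureMatrices:
    """U-, P- and U*-matrix heights per neuron plus the density radius used."""

    u: np.ndarray  # (rows, cols) nonnegative heights
    p: np.ndarray  # (rows, cols) nonnegative integer counts
    u_star: np.ndarray  # (rows, cols) nonnegative heights
    radius_r: float


def _moore_neighbors(config: ESOMConfig, r: int, c: int) -> list[tuple[int, int]]:
    """Deduplicated toroidal Moore (8-)neighborhood of a grid cell, self excluded."""
    out: set[tuple[int, int]] = set()
    for dr in (-1, 0, 1):
        for dc in (-1, 0, 1):
            if dr == 0 and dc == 0:
                continue
            if config.toroidal:
                out.add(((r + dr) % config.rows, (c + dc) % config.cols))
            else:
                rr, cc = r + dr, c + dc
                if 0 <= rr < config.rows and 0 <= cc < config.cols:
                    out.add((rr, cc))
    out.discard((r, c))
    return sorted(out)


def u_matrix(model: ESOMModel) -> np.ndarray:
    """Per-neuron mean Euclidean distance to the neighboring prototypes.

    Neighbors are the Moore 8-neighborhood with toroidal wrap; on degenerate
    grids (fewer than 3 rows or columns) wrap-duplicated neighbors are
    counted once.
    """
    cfg = model.config
    W = model.weights.reshape(cfg.rows, cfg.cols, model.d)
    if cfg.toroidal and cfg.rows >= 3 and cfg.cols >= 3:
        # no wrap-induced duplicates: vectorize over the 8 shifts
        acc = np.zeros((cfg.rows, cfg.cols))
        for dr in (-1, 0, 1):
            for dc in (-1, 0, 1):
                if dr == 0 and dc == 0:
                    continue
                shifted = np.roll(np.roll(W, dr, axis=0), dc, axis=1)
                acc += np.sqrt(((W - shifted) ** 2).sum(axis=2))
        return acc / 8.0
    heights = np.zeros((cfg.rows, cfg.cols))
    for r in range(cfg.rows):
        for c in range(cfg.cols):
            nbrs = _moore_neighbors(cfg, r, c)
            if nbrs:
                heights[r, c] = float(
                    np.mean([np.linalg.norm(W[r, c] - W[rr, cc]) for rr, cc in nbrs])
                )
    return heights


def pareto_radius(data: np.ndarray, percentile: float = 20.0) -> float:
    """Density-estimation bandwidth: a percentile of the nonzero pairwise distances."""
    X = np.atleast_2d(np.asarray(data, dtype=float))
    if X.shape[0] < 2:
        raise DegenerateInputError("pareto_radius needs at least two points")
    dists = pdist(X)
    nz = dists[dists > 0]
    if nz.size == 0:
        raise DegenerateInputError("all points identical: no nonzero pairwise distance")
    return float(np.percentile(nz, percentile))


def p_matrix(model: ESOMModel, data: np.ndarray, r: float) -> np.ndarray:
    """Per-neuron count of data points within distance ``r`` of the prototype.

    The boundary is inclusive: a point exactly at distance ``r`` counts.
    """
    if not r > 0:
        raise DegenerateInputError(f"radius r must be > 0, got {r}")
    cfg = model.config
    X = np.asarray(data, dtype=float)
    if X.size == 0:
        return np.zeros((cfg.rows, cfg.cols), dtype=int)
    X = np.atleast_2d(X)
    d = cdist(model.weights, X)
    return (d <= r).sum(axis=1).reshape(cfg.rows, cfg.cols)


def u_star_matrix(u: np.ndarray, p: np.ndarray) -> np.ndarray:
    """Combine distance (U) and density (P) structure into the U*-matrix.

    ``u*(i) = u(i) * f(i)`` with ``f(i) = (p(i) - max(P)) / (mean(P) - max(P))``,
    clipped below at 0: f is 1 at mean density, 0 at maximum density and > 1
    in sparse regions.  Uniform density degenerates to ``u* = u`` (warned).
    """
    u = np.asarray(u, dtype=float)
    p = np.asarray(p, dtype=float)
    if u.shape != p.shape:
        raise DegenerateInputError("u and p must be congruent arrays")
    p_max, p_mean = p.max(), p.mean()
    if p_mean == p_max:
        warnings.warn("uniform P-matrix density: U* falls back to U", stacklevel=2)
        return u.copy()
    f = np.clip((p - p_max) / (p_mean - p_max), 0.0, None)
    return u * f


def structure_matrices(
    model: ESOMModel, data: np.ndarray, radius: float | None = None
) -> StructureMatrices:
    """Convenience: compute U, P (at the Pareto radius by default) and U*."""
    u = u_matrix(model)
    r = pareto_radius(data) if radius is None else radius
    p = p_matrix(model, data, r)
    return StructureMatrices(u=u, p=p, u_star=u_star_matrix(u, p), radius_r=r)


# ---------------------------------------------------------------------------
# clusters and outliers


@dataclass
class ClusterAssignment:
    """Patient-level cluster/outlier labels read off the U*-matrix basins.

    ``labels`` holds a 1-based group id per patient; groups with at least
    ``min_cluster_size`` patients are clusters (ids 1..k in decreasing size
    order), smaller ones are outlier groups (ids k+1..) with ``is_outlier``
    set.  ``basin_grid`` maps every neuron to a group id (above-threshold
    neurons were attached to the nearest basin; 0 marks basins holding no
    patients).
    """

    labels: np.ndarray  # (n,) int, 1-based
    is_outlier: np.ndarray  # (n,) bool
    cluster_sizes: dict[int, int]  # group id -> patient count (incl. outlier groups)
    basin_grid: np.ndarray  # (rows, cols) int group ids
    min_cluster_size: int
    threshold: float

    def cluster_ids(self) -> list[int]:
        """Ids of proper clusters (size >= min_cluster_size)."""
        return sorted(
            g for g, s in self.cluster_sizes.items() if s >= self.min_cluster_size
        )

    def outlier_group_ids(self) -> list[int]:
        return sorted(set(self.labels[self.is_outlier].tolist()))

    def to_frame(self, patient_ids) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "patient_id": list(patient_ids),
                "cluster": self.labels,
                "is_outlier": self.is_outlier,
            }
        )


def _connected_components(adjacency: np.ndarray) -> tuple[int, np.ndarray]:
    """Connected components of a boolean adjacency matrix (single linkage)."""
    n = adjacency.shape[0]
    comp = np.full(n, -1, dtype=int)
    current = 0
    for start in range(n):
        if comp[start] != -1:
            continue
        queue = deque([start])
        comp[start] = current
        while queue:
            i = queue.popleft()
            for j in np.flatnonzero(adjacency[i]):
                if comp[j] == -1:
                    comp[j] = current
                    queue.append(j)
        current += 1
    return current, comp


def _flood_fill_basins(mask: np.ndarray, toroidal: bool) -> np.ndarray:
    """Label 8-connected components of ``mask`` (True cells); -1 elsewhere."""
    rows, cols = mask.shape
    labels = np.full((rows, cols), -1, dtype=int)
    current = 0
    for r0 in range(rows):
        for c0 in range(cols):
            if not mask[r0, c0] or labels[r0, c0] != -1:
                continue
            queue = deque([(r0, c0)])
            labels[r0, c0] = current
            while queue:
                r, c = queue.popleft()
                for dr in (-1, 0, 1):
                    for dc in (-1, 0, 1):
                        if dr == 0 and dc == 0:
                            continue
                        rr, cc = r + dr, c + dc
                        if toroidal:
                            rr, cc = rr % rows, cc % cols
                        elif not (0 <= rr < rows and 0 <= cc < cols):
                            continue
                        if mask[rr, cc] and labels[rr, cc] == -1:
                            labels[rr, cc] = current
                            queue.append((rr, cc))
            current += 1
    return labels


def extract_clusters(
    u_star: np.ndarray,
    bmus: np.ndarray,
    config: ESOMConfig,
    min_cluster_size: int = 3,
    threshold_percentile: float = 50.0,
    isolation_radius: float | None = None,
) -> ClusterAssignment:
    """Cut the U*-matrix into basins and assign patients to clusters/outliers.

    The height threshold is the ``threshold_percentile`` of the U* heights at
    occupied neurons (default: their median).  Below-threshold neurons form
    8-connected toroidal basins; each patient inherits the basin of its BMU,
    with above-threshold BMUs attached to the nearest below-threshold neuron
    by toroidal grid distance (ties toward the lowest row-major index).

    Occupied neurons farther than ``isolation_radius`` (grid distance;
    default ``max(rows, cols) / 6``) from every below-threshold neuron are
    *not* attached: they sit on isolated high ground — the "volcanic
    craters" in the topographic reading of the map — and form their own
    basins (single-linkage over the same radius).  Basins holding fewer
    than ``min_cluster_size`` patients become outlier groups.
    """
    if isolation_radius is None:
        isolation_radius = max(config.rows, config.cols) / 6.0
    u_star = np.asarray(u_star, dtype=float)
    bmus = np.asarray(bmus, dtype=int)
    rows, cols = u_star.shape
    if bmus.size == 0:
        raise DegenerateInputError("no occupied neurons: empty BMU list")
    occupied = np.unique(bmus)
    threshold = float(np.percentile(u_star.reshape(-1)[occupied], threshold_percentile))
    mask = u_star <= threshold
    basin = _flood_fill_basins(mask, config.toroidal)

    def grid_dist2(a: np.ndarray, b: np.ndarray) -> np.ndarray:
        """Pairwise squared toroidal grid distances between coordinate lists."""
        dr = np.abs(a[:, 0:1] - b[None, :, 0])
        dc = np.abs(a[:, 1:2] - b[None, :, 1])
        if config.toroidal:
            dr = np.minimum(dr, rows - dr)
            dc = np.minimum(dc, cols - dc)
        return dr**2 + dc**2

    # attach above-threshold cells to the nearest below-threshold basin
    basin_full = basin.copy()
    below = np.argwhere(mask)
    above = np.argwhere(~mask)
    if above.size:
        d2 = grid_dist2(above, below)
        nearest = d2.argmin(axis=1)
        basin_full[above[:, 0], above[:, 1]] = basin[below[nearest, 0], below[nearest, 1]]

    # isolated occupied high ground forms its own crater basins
    occ_pos = np.column_stack(divmod(occupied, cols))
    iso = np.sqrt(grid_dist2(occ_pos, below).min(axis=1)) > isolation_radius
    iso_idx = occupied[iso]
    if iso_idx.size:
        next_basin = basin.max() + 1
        iso_pos = occ_pos[iso]
        link = grid_dist2(iso_pos, iso_pos) <= isolation_radius**2
        n_comp, comp = _connected_components(link)
        for k, neuron in enumerate(iso_idx):
            basin_full[iso_pos[k, 0], iso_pos[k, 1]] = next_basin + comp[k]

    patient_basin = basin_full.reshape(-1)[bmus]
    sizes = pd.Series(patient_basin).value_counts()
    clusters = [int(b) for b, s in sizes.items() if s >= min_cluster_size]
    outlier_groups = [int(b) for b, s in sizes.items() if s < min_cluster_size]
    id_of = {b: i + 1 for i, b in enumerate(clusters + outlier_groups)}
    labels = np.array([id_of[int(b)] for b in patient_basin], dtype=int)
    is_outlier = np.isin(patient_basin, outlier_groups)
    basin_ids = np.array(
        [[id_of.get(int(b), 0) for b in row] for row in basin_full], dtype=int
    )
    return ClusterAssignment(
        labels=labels,
        is_outlier=is_outlier,
        cluster_sizes={id_of[int(b)]: int(s) for b, s in sizes.items()},
        basin_grid=basin_ids,
        min_cluster_size=min_cluster_size,
        threshold=threshold,
    )


def cluster_stage_association(
    assignment: ClusterAssignment,
    stages: np.ndarray,
    min_members: int = 5,
) -> dict:
    """Pearson chi-square of the cluster x stage table, small clusters excluded.

    Clusters with fewer than ``min_members`` patients are dropped before
    testing.  Returns the statistic, degrees of freedom, p-value and the
    Pearson residuals ``(obs - exp) / sqrt(exp)``.
    """
    stages = np.asarray(stages)
    keep_groups = [g for g, s in assignment.cluster_sizes.items() if s >= min_members]
    if len(keep_groups) < 2:
        raise DegenerateInputError(
            f"need >= 2 clusters with >= {min_members} members, got {len(keep_groups)}"
        )
    keep = np.isin(assignment.labels, keep_groups)
    table = pd.crosstab(assignment.labels[keep], stages[keep])
    table = table.loc[:, table.sum(axis=0) > 0]
    if table.shape[0] < 2 or table.shape[1] < 2:
        raise DegenerateInputError("degenerate contingency table after exclusion")
    chi2, p, dof, expected = chi2_contingency(table.to_numpy(), correction=False)
    residuals = (table.to_numpy() - expected) / np.sqrt(expected)
    return {
        "chi2": float(chi2),
        "df": int(dof),
        "p": float(p),
        "residuals": pd.DataFrame(residuals, index=table.index, columns=table.columns),
        "table": table,
    }
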