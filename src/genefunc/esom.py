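"""Emergent self-organizing map (ESOM) on a toroid grid.

A Kohonen SOM large enough that single neurons do not represent whole
clusters is trained on the binary gene x process matrix.  The grid is a
torus (opposite edges connected) so the map has no boundary artefacts.
Cluster structure is read from the neuron landscape:

* **U-matrix** — per-neuron mean weight distance to its 8 grid
  neighbours; ridges mark large distances in feature space.
* **P-matrix** — per-neuron count of data points within radius ``r`` of
  the neuron's weight vector (a density estimate).
* **U\\*-matrix** — the U-matrix attenuated where density is high, so
  ridges inside dense regions vanish and true inter-cluster ridges stand
  out.

Genes are placed at their best-matching units (BMUs) and clusters are
extracted by a watershed flood-fill of the U* landscape from its local
minima, merging basins whose separating ridge is low.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import cdist, pdist

from .feature_matrix import GeneProcessMatrix

logger = logging.getLogger(__name__)

_NEIGHBOR_SHIFTS = [(-1, -1), (-1, 0), (-1, 1), (0, -1), (0, 1), (1, -1), (1, 0), (1, 1)]


@dataclass
class SomConfig:
    """Training schedule for the toroid SOM.

    The 25 x 35 grid and 25 training epochs are the package defaults for
    gene-function matrices of around a hundred rows; learning rate and
    neighbourhood radius decay linearly per epoch.
    """

    rows: int = 25
    cols: int = 35
    epochs: int = 25
    radius_start: float | None = None  # defaults to max(rows, cols) / 2
    radius_end: float = 1.0
    rate_start: float = 0.5
    rate_end: float = 0.05
    seed: int = 0

    def __post_init__(self):
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")
        if self.rows < 2 or self.cols < 2:
            raise ValueError("grid must be at least 2 x 2")
        if self.radius_start is None:
            self.radius_start = max(self.rows, self.cols) / 2.0


def toroid_distance(p1, p2, shape: tuple[int, int]) -> float:
    """Euclidean distance between grid positions with wrap-around."""
    rows, cols = shape
    dr = abs(p1[0] - p2[0])
    dc = abs(p1[1] - p2[1])
    dr = min(dr, rows - dr)
    dc = min(dc, cols - dc)
    return float(np.hypot(dr, dc))


def _grid_sq_dist_template(rows: int, cols: int) -> np.ndarray:
    """Squared toroid grid distance from (0, 0) to every cell."""
    dr = np.minimum(np.arange(rows), rows - np.arange(rows))
    dc = np.minimum(np.arange(cols), cols - np.arange(cols))
    return dr[:, None] ** 2 + dc[None, :] ** 2


@dataclass
class TrainedSom:
    weights: np.ndarray  # (rows, cols, d)
    bmu_map: dict[str, tuple[int, int]]
    config: SomConfig

    @property
    def shape(self) -> tuple[int, int]:
        return self.weights.shape[:2]

    def bmu(self, x: np.ndarray) -> tuple[int, int]:
        """Best-matching unit: nearest weight, ties to lowest (row, col)."""
        flat = self.weights.reshape(-1, self.weights.shape[-1])
        d2 = ((flat - x[None, :]) ** 2).sum(axis=1)
        idx = int(np.argmin(d2))  # row-major argmin = lowest (row, col) tie-break
        return divmod(idx, self.weights.shape[1])


@dataclass
class HeightGrid:
    values: np.ndarray
    kind: str  # "U", "P" or "Ustar"
    radius: float | None = None  # P-matrix sphere radius
    meta: dict = field(default_factory=dict)

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def to_csv(self, path) -> None:
        np.savetxt(path, self.values, delimiter=",")

    def write_sidecar(self, path) -> None:
        with open(path, "w") as fh:
            json.dump({"kind": self.kind, "radius": self.radius, **self.meta}, fh, indent=2)


@dataclass
class ClusterAssignment:
    labels: dict[str, int]  # gene -> cluster id >= 1 (0 = unassigned)
    n_clusters: int

    def to_tsv(self, path, som: TrainedSom | None = None) -> None:
        with open(path, "w") as fh:
            fh.write("gene\trow\tcol\tcluster\n")
            for gene in sorted(self.labels):
                r, c = som.bmu_map[gene] if som else (-1, -1)
                fh.write(f"{gene}\t{r}\t{c}\t{self.labels[gene]}\n")


def train(matrix: GeneProcessMatrix, config: SomConfig | None = None) -> TrainedSom:
    """Train the SOM online: shuffled rows, Gaussian neighbourhood update.

    Weights initialize uniformly within each column's data range from the
    seeded generator; the same matrix and seed always give bit-identical
    weights.
    """
    config = config or SomConfig()
    data = matrix.values
    n, d = data.shape
    if d == 0:
        raise ValueError("feature matrix has zero columns")
    if config.rows * config.cols <= n:
        warnings.warn(
            f"grid of {config.rows * config.cols} neurons is not larger than "
            f"the {n} data points; the map may not be emergent",
            stacklevel=2,
        )
    rng = np.random.default_rng(config.seed)
    lo, hi = data.min(axis=0), data.max(axis=0)
    weights = rng.uniform(lo, hi, size=(config.rows, config.cols, d))

    d2_template = _grid_sq_dist_template(config.rows, config.cols)
    denom = max(config.epochs - 1, 1)
    for epoch in range(config.epochs):
        frac = epoch / denom
        rate = config.rate_start + (config.rate_end - config.rate_start) * frac
        radius = config.radius_start + (config.radius_end - config.radius_start) * frac
        order = rng.permutation(n)
        flat = weights.reshape(-1, d)
        for i in order:
            x = data[i]
            idx = int(np.argmin(((flat - x[None, :]) ** 2).sum(axis=1)))
            r, c = divmod(idx, config.cols)
            g2 = np.roll(d2_template, (r, c), axis=(0, 1))
            h = np.exp(-g2 / (2.0 * radius * radius))
            weights += (rate * h)[:, :, None] * (x[None, None, :] - weights)
            flat = weights.reshape(-1, d)

    som = TrainedSom(weights=weights, bmu_map={}, config=config)
    som.bmu_map = {g: som.bmu(data[i]) for i, g in enumerate(matrix.genes)}
    return som


def umatrix(som: TrainedSom) -> HeightGrid:
    """U-height per neuron: mean weight distance to its 8 toroid neighbours.

    On grids smaller than 3 x 3 the wrapped 8-neighbourhood collapses onto
    fewer distinct cells; the mean is taken over the distinct neighbours.
    """
    w = som.weights
    rows, cols = w.shape[:2]
    if rows >= 3 and cols >= 3:  # no wrap collisions: vectorized rolls
        acc = np.zeros((rows, cols))
        for dr, dc in _NEIGHBOR_SHIFTS:
            shifted = np.roll(w, (dr, dc), axis=(0, 1))
            acc += np.sqrt(((w - shifted) ** 2).sum(axis=2))
        return HeightGrid(values=acc / len(_NEIGHBOR_SHIFTS), kind="U")
    values = np.zeros((rows, cols))
    for r in range(rows):
        for c in range(cols):
            cells = {((r + dr) % rows, (c + dc) % cols) for dr, dc in _NEIGHBOR_SHIFTS}
            cells.discard((r, c))
            dists = [np.linalg.norm(w[r, c] - w[nr, nc]) for nr, nc in cells]
            values[r, c] = float(np.mean(dists)) if dists else 0.0
    return HeightGrid(values=values, kind="U")


def pmatrix(
    som: TrainedSom, matrix: GeneProcessMatrix, r: float | str = "auto"
) -> HeightGrid:
    """Data density per neuron: points within Euclidean radius ``r``.

    ``r="auto"`` uses the 20th percentile of all pairwise data distances
    (a Pareto-radius heuristic).
    """
    data = matrix.values
    if isinstance(r, str):
        if r != "auto":
            raise ValueError(f"radius must be a number or 'auto', got {r!r}")
        pair = pdist(data)
        r = float(np.percentile(pair, 20)) if pair.size else 0.0
    flat = som.weights.reshape(-1, som.weights.shape[-1])
    dist = cdist(flat, data)
    counts = (dist <= r).sum(axis=1).reshape(som.shape)
    return HeightGrid(values=counts.astype(float), kind="P", radius=float(r))


def ustar(u: HeightGrid, p: HeightGrid) -> HeightGrid:
    """Attenuate U-heights by density: U* = U * scale(P).

    ``scale`` falls linearly from 1 at the median density to 0 at the
    maximum, clamped to [0, 1]; if the density grid is flat the scale is
    0 everywhere (a flat density cannot separate ridge from valley).
    """
    if u.shape != p.shape:
        raise ValueError(f"shape mismatch: U {u.shape} vs P {p.shape}")
    pv = p.values
    pmed, pmax = float(np.median(pv)), float(pv.max())
    if pmax <= pmed:
        scale = np.zeros_like(pv)
    else:
        scale = np.clip((pmax - pv) / (pmax - pmed), 0.0, 1.0)
    meta = {"rule": "U * clip((Pmax - P) / (Pmax - Pmedian), 0, 1)",
            "p_median": pmed, "p_max": pmax}
    return HeightGrid(values=u.values * scale, kind="Ustar", meta=meta)


class _UnionFind:
    def __init__(self, n: int):
        self.parent = list(range(n))

    def find(self, a: int) -> int:
        while self.parent[a] != a:
            self.parent[a] = self.parent[self.parent[a]]
            a = self.parent[a]
        return a

    def union(self, a: int, b: int) -> int:
        ra, rb = self.find(a), self.find(b)
        if ra == rb:
            return ra
        keep, drop = min(ra, rb), max(ra, rb)
        self.parent[drop] = keep
        return keep


def extract_clusters(
    som: TrainedSom,
    heights: HeightGrid,
    matrix: GeneProcessMatrix,
    ridge_threshold: float = 0.5,
) -> ClusterAssignment:
    """Watershed flood-fill of the toroid height landscape.

    Cells are processed in ascending height; each local minimum seeds a
    basin and cells join the basin of their lowest-minimum processed
    neighbour.  When two basins meet, they merge if the separating ridge
    is lower than ``ridge_threshold`` times the landscape maximum.  Genes
    inherit the basin label of their BMU.
    """
    hv = heights.values
    rows, cols = hv.shape
    if np.allclose(hv.max(), hv.min()):
        warnings.warn("flat height landscape: returning a single cluster", stacklevel=2)
        return ClusterAssignment(labels={g: 1 for g in matrix.genes}, n_clusters=1)

    merge_limit = ridge_threshold * float(hv.max())
    order = sorted(
        ((hv[r, c], r, c) for r in range(rows) for c in range(cols)),
        key=lambda t: (t[0], t[1], t[2]),
    )
    cell_basin = -np.ones((rows, cols), dtype=int)
    uf = _UnionFind(rows * cols)
    basin_min: dict[int, float] = {}

    for h, r, c in order:
        neighbor_roots: list[int] = []
        for dr, dc in _NEIGHBOR_SHIFTS:
            nr, nc = (r + dr) % rows, (c + dc) % cols
            b = cell_basin[nr, nc]
            if b >= 0:
                root = uf.find(b)
                if root not in neighbor_roots:
                    neighbor_roots.append(root)
        if not neighbor_roots:
            b = r * cols + c  # new basin seeded at a local minimum
            cell_basin[r, c] = b
            basin_min[b] = h
            continue
        # join the basin with the lowest minimum (ties: smallest id)
        neighbor_roots.sort(key=lambda b: (basin_min[b], b))
        home = neighbor_roots[0]
        for other in neighbor_roots[1:]:
            if h < merge_limit:  # low ridge: basins are one cluster
                merged = uf.union(home, other)
                basin_min[merged] = min(basin_min[home], basin_min[other])
                home = merged
        cell_basin[r, c] = home

    # label genes by the final basin of their BMU, compacted to 1..k
    gene_roots = {
        g: uf.find(cell_basin[rc[0], rc[1]]) for g, rc in som.bmu_map.items()
    }
    distinct = sorted(set(gene_roots.values()), key=lambda b: (basin_min[uf.find(b)], b))
    relabel = {b: i + 1 for i, b in enumerate(distinct)}
    labels = {g: relabel[b] for g, b in gene_roots.items()}
    return ClusterAssignment(labels=labels, n_clusters=len(distinct))
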