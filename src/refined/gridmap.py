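"""2D embeddings, square-grid tessellation, and hill-climbing refinement.

The pipeline turns a feature distance matrix into an injective assignment of
features to pixels of the smallest square grid that holds them:

1. an initial 2D embedding (classical MDS by default; isomap / LLE /
   Laplacian eigenmaps / uniform-random as ablation alternatives),
2. optionally Bayesian metric MDS to refine locations on the unit square,
3. tessellation of the square into ``ceil(sqrt(p))^2`` pixels with at most
   one feature per pixel,
4. greedy hill climbing that swaps each feature with its Moore (8-connected)
   neighbours whenever the swap lowers the total absolute difference between
   pixel-centre distances and the benchmark distances delta-hat.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform

from .bmds import BayesianMDS, BmdsConfig, BMDSResults, LocationSet
from .data import DistanceMatrix, FeatureTable, ValidationError, feature_distance_matrix

__all__ = [
    "PixelMap",
    "HillClimbReport",
    "RefinedConfig",
    "RefinedMapper",
    "RefinedMapResults",
    "mds_init",
    "alt_init",
    "grid_side",
    "assign_to_grid",
    "map_cost",
    "hill_climb",
    "build_refined_map",
    "rescale_to_unit_square",
    "scale_distances",
]


@dataclass
class PixelMap:
    """Injective assignment of features to pixels of a square grid."""

    grid_rows: int
    grid_cols: int
    assignment: dict  # feature name -> (row, col), 0-based

    def __post_init__(self):
        cells = list(self.assignment.values())
        if len(set(cells)) != len(cells):
            raise ValidationError("pixel map is not injective")
        for r, c in cells:
            if not (0 <= r < self.grid_rows and 0 <= c < self.grid_cols):
                raise ValidationError(f"pixel ({r}, {c}) outside {self.grid_rows}x{self.grid_cols} grid")
        if self.grid_rows * self.grid_cols < len(cells):
            raise ValidationError("grid too small for feature count")

    @property
    def p(self) -> int:
        return len(self.assignment)

    @property
    def features(self) -> list:
        return list(self.assignment)

    def positions(self, order=None) -> np.ndarray:
        """(p, 2) array of (row, col) in the given feature order."""
        order = self.features if order is None else order
        return np.array([self.assignment[f] for f in order], dtype=float)

    def pixel_distances(self, order=None) -> np.ndarray:
        """Pairwise Euclidean pixel-centre distances rescaled to the unit square."""
        side = max(self.grid_rows, self.grid_cols)
        return squareform(pdist(self.positions(order))) / side

    def write(self, csv_path, json_path=None, **header) -> None:
        frame = pd.DataFrame(
            [(f, r, c) for f, (r, c) in self.assignment.items()],
            columns=["feature", "row", "col"],
        )
        frame.to_csv(csv_path, index=False)
        if json_path is not None:
            meta = {"grid_rows": self.grid_rows, "grid_cols": self.grid_cols, **header}
            with open(json_path, "w", encoding="utf-8") as fh:
                json.dump(meta, fh, indent=2)

    @classmethod
    def read(cls, csv_path, json_path) -> "PixelMap":
        frame = pd.read_csv(csv_path)
        with open(json_path, "r", encoding="utf-8") as fh:
            meta = json.load(fh)
        assignment = {
            str(row.feature): (int(row.row), int(row.col)) for row in frame.itertuples()
        }
        return cls(meta["grid_rows"], meta["grid_cols"], assignment)


@dataclass
class HillClimbReport:
    """Bookkeeping for one hill-climbing run."""

    initial_cost: float
    final_cost: float
    n_sweeps: int
    cost_trace: list
    final_correlation: float = np.nan  # pixel-distance vs delta-hat Pearson r (monitoring)

    def write_csv(self, path) -> None:
        pd.DataFrame({"step": range(len(self.cost_trace)), "cost": self.cost_trace}).to_csv(
            path, index=False
        )


def rescale_to_unit_square(coords: np.ndarray) -> np.ndarray:
    """Similarity-rescale 2D coordinates into [0, 1]^2 (shape-preserving).

    Both axes are divided by the larger axis range, so relative distances are
    preserved; a degenerate (single-point) cloud collapses to the centre.
    """
    coords = np.asarray(coords, dtype=float)
    lo = coords.min(axis=0)
    span = coords.max(axis=0) - lo
    scale = span.max()
    if scale <= 0:
        return np.full_like(coords, 0.5)
    return (coords - lo) / scale


def scale_distances(d: DistanceMatrix) -> DistanceMatrix:
    """Linearly rescale distances so the maximum is 1 (unit-square commensurate)."""
    m = d.d.max()
    if m <= 0:
        raise ValidationError("degenerate all-zero distance matrix")
    return DistanceMatrix(labels=list(d.labels), d=d.d / m)


def _classical_mds_coords(d: np.ndarray, n_components: int = 2) -> np.ndarray:
    """Torgerson double-centering eigendecomposition; deterministic."""
    d2 = d**2
    n = d.shape[0]
    j = np.eye(n) - np.ones((n, n)) / n
    b = -0.5 * j @ d2 @ j
    vals, vecs = np.linalg.eigh(b)
    order = np.argsort(vals)[::-1][:n_components]
    vals = np.clip(vals[order], 0.0, None)
    coords = vecs[:, order] * np.sqrt(vals)
    # deterministic sign convention: largest-magnitude entry positive
    for k in range(coords.shape[1]):
        col = coords[:, k]
        if col[np.argmax(np.abs(col))] < 0:
            coords[:, k] = -col
    return coords


def mds_init(d: DistanceMatrix, seed: int | None = None) -> LocationSet:
    """Classical metric MDS embedding rescaled into the unit square.

    Deterministic; the seed argument is accepted for interface uniformity
    with the stochastic initializers.
    """
    if d.p < 2:
        raise ValidationError("need p >= 2")
    if d.d.max() <= 0:
        raise ValidationError("degenerate all-zero distance matrix")
    coords = _classical_mds_coords(d.d)
    return LocationSet(list(d.labels), rescale_to_unit_square(coords))


def alt_init(
    d: DistanceMatrix, method: str, k_neighbors: int = 10, seed: int = 0
) -> LocationSet:
    """Alternative 2D initializers: isomap, LLE, Laplacian eigenmaps, random."""
    p = d.p
    if method == "random":
        rng = np.random.default_rng(seed)
        return LocationSet(list(d.labels), rng.uniform(size=(p, 2)))
    if method in ("isomap", "lle", "le") and not 1 <= k_neighbors < p:
        raise ValidationError(f"k_neighbors must be in [1, p); got {k_neighbors} for p={p}")
    if method == "isomap":
        from sklearn.manifold import Isomap

        emb = Isomap(n_neighbors=k_neighbors, n_components=2, metric="precomputed")
        coords = emb.fit_transform(d.d)
    elif method == "lle":
        from sklearn.manifold import LocallyLinearEmbedding

        # LLE needs point coordinates: recover them from the distances first
        full = _classical_mds_coords(d.d, n_components=min(p - 1, 10))
        emb = LocallyLinearEmbedding(
            n_neighbors=k_neighbors, n_components=2, random_state=seed
        )
        coords = emb.fit_transform(full)
    elif method == "le":
        from sklearn.manifold import SpectralEmbedding
        from sklearn.neighbors import kneighbors_graph

        graph = kneighbors_graph(d.d, n_neighbors=k_neighbors, metric="precomputed")
        affinity = 0.5 * (graph + graph.T)
        emb = SpectralEmbedding(n_components=2, affinity="precomputed", random_state=seed)
        coords = emb.fit_transform(affinity.toarray())
    else:
        raise ValidationError(f"unknown init method {method!r}")
    return LocationSet(list(d.labels), rescale_to_unit_square(coords))


def grid_side(p: int) -> int:
    """Side of the smallest square grid holding p features: ceil(sqrt(p))."""
    if p < 1:
        raise ValidationError("p must be >= 1")
    return math.isqrt(p - 1) + 1 if math.isqrt(p) ** 2 != p else math.isqrt(p)


def _ring_cells(r0: int, c0: int, radius: int, rows: int, cols: int):
    """Cells at Chebyshev distance `radius`, in row-then-column order."""
    for r in range(r0 - radius, r0 + radius + 1):
        if not 0 <= r < rows:
            continue
        for c in range(c0 - radius, c0 + radius + 1):
            if not 0 <= c < cols:
                continue
            if max(abs(r - r0), abs(c - c0)) == radius:
                yield r, c


def assign_to_grid(loc: LocationSet) -> PixelMap:
    """Tessellate the unit square; each feature gets the pixel containing it.

    Collisions are resolved deterministically: features are processed in
    label order, and a feature whose pixel is taken moves to the nearest free
    pixel by increasing Chebyshev ring, ties broken row-then-column.
    """
    p = loc.p
    side = grid_side(p)
    taken: set = set()
    assignment: dict = {}
    for name, (x, y) in zip(loc.labels, loc.s):
        row = min(int(y * side), side - 1)
        col = min(int(x * side), side - 1)
        if (row, col) not in taken:
            taken.add((row, col))
            assignment[name] = (row, col)
            continue
        placed = False
        for radius in range(1, 2 * side):
            for cell in _ring_cells(row, col, radius, side, side):
                if cell not in taken:
                    taken.add(cell)
                    assignment[name] = cell
                    placed = True
                    break
            if placed:
                break
        if not placed:  # cannot happen: grid has >= p cells
            raise ValidationError("no free pixel found")
    return PixelMap(side, side, assignment)


def map_cost(m: PixelMap, delta_hat: DistanceMatrix) -> float:
    """Sum over pairs of |pixel-centre distance - delta_hat| (unit-square scale)."""
    if set(m.features) != set(delta_hat.labels):
        raise ValidationError("pixel-map features do not match distance labels")
    order = list(delta_hat.labels)
    pix = m.pixel_distances(order)
    return float(np.sum(np.abs(squareform(pix, checks=False) - delta_hat.condensed())))


def hill_climb(
    m: PixelMap,
    delta_hat: DistanceMatrix,
    max_sweeps: int = 50,
    seed: int | None = None,
):
    """Greedy local search over Moore-neighbourhood exchanges.

    Pixels are visited sequentially in row-major order.  For the feature at
    each occupied pixel, all 8 neighbouring cells are tried: an occupied
    neighbour means swapping the two features, an empty one means moving the
    centre feature.  The best strictly-improving candidate is accepted.
    Sweeps repeat until a full sweep changes nothing or ``max_sweeps`` is
    reached; the cost never increases.  Deterministic (seed unused, kept for
    interface symmetry).
    """
    if set(m.features) != set(delta_hat.labels):
        raise ValidationError("pixel-map features do not match distance labels")
    order = list(delta_hat.labels)
    index = {f: i for i, f in enumerate(order)}
    p = len(order)
    rows, cols = m.grid_rows, m.grid_cols
    side = max(rows, cols)
    delta = delta_hat.d

    pos = np.zeros((p, 2), dtype=int)
    grid = -np.ones((rows, cols), dtype=int)
    for f, (r, c) in m.assignment.items():
        i = index[f]
        pos[i] = (r, c)
        grid[r, c] = i

    def pair_cost_rows(i: int, cell) -> np.ndarray:
        """|pixdist - delta| of feature i against all others if i sat at `cell`."""
        diff = pos - np.asarray(cell, dtype=float)
        dist = np.sqrt(np.einsum("ij,ij->i", diff.astype(float), diff.astype(float))) / side
        out = np.abs(dist - delta[i])
        out[i] = 0.0
        return out

    def current_cost() -> float:
        pix = squareform(pdist(pos.astype(float))) / side
        return float(np.sum(np.abs(pix - delta)) / 2.0)

    cost = current_cost()
    initial_cost = cost
    trace = [cost]
    neighbours = [(-1, -1), (-1, 0), (-1, 1), (0, -1), (0, 1), (1, -1), (1, 0), (1, 1)]
    sweeps = 0
    for _ in range(max_sweeps):
        sweeps += 1
        changed = False
        for r in range(rows):
            for c in range(cols):
                i = grid[r, c]
                if i < 0:
                    continue
                base_i = pair_cost_rows(i, (r, c)).sum()
                best_gain = -1e-12
                best = None
                for dr, dc in neighbours:
                    nr, nc = r + dr, c + dc
                    if not (0 <= nr < rows and 0 <= nc < cols):
                        continue
                    g = grid[nr, nc]
                    if g < 0:
                        gain = pair_cost_rows(i, (nr, nc)).sum() - base_i
                    else:
                        old = base_i + pair_cost_rows(g, (nr, nc)).sum()
                        # pair (i, g) distance is unchanged by the swap; it is
                        # double-counted identically on both sides
                        new_i = pair_cost_rows(i, (nr, nc))
                        new_g = pair_cost_rows(g, (r, c))
                        fix = (
                            new_i[g]
                            - abs(np.hypot(nr - r, nc - c) / side - delta[i, g])
                            + new_g[i]
                            - abs(np.hypot(nr - r, nc - c) / side - delta[g, i])
                        )
                        gain = new_i.sum() + new_g.sum() - fix - old
                    if gain < best_gain:
                        best_gain = gain
                        best = (nr, nc, g)
                if best is not None:
                    nr, nc, g = best
                    if g < 0:
                        grid[r, c] = -1
                        grid[nr, nc] = i
                        pos[i] = (nr, nc)
                    else:
                        grid[r, c], grid[nr, nc] = g, i
                        pos[i] = (nr, nc)
                        pos[g] = (r, c)
                    cost = current_cost()
                    trace.append(cost)
                    changed = True
        if not changed:
            break

    assignment = {order[i]: (int(pos[i, 0]), int(pos[i, 1])) for i in range(p)}
    final_map = PixelMap(rows, cols, assignment)
    pix = squareform(pdist(pos.astype(float))) / side
    triu = np.triu_indices(p, 1)
    corr = float(np.corrcoef(pix[triu], delta[triu])[0, 1]) if p > 2 else np.nan
    report = HillClimbReport(
        initial_cost=initial_cost,
        final_cost=cost,
        n_sweeps=sweeps,
        cost_trace=trace,
        final_correlation=corr,
    )
    return final_map, report


@dataclass
class RefinedConfig:
    """Pipeline configuration for building a feature map."""

    init_method: str = "mds"  # mds | isomap | lle | le | random
    use_bmds: bool = True  # only honoured for init_method="mds"
    bmds: BmdsConfig = field(default_factory=BmdsConfig)
    k_neighbors: int = 10
    max_sweeps: int = 50
    seed: int = 0


class RefinedMapper:
    """End-to-end mapper: distances -> embedding -> (BMDS) -> grid -> hill climb.

    Examples
    --------
    >>> mapper = RefinedMapper(table, RefinedConfig(seed=7))
    >>> res = mapper.fit()
    >>> res.pixel_map.grid_rows
    10
    """

    def __init__(self, table: FeatureTable, config: RefinedConfig | None = None):
        self.table = table
        self.config = config if config is not None else RefinedConfig()

    @classmethod
    def from_dataframe(cls, frame: pd.DataFrame, config: RefinedConfig | None = None):
        return cls(FeatureTable.from_frame(frame), config)

    def fit(self) -> "RefinedMapResults":
        cfg = self.config
        d_raw = feature_distance_matrix(self.table)
        d = scale_distances(d_raw)
        bmds_results = None
        if cfg.init_method == "mds":
            init = mds_init(d, seed=cfg.seed)
            if cfg.use_bmds:
                bcfg = replace(cfg.bmds, seed=cfg.bmds.seed or cfg.seed)
                bmds_results = BayesianMDS(d, bcfg).fit(init)
                locations = bmds_results.point_estimate
                delta_hat = bmds_results.estimated_distances()
            else:
                locations = init
                delta_hat = d
        else:
            locations = alt_init(d, cfg.init_method, cfg.k_neighbors, cfg.seed)
            delta_hat = d
        initial_map = assign_to_grid(locations)
        final_map, report = hill_climb(initial_map, delta_hat, cfg.max_sweeps, cfg.seed)
        return RefinedMapResults(
            mapper=self,
            pixel_map=final_map,
            initial_map=initial_map,
            report=report,
            bmds_results=bmds_results,
            delta_hat=delta_hat,
            distances=d,
        )


@dataclass
class RefinedMapResults:
    """Fitted feature map with the hill-climbing report and BMDS results."""

    mapper: RefinedMapper
    pixel_map: PixelMap
    initial_map: PixelMap
    report: HillClimbReport
    bmds_results: BMDSResults | None
    delta_hat: DistanceMatrix
    distances: DistanceMatrix

    def summary(self) -> str:
        cfg = self.mapper.config
        lines = [
            "Feature-to-pixel map",
            f"  features (p):        {self.pixel_map.p}",
            f"  grid:                {self.pixel_map.grid_rows} x {self.pixel_map.grid_cols}",
            f"  init method:         {cfg.init_method}"
            + (" + BMDS" if self.bmds_results is not None else ""),
            f"  hill-climb sweeps:   {self.report.n_sweeps}",
            f"  cost initial/final:  {self.report.initial_cost:.4f} / {self.report.final_cost:.4f}",
            f"  pixel-dist vs delta-hat r: {self.report.final_correlation:.4f}",
        ]
        return "\n".join(lines)


def build_refined_map(t: FeatureTable, cfg: RefinedConfig | None = None):
    """Functional wrapper returning (PixelMap, HillClimbReport)."""
    res = RefinedMapper(t, cfg).fit()
    return res.pixel_map, res.report
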