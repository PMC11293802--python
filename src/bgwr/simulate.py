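"""Seeded generators for the two synthetic study designs, plus a
neighbour-based imputation utility for areal covariate tables.

Two designs are provided.  The first ("Louisiana-like") has no spatial
variation in the coefficients: 64 regions on a regular lattice rescaled so
the maximum pairwise distance is 10, three observations per region (192
rows), five i.i.d. standard-normal covariates, truth beta = (2, 0, 0, 4, 8)
and unit Gaussian noise.  The second ("Georgia-like") has 159 regions on a
jittered lattice partitioned into three contiguous clusters of sizes
51/49/59; six spatially correlated covariates are drawn from a Gaussian
process with squared-exponential covariance over the centroid distances, and
each cluster has its own six-coefficient vector (three signal-strength
settings), with one observation per region and unit noise.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .data import ObservationTable
from .geo import AreaMap, distance_matrix

LOUISIANA_BETA = (2.0, 0.0, 0.0, 4.0, 8.0)

#: per-cluster coefficient vectors (beta_1..beta_6, intercept 0) for the
#: three signal-strength settings of the spatially varying design
GEORGIA_SETTINGS = {
    1: [(1, 0, 1, 0, 0.5, 2), (1, 0.7, 0.3, 2, 0, 3), (2, 1, 0.8, 1, 0, 1)],
    2: [(2, 0, 1, 0, 4, 2), (1, 0, 3, 2, 0, 3), (4, 1, 0, 3, 0, 1)],
    3: [(9, 0, -4, 0, 2, 5), (1, 7, 3, 6, 0, -1), (2, 0, 6, 1, 7, 0)],
}
GEORGIA_CLUSTER_SIZES = (51, 49, 59)


@dataclass
class SyntheticStudy:
    """A generated map, observation table and ground truth."""

    area_map: AreaMap
    table: ObservationTable
    true_beta: np.ndarray          # (S, p) generating coefficient field
    true_clusters: Optional[np.ndarray]  # per-region labels, or None
    setting: str
    seed: int


def _lattice(side_x: int, side_y: int) -> np.ndarray:
    xs, ys = np.meshgrid(np.arange(side_x), np.arange(side_y), indexing="ij")
    return np.column_stack([xs.ravel(), ys.ravel()]).astype(float)


def _rescale_max_distance(centroids: np.ndarray, target: float) -> np.ndarray:
    diff = centroids[:, None, :] - centroids[None, :, :]
    mx = np.sqrt((diff**2).sum(-1)).max()
    return centroids * (target / mx)


def _grid_adjacency(region_ids, grid_pos) -> list:
    pos = {tuple(p): r for p, r in zip(grid_pos, region_ids)}
    edges = []
    for (gx, gy), r in pos.items():
        for nb in ((gx + 1, gy), (gx, gy + 1)):
            if nb in pos:
                edges.append((r, pos[nb]))
    return edges


def louisiana_like(
    seed: int = 0,
    n_regions: int = 64,
    obs_per_region: int = 3,
    beta: Sequence[float] = LOUISIANA_BETA,
    noise_sd: float = 1.0,
    centroids: Optional[np.ndarray] = None,
) -> SyntheticStudy:
    """Constant-coefficient design: lattice regions, i.i.d. covariates.

    Centroids sit on a regular sqrt(n) x sqrt(n) lattice rescaled so the
    maximum pairwise distance is 10; covariates are i.i.d. N(0, 1) per
    observation and ``y = X beta + eps`` with ``eps ~ N(0, noise_sd^2)``.
    """
    rng = np.random.default_rng(seed)
    beta = np.asarray(beta, dtype=float)
    p = beta.shape[0]
    if centroids is None:
        side = int(round(np.sqrt(n_regions)))
        if side * side != n_regions:
            raise ValueError(
                "n_regions must be a perfect square for the default lattice "
                "(or pass explicit centroids)"
            )
        centroids = _lattice(side, side)
    centroids = _rescale_max_distance(np.asarray(centroids, dtype=float), 10.0)
    region_ids = list(range(1, n_regions + 1))
    area_map = AreaMap(region_ids, centroids, "planar")

    n = n_regions * obs_per_region
    X = rng.standard_normal((n, p))
    eps = rng.normal(0.0, noise_sd, size=n) if noise_sd > 0 else np.zeros(n)
    y = X @ beta + eps
    obs_region = np.repeat(region_ids, obs_per_region)
    table = ObservationTable(
        y=y, X=X, obs_region=obs_region,
        covariate_names=[f"x{j + 1}" for j in range(p)],
    )
    return SyntheticStudy(
        area_map=area_map,
        table=table,
        true_beta=np.tile(beta, (n_regions, 1)),
        true_clusters=None,
        setting="louisiana",
        seed=seed,
    )


def georgia_like(
    setting: int = 3,
    seed: int = 0,
    n_regions: int = 159,
    phi: Optional[float] = None,
    noise_sd: float = 1.0,
) -> SyntheticStudy:
    """Spatially varying design with three contiguous coefficient clusters.

    159 jittered-lattice centroids (rescaled to maximum distance 10) are
    split into contiguous blocks of 51/49/59 by sorted first-then-second
    coordinate.  Each of six covariates is one draw from a zero-mean
    Gaussian process with covariance ``exp(-(d / phi)^2)``; ``phi`` defaults
    to one-fifth of the maximum pairwise distance.  The response is
    ``y(s) = sum_k beta_k(s) X_k(s) + eps(s)`` (intercept 0) with the
    cluster-wise coefficient vectors of the chosen setting.
    """
    if setting not in GEORGIA_SETTINGS:
        raise ValueError(f"setting must be one of {sorted(GEORGIA_SETTINGS)}")
    rng = np.random.default_rng(seed)
    side = int(np.ceil(np.sqrt(n_regions)))
    grid = _lattice(side, side)[:n_regions]
    jitter = rng.uniform(-0.2, 0.2, size=grid.shape)
    centroids = _rescale_max_distance(grid + jitter, 10.0)
    region_ids = list(range(1, n_regions + 1))
    adjacency = _grid_adjacency(region_ids, [tuple(g) for g in grid])
    area_map = AreaMap(region_ids, centroids, "planar", adjacency=adjacency)

    dm = distance_matrix(area_map, "euclidean").values
    if phi is None:
        phi = dm.max() / 5.0
    cov = np.exp(-((dm / phi) ** 2)) + 1e-8 * np.eye(n_regions)
    L = np.linalg.cholesky(cov)
    X = L @ rng.standard_normal((n_regions, 6))  # six spatially correlated fields

    sizes = GEORGIA_CLUSTER_SIZES if n_regions == 159 else _proportional_sizes(n_regions)
    order = np.lexsort((centroids[:, 1], centroids[:, 0]))
    clusters = np.empty(n_regions, dtype=int)
    start = 0
    for k, sz in enumerate(sizes, start=1):
        clusters[order[start : start + sz]] = k
        start += sz

    vectors = np.asarray(GEORGIA_SETTINGS[setting], dtype=float)
    true_beta = np.column_stack(
        [np.zeros(n_regions), vectors[clusters - 1]]
    )  # intercept 0 + beta_1..beta_6
    eps = rng.normal(0.0, noise_sd, size=n_regions) if noise_sd > 0 else 0.0
    y = (X * vectors[clusters - 1]).sum(axis=1) + eps

    table = ObservationTable(
        y=y,
        X=np.column_stack([np.ones(n_regions), X]),
        obs_region=region_ids,
        covariate_names=["intercept"] + [f"x{j + 1}" for j in range(6)],
    )
    return SyntheticStudy(
        area_map=area_map,
        table=table,
        true_beta=true_beta,
        true_clusters=clusters,
        setting=f"georgia-{setting}",
        seed=seed,
    )


def _proportional_sizes(n_regions: int) -> tuple:
    props = np.array(GEORGIA_CLUSTER_SIZES) / 159.0
    sizes = np.floor(props * n_regions).astype(int)
    sizes[-1] = n_regions - sizes[:-1].sum()
    return tuple(sizes)


def impute_by_neighbors(
    frame: pd.DataFrame,
    area_map: AreaMap,
    region_col: str = "region_id",
    categorical: Sequence[str] = (),
) -> pd.DataFrame:
    """Fill missing region-level values from contiguous neighbours.

    Continuous columns get the mean of non-missing neighbour values;
    categorical columns get the neighbours' highest-frequency category
    (ties -> smallest value).  Regions with no neighbours at all are dropped
    with a warning; a missing value whose neighbours are all missing raises.
    """
    if area_map.adjacency is None:
        raise ValueError("imputation requires adjacency")
    out = frame.copy()
    nbrs: dict = {r: [] for r in area_map.region_ids}
    for a, b in area_map.adjacency:
        nbrs[a].append(b)
    by_region = out.set_index(region_col)

    islands = [r for r in by_region.index if not nbrs.get(r)]
    isolated_missing = [
        r for r in islands if by_region.loc[r].isna().any()
    ]
    if isolated_missing:
        warnings.warn(
            f"dropping {len(isolated_missing)} region(s) with missing values "
            f"and no neighbours: {isolated_missing}",
            RuntimeWarning,
        )
        out = out[~out[region_col].isin(isolated_missing)]
        by_region = out.set_index(region_col)

    value_cols = [c for c in out.columns if c != region_col]
    for col in value_cols:
        missing_regions = by_region.index[by_region[col].isna()]
        for r in missing_regions:
            vals = by_region.loc[
                [n for n in nbrs.get(r, []) if n in by_region.index], col
            ].dropna()
            if vals.empty:
                raise ValueError(
                    f"cannot impute {col!r} for region {r}: all neighbours missing"
                )
            if col in categorical:
                counts = vals.value_counts()
                top = counts[counts == counts.max()].index
                fill = sorted(top)[0]
            else:
                fill = float(vals.mean())
            out.loc[out[region_col] == r, col] = fill
    return out
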