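"""Areal geometry: region maps, distance matrices and kernel weight functions.

Geographically weighted regression down-weights observations by their
distance from a focal region.  This module provides the geometry substrate:
an :class:`AreaMap` of region centroids (planar or lon/lat) with optional
adjacency, pairwise distance matrices under three metrics (Euclidean,
great-circle, graph hop count), and the three kernel functions that turn
distances into weights in [0, 1] under a bandwidth ``b``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import networkx as nx
import numpy as np

EARTH_RADIUS_KM = 6371.0

#: weights below this are floored in likelihood evaluations so that the
#: implied observation variance sigma^2 / w stays finite (bounded-support
#: kernels such as the bi-square produce exact zeros beyond the bandwidth)
WEIGHT_FLOOR = 1e-12

KERNELS = ("exponential", "gaussian", "bisquare")
METRICS = ("euclidean", "gcd", "graph")


@dataclass
class AreaMap:
    """Regions with centroids and optional adjacency.

    Parameters
    ----------
    region_ids
        Unique region identifiers (any hashable; order defines the index).
    centroids
        ``(S, 2)`` array of coordinate pairs.  For ``coordinate_system ==
        "lonlat"`` these are decimal degrees (longitude, latitude) on WGS84.
    coordinate_system
        ``"planar"`` or ``"lonlat"``.
    adjacency
        Optional symmetric edge list of ``(id, id)`` pairs over
        ``region_ids`` (no self-edges).
    """

    region_ids: Sequence
    centroids: np.ndarray
    coordinate_system: str = "planar"
    adjacency: Optional[Sequence[tuple]] = None

    def __post_init__(self) -> None:
        self.region_ids = list(self.region_ids)
        self.centroids = np.asarray(self.centroids, dtype=float)
        if len(set(self.region_ids)) != len(self.region_ids):
            raise ValueError("region ids must be unique")
        if self.centroids.shape != (len(self.region_ids), 2):
            raise ValueError(
                f"centroids must be ({len(self.region_ids)}, 2), "
                f"got {self.centroids.shape}"
            )
        if self.coordinate_system not in ("planar", "lonlat"):
            raise ValueError(f"unknown coordinate_system {self.coordinate_system!r}")
        if self.adjacency is not None:
            known = set(self.region_ids)
            seen = set()
            for a, b in self.adjacency:
                if a not in known or b not in known:
                    raise ValueError(f"adjacency endpoint ({a}, {b}) not a known region")
                if a == b:
                    raise ValueError(f"self-edge on region {a}")
                seen.add((a, b))
            # symmetrize: an edge listed one way implies the reverse
            self.adjacency = sorted(
                {(a, b) for a, b in seen} | {(b, a) for a, b in seen}
            )

    @property
    def n_regions(self) -> int:
        return len(self.region_ids)

    def index_of(self, region_id) -> int:
        return self.region_ids.index(region_id)


@dataclass
class DistanceMatrix:
    """Symmetric zero-diagonal matrix of pairwise region distances."""

    values: np.ndarray
    metric: str

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2 or self.values.shape[0] != self.values.shape[1]:
            raise ValueError("distance matrix must be square")
        if not np.allclose(self.values, self.values.T):
            raise ValueError("distance matrix must be symmetric")
        if not np.allclose(np.diag(self.values), 0.0):
            raise ValueError("distance matrix must have zero diagonal")
        if np.any(self.values < 0):
            raise ValueError("distances must be nonnegative")

    @property
    def max_distance(self) -> float:
        return float(self.values.max())

    def rescaled_to(self, max_value: float) -> "DistanceMatrix":
        """Globally rescale so the maximum pairwise distance equals ``max_value``."""
        cur = self.max_distance
        if cur <= 0:
            raise ValueError("cannot rescale a zero distance matrix")
        return DistanceMatrix(self.values * (max_value / cur), self.metric)


@dataclass
class KernelSpec:
    """Kernel family plus either a fixed bandwidth or a prior upper bound.

    ``bandwidth`` fixes the kernel scale ``b``; leaving it ``None`` means the
    sampler estimates ``b`` under a Uniform(0, D) prior with ``D`` taken from
    the prior specification.
    """

    kernel: str = "exponential"
    bandwidth: Optional[float] = None

    def __post_init__(self) -> None:
        if self.kernel not in KERNELS:
            raise ValueError(f"kernel must be one of {KERNELS}, got {self.kernel!r}")
        if self.bandwidth is not None and self.bandwidth <= 0:
            raise ValueError("bandwidth must be positive")


def distance_matrix(area_map: AreaMap, metric: str = "euclidean") -> DistanceMatrix:
    """Pairwise region distances under the chosen metric.

    ``euclidean`` uses planar coordinates directly; ``gcd`` is the haversine
    great-circle distance in km (mean Earth radius 6371 km, lon/lat degrees
    required); ``graph`` is the unweighted shortest-path hop count over the
    map's adjacency.
    """
    if metric not in METRICS:
        raise ValueError(f"metric must be one of {METRICS}, got {metric!r}")
    xy = area_map.centroids
    if metric == "euclidean":
        diff = xy[:, None, :] - xy[None, :, :]
        vals = np.sqrt((diff**2).sum(axis=-1))
    elif metric == "gcd":
        if area_map.coordinate_system != "lonlat":
            raise ValueError("great-circle distance requires lonlat coordinates")
        vals = _haversine_matrix(xy)
    else:  # graph
        if area_map.adjacency is None:
            raise ValueError("graph distance requires adjacency")
        vals = _graph_hop_matrix(area_map)
    np.fill_diagonal(vals, 0.0)
    vals = 0.5 * (vals + vals.T)  # kill fp asymmetry
    return DistanceMatrix(vals, metric)


def _haversine_matrix(lonlat_deg: np.ndarray) -> np.ndarray:
    lon = np.radians(lonlat_deg[:, 0])
    lat = np.radians(lonlat_deg[:, 1])
    dlon = lon[:, None] - lon[None, :]
    dlat = lat[:, None] - lat[None, :]
    h = (
        np.sin(dlat / 2) ** 2
        + np.cos(lat)[:, None] * np.cos(lat)[None, :] * np.sin(dlon / 2) ** 2
    )
    return 2 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(np.clip(h, 0.0, 1.0)))


def _graph_hop_matrix(area_map: AreaMap) -> np.ndarray:
    g = nx.Graph()
    g.add_nodes_from(area_map.region_ids)
    g.add_edges_from(area_map.adjacency)
    idx = {r: i for i, r in enumerate(area_map.region_ids)}
    S = area_map.n_regions
    vals = np.full((S, S), np.inf)
    for src, lengths in nx.all_pairs_shortest_path_length(g):
        for dst, hops in lengths.items():
            vals[idx[src], idx[dst]] = hops
    if np.isinf(vals).any():
        bad = [
            (area_map.region_ids[i], area_map.region_ids[j])
            for i, j in zip(*np.where(np.isinf(vals)))
            if i < j
        ]
        raise ValueError(
            f"graph is disconnected; unreachable region pairs: {bad[:10]}"
            + ("..." if len(bad) > 10 else "")
        )
    return vals


def kernel_weights(distances: np.ndarray, spec: KernelSpec) -> np.ndarray:
    """Kernel weights in [0, 1] for distances to a focal region.

    exponential: ``exp(-d/b)``; gaussian: ``exp(-(d/b)^2)``; bisquare:
    ``(1 - (d/b)^2)^2`` for ``d < b``, else 0.  All kernels give weight
    exactly 1 at zero distance and are nonincreasing in distance.
    """
    d = np.asarray(distances, dtype=float)
    if np.any(d < 0):
        raise ValueError("distances must be nonnegative")
    b = spec.bandwidth
    if b is None or b <= 0:
        raise ValueError("kernel_weights requires a positive bandwidth")
    if spec.kernel == "exponential":
        return np.exp(-d / b)
    if spec.kernel == "gaussian":
        return np.exp(-((d / b) ** 2))
    u = d / b
    return np.where(u < 1.0, (1.0 - u**2) ** 2, 0.0)


def floored_weights(distances: np.ndarray, spec: KernelSpec) -> np.ndarray:
    """Kernel weights floored at :data:`WEIGHT_FLOOR` for likelihood use."""
    return np.maximum(kernel_weights(distances, spec), WEIGHT_FLOOR)
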