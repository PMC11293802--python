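"""Readers and writers: area maps and data from CSV/GeoJSON, posterior
draws to a columnar on-disk layout with a JSON manifest."""

from __future__ import annotations

import json
from dataclasses import asdict
from pathlib import Path
from typing import Tuple

import numpy as np
import pandas as pd

from .data import ObservationTable
from .geo import AreaMap, KernelSpec
from .sampler import BgwrDraws, McmcSettings, PriorSpec
from .selection import SelectionDraws


def load_area_map(map_path, adjacency_path=None) -> AreaMap:
    """Read an AreaMap from CSV (region_id, x|lon, y|lat) or GeoJSON polygons.

    GeoJSON features must carry a ``region_id`` property; centroids are the
    polygons' representative points and the coordinate system is lon/lat.
    An optional two-column edge-list CSV supplies adjacency.
    """
    map_path = Path(map_path)
    if map_path.suffix.lower() in (".geojson", ".json"):
        ids, centroids = _read_geojson(map_path)
        system = "lonlat"
    else:
        df = pd.read_csv(map_path)
        if "region_id" not in df.columns:
            raise ValueError("map CSV must have a region_id column")
        if {"lon", "lat"} <= set(df.columns):
            xcol, ycol, system = "lon", "lat", "lonlat"
        elif {"x", "y"} <= set(df.columns):
            xcol, ycol, system = "x", "y", "planar"
        else:
            raise ValueError("map CSV must have columns x,y or lon,lat")
        dup = df["region_id"][df["region_id"].duplicated()].tolist()
        if dup:
            raise ValueError(f"duplicate region ids in map: {sorted(set(dup))}")
        ids = df["region_id"].tolist()
        centroids = df[[xcol, ycol]].to_numpy(dtype=float)
    adjacency = None
    if adjacency_path is not None:
        edges = pd.read_csv(adjacency_path)
        adjacency = list(edges.iloc[:, :2].itertuples(index=False, name=None))
    return AreaMap(ids, centroids, system, adjacency=adjacency)


def _read_geojson(path: Path):
    from shapely.geometry import shape

    gj = json.loads(path.read_text())
    features = gj["features"] if gj.get("type") == "FeatureCollection" else [gj]
    ids, pts = [], []
    for feat in features:
        props = feat.get("properties") or {}
        if "region_id" not in props:
            raise ValueError("each GeoJSON feature needs a region_id property")
        geom = shape(feat["geometry"])
        rp = geom.representative_point()
        ids.append(props["region_id"])
        pts.append((rp.x, rp.y))
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate region ids in GeoJSON")
    return ids, np.asarray(pts, dtype=float)


def load_study(
    map_path, data_path, adjacency_path=None, response: str = "y"
) -> Tuple[AreaMap, ObservationTable]:
    """Load and cross-validate a map plus per-observation data table.

    The data CSV needs ``region_id``, the response column, and one column
    per covariate (every remaining column).  Rows referencing unknown
    regions raise with the offending ids listed.
    """
    area_map = load_area_map(map_path, adjacency_path)
    df = pd.read_csv(data_path)
    for col in ("region_id", response):
        if col not in df.columns:
            raise ValueError(f"data CSV must have a {col!r} column")
    known = set(area_map.region_ids)
    unknown = sorted({r for r in df["region_id"] if r not in known})
    if unknown:
        raise ValueError(f"data references unknown region ids: {unknown}")
    covs = [c for c in df.columns if c not in ("region_id", response)]
    table = ObservationTable(
        y=df[response].to_numpy(dtype=float),
        X=df[covs].to_numpy(dtype=float),
        obs_region=df["region_id"].tolist(),
        covariate_names=covs,
    )
    return area_map, table


def save_draws(draws: BgwrDraws, outdir) -> Path:
    """Write draw arrays (.npz) plus a JSON manifest; returns the directory."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    arrays = {
        "beta": draws.beta,
        "sigma2": draws.sigma2,
        "sigma_beta2": draws.sigma_beta2,
        "bandwidth": draws.bandwidth,
    }
    if isinstance(draws, SelectionDraws):
        arrays["gamma"] = draws.gamma
        arrays["psi"] = draws.psi
    np.savez_compressed(outdir / "draws.npz", **arrays)
    manifest = {
        "model": "bgwr-select" if isinstance(draws, SelectionDraws) else "bgwr",
        "kernel": asdict(draws.kernel),
        "priors": asdict(draws.priors),
        "settings": asdict(draws.settings),
        "seed": draws.settings.seed,
        "acceptance_rate": draws.acceptance_rate,
        "region_ids": list(draws.region_ids),
        "covariate_names": list(draws.covariate_names),
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return outdir


def load_draws(outdir) -> BgwrDraws:
    outdir = Path(outdir)
    manifest = json.loads((outdir / "manifest.json").read_text())
    arrays = np.load(outdir / "draws.npz")
    common = dict(
        beta=arrays["beta"],
        sigma2=arrays["sigma2"],
        sigma_beta2=arrays["sigma_beta2"],
        bandwidth=arrays["bandwidth"],
        acceptance_rate=manifest["acceptance_rate"],
        region_ids=manifest["region_ids"],
        covariate_names=manifest["covariate_names"],
        settings=McmcSettings(**manifest["settings"]),
        priors=PriorSpec(**manifest["priors"]),
        kernel=KernelSpec(**manifest["kernel"]),
    )
    if manifest["model"] == "bgwr-select":
        return SelectionDraws(gamma=arrays["gamma"], psi=arrays["psi"], **common)
    return BgwrDraws(**common)
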