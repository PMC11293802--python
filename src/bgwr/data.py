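"""Observation tables: response, design matrix and region assignment."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .geo import AreaMap


@dataclass
class ObservationTable:
    """Response vector, covariate matrix and observation-to-region map.

    ``active_mask`` is a per-region binary mask over covariate columns: a
    region samples only its active covariates (used for one-hot category
    columns that never occur among a region's relevant observations, which
    would otherwise be sampled from the prior alone).  Defaults to all
    active.
    """

    y: np.ndarray
    X: np.ndarray
    obs_region: Sequence
    covariate_names: Optional[Sequence[str]] = None
    active_mask: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.y = np.asarray(self.y, dtype=float).ravel()
        self.X = np.asarray(self.X, dtype=float)
        if self.X.ndim != 2 or self.X.shape[0] != self.y.shape[0]:
            raise ValueError("X must be (n, p) with n matching y")
        if np.isnan(self.y).any() or np.isnan(self.X).any():
            raise ValueError("missing values must be imputed before model fitting")
        self.obs_region = list(self.obs_region)
        if len(self.obs_region) != self.n_obs:
            raise ValueError("obs_region must have one entry per observation")
        if self.covariate_names is None:
            self.covariate_names = [f"x{j + 1}" for j in range(self.n_covariates)]
        else:
            self.covariate_names = list(self.covariate_names)
            if len(self.covariate_names) != self.n_covariates:
                raise ValueError("covariate_names length mismatch")

    @property
    def n_obs(self) -> int:
        return self.y.shape[0]

    @property
    def n_covariates(self) -> int:
        return self.X.shape[1]

    def region_index(self, area_map: AreaMap) -> np.ndarray:
        """Observation -> region position in ``area_map`` (validates ids)."""
        idx = {r: i for i, r in enumerate(area_map.region_ids)}
        missing = sorted({r for r in self.obs_region if r not in idx})
        if missing:
            raise ValueError(f"observations reference unknown regions: {missing}")
        return np.array([idx[r] for r in self.obs_region], dtype=int)

    def resolved_mask(self, area_map: AreaMap) -> np.ndarray:
        """``(S, p)`` boolean active-covariate mask aligned to the map."""
        S, p = area_map.n_regions, self.n_covariates
        if self.active_mask is None:
            return np.ones((S, p), dtype=bool)
        mask = np.asarray(self.active_mask, dtype=bool)
        if mask.shape != (S, p):
            raise ValueError(f"active_mask must be ({S}, {p}), got {mask.shape}")
        if not mask.any(axis=1).all():
            bad = [area_map.region_ids[i] for i in np.where(~mask.any(axis=1))[0]]
            raise ValueError(f"regions with zero active covariates: {bad}")
        return mask


def build_observation_table(
    frame: pd.DataFrame,
    area_map: AreaMap,
    response: str,
    covariates: Sequence[str],
    region_col: str = "region_id",
    intercept: bool = False,
    categorical: Sequence[str] = (),
) -> ObservationTable:
    """Assemble an :class:`ObservationTable` from a tidy per-observation frame.

    Categorical columns are one-hot encoded (dropping the first level as the
    reference); the per-region active mask deactivates a category column in
    every region where that category never occurs, so its coefficient is not
    sampled from the prior alone there.
    """
    cols: list[np.ndarray] = []
    names: list[str] = []
    if intercept:
        cols.append(np.ones(len(frame)))
        names.append("intercept")
    cat_levels: dict[str, list] = {}
    for c in covariates:
        if c in categorical:
            levels = sorted(frame[c].dropna().unique())
            for lev in levels[1:]:
                cols.append((frame[c] == lev).to_numpy(dtype=float))
                names.append(f"{c}[{lev}]")
                cat_levels[f"{c}[{lev}]"] = [c, lev]
        else:
            cols.append(frame[c].to_numpy(dtype=float))
            names.append(c)
    X = np.column_stack(cols)
    obs_region = frame[region_col].tolist()

    mask = np.ones((area_map.n_regions, len(names)), dtype=bool)
    if cat_levels:
        ridx = {r: i for i, r in enumerate(area_map.region_ids)}
        for j, name in enumerate(names):
            if name not in cat_levels:
                continue
            col, lev = cat_levels[name]
            present = set(frame.loc[frame[col] == lev, region_col])
            for r, i in ridx.items():
                if r not in present:
                    mask[i, j] = False
    return ObservationTable(
        y=frame[response].to_numpy(dtype=float),
        X=X,
        obs_region=obs_region,
        covariate_names=names,
        active_mask=mask if cat_levels else None,
    )
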