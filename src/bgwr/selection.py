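"""Per-region covariate selection by reversible-jump moves.

Each (region, covariate) pair carries a binary inclusion indicator
``gamma_j(s)``; the linear predictor is ``x_i' (Gamma_s * beta(s))``
(elementwise product).  Indicators are a priori Bernoulli(psi_j) with
``psi_j ~ Beta(1, 1)`` shared across regions for each covariate.

The trans-dimensional move uses the coefficient prior as the birth
proposal: a birth draws a fresh ``beta_j(s) ~ N(0, sigma_beta^2)``, so the
proposal density cancels the prior and the acceptance ratio reduces to the
weighted-likelihood ratio times ``psi_j / (1 - psi_j)``; a death removes
the coefficient with the reciprocal ratio.  With the prior as proposal this
is equivalent in stationary distribution to Kuo-Mallick indicator sampling.
``psi_j`` then has a conjugate Beta full conditional.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .data import ObservationTable
from .geo import AreaMap, DistanceMatrix, KernelSpec
from .sampler import BgwrDraws, McmcSettings, PriorSpec, _Core


@dataclass
class SelectionDraws(BgwrDraws):
    """BGWR draws augmented with inclusion indicators and psi draws.

    ``gamma`` is (draw, region, covariate) in {0, 1}; excluded coefficients
    are stored as exact zeros in ``beta`` for that draw.  ``psi`` is
    (draw, covariate).
    """

    gamma: np.ndarray = None
    psi: np.ndarray = None


def _resolve_always_include(table: ObservationTable, always_include) -> np.ndarray:
    """Map covariate names/indices to a boolean always-include vector.

    Defaults to the intercept: any column named ``intercept`` or constant
    over all observations.
    """
    p = table.n_covariates
    keep = np.zeros(p, dtype=bool)
    if always_include is None:
        for j, name in enumerate(table.covariate_names):
            col = table.X[:, j]
            if name == "intercept" or np.all(col == col[0]):
                keep[j] = True
        return keep
    for item in always_include:
        if isinstance(item, str):
            if item not in table.covariate_names:
                raise ValueError(f"always_include references unknown covariate {item!r}")
            keep[table.covariate_names.index(item)] = True
        else:
            if not 0 <= int(item) < p:
                raise ValueError(f"always_include index {item} out of range")
            keep[int(item)] = True
    return keep


def run_bgwr_select(
    table: ObservationTable,
    area_map: AreaMap,
    kernel: KernelSpec,
    priors: PriorSpec,
    settings: McmcSettings,
    always_include: Optional[Sequence] = None,
    metric: str = "euclidean",
    distances: Optional[DistanceMatrix] = None,
    fixed_sigma2: Optional[float] = None,
    fixed_sigma_beta2: Optional[float] = None,
) -> SelectionDraws:
    """Fit BGWR with per-region reversible-jump covariate selection."""
    keep = _resolve_always_include(table, always_include)
    core = _Core(
        table, area_map, kernel, priors, settings,
        metric=metric, distances=distances,
        fixed_sigma2=fixed_sigma2, fixed_sigma_beta2=fixed_sigma_beta2,
    )
    S, p, n = core.S, core.p, core.n
    rng = core.rng

    gamma = core.mask.copy()  # start fully included (within the active mask)
    core.beta = core.beta * gamma
    psi = np.full(p, 0.5)
    selectable = ~keep  # covariates eligible for birth/death moves

    kept = {k: [] for k in ("beta", "sigma2", "sigma_beta2", "bandwidth", "gamma", "psi")}
    for it in range(settings.iterations):
        mask_eff = core.mask & gamma
        core.draw_beta(mask_eff)
        R = core.residuals()
        core.draw_sigma2(R)
        core.draw_sigma_beta2(mask_eff)
        core.draw_bandwidth(R)
        R = core.residuals()

        # birth/death flips, vectorized over regions for each covariate
        for j in np.flatnonzero(selectable):
            flippable = core.mask[:, j]
            if not flippable.any():
                continue
            xj = core.X[:, j]
            gj = gamma[:, j]
            births = ~gj
            # proposed coefficient: fresh prior draw for births, the current
            # value for deaths (the value being removed)
            beta_prop = np.where(
                births,
                rng.normal(0.0, np.sqrt(core.sigma_beta2), size=S),
                core.beta[:, j],
            )
            dvec = beta_prop[:, None] * xj[None, :]  # (S, n)
            sgn = np.where(births, -1.0, 1.0)
            # delta weighted SSR = sum_i w * ((R + sgn*d)^2 - R^2)
            dwrss = np.einsum(
                "sn,sn->s", core.W, 2.0 * sgn[:, None] * R * dvec + dvec**2
            )
            logit = np.log(psi[j]) - np.log1p(-psi[j])
            log_ratio = -0.5 * dwrss / core.sigma2 + np.where(births, logit, -logit)
            accept = flippable & (np.log(rng.uniform(size=S)) < log_ratio)
            if accept.any():
                R[accept] += sgn[accept, None] * dvec[accept]
                gamma[accept, j] = births[accept]
                core.beta[accept, j] = np.where(births[accept], beta_prop[accept], 0.0)

        # conjugate Beta update of the shared inclusion probabilities
        counts = gamma.sum(axis=0)
        psi = rng.beta(1.0 + counts, 1.0 + S - counts)

        if not np.all(np.isfinite(core.beta)):
            raise RuntimeError(f"divergent state at iteration {it}")
        if it >= settings.burn_in and (it - settings.burn_in) % settings.thinning == 0:
            kept["beta"].append(core.beta.copy())
            kept["sigma2"].append(core.sigma2.copy())
            kept["sigma_beta2"].append(core.sigma_beta2)
            kept["bandwidth"].append(core.b)
            kept["gamma"].append(gamma.astype(np.int8))
            kept["psi"].append(psi.copy())

    return SelectionDraws(
        beta=np.array(kept["beta"]),
        sigma2=np.array(kept["sigma2"]),
        sigma_beta2=np.array(kept["sigma_beta2"]),
        bandwidth=np.array(kept["bandwidth"]),
        acceptance_rate=core.acceptance_rate,
        region_ids=list(area_map.region_ids),
        covariate_names=list(table.covariate_names),
        settings=settings,
        priors=priors,
        kernel=kernel,
        gamma=np.array(kept["gamma"]),
        psi=np.array(kept["psi"]),
    )


def inclusion_probabilities(draws: SelectionDraws) -> np.ndarray:
    """Posterior inclusion probability per (region, covariate): mean of gamma."""
    if draws.gamma is None or len(draws.gamma) == 0:
        raise ValueError("no post-burn-in selection draws")
    return draws.gamma.mean(axis=0)


def conditional_effects(draws: SelectionDraws) -> np.ndarray:
    """Conditional posterior mean E[beta_j(s) | gamma_j(s) = 1].

    Entries never included in any retained draw are NaN (absent), not 0.
    """
    if draws.gamma is None or len(draws.gamma) == 0:
        raise ValueError("no post-burn-in selection draws")
    g = draws.gamma.astype(float)
    counts = g.sum(axis=0)
    sums = (draws.beta * g).sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        out = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
    return out


def selection_summary(draws: SelectionDraws) -> pd.DataFrame:
    """Tidy per-(region, covariate) table of inclusion and effect summaries."""
    prob = inclusion_probabilities(draws)
    cond = conditional_effects(draws)
    marg = draws.beta.mean(axis=0)  # marginal: E[gamma * beta]
    rows = []
    for i, rid in enumerate(draws.region_ids):
        for j, cov in enumerate(draws.covariate_names):
            rows.append(
                {
                    "region_id": rid,
                    "covariate": cov,
                    "inclusion_prob": prob[i, j],
                    "conditional_mean": cond[i, j],
                    "marginal_mean": marg[i, j],
                }
            )
    return pd.DataFrame(rows)
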