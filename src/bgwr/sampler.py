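"""Bayesian geographically weighted regression by Metropolis-within-Gibbs.

The model places an independent weighted Gaussian likelihood at every focal
region ``s``: observation ``i`` contributes ``N(y_i | x_i' beta(s),
sigma^2(s) / w_i(s))``, where the kernel weight ``w_i(s)`` decays with the
distance between region ``s`` and the region of observation ``i`` — nearby
observations carry more precision.  Hierarchical priors are
``beta_j(s) ~ N(0, sigma_beta^2)`` with a shared inverse-gamma prior on
``sigma_beta^2``, inverse-gamma priors on each local ``sigma^2(s)``, and a
Uniform(0, D) prior on the single shared bandwidth ``b``.

Coefficients and variances have conjugate full conditionals and are Gibbs
sampled, batched across regions; the bandwidth is updated by a reflected
random-walk Metropolis step whose target is the product of all region-wise
weighted likelihoods (a joint pseudo-posterior: each datum informs every
region's local model).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd

from .data import ObservationTable
from .geo import AreaMap, DistanceMatrix, KernelSpec, distance_matrix, floored_weights

LOG_2PI = float(np.log(2.0 * np.pi))


@dataclass
class PriorSpec:
    """Hyperparameters of the BGWR hierarchy.

    ``alpha1, alpha2``: shape/rate of the inverse-gamma prior on each local
    error variance sigma^2(s).  ``a_beta, b_beta``: shape/rate of the
    inverse-gamma prior on the shared coefficient-prior variance
    sigma_beta^2.  ``D``: upper bound of the Uniform(0, D) bandwidth prior —
    set it relative to the distance scale of the map (much larger than the
    maximum pairwise distance approximates a global, equally-weighted model).
    """

    alpha1: float = 0.01
    alpha2: float = 0.01
    a_beta: float = 0.01
    b_beta: float = 0.01
    D: float = 100.0

    def __post_init__(self) -> None:
        for name in ("alpha1", "alpha2", "a_beta", "b_beta", "D"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")


@dataclass
class McmcSettings:
    iterations: int = 5000
    burn_in: int = 1000
    thinning: int = 1
    seed: int = 0
    bandwidth_step: Optional[float] = None  # default D/20

    def __post_init__(self) -> None:
        if self.iterations <= 0 or self.burn_in < 0 or self.thinning <= 0:
            raise ValueError("iterations, thinning must be positive; burn_in nonnegative")
        if self.burn_in >= self.iterations:
            raise ValueError("burn_in must be smaller than iterations")
        if self.bandwidth_step is not None and self.bandwidth_step <= 0:
            raise ValueError("bandwidth_step must be positive")


@dataclass
class BgwrDraws:
    """Posterior draws from :func:`run_bgwr` (post burn-in, thinned).

    ``beta`` is indexed (draw, region, covariate) in the region order of the
    fitted map; masked-out covariates are identically zero.
    """

    beta: np.ndarray
    sigma2: np.ndarray
    sigma_beta2: np.ndarray
    bandwidth: np.ndarray
    acceptance_rate: float
    region_ids: list
    covariate_names: list
    settings: McmcSettings
    priors: PriorSpec
    kernel: KernelSpec

    @property
    def n_draws(self) -> int:
        return self.beta.shape[0]


def gwr_wls_estimate(X, y, weights, active=None, ridge: float = 0.0) -> np.ndarray:
    """Weighted least-squares coefficients for one focal region.

    Solves ``(X' W X) b = X' W y`` on the active covariate columns (others
    are returned as zero).  A small ``ridge`` stabilizes near-singular
    weighted normal matrices (used by the sampler initializer).
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    w = np.asarray(weights, dtype=float).ravel()
    if np.any(w < 0):
        raise ValueError("weights must be nonnegative")
    p = X.shape[1]
    act = np.arange(p) if active is None else np.flatnonzero(np.asarray(active))
    Xa = X[:, act]
    A = Xa.T @ (w[:, None] * Xa) + ridge * np.eye(len(act))
    rhs = Xa.T @ (w * y)
    try:
        sol = np.linalg.solve(A, rhs)
    except np.linalg.LinAlgError as exc:
        raise ValueError(
            "singular weighted normal matrix; consider a larger bandwidth"
        ) from exc
    if not np.all(np.isfinite(sol)):
        raise ValueError("singular weighted normal matrix; consider a larger bandwidth")
    beta = np.zeros(p)
    beta[act] = sol
    return beta


def log_likelihood_region(y, X, beta_s, sigma2_s, weights_s) -> float:
    """Weighted Gaussian log likelihood of all data under region s's model.

    ``sum_i log N(y_i | x_i' beta(s), sigma^2(s) / w_i(s))`` — equal to the
    diagonal-covariance multivariate normal log density with covariance
    ``sigma^2(s) * diag(1/w)``.
    """
    y = np.asarray(y, dtype=float).ravel()
    X = np.asarray(X, dtype=float)
    w = np.asarray(weights_s, dtype=float).ravel()
    if sigma2_s <= 0:
        raise ValueError("sigma2 must be strictly positive")
    if np.any(w <= 0):
        raise ValueError("weights must be strictly positive (floor zeros first)")
    r = y - X @ np.asarray(beta_s, dtype=float)
    n = y.shape[0]
    return float(
        -0.5 * n * (LOG_2PI + np.log(sigma2_s))
        + 0.5 * np.sum(np.log(w))
        - 0.5 * np.sum(w * r**2) / sigma2_s
    )


class _Core:
    """Shared state and update steps for the plain and selection samplers."""

    def __init__(
        self,
        table: ObservationTable,
        area_map: AreaMap,
        kernel: KernelSpec,
        priors: PriorSpec,
        settings: McmcSettings,
        metric: str = "euclidean",
        distances: Optional[DistanceMatrix] = None,
        fixed_sigma2: Optional[float] = None,
        fixed_sigma_beta2: Optional[float] = None,
    ) -> None:
        self.table = table
        self.area_map = area_map
        self.kernel = kernel
        self.priors = priors
        self.settings = settings
        self.rng = np.random.default_rng(settings.seed)

        self.X = table.X
        self.y = table.y
        self.n, self.p = self.X.shape
        self.S = area_map.n_regions
        self.ridx = table.region_index(area_map)
        self.mask = table.resolved_mask(area_map)
        dm = distances if distances is not None else distance_matrix(area_map, metric)
        self.dist = dm.values

        self.fixed_sigma2 = fixed_sigma2
        self.fixed_sigma_beta2 = fixed_sigma_beta2
        self.estimate_bandwidth = kernel.bandwidth is None
        self.D = priors.D
        self.step = settings.bandwidth_step or self.D / 20.0

        # state
        self.b = kernel.bandwidth if kernel.bandwidth is not None else self.D / 2.0
        self._set_weights(self.b)
        self.sigma2 = np.full(self.S, 1.0 if fixed_sigma2 is None else fixed_sigma2)
        self.sigma_beta2 = 1.0 if fixed_sigma_beta2 is None else fixed_sigma_beta2
        scale = float(np.trace(self.X.T @ self.X)) / self.p
        self.beta = np.stack(
            [
                gwr_wls_estimate(
                    self.X, self.y, self.W[s], active=self.mask[s], ridge=1e-8 * scale
                )
                for s in range(self.S)
            ]
        )
        self.accepted = 0
        self.proposed = 0

    # -- weights ---------------------------------------------------------
    def _weights_for(self, b: float) -> np.ndarray:
        spec = KernelSpec(self.kernel.kernel, b)
        K = floored_weights(self.dist, spec)  # (S, S) region-level
        return K[:, self.ridx]  # (S, n) per-observation

    def _set_weights(self, b: float) -> None:
        self.b = b
        self.W = self._weights_for(b)
        self.logW_sum = np.log(self.W).sum(axis=1)  # (S,)
        # sufficient statistics for the conjugate beta update
        self.XtWX = np.einsum("sn,ni,nj->sij", self.W, self.X, self.X)
        self.XtWy = self.W @ (self.X * self.y[:, None])

    # -- likelihood ------------------------------------------------------
    def residuals(self) -> np.ndarray:
        return self.y[None, :] - self.beta @ self.X.T  # (S, n)

    def joint_loglik(self, W, logW_sum, R) -> float:
        wrss = np.einsum("sn,sn->s", W, R**2)
        ll = (
            -0.5 * self.n * (LOG_2PI + np.log(self.sigma2))
            + 0.5 * logW_sum
            - 0.5 * wrss / self.sigma2
        )
        return float(ll.sum())

    # -- Gibbs updates ---------------------------------------------------
    def draw_beta(self, mask: np.ndarray) -> None:
        """Batched draw of beta(s) from its multivariate-normal full
        conditional, restricted to ``mask`` (inactive entries fixed at 0)."""
        M = mask.astype(float)
        A = self.XtWX / self.sigma2[:, None, None]
        A = A + np.eye(self.p)[None, :, :] / self.sigma_beta2
        A = A * M[:, :, None] * M[:, None, :]
        ar = np.arange(self.p)
        A[:, ar, ar] += 1.0 - M  # unit precision placeholder for inactive
        rhs = (self.XtWy / self.sigma2[:, None]) * M
        mean = np.linalg.solve(A, rhs[..., None])[..., 0]
        L = np.linalg.cholesky(A)
        z = self.rng.standard_normal((self.S, self.p))
        noise = np.linalg.solve(np.swapaxes(L, 1, 2), z[..., None])[..., 0]
        self.beta = (mean + noise) * M

    def draw_sigma2(self, R: np.ndarray) -> None:
        if self.fixed_sigma2 is not None:
            return
        wrss = np.einsum("sn,sn->s", self.W, R**2)
        shape = self.priors.alpha1 + 0.5 * self.n
        rate = self.priors.alpha2 + 0.5 * wrss
        self.sigma2 = rate / self.rng.gamma(shape, 1.0, size=self.S)

    def draw_sigma_beta2(self, mask: np.ndarray) -> None:
        if self.fixed_sigma_beta2 is not None:
            return
        n_act = int(mask.sum())
        ssq = float((self.beta[mask] ** 2).sum())
        shape = self.priors.a_beta + 0.5 * n_act
        rate = self.priors.b_beta + 0.5 * ssq
        self.sigma_beta2 = rate / self.rng.gamma(shape)

    def draw_bandwidth(self, R: np.ndarray) -> None:
        """Reflected random-walk Metropolis on the shared bandwidth."""
        if not self.estimate_bandwidth:
            return
        self.proposed += 1
        bp = self.b + self.step * self.rng.standard_normal()
        # reflect into (0, D); the reflection map is an involution, so the
        # proposal stays symmetric
        for _ in range(100):
            if bp < 0:
                bp = -bp
            elif bp > self.D:
                bp = 2.0 * self.D - bp
            else:
                break
        ll_cur = self.joint_loglik(self.W, self.logW_sum, R)
        Wp = self._weights_for(bp)
        logWp = np.log(Wp).sum(axis=1)
        ll_prop = self.joint_loglik(Wp, logWp, R)
        if not np.isfinite(ll_cur) or not np.isfinite(ll_prop):
            raise RuntimeError("non-finite log-likelihood in bandwidth step")
        # the product over focal regions reuses every datum S times; temper
        # the bandwidth target by 1/S so the data enter it once effectively,
        # otherwise the S-fold duplication drives b to a prior boundary
        if np.log(self.rng.uniform()) < (ll_prop - ll_cur) / self.S:
            self.accepted += 1
            self.b = bp
            self.W = Wp
            self.logW_sum = logWp
            self.XtWX = np.einsum("sn,ni,nj->sij", Wp, self.X, self.X)
            self.XtWy = Wp @ (self.X * self.y[:, None])

    @property
    def acceptance_rate(self) -> float:
        return self.accepted / self.proposed if self.proposed else float("nan")


def run_bgwr(
    table: ObservationTable,
    area_map: AreaMap,
    kernel: KernelSpec,
    priors: PriorSpec,
    settings: McmcSettings,
    metric: str = "euclidean",
    distances: Optional[DistanceMatrix] = None,
    fixed_sigma2: Optional[float] = None,
    fixed_sigma_beta2: Optional[float] = None,
) -> BgwrDraws:
    """Fit the BGWR model and return posterior draws.

    One sweep per iteration: batched conjugate draws of beta(s) and
    sigma^2(s), a draw of the shared sigma_beta^2, and a Metropolis update
    of the bandwidth (skipped when ``kernel.bandwidth`` is fixed).
    ``fixed_sigma2`` / ``fixed_sigma_beta2`` pin those variances, which is
    useful for conjugate calibration checks.
    """
    core = _Core(
        table, area_map, kernel, priors, settings,
        metric=metric, distances=distances,
        fixed_sigma2=fixed_sigma2, fixed_sigma_beta2=fixed_sigma_beta2,
    )
    kept_beta, kept_s2, kept_sb2, kept_b = [], [], [], []
    for it in range(settings.iterations):
        core.draw_beta(core.mask)
        R = core.residuals()
        core.draw_sigma2(R)
        core.draw_sigma_beta2(core.mask)
        core.draw_bandwidth(R)
        if not np.all(np.isfinite(core.beta)):
            raise RuntimeError(f"divergent state at iteration {it}")
        if it >= settings.burn_in and (it - settings.burn_in) % settings.thinning == 0:
            kept_beta.append(core.beta.copy())
            kept_s2.append(core.sigma2.copy())
            kept_sb2.append(core.sigma_beta2)
            kept_b.append(core.b)
    return BgwrDraws(
        beta=np.array(kept_beta),
        sigma2=np.array(kept_s2),
        sigma_beta2=np.array(kept_sb2),
        bandwidth=np.array(kept_b),
        acceptance_rate=core.acceptance_rate,
        region_ids=list(area_map.region_ids),
        covariate_names=list(table.covariate_names),
        settings=settings,
        priors=priors,
        kernel=kernel,
    )


def select_bandwidth_cv(
    table: ObservationTable,
    area_map: AreaMap,
    kernel: str,
    grid,
    metric: str = "euclidean",
    distances: Optional[DistanceMatrix] = None,
) -> tuple[float, pd.DataFrame]:
    """Leave-one-out cross-validated bandwidth on the weighted-LS surface.

    For each candidate bandwidth, every observation is predicted from its
    own region's weighted least-squares fit with that observation's weight
    zeroed, and the squared prediction errors are summed.  Returns the
    bandwidth with the smallest score plus the full score table.  This is
    the classic GWR bandwidth selector: unlike in-sample criteria it
    penalizes both over-localized fits (which interpolate) and near-global
    fits (which smooth real coefficient variation away).
    """
    from .geo import floored_weights

    dm = distances if distances is not None else distance_matrix(area_map, metric)
    ridx = table.region_index(area_map)
    mask = table.resolved_mask(area_map)
    X, y = table.X, table.y
    scale = float(np.trace(X.T @ X)) / X.shape[1]
    rows = []
    for b in grid:
        K = floored_weights(dm.values, KernelSpec(kernel, float(b)))
        W = K[:, ridx]
        sse = 0.0
        for i in range(table.n_obs):
            s = ridx[i]
            w = W[s].copy()
            w[i] = 0.0
            try:
                beta = gwr_wls_estimate(X, y, w, active=mask[s], ridge=1e-8 * scale)
            except ValueError:
                sse = np.inf
                break
            sse += (y[i] - X[i] @ beta) ** 2
        rows.append({"bandwidth": float(b), "cv_score": float(sse)})
    scores = pd.DataFrame(rows)
    best = float(scores.loc[scores["cv_score"].idxmin(), "bandwidth"])
    return best, scores


def posterior_summary(draws: BgwrDraws, level: float = 0.95) -> pd.DataFrame:
    """Per-region coefficient summaries with central credible intervals.

    Returns one row per (region, covariate) with the posterior mean, sd,
    empirical-quantile interval at ``level``, and a flag for intervals that
    exclude zero.
    """
    if not 0.0 < level < 1.0:
        raise ValueError("level must be in (0, 1)")
    if draws.n_draws == 0:
        raise ValueError("no post-burn-in draws to summarize")
    lo_q, hi_q = (1.0 - level) / 2.0, 1.0 - (1.0 - level) / 2.0
    mean = draws.beta.mean(axis=0)
    sd = draws.beta.std(axis=0, ddof=1) if draws.n_draws > 1 else np.zeros_like(mean)
    lo = np.quantile(draws.beta, lo_q, axis=0)
    hi = np.quantile(draws.beta, hi_q, axis=0)
    rows = []
    for i, rid in enumerate(draws.region_ids):
        for j, cov in enumerate(draws.covariate_names):
            rows.append(
                {
                    "region_id": rid,
                    "covariate": cov,
                    "mean": mean[i, j],
                    "sd": sd[i, j],
                    "lower": lo[i, j],
                    "upper": hi[i, j],
                    "excludes_zero": bool(lo[i, j] > 0 or hi[i, j] < 0),
                }
            )
    return pd.DataFrame(rows)
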