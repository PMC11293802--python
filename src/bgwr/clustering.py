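"""Probabilistic clustering of posterior coefficient surfaces.

A fitted BGWR model yields, at each retained MCMC iteration, an ``S x p``
matrix of local coefficients (one row per region).  Regions with similar
coefficient vectors can be grouped by a finite Gaussian mixture (EM with the
component count chosen by BIC) or by a Dirichlet-process mixture sampled in
its truncated stick-breaking representation.  Consensus partitions are
derived from assignment draws by Dahl's least-squares coassignment method or
by the per-region mode; a two-stage procedure clusters many sampled
iterations and aggregates across them.  Agreement with a reference partition
is scored by the Rand index.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment
from scipy.special import logsumexp

from .sampler import LOG_2PI, BgwrDraws

COV_FLOOR = 1e-6


# ---------------------------------------------------------------------------
# containers


@dataclass
class CoefficientSample:
    """One posterior draw's region-by-covariate coefficient matrix."""

    values: np.ndarray
    draw_index: int = 0

    def __post_init__(self) -> None:
        self.values = np.atleast_2d(np.asarray(self.values, dtype=float))
        if not np.all(np.isfinite(self.values)):
            raise ValueError("coefficient sample contains non-finite entries")
        if self.values.shape[0] < 2:
            raise ValueError("need at least two regions to cluster")


@dataclass
class GmmFit:
    K: int
    weights: np.ndarray
    means: np.ndarray
    covariances: np.ndarray
    responsibilities: np.ndarray
    log_likelihood: float
    bic: float
    log_likelihood_path: np.ndarray

    @property
    def assignment(self) -> np.ndarray:
        """Hard labels (1-based) by maximum responsibility."""
        return self.responsibilities.argmax(axis=1) + 1


@dataclass
class DpmmDraws:
    truncation: int
    z: np.ndarray          # (M, S) component indices, 0-based
    V: np.ndarray          # (M, H) stick fractions
    C: np.ndarray          # (M, H) mixture weights
    means: np.ndarray      # (M, H, p)
    variances: np.ndarray  # (M, H, p)
    alpha: np.ndarray      # (M,) concentration (constant unless resampled)
    base_params: dict


@dataclass
class ClusterConfiguration:
    """Per-region cluster labels (1..K contiguous) from a consensus method."""

    assignment: np.ndarray
    method: str
    n_clusters: int
    probabilities: Optional[pd.DataFrame] = None


@dataclass
class CoassignmentSummary:
    M: int
    mean_matrix: np.ndarray
    chosen_iteration: int


# ---------------------------------------------------------------------------
# Gaussian mixture via EM


def _mvn_logpdf(points: np.ndarray, mean: np.ndarray, cov: np.ndarray) -> np.ndarray:
    p = points.shape[1]
    cov = cov + COV_FLOOR * np.eye(p)
    L = np.linalg.cholesky(cov)
    dev = np.linalg.solve(L, (points - mean).T)
    return (
        -0.5 * p * LOG_2PI
        - np.log(np.diag(L)).sum()
        - 0.5 * (dev**2).sum(axis=0)
    )


def _em_once(points, K, rng, tol, max_iter):
    S, p = points.shape
    means = points[rng.choice(S, size=K, replace=False)].copy()
    pooled = np.cov(points.T, bias=True).reshape(p, p) + COV_FLOOR * np.eye(p)
    covs = np.repeat(pooled[None], K, axis=0)
    weights = np.full(K, 1.0 / K)
    ll_path = []
    resp = np.full((S, K), 1.0 / K)
    ll = -np.inf
    for _ in range(max_iter):
        logp = np.column_stack(
            [np.log(weights[k]) + _mvn_logpdf(points, means[k], covs[k]) for k in range(K)]
        )
        norm = logsumexp(logp, axis=1)
        new_ll = float(norm.sum())
        resp = np.exp(logp - norm[:, None])
        ll_path.append(new_ll)
        if np.isfinite(ll) and abs(new_ll - ll) < tol * max(1.0, abs(new_ll)):
            ll = new_ll
            break
        ll = new_ll
        nk = resp.sum(axis=0) + 1e-12
        weights = nk / S
        means = (resp.T @ points) / nk[:, None]
        for k in range(K):
            dev = points - means[k]
            covs[k] = (resp[:, k][:, None] * dev).T @ dev / nk[k]
            covs[k][np.diag_indices(p)] += COV_FLOOR
    return weights, means, covs, resp, ll, np.array(ll_path)


def gmm_em_fit(
    points: np.ndarray,
    K: int,
    seed: int = 0,
    tol: float = 1e-6,
    max_iter: int = 500,
    restarts: int = 10,
) -> GmmFit:
    """Fit a K-component full-covariance Gaussian mixture by EM.

    Runs ``restarts`` seeded initializations (means drawn from the data,
    pooled covariance) and keeps the run with the highest converged
    log likelihood.  Covariance diagonals are floored at 1e-6.  BIC is
    ``-2 logL + q log S`` with ``q = K - 1 + K p + K p (p + 1) / 2``.
    """
    points = np.atleast_2d(np.asarray(points, dtype=float))
    S, p = points.shape
    if K < 1 or K >= S:
        raise ValueError(f"K must satisfy 1 <= K < n_points; got K={K}, n={S}")
    if np.allclose(points, points[0]):
        if K > 1:
            warnings.warn(
                "all points identical; returning a single-component fit",
                RuntimeWarning,
            )
        K = 1
    rng = np.random.default_rng(seed)
    best = None
    for _ in range(max(1, restarts)):
        out = _em_once(points, K, rng, tol, max_iter)
        if best is None or out[4] > best[4]:
            best = out
    weights, means, covs, resp, ll, path = best
    q = (K - 1) + K * p + K * p * (p + 1) // 2
    bic = -2.0 * ll + q * np.log(S)
    return GmmFit(K, weights, means, covs, resp, ll, bic, path)


def gmm_select_K(
    points: np.ndarray,
    K_range: Iterable[int],
    seed: int = 0,
    **kwargs,
) -> GmmFit:
    """Fit over ``K_range`` and return the fit minimizing BIC (ties -> smaller K)."""
    ks = sorted(set(int(k) for k in K_range))
    if not ks:
        raise ValueError("K_range must be nonempty")
    best = None
    for k in ks:
        fit = gmm_em_fit(points, k, seed=seed, **kwargs)
        if best is None or fit.bic < best.bic:
            best = fit
    return best


# ---------------------------------------------------------------------------
# Dirichlet process mixture (truncated stick-breaking, blocked Gibbs)


def stick_breaking_weights(V: np.ndarray) -> np.ndarray:
    """Weights ``C_k = V_k prod_{j<k} (1 - V_j)`` along the last axis."""
    V = np.asarray(V, dtype=float)
    log_remain = np.cumsum(np.log1p(-V), axis=-1)
    shifted = np.concatenate(
        [np.zeros(V.shape[:-1] + (1,)), log_remain[..., :-1]], axis=-1
    )
    return V * np.exp(shifted)


def default_base_params(points: np.ndarray) -> dict:
    """Empirical Normal-Inverse-Gamma base measure (independent per dimension).

    ``sigma2_kd ~ InvGamma(a0, b0_d)`` with prior mean the pooled variance,
    ``mu_kd | sigma2_kd ~ N(m_d, sigma2_kd / kappa0)`` with a small kappa0 so
    cluster means range widely over the data scale.
    """
    pooled_var = np.maximum(points.var(axis=0), COV_FLOOR)
    return {
        "m": points.mean(axis=0),
        "kappa0": 0.01,
        "a0": 2.0,
        "b0": pooled_var,
    }


def dpmm_fit(
    points: np.ndarray,
    alpha: float = 1.0,
    base_params: Optional[dict] = None,
    truncation: int = 20,
    iterations: int = 1000,
    burn_in: int = 200,
    seed: int = 0,
    sample_alpha: bool = False,
) -> DpmmDraws:
    """Blocked Gibbs sampler for a truncated stick-breaking DPMM.

    Per sweep: assignments ``z | C, theta`` (categorical), stick fractions
    ``V_k | z ~ Beta(1 + n_k, alpha + sum_{l>k} n_l)``, and conjugate
    Normal-Inverse-Gamma updates of each component's per-dimension mean and
    variance (prior draws for empty components).  With ``sample_alpha`` the
    concentration gets a Gamma(2, 2) hyperprior and a conjugate update.
    """
    points = np.atleast_2d(np.asarray(points, dtype=float))
    S, p = points.shape
    H = int(truncation)
    if H < 2:
        raise ValueError("truncation must be at least 2")
    if alpha <= 0:
        raise ValueError("alpha must be positive")
    if burn_in >= iterations:
        raise ValueError("burn_in must be smaller than iterations")
    rng = np.random.default_rng(seed)
    base = dict(base_params) if base_params is not None else default_base_params(points)
    m, kappa0, a0 = base["m"], float(base["kappa0"]), float(base["a0"])
    b0 = np.broadcast_to(np.asarray(base["b0"], dtype=float), (p,))

    # initial state: atoms from the prior, assignments uniform
    var = b0 / rng.gamma(a0, 1.0, size=(H, p))
    mu = rng.normal(m, np.sqrt(var / kappa0))
    V = rng.beta(1.0, alpha, size=H)
    z = rng.integers(0, H, size=S)
    alpha_cur = float(alpha)
    saturated = False

    out = {k: [] for k in ("z", "V", "C", "mu", "var", "alpha")}
    for it in range(iterations):
        C = stick_breaking_weights(V)
        logp = np.log(np.maximum(C, 1e-300))[None, :] + (
            -0.5 * (LOG_2PI + np.log(var))[None, :, :]
            - 0.5 * (points[:, None, :] - mu[None, :, :]) ** 2 / var[None, :, :]
        ).sum(axis=2)
        gumbel = rng.gumbel(size=(S, H))
        z = (logp + gumbel).argmax(axis=1)

        nk = np.bincount(z, minlength=H)
        if (nk > 0).sum() == H:
            saturated = True
        tail = np.concatenate([np.cumsum(nk[::-1])[::-1][1:], [0]])
        V = rng.beta(1.0 + nk, alpha_cur + tail)

        for h in range(H):
            members = points[z == h]
            n_h = members.shape[0]
            if n_h == 0:
                var[h] = b0 / rng.gamma(a0, 1.0, size=p)
                mu[h] = rng.normal(m, np.sqrt(var[h] / kappa0))
                continue
            ybar = members.mean(axis=0)
            ssd = ((members - ybar) ** 2).sum(axis=0)
            kn = kappa0 + n_h
            mn = (kappa0 * m + n_h * ybar) / kn
            an = a0 + 0.5 * n_h
            bn = b0 + 0.5 * ssd + 0.5 * kappa0 * n_h * (ybar - m) ** 2 / kn
            var[h] = bn / rng.gamma(an, 1.0, size=p)
            mu[h] = rng.normal(mn, np.sqrt(var[h] / kn))

        if sample_alpha:
            # V_1..V_H ~ Beta(1, alpha) => conjugate Gamma update
            alpha_cur = rng.gamma(2.0 + H, 1.0 / (2.0 - np.sum(np.log1p(-V))))

        if it >= burn_in:
            out["z"].append(z.copy())
            out["V"].append(V.copy())
            out["C"].append(stick_breaking_weights(V))
            out["mu"].append(mu.copy())
            out["var"].append(var.copy())
            out["alpha"].append(alpha_cur)

    if saturated:
        warnings.warn(
            "all truncation components were occupied at some sweep; "
            "consider a larger truncation",
            RuntimeWarning,
        )
    return DpmmDraws(
        truncation=H,
        z=np.array(out["z"]),
        V=np.array(out["V"]),
        C=np.array(out["C"]),
        means=np.array(out["mu"]),
        variances=np.array(out["var"]),
        alpha=np.array(out["alpha"]),
        base_params=base,
    )


# ---------------------------------------------------------------------------
# consensus configurations


def canonical_relabel(labels: np.ndarray) -> np.ndarray:
    """Relabel to 1..K by order of first appearance (missing stays NaN)."""
    labels = np.asarray(labels)
    out = np.full(labels.shape, np.nan)
    mapping: dict = {}
    for i, lab in enumerate(labels):
        if _is_missing(lab):
            continue
        if lab not in mapping:
            mapping[lab] = len(mapping) + 1
        out[i] = mapping[lab]
    if not np.isnan(out).any():
        return out.astype(int)
    return out


def _is_missing(lab) -> bool:
    try:
        return bool(np.isnan(lab))
    except TypeError:
        return lab is None


def dahl_configuration(assignment_draws: np.ndarray):
    """Dahl's least-squares consensus over M assignment draws.

    Builds each draw's coassignment matrix ``B^(c)(i,j) = 1(z_i = z_j)``,
    the posterior mean coassignment, and returns the draw minimizing the
    squared distance to that mean (ties -> smallest draw index), canonically
    relabeled, together with the coassignment summary.
    """
    z = np.atleast_2d(np.asarray(assignment_draws))
    M, S = z.shape
    if M < 1 or S < 1:
        raise ValueError("assignment draws must be a nonempty M x S matrix")
    eq = z[:, :, None] == z[:, None, :]
    mean = eq.mean(axis=0)
    dist = ((eq - mean) ** 2).sum(axis=(1, 2))
    c = int(dist.argmin())
    assignment = canonical_relabel(z[c])
    config = ClusterConfiguration(
        assignment=assignment,
        method="dahl",
        n_clusters=int(np.max(assignment)),
    )
    return config, CoassignmentSummary(M=M, mean_matrix=mean, chosen_iteration=c)


def mode_configuration(
    assignment_draws: np.ndarray, ignore_missing: bool = True
) -> ClusterConfiguration:
    """Per-region most frequent label across draws (ties -> smallest label).

    Missing entries (NaN) are skipped when ``ignore_missing``; a region with
    only missing labels raises.  The companion ``probabilities`` frame gives
    each region's relative frequency of every label (columns relabeled
    consistently with the winning assignment).
    """
    z = np.atleast_2d(np.asarray(assignment_draws, dtype=float))
    M, S = z.shape
    if M < 1:
        raise ValueError("assignment draws must be nonempty")
    winners = np.empty(S)
    freq_rows = []
    observed = [lab for lab in np.unique(z) if not np.isnan(lab)]
    for s in range(S):
        col = z[:, s]
        valid = col[~np.isnan(col)] if ignore_missing else col
        if valid.size == 0 or np.isnan(valid).any():
            raise ValueError(f"region index {s} has no valid cluster labels")
        labs, counts = np.unique(valid, return_counts=True)
        winners[s] = labs[counts.argmax()]  # first max -> smallest label
        freq_rows.append({lab: c / len(valid) for lab, c in zip(labs, counts)})
    assignment = canonical_relabel(winners).astype(int)
    # map original labels through the winners' canonical relabeling;
    # labels that never win keep increasing labels in sorted order
    mapping: dict = {}
    for orig, new in zip(winners, assignment):
        mapping.setdefault(orig, int(new))
    for lab in sorted(observed):
        mapping.setdefault(lab, len(mapping) + 1)
    probs = pd.DataFrame(freq_rows).fillna(0.0)
    probs = probs.rename(columns=mapping)
    probs = probs[sorted(probs.columns)]
    return ClusterConfiguration(
        assignment=assignment,
        method="mode",
        n_clusters=int(assignment.max()),
        probabilities=probs,
    )


def _hungarian_align(labels: np.ndarray, reference: np.ndarray) -> np.ndarray:
    """Permute ``labels`` to maximize overlap with ``reference`` clusters."""
    la = np.unique(labels)
    lb = np.unique(reference)
    cost = np.zeros((len(la), len(lb)))
    for i, a in enumerate(la):
        for j, b in enumerate(lb):
            cost[i, j] = -np.sum((labels == a) & (reference == b))
    rows, cols = linear_sum_assignment(cost)
    mapping = {la[i]: lb[j] for i, j in zip(rows, cols)}
    spare = max(lb.max(), la.max()) + 1
    out = np.empty_like(labels)
    for i, lab in enumerate(labels):
        if lab in mapping:
            out[i] = mapping[lab]
        else:
            out[i] = spare
            spare += 1
    return out


def two_stage_configuration(
    draws: BgwrDraws,
    n_samples: int = 500,
    clusterer: str = "dpmm",
    config_method: str = "mode",
    seed: int = 0,
    covariates: Optional[Sequence] = None,
    K_range: Iterable[int] = range(1, 11),
    gmm_restarts: int = 10,
    dpmm_kwargs: Optional[dict] = None,
    align: str = "hungarian",
) -> ClusterConfiguration:
    """Two-stage consensus clustering of posterior coefficient surfaces.

    Stage 1 draws ``n_samples`` posterior iterations without replacement and
    clusters each iteration's region-by-covariate coefficient matrix — by a
    BIC-selected Gaussian mixture, or by a DPMM whose assignment draws are
    reduced with ``config_method`` (mode or Dahl).  Stage 2 aligns every sample's
    labels — by default Hungarian matching against the first sample's
    partition; ``align="canonical"`` relabels by order of first region
    appearance instead — and takes the per-region mode across samples,
    ignoring missing entries.
    """
    if clusterer not in ("gmm", "dpmm"):
        raise ValueError("clusterer must be 'gmm' or 'dpmm'")
    if config_method not in ("dahl", "mode"):
        raise ValueError("config_method must be 'dahl' or 'mode'")
    B = draws.beta
    T = B.shape[0]
    if n_samples > T:
        raise ValueError(f"n_samples={n_samples} exceeds available draws ({T})")
    if covariates is not None:
        idx = [
            draws.covariate_names.index(c) if isinstance(c, str) else int(c)
            for c in covariates
        ]
        B = B[:, :, idx]
    ss = np.random.SeedSequence(seed)
    rng = np.random.default_rng(ss.spawn(1)[0])
    chosen = rng.choice(T, size=n_samples, replace=False)
    child_seeds = [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(n_samples)]

    dkw = dict(dpmm_kwargs or {})
    partitions = np.full((n_samples, B.shape[1]), np.nan)
    for k, (t, cseed) in enumerate(zip(chosen, child_seeds)):
        pts = B[t]
        if clusterer == "gmm":
            fit = gmm_select_K(pts, K_range, seed=cseed, restarts=gmm_restarts)
            labels = fit.assignment
        else:
            dd = dpmm_fit(pts, seed=cseed, **dkw)
            if config_method == "mode":
                labels = mode_configuration(dd.z + 1).assignment
            else:
                labels = dahl_configuration(dd.z + 1)[0].assignment
        labels = canonical_relabel(labels)
        if align == "hungarian" and k > 0:
            labels = _hungarian_align(labels, partitions[0].astype(int))
        partitions[k] = labels

    final = mode_configuration(partitions, ignore_missing=True)
    return ClusterConfiguration(
        assignment=final.assignment,
        method=f"{clusterer}+{config_method}",
        n_clusters=final.n_clusters,
        probabilities=final.probabilities,
    )


# ---------------------------------------------------------------------------
# accuracy


def rand_index(C: Sequence, C_prime: Sequence) -> float:
    """Rand index: proportion of pairs on which two partitions agree.

    ``(a + b) / C(n, 2)`` where ``a`` counts pairs co-clustered in both
    partitions and ``b`` pairs separated in both.
    """
    a1 = np.asarray(C)
    a2 = np.asarray(C_prime)
    if a1.shape != a2.shape or a1.ndim != 1:
        raise ValueError("partitions must be equal-length 1-D label vectors")
    n = a1.shape[0]
    if n < 2:
        raise ValueError("need at least two items")
    if pd.isna(a1).any() or pd.isna(a2).any():
        raise ValueError("partitions must not contain missing labels")
    pair = lambda m: m * (m - 1) / 2.0
    _, inv1 = np.unique(a1, return_inverse=True)
    _, inv2 = np.unique(a2, return_inverse=True)
    contingency = np.zeros((inv1.max() + 1, inv2.max() + 1))
    np.add.at(contingency, (inv1, inv2), 1)
    a = pair(contingency).sum()
    same1 = pair(contingency.sum(axis=1)).sum()
    same2 = pair(contingency.sum(axis=0)).sum()
    total = pair(n)
    b = total - same1 - same2 + a
    return float((a + b) / total)
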