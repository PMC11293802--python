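"""Predictive information criteria (WAIC, DIC) for fitted BGWR models.

Each observation's pointwise predictive density uses its own region's local
parameters at zero distance (self-weight exactly 1):
``N(y_i | x_i' beta(s_i), sigma^2(s_i))`` — the only choice under which
every observation has a single well-defined predictive density in a model
where each datum otherwise enters every region's weighted likelihood.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .data import ObservationTable
from .geo import AreaMap
from .sampler import LOG_2PI, BgwrDraws


@dataclass
class FitAssessment:
    waic: float
    dic: float
    p_d: float
    p_waic: float
    lppd: float
    pointwise_lppd: np.ndarray
    n_draws: int

    def as_dict(self) -> dict:
        return {
            "waic": self.waic,
            "dic": self.dic,
            "p_d": self.p_d,
            "p_waic": self.p_waic,
            "n_draws": self.n_draws,
        }


def assess_fit(
    draws: BgwrDraws, table: ObservationTable, area_map: AreaMap
) -> FitAssessment:
    """WAIC and DIC from posterior draws.

    ``WAIC = -2 (lppd - p_waic)`` with ``lppd = sum_i log mean_t p_ti`` and
    ``p_waic = sum_i Var_t log p_ti``; ``DIC = D(theta_bar) + 2 p_d`` with
    ``p_d = mean deviance - deviance at the posterior means`` (equivalently
    ``DIC = mean deviance + p_d``).
    """
    T = draws.n_draws
    if T < 2:
        raise ValueError("need at least two posterior draws")
    ridx = table.region_index(area_map)
    X, y = table.X, table.y

    beta_i = draws.beta[:, ridx, :]          # (T, n, p)
    mu = np.einsum("tnp,np->tn", beta_i, X)  # (T, n)
    s2 = draws.sigma2[:, ridx]               # (T, n)
    logdens = -0.5 * (LOG_2PI + np.log(s2)) - 0.5 * (y[None, :] - mu) ** 2 / s2

    # lppd via a stable log-mean-exp over draws
    mx = logdens.max(axis=0)
    pointwise_lppd = mx + np.log(np.exp(logdens - mx).mean(axis=0))
    lppd = float(pointwise_lppd.sum())
    p_waic = float(logdens.var(axis=0, ddof=0).sum())
    waic = -2.0 * (lppd - p_waic)

    deviance = -2.0 * logdens.sum(axis=1)  # (T,)
    mean_dev = float(deviance.mean())
    beta_bar = draws.beta.mean(axis=0)[ridx]
    s2_bar = draws.sigma2.mean(axis=0)[ridx]
    mu_bar = np.einsum("np,np->n", beta_bar, X)
    dev_at_mean = float(
        -2.0
        * (
            -0.5 * (LOG_2PI + np.log(s2_bar)) - 0.5 * (y - mu_bar) ** 2 / s2_bar
        ).sum()
    )
    p_d = mean_dev - dev_at_mean
    dic = mean_dev + p_d

    return FitAssessment(
        waic=waic,
        dic=dic,
        p_d=p_d,
        p_waic=p_waic,
        lppd=lppd,
        pointwise_lppd=pointwise_lppd,
        n_draws=T,
    )
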