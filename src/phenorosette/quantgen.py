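"""Broad-sense heritability from genotype/replicate trait tables.

The model is the one-way random-effects decomposition

    y_ik = mu + G_i + e_ik,   G_i ~ N(0, sigma_G^2),  e_ik ~ N(0, sigma_E^2)

with genotype as a random factor, and broad-sense heritability

    H^2 = sigma_G^2 / (sigma_G^2 + sigma_E^2).

Two estimators are provided: a Bayesian conjugate Gibbs sampler with
weakly-informative inverse-gamma(0.001, 0.001) priors on both variances
(13000 iterations, 3000 burn-in, thinning 10 — the customary defaults of
Bayesian mixed-model software), whose point estimate is the posterior mean
of the per-sample H^2 ratio (not the ratio of posterior means — they
differ); and a method-of-moments ANOVA cross-check, sigma_G^2 =
(MS_between - MS_within) / k_bar with k_bar the mean replicate number,
truncated at zero.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = ["H2Estimate", "mcmc_h2", "anova_h2"]


@dataclass
class H2Estimate:
    """Variance components and broad-sense heritability."""

    sigma2_G: float
    sigma2_E: float
    H2: float
    ci95: Optional[tuple[float, float]]
    n_samples: int
    method: str  # "mcmc" or "anova"
    flags: list[str] = field(default_factory=list)


def _extract(
    table: pd.DataFrame, genotype_col: str, value_col: str
) -> tuple[np.ndarray, np.ndarray, int]:
    df = table[[genotype_col, value_col]].dropna()
    codes, _ = pd.factorize(df[genotype_col], sort=True)
    y = df[value_col].to_numpy(dtype=float)
    q = int(codes.max()) + 1 if len(codes) else 0
    if q < 2:
        raise ValueError("need at least 2 genotypes")
    return y, codes, q


def mcmc_h2(
    table: pd.DataFrame,
    iters: int = 13000,
    burnin: int = 3000,
    thin: int = 10,
    seed: int = 0,
    genotype_col: str = "genotype_id",
    value_col: str = "value",
) -> H2Estimate:
    """Gibbs sampler for the one-way random-effects model.

    Conjugate updates for the genotype effects, the grand mean (flat
    prior), and both variances (inverse-gamma(0.001, 0.001) priors).
    Reports the posterior mean of the per-sample heritability ratio and
    its central 95% credible interval.  Identical seeds give identical
    chains.
    """
    y, codes, q = _extract(table, genotype_col, value_col)
    n = len(y)
    rng = np.random.default_rng(seed)
    n_i = np.bincount(codes, minlength=q).astype(float)
    a0 = b0 = 0.001

    mu = float(np.mean(y))
    g = np.zeros(q)
    s2g = max(float(np.var(y)) / 2.0, 1e-8)
    s2e = max(float(np.var(y)) / 2.0, 1e-8)

    kept_h2 = []
    kept_s2g = []
    kept_s2e = []
    for it in range(iters):
        # genotype effects
        prec = n_i / s2e + 1.0 / s2g
        mean_g = np.bincount(codes, weights=y - mu, minlength=q) / s2e / prec
        g = mean_g + rng.standard_normal(q) / np.sqrt(prec)
        # grand mean (flat prior)
        resid_mu = y - g[codes]
        mu = float(
            rng.normal(np.mean(resid_mu), np.sqrt(s2e / n))
        )
        # variances (inverse-gamma conjugate updates)
        s2g = 1.0 / rng.gamma(a0 + q / 2.0, 1.0 / (b0 + 0.5 * np.sum(g**2)))
        resid = y - mu - g[codes]
        s2e = 1.0 / rng.gamma(
            a0 + n / 2.0, 1.0 / (b0 + 0.5 * np.sum(resid**2))
        )
        if it >= burnin and (it - burnin) % thin == 0:
            kept_s2g.append(s2g)
            kept_s2e.append(s2e)
            kept_h2.append(s2g / (s2g + s2e))

    h2 = np.asarray(kept_h2)
    lo, hi = np.percentile(h2, [2.5, 97.5])
    return H2Estimate(
        sigma2_G=float(np.mean(kept_s2g)),
        sigma2_E=float(np.mean(kept_s2e)),
        H2=float(np.mean(h2)),
        ci95=(float(lo), float(hi)),
        n_samples=len(kept_h2),
        method="mcmc",
    )


def anova_h2(
    table: pd.DataFrame,
    genotype_col: str = "genotype_id",
    value_col: str = "value",
) -> H2Estimate:
    """Method-of-moments heritability from the one-way ANOVA table.

    sigma_G^2 = (MS_between - MS_within) / k_bar (k_bar = mean number of
    replicates per genotype), truncated at 0 and flagged when negative.
    Intended for balanced or near-balanced designs, as a cross-check on
    the sampler.
    """
    y, codes, q = _extract(table, genotype_col, value_col)
    n = len(y)
    n_i = np.bincount(codes, minlength=q).astype(float)
    means = np.bincount(codes, weights=y, minlength=q) / n_i
    grand = float(np.mean(y))
    ss_between = float(np.sum(n_i * (means - grand) ** 2))
    ss_within = float(np.sum((y - means[codes]) ** 2))
    ms_between = ss_between / (q - 1)
    ms_within = ss_within / (n - q) if n > q else 0.0
    k_bar = n / q

    flags: list[str] = []
    s2g = (ms_between - ms_within) / k_bar
    if s2g < 0:
        flags.append("sigma2_G truncated at 0")
        s2g = 0.0
    s2e = ms_within
    total = s2g + s2e
    if total == 0:
        flags.append("zero total variance; H2 set to 0")
        h2 = 0.0
    else:
        h2 = s2g / total
    return H2Estimate(
        sigma2_G=s2g,
        sigma2_E=s2e,
        H2=float(h2),
        ci95=None,
        n_samples=0,
        method="anova",
        flags=flags,
    )
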