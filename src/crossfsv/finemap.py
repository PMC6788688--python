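"""Bayesian fine-mapping from summary statistics and LD.

The model follows the CAVIAR family: for a causal configuration c (a subset
of at most k variants), the vector of association Z-scores is multivariate
normal with mean zero and covariance S + s^2 S I_c S, where S is the LD
correlation matrix, I_c the indicator diagonal for c, and s the prior
non-centrality scale of a causal variant.  Configurations carry a Bernoulli
inclusion prior g per variant; posteriors over all configurations (null
included) give each variant's posterior inclusion probability (PIP).

eCAVIAR-style colocalization multiplies a variant's PIPs for two traits
(CLPP), measuring the probability it is causal for both.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from scipy.linalg import cho_factor, cho_solve
from scipy.special import logsumexp

__all__ = [
    "compute_ld",
    "caviar_posteriors",
    "credible_set",
    "clpp",
    "FineMapResult",
    "CLPPResult",
]


def compute_ld(genotypes, variant_idx=None, eps=1e-4):
    """Pairwise-complete Pearson LD (r) matrix of additive genotype codes.

    ``genotypes``: (n_individuals, m) 0/1/2 with -1 missing.  Monomorphic
    variants are dropped (returned in ``dropped``).  The matrix is
    regularized by adding ``eps`` to the diagonal when not PSD.
    Returns (R, kept_idx, dropped_idx).
    """
    G = np.asarray(genotypes, dtype=float)
    if G.shape[0] < 2:
        raise ValueError("need at least 2 individuals")
    if variant_idx is not None:
        G = G[:, np.asarray(variant_idx, dtype=int)]
    Gm = np.ma.masked_less(G, 0)
    sd = Gm.std(axis=0)
    kept = np.flatnonzero(sd.filled(0.0) > 0)
    dropped = np.flatnonzero(sd.filled(0.0) <= 0)
    R = np.ma.corrcoef(Gm[:, kept], rowvar=False).filled(0.0)
    np.fill_diagonal(R, 1.0)
    R = np.clip((R + R.T) / 2.0, -1.0, 1.0)
    if np.linalg.eigvalsh(R).min() < 0:
        R = R + eps * np.eye(len(R))
    return R, kept, dropped


def _mvn_logpdf(z, cov):
    """Log density of N(0, cov) at z, with escalating jitter if needed."""
    m = len(z)
    jitter = 0.0
    for _ in range(6):
        try:
            c, low = cho_factor(cov + jitter * np.eye(m), lower=True)
            break
        except np.linalg.LinAlgError:
            jitter = 1e-10 if jitter == 0 else jitter * 100
    else:
        raise np.linalg.LinAlgError("covariance not factorizable")
    logdet = 2.0 * np.sum(np.log(np.diag(c)))
    alpha = cho_solve((c, low), z)
    return -0.5 * (m * np.log(2 * np.pi) + logdet + float(z @ alpha))


@dataclass
class FineMapResult:
    """Posterior over causal configurations and per-variant PIPs."""

    pip: np.ndarray
    configs: list                      # tuples of variant indices (() = null)
    config_post: np.ndarray            # posterior per configuration, sums to 1
    positions: np.ndarray | None = None
    trait: str = ""
    k: int = 2
    gamma: float = 0.01
    sigma: float = 5.2

    @property
    def m(self) -> int:
        return len(self.pip)

    def top_variant(self) -> int:
        return int(np.argmax(self.pip))

    def to_dataframe(self) -> pd.DataFrame:
        df = pd.DataFrame({"pip": self.pip})
        if self.positions is not None:
            df.insert(0, "pos", self.positions)
        return df


def caviar_posteriors(
    zscores,
    ld,
    k: int = 2,
    gamma: float = 0.01,
    sigma: float = 5.2,
    positions=None,
    trait: str = "",
    max_configs: int = 1_000_000,
) -> FineMapResult:
    """Exhaustive posterior over causal configurations of size <= k.

    Likelihoods are accumulated in log space; the null configuration is
    included.  Priors (gamma, sigma) are CAVIAR-style defaults and
    configurable.
    """
    z = np.asarray(zscores, dtype=float)
    S = np.asarray(ld, dtype=float)
    m = len(z)
    if S.shape != (m, m):
        raise ValueError("Z-score / LD dimension mismatch")
    if k < 1:
        raise ValueError("k must be >= 1")
    if not np.all(np.isfinite(z)):
        raise ValueError("non-finite Z-score")
    from math import comb

    n_configs = sum(comb(m, j) for j in range(min(k, m) + 1))
    if n_configs > max_configs:
        raise ValueError(
            f"{n_configs} configurations exceed the enumeration cap {max_configs}"
        )

    configs, loglik, logprior = [], [], []
    s2 = sigma * sigma
    lg, l1g = np.log(gamma), np.log1p(-gamma)
    for size in range(min(k, m) + 1):
        for c in combinations(range(m), size):
            cov = S.copy()
            if c:
                idx = np.asarray(c)
                cov = cov + s2 * (S[:, idx] @ S[idx, :])
            configs.append(c)
            loglik.append(_mvn_logpdf(z, cov))
            logprior.append(size * lg + (m - size) * l1g)
    logpost = np.asarray(loglik) + np.asarray(logprior)
    logpost -= logsumexp(logpost)
    post = np.exp(logpost)
    post /= post.sum()
    pip = np.zeros(m)
    for c, w in zip(configs, post):
        for i in c:
            pip[i] += w
    return FineMapResult(
        pip=pip, configs=configs, config_post=post,
        positions=None if positions is None else np.asarray(positions),
        trait=trait, k=k, gamma=gamma, sigma=sigma,
    )


def credible_set(result: FineMapResult, rho: float = 0.99):
    """Smallest variant set whose fully-contained configuration mass >= rho.

    Variants are added greedily by PIP (ties broken by position, then
    index); after each addition the summed posterior of configurations
    entirely inside the set is checked against rho.  ``rho`` at or below 0
    is disallowed except that the top variant is always returned.
    """
    if not 0.0 <= rho < 1.0 + 1e-12:
        raise ValueError("rho must lie in [0, 1)")
    order_key = np.lexsort(
        (
            np.arange(result.m),
            result.positions if result.positions is not None else np.arange(result.m),
            -result.pip,
        )
    )
    chosen: set = set()
    members = []
    for idx in order_key:
        chosen.add(int(idx))
        members.append(int(idx))
        mass = sum(
            w for c, w in zip(result.configs, result.config_post)
            if c and set(c) <= chosen
        )
        if mass >= rho:
            break
    return members


@dataclass
class CLPPResult:
    """Colocalization posterior per variant for a trait pair."""

    clpp: np.ndarray
    pip1: np.ndarray
    pip2: np.ndarray
    threshold: float
    positions: np.ndarray | None = None

    @property
    def colocalized(self) -> np.ndarray:
        return self.clpp > self.threshold

    def top_variant(self) -> int:
        return int(np.argmax(self.clpp))


def clpp(result1: FineMapResult, result2: FineMapResult, threshold: float = 0.99) -> CLPPResult:
    """Combined likelihood posterior probability: CLPP_i = PIP1_i * PIP2_i."""
    if result1.m != result2.m:
        raise ValueError("results cover different variant sets")
    if (
        result1.positions is not None
        and result2.positions is not None
        and not np.array_equal(result1.positions, result2.positions)
    ):
        raise ValueError("variant positions differ between traits")
    return CLPPResult(
        clpp=result1.pip * result2.pip,
        pip1=result1.pip,
        pip2=result2.pip,
        threshold=threshold,
        positions=result1.positions,
    )


def mean_impute(genotypes):
    """Replace missing genotype codes by the per-variant mean (with a
    warning); fine-mapping assumes complete genotypes."""
    import warnings

    G = np.asarray(genotypes, dtype=float)
    miss = G < 0
    if miss.any():
        warnings.warn("missing genotypes mean-imputed before fine-mapping",
                      stacklevel=2)
        means = np.where(miss, np.nan, G).astype(float)
        col_mean = np.nanmean(means, axis=0)
        G = np.where(miss, col_mean[None, :], G)
    return G
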