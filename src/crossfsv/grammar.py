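"""GRAMMAR two-stage genome-wide association.

Stage 1 fits a polygenic mixed model y = Xb + u + e with u ~ N(0, A sg2)
from the pedigree relationship matrix A (REML via a single eigendecomposition
of A and a 1-D profile over the heritability ratio).  Stage 2 regresses the
stage-1 residuals on each marker's additive genotype code, which corrects
per-marker tests for familial relatedness at a fraction of the cost of an
exact mixed-model scan.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.optimize import minimize_scalar

__all__ = [
    "kinship_from_pedigree",
    "fit_polygenic",
    "grammar_scan",
    "significance_thresholds",
    "pct_var_snp",
    "genomic_inflation",
    "PolygenicFit",
    "AssocResult",
]


def kinship_from_pedigree(pedigree: pd.DataFrame):
    """Additive relationship matrix by the recursive tabular method.

    Founders (unknown parents) are taken unrelated and non-inbred.  The
    pedigree is topologically sorted internally, so parents need not precede
    offspring in the input; a cycle raises ``ValueError``.
    Returns ``(ids, A)`` with rows of A in the *input* order.
    """
    ids = pedigree["id"].astype(str).to_list()
    sires = pedigree["sire"].astype(str).to_list()
    dams = pedigree["dam"].astype(str).to_list()
    pos = {v: i for i, v in enumerate(ids)}
    if len(pos) != len(ids):
        raise ValueError("duplicate individual ids in pedigree")

    # topological order (parents first)
    order, state = [], {}

    def visit(i):
        stack = [(i, False)]
        while stack:
            node, done = stack.pop()
            if done:
                state[node] = 2
                order.append(node)
                continue
            if state.get(node) == 2:
                continue
            if state.get(node) == 1:
                raise ValueError("pedigree contains a cycle")
            state[node] = 1
            stack.append((node, True))
            for p in (sires[node], dams[node]):
                if p in pos and state.get(pos[p]) != 2:
                    stack.append((pos[p], False))

    for i in range(len(ids)):
        if state.get(i) != 2:
            visit(i)

    n = len(ids)
    A = np.zeros((n, n))
    for k, node in enumerate(order):
        s = pos.get(sires[node], -1)
        d = pos.get(dams[node], -1)
        if k:
            pj = np.array(order[:k])
            contrib = np.zeros(len(pj))
            if s >= 0:
                contrib += A[pj, s]
            if d >= 0:
                contrib += A[pj, d]
            A[node, pj] = A[pj, node] = 0.5 * contrib
        A[node, node] = 1.0 + (0.5 * A[s, d] if s >= 0 and d >= 0 else 0.0)
    return ids, A


@dataclass
class PolygenicFit:
    """REML variance components and GRAMMAR residuals."""

    sigma_g2: float
    sigma_e2: float
    h2: float
    loglik: float
    beta: np.ndarray
    blup: np.ndarray        # BLUP of the polygenic effect per individual
    residuals: np.ndarray   # y - X beta - blup


def _reml_neg_loglik(h2, d, ystar, Xstar):
    n, p = Xstar.shape
    w = h2 * d + (1.0 - h2)
    Xw = Xstar / w[:, None]
    XtWX = Xstar.T @ Xw
    beta = np.linalg.solve(XtWX, Xw.T @ ystar)
    r = ystar - Xstar @ beta
    rss_w = float(r @ (r / w))
    sigma_p2 = rss_w / (n - p)
    sign, logdet = np.linalg.slogdet(XtWX)
    ll = -0.5 * (
        (n - p) * (np.log(2 * np.pi * sigma_p2) + 1.0)
        + np.sum(np.log(w))
        + logdet
    )
    return -ll, beta, sigma_p2, r, w


def fit_polygenic(y, X, A, tol=1e-6) -> PolygenicFit:
    """REML fit of the polygenic model via eigendecomposition of A.

    The profile REML log-likelihood is optimized over h2 = sg2/(sg2+se2) on
    a coarse grid refined by bounded scalar minimization (deterministic).
    """
    y = np.asarray(y, dtype=float)
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[0] != len(y):
        X = X.T
    n, p = X.shape
    if np.linalg.matrix_rank(X) < p:
        raise ValueError("fixed-effect design matrix is singular")
    A = np.asarray(A, dtype=float)
    d, U = np.linalg.eigh(A)
    if d.min() < -1e-6:
        raise ValueError("relationship matrix is not positive semi-definite")
    d = np.clip(d, 0.0, None)
    ystar = U.T @ y
    Xstar = U.T @ X

    grid = np.linspace(0.0, 0.99, 34)
    vals = [_reml_neg_loglik(h, d, ystar, Xstar)[0] for h in grid]
    i0 = int(np.argmin(vals))
    lo = grid[max(i0 - 1, 0)]
    hi = min(grid[min(i0 + 1, len(grid) - 1)], 1.0 - 1e-9)
    res = minimize_scalar(
        lambda h: _reml_neg_loglik(h, d, ystar, Xstar)[0],
        bounds=(lo, hi), method="bounded", options={"xatol": tol},
    )
    # keep the grid solution at numerical ties (flat profiles, e.g. A = I)
    h2 = float(res.x) if res.fun < vals[i0] - 1e-9 else float(grid[i0])

    nll, beta, sigma_p2, rstar, w = _reml_neg_loglik(h2, d, ystar, Xstar)
    ustar = h2 * d * (rstar / w)
    blup = U @ ustar
    residuals = y - X @ beta - blup
    return PolygenicFit(
        sigma_g2=h2 * sigma_p2,
        sigma_e2=(1.0 - h2) * sigma_p2,
        h2=h2,
        loglik=-nll,
        beta=beta,
        blup=blup,
        residuals=residuals,
    )


@dataclass
class AssocResult:
    """Per-marker association summary from the GRAMMAR scan."""

    effect: np.ndarray      # slope per copy of the minor allele
    se: np.ndarray
    p: np.ndarray
    maf: np.ndarray
    n_used: np.ndarray
    monomorphic: np.ndarray
    thresholds: dict = field(default_factory=dict)
    lambda_gc: float = np.nan
    marker_names: np.ndarray | None = None

    def zscores(self) -> np.ndarray:
        with np.errstate(invalid="ignore", divide="ignore"):
            z = np.where(self.se > 0, self.effect / self.se, 0.0)
        return z

    def pct_var(self, sigma_g2: float) -> np.ndarray:
        return pct_var_snp(self.maf, self.effect, sigma_g2)

    def to_dataframe(self) -> pd.DataFrame:
        df = pd.DataFrame(
            {
                "effect": self.effect,
                "se": self.se,
                "p": self.p,
                "maf": self.maf,
                "n": self.n_used,
                "monomorphic": self.monomorphic,
            }
        )
        if self.marker_names is not None:
            df.insert(0, "name", self.marker_names)
        return df


def grammar_scan(residuals, genotypes, marker_names=None) -> AssocResult:
    """Regress GRAMMAR residuals on each marker's additive code.

    Genotypes are 0/1/2 counts with -1 missing; markers are recoded to count
    the minor allele, missing entries are dropped per marker, and
    monomorphic markers are flagged (effect 0, p = 1).
    """
    r = np.asarray(residuals, dtype=float)
    G = np.asarray(genotypes, dtype=float)
    if G.shape[0] != len(r):
        raise ValueError("residuals and genotypes are not aligned")
    M = G >= 0
    Gm = np.where(M, G, 0.0)
    nj = M.sum(axis=0).astype(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        freq = Gm.sum(axis=0) / (2 * nj)
    flip = freq > 0.5
    Gm = np.where(M, np.where(flip[None, :], 2.0 - G, G), 0.0)
    maf = np.minimum(freq, 1.0 - freq)

    Sr = (r[:, None] * M).sum(axis=0)
    Sg = Gm.sum(axis=0)
    Sgg = (Gm * Gm).sum(axis=0)
    Sgr = (Gm * r[:, None]).sum(axis=0)
    Srr = ((r * r)[:, None] * M).sum(axis=0)

    with np.errstate(invalid="ignore", divide="ignore"):
        sxx = Sgg - Sg * Sg / nj
        sxy = Sgr - Sg * Sr / nj
        syy = Srr - Sr * Sr / nj
        mono = (sxx <= 1e-12) | (nj < 3)
        slope = np.where(mono, 0.0, sxy / np.where(sxx > 0, sxx, 1.0))
        rss = np.maximum(syy - slope * sxy, 0.0)
        dfree = np.maximum(nj - 2, 1)
        se = np.where(mono, np.nan, np.sqrt(rss / dfree / np.where(sxx > 0, sxx, 1.0)))
        tstat = np.where(mono | (se == 0), 0.0, slope / np.where(se > 0, se, 1.0))
    p = np.where(mono, 1.0, 2.0 * stats.t.sf(np.abs(tstat), dfree))
    p = np.clip(p, np.finfo(float).tiny, 1.0)
    return AssocResult(
        effect=slope, se=se, p=p, maf=maf, n_used=nj.astype(int),
        monomorphic=mono,
        marker_names=None if marker_names is None else np.asarray(marker_names),
    )


def significance_thresholds(n_markers: int, alpha: float = 0.05) -> dict:
    """Bonferroni-adjusted significant and suggestive genome-wide thresholds."""
    if n_markers < 1:
        raise ValueError("n_markers must be >= 1")
    bonferroni = alpha / n_markers
    return {
        "bonferroni_p": bonferroni,
        "suggestive_p": 1.0 / n_markers,
        "threshold_minus_log10": -np.log10(bonferroni),
    }


def pct_var_snp(p, a, sigma_g2):
    """Percent of additive genetic variance explained by a SNP:
    100 * 2 p (1-p) a^2 / sigma_g2 with p the minor allele frequency."""
    if np.any(np.asarray(sigma_g2) <= 0):
        raise ValueError("sigma_g2 must be > 0")
    p = np.asarray(p, dtype=float)
    a = np.asarray(a, dtype=float)
    out = 100.0 * 2.0 * p * (1.0 - p) * a * a / sigma_g2
    return float(out) if out.ndim == 0 else out


_CHI2_NULL_MEDIAN = stats.chi2.ppf(0.5, df=1)   # 0.4549364...


def genomic_inflation(p_values) -> float:
    """Genomic inflation factor: median association chi2 over its null median."""
    p = np.asarray(p_values, dtype=float)
    p = p[np.isfinite(p)]
    if p.size == 0:
        raise ValueError("empty p-value vector")
    chi2 = stats.chi2.isf(p, df=1)
    return float(np.median(chi2) / _CHI2_NULL_MEDIAN)


def bonferroni_adjusted(p, n_markers):
    """p * n_markers capped at 1 (reported alongside raw p-values)."""
    return np.minimum(np.asarray(p, dtype=float) * n_markers, 1.0)


def marker_effect_gls(y, X, g, A, sigma_g2, sigma_e2):
    """GLS (single-marker mixed model) allele effect at one marker.

    The GRAMMAR residual regression is known to attenuate effect sizes;
    for reporting the variance explained by a top marker this unshrunken
    estimate is preferable.  Fits y = X b + g a + u + e with the variance
    components held at the polygenic REML estimates.  Returns (effect, se).
    """
    y = np.asarray(y, dtype=float)
    g = np.asarray(g, dtype=float)
    M = np.column_stack([np.atleast_2d(X) if np.atleast_2d(X).shape[0] == len(y)
                         else np.atleast_2d(X).T, g])
    V = sigma_g2 * np.asarray(A, dtype=float) + sigma_e2 * np.eye(len(y))
    L = np.linalg.cholesky(V + 1e-10 * np.eye(len(y)))
    from scipy.linalg import solve_triangular

    Mw = solve_triangular(L, M, lower=True)
    yw = solve_triangular(L, y, lower=True)
    XtX = Mw.T @ Mw
    beta = np.linalg.solve(XtX, Mw.T @ yw)
    cov = np.linalg.inv(XtX)
    resid = yw - Mw @ beta
    s2 = float(resid @ resid) / (len(y) - M.shape[1])
    return float(beta[-1]), float(np.sqrt(s2 * cov[-1, -1]))
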