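"""Haley-Knott regression interval mapping for F2 line crosses.

Line-origin probabilities at arbitrary positions are computed per F2
haplotype by two-marker flanking conditioning: evidence at the nearest
informative marker on each side (breed allele-frequency likelihoods) is
combined through Kosambi transition probabilities.  This is an approximation
to full multipoint computation that is adequate at chip marker density.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .containers import GeneticMap
from .simcross import BREED_B, CrossData, kosambi_recombination

__all__ = [
    "line_cross_probabilities",
    "line_cross_scan",
    "pct_var_qtl",
    "permutation_thresholds",
    "halfsib_family_scan",
    "FProfile",
    "covariate_matrix",
]


def covariate_matrix(cross: CrossData, covariates=("sex", "batch", "carcass_weight")):
    """Fixed-effect design columns (without intercept) for the F2 cohort."""
    ped = cross.pedigree.loc[cross.f2_mask]
    cols = []
    for c in covariates:
        if c == "sex":
            cols.append((ped["sex"] == "M").to_numpy(float)[:, None])
        elif c == "batch":
            b = ped["batch"].to_numpy()
            levels = np.unique(b)
            cols.append((b[:, None] == levels[1:][None, :]).astype(float))
        elif c == "carcass_weight":
            cw = ped["carcass_weight"].to_numpy(float)
            cols.append((cw - np.nanmean(cw))[:, None])
        else:
            raise KeyError(f"unknown covariate {c!r}")
    if not cols:
        return np.empty((len(ped), 0))
    X = np.hstack(cols)
    if np.linalg.matrix_rank(np.column_stack([np.ones(len(X)), X])) < X.shape[1] + 1:
        raise ValueError("collinear covariates")
    return X


def _trait_vector(cross: CrossData, trait: str) -> np.ndarray:
    if cross.phenotypes is None or trait not in cross.phenotypes:
        raise KeyError(f"trait {trait!r} not present")
    tab = cross.phenotypes.set_index("id").loc[cross.f2_ids]
    return tab[trait].to_numpy(float)


def _state_probability(w, cm_inf, query_cm):
    """P(state 1) at ``query_cm`` for each row, from per-marker evidence.

    ``w``: (n, J, 2) likelihood of the observation at informative marker j
    under state 0/1; ``cm_inf``: (J,) marker positions.  Conditioning uses
    the marker at the query position (if any) plus the nearest informative
    flank on each side; the prior is 1/2.
    """
    n, J, _ = w.shape
    if J == 0:
        return np.full(n, 0.5)
    post = np.ones((n, 2)) * 0.5
    at = np.flatnonzero(np.isclose(cm_inf, query_cm))
    if at.size:
        post = post * w[:, at[0], :]
    left = np.searchsorted(cm_inf, query_cm - 1e-9) - 1
    right = np.searchsorted(cm_inf, query_cm + 1e-9)
    if at.size:
        if left == at[0]:
            left -= 1
        if right == at[0]:
            right += 1
    for j, side in ((left, "L"), (right, "R")):
        if j < 0 or j >= J:
            continue
        r = kosambi_recombination(abs(query_cm - cm_inf[j]))
        T = np.array([[1 - r, r], [r, 1 - r]])
        # sum over the flank state with its evidence; prior folds into both
        msg = w[:, j, :] @ T     # (n, 2): message passed to the query state
        post = post * msg
    tot = post.sum(axis=1, keepdims=True)
    bad = tot[:, 0] <= 0
    post[bad] = 0.5
    tot[bad] = 1.0
    return post[:, 1] / tot[:, 0]


def _breed_evidence(cross: CrossData, chrom):
    """Evidence arrays for paternal/maternal F2 haplotype breed origin.

    Returns (w_pat, w_mat, cm_inf): (n_f2, J, 2) likelihoods of the observed
    haplotype allele under origin breed A (state 0) / breed B (state 1) at
    each informative marker of ``chrom``.
    """
    sl = cross.gmap.chrom_slice(chrom)
    # simulator truth frequencies when available, else founder sample freqs
    freqs = cross.truth.get("breed_freqs")
    freqs = (np.asarray(freqs) if freqs is not None
             else cross.founder_breed_freqs())[:, sl]   # (2, m) allele-1 freq
    informative = np.abs(freqs[0] - freqs[1]) > 1e-9
    cm_inf = cross.gmap.cm[sl][informative]
    f2 = np.flatnonzero(cross.f2_mask)
    out = []
    for hap in (0, 1):
        alleles = cross.haplotypes[f2, hap, sl][:, informative].astype(float)
        w = np.empty((len(f2), informative.sum(), 2))
        for state in (0, 1):
            f = freqs[state][informative]
            w[:, :, state] = alleles * f + (1 - alleles) * (1 - f)
        dead = w.sum(axis=2) <= 0       # allele absent from both breeds' founders
        w[dead] = 0.5
        out.append(w)
    return out[0], out[1], cm_inf


def line_cross_probabilities(cross: CrossData, chrom, pos_cm):
    """Per-F2 probabilities (p_QQ, p_Qq, p_qq) at one position.

    Assumes the line-cross model: a haplotype of breed-B origin carries Q.
    """
    sl = cross.gmap.chrom_slice(chrom)
    if not (cross.gmap.cm[sl].min() - 1e-9 <= pos_cm <= cross.gmap.cm[sl].max() + 1e-9):
        raise ValueError("position outside the chromosome map")
    w_pat, w_mat, cm_inf = _breed_evidence(cross, chrom)
    pb_pat = _state_probability(w_pat, cm_inf, pos_cm)
    pb_mat = _state_probability(w_mat, cm_inf, pos_cm)
    p_qq_cap = pb_pat * pb_mat
    p_qq_low = (1 - pb_pat) * (1 - pb_mat)
    p_het = 1.0 - p_qq_cap - p_qq_low
    return np.column_stack([p_qq_cap, p_het, p_qq_low])


@dataclass
class FProfile:
    """Position-wise F statistics from a Haley-Knott scan."""

    chrom: np.ndarray
    cm: np.ndarray
    bp: np.ndarray
    F: np.ndarray
    p: np.ndarray
    rss_full: np.ndarray
    rss_reduced: np.ndarray
    add_effect: np.ndarray     # fitted additive coefficient a per position
    dom_effect: np.ndarray
    df1: int
    df2: int

    @property
    def peak_add_effect(self) -> float:
        """Allele substitution effect estimate at the profile maximum."""
        return float(self.add_effect[self.argmax])

    @property
    def argmax(self) -> int:
        return int(np.argmax(self.F))

    @property
    def max_F(self) -> float:
        return float(self.F[self.argmax])

    @property
    def peak_cm(self) -> float:
        return float(self.cm[self.argmax])

    @property
    def peak_bp(self) -> int:
        return int(self.bp[self.argmax])

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "chrom": self.chrom, "cm": self.cm, "bp": self.bp,
                "F": self.F, "p": self.p,
                "rss_full": self.rss_full, "rss_reduced": self.rss_reduced,
            }
        )


def _scan_positions(gmap: GeneticMap, chrom, step_cm):
    sl = gmap.chrom_slice(chrom)
    lo, hi = gmap.cm[sl].min(), gmap.cm[sl].max()
    pos = np.arange(lo, hi + 1e-9, step_cm)
    if pos[-1] < hi - 1e-9:
        pos = np.append(pos, hi)
    return pos


def _f_test(y, X_red, X_full):
    from scipy import stats

    n = len(y)
    q = X_full.shape[1] - X_red.shape[1]
    rss_red = _rss(y, X_red)
    rss_full = _rss(y, X_full)
    df2 = n - np.linalg.matrix_rank(X_full)
    degenerate = rss_full <= 1e-10 * max(1.0, float(y @ y))
    if degenerate or df2 <= 0:
        return 0.0, 1.0, rss_full, rss_red, q, max(df2, 1)
    F = max((rss_red - rss_full) / q / (rss_full / df2), 0.0)
    p = float(stats.f.sf(F, q, df2))
    return F, p, rss_full, rss_red, q, df2


def _rss(y, X):
    beta, res, rank, _ = np.linalg.lstsq(X, y, rcond=None)
    r = y - X @ beta
    return float(r @ r)


def line_cross_scan(
    cross: CrossData,
    trait: str,
    covariates=("sex", "batch", "carcass_weight"),
    step_cm: float = 1.0,
    chrom=None,
) -> FProfile:
    """F2 line-cross Haley-Knott scan of one trait.

    At each position the trait is regressed on covariates plus an additive
    coefficient (p_QQ - p_qq) and a dominance coefficient p_Qq; F compares
    this against the covariates-only model.
    """
    y = _trait_vector(cross, trait)
    C = covariate_matrix(cross, covariates)
    ones = np.ones((len(y), 1))
    X_red = np.hstack([ones, C])
    chroms = [chrom] if chrom is not None else cross.gmap.chromosomes
    rows = []
    for c in chroms:
        w_pat, w_mat, cm_inf = _breed_evidence(cross, c)
        sl = cross.gmap.chrom_slice(c)
        for pos in _scan_positions(cross.gmap, c, step_cm):
            pb_pat = _state_probability(w_pat, cm_inf, pos)
            pb_mat = _state_probability(w_mat, cm_inf, pos)
            x_add = pb_pat + pb_mat - 1.0           # p_QQ - p_qq
            x_dom = 1.0 - pb_pat * pb_mat - (1 - pb_pat) * (1 - pb_mat)
            X_full = np.hstack([X_red, x_add[:, None], x_dom[:, None]])
            F, p, rf, rr, q, df2 = _f_test(y, X_red, X_full)
            beta, *_ = np.linalg.lstsq(X_full, y, rcond=None)
            rows.append(
                (c, pos, cross.gmap.cm_to_bp(c, pos), F, p, rf, rr, beta[-2], beta[-1])
            )
    arr = list(zip(*rows))
    return FProfile(
        chrom=np.asarray(arr[0], dtype=object),
        cm=np.asarray(arr[1], dtype=float),
        bp=np.asarray(arr[2], dtype=np.int64),
        F=np.asarray(arr[3], dtype=float),
        p=np.asarray(arr[4], dtype=float),
        rss_full=np.asarray(arr[5], dtype=float),
        rss_reduced=np.asarray(arr[6], dtype=float),
        add_effect=np.asarray(arr[7], dtype=float),
        dom_effect=np.asarray(arr[8], dtype=float),
        df1=2,
        df2=len(y) - X_red.shape[1] - 2,
    )


def pct_var_qtl(rss_reduced: float, rss_full: float) -> float:
    """Percent phenotypic variance explained by the fitted QTL:
    100 (RSS_reduced - RSS_full) / RSS_reduced."""
    if rss_reduced <= 0 or rss_full <= 0:
        raise ValueError("residual sums of squares must be > 0")
    if rss_full > rss_reduced * (1 + 1e-12):
        raise ValueError("rss_full must not exceed rss_reduced")
    return 100.0 * (rss_reduced - rss_full) / rss_reduced


@dataclass
class PermutationThresholds:
    thresholds: dict
    max_stats: np.ndarray
    n_perm: int


def permutation_thresholds(
    cross: CrossData,
    trait: str,
    scan_spec: dict | None = None,
    n_perm: int = 1000,
    alphas=(0.05, 0.01),
    seed: int = 0,
) -> PermutationThresholds:
    """Empirical genome/chromosome-wide F thresholds.

    Covariate-adjusted residuals of the trait are shuffled across the F2
    (family sizes preserved by construction), the scan is re-run for each
    shuffle, and the requested upper quantiles of the per-shuffle maximum F
    are returned.  Deterministic for a given seed.
    """
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100")
    spec = {"covariates": ("sex", "batch", "carcass_weight"),
            "step_cm": 1.0, "chrom": None}
    spec.update(scan_spec or {})
    for a in alphas:
        if n_perm * a < 5:
            warnings.warn(f"n_perm={n_perm} is small for alpha={a}", stacklevel=2)

    y = _trait_vector(cross, trait)
    C = covariate_matrix(cross, spec["covariates"])
    ones = np.ones((len(y), 1))
    X_red = np.hstack([ones, C])
    Q_red, _ = np.linalg.qr(X_red)
    y_adj = y - Q_red @ (Q_red.T @ y)

    chroms = [spec["chrom"]] if spec["chrom"] is not None else cross.gmap.chromosomes
    Q_fulls = []
    for c in chroms:
        w_pat, w_mat, cm_inf = _breed_evidence(cross, c)
        for pos in _scan_positions(cross.gmap, c, spec["step_cm"]):
            pb_pat = _state_probability(w_pat, cm_inf, pos)
            pb_mat = _state_probability(w_mat, cm_inf, pos)
            x_add = pb_pat + pb_mat - 1.0
            x_dom = 1.0 - pb_pat * pb_mat - (1 - pb_pat) * (1 - pb_mat)
            X_full = np.hstack([X_red, x_add[:, None], x_dom[:, None]])
            Qf, _ = np.linalg.qr(X_full)
            Q_fulls.append((Qf, np.linalg.matrix_rank(X_full)))

    rng = np.random.default_rng(seed)
    n = len(y)
    Y = np.empty((n, n_perm))
    for k in range(n_perm):
        Y[:, k] = y_adj[rng.permutation(n)]
    tot = (Y * Y).sum(axis=0)
    rss_red = tot - ((Q_red.T @ Y) ** 2).sum(axis=0)
    max_F = np.full(n_perm, -np.inf)
    for Qf, rank in Q_fulls:
        rss_full = tot - ((Qf.T @ Y) ** 2).sum(axis=0)
        df2 = n - rank
        with np.errstate(invalid="ignore", divide="ignore"):
            F = np.where(rss_full > 0, (rss_red - rss_full) / 2.0 / (rss_full / df2), 0.0)
        max_F = np.maximum(max_F, F)
    thresholds = {a: float(np.quantile(max_F, 1.0 - a)) for a in alphas}
    return PermutationThresholds(thresholds=thresholds, max_stats=max_F, n_perm=n_perm)


def paternal_transmission(cross: CrossData, sire_id, chrom, positions_cm):
    """P(offspring inherited the sire's first haplotype) at each position.

    Evidence comes from markers where the sire is heterozygous; the
    offspring's paternal haplotype allele then identifies the transmitted
    sire haplotype up to recombination.  Returns (off_rows, (n_off, P) array)
    or flags the sire uninformative when it is homozygous throughout.
    """
    off = cross.offspring_of_sire(sire_id)
    if off.size == 0:
        raise ValueError(f"sire {sire_id} has no F2 offspring")
    s = cross.row(sire_id)
    sl = cross.gmap.chrom_slice(chrom)
    sire_h = cross.haplotypes[s, :, sl.start:sl.stop]         # (2, m)
    informative = sire_h[0] != sire_h[1]
    cm_inf = cross.gmap.cm[sl][informative]
    if cm_inf.size == 0:
        return off, None
    pat = cross.haplotypes[off, 0, sl.start:sl.stop][:, informative]
    w = np.empty((off.size, int(informative.sum()), 2))
    for state in (0, 1):
        w[:, :, state] = (pat == sire_h[state][informative]).astype(float)
    probs = np.column_stack(
        [1.0 - _state_probability(w, cm_inf, pos) for pos in np.atleast_1d(positions_cm)]
    )
    return off, probs


@dataclass
class HalfsibProfile:
    sire_id: str
    chrom: object
    cm: np.ndarray
    bp: np.ndarray
    neglog10p: np.ndarray
    slope: np.ndarray
    n_offspring: int
    uninformative: bool = False

    @property
    def max_neglog10p(self) -> float:
        return float(self.neglog10p.max()) if len(self.neglog10p) else 0.0

    @property
    def peak_cm(self) -> float:
        return float(self.cm[int(np.argmax(self.neglog10p))])


def halfsib_family_scan(
    cross: CrossData,
    sire_id,
    trait: str,
    step_cm: float = 1.0,
    chrom=None,
    min_offspring: int = 10,
) -> HalfsibProfile:
    """Within-family scan for QTL segregation in one F1 sire.

    The trait is regressed on the paternal transmission probability among
    the sire's F2 half-sib family; the profile holds -log10 p of the slope.
    """
    from scipy import stats

    if chrom is None:
        chrom = cross.gmap.chromosomes[0]
    off = cross.offspring_of_sire(sire_id)
    if off.size < min_offspring:
        raise ValueError(
            f"sire {sire_id} has {off.size} offspring (< {min_offspring})"
        )
    positions = _scan_positions(cross.gmap, chrom, step_cm)
    off, probs = paternal_transmission(cross, sire_id, chrom, positions)
    y_all = _trait_vector(cross, trait)
    f2_rows = np.flatnonzero(cross.f2_mask)
    y = y_all[np.searchsorted(f2_rows, off)]
    if probs is None:
        return HalfsibProfile(
            sire_id=str(sire_id), chrom=chrom, cm=positions,
            bp=np.array([cross.gmap.cm_to_bp(chrom, p) for p in positions]),
            neglog10p=np.zeros(len(positions)), slope=np.zeros(len(positions)),
            n_offspring=off.size, uninformative=True,
        )
    nl10p = np.zeros(len(positions))
    slopes = np.zeros(len(positions))
    n = len(y)
    for j in range(len(positions)):
        x = probs[:, j]
        sxx = float(((x - x.mean()) ** 2).sum())
        if sxx < 1e-12:
            continue
        b = float(((x - x.mean()) * (y - y.mean())).sum() / sxx)
        r = y - y.mean() - b * (x - x.mean())
        s2 = float(r @ r) / max(n - 2, 1)
        se = np.sqrt(s2 / sxx)
        t = b / se if se > 0 else 0.0
        p = 2.0 * stats.t.sf(abs(t), max(n - 2, 1))
        nl10p[j] = -np.log10(max(p, np.finfo(float).tiny))
        slopes[j] = b
    return HalfsibProfile(
        sire_id=str(sire_id), chrom=chrom, cm=positions,
        bp=np.array([cross.gmap.cm_to_bp(chrom, p) for p in positions]),
        neglog10p=nl10p, slope=slopes, n_offspring=off.size,
    )
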