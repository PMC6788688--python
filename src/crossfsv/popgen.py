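"""Population diversity diagnostics with missing data.

Nucleotide diversity uses the per-site unbiased estimator
pi = sum_i [n_i/(n_i - 1)] 2 p_i (1 - p_i) / L with n_i the number of
called alleles at site i; with complete data this equals the classic
average pairwise difference per base.  Tajima's D uses the standard
constants evaluated at an effective sample size n* = rounded mean of the
per-site called allele counts (a light-weight missing-data adjustment).
Indels are expected to be excluded upstream; sites here are SNPs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "PopulationSample",
    "DiversityStats",
    "allele_frequency_table",
    "nucleotide_diversity",
    "tajimas_d",
    "diversity_stats",
]


@dataclass
class PopulationSample:
    """Haplotype calls of one population over a region.

    ``alleles``: (n_sequences, n_sites) int8 in {0, 1}, -1 for missing;
    ``l_callable``: callable region length in bp (includes invariant
    sites, which do not appear in ``alleles``).
    """

    label: str
    alleles: np.ndarray
    positions: np.ndarray | None = None
    l_callable: int = 0

    def __post_init__(self):
        self.alleles = np.asarray(self.alleles, dtype=np.int8)
        if self.alleles.ndim != 2:
            raise ValueError("alleles must be (n_sequences, n_sites)")
        if self.positions is not None:
            self.positions = np.asarray(self.positions, dtype=np.int64)
            if len(self.positions) != self.alleles.shape[1]:
                raise ValueError("positions/site mismatch")

    @property
    def n_sequences(self) -> int:
        return self.alleles.shape[0]

    def called_counts(self) -> np.ndarray:
        """Number of non-missing alleles per site."""
        return (self.alleles >= 0).sum(axis=0)

    def derived_counts(self) -> np.ndarray:
        return ((self.alleles == 1).sum(axis=0)).astype(np.int64)


@dataclass
class DiversityStats:
    label: str
    pi: float                 # per-bp nucleotide diversity
    S: int                    # segregating sites
    tajimas_d: float | None   # None when S == 0
    n_effective: int
    l_callable: int


def allele_frequency_table(samples_by_pop: dict, allele: int = 1, site: int = 0) -> pd.DataFrame:
    """Per-population frequency of one allele at a focal site.

    ``samples_by_pop`` maps a population label to a genotype/haplotype
    allele array ((n, 2) or (n_sequences,) values in {0,1,-1}).  Missing
    alleles are excluded from the denominator; a population with zero calls
    is flagged with frequency NaN.
    """
    rows = []
    for pop, calls in samples_by_pop.items():
        a = np.asarray(calls).ravel()
        called = a >= 0
        n_called = int(called.sum())
        freq = float((a[called] == allele).sum() / n_called) if n_called else np.nan
        rows.append({"population": pop, "frequency": freq,
                     "n_alleles_called": n_called, "defined": n_called > 0})
    return pd.DataFrame(rows)


def _site_terms(sample: PopulationSample):
    n_i = sample.called_counts().astype(float)
    d_i = sample.derived_counts().astype(float)
    usable = n_i >= 2
    with np.errstate(invalid="ignore", divide="ignore"):
        p = np.where(usable, d_i / np.where(n_i > 0, n_i, 1.0), 0.0)
        terms = np.where(usable, n_i / (n_i - 1.0) * 2.0 * p * (1.0 - p), 0.0)
    seg = usable & (d_i > 0) & (d_i < n_i)
    return terms, seg, n_i, usable


def nucleotide_diversity(sample: PopulationSample) -> float:
    """Per-bp nucleotide diversity; sites with fewer than 2 called alleles
    are skipped."""
    if sample.l_callable <= 0:
        raise ValueError("callable length must be > 0")
    terms, _, _, _ = _site_terms(sample)
    return float(terms.sum() / sample.l_callable)


def _tajima_constants(n: int):
    i = np.arange(1, n)
    a1 = float(np.sum(1.0 / i))
    a2 = float(np.sum(1.0 / i**2))
    b1 = (n + 1.0) / (3.0 * (n - 1.0))
    b2 = 2.0 * (n * n + n + 3.0) / (9.0 * n * (n - 1.0))
    c1 = b1 - 1.0 / a1
    c2 = b2 - (n + 2.0) / (a1 * n) + a2 / a1**2
    e1 = c1 / a1
    e2 = c2 / (a1 * a1 + a2)
    return a1, a2, e1, e2


def tajimas_d(sample: PopulationSample):
    """Tajima's D with the mean-effective-sample-size missing-data
    adjustment.  Returns (D, n_effective); raises when S = 0 (the statistic
    is undefined, not zero)."""
    terms, seg, n_i, usable = _site_terms(sample)
    S = int(seg.sum())
    if S == 0:
        raise ValueError("Tajima's D undefined with no segregating sites")
    n_star = int(round(float(n_i[seg].mean())))
    if n_star < 4:
        raise ValueError("need effective sample size >= 4")
    a1, a2, e1, e2 = _tajima_constants(n_star)
    pi_total = float(terms.sum())
    theta_w = S / a1
    var = e1 * S + e2 * S * (S - 1.0)
    d = (pi_total - theta_w) / np.sqrt(var)
    return float(d), n_star


def diversity_stats(sample: PopulationSample) -> DiversityStats:
    """Convenience bundle: pi, S, Tajima's D for one population."""
    terms, seg, n_i, _ = _site_terms(sample)
    S = int(seg.sum())
    if S > 0:
        d, n_star = tajimas_d(sample)
    else:
        d, n_star = None, int(round(float(n_i.mean()))) if len(n_i) else 0
    return DiversityStats(
        label=sample.label,
        pi=nucleotide_diversity(sample),
        S=S,
        tajimas_d=d,
        n_effective=n_star,
        l_callable=sample.l_callable,
    )
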