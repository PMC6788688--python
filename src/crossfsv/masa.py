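"""Marker-assisted segregation analysis and the candidate-variant cascade.

MASA calls each F1 sire's QTL genotype (heterozygous Q/q versus homozygous)
from its half-sib F2 family: the log10 likelihood ratio compares a fixed
paternal substitution effect (taken from the across-family line-cross fit)
against no effect.  Sires with |log10 LR| < 2 stay undetermined.

The candidate cascade then narrows a sequence-variant panel to functional
candidates: (1) biallelic variants only (a bimodal haplotype-effect
distribution implies two functional alleles), (2) genotype pattern matching
the called sires (heterozygous in every segregating sire, homozygous in
every non-segregating one), (3) present in both crosses, (4) overlapping a
regulatory motif interval.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .containers import MotifTrack, VariantPanel
from .linkage import paternal_transmission
from .simcross import CrossData

__all__ = [
    "masa_genotype_sires",
    "filter_biallelic",
    "filter_segregation_pattern",
    "intersect_crosses",
    "filter_motif_overlap",
    "run_cascade",
    "SireQTLCall",
    "FSVCandidateSet",
]

HET_THRESHOLD = 2.0    # log10 LR above which a sire is called heterozygous
HOM_THRESHOLD = -2.0   # ... below which it is called homozygous


@dataclass(frozen=True)
class SireQTLCall:
    sire_id: str
    log10_lr: float
    call: str            # heterozygous | homozygous | undetermined
    n_offspring: int


def _call_from_lr(lr: float) -> str:
    if lr > HET_THRESHOLD:
        return "heterozygous"
    if lr < HOM_THRESHOLD:
        return "homozygous"
    return "undetermined"


def masa_genotype_sires(
    cross: CrossData,
    trait: str,
    position_cm: float,
    effect_estimate: float,
    chrom=None,
    min_offspring: int = 10,
):
    """Call the QTL genotype of every F1 sire from its half-sib family.

    ``effect_estimate`` is the allele substitution effect from the
    across-family line-cross fit at the same position; within a family the
    regressor x = P(hap1) - P(hap2) spans two alleles, so the fixed slope
    tested is effect/2 (against either sire phase).  log10 LR =
    (n/2) log10(RSS_null / RSS_effect) with the residual variance profiled
    out under each hypothesis.
    """
    if chrom is None:
        chrom = cross.gmap.chromosomes[0]
    from .linkage import _trait_vector

    y_all = _trait_vector(cross, trait)
    f2_rows = np.flatnonzero(cross.f2_mask)
    calls = []
    for sire_id in cross.f1_sire_ids:
        off = cross.offspring_of_sire(sire_id)
        if off.size < min_offspring:
            raise ValueError(
                f"sire {sire_id}: family size {off.size} below minimum {min_offspring}"
            )
        off, probs = paternal_transmission(cross, sire_id, chrom, [position_cm])
        y = y_all[np.searchsorted(f2_rows, off)]
        n = len(y)
        if probs is None:
            calls.append(SireQTLCall(str(sire_id), 0.0, "undetermined", n))
            continue
        x = 2.0 * probs[:, 0] - 1.0      # P(hap1) - P(hap2)
        beta = effect_estimate / 2.0
        rss0 = _rss_fixed_slope(y, x, 0.0)
        rss1 = min(_rss_fixed_slope(y, x, beta), _rss_fixed_slope(y, x, -beta))
        lr = (n / 2.0) * np.log10(rss0 / rss1) if rss1 > 0 else np.inf
        calls.append(SireQTLCall(str(sire_id), float(lr), _call_from_lr(float(lr)), n))
    return calls


def _rss_fixed_slope(y, x, beta):
    r = y - beta * x
    r = r - r.mean()
    return float(r @ r)


@dataclass
class FSVCandidateSet:
    """Surviving variants plus per-stage counts through the cascade."""

    cross_id: str
    panel: VariantPanel
    index: np.ndarray                  # indices into panel of surviving variants
    stage_counts: dict = field(default_factory=dict)

    @property
    def positions(self) -> np.ndarray:
        return self.panel.positions[self.index]

    @property
    def n(self) -> int:
        return len(self.index)

    def keys(self) -> set:
        return {self.panel.variant_key(int(i)) for i in self.index}

    def report(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"stage": list(self.stage_counts), "n": list(self.stage_counts.values())}
        )


def filter_biallelic(panel: VariantPanel) -> FSVCandidateSet:
    """Stage 1: keep variants with exactly two observed alleles."""
    if panel.n_variants == 0:
        raise ValueError("empty variant panel")
    keep = np.array(
        [panel.observed_allele_count(i) == 2 for i in range(panel.n_variants)]
    )
    return FSVCandidateSet(
        cross_id=panel.cross_id,
        panel=panel,
        index=np.flatnonzero(keep),
        stage_counts={"input": panel.n_variants, "biallelic": int(keep.sum())},
    )


def filter_segregation_pattern(candidates: FSVCandidateSet, sire_calls) -> FSVCandidateSet:
    """Stage 2: variant heterozygous in every heterozygous-called sire and
    homozygous in every homozygous-called sire.

    Undetermined sires impose no constraint; a missing sire genotype fails
    the variant (conservative).
    """
    panel = candidates.panel
    het = [c.sire_id for c in sire_calls if c.call == "heterozygous"]
    hom = [c.sire_id for c in sire_calls if c.call == "homozygous"]
    if not het and not hom:
        raise ValueError("no called sires to filter on")
    for sid in het + hom:
        if sid not in panel.sample_ids:
            raise KeyError(f"sire {sid} not genotyped in panel")
    het_cols = [panel.sample_ids.index(s) for s in het]
    hom_cols = [panel.sample_ids.index(s) for s in hom]
    keep = []
    for i in candidates.index:
        g = panel.genotypes[int(i)]
        if np.any(g[het_cols + hom_cols] < 0):
            continue
        ok = all(g[j, 0] != g[j, 1] for j in het_cols) and all(
            g[j, 0] == g[j, 1] for j in hom_cols
        )
        if ok:
            keep.append(int(i))
    counts = dict(candidates.stage_counts)
    counts["pattern"] = len(keep)
    return FSVCandidateSet(candidates.cross_id, panel, np.asarray(keep, dtype=int), counts)


def intersect_crosses(a: FSVCandidateSet, b: FSVCandidateSet) -> FSVCandidateSet:
    """Stage 3: variants present (same position, ref and alt) in both sets."""
    if a.panel.chrom != b.panel.chrom:
        raise ValueError("candidate sets refer to different reference regions")
    if (
        a.panel.region is not None
        and b.panel.region is not None
        and (a.panel.region.start, a.panel.region.end)
        != (b.panel.region.start, b.panel.region.end)
    ):
        raise ValueError("candidate sets cover different regions")
    shared = a.keys() & b.keys()
    keep = [int(i) for i in a.index if a.panel.variant_key(int(i)) in shared]
    counts = dict(a.stage_counts)
    counts["intersected"] = len(keep)
    return FSVCandidateSet(
        cross_id=f"{a.cross_id}&{b.cross_id}", panel=a.panel,
        index=np.asarray(keep, dtype=int), stage_counts=counts,
    )


def filter_motif_overlap(candidates: FSVCandidateSet, motifs: MotifTrack) -> FSVCandidateSet:
    """Stage 4: keep variants whose footprint overlaps a motif interval.

    SNPs overlap at their single base; a deletion overlaps when any deleted
    base intersects the motif (BED converted to 1-based internally).
    """
    panel = candidates.panel
    keep = []
    if len(motifs) and motifs.chrom != panel.chrom:
        raise ValueError("motif track on a different chromosome")
    for i in candidates.index:
        span = panel.variant_span(int(i))
        if len(motifs) and motifs.overlaps(span):
            keep.append(int(i))
    counts = dict(candidates.stage_counts)
    counts["motif"] = len(keep)
    return FSVCandidateSet(candidates.cross_id, panel, np.asarray(keep, dtype=int), counts)


def run_cascade(panel_a, sire_calls_a, panel_b, sire_calls_b, motifs) -> FSVCandidateSet:
    """Full four-stage cascade on two crosses' panels."""
    s1a = filter_biallelic(panel_a)
    s1b = filter_biallelic(panel_b)
    s2a = filter_segregation_pattern(s1a, sire_calls_a)
    s2b = filter_segregation_pattern(s1b, sire_calls_b)
    s3 = intersect_crosses(s2a, s2b)
    return filter_motif_overlap(s3, motifs)
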