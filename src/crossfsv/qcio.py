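"""Readers/writers for PED/MAP, minimal VCF and BED, plus marker QC.

Genotype matrices are (n_individuals, n_markers) int8 arrays coding the
count of allele "2" (0/1/2) with -1 for missing.  PED files use the 1/2
allele coding with "0 0" for a missing genotype.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from cyvcf2 import VCF

from .containers import GeneticMap, GenomicInterval, MotifTrack, VariantPanel

MISSING = -1

PED_COLUMNS = ["fid", "id", "sire", "dam", "sex", "phenotype"]


# ---------------------------------------------------------------------------
# PED / MAP

def write_ped_map(ped_path, map_path, pedigree: pd.DataFrame, genotypes, gmap: GeneticMap):
    """Write a PED/MAP pair (alleles coded 1/2, missing '0 0')."""
    genotypes = np.asarray(genotypes)
    sex_code = pedigree["sex"].map({"M": "1", "F": "2"}).fillna("0")
    with open(map_path, "w") as fh:
        for c, n, cm, bp in zip(gmap.chrom, gmap.name, gmap.cm, gmap.bp):
            fh.write(f"{c}\t{n}\t{cm:.6g}\t{bp}\n")
    with open(ped_path, "w") as fh:
        for i, row in enumerate(pedigree.itertuples(index=False)):
            g = genotypes[i]
            pairs = np.empty((len(g), 2), dtype="U1")
            pairs[g == 0] = ("1", "1")
            pairs[g == 1] = ("1", "2")
            pairs[g == 2] = ("2", "2")
            pairs[g == MISSING] = ("0", "0")
            fields = [
                "0",
                str(row.id),
                str(getattr(row, "sire", "0")),
                str(getattr(row, "dam", "0")),
                str(sex_code.iloc[i]),
                "-9",
            ]
            fh.write(" ".join(fields) + " " + " ".join(pairs.ravel()) + "\n")


def read_map(map_path) -> GeneticMap:
    df = pd.read_csv(
        map_path, sep=r"\s+", header=None, names=["chrom", "name", "cm", "bp"],
        dtype={"chrom": str},
    )
    if df.isna().any().any():
        raise ValueError(f"malformed MAP file {map_path}")
    return GeneticMap(df["chrom"], df["name"], df["cm"], df["bp"])


def read_ped_map(ped_path, map_path):
    """Read a PED/MAP pair -> (pedigree DataFrame, genotype matrix, GeneticMap)."""
    gmap = read_map(map_path)
    m = gmap.n_markers
    ids, sires, dams, sexes, genos = [], [], [], [], []
    with open(ped_path) as fh:
        for ln, line in enumerate(fh, 1):
            fields = line.split()
            if not fields:
                continue
            if len(fields) != 6 + 2 * m:
                raise ValueError(
                    f"{ped_path}:{ln}: expected {6 + 2 * m} fields, got {len(fields)}"
                )
            ids.append(fields[1]); sires.append(fields[2]); dams.append(fields[3])
            sexes.append({"1": "M", "2": "F"}.get(fields[4], ""))
            alleles = np.array(fields[6:])
            a = alleles.reshape(m, 2)
            g = np.full(m, MISSING, dtype=np.int8)
            called = ~np.any(a == "0", axis=1)
            g[called] = (a[called] == "2").sum(axis=1)
            bad = called & ~np.all(np.isin(a, ("1", "2")) | (a == "0"), axis=1)
            if np.any(bad):
                raise ValueError(f"{ped_path}:{ln}: unrecognized allele code")
            genos.append(g)
    pedigree = pd.DataFrame({"id": ids, "sire": sires, "dam": dams, "sex": sexes})
    return pedigree, np.asarray(genos, dtype=np.int8), gmap


# ---------------------------------------------------------------------------
# VCF (minimal GT-only dialect) and BED

def write_vcf_minimal(panel: VariantPanel, path):
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write(f"##contig=<ID={panel.chrom}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(panel.sample_ids) + "\n"
        )
        for i in range(panel.n_variants):
            gts = []
            for a, b in panel.genotypes[i]:
                gts.append(
                    f"{'.' if a < 0 else int(a)}/{'.' if b < 0 else int(b)}"
                )
            fh.write(
                f"{panel.chrom}\t{panel.positions[i]}\tv{i + 1}\t{panel.ref[i]}\t"
                f"{','.join(panel.alt[i])}\t.\t.\t.\tGT\t" + "\t".join(gts) + "\n"
            )


def read_vcf_minimal(path, cross_id="") -> VariantPanel:
    """Read a GT-only VCF into a VariantPanel (positions 1-based)."""
    vcf = VCF(str(path))
    samples = list(vcf.samples)
    chroms, positions, refs, alts, genos = [], [], [], [], []
    for v in vcf:
        chroms.append(v.CHROM)
        positions.append(v.POS)
        refs.append(v.REF)
        alts.append(list(v.ALT))
        g = np.array([gt[:2] for gt in v.genotypes], dtype=np.int8)
        genos.append(g)
    vcf.close()
    if not positions:
        return VariantPanel(
            chrom="", positions=np.empty(0, dtype=np.int64), ref=[], alt=[],
            sample_ids=samples,
            genotypes=np.zeros((0, len(samples), 2), dtype=np.int8),
            cross_id=cross_id,
        )
    if len(set(chroms)) != 1:
        raise ValueError("minimal VCF reader expects a single chromosome")
    return VariantPanel(
        chrom=chroms[0],
        positions=np.asarray(positions, dtype=np.int64),
        ref=refs,
        alt=alts,
        sample_ids=samples,
        genotypes=np.asarray(genos, dtype=np.int8),
        cross_id=cross_id,
    )


def write_bed(track: MotifTrack, path):
    with open(path, "w") as fh:
        for s, e, lab in zip(track.starts, track.ends, track.labels):
            fh.write(f"{track.chrom}\t{s}\t{e}\t{lab}\n")


def read_bed(path) -> MotifTrack:
    """Read a BED file (0-based half-open) into a MotifTrack."""
    chroms, starts, ends, labels = [], [], [], []
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            fields = line.split()
            if not fields or fields[0].startswith(("#", "track", "browser")):
                continue
            if len(fields) < 3:
                raise ValueError(f"{path}:{ln}: BED needs >= 3 columns")
            try:
                s, e = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise ValueError(f"{path}:{ln}: non-numeric coordinates") from exc
            chroms.append(fields[0]); starts.append(s); ends.append(e)
            labels.append(fields[3] if len(fields) > 3 else f"motif_{ln}")
    if not chroms:
        return MotifTrack(chrom="", starts=np.empty(0, dtype=np.int64),
                          ends=np.empty(0, dtype=np.int64))
    if len(set(chroms)) != 1:
        raise ValueError("motif track must be single-chromosome")
    return MotifTrack(chrom=chroms[0], starts=np.asarray(starts),
                      ends=np.asarray(ends), labels=labels)


def bed_to_interval(chrom, start, end) -> GenomicInterval:
    """Convert one BED record (0-based half-open) to 1-based inclusive."""
    return GenomicInterval(str(chrom), int(start) + 1, int(end))


# ---------------------------------------------------------------------------
# Marker QC

@dataclass(frozen=True)
class MarkerQCRule:
    """Per-marker retention thresholds."""

    maf_min: float = 0.05
    call_rate_min: float = 0.90
    hwe_p_min: float = 1e-6
    mendel_error_max: float = 0.05

    def __post_init__(self):
        for v in (self.maf_min, self.call_rate_min, self.hwe_p_min, self.mendel_error_max):
            if not 0.0 <= v <= 1.0:
                raise ValueError("QC thresholds must lie in [0, 1]")


def hwe_exact_test(n_hom1: int, n_het: int, n_hom2: int) -> float:
    """Exact two-sided Hardy-Weinberg test (sum of probabilities of
    heterozygote counts no more likely than observed, conditional on the
    allele counts)."""
    n = n_hom1 + n_het + n_hom2
    if n == 0:
        return 1.0
    n_rare = min(2 * n_hom1 + n_het, 2 * n_hom2 + n_het)
    # log-probability of each possible het count with the same allele counts
    hets = np.arange(n_rare % 2, n_rare + 1, 2)
    from scipy.special import gammaln

    n_common = 2 * n - n_rare
    lp = (
        hets * np.log(2.0)
        + gammaln(n + 1)
        - gammaln((n_rare - hets) / 2 + 1)
        - gammaln(hets + 1)
        - gammaln((n_common - hets) / 2 + 1)
        + gammaln(n_rare + 1)
        + gammaln(n_common + 1)
        - gammaln(2 * n + 1)
    )
    p = np.exp(lp - lp.max())
    p /= p.sum()
    obs = np.flatnonzero(hets == n_het)
    if obs.size == 0:  # genotype counts inconsistent (defensive)
        return 1.0
    return float(min(1.0, p[p <= p[obs[0]] * (1 + 1e-12)].sum()))


def qc_filter_markers(genotypes, rules: MarkerQCRule, f2_mask=None,
                      mendel_rates=None):
    """Apply per-marker QC; returns (keep mask, report DataFrame).

    MAF and call rate use all individuals; the exact HWE test uses the F2
    subset when ``f2_mask`` is given.  ``mendel_rates`` (per-marker, from
    :func:`check_mendelian`) is applied when provided.
    """
    G = np.asarray(genotypes)
    if G.size == 0:
        raise ValueError("empty genotype matrix")
    called = G >= 0
    n_called = called.sum(axis=0)
    call_rate = n_called / G.shape[0]
    with np.errstate(invalid="ignore", divide="ignore"):
        freq = np.where(n_called > 0, (G * called).sum(axis=0) / (2 * n_called), 0.0)
    maf = np.minimum(freq, 1 - freq)

    sub = G[np.asarray(f2_mask)] if f2_mask is not None else G
    hwe_p = np.ones(G.shape[1])
    for j in range(G.shape[1]):
        g = sub[:, j][sub[:, j] >= 0]
        hwe_p[j] = hwe_exact_test(int((g == 0).sum()), int((g == 1).sum()),
                                  int((g == 2).sum()))

    fail_maf = maf < rules.maf_min
    fail_call = call_rate < rules.call_rate_min
    fail_hwe = hwe_p <= rules.hwe_p_min
    fail_mendel = (
        np.asarray(mendel_rates) > rules.mendel_error_max
        if mendel_rates is not None
        else np.zeros(G.shape[1], dtype=bool)
    )
    keep = ~(fail_maf | fail_call | fail_hwe | fail_mendel)
    report = pd.DataFrame(
        {
            "maf": maf,
            "call_rate": call_rate,
            "hwe_p": hwe_p,
            "fail_maf": fail_maf,
            "fail_call_rate": fail_call,
            "fail_hwe": fail_hwe,
            "fail_mendel": fail_mendel,
            "keep": keep,
        }
    )
    return keep, report


# possible transmitted alleles per genotype code
_TRANSMIT = {0: (0,), 1: (0, 1), 2: (1,)}


def check_mendelian(genotypes, pedigree: pd.DataFrame):
    """Per-marker Mendelian-inconsistency rate over informative trios.

    A trio is informative at a marker when child and both parents are
    genotyped; individuals whose parents are absent from the matrix are
    skipped.  Returns (rates, n_informative) per marker.
    """
    G = np.asarray(genotypes)
    ids = pedigree["id"].astype(str).to_numpy()
    row = {v: i for i, v in enumerate(ids)}
    m = G.shape[1]
    errors = np.zeros(m, dtype=np.int64)
    informative = np.zeros(m, dtype=np.int64)

    # impossible child genotype lookup: (sire, dam) -> set of valid children
    valid = np.zeros((3, 3, 3), dtype=bool)
    for s in range(3):
        for d in range(3):
            for a in _TRANSMIT[s]:
                for b in _TRANSMIT[d]:
                    valid[s, d, a + b] = True

    for child, sire, dam in pedigree[["id", "sire", "dam"]].astype(str).itertuples(index=False):
        if sire not in row or dam not in row:
            continue
        c, s, d = G[row[child]], G[row[sire]], G[row[dam]]
        ok = (c >= 0) & (s >= 0) & (d >= 0)
        informative += ok
        idx = np.flatnonzero(ok)
        errors[idx] += ~valid[s[idx], d[idx], c[idx]]
    with np.errstate(invalid="ignore", divide="ignore"):
        rates = np.where(informative > 0, errors / informative, 0.0)
    return rates, informative


def trio_phase(genotypes, pedigree: pd.DataFrame):
    """Rule-based phasing of offspring with genotyped parents.

    Returns an (n, 2, m) int8 array with hap 0 paternal; -1 where the
    parental genotypes do not resolve the phase (both parents heterozygous
    around a heterozygous child, missing data, or Mendelian conflict).
    Homozygous children are trivially phased.
    """
    G = np.asarray(genotypes)
    n, m = G.shape
    ids = pedigree["id"].astype(str).to_numpy()
    row = {v: i for i, v in enumerate(ids)}
    haps = np.full((n, 2, m), MISSING, dtype=np.int8)
    for i, (child, sire, dam) in enumerate(
        pedigree[["id", "sire", "dam"]].astype(str).itertuples(index=False)
    ):
        g = G[i]
        haps[i, 0, g == 0] = 0
        haps[i, 1, g == 0] = 0
        haps[i, 0, g == 2] = 1
        haps[i, 1, g == 2] = 1
        if sire not in row or dam not in row:
            continue
        s, d = G[row[sire]], G[row[dam]]
        het = g == 1
        # sire homozygous: paternal allele known, maternal is the other
        s_hom = het & ((s == 0) | (s == 2))
        haps[i, 0, s_hom] = (s[s_hom] // 2).astype(np.int8)
        haps[i, 1, s_hom] = 1 - s[s_hom] // 2
        d_hom = het & ((d == 0) | (d == 2)) & ~s_hom
        haps[i, 1, d_hom] = (d[d_hom] // 2).astype(np.int8)
        haps[i, 0, d_hom] = 1 - d[d_hom] // 2
    return haps
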