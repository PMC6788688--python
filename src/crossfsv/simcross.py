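"""Synthetic two-cross F2 intercross simulator.

Generates the data structures the downstream mapping chain expects: a marker
map with Kosambi genetic distances, phased founder/F1/F2 genotypes produced
by interference-free meiosis, two correlated quantitative traits with a
planted biallelic QTL plus pedigree polygenic background and fixed effects,
and a sequence-variant panel in a focal region containing one planted causal
regulatory variant inside a motif interval.

The design emulates two divergent-breed intercrosses: a large one
(17 x 19 founders, 91 F1, 1105 F2) and a small one (9 x 5 founders, 36 F1,
345 F2).  The high-value QTL allele Q is fixed (or near-fixed) in one
founder breed, so every F1 is Q/q and the F2 segregates 1:2:1.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from .containers import GeneticMap, GenomicInterval, MotifTrack, VariantPanel

BREED_A = 0  # "Western" breed: q allele
BREED_B = 1  # "Asian-like" breed: Q allele


def kosambi_recombination(distance_cm):
    """Recombination fraction for a Kosambi map distance in cM.

    r = tanh(2m) / 2 with m the distance in Morgans; interference is implied
    by the map function but meiosis here applies r independently per
    interval.
    """
    d = np.asarray(distance_cm, dtype=float)
    if np.any(d < 0):
        raise ValueError("map distance must be >= 0")
    r = 0.5 * np.tanh(2.0 * d / 100.0)
    return float(r) if np.isscalar(distance_cm) else r


def build_genetic_map(n_chromosomes, markers_per_chromosome, mean_spacing_cm, seed=0):
    """Regularly spaced genetic map with jittered physical positions.

    Genetic positions are exactly ``mean_spacing_cm`` apart; physical
    positions are roughly proportional (~1 Mb/cM) with multiplicative
    jitter, strictly increasing.
    """
    if n_chromosomes < 1 or markers_per_chromosome < 1:
        raise ValueError("counts must be >= 1")
    if mean_spacing_cm <= 0:
        raise ValueError("spacing must be > 0")
    rng = np.random.default_rng(seed)
    chrom, name, cm, bp = [], [], [], []
    for c in range(1, n_chromosomes + 1):
        pos_cm = mean_spacing_cm * np.arange(markers_per_chromosome)
        # ~1 Mb per cM with +-30% jitter per interval, minimum 1 bp
        incr = np.maximum(
            1,
            np.round(
                mean_spacing_cm * 1e6 * rng.uniform(0.7, 1.3, markers_per_chromosome)
            ).astype(np.int64),
        )
        pos_bp = 1 + np.concatenate([[0], np.cumsum(incr[:-1])])
        chrom.extend([str(c)] * markers_per_chromosome)
        name.extend(f"M{c}_{i + 1}" for i in range(markers_per_chromosome))
        cm.extend(pos_cm)
        bp.extend(pos_bp)
    return GeneticMap(chrom, name, cm, bp)


@dataclass(frozen=True)
class QTLSpec:
    """A biallelic QTL placed exactly on a map marker."""

    chrom: str
    bp: int
    alleles: tuple = ("Q", "q")
    add_effects: tuple = (1.0, 1.0)    # a per trait: half the homozygote difference
    dom_effects: tuple = (0.0, 0.0)    # d per trait
    freq_breed_a: float = 0.0          # Q-allele frequency in breed A founders
    freq_breed_b: float = 1.0          # ... and in breed B founders


@dataclass
class CrossConfig:
    """Design and trait-model parameters for one simulated intercross."""

    n_f0_sires: int
    n_f0_dams: int
    n_f1: int
    n_f2: int
    qtl: QTLSpec
    sigma_g2: tuple = (1.0, 1.0)       # additive polygenic variance per trait
    sigma_e2: tuple = (1.0, 1.0)       # residual variance per trait
    residual_corr: float = 0.3         # residual correlation between the traits
    trait_means: tuple = (0.0, 0.0)
    sex_effects: tuple = (0.3, 0.3)    # male minus female, trait units
    batch_amplitudes: tuple = (0.3, 0.3)
    carcass_slopes: tuple = (0.02, 0.02)  # trait units per kg
    n_batches: int = 4
    carcass_mean: float = 79.2
    carcass_sd: float = 12.6
    founder_divergence: float = 0.6    # allele-frequency gap between breeds
    trait_names: tuple = ("trait1", "trait2")
    cross_id: str = "cross"
    seed: int = 0
    # optional prescribed QTL genotype ('het'/'hom') for each F1 sire in
    # order; breed-B dams are then made Q/q at the QTL so the forced
    # transmission stays Mendelian-consistent
    sire_qtl_pattern: tuple | None = None

    def __post_init__(self) -> None:
        for v in (*self.sigma_g2, *self.sigma_e2):
            if v < 0:
                raise ValueError("variances must be >= 0")
        if not abs(self.residual_corr) < 1:
            raise ValueError("|residual correlation| must be < 1")
        for n in (self.n_f0_sires, self.n_f0_dams, self.n_f1, self.n_f2):
            if n < 1:
                raise ValueError("counts must be >= 1")

    @property
    def n_traits(self) -> int:
        return len(self.trait_names)

    @classmethod
    def from_yaml(cls, path) -> "CrossConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        qtl = QTLSpec(**{k: tuple(v) if isinstance(v, list) else v
                         for k, v in raw.pop("qtl").items()})
        raw = {k: tuple(v) if isinstance(v, list) else v for k, v in raw.items()}
        return cls(qtl=qtl, **raw)

    def to_yaml(self, path) -> None:
        d = dataclasses.asdict(self)
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh, default_flow_style=None, sort_keys=False)


def _qtl_effect(var_share, total_background=2.0):
    """Additive effect a giving the QTL the requested share of phenotypic
    variance in an F2 (allele frequency 1/2, additive variance a^2/2)."""
    v = var_share / (1.0 - var_share) * total_background
    return float(np.sqrt(2.0 * v))


def lk_config(gmap: GeneticMap, seed=0, qtl_var_share=0.25, **overrides) -> CrossConfig:
    """Large-cross default design (Landrace x native style: 1105 F2)."""
    chrom = gmap.chromosomes[0]
    sl = gmap.chrom_slice(chrom)
    mid = sl.start + (sl.stop - sl.start) // 2
    a = _qtl_effect(qtl_var_share)
    base = dict(
        n_f0_sires=17, n_f0_dams=19, n_f1=91, n_f2=1105,
        qtl=QTLSpec(chrom=str(chrom), bp=int(gmap.bp[mid]),
                    add_effects=(a, a)),
        carcass_mean=79.2, carcass_sd=12.6,
        cross_id="LK", seed=seed,
    )
    base.update(overrides)
    return CrossConfig(**base)


def dk_config(gmap: GeneticMap, seed=0, qtl_var_share=0.25, **overrides) -> CrossConfig:
    """Small-cross default design (Duroc x native style: 345 F2)."""
    chrom = gmap.chromosomes[0]
    sl = gmap.chrom_slice(chrom)
    mid = sl.start + (sl.stop - sl.start) // 2
    a = _qtl_effect(qtl_var_share)
    base = dict(
        n_f0_sires=9, n_f0_dams=5, n_f1=36, n_f2=345,
        qtl=QTLSpec(chrom=str(chrom), bp=int(gmap.bp[mid]),
                    add_effects=(a, a)),
        carcass_mean=69.7, carcass_sd=12.6,
        cross_id="DK", seed=seed,
    )
    base.update(overrides)
    return CrossConfig(**base)


@dataclass
class CrossData:
    """One simulated intercross: pedigree, phased genotypes, truth record."""

    pedigree: pd.DataFrame            # id, sire, dam, generation, sex, batch, carcass_weight, breed
    gmap: GeneticMap
    haplotypes: np.ndarray            # (n_ind, 2, n_markers) int8 alleles {0,1}; hap 0 paternal
    origins: np.ndarray               # same shape; founder-breed-of-origin {0,1}
    truth: dict = field(default_factory=dict)
    phenotypes: pd.DataFrame | None = None
    cross_id: str = ""

    @property
    def ids(self) -> np.ndarray:
        return self.pedigree["id"].to_numpy()

    @property
    def n_individuals(self) -> int:
        return len(self.pedigree)

    @property
    def f2_mask(self) -> np.ndarray:
        return (self.pedigree["generation"] == 2).to_numpy()

    @property
    def f2_ids(self) -> np.ndarray:
        return self.ids[self.f2_mask]

    @property
    def founder_ids(self) -> np.ndarray:
        return self.ids[(self.pedigree["generation"] == 0).to_numpy()]

    @property
    def f1_sire_ids(self) -> list:
        """F1 individuals that actually sired F2 offspring, in pedigree order."""
        f2 = self.pedigree[self.pedigree["generation"] == 2]
        sires = pd.unique(f2["sire"])
        return list(sires)

    def row(self, ind_id) -> int:
        hits = np.flatnonzero(self.ids == ind_id)
        if hits.size == 0:
            raise KeyError(ind_id)
        return int(hits[0])

    def genotypes(self) -> np.ndarray:
        """Additive genotype codes 0/1/2 (count of allele 1), no missing."""
        return self.haplotypes.sum(axis=1).astype(np.int8)

    def qtl_genotypes(self) -> np.ndarray:
        """Count of Q alleles (allele 1 at the QTL marker) per individual."""
        return self.haplotypes[:, :, self.truth["qtl_index"]].sum(axis=1)

    def offspring_of_sire(self, sire_id) -> np.ndarray:
        """Row indices of the F2 offspring of one F1 sire."""
        ped = self.pedigree
        mask = (ped["generation"] == 2) & (ped["sire"] == sire_id)
        return np.flatnonzero(mask.to_numpy())

    def founder_breed_freqs(self) -> np.ndarray:
        """Observed allele-1 frequency per marker in each founder breed (2, m)."""
        out = np.empty((2, self.gmap.n_markers))
        ped = self.pedigree
        for b, label in enumerate(("A", "B")):
            rows = np.flatnonzero(
                ((ped["generation"] == 0) & (ped["breed"] == label)).to_numpy()
            )
            out[b] = self.haplotypes[rows].reshape(-1, self.gmap.n_markers).mean(axis=0)
        return out


def _interval_switch_probs(gmap: GeneticMap) -> np.ndarray:
    """Per-marker probability that meiosis switches parental strand relative
    to the previous marker; 0.5 at each chromosome start (independent)."""
    p = np.empty(gmap.n_markers)
    for c in gmap.chromosomes:
        sl = gmap.chrom_slice(c)
        p[sl.start] = 0.5
        d = np.diff(gmap.cm[sl])
        p[sl.start + 1 : sl.stop] = kosambi_recombination(d)
    return p


def _gametes(haps, origins, switch_p, rng, n):
    """Draw ``n`` gametes from one parent's phased pair by interference-free
    meiosis.  Returns (alleles, origins), each (n, m) int8."""
    m = haps.shape[1]
    switches = rng.random((n, m)) < switch_p
    strand = np.cumsum(switches, axis=1) % 2   # 0/1 parental strand per marker
    cols = np.arange(m)
    return haps[strand, cols].astype(np.int8), origins[strand, cols].astype(np.int8)


def simulate_cross(config: CrossConfig, gmap: GeneticMap) -> CrossData:
    """Simulate founders, F1 and F2 with phased genotypes and truth labels.

    Deterministic for a given ``config.seed``.
    """
    rng = np.random.default_rng(config.seed)
    m = gmap.n_markers
    try:
        qtl_idx = gmap.index_at(config.qtl.chrom, config.qtl.bp)
    except KeyError as exc:
        raise ValueError("QTL position must coincide with a map marker") from exc
    if config.sire_qtl_pattern is not None and config.qtl.freq_breed_a != 0.0:
        raise ValueError("sire_qtl_pattern requires the Q allele absent from breed A")

    # breed allele-1 frequencies, divergent by construction
    base = rng.uniform(0.15, 0.85, m)
    sign = rng.choice([-1.0, 1.0], m)
    half = config.founder_divergence / 2.0
    freqs = np.empty((2, m))
    freqs[BREED_A] = np.clip(base - sign * half, 0.02, 0.98)
    freqs[BREED_B] = np.clip(base + sign * half, 0.02, 0.98)
    freqs[BREED_A, qtl_idx] = config.qtl.freq_breed_a
    freqs[BREED_B, qtl_idx] = config.qtl.freq_breed_b

    switch_p = _interval_switch_probs(gmap)

    n_f0 = config.n_f0_sires + config.n_f0_dams
    n_total = n_f0 + config.n_f1 + config.n_f2
    haps = np.zeros((n_total, 2, m), dtype=np.int8)
    orig = np.zeros((n_total, 2, m), dtype=np.int8)

    ids, sires, dams, sex, breed = [], [], [], [], []

    # --- F0: breed A sires, breed B dams, haplotypes iid from breed freqs
    for i in range(config.n_f0_sires):
        r = len(ids)
        haps[r] = (rng.random((2, m)) < freqs[BREED_A]).astype(np.int8)
        orig[r] = BREED_A
        ids.append(f"A{i + 1:03d}")
        sires.append("0"); dams.append("0"); sex.append("M"); breed.append("A")
    for i in range(config.n_f0_dams):
        r = len(ids)
        haps[r] = (rng.random((2, m)) < freqs[BREED_B]).astype(np.int8)
        orig[r] = BREED_B
        if config.sire_qtl_pattern is not None:
            haps[r, :, qtl_idx] = (1, 0)   # Q/q dam: either transmission is legal
            freqs[BREED_B, qtl_idx] = 0.5  # truth record reflects the forced dams
        ids.append(f"B{i + 1:03d}")
        sires.append("0"); dams.append("0"); sex.append("F"); breed.append("B")

    # --- F1: cyclic matings of A sires x B dams; alternating sex
    f0_sire_rows = np.arange(config.n_f0_sires)
    f0_dam_rows = config.n_f0_sires + np.arange(config.n_f0_dams)
    for i in range(config.n_f1):
        r = len(ids)
        ps = f0_sire_rows[i % config.n_f0_sires]
        pd_ = f0_dam_rows[i % config.n_f0_dams]
        ga, go = _gametes(haps[ps], orig[ps], switch_p, rng, 1)
        haps[r, 0], orig[r, 0] = ga[0], go[0]
        ga, go = _gametes(haps[pd_], orig[pd_], switch_p, rng, 1)
        haps[r, 1], orig[r, 1] = ga[0], go[0]
        if config.sire_qtl_pattern is not None and i % 2 == 0:
            male_idx = i // 2
            if male_idx < len(config.sire_qtl_pattern):
                want = config.sire_qtl_pattern[male_idx]
                if want not in ("het", "hom"):
                    raise ValueError(f"unknown sire pattern entry {want!r}")
                # paternal allele is q (breed A); maternal sets the genotype
                haps[r, 1, qtl_idx] = 1 if want == "het" else 0
        ids.append(f"F1_{i + 1:03d}")
        sires.append(ids[ps]); dams.append(ids[pd_])
        sex.append("M" if i % 2 == 0 else "F"); breed.append("")

    f1_rows = n_f0 + np.arange(config.n_f1)
    f1_male_rows = f1_rows[::2][: (config.n_f1 + 1) // 2]
    f1_female_rows = f1_rows[1::2]
    if len(f1_male_rows) == 0 or len(f1_female_rows) == 0:
        raise ValueError("need at least one F1 of each sex")

    # --- F2: contiguous sire families (block allocation), cyclic dams
    n_sires = len(f1_male_rows)
    for k in range(config.n_f2):
        r = len(ids)
        s_row = f1_male_rows[k * n_sires // config.n_f2]
        d_row = f1_female_rows[k % len(f1_female_rows)]
        ga, go = _gametes(haps[s_row], orig[s_row], switch_p, rng, 1)
        haps[r, 0], orig[r, 0] = ga[0], go[0]
        ga, go = _gametes(haps[d_row], orig[d_row], switch_p, rng, 1)
        haps[r, 1], orig[r, 1] = ga[0], go[0]
        ids.append(f"F2_{k + 1:04d}")
        sires.append(ids[s_row]); dams.append(ids[d_row])
        sex.append("M" if k % 2 == 0 else "F"); breed.append("")

    gen = [0] * n_f0 + [1] * config.n_f1 + [2] * config.n_f2
    batch = np.full(n_total, -1)
    # consecutive sibling pairs share a batch so sex (alternating) and batch
    # stay jointly full-rank
    batch[n_f0 + config.n_f1 :] = (np.arange(config.n_f2) // 2) % config.n_batches
    cw = np.full(n_total, np.nan)
    cw[n_f0 + config.n_f1 :] = rng.normal(
        config.carcass_mean, config.carcass_sd, config.n_f2
    )

    pedigree = pd.DataFrame(
        {
            "id": ids,
            "sire": sires,
            "dam": dams,
            "generation": gen,
            "sex": sex,
            "batch": batch,
            "carcass_weight": cw,
            "breed": breed,
        }
    )

    cross = CrossData(
        pedigree=pedigree,
        gmap=gmap,
        haplotypes=haps,
        origins=orig,
        cross_id=config.cross_id,
    )
    qtl_geno = haps[:, :, qtl_idx].sum(axis=1)
    sire_truth = {}
    for s_row in np.unique([cross.row(s) for s in pedigree.loc[pedigree["generation"] == 2, "sire"]]):
        sire_truth[ids[s_row]] = "het" if qtl_geno[s_row] == 1 else "hom"
    cross.truth = {
        "qtl_index": qtl_idx,
        "qtl_chrom": config.qtl.chrom,
        "qtl_bp": config.qtl.bp,
        "qtl_genotype": qtl_geno.copy(),
        "sire_qtl": sire_truth,
        "breed_freqs": freqs,
    }
    return cross


def simulate_phenotypes(cross: CrossData, config: CrossConfig, seed=0) -> pd.DataFrame:
    """Simulate the two correlated traits for every F2.

    y_t = mu_t + sex + batch + beta_t * (carcass weight) + a_t*x_add +
    d_t*x_dom + u_t + e_t, with u ~ N(0, A sigma_g2) from the pedigree
    relationship matrix and residuals correlated across traits.
    """
    from .grammar import kinship_from_pedigree

    if "qtl_genotype" not in cross.truth:
        raise ValueError("cross is missing truth QTL genotypes")
    rng = np.random.default_rng(seed)
    ped = cross.pedigree
    f2 = cross.f2_mask
    n2 = int(f2.sum())

    _, A = kinship_from_pedigree(ped)
    L = np.linalg.cholesky(A + 1e-10 * np.eye(len(A)))

    x_add = (cross.truth["qtl_genotype"][f2] - 1).astype(float)
    x_dom = (cross.truth["qtl_genotype"][f2] == 1).astype(float)
    sex = (ped.loc[f2, "sex"] == "M").to_numpy(float) - 0.5
    batches = ped.loc[f2, "batch"].to_numpy()
    cw = ped.loc[f2, "carcass_weight"].to_numpy()
    cw_c = cw - np.nanmean(cw)

    n_b = config.n_batches
    batch_levels = np.linspace(-1.0, 1.0, n_b) if n_b > 1 else np.zeros(1)

    # correlated residuals across the two traits
    se = np.sqrt(np.asarray(config.sigma_e2, dtype=float))
    rho = config.residual_corr
    cov_e = np.array(
        [[se[0] ** 2, rho * se[0] * se[1]], [rho * se[0] * se[1], se[1] ** 2]]
    )
    e = rng.multivariate_normal(np.zeros(2), cov_e, size=n2)

    data = {"id": cross.f2_ids}
    for t, name in enumerate(config.trait_names):
        u_all = L @ rng.standard_normal(len(A)) * np.sqrt(config.sigma_g2[t])
        y = (
            config.trait_means[t]
            + config.sex_effects[t] * sex
            + config.batch_amplitudes[t] * batch_levels[batches]
            + config.carcass_slopes[t] * cw_c
            + config.qtl.add_effects[t] * x_add
            + config.qtl.dom_effects[t] * x_dom
            + u_all[f2]
            + e[:, t]
        )
        data[name] = y
    table = pd.DataFrame(data)
    cross.phenotypes = table
    return table


def simulate(config: CrossConfig, gmap: GeneticMap) -> CrossData:
    """Convenience wrapper: genotypes then phenotypes, seeds derived from
    ``config.seed``."""
    cross = simulate_cross(config, gmap)
    simulate_phenotypes(cross, config, seed=config.seed + 1_000_003)
    return cross


_SNP_ALLELES = np.array(list("ACGT"))


def simulate_variant_panels(
    crosses,
    region: GenomicInterval,
    n_variants: int,
    n_pattern_consistent: int,
    causal_in_motif: bool = True,
    seed: int = 0,
    multiallelic_frac: float = 0.1,
    shared_frac: float = 0.5,
    n_decoy_motifs: int = 5,
    include_causal: bool = True,
):
    """Sequence-variant panels for one or more crosses plus a motif track.

    Each panel genotypes the cross's founders and F1 sires over ``n_variants``
    records in ``region``: multi-allelic decoys, random biallelic variants,
    exactly ``n_pattern_consistent`` variants in full LD with the QTL (so
    they match every sire's true QTL genotype), and one planted causal 6-bp
    deletion at the QTL position itself.  Pattern-consistent variants and a
    ``shared_frac`` share of the random ones occur at the same positions with
    the same alleles in every panel; the rest are cross-private, so the
    cross-intersection filter has work to do.

    Returns ``(panels, motifs)``; the planted variant's position is recorded
    in each cross's truth dict under ``"causal_variant_pos"``.
    """
    n_causal = int(include_causal) if n_variants > 0 else 0
    if n_pattern_consistent > n_variants - n_causal:
        raise ValueError("n_pattern_consistent exceeds the panel size")
    crosses = list(crosses)
    if not crosses:
        raise ValueError("need at least one cross")
    qtl_bp = crosses[0].truth["qtl_bp"]
    chrom = str(crosses[0].truth["qtl_chrom"])
    for c in crosses:
        if c.truth["qtl_bp"] != qtl_bp or str(c.truth["qtl_chrom"]) != chrom:
            raise ValueError("crosses must share the QTL placement")
    if not region.contains(chrom, qtl_bp):
        raise ValueError("region must contain the QTL position")
    if region.length_bp < 20 * max(n_variants, 1) + 200:
        raise ValueError("region too small for the requested number of variants")

    rng = np.random.default_rng(seed)
    n_random = n_variants - n_causal - n_pattern_consistent
    n_multi = int(round(multiallelic_frac * n_random))
    n_shared_rand = int(round(shared_frac * (n_random - n_multi)))
    n_private = n_random - n_multi - n_shared_rand

    # distinct positions for every record of every panel (keeps intersection
    # semantics unambiguous); the causal deletion needs a 6-bp footprint.
    n_pos_needed = (
        n_pattern_consistent + n_multi + n_shared_rand + n_private * len(crosses)
    )
    population = np.arange(region.start, region.end - 6)
    draw = min(len(population), 4 * n_pos_needed)
    pool = rng.choice(population, size=draw, replace=False)
    pool = pool[np.abs(pool - qtl_bp) > 6][:n_pos_needed]
    if len(pool) < n_pos_needed:
        raise ValueError("region too small for the requested number of variants")
    p = 0
    pat_pos = np.sort(pool[p : p + n_pattern_consistent]); p += n_pattern_consistent
    multi_pos = pool[p : p + n_multi]; p += n_multi
    sharedr_pos = pool[p : p + n_shared_rand]; p += n_shared_rand
    private_pos = [
        pool[p + i * n_private : p + (i + 1) * n_private] for i in range(len(crosses))
    ]

    def snp_alleles():
        ref, alt = rng.choice(4, 2, replace=False)
        return _SNP_ALLELES[ref], [str(_SNP_ALLELES[alt])]

    def tri_alleles():
        a = rng.choice(4, 3, replace=False)
        return _SNP_ALLELES[a[0]], [str(_SNP_ALLELES[a[1]]), str(_SNP_ALLELES[a[2]])]

    causal_ref = "G" + "".join(rng.choice(list("ACGT"), 6))
    shared_alleles = {
        int(pos): snp_alleles() for pos in np.concatenate([pat_pos, sharedr_pos])
    }
    multi_alleles = {int(pos): tri_alleles() for pos in multi_pos}
    shared_freq = {int(pos): rng.uniform(0.1, 0.9) for pos in sharedr_pos}

    panels = []
    for ci, cross in enumerate(crosses):
        founders = list(cross.founder_ids)
        sires = cross.f1_sire_ids
        samples = founders + sires
        rows = np.array([cross.row(s) for s in samples])
        qtl_hap = cross.haplotypes[rows][:, :, cross.truth["qtl_index"]]  # (ns, 2) Q=1

        positions, refs, alts, genos = [], [], [], []

        def add(pos, ref, alt, g):
            positions.append(int(pos)); refs.append(str(ref)); alts.append(list(alt))
            genos.append(g)

        # planted causal deletion: alt allele (index 1) tracks Q exactly
        if n_causal:
            add(qtl_bp, causal_ref, [causal_ref[0]], qtl_hap.astype(np.int8))

        # pattern-consistent variants: full LD with the QTL
        for pos in pat_pos:
            ref, alt = shared_alleles[int(pos)]
            add(pos, ref, alt, qtl_hap.astype(np.int8))

        # shared + private random biallelic variants
        for pos in sharedr_pos:
            ref, alt = shared_alleles[int(pos)]
            g = (rng.random((len(samples), 2)) < shared_freq[int(pos)]).astype(np.int8)
            add(pos, ref, alt, g)
        for pos in private_pos[ci]:
            ref, alt = snp_alleles()
            f = rng.uniform(0.1, 0.9)
            g = (rng.random((len(samples), 2)) < f).astype(np.int8)
            add(pos, ref, alt, g)

        # multi-allelic decoys (shared positions, three observed alleles)
        for pos in multi_pos:
            ref, alt = multi_alleles[int(pos)]
            g = rng.choice(3, size=(len(samples), 2), p=[0.5, 0.3, 0.2]).astype(np.int8)
            # force all three alleles observed
            g[0] = (0, 1); g[1] = (1, 2)
            add(pos, ref, alt, g)

        order = np.argsort(positions)
        geno_arr = (
            np.asarray(genos, dtype=np.int8)[order]
            if genos
            else np.zeros((0, len(samples), 2), dtype=np.int8)
        )
        panels.append(
            VariantPanel(
                chrom=chrom,
                positions=np.asarray(positions, dtype=np.int64)[order],
                ref=[refs[i] for i in order],
                alt=[alts[i] for i in order],
                sample_ids=samples,
                genotypes=geno_arr,
                region=region,
                cross_id=cross.cross_id,
            )
        )
        if n_causal:
            cross.truth["causal_variant_pos"] = int(qtl_bp)

    motifs = _plant_motifs(
        rng, region, chrom, qtl_bp, causal_ref, causal_in_motif,
        forbidden=np.unique(np.concatenate([p.positions for p in panels])),
        n_decoys=n_decoy_motifs,
    )
    return panels, motifs


def _plant_motifs(rng, region, chrom, qtl_bp, causal_ref, causal_in_motif, forbidden, n_decoys):
    starts, ends, labels = [], [], []
    span_lo, span_hi = qtl_bp + 1, qtl_bp + len(causal_ref) - 1  # deleted bases, 1-based
    if causal_in_motif:
        starts.append(span_lo - 1 - 4)        # BED start, small pad
        ends.append(span_hi + 4)
        labels.append("mrf_site")
    width = 15
    tries = 0
    while len(starts) < n_decoys + int(causal_in_motif) and tries < 10_000:
        tries += 1
        s = int(rng.integers(region.start - 1, region.end - width))
        lo1, hi1 = s + 1, s + width     # 1-based occupied bases
        if not causal_in_motif and not (hi1 < span_lo or lo1 > span_hi):
            continue
        if np.any((forbidden >= lo1 - 8) & (forbidden <= hi1 + 8)):
            continue
        if any(not (hi1 < a + 1 or lo1 > b) for a, b in zip(starts, ends)):
            continue
        starts.append(s)
        ends.append(s + width)
        labels.append(f"decoy_{len(starts)}")
    order = np.argsort(starts)
    return MotifTrack(
        chrom=chrom,
        starts=np.asarray(starts)[order],
        ends=np.asarray(ends)[order],
        labels=[labels[i] for i in order],
    )


# ---------------------------------------------------------------------------
# Persistence of a simulated cross (text formats only)

def save_cross(cross: CrossData, outdir, config: CrossConfig | None = None) -> None:
    """Write a cross to ``outdir``: PED/MAP genotypes, pedigree/phenotype
    tables, phased haplotypes and origins, and the truth record."""
    import os

    from . import qcio

    os.makedirs(outdir, exist_ok=True)
    j = os.path.join
    qcio.write_ped_map(j(outdir, "cross.ped"), j(outdir, "cross.map"),
                       cross.pedigree, cross.genotypes(), cross.gmap)
    cross.pedigree.to_csv(j(outdir, "pedigree.tsv"), sep="\t", index=False)
    if cross.phenotypes is not None:
        ped = cross.pedigree.set_index("id")
        tab = cross.phenotypes.copy()
        for col in ("sire", "dam", "sex", "batch", "carcass_weight"):
            tab.insert(1, col, ped.loc[tab["id"], col].to_numpy())
        tab.to_csv(j(outdir, "phenotypes.tsv"), sep="\t", index=False)
    for name, arr in (("haplotypes", cross.haplotypes), ("origins", cross.origins)):
        with open(j(outdir, f"{name}.tsv"), "w") as fh:
            fh.write("id\thap\talleles\n")
            for i, ind in enumerate(cross.ids):
                for h in (0, 1):
                    fh.write(f"{ind}\t{h}\t{''.join(map(str, arr[i, h]))}\n")
    truth = {
        k: (int(v) if np.isscalar(v) and not isinstance(v, str) else v)
        for k, v in cross.truth.items()
        if k in ("qtl_index", "qtl_chrom", "qtl_bp", "causal_variant_pos")
    }
    truth["sire_qtl"] = dict(cross.truth.get("sire_qtl", {}))
    truth["qtl_genotype"] = [int(x) for x in cross.truth["qtl_genotype"]]
    truth["cross_id"] = cross.cross_id
    with open(j(outdir, "truth.yaml"), "w") as fh:
        yaml.safe_dump(truth, fh)
    if config is not None:
        config.to_yaml(j(outdir, "config.yaml"))


def load_cross(outdir) -> CrossData:
    """Reload a cross written by :func:`save_cross`."""
    import os

    from . import qcio

    j = os.path.join
    gmap = qcio.read_map(j(outdir, "cross.map"))
    pedigree = pd.read_csv(j(outdir, "pedigree.tsv"), sep="\t",
                           dtype={"id": str, "sire": str, "dam": str})
    pedigree["breed"] = pedigree.get("breed", "").fillna("")
    n, m = len(pedigree), gmap.n_markers
    arrays = {}
    for name in ("haplotypes", "origins"):
        arr = np.zeros((n, 2, m), dtype=np.int8)
        tab = pd.read_csv(j(outdir, f"{name}.tsv"), sep="\t", dtype=str)
        row = {v: i for i, v in enumerate(pedigree["id"])}
        for ind, h, alleles in tab.itertuples(index=False):
            arr[row[ind], int(h)] = np.frombuffer(alleles.encode(), dtype=np.uint8) - ord("0")
        arrays[name] = arr
    with open(j(outdir, "truth.yaml")) as fh:
        truth = yaml.safe_load(fh)
    truth["qtl_genotype"] = np.asarray(truth["qtl_genotype"], dtype=np.int8)
    cross_id = truth.pop("cross_id", "")
    phen_path = j(outdir, "phenotypes.tsv")
    phenotypes = None
    if os.path.exists(phen_path):
        tab = pd.read_csv(phen_path, sep="\t", dtype={"id": str})
        keep = [c for c in tab.columns
                if c not in ("sire", "dam", "sex", "batch", "carcass_weight")]
        phenotypes = tab[keep]
    return CrossData(
        pedigree=pedigree, gmap=gmap, haplotypes=arrays["haplotypes"],
        origins=arrays["origins"], truth=truth, phenotypes=phenotypes,
        cross_id=cross_id,
    )
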