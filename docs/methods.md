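# Methods

This note records the models implemented in `crossfsv`, the assumptions and
defaults behind them, and the places where the design was genuinely open.

## The synthetic two-cross design

`simcross` emulates two F2 intercrosses between divergent founder breeds.
Breed A ("Western") founders carry the low allele q, breed B ("Asian-like")
founders the high allele Q, fixed by default (`freq_breed_a = 0`,
`freq_breed_b = 1`), so every F1 is Q/q and the F2 segregates 1:2:1.  The
factory configurations mirror the two cohorts the design targets: a large
cross (17 × 19 founders, 91 F1, 1105 F2) and a small one (9 × 5 founders,
36 F1, 345 F2).

**Meiosis** is interference-free: each inter-marker interval recombines
independently with probability given by the Kosambi map function
`r = tanh(2m)/2`.  The map function implies interference at the scale of map
distances; modelling crossover interference mechanistically is out of scope,
and marker-pair recombination fractions still match the Kosambi distances,
which is what the linkage machinery consumes.

**Traits.**  Two traits (a redness-like and an intramuscular-fat-like
phenotype) follow

    y_t = μ_t + sex + batch + β_t·carcass + a_t·x_add + d_t·x_dom + u_t + e_t

with `x_add ∈ {−1,0,1}`, `x_dom ∈ {0,1,0}`, polygenic effects
`u ~ N(0, A σg²)` sampled through the Cholesky factor of the pedigree
relationship matrix, and residuals correlated across traits (default
r = 0.3).  Defaults are `σg² = σe² = 1` per trait.  The QTL effect is tuned
by a variance share: `a = sqrt(2·s/(1−s)·(σg²+σe²))` gives the QTL a share
`s` (default 0.25) of F2 phenotypic variance — the share is a calibration
choice, not an empirical fact, picked so that a 1000-animal cross has
comfortable but not overwhelming power.  Dominance defaults to zero
("mostly additive"); it is configurable.  Sexes alternate and batches are
assigned per sibling pair so sex and batch stay jointly estimable at any n;
carcass weight is an independent normal covariate (mean 79.2 or 69.7 kg,
SD 12.6), matching the role it plays as a fixed-effect adjustment.

**Prescribed sire genotypes.**  With Q fixed in breed B every F1 sire is
heterozygous, so the segregation-analysis design (8 segregating and 4
non-segregating sires) cannot arise.  `sire_qtl_pattern` forces the QTL
genotype of each F1 sire: breed-B dams are set Q/q at the QTL marker so the
forced transmission remains Mendelian-consistent, and the truth record
(including the breed allele frequency at the QTL) is updated accordingly.

**Variant panels.**  `simulate_variant_panels` genotypes each cross's
founders and F1 sires over a focal region: multi-allelic decoys (default
10% of the random variants), random biallelic variants (half shared across
crosses, half cross-private so the intersection filter has work to do),
exactly `n_pattern_consistent` variants in full LD with the QTL, and one
planted causal 6-bp deletion at the QTL position, VCF-style (REF holds the
anchor base plus the deleted bases).  Motif intervals are placed so that
only the causal variant's deleted span overlaps one (decoy motifs avoid all
panel positions); this makes "exactly the planted variant survives the
cascade" a property of the construction, which is what the end-to-end tests
verify.

**What the simulator does not emulate:** genotyping error, missing chip
genotypes, selection or drift across generations, crossover interference,
sex chromosomes, and LD between the founder breeds beyond the two-frequency
model.  Passing tests therefore demonstrate correctness of the inference
chain under clean Mendelian data, not robustness to real-data artefacts.

## Marker QC

MAF and call rate are computed over all genotyped individuals; the exact
Hardy–Weinberg test (Levene–Haldane conditional distribution of heterozygote
counts, summing probabilities no larger than the observed one) is computed
among F2 individuals only — an F2 of divergent lines is the nearest thing to
an equilibrium cohort in this design, and the χ² approximation is unreliable
at the 10⁻⁶ threshold the pipeline uses.  Mendelian error rates are
reported per marker over informative trios; removal applies to markers.
Missing genotypes are dropped pairwise downstream.

## GRAMMAR association

Stage 1 fits `y = Xb + u + e`, `u ~ N(0, A σg²)` by REML: one
eigendecomposition of `A` turns the likelihood into a 1-D profile over
`h² = σg²/(σg²+σe²)`, optimized on a 34-point grid refined by bounded
scalar minimization (tolerance 1e-6, deterministic; ties resolve to the
grid point, which matters when the profile is flat, e.g. `A = I`).  Stage 2
regresses the residuals `y − Xb̂ − û` on each marker's minor-allele count.
This two-stage scheme is fast and slightly conservative; the test suite
asserts rejection ≤ 6% at nominal 5% on pedigree-linked null markers.

GRAMMAR is also known to *attenuate* effect sizes: the polygenic BLUP
absorbs part of any true marker effect, and the REML fit pushes the
unmodelled QTL variance into the residual component.  For reporting the
variance share of a top marker, `marker_effect_gls` therefore re-estimates
the allele effect at that single position by GLS under the fitted variance
components (this is not a genome-wide exact mixed-model scan, which remains
out of scope).  With the QTL absorbed into σ̂e², the sum σ̂g² + σ̂e² is the
phenotypic variance, and `2p(1−p)a²` over that sum recovers the simulated
phenotypic share.  The `pct_var_snp` operation itself keeps the standard
formula `100·2p(1−p)a²/σ²` with a caller-supplied denominator.

Bonferroni-adjusted per-marker p-values are reported as `p·M` capped at 1.

## Haley–Knott linkage

Line-origin probabilities per F2 haplotype use two-marker flanking
conditioning: evidence at the nearest informative marker on each side
(likelihood of the observed haplotype allele under each breed origin, using
the simulator's true breed allele frequencies when available, otherwise
founder sample frequencies) is propagated through Kosambi transition
probabilities with a uniform prior.  This is an approximation to full
multipoint computation, adequate at chip density; at a fully informative
marker the probabilities are degenerate and the F statistic provably equals
direct regression on the true genotype codes (asserted at 1e-8).

Permutation thresholds shuffle covariate-adjusted residuals across the F2
(family sizes preserved), recomputing the maximum F per shuffle via
precomputed QR projections.  The half-sib scan regresses the trait on the
paternal transmission probability within one sire family; phase comes from
the simulator (rule-based trio phasing, `qcio.trio_phase`, resolves F2
phase where a parent is homozygous and is provided for chip-only data).

## Haplotype-cluster (joint linkage/LD) scan

The HMM-based haplotype reconstruction used by dedicated software is
replaced by window-identity clustering: haplotypes identical over a
`window_markers`-wide window (default 5) share a cluster, smallest clusters
merging into their Hamming-nearest neighbour until at most K (default 20)
remain; the procedure is deterministic.  The trait, pre-adjusted for fixed
effects and the polygenic background (GRAMMAR residuals — a two-stage
stand-in for the joint fit), is then modelled with a random cluster effect
`h ~ N(0, σh² I_K)`; σh² is profiled by REML through the Woodbury identity
and LOD = log₁₀ of the REML likelihood ratio against the no-cluster model.
With a cofactor position set, that position's cluster design enters the
fixed effects (residual scan for additional signals).

LOD-drop support intervals take the outermost scanned positions with
LOD ≥ max − drop (drop 2 by default, 3 where a more conservative interval is
wanted); boundaries are reported at marker-grid resolution, 1-based
inclusive, and interval sizes in kb as `(end − start + 1)/1000` rounded to
0.1 — the convention that reproduces the published 718.4 / 858.6 / 488.1 kb
arithmetic.

**Bimodality of cluster effects.**  The BLUP cluster effects at the maximum
are split by exact 1-D two-means; the verdict is "bimodal" (supporting a
biallelic QTL) when `|m₁ − m₂| / pooled within-group SD` exceeds the
threshold.  The optimal split of a *unimodal* Gaussian sample already
yields separations near 3, so the default threshold is 4.0 — about the 95th
null percentile at 20 effects — giving ≥ 95% specificity while clearly
separated modes score ≥ 13.

## MASA

For each F1 sire the paternal transmission coefficient
`x = P(hap₁) − P(hap₂) ∈ [−1, 1]` spans two paternal alleles, so the fixed
slope tested is `α/2` where α is the allele substitution effect taken from
the across-family Haley–Knott fit at the same position.  The log₁₀
likelihood ratio profiles the residual variance out under each hypothesis:
`LR = (n/2)·log₁₀(RSS₀ / min(RSS₊, RSS₋))`, the minimum over both sire
phases.  Calls: heterozygous above +2, homozygous below −2, undetermined
between (the printed rule "homozygous if score > −2" contradicts the
undetermined band and is implemented as < −2).  Undetermined sires impose
no constraint in the segregation-pattern filter; variants with missing
genotypes in a called sire fail it (conservative).  Family minimum size is
10 by default.

## Candidate cascade

Stage 1 keeps variants with exactly two *observed* alleles across founders
and sires (the bimodal haplotype-effect distribution implies two functional
alleles).  Stage 2 applies the sire calls.  Stage 3 intersects crosses by
position, REF and ALT.  Stage 4 keeps variants whose footprint — a single
base for SNPs, the deleted span for deletions — overlaps a motif interval
(BED half-open converted to 1-based inclusive).  Counts are monotone
non-increasing and stages 1–2 commute.

## Fine-mapping

For a causal configuration c, `Z ~ N(0, Σ + σ²·Σ I_c Σ)` with Σ the LD
correlation matrix (pairwise-complete Pearson r of genotype codes,
ε = 1e-4 ridge if not PSD) and σ the prior non-centrality scale.
Configurations up to size k carry the prior `γ^|c|(1−γ)^(m−|c|)`;
enumeration is exhaustive (capped at 10⁶ configurations), accumulated in
log space, and matches an independent full-2^m oracle to 1e-10.  Priors are
not derivable from the study design; the defaults γ = 0.01, σ = 5.2, k = 2
follow the published CAVIAR defaults and are configurable.

The ρ-credible set grows greedily by PIP (ties by position) until the
summed posterior of non-null configurations fully contained in the set
reaches ρ; excluding the null mass makes the set slightly conservative.
CLPP is the per-variant product of the two traits' PIPs with a 0.99
colocalization threshold.  When the signal is far stronger than the σ prior
(|Z| ≈ 20), pair configurations dominate and two variants can share
PIP ≈ 1; the causal variant then *ties* for the maximal CLPP, which is how
the acceptance run counts recovery.  Fine-mapping runs per cross and per
trait; missing genotypes are mean-imputed with a warning.

## Diversity statistics

π uses the per-site unbiased estimator `Σ [nᵢ/(nᵢ−1)]·2p̂ᵢ(1−p̂ᵢ) / L` with
nᵢ the called alleles at site i (sites with nᵢ < 2 skipped); with complete
data this equals the all-pairs average Hamming distance per bp exactly
(asserted to 1e-12).  Tajima's D evaluates the standard constants at
`n* = round(mean per-site called alleles)` — a lightweight missing-data
adjustment; exact per-site weighting in the style of the dedicated
estimators would be a natural extension.  D is undefined (an error, not
zero) with no segregating sites; the region is aggregated as a whole.
Indel sites are expected to be excluded by the caller; the estimators treat
sites as biallelic SNPs.

## Problem sizes used by the test and acceptance runs

Unit and acceptance tests simulate one 120-marker, 120-cM chromosome
(~1 Mb/cM).  Recovery checks use ten (tests) or five (acceptance script)
replicate 1000-F2 crosses at the 25% QTL share; MASA checks use the
prescribed 8 + 4 sire design with 80 offspring per family and a 40% share
("strong QTL"); credible-set coverage uses 200 (tests) or 100 (script)
simulated 30-variant LD regions; permutation calibration uses 100 (tests)
or 60 (script) null traits at 200 permutations each.  These sizes keep the
whole suite within a few CPU-minutes while leaving the binomial acceptance
margins meaningful.

## Known limitations

- Flanking-marker conditioning (not full multipoint) for transmission
  probabilities; fine at chip density, degrades with sparse or uninformative
  maps.
- The haplotype-cluster scan adjusts for the polygenic background in two
  stages rather than jointly; LOD scales can differ slightly from a joint
  fit.
- The MASA likelihood assumes a Gaussian trait within families and takes
  the substitution effect as known.
- Kinship is pedigree-based throughout (no marker-based genomic
  relationship matrix).
- Exhaustive configuration enumeration limits fine-mapping to regions where
  C(m, k) stays below the cap; no stochastic search is provided.
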