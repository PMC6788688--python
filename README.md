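# crossfsv

Genetic-inference toolkit for F2 intercross designs: from a two-cross QTL
mapping experiment all the way down to a single candidate causal regulatory
variant.

Experimental crosses between divergent livestock breeds segregate large-effect
QTL, but a chip-based association peak spans megabases and thousands of
sequence variants.  `crossfsv` implements the full chain used to close that
gap, aimed at quantitative geneticists working with pedigreed intercross
cohorts:

- **GRAMMAR association** — a polygenic mixed model
  `y = Xb + u + e`, `u ~ N(0, A σg²)` with `A` the pedigree relationship
  matrix, is fitted by REML; per-marker tests regress the residuals on
  additive genotype codes.  Bonferroni (`0.05/M`) and suggestive (`1/M`)
  thresholds, the genomic inflation factor
  `λ = median(χ²)/0.4549`, and the variance share of the top SNP
  `%Var = 100·2p(1−p)a²/σ²` are reported.
- **Haley–Knott interval mapping** — line-origin probabilities from flanking
  markers under the Kosambi map function (`r = ½·tanh(2m)`), F-statistic
  profiles, `%Var_QTL = 100·(RSS_reduced − RSS_full)/RSS_reduced`, and
  empirical significance by trait permutation.  Half-sib versions scan for
  segregation within single sire families.
- **Joint linkage/LD (founder-haplotype) mapping** — haplotypes are grouped
  into K clusters per position and fitted as a random effect next to the
  polygenic term; LOD-drop support intervals from the profile, intersected
  across crosses to a shared critical region.
- **MASA** — each F1 sire's QTL genotype is called from its half-sib family
  by a log₁₀ likelihood-ratio test (heterozygous > 2, homozygous < −2,
  otherwise undetermined).
- **Candidate-variant cascade** — biallelic → sire-segregation-pattern →
  cross-intersection → regulatory-motif overlap, shrinking thousands of
  sequence variants to a handful of functional candidates.
- **Bayesian fine-mapping** — CAVIAR-style posteriors over causal
  configurations from Z-scores and LD (`Z ~ N(0, Σ + σ²·Σ I_c Σ)`), 99%
  credible sets, and eCAVIAR-style colocalization
  (`CLPP = PIP_trait1 × PIP_trait2`).
- **Population diversity** — nucleotide diversity π and Tajima's D with
  missing-data adjustments, plus per-population allele frequencies of a
  focal variant.

Because intercross genotype data of this kind is not publicly deposited, the
package ships a first-class simulator (`crossfsv.simcross`) that generates
pedigreed two-cross cohorts with a planted pleiotropic QTL, sequence-variant
panels with a planted causal deletion inside a motif interval, and all the
file formats the tools consume (PED/MAP, minimal VCF, BED, TSV).

## Worked example

Simulate two crosses sharing a planted causal variant (configs follow
`CrossConfig`; `qtl.bp: null` places the QTL on the middle map marker), then
run the chain:

```bash
crossfsv simulate --config lk.yaml --config dk.yaml --out sim --seed 7 \
    --map-markers 120 --map-spacing-cm 1
# wrote sim/LK: 960 F2, 120 markers
# wrote sim/DK: 400 F2, 120 markers
# wrote panels (200 variants) and motifs.bed

crossfsv gwas --ped sim/LK/cross.ped --map sim/LK/cross.map \
    --pheno sim/LK/phenotypes.tsv --trait trait1 --out gwas.tsv
# h2=0.697 lambda=50.095 bonferroni=0.000417

crossfsv lald --dir sim/LK --trait trait1 --step 2 --out lod_lk.tsv
# max LOD 63.42 at 59626599; 2.0-LOD drop interval 1:59626599-61772431 (2145.8 kb)

crossfsv masa --dir sim/LK --trait trait1 --position-cm 60 --out sires_lk.tsv
# 12 sires: 7 heterozygous, 2 homozygous, 3 undetermined

crossfsv fsv-filter --vcf-a sim/panel_LK.vcf --vcf-b sim/panel_DK.vcf \
    --sires-a sires_lk.tsv --sires-b sires_dk.tsv \
    --motifs sim/motifs.bed --report cascade.tsv
# input:200 -> biallelic:183 -> pattern:26 -> intersected:26 -> motif:1
```

Reading the numbers: `h2` is the REML heritability of the adjusted trait and
`lambda` the genomic inflation of the scan — far above 1 here because the
simulated genome is a single chromosome harbouring a strong QTL, so most
markers are genuinely associated.  The LOD-drop interval brackets the
maximum of the haplotype-cluster profile.  MASA calls 7 of the 8 truly
segregating sires heterozygous and none in the wrong direction; the cascade
then narrows 200 panel variants to exactly one — the planted 6-bp promoter
deletion (the surviving position in `cascade.tsv` matches
`causal_variant_pos` in `sim/LK/truth.yaml`).

Interval arithmetic works on published coordinates directly:

```bash
crossfsv intersect --intervals '[["12",54842795,55561243],["12",55073130,55931714]]'
# 12:55073130-55561243   488.1 kb
```

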