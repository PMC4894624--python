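# Methods

This note documents the models, the numerical choices, and what the
simulator does and does not emulate.

## Data model and conventions

Genotypes are diallelic codes counting copies of the variant's minor
allele: −1 missing, 0 `dd`, 1 `Dd`, 2 `DD`. The PED/MAP reader assigns a
*provisional* orientation (the rarer sample allele is minor, ties broken
alphabetically); the frequency-estimation step finalizes it, because the
population — not the sample — defines which allele is rare. Coordinates
are 1-based bp and sex-averaged Haldane cM. PLINK conventions are used for
sex (1/2) and affection (1 unaffected, 2 affected, other unknown).
Half-specified parents (exactly one parent id) are rejected as malformed
rather than auto-created: founder counts must stay well defined for the
bit-size formula `2·(non-founders) − (founders)`. Pedigrees must be
acyclic; a topological pass detects cycles at construction.

Kinship is computed by the recursive tabular method processing parents
before children: φ(i,i) = ½ + ½·φ(father, mother) and, for j earlier in
the order, φ(i,j) = ½·(φ(father,j) + φ(mother,j)). Pair classification is
`parent_offspring` iff one member is the *recorded* parent of the other,
`other_blood_relative` iff φ > 0 otherwise, else `unrelated`.

## Weighted allele frequency

`f_w = (n f_s + m f_e)/(n + m)`, a convex combination, monotone in each
argument, with `f_w = f_s` when no external record exists. `n` counts
*observed* sample alleles (2 × non-missing genotypes), over all genotyped
members rather than founders only — the estimate is therefore slightly
enriched for alleles segregating in the families, a known limitation of
sample frequencies that the external panel term is meant to dilute. Any
allele observed at least once has `f_w > 0`, which is the property that
matters downstream (a frequency of exactly 0 for an observed allele breaks
likelihood-based engines). An exact `f_w = 0.5` tie resolves to the
alphabetically first allele for reproducibility. For variants monomorphic
in the sample the second allele has no name in a PED file; if an external
record names a different allele than the observed one, that identity is
adopted as the minor allele.

## Segregation scores

The score for a variant under a disease model is the product of
per-individual weights; the defaults (dominant 0.8/0.5/0.1/0.01, recessive
0.5/0.1/0.1, all other cells 1) encode roughly 50% detection sensitivity,
a 20% heterozygote-to-homozygote miscall rate and a 10% false-positive
rate, and are user-overridable within (0, 1]. Missing genotypes and
unknown phenotypes contribute a neutral factor 1 — absence of evidence is
not a violation. The score is multiplicative over disjoint sets of
individuals, so a joint all-family score and a per-family score (row
subset) are both exposed; per-family scoring is the natural mode when each
family may carry its own private mutation. Ranking is by descending score
with genomic-order tie-breaking, making output deterministic.

## Weighted-sum burden test

Per variant, `q_j = (m_j + 1)/(2 n_U + 2)` is the minor-allele frequency
among genotyped unaffected individuals at that variant with a +1
pseudo-count; `w_j = √(n_j q_j (1 − q_j))` with `n_j` the genotyped count;
individual burdens are `γ_i = Σ_j c_ij / w_j` (missing genotypes
contribute 0); the statistic is the rank-sum (midranks for ties) of
burdens over affected individuals.

The permutation null permutes affection labels **and recomputes the
control-derived weights for every permuted labelling**. This is essential:
with weights frozen at the observed labels the statistic is adapted to the
observed controls, and the test is anti-conservative (in a null
calibration of this implementation the mean p-value was 0.44 rather than
0.5). With recomputation, null p-values pass a Kolmogorov–Smirnov
uniformity check (asserted in the test suite).

When the number of distinct labellings C(n, n_affected) is ≤ 10,000 the
enumeration is exhaustive and p = #{x_perm ≥ x}/total is exact; otherwise
p = (1 + #{x_perm ≥ x})/(1 + B) over B Monte-Carlo draws (default 1,000).
z standardizes x against the permutation distribution. Degenerate genes
(all burdens equal) report p = 1, z = 0, flagged. If a variant has no
genotyped unaffected individuals, `q_j` falls back to the external
frequency with the same pseudo-count, `(f_e m + 1)/(m + 2)`, flagged in
the output. Labels are permuted freely across families by default —
appropriate for unrelated cases; a within-family block permutation is
available when relatedness should be preserved under the null. Per-gene
Monte-Carlo streams are seeded from (seed, gene id), so results are
independent of gene evaluation order.

## Compound-heterozygosity rules

Variant-level rules with a proportion relaxation (default 0.95, strict at
1.0): R1 — fraction of genotyped affected individuals heterozygous; R2 —
fraction of genotyped unaffected individuals *not* homozygous-minor; R3 —
among affected children heterozygous at the variant with both parents
genotyped, fraction with at most one heterozygous parent. Gene level:
R4 — at least two variants passing R1∧R2∧R3; R5 — at least one passing
variant with paternal and one with maternal transmission evidence.
Transmission is assigned only when exactly one genotyped parent carries
the minor allele; two-carrier configurations are phase-ambiguous and
contribute nothing. R5 is skipped (``auto``) when any affected child has
an affected parent, since every disease allele then descends from that
parent.

Empty denominators: a variant with no genotyped affected individual fails
R1 (no supporting evidence), while empty R2/R3 denominators pass vacuously
(nothing can violate them). The relaxation denominator is affected
individuals for R1/R2 and informative affected children for R3.

## Genetic map and marker selection

Genetic positions are linear in bp between reference-map anchors; beyond
the anchor span the terminal segment's slope is extended and clipped at
0 cM (reference maps rarely cover telomeres). The Haldane map function
θ = ½(1 − e^(−2d/100)) (d in cM) converts distances to recombination
fractions, with the exact inverse d = −50·ln(1 − 2θ).

Marker selection applies three filters in order: weighted MAF > 0.2;
VIF pruning over sliding windows (50 variants, step 5) removing the
worst-VIF variant while any VIF = 1/(1 − R²) exceeds the threshold
(default 1 + 1e-9, i.e. numerically uncorrelated); and a left-to-right
greedy scan dropping variants closer than 0.5 cM to the last kept one.
R² regresses mean-imputed {0,1,2} dosages on the other retained window
members. Two caveats are deliberate: an exact VIF of 1 is unattainable
with sampled dosages, so the epsilon reading makes the default very
aggressive (with finite samples most correlated markers go, often leaving
few per window — consistent with demanding complete independence); and the
window sweep is iterated to a fixed point so that pruning a pruned set
changes nothing (idempotence would otherwise be broken by window-boundary
shifts as variants drop out).

## IBD sharing and regions

A pair is eligible if both members are affected, in the same family,
related by blood, and not parent–offspring. At each grid position a pair
with 1 − p0 strictly greater than the pair threshold (default 0.5) counts
as an IBD pair; the statistic is the fraction of IBD pairs among eligible
pairs with records at that position, pooled across families by default
(per-family tracks optional; the pooled value is the eligible-pair-count
weighted mean of per-family values). Variants take the value of the grid
point at or immediately left of their cM position; variants outside the
grid span take the nearest endpoint and are flagged. Regions are maximal
runs of grid points strictly beyond the threshold ("greater than" is
strict), reported with peak value and grid-point count. The caller also
serves LOD-style tracks (direction ``above``) and p-value tracks
(``below``).

## Simulator

Founder haplotypes are i.i.d. Bernoulli draws from the frequency spectrum
(default 80% rare, MAF ~ U(0.001, 0.01); 20% common, U(0.05, 0.5)) at
variant positions placed uniformly on a 100 cM region (1 cM ≈ 1 Mb);
variants are partitioned into consecutive blocks as genes (default 10).
Meioses start on a random parental haplotype and switch between adjacent
positions with probability θ(gap). Dropping is haplotype-level: true IBD
states at grid points derive from founder-haplotype labels, and trans
configurations are well defined. Templates: a nuclear family (2 children)
and a 12-member three-generation family (4 founders, 8 non-founders, bit
size 12).

Scenario injection: scen1 places one private rare causal variant per
family on a founder haplotype (for a recessive model a second founder also
carries), assigns affection by the disease model with penetrance (default
1.0) and phenocopy (default 0.0) rates, and resamples the family until at
least one affected non-parent-offspring pair plus one unaffected member
exist (cap 1,000, then error). scen2 simulates 10 unrelated affected
singletons — each heterozygous for a distinct causal variant in one
designated 10-variant gene — plus 10 unaffected singleton controls. scen3
simulates nuclear families whose affected child inherits one causal
variant from each parent (alleles are written onto the transmitted founder
haplotypes, so the data stay Mendelian-consistent and the configuration is
trans by construction); the single-carrier-parent design means no
unaffected member can be homozygous for a causal allele. The null scenario
fixes the template's affected pattern (nuclear: one child; 12-member: two
cousins) independent of genotypes. The genotyping-error channel
(heterozygote miscalls to a random homozygote, false heterozygotes,
missingness) runs last.

The desk-scale strategy comparison ranks the shared gene universe by the
best per-variant segregation score (dominant model) and by the
weighted-sum z, over 100 replicates per scenario; sensitivity/specificity
are aggregated over rank cutoffs and the AUC difference gets a bootstrap
SE over replicates (200 resamples). These sizes keep the whole comparison
under a minute while leaving the AUC ordering many standard errors wide.

What the simulator does **not** emulate: linkage disequilibrium beyond
physical linkage within simulated pedigrees (founder haplotypes are drawn
site-independently), sequencing-read-level error structure, population
stratification, de novo mutations, indels, or sex chromosomes. Passing
tests therefore demonstrate correctness of the statistical machinery under
clean Mendelian transmission, not robustness to every artifact of real
sequencing data.

## Pipeline

Stage order is fixed: map update → allele-frequency estimation → pruning →
{disease-model identification, IBD sharing} → region calling. Chromosomes
are processed as independent sequential batches; every stage is
deterministic given the seed, so outputs are byte-identical across runs
and batchings (floats are serialized with a fixed `%.6g` format). The
merged results table has exactly one row per input variant — pruning
restricts analysis sets, never the reporting universe. Exit codes: 0
success, 2 validation error (nothing written), 3 stage failure.

## Known limitations

- Sample allele frequencies use all genotyped members; within-family
  allele correlation inflates `n` relative to the effective number of
  independent alleles.
- The free permutation of the weighted-sum test ignores relatedness; use
  the within-family mode for related samples.
- The strict VIF = 1 default is intentionally severe; users wanting
  PLINK-like behavior should raise `vif_max` to 1.5–2.
- Autosomal, diallelic variants only.
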