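"""Disease-model identification: three strategies for prioritizing variants
or genes responsible for Mendelian disorders in family sequencing data.

1. **Segregation scores** (per variant, dominant and recessive models):
   a multiplicative score over all individuals where genotype/phenotype
   combinations inconsistent with the assumed model receive sub-unit
   weights.  The weights tolerate genotyping error, so a single violating
   call penalizes rather than eliminates a variant.  Variants are ranked by
   score; the score of a perfectly co-segregating variant is 1.

2. **Weighted-sum statistic** (per gene): a burden statistic summing
   inverse-frequency-weighted minor-allele counts per individual, tested by
   the rank-sum of affected individuals against a permutation null.  Suited
   to genes hit by *different* mutations in different cases.

3. **Compound-heterozygosity filtering rules** (per gene): five rules
   capturing two heterozygous hits inherited in trans, with a proportion
   relaxation to tolerate genotyping error and an exception to the
   two-parental-origins rule when a parent is affected.

Genotype codes and the D (minor = presumed disease allele) / d (major)
orientation come from :mod:`pedpipe.pedio` and :mod:`pedpipe.afe`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .pedio import (AFFECTED, HET, HOM_MAJOR, HOM_MINOR, MISSING, UNAFFECTED,
                    UNKNOWN, GenotypeMatrix, Pedigree)

DOMINANT = "dominant"
RECESSIVE = "recessive"

_EXHAUSTIVE_LIMIT = 10_000


@dataclass
class SegregationScoreParams:
    """Per-individual weights for genotype/phenotype combinations that
    violate the assumed disease model.

    Defaults reflect roughly 50% detection sensitivity, a 20% rate of
    heterozygotes miscalled as homozygotes, and a 10% false-positive call
    rate.  Combinations not listed (and missing genotypes or unknown
    phenotypes) score 1.  All weights must lie in (0, 1].
    """
    dom_affected_hom_minor: float = 0.8
    dom_affected_hom_major: float = 0.5
    dom_unaffected_het: float = 0.1
    dom_unaffected_hom_minor: float = 0.01
    rec_affected_het: float = 0.5
    rec_affected_hom_major: float = 0.1
    rec_unaffected_hom_minor: float = 0.1

    def __post_init__(self):
        for name, value in self.__dict__.items():
            if not 0 < value <= 1:
                raise ValueError(f"weight {name} = {value} outside (0, 1]")

    def weight_table(self, model: str) -> np.ndarray:
        """Weight lookup indexed by [phenotype, genotype code + 1] with
        phenotype 0 = affected, 1 = unaffected, 2 = unknown and genotype
        codes -1 (missing), 0 (dd), 1 (Dd), 2 (DD)."""
        w = np.ones((3, 4))
        if model == DOMINANT:
            w[0, HOM_MINOR + 1] = self.dom_affected_hom_minor
            w[0, HOM_MAJOR + 1] = self.dom_affected_hom_major
            w[1, HET + 1] = self.dom_unaffected_het
            w[1, HOM_MINOR + 1] = self.dom_unaffected_hom_minor
        elif model == RECESSIVE:
            w[0, HET + 1] = self.rec_affected_het
            w[0, HOM_MAJOR + 1] = self.rec_affected_hom_major
            w[1, HOM_MINOR + 1] = self.rec_unaffected_hom_minor
        else:
            raise ValueError(f"unknown disease model {model!r}; "
                             f"use {DOMINANT!r} or {RECESSIVE!r}")
        return w


def phenotype_vector(pedigrees: list[Pedigree],
                     genotypes: GenotypeMatrix) -> np.ndarray:
    """Phenotype index per genotype row: 0 affected, 1 unaffected, 2 unknown."""
    status = {}
    for ped in pedigrees:
        for ind in ped.members:
            status[(ped.family_id, ind.individual_id)] = ind.affection
    lookup = {AFFECTED: 0, UNAFFECTED: 1, UNKNOWN: 2}
    return np.array([lookup[status.get(s, UNKNOWN)] for s in genotypes.samples],
                    dtype=np.int64)


def segregation_score(genotypes: GenotypeMatrix, variant_id: str,
                      phenotypes: np.ndarray, model: str,
                      params: SegregationScoreParams | None = None) -> float:
    """Segregation score for one variant: the product over all individuals
    of the per-individual weight under the given disease model."""
    params = params or SegregationScoreParams()
    w = params.weight_table(model)
    col = genotypes.column(variant_id)
    return float(np.prod(w[phenotypes, col.astype(np.int64) + 1]))


def segregation_score_track(genotypes: GenotypeMatrix, variants: pd.DataFrame,
                            phenotypes: np.ndarray, model: str,
                            params: SegregationScoreParams | None = None,
                            family_rows: np.ndarray | None = None
                            ) -> pd.DataFrame:
    """Segregation scores for all variants (columns ``variant_id``,
    ``score``), preserving genomic order.

    ``family_rows`` restricts the product to a boolean row subset — the
    per-family scoring mode, useful when each family may carry its own
    private mutation.  Scores are multiplicative over disjoint row subsets.
    """
    params = params or SegregationScoreParams()
    w = params.weight_table(model)
    codes = genotypes.codes.astype(np.int64) + 1
    ph = phenotypes
    if family_rows is not None:
        codes = codes[family_rows]
        ph = phenotypes[family_rows]
    logw = np.log(w)[ph[:, None], codes]  # (rows, variants)
    scores = np.exp(logw.sum(axis=0))
    order = {v: k for k, v in enumerate(genotypes.variant_ids)}
    vids = variants["variant_id"].tolist()
    return pd.DataFrame({
        "variant_id": vids,
        "score": [scores[order[v]] for v in vids]})


def rank_variants_by_segregation(score_track: pd.DataFrame) -> list[str]:
    """Variant ids ranked best-first: descending score, ties broken by
    genomic order (the input row order), so rank 1 is the top candidate."""
    df = score_track.reset_index(drop=True)
    order = sorted(range(len(df)),
                   key=lambda i: (-df["score"].iloc[i], i))
    return [df["variant_id"].iloc[i] for i in order]


# ---------------------------------------------------------------------------
# Weighted-sum statistic
# ---------------------------------------------------------------------------

@dataclass
class WeightedSumResult:
    gene_id: str
    x: float                 # rank-sum of affected individuals' burden
    z: float                 # standardized against the permutation null
    p_value: float
    n_permutations: int
    exhaustive: bool         # full enumeration of label assignments
    degenerate: bool = False  # all burdens equal: no information
    external_weights: bool = False  # q_j from external frequencies (no controls)
    variant_ids: list[str] = field(default_factory=list)


def burden_scores(genotypes: GenotypeMatrix, phenotypes: np.ndarray,
                  gene_variants: list[str],
                  external_freqs: dict[str, tuple[float, int]] | None = None
                  ) -> tuple[np.ndarray, bool]:
    """Per-individual weighted minor-allele burden over a gene's variants.

    Variant weights follow the standard weighted-sum construction: the
    minor-allele frequency among unaffected individuals with a +1
    pseudo-count, q_j = (m_j + 1) / (2 n_U_j + 2), and
    w_j = sqrt(n_j q_j (1 - q_j)) with n_j the genotyped count.  The burden
    of individual i is sum_j c_ij / w_j over their observed minor-allele
    counts.  When a variant has no genotyped unaffected individuals, q_j is
    formed from the external frequency with the same pseudo-count
    (q_j = (f_e m + 1) / (m + 2)); returns a flag when that fallback fired.
    """
    counts, missing, ext_q = _burden_inputs(genotypes, gene_variants,
                                            external_freqs)
    unaff = (phenotypes == 1).astype(float)
    gamma, used_external = _burden_given_labels(counts, missing, ext_q,
                                                unaff[None, :])
    return gamma[0], used_external


def _burden_inputs(genotypes, gene_variants, external_freqs):
    cols = np.stack([genotypes.column(v).astype(float)
                     for v in gene_variants], axis=1)
    missing = cols == MISSING
    counts = np.where(missing, 0.0, cols)
    ext_q = np.full(len(gene_variants), 0.5)
    for j, vid in enumerate(gene_variants):
        if external_freqs and vid in external_freqs:
            f_e, m = external_freqs[vid]
            ext_q[j] = (f_e * m + 1.0) / (m + 2.0)
    return counts, missing, ext_q


def _burden_given_labels(counts, missing, ext_q, unaff):
    """Burdens for a batch of label assignments.

    ``unaff``: (B, n) 0/1 matrix of unaffected indicators.  The control
    frequency q_j, and hence the variant weights, are recomputed for each
    assignment — the permutation null must re-weight exactly as the
    observed analysis did.  Returns (B, n) burdens and a flag set when any
    assignment/variant fell back to the external frequency.
    """
    observed = ~missing                       # (n, nv)
    n_j = observed.sum(axis=0).astype(float)  # genotyped count per variant
    n_u = unaff @ observed                    # (B, nv)
    m_j = unaff @ counts                      # (B, nv) control minor counts
    with np.errstate(divide="ignore", invalid="ignore"):
        q = (m_j + 1.0) / (2.0 * n_u + 2.0)
    fallback = n_u == 0
    if fallback.any():
        q = np.where(fallback, ext_q[None, :], q)
    w = np.sqrt(np.maximum(n_j, 1.0)[None, :] * q * (1.0 - q))  # (B, nv)
    gamma = counts @ (1.0 / w).T              # (n, B)
    return gamma.T, bool(fallback.any())


def weighted_sum_statistic(genotypes: GenotypeMatrix, phenotypes: np.ndarray,
                           gene_variants: list[str],
                           n_permutations: int = 1000,
                           seed: int | None = None,
                           gene_id: str = "",
                           external_freqs: dict[str, tuple[float, int]] | None = None,
                           family_of: np.ndarray | None = None,
                           method: str = "auto") -> WeightedSumResult:
    """Weighted-sum burden test for one gene.

    The statistic x is the sum of (mid)ranks of the per-individual burden
    over affected individuals.  The null distribution permutes affection
    labels, recomputing the control-derived variant weights (and hence the
    burdens) under each assignment exactly as for the observed labels —
    otherwise weights adapted to the observed controls make the test
    anti-conservative.  When the number of distinct assignments C(n, n_affected)
    is at most 10,000 the enumeration is exhaustive and the p-value exact
    (p = #{x_perm >= x} / total); otherwise ``n_permutations`` Monte-Carlo
    draws give p = (1 + #{x_perm >= x}) / (1 + B).

    ``family_of`` (an integer family label per row) switches to a
    within-family permutation that shuffles labels only among members of
    the same family, preserving the relatedness structure of the labels.
    ``method`` forces ``exhaustive`` or ``monte_carlo`` instead of the
    automatic size-based choice.
    """
    if not gene_variants:
        raise ValueError("gene has no variants")
    if method not in ("auto", "exhaustive", "monte_carlo"):
        raise ValueError("method must be auto, exhaustive or monte_carlo")
    known = phenotypes != 2
    aff = (phenotypes[known] == 0)
    n, k = int(known.sum()), int(aff.sum())
    if k == 0 or k == n:
        raise ValueError("need at least one affected and one unaffected "
                         "individual with known phenotype")

    counts, missing, ext_q = _burden_inputs(genotypes, gene_variants,
                                            external_freqs)
    counts, missing = counts[known], missing[known]

    def rank_sums(aff_labels: np.ndarray) -> tuple[np.ndarray, bool]:
        """x for each (B, n) affected-label assignment, re-weighting the
        burden by that assignment's control frequencies."""
        gamma, ext = _burden_given_labels(counts, missing, ext_q,
                                          1.0 - aff_labels)
        ranks = rankdata(gamma, axis=1)  # midranks for ties
        return (ranks * aff_labels).sum(axis=1), ext

    obs = aff.astype(float)[None, :]
    x_arr, used_external = rank_sums(obs)
    x = float(x_arr[0])

    gamma_obs, _ = _burden_given_labels(counts, missing, ext_q, 1.0 - obs)
    if np.ptp(gamma_obs) == 0:
        return WeightedSumResult(gene_id, x, 0.0, 1.0, 0, exhaustive=True,
                                 degenerate=True,
                                 external_weights=used_external,
                                 variant_ids=list(gene_variants))

    use_exhaustive = (family_of is None
                      and method != "monte_carlo"
                      and (method == "exhaustive"
                           or math.comb(n, k) <= _EXHAUSTIVE_LIMIT))
    if use_exhaustive:
        combos = np.fromiter(
            (i for c in combinations(range(n), k) for i in c),
            dtype=np.int64).reshape(-1, k)
        labels = np.zeros((len(combos), n))
        labels[np.arange(len(combos))[:, None], combos] = 1.0
        x_perm, ext = rank_sums(labels)
        used_external |= ext
        total = len(x_perm)
        p = float((x_perm >= x - 1e-9).sum()) / total
        exhaustive = True
        b = total
    else:
        rng = np.random.default_rng(seed)
        labels = np.zeros((n_permutations, n))
        if family_of is None:
            for b_i in range(n_permutations):
                labels[b_i, rng.permutation(n)[:k]] = 1.0
        else:
            fam = np.asarray(family_of)[known]
            blocks = [np.flatnonzero(fam == f) for f in np.unique(fam)]
            base = aff.astype(float)
            for b_i in range(n_permutations):
                row = np.empty(n)
                for idx in blocks:
                    row[idx] = base[rng.permutation(idx)]
                labels[b_i] = row
        x_perm, ext = rank_sums(labels)
        used_external |= ext
        p = (1.0 + float((x_perm >= x - 1e-9).sum())) / (1.0 + n_permutations)
        exhaustive = False
        b = n_permutations

    sd = float(x_perm.std())
    z = 0.0 if sd == 0 else (x - float(x_perm.mean())) / sd
    return WeightedSumResult(gene_id, x, z, p, b, exhaustive=exhaustive,
                             degenerate=sd == 0,
                             external_weights=used_external,
                             variant_ids=list(gene_variants))


def weighted_sum_by_gene(genotypes: GenotypeMatrix, phenotypes: np.ndarray,
                         gene_map: pd.DataFrame, n_permutations: int = 1000,
                         seed: int | None = None,
                         external_freqs: dict[str, tuple[float, int]] | None = None
                         ) -> list[WeightedSumResult]:
    """Weighted-sum test per gene, genes in order of first appearance.

    Each gene draws its permutations from an independent stream derived
    from ``seed`` and the gene id, so results do not depend on gene
    evaluation order.
    """
    import zlib

    present = set(genotypes.variant_ids)
    out = []
    genes = list(dict.fromkeys(gene_map["gene_id"]))
    for gene in genes:
        vids = [v for v in gene_map.loc[gene_map["gene_id"] == gene,
                                        "variant_id"] if v in present]
        if not vids:
            continue
        child = np.random.SeedSequence(
            [0 if seed is None else int(seed),
             zlib.crc32(str(gene).encode())])
        out.append(weighted_sum_statistic(
            genotypes, phenotypes, vids, n_permutations,
            seed=int(child.generate_state(1)[0] % (2**31)),
            gene_id=gene, external_freqs=external_freqs))
    return out


# ---------------------------------------------------------------------------
# Compound heterozygosity
# ---------------------------------------------------------------------------

@dataclass
class CompoundHetConfig:
    """Relaxation settings for the five compound-heterozygosity rules.

    ``min_rule_proportion``: fraction of affected individuals (rules 1-2)
    or informative affected children (rule 3) that must satisfy each
    variant-level rule; 1.0 is the strict reading, 0.95 tolerates sporadic
    genotyping errors.

    ``apply_rule5``: the two-parental-origins rule is meaningless when a
    parent of an affected child is itself affected (every disease allele
    then descends from that parent), so ``auto`` skips it in that case;
    ``always``/``never`` force it on or off.
    """
    min_rule_proportion: float = 0.95
    apply_rule5: str = "auto"

    def __post_init__(self):
        if not 0 < self.min_rule_proportion <= 1:
            raise ValueError("min_rule_proportion must be in (0, 1]")
        if self.apply_rule5 not in ("auto", "always", "never"):
            raise ValueError("apply_rule5 must be auto, always or never")


@dataclass
class GeneResult:
    gene_id: str
    variant_flags: pd.DataFrame  # variant_id, r1, r2, r3, passes_123
    r4: bool
    r5: bool | None              # None when rule 5 was skipped
    passes: bool
    contributing_variants: list[str] = field(default_factory=list)


def compound_het_scan(pedigrees: list[Pedigree], genotypes: GenotypeMatrix,
                      variants: pd.DataFrame, gene_map: pd.DataFrame,
                      config: CompoundHetConfig | None = None
                      ) -> list[GeneResult]:
    """Scan genes for compound-heterozygous configurations.

    Variant-level rules (with the proportion relaxation):

    - R1: heterozygous in (a sufficient proportion of) genotyped affected
      individuals;
    - R2: not homozygous for the disease (minor) allele in genotyped
      unaffected individuals;
    - R3: among affected children heterozygous at the variant with both
      parents genotyped, at most one parent is a carrier (two heterozygous
      parents would make the child's heterozygosity uninformative for a
      single inherited copy).

    Gene-level rules: R4 requires at least two variants passing R1-R3;
    R5 requires at least one passing variant with paternal and one with
    maternal transmission evidence (a trans configuration).  Transmission
    is assigned for a heterozygous affected child only when exactly one
    genotyped parent carries the minor allele; both-carrier configurations
    are phase-ambiguous and contribute no evidence.

    Variants with no genotyped affected individual fail R1 (no supporting
    evidence); rules whose denominator is empty otherwise pass vacuously.
    Genes with no mapped variants are absent from the output.
    """
    config = config or CompoundHetConfig()
    phen = phenotype_vector(pedigrees, genotypes)
    present = set(genotypes.variant_ids)

    affected_parent_exists = _any_affected_parent_of_affected_child(pedigrees)
    skip_r5 = (config.apply_rule5 == "never"
               or (config.apply_rule5 == "auto" and affected_parent_exists))

    trios = _genotyped_trios(pedigrees, genotypes)
    aff_rows = np.flatnonzero(phen == 0)
    unaff_rows = np.flatnonzero(phen == 1)

    results = []
    for gene in dict.fromkeys(gene_map["gene_id"]):
        vids = [v for v in gene_map.loc[gene_map["gene_id"] == gene,
                                        "variant_id"] if v in present]
        if not vids:
            continue
        flags = []
        passing = []
        paternal_variants, maternal_variants = set(), set()
        for vid in vids:
            col = genotypes.column(vid)
            r1 = _proportion_rule(col[aff_rows], lambda g: g == HET,
                                  config.min_rule_proportion,
                                  empty_passes=False)
            r2 = _proportion_rule(col[unaff_rows], lambda g: g != HOM_MINOR,
                                  config.min_rule_proportion,
                                  empty_passes=True)
            r3, pat, mat = _rule3_and_transmission(col, trios,
                                                   config.min_rule_proportion)
            ok = r1 and r2 and r3
            flags.append((vid, r1, r2, r3, ok))
            if ok:
                passing.append(vid)
                if pat:
                    paternal_variants.add(vid)
                if mat:
                    maternal_variants.add(vid)
        r4 = len(passing) >= 2
        r5 = None if skip_r5 else bool(paternal_variants and maternal_variants)
        passes = r4 and (r5 is None or r5)
        results.append(GeneResult(
            gene_id=gene,
            variant_flags=pd.DataFrame(
                flags, columns=["variant_id", "r1", "r2", "r3", "passes_123"]),
            r4=r4, r5=r5, passes=passes,
            contributing_variants=passing if passes else []))
    return results


def _proportion_rule(geno: np.ndarray, good, min_prop: float,
                     empty_passes: bool) -> bool:
    obs = geno[geno != MISSING]
    if len(obs) == 0:
        return empty_passes
    return np.mean([good(g) for g in obs]) >= min_prop - 1e-12


def _rule3_and_transmission(col: np.ndarray, trios, min_prop: float):
    """Rule 3 over informative affected children plus per-variant
    transmission-origin evidence for rule 5."""
    informative = 0
    conforming = 0
    paternal = maternal = False
    for child_row, father_row, mother_row in trios:
        if col[child_row] != HET:
            continue
        gf, gm = col[father_row], col[mother_row]
        if gf == MISSING or gm == MISSING:
            continue
        informative += 1
        if int(gf == HET) + int(gm == HET) <= 1:
            conforming += 1
        father_carries = gf >= HET
        mother_carries = gm >= HET
        if father_carries and not mother_carries:
            paternal = True
        elif mother_carries and not father_carries:
            maternal = True
    r3 = True if informative == 0 else (
        conforming / informative >= min_prop - 1e-12)
    return r3, paternal, maternal


def _genotyped_trios(pedigrees, genotypes: GenotypeMatrix):
    """(child_row, father_row, mother_row) for every affected non-founder
    whose parents appear in the genotype matrix."""
    trios = []
    for ped in pedigrees:
        for ind in ped.members:
            if ind.affection != AFFECTED or ind.is_founder:
                continue
            try:
                trios.append((
                    genotypes.row_index(ped.family_id, ind.individual_id),
                    genotypes.row_index(ped.family_id, ind.father_id),
                    genotypes.row_index(ped.family_id, ind.mother_id)))
            except KeyError:
                continue
    return trios


def _any_affected_parent_of_affected_child(pedigrees) -> bool:
    for ped in pedigrees:
        for ind in ped.members:
            if ind.affection != AFFECTED or ind.is_founder:
                continue
            for pid in (ind.father_id, ind.mother_id):
                if ped[pid].affection == AFFECTED:
                    return True
    return False
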