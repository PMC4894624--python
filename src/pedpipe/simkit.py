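"""Gene-dropping pedigree simulator and ROC evaluation utilities.

Founder haplotypes are drawn independently from a configurable allele
frequency spectrum; non-founder haplotypes descend through the pedigree
with recombination governed by the Haldane map function on inter-marker
genetic gaps.  Dropping is haplotype-level, so compound-heterozygous trans
configurations and true founder-origin IBD states are well defined.

Three disease scenarios mirror the settings in which the three
disease-model identification strategies shine, plus a null:

- ``scen1_family_specific``: one private causal variant per family placed
  on a founder haplotype; affection follows the configured disease model
  with penetrance/phenocopy; families are resampled until at least two
  affected non-parent-offspring relatives exist.
- ``scen2_gene_multivariant``: unrelated affected cases, each carrying a
  distinct rare causal variant in one designated gene, plus unrelated
  unaffected controls.
- ``scen3_compound_het``: nuclear families whose affected child is
  heterozygous at two causal variants in one gene in trans (one inherited
  from each parent); unaffected members are never homozygous for either.
- ``null``: phenotypes follow a fixed template pattern independent of
  genotypes.

A genotyping-error channel (heterozygote miscalls, false heterozygotes,
missingness) is applied last.  True IBD is emitted as indicator-probability
records derived from founder-allele identity at each grid point.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genmap import haldane_theta
from .pedio import (AFFECTED, HET, HOM_MAJOR, HOM_MINOR, MISSING, UNAFFECTED,
                    GenotypeMatrix, Individual, Pedigree, make_variant_table)

SCEN1 = "scen1_family_specific"
SCEN2 = "scen2_gene_multivariant"
SCEN3 = "scen3_compound_het"
NULL = "null"

_TEMPLATES = {
    # iid, father, mother, sex
    "nuclear": [
        ("1", None, None, "male"), ("2", None, None, "female"),
        ("3", "1", "2", "male"), ("4", "1", "2", "female"),
    ],
    "three_generation_12": [
        ("1", None, None, "male"), ("2", None, None, "female"),
        ("3", "1", "2", "male"), ("4", "1", "2", "female"),
        ("5", "1", "2", "female"),
        ("6", None, None, "female"), ("7", None, None, "male"),
        ("8", "3", "6", "male"), ("9", "3", "6", "female"),
        ("10", "3", "6", "male"), ("11", "7", "4", "female"),
        ("12", "7", "4", "male"),
    ],
}

# fixed affected pattern for the null scenario (independent of genotypes)
_NULL_AFFECTED = {"nuclear": {"3"}, "three_generation_12": {"9", "11"}}


@dataclass
class SimConfig:
    """Study-design parameters for one simulated dataset.

    The defaults describe a desk-scale rare-disease design: a single
    chromosome region of 100 cM carrying 100 variants grouped into 10
    genes, a frequency spectrum dominated by rare alleles (80% with MAF
    uniform on [0.001, 0.01], 20% common with MAF uniform on [0.05, 0.5]),
    full penetrance and no phenocopies, and a clean genotyping channel.
    """
    pedigree_template: str = "three_generation_12"
    n_families: int = 1
    n_cases: int = 10            # scen2: unrelated affected singletons
    n_controls: int = 10         # scen2: unrelated unaffected singletons
    n_variants: int = 100
    n_genes: int = 10
    region_length_cm: float = 100.0
    rare_fraction: float = 0.8
    rare_maf: tuple[float, float] = (0.001, 0.01)
    common_maf: tuple[float, float] = (0.05, 0.5)
    scenario: str = NULL
    disease_model: str = "dominant"
    penetrance: float = 1.0
    phenocopy: float = 0.0
    miscall_het_to_hom: float = 0.0
    false_het_rate: float = 0.0
    missing_rate: float = 0.0
    grid_cm: float = 1.0
    emit_true_ibd: bool = True
    seed: int = 0
    max_resample: int = 1000

    def __post_init__(self):
        if self.n_variants < 1:
            raise ValueError("n_variants must be >= 1")
        for name in ("penetrance", "phenocopy", "miscall_het_to_hom",
                     "false_het_rate", "missing_rate", "rare_fraction"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} = {v} outside [0, 1]")
        if self.scenario not in (SCEN1, SCEN2, SCEN3, NULL):
            raise ValueError(f"unknown scenario {self.scenario!r}")
        if self.pedigree_template not in _TEMPLATES:
            raise ValueError(f"unknown template {self.pedigree_template!r}")


@dataclass
class TruthRecord:
    """Ground truth of one simulated dataset."""
    causal_variants: dict[str, list[str]]  # family_id -> causal variant ids
    causal_gene: str | None
    true_maf: np.ndarray
    grid_positions_cm: np.ndarray
    # (family_id, individual_id) -> (2, n_grid) founder-haplotype labels
    grid_labels: dict[tuple[str, str], np.ndarray] = field(default_factory=dict)

    def all_causal_variants(self) -> set[str]:
        return {v for vs in self.causal_variants.values() for v in vs}


@dataclass
class SimResult:
    pedigrees: list[Pedigree]
    genotypes: GenotypeMatrix
    variants: pd.DataFrame
    gene_map: pd.DataFrame
    truth: TruthRecord
    true_ibd: pd.DataFrame | None


def simulate(config: SimConfig) -> SimResult:
    """Simulate one dataset under the configured scenario.

    Genotype codes count the designated minor allele (the allele whose
    frequency the spectrum sampled), matching the orientation downstream
    modules expect; the genotyping-error channel may perturb them.
    """
    rng = np.random.default_rng(config.seed)
    n_var = config.n_variants

    var_cm = np.sort(rng.uniform(0.0, config.region_length_cm, n_var))
    mafs = _sample_mafs(rng, config)
    grid = np.arange(0.0, config.region_length_cm + 1e-9, config.grid_cm)
    merged = np.unique(np.concatenate([var_cm, grid]))
    var_idx = np.searchsorted(merged, var_cm)
    grid_idx = np.searchsorted(merged, grid)
    switch_p = haldane_theta(np.diff(merged))

    variant_ids = [f"v{j + 1:04d}" for j in range(n_var)]
    gene_ids = [f"g{j * config.n_genes // n_var + 1:03d}" for j in range(n_var)]
    variants = make_variant_table([
        dict(variant_id=variant_ids[j], chromosome="1",
             bp=int(round(var_cm[j] * 1e6)) + 1, cm=var_cm[j],
             allele_minor="A", allele_major="G", f_w=np.nan,
             gene_id=gene_ids[j])
        for j in range(n_var)])
    gene_map = pd.DataFrame({"variant_id": variant_ids, "gene_id": gene_ids})

    builder = {SCEN1: _build_scen1, SCEN2: _build_scen2,
               SCEN3: _build_scen3, NULL: _build_null}[config.scenario]
    pedigrees, sample_keys, codes, truth_cv, causal_gene, labels = builder(
        config, rng, mafs, merged, var_idx, variant_ids, gene_map)

    codes = _error_channel(codes, rng, config)
    genotypes = GenotypeMatrix(sample_keys, variant_ids, codes)

    grid_labels = {key: labs[:, grid_idx] for key, labs in labels.items()}
    truth = TruthRecord(causal_variants=truth_cv, causal_gene=causal_gene,
                        true_maf=mafs, grid_positions_cm=grid,
                        grid_labels=grid_labels)
    true_ibd = (_emit_true_ibd(pedigrees, grid, grid_labels)
                if config.emit_true_ibd else None)
    return SimResult(pedigrees, genotypes, variants, gene_map, truth, true_ibd)


def _sample_mafs(rng, config: SimConfig) -> np.ndarray:
    n = config.n_variants
    rare = rng.random(n) < config.rare_fraction
    maf = np.where(rare,
                   rng.uniform(*config.rare_maf, n),
                   rng.uniform(*config.common_maf, n))
    return maf


# ---------------------------------------------------------------------------
# Gene dropping
# ---------------------------------------------------------------------------

def _drop_family(members, rng, mafs, n_positions, var_idx, switch_p):
    """Drop haplotypes through one family.

    Returns per-member (2, n_positions) founder-haplotype label arrays and
    the founder allele matrix (one row per founder haplotype, one column
    per variant).
    """
    labels: dict[str, np.ndarray] = {}
    founder_alleles: list[np.ndarray] = []
    next_hap = 0
    for iid, fat, mot, _sex in members:
        if fat is None:
            labs = np.empty((2, n_positions), dtype=np.int64)
            for h in range(2):
                founder_alleles.append(
                    (rng.random(len(mafs)) < mafs).astype(np.int8))
                labs[h, :] = next_hap
                next_hap += 1
            labels[iid] = labs
        else:
            labels[iid] = np.stack([_meiosis(labels[fat], rng, switch_p),
                                    _meiosis(labels[mot], rng, switch_p)])
    return labels, np.array(founder_alleles)


def _meiosis(parent_labels: np.ndarray, rng, switch_p: np.ndarray) -> np.ndarray:
    """One gamete: start on a random parental haplotype, cross over between
    adjacent positions with the Haldane recombination fraction."""
    n_pos = parent_labels.shape[1]
    steps = np.empty(n_pos, dtype=np.int64)
    steps[0] = rng.integers(2)
    steps[1:] = rng.random(n_pos - 1) < switch_p
    source = np.cumsum(steps) % 2
    return parent_labels[source, np.arange(n_pos)]


def _genotypes_from_labels(members, labels, founder_alleles, var_idx):
    n_var = founder_alleles.shape[1]
    cols = np.arange(n_var)
    rows = []
    for iid, *_ in members:
        labs = labels[iid][:, var_idx]
        rows.append(founder_alleles[labs[0], cols]
                    + founder_alleles[labs[1], cols])
    return np.array(rows, dtype=np.int8)


def _mendelian_possible(child: np.ndarray, father: np.ndarray,
                        mother: np.ndarray) -> np.ndarray:
    """Vectorized unphased-trio consistency: child codes reachable from the
    parents' transmittable alleles (missing anywhere is never a violation)."""
    lo = (father == HOM_MINOR).astype(np.int8) + (mother == HOM_MINOR)
    hi = 2 - (father == HOM_MAJOR) - (mother == HOM_MAJOR)
    ok = (child >= lo) & (child <= hi)
    anymiss = (child == MISSING) | (father == MISSING) | (mother == MISSING)
    return ok | anymiss


def audit_mendelian(pedigrees: list[Pedigree], genotypes: GenotypeMatrix
                    ) -> list[tuple[str, str, str]]:
    """All (family_id, individual_id, variant_id) trio inconsistencies."""
    violations = []
    for ped in pedigrees:
        for ind in ped.nonfounders:
            try:
                c = genotypes.codes[
                    genotypes.row_index(ped.family_id, ind.individual_id)]
                f = genotypes.codes[
                    genotypes.row_index(ped.family_id, ind.father_id)]
                m = genotypes.codes[
                    genotypes.row_index(ped.family_id, ind.mother_id)]
            except KeyError:
                continue
            bad = ~_mendelian_possible(c, f, m)
            for j in np.flatnonzero(bad):
                violations.append((ped.family_id, ind.individual_id,
                                   genotypes.variant_ids[j]))
    return violations


# ---------------------------------------------------------------------------
# Scenario builders
# ---------------------------------------------------------------------------

def _make_pedigree(fid, members, affected_ids) -> Pedigree:
    return Pedigree(fid, [
        Individual(family_id=fid, individual_id=iid, father_id=fat,
                   mother_id=mot, sex=sex,
                   affection=AFFECTED if iid in affected_ids else UNAFFECTED)
        for iid, fat, mot, sex in members])


def _build_null(config, rng, mafs, merged, var_idx, variant_ids, gene_map):
    members = _TEMPLATES[config.pedigree_template]
    affected = _NULL_AFFECTED[config.pedigree_template]
    switch_p = haldane_theta(np.diff(merged))
    pedigrees, keys, rows, labels = [], [], [], {}
    for k in range(config.n_families):
        fid = f"F{k + 1}"
        labs, founder_alleles = _drop_family(members, rng, mafs, len(merged),
                                             var_idx, switch_p)
        rows.append(_genotypes_from_labels(members, labs, founder_alleles,
                                           var_idx))
        pedigrees.append(_make_pedigree(fid, members, affected))
        keys.extend((fid, iid) for iid, *_ in members)
        labels.update({(fid, iid): labs[iid] for iid, *_ in members})
    return pedigrees, keys, np.vstack(rows), {}, None, labels


def _build_scen1(config, rng, mafs, merged, var_idx, variant_ids, gene_map):
    members = _TEMPLATES[config.pedigree_template]
    switch_p = haldane_theta(np.diff(merged))
    rare = np.flatnonzero(mafs <= max(config.rare_maf))
    if len(rare) < config.n_families:
        raise ValueError("not enough rare variants for family-specific "
                         "causal assignment")
    causal_for_family = rng.choice(rare, size=config.n_families,
                                   replace=False)
    pedigrees, keys, rows, labels, truth_cv = [], [], [], {}, {}
    recessive = config.disease_model == "recessive"
    for k in range(config.n_families):
        fid = f"F{k + 1}"
        cj = int(causal_for_family[k])
        for attempt in range(config.max_resample + 1):
            labs, founder_alleles = _drop_family(members, rng, mafs,
                                                 len(merged), var_idx,
                                                 switch_p)
            # the causal allele is private to the first founder haplotype
            founder_alleles[:, cj] = 0
            founder_alleles[0, cj] = 1
            if recessive:
                founder_alleles[2, cj] = 1  # second founder also carries
            geno = _genotypes_from_labels(members, labs, founder_alleles,
                                          var_idx)
            causal_col = geno[:, cj]
            at_risk = (causal_col == HOM_MINOR) if recessive else \
                (causal_col >= HET)
            affected_mask = np.where(
                at_risk, rng.random(len(members)) < config.penetrance,
                rng.random(len(members)) < config.phenocopy)
            affected = {members[i][0] for i in np.flatnonzero(affected_mask)}
            ped = _make_pedigree(fid, members, affected)
            if _ascertained(ped):
                break
        else:
            raise RuntimeError(
                f"family {fid}: ascertainment failed after "
                f"{config.max_resample} resamples")
        pedigrees.append(ped)
        keys.extend((fid, iid) for iid, *_ in members)
        rows.append(geno)
        labels.update({(fid, iid): labs[iid] for iid, *_ in members})
        truth_cv[fid] = [variant_ids[cj]]
    causal_gene = None
    if config.n_families == 1:
        causal_gene = gene_map.set_index("variant_id")["gene_id"].loc[
            truth_cv["F1"][0]]
    return pedigrees, keys, np.vstack(rows), truth_cv, causal_gene, labels


def _ascertained(ped: Pedigree) -> bool:
    """At least one affected non-parent-offspring blood-relative pair and
    at least one unaffected member."""
    aff = ped.affected_ids()
    if len(aff) < 2 or len(aff) == len(ped):
        return False
    for i in range(len(aff)):
        for j in range(i + 1, len(aff)):
            if ped.classify_pair(aff[i], aff[j]) == "other_blood_relative":
                return True
    return False


def _build_scen2(config, rng, mafs, merged, var_idx, variant_ids, gene_map):
    """Unrelated affected singletons, each with a distinct causal variant
    in one designated gene, plus unrelated unaffected singleton controls."""
    genes = list(dict.fromkeys(gene_map["gene_id"]))
    sizes = gene_map.groupby("gene_id", sort=False).size()
    eligible = [g for g in genes if sizes[g] >= config.n_cases]
    if not eligible:
        raise ValueError(
            f"no gene has >= {config.n_cases} variants for scen2")
    causal_gene = eligible[int(rng.integers(len(eligible)))]
    gene_vids = gene_map.loc[gene_map["gene_id"] == causal_gene,
                             "variant_id"].tolist()
    chosen = [gene_vids[i] for i in
              rng.choice(len(gene_vids), size=config.n_cases, replace=False)]
    vpos = {v: j for j, v in enumerate(variant_ids)}

    switch_p = haldane_theta(np.diff(merged))
    member = [("1", None, None, "unknown")]
    pedigrees, keys, rows, labels, truth_cv = [], [], [], {}, {}
    for k in range(config.n_cases + config.n_controls):
        fid = f"S{k + 1}"
        is_case = k < config.n_cases
        labs, founder_alleles = _drop_family(member, rng, mafs, len(merged),
                                             var_idx, switch_p)
        if is_case:
            cj = vpos[chosen[k]]
            founder_alleles[0, cj] = 1
            founder_alleles[1, cj] = 0
            truth_cv[fid] = [chosen[k]]
        geno = _genotypes_from_labels(member, labs, founder_alleles, var_idx)
        pedigrees.append(_make_pedigree(fid, member,
                                        {"1"} if is_case else set()))
        keys.append((fid, "1"))
        rows.append(geno)
        labels[(fid, "1")] = labs["1"]
    return pedigrees, keys, np.vstack(rows), truth_cv, causal_gene, labels


def _build_scen3(config, rng, mafs, merged, var_idx, variant_ids, gene_map):
    """Nuclear families whose affected child carries two causal variants in
    one gene in trans: one transmitted by each parent."""
    genes = list(dict.fromkeys(gene_map["gene_id"]))
    sizes = gene_map.groupby("gene_id", sort=False).size()
    eligible = [g for g in genes if sizes[g] >= 2]
    causal_gene = eligible[int(rng.integers(len(eligible)))]
    gene_vids = gene_map.loc[gene_map["gene_id"] == causal_gene,
                             "variant_id"].tolist()
    pick = rng.choice(len(gene_vids), size=2, replace=False)
    v_pat, v_mat = gene_vids[pick[0]], gene_vids[pick[1]]
    vpos = {v: j for j, v in enumerate(variant_ids)}
    j_pat, j_mat = vpos[v_pat], vpos[v_mat]
    pos_pat = var_idx[j_pat]
    pos_mat = var_idx[j_mat]

    members = _TEMPLATES["nuclear"]
    switch_p = haldane_theta(np.diff(merged))
    pedigrees, keys, rows, labels, truth_cv = [], [], [], {}, {}
    for k in range(config.n_families):
        fid = f"F{k + 1}"
        labs, founder_alleles = _drop_family(members, rng, mafs, len(merged),
                                             var_idx, switch_p)
        # father haps are global ids 0/1, mother 2/3 in this template
        child_pat_hap = int(labs["3"][0, pos_pat])   # transmitted by father
        child_mat_hap = int(labs["3"][1, pos_mat])   # transmitted by mother
        founder_alleles[:4, j_pat] = 0
        founder_alleles[child_pat_hap, j_pat] = 1
        founder_alleles[:4, j_mat] = 0
        founder_alleles[child_mat_hap, j_mat] = 1
        geno = _genotypes_from_labels(members, labs, founder_alleles, var_idx)
        pedigrees.append(_make_pedigree(fid, members, {"3"}))
        keys.extend((fid, iid) for iid, *_ in members)
        rows.append(geno)
        labels.update({(fid, iid): labs[iid] for iid, *_ in members})
        truth_cv[fid] = [v_pat, v_mat]
    return pedigrees, keys, np.vstack(rows), truth_cv, causal_gene, labels


# ---------------------------------------------------------------------------
# Error channel & true IBD
# ---------------------------------------------------------------------------

def _error_channel(codes: np.ndarray, rng, config: SimConfig) -> np.ndarray:
    codes = codes.copy()
    if config.miscall_het_to_hom > 0:
        het = codes == HET
        hit = het & (rng.random(codes.shape) < config.miscall_het_to_hom)
        to_minor = rng.random(codes.shape) < 0.5
        codes[hit & to_minor] = HOM_MINOR
        codes[hit & ~to_minor] = HOM_MAJOR
    if config.false_het_rate > 0:
        hom = (codes == HOM_MAJOR) | (codes == HOM_MINOR)
        hit = hom & (rng.random(codes.shape) < config.false_het_rate)
        codes[hit] = HET
    if config.missing_rate > 0:
        hit = rng.random(codes.shape) < config.missing_rate
        codes[hit] = MISSING
    return codes


def _ibd_state(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Vectorized multiset-intersection IBD state from label pairs."""
    m11 = a[0] == b[0]
    m12 = a[0] == b[1]
    m21 = a[1] == b[0]
    m22 = a[1] == b[1]
    ibd2 = (m11 & m22) | (m12 & m21)
    ibd1 = (m11 | m12 | m21 | m22) & ~ibd2
    return ibd2.astype(np.int8) * 2 + ibd1.astype(np.int8)


def _emit_true_ibd(pedigrees, grid, grid_labels) -> pd.DataFrame:
    rows = []
    for ped in pedigrees:
        ids = [m.individual_id for m in ped.members]
        for i in range(len(ids)):
            for j in range(i + 1, len(ids)):
                a = grid_labels[(ped.family_id, ids[i])]
                b = grid_labels[(ped.family_id, ids[j])]
                states = _ibd_state(a, b)
                for g, s in zip(grid, states):
                    rows.append((ped.family_id, ids[i], ids[j], float(g),
                                 1.0 if s == 0 else 0.0,
                                 1.0 if s == 1 else 0.0,
                                 1.0 if s == 2 else 0.0))
    return pd.DataFrame(rows, columns=["family_id", "id1", "id2", "position",
                                       "p0", "p1", "p2"])


# ---------------------------------------------------------------------------
# ROC evaluation
# ---------------------------------------------------------------------------

def roc_evaluate(ranked_lists: list[list[str]], truths: list[set[str]],
                 rank_cutoffs: list[int] | None = None) -> dict:
    """Sensitivity/specificity over rank cutoffs and trapezoidal AUC.

    Each replicate supplies a full best-first ranking and its truth set.
    At cutoff k, sensitivity is the fraction of causal units ranked <= k
    across all replicates and specificity the fraction of non-causal units
    ranked > k.  The AUC integrates the (1 - specificity, sensitivity)
    curve over all cutoffs with (0, 0) and (1, 1) endpoints appended.
    """
    if len(ranked_lists) != len(truths):
        raise ValueError("need one truth set per ranked list")
    n_causal = sum(len(t) for t in truths)
    if n_causal == 0:
        raise ValueError("empty truth set: no causal units to evaluate")
    causal_ranks, noncausal_ranks = [], []
    for ranking, truth in zip(ranked_lists, truths):
        rank_of = {u: r + 1 for r, u in enumerate(ranking)}
        for u in truth:
            causal_ranks.append(rank_of.get(u, np.inf))
        for u in ranking:
            if u not in truth:
                noncausal_ranks.append(rank_of[u])
    causal_ranks = np.array(causal_ranks, dtype=float)
    noncausal_ranks = np.array(noncausal_ranks, dtype=float)

    max_k = max(len(r) for r in ranked_lists)
    cutoffs = list(rank_cutoffs) if rank_cutoffs is not None \
        else list(range(0, max_k + 1))
    rows = []
    for k in cutoffs:
        sens = float((causal_ranks <= k).mean())
        spec = float((noncausal_ranks > k).mean()) if len(noncausal_ranks) \
            else 1.0
        rows.append((k, sens, spec))
    table = pd.DataFrame(rows, columns=["cutoff", "sensitivity",
                                        "specificity"])
    fpr = np.concatenate([[0.0], 1.0 - table["specificity"].to_numpy(),
                          [1.0]])
    tpr = np.concatenate([[0.0], table["sensitivity"].to_numpy(), [1.0]])
    order = np.argsort(fpr, kind="stable")
    auc = float(np.trapezoid(tpr[order], fpr[order]))
    return {"table": table, "auc": auc}


@dataclass
class DmiComparison:
    """Head-to-head comparison of segregation-score and weighted-sum gene
    rankings over replicated simulations."""
    scenario: str
    n_replicates: int
    auc_segregation: float
    auc_weighted_sum: float
    auc_difference: float          # segregation minus weighted-sum
    bootstrap_se: float
    seg_rankings: list[list[str]] = field(default_factory=list)
    ws_rankings: list[list[str]] = field(default_factory=list)
    truths: list[set[str]] = field(default_factory=list)


def compare_dmi_strategies(scenario: str, n_replicates: int = 100,
                           seed: int = 0, n_variants: int = 100,
                           n_genes: int = 10, n_permutations: int = 1000,
                           n_bootstrap: int = 200,
                           template: str = "three_generation_12"
                           ) -> DmiComparison:
    """Replicate a scenario and rank genes by each strategy.

    The segregation ranking scores each gene by the best (maximum)
    per-variant segregation score under the dominant model; the
    weighted-sum ranking orders genes by their standardized burden
    statistic.  Both rankings share the gene universe, so their ROC curves
    are directly comparable.  The bootstrap resamples replicates to give a
    standard error for the AUC difference.
    """
    from . import dmi as _dmi

    ss = np.random.SeedSequence(seed)
    children = ss.spawn(n_replicates + 1)
    seg_rankings, ws_rankings, truths = [], [], []
    for r in range(n_replicates):
        rep_seed = int(children[r].generate_state(1)[0] % (2**31))
        if scenario == SCEN1:
            config = SimConfig(scenario=SCEN1, pedigree_template=template,
                               n_families=1, n_variants=n_variants,
                               n_genes=n_genes, emit_true_ibd=False,
                               seed=rep_seed)
        elif scenario == SCEN2:
            config = SimConfig(scenario=SCEN2, n_variants=n_variants,
                               n_genes=n_genes, emit_true_ibd=False,
                               seed=rep_seed)
        else:
            raise ValueError("comparison is defined for scen1/scen2")
        sim = simulate(config)
        phen = _dmi.phenotype_vector(sim.pedigrees, sim.genotypes)

        seg = _dmi.segregation_score_track(
            sim.genotypes, sim.variants, phen, _dmi.DOMINANT)
        seg = seg.merge(sim.gene_map, on="variant_id")
        gene_order = list(dict.fromkeys(sim.gene_map["gene_id"]))
        gene_score = seg.groupby("gene_id", sort=False)["score"].max()
        seg_rank = sorted(gene_order,
                          key=lambda g: (-gene_score[g],
                                         gene_order.index(g)))

        ws = _dmi.weighted_sum_by_gene(
            sim.genotypes, phen, sim.gene_map,
            n_permutations=n_permutations, seed=rep_seed)
        ws_by_gene = {w.gene_id: w for w in ws}
        ws_rank = sorted(gene_order,
                         key=lambda g: (-ws_by_gene[g].z,
                                        -ws_by_gene[g].x,
                                        gene_order.index(g)))

        seg_rankings.append(seg_rank)
        ws_rankings.append(ws_rank)
        truths.append({sim.truth.causal_gene})

    auc_seg = roc_evaluate(seg_rankings, truths)["auc"]
    auc_ws = roc_evaluate(ws_rankings, truths)["auc"]

    boot_rng = np.random.default_rng(
        int(children[-1].generate_state(1)[0] % (2**31)))
    diffs = np.empty(n_bootstrap)
    for b in range(n_bootstrap):
        idx = boot_rng.integers(0, n_replicates, n_replicates)
        a1 = roc_evaluate([seg_rankings[i] for i in idx],
                          [truths[i] for i in idx])["auc"]
        a2 = roc_evaluate([ws_rankings[i] for i in idx],
                          [truths[i] for i in idx])["auc"]
        diffs[b] = a1 - a2
    return DmiComparison(
        scenario=scenario, n_replicates=n_replicates,
        auc_segregation=auc_seg, auc_weighted_sum=auc_ws,
        auc_difference=auc_seg - auc_ws,
        bootstrap_se=float(diffs.std(ddof=1)),
        seg_rankings=seg_rankings, ws_rankings=ws_rankings, truths=truths)
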