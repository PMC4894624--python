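"""Pipeline orchestration: run the analysis stages in a fixed order and
assemble one merged per-variant results table.

Stage order: map update -> allele frequency estimation -> marker pruning ->
{disease-model identification, IBD sharing} -> region calling.  Chromosomes
are processed as independent sequential batches; results are identical for
any batching because every stage is deterministic given the seed.
"""

from __future__ import annotations

import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import afe, dmi, genmap, ibdshare, pedio


class ValidationError(ValueError):
    """The run configuration is inconsistent or inputs are missing."""


class StageError(RuntimeError):
    """A pipeline stage failed; message names the stage."""


@dataclass
class RunConfig:
    """Inputs, module toggles and per-module parameters for one run."""
    ped: str = ""
    map: str = ""
    freq: str | None = None
    ibd: str | None = None
    genemap: str | None = None
    refmap: str | None = None
    out_dir: str = "pedpipe_out"
    seed: int = 0

    map_update: bool = False
    afe: bool = True
    prune: bool = False
    dmi: bool = False
    ibd_share: bool = False
    regions: bool = False

    prune_params: dict = field(default_factory=dict)
    dmi_params: dict = field(default_factory=dict)
    ibd_params: dict = field(default_factory=dict)

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        inputs = d.get("inputs", {})
        modules = d.get("modules", {})
        params = d.get("params", {})
        return cls(
            ped=inputs.get("ped", ""), map=inputs.get("map", ""),
            freq=inputs.get("freq"), ibd=inputs.get("ibd"),
            genemap=inputs.get("genemap"), refmap=inputs.get("refmap"),
            out_dir=d.get("out_dir", "pedpipe_out"),
            seed=int(d.get("seed", 0)),
            map_update=bool(modules.get("map_update", False)),
            afe=bool(modules.get("afe", True)),
            prune=bool(modules.get("prune", False)),
            dmi=bool(modules.get("dmi", False)),
            ibd_share=bool(modules.get("ibd_share", False)),
            regions=bool(modules.get("regions", False)),
            prune_params=params.get("prune", {}),
            dmi_params=params.get("dmi", {}),
            ibd_params=params.get("ibd_share", {}))

    def validate(self) -> None:
        toggles = [self.map_update, self.afe, self.prune, self.dmi,
                   self.ibd_share, self.regions]
        if not any(toggles):
            raise ValidationError("no module enabled: nothing to run")
        if not self.ped or not self.map:
            raise ValidationError("ped and map input paths are required")
        for name, path in (("ped", self.ped), ("map", self.map),
                           ("freq", self.freq), ("ibd", self.ibd),
                           ("genemap", self.genemap),
                           ("refmap", self.refmap)):
            if path and not Path(path).exists():
                raise ValidationError(f"{name} input not found: {path}")
        if self.map_update and not self.refmap:
            raise ValidationError("map_update requires a reference map")
        if self.dmi and not self.genemap:
            raise ValidationError("dmi gene-level statistics require a "
                                  "gene map")
        if (self.ibd_share or self.regions) and not self.ibd:
            raise ValidationError("ibd_share/regions require an IBD table")
        if self.prune and not self.afe:
            raise ValidationError("prune requires afe (weighted MAF filter)")


def run_pipeline(config: RunConfig) -> Path:
    """Execute the enabled stages; returns the results directory.

    Writes ``results.tsv`` (one row per variant in the post-map-update
    reporting universe), ``regions.tsv`` when region calling ran, and
    ``run.log`` with config, seed and per-stage wall times.
    """
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    timings: list[tuple[str, float]] = []

    def stage(name, fn, *args, **kwargs):
        t0 = time.perf_counter()
        try:
            result = fn(*args, **kwargs)
        except (ValidationError, StageError):
            raise
        except Exception as exc:
            raise StageError(f"stage {name!r} failed: {exc}") from exc
        timings.append((name, time.perf_counter() - t0))
        return result

    pedigrees, genotypes, variants = stage(
        "read", pedio.read_ped_map, config.ped, config.map)

    if config.map_update:
        refmap = stage("read_refmap", genmap.read_reference_map,
                       config.refmap)
        variants = stage("map_update", genmap.interpolate_cm, variants,
                         refmap)

    freq_table = None
    if config.freq:
        freq_table = stage("read_freq", pedio.read_frequency_table,
                           config.freq)
    if config.afe:
        variants, genotypes, _ = stage(
            "afe", afe.assign_minor_alleles, genotypes, variants, freq_table)

    results = variants[["variant_id", "chromosome", "bp", "cm",
                        "allele_minor", "allele_major", "f_w"]].copy()

    if config.prune:
        kept = stage("prune", _prune_per_chromosome, genotypes, variants,
                     config.prune_params)
        results["prune_kept"] = results["variant_id"].isin(kept)

    gene_map = None
    if config.genemap:
        gene_map = stage("read_genemap", pedio.read_gene_map, config.genemap)

    if config.dmi:
        results = stage("dmi", _dmi_stage, pedigrees, genotypes, variants,
                        gene_map, config.dmi_params, config.seed, results)

    region_list = []
    if config.ibd_share:
        ibd_records = stage("read_ibd", pedio.read_ibd_table, config.ibd)
        params = config.ibd_params
        share_cfg = ibdshare.IBDShareConfig(
            grid_cm=float(params.get("grid_cm", 1.0)),
            pair_threshold=float(params.get("pair_threshold", 0.5)),
            region_threshold=float(params.get("region_threshold", 0.5)))
        chroms = variants["chromosome"].astype(str).unique()
        # the pairwise IBD table carries no chromosome; it describes the
        # (single) chromosome the variants live on
        track_chrom = chroms[0] if len(chroms) == 1 else "0"
        track = stage("ibd_share", ibdshare.sharing_statistic, pedigrees,
                      ibd_records, share_cfg, track_chrom)
        per_variant = stage("ibd_project", ibdshare.project_to_variants,
                            track, variants)
        results["ibd_sharing"] = per_variant["value"].to_numpy()
        if config.regions:
            region_list = stage("regions", ibdshare.call_regions, track,
                                share_cfg.region_threshold, "above")
            in_region = np.zeros(len(results), dtype=bool)
            for reg in region_list:
                hit = ((results["chromosome"].astype(str) == reg.chromosome)
                       & (results["cm"] >= reg.start_cm)
                       & (results["cm"] <= reg.end_cm))
                in_region |= hit.to_numpy()
            results["in_ibd_region"] = in_region
            ibdshare.write_regions(region_list, out / "regions.tsv")

    results_path = out / "results.tsv"
    results.to_csv(results_path, sep="\t", index=False, float_format="%.6g")

    from . import __version__
    log = {
        "package_version": __version__,
        "numpy_version": np.__version__,
        "pandas_version": pd.__version__,
        "seed": config.seed,
        "config": {k: v for k, v in vars(config).items()},
        "stage_seconds": {name: round(t, 4) for name, t in timings},
        "n_variants": int(len(results)),
        "n_regions": len(region_list),
    }
    (out / "run.log").write_text(json.dumps(log, indent=2, default=str)
                                 + "\n")
    return out


def _prune_per_chromosome(genotypes, variants, params) -> list[str]:
    cfg = genmap.PruneConfig(
        maf_min=float(params.get("maf_min", 0.2)),
        vif_max=float(params.get("vif_max", 1.0)),
        window=int(params.get("window", 50)),
        step=int(params.get("step", 5)),
        min_spacing_cm=float(params.get("min_spacing_cm", 0.5)))
    return genmap.select_informative_independent(genotypes, variants, cfg)


def _dmi_stage(pedigrees, genotypes, variants, gene_map, params, seed,
               results: pd.DataFrame) -> pd.DataFrame:
    phen = dmi.phenotype_vector(pedigrees, genotypes)
    sp = dmi.SegregationScoreParams()
    for model, col in ((dmi.DOMINANT, "seg_dominant"),
                       (dmi.RECESSIVE, "seg_recessive")):
        track = dmi.segregation_score_track(genotypes, variants, phen, model,
                                            sp)
        results[col] = track["score"].to_numpy()

    if gene_map is not None and params.get("weighted_sum", True):
        ws = dmi.weighted_sum_by_gene(
            genotypes, phen, gene_map,
            n_permutations=int(params.get("permutations", 1000)), seed=seed)
        by_gene = {w.gene_id: w for w in ws}
        gene_of = dict(zip(gene_map["variant_id"], gene_map["gene_id"]))
        results["gene_id"] = [gene_of.get(v, "")
                              for v in results["variant_id"]]
        results["ws_p"] = [
            by_gene[g].p_value if g in by_gene else np.nan
            for g in results["gene_id"]]
        results["ws_z"] = [
            by_gene[g].z if g in by_gene else np.nan
            for g in results["gene_id"]]

    if gene_map is not None and params.get("compound_het", True):
        ch_cfg = dmi.CompoundHetConfig(
            min_rule_proportion=float(params.get("min_rule_proportion",
                                                 0.95)),
            apply_rule5=params.get("apply_rule5", "auto"))
        ch = dmi.compound_het_scan(pedigrees, genotypes, variants, gene_map,
                                   ch_cfg)
        gene_pass = {r.gene_id: r.passes for r in ch}
        flag_by_variant: dict[str, bool] = {}
        for r in ch:
            for rec in r.variant_flags.itertuples(index=False):
                flag_by_variant[rec.variant_id] = bool(rec.passes_123)
        gene_of = dict(zip(gene_map["variant_id"], gene_map["gene_id"]))
        results["ch_variant_pass"] = [
            flag_by_variant.get(v, False) for v in results["variant_id"]]
        results["ch_gene_pass"] = [
            gene_pass.get(gene_of.get(v, ""), False)
            for v in results["variant_id"]]
    return results
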