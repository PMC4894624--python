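"""IBD-sharing statistic over affected relative pairs and threshold-based
region calling.

For every grid point on a chromosome, pairwise IBD state probabilities
(p0, p1, p2) come from an external multipoint engine.  A pair of affected
blood relatives counts as an *IBD pair* at a grid point when
P(IBD != 0) = 1 - p0 exceeds a threshold.  Parent-offspring pairs are
excluded — they always share exactly one allele IBD, so they carry no
signal.  The sharing statistic is the proportion of IBD pairs among all
eligible pairs; maximal runs of grid points where a score exceeds a
threshold are reported as regions.  The region caller is generic and is
reused for any positional score track (e.g., LOD scores).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .pedio import AFFECTED, Pedigree


@dataclass
class IBDShareConfig:
    """grid_cm: grid spacing used by the upstream IBD engine (cM).
    pair_threshold: P(IBD != 0) above which a pair is an IBD pair.
    region_threshold: sharing-statistic level defining IBD regions.
    scope: ``pooled`` pools pairs across families; ``per_family`` returns a
    track per family."""
    grid_cm: float = 1.0
    pair_threshold: float = 0.5
    region_threshold: float = 0.5
    scope: str = "pooled"

    def __post_init__(self):
        if self.grid_cm <= 0:
            raise ValueError("grid_cm must be positive")
        if not 0 < self.pair_threshold < 1:
            raise ValueError("pair_threshold must be in (0, 1)")
        if self.scope not in ("pooled", "per_family"):
            raise ValueError("scope must be 'pooled' or 'per_family'")


@dataclass
class Region:
    chromosome: str
    start_cm: float
    end_cm: float
    peak_value: float
    n_grid_points: int


def eligible_pairs(pedigree: Pedigree) -> list[tuple[str, str]]:
    """Within-family pairs of affected individuals related by blood but not
    parent-offspring, in deterministic member order."""
    aff = pedigree.affected_ids()
    out = []
    for i in range(len(aff)):
        for j in range(i + 1, len(aff)):
            if pedigree.classify_pair(aff[i], aff[j]) == "other_blood_relative":
                out.append((aff[i], aff[j]))
    return out


def sharing_statistic(pedigrees: list[Pedigree], ibd_records: pd.DataFrame,
                      config: IBDShareConfig | None = None,
                      chromosome: str = "0") -> pd.DataFrame:
    """IBD sharing statistic per grid position.

    Returns a score track (columns ``chromosome``, ``position_cm``,
    ``value`` and, under per-family scope, ``family_id``).  At each grid
    position the statistic is (#pairs with 1 - p0 > pair_threshold) /
    (#eligible pairs observed there); pairs without a record at a position
    drop out of both numerator and denominator.
    """
    config = config or IBDShareConfig()
    peds = {p.family_id: p for p in pedigrees}
    wanted: dict[str, set[frozenset[str]]] = {}
    n_eligible = 0
    for fid, ped in peds.items():
        pairs = {frozenset(p) for p in eligible_pairs(ped)}
        wanted[fid] = pairs
        n_eligible += len(pairs)
    if n_eligible == 0:
        raise ValueError(
            "no eligible affected relative pairs in any family "
            f"({sorted(peds)}): the sharing statistic is undefined")

    rec = ibd_records.copy()
    rec["pair"] = [frozenset((a, b)) for a, b in zip(rec["id1"], rec["id2"])]
    keep = [fid in wanted and pair in wanted[fid]
            for fid, pair in zip(rec["family_id"], rec["pair"])]
    rec = rec[keep]
    if rec.empty:
        raise ValueError("IBD table contains no records for eligible "
                         "affected relative pairs")
    rec["is_ibd"] = (1.0 - rec["p0"]) > config.pair_threshold

    if config.scope == "per_family":
        grouped = rec.groupby(["family_id", "position"], sort=True)["is_ibd"]
        df = grouped.mean().reset_index()
        df.columns = ["family_id", "position_cm", "value"]
        df.insert(0, "chromosome", chromosome)
        return df
    grouped = rec.groupby("position", sort=True)["is_ibd"]
    df = grouped.mean().reset_index()
    df.columns = ["position_cm", "value"]
    df.insert(0, "chromosome", chromosome)
    return df


def project_to_variants(score_track: pd.DataFrame,
                        variants: pd.DataFrame) -> pd.DataFrame:
    """Assign each variant the track value of its containing grid interval.

    A variant takes the value at the grid point at or immediately to the
    left of its cM position (left-closed intervals); variants outside the
    grid span take the nearest endpoint's value and are flagged in the
    ``outside_grid`` column.
    """
    out = variants[["variant_id", "chromosome", "cm"]].copy()
    values = np.full(len(out), np.nan)
    outside = np.zeros(len(out), dtype=bool)
    for chrom, sub in out.groupby("chromosome", sort=False):
        if "chromosome" in score_track.columns:
            tr = score_track[score_track["chromosome"].astype(str) == str(chrom)]
        else:
            tr = score_track
        if tr.empty:
            continue
        pos = tr["position_cm"].to_numpy(dtype=float)
        val = tr["value"].to_numpy(dtype=float)
        order = np.argsort(pos)
        pos, val = pos[order], val[order]
        cm = sub["cm"].to_numpy(dtype=float)
        idx = np.searchsorted(pos, cm, side="right") - 1
        below = idx < 0
        idx = np.clip(idx, 0, len(pos) - 1)
        values[sub.index] = val[idx]
        outside[sub.index] = below | (cm > pos[-1])
    out["value"] = values
    out["outside_grid"] = outside
    return out


def call_regions(score_track: pd.DataFrame, threshold: float,
                 direction: str = "above") -> list[Region]:
    """Maximal runs of consecutive grid points strictly beyond a threshold.

    ``direction='above'`` calls runs with value > threshold (IBD regions,
    LOD peaks); ``'below'`` calls value < threshold (e.g., p-value tracks).
    Regions span [first grid cm, last grid cm] of the run and report the
    peak value (max for above, min for below).
    """
    if direction not in ("above", "below"):
        raise ValueError("direction must be 'above' or 'below'")
    if score_track.empty:
        return []
    regions: list[Region] = []
    if "chromosome" in score_track.columns:
        groups = score_track.groupby("chromosome", sort=False)
    else:
        groups = [("0", score_track)]
    for chrom, tr in groups:
        tr = tr.sort_values("position_cm")
        pos = tr["position_cm"].to_numpy(dtype=float)
        val = tr["value"].to_numpy(dtype=float)
        hit = val > threshold if direction == "above" else val < threshold
        start = None
        for i, h in enumerate(hit):
            if h and start is None:
                start = i
            elif not h and start is not None:
                regions.append(_region(str(chrom), pos, val, start, i,
                                       direction))
                start = None
        if start is not None:
            regions.append(_region(str(chrom), pos, val, start, len(pos),
                                   direction))
    return regions


def _region(chrom, pos, val, start, stop, direction) -> Region:
    seg = val[start:stop]
    peak = float(seg.max() if direction == "above" else seg.min())
    return Region(chromosome=chrom, start_cm=float(pos[start]),
                  end_cm=float(pos[stop - 1]), peak_value=peak,
                  n_grid_points=stop - start)


def write_regions(regions: list[Region], path) -> None:
    """BED-like tab-delimited region output; coordinates are cM, not bp."""
    with open(path, "w") as fh:
        fh.write("#coordinates: centimorgan (cM)\n")
        fh.write("chromosome\tstart_cm\tend_cm\tpeak_value\tn_grid_points\n")
        for r in regions:
            fh.write(f"{r.chromosome}\t{r.start_cm:g}\t{r.end_cm:g}\t"
                     f"{r.peak_value:g}\t{r.n_grid_points}\n")
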