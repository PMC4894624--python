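"""Genetic-map interpolation, the Haldane map function, and selection of an
informative, approximately independent marker set.

Downstream multipoint methods (IBD estimation, linkage) assume markers are
informative (common enough to carry inheritance information) and in linkage
equilibrium.  The selection here mirrors the usual preparation for such
analyses: a minor-allele-frequency filter, windowed variance-inflation-factor
(VIF) pruning of correlated markers, and a minimum genetic spacing between
adjacent kept markers.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .pedio import GenotypeMatrix, MISSING

_VIF_EPS = 1e-9


@dataclass
class PruneConfig:
    """Marker-selection thresholds.

    maf_min : drop variants with weighted MAF at or below this (default 0.2).
    vif_max : maximum tolerated VIF, 1/(1-R^2) of each marker's dosage
        regressed on the other retained markers in a sliding window;
        1.0 demands (numerically) uncorrelated markers (default 1.0).
    window, step : sliding-window geometry in variant counts (defaults 50/5,
        the conventional pruning window).
    min_spacing_cm : minimum genetic distance between adjacent kept markers
        (default 0.5 cM).
    """
    maf_min: float = 0.2
    vif_max: float = 1.0
    window: int = 50
    step: int = 5
    min_spacing_cm: float = 0.5

    def __post_init__(self):
        if not 0 <= self.maf_min < 0.5:
            raise ValueError("maf_min must be in [0, 0.5)")
        if self.vif_max < 1:
            raise ValueError("vif_max must be >= 1")
        if self.min_spacing_cm < 0:
            raise ValueError("min_spacing_cm must be >= 0")


def read_reference_map(path) -> pd.DataFrame:
    """Read a tab-delimited reference genetic map (chromosome, bp, cm).

    Anchors must have strictly increasing bp and non-decreasing cm within
    each chromosome (sex-averaged Haldane scale).
    """
    df = pd.read_csv(path, sep="\t", dtype={"chromosome": str})
    if not {"chromosome", "bp", "cm"} <= set(df.columns):
        raise ValueError(f"reference map {path} needs chromosome/bp/cm columns")
    validate_reference_map(df)
    return df


def validate_reference_map(ref: pd.DataFrame) -> None:
    for chrom, sub in ref.groupby("chromosome", sort=False):
        bp = sub["bp"].to_numpy()
        cm = sub["cm"].to_numpy()
        if not (np.diff(bp) > 0).all():
            raise ValueError(f"reference map chromosome {chrom}: bp not "
                             "strictly increasing")
        if not (np.diff(cm) >= 0).all():
            raise ValueError(f"reference map chromosome {chrom}: cm decreases")


def interpolate_cm(variants: pd.DataFrame, reference_map: pd.DataFrame
                   ) -> pd.DataFrame:
    """Fill variant genetic positions by linear interpolation in bp.

    A variant at an anchor bp gets the anchor cm exactly; between anchors,
    cm is linear in bp.  Beyond the anchor range the terminal segment's
    cM/bp slope is extended, clipped at 0 (genetic positions are
    non-negative).  The result is non-decreasing in bp per chromosome.
    """
    validate_reference_map(reference_map)
    variants = variants.copy()
    covered = set(reference_map["chromosome"].unique())
    wanted = set(variants["chromosome"].unique())
    absent = sorted(wanted - covered, key=str)
    if absent:
        raise ValueError(
            f"chromosomes absent from reference map: {absent}")

    for chrom, sub in variants.groupby("chromosome", sort=False):
        anchors = reference_map[reference_map["chromosome"] == chrom]
        bp_a = anchors["bp"].to_numpy(dtype=float)
        cm_a = anchors["cm"].to_numpy(dtype=float)
        if len(bp_a) < 2:
            raise ValueError(
                f"reference map needs >= 2 anchors on chromosome {chrom}")
        bp = sub["bp"].to_numpy(dtype=float)
        cm = np.interp(bp, bp_a, cm_a)
        # terminal-slope extrapolation outside the anchor span
        left = bp < bp_a[0]
        right = bp > bp_a[-1]
        if left.any():
            slope = (cm_a[1] - cm_a[0]) / (bp_a[1] - bp_a[0])
            cm[left] = cm_a[0] + slope * (bp[left] - bp_a[0])
        if right.any():
            slope = (cm_a[-1] - cm_a[-2]) / (bp_a[-1] - bp_a[-2])
            cm[right] = cm_a[-1] + slope * (bp[right] - bp_a[-1])
        variants.loc[sub.index, "cm"] = np.maximum(cm, 0.0)
    return variants


def haldane_theta(d_cm: float | np.ndarray) -> float | np.ndarray:
    """Recombination fraction for a genetic distance in cM, assuming no
    crossover interference: theta = (1 - exp(-2 d)) / 2 with d in Morgans."""
    d = np.asarray(d_cm, dtype=float)
    if (d < 0).any():
        raise ValueError("genetic distance must be non-negative")
    theta = 0.5 * (1.0 - np.exp(-2.0 * d / 100.0))
    return float(theta) if np.isscalar(d_cm) else theta


def haldane_distance(theta: float | np.ndarray) -> float | np.ndarray:
    """Inverse map function: genetic distance in cM for a recombination
    fraction in [0, 0.5)."""
    t = np.asarray(theta, dtype=float)
    if ((t < 0) | (t >= 0.5)).any():
        raise ValueError("theta must be in [0, 0.5)")
    d = -50.0 * np.log(1.0 - 2.0 * t)
    return float(d) if np.isscalar(theta) else d


def select_informative_independent(genotypes: GenotypeMatrix,
                                   variants: pd.DataFrame,
                                   config: PruneConfig | None = None
                                   ) -> list[str]:
    """Select an informative, approximately independent marker set.

    Three filters in sequence:

    1. informativeness — keep variants with weighted MAF ``f_w`` above
       ``maf_min``;
    2. VIF pruning — over sliding windows of ``window`` retained variants
       advancing by ``step``, repeatedly remove the variant with the
       largest VIF while any VIF exceeds ``vif_max`` (plus a numerical
       epsilon);
    3. spacing — a left-to-right greedy scan per chromosome keeps the first
       variant and drops any variant closer than ``min_spacing_cm`` to the
       last kept one.

    Returns kept variant ids in genomic order.  Requires ``cm`` on all
    candidate variants.
    """
    config = config or PruneConfig()
    cand = variants[variants["f_w"] > config.maf_min]
    if cand["cm"].isna().any():
        bad = cand.loc[cand["cm"].isna(), "variant_id"].iloc[0]
        raise ValueError(f"variant {bad!r} lacks a genetic position; "
                         "run map interpolation first")

    kept: list[str] = []
    for chrom, sub in cand.groupby("chromosome", sort=False):
        ids = sub["variant_id"].tolist()
        ids = _vif_prune(genotypes, ids, config)
        ids = _spacing_filter(sub, ids, config.min_spacing_cm)
        kept.extend(ids)
    return kept


def _vif_prune(genotypes: GenotypeMatrix, ids: list[str],
               config: PruneConfig) -> list[str]:
    retained = list(ids)
    # sweep sliding windows to a fixed point so that the result is stable
    # under re-pruning (window membership shifts as variants drop out)
    while len(retained) >= 2:
        any_removed = False
        start = 0
        while True:
            window_ids = retained[start:start + config.window]
            if len(window_ids) >= 2:
                removed = _prune_window(genotypes, window_ids, config.vif_max)
                if removed:
                    any_removed = True
                    retained = [v for v in retained if v not in removed]
            if start + config.window >= len(retained):
                break
            start += config.step
        if not any_removed:
            break
    return retained


def _prune_window(genotypes: GenotypeMatrix, window_ids: list[str],
                  vif_max: float) -> set[str]:
    """Greedy removal of the worst-VIF variant until all VIFs conform."""
    dos = np.stack([genotypes.column(v).astype(float) for v in window_ids],
                   axis=1)
    dos[dos == MISSING] = np.nan
    active = list(range(len(window_ids)))
    removed: set[str] = set()
    while len(active) >= 2:
        vifs = _vifs(dos[:, active])
        worst = int(np.argmax(vifs))
        if vifs[worst] <= vif_max + _VIF_EPS:
            break
        removed.add(window_ids[active[worst]])
        active.pop(worst)
    return removed


def _vifs(dosages: np.ndarray) -> np.ndarray:
    """Per-column VIF = 1/(1 - R^2) against the remaining columns.

    Missing dosages are mean-imputed column-wise for the regression; a
    constant column has VIF 1 (it carries no linear information).
    """
    X = dosages.copy()
    n, p = X.shape
    for j in range(p):
        col = X[:, j]
        mu = np.nanmean(col) if not np.isnan(col).all() else 0.0
        col[np.isnan(col)] = mu
    sd = X.std(axis=0)
    out = np.ones(p)
    informative = sd > 0
    if informative.sum() < 2:
        return out
    Z = (X[:, informative] - X[:, informative].mean(axis=0)) / sd[informative]
    k = Z.shape[1]
    for jj in range(k):
        y = Z[:, jj]
        others = np.delete(Z, jj, axis=1)
        coef, *_ = np.linalg.lstsq(others, y, rcond=None)
        resid = y - others @ coef
        r2 = 1.0 - resid @ resid / (y @ y)
        r2 = min(max(r2, 0.0), 1.0 - 1e-12)
        out[np.flatnonzero(informative)[jj]] = 1.0 / (1.0 - r2)
    return out


def _spacing_filter(sub: pd.DataFrame, ids: list[str],
                    min_spacing_cm: float) -> list[str]:
    cm = dict(zip(sub["variant_id"], sub["cm"]))
    kept: list[str] = []
    for vid in ids:
        if not kept or cm[vid] - cm[kept[-1]] >= min_spacing_cm:
            kept.append(vid)
    return kept
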