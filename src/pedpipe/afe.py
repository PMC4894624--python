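"""Weighted allele-frequency estimation and minor-allele assignment.

Sample allele frequencies estimated from a handful of families are biased
estimates of population frequencies — rare disease alleles are enriched in
ascertained pedigrees — while external population panels may report a
frequency of exactly 0 for a private family mutation, which breaks
likelihood-based downstream tools.  The weighted estimate pools both
sources by allele count:

    f_w = (n * f_s + m * f_e) / (n + m)

where ``f_s`` is the sample frequency over ``n`` observed sample alleles
and ``f_e`` the external panel frequency over ``m`` panel alleles.  When no
external record exists, ``f_w = f_s``.  Any allele observed at least once
in the sample therefore gets ``f_w > 0``.

The allele with the smaller weighted frequency becomes the variant's minor
allele (``D``, the presumed rare disease allele), and the genotype matrix
is re-oriented accordingly.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import pedio
from .pedio import GenotypeMatrix, MISSING


@dataclass
class WeightedFrequencyResult:
    """Per-variant frequency bookkeeping for the tracked (minor) allele."""
    variant_id: str
    f_s: float          # sample frequency; NaN if no genotypes observed
    n: int              # observed sample alleles (2 x non-missing genotypes)
    f_e: float          # external frequency; NaN if absent
    m: int              # external allele count; 0 if absent
    f_w: float          # weighted frequency


def sample_allele_frequency(genotypes: GenotypeMatrix,
                            variant_id: str) -> tuple[float, int]:
    """Sample frequency of the coded (minor) allele at one variant.

    Returns ``(f_s, n)`` with ``n`` the number of observed alleles.  An
    all-missing variant yields ``(nan, 0)``.
    """
    col = genotypes.column(variant_id)
    nonmiss = col != MISSING
    n = 2 * int(nonmiss.sum())
    if n == 0:
        return float("nan"), 0
    return float(col[nonmiss].sum()) / n, n


def weighted_frequency(f_s: float, n: int,
                       f_e: float | None = None,
                       m: int | None = None) -> float:
    """Allele-count-weighted pooling of sample and external frequencies.

    ``f_w = (n*f_s + m*f_e) / (n + m)``; with no external record,
    ``f_w = f_s``.  Always lies between ``f_s`` and ``f_e``.
    """
    if f_e is None or m is None or (isinstance(f_e, float) and np.isnan(f_e)):
        if n <= 0:
            raise ValueError("no sample alleles and no external frequency")
        return float(f_s)
    if n + m <= 0:
        raise ValueError("weighted frequency undefined: n + m = 0")
    if np.isnan(f_s) or n == 0:
        return float(f_e)
    return (n * f_s + m * f_e) / (n + m)


def assign_minor_alleles(genotypes: GenotypeMatrix, variants: pd.DataFrame,
                         frequency_table: pd.DataFrame | None = None
                         ) -> tuple[pd.DataFrame, GenotypeMatrix,
                                    list[WeightedFrequencyResult]]:
    """Finalize minor-allele orientation using weighted frequencies.

    For each variant, compute ``f_w`` for both alleles; the allele with the
    smaller ``f_w`` becomes ``allele_minor`` and the genotype column is
    flipped if the provisional orientation disagrees.  On an exact tie the
    alphabetically first allele is minor (deterministic).

    A frequency-table record whose allele matches neither sample allele is
    ignored with a warning.

    Returns the updated variant table (``f_w`` filled for the minor allele),
    the re-oriented genotype matrix, and per-variant bookkeeping.
    """
    variants = variants.copy()
    genotypes = genotypes.copy()
    ext = _index_frequency_table(frequency_table)
    results: list[WeightedFrequencyResult] = []

    for i, row in variants.iterrows():
        vid = row["variant_id"]
        a_min, a_maj = row["allele_minor"], row["allele_major"]
        f_s, n = sample_allele_frequency(genotypes, vid)

        f_e, m = float("nan"), 0
        rec = ext.get(vid) if ext is not None else None
        if rec is not None:
            allele, freq, count = rec
            if a_min == "." and allele != a_maj:
                # sample-monomorphic variant: the unobserved allele has no
                # name in the PED file; adopt the external table's identity
                a_min = allele
                variants.at[i, "allele_minor"] = allele
            if allele == a_min:
                f_e, m = freq, count
            elif allele == a_maj:
                f_e, m = 1.0 - freq, count
            else:
                warnings.warn(
                    f"frequency-table allele {allele!r} for variant {vid!r} "
                    f"matches neither sample allele ({a_min}/{a_maj}); "
                    "external frequency ignored")

        if n == 0 and m == 0:
            # no information at all: flagged by leaving f_w missing
            variants.at[i, "f_w"] = np.nan
            results.append(WeightedFrequencyResult(
                variant_id=vid, f_s=f_s, n=n, f_e=f_e, m=m, f_w=float("nan")))
            continue
        f_w = weighted_frequency(f_s, n, f_e if m else None, m if m else None)

        if f_w > 0.5 or (f_w == 0.5 and _alpha_major_first(a_min, a_maj)):
            # the provisional minor allele is actually the common one
            genotypes.flip_orientation(vid)
            variants.at[i, "allele_minor"] = a_maj
            variants.at[i, "allele_major"] = a_min
            f_s = 1.0 - f_s if not np.isnan(f_s) else f_s
            f_e = 1.0 - f_e if m else f_e
            f_w = 1.0 - f_w
        variants.at[i, "f_w"] = f_w
        results.append(WeightedFrequencyResult(
            variant_id=vid, f_s=f_s, n=n, f_e=f_e, m=m, f_w=f_w))

    return variants, genotypes, results


def _alpha_major_first(a_min, a_maj) -> bool:
    """Tie at f_w = 0.5: minor allele is the alphabetically first allele."""
    return str(a_maj) < str(a_min)


def _index_frequency_table(table: pd.DataFrame | None):
    if table is None:
        return None
    out = {}
    for rec in table.itertuples(index=False):
        out[str(rec.variant_id)] = (str(rec.allele), float(rec.freq),
                                    int(rec.allele_count))
    return out
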