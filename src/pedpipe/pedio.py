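"""Pedigree and genotype data model with readers/writers for the text
formats a family-based sequencing workflow touches.

The canonical interchange format is PLINK text PED/MAP.  Genotypes are held
as small-integer codes counting copies of the variant's *minor* allele
(``D`` in the usual Mendelian shorthand):

====  ==========  =========
code  symbol      meaning
====  ==========  =========
-1    ``./.``     missing
 0    ``dd``      homozygous major
 1    ``Dd``      heterozygous
 2    ``DD``      homozygous minor
====  ==========  =========

The PED reader assigns a *provisional* minor allele from sample allele
counts; the frequency-estimation step may later flip the orientation once
weighted population frequencies are known (see :mod:`pedpipe.afe`).
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

MISSING = -1
HOM_MAJOR = 0
HET = 1
HOM_MINOR = 2

SEX_MALE = "male"
SEX_FEMALE = "female"
SEX_UNKNOWN = "unknown"

AFFECTED = "affected"
UNAFFECTED = "unaffected"
UNKNOWN = "unknown"

_SEX_FROM_PLINK = {"1": SEX_MALE, "2": SEX_FEMALE}
_SEX_TO_PLINK = {SEX_MALE: "1", SEX_FEMALE: "2", SEX_UNKNOWN: "0"}
_PHENO_FROM_PLINK = {"1": UNAFFECTED, "2": AFFECTED}
_PHENO_TO_PLINK = {UNAFFECTED: "1", AFFECTED: "2", UNKNOWN: "0"}


class PedFileError(ValueError):
    """Malformed pedigree/genotype input; message names file and line."""

    def __init__(self, message: str, path: str | None = None,
                 line: int | None = None):
        loc = ""
        if path is not None:
            loc = f" [{path}" + (f", line {line}" if line is not None else "") + "]"
        super().__init__(message + loc)
        self.path = path
        self.line = line


class ColumnCountError(PedFileError):
    """A line has an unexpected number of whitespace-delimited fields."""


class UnknownParentError(PedFileError):
    """A parent id does not resolve to an individual in the same family."""


class DuplicateIndividualError(PedFileError):
    """An individual id occurs more than once within a family."""


class IbdTableError(ValueError):
    """An IBD probability record violates the probability-simplex invariant."""


@dataclass(frozen=True)
class Individual:
    """One pedigree member.

    ``father_id``/``mother_id`` are either both ``None`` (founder) or both
    given and resolving within the family.  Half-specified parents are
    rejected at construction: founder counts must be well defined for the
    pedigree bit-size formula.
    """

    family_id: str
    individual_id: str
    father_id: str | None = None
    mother_id: str | None = None
    sex: str = SEX_UNKNOWN
    affection: str = UNKNOWN

    def __post_init__(self):
        if (self.father_id is None) != (self.mother_id is None):
            raise PedFileError(
                f"individual {self.individual_id!r} in family "
                f"{self.family_id!r} has exactly one parent specified; "
                "give both or neither")

    @property
    def is_founder(self) -> bool:
        return self.father_id is None


class Pedigree:
    """An ordered collection of :class:`Individual` sharing a family id."""

    def __init__(self, family_id: str, members: Iterable[Individual]):
        self.family_id = family_id
        self.members: list[Individual] = list(members)
        if not self.members:
            raise PedFileError(f"family {family_id!r} has no members")
        self._by_id: dict[str, Individual] = {}
        for ind in self.members:
            if ind.individual_id in self._by_id:
                raise DuplicateIndividualError(
                    f"duplicate individual id {ind.individual_id!r} in "
                    f"family {family_id!r}")
            self._by_id[ind.individual_id] = ind
        for ind in self.members:
            for pid, role in ((ind.father_id, "father"), (ind.mother_id, "mother")):
                if pid is not None and pid not in self._by_id:
                    raise UnknownParentError(
                        f"{role} {pid!r} of individual "
                        f"{ind.individual_id!r} is not in family {family_id!r}")
        self._order = self._topological_order()
        self._kinship: np.ndarray | None = None

    def __len__(self) -> int:
        return len(self.members)

    def __contains__(self, individual_id: str) -> bool:
        return individual_id in self._by_id

    def __getitem__(self, individual_id: str) -> Individual:
        try:
            return self._by_id[individual_id]
        except KeyError:
            raise KeyError(
                f"no individual {individual_id!r} in family "
                f"{self.family_id!r}") from None

    @property
    def founders(self) -> list[Individual]:
        return [m for m in self.members if m.is_founder]

    @property
    def nonfounders(self) -> list[Individual]:
        return [m for m in self.members if not m.is_founder]

    def affected_ids(self) -> list[str]:
        return [m.individual_id for m in self.members if m.affection == AFFECTED]

    def _topological_order(self) -> list[str]:
        """Member ids with parents strictly before children; detects cycles."""
        order: list[str] = []
        placed: set[str] = set()
        remaining = {m.individual_id for m in self.members}
        while remaining:
            ready = [iid for iid in remaining
                     if all(p is None or p in placed
                            for p in (self._by_id[iid].father_id,
                                      self._by_id[iid].mother_id))]
            if not ready:
                raise PedFileError(
                    f"family {self.family_id!r} contains a pedigree cycle "
                    f"involving {sorted(remaining)}")
            # deterministic: keep original member order among ready ids
            for m in self.members:
                if m.individual_id in ready:
                    order.append(m.individual_id)
                    placed.add(m.individual_id)
                    remaining.discard(m.individual_id)
        return order

    # -- kinship ---------------------------------------------------------

    def kinship_matrix(self) -> pd.DataFrame:
        """Full kinship matrix by the recursive tabular method.

        Processes members parents-first; for non-founder *i* and earlier *j*,
        phi(i, j) = (phi(father_i, j) + phi(mother_i, j)) / 2 and
        phi(i, i) = 1/2 + phi(father_i, mother_i) / 2.
        """
        if self._kinship is None:
            order = self._order
            idx = {iid: k for k, iid in enumerate(order)}
            n = len(order)
            phi = np.zeros((n, n))
            for k, iid in enumerate(order):
                ind = self._by_id[iid]
                if ind.is_founder:
                    phi[k, k] = 0.5
                else:
                    f, m = idx[ind.father_id], idx[ind.mother_id]
                    phi[k, k] = 0.5 + 0.5 * phi[f, m]
                    for j in range(k):
                        phi[k, j] = phi[j, k] = 0.5 * (phi[f, j] + phi[m, j])
            self._kinship = pd.DataFrame(phi, index=order, columns=order)
        return self._kinship

    def kinship(self, id1: str, id2: str) -> float:
        """Kinship coefficient between two members (0.25 parent-offspring,
        0.0625 first cousins, 0 for unrelated)."""
        self[id1], self[id2]
        return float(self.kinship_matrix().loc[id1, id2])

    def classify_pair(self, id1: str, id2: str) -> str:
        """Classify a pair as ``parent_offspring``, ``other_blood_relative``
        or ``unrelated``.

        Parent-offspring means one is the *recorded* parent of the other.
        """
        a, b = self[id1], self[id2]
        if id1 in (b.father_id, b.mother_id) or id2 in (a.father_id, a.mother_id):
            return "parent_offspring"
        if self.kinship(id1, id2) > 0:
            return "other_blood_relative"
        return "unrelated"


def bit_size(pedigree: Pedigree) -> int:
    """Pedigree complexity: twice the number of non-founders minus the
    number of founders.  Governs the feasibility of exact pedigree-likelihood
    algorithms; may be negative for degenerate all-founder collections."""
    return 2 * len(pedigree.nonfounders) - len(pedigree.founders)


class GenotypeMatrix:
    """Diallelic genotype codes for (individual, variant) pairs.

    Rows are ``(family_id, individual_id)`` keys; columns are variant ids.
    Codes count copies of the variant's declared minor allele (see module
    docstring).
    """

    def __init__(self, samples: Sequence[tuple[str, str]],
                 variant_ids: Sequence[str], codes: np.ndarray):
        codes = np.asarray(codes, dtype=np.int8)
        if codes.shape != (len(samples), len(variant_ids)):
            raise ValueError(
                f"code matrix shape {codes.shape} does not match "
                f"{len(samples)} samples x {len(variant_ids)} variants")
        self.samples = list(samples)
        self.variant_ids = list(variant_ids)
        self.codes = codes
        self._row = {s: i for i, s in enumerate(self.samples)}
        self._col = {v: j for j, v in enumerate(self.variant_ids)}

    def row_index(self, family_id: str, individual_id: str) -> int:
        return self._row[(family_id, individual_id)]

    def col_index(self, variant_id: str) -> int:
        return self._col[variant_id]

    def genotype(self, family_id: str, individual_id: str,
                 variant_id: str) -> int:
        return int(self.codes[self.row_index(family_id, individual_id),
                              self.col_index(variant_id)])

    def column(self, variant_id: str) -> np.ndarray:
        return self.codes[:, self.col_index(variant_id)]

    def flip_orientation(self, variant_id: str) -> None:
        """Swap hom-minor/hom-major codes in place (minor allele relabelled);
        heterozygotes and missing cells are untouched."""
        j = self.col_index(variant_id)
        col = self.codes[:, j]
        nonmiss = col >= 0
        col[nonmiss] = 2 - col[nonmiss]

    def copy(self) -> "GenotypeMatrix":
        return GenotypeMatrix(self.samples, self.variant_ids, self.codes.copy())


VARIANT_COLUMNS = ["variant_id", "chromosome", "bp", "cm",
                   "allele_minor", "allele_major", "f_w", "gene_id"]


def make_variant_table(records: Iterable[dict]) -> pd.DataFrame:
    """Assemble a variant table with the canonical column set.

    Within each chromosome, variants must be sorted by bp ascending;
    variant ids must be unique and minor/major alleles must differ.
    """
    df = pd.DataFrame(list(records))
    for col in VARIANT_COLUMNS:
        if col not in df.columns:
            df[col] = np.nan
    df = df[VARIANT_COLUMNS].reset_index(drop=True)
    validate_variant_table(df)
    return df


def validate_variant_table(df: pd.DataFrame) -> None:
    if df["variant_id"].duplicated().any():
        dup = df.loc[df["variant_id"].duplicated(), "variant_id"].iloc[0]
        raise ValueError(f"duplicate variant id {dup!r}")
    for chrom, sub in df.groupby("chromosome", sort=False):
        if not sub["bp"].is_monotonic_increasing:
            raise ValueError(
                f"variants on chromosome {chrom} are not sorted by bp")
    bad = df["allele_minor"].notna() & (df["allele_minor"] == df["allele_major"])
    if bad.any():
        raise ValueError(
            f"variant {df.loc[bad, 'variant_id'].iloc[0]!r} has identical "
            "minor and major alleles")


# ---------------------------------------------------------------------------
# PED/MAP
# ---------------------------------------------------------------------------

def read_ped_map(ped_path, map_path):
    """Read PLINK text PED/MAP files.

    Returns ``(pedigrees, genotypes, variants)`` where *pedigrees* is a list
    of :class:`Pedigree` (one per family id, in order of first appearance),
    *genotypes* a :class:`GenotypeMatrix` coded against a provisional minor
    allele (the rarer allele in the sample; ties broken alphabetically), and
    *variants* a variant-table DataFrame.

    PED rows carry six leading columns (FID IID FAT MOT SEX PHENO) followed
    by two allele columns per variant; ``0`` alleles mark missing genotypes.
    Parent ids of ``0`` mean "no parent recorded".
    """
    variants_raw = _read_map(map_path)
    n_var = len(variants_raw)

    inds: list[Individual] = []
    sample_keys: list[tuple[str, str]] = []
    allele_rows: list[list[str]] = []
    seen: set[tuple[str, str]] = set()
    parent_refs: list[tuple[str, str, str, str, int]] = []

    with open(ped_path) as fh:
        for lineno, line in enumerate(fh, start=1):
            fields = line.split()
            if not fields:
                continue
            expected = 6 + 2 * n_var
            if len(fields) != expected:
                raise ColumnCountError(
                    f"expected {expected} columns (6 + 2 x {n_var} variants), "
                    f"found {len(fields)}", str(ped_path), lineno)
            fid, iid, fat, mot, sex, pheno = fields[:6]
            if (fid, iid) in seen:
                raise DuplicateIndividualError(
                    f"duplicate individual id {iid!r} in family {fid!r}",
                    str(ped_path), lineno)
            seen.add((fid, iid))
            father = None if fat == "0" else fat
            mother = None if mot == "0" else mot
            if (father is None) != (mother is None):
                raise PedFileError(
                    f"individual {iid!r} has exactly one parent recorded",
                    str(ped_path), lineno)
            if father is not None:
                parent_refs.append((fid, iid, fat, mot, lineno))
            inds.append(Individual(
                family_id=fid, individual_id=iid,
                father_id=father, mother_id=mother,
                sex=_SEX_FROM_PLINK.get(sex, SEX_UNKNOWN),
                affection=_PHENO_FROM_PLINK.get(pheno, UNKNOWN)))
            sample_keys.append((fid, iid))
            allele_rows.append(fields[6:])

    for fid, iid, fat, mot, lineno in parent_refs:
        for pid, role in ((fat, "father"), (mot, "mother")):
            if (fid, pid) not in seen:
                raise UnknownParentError(
                    f"{role} {pid!r} of individual {iid!r} is not present "
                    f"in family {fid!r}", str(ped_path), lineno)

    by_family: dict[str, list[Individual]] = {}
    for ind in inds:
        by_family.setdefault(ind.family_id, []).append(ind)
    pedigrees = [Pedigree(fid, members) for fid, members in by_family.items()]

    codes, minor_alleles, major_alleles = _code_alleles(
        allele_rows, n_var, str(ped_path))

    records = []
    for j, (chrom, vid, cm, bp) in enumerate(variants_raw):
        records.append(dict(
            variant_id=vid, chromosome=chrom, bp=bp,
            cm=cm if cm > 0 else np.nan,
            allele_minor=minor_alleles[j], allele_major=major_alleles[j],
            f_w=np.nan, gene_id=np.nan))
    variants = make_variant_table(records) if records else pd.DataFrame(
        columns=VARIANT_COLUMNS)

    genotypes = GenotypeMatrix(sample_keys, [v[1] for v in variants_raw],
                               codes)
    return pedigrees, genotypes, variants


def _read_map(map_path):
    out = []
    with open(map_path) as fh:
        for lineno, line in enumerate(fh, start=1):
            fields = line.split()
            if not fields:
                continue
            if len(fields) != 4:
                raise ColumnCountError(
                    f"expected 4 columns, found {len(fields)}",
                    str(map_path), lineno)
            chrom, vid, cm, bp = fields
            out.append((chrom, vid, float(cm), int(bp)))
    return out


def _code_alleles(allele_rows, n_var, path):
    """Count-based provisional orientation: the rarer allele is minor."""
    n = len(allele_rows)
    codes = np.full((n, n_var), MISSING, dtype=np.int8)
    minor = [None] * n_var
    major = [None] * n_var
    for j in range(n_var):
        counts: dict[str, int] = {}
        for row in allele_rows:
            for a in (row[2 * j], row[2 * j + 1]):
                if a != "0":
                    counts[a] = counts.get(a, 0) + 1
        alleles = sorted(counts)  # alphabetical tie-break
        if len(alleles) > 2:
            raise PedFileError(
                f"variant column {j} has more than two alleles: {alleles}",
                path)
        if not alleles:
            minor[j], major[j] = "D", "d"  # all-missing placeholder
            continue
        if len(alleles) == 1:
            # monomorphic: observed allele is major, minor is unknown ('.')
            major[j] = alleles[0]
            minor[j] = "."
            mn = "."
        else:
            a, b = alleles
            mn = a if counts[a] <= counts[b] else b
            minor[j] = mn
            major[j] = b if mn == a else a
        for i, row in enumerate(allele_rows):
            a1, a2 = row[2 * j], row[2 * j + 1]
            if a1 == "0" or a2 == "0":
                continue
            codes[i, j] = (a1 == mn) + (a2 == mn)
    return codes, minor, major


def write_ped_map(pedigrees, genotypes: GenotypeMatrix, variants: pd.DataFrame,
                  ped_path, map_path) -> None:
    """Write PLINK text PED/MAP; inverse of :func:`read_ped_map` up to
    allele-label permutation."""
    with open(map_path, "w") as fh:
        for _, v in variants.iterrows():
            cm = v["cm"] if pd.notna(v["cm"]) else 0
            fh.write(f"{v['chromosome']}\t{v['variant_id']}\t{cm:g}\t"
                     f"{int(v['bp'])}\n")

    minor = variants["allele_minor"].tolist()
    major = variants["allele_major"].tolist()
    with open(ped_path, "w") as fh:
        for ped in pedigrees:
            for ind in ped.members:
                row = genotypes.codes[
                    genotypes.row_index(ped.family_id, ind.individual_id)]
                fields = [ped.family_id, ind.individual_id,
                          ind.father_id or "0", ind.mother_id or "0",
                          _SEX_TO_PLINK[ind.sex], _PHENO_TO_PLINK[ind.affection]]
                for j, code in enumerate(row):
                    if code == MISSING:
                        fields += ["0", "0"]
                    elif code == HOM_MAJOR:
                        fields += [major[j], major[j]]
                    elif code == HET:
                        fields += [minor[j], major[j]]
                    else:
                        fields += [minor[j], minor[j]]
                fh.write(" ".join(fields) + "\n")


# ---------------------------------------------------------------------------
# Auxiliary tables
# ---------------------------------------------------------------------------

IBD_COLUMNS = ["family_id", "id1", "id2", "position", "p0", "p1", "p2"]


def read_ibd_table(path) -> pd.DataFrame:
    """Read a Merlin-style pairwise IBD table.

    Whitespace-delimited columns: FAMILY ID1 ID2 POSITION P0 P1 P2, header
    optional.  Each record's (p0, p1, p2) must sum to 1 within 1e-6.
    """
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            fields = line.split()
            if not fields:
                continue
            if len(fields) != 7:
                raise IbdTableError(
                    f"{path}, line {lineno}: expected 7 columns, "
                    f"found {len(fields)}")
            try:
                pos = float(fields[3])
                p0, p1, p2 = (float(x) for x in fields[4:7])
            except ValueError:
                if lineno == 1:
                    continue  # header line
                raise IbdTableError(
                    f"{path}, line {lineno}: non-numeric probability fields")
            if abs(p0 + p1 + p2 - 1.0) > 1e-6:
                raise IbdTableError(
                    f"{path}, line {lineno}: IBD state probabilities sum to "
                    f"{p0 + p1 + p2:.8f}, not 1")
            rows.append((fields[0], fields[1], fields[2], pos, p0, p1, p2))
    return pd.DataFrame(rows, columns=IBD_COLUMNS)


def write_ibd_table(df: pd.DataFrame, path) -> None:
    with open(path, "w") as fh:
        fh.write("FAMILY ID1 ID2 POSITION P0 P1 P2\n")
        for rec in df.itertuples(index=False):
            fh.write(f"{rec.family_id} {rec.id1} {rec.id2} {rec.position:g} "
                     f"{rec.p0:g} {rec.p1:g} {rec.p2:g}\n")


def read_frequency_table(path) -> pd.DataFrame:
    """Read a tab-delimited external allele-frequency table.

    Columns: variant_id, chromosome, bp, allele, freq, allele_count.  The
    frequency refers to the named allele; allele_count is the number of
    chromosomes it was estimated from.
    """
    df = pd.read_csv(path, sep="\t", dtype={"variant_id": str,
                                            "chromosome": str,
                                            "allele": str})
    required = {"variant_id", "allele", "freq", "allele_count"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"frequency table {path} lacks columns {sorted(missing)}")
    if ((df["freq"] < 0) | (df["freq"] > 1)).any():
        raise ValueError(f"frequency table {path} has freq outside [0, 1]")
    if (df["allele_count"] < 0).any():
        raise ValueError(f"frequency table {path} has negative allele_count")
    return df


def read_gene_map(path) -> pd.DataFrame:
    """Read a tab-delimited variant-to-gene assignment (variant_id, gene_id)."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    if not {"variant_id", "gene_id"} <= set(df.columns):
        raise ValueError(f"gene map {path} must have variant_id and gene_id columns")
    return df
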