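import numpy as np
import pytest

from pedpipe.pedio import (AFFECTED, UNAFFECTED, GenotypeMatrix, Individual,
                           Pedigree)


def make_matrix(codes, family="F1"):
    """GenotypeMatrix from a codes array; rows are individuals 1..n of one
    family, columns v1..vm."""
    codes = np.asarray(codes, dtype=np.int8)
    samples = [(family, str(i + 1)) for i in range(codes.shape[0])]
    vids = [f"v{j + 1}" for j in range(codes.shape[1])]
    return GenotypeMatrix(samples, vids, codes)


def build_pedigree(family_id, rows):
    """rows: (iid, father, mother, sex, affection)."""
    return Pedigree(family_id, [
        Individual(family_id=family_id, individual_id=i, father_id=f,
                   mother_id=m, sex=s, affection=a)
        for i, f, m, s, a in rows])


@pytest.fixture
def nuclear_family():
    """Two parents, affected son, unaffected daughter."""
    return build_pedigree("F1", [
        ("1", None, None, "male", UNAFFECTED),
        ("2", None, None, "female", UNAFFECTED),
        ("3", "1", "2", "male", AFFECTED),
        ("4", "1", "2", "female", UNAFFECTED),
    ])


@pytest.fixture
def three_generation_family():
    """12 members, 4 founders: grandparents, three children (two married
    to founder spouses), five grandchildren; two affected cousins."""
    return build_pedigree("F1", [
        ("1", None, None, "male", UNAFFECTED),
        ("2", None, None, "female", UNAFFECTED),
        ("3", "1", "2", "male", UNAFFECTED),
        ("4", "1", "2", "female", UNAFFECTED),
        ("5", "1", "2", "female", UNAFFECTED),
        ("6", None, None, "female", UNAFFECTED),
        ("7", None, None, "male", UNAFFECTED),
        ("8", "3", "6", "male", UNAFFECTED),
        ("9", "3", "6", "female", AFFECTED),
        ("10", "3", "6", "male", UNAFFECTED),
        ("11", "7", "4", "female", AFFECTED),
        ("12", "7", "4", "male", UNAFFECTED),
    ])
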