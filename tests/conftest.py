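"""Shared fixtures: the packaged annotation table and small synthetic inputs."""

import numpy as np
import pytest

import ripscan as rs

AAS = np.array(list("ACDEFGHIKLMNPQRSTVWY"))


@pytest.fixture(scope="session")
def table1():
    return rs.load_table1_fixture()


@pytest.fixture(scope="session")
def table1_by_id(table1):
    return {a.protein_id: a for a in table1}


@pytest.fixture(scope="session")
def catalog():
    return rs.default_catalog()


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def random_protein(rng, length, pid="P1"):
    return rs.ProteinRecord(id=pid, sequence="".join(rng.choice(AAS, size=length)))


@pytest.fixture()
def toy_mbtf():
    """A 120-residue protein: TFFD 10-60, TMD 81-102 (type II, C-class)."""
    seq = (
        "M" + "Q" * 9                      # 1-10
        + "D" * 51                          # TFFD body to 61
        + "S" * 19                          # linker to 80
        + "LLLLLAGALLLLVVKLLLILLL"          # TMD 81-102 (GA at 87-88, K at 95)
        + "N" * 18                          # tail to 120
    )
    rec = rs.ProteinRecord(id="TOY1", sequence=seq)
    ann = rs.DomainAnnotation(
        protein_id="TOY1", tffd=(10, 60),
        tmds=[rs.TMDSpan(start=81, end=102, topology="II")],
    )
    return rec, ann
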