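import numpy as np
import pandas as pd
import pytest

from ampliscope import generate_fixture_collection, hc_design, simulate_dataset
from ampliscope.simulate import ERROR_FREE
from ampliscope.taxonomy import TaxNode, TaxonomyTree

#: Hand-built taxonomy: an order with two families, one lineage per genus;
#: taxids 22 and 43 share the name "Dup" at different depths.
TOY_NODES = {
    1: TaxNode(1, 1, "no rank", "root"),
    10: TaxNode(10, 1, "order", "OrderA"),
    20: TaxNode(20, 10, "family", "FamX"),
    21: TaxNode(21, 10, "family", "FamY"),
    22: TaxNode(22, 10, "family", "Dup"),
    30: TaxNode(30, 20, "genus", "GenX1"),
    31: TaxNode(31, 21, "genus", "GenY1"),
    40: TaxNode(40, 30, "species", "SpX1a"),
    41: TaxNode(41, 31, "species", "SpY1a"),
    42: TaxNode(42, 31, "species", "SpY1b"),
    43: TaxNode(43, 31, "species", "Dup"),
}


@pytest.fixture()
def toy_tree() -> TaxonomyTree:
    return TaxonomyTree(dict(TOY_NODES))


@pytest.fixture(scope="session")
def fixture_collection():
    return generate_fixture_collection(seed=1)


@pytest.fixture(scope="session")
def error_free_dataset(fixture_collection, tmp_path_factory):
    """HC design, 1,200 error-free reads off the synthetic genomes."""
    fc = fixture_collection
    design = hc_design(sorted(fc.genomes))
    out = tmp_path_factory.mktemp("ds") / "reads.fastq"
    return simulate_dataset(
        fc.genomes, fc.species_taxids, design, fc.primers,
        n_reads=1200, params=ERROR_FREE, seed=11, out_fastq=out,
    )


def oracle_assignment(truth: pd.DataFrame) -> pd.DataFrame:
    """Truth-copying pipeline: every read classified to its source taxid."""
    return pd.DataFrame(
        {"read_id": truth["read_id"], "status": "classified", "taxid": truth["taxid"]}
    )


def all_unclassified(truth: pd.DataFrame) -> pd.DataFrame:
    return pd.DataFrame(
        {"read_id": truth["read_id"], "status": "unclassified", "taxid": pd.NA}
    )


# -- independent oracles ---------------------------------------------------


def set_partitions(items):
    """All set partitions of *items* (independent recursive enumeration)."""
    items = list(items)
    if not items:
        yield []
        return
    first, rest = items[0], items[1:]
    for part in set_partitions(rest):
        for i in range(len(part)):
            yield part[:i] + [[first] + part[i]] + part[i + 1:]
        yield part + [[first]]


def partition_to_labels(partition, n):
    labels = [0] * n
    for k, block in enumerate(partition):
        for item in block:
            labels[item] = k
    return labels


def entropy_oracle(labels) -> float:
    counts = pd.Series(list(labels)).value_counts().to_numpy(dtype=float)
    p = counts / counts.sum()
    return float(-(p * np.log(p)).sum())


def mutual_info_oracle(u, v) -> float:
    n = len(u)
    joint: dict = {}
    for a, b in zip(u, v):
        joint[(a, b)] = joint.get((a, b), 0) + 1
    pu = pd.Series(list(u)).value_counts() / n
    pv = pd.Series(list(v)).value_counts() / n
    mi = 0.0
    for (a, b), c in joint.items():
        pab = c / n
        mi += pab * np.log(pab / (pu[a] * pv[b]))
    return float(max(0.0, mi))


def nmi_oracle(u, v) -> float:
    """I / max(H_U, H_V) with the package's degenerate conventions."""
    hu, hv = entropy_oracle(u), entropy_oracle(v)
    if hu == 0.0 and hv == 0.0:
        return 1.0
    if hu == 0.0 or hv == 0.0:
        return 0.0
    return mutual_info_oracle(u, v) / max(hu, hv)
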