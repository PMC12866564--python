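import numpy as np
import pandas as pd
import pytest

from phyllopan.io_formats import AbundanceTable, MetadataTable, OrthogroupMatrix


@pytest.fixture
def tiny_matrix() -> OrthogroupMatrix:
    counts = pd.DataFrame(
        [[2, 0, 1], [0, 3, 1], [1, 1, 0]],
        index=["A", "B", "C"], columns=["OG1", "OG2", "OG3"],
    )
    return OrthogroupMatrix(counts=counts)


@pytest.fixture
def six_isolate_meta() -> MetadataTable:
    rows = []
    for i, (genus, source) in enumerate([
        ("Aureobasidium", "leaf"), ("Aureobasidium", "leaf"),
        ("Candida", "soil"), ("Candida", "soil"),
        ("Rhodotorula", "water"), ("Rhodotorula", "water"),
    ]):
        rows.append({"isolate_id": f"i{i + 1}", "genus": genus, "species": "-",
                     "source": source, "year": "-", "cluster": "-"})
    return MetadataTable(pd.DataFrame(rows).set_index("isolate_id"))


@pytest.fixture
def abundance_two_years() -> AbundanceTable:
    rng = np.random.default_rng(11)
    samples = [f"y{yr}_s{i}" for yr in (2020, 2021) for i in range(5)]
    years = pd.Series([2020] * 5 + [2021] * 5, index=samples)
    counts = pd.DataFrame(rng.integers(0, 200, size=(10, 4)),
                          index=samples, columns=list("wxyz"))
    counts += 1  # keep totals positive
    return AbundanceTable(counts=counts, sample_year=years)


@pytest.fixture
def annotation_frame() -> pd.DataFrame:
    rows = [
        ("A_g1", "A", "OG1", frozenset("G"), frozenset({"K00001"})),
        ("A_g2", "A", "OG1", frozenset("GQ"), frozenset()),
        ("A_g3", "A", "OG2", frozenset(), frozenset({"K00002", "K00003"})),
        ("B_g1", "B", "OG2", frozenset("E"), frozenset()),
        ("B_g2", "B", "OG3", frozenset("Q"), frozenset({"K00001"})),
    ]
    return pd.DataFrame(rows, columns=["gene_id", "isolate_id", "orthogroup_id",
                                       "cog", "kos"])
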