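import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from stablepull import Ontology
from stablepull.quant import QuantTable

settings.register_profile("suite", derandomize=True, max_examples=50,
                          deadline=None)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def chain():
    """C is_a A is_a R."""
    return Ontology.from_edges([("C", "A", "is_a"), ("A", "R", "is_a")])


@pytest.fixture(scope="session")
def diamond():
    """C is_a {A, B}; A, B is_a R."""
    return Ontology.from_edges([
        ("C", "A", "is_a"), ("C", "B", "is_a"),
        ("A", "R", "is_a"), ("B", "R", "is_a"),
    ])


def make_table(rows, replicate_id="rep1", protocol="adapted"):
    """Build a QuantTable from compact row dicts (defaults pass filters)."""
    records = []
    for i, row in enumerate(rows):
        rec = {
            "protein_group_id": f"P{i + 1:03d}",
            "gene_name": f"G{i + 1:03d}",
            "ratio_hl": 1.0,
            "ratio_count": 3,
            "peptides": 3,
            "unique_peptides": 2,
            "intensity": 1e7,
            "only_by_site": False,
            "reverse": False,
            "contaminant": False,
            "ratio_rnase": np.nan,
        }
        rec.update(row)
        records.append(rec)
    return QuantTable(replicate_id=replicate_id, protocol=protocol,
                      data=pd.DataFrame(records))


@pytest.fixture
def toy_table():
    return make_table([{} for _ in range(5)])
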