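import numpy as np
import pandas as pd
import pytest

from xci.io_formats import GeneModel


@pytest.fixture
def toy_counts() -> pd.DataFrame:
    """Two sites, two tissues, hand-sized counts."""
    rows = []
    for unit, (r1, a1, r2, a2) in {
        "tissue_A": (95, 5, 40, 60),
        "tissue_B": (90, 10, 45, 55),
    }.items():
        rows.append(("X", 1000, "X:1000", "A", "G", unit, r1, a1))
        rows.append(("X", 2000, "X:2000", "C", "T", unit, r2, a2))
    return pd.DataFrame(
        rows,
        columns=[
            "chrom",
            "pos",
            "site_id",
            "ref_allele",
            "alt_allele",
            "unit_id",
            "ref_count",
            "alt_count",
        ],
    )


@pytest.fixture
def toy_genes() -> list[GeneModel]:
    return [
        GeneModel("GENE1", "GENE1", "X", 500, 1500, "nonPAR_Xp"),
        GeneModel("GENE2", "GENE2", "X", 1800, 2500, "nonPAR_Xp"),
    ]
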