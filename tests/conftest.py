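import numpy as np
import pandas as pd
import pytest

from interactome_kit.calling import QuantTable
from interactome_kit.orthology import Member, OrthologGroupSet
from interactome_kit.profiles import RegionModel
from interactome_kit.synthetic_data import default_trna_region_model


@pytest.fixture
def small_quant_table() -> QuantTable:
    """Six protein groups, three replicates, hand-set ratios."""
    index = pd.Index([f"PG{i}" for i in range(6)], name="group_id")
    ratios = pd.DataFrame(
        [
            [2.1, 1.9, 2.0],
            [0.1, -0.2, 0.05],
            [3.0, 2.5, 2.8],
            [0.0, 0.0, 0.0],
            [-1.0, -1.2, -0.9],
            [0.5, np.nan, 0.4],
        ],
        index=index,
        columns=["CL_rep1_logratio", "CL_rep2_logratio", "CL_rep3_logratio"],
    )
    return QuantTable(
        ratios=ratios,
        accessions=pd.Series([[f"P{i}"] for i in range(6)], index=index),
        gene=pd.Series([f"gene{i}" for i in range(6)], index=index),
        organism="yeast",
    )


@pytest.fixture
def toy_groups() -> OrthologGroupSet:
    return OrthologGroupSet(
        groups={
            "OG1": [
                Member("yeast", "Y1", 100),
                Member("human", "H1", 300),
                Member("human", "H2", 250),
            ],
            "OG2": [Member("yeast", "Y2", 150), Member("human", "H3", 200)],
            "OG3": [Member("yeast", "Y3", 120), Member("human", "H4", 180)],
        },
        species=("yeast", "human"),
    )


@pytest.fixture
def trna_model() -> RegionModel:
    return default_trna_region_model(n_genes=4)
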