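import numpy as np
import pandas as pd
import pytest

from regulonet.diffexpr import CountMatrix, DEResult
from regulonet.regulon import InteractionDatabase


@pytest.fixture
def toy_db() -> InteractionDatabase:
    """Three regulators over four targets with partial sharing."""
    edges = {
        ("A", "G1"), ("A", "G2"),
        ("B", "G1"),
        ("C", "G2"), ("C", "G3"), ("C", "G4"),
    }
    return InteractionDatabase(edges=frozenset(edges))


@pytest.fixture
def toy_counts() -> CountMatrix:
    """Six genes x four samples (2 WT vs 2 KO in HE), exact integers."""
    rng = np.random.default_rng(42)
    counts = pd.DataFrame(
        rng.poisson(100, size=(6, 4)),
        index=[f"G{i}" for i in range(1, 7)],
        columns=["HE_WT_1", "HE_WT_2", "HE_KO_1", "HE_KO_2"],
    )
    metadata = pd.DataFrame(
        {
            "subset": ["HE"] * 4,
            "genotype": ["WT", "WT", "KO", "KO"],
            "dox": ["no"] * 4,
            "replicate": [1, 2, 1, 2],
        },
        index=counts.columns,
    )
    return CountMatrix(counts=counts, metadata=metadata)


def make_de_result(universe, up=(), down=(), contrast_id="toy", lfc=None):
    """Hand-built classified DEResult over an explicit gene universe."""
    universe = list(universe)
    up, down = set(up), set(down)
    direction = ["up" if g in up else "down" if g in down else "nc" for g in universe]
    if lfc is None:
        lfc = [2.0 if g in up else -2.0 if g in down else 0.0 for g in universe]
    table = pd.DataFrame(
        {
            "log2fc": lfc,
            "p_value": [0.001 if g in up | down else 0.5 for g in universe],
            "q_value": [0.01 if g in up | down else 0.9 for g in universe],
            "direction": direction,
        },
        index=pd.Index(universe, name="gene"),
    )
    return DEResult(table=table, contrast_id=contrast_id)


@pytest.fixture
def de_20genes():
    """Universe of 20 genes with a 5-gene up set (matches the 155/4845 case)."""
    universe = [f"G{i}" for i in range(1, 21)]
    return make_de_result(universe, up=universe[:5])
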