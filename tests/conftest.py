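import numpy as np
import pandas as pd
import pytest

from ncnet.de import CountMatrix
from ncnet.io import InteractionTable


@pytest.fixture
def toy_counts():
    """Small two-group count matrix with equal per-group structure."""
    rng = np.random.default_rng(42)
    counts = pd.DataFrame(
        rng.poisson(50, size=(30, 8)),
        index=[f"f{i}" for i in range(30)],
        columns=[f"s{i}" for i in range(8)],
    )
    groups = {f"s{i}": ("A" if i < 4 else "B") for i in range(8)}
    return CountMatrix(counts, groups)


def make_interactions(rows):
    """Build an InteractionTable from (src, scls, tgt, tcls, ev, score)."""
    df = pd.DataFrame(rows, columns=["source_id", "source_class", "target_id",
                                     "target_class", "evidence", "score"])
    df["score"] = df["score"].astype(float)
    return InteractionTable(df)


@pytest.fixture
def evidence_small():
    return make_interactions([
        ("miR-1", "miRNA", "G1", "mRNA", "validated", np.nan),
        ("miR-1", "miRNA", "G2", "mRNA", "validated", np.nan),
        ("miR-2", "miRNA", "G1", "mRNA", "validated", np.nan),
        ("L1", "lncRNA", "miR-1", "miRNA", "validated", np.nan),
        ("L1", "lncRNA", "miR-2", "miRNA", "predicted", 0.8),
        ("L2", "lncRNA", "miR-1", "miRNA", "predicted", 0.59),
        ("L2", "lncRNA", "miR-2", "miRNA", "predicted", 0.60),
        ("L1", "lncRNA", "G1", "mRNA", "validated", np.nan),
        ("L2", "lncRNA", "G2", "mRNA", "predicted", 0.9),
    ])
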