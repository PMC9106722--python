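import numpy as np
import pandas as pd
import pytest

from pausekit.genome import CoverageTrack


def jaccard(a, b) -> float:
    a, b = set(a), set(b)
    return len(a & b) / len(a | b) if (a or b) else 1.0


def make_tr_table(tr_values, gene_ids=None) -> pd.DataFrame:
    """TR table with the given TR values, all genes eligible."""
    n = len(tr_values)
    if gene_ids is None:
        gene_ids = [f"g{i}" for i in range(n)]
    return pd.DataFrame(
        {
            "gene_id": list(gene_ids),
            "promoter_density": np.asarray(tr_values, dtype=float),
            "body_density": np.ones(n),
            "tr": np.asarray(tr_values, dtype=float),
            "eligible": [True] * n,
            "reason": [""] * n,
        }
    )


@pytest.fixture
def uniform_track():
    """Track with constant coverage 2.0 over a 100 kb chromosome and a 1e6
    fragment library, so densities equal raw mean coverage."""
    return CoverageTrack(
        coverage={"chr1": np.full(100_000, 2.0)}, total_fragments=1_000_000
    )
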