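import numpy as np
import pandas as pd
import pytest


@pytest.fixture
def toy_report() -> pd.DataFrame:
    """Six cytosines over two bins, both strands, all three contexts."""
    return pd.DataFrame(
        {
            "chrom": ["2"] * 6,
            "pos": [1, 150, 200, 201, 350, 401],
            "strand": ["+", "-", "+", "+", "-", "+"],
            "meth": [3, 1, 4, 0, 2, 5],
            "unmeth": [7, 9, 6, 10, 8, 5],
            "context": ["CG", "CG", "CHG", "CG", "CHH", "CG"],
            "trinucleotide": ["NNN"] * 6,
        }
    )


@pytest.fixture
def random_report() -> pd.DataFrame:
    """10 000 random cytosine records for conservation checks."""
    rng = np.random.default_rng(123)
    n = 10_000
    return pd.DataFrame(
        {
            "chrom": rng.choice(["1", "2"], size=n),
            "pos": rng.integers(1, 50_000, size=n),
            "strand": rng.choice(["+", "-"], size=n),
            "meth": rng.integers(0, 20, size=n),
            "unmeth": rng.integers(0, 20, size=n),
            "context": rng.choice(["CG", "CHG", "CHH"], size=n),
            "trinucleotide": "NNN",
        }
    )
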