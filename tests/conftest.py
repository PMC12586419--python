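import numpy as np
import pandas as pd
import pytest

from wheatgs.panel import MarkerPanel


@pytest.fixture(scope="session")
def random_panel():
    """Complete 60 x 200 dosage panel with a plain map (no structure)."""
    rng = np.random.default_rng(42)
    p = 200
    freqs = rng.uniform(0.1, 0.9, p)
    dosage = rng.binomial(2, freqs, size=(60, p)).astype(float)
    marker_map = pd.DataFrame(
        {
            "marker": [f"m{j}" for j in range(p)],
            "chromosome": (np.arange(p) % 4 + 1).astype(str),
            "position_mb": np.tile(np.linspace(1, 100, p // 4), 4),
        }
    )
    return MarkerPanel(
        dosage=dosage,
        marker_map=marker_map,
        genotype_ids=np.array([f"g{i:03d}" for i in range(60)]),
        imputed=True,
    )


@pytest.fixture(scope="session")
def balanced_book():
    """Balanced 40-genotype x 3-env x 2-rep phenotype table with known truth."""
    rng = np.random.default_rng(7)
    g, e, r = 40, 3, 2
    gen = rng.normal(0, 2.0, g)
    env = rng.normal(0, 1.0, e)
    rep = rng.normal(0, 0.5, (e, r))
    ge = rng.normal(0, 1.0, (g, e))
    rows = []
    for j in range(e):
        for i in range(r):
            eps = rng.normal(0, 1.0, g)
            for k in range(g):
                rows.append(
                    (f"g{k:03d}", f"E{j + 1}", f"R{i + 1}", "t",
                     10 + env[j] + rep[j, i] + gen[k] + ge[k, j] + eps[k])
                )
    book = pd.DataFrame(rows, columns=["genotype", "environment", "replicate",
                                       "trait", "value"])
    return book, gen
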