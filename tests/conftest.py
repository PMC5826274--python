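import numpy as np
import pandas as pd
import pytest

from coexnet.synthdata import SynthConfig, generate_expression


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240817)


@pytest.fixture(scope="session")
def small_planted():
    """Three 60-gene modules plus background, 40 samples: fast recovery fixture."""
    cfg = SynthConfig(
        n_samples=40,
        module_sizes=(60, 60, 60),
        n_background_genes=90,
        kme_targets=0.9,
        trait_couplings={"motifs": ("blue", 0.85)},
        preserved_modules=("turquoise", "blue"),
        seed=101,
    )
    expr, truth = generate_expression(cfg)
    return cfg, expr, truth


@pytest.fixture()
def toy_expr():
    """Tiny deterministic expression matrix (4 genes x 6 samples)."""
    rng = np.random.default_rng(7)
    x = rng.standard_normal((4, 6))
    return pd.DataFrame(
        x,
        index=pd.Index([f"g{i}" for i in range(4)], name="gene_id"),
        columns=[f"s{j}" for j in range(6)],
    )
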