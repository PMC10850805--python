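import numpy as np
import pandas as pd
import pytest

from vulnprior.panel_io import GeneId, ScreenMatrix
from vulnprior.synthetic_panel import PanelConfig, generate_panel


@pytest.fixture(scope="session")
def small_config() -> PanelConfig:
    return PanelConfig(
        n_lines=30,
        n_hnscc=20,
        n_genes=120,
        n_druggable=40,
        n_common_essential=8,
        n_core_fitness=6,
        n_planted_targets=5,
        n_tumours=80,
        n_hpv_positive=10,
        n_hpv_unknown=5,
        seed=11,
    )


@pytest.fixture(scope="session")
def small_bundle(small_config):
    return generate_panel(small_config)


@pytest.fixture(scope="session")
def small_bundle_dir(small_config, tmp_path_factory):
    out = tmp_path_factory.mktemp("bundle")
    generate_panel(small_config, out_dir=out)
    return out


def make_matrix(values, line_ids=None, symbols=None, role="effect") -> ScreenMatrix:
    """Build a ScreenMatrix from a 2-D array for tests."""
    arr = np.asarray(values, dtype=float)
    lines = line_ids or [f"L{i}" for i in range(arr.shape[0])]
    syms = symbols or [f"G{j}" for j in range(arr.shape[1])]
    df = pd.DataFrame(arr, index=lines, columns=syms)
    return ScreenMatrix(role, df, [GeneId(s) for s in syms])
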