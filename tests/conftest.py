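import numpy as np
import pandas as pd
import pytest

import leukotraj as lt


@pytest.fixture(scope="session")
def small_cfg() -> lt.SimulationConfig:
    """A compact but composition-balanced synthetic study."""
    return lt.SimulationConfig(n_genes_per_class=40, n_background=2000,
                               n_absent=40, n_other=20, seed=42)


@pytest.fixture(scope="session")
def small_study(small_cfg):
    matrix, truth = lt.simulate_trajectory_counts(small_cfg)
    return small_cfg, matrix, truth


@pytest.fixture(scope="session")
def small_profile(small_study):
    _cfg, matrix, _truth = small_study
    return lt.summarize_conditions(lt.normalize_cpm(matrix))


def random_profile_frame(rng: np.random.Generator, n: int) -> pd.DataFrame:
    """Random per-gene (summary, presence) triples spanning all rule regions."""
    summaries = rng.uniform(0.0, 12.0, size=(n, 3))
    presence = rng.random((n, 3)) < 0.8
    return pd.DataFrame({
        "c": summaries[:, 0], "s": summaries[:, 1], "l": summaries[:, 2],
        "pc": presence[:, 0], "ps": presence[:, 1], "pl": presence[:, 2],
    })
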