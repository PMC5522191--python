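from pathlib import Path

import numpy as np
import pandas as pd
import pytest

from lincqtl.simulate import SimConfig, generate_dataset

REPO_ROOT = Path(__file__).resolve().parent.parent
QTL_TOP20 = REPO_ROOT / "examples" / "data" / "qtl_top20.tsv"


def zero_noise_config(seed: int = 11, de_fraction: float = 0.0) -> SimConfig:
    """No coding-call flips, optionally no planted DE effects."""
    return SimConfig(
        seed=seed,
        de_fraction=de_fraction,
        coding_tool_error_rates={t: (0.0, 0.0) for t in ("CPC", "CNCI", "CPAT", "Pfam")},
    )


@pytest.fixture(scope="session")
def sim_zero_noise(tmp_path_factory):
    """Clean coding calls, no DE effects: exact-recovery conditions."""
    out = tmp_path_factory.mktemp("sim_zero")
    return generate_dataset(zero_noise_config(), out)


@pytest.fixture(scope="session")
def sim_planted_de(tmp_path_factory):
    """Clean coding calls with planted DE effects (default fraction)."""
    out = tmp_path_factory.mktemp("sim_de")
    return generate_dataset(zero_noise_config(seed=13, de_fraction=0.1), out)


@pytest.fixture(scope="session")
def qtl_top20() -> pd.DataFrame:
    return pd.read_csv(QTL_TOP20, sep="\t", dtype={"Chrome": str, "Score": str})


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20240917)
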