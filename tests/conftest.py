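import numpy as np
import pandas as pd
import pytest

from pollennet import SimulationConfig, simulate_dataset


@pytest.fixture()
def toy_loads() -> pd.DataFrame:
    """Nine stigmas over three species: pure-CP, mixed, and one empty stigma."""
    rows = [
        ("s1", "A", 10, 0, 0),
        ("s2", "A", 20, 0, 0),
        ("s3", "A", 30, 0, 0),
        ("s4", "B", 30, 4, 2),
        ("s5", "B", 10, 2, 1),
        ("s6", "B", 20, 0, 0),
        ("s7", "C", 0, 0, 0),
        ("s8", "C", 5, 5, 1),
        ("s9", "C", 15, 10, 3),
    ]
    return pd.DataFrame(rows, columns=["stigma_id", "species", "cp", "hp", "hp_diversity"])


@pytest.fixture(scope="session")
def small_community():
    """A 6-plant synthetic community reused across read-only tests."""
    cfg = SimulationConfig(
        n_plants=6, n_pollinators=8, target_links=20, n_stigmas=50, seed=11
    )
    return simulate_dataset(cfg)


@pytest.fixture()
def write_csv(tmp_path):
    def _write(name: str, text: str):
        p = tmp_path / name
        p.write_text(text)
        return p

    return _write
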