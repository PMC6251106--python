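import numpy as np
import pandas as pd
import pytest

from sociobiome import io as sio
from sociobiome.simulate import (
    BandComposition,
    SimConfig,
    build_relationship_map,
    simulate_study,
    small_config,
)


@pytest.fixture(scope="session")
def small_study():
    """One reduced synthetic study shared by read-only tests."""
    return simulate_study(small_config(seed=11))


@pytest.fixture(scope="session")
def small_rel(small_study):
    return sio.to_relative_abundance(small_study["counts"])


@pytest.fixture()
def tiny_config():
    """Single band of three individuals; fast degenerate-case runs."""
    return SimConfig(
        band_names=["B1"],
        compositions=[BandComposition(mares=1, foal_f=1)],
        n_svs=10,
        samples_per_individual=(2, 2),
        depth_range=(500, 500),
        n_days=6,
        seed=5,
    )


def relmap_for(config):
    return build_relationship_map(config)


def rel_rows(*rows, prefix="s"):
    """Relative-abundance DataFrame from explicit row tuples."""
    arr = np.asarray(rows, dtype=float)
    return pd.DataFrame(
        arr,
        index=[f"{prefix}{i + 1}" for i in range(arr.shape[0])],
        columns=[f"SV{j + 1}" for j in range(arr.shape[1])],
    )
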