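import numpy as np
import pandas as pd
import pytest

from aposcore import synthetic_data as sd
from aposcore.game_ingest import LOG_COLUMNS


@pytest.fixture(scope="session")
def small_config():
    """A scaled-down study: 12 species, 5 backgrounds, 80 players."""
    return sd.SimConfig(
        n_species=12,
        n_backgrounds=5,
        rounds_per_game=5,
        n_players=80,
        games_per_player=2,
        n_missing_dorsal=2,
        n_dimorphic=1,
        seed=7,
    )


@pytest.fixture(scope="session")
def small_dataset(small_config):
    return sd.simulate_dataset(small_config)


def make_rounds(rows):
    """Build a round-log DataFrame from (user, game, idx, img, sp, side, bg,
    outcome, time) tuples."""
    return pd.DataFrame(rows, columns=LOG_COLUMNS)


def write_log(path, df):
    df.to_csv(path, sep="\t", index=False)
    return str(path)


@pytest.fixture
def rng():
    return np.random.default_rng(2024)
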