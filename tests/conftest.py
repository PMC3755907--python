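import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))

from mapipe.simulate import (SimConfig, generate_genome, simulate_ma_lines)


def small_sim_config(**overrides) -> SimConfig:
    """A reduced MA experiment (120 kb genome, short repeats only) that keeps
    every qualitative feature of the full study conditions but runs in ~1 s."""
    spec = []
    for unit, counts in [("A", [1200, 400, 133, 44]),
                         ("C", [40, 14, 5, 2]),
                         ("GT", [120, 40, 13, 4]),
                         ("AT", [120, 40, 13, 4]),
                         ("AAT", [12, 4, 0, 0])]:
        for i, n in enumerate(counts):
            if n:
                spec.append((unit, 3 + i, n))
    defaults = dict(genome_length=120_000, repeat_spec=spec,
                    slippage_base_rate=1e-5, snv_rate=2e-8,
                    cluster_fraction=0.4)
    defaults.update(overrides)
    return SimConfig(**defaults)


@pytest.fixture(scope="session")
def small_ma_run():
    """One deterministic reduced MA experiment shared across tests."""
    cfg = small_sim_config()
    sequences, truth = generate_genome(cfg, seed=7)
    calls, events = simulate_ma_lines(sequences, truth, cfg, seed=7)
    return cfg, sequences, truth, calls, events


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
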