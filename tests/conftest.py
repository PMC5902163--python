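import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for the oracles module

from astroca.preprocess import NormalizedTrace
from astroca.synthetic import PopulationPreset, TraceSpec, get_preset

MASTER_SEED = 20250929


@pytest.fixture
def master_seed() -> int:
    return MASTER_SEED


@pytest.fixture
def invitro_spec() -> TraceSpec:
    """Standard in-vitro acquisition geometry (0.5 s frames, Fluo-4 kinetics)."""
    return TraceSpec(seed=MASTER_SEED)


@pytest.fixture
def all_oscillating_preset() -> PopulationPreset:
    """A mutant-like preset with every cell active (for movie round trips)."""
    base = get_preset("human_MT_soma")
    return PopulationPreset("all_osc", 1.0, base.oscillating_spec, base.silent_spec)


def constant_trace(value: float = 1.0, n: int = 300, dt: float = 0.5) -> NormalizedTrace:
    t = np.arange(n) * dt
    return NormalizedTrace(time_s=t, f_over_f0=np.full(n, value))
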