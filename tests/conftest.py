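import numpy as np
import pytest
from hypothesis import settings as hyp_settings

import postshim as ps

hyp_settings.register_profile("deterministic", derandomize=True, deadline=None)
hyp_settings.load_profile("deterministic")
from postshim.generator import LGComponent, lg_peak

FREQ_STEP = 0.3406  # Hz, the 700 MHz acquisition default
N_RESPONSE = 63


@pytest.fixture(scope="session")
def freq_step() -> float:
    return FREQ_STEP


@pytest.fixture(scope="session")
def field_model() -> ps.FieldModel:
    return ps.FieldModel()


@pytest.fixture(scope="session")
def best_singlet(freq_step) -> ps.Spectrum1D:
    """A clean Lorentzian-Gaussian singlet used as deconvolution reference."""
    n = 2048
    freqs = (np.arange(n) - n // 2) * freq_step
    vals = lg_peak(freqs, LGComponent(height=16.0, gaussian_fraction=0.3, center=0.0, width=0.5))
    return ps.Spectrum1D(freqs[0], freq_step, vals)


@pytest.fixture(scope="session")
def small_library(field_model, freq_step) -> ps.ResponseLibrary:
    """An 8x8 grid of simulated ground-truth responses."""
    vals = np.linspace(-100, 100, 8)
    responses = [
        ps.simulate_response(ps.ShimSetting(z1, z2), field_model, freq_step, N_RESPONSE).values
        for z1 in vals
        for z2 in vals
    ]
    return ps.ResponseLibrary(np.array(responses), freq_step, grid_shape=(8, 8))


@pytest.fixture(scope="session")
def tiny_state() -> ps.ModelState:
    """A small random model for shape/determinism checks."""
    cfg = ps.ModelConfig(channels=8, kernel=7, depth=4, aux_hidden=16, n_response=N_RESPONSE, seed=7)
    return ps.init_state(cfg, meta={"freq_step": FREQ_STEP, "target_height": 16.0})


SMOKE_SCHEDULE_PHASES = ((25_600, 32, 3e-3), (9_600, 32, 1e-3))
SMOKE_CHANNELS = 24
SMOKE_N_POINTS = 512
SMOKE_SEEDS = (0, 1, 2)  # model seeds; training streams use 1000 + seed


def train_smoke_model(seed: int, library: ps.ResponseLibrary) -> ps.ModelState:
    """One desk-scale training run of the scaled 24-channel model."""
    from postshim.training import TrainingSchedule

    config = ps.SpectrumSamplingConfig(freq_step=FREQ_STEP, n_points=SMOKE_N_POINTS)
    cfg = ps.ModelConfig(
        channels=SMOKE_CHANNELS, kernel=7, depth=4, aux_hidden=64,
        n_response=library.n_response, seed=seed,
    )
    state = ps.init_state(cfg, meta={"freq_step": FREQ_STEP, "target_height": 16.0})
    schedule = TrainingSchedule(phases=SMOKE_SCHEDULE_PHASES)
    state, _ = ps.train(state, library, config, schedule, seed=1000 + seed)
    return state


@pytest.fixture(scope="session")
def smoke_trained_state(small_library) -> ps.ModelState:
    """A desk-scale trained model (seed 1), shared across the suite."""
    return train_smoke_model(1, small_library)


@pytest.fixture(scope="session")
def default_state() -> ps.ModelState:
    """The reference-architecture model (64 channels, kernel 7, depth 4)."""
    cfg = ps.ModelConfig(n_response=61, seed=11)
    return ps.init_state(cfg, meta={"freq_step": FREQ_STEP, "target_height": 16.0})
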