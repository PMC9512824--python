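import numpy as np
import pytest

from csretina import opl_sim, stimuli


@pytest.fixture(scope="session")
def moving_bar_movie():
    """Default rightward 1-mm bar crossing the 1500-µm circuit array."""
    spec = stimuli.BarSpec(bar_length=1000.0, speed=0.5, contrast=1.0)
    return stimuli.make_moving_bar(spec, extent=1500.0, dx=10.0)


@pytest.fixture(scope="session")
def circuit_battery(moving_bar_movie):
    """Full / emerging / exiting / flash movies for the circuit simulator."""
    extent, mask = 1500.0, 300.0
    flash = stimuli.make_static_flash(
        stimuli.BarSpec(bar_length=extent, contrast=1.0), extent=extent, dx=10.0
    )
    return {
        "full": moving_bar_movie,
        "emerging": stimuli.apply_mask(moving_bar_movie, (0.0, mask)),
        "exiting": stimuli.apply_mask(moving_bar_movie, (extent - mask, extent)),
        "flash": flash,
    }


@pytest.fixture(scope="session")
def circuit_traces(circuit_battery):
    """Default-parameter circuit simulations for the whole battery."""
    record = ("ph", "hc", "bc_vm_transient", "bc_vm_sustained")
    return {
        name: opl_sim.run_simulation(movie, record=record)
        for name, movie in circuit_battery.items()
    }


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
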