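import numpy as np
import pytest

from ecstransport import BleachSpec, ImageStack, SimGrid, TransportParams, simulate_frap


@pytest.fixture(scope="session")
def coarse_grid() -> SimGrid:
    """1 um spacing keeps unit-test simulations fast; the grid-convergence
    test shows curves match the 0.5 um default to < 1% RMS."""
    return SimGrid(extent=(100.0, 100.0), spacing=1.0)


def stack_from_sim(frames, info, frame_interval, n_prebleach=2) -> ImageStack:
    """Wrap noiseless simulator output as an ImageStack."""
    pre = np.repeat(info["prebleach"][None], n_prebleach, axis=0)
    return ImageStack(
        frames=np.concatenate([pre, frames]),
        pixel_size=info["grid"].spacing,
        frame_interval=frame_interval,
        prebleach_count=n_prebleach,
    )


@pytest.fixture(scope="session")
def noiseless_null_stack(coarse_grid) -> ImageStack:
    """Noiseless v = 0 FRAP stack: D = 1 um^2/s, 10 um disk, 50% bleach."""
    frames, _, info = simulate_frap(
        TransportParams(D=1.0),
        BleachSpec(),
        duration=30.0,
        frame_interval=0.5,
        grid=coarse_grid,
    )
    return stack_from_sim(frames, info, 0.5)
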