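import numpy as np
import pytest

from petfcs import ACFCurve, EmpiricalParams, eval_empirical_acf


@pytest.fixture
def lag_grid():
    """Quasi-logarithmic lag ladder, 8 points per octave, 1e-7..1 s."""
    return 1e-7 * 2 ** (np.arange(0, 186) / 8.0)


@pytest.fixture
def reference_params():
    """A representative multiphasic parameter set: two µs-range
    relaxations, ~40 µs triplet, 1 ms diffusion, one molecule in focus."""
    return EmpiricalParams(
        c1=1.2, k1=2e6, c2=0.4, k2=1e5, N=0.9, F=0.15, kf=2.5e4, kd=1e3
    )


@pytest.fixture
def reference_curve(lag_grid, reference_params):
    return ACFCurve(
        lags=lag_grid,
        amplitudes=eval_empirical_acf(reference_params, lag_grid),
        construct="ref",
    )
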