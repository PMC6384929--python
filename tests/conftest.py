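import numpy as np
import pytest

from quenchfit import SyntheticSpec, TitrationSeries, generate_orientation_series

KQ_REF = 1.0e7  # M^-1, the calibrated quenching constant used throughout


@pytest.fixture
def kq_ref() -> float:
    return KQ_REF


@pytest.fixture
def make_calibration_points():
    """Noise-free Stern-Volmer series over the default 11-point design."""

    def _make(kq: float = KQ_REF, n: int = 11, q_max: float = 1e-6, i0: float = 1000.0):
        Q = np.linspace(0.0, q_max, n)
        I = i0 / (1.0 + kq * Q)
        return TitrationSeries("cal", list(zip(Q.tolist(), I.tolist())))

    return _make


@pytest.fixture
def make_orientation_series():
    """Orientation series via the synthetic generator (noise optional)."""

    def _make(x: float, kq: float = KQ_REF, noise_cv: float = 0.0, seed: int = 0, **kw):
        spec = SyntheticSpec(Kq_true=kq, x_true=x, noise_cv=noise_cv, seed=seed, **kw)
        return generate_orientation_series(spec)

    return _make
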