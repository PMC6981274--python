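import numpy as np
import pytest

from saxsconf import ScatteringProfile


def sphere_intensity(q: np.ndarray, radius: float, i0: float = 1.0) -> np.ndarray:
    """Analytic form factor of a uniform sphere: I = i0 [3(sin u - u cos u)/u^3]^2."""
    u = q * radius
    return i0 * (3.0 * (np.sin(u) - u * np.cos(u)) / u**3) ** 2


@pytest.fixture(scope="session")
def sphere_profile() -> ScatteringProfile:
    """Noise-free uniform-sphere curve, R = 50 A, I(0) = 2, tight sigma."""
    q = np.linspace(0.003, 0.3, 400)
    I = sphere_intensity(q, 50.0, i0=2.0)
    return ScatteringProfile(q, I, np.full_like(q, 1e-4), label="sphere50")


@pytest.fixture(scope="session")
def toy_scenario():
    """Shared two-state toy: closed/open pair plus a noisy open-state curve."""
    import saxsconf as sx

    toy = sx.make_two_state_toy(seed=7)
    q = np.linspace(0.008, 0.11, 60)
    apo = sx.simulate_profile(toy.open, q, noise_level=0.01, seed=107)
    return toy, q, apo
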