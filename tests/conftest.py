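import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from photokin import photocycle as pc
from photokin import spectra as sp

settings.register_profile(
    "ci", derandomize=True, max_examples=50,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("ci")


@pytest.fixture(scope="session")
def registry() -> sp.SpeciesRegistry:
    return sp.default_registry()


@pytest.fixture(scope="session")
def wt_scheme() -> pc.KineticScheme:
    return pc.preset_scheme("WT")


#: Preset schemes used by the property suites (cysteine at 0.3 M, the
#: highest published scavenger concentration).
def all_preset_schemes() -> list[pc.KineticScheme]:
    schemes = [pc.preset_scheme(v) for v in ("WT", "WT_D2O", "W388F", "E387Q", "Y345F")]
    schemes.append(pc.preset_scheme("WT_cysteine", cysteine_molar=0.3))
    return schemes


def rk4_fixed_step(K: np.ndarray, p0: np.ndarray, t: float, h_target: float) -> np.ndarray:
    """Independent propagation oracle: classical fixed-step RK4.

    For the linear system dp/dt = K·p one RK4 step is multiplication by the
    constant matrix R(h) = I + hK + (hK)²/2 + (hK)³/6 + (hK)⁴/24, so n steps
    are R(h)ⁿ·p0, evaluated exactly by binary matrix powering.  This shares
    no code path with the eigendecomposition-based solver.

    Rounding in the base matrix R is amplified n-fold by the powering (as it
    would be by literal stepping), so the oracle is computed in extended
    precision and is trustworthy to 1e-8 only for n ≲ 1e9 steps; use
    :func:`rk4_valid_horizon` to pick comparison times.
    """
    import math
    n = max(1, math.ceil(t / h_target))
    A = ((t / n) * K).astype(np.longdouble)
    A2 = A @ A
    R = np.eye(K.shape[0], dtype=np.longdouble) + A + A2 / 2 + A2 @ A / 6 + A2 @ A2 / 24
    out = np.linalg.matrix_power(R, n) @ p0.astype(np.longdouble)
    return out.astype(float)


def rk4_valid_horizon(h_target: float, n_max: float = 1e9) -> float:
    """Largest time at which the fixed-step oracle stays below n_max steps."""
    return n_max * h_target


def radau_oracle(K: np.ndarray, p0: np.ndarray, times: np.ndarray) -> np.ndarray:
    """Second independent oracle: implicit Runge–Kutta (Radau IIA) at tight
    tolerance, valid across the full stiff dynamic range."""
    import scipy.integrate
    sol = scipy.integrate.solve_ivp(
        lambda _, p: K @ p, (0.0, float(times[-1])), p0, method="Radau",
        t_eval=times, rtol=1e-12, atol=1e-14)
    assert sol.success
    return sol.y.T
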