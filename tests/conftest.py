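import cmath

import numpy as np
import pytest

from fracz import (
    AcquisitionSpec,
    FrequencyGrid,
    default_grid,
    simulate_spectrum,
    table_fixture,
)


@pytest.fixture(scope="session")
def grid61() -> FrequencyGrid:
    """The default 61-point acquisition grid, 0.1 Hz - 100 kHz."""
    return default_grid(AcquisitionSpec())


@pytest.fixture(scope="session")
def small_grid() -> FrequencyGrid:
    return FrequencyGrid(np.geomspace(0.5, 2e3, 9))


def noiseless_spectrum(fixture_name: str):
    """Exact model curve of a table fixture on the default grid, 1 replicate."""
    return simulate_spectrum(
        table_fixture(fixture_name),
        AcquisitionSpec(n_replicates=1, noise_rel=0.0, seed=0),
    )


# ---------------------------------------------------------------------------
# independent straight-line oracles (scalar, transcribed separately from the
# vectorized production code; used by the equivalence tests)
# ---------------------------------------------------------------------------


def oracle_cole(r0, r_inf, alpha, tau, f):
    w = 2.0 * cmath.pi * f
    return r_inf + (r0 - r_inf) / (1.0 + (1j * w * tau) ** alpha)


def oracle_factor(f, alpha, beta, tau, p, mac=(0.0, 0.0, 0.0, 0.0)):
    """Scalar generalized scaling factor, written out long-hand."""
    w = 2.0 * cmath.pi * f
    L = cmath.log(1j * w * tau)
    v = (0.5j * cmath.pi) / L
    a = alpha * L
    if beta != 0.0:
        a += beta * (v + cmath.log(p))
    g, d, e, z = mac
    a += g * v**2 + d * v**3 + e * v**4 + z * v**5
    return cmath.exp(a)


def oracle_element(kind, prm, f):
    if kind == "cole":
        fac = (1j * 2.0 * cmath.pi * f * prm.tau) ** prm.alpha
    else:
        mac = prm.maclaurin.as_tuple() if prm.maclaurin is not None else (0,) * 4
        fac = oracle_factor(f, prm.alpha, prm.beta, prm.tau, prm.p, mac)
    return prm.dr / (1.0 + fac)


def oracle_serial(spec, f):
    return spec.r_inf + sum(
        oracle_element(el.kind, el.params, f) for el in spec.elements
    )


def random_cole_params(rng):
    r_inf = float(rng.uniform(1e2, 1e4))
    r0 = r_inf + float(rng.uniform(1e4, 2e6))
    alpha = float(rng.uniform(0.4, 0.99))
    tau = float(np.exp(rng.uniform(-2.0, 1.5)))
    return r0, r_inf, alpha, tau
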