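"""Shared fixtures: field contexts, exact spectral-density maps, the standard grid."""

import numpy as np
import pytest

from impactnmr.impact import build_grid
from impactnmr.relaxation import make_field_context
from impactnmr.sdm import SpectralDensityMap

FIVE_FIELDS_MHZ = (400.0, 500.0, 600.0, 800.0, 1000.0)


@pytest.fixture(scope="session")
def fields5():
    return tuple(make_field_context(m) for m in FIVE_FIELDS_MHZ)


@pytest.fixture(scope="session")
def map_frequencies(fields5):
    """The 11 mapped angular frequencies for a complete five-field dataset."""
    omega = np.array(
        [f.omega_eff for f in fields5] + [f.omega_N for f in fields5] + [0.0]
    )
    labels = np.array(["high"] * 5 + ["nitrogen"] * 5 + ["zero"])
    return omega, labels


@pytest.fixture(scope="session")
def standard_grid():
    """The standard six-point array between 21 ps and 21 ns."""
    return build_grid(21e-12, 21e-9, 6)


@pytest.fixture
def exact_map(map_frequencies):
    """Factory building a map directly from a true J, optionally with noise.

    Bypasses the rate-level mapping stage: points are the truth evaluated at
    the 11 standard frequencies.  ``sigma_rel`` adds Gaussian noise and sets
    matching point sigmas.
    """
    omega, labels = map_frequencies

    def _make(jfun, rid=1, sigma_rel=0.0, rng=None):
        y = np.asarray(jfun(omega), dtype=float)
        sig = np.abs(y) * sigma_rel
        if sigma_rel > 0.0:
            if rng is None:
                rng = np.random.default_rng(0)
            y = y + sig * rng.standard_normal(len(y))
        return SpectralDensityMap(
            residue_id=rid,
            omega=omega,
            J=y,
            sigma=sig,
            labels=labels,
            j0_field_mhz=1000.0,
            fields_mhz=FIVE_FIELDS_MHZ,
        )

    return _make
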