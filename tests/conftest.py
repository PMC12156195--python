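"""Shared fixtures and independent scalar oracles for the test suite."""

from __future__ import annotations

import math

import numpy as np
import pytest

from tensiofit import (
    DEFAULT_SYSTEM,
    ISOTHERM_PRESETS,
    InterfaceSystem,
    ReorientationParams,
)

R = 8.314


# --- independent scalar oracles (plain math, no package internals) ---------

def oracle_orientation_factor(pi: float, p: ReorientationParams, T: float) -> float:
    return (p.omega1 / p.omega2) ** p.alpha * math.exp(
        -pi * (p.omega1 - p.omega2) / (R * T)
    )


def oracle_mean_molar_area(pi: float, p: ReorientationParams, T: float) -> float:
    x = oracle_orientation_factor(pi, p, T)
    return (p.omega1 * x + p.omega2) / (1.0 + x)


def oracle_coverage(pi: float, p: ReorientationParams, T: float) -> float:
    return 1.0 - math.exp(-pi * oracle_mean_molar_area(pi, p, T) / (R * T))


def oracle_concentration(pi: float, p: ReorientationParams, T: float) -> float:
    w = oracle_mean_molar_area(pi, p, T)
    num = 1.0 - math.exp(-pi * w / (R * T))
    den = (p.omega1 / p.omega2) ** p.alpha * math.exp(
        -pi * p.omega1 / (R * T)
    ) + math.exp(-pi * p.omega2 / (R * T))
    return num / den / p.b


def oracle_dwell_label(distances, dt, cutoff, min_dwell):
    """Run-length scan in plain Python: per-frame aggregated flags."""
    n = len(distances)
    out = [False] * n
    i = 0
    while i < n:
        if distances[i] < cutoff:
            j = i
            while j < n and distances[j] < cutoff:
                j += 1
            if (j - i) * dt >= min_dwell - 1e-12:
                for k in range(i, j):
                    out[k] = True
            i = j
        else:
            i += 1
    return np.array(out)


# --- fixtures ---------------------------------------------------------------

@pytest.fixture(scope="session")
def system() -> InterfaceSystem:
    return DEFAULT_SYSTEM


@pytest.fixture(scope="session")
def water_params() -> ReorientationParams:
    return ISOTHERM_PRESETS["table2_water"][0]


@pytest.fixture(scope="session")
def acetic_params() -> ReorientationParams:
    return ISOTHERM_PRESETS["table2_acetic"][0]
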