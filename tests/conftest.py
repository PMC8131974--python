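"""Shared fixtures and independent oracles.

The oracles here are deliberately naive (closed-form normal equations,
brute-force loops) so they stay independent of the library paths they
cross-check.
"""

from __future__ import annotations

import numpy as np
import pytest

from npbind.quenchfit import QuenchTitration


def ols_oracle(x, y):
    """Closed-form unweighted least squares via the normal equations.

    Returns (slope, intercept, r_squared), computed from sums only.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(x)
    sx, sy = x.sum(), y.sum()
    sxx, sxy = (x * x).sum(), (x * y).sum()
    slope = (n * sxy - sx * sy) / (n * sxx - sx * sx)
    intercept = (sy - slope * sx) / n
    resid = y - (intercept + slope * x)
    ss_res = float((resid**2).sum())
    ss_tot = float(((y - y.mean()) ** 2).sum())
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 0.0
    return slope, intercept, r2


@pytest.fixture
def ksv_by_temperature():
    """Published-style Stern-Volmer series: Ksv (uM^-1) by temperature (K),
    decreasing with temperature as static quenching requires."""
    return [(298.0, 6.2e-2), (303.0, 4.5e-2), (308.0, 3.3e-2), (313.0, 3.0e-2)]


@pytest.fixture
def purification_rows():
    """Four-step purification series (name, volume ml, conc mg/ml, total U)."""
    return [
        ("crude", 162.0, 3.87, 429.1),
        ("soluble", 118.0, 2.14, 398.23),
        ("ni_affinity", 40.0, 0.71, 103.63),
        ("desalting", 7.2, 3.5, 96.96),
    ]


def make_titration(ksv=0.05, f0=1000.0, q=(0, 10, 20, 30, 40, 50, 60),
                   temperature=298.0):
    """Exact Stern-Volmer titration: F = F0 / (1 + Ksv.Q)."""
    q = np.asarray(q, dtype=float)
    f = f0 / (1.0 + ksv * q)
    return QuenchTitration(temperature=temperature, quencher_conc=q, fluorescence=f)
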