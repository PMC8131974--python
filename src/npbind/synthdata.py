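"""Seeded synthetic-data generators with known ground truth.

Every input class the analysis modules consume can be generated here
with parameters chosen up front, so each fitting routine can be tested
as a generator/fit round trip.  All randomness flows through
``numpy.random.default_rng(seed)``: a fixed seed fixes the output
exactly.

Default designs mirror a typical nanoparticle-protein quenching study:
quencher grid 0-60 uM in 10 uM steps, temperatures 298-313 K in 5 K
steps, UV-Vis 300-800 nm, FTIR 1500-1800 cm^-1 at 2 cm^-1.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np

from .enzyme import TimeCourse
from .quenchfit import QuenchTitration
from .spectra import Spectrum
from .thermo import GAS_CONSTANT

__all__ = [
    "DEFAULT_Q_GRID",
    "DEFAULT_TEMPERATURES",
    "gen_quench_titration",
    "gen_temperature_series",
    "gen_timecourse",
    "gen_spectrum",
    "vant_hoff_k",
]

#: quencher concentrations, uM
DEFAULT_Q_GRID = (0.0, 10.0, 20.0, 30.0, 40.0, 50.0, 60.0)
#: assay temperatures, K
DEFAULT_TEMPERATURES = (298.0, 303.0, 308.0, 313.0)


def _noise(rng: np.random.Generator, sd: float, n: int) -> np.ndarray:
    return rng.normal(0.0, sd, size=n) if sd > 0 else np.zeros(n)


def gen_quench_titration(
    model: str = "static_hill",
    *,
    temperature: float = 298.0,
    f0: float = 1000.0,
    ka: float = 0.1,          # uM^-1  (static_hill)
    n_sites: float = 1.0,     # static_hill
    ksv: float = 0.05,        # uM^-1  (lehrer)
    theta: float = 1.0,       # lehrer
    q_grid: Sequence[float] = DEFAULT_Q_GRID,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> QuenchTitration:
    """Synthetic quenching titration with known parameters.

    ``static_hill``: F = F0 / (1 + Ka.Q^n) — quenched fraction follows
    the double-log (Hill) law exactly; with n = 1 this is also an exact
    Stern-Volmer line with Ksv = Ka.
    ``lehrer``: F = F0.(1-theta) + F0.theta/(1 + Ksv.Q) — a fraction
    theta of fluorophores is quenchable with constant Ksv.

    Gaussian noise of sd ``noise_sd * f0`` is added to every point.
    """
    rng = np.random.default_rng(seed)
    q = np.asarray(q_grid, dtype=float)
    if model == "static_hill":
        f = f0 / (1.0 + ka * np.power(q, n_sites, where=q > 0, out=np.zeros_like(q)))
        f[q == 0] = f0
    elif model == "lehrer":
        f = f0 * (1.0 - theta) + f0 * theta / (1.0 + ksv * q)
    else:
        raise ValueError(f"unknown titration model {model!r}")
    f = f + _noise(rng, noise_sd * f0, len(q))
    f = np.maximum(f, 1e-9)   # fluorescence stays positive
    return QuenchTitration(
        temperature=temperature, quencher_conc=q, fluorescence=f,
        label=f"synthetic:{model}",
    )


def vant_hoff_k(delta_h: float, delta_s: float, temperature: float) -> float:
    """K(T) = exp(-dH/(R.T) + dS/R) — the van't Hoff law, exactly."""
    return float(
        np.exp(-delta_h / (GAS_CONSTANT * temperature) + delta_s / GAS_CONSTANT)
    )


def gen_temperature_series(
    delta_h: float,
    delta_s: float,
    temperatures: Sequence[float] = DEFAULT_TEMPERATURES,
    *,
    model: str = "static_hill",
    n_sites: float = 1.0,
    theta: float = 1.0,
    f0: float = 1000.0,
    q_grid: Sequence[float] = DEFAULT_Q_GRID,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> tuple[list[QuenchTitration], dict[float, float]]:
    """Titrations at several temperatures whose K(T) obeys van't Hoff.

    The per-temperature constant K (uM^-1) feeds the titration model as
    Ka (static_hill) or Ksv (lehrer).  Returns the titrations and the
    ground-truth K(T) map.
    """
    rng = np.random.default_rng(seed)
    truth: dict[float, float] = {}
    titrations: list[QuenchTitration] = []
    for t in temperatures:
        k = vant_hoff_k(delta_h, delta_s, t)
        truth[float(t)] = k
        sub_seed = int(rng.integers(0, 2**31 - 1))
        titrations.append(
            gen_quench_titration(
                model,
                temperature=float(t),
                f0=f0,
                ka=k,
                n_sites=n_sites,
                ksv=k,
                theta=theta,
                q_grid=q_grid,
                noise_sd=noise_sd,
                seed=sub_seed,
            )
        )
    return titrations, truth


def gen_timecourse(
    rate: float = 0.594,          # umol ml^-1 min^-1
    calibration: float = 1.0,     # fluorescence units per (umol ml^-1)
    duration: float = 20.0,       # minutes
    n_points: int = 21,
    f_start: float = 100.0,
    noise_sd: float = 0.0,
    seed: int = 0,
    condition: str = "synthetic",
) -> TimeCourse:
    """Linear product-formation time course with known rate.

    F(t) = f_start + rate.calibration.t plus absolute Gaussian noise of
    sd ``noise_sd`` (fluorescence units).
    """
    rng = np.random.default_rng(seed)
    t = np.linspace(0.0, duration, n_points)
    f = f_start + rate * calibration * t + _noise(rng, noise_sd, n_points)
    return TimeCourse(time=t, fluorescence=f, condition=condition,
                      calibration=calibration)


def gen_spectrum(
    peaks: Sequence[tuple[float, float, float]] = ((405.0, 1.0, 20.0),),
    *,
    kind: str = "uvvis_absorbance",
    grid: tuple[float, float, float] = (300.0, 800.0, 1.0),
    baseline: float | tuple[float, float] = None,
    noise_sd: float = 0.0,
    seed: int = 0,
    label: str = "synthetic",
) -> Spectrum:
    """Sum-of-Gaussians spectrum on a regular grid.

    ``peaks`` are (center, amplitude, sigma) triples.  For absorbance
    the Gaussians add to the baseline (default 0); for transmittance
    they subtract from it (default 1), producing dips.  ``baseline`` may
    be a constant or a (slope, intercept) pair for a tilted background.
    Absolute Gaussian noise of sd ``noise_sd`` is added.
    """
    rng = np.random.default_rng(seed)
    lo, hi, step = grid
    x = np.arange(lo, hi + step / 2, step)
    if baseline is None:
        base = np.ones_like(x) if kind == "ftir_transmittance" else np.zeros_like(x)
    elif np.isscalar(baseline):
        base = np.full_like(x, float(baseline))
    else:
        slope, intercept = baseline
        base = slope * x + intercept
    bands = np.zeros_like(x)
    for center, amp, sigma in peaks:
        bands += amp * np.exp(-0.5 * ((x - center) / sigma) ** 2)
    y = base - bands if kind == "ftir_transmittance" else base + bands
    y = y + _noise(rng, noise_sd, len(x))
    return Spectrum(abscissa=x, ordinate=y, kind=kind, label=label)
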