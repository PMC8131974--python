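"""Temperature-dependent binding thermodynamics.

From equilibrium (or Stern-Volmer) constants measured at several
temperatures, the van't Hoff relation

    ln(K2/K1) = dH/R . (1/T1 - 1/T2)

yields the binding enthalpy dH; the entropy dS follows either from the
van't Hoff intercept (dS = R x intercept of ln K on 1/T — a quantity
that depends on the concentration units of K) or from the Gibbs identity
dS = (dH - dG)/T given one known dG; and dG(T) = dH - T.dS.

The signs of dH and dS classify the dominant binding force
(Ross-Subramanian rules): dH<0, dS>0 electrostatic; both positive
hydrophobic; both negative van der Waals / hydrogen bonding.  dG<0
means spontaneous binding.

:class:`VantHoffModel` bundles the workflow: construct from (T, K)
pairs, ``fit()`` returns a :class:`ThermoResult` with a ``summary()``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
from scipy import stats

from .exceptions import UnitDependenceWarning

__all__ = [
    "GAS_CONSTANT",
    "ThermoResult",
    "VantHoffModel",
    "vant_hoff_enthalpy",
    "entropy",
    "gibbs",
    "classify_forces",
    "spontaneity",
]

#: gas constant, J mol^-1 K^-1
GAS_CONSTANT = 8.314

EnthalpyMode = Literal["pair_extremes", "regression"]
EntropyMode = Literal["vant_hoff_intercept", "gibbs_identity"]


def _check_tk(k_values: Sequence[tuple[float, float]]) -> tuple[np.ndarray, np.ndarray]:
    arr = np.asarray(sorted(k_values), dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 2 or arr.shape[0] < 2:
        raise ValueError("need >=2 (temperature, K) pairs")
    t, k = arr[:, 0], arr[:, 1]
    if np.any(t <= 0):
        raise ValueError("temperatures must be positive kelvin")
    if np.any(k <= 0):
        raise ValueError("equilibrium constants must be > 0")
    return t, k


def vant_hoff_enthalpy(
    k_values: Sequence[tuple[float, float]],
    mode: EnthalpyMode = "pair_extremes",
) -> float:
    """Binding enthalpy (J mol^-1) from K(T).

    ``pair_extremes`` (default) applies the two-point van't Hoff formula
    to the lowest- and highest-temperature entries; ``regression`` uses
    -R x slope of the OLS line of ln K on 1/T over all points.
    """
    t, k = _check_tk(k_values)
    if mode == "pair_extremes":
        t1, t2 = t[0], t[-1]
        if t1 == t2:
            raise ValueError("pair mode needs two distinct temperatures")
        k1, k2 = k[0], k[-1]
        return GAS_CONSTANT * np.log(k2 / k1) / (1.0 / t1 - 1.0 / t2)
    if mode == "regression":
        res = stats.linregress(1.0 / t, np.log(k))
        return -GAS_CONSTANT * float(res.slope)
    raise ValueError(f"unknown enthalpy mode {mode!r}")


def entropy(
    delta_h: float,
    *,
    mode: EntropyMode = "gibbs_identity",
    k_values: Sequence[tuple[float, float]] | None = None,
    delta_g: float | None = None,
    temperature: float | None = None,
    k_units: str = "uM^-1",
) -> float:
    """Binding entropy (J mol^-1 K^-1).

    ``gibbs_identity`` needs one (temperature, delta_g) anchor and
    returns (dH - dG)/T.  ``vant_hoff_intercept`` returns R x intercept
    of the OLS line of ln K on 1/T; that intercept — hence the entropy —
    shifts by R.ln(c) when K is rescaled by c, so the units of K must be
    stated and the value read with that caveat (a warning is emitted).
    """
    if mode == "gibbs_identity":
        if delta_g is None or temperature is None:
            raise ValueError("gibbs_identity mode needs delta_g and temperature")
        if temperature == 0:
            raise ValueError("temperature must be nonzero")
        return (delta_h - delta_g) / temperature
    if mode == "vant_hoff_intercept":
        if k_values is None:
            raise ValueError("vant_hoff_intercept mode needs (T, K) pairs")
        t, k = _check_tk(k_values)
        res = stats.linregress(1.0 / t, np.log(k))
        warnings.warn(
            f"van't Hoff intercept entropy depends on the units of K "
            f"(taken as {k_units}); rescaling K by c shifts dS by R.ln(c)",
            UnitDependenceWarning,
            stacklevel=2,
        )
        return GAS_CONSTANT * float(res.intercept)
    raise ValueError(f"unknown entropy mode {mode!r}")


def gibbs(
    delta_h: float, delta_s: float, temperatures: Sequence[float]
) -> dict[float, float]:
    """dG(T) = dH - T.dS per temperature, J mol^-1."""
    temps = np.asarray(temperatures, dtype=float)
    if np.any(temps <= 0):
        raise ValueError("temperatures must be positive kelvin")
    return {float(t): float(delta_h - t * delta_s) for t in temps}


def classify_forces(delta_h: float, delta_s: float, tolerance: float = 0.0) -> str:
    """Dominant binding force from the signs of dH and dS.

    dH < -tol and dS > +tol -> ``electrostatic``; both > +tol ->
    ``hydrophobic``; both < -tol -> ``vdw_hbond``; anything within the
    tolerance band or the remaining sign pattern -> ``indeterminate``.
    """
    if tolerance < 0:
        raise ValueError("tolerance must be >= 0")
    if delta_h < -tolerance and delta_s > tolerance:
        return "electrostatic"
    if delta_h > tolerance and delta_s > tolerance:
        return "hydrophobic"
    if delta_h < -tolerance and delta_s < -tolerance:
        return "vdw_hbond"
    return "indeterminate"


def spontaneity(delta_g: float) -> bool:
    """True iff binding is spontaneous (dG < 0)."""
    return delta_g < 0


@dataclass
class ThermoResult:
    """Thermodynamic characterization of a binding interaction.

    ``delta_g_by_temperature`` is built as dH - T.dS, so the Gibbs
    identity holds exactly at every stored temperature by construction.
    """

    delta_h: float                          # J mol^-1
    delta_s: float                          # J mol^-1 K^-1
    delta_g_by_temperature: dict[float, float]
    mechanism: str = "unknown"              # copied from the quenching stage
    force_class: str = "indeterminate"
    enthalpy_mode: str = "pair_extremes"
    entropy_mode: str = "gibbs_identity"
    entropy_unit_dependent: bool = False
    k_units: str = "uM^-1"

    @property
    def spontaneous(self) -> dict[float, bool]:
        return {t: spontaneity(g) for t, g in self.delta_g_by_temperature.items()}

    def to_dict(self) -> dict:
        return {
            "delta_h_J_per_mol": self.delta_h,
            "delta_s_J_per_mol_K": self.delta_s,
            "delta_g_J_per_mol": {str(t): g for t, g in self.delta_g_by_temperature.items()},
            "delta_g_kJ_per_mol": {
                str(t): g / 1e3 for t, g in self.delta_g_by_temperature.items()
            },
            "spontaneous": {str(t): s for t, s in self.spontaneous.items()},
            "mechanism": self.mechanism,
            "force_class": self.force_class,
            "method": {
                "enthalpy_mode": self.enthalpy_mode,
                "entropy_mode": self.entropy_mode,
                "entropy_unit_dependent": self.entropy_unit_dependent,
                "k_units": self.k_units,
            },
        }

    def summary(self) -> str:
        lines = ["Binding thermodynamics"]
        lines.append("-" * len(lines[0]))
        lines.append(f"  dH = {self.delta_h:.4g} J/mol  ({self.delta_h/1e3:.4g} kJ/mol; {self.enthalpy_mode})")
        caveat = "  [unit-dependent]" if self.entropy_unit_dependent else ""
        lines.append(f"  dS = {self.delta_s:.4g} J/mol/K  ({self.entropy_mode}){caveat}")
        for t in sorted(self.delta_g_by_temperature):
            g = self.delta_g_by_temperature[t]
            tag = "spontaneous" if g < 0 else "non-spontaneous"
            lines.append(f"  dG({t:g} K) = {g/1e3:.4g} kJ/mol  [{tag}]")
        lines.append(f"  quenching mechanism: {self.mechanism}")
        lines.append(f"  dominant force:      {self.force_class}")
        return "\n".join(lines)


class VantHoffModel:
    """van't Hoff analysis of K(T) for one binding interaction.

    Parameters
    ----------
    k_values : sequence of (temperature_K, K)
        Equilibrium (or Stern-Volmer) constants by temperature.
    k_units : str
        Concentration units of K; only surfaced in metadata and in the
        unit-dependence caveat of intercept entropies.
    """

    def __init__(self, k_values: Sequence[tuple[float, float]], k_units: str = "uM^-1"):
        self.k_values = [(float(t), float(k)) for t, k in k_values]
        self.k_units = k_units
        _check_tk(self.k_values)

    def fit(
        self,
        enthalpy_mode: EnthalpyMode = "pair_extremes",
        entropy_mode: EntropyMode | None = None,
        delta_g_anchor: tuple[float, float] | None = None,
        mechanism: str = "unknown",
        force_tolerance: float = 0.0,
    ) -> ThermoResult:
        """Estimate dH, dS and dG at every input temperature.

        ``delta_g_anchor`` is one (temperature, dG in J/mol) pair; when
        supplied (and unless overridden) the entropy comes from the
        Gibbs identity at that anchor, otherwise from the van't Hoff
        intercept with a unit-dependence warning.
        """
        dh = vant_hoff_enthalpy(self.k_values, mode=enthalpy_mode)
        if entropy_mode is None:
            entropy_mode = "gibbs_identity" if delta_g_anchor is not None else "vant_hoff_intercept"
        if entropy_mode == "gibbs_identity":
            if delta_g_anchor is None:
                raise ValueError("gibbs_identity entropy needs delta_g_anchor=(T, dG)")
            t_anchor, g_anchor = delta_g_anchor
            ds = entropy(dh, mode="gibbs_identity", delta_g=g_anchor, temperature=t_anchor)
            unit_dep = False
        else:
            ds = entropy(dh, mode="vant_hoff_intercept", k_values=self.k_values,
                         k_units=self.k_units)
            unit_dep = True
        temps = [t for t, _ in self.k_values]
        dg = gibbs(dh, ds, temps)
        return ThermoResult(
            delta_h=dh,
            delta_s=ds,
            delta_g_by_temperature=dg,
            mechanism=mechanism,
            force_class=classify_forces(dh, ds, force_tolerance),
            enthalpy_mode=enthalpy_mode,
            entropy_mode=entropy_mode,
            entropy_unit_dependent=unit_dep,
            k_units=self.k_units,
        )

    def plot(self, ax=None):
        """van't Hoff plot: ln K against 1/T with the regression line."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        t = np.array([p[0] for p in self.k_values])
        k = np.array([p[1] for p in self.k_values])
        x, y = 1.0 / t, np.log(k)
        res = stats.linregress(x, y)
        ax.plot(x, y, "o", label="ln K")
        grid = np.linspace(x.min(), x.max(), 50)
        ax.plot(grid, res.intercept + res.slope * grid, "-",
                label=f"dH={-GAS_CONSTANT * res.slope / 1e3:.3g} kJ/mol")
        ax.set_xlabel("1/T (1/K)")
        ax.set_ylabel(f"ln K ({self.k_units})")
        ax.set_title("van't Hoff plot")
        ax.legend()
        return ax
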