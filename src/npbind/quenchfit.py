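"""Fluorescence-quenching titration analysis.

A quencher (here a nanoparticle suspension) titrated into a protein
solution reduces the intrinsic tryptophan fluorescence.  Three classical
linearizations extract binding parameters from a titration measured at a
single temperature:

* Stern-Volmer:      F0/F = 1 + Ksv.[Q]            (slope Ksv)
* Lehrer:            F0/(F0-F) = 1/(theta.Ksv.[Q]) + 1/theta
* Hill double-log:   log10[(F0-F)/F] = log10(Ka) + n.log10[Q]

where F0 is the fluorescence with no quencher, theta the fraction of
fluorophores accessible to the quencher, Ka the association constant,
Kd = 1/Ka the dissociation constant and n the number of binding sites.

The temperature trend of Ksv distinguishes the quenching mechanism:
Ksv falling with temperature indicates static quenching (a ground-state
complex that dissociates on heating), rising Ksv indicates dynamic
(collisional) quenching.

The module follows a model/results idiom: :class:`QuenchBindingModel`
wraps one titration and its :meth:`~QuenchBindingModel.fit` returns a
:class:`BindingFit` carrying estimates, goodness of fit and a
``summary()`` table.  The individual linearizations are also exposed as
plain functions.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .exceptions import (
    DegenerateFitWarning,
    ExcludedPointsWarning,
    FitError,
    NonPhysicalWarning,
)

__all__ = [
    "QuenchTitration",
    "QuenchBindingModel",
    "BindingFit",
    "SternVolmerFit",
    "LehrerFit",
    "HillFit",
    "fit_stern_volmer",
    "fit_lehrer",
    "fit_hill_double_log",
    "classify_quenching",
    "fit_titrations",
    "load_titrations",
    "fits_to_frame",
]

#: significant digits used when comparing Ksv values for monotonicity
_KSV_ROUND_DIGITS = 10


@dataclass(frozen=True)
class QuenchTitration:
    """One quenching titration at a fixed temperature.

    Parameters
    ----------
    temperature : float
        Absolute temperature in kelvin.
    quencher_conc : array-like
        Quencher concentrations in uM.  Must contain exactly one zero
        entry (the F0 reference) and at least three distinct nonzero
        concentrations.
    fluorescence : array-like
        Fluorescence intensities (arbitrary units), same length as
        ``quencher_conc``; all strictly positive.
    """

    temperature: float
    quencher_conc: np.ndarray
    fluorescence: np.ndarray
    label: str = ""

    def __post_init__(self):
        q = np.asarray(self.quencher_conc, dtype=float)
        f = np.asarray(self.fluorescence, dtype=float)
        object.__setattr__(self, "quencher_conc", q)
        object.__setattr__(self, "fluorescence", f)
        if q.shape != f.shape or q.ndim != 1:
            raise ValueError("quencher_conc and fluorescence must be 1-D and equal length")
        if not np.all(np.isfinite(q)) or not np.all(np.isfinite(f)):
            raise ValueError("non-finite values in titration")
        if np.any(f <= 0):
            raise ValueError("all fluorescence values must be > 0")
        if np.any(q < 0):
            raise ValueError("negative quencher concentration")
        nzero = int(np.sum(q == 0.0))
        if nzero != 1:
            raise ValueError(
                f"exactly one zero-concentration row must define F0 (found {nzero})"
            )
        if len(np.unique(q[q > 0])) < 3:
            raise ValueError("need at least 3 distinct nonzero quencher concentrations")
        if self.temperature <= 0:
            raise ValueError("temperature must be positive (kelvin)")

    @property
    def f0(self) -> float:
        """Fluorescence of the zero-quencher row."""
        return float(self.fluorescence[self.quencher_conc == 0.0][0])

    def nonzero(self) -> tuple[np.ndarray, np.ndarray]:
        """(Q, F) over the nonzero-quencher rows, in input order."""
        m = self.quencher_conc > 0.0
        return self.quencher_conc[m], self.fluorescence[m]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "temperature_K": self.temperature,
                "quencher_uM": self.quencher_conc,
                "fluorescence": self.fluorescence,
            }
        )


class SternVolmerFit(NamedTuple):
    ksv: float          # uM^-1
    intercept: float    # dimensionless; the model predicts 1
    r_squared: float
    points_used: int
    n_excluded: int
    degenerate: bool = False


class LehrerFit(NamedTuple):
    theta: float        # accessible fraction, physically in (0, 1]
    ksv: float          # uM^-1
    r_squared: float
    points_used: int
    n_excluded: int
    theta_physical: bool = True


class HillFit(NamedTuple):
    ka: float           # uM^-1
    n_sites: float
    kd: float           # uM
    r_squared: float
    points_used: int
    n_excluded: int


def _ols(x: np.ndarray, y: np.ndarray) -> tuple[float, float, float]:
    """Unweighted OLS line; returns (slope, intercept, r_squared).

    A constant response is a formally degenerate regression; it is
    returned as slope 0 through the mean with r_squared 0 so callers can
    flag it rather than crash on it.
    """
    if np.ptp(y) == 0.0:
        return 0.0, float(y[0]), 0.0
    res = stats.linregress(x, y)
    return float(res.slope), float(res.intercept), float(res.rvalue**2)


def _usable_mask(t: QuenchTitration, *, drop_no_quench: bool) -> tuple[np.ndarray, int]:
    """Mask of nonzero-Q points with F <= F0 (enhancement excluded).

    With ``drop_no_quench`` points with F == F0 are excluded too (the
    Lehrer and double-log transforms are undefined there).  Returns the
    mask over nonzero-Q points and the count of excluded ones.
    """
    q, f = t.nonzero()
    keep = f < t.f0 if drop_no_quench else f <= t.f0
    n_excl = int(np.sum(~keep))
    if n_excl:
        warnings.warn(
            f"{n_excl} titration point(s) excluded "
            f"(fluorescence {'>=':s} F0) at T={t.temperature:g} K",
            ExcludedPointsWarning,
            stacklevel=3,
        )
    return keep, n_excl


def fit_stern_volmer(titration: QuenchTitration) -> SternVolmerFit:
    """Fit F0/F = 1 + Ksv.[Q] by unweighted OLS over nonzero-Q points.

    The intercept is estimated, not forced to 1: its departure from 1 is
    itself diagnostic (external quenching by other fluors).  Points with
    F > F0 (enhancement) are excluded with a warning.  A titration in
    which every F equals F0 returns slope 0 flagged degenerate.
    """
    q, f = titration.nonzero()
    keep, n_excl = _usable_mask(titration, drop_no_quench=False)
    q, f = q[keep], f[keep]
    if len(q) < 3:
        raise FitError(
            f"Stern-Volmer fit needs >=3 usable points, got {len(q)} "
            f"after excluding {n_excl} enhancement point(s)"
        )
    y = titration.f0 / f
    slope, intercept, r2 = _ols(q, y)
    degenerate = bool(np.ptp(y) == 0.0)
    if degenerate:
        warnings.warn(
            "no quenching observed (F0/F constant); Stern-Volmer slope is 0",
            DegenerateFitWarning,
            stacklevel=2,
        )
    return SternVolmerFit(slope, intercept, r2, len(q), n_excl, degenerate)


def fit_lehrer(titration: QuenchTitration) -> LehrerFit:
    """Fit the Lehrer (modified Stern-Volmer) plot F0/(F0-F) vs 1/[Q].

    theta = 1/intercept and Ksv = intercept/slope.  Zero-quencher rows
    and rows with F >= F0 are excluded (both transforms are undefined
    there).  A non-positive intercept makes theta non-physical; it is
    returned with a warning rather than suppressed.
    """
    q, f = titration.nonzero()
    keep, n_excl = _usable_mask(titration, drop_no_quench=True)
    q, f = q[keep], f[keep]
    n_excl += 1  # the zero-quencher row itself
    if len(q) < 3:
        raise FitError(
            f"Lehrer fit needs >=3 usable points, got {len(q)}"
        )
    x = 1.0 / q
    y = titration.f0 / (titration.f0 - f)
    slope, intercept, r2 = _ols(x, y)
    physical = intercept > 0.0
    if not physical:
        warnings.warn(
            f"Lehrer intercept {intercept:.4g} <= 0: theta is non-physical",
            NonPhysicalWarning,
            stacklevel=2,
        )
    theta = math.inf if intercept == 0.0 else 1.0 / intercept
    ksv = math.nan if slope == 0.0 else intercept / slope
    return LehrerFit(theta, ksv, r2, len(q), n_excl, physical)


def fit_hill_double_log(titration: QuenchTitration) -> HillFit:
    """Fit the double-logarithmic (Hill-type) binding plot.

    log10[(F0-F)/F] regressed on log10[Q] over nonzero-Q points with
    F < F0; slope = n (binding sites), 10**intercept = Ka (uM^-1),
    Kd = 1/Ka.  Base-10 logarithms throughout.
    """
    q, f = titration.nonzero()
    keep, n_excl = _usable_mask(titration, drop_no_quench=True)
    q, f = q[keep], f[keep]
    if len(q) < 3:
        raise FitError(
            "double-log fit needs >=3 usable points "
            f"(got {len(q)}: no quenching or too few titration points)"
        )
    x = np.log10(q)
    y = np.log10((titration.f0 - f) / f)
    slope, intercept, r2 = _ols(x, y)
    ka = 10.0**intercept
    return HillFit(ka, slope, 1.0 / ka, r2, len(q), n_excl + 1)


@dataclass
class BindingFit:
    """Binding parameters of one titration at one temperature.

    Aggregates the three linearizations.  ``kd * ka == 1`` holds to
    machine precision by construction.  ``summary()`` renders a one-row
    report mirroring the per-temperature table of a quenching study.
    """

    temperature: float
    stern_volmer: SternVolmerFit
    lehrer: LehrerFit
    hill: HillFit
    label: str = ""
    model: "QuenchBindingModel | None" = field(
        default=None, repr=False, compare=False
    )

    # convenience accessors -------------------------------------------------
    @property
    def ksv(self) -> float:
        return self.stern_volmer.ksv

    @property
    def sv_intercept(self) -> float:
        return self.stern_volmer.intercept

    @property
    def theta(self) -> float:
        return self.lehrer.theta

    @property
    def ka(self) -> float:
        return self.hill.ka

    @property
    def kd(self) -> float:
        return self.hill.kd

    @property
    def n_sites(self) -> float:
        return self.hill.n_sites

    def to_dict(self) -> dict:
        return {
            "temperature_K": self.temperature,
            "Ksv_per_uM": self.ksv,
            "sv_intercept": self.sv_intercept,
            "sv_r_squared": self.stern_volmer.r_squared,
            "theta": self.theta,
            "lehrer_Ksv_per_uM": self.lehrer.ksv,
            "lehrer_r_squared": self.lehrer.r_squared,
            "Ka_per_uM": self.ka,
            "Kd_uM": self.kd,
            "n_sites": self.n_sites,
            "hill_r_squared": self.hill.r_squared,
            "points_used_sv": self.stern_volmer.points_used,
            "points_used_lehrer": self.lehrer.points_used,
            "points_used_hill": self.hill.points_used,
        }

    def summary(self) -> str:
        d = self.to_dict()
        lines = [f"Binding fit at {self.temperature:g} K" + (f" ({self.label})" if self.label else "")]
        lines.append("-" * len(lines[0]))
        lines.append(f"  Ksv       = {d['Ksv_per_uM']:.4g} uM^-1   (intercept {d['sv_intercept']:.4g}, r2 {d['sv_r_squared']:.4f})")
        lines.append(f"  theta     = {d['theta']:.4g}          (Lehrer, r2 {d['lehrer_r_squared']:.4f})")
        lines.append(f"  Ka        = {d['Ka_per_uM']:.4g} uM^-1   Kd = {d['Kd_uM']:.4g} uM")
        lines.append(f"  n (sites) = {d['n_sites']:.4g}          (double-log, r2 {d['hill_r_squared']:.4f})")
        lines.append(f"  points used (SV/Lehrer/double-log): "
                     f"{d['points_used_sv']}/{d['points_used_lehrer']}/{d['points_used_hill']}")
        return "\n".join(lines)

    def plot(self, ax=None):
        """Stern-Volmer diagnostic plot: F0/F against [Q] with the fit line.

        Requires the fit to have been produced by a
        :class:`QuenchBindingModel` (which attaches the data).
        """
        if self.model is None:
            raise ValueError("no titration attached; fit via QuenchBindingModel")
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        t = self.model.titration
        q, f = t.nonzero()
        ax.plot(q, t.f0 / f, "o", label="data")
        grid = np.linspace(0.0, q.max(), 50)
        ax.plot(grid, self.sv_intercept + self.ksv * grid, "-",
                label=f"Ksv={self.ksv:.3g} /uM")
        ax.set_xlabel("[Q] (uM)")
        ax.set_ylabel("F0/F")
        ax.set_title(f"Stern-Volmer plot, {self.temperature:g} K")
        ax.legend()
        return ax


class QuenchBindingModel:
    """Model object for one quenching titration.

    ``QuenchBindingModel(titration).fit()`` runs all three
    linearizations and returns a :class:`BindingFit`.
    """

    def __init__(self, titration: QuenchTitration):
        self.titration = titration

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, temperature: float | None = None) -> "QuenchBindingModel":
        """Build from a frame with columns temperature_K, quencher_uM, fluorescence.

        If ``temperature`` is given, rows are filtered to it; otherwise
        the frame must contain a single temperature.
        """
        if temperature is not None:
            df = df[df["temperature_K"] == temperature]
        temps = df["temperature_K"].unique()
        if len(temps) != 1:
            raise ValueError(
                f"frame holds {len(temps)} temperatures; pass `temperature=` to select one"
            )
        t = QuenchTitration(
            temperature=float(temps[0]),
            quencher_conc=df["quencher_uM"].to_numpy(float),
            fluorescence=df["fluorescence"].to_numpy(float),
        )
        return cls(t)

    def fit(self) -> BindingFit:
        t = self.titration
        return BindingFit(
            temperature=t.temperature,
            stern_volmer=fit_stern_volmer(t),
            lehrer=fit_lehrer(t),
            hill=fit_hill_double_log(t),
            label=t.label,
            model=self,
        )


def fit_titrations(titrations: Sequence[QuenchTitration]) -> list[BindingFit]:
    """Fit every titration, returned sorted by temperature."""
    fits = [QuenchBindingModel(t).fit() for t in titrations]
    return sorted(fits, key=lambda f: f.temperature)


def classify_quenching(fits: Sequence[BindingFit] | Sequence[tuple[float, float]]) -> str:
    """Classify the quenching mechanism from the temperature trend of Ksv.

    Accepts BindingFit objects or (temperature, ksv) pairs.  After
    sorting by temperature and rounding Ksv to 10 significant digits,
    strictly decreasing Ksv -> ``"static"``, strictly increasing ->
    ``"dynamic"``, anything else (including ties) -> ``"indeterminate"``.
    """
    pairs = []
    for f in fits:
        if isinstance(f, BindingFit):
            pairs.append((f.temperature, f.ksv))
        else:
            pairs.append((float(f[0]), float(f[1])))
    if len(pairs) < 2:
        raise ValueError("mechanism classification needs >=2 temperatures")
    pairs.sort(key=lambda p: p[0])
    ksv = [float(f"{k:.{_KSV_ROUND_DIGITS}g}") for _, k in pairs]
    diffs = np.diff(ksv)
    if np.all(diffs < 0):
        return "static"
    if np.all(diffs > 0):
        return "dynamic"
    return "indeterminate"


def load_titrations(path) -> list[QuenchTitration]:
    """Read titrations from delimited text (columns temperature_K,
    quencher_uM, fluorescence); one file may hold several temperatures."""
    df = pd.read_csv(path, sep=None, engine="python")
    required = {"temperature_K", "quencher_uM", "fluorescence"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"missing column(s): {sorted(missing)}")
    out = []
    for temp, grp in df.groupby("temperature_K", sort=True):
        out.append(
            QuenchTitration(
                temperature=float(temp),
                quencher_conc=grp["quencher_uM"].to_numpy(float),
                fluorescence=grp["fluorescence"].to_numpy(float),
            )
        )
    return out


def fits_to_frame(fits: Sequence[BindingFit]) -> pd.DataFrame:
    """Per-temperature fit table (one row per temperature)."""
    return pd.DataFrame([f.to_dict() for f in fits])
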