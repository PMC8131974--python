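"""End-to-end orchestration: configuration, staging and report assembly.

``run_binding_analysis`` chains the quenching fits, mechanism
classification and thermodynamics for a multi-temperature titration set;
``run_full`` additionally runs the activity, purification, spectral and
nanoparticle-model stages as configured and assembles an
:class:`AnalysisReport` that serializes losslessly to JSON.

Configuration is a plain hierarchical mapping (typically loaded from
YAML); every section is optional — missing sections are skipped with a
notice, and per-stage failures are recorded without aborting the rest
of the run.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from typing import Any, Sequence

import numpy as np

from . import __version__
from . import enzyme, npmodel, quenchfit, spectra, synthdata, thermo
from .quenchfit import BindingFit, QuenchTitration

log = logging.getLogger("npbind")

__all__ = [
    "AnalysisReport",
    "run_binding_analysis",
    "run_full",
    "demo_config",
    "validate_report",
    "REPORT_SCHEMA",
]

#: published report schema: required sections and the type of each.
#: ``None`` marks a section that may be absent (skipped stage).
REPORT_SCHEMA: dict[str, Any] = {
    "binding": (dict, type(None)),
    "activity": (dict, type(None)),
    "purification": (list, type(None)),
    "spectra": (dict, type(None)),
    "npmodel": (dict, type(None)),
    "notices": (list,),
    "provenance": (dict,),
}

_PROVENANCE_KEYS = ("config", "seed", "versions")


def validate_report(d: dict) -> None:
    """Check a report dict against :data:`REPORT_SCHEMA`; raise on breach."""
    for key, types in REPORT_SCHEMA.items():
        if key not in d:
            raise ValueError(f"report missing section {key!r}")
        if not isinstance(d[key], types):
            raise ValueError(
                f"report section {key!r} has type {type(d[key]).__name__}, "
                f"expected one of {[t.__name__ for t in types]}"
            )
    for key in _PROVENANCE_KEYS:
        if key not in d["provenance"]:
            raise ValueError(f"provenance missing {key!r}")
    extra = set(d) - set(REPORT_SCHEMA)
    if extra:
        raise ValueError(f"unknown report section(s): {sorted(extra)}")


@dataclass
class AnalysisReport:
    """Assembled results of one pipeline run.

    Sections are plain JSON-compatible structures so the report
    round-trips through ``to_json``/``from_json`` without loss; the
    provenance block records the configuration, seed and library
    versions (no timestamps, so reruns are byte-identical).
    """

    binding: dict | None = None
    activity: dict | None = None
    purification: list | None = None
    spectra: dict | None = None
    npmodel: dict | None = None
    notices: list = field(default_factory=list)
    provenance: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        d = asdict(self)
        validate_report(d)
        return d

    def to_json(self, indent: int = 2) -> str:
        return json.dumps(self.to_dict(), indent=indent, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "AnalysisReport":
        d = json.loads(text)
        validate_report(d)
        return cls(**d)

    def summary(self) -> str:
        lines = [f"npbind analysis report (v{self.provenance.get('versions', {}).get('npbind', '?')})"]
        for name in ("binding", "activity", "purification", "spectra", "npmodel"):
            status = "present" if getattr(self, name) is not None else "skipped"
            lines.append(f"  {name:13s}: {status}")
        for n in self.notices:
            lines.append(f"  note: {n}")
        return "\n".join(lines)


def _provenance(config: dict, seed: int | None) -> dict:
    return {
        "config": config,
        "seed": seed,
        "versions": {"npbind": __version__, "numpy": np.__version__},
    }


def run_binding_analysis(
    titrations: Sequence[QuenchTitration],
    config: dict | None = None,
) -> tuple[dict | None, list[str]]:
    """Quenching fits, mechanism and thermodynamics for one titration set.

    Returns the binding section (or None if nothing could be fitted)
    plus a list of human-readable notices.  Per-temperature fit failures
    are recorded and the remaining temperatures still run; with fewer
    than two usable temperatures the thermodynamics is skipped with an
    explicit notice.
    """
    config = config or {}
    notices: list[str] = []
    fits: list[BindingFit] = []
    for t in sorted(titrations, key=lambda t: t.temperature):
        try:
            fits.append(quenchfit.QuenchBindingModel(t).fit())
        except Exception as exc:  # record, continue with other temperatures
            msg = f"binding fit failed at {t.temperature:g} K: {exc}"
            log.warning(msg)
            notices.append(msg)
    if not fits:
        return None, notices + ["no titration could be fitted"]

    section: dict[str, Any] = {
        "fits": [f.to_dict() for f in fits],
        "mechanism": None,
        "thermo": None,
    }
    if len(fits) >= 2:
        section["mechanism"] = quenchfit.classify_quenching(fits)
        model = thermo.VantHoffModel(
            [(f.temperature, f.ksv) for f in fits], k_units="uM^-1"
        )
        anchor = config.get("delta_g_anchor")  # (T, dG J/mol) if provided
        import warnings as _warnings

        with _warnings.catch_warnings():
            _warnings.simplefilter("ignore")
            result = model.fit(
                enthalpy_mode=config.get("enthalpy_mode", "pair_extremes"),
                delta_g_anchor=tuple(anchor) if anchor else None,
                mechanism=section["mechanism"],
                force_tolerance=float(config.get("force_tolerance", 0.0)),
            )
        section["thermo"] = result.to_dict()
        if result.entropy_unit_dependent:
            notices.append(
                "entropy from the van't Hoff intercept depends on the "
                "concentration units of K (uM^-1 assumed)"
            )
    else:
        notices.append(
            "thermodynamics skipped: needs >=2 temperatures, got "
            f"{len(fits)}"
        )
    return section, notices


def _binding_stage(cfg: dict, seed: int) -> tuple[dict | None, list[str]]:
    if "file" in cfg:
        titrations = quenchfit.load_titrations(cfg["file"])
    elif "synthetic" in cfg:
        syn = dict(cfg["synthetic"])
        syn.setdefault("seed", seed)
        titrations, _truth = synthdata.gen_temperature_series(
            delta_h=syn.get("delta_h", -3.76e4),
            delta_s=syn.get("delta_s", -149.3),
            temperatures=syn.get("temperatures", synthdata.DEFAULT_TEMPERATURES),
            model=syn.get("model", "static_hill"),
            n_sites=syn.get("n_sites", 1.0),
            theta=syn.get("theta", 1.0),
            noise_sd=syn.get("noise_sd", 0.0),
            seed=syn["seed"],
        )
    else:
        raise ValueError("binding section needs 'file' or 'synthetic'")
    return run_binding_analysis(titrations, cfg)


def _activity_stage(cfg: dict, seed: int) -> dict:
    calibration = float(cfg.get("calibration", 1.0))
    if "file" in cfg:
        courses = enzyme.load_timecourses(cfg["file"], calibration=calibration)
    elif "synthetic" in cfg:
        syn = dict(cfg["synthetic"])
        control_rate = float(syn.get("control_rate", 0.594))
        rel = syn.get("relative", {"control": 1.0})
        courses = [
            synthdata.gen_timecourse(
                rate=control_rate * float(factor),
                calibration=calibration,
                noise_sd=float(syn.get("noise_sd", 0.0)),
                seed=seed + i,
                condition=str(name),
            )
            for i, (name, factor) in enumerate(rel.items())
        ]
    else:
        raise ValueError("activity section needs 'file' or 'synthetic'")
    window = cfg.get("window_minutes")
    rates = {
        tc.condition: enzyme.initial_rate(tc, tuple(window) if window else None)
        for tc in courses
    }
    control_name = cfg.get("control", next(iter(rates)))
    control = rates[control_name]
    return {
        "rates_umol_per_ml_min": rates,
        "control": control_name,
        "relative_activity_percent": {
            name: enzyme.relative_activity(r, control) for name, r in rates.items()
        },
    }


def _purification_stage(cfg: dict) -> list:
    if "file" in cfg:
        steps = enzyme.load_purification(cfg["file"])
    elif "steps" in cfg:
        steps = enzyme.purification_table(
            [(s["name"], s["volume_ml"], s["conc_mg_per_ml"], s["total_activity_U"])
             for s in cfg["steps"]]
        )
    else:
        raise ValueError("purification section needs 'file' or 'steps'")
    return [s.rounded() for s in steps]


def _spectra_stage(cfg: dict, seed: int) -> dict:
    out: dict[str, Any] = {}
    if "plasmon" in cfg:
        pcfg = cfg["plasmon"]
        if "synthetic" in pcfg:
            syn = pcfg["synthetic"]
            centers = syn.get("centers", [405.0, 407.0, 409.0, 411.0, 412.0])
            sigmas = syn.get("sigmas", [20.0 + 2.0 * i for i in range(len(centers))])
            series = [
                synthdata.gen_spectrum(
                    peaks=[(c, 1.0, s)], kind="uvvis_absorbance",
                    noise_sd=float(syn.get("noise_sd", 0.0)), seed=seed + i,
                )
                for i, (c, s) in enumerate(zip(centers, sigmas))
            ]
            covariates = syn.get("covariates", list(range(len(series))))
        else:
            series = [spectra.load_spectrum(p, kind="uvvis_absorbance")
                      for p in pcfg["files"]]
            covariates = pcfg.get("covariates", list(range(len(series))))
        df = spectra.shift_series(series, covariates,
                                  window=tuple(pcfg.get("window", (320.0, 500.0))))
        out["plasmon"] = {
            "table": df.to_dict(orient="records"),
            "red_shift": df.attrs["red_shift"],
            "broadening": df.attrs["broadening"],
        }
    if "ftir" in cfg:
        fcfg = cfg["ftir"]
        if "synthetic" in fcfg:
            syn = fcfg["synthetic"]
            # 1 cm^-1 grid so the canonical band centers are representable
            grid = tuple(syn.get("grid", (1500.0, 1800.0, 1.0)))
            free = synthdata.gen_spectrum(
                peaks=syn.get("free_bands", [(1635.0, 0.35, 2.0), (1651.0, 0.4, 2.0)]),
                kind="ftir_transmittance", grid=grid,
                noise_sd=float(syn.get("noise_sd", 0.0)), seed=seed,
            )
            bound = synthdata.gen_spectrum(
                peaks=syn.get("bound_bands", [(1646.0, 0.3, 2.0), (1651.0, 0.35, 2.0)]),
                kind="ftir_transmittance", grid=grid,
                noise_sd=float(syn.get("noise_sd", 0.0)), seed=seed + 1,
            )
        else:
            free = spectra.load_spectrum(fcfg["free_file"], kind="ftir_transmittance")
            bound = spectra.load_spectrum(fcfg["bound_file"], kind="ftir_transmittance")
        free_bands = spectra.amide_bands(free)
        bound_bands = spectra.amide_bands(bound)
        out["ftir"] = {
            "free_bands": [vars(b) for b in free_bands],
            "bound_bands": [vars(b) for b in bound_bands],
            "shifts": spectra.band_shift(free_bands, bound_bands),
        }
    return out


def _npmodel_stage(cfg: dict) -> dict:
    a = float(cfg.get("lattice_constant", npmodel.SILVER_LATTICE_CONSTANT))
    radius = float(cfg.get("radius", 30.0))
    block = npmodel.build_fcc(a, radius)
    sphere = npmodel.carve_sphere(block, radius=radius)
    out: dict[str, Any] = {
        "lattice_constant": a,
        "radius": radius,
        "sphere_atoms": len(sphere),
    }
    if "cap_atom_count" in cfg:
        cap, meta = npmodel.carve_cap(sphere, radius,
                                      atom_count=int(cfg["cap_atom_count"]))
        out["cap"] = meta
    if "binding_energy_kcal" in cfg:
        dg = float(cfg["binding_energy_kcal"])
        temp = float(cfg.get("temperature", 298.15))
        out["ki_M"] = npmodel.ki_from_binding_energy(dg, temp)
        out["ki_mM"] = out["ki_M"] * 1e3
    out.update(npmodel.grid_box_stanza(
        tuple(cfg.get("grid_box", (49.026, 51.0687, 51.0687)))))
    return out


_STAGES = {"binding", "activity", "purification", "spectra", "npmodel", "seed"}


def run_full(config: dict) -> AnalysisReport:
    """Run every configured stage and assemble the report.

    Unknown top-level configuration keys raise a validation error naming
    the key; missing sections are skipped and noted.
    """
    unknown = set(config) - _STAGES
    if unknown:
        raise ValueError(f"unknown configuration key(s): {sorted(unknown)}")
    seed = int(config.get("seed", 0))
    report = AnalysisReport(provenance=_provenance(config, seed))

    if "binding" in config:
        section, notices = _binding_stage(config["binding"], seed)
        report.binding = section
        report.notices.extend(notices)
    else:
        report.notices.append("binding stage skipped: not configured")
    if "activity" in config:
        report.activity = _activity_stage(config["activity"], seed)
    else:
        report.notices.append("activity stage skipped: not configured")
    if "purification" in config:
        report.purification = _purification_stage(config["purification"])
    else:
        report.notices.append("purification stage skipped: not configured")
    if "spectra" in config:
        report.spectra = _spectra_stage(config["spectra"], seed)
    else:
        report.notices.append("spectra stage skipped: not configured")
    if "npmodel" in config:
        report.npmodel = _npmodel_stage(config["npmodel"])
    else:
        report.notices.append("npmodel stage skipped: not configured")

    validate_report(report.to_dict())
    return report


def demo_config(seed: int = 0) -> dict:
    """All-synthetic configuration exercising every stage."""
    return {
        "seed": seed,
        "binding": {
            "synthetic": {"delta_h": -3.76e4, "delta_s": -149.3, "noise_sd": 0.0},
            # Gibbs-identity entropy anchor (T, dG in J/mol)
            "delta_g_anchor": [298.0, -8.225e4],
        },
        "activity": {
            "synthetic": {
                "control_rate": 0.594,
                "relative": {"control": 1.0, "np_60uM": 0.73,
                             "np_80uM": 0.29, "np_100uM": 0.01},
            },
            "control": "control",
        },
        "purification": {
            "steps": [
                {"name": "crude", "volume_ml": 162.0, "conc_mg_per_ml": 3.87,
                 "total_activity_U": 429.1},
                {"name": "soluble", "volume_ml": 118.0, "conc_mg_per_ml": 2.14,
                 "total_activity_U": 398.23},
                {"name": "ni_affinity", "volume_ml": 40.0, "conc_mg_per_ml": 0.71,
                 "total_activity_U": 103.63},
                {"name": "desalting", "volume_ml": 7.2, "conc_mg_per_ml": 3.5,
                 "total_activity_U": 96.96},
            ]
        },
        "spectra": {
            "plasmon": {"synthetic": {"centers": [405, 407, 409, 411, 412]}},
            "ftir": {"synthetic": {}},
        },
        "npmodel": {"radius": 30.0, "cap_atom_count": 277,
                    "binding_energy_kcal": -3.74},
    }
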