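"""Crystal-lattice nanoparticle models and docking-input geometry.

A metal nanoparticle is modelled by replicating the face-centered-cubic
(FCC) unit cell of the bulk crystal, carving a sphere of the desired
radius out of the lattice and, when the docking surface of interest is
a facet, cutting a sphere cap off the top.  The cap is exported as a
rigid PDBQT receptor with custom AutoDock-style van der Waals
parameters for the metal (for silver: Rii = 3.15 A, eps = 0.036
kcal/mol).  A docking binding energy converts to an inhibition constant
through Ki = exp(dG/RT), and the contact footprint of a docked protein
on the particle is the set of residues whose minimum atom-atom distance
to the particle falls below a cutoff.

Default lattice constant is that of FCC silver, a = 4.0857 A.
"""

from __future__ import annotations

import io
import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from scipy.spatial import cKDTree

__all__ = [
    "SILVER_LATTICE_CONSTANT",
    "KCAL_GAS_CONSTANT",
    "AtomCloud",
    "MetalParams",
    "SILVER_PARAMS",
    "build_fcc",
    "carve_sphere",
    "carve_cap",
    "write_pdbqt",
    "read_pdbqt",
    "ad4_parameter_line",
    "ki_from_binding_energy",
    "contact_footprint",
    "read_pdb",
    "grid_box_stanza",
]

#: conventional cell edge of FCC silver, angstrom
SILVER_LATTICE_CONSTANT = 4.0857

#: gas constant in kcal mol^-1 K^-1 (AutoDock convention)
KCAL_GAS_CONSTANT = 1.98720e-3

#: fractional coordinates of the 4-atom FCC basis
_FCC_BASIS = np.array(
    [[0.0, 0.0, 0.0], [0.5, 0.5, 0.0], [0.5, 0.0, 0.5], [0.0, 0.5, 0.5]]
)


@dataclass(frozen=True)
class AtomCloud:
    """A set of atoms: element symbols plus cartesian coordinates (A).

    Protein clouds read from structure files additionally carry per-atom
    residue metadata as (residue number, residue name) tuples.
    """

    elements: tuple[str, ...]
    coords: np.ndarray                       # (N, 3) angstrom
    residues: tuple[tuple[int, str], ...] | None = None
    lattice_constant: float | None = None

    def __post_init__(self):
        c = np.asarray(self.coords, dtype=float).reshape(-1, 3)
        object.__setattr__(self, "coords", c)
        object.__setattr__(self, "elements", tuple(self.elements))
        if len(self.elements) != len(c):
            raise ValueError("element list length must equal coordinate count")
        if not np.all(np.isfinite(c)):
            raise ValueError("non-finite coordinates")
        if self.residues is not None and len(self.residues) != len(c):
            raise ValueError("residue metadata length must equal coordinate count")

    def __len__(self) -> int:
        return len(self.elements)


@dataclass(frozen=True)
class MetalParams:
    """AutoDock-style van der Waals parameters for one metal element."""

    element: str
    r_ii: float      # angstrom, vdW diameter-like parameter
    eps_ii: float    # kcal/mol, well depth

    def __post_init__(self):
        if self.r_ii <= 0:
            raise ValueError("r_ii must be > 0")
        if self.eps_ii < 0:
            raise ValueError("eps_ii must be >= 0")


SILVER_PARAMS = MetalParams("Ag", 3.15, 0.036)


def build_fcc(
    lattice_constant: float = SILVER_LATTICE_CONSTANT,
    extent_radius: float = 30.0,
    element: str = "Ag",
    atom_centered: bool = True,
) -> AtomCloud:
    """Replicate the FCC unit cell to cover a ball of ``extent_radius``.

    The 4-atom basis (0,0,0), (1/2,1/2,0), (1/2,0,1/2), (0,1/2,1/2) is
    tiled over every integer cell whose atoms can fall within the ball
    centered at the origin.  With ``atom_centered`` (default) the origin
    coincides with a lattice atom; otherwise the lattice is offset by a
    quarter body diagonal so the center sits interstitially.
    """
    if lattice_constant <= 0:
        raise ValueError("lattice_constant must be > 0")
    a = lattice_constant
    n = int(math.ceil(extent_radius / a)) + 1
    idx = np.arange(-n, n + 1)
    cells = np.array(np.meshgrid(idx, idx, idx, indexing="ij")).reshape(3, -1).T
    frac = cells[:, None, :] + _FCC_BASIS[None, :, :]     # (ncells, 4, 3)
    coords = (frac.reshape(-1, 3)) * a
    if not atom_centered:
        coords = coords + a / 4.0
    # keep the block just large enough to guarantee coverage of the ball
    keep = np.all(np.abs(coords) <= (extent_radius + a), axis=1)
    coords = coords[keep]
    return AtomCloud(
        elements=(element,) * len(coords),
        coords=coords,
        lattice_constant=a,
    )


def carve_sphere(
    cloud: AtomCloud, center: Sequence[float] = (0.0, 0.0, 0.0), radius: float = 30.0
) -> AtomCloud:
    """Retain atoms with distance <= radius from center (boundary kept)."""
    c = np.asarray(center, dtype=float)
    d = np.linalg.norm(cloud.coords - c, axis=1)
    keep = d <= radius
    return replace(
        cloud,
        elements=tuple(e for e, k in zip(cloud.elements, keep) if k),
        coords=cloud.coords[keep],
        residues=None if cloud.residues is None
        else tuple(r for r, k in zip(cloud.residues, keep) if k),
    )


def carve_cap(
    sphere: AtomCloud,
    radius: float,
    height: float | None = None,
    atom_count: int | None = None,
) -> tuple[AtomCloud, dict]:
    """Cut the sphere cap z >= radius - h off an atom sphere.

    Exactly one of ``height`` (h, in A along +z) or ``atom_count`` must
    be given.  In count mode, h is found by bisection to the smallest
    height whose cap holds at least ``atom_count`` atoms; atoms tied on
    the boundary plane are all kept, so the achieved count (reported in
    the metadata dict) may exceed the target.
    """
    if (height is None) == (atom_count is None):
        raise ValueError("give exactly one of height or atom_count")

    z = sphere.coords[:, 2]

    def cap_mask(h: float) -> np.ndarray:
        return z >= radius - h

    if atom_count is not None:
        if atom_count <= 0:
            raise ValueError("atom_count must be positive")
        if atom_count > len(sphere):
            raise ValueError(
                f"requested {atom_count} atoms but the sphere holds {len(sphere)}"
            )
        lo, hi = 0.0, 2.0 * radius
        # count(h) is a monotone step function of h; bisect to the jump
        for _ in range(200):
            mid = 0.5 * (lo + hi)
            if int(cap_mask(mid).sum()) >= atom_count:
                hi = mid
            else:
                lo = mid
            if hi - lo < 1e-9:
                break
        height = hi

    mask = cap_mask(height)
    cap = replace(
        sphere,
        elements=tuple(e for e, k in zip(sphere.elements, mask) if k),
        coords=sphere.coords[mask],
        residues=None,
    )
    meta = {
        "height": float(height),
        "achieved_count": len(cap),
        "target_count": atom_count,
    }
    return cap, meta


def ad4_parameter_line(params: MetalParams) -> str:
    """AD4-style atom_par line carrying Rii and eps for the metal.

    Trailing fields (volume, solvation, H-bond flags, bond index) use
    neutral defaults; the docking engine reads Rii/eps from columns 2-3.
    """
    return (
        f"atom_par {params.element:<2s}     {params.r_ii:6.2f}  {params.eps_ii:7.4f}"
        f"  12.0000  -0.00110  0.0  0.0  0  -1  -1  4"
    )


def write_pdbqt(
    cloud: AtomCloud,
    params: MetalParams,
    charge: float = 0.0,
    residue_name: str = "NP",
) -> str:
    """Serialize a single-element cloud as a rigid PDBQT receptor.

    One fixed-width ATOM record per atom (no torsion tree), the partial
    charge as given (bare metal clusters default to 0.000) and the
    AutoDock atom type set to the element symbol.  The AD4 parameter
    line for the metal is included as a REMARK for provenance.
    """
    if len(set(cloud.elements)) != 1:
        raise ValueError("PDBQT export requires a single-element cloud")
    el = cloud.elements[0]
    if el != params.element:
        raise ValueError(f"cloud element {el!r} does not match params {params.element!r}")
    lines = [
        f"REMARK  rigid nanoparticle model, {len(cloud)} {el} atoms",
        f"REMARK  {ad4_parameter_line(params)}",
    ]
    for i, (x, y, z) in enumerate(cloud.coords, start=1):
        name = el[:4]
        lines.append(
            f"ATOM  {i:5d} {name:<4s} {residue_name:<3s} A{1:4d}    "
            f"{x:8.3f}{y:8.3f}{z:8.3f}{1.00:6.2f}{0.00:6.2f}    "
            f"{charge:6.3f} {el:<2s}"
        )
    lines.append("TER")
    lines.append("END")
    return "\n".join(lines) + "\n"


def read_pdbqt(text: str) -> AtomCloud:
    """Parse ATOM/HETATM records of a PDBQT document back to a cloud."""
    elements: list[str] = []
    coords: list[list[float]] = []
    for line in text.splitlines():
        if line.startswith(("ATOM", "HETATM")):
            coords.append(
                [float(line[30:38]), float(line[38:46]), float(line[46:54])]
            )
            elements.append(line[77:79].strip() or line[12:16].strip())
    if not elements:
        raise ValueError("no ATOM records found")
    return AtomCloud(elements=tuple(elements), coords=np.array(coords))


def ki_from_binding_energy(delta_g: float, temperature: float = 298.15) -> float:
    """Inhibition constant (mol/L) from a docking binding energy.

    Ki = exp(dG / (R.T)) with dG in kcal/mol and R = 1.98720e-3
    kcal mol^-1 K^-1; a negative dG gives Ki < 1 M.
    """
    if temperature <= 0:
        raise ValueError("temperature must be > 0")
    return math.exp(delta_g / (KCAL_GAS_CONSTANT * temperature))


def contact_footprint(
    protein: AtomCloud, np_cloud: AtomCloud, cutoff: float = 3.5
) -> list[tuple[tuple[int, str], float]]:
    """Residues of the protein within ``cutoff`` A of the nanoparticle.

    For each residue the minimum atom-atom distance to any particle atom
    is computed (k-d tree over the particle atoms); residues at or below
    the cutoff are returned ascending by residue number.
    """
    if len(protein) == 0 or len(np_cloud) == 0:
        raise ValueError("both clouds must be non-empty")
    if protein.residues is None:
        raise ValueError("protein cloud lacks residue metadata")
    tree = cKDTree(np_cloud.coords)
    dmin, _ = tree.query(protein.coords)
    per_res: dict[tuple[int, str], float] = {}
    for res, d in zip(protein.residues, dmin):
        key = (int(res[0]), str(res[1]))
        if key not in per_res or d < per_res[key]:
            per_res[key] = float(d)
    hits = [(res, d) for res, d in per_res.items() if d <= cutoff]
    return sorted(hits, key=lambda item: item[0][0])


def read_pdb(path, model_index: int = 0) -> AtomCloud:
    """Read protein coordinates and residue metadata from a PDB file."""
    from Bio.PDB import PDBParser

    parser = PDBParser(QUIET=True)
    structure = parser.get_structure("protein", path)
    model = list(structure)[model_index]
    elements: list[str] = []
    coords: list[np.ndarray] = []
    residues: list[tuple[int, str]] = []
    for chain in model:
        for residue in chain:
            resseq = residue.id[1]
            resname = residue.get_resname().strip()
            for atom in residue:
                el = (atom.element or atom.get_name()[0]).strip().capitalize()
                elements.append(el)
                coords.append(atom.get_coord())
                residues.append((int(resseq), resname))
    if not elements:
        raise ValueError(f"no atoms read from {path}")
    return AtomCloud(
        elements=tuple(elements),
        coords=np.array(coords, dtype=float),
        residues=tuple(residues),
    )


def grid_box_stanza(
    dimensions: tuple[float, float, float] = (49.026, 51.0687, 51.0687),
    center: tuple[float, float, float] = (0.0, 0.0, 0.0),
    spacing: float = 0.375,
) -> dict:
    """Grid-box metadata block for external docking tools."""
    return {
        "grid_box": {
            "size_angstrom": list(dimensions),
            "center_angstrom": list(center),
            "spacing_angstrom": spacing,
        }
    }
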