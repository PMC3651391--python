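"""Protein structure ingestion and solvent accessibility.

Per-atom accessible surface area (ASA) is computed by the Shrake-Rupley
point-sampling method: quasi-uniform test points are placed on each atom's
probe-expanded sphere and the exposed fraction — points not inside any other
atom's expanded sphere — times the sphere area gives the atom's ASA.  A
residue's relative accessibility is its summed atom ASA divided by a
reference maximum for that residue type; residues with relative
accessibility below 0.1 are called buried.

Sphere points come from a deterministic golden-section spiral in a fixed
global frame, so results are exactly reproducible for a given point count;
rotating a structure changes ASA only within the sampling tolerance.
"""

from __future__ import annotations

import functools
import io
import json
import math
import warnings
from dataclasses import dataclass
from enum import Enum

import numpy as np
from scipy.spatial import cKDTree

from .aa_properties import THREE_TO_ONE

__all__ = [
    "AtomRecord",
    "StructureModel",
    "AccessibilityResult",
    "Burial",
    "DEFAULT_VDW_RADII",
    "DEFAULT_PROBE_RADIUS",
    "DEFAULT_SPHERE_POINTS",
    "PDBParseError",
    "MissingResidueError",
    "UnknownElementError",
    "read_structure",
    "golden_spiral_points",
    "shrake_rupley_asa",
    "residue_asa",
    "residue_relative_accessibility",
    "classify_burial",
    "accessibility_table",
    "ideal_residue_structure",
    "reference_max_asa",
]

DEFAULT_PROBE_RADIUS = 1.4  # water probe, Å
DEFAULT_SPHERE_POINTS = 960
BURIAL_THRESHOLD = 0.1

# Element-based van der Waals radii (Å); overridable per call.
DEFAULT_VDW_RADII: dict[str, float] = {
    "C": 1.70,
    "N": 1.55,
    "O": 1.52,
    "S": 1.80,
    "P": 1.80,
    "SE": 1.90,
}


class PDBParseError(ValueError):
    pass


class UnknownElementError(PDBParseError):
    pass


class MissingResidueError(KeyError):
    """A residue position absent from the structure (e.g. an unmodeled loop).

    Carries ``chain`` and ``residue_number`` so callers can substitute a
    user-supplied accessibility for that position.
    """

    def __init__(self, chain: str, residue_number: int):
        super().__init__((chain, residue_number))
        self.chain = chain
        self.residue_number = residue_number

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return f"residue {self.residue_number} of chain {self.chain!r} is not in the structure"


class Burial(str, Enum):
    BURIED = "buried"
    SURFACE = "surface"


@dataclass(frozen=True)
class AtomRecord:
    chain: str
    residue_number: int
    insertion_code: str
    residue_name: str
    atom_name: str
    element: str
    coords: tuple[float, float, float]
    vdw_radius: float
    hetero: bool = False
    is_water: bool = False


@dataclass(frozen=True)
class StructureModel:
    atoms: tuple[AtomRecord, ...]
    model_index: int = 0

    def residue_key(self, atom: AtomRecord) -> tuple[str, int, str]:
        return (atom.chain, atom.residue_number, atom.insertion_code)


@dataclass(frozen=True)
class AccessibilityResult:
    chain: str
    residue_number: int
    residue_name: str
    absolute_asa: float
    relative_accessibility: float
    burial: Burial


def _radius_for(element: str, atom_name: str, radii: dict[str, float]) -> float:
    el = element.upper().strip()
    if el in radii:
        return radii[el]
    raise UnknownElementError(
        f"no van der Waals radius for element {element!r} (atom {atom_name!r}); "
        "extend the radius table to include it"
    )


def read_structure(
    pdb_text: str,
    radii: dict[str, float] | None = None,
    keep_hydrogens: bool = False,
) -> StructureModel:
    """Parse PDB-format text into a :class:`StructureModel`.

    Only the first model of a multi-model file is kept.  Alternate locations
    are resolved to the highest-occupancy conformer (ties: first listed).
    Waters and non-protein heteroatoms are retained but flagged, and are
    excluded from ASA computations unless requested.  Hydrogens are dropped
    by default.  Parsing itself is delegated to Biopython.
    """
    from Bio.PDB import PDBParser

    radii = DEFAULT_VDW_RADII if radii is None else radii
    parser = PDBParser(QUIET=True)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        bio_structure = parser.get_structure("s", io.StringIO(pdb_text))
    models = list(bio_structure.get_models())
    if not models:
        raise PDBParseError("no ATOM or HETATM records found in the input")
    model = models[0]

    atoms: list[AtomRecord] = []
    for chain in model:
        for residue in chain:
            hetfield, resseq, icode = residue.get_id()
            is_water = hetfield == "W"
            hetero = hetfield.strip() != "" and not is_water
            for atom in residue:
                if atom.is_disordered():
                    alts = atom.disordered_get_list()
                    atom = max(alts, key=lambda a: (a.get_occupancy() or 0.0))
                element = (atom.element or "").strip()
                if not keep_hydrogens and element in ("H", "D"):
                    continue
                coords = atom.get_coord()
                if not np.all(np.isfinite(coords)):
                    raise PDBParseError(
                        f"non-finite coordinates on atom {atom.get_name()!r}"
                    )
                atoms.append(
                    AtomRecord(
                        chain=chain.id,
                        residue_number=int(resseq),
                        insertion_code=icode.strip(),
                        residue_name=residue.get_resname().strip(),
                        atom_name=atom.get_name(),
                        element=element,
                        coords=tuple(float(x) for x in coords),
                        vdw_radius=_radius_for(element, atom.get_name(), radii),
                        hetero=hetero,
                        is_water=is_water,
                    )
                )
    if not atoms:
        raise PDBParseError("no ATOM or HETATM records found in the input")
    return StructureModel(atoms=tuple(atoms), model_index=0)


@functools.lru_cache(maxsize=8)
def golden_spiral_points(n: int) -> np.ndarray:
    """``n`` quasi-uniform unit vectors from the golden-section spiral."""
    if n < 10:
        raise ValueError("need at least 10 sphere points")
    i = np.arange(n, dtype=float)
    z = 1.0 - (2.0 * i + 1.0) / n
    theta = i * math.pi * (3.0 - math.sqrt(5.0))
    rho = np.sqrt(np.clip(1.0 - z * z, 0.0, 1.0))
    pts = np.column_stack([rho * np.cos(theta), rho * np.sin(theta), z])
    pts.setflags(write=False)
    return pts


def _included_atoms(
    structure: StructureModel, include_hetero: bool, include_waters: bool
) -> list[int]:
    idx = []
    for i, a in enumerate(structure.atoms):
        if a.is_water and not include_waters:
            continue
        if a.hetero and not a.is_water and not include_hetero:
            continue
        idx.append(i)
    return idx


def shrake_rupley_asa(
    structure: StructureModel,
    probe_radius: float = DEFAULT_PROBE_RADIUS,
    n_sphere_points: int = DEFAULT_SPHERE_POINTS,
    include_hetero: bool = False,
    include_waters: bool = False,
) -> dict[int, float]:
    """Per-atom solvent accessible surface area in Å².

    Returns a map from atom index (into ``structure.atoms``) to ASA for every
    included atom.  A test point is buried when it lies strictly inside
    another included atom's probe-expanded sphere.  Neighbour candidates come
    from a KD-tree; the result is identical to all-pairs checking.
    """
    if probe_radius <= 0:
        raise ValueError("probe_radius must be positive")
    unit = golden_spiral_points(n_sphere_points)

    idx = _included_atoms(structure, include_hetero, include_waters)
    if not idx:
        return {}
    coords = np.array([structure.atoms[i].coords for i in idx], dtype=float)
    if not np.all(np.isfinite(coords)):
        raise ValueError("non-finite coordinates in structure")
    radii = np.array([structure.atoms[i].vdw_radius for i in idx], dtype=float) + probe_radius

    tree = cKDTree(coords)
    max_r = radii.max()
    out: dict[int, float] = {}
    for k, atom_index in enumerate(idx):
        r = radii[k]
        neighbours = [
            j
            for j in tree.query_ball_point(coords[k], r + max_r)
            if j != k and np.linalg.norm(coords[j] - coords[k]) < r + radii[j]
        ]
        pts = coords[k] + r * unit
        exposed = np.ones(len(pts), dtype=bool)
        for j in neighbours:
            d2 = np.einsum("ij,ij->i", pts - coords[j], pts - coords[j])
            exposed &= d2 >= radii[j] ** 2
        out[atom_index] = 4.0 * math.pi * r * r * float(exposed.mean())
    return out


def residue_asa(
    structure: StructureModel,
    probe_radius: float = DEFAULT_PROBE_RADIUS,
    n_sphere_points: int = DEFAULT_SPHERE_POINTS,
    include_hetero: bool = False,
) -> dict[tuple[str, int, str], float]:
    """Summed atom ASA per (chain, residue number, insertion code)."""
    atom_asa = shrake_rupley_asa(
        structure, probe_radius, n_sphere_points, include_hetero=include_hetero
    )
    out: dict[tuple[str, int, str], float] = {}
    for i, asa in atom_asa.items():
        a = structure.atoms[i]
        if a.hetero or a.is_water:
            continue
        out[structure.residue_key(a)] = out.get(structure.residue_key(a), 0.0) + asa
    return out


def ideal_residue_structure(three_letter: str) -> StructureModel:
    """An isolated residue with idealized coordinates (heavy atoms, no OXT).

    Coordinates come from the chemical component dictionary bundled with
    biotite; the terminal carboxyl oxygen is dropped so the residue mimics an
    in-chain residue.
    """
    import biotite.structure.info as struc_info

    arr = struc_info.residue(three_letter.upper())
    if arr is None:
        raise KeyError(f"unknown residue {three_letter!r}")
    atoms = []
    for name, element, coord in zip(arr.atom_name, arr.element, arr.coord):
        if element in ("H", "D") or name == "OXT":
            continue
        atoms.append(
            AtomRecord(
                chain="A",
                residue_number=1,
                insertion_code="",
                residue_name=three_letter.upper(),
                atom_name=str(name),
                element=str(element),
                coords=tuple(float(x) for x in coord),
                vdw_radius=_radius_for(str(element), str(name), DEFAULT_VDW_RADII),
            )
        )
    return StructureModel(atoms=tuple(atoms))


@functools.lru_cache(maxsize=4)
def reference_max_asa(
    probe_radius: float = DEFAULT_PROBE_RADIUS,
    n_sphere_points: int = DEFAULT_SPHERE_POINTS,
) -> dict[str, float]:
    """Reference maximum ASA per residue type (3-letter code), in Å².

    Computed by this module's own ASA engine on isolated idealized residues,
    so that an isolated residue normalizes to exactly 1.0.  A user-supplied
    table (e.g. from an extended-peptide convention) can be passed to
    :func:`residue_relative_accessibility` instead.
    """
    table = {}
    for three in THREE_TO_ONE:
        s = ideal_residue_structure(three)
        table[three] = sum(
            shrake_rupley_asa(s, probe_radius, n_sphere_points).values()
        )
    return table


def residue_relative_accessibility(
    structure: StructureModel,
    chain: str,
    residue_number: int,
    max_asa_table: dict[str, float] | None = None,
    probe_radius: float = DEFAULT_PROBE_RADIUS,
    n_sphere_points: int = DEFAULT_SPHERE_POINTS,
    include_hetero: bool = False,
) -> float:
    """Relative accessibility of one residue (may exceed 1 for extended/terminal residues)."""
    per_residue = residue_asa(structure, probe_radius, n_sphere_points, include_hetero)
    key = (chain, residue_number, "")
    if key not in per_residue:
        raise MissingResidueError(chain, residue_number)
    resname = next(
        a.residue_name for a in structure.atoms if structure.residue_key(a) == key
    )
    table = (
        reference_max_asa(probe_radius, n_sphere_points)
        if max_asa_table is None
        else max_asa_table
    )
    if resname not in table:
        raise KeyError(f"residue type {resname!r} absent from the reference max-ASA table")
    return per_residue[key] / table[resname]


def classify_burial(relative_accessibility: float, threshold: float = BURIAL_THRESHOLD) -> Burial:
    """Buried/surface split; strictly below the threshold is buried."""
    if not np.isfinite(relative_accessibility) or relative_accessibility < 0:
        raise ValueError("relative accessibility must be finite and non-negative")
    return Burial.BURIED if relative_accessibility < threshold else Burial.SURFACE


def accessibility_table(
    structure: StructureModel,
    max_asa_table: dict[str, float] | None = None,
    probe_radius: float = DEFAULT_PROBE_RADIUS,
    n_sphere_points: int = DEFAULT_SPHERE_POINTS,
    include_hetero: bool = False,
    burial_threshold: float = BURIAL_THRESHOLD,
) -> "pandas.DataFrame":  # noqa: F821
    """Per-residue accessibility as a DataFrame (chain, resnum, resname, asa_A2, rel_acc, burial)."""
    import pandas as pd

    per_residue = residue_asa(structure, probe_radius, n_sphere_points, include_hetero)
    table = (
        reference_max_asa(probe_radius, n_sphere_points)
        if max_asa_table is None
        else max_asa_table
    )
    names = {}
    for a in structure.atoms:
        names.setdefault(structure.residue_key(a), a.residue_name)
    rows = []
    for (chain, resnum, icode), asa in per_residue.items():
        resname = names[(chain, resnum, icode)]
        rel = asa / table[resname] if resname in table else float("nan")
        rows.append(
            {
                "chain": chain,
                "resnum": resnum,
                "resname": resname,
                "asa_A2": asa,
                "rel_acc": rel,
                "burial": classify_burial(rel, burial_threshold).value
                if np.isfinite(rel)
                else ".",
            }
        )
    return pd.DataFrame(rows)


def load_radius_table(path) -> dict[str, float]:
    with open(path) as fh:
        table = json.load(fh)
    return {str(k).upper(): float(v) for k, v in table.items()}
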