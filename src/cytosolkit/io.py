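"""Readers/writers for standard structure and trajectory formats.

Parsing and serialization of GRO/PDB/XYZ are delegated to MDAnalysis; this
module maps the parsed records onto the package's :class:`~cytosolkit.model.Topology`
and :class:`~cytosolkit.model.Trajectory` types, fills in per-atom charges
and radii from a species parameter table (the formats carry neither), and
enforces the package's strictness rules (orthorhombic cells only, uniform
frame spacing, no silently skipped records).
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .model import Molecule, SimulationCell, Topology, Trajectory

__all__ = [
    "ParameterTable",
    "read_structure",
    "write_structure",
    "read_trajectory",
    "load_config",
    "ParseError",
]


class ParseError(ValueError):
    """A structure or trajectory file violated its format or our contracts."""


# Bondi van der Waals radii (Å) by element; overridable per species.
BONDI_RADII = {
    "H": 1.20,
    "C": 1.70,
    "N": 1.55,
    "O": 1.52,
    "P": 1.80,
    "S": 1.80,
    "F": 1.47,
    "CL": 1.75,
    "NA": 2.27,
    "K": 2.75,
    "MG": 1.73,
    "CA": 2.31,
}

WATER_RESNAMES = {"SOL", "WAT", "HOH", "TIP3", "TIP3P", "SPC"}

AMINO_ACIDS = {
    "ALA", "ARG", "ASN", "ASP", "CYS", "GLN", "GLU", "GLY", "HIS", "ILE",
    "LEU", "LYS", "MET", "PHE", "PRO", "SER", "THR", "TRP", "TYR", "VAL",
    "HSD", "HSE", "HSP", "HID", "HIE", "HIP",
}

# TIP3P-style water partial charges by atom-name initial.
_WATER_CHARGES = {"O": -0.834, "H": 0.417}

_TWO_LETTER_ELEMENTS = ("CL", "NA", "MG", "CA", "BR", "FE", "ZN")


def infer_element(atom_name: str) -> str:
    """Infer the element symbol from an atom name (GRO/PDB convention)."""
    name = re.sub(r"^\d+", "", atom_name.strip()).upper()
    if not name:
        raise ParseError(f"cannot infer element from atom name {atom_name!r}")
    for two in _TWO_LETTER_ELEMENTS:
        if name.startswith(two):
            return two
    return name[0]


@dataclass
class SpeciesParams:
    """Per-species overrides for kind, charges and radii."""

    kind: str = "metabolite"
    net_charge: float | None = None
    atom_charges: dict[str, float] = field(default_factory=dict)
    atom_radii: dict[str, float] = field(default_factory=dict)


class ParameterTable:
    """Maps species (residue names) and elements to charges, radii and kinds.

    The default table knows water, the neutralizing ions used by the model
    cytosol (K⁺, Mg²⁺, Na⁺, Cl⁻, putrescine) and Bondi element radii; a
    species absent from both the table and the radii map raises a lookup
    error rather than guessing.
    """

    def __init__(self, species: dict[str, SpeciesParams] | None = None,
                 element_radii: dict[str, float] | None = None):
        self.element_radii = dict(BONDI_RADII)
        if element_radii:
            self.element_radii.update(element_radii)
        self.species: dict[str, SpeciesParams] = {}
        for resname in WATER_RESNAMES:
            self.species[resname] = SpeciesParams(kind="water")
        for ion, q in (("K", 1.0), ("K+", 1.0), ("NA", 1.0), ("NA+", 1.0),
                       ("MG", 2.0), ("MG2+", 2.0), ("CL", -1.0), ("CL-", -1.0)):
            self.species[ion] = SpeciesParams(kind="ion", net_charge=q)
        self.species["PUT"] = SpeciesParams(kind="metabolite", net_charge=2.0)
        if species:
            self.species.update(species)

    def kind_of(self, resname: str) -> str:
        key = resname.upper()
        if key in self.species:
            return self.species[key].kind
        if key in AMINO_ACIDS:
            return "protein"
        return "metabolite"

    def charge_of(self, resname: str, atom_name: str, element: str,
                  n_atoms_in_molecule: int) -> float:
        key = resname.upper()
        sp = self.species.get(key)
        if sp is not None:
            if atom_name in sp.atom_charges:
                return sp.atom_charges[atom_name]
            if sp.kind == "water":
                return _WATER_CHARGES.get(element, 0.0)
            if sp.net_charge is not None and n_atoms_in_molecule == 1:
                return sp.net_charge
        return 0.0

    def radius_of(self, resname: str, atom_name: str, element: str) -> float:
        sp = self.species.get(resname.upper())
        if sp is not None and atom_name in sp.atom_radii:
            return sp.atom_radii[atom_name]
        try:
            return self.element_radii[element]
        except KeyError:
            raise ParseError(
                f"no radius for element {element!r} (atom {atom_name!r} of "
                f"{resname!r}) and no species override provided"
            ) from None


def _cell_from_dimensions(dims, temperature: float) -> SimulationCell | None:
    if dims is None:
        return None
    dims = np.asarray(dims, dtype=float)
    if not np.any(dims[:3] > 0):
        return None
    if not np.allclose(dims[3:], 90.0, atol=1e-3):
        raise ParseError(
            f"triclinic cells are unsupported (angles {dims[3:].tolist()}); "
            "only orthorhombic boxes are handled"
        )
    return SimulationCell(tuple(dims[:3]), temperature)


def _import_mda():
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        import MDAnalysis as mda
    return mda


def read_structure(path, fmt: str | None = None,
                   params: ParameterTable | None = None,
                   temperature: float = 310.15):
    """Read a PDB/GRO/XYZ structure into (Topology, coords, cell).

    Molecule grouping is inferred from residue records: runs of consecutive
    amino-acid residues form one protein molecule (with residue grouping
    retained); every other residue is one molecule.  Charges and radii come
    from ``params`` since the formats carry neither.
    """
    mda = _import_mda()
    params = params or ParameterTable()
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    kwargs = {"format": fmt} if fmt else {}
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            u = mda.Universe(str(path), **kwargs)
    except FileNotFoundError:
        raise
    except Exception as exc:  # MDAnalysis raises assorted types per format
        raise ParseError(f"{path.name}: {exc}") from exc

    atoms = u.atoms
    n = len(atoms)
    if n == 0:
        raise ParseError(f"{path.name}: no atoms parsed")
    names = [str(a.name) for a in atoms]
    try:
        resnames = [str(a.resname) for a in atoms]
        resids = [int(a.resid) for a in atoms]
    except (AttributeError, mda.exceptions.NoDataError):
        # XYZ carries no residue records: every atom is its own molecule.
        resnames = [infer_element(nm) for nm in names]
        resids = list(range(1, n + 1))
    for i, rn in enumerate(resnames):
        if not rn.strip():
            raise ParseError(f"{path.name}: atom {i} belongs to no residue")

    elements = [infer_element(nm) for nm in names]

    # group atoms into residues (by consecutive resid+resname runs)
    residues: list[tuple[str, list[int]]] = []
    prev = None
    for i in range(n):
        key = (resids[i], resnames[i])
        if key != prev:
            residues.append((resnames[i], [i]))
            prev = key
        else:
            residues[-1][1].append(i)

    molecules: list[Molecule] = []
    i = 0
    while i < len(residues):
        resname, aids = residues[i]
        if resname.upper() in AMINO_ACIDS:
            run = list(aids)
            j = i + 1
            while j < len(residues) and residues[j][0].upper() in AMINO_ACIDS:
                run.extend(residues[j][1])
                j += 1
            molecules.append(Molecule("protein", np.array(run), kind="protein"))
            i = j
        else:
            kind = params.kind_of(resname)
            molecules.append(Molecule(resname, np.array(aids), kind=kind))
            i += 1

    charges = np.zeros(n)
    radii = np.zeros(n)
    for mol in molecules:
        for a in mol.atom_ids:
            charges[a] = params.charge_of(
                resnames[a], names[a], elements[a], mol.n_atoms
            )
            radii[a] = params.radius_of(resnames[a], names[a], elements[a])

    topo = Topology(elements, radii, charges, molecules,
                    resids=resids, resnames=resnames)
    coords = atoms.positions.astype(float).copy()  # MDAnalysis positions are Å
    cell = _cell_from_dimensions(u.dimensions, temperature)
    return topo, coords, cell


def write_structure(path, topology: Topology, coords: np.ndarray,
                    cell: SimulationCell | None = None) -> None:
    """Write a single-frame structure (format chosen from the extension)."""
    mda = _import_mda()
    n = topology.n_atoms
    resindex = np.empty(n, dtype=int)
    resnames = []
    for i, mol in enumerate(topology.molecules):
        resindex[mol.atom_ids] = i
        resnames.append(mol.species[:5])
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        u = mda.Universe.empty(n, n_residues=len(topology.molecules),
                               atom_resindex=resindex, trajectory=True)
        u.add_TopologyAttr("names", [str(e) for e in topology.elements])
        u.add_TopologyAttr("resnames", resnames)
        u.add_TopologyAttr("resids", np.arange(1, len(topology.molecules) + 1))
        u.atoms.positions = np.asarray(coords, dtype=np.float32)
        if cell is not None:
            u.dimensions = [*cell.lengths, 90.0, 90.0, 90.0]
        u.atoms.write(str(path))


def read_trajectory(paths, topology: Topology, dt: float | None = None,
                    cell: SimulationCell | None = None,
                    times: np.ndarray | None = None) -> Trajectory:
    """Read one or more coordinate-frame files into a Trajectory.

    XYZ streams carry neither time nor box information, so ``dt`` (ps) and
    ``cell`` must be supplied for them; formats that embed box vectors use
    those per frame.  Frames must be uniformly spaced in time — an explicit
    non-uniform ``times`` array is rejected with the offending frames listed.
    """
    mda = _import_mda()
    if isinstance(paths, (str, Path)):
        paths = [paths]
    coords_list = []
    cells: list[SimulationCell] = []
    temperature = cell.temperature if cell is not None else 310.15
    for p in paths:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            u = mda.Universe(str(p)) if topology is None else mda.Universe(
                str(p), to_guess=()
            )
            for ts in u.trajectory:
                if ts.positions.shape[0] != topology.n_atoms:
                    raise ParseError(
                        f"{p}: frame {ts.frame} has {ts.positions.shape[0]} atoms, "
                        f"topology has {topology.n_atoms}"
                    )
                coords_list.append(ts.positions.astype(float).copy())
                c = _cell_from_dimensions(ts.dimensions, temperature)
                cells.append(c if c is not None else cell)
    if any(c is None for c in cells):
        raise ValueError("no cell in file; pass cell= explicitly")
    n_frames = len(coords_list)
    if times is None:
        if dt is None:
            raise ValueError("dt must be given for formats without time records")
        times = np.arange(n_frames) * float(dt)
    else:
        times = np.asarray(times, dtype=float)
        dts = np.diff(times)
        if n_frames > 2 and not np.allclose(dts, dts[0]):
            bad = np.nonzero(~np.isclose(dts, dts[0]))[0] + 1
            raise ParseError(f"non-uniform frame times at frames {bad.tolist()}")
    return Trajectory(times, np.stack(coords_list), cells)


def write_xyz_trajectory(path, topology: Topology, coords: np.ndarray) -> None:
    """Write frames (n_frames, n_atoms, 3) as a plain multi-frame XYZ stream."""
    coords = np.asarray(coords)
    names = [str(e) for e in topology.elements]
    with open(path, "w") as fh:
        for f in range(coords.shape[0]):
            fh.write(f"{topology.n_atoms}\nframe {f}\n")
            for nm, (x, y, z) in zip(names, coords[f]):
                fh.write(f"{nm} {x:.6f} {y:.6f} {z:.6f}\n")


DEFAULT_CONFIG = {
    "temperature_K": 310.15,
    "probe_radius_A": 1.4,
    "contact_threshold_A2": 0.48,
    "msd_origin_stride_ps": 50.0,
    "diffusion_fit_window_ps": [100.0, 2000.0],
    "helfand_fit_window_ps": [100.0, 500.0],
    "n_blocks": 10,
    "seed": 0,
}


def load_config(path=None) -> dict:
    """Load an analysis configuration (YAML key-value file) over defaults."""
    cfg = dict(DEFAULT_CONFIG)
    if path is not None:
        with open(path) as fh:
            user = yaml.safe_load(fh) or {}
        unknown = set(user) - set(cfg)
        if unknown:
            raise KeyError(f"unknown config keys: {sorted(unknown)}")
        cfg.update(user)
    return cfg
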