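"""Core data model: topologies, orthorhombic periodic cells and trajectories.

Internal conventions: coordinates in Å, times in ps, charges in elementary
charges, 0-based atom/molecule indexing.  Only orthorhombic cells are
supported (the model boxes are cubic); triclinic input is rejected at the
I/O boundary.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "SimulationCell",
    "Molecule",
    "Topology",
    "Trajectory",
    "wrap_coordinates",
    "unwrap",
]

# Average atomic masses (u) for center-of-mass weighting; unknown elements
# fall back to carbon so a missing entry biases COM only mildly.
ATOMIC_MASSES = {
    "H": 1.008,
    "C": 12.011,
    "N": 14.007,
    "O": 15.999,
    "P": 30.974,
    "S": 32.06,
    "K": 39.098,
    "MG": 24.305,
    "NA": 22.990,
    "CL": 35.45,
    "CA": 40.078,
    "F": 18.998,
}
_DEFAULT_MASS = 12.011

MOLECULE_KINDS = ("protein", "metabolite", "ion", "water")


@dataclass(frozen=True)
class SimulationCell:
    """Orthorhombic periodic cell with edge lengths in Å and temperature in K."""

    lengths: tuple[float, float, float]
    temperature: float = 310.15  # 37 °C

    def __post_init__(self) -> None:
        if len(self.lengths) != 3 or any(L <= 0 for L in self.lengths):
            raise ValueError(f"cell edges must be positive, got {self.lengths}")
        if self.temperature <= 0:
            raise ValueError(f"temperature must be positive, got {self.temperature}")

    @property
    def volume(self) -> float:
        """Cell volume in Å³."""
        lx, ly, lz = self.lengths
        return lx * ly * lz

    @property
    def edges(self) -> np.ndarray:
        return np.asarray(self.lengths, dtype=float)

    @classmethod
    def cubic(cls, edge: float, temperature: float = 310.15) -> "SimulationCell":
        return cls((edge, edge, edge), temperature)


@dataclass
class Molecule:
    """An ordered group of atoms forming one molecule."""

    species: str
    atom_ids: np.ndarray  # 0-based atom indices, ordered
    kind: str = "metabolite"  # protein | metabolite | ion | water
    charge: float | None = None  # net charge in e; validated against atoms

    def __post_init__(self) -> None:
        self.atom_ids = np.asarray(self.atom_ids, dtype=np.intp)
        if self.atom_ids.size == 0:
            raise ValueError(f"molecule {self.species!r} has no atoms")
        if self.kind not in MOLECULE_KINDS:
            raise ValueError(f"unknown molecule kind {self.kind!r}")

    @property
    def n_atoms(self) -> int:
        return int(self.atom_ids.size)


class Topology:
    """Atoms (element, radius, partial charge) grouped into molecules.

    Invariants enforced at construction: every atom belongs to exactly one
    molecule, radii are positive, and each molecule's declared net charge
    matches the sum of its atomic partial charges to 1e-6 e.
    """

    def __init__(
        self,
        elements,
        radii,
        charges,
        molecules: list[Molecule],
        resids=None,
        resnames=None,
        masses=None,
    ):
        self.elements = np.asarray(elements, dtype=object)
        self.radii = np.asarray(radii, dtype=float)
        self.charges = np.asarray(charges, dtype=float)
        self.molecules = list(molecules)
        n = self.elements.size
        if not (self.radii.size == n and self.charges.size == n):
            raise ValueError("elements, radii and charges must have equal length")
        if np.any(self.radii <= 0):
            bad = int(np.argmax(self.radii <= 0))
            raise ValueError(f"non-positive radius for atom {bad}")

        seen = np.zeros(n, dtype=np.int64)
        for mol in self.molecules:
            if np.any(mol.atom_ids < 0) or np.any(mol.atom_ids >= n):
                raise ValueError(f"molecule {mol.species!r} references absent atoms")
            seen[mol.atom_ids] += 1
        if np.any(seen != 1):
            bad = int(np.argmax(seen != 1))
            raise ValueError(
                f"atom {bad} belongs to {seen[bad]} molecules (must be exactly 1)"
            )

        for mol in self.molecules:
            q_atoms = float(self.charges[mol.atom_ids].sum())
            if mol.charge is None:
                mol.charge = q_atoms
            elif abs(mol.charge - q_atoms) > 1e-6:
                raise ValueError(
                    f"molecule {mol.species!r}: declared charge {mol.charge} "
                    f"differs from atomic sum {q_atoms:.8f} by more than 1e-6 e"
                )

        self.resids = None if resids is None else np.asarray(resids, dtype=np.intp)
        self.resnames = (
            None if resnames is None else np.asarray(resnames, dtype=object)
        )
        if masses is not None:
            self.masses = np.asarray(masses, dtype=float)
        else:
            self.masses = np.array(
                [ATOMIC_MASSES.get(str(e).upper(), _DEFAULT_MASS) for e in self.elements],
                dtype=float,
            )
        # atom -> molecule lookup
        self.mol_index = np.empty(n, dtype=np.intp)
        for i, mol in enumerate(self.molecules):
            self.mol_index[mol.atom_ids] = i

    @property
    def n_atoms(self) -> int:
        return int(self.elements.size)

    @property
    def n_molecules(self) -> int:
        return len(self.molecules)

    def molecule_charges(self) -> np.ndarray:
        """Net charge per molecule in e."""
        return np.array([m.charge for m in self.molecules], dtype=float)

    def select(self, kind: str) -> list[int]:
        """Indices of molecules of the given kind."""
        return [i for i, m in enumerate(self.molecules) if m.kind == kind]

    def non_water(self) -> list[int]:
        return [i for i, m in enumerate(self.molecules) if m.kind != "water"]

    def com(self, coords: np.ndarray, mol: int | Molecule) -> np.ndarray:
        """Mass-weighted center of a molecule for one frame of coordinates."""
        if isinstance(mol, int):
            mol = self.molecules[mol]
        w = self.masses[mol.atom_ids]
        return (coords[mol.atom_ids] * w[:, None]).sum(axis=0) / w.sum()


def wrap_coordinates(coords: np.ndarray, edges: np.ndarray) -> np.ndarray:
    """Wrap coordinates into the primary cell [0, L) per component."""
    edges = np.asarray(edges, dtype=float)
    return coords - edges * np.floor(coords / edges)


class Trajectory:
    """Uniformly sampled frames of wrapped coordinates with per-frame cells.

    Per-frame cells accommodate barostat volume fluctuations; prefactors that
    need a single volume use the mean cell volume.
    """

    def __init__(
        self,
        times: np.ndarray,
        coords: np.ndarray,
        cells: SimulationCell | list[SimulationCell],
        unwrapped: np.ndarray | None = None,
    ):
        self.times = np.asarray(times, dtype=float)
        self.coords = np.asarray(coords, dtype=float)
        if self.coords.ndim != 3 or self.coords.shape[2] != 3:
            raise ValueError("coords must have shape (n_frames, n_atoms, 3)")
        if self.times.size != self.coords.shape[0]:
            raise ValueError("times and coords disagree on frame count")
        if self.times.size < 2:
            raise ValueError("a trajectory needs at least 2 frames")
        dts = np.diff(self.times)
        if np.any(dts <= 0):
            raise ValueError("frame times must be strictly increasing")
        if not np.allclose(dts, dts[0], rtol=1e-9, atol=1e-9):
            bad = np.nonzero(~np.isclose(dts, dts[0], rtol=1e-9, atol=1e-9))[0]
            raise ValueError(
                f"non-uniform frame spacing at frame transitions {bad.tolist()}"
            )
        if isinstance(cells, SimulationCell):
            cells = [cells] * self.n_frames
        self.cells = list(cells)
        if len(self.cells) != self.n_frames:
            raise ValueError("one cell per frame required")
        self._unwrapped = unwrapped

    @property
    def n_frames(self) -> int:
        return int(self.times.size)

    @property
    def n_atoms(self) -> int:
        return int(self.coords.shape[1])

    @property
    def dt(self) -> float:
        return float(self.times[1] - self.times[0])

    @property
    def mean_volume(self) -> float:
        """Mean cell volume in Å³ (barostat-aware prefactor volume)."""
        return float(np.mean([c.volume for c in self.cells]))

    @property
    def temperature(self) -> float:
        return self.cells[0].temperature

    @property
    def unwrapped(self) -> np.ndarray:
        """Unwrapped coordinates; computed lazily via :func:`unwrap`."""
        if self._unwrapped is None:
            self._unwrapped = _unwrap_coords(self)
        return self._unwrapped

    def rewrapped(self) -> np.ndarray:
        """Wrap the unwrapped coordinates back into each frame's cell."""
        out = np.empty_like(self.unwrapped)
        for f in range(self.n_frames):
            out[f] = wrap_coordinates(self.unwrapped[f], self.cells[f].edges)
        return out


def _unwrap_coords(traj: Trajectory) -> np.ndarray:
    """Minimum-image unwrapping of a wrapped trajectory.

    Assumes the sampling cadence is fine enough that no atom moves half a
    cell edge between stored frames; successive unwrapped displacements are
    then strictly below half an edge per component by construction.
    """
    out = np.empty_like(traj.coords)
    out[0] = traj.coords[0]
    for f in range(1, traj.n_frames):
        edges = traj.cells[f].edges
        disp = traj.coords[f] - traj.coords[f - 1]
        disp -= edges * np.round(disp / edges)
        out[f] = out[f - 1] + disp
    return out


def unwrap(traj: Trajectory) -> Trajectory:
    """Return a trajectory whose unwrapped coordinates are materialized.

    Re-wrapping the result recovers the input wrapped coordinates exactly
    (up to floating-point wrap of atoms sitting on a boundary).
    """
    return Trajectory(
        traj.times, traj.coords, traj.cells, unwrapped=_unwrap_coords(traj)
    )
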