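"""Synthetic trajectories and configurations with known ground truth.

Every estimator in the package is validated against data generated here:
ideal Brownian particles (known diffusion coefficients, and — for charged
species — an exactly known Nernst–Einstein conductivity), rigid rotating
dipoles with a known stationary orientation distribution, hand-built
clustered configurations for contact/NIMS detection, and verbatim contact
timelines for event statistics.  All generators are deterministic under a
fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .constants import SIGMA_PREFACTOR
from .model import Molecule, SimulationCell, Topology, Trajectory, wrap_coordinates

__all__ = [
    "BrownianSpec",
    "BrownianSystem",
    "gen_brownian",
    "DipoleGasSpec",
    "DipoleGas",
    "gen_dipole_gas",
    "gen_cluster_config",
    "gen_contact_timeline",
    "nernst_einstein_sigma",
]


@dataclass
class BrownianSpec:
    """Ideal (non-interacting) Brownian particle gas.

    Each coordinate increment per frame is Gaussian with mean 0 and variance
    2·D·dt; particles are independent.  Charged species make the system an
    ideal charge gas whose conductivity is exactly Nernst–Einstein.
    """

    counts: dict[str, int]
    diffusion: dict[str, float]  # D_true per species, Å²/ps
    charges: dict[str, float] = field(default_factory=dict)  # e per species
    cell: SimulationCell = field(default_factory=lambda: SimulationCell.cubic(50.0))
    dt: float = 4.0  # ps
    n_frames: int = 1000
    seed: int = 0
    radius: float = 2.0  # Å, per-atom radius used in the topology

    def __post_init__(self) -> None:
        if self.n_frames < 2:
            raise ValueError("n_frames must be ≥ 2")
        for sp, D in self.diffusion.items():
            if D < 0:
                raise ValueError(f"{sp}: D_true must be ≥ 0")


@dataclass
class BrownianSystem:
    trajectory: Trajectory
    topology: Topology
    ground_truth: np.ndarray  # raw unwrapped paths (n_frames, N, 3)
    D_per_molecule: np.ndarray  # (N,)
    spec: BrownianSpec


def gen_brownian(spec: BrownianSpec) -> BrownianSystem:
    """Generate an ideal Brownian gas trajectory (wrapped + ground truth)."""
    rng = np.random.default_rng(spec.seed)
    species: list[str] = []
    D_mol: list[float] = []
    q_mol: list[float] = []
    for name, n in spec.counts.items():
        species.extend([name] * int(n))
        D_mol.extend([spec.diffusion[name]] * int(n))
        q_mol.extend([spec.charges.get(name, 0.0)] * int(n))
    N = len(species)
    D_arr = np.asarray(D_mol)
    edges = spec.cell.edges

    x0 = rng.uniform(0.0, edges, size=(N, 3))
    sigma = np.sqrt(2.0 * D_arr * spec.dt)  # per-dimension step SD
    steps = rng.standard_normal((spec.n_frames - 1, N, 3)) * sigma[None, :, None]
    unwrapped = np.empty((spec.n_frames, N, 3))
    unwrapped[0] = x0
    np.cumsum(steps, axis=0, out=unwrapped[1:])
    unwrapped[1:] += x0

    wrapped = wrap_coordinates(unwrapped, edges)
    times = np.arange(spec.n_frames) * spec.dt
    traj = Trajectory(times, wrapped, spec.cell)

    molecules = [
        Molecule(sp, np.array([i]), kind="ion" if q_mol[i] else "metabolite")
        for i, sp in enumerate(species)
    ]
    topo = Topology(
        elements=["C"] * N,
        radii=[spec.radius] * N,
        charges=q_mol,
        molecules=molecules,
    )
    return BrownianSystem(traj, topo, unwrapped, D_arr, spec)


def nernst_einstein_sigma(charges, diffusion, volume: float, temperature: float) -> float:
    """σ = Σ qᵢ²·Dᵢ / (V·k_B·T) in S/m — exact for non-interacting carriers.

    ``charges`` in e, ``diffusion`` in Å²/ps, ``volume`` in Å³.
    """
    q = np.asarray(charges, dtype=float)
    D = np.asarray(diffusion, dtype=float)
    return SIGMA_PREFACTOR * float((q * q * D).sum()) / (volume * temperature)


@dataclass
class DipoleGasSpec:
    """Gas of N rigid point dipoles of magnitude μ (e·Å).

    The null rotational update resamples each orientation uniformly on the
    sphere every frame (no angular autocorrelation): sufficient for the
    static-dielectric oracle, which depends only on the stationary
    distribution.  ``frozen=True`` keeps the initial orientations for all
    frames (zero-variance degenerate case).
    """

    n_dipoles: int
    mu: float  # e·Å
    cell: SimulationCell = field(default_factory=lambda: SimulationCell.cubic(50.0))
    n_frames: int = 1000
    seed: int = 0
    frozen: bool = False

    def __post_init__(self) -> None:
        if self.mu < 0:
            raise ValueError("dipole magnitude must be ≥ 0")
        if self.n_dipoles < 1:
            raise ValueError("need at least one dipole")


@dataclass
class DipoleGas:
    dipoles: np.ndarray  # (n_frames, N, 3) molecular dipole vectors, e·Å
    spec: DipoleGasSpec

    @property
    def M_D(self) -> np.ndarray:
        """System rotational dipole per frame (n_frames, 3)."""
        return self.dipoles.sum(axis=1)


def _uniform_sphere(rng: np.random.Generator, shape) -> np.ndarray:
    v = rng.standard_normal((*shape, 3))
    return v / np.linalg.norm(v, axis=-1, keepdims=True)


def gen_dipole_gas(spec: DipoleGasSpec) -> DipoleGas:
    rng = np.random.default_rng(spec.seed)
    if spec.frozen:
        u = _uniform_sphere(rng, (spec.n_dipoles,))
        dip = np.broadcast_to(u, (spec.n_frames, spec.n_dipoles, 3)).copy()
    else:
        dip = _uniform_sphere(rng, (spec.n_frames, spec.n_dipoles))
    return DipoleGas(dip * spec.mu, spec)


def gen_cluster_config(
    sizes,
    separation: float,
    spacing: float = 3.0,
    radius: float = 1.9,
    cell: SimulationCell | None = None,
    protein_clusters=(),
):
    """Hand-built clustered configuration of single-atom molecules.

    Clusters of the given sizes are laid out on a coarse grid with centers
    ``separation`` Å apart; members of a cluster sit on a circle so that
    neighbours are ``spacing`` Å apart (well inside contact range when
    ``spacing`` < the contact cutoff).  Molecules in ``protein_clusters``
    (cluster indices) are flagged protein.  Returns
    ``(topology, coords, clusters)`` where ``clusters`` is the ground-truth
    list of molecule-index lists.
    """
    sizes = list(sizes)
    n_clusters = len(sizes)
    if cell is None:
        edge = max(separation * (n_clusters + 1), 4 * separation, 30.0)
        cell = SimulationCell.cubic(edge)

    coords = []
    clusters = []
    molecules = []
    mol_id = 0
    for c, k in enumerate(sizes):
        center = np.array([separation * (c + 0.5), cell.lengths[1] / 2,
                           cell.lengths[2] / 2])
        members = []
        if k == 1:
            pts = [center]
        else:
            rho = spacing / (2.0 * np.sin(np.pi / k))
            ang = 2.0 * np.pi * np.arange(k) / k
            pts = center + rho * np.stack(
                [np.cos(ang), np.sin(ang), np.zeros(k)], axis=1
            )
        for p in pts:
            coords.append(p)
            kind = "protein" if c in protein_clusters else "metabolite"
            molecules.append(Molecule(f"C{c}", np.array([mol_id]), kind=kind))
            members.append(mol_id)
            mol_id += 1
        clusters.append(members)

    coords = np.asarray(coords, dtype=float)
    topo = Topology(
        elements=["C"] * mol_id,
        radii=[radius] * mol_id,
        charges=[0.0] * mol_id,
        molecules=molecules,
    )
    return topo, coords, clusters


def gen_contact_timeline(values, dt: float = 4.0, threshold: float = 0.48):
    """Wrap a hand-specified excluded-area series into a ContactSeries."""
    from .sasa_contact import ContactSeries

    values = np.asarray(values, dtype=float)
    if values.size == 0:
        raise ValueError("a contact timeline needs at least one frame")
    return ContactSeries(
        values=values.reshape(-1, 1),
        molecule_ids=[0],
        dt=dt,
        threshold=threshold,
    )
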