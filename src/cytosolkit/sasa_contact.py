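"""Solvent-accessible surface areas, contact areas and contact statistics.

SASA is computed by Shrake–Rupley point sampling: a deterministic Fibonacci
lattice of test points is placed on each atom's solvent-accessible sphere
(radius + probe) and a point counts as accessible unless it falls inside
the accessible sphere of an occluding atom from the chosen context.  The
occluder context is an explicit atom selection, which is what the contact
analyses need: the excluded (contact) area of a molecule is its SASA in
isolation minus its SASA inside the non-water environment.

Contact in time is the strict criterion ``excluded area > 0.48 Ų`` (the
average excluded area observed when two hydrogen bonds are present);
maximal runs of contact frames are contact events and maximal runs of
non-contact frames are full-solvation events.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .model import Topology, Trajectory

__all__ = [
    "SASAResult",
    "ContactSeries",
    "ContactStats",
    "fibonacci_sphere",
    "compute_sasa",
    "molecule_sasa",
    "contact_area_series",
    "contact_stats",
    "residue_contact_profile",
    "total_sasa_trace",
    "magnesium_ionic_bonds",
]

DEFAULT_PROBE = 1.4  # Å, water-sized probe
DEFAULT_POINTS = 960
CONTACT_THRESHOLD = 0.48  # Ų


def fibonacci_sphere(n: int) -> np.ndarray:
    """Deterministic, nearly uniform unit-sphere point set (n, 3)."""
    i = np.arange(n, dtype=float) + 0.5
    phi = np.pi * (3.0 - np.sqrt(5.0)) * i
    z = 1.0 - 2.0 * i / n
    r = np.sqrt(np.maximum(0.0, 1.0 - z * z))
    return np.stack([r * np.cos(phi), r * np.sin(phi), z], axis=1)


@dataclass
class SASAResult:
    areas: np.ndarray  # Ų per target atom
    context: str  # "isolated" | "in_environment"
    probe: float
    n_points: int

    @property
    def total(self) -> float:
        return float(self.areas.sum())


def compute_sasa(coords: np.ndarray, radii: np.ndarray,
                 probe: float = DEFAULT_PROBE,
                 targets=None, context=None,
                 n_points: int = DEFAULT_POINTS,
                 edges: np.ndarray | None = None,
                 context_label: str = "isolated") -> SASAResult:
    """Per-atom SASA of ``targets`` occluded by ``context`` atoms only.

    ``targets`` defaults to all atoms and ``context`` to the targets
    themselves.  With ``edges`` given, occlusion uses the minimum-image
    convention in an orthorhombic cell.  Converges to the analytic sphere
    (union) area as ``n_points`` grows; at the default resolution a single
    atom is within ~0.1% of 4π(r+probe)².
    """
    coords = np.asarray(coords, dtype=float)
    radii = np.asarray(radii, dtype=float)
    if probe < 0:
        raise ValueError("probe radius must be ≥ 0")
    if np.any(radii <= 0):
        raise ValueError("atomic radii must be positive")
    targets = np.arange(len(coords)) if targets is None else np.asarray(targets)
    if targets.size == 0:
        raise ValueError("empty target selection")
    context = targets if context is None else np.asarray(context)

    sphere = fibonacci_sphere(n_points)
    acc_r = radii + probe  # accessible-sphere radii
    areas = np.empty(targets.size)
    ctx_coords = coords[context]
    ctx_r = acc_r[context]
    for k, t in enumerate(targets):
        rt = acc_r[t]
        # occluders: context atoms (other than t) whose accessible spheres
        # can intersect t's accessible sphere
        delta = ctx_coords - coords[t]
        if edges is not None:
            delta = delta - edges * np.round(delta / edges)
        d2 = np.einsum("ij,ij->i", delta, delta)
        reach = ctx_r + rt
        near = (d2 < reach * reach) & (d2 > 1e-12)
        if targets.size and context.size:
            near &= context != t
        if not np.any(near):
            areas[k] = 4.0 * np.pi * rt * rt
            continue
        occ_c = delta[near]
        occ_r2 = ctx_r[near] ** 2
        pts = sphere * rt  # test points relative to atom t center
        # point is buried if within any occluder's accessible sphere
        diff = pts[:, None, :] - occ_c[None, :, :]
        buried = np.any(
            np.einsum("pij,pij->pi", diff, diff) < occ_r2[None, :], axis=1
        )
        frac = 1.0 - buried.mean()
        areas[k] = frac * 4.0 * np.pi * rt * rt
    return SASAResult(areas, context_label, probe, n_points)


def molecule_sasa(coords: np.ndarray, topology: Topology, molecule: int,
                  environment=None, probe: float = DEFAULT_PROBE,
                  n_points: int = DEFAULT_POINTS,
                  edges: np.ndarray | None = None) -> float:
    """Total SASA (Ų) of one molecule, occluded by itself + ``environment``
    molecules (indices).  ``environment=None`` means isolated."""
    mol = topology.molecules[molecule]
    targets = mol.atom_ids
    if environment:
        env_ids = np.concatenate(
            [topology.molecules[m].atom_ids for m in environment]
        )
        if np.intersect1d(env_ids, targets).size:
            raise ValueError("target molecule intersects environment selection")
        context = np.concatenate([targets, env_ids])
        label = "in_environment"
    else:
        context = targets
        label = "isolated"
    return compute_sasa(coords, topology.radii, probe, targets, context,
                        n_points, edges, label).total


@dataclass
class ContactSeries:
    """Per-frame excluded (contact) areas, one column per tracked molecule."""

    values: np.ndarray  # (n_frames, n_molecules) Ų
    molecule_ids: list[int]
    dt: float  # ps
    threshold: float = CONTACT_THRESHOLD
    isolated_mean: np.ndarray | None = None  # Ų per molecule

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be (n_frames, n_molecules)")
        if self.values.size == 0:
            raise ValueError("empty contact series")
        if self.threshold <= 0:
            raise ValueError("contact threshold must be positive")

    @property
    def n_frames(self) -> int:
        return self.values.shape[0]

    def column(self, molecule_id: int) -> np.ndarray:
        return self.values[:, self.molecule_ids.index(molecule_id)]


@dataclass
class ContactStats:
    percent_in_contact: float
    contact_events: list[tuple[int, int]]  # (start frame, length in frames)
    solvation_events: list[tuple[int, int]]
    mean_contact_ps: float
    max_contact_ps: float
    mean_solvation_ps: float
    max_solvation_ps: float


def _runs(mask: np.ndarray) -> list[tuple[int, int]]:
    """Maximal runs of True as (start, length)."""
    out = []
    n = mask.size
    i = 0
    while i < n:
        if mask[i]:
            j = i
            while j < n and mask[j]:
                j += 1
            out.append((i, j - i))
            i = j
        else:
            i += 1
    return out


def contact_stats(series, dt: float | None = None,
                  threshold: float | None = None) -> ContactStats:
    """Event statistics of a single-molecule excluded-area timeline.

    A frame is in contact iff its excluded area strictly exceeds the
    threshold; contact and full-solvation events are the maximal runs of
    contact and non-contact frames, so their lengths tile the frame axis.
    """
    if isinstance(series, ContactSeries):
        if series.values.shape[1] != 1:
            raise ValueError("pass a single-molecule series (one column)")
        values = series.values[:, 0]
        dt = series.dt if dt is None else dt
        threshold = series.threshold if threshold is None else threshold
    else:
        values = np.asarray(series, dtype=float)
        if dt is None or threshold is None:
            raise ValueError("dt and threshold required for a bare array")
    if values.size == 0:
        raise ValueError("empty contact series")

    in_contact = values > threshold  # strict: exactly at threshold is free
    contact_ev = _runs(in_contact)
    solv_ev = _runs(~in_contact)
    c_len = np.array([l for _, l in contact_ev], dtype=float)
    s_len = np.array([l for _, l in solv_ev], dtype=float)
    return ContactStats(
        percent_in_contact=100.0 * in_contact.mean(),
        contact_events=contact_ev,
        solvation_events=solv_ev,
        mean_contact_ps=float(c_len.mean() * dt) if c_len.size else 0.0,
        max_contact_ps=float(c_len.max() * dt) if c_len.size else 0.0,
        mean_solvation_ps=float(s_len.mean() * dt) if s_len.size else 0.0,
        max_solvation_ps=float(s_len.max() * dt) if s_len.size else 0.0,
    )


def contact_area_series(traj: Trajectory, topology: Topology,
                        targets=None, probe: float = DEFAULT_PROBE,
                        n_points: int = DEFAULT_POINTS,
                        threshold: float = CONTACT_THRESHOLD) -> ContactSeries:
    """Excluded area per frame for each target molecule.

    Excluded area = SASA(isolated) − SASA(in the non-water environment);
    the environment of a molecule is every other non-water molecule.
    """
    non_water = topology.non_water()
    if targets is None:
        targets = non_water
    if not targets:
        raise ValueError("no target molecules")
    n_frames = traj.n_frames
    values = np.empty((n_frames, len(targets)))
    iso_sum = np.zeros(len(targets))
    for f in range(n_frames):
        coords = traj.coords[f]
        edges = traj.cells[f].edges
        for j, m in enumerate(targets):
            env = [k for k in non_water if k != m]
            iso = molecule_sasa(coords, topology, m, None, probe, n_points,
                                edges)
            inenv = molecule_sasa(coords, topology, m, env, probe, n_points,
                                  edges)
            values[f, j] = max(0.0, iso - inenv)
            iso_sum[j] += iso
    return ContactSeries(values, list(targets), traj.dt, threshold,
                         isolated_mean=iso_sum / n_frames)


def contact_summary(series: ContactSeries) -> pd.DataFrame:
    """Per-molecule average contact area, percent contact area and percent
    contact time (the per-metabolite contact table)."""
    rows = []
    for j, m in enumerate(series.molecule_ids):
        stats = contact_stats(series.values[:, j], series.dt, series.threshold)
        avg_excl = float(series.values[:, j].mean())
        iso = (float(series.isolated_mean[j])
               if series.isolated_mean is not None else np.nan)
        rows.append({
            "molecule": m,
            "avg_contact_area_A2": avg_excl,
            "percent_contact_area": 100.0 * avg_excl / iso if iso else np.nan,
            "percent_contact_time": stats.percent_in_contact,
        })
    return pd.DataFrame(rows)


def residue_contact_profile(traj: Trajectory, topology: Topology,
                            protein: int, probe: float = DEFAULT_PROBE,
                            n_points: int = DEFAULT_POINTS) -> pd.DataFrame:
    """Per-residue percent contact area of a protein, ranked descending.

    Residue contact area = SASA without the environment − SASA with the
    environment, reported as a percentage of the average SASA without the
    environment.  The environment here is the metabolites (not other
    protein copies, ions or water).
    """
    mol = topology.molecules[protein]
    if mol.kind != "protein":
        raise ValueError(f"molecule {protein} is not flagged protein")
    if topology.resids is None:
        raise ValueError("topology has no residue grouping")
    res_of = topology.resids[mol.atom_ids]
    resnames = (topology.resnames[mol.atom_ids]
                if topology.resnames is not None else res_of.astype(str))
    unique_res = list(dict.fromkeys(res_of.tolist()))

    env_ids = [k for k, m in enumerate(topology.molecules)
               if m.kind == "metabolite"]
    env_atoms = (np.concatenate([topology.molecules[k].atom_ids
                                 for k in env_ids])
                 if env_ids else np.array([], dtype=np.intp))

    iso_sum = {r: 0.0 for r in unique_res}
    env_sum = {r: 0.0 for r in unique_res}
    for f in range(traj.n_frames):
        coords = traj.coords[f]
        edges = traj.cells[f].edges
        iso = compute_sasa(coords, topology.radii, probe, mol.atom_ids,
                           mol.atom_ids, n_points, edges)
        ctx = np.concatenate([mol.atom_ids, env_atoms])
        inenv = compute_sasa(coords, topology.radii, probe, mol.atom_ids,
                             ctx, n_points, edges, "in_environment")
        for a, ai, ae in zip(mol.atom_ids, iso.areas, inenv.areas):
            r = topology.resids[a]
            iso_sum[r] += ai
            env_sum[r] += ae
    rows = []
    name_of = {r: n for r, n in zip(res_of, resnames)}
    for r in unique_res:
        iso_avg = iso_sum[r] / traj.n_frames
        excl_avg = (iso_sum[r] - env_sum[r]) / traj.n_frames
        pct = 100.0 * excl_avg / iso_avg if iso_avg > 0 else 0.0
        rows.append({"resid": int(r), "resname": str(name_of[r]),
                     "percent_contact_area": max(0.0, pct)})
    df = pd.DataFrame(rows).sort_values(
        "percent_contact_area", ascending=False, kind="stable"
    )
    return df.reset_index(drop=True)


@dataclass
class SASATrace:
    times: np.ndarray  # ps
    total: np.ndarray  # Ų per frame
    running_average: np.ndarray  # Ų, trailing window
    percent_loss: float  # initial running average → final plateau


def total_sasa_trace(traj: Trajectory, topology: Topology,
                     probe: float = DEFAULT_PROBE,
                     n_points: int = DEFAULT_POINTS,
                     window_ps: float = 2000.0) -> SASATrace:
    """Per-frame total non-water SASA with a running average and percent loss.

    Percent loss compares the running average at the start of the trace with
    the equilibrated plateau at its end (how much surface disappears as the
    initially spaced molecules collapse into clusters).
    """
    non_water = topology.non_water()
    atoms = np.concatenate([topology.molecules[m].atom_ids for m in non_water])
    total = np.empty(traj.n_frames)
    for f in range(traj.n_frames):
        res = compute_sasa(traj.coords[f], topology.radii, probe, atoms,
                           atoms, n_points, traj.cells[f].edges,
                           "in_environment")
        total[f] = res.total
    return _trace_from_totals(traj.times, total, traj.dt, window_ps)


def _trace_from_totals(times, total, dt, window_ps) -> SASATrace:
    total = np.asarray(total, dtype=float)
    w = max(1, min(int(round(window_ps / dt)), total.size))
    kernel = np.ones(w) / w
    ra = np.convolve(total, kernel, mode="valid")  # trailing average
    start, end = ra[0], ra[-1]
    loss = 100.0 * (start - end) / start if start > 0 else 0.0
    return SASATrace(np.asarray(times), total, ra, loss)


def magnesium_ionic_bonds(coords: np.ndarray, topology: Topology,
                          edges: np.ndarray | None = None,
                          cutoff: float = 3.0,
                          min_partial_charge: float = -0.3) -> dict[int, int]:
    """Count Mg²⁺ 'ionic bonds' per Mg ion via a distance criterion.

    Operational definition (a geometric stand-in for coordination): an ionic
    bond is an O or N atom of a charged group (partial charge ≤
    ``min_partial_charge`` e) within ``cutoff`` Å of the Mg center.
    """
    mg_mols = [i for i, m in enumerate(topology.molecules)
               if m.species.upper().startswith("MG")]
    donors = np.array([
        a for a in range(topology.n_atoms)
        if str(topology.elements[a]).upper() in ("O", "N")
        and topology.charges[a] <= min_partial_charge
    ], dtype=np.intp)
    out: dict[int, int] = {}
    for i in mg_mols:
        center = coords[topology.molecules[i].atom_ids[0]]
        if donors.size == 0:
            out[i] = 0
            continue
        delta = coords[donors] - center
        if edges is not None:
            delta = delta - edges * np.round(delta / edges)
        d2 = np.einsum("ij,ij->i", delta, delta)
        out[i] = int(np.count_nonzero(d2 <= cutoff * cutoff))
    return out
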