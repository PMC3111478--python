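"""Non-covalently interacting metabolite structures (NIMS).

Transient clusters of metabolites — held together by hydrogen bonds, ionic
contacts and π-stacking — are operationalized as connected components of a
per-frame contact graph over the non-water molecules.  Edges come either
from the pairwise excluded-SASA criterion (> 0.48 Ų, the same threshold as
the contact-time analysis) or from a cheap minimum-image distance screen
(any interatomic distance below a cutoff, 4.0 Å by default); the distance
graph is a superset of the SASA graph at matched scales.  Components are
tracked across frames by maximal member overlap, and ring geometry flags
π-stacked pairs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

from .model import Topology, Trajectory
from .sasa_contact import CONTACT_THRESHOLD, DEFAULT_POINTS, DEFAULT_PROBE, compute_sasa

__all__ = [
    "contact_graph",
    "ComponentTrack",
    "components_and_tracks",
    "pi_stack_flags",
]

DEFAULT_DISTANCE_CUTOFF = 4.0  # Å


def _pair_min_dist2(coords_a, coords_b, edges):
    delta = coords_a[:, None, :] - coords_b[None, :, :]
    if edges is not None:
        delta = delta - edges * np.round(delta / edges)
    return float(np.min(np.einsum("ijk,ijk->ij", delta, delta)))


def _pair_excluded_area(coords, topology, i, j, edges, probe, n_points):
    """Symmetrized pairwise excluded SASA of molecules i and j (Ų)."""
    ids_i = topology.molecules[i].atom_ids
    ids_j = topology.molecules[j].atom_ids
    both = np.concatenate([ids_i, ids_j])
    excl = 0.0
    for tgt in (ids_i, ids_j):
        iso = compute_sasa(coords, topology.radii, probe, tgt, tgt,
                           n_points, edges).total
        env = compute_sasa(coords, topology.radii, probe, tgt, both,
                           n_points, edges, "in_environment").total
        excl += max(0.0, iso - env)
    return excl / 2.0


def contact_graph(coords: np.ndarray, topology: Topology,
                  edges: np.ndarray | None = None,
                  mode: str = "distance",
                  cutoff: float = DEFAULT_DISTANCE_CUTOFF,
                  threshold: float = CONTACT_THRESHOLD,
                  probe: float = DEFAULT_PROBE,
                  n_points: int = DEFAULT_POINTS,
                  molecules=None) -> nx.Graph:
    """Per-frame contact graph over non-water molecules.

    ``distance`` mode: an edge when any interatomic minimum-image distance
    is below ``cutoff``.  ``sasa`` mode: an edge when the pairwise excluded
    SASA exceeds ``threshold`` (a distance pre-screen at the occlusion reach
    keeps this affordable).
    """
    if mode not in ("distance", "sasa"):
        raise ValueError(f"unknown contact-graph mode {mode!r}")
    if molecules is None:
        molecules = topology.non_water()
    g = nx.Graph()
    g.add_nodes_from(molecules)
    r_max = float(topology.radii.max())
    screen = 2.0 * (r_max + probe) if mode == "sasa" else cutoff
    for a in range(len(molecules)):
        i = molecules[a]
        ci = coords[topology.molecules[i].atom_ids]
        for b in range(a + 1, len(molecules)):
            j = molecules[b]
            cj = coords[topology.molecules[j].atom_ids]
            d2 = _pair_min_dist2(ci, cj, edges)
            if d2 >= screen * screen:
                continue
            if mode == "distance":
                g.add_edge(i, j)
            else:
                area = _pair_excluded_area(coords, topology, i, j, edges,
                                           probe, n_points)
                if area > threshold:
                    g.add_edge(i, j)
    return g


@dataclass
class ComponentTrack:
    """One NIMS tracked through time by maximal member overlap."""

    track_id: int
    birth: int  # frame index
    members_per_frame: dict[int, frozenset] = field(default_factory=dict)
    death: int | None = None  # last frame alive (inclusive)

    def lifetime_ps(self, dt: float) -> float:
        last = self.death if self.death is not None else max(
            self.members_per_frame
        )
        return (last - self.birth) * dt

    def max_size(self) -> int:
        return max(len(m) for m in self.members_per_frame.values())


def _jaccard(a: frozenset, b: frozenset) -> float:
    return len(a & b) / len(a | b)


def components_and_tracks(traj: Trajectory, topology: Topology,
                          mode: str = "distance",
                          cutoff: float = DEFAULT_DISTANCE_CUTOFF,
                          threshold: float = CONTACT_THRESHOLD,
                          min_jaccard: float = 0.5):
    """Connected components per frame plus cross-frame identity tracks.

    A component in frame f continues the track whose previous-frame members
    overlap it most (Jaccard ≥ ``min_jaccard``; ties go to the older track);
    otherwise a new track is born.  Tracks carry protein-attachment (any
    protein member) and bridge (≥ 2 protein members) flags.  Returns
    ``(tracks, sizes)`` where ``sizes`` is a per-frame DataFrame of
    component sizes.
    """
    protein_mols = set(topology.select("protein"))
    tracks: list[ComponentTrack] = []
    active: dict[int, frozenset] = {}  # track_id -> members in previous frame
    size_rows = []
    for f in range(traj.n_frames):
        g = contact_graph(traj.coords[f], topology, traj.cells[f].edges,
                          mode=mode, cutoff=cutoff, threshold=threshold)
        comps = [frozenset(c) for c in nx.connected_components(g)]
        for c in comps:
            size_rows.append({"frame": f, "size": len(c)})
        assigned: dict[int, frozenset] = {}
        unmatched = []
        for comp in sorted(comps, key=lambda c: sorted(c)):
            best_id, best_j = None, 0.0
            for tid, prev in active.items():
                if tid in assigned:
                    continue
                jac = _jaccard(comp, prev)
                if jac > best_j or (jac == best_j and jac > 0
                                    and (best_id is None or tid < best_id)):
                    best_id, best_j = tid, jac
            if best_id is not None and best_j >= min_jaccard:
                assigned[best_id] = comp
                tracks[best_id].members_per_frame[f] = comp
            else:
                unmatched.append(comp)
        for tid, prev in active.items():
            if tid not in assigned:
                tracks[tid].death = f - 1
        for comp in unmatched:
            tid = len(tracks)
            t = ComponentTrack(tid, birth=f)
            t.members_per_frame[f] = comp
            tracks.append(t)
            assigned[tid] = comp
        active = assigned
    for tid in active:
        tracks[tid].death = traj.n_frames - 1
    for t in tracks:
        members_union = frozenset().union(*t.members_per_frame.values())
        t.protein_attached = bool(members_union & protein_mols)
        t.bridge = any(
            len(m & protein_mols) >= 2 for m in t.members_per_frame.values()
        )
    sizes = pd.DataFrame(size_rows)
    return tracks, sizes


def tracks_summary(tracks, dt: float) -> pd.DataFrame:
    rows = [{
        "track_id": t.track_id,
        "birth_frame": t.birth,
        "death_frame": t.death,
        "lifetime_ps": t.lifetime_ps(dt),
        "max_size": t.max_size(),
        "protein_attached": t.protein_attached,
        "bridge": t.bridge,
    } for t in tracks]
    return pd.DataFrame(rows)


def _ring_plane_normal(pts: np.ndarray) -> np.ndarray:
    centered = pts - pts.mean(axis=0)
    _, _, vt = np.linalg.svd(centered, full_matrices=False)
    return vt[-1]


def pi_stack_flags(coords: np.ndarray, rings: list[np.ndarray],
                   max_centroid_dist: float = 4.5,
                   max_angle_deg: float = 30.0,
                   edges: np.ndarray | None = None) -> list[tuple[int, int]]:
    """Flag π-stacked ring pairs by centroid distance and inter-plane angle.

    ``rings`` is a list of atom-index arrays (≥ 3 atoms each).  A pair is
    stacked when centroids are within ``max_centroid_dist`` Å and the planes
    are within ``max_angle_deg`` of parallel.
    """
    cents, normals = [], []
    for ring in rings:
        ring = np.asarray(ring, dtype=np.intp)
        if ring.size < 3:
            raise ValueError("a ring needs at least 3 atoms")
        if np.any(ring < 0) or np.any(ring >= len(coords)):
            raise ValueError("ring definition references absent atoms")
        pts = coords[ring]
        cents.append(pts.mean(axis=0))
        normals.append(_ring_plane_normal(pts))
    flags = []
    for i in range(len(rings)):
        for j in range(i + 1, len(rings)):
            delta = cents[i] - cents[j]
            if edges is not None:
                delta = delta - edges * np.round(delta / edges)
            if np.linalg.norm(delta) > max_centroid_dist:
                continue
            cosang = abs(float(np.dot(normals[i], normals[j])))
            angle = np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0)))
            if angle <= max_angle_deg:
                flags.append((i, j))
    return flags
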