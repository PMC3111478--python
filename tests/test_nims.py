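"""Contact graphs, NIMS component detection/tracking and π-stack geometry."""

import networkx as nx
import numpy as np
import pytest

from cytosolkit.model import Molecule, SimulationCell, Topology, Trajectory
from cytosolkit.nims import (
    components_and_tracks,
    contact_graph,
    pi_stack_flags,
    tracks_summary,
)
from cytosolkit.synthetic import gen_cluster_config


def brute_force_components(coords, topo, cutoff, edges=None):
    """Independent union-find over pairwise minimum-image atom distances."""
    n = topo.n_molecules
    parent = list(range(n))

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for i in range(n):
        ci = coords[topo.molecules[i].atom_ids]
        for j in range(i + 1, n):
            cj = coords[topo.molecules[j].atom_ids]
            d = ci[:, None, :] - cj[None, :, :]
            if edges is not None:
                d = d - edges * np.round(d / edges)
            if np.sqrt((d * d).sum(-1)).min() < cutoff:
                parent[find(i)] = find(j)
    comps = {}
    for i in range(n):
        comps.setdefault(find(i), set()).add(i)
    return sorted((sorted(c) for c in comps.values()), key=lambda c: c[0])


class TestContactGraph:
    def test_isolated_molecules_edgeless(self):
        topo, coords, _ = gen_cluster_config([1, 1, 1], separation=20.0)
        g = contact_graph(coords, topo, mode="distance", cutoff=4.0)
        assert g.number_of_edges() == 0
        assert g.number_of_nodes() == 3

    def test_trimer_chain_has_chain_edges_only(self):
        # A–B–C at 3.5 Å spacing along x: AB and BC touch, AC does not
        coords = np.array([[10.0, 10, 10], [13.5, 10, 10], [17.0, 10, 10]])
        mols = [Molecule(s, np.array([i])) for i, s in enumerate("ABC")]
        topo = Topology(["C"] * 3, [1.7] * 3, [0.0] * 3, mols)
        g = contact_graph(coords, topo, mode="distance", cutoff=4.0)
        assert sorted(g.edges()) == [(0, 1), (1, 2)]

    def test_unknown_mode_rejected(self):
        topo, coords, _ = gen_cluster_config([1], separation=10.0)
        with pytest.raises(ValueError, match="mode"):
            contact_graph(coords, topo, mode="psychic")

    def test_distance_graph_superset_of_sasa_graph(self, rng):
        """At matched scales the distance screen admits every SASA edge."""
        for trial in range(3):
            r = np.random.default_rng(trial)
            coords = r.uniform(10, 30, (8, 3))
            mols = [Molecule(f"m{i}", np.array([i])) for i in range(8)]
            topo = Topology(["C"] * 8, [1.7] * 8, [0.0] * 8, mols)
            g_d = contact_graph(coords, topo, mode="distance",
                                cutoff=2 * (1.7 + 1.4))
            g_s = contact_graph(coords, topo, mode="sasa")
            assert set(g_s.edges()) <= set(g_d.edges())

    def test_sasa_mode_detects_touching_pair(self):
        coords = np.array([[10.0, 10, 10], [13.0, 10, 10], [30.0, 30, 30]])
        mols = [Molecule(f"m{i}", np.array([i])) for i in range(3)]
        topo = Topology(["C"] * 3, [1.7] * 3, [0.0] * 3, mols)
        g = contact_graph(coords, topo, mode="sasa")
        assert sorted(g.edges()) == [(0, 1)]

    def test_periodic_edge_across_boundary(self):
        edges = np.full(3, 20.0)
        coords = np.array([[0.5, 10, 10], [19.5, 10, 10]])
        mols = [Molecule(f"m{i}", np.array([i])) for i in range(2)]
        topo = Topology(["C"] * 2, [1.7] * 2, [0.0] * 2, mols)
        g = contact_graph(coords, topo, edges=edges, mode="distance",
                          cutoff=4.0)
        assert g.has_edge(0, 1)


class TestComponents:
    def test_matches_brute_force_union_find(self):
        """Production components agree exactly with an independent
        union-find on ≤ 20-molecule fixtures."""
        for seed in range(5):
            r = np.random.default_rng(seed)
            n = 15
            coords = r.uniform(0, 30, (n, 3))
            mols = [Molecule(f"m{i}", np.array([i])) for i in range(n)]
            topo = Topology(["C"] * n, [1.7] * n, [0.0] * n, mols)
            edges = np.full(3, 30.0)
            g = contact_graph(coords, topo, edges=edges, mode="distance",
                              cutoff=5.0)
            mine = sorted((sorted(c) for c in nx.connected_components(g)),
                          key=lambda c: c[0])
            ref = brute_force_components(coords, topo, 5.0, edges)
            assert mine == ref

    def test_partition_covers_all_molecules(self):
        topo, coords, _ = gen_cluster_config([3, 2, 1], separation=20.0)
        g = contact_graph(coords, topo, mode="distance", cutoff=4.0)
        comps = list(nx.connected_components(g))
        all_mols = set().union(*comps)
        assert all_mols == set(range(topo.n_molecules))
        assert sum(len(c) for c in comps) == topo.n_molecules


def _static_traj(coords, n_frames=5, edge=80.0, dt=4.0):
    cell = SimulationCell.cubic(edge)
    return Trajectory(np.arange(n_frames) * dt,
                      np.repeat(coords[None], n_frames, axis=0), cell)


class TestTracks:
    def test_static_clusters_live_forever(self):
        topo, coords, clusters = gen_cluster_config([3, 2, 1],
                                                    separation=20.0)
        traj = _static_traj(coords)
        tracks, sizes = components_and_tracks(traj, topo)
        assert len(tracks) == 3
        df = tracks_summary(tracks, traj.dt)
        assert np.all(df.lifetime_ps == (traj.n_frames - 1) * traj.dt)
        assert sorted(df.max_size) == [1, 2, 3]
        per_frame = sizes.groupby("frame")["size"].apply(sorted)
        assert all(v == [1, 2, 3] for v in per_frame)

    def test_merge_inherits_larger_parent(self):
        # frames 0-1: clusters {0,1,2} and {3,4} apart; frame 2: merged
        topo, coords, _ = gen_cluster_config([3, 2], separation=25.0,
                                             spacing=3.0)
        apart = coords.copy()
        merged = coords.copy()
        merged[3:] -= np.array([21.0, 0.0, 0.0])  # bring pair next to trio
        frames = np.stack([apart, apart, merged])
        cell = SimulationCell.cubic(80.0)
        traj = Trajectory(np.arange(3) * 4.0, frames, cell)
        tracks, _ = components_and_tracks(traj, topo)
        # the merged 5-molecule component continues the size-3 track
        big = [t for t in tracks if t.max_size() == 5]
        assert len(big) == 1
        assert big[0].birth == 0
        assert len(big[0].members_per_frame[0]) == 3

    def test_all_singletons_no_multimolecule_nims(self):
        topo, coords, _ = gen_cluster_config([1] * 6, separation=15.0)
        traj = _static_traj(coords, edge=120.0)
        tracks, _ = components_and_tracks(traj, topo)
        assert all(t.max_size() == 1 for t in tracks)

    def test_protein_attachment_and_bridge_flags(self):
        # two protein singletons bridged by one metabolite in the middle
        coords = np.array([[10.0, 10, 10], [13.0, 10, 10], [16.0, 10, 10]])
        mols = [Molecule("p1", np.array([0]), kind="protein"),
                Molecule("met", np.array([1]), kind="metabolite"),
                Molecule("p2", np.array([2]), kind="protein")]
        topo = Topology(["C"] * 3, [1.7] * 3, [0.0] * 3, mols)
        traj = _static_traj(coords, edge=50.0)
        tracks, _ = components_and_tracks(traj, topo)
        assert len(tracks) == 1
        assert tracks[0].protein_attached
        assert tracks[0].bridge

    def test_lifetime_invariant_under_subsampling(self):
        topo, coords, _ = gen_cluster_config([2, 1], separation=20.0)
        cell = SimulationCell.cubic(80.0)
        n = 12
        frames = np.repeat(coords[None], n, axis=0)
        traj = Trajectory(np.arange(n) * 4.0, frames, cell)
        tracks_full, _ = components_and_tracks(traj, topo)
        sub = Trajectory(np.arange(0, n, 3) * 4.0, frames[::3], cell)
        tracks_sub, _ = components_and_tracks(sub, topo)
        for tf, ts in zip(tracks_full, tracks_sub):
            # equal up to ±1 subsampled frame of boundary quantization
            assert abs(tf.lifetime_ps(4.0) - ts.lifetime_ps(12.0)) <= 12.0


class TestPiStacking:
    def _ring(self, center, normal="z", r=1.4):
        ang = np.linspace(0, 2 * np.pi, 6, endpoint=False)
        flat = np.stack([r * np.cos(ang), r * np.sin(ang), np.zeros(6)], 1)
        if normal == "x":
            flat = flat[:, [2, 0, 1]]
        return flat + center

    def test_parallel_close_rings_flagged(self):
        pts = np.vstack([self._ring([0, 0, 0]), self._ring([0, 0, 3.5])])
        flags = pi_stack_flags(pts, [np.arange(6), np.arange(6, 12)])
        assert flags == [(0, 1)]

    def test_perpendicular_rings_not_flagged(self):
        pts = np.vstack([self._ring([0, 0, 0]),
                         self._ring([0, 0, 3.5], normal="x")])
        assert pi_stack_flags(pts, [np.arange(6), np.arange(6, 12)]) == []

    def test_coplanar_distant_rings_not_flagged(self):
        pts = np.vstack([self._ring([0, 0, 0]), self._ring([10, 0, 0])])
        assert pi_stack_flags(pts, [np.arange(6), np.arange(6, 12)]) == []

    def test_absent_atoms_rejected(self):
        pts = self._ring([0, 0, 0])
        with pytest.raises(ValueError, match="absent"):
            pi_stack_flags(pts, [np.arange(6), np.arange(6, 12)])
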