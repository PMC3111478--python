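"""SASA closed forms, contact areas, event statistics and contact profiles."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cytosolkit.model import Molecule, SimulationCell, Topology, Trajectory
from cytosolkit.sasa_contact import (
    _trace_from_totals,
    compute_sasa,
    contact_area_series,
    contact_stats,
    contact_summary,
    magnesium_ionic_bonds,
    molecule_sasa,
    residue_contact_profile,
    total_sasa_trace,
)
from cytosolkit.synthetic import gen_contact_timeline

PROBE = 1.4


def sphere_area(r):
    return 4.0 * np.pi * r * r


def two_sphere_union_area(R1, R2, d):
    """Closed-form exposed area of two overlapping accessible spheres."""
    if d >= R1 + R2:
        return sphere_area(R1) + sphere_area(R2)
    h1 = R1 - (d * d + R1 * R1 - R2 * R2) / (2 * d)
    h2 = R2 - (d * d + R2 * R2 - R1 * R1) / (2 * d)
    return (sphere_area(R1) - 2 * np.pi * R1 * h1
            + sphere_area(R2) - 2 * np.pi * R2 * h2)


class TestComputeSASA:
    def test_single_atom_closed_form(self):
        """r=1.9 Å, probe=1.4 Å → 4π(3.3)² ≈ 136.8 Ų within 1%."""
        res = compute_sasa(np.zeros((1, 3)), np.array([1.9]), PROBE)
        assert res.total == pytest.approx(sphere_area(3.3), rel=0.01)

    def test_distant_atoms_sum_of_isolated(self):
        coords = np.array([[0.0, 0, 0], [20.0, 0, 0]])
        res = compute_sasa(coords, np.array([1.9, 1.5]), PROBE)
        expected = sphere_area(3.3) + sphere_area(2.9)
        assert res.total == pytest.approx(expected, rel=1e-6)

    @pytest.mark.parametrize("d", [1.0, 2.0, 3.5, 5.0])
    def test_two_overlapping_spheres_match_cap_formula(self, d):
        coords = np.array([[0.0, 0, 0], [d, 0, 0]])
        radii = np.array([1.9, 1.5])
        res = compute_sasa(coords, radii, PROBE)
        exact = two_sphere_union_area(1.9 + PROBE, 1.5 + PROBE, d)
        assert res.total == pytest.approx(exact, rel=0.01)

    def test_monotone_under_added_occluders(self, rng):
        """SASA of a target never increases as context atoms are added."""
        coords = rng.uniform(0, 8, (12, 3))
        radii = np.full(12, 1.7)
        target = np.array([0])
        prev = np.inf
        for k in range(1, 13):
            ctx = np.arange(k)
            a = compute_sasa(coords, radii, PROBE, target, ctx).areas[0]
            assert a <= prev + 1e-9
            prev = a

    def test_resolution_convergence(self):
        a1 = compute_sasa(np.zeros((1, 3)), np.array([1.9]), PROBE,
                          n_points=960).total
        a2 = compute_sasa(np.zeros((1, 3)), np.array([1.9]), PROBE,
                          n_points=1920).total
        assert abs(a2 - a1) / a1 < 0.005

    def test_periodic_occlusion_uses_minimum_image(self):
        # neighbors across the boundary occlude
        edges = np.full(3, 10.0)
        coords = np.array([[0.5, 5, 5], [9.5, 5, 5]])
        radii = np.array([1.7, 1.7])
        with_pbc = compute_sasa(coords, radii, PROBE, edges=edges).total
        without = compute_sasa(coords, radii, PROBE).total
        assert with_pbc < without

    def test_empty_selection_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            compute_sasa(np.zeros((1, 3)), np.array([1.9]), PROBE,
                         targets=np.array([], dtype=int))

    def test_cross_check_against_mdtraj(self):
        """Independent Shrake–Rupley (mdtraj) agrees on a carbon cluster."""
        md = pytest.importorskip("mdtraj")
        rng = np.random.default_rng(3)
        n = 6
        coords = rng.uniform(0, 6, (n, 3))
        top = md.Topology()
        ch = top.add_chain()
        res = top.add_residue("UNK", ch)
        for i in range(n):
            top.add_atom(f"C{i}", md.element.carbon, res)
        t = md.Trajectory(coords[None] / 10.0, top)  # nm
        ref = md.shrake_rupley(t, probe_radius=0.14, n_sphere_points=960)
        ref_total = ref.sum() * 100.0  # nm² → Å²
        mine = compute_sasa(coords, np.full(n, 1.7), 1.4).total
        assert mine == pytest.approx(ref_total, rel=0.02)


def _two_molecule_fixture(d):
    coords = np.array([[0.0, 10, 10], [d, 10, 10]])
    mols = [Molecule("A", np.array([0])), Molecule("B", np.array([1]))]
    topo = Topology(["C", "C"], [1.9, 1.5], [0.0, 0.0], mols)
    return topo, coords


class TestContactAreaSeries:
    def test_no_neighbor_means_zero_excluded(self, cell50):
        topo, coords = _two_molecule_fixture(20.0)
        traj = Trajectory([0.0, 4.0], np.stack([coords, coords]), cell50)
        series = contact_area_series(traj, topo)
        np.testing.assert_allclose(series.values, 0.0, atol=1e-9)
        summary = contact_summary(series)
        assert np.all(summary.percent_contact_time == 0.0)

    def test_dimer_equals_direct_subtraction(self, cell50):
        """Excluded area of a dimer equals two independent SASA calls."""
        topo, coords = _two_molecule_fixture(3.0)
        traj = Trajectory([0.0, 4.0], np.stack([coords, coords]), cell50)
        series = contact_area_series(traj, topo)
        iso = molecule_sasa(coords, topo, 0, None, edges=cell50.edges)
        env = molecule_sasa(coords, topo, 0, [1], edges=cell50.edges)
        assert series.values[0, 0] == pytest.approx(iso - env, abs=1e-9)
        assert series.values[0, 0] > 0

    def test_fully_enclosed_molecule_near_100_percent(self, cell50):
        # central atom caged by 12 tightly packed neighbors
        center = np.array([[25.0, 25.0, 25.0]])
        phi = np.pi * (3 - np.sqrt(5)) * (np.arange(12) + 0.5)
        z = 1 - 2 * (np.arange(12) + 0.5) / 12
        r = np.sqrt(1 - z * z)
        shell = center + 2.4 * np.stack(
            [r * np.cos(phi), r * np.sin(phi), z], axis=1
        )
        coords = np.vstack([center, shell])
        mols = [Molecule(f"m{i}", np.array([i])) for i in range(13)]
        topo = Topology(["C"] * 13, [1.7] * 13, [0.0] * 13, mols)
        traj = Trajectory([0.0, 4.0], np.stack([coords, coords]), cell50)
        series = contact_area_series(traj, topo, targets=[0])
        iso = molecule_sasa(coords, topo, 0)
        assert series.values[0, 0] / iso > 0.95

    def test_target_in_environment_rejected(self, cell50):
        topo, coords = _two_molecule_fixture(3.0)
        with pytest.raises(ValueError, match="environment"):
            molecule_sasa(coords, topo, 0, [0, 1])


class TestContactStats:
    def test_hand_enumerated_events(self):
        """[0.5, 0.5, 0.4, 0.6] at threshold 0.48, dt=4: 75% in contact,
        events of 2 and 1 frames → mean 6 ps, max 8 ps."""
        series = gen_contact_timeline([0.5, 0.5, 0.4, 0.6], dt=4.0)
        stats = contact_stats(series)
        assert stats.percent_in_contact == pytest.approx(75.0)
        assert [l for _, l in stats.contact_events] == [2, 1]
        assert stats.mean_contact_ps == pytest.approx(6.0)
        assert stats.max_contact_ps == pytest.approx(8.0)

    def test_all_below_threshold_single_solvation_event(self):
        series = gen_contact_timeline([0.1] * 7, dt=4.0)
        stats = contact_stats(series)
        assert stats.percent_in_contact == 0.0
        assert stats.solvation_events == [(0, 7)]

    def test_value_exactly_at_threshold_is_not_contact(self):
        """The criterion is strictly 'greater than 0.48'."""
        stats = contact_stats(gen_contact_timeline([0.48], dt=4.0))
        assert stats.percent_in_contact == 0.0

    def test_empty_series_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            contact_stats(np.array([]), dt=4.0, threshold=0.48)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.lists(st.floats(0.0, 1.0), min_size=1, max_size=60))
    def test_events_tile_the_frame_axis(self, values):
        stats = contact_stats(np.asarray(values), dt=4.0, threshold=0.48)
        total = sum(l for _, l in stats.contact_events)
        total += sum(l for _, l in stats.solvation_events)
        assert total == len(values)
        # events are disjoint and ordered
        starts = sorted(s for s, _ in stats.contact_events
                        + stats.solvation_events)
        assert len(starts) == len(set(starts))


class TestResidueContactProfile:
    @pytest.fixture
    def protein_with_metabolite(self, cell50):
        # 3-"residue" mini protein along x plus one metabolite near residue 2
        # res 3 sits beyond the occlusion reach 2(r+probe) = 6.2 Å of the
        # metabolite; res 2 is closest and res 1 marginal
        coords = np.array([
            [10.0, 10.0, 10.0],  # res 1
            [14.0, 10.0, 10.0],  # res 2
            [22.0, 10.0, 10.0],  # res 3 (8.5 Å from the metabolite)
            [14.0, 13.0, 10.0],  # metabolite 3 Å from residue 2
        ])
        mols = [Molecule("prot", np.array([0, 1, 2]), kind="protein"),
                Molecule("met", np.array([3]), kind="metabolite")]
        topo = Topology(["C"] * 4, [1.7] * 4, [0.0] * 4, mols,
                        resids=[1, 2, 3, 99],
                        resnames=["ALA", "GLY", "SER", "MET"])
        traj = Trajectory([0.0, 4.0], np.stack([coords, coords]), cell50)
        return traj, topo

    def test_contacted_residue_ranks_first(self, protein_with_metabolite):
        traj, topo = protein_with_metabolite
        df = residue_contact_profile(traj, topo, 0)
        assert df.iloc[0].resid == 2
        assert df.iloc[0].percent_contact_area > 0

    def test_distant_residue_zero(self, protein_with_metabolite):
        traj, topo = protein_with_metabolite
        df = residue_contact_profile(traj, topo, 0)
        assert df[df.resid == 3].percent_contact_area.iloc[0] == pytest.approx(
            0.0, abs=1e-6
        )

    def test_non_protein_rejected(self, protein_with_metabolite):
        traj, topo = protein_with_metabolite
        with pytest.raises(ValueError, match="protein"):
            residue_contact_profile(traj, topo, 1)


class TestTotalSASATrace:
    def test_static_configuration_flat_zero_loss(self, cell50):
        topo, coords = _two_molecule_fixture(20.0)
        traj = Trajectory(np.arange(5) * 4.0,
                          np.repeat(coords[None], 5, axis=0), cell50)
        trace = total_sasa_trace(traj, topo, window_ps=8.0)
        assert np.ptp(trace.total) < 1e-9
        assert trace.percent_loss == pytest.approx(0.0, abs=1e-9)
        assert trace.total.size == traj.n_frames

    def test_two_plateau_trace_recovers_constructed_drop(self):
        totals = np.array([1000.0] * 50 + [800.0] * 50)
        trace = _trace_from_totals(np.arange(100) * 4.0, totals, 4.0,
                                   window_ps=40.0)
        assert trace.percent_loss == pytest.approx(20.0)


def test_magnesium_ionic_bond_count():
    # Mg with two carboxylate-like oxygens in range, one out of range
    coords = np.array([
        [10.0, 10.0, 10.0],  # Mg
        [12.0, 10.0, 10.0],  # O, q=-0.8, d=2.0 → bonded
        [10.0, 12.5, 10.0],  # O, q=-0.8, d=2.5 → bonded
        [10.0, 10.0, 16.0],  # O, q=-0.8, d=6.0 → not bonded
        [12.0, 12.0, 10.0],  # O, q=0.0 → not a charged group
    ])
    mols = [Molecule("MG", np.array([0]), kind="ion", charge=2.0),
            Molecule("m1", np.array([1]), charge=-0.8),
            Molecule("m2", np.array([2]), charge=-0.8),
            Molecule("m3", np.array([3]), charge=-0.8),
            Molecule("m4", np.array([4]), charge=0.0)]
    topo = Topology(["MG", "O", "O", "O", "O"], [1.73, 1.52, 1.52, 1.52, 1.52],
                    [2.0, -0.8, -0.8, -0.8, 0.0], mols)
    counts = magnesium_ionic_bonds(coords, topo)
    assert counts == {0: 2}
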