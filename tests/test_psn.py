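"""COM series, contact persistence, and graph filtering."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from psnkit.ensemble_io import MassTable, StructuralEnsemble, select_sidechains
from psnkit.psn import (
    ComSeries,
    build_graph,
    compute_com_series,
    compute_persistence,
    write_edge_list,
)

from conftest import random_rotation, residue


def _ensemble_of(atom_rows, coordinates):
    """atom_rows: (name, element, chain, resid, resname)."""
    atoms = pd.DataFrame(
        atom_rows, columns=["name", "element", "chain", "resid", "resname"]
    )
    atoms["icode"] = ""
    coords = np.asarray(coordinates, dtype=float)
    return StructuralEnsemble(
        atoms=atoms,
        coordinates=coords,
        frame_indices=np.arange(coords.shape[0]),
    )


def _two_point_series(distance, n_frames=1):
    pos = np.zeros((n_frames, 2, 3))
    pos[:, 1, 0] = distance
    return ComSeries(nodes=[residue(1), residue(2)], positions=pos)


class TestComSeries:
    def test_equal_masses_give_midpoint(self):
        ens = _ensemble_of(
            [("CB", "C", "A", 1, "XXX"), ("CG", "C", "A", 1, "XXX")],
            [[[0, 0, 0], [2, 0, 0]]],
        )
        coms = compute_com_series(ens, select_sidechains(ens), MassTable())
        np.testing.assert_allclose(coms.positions[0, 0], [1, 0, 0])

    def test_mass_weighted_mean(self):
        # masses 12.011 (C) and 15.999 (O) at z=0 and z=7
        ens = _ensemble_of(
            [("CB", "C", "A", 1, "XXX"), ("OG", "O", "A", 1, "XXX")],
            [[[0, 0, 0], [0, 0, 7.0]]],
        )
        coms = compute_com_series(ens, select_sidechains(ens), MassTable())
        expected_z = 15.999 * 7.0 / (12.011 + 15.999)
        np.testing.assert_allclose(coms.positions[0, 0], [0, 0, expected_z])

    def test_exact_integer_masses(self):
        table = MassTable(element_masses={"C": 12.0, "O": 16.0})
        ens = _ensemble_of(
            [("CB", "C", "A", 1, "XXX"), ("OG", "O", "A", 1, "XXX")],
            [[[0, 0, 0], [0, 0, 7.0]]],
        )
        coms = compute_com_series(ens, select_sidechains(ens), table)
        np.testing.assert_allclose(coms.positions[0, 0], [0, 0, 4.0])

    def test_single_atom_sidechain_is_identity(self):
        ens = _ensemble_of([("CB", "C", "A", 1, "ALA")], [[[1.5, -2.5, 3.0]]])
        coms = compute_com_series(ens, select_sidechains(ens), MassTable())
        np.testing.assert_array_equal(coms.positions[0, 0], [1.5, -2.5, 3.0])

    def test_com_invariant_under_atom_permutation(self):
        rows = [
            ("CB", "C", "A", 1, "LEU"),
            ("CG", "C", "A", 1, "LEU"),
            ("CD1", "C", "A", 1, "LEU"),
        ]
        coords = np.array([[[0, 0, 0], [1.4, 0.3, 0], [2.1, 1.5, 0.5]]])
        a = _ensemble_of(rows, coords)
        b = _ensemble_of(rows[::-1], coords[:, ::-1])
        com_a = compute_com_series(a, select_sidechains(a), MassTable())
        com_b = compute_com_series(b, select_sidechains(b), MassTable())
        np.testing.assert_allclose(com_a.positions, com_b.positions)


class TestPersistence:
    def test_fraction_of_frames_in_contact(self):
        pos = np.zeros((10, 2, 3))
        pos[:, 1, 0] = 12.0
        pos[:3, 1, 0] = 4.0  # within cutoff 5 in 3 of 10 frames
        coms = ComSeries([residue(1), residue(2)], pos)
        pm = compute_persistence(coms, 5.0)
        assert pm.values[0, 1] == 0.3
        assert pm.values[1, 0] == 0.3

    def test_all_far_gives_zero_matrix(self):
        pm = compute_persistence(_two_point_series(50.0, n_frames=4), 5.0)
        assert not pm.values.any()

    def test_threshold_is_inclusive_and_sharp(self):
        series = _two_point_series(4.9, n_frames=5)
        assert compute_persistence(series, 5.0).values[0, 1] == 1.0
        assert compute_persistence(series, 4.5).values[0, 1] == 0.0
        assert compute_persistence(series, 4.9).values[0, 1] == 1.0  # ties kept

    def test_diagonal_zero_and_symmetric(self):
        rng = np.random.default_rng(0)
        coms = ComSeries(
            [residue(i) for i in range(1, 7)], rng.uniform(0, 10, (8, 6, 3))
        )
        pm = compute_persistence(coms, 5.0)
        np.testing.assert_array_equal(pm.values, pm.values.T)
        assert not np.diag(pm.values).any()

    def test_rigid_motion_invariance(self):
        rng = np.random.default_rng(42)
        positions = rng.uniform(0, 20, size=(20, 15, 3))
        nodes = [residue(i) for i in range(1, 16)]
        rotation = random_rotation(rng)
        translation = rng.uniform(-50, 50, 3)
        moved = positions @ rotation.T + translation
        before = compute_persistence(ComSeries(nodes, positions), 6.0)
        after = compute_persistence(ComSeries(nodes, moved), 6.0)
        assert np.abs(before.values - after.values).max() <= 1e-9

    def test_frame_permutation_invariance(self):
        rng = np.random.default_rng(7)
        positions = rng.uniform(0, 15, size=(12, 8, 3))
        nodes = [residue(i) for i in range(1, 9)]
        perm = rng.permutation(12)
        a = compute_persistence(ComSeries(nodes, positions), 5.0)
        b = compute_persistence(ComSeries(nodes, positions[perm]), 5.0)
        np.testing.assert_array_equal(a.values, b.values)

    @settings(deadline=None, derandomize=True, max_examples=25)
    @given(
        seed=st.integers(0, 10_000),
        c1=st.floats(1.0, 10.0),
        c2=st.floats(1.0, 10.0),
    )
    def test_cutoff_monotonicity(self, seed, c1, c2):
        """Persistence is element-wise non-decreasing in the cutoff."""
        c1, c2 = min(c1, c2), max(c1, c2)
        rng = np.random.default_rng(seed)
        coms = ComSeries(
            [residue(i) for i in range(1, 7)], rng.uniform(0, 12, (6, 6, 3))
        )
        low = compute_persistence(coms, c1).values
        high = compute_persistence(coms, c2).values
        assert (low <= high).all()

    def test_rejects_nonpositive_cutoff(self):
        with pytest.raises(ValueError):
            compute_persistence(_two_point_series(1.0), 0.0)


class TestBuildGraph:
    def _pm(self, values, n):
        from psnkit.psn import PersistenceMatrix

        return PersistenceMatrix(
            nodes=[residue(i) for i in range(1, n + 1)],
            values=np.asarray(values, dtype=float),
            cutoff=5.0,
            n_frames_used=10,
        )

    def test_edge_at_default_pcrit_carries_percent_weight(self):
        pm = self._pm([[0, 0.30], [0.30, 0]], 2)
        psn = build_graph(pm, p_crit=20.0)
        assert psn.n_edges == 1
        (_, _, data), = psn.graph.edges(data=True)
        assert data["weight"] == 30.0

    def test_below_threshold_edge_absent_and_tie_kept(self):
        pm = self._pm([[0, 0.15], [0.15, 0]], 2)
        assert build_graph(pm, 20.0).n_edges == 0
        pm_tie = self._pm([[0, 0.20], [0.20, 0]], 2)
        assert build_graph(pm_tie, 20.0).n_edges == 1  # inclusive at p_crit

    def test_pcrit_extremes_match_brute_force(self):
        rng = np.random.default_rng(3)
        vals = rng.choice([0.0, 0.1, 0.2, 0.5, 1.0], size=(5, 5))
        vals = np.triu(vals, 1) + np.triu(vals, 1).T
        pm = self._pm(vals, 5)
        nonzero_pairs = {
            (i, j) for i in range(5) for j in range(i + 1, 5) if vals[i, j] > 0
        }
        permanent_pairs = {
            (i, j) for i in range(5) for j in range(i + 1, 5) if vals[i, j] == 1.0
        }
        assert build_graph(pm, 0.0).n_edges == len(nonzero_pairs)
        assert build_graph(pm, 100.0).n_edges == len(permanent_pairs)

    def test_pcrit_monotonicity_nests_edge_sets(self):
        rng = np.random.default_rng(11)
        vals = rng.uniform(0, 1, size=(8, 8))
        vals = np.triu(vals, 1) + np.triu(vals, 1).T
        pm = self._pm(vals, 8)
        previous = None
        for p_crit in (0, 20, 50, 80, 100):
            edges = set(map(frozenset, build_graph(pm, p_crit).graph.edges()))
            if previous is not None:
                assert edges <= previous
            previous = edges

    def test_isolated_nodes_retained(self):
        pm = self._pm(np.zeros((4, 4)), 4)
        psn = build_graph(pm, 20.0)
        assert psn.graph.number_of_nodes() == 4

    def test_min_seq_separation_drops_neighbors(self):
        vals = np.zeros((3, 3))
        vals[0, 1] = vals[1, 0] = 1.0  # residues 1-2, adjacent
        vals[0, 2] = vals[2, 0] = 1.0  # residues 1-3, separation 2
        pm = self._pm(vals, 3)
        assert build_graph(pm, 20.0).n_edges == 2
        psn = build_graph(pm, 20.0, min_seq_separation=2)
        assert psn.n_edges == 1
        (a, b), = psn.graph.edges()
        assert {a.resid, b.resid} == {1, 3}

    def test_edge_list_writer_is_sorted_and_deterministic(self, tmp_path):
        rng = np.random.default_rng(5)
        vals = rng.uniform(0, 1, size=(6, 6))
        vals = np.triu(vals, 1) + np.triu(vals, 1).T
        psn = build_graph(self._pm(vals, 6), 20.0)
        p1 = write_edge_list(psn, tmp_path / "a.tsv")
        p2 = write_edge_list(psn, tmp_path / "b.tsv")
        assert p1.read_bytes() == p2.read_bytes()
        lines = p1.read_text().splitlines()
        assert lines == sorted(lines)
        assert all(len(line.split("\t")) == 3 for line in lines)
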