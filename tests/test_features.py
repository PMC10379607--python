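"""Feature layer: structure I/O, Kabsch RMSD, native contacts, FNC series."""

import numpy as np
import pytest
from hypothesis import given, strategies as st
from scipy.spatial.transform import Rotation

import porescan as ps
from porescan.errors import (
    DegenerateGeometryError,
    EmptyInputError,
    FormatError,
    ShapeError,
    UndefinedFractionError,
)
from porescan.features import rmsd_series
from porescan.structure import write_structure, write_trajectory

from oracles import brute_contacts, brute_fnc, grid_rmsd


# ----------------------------------------------------------------- I/O ----

class TestStructureIO:
    def test_pdb_round_trip(self, tmp_path, rng):
        s = ps.Structure(rng.uniform(-2, 2, (17, 3)))
        write_structure(s, tmp_path / "s.pdb")
        back = ps.read_structure(tmp_path / "s.pdb")
        assert back.n_atoms == 17
        # PDB stores 3 decimals in Å → 1e-4 nm quantisation
        np.testing.assert_allclose(back.coords, s.coords, atol=1e-3)

    def test_hand_written_pdb_in_nm(self, tmp_path):
        lines = [
            "ATOM      1  CA  GLY A   1       1.000   2.000   3.000  1.00  0.00           C",
            "ATOM      2  CA  GLY A   2       4.000   5.000   6.000  1.00  0.00           C",
            "ATOM      3  CA  GLY A   3       7.000   8.000   9.000  1.00  0.00           C",
            "END",
        ]
        p = tmp_path / "three.pdb"
        p.write_text("\n".join(lines) + "\n")
        s = ps.read_structure(p)
        assert s.n_atoms == 3
        np.testing.assert_allclose(s.coords[0], [0.1, 0.2, 0.3], atol=1e-6)

    def test_malformed_atom_line_raises(self, tmp_path):
        p = tmp_path / "bad.pdb"
        p.write_text("ATOM      1  CA  GLY A   1      abc    2.0     3.0\nEND\n")
        with pytest.raises((FormatError, EmptyInputError)):
            ps.read_structure(p)

    def test_trajectory_round_trip(self, tmp_path, rng):
        coords = rng.uniform(-1, 1, (5, 8, 3))
        traj = ps.ReplicaTrajectory("r1", coords, frame_interval=10.0)
        write_structure(ps.Structure(coords[0]), tmp_path / "ref.pdb")
        write_trajectory(traj, tmp_path / "traj.pdb")
        back = ps.read_trajectory(tmp_path / "ref.pdb", tmp_path / "traj.pdb")
        assert back.n_frames == 5
        np.testing.assert_allclose(back.coords, coords, atol=1e-3)

    def test_atom_count_mismatch_raises(self, tmp_path, rng):
        write_structure(ps.Structure(rng.uniform(-1, 1, (6, 3))), tmp_path / "ref.pdb")
        traj = ps.ReplicaTrajectory("r1", rng.uniform(-1, 1, (3, 8, 3)), 10.0)
        write_trajectory(traj, tmp_path / "traj.pdb")
        with pytest.raises(ShapeError):
            ps.read_trajectory(tmp_path / "ref.pdb", tmp_path / "traj.pdb")


# --------------------------------------------------------------- RMSD ----

class TestSuperposeRmsd:
    def test_self_superposition_is_identity(self, native):
        rot, trans, value = ps.superpose(native, native)
        assert value == pytest.approx(0.0, abs=1e-9)
        np.testing.assert_allclose(rot, np.eye(3), atol=1e-8)
        np.testing.assert_allclose(trans, 0.0, atol=1e-8)

    @given(st.integers(0, 10_000))
    def test_rigid_motion_invariance(self, seed):
        rng = np.random.default_rng(seed)
        x = ps.Structure(rng.normal(size=(9, 3)))
        rot = Rotation.random(rng=np.random.default_rng(seed + 1)).as_matrix()
        moved = ps.Structure(x.coords @ rot.T + rng.normal(size=3))
        assert ps.rmsd(x, moved) == pytest.approx(0.0, abs=1e-6)
        r, t, v = ps.superpose(moved, x)
        assert v == pytest.approx(0.0, abs=1e-6)
        assert np.linalg.det(r) == pytest.approx(1.0, abs=1e-9)

    def test_collinear_superpose_degenerate(self):
        line = ps.Structure(np.outer(np.arange(4.0), [1.0, 0, 0]))
        with pytest.raises(DegenerateGeometryError):
            ps.superpose(line, line)

    @pytest.mark.parametrize("d1,d2", [(1.0, 3.0), (0.4, 0.4), (2.0, 0.5)])
    def test_two_atom_closed_form(self, d1, d2):
        # after centering, the optimum aligns the bonds: rmsd = |d1 - d2| / 2
        x = ps.Structure([[0, 0, 0], [d1, 0, 0]])
        y = ps.Structure([[0, 0, 0], [0, d2, 0]])
        assert ps.rmsd(x, y) == pytest.approx(abs(d1 - d2) / 2, abs=1e-9)

    @given(st.integers(0, 10_000))
    def test_symmetry(self, seed):
        rng = np.random.default_rng(seed)
        x = ps.Structure(rng.normal(size=(7, 3)))
        y = ps.Structure(rng.normal(size=(7, 3)))
        assert ps.rmsd(x, y) == pytest.approx(ps.rmsd(y, x), abs=1e-9)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_against_rotation_grid_oracle(self, seed):
        rng = np.random.default_rng(seed)
        x = rng.uniform(-0.5, 0.5, (5, 3))
        y = rng.uniform(-0.5, 0.5, (5, 3))
        ours = ps.rmsd(ps.Structure(x), ps.Structure(y))
        grid = grid_rmsd(x, y, step_deg=4.0)
        assert ours <= grid + 1e-9
        assert grid - ours < 0.08  # grid resolution slack

    def test_against_scipy_align_vectors(self, rng):
        x = rng.normal(size=(11, 3))
        y = rng.normal(size=(11, 3))
        _, rssd = Rotation.align_vectors(
            y - y.mean(axis=0), x - x.mean(axis=0)
        )
        assert ps.rmsd(ps.Structure(x), ps.Structure(y)) == pytest.approx(
            rssd / np.sqrt(11), abs=1e-9
        )

    def test_series_matches_pairwise(self, rng):
        ref = rng.normal(size=(10, 3))
        frames = rng.normal(size=(6, 10, 3))
        series = rmsd_series(frames, ref)
        for k in range(6):
            assert series[k] == pytest.approx(
                ps.rmsd(ps.Structure(frames[k]), ps.Structure(ref)), abs=1e-10
            )


# ----------------------------------------------------------- contacts ----

class TestContactsFnc:
    def test_two_atoms_in_contact(self):
        s = ps.Structure([[0, 0, 0], [0.5, 0, 0]])
        assert ps.native_contacts(s, min_sequence_separation=1).n_pairs == 1

    def test_two_atoms_out_of_contact(self):
        s = ps.Structure([[0, 0, 0], [0.9, 0, 0]])
        assert ps.native_contacts(s).n_pairs == 0

    @pytest.mark.parametrize("seed,min_sep", [(0, 0), (1, 1), (2, 3)])
    def test_against_brute_force(self, seed, min_sep):
        rng = np.random.default_rng(seed)
        coords = rng.uniform(0, 1.5, (10, 3))
        cs = ps.native_contacts(ps.Structure(coords), 0.8, min_sep)
        got = {tuple(p) for p in cs.pairs}
        assert got == brute_contacts(coords, 0.8, min_sep)

    def test_fnc_of_reference_is_one(self, native):
        cs = ps.native_contacts(native)
        assert ps.fnc(native, cs) == 1.0

    def test_fnc_zero_when_blown_apart(self, native):
        cs = ps.native_contacts(native)
        far = ps.Structure(native.coords * 100.0)
        assert ps.fnc(far, cs) == 0.0

    def test_fnc_half_matches_recount(self, rng):
        # stretch half the contact pairs past the cutoff, recount by brute force
        coords = np.array([[i * 0.5, 0.0, 0.0] for i in range(10)])
        s = ps.Structure(coords)
        cs = ps.native_contacts(s, cutoff=0.8, min_sequence_separation=1)
        moved = coords.copy()
        moved[1::2, 2] += 5.0  # push odd atoms away
        got = ps.fnc(ps.Structure(moved), cs)
        assert got == pytest.approx(brute_fnc(moved, cs.pairs, 0.8), abs=1e-12)

    @given(st.floats(1.0, 5.0))
    def test_fnc_non_increasing_under_expansion(self, factor):
        s = ps.make_native(20, seed=3)
        cs = ps.native_contacts(s)
        base = ps.fnc(s, cs)
        expanded = ps.fnc(ps.Structure(s.coords * factor), cs)
        assert expanded <= base + 1e-12

    def test_empty_contact_set_undefined(self, native):
        empty = ps.ContactSet(np.empty((0, 2)), 0.8, native.n_atoms)
        with pytest.raises(UndefinedFractionError):
            ps.fnc(native, empty)


# ----------------------------------------------------------- featurize ----

class TestFeaturize:
    def test_single_frame(self, native):
        traj = ps.ReplicaTrajectory("r0", native.coords[None], 10.0)
        s = ps.featurize(traj)
        assert s.rmsd.tolist() == [0.0]
        assert s.fnc.tolist() == [1.0]

    def test_pinned_replica_flat(self, native, states):
        cfg = ps.GeneratorConfig(
            n_replicas=1, duration=1.0, frame_interval=50.0, noise_sigma=0.0,
            relaxation_rate=0.0, fraction_unstable=0.0, fraction_closed=0.0,
        )
        traj = ps.simulate_replica(native, states[0], cfg, seed=0)
        s = ps.featurize(traj)
        np.testing.assert_allclose(s.rmsd, 0.0, atol=1e-9)
        np.testing.assert_allclose(s.fnc, 1.0, atol=1e-12)

    def test_plateau_matches_template_rmsd(self, native, states):
        """Late-frame mean RMSD approaches the template distance (20 seeds).

        The reference is the replica's first frame, itself already
        e^(−r·Δt) of the way toward the template, so the exact expected
        plateau is e^(−r·Δt) · RMSD(native, template).
        """
        template_rmsd = ps.rmsd(native, states[1].template)
        cfg = ps.GeneratorConfig(
            n_replicas=1, duration=5.0, frame_interval=50.0,
            fraction_unstable=0.0, fraction_closed=0.0,
        )
        expected = np.exp(-cfg.relaxation_rate * cfg.frame_interval / 1000.0) * template_rmsd
        plateaus = []
        for seed in range(20):
            traj = ps.simulate_replica(native, states[1], cfg, seed=seed)
            s = ps.featurize(traj)
            tail = s.rmsd[-max(1, s.n_frames // 10):]
            plateaus.append(tail.mean())
        plateaus = np.asarray(plateaus)
        se = plateaus.std(ddof=1) / np.sqrt(len(plateaus))
        # thermal noise adds a small positive bias to measured RMSD
        bias_allowance = 0.01
        assert abs(plateaus.mean() - expected) < 3 * se + bias_allowance

    def test_tsv_round_trip(self, tmp_path, tiny_campaign_config):
        trajs, _ = ps.simulate_campaign(tiny_campaign_config)
        series = [ps.featurize(t) for t in trajs[:3]]
        path = tmp_path / "features.tsv"
        ps.features.write_features_tsv(series, path)
        back = ps.features.read_features_tsv(path)
        assert [s.replica_id for s in back] == [s.replica_id for s in series]
        np.testing.assert_allclose(back[1].rmsd, series[1].rmsd, rtol=1e-4, atol=1e-6)
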