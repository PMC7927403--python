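"""Structure I/O, Kabsch superposition and the inter-residue descriptor."""

import numpy as np
import pytest
from scipy.optimize import minimize
from scipy.spatial.transform import Rotation

from conformo.structio import (
    ResiduePairDescriptor,
    StructureModel,
    align_ensemble,
    apply_superposition,
    pair_distance,
    read_frames,
    read_structure,
    residue_stability,
    select_template,
    superpose,
    write_pdb,
)

from conftest import pdb_line, random_model, rigid_copy

PAIR = ResiduePairDescriptor()


class TestReadStructure:
    def test_reads_exactly_the_chain_A_residues(self, three_residue_pdb):
        model = read_structure(three_residue_pdb, chain_id="A", residue_range=None)
        assert model.residues == [84, 100, 249]

    def test_hetatm_ignored_and_residue_window_applied(self, three_residue_pdb):
        model = read_structure(three_residue_pdb, chain_id="A", residue_range=(1, 320))
        assert 500 not in model.ca_coords and model.residues == [84, 100, 249]

    def test_altloc_keeps_highest_occupancy(self, tmp_path):
        lines = [
            pdb_line(1, 84, 1.0, 0.0, 0.0, occ=0.6, altloc="A"),
            pdb_line(2, 84, 2.0, 0.0, 0.0, occ=0.4, altloc="B"),
            pdb_line(3, 85, 0.0, 0.0, 0.0),
        ]
        p = tmp_path / "alt.pdb"
        p.write_text("\n".join(lines) + "\n")
        model = read_structure(p)
        assert model.ca_coords[84][0] == pytest.approx(1.0)

    def test_altloc_occupancy_tie_keeps_first(self, tmp_path):
        lines = [
            pdb_line(1, 84, 1.0, 0.0, 0.0, occ=0.5, altloc="A"),
            pdb_line(2, 84, 2.0, 0.0, 0.0, occ=0.5, altloc="B"),
        ]
        p = tmp_path / "tie.pdb"
        p.write_text("\n".join(lines) + "\n")
        assert read_structure(p).ca_coords[84][0] == pytest.approx(1.0)

    def test_missing_chain_error_names_available_chains(self, three_residue_pdb):
        with pytest.raises(ValueError, match="available chains: A, B"):
            read_structure(three_residue_pdb, chain_id="X")

    def test_malformed_coordinate_reports_line_number(self, tmp_path):
        good = pdb_line(1, 84, 0.0, 0.0, 0.0)
        bad = good[:30] + "  xx.xxx" + good[38:]
        p = tmp_path / "bad.pdb"
        p.write_text(good + "\n" + bad + "\n")
        with pytest.raises(ValueError, match="line 2"):
            read_structure(p)

    def test_insertion_code_rejected(self, tmp_path):
        p = tmp_path / "icode.pdb"
        p.write_text(pdb_line(1, 84, 0.0, 0.0, 0.0, icode="A") + "\n")
        with pytest.raises(ValueError, match="insertion code"):
            read_structure(p)

    def test_pdb_round_trip_is_exact_to_writer_precision(self, tmp_path):
        rng = np.random.default_rng(0)
        model = random_model(rng, n=8)
        path = tmp_path / "rt.pdb"
        write_pdb(model, path)
        back = read_structure(path, residue_range=None)
        for res in model.residues:
            assert np.allclose(back.ca_coords[res], model.ca_coords[res], atol=5e-4)

    def test_multi_model_file_yields_one_frame_per_model(self, tmp_path):
        rng = np.random.default_rng(1)
        frames = [random_model(rng, n=5, structure_id="f") for _ in range(3)]
        path = tmp_path / "multi.pdb"
        write_pdb(frames, path)
        assert len(read_frames(path, residue_range=None)) == 3


class TestPairDistance:
    def test_three_four_five_triangle(self):
        model = StructureModel("t", "A", {84: [0, 0, 0], 249: [3, 4, 0]})
        assert pair_distance(model, PAIR) == pytest.approx(5.0)

    def test_missing_residue_named_in_error(self):
        model = StructureModel("t", "A", {84: [0, 0, 0]})
        with pytest.raises(ValueError, match="249"):
            pair_distance(model, PAIR)

    def test_invariant_under_rigid_motion(self):
        rng = np.random.default_rng(7)
        model = StructureModel("t", "A", {84: rng.uniform(-5, 5, 3), 249: rng.uniform(-5, 5, 3)})
        d0 = pair_distance(model, PAIR)
        for _ in range(20):
            assert pair_distance(rigid_copy(model, rng), PAIR) == pytest.approx(d0, abs=1e-9)


class TestSuperpose:
    def test_self_superposition_is_identity(self):
        model = random_model(np.random.default_rng(2))
        res = superpose(model, model)
        assert res.rmsd == pytest.approx(0.0, abs=1e-10)
        assert np.allclose(res.rotation, np.eye(3), atol=1e-8)
        assert np.linalg.det(res.rotation) == pytest.approx(1.0)

    def test_recovers_random_rigid_motion(self):
        rng = np.random.default_rng(3)
        ref = random_model(rng)
        moved = rigid_copy(ref, rng)
        res = superpose(moved, ref)
        assert res.rmsd == pytest.approx(0.0, abs=1e-8)
        fitted = apply_superposition(moved, res)
        for r in ref.residues:
            assert np.allclose(fitted.ca_coords[r], ref.ca_coords[r], atol=1e-8)

    def test_rmsd_matches_brute_force_minimisation(self):
        # one atom of ten displaced by 1 A; compare with direct numeric
        # minimisation over rotation vector + translation
        rng = np.random.default_rng(4)
        ref = random_model(rng, n=10)
        mob_coords = {r: c.copy() for r, c in ref.ca_coords.items()}
        mob_coords[5] = mob_coords[5] + np.array([1.0, 0.0, 0.0])
        mob = StructureModel("mob", "A", mob_coords)
        res = superpose(mob, ref)

        shared = ref.residues
        A = mob.coords(shared)
        B = ref.coords(shared)

        def cost(params):
            rot = Rotation.from_rotvec(params[:3]).as_matrix()
            moved = A @ rot.T + params[3:]
            return np.sqrt(np.mean(np.sum((moved - B) ** 2, axis=1)))

        best = min(
            (minimize(cost, x0, method="Nelder-Mead",
                      options={"xatol": 1e-10, "fatol": 1e-12, "maxiter": 20000})
             for x0 in (np.zeros(6), np.concatenate([rng.uniform(-1, 1, 3), np.zeros(3)]))),
            key=lambda r: r.fun,
        )
        assert res.rmsd == pytest.approx(best.fun, abs=1e-6)

    def test_fewer_than_three_shared_residues_errors(self):
        a = StructureModel("a", "A", {1: [0, 0, 0], 2: [1, 0, 0]})
        b = StructureModel("b", "A", {1: [0, 0, 0], 2: [1, 0, 0]})
        with pytest.raises(ValueError, match="3 shared"):
            superpose(a, b)

    def test_collinear_atoms_rejected(self):
        coords = {i: [float(i), 0.0, 0.0] for i in range(1, 6)}
        a = StructureModel("a", "A", coords)
        with pytest.raises(ValueError, match="degenerate"):
            superpose(a, a)


class TestAlignEnsemble:
    def test_identical_members_give_zero_spread(self):
        model = random_model(np.random.default_rng(5))
        alignment = align_ensemble([model, model])
        for r in alignment.shared_residues:
            assert np.allclose(alignment.mean_positions[r], model.ca_coords[r], atol=1e-10)
            assert residue_stability(alignment, r).rmsd_from_mean == pytest.approx(0.0, abs=1e-10)

    def test_rigidly_moved_member_changes_nothing(self):
        rng = np.random.default_rng(6)
        base = [random_model(rng, structure_id=f"m{i}") for i in range(3)]
        moved = [base[0], base[1], rigid_copy(base[2], rng)]
        al_a = align_ensemble(base)
        al_b = align_ensemble(moved)
        # mean structures agree up to a global rigid motion: compare all
        # internal distances
        res = al_a.shared_residues
        pa = np.array([al_a.mean_positions[r] for r in res])
        pb = np.array([al_b.mean_positions[r] for r in res])
        da = np.linalg.norm(pa[:, None] - pa[None], axis=-1)
        db = np.linalg.norm(pb[:, None] - pb[None], axis=-1)
        assert np.allclose(da, db, atol=1e-6)

    def test_mean_positions_track_generating_mean(self):
        # three copies of one scaffold with sigma-jittered residue 249
        rng = np.random.default_rng(8)
        sigma = 0.3
        base = random_model(rng, n=12, start_res=240)
        members = []
        for i in range(3):
            coords = {r: c.copy() for r, c in base.ca_coords.items()}
            coords[249] = coords[249] + rng.normal(0, sigma, 3)
            members.append(StructureModel(f"j{i}", "A", coords))
        alignment = align_ensemble(members)
        err = np.linalg.norm(alignment.mean_positions[249] - base.ca_coords[249])
        assert err < 3 * sigma / np.sqrt(3) + 0.2  # alignment slack


class TestResidueStability:
    def test_two_members_two_angstroms_apart_give_one(self):
        rng = np.random.default_rng(11)
        coords = {i: rng.uniform(-8, 8, 3) for i in range(1, 6)}
        a = StructureModel("a", "A", coords)
        bc = {r: c.copy() for r, c in coords.items()}
        alignment = align_ensemble([a, StructureModel("b", "A", bc)], n_iterations=1)
        # displace residue 3 of member b by 2 A post-alignment
        alignment.members[1].ca_coords[3] = alignment.members[1].ca_coords[3] + np.array([0, 2.0, 0])
        pos = np.stack([m.ca_coords[3] for m in alignment.members])
        alignment.mean_positions[3] = pos.mean(axis=0)
        assert residue_stability(alignment, 3).rmsd_from_mean == pytest.approx(1.0)

    def test_unshared_residue_rejected(self):
        model = random_model(np.random.default_rng(9))
        alignment = align_ensemble([model, model])
        with pytest.raises(ValueError, match="999"):
            residue_stability(alignment, 999)

    def test_scales_linearly_with_deviations(self):
        rng = np.random.default_rng(10)
        base = random_model(rng, n=8)
        members = []
        for i, scale in enumerate((1.0, 1.0)):
            coords = {r: c.copy() for r, c in base.ca_coords.items()}
            members.append(StructureModel(f"s{i}", "A", coords))
        members[1].ca_coords[4] = members[1].ca_coords[4] + np.array([0.5, 0, 0])
        al1 = align_ensemble(members, n_iterations=1)
        members[1].ca_coords[4] = members[1].ca_coords[4] + np.array([0.5, 0, 0])
        al2 = align_ensemble(members, n_iterations=1)
        r1 = residue_stability(al1, 4).rmsd_from_mean
        r2 = residue_stability(al2, 4).rmsd_from_mean
        assert r2 == pytest.approx(2 * r1, rel=0.05)


class TestSelectTemplate:
    def _model(self, sid, state, d):
        return StructureModel(sid, "A", {84: [0, 0, 0], 249: [d, 0, 0]}, state)

    def test_max_mode_picks_widest(self):
        models = [self._model("x", "inactive", 12.9), self._model("y", "active", 14.5)]
        tid, table = select_template(models, PAIR, mode="max")
        assert tid == "y"
        assert set(table["structure_id"]) == {"x", "y"}

    def test_tie_breaks_lexicographically(self):
        models = [
            self._model("c", "unknown", 13.0),
            self._model("a", "unknown", 14.0),
            self._model("b", "unknown", 14.0),
        ]
        tid, _ = select_template(models, PAIR, mode="max")
        assert tid == "a"

    def test_single_model(self):
        tid, _ = select_template([self._model("only", "active", 14.0)], PAIR)
        assert tid == "only"

    def test_no_model_with_both_residues_errors(self):
        model = StructureModel("m", "A", {84: [0, 0, 0]})
        with pytest.raises(ValueError, match="descriptor residues"):
            select_template([model], PAIR)
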