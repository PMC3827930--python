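"""PDB parsing, tunnel detection on constructed ground truth, lining scores."""

import numpy as np
import pytest

from lipmine import (
    HydrophobicSet,
    InputError,
    ParseError,
    ToyStructureSpec,
    Tunnel,
    TunnelParams,
    classify_shape,
    find_tunnels,
    generate_structure,
    read_structure,
    score_tunnel,
)
from conftest import TOY_TUNNEL_PARAMS


def lining_resnums(structure, tunnels, cutoff=4.0):
    score = score_tunnel(structure, tunnels, cutoff=cutoff)
    return {rid[1] for rid in score.lining_residues}


def jaccard(a, b):
    return len(a & b) / len(a | b)


class TestReadStructure:
    def test_round_trip_atom_count(self, straight_toy):
        s = read_structure(straight_toy.pdb_text)
        assert len(s.atoms) == len(straight_toy.residues)

    def test_altloc_b_dropped_with_warning(self):
        text = (
            "ATOM      1  CA  ALA A   1      0.000   0.000   0.000  1.00  0.00           C\n"
            "ATOM      2  CA BALA A   2      3.000   0.000   0.000  1.00  0.00           C\n"
            "END\n"
        )
        with pytest.warns(UserWarning, match="alternate-location"):
            s = read_structure(text)
        assert len(s.atoms) == 1

    def test_interleaved_remarks_same_atoms(self, straight_toy):
        lines = straight_toy.pdb_text.splitlines()
        noisy = []
        for i, line in enumerate(lines):
            noisy.append(line)
            if i % 50 == 0:
                noisy.extend(["REMARK 350 SYNTHETIC", "TER"])
        a = read_structure("\n".join(noisy))
        b = read_structure(straight_toy.pdb_text)
        assert [x.serial for x in a.atoms] == [x.serial for x in b.atoms]
        assert np.allclose(a.coords, b.coords)

    def test_malformed_record_reports_line(self):
        text = "ATOM      1  CA  ALA A   1      xxx.000   0.000   0.000\n"
        with pytest.raises(ParseError, match="line 1"):
            read_structure(text)

    def test_no_atoms_rejected(self):
        with pytest.raises(ParseError):
            read_structure("REMARK nothing here\nEND\n")


class TestFindTunnels:
    def test_straight_cylinder_single_tunnel_recovered(self, straight_toy):
        s = read_structure(straight_toy.pdb_text)
        tunnels = find_tunnels(s, 1, TOY_TUNNEL_PARAMS)
        assert len(tunnels) == 1
        det = lining_resnums(s, tunnels)
        assert jaccard(det, set(straight_toy.lining)) >= 0.9
        assert tunnels[0].straightness >= 0.97

    def test_solid_block_returns_empty(self):
        from lipmine.synthetic import _format_pdb
        lin = np.arange(-8.0, 8.1, 1.5)
        x, y, z = np.meshgrid(lin, lin, lin)
        pts = np.c_[x.ravel(), y.ravel(), z.ravel()]
        pdb = _format_pdb(range(1, len(pts) + 1), ["ALA"] * len(pts), pts)
        s = read_structure(pdb)
        seed = int(np.argmin(np.linalg.norm(pts, axis=1))) + 1
        assert find_tunnels(s, seed, TOY_TUNNEL_PARAMS) == []

    def test_two_exits_give_two_tunnels_with_distinct_mouths(self):
        toy = generate_structure(ToyStructureSpec(seed=2, n_exits=2))
        s = read_structure(toy.pdb_text)
        tunnels = find_tunnels(s, 1, TOY_TUNNEL_PARAMS)
        assert len(tunnels) == 2
        sep = np.linalg.norm(tunnels[0].mouth - tunnels[1].mouth)
        assert sep > TOY_TUNNEL_PARAMS.mouth_min_separation

    def test_missing_seed_residue(self, straight_toy):
        s = read_structure(straight_toy.pdb_text)
        with pytest.raises(InputError):
            find_tunnels(s, 99999, TOY_TUNNEL_PARAMS)

    def test_bent_tunnel_straightness_tracks_truth(self, bent_toy):
        s = read_structure(bent_toy.pdb_text)
        tunnels = find_tunnels(s, 1, TOY_TUNNEL_PARAMS)
        assert len(tunnels) >= 1
        assert tunnels[0].straightness == pytest.approx(bent_toy.straightness,
                                                        abs=0.05)


class TestRigidMotionInvariance:
    @staticmethod
    def transform(pdb_text, rotation, translation):
        s = read_structure(pdb_text)
        moved = s.coords @ rotation.T + translation
        from lipmine.synthetic import _format_pdb
        resnums = [a.resseq for a in s.atoms]
        resnames = [a.resname for a in s.atoms]
        return _format_pdb(resnums, resnames, moved)

    def test_lining_and_straightness_invariant(self):
        from scipy.spatial.transform import Rotation

        toy = generate_structure(ToyStructureSpec(seed=8, tunnel_length=18.0,
                                                  decoy_residues=15))
        rot = Rotation.from_rotvec([0.4, -1.1, 0.7]).as_matrix()
        moved_text = self.transform(toy.pdb_text, rot, np.array([11.0, -3.0, 42.0]))
        s0 = read_structure(toy.pdb_text)
        s1 = read_structure(moved_text)
        t0 = find_tunnels(s0, 1, TOY_TUNNEL_PARAMS)
        t1 = find_tunnels(s1, 1, TOY_TUNNEL_PARAMS)
        assert len(t0) == len(t1) >= 1
        assert t0[0].straightness == pytest.approx(t1[0].straightness, rel=1e-6)
        sc0 = score_tunnel(s0, t0)
        sc1 = score_tunnel(s1, t1)
        assert sc0.lining_residues == sc1.lining_residues
        assert sc0.hydrophobic_fraction == sc1.hydrophobic_fraction


class TestGridConvergence:
    def test_halving_grid_step_changes_lining_little(self):
        toy = generate_structure(ToyStructureSpec(seed=4, tunnel_length=15.0,
                                                  decoy_residues=10))
        s = read_structure(toy.pdb_text)
        coarse = TunnelParams(grid_step=0.7, probe_radius=0.8, atom_radius=1.0)
        fine = TunnelParams(grid_step=0.35, probe_radius=0.8, atom_radius=1.0)
        la = lining_resnums(s, find_tunnels(s, 1, coarse))
        lb = lining_resnums(s, find_tunnels(s, 1, fine))
        assert 1 - jaccard(la, lb) < 0.1


class TestScoreTunnel:
    @staticmethod
    def ring_structure(n_total, n_hydro):
        """n_total residues on a ring around a straight centerline."""
        from lipmine.synthetic import _format_pdb

        angles = 2 * np.pi * np.arange(n_total) / n_total
        zs = np.linspace(0, 10, n_total)
        pts = np.c_[3.0 * np.cos(angles), 3.0 * np.sin(angles), zs]
        far = np.array([[20.0, 0.0, z] for z in np.linspace(0, 10, 5)])
        names = ["LEU"] * n_hydro + ["SER"] * (n_total - n_hydro) + ["GLY"] * 5
        pdb = _format_pdb(range(1, n_total + 6), names, np.vstack([pts, far]))
        structure = read_structure(pdb)
        zpts = np.linspace(0.0, 10.0, 21)
        centerline = np.c_[np.zeros_like(zpts), np.zeros_like(zpts), zpts]
        tunnel = Tunnel(centerline=centerline, radii=np.full(len(zpts), 1.5),
                        seed_residue=1, mouth=centerline[-1],
                        arc_length=10.0, straightness=1.0)
        return structure, tunnel

    def test_13_of_22_rounds_to_59(self):
        structure, tunnel = self.ring_structure(22, 13)
        score = score_tunnel(structure, tunnel)
        assert (score.total_count, score.hydrophobic_count) == (22, 13)
        assert score.hydrophobic_fraction == 59

    def test_8_of_22_rounds_to_36(self):
        structure, tunnel = self.ring_structure(22, 8)
        score = score_tunnel(structure, tunnel)
        assert score.hydrophobic_fraction == 36

    def test_all_glycine_scores_zero(self):
        structure, tunnel = self.ring_structure(22, 0)
        glycine = HydrophobicSet(frozenset("AVLIMFWP"))
        score = score_tunnel(structure, tunnel, glycine)
        assert score.hydrophobic_count == 0
        assert score.hydrophobic_fraction == 0

    def test_fraction_invariant_to_renumbering(self, straight_toy):
        a = generate_structure(ToyStructureSpec(seed=9))
        b = generate_structure(ToyStructureSpec(seed=9, seed_residue=101))
        sa = read_structure(a.pdb_text)
        sb = read_structure(b.pdb_text)
        ta = find_tunnels(sa, 1, TOY_TUNNEL_PARAMS)
        tb = find_tunnels(sb, 101, TOY_TUNNEL_PARAMS)
        assert score_tunnel(sa, ta).hydrophobic_fraction == \
            score_tunnel(sb, tb).hydrophobic_fraction

    def test_empty_tunnel_list_rejected(self, straight_toy):
        s = read_structure(straight_toy.pdb_text)
        with pytest.raises(InputError):
            score_tunnel(s, [])


class TestClassifyShape:
    def test_straight_cylinder_classified_straight(self, straight_toy):
        s = read_structure(straight_toy.pdb_text)
        t = find_tunnels(s, 1, TOY_TUNNEL_PARAMS)[0]
        assert classify_shape(t) == "straight"

    def test_bend_90_classified_bent(self, bent_toy):
        s = read_structure(bent_toy.pdb_text)
        t = find_tunnels(s, 1, TOY_TUNNEL_PARAMS)[0]
        assert classify_shape(t) == "bent"

    def test_threshold_sweep_matches_analytic_straightness(self):
        # synthetic bends: classification boundary at the analytic value
        for angle in (0.0, 40.0, 80.0, 120.0):
            theta = np.radians(angle)
            analytic = np.sqrt(2 + 2 * np.cos(theta)) / 2
            centerline = np.array([[0, 0, 0], [0, 0, 10],
                                   [10 * np.sin(theta), 0, 10 + 10 * np.cos(theta)]],
                                  dtype=float)
            arc = 20.0
            chord = float(np.linalg.norm(centerline[-1] - centerline[0]))
            t = Tunnel(centerline=centerline, radii=np.array([1.0] * 3),
                       seed_residue=1, mouth=centerline[-1], arc_length=arc,
                       straightness=chord / arc)
            assert t.straightness == pytest.approx(analytic, abs=1e-12)
            for threshold in (0.5, 0.85, 0.95):
                expect = "straight" if analytic >= threshold else "bent"
                assert classify_shape(t, threshold) == expect
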