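"""Structure parsing, node selection, fragments and superposition."""

import numpy as np
import pytest

import cugdyn as cd
from cugdyn.structures import EmptyStructureError, ModifiedResidueError

from conftest import random_nodes


def _all_coords(structure):
    return np.vstack([a.coords for r in structure.residues() for a in r.atoms])


class TestPdbRoundTrip:
    def test_single_model(self, capped2, tmp_path):
        path = cd.write_pdb(capped2, tmp_path / "capped2.pdb")
        back = cd.read_pdb(path)
        assert len(back) == 1
        assert [c.sequence for c in back[0].chains] == ["GCUGCUGC", "GCUGCUGC"]
        assert back[0].n_residues == 16
        np.testing.assert_allclose(_all_coords(back[0]), _all_coords(capped2),
                                   atol=1e-3)

    def test_multi_model(self, nodes_cg2, tmp_path):
        dim = 3 * nodes_cg2.n_nodes
        model = cd.GenerativeModel(nodes_cg2, np.eye(dim)[:, :2],
                                   np.array([1.0, 0.5]), seed=3)
        path, frames = cd.synthetic_trajectory(model, 7, tmp_path / "traj.pdb")
        back = cd.read_pdb(path)
        assert len(back) == 7
        got = cd.select_nodes(back[2], "CG2")
        np.testing.assert_allclose(got.coords, frames[2].coords, atol=1e-3)

    def test_solvent_only_is_empty(self, tmp_path):
        path = tmp_path / "water.pdb"
        path.write_text(
            "ATOM      1  O   HOH A   1       0.000   0.000   0.000  1.00  0.00           O\n"
            "END\n"
        )
        with pytest.raises(EmptyStructureError):
            cd.read_pdb(path)

    def test_missing_file(self, tmp_path):
        with pytest.raises(IOError):
            cd.read_pdb(tmp_path / "nope.pdb")

    def test_modified_residue_needs_alias(self, tmp_path):
        lines = [
            "ATOM      1  C1' 5BU A   1       0.000   0.000   0.000  1.00  0.00           C",
            "ATOM      2  N3  5BU A   1       1.400   0.000   0.000  1.00  0.00           N",
            "END",
        ]
        path = tmp_path / "mod.pdb"
        path.write_text("\n".join(lines) + "\n")
        with pytest.raises(ModifiedResidueError):
            cd.read_pdb(path)
        structure = cd.read_pdb(path, aliases={"5BU": "U"})[0]
        assert next(structure.residues()).name == "U"

    def test_altloc_highest_occupancy(self, tmp_path):
        lines = [
            "ATOM      1  C1'AU   A   1       0.000   0.000   0.000  0.30 10.00           C",
            "ATOM      2  C1'BU   A   1       5.000   0.000   0.000  0.70 10.00           C",
            "END",
        ]
        path = tmp_path / "altloc.pdb"
        path.write_text("\n".join(lines) + "\n")
        res = next(cd.read_pdb(path)[0].residues())
        assert res.atom("C1'").coords[0] == pytest.approx(5.0)


class TestNodeSelection:
    @pytest.mark.parametrize("scheme,expected", [("CG2", 70), ("CG1", 52)])
    def test_duplex_counts(self, duplex3, scheme, expected):
        # 18 nt x scheme size, minus the two 5'-terminal phosphates
        assert cd.select_nodes(duplex3, scheme).n_nodes == expected

    def test_all_heavy_atoms_single_residue(self, duplex3):
        res = duplex3.chains[0].residues[0]   # 5'-terminal C
        single = cd.RnaStructure([cd.Chain("A", [res])])
        nodes = cd.select_nodes(single, "ALL")
        assert nodes.n_nodes == len(res.heavy_atoms)

    def test_unknown_scheme(self, duplex3):
        with pytest.raises(ValueError, match="scheme"):
            cd.select_nodes(duplex3, "CG9")

    def test_labels_unique_and_ordered(self, nodes_cg2):
        assert len(set(nodes_cg2.labels)) == nodes_cg2.n_nodes
        chain_a = [lab for lab in nodes_cg2.labels if lab[0] == "A"]
        assert chain_a == sorted(chain_a, key=lambda lab: lab[1])


class TestFragments:
    @pytest.mark.parametrize("n_rep,expected", [(3, 1), (4, 2), (5, 3), (6, 4)])
    def test_window_count(self, n_rep, expected):
        # overlapping windows advanced by one triplet: R - 3 + 1 of them
        duplex = cd.build_cug_duplex(n_rep)
        frags = cd.extract_cug_fragments(duplex, n_repeats=3)
        assert len(frags) == expected
        for f in frags:
            assert [c.sequence for c in f.chains] == ["CUGCUGCUG"] * 2

    def test_stride_three_gives_disjoint_windows(self):
        duplex = cd.build_cug_duplex(6)
        assert len(cd.extract_cug_fragments(duplex, 3, stride=3)) == 2

    def test_too_short_tract_gives_empty_list(self):
        duplex = cd.build_cug_duplex(2)
        assert cd.extract_cug_fragments(duplex, n_repeats=3) == []

    def test_non_cug_duplex_gives_empty_list(self):
        duplex = cd.build_aform_duplex("GCGCGCGC")
        assert cd.extract_cug_fragments(duplex) == []

    def test_fragment_coordinates_come_from_parent(self):
        duplex = cd.build_cug_duplex(4)
        frag = cd.extract_cug_fragments(duplex, 3)[1]   # window at repeats 2-4
        parent = duplex.chains[0].residues[3]           # first C of repeat 2
        np.testing.assert_array_equal(
            frag.chains[0].residues[0].atom("C1'").coords,
            parent.atom("C1'").coords,
        )


class TestSuperposition:
    def test_identity(self, rng):
        x = random_nodes(rng, 10).coords
        rot, trans, rmsd = cd.kabsch_superpose(x, x)
        np.testing.assert_allclose(rot, np.eye(3), atol=1e-10)
        assert rmsd == pytest.approx(0.0, abs=1e-10)

    def test_recovers_known_rotation(self, rng):
        x = random_nodes(rng, 12).coords
        applied = np.array([[0.0, -1.0, 0.0], [1.0, 0.0, 0.0], [0.0, 0.0, 1.0]])
        moved = x @ applied.T + np.array([1.0, -2.0, 3.0])
        rot, trans, rmsd = cd.kabsch_superpose(moved, x)
        assert rmsd == pytest.approx(0.0, abs=1e-8)
        np.testing.assert_allclose(rot, applied.T, atol=1e-8)

    def test_rmsd_invariant_under_rigid_transform(self, rng):
        x = random_nodes(rng, 15).coords
        y = x + rng.normal(scale=0.5, size=x.shape)
        _, _, rmsd0 = cd.kabsch_superpose(y, x)
        theta = 1.1
        rot = np.array([[np.cos(theta), -np.sin(theta), 0],
                        [np.sin(theta), np.cos(theta), 0], [0, 0, 1.0]])
        _, _, rmsd1 = cd.kabsch_superpose(y @ rot.T + 7.0, x)
        _, _, rmsd2 = cd.kabsch_superpose(y, x @ rot.T - 3.0)
        assert rmsd1 == pytest.approx(rmsd0, abs=1e-8)
        assert rmsd2 == pytest.approx(rmsd0, abs=1e-8)

    def test_noise_rmsd_scale(self):
        # isotropic noise of std sigma on both? one side: E[rmsd^2] ~ 3 sigma^2
        # minus the rigid-body fit absorption; Monte-Carlo over seeds
        sigma = 0.3
        vals = []
        for seed in range(20):
            g = np.random.default_rng(seed)
            x = g.uniform(0, 10, (50, 3))
            y = x + g.normal(scale=sigma, size=x.shape)
            vals.append(cd.kabsch_superpose(y, x)[2])
        assert np.mean(vals) == pytest.approx(sigma * np.sqrt(3.0), rel=0.1)

    @pytest.mark.parametrize("bad", ["mismatch", "too_few"])
    def test_errors(self, rng, bad):
        x = random_nodes(rng, 5).coords
        with pytest.raises(ValueError):
            if bad == "mismatch":
                cd.kabsch_superpose(x, x[:4])
            else:
                cd.kabsch_superpose(x[:2], x[:2])


class TestAlignEnsemble:
    def test_rigid_copies_collapse(self, nodes_cg2, rng):
        conformers = []
        for _ in range(5):
            theta = rng.uniform(0, 2 * np.pi)
            rot = np.array([[np.cos(theta), -np.sin(theta), 0],
                            [np.sin(theta), np.cos(theta), 0], [0, 0, 1.0]])
            conformers.append(nodes_cg2.with_coords(
                nodes_cg2.coords @ rot.T + rng.uniform(-20, 20, 3)))
        ens = cd.align_ensemble(conformers)
        assert ens.aligned
        for t in range(1, 5):
            assert np.abs(ens.coords[t] - ens.coords[0]).max() < 1e-6

    def test_mean_is_fixed_point(self, nodes_cg2, rng):
        conformers = [nodes_cg2.with_coords(
            nodes_cg2.coords + rng.normal(scale=0.4, size=nodes_cg2.coords.shape))
            for _ in range(6)]
        ens = cd.align_ensemble(conformers)
        refit = cd.superpose_coords(ens.mean, ens.mean)
        np.testing.assert_allclose(refit, ens.mean, atol=1e-8)

    def test_label_mismatch_reports_node(self, nodes_cg2):
        changed = list(nodes_cg2.labels)
        changed[0] = (changed[0][0], changed[0][1], changed[0][2], "O5'")
        other = cd.NodeSet(nodes_cg2.coords, changed)
        with pytest.raises(ValueError, match="first mismatch"):
            cd.align_ensemble([nodes_cg2, other])
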