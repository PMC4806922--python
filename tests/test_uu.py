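"""U-U pair detection, geometry, type classification and clustering."""

import copy

import numpy as np
import pytest

import cugdyn as cd
from cugdyn.uu import TYPE_REQUIREMENTS, groove_axis


def _rigid(structure, seed=0):
    rng = np.random.default_rng(seed)
    theta = rng.uniform(0, 2 * np.pi)
    rot = np.array([[np.cos(theta), -np.sin(theta), 0],
                    [np.sin(theta), np.cos(theta), 0], [0, 0, 1.0]])
    axis = np.linalg.qr(rng.standard_normal((3, 3)))[0]
    rot = axis @ rot @ axis.T
    if np.linalg.det(rot) < 0:
        rot = -rot
    return structure.transformed(rot, rng.uniform(-30, 30, 3))


class TestFindPairs:
    def test_capped_two_repeats_has_two(self, capped2):
        pairs = cd.find_uu_pairs(capped2)
        assert len(pairs) == 2
        for p in pairs:
            assert p.res_a.name == p.res_b.name == "U"

    def test_one_per_repeat(self):
        assert len(cd.find_uu_pairs(cd.build_cug_duplex(6))) == 6

    def test_watson_crick_duplex_has_none(self):
        duplex = cd.build_aform_duplex("GCGCGCGC")
        assert cd.find_uu_pairs(duplex) == []

    def test_flanks_are_canonical(self, capped2):
        pair = cd.find_uu_pairs(capped2)[0]
        for fa, fb in (pair.flank_5, pair.flank_3):
            assert {fa.name, fb.name} == {"C", "G"}


class TestHBonds:
    def test_builder_default_is_stretched_wobble(self, capped2):
        bonds = cd.detect_hbonds(cd.find_uu_pairs(capped2)[0])
        assert len(bonds) == 1
        assert bonds[0].distance == pytest.approx(2.9, abs=0.05)
        assert bonds[0].acceptor.endswith("O4")

    @pytest.mark.parametrize("target,expected", [("I", 2), ("III", 0), ("IV", 1)])
    def test_perturbed_counts(self, capped2, target, expected):
        perturbed = cd.perturb_uu(capped2, 0, target)
        pair = cd.find_uu_pairs(perturbed)[0]
        assert len(cd.detect_hbonds(pair)) == expected

    def test_all_far_means_zero(self, capped2):
        pair = cd.find_uu_pairs(cd.perturb_uu(capped2, 0, "III"))[0]
        assert cd.detect_hbonds(pair, dist_cutoff=3.5) == []

    def test_missing_atom_names_residue(self, capped2):
        broken = capped2.copy()
        pair = cd.find_uu_pairs(broken)[0]
        pair.res_a.atoms = [a for a in pair.res_a.atoms if a.name != "O4"]
        with pytest.raises(ValueError, match="O4"):
            cd.detect_hbonds(pair)


class TestGeometry:
    def test_c1c1_watson_crick_scale(self, capped2):
        pair = cd.find_uu_pairs(capped2)[0]
        assert cd.c1c1_distance(pair) == pytest.approx(10.4, abs=0.05)

    def test_measurements_rigid_invariant(self, capped2):
        pair0 = cd.find_uu_pairs(capped2)[0]
        moved = _rigid(capped2, seed=3)
        pair1 = cd.find_uu_pairs(moved)[0]
        assert cd.c1c1_distance(pair1) == pytest.approx(
            cd.c1c1_distance(pair0), abs=1e-8)
        assert cd.inclination(pair1)[1] == pytest.approx(
            cd.inclination(pair0)[1], abs=1e-8)
        assert len(cd.detect_hbonds(pair1)) == len(cd.detect_hbonds(pair0))

    def test_unperturbed_is_not_inclined(self, capped2):
        label, disp = cd.inclination(cd.find_uu_pairs(capped2)[0])
        assert label == "none"
        assert abs(disp) < 1e-8

    @pytest.mark.parametrize("shift,expected", [(1.5, "major"), (-1.5, "minor")])
    def test_groove_shift_flips_label(self, capped2, shift, expected):
        moved = capped2.copy()
        pair = cd.find_uu_pairs(moved)[0]
        g = groove_axis(pair)
        for res in (pair.res_a, pair.res_b):
            for atom in res.atoms:
                if atom.name in ("N1", "C2", "O2", "N3", "C4", "O4", "C5", "C6"):
                    atom.coords = atom.coords + shift * g
        label, disp = cd.inclination(pair)
        assert label == expected
        assert disp == pytest.approx(shift, abs=0.01)


class TestClassification:
    @pytest.mark.parametrize("target", list("I II III IV V VI".split()))
    def test_round_trip_all_types(self, capped2, target):
        perturbed = cd.perturb_uu(capped2, 0, target)
        cls = cd.classify_uu(cd.find_uu_pairs(perturbed)[0])
        n_hb, incl = TYPE_REQUIREMENTS[target]
        assert cls.type_label == target
        assert cls.n_hbonds == n_hb
        assert cls.inclination == incl
        assert not cls.atypical

    def test_reperturbing_same_type_is_stable(self, capped2):
        once = cd.perturb_uu(capped2, 0, "IV")
        twice = cd.perturb_uu(once, 0, "IV")
        a = np.vstack([at.coords for r in once.residues() for at in r.atoms])
        b = np.vstack([at.coords for r in twice.residues() for at in r.atoms])
        assert np.abs(a - b).max() < 0.2

    def test_other_pairs_untouched(self, capped2):
        perturbed = cd.perturb_uu(capped2, 0, "V")
        orig = cd.find_uu_pairs(capped2)[1]
        new = cd.find_uu_pairs(perturbed)[1]
        np.testing.assert_array_equal(
            np.vstack([a.coords for a in new.res_a.atoms]),
            np.vstack([a.coords for a in orig.res_a.atoms]))

    def test_classification_rigid_invariant(self, capped2):
        perturbed = cd.perturb_uu(capped2, 0, "II")
        moved = _rigid(perturbed, seed=8)
        assert cd.classify_uu(cd.find_uu_pairs(moved)[0]).type_label == "II"

    def test_unknown_type_rejected(self, capped2):
        with pytest.raises(ValueError, match="I..VI"):
            cd.perturb_uu(capped2, 0, "VII")


def _shifted_copy(structure, pair_index, shift, jitter, seed):
    """Copy with one U-U pair's bases moved along the groove axis + jitter."""
    rng = np.random.default_rng(seed)
    out = structure.copy()
    pair = cd.find_uu_pairs(out)[pair_index]
    g = groove_axis(pair)
    for res in (pair.res_a, pair.res_b):
        for atom in res.atoms:
            if atom.name in ("N1", "C2", "O2", "N3", "C4", "O4", "C5", "C6"):
                atom.coords = (atom.coords + shift * g
                               + rng.normal(scale=jitter, size=3))
    return out


class TestClustering:
    def test_identical_frames_single_cluster(self, capped2):
        result = cd.cluster_uu_trajectory([capped2] * 6, 0)
        assert result.n_clusters == 1
        assert result.populations[0] == pytest.approx(1.0)

    def test_two_geometry_mixture_splits_evenly(self, capped2):
        frames = [_shifted_copy(capped2, 0, -2.5, 0.05, seed=t)
                  for t in range(10)]
        frames += [_shifted_copy(capped2, 0, 2.5, 0.05, seed=100 + t)
                   for t in range(10)]
        dist = cd.uu_pairwise_rmsd(frames, 0)
        assert dist[0, 10] > 3.0                  # inter-cluster separation
        result = cd.cluster_uu_trajectory(frames, 0, threshold=3.0)
        assert result.n_clusters == 2
        np.testing.assert_allclose(result.populations, [0.5, 0.5])
        assert result.populations.sum() == pytest.approx(1.0)

    def test_huge_threshold_merges_everything(self, capped2):
        frames = [_shifted_copy(capped2, 0, s, 0.05, seed=i)
                  for i, s in enumerate([-2.5, 0.0, 2.5, 2.5])]
        result = cd.cluster_uu_trajectory(frames, 0, threshold=1000.0)
        assert result.n_clusters == 1

    def test_matches_naive_agglomeration(self, capped2):
        frames = []
        for t in range(7):
            frames.append(_shifted_copy(capped2, 0, -2.0, 0.3, seed=t))
        for t in range(6):
            frames.append(_shifted_copy(capped2, 0, 2.0, 0.3, seed=50 + t))
        threshold = 3.0
        dist = cd.uu_pairwise_rmsd(frames, 0)
        # brute-force average-linkage agglomeration
        clusters = [[i] for i in range(len(frames))]
        while len(clusters) > 1:
            best = None
            for a in range(len(clusters)):
                for b in range(a + 1, len(clusters)):
                    d = np.mean([dist[i, j] for i in clusters[a]
                                 for j in clusters[b]])
                    if best is None or d < best[0]:
                        best = (d, a, b)
            if best[0] > threshold:
                break
            d, a, b = best
            clusters[a] = clusters[a] + clusters[b]
            del clusters[b]
        expected = {frozenset(c) for c in clusters}
        result = cd.cluster_uu_trajectory(frames, 0, threshold=threshold)
        got = {frozenset(np.nonzero(result.labels == k)[0].tolist())
               for k in range(1, result.n_clusters + 1)}
        assert got == expected

    def test_absent_pair_names_frame(self, capped2):
        watson_crick = cd.build_aform_duplex("GCGCGCGC")
        with pytest.raises(ValueError, match="frame 1"):
            cd.cluster_uu_trajectory([capped2, watson_crick], 0)

    def test_too_few_frames(self, capped2):
        with pytest.raises(ValueError):
            cd.cluster_uu_trajectory([capped2], 0)
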