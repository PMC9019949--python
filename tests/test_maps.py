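"""Distance maps, the mutual cutoff filter, and difference-map construction."""

import numpy as np
import pytest

from diffqa.maps import (
    DistanceMap,
    MapError,
    MapSource,
    apply_threshold_filter,
    coords_to_distance_map,
    difference_map,
    featurize_model,
    model_distance_map,
    read_predicted_map,
)
from diffqa.synthetic import generate_chain, write_pdb

from conftest import random_symmetric_map


def brute_force_filter(a, b, threshold):
    n = a.shape[0]
    a_star, b_star = a.copy(), b.copy()
    for i in range(n):
        for j in range(n):
            if a[i, j] > threshold or b[i, j] > threshold:
                a_star[i, j] = 0.0
                b_star[i, j] = 0.0
    return a_star, b_star


def brute_force_difference(a_star, b_star):
    n = a_star.shape[0]
    u = np.zeros_like(a_star)
    for i in range(n):
        for j in range(n):
            if i < j:
                u[i, j] = a_star[i, j] - b_star[i, j]
    return u


class TestModelDistanceMap:
    def test_three_four_five_triangle(self, tiny_pdb):
        # CB of an isolated pair is offset from CA but GLY falls back to CA,
        # so an all-GLY model measures CA-CA distances exactly.
        path = tiny_pdb([[0, 0, 0], [0, 0, 3.8], [3, 4, 3.8], [3, 4, 7.6],
                         [0, 4, 7.6]], residue_names=["GLY"] * 5)
        dm = model_distance_map(path)
        assert dm.values[1, 2] == pytest.approx(5.0, abs=1e-3)
        assert dm.source is MapSource.MODEL

    def test_symmetry_and_zero_diagonal(self, tiny_pdb, rng):
        path = tiny_pdb(generate_chain(8, seed=5))
        dm = model_distance_map(path)
        np.testing.assert_array_equal(dm.values, dm.values.T)
        assert np.all(np.diag(dm.values) == 0)

    def test_matches_brute_force_euclidean(self, tiny_pdb):
        coords = generate_chain(5, seed=11)
        path = tiny_pdb(coords, residue_names=["GLY"] * 5)
        dm = model_distance_map(path)
        expected = np.zeros((5, 5))
        for i in range(5):
            for j in range(5):
                expected[i, j] = np.sqrt(np.sum((coords[i] - coords[j]) ** 2))
        # PDB coordinates are written at 1e-3 A precision
        np.testing.assert_allclose(dm.values, expected, atol=5e-3)

    def test_corrupt_coordinate_names_line(self, tmp_path):
        path = tmp_path / "bad.pdb"
        good = "ATOM      1  CA  ALA A   1       0.000   0.000   0.000  1.00  0.00           C"
        bad = good.replace("   0.000   0.000   0.000", "   0.000   xx.yy   0.000")
        path.write_text(good + "\n" + bad.replace("A   1", "A   2") + "\nEND\n")
        with pytest.raises(MapError, match=r"bad\.pdb:2"):
            model_distance_map(str(path))

    def test_single_residue_is_degenerate(self, tiny_pdb):
        path = tiny_pdb([[0, 0, 0]])
        with pytest.raises(MapError, match="at least 2 residues"):
            model_distance_map(path)

    def test_interior_gap_filled_above_cutoff(self, tmp_path):
        coords = generate_chain(6, seed=3)
        full = tmp_path / "full.pdb"
        write_pdb(full, coords, ["GLY"] * 6)
        # drop residue 3 (resseq 3) to create an interior gap
        lines = [l for l in full.read_text().splitlines()
                 if not (l.startswith("ATOM") and int(l[22:26]) == 3)]
        gapped = tmp_path / "gap.pdb"
        gapped.write_text("\n".join(lines) + "\n")
        dm = model_distance_map(str(gapped), expected_length=6)
        assert dm.length == 6
        off_diag = np.delete(dm.values[2], 2)
        assert np.all(off_diag > 100)  # far above any sensible cutoff


class TestReadPredictedMap:
    def test_identity_read(self, tmp_path, rng):
        m = random_symmetric_map(rng, 3)
        path = tmp_path / "m.map"
        np.savetxt(path, m, fmt="%.6f")
        dm = read_predicted_map(str(path))
        np.testing.assert_allclose(dm.values, m, atol=1e-6)
        assert dm.source is MapSource.PREDICTED

    def test_mild_asymmetry_is_symmetrized(self, tmp_path):
        m = np.array([[0.0, 8.0], [8.2, 0.0]])
        path = tmp_path / "m.map"
        np.savetxt(path, m, fmt="%.6f")
        dm = read_predicted_map(str(path))
        assert dm.values[0, 1] == pytest.approx(8.1)
        assert dm.values[1, 0] == pytest.approx(8.1)

    def test_large_asymmetry_rejected(self, tmp_path):
        m = np.array([[0.0, 8.0], [9.0, 0.0]])
        path = tmp_path / "m.map"
        np.savetxt(path, m, fmt="%.6f")
        with pytest.raises(MapError, match="asymmetry"):
            read_predicted_map(str(path))

    def test_dimension_mismatch(self, tmp_path, rng):
        path = tmp_path / "m.map"
        np.savetxt(path, rng.uniform(0, 1, (4, 5)), fmt="%.4f")
        with pytest.raises(MapError, match="square"):
            read_predicted_map(str(path))
        sq = random_symmetric_map(rng, 4)
        np.savetxt(path, sq, fmt="%.4f")
        with pytest.raises(MapError, match="expected length 5"):
            read_predicted_map(str(path), expected_length=5)

    def test_non_numeric_token_position(self, tmp_path):
        path = tmp_path / "m.map"
        path.write_text("0.0 1.0\n1.0 abc\n")
        with pytest.raises(MapError, match="row 2, column 2"):
            read_predicted_map(str(path))


class TestThresholdFilter:
    def test_mutual_rule_zeroes_both(self):
        a = np.zeros((3, 3))
        b = np.zeros((3, 3))
        a[0, 2] = a[2, 0] = 20.0
        b[0, 2] = b[2, 0] = 10.0
        pair = apply_threshold_filter(
            DistanceMap(a, MapSource.PREDICTED),
            DistanceMap(b, MapSource.MODEL), 16.0,
        )
        assert pair.a_star[0, 2] == 0.0
        assert pair.b_star[0, 2] == 0.0

    def test_identity_below_cutoff(self, rng):
        a = random_symmetric_map(rng, 5, high=15.0)
        b = random_symmetric_map(rng, 5, high=15.0)
        pair = apply_threshold_filter(
            DistanceMap(a, MapSource.PREDICTED),
            DistanceMap(b, MapSource.MODEL), 16.0,
        )
        np.testing.assert_array_equal(pair.a_star, a)
        np.testing.assert_array_equal(pair.b_star, b)

    def test_matches_elementwise_oracle(self, rng):
        a = random_symmetric_map(rng, 6)
        b = random_symmetric_map(rng, 6)
        pair = apply_threshold_filter(
            DistanceMap(a, MapSource.PREDICTED),
            DistanceMap(b, MapSource.MODEL), 16.0,
        )
        ea, eb = brute_force_filter(a, b, 16.0)
        np.testing.assert_array_equal(pair.a_star, ea)
        np.testing.assert_array_equal(pair.b_star, eb)

    def test_idempotent(self, rng):
        a = random_symmetric_map(rng, 7)
        b = random_symmetric_map(rng, 7)
        pair = apply_threshold_filter(
            DistanceMap(a, MapSource.PREDICTED),
            DistanceMap(b, MapSource.MODEL), 16.0,
        )
        again = apply_threshold_filter(
            DistanceMap(pair.a_star, MapSource.PREDICTED),
            DistanceMap(pair.b_star, MapSource.MODEL), 16.0,
        )
        np.testing.assert_array_equal(again.a_star, pair.a_star)
        np.testing.assert_array_equal(again.b_star, pair.b_star)

    def test_length_mismatch(self, rng):
        a = DistanceMap(random_symmetric_map(rng, 4), MapSource.PREDICTED)
        b = DistanceMap(random_symmetric_map(rng, 5), MapSource.MODEL)
        with pytest.raises(MapError, match="mismatch"):
            apply_threshold_filter(a, b, 16.0)


class TestDifferenceMap:
    def test_equal_inputs_give_zero(self, rng):
        a = random_symmetric_map(rng, 5, high=14.0)
        pair = apply_threshold_filter(
            DistanceMap(a, MapSource.PREDICTED),
            DistanceMap(a.copy(), MapSource.MODEL), 16.0,
        )
        u = difference_map(pair)
        np.testing.assert_array_equal(u.values, np.zeros((5, 5)))

    def test_hand_worked_example(self):
        a = np.zeros((3, 3))
        b = np.zeros((3, 3))
        a[0, 1] = a[1, 0] = 5.0
        b[0, 1] = b[1, 0] = 6.0
        pair = apply_threshold_filter(
            DistanceMap(a, MapSource.PREDICTED),
            DistanceMap(b, MapSource.MODEL), 16.0,
        )
        u = difference_map(pair)
        assert u.values[0, 1] == -1.0
        assert u.values[1, 0] == 0.0
        assert np.count_nonzero(u.values) == 1

    def test_lower_triangle_exactly_zero(self, rng):
        a = random_symmetric_map(rng, 9)
        b = random_symmetric_map(rng, 9)
        pair = apply_threshold_filter(
            DistanceMap(a, MapSource.PREDICTED),
            DistanceMap(b, MapSource.MODEL), 16.0,
        )
        u = difference_map(pair).values
        assert np.all(np.tril(u) == 0)

    def test_antisymmetric_in_arguments(self, rng):
        a = random_symmetric_map(rng, 6)
        b = random_symmetric_map(rng, 6)
        u_ab = difference_map(apply_threshold_filter(
            DistanceMap(a, MapSource.PREDICTED),
            DistanceMap(b, MapSource.MODEL), 16.0)).values
        u_ba = difference_map(apply_threshold_filter(
            DistanceMap(b, MapSource.PREDICTED),
            DistanceMap(a, MapSource.MODEL), 16.0)).values
        np.testing.assert_allclose(u_ab, -u_ba)

    def test_nonzero_entries_respect_filter(self, rng):
        a = random_symmetric_map(rng, 8)
        b = random_symmetric_map(rng, 8)
        pair = apply_threshold_filter(
            DistanceMap(a, MapSource.PREDICTED),
            DistanceMap(b, MapSource.MODEL), 16.0,
        )
        u = difference_map(pair).values
        for i, j in zip(*np.nonzero(u)):
            assert i < j
            assert a[i, j] <= 16.0
            assert b[i, j] <= 16.0


class TestFeaturizeModel:
    def _write_pair(self, tmp_path, length=10, seed=0):
        coords = generate_chain(length, seed=seed)
        pdb = tmp_path / "decoy.pdb"
        names = ["GLY"] * length  # CA convention keeps A == B achievable
        write_pdb(pdb, coords, names)
        a = coords_to_distance_map(coords)
        mp = tmp_path / "pred.map"
        np.savetxt(mp, a, fmt="%.6f")
        return str(pdb), str(mp), coords

    def test_perfect_model_gives_near_zero_map(self, tmp_path):
        pdb, mp, _ = self._write_pair(tmp_path)
        rec = featurize_model(pdb, mp)
        # only PDB coordinate rounding (1e-3 A) separates A from B
        assert np.max(np.abs(rec.difference_map.values)) < 5e-3

    def test_matches_manual_composition(self, tmp_path):
        pdb, mp, _ = self._write_pair(tmp_path, seed=4)
        rec = featurize_model(pdb, mp, threshold=16.0)
        a = read_predicted_map(mp)
        b = model_distance_map(pdb, "CB", expected_length=a.length)
        u = difference_map(apply_threshold_filter(a, b, 16.0))
        np.testing.assert_array_equal(rec.difference_map.values, u.values)

    def test_deterministic(self, tmp_path):
        pdb, mp, _ = self._write_pair(tmp_path, seed=9)
        u1 = featurize_model(pdb, mp).difference_map.values
        u2 = featurize_model(pdb, mp).difference_map.values
        np.testing.assert_array_equal(u1, u2)

    def test_length_mismatch_reports_both(self, tmp_path, rng):
        pdb, _, _ = self._write_pair(tmp_path, length=9)
        mp = tmp_path / "big.map"
        np.savetxt(mp, random_symmetric_map(rng, 10), fmt="%.4f")
        with pytest.raises(MapError, match="9.*10x10"):
            featurize_model(pdb, str(mp))
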