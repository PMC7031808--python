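"""Coarse-grained dimer criterion and orientation classification."""

import numpy as np
import pandas as pd
import pytest

from sdpfit.dimers import (
    DEFAULT_DISTANCE_SET,
    GeometryError,
    MARKERS,
    PeptideMarkers,
    classify_orientation,
    dimer_statistics,
    is_dimer,
    load_markers_csv,
    marker_distances,
)


def helix(pid, species, com, axis, n_frames=1, length=3.0):
    """Straight helix markers: COM at ``com``, N/C at +/- axis*length/2."""
    com = np.asarray(com, float)
    axis = np.asarray(axis, float)
    axis = axis / np.linalg.norm(axis)
    coords = {
        "COM": np.tile(com, (n_frames, 1)),
        "N": np.tile(com - axis * length / 2, (n_frames, 1)),
        "C": np.tile(com + axis * length / 2, (n_frames, 1)),
    }
    return PeptideMarkers(pid, species, coords)


class TestCriterion:
    def test_distant_peptides_are_not_dimers(self):
        a = helix("a", "MG2a", [0, 0, 0], [1, 0, 0])
        b = helix("b", "MG2a", [10, 10, 0], [1, 0, 0])
        assert not is_dimer(a, b, 0)

    def test_two_close_distances_suffice(self):
        # COM-COM = 0.9 and C-C = 0.8 nm below cutoff, N-N above
        a = PeptideMarkers("a", "X", {
            "COM": [[0.0, 0, 0]], "N": [[-2.0, 0, 0]], "C": [[2.0, 0, 0]]})
        b = PeptideMarkers("b", "X", {
            "COM": [[0.9, 0, 0]], "N": [[-0.9, 2.0, 0]], "C": [[2.8, 0, 0]]})
        d = marker_distances(a, b, 0)
        assert np.count_nonzero(d < 1.0) == 2
        assert is_dimer(a, b, 0)

    def test_one_close_distance_is_not_enough(self):
        a = helix("a", "X", [0, 0, 0], [1, 0, 0], length=4.0)
        b = helix("b", "X", [0.9, 3.0, 0], [0, 1, 0], length=4.0)
        d = marker_distances(a, b, 0)
        assert np.count_nonzero(d < 1.0) <= 1
        assert not is_dimer(a, b, 0)

    def test_minimum_image_convention(self):
        box = [10.0, 10.0, 10.0]
        a = helix("a", "X", [0.2, 5, 5], [1, 0, 0], length=1.0)
        b = helix("b", "X", [9.8, 5, 5], [1, 0, 0], length=1.0)
        assert is_dimer(a, b, 0, box=box)
        assert not is_dimer(a, b, 0)  # 9.6 nm apart without wrapping

    def test_missing_frame_rejected(self):
        a = helix("a", "X", [0, 0, 0], [1, 0, 0])
        b = helix("b", "X", [0, 0.5, 0], [1, 0, 0])
        with pytest.raises(GeometryError):
            is_dimer(a, b, 5)

    def test_brute_force_oracle_on_random_walk(self):
        """Frame-by-frame agreement with a naive reimplementation of the
        >=2-of-5 rule on a 100-frame random-walk trajectory."""
        rng = np.random.default_rng(42)
        n_frames = 100
        peptides = []
        for pid in "abcd":
            com = np.cumsum(rng.normal(0, 0.4, (n_frames, 3)), axis=0)
            axis = rng.normal(0, 1, (n_frames, 3))
            axis /= np.linalg.norm(axis, axis=1, keepdims=True)
            coords = {"COM": com, "N": com - axis, "C": com + axis}
            peptides.append(PeptideMarkers(pid, "X", coords))

        def naive(a, b, f):
            pairs = [("COM", "COM"), ("N", "N"), ("C", "C"), ("N", "C"),
                     ("C", "N")]
            hits = 0
            for ma, mb in pairs:
                diff = a.coords[ma][f] - b.coords[mb][f]
                if float(np.sqrt((diff**2).sum())) < 1.0:
                    hits += 1
            return hits >= 2

        for f in range(n_frames):
            for i in range(4):
                for j in range(i + 1, 4):
                    assert is_dimer(peptides[i], peptides[j], f) == naive(
                        peptides[i], peptides[j], f)


class TestOrientation:
    def test_identical_axes_parallel(self):
        a = helix("a", "X", [0, 0, 0], [1, 0, 0])
        b = helix("b", "X", [0, 0.5, 0], [1, 0, 0])
        assert classify_orientation(a, b, 0) == "parallel"

    def test_reversed_axes_antiparallel(self):
        a = helix("a", "X", [0, 0, 0], [1, 0, 0])
        b = helix("b", "X", [0, 0.5, 0], [-1, 0, 0])
        assert classify_orientation(a, b, 0) == "antiparallel"

    @pytest.mark.parametrize("deg,expected", [(89, "parallel"),
                                              (91, "antiparallel")])
    def test_threshold_bracketing(self, deg, expected):
        th = np.deg2rad(deg)
        a = helix("a", "X", [0, 0, 0], [1, 0, 0])
        b = helix("b", "X", [0, 0.5, 0], [np.cos(th), np.sin(th), 0])
        assert classify_orientation(a, b, 0) == expected

    def test_exact_right_angle_breaks_to_antiparallel(self):
        a = helix("a", "X", [0, 0, 0], [1, 0, 0])
        b = helix("b", "X", [0, 0.5, 0], [0, 1, 0])
        assert classify_orientation(a, b, 0) == "antiparallel"

    def test_zero_axis_rejected(self):
        a = helix("a", "X", [0, 0, 0], [1, 0, 0])
        b = PeptideMarkers("b", "X", {
            "COM": [[0, 0.5, 0]], "N": [[0, 0.5, 0]], "C": [[0, 0.5, 0]]})
        with pytest.raises(GeometryError):
            classify_orientation(a, b, 0)


class TestStatistics:
    def test_single_parallel_heterodimer(self):
        a = helix("a", "MG2a", [0, 0, 0], [1, 0, 0], length=1.0)
        b = helix("b", "L18W-PGLa", [0, 0.5, 0], [1, 0, 0], length=1.0)
        stats = dimer_statistics([a, b])
        assert stats[("parallel", "hetero")] == 1.0
        assert sum(stats.values()) == 1.0

    def test_half_occupancy_over_two_frames(self):
        close = np.array([[0, 0.5, 0], [0, 5.0, 0]])
        a = PeptideMarkers("a", "X", {
            "COM": np.zeros((2, 3)), "N": np.tile([-0.5, 0, 0], (2, 1)),
            "C": np.tile([0.5, 0, 0], (2, 1))})
        b = PeptideMarkers("b", "X", {
            "COM": close, "N": close + [-0.5, 0, 0], "C": close + [0.5, 0, 0]})
        stats = dimer_statistics([a, b])
        assert stats[("parallel", "homo")] == 0.5

    def test_greedy_pairing_is_exclusive(self):
        # three mutually close peptides yield one dimer, not three
        ps = [helix(pid, "X", [0.3 * i, 0, 0], [1, 0, 0], length=0.5)
              for i, pid in enumerate("abc")]
        stats, records = dimer_statistics(ps, return_records=True)
        assert len(records) == 1
        assert sum(stats.values()) == 1.0

    def test_rigid_motion_invariance(self, rng):
        a = helix("a", "X", [0, 0, 0], [1, 0, 0], length=1.0)
        b = helix("b", "Y", [0.4, 0.3, 0], [-1, 0.2, 0], length=1.0)
        base = dimer_statistics([a, b])
        # random rotation + translation applied to every marker
        q, _ = np.linalg.qr(rng.normal(size=(3, 3)))
        if np.linalg.det(q) < 0:
            q[:, 0] *= -1
        shift = rng.normal(0, 5, 3)
        moved = []
        for p in (a, b):
            coords = {m: p.coords[m] @ q.T + shift for m in MARKERS}
            moved.append(PeptideMarkers(p.peptide_id, p.species, coords))
        assert dimer_statistics(moved) == base

    def test_input_order_invariance(self):
        a = helix("a", "MG2a", [0, 0, 0], [1, 0, 0], length=1.0)
        b = helix("b", "L18W-PGLa", [0, 0.5, 0], [-1, 0, 0], length=1.0)
        assert dimer_statistics([a, b]) == dimer_statistics([b, a])

    def test_planted_occupancy_recovered(self):
        """A trajectory with 30% planted dimer frames averages to ~0.3."""
        rng = np.random.default_rng(3)
        n_frames = 400
        present = rng.random(n_frames) < 0.3
        com_b = np.where(present[:, None], [0.0, 0.5, 0.0], [0.0, 8.0, 0.0])
        axis = np.array([0.5, 0, 0])
        a = PeptideMarkers("a", "X", {
            "COM": np.zeros((n_frames, 3)),
            "N": np.tile(-axis, (n_frames, 1)),
            "C": np.tile(axis, (n_frames, 1))})
        b = PeptideMarkers("b", "X", {
            "COM": com_b, "N": com_b - axis, "C": com_b + axis})
        stats = dimer_statistics([a, b])
        total = sum(stats.values())
        assert total == pytest.approx(present.mean(), abs=1e-12)
        assert abs(total - 0.3) < 0.05


class TestCSV:
    def test_roundtrip_and_box(self, tmp_path):
        rows = []
        for f in range(2):
            for pid, species, com in [("p1", "MG2a", [0, 0, 0]),
                                      ("p2", "L18W-PGLa", [0.4, 0.3, 0])]:
                com = np.asarray(com, float) + f * 0.1
                for marker, pos in [("COM", com), ("N", com - [0.5, 0, 0]),
                                    ("C", com + [0.5, 0, 0])]:
                    rows.append(dict(frame=f, peptide_id=pid, species=species,
                                     marker=marker, x=pos[0], y=pos[1],
                                     z=pos[2], box_x=10.0, box_y=10.0,
                                     box_z=10.0))
        path = tmp_path / "markers.csv"
        pd.DataFrame(rows).to_csv(path, index=False)
        peptides, box = load_markers_csv(path)
        assert len(peptides) == 2 and peptides[0].n_frames == 2
        np.testing.assert_allclose(box, [10.0, 10.0, 10.0])
        stats = dimer_statistics(peptides, box=box)
        assert stats[("parallel", "hetero")] == 1.0

    def test_missing_marker_rejected(self, tmp_path):
        df = pd.DataFrame([dict(frame=0, peptide_id="p", species="X",
                                marker="COM", x=0, y=0, z=0)])
        path = tmp_path / "bad.csv"
        df.to_csv(path, index=False)
        with pytest.raises(GeometryError):
            load_markers_csv(path)
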