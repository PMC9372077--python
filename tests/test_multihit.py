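"""Consecutive-hit classification, orientation changes, and summaries."""

from dataclasses import replace

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from mhsfx.multihit import (HitLabel, MultiHitCriteria, RunSummary, classify,
                            orientation_change, orientation_histogram, split,
                            summarize)
from mhsfx.stream_io import FrameRecord, StreamDataset
from mhsfx.synthetic_data import (SimConfig, hit_window_for_double_fraction,
                                  simulate_stream)

from conftest import make_crystal, rotation_about


def make_dataset(frame_specs):
    """frame_specs: list of (train_id, pulse_id, [crystals])."""
    ds = StreamDataset()
    for i, (train, pulse, crystals) in enumerate(frame_specs):
        ds.frames.append(FrameRecord(frame_index=i, train_id=train,
                                     pulse_id=pulse,
                                     crystals=list(crystals)))
    return ds


class TestOrientationChange:
    def test_identity(self):
        ch = orientation_change(make_crystal(), make_crystal())
        assert (ch.angle_a, ch.angle_b, ch.angle_c) == (0.0, 0.0, 0.0)
        assert ch.ratio_a == ch.ratio_b == ch.ratio_c == pytest.approx(1.0)
        assert ch.summary_angle == 0.0

    def test_rigid_rotation_about_cstar(self):
        """3 deg about c* turns a* and b* by 3 deg and leaves c* fixed."""
        rot = rotation_about([0, 0, 1], 3.0)
        ch = orientation_change(make_crystal(), make_crystal(rotation=rot))
        assert ch.angle_a == pytest.approx(3.0, abs=1e-9)
        assert ch.angle_b == pytest.approx(3.0, abs=1e-9)
        assert ch.angle_c == pytest.approx(0.0, abs=1e-9)
        for r in (ch.ratio_a, ch.ratio_b, ch.ratio_c):
            assert r == pytest.approx(1.0, rel=1e-12)
        assert ch.summary_angle == pytest.approx(3.0)

    def test_pure_scaling(self):
        ch = orientation_change(make_crystal(), make_crystal(scale=1.12))
        assert ch.summary_angle == pytest.approx(0.0, abs=1e-9)
        for r in (ch.ratio_a, ch.ratio_b, ch.ratio_c):
            assert r == pytest.approx(1.12)

    def test_rotation_matrix_oracle(self):
        """Recovered angles match the applied per-vector rotation angles
        computed independently from the rotation matrix, to 1e-9."""
        rng = np.random.default_rng(7)
        basis = np.diag([0.126, 0.126, 0.265])
        for _ in range(200):
            rot = Rotation.random(rng=rng).as_matrix()
            ch = orientation_change(make_crystal(basis=basis),
                                    make_crystal(basis=basis, rotation=rot))
            for row, got in zip(basis, (ch.angle_a, ch.angle_b, ch.angle_c)):
                u = row / np.linalg.norm(row)
                expected = np.degrees(
                    np.arccos(np.clip(u @ rot @ u, -1.0, 1.0)))
                assert got == pytest.approx(expected, abs=1e-9)

    def test_zero_vector_rejected(self):
        good = make_crystal()
        bad = make_crystal()
        bad.astar = np.array([1e-300, 0.0, 0.0])
        with pytest.raises(ValueError):
            orientation_change(good, bad)


class TestClassify:
    def test_adjacent_same_basis(self):
        ds = make_dataset([(1, 0, [make_crystal()]), (1, 1, [make_crystal()])])
        res = classify(ds)
        assert res.labels[(0, 0)] is HitLabel.FIRST
        assert res.labels[(1, 0)] is HitLabel.SECOND
        assert len(res.pairs) == 1

    def test_large_rotation_stays_single(self):
        rot = rotation_about([1, 1, 0], 8.0)
        ds = make_dataset([(1, 0, [make_crystal()]),
                           (1, 1, [make_crystal(rotation=rot)])])
        res = classify(ds)
        assert all(v is HitLabel.SINGLE for v in res.labels.values())

    def test_nonadjacent_pulses_stay_single(self):
        ds = make_dataset([(1, 4, [make_crystal()]), (1, 6, [make_crystal()])])
        res = classify(ds)
        assert all(v is HitLabel.SINGLE for v in res.labels.values())

    def test_different_trains_stay_single(self):
        ds = make_dataset([(1, 5, [make_crystal()]), (2, 6, [make_crystal()])])
        res = classify(ds)
        assert all(v is HitLabel.SINGLE for v in res.labels.values())

    def test_length_mismatch_stays_single(self):
        ds = make_dataset([(1, 0, [make_crystal()]),
                           (1, 1, [make_crystal(scale=1.15)])])
        res = classify(ds)
        assert all(v is HitLabel.SINGLE for v in res.labels.values())

    def test_chain_of_three(self):
        ds = make_dataset([(1, 0, [make_crystal()]),
                           (1, 1, [make_crystal()]),
                           (1, 2, [make_crystal()])])
        res = classify(ds)
        assert res.labels[(0, 0)] is HitLabel.FIRST
        assert res.labels[(1, 0)] is HitLabel.SECOND
        assert res.labels[(2, 0)] is HitLabel.RUN_EXTRA
        assert len(res.pairs) == 1          # only the first pair counts
        assert len(res.links) == 2

    def test_multi_crystal_frame_greedy_smallest_angle(self):
        """With two candidates, the smaller orientation change wins."""
        near = make_crystal(rotation=rotation_about([0, 0, 1], 0.5))
        far = make_crystal(rotation=rotation_about([0, 0, 1], 3.0))
        ds = make_dataset([(1, 0, [far, make_crystal()]),
                           (1, 1, [near])])
        res = classify(ds)
        assert res.labels[(0, 1)] is HitLabel.FIRST   # exact match beats 3 deg
        assert res.labels[(0, 0)] is HitLabel.SINGLE
        assert res.labels[(1, 0)] is HitLabel.SECOND

    def test_pair_symmetry_and_shift_invariance(self):
        cfg = SimConfig(n_trains=8, seed=5, arrival_rate=0.08, n_reflections=0)
        ds, _ = simulate_stream(cfg)
        res = classify(ds)
        assert res.count(HitLabel.FIRST) == res.count(HitLabel.SECOND)
        for f in ds.frames:
            f.train_id += 1000
        res2 = classify(ds)
        assert res.labels == res2.labels

    def test_false_positive_control(self):
        """Purely random orientations: double rate below 0.2% over ~10k
        adjacent pairs (orientation scrambling via an extreme tumble)."""
        cfg = SimConfig(n_trains=330, seed=9, arrival_rate=0.15,
                        n_reflections=0, tumble_deg=180.0)
        cfg = replace(cfg, hit_window_um=cfg.interpulse_um * 1.999)
        ds, truth = simulate_stream(cfg)
        res = classify(ds)
        n_adjacent_pairs = sum(1 for c in truth.crystals if len(c.pulses) >= 2)
        assert n_adjacent_pairs > 8000
        summ = summarize(ds, res)
        assert summ.double_hit_pct < 0.2


class TestHistogram:
    def test_small_rotations_all_below_5deg(self):
        rot = rotation_about([1, 2, 3], 2.0)
        frames = []
        for i in range(10):   # separate trains: exactly one pair per train
            frames.append((i, 0, [make_crystal()]))
            frames.append((i, 1, [make_crystal(rotation=rot)]))
        hist = orientation_histogram(make_dataset(frames), bin_width=1.0)
        assert hist.n_pairs == 10
        assert hist.frequency.sum() == pytest.approx(1.0)
        assert hist.mass_below(5.0) == pytest.approx(1.0)

    def test_uniform_rotations_rarely_below_5deg(self):
        """A uniform random rotation almost never keeps all three axis
        angles under 5 degrees (Monte-Carlo, 2000 pairs)."""
        rng = np.random.default_rng(123)
        frames = []
        for i in range(2000):
            r1 = Rotation.random(rng=rng).as_matrix()
            r2 = Rotation.random(rng=rng).as_matrix()
            frames.append((i, 0, [make_crystal(rotation=r1)]))
            frames.append((i, 1, [make_crystal(rotation=r2)]))
        hist = orientation_histogram(make_dataset(frames), bin_width=5.0)
        assert hist.n_pairs == 2000
        assert hist.mass_below(5.0) < 0.01

    def test_planted_doubles_show_low_angle_excess(self):
        cfg = SimConfig(n_trains=30, seed=3, arrival_rate=0.1, n_reflections=0)
        cfg = hit_window_for_double_fraction(cfg, 0.06)
        ds, _ = simulate_stream(cfg)
        hist = orientation_histogram(ds, bin_width=5.0)
        assert hist.mass_below(5.0) > 0.02     # >> 1e-4 random baseline

    def test_empty_flagged(self):
        ds = make_dataset([(1, 0, [make_crystal()])])
        hist = orientation_histogram(ds)
        assert hist.empty


class TestSummarize:
    @pytest.mark.parametrize(
        "counts, hit_rate, index_rate, double_pct",
        [((440000, 10726, 9970, 1190, 8780), 2.4, 93.0, 6.4),
         ((60000, 1638, 1509, 28, 1481), 2.7, 92.1, 0.9),
         ((240000, 3733, 3474, 20, 3454), 1.6, 93.1, 0.3)])
    def test_run_statistics_arithmetic(self, counts, hit_rate, index_rate,
                                       double_pct):
        """Published-style run counts reproduce their quoted percentages."""
        summ = RunSummary(*counts)
        assert round(summ.hit_rate, 1) == hit_rate
        assert round(summ.index_rate, 1) == index_rate
        # quoted percentages carry one-decimal rounding slack
        assert summ.double_hit_pct == pytest.approx(double_pct, abs=0.06)

    def test_all_singles(self):
        ds = make_dataset([(1, 0, [make_crystal()]),
                           (2, 0, [make_crystal()])])
        res = classify(ds)
        summ = summarize(ds, res)
        assert summ.double_hit_pct == 0.0
        assert summ.n_single_hits == 2

    def test_empty_dataset_rejected(self):
        ds = make_dataset([])
        with pytest.raises(ValueError):
            summarize(ds, classify(ds))


class TestSplit:
    def test_one_pair_one_single(self):
        rot = rotation_about([0, 1, 0], 40.0)
        ds = make_dataset([(1, 0, [make_crystal()]),
                           (1, 1, [make_crystal(), make_crystal(rotation=rot)])])
        res = classify(ds)
        singles, firsts, seconds = split(ds, res)
        assert (singles.n_crystals, firsts.n_crystals,
                seconds.n_crystals) == (1, 1, 1)

    def test_empty_input(self):
        ds = make_dataset([])
        singles, firsts, seconds = split(ds, classify(ds))
        assert (len(singles), len(firsts), len(seconds)) == (0, 0, 0)

    def test_planted_sizes_and_disjointness(self):
        cfg = SimConfig(n_trains=20, seed=17, arrival_rate=0.1,
                        n_reflections=0)
        cfg = hit_window_for_double_fraction(cfg, 0.1)
        ds, truth = simulate_stream(cfg)
        res = classify(ds)
        singles, firsts, seconds = split(ds, res)
        assert firsts.n_crystals == seconds.n_crystals
        assert singles.n_crystals == truth.count(HitLabel.SINGLE)
        assert firsts.n_crystals == truth.count(HitLabel.FIRST)
        total = (singles.n_crystals + firsts.n_crystals + seconds.n_crystals
                 + res.count(HitLabel.RUN_EXTRA))
        assert total == ds.n_crystals
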