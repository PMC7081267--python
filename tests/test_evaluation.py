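"""Metrics and matching protocol, checked against brute-force oracles."""

import itertools

import numpy as np
import pytest

from pocketseg import (
    GridSpec,
    PocketMask,
    dcc,
    detection_f1,
    dvo,
    f1_score,
    match_predictions,
    sentinel_dcc,
    success_rate,
    success_rate_curve,
)
from pocketseg.evaluation import MatchResult, ReferencePocket, summarize
from pocketseg.inference import PocketSegment


def make_segment(spec, indices, score=1.0):
    idx = np.asarray(indices, dtype=int)
    center = spec.node_coords(idx).mean(axis=0)
    return PocketSegment(idx, score, center, spec)


def make_truth(spec, indices):
    p = spec.points_per_axis
    values = np.zeros((p, p, p), dtype=np.uint8)
    idx = np.asarray(indices, dtype=int)
    values[idx[:, 0], idx[:, 1], idx[:, 2]] = 1
    return ReferencePocket.from_mask(PocketMask(spec, values))


class TestDcc:
    def test_identical_centers(self):
        assert dcc((1, 2, 3), (1, 2, 3)) == 0.0

    def test_three_four_five(self):
        assert dcc((0, 0, 0), (3, 4, 0)) == pytest.approx(5.0)

    def test_random_pairs_match_root_sum_square_oracle(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            a, b = rng.normal(size=(2, 3))
            assert dcc(a, b) == pytest.approx(np.sqrt(np.sum((a - b) ** 2)), abs=1e-9)


class TestSentinelDcc:
    def test_default_grid_is_121_24(self):
        assert round(sentinel_dcc(GridSpec()), 2) == 121.24

    def test_two_point_unit_lattice(self):
        assert sentinel_dcc(GridSpec(spacing=1.0, points_per_axis=2)) == pytest.approx(np.sqrt(3))

    def test_equals_max_pairwise_corner_distance(self):
        for spacing, points in [(1.5, 4), (2.0, 36), (0.7, 9)]:
            spec = GridSpec(spacing=spacing, points_per_axis=points)
            corners = np.array(
                [spec.node_coords(np.array([c])) [0]
                 for c in itertools.product([0, points - 1], repeat=3)]
            )
            brute = max(
                np.linalg.norm(a - b) for a, b in itertools.combinations(corners, 2)
            )
            assert sentinel_dcc(spec) == pytest.approx(brute, abs=1e-9)


class TestDvo:
    def test_identical_nonempty_masks(self):
        m = np.zeros((4, 4, 4))
        m[:2] = 1
        assert dvo(m, m) == 1.0

    def test_disjoint_masks(self):
        a = np.zeros((4, 4, 4))
        b = np.zeros((4, 4, 4))
        a[0] = 1
        b[3] = 1
        assert dvo(a, b) == 0.0

    def test_counting_oracle_case(self):
        a = np.zeros(27)
        b = np.zeros(27)
        a[:8] = 1
        b[4:12] = 1  # |A|=8, |B|=8, |A∩B|=4, |A∪B|=12
        assert dvo(a.reshape(3, 3, 3), b.reshape(3, 3, 3)) == pytest.approx(4 / 12)

    def test_both_empty_defined_as_zero(self):
        z = np.zeros((3, 3, 3))
        assert dvo(z, z) == 0.0

    def test_symmetry_bounds_and_oracle_on_random_masks(self):
        rng = np.random.default_rng(5)
        for _ in range(50):
            a = rng.random((6, 6, 6)) < 0.3
            b = rng.random((6, 6, 6)) < 0.3
            v = dvo(a, b)
            assert v == dvo(b, a)
            assert 0.0 <= v <= 1.0
            inter = int(np.sum(a & b))
            union = int(np.sum(a | b))
            assert v == pytest.approx(inter / union if union else 0.0)


class TestMatchPredictions:
    SPEC = GridSpec(center=(0.0, 0.0, 0.0), spacing=2.0, points_per_axis=12)

    def test_no_predictions_gives_sentinels_for_every_truth(self):
        truths = [make_truth(self.SPEC, [[1, 1, 1]]), make_truth(self.SPEC, [[8, 8, 8]])]
        results = match_predictions([], truths, self.SPEC)
        assert len(results) == 2
        assert all(r.sentinel for r in results)
        assert all(r.dcc == pytest.approx(sentinel_dcc(self.SPEC)) for r in results)
        assert all(r.dvo == 0.0 for r in results)

    def test_perfect_prediction_scores_zero_dcc(self):
        truth = make_truth(self.SPEC, [[5, 5, 5]])
        pred = make_segment(self.SPEC, [[5, 5, 5]])
        (r,) = match_predictions([pred], [truth], self.SPEC)
        assert not r.sentinel
        assert r.dcc == pytest.approx(0.0)
        assert r.dvo == pytest.approx(1.0)

    def test_empty_truths_rejected(self):
        with pytest.raises(ValueError):
            match_predictions([], [], self.SPEC)

    def test_random_geometry_matches_enumeration_oracle(self):
        rng = np.random.default_rng(9)
        for _ in range(30):
            n_pred = int(rng.integers(0, 5))
            n_truth = int(rng.integers(1, 4))
            preds, truths = [], []
            for _ in range(n_pred):
                idx = rng.integers(0, 12, size=(int(rng.integers(1, 6)), 3))
                preds.append(make_segment(self.SPEC, np.unique(idx, axis=0), float(rng.random())))
            for _ in range(n_truth):
                idx = rng.integers(0, 12, size=(int(rng.integers(1, 6)), 3))
                truths.append(make_truth(self.SPEC, np.unique(idx, axis=0)))
            results = match_predictions(preds, truths, self.SPEC)

            # oracle: truncate by score, nearest truth per retained prediction,
            # sentinel for unmatched truths
            retained = sorted(preds, key=lambda s: -s.score)[:n_truth]
            expected = []
            hit = set()
            for p in retained:
                ds = [np.linalg.norm(p.center - t.center) for t in truths]
                j = int(np.argmin(ds))
                hit.add(j)
                expected.append((round(float(min(ds)), 9), False))
            for j in range(n_truth):
                if j not in hit:
                    expected.append((round(sentinel_dcc(self.SPEC), 9), True))
            got = sorted((round(r.dcc, 9), r.sentinel) for r in results)
            assert got == sorted(expected)
            # every truth appears at least once (matched or sentinel)
            assert len(results) >= n_truth

    def test_exclusive_matching_assigns_each_truth_once(self):
        truths = [make_truth(self.SPEC, [[2, 2, 2]]), make_truth(self.SPEC, [[9, 9, 9]])]
        preds = [
            make_segment(self.SPEC, [[2, 2, 3]], score=2.0),
            make_segment(self.SPEC, [[2, 3, 2]], score=1.0),
        ]
        greedy = match_predictions(preds, truths, self.SPEC, exclusive=False)
        exclusive = match_predictions(preds, truths, self.SPEC, exclusive=True)
        assert sum(r.sentinel for r in greedy) == 1  # both preds chase truth 0
        assert sum(r.sentinel for r in exclusive) == 0


class TestSuccessRate:
    def test_paper_style_counting(self):
        rng = np.random.default_rng(1)
        dccs = np.concatenate([rng.uniform(0, 3.99, 120), rng.uniform(4.01, 100, 149)])
        matches = [
            MatchResult(np.zeros(3), float(d), 0.0, sentinel=False, predicted_center=np.zeros(3))
            for d in dccs
        ]
        assert round(success_rate(matches, 4.0), 3) == round(120 / 269, 3) == 0.446

    def test_boundary_is_strict(self):
        m = MatchResult(np.zeros(3), 4.0, 0.0, sentinel=False, predicted_center=np.zeros(3))
        assert success_rate([m], 4.0) == 0.0

    def test_all_sentinel_is_zero_below_20(self):
        spec = GridSpec()
        ms = [MatchResult(np.zeros(3), sentinel_dcc(spec), 0.0, sentinel=True) for _ in range(5)]
        for thr in np.arange(0.5, 20.5, 0.5):
            assert success_rate(ms, float(thr)) == 0.0

    def test_curve_is_nondecreasing_and_zero_at_zero(self):
        rng = np.random.default_rng(2)
        ms = [
            MatchResult(np.zeros(3), float(d), 0.0, sentinel=False, predicted_center=np.zeros(3))
            for d in rng.uniform(0, 25, 100)
        ]
        curve = success_rate_curve(ms)
        fracs = [f for _, f in curve]
        assert curve[0] == (0.0, 0.0)
        assert all(b >= a for a, b in zip(fracs, fracs[1:]))

    def test_random_values_match_counting_oracle(self):
        rng = np.random.default_rng(3)
        d = rng.uniform(0, 10, 57)
        ms = [
            MatchResult(np.zeros(3), float(x), 0.0, sentinel=False, predicted_center=np.zeros(3))
            for x in d
        ]
        for thr in (1.0, 4.0, 7.5):
            assert success_rate(ms, thr) == pytest.approx(np.mean(d < thr))


class TestDetectionF1:
    def test_reported_precision_recall_pairs(self):
        assert round(f1_score(0.64, 0.35), 2) == 0.45
        assert round(f1_score(0.73, 0.66), 2) == 0.69

    def test_perfect_precision_and_recall(self):
        assert f1_score(1.0, 1.0) == 1.0

    def test_zero_denominator(self):
        assert f1_score(0.0, 0.0) == 0.0

    def test_counts_from_matches(self):
        ok = MatchResult(np.zeros(3), 1.0, 0.5, sentinel=False, predicted_center=np.zeros(3))
        bad = MatchResult(np.zeros(3), 9.0, 0.0, sentinel=False, predicted_center=np.zeros(3))
        sen = MatchResult(np.zeros(3), 121.24, 0.0, sentinel=True)
        p, r, f1 = detection_f1([ok, ok, bad, sen], n_predicted_total=4, n_truth_total=5)
        assert p == pytest.approx(2 / 4)
        assert r == pytest.approx(2 / 5)
        assert f1 == pytest.approx(2 * p * r / (p + r))


class TestSummarize:
    def test_identity_predictions_summarize_to_perfect_rates(self):
        spec = GridSpec(points_per_axis=12)
        per_structure = []
        for seed in range(3):
            rng = np.random.default_rng(seed)
            idx = np.unique(rng.integers(0, 12, size=(5, 3)), axis=0)
            truth = make_truth(spec, idx)
            pred = make_segment(spec, idx)
            matches = match_predictions([pred], [truth], spec)
            per_structure.append(([pred], [truth], matches))
        summary = summarize(per_structure)
        assert summary.f1 == pytest.approx(1.0)
        assert dict(summary.success_rate_curve)[4.0] == pytest.approx(1.0)
        assert summary.n_structures_no_prediction == 0
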