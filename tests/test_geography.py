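import numpy as np
import pytest
from scipy.stats import rankdata

import netstates as ns
from netstates.exceptions import ValidationError


def brute_force_auc(strengths, positives):
    """Count all positive/negative pairs; ties get half credit."""
    pos = strengths[positives]
    neg = strengths[~positives]
    wins = sum((p > n) + 0.5 * (p == n) for p in pos for n in neg)
    return wins / (len(pos) * len(neg))


def _sensors(n_soz=2, rows=2, cols=2):
    sm = ns.generate_sensor_grid(rows, cols, 10.0)
    frame = sm.frame.copy()
    frame.loc[: n_soz - 1, "soz"] = True
    return ns.SensorMap(frame)


class TestClassifyPairs:
    def test_two_of_four_soz(self):
        classes = ns.classify_pairs(_sensors(2))
        vals, counts = np.unique(classes, return_counts=True)
        assert dict(zip(vals, counts)) == {"SOZ-SOZ": 1, "SOZ-OUT": 4, "OUT-OUT": 1}

    def test_no_soz(self):
        assert set(ns.classify_pairs(_sensors(0))) == {"OUT-OUT"}

    def test_all_soz(self):
        assert set(ns.classify_pairs(_sensors(4))) == {"SOZ-SOZ"}


class TestStrengthByClass:
    def test_uniform_weights(self):
        classes = ns.classify_pairs(_sensors(2))
        out = ns.strength_by_class(np.full((6, 3), 0.4), [0, 1], classes)
        assert all(v == pytest.approx(0.4) for v in out.values())

    def test_planted_class_means(self):
        classes = ns.classify_pairs(_sensors(2))
        vals = np.where(classes == "SOZ-SOZ", 0.9, 0.2)[:, None] * np.ones((1, 2))
        out = ns.strength_by_class(vals, [0, 1], classes)
        assert out["SOZ-SOZ"] == pytest.approx(0.9)
        assert out["SOZ-OUT"] == pytest.approx(0.2)
        assert out["OUT-OUT"] == pytest.approx(0.2)

    def test_matches_masked_mean(self, rng):
        sm = _sensors(3, rows=3, cols=3)
        classes = ns.classify_pairs(sm)
        vals = rng.random((36, 5))
        idx = [1, 4]
        out = ns.strength_by_class(vals, idx, classes)
        for lab in ns.CLASS_LABELS:
            assert out[lab] == pytest.approx(vals[classes == lab][:, idx].mean(), abs=1e-12)


class TestSozAuc:
    def test_perfect_separation(self):
        s = np.array([0.9, 0.8, 0.7, 0.6, 0.5])
        assert ns.soz_auc(s, np.array([1, 1, 0, 0, 0], bool)) == 1.0

    def test_all_ties_half(self):
        s = np.full(6, 0.4)
        assert ns.soz_auc(s, np.array([1, 1, 0, 0, 0, 0], bool)) == 0.5

    def test_hand_counted(self):
        s = np.array([0.8, 0.4, 0.6, 0.2])
        assert ns.soz_auc(s, np.array([1, 1, 0, 0], bool)) == 0.75

    def test_matches_brute_force_and_sklearn(self, rng):
        from sklearn.metrics import roc_auc_score

        for _ in range(20):
            n = rng.integers(6, 50)
            s = np.round(rng.random(n), 2)  # rounding forces ties
            pos = rng.random(n) < 0.4
            if pos.all() or not pos.any():
                continue
            auc = ns.soz_auc(s, pos)
            assert auc == pytest.approx(brute_force_auc(s, pos), abs=1e-12)
            assert auc == pytest.approx(roc_auc_score(pos, s), abs=1e-12)

    def test_degenerate_classes_rejected(self):
        with pytest.raises(ValidationError):
            ns.soz_auc(np.ones(4), np.ones(4, bool))


class TestAucNull:
    def test_same_seed_identical_ci(self, rng):
        s = rng.random(28)
        soz = np.zeros(8, bool)
        soz[:3] = True
        a = ns.auc_null(s, soz, n_permutations=500, seed=9)
        b = ns.auc_null(s, soz, n_permutations=500, seed=9)
        assert a.null_ci == b.null_ci and a.auc == b.auc

    def test_null_distribution_matches_loop(self, rng):
        # vectorized permutation AUCs equal per-permutation recomputation
        n = 6
        s = rng.random(15)
        soz = np.zeros(n, bool)
        soz[:2] = True
        res = ns.auc_null(s, soz, n_permutations=200, seed=3)
        rng2 = np.random.default_rng(3)
        order = np.argsort(rng2.random((200, n)), axis=1)
        a, b = np.triu_indices(n, 1)
        aucs = []
        for perm in range(200):
            member = np.zeros(n, bool)
            member[order[perm, :2]] = True
            aucs.append(ns.soz_auc(s, member[a] & member[b]))
        lo, hi = np.percentile(aucs, [2.5, 97.5])
        assert res.null_ci == pytest.approx((lo, hi), abs=1e-12)

    def test_planted_soz_significant(self):
        sm = ns.generate_sensor_grid(4, 4, soz_block=((0, 1), (0, 1)))
        classes = ns.classify_pairs(sm)
        rng = np.random.default_rng(0)
        s = np.where(classes == "SOZ-SOZ", 0.8, 0.3) + 0.05 * rng.random(classes.size)
        res = ns.auc_null(s, sm.soz, n_permutations=1000, seed=1)
        assert res.significant and res.auc > 0.95

    def test_soz_size_bounds(self, rng):
        s = rng.random(6)
        with pytest.raises(ValidationError):
            ns.auc_null(s, np.array([1, 0, 0, 0], bool), 100, 0)
        with pytest.raises(ValidationError):
            ns.auc_null(s, np.ones(4, bool), 100, 0)


class TestLengthStrengthCorrelation:
    def test_exponential_decay_gives_minus_one(self):
        sm = ns.generate_sensor_grid(3, 3, 10.0)
        d = sm.distances_mm()[np.triu_indices(9, 1)]
        vals = np.exp(-d / 20.0)[:, None] * np.ones((1, 4))
        res = ns.length_strength_correlation(vals, np.arange(4), sm)
        assert res.mean_rho == pytest.approx(-1.0)
        assert res.n_pairs == 36

    def test_independent_strengths_near_zero(self):
        sm = ns.generate_sensor_grid(4, 4, 10.0)
        rhos = []
        for seed in range(30):
            vals = np.random.default_rng(seed).random((120, 10))
            rhos.append(ns.length_strength_correlation(vals, np.arange(10), sm).mean_rho)
        assert abs(np.mean(rhos)) < 2 / np.sqrt(120 * 10 * 30 / 4)

    def test_midrank_tie_handling_matches_formula(self):
        sm = ns.generate_sensor_grid(2, 2, 10.0)
        # 2x2 grid: lengths [10, 10, 14.14, 14.14, 10, 10] for the 6 pairs
        strengths = np.array([0.9, 0.8, 0.1, 0.2, 0.7, 0.6])[:, None]
        res = ns.length_strength_correlation(strengths, [0], sm)
        d = sm.distances_mm()[np.triu_indices(4, 1)]
        rd, rs = rankdata(d), rankdata(strengths[:, 0])
        expected = np.corrcoef(rd, rs)[0, 1]
        assert res.mean_rho == pytest.approx(expected, abs=1e-12)

    def test_zero_variance_window_skipped(self):
        sm = ns.generate_sensor_grid(2, 2, 10.0)
        vals = np.column_stack([np.full(6, 0.5), np.linspace(0.1, 0.6, 6)])
        with pytest.warns(UserWarning, match="skipped"):
            res = ns.length_strength_correlation(vals, [0, 1], sm)
        assert res.n_windows_used == 1

    def test_off_grid_channels_excluded(self):
        sm = ns.generate_sensor_grid(2, 2, 10.0)
        frame = sm.frame.copy()
        frame.loc[3, "grid_id"] = None
        sm2 = ns.SensorMap(frame)
        vals = np.random.default_rng(1).random((6, 3))
        res = ns.length_strength_correlation(vals, [0, 1, 2], sm2)
        assert res.n_pairs == 3  # only pairs among the 3 on-grid channels
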