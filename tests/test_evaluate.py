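import numpy as np
import pandas as pd
import pytest

from susiq.evaluate import (BootDist, bootstrap_auc_diff, classification_report,
                            delong_ci, delong_paired_test, roc_auc,
                            sign_test_double_diff, two_way_anova, welch_t_test,
                            youden_cutoff)


def brute_force_auc(scores, labels, orientation="lower"):
    """O(n^2) pair-counting oracle with ties counted 1/2."""
    s = -np.asarray(scores, float) if orientation == "lower" else np.asarray(scores, float)
    pos = s[np.asarray(labels, bool)]
    neg = s[~np.asarray(labels, bool)]
    wins = sum((p > n) + 0.5 * (p == n) for p in pos for n in neg)
    return wins / (pos.size * neg.size)


def brute_force_youden(scores, labels, orientation="lower"):
    """Exhaustive threshold search with the documented tie rules."""
    scores = np.asarray(scores, float)
    pos = np.asarray(labels, bool)
    uniq = np.unique(scores)
    cands = np.concatenate([[uniq[0] - 1], (uniq[:-1] + uniq[1:]) / 2,
                            [uniq[-1] + 1]])
    best = None
    for c in cands:
        pred = scores < c if orientation == "lower" else scores > c
        sens = (pred & pos).sum() / pos.sum()
        spec = (~pred & ~pos).sum() / (~pos).sum()
        acc = (pred == pos).mean()
        key = (sens + spec - 1, acc, -pred.sum())
        if best is None or key > best[0]:
            best = (key, (c, acc, sens, spec))
    return best[1]


def random_instance(rng, with_ties=True):
    n = int(rng.integers(8, 51))
    if with_ties and rng.random() < 0.5:
        scores = rng.integers(0, 8, n).astype(float)  # heavy ties
    else:
        scores = rng.normal(size=n)
    labels = np.zeros(n, bool)
    labels[: int(rng.integers(1, n))] = True
    rng.shuffle(labels)
    if labels.all() or not labels.any():
        labels[0] = ~labels[0]
    return scores, labels


class TestRocAuc:
    def test_perfect_separation(self):
        scores = np.array([1.0, 2.0, 3.0, 10.0, 11.0, 12.0])
        labels = np.array([1, 1, 1, 0, 0, 0], bool)
        assert roc_auc(scores, labels, "lower") == 1.0

    def test_all_ties(self):
        assert roc_auc(np.ones(10), np.arange(10) < 4, "lower") == 0.5

    def test_matches_brute_force(self, rng):
        for _ in range(30):
            scores, labels = random_instance(rng)
            assert roc_auc(scores, labels, "lower") == pytest.approx(
                brute_force_auc(scores, labels, "lower"), abs=1e-12
            )

    def test_matches_sklearn(self, rng):
        # independent library cross-check on continuous scores
        from sklearn.metrics import roc_auc_score

        for _ in range(10):
            scores, labels = random_instance(rng, with_ties=False)
            assert roc_auc(scores, labels, "lower") == pytest.approx(
                roc_auc_score(labels, -scores), abs=1e-12
            )

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            roc_auc(np.arange(5.0), np.ones(5, bool))


class TestDelong:
    def test_duplicated_data_narrows_ci(self, rng):
        # mid-range AUC so neither CI is truncated at 0 or 1
        n = 40
        labels = np.arange(n) < 20
        scores = rng.normal(size=n) - 0.8 * labels
        lo1, hi1, d1 = delong_ci(scores, labels)
        lo2, hi2, d2 = delong_ci(np.tile(scores, 2), np.tile(labels, 2))
        assert not d1 and not d2
        assert 0.0 < lo1 and hi1 < 1.0
        ratio = (hi2 - lo2) / (hi1 - lo1)
        assert 0.6 < ratio < 0.8  # roughly 1/sqrt(2)

    def test_perfect_separation_degenerate(self):
        scores = np.array([1.0, 2.0, 8.0, 9.0])
        labels = np.array([1, 1, 0, 0], bool)
        lo, hi, degenerate = delong_ci(scores, labels)
        assert (lo, hi) == (1.0, 1.0)
        assert degenerate

    def test_identical_scores_p_one(self, rng):
        scores, labels = random_instance(rng)
        assert delong_paired_test(scores, scores.copy(), labels) == 1.0

    def test_monotone_transform_p_one(self, rng):
        scores, labels = random_instance(rng, with_ties=False)
        transformed = np.exp(0.5 * scores) + 3.0
        assert delong_paired_test(scores, transformed, labels) == pytest.approx(1.0)

    def test_against_permutation_oracle(self, rng):
        # within-subject label swap permutation null for the AUC difference
        n = 30
        labels = np.arange(n) < 12
        base = rng.normal(size=n) - labels * 1.2
        a = base + rng.normal(0, 0.6, n)
        b = base + rng.normal(0, 0.6, n)
        p_delong = delong_paired_test(a, b, labels)
        observed = abs(roc_auc(a, labels) - roc_auc(b, labels))
        count = 0
        n_perm = 4000
        for _ in range(n_perm):
            swap = rng.random(n) < 0.5
            aa = np.where(swap, b, a)
            bb = np.where(swap, a, b)
            diff = abs(roc_auc(aa, labels) - roc_auc(bb, labels))
            count += diff >= observed - 1e-12
        p_perm = count / n_perm
        assert abs(p_delong - p_perm) <= 0.05


class TestYouden:
    def test_separated_classes(self):
        scores = np.array([1.0, 2.0, 3.0, 10.0, 11.0, 12.0])
        labels = np.array([1, 1, 1, 0, 0, 0], bool)
        cutoff, acc, sens, spec = youden_cutoff(scores, labels, "lower")
        assert sens == 1.0 and spec == 1.0 and acc == 1.0
        assert cutoff == pytest.approx(6.5)

    def test_matches_exhaustive_search(self, rng):
        for _ in range(30):
            scores, labels = random_instance(rng)
            got = youden_cutoff(scores, labels, "lower")
            expected = brute_force_youden(scores, labels, "lower")
            assert got == pytest.approx(expected)

    def test_orientation_flip_symmetric(self, rng):
        scores, labels = random_instance(rng, with_ties=False)
        c1, a1, s1, p1 = youden_cutoff(scores, labels, "lower")
        c2, a2, s2, p2 = youden_cutoff(-scores, labels, "higher")
        assert (a1, s1, p1) == (a2, s2, p2)
        assert c2 == pytest.approx(-c1)


class TestBootstrap:
    def test_identical_scores_all_zero(self, rng):
        scores, labels = random_instance(rng)
        boot = bootstrap_auc_diff(scores, scores.copy(), labels, n_boot=1000,
                                  seed=5)
        assert np.all(boot.samples == 0.0)

    def test_seed_determinism(self, rng):
        a, labels = random_instance(rng, with_ties=False)
        b = a + rng.normal(0, 0.5, a.size)
        d1 = bootstrap_auc_diff(a, b, labels, n_boot=1000, seed=9)
        d2 = bootstrap_auc_diff(a, b, labels, n_boot=1000, seed=9)
        np.testing.assert_array_equal(d1.samples, d2.samples)

    def test_mean_tracks_point_estimate(self, rng):
        n = 60
        labels = np.arange(n) < 30
        base = rng.normal(size=n) - labels * 1.0
        a = base + rng.normal(0, 0.4, n)
        b = base + rng.normal(0, 0.8, n)
        point = roc_auc(a, labels) - roc_auc(b, labels)
        boot = bootstrap_auc_diff(a, b, labels, n_boot=4000, seed=2)
        se = boot.samples.std() / np.sqrt(boot.n_boot)
        # 2 Monte-Carlo SE plus a small allowance for bootstrap bias
        assert boot.mean == pytest.approx(point, abs=2 * se + 0.01)

    def test_n_boot_floor(self, rng):
        scores, labels = random_instance(rng)
        with pytest.raises(ValueError):
            bootstrap_auc_diff(scores, scores, labels, n_boot=10, seed=0)


class TestSignTest:
    @staticmethod
    def const_dist(value, n=2000):
        return BootDist(samples=np.full(n, value), n_boot=n, seed=0)

    def test_degenerate_separated(self):
        assert sign_test_double_diff(self.const_dist(0.1),
                                     self.const_dist(-0.1), 1000, 0) == 0.0
        assert sign_test_double_diff(self.const_dist(-1.0),
                                     self.const_dist(1.0), 1000, 0) == 1.0

    def test_identical_distributions_half(self, rng):
        samples = rng.normal(size=5000)
        d1 = BootDist(samples=samples, n_boot=5000, seed=0)
        d2 = BootDist(samples=samples.copy(), n_boot=5000, seed=1)
        p = sign_test_double_diff(d1, d2, n_pairs=10_000, seed=3)
        assert p == pytest.approx(0.5, abs=0.02)


class TestWelch:
    def test_identical_groups(self):
        x = np.array([1.0, 2.0, 5.0])
        t, p = welch_t_test(x, x.copy())
        assert t == 0.0 and p == 1.0

    def test_textbook_example(self):
        # x={1,2,3}, y={4,5,6}: t = -3/sqrt(2/3), df = 4
        t, p = welch_t_test([1.0, 2.0, 3.0], [4.0, 5.0, 6.0])
        assert t == pytest.approx(-3.0 / np.sqrt(2.0 / 3.0), rel=1e-12)
        from scipy import stats

        assert p == pytest.approx(2 * stats.t.sf(abs(t), df=4), rel=1e-9)

    def test_zero_variance_equal_means(self):
        t, p = welch_t_test([2.0, 2.0], [2.0, 2.0])
        assert (t, p) == (0.0, 1.0)

    def test_null_rejection_rate(self, rng):
        # type-I error at alpha = 0.05 within [0.03, 0.07] over 2000 reps
        rejections = 0
        for _ in range(2000):
            x = rng.normal(size=12)
            y = rng.normal(size=20)
            _, p = welch_t_test(x, y)
            rejections += p < 0.05
        assert 0.03 <= rejections / 2000 <= 0.07


class TestTwoWayAnova:
    @staticmethod
    def balanced(rng, n=6, shift=0.0):
        a = np.repeat(["x", "y"], 2 * n)
        b = np.tile(np.repeat(["u", "v"], n), 2)
        values = rng.normal(size=4 * n)
        values[(a == "x") & (b == "u")] += shift
        return values, a, b

    def test_all_equal(self):
        values = np.ones(12)
        a = np.repeat([0, 1], 6)
        b = np.tile([0, 1], 6)
        table = two_way_anova(values, a, b)
        for effect in ("A", "B", "A:B"):
            assert table.loc[effect, "F"] == 0.0
            assert table.loc[effect, "p"] == 1.0

    def test_balanced_type3_equals_sequential(self, rng):
        import statsmodels.api as sm
        from statsmodels.formula.api import ols

        values, a, b = self.balanced(rng, shift=1.0)
        table = two_way_anova(values, a, b)
        df = pd.DataFrame({"value": values, "a": a, "b": b})
        seq = sm.stats.anova_lm(ols("value ~ C(a) * C(b)", df).fit(), typ=1)
        for ours, theirs in (("A", "C(a)"), ("B", "C(b)"), ("A:B", "C(a):C(b)")):
            assert table.loc[ours, "sum_sq"] == pytest.approx(
                seq.loc[theirs, "sum_sq"], rel=1e-8
            )

    def test_interaction_matches_cell_means_oracle(self, rng):
        values, a, b = self.balanced(rng, n=5, shift=0.8)
        table = two_way_anova(values, a, b)
        df = pd.DataFrame({"v": values, "a": a, "b": b})
        cell = df.groupby(["a", "b"])["v"].mean().unstack()
        n = 5
        grand = df["v"].mean()
        row = df.groupby("a")["v"].mean()
        col = df.groupby("b")["v"].mean()
        ss_int = n * sum(
            (cell.loc[i, j] - row[i] - col[j] + grand) ** 2
            for i in ("x", "y") for j in ("u", "v")
        )
        resid = df["v"] - df.groupby(["a", "b"])["v"].transform("mean")
        ms_resid = (resid**2).sum() / (len(df) - 4)
        assert table.loc["A:B", "F"] == pytest.approx(ss_int / ms_resid, rel=1e-8)

    def test_empty_cell_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            two_way_anova([1.0, 2.0, 3.0], ["x", "x", "y"], ["u", "v", "u"])


class TestClassificationReport:
    @staticmethod
    def quant_frame():
        scores_susi = [5.0, 6.0, 7.0, 20.0, 21.0, 10.0]
        scores_sbr = [0.5, 0.6, 2.5, 2.0, 2.1, 0.9]
        return pd.DataFrame({
            "subject_id": [f"s{i}" for i in range(6)],
            "label": ["disease"] * 3 + ["control"] * 3,
            "susi_putamen_min": scores_susi,
            "sbr_putamen_min": scores_sbr,
            "rel_iqr": np.linspace(0.1, 0.2, 6),
        })

    def test_partition_and_discrepancy(self):
        out = classification_report(self.quant_frame(), "susi", "putamen",
                                    other_method="sbr")
        counts = out["status_susi"].value_counts()
        assert counts.sum() == 6
        assert out["discrepant"].dtype == bool

    def test_at_cutoff_is_negative(self):
        q = self.quant_frame()
        out = classification_report(q, "susi", "putamen")
        cutoff = out["cutoff_susi"].iloc[0]
        at_cut = q["susi_putamen_min"] == cutoff
        # a subject exactly at the cutoff is classified negative
        q2 = q.copy()
        q2.loc[0, "susi_putamen_min"] = cutoff
        out2 = classification_report(q2, "susi", "putamen")
        # cutoff may shift since it is refit; check the documented rule on
        # the refit cutoff instead
        c2 = out2["cutoff_susi"].iloc[0]
        assert not out2.loc[q2["susi_putamen_min"] == c2, "predicted_susi"].any()

    def test_dscore_zero_at_cutoff(self):
        out = classification_report(self.quant_frame(), "susi", "putamen")
        cutoff = out["cutoff_susi"].iloc[0]
        d = 100.0 * (out["score_susi"] - cutoff) / cutoff
        np.testing.assert_allclose(out["dsusi"], d)

    def test_missing_measure_rejected(self):
        with pytest.raises(ValueError, match="missing"):
            classification_report(self.quant_frame(), "susi", "caudate")
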