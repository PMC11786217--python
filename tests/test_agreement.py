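"""Agreement statistics: correlations, CCC, kappas, Pearson-Filon."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from bmrano.agreement import (
    ConfusionMatrix,
    cohen_kappa,
    confusion,
    lin_ccc,
    pabak,
    pearson_filon_test,
    pearson_r,
    percent_agreement,
)
from bmrano.response import Category, ResponseSequence


class TestPearson:
    def test_linear_transform_is_one(self):
        x = np.array([1.0, 2, 3, 5, 8])
        assert pearson_r(x, 2 * x + 1) == pytest.approx(1.0)
        assert pearson_r(x, -x) == pytest.approx(-1.0)

    def test_sum_of_products_oracle(self):
        x = np.array([1.0, 2, 3, 4])
        y = np.array([1.0, 3, 2, 4])
        # explicit arithmetic: cov = 1.25, sd_x = sd_y = sqrt(1.25)
        xc, yc = x - x.mean(), y - y.mean()
        expected = (xc * yc).sum() / np.sqrt((xc**2).sum() * (yc**2).sum())
        assert expected == pytest.approx(0.8)
        assert pearson_r(x, y) == pytest.approx(expected)

    def test_zero_variance_raises(self):
        with pytest.raises(ValueError):
            pearson_r([1, 1, 1], [1, 2, 3])


class TestCCC:
    def test_identity_is_one(self):
        x = np.array([1.0, 4, 2, 7])
        assert lin_ccc(x, x) == pytest.approx(1.0)

    def test_scale_shift_penalised(self):
        # pearson is 1 but CCC = 2*cov/(var_x+var_y+dmean^2) = 8/22
        x = np.array([1.0, 2, 3])
        y = np.array([2.0, 4, 6])
        assert pearson_r(np.array([1.0, 2, 3, 4]), np.array([2.0, 4, 6, 8])) == pytest.approx(1.0)
        assert lin_ccc(x, y) == pytest.approx(8 / 22)

    def test_location_shift_below_one(self):
        x = np.array([1.0, 2, 3, 4])
        assert lin_ccc(x, x + 1.0) < 1.0

    @given(
        st.lists(st.floats(-50, 50), min_size=4, max_size=20),
        st.lists(st.floats(-50, 50), min_size=4, max_size=20),
    )
    @settings(max_examples=100, deadline=None, derandomize=True)
    def test_ccc_bounded_by_abs_pearson(self, xs, ys):
        n = min(len(xs), len(ys))
        x, y = np.array(xs[:n]), np.array(ys[:n])
        if np.ptp(x) == 0 or np.ptp(y) == 0 or n < 3:
            return
        assert abs(lin_ccc(x, y)) <= abs(pearson_r(x, y)) + 1e-9


class TestKappas:
    def test_percent_agreement(self):
        cm = ConfusionMatrix(("a", "b"), [[20, 0], [0, 20]])
        assert percent_agreement(cm) == 1.0
        cm0 = ConfusionMatrix(("a", "b"), [[0, 5], [5, 0]])
        assert percent_agreement(cm0) == 0.0
        cm4 = ConfusionMatrix(("a", "b", "c", "d"), np.diag([10, 10, 5, 5]) + np.eye(4, k=1, dtype=int) * 0)
        assert percent_agreement(ConfusionMatrix(("a", "b"), [[15, 5], [5, 15]])) == 0.75

    def test_cohen_kappa_marginal_oracle(self):
        cm = ConfusionMatrix(("a", "b"), [[20, 5], [10, 15]])
        # po = 35/50, rows (0.5, 0.5), cols (0.6, 0.4), pe = 0.5
        assert cohen_kappa(cm) == pytest.approx((0.7 - 0.5) / 0.5)

    def test_cohen_kappa_matches_sklearn(self):
        from sklearn.metrics import cohen_kappa_score

        rng = np.random.default_rng(0)
        labels = ["PD", "SD", "PR", "CR"]
        a = rng.choice(labels, 200)
        b = np.where(rng.random(200) < 0.6, a, rng.choice(labels, 200))
        cm = ConfusionMatrix.from_pairs(zip(a, b))
        assert cohen_kappa(cm) == pytest.approx(
            cohen_kappa_score(a, b, labels=labels), abs=1e-12
        )

    def test_independence_table_kappa_zero(self):
        row = np.array([0.5, 0.5])
        col = np.array([0.25, 0.75])
        counts = (np.outer(row, col) * 400).astype(int)
        assert cohen_kappa(ConfusionMatrix(("a", "b"), counts)) == pytest.approx(0.0)

    def test_pabak(self):
        perfect = ConfusionMatrix(("a", "b", "c"), np.diag([5, 5, 5]))
        assert pabak(perfect) == 1.0
        # k=4 at chance level p_o = 0.25
        counts = np.zeros((4, 4), dtype=int)
        counts[0, 0] = 25
        counts[0, 1] = 75
        cm = ConfusionMatrix(("a", "b", "c", "d"), counts)
        assert pabak(cm) == pytest.approx(0.0)
        # k=2, p_o = 0.9
        cm2 = ConfusionMatrix(("a", "b"), [[45, 5], [5, 45]])
        assert pabak(cm2) == pytest.approx(0.8)

    def test_pabak_equals_kappa_for_uniform_marginals(self):
        # uniform marginals: pe = 1/k, so the two corrections coincide
        counts = np.array([[30, 10, 10], [10, 30, 10], [10, 10, 30]])
        cm = ConfusionMatrix(("a", "b", "c"), counts)
        assert pabak(cm) == pytest.approx(cohen_kappa(cm))


class TestPearsonFilon:
    R = np.array(
        [[1, 0.6, 0.3, 0.3], [0.6, 1, 0.3, 0.3], [0.3, 0.3, 1, 0.52], [0.3, 0.3, 0.52, 1]]
    )

    def draw(self, n, seed):
        rng = np.random.default_rng(seed)
        return rng.standard_normal((n, 4)) @ np.linalg.cholesky(self.R).T

    def test_same_pair_twice_is_null(self):
        x = self.draw(50, 0)
        z, p = pearson_filon_test(x[:, 0], x[:, 1], x[:, 0], x[:, 1])
        assert z == 0.0 and p == 1.0

    def test_antisymmetry_under_pair_swap(self):
        x = self.draw(80, 3)
        z1, p1 = pearson_filon_test(x[:, 0], x[:, 1], x[:, 2], x[:, 3])
        z2, p2 = pearson_filon_test(x[:, 2], x[:, 3], x[:, 0], x[:, 1])
        assert z1 == pytest.approx(-z2)
        assert p1 == pytest.approx(p2)

    def test_degenerate_correlation_raises(self):
        x = np.arange(20.0)
        with pytest.raises(ValueError):
            pearson_filon_test(x, 2 * x, x + 1, np.random.default_rng(0).random(20))

    def test_too_short_raises(self):
        with pytest.raises(ValueError):
            pearson_filon_test([1, 2, 3], [1, 2, 3], [1, 2, 3], [3, 2, 1])

    def test_bootstrap_oracle_agreement(self):
        """Asymptotic p agrees with a 10^4-resample paired bootstrap."""
        X = self.draw(500, 0)
        z, p = pearson_filon_test(X[:, 0], X[:, 1], X[:, 2], X[:, 3])
        rng = np.random.default_rng(0)
        idx = rng.integers(0, 500, size=(10000, 500))
        S = X[idx]
        Sc = S - S.mean(axis=1, keepdims=True)
        num = np.einsum("bni,bnj->bij", Sc, Sc)
        sd = np.sqrt(np.einsum("bii->bi", num))
        d = num[:, 0, 1] / (sd[:, 0] * sd[:, 1]) - num[:, 2, 3] / (sd[:, 2] * sd[:, 3])
        p_boot = 2 * min((d <= 0).mean(), (d >= 0).mean())
        assert p == pytest.approx(p_boot, abs=0.02)

    def test_type_one_error_calibrated(self):
        """Null rejection rate at alpha = 0.05 over 2000 simulations, n=100."""
        R0 = np.array(
            [[1, 0.5, 0.3, 0.3], [0.5, 1, 0.3, 0.3], [0.3, 0.3, 1, 0.5], [0.3, 0.3, 0.5, 1]]
        )
        L = np.linalg.cholesky(R0)
        rng = np.random.default_rng(7)
        rejections = 0
        for _ in range(2000):
            x = rng.standard_normal((100, 4)) @ L.T
            _, p = pearson_filon_test(x[:, 0], x[:, 1], x[:, 2], x[:, 3])
            rejections += p < 0.05
        assert 0.03 <= rejections / 2000 <= 0.07


class TestConfusion:
    def seq(self, lesion, cats, method="m"):
        times = tuple(30.0 * (i + 1) for i in range(len(cats)))
        return ResponseSequence(lesion, method, times, tuple(Category(c) for c in cats))

    def test_self_comparison_diagonal(self):
        seqs = [self.seq("L0", ["PR", "SD", "PD"]), self.seq("L1", ["CR", "CR"])]
        cm = confusion(seqs, seqs)
        assert np.trace(cm.counts) == cm.n == 5
        assert percent_agreement(cm) == 1.0

    def test_two_positions_differ(self):
        a = [self.seq("L0", ["PR", "SD", "PD", "SD", "CR"])]
        b = [self.seq("L0", ["PR", "PD", "PD", "PR", "CR"])]
        cm = confusion(a, b)
        assert cm.n == 5
        assert np.trace(cm.counts) == 3

    def test_alignment_on_intersection(self):
        a = [self.seq("L0", ["PR", "SD"]), self.seq("L1", ["PD"])]
        b = [self.seq("L0", ["PR", "SD", "PD"])]  # extra follow-up, no L1
        cm = confusion(a, b)
        assert cm.n == 2

    def test_empty_intersection_raises(self):
        with pytest.raises(ValueError):
            confusion([self.seq("L0", ["PR"])], [self.seq("L1", ["PR"])])

    def test_biased_diameters_disagree(self, default_cohort):
        """A multiplicatively biased diameter reading produces response
        sequences that disagree with the contour-derived ones."""
        from bmrano.pipeline import assess_cohort

        seqs = assess_cohort(default_cohort)
        cm = confusion(seqs["RANOu-mandiam"], seqs["RANOu-manseg"])
        assert percent_agreement(cm) < 1.0


def test_diam_vol_correlation_higher_for_automatic(default_cohort):
    """Sawtooth manual contours degrade the diameter-volume coupling; the
    smooth automatic contours preserve it, and the Pearson-Filon test flags
    the difference."""
    from bmrano.pipeline import agreement_analysis

    result = agreement_analysis(default_cohort)
    dv = result["diam_vol_correlation"]
    assert dv["automatic"] > dv["manual"]
    assert dv["pearson_filon_p"] < 0.05
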