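"""One-tailed t-test, BH step-up, and the inclusion taxonomy."""

import itertools

import numpy as np
import pytest
from scipy import stats

import dcvkit as d
from dcvkit.inference import apply_fdr


def bh_brute_force(pvalues, alpha):
    """Independent step-up oracle: largest k with p_(k) <= k*alpha/m."""
    p = np.asarray(pvalues, dtype=float)
    m = p.size
    order = np.argsort(p, kind="stable")
    sorted_p = p[order]
    best_k = 0
    for k in range(m, 0, -1):
        if sorted_p[k - 1] <= k * alpha / m:
            best_k = k
            break
    flags = np.zeros(m, dtype=bool)
    flags[order[:best_k]] = True
    return flags


class TestOneSampleT:
    def test_symmetric_scores_give_half(self):
        scores = [1.0] * 10 + [-1.0] * 10
        res = d.one_sample_t_greater(scores)
        assert res.mean == 0 and res.t == 0 and res.p == pytest.approx(0.5)

    def test_against_direct_formula(self):
        scores = [0.4, 0.6, 0.2, -0.2, 0.5]
        res = d.one_sample_t_greater(scores)
        x = np.array(scores)
        t_ref = x.mean() / (x.std(ddof=1) / np.sqrt(5))
        p_ref = stats.t.sf(t_ref, 4)
        assert res.t == pytest.approx(t_ref, rel=1e-12)
        assert res.p == pytest.approx(p_ref, rel=1e-12)
        assert res.df == 4 and res.n == 5

    def test_oracle_thousand_vectors(self):
        """(t, p) agree with scipy's independent routine to 1e-10 relative."""
        rng = np.random.default_rng(42)
        for _ in range(1000):
            n = int(rng.integers(3, 26))
            x = rng.normal(rng.uniform(-0.5, 0.5), rng.uniform(0.1, 1.0), size=n)
            res = d.one_sample_t_greater(x)
            t_ref, p_ref = stats.ttest_1samp(x, 0.0, alternative="greater")
            assert res.t == pytest.approx(float(t_ref), rel=1e-10)
            assert res.p == pytest.approx(float(p_ref), rel=1e-10, abs=1e-300)

    @pytest.mark.parametrize(
        "value,expected_p",
        [(0.5, 0.0), (-0.5, 1.0), (0.0, 0.5)],
    )
    def test_zero_variance_conventions(self, value, expected_p):
        res = d.one_sample_t_greater([value] * 6)
        assert res.sd == 0.0 and res.p == expected_p

    def test_back_solved_sd_reproduces_printed_t(self):
        """A 19-judge score vector with mean .88 and the implied sd gives t = 17.58."""
        n, mean, t_printed = 19, 0.88, 17.58
        implied_sd = mean * np.sqrt(n) / t_printed
        assert implied_sd == pytest.approx(0.218, abs=5e-4)
        rng = np.random.default_rng(0)
        z = rng.normal(size=n)
        z = (z - z.mean()) / z.std(ddof=1)
        scores = mean + implied_sd * z
        res = d.one_sample_t_greater(scores)
        assert res.t == pytest.approx(t_printed, rel=1e-9)

    def test_small_n_rejected(self):
        with pytest.raises(d.DcvValidationError, match="n >= 2"):
            d.one_sample_t_greater([1.0])


class TestBH:
    def test_all_zero_p_rejected(self):
        flags, _ = d.bh_adjust([0.0, 0.0, 0.0], alpha=0.05)
        assert flags.all()

    def test_hand_worked_step_up(self):
        p = [0.001, 0.008, 0.039, 0.041, 0.042, 0.06]
        flags, _ = d.bh_adjust(p, alpha=0.05)
        assert list(flags) == [True, True, False, False, False, False]

    def test_single_p_reduces_to_alpha(self):
        flags, _ = d.bh_adjust([0.04], alpha=0.05)
        assert flags[0]

    def test_exhaustive_grid_matches_brute_force(self):
        """All small p-vectors over a grid: flags equal the step-up oracle."""
        grid = [0.001, 0.008, 0.039, 0.06, 0.10]
        for m in range(1, 5):
            for p in itertools.product(grid, repeat=m):
                flags, _ = d.bh_adjust(p, alpha=0.05)
                np.testing.assert_array_equal(flags, bh_brute_force(p, 0.05))

    def test_random_vectors_match_brute_force(self):
        rng = np.random.default_rng(11)
        for _ in range(200):
            p = rng.uniform(0, 1, size=int(rng.integers(1, 30)))
            flags, _ = d.bh_adjust(p, alpha=0.05)
            np.testing.assert_array_equal(flags, bh_brute_force(p, 0.05))

    def test_out_of_range_rejected(self):
        with pytest.raises(d.DcvValidationError):
            d.bh_adjust([0.5, 1.2])
        with pytest.raises(d.DcvValidationError):
            d.bh_adjust([])


def _result(item, domain, mean, p, intended):
    return d.DcvTestResult(
        item_id=item, target_domain=domain, n=19, mean=mean,
        sd=0.2, t=mean / (0.2 / np.sqrt(19)), df=18, p=p, is_intended=intended,
    )


class TestClassification:
    def _classified(self, results, coalloc, intended, fdr="none"):
        params = d.AnalysisParams(fdr_method=fdr)
        apply_fdr(results, params)
        return d.classify_item(results, coalloc=coalloc, intended=intended, params=params)

    def test_pure_intended(self):
        cls = self._classified([_result("I1", "D3", 0.89, 1e-9, True)], (), ("D3",))
        assert cls.outcome == "pure_intended" and cls.include_final

    def test_misclassified_other_domain(self):
        results = [
            _result("I1", "D7", -0.68, 0.999, True),
            _result("I1", "D6", 0.55, 1e-5, False),
        ]
        cls = self._classified(results, ("D6", "D4"), ("D7",))
        assert cls.outcome == "misclassified" and not cls.include_final

    def test_mixed_when_coallocated(self):
        results = [
            _result("I1", "D9", 0.47, 0.01, True),
            _result("I1", "D14", 0.10, 0.30, True),
            _result("I1", "D8", -0.2, 0.9, False),
        ]
        cls = self._classified(results, ("D8",), ("D9", "D14"))
        assert cls.outcome == "mixed"

    def test_unclassified_without_signal(self):
        cls = self._classified([_result("I1", "D10", 0.1, 0.4, True)], (), ("D10",))
        assert cls.outcome == "unclassified" and not cls.include_final

    def test_significant_negative_mean_is_not_classification(self):
        """One-tailed logic: only positive means can classify an item."""
        results = [_result("I1", "D1", -0.9, 1e-12, True)]
        # p tiny but mean negative cannot happen for an upper-tailed test on the
        # same data; guard that classification keys on mean > 0 regardless
        cls = self._classified(results, (), ("D1",))
        assert cls.outcome == "unclassified"

    def test_missing_intended_test_rejected(self):
        results = [_result("I1", "D2", 0.5, 0.01, False)]
        with pytest.raises(d.DcvValidationError, match="intended"):
            self._classified(results, (), ("D1",))

    def test_monotone_in_added_rejections(self):
        """A rejected non-intended test can only move an item away from pure."""
        base = [_result("I1", "D1", 0.8, 1e-6, True)]
        pure = self._classified(list(base), (), ("D1",))
        assert pure.outcome == "pure_intended"
        worse = base + [_result("I1", "D2", 0.5, 1e-6, False)]
        demoted = self._classified(worse, (), ("D1",))
        assert demoted.outcome != "pure_intended"

    def test_fdr_none_single_test_threshold(self):
        at = self._classified([_result("I1", "D1", 0.5, 0.05, True)], (), ("D1",))
        above = self._classified([_result("I1", "D1", 0.5, 0.0501, True)], (), ("D1",))
        assert at.outcome == "pure_intended" and above.outcome == "unclassified"


class TestSelectFinal:
    def test_grouping_with_empty_domains(self):
        cls = [
            d.ItemClassification("I1", ("D8",), frozenset({"D8"}), frozenset(),
                                 "pure_intended", True),
            d.ItemClassification("I2", ("D8",), frozenset({"D8"}), frozenset(),
                                 "pure_intended", True),
            d.ItemClassification("I3", ("D7",), frozenset(), frozenset({"D6"}), "mixed", False),
        ]
        groups = d.select_final_items(cls, domains=("D7", "D8"))
        assert groups == {"D7": [], "D8": ["I1", "I2"]}

    def test_empty_input(self):
        assert d.select_final_items([]) == {}
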