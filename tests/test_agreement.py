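"""Cohen/Light kappa, per-domain agreement, bootstrap CIs, judge correlation."""

from itertools import combinations

import numpy as np
import pandas as pd
import pytest

import dcvkit as d
from tests.conftest import make_table


class TestCohenKappa:
    def test_identical_vectors(self):
        assert d.cohen_kappa(["x", "y", "x"], ["x", "y", "x"]) == 1.0

    def test_hand_worked_half(self):
        # p_o = .75, p_e = .5 -> kappa = 0.5
        assert d.cohen_kappa(list("xxyy"), list("xyyy")) == pytest.approx(0.5)

    def test_constant_rater_gives_zero(self):
        assert d.cohen_kappa(["x", "y"], ["x", "x"]) == pytest.approx(0.0)

    def test_degenerate_pe_one(self):
        assert d.cohen_kappa(["x", "x"], ["x", "x"]) == 1.0

    def test_pairwise_complete_deletion(self):
        a = ["x", None, "y", "x"]
        b = ["x", "y", None, "x"]
        assert d.cohen_kappa(a, b) == 1.0  # only complete pairs agree perfectly

    def test_errors(self):
        with pytest.raises(d.DcvValidationError, match="length"):
            d.cohen_kappa(["x"], ["x", "y"])
        with pytest.raises(d.DcvValidationError, match="complete"):
            d.cohen_kappa([None, None], ["x", "y"])

    def test_matches_sklearn_on_random_vectors(self):
        from sklearn.metrics import cohen_kappa_score

        rng = np.random.default_rng(5)
        for _ in range(50):
            n = int(rng.integers(5, 60))
            a = rng.integers(0, 4, size=n).astype(str)
            b = rng.integers(0, 4, size=n).astype(str)
            if len(set(a)) < 2 and len(set(b)) < 2:
                continue
            assert d.cohen_kappa(a, b) == pytest.approx(
                cohen_kappa_score(a, b), rel=1e-12, abs=1e-12
            )


class TestLightKappa:
    def test_identical_judges(self):
        m = pd.DataFrame({"J1": list("abcab"), "J2": list("abcab"), "J3": list("abcab")})
        assert d.light_kappa(m) == 1.0

    def test_equals_pairwise_mean(self):
        rng = np.random.default_rng(2)
        m = pd.DataFrame(rng.integers(0, 3, size=(30, 4)).astype(str))
        expected = np.mean(
            [d.cohen_kappa(m.iloc[:, i], m.iloc[:, j])
             for i, j in combinations(range(4), 2)]
        )
        assert d.light_kappa(m) == pytest.approx(expected, rel=1e-12)

    def test_two_judges_reduces_to_cohen(self):
        rng = np.random.default_rng(3)
        m = pd.DataFrame(rng.integers(0, 5, size=(40, 2)).astype(str))
        assert d.light_kappa(m) == pytest.approx(
            d.cohen_kappa(m.iloc[:, 0], m.iloc[:, 1]), rel=1e-12
        )

    def test_judge_permutation_and_relabel_invariance(self):
        rng = np.random.default_rng(4)
        m = pd.DataFrame(rng.integers(0, 4, size=(25, 5)).astype(str))
        shuffled = m.iloc[:, rng.permutation(5)]
        relabel = m.replace({"0": "D9", "1": "D3", "2": "D7", "3": "D1"})
        assert d.light_kappa(shuffled) == pytest.approx(d.light_kappa(m))
        assert d.light_kappa(relabel) == pytest.approx(d.light_kappa(m))

    def test_single_judge_rejected(self):
        with pytest.raises(d.DcvValidationError, match="2 raters"):
            d.light_kappa(pd.DataFrame({"J1": list("ab")}))

    def test_null_agreement_near_zero(self):
        """Independent uniform allocation (14 domains, 79x19): mean kappa ~ 0."""
        rng = np.random.default_rng(99)
        values = [
            d.light_kappa(pd.DataFrame(rng.integers(1, 15, size=(79, 19)).astype(str)))
            for _ in range(200)
        ]
        assert -0.02 <= float(np.mean(values)) <= 0.02


class TestDomainKappa:
    def _table(self):
        # 6 judges, 10 items; judges J1-J4 allocate odd items to D1, J5/J6 never use D1
        rows = []
        for j in range(1, 5):
            for i in range(10):
                dom = "D1" if i % 2 else "D2"
                rows.append((f"J{j}", f"I{i}", 1, dom, 0.8))
        for j in (5, 6):
            for i in range(10):
                rows.append((f"J{j}", f"I{i}", 1, "D3", 0.8))
        doms = d.DomainSet(tuple(d.Domain(f"D{k}", "") for k in (1, 2, 3)))
        return make_table(rows, domains=doms)

    def test_perfect_agreement(self):
        table = self._table()
        res = d.domain_kappa(table, "D1")
        assert res.kappa == 1.0
        assert res.excluded_raters == {"J5", "J6"}
        assert res.n_raters_used == 4

    def test_keep_empty_raters(self):
        res = d.domain_kappa(self._table(), "D1", drop_empty_raters=False)
        assert res.n_raters_used == 6
        assert res.kappa < 1.0  # all-zero columns disagree with informative ones

    def test_too_few_raters_rejected(self):
        res_domain = "D2"
        rows = [("J1", "I1", 1, "D2", 0.5), ("J2", "I1", 1, "D1", 0.5)]
        doms = d.DomainSet((d.Domain("D1", ""), d.Domain("D2", "")))
        table = make_table(rows, domains=doms)
        with pytest.raises(d.DcvValidationError, match="fewer than 2"):
            d.domain_kappa(table, res_domain, drop_empty_raters=True)

    def test_rank_scope_first_vs_any(self):
        rows = [
            ("J1", "I1", 1, "D1", 0.6), ("J1", "I1", 2, "D2", 0.3),
            ("J2", "I1", 1, "D1", 0.6), ("J2", "I1", 2, "D2", 0.3),
            ("J1", "I2", 1, "D1", 0.6), ("J2", "I2", 1, "D1", 0.6),
        ]
        doms = d.DomainSet((d.Domain("D1", ""), d.Domain("D2", "")))
        table = make_table(rows, domains=doms)
        any_rank = d.domain_binary_matrix(table, "D2", rank_scope="any")
        first = d.domain_binary_matrix(table, "D2", rank_scope="first")
        assert any_rank.to_numpy().sum() == 2 and first.to_numpy().sum() == 0


class TestBootstrapCI:
    def test_perfect_agreement_degenerate_ci(self):
        m = pd.DataFrame({"J1": list("ababab"), "J2": list("ababab")})
        assert d.bootstrap_kappa_ci(m, n_boot=200, seed=1) == (1.0, 1.0)

    def test_deterministic_given_seed(self):
        rng = np.random.default_rng(8)
        m = pd.DataFrame(rng.integers(0, 3, size=(30, 4)).astype(str))
        ci1 = d.bootstrap_kappa_ci(m, n_boot=300, seed=42)
        ci2 = d.bootstrap_kappa_ci(m, n_boot=300, seed=42)
        assert ci1 == ci2

    def test_ci_brackets_point_estimate(self):
        rng = np.random.default_rng(12)
        base = rng.integers(0, 3, size=60)
        cols = {
            f"J{k}": np.where(rng.random(60) < 0.7, base, rng.integers(0, 3, size=60))
            for k in range(4)
        }
        m = pd.DataFrame(cols).astype(str)
        k_hat = d.light_kappa(m)
        lo, hi = d.bootstrap_kappa_ci(m, n_boot=500, seed=3)
        assert lo <= k_hat <= hi

    def test_width_shrinks_with_items(self):
        """Percentile CI narrows as the item pool grows (20 -> 320 items)."""
        rng = np.random.default_rng(21)

        def matrix(n_items):
            base = rng.integers(0, 3, size=n_items)
            cols = {
                f"J{k}": np.where(rng.random(n_items) < 0.7, base,
                                  rng.integers(0, 3, size=n_items))
                for k in range(4)
            }
            return pd.DataFrame(cols).astype(str)

        lo_s, hi_s = d.bootstrap_kappa_ci(matrix(20), n_boot=300, seed=5)
        lo_l, hi_l = d.bootstrap_kappa_ci(matrix(320), n_boot=300, seed=5)
        assert (hi_l - lo_l) < (hi_s - lo_s)

    def test_single_item_rejected(self):
        m = pd.DataFrame({"J1": ["a"], "J2": ["a"]})
        with pytest.raises(d.DcvValidationError, match="at least 2 items"):
            d.bootstrap_kappa_ci(m, n_boot=200, seed=0)


class TestJudgeMatchCorrelation:
    def _setup(self):
        doms = d.DomainSet((d.Domain("D1", ""), d.Domain("D2", "")))
        bank = d.ItemBank(
            tuple(d.ItemSpec(item_id=f"I{i}", intended_domains=("D1",)) for i in range(6))
        )
        rng = np.random.default_rng(9)
        rows = []
        for j in range(8):
            for i in range(6):
                dom = "D1" if rng.random() < 0.3 + 0.08 * j else "D2"
                rows.append((f"J{j}", f"I{i}", 1, dom, 0.9))
        return make_table(rows, domains=doms), bank

    def test_self_correlation_is_one(self):
        table, bank = self._setup()
        counts = d.judge_match_counts(table, bank)
        r, _ = d.judge_match_correlation(table, bank, counts.to_dict())
        assert r == pytest.approx(1.0)
        r_neg, _ = d.judge_match_correlation(table, bank, (-counts).to_dict())
        assert r_neg == pytest.approx(-1.0)

    def test_matches_numpy_oracle(self):
        table, bank = self._setup()
        rng = np.random.default_rng(10)
        cov = {j: float(rng.normal()) for j in table.judges}
        r, _ = d.judge_match_correlation(table, bank, cov)
        counts = d.judge_match_counts(table, bank)
        expected = np.corrcoef(
            counts.to_numpy(dtype=float), [cov[j] for j in counts.index]
        )[0, 1]
        assert r == pytest.approx(float(expected), rel=1e-12)

    def test_zero_variance_rejected(self):
        table, bank = self._setup()
        with pytest.raises(d.DcvValidationError, match="zero variance"):
            d.judge_match_correlation(table, bank, {j: 1.0 for j in table.judges})
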