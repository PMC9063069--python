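import numpy as np
import pandas as pd
import pytest
from scipy import stats

from telopipe.screen import (
    StressFeatureTable,
    TypingError,
    classify_feature,
    correlation_network,
    cv_predict,
    impute_median,
    network_to_json,
    univariate_association,
)

from .oracles import spearman_edge_counts


def _table(data: dict, types: dict | None = None) -> StressFeatureTable:
    return StressFeatureTable(data=pd.DataFrame(data), types=types or {})


class TestClassifyFeature:
    @pytest.mark.parametrize(
        "values, expected",
        [
            ([0, 1, 1, 0], "binary"),
            (["yes", "no", "yes"], "binary"),
            ([1, 2, 3, 4, 5], "categorical"),  # integer-coded, <=6 levels
            ([22.1, 25.3, 19.8], "numeric"),
            (list(range(1, 8)), "numeric"),  # 7 integer levels exceeds the rule
            (["a", "b", "c", "d"], "categorical"),
        ],
    )
    def test_inference_rules(self, values, expected):
        assert classify_feature(values) == expected

    def test_declaration_overrides(self):
        assert classify_feature(list(range(1, 8)), declared="categorical") == "categorical"

    def test_all_missing_raises(self):
        with pytest.raises(TypingError):
            classify_feature([np.nan, np.nan])


class TestUnivariateAssociation:
    def test_perfect_concordance(self):
        y = [1.0, 2.0, 3.0, 4.0, 5.0, 6.0]
        res = univariate_association(y, y, kind="numeric")
        assert res.statistic == pytest.approx(1.0)
        assert res.direction == 1
        assert res.p_value < 0.01

    def test_binary_rank_sum_enumeration(self):
        res = univariate_association([0, 0, 1, 1], [1.0, 2.0, 3.0, 4.0], kind="binary")
        assert res.p_value == pytest.approx(1.0 / 3.0)
        assert res.direction == 1  # higher level has larger mean LTL

    def test_constant_feature_degenerates(self):
        res = univariate_association([1, 1, 1, 1], [1.0, 2.0, 3.0, 4.0], kind="binary")
        assert res.p_value == 1.0
        assert res.direction == 0

    def test_kruskal_two_groups_equals_rank_sum(self, rng):
        """For k=2 the Kruskal-Wallis chi2 p equals the tie-corrected
        normal rank-sum p (H = z**2), so the dispatch choice cannot flip
        a rejection decision on binary-like data."""
        f = rng.integers(0, 2, 60).astype(float)
        y = rng.integers(0, 15, 60).astype(float) + 0.3 * f
        p_kw = univariate_association(f, y, kind="categorical").p_value
        p_rs = univariate_association(f, y, kind="binary").p_value
        assert p_kw == pytest.approx(p_rs, abs=1e-10)

    def test_requires_three_pairs(self):
        with pytest.raises(ValueError):
            univariate_association([1.0, 2.0], [1.0, 2.0])


class TestImputation:
    def test_numeric_median(self):
        t = _table({"a": [1.0, np.nan, 3.0]}, {"a": "numeric"})
        assert impute_median(t).data["a"].tolist() == [1.0, 2.0, 3.0]

    def test_binary_median_rounds_to_observed_level(self):
        t = _table({"a": [0.0, 0.0, 1.0, np.nan]}, {"a": "binary"})
        assert impute_median(t).data["a"].tolist() == [0.0, 0.0, 1.0, 0.0]

    def test_categorical_mode_tie_takes_lowest_code(self):
        t = _table({"a": [1.0, 1.0, 2.0, 2.0, 3.0, np.nan]}, {"a": "categorical"})
        assert impute_median(t).data["a"].iloc[-1] == 1.0

    def test_complete_table_unchanged(self):
        t = _table({"a": [1.0, 2.0, 3.0], "b": [0.0, 1.0, 0.0]})
        assert impute_median(t).data.equals(t.data)


def _assoc(features, p=0.5, direction=1):
    from telopipe.screen import AssociationResult

    return [
        AssociationResult(name, "kendall-tau", 0.1, p, direction, 10)
        for name in features
    ]


class TestCorrelationNetwork:
    def test_duplicated_feature_gives_thick_unit_edge(self, rng):
        x = rng.normal(0, 1, 30)
        t = _table({"a": x, "b": x.copy(), "c": rng.normal(0, 1, 30)})
        g = correlation_network(t, _assoc(["a", "b", "c"]), embed_seed=0)
        assert g.has_edge("a", "b")
        assert g.edges["a", "b"]["r"] == pytest.approx(1.0)
        assert g.edges["a", "b"]["weight_class"] == "thick"

    def test_independent_features_have_no_thick_edges(self, rng):
        data = {f"f{i}": rng.normal(0, 1, 100) for i in range(12)}
        g = correlation_network(_table(data), _assoc(data.keys()), embed_seed=0)
        assert not any(d["weight_class"] == "thick" for _, _, d in g.edges(data=True))

    def test_planted_two_block_structure(self, rng):
        n, r_within = 400, 0.6
        blocks = {}
        for b in range(2):
            shared = rng.normal(0, 1, n)
            for k in range(5):
                lam = np.sqrt(r_within)
                blocks[f"b{b}_{k}"] = lam * shared + np.sqrt(1 - lam**2) * rng.normal(0, 1, n)
        g = correlation_network(_table(blocks), _assoc(blocks.keys()), embed_seed=0)
        for u, v in g.edges():
            assert u.split("_")[0] == v.split("_")[0], "cross-block edge"
        for b in range(2):
            names = [f"b{b}_{k}" for k in range(5)]
            for i in range(5):
                for j in range(i + 1, 5):
                    assert g.has_edge(names[i], names[j])

    def test_deterministic_for_fixed_seed(self, rng):
        data = {f"f{i}": rng.normal(0, 1, 40) for i in range(8)}
        t = _table(data)
        a = correlation_network(t, _assoc(data.keys()), embed_seed=3)
        b = correlation_network(t, _assoc(data.keys()), embed_seed=3)
        assert network_to_json(a) == network_to_json(b)

    def test_node_annotations_follow_thresholds(self, rng):
        data = {f"f{i}": rng.normal(0, 1, 30) for i in range(3)}
        assoc = _assoc(["f0"], p=0.04, direction=1)
        assoc += _assoc(["f1"], p=0.08, direction=-1)
        assoc += _assoc(["f2"], p=0.5)
        g = correlation_network(_table(data), assoc, embed_seed=0)
        assert g.nodes["f0"]["bold"] and g.nodes["f0"]["color"] == "orange"
        assert not g.nodes["f1"]["bold"] and g.nodes["f1"]["color"] == "blue"
        assert g.nodes["f2"]["color"] is None
        assert g.nodes["f0"]["size"] == pytest.approx(-np.log10(0.04))

    def test_edge_counts_match_brute_force(self, rng):
        n = 50
        base = rng.normal(0, 1, n)
        data = {
            f"f{i}": 0.5 * base + rng.normal(0, 1, n) * (0.2 + 0.2 * i) for i in range(9)
        }
        t = _table(data)
        g = correlation_network(t, _assoc(data.keys()), embed_seed=0)
        classes = [d["weight_class"] for _, _, d in g.edges(data=True)]
        assert (classes.count("thin"), classes.count("thick")) == spearman_edge_counts(
            t.data
        )

    def test_incomplete_table_rejected(self):
        t = _table({"a": [1.0, np.nan, 3.0]}, {"a": "numeric"})
        with pytest.raises(ValueError, match="imputed"):
            correlation_network(t, _assoc(["a"]), embed_seed=0)


class TestCVPredict:
    def test_noiseless_linear_signal_is_learned(self, rng):
        n = 80
        x1 = rng.normal(0, 1, n)
        t = _table({"x1": x1, "x2": rng.normal(0, 1, n)})
        y = pd.Series(2.0 * x1, index=t.data.index)
        res = cv_predict(t, y, folds=10, seed=0, n_permutations=30)
        assert res.r2 > 0.9
        assert res.significant

    def test_permuted_outcome_sits_in_its_own_null(self, rng):
        n = 40
        t = _table({f"f{i}": rng.normal(0, 1, n) for i in range(10)})
        y = pd.Series(rng.permutation(np.linspace(0, 1, n)), index=t.data.index)
        res = cv_predict(t, y, folds=10, seed=0, n_permutations=60)
        lo, hi = np.percentile(res.null_r2, [1, 99])
        assert lo <= res.r2 <= hi or not res.significant

    def test_folds_exceeding_n_rejected(self, rng):
        t = _table({"a": rng.normal(0, 1, 5)})
        with pytest.raises(ValueError):
            cv_predict(t, pd.Series(np.arange(5.0), index=t.data.index), folds=10)
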