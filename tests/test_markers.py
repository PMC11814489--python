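import numpy as np
import pandas as pd
import pytest

from annoflow import (
    ExpressionMatrix,
    LinkProvenance,
    MultimodalDataset,
    NodeProvenance,
    Selection,
    cohens_d,
    effect_table,
    mean_expression,
    resolve_selection,
    select_display_markers,
)
from annoflow.errors import ConfigurationError, ValidationError


def naive_cohens_d(x, y):
    """Pure-python reference implementation (independent of the vectorized path)."""
    mx = sum(x) / len(x)
    my = sum(y) / len(y)
    vx = sum((v - mx) ** 2 for v in x) / len(x)
    vy = sum((v - my) ** 2 for v in y) / len(y)
    denom = ((vx + vy) / 2) ** 0.5
    if denom == 0:
        return 0.0 if mx == my else float("inf") * (1 if mx > my else -1)
    return (mx - my) / denom


def naive_effect_table(values, labels):
    """Per-pair loop oracle: dict (feature_idx, a, b) -> d and medians."""
    groups = sorted(set(labels))
    pairwise = {}
    for f in range(values.shape[1]):
        for a in groups:
            for b in groups:
                if a == b:
                    continue
                x = [values[i, f] for i in range(len(labels)) if labels[i] == a]
                y = [values[i, f] for i in range(len(labels)) if labels[i] == b]
                pairwise[(f, a, b)] = naive_cohens_d(x, y)
    medians = {}
    for f in range(values.shape[1]):
        for a in groups:
            ds = sorted(pairwise[(f, a, b)] for b in groups if b != a)
            m = len(ds)
            medians[(f, a)] = (ds[m // 2] if m % 2
                               else (ds[m // 2 - 1] + ds[m // 2]) / 2)
    return pairwise, medians


class TestCohensD:
    def test_unit_variance_groups(self):
        # mean 3 sd 1 vs mean 1 sd 1 -> d = 2
        x = np.array([2.0, 4.0, 3.0, 3.0])   # mean 3, pop var 0.5
        x = (x - x.mean()) / x.std() + 3.0   # force mean 3, pop sd 1
        y = (x - 3.0) + 1.0                  # mean 1, pop sd 1
        assert cohens_d(x, y) == pytest.approx(2.0)

    def test_zero_variance_separated_groups_is_infinite(self):
        assert cohens_d([3, 3], [1, 1]) == np.inf
        assert cohens_d([1, 1], [3, 3]) == -np.inf

    def test_identical_samples_give_zero(self):
        x = [1.0, 2.0, 5.0]
        assert cohens_d(x, x) == 0.0
        assert cohens_d([2, 2], [2, 2]) == 0.0

    def test_empty_vector_rejected(self):
        with pytest.raises(ValidationError):
            cohens_d([], [1.0])

    def test_matches_naive_on_random_vectors(self):
        rng = np.random.default_rng(20)
        for _ in range(50):
            x = rng.normal(size=rng.integers(1, 10))
            y = rng.normal(size=rng.integers(1, 10))
            assert cohens_d(x, y) == pytest.approx(
                naive_cohens_d(list(x), list(y)), abs=1e-12)


class TestEffectTable:
    def _matrix(self, rng, n=30, f=15):
        return ExpressionMatrix(rng.normal(size=(n, f)),
                                [f"f{j:02d}" for j in range(f)])

    def test_median_of_two_pairwise_values(self):
        # engineered so feature f00 has d(A,B)=1 and d(A,C)=3 exactly
        def group(mean, sd, n=4):
            base = np.array([-1.0, 1.0, -1.0, 1.0])  # mean 0, pop sd 1
            return base * sd + mean
        values = np.concatenate([group(2.0, 1.0), group(1.0, 1.0), group(-1.0, 1.0)])
        labels = ["A"] * 4 + ["B"] * 4 + ["C"] * 4
        table = effect_table(ExpressionMatrix(values[:, None], ["f00"]), labels)
        assert table.pairwise_d("f00", "A", "B") == pytest.approx(1.0)
        assert table.pairwise_d("f00", "A", "C") == pytest.approx(3.0)
        assert table.median_d("f00", "A") == pytest.approx(2.0)

    def test_two_groups_median_equals_single_pairwise(self):
        rng = np.random.default_rng(21)
        mat = self._matrix(rng)
        labels = ["A"] * 15 + ["B"] * 15
        table = effect_table(mat, labels)
        np.testing.assert_allclose(table.median[0], table.pairwise[0, 1],
                                   atol=1e-12)

    def test_matches_naive_oracle(self):
        rng = np.random.default_rng(22)
        for _ in range(5):
            mat = self._matrix(rng)
            labels = list(rng.choice(["A", "B", "C"], size=30))
            while len(set(labels)) < 3:
                labels = list(rng.choice(["A", "B", "C"], size=30))
            table = effect_table(mat, labels)
            pairwise, medians = naive_effect_table(mat.dense(), labels)
            for (f, a, b), d in pairwise.items():
                assert table.pairwise[table.groups.index(a),
                                      table.groups.index(b), f] == pytest.approx(
                    d, abs=1e-10)
            for (f, a), m in medians.items():
                assert table.median[table.groups.index(a), f] == pytest.approx(
                    m, abs=1e-10)

    def test_pairwise_antisymmetry(self):
        rng = np.random.default_rng(23)
        mat = self._matrix(rng)
        labels = list(rng.choice(["A", "B", "C"], size=30))
        table = effect_table(mat, labels)
        for ai in range(len(table.groups)):
            for bi in range(len(table.groups)):
                if ai == bi:
                    continue
                fwd, rev = table.pairwise[ai, bi], table.pairwise[bi, ai]
                finite = np.isfinite(fwd)
                np.testing.assert_allclose(fwd[finite], -rev[finite], atol=1e-12)
                assert np.array_equal(fwd[~finite], -rev[~finite])

    def test_invariant_to_cell_and_label_order(self):
        rng = np.random.default_rng(24)
        mat = self._matrix(rng)
        labels = np.array(["A"] * 10 + ["B"] * 10 + ["C"] * 10, dtype=object)
        table = effect_table(mat, labels)
        perm = rng.permutation(30)
        shuffled = effect_table(
            ExpressionMatrix(mat.dense()[perm], list(mat.feature_ids)), labels[perm])
        np.testing.assert_allclose(table.median, shuffled.median, atol=1e-10)
        assert table.top_k == shuffled.top_k

    def test_top_k_positive_only_lexicographic_ties(self):
        # two features with identical positive medians -> id order breaks the tie
        values = np.array([[1.0, 1.0, 0.0], [1.0, 1.0, 0.0],
                           [0.0, 0.0, 0.0], [0.0, 0.0, 0.0]])
        # add tiny noise to give nonzero variance without touching means' order
        noise = np.array([[1, -1, 1, -1]]).T * 1e-6
        table = effect_table(ExpressionMatrix(values + noise, ["b", "a", "c"]),
                             ["hi", "hi", "lo", "lo"], k=2)
        assert table.top_k["hi"] == ["a", "b"]  # equal medians, id ascending
        assert table.top_k["lo"] == []          # nothing upregulated in "lo"

    def test_small_groups_dropped_with_warning(self, caplog):
        rng = np.random.default_rng(25)
        mat = self._matrix(rng, n=9)
        labels = ["A"] * 4 + ["B"] * 4 + ["C"]
        with caplog.at_level("WARNING"):
            table = effect_table(mat, labels)
        assert table.groups == ["A", "B"]
        with pytest.raises(ValidationError):
            effect_table(self._matrix(rng, n=5), ["A"] * 4 + ["C"])


class TestMeanExpression:
    def test_single_cell_selection_returns_its_row(self):
        rng = np.random.default_rng(26)
        mat = ExpressionMatrix(rng.normal(size=(5, 4)), list("abcd"))
        mask = np.zeros(5, dtype=bool)
        mask[2] = True
        np.testing.assert_array_equal(mean_expression(mat, mask), mat.dense()[2])

    def test_halves_average_to_global_mean(self):
        rng = np.random.default_rng(27)
        mat = ExpressionMatrix(rng.normal(size=(10, 4)), list("abcd"))
        first = mean_expression(mat, np.arange(10) < 5)
        second = mean_expression(mat, np.arange(10) >= 5)
        np.testing.assert_allclose((first + second) / 2, mat.dense().mean(axis=0),
                                   atol=1e-12)

    def test_empty_selection_rejected(self):
        mat = ExpressionMatrix(np.ones((3, 2)), ["a", "b"])
        with pytest.raises(ValidationError):
            mean_expression(mat, np.zeros(3, dtype=bool))


def _two_group_dataset(rng, n_features, n_per_side=200, planted=()):
    """Two groups; `planted` = [(feature_idx, delta)] mean shifts for group 'g1'."""
    n = 2 * n_per_side
    values = rng.normal(0.0, 0.3, size=(n, n_features))
    for j, delta in planted:
        values[:n_per_side, j] += delta
    return MultimodalDataset(
        [f"c{i}" for i in range(n)],
        {"M": ExpressionMatrix(values, [f"f{j:04d}" for j in range(n_features)])},
        pd.DataFrame({"ann": ["g1"] * n_per_side + ["g2"] * n_per_side}),
    )


class TestSelectDisplayMarkers:
    def test_low_dim_path_uses_all_features(self):
        rng = np.random.default_rng(28)
        ds = _two_group_dataset(rng, n_features=30)
        s1 = resolve_selection(ds, NodeProvenance("ann", "g1"))
        s2 = resolve_selection(ds, NodeProvenance("ann", "g2"))
        panel = select_display_markers(ds, "M", s1, s2)
        assert panel.strategy == "low_dim"
        assert len(panel.ranking) == 30  # every feature was a candidate

    def test_planted_markers_rank_first(self):
        hits = 0
        for seed in range(20):
            rng = np.random.default_rng(seed)
            ds = _two_group_dataset(rng, 30, planted=[(4, 2.0), (11, -2.0)])
            s1 = resolve_selection(ds, NodeProvenance("ann", "g1"))
            s2 = resolve_selection(ds, NodeProvenance("ann", "g2"))
            panel = select_display_markers(ds, "M", s1, s2)
            if set(panel.markers[:2]) == {"f0004", "f0011"}:
                hits += 1
        assert hits == 20

    def test_identical_selections_fall_back_to_tie_break_order(self):
        rng = np.random.default_rng(29)
        ds = _two_group_dataset(rng, 10)
        s1 = resolve_selection(ds, NodeProvenance("ann", "g1"))
        panel = select_display_markers(ds, "M", s1, s1, required=["f0007"],
                                       n_display=3)
        assert panel.markers[0] == "f0007"
        # all deltas are exactly 0 -> candidates in feature-id order
        assert panel.markers[1:] == ["f0000", "f0001", "f0002"]

    def test_required_unknown_feature_named_in_error(self):
        rng = np.random.default_rng(30)
        ds = _two_group_dataset(rng, 10)
        s1 = resolve_selection(ds, NodeProvenance("ann", "g1"))
        s2 = resolve_selection(ds, NodeProvenance("ann", "g2"))
        with pytest.raises(ConfigurationError, match="nope"):
            select_display_markers(ds, "M", s1, s2, required=["nope"])

    def test_high_dim_path_prefilters_by_effect_table(self):
        rng = np.random.default_rng(31)
        ds = _two_group_dataset(rng, 1200, planted=[(7, 2.0)])
        s1 = resolve_selection(ds, NodeProvenance("ann", "g1"))
        s2 = resolve_selection(ds, NodeProvenance("ann", "g2"))
        panel = select_display_markers(ds, "M", s1, s2, high_dim_threshold=1000)
        assert panel.strategy == "high_dim"
        assert len(panel.ranking) <= 20  # union of top-10 lists of 2 groups
        assert panel.markers[0] == "f0007"

    def test_dispatch_threshold_is_strict(self):
        rng = np.random.default_rng(32)
        ds = _two_group_dataset(rng, 50)
        s1 = resolve_selection(ds, NodeProvenance("ann", "g1"))
        s2 = resolve_selection(ds, NodeProvenance("ann", "g2"))
        assert select_display_markers(ds, "M", s1, s2,
                                      high_dim_threshold=50).strategy == "low_dim"
        assert select_display_markers(ds, "M", s1, s2,
                                      high_dim_threshold=49).strategy == "high_dim"

    def test_prefiltered_on_candidate_union_matches_high_dim(self):
        # consistency identity: high-dim result == prefiltered result when the
        # prefiltered matrix equals the high-dim candidate union
        rng = np.random.default_rng(33)
        ds = _two_group_dataset(rng, 1100, planted=[(3, 1.5), (900, -1.0)])
        s1 = resolve_selection(ds, NodeProvenance("ann", "g1"))
        s2 = resolve_selection(ds, NodeProvenance("ann", "g2"))
        panel_hd = select_display_markers(ds, "M", s1, s2, high_dim_threshold=1000)
        candidates = sorted(panel_hd.ranking["feature"])
        sub = MultimodalDataset(
            ds.cell_ids,
            {"M": ds.modalities["M"].subset_features(candidates)},
            ds.annotations,
        )
        panel_pf = select_display_markers(sub, "M",
                                          resolve_selection(sub, s1.provenance),
                                          resolve_selection(sub, s2.provenance),
                                          prefiltered=True)
        assert panel_pf.markers == panel_hd.markers
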