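import numpy as np
import pandas as pd
import pytest

from annoflow import (
    ContingencyTable,
    ExpressionMatrix,
    MultimodalDataset,
    build_crosstab,
    filter_links,
    merge_labels,
    sankey_payload,
)
from annoflow.errors import AllFilteredError, ConfigurationError
from conftest import make_random_dataset


def brute_force_crosstab(dataset, left, right):
    """Independent nested-loop counter (the oracle)."""
    counts = {}
    lvals = dataset.annotation(left)
    rvals = dataset.annotation(right)
    for i in range(dataset.n_cells):
        a, b = lvals[i], rvals[i]
        if a == dataset.missing_token or b == dataset.missing_token:
            continue
        counts[(a, b)] = counts.get((a, b), 0) + 1
    return counts


def make_dataset_from_labels(left, right):
    n = len(left)
    return MultimodalDataset(
        [f"c{i}" for i in range(n)],
        {"M": ExpressionMatrix(np.zeros((n, 1)), ["f"])},
        pd.DataFrame({"A": left, "B": right}),
    )


class TestBuildCrosstab:
    def test_simple_counts(self):
        ds = make_dataset_from_labels(["x", "x", "y"], ["u", "v", "u"])
        table = build_crosstab(ds, "A", "B")
        assert table.counts == {("x", "u"): 1, ("x", "v"): 1, ("y", "u"): 1}

    def test_constant_left_column_gives_one_row(self):
        ds = make_dataset_from_labels(["x"] * 5, ["u", "u", "v", "v", "v"])
        table = build_crosstab(ds, "A", "B")
        assert table.left_labels() == ["x"]
        assert table.to_frame().loc["x"].to_dict() == {"u": 2, "v": 3}

    def test_identical_annotation_names_rejected(self, tiny_dataset):
        with pytest.raises(ConfigurationError):
            build_crosstab(tiny_dataset, "main", "main")

    def test_missing_token_cells_excluded(self):
        ds = make_dataset_from_labels(["x", "NA", "y"], ["u", "u", "NA"])
        table = build_crosstab(ds, "A", "B")
        assert table.counts == {("x", "u"): 1}

    def test_matches_brute_force_on_random_datasets(self):
        rng = np.random.default_rng(10)
        for _ in range(100):
            ds = make_random_dataset(rng, missing_rate=0.1)
            assert build_crosstab(ds, "A", "B").counts == brute_force_crosstab(ds, "A", "B")


def random_table(rng, max_count=40):
    n_left = int(rng.integers(1, 6))
    n_right = int(rng.integers(1, 6))
    counts = {}
    for a in range(n_left):
        for b in range(n_right):
            c = int(rng.integers(0, max_count))
            if c > 0:
                counts[(f"l{a}", f"r{b}")] = c
    return ContingencyTable("A", "B", counts)


class TestFilterLinks:
    def test_threshold_drops_small_links(self):
        table = ContingencyTable("A", "B", {("a", "x"): 25, ("b", "y"): 19,
                                            ("c", "z"): 5})
        ls = filter_links(table, min_cells=20)
        assert ls.links == [("a", "x", 25)]

    def test_zero_threshold_is_identity(self):
        rng = np.random.default_rng(11)
        table = random_table(rng)
        ls = filter_links(table, min_cells=0)
        assert dict(((a, b), n) for a, b, n in ls.links) == table.counts

    def test_node_totals_equal_sum_of_surviving_links(self):
        rng = np.random.default_rng(12)
        for _ in range(50):
            table = random_table(rng)
            try:
                ls = filter_links(table, min_cells=int(rng.integers(0, 30)))
            except AllFilteredError:
                continue
            for label, total in ls.left_nodes:
                assert total == sum(n for a, _, n in ls.links if a == label)
            for label, total in ls.right_nodes:
                assert total == sum(n for _, b, n in ls.links if b == label)
            link_labels = {a for a, _, _ in ls.links} | {b for _, b, _ in ls.links}
            node_labels = {l for l, _ in ls.left_nodes} | {l for l, _ in ls.right_nodes}
            assert link_labels == node_labels

    def test_node_filtering_iterates_to_fixed_point(self):
        # dropping link (b,y):15 leaves node b at 10 < 20, which orphans
        # (b,x):10, which drops node-x flow to 15 < 20, killing (a,x):15 too
        table = ContingencyTable("A", "B", {
            ("a", "x"): 15, ("b", "x"): 10, ("b", "y"): 15, ("c", "y"): 40,
        })
        ls = filter_links(table, min_cells=20)
        assert ls.links == [("c", "y", 40)]

    def test_idempotent_at_every_threshold(self):
        rng = np.random.default_rng(13)
        for _ in range(30):
            table = random_table(rng)
            max_count = max(table.counts.values(), default=0)
            for t in range(max_count + 2):
                try:
                    once = filter_links(table, t)
                except AllFilteredError:
                    continue
                again = filter_links(
                    ContingencyTable("A", "B",
                                     {(a, b): n for a, b, n in once.links}), t)
                assert once.links == again.links

    def test_survivors_shrink_monotonically_with_threshold(self):
        rng = np.random.default_rng(14)
        for _ in range(30):
            table = random_table(rng)
            max_count = max(table.counts.values(), default=0)
            prev = None
            for t in range(max_count + 2):
                try:
                    links = set(map(tuple, filter_links(table, t).links))
                except AllFilteredError:
                    links = set()
                if prev is not None:
                    assert links <= prev
                prev = links

    def test_all_filtered_error_carries_max_viable_threshold(self):
        table = ContingencyTable("A", "B", {("a", "x"): 25, ("b", "y"): 10})
        with pytest.raises(AllFilteredError) as err:
            filter_links(table, min_cells=26)
        assert err.value.max_viable_threshold == 25
        assert filter_links(table, 25).links == [("a", "x", 25)]


class TestMergeLabels:
    def test_merged_crosstab_counts_add(self, tiny_dataset):
        mapping = {"TCM": "CD4 T", "Naive": "CD4 T"}
        merged = merge_labels(tiny_dataset, "fine", mapping)
        assert "fine__grouped" in merged.annotation_names
        assert "fine" in merged.annotation_names  # original preserved
        before = build_crosstab(tiny_dataset, "fine", "main")
        after = build_crosstab(merged, "fine__grouped", "main")
        assert after.counts[("CD4 T", "CD4 T")] == (
            before.counts[("TCM", "CD4 T")] + before.counts[("Naive", "CD4 T")])

    def test_identity_mapping_leaves_crosstab_unchanged(self, tiny_dataset):
        labels = set(tiny_dataset.annotation("fine"))
        merged = merge_labels(tiny_dataset, "fine", {l: l for l in labels})
        assert (build_crosstab(merged, "fine__grouped", "main").counts
                == build_crosstab(tiny_dataset, "fine", "main").counts)

    def test_mapping_to_missing_token_rejected(self, tiny_dataset):
        with pytest.raises(ConfigurationError):
            merge_labels(tiny_dataset, "fine", {"TCM": "NA"})

    def test_merge_then_crosstab_commutes_with_row_summing(self):
        # commutativity oracle on random datasets and random mappings
        rng = np.random.default_rng(15)
        for _ in range(50):
            ds = make_random_dataset(rng)
            labels = sorted(set(ds.annotation("A")))
            groups = [f"G{rng.integers(0, 3)}" for _ in labels]
            mapping = dict(zip(labels, groups))
            merged_counts = build_crosstab(
                merge_labels(ds, "A", mapping), "A__grouped", "B").counts
            summed = {}
            for (a, b), n in build_crosstab(ds, "A", "B").counts.items():
                key = (mapping.get(a, a), b)
                summed[key] = summed.get(key, 0) + n
            assert merged_counts == summed
            assert sum(merged_counts.values()) == sum(
                build_crosstab(ds, "A", "B").counts.values())


class TestSankeyPayload:
    def test_two_by_two_all_twenties(self):
        table = ContingencyTable("A", "B", {
            ("a", "x"): 20, ("a", "y"): 20, ("b", "x"): 20, ("b", "y"): 20})
        payload = sankey_payload(filter_links(table, 20))
        assert len(payload["nodes"]) == 4
        assert len(payload["links"]) == 4
        assert all(l["value"] == 20 for l in payload["links"])

    def test_payload_is_deterministic(self):
        rng = np.random.default_rng(16)
        table = random_table(rng)
        ls = filter_links(table, 0)
        assert sankey_payload(ls) == sankey_payload(ls)

    def test_link_values_sum_to_linkset_total(self):
        rng = np.random.default_rng(17)
        for _ in range(20):
            table = random_table(rng)
            ls = filter_links(table, 0)
            if not ls.links:
                continue
            payload = sankey_payload(ls)
            assert sum(l["value"] for l in payload["links"]) == ls.total

    def test_nodes_ordered_by_descending_total_then_label(self):
        table = ContingencyTable("A", "B", {
            ("a", "x"): 5, ("b", "x"): 30, ("c", "x"): 30})
        payload = sankey_payload(filter_links(table, 0))
        left = [n["label"] for n in payload["nodes"] if n["side"] == "left"]
        assert left == ["b", "c", "a"]

    def test_selected_links_carry_color_tags(self):
        table = ContingencyTable("A", "B", {("a", "x"): 20, ("b", "y"): 20})
        payload = sankey_payload(filter_links(table, 0),
                                 selected_links={("a", "x"): 1})
        tags = {(payload["nodes"][l["source"]]["label"],
                 payload["nodes"][l["target"]]["label"]): l["color_tag"]
                for l in payload["links"]}
        assert tags[("a", "x")] == 1 and tags[("b", "y")] == 0
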