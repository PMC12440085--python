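"""Noise-band classification rules, tallies, aggregation and hub tables."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import conndiff as cd
from conndiff.classify import NOT_CLASSIFIED, read_chord_table
from conndiff.exceptions import ConfigError, ValidationError

GRID = (-0.3, -0.1, -0.04, 0.0, 0.04, 0.1, 0.3)
THR = 0.05


def banded(v):
    if v >= THR:
        return "P"
    if v <= -THR:
        return "N"
    return "Z"


def oracle_cross_sectional(a, b):
    """Independent decision table for the cross-sectional rule.

    Enumerates on (banded sign of a, banded sign of b, sign of d) with the
    magnitude tie-break spelled out case by case.
    """
    d = a - b
    sa, sb = banded(a), banded(b)
    if d == 0 or (sa == "Z" and sb == "Z"):
        return "indeterminate"
    table = {
        # d > 0 (A above B)
        ("P", "P", "+"): "stronger_positive_in_A",
        ("P", "Z", "+"): "stronger_positive_in_A",
        ("P", "N", "+"): "TIE_POSA_NEGB",
        ("Z", "N", "+"): "stronger_negative_in_B",
        ("N", "N", "+"): "stronger_negative_in_B",
        # d < 0 (A below B)
        ("N", "N", "-"): "stronger_negative_in_A",
        ("N", "Z", "-"): "stronger_negative_in_A",
        ("N", "P", "-"): "TIE_NEGA_POSB",
        ("Z", "P", "-"): "stronger_positive_in_B",
        ("P", "P", "-"): "stronger_positive_in_B",
    }
    cat = table.get((sa, sb, "+" if d > 0 else "-"), "indeterminate")
    if cat == "TIE_POSA_NEGB":
        if abs(a) > abs(b):
            return "stronger_positive_in_A"
        if abs(b) > abs(a):
            return "stronger_negative_in_B"
        return "stronger_positive_in_A"  # exact tie: positive preferred
    if cat == "TIE_NEGA_POSB":
        if abs(a) > abs(b):
            return "stronger_negative_in_A"
        if abs(b) > abs(a):
            return "stronger_positive_in_B"
        return "stronger_positive_in_B"  # exact tie: positive preferred
    return cat


def oracle_longitudinal(pre, post):
    """Independent decision table for the longitudinal rule."""
    d = post - pre
    sp, so = banded(pre), banded(post)
    if {sp, so} == {"P", "N"}:
        return "sign_transition"
    if sp == "Z" and so == "Z":
        return "indeterminate"
    if d == 0:
        return "indeterminate"
    table = {
        ("Z", "P", "+"): "more_positive",
        ("P", "P", "+"): "more_positive",
        ("P", "P", "-"): "less_positive",
        ("P", "Z", "-"): "less_positive",
        ("Z", "N", "-"): "more_negative",
        ("N", "N", "-"): "more_negative",
        ("N", "N", "+"): "less_negative",
        ("N", "Z", "+"): "less_negative",
    }
    return table.get((sp, so, "+" if d > 0 else "-"), "indeterminate")


class TestBandSign:
    @pytest.mark.parametrize("z,expected", [
        (0.04, "Z"),   # inside the open band: effectively zero
        (0.05, "P"),   # boundary counts as meaningful
        (-0.05, "N"),
        (-0.2, "N"),
        (0.0, "Z"),
    ])
    def test_examples(self, z, expected):
        assert cd.band_sign(z) == expected

    @given(st.floats(-1, 1))
    @settings(deadline=None)
    def test_mirror(self, z):
        mirror = {"P": "N", "N": "P", "Z": "Z"}
        assert cd.band_sign(-z) == mirror[cd.band_sign(z)]

    def test_bad_threshold(self):
        with pytest.raises(ConfigError):
            cd.band_sign(0.1, threshold=0.0)

    def test_nonfinite(self):
        with pytest.raises(ValidationError):
            cd.band_sign(float("nan"))


class TestCrossSectionalClassification:
    def test_exhaustive_grid_matches_oracle(self):
        for a in GRID:
            for b in GRID:
                got = cd.classify_cross_sectional(a, b, True, THR)
                want = oracle_cross_sectional(a, b)
                assert got == want, f"(a={a}, b={b}): {got} != {want}"

    @pytest.mark.parametrize("a,b,expected", [
        (0.3, 0.1, "stronger_positive_in_A"),
        (-0.3, -0.1, "stronger_negative_in_A"),
        (0.02, -0.01, "indeterminate"),
        (0.1, -0.3, "stronger_negative_in_B"),   # |b| larger wins
        (0.3, -0.1, "stronger_positive_in_A"),   # |a| larger wins
        (0.1, -0.1, "stronger_positive_in_A"),   # exact tie: positive
    ])
    def test_examples(self, a, b, expected):
        assert cd.classify_cross_sectional(a, b, True) == expected

    def test_not_significant_sentinel(self):
        assert cd.classify_cross_sectional(0.3, 0.1, False) == NOT_CLASSIFIED


class TestLongitudinalClassification:
    def test_exhaustive_grid_matches_oracle(self):
        for pre in GRID:
            for post in GRID:
                got = cd.classify_longitudinal(pre, post, True, THR)
                want = oracle_longitudinal(pre, post)
                assert got == want, f"(pre={pre}, post={post}): {got} != {want}"

    @pytest.mark.parametrize("pre,post,expected", [
        (0.1, 0.3, "more_positive"),
        (-0.1, -0.3, "more_negative"),
        (0.04, -0.04, "indeterminate"),
        (0.3, 0.1, "less_positive"),
        (-0.3, -0.1, "less_negative"),
        (0.2, -0.2, "sign_transition"),
        (-0.1, 0.1, "sign_transition"),
    ])
    def test_examples(self, pre, post, expected):
        assert cd.classify_longitudinal(pre, post, True) == expected

    def test_not_significant_sentinel(self):
        assert cd.classify_longitudinal(0.1, 0.3, False) == NOT_CLASSIFIED


class TestCountCategories:
    def test_tally_and_proportions(self):
        df = cd.count_categories([
            "stronger_positive_in_A", "stronger_positive_in_A",
            "stronger_positive_in_B", "indeterminate",
        ])
        by_cat = df.set_index("category")
        assert by_cat.loc["stronger_positive_in_A", "count"] == 2
        assert by_cat.loc["stronger_positive_in_A", "proportion"] == 0.5
        assert by_cat.loc["stronger_positive_in_B", "proportion"] == 0.25
        assert df["count"].sum() == 4

    def test_empty(self):
        assert cd.count_categories([]).empty

    @given(st.lists(st.sampled_from(["a", "b", "c"]), min_size=1,
                    max_size=40))
    @settings(deadline=None)
    def test_proportions_sum_to_one(self, cats):
        df = cd.count_categories(cats)
        assert df["proportion"].sum() == pytest.approx(1.0)
        assert df["count"].sum() == len(cats)


def _classified_frame(rows):
    return pd.DataFrame(
        rows, columns=["edge_i", "edge_j", "category", "delta_z", "q",
                       "weight"])


class TestAggregatePairs:
    def test_three_edge_fixture(self, parcellation16):
        lobes = [r.lobe for r in parcellation16]
        fr = [i for i, l in enumerate(lobes) if l == "Frontal"]
        li = [i for i, l in enumerate(lobes) if l == "Limbic"]
        te = [i for i, l in enumerate(lobes) if l == "Temporal"]
        df = _classified_frame([
            (min(fr[0], li[0]), max(fr[0], li[0]), "x", 0.1, 0.01, 1.0),
            (min(fr[1], li[1]), max(fr[1], li[1]), "x", 0.1, 0.01, 2.0),
            (min(fr[0], te[0]), max(fr[0], te[0]), "x", 0.1, 0.01, 0.5),
        ])
        table = cd.aggregate_pairs(df, parcellation16, "lobe")
        get = lambda a, b: table.counts[table.labels.index(a),
                                        table.labels.index(b)]
        assert get("Frontal", "Limbic") == 2
        assert get("Limbic", "Frontal") == 2
        assert get("Frontal", "Temporal") == 1
        assert table.total_edges == 3
        assert table.total_weight == pytest.approx(3.5)

    def test_within_label_edge_on_diagonal(self, parcellation16):
        lobes = [r.lobe for r in parcellation16]
        fr = [i for i, l in enumerate(lobes) if l == "Frontal"]
        df = _classified_frame([(fr[0], fr[1], "x", 0.1, 0.01, 1.0)])
        table = cd.aggregate_pairs(df, parcellation16, "lobe")
        k = table.labels.index("Frontal")
        assert table.counts[k, k] == 1
        assert table.total_edges == 1

    def test_unknown_region_rejected(self, parcellation16):
        df = _classified_frame([(0, 99, "x", 0.1, 0.01, 1.0)])
        with pytest.raises(ValidationError, match="99"):
            cd.aggregate_pairs(df, parcellation16, "lobe")

    def test_conservation_randomized(self, parcellation16):
        """Counts and weights are conserved at every level, 100+ cases."""
        rng = np.random.default_rng(33)
        n = len(parcellation16)
        for _ in range(120):
            n_edges = int(rng.integers(0, 25))
            rows = []
            for _ in range(n_edges):
                i, j = sorted(rng.choice(n, size=2, replace=False))
                rows.append((i, j, "x", rng.normal(),
                             rng.uniform(), rng.uniform()))
            df = _classified_frame(rows)
            for level in ("hemisphere", "lobe", "network"):
                table = cd.aggregate_pairs(df, parcellation16, level)
                assert table.total_edges == n_edges
                assert table.total_weight == pytest.approx(
                    df["weight"].sum() if n_edges else 0.0)
                np.testing.assert_array_equal(table.counts, table.counts.T)
                np.testing.assert_allclose(table.weights, table.weights.T)


class TestHubTable:
    def test_star_graph(self):
        df = _classified_frame([
            (0, 1, "x", 0.1, 0.01, 1.0),
            (0, 2, "x", 0.1, 0.01, 1.0),
            (0, 3, "x", 0.1, 0.01, 1.0),
        ])
        hubs = cd.hub_table(df)
        assert hubs.iloc[0]["region_id"] == 0
        assert hubs.iloc[0]["n_connections"] == 3
        assert set(hubs["n_connections"][1:]) == {1}

    def test_empty(self):
        hubs = cd.hub_table(_classified_frame([]))
        assert hubs.empty

    def test_handshake_random_fixture(self):
        rng = np.random.default_rng(34)
        edges = set()
        while len(edges) < 20:
            i, j = sorted(rng.choice(15, size=2, replace=False))
            edges.add((int(i), int(j)))
        df = _classified_frame([
            (i, j, "x", 0.1, 0.01, rng.uniform()) for i, j in sorted(edges)])
        hubs = cd.hub_table(df)
        # brute-force degree count
        degree = {}
        for i, j in edges:
            degree[i] = degree.get(i, 0) + 1
            degree[j] = degree.get(j, 0) + 1
        assert hubs["n_connections"].sum() == 2 * len(edges)
        for row in hubs.itertuples(index=False):
            assert row.n_connections == degree[row.region_id]

    def test_deterministic_sort(self):
        df = _classified_frame([
            (0, 1, "x", 0.1, 0.01, 1.0),
            (2, 3, "x", 0.1, 0.01, 5.0),
        ])
        hubs = cd.hub_table(df)
        # equal degree: heavier first, then lower id
        assert list(hubs["region_id"]) == [2, 3, 0, 1]


class TestChordExport:
    def test_roundtrip(self, parcellation16, tmp_path):
        lobes = [r.lobe for r in parcellation16]
        fr = [i for i, l in enumerate(lobes) if l == "Frontal"]
        li = [i for i, l in enumerate(lobes) if l == "Limbic"]
        te = [i for i, l in enumerate(lobes) if l == "Temporal"]
        df = _classified_frame([
            (min(fr[0], li[0]), max(fr[0], li[0]), "x", 0.1, 0.01, 1.0),
            (min(fr[1], li[1]), max(fr[1], li[1]), "x", 0.1, 0.01, 2.0),
            (min(fr[0], te[0]), max(fr[0], te[0]), "x", 0.1, 0.01, 0.5),
        ])
        table = cd.aggregate_pairs(df, parcellation16, "lobe")
        path = tmp_path / "chord.tsv"
        cd.export_chord_table(table, path)
        back = read_chord_table(path)
        assert len(back) == 2  # Frontal-Limbic and Frontal-Temporal
        # re-import reproduces the upper triangle
        for row in back.itertuples(index=False):
            a = table.labels.index(row.from_label)
            b = table.labels.index(row.to_label)
            assert table.counts[a, b] == row.count
            assert table.weights[a, b] == pytest.approx(row.weight)

    def test_empty_table_header_only(self, parcellation16, tmp_path):
        table = cd.aggregate_pairs(_classified_frame([]), parcellation16,
                                   "lobe")
        path = tmp_path / "chord.tsv"
        cd.export_chord_table(table, path)
        lines = path.read_text().strip().splitlines()
        assert lines == ["from_label\tto_label\tcount\tweight"]
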