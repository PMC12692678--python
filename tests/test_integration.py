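"""Quadrant assignment, critical-gene selection and miRNA re-selection."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mirstab.integrate import (
    assign_quadrants,
    mean_logfc,
    reselect_mirnas,
    select_critical_genes,
)
from tests._oracles import brute_force_top_genes


def _gene_logfc(rows):
    return pd.DataFrame(rows, columns=["gene_id", "cancer_type", "logfc"])


def _gene_profiles(divs):
    return pd.DataFrame(
        {"gene_id": list(divs), "n_under_regulators": 0, "n_over_regulators": 0,
         "n_total_regulators": 30, "gene_div": list(divs.values())}
    )


class TestMeanLogfc:
    @pytest.mark.parametrize("values,expected", [([1.0, -1.0], 0.0), ([2.0, 4.0, 6.0], 4.0)])
    def test_arithmetic(self, values, expected):
        table = _gene_logfc([("g", f"c{i}", v) for i, v in enumerate(values)])
        assert mean_logfc(table)["g"] == pytest.approx(expected)

    def test_invariant_to_cancer_order(self):
        table = _gene_logfc([("g", "c1", 1.0), ("g", "c2", 3.0)])
        reordered = table.iloc[::-1].reset_index(drop=True)
        assert mean_logfc(table)["g"] == mean_logfc(reordered)["g"]

    def test_gene_without_values_dropped_with_warning(self):
        table = _gene_logfc([("g1", "c1", 1.0), ("g2", "c1", np.nan)])
        with pytest.warns(UserWarning, match="g2"):
            means = mean_logfc(table)
        assert list(means.index) == ["g1"]


class TestAssignQuadrants:
    def test_sign_pattern_examples(self):
        profiles = _gene_profiles({"a": 0.8, "b": 0.8, "c": -0.5, "d": -0.5})
        means = pd.Series([2.0, -2.0, -1.0, 1.0], index=["a", "b", "c", "d"],
                          name="mean_logfc").rename_axis("gene_id")
        out = assign_quadrants(profiles, means).set_index("gene_id")
        assert out.loc["a", "quadrant"] == 1 and out.loc["a", "concordant"]
        assert out.loc["b", "quadrant"] == 2 and not out.loc["b", "concordant"]
        assert out.loc["c", "quadrant"] == 3 and out.loc["c", "concordant"]
        assert out.loc["d", "quadrant"] == 4 and not out.loc["d", "concordant"]

    @pytest.mark.parametrize(
        "ml,gd,quadrant",
        [(0.0, 0.5, 1), (0.0, -0.5, 3), (1.0, 0.0, 1), (-1.0, 0.0, 2), (0.0, 0.0, 1)],
    )
    def test_zero_axis_lower_quadrant_non_concordant(self, ml, gd, quadrant):
        profiles = _gene_profiles({"g": gd})
        means = pd.Series([ml], index=["g"], name="mean_logfc").rename_axis("gene_id")
        row = assign_quadrants(profiles, means).iloc[0]
        assert row["quadrant"] == quadrant
        assert not row["concordant"]

    @given(
        ml=st.floats(-10, 10, allow_nan=False),
        gd=st.floats(-1, 1, allow_nan=False),
    )
    @settings(deadline=None, max_examples=100, derandomize=True)
    def test_quadrants_partition_the_plane(self, ml, gd):
        profiles = _gene_profiles({"g": gd})
        means = pd.Series([ml], index=["g"], name="mean_logfc").rename_axis("gene_id")
        row = assign_quadrants(profiles, means).iloc[0]
        assert row["quadrant"] in (1, 2, 3, 4)
        assert row["concordant"] == bool((ml > 0 and gd > 0) or (ml < 0 and gd < 0))


def _summaries(rows):
    return pd.DataFrame(rows, columns=["gene_id", "mean_logfc", "gene_div"]).assign(
        quadrant=1, concordant=False
    )


class TestSelectCriticalGenes:
    def test_pareto_dominant_gene_ranks_first(self):
        summaries = _summaries([("weak", 0.5, 0.1), ("strong", 3.0, 0.9)])
        assert select_critical_genes(summaries, n=1) == ["strong"]

    def test_all_equal_scores_fall_back_to_lexicographic(self):
        summaries = _summaries([("gb", 1.0, 0.5), ("ga", 1.0, 0.5), ("gc", 1.0, 0.5)])
        assert select_critical_genes(summaries, n=2) == ["ga", "gb"]

    def test_matches_brute_force_sort_on_synthetic_instance(self):
        rng = np.random.default_rng(23)
        summaries = _summaries(
            [(f"g{i:03d}", rng.normal(0, 2), rng.uniform(-1, 1)) for i in range(100)]
        )
        assert select_critical_genes(summaries, n=30) == brute_force_top_genes(summaries, 30)

    def test_permutation_invariance(self):
        rng = np.random.default_rng(29)
        summaries = _summaries(
            [(f"g{i}", rng.normal(), rng.uniform(-1, 1)) for i in range(50)]
        )
        shuffled = summaries.sample(frac=1.0, random_state=1).reset_index(drop=True)
        assert select_critical_genes(summaries, n=10) == select_critical_genes(shuffled, n=10)

    def test_invalid_n_rejected(self):
        summaries = _summaries([("g", 1.0, 0.5)])
        with pytest.raises(ValueError):
            select_critical_genes(summaries, n=0)
        with pytest.raises(ValueError):
            select_critical_genes(summaries, n=2)

    def test_product_rule_orders_by_raw_product(self):
        summaries = _summaries([("a", 4.0, 0.1), ("b", 1.0, 0.9)])
        assert select_critical_genes(summaries, n=1, score_rule="product") == ["b"]


def _labels(mapping):
    return pd.DataFrame({"mirna_id": list(mapping), "label": list(mapping.values())})


class TestReselectMirnas:
    def _instance(self, seed=31, n_mirnas=30, n_genes=40, targets_per_mirna=12):
        rng = np.random.default_rng(seed)
        genes = [f"g{i}" for i in range(n_genes)]
        rows = [
            (f"m{i}", g)
            for i in range(n_mirnas)
            for g in rng.choice(genes, size=targets_per_mirna, replace=False)
        ]
        pairs = pd.DataFrame(rows, columns=["mirna_id", "gene_id"])
        labels = _labels(
            {f"m{i}": ("critical_under" if i % 3 == 0 else
                       "critical_over" if i % 3 == 1 else "neutral")
             for i in range(n_mirnas)}
        )
        return pairs, labels, genes

    def test_min_one_selects_every_critical_mirna_with_a_hit(self):
        pairs, labels, genes = self._instance()
        sel = reselect_mirnas(pairs, genes, labels, min_genes=1)
        hit = set(pairs["mirna_id"])
        expect_under = {m for m in hit if m.startswith("m")
                        and int(m[1:]) % 3 == 0}
        assert sel.reselected_under == expect_under

    def test_inclusive_boundary_at_exactly_min_genes(self):
        pairs = pd.DataFrame(
            {"mirna_id": "m0", "gene_id": [f"g{i}" for i in range(10)]}
        )
        labels = _labels({"m0": "critical_under"})
        sel = reselect_mirnas(pairs, [f"g{i}" for i in range(10)], labels, min_genes=10)
        assert sel.reselected_under == {"m0"}

    def test_neutral_mirnas_never_selected(self):
        pairs, labels, genes = self._instance()
        sel = reselect_mirnas(pairs, genes, labels, min_genes=1)
        neutral = set(labels.loc[labels["label"] == "neutral", "mirna_id"])
        assert not (sel.reselected_under | sel.reselected_over) & neutral

    def test_counts_match_brute_force_bipartite_count(self):
        pairs, labels, genes = self._instance(seed=37)
        critical_genes = genes[:15]
        sel = reselect_mirnas(pairs, critical_genes, labels, min_genes=5)
        label_of = dict(zip(labels["mirna_id"], labels["label"]))
        brute_under = {
            m
            for m in set(pairs["mirna_id"])
            if label_of[m] == "critical_under"
            and len({g for _, g in pairs[pairs["mirna_id"] == m].itertuples(index=False)
                     if g in set(critical_genes)}) >= 5
        }
        assert sel.reselected_under == brute_under

    def test_raising_min_genes_never_grows_the_sets(self):
        pairs, labels, genes = self._instance(seed=41)
        previous_under, previous_over = None, None
        for k in (1, 3, 5, 8, 12):
            sel = reselect_mirnas(pairs, genes, labels, min_genes=k)
            if previous_under is not None:
                assert sel.reselected_under <= previous_under
                assert sel.reselected_over <= previous_over
            previous_under, previous_over = sel.reselected_under, sel.reselected_over

    def test_sets_are_disjoint(self):
        pairs, labels, genes = self._instance(seed=43)
        sel = reselect_mirnas(pairs, genes, labels, min_genes=2)
        assert not sel.reselected_under & sel.reselected_over
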