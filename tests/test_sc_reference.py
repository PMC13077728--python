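"""Specificity-score derivation: control filters, normalization, selection."""

import numpy as np
import pandas as pd
import pytest
import scipy.sparse as sp
from hypothesis import given, settings, strategies as st

from ctprs.core import FeatureMatrix
from ctprs.sc_reference import (
    ControlCriteria,
    filter_expressed_features,
    hierarchical_subtype_selection,
    mean_activity_by_type,
    normalize_rna,
    select_control_cells,
    select_top_fraction,
    specificity_scores,
    tfidf_transform,
)

from conftest import make_cells, make_features, make_matrix


class TestControlCells:
    def test_control_like_cell_selected(self):
        cells = make_cells(1, braak=[2], neuritic_plaque_status=["possible"])
        assert select_control_cells(cells, ControlCriteria.rna_default()) == {"c0"}

    def test_braak_above_two_excluded(self):
        cells = make_cells(2, braak=[2, 3])
        assert select_control_cells(cells, ControlCriteria.rna_default()) == {"c0"}

    def test_tss_enrichment_boundary_is_strict(self):
        # TSS enrichment must exceed 1; exactly 1.0 fails the gate.
        cells = make_cells(3, tss_enrichment=[1.0, 1.01, 0.5])
        got = select_control_cells(cells, ControlCriteria.atac_default())
        assert got == {"c1"}

    def test_mmse_boundary_is_strict(self):
        cells = make_cells(2, mmse=[23.0, 23.5])
        assert select_control_cells(cells, ControlCriteria.rna_default()) == {"c1"}

    def test_missing_required_field_errors(self):
        cells = make_cells(2, braak=[1, np.nan])
        with pytest.raises(ValueError, match="braak"):
            select_control_cells(cells, ControlCriteria.rna_default())

    def test_unknown_cell_type_errors(self):
        cells = make_cells(1, cell_type="XXX")
        with pytest.raises(ValueError, match="unknown cell_type"):
            select_control_cells(
                cells, ControlCriteria.rna_default(), known_types=("AST",)
            )

    def test_no_survivors_errors(self):
        cells = make_cells(2, braak=[5, 6])
        with pytest.raises(ValueError, match="no control cells"):
            select_control_cells(cells, ControlCriteria.rna_default())


class TestExpressionFilter:
    def test_kept_dropped_and_boundary(self):
        # gene0: 3/10 AST cells -> kept; gene1: nowhere -> dropped;
        # gene2: exactly 1/10 of one type -> kept (>= is inclusive).
        counts = np.zeros((20, 3))
        counts[:3, 0] = 5
        counts[10, 2] = 1
        m = make_matrix(counts, ["AST"] * 10 + ["MIC"] * 10)
        assert filter_expressed_features(m, 0.10) == ["f0", "f2"]

    def test_order_preserved(self):
        counts = np.ones((4, 5))
        m = make_matrix(counts, ["AST", "AST", "MIC", "MIC"])
        assert filter_expressed_features(m, 0.5) == [f"f{i}" for i in range(5)]


class TestNormalizeRna:
    def test_counts_per_scale(self):
        m = make_matrix([[1, 1, 2]], ["AST"])
        out = np.asarray(normalize_rna(m).todense())
        np.testing.assert_allclose(out, [[2500, 2500, 5000]])

    def test_single_nonzero_feature_gets_full_scale(self):
        m = make_matrix([[0, 7, 0]], ["AST"])
        out = np.asarray(normalize_rna(m).todense())
        np.testing.assert_allclose(out, [[0, 1e4, 0]])

    def test_proportional_cells_normalize_identically(self):
        m = make_matrix([[1, 2, 3], [10, 20, 30]], ["AST", "AST"])
        out = np.asarray(normalize_rna(m).todense())
        np.testing.assert_allclose(out[0], out[1])

    def test_all_zero_cell_errors_with_ids(self):
        m = make_matrix([[1, 1], [0, 0]], ["AST", "AST"])
        with pytest.raises(ValueError, match="c1"):
            normalize_rna(m)


class TestTfidf:
    def test_uniform_two_by_two(self):
        m = make_matrix([[1, 1], [1, 1]], ["AST", "MIC"], modality="ATAC")
        out = np.asarray(tfidf_transform(m).todense())
        np.testing.assert_allclose(out, np.log(1 + 5000) * np.ones((2, 2)))

    def test_absent_peak_column_stays_zero(self):
        m = make_matrix([[1, 0], [2, 0]], ["AST", "MIC"], modality="ATAC")
        out = np.asarray(tfidf_transform(m).todense())
        np.testing.assert_array_equal(out[:, 1], 0)

    def test_tf_is_scale_invariant_within_cell(self):
        m1 = make_matrix([[1, 3], [5, 5]], ["AST", "MIC"], modality="ATAC")
        m2 = make_matrix([[2, 6], [5, 5]], ["AST", "MIC"], modality="ATAC")
        out1 = np.asarray(tfidf_transform(m1).todense())
        out2 = np.asarray(tfidf_transform(m2).todense())
        np.testing.assert_allclose(out1[0], out2[0])

    def test_requires_atac(self):
        m = make_matrix([[1]], ["AST"], modality="RNA")
        with pytest.raises(ValueError, match="ATAC"):
            tfidf_transform(m)


class TestMeanActivity:
    def test_group_means(self):
        cells = make_cells(3)
        cells["cell_type"] = ["AST", "AST", "MIC"]
        vals = sp.csr_matrix(np.array([[2.0], [4.0], [10.0]]))
        out = mean_activity_by_type(vals, cells, ["g0"])
        assert out.loc["g0", "AST"] == 3.0
        assert out.loc["g0", "MIC"] == 10.0

    def test_negative_values_clipped_for_atac(self):
        cells = make_cells(2)
        vals = sp.csr_matrix(np.array([[-1.0], [3.0]]))
        out = mean_activity_by_type(vals, cells, ["p0"], clip_negative=True)
        assert out.loc["p0", "AST"] == 1.5


class TestSpecificity:
    def test_uniform_means_give_uniform_specificity(self):
        means = pd.DataFrame(
            {c: [2.0] for c in "ABCDEFG"}, index=pd.Index(["g"], name="feature_id")
        )
        spec = specificity_scores(means)
        np.testing.assert_allclose(spec["specificity"], 1 / 7)

    def test_exclusive_expression(self):
        means = pd.DataFrame(
            {"AST": [5.0], "MIC": [0.0]}, index=pd.Index(["g"], name="feature_id")
        )
        spec = specificity_scores(means).set_index("cell_type")["specificity"]
        assert spec["AST"] == 1.0 and spec["MIC"] == 0.0

    def test_three_to_one_split(self):
        means = pd.DataFrame(
            {"AST": [3.0], "MIC": [1.0]}, index=pd.Index(["g"], name="feature_id")
        )
        spec = specificity_scores(means).set_index("cell_type")["specificity"]
        assert spec["AST"] == 0.75 and spec["MIC"] == 0.25

    def test_zero_sum_feature_flagged_not_nan(self):
        means = pd.DataFrame(
            {"AST": [0.0, 1.0], "MIC": [0.0, 1.0]},
            index=pd.Index(["dead", "live"], name="feature_id"),
        )
        spec = specificity_scores(means)
        dead = spec[spec["feature_id"] == "dead"]
        assert (dead["specificity"] == 0).all() and dead["zero_sum"].all()

    def test_row_sums_are_one_or_zero(self, small_reference):
        from ctprs.sc_reference import specificity_pipeline

        matrix, _ = small_reference
        spec, _ = specificity_pipeline(matrix)
        sums = spec.groupby("feature_id")["specificity"].sum()
        zero = spec.groupby("feature_id")["zero_sum"].first()
        np.testing.assert_allclose(sums[~zero], 1.0, atol=1e-9)
        np.testing.assert_allclose(sums[zero], 0.0)

    @settings(deadline=None, max_examples=25, derandomize=True)
    @given(
        k=st.floats(min_value=1e-3, max_value=1e3),
        vals=st.lists(
            st.lists(st.floats(min_value=0, max_value=100), min_size=3, max_size=3),
            min_size=2,
            max_size=6,
        ),
    )
    def test_scale_invariance(self, k, vals):
        """Multiplying all means by one constant leaves specificity unchanged."""
        means = pd.DataFrame(
            vals, columns=["A", "B", "C"],
            index=pd.Index([f"g{i}" for i in range(len(vals))], name="feature_id"),
        )
        s1 = specificity_scores(means)["specificity"].to_numpy()
        s2 = specificity_scores(means * k)["specificity"].to_numpy()
        np.testing.assert_allclose(s1, s2, atol=1e-9)


def brute_force_top_q(means: pd.DataFrame, ct: str, q: float) -> set:
    """Independent full-sort oracle for per-type top-fraction selection."""
    totals = means.sum(axis=1)
    live = totals > 0
    spec = means[ct].where(live, 0) / totals.where(live, 1)
    order = sorted(
        means.index[live],
        key=lambda g: (-spec[g], -means.loc[g, ct], g),
    )
    n = int(np.floor(q * len(means)))
    return set(order[:n])


class TestTopFraction:
    def test_selection_count_is_floor(self):
        rng = np.random.default_rng(0)
        means = pd.DataFrame(
            rng.uniform(0.1, 1, size=(10, 2)), columns=["AST", "MIC"],
            index=pd.Index([f"g{i}" for i in range(10)], name="feature_id"),
        )
        spec = specificity_scores(means)
        sel = select_top_fraction(spec, 0.20)
        assert all(len(s) == 2 for s in sel.values())

    def test_tie_break_by_feature_id(self):
        means = pd.DataFrame(
            {"AST": [0.9, 0.5, 0.5, 0.2, 0.1], "MIC": [0.1, 0.5, 0.5, 0.8, 0.9]},
            index=pd.Index(["a", "b", "c", "d", "e"], name="feature_id"),
        )
        spec = specificity_scores(means)
        sel = select_top_fraction(spec, 0.4)
        assert sel["AST"] == {"a", "b"}  # 'b' < 'c' lexicographically

    def test_matches_brute_force_on_random_instances(self):
        rng = np.random.default_rng(123)
        for _ in range(20):
            means = pd.DataFrame(
                rng.uniform(0, 1, size=(200, 4)).round(2),  # rounding forces ties
                columns=["AST", "MIC", "GLU", "GAB"],
                index=pd.Index([f"g{i:03d}" for i in range(200)], name="feature_id"),
            )
            spec = specificity_scores(means)
            sel = select_top_fraction(spec, 0.1)
            for ct in means.columns:
                assert sel[ct] == brute_force_top_q(means, ct, 0.1)

    def test_too_small_universe_errors(self):
        means = pd.DataFrame(
            {"AST": [1.0], "MIC": [1.0]}, index=pd.Index(["g"], name="feature_id")
        )
        with pytest.raises(ValueError, match="< 1"):
            select_top_fraction(specificity_scores(means), 0.5)

    def test_determinism(self):
        rng = np.random.default_rng(5)
        means = pd.DataFrame(
            rng.uniform(0, 1, size=(50, 3)), columns=["A", "B", "C"],
            index=pd.Index([f"g{i}" for i in range(50)], name="feature_id"),
        )
        s1 = specificity_scores(means)
        s2 = specificity_scores(means.copy())
        pd.testing.assert_frame_equal(s1, s2)
        assert select_top_fraction(s1, 0.2) == select_top_fraction(s2, 0.2)


class TestHierarchicalSubtypes:
    def test_floor_arithmetic_two_stage(self):
        rng = np.random.default_rng(1)
        fids = pd.Index([f"p{i:02d}" for i in range(50)], name="feature_id")
        primary = specificity_scores(
            pd.DataFrame(
                rng.uniform(0.1, 1, size=(50, 2)), columns=["GAB", "GLU"], index=fids
            )
        )
        sub_means = pd.DataFrame(
            rng.uniform(0.1, 1, size=(50, 4)),
            columns=[f"GAB_S{i}" for i in range(4)],
            index=fids,
        )
        sel = hierarchical_subtype_selection(primary, "GAB", sub_means)
        assert set(sel) == set(sub_means.columns)
        assert all(len(s) == 2 for s in sel.values())  # floor(.2*floor(.2*50))

    def test_planted_subtype_markers_recovered(self):
        from ctprs.sc_reference import specificity_pipeline
        from ctprs.synthdata import simulate_reference

        matrix, manifest = simulate_reference(
            n_types=2, type_labels=("GAB", "GLU"), n_cells_per_type=80,
            n_features=200, n_markers_per_type=20, fold=4.0, seed=9,
            subtype_parent="GAB", n_subtypes=4, n_markers_per_subtype=5,
        )
        spec, _ = specificity_pipeline(matrix, q=0.10)
        sub_cells = matrix.cells[matrix.cells["cell_type"] == "GAB"]
        universe = spec["feature_id"].unique().tolist()
        keep = matrix.features["feature_id"].isin(universe).to_numpy()
        sub_matrix = FeatureMatrix(
            counts=matrix.counts[:, keep],
            modality="RNA",
            features=matrix.features.loc[keep],
            cells=matrix.cells,
        )
        vals = normalize_rna(sub_matrix)
        gab = sub_cells.index.to_numpy()
        sub_means = mean_activity_by_type(
            sp.csr_matrix(vals)[gab],
            matrix.cells.loc[gab].reset_index(drop=True),
            sub_matrix.features["feature_id"],
            group_by="subtype",
        )
        sel = hierarchical_subtype_selection(
            spec, "GAB", sub_means, q_parent=0.5, q_subtype=0.2
        )
        hits = sum(
            len(set(manifest.marker_map[s]) & sel[s]) for s in sel
        )
        planted = sum(len(manifest.marker_map[s]) for s in sel)
        assert hits / planted >= 0.8
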