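import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy.stats import spearmanr

import neurosig as ns
from neurosig.core import FormatError
from neurosig.signatures import DeltaTable, SignatureMatrix, delta_profile


def matrix_from(values, genes=None, cells=None, unit="counts"):
    values = np.asarray(values, dtype=float)
    genes = genes or [f"g{i}" for i in range(values.shape[0])]
    cells = cells or [f"c{j}" for j in range(values.shape[1])]
    return ns.ExpressionMatrix(values, genes, cells, unit=unit)


class TestToCpm:
    @pytest.mark.parametrize(
        "counts,expected",
        [
            ([90, 10], [900_000, 100_000]),
            ([1, 1, 2], [250_000, 250_000, 500_000]),
        ],
    )
    def test_proportional_scaling(self, counts, expected):
        matrix = matrix_from(np.array(counts)[:, None])
        cpm = ns.to_cpm(matrix)
        np.testing.assert_allclose(cpm.values[:, 0], expected)
        assert cpm.unit == "CPM"

    def test_columns_sum_to_one_million(self, small_dataset):
        _, matrix, _, _ = small_dataset
        cpm = ns.to_cpm(matrix)
        np.testing.assert_allclose(cpm.values.sum(axis=0), 1e6, rtol=1e-12)

    def test_idempotent_on_cpm(self, small_dataset):
        _, matrix, _, _ = small_dataset
        cpm = ns.to_cpm(matrix)
        again = ns.to_cpm(cpm)
        np.testing.assert_allclose(again.values, cpm.values)

    def test_zero_total_cell_reported_by_id(self):
        matrix = matrix_from([[1, 0], [2, 0]], cells=["ok", "empty"])
        with pytest.raises(FormatError, match="empty"):
            ns.to_cpm(matrix)


def _three_type_dataset(counts_per_type):
    """One gene, one region; counts_per_type like {'tA': 20, ...}."""
    cells, types = [], []
    for t, n in counts_per_type.items():
        for i in range(n):
            cells.append(f"{t}_{i}")
            types.append(t)
    values = np.ones((1, len(cells)))
    matrix = matrix_from(values, genes=["g"], cells=cells)
    leaves = pd.DataFrame(
        {
            "supertype_id": "st",
            "subclass_id": "sc",
            "class_id": "cl",
            "neurotransmitter": "GABAergic",
        },
        index=pd.Index(sorted(counts_per_type), name="type_id"),
    )
    taxonomy = ns.Taxonomy(leaves)
    annot = pd.DataFrame(
        {
            "region": "CA1",
            "type_id": types,
            "supertype_id": "st",
            "subclass_id": "sc",
            "class_id": "cl",
        },
        index=pd.Index(cells, name="cell_id"),
    )
    return matrix, ns.CellAnnotation(annot), taxonomy


class TestSelectCells:
    def test_sixteen_cell_boundary_is_inclusive(self):
        matrix, annotation, taxonomy = _three_type_dataset(
            {"tA": 20, "tB": 16, "tC": 15}
        )
        _, _, retained = ns.select_cells(
            matrix, annotation, taxonomy, ns.FilterSpec(min_cells_per_type=16)
        )
        assert retained == ["tA", "tB"]

    def test_min_one_keeps_all_nonempty(self):
        matrix, annotation, taxonomy = _three_type_dataset({"tA": 3, "tB": 1})
        _, _, retained = ns.select_cells(
            matrix, annotation, taxonomy, ns.FilterSpec(min_cells_per_type=1)
        )
        assert retained == ["tA", "tB"]

    def test_simulated_dataset_keeps_all_types(self, recovery_dataset):
        taxonomy, matrix, annotation, _ = recovery_dataset
        _, _, retained = ns.select_cells(
            matrix, annotation, taxonomy, ns.FilterSpec()
        )
        assert retained == taxonomy.type_ids

    def test_region_filter_and_no_survivor_error(self):
        matrix, annotation, taxonomy = _three_type_dataset({"tA": 10})
        with pytest.raises(FormatError, match="no type"):
            ns.select_cells(
                matrix, annotation, taxonomy,
                ns.FilterSpec(region="DG", min_cells_per_type=1),
            )


class TestTypeMeans:
    def test_hand_example(self):
        matrix = matrix_from(
            [[10, 20, 0]], genes=["g"], cells=["a1", "a2", "b1"], unit="CPM"
        )
        annot = pd.DataFrame(
            {
                "region": "CA1",
                "type_id": ["A", "A", "B"],
                "supertype_id": "st",
                "subclass_id": "sc",
                "class_id": "cl",
            },
            index=pd.Index(["a1", "a2", "b1"], name="cell_id"),
        )
        sig = ns.type_means(matrix, ns.CellAnnotation(annot), ["A", "B"])
        assert sig.means.loc["g", "A"] == 15.0
        assert sig.means.loc["g", "B"] == 0.0
        assert sig.cells_per_type.tolist() == [2, 1]

    def test_single_cell_types_return_cell_rows(self):
        rng = np.random.default_rng(0)
        values = rng.poisson(20, size=(5, 3)).astype(float)
        matrix = matrix_from(values, unit="CPM")
        annot = pd.DataFrame(
            {
                "region": "CA1",
                "type_id": ["t0", "t1", "t2"],
                "supertype_id": "st",
                "subclass_id": "sc",
                "class_id": "cl",
            },
            index=pd.Index(matrix.cell_ids, name="cell_id"),
        )
        sig = ns.type_means(matrix, ns.CellAnnotation(annot), ["t0", "t1", "t2"])
        np.testing.assert_allclose(sig.means.to_numpy(), values)

    def test_matches_brute_force_group_by_oracle(self):
        rng = np.random.default_rng(42)
        n_genes, n_cells = 50, 200
        values = rng.gamma(2.0, 30.0, size=(n_genes, n_cells))
        types = rng.choice([f"t{k}" for k in range(6)], size=n_cells)
        matrix = matrix_from(values, unit="CPM")
        annot = pd.DataFrame(
            {
                "region": "CA1",
                "type_id": types,
                "supertype_id": "st",
                "subclass_id": "sc",
                "class_id": "cl",
            },
            index=pd.Index(matrix.cell_ids, name="cell_id"),
        )
        retained = sorted(set(types))
        sig = ns.type_means(matrix, ns.CellAnnotation(annot), retained)
        # naive double loop
        for gi, gene in enumerate(matrix.gene_symbols):
            for t in retained:
                acc, n = 0.0, 0
                for ci in range(n_cells):
                    if types[ci] == t:
                        acc += values[gi, ci]
                        n += 1
                assert sig.means.loc[gene, t] == pytest.approx(acc / n, rel=0, abs=0)

    def test_requires_cpm_unit(self, small_dataset):
        _, matrix, annotation, _ = small_dataset
        with pytest.raises(FormatError, match="CPM"):
            ns.type_means(matrix, annotation, ["type00"])


class TestDelta:
    @pytest.mark.parametrize(
        "mu,expected",
        [
            ([5, 5, 5, 5, 5], 0.0),
            ([0, 0, 7, 0], 1.0),
            ([10, 5, 0, 0], 2.5 / 3),
            ([25.0] * 42, 0.0),
            ([100.0] + [0.0] * 41, 1.0),
        ],
    )
    def test_closed_form_examples(self, mu, expected):
        assert ns.delta(mu) == pytest.approx(expected, abs=1e-12)

    def test_all_zero_row_is_undefined_not_zero(self):
        assert math.isnan(ns.delta([0, 0, 0]))

    @pytest.mark.parametrize("bad", [[5.0], [], [1, -2, 3]])
    def test_invalid_inputs_rejected(self, bad):
        with pytest.raises(FormatError):
            ns.delta(bad)

    @given(
        mu=st.lists(st.floats(0, 1e6), min_size=2, max_size=50).filter(
            lambda v: max(v) > 0
        ),
        scale=st.floats(1e-3, 1e3),
        seed=st.integers(0, 2**16),
    )
    @settings(max_examples=300, derandomize=True, deadline=None)
    def test_bounded_scale_and_permutation_invariant(self, mu, scale, seed):
        d = ns.delta(mu)
        assert 0.0 <= d <= 1.0 + 1e-12
        assert ns.delta([scale * m for m in mu]) == pytest.approx(d, abs=1e-9)
        perm = np.random.default_rng(seed).permutation(len(mu))
        assert ns.delta(np.asarray(mu)[perm]) == pytest.approx(d, abs=1e-12)

    @given(
        mu=st.lists(st.floats(0, 1e4), min_size=2, max_size=30).filter(
            lambda v: max(v) > 0 and min(v) / max(v) < 1 - 1e-9
        )
    )
    @settings(max_examples=200, derandomize=True, deadline=None)
    def test_duplicating_max_type_dilutes_specificity(self, mu):
        """Appending a second copy of the maximal mean strictly lowers delta
        for any non-uniform profile."""
        diluted = list(mu) + [max(mu)]
        assert ns.delta(diluted) < ns.delta(mu)

    def test_vectorized_profile_matches_scalar(self):
        rng = np.random.default_rng(1)
        means = pd.DataFrame(rng.gamma(1.0, 50.0, size=(30, 10)))
        table = delta_profile(means)
        for i in range(30):
            assert table["delta"].iloc[i] == pytest.approx(
                ns.delta(means.iloc[i]), abs=1e-12
            )
            assert table["mu_max"].iloc[i] == means.iloc[i].max()


class TestFilterGenes:
    def _signature(self, rows: dict):
        means = pd.DataFrame(rows).T
        means.columns = [f"t{j}" for j in range(means.shape[1])]
        return SignatureMatrix(means, pd.Series(20, index=means.columns))

    def test_strictly_greater_than_boundary(self):
        sig = self._signature(
            {"a": [10.5, 1, 1], "b": [10.0, 1, 1], "c": [3.0, 1, 1]}
        )
        kept, table = ns.filter_genes(sig, spec=ns.FilterSpec(expression_threshold=10))
        assert kept.gene_symbols == ["a"]
        assert table.cascade == {
            "candidates": 3, "detected": 3, "retained": 1, "missing_symbols": 0
        }

    def test_threshold_zero_keeps_any_expression(self):
        sig = self._signature({"a": [0.1, 0, 0], "b": [0, 0, 0]})
        kept, _ = ns.filter_genes(sig, spec=ns.FilterSpec(expression_threshold=0))
        assert kept.gene_symbols == ["a"]

    def test_missing_panel_symbols_reported_not_fatal(self, npp_panel):
        sig = self._signature({"Npp0": [50, 0, 0], "other": [50, 50, 50]})
        kept, table = ns.filter_genes(sig, panel=npp_panel)
        assert kept.gene_symbols == ["Npp0"]
        assert table.cascade["candidates"] == 36
        assert table.cascade["missing_symbols"] == 35
        assert table.table.loc["Npp0", "category"] == "NPP"


class TestOrderByDelta:
    def _table(self, rows):
        df = pd.DataFrame(rows).T
        df.columns = ["delta", "mu_max"]
        df["log10_rowmax"] = np.log10(df["mu_max"])
        df["defined"] = True
        return DeltaTable(df)

    def test_descending_delta(self):
        order = ns.order_by_delta(
            self._table({"a": [0.2, 1], "b": [0.9, 1], "c": [0.5, 1]})
        )
        assert order == ["b", "c", "a"]

    def test_tie_broken_by_mu_max_then_symbol(self):
        order = ns.order_by_delta(
            self._table({"b": [0.5, 10], "a": [0.5, 100], "c": [0.5, 10]})
        )
        assert order == ["a", "b", "c"]

    def test_sorted_input_is_identity(self):
        table = self._table({"a": [0.9, 5], "b": [0.5, 5], "c": [0.1, 5]})
        assert ns.order_by_delta(table) == ["a", "b", "c"]

    def test_undefined_rows_excluded(self):
        df = pd.DataFrame(
            {
                "delta": [0.5, np.nan],
                "mu_max": [10.0, 0.0],
                "log10_rowmax": [1.0, np.nan],
                "defined": [True, False],
            },
            index=["a", "z"],
        )
        assert ns.order_by_delta(DeltaTable(df)) == ["a"]


class TestParameterRecovery:
    def test_planted_specificity_is_recovered(self, recovery_dataset,
                                              recovery_signature):
        """delta estimated from noisy counts tracks the planted specificity
        classes: one-hot markers near 1, ubiquitous genes low, and the
        class ranking near-perfectly recovered."""
        _, _, _, truth = recovery_dataset
        _, _, _, _, delta_table = recovery_signature
        est = delta_table.table["delta"]
        markers = est.loc[truth.symbols_of("one_type_marker")]
        ubiquitous = est.loc[truth.symbols_of("ubiquitous")]
        assert (markers > 0.95).all()
        assert (ubiquitous < 0.3).all()
        rank = truth.specificity_rank().loc[est.index]
        rho = spearmanr(rank, est).statistic
        assert rho > 0.9
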