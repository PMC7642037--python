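"""Correlation, scale-free fit, cutoff scanning and network construction."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import linregress

from gelnet.coexpression import (
    CorrelationMatrix,
    ThresholdSelector,
    build_network,
    correlation_matrix,
    network_density,
    pearson,
    scale_free_fit,
    scan_thresholds,
    select_cutoff,
)
from gelnet.errors import UndefinedStatisticError, ValidationError
from gelnet.io import ExpressionMatrix
from gelnet.simulate import power_law_degrees, simulate_scale_free_correlation


class TestPearson:
    @pytest.mark.parametrize(
        "x, y, expected",
        [
            ((1, 2, 3), (2, 4, 6), 1.0),
            ((1, 2, 3), (3, 2, 1), -1.0),
            ((1, 2, 3, 4), (1, 3, 2, 4), 0.8),  # hand evaluation of the formula
        ],
    )
    def test_formula_values(self, x, y, expected):
        assert pearson(x, y) == pytest.approx(expected, abs=1e-12)

    def test_constant_vector_undefined(self):
        with pytest.raises(UndefinedStatisticError):
            pearson((1, 1, 1), (1, 2, 3))

    def test_too_few_samples(self):
        with pytest.raises(ValidationError):
            pearson((1, 2), (3, 4))


class TestCorrelationMatrix:
    def test_matches_pairwise_loop_oracle(self, rng):
        X = rng.gamma(2.0, 2.0, size=(50, 20))
        em = ExpressionMatrix(
            pd.DataFrame(X, index=[f"g{i}" for i in range(50)],
                         columns=[f"s{j}" for j in range(20)])
        )
        cm = correlation_matrix(em, min_expressed_samples=0, min_fpkm=0.0)
        for i in range(cm.n_genes):
            for j in range(i + 1, cm.n_genes):
                expect = pearson(X[i], X[j])
                assert cm.matrix[i, j] == pytest.approx(expect, abs=1e-10)

    def test_constant_gene_excluded_and_reported(self):
        df = pd.DataFrame(
            [[5.0, 5.0, 5.0, 5.0], [1.0, 2.0, 3.0, 4.0], [4.0, 3.0, 2.0, 1.0]],
            index=["flat", "up", "down"], columns=list("abcd")
        )
        cm = correlation_matrix(ExpressionMatrix(df), min_expressed_samples=2, min_fpkm=1.0)
        assert cm.gene_ids == ("up", "down")
        assert cm.excluded == {"flat": "zero_variance"}

    def test_duplicated_profile_gives_unit_offdiagonal(self):
        df = pd.DataFrame(
            [[1.0, 2.0, 3.0], [1.0, 2.0, 3.0]], index=["a", "b"], columns=list("xyz")
        )
        cm = correlation_matrix(ExpressionMatrix(df), 0, 0.0)
        assert cm.matrix[0, 1] == pytest.approx(1.0)

    def test_too_few_survivors_is_error(self):
        df = pd.DataFrame([[1.0, 2.0], [0.0, 0.0], [0.0, 0.0]],
                          index=list("abc"), columns=["s1", "s2"])
        with pytest.raises(ValidationError):
            correlation_matrix(ExpressionMatrix(df), min_expressed_samples=1, min_fpkm=1.0)


class TestDensity:
    @pytest.mark.parametrize("n, e, expected", [(4, 3, 0.5), (7, 0, 0.0), (5, 10, 1.0)])
    def test_values(self, n, e, expected):
        assert network_density(n, e) == pytest.approx(expected)

    def test_impossible_edge_count(self):
        with pytest.raises(ValidationError):
            network_density(4, 7)


class TestScaleFreeFit:
    def test_exact_power_law_scores_high(self):
        assert scale_free_fit(power_law_degrees(exponent=2.0)) >= 0.95

    def test_constant_degrees_undefined(self):
        assert scale_free_fit([4, 4, 4, 4]) is None

    def test_matches_independent_regression_oracle(self):
        degrees = [1, 1, 1, 1, 2, 2, 3]
        got = scale_free_fit(degrees, n_bins=3)
        # independent oracle: bin by hand, least-squares on log-log points
        k = np.array(degrees, dtype=float)
        edges = np.linspace(1, 3, 4)
        pts = []
        for b in range(3):
            lo, hi = edges[b], edges[b + 1]
            mask = (k >= lo) & (k < hi) if b < 2 else (k >= lo) & (k <= hi)
            if mask.any():
                pts.append((np.log10(k[mask].mean()), np.log10(mask.sum() / k.size)))
        x, y = zip(*pts)
        expect = linregress(x, y).rvalue ** 2
        assert got == pytest.approx(expect, abs=1e-12)

    def test_power_law_beats_constant_p_graph(self, rng):
        er_degrees = rng.binomial(1999, 6 / 1999, size=2000)
        pl = scale_free_fit(power_law_degrees(exponent=2.0))
        er = scale_free_fit(er_degrees)
        assert pl > er


class TestScan:
    def _two_block(self):
        m = np.full((20, 20), 0.05)
        m[:10, :10] = 0.92
        m[10:, 10:] = 0.92
        np.fill_diagonal(m, 1.0)
        return CorrelationMatrix(tuple(f"g{i}" for i in range(20)), m)

    def test_edge_count_monotone(self):
        scan = scan_thresholds(self._two_block(), (0.5, 0.9))
        e = scan.table["n_edges"].to_numpy()
        assert e[1] <= e[0]

    def test_zero_offdiagonal_gives_empty_rows(self):
        m = np.eye(8)
        cm = CorrelationMatrix(tuple(f"g{i}" for i in range(8)), m)
        scan = scan_thresholds(cm, (0.5,))
        row = scan.table.iloc[0]
        assert row["n_edges"] == 0 and np.isnan(row["r_squared"])

    def test_rows_match_per_cutoff_recomputation(self):
        cm = simulate_scale_free_correlation(n_nodes=300, seed=5)
        grid = (0.6, 0.7, 0.8, 0.9)
        scan = scan_thresholds(cm, grid)
        for cutoff, row in zip(grid, scan.table.itertuples()):
            single = scan_thresholds(cm, (cutoff,)).table.iloc[0]
            assert row.n_edges == single["n_edges"]
            assert row.density == pytest.approx(single["density"])
            if np.isnan(single["r_squared"]):
                assert np.isnan(row.r_squared)
            else:
                assert row.r_squared == pytest.approx(single["r_squared"], abs=1e-12)

    def test_negative_sign_uses_lower_tail(self):
        m = np.array([[1.0, -0.9], [-0.9, 1.0]])
        cm = CorrelationMatrix(("a", "b"), m)
        scan = scan_thresholds(cm, (0.8,), sign="negative")
        assert scan.table.iloc[0]["n_edges"] == 1


class TestSelectCutoff:
    @staticmethod
    def _scan(rows):
        from gelnet.coexpression import ThresholdScan

        df = pd.DataFrame(rows, columns=["cutoff", "n_nodes", "n_edges", "density", "r_squared"])
        return ThresholdScan("positive", df)

    def test_argmax_under_density_bound(self):
        scan = self._scan([
            (0.6, 100, 500, 0.10, 0.50),
            (0.8, 90, 40, 0.01, 0.90),
            (0.9, 50, 6, 0.005, 0.85),
        ])
        assert select_cutoff(scan, max_density=0.05) == 0.8

    def test_grid_with_maximum_at_eight_tenths(self):
        # shape mirrors the published scan over {0.6 .. 0.95}: R^2 peaks at 0.8
        rows = [
            (0.60, 900, 9000, 0.022, 0.71),
            (0.65, 850, 7000, 0.019, 0.74),
            (0.70, 800, 5200, 0.016, 0.78),
            (0.75, 720, 3600, 0.014, 0.83),
            (0.80, 640, 2400, 0.012, 0.91),
            (0.85, 520, 1400, 0.010, 0.88),
            (0.90, 380, 700, 0.010, 0.84),
            (0.95, 200, 180, 0.009, 0.77),
        ]
        assert select_cutoff(self._scan(rows), max_density=0.05) == 0.8

    def test_tie_breaks_toward_smaller_cutoff(self):
        scan = self._scan([
            (0.6, 100, 50, 0.01, 0.9),
            (0.8, 80, 20, 0.006, 0.9),
        ])
        assert select_cutoff(scan, max_density=0.05) == 0.6

    def test_no_row_under_bound_is_error(self):
        scan = self._scan([(0.6, 100, 900, 0.18, 0.9)])
        with pytest.raises(ValidationError, match="larger bound"):
            select_cutoff(scan, max_density=0.05)

    def test_selection_returns_grid_member(self):
        cm = simulate_scale_free_correlation(n_nodes=400, seed=2)
        grid = (0.6, 0.65, 0.7, 0.75, 0.8, 0.85, 0.9, 0.95)
        scan = scan_thresholds(cm, grid)
        chosen = select_cutoff(scan, max_density=0.05)
        assert chosen in grid
        row = scan.table[scan.table["cutoff"] == chosen].iloc[0]
        assert row["density"] <= 0.05


class TestBuildNetwork:
    def test_boundary_pair_excluded_by_strict_inequality(self):
        m = np.array([[1.0, 0.8], [0.8, 1.0]])
        cm = CorrelationMatrix(("a", "b"), m)
        pos, _ = build_network(cm, pos_cutoff=0.8)
        assert pos.n_edges == 0

    def test_negative_pair_included(self):
        m = np.array([[1.0, -0.8], [-0.8, 1.0]])
        cm = CorrelationMatrix(("a", "b"), m)
        _, neg = build_network(cm, neg_cutoff=-0.75)
        assert neg.n_edges == 1
        assert neg.edges.loc[0, "pcc"] == pytest.approx(-0.8)

    def test_planted_blocks_yield_within_block_edges_only(self):
        m = np.full((20, 20), 0.0)
        m[:10, :10] = 0.9
        m[10:, 10:] = 0.9
        np.fill_diagonal(m, 1.0)
        cm = CorrelationMatrix(tuple(f"g{i:02d}" for i in range(20)), m)
        pos, _ = build_network(cm, pos_cutoff=0.8)
        block = lambda g: int(g[1:]) // 10
        assert all(block(a) == block(b) for a, b in zip(pos.edges["gene_a"], pos.edges["gene_b"]))
        assert pos.n_edges == 2 * (10 * 9 // 2)


class TestThresholdSelectorEstimator:
    def test_fit_sets_attributes_and_is_cloneable(self, block_sim):
        from sklearn.base import clone

        sel = ThresholdSelector(max_density=1.0)
        clone(sel)  # sklearn param contract
        sel.fit(block_sim.expression)
        assert hasattr(sel, "scan_") and hasattr(sel, "cutoff_")
        assert sel.cutoff_ in sel.get_params()["cutoffs"]

    def test_get_set_params_round_trip(self):
        sel = ThresholdSelector()
        sel.set_params(max_density=0.2, sign="negative")
        assert sel.get_params()["max_density"] == 0.2
        assert sel.get_params()["sign"] == "negative"
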