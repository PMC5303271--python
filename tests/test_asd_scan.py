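import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm

from sdscan.asd_scan import (PolyFitResult, ScanCell, ScanLandscape,
                             adjusted_r2, enumerate_asd_candidates,
                             fit_polynomial, quintile_analysis, scan_landscape,
                             select_best, stratify_by_operon,
                             utr_composition_profile)


class TestAdjustedR2:
    @pytest.mark.parametrize("r2, n, p, expected", [
        (1.0, 100, 3, 1.0),
        (0.5, 102, 1, 0.495),
        (0.0, 100, 3, -3.0 / 96.0),
    ])
    def test_closed_form(self, r2, n, p, expected):
        assert adjusted_r2(r2, n, p) == pytest.approx(expected, abs=1e-15)

    def test_too_few_points(self):
        with pytest.raises(ValueError):
            adjusted_r2(0.5, 4, 3)


class TestFitPolynomial:
    def test_exact_line(self):
        x = np.linspace(-10, 0, 50)
        fit = fit_polynomial(x, 2 + 3 * x, 1)
        np.testing.assert_allclose(fit.coefficients, [2.0, 3.0], atol=1e-10)
        assert fit.r2 == pytest.approx(1.0)

    def test_agrees_with_statsmodels(self):
        rng = np.random.default_rng(10)
        x = rng.uniform(-14, 0, 400)
        y = 0.1 * x + 0.01 * x ** 3 + rng.normal(0, 0.3, 400)
        for order in (1, 3):
            fit = fit_polynomial(x, y, order)
            ref = sm.OLS(y, np.vander(x, order + 1, increasing=True)).fit()
            assert fit.r2 == pytest.approx(ref.rsquared)
            assert fit.r2_adj == pytest.approx(ref.rsquared_adj)
            assert fit.f_pvalue == pytest.approx(ref.f_pvalue)
            # same likelihood; the parameter count differs by the fixed
            # variance term, which cancels from order comparisons
            assert fit.aic == pytest.approx(ref.aic + 2.0)

    def test_peaked_truth_prefers_cubic(self):
        rng = np.random.default_rng(17)
        x = rng.uniform(-12, 0, 1000)
        y = -((x + 5) ** 2) + rng.normal(0, 0.1, 1000)
        assert fit_polynomial(x, y, 3).aic < fit_polynomial(x, y, 1).aic

    def test_f_test_type_i_error_rate(self):
        """Independent response: F-test p > 0.01 in >= 95 of 100 replicates."""
        hits = 0
        for seed in range(100):
            rng = np.random.default_rng(seed)
            x = rng.uniform(-12, 0, 1000)
            y = rng.normal(0, 0.3, 1000)
            hits += fit_polynomial(x, y, 1).f_pvalue > 0.01
        assert hits >= 95

    def test_degenerate_predictor(self):
        with pytest.raises(ValueError, match="degenerate"):
            fit_polynomial(np.full(100, -3.0), np.random.default_rng(0)
                           .normal(size=100), 1)

    def test_r2_adj_never_exceeds_r2(self):
        rng = np.random.default_rng(3)
        x = rng.uniform(-10, 0, 60)
        y = rng.normal(size=60)
        for order in (1, 3):
            fit = fit_polynomial(x, y, order)
            assert fit.r2_adj <= fit.r2


class TestEnumerateCandidates:
    def test_enumeration(self):
        cands = enumerate_asd_candidates("UCACCUCCUUUCU", "CCUCC", 2, 2)
        assert len(cands) == 9
        assert "ACCUCCU" in cands
        assert all("CCUCC" in c for c in cands)

    def test_no_extension(self):
        assert enumerate_asd_candidates("UCACCUCCUUUCU", "CCUCC", 0, 0) == ["CCUCC"]

    def test_core_absent(self):
        with pytest.raises(ValueError):
            enumerate_asd_candidates("AAAA", "CCUCC", 1, 1)

    def test_core_repeated(self):
        with pytest.raises(ValueError):
            enumerate_asd_candidates("CCUCCACCUCC", "CCUCC", 0, 0)

    def test_extension_beyond_tail(self):
        with pytest.raises(ValueError):
            enumerate_asd_candidates("ACCUCCU", "CCUCC", 3, 0)


class TestScanLandscape:
    def test_single_cell_matches_fit_polynomial(self):
        rng = np.random.default_rng(21)
        utrs = []
        for _ in range(120):
            utr = list("".join(rng.choice(list("ACGU"), size=30)))
            utrs.append("".join(utr))
        y = rng.normal(0, 0.3, 120)
        landscape = scan_landscape(utrs, y, ["CCUCC"], [-7], min_n=50)
        cell = landscape.cells[("CCUCC", -7)]
        from sdscan.asd_scan import encode_utrs
        from sdscan.hybridization import binding_energy_matrix
        dg = binding_energy_matrix(encode_utrs(utrs), "CCUCC", [-7])[:, 0]
        direct = fit_polynomial(dg, y, 3)
        assert cell.fit3.r2_adj == pytest.approx(direct.r2_adj)
        assert cell.fit1.order == 1 and cell.fit3.order == 3

    def test_small_cells_marked_invalid_not_dropped(self):
        rng = np.random.default_rng(4)
        utrs = ["".join(rng.choice(list("ACGU"), size=30)) for _ in range(20)]
        landscape = scan_landscape(utrs, rng.normal(size=20), ["CCUCC"], [-7],
                                   min_n=50)
        cell = landscape.cells[("CCUCC", -7)]
        assert not cell.valid and cell.n == 20


def _fake_cell(asd, d, r2_adj):
    fit = PolyFitResult(3, np.zeros(4), 1000, r2_adj, r2_adj, 0.0, 0.5)
    return ScanCell(asd, d, 1000, fit, fit, True)


class TestSelectBest:
    def test_single_cell(self):
        ls = ScanLandscape({("CCUCC", -7): _fake_cell("CCUCC", -7, 0.02)})
        assert select_best(ls)[:2] == ("CCUCC", -7)

    def test_shortest_within_tolerance(self):
        ls = ScanLandscape({
            ("ACCUCCUUA", -5): _fake_cell("ACCUCCUUA", -5, 0.0410),
            ("CACCUCCUUA", -4): _fake_cell("CACCUCCUUA", -4, 0.0412),
        })
        assert select_best(ls, tolerance=0.005)[0] == "ACCUCCUUA"

    def test_zero_tolerance_returns_argmax(self):
        ls = ScanLandscape({
            ("ACCUCCUUA", -5): _fake_cell("ACCUCCUUA", -5, 0.0410),
            ("CACCUCCUUA", -4): _fake_cell("CACCUCCUUA", -4, 0.0412),
        })
        assert select_best(ls, tolerance=0.0)[0] == "CACCUCCUUA"

    def test_no_valid_cells(self):
        ls = ScanLandscape({("CCUCC", -7): ScanCell("CCUCC", -7, 0, None, None,
                                                    False)})
        with pytest.raises(ValueError):
            select_best(ls)


class TestQuintiles:
    def test_flat_residuals_zero_effect(self):
        q = quintile_analysis(np.linspace(-10, 0, 50), np.zeros(50))
        assert q.effect_pct == 0.0

    def test_closed_form_fifty_percent(self):
        # weakest bin mean 0, best bin mean log10(1.5) -> 50% increase
        dg = np.repeat([0.0, -2.0, -4.0, -6.0, -8.0], 10)
        resid = np.repeat([0.0, 0.0, 0.0, np.log10(1.5), 0.0], 10)
        q = quintile_analysis(dg, resid)
        assert q.effect_pct == pytest.approx(50.0)
        assert q.best_bin == 3

    def test_bin_sizes_for_n12(self):
        q = quintile_analysis(np.linspace(-11, 0, 12), np.zeros(12))
        assert list(q.counts) == [3, 3, 2, 2, 2]

    def test_weakest_bin_first(self):
        dg = np.array([-10.0, -1.0, -5.0, -8.0, -3.0])
        resid = np.arange(5.0)
        q = quintile_analysis(dg, resid)
        # weakest = least negative dg (-1.0), i.e. residual 1.0 in bin 0
        assert q.means[0] == 1.0 and q.means[-1] == 0.0


class TestStratifyByOperon:
    @staticmethod
    def _table(rows):
        return pd.DataFrame(rows, columns=["gene_id", "operon_id", "position"])

    def test_partition(self):
        # 3 TUs of sizes 1, 2, 3 -> strata (3 first, 3 internal)
        table = self._table([
            ("a", "TU1", 1),
            ("b", "TU2", 1), ("c", "TU2", 2),
            ("d", "TU3", 1), ("e", "TU3", 2), ("f", "TU3", 3),
        ])
        strata = stratify_by_operon(list("abcdef"), table)
        assert sorted(strata["first_in_TU"]) == ["a", "b", "d"]
        assert sorted(strata["internal"]) == ["c", "e", "f"]

    def test_absent_genes_unclassified(self):
        table = self._table([("a", "TU1", 1)])
        strata = stratify_by_operon(["a", "zz"], table)
        assert strata["unclassified"] == ["zz"]

    def test_duplicate_gene_rejected(self):
        table = self._table([("a", "TU1", 1), ("a", "TU2", 2)])
        with pytest.raises(ValueError, match="duplicate"):
            stratify_by_operon(["a"], table)


class TestUtrComposition:
    def test_information_content_extremes(self):
        utrs = ["G" * 20, "G" * 20, "G" * 20, "G" * 20]
        freqs, info = utr_composition_profile(utrs, 20)
        assert np.allclose(info, 2.0)
        utrs = ["A" * 20, "C" * 20, "G" * 20, "U" * 20]
        _, info = utr_composition_profile(utrs, 20)
        assert np.allclose(info, 0.0)

    def test_two_base_mixture_one_bit(self):
        _, info = utr_composition_profile(["A" * 20, "G" * 20], 20)
        assert np.allclose(info, 1.0)

    def test_columns_sum_to_one(self):
        rng = np.random.default_rng(6)
        utrs = ["".join(rng.choice(list("ACGU"), size=25)) for _ in range(30)]
        freqs, _ = utr_composition_profile(utrs, 20)
        assert np.allclose(freqs.sum(axis=0), 1.0)
        assert list(freqs.columns) == list(range(-20, 0))

    def test_empty_input(self):
        with pytest.raises(ValueError):
            utr_composition_profile([], 20)
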