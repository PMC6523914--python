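import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy.stats import chi2_contingency

from dmrscan import (
    BinomialScanTest,
    WindowSpec,
    apply_pseudocounts,
    call_dmrs,
    fit_covariate_model,
    multinomial_scan,
    scan,
    window_lr,
)
from dmrscan.adjust import design_effect_adjust
from dmrscan.ssm import ScanResult, multinomial_window_lr, window_scan

from conftest import make_dataset


def printed_delta(rA, CA, rU, CU):
    """Scan statistic written with the share parameters.

    Independent implementation in terms of the coverage share
    b_A = C_A/(C_A+C_U), methylated share r_A/(r_A+r_U), overall rate
    T and Φ = 1/(C_A+C_U); algebraically equal to the binomial
    log-likelihood ratio.
    """
    b = CA / (CA + CU)
    r = rA / (rA + rU)
    T = (rA + rU) / (CA + CU)
    phi = 1.0 / (CA + CU)
    bracket = (
        r * np.log(r / b)
        + (b / T - r) * np.log(1.0 - T * r / b)
        + (1.0 - r) * np.log((1.0 - r) / (1.0 - b))
        + ((1.0 - b) / T - 1.0 + r) * np.log(1.0 - T * (1.0 - r) / (1.0 - b))
    )
    return (T / phi) * bracket - ((1.0 - T) / phi) * np.log(1.0 - T)


class TestWindowLr:
    def test_equal_proportions_give_zero(self):
        assert window_lr(5, 10, 50, 100) == pytest.approx(0.0, abs=1e-12)

    def test_hand_computed_value(self):
        # 16 ln 0.8 + 4 ln 0.2 - 20 ln 0.5
        assert window_lr(8, 10, 2, 10) == pytest.approx(3.8548951, abs=1e-6)

    def test_symmetric_in_groups(self):
        assert window_lr(8, 10, 2, 10) == pytest.approx(
            window_lr(2, 10, 8, 10), rel=1e-12)

    def test_degenerate_proportions_rejected(self):
        with pytest.raises(ValueError):
            window_lr(0, 10, 5, 10)
        with pytest.raises(ValueError):
            window_lr(10, 10, 5, 10)

    def test_linear_in_total_coverage(self):
        base = window_lr(8, 10, 2, 10)
        assert window_lr(24, 30, 6, 30) == pytest.approx(3 * base, rel=1e-10)

    @settings(max_examples=100, deadline=None)
    @given(st.integers(1, 50), st.integers(1, 50),
           st.integers(1, 50), st.integers(1, 50))
    def test_half_g_squared_oracle(self, a, b, c, d):
        """2·LR equals the G² (log-likelihood-ratio) statistic of the
        2×2 methylated/unmethylated table."""
        table = np.array([[a, b], [c, d]])
        g2 = chi2_contingency(table, correction=False,
                              lambda_="log-likelihood")[0]
        lr = window_lr(a, a + b, c, c + d)
        assert 2 * lr == pytest.approx(g2, rel=1e-10, abs=1e-10)
        assert lr >= -1e-12

    @settings(max_examples=100, deadline=None)
    @given(st.floats(0.5, 400), st.floats(0.5, 400),
           st.floats(1.0, 500), st.floats(1.0, 500))
    def test_printed_share_form_equivalence(self, rA, rU, eA, eU):
        """The share-parameter form of the statistic matches the nested
        log-likelihood form to 1e-10 relative on real-valued counts."""
        CA, CU = rA + eA, rU + eU
        lr = window_lr(rA, CA, rU, CU)
        assert printed_delta(rA, CA, rU, CU) == pytest.approx(
            lr, rel=1e-10, abs=1e-10)


class TestMultinomialLr:
    def test_two_group_reduction(self):
        assert multinomial_window_lr([8, 2], [10, 10]) == pytest.approx(
            window_lr(8, 10, 2, 10), rel=1e-12)

    def test_equal_rates_give_zero(self):
        assert multinomial_window_lr([3, 6, 9], [10, 20, 30]) == \
            pytest.approx(0.0, abs=1e-12)

    def test_three_group_half_g_squared(self):
        r = np.array([8.0, 5.0, 2.0])
        C = np.array([10.0, 10.0, 10.0])
        table = np.vstack([r, C - r])
        g2 = chi2_contingency(table, lambda_="log-likelihood")[0]
        assert multinomial_window_lr(r, C) == pytest.approx(g2 / 2, rel=1e-10)


class TestPseudocounts:
    def test_shift(self, four_sample_dataset):
        adj = fit_covariate_model(four_sample_dataset)
        dec = design_effect_adjust(adj, four_sample_dataset)
        pc = apply_pseudocounts(dec)
        np.testing.assert_allclose(pc.r_tilde, dec.r_tilde + 1)
        np.testing.assert_allclose(pc.C_tilde, dec.C_tilde + 2)

    @pytest.mark.parametrize("fill", ["zeros", "full"])
    def test_degenerate_datasets_scan_cleanly(self, fill):
        """All-unmethylated and fully methylated regions produce finite
        statistics thanks to the per-site pseudo-counts."""
        cov = np.full((6, 10), 20)
        meth = np.zeros_like(cov) if fill == "zeros" else cov.copy()
        ds = make_dataset(meth=meth, coverage=cov,
                          groups=["A", "U"] * 3)
        res = scan(ds, WindowSpec(sizes=(4,)), permutations=30, seed=0)
        assert np.isfinite(res.global_LR)
        assert res.global_LR == pytest.approx(0.0, abs=1e-9)
        assert np.isfinite(res.per_window["LR"]).all()


class TestScan:
    def _signal_dataset(self, seed=0, n=30, m=24, lo=10, hi=16):
        rng = np.random.default_rng(seed)
        cov = np.full((n, m), 200)
        p = np.full((n, m), 0.1)
        p[: n // 2, lo:hi] = 0.4
        meth = rng.binomial(cov, p)
        return make_dataset(meth=meth, coverage=cov,
                            groups=["A"] * (n // 2) + ["U"] * (n // 2))

    def test_planted_window_is_argmax(self):
        ds = self._signal_dataset()
        res = scan(ds, WindowSpec(sizes=(6,)), permutations=99, seed=1)
        best = res.best_window
        # exhaustive enumeration agrees on the argmax
        assert best["LR"] == res.per_window["LR"].max()
        end = int(best["start"]) + int(best["size"]) - 1
        assert not (end < 10 or int(best["start"]) > 15)
        assert res.global_p <= 0.05
        assert len(res.calls) >= 1 and res.calls[0].method == "SSM"
        # the call spans exactly one window of the scanned size
        assert res.calls[0].n_sites == 6

    def test_single_window_equals_direct_lr(self, four_sample_dataset):
        ds = four_sample_dataset
        res = scan(ds, WindowSpec(sizes=(1,)), permutations=30, seed=0,
                   design_effect=False)
        # one site: group sums 14/20 vs 2/20, pseudo-counted to 15/22, 3/22
        assert res.global_LR == pytest.approx(
            window_lr(15, 22, 3, 22), rel=1e-12)

    def test_oversized_window_skipped(self, two_site_dataset):
        res = scan(two_site_dataset, WindowSpec(sizes=(2, 30)),
                   permutations=20, seed=0)
        assert set(res.per_window["size"]) == {2}

    def test_no_fitting_window_raises(self, two_site_dataset):
        with pytest.raises(ValueError):
            scan(two_site_dataset, WindowSpec(sizes=(30,)),
                 permutations=20, seed=0)

    def test_relabel_symmetry(self):
        ds = self._signal_dataset(seed=5, n=12)
        flipped = make_dataset(
            meth=ds.meth, coverage=ds.coverage,
            groups=["U"] * 6 + ["A"] * 6)
        spec = WindowSpec(sizes=(6,))
        a = scan(ds, spec, permutations=20, seed=2)
        b = scan(flipped, spec, permutations=20, seed=2)
        assert a.global_LR == pytest.approx(b.global_LR, rel=1e-10)

    def test_window_scan_matches_engine_without_design_effect(
            self, four_sample_dataset):
        ds = self._signal_dataset(seed=3, n=10, m=12, lo=4, hi=8)
        adj = fit_covariate_model(ds)
        dec = design_effect_adjust(adj, ds, floor=1.0)
        # neutralise the deflation so both paths see identical counts
        dec.r_tilde = dec.r_tilde * dec.deff
        dec.C_tilde = dec.C_tilde * dec.deff
        dec.deff = np.ones_like(dec.deff)
        table = window_scan(dec, WindowSpec(sizes=(4,)))
        res = scan(ds, WindowSpec(sizes=(4,)), permutations=10, seed=0,
                   adjusted=adj, design_effect=False)
        np.testing.assert_allclose(table["LR"].to_numpy(),
                                   res.per_window["LR"].to_numpy(),
                                   rtol=1e-10)

    def test_three_groups_multinomial(self):
        rng = np.random.default_rng(12)
        cov = np.full((12, 10), 50)
        meth = rng.binomial(cov, 0.2)
        ds = make_dataset(meth=meth, coverage=cov,
                          groups=["A", "B", "C"] * 4)
        res = multinomial_scan(ds, WindowSpec(sizes=(5,)),
                               permutations=50, seed=0)
        assert np.isfinite(res.global_LR)
        assert 0 < res.global_p <= 1

    def test_two_group_scan_requires_two_groups(self):
        ds = make_dataset(meth=[[1, 1]] * 3, coverage=[[5, 5]] * 3,
                          groups=["A", "U", "C"])
        with pytest.raises(ValueError):
            scan(ds, WindowSpec(sizes=(2,)), permutations=10)

    def test_ordered_groups_unsupported(self, four_sample_dataset):
        with pytest.raises(NotImplementedError):
            multinomial_scan(four_sample_dataset, WindowSpec(sizes=(1,)),
                             permutations=10, ordered=True)

    def test_model_interface(self):
        ds = self._signal_dataset(seed=7)
        model = BinomialScanTest(ds, window_sizes=(5, 10), step=1)
        res = model.fit(permutations=99, seed=4)
        assert "Binomial Scan Test" in res.summary()
        assert res.global_LR == res.per_window["LR"].max()


class TestCallDmrs:
    def _result(self, rows):
        pw = pd.DataFrame(rows)
        return ScanResult(per_window=pw, global_LR=pw["LR"].max(),
                          global_p=0.01, n_permutations=99, alpha=0.05,
                          calls=[], sites=pd.DataFrame(), group_labels=[])

    def test_none_significant(self):
        res = self._result([{"start": 0, "size": 5, "chromosome": "chr1",
                             "start_bp": 1, "end_bp": 5, "LR": 2.0,
                             "p_value": 0.2}])
        assert call_dmrs(res, alpha=0.05) == []

    def test_overlapping_keeps_larger_lr(self):
        res = self._result([
            {"start": 0, "size": 5, "chromosome": "chr1", "start_bp": 1,
             "end_bp": 5, "LR": 5.0, "p_value": 0.01},
            {"start": 3, "size": 5, "chromosome": "chr1", "start_bp": 4,
             "end_bp": 8, "LR": 4.0, "p_value": 0.02},
        ])
        calls = call_dmrs(res, alpha=0.05)
        assert len(calls) == 1 and calls[0].statistic == 5.0

    def test_disjoint_returned_in_genomic_order(self):
        res = self._result([
            {"start": 10, "size": 3, "chromosome": "chr1", "start_bp": 50,
             "end_bp": 60, "LR": 7.0, "p_value": 0.001},
            {"start": 0, "size": 3, "chromosome": "chr1", "start_bp": 1,
             "end_bp": 10, "LR": 3.0, "p_value": 0.03},
        ])
        calls = call_dmrs(res, alpha=0.05)
        assert [c.start_bp for c in calls] == [1, 50]
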