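import math
from itertools import combinations

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from immfocus import (compute_lod, gene_survival_scan, km_curve, logrank_test,
                      stratify_by_tertiles)


def _series(values, ids=None):
    ids = ids or [f"S{i:03d}" for i in range(len(values))]
    return pd.Series(np.asarray(values, dtype=float), index=ids)


class TestTertiles:
    def test_exact_thirds(self):
        low, high = stratify_by_tertiles(_series(range(1, 10)))
        assert low == ["S000", "S001", "S002"]
        assert high == ["S006", "S007", "S008"]

    def test_floor_rule_n10(self):
        low, high = stratify_by_tertiles(_series(range(10)))
        assert len(low) == len(high) == 3

    def test_tie_broken_by_sample_id(self):
        values = _series([1, 1, 1, 2, 3, 4], ids=list("fedcba"))
        low, _ = stratify_by_tertiles(values)
        assert low == ["d", "e"]       # tied values resolved by id order

    def test_too_few_samples(self):
        with pytest.raises(ValueError):
            stratify_by_tertiles(_series([1, 2, 3]))


class TestKaplanMeier:
    def test_hand_product_limit(self):
        km = km_curve([1, 2, 3, 4, 5], [1, 0, 1, 0, 1])
        assert km.survival_at(1) == pytest.approx(0.8)
        assert km.survival_at(3) == pytest.approx(0.8 * 2 / 3)
        assert km.survival_at(5) == pytest.approx(0.0)

    def test_all_censored_is_flat_one(self):
        km = km_curve([3, 5, 9], [0, 0, 0])
        assert km.event_times.size == 0
        assert km.survival_at(100) == 1.0

    def test_single_subject(self):
        km = km_curve([7], [1])
        assert km.survival_at(7) == 0.0

    def test_equals_one_minus_ecdf_without_censoring(self):
        rng = np.random.default_rng(0)
        t = rng.exponential(10, 40)
        km = km_curve(t, np.ones(40))
        for q in np.quantile(t, [0.1, 0.5, 0.9]):
            assert km.survival_at(q) == pytest.approx((t > q).mean(), abs=1e-12)

    def test_matches_lifelines(self):
        from lifelines import KaplanMeierFitter
        rng = np.random.default_rng(1)
        t = rng.exponential(100, 60).round(1)
        e = rng.integers(0, 2, 60)
        km = km_curve(t, e)
        kmf = KaplanMeierFitter().fit(t, e)
        for ti in km.event_times:
            assert km.survival_at(ti) == pytest.approx(
                float(kmf.predict(ti)), abs=1e-10)


class TestLogrank:
    def test_identical_groups_statistic_zero(self):
        t, e = [1, 3, 5, 8], [1, 0, 1, 1]
        chi2, p = logrank_test(t, e, t, e)
        assert chi2 == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)

    def test_separated_groups_match_permutation_oracle(self):
        # A events at (1,2,3), B at (4,5,6), all uncensored.  The frozen
        # statistic and exact permutation rank were enumerated over all 20
        # label assignments of 3+3 before the implementation was written.
        chi2, p = logrank_test([1, 2, 3], [1, 1, 1], [4, 5, 6], [1, 1, 1])
        assert chi2 == pytest.approx(5.051660516605167, rel=1e-12)
        # independent re-enumeration at test time
        times = np.array([1, 2, 3, 4, 5, 6], dtype=float)
        stats = []
        for comb in combinations(range(6), 3):
            in_a = np.zeros(6, bool)
            in_a[list(comb)] = True
            O = E = V = 0.0
            for ti in times:  # every subject dies; all times are event times
                at_risk = times >= ti
                n, n_a = at_risk.sum(), (at_risk & in_a).sum()
                O += float(in_a[times == ti][0])
                E += n_a / n
                if n > 1:
                    V += (n_a / n) * (1 - n_a / n)  # d=1 at each time
            stats.append((O - E) ** 2 / V)
        assert chi2 == pytest.approx(max(stats), rel=1e-12)
        exact_p = np.mean([s >= chi2 - 1e-9 for s in stats])
        assert exact_p == pytest.approx(0.1)

    def test_hand_expanded_oe_table_with_censoring(self):
        # A: (2,1),(4,1),(6,0); B: (1,0),(3,1),(5,0)
        # t=2: n=5, nA=3, d=1 in A -> O+=1, E+=3/5,  V+=(3/5)(2/5)
        # t=3: n=4, nA=2, d=1 in B ->        E+=1/2,  V+=(1/2)(1/2)
        # t=4: n=3, nA=2, d=1 in A -> O+=1, E+=2/3,  V+=(2/3)(1/3)
        chi2, p = logrank_test([2, 4, 6], [1, 1, 0], [1, 3, 5], [0, 1, 0])
        O, E = 2.0, 3 / 5 + 1 / 2 + 2 / 3
        V = (3 / 5) * (2 / 5) + (1 / 2) * (1 / 2) + (2 / 3) * (1 / 3)
        assert chi2 == pytest.approx((O - E) ** 2 / V, rel=1e-12)

    def test_no_events_undefined(self):
        chi2, p = logrank_test([1, 2], [0, 0], [3, 4], [0, 0])
        assert math.isnan(chi2) and math.isnan(p)

    def test_matches_lifelines(self):
        from lifelines.statistics import logrank_test as ll_logrank
        rng = np.random.default_rng(2)
        for _ in range(5):
            ta = rng.exponential(50, 30)
            tb = rng.exponential(80, 25)
            ea = rng.integers(0, 2, 30)
            eb = rng.integers(0, 2, 25)
            chi2, p = logrank_test(ta, ea, tb, eb)
            ref = ll_logrank(ta, tb, event_observed_A=ea, event_observed_B=eb)
            assert chi2 == pytest.approx(ref.test_statistic, rel=1e-9)
            assert p == pytest.approx(ref.p_value, rel=1e-9)

    @settings(derandomize=True, max_examples=25)
    @given(st.integers(0, 10_000), st.floats(0.1, 50.0))
    def test_symmetry_and_time_rescaling(self, seed, scale):
        rng = np.random.default_rng(seed)
        ta, tb = rng.exponential(10, 12), rng.exponential(14, 10)
        ea, eb = rng.integers(0, 2, 12), rng.integers(0, 2, 10)
        if ea.sum() + eb.sum() == 0:
            return
        chi2, p = logrank_test(ta, ea, tb, eb)
        chi2_sym, p_sym = logrank_test(tb, eb, ta, ea)
        assert chi2 == pytest.approx(chi2_sym, rel=1e-9)
        chi2_sc, _ = logrank_test(ta * scale, ea, tb * scale, eb)
        assert chi2 == pytest.approx(chi2_sc, rel=1e-9)


class TestLOD:
    def test_identity_zero(self):
        assert compute_lod(0.01, 0.01) == 0.0

    def test_e_squared_fold_is_minus_two(self):
        assert compute_lod(0.05 / math.e ** 2, 0.05) == pytest.approx(-2.0)

    def test_direct_log(self):
        assert compute_lod(0.05, 0.005) == pytest.approx(math.log(10), rel=1e-12)

    def test_floor_prevents_log_zero(self):
        assert math.isfinite(compute_lod(0.0, 0.5))


class TestScan:
    def test_identical_matrices_give_zero_lod(self, normalized_cohort):
        expr, _, clin, truth, _ = normalized_cohort
        genes = truth.tumor_block[:5]
        scan = gene_survival_scan(expr, expr, clin, genes)
        np.testing.assert_allclose(scan["lod"], 0.0, atol=1e-12)

    def test_normalization_rescues_confounded_prognostic_genes(
            self, normalized_cohort):
        expr, norm, clin, truth, _ = normalized_cohort
        genes = truth.genes_of("prognostic_immune")
        scan = gene_survival_scan(expr, norm, clin, genes)
        assert scan["sig_norm"].sum() >= scan["sig_raw"].sum()
        assert np.median(scan["lod"]) < 0

    def test_direction_sign(self, normalized_cohort):
        # higher activity -> higher hazard, so a positive-gamma prognostic
        # gene should associate with shorter survival ('-') and a
        # negative-gamma gene with longer survival ('+')
        expr, norm, clin, truth, _ = normalized_cohort
        pos = truth.gamma.index[truth.gamma > 0][:3]
        neg = truth.gamma.index[truth.gamma < 0][:3]
        scan = gene_survival_scan(expr, norm, clin, list(pos) + list(neg))
        assert (scan.loc[pos, "direction"] == "-").all()
        assert (scan.loc[neg, "direction"] == "+").all()

    def test_bonferroni_threshold_and_fdr_monotonicity(self, normalized_cohort):
        expr, norm, clin, truth, _ = normalized_cohort
        genes = truth.genes_of("prognostic_immune") + truth.tumor_block[:10]
        bonf = gene_survival_scan(expr, norm, clin, genes, adjust="bonferroni")
        fdr = gene_survival_scan(expr, norm, clin, genes, adjust="fdr")
        threshold = 0.05 / bonf.attrs["n_tests"]
        assert ((bonf["p_norm"] < threshold) == bonf["sig_norm"]).all()
        # Bonferroni is never more permissive than Benjamini-Hochberg
        assert (fdr["sig_norm"] | ~bonf["sig_norm"]).all()

    def test_fixed_grouping_mode(self, normalized_cohort):
        expr, norm, clin, truth, _ = normalized_cohort
        genes = truth.tumor_block[:4]
        fixed = gene_survival_scan(expr, norm, clin, genes, fixed_grouping=True)
        refit = gene_survival_scan(expr, norm, clin, genes)
        # under fixed grouping p_norm is computed on raw-derived groups,
        # i.e. equals p_raw whenever both use the same groups
        np.testing.assert_allclose(fixed["p_norm"], fixed["p_raw"], rtol=1e-9)
        assert not np.allclose(refit["p_norm"], refit["p_raw"])
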