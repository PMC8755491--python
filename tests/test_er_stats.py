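import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from domainer.er_stats import (
    abundance_terciles,
    average_across_tissues,
    binomial_test,
    fisher_r_to_z,
    is_intermediate,
    ordering_fractions,
    spearman,
    steiger_z,
    tissue_sweep,
)


def _rates(omega_i, omega_t=None, omega_e=None, genes=None):
    n = len(omega_i)
    genes = genes or [f"g{k}" for k in range(n)]
    frame = {"gene": genes, "engine": ["ng86"] * n}
    for d, vals in (("i", omega_i), ("t", omega_t), ("e", omega_e)):
        vals = vals if vals is not None else omega_i
        frame[f"omega_{d}"] = vals
        frame[f"valid_{d}"] = [v == v for v in vals]
        frame[f"n_codons_{d}"] = [100] * n
        frame[f"dN_{d}"] = vals
        frame[f"dS_{d}"] = [1.0] * n
    return pd.DataFrame(frame)


class TestSpearman:
    def test_perfect_monotone(self):
        x = [1.0, 2.0, 5.0, 9.0, 12.0]
        assert spearman(x, x).rho == pytest.approx(1.0)
        assert spearman(x, [-v for v in x]).rho == pytest.approx(-1.0)

    def test_ties_match_rank_then_pearson_oracle(self):
        rng = np.random.default_rng(8)
        for _ in range(10):
            x = rng.integers(0, 5, 12).astype(float)  # many ties
            y = rng.integers(0, 5, 12).astype(float)
            if np.unique(x).size < 2 or np.unique(y).size < 2:
                continue
            res = spearman(x, y)
            oracle = np.corrcoef(stats.rankdata(x), stats.rankdata(y))[0, 1]
            assert res.rho == pytest.approx(oracle, abs=1e-12)

    def test_constant_vector_is_flagged_undefined(self):
        res = spearman([1, 1, 1, 1], [1, 2, 3, 4])
        assert math.isnan(res.rho)

    def test_too_few_observations_rejected(self):
        with pytest.raises(ValueError):
            spearman([1, 2, 3], [1, 2, 3])


class TestFisherRToZ:
    def test_equal_correlations_give_zero(self):
        res = fisher_r_to_z(0.3, 100, 0.3, 250)
        assert res.z == pytest.approx(0.0, abs=1e-12)
        assert res.p_one_tailed == pytest.approx(0.5)
        assert res.p_two_tailed == pytest.approx(1.0)

    def test_antisymmetry(self):
        a = fisher_r_to_z(-0.2, 500, 0.1, 400)
        b = fisher_r_to_z(0.1, 400, -0.2, 500)
        assert a.z == pytest.approx(-b.z, abs=1e-12)

    def test_z_sign_follows_atanh_difference(self):
        res = fisher_r_to_z(-0.3, 50, 0.2, 50)
        assert res.z < 0
        assert res.p_one_tailed == pytest.approx(stats.norm.cdf(res.z))

    def test_degenerate_correlation_rejected(self):
        with pytest.raises(ValueError, match="rho"):
            fisher_r_to_z(1.0, 100, 0.5, 100)

    def test_steiger_variant_is_finite_and_signed(self):
        res = steiger_z(-0.12, -0.04, 0.41, 3308)
        assert res.z < 0 and np.isfinite(res.z)
        assert 0 < res.p_one_tailed < 0.5


class TestBinomialTest:
    def test_all_successes_closed_form(self):
        for n in (5, 12, 30):
            res = binomial_test(n, n, 0.5, "greater")
            assert res.p_value == pytest.approx(0.5 ** n, rel=1e-12)

    def test_tail_probability_decreases_in_k(self):
        pvals = [binomial_test(k, 30, 1 / 3, "greater").p_value for k in range(31)]
        assert all(a > b for a, b in zip(pvals, pvals[1:]))

    def test_two_sided_uses_minlike_convention(self):
        res = binomial_test(28, 32, 0.5, "two-sided")
        assert res.p_value == pytest.approx(
            stats.binomtest(28, 32, 0.5, alternative="two-sided").pvalue)

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            binomial_test(5, 3, 0.5)
        with pytest.raises(ValueError):
            binomial_test(1, 3, 0.0)


class TestOrderingFractions:
    def test_all_e_greater_counts_everything(self):
        frame = _rates(omega_i=[0.1] * 6, omega_t=[0.05] * 6, omega_e=[0.3] * 6)
        out = ordering_fractions(frame)
        assert out["e_gt_i"].k_success == 6 and out["e_gt_i"].n_trials == 6
        assert out["t_lt_both"].k_success == 6

    def test_exact_tie_counts_as_failure(self):
        frame = _rates(omega_i=[0.2, 0.1], omega_t=[0.05, 0.05],
                       omega_e=[0.2, 0.3])  # first gene ties
        out = ordering_fractions(frame)
        assert out["e_gt_i"].k_success == 1

    def test_invalid_genes_excluded(self):
        frame = _rates(omega_i=[0.1, 0.2], omega_e=[0.3, float("nan")])
        assert ordering_fractions(frame)["e_gt_i"].n_trials == 1


class TestAbundanceTerciles:
    def test_even_split(self):
        frame = _rates(omega_i=list(np.linspace(0.1, 0.3, 9)))
        abund = pd.Series({f"g{k}": float(k + 1) for k in range(9)})
        out = abundance_terciles(frame, abund)
        assert list(out["n"]) == [3, 3, 3]

    def test_remainder_goes_to_lowest_bins(self):
        frame = _rates(omega_i=list(np.linspace(0.1, 0.3, 10)))
        abund = pd.Series({f"g{k}": float(k + 1) for k in range(10)})
        out = abundance_terciles(frame, abund)
        assert list(out["n"]) == [4, 3, 3]

    def test_null_cohort_bins_match_global_fraction(self):
        """With abundance-independent omega the per-bin percentage stays
        within 3 binomial SEs of the global one."""
        rng = np.random.default_rng(17)
        n = 600
        omega_i = rng.lognormal(-2, 0.5, n)
        omega_e = rng.lognormal(-2, 0.5, n)
        frame = _rates(omega_i=list(omega_i), omega_e=list(omega_e))
        abund = pd.Series({f"g{k}": v for k, v in enumerate(rng.lognormal(3, 1, n))})
        out = abundance_terciles(frame, abund)
        p_global = (omega_e > omega_i).mean()
        for _, row in out.iterrows():
            se = math.sqrt(p_global * (1 - p_global) / row["n"])
            assert abs(row["pct_e_gt_i"] / 100 - p_global) < 3 * se


class TestTissueAveraging:
    def test_mean_over_measured_tissues(self):
        table = pd.DataFrame({"gene": ["g1", "g1"], "context": ["a", "b"],
                              "abundance": [2.0, 4.0]})
        assert average_across_tissues(table)["g1"] == pytest.approx(3.0)

    def test_missing_tissue_dropped_not_zeroed(self):
        table = pd.DataFrame({"gene": ["g1", "g1"], "context": ["a", "c"],
                              "abundance": [3.0, 6.0]})
        assert average_across_tissues(table)["g1"] == pytest.approx(4.5)

    def test_dense_table_equals_row_means(self):
        rng = np.random.default_rng(4)
        wide = pd.DataFrame(rng.lognormal(1, 1, (20, 5)),
                            index=[f"g{k}" for k in range(20)])
        long = wide.reset_index().melt(id_vars="index", var_name="context",
                                       value_name="abundance").rename(columns={"index": "gene"})
        means = average_across_tissues(long)
        expected = wide.mean(axis=1)
        assert np.allclose(means.sort_index(), expected.sort_index())


class TestTissueSweep:
    def test_intermediacy_predicate(self):
        assert is_intermediate(-0.2, -0.1, 0.0) is True
        assert is_intermediate(-0.2, -0.3, 0.0) is False
        assert is_intermediate(-0.2, -0.2, 0.0) is False  # strict

    def test_counts_match_scalar_loop_oracle(self):
        rng = np.random.default_rng(30)
        n = 80
        omega = {d: rng.lognormal(-2, 0.5, n) for d in "ite"}
        frame = _rates(omega_i=list(omega["i"]), omega_t=list(omega["t"]),
                       omega_e=list(omega["e"]))
        rows = []
        for tissue in [f"t{j}" for j in range(10)]:
            for k in range(n):
                rows.append({"gene": f"g{k}", "context": tissue,
                             "abundance": float(rng.lognormal(3, 1))})
        table = pd.DataFrame(rows)
        sweep, summary = tissue_sweep(frame, table)

        k_oracle = 0
        for tissue in sorted(table["context"].unique()):
            sub = table[table["context"] == tissue].set_index("gene")["abundance"]
            rhos = {}
            for d in "ite":
                genes = sorted(sub.index)
                rhos[d] = stats.spearmanr(sub.loc[genes],
                                          pd.Series(omega[d], index=[f"g{k}" for k in range(n)]).loc[genes])[0]
            k_oracle += is_intermediate(rhos["i"], rhos["t"], rhos["e"])
        assert summary.k_success == k_oracle
        assert summary.n_trials == 10
        assert len(sweep) == 10
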