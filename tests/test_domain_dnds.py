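import numpy as np
import pytest
from scipy import stats

from conftest import random_codon_alignment
from helpers_oracles import oracle_ng86_counts, oracle_sites
from domainer._codons import CODON_ARRAY, CODONS
from domainer.codon_models import build_m0_generator
from domainer.domain_dnds import (
    apply_ds_filter,
    DomainRates,
    GeneRates,
    m0_fit,
    m0_transition_matrix,
    ng86_estimate,
    ng86_sites,
    rates_frame,
)
from domainer.ortholog_align import CodonAlignment
from domainer.synthetic_data import evolve_pair

UNIFORM = np.full(61, 1 / 61)


def _simulated_alignment(seed, omega, kappa=2.0, t=0.4, n_codons=2000):
    rng = np.random.default_rng(seed)
    Q = build_m0_generator(kappa, omega)
    anc = rng.integers(0, 61, n_codons)
    a, b = evolve_pair(anc, Q, t, rng, stationary_frequencies=UNIFORM)
    return CodonAlignment("a", "b", "".join(CODON_ARRAY[a]), "".join(CODON_ARRAY[b]))


class TestNg86Sites:
    def test_phenylalanine_matches_neighbor_enumeration(self):
        n, s = ng86_sites("TTT")
        n_oracle, s_oracle = oracle_sites("TTT")
        assert (n, s) == pytest.approx((n_oracle, s_oracle), abs=1e-12)

    def test_methionine_has_no_synonymous_sites(self):
        assert ng86_sites("ATG") == (3.0, 0.0)

    def test_sites_sum_to_three_for_every_sense_codon(self):
        for codon in CODONS:
            n, s = ng86_sites(codon)
            n_o, s_o = oracle_sites(codon)
            assert n + s == pytest.approx(3.0, abs=1e-12)
            assert (n, s) == pytest.approx((n_o, s_o), abs=1e-12)

    def test_stop_codon_rejected(self):
        with pytest.raises(ValueError):
            ng86_sites("TAA")


class TestNg86Estimate:
    def test_identical_sequences_are_invalid(self):
        aln = CodonAlignment("a", "b", "ATGAAACCC", "ATGAAACCC")
        est = ng86_estimate(aln)
        assert est.dN == 0 and est.dS == 0
        assert est.valid is False and est.omega is None

    def test_single_synonymous_change(self):
        est = ng86_estimate(CodonAlignment("a", "b", "AAA", "AAG"))
        assert est.Sd == pytest.approx(1.0)
        assert est.Nd == pytest.approx(0.0)

    def test_counts_match_path_enumeration_oracle(self):
        """(N, S, Nd, Sd) on random alignments vs exhaustive enumeration."""
        rng = np.random.default_rng(13)
        for _ in range(50):
            aln = random_codon_alignment(rng, 30)
            est = ng86_estimate(aln)
            N, S, Nd, Sd = oracle_ng86_counts(aln.row_a, aln.row_b)
            assert est.N_sites == pytest.approx(N, abs=1e-9)
            assert est.S_sites == pytest.approx(S, abs=1e-9)
            assert est.Nd == pytest.approx(Nd, abs=1e-9)
            assert est.Sd == pytest.approx(Sd, abs=1e-9)

    def test_gap_and_stop_columns_skipped(self):
        aln = CodonAlignment("a", "b", "AAA---TGACCC", "AAGAAATGGCCA")
        est = ng86_estimate(aln)
        assert est.n_codons == 2  # AAA/AAG and CCC/CCA


class TestM0TransitionMatrix:
    def test_zero_time_identity(self):
        P = m0_transition_matrix(2.0, 0.5, None, 0.0)
        assert np.allclose(P, np.eye(61), atol=1e-12)

    def test_rows_sum_to_one(self):
        rng = np.random.default_rng(3)
        for _ in range(3):
            P = m0_transition_matrix(rng.uniform(0.5, 5), rng.uniform(0.05, 2),
                                     None, rng.uniform(0.01, 1))
            assert np.abs(P.sum(axis=1) - 1).max() < 1e-10


class TestM0Fit:
    def test_identical_sequences_hit_lower_bound(self):
        aln = CodonAlignment("a", "b", "ATGAAACCC" * 10, "ATGAAACCC" * 10)
        est = m0_fit(aln)
        assert est.valid is False
        assert est.dN == 0 and est.dS == 0

    def test_optimum_likelihood_beats_truth(self):
        """lnL at the ML point is >= lnL at the simulating parameters."""
        from domainer.codon_models import _expm_reversible
        from domainer.domain_dnds import _pattern_counts, _usable_pairs

        for seed in range(5):
            aln = _simulated_alignment(seed, omega=0.3, n_codons=500)
            est = m0_fit(aln, freqs="uniform")
            ia, ib = _usable_pairs(aln)
            counts = _pattern_counts(ia, ib)
            Q = build_m0_generator(2.0, 0.3)
            P = _expm_reversible(Q, UNIFORM, 0.4)
            ll_truth = (counts * (np.log(UNIFORM)[:, None] + np.log(P))).sum()
            assert est.lnL >= ll_truth - 1e-6

    @pytest.mark.parametrize("omega_true", [0.1, 0.5, 1.0])
    def test_omega_recovery_bias_under_ten_percent(self, omega_true):
        estimates = [
            m0_fit(_simulated_alignment(1000 + rep, omega_true), freqs="uniform").omega
            for rep in range(50)
        ]
        bias = abs(np.mean(estimates) - omega_true)
        assert bias < 0.1 * omega_true

    def test_dn_ds_ratio_equals_fitted_omega(self):
        aln = _simulated_alignment(4, omega=0.4, n_codons=800)
        est = m0_fit(aln, freqs="uniform")
        assert est.dN / est.dS == pytest.approx(est.omega, rel=1e-6)


class TestEngineConsistency:
    def test_ng86_and_m0_rank_concordant(self):
        """Spearman(omega_NG86, omega_M0) > 0.9 over omega in [0.05, 1]."""
        rng = np.random.default_rng(21)
        omegas_true = rng.uniform(0.05, 1.0, 40)
        ng, m0 = [], []
        for rep, w in enumerate(omegas_true):
            aln = _simulated_alignment(3000 + rep, float(w), n_codons=300)
            ng.append(ng86_estimate(aln).omega)
            m0.append(m0_fit(aln, freqs="uniform").omega)
        rho, _ = stats.spearmanr(ng, m0)
        assert rho > 0.9

    def test_concatenation_consistency(self):
        """omega on the union of two same-process subalignments lies between
        the two, or within 2 Monte-Carlo SEs of both."""
        fits = [m0_fit(_simulated_alignment(5000 + rep, 0.3, n_codons=400),
                       freqs="uniform").omega for rep in range(10)]
        mc_se = np.std(fits, ddof=1)
        a = _simulated_alignment(6001, 0.3, n_codons=400)
        b = _simulated_alignment(6002, 0.3, n_codons=400)
        union = CodonAlignment("a", "b", a.row_a + b.row_a, a.row_b + b.row_b)
        wa = m0_fit(a, freqs="uniform").omega
        wb = m0_fit(b, freqs="uniform").omega
        wu = m0_fit(union, freqs="uniform").omega
        between = min(wa, wb) <= wu <= max(wa, wb)
        close = abs(wu - wa) <= 2 * mc_se and abs(wu - wb) <= 2 * mc_se
        assert between or close


class TestDsFilter:
    def _frame(self):
        genes = []
        g = GeneRates("g1", "ng86")
        g.domains["i"] = DomainRates("i", "ng86", 100, dN=0.1, dS=0.2, omega=0.5, valid=True)
        g.domains["t"] = DomainRates("t", "ng86", 20, dN=0.05, dS=0.1, omega=0.5, valid=True)
        g.domains["e"] = DomainRates("e", "ng86", 150, dN=0.1, dS=0.0, valid=False)
        genes.append(g)
        g = GeneRates("g2", "ng86")
        for d, n in (("i", 100), ("t", 20), ("e", 150)):
            g.domains[d] = DomainRates(d, "ng86", n, dN=0.1, dS=0.2, omega=0.5, valid=True)
        genes.append(g)
        return rates_frame(genes)

    def test_per_domain_scope_keeps_other_domains(self):
        out = apply_ds_filter(self._frame(), scope="per-domain")
        row = out[out["gene"] == "g1"].iloc[0]
        assert row["valid_i"] and not row["valid_e"]
        assert np.isnan(row["omega_e"])

    def test_whole_gene_scope_drops_everywhere(self):
        out = apply_ds_filter(self._frame(), scope="whole-gene")
        row = out[out["gene"] == "g1"].iloc[0]
        assert not row["valid_i"] and not row["valid_t"] and not row["valid_e"]
        assert out[out["gene"] == "g2"].iloc[0]["valid_i"]

    def test_no_zero_ds_is_identity(self):
        frame = self._frame()
        clean = frame[frame["gene"] == "g2"].reset_index(drop=True)
        out = apply_ds_filter(clean, scope="per-domain")
        assert out.equals(clean)
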