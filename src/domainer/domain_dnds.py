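"""Per-subalignment dN/dS estimation: NG86 counting and ML under GY94 M0.

Both engines operate on pairwise codon alignments.  NG86 counts synonymous
and nonsynonymous sites and differences (equal-weight averaging over minimal
substitution paths, Jukes–Cantor multiple-hit correction).  The M0 engine
maximises the likelihood of the codon pair under the Goldman–Yang one-ratio
model with F3x4 (or uniform) frequencies, then derives dN and dS from the
fitted generator in the PAML convention.

Genes whose synonymous divergence is zero have an undefined ω and are
flagged invalid; ``apply_ds_filter`` removes them from downstream analyses.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import minimize

from ._codons import (
    N_CODONS,
    NONSYN_SITES,
    SYN_SITES,
    encode_codons,
    ng86_diff_tables,
)
from .codon_models import (
    _check_frequencies,
    _expm_reversible,
    build_m0_generator,
    dn_ds_from_m0,
    transition_matrix,  # noqa: F401  (re-exported: shares the simulator's generator)
    uniform_codon_frequencies,
)
from .ortholog_align import CodonAlignment

DOMAINS = ("i", "t", "e")
ENGINES = ("ng86", "m0")

# PAML-like box constraints
KAPPA_BOUNDS = (0.01, 99.0)
OMEGA_BOUNDS = (1e-4, 99.0)
T_BOUNDS = (1e-6, 50.0)
OMEGA_STARTS = (0.1, 0.5, 2.0)


@dataclass
class DomainRates:
    """dN, dS and ω for one domain of one gene, with validity flag."""

    domain: str
    engine: str
    n_codons: int
    dN: float = float("nan")
    dS: float = float("nan")
    omega: float | None = None
    valid: bool = False
    # NG86 counts
    N_sites: float = float("nan")
    S_sites: float = float("nan")
    Nd: float = float("nan")
    Sd: float = float("nan")
    # M0 parameters
    t: float | None = None
    kappa: float | None = None
    lnL: float | None = None


@dataclass
class GeneRates:
    gene: str
    engine: str
    domains: dict = field(default_factory=dict)


def ng86_sites(codon: str) -> tuple[float, float]:
    """(nonsynonymous, synonymous) NG86 site counts for one sense codon.

    Per position, the synonymous fraction is taken among the sense (non-stop)
    single-nucleotide neighbours, so the two counts always sum to 3.
    """
    idx = encode_codons(codon)
    if idx[0] < 0:
        raise ValueError(f"not a sense codon: {codon!r}")
    i = int(idx[0])
    return float(NONSYN_SITES[i]), float(SYN_SITES[i])


def _usable_pairs(alignment: CodonAlignment) -> tuple[np.ndarray, np.ndarray]:
    """Encoded codon indices for columns where both rows are usable."""
    ia = encode_codons(alignment.row_a)
    ib = encode_codons(alignment.row_b)
    mask = (ia >= 0) & (ib >= 0)
    return ia[mask], ib[mask]


def _jukes_cantor(p: float) -> float:
    if p >= 0.75:
        return float("nan")
    return -0.75 * np.log1p(-4.0 * p / 3.0)


def ng86_estimate(alignment: CodonAlignment) -> DomainRates:
    """NG86 dN/dS for a pairwise codon subalignment.

    Columns with gaps, stops or ambiguity in either row are skipped
    (pairwise deletion).  Site counts are averaged between the two
    sequences; observed differences average over minimal substitution paths;
    proportions are Jukes–Cantor corrected.  dS = 0 yields valid=False.
    """
    ia, ib = _usable_pairs(alignment)
    out = DomainRates("", "ng86", n_codons=int(ia.size))
    if ia.size == 0:
        return out
    nd_tab, sd_tab = ng86_diff_tables()
    out.N_sites = float((NONSYN_SITES[ia].sum() + NONSYN_SITES[ib].sum()) / 2.0)
    out.S_sites = float((SYN_SITES[ia].sum() + SYN_SITES[ib].sum()) / 2.0)
    out.Nd = float(nd_tab[ia, ib].sum())
    out.Sd = float(sd_tab[ia, ib].sum())
    pN = out.Nd / out.N_sites if out.N_sites > 0 else float("nan")
    pS = out.Sd / out.S_sites if out.S_sites > 0 else float("nan")
    out.dN = _jukes_cantor(pN) if pN == pN else float("nan")
    out.dS = _jukes_cantor(pS) if pS == pS else float("nan")
    if out.dS == out.dS and out.dS > 0 and out.dN == out.dN:
        out.omega = out.dN / out.dS
        out.valid = True
    return out


def f3x4_frequencies(alignment: CodonAlignment) -> np.ndarray:
    """F3x4 codon frequencies from both rows jointly.

    Nucleotide frequencies are tabulated per codon position over all usable
    codons of both sequences; sense-codon frequencies are their product,
    renormalised over the 61 sense codons.  A small floor keeps frequencies
    strictly positive.
    """
    from ._codons import CODON_NT

    ia, ib = _usable_pairs(alignment)
    if ia.size == 0:
        return uniform_codon_frequencies()
    counts = np.zeros((3, 4))
    for idx in (ia, ib):
        nts = CODON_NT[idx]  # (n, 3)
        for pos in range(3):
            counts[pos] += np.bincount(nts[:, pos], minlength=4)
    freqs = (counts + 0.5) / (counts + 0.5).sum(axis=1, keepdims=True)
    pi = (freqs[0, CODON_NT[:, 0]] * freqs[1, CODON_NT[:, 1]] * freqs[2, CODON_NT[:, 2]])
    return pi / pi.sum()


def m0_transition_matrix(kappa: float, omega: float, codon_frequencies=None,
                         t: float = 0.0) -> np.ndarray:
    """exp(Q·t) under the GY94 generator shared with the simulator."""
    return transition_matrix(kappa, omega, codon_frequencies, t)


def _pattern_counts(ia: np.ndarray, ib: np.ndarray) -> np.ndarray:
    counts = np.zeros((N_CODONS, N_CODONS))
    np.add.at(counts, (ia, ib), 1.0)
    return counts


def m0_fit(alignment: CodonAlignment, freqs: str = "f3x4") -> DomainRates:
    """Maximum-likelihood M0 fit to a pairwise codon alignment.

    Maximises Σ_sites log(π_x · P_xy(t)) over (t, κ, ω) with L-BFGS-B on log
    parameters, three fixed ω starting points, best log-likelihood winning
    (ties to the smallest ω).  dN and dS are derived from the fitted
    generator (PAML convention), so dN/dS equals the fitted ω.
    """
    if freqs not in ("f3x4", "uniform"):
        raise ValueError(f"unknown frequency model {freqs!r}")
    ia, ib = _usable_pairs(alignment)
    out = DomainRates("", "m0", n_codons=int(ia.size))
    if ia.size == 0:
        return out
    pi = f3x4_frequencies(alignment) if freqs == "f3x4" else uniform_codon_frequencies()
    pi = _check_frequencies(pi)
    counts = _pattern_counts(ia, ib)
    log_pi = np.log(pi)

    if (ia == ib).all():
        # no variable sites: t collapses to its lower bound, omega undefined
        out.t, out.kappa = T_BOUNDS[0], float("nan")
        out.dN = out.dS = 0.0
        out.lnL = float((np.diag(counts) * log_pi).sum())
        return out

    def nll(theta):
        t, kappa, omega = np.exp(theta)
        Q = build_m0_generator(kappa, omega, pi)
        P = _expm_reversible(Q, pi, t)
        ll = counts * (log_pi[:, np.newaxis] + np.log(np.maximum(P, 1e-300)))
        return -ll.sum()

    p_diff = float((ia != ib).mean())
    t0 = max(0.05, -np.log(max(1.0 - p_diff, 0.02)))
    bounds = [tuple(np.log(T_BOUNDS)), tuple(np.log(KAPPA_BOUNDS)), tuple(np.log(OMEGA_BOUNDS))]
    results = []
    for omega0 in OMEGA_STARTS:
        res = minimize(nll, x0=np.log([t0, 2.0, omega0]), method="L-BFGS-B", bounds=bounds)
        if res.success or np.isfinite(res.fun):
            results.append(res)
    if not results:
        raise RuntimeError(
            f"M0 optimisation failed for pair ({alignment.id_a}, {alignment.id_b}); "
            f"{ia.size} codons, p_diff={p_diff:.4f}"
        )
    best = min(results, key=lambda r: (round(r.fun, 8), np.exp(r.x[2])))
    t_hat, kappa_hat, omega_hat = np.exp(best.x)
    out.t, out.kappa, out.lnL = float(t_hat), float(kappa_hat), float(-best.fun)
    out.dN, out.dS = dn_ds_from_m0(t_hat, kappa_hat, omega_hat, pi)
    if out.dS > 1e-8 and t_hat > T_BOUNDS[0] * 1.01:
        out.omega = float(omega_hat)
        out.valid = True
    return out


def estimate_subalignment(alignment: CodonAlignment, engine: str = "ng86",
                          freqs: str = "f3x4") -> DomainRates:
    if engine not in ENGINES:
        raise ValueError(f"unknown engine {engine!r}; expected one of {ENGINES}")
    if engine == "ng86":
        return ng86_estimate(alignment)
    return m0_fit(alignment, freqs=freqs)


def estimate_gene(gene: str, subalignments: dict, engine: str = "ng86",
                  freqs: str = "f3x4") -> GeneRates:
    """Estimate rates for the i/t/e subalignments of one gene."""
    rates = GeneRates(gene, engine)
    for domain in DOMAINS:
        sub = subalignments.get(domain)
        if sub is None or sub.n_columns == 0:
            rates.domains[domain] = DomainRates(domain, engine, n_codons=0)
            continue
        est = estimate_subalignment(sub, engine=engine, freqs=freqs)
        est.domain = domain
        rates.domains[domain] = est
    return rates


def rates_frame(gene_rates) -> pd.DataFrame:
    """Flatten GeneRates into the documented per-gene table."""
    rows = []
    for gr in gene_rates:
        row = {"gene": gr.gene, "engine": gr.engine}
        for d in DOMAINS:
            est = gr.domains.get(d) or DomainRates(d, gr.engine, n_codons=0)
            row[f"n_codons_{d}"] = est.n_codons
            row[f"dN_{d}"] = est.dN
            row[f"dS_{d}"] = est.dS
            row[f"omega_{d}"] = est.omega if est.valid else float("nan")
            row[f"valid_{d}"] = bool(est.valid)
        rows.append(row)
    columns = ["gene", "engine"] + [f"{k}_{d}" for d in DOMAINS
                                    for k in ("n_codons", "dN", "dS", "omega", "valid")]
    return pd.DataFrame(rows, columns=columns)


def apply_ds_filter(rates: pd.DataFrame, scope: str = "per-domain") -> pd.DataFrame:
    """Remove genes with dS = 0 (infinite ω) from downstream analyses.

    ``per-domain``: a gene contributes to a domain's analyses only if that
    domain's estimate is valid (dS > 0).  ``whole-gene``: a gene with dS = 0
    in any domain that has codons is dropped from every analysis.
    """
    if scope not in ("per-domain", "whole-gene"):
        raise ValueError(f"unknown dS-filter scope {scope!r}")
    out = rates.copy()
    for d in DOMAINS:
        bad = ~out[f"valid_{d}"] | ~(out[f"dS_{d}"] > 0)
        out.loc[bad, f"valid_{d}"] = False
        out.loc[bad, f"omega_{d}"] = float("nan")
    if scope == "whole-gene":
        zero = pd.Series(False, index=out.index)
        for d in DOMAINS:
            has_codons = out[f"n_codons_{d}"] > 0
            zero |= has_codons & ~out[f"valid_{d}"]
        for d in DOMAINS:
            out.loc[zero, f"valid_{d}"] = False
            out.loc[zero, f"omega_{d}"] = float("nan")
    return out
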