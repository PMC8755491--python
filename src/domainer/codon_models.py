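"""Goldman–Yang (GY94) one-ratio codon substitution model.

The instantaneous generator over the 61 sense codons has zero rate for
multi-nucleotide changes; a single-nucleotide change i→j has rate
proportional to π_j, multiplied by κ for transitions and by ω for
nonsynonymous changes.  The generator is scaled so that the expected number
of substitutions per codon per unit time equals one, which makes the branch
length t directly interpretable as substitutions per codon.

This module is shared by the forward simulator (synthetic_data) and the
maximum-likelihood estimator (domain_dnds): both use exactly the same model
family, so estimator recovery is well-posed.
"""
from __future__ import annotations

import numpy as np

from ._codons import (
    N_CODONS,
    NONSYN_SITES,
    SINGLE_NT_MASK,
    SYN_SITES,
    SYNONYMOUS_MASK,
    TRANSITION_MASK,
)

__all__ = [
    "uniform_codon_frequencies",
    "build_m0_generator",
    "transition_matrix",
    "substitution_split",
    "dn_ds_from_m0",
]


def uniform_codon_frequencies() -> np.ndarray:
    return np.full(N_CODONS, 1.0 / N_CODONS)


def _check_frequencies(codon_frequencies) -> np.ndarray:
    if codon_frequencies is None:
        return uniform_codon_frequencies()
    pi = np.asarray(codon_frequencies, dtype=float)
    if pi.shape != (N_CODONS,):
        raise ValueError(f"expected {N_CODONS} codon frequencies, got shape {pi.shape}")
    if (pi <= 0).any():
        raise ValueError("codon frequencies must be strictly positive")
    if abs(pi.sum() - 1.0) > 1e-6:
        raise ValueError(f"codon frequencies must sum to 1 (sum={pi.sum():.8f})")
    return pi / pi.sum()


def build_m0_generator(kappa: float, omega: float, codon_frequencies=None) -> np.ndarray:
    """61×61 GY94 rate matrix, scaled to one expected substitution per unit time.

    Raises ValueError for negative kappa or omega, or invalid frequencies.
    """
    if kappa < 0:
        raise ValueError(f"kappa must be non-negative, got {kappa}")
    if omega < 0:
        raise ValueError(f"omega must be non-negative, got {omega}")
    pi = _check_frequencies(codon_frequencies)
    rates = np.where(SINGLE_NT_MASK, pi[np.newaxis, :], 0.0)
    rates = np.where(TRANSITION_MASK, rates * kappa, rates)
    nonsyn = SINGLE_NT_MASK & ~SYNONYMOUS_MASK
    rates = np.where(nonsyn, rates * omega, rates)
    np.fill_diagonal(rates, 0.0)
    np.fill_diagonal(rates, -rates.sum(axis=1))
    scale = -(pi * np.diag(rates)).sum()
    if scale <= 0:
        raise ValueError("degenerate generator: total substitution rate is zero")
    return rates / scale


def _expm_reversible(Q: np.ndarray, pi: np.ndarray, t: float) -> np.ndarray:
    """exp(Q t) for a time-reversible Q via symmetric eigendecomposition."""
    d = np.sqrt(pi)
    B = Q * d[:, np.newaxis] / d[np.newaxis, :]
    B = (B + B.T) / 2.0
    w, U = np.linalg.eigh(B)
    P = (U * np.exp(w * t)) @ U.T
    P = P / d[:, np.newaxis] * d[np.newaxis, :]
    np.clip(P, 0.0, None, out=P)
    P /= P.sum(axis=1, keepdims=True)
    return P


def transition_matrix(kappa: float, omega: float, codon_frequencies=None, t: float = 0.0) -> np.ndarray:
    """exp(Q·t): codon transition probabilities after t expected substitutions."""
    if t < 0:
        raise ValueError(f"t must be non-negative, got {t}")
    pi = _check_frequencies(codon_frequencies)
    Q = build_m0_generator(kappa, omega, pi)
    return _expm_reversible(Q, pi, t)


def substitution_split(kappa: float, omega: float, codon_frequencies=None) -> tuple[float, float]:
    """Fractions (synonymous, nonsynonymous) of the equilibrium substitution flux."""
    pi = _check_frequencies(codon_frequencies)
    Q = build_m0_generator(kappa, omega, pi)
    flux = pi[:, np.newaxis] * Q
    syn = flux[SINGLE_NT_MASK & SYNONYMOUS_MASK].sum()
    non = flux[SINGLE_NT_MASK & ~SYNONYMOUS_MASK].sum()
    total = syn + non
    return syn / total, non / total


def dn_ds_from_m0(t: float, kappa: float, omega: float, codon_frequencies=None) -> tuple[float, float]:
    """(dN, dS) per site from fitted M0 parameters, PAML convention.

    The expected substitutions per codon (t) are partitioned into synonymous
    and nonsynonymous classes by the fitted generator's flux; the site
    proportions come from the same generator evaluated at ω = 1 (the
    mutational opportunity), so that dN/dS equals the fitted ω exactly.
    """
    pi = _check_frequencies(codon_frequencies)
    rho_s, rho_n = substitution_split(kappa, omega, pi)
    rho_s1, rho_n1 = substitution_split(kappa, 1.0, pi)
    dS = t * rho_s / (3.0 * rho_s1)
    dN = t * rho_n / (3.0 * rho_n1)
    return dN, dS


def ng86_site_counts() -> tuple[np.ndarray, np.ndarray]:
    """Per-codon (nonsynonymous, synonymous) NG86 site counts."""
    return NONSYN_SITES.copy(), SYN_SITES.copy()
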