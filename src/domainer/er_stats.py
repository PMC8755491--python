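"""Expression–rate correlation statistics.

Spearman correlations of per-domain ω with abundance, Fisher r-to-z
comparison of two correlation coefficients, exact binomial ordering tests,
abundance terciles, and multi-tissue sweeps with ω_t-intermediacy counts.

The Fisher comparison uses the independent-samples formula
Z = (atanh(r1) − atanh(r2)) / sqrt(1/(n1−3) + 1/(n2−3)); both tails are
reported, with the one-tailed probability Φ(Z) for the alternative r1 < r2.
A Steiger-type variant for overlapping correlations (two correlations
sharing the abundance variable) is available as an option.
"""
from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

DOMAINS = ("i", "t", "e")


@dataclass(frozen=True)
class CorrelationResult:
    """A Spearman coefficient with its sample size and two-tailed p."""

    label: str
    rho: float
    n: int
    p_two_tailed: float


@dataclass(frozen=True)
class ERTestResult:
    """Fisher r-to-z comparison of two correlation coefficients."""

    label: str
    rho_1: float
    n_1: int
    rho_2: float
    n_2: int
    z: float
    p_one_tailed: float
    p_two_tailed: float


@dataclass(frozen=True)
class OrderingCounts:
    """An exact binomial test on k successes out of n trials."""

    label: str
    k_success: int
    n_trials: int
    null_p: float
    p_value: float
    direction: str


def spearman(x, y, label: str = "") -> CorrelationResult:
    """Spearman rank correlation with average ranks for ties.

    The two-tailed p uses the t-distribution approximation with n − 2
    degrees of freedom.  Requires n ≥ 4 pairwise-complete observations;
    a constant vector makes rho undefined (NaN).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("x and y must have equal length")
    n = x.size
    if n < 4:
        raise ValueError(f"need at least 4 observations, got {n}")
    if np.unique(x).size < 2 or np.unique(y).size < 2:
        return CorrelationResult(label, float("nan"), n, float("nan"))
    rho, p = stats.spearmanr(x, y)
    return CorrelationResult(label, float(rho), n, float(p))


def fisher_r_to_z(rho_1: float, n_1: int, rho_2: float, n_2: int,
                  label: str = "") -> ERTestResult:
    """Compare two independent correlation coefficients.

    Z = (atanh(rho_1) − atanh(rho_2)) / sqrt(1/(n_1−3) + 1/(n_2−3));
    p_one_tailed = Φ(Z) (alternative rho_1 < rho_2),
    p_two_tailed = 2·Φ(−|Z|).
    """
    for rho, n in ((rho_1, n_1), (rho_2, n_2)):
        if abs(rho) >= 1.0:
            raise ValueError(f"|rho| must be < 1 for the r-to-z transform, got {rho}")
        if n < 4:
            raise ValueError(f"need n >= 4, got {n}")
    z = (math.atanh(rho_1) - math.atanh(rho_2)) / math.sqrt(
        1.0 / (n_1 - 3) + 1.0 / (n_2 - 3)
    )
    p_one = float(stats.norm.cdf(z))
    p_two = float(2.0 * stats.norm.cdf(-abs(z)))
    return ERTestResult(label, rho_1, n_1, rho_2, n_2, float(z), p_one, p_two)


def steiger_z(rho_1: float, rho_2: float, r_12: float, n: int,
              label: str = "") -> ERTestResult:
    """Compare two overlapping correlations sharing one variable.

    Meng–Rosenthal–Rubin form: both correlations are measured on the same n
    cases and share a variable (here abundance); r_12 is the correlation
    between the two non-shared variables (here ω_i and ω_e).
    """
    for rho in (rho_1, rho_2, r_12):
        if abs(rho) >= 1.0:
            raise ValueError(f"|rho| must be < 1, got {rho}")
    if n < 4:
        raise ValueError(f"need n >= 4, got {n}")
    r2bar = (rho_1 ** 2 + rho_2 ** 2) / 2.0
    f = min(1.0, (1.0 - r_12) / (2.0 * (1.0 - r2bar)))
    h = (1.0 - f * r2bar) / (1.0 - r2bar)
    z = (math.atanh(rho_1) - math.atanh(rho_2)) * math.sqrt(
        (n - 3) / (2.0 * (1.0 - r_12) * h)
    )
    p_one = float(stats.norm.cdf(z))
    p_two = float(2.0 * stats.norm.cdf(-abs(z)))
    return ERTestResult(label, rho_1, n, rho_2, n, float(z), p_one, p_two)


def binomial_test(k: int, n: int, null_p: float, direction: str = "greater",
                  label: str = "") -> OrderingCounts:
    """Exact binomial tail test.

    ``greater``: P(X ≥ k); ``two-sided``: the minimum-likelihood convention
    (sum of all outcome probabilities no larger than pmf(k)).
    """
    if not 0 <= k <= n:
        raise ValueError(f"need 0 <= k <= n, got k={k}, n={n}")
    if not 0.0 < null_p < 1.0:
        raise ValueError(f"null_p must be in (0, 1), got {null_p}")
    if direction not in ("greater", "two-sided"):
        raise ValueError(f"unknown direction {direction!r}")
    alternative = "greater" if direction == "greater" else "two-sided"
    p = float(stats.binomtest(k, n, null_p, alternative=alternative).pvalue)
    return OrderingCounts(label, k, n, null_p, p, direction)


def _valid_omega(rates: pd.DataFrame, domain: str) -> pd.Series:
    mask = rates[f"valid_{domain}"] & rates[f"omega_{domain}"].notna()
    return rates.loc[mask].set_index("gene")[f"omega_{domain}"]


def ordering_fractions(rates: pd.DataFrame) -> dict:
    """Ordering counts among genes with all compared domains valid.

    ``e_gt_i``: ω_e > ω_i (null 1/2, two-sided, ties count as failures);
    ``t_lt_both``: ω_t < min(ω_i, ω_e) (null 1/3, greater).
    """
    both = rates[rates["valid_i"] & rates["valid_e"]]
    k_ei = int((both["omega_e"] > both["omega_i"]).sum())
    out = {
        "e_gt_i": binomial_test(k_ei, len(both), 0.5, "two-sided",
                                label="omega_e > omega_i")
    }
    all3 = rates[rates["valid_i"] & rates["valid_t"] & rates["valid_e"]]
    k_t = int((all3["omega_t"] < np.minimum(all3["omega_i"], all3["omega_e"])).sum())
    out["t_lt_both"] = binomial_test(k_t, len(all3), 1.0 / 3.0, "greater",
                                     label="omega_t < min(omega_i, omega_e)")
    return out


def abundance_terciles(rates: pd.DataFrame, abundances) -> pd.DataFrame:
    """Percentage of genes with ω_e > ω_i within abundance terciles.

    Genes are ranked by abundance (stable order for ties) and split into
    low/mid/high bins; with n not divisible by 3 the extra genes go to the
    lowest bins first (n = 10 → 4/3/3).
    """
    abund = pd.Series(abundances).dropna()
    both = rates[rates["valid_i"] & rates["valid_e"]].set_index("gene")
    genes = both.index.intersection(abund.index)
    n = len(genes)
    if n < 3:
        raise ValueError(f"need at least 3 genes with valid omega and abundance, got {n}")
    values = abund.loc[genes]
    order = np.argsort(values.to_numpy(), kind="stable")
    base, rem = divmod(n, 3)
    sizes = [base + (1 if b < rem else 0) for b in range(3)]
    rows = []
    start = 0
    for name, size in zip(("low", "mid", "high"), sizes):
        idx = genes[order[start:start + size]]
        start += size
        sub = both.loc[idx]
        k = int((sub["omega_e"] > sub["omega_i"]).sum())
        rows.append({"bin": name, "n": size, "k_e_gt_i": k,
                     "pct_e_gt_i": 100.0 * k / size})
    return pd.DataFrame(rows, columns=["bin", "n", "k_e_gt_i", "pct_e_gt_i"])


def average_across_tissues(table: pd.DataFrame) -> pd.Series:
    """Per-gene arithmetic mean abundance over the tissues where measured.

    ``table`` is long-form (gene, context, abundance); missing tissues are
    dropped, not zero-filled, and genes with no measurements are excluded.
    """
    return table.groupby("gene")["abundance"].mean()


def correlate_domains(rates: pd.DataFrame, abundances, context: str = "") -> dict:
    """Spearman(ω_d, abundance) for d ∈ {i, t, e} on pairwise-complete genes.

    A gene enters a domain's correlation only if that domain's ω is valid
    and its abundance is present and strictly positive (zero abundance is
    below detection, treated as missing).
    """
    abund = pd.Series(abundances).dropna()
    abund = abund[abund > 0]
    out = {}
    for d in DOMAINS:
        omega = _valid_omega(rates, d)
        genes = omega.index.intersection(abund.index)
        tag = f"omega_{d} vs {context}" if context else f"omega_{d}"
        if len(genes) < 4:
            out[d] = CorrelationResult(tag, float("nan"), len(genes), float("nan"))
            continue
        out[d] = spearman(abund.loc[genes], omega.loc[genes], label=tag)
    return out


def compare_er(rates: pd.DataFrame, abundances, context: str = "",
               overlap_correction: bool = False) -> tuple[dict, list]:
    """The headline comparison: three correlations plus pairwise Fisher tests.

    Returns (correlations by domain, [i-vs-e, i-vs-t, t-vs-e] test results).
    With ``overlap_correction`` the Steiger-type statistic on the common
    gene set replaces the independent-samples formula.
    """
    corr = correlate_domains(rates, abundances, context=context)
    tests = []
    for d1, d2 in (("i", "e"), ("i", "t"), ("t", "e")):
        c1, c2 = corr[d1], corr[d2]
        label = f"omega_{d1} vs omega_{d2}" + (f" ({context})" if context else "")
        if not (np.isfinite(c1.rho) and np.isfinite(c2.rho)):
            tests.append(ERTestResult(label, c1.rho, c1.n, c2.rho, c2.n,
                                      float("nan"), float("nan"), float("nan")))
            continue
        if overlap_correction:
            abund = pd.Series(abundances).dropna()
            abund = abund[abund > 0]
            o1 = _valid_omega(rates, d1)
            o2 = _valid_omega(rates, d2)
            genes = o1.index.intersection(o2.index).intersection(abund.index)
            r12 = spearman(o1.loc[genes], o2.loc[genes]).rho
            ra = spearman(abund.loc[genes], o1.loc[genes]).rho
            rb = spearman(abund.loc[genes], o2.loc[genes]).rho
            tests.append(steiger_z(ra, rb, r12, len(genes), label=label))
        else:
            tests.append(fisher_r_to_z(c1.rho, c1.n, c2.rho, c2.n, label=label))
    return corr, tests


def is_intermediate(rho_i: float, rho_t: float, rho_e: float) -> bool:
    """ω_t-intermediacy: rho_t strictly between rho_i and rho_e."""
    return min(rho_i, rho_e) < rho_t < max(rho_i, rho_e)


def tissue_sweep(rates: pd.DataFrame, table: pd.DataFrame) -> tuple[pd.DataFrame, OrderingCounts]:
    """Per-tissue correlations and the ω_t-intermediacy summary.

    ``table`` is a long-form abundance table whose contexts are tissues.
    Returns the per-tissue frame (tissue, rho_i, rho_t, rho_e, n_i, n_t,
    n_e, intermediate) and the binomial test of the intermediacy count
    against the null of one-third.
    """
    tissues = sorted(table["context"].unique())
    if not tissues:
        raise ValueError("abundance table has no contexts")
    rows = []
    k = 0
    n_informative = 0
    for tissue in tissues:
        abund = table.loc[table["context"] == tissue].set_index("gene")["abundance"]
        corr = correlate_domains(rates, abund, context=tissue)
        rec = {"tissue": tissue}
        for d in DOMAINS:
            rec[f"rho_{d}"] = corr[d].rho
            rec[f"n_{d}"] = corr[d].n
        finite = all(np.isfinite(corr[d].rho) for d in DOMAINS)
        rec["intermediate"] = bool(
            finite and is_intermediate(corr["i"].rho, corr["t"].rho, corr["e"].rho)
        )
        if finite:
            n_informative += 1
            k += rec["intermediate"]
        rows.append(rec)
    summary = binomial_test(k, n_informative, 1.0 / 3.0, "greater",
                            label="omega_t intermediate across tissues")
    columns = ["tissue"] + [f"rho_{d}" for d in DOMAINS] + [f"n_{d}" for d in DOMAINS] + ["intermediate"]
    return pd.DataFrame(rows, columns=columns), summary
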