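"""Independent brute-force oracles used by the tests.

These are deliberately structured differently from the package code: sites
by explicit neighbour enumeration with the standard genetic code written out
via Biopython, differences by recursive path enumeration, alignment scores
by a plain Gotoh dynamic program.
"""
from itertools import permutations

from Bio.Data import CodonTable
from Bio.Align import substitution_matrices

_CODE = CodonTable.unambiguous_dna_by_id[1]
_SENSE = set(_CODE.forward_table)


def _aa(codon):
    return _CODE.forward_table[codon]


def oracle_sites(codon):
    """(nonsyn, syn) NG86 sites: per position, synonymous fraction among
    sense single-nucleotide neighbours; one site per position."""
    syn = 0.0
    for pos in range(3):
        sense_neighbors = []
        for nt in "ACGT":
            if nt == codon[pos]:
                continue
            other = codon[:pos] + nt + codon[pos + 1:]
            if other in _SENSE:
                sense_neighbors.append(other)
        n_syn = sum(_aa(v) == _aa(codon) for v in sense_neighbors)
        syn += n_syn / len(sense_neighbors)
    return 3.0 - syn, syn


def oracle_diffs(x, y):
    """(nonsyn, syn) observed differences averaged over minimal paths whose
    intermediates are sense codons (all paths if every one is blocked)."""
    positions = [p for p in range(3) if x[p] != y[p]]
    if not positions:
        return 0.0, 0.0
    results = []
    for order in permutations(positions):
        codons = [x]
        for p in order:
            prev = codons[-1]
            codons.append(prev[:p] + y[p] + prev[p + 1:])
        ok = all(c in _SENSE for c in codons[1:-1])
        syn = sum(1 for a, b in zip(codons, codons[1:])
                  if a in _SENSE and b in _SENSE and _aa(a) == _aa(b))
        results.append((len(positions) - syn, syn, ok))
    usable = [r for r in results if r[2]] or results
    nd = sum(r[0] for r in usable) / len(usable)
    sd = sum(r[1] for r in usable) / len(usable)
    return nd, sd


def oracle_ng86_counts(row_a, row_b):
    """Aggregate (N, S, Nd, Sd) over the usable columns of a codon pair."""
    N = S = Nd = Sd = 0.0
    for k in range(0, len(row_a), 3):
        ca, cb = row_a[k:k + 3], row_b[k:k + 3]
        if ca not in _SENSE or cb not in _SENSE:
            continue
        na, sa = oracle_sites(ca)
        nb, sb = oracle_sites(cb)
        N += (na + nb) / 2.0
        S += (sa + sb) / 2.0
        nd, sd = oracle_diffs(ca, cb)
        Nd += nd
        Sd += sd
    return N, S, Nd, Sd


def oracle_global_score(a, b, gap_open=11, gap_extend=1):
    """Affine-gap global alignment score by the Gotoh dynamic program.

    A gap of length L costs gap_open + L * gap_extend (BLAST convention),
    i.e. the first gapped residue costs gap_open + gap_extend.
    """
    blosum = substitution_matrices.load("BLOSUM62")
    first = gap_open + gap_extend
    neg = float("-inf")
    n, m = len(a), len(b)
    M = [[neg] * (m + 1) for _ in range(n + 1)]
    Ix = [[neg] * (m + 1) for _ in range(n + 1)]  # gap in b (moving along a)
    Iy = [[neg] * (m + 1) for _ in range(n + 1)]  # gap in a
    M[0][0] = 0.0
    for i in range(1, n + 1):
        Ix[i][0] = -first - (i - 1) * gap_extend
    for j in range(1, m + 1):
        Iy[0][j] = -first - (j - 1) * gap_extend
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            s = blosum[a[i - 1], b[j - 1]]
            M[i][j] = max(M[i - 1][j - 1], Ix[i - 1][j - 1], Iy[i - 1][j - 1]) + s
            Ix[i][j] = max(M[i - 1][j] - first, Ix[i - 1][j] - gap_extend,
                           Iy[i - 1][j] - first)
            Iy[i][j] = max(M[i][j - 1] - first, Iy[i][j - 1] - gap_extend,
                           Ix[i][j - 1] - first)
    return max(M[n][m], Ix[n][m], Iy[n][m])
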