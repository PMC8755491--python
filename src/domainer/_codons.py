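"""Standard-genetic-code codon tables and fast codon encoding.

Everything here is derived once from Biopython's standard code table: the 61
sense codons in alphabetical order, per-codon NG86 site counts, and pairwise
NG86 difference counts averaged over minimal substitution paths.
"""
from __future__ import annotations

from itertools import permutations

import numpy as np
from Bio.Data import CodonTable

_TABLE = CodonTable.unambiguous_dna_by_id[1]

NUCLEOTIDES = "ACGT"
STOP_CODONS = tuple(sorted(_TABLE.stop_codons))
CODONS = tuple(sorted(_TABLE.forward_table))  # 61 sense codons
N_CODONS = len(CODONS)
CODON_INDEX = {c: i for i, c in enumerate(CODONS)}
AMINO_ACIDS = tuple(_TABLE.forward_table[c] for c in CODONS)
CODON_ARRAY = np.array(CODONS)

GAP_CODON = "---"

#: nucleotide values (A=0,C=1,G=2,T=3) of each sense codon's three positions
CODON_NT = np.array([["ACGT".index(c) for c in codon] for codon in CODONS])

_NT_VAL = np.full(256, -1, dtype=np.int8)
for _i, _c in enumerate(NUCLEOTIDES):
    _NT_VAL[ord(_c)] = _i
    _NT_VAL[ord(_c.lower())] = _i

_SENSE_OF_64 = np.full(64, -1, dtype=np.int64)
for _codon, _idx in CODON_INDEX.items():
    _k = 16 * _NT_VAL[ord(_codon[0])] + 4 * _NT_VAL[ord(_codon[1])] + _NT_VAL[ord(_codon[2])]
    _SENSE_OF_64[_k] = _idx


def encode_codons(seq: str) -> np.ndarray:
    """Map a nucleotide string to sense-codon indices, one int per codon.

    Returns values in 0..60 for sense codons and -1 for anything that cannot
    be used in pairwise counting: stop codons, gap codons, and codons with
    ambiguity characters.
    """
    if len(seq) % 3:
        raise ValueError(f"sequence length {len(seq)} is not a multiple of 3")
    raw = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    vals = _NT_VAL[raw].reshape(-1, 3).astype(np.int64)
    ok = (vals >= 0).all(axis=1)
    k = vals[:, 0] * 16 + vals[:, 1] * 4 + vals[:, 2]
    return np.where(ok, _SENSE_OF_64[np.where(ok, k, 0)], -1)


def decode_codons(indices: np.ndarray) -> str:
    return "".join(CODON_ARRAY[np.asarray(indices, dtype=np.int64)])


def translate_codon(codon: str) -> str:
    """Amino acid for a sense codon, '*' for a stop."""
    c = codon.upper()
    if c in _TABLE.forward_table:
        return _TABLE.forward_table[c]
    if c in _TABLE.stop_codons:
        return "*"
    raise ValueError(f"not an unambiguous codon: {codon!r}")


def _is_transition(a: str, b: str) -> bool:
    return {a, b} in ({"A", "G"}, {"C", "T"})


def _single_nt_masks():
    single = np.zeros((N_CODONS, N_CODONS), dtype=bool)
    transition = np.zeros((N_CODONS, N_CODONS), dtype=bool)
    synonymous = np.zeros((N_CODONS, N_CODONS), dtype=bool)
    for i, x in enumerate(CODONS):
        for j, y in enumerate(CODONS):
            diffs = [p for p in range(3) if x[p] != y[p]]
            if len(diffs) != 1:
                continue
            single[i, j] = True
            p = diffs[0]
            transition[i, j] = _is_transition(x[p], y[p])
            synonymous[i, j] = AMINO_ACIDS[i] == AMINO_ACIDS[j]
    return single, transition, synonymous


SINGLE_NT_MASK, TRANSITION_MASK, SYNONYMOUS_MASK = _single_nt_masks()


def _site_counts():
    """NG86 synonymous/nonsynonymous site counts per sense codon.

    Each codon position contributes one site, split by the fraction of
    synonymous changes among its sense (non-stop) single-nucleotide
    neighbours, so syn + nonsyn = 3 for every codon.
    """
    syn = np.zeros(N_CODONS)
    for i, codon in enumerate(CODONS):
        for p in range(3):
            variants = [codon[:p] + n + codon[p + 1:] for n in NUCLEOTIDES if n != codon[p]]
            sense = [v for v in variants if v in CODON_INDEX]
            # at most two of the three variants can be stops, so sense is non-empty
            n_syn = sum(AMINO_ACIDS[CODON_INDEX[v]] == AMINO_ACIDS[i] for v in sense)
            syn[i] += n_syn / len(sense)
    return syn, 3.0 - syn


SYN_SITES, NONSYN_SITES = _site_counts()

_DIFF_TABLES: tuple[np.ndarray, np.ndarray] | None = None


def ng86_diff_tables() -> tuple[np.ndarray, np.ndarray]:
    """(nonsyn, syn) observed-difference counts for every ordered codon pair.

    Counts are averaged with equal weight over the minimal substitution paths
    whose intermediates are all sense codons; if every path is blocked by a
    stop codon, all paths are used with stop-involving steps counted as
    nonsynonymous.
    """
    global _DIFF_TABLES
    if _DIFF_TABLES is not None:
        return _DIFF_TABLES
    nd = np.zeros((N_CODONS, N_CODONS))
    sd = np.zeros((N_CODONS, N_CODONS))
    for i, x in enumerate(CODONS):
        for j, y in enumerate(CODONS):
            if i == j:
                continue
            pos = [p for p in range(3) if x[p] != y[p]]
            paths = []
            for order in permutations(pos):
                chain = [x]
                cur = x
                for p in order:
                    cur = cur[:p] + y[p] + cur[p + 1:]
                    chain.append(cur)
                valid = all(c in CODON_INDEX for c in chain[1:-1])
                syn = sum(
                    1
                    for a, b in zip(chain, chain[1:])
                    if a in CODON_INDEX
                    and b in CODON_INDEX
                    and AMINO_ACIDS[CODON_INDEX[a]] == AMINO_ACIDS[CODON_INDEX[b]]
                )
                paths.append((syn, len(pos) - syn, valid))
            usable = [p for p in paths if p[2]] or paths
            sd[i, j] = sum(p[0] for p in usable) / len(usable)
            nd[i, j] = sum(p[1] for p in usable) / len(usable)
    _DIFF_TABLES = (nd, sd)
    return _DIFF_TABLES
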