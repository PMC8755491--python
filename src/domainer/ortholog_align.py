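"""Ortholog identification and protein-guided codon alignment.

Orthologs are called by reciprocal best hit over exact affine-gap global
alignment scores (BLOSUM62); the protein alignment then guides the
back-translation of the two CDSs into a codon alignment whose gap unit is
the whole codon.
"""
from __future__ import annotations

from dataclasses import dataclass

from Bio import Align
from Bio.Align import substitution_matrices

from ._codons import translate_codon
from .io_formats import SequenceRecord

# 20 standard residues plus the BLOSUM62 ambiguity codes
_ALLOWED_RESIDUES = set("ACDEFGHIKLMNPQRSTVWYBZX")

DEFAULT_GAP_OPEN = 11
DEFAULT_GAP_EXTEND = 1
DEFAULT_MIN_SCORE = 50.0


@dataclass(frozen=True)
class ProteinAlignment:
    """A gap-aligned pair of protein sequences."""

    id_a: str
    id_b: str
    aligned_a: str
    aligned_b: str
    score: float

    def __post_init__(self):
        if len(self.aligned_a) != len(self.aligned_b):
            raise ValueError("aligned rows differ in length")


@dataclass(frozen=True)
class CodonAlignment:
    """A gap-aligned pair of CDS sequences; gaps come in whole codons."""

    id_a: str
    id_b: str
    row_a: str
    row_b: str

    def __post_init__(self):
        if len(self.row_a) != len(self.row_b):
            raise ValueError("codon alignment rows differ in length")
        if len(self.row_a) % 3:
            raise ValueError("codon alignment length not a multiple of 3")

    @property
    def n_columns(self) -> int:
        return len(self.row_a) // 3

    def codon(self, row: str, column: int) -> str:
        return row[3 * column:3 * column + 3]


def select_longest(groups) -> dict:
    """Pick one record per gene: the longest; ties go to the smallest id.

    ``groups`` maps gene -> sequence of SequenceRecord (e.g. transcripts).
    """
    chosen = {}
    for gene, records in groups.items():
        if not records:
            raise ValueError(f"gene {gene!r} has no records")
        chosen[gene] = min(records, key=lambda r: (-len(r.residues), r.identifier))
    return chosen


def make_aligner(gap_open: float = DEFAULT_GAP_OPEN, gap_extend: float = DEFAULT_GAP_EXTEND,
                 matrix: str = "BLOSUM62") -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.substitution_matrix = substitution_matrices.load(matrix)
    # BLAST convention: a gap of length L costs gap_open + L * gap_extend
    aligner.open_gap_score = -(gap_open + gap_extend)
    aligner.extend_gap_score = -gap_extend
    aligner.mode = "global"
    return aligner


def _check_protein(record: SequenceRecord) -> None:
    bad = set(record.residues) - _ALLOWED_RESIDUES
    if bad:
        raise ValueError(f"{record.identifier}: non-amino-acid characters {sorted(bad)}")


def global_align(protein_a: SequenceRecord, protein_b: SequenceRecord,
                 gap_open: float = DEFAULT_GAP_OPEN, gap_extend: float = DEFAULT_GAP_EXTEND,
                 aligner: Align.PairwiseAligner | None = None) -> ProteinAlignment:
    """Optimal affine-gap global (Needleman–Wunsch) alignment under BLOSUM62.

    The first alignment of the deterministic traceback is returned, so equal
    inputs always give equal outputs.
    """
    if not protein_a.residues or not protein_b.residues:
        raise ValueError("cannot align empty sequences")
    _check_protein(protein_a)
    _check_protein(protein_b)
    if aligner is None:
        aligner = make_aligner(gap_open, gap_extend)
    alignments = aligner.align(protein_a.residues, protein_b.residues)
    best = alignments[0]
    return ProteinAlignment(protein_a.identifier, protein_b.identifier,
                            best[0], best[1], float(best.score))


def reciprocal_best_hits(proteome_a, proteome_b,
                         min_score: float = DEFAULT_MIN_SCORE,
                         gap_open: float = DEFAULT_GAP_OPEN,
                         gap_extend: float = DEFAULT_GAP_EXTEND) -> list[tuple[str, str, float]]:
    """Ortholog pairs by reciprocal best hit over all-vs-all alignment scores.

    A pair (x, y) is kept iff y is x's unique best-scoring partner and vice
    versa; score ties for the best partner exclude the pair, as do scores
    below ``min_score``.  Returns (id_a, id_b, score) triples in proteome-A
    order.
    """
    if not proteome_a or not proteome_b:
        raise ValueError("both proteomes must be non-empty")
    for rec in list(proteome_a) + list(proteome_b):
        _check_protein(rec)
    aligner = make_aligner(gap_open, gap_extend)
    scores = [[aligner.score(a.residues, b.residues) for b in proteome_b] for a in proteome_a]

    def unique_argmax(values):
        best = max(values)
        idx = [i for i, v in enumerate(values) if v == best]
        return (idx[0], best) if len(idx) == 1 else (None, best)

    best_in_b = [unique_argmax(row) for row in scores]
    best_in_a = [unique_argmax([scores[i][j] for i in range(len(proteome_a))])
                 for j in range(len(proteome_b))]
    pairs = []
    for i, (j, score) in enumerate(best_in_b):
        if j is None or score < min_score:
            continue
        if best_in_a[j][0] == i:
            pairs.append((proteome_a[i].identifier, proteome_b[j].identifier, float(score)))
    return pairs


def has_internal_stop(cds: str) -> bool:
    return any(cds[i:i + 3].upper() in ("TAA", "TAG", "TGA") for i in range(0, len(cds) - 2, 3))


def backtranslate(protein_alignment: ProteinAlignment, cds_a: str, cds_b: str) -> CodonAlignment:
    """Thread the two CDSs through the protein alignment.

    Residue gaps become the codon gap ``---``; every codon must translate to
    its aligned residue (mismatches are hard errors naming the position).
    """
    rows = []
    for aligned, cds, ident in ((protein_alignment.aligned_a, cds_a, protein_alignment.id_a),
                                (protein_alignment.aligned_b, cds_b, protein_alignment.id_b)):
        ungapped = aligned.replace("-", "")
        if len(cds) != 3 * len(ungapped):
            raise ValueError(
                f"{ident}: CDS length {len(cds)} does not match protein length {len(ungapped)}"
            )
        out = []
        k = 0
        for col, residue in enumerate(aligned):
            if residue == "-":
                out.append("---")
                continue
            codon = cds[3 * k:3 * k + 3]
            aa = translate_codon(codon)
            if residue != "X" and aa != residue:
                raise ValueError(
                    f"{ident}: codon {codon} at residue {k + 1} (alignment column {col + 1}) "
                    f"translates to {aa}, expected {residue}"
                )
            out.append(codon)
            k += 1
        rows.append("".join(out))
    return CodonAlignment(protein_alignment.id_a, protein_alignment.id_b, rows[0], rows[1])
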