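"""Project per-residue membrane topology onto codon-alignment columns.

Each codon column is labelled in both species ('i'ntracellular, 'M'embrane,
'o'utside, or '-' for a gap); columns with concordant labels define the
intracellular / transmembrane / extracellular subalignments on which ω is
estimated separately.
"""
from __future__ import annotations

from dataclasses import dataclass

from .io_formats import TopologySegments
from .ortholog_align import CodonAlignment

GAP_LABEL = "-"
POLICIES = ("concordant", "reference")


@dataclass(frozen=True)
class DomainPartition:
    """Codon-column index sets for the i/t/e domain classes (0-based)."""

    n_columns: int
    cols_i: tuple
    cols_t: tuple
    cols_e: tuple

    def __post_init__(self):
        sets = [set(self.cols_i), set(self.cols_t), set(self.cols_e)]
        if sum(len(s) for s in sets) != len(set().union(*sets)):
            raise ValueError("domain column sets overlap")
        for s in sets:
            if any(c < 0 or c >= self.n_columns for c in s):
                raise ValueError("column index out of range")


@dataclass(frozen=True)
class DomainPresence:
    has_inside: bool
    has_outside: bool
    has_membrane: bool


def project_topology(topology, protein_row: str) -> list[str]:
    """Per-column labels for one gapped protein row.

    ``topology`` is a TopologySegments or its per-residue string.  The k-th
    non-gap column receives the k-th residue's label; gap columns get '-'.
    """
    codes = topology.residue_string() if isinstance(topology, TopologySegments) else topology
    ungapped = len(protein_row) - protein_row.count("-")
    if len(codes) != ungapped:
        raise ValueError(
            f"topology length {len(codes)} != ungapped row length {ungapped}"
        )
    labels = []
    k = 0
    for ch in protein_row:
        if ch == "-":
            labels.append(GAP_LABEL)
        else:
            labels.append(codes[k])
            k += 1
    return labels


def classify_columns(labels_a, labels_b, policy: str = "concordant") -> DomainPartition:
    """Assign codon columns to domain classes from the two label vectors.

    ``concordant`` (default): a column is assigned only when both species
    agree (i/i, M/M or o/o); disagreements and gaps are unassigned.
    ``reference``: species-A's label decides, but columns where either row
    is a gap stay unassigned (so subalignments never contain gap codons).
    """
    if policy not in POLICIES:
        raise ValueError(f"unknown policy {policy!r}; expected one of {POLICIES}")
    if len(labels_a) != len(labels_b):
        raise ValueError("label vectors differ in length")
    cols = {"i": [], "M": [], "o": []}
    for idx, (a, b) in enumerate(zip(labels_a, labels_b)):
        if a == GAP_LABEL or b == GAP_LABEL:
            continue
        if policy == "concordant":
            if a == b and a in cols:
                cols[a].append(idx)
        else:  # reference
            if a in cols:
                cols[a].append(idx)
    return DomainPartition(len(labels_a), tuple(cols["i"]), tuple(cols["M"]), tuple(cols["o"]))


def domain_presence(topology: TopologySegments) -> DomainPresence:
    labels = {label for label, _, _ in topology.segments}
    return DomainPresence("inside" in labels, "outside" in labels, "TMhelix" in labels)


def retain_gene(presence_a: DomainPresence, presence_b: DomainPresence) -> bool:
    """True iff both species have both an inside and an outside domain."""
    return (presence_a.has_inside and presence_a.has_outside
            and presence_b.has_inside and presence_b.has_outside)


def extract_subalignment(alignment: CodonAlignment, column_set) -> CodonAlignment:
    """Concatenate the selected codon columns (ascending) from both rows.

    An empty column set yields an empty alignment; ω is undefined downstream.
    """
    cols = sorted(column_set)
    if cols and (cols[0] < 0 or cols[-1] >= alignment.n_columns):
        raise ValueError("column index outside the alignment")
    row_a = "".join(alignment.row_a[3 * c:3 * c + 3] for c in cols)
    row_b = "".join(alignment.row_b[3 * c:3 * c + 3] for c in cols)
    return CodonAlignment(alignment.id_a, alignment.id_b, row_a, row_b)


def partition_alignment(alignment: CodonAlignment, topology_a, topology_b,
                        policy: str = "concordant") -> tuple[DomainPartition, dict]:
    """Label both rows, classify columns, and extract the three subalignments.

    Protein rows are derived from the codon rows by treating each codon
    column as one residue.  Returns the partition and a dict of
    subalignments keyed 'i', 't', 'e'.
    """
    def protein_row(row: str) -> str:
        return "".join("-" if row[3 * c:3 * c + 3] == "---" else "X"
                       for c in range(len(row) // 3))

    labels_a = project_topology(topology_a, protein_row(alignment.row_a))
    labels_b = project_topology(topology_b, protein_row(alignment.row_b))
    partition = classify_columns(labels_a, labels_b, policy)
    subs = {
        "i": extract_subalignment(alignment, partition.cols_i),
        "t": extract_subalignment(alignment, partition.cols_t),
        "e": extract_subalignment(alignment, partition.cols_e),
    }
    return partition, subs
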