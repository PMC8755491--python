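"""External representations: FASTA, topology TSV, abundance TSV, result TSVs.

Coordinate convention: topology files are 1-based inclusive (the convention
of TMHMM-style segment output); everything internal is 0-based half-open.
"""
from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

TOPOLOGY_LABELS = ("inside", "TMhelix", "outside")
#: single-letter per-residue codes for the three segment labels
LABEL_CODE = {"inside": "i", "TMhelix": "M", "outside": "o"}
CODE_LABEL = {v: k for k, v in LABEL_CODE.items()}

RATES_COLUMNS = [
    "gene", "engine",
    "n_codons_i", "dN_i", "dS_i", "omega_i", "valid_i",
    "n_codons_t", "dN_t", "dS_t", "omega_t", "valid_t",
    "n_codons_e", "dN_e", "dS_e", "omega_e", "valid_e",
]
TESTS_COLUMNS = ["comparison", "rho_1", "n_1", "rho_2", "n_2", "Z", "p_one", "p_two"]


@dataclass(frozen=True)
class SequenceRecord:
    """One FASTA record: a unique identifier plus residues."""

    identifier: str
    residues: str

    def __post_init__(self):
        if not self.identifier or any(ch.isspace() for ch in self.identifier):
            raise ValueError(f"invalid identifier: {self.identifier!r}")

    def __len__(self) -> int:
        return len(self.residues)


@dataclass(frozen=True)
class TopologySegments:
    """Membrane topology of one protein as contiguous labelled segments.

    Segments are (label, start, end) with 1-based inclusive coordinates,
    contiguous from 1 and covering the protein exactly.
    """

    identifier: str
    segments: tuple = field(default_factory=tuple)

    def __post_init__(self):
        if not self.segments:
            raise ValueError(f"{self.identifier}: no segments")
        expected_start = 1
        for label, start, end in self.segments:
            if label not in TOPOLOGY_LABELS:
                raise ValueError(f"{self.identifier}: unknown topology label {label!r}")
            if start != expected_start:
                raise ValueError(
                    f"{self.identifier}: segment starts at {start}, expected {expected_start} "
                    "(segments must be contiguous from position 1)"
                )
            if end < start:
                raise ValueError(f"{self.identifier}: segment end {end} < start {start}")
            expected_start = end + 1

    def __len__(self) -> int:
        return self.segments[-1][2]

    def residue_string(self) -> str:
        """Per-residue expansion, e.g. 'iiiMMMooo'."""
        return "".join(LABEL_CODE[label] * (end - start + 1) for label, start, end in self.segments)

    @classmethod
    def from_residue_string(cls, identifier: str, codes: str) -> "TopologySegments":
        if not codes:
            raise ValueError(f"{identifier}: empty topology string")
        bad = set(codes) - set(CODE_LABEL)
        if bad:
            raise ValueError(f"{identifier}: unknown topology codes {sorted(bad)}")
        segments = []
        start = 0
        for pos in range(1, len(codes) + 1):
            if pos == len(codes) or codes[pos] != codes[start]:
                segments.append((CODE_LABEL[codes[start]], start + 1, pos))
                start = pos
        return cls(identifier, tuple(segments))


def read_fasta(path) -> list[SequenceRecord]:
    """Read a FASTA file into records, preserving file order.

    Sequences are uppercased; ambiguity characters are preserved.  Duplicate
    identifiers and empty files are hard errors.
    """
    records = []
    seen = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise ValueError(f"{path}: duplicate identifier {rec.id!r}")
        seen.add(rec.id)
        records.append(SequenceRecord(rec.id, str(rec.seq).upper()))
    if not records:
        raise ValueError(f"{path}: no FASTA records found")
    return records


def write_fasta(records, path, width: int = 60) -> None:
    seqs = [SeqRecord(Seq(r.residues), id=r.identifier, description="") for r in records]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(seqs)


def trim_terminal_stop(cds: str) -> str:
    """Drop a trailing stop codon if present (Ensembl CDSs carry one)."""
    if len(cds) >= 3 and len(cds) % 3 == 0 and cds[-3:].upper() in ("TAA", "TAG", "TGA"):
        return cds[:-3]
    return cds


def read_topology(path) -> list[TopologySegments]:
    """Read topology annotations.

    Two dialects are accepted, detected per line:

    * 4 columns ``id<TAB>label<TAB>start<TAB>end`` with labels in
      {inside, TMhelix, outside} and 1-based inclusive coordinates;
    * 2 columns ``id<TAB>codes`` with a per-residue string over {i, M, o}.

    Segments are grouped per identifier and must tile the protein without
    gaps or overlaps.
    """
    rows: dict[str, list] = {}
    strings: dict[str, str] = {}
    order: list[str] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) == 2:
                ident, codes = parts
                if ident in strings or ident in rows:
                    raise ValueError(f"{path}:{lineno}: duplicate topology for {ident!r}")
                strings[ident] = codes
                order.append(ident)
            elif len(parts) == 4:
                ident, label, start, end = parts
                if ident in strings:
                    raise ValueError(f"{path}:{lineno}: mixed dialects for {ident!r}")
                if label not in TOPOLOGY_LABELS:
                    raise ValueError(f"{path}:{lineno}: unknown label {label!r}")
                if ident not in rows:
                    rows[ident] = []
                    order.append(ident)
                rows[ident].append((label, int(start), int(end)))
            else:
                raise ValueError(f"{path}:{lineno}: expected 2 or 4 tab-separated fields")
    out = []
    for ident in order:
        if ident in strings:
            out.append(TopologySegments.from_residue_string(ident, strings[ident]))
        else:
            segs = sorted(rows[ident], key=lambda s: s[1])
            out.append(TopologySegments(ident, tuple(segs)))  # contiguity checked there
    if not out:
        raise ValueError(f"{path}: no topology records found")
    return out


def write_topology(annotations, path) -> None:
    with open(path, "w") as fh:
        for ann in annotations:
            for label, start, end in ann.segments:
                fh.write(f"{ann.identifier}\t{label}\t{start}\t{end}\n")


def read_abundance(path) -> pd.DataFrame:
    """Read a wide abundance TSV (gene column + one column per context).

    Returns a long-form frame with columns (gene, context, abundance).
    Missing cells are dropped, not zero-filled; negative abundances and
    duplicate (gene, context) pairs are hard errors.
    """
    wide = pd.read_csv(path, sep="\t", dtype={0: str})
    gene_col = wide.columns[0]
    if wide[gene_col].duplicated().any():
        dup = wide.loc[wide[gene_col].duplicated(), gene_col].iloc[0]
        raise ValueError(f"{path}: duplicate gene row {dup!r}")
    long = wide.melt(id_vars=[gene_col], var_name="context", value_name="abundance")
    long = long.rename(columns={gene_col: "gene"}).dropna(subset=["abundance"])
    if (long["abundance"] < 0).any():
        bad = long.loc[long["abundance"] < 0].iloc[0]
        raise ValueError(f"{path}: negative abundance for gene {bad['gene']!r} in {bad['context']!r}")
    if long.duplicated(subset=["gene", "context"]).any():
        raise ValueError(f"{path}: duplicate (gene, context) pair")
    return long.reset_index(drop=True)


def _fmt(value) -> str:
    """6-significant-digit float formatting with NA for missing."""
    if value is None or (isinstance(value, float) and value != value):
        return "NA"
    if isinstance(value, bool):
        return str(value)
    if isinstance(value, float):
        return f"{value:.6g}"
    return str(value)


def write_rates(rates: pd.DataFrame, path) -> None:
    """Write the per-gene rates table (RATES_COLUMNS order, 6 sig. digits, NA)."""
    with open(path, "w") as fh:
        fh.write("\t".join(RATES_COLUMNS) + "\n")
        for _, row in rates.iterrows():
            fh.write("\t".join(_fmt(row.get(col)) for col in RATES_COLUMNS) + "\n")


def write_tests(tests, path) -> None:
    """Write the per-comparison tests table (TESTS_COLUMNS order)."""
    with open(path, "w") as fh:
        fh.write("\t".join(TESTS_COLUMNS) + "\n")
        for t in tests:
            vals = [t.label, t.rho_1, t.n_1, t.rho_2, t.n_2, t.z, t.p_one_tailed, t.p_two_tailed]
            fh.write("\t".join(_fmt(v) for v in vals) + "\n")


def write_results(rates: pd.DataFrame, tests, rates_path, tests_path) -> None:
    """Write both output tables: per-gene rates and per-comparison tests.

    Floats are written at 6 significant digits, missing values as the
    literal ``NA``.  Empty inputs yield header-only files.
    """
    write_rates(rates, rates_path)
    write_tests(tests, tests_path)


def read_rates(path) -> pd.DataFrame:
    frame = pd.read_csv(path, sep="\t", na_values=["NA"])
    for col in [c for c in frame.columns if c.startswith("valid_")]:
        frame[col] = frame[col].astype(str).str.lower() == "true"
    return frame


def fasta_string(records) -> str:
    buf = io.StringIO()
    for r in records:
        buf.write(f">{r.identifier}\n")
        for i in range(0, len(r.residues), 60):
            buf.write(r.residues[i:i + 60] + "\n")
    return buf.getvalue()


def ensure_dir(path) -> Path:
    p = Path(path)
    p.mkdir(parents=True, exist_ok=True)
    return p
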