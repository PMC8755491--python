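"""End-to-end orchestration: simulate → align → partition → dnds → correlate.

A run is a directory of stage outputs plus a manifest recording, per stage,
the parameter/input hashes, output files, and row counts.  Re-running with
an unchanged config reuses up-to-date stages; a stage whose inputs,
parameters or outputs changed re-executes, and everything downstream of it
re-executes too.  Gene attrition (internal stops, the both-domains-in-both-
species retention rule, dS = 0, missing abundance) is logged per stage so
sample sizes stay auditable.
"""
from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import er_stats
from .domain_dnds import DOMAINS, apply_ds_filter, estimate_gene, rates_frame
from .io_formats import (
    SequenceRecord,
    ensure_dir,
    read_abundance,
    read_fasta,
    read_topology,
    trim_terminal_stop,
    write_fasta,
    write_rates,
    write_tests,
)
from .ortholog_align import (
    CodonAlignment,
    backtranslate,
    global_align,
    has_internal_stop,
    make_aligner,
    reciprocal_best_hits,
    select_longest,
)
from .synthetic_data import SimulationConfig, sample_cohort
from .topology_partition import domain_presence, partition_alignment, retain_gene

log = logging.getLogger("domainer")

STAGES = ("simulate", "align", "partition", "dnds", "correlate")

_ENUMS = {
    "mode": ("synthetic", "real"),
    "engine": ("ng86", "m0"),
    "freqs": ("f3x4", "uniform"),
    "ds_filter": ("per-domain", "whole-gene"),
    "pairing": ("by-id", "rbh"),
    "policy": ("concordant", "reference"),
}
_REAL_INPUT_KEYS = ("protein_a", "protein_b", "cds_a", "cds_b",
                    "topology_a", "topology_b", "abundance")


@dataclass
class RunConfig:
    """Validated configuration for one pipeline run."""

    mode: str = "synthetic"
    outdir: str = "run"
    seed: int = 0
    engine: str = "ng86"
    freqs: str = "f3x4"
    ds_filter: str = "per-domain"
    pairing: str = "by-id"
    policy: str = "concordant"
    overlap_correction: bool = False
    min_score: float = 50.0
    log_level: str = "INFO"
    simulate: SimulationConfig | None = None
    inputs: dict = field(default_factory=dict)


def validate_config(path) -> tuple[RunConfig | None, list[str]]:
    """Load and validate a YAML config, reporting every problem at once."""
    problems: list[str] = []
    try:
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
    except (OSError, yaml.YAMLError) as exc:
        return None, [f"cannot read config {path}: {exc}"]
    if not isinstance(raw, dict):
        return None, [f"config {path} must be a mapping"]

    known = {f.name for f in dataclasses.fields(RunConfig)}
    for key in raw:
        if key not in known:
            problems.append(f"unknown key {key!r}")
    for key, allowed in _ENUMS.items():
        value = raw.get(key)
        if value is not None and value not in allowed:
            problems.append(f"{key}: {value!r} not one of {allowed}")

    sim_cfg = None
    mode = raw.get("mode", "synthetic")
    if mode == "synthetic":
        sim_raw = raw.get("simulate") or {}
        sim_fields = {f.name for f in dataclasses.fields(SimulationConfig)}
        for key in sim_raw:
            if key not in sim_fields:
                problems.append(f"simulate.{key}: unknown key")
        if not problems:
            try:
                sim_raw = dict(sim_raw)
                if "domain_architecture" in sim_raw:
                    sim_raw["domain_architecture"] = tuple(
                        (label, int(length)) for label, length in sim_raw["domain_architecture"]
                    )
                sim_raw.setdefault("seed", int(raw.get("seed", 0)))
                sim_cfg = SimulationConfig(**sim_raw)
            except (TypeError, ValueError) as exc:
                problems.append(f"simulate: {exc}")
    elif mode == "real":
        inputs = raw.get("inputs") or {}
        for key in _REAL_INPUT_KEYS:
            if key not in inputs:
                problems.append(f"inputs.{key}: missing")
            elif not Path(inputs[key]).exists():
                problems.append(f"inputs.{key}: no such file {inputs[key]}")

    if problems:
        return None, problems
    cfg = RunConfig(
        mode=mode,
        outdir=str(raw.get("outdir", "run")),
        seed=int(raw.get("seed", 0)),
        engine=raw.get("engine", "ng86"),
        freqs=raw.get("freqs", "f3x4"),
        ds_filter=raw.get("ds_filter", "per-domain"),
        pairing=raw.get("pairing", "by-id" if mode == "synthetic" else "rbh"),
        policy=raw.get("policy", "concordant"),
        overlap_correction=bool(raw.get("overlap_correction", False)),
        min_score=float(raw.get("min_score", 50.0)),
        log_level=str(raw.get("log_level", "INFO")),
        simulate=sim_cfg,
        inputs=dict(raw.get("inputs") or {}),
    )
    return cfg, []


def _hash(*parts) -> str:
    h = hashlib.sha256()
    for part in parts:
        if isinstance(part, Path):
            h.update(part.read_bytes())
        else:
            h.update(str(part).encode())
        h.update(b"\x00")
    return h.hexdigest()


class _Manifest:
    def __init__(self, path: Path):
        self.path = path
        self.data = {}
        if path.exists():
            self.data = json.loads(path.read_text())

    def up_to_date(self, stage: str, key: str, outputs) -> bool:
        entry = self.data.get(stage)
        return (entry is not None and entry.get("key") == key
                and all(Path(p).exists() for p in outputs))

    def record(self, stage: str, key: str, outputs, rows: dict, ran: bool) -> None:
        self.data[stage] = {"key": key, "outputs": [str(p) for p in outputs],
                            "rows": rows, "ran": ran}
        self.path.write_text(json.dumps(self.data, indent=2, sort_keys=True))


def _gene_of(identifier: str) -> str:
    """Transcripts of one gene share the id up to the first '.'."""
    return identifier.split(".")[0]


def _grouped(records) -> dict:
    groups: dict[str, list] = {}
    for rec in records:
        groups.setdefault(_gene_of(rec.identifier), []).append(rec)
    return groups


def _fmt(value) -> str:
    if isinstance(value, float):
        return "NA" if value != value else f"{value:.6g}"
    return str(value)


def run_pipeline(config: RunConfig) -> Path:
    """Execute all stages under config.outdir; returns the run directory."""
    run_dir = ensure_dir(config.outdir)
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO),
                        format="%(levelname)s %(name)s: %(message)s")
    manifest = _Manifest(run_dir / "manifest.json")
    upstream_ran = False

    # ---- simulate -------------------------------------------------------
    inputs_dir = run_dir / "inputs"
    if config.mode == "synthetic":
        sim = config.simulate or SimulationConfig(seed=config.seed)
        key = _hash("simulate", sim)
        outputs = [inputs_dir / name for name in (
            "species_a.cds.fa", "species_b.cds.fa", "species_a.protein.fa",
            "species_b.protein.fa", "species_a.topology.tsv",
            "species_b.topology.tsv", "abundance.tsv", "truth.tsv")]
        if manifest.up_to_date("simulate", key, outputs):
            log.info("simulate: up to date")
        else:
            log.info("simulate: %d genes, seed %d", sim.n_genes, sim.seed)
            cohort = sample_cohort(sim)
            cohort.write(inputs_dir)
            upstream_ran = True
        manifest.record("simulate", key, outputs,
                        {"n_genes": sim.n_genes}, upstream_ran)
        paths = {
            "protein_a": inputs_dir / "species_a.protein.fa",
            "protein_b": inputs_dir / "species_b.protein.fa",
            "cds_a": inputs_dir / "species_a.cds.fa",
            "cds_b": inputs_dir / "species_b.cds.fa",
            "topology_a": inputs_dir / "species_a.topology.tsv",
            "topology_b": inputs_dir / "species_b.topology.tsv",
            "abundance": inputs_dir / "abundance.tsv",
        }
    else:
        paths = {k: Path(v) for k, v in config.inputs.items()}

    # ---- align ----------------------------------------------------------
    align_dir = run_dir / "alignments"
    orthologs_tsv = run_dir / "orthologs.tsv"
    key = _hash("align", config.pairing, config.min_score,
                *(paths[k] for k in ("protein_a", "protein_b", "cds_a", "cds_b")))
    stage_ran = False
    if not upstream_ran and manifest.up_to_date("align", key, [orthologs_tsv]):
        log.info("align: up to date")
        pairs_frame = pd.read_csv(orthologs_tsv, sep="\t")
    else:
        stage_ran = True
        pairs_frame = _run_align(config, paths, align_dir, orthologs_tsv)
    manifest.record("align", key, [orthologs_tsv], {"genes_aligned": len(pairs_frame)},
                    stage_ran)
    upstream_ran = upstream_ran or stage_ran

    # ---- partition ------------------------------------------------------
    sub_dir = run_dir / "subalignments"
    report_tsv = run_dir / "partition_report.tsv"
    key = _hash("partition", config.policy, orthologs_tsv,
                paths["topology_a"], paths["topology_b"])
    stage_ran = False
    if not upstream_ran and manifest.up_to_date("partition", key, [report_tsv]):
        log.info("partition: up to date")
        report = pd.read_csv(report_tsv, sep="\t")
    else:
        stage_ran = True
        report = _run_partition(config, paths, pairs_frame, align_dir, sub_dir, report_tsv)
    n_retained = int(report["retained"].sum())
    manifest.record("partition", key, [report_tsv],
                    {"genes_aligned": len(report), "genes_after_retention": n_retained},
                    stage_ran)
    upstream_ran = upstream_ran or stage_ran

    # ---- dnds -----------------------------------------------------------
    rates_tsv = run_dir / "rates.tsv"
    key = _hash("dnds", config.engine, config.freqs, config.ds_filter, report_tsv)
    stage_ran = False
    if not upstream_ran and manifest.up_to_date("dnds", key, [rates_tsv]):
        log.info("dnds: up to date")
        from .io_formats import read_rates
        rates = read_rates(rates_tsv)
    else:
        stage_ran = True
        rates = _run_dnds(config, report, sub_dir, rates_tsv)
    rows = {"genes_rated": len(rates)}
    for d in DOMAINS:
        rows[f"genes_after_dS_filter_{d}"] = int(rates[f"valid_{d}"].sum())
    manifest.record("dnds", key, [rates_tsv], rows, stage_ran)
    upstream_ran = upstream_ran or stage_ran

    # ---- correlate ------------------------------------------------------
    tests_tsv = run_dir / "tests.tsv"
    summary_tsv = run_dir / "summary.tsv"
    sweep_tsv = run_dir / "sweep.tsv"
    key = _hash("correlate", config.overlap_correction, rates_tsv, paths["abundance"])
    stage_ran = False
    if not upstream_ran and manifest.up_to_date("correlate", key, [tests_tsv, summary_tsv]):
        log.info("correlate: up to date")
        rows = manifest.data["correlate"]["rows"]
    else:
        stage_ran = True
        rows = _run_correlate(config, rates, paths["abundance"], rates_tsv,
                              tests_tsv, summary_tsv, sweep_tsv)
    manifest.record("correlate", key, [tests_tsv, summary_tsv], rows, stage_ran)
    return run_dir


def analyze_cohort(cohort, engine: str = "ng86", freqs: str = "f3x4",
                   policy: str = "concordant", ds_filter: str = "per-domain"):
    """In-memory analysis of a synthetic cohort: partition, estimate, filter.

    Synthetic pairs are indel-free and column-aligned by construction, so the
    codon alignment is the pair itself; each gene is partitioned by its two
    topologies and rated per domain.  Returns (rates frame, abundance Series).
    """
    gene_rates = []
    abundance = {}
    for gene in cohort.genes:
        alignment = CodonAlignment(gene.gene_id, gene.gene_id, gene.cds_a, gene.cds_b)
        pres_a = domain_presence(gene.topology_a)
        pres_b = domain_presence(gene.topology_b)
        if not retain_gene(pres_a, pres_b):
            continue
        _, subs = partition_alignment(alignment, gene.topology_a, gene.topology_b,
                                      policy=policy)
        gene_rates.append(estimate_gene(gene.gene_id, subs, engine=engine, freqs=freqs))
        abundance[gene.gene_id] = gene.abundance
    rates = apply_ds_filter(rates_frame(gene_rates), scope=ds_filter)
    return rates, pd.Series(abundance, name="abundance")


def _run_align(config: RunConfig, paths: dict, align_dir: Path,
               orthologs_tsv: Path) -> pd.DataFrame:
    proteins_a = select_longest(_grouped(read_fasta(paths["protein_a"])))
    proteins_b = select_longest(_grouped(read_fasta(paths["protein_b"])))
    cds_a = {_gene_of(r.identifier): r for r in read_fasta(paths["cds_a"])}
    cds_b = {_gene_of(r.identifier): r for r in read_fasta(paths["cds_b"])}

    if config.pairing == "by-id":
        shared = sorted(set(proteins_a) & set(proteins_b))
        pairs = [(g, g, float("nan")) for g in shared]
    else:
        ids_a = sorted(proteins_a)
        ids_b = sorted(proteins_b)
        rbh = reciprocal_best_hits([proteins_a[g] for g in ids_a],
                                   [proteins_b[g] for g in ids_b],
                                   min_score=config.min_score)
        pairs = [(_gene_of(a), _gene_of(b), score) for a, b, score in rbh]

    ensure_dir(align_dir)
    aligner = make_aligner()
    rows = []
    n_dropped = 0
    for gene_a, gene_b, score in pairs:
        rec_a, rec_b = proteins_a[gene_a], proteins_b[gene_b]
        seq_a = trim_terminal_stop(cds_a[gene_a].residues)
        seq_b = trim_terminal_stop(cds_b[gene_b].residues)
        if has_internal_stop(seq_a) or has_internal_stop(seq_b):
            log.warning("align: dropping %s/%s (internal stop codon)", gene_a, gene_b)
            n_dropped += 1
            continue
        prot_aln = global_align(rec_a, rec_b, aligner=aligner)
        codon_aln = backtranslate(prot_aln, seq_a, seq_b)
        write_fasta([SequenceRecord(f"{gene_a}|a", codon_aln.row_a),
                     SequenceRecord(f"{gene_b}|b", codon_aln.row_b)],
                    align_dir / f"{gene_a}.fa")
        rows.append({"gene": gene_a, "id_a": rec_a.identifier, "id_b": rec_b.identifier,
                     "score": prot_aln.score if config.pairing == "rbh" else score})
    log.info("align: %d pairs aligned, %d dropped (internal stops)", len(rows), n_dropped)
    frame = pd.DataFrame(rows, columns=["gene", "id_a", "id_b", "score"])
    frame.to_csv(orthologs_tsv, sep="\t", index=False, float_format="%.6g")
    return frame


def _run_partition(config: RunConfig, paths: dict, pairs_frame: pd.DataFrame,
                   align_dir: Path, sub_dir: Path, report_tsv: Path) -> pd.DataFrame:
    topo_a = {_gene_of(t.identifier): t for t in read_topology(paths["topology_a"])}
    topo_b = {_gene_of(t.identifier): t for t in read_topology(paths["topology_b"])}
    ensure_dir(sub_dir)
    rows = []
    for _, pair in pairs_frame.iterrows():
        gene = pair["gene"]
        gene_b = _gene_of(pair["id_b"])
        if gene not in topo_a or gene_b not in topo_b:
            log.warning("partition: no topology for %s, skipped", gene)
            continue
        recs = read_fasta(align_dir / f"{gene}.fa")
        alignment = CodonAlignment(gene, gene_b, recs[0].residues, recs[1].residues)
        pres_a = domain_presence(topo_a[gene])
        pres_b = domain_presence(topo_b[gene_b])
        retained = retain_gene(pres_a, pres_b)
        row = {"gene": gene,
               "has_inside_a": pres_a.has_inside, "has_outside_a": pres_a.has_outside,
               "has_inside_b": pres_b.has_inside, "has_outside_b": pres_b.has_outside,
               "retained": retained, "n_cols_i": 0, "n_cols_t": 0, "n_cols_e": 0}
        if retained:
            _, subs = partition_alignment(alignment, topo_a[gene], topo_b[gene_b],
                                          policy=config.policy)
            for d, sub in subs.items():
                row[f"n_cols_{d}"] = sub.n_columns
                if sub.n_columns:
                    write_fasta([SequenceRecord(f"{gene}|a", sub.row_a),
                                 SequenceRecord(f"{gene_b}|b", sub.row_b)],
                                sub_dir / f"{gene}.{d}.fa")
        rows.append(row)
    report = pd.DataFrame(rows)
    log.info("partition: %d/%d genes retained (both domain kinds in both species)",
             int(report["retained"].sum()), len(report))
    report.to_csv(report_tsv, sep="\t", index=False)
    return report


def _run_dnds(config: RunConfig, report: pd.DataFrame, sub_dir: Path,
              rates_tsv: Path) -> pd.DataFrame:
    gene_rates = []
    for _, row in report[report["retained"]].iterrows():
        gene = row["gene"]
        subs = {}
        for d in DOMAINS:
            path = sub_dir / f"{gene}.{d}.fa"
            if row[f"n_cols_{d}"] and path.exists():
                recs = read_fasta(path)
                subs[d] = CodonAlignment(gene, gene, recs[0].residues, recs[1].residues)
        gene_rates.append(estimate_gene(gene, subs, engine=config.engine,
                                        freqs=config.freqs))
    rates = apply_ds_filter(rates_frame(gene_rates), scope=config.ds_filter)
    for d in DOMAINS:
        n_zero = int((~rates[f"valid_{d}"]).sum())
        log.info("dnds: domain %s: %d/%d genes valid after dS filter (%d dropped)",
                 d, int(rates[f"valid_{d}"].sum()), len(rates), n_zero)
    write_rates(rates, rates_tsv)
    return rates


def _run_correlate(config: RunConfig, rates: pd.DataFrame, abundance_path,
                   rates_tsv: Path, tests_tsv: Path, summary_tsv: Path,
                   sweep_tsv: Path) -> dict:
    table = read_abundance(abundance_path)
    contexts = sorted(table["context"].unique())
    if "integrated" in contexts:
        integrated = table[table["context"] == "integrated"].set_index("gene")["abundance"]
    else:
        integrated = er_stats.average_across_tissues(table)
    corr, tests = er_stats.compare_er(rates, integrated, context="integrated",
                                      overlap_correction=config.overlap_correction)
    ordering = er_stats.ordering_fractions(rates)
    terciles = er_stats.abundance_terciles(rates, integrated)

    write_tests(tests, tests_tsv)

    tissues = [c for c in contexts if c != "integrated"]
    sweep = summary_sweep = None
    if len(tissues) >= 2:
        sweep, summary_sweep = er_stats.tissue_sweep(
            rates, table[table["context"] != "integrated"])
        sweep.to_csv(sweep_tsv, sep="\t", index=False, float_format="%.6g")

    with open(summary_tsv, "w") as fh:
        fh.write("section\tlabel\tstatistic\tn\tp_value\n")
        for d in DOMAINS:
            c = corr[d]
            fh.write(f"correlation\t{c.label}\t{_fmt(c.rho)}\t{c.n}\t{_fmt(c.p_two_tailed)}\n")
        for t in tests:
            fh.write(f"fisher\t{t.label}\t{_fmt(t.z)}\t{t.n_1};{t.n_2}\t{_fmt(t.p_one_tailed)}\n")
        for name, oc in ordering.items():
            fh.write(f"ordering\t{oc.label}\t{oc.k_success}/{oc.n_trials}\t{oc.n_trials}\t{_fmt(oc.p_value)}\n")
        for _, row in terciles.iterrows():
            fh.write(f"tercile\tpct omega_e > omega_i ({row['bin']})\t"
                     f"{_fmt(float(row['pct_e_gt_i']))}\t{int(row['n'])}\tNA\n")
        if summary_sweep is not None:
            fh.write(f"sweep\t{summary_sweep.label}\t"
                     f"{summary_sweep.k_success}/{summary_sweep.n_trials}\t"
                     f"{summary_sweep.n_trials}\t{_fmt(summary_sweep.p_value)}\n")
    rows = {f"genes_in_correlation_{d}": corr[d].n for d in DOMAINS}
    log.info("correlate: rho_i=%.4g rho_t=%.4g rho_e=%.4g (n=%d)",
             corr["i"].rho, corr["t"].rho, corr["e"].rho, corr["i"].n)
    return rows
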