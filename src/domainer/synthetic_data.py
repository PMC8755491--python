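"""Synthetic ortholog cohorts with known per-domain ω and abundances.

Each gene carries a membrane-topology architecture (inside / TMhelix /
outside segments), gene-specific per-domain ω drawn log-normally around the
configured targets, and an abundance whose rank correlation with ω_i and
ω_e is controlled through a Gaussian copula.  Codon pairs are then evolved
forward under the GY94 generator with the gene's domain-specific ω, split
symmetrically over the two lineages (t/2 each), with no indels.

The defaults define the study conditions: a single-pass-receptor-like
architecture (inside 120 aa, TM helix 21 aa, outside 150 aa), human–mouse
scale divergence (t = 0.5 substitutions per codon), κ = 2, strong purifying
selection with the transmembrane region most constrained
(ω_i = 0.15, ω_t = 0.10, ω_e = 0.25), and PaxDB-like abundances spanning
orders of magnitude (log10 ppm ~ Normal(1.5, 1.0)).
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from ._codons import CODON_ARRAY, N_CODONS
from .codon_models import _check_frequencies, _expm_reversible, build_m0_generator
from .io_formats import (
    SequenceRecord,
    TopologySegments,
    ensure_dir,
    write_fasta,
    write_topology,
)

DEFAULT_ARCHITECTURE = (("inside", 120), ("TMhelix", 21), ("outside", 150))

_DOMAIN_OF_LABEL = {"inside": "i", "TMhelix": "t", "outside": "e"}


@dataclass
class SimulationConfig:
    """Conditions for one synthetic cohort.

    target_rho_i / target_rho_e are the desired Spearman correlations
    between log-abundance and the gene-level true ω of the corresponding
    domain class; omega_sigma is the lognormal spread of gene-level ω
    around each domain's target.
    """

    n_genes: int = 500
    domain_architecture: tuple = DEFAULT_ARCHITECTURE
    kappa: float = 2.0
    t: float = 0.5  # total divergence, substitutions per codon, both lineages
    omega_i: float = 0.15
    omega_t: float = 0.10
    omega_e: float = 0.25
    omega_sigma: float = 0.5
    target_rho_i: float = 0.0
    target_rho_e: float = 0.0
    log10_abundance_mean: float = 1.5
    log10_abundance_sigma: float = 1.0
    n_tissues: int = 1
    tissue_sigma: float = 0.3
    discordant_fraction: float = 0.0
    codon_frequencies: object = None  # None -> uniform over the 61 sense codons
    seed: int = 0

    def __post_init__(self):
        if self.n_genes < 1:
            raise ValueError("n_genes must be positive")
        if self.kappa <= 0:
            raise ValueError("kappa must be > 0")
        if self.t < 0:
            raise ValueError("t must be >= 0")
        for name in ("omega_i", "omega_t", "omega_e"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        labels = [label for label, _ in self.domain_architecture]
        lengths = [length for _, length in self.domain_architecture]
        if "inside" not in labels or "outside" not in labels:
            raise ValueError("architecture must contain at least one inside and one outside segment")
        if any(l < 1 for l in lengths):
            raise ValueError("segment lengths must be >= 1")
        for rho in (self.target_rho_i, self.target_rho_e):
            if not -1.0 <= rho <= 1.0:
                raise ValueError(f"target rho {rho} outside [-1, 1]")
            if abs(rho) == 1.0 and self.omega_sigma > 0:
                raise ValueError(
                    "|target rho| = 1 is unattainable with nondegenerate omega noise"
                )
        if not 0.0 <= self.discordant_fraction <= 1.0:
            raise ValueError("discordant_fraction must be in [0, 1]")


@dataclass
class SyntheticGene:
    gene_id: str
    cds_a: str
    cds_b: str
    topology_a: TopologySegments
    topology_b: TopologySegments
    true_omega: dict
    abundance: float
    tissue_abundance: dict = field(default_factory=dict)


@dataclass
class SyntheticCohort:
    config: SimulationConfig
    genes: list

    def truth_frame(self) -> pd.DataFrame:
        rows = [
            {
                "gene": g.gene_id,
                "omega_i": g.true_omega["i"],
                "omega_t": g.true_omega["t"],
                "omega_e": g.true_omega["e"],
                "abundance": g.abundance,
            }
            for g in self.genes
        ]
        return pd.DataFrame(rows)

    def write(self, outdir) -> dict:
        """Write FASTA pairs, topology TSVs, abundance TSV and truth TSV."""
        from Bio.Seq import Seq

        out = ensure_dir(outdir)
        paths = {
            "cds_a": out / "species_a.cds.fa",
            "cds_b": out / "species_b.cds.fa",
            "protein_a": out / "species_a.protein.fa",
            "protein_b": out / "species_b.protein.fa",
            "topology_a": out / "species_a.topology.tsv",
            "topology_b": out / "species_b.topology.tsv",
            "abundance": out / "abundance.tsv",
            "truth": out / "truth.tsv",
        }
        write_fasta([SequenceRecord(g.gene_id, g.cds_a) for g in self.genes], paths["cds_a"])
        write_fasta([SequenceRecord(g.gene_id, g.cds_b) for g in self.genes], paths["cds_b"])
        write_fasta(
            [SequenceRecord(g.gene_id, str(Seq(g.cds_a).translate())) for g in self.genes],
            paths["protein_a"],
        )
        write_fasta(
            [SequenceRecord(g.gene_id, str(Seq(g.cds_b).translate())) for g in self.genes],
            paths["protein_b"],
        )
        write_topology([g.topology_a for g in self.genes], paths["topology_a"])
        write_topology([g.topology_b for g in self.genes], paths["topology_b"])
        tissues = sorted(self.genes[0].tissue_abundance) if self.genes else []
        with open(paths["abundance"], "w") as fh:
            fh.write("\t".join(["gene", "integrated"] + tissues) + "\n")
            for g in self.genes:
                vals = [f"{g.abundance:.6g}"] + [f"{g.tissue_abundance[t]:.6g}" for t in tissues]
                fh.write("\t".join([g.gene_id] + vals) + "\n")
        self.truth_frame().to_csv(paths["truth"], sep="\t", index=False, float_format="%.6g")
        return {k: str(v) for k, v in paths.items()}


def spearman_to_pearson(rho_s: float) -> float:
    """Gaussian-copula latent correlation giving Spearman rho_s: r = 2 sin(π ρ_s / 6)."""
    return 2.0 * math.sin(math.pi * rho_s / 6.0)


def build_m0_generator_scaled(kappa, omega, codon_frequencies=None):
    """Alias kept close to the estimator: the shared GY94 generator."""
    return build_m0_generator(kappa, omega, codon_frequencies)


def evolve_pair(ancestral_codons: np.ndarray, generator: np.ndarray, t: float,
                rng: np.random.Generator,
                stationary_frequencies=None) -> tuple[np.ndarray, np.ndarray]:
    """Evolve both lineages independently for t/2 from a common ancestor.

    ``ancestral_codons`` are sense-codon indices; returns the two descendant
    index arrays.  Sites evolve independently via exp(Q·t/2); no indels.
    Passing the generator's stationary frequencies skips recovering them
    from the matrix.
    """
    if t < 0:
        raise ValueError("t must be >= 0")
    anc = np.asarray(ancestral_codons, dtype=np.int64)
    if t == 0:
        return anc.copy(), anc.copy()
    pi = (np.asarray(stationary_frequencies, dtype=float)
          if stationary_frequencies is not None
          else _stationary_from_generator(generator))
    P = _expm_reversible(generator, pi, t / 2.0)
    cum = np.cumsum(P, axis=1)
    children = []
    for _ in range(2):
        u = rng.random(anc.size)
        rows = cum[anc]
        child = (rows < u[:, np.newaxis]).sum(axis=1)
        children.append(np.minimum(child, N_CODONS - 1))
    return children[0], children[1]


def _stationary_from_generator(Q: np.ndarray) -> np.ndarray:
    # GY94 rows: q_ij ∝ π_j × factors; recover π from the null left vector
    w, v = np.linalg.eig(Q.T)
    k = int(np.argmin(np.abs(w)))
    pi = np.real(v[:, k])
    pi = np.abs(pi)
    return pi / pi.sum()


def _architecture_topology(gene_id: str, architecture) -> TopologySegments:
    segments = []
    pos = 1
    for label, length in architecture:
        segments.append((label, pos, pos + length - 1))
        pos += length
    return TopologySegments(gene_id, tuple(segments))


def _relabel_outside_as_inside(topology: TopologySegments) -> TopologySegments:
    segs = tuple(("inside" if label == "outside" else label, s, e)
                 for label, s, e in topology.segments)
    # merge is unnecessary for validity; segments stay contiguous
    return TopologySegments(topology.identifier, segs)


def sample_cohort(config: SimulationConfig) -> SyntheticCohort:
    """Draw a full cohort reproducibly from the config's seed.

    Gene-level log-ω and log-abundance come from a Gaussian copula whose
    latent correlation is chosen so the rank correlation matches the target
    in expectation.  Each gene uses an independent random substream keyed by
    (seed, gene index), so results do not depend on iteration order.
    """
    cfg = config
    pi = _check_frequencies(cfg.codon_frequencies)
    r_i = spearman_to_pearson(cfg.target_rho_i)
    r_e = spearman_to_pearson(cfg.target_rho_e)
    targets = {"i": cfg.omega_i, "t": cfg.omega_t, "e": cfg.omega_e}
    width = len(str(cfg.n_genes))
    genes = []
    # generator cache: many genes share (omega, domain) only if sigma == 0
    for g in range(cfg.n_genes):
        rng = np.random.default_rng([cfg.seed, g])
        z = rng.standard_normal(4)  # z0: abundance; z1: omega_i; z2: omega_e; z3: omega_t
        z_abund = z[0]
        z_i = r_i * z_abund + math.sqrt(max(0.0, 1 - r_i ** 2)) * z[1]
        z_e = r_e * z_abund + math.sqrt(max(0.0, 1 - r_e ** 2)) * z[2]
        z_t = z[3]
        omega = {
            "i": targets["i"] * math.exp(cfg.omega_sigma * z_i),
            "e": targets["e"] * math.exp(cfg.omega_sigma * z_e),
            "t": targets["t"] * math.exp(cfg.omega_sigma * z_t),
        }
        abundance = 10.0 ** (cfg.log10_abundance_mean + cfg.log10_abundance_sigma * z_abund)
        tissue_abundance = {}
        if cfg.n_tissues > 1:
            noise = rng.standard_normal(cfg.n_tissues)
            for k in range(cfg.n_tissues):
                tissue_abundance[f"tissue{k + 1:02d}"] = 10.0 ** (
                    math.log10(abundance) + cfg.tissue_sigma * noise[k]
                )
        discordant = rng.random() < cfg.discordant_fraction

        parts_a = []
        parts_b = []
        for label, length in cfg.domain_architecture:
            dom = _DOMAIN_OF_LABEL[label]
            Q = build_m0_generator(cfg.kappa, omega[dom], pi)
            anc = rng.choice(N_CODONS, size=length, p=pi)
            ca, cb = evolve_pair(anc, Q, cfg.t, rng, stationary_frequencies=pi)
            parts_a.append("".join(CODON_ARRAY[ca]))
            parts_b.append("".join(CODON_ARRAY[cb]))
        gene_id = f"g{g + 1:0{width}d}"
        topo = _architecture_topology(gene_id, cfg.domain_architecture)
        topo_b = _relabel_outside_as_inside(topo) if discordant else topo
        genes.append(
            SyntheticGene(
                gene_id=gene_id,
                cds_a="".join(parts_a),
                cds_b="".join(parts_b),
                topology_a=topo,
                topology_b=topo_b,
                true_omega=omega,
                abundance=abundance,
                tissue_abundance=tissue_abundance,
            )
        )
    return SyntheticCohort(cfg, genes)
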