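# domainer

Highly expressed proteins evolve slowly — the expression level–evolutionary
rate (E–R) anticorrelation. Transmembrane proteins are a natural experiment
on *why*: their intracellular domains fold and act in the cytosol, while
their extracellular domains complete folding in the endoplasmic reticulum
and act outside the cell, where misfolding and misinteraction are less
costly. If the anticorrelation is driven by selection against misfolding or
misinteraction, it should be stronger for intracellular than for
extracellular domains of the *same* proteins.

`domainer` is a library (plus a thin CLI) for running that test end to end
on pairwise ortholog data:

- **Ortholog alignment** — reciprocal-best-hit ortholog calling over exact
  affine-gap global alignment scores (BLOSUM62), and protein-guided
  back-translation into codon alignments (gap unit: the whole codon).
- **Topology partitioning** — per-residue membrane topology (TMHMM-style
  `inside`/`TMhelix`/`outside` segments) projected onto codon-alignment
  columns; columns concordant between the two species define the
  intracellular, transmembrane and extracellular subalignments. Only genes
  with both an inside and an outside domain *in both species* are retained.
- **Per-domain dN/dS** — two interchangeable engines per subalignment:
  Nei–Gojobori (1986) counting with Jukes–Cantor correction, and maximum
  likelihood under the Goldman–Yang one-ratio (M0) codon model with F3x4
  frequencies, giving ω_i, ω_t, ω_e per gene. Genes with dS = 0 (infinite
  ω) are removed.
- **Statistics** — Spearman correlations of each ω with protein or mRNA
  abundance; Fisher r-to-z comparison
  Z = (atanh ρ₁ − atanh ρ₂)/√(1/(n₁−3) + 1/(n₂−3)); exact binomial ordering
  tests (ω_e > ω_i; ω_t below both); abundance terciles; multi-tissue
  sweeps with ω_t-intermediacy counts.
- **Synthetic cohorts** — a GY94 forward simulator that evolves ortholog
  codon pairs under domain-specific ω and draws abundances with a
  controllable rank correlation to ω_i and ω_e (Gaussian copula,
  ρ_S = (6/π)·asin(r/2)), so every stage can be validated against ground
  truth.

## Worked example

`examples/worked_statistics.py` feeds published (ρ, n) pairs to the test
layer:

```
human  protein abundance: Z = -3.40, one-tailed P = 0.0003
yeast  protein abundance: Z = -1.99, one-tailed P = 0.023
mRNA sweep 30/32 intermediate: P = 1.11e-12
protein sweep 13/20 intermediate: P = 0.004
```

The negative Z says the intracellular E–R correlation is significantly more
negative than the extracellular one. `examples/full_pipeline.py` runs the
whole pipeline on a 200-gene synthetic cohort simulated with
Spearman(log abundance, ω_i) = −0.3 and ω_e uncorrelated, printing (among
other rows):

```
correlation  omega_i vs integrated   -0.322933  200  3.10276e-06
correlation  omega_t vs integrated   -0.0634514 199  0.373277
correlation  omega_e vs integrated   -0.0542294 200  0.445658
fisher       omega_i vs omega_e (integrated)  -2.78522  200;200  0.00267454
ordering     omega_e > omega_i       135/200   200  8.32791e-07
ordering     omega_t < min(omega_i, omega_e)  117/199  199  1.73921e-13
```

The pipeline recovers the injected contrast (ρ_i ≈ −0.32 vs ρ_e ≈ −0.05,
one-tailed P ≈ 0.003) and reproduces the expected biology: extracellular
domains evolve faster than intracellular ones for most genes, and
transmembrane domains are the most constrained.

The same run is available from the shell:

```sh
domainer run --config config.yaml          # full pipeline
domainer simulate|align|partition|dnds|correlate|report ...   # single stages
```

See `examples/` for narrative scripts covering each capability, and
`docs/methods.md` for models, parameters and numerical choices.

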