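# Methods

## Problem and model

For a transmembrane protein with a pairwise ortholog codon alignment, the
per-domain evolutionary rates ω_i, ω_t, ω_e are dN/dS ratios estimated
separately on the alignment columns whose residues are intracellular,
within the membrane, or extracellular in *both* species. The scientific
question is whether the rank correlation of ω with expression level (the
E–R anticorrelation) is stronger for the intracellular than the
extracellular class; the primary statistic is the Fisher r-to-z comparison
of the two Spearman coefficients.

## Codon substitution model (GY94 / M0)

Both the simulator and the likelihood engine use the Goldman–Yang one-ratio
model over the 61 sense codons of the standard code: zero rate for
multi-nucleotide changes, and rate π_j · κ^[transition] · ω^[nonsynonymous]
for a single-nucleotide change i→j. The generator is rescaled so the
expected number of substitutions per codon per unit time is one, making the
branch length t directly interpretable. Matrix exponentials use the
symmetric eigendecomposition available for reversible generators
(B = D^{1/2} Q D^{-1/2} with D = diag(π)), which is exact and fast enough
to sit inside the optimizer.

`m0_fit` maximises Σ_sites log(π_x P_xy(t)) over (t, κ, ω) with L-BFGS-B on
log-parameters, PAML-like boxes (κ ∈ [0.01, 99], ω ∈ [10⁻⁴, 99],
t ∈ [10⁻⁶, 50]), and three fixed ω starting points {0.1, 0.5, 2.0} (best
log-likelihood wins; ties go to the smallest ω — pairwise M0 likelihoods
can be multimodal at low divergence). Codon frequencies default to F3x4
computed jointly from both sequences with a half-count floor per
nucleotide; a uniform option exists for closed-form checks. dN and dS are
derived from the fitted generator by splitting the expected substitution
flux into synonymous and nonsynonymous classes and dividing by the site
proportions of the same generator at ω = 1, so dN/dS equals the fitted ω
identically. Alignments with no variable sites return t at its lower bound
and are flagged invalid.

## NG86 engine

Site counts: each codon position contributes one site, split by the
fraction of synonymous changes among its *sense* single-nucleotide
neighbours (changes to stop codons are excluded from the per-position
denominator), so synonymous + nonsynonymous sites = 3 for every codon; the
two sequences' totals are averaged. Observed differences average syn/nonsyn
step counts with equal weight over the minimal substitution paths whose
intermediates are all sense codons; if every path is blocked by a stop
(rare), all paths are used with stop-involving steps counted as
nonsynonymous. Proportions are corrected with Jukes–Cantor,
d = −(3/4)·ln(1 − 4p/3); p ≥ 3/4 or dS = 0 makes ω undefined. Columns with
a gap, stop or ambiguity in either row are skipped (pairwise deletion).

## dS = 0 filter

Genes with zero synonymous divergence have infinite ω and are removed. Two
scopes are implemented because the rule is ambiguous at the domain level:
`per-domain` (default — the gene only leaves analyses of the affected
domain) and `whole-gene` (the gene leaves everything). The pipeline logs
per-domain attrition so sample sizes stay auditable.

## Ortholog alignment choices

Protein pairs are aligned with deterministic affine-gap Needleman–Wunsch
under BLOSUM62, gap open 11 / extend 1 in the BLAST convention (a gap of
length L costs 11 + L). This replaces a probabilistic consistency aligner:
it is deterministic and dependency-free, and for closely related orthologs
the alignment is essentially forced. Orthology is reciprocal best hit over
exact all-vs-all alignment scores with a minimum-score floor (default 50)
instead of E-value screening, which is database-size-dependent; ties for
best partner exclude the pair. CDSs are trimmed of a terminal stop; genes
with internal stops are dropped with a warning (annotation errors). No
alignment-column confidence filtering is applied.

## Topology partitioning

Topology input is either 4-column TMHMM-style segments (1-based inclusive)
or a per-residue `i`/`M`/`o` string; internally everything is 0-based. The
default column policy is `concordant`: a codon column joins a domain class
only if both species carry the same label there; discordant or gapped
columns are unassigned (conservative and symmetric). A `reference` policy
(species A decides) exists for sensitivity analysis. Retention requires
inside and outside segments in both species; signal peptides and re-entrant
loops are not modelled — labels are taken at face value.

## Statistics

Spearman correlations use average ranks and the t-approximation for p
(adequate at the sample sizes involved). A gene enters a correlation only
if that domain's ω is valid and its abundance is present and positive (zero
abundance is treated as below detection, i.e. missing). The Fisher
comparison uses the independent-samples formula even though ω_i and ω_e
share genes and the abundance variable — back-calculation from the
published examples shows that is the computation being mirrored, and the
published probabilities are one-tailed (Φ(Z)); both tails are always
reported. A Meng–Rosenthal–Rubin overlapping-correlations variant is
provided as an option but is not the default. Binomial ordering tests are
exact: ω_e > ω_i against 1/2 (two-sided, minimum-likelihood convention;
ties are failures) and ω_t < min(ω_i, ω_e) against 1/3 (one-sided greater).
Abundance terciles cut the stable abundance ranking with remainders going
to the lowest bins (n = 10 → 4/3/3). Tissue sweeps correlate each domain's
ω with each tissue's abundance and count tissues where ρ_t lies strictly
between ρ_i and ρ_e, tested against 1/3. No multiple-testing correction is
applied across tissues; α is nominal.

## Synthetic cohorts

The generator's defaults define the study conditions. Architecture: one
inside segment of 120 residues, one TM helix of 21, one outside segment of
150 — a single-pass-receptor-like protein, large enough per domain that
per-gene ω estimates are informative. Divergence t = 0.5 substitutions per
codon (total over both lineages, split t/2 each — a pairwise estimate only
identifies the sum), κ = 2, domain targets ω_i = 0.15, ω_t = 0.10,
ω_e = 0.25: strong purifying selection, transmembrane most constrained,
extracellular least, the ordering expected for membrane proteins.
Gene-level ω vary log-normally (σ = 0.5 on the log scale) around the
targets; ω is positive and right-skewed in real data. Abundances are
log10-normal (mean 1.5, σ = 1.0, in ppm), optionally fanned out into
tissues with σ = 0.3 log10 noise around the integrated value. The rank
correlation between log-abundance and gene-level ω_i (and ω_e) is set
through a Gaussian copula: the latent Pearson correlation is
r = 2·sin(π·ρ_S/6), the exact inverse of the bivariate-normal rank
correlation identity. Ancestral codons are i.i.d. from the stationary
frequencies (uniform by default, keeping closed-form expectations
checkable). Randomness uses one root seed with per-gene substreams keyed by
(seed, gene index), so cohorts are byte-identical across runs and
independent of iteration order. A `discordant_fraction` toggle relabels
species-B outside segments as inside for a random subset of genes, to
exercise the retention filter's failure path.

What the simulator does **not** emulate: indels (so alignment is never
stressed by the cohort), among-site rate variation beyond the three-domain
partition, codon-usage bias beyond the frequency vector, topology
prediction error, and abundance measurement error. Passing tests therefore
validate the estimation and statistics machinery under the model family it
assumes, not robustness to real-data artefacts.

## Problem sizes in the test suite

Estimator recovery uses 50 replicates of 2,000-codon pairs at
(ω = 0.2, κ = 2, t = 0.4) and 50 replicates per ω ∈ {0.1, 0.5, 1.0} for the
bias bound. The power regression uses 100 cohorts of 500 genes at targets
ρ_i = −0.3 / ρ_e = 0 (NG86 engine; the engines' ω ranks agree above 0.9 and
NG86 is orders of magnitude faster), and the null calibration uses 200
cohorts with both targets 0. End-to-end pipeline tests run 30–60 gene
cohorts.

## Known limitations

Pairwise (two-taxon) estimation only; no site-model heterogeneity (M1a/M2a)
or codon-usage-corrected dS variants (LWL, YN00); the NG86 multiple-hit
correction underestimates divergence at high t; the independent-samples
Fisher test ignores the positive dependence between ω_i and ω_e, which is
mildly conservative for the null calibration in this setting; F3x4 shares
the known biases of position-wise frequency products.
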