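"""The comparison statistics on published inputs.

Feeds printed (Spearman rho, n) pairs to the Fisher r-to-z test and printed
counts to the exact binomial test, reproducing the headline numbers of the
human and yeast transmembrane-protein analyses.
"""
from domainer import binomial_test, fisher_r_to_z

# Human: intracellular-domain omega correlates with whole-body protein
# abundance at rho = -0.124, extracellular at -0.041, both over 3,308 genes.
human = fisher_r_to_z(-0.124, 3308, -0.041, 3308)
print(f"human  protein abundance: Z = {human.z:.2f}, one-tailed P = {human.p_one_tailed:.1g}")

# Yeast (S. cerevisiae vs S. paradoxus): rho_i = -0.049, rho_e = +0.049, n = 829.
yeast = fisher_r_to_z(-0.049, 829, 0.049, 829)
print(f"yeast  protein abundance: Z = {yeast.z:.2f}, one-tailed P = {yeast.p_one_tailed:.2g}")

# Transmembrane-domain intermediacy across tissues: in 30 of 32 tissues the
# omega_t correlation fell between omega_i's and omega_e's (null: 1/3).
mrna = binomial_test(30, 32, 1 / 3, "greater")
print(f"mRNA sweep 30/32 intermediate: P = {mrna.p_value:.3g}")
protein = binomial_test(13, 20, 1 / 3, "greater")
print(f"protein sweep 13/20 intermediate: P = {protein.p_value:.1g}")

# A negative Z means the first correlation is more negative than the second:
# the intracellular E-R anticorrelation is stronger than the extracellular one.
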