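"""Per-population diversity statistics on a study-shaped synthetic dataset.

Generates the default 376-individual x 11-locus dataset (one mainland
population split into 9 regions plus four island populations founded by a
staged colonization) and prints the classic diversity table: sample size
N, allele count A, rarefied allelic richness AR (at 160 genes), private
alleles PA, observed and expected heterozygosity, and the inbreeding
coefficient Fis = 1 - Ho/He.  Rarefaction uses a 16-gene standard, the
largest every population (including 11-individual Floreana) supports.
"""

from ssrtrace.diversity import diversity_table
from ssrtrace.synthetic import generate_study_like

g, truth = generate_study_like(seed=1)
table = diversity_table(g, rarefaction_genes=16)
print(table.round(3))
print(
    "\nThe mainland population retains far more alleles and higher gene"
    "\ndiversity (He) than any island: the signature of serial founder"
    "\nevents during the island invasion."
)
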