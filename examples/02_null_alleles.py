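"""EM estimation of null-allele frequencies and corrected statistics.

Null alleles fail to amplify in PCR: heterozygote carriers type as
homozygotes and null homozygotes as blanks, inflating apparent
homozygosity.  This script builds a single-population benchmark with a
known null frequency, recovers it by EM, and shows the corrected
expected heterozygosity rising back toward the truth.
"""

from ssrtrace.diversity import mean_expected_het
from ssrtrace.null_alleles import corrected_expected_het, em_null_frequency, estimate_null_alleles
from ssrtrace.synthetic import generate_null_allele_benchmark

for beta in (0.1, 0.2, 0.3):
    (g, truth), = generate_null_allele_benchmark([beta], n=500, seed=42)
    fit = em_null_frequency(g, "L1", "pop1")
    est = estimate_null_alleles(g)
    raw_he = mean_expected_het(g, "pop1")
    corr_he = corrected_expected_het(est, g, "pop1")
    print(
        f"true beta={truth:.2f}  EM estimate={fit.beta:.3f} "
        f"({fit.n_iter} iterations)  He raw={raw_he:.3f} corrected={corr_he:.3f}"
    )
print(
    "\nThe EM estimate tracks the true null frequency, and the corrected"
    "\nHe exceeds the raw value because the inferred null class rejoins"
    "\nthe frequency vector."
)
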