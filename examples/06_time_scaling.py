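"""Converting mutation-scaled durations into generations and years.

Demographic MLEs report the duration of a population-size change scaled
by the mutation rate (D_g*mu).  With a per-locus SSR mutation rate of
mu = 3.5e-4 per generation and a 2-year minimum generation time, these
become absolute dates for each island's founder event.
"""

from ssrtrace.coalescent import generations_to_years, scale_duration_to_generations

MU = 3.5e-4
islands = {
    "Isabela": (0.0832, (0.0265, 1.111)),
    "Floreana": (0.0431, (5.5e-06, 1.294)),
    "Santa Cruz": (0.0179, (0.0079, 0.121)),
    "San Cristobal": (0.0067, (0.0004, 0.546)),
}
for island, (d, ci) in islands.items():
    gens, gen_ci = scale_duration_to_generations(d, MU, ci=ci)
    years = generations_to_years(gens, 2)
    print(
        f"{island:>14}: {gens:>4} generations (95% CI {gen_ci[0]}-{gen_ci[1]})"
        f"  -> at least ~{years} years ago"
    )
print(
    "\nDividing D_g*mu by mu gives generations since the founder event;"
    "\nmultiplying by the 2-year generation floor gives a minimum age in"
    "\nyears, placing the island introductions within the historical era."
)
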