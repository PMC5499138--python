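"""Walk the crossing scheme: half-diallel, bulk-pollen intermating, selfing.

Follows the population-development steps of a multiparental recurrent
program: all pairwise crosses among 18 inbred founders, one round of
two-group bulk-pollen intermating, then selfing into ear-to-row families.
Prints the family counts and the heterozygosity at each step — selfing
should halve it.
"""

import numpy as np

from rcgs import bulk_intermate, half_diallel, simulate_founders, simulate_map
from rcgs.breeding import ear_to_row_families

rng = np.random.default_rng(7)
gmap = simulate_map(10, 100, seed=1)
panel = simulate_founders(gmap, 18, seed=2)

f1 = half_diallel(panel.population, progeny_per_cross=2, rng=rng)
print(f"F1 families from 18 parents: {len(f1.families())} (= 18*17/2)")
print(f"F1 heterozygosity:           {f1.heterozygosity():.3f}")

s1 = bulk_intermate(f1, ears_to_harvest=200, rng=rng, cycle="S1")
print(f"intermated plants:           {s1.n}")
print(f"S1 heterozygosity:           {s1.heterozygosity():.3f}")

families = ear_to_row_families(s1, range(50), n_progeny=25, rng=rng, prefix="C0_f", cycle="C0")
print(f"ear-to-row families:         {len(families.families())} x 25 plants")
print(f"selfed-family heterozygosity:{families.heterozygosity():.3f}")
print()
print("Intermating preserves heterozygosity (random mating); one selfing")
print("generation halves it, which is the S1 -> S2 step of the program.")
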