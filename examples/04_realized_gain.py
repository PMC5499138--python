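"""Realized-gain analytics on the published cycle means.

Regresses the published combined grain-yield cycle means on the cycle
index, converts the per-cycle gain to a per-year figure for a program
running two cycles per year over 4.5 years, and prints the percent gains.
"""

from rcgs import gain_per_year, percent_gain, regress_gain
from rcgs.reference import combined_cycle_means

means = combined_cycle_means()
print("combined GY cycle means (t/ha):")
for cyc, v in means.items():
    print(f"  {cyc}: {v:.2f}")

slope_all = regress_gain(means)
slope_gs = regress_gain(means, ["C1", "C2", "C3", "C4"])
print(f"\ngain per cycle C0-C4: {slope_all:.3f} t/ha")
print(f"gain per cycle C1-C4: {slope_gs:.3f} t/ha (genomic-selection cycles)")
print(f"gain per year:        {gain_per_year(slope_gs, cycles_per_year=2, total_years=4.5):.3f} t/ha/yr")
print(f"percent gain C1->C4:  {percent_gain(means['C1'], means['C4']):.2f}%")
print(f"percent gain C0->C4:  {percent_gain(means['C0'], means['C4']):.1f}%")
print()
print("0.225 t/ha/cycle over the three prediction-driven cycles amortizes")
print("to 0.100 t/ha/yr over the whole program — competitive with")
print("phenotypic-selection programs that need far longer cycles.")
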