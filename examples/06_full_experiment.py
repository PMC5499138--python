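"""Run the whole in-silico rapid-cycling genomic selection experiment.

One call executes the full program at desk scale (published plan divided
by ten, 2000 markers): training-population development, phenotypic
selection into C1, GBLUP-ranked recombination through C3, the ungenotyped
C4, the two-location evaluation trial, and all reports. Prints the
realized cycle means, the gain regressions, and the diversity trend.
Artifacts (TSV reports, pedigree, phenotypes, config) land in ./scratch.
"""

from rcgs import ExperimentConfig, run_experiment

cfg = ExperimentConfig(seed=4)
result = run_experiment(cfg, out_dir="scratch/experiment_seed4")

print("evaluation-trial cycle means (combined, t/ha):")
print(result.cycle_means().round(3).to_string())
print(f"\nrealized gain per cycle C1-C4 (trial):  {result.slope():.3f} t/ha")
print(f"genetic trend per cycle C1-C4 (census): {result.census_slope():.3f} t/ha")
print(f"training CV accuracy ({result.cv['reps']} reps):     {result.cv['mean']:.3f}")
print("\nheterozygosity by group:")
cols = ["group", "heterozygosity", "shannon"]
print(result.diversity_report[cols].round(4).to_string(index=False))
print()
print("At one-tenth scale the per-cycle response is positive on average but")
print("drift among the few selected families makes single runs noisy; the")
print("heterozygosity decline from C0 to C3 mirrors the narrowing that")
print("recurrent selection produces in the real program.")
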