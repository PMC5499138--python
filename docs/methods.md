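# Methods

## The program being modeled

The package models a multiparental recurrent-selection program in tropical
maize. Eighteen fully inbred founders are crossed in a half-diallel (153
families, no selfs, no reciprocals), the F1s are intermated once by
two-group bulk pollination, and the intermated plants are selfed; the best
ears are planted ear-to-row to form the training cycle C0 (1000 families at
full scale). Each family is genotyped as a single DNA bulk of 15 plants and
phenotyped as a testcross to a common single-cross tester in multi-location
trials. One cycle of phenotypic selection forms C1; subsequent cycles
(C2, C3) are recombined on the strength of genomic predictions from the
model trained on C0, with no new phenotyping, so that two cycles fit in a
year; the final cycle C4 is not genotyped. A two-location trial of entries
from every cycle plus benchmark checks estimates the realized gain.

## Meiosis

Gametes follow the Haldane model (no crossover interference). Rather than
drawing a Poisson(L/100) crossover count with uniform positions, the
implementation draws, per adjacent-marker interval of d cM, an independent
phase switch with probability r = (1 − e^(−2d/100))/2, with a fair-coin
phase at the first marker of each chromosome. For marker genotypes the two
formulations are the same law — under no interference the crossover count
in an interval is Poisson and the phase switches exactly when the count is
odd — and the interval form vectorizes over gametes, which is what makes
thousand-family populations cheap. A closed-form check (recombinant
fraction (1 − e^(−2d/100))/2) is part of the test suite.

## Populations and genotypes

Individuals are phased diploids over a marker map (10 chromosomes,
bp + cM positions, cM proportional to bp by default). Dosages count the
coded allele (ALT in the VCF dialect); family bulks are real-valued mean
dosages over min(15, family size) sampled plants, which estimate the
family mean dosage — the selection unit of a family-based program — and
enter the relationship matrix exactly like integer dosages. Missing calls
are injected independently per (sample, marker) cell at the configured
rate (default 5%, matching a <10% GBS pipeline) and are an explicit NaN
sentinel, never 0. Marker QC retains MAF strictly > 0.05 and missingness
strictly < 10%.

## Founder panel

The founder allele-frequency spectrum is a two-component mixture: with
probability 0.2 the major-allele frequency is Uniform(0.5, 0.95), else
Uniform(0.95, 1.0). This skewed spectrum reproduces the expected
heterozygosity (~0.105, band 0.09–0.14) and Shannon index scale of elite
tropical GBS panels, where most SNPs are close to fixation. The spectrum
is a modeling construction: real panels' site-frequency spectra are shaped
by breeding history that is not simulated here.

## Trait model and calibration

Grain yield is purely additive: 40 QTL sampled from markers segregating in
the founders, normal effects, intercept 8.5 t/ha. Because entries are
always evaluated as hybrids with one tester, the genetic value used
throughout is the analytic expectation over tester gametes:
entry dosage/2 + tester-F1 dosage/2 at each QTL. Effects are rescaled so
the between-family genetic SD of a simulated training population is
0.5 t/ha — family means of selfed ear-to-row progeny, not individual
plants, because within-family segregation variance does not appear among
entry means. Genotype-by-location and plot-error variances are then solved
so the entry-mean broad-sense heritability of the training design
(4 locations × 1 rep) equals the 0.34 target, holding σ²_GE = σ²_e/2.
Realized H² at the 1000-family scale is ~0.35; the replicate-mean over 10
seeds at 200 families sits inside the ±0.05 calibration band (single-run
estimates carry ~0.06 sampling noise). Location main effects are fixed
draws (SD 1.5 t/ha) and cancel from all entry-mean contrasts. Dominance,
epistasis and stress-environment regimes are deliberately absent.

## GBLUP

The model is y = Xβ + u + e with u ~ N(0, G σ²_u) and G the VanRaden
method-1 matrix centered at data frequencies (mean-imputing missing
dosages first). REML profiles β and σ²_u out on the eigenbasis of G and
searches λ = σ²_e/σ²_u with a bounded scalar minimizer on log λ in
[1e−4, 1e4] (tolerance 1e−6), so fits are deterministic. Candidate GEBVs
are G_ct (G_tt + λI)⁻¹ (y − Xβ̂). Cross-validation re-fits REML inside
every fold; fold assignment depends only on (seed, n, k). Training
phenotypes are location-adjusted entry means (subtract location means,
average plots); the intercept is the only fixed effect. One caveat worth
recording: under a GLS intercept the GEBVs do not sum exactly to zero
(their sum equals the unweighted residual sum); it is small relative to
their spread but not numerically zero.

## Gain analytics

Cycle means are arithmetic entry means (checks reported separately); the
published combined means reproduce their printed slopes (0.158 and 0.225
t/ha/cycle) under exactly this choice, while per-location printed slopes
were evidently computed from unrounded upstream values and are not exact
under arithmetic means of the printed table. Gain per year is
(cycles/year × gain/cycle)/total years. The breeders' equation is
implemented verbatim as i·r·h/I — as printed it omits the additive SD
factor, so its output is in units of σ_A per year. H² uses the entry-mean
basis with the standard ℓ and ℓr divisors.

## Diversity and status changes

The Shannon index is −(1/A) Σ p̂_a ln p̂_a over major-allele frequencies
(the leading minus sign is required for the index to be positive on
frequencies in [0.5, 1]); expected heterozygosity is the mean of 2p̂q̂ over
markers. Exact 0.5 ties assign the major allele to the reference (non-
coded) allele, deterministically. MDS is Torgerson double-centering of
squared identity-by-state distances (mean |x_i − x_j|/2 over shared
non-missing markers), keeping positive-eigenvalue axes. Status changes
track the frequency of epoch 1's major allele in both epochs: a marker is
polymorphic when that frequency lies in [0.05, 0.95] inclusive;
transitions out of or into that band take precedence over allele swaps
(major allele flips while polymorphic in both). Clusters chain changed
SNPs per chromosome and per category with single-linkage at gaps strictly
below 1000 bp, reporting clusters of ≥3. The epoch-2 group is an explicit
sample list; the pipeline uses the C3 bulks (the last genotyped cycle)
against the founder panel.

## The scaled experiment and what it shows

The default `ExperimentConfig` runs the program at one-tenth of the
published plan — 100/16/9/4 families sown, 5/3/2/2 selected, 16/9/4/2
ears, 4 final ears, 25 plants per family, 2000 markers — with a
4-location training trial, a 2-location × 2-rep evaluation of ~5 entries
per cycle, and 10-replicate fivefold CV. A run takes a few seconds and is
byte-reproducible from (config, seed); stage seeds are stable hashes of
(master seed, stage name) so adding a stage never perturbs another's
stream.

Desk scale changes the statistics, and honestly reporting that is part of
the design. Training on 100 families gives CV accuracy ~0.28 on average
with a wide seed-to-seed spread (−0.05 to 0.53 over six seeds), versus a
stable 0.41–0.43 at the full 1000 families; and with only 2–3 families
selected per cycle,
between-cycle drift on cycle means is of the same order as the per-cycle
response. Over 50 seeds the realized C1–C4 trial slope is positive in
only ~60% of runs (mean +0.03 t/ha/cycle, SD 0.20) and the noise-free
census of true breeding values is positive in ~80% (mean +0.054, SD
0.07), while C3 heterozygosity falls below C0 in every run
(mean change −0.028). Selection works — the genetic trend is positive on
average and diversity narrows exactly as expected — but a tenth-scale
program cannot deliver the near-certain positive slope that the full-size
program does, because Ne and training size, not the method, are the
binding constraints. Null runs (selection replaced by random choice) give
slopes centered at zero.

Problem sizes used by the test suite and the acceptance script (50
replicate scaled runs; a single 1000-family training analogue; 10-replicate
CV where the published design used 100) were chosen as desk-scale defaults;
`cross_validate` defaults to the published 100 replicates.

## Numerical and degenerate-input choices

Selection ties break lexicographically by family label (logged). Odd
family counts at intermating put the extra family in the first pollination
half (logged). Ears spread across selected families as evenly as possible,
remainder at random. Negative variance-component moment estimates clip at
zero. Non-PSD relationship matrices (beyond −1e−8 eigenvalue tolerance)
are rejected. Fully missing markers are excluded from frequency profiles
and flagged. The DS (fractional dosage) VCF dialect is written and parsed
at full float64 precision so write→read round-trips are exact; GT-based
files go through cyvcf2.

## Known limitations

No crossover interference or sex-specific maps; no dominance or epistasis;
no incomplete-block or p-rep trial structure (balanced RCBD within
location instead — gain and diversity conclusions at desk scale do not
depend on block recovery); founder LD limited to what inbred-line sampling
induces (no coalescent history); secondary traits are not simulated; the
scaled plan's tiny Ne makes single-run gain estimates noisy by
construction, as quantified above.
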