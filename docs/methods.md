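# Methods

## Measurement model

The raw datum is one homolog of one chromosome pair measured in one
metaphase cell: short-arm, long-arm and satellite lengths in µm. Records
are *oriented* (arms swapped so short ≤ long) before any statistics;
orientation compares satellite-inclusive arm lengths and is idempotent.
Homolog pairing is an input (`pair_id`): chromosomes are identified by
karyotyping, and silent automatic pairing by length would risk assigning
wrong arm ratios, so none is attempted.

Satellites are counted inside their arm for RL/AR/CI and flagged
separately for the karyotype formula and idiogram (configurable via
`AnalysisConfig.include_satellite`; the alternative convention excludes
the satellite from the arm).

Averaging follows the standard karyotyping protocol: b and B are means
over homologs and cells; RL is computed within each cell (so the
condensation state of a spread cancels) and then averaged; TCL is the
mean over per-cell haploid totals with its SE over cells (sample SD/√n;
a single cell yields SE 0 with a warning). Pairs are renumbered by
decreasing RL, ties broken by the lower input id.

## Indices and classifications

All dispersion statistics are sample (n−1) standard deviations. The CI
dispersion attached to the complement mean is treated as the SD over the
per-pair CI values: Paszko's AI = CVcl·CVci/100 reproduces the published
AI values for the two species checked (1.52, 1.41) only under that
reading, even where the table labels the ± an "SE". With A2 printed at
two decimals the same reconstruction is off by up to ±0.03 for the other
three species — pure rounding, documented rather than targeted.

Levan intervals are left-open as calibrated for two-decimal arm ratios:
M exactly at 1.00, m (1, 1.70], sm (1.70, 3], st (3, 7], t above 7. The
karyotype formula counts M with m, orders classes m, sm, st, t, and
annotates satellited pairs `(kSAT)` inside their class term.

Stebbins: digit from the proportion of pairs with AR strictly above 2.0
(1: none, 2: ≤½, 3: <1, 4: all; AR exactly 2 counts as symmetric), letter
from the largest/smallest relative-length ratio (A < 2 ≤ B ≤ 4 < C).
Whether the ratio uses absolute or relative lengths is immaterial (they
are proportional within a karyotype); relative lengths are used.

## Marker statistics

Marker coordinates are fractions of the arm, origin at the centromere —
matching the definition of di = 100·d/a, where d runs to the *starting
point* of a terminal site but to the *center* of a non-terminal site, and
a is the arm length. A site is terminal when it reaches within 2% of the
telomere (`ter_min_end_frac = 0.98`, absorbing measurement noise).
Centromere-spanning sites are CEN with no di. The PCEN/INT cut-off is
di ≤ 28, a numeric reconstruction bracketing the published assignments
(largest PCEN di 25.05, smallest INT di 30.86); the original assignments
were visual, so the threshold is exposed in the configuration.

Band amounts use haploid accounting: one homolog per pair, band size
(end−start)·a µm, totals as a percentage of TCL. The headline CPD total
excludes CPD bands overlapping a 45S site on the same pair and arm
(rDNA-associated heterochromatin); the including-rDNA total is reported
alongside. Per-pair band sizes sum to the per-type totals exactly.

## Synthetic generator

`generate_dataset` emulates a five-metaphase-plate measurement design:
per cell, a lognormal condensation factor (default CV 5%) scales the
whole spread; each homolog arm then receives independent unit-mean
lognormal noise with CV `noise_cv` (default 5%), the satellite scaling
with its host arm. Lognormal multipliers keep lengths positive and make
cell-level variation uniform, so all dimensionless statistics are exactly
invariant to condensation. Because the two arms are perturbed
independently, the CV of whole-chromosome lengths is slightly below
`noise_cv` (≈ noise_cv·√(b²+B²)/(b+B)); the convergence test therefore
checks arm lengths. No published noise model exists; these are minimal
assumptions for positive, cell-correlated measurements.

The five built-in templates are parameterized from the published
comparative tables. Only the relative-length *extremes* per species were
published, so the interior profile is a warped geometric interpolation
rl_i = rl_max·(rl_min/rl_max)^((i/(n−1))^γ) with γ solved (Brent) so the
profile sums to exactly 100 while both extremes stay exactly at the
published values; a pure geometric profile cannot satisfy both. Per-pair
arm ratios are likewise unpublished: they are fixed choices inside the
published Levan classes and below the Stebbins cut-off of 2 (e.g.
submetacentric pairs at AR 1.85–1.95, far enough from the 1.70 boundary
that 5% arm noise flips the formula in well under 5% of seeds), with the
mean CI near the published complement mean. Marker layouts place terminal
rDNA sites from their published di as the start fraction, non-terminal
sites as ±0.03 intervals about the published center; (peri)centromeric
CPD bands cover all arms not occupied by a 45S locus, sized so the
non-rDNA CPD total matches the published amount exactly; interstitial
CPD and pericentromeric DAPI bands are sized the same way from their
published totals and arm lists; the satellited template carries its 45S
locus over the whole short arm up to the satellite (drawn as a secondary
constriction).

Consequently the noiseless templates reproduce karyotype formulae, RRL
extremes, satellite, rDNA locus counts/positions and band totals exactly
— but A1, A2, CI dispersion and AI depend on the unpublished per-pair
values and are **not** fidelity targets; synthetic values of those
indices differ from the published ones. Passing tests therefore
demonstrate correctness of the computations and stability under the
stated noise model, not recovery of unpublished raw data. Real metaphase
measurements also feature correlated homolog errors, non-lognormal tails
and occasional misidentification, none of which the generator models.

## Numerical choices

- RL normalization: Σ RL = 100 within 1e−6 by construction (per-cell).
- Identity AsK% + length-weighted mean CI = 100 holds to 1e−6 and is
  property-tested on random karyotypes.
- All indices are cross-checked against one-line brute-force
  recomputations on 1000 random karyotypes (2–12 pairs) to 1e−9.
- Report tables round to 2 decimals; JSON keeps full precision and
  round-trips exactly.
- SVG rendering formats all coordinates at 3 decimals from pure string
  templating, so output is byte-deterministic for a fixed input and style
  (golden-file tested).
- Degenerate inputs: a single cell yields SE 0 with a warning; fewer than
  two pairs make dispersion indices an error; AR < 1 is a domain error
  directing the caller to orient records first.

## Problem sizes

Tests and the acceptance script run on the study-scale design: 11 pairs ×
2 homologs × 5 cells per species, 200 seeds for the stochastic-recovery
check and 1000 random karyotypes for the oracle-equivalence suite —
seconds in total.

## Known limitations

- Band amounts assume homolog-symmetric markers (haploid accounting);
  heteromorphic bands are out of scope.
- The PCEN/INT threshold is a reconstruction of visual assignments.
- Centromere-spanning bands use a symmetric-about-the-centromere
  convention for size and drawing.
- Idiograms draw the satellite on the short arm, distally, by convention.
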