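# karyostat

Comparative molecular-cytogenetic karyotype analysis for plant cytogeneticists:
from chromosome arm measurement tables and band/rDNA-site annotations to
karyotype formulae, the full asymmetry-index suite, marker-position statistics,
comparative species reports and SVG idiograms. A synthetic-karyotype generator
(with built-in templates for five wild *Vigna* species, all 2n = 2x = 22)
makes every pipeline stage reproducible without microscope data.

## What it computes

Given per-homolog, per-cell measurements (short arm *b*, long arm *B*,
satellite, in µm), karyostat derives for each chromosome pair:

- arm ratio AR = B/b and Levan class (M at AR = 1; m ≤ 1.70 < sm ≤ 3.00 < st ≤ 7.00 < t),
- centromeric index CI = 100·b/(b+B),
- relative length RL = 100·L/Σ L (computed per cell, then averaged),

and for the complement:

- the haploid karyotype formula (e.g. `10m (1SAT) + 1sm`),
- TCL (total haploid complement length) ± SE over cells, and C = TCL/n,
- Romero Zarco indices A1 = 1 − mean(b_i/B_i) and A2 = sd(L_i)/mean(L_i),
- Arano's AsK% = 100·ΣB_i/Σ(b_i+B_i),
- Paszko's AI = CVcl·CVci/100 with CVcl = 100·A2, CVci = 100·sd(CI)/mean(CI),
- the Stebbins two-way symmetry category (1–4 × A–C).

Fluorochrome bands (CPD, DAPI+) and rDNA sites (5S, 45S) are fractional
intervals along an arm (0 = centromere). For each site karyostat computes
di = 100·d/a (d to the start of a terminal site, to the center otherwise),
its CEN/PCEN/INT/TER position class, band amounts as % of the karyotype
length (the headline CPD total excludes 45S-colocalized bands), rDNA locus
counts, syntenic pairs and band/rDNA colocalization.

## Worked example

Generate a measurement-error-free dataset from the built-in *V. caracalla*
template and analyze it:

```sh
karyostat generate --template caracalla --noise-cv 0 --seed 0 --out demo/data
karyostat analyze --measurements demo/data/measurements.tsv \
    --markers demo/data/markers.tsv --species "V. caracalla" --out demo/out
```

which logs

```
INFO KF 10m (1SAT) + 1sm, TCL 46.67 ± 0.45 µm, Stebbins 1B
```

and writes `report.json`, `karyotype_table.tsv`, `marker_table.tsv` and
`idiogram.svg`. The karyotype table row reads

```
species       2n  KF                TCL_um  TCL_SE_um  C_um  RRL         CI_mean  CI_SD  A1    A2    AsK_percent  AI    Stebbins
V. caracalla  22  10m (1SAT) + 1sm  46.67   0.45       4.24  5.61-12.80  42.96    3.04   0.24  0.27  56.69        1.91  1B
```

The formula says ten metacentric pairs (one satellited) plus one
submetacentric pair; the complement is ~46.7 µm long (the small ± comes from
the cell-level condensation factor, still on at `--noise-cv 0`), mean
chromosome length 4.24 µm, relative lengths spanning 5.61–12.80 % — a ratio
above 2, hence Stebbins 1B (no arm ratio exceeds 2, but the largest
chromosome is more than twice the smallest). A1/A2/AI reflect the template's
interpolated per-pair profile, not published per-pair data (see
`docs/methods.md`).

`karyostat compare out1/report.json out2/report.json ...` assembles the
one-row-per-species comparative table and cross-species ratios (e.g. the
longest/shortest complement ratio).

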