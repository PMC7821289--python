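# fibrequant

Quantification of nerve-fibre density and neurochemical marker co-expression
in immunofluorescent muscle sections, with a synthetic-image generator for
validation.

## The problem

Skeletal-muscle biopsies (the motivating system is the human masseter, a jaw
muscle) are sectioned, stained for the pan-axonal marker **PGP 9.5** together
with three co-expression markers — **SP** (substance P, a neuropeptide of
small sensory afferents), **NR2B** (the 2B subunit of the NMDA glutamate
receptor) and **NGF** (nerve growth factor) — and imaged as 4-channel
fluorescence micrographs. The scientific questions are where the innervation
sits (within connective tissue, i.e. endo-/perimysium, versus associated
with myocytes), what the fibres express, and whether density or expression
differs between tissues and sexes or changes with age.

`fibrequant` implements the complete quantification:

1. **Detection.** A fluorescent signal is *positive* when it exceeds the
   picture's background mean + 2 SD (an estimate of the upper 95% bound of
   the background). 8-connected signal components are assigned to a tissue
   compartment by majority vote over a per-pixel label map; components
   separated by ≤ 5 µm that share the same path (compatible principal axes)
   and tissue are merged as one fibre; merged objects at least 4 µm long
   *and* 4 µm wide (max/min Feret diameters) count as positive nerve fibres.
2. **Colocalization.** Each marker channel is thresholded the same way; a
   fibre expresses a marker when its footprint overlaps the marker's mask.
   The three flags generate 7 combinations (SP, NR2B, NGF, SP/NR2B, SP/NGF,
   NR2B/NGF, SP/NR2B/NGF), read non-exclusively.
3. **Quantification.** Per image and tissue: density `D = N / A` (positive
   fibres per mm² of that tissue) and expression frequency
   `F_c = N_c / N` per combination `c`; both are averaged over each
   participant's images (only over images where the quantity is defined).
   Cohort tables report median and IQR (75th − 25th percentile), stratified
   All/Men/Women × Combined/Myocytes/Connective.
4. **Statistics.** Mann-Whitney U for tissue and sex comparisons (α = .05;
   exact by enumeration for small tie-free samples, tie-corrected normal
   approximation otherwise), Spearman rank correlation of age with each
   combined expression frequency per sex, judged at the Bonferroni-adjusted
   level α/7 ≈ .007.

Because real micrographs of this kind are rarely shareable, the package
ships a first-class synthetic generator (`fibrequant.simulate`) that renders
calibrated multichannel sections with full ground truth — fibre geometry,
compartments, marker states, participant covariates — including a planted
sex difference in SP-containing expression and a negative age trend of
triple-positive expression in women.

## Worked example

```bash
cat > sim_small.yaml <<EOF
n_participants: 8
images_per_participant: 2
image_shape: [256, 256]
EOF
fibrequant simulate --out demo --seed 1 --config sim_small.yaml
fibrequant run demo/manifest.csv --out reports
```

prints

```
wrote 16 images; manifest: demo/manifest.csv
8 participants analysed
  myocyte: 21.6% of fibres
  connective: 78.4% of fibres
  10 significant tests (see reports/stats_report.csv)
```

Most fibres sit in connective tissue because the generator places them at
400/mm² there versus 230/mm² near myocytes. The cohort report
(`reports/cohort_report.csv`) contains the stratified medians; for this run:

```
     scope  n  density_median  density_iqr  SP_median_pct  NR2B/NGF_median_pct
  combined  8           335.7         61.0           43.2                 29.4
   myocyte  8           152.6        171.7           16.7                 83.3
connective  8           432.3        114.4           47.5                  7.1
```

— connective-tissue fibres are denser and SP-rich (sensory phenotype) while
myocyte-associated fibres co-express NR2B/NGF (putative motor phenotype),
exactly the structure the generator plants. `reports/stats_report.csv`
lists every test with its U or ρ statistic, p-value, threshold and decision;
the first row shows the tissue-density difference
(U = 61, p = .0026 < .05, significant).

The same stages are available as library calls (`generate_dataset`,
`detect_fibres`, `score_fibres`, `quantify_image`, `summarize_participant`,
`cohort_table`, `run_study_battery`) on in-memory objects.

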