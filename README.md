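# trapscreen

Diagnostic metabarcoding of bulk insect trap catches: detect low-abundance
pest species (single specimens among hundreds to a thousand trapped insects)
from multi-locus amplicon sequencing, with defensible false-positive control.

Biosecurity surveillance programs screen sticky- and suction-trap catches for
invasive pests such as Russian wheat aphid (*Diuraphis noxia*) or tomato
potato psyllid (*Bactericera cockerelli*). Morphological sorting of thousands
of specimens is slow and misses damaged individuals; metabarcoding of the
bulk sample is fast but has two failure modes this package addresses head-on:

1. **A dirty reference database makes a confident classifier wrong.**
   Public barcode repositories carry duplicated, truncated, poorly identified
   (*"Acizzia sp."*), endosymbiont-derived (*Wolbachia*) and outright
   mislabelled records.
2. **Index switching fabricates detections.** A small fraction of Illumina
   reads acquire another library's sample index, so a pest present in one
   trap "appears" at trace abundance in every other trap on the flow cell —
   precisely the signal range where real rare pests live.

## What the package does

`trapscreen` implements the full analysis as a tested library
(`src/trapscreen/`) with numbered drivers (`analysis/01…05`) and a
`trapscreen` CLI:

- **`synth`** — a trap-catch simulator that generates every pipeline input
  with known ground truth: reference sets with hierarchical divergence
  (including a conserved 18S-like locus where congeners are identical),
  planted database defects with a manifest, mock pools of 100–1000
  individuals with single-specimen rare targets, multinomial read counts
  with per-species amplification bias, and per-read index switching under
  combinatorial or unique-dual indexing.
- **`refdb`** — a four-rule decontamination cascade: (1) length bounds
  (< 200 or > 3000 bases) and exact duplicates; (2) insufficient-identification
  terms (*sp.*, *nr.*, *aff.*, …) and missing binomials; (3) > 95 % identity to
  a symbiont contaminant panel; (4) 99 %-identity clustering with removal of
  minority-lineage members of clusters mixing phyla/classes/orders — then
  primer-region trimming and classifier training-set export.
- **`qc`** — primer trimming (IUPAC-aware, ≤ 1 mismatch), expected-error read
  filtering (EE = Σ 10^(−Q/10) ≤ 2, no Ns, length > 100 bp), and a COI
  pseudogene (NUMT) screen for frame shifts and stop codons under the
  invertebrate mitochondrial code.
- **`classify`** — an RDP-style naive-Bayes classifier: 8-base canonical
  words, Wang-smoothed genus-conditional word probabilities
  P(wᵢ|g) = (m(wᵢ)+Pᵢ)/(M+1) with word prior Pᵢ = (n(wᵢ)+0.5)/(N+1),
  bootstrap resampling of ⅛ of the query's words × 100 iterations, assignment
  truncated at the lowest rank with ≥ 80 % support; species by exact sequence
  matching, with identical conserved-locus congeners reported as an
  aggregate (e.g. `Genusa aspecies/bspecies`).
- **`contam`** — the detection-threshold statistic: the single-end switching
  rate c is estimated from reads on invalid index-pair combinations,
  c = (R_invalid/R_total) · (C_offdiag/C_invalid), and the residual
  double-switch misidentification threshold is **t = c²**; taxa below t per
  library are removed.
- **`detect`** — per-locus relative abundances merged by arithmetic mean
  across loci with reads, detections called against known mock designs,
  false positives/negatives, locus-overlap counts and group read
  proportions.

## Worked example

Run the drivers in order (each prints its findings and writes tables under
`results/`):

```bash
python analysis/01_simulate_inputs.py
python analysis/02_curate_reference_db.py
python analysis/03_classify_asvs.py
python analysis/04_estimate_switching_threshold.py
python analysis/05_call_detections.py
```

Output of the last two steps:

```
invalid-pair reads: 2005 of 200000
single-end contamination rate c = 1.00%
residual misidentification threshold t = c² = 0.0101% (prints as 0.01% at two decimals)
indexing contrast over 20 seeds: mean cross-sample FP reads 801 (combinatorial) vs 1.2 (unique dual); combinatorial higher in 100% of seeds
...
pools with every designed species detected: 100%; false-positive-free pools: 100%
  Pool100: rare taxon 'Genusd aspecies/bspecies' expected 1.00%, observed 0.950%; FP=none FN=none
  Pool250: rare taxon 'Genusd aspecies/bspecies' expected 0.40%, observed 0.432%; FP=none FN=none
  Pool500: rare taxon 'Genusd aspecies/bspecies' expected 0.20%, observed 0.224%; FP=none FN=none
  Pool1000: rare taxon 'Genusd aspecies/bspecies' expected 0.10%, observed 0.093%; FP=none FN=none
```

Reading this: four mock pools were sequenced at 50 000 reads each with a
per-end switch rate tuned so ~1 % of reads land on invalid index pairs. The
estimator recovers c = 1.00 %, the threshold t = c² ≈ 0.01 % removes the
cross-sample leakage, and the single-specimen target — down to 1 in 1000
individuals, i.e. an expected relative abundance of 0.10 % — is detected in
every pool with no false positives. The same pipeline under combinatorial
indexing leaks ~800 cross-sample false-positive reads where unique dual
indexing leaks ~1.

The same steps are available as a CLI (`trapscreen simulate | curate | qc |
classify | contam | detect`); see `trapscreen --help`.

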