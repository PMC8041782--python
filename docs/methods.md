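# Methods

This note documents the models behind `trapscreen`, the parameter defaults
and why they hold, the conventions that pin down otherwise ambiguous
numerics, and what the synthetic benchmarks do and do not demonstrate.

## The detection problem

A bulk trap catch is a pool of N insects (here 100–1000) of mixed species;
the quantity of interest is presence of specific pest taxa, possibly at a
single specimen. Amplicon sequencing of three marker loci (COI, 12S, 18S)
turns the pool into per-locus read counts over amplicon sequence variants
(ASVs). Detection at the single-specimen level is limited not by depth but
by two error sources: reference-database error (wrong taxonomy on a matched
sequence) and index switching (reads mis-assigned between co-sequenced
libraries). The pipeline treats both explicitly.

## Switching model and the t = c² threshold

Each read carries an i5 and an i7 index identifying its library. The
simulator's model: independently per read and per end, with probability `s`
the index is replaced by a uniform draw from the in-use pool for that end
(the draw may return the original value — a silent non-event). This is the
simplest model consistent with single-end switching and a
uniform-destination assumption.

Under **unique dual indexing** (no index value shared between samples) any
visible single-end switch lands on a combination never applied during
library preparation. The single-end contamination rate is estimated from
the invalid-pair read fraction:

```
c = (R_invalid / R_total) × (C_offdiag / C_invalid)
```

where `C_offdiag` counts grid cells reachable from any valid pair by
switching exactly one end, and `C_invalid` the invalid cells among them.
Under unique dual indexing the factor is 1 and c is the plain invalid read
fraction; under combinatorial indexing some single-switch destinations are
other samples' valid pairs, invalid reads undercount switching, and the
factor scales the estimate up under the uniform-destination assumption.
A fully saturated combinatorial grid has `C_invalid = 0` and the rate is
reported as unidentifiable rather than guessed.

A read is silently mis-assigned to another sample only when **both** ends
switch onto that sample's pair, so the residual misidentification rate is
bounded by `t = c²`, which serves as a per-library relative-abundance
detection threshold: per library, any taxon strictly below t is zeroed.
Surviving abundances are deliberately **not** renormalised, so they remain
interpretable against the original library depth. The threshold comparison
is strict (`< t` removes) because the rule is phrased as "below the
threshold"; a taxon exactly at t survives. Worked example: c = 1.08 % gives
t = 0.011664 %, which prints as 0.01 % at two decimal places.

The "true contamination" targeted by the recovery benchmark is defined as
the expected invalid-pair read fraction under the switching model;
`synth.switch_rate_for_contamination` inverts the closed-form expectation
(Brent root-finding, tolerance 1e-12) to find the per-end `s` producing a
requested fraction.

## Reference curation

Four rules, applied in fixed order 1→2→3→4 (then optional primer trimming);
the first matching rule logs each removal, so the audit trail is
reproducible and no record is removed twice. The cascade is idempotent on
its own output.

1. **Length and duplicates.** Records shorter than 200 or longer than 3000
   bases are removed; bounds are exclusive for removal (exactly 200 or 3000
   is kept). A *duplicate* is an identical sequence carrying the same
   species label at the same locus; among duplicates the smallest record id
   survives. Taxon identity is part of the key on purpose: congeners
   legitimately share identical sequences at conserved loci (the 18S case),
   and exact-match species assignment needs both copies present to report
   the aggregate rather than an arbitrary single species.
2. **Insufficient identification.** Any whitespace-delimited token of the
   raw label or species name matching a configurable exclusion list
   (`sp.`, `nr.`, `aff.`, `cf.`, `gen.`, `complex`, `hybrid`,
   `environmental`, `uncultured`, `undescribed`), or a missing/incomplete
   binomial, removes the record. The default list is a superset guess and
   is configurable; real deployments should extend it.
3. **Contaminant screen.** Best identity against a symbiont contaminant
   panel strictly above 0.95 removes the record. Identity here is matches
   over alignment columns with end gaps free (the record may extend past
   the panel sequence). The bundled panel in the simulator is synthetic
   ("Symbiontella", generated sequences), labelled as contaminant lineage;
   it stands in for a curated *Wolbachia* panel in real use.
4. **Misannotation clustering.** Greedy centroid clustering at 0.99
   identity (global alignment, end gaps penalised), visiting records
   longest-first with record-id tie-break — the order is fixed because
   greedy clusters depend on it. Clusters whose members disagree at phylum,
   class or order are mixed; at the first discordant rank the members
   outside the majority label are removed. A tied vote anchors to the
   centroid's lineage: the founder (longest record) is kept and discordant
   members removed. This automates what would otherwise be a manual
   review of mixed clusters; removed records are all logged for review.

**Primer trimming.** Each record is aligned (infix mode) to the
best-matching in-house seed amplicon of its locus; the columns spanning the
seed's region between — and excluding — the primer binding sites define the
trimmed record. Records covering < 80 % of that region are removed (the
floor is configurable; nothing in the protocol fixes it). Coordinates are
0-based half-open internally and 1-based inclusive in logs.

Two curated exports: a genus-level lineage-string FASTA
(`>ID Root;Phylum;…;Genus`) for classifier training and a species FASTA
(`>ID Genus species`) for exact matching, both ordered by record id.

## Read QC

Expected errors EE = Σᵢ 10^(−Qᵢ/10) over Phred scores; reads with EE > 2,
any ambiguous N, or length ≤ 100 (the "> 100 bp" cut is exclusive, and is
applied after primer removal) are discarded, with one reason recorded per
read in the precedence EE → N → length. Primer demultiplexing is
IUPAC-aware and indel-free with a 1-mismatch tolerance (a conservative,
configurable default; the upstream tools leave this unstated); reads
matching forward primers of several loci are discarded as ambiguous.

**COI pseudogene screen.** Nuclear mitochondrial copies accumulate frame
shifts and internal stops. Each COI ASV is globally aligned to an in-house
amplicon of known reading frame; it is discarded when the net interior
indel length is not a multiple of 3, or when its translation in the
inherited frame (invertebrate mitochondrial code, table 5; configurable)
contains a stop. This pairwise-alignment check is a deliberate
simplification of codon-aware multiple alignment; it is exact for the
simulator's ASVs and adequate for amplicon-length sequences. The screen is
COI-only: rRNA pseudogene detection is a different and harder problem.

## Classification

Wang-style naive Bayes over 8-base words. Words are canonicalised
(lexicographic minimum of word and reverse complement) so classification is
strand-insensitive; distinct words, not multiplicities, score a query. With
N training sequences, word prior Pᵢ = (n(wᵢ)+0.5)/(N+1); genus-conditional
probability (m(wᵢ)+Pᵢ)/(M+1) over a genus's M sequences. The winning genus
maximises the summed log conditional probability; ties break alphabetically
for determinism.

Bootstrap: 100 iterations, each resampling ⌈W/8⌉ of the query's W distinct
words with replacement (classic defaults for this classifier family; only
the 80 % support cutoff is externally fixed). Per-rank support is the
fraction of iterations whose winner agrees with the overall winner at that
rank; the assignment truncates at the lowest rank where support ≥ 0.80
holds there and at every higher rank.

**Evidence floor.** A deterministic tie-break has a failure mode: a query
sharing essentially no words with the training vocabulary ties every
bootstrap draw and would inherit perfect support for the alphabetically
first genus. Queries whose fraction of training-vocabulary words falls
below `min_word_evidence` (default 0.05) are therefore returned unassigned.
This doubles as the exclusion of sequences outside the training set's
phylum coverage: ASVs unassigned at phylum are dropped from downstream
tables.

**Species.** Exact full-sequence match (forward or reverse complement)
against the species references. Several matching species — congeners
identical at a conserved locus — yield a slash-joined aggregate
(`Genus aepithet/bepithet`, epithets sorted), never an arbitrary single
species; the same aggregation map is applied to mock designs when scoring
detections, so expected and observed labels stay comparable.

## Detection calling

Per library and locus, taxon abundance is the read fraction at that locus;
the combined abundance is the arithmetic mean over loci with nonzero reads
for that library (loci without reads are excluded from the mean, not
counted as zeros). Detection is strictly positive post-threshold combined
abundance — no per-locus minimum count. Expected abundance is specimen
count / pool size (equal biomass assumed). False positives are detected
taxa absent from the design; false negatives are designed taxa not
detected. Locus-overlap counts partition distinct rank labels by the exact
subset of loci detecting them; group read proportions are classified-read
fractions pooled across loci, undefined (NaN) for libraries with no
classified reads.

## The simulator: what it emulates, what it does not

The generator's defaults are the study conditions the benchmarks run
under: pools of 100/250/500/1000 individuals with a single-specimen rare
target; 50 000 reads per library split evenly across three loci; loci of
300/250/280 bases with 2 % within-genus and 10 % between-genus divergence
(0 % within-genus at the 18S-like locus, creating indistinguishable
congeners); unit amplification biases unless a log-normal spread
(`bias_log2_sd`) is requested — the direction of real amplification bias
is well attested but its magnitude is assay-specific and deliberately
left configurable rather than calibrated.

Divergence is constructed, not sampled: each genus and each species mutates
a dedicated, disjoint block of positions of a shared root (block sizes
`round(divergence × length)`), so every within-genus identity strictly
exceeds every between-genus identity by construction, and zero within-genus
divergence yields byte-identical congeneric templates. This makes the
hierarchical-divergence contract a guarantee rather than a probabilistic
tendency; the price is that synthetic divergence is uniform rather than
clocklike.

One ASV per species per locus: sequencing error, intraspecific variation
and chimeras are not simulated — the pipeline consumes denoised tables, and
denoising itself is out of scope. The optional FASTQ emitter writes uniform
Q35 reads purely to exercise the QC module. Planted database defects use
"Z"-prefixed record ids so rule-1 deduplication deterministically keeps the
clean twin.

Consequently, the passing benchmarks demonstrate the pipeline's logic —
estimator consistency, threshold behaviour, curation completeness,
classifier calibration on cleanly separated taxa — under the stated
statistical model. They do not demonstrate robustness to denoising
artefacts, primer-binding bias, degraded DNA, skewed index-destination
distributions, or reference databases whose errors are subtler than the
planted classes.

## Problem sizes and seeds

Benchmarks run at: 200 seeds × 10⁵ reads (estimator recovery, tolerance
±0.2 percentage points around a true 1.0 %), 50 seeds (indexing-mode
contrast), 20 seeds × 4 pools × 5×10⁴ reads (end-to-end recovery), 50
random fixtures (curation), 1000 queries at 3 % divergence (classifier).
Every stochastic component draws from `numpy.random.default_rng` seeded via
CRC-tagged `SeedSequence` children of a single base seed, so all outputs
are reproducible bit-for-bit and independent streams do not collide.

## Known limitations

- The switching estimator's correction factor assumes uniform switch
  destinations; structured hopping (e.g. sequence-similarity-dependent)
  would bias it.
- The minority-lineage rule can mis-resolve a mixed cluster in which the
  *misannotated* records outnumber the correct ones; such clusters need
  manual review (all removals are logged).
- Aggregated species labels are only as good as the aggregation map;
  designs containing one congener of an aggregate are credited when any
  member of the aggregate is observed.
- Per-library relative abundance for thresholding is computed over all
  loci combined by default; a per-locus mode exists but changes what t
  means for loci with very uneven depth.
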