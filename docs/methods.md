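# Methods

## Assay model

The unit of analysis is a short bisulfite PCR amplicon: an insert sequence
on the bisulfite top strand, an ordered set of marker CpG positions between
the primer footprints, and the primer/adapter sequences. Coordinates are
0-based half-open internally; the 1-based genomic interval string is a
display label. Only the top strand (C→T chemistry) is modelled: amplicon
PCR with a fixed primer pair fixes read orientation, so bottom-strand
(G→A) alignment is unnecessary. This is a limitation for assays whose
primers do not fix orientation.

The packaged default assay is a 90 bp synthetic stand-in for the six-CpG
cardiomyocyte marker island (the true genomic insert sequence is not
distributed): six CpGs at realistic spacing between the published primer
locus-portions, which convert cleanly under bisulfite chemistry, plus the
published adapter overhangs stored verbatim. Any real assay can be
substituted through the YAML assay format.

For alignment the reference is converted in silico: every non-CpG C becomes
T (these positions are always unmethylated in vivo and double as
conversion-rate reporters), and every CpG C becomes the IUPAC code `Y`
(C or T), so both methylation states match with zero penalty and alignment
is methylation-unbiased.

## Synthetic data generator

The generator emulates the statistical structure the analysis assumes, with
defaults fixed to the study conditions:

| parameter | default | meaning |
|---|---|---|
| fragment mode / max | 150 / 200 bp | serum cfDNA fragment sizes |
| fragment dispersion | 0.2 (log-sd) | spread of the log-normal length law |
| conversion efficiency e | 0.99 | P(unmethylated C reads T) |
| inappropriate conversion | 0.005 | P(methylated C reads T) |
| sequencing error ε | 0.001 /base | substitution rate, both mates |
| read length | 150 bp ×2 | paired-end amplicon sequencing |
| cohort depth | 35,000–74,000 pairs | uniform per sample |
| cardiomyocyte u | 0.78 | fully-unmethylated haplotype fraction |
| ventricle u | 0.20 | mixed cell population |
| non-cardiac / buffy coat u | 0.001 | background tissues (< 0.2%) |
| methylated control u | 0.0 | universally methylated standard |

Fragment lengths are discretised log-normal with the mode at `mode_length`
(µ = ln mode + σ²) truncated at `max_length`; both printed constraints of
serum cfDNA (mode ~150, max 200) are honoured and the shape is the standard
cfDNA one. A fragment is amplifiable iff it spans both primer footprints;
emitted molecules are rejection-sampled from the amplifiable set, since PCR
performs exactly this selection. Neither ε nor the inappropriate-conversion
rate is measured by the assay itself; they are set so that fully methylated
DNA produces a fully-unmethylated background (≈ 0.005⁶ per molecule plus
error leakage) far below the assay's reported specificity bounds, which is
the regime the assay demonstrably operates in.

Each emitted read pair is one distinct molecule: PCR resampling is
degenerate (every molecule sequenced once), so counts are exactly binomial
and molecule- and read-pair-level counts coincide (the truth table carries
both explicitly). The assay has no UMIs, and the analysis counts read
pairs, so duplicate-induced variance is deliberately not modelled — real
libraries will therefore show somewhat wider replicate scatter than the
simulator. Also not modelled: indels, adapter read-through, index hopping,
strand-specific PCR bias, and base-quality variation (qualities are
constant Q37 and unused by the filters). Passing tests therefore establish
correctness of the analysis under the assumed generative model, not
robustness to these artefacts.

The default longitudinal cohort is a fixed 10-patient × 3-timepoint table
of true cardiomyocyte shedding fractions with per-timepoint medians of
0.018–0.020, three patients starting below the detection limit, and two
high outliers — the qualitative shape of the study cohort, whose per-sample
values were never published numerically.

## Alignment and filtering

Mates are merged first (2×150 bp reads fully overlap a <200 bp amplicon).
The merger scans relative placements of R1 against reverse-complemented R2,
largest overlap first (ties: smallest absolute shift, then leftmost),
scoring agreements minus disagreements over non-N bases; a placement with
≥ 95% overlap identity is accepted immediately, otherwise the best-scoring
placement wins if its identity reaches `min_identity` (default 0.75) over
at least `min_overlap` (default 20) bases. Overlap disagreements become
`N` — conservative, since base qualities are synthetic — which renders any
affected CpG unevaluable downstream; where one mate reads `N`, the other
mate's base is kept.

The merged molecule is placed by exhaustive ungapped scan over every offset
of the converted reference (exact and cheap at amplicon scale — a
seed-and-extend mapper would add approximation without benefit here),
minimising mismatches under the bisulfite rules: read T or C over a
non-CpG reference C is never a mismatch (conversion product / incomplete
conversion), CpG positions match C or T freely, and `N` is neither match
nor mismatch. Ties break to the smallest offset. Reads longer than the
reference are flagged unaligned rather than raising.

Filters mirror standard amplicon QC — merged "proper pair", "primary"
(placeable) alignment, insert size within the expected amplicon length ± 5
bp, mismatch rate ≤ 0.1 of aligned length. The insert window reflects that
a fixed-primer amplicon has a single expected insert; the mismatch ceiling
removes garbage while tolerating ε = 0.001 chemistry. The QC tally
partitions the input exactly (each molecule counted once, under its first
failing reason).

## Haplotype calling and quantification

Per molecule, each CpG position covered by the merged sequence is read as
C → methylated, T → unmethylated, anything else → ambiguous; uncovered
positions are ambiguous. Labels follow the all-or-nothing rule:
FULLY_UNMETHYLATED iff all CpGs unmethylated, UNEVALUABLE iff any CpG
ambiguous, OTHER otherwise. Non-CpG cytosine positions reading C or T are
pooled across molecules into the conversion-rate estimate with a
Clopper–Pearson interval; positions reading `N` are uninformative and
skipped. An optional per-molecule conversion-failure exclusion (few
converted non-CpG Cs and at least one unconverted) is not applied by
default, since the assay's published filtering does not include one.

The primary sample statistic is f = k/N over evaluable molecules; the
molecule ratio k/(N−k) is emitted as a secondary column because both
conventions ("fraction of total reads" and "unmethylated/methylated
ratio") are in circulation, and the choice matters at high signal.
Unevaluable molecules are excluded from the denominator: they carry no
haplotype information, and including them would bias f with the error rate.

The limit of detection is defined as the one-sided exact binomial upper
(1−α) bound on the pooled negative-control fraction (α = 0.05); the
published assay shows a detection-limit band without stating its
derivation, so this package adopts the most assumption-light reproducible
definition. Detection is strict exceedance. A spike-in series must include
a 0% level; the lowest detectable level is the smallest nonzero fraction
at which every replicate exceeds the LoD. The pre/post cohort comparison
is a paired two-sided Wilcoxon signed-rank p-value, reported descriptively
and never used for gating. Genome equivalents use f × mass / 3.3 pg, the
standard haploid-genome accounting, only when an input mass is supplied.

## Numerical and degenerate-input choices

* Exact binomial (beta-quantile) intervals throughout; the k = 0 LoD
  reduces to the closed form 1 − α^(1/N) (tested to 1e-12).
* Zero-CpG assays are valid (every molecule trivially fully unmethylated);
  zero evaluable molecules, empty control lists, and series without a 0%
  level raise explicit data/configuration errors instead of returning NaN.
* All generators consume a single integer seed through
  `numpy.random.SeedSequence` spawning, making every output byte-identical
  across reruns (gzip timestamps and filenames are pinned).
* Simulation and analysis problem sizes in the tests and the
  characterisation script use 50,000 read pairs per sample — the study's
  own per-sample depth scale — which makes binomial tolerances (3 SDs)
  sharp enough to be meaningful.

## Expected readout under the chemistry model

A tissue whose fully-unmethylated haplotype fraction is u yields an
expected pipeline readout of u·e⁶ (each of the six unmethylated CpGs must
actually convert to be read as unmethylated), i.e. ≈ 0.941·u at e = 0.99 —
for example ≈ 73.4% for u = 0.78. Recovery tests compare against this
chemistry-corrected expectation within 3 binomial SDs. Conversely,
published readouts measured *after* bisulfite conversion already include
this attenuation; users calibrating tissue profiles from such readouts may
prefer u = readout/e⁶.

## Known limitations

Single amplicon and single strand only; no indel handling; no real
base-quality model; the packaged insert sequence is synthetic; PCR
duplicate variance is not represented; the LoD definition is one of
several reasonable choices and affects which low-signal samples are called
detected.
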