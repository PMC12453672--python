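# Methods

## Problem and model

Standard PGT-A (preimplantation genetic testing for aneuploidy) sequences a
trophectoderm biopsy at ultra-low coverage and calls chromosome copy number
from binned read counts. Whole-genome ploidy abnormalities — triploidy,
genome-wide uniparental diploidy (GW-UPD), haploidy — are invisible to that
readout, because a genome-wide scale factor is absorbed by coverage
normalisation. `ploidyscope` recovers them from the allelic content of the
same reads, using three evidence channels plus a supervised classifier:

1. **Haplotype-frequency likelihood ratios.** For the reads inside a 100 kb
   window, the likelihood under a homolog-dosage hypothesis with k homologs
   and weights w is the exhaustive sum over read-to-homolog assignments

       L(reads | hyp) = Σ_a Π_r w_{a(r)} · Π_i F(S_i(a)),

   where S_i(a) is the set of (position, allele) observations assigned to
   homolog i and F is the joint frequency of that pattern among the phased
   panel haplotypes (F(∅)=1; zero counts floored at ε = 1/(2N)).
   Hypotheses: monosomy (1), disomy (1/2, 1/2), SPH — a duplicated single
   parental homolog — (2/3, 1/3), and BPH — both parental homologs from one
   parent plus one from the other — (1/3, 1/3, 1/3). Reads assigned to one
   homolog must be jointly consistent with a single panel haplotype, so
   linkage disequilibrium is what separates three distinct homologs from a
   duplicated one. Window statistics use multiple sampling: n_draws = 16
   draws of m = 3 distinct reads, recording the mean and variance of each
   pairwise log-ratio (natural log). Windows with fewer than m usable reads
   are null. Adjacent windows can be merged into segments pooled to a
   target read count (default 12), with pooled variance Σvar/k².

2. **Heterozygosity and runs of homozygosity.** A site is informative with
   ≥ 2 reads; heterozygous when both alleles are seen. Per-chromosome rates
   are standardised into Z-scores against a diploid baseline (mean/SD per
   chromosome from known diploid samples; SD floored at 1e-3). ROH use
   non-overlapping 1 Mb windows: windows below het rate 0.02 are merged
   (1-window gap tolerance); a region must contain at least two
   sub-threshold windows. The two-window minimum exists because at 0.2
   reads/site a single 1 Mb window has a non-negligible chance of showing
   zero heterozygous sites in a true diploid; requiring two consecutive
   windows drops the diploid false-call rate to near zero while leaving
   real ROH (which span many megabases) untouched. GW-ROH is flagged when
   ROH cover > 80% of the autosome — between homozygous GW-UPD (~100%) and
   consanguinity-scale ROH (< 20%).

3. **Copy number.** 600 kb bins are corrected for GC (lowess), divided by
   mappability and the diploid per-bin baseline, and median-rescaled to
   copy ratio 2.0. A 5-state Gaussian HMM (means 1.0/1.5/2.0/2.5/3.0, stay
   probability 0.999, emission SD from the MAD of autosomal bins, floored
   at 0.05) yields Viterbi segments; states follow the copy-ratio bands
   <1.3 deletion, [1.3, 1.7) mosaic deletion, (2.3, 2.7] mosaic
   duplication, >2.7 duplication, which correspond to a 30–70% mosaic cell
   fraction. Reportable events: ≥ 1 Mb (full), ≥ 10 Mb (mosaic).

The classifier consumes 11 features (window proportions/means of the four
LLR contrasts, per-chromosome SDs of LLRs, het rates and Z-scores, the
aneuploidy count and the SD of per-chromosome median copy ratios) out of a
documented pool of 23 candidates. The 12 non-final candidates are built by
systematic analogy — the same statistic families (proportion of windows
> 0, window mean, positive-window mean, per-chromosome SD) applied to the
remaining hypothesis contrasts, plus genome-wide het rate, mean |Z|, and
the autosomal ROH fraction. They exist to exercise the selection pipeline
(Gini ranking → |r| > 0.8 correlation components → VIF > 10 with
importance below the 0.033 reference); the shipped model uses the 11
finals directly.

Classifier: Random Forest, 100 trees, depth 15, min_samples_split 4,
min_samples_leaf 2, √p features per split, per-class balanced bootstrap;
class probabilities are tree-vote fractions and the clinical call is
majority vote with an *indeterminable* outcome when QC failed upstream,
the vote is tied, or the top fraction falls below τ = 0.6. SVM and
logistic-regression baselines run through the identical cross-validation
folds for paired comparison.

## Interpretation choices on ambiguous definitions

- The printed copy-ratio thresholds 23/27/17/13 are read as 2.3/2.7/1.7/1.3
  on the diploid = 2.0 scale (decimal separators lost in typesetting);
  the resulting 1.3–1.7 / 2.3–2.7 bands match the stated 30–70% mosaicism
  detection window exactly.
- The "PGT-A score" feeding the score-variance feature is taken as the
  per-chromosome median copy ratio; its SD across autosomes is the feature.
- The ROH "Euclidean distance" is computed between a region's window-het
  vector and the mean het level of non-ROH windows.
- SPH is one hypothesis with weights (2/3, 1/3): without parental DNA the
  identity of the duplicated parent is unobservable, so the two parental
  variants collapse.
- Haploid embryos are labelled with the GW-UPD class for training: their
  evidence signature (monosomy-dominant LLRs, global homozygosity) matches
  the homozygous GW-UPD pattern, and the clinical output classes are
  diploid / triploid / GW-UPD / indeterminable.
- Sample SDs use n−1 throughout. Coordinates are 1-based inclusive at
  interfaces; window arithmetic is 0-based half-open internally. Sex
  chromosomes are excluded from every statistic; the simulator still emits
  X to exercise the exclusion.

## The synthetic cohort generator

No sequencing data accompanies the method, so the package ships a
generator that emulates every cohort class end to end.

**Reference panel.** msprime coalescent per chromosome (population size
5 000, 200 haplotypes, mutation rate 2.4e-7 giving ~5 SNP/kb after
ascertainment), with the site list ascertained to MAF ∈ [0.10, 0.5] — a
frequency-ascertained common-SNP list, as a dbSNP-derived target set is in
practice. The analysis loader's own MAF filter remains [0.01, 0.5].
Recombination follows a human-like hotspot map: 1 kb hotspots every 60 kb
with population-scaled intensity ρ = 5 per hotspot and ρ = 0.05 across
each cold block, giving tight LD within blocks, partial decay across
hotspots, and ~200 near-independent genealogies per chromosome.

**Desk-scale genome.** 22 autosomes plus X, 12 Mb each. Chromosome length
and the panel parameters are scaling choices: they were set so that the
information regime matches the one the method operates in on real data —
LD blocks on the order of the 100 kb likelihood window, chromosomes that
average over hundreds of independent genealogies (so inter-individual
heterozygosity variance is as negligible as it is between real humans),
thousands of informative (≥ 2-read) sites per sample, and per-site
heterozygosity ~0.2–0.3 at common SNPs. With shorter chromosomes or
uniform recombination the evidence per sample is artificially scarce or
the baseline artificially noisy, and class clouds overlap for reasons
that have nothing to do with the method; the chosen scale restores the
separability the method actually has at genome scale while keeping the
full pipeline within desk runtimes.

**Parents, meiosis, karyotypes.** Parental diploids are mosaic copies
along the panel (per-site switch probability 4e-3), so embryos are not
verbatim panel members. Gametes recombine with Poisson(λ = 1.5) crossovers
per chromosome at uniform breakpoints, recording tract provenance.
Classes: diploid (1 maternal + 1 paternal gamete), digynic/diandric
triploid (two distinct same-parent gametes + one other), homozygous GW-UPD
(one gamete at dosage 2), hybrid GW-UPD (two distinct same-parent gametes
— their identical-by-descent tracts become ROH), haploid; aneuploidies and
segmental events modify per-homolog dosage, with read-level mosaic
fractions blending base and event dosages.

**Evidence model.** Each SNP site receives Poisson(d = 0.2) reads; each
read picks a homolog proportionally to dosage and reports its allele,
flipped with probability e = 0.002; with probability ρ a read comes from an
unrelated diploid contaminant (admixture). Reads cover exactly one SNP
site. Bin counts are Poisson around 200 × (dosage/2) per 600 kb bin with a
mild concave GC bias and per-bin mappability. Depth and error were chosen
for the typical ulc-WGS PGT regime.

**What the generator does not emulate** — and hence what passing tests do
not establish about real data: amplification artefacts and allelic dropout
of whole-genome amplification, reference-alignment bias, population
stratification or panel mismatch between sample and reference, real
recombination hotspot structure, chimeric reads, and segmental mosaicism
of the biopsy itself. Results on the synthetic cohorts demonstrate the
pipeline's correctness and its statistical behaviour under the stated
evidence model, not clinical performance.

## Numerical and degenerate-input behaviour

- Joint frequencies are exact rational counts over N haplotypes; the ε
  floor only replaces exact zeros, keeping the antitone property intact
  elsewhere.
- Likelihood sums are evaluated with per-subset frequency tables
  (2^m − 1 subsets per draw) and precomputed assignment coefficient
  matrices; m = 3 keeps the k^m sum trivial.
- Windows with all reads identical produce zero LLR variance (ddof = 1
  over identical draws); segments with zero pooled variance report a NaN
  z-score rather than ±inf.
- Chromosomes with < 3 bins yield one low-confidence CNV segment; bins
  below the mappability floor must stay under 20% of the genome.
- Zero-coverage chromosomes are flagged missing and excluded from
  features with a QC flag; samples with fewer than 20 usable LLR windows
  are QC-failed and classified indeterminable without model invocation.
- VIF is computed by direct least-squares regression with R² clipped away
  from 1 (1e-12), so singular designs yield large finite VIFs and are
  flagged rather than crashing. Importance ties inside a correlation
  component break lexicographically.

## Problem sizes used in the shipped experiments

The default verification cohort is 50 diploid / 25 triploid / 15 GW-UPD
samples plus 20 baseline diploids, evaluated on a stratified 30% hold-out;
spot-check experiments in the test suite use 2–6 chromosome genomes, 8–20
replicate cohorts, and scaled-down Monte-Carlo loops (600 gametes for the
crossover distribution, 20 seeds for false-positive ROH rates). These
sizes are the package's chosen experiment scale; all statistics are
computed fresh at run time.

## Known limitations

- Polyploidy with identical chromosome sets (e.g. 92,XXXX), GW-UPD from
  two identical non-recombinant sets, and mosaic triploidy/GW-UPD are out
  of scope by design; their evidence signatures are degenerate or blended.
- Parental origin of the extra set is not assigned (digynic and diandric
  triploids are one class); no single-chromosome UPD calling.
- Heavy contamination shifts every channel toward the diploid mixture and
  is only handled as a QC concern, not deconvolved.
- The indeterminable rule is a vote-confidence threshold, not a calibrated
  posterior.
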