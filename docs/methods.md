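# Methods

## Background and model

Pooled first and second polar bodies of a euploid oocyte carry **three
chromatids** of every chromosome: two from the first polar body and one from
the second. Copy-number screening of this material therefore has a trisomic
euploid baseline, and both analysis arms of this package are built around
that fact.

### Sequencing arm

Low-pass single-cell sequencing after whole-genome amplification (WGA)
yields read counts per genomic bin that are proportional to local chromatid
number but heavily distorted: WGA amplifies unevenly at the bin scale,
produces over-dispersed counts, and occasionally drops regions out
entirely; GC content biases amplification smoothly along the genome.

The caller proceeds as follows.

1. **Ingestion.** Aligned reads (BAM/SAM via pysam, or a plain
   `chrom/start/mapq` TSV) are filtered: unmapped, secondary and
   supplementary records are removed, as are reads with MAPQ < 5 and reads
   on chromosomes outside the analysis set (22 autosomes + X; Y is excluded
   because polar bodies are maternal). Reads are represented by their
   leftmost position only and duplicates are kept. Coordinates are 0-based
   half-open throughout.
2. **Blacklisting.** Reads of a merged euploid reference pool are counted
   in fixed 100-kb bins; bins strictly above the 0.9985 or strictly below
   the 0.1 empirical quantile (linear-interpolation/type-7) of the
   reference's genome-wide distribution are blacklisted, and reads of both
   sample and reference falling there are discarded. The blacklist is
   computed from the **reference only**: applying the 10% low-quantile cut
   to the sample's own counts would mask genuine whole-chromosome losses,
   since one chromosome is only ~4% of the genome and a lost chromosome's
   bins are exactly the lowest counts.
3. **Variable-width binning.** ~1-Mb bins are built so that each holds the
   same number of reference reads T (the median fixed-1-Mb reference
   count), with boundaries at midpoints between flanking reference reads;
   low-mappability (or blacklisted) regions become genomically wider bins.
   A terminal bin holding under T/2 reference reads merges into its
   neighbour, so bins tile each chromosome exactly.
4. **Reference normalisation.** Because terminal bins are truncated or
   merged, bins hold only *approximately* T reference reads; each sample
   bin count is rescaled by (median reference bin count)/(reference count
   in that bin). After this step the expected count is uniform across bins
   for a flat karyotype. Without it, merged terminal bins (up to 1.5 T)
   masquerade as gains.
5. **GC correction.** A 2nd-degree polynomial of count on bin GC fraction
   is fitted over usable bins; counts are divided by the fitted curve and
   rescaled to preserve the mean. Non-positive fitted values are clamped to
   the 1st percentile of the curve. Bin GC is the length-weighted mean of
   the overlapping GC windows.
6. **Hidden Markov model.** Six states: a zero-inflation state (point mass
   at zero count) and somy 0–4. Emissions are tied negative binomials: an
   s-somy bin emits NB(mean = s·μ, var = s·σ²) for s = 1..4, where μ is the
   per-chromatid unit mean. The 0-somy state uses mean ε·μ with ε = 0.1 —
   residual misalignment background — because a second point mass at zero
   would be unidentifiable against zero-inflation. The NB is parameterised
   by (mean, variance) with variance floored at 1.05·mean. Initialisation:
   μ₀ = (10%-trimmed mean of positive counts)/3, σ₀² = moment variance/3,
   sticky transitions (0.99 self), uniform start. Fitting is Baum–Welch
   over per-chromosome sequences (no transition crosses a chromosome
   boundary) with per-bin scaling of the recursions; the tied (μ, σ²) pair
   has no closed-form M-step under NB likelihoods, so it is updated by
   numerical maximisation of the expected complete-data log-likelihood and
   the candidate is accepted only if it improves it (generalized EM), which
   keeps the log-likelihood trace non-decreasing. Three restarts with
   jittered transition matrices are run and the best likelihood kept;
   restarts reduce — but do not eliminate — the local optima that manifest
   as baseline shifts in real data.
7. **Baseline anchoring.** The Viterbi path is decoded; if the state
   occupying the most bp is not 3-somy, μ is rescaled by (modal somy)/3 and
   the model refitted, up to three times. Failure sets `baseline_flag` and
   returns the best-likelihood fit; a zero-inflation-modal decode raises an
   error (sample unanalysable). This re-anchor loop is this package's
   mechanism for the "most frequent state = 3-somy" constraint; it is
   surfaced in every report rather than hidden inside the fit.
8. **Segments and calls.** Runs of equal decoded somy become segments;
   zero-inflation bins are absorbed by the larger flanking segment (ties go
   left). Segments shorter than 10 Mb are reassigned to their dominant
   neighbour — rather than deleted — so each chromosome stays fully tiled,
   iterating until stable. Each chromosome is called by the somy with the
   greatest bp (ties prefer the state nearer 3, then the lower somy); a
   chromosome with no decoded bins is a `no-call`, never silently euploid.
   A sample is *aneuploid* if ≥1 chromosome deviates, and *highly complex*
   if ≥12 of 23 do. X is called exactly like an autosome: three maternal
   X chromatids are expected.

### aCGH arm

Expected mean log2 ratios against a 3-chromatid baseline are
log2(4/3) = 0.42 for a gain and log2(2/3) = −0.58 for a loss (versus 0.58
and −1 on a diploid baseline). Thresholds sit at the copy-number midpoints:
gain above log2(3.5/3) = 0.22, loss below log2(2.5/3) = −0.26. An autosome
is called aneuploid only when its mean log2 ratio against **both** the male
and female control crosses a threshold in the same direction — a
single-channel excursion is treated as a control-specific artifact (the
either-channel reading of the rule is defensible too; this package uses
the conservative one). Chromosome X uses the female channel only.
Comparisons are strict, so borderline values never silently classify.
The DLR spread (DLRS) quality metric is the robust SD of adjacent-probe
log2 differences within chromosomes, IQR/(1.349·√2); for iid Normal probe
noise it estimates the probe SD. A robust scale is used deliberately:
single-cell WGA profiles carry outlier probes.

### Concordance

Calls from the two arms are cross-tabulated at sample level
({euploid, aneuploid}) or chromosome level ({euploid, gain, loss}; all
sub-baseline somies map to "loss"). Overall concordance is trace/total;
per-class concordance is conditioned on the rows of method A (by
convention the aCGH classification). Highly complex samples can be
excluded by id, reproducing the cohort-filtering step; the package always
reports its own denominators.

## Synthetic data

The simulator provides ground truth for every other module.

* **Karyotypes** are chromatid counts per chromosome (0–4, baseline 3)
  plus optional segmental events (interval + chromatid delta).
* **Reads** are drawn per GC-window with probability proportional to
  local copy number × GC bias (multiplicative, slope per unit GC deviation
  from the genome mean) × a per-window lognormal WGA factor × a gamma
  factor tuned to a target variance/mean ratio; zero-inflated windows emit
  nothing. Defaults — gc_slope 0.8, wga_sigma 0.25, zero_inflation_p 0.01,
  nb_dispersion 2.0 — are chosen as moderate single-cell WGA severity: the
  lognormal term reproduces the undulating bin-scale patterns and baseline
  ambiguity seen in real WGA profiles at a level where calling should
  still succeed, matching a cohort in which the analysis worked for nearly
  all samples. The euploid reference pool is simulated with milder noise
  (wga_sigma 0.1), as merging several samples averages amplification
  noise away.
* **aCGH profiles** place probes proportional to chromosome length at
  log2(copies/baseline) + Normal(0, σ) with σ equal to the target DLRS
  (0.57, the cohort mean); the male-control X channel sits one log2 unit
  higher, reflecting the single X of an XY control.
* **What is not emulated:** mappability structure from real alignment
  (the synthetic GC landscape is smooth and deterministic, not a genome
  track), read lengths and sequencing error, polar-body fragmentation or
  degradation gradients, centromeres/acrocentric arms, and
  amplification failure of one polar body. Passing tests therefore show
  the algorithmic machinery is correct under a realistic noise *model*,
  not that real-sample performance matches the cohort's.

Two layouts exist: full GRCh38 chromosome lengths (for physically sized
segmental events), and a 1:30-scaled toy genome (~101 Mb) so that
million-read end-to-end regimes run in roughly a second each — the scale
used throughout the test suite except where event sizes in Mb matter.

## Numerical choices and degenerate inputs

* Quantiles are type-7 (linear interpolation); masking uses strict
  inequalities, so a degenerate all-equal distribution masks nothing.
* The NB log-pmf is computed via gamma functions, so GC-corrected
  (non-integer) counts are valid arguments.
* Forward–backward subtracts each bin's max emission log-probability
  before exponentiation and rescales per bin; EM stops when the relative
  log-likelihood gain falls below 1e-4 (or at 500 iterations).
* Ties: modal-somy ties prefer the state nearest 3, then the lower somy;
  zero-inflation absorption ties go left.
* A chromosome whose decoded span is shorter than the 10-Mb minimum
  segment size keeps its raw segments with a warning (routine on the toy
  genome).
* Downsampling is uniform without replacement via a seeded generator;
  identical seeds give identical subsets.

## Problem sizes used in the checks

The automated checks run the toy genome at 1 M reads per sample
(50-sample end-to-end recovery), and full-length chromosomes at 300 k
reads for segmental-event detection (10 seeds per event size, sizes 30–60
Mb tested ascending). The acceptance script reports the smallest event
size detected in ≥9 of 10 seeds; with the default noise model this is
30 Mb, comfortably inside the 50-Mb working bound quoted for ~300 k-read
low-pass data.

## Known limitations

* The re-anchoring loop can fail on genuinely bimodal samples (flagged,
  not fixed); clinical review of flagged samples is out of scope.
* Breakpoints are bin-resolution; no sub-bin refinement.
* Mosaicism is deliberately not modelled (absent in polar bodies).
* The aCGH classifier is thresholds-only; it does not reproduce the
  manual clinical review that can overrule thresholds on segmental or
  borderline cases.
* Whole-genome ploidy errors (e.g. triploidy) are invisible to both arms,
  as both are relative-dosage methods.
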