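# Methods

## Overview

`gliocnv` turns binned read counts from low-pass long-read whole-genome
sequencing into tumor-fraction-aware copy-number calls for the CNV markers
that drive adult diffuse-glioma classification (1p/19q codeletion,
CDKN2A/B homozygous vs hemizygous deletion, EGFR amplification, chromosome
7 gain with chromosome 10 loss), and renders the result as a single HTML
report. The pipeline is:

1. count reads per fixed 500-kb bin (MAPQ ≥ 20, secondary and supplementary
   records dropped, leftmost-aligned-base assignment), or ingest a
   precomputed fixedStep WIG;
2. correct GC and mappability bias, exclude centromeric bins, express the
   result as median-centered log2 copy ratios, optionally subtract a panel
   of normals;
3. segment with a tumor-fraction-aware HMM and estimate tumor fraction by a
   likelihood grid scan;
4. call per-marker statuses, using an admixture-calibrated baseline to
   separate homozygous from hemizygous CDKN2A/B deletions;
5. apply a deterministic WHO-CNS5-style rule engine and render the report.

## Copy-ratio model

A bulk sample with tumor fraction `t` whose tumor cells carry `c` copies of
a locus (normal cells diploid) has expected log2 ratio

    mu(c, t) = log2( (t·c + 2(1−t)) / 2 ).

`mu(2, t) = 0` for every `t`; deviations shrink toward 0 as `t` falls,
which is why a fixed log2 threshold cannot grade deletions in impure
samples. Copy values reported in marker calls are the diploid
back-transform `2·2^log2`, averaged over the valid marker bins.

## Bias correction

Stage 1 fits count versus GC fraction non-parametrically: 51 knots across
the observed GC range, median count per knot, then a moving-average smooth
spanning 30% of the GC range; each count is divided by its interpolated
fit. The fit is scale-equivariant, so log2 ratios are exactly invariant to
sequencing depth. Stage 2 divides by per-bin mappability and drops bins
below a threshold (default 0.75). Centering uses the median over valid
autosomal bins only; sex chromosomes never influence the diploid baseline.
Bins are invalid when masked (centromere ± 1 bin by default), zero-count,
missing GC, or low-mappability; invalid bins never regain validity
downstream. Panels of normals are aggregated per bin by the median (robust
to one aberrant normal); bins invalid in ≥ 50% of members are invalidated,
and the profile is re-centered after subtraction.

## Segmentation and tumor fraction

The HMM runs over integer copy states 0..5 (5 means "≥ 5") per chromosome
independently, with uniform initial distribution, stay probability
`1 − switch_prob` (default `switch_prob = 1e-4`) and uniform off-diagonal
transitions. Emissions are Gaussian around `mu(c, t)` with a shared
standard deviation, estimated by default from the median absolute
deviation of within-chromosome first differences
(`sd = 1.4826·MAD/√2`, floor 0.01) — a noise estimate insensitive to
segment structure. The `c = 0, t = 1` center is clamped at −8 log2 units.
Invalid bins are bridged by a single transition without emitting.

**Neutral-state prior.** Each bin's emission score carries an additional
log-prior `−α·|c − 2|` with `α = 0.1` (`neutral_state_bias`). This term is
what makes tumor fraction identifiable: without it, any profile whose
aberrant copies `c` all satisfy `2c − 2 ∈ {0..5}` is *exactly*
likelihood-tied with a halved-purity interpretation (`t/2`, every
deviation doubled — the classic purity/ploidy ambiguity), and a
smaller-`t` tie-break would always pick the wrong branch. The prior
resolves the tie deterministically toward the least-aberrant genome, i.e.
the true `t`, with a margin that grows with the number of altered bins. α
is deliberately small so that it acts as a tie-breaker, never overriding
real signal: at the lowest purity the package targets (t = 0.2, sd 0.1)
the per-bin emission evidence for a single-copy loss (~1.2 log units)
still exceeds α by an order of magnitude. Larger values were rejected
because they bias the zygosity reading of small focal deletions toward
the less-aberrant hemizygous state near the `t = 1` grid edge.

Tumor fraction is estimated by running Viterbi at every `t` on a grid
(0.05..1.00, step 0.01) and keeping the best path score; exact ties break
toward smaller `t`. The reported likelihood is the joint log-probability
(including the prior) of the reported path, verified in tests against an
independent re-scoring and, on small instances, against exhaustive path
enumeration. If the winning path is entirely copy-neutral the profile
carries no information about `t`; the result is flagged non-informative
and downstream deletion calls are suppressed.

A genuine limitation remains: a sample whose only alteration is a focal
hemizygous deletion is intrinsically ambiguous (hemizygous at `t` vs
homozygous at `t/2` fit equally well up to the prior), and a focal
homozygous deletion at `t ≤ 0.5` has an in-grid hemizygous reading at
`2t`. Chromosome-scale co-alterations — near-universal in the tumors this
tool targets — anchor the estimate and remove the ambiguity; the
deletion-discrimination studies therefore plant a chr10 loss alongside the
CDKN2A/B event.

## CDKN2A/B deletion baseline

The calibrator mixes a normal count profile with a homozygous-deletion
tumor profile at fractions 0.1..0.9 (both depth-normalized first, so the
fractions are molecular), pushes each mixture through the correction
pipeline, and fits ordinary least squares of the CDKN2A/B copy value on
the known fraction. Noiseless algebra gives `copy(t) = 2 − 2t` exactly
(slope −2); the shipped default artifact, fitted on a synthetic noiseless
series (see `scripts/make_default_baseline.py`), reproduces it to < 1e-4
and is labeled synthetic in its provenance. The hemizygous expectation is
the analytic `2 − t`; only the homozygous relation is fitted, since that
is the one an assay must calibrate. Classification of an observed copy
value at estimated tumor fraction `t̂` is nearest-expectation with cuts at
the midpoints, so the homo/hemi margin is `t̂/4` on the copy scale — the
purer the tumor, the safer the call. The HMM's modal state over the
marker bins gates deletion *presence*; the baseline decides only
*zygosity*. This prevents the nearest-expectation rule from conjuring
losses at tiny, non-informative `t̂`, where the neutral/hemizygous cut
approaches the neutral expectation.

## Marker and composite calls

Arm and whole-chromosome markers are called from the fraction of valid
bins in an altered state, with a completeness threshold of 0.8: the
1p/19q codeletion that defines oligodendroglioma is a *complete* arm
loss, so partial losses (fraction 0.2–0.8) are surfaced in the evidence
note but not called. Arms with fewer than 5 valid bins are indeterminate.
EGFR amplification requires the capped top state (≥ 5 tumor copies),
distinguishing it from single-copy gain (states 3–4). Composites:
codeletion = loss on both 1p and 19q; +7/−10 = chr7 gain/amplification
and chr10 loss; indeterminate inputs propagate.

The rule engine is total and deterministic over every combination of
statuses and IDH states: codeletion → oligodendroglioma; otherwise
diffuse-glioma CNV evidence with IDH mutant/unknown → astrocytoma; +7/−10
or EGFR amplification with IDH wildtype/unknown → glioblastoma
(molecular), overriding the astrocytoma reading (the override is recorded
in the fired rules); CDKN2A/B homozygous loss → grade-4 support regardless
of lineage. IDH status is advisory — CNV data cannot determine it — and
every output is phrased as decision support with a fixed disclaimer.

## Simulator and what the tests show

The generator draws per-bin counts negative-binomially around
`depth_lambda · gc_bias(gc) · (t·c + 2(1−t))/2`, with a deterministic
smooth GC track shared by all samples on a grid. Defaults: 100 reads/bin,
dispersion 20. Note that dispersion 20 imposes a per-bin log2 noise floor
of `√(1/20)/ln2 ≈ 0.32` at any depth; that regime supports arm-level
calling but can never resolve a 2-bin focal deletion against the Viterbi
switch penalty. The studies that exercise focal events therefore use
deeper, less overdispersed conditions (depth 1000, dispersion 400 →
per-bin log2 noise ≈ 0.09), matching the ~0.1 log2-unit regime the
segmentation studies assume; the HMM-recovery studies simulate directly in
log2 space at sd 0.1. The scenario presets (neutral, oligodendroglioma-
like, gbm-like, astro-grade4-like) use the deep conditions.

The simulator emulates bin-level depth, GC bias, overdispersion, and
admixture. It does not emulate read-level nanopore error profiles, real
mappability structure, replication-timing or batch artifacts, subclonal
heterogeneity, or genuine germline CNVs — passing tests therefore
demonstrate correctness of the algorithms under the stated noise model,
not clinical performance on patient data.

## Numerical and degenerate-input choices

- Reads are assigned to the bin of their leftmost aligned base
  (deterministic for long reads spanning bins).
- A degenerate GC range skips the GC stage with a recorded warning; fewer
  than 50 valid bins, or GC annotation below 80% of non-excluded bins, is
  an error.
- Tumor-fraction estimation requires ≥ 100 valid bins (configurable).
- Grid ties in the tumor-fraction scan go to the smaller value; the
  non-informative flag marks all-neutral paths.
- WIG I/O is 1-based fixedStep with step = span = bin size; internal
  coordinates are 0-based half-open; integer counts round-trip bit-exactly.
- Reports embed the SVG plot inline, pin the SVG hash salt and suppress
  timestamps by default, so identical inputs render byte-identical files.

## Problem sizes

The test suite and the acceptance script run everything on the hg38 grid
(6,188 bins at 500 kb) or smaller toy grids: 200 exhaustively-enumerated
HMM instances (≤ 8 bins, ≤ 4 states), 20 replicates per tumor fraction for
recovery, 20 seeds per condition for zygosity discrimination and scenario
recovery, and 9-point admixture series for the baseline.

## Known limitations

- 500-kb resolution: events much smaller than a bin dilute below
  detectability; CDKN2A/B and EGFR each span 1–2 bins by design.
- Ploidy is fixed at 2; whole-genome doubling would be misread.
- No subclonal modeling; tumor fraction is a single global parameter.
- The shipped deletion baseline is synthetic; laboratories should refit it
  from their own matched normal / homozygous-deletion samples
  (`gliocnv fit-baseline`).
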