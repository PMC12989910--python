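# Methods

## Problem and model

Hybrid-capture sequencing of a small diagnostic panel produces two read
streams: on-target reads over the ~0.15 Mb of probed exons and
off-target reads scattered genome-wide by non-specific hybridisation.
Both carry copy-number signal. The pipeline bins the genome — panel
intervals verbatim as *target* bins (the panel is too small to be worth
sub-splitting), and the remainder of each chromosome, clear of a 5 kb
margin around every target, as *antitarget* bins of ~100 kb (each
contiguous accessible region is cut into `floor(len/100 kb)` windows;
the last window absorbs the remainder, sub-window leftovers are
dropped).

For a tumour of purity *p* with a region at total copy number *CN* in a
diploid background, the expected bin-level copy ratio is the
two-population mixture `r = p·CN/2 + (1 − p)` and the observed log2
ratio is `log2 r` (floored at −8 when the mixture is zero). All
downstream behaviour follows from this attenuation: at the ±0.5
arm-call threshold, single-copy losses are callable above ~59% purity
and single-copy gains only above ~83%, while CN ≥ 20 amplifications
remain far above threshold at any purity in the cohort range. Sample
purity is simulator truth here and is never inferred; absolute-ploidy
shifts (near-haploid/tetraploid genomes) are out of scope.

## Pipeline stages and numerical choices

**Normalisation.** Within each stream separately: expected count per bin
is the stream total split proportional to bin length; the per-bin value
is `log2((n + 0.5)/(expected + 0.5))` (pseudocount 0.5 keeps empty bins
finite), centred so the length-weighted median over autosomal bins is
zero. Streams are normalised separately because capture efficiency
differs by orders of magnitude between them. Median centring assumes
less than about half the genome is altered; heavily aneuploid genomes
(e.g. choroid plexus tumours) shift the baseline, which is the same
caveat that applies to the real assay.

**GC correction.** Bins are ordered by GC fraction and a rolling median
(window 101 bins, truncated at the edges, shrunk with a warning when a
stream has fewer bins) is subtracted, then genome order is restored.
A rolling median is not an exact projection: applying the corrector
twice moves values by a small residual (~1e-2 on flat data), an order of
magnitude below the first pass. The corrector is applied to every
reference-pool sample, where it is unconditionally safe (flat profiles
carry no signal to erode), but **not** to tumour samples: in heavily
aneuploid genomes the altered bins shift the windowed medians and the
"trend" estimate absorbs real copy-number signal — measurably eroding
single-copy gains at desk-scale noise. Design-shared GC bias is instead
cancelled by the pooled reference, which is precisely the reference's
job; the per-sample corrector remains available
(`normalize_sample(..., gc_correct=True)`) for assays where
sample-specific GC variation dominates.

**Pooled reference.** At least two (by default eight) copy-neutral
samples are normalised, GC-corrected and pooled: per-bin expected log2
is the across-pool mean, spread is 1.4826 × MAD. Bins with fewer than
10 pooled reads or spread above 1.0 are masked and dropped from every
downstream statistic. Sample-minus-reference ratios are weighted
`1/(spread² + 0.01)`, rescaled to a maximum of 1, and re-centred on the
autosomal length-weighted median.

**Segmentation.** Circular binary segmentation per chromosome: the
candidate split is the arc (i, j] maximising the weighted two-sample
statistic `|m_in − m_out| / sqrt(1/W_in + 1/W_out)`; it is accepted when
it exceeds the (1 − α) quantile of the same maximised statistic under
seeded permutations of the (value, weight) pairs (α = 0.01, 1000
permutations, early futility stopping once enough exceedances have
accumulated to settle the outcome), and the procedure recurses.
Chromosomes with fewer than 4 bins are single segments without a test.
Two tractability choices, both applied identically to observed data and
permutations so the test stays exact at level α: (i) the maximisation
runs over a restricted arc-length grid (every length up to 32 bins, the
mirrored lengths at the complement end, and a 1.25× geometric grid
between; sequences of ≤ 64 bins are searched exhaustively), and
(ii) accepted splits are refined by an exhaustive search between the
flanking grid lengths, so reported breakpoints match the brute-force
argmax. Finally, adjacent segments are merged while the gap z-score in
the weighted metric is below 3 × the robust (MAD-based) per-unit-weight
residual sigma. A flat gap threshold proportional to bin noise was
rejected during design: at desk-scale noise it sits on top of the
single-copy event amplitude at high purity and absorbs true ~20-bin
focal gains, whereas the SE-scaled test merges broad same-level segments
while never absorbing short high-amplitude events.

**Arm calls.** Length-weighted mean log2 per comparable arm — the 39
autosomal arms excluding the five acrocentric p-arms; sex chromosomes
are excluded throughout — with inclusive three-class thresholds
(gain ≥ +0.5, loss ≤ −0.5). Bins straddling the centromere contribute
pro-rata to both arms. A segment-based alternative flags an arm when
segments beyond ±0.5 cover ≥ 50% of its length. Cross-platform
concordance is the fraction of shared arms with identical class
(neutral–neutral agreement counts); correlation pairs bins across grids
by maximal overlap and reports Pearson r genome-wide and per arm.

**Focal events.** On segments spanning ≤ 10 Mb: amplification when the
mean exceeds the arm's bin-level baseline by ≥ 1.0 (so amplifications
riding on gained arms are seen and whole-arm gains are never focal),
high-level at absolute mean ≥ 2.0; homozygous deletion when a
gene-overlapping segment is ≤ −1.3, with the band (−1.3, −0.8] flagged
ambiguous — at 72% purity a true two-copy loss sits at log2(1 − p) ≈
−1.8, but lower-purity samples land in the ambiguity band, mirroring
the hard-to-resolve cases in real FFPE material. A purity-aware
expected-homdel level is reported alongside and never changes the call.

**Clinical rules.** Meningioma: TERT promoter mutation or CDKN2A/B
homozygous deletion → integrated grade 3; 1p + 22q co-deletion →
grade ≥ 2; a separate high-risk flag fires on whole-arm losses in ≥ 2 of
chromosomes 6, 10, 14, 18 (counted per chromosome — either arm
qualifies — and reported independently rather than gated on 1p/22q,
leaving the interpretation to the caller; it never changes the grade).
BRAF-fusion indicator: a segment of ≤ 5 Mb and ≥ 3 supporting bins that
deviates from the 7q baseline by ≥ 0.4 — a gain overlapping the 7q34
band implies a KIAA1549::BRAF-like duplication, a loss anywhere on 7q a
FAM131B::BRAF-like deletion; at most one family is reported (strongest
deviation wins) and a whole-chromosome-7 gain is never focal evidence.
The 0.4 threshold sits below the high-purity single-copy value (~0.58)
because fusion duplications are one-copy events; the 3-bin minimum
exists because permutation-significant two-bin Poisson dips occasionally
mimic focal losses, while a real ~2 Mb footprint spans ~20 bins at
100 kb.

## The synthetic cohort generator

The generator is the package's stand-in for the study's patient cohorts
and defines the conditions every cohort-level number is computed under.

* **Truth.** Scenario prescriptions fix the clinically characteristic
  events (+7/−10 in glioblastoma with two isolated-7q and one
  isolated-10q case, 1p/19q co-deletion in oligodendroglioma, the
  focal-amplification table — EGFR ×10, MDM4 ×4, FGFR3, TERT, PDGFRA in
  glioblastomas, one oligodendroglioma PDGFRA, one spinal-ependymoma
  MYCN — 17 + 1 CDKN2A/B and one PTEN homozygous deletion, the
  meningioma alteration table, the six pilocytic chr7 patterns). Event
  burdens are topped up with uniformly drawn comparable arms to the
  entity means (choroid plexus 17.6, glioblastoma 9.5, ependymoma 8.9,
  medulloblastoma 8, oligodendroglioma 5.2; meningioma 3.46/8.05/7 by
  grade), since the per-sample arm assignments are not published.
  Meningioma extras exclude 1p and 22q so random draws cannot alter the
  co-deletion table. Arm gains are CN 3, losses CN 1, amplifications
  CN 20–50 (so observed log2 ≥ 2 at purity ≥ 0.6), homozygous deletions
  CN 0. Purity is a scaled Beta(3.5, 1.54) on [0.20, 0.95] with mean
  0.72 (~10% of samples below 50%, as in the study); DIN is uniform on
  [2, 8].
* **NGS counts.** Library size is log-normal (sd 0.45 in log) around
  0.02 × 24 M reads; the off-target fraction follows
  `clamp(0.95 − 0.04·DIN + N(0, 0.05), 0.30, 0.95)`, calibrated so the
  cohort DIN/off-target-count correlation is ≈ −0.4 (only the observed
  correlation is known, not a mechanistic model). Reads land in bins
  proportional to length × mixture ratio × exp(0.6·(GC − 0.42)),
  realised as independent Poisson counts. GC per bin is drawn once per
  design from a Beta with mean 0.41, sd 0.05 — GC is treated as an input
  annotation, not computed from sequence.
* **Array profiles.** Fixed 100 kb bins carrying the same mixture log2
  plus an arm-level wave N(0, 0.05) and per-bin noise N(0, 0.15),
  emulating array bin files at the bin level (probe-level array
  behaviour, methylation values and array-specific artefacts are not
  modelled). Both platforms read the same mixture value from shared
  truth — the mechanism behind high cross-platform concordance even at
  low purity.

What passing tests show, and what they do not: the simulation captures
purity attenuation, depth-dependent Poisson noise, GC capture bias,
capture-efficiency differences between streams and the DIN/off-target
relation; it does not model FFPE fragmentation artefacts, mappability,
waviness correlated across neighbouring NGS bins, subclonality or
ploidy shifts. Agreement on these cohorts demonstrates the pipeline's
statistical machinery, not assay-level validity on tissue.

## Problem sizes

Simulations are desk-scale replicas chosen so the quantities being
tested keep the precision regime of the real assay. Libraries default to
2% of the study's 24 M-read median (~480 k read-equivalents, ~12 reads
per 100 kb antitarget bin): per-arm standard errors (~0.02 log2) stay
far below the 0.5 call threshold, and CN ≥ 20 amplifications stay far
above the segmentation noise floor. Two workflows deviate deliberately:
focal-amplification recovery segments on 250 kb antitarget bins
(segmentation cost scales with bin count; a 0.5–2 Mb amplification
still spans 2–8 bins at amplitude ≫ noise), and the pilocytic scenario
uses 10% of its 16.85 M-read median, because a single-copy 2 Mb focal
event needs per-bin noise ≲ 0.25 log2 for the permutation test to retain
power — the regime the full-depth assay (~600 reads/bin) operates in,
which 2% scaling does not preserve. The cross-platform concordance study
averages 60 samples over 10 seeds.

## Known limitations

* Arm-level sensitivity is purity-bound: below ~83% purity single-copy
  gains are invisible at ±0.5 on *any* platform; concordance stays high
  because both platforms attenuate identically.
* Called arm-event counts are therefore compared against the
  attenuation-aware expectation (arms whose noise-free mixture crosses
  the threshold), not against the implanted-event count.
* Weighted-median centring defines log2 = 0 at the sample's own modal
  copy state; when close to half the genome is altered the baseline
  shifts, and at desk-scale bin noise the blurred modes additionally
  pull the median a few hundredths towards the dominant alteration,
  deflating threshold-edge gain calls. Both effects shrink with
  read depth and are intrinsic to relative, depth-based profiling.
* The homozygous-deletion ambiguity band is a reporting device, not a
  calibrated posterior; confirmatory testing is the intended follow-up
  for banded calls.
* Median centring and the pooled flat reference assume a mostly diploid
  background; strongly aneuploid genomes shift the baseline.
* The CBS permutation test assumes exchangeable bins within a
  chromosome; heavy-tailed low-count bins can make isolated short
  segments "significant", which is why the fusion indicator requires
  ≥ 3 supporting bins.
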