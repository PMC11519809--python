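# Methods

## The screening procedure

The pipeline identifies genes specific to the resident cells of the mature
organizer (the mesodermal stem zone, MSZ) from paired transcriptomes of
labelled residents ("red") and adjacent unlabelled neural/paraxial cells
("white"), followed by two expression-localization filters.

**Pair scoring.** For each (capture method, replicate) pair, a gene receives
score 2 when its white abundance is exactly zero and its red abundance is at
least τ, score 1 when red ≥ F·white with white > 0, score 0 otherwise. Two
interpretive choices were genuinely open and are resolved as follows:

- *"Significant" red count.* Operationalized as normalized abundance ≥ τ
  (default 1 CPM) — a simple, unit-stable detection proxy. τ = 0 reduces
  score 2 to "anything in red, nothing in white".
- *Zero-in-white precedence.* The fold rule is undefined at white = 0; the
  score-2 test is evaluated first, treating absence from the white sample as
  the stronger evidence class. Consequently a red abundance below τ with
  white = 0 scores 0, not 1.
- *Normalization.* The screen's original count basis is not fixed by the
  method; the default is CPM (making scores invariant to per-sample
  sequencing depth, which we consider the only defensible default for
  libraries of different depth), with `none` available for pre-normalized
  input. Fold changes reported alongside scores are red/(white+ε); with the
  default ε = 0 the white = 0 case is reported as undefined (NaN), never as
  infinity, and ε never enters score decisions.

**Aggregate ranking.** The aggregate score is the sum over all pairs —
across both capture methods, treating the six pairs symmetrically (ranking
within method and merging would weight the noisier method equally; summing
is the simpler default and is what the aggregate bound 0…2·n_pairs
presumes). Ties are broken deterministically by number of score-2 pairs
(desc), mean log ratio log(red+1) − log(white+1) averaged over pairs (desc),
then gene id (asc), so a ranking is a pure function of its input.

**Selection.** The base set is genes with score ≥ 1 in *every* pair
("consistently higher in red"; a `min_aggregate` alternative is exposed
since "consistently" is not formally defined). A discard list models genes
whose expression was already known to be nonspecific. The rescue rule
re-admits genes with extreme enrichment — score 2 or fold ≥ F_high (default
25) — in at least k pairs (default 2), modelling "very dissimilar levels in
at least some pairs"; k and F_high are free parameters with no canonical
values. Discard takes precedence over rescue: a known-nonspecific gene is
excluded no matter how it scores (the rescue rule would otherwise re-admit
any discarded gene with strong scores, making the discard list inert).

**Regional filter.** Expression across the six fixed regions is binarized
at a closed threshold δ (value ≥ δ ⇒ detected; default 1 expression unit),
a deterministic proxy for an RT-PCR band call. A candidate is kept iff
detected in the anterior PS and in none of {caudal_neural, anterior_neural,
caudal_PS, non_neural_ectoderm}. Anterior-midline detection is permitted by
default — the midline contains organizer derivatives, so midline presence
is compatible with MSZ specificity — and a strict mode requires it.

**Marker criteria.** Against the stage × region table, with the same kind
of threshold δ: (i) no region reaches δ at gastrulation; (ii) at initiation
of elongation the anterior PS reaches δ and the other five regions do not —
by default the anterior midline also disqualifies at this stage, since the
criterion concerns the anterior PS proper; a toggle tolerates midline;
(iii) the anterior PS reaches δ at *every* provided elongation timepoint
("throughout elongation"; ≥ 1 timepoint required). `is_marker` is the
conjunction. Recovery against planted truth uses precision = TP/(TP+FP) and
recall = TP/(TP+FN), with 0/0 defined as 0.

## The synthetic-data generator

The generator emulates the experimental design, not any particular
sequencing run: 2 capture methods × 3 biological replicate pairs, each pair
one red and one white sample. Defaults (all configurable):

| parameter | default | rationale |
|---|---|---|
| n_genes | 1000 | desk-scale screen; class structure below, remainder silent |
| class counts | 4 markers; 50 each of neural, paraxial, housekeeping, gastrulation-transient, anteriorPS-nonspecific, MSZ-like-transient | 4 mirrors the true-marker count the screen is built to find; 50 gives each confounder class stable statistics |
| base_mean | 100 counts | comfortably detected gene at unit library scale |
| dispersion α (laser / manual) | 0.4 / 0.15 | NB variance μ+αμ²; degraded laser-capture RNA is noisier |
| dropout prob (laser / manual) | 0.2 / 0 | post-sampling Bernoulli zeroing; models degraded RNA, not biology |
| contamination λ (laser / manual) | 0 / 0.1 | laser capture separates cleanly; manual dissection is coarse. Mixing is linear on expectations: red abundance = (1−λ)·red profile + λ·white profile, symmetric for white |
| library scale (laser / manual) | 0.5 / 1.0 | laser libraries are shallower |
| library size factor | Gamma, mean 1.0, CV 0.3 | typical bulk depth variability |
| elongation timepoints | 3 | "throughout elongation" needs several checkpoints |

Negative binomial is the community-standard count model for RNA-seq;
nothing in the screening rule depends on that choice beyond overdispersed
counts with exact zeros. Sequencing depth and per-gene abundance are free
parameters of the generator, chosen as round values — they are not
calibrated to any deposited dataset.

The planted classes tie counts and tables together: markers and the
transient/nonspecific confounders are red-compartment expressed (so they
survive scoring) and are then rejected by exactly one downstream rule each
— nonspecific genes by the regional filter (anterior PS plus one disallowed
region, cycled deterministically over the four), gastrulation-transients by
criterion (i), MSZ-like transients by criterion (iii) (off at the last
elongation timepoint). A nonspecific gene's white-compartment abundance is
positive only when its extra region is a tissue the white dissection
contains (neural domains, caudal streak), so a quarter of them reach the
regional filter in a full run. The `paraxial` class is localized to
`caudal_PS` in the tables: the six-region vocabulary has no separate
paraxial-mesoderm entry and the presomitic territory at the caudal streak
is its closest match. Regional and stage tables are noise-free expectations
by default (the wet readouts they stand for are qualitative band/stain
calls); `table_noise_sd` adds truncated Gaussian noise when robustness to
fuzzy calls is of interest.

**Sampling by inverse CDF.** All randomness comes from one
`numpy.random.default_rng(seed)` stream drawn in a fixed order (library
uniforms, count uniforms, dropout uniforms) with shapes that depend only on
the design dimensions. Counts are produced by evaluating the NB quantile
function at the count uniforms (Poisson when α = 0, zero when μ = 0). Two
consequences: outputs are bit-for-bit reproducible for a given config+seed
on any platform, and two configs differing only in a noise parameter share
their underlying uniforms, so a parameter sweep is coupled by common random
numbers. Because the NB quantile is monotone in its mean and the pair score
is monotone in red (up) and white (down), recall of the planted markers
degrades monotonically along a contamination sweep at fixed seed instead of
fluctuating through resampling noise. (CPM renormalization can in principle
perturb this through per-sample totals, but the effect is orders of
magnitude below the fold thresholds.)

## What passing tests do and do not show

The generator plants exact structural zeros (a marker's white abundance is
identically 0 before contamination) and noise-free localization tables.
Real data have ambient contamination, mapping artefacts and qualitative
band calls, so perfect noise-free recovery demonstrates correctness of the
rule implementations — that the screen computes what it claims — not that
the thresholds (5×, τ, δ, k, F_high) are optimal for any real experiment.
The noisy default and the contamination sweep probe graceful degradation,
again against the generator's assumptions (independent NB noise, linear
mixing), not against library-preparation reality.

## Numerical and degenerate-input choices

- All thresholds are closed (≥), giving deterministic boundary behaviour;
  an abundance exactly at τ, F·white or δ passes.
- An all-zero sample column under CPM is left all-zero with a logged
  warning rather than dividing by zero.
- Negative counts/abundances, unknown region or stage names, unpaired
  samples, candidates missing from a table, and missing stage/region
  combinations raise errors naming the offender; a pipeline stage failure
  is re-raised naming the stage, with earlier artifacts retained.
- The run report excludes timestamps, hostnames and absolute paths, and all
  JSON is dumped with sorted keys, so fixed config+seed runs are
  byte-identical.
- Problem sizes used by the test suite and the acceptance script — 1000
  genes, 12 samples, 1000 random 20×6 scoring matrices, a four-point
  contamination sweep — keep any single check under a minute while leaving
  every class populated enough for exact structural assertions.

## Known limitations

- No read-level simulation (FASTQ), alignment, isoforms, or count
  uncertainty from multi-mapping; count matrices are the abstraction
  boundary.
- The scoring stage is deliberately threshold-based, mirroring the screen
  it implements; it is not a differential-expression test and provides no
  error control (no NB GLM, no FDR).
- Contamination is a single linear mixing fraction per method; real
  cross-contamination varies per replicate and per cell-type proximity.
- The regional/stage tables abstract RT-PCR and in situ readouts as
  thresholded expression values; primer efficiency, cycle kinetics and
  stain intensity are out of scope.
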