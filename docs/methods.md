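# Methods

This note documents the models and procedures implemented in `fecalsig`,
the parameters that matter, the numerical conventions chosen where a
convention had to be fixed, and what the synthetic data do and do not
establish.

## Read filtering and region handling

Merged amplicon reads pass two per-read predicates before anything else:
a length window around the targeted region's median — 372 bp ± 5% (V4V5),
253 bp ± 10% (V4), 60 bp ± 10% (V6) — and a quality screen removing reads
with any ambiguous base or a homopolymer run longer than 8 (a run of
exactly 8 survives; this is the standard `maxhomop=8` semantics). Window
bounds are `ceil(median·(1−tol))` and `floor(median·(1+tol))`: integer,
deterministic, and conservative at the edges. Because both filters are
per-read predicates, their order cannot change the outcome; the tests
assert this.

The targeted region is detected from the median read length against those
three windows. Length-based detection is deterministic and independent of
any reference data; content-based detection (matching reads against
stored signature ASVs) would only be needed for inputs whose length
distribution is corrupted, and is not implemented.

V4V5 reads can be trimmed to V4 coordinates for classification against V4
signatures. V4 and V4V5 amplicons share their forward primer, so
primer-trimmed V4V5 reads already start at the V4 fragment; only the
internal V4 reverse-primer site must be located. Matching is
IUPAC-degenerate with a configurable mismatch budget (default 2,
following the lower end of the 2–4 mismatch convention for these
primers); an `N` in the read never matches any primer base, because an
ambiguous base is no evidence of a primer site. The primer pair itself is
configuration, defaulting to the Earth Microbiome Project V4 pair
(515F `GTGYCAGCMGCCGCAGCGG`, 806R `GGACTACNVGGGTWTCTAAT`): primer choice
is a protocol property, not part of the method.

## Minimum entropy decomposition

Reads of one region are equal length after filtering, so alignment
columns are read positions and no alignment step exists. Each node of the
decomposition holds a multiset of sequences; its entropy profile is the
per-position Shannon entropy (log base 2) of base frequencies over
{A,C,G,T} — `N`-containing reads never reach this stage. A position is
*discriminative* when its entropy strictly exceeds `max_entropy`
(default 0) and at least `minor_count_floor` (default 1) reads carry a
non-majority base. Nodes split on the joint base pattern at up to
`max_discriminants` (default 4) highest-entropy discriminative positions;
children with fewer than `M` reads are dissolved and their reads counted
as discarded. Recursion ends when no position is discriminative, so with
the default threshold every surviving ASV is a single exact sequence.

The minimum substantive abundance is `M = ceil(N / d)` with
`d` = 30,000 (V4V5), 40,000 (V4), 60,000 (V6) and `N` the pooled read
count, clamped from below at 2 so a singleton can never found an ASV.
The published divisors are kept even though desk-scale synthetic runs
(~10^6 reads at most) rarely push `M` above the clamp.

Implementation notes. The decomposition operates on unique sequences with
multiplicities, sorted lexicographically, which makes the result a
function of the read *multiset* — read order cannot matter, and the tests
assert bit-identical tables under shuffling. The representative sequence
of an ASV is its most abundant member, ties broken lexicographically.
Sample retention is the fraction of a sample's reads assigned to a
surviving ASV; a sample fails retention QC when strictly more than half
its reads were discarded (exactly half passes).

The oracle used in tests and in `scripts/acceptance.py` is brute-force
grouping by full-sequence identity with the `M` floor applied; for read
sets whose variation is confined to ≤3 positions with all haplotype
counts ≥ M the decomposition must reproduce it exactly, and does.

## Cohort screening and train/test design

Bray–Curtis dissimilarity is computed on relative abundances (per-sample
normalization) because sequencing depth varies by orders of magnitude
across platforms and would otherwise dominate. Box-plot outlier rules use
linear-interpolation (type-7) quantiles — a convention had to be fixed
for the 1.5×IQR rules to be testable. Screens run in order: MED
retention, then log10 depth lower outliers, then mean-intrasource-BC
upper outliers among the survivors. Excluded samples are reported with
exactly one reason each; community outliers are withheld from training
and evaluation but never deleted from the report.

Training takes the `train_size` (15–20, default 20) samples with the
smallest mean intrasource dissimilarity; everything else — by
construction the most dissimilar part of the cohort — tests the
classifier, which is a deliberately stringent evaluation design. The test
set must hold at least 6 samples and at least 30% of the training-set
size; when that fails, `train_size` shrinks toward 15 before the cohort
is rejected as insufficient. Ties in cohesion break by sample id, making
the split a pure function of the dissimilarity matrix.

Community bifurcations are detected by Ward clustering of the BC matrix.
The branch criterion compares the final merge height against the
preceding one; heights follow the *legacy* Ward agglomeration criterion
applied to raw dissimilarities (R `hclust` `ward.D`), reproduced in scipy
by running Ward linkage on √BC and squaring the heights. The convention
matters: with a planted two-type cohort (10+10 samples, disjoint ASVs)
the legacy criterion yields a height step ≈ 7.4 — above the default
threshold of 5 — while the Euclidean-consistent `ward.D2` criterion
yields ≈ 2.7 and would never trigger at that threshold. A homogeneous
cohort yields a step ≈ 0.1 under either. When a bifurcation is found, the
training draw is balanced across the two subgroups (quota split as evenly
as subgroup sizes allow, shortfalls spilling over).

Diet/physiology classifiers (e.g. ruminant = cattle + deer) are trained
and tested on the union of the member cohorts' splits, with the union as
the positive class.

## Signature training

*Ranking.* Replicate random forests (default 100 replicates × 10,000
trees; Gini splits; √p candidate features per split; bootstrap sampling —
the R `randomForest` defaults) are grown on relative-abundance profiles
with one-vs-rest labels, and each ASV's mean decrease in Gini is averaged
across replicates. scikit-learn's impurity importances are normalized per
forest where R's are not; this affects scale only, never ranking order,
and everything downstream depends on order and relative magnitude.

*Breakpoint selection.* The averaged importances, sorted descending, form
a scree curve. A single change-point is placed by exhaustive two-segment
least squares with each segment fitted by its mean — the same objective a
segmented-regression change-point estimator minimizes, computed exactly
rather than approximately since p is at most a few thousand. The
breakpoint is accepted only when the two-segment fit explains the curve:
residual SSE below 10% of the single-segment SSE. A smooth decay
(geometric, or pure noise) leaves a large relative residual at every
split; in that case selection falls back to the smallest prefix carrying
90% of total importance, with a warning — a signature is never silently
empty. Only the single-change-point form is implemented; multi-breakpoint
selection via an information criterion was considered and dropped because
the decision rule downstream uses a single threshold and the planted
recovery task never requires more.

*Ensemble.* Profiles restricted to the selected ASVs are renormalized to
sum to 1 (the signature carries 100% of the relative abundance; a sample
with no reads on the signature keeps an all-zero profile and is flagged).
Replicate forests (default 100 × 1,000 trees, seeds `seed + i`) are
pooled at tree level; the voting probability of a query is the fraction
of all pooled trees voting the focal class. Tree-level vote counting is
used rather than probability averaging because the two differ for
sklearn's soft-voting trees and the vote fraction is the quantity the
decision cutoff is defined on.

*Cutoff calibration.* Candidate cutoffs are all midpoints between
adjacent distinct observed test probabilities plus the percent grid
0.01–1.00. Feasible cutoffs have sensitivity and specificity both
≥ 70% on the held-out test samples; among feasible cutoffs the objective
is max min(sensitivity, specificity). Ties break by higher sensitivity
(detection is the platform's purpose), then higher specificity, then the
*largest margin* — the candidate farthest from every observed probability,
i.e. the mid-gap point between the score distributions — then the lower
cutoff. The margin tie-break is what places a perfectly-separating
cutoff in the middle of the gap rather than at an arbitrary grid edge;
an edge placement would misrepresent a clean separation as a borderline
(draft or discarded) classifier. All negatives present in the test panel
participate in both the cutoff search and the specificity estimate.
Classifier typing: cutoff > 10% global, > 5% and ≤ 10% draft, ≤ 5% or no
feasible cutoff discarded.

Every replicate seed derives from the run seed, and the signature bundle
records seeds, replicate/tree counts, train/test ids and the held-out
score distributions, so a rebuild is bit-identical and the empirical
specificity at any observed probability can be reconstructed at
classification time.

## Classification of query samples

A query read counts toward a signature ASV only when byte-identical to
its representative sequence — which is why exact region trimming matters.
Reads matching nothing change nothing: only the renormalized profile over
the signature's ASVs enters the ensemble. Contamination is declared on
strictly greater than the cutoff; a probability exactly at the cutoff is
not a call. Discarded classifiers still report their probability but
never call, and carry a flag saying so.

Flags: `LOW_INPUT` below 1,000 total reads, `LOW_MATCH` below 1,000
matching reads or 100 unique matched ASVs, `NO_MATCH` at zero matches.
The thresholds mirror the empirical finding that ~1,000 signature
sequences over ~100 unique variants are needed for a reliable call; they
are configurable because they were estimated on particular cohorts.

Per-source arcs summarize a sample's fecal composition: each source's
share of all signature-matched reads. ASVs shared between two signatures
count toward both signatures' match totals, but arcs assign such reads
fractionally (split equally among owning sources) so shares sum to 1.

## Sensitivity, specificity and detection limits

Sensitivity is TP/(TP+FN) over samples whose true source is the focal
one; specificity is TN/(TN+FP) over everything else, including any extra
hold-out sources supplied to harden the negative panel. Undefined
quotients are reported as missing, never coerced to 0.

The detection limit is probed by subsampling a positive sample without
replacement at 90, 80, ..., 0.001% (the published fraction ladder),
re-classifying each draw (default 10 repeats per fraction; the mixture
analysis uses the published 99), and reporting the smallest mean
matched-read count at which the call still holds. Matched reads scale
linearly with the fraction; the voting probability falls off
logarithmically — flat at high depth, collapsing only near the limit.
Artificial mixtures combine defined read proportions from background
water and fecal samples at a stated depth, ground truth retained.

## Synthetic data: what it emulates and what it does not

The generator plants the structure the method exploits: per-source
exclusive ASVs (default 30), ASVs shared between neighboring sources
(default 5), an environmental background pool (default 100), Dirichlet
sample-to-sample variability (concentration 50 per ASV), multinomial
reads, optional per-base substitution noise, and optional two-type
sources for bifurcation tests. All sequences are random equal-length
oligomers at pairwise Hamming distance ≥ 2, so exact matching and the
entropy decomposition are unambiguous. Everything is bit-reproducible
from (design, seed).

The default design — 5 sources × 25 samples at ~10^4 reads — is sized so
every cohort satisfies the 15–20/≥6 split rule while a full build runs in
seconds to minutes; test and acceptance runs use reduced forest sizes
(10 replicates × 100 trees) which are always passed explicitly, never
silently substituted for the full defaults. Per-source depths are drawn
as stratified quantiles of the log-normal depth distribution (one draw
per probability stratum, shuffled): the spread follows the stated
distribution while the survey cannot contain accidental box-plot depth
outliers, emulating cohorts that already passed per-run sequencing QC.

What passing these tests shows: the machinery — decomposition, screening,
selection, calibration, matching, flag logic — is correct, deterministic
and self-consistent, and recovers planted structure perfectly when
sources are well separated. What it does not show: performance on real
fecal communities, where source overlap is continuous, variant abundance
distributions are heavy-tailed, and chimeras and indels exist (the noise
model is substitution-only). Real sensitivities and specificities must be
established on real cohorts; increasing the planted inter-source overlap
measurably degrades specificity, and the synthetic defaults deliberately
sit in the well-separated regime.

## Numerical conventions and degenerate inputs

- Quantiles: linear interpolation (type-7) everywhere.
- Entropy: log base 2; all-zero columns are errors, not zeros.
- Renormalized profiles sum to 1 within 1e−9 whenever any selected ASV is
  present; all-zero profiles stay zero and are flagged.
- Bray–Curtis of two all-zero samples is an error (undefined), not 0.
- Probability exactly at the cutoff: no call. Retention exactly at 50%:
  pass. Homopolymer run exactly 8: pass.
- Ties: ASV representatives and cohesion ranks break lexicographically;
  cutoff ties as described above.
- Sensitivity/specificity with empty denominators: missing, never 0.

## Known limitations

- Taxonomic restriction to Bacteroidales/Clostridiales is accepted as an
  upstream pre-filter (the `group` label is bookkeeping); no taxonomy
  assignment is performed.
- No chimera detection, no indel error model, no paired-end merging or
  FASTQ quality filtering — inputs are merged, primer-trimmed FASTA.
- The entropy-decomposition stopping threshold defaults to 0 bits with a
  minor-count floor of 1, which is exact on substitution-noise-free data
  and relies on the `M` floor to absorb sequencing noise; heavily noisy
  data may fragment variants before the floor catches them.
- Single scree breakpoint only; sources whose importance curve has
  several genuine plateaus fall back to the cumulative-mass rule.
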