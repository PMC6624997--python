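# Methods

## Model and assumptions

The caller assumes paired-end coverage in which enrichment manifests as
contiguous runs of nonzero signal ("signal blocks") separated by long
zero runs, and in which a non-specific (IgG) control samples the same
background process as the target. No parametric background
distribution is fitted; all decisions are made on the empirical
distributions of block total signal,

    t = sum_i (end_i - start_i) * signal_i,

summed left to right in genomic order so totals are bit-reproducible.
Coordinates are 0-based half-open everywhere; two intervals are
adjacent iff `end_i == start_{i+1}`, and a configurable `merge_gap`
(default 0) can relax adjacency. Explicit zero-signal bedgraph rows are
treated exactly like gaps (they split blocks), since the input contract
says zero regions are omitted; both representations behave identically.
Max-signal ties within a block keep the leftmost component.

## Threshold machinery

**Candidate grid.** F(t) = p_T/(p_T + p_C) with p_T, p_C the fractions
of target/control blocks with total strictly above t. F changes only
at observed totals, so the grid {0} ∪ {distinct totals from both sets,
post-scaling} makes the sweep exact, not an approximation. Candidates
where p_T + p_C = 0 are excluded. Retention uses strict inequality
`total > t` consistently across curve, filtering and FDR.

**Tie-break.** The stringent threshold is the *smallest* candidate
attaining max F, maximizing recall among equal-F choices.

**Pooled denominators.** Both F and the empirical FDR
(`#control above / (#target above + #control above)`) pool target and
control; a control-only denominator variant is not offered.

**F variant.** An alternative definition from counts of blocks
*removed* at t rather than remaining exists behind
`variant="removed"`. The remaining form is canonical: it is the one
consistent with a "fraction of blocks exceeding the threshold" curve
and has a well-behaved maximizer; the removed form is provided for
comparison only.

**Relaxed mode.** The knee is detected on F versus candidate index via
discrete second differences `d2[i] = F[i+1] - 2F[i] + F[i-1]`; among
interior candidates with `d2 < 0` and `F < F_max`, the largest F
(rightmost on exact ties) is the knee value k. The operating point
`F_max - (F_max - k)/2` is mapped back to a threshold by piecewise
linear interpolation between the flanking candidates — the relaxed rule
is defined in F-space, so interpolation in t is the only free choice.
With fewer than three candidates or no qualifying knee, relaxed falls
back to the stringent threshold. Because the relaxed threshold never
exceeds the stringent one and retention is strict, the stringent peak
set is always a subset of the relaxed set before control-overlap
filtering (and in practice after it; the overlap filter can in
principle remove a peak only at the lower relaxed threshold).

**Normalization.** The scaling factor is the ratio of the target and
control block-total density modes. Modes are located with a Gaussian
KDE (Silverman bandwidth) evaluated at the union of a 512-point uniform
grid over [0, max] and the observed totals themselves. Including the
data points matters when one extreme block (a broad domain) stretches
the grid so far that the bulk falls between grid points; every
evaluation point scales linearly with the sample, so the factor is
exactly invariant to rescaling the inputs, and samples with a single
distinct value return that value. Because background blocks dominate
both samples, the mode tracks depth differences, not enrichment.

**Global mode.** A numeric control q ∈ (0,1) is read as a top-fraction:
the threshold is the empirical (1-q)-quantile of target totals with
"lower" interpolation, so roughly the top q fraction of blocks are
strictly above it, and an all-equal input retains nothing (with a
warning) rather than everything. A raw signal-value reading was
rejected as depth-dependent. No control filtering or FDR applies.

**Degenerate inputs.** Empty target or control bedgraphs error with an
instruction to use global mode; thresholds at or above the maximum
total produce an empty call with a warning, not an error.

## Evaluation

Overlap semantics are directed ≥1 bp half-open hits, each interval
counted once (both directions). The PR curve sweeps distinct ranking
metric values descending; ties share one cutoff. A reference peak
counts as recalled at cutoff v iff the best metric among called peaks
overlapping it is ≥ v, which is equivalent to re-intersecting each
subset. AUPR is the trapezoidal area over (recall, precision) points
anchored at recall 0 with the top-cutoff precision and not extrapolated
toward recall 1; under this rule an all-true-positive ranking scores
exactly its maximum recall and a constant metric scores
precision × recall. Production overlap counting uses merged-interval
binary search; the test suite checks it against a quadratic
double-loop oracle.

## Synthetic data generator

The generator emulates the sparse CUT&RUN regime at desk scale:

- **Genome**: one 5 Mb chromosome by default.
- **Background**: independent fragments at 200 fragments/Mb (the
  density a typical ~1M-fragment IgG library has per Mb of a 3 Gb
  genome), identical law for target and IgG. Most background blocks
  are single fragments; occasional stacks give the total distribution
  its tail.
- **Fragment lengths**: drawn on a 10 bp grid with a bell-shaped
  (binomial over grid indices) law within the preset range, emulating
  size-selected libraries with a characteristic fragment size. Because
  a block's total equals the summed lengths of its fragments, this
  reproduces both the tie structure of sparse background totals and a
  well-defined density mode for normalization to anchor on.
- **Presets**: `tf` (20 peaks of 200–700 bp, Poisson mean 50 fragments
  per peak, ~550× background fragment density — CUT&RUN enrichment over
  a near-zero background is orders of magnitude), `histone` (10 peaks
  of 2–10 kb, 300 fragments), `broad` (one 50 kb domain at 200×
  background, dense enough that fragment spacing ≪ fragment length and
  coverage is contiguous), and `null` (target drawn exactly as IgG,
  empty truth set — the unexpressed-factor gold standard used for
  specificity).
- Everything is reproducible byte-for-byte from one integer seed.

What the generator does **not** model: mappability and GC bias, copy
number, chromatin-accessibility-correlated background, shared artifact
hotspots between target and control, spike-ins, or read-level error.
Passing tests therefore demonstrate the algorithmic properties of the
method under its own assumptions, not performance on any real library.

## Known limitations

- Under an *exactly* exchangeable null, threshold selection is not
  uniformly safe per dataset: the argmax of F is driven by the target
  share among the top-k pooled blocks, and with probability that decays
  only slowly with block count (~13% at m = n = 1000 in idealized
  simulations) the maximum lands in the bulk of the distribution,
  retaining a large fraction of blocks with F_max barely above 0.5. In
  expectation over replicates the retained fraction stays small (the
  median replicate retains ≈0.3%), and on enriched data the effect is
  irrelevant because true peaks dominate the tail, but single null
  replicates can be outliers. A low F_max (equivalently an empirical
  FDR near 0.5) is the observable symptom and is reported in the run
  summary.
- Normalization assumes background dominates both libraries; a target
  whose majority of blocks are true signal would mis-scale.
- The overlap filter requires control blocks, so global mode offers no
  artifact suppression.
- Chromosomes are ordered lexicographically; no genome file is
  consulted.

## Problem sizes

Tests and the acceptance script run at desk scale by design: 5 Mb
genomes, ~1000 background blocks per dataset, 500/200/200-case oracle
sweeps, 10 enriched / 20 null replicates. These sizes make every
distributional property measurable in seconds while remaining in the
regime the method targets (blocks ≫ peaks, background ≫ signal in
count, signal ≫ background in total).
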