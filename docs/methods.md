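# Methods

## The observation model

A *gap-site* is the genomic location of an alignment gap: sequence name,
strand, and the 1-based positions of the first and last intronic base.
TopHat's BED12 junctions are converted to this key space
(`intron_start = chromStart + blockSizes[0] + 1`,
`intron_end = chromStart + blockStarts[1]`), so batches from either aligner
merge on identical keys. Strand is part of the key by default (STAR strand
code 0 maps to `.`); `--ignore-strand` collapses it, since different
aligner configurations disagree on strand assignment. A site is "present"
in a sample when its read support passes `min_reads` (default 1;
multimapping reads excluded unless requested).

The model treats sites as a heterogeneous population observed
independently: site *i* is present in each sample with its own probability
*p_i*, independently across samples and sites. Observed data only
constrain *p* through the multiplicity *j* (number of samples containing
the site), estimated as *p_j = j/n*. Normalising the multiplicity spectrum
*z_j* over the support {j/n} gives the observation prior — the two-step
generative model is: draw *p* from the prior, then draw presence
Bernoulli(*p*) per sample.

Under independence the expected distinct-site count at batch size ν is
`Σ_bins count · (1 − (1 − p)^ν)`, which for integer bins is exactly the
accumulation formula in the README. Assumptions worth keeping in mind:

* **Independence across sites and samples.** Co-regulated junction
  clusters or batch effects violate it; the model has no dispersion term.
* **Within-batch probability estimation.** *p_j = j/n* is estimated from
  the same batch the curve is predicted for. The resampling evaluation
  draws sub-batches *without replacement* from that fixed batch
  (hypergeometric), while the model assumes independent Bernoulli
  observation (binomial). The binomial unseen probability
  (1 − j/n)^ν exceeds the hypergeometric one, which is one face of the
  finite-sampling bias: the raw curve under-predicts, most visibly for
  rare sites.

## The virtual-event correction

The deficit of the raw prediction at ν = n is `Σ_{j<n} (1 − j/n)^n z_j`.
The correction adds a single virtual bin (μ_v, m_v): m_v events with
observation probability μ_v/n, μ_v ∈ (0, 1) strictly below the smallest
real multiplicity, so the observed integer bins and all descriptive
statistics are untouched. m_v is solved in closed form so the corrected
expectation at ν = n equals |S_n| exactly (`calibrate_virtual_count`);
this replaces any manual tuning of the pair and is the package default.
μ_v itself remains free and defaults to **0.24**; it controls only the
shape (how early the virtual mass is discovered), not the endpoint.
`fit_virtual_multiplicity` grid-searches μ_v ∈ (0, 1) against a smoothed
empirical curve, minimising the median relative deviation, for users who
want a full-curve fit. The corrected model is a bias patch in the spirit
of the virtual-event device, not an unseen-species estimator: no claim is
made about the true number of never-observed sites.

## Resampling evaluation and the basal rate

`draw_subbatches` draws `n_reps` (default 200) sub-batches with sizes
uniform on {2, …, n−1} and counts union sites, then appends one
deterministic ν = 1 result per sample so the smallest size is always
anchored. Counting is vectorised over a boolean site × sample presence
matrix; identical seeds give identical draws.

Smoothing is locally weighted linear regression (tricube weights) with one
robustness iteration and span 0.75 — conventional loess defaults, exposed
as parameters — evaluated at each integer size present in the results, via
statsmodels' `lowess`. On exactly linear data the smoother reproduces the
line to machine precision, which the tests exploit.

The basal rate (gbr) is the OLS slope of the smoothed curve over its
terminal window: ν ≥ 40 when the curve reaches ν ≥ 50 (the natural window
for batches of ~54), otherwise the top quarter of the range. Unique-site
statistics (total, per-sample mean/SD, share of the gbr) are computed from
whole-batch multiplicities.

Model-vs-data agreement is summarised by the median over shared ν of
100·|predicted − smoothed|/smoothed. The median is used because the raw
model's error is strongly size-dependent (worst at large ν).

## Sample-size calculation

With per-sample observation probability *po* and required power *pw*, the
required batch size is n = ln(1−pw)/ln(1−po), rounded up; an exactly
integral quotient is kept (it meets the power with equality). The
implementation enforces minimality numerically — smallest n with
1 − (1−po)^n ≥ pw — which is identical to the ceiling except where
floating-point representation would mis-round an integral quotient.
Rule-of-thumb categories at 80% power: rare (po < 0.15, > 10 samples),
occasional (0.15 ≤ po ≤ 0.5, 3–10), regular (po > 0.5, 1–3); band edges are
assigned to "occasional". Observation probabilities depend on alignment
depth; `adjust_observation_probability` accepts a user-supplied callable
for that rescaling — the package deliberately does not prescribe a depth
model.

## Synthetic batches

`generate_batch` implements the generative model directly: each site gets
a true *p* (explicit classes, or the Beta-mixture prior
0.85·Beta(0.3, 8) + 0.15·Beta(8, 0.3)), a distinct random genomic key, and
independent Bernoulli presence per sample. Sites observed nowhere are
dropped from the samples but kept in the returned truth map. The default
mixture produces a U-shaped spectrum in which roughly three quarters of
sites at n = 54 have multiplicity < 5 or > 50; it is a stand-in for
empirical priors, not a calibrated fit to any tissue. What it does *not*
emulate: read-level sampling, alignment errors with genomic structure,
correlated (co-regulated) junctions, depth differences between samples, and
annotation-dependent site quality. Passing tests on synthetic batches
therefore validate the internal consistency of the estimator chain under
the independence model, not its adequacy for any particular real dataset —
on real data the independence and within-batch-estimation assumptions must
be judged from the deviation diagnostics.

Problem sizes used in the shipped checks: the full-pipeline consistency
check runs one batch of 54 samples × 10⁵ sites with 200 resampling
replicates (a scale at which sampling noise in the median deviation is
small); the Monte-Carlo oracle for the expectation formula uses spectra of
≤ 50 sites over ≤ 6 samples with 20,000 replicates and a 3-standard-error
band.

## Numerical choices and degenerate inputs

* (1 − p)^ν is computed as `exp(ν · log1p(−p))` for accuracy at small p
  and large ν; p = 1 is short-circuited to an unseen probability of 0.
* ν is integer and ≥ 1 (at ν = 0 the accumulation formula degenerates to
  z_n rather than 0, so it is rejected); predictions beyond the training
  batch size are allowed but flagged as extrapolation.
* A spectrum with all mass at multiplicity n has no deficit: m_v = 0 and
  the raw and corrected curves coincide.
* Empty spectra are rejected wherever a prior or prediction is requested;
  duplicate sample ids are rejected when building spectra (double-counting
  risk).
* Spectrum TSVs store counts with full precision (`repr`), so round-trips
  are exact, including fractional virtual bins.

## Known limitations

* The observation prior is estimated from the analysed batch itself;
  transferring a fitted curve to a different tissue, depth, or aligner
  configuration is extrapolation beyond the model.
* The correction guarantees the endpoint by construction; mid-curve
  accuracy depends on μ_v and on how well independence holds.
* gbr estimation assumes the terminal window is already in the linear
  regime; for small batches (n ≲ 16) the top-quarter window may still be
  curved.
* BAM traversal, junction validation scores and annotation are out of
  scope; junction tables are the entry point, and per-site quality labels
  are accepted only as external categories.
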