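# splicesat

**How many RNA-seq samples do you need to observe the splice junctions in a
tissue?**

When spliced reads are aligned to a genome, every alignment gap marks a
putative splice junction ("gap-site"). Merging junctions across samples
keeps discovering new ones: junctions of constitutively expressed genes
appear in every sample, while rare splicing events — and aligner noise —
appear only sporadically. `splicesat` models this saturation behaviour and
turns it into concrete experimental-design numbers.

It is aimed at people planning or analysing bulk/single-cell transcriptome
experiments who need to know how junction discovery scales with batch size,
and how many replicates a detection target requires.

## The model

For a batch of *n* samples, let *z_j* be the number of gap-sites detected in
exactly *j* samples (the multiplicity spectrum) and |S_n| = Σ_j z_j the
distinct sites observed. Giving each multiplicity-*j* site the per-sample
observation probability *p_j = j/n* and assuming sites are observed
independently across samples, the expected number of distinct sites seen in
a batch of size ν is

    E|S_ν| = |S_n| − Σ_{j=1}^{n−1} (1 − j/n)^ν · z_j

Real spectra are strongly U-shaped (most mass at multiplicity near 1 and
near *n*), and this raw model has a finite-sampling bias: a multiplicity-1
("unique") site stays unpredicted with probability (1 − 1/n)^n → 1/e ≈
0.368, so ~36.8% of unique events are missing from the prediction at ν = n
no matter how large *n* is. `splicesat` corrects this by adding *m_v*
virtual events with fractional multiplicity μ_v ∈ (0, 1) — below anything a
real sample can produce — with *m_v* calibrated in closed form so the
corrected curve passes through |S_n| exactly:

    m_v = Σ_{j<n} (1 − j/n)^n z_j  /  (1 − (1 − μ_v/n)^n)

The model is evaluated against sub-batch resampling: random sub-batches are
drawn without replacement, union counts loess-smoothed, and the median
relative deviation between model and smoothed curve reported. The terminal
slope of the smoothed curve is the **basal observation rate (gbr)**: new
gap-sites per added sample in large batches, dominated by unique sites.

For design, the binomial detection model gives the required batch size for
an event with per-sample observation probability *po* at power *pw*:

    n = ⌈ ln(1 − pw) / ln(1 − po) ⌉

## Worked example

Junction files are read per sample from STAR `SJ.out.tab` or TopHat
`junctions.bed` and merged on canonical 1-based intron coordinates. Here we
use a synthetic batch drawn from a U-shaped observation prior instead:

```python
from splicesat import SyntheticBatchSpec, generate_batch, JunctionSaturationModel

spec = SyntheticBatchSpec(n_samples=54, n_sites=100_000, seed=7)
samples, truth = generate_batch(spec)
res = JunctionSaturationModel.from_samples(samples).fit(n_reps=200, seed=7)
print(res.summary())
```

```
Junction saturation model
==========================================================
batch size n                  54
distinct gap-sites |S_n|      54546
unique (multiplicity 1)       11983
U-shape: frac <5 or >50       0.723
----------------------------------------------------------
raw prediction at nu=n        48970.1 (10.2% deficit)
unique-event bias (1-1/n)^n   0.364
virtual events: mu_v          0.24
                m_v           26080.8
corrected prediction at nu=n  54546.0
----------------------------------------------------------
sub-batches drawn             254
median deviation, raw         7.35%
median deviation, corrected   1.53%
basal rate gbr                358.5 sites/sample
unique sites total            11983
unique per sample (mean, SD)  221.9, 12.9
unique share of gbr           61.9%
==========================================================
```

Reading the output: of 100,000 true sites, 54,546 were observed at least
once in 54 samples. The raw occupancy model predicts only 48,970 at ν = 54
(a 10.2% deficit — close to the 36.4% unique-event bias applied to the
11,983 unique sites), while the corrected model recovers the total exactly
and tracks the resampled counts within a 1.5% median deviation versus 7.4%
for the raw model. Each added sample contributes ~359 new sites, of which
~62% are unique in this batch.

Sample-size planning from the shell:

```
$ splicesat samplesize --table
po      n_required      achieved_power  category
0.1     16      0.815   rare
0.15    10      0.803   occasional
0.2     8       0.832   occasional
0.5     3       0.875   occasional
0.8     1       0.800   regular
```

So an event present in half the samples needs only 3 replicates for 80%
detection power, while a po = 0.1 event needs 16.

Other CLI entry points: `splicesat spectrum` (junction files → spectrum
TSV), `splicesat predict` (spectrum TSV → saturation curve), `splicesat
simulate` (resampling evaluation + summary), `splicesat synth` (write a
synthetic batch in either junction dialect).

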