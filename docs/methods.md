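# Methods

`kmerdelta` measures genome size and genome composition differences
between individuals directly from shotgun sequencing reads, using
k-mer inventories instead of genome assemblies or read alignments.
This note records the model, the numerical choices, and what the
synthetic-data generator does and does not emulate.

## The k-mer model of a diploid genome

Every window of k = 21 consecutive unambiguous bases in the read data
is counted toward its canonical form, the lexicographic minimum of the
window and its reverse complement (A < C < G < T).  Odd k guarantees
no k-mer is its own reverse complement.  The resulting *k-mer dump*
(sorted k-mer → multiplicity table) is the identity-aware
representation of a sample; tallying its multiplicities gives the
*k-mer spectrum*, the identity-free one.

In a diploid sequenced at per-haplotype depth c, k-mers present on
only one of the two genome copies (heterozygous sites) are observed at
multiplicity ≈ c — the *monoploid peak* — and homozygous k-mers at
≈ 2c.  A repeat present N times per diploid (2C) genome appears at
≈ N·c.  Dividing multiplicities by c therefore converts them to
genomic copy numbers, a scale on which samples with different
sequencing depths are directly comparable.

Note that c is the *k-mer-level* coverage, not the nominal base
coverage: a read of length L contributes only L − k + 1 of the L
window starts it spans, and a window survives only if all k bases are
error-free, so c ≈ c_base · (L − k + 1)/L · (1 − e)^k.  Dividing by
the observed peak location cancels these losses, which is why the
estimator needs no explicit error model.

## Genome size estimation

With the organellar k-mers removed (see below) and a monoploid
coverage c, the diploid genome size is

    GS(2C) = Σ_{m ≥ c/2} m · n(m) / c      [base pairs]

where n(m) is the number of distinct k-mers at multiplicity m.  The
m < c/2 portion of the spectrum — dominated by sequencing-error and
contaminant k-mers — is discarded before summing.  Picogram conversion
uses 1 pg = 978 Mbp and 1C = 2C/2 (diploids only).  The (k−1)-bases
undercount per contiguous sequence is ignored; it is negligible at
genome scale.

Organelle handling mirrors counter practice: organellar references are
counted with the minimum-count filter disabled (an assembly represents
each locus once, so singletons are genuine), and their k-mers are
subtracted from the sample dump before any estimate.

### Monoploid peak detection

The built-in detector is deliberately simple: moving-average smoothing
(window 3) of the spectrum counts, the error trough found as the first
local minimum from multiplicity 1, and the tallest smoothed local
maximum after the trough inside a user-given search range.  Because
smoothing flattens narrow peaks into plateaus, the integer location is
snapped to the raw-count maximum of the plateau, then refined to a
real value by the centroid of the raw counts in a symmetric window
(±40% of the peak multiplicity, clipped at the trough).  The centroid
matters: a Poisson-like sampling peak has an integer mode up to half a
unit below its mean, and the mean is the quantity the estimator
divides by; at c ≈ 25 using the mode alone biases genome size by ~4%.
Ties break toward lower multiplicity; a spectrum with no local maximum
in range (e.g. pure error decay) raises an error directing the user to
supply the coverage manually.  Model-based fitters estimate coverage
better on real data; a known coverage passed explicitly is always the
authoritative path, and the end-to-end tests centre the search window
on the nominal simulation coverage, standing in for such an external
estimate.

## Scaling, binning and coarse ranges

Scaled multiplicities (copy numbers) at or below 0.5 are discarded as
likely contaminants.  The remainder is pooled into geometric bins

    bin i = ( 0.5 · 1.1^i ,  0.5 · 1.1^(i+1) ]      i = 0, 1, …

whose upper limit is 10% above the lower limit; bin 39 spans
(20.57, 22.63].  The highest bin is set by the highest-copy k-mer
observed.  Note the one-point asymmetry kept deliberately: the genome
size estimator keeps multiplicities m ≥ c/2, while binning discards
scaled values ≤ 0.5 — both rules are applied exactly as defined,
per procedure.

The *expected copy number* of k-mers in bin i — used to convert k-mer
counts to base pairs — is the geometric mean of the bin bounds,
√(lower·upper), consistent with the geometric bin growth.  The
arithmetic midpoint differs by < 0.12% at 10% growth and is available
as an option.  Coarse range summaries (default breakpoints 10, 100,
10³, 10⁴, 10⁵, 10⁶) assign each bin to the range containing its
representative copy number, so the ranges partition the binned mass
exactly and always sum to the binned genome size.

## Pairwise and cohort comparisons

**Difference graphs** subtract per-bin k-mer counts of two samples over
the union of occupied bins, multiply by the bin's expected copy
number, and cumulate in ascending bin order (increasing
repetitiveness).  The total equals the difference of the two binned
genome sizes by construction, and the graph is antisymmetric under
argument swap.  A caveat on resolution: when a difference is carried
by few distinct k-mers concentrated in a single bin per sample (e.g. a
pure satellite-array change), the ±5% representative-value
quantization of two large, nearby bin masses can amplify to ~15–25% on
their *difference*; differences spread over many bins average this
out.  The step *location* in the cumulative graph — the diagnostic the
graphs exist for — is accurate to one bin (10%) regardless.

**Joint k-mer spectra** join two dumps on the k-mer column (full outer
join by default) and tally pairs of per-axis bins; a reserved absent
index (−1) records k-mers missing from one dump or discarded by that
axis's ≤ 0.5 cutoff, so presence/absence variation stays visible.  An
inner-join mode restricts to k-mers surviving on both axes.  Marginals
over either axis reproduce each sample's binned spectrum restricted to
its surviving k-mers — a consistency identity used as a test.

**Repeat attribution** reduces each repeat family to the k-mers unique
to it (k-mers shared between families are dropped from all, so family
sets are globally disjoint and contributions additive).  Restricting a
sample dump to a family's set and applying the genome-size sum — with
the same m ≥ c/2 cutoff, chosen for consistency with the global
estimator — gives that family's bp contribution; differencing two
samples and dividing by their total size difference gives the
explained fraction, which may exceed 1 when the non-repeat fraction
moves the other way.  Because only family-unique k-mers count,
contributions are systematically underestimates; no correction is
attempted.

**Distances and cohort tests.**  Manhattan distance is the summed
absolute per-bin count difference; the Gower distance is Gower's
coefficient restricted to quantitative variables — the mean over
occupied bins of |difference| divided by the cohort-wide count range
of that bin (zero-range bins skipped), bounded by [0, 1].  The cohort
check is a one-way fixed-effects ANOVA (sums of squares computed
directly so the explained-variance fraction SS_between/SS_total is
available; p from the F distribution) plus a label-permutation null:
labels shuffled uniformly n_perm times, exceedance reported with the
add-one rule (1 + #{perm ≥ obs})/(1 + n_perm) so p never reaches zero,
alongside the one-sided 95% null quantile.

## Synthetic data: what it emulates, what it does not

The generator builds a diploid genome as: single-copy sequence with a
dispersed TE family inserted at uniform positions (each copy
independently diverged by substitutions), followed by a head-to-tail
satellite array and a tandem rDNA-like block; haplotype B is haplotype
A with i.i.d. substitutions at the heterozygosity rate; a separate
organellar molecule is sequenced at a relative depth multiplier.
Reads are fixed-length, uniform-start, substitution-error only.
Defaults are a desk-scale rendering of a heterozygous plant genome:
1 Mbp single-copy (1C), 0.5% heterozygosity (field estimates for such
cohorts span ~0.1–1.4%), a 145-nt satellite at 1,500 copies per
haplotype, a 5-kb TE at 30 copies with 2% divergence, a 10-kb rDNA
unit at 20 copies, a 150-kb organelle at 20× relative depth, 150-bp
reads at 30× per haplotype with 0.2% error.

`make_pair` derives a second genome from the same components with
whole repeat copies added or removed, so the two genomes differ *only*
by the planted edit (plus their independent heterozygous
substitutions), and records the exact planted bp difference.  Family
ground truth stores the distinct canonical k-mers lying fully inside
family copies as placed on haplotype A; counting k-mers on the emitted
haplotype therefore reproduces each family's distinct-k-mer count
exactly, which is tested.

Deliberately not modelled: indels (k-mer identity methods never
inspect alignments, and substitution-only keeps truth exact), PCR
duplicates, GC bias, quality scores, and platform-dependent spectrum
peak widths — real spectra show substantially wider, sample-dependent
peaks than the Poisson-like sampling here.  Passing tests therefore
demonstrate the *arithmetic and bookkeeping* of the pipeline at
realistic structure and coverage, not robustness to every real-data
artefact; on real data, coverage should come from a model-based fitter
rather than the built-in detector.

## Problem sizes and numerical choices

End-to-end tests and examples use genomes of ~0.9–2 Mbp (1C) at 25–30×
per-haplotype coverage with ≤ 0.5% read error — small enough to run
comfortably on one CPU while keeping every structural feature (het
peaks, dispersed TEs, a multi-thousand-copy satellite, organellar
contamination) resolvable.  K-mers are held as 2-bit-packed uint64
codes in sorted numpy arrays (code order equals lexicographic order
for fixed k), so counting is exact single-pass with no probabilistic
sketches, and set operations are sorted-array merges.  Bin indices are
computed in closed form from logarithms with a one-step boundary
correction against floating-point error; the bin-39 bounds reproduce
(20.57, 22.63] to machine precision of the closed form.  All
randomness flows from explicit integer seeds through
`numpy.random.Generator`; identical seeds yield byte-identical
genomes, reads and outputs.

## Known limitations

* The peak detector assumes a visible monoploid peak; very low
  heterozygosity samples may require the manual coverage override
  (mirroring how coverage is obtained externally in practice).
* Diploids only: 1C = 2C/2, no ploidy inference, no mixture-model
  fitting of heterozygosity or peak width.
* Organelle subtraction removes any nuclear insertions of organellar
  DNA along with the organelles, slightly deflating estimates.
* Repeat contributions use family-unique k-mers only and are
  underestimates; shared-k-mer mass is not redistributed.
* Single-bin copy-number differences are located exactly but their
  binned magnitude carries the quantization error described above.
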