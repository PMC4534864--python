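# Methods

This note records the models, numerical choices and known limitations
behind `epifidelity`, in the order data flows through the package.

## Study design emulated by the generators

All simulators share one `SimConfig`: five cassava varieties, two
propagation conditions (field cuttings vs *in vitro* meristem culture),
three tissues (young leaf, mature leaf, root tip) and three replicate
plants per cell. One field tissue of one variety (Mfaransa, mature leaf)
is missing by default, giving 87 samples; `missing_cells` is exposed
because real designs of this shape are rarely complete and the exact
missing cells of the emulated survey are not recoverable. The same seed
and config always produce byte-identical outputs; ground truth is
*closed*, meaning every planted effect can be scored from the returned
`GroundTruth` alone.

### MSAP profiles

Each of the (default 160) loci is a CCGG site with a fixed fragment size
drawn on a 3-bp grid in [50, 600] bp, jittered per sample by N(0, 0.05)
to exercise the binning stage. Each locus carries one methylation state
per (variety, condition) drawn from (unmethylated 0.45, internal-mC
0.25, hemi-external-mC 0.10, hypermethylated/absent 0.20) — a plausible
mix for a plant genome where most assayable CCGG sites are either open or
CG-methylated. A fraction `frac_condition_loci` (default 0.15) of loci
switches state between conditions identically in all varieties,
emulating reproducible culture-induced methylation change. Fragment
presence follows enzyme biochemistry — HpaII cuts {unmethylated,
hemi-external}, MspI cuts {unmethylated, internal} — with a dropout
probability (default 0.02) deleting otherwise-present peaks (PCR/sizing
failure). Present peaks get lognormal heights (meanlog 6.5, sdlog 0.4,
arbitrary fluorescence units); absent loci emit no peak at all rather
than low noise, which keeps binary scoring unambiguous.

### msGBS tag counts and reads

Tag counts are negative binomial: `mu = lib_size * rel_abundance *
2^(±logfc/2)` with dispersion φ (default 0.2, a typical biological-
replicate value; Poisson at φ = 0), library sizes uniform in 80k–120k
reads and lognormal relative abundances. The default 40 of 2000 tags are
planted DMRs at |log2FC| = 3, split symmetrically across conditions so
group means separate by 8×; phase is drawn up-in-field with probability
0.9, mirroring the strong field-phase dominance such surveys report. The
planted effect applies in `dmr_varieties` (default all 5) varieties.

Read simulation plants each tag at a genomic position in a toy genome
(single chromosome, non-overlapping 3-exon genes every 14 kb), cycling
through the five annotation compartments and alternating strand, with
every site beginning `CGG`. Reads are `barcode + CGG + tag body`;
contaminants (corrupted barcode or cut site) are added at a configurable
fraction and logged. Only read 1 of a paired-end run is emulated since
the analysis uses single 64-mers. No sequencing-error, adapter-dimer or
chimera model: the demultiplexer's exact-match rules make base-level
error modelling equivalent to the contaminant fraction.

What the generator does **not** emulate — GC/length biases, PCR
duplicates, fragment-size homoplasy between loci, shared-ancestry
correlation between varieties, tissue-specific methylation beyond the
state table — means a passing suite demonstrates correctness of the
algorithms under the stated model, not robustness to every artefact of
real capillary or Illumina data.

## MSAP scoring

Peaks are clustered into loci per enzyme by single linkage with a size
tolerance (default 0.5 bp): a bin grows while consecutive sorted sizes
are within tolerance, and two peaks from the same sample never share a
bin — the taller keeps its place, the displaced peak seeds or joins the
next bin. Bin centers are mean member sizes. Binary scoring marks a cell
present iff the sample has a peak in the bin with height strictly above
`presence_threshold` (default 0, since instrument noise floors vary and
the generator emits no sub-threshold noise). Size windows are closed
intervals: [100, 580] bp qualitative (limits size homoplasy), [50, 550]
bp quantitative. Within a bin, same-sample heights are summed rather
than taking the maximum — robust to split peaks. The quantitative
low-intensity filter (`mean` or `total` height threshold) is exposed
unset by default; the emulated survey reports its filtered marker count
but not its threshold.

Cross-enzyme loci are matched greedily by bin center within the binning
tolerance. A locus polymorphic between groups in exactly one enzyme is
classed `epigenetic_only` (both enzymes see the same DNA sequence, so a
single-enzyme difference can only be methylation), in both
`genetic_or_epigenetic`, otherwise `monomorphic`. Per-site methylation
calls map (HpaII, MspI) presence to (1,1) unmethylated, (0,1)
internal-mC, (1,0) hemi-external-mC, (0,0) hypermethylated-or-absent
(uninterpretable: absence is also consistent with a sequence change).

## AMOVA / PhiPT / PCoA

Distances between binary profiles are squared Euclidean, i.e. mismatch
counts. PhiPT follows the standard two-level distance partition with the
unequal-n coefficient; negative among-group variance is truncated at
zero before forming PhiPT (the convention of the dominant-marker
population-genetics tools), and PhiPT is defined as 0 when both
components vanish (all-identical input). Permutation p-values use the
add-one correction with a default 999 permutations; whenever the number
of distinct label assignments does not exceed the requested
permutations, the null distribution is enumerated exactly and p is the
exact tail proportion (the identity assignment included, so p > 0).
Pairwise group contrasts are computed by subsetting to the two groups,
not from a global model; missing samples are dropped listwise per
comparison.

PCoA applies Gower centering to −½·d (the matrix already holds squared
distances), takes the symmetric eigendecomposition, scales eigenvectors
by the square root of positive eigenvalues, and reports negative
eigenvalues while dropping their axes. Cross-cultivar tissue-divergence
averages are arithmetic means over non-missing cultivars, rounded to 4
decimals (the precision such tables print).

## Count statistics

**TMM.** The reference sample is the one whose upper-quartile abundance
is closest to the mean upper-quartile. Per non-reference sample, log
ratios M and mean abundances A are computed over tags positive in both
libraries; 30 % of extreme M and 5 % of extreme A are trimmed (the
published defaults of the weighted-trimmed-mean method); the factor is
the precision-weighted mean of the surviving M. Precision weights use
the asymptotic binomial variance evaluated at a depth common to the
pair, so the shared depth factor cancels and the factor is exactly
invariant to rescaling either library — a deliberate deviation from
using each library's own depth in the weights, which would break that
exact invariance while changing weights only marginally. Factors are
rescaled to geometric mean 1; library depth lives in `lib_size`.

**Quantile adjustment.** Before conditioning, counts are mapped to a
common effective library size (geometric mean of `lib_size ×
norm_factor`) by carrying each count's lower-tail NB probability to the
target distribution and inverting on the piecewise-linear interpolation
of the target CDF between consecutive integers. Per-tag expected
abundances are estimated within group so genuine fold-changes are not
flattened.

**Dispersion.** The common dispersion maximises the summed conditional
NB log-likelihood of the pseudo-counts over φ ∈ [1e−6, 10] (bounded
search on the log scale), iterating equalisation and maximisation until
the estimate is stable to 1e−4 in log; flat or monotone-decreasing
likelihoods (Poisson-like or degenerate data) return the lower bound.
Tagwise dispersions maximise `CL_tag(φ) + prior_n · meanCL(φ)`
(empirical-Bayes shrinkage toward the common value, default prior_n 10).
Maximisation is a dense 85-point log-grid pass, an 11-point local
refinement, and quadratic interpolation; the shared curve is
cubic-spline interpolated so that large prior weights cannot pin
argmaxes to grid knots. `prior_n = 0` reproduces per-tag conditional
MLEs; `prior_n → ∞` reproduces the common value to < 1e−3 in log.

**Exact test.** Group pseudo-count sums are rounded per group (rounding
the grand total instead would make the test asymmetric under group
swap), and the conditional distribution of the group-1 sum — the
normalised product of two NB mass functions with sizes `n_g/φ` and a
common per-sample mean `t/(n1+n2)` — is enumerated over the full
support. The two-sided p-value sums all outcomes with probability no
greater than the observed one (minimum-likelihood method, tie-inclusive
at 1e−12 relative tolerance, no doubling); φ < 1e−10 switches to the
exact binomial limit. A zero total gives p = 1. Log2 fold-changes add a
prior count of 0.125 per observation. Peak-height matrices are rounded
to integers before entering this machinery — intensities are treated as
count-like abundances, an approximation adequate for rank/significance
purposes but not for absolute quantification.

## msGBS processing and DMR consensus

Demultiplexing retains a read iff it begins with an exact sample barcode
immediately followed by `CGG`; the 64-bp tag *includes* the CGG remnant
at its 5′ end (the trimming convention is ambiguous in the field;
configurable). Reads shorter than the tag length after barcode removal
are rejected rather than padded, avoiding phantom tags. Barcode maps
must be prefix-free. No quality filtering beyond structure. Tags seen in
the negative water control are removed first, then tags present in
fewer than 3 samples (the order is configurable; control-first is the
default). Retained + rejected always equals input, per file.

Per-variety tests pool tissues within condition and apply BH within
variety (matching how per-variety significant counts are tabulated). A
tag is a consensus DMR iff its q-value is below the FDR threshold
(default 0.05) with the same phase in at least `min_varieties` (default
4 of 5) varieties, no variety is significant with the opposite phase,
and the tag is observed (count > 0) in at least one sample of every
variety — the last rule standing in for "no variety-specific sequence
variants", which cannot be checked without genotypes. The 4-of-5
default with a strict no-opposite-phase rule reconciles the two natural
readings of "consistent across genotypes": tolerant of one
underpowered variety, intolerant of contradiction.

## Annotation

Exact 64-mer search (forward and reverse complement) replaces alignment:
at this length an exact hit is effectively unambiguous, and an adapter
accepts an external hit table for users who ran BLAST themselves.
GFF3's 1-based inclusive coordinates are converted to 0-based half-open
internally (round-trip tested). Classification priority: exon overlap,
then gene-body (intron), then strand-aware flanks — gaps of up to
exactly 5000 bp to the TSS (upstream) or from the TTS (downstream) —
else intergenic. The nearest qualifying gene wins; ties break by smaller
distance, gene-body over flank, then lexicographic gene id.

## Problem sizes used in validation

The test suite verifies the AMOVA engine against a definitional
sums-of-squares oracle with exhaustive permutation enumeration on all
fixtures up to 8 samples; the exact test against direct enumeration for
totals up to 200 and the exact binomial at φ = 0; type-I error on a
2000-tag null (3 vs 3, φ = 0.2) against the 99 % binomial envelope of
α = 0.05; dispersion recovery at φ ∈ {0.05, 0.2} with 2000 tags and
6 + 6 samples; and the full consensus caller at the generator's design
defaults over 20 seeds (recall ≥ 0.9, empirical FDP ≤ 0.10). Read-level
checks (demultiplexer conservation, annotation of planted tags) run on a
scaled-down simulation — 12 libraries of a few hundred reads and a
50-gene-scale toy genome — because the rules they verify are exact and
scale-free, while count-level performance is measured at full design
scale.

## Known limitations

* Intensities-as-counts: the NB machinery on MSAP peak heights inherits
  the rounding approximation above.
* The conditional exact test is discrete and therefore mildly
  conservative at small totals.
* Consensus calling treats varieties as independent evidence; shared
  ancestry among cultivars would make the 4-of-5 rule anti-conservative
  in ways the generator does not emulate.
* Exact tag location ignores polymorphism between the sample and the
  reference genome; a single SNP in a tag hides it from annotation
  (the external-hit adapter is the escape hatch).
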