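# Methods

This note records the models, conventions and design choices behind
`foliarchem`, in the spirit of a statistical-methods appendix.

## Spectral scoring and clustering

A spectrum is a precursor m/z plus an m/z-sorted list of positive-intensity
fragment peaks.  The similarity of two spectra is the cosine of the angle
between their matched fragment vectors:

* candidate peak pairs are those within `fragment_tol` (default 0.02 Da) of
  each other, and — when precursor-shift matching is on — those whose m/z
  difference equals the precursor mass difference within the same
  tolerance ("modified cosine", the convention of molecular networking);
* candidates are accepted greedily by decreasing intensity product, each
  peak used at most once.  Greedy matching is near-optimal and
  linearithmic; at networking tolerances candidate pairs are almost always
  disjoint, where greedy *is* the exact optimal assignment (the test suite
  checks this against exhaustive enumeration, and against matchms);
* intensities are raised to power 0.5 before use (default; configurable).
  Square-root weighting tempers the dominance of base peaks and is standard
  practice in molecular networking;
* the dot product is normalised by the L2 norms of the *full* weighted peak
  vectors, so scores lie in [0, 1] and 1 requires identical spectra.

Clustering into consensus compounds is single-pass greedy: a spectrum joins
the first compound whose consensus precursor is within `precursor_tol`
(0.02 Da) and whose consensus cosine is at least `cluster_threshold`
(0.95), else founds a new compound.  Precursor-shift matching is *off*
during clustering — cluster identity means "same molecule", and a shifted
match contradicts that — and *on* during network scoring, where edges mean
"structural analog".  Consensus peaks are tolerance-merged
intensity-weighted means with summed intensities; the consensus precursor
is the intensity-weighted mean over members.  Clustering order matters only
through ties; with classes separated by more than ~0.2 in cosine the
partition is order-invariant (tested).

The network links compound pairs with modified cosine ≥ 0.6, inclusively.
No minimum-matched-peaks or top-K topology pruning is applied: the
upstream tools' defaults for these are not part of the analysis being
reproduced, and the synthetic classes do not need them.

## CSCS and Bray–Curtis

The chemical structural similarity matrix css has 1 on the diagonal, the
edge cosine where a network edge exists, 0 elsewhere.  With samples as
relative-intensity vectors (rows normalised to sum to 1),

    CSCS(A,B) = A' css B / max(A' css A, B' css B),
    BC(A,B)   = 2 Σ min(aᵢ,bᵢ) / Σ (aᵢ+bᵢ).

The CSCS quadratic form follows the metric's original formulation; it is
isolated in `cscs_pair` so an alternative definition can be substituted in
one place.  Both metrics are computed on relative intensities so they are
scale-free; a flag disables normalisation for pre-normalised tables.
Because css is generally not positive semidefinite, the raw CSCS quotient
can marginally exceed 1; values are clamped to [0, 1], with a warning when
the excess passes 1e-9.  Clamping (rather than failing) keeps the matrix
usable while making the event visible; the brute-force oracle in the tests
applies the same clamp, since it is part of the definition.

## Constrained permutation inference

For factor F with optional control C on a sample subset, Δ = mean
similarity over pairs concordant for F and C, minus mean over pairs
discordant for F but concordant for C.  The test shuffles the F labels
across the subset's samples — preserving the dependence structure among
pairs sharing a sample — while C labels stay fixed, and re-applies the
C-discordant-pair rejection after each shuffle.  Permutations that leave an
empty pair set are redrawn (capped at 100 × n_perm).  One-sided for
within > between.

Two p-values are reported:

* `p_paper`: the strict proportion of permuted Δ larger than observed
  (ties count as "not larger"); it can be exactly 0 or 1;
* `p_corrected` (default): (#{Δ* ≥ Δ} + 1)/(n_perm + 1).  Ties belong in
  the tail here: under label shuffling the observed partition itself recurs
  (probability 1/35 for a 4+4 binary factor), and excluding those ties
  makes the test anti-conservative — measured null rejection ≈ 0.07–0.08
  at α = 0.05 versus 0.03–0.05 with ties included.

Calibration was verified on null data (no treatment effect): with 6
samples per arm the rejection rate at α = 0.05 over 500 simulated datasets
is 0.050–0.054 across seeds, and the p-distribution is uniform at 0.10 and
0.25 as well.  Note that a 4+4 stratum admits only 35 distinct label
partitions, so *any* valid permutation p there is quantized in ~0.029
steps; the calibration suite therefore uses 6+6 strata (924 partitions),
where granularity no longer dominates.

The species contrast follows the focal/congener design: within pairs are
all pairs of focal-species samples (ages and treatments pooled); between
pairs join each focal sample with each congener young-control sample.
Pairs of two distinct congeners are never compared — each congener
contributes a single sample, so such pairs estimate nothing about
within-species variation.  Permutations shuffle the species labels over
the genus subset with the same pair rules.

Species-level p-values are combined with the weighted-Z method,
Zᵂ = Σ wᵢZᵢ/√Σwᵢ², default weights wᵢ = √(n_within,i + n_between,i)
(size-weighting in the Stouffer tradition).  Combination requires
p ∈ (0, 1), so the pipeline's combined rows use `p_corrected`; Wilcoxon
p-values entering a combined row are clipped to [1e-6, 1−1e-6] as a guard
against exact 0/1 from small-sample enumeration.  The one-sided Wilcoxon
rank-sum test enumerates all rank assignments exactly up to 12 untied
observations and otherwise uses the normal approximation with tie and
continuity corrections.

Classical MDS embeds samples from d = 1 − s (√(1−s) available; the choice
matters little for visualisation and 1 − s is kept as the default for
interpretability).  The doubly-centered squared-distance matrix is
eigendecomposed; coordinates come from the top-k positive eigenvalues, and
negative eigenvalues (similarity matrices need not be Euclidean) are
dropped with a logged count.

## The synthetic study generator

The generator produces data with the statistical structure the analysis
assumes, so the pipeline can be exercised and validated end to end.

**Compound library.** 67 classes × 12 compounds + 498 singletons = 1,302
compounds by default.  Each class has a template of 20 fragment positions
on [50, 1600] Da (spanning typical LC-MS/MS detection); class members draw
80% of their 25 peaks from the template with lognormally jittered template
intensities (σ = 0.3), the rest fresh, so same-class cosines land around
0.7–0.8 (above the 0.6 edge threshold) and singleton/between-class cosines
near 0.  Precursor = heaviest fragment + one proton mass.

**Design.** Four genera with 14, 10, 2 and 19 congeners (one young,
control sample each; 45 total) and one focal species each, sampled over
{young, mature} × {JA, control}.  Per-cell counts (4,4,4,3) for the first
focal species and (4,4,3,3) for the rest give the 57 focal samples that
complete the 102-sample default; the split is recorded in the truth file
since only the total is externally fixed.  Blanks (3 by default) contain
only the designated contaminant compounds, which are drawn from library
compounds unused by any species.

**Effects.** Each species holds 70 compounds: a genus core of
round(overlap × 70) compounds shared by all congeners
(`species_compound_overlap` = 0.15) plus species-unique compounds drawn
disjointly within the genus — so congener overlap is exact by
construction, and overlap 0 means provably disjoint congeners.
`age_turnover` = 0.30 of a species' compounds are split young-only /
mature-only; `inducible_fraction` = 0.10 of them (sampled per species, as
induction responses are species-specific) gain a ×2 intensity
`induction_fold` under JA.  Intensities are lognormal (σ = 0.6) around
per-compound base abundances drawn log-uniform over three decades.  These
defaults realise the qualitative ordering the analysis is designed to
detect: species turnover ≫ ontogenetic turnover ≫ induction.

**Data contract.** Replicate spectra (3 per observed compound, ±0.0025 Da
m/z jitter, 20% intensity CV) are written as MGF with
TITLE = `<feature_id>.<replicate>`; the quantification table's columns are
the feature ids.  The pipeline clusters the spectra, then assigns each
cluster the majority feature id of its members — mirroring feature-based
molecular networking, where the spectrum→feature mapping is part of the
upstream export.  The generator's latent truth (classes, species pools,
inducible sets, contaminants) goes to a separate JSON used only by tests.

**What the generator does not emulate:** chromatographic retention and
co-elution, isotope patterns and adduct chemistry, missing-data structure
from peak picking, instrument drift and batch effects, and realistic
fragment-mass distributions (peaks are uniform on the mass range).
Passing tests therefore demonstrate that the statistical machinery behaves
correctly under the assumed data-generating model, not that the pipeline
is robust to every artefact of real instrument data.

## Numerical and reporting conventions

* All randomness flows from explicit seeds; the pipeline derives per-test
  seeds from one root generator in a fixed order, so a fixed configuration
  reproduces byte-identical CSV outputs.
* Fragment tolerances are absolute Da (the simulated mass accuracy is
  constant across the range); ppm tolerances were not needed.
* Blank subtraction removes any compound reaching `min_blank_intensity`
  (default: any positive intensity) in any blank.
* Problem sizes in the validation suites — 500 null datasets at
  n_perm = 199 for calibration, 100 realizations for power, the full
  102-sample design with 999 permutations for effect recovery — were
  chosen to make the binomial uncertainty of the measured rates small
  relative to the bands being checked.
* Kovats retention indices interpolate linearly between bracketing alkanes
  (van den Dool & Kratz form, appropriate for temperature-programmed GC);
  retention times outside the ladder raise rather than extrapolate.

## Known limitations

* Greedy clustering is order-dependent in principle; consensus drift can
  split a compound when replicates straddle the threshold (the pipeline
  run above yields 1,261 clusters for ~1,260 observed compounds).
  Cluster→feature assignment absorbs such splits.
* CSCS depends on the network threshold through css sparsity; no
  sensitivity analysis across thresholds is built in.
* The permutation test conditions on the realised design; severely
  unbalanced strata reduce the number of distinct partitions and hence the
  attainable p-value resolution (see calibration discussion above).
* No multiple-testing correction is applied across report rows, matching
  the reported analysis; users scanning many factors should correct
  externally.
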