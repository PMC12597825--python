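# Methods

This note documents the statistical model, the default parameters and their
rationale, the numerical choices, and the scope of the built-in simulator.

## Overview

Genotyping a locus is posed as model selection over haplotype pairs. For each
candidate genotype the recruited reads are aligned to both haplotypes, every
read is assigned to one of its possible locations by an optimizer, and the
genotype is scored by the optimized joint log-likelihood. The pipeline has
four stages: profile fitting, read recruitment, alignment, and genotype
selection.

## Profile fitting

All profiles are fitted to the sample's own reads aligned to a user-supplied
background region, chosen to be diploid, unique and well-assembled, so that
the profiles reflect the library and instrument rather than the target locus.

- **Insert size.** Outer fragment lengths of proper pairs are fitted by a
  negative binomial via moment matching (method-of-moments `n` and `psi` from
  the sample mean and variance; underdispersed data are clamped to
  `psi = 0.999`). Fragments outside the central 99.9% quantile range are
  discarded before the final fit; the model stores the 99.9% interval used to
  gate candidate alignment pairs.
- **Errors.** Per-read edit operations (mismatch, insertion, deletion) against
  the background are pooled. A beta-binomial captures the per-read error-count
  distribution (over-dispersion across reads), and the relative rates of the
  three operation types are kept as multinomial fractions.
- **Depth.** The background is tiled into 100 bp windows; the first-mate count
  per window is fitted by a negative binomial, stratified by GC content in
  integer percent bins (nearest fitted bin is used at lookup time). Windows
  with k-mer uniqueness below a threshold are excluded from fitting because
  multi-mapping inflates their counts.

## Read recruitment

Targets are indexed by (w=10, k=15) minimizers. Minimizers occurring at least
5 times in the off-target portion of the genome are marked uninformative and
excluded from the match denominator. A short read is recruited when each end
matches at least a fraction (default 0.7 single-end, 0.5 per end for pairs) of
its informative minimizers against some locus. Long reads are scored with a
maximum-subarray (Kadane) statistic over per-minimizer match/mismatch scores
within subregions, with an analytic threshold derived from the match-fraction
parameters; at defaults the threshold for a full-length subregion is 364. The
empty subarray is allowed, so an all-negative score vector scores 0.

Each read also gets a count of target-specific k-mers (present in the locus,
absent off-target). Reads with fewer than 5 such k-mers are treated as
location-uninformative: their location probabilities are equalized so they
contribute depth but no alignment preference.

## Alignment and filtering

Reads are aligned to every panel haplotype with banded edit-distance alignment
(edlib), band width `max(16, round(0.12 · read_len))`, reported as extended
CIGARs so mismatches, insertions and deletions are separated. Each alignment
gets a beta-binomial tail p-value for its error count. A read pair is kept
only if every end has some alignment with p ≥ 0.01; within kept reads,
alignments with p < 0.001 are dropped. The two-tier rule keeps marginal but
plausible secondary alignments while discarding reads that fit no haplotype.

## Genotype likelihood

For genotype G and read assignment ξ,

```
L(ξ) = Ω_R Σ_r log P(loc_r) + Ω_D Σ_w ζ_w log φ_w(d_w)
```

- `P(loc_r)` multiplies per-end alignment likelihoods (beta-binomial error
  model) and the insert-size likelihood, normalized over all of the read's
  locations on G. Partially or fully unmapped locations use a penalty factor
  Λ = 1e-5 times the best alignment probability per unmapped end.
- Windows tile each haplotype; trailing bases short of a full window are
  merged into the last window. A synthetic *null window* with ζ = 0 and
  φ ≡ 1 receives unmapped ends, so the depth term is indifferent to them and
  bookkeeping stays uniform.
- `φ_w(d)` is the posterior that depth `d` arises from copy number 1 (per
  haplotype) rather than the alternatives 0.5 or 1.5, under GC-matched
  negative binomials. Depth counts are capped at `dcap`, sized per problem so
  the cap is never binding.
- `ζ_w` multiplies a k-mer-uniqueness weight and a linguistic-complexity
  weight, each passed through the gate
  `ϑ(x; η, q) = 1 / (1 + ((1-x)/x)^q · (η/(1-η))^(-q))`
  — a smooth, strictly increasing map of [0,1] onto [0,1] with ϑ(0)=0,
  ϑ(η)=1/2, ϑ(1)=1. Defaults: (η=0.2, q=4) for uniqueness, (η=0.5, q=4) for
  complexity. Optional per-base explicit weights from a BED file multiply in.
- Ω_R = 0.15, Ω_D = 1.85: depth is weighted up because per-window depth terms
  are fewer and individually weaker than per-read alignment terms, yet depth
  is what distinguishes copy-number differences between haplotypes.

Moving one read between locations changes at most four window depths, so the
likelihood delta is computed in constant time; an `AssignmentState` maintains
depths and the current value incrementally.

## Optimization

- **Simulated annealing** (default): geometric cooling (factor 0.97 per
  block), block length `max(#movable reads, 20)`. The initial temperature is
  calibrated per problem as the 90th percentile of |Δ| over 100 random moves,
  so the schedule adapts to the likelihood scale. The best-seen state is
  restored at the end and polished by greedy passes.
- **Greedy**: repeated passes in random read order taking the best
  single-read move until no move improves by more than 1e-12.
- **ILP**: exact formulation with one-hot location variables per read and
  one-hot depth-level variables per window (HiGHS backend via scipy). Reads
  with a single location are folded into constants; if all reads are such,
  the forced assignment is returned directly.
- **Brute force**: exhaustive product over locations, guarded by a size limit;
  used as a test oracle.

The annealing and greedy inner loops have numba-compiled kernels operating on
a flattened problem layout; the kernels compute exactly the same deltas as
the reference implementation (apply-and-revert on the affected windows) and
are covered by equivalence tests. Without numba the pure-Python path runs.

## Genotype ranking and quality

Candidate genotypes are prefiltered by a per-read upper bound on the
alignment term: a genotype is dropped only when its bound falls more than
100·ln 10 below the best bound, and never when at most 500 candidates exist.
Each surviving genotype is re-optimized under repeated multiplicative noise
injections of the per-location log-probabilities (default 20 replicates).
The primary genotype maximizes the mean optimized likelihood; its quality is
`-10 log10 p` (capped at 1000) where `p` is the one-sided Welch t-test
p-value against the runner-up's replicate values, and probabilities across
genotypes are a softmax of mean likelihoods. Genotypes within a factor 1e-3
of the primary are reported as probable alternatives. Diagnostics include the
number of reads left unexplained (best location unmapped) and a weighted
Jaccard distance between observed and expected window-depth multisets.

## Evaluation

Predicted haplotypes are scored by global alignment against the truth. The
corrected QV is `-10 log10((delta + 0.5·[delta = 0]) / size)` where `size`
counts matches plus edits, so identical sequences get a finite value and each
additional edit near zero costs exactly `10 log10 2 ≈ 3.01` QV. Diploid
predictions are paired with the truth in the orientation minimizing pooled
divergence; trio concordance scores a child's haplotypes against the best
parental assignment.

## Simulator

The simulator generates: a random locus with an embedded tandem repeat whose
copy number varies per haplotype, point mutations at configurable SNV/indel
rates, optional structural variants (insertions/deletions, default one of
300 bp), paired short reads with NB insert sizes and per-base errors, long
reads with log-normal-like lengths, and a separate background region with
reads for profile fitting. Two lineage modes control panel relatedness:
`star` mutates every haplotype independently from the root, while `tree`
mutates each new haplotype from a uniformly chosen earlier one, producing the
nested similarity structure typical of real haplotype panels.

## Limitations

- Reads are assigned to one location each; chimeric reads and split
  alignments are not modelled.
- Depth windows assume a roughly constant per-window rate given GC; strong
  positional coverage biases (e.g. fragmentation hotspots) are not modelled.
- The corrected QV is global-alignment-based and thus O(n·m) in sequence
  length; very long haplotypes are better compared with banded methods.
- Copy-number differences that only long-range information can resolve (for
  example repeat expansions with perfectly repeated units longer than the
  insert size) are genuinely ambiguous for short reads: the likelihood is
  then driven by depth alone and close copy numbers may not separate.
- The ILP solver is exact but scales poorly with depth-level counts; it is
  intended for validation and small problems.
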