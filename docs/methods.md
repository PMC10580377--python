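# Methods

## Model and procedure

Kataegis — regional somatic hypermutation — manifests as runs of unusually
small intermutation distances (IMDs). `kataseg` treats the per-chromosome
IMD sequence as piecewise-exponential: within a segment, IMDs are
exponential with a constant rate, and a changepoint marks a rate shift.
Detection proceeds per sample:

1. **Preprocessing.** Variants are sorted per chromosome; records whose
   [start, end] intervals overlap are merged into one record spanning their
   union (the earliest record's alleles are kept). Phasing and clonality
   are not considered. After preprocessing, starts are strictly increasing,
   so every IMD is ≥ 1.
2. **IMDs.** `IMD_1 = s_1` (distance from the chromosome start) and
   `IMD_i = s_i − s_{i−1}`; a closing pseudo-IMD
   `n_chrom − s_last` makes the sequence sum exactly to the chromosome
   length. The pseudo-IMD participates in segmentation as the final
   observation but is never counted as a variant. A pseudo-IMD of 0 (last
   variant on the final base) is replaced by 1 in the observation vector
   only, keeping the exponential cost defined; the stored value remains 0
   so the conservation identity stays exact.
3. **Segmentation.** Penalized changepoint detection with segment cost
   `2·m·(ln S − ln m)` (twice the negative maximized exponential
   log-likelihood, additive constants dropped — they cancel across
   segmentations), penalty β = `2·ln n` per changepoint (BIC: each extra
   segment adds one free rate and one changepoint location), and minimum
   segment length 2. The default search is PELT, which returns the exact
   penalized optimum. Chromosomes with fewer than `2·min_seg_len`
   observations (variants + pseudo-IMD) skip the search and form one
   segment.
4. **Annotation.** Segments tile the chromosome: a segment runs from one
   base past the previous segment's last variant to its own last variant
   (the final segment ends at the chromosome end). Member counts, mean IMD
   and rate `λ_s = k_s / n_s` use member variants only, so
   `Σ k_s = k_total` and `Σ n_s = n_chrom` hold exactly and the sample rate
   satisfies `λ_t = k_t / n_t = Σ λ_s n_s / n_t` (asserted to 1e−9
   relative on every run).
5. **Calling.** A segment qualifies when its mean IMD is at most the IMD
   cutoff and it represents at least `min_size_kataegis` variants.
   Variant counting here includes the segment's upstream **anchor** (see
   below). Cutoffs are evaluated per segment before merging; maximal runs
   of adjacent qualifying segments are merged into single loci with pooled
   counts and pooled mean IMD (total member IMD sum over total member
   count). A locus spans from its first segment's anchor (or first member,
   at a chromosome start) to its last member variant.

### The anchor convention

An IMD is a pairwise quantity: a run of *m* consecutive small IMDs is
witnessed by *m* + 1 variants. The first variant of a mutation cluster
carries, as its own IMD, the large gap from the preceding variant — that
observation belongs to the upstream segment — yet the variant itself is
part of the cluster: its distance to the next variant is the segment's
first small IMD, and it sits exactly 1 bp before the segment's genomic
start. The classical kataegis definition counts *variants* (≥ 6 variants ⇔
≥ 5 clustered IMDs), so size filtering and locus bounds include the anchor.
Without it, a planted 6-variant locus is structurally undetectable at
`min_size_kataegis = 6` (its segment holds only 5 member variants), which
contradicts the benchmark behaviour this package reproduces (see
`tests/test_acceptance.py`). Segment partition fields keep exclusive
semantics, so the rate identities and tiling invariants are unaffected.

### PELT via functional pruning

Classic PELT prunes candidate changepoints by an objective inequality; on
homogeneous (changepoint-free) sequences that pruning removes almost
nothing and the search degenerates to O(n²) — prohibitive at n ≈ 1.25×10⁵
observations per chromosome. `kataseg.pelt` therefore prunes
*functionally*: writing the last segment's mean as μ and z = ln μ, each
candidate's cost contribution is `a + 2b·e^(−z) + 2c·z`, a convex curve in
z, and the dynamic program only needs the lower envelope of these curves.
Candidates that leave the envelope can never become optimal again (adding
a new observation shifts every curve identically), so the per-step work is
proportional to the number of envelope pieces — empirically a few dozen —
independent of how many candidates a homogeneous stretch accumulates.
Curve intersections are found by safeguarded Newton iteration (bisection
fallback, tolerance 1e−13 relative in z) on a z-domain padded two units
beyond [ln min(obs), ln Σ obs], which contains every attainable segment
mean. The result is the same optimum as unpruned optimal partitioning:
the test suite verifies identical changepoint sets and objectives against
a brute-force dynamic program on hundreds of random sequences, and against
the classic inequality-pruned PELT (`_pelt_quadratic`, retained for
cross-checking) on mid-size structured sequences.

Reported objectives of all four searches are recomputed from the returned
changepoint set through one shared cost routine, so equal segmentations
give bitwise-equal objectives regardless of the search internals.

Tie-breaking is deterministic everywhere: among equal-objective options the
earliest admissible previous endpoint wins (hence fewer/earlier
changepoints); numpy `argmin`-style first-minimum rules apply in binseg,
segneigh and amoc.

## Parameters

| parameter | default | units | role |
|---|---|---|---|
| `imd_cutoff` | 1000 | bp | max mean IMD of a kataegis segment; `"pcawg"` selects the adaptive rule `−ln(1 − (0.01/L_s)^{1/(k_s−1)}) / λ_med`, `λ_med = ln 2 / median(IMD)`, capped at 1000 bp (the cap is our reading of the rule's bracketed constant; segments with k < 2 get cutoff 0) |
| `min_size_kataegis` | 6 | variants | minimum locus size, anchor included |
| `search` | `pelt` | — | changepoint search; binseg is greedy (objective ≥ PELT's), segneigh exact under a segment budget, amoc at most one change |
| `min_seg_len` | 2 | observations | smallest segment; 2 is the smallest length for which a rate is a meaningful fit |
| `penalty` | `bic` (2 ln n) | — | per-changepoint penalty; larger β ⇒ fewer segments |

## Synthetic data generator

The generator emulates a neutral mutation process: every base mutates with
equal probability (a Bernoulli process along the chromosome), so background
IMDs are geometric with mean 1/p. Conditioned on the mutation count the
process is uniform placement without replacement, which is how positions
are drawn; the count is fixed by the tumor mutational burden,
`round(TMB · L / 10⁶)` (half away from zero). Each planted kataegis locus
places k variants uniformly without replacement in a window of
`E(T)·(k+1)` bp starting at a uniform position (windows are resampled until
pairwise disjoint and in-bounds), which makes the expected intra-locus gap
E(T). All positions in a sample are distinct; a variant's truth label is
TRUE iff it lies inside a planted window, so background variants that land
there are labeled TRUE. Alleles are uniform SNVs (ref over ACGT, alt over
the remaining three), assigned from the same per-sample random stream.

The benchmark design crosses 8 TMB classes (0.1, 0.5, 1, 5, 10, 50, 100,
500 mutations/Mbp) with locus count {1, 2, 3, 5} × variants-per-locus
{6, 10, 25, 50} × expected IMD {100, 250, 500, 750} bp, plus 64 locus-free
samples per class: 1,024 samples, 176 planted loci and 4,004 planted
in-locus variants per class, 21,299,360 variants in total on a
249,250,621 bp chromosome (hg19 chr1 length). A single master seed derives
per-sample substreams positionally, so any sample regenerates in
isolation.

**What the generator does not model:** trinucleotide context and mutational
signatures, the reference genome's N-base mask, copy-number or clonality
structure, indels/SVs (planted variants are SNVs), and inter-chromosome
effects (all simulation is single-chromosome). Passing benchmark tests
therefore demonstrates correct behaviour under a neutral uniform background
with planted clusters — not performance on the full complexity of real
tumor genomes, where validated callsets are required.

## Numerical and design choices

- Coordinates are 1-based inclusive internally (VCF/MAF convention); BED
  output converts to 0-based half-open at the boundary only.
- Chromosome names are normalized to the dialect of the supplied
  chromosome-length table ("chr1" vs "1").
- VCF FILTER handling is keep-all by default (configurable), multi-allelic
  rows split into one record per alternate allele; indel/SV rows import by
  their POS like any row.
- MCC with a zero denominator factor is defined as 0 (nMCC 0.5):
  degenerate all-negative samples are common in the null half of the
  benchmark. Confusion matrices are pooled (summed) within TMB class
  before computing metrics, rather than averaging per-sample metrics.
- Variant matching in evaluation is positional (chromosome, position), not
  allele-aware, matching the generator's positional labels.
- Locus concordance uses the ≥ 1 bp overlap rule on closed genomic
  intervals; abutting loci do not match.
- Rainfall plots place variants at ordinal x positions (genomic order, not
  coordinate), floor IMDs at 1 for the log axis, and mark chromosome
  boundaries when plotting everything.

## Problem sizes in the shipped checks

The test suite and `scripts/acceptance.py` regenerate and analyse the full
1,024-sample benchmark (≈ 21.3M variants); functional pruning makes this a
few minutes of single-core work. Changepoint exactness is verified on 200
random sequences of n ≤ 30 against the brute-force oracle (where exhaustive
dynamic programming is tractable) plus structured sequences of n ≈ 800
against quadratic PELT.

## Known limitations

- Only the exponential cost is implemented (no Gaussian/nonparametric
  costs, no penalty-path sweeping): the observation model is fixed by the
  method.
- The detector targets kataegis; smaller clustered-mutation classes
  (e.g. omikli) are reachable by lowering `min_size_kataegis` but are
  untested here.
- With `min_seg_len = 2`, one cluster-edge variant can be sacrificed when
  the closing pseudo-IMD or a chromosome boundary forces a pairing; this
  is inherent to the minimum-segment-length constraint.
- Greedy binseg can underfit (tests assert its objective never beats
  PELT's); segneigh is O(Q·n²) and intended for short sequences or tight
  budgets.
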