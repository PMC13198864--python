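# Methods

This note documents the statistical model, the tunable parameters, the
synthetic-data generator and the numerical choices made where the design
was genuinely open.  Nothing here reports an empirical value that the
test suite or `scripts/acceptance.py` does not itself compute.

## Model and procedure

### Relatedness screen

Partners for a focal individual are all cohort members with diploid SNP
relatedness π̂ < `pihat_max` (default 0.33), computed genome-wide on all
QC-passing SNPs with the standard GRM off-diagonal estimator.  The
threshold removes parents, offspring and full siblings — full siblings are
uninformative here because they inherit haplotypes from both of the same
parents — while retaining 2nd-degree and more distant relatives, whose
cross-chromosome IBD sharing is the phasing signal.  π̂ is accumulated
chromosome-by-chromosome in single precision; at ~40k SNPs the dot-product
rounding error (~1e-3) is negligible against the 0.33 threshold.

### Windows

Chromosomes are cut at recombination hotspots so that windows are
approximately independent: per chromosome the 10 map intervals with the
highest cM/Mb ratio are boundary candidates (midpoint placement, ties to
the smaller bp), swept left to right; a candidate closes a window only if
that window spans at least `min_span_cM` (default 25 cM).  The terminal
window runs to the chromosome end and merges into its left neighbour if
too short, so only a chromosome-end window may be shorter than the
minimum.  Windows are built from the map alone and SNPs are then assigned
to half-open bp spans (a SNP exactly on a boundary goes right; windows
left empty are dropped and their span folded into a neighbour).

### Haploid similarity

`psi_window` restricts both haplotypes to the focal-heterozygous sites of
one window, finds the longest contiguous run of identical alleles, and
sums `((x_k − p_k)² / (p_k (1 − p_k)))^(1/5)` over that run.  Choices:

* **Run axis.** "Contiguous" is measured in focal-heterozygous sites after
  restriction — not bp, cM or all-SNP count — because only heterozygous
  sites are phase-informative and the sum itself ranges over the
  restricted index.
* **Ties.** Among equal-length runs the larger term sum wins, then the
  leftmost start.  Ties are vanishingly rare on real-valued terms but the
  rule makes the kernel, the reference implementation and the brute-force
  oracle agree bit-for-bit.
* **Non-negativity.** Minor-allele coding caps p at 0.5 and the run
  contains only identical alleles, so every term is ≥ 0; this is asserted
  at run time.
* **Exponent 1/5** (`psi_term_exponent`): damps the weight of rare-allele
  matches; a single match at p = 0.05 still counts more than one at
  p = 0.5, but less than 5× more.

`psi_star` takes the larger of the two ψ̂ values against a partner's two
haplotypes and raises it to `psi_star_power` (default 2), sharpening the
contrast between background similarity and IBD-driven similarity.  The
per-window max makes the tensor invariant to partner-side haplotype
relabelling inside any window, hence robust to partner switch errors.
The power default of 2 follows the displayed definition of the statistic;
it is exposed as configuration because the source material is not fully
self-consistent about it (an adjacent prose statement says 4).

The inner longest-run scan is JIT-compiled (numba) over a
(partner-haplotypes × het-sites) match matrix; the pure-NumPy
`psi_window` is the reference path and the two are cross-checked against
an O(L²) all-runs oracle in the test suite.

### Window-pair λ and greedy merging

λ is the signed combination of the four Pearson correlations between two
windows' ψ̂* vectors, computed as
`(r(A,A) + r(B,B)) − (r(A,B) + r(B,A))` — grouped so that relabelling one
window's slots flips the sign exactly in IEEE arithmetic.  Zero-variance
vectors make λ undefined (NaN) and the pair is skipped.

Greedy merging seeds with the pair of maximal |adjusted λ|, then
repeatedly folds in the unassigned window with the largest |adjusted λ|
against the merged group, orienting it by the raw λ's sign.  Specifics:

* **Same-chromosome prior.** A negative λ between windows on the same
  chromosome is multiplied by `same_chrom_penalty` (default 0.75) before
  the magnitude comparison: an opposite-parent call within a chromosome
  implies a switch error between the windows, which is less likely than
  not.  The adjustment affects selection order only — orientation is
  always the sign of the raw λ.  Setting the penalty to 1 recovers the
  unadjusted variant.  For window-vs-group comparisons the prior applies
  when the candidate shares a chromosome with any group member.
* **Group representation** (`group_aggregate`).  The merged group is
  summarised per parental side by the sum of its members' ψ̂* vectors,
  each member **z-scored** before summing (default `"standardized"`).
  A raw sum (`"sum"`, also available) weights members by their variance,
  so one window with a very large ψ̂* outlier dominates the group's
  correlation structure and drowns the weaker signal other members carry;
  standardization lets every merged window contribute comparably.  This
  was the one materially open design point; the choice was validated on
  simulated cohorts, where it reduces mis-oriented windows relative to
  the raw sum.
* **Determinism.** Ties in |adjusted λ| break toward the lowest window
  index (pair); a fixed tensor therefore yields an identical merge log on
  every run.  Windows with no heterozygous site or zero-variance vectors
  are flagged uninformative and receive orientation +1 by convention.
* Focal individuals are phased independently; per-focal results are pure
  functions of (cohort, windows, config) and identical for any thread
  count.

### Trio truth and ACPA

At focal-heterozygous SNPs, a homozygous parent forces the origin of the
matching offspring allele (cross-checked against the other parent);
triple-heterozygous sites are `unresolved`; impossible configurations are
`mendelian_error` (a rate above 1% of het sites triggers a warning).
Unresolved sites are excluded from the ACPA denominator — filling them
from flanking within-chromosome phase would entangle the score with
parental phasing quality.

ACPA marks, at every resolved site, whether the allele in phased slot 0
descends from one and the same parent.  Two labelling conventions are
provided:

* `mapping="best"` (default): the global set-1↔parent correspondence is
  chosen once, genome-wide, to maximize agreement.  Scores land in
  [50, 100]; per-chromosome values reuse the same global mapping and may
  fall below 50 (the worked four-chromosome example contains a 0%
  chromosome for exactly this reason).
* `mapping="fixed"`: the arbitrary truth labelling is kept.  This is the
  convention under which random assignment scores 50% in expectation —
  under the maximizing convention the expected score of random
  orientations exceeds 50 by the expected |deviation| of a ~12-window
  binomial, so a 50% baseline is only meaningful with a fixed labelling.
  The random-baseline acceptance test uses it for that reason.

Stratification groups focal individuals by the maximum π̂ to any
non-focal cohort member, binned at midpoints between the canonical
expectations (0.5, 0.25, 0.125, 0.0625).

## Synthetic-data generator

`build_cohort` emulates, at reduced scale, the study design the method is
meant for: a large mostly-unrelated cohort containing trio offspring to be
phased blind and scored against truth.

* **Founders** are drawn site-independently at minor allele frequencies
  uniform on [0.05, 0.5] (optionally from two Balding–Nichols
  subpopulations with configurable F_ST; the two parents of each focal
  are then drawn from different subpopulations, emulating
  parental-generation stratification).
* **Meiosis**: crossover count ~ Poisson(length/100 cM), positions
  uniform on the cM axis, no interference, starting haplotype by fair
  coin — the standard sex-averaged model.
* **Relatives** attach through a grandparental couple: degree 2 is an
  uncle/aunt, degree 3 a first cousin, degree 4 a cousin once removed;
  sides alternate (first relative through parent 1, second through
  parent 2) so both parental lineages carry signal.  Among the standard
  relationship types of each degree these have the highest IBD
  segment-transition density, i.e. the best per-window coverage for a
  fixed kinship.  Degree 1 places the parent itself in the cohort (it is
  then excluded by the π̂ screen, as in a real analysis).
* **Slot scrambling**: every individual's haplotype slot order is
  randomized per chromosome, so slots carry no phase information by
  construction.
* **Switch errors**: at each heterozygous site, with probability
  `switch_error_rate`, the two haplotypes swap from that site to the
  chromosome end — the standard switch-error model.  Injection leaves
  diploid genotypes (hence π̂ and QC) unchanged, and the transmission
  truth remains valid because it records transmitted alleles, not slots.
* **Truth** is the simulator's own transmission record: every
  focal-heterozygous site is resolved.  The trio evaluator reproduces it
  exactly wherever a parent is homozygous (tested).

### Default conditions, and what they represent

The defaults describe a cohort of ~2,000 individuals: 24 focal trio
offspring each with one 2nd- and one 3rd-degree relative, 8 focal
offspring with none, and unrelated fill; 6 chromosomes of 80 cM with
7,000 SNPs each.  The SNP density (~88 SNPs/cM) matches a genotyping-array
biobank panel (~330k SNPs over a ~3,500 cM genome); density matters
because it sets the length of the shortest IBD segment that stands out of
the background match-run distribution.  The simulated genetic map places
spatially clustered hot regions (~1 per 40 cM, ~30-fold rate boost over a
heavy-tailed cold background), mirroring the clustered hotspot structure
of pedigree-based human maps; under the top-10/≥25 cM windowing rule this
yields ~2 windows per chromosome with spans of ~25–55 cM, matching the
window-size regime the method is designed for.

### What the generator does not emulate

* **Linkage disequilibrium**: founder sites are independent, so
  background identity runs are shorter than in real data and absolute ψ̂
  magnitudes are not comparable to real-cohort values.  (An IBD segment
  still produces an identical run of its full genetic length, so the
  signal side is faithful; the noise side is optimistic.)
* **Background distant relatedness**: real biobank cohorts contain many
  undetected 4th–6th-degree relatives of every participant, which give
  real no-close-relative individuals substantial phasing signal.  The
  simulated cohort is structureless apart from the planted relatives, so
  simulated no-relative individuals score near the random baseline — a
  *harder* setting than reality for them, and the main reason cohort-level
  means here undershoot what a real cohort of this size would give.
* Genotyping error, mutation, sex-specific maps and crossover
  interference are out of scope.

Consequently, passing tests demonstrate the machinery end to end and the
direction and rough magnitude of every effect, not the exact accuracy the
method attains on a specific real cohort.

### Scale of the shipped experiments

The acceptance-level simulation (~2,000 individuals × 42k SNPs, three
error conditions) was sized to run in a few minutes on one CPU; per-window
IBD-coverage arithmetic makes the expected number of coin-flip windows per
focal individual ~0.7 at this scale, which places the median accuracy
near — and at the default seed above — the 95% mark, with roughly half of
the focal individuals phased perfectly.  Larger partner pools, longer
genomes or any background relatedness all push accuracy upward.

## Numerical and degenerate-input choices

* Genetic positions interpolate linearly in bp between map anchors and
  clamp to the boundary cM outside the anchored range.
* Missing genotypes abort the VCF load by default (`on_missing="drop"`
  drops the record): the longest-run logic is undefined across gaps.
* Minor-allele orientation is fixed at load time (code 1 = minor); the
  original REF/ALT orientation is remembered and restored on write, and
  results are invariant to how the input VCF oriented its alleles.
* HWE uses the 1-df χ² goodness-of-fit test on observed vs expected
  genotype counts with the allele frequency estimated from the sample;
  monomorphic SNPs get p = 1 there but are removed by the MAF filter.
* Chromosomes losing all SNPs to QC, empty partner pools, fewer than two
  usable windows, and all-NaN λ matrices are hard errors; windows without
  focal-het SNPs degrade to flagged, +1-oriented placeholders.
* Seeds: every stochastic component takes a `numpy` Generator or integer
  seed; cohort construction, phasing and evaluation are bit-reproducible.
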