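# Methods

## Model and estimators

### The dating model

The Y chromosome is treated as a single non-recombining locus: one genealogy
applies to every site.  Mutations arise as a Poisson process at rate μ per
callable site per year (default 0.76×10⁻⁹, with 95% bounds 0.67–0.86×10⁻⁹
used for uncertainty propagation), under the infinite-sites assumption (each
site mutates at most once; the simulator errors rather than silently
multi-hitting, and homoplasic sites in real data are excluded from dating).

For a clade with tips *s* relative to an ancestor node *v*,

ρ = Σ_s n_s(v) / Σ_s L_s,

where n_s(v) counts mutations assigned to branches on the path *s* → *v*,
restricted to sites inside sample *s*'s callable mask, and L_s is the size of
that mask.  Restricting numerator and denominator to the same per-sample site
set makes the ratio invariant to missing-completely-at-random masking, and the
pooled (count-sum over callable-sum) form keeps the estimator stable for very
low-coverage samples, where a per-sample ratio would be noisy.  The divergence
time of clades A and B is T = ((ρ_A + ρ_B)/2)/μ, both ρ measured to
MRCA(A ∪ B).

### Rate calibration by branch shortening

An ancient sample of age *a* has a lineage that stopped *a* years short of the
present, so its ρ to an ancestor shared with modern samples is deficient by
μ·a per site.  `calibrate_rate` returns (ρ_modern − ρ_ancient)/a, with
ρ_modern the arithmetic mean of the per-tip modern ρ values (identical to the
pooled form when the modern tips have equal callability).  A non-positive
numerator raises: it indicates mis-rooting or a wrong age.

### Confidence intervals

1. **Rate propagation**: (T·μ/μ_hi, T·μ/μ_lo) — a faster clock means a
   younger date.  The relative width is the same for every T.
2. **Site bootstrap**: all columns of the callable universe (variant and
   invariant alike) are resampled with replacement; per replicate the mutation
   counting, ρ, and time conversion re-run on the fixed topology, and the CI
   is the 2.5/97.5 percentile pair (linear interpolation) over (default) 100
   replicates.  Because per-site parsimony assignments do not depend on column
   multiplicity, resampling reduces to multinomial reweighting of columns —
   exact and fast.  The topology itself is never re-inferred here; it is fixed
   and separately supported (below).  Percentile rather than BCa is the
   simplest defensible reading of a 95% CI from 100 replicates.
3. **Combined**: the rate bounds applied multiplicatively to the bootstrap
   endpoints — deliberately conservative, containing both sources.

Reported times are rounded to 0.1 ky.  With the default rate bounds the
propagation arithmetic reproduces interval endpoints such as 54.3 → (48.0,
61.6) ky and 48.4 → (42.8, 54.9) ky exactly at that precision; three
published-style endpoints (44.9, 56.9, 11.9) differ by 0.1 ky from this
package's arithmetic (45.0, 56.8, 11.8), which is expected rounding ambiguity
in unrounded intermediates and is not corrected for.

### Tree construction and mutation mapping

Pairwise distances use pairwise deletion with a **shared-callable
denominator**: discordant non-missing calls over (mutually callable variant
sites + mutually callable invariant sites).  Without the invariant-site term,
low-coverage samples would appear artificially close.  Neighbor joining is
standard Saitou–Nei with two determinism rules: Q-criterion ties break to the
lowest (row, column) pair in the current agglomeration order, and a negative
branch length is clamped to zero with the deficit moved to its sibling.  The
implementation is cross-checked against scikit-bio's NJ on random additive
matrices in the test suite.  Rooting places the root at the midpoint of the
branch separating a user-specified outgroup (which must be monophyletic).

Variant sites are assigned to branches by Fitch parsimony with missing calls
treated as unknown and the root constrained to the ancestral allele.  Sites
requiring more than one change are flagged homoplasic and excluded from dating
(counts logged).  Among the equally parsimonious placements a single change
can take when neighbouring calls are missing, the change is placed on the stem
of the **smallest clade containing every definitely derived leaf** (delayed,
tipward resolution).  This choice is load-bearing for ρ: it keeps each
mutation on the root paths of exactly the samples observed to carry it, so the
callability-restricted path counts are exact whenever each daughter clade of
the reference ancestor retains at least one fully callable lineage (the study
design simulated here always does).  Without that anchor a mutation above the
ancestor whose carriers are all masked in one clade is genuinely
indistinguishable from a clade-internal one; the residual bias term is of
order (1−c)^k in the clade size k.

Clade support is a site bootstrap in which the tree *is* rebuilt per
replicate from reweighted distances; support is the percentage of replicates
in which the focal leaf set forms one side of a split.

### Haplogroup assignment

Markers (e.g. C-M130, C-M347, K-M526, S-P308, M-M186) form a tree-shaped
hierarchy.  The deepest marker with a derived call wins; missing intermediate
markers are tolerated; derived calls on incompatible branches raise an error,
since they indicate a data problem rather than a resolvable state.

### STR dating and saturation

Under an unbounded symmetric single-step model, E[ASD] = 2·μ_STR·t
generations, so T̂ = ASD/(2μ_STR)·g years is unbiased in the linear regime
(verified by simulation at small t).  Real repeat alleles occupy a narrow
range; the simulator models this with reflecting boundaries at ±b steps from
the root allele.  The stationary ASD for bound b is 2·((2b+1)²−1)/12, which
caps the recoverable time at T_max = stationary-ASD/(2μ_STR)·g regardless of
the true divergence.

A quantitative point that shaped the defaults: at the fast genealogical rate
2.08×10⁻³ per locus per generation with 25-year generations, a 50-ky split
accumulates only ~4.2 events per lineage per locus.  A ±10-step bound
(stationary pair variance ≈ 73) is therefore effectively unbounded on this
timescale — measured bias ratio ≈ 0.99 at 50 ky, with saturation only far
beyond 400 ky.  The saturation demonstration instead uses b = 2 (a 5-allele
effective range, matching the narrow effective diversity of simple Y-STR
loci), for which the plateau sits near 24 ky and the measured mean estimate of
a true 50-ky split is ≈ 0.35 of the truth, while the matched sequence-based
estimator on the same genealogies stays unbiased within Monte-Carlo error.
The simulator's general-purpose default bound remains ±10 and is fully
configurable; the experiment table reports both estimators with standard
errors so any configuration can be audited.

## The synthetic-data generator

`simdata` emulates the target study design: a fixed known genealogy (default:
two clades of five tips splitting 54 ky ago with 45-ky crowns, one outgroup
lineage at 70 ky), μ = 0.76×10⁻⁹/site/year, L = 10⁷ callable sites, a mix of
fully callable (c = 1.0) and low-coverage (c = 0.4) samples, optional ancient
tips of known age, and a 10-locus STR panel at 2.08×10⁻³ per locus per
generation.  Branch mutation counts are Poisson(μ·L·t years); mutation sites
are drawn without replacement (infinite sites); masks drop sites per sample
independently (missing completely at random — the missingness mechanism of
real low-coverage call sets is not public, so MCAR is the documented
assumption).  All randomness derives from one seed via deterministic
substreams; identical configs give byte-identical output files.

**Representation.**  Only variant sites are materialized.  Invariant-site
callability is stored as joint callable-pattern counts: a multinomial draw
over the 2ⁿ product-Bernoulli patterns (exact for ≤16 samples; chunked
per-site sampling beyond).  This is distributionally identical to per-site
masking and exact for every downstream statistic (per-sample L_s, pairwise
shared-callable counts, bootstrap reweighting) while making an L = 10⁷
simulation run in milliseconds.  When BED masks are written, per-site masks
are realized deterministically from the seed: every mutated position (visible
or not) keeps the exact mask column it was simulated with, and unmutated
positions receive the invariant pattern classes in a random arrangement (they
are exchangeable, so the realization has the same joint law).  Matrices read
back from VCF+BED reproduce the in-memory calls, callable totals, and pattern
summaries exactly.

**What the generator does not model**, and hence what passing tests do not
show about real data: sequencing error and genotype-likelihood uncertainty,
ancient-DNA damage, reference/mapping bias, non-random missingness
(coverage varies along the chromosome in reality), recurrent mutation, and
coalescent variance in topology (the genealogy is fixed, which is appropriate
for a single non-recombining locus but means crown ages are inputs, not
draws).

## Numerical and design choices

* **Coordinates**: VCF 1-based, BED 0-based half-open, internal storage
  1-based on a single synthetic contig "Y".  Haploid calls are written as
  single-allele genotypes; a homozygous-diploid writer dialect is provided
  since public Y call sets use both.  Heterozygous diploid calls on the Y are
  treated as missing (a genotype-quality proxy) and counted.
* **Ancestral allele** = REF unless an AA INFO tag names the ALT (then
  polarity flips); sites whose AA matches neither allele are dropped and
  counted.
* **Reference-implied calls on merge**: a sample lacking a record at a
  position is called ancestral only inside its callable mask, missing outside
  — absence of evidence in a low-coverage sample is not evidence of the
  reference allele.  Merging requires positional masks (matrices read from
  files carry them; large in-memory simulations carry only the exact pattern
  summary, so they are merged after a write→read round trip).
* **Tie-breaking** is lexicographic everywhere (sample order, NJ indices) for
  reproducibility; bootstrap and simulation seeds derive from the single run
  seed.
* **Degenerate inputs**: zero mutation rate yields an empty variant matrix
  (valid); empty callable masks yield L_s = 0 with a warning and are rejected
  only where a ρ denominator would vanish; clades are validated for
  monophyly before dating and bootstrap; a non-monophyletic outgroup is an
  error listing the offending leaves.

## Problem sizes used in the shipped experiments

Parameter recovery runs 50 pipeline replicates at L = 10⁷ (the full design);
bootstrap coverage runs 100 outer replicates at L = 10⁶ with 100 bootstrap
replicates each, mapping mutations on the fixed generating topology — at the
reduced L the 9-ky clade stems carry too few mutations for distance-based NJ
to resolve reliably, and the bootstrap procedure is defined on a fixed
topology in any case; clade support uses the NJ-inferred tree at L = 10⁷,
where deep-clade resolution is essentially certain (the stems carry ≥50
mutations).  The STR experiment uses 200 replicates.  These sizes are the
package's standard demonstration settings; all are parameters of the
respective functions.

## Known limitations

ρ's variance model is purely Poisson over sites; it ignores topology
uncertainty below the dated node (mitigated by fixing and separately
supporting the deep topology).  The delayed-placement identifiability
argument above assumes MCAR masks.  NJ is a distance method: it is used here
because the acceptance surface needs correct deep topology and support at
desk scale, not a maximum-likelihood tree; branch lengths on the output tree
are mutation counts, not time.  The STR saturation mechanism is deliberately
minimal (uniform per-locus rate, symmetric single steps, hard reflecting
bounds); real Y-STR panels mix locus types and rates.
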