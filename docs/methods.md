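# Methods

## The marker model

A triallelic marker is a single genomic site with three role-labelled
alleles: the *Bos* ancestral allele A1 (shared across gaur, banteng and
bison), the yak-associated allele A2, and the *B. taurus*-associated
allele A3, which is the base of the cattle-like reference assembly at
that site. Roles, not bases, drive every computation in the package;
bases are carried only for file IO. Ploidy is fixed at 2 and markers
are autosomal. Markers are treated as unlinked throughout; combined
identity and exclusion statistics are therefore underestimates where
markers share a chromosome, and no linkage-disequilibrium correction is
attempted.

A genotype is an unordered allele pair or a single "no call"; half
calls are not representable at the container level. Allelic dropout —
a heterozygote losing one allele and presenting as a homozygote — is
owned entirely by the error simulator.

## Discovery filters

Candidate sites pass through six stages, each a pure predicate on one
site, so the surviving set is independent of stage order even though
the per-stage survivor counts are not:

1. **SNV pre-filter.** Sites with indel/symbolic alleles or more than
   three observed alleles are skipped with a logged reason.
2. **Coarse species filter.** All outgroup animals called and
   homozygous for one shared allele (the inferred ancestral allele),
   which must differ from the reference base; all reference yaks called
   and heterozygous for the ancestral allele plus one common second
   allele (the yak allele), which must be absent from the outgroups and
   from the reference. A fourth allele in any outgroup animal fails the
   homozygosity requirement and hence the filter; this deliberately
   closes the known loophole where an outgroup heterozygous for a
   novel allele could slip through.
3. **Fine cattle filter.** The reference allele must account for at
   least `min_ref_alleles` of the panel's `possible_alleles`
   (defaults 183 of 192, i.e. >95% in a 96-animal panel). The
   denominator is fixed at the panel's possible allele count, so
   missing cattle calls count against passing.
4. **Flank masking and assay feasibility.** 100 bases either side of
   the marker are extracted from the reference. Cattle flanking
   variants at ≥5% frequency (count ≥9 of 192) and yak flanking
   variants at any nonzero frequency are masked to N, since they can
   disrupt assay-probe hybridization. Masking never changes flank
   length, and the center is rendered `[A1/A2/A3]`. Markers whose
   flanks exceed `max_masked_fraction` N (default 0.10, our own
   feasibility rule: a probe window more than one-tenth degenerate is a
   poor assay target on any platform) are dropped at this stage.
5. **Unique mapping.** Markers are retained only if their flank
   sequence maps exactly once to the yak assembly. Alignment itself is
   out of scope; the filter consumes a marker → hit-count table
   produced externally (or by the synthetic generator).
6. **Monomorphic filter.** Markers whose parentage-allele MAF is zero
   (or that have no calls) in the genotyped population are removed.

Bin assignment is greedy left-to-right within each chromosome: a marker
joins the current bin when its gap to the previous marker is ≤1 Mb,
else a new bin opens. The bin representative is the median marker
position, and the reported inter-bin spacing averages distances between
consecutive representatives within chromosomes only — the averaging
convention is our own choice, since several conventions reproduce a
"~5 Mb average spacing" statement equally well. For design arithmetic,
a perfectly tiled genome of 2479 Mb at 5 Mb spacing yields
round(2479/5) = 496 interior bins plus one end bin per chromosome.

## Identity and exclusion statistics

Under Hardy–Weinberg proportions with parentage-allele MAF `p`
(`q = 1 − p`), the per-marker probability of identity is
`P_I = (q²)² + (2pq)² + (p²)²` and the one-parent probability of
exclusion is the probability of opposing homozygotes,
`P_E = P_OH = 2p²q²`. Combined panel values multiply (`P_I`) or
accumulate the unexcluded remainder (`P_E`): each marker excludes a
fraction `r·P_E` of the adults still unexcluded, which for unrelated
adults (r = 1) reduces to `1 − Π(1 − P_E,i)`, and for related
candidate parents scales every term by the relatedness coefficient
`r ∈ {0.125, 0.25, 0.5}` (equivalently `1 − Π(1 − r·P_E,i)`). MAF is
defined over the two parentage alleles only; the cattle-associated
allele is excluded from that denominator and tracked separately, since
its frequency in yak (~0.004) is negligible for parentage.

`bulls_excludable` reports `round(ln(confidence)/ln(1 − u))` for
per-bull non-exclusion probability `u`; rounding to nearest is chosen
so the boundary case u = 5.3 × 10⁻⁴ at 99% gives 19 (the value is
18.96); users wanting the strict guarantee can floor it.
`snps_required` scans n upward for the smallest panel with
`(1 − (1−P_E)ⁿ)^B ≥ confidence`; at MAF 0.296 and B = 30 bulls this
gives 88 markers (87 at MAF 0.30 — the statistic is steep in MAF near
this operating point).

## The exclusion calculus

An adult is excluded at a site when it shares no allele with the calf.
With three alleles this covers configurations a biallelic test misses
(calf A1/A1 vs adult A2/A3; calf A1/A3 vs adult A2/A2). When the dam
is genotyped, the obligate paternal allele is inferred: if exactly one
calf allele can be maternal, the other must have come from the sire,
excluding adults that lack it. A calf sharing no allele with its
recorded dam is reported as "dam inconsistent" rather than counted as
an exclusion of the adult, because it signals a pedigree or sample
error upstream. Sites with missing calls are skipped, never imputed;
the number of compared sites is reported so callers can apply a
coverage floor (default 94% of the panel, the pairwise bound implied
by a 97% per-animal call rate). The default verdict tolerates 2 false
exclusions, matching the overlap analysis at a 1% genotyping error
rate; the threshold is error-rate-dependent and exposed as a flag.

## Simulators

All simulators take an explicit seed, never touch global random state,
and are chunked (100 000 pairs at a time) so a million-pair run stays
within a small, flat memory footprint. The cattle-associated allele is
ignored in the parentage simulations — its yak-population frequency is
too low to contribute measurably — so animals are represented by their
yak-allele dosage (0/1/2) per marker.

- **Random pairs**: both animals drawn from HW proportions at each of
  `n_markers` unlinked markers; the histogram of opposing-homozygote
  counts per pair is returned. It matches Binomial(n_markers, 2p²q²)
  by construction.
- **True parent with dropout**: the sire is HW; the offspring inherits
  one uniformly chosen sire allele plus one population allele. Dropout
  is applied to each genotype of *both* animals independently at the
  configured rate (omitting one uniformly chosen allele; a homozygote
  is unaffected). Which animal's genotypes are perturbed is a genuine
  modelling choice; applying the error to both is the realistic
  reading, since assay error does not know pedigree roles. With no
  dropout a true pair can never show an exclusion, which is asserted
  as a property.
- **Backcross decay**: generation 0 (the F1) carries exactly one
  cattle allele at every panel site; each backcross transmits each
  remaining cattle allele with probability 1/2 and receives a
  non-cattle allele from yak frequencies, so generation-g counts follow
  Binomial(panel, 2⁻ᵍ) and means halve each generation. For an
  87-marker panel at generation 3, (n+1)p = 11 is an integer, so the
  distribution has exactly tied modes at 10 and 11;
  `backcross_modal_counts` evaluates the exact pmf and reports the full
  modal set rather than pretending the simulation breaks the tie.
- **Introgression classifier**: maximum likelihood over the hypotheses
  fullblood (count ~ Binomial(2n, background ≈ 0.0043)), F1 (count
  = n exactly) and backcross generations Bg (count ~ Binomial(n, 2⁻ᵍ),
  g ≤ 3 by default), with flat priors. Ties break toward the more
  recent hybridization — the conservative direction when screening
  breeding stock. Counts below 3 of 87 land on fullblood: such an
  animal is unlikely to have an F1 ancestor within three generations.

## Synthetic data

The cohort generator emulates the discovery study design: 2 reference
yaks heterozygous at every true site, 5 outgroup animals homozygous for
the ancestral allele, a 96-animal cattle panel with reference-allele
frequency 0.99 (the per-site non-reference count is truncated at the
fine-filter headroom so planted sites pass by construction), default
flank variants at the masking boundary (a cattle variant at count 9,
one at 8, a yak variant at 10%), and a 170-animal population genotyped
at MAF 0.296 with a 0.48% missing rate and a 0.0043 cattle-allele
background — the operating point estimated for North American yak.
Decoys are generated one-filter-at-a-time: each class violates exactly
one discovery rule while satisfying all others, so every filter is
unit-testable in isolation and the end-to-end truth-table check is
exact. Sites are placed 10 kb apart on one synthetic contig; bin
behaviour across chromosomes is exercised with hand-built markers
instead.

What the generator does *not* emulate: read-level errors (input begins
at genotypes), linkage (sites are unlinked by construction, so tests
cannot detect LD-induced bias in combined statistics), population
structure or relatedness in the population matrix, and per-marker MAF
variation unless a per-marker list is supplied. Passing tests
therefore demonstrate the correctness of the filtering and statistical
machinery at the study's operating point, not robustness to those
real-data complications.

## Problem sizes and numerical choices

The parentage simulations use 10⁶ pairs × 87 markers and the backcross
simulation 10⁵ replicates — the scales at which the reported overlap
fractions (≈0.05 and ≈0.03) and modal counts were defined; smaller
property tests use 2 × 10⁴–5 × 10⁴ draws with tolerances set from
binomial standard errors (3–4σ). The Hardy–Weinberg recovery check
uses a chi-square test at α = 0.001 with n = 10⁴ animals and a fixed
seed as a flakiness guard. Combined-exclusion arithmetic uses
`log1p`/`expm1` where products of near-one terms would lose precision,
and the iterative-accumulation identity with `1 − Π(1−P)` is asserted
to 10⁻¹². Modal-set detection in the exact binomial pmf uses a 10⁻⁹
relative tolerance to catch genuinely tied modes without merging
nearby ones. Coordinates are 1-based inclusive in VCF and marker
tables, 0-based half-open in BED; the 2001-base assay locus around
1-based position p is the BED interval [p−1001, p+1000), clamped at
the contig start.

## Known limitations

- No linkage model anywhere; combined P_I/P_E and the backcross
  binomial all assume independent markers.
- The introgression classifier considers a single hybridization event;
  multiple F1 ancestors in one pedigree produce mixtures it does not
  model.
- One-parent exclusion statistics assume genotype frequencies are
  age-independent and the population unstructured.
- The unique-mapping filter trusts the supplied hit counts; the
  package does not run an aligner.
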