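# Methods

## The locus model

`sdfusion` studies a gene flanked by two near-identical segmental
duplications (SD1 upstream, SD2 downstream). Misalignment of SD1 against
SD2 during meiosis (non-allelic homologous recombination, NAHR) deletes
the intervening gene and leaves a single chimeric "fused SD" on the
deleted haplotype: SD1-derived sequence upstream of the crossover point,
SD2-derived downstream. When the same gene is polymorphically deleted in
two sister species, two histories are possible and distinguishable:

- **recurrent**: each lineage experienced its own NAHR event after the
  species split, so each species' fused haplotypes coalesce recently and
  cluster with that species' own reference SDs;
- **identical by descent (IBD)**: a single fusion predates the split and
  survived in both species as a trans-species polymorphism through
  incomplete lineage sorting, so all fused haplotypes of both species form
  one clade exclusive of the references.

The package provides a forward simulator of this history, the inference
stages that recover it (divergence scan, breakpoint localization,
phylogenetic classification, dating), and population-scale utilities
(allele counting, read-depth genotyping, reciprocal-overlap sharing).

## Forward simulator (`simlocus`)

Substitutions are Jukes–Cantor single-nucleotide replacements with no
indels: per branch of length *t* years over *L* sites, the number of
events is Poisson(*r·t·L*) with per-site rate *r*; each event hits a
uniform site and replaces the current base by one of the other three.
Because there are no indels, alignment columns equal sequence coordinates
(0-based, half-open) throughout.

Event sequence: an ancestral segment is duplicated; SD1 and SD2 evolve
independently for `t_pre_split` years; gene-conversion tracts copy
sequence between the paralogs (default SD1→SD2) immediately before the
first fusion event; fusions concatenate the lineage's SD1 and SD2 at a
breakpoint; fused haplotypes within a species descend from the founder as
a star genealogy (they coalesce at the fusion exactly — the simplest model
consistent with dating the event from within-species diversity); optional
lineage-specific conversion or exchange events are applied to one species'
reference paralogs at the split.

Key defaults, with reasoning:

| parameter | default | why |
|---|---|---|
| `sd_length` | 12,541 b | aligned length of the SD pair under study |
| `per_site_rate` | 1e-9 /site/year | standard neutral primate substitution rate |
| `t_div` | 6.3e6 y | human–chimpanzee divergence used for calibration |
| `t_pre_split` | 3e7 y | the gene family's duplications predate the Old World monkey split; an old duplication also separates background paralog divergence (~0.07) from post-conversion divergence inside tracts (~0.013) by ~5×, which is what makes the conversion "islands" a detectable signal rather than a marginal one |
| `t_fusion_a/b` (recurrent) | 4e5 y | of the order of the dated fusion ages (~0.34–0.58 Myr) |
| `t_fusion_a` (ibd) | 5e6 y before the split | an IBD deletion surviving as trans-species polymorphism implies a long-lived (balanced) polymorphism; the age also gives the fused clade an internal edge long enough (≥ ~2 expected substitutions per kb region) that bootstrap support can in principle reach the 70% threshold — a very recent pre-split fusion is statistically indistinguishable from recurrence in any method |
| `t_ibd_star` | 4e5 y | within-species coalescence of fused haplotypes under IBD |
| `ancestral_conversion_tracts` | (1500, 3500), (8000, 11000) | two tracts inside the gaps left between the tree regions (below), jointly ~40% of the locus so that the median window divergence reflects the unconverted background |
| `lineage_conversion_tracts` | chimp: (4001, 7500) swap | the post-split reciprocal SD1/SD2 exchange in the second lineage that makes region 2 trees disagree with regions 1 and 3 |
| `n_haplotypes_per_species` | 7 | matches the sequenced sample per species |

Default breakpoints are drawn uniformly inside the *downstream* conversion
tract: NAHR requires local homology, and a downstream switch point makes
the fused haplotype SD1-derived through regions 1–2 and SD2-derived in
region 3, the configuration the region partition assumes. Requesting a
breakpoint outside every tract is a configuration error unless
`require_breakpoint_in_tract=False`.

In IBD mode `t_fusion_a` is measured *before the split* (the fusion sits at
`t_div + t_fusion_a` before present), so the emitted genealogy has the
fused lineage separating from SD1 deeper than the species split, while the
two species' fused haplotypes separate from each other exactly at the
split.

Randomness: one `numpy` generator seeded by `SimConfig.seed`; the stream
order (root sequence, breakpoints, ancestor-first branch order, species in
configured order, haplotypes 1..n) is fixed and documented in
`simulate_locus`, so a seed fully determines the output.

## Divergence scan (`windowscan`)

π between two aligned haplotypes is mismatches per comparable site
(both bases in {A,C,G,T}) in sliding windows (default 500 b / 100 b step;
full windows only, so a 12,541 b alignment yields 121 windows). A window
with no comparable site is NaN, never 0.

Conversion tracts are maximal runs of ≥ 2 consecutive windows with
π < `low_frac` × median π (default 0.5). Because windows overlap, runs
interrupted by a single noisy window produce overlapping spans; such spans
are merged. This median-based rule presumes the tracts are a minority of
the profile — with converted sequence covering most of the locus the
median itself would sit inside the tracts and the detector is not
meaningful.

The fusion breakpoint of a fused haplotype is the argmin over switch
points *b* of total(b) = mismatches(fused[0:b], SD1[0:b]) +
mismatches(fused[b:L], SD2[b:L]), computed in one prefix-sum pass.
Wherever SD1 = SD2 locally the argmin is a plateau: the interval of
optimal switch points is the finest attainable resolution and is reported
as such (half-open, with a flag when the argmin set is non-contiguous).
No point estimate is invented inside the plateau.

The strict argmin is a point-estimator analogue and is deliberately not
what the analysis reports as the breakpoint *region*: a single
substitution arising on a reference paralog after the fusion (expected
a handful per flank at the default rates) systematically pushes the
strict minimum past the true switch point, and because the references are
shared, the error repeats across every fused haplotype of the species.
`locate_breakpoint(..., slack=k)` therefore admits every switch point
within *k* mismatches of the minimum, and
`species_breakpoint_interval` reports the span enclosing all of a
species' per-haplotype slack-1 intervals — one expected post-fusion
substitution tolerated per comparison. At the default conditions this
widens the reported region from ~130 b to ~310 b, still an order of
magnitude finer than the ~4 kb resolution the published comparison
worked at.

## Trees and classification (`phylotree`)

Distances are uncorrected p-distances over comparable columns
(divergences here are ≤ ~0.07, far from saturation; a Jukes–Cantor
correction is available). Neighbor joining uses the standard Q criterion;
ties are broken lexicographically on the representative leaf-label pair,
making the topology deterministic; negative branch-length estimates are
clamped to zero on output (additive inputs are reproduced exactly).
Bootstrap resamples columns within the region (default 100 replicates) and
scores each internal edge of the original tree by the percentage of
replicate trees containing the same bipartition; bipartition matching
ignores branch lengths.

Trees are built per region — region 1 [0, 1000), region 2 [4001, 7500),
region 3 [12000, L) — chosen to avoid the conversion tracts, whose
histories differ from the genealogy. A region votes **recurrent** when,
for every species, a bipartition with support ≥ 70% groups that species'
fused haplotypes with at least one of its own reference SDs and nothing
else; it votes **identical_by_descent** when a supported bipartition
isolates all fused haplotypes of both species from every reference;
anything else is **ambiguous**. The overall call is the majority among
regions that produced a supported vote — regions without signal do not
veto, but conflicting supported votes yield ambiguous.

`nearest_reference_profile` assigns each haplotype its closest reference
per region; an assignment that flips between regions (e.g. one species'
SD1 pairing with the *other* species' SD2 only in region 2) is the
signature of a region-restricted sequence exchange between paralogs.

## Dating (`ratedating`)

From pairwise differences *d* between each fused haplotype and its
species' SD1 over the SD1-derived segment [0, breakpoint):

- absolute: t = d / (2μ);
- relative: t = (d / d_between) · t_div, with d_between the
  between-species SD1 divergence (spanning 2·t_div of branch, so the
  factor 2 cancels).

The point estimate is the mean over pairs, the interval the (min, max)
range. The pipeline measures d over the whole SD1-derived segment rather
than only region 1: post-fusion divergence is uniform along the fused
haplotype (conversions predate the fusion in the model), and 1 kb at
2rt ≈ 8×10⁻⁴ carries less than one expected difference per pair, which
makes a region-1-only estimate unusably granular. d_between, by contrast,
is taken from region 1 only, because the lineage-specific exchange
corrupts SD1 orthology in region 2. On real data the same choice would
need the conversion history checked first — that is exactly what the scan
stage provides.

The deletion mutation-rate lower bound divides the number of independent
deletion events by the total branch length separating the species
(2 events / 12.6 Myr = 1.59×10⁻⁷ per year); ignoring events lost from
contemporary populations makes it conservative.

The recurrence probability squares the per-lineage expectation
e = (sv_rate × 2 / gen_time) / genome_size × breakpoint_window × t_split,
with defaults 0.041 SV per haploid genome per generation, 20-year
generations, 7 Myr of separation, a 4,000 b breakpoint window and a 3.2 Gb
genome, giving e ≈ 0.036 and e² ≈ 1.3×10⁻³. Two readings of the model's
"per 7 million years" term are arithmetically possible; the per-branch
accumulation reading (multiplication) is used because the alternative
(division) yields e² ≈ 10⁻¹⁵, at which point any stated bound below 0.01
would be vacuous and the probability-vs-rate curve trivial. The genome
size is not part of the published parameter set; 3.2×10⁹ (human haploid)
is the default and the < 0.01 conclusion holds for any genome ≥ 2 Gb.
The probability is capped at 1 and is monotone in the SV rate.

## Genotyping and sharing (`genoshare`)

Allele counting is exact: n_del = 2·hom_del + het over 2·total alleles.
For the published chimpanzee counts (6 hom, 17 het, 37 individuals) this
is 29/74 = 0.392; the survey's printed frequency of 0.41 for the same
counts is not arithmetically reproducible from them and is flagged in the
docstring rather than imitated. Read-depth genotyping divides mean depth
in the gene by genome-wide depth and rounds 2×ratio half-up to a copy
number (0 → hom_del, 1 → het, ≥ 2 → hom_ref); classification of noisy
depth beyond rounding is out of scope.

Two deletion calls share a locus when their intersection covers ≥ 70%
(inclusive) of *each* interval. Callset comparison uses an interval tree
per chromosome, reports every passing pair (a call may have several
partners), and summarizes the count and fraction of query calls with at
least one partner. Coordinates are BED-style 0-based half-open; a
converter from 1-based inclusive is provided. Lift-over between assemblies
is out of scope — both callsets must share one coordinate system.

## What the simulator does and does not emulate

It emulates: paralog divergence and its local erasure by conversion,
independent vs shared NAHR fusions, neutral substitution accumulation at a
fixed clock, star-like within-species genealogies, and a lineage-specific
paralog exchange. It does not emulate: indels (the real alignment needed
manual curation of 10–20 b indels), rate variation across sites or
lineages, drift/selection on the deletion frequency, non-star
within-species genealogies, or sequencing error. Passing recovery tests
therefore show the inference is correct *for the modelled signal*; on
real data, alignment quality and conversion complexity are the dominant
extra risks.

## Numerical and testing choices

- Windows, regions and intervals are all 0-based half-open; ties in the
  breakpoint argmin are reported as the full plateau.
- The recovery power checks use 50 seeded replicates per condition
  (breakpoint containment, scenario classification at 100 bootstrap
  replicates, dating within 20% of a 4×10⁵-year truth): large enough that
  a ≥ 95% power criterion is meaningful, small enough to run on one CPU in
  minutes.
- Brute-force oracles (per-window column counting, exhaustive switch-point
  evaluation, quadratic overlap search) are kept in the test suite and
  asserted equal to the production implementations on randomized
  instances; neighbor joining is additionally cross-checked against
  scikit-bio's implementation on random metric matrices.
- Known limitation: bootstrap support values on very short regions
  (region 3 spans 541 columns) are noisy; the overall classification
  tolerates an uninformative region by majority over supported votes.
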