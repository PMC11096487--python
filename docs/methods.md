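# Methods

`taxpop` reimplements, as a tested library, the population-genetic and
model-based analyses used to dissect the phylogeography of insular yew
(*Taxus*) lineages: within-population diversity and Hardy–Weinberg
testing, Φ-statistic differentiation and clustering, statistical-parsimony
haplotype networks with introgression counting, a mechanistic model of
chloroplast-versus-nuclear introgression dynamics, and the
likelihood-ratio machinery around isolation-with-migration (IM) output.
This note records the models, the conventions and the genuinely open
design choices.

## Data model and conventions

Aligned sequences are plain strings over `{A, C, G, T, -, N}`.  `N` is
always treated as missing.  Chloroplast markers are haploid and
concatenated per individual (the cp genome is inherited as one
non-recombining locus); the nuclear ribosomal ITS marker is diploid and
enters as two phased sequences per individual, named `<sample>_h1` /
`<sample>_h2` — an explicit, greppable convention with no FASTA-dialect
pitfalls.  Coordinates are 0-based half-open internally and printed
1-based inclusive.

Gap handling is per-statistic, mirroring the dominant convention of the
standard tool-chain (DnaSP-like): pairwise deletion of gap/`N` sites for
nucleotide diversity, complete-column deletion for the segregating-site
count behind Watterson's estimator.  For haplotype definition and
networks, each contiguous gap run is recoded as a single presence/absence
character ("simple indel coding"): a run scores `1` where a sequence has
exactly that maximal run, `0` where it has nucleotides across the span,
and missing where a longer run subsumes it.  One coded indel event counts
as one mutational step.  Haplotypes for the diversity statistics are
defined without the indel characters; for networks, with them — the
sources we follow do not state the split explicitly, so the flag is
exposed on `collapse_haplotypes` and the defaults are documented here.

With missing characters present, haplotype matching treats missing as a
wildcard and merges compatible records by first occurrence; the order
dependence this could in principle introduce does not arise in the
packaged fixtures (they contain no missing data).

## Diversity and Hardy–Weinberg testing

Haplotype diversity is Nei's unbiased gene diversity
Hd = n/(n−1)·(1 − Σp²).  π is the mean per-site pairwise difference
(each pair normalised by its own comparable length); θ_W = S/(a_{n−1}·L).
Reports can scale π and θ_W by 1,000, the presentation used for the
study's tables.  ITS statistics treat the two phased sequences per
individual as 2n sequences.

F_IS is Weir & Cockerham's single-population f̂, combining per-allele
variance components (between-individual b, within-individual c) by
summation before forming the ratio.  It is reported missing, not zero,
for monomorphic samples.

The exact Hardy–Weinberg test conditions on the allele counts.  When the
genotype-table universe is small (≤ 10⁵ tables) the tail probability —
the total conditional probability of tables no more probable than the
observed one — is computed by full enumeration.  Otherwise a Markov
chain estimates the same quantity: the state is the assignment of the 2n
observed allele copies to 2n labelled slots (two per individual), over
which the conditional null is exactly uniform, so transposing two
uniformly chosen slots per step (no accept/reject) has the target
stationary distribution.  Defaults: 10⁶ steps after 10⁴ burn-in, seed
mandatory.  The chain is validated against enumeration on all small
tables in the test suite; batch-means standard errors accompany the
estimate.  Bonferroni correction uses per-test threshold α/k and
adjusted p = min(1, k·p).

## Differentiation: Φ-statistics, AMOVA, NJ

Molecular distances are counts of differing characters (substitutions
plus optional indel characters, pairwise deletion of missing) and are
used directly as the squared distance δ² in the
sums-of-squared-deviations AMOVA — the convention for DNA haplotype
data in Arlequin, the tool the study used.  The haploid design has three
levels (among taxa, among populations within taxa, within populations);
the phased-diploid design adds a within-individual level and Φ_IS.
Variance components come from the expected mean squares of the unequal-n
nested design; negative components are retained, and the percent-variation
vector always sums to 100.

Permutation tests (default 2,000 permutations, seeded) follow the
standard schemes: whole populations among taxa for Φ_CT; individuals
among populations within taxa for Φ_SC; individuals among all
populations for Φ_ST; phased sequences among individuals within
populations for Φ_IS.  p = (count(perm ≥ obs) + 1)/(n_perm + 1), which
cannot return zero.  Degenerate designs (a taxon with one population)
are reported with a warning rather than silently dropped.

Population clustering applies neighbour joining to the pairwise Φ_ST
matrix (raw values, negatives retained; scikit-bio's NJ behind the
module surface, labels canonicalised lexicographically for deterministic
tie-breaking, negative branch lengths clamped to zero in output only).

## Statistical-parsimony networks

The connection limit is the largest number of steps j whose probability
of a homoplasy-free (parsimonious) connection is at least 0.95.  The
exact numeric behaviour of the original TCS program is not published, so
the probability is computed from a documented reconstruction: estimate
the per-site substitution intensity along the connecting path from the
observed proportion of differing sites with the Jukes–Cantor correction,
and multiply, over the j differing sites, the probability that a site
experienced exactly one hit given at least one.  The resulting limit is
non-decreasing in alignment length and collapses to 0 at a threshold of
1.0.  Because this reconstruction is contestable, an explicit
`max_steps` override is accepted everywhere and every packaged fixture
and acceptance run sets it explicitly.

Network construction joins haplotype pairs in order of increasing
mutational distance, freezing component membership at the start of each
distance level so that equal-length alternative connections are all
retained (reticulations).  A d-step connection inserts d−1 inferred
intermediate nodes; no edge ever spans more than one step, and pairs
beyond the limit are never joined, so components are separated by more
than the limit — the "two separate networks" behaviour seen with highly
divergent singletons.  Haplogroups default to network components
labelled by their majority taxon (ties broken by label order with a
warning).  Where biological haplogroups are subgraphs of one connected
network, user-declared reference haplotypes seed the labels and every
haplotype takes the label of its graph-nearest reference.
Introgression is then counted as focal-taxon sequences assigned to a
donor haplogroup, with percentages reported to one decimal.

## Chloroplast-versus-nuclear introgression dynamics

*Taxus* is dioecious with paternally inherited chloroplasts.  The model
tracks, through discrete non-overlapping generations (25 years for any
calendar conversion), the exotic-gene frequencies x (cp) and y (nuclear)
separately in the male and female pools; the population-level
introgression level of a locus is the equal-weight average of the two
sex pools (the simplest convention consistent with an even adult sex
ratio).

Under pollen-only flow at rate p, every recruit has a local mother and
an exotic father with probability p: x′ = p + (1−p)·x_M for both sexes,
y′ = ½[y_F + p + (1−p)·y_M].  One step from a pristine population gives
L_cp = p and L_nuc = p/2 — cp introgression is instantaneously exactly
twice the nuclear level, and stays ahead forever.  Under seed-only flow
at rate s, recruits are a mixture of exotic seeds (both loci exotic) and
local offspring; an exotic recruit is female with probability φ_e, a
local one with probability φ_l, and each sex pool is the mixture
conditioned on that sex.  With φ_e = φ_l the two loci are exchangeable
and L_cp = L_nuc for all time; with φ_e > φ_l the exotic contribution is
funnelled away from the cp-transmitting male pool and L_nuc ≥ L_cp, the
observed cytonuclear asymmetry.  At φ_e = 1 exotic chloroplasts never
enter the male pool and x_M stays at zero.

The published account states this mechanism verbally but does not print
its supplementary recursions, so the equations above are reconstructed
from the stated inheritance rules (paternal cp, biparental nuclear,
origin-conditioned sex ratios).  Two ambiguities were decided and are
flagged here: sex-ratio adjustment conditions on recruit *origin*
(immigrant versus local), not on locus genotype; and observed levels
weight the sexes equally rather than by sampled counts.  An
individual-based dioecious forward simulator — random mother/father
sampling, per-parent allele transmission, per-recruit sex assignment —
is kept in the package as the arbiter of the recursions; the recursion
is its infinite-population limit, and the test and acceptance suites
check agreement within three Monte-Carlo standard errors on a 3×3
parameter grid (N = 2,000, T = 50, 50 replicates).

`calibrate` fits (rate, φ_e) to an observed pair (L_cp, L_nuc) by grid
least squares on the trajectory endpoint, returning the full objective
surface.  Pollen-only flow cannot produce L_nuc > L_cp, so such targets
(e.g. the observed mainland-to-Taiwan levels 1.4 % cp vs 5.7 % ITS)
return an explicit infeasibility result instead of a silent best fit.

## Migration likelihood-ratio test and IM unit conversion

A zero migration rate lies on the boundary of the IM parameter space, so
−2 log Λ is compared with a 50:50 mixture of χ²(0 df) (a point mass at
zero) and χ²(1 df): p = ½·P(χ²₁ ≥ stat) for a positive statistic, 1 at
zero, and the α-level critical value is the χ²₁ quantile at 1 − 2α
(2.71 at α = 0.05).  Scaled IM parameters convert with locus-wide yearly
rates 1.67×10⁻⁶ (cp) and 1.24×10⁻⁶ (ITS), combined as a geometric mean
(the IM software's convention; the source text does not restate it, so
the choice is echoed in the conversion metadata): Ne = q/(4·u·g) with
g = 25 years, and T = t/u_year, i.e. t is taken as scaled by the yearly
rate so times emerge directly in years (the alternative is exposed via
the scaling object).  Inheritance scalars are products of a ploidy
factor (haploid ½) and a transmitting-sex factor (uniparental ½ under an
even dioecious sex ratio): 0.25 for paternal cp, 1 for biparental
nuclear loci.

## Synthetic data

Two generators support fully offline testing.  The structured-coalescent
simulator implements the three-deme history ((Taiwan, Philippines),
mainland) backward in time with exponential waiting times, per-deme
coalescence at pair rate 1/(2N·scalar) and backward per-lineage
migration; the Taiwan/Philippines ancestor takes the Taiwanese size and
the root the mainland size (no sizes for ancestral demes are published;
these are the adjacent extant values).  Default magnitudes follow the
study's modal estimates: N = 16,400/6,900/2,700 individuals, splits at
1.56 and 4.16 Myr with 25-year generations.  Mutations are
infinite-sites Poisson placements (erroring rather than recycling sites)
with optional 1–3 bp indel events.  Closed-form checks — E[TMRCA] = 2N
generations for a nuclear pair, N/2 for chloroplast, E[π] = 4Nμ — are
exercised in the tests at Monte-Carlo tolerance.

The fixture builder is deterministic by design: migrant lineages are
injected by recipe, not sampled, so classify-and-count results are
exact.  Haplogroups are built on disjoint mutated site sets at least 12
steps apart (far beyond the fixture connection limit of 10), with
within-group variants one step apart.  The packaged recipes replicate
the study's sampling design — nine Taiwanese populations (141 trees),
two Philippine (38), seven mainland (105) — and its introgression
bookkeeping: 16/282 ITS and 2/141 cp mainland-haplogroup sequences in
Taiwan, 19/76 ITS and 2/38 cp Taiwan-lineage sequences in the
Philippines.  Diploid fixtures pair haplotypes randomly within taxa
(Hardy–Weinberg by construction); a recipe flag rebuilds the Mt. Apo
population all-heterozygous to emulate its strong heterozygote excess
(F_IS ≈ −0.9).  What the fixtures deliberately do not emulate: realistic
haplotype frequency spectra (not published), recombination, selection,
or substitution models beyond infinite sites.  Passing fixture-based
tests therefore demonstrates the correctness of the counting and
classification machinery, not the realism of the sequences.

## Problem sizes and numerical choices

The test and acceptance workloads are chosen at desk scale: coalescent
Monte-Carlo checks use hundreds of replicates on demes of a few hundred;
the forward-simulation grid uses N = 2,000 and 50 replicates; HWE
chain-versus-enumeration checks use tables of up to six individuals with
40,000-step chains.  Permutation p-values use the +1 correction;
all stochastic code draws from `numpy.random.default_rng` seeded
explicitly, and every pipeline output embeds the config hash and seed.

## Known limitations

The parsimony-probability formula is a reconstruction, not a
re-implementation of TCS; explicit limits sidestep it where exactness
matters.  The AMOVA assumes populations nest cleanly in taxa and phased
diploids contribute exactly two sequences.  The coalescent simulator has
no recombination and applies migration only below the first split.  The
introgression model treats pollen and seed flow as exclusive modes;
joint mixtures are out of scope.  IM likelihood statistics are inputs
here — the package does not run the IM sampler itself.
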