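# Methods

`hgtsweep` models the fate of a beneficial, horizontally transferable
allele in a microbial community that receives immigrants. Three linked
models share one parameterisation; all rates are per generation and one
model time unit is one generation.

## Compartment model

A well-mixed community of fixed size `N` is split into carriers (fraction
`C`) and non-carriers of the allele. Carriers have fitness `w = 1 + s`
(`s = b − ε`, local benefit minus carriage cost; the package requires
`s ≥ 0`). Horizontal transfer converts a non-carrier with per-capita
probability `r·C` per generation, and a fraction `m` of the community is
replaced each generation by allele-free immigrants. The carrier fraction
obeys

    dC/dt = s·C(1−C)/(1+sC) + r·C(1−C) − m·C .

The selection term is the deterministic limit of fitness-proportional
(Wright–Fisher) resampling; the `1/(1+sC)` factor is mean-fitness
normalisation. Fixed points: without migration `C* ∈ {0 (unstable),
1 (stable)}` — the allele always fixes; with migration and `r ≈ 0` the
stable interior point is the migration–selection balance
`C* = (s−m)/((m+1)s)`, which exists only while `s > m`. The
community-level transfer rate ("horizontal gene flux") is `r·C(1−C)·N`
events per generation; its time integral counts expected transfer events.
In an isolated patch the flux window closes at fixation and the
`r → 0` change-of-variables limit gives a closed form for the total,
`(rN/s)(1−C0+s(1−C0²)/2)`; with migration the partial sweep parks at
`C* < 1` and flux continues indefinitely, maximal when `C* = 1/2`, i.e.
at `s = 2m/(1−m)`.

Numerics: adaptive LSODA with rtol 1e−8 / atol 1e−12 and dense output;
trajectories are sampled on a uniform grid of ≥ 10⁴ points and the
cumulative flux uses the left-endpoint rectangle rule with automatic step
halving until the total changes by < 0.5 %. Solutions straying more than
1e−6 outside [0, 1] raise an integration error; smaller excursions are
clipped. The degenerate field `s = r = m = 0` integrates to a constant
trajectory and `steady_states` reports a single "neutral" flat-field
entry rather than raising.

### Two-patch extension

To relax the assumption that immigrants never carry the allele, an
explicit external environment of relative size `ρ` is coupled to the
focal patch by a per-capita exchange rate `e`; equal cell swaps conserve
both patch sizes, giving

    dC_F/dt = g(C_F; s)      + e·(C_E − C_F)
    dC_E/dt = g(C_E; s_env)  + (e/ρ)·(C_F − C_E)

with `g` the within-patch selection-plus-transfer field and `s_env ≤ 0`
(the trait is disfavoured outside). This specific coupling is the
simplest closed form with both required limits: a large environment
(`ρ ≫ 1`) loses the allele internally and reproduces the one-patch
migration model with `m = e`, while a small environment (`ρ ≪ 1`)
equilibrates with the focal patch so the pair behaves as a single
isolated patch in which the allele fixes.

## Pair-coalescence diversity model

Genomic consequences are computed for two loci: the transferable focal
locus and an unlinked background locus. Two copies of a locus sampled at
`t_end` are traced backward through the forward solution `C(t)`; the pair
occupies one of six states (both lineages in carriers S11, both in
non-carriers S00, mixed S01, coalesced in a carrier S1, coalesced in a
non-carrier S0, emigrated SM). Backward per-generation rates:

* within-class coalescence at `1/(N·x)` for a class of frequency `x`
  (neutral-within-class approximation: selection acts only through
  `C(t)` and the class sizes);
* a non-carrier lineage is a fresh immigrant at rate `m/(1−C)` (all
  immigrants are allele-free and genetically unique), sending the
  non-coalesced pair to SM;
* background locus only: a lineage in a carrier switches to the
  non-carrier class at `r(1−C)`, because forward transfer converts a
  non-carrier in place, keeping its background genome;
* focal locus only: a transfer recipient's allele traces back to the
  donor — another carrier — so focal lineages never leave the carrier
  class; the donor jump contributes an additional (numerically
  negligible) coalescence term `2r(1−C)/(N·C)` for carrier pairs.

Coalesced states are absorbing: identity is decided at the first
coalescence, and the earlier history of a coalesced pair (including
whether that single ancestral individual was an immigrant) cannot change
it. SM is absorbing and counts as non-identity, since a pair that
emigrates before coalescing traces to two distinct, unique genomes.

Identity conventions mirror the individual-based initial condition: the
founding carriers are a single clone (identical at both loci), initial
non-carriers and every immigrant are unique. Hence the identity
probability is `F = P(S1) + P(S0) + P(S11)` at `t = 0`, the diversity is
the order-2 Hill number of the effective composition, `D = 1/F`, and the
diversity ratio is `DR = D_bg/D_f = F_f/F_b`. These conventions are the
ones under which an isolated vertical sweep yields `DR ≈ 1` (both loci
purged alike), the observed null behaviour.

Numerics: the 6-state master equation is integrated backward with LSODA
(rtol 1e−10 / atol 1e−14); probability is conserved to 1e−9 or the solve
raises. Class frequencies in rate denominators are floored at `1/N` — an
occupied class holds at least one cell — which keeps the generator
bounded at the `C → 0, 1` boundaries where the corresponding state mass
vanishes anyway.

## Individual-based model

A stochastic discrete-generation model of `N` cells, each a triple
(focal allele, background genotype, niche). Generations apply, in order:
resource allocation → Wright–Fisher reproduction → horizontal transfer →
migration. The order is a modelling choice; its per-generation
sensitivity is O(m·r) and negligible at the rates studied.

*Resources.* Each of `n` niches holds a share `N/n`. A cell of fitness
`f` (1+s for carriers) competes in its assigned niche with weight `f·z`
and in each other niche with weight `f·(1−z)/(n−1)`; `z = 1/n` is
uniform competition, `z = 1` full specialisation (`z < 1/n` is allowed
with a warning). A cell harvests from each niche in proportion to its
relative competitive weight there; empty niches forfeit their share
(simplest reading of a fixed per-niche resource pool). Harvested
resources `R_i` are the mean offspring number.

*Reproduction.* Stated as Poisson offspring within a fixed-size
community, which is consistent only after conditioning on the total:
offspring counts are drawn multinomially with class weights
`count_i·R_i`, the law of independent Poissons conditioned on summing to
`N`. This keeps `N` exact every generation (asserted at run time).

*Transfer.* Every non-carrier converts with probability `C·r`, keeping
its background genome and niche; realized conversions are recorded as
the generation's gene flux.

*Migration.* `Binomial(N, m)` uniformly chosen cells are replaced by
immigrants — allele-free, globally unique genotypes, uniformly random
niches (the uniform niche assignment is a choice; immigrants carry no
niche information).

*Diversity.* Order-2 Hill numbers `D = 1/Σp_i²` of the focal-locus and
background compositions, and `DR = D_bg/D_f`; zero-count variants are
dropped.

*State representation.* Counts over distinct (focal, background, niche)
classes. Genotypes whose label is never shared — initial non-carriers
and immigrants — are exchangeable and are held in occupancy buckets
(number of anonymous lineages per niche and copy number) rather than as
individual rows. Their reproduction is sampled by multinomial
aggregation (group total, then uniform drop onto the group's lineages)
and migration removal by mapping uniformly chosen distinct cell
positions onto lineages block-wise; both realize exactly the per-lineage
laws. A lineage is promoted to explicit rows, with a fresh identifier,
when transfer first copies the allele out of it. Without this the class
table grows by `m·N` unique rows per generation, which dominates the
runtime at `N = 10⁵`. The bucket machinery is validated against
closed-form Wright–Fisher expectations (mean selection response,
per-generation heterozygosity decay `(1−1/N)^t`, transfer and migration
expectations) in the test suite.

A single `numpy` PCG64 generator seeded from `seed` drives each run;
replicate k of a scan uses `base_seed + k`, and identical (parameters,
seed) reproduce bit-identical series. `run()` records the carrier
fraction and realized flux every generation; the diversity metrics are
recorded every `metrics_every` generations (and always at the first and
last generation), since they are the costly part of the bookkeeping.

## Study conditions and problem sizes

The standard parameterisation is `N = 10⁸`, `C(0) = 1000/N`,
`r ∈ [10⁻⁶, 10⁻⁴]` (around the conservative literature estimate of 10⁻⁶
per gene per generation), `m = 0.02`, and `s` scanned over
(0, 0.15]. Deterministic experiments run at these values directly:
cumulative-flux curves to `t = 10⁵` and diversity-ratio scans to
`t_end = 5×10⁶` with the s-grid {0.005, …, 0.150} in steps of 0.005
(fine enough to resolve the DR peak near s ≈ 0.04).

Individual-based experiments are scaled down to desk size as the
package's standard configuration: `N = 10⁵`, `t_end = 10⁴`,
20 replicates (the full-size niche experiments at `N = 10⁶`,
`t_end = 10⁵`, 50 replicates are cluster-scale; the CLI exposes
`--scale/--full-scale` to move between them, and provenance records the
scale used). The coalescence/IBM cross-check runs at `N = 10⁴`,
`t_end = 2×10⁴`, `s = 0.05`, `m = 0.02` with the transfer rate rescaled
to `r = 10⁻³` so expected event counts match the large-N regimes, and
`C0 = 0.01`.

## What the models do and do not capture

The generators here emulate the idealised study system: a well-mixed
(or niche-subdivided) fixed-size community, one focal locus, one
unlinked background locus, immigrants always allele-free and unique.
They do not model the mechanism of transfer (plasmid, phage, natural
transformation), sequence mutation, linkage, within-patch spatial
structure, or varying community size — so passing tests demonstrate the
internal consistency and the stated population-genetic effects, not the
quantitative behaviour of any particular natural community.

Known limitations: the coalescence model's within-class coalescence
ignores variance in offspring number beyond the neutral rate (exact in
the large-N, weak-selection limit); the reduced-scale IBM runs have
large replicate variance in DR, so ordering comparisons between close
configurations (e.g. n = 1 vs n = 10 niches at z = 0.2) sit near the
resolution limit of 20 replicates; and the two-patch coupling is one of
several size-conserving exchange schemes, constrained only by its two
limiting behaviours.
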