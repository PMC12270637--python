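# Methods

This note documents the models and numerical choices behind `pollnet`:
what each statistic computes, what the synthetic community generator
does and does not emulate, and where genuinely open design decisions
were resolved.

## Data model

The atomic observation is a visitation event: (month, site, plant,
pollinator, count), with count the number of pollinator individuals
recorded. Monthly networks are quantitative plant × pollinator count
matrices; sites are pooled before aggregation, duplicate rows are
summed, and a species enters a month's matrix only if it interacted
that month. The annual meta-network is the union of the twelve monthly
networks with summed cell weights; per-month contributions are retained
as provenance so each monthly network is exactly reconstructable. Three
conservation identities are asserted at pipeline runtime: event totals
= summed monthly totals = meta-network total.

## Network-level indices

**Weighted connectance.** Quantitative linkage density divided by total
species number I + J. Linkage density is the flow-weighted mean of each
species' effective partner number 2^H, where H is the base-2 Shannon
entropy of its interaction frequencies:
LD = ½ [ Σ_j (A_·j/m) 2^{H_j} + Σ_i (A_i·/m) 2^{H_i} ]. This is the
standard quantitative (Shannon) connectance of the bipartite-analysis
literature; it is stated explicitly here so results are reproducible
from this document alone. Connectance is not null-standardized.

**H2′.** Community-level interaction specialization:
H2′ = (H2max − H2)/(H2max − H2min), with H2 = −Σ (a_ij/m) ln(a_ij/m)
over positive cells (natural log) and H2max/H2min the extreme
two-dimensional entropies attainable by a non-negative integer matrix
with the observed marginal totals. For matrices with total ≤ 24 and
both dimensions ≤ 5 the extremes are computed exactly by enumerating
the transportation polytope; larger matrices use greedy heuristics
(max–min pairing for the minimum, proportional largest-remainder fill
for the maximum) refined by marginal-preserving 2×2 swap hill-climbing
up to 100 cells. The greedy heuristic alone can miss the true optimum
on small matrices (verified against enumeration), which is why the
exact route exists; at survey scale the greedy value is the
field-standard approximation. The value is clipped to [0, 1];
single-row/column networks return 0 with a warning.

**Weighted NODF.** For every ordered pair of rows (and of columns) with
strictly decreasing marginal totals, the contribution is 100 × the
fraction of the smaller species' links that the larger species also
uses at strictly higher weight; the index is the mean over all row and
column pairs. Ties in marginal totals contribute 0, so a matrix with
all-equal totals scores 0.

**Barber's bipartite modularity.** Q = Σ_j [ m_j/m − s_j p_j / m² ]
over modules j, with m the total link mass, m_j the within-module mass,
and s_j, p_j the summed plant and pollinator degrees of the module.
Mass and degrees use summed visit counts by default (the networks are
quantitative); a binary mode is available since the defining formula
speaks of link counts.

## Module detection and genealogy

Modules are found with Louvain or fast-greedy agglomeration (igraph) on
the weighted bipartite graph treated as a general undirected graph, and
the resulting assignment is then scored with Barber's Q. The detection
step therefore optimizes Newman modularity while the reported score is
bipartite-aware; this mirrors the common pairing of general-graph
community detection with a bipartite quality index, and is a documented
mismatch, not a hidden one. Louvain runs 100 restarts by default (20 in
the pipeline, fewer inside null loops) from a seeded RNG, keeping the
membership with the highest Newman modularity; fast-greedy is
deterministic. Module labels are renumbered by first appearance over
the lexicographically sorted species list, so detection is fully
deterministic given the seed. Resolution defaults to 1.

Genealogy: every species present in two consecutive months contributes
one unit of flow from its month-t module to its month-t+1 module; flows
are grouped and counted. Fission and fusion are read directly off the
grouped flows (one module feeding several, several feeding one); no
extra event-classification heuristic is imposed.

## Null model and standardization

The null permutes the plant labels across a month's interaction events
(a uniform permutation of the label multiset) and re-aggregates to a
species-level network, preserving the month's total weight and every
pollinator's marginal by construction. This is the weakest-assumption
reading of shuffling "at sample level" followed by conversion to
species-level networks; pollinator labels are never shuffled.
Standardization: z = (observed − null mean)/null SD with sample (n−1)
SD; two-sided empirical p = 2·min[(1+#{null ≥ obs})/(N+1),
(1+#{null ≤ obs})/(N+1)] capped at 1. N defaults to 1000, overridable.
A zero-range ensemble is flagged degenerate (z undefined, p = 1).
Significance across the twelve months of one index is controlled with
Benjamini–Hochberg FDR at α = 0.05; the FDR family is per-index.

## Interaction turnover partition

Over the link union of two monthly networks, the shared mass is
A = Σ min(w1, w2) per link, and each link's excess |w1 − w2| is classed
by its endpoints: both species present in both networks → rewiring
(OS); plant present in only one network → ST.l; pollinator only →
ST.h; both → ST.lh. All components divide one common denominator D, so
βWN = βOS + βST and βST = βST.l + βST.h + βST.lh hold to machine
precision — the only convention under which the additive decomposition
is exact. Per-component renormalization is deliberately rejected.

Quantitative mode uses D = A + B + C (the Ruzicka / quantitative
Jaccard family). Binary mode replaces weights with presence and uses
D = 2A + B + C, so the total reduces exactly to Whittaker's
βWN = (b + c)/(2a + b + c). The two modes answer the same question on
different scales and both are first-class; the companion
species-composition dissimilarity βS applies the same family to pooled
species marginal totals ("present" meaning ≥ 1 positive link). The
consecutive-pair series wraps December → January, completing the annual
cycle. The packaged reference turnover table is checked only to the
0.015 tolerance implied by its 2-decimal rounding, since the index
family that produced it is not recoverable from the printed values.

## Species roles

**d′.** For plant i with visit vector a_i· and partner availability
q_j = A_·j/m: d = Σ p′_ij ln(p′_ij/q_j), standardized between d_min
and d_max over feasible integer visit distributions (vectors summing to
the row total with entries capped by partner totals — exactly the
distributions completable to a matrix with the observed marginals).
d_min is found by greedy unit allocation, which is provably exact for
this separable convex minimization; d_max by exhaustive enumeration
when the row total is ≤ 12 and partners ≤ 6, otherwise by concentrating
visits on the rarest partners (also testing single-partner
concentrations). 1 − d′ is reported as interaction generality.

**Betweenness.** Computed on the binary undirected bipartite graph with
unweighted shortest paths (the standardization formula
2B/((n−1)(n−2)) is the unweighted one); pairs in different components
contribute no paths, and the standardization always uses the full
vertex count n. Networks with n < 3 get 0. Plants with standardized
betweenness strictly greater than 0.25 are classed core.

**Meta-network roles.** Within-module degree z uses binary link counts
to own-module members, standardized with the population SD over the
module (z := 0 with a warning when all members tie). Among-module
connectivity is the participation coefficient c = 1 − Σ_j (k_ij/k_i)².
The defining formula as often printed omits the exponent, which would
make c identically zero; the squared form is the established one and is
used here. Note the maximum of c is 1 − 1/NM, approaching 1 only as
the number of modules grows. Roles: super generalist (z > 2.5 and
c > 0.62), module hub (z > 2.5 only), connector (c > 0.62 only), else
peripheral; all inequalities strict. A weighted-degree variant of z and
c exists but is off by default.

## Synthetic community generator

The generator emulates a year-round urban botanical-garden community:
species pools of 151 plants (77 native / 74 exotic, nearest-integer
split) and 142 pollinators allocated across the five orders by largest
remainder (68/24/45/3/2 at the default mix), per-species phenology
windows (start uniform over months, duration uniform on 2–4 months for
ordinary species and 9–12 for the seven long-flowering plants and seven
long-active pollinators, windows wrapping December → January), block
affinities (8 blocks, uniform assignment), log-normal(0, 1) abundance /
activity factors, and Poisson visit counts with intensity
abundance × activity × rate, where the rate is 0.6 within blocks and
0.06 between (a ten-fold contrast). Defaults were chosen once to match
the observed community's scale and strong seasonal turnover and are not
tuned to any downstream test. Under them a typical year yields roughly
3–4 thousand events, monthly networks of ~30–50 species per guild, and
consecutive-month interaction dissimilarity in the 0.8–0.9 range —
the regime reported for real monthly pollination webs.

What the generator does **not** emulate: partner fidelity beyond block
structure. Within a block, intensities are rank-1 (abundance ×
activity), i.e. neutral; real communities show stronger reciprocal
specialization. Consequently synthetic networks typically score *below*
the plant-shuffle null on H2′ (negative z), whereas field studies
usually report the opposite sign. Passing tests therefore demonstrate
correctness of the machinery — conservation, calibration, recovery of
planted structure — not that the generator reproduces every qualitative
signature of real data. Behavioral foraging dynamics, site differences
and observation effort are likewise out of scope; negative-binomial
counts are left as a configuration extension.

Planted fixtures: `planted_blocks_network` gives a single modular
network with known labels and no abundance heterogeneity (clean
planted-partition signal); `planted_fission_fixture` gives two months
in which one six-by-six block splits into two three-by-three blocks
beside an unchanged reference block, so module genealogy must show
exactly two out-flows from the source module.

## Problem sizes and numerical choices

The test suite runs the full pipeline on a reduced community (15–25
species per guild, 19 permutations) and statistical checks at the sizes
stated in their docstrings: null calibration with N = 199 permutations
and 500 draws on a 14-event month; planted-block recovery over 20
seeds; oracle equivalence on ≥ 50 enumerable matrices (marginal totals
≤ 6) and graphs ≤ 12 vertices. The acceptance script simulates one
paper-scale year and averages block recovery over 10 seeds. These sizes
were chosen so the whole suite completes in well under a minute of
CPU-bound statistics plus ~20 s of calibration, while keeping every
stochastic assertion at ≥ 3-sigma separation from its threshold.

Tie-breaking is fixed throughout by sorted species labels; all
randomness flows from explicit seeds (numpy `SeedSequence` substreams
per pipeline stage). Degenerate inputs (single-species axes, zero-SD
ensembles, uniform modules, isolated species) return flagged or defined
values rather than raising, except where the contract demands an error
(empty matrices, unknown species, invalid configs).

## Known limitations

- Louvain optimizes unipartite Newman modularity, not Barber's Q
  directly; on bipartite graphs with weak signal the detected partition
  need not maximize the reported score.
- The greedy H2′/d′ extremes beyond the exact-enumeration gate are
  heuristics; the standardized values at survey scale inherit their
  (small, one-sided) bias, as they do in the standard tooling.
- The turnover table shipped as reference data is transcribed at
  2-decimal precision, limiting any check against it to ±0.015.
- Module genealogy tracks species co-membership only; it does not test
  whether a fission is statistically meaningful.
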