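# Methods notes

This note records the modelling choices, parameter defaults and numerical
conventions behind `batfruitnet`, and what the synthetic-data tests do and
do not establish about real field data.

## Data model

Interaction matrices are `A × P` with rows = animals (bats) and columns =
plants; readers reject any other orientation instead of guessing.  Cells
are non-negative reals internally, written back as integers when every
input was integral so count matrices round-trip bit-exactly.  All-zero
rows/columns are dropped (and reported) before any metric; metrics refuse
matrices smaller than 2×2 rather than returning NaN.  Frugivory level
(primary / secondary / occasional) is an *input* classification of the
bats — the package does not infer it.

## Nestedness

NODF is computed order-invariantly: an unordered pair of lines qualifies
iff its marginal totals differ strictly, contributing
`overlap / min(marginal)`; the network value is the plain mean over all
row pairs and column pairs.  This is algebraically identical to the usual
"sort by marginal totals, count decreasing-fill pairs" presentation
(the test suite checks the equivalence exhaustively on all binary
matrices up to 4×4 and against the R `vegan` implementation), but needs
no tie-breaking among equal-marginal lines.  Weighted matrices must be
binarized explicitly by the caller; there is no silent thresholding.
`nodf_delta` (the jackknife building block) drops lines emptied by a
removal before recomputing, mirroring secondary-loss bookkeeping, and
flags removals that would leave fewer than two lines on a side as not
computable.

## Complementary specialization

`H2` is the Shannon entropy (nats; the base cancels in the ratio) of the
cell proportions.  The maximum given the marginals uses the continuous
independence table `p_ij = (r_i/Σ)(c_j/Σ)` rather than an
integer-rounding scheme; the difference is `O(1/Σw)` and negligible at
fecal-sample totals.  The minimum uses greedy concentration — repeatedly
place `min(remaining row, remaining column)` mass in the cell of the
currently largest row × largest column — with ties broken by larger row
total, then larger column total, then index order, for determinism.
Exhaustive enumeration of contingency tables at small marginals confirms
the greedy minimum is exact on every case tested.  `H2'` is clamped into
`[0, 1]` only against numerical noise (`1e-9`); larger violations raise,
since they would mean the observed table out-concentrated the greedy
extremum.  Binary-only matrices are rejected as not computable — an
entropy of presence/absence says nothing about interaction frequencies —
which is also how the one presence/absence field network is handled
(reported `n/a`).

## Null models and Monte Carlo convention

* **Ce** (binary, degree-proportional): cell `(i, j)` filled independently
  with probability `(d_i/P + d_j/A)/2`.  Draws containing an empty line
  are rejected and the whole matrix resampled (capped at 1000 attempts)
  — repairing single cells would bias cell probabilities.  Note the
  conditioning itself shifts realized frequencies slightly upward; the
  unconditioned draw is exposed for diagnostics (`require_connected=False`).
* **Patefield** (weighted, fixed marginals): uniform allocation of the
  `Σw` interaction events conditional on both marginal vectors, via
  `scipy.stats.random_table(..., method="patefield")`.  Marginals are
  conserved exactly, always.

P-values are one-sided: the proportion of null statistics *equal to or
higher than* the observed one (ties count toward the numerator).  When no
null reaches the observed value, the result is reported as the bound
`P < 1/N` with an explicit flag, never as zero.  Default ensemble sizes
are 1000 (NODF), 10000 (H2'), 100 (modularity) — the conventional counts
for these statistics — and are configurable everywhere.  A master
`SeedSequence` spawns one substream per replicate, so serial and parallel
evaluation produce identical ensembles.

## Modularity by simulated annealing

The bipartite network is embedded as an undirected unipartite graph (no
within-side edges exist, so nothing is added) and Newman–Girvan
modularity is maximized directly on it; a bipartite-specific modularity
(Barber's) is deliberately not used, to keep module membership defined
jointly over bats and plants in the usual way for mutualistic-network
guild analysis.

Search: Metropolis acceptance; per temperature, `S²` single-node moves
(target module drawn from a random node's module, with a 10% chance of
opening a fresh singleton module) and `S` collective moves (merge of two
random modules, or random bisection of a module followed by a local
node-move pass at the current temperature, accepted or rejected as a
whole).  Geometric cooling `T ← 0.95·T` from `T0 = 0.05` down to `1e-5`,
stopping early after 50 coolings without improvement of the best value;
the best state is finished with greedy node moves to a local optimum, and
the best of 5 restarts (default) wins.  Module bookkeeping (within-module
edges, module degrees) is integer, so the incremental modularity is free
of float drift.

The initial temperature is deliberately on the scale of single-move
modularity deltas (about `1/L` for these networks).  Starting far above
that scale makes the walk unselective: the best-so-far stops improving
while the schedule is still in pure noise, the stagnation stop fires
there, and the returned partition is essentially whatever the final
greedy polish salvages — measurably worse and much more variable across
restarts.  `T0`, cooling factor, stagnation window, proposal budget and
restart count are all exposed.

Annealing is stochastic, so module counts and `M` values on real-size
networks are reproducible only for a fixed seed; the planted-recovery
tests establish accuracy, not uniqueness, of the optimum.

## Guild counting and G tests

For each bat genus with a predicted preferred plant genus
(*Artibeus–Ficus*, *Carollia–Piper*, *Sturnira–Solanum* by default), a
network "follows" the prediction iff the module holding that genus also
holds at least one plant of the predicted genus.  If a genus is split
across modules (possible on synthetic data), the module with the majority
of its bats is used and the event is logged.  Counts are pooled across
networks and tested against equal proportions with a goodness-of-fit G
test; the Yates correction moves each observed count 0.5 toward the
expectation without crossing it, and `G` is referred to chi-square with
1 df.

## Functional roles

`k_r` = degree / partners available on the other side.  Betweenness uses
all species pairs (not only opposite-side pairs — the definition refers
to paths between *all* pairs), normalized by `(n−1)(n−2)/2`; disconnected
pairs contribute no paths and the normalization is unchanged.  Hubs and
connectors are flagged by within-network quantile thresholds (default
0.9, `≥` comparison so threshold ties are all flagged) because the
concepts name tails, not fixed cutoffs.  Side comparisons use a pooled-
variance t test (df = n−2); frugivory-level comparisons use
Kruskal–Wallis.  Groups whose values are all identical short-circuit to
statistic 0, p = 1 rather than a 0/0.

## Robustness

Removal order is uniformly random ("error" tolerance); a caller-supplied
order is accepted for targeted experiments but not used by the default
analysis.  The survivor curve runs from (0, 1) to (1, 0) — the endpoint
is automatic because validated matrices have no never-connected species —
and `R` is its trapezoid area over removal *fractions*.  Closed forms
used as tests: one-to-one networks give `R = 0.5` exactly for every
order; complete networks give `R = 1 − 1/(2P)`.  Other integrators (e.g.
step functions) shift `R` at the second decimal, so published per-network
`R` values are treated as convention-dependent rather than exactly
reproducible.  Secondary losses cannot cascade further in a bipartite
network, and removals model exclusion from the seed-dispersal service,
not literal extinction; output vocabulary says "removal/loss"
accordingly.

## Synthetic generator: what it emulates, and what not

Planted structure: up to three genus-paired modules (plus a background
module for the remaining species), scaled to roughly a quarter of each
side per genus.  Presence probability is
`1 − (1 − base)^(s_i s_j)` with `base = p_in` within modules and `p_out`
elsewhere — exactly `base` for unit propensities, exact 0/1 blocks at the
extremes, always a probability.  Propensities are log-normal with
`σ = ln(nestedness_skew)`, so `skew = 1` means homogeneous species and
`skew > 1` produces the right-skewed degree distributions of real
frugivory data; primary frugivores get a ×3 propensity boost so
role-direction tests have a planted signal.  Weights are geometric
(mean `weight_mean`), matching the long-tailed look of fecal-sample
counts.  Isolated species are repaired with one forced link to the
highest-propensity partner, deterministically and logged.

Defaults (`p_in = 0.7`, `p_out = 0.08`, `skew = 2.5`, `weight_mean = 4`,
frugivory mix 0.6/0.2/0.2) were chosen so the nine-network suite at the
field sizes lands near the field matrices' fill (mean normalized degree
≈ 0.28–0.30 per side) with module counts in the observed 3–6 range.  The
suite generates its largest network binary-only, mirroring the one
presence/absence field dataset and exercising the `n/a` path.

What passing synthetic tests do **not** show about real data: the
generator plants conditional independence given propensities and modules,
so it reproduces degree heterogeneity and module structure but not, e.g.,
phylogenetic correlation beyond genus blocks, sampling effort gradients,
or the field matrices' extreme singleton-rich tails — its robustness
areas run somewhat higher than the published field range for the same
sizes.  Direction tests (primary frugivores more connected and more
central; generalist removals hurting nestedness more) verify that the
pipeline detects planted effects, not that nature behaves this way.

The planted-recovery experiment uses strong contrast (`p_in = 0.9`,
`p_out = 0.02`) with homogeneous propensities, because it is a test of
the *search*: under weaker contrast or heavy propensity tails the
realized graph's modularity optimum genuinely differs from the planting
(the annealer still always returns a partition at least as good as the
planted one), so recovery accuracy is then bounded by the data, not the
algorithm.

## Problem sizes in the shipped analyses

The acceptance script runs the full pipeline on the nine synthetic
networks with 200 nulls for NODF and H2' (p-value resolution 0.005), two
annealing restarts, 100 removal replicates, and 8 recovery runs — sizes
chosen so a complete from-scratch reproduction stays around half a minute
on one CPU while keeping every reported quantity stable to the second
decimal across seeds.  The library defaults remain the conventional
1000/10000/100 ensembles.

## Known limitations

* `H2_min` is a greedy extremum; it is exact on every enumerated small
  case, but global optimality for arbitrary marginals is not guaranteed,
  and published per-network H2' values computed with other extremum
  heuristics can differ in the second decimal.
* The Ce rejection step conditions on connectedness; for very sparse
  matrices the attempt cap can be hit, which is reported as an error
  rather than silently repaired.
* Modularity values from annealing are lower bounds on the optimum; module
  counts should be read with their seeds.
* The G-test pooling treats networks as independent observations of one
  2-outcome experiment per genus; with nine networks its power is limited.
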