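# batfruitnet

Structure and robustness analysis of bipartite **bat–fruit seed-dispersal
networks**.

Neotropical fruit-eating bats (family Phyllostomidae) and the plants whose
seeds they disperse form bipartite mutualistic networks: an `A × P` matrix
whose rows are bat species, columns are plant species, and cells count
interaction records (typically fecal samples containing seeds), or record
presence/absence.  `batfruitnet` is a library plus CLI for the standard
community-level analysis of such matrices, aimed at network ecologists who
want every step — metrics, null models, significance, species roles,
extinction simulations — reproducible from a single seed.

## What it computes

**Nestedness (NODF).** For every pair of rows and every pair of columns, a
pair with strictly different marginal totals contributes
`(shared presences) / (marginal of the sparser line)`; pairs with equal
marginals contribute 0.  NODF is the mean over all
`A(A−1)/2 + P(P−1)/2` pair contributions, normalized to `[0, 1]`
(0 = not nested, 1 = every specialist's diet is a subset of some
generalist's).  Significance comes from Monte Carlo draws of the binary
**Ce null model**, where cell `(i, j)` is filled with probability
`(d_i/P + d_j/A)/2` — the average of the row and column fills.

**Complementary specialization (H2′).** The Shannon entropy `H2` of the
interaction-frequency distribution `p_ij = w_ij / Σw`, rescaled between
the marginal-constrained entropy extrema:

    H2′ = (H2_max − H2) / (H2_max − H2_min)

0 means species share partners in proportion to availability (redundancy),
1 means each species keeps its own partners (complementarity).
Significance uses the **Patefield null model** — uniform contingency
tables with both marginal vectors fixed.  H2′ needs weighted data; it is
reported `n/a` for presence/absence matrices.

**Modularity (M).** Newman–Girvan modularity
`M = Σ_s [ l_s/L − (d_s/2L)² ]` on the bipartite graph, maximized by
simulated annealing (single-node moves plus module merges and
random-bisection splits, geometric cooling, greedy polish, best of several
restarts).  Module composition is then tested against the classic
genus-level feeding associations (*Artibeus–Ficus*, *Carollia–Piper*,
*Sturnira–Solanum*) with G tests (Yates-corrected).

**Functional roles.** Normalized degree `k_r` (partners used / partners
available) and betweenness centrality `bc` (share of shortest paths
through the species), with top-quantile species flagged as *hubs* (`k_r`)
and *connectors* (`bc`), and side/frugivory-level comparisons (t,
Kruskal–Wallis).

**Robustness.** Cumulative random removals of one side; opposite-side
species whose partners are all gone count as secondary losses.  `R` is the
area under the survivor curve (1 = collapse only at the end, 0 = immediate
collapse).  Single-species jackknife gives `NODF_r = (NODF_reduced −
NODF_original)/NODF_original` and the secondarily lost fraction `SL_r`,
correlated against `k_r` and frugivory level (Spearman, Kruskal–Wallis).

**Synthetic data.** A generator of bat–fruit-like matrices with planted
genus modules, heavy-tailed species propensities, geometric count weights
and a configurable primary/secondary/occasional frugivory mix, so the
whole pipeline is testable without field data.  The package also ships the
published summary table of nine field bat–fruit networks for
cross-checking.

## Worked example

```bash
$ batfruitnet simulate --out demo --seed 4 --n-bats 7 --n-plants 12
WARN repaired isolated species with forced link Anoura_bat7 -- Solanum_plant7
...
wrote 7 x 12 network to demo

$ batfruitnet nestedness demo/matrix.tsv --nulls 1000 --seed 1
NODF = 0.4211 (rows 0.3635, cols 0.4394)
null mean 0.3623 +- 0.0891 (N=1000), P = 0.245

$ batfruitnet specialization demo/matrix.tsv --nulls 1000 --seed 1
H2' = 0.6690 (H2 2.7407 in [2.2953, 3.6409])
null mean 0.2292 +- 0.0305 (N=1000), P < 0.001

$ batfruitnet modularity demo/matrix.tsv --seed 1 --restarts 3
M = 0.3140, modules = 2
module 0: 2 bats, 7 plants
module 1: 5 bats, 5 plants

$ batfruitnet robustness demo/matrix.tsv --side animal --reps 100 --seed 1
R (animal removals) = 0.6342 +- 0.1477 over 100 replicates
```

Reading this: the simulated 7×12 network is not significantly more nested
than its degree-proportional nulls (P = 0.245), but its interaction
frequencies are far more specialized than fixed-marginal chance
(H2′ = 0.67, P < 0.001); annealing finds two modules with modest
modularity; and after random bat removals just under two thirds of the
survivor-curve area is retained (R = 0.63), i.e. plants disappear slowly.

The full per-network pipeline (`batfruitnet run --matrix ... --meta ...
--out DIR --seed 1`) writes a one-row summary table (NODF, H2′, M, module
count, R for both sides, each with its null-model p-value), a species
roles table, jackknife impacts, and a manifest of every seed and replicate
count.  `batfruitnet summarize --field` prints the cross-network
mean/SD/min/max of the published nine-network table.

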