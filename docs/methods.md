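# Methods

## Search model

The engine is an Ant System over loci. A pheromone field τ (one positive
weight per SNP, initialized at τ₀) defines a selection distribution
P_k ∝ τ_k^α η_k with a flat prior η ≡ 1. Each iteration, `iAntCount` ants
draw sets of n distinct loci by probability-proportional sampling
*without replacement*; the implementation uses the exponential-race
formulation (order loci by E_k / p_k with i.i.d. standard exponentials
E_k), which is exactly equivalent to sequential sampling with
renormalization and vectorizes across ants. Updates are synchronous: all
ants of an iteration sample from the same distribution, evaporation
(1 − ρ) is applied once, and deposits 0.1 χ²(S_m) per member locus are
summed. Synchronous updating makes an iteration independent of ant order;
whether the original applied evaporation per ant or per iteration is not
recoverable, and the synchronous variant is the reproducible choice.

τ stays positive (evaporation never reaches zero, deposits are
nonnegative) and is bounded by τ₀ + iAntCount · 0.1 · χ²_max / ρ, a
geometric-series bound asserted in the tests.

The two-stage search runs the colony twice from a fresh field — set size
`largesetsize` for `iItCountLarge` iterations, then `smallsetsize` for
`iItCountSmall` — keeping each round's `iTopModel` best distinct sets by
raw χ². Restarting between rounds keeps the two searches' sensitivities
(strong vs weak signals) independent. Stage 2 scores every
`iEpiModel`-sized subset of the suspected sets and of the reduced
top-pheromone locus set, reports `EI_all = {p < pvalue}` sorted by
ascending p (ties broken lexicographically by locus indices for
determinism), and prunes it to `EI_m`.

### Combining the rounds' pheromone rankings

The reduced locus set is "determined by pheromone levels", but the two
rounds' pheromone fields live on very different scales: a random size-6
set over N = 4000 samples already scores χ² ≈ 500 (most of its ≤ 3⁶ cells
are occupied), so the large round deposits enormous, weakly informative
amounts, while the small round's baseline is χ² ≈ 25 and its deposits
track per-locus association closely. Direct magnitude combinations fail
here: on a 5000-SNP panel with 20 planted interactions, min-max
normalizing each field and summing put only 10 of the 40 causal loci in
the combined top 200, although 27 of them led the small round's own
ranking (z-score and rank-sum combinations were measured at 17 and 11).
The package therefore merges the two rounds' *own* rankings by
alternating picks until `iTopLoci` distinct loci are collected — both
rounds contribute their most reinforced loci on equal footing and no
cross-round magnitude comparison is ever made.

## Scoring

Association of a locus set is the Pearson χ² of its observed
genotype-combination × status table. Unobserved combinations are dropped;
degrees of freedom are K − 1 for K observed rows (so ≤ 8 for pairs,
≤ 26 for triples), which keeps p-values defined for the large stage-1
sets where most of the 3ⁿ cells are empty. Stage-1 ranking uses the raw
statistic, so the df convention affects only reported p-values. No
continuity correction and no minimum-expected-count filter are applied —
the plain test's mild conservatism on discrete data is part of the
method's published calibration. Degenerate tables (an empty status
column, or a single observed row) score χ² = 0, p = 1.

All heavy paths funnel into one vectorized kernel over batched (K × 2)
count arrays: the exhaustive pair scan tallies counts with 18 one-hot
matrix products per block (BLAS does the O(L²N) work; float32 products
are exact for counts < 2²⁴ and rounded back to integers), and the ant-set
scorer tallies base-3 combination codes with `bincount`. Because both
routes feed identical integer counts to the identical kernel, stage 2
restricted to a panel-covering locus set reproduces the exhaustive scan
*bit for bit* — an equivalence the tests assert exactly. The scan refuses
combination counts beyond 2 × 10⁷ and reports the offending count.

## False-positive minimization

`EI_all` is processed in ascending-p order; an interaction is kept iff it
shares no locus with anything kept before it (with the replace-if-better
branch retained for externally ordered input). The published procedure
leaves the iteration order and the multiple-overlap rule open;
ascending-p processing makes the outcome deterministic, guarantees
`EI_m` is locus-disjoint, and always retains the single best
interaction.

## Disease models and calibration

Two-locus penetrance is defined on the odds scale,
odds(g₁, g₂) = γ(1+θ)^e with e = g₁+g₂ (additive), g₁·g₂
(multiplicative) or 1[g₁≥1 ∧ g₂≥1] (threshold), and penetrance
odds/(1+odds). A model is specified by the marginal effect size λ per
causal locus: θ is solved (bracketed Brent, relative tolerance ≤ 10⁻¹⁰)
so that the **marginal per-allele (allelic) odds ratio** of the
single-locus disease table under HWE equals 1 + λ, and γ is solved so the
population prevalence matches its target (default 0.01; power under
balanced case-control ascertainment is nearly invariant to it — measured
noncentrality changes by < 3% between prevalence 0.01 and 0.2). The
per-allele odds ratio is the standard single-marker effect measure and is
exact for the reference single-locus model odds = γ(1+λ)^g. Two
alternative readings were evaluated and rejected: a marginal
*heterozygote* odds ratio of 1 + λ leaves the threshold model essentially
undetectable (joint χ² noncentrality 13.5 at MAF 0.5, λ = 0.2,
N = 4000 — detection power 0.002 at the Bonferroni level of a 1000-SNP
scan), and matching the marginal single-locus noncentrality to the
multiplicative reference gives 0.28 there; the allelic definition yields
0.86, the strong-signal behaviour these benchmark models are known for.
A structural consequence worth knowing: at MAF 0.5 and λ = 0.2 the
*multiplicative* model's joint noncentrality is ≈ 38 under every marginal
calibration examined, capping any search method's power near 0.32 at
α = 0.01/C(1000, 2) — that regime is not strong-signal, and the test
suite documents the resulting shortfall rather than inflating λ.

Markers in LD: a causal locus with allele frequency f is observed through
a marker with the same frequency and haplotype frequency
h₁₁ = f² + √r² f(1−f), so the squared allelic correlation is exactly r².
Marker alleles are drawn per chromosome given the causal alleles; at
r² = 1 the marker *is* the causal locus and the causal pair is in the
panel, below 1 only the tags are.

## Panel generation

Background SNPs are independent, in HWE, MAF ~ U[0.1, 0.5] — the null
design of the false-positive study. Case-control panels with planted
interactions fix the status vector (the requested quotas) and draw each
interaction's two-locus genotypes from the exact conditional
distributions P(g₁,g₂ | case) ∝ HWE · penetrance and
P(g₁,g₂ | control) ∝ HWE · (1 − penetrance); this is mathematically
identical to rejection-sampling population draws against quotas, in
constant time. Multi-interaction panels inject every interaction
independently against the same status vector at disjoint random
positions — the "interactions added to the data" design of the
large-scale study — so each planted pair carries its full association
signal; partitioning individuals across interactions instead would
divide every signal's noncentrality by the number of interactions and
make all of them undetectable. A side effect faithful to that design:
conditioning all causal pairs on one status vector correlates causal
loci *across* interactions, so pairs of strong-marginal loci from
different interactions can out-score true pairs (additive-model pairs
have no epistatic excess at all); overlap pruning then sometimes prefers
such cross pairs. The simulated studies therefore probe exact-tuple
recovery under harder conditions than a single-interaction panel.

What the generator does not emulate: background LD (haplotype blocks),
missing genotypes, genotyping error, or population structure. Passing
tests demonstrate calibration and detection behaviour under clean HWE
panels, not robustness to those real-data features.

## Parameters

| name | meaning | default |
|---|---|---|
| iAntCount | ants per iteration | 1000 |
| iItCountLarge / iItCountSmall | iterations of the large/small round | 150 / 300 |
| α | pheromone exponent | 1 |
| ρ | evaporation rate per iteration | 0.05 |
| τ₀ | initial pheromone | 100 |
| largesetsize / smallsetsize | stage-1 set sizes | 6 / 3 (6 / 4 for triples) |
| iTopModel | suspected sets kept per round | 1000 |
| iTopLoci | reduced top-pheromone set size | 200 |
| iEpiModel | interaction order | 2 |
| pvalue | reporting threshold | 0.01 |

Defaults are the medium-panel settings of the published simulation
studies; `iTopModel`/`iTopLoci` are declared package defaults chosen so
stage 2 tests ≪ C(L, 2) combinations. `suggest_parameters(L)` applies the
published scaling rules — iItCountSmall = ⌈0.1 L⌉ with iItCountLarge half
of it, 500–5000 ants growing with L, ρ ∈ [0.01, 0.1] shrinking with L —
and reproduces the reference L = 2000 setting exactly.

## Study scales used by the test suite

The calibration studies are run at desk scale: the null false-positive
study at its full published size (L = 2000, 2000 + 2000 samples, all
1,999,000 pairs); the search-level false-positive study at L = 1000 with
`suggest_parameters(1000)`; the power study at L = 1000, 10 replicates
per model (MAF 0.5, r² = 1); the large-scale study at L = 5000 with 20
planted interactions, reusing the reference parameter values as the
original large-scale run did, at reporting threshold 10⁻⁴. The
single-stage baseline ("generic ACO") runs the same engine at the
interaction order for twice the two-stage search's total iterations and
reports every distinct sampled set below the threshold. With only 10
replicates the power estimates carry binomial noise of ±0.13; the
200-replicate check in the unit suite pins the threshold-regime
detection probability at 0.85 ± 0.03.

## Determinism

One seedable `numpy.random.Generator` threads through every stochastic
operation; identical seeds give identical panels, searches and reports.
Ties anywhere (χ² ranking, p-value sorting, pheromone ranking) break on
locus order.
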