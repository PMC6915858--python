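# Methods

## Branching process

A gene family starts from one root gene at the oldest event. Event i
(i = 1..m, oldest first) replaces each extant gene with r_i ∈ {2, 3} progeny;
exactly j of them survive to the next event (or to the present) with
probability p_j^(i), j ≥ 1 — extinction of a whole lineage is conditioned
away, which matches what a self-synteny dataset can see. The per-event rates
are written u = p_2^(1), u′ = p_3^(1), v, v′, w, w′ for later events. By
default triplings obey the squared constraint u′ = u² (toggleable where
profiles are computed; estimation from pair counts requires it for
identifiability).

Expected quantities per root all derive from three per-event moments of the
survivor count c: E[C(c,2)] = p₂ + 3p₃ (new same-event pairs per gene),
E[c] = 1 + p₂ + 2p₃ (growth), and E[C(c,3)] = p₃ (new same-event triples).
The closed-form triplet profiles for two and three events are polynomial in
these moments and reproduce the published per-model tables term by term.

Two independent computation routes exist and are cross-checked in tests:

* **Exhaustive enumeration** (`expected_triplet_profile_bruteforce`): all
  survivor-count genealogy shapes are enumerated once per schedule; each
  shape carries exact leaf/pair/triple counts and the exponents of every
  survival probability, so expectations at any parameter values are one
  weighted sum. Aggregating shapes with identical signatures keeps
  three-event tables at ~10³ entries. Capped at 4 events (the cap is a
  parameter); closed forms are never extrapolated past 3 events.
* **Closed forms** (`expected_triplet_profile_closed`), two or three events
  only.

A third, fully explicit route (`enumerate_genealogies` + `classify_triplet`
over all leaf triples) is kept as the oracle for small schedules.

Triplet types are size-3 multisets of event indices; there are
m(m+1)(m+2)/6 of them. A type is realizable only if its oldest event index
appears at least twice (ultrametric genealogy); unrealizable types have
*exactly* zero expectation in every route.

## Survival-parameter estimation

The source text asks for "maximum likelihood values of u and v" without a
procedure. Default here: moment matching — bounded least squares (trust
region, bounds [0,1], with the golden-ratio upper bound p₂ ≤ (√5−1)/2 when
p₃ = p₂²) on the relative errors of G·(expected pair counts per event) and
G·(expected genes) against the observations, with G profiled out in closed
form. Exact expectations invert to machine precision; the residual is
reported and logged when large (a wrong candidate model typically cannot
match the data, which is informative, not an error). A likelihood
alternative (`method="multinomial"`) maximizes a multinomial likelihood over
the pair-event categories augmented with the gene count — without the
augmentation the category proportions leave an m−1-dimensional ridge for m
rates.

Genes whose paralogs were all lost are invisible in a self-synteny pair
list, so the pipeline matches the expected count of *observable* genes
(E[m·1{m≥2}] = Π(1+p₂+2p₃) − Πp₁) against the distinct genes in the pair
list (`observable_only=True`); the plain contract matches E[m] and suits
simulation truth data.

## Mixture and transition points

The similarity distribution is fitted by a univariate Gaussian-mixture EM
written in-package (fixed-means support is needed when older components are
pinned, e.g. at 71% and 79.5% for a three-event analysis). Initialization is
deterministic: quantile means, pooled sd, equal proportions. Component sds
are floored at 0.01 percentage points; globally constant data is an error.
The log-likelihood path is recorded and is non-decreasing.

The transition point H between adjacent components maximizes the product of
the lower component's full normal density over similarities ≤ h and the
upper component's over similarities > h, for h between the two means. That
objective is piecewise constant between order statistics, so the search is
exact: prefix sums of log-density gaps over the sorted data, with the
midpoint of the maximizing data interval returned (plateau rule). A numeric
grid (`grid_step`) exists for comparison. On the symmetric 4-point example
{69, 71, 89, 91} with equal sds this yields exactly the mean midpoint 80.
Similarities equal to a cutoff classify to the older event. All percentages
are on the 0–100 scale throughout.

## Triangles, observed profile, covariance

Triples are the triangles of the graph whose edges are the filtered pairs
(kept when low_exclusion < similarity ≤ high_exclusion). The observed
profile classifies each triangle's three similarities by the cutoffs and
counts type multisets.

The trivariate covariance for a triplet type is assembled from per-event
variances (over every classified similarity occurring in triangles,
multiplicity-weighted) and within-triplet same-event covariances (over all
unordered same-event similarity pairs inside each triangle; a triangle with
three same-event similarities contributes its 3 pairs — `all_pairs=False`
keeps only the first, the unbiased alternative). The source text's
description of this estimator is garbled; the within-triplet reading adopted
here is the one consistent with "covar(t1,t2) = 0", which is imposed
exactly (Markov property: divergences at different events are conditionally
independent). Non-PSD assemblies are repaired by shrinking within-event
covariances by 0.9 per step (logged); events with fewer than two classified
similarities fall back to the mixture sd with zero covariance (logged).

## Predicted profiles and ranking

For each underlying type Δ the trivariate normal with component means and
the covariance above is integrated over every ordered box of the cutoff
partition (the 2³ octants for two events, 3³ boxes for three); ordered
patterns collapse into category multisets. Diagonal covariances use the
exact univariate factorization; otherwise scipy's quasi-Monte-Carlo
rectangle integrator runs with abseps 1e-10, maxpts 2·10⁶ and a fixed
generator seed, making results deterministic and conservation of total mass
good to ~1e-9. The predicted profile is Σ_Δ W_M(Δ)·mass_Δ(category),
rescaled so every profile (underlying, predicted) totals the observed
triangle count.

"Closest fit" is not defined in the source text. Ranking uses
Σ (O−E)²/max(E, 0.5) — scale-aware and finite when a model predicts zero
where triangles were observed (exactly the signal that separates doubling
from tripling) — with L1 distance reported alongside and breaking ties. The
full table is always emitted.

## Synthetic data

`simulate_history` draws G independent root genealogies; every extant pair
is labelled by its last-common-ancestor event and `emit_similarities` draws
its similarity from that event's normal component, redrawn (cap 100, then
clamped, logged) into (0, 100]. Defaults are the conditions exercised
throughout: two events, components at 71% (sd 4) and 90% (sd 3), rates
u = 0.3, v = 0.4, G = 20000 — component placement follows the well-studied
two-peak self-comparison distributions of flowering-plant genomes, and G is
of the order of an angiosperm gene-family count. Optional contaminants
(similarity in (98, 100]) emulate recent non-polyploidy duplicates removed
by the high exclusion; a uniform background-pair rate is also available.

What the generator does *not* emulate: synteny-block geometry and block-wise
correlation of similarities, tandem arrays, Ks saturation, and dependence
between the survival draws of neighboring genes. A green end-to-end test
therefore establishes that the statistical machinery recovers the generating
model under the stated mixture-of-normals world, not that any real genome's
SynMap export satisfies those assumptions.

## Numerical choices

* Closed vs brute-force equality asserted at 1e-10 absolute per root.
* Genealogy weights sum to 1 at 1e-12; octant masses per Δ to 1 ± 1e-6.
* EM: tol 1e-8 per point on mean log-likelihood, max 500 iterations,
  non-convergence warns and returns the best fit.
* Transition-point ties (within 1e-12 of the max) merge into one plateau.
* least_squares xtol/ftol/gtol 1e-14 with three starts; boundary estimates
  (a rate pinned at 0 with zero observed pairs) warn.

## Known limitations

* Candidate models share the event count m with the mixture; model selection
  across different m (AIC/BIC) is out of scope.
* Four-event analyses run through the brute-force enumerator only and get
  slow for tripling-heavy schedules.
* The pipeline's per-model survival fits use cutoff-classified pair counts;
  misclassification near H biases rates slightly toward each other (the
  predicted-profile integration compensates at the profile level).
* No plotting; diagnostics are the TSV/JSON reports and the run log.
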