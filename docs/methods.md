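# Methods

This note documents the statistical models implemented in `finsurvey`,
the assumptions they make, the defaults and why, and the places where a
design choice was genuinely open.

## The sampling design and its simulator

The survey design the package analyzes is hierarchical: repeated
sampling events; a fixed number of randomly chosen vendors per event;
two bags of fin trimmings bought from each vendor; ten trimmings
analyzed per bag. The simulator (`finsurvey.simulate`) reproduces this
structure exactly, with defaults set to the surveyed conditions:

| parameter | default | meaning |
|---|---|---|
| `n_events` | 10 | sampling events |
| `vendors_per_event` | 10 | vendors visited per event |
| `bags_per_vendor` | 2 | bags per vendor visit |
| `trimmings_per_bag` | 10 | trimmings analyzed per bag |
| `fail_rate` | 0.137 | per-trimming amplification failure probability |
| `genus_only_rate` | 0.125 | demotion of a species-level call to genus |
| `vendor_heterogeneity` (θ) | 25 | Dirichlet concentration multiplier |
| `species_pool` | packaged survey shares | 43-category skewed pool (~36% blue shark) |

The default pool proportions are the species/complex shares of the
packaged market table, so simulated surveys carry the same strong skew
as the real market. The genus-only rate of 0.125 matches the fraction
of identified trimmings that the survey table reports only at
genus/family level (214 of 1,706).

Vendor heterogeneity is modeled by drawing each vendor's proportion
vector from Dirichlet(θ·π). The survey design itself implies clustered
sampling (two bags from the same vendor are more alike than two random
bags), but no heterogeneity model is specified by the design, so θ is
exposed: θ → ∞ recovers homogeneous multinomial sampling, and the
default θ = 25 produces moderate between-vendor overdispersion (about
2–4× binomial variance for a common species at bag size 10) — the level
a surveyor would call realistic for vendors supplied by overlapping but
not identical processors. Bags inherit their vendor's proportions with
no extra bag-level dispersion, the simplest structure consistent with
the design. Failures and genus demotions are independent per-trimming
Bernoulli events layered on top.

What the simulator does *not* emulate: temporal trends across events,
vendor price/size structure, sequence-quality gradients, or any
correlation between a species' identity and its failure probability.
Tests passing on simulated data therefore validate the estimators under
the design's sampling structure, not under every failure mode of real
market data.

All randomness descends from one integer seed through deterministic
per-(event, vendor) substreams; identical configs give byte-identical
ledgers.

## Mini-barcode assignment

Distances are ungapped mismatch counts. Equal-length sequences use the
Hamming distance with N matching anything; a shorter fragment is slid
along a longer one and the minimum over offsets taken. Indels are out
of scope because the mini-barcode fragments are fixed-length amplicons;
an edit-distance variant would change only queries that are already
unidentifiable under this rule.

A species-level call requires both: (i) reference set A's
minimum-distance candidates, after collapsing known complexes, form a
single category within 2 mismatches, and (ii) reference set B's
candidates collapse to the same single category — with no distance
threshold applied to set B, since the rule's second criterion is about
agreement, not proximity. Queries failing both criteria fall back to
genus when all candidate species share one genus, to family when they
share only a family (reference records carry family metadata; the
family fallback exists because survey tables contain family-level
rows), and otherwise to unidentified — including equal-distance ties
spanning genera, the conservative choice. Queries with more than 20% N
bases are treated as failed; the threshold is a package convention,
exposed as `MAX_N_FRACTION`.

## Tabulation conventions

Percentages use the number of *identified* trimmings (species,
complex, genus and family ranks) as denominator, rounded half-up to two
decimals; rollup shares use one decimal. Both conventions are forced by
the printed values they reproduce (e.g. 616/1,706 = 36.11%, oceanic
1,222/1,706 = 71.6%). A sampling unit for incidence data is the
(event, vendor) pair — the two bags pooled; a per-bag option exists but
is not the default. Species complexes with mixed IUCN statuses
("DD/VU") satisfy a threat predicate if any member does; this
any-member rule reproduces the printed 22/53 = 41.5% threatened share.

Known inconsistencies in the transcribed source table, preserved rather
than reconciled: the Guangzhou counts sum to 1,707 while the stated
identified total (and the denominator every printed percentage actually
uses) is 1,706; one row (spot-tail shark) prints count 26 with a
percentage corresponding to 27; and the stated 86.3% identification
success differs from 1,706/2,000 = 85.3%. The fixture loader therefore
builds the table with the printed denominator, while count tables built
from ledgers always compute their denominator from the data.

## Richness estimators

All twelve models are driven by the frequency counts f_k (abundance)
or Q_k (incidence). Point estimators follow the standard forms:
Chao-type (classic, bias-corrected, and improved using f3/f4 with the
(n−3)/(4n) correction and f4 → 1 when zero), coverage-based ACE/ICE
with rare/infrequent cutoff k = 10 (exposed as a parameter), and the
homogeneous model S_obs/Ĉ with Good–Turing coverage Ĉ = 1 − f1/n. The
ACE-1/ICE-1 variants inflate the squared CV by
[1 + (1−Ĉ_rare)/Ĉ_rare · Σ i(i−1)f_i/(n_rare−1)] for highly
heterogeneous assemblages. For incidence data the CV carries the
T/(T−1) finite-unit factor; the number of units containing an
infrequent species is approximated by T, which is what frequency-count
input allows.

Variances use a generic delta method with the multinomial
frequency-count covariance cov(f_i, f_j) = f_i(δ_ij − f_i/Ŝ),
numerically differentiated — this reproduces the published analytic
Chao variances and extends uniformly to the coverage estimators. The
bootstrap alternative resamples from the *unseen-augmented* assemblage
(Ŝ categories at estimated shares): resampling only observed categories
understates the variance of the rare frequencies by severalfold. The
delta and bootstrap SEs agree within ~15% for the Chao estimators;
ACE's delta form omits part of the unseen-category uncertainty and can
differ from the augmented bootstrap by ~25–35%, which is why the
bootstrap is kept available as a switch. Confidence intervals use the
Chao (1987) log-transform on D = Ŝ − S_obs, so the lower bound cannot
fall below the observed richness; D = 0 collapses the interval to
S_obs.

Numeric reproduction of the published richness-estimate table is
deliberately not attempted: the exact input partition behind it (a
month-matched subset of the raw per-bag data) is not recoverable from
the printed category counts, under any rank-inclusion rule. The
estimators are instead validated by hand-computed oracles, an
independent reference implementation (vegan's `estimateR`, frozen
values), algebraic properties (Ŝ ≥ S_obs; bias-corrected ≤ classic when
f2 ≥ 1; reduction to S_obs when f1 = 0), and simulation consistency.

## Hill-number rarefaction and extrapolation

Interpolation is the exact expectation over hypergeometric subsamples:
the classic formula for q = 0, the expected plug-in entropy for q = 1,
and for q = 2 the closed form 1/(1/m + (1−1/m)·Σx(x−1)/(n(n−1))),
which is exact for every m and is also used beyond n. Extrapolation
for q = 0 rises geometrically to the Chao1/Chao2 asymptote
S_obs + f̂0; for q = 1 the log-diversity interpolates linearly (in
weight n/(n+m*)) between the observed plug-in entropy and an asymptotic
entropy estimator with a Good–Turing tail correction
(A = 2f2/((n−1)f1+2f2), tail term (1−A)^(1−n)·(−ln A − Σ(1−A)^r/r)).
The curve is continuous at m = n by construction. Binomial
coefficients are computed via log-gamma, safe to n ≈ 1e5.

The two non-q=0 asymptotes carry the small-sample bias corrections of
their estimators, so on an idealized uniform assemblage they converge
to the true S only within ~2% (order 1/x_i); q = 0 converges exactly.

Confidence bands follow the unseen-category bootstrap: the observed
assemblage is augmented with ⌈f̂0⌉ unseen categories at shares
implied by the estimated sample coverage, n individuals (or T units
via per-category binomials) are resampled, and the band is the normal
approximation estimate ± z·SD per knot (a percentile option exists).
Defaults mirror survey practice — 10,000 bootstrap replicates, 0.95
confidence, endpoints of 10,000 samples / 500 sampling units, 40
evenly spaced knots including the observed size — while tests and the
acceptance script run scaled replicates (50 assemblages × 200
bootstraps), sizes chosen to keep the whole suite interactive on one
CPU.

## Composition model

Per-bag counts are modeled as y[b,c] ~ Poisson(λ_c·ε_b) with bag
effects ε_b (ε_1 ≡ 1 for identifiability) — the Poisson trick for a
multinomial with random bag totals. "Non-informative" is fixed as
λ_c ~ Gamma(0.01, 0.01) and ε_b ~ Gamma(1, 1); every full conditional
is then conjugate Gamma, so the model is fitted by plain Gibbs sampling
with no external MCMC engine. The posterior of interest is
π_c = λ_c/Σλ, whose draws sum to 1 exactly. In the single-bag case
the π posterior is exactly Dirichlet(a + y), which is the closed-form
oracle used in the tests; whether the original survey model carried
bag effects beyond totals is not recoverable from the survey write-up,
so the ε_b formulation is this package's own declared structure,
validated against that oracle and by parameter recovery.

Defaults: 3 chains × 20,000 iterations, 50% burn-in, thinning 5 (all
exposed); the examples and acceptance script use 6,000–8,000
iterations, which this conjugate sampler mixes through easily (R̂ ≈ 1.00
at survey scale). Each category's λ is drawn from its own random
substream keyed by (seed, chain, category label), so permuting category
order permutes the posterior exactly. Convergence is declared by split
Gelman–Rubin R̂ < 1.1 on all λ parameters across ≥ 2 chains (the
implementation is cross-checked against ArviZ in the tests). DIC is
the Spiegelhalter form D̄ + p_D with p_D = D̄ − D(θ̄).

Binning: species/complex categories with strictly more than `cutoff`
(default 20) trimmings are modeled individually; rarer taxa and
genus-/family-rank rows join their genus bin (*Carcharhinus*,
*Callorhinchus*) or "Other"; unidentified trimmings form their own
category and are never redistributed — the conservative reading of the
survey's treatment. `cutoff_search` walks the cutoff down the grid
20 → 15 → 10 → 5 → 1, keeping the last fit whose chains all converged.

## Degenerate inputs and numerical conventions

Zero sample coverage (all singletons) flags the coverage-based
estimate as undefined (NaN with a warning) rather than returning
infinity. f2 = 0 switches Chao estimators to the bias-corrected
fallback. A single-category assemblage yields flat diversity curves at
1 with zero-width bands. Ties in reference matching enlarge candidate
sets deterministically; assignment is invariant to reference order and
query case. Percent rounding is half-up (spreadsheet convention), not
banker's rounding, because that is what published tables use.

## Known limitations

- Reference-set matching is local and ungapped; it cannot model
  chimeric or indel-bearing queries.
- The ICE family approximates T_infreq by T (frequency-count input
  does not carry which units hold infrequent species).
- The q = 1 extrapolation is an entropy mixture, not an exact
  expectation; it is continuous and monotone but its asymptote is the
  entropy estimator's, with that estimator's bias.
- The composition model treats bags as exchangeable given their vendor
  totals; vendor-level correlation beyond bag totals is not modeled.
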