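# Methods

This note documents the models and procedures `gestnet` implements, the
parameters that matter, what the synthetic-data generator does and does
not emulate, and the numerical choices made where the design was open.

## Study design being modelled

The package targets focal-animal sampling of a fission–fusion community of
adult great apes: 18-minute focal follows containing nine instantaneous
scans at 2-minute intervals (party membership within a ~35 m spread,
identities within 10 m, the nearest neighbour with distance and a mutual
bodily-orientation flag, activity states of focal and neighbour), plus
continuous video recording of intentional gestures with signaller,
recipient, gesture type, sensory modality (visual, tactile, auditory
short-range, auditory long-range), pant-hoot accompaniment and the
recipient's response. The canonical population size is 12 adults (six per
sex). All tabular files use 999 as the numeric missing-value sentinel.

## Repertoires and overlap

An individual's repertoire is the set of gesture types it produced as
signaller toward adult recipients at least once; gestures toward
non-adults are excluded. An optional intentionality filter retains only
gesture types whose pooled fraction of occurrences meeting the
intentionality criteria exceeds 0.60 — read strictly (> 0.60), with a
switch for ≥; types with zero observations are dropped and logged.

Dyadic overlap uses three statistics:

- **Cohen's κ** on the two presence/absence vectors over the catalog
  (2×2 contingency table; κ = (p_o − p_e)/(1 − p_e)). κ is undefined when
  p_e = 1 (e.g. both repertoires empty, or both spanning the entire
  universe); undefined values propagate as missing and are excluded from
  network ties and means, with a log record.
- **Homogeneous repertoire size** |A ∩ B| and **heterogeneous repertoire
  size** |A \ B| + |B \ A|; the latter is symmetric by construction.
- **Sequence-level homogeneity**: each distinct gesture type in a sequence
  is homogeneous iff present in both the signaller's and the recipient's
  repertoire. Sequences whose recipient has no observed repertoire cannot
  be classified and are flagged rather than guessed.

κ universe: per-modality computations use that modality's catalog only;
the all-gestures computation uses the full catalog. This keeps each
modality's κ independent of the other modalities' catalog sizes. The
alternative (full catalog throughout) would deflate per-modality κ for
small catalogs.

## Sequences and pant-hoot recipients

A gesture sequence is a run of gestures by one signaller toward one
recipient in one context with consecutive gaps ≤ 30 s. Context is an
explicit categorical column in the gesture file; if the column is absent,
context is ignored (logged). Sequence ids are assigned deterministically
after sorting by (signaller, follow, time, event id), so grouping is
idempotent and order-invariant.

Sequences accompanied by pant-hoots are reassigned for observation-level
analyses: visual-only sequences to the most dominant party member
(excluding the signaller), sequences containing auditory gestures to the
focal's nearest neighbour (unusable, and flagged, if no neighbour was
recorded). Dominance is operationalized as pant-grunt in-degree
(descending), tie-broken by pant-grunt out-degree and then id — pant-grunts
are directed up the hierarchy, so receiving many is a dominance signal.
This operationalization is an inference; the field convention reports the
pant-grunt rates but no explicit ranking rule.

## Bonding rates

Every scan contributes one 2-minute interval, so the dyad's i→j rate of a
behaviour is 60 · n_behaviour / n_party minutes per hour co-present in a
party, where n_party counts scans with i focal and j in i's party. This is
the natural estimator given instantaneous sampling; it is bounded by
[0, 60] and missing when n_party = 0. Rates are directed because they are
estimated from i's follows only; i→j and j→i are kept separate.

Behaviour conditions: proximity = partner is the nearest neighbour within
2 m; joint feed/rest/travel and the two attention states add their extra
condition on top of proximity (hence are nested under it, an invariant the
tests assert); grooming rates require the matching focal grooming activity
code with the partner as nearest neighbour but no distance condition,
since grooming implies contact. The "within 2 m and nearest neighbour"
conjunction is applied literally for the nested behaviours.

The scan-independence quality check compares per-dyad association counts
at scan positions (1, 2) and (1, 9) with Wilcoxon signed-rank tests
(zero differences discarded; reported statistic is min(T⁺, T⁻)). For
N ≤ 14 non-zero differences the two-sided p is computed by exhaustive
enumeration over sign assignments with mid-ranks (exact even under ties);
larger N uses the normal approximation. A degenerate comparison (all
differences zero) is reported as not applicable rather than a p-value.

## Networks and centrality

Networks are dense labelled matrices over the focal subjects with an
undefined diagonal; κ networks are undirected (symmetry is asserted on
construction), rate networks directed. Normalized degree centrality is the
row mean (outdegree), column mean (indegree) or, for undirected networks,
the single n-degree. Missing ties are excluded from the mean — a node's
centrality averages its defined ties only — with a `zero_fill` switch to
mimic tools that store absent ties as zeros. Nodes with no defined ties
get a missing centrality, logged.

## Permutation inference

**MRQAP double semi-partialling.** Variables are the vectorized
off-diagonal dyads, z-scored, so coefficients are standardized betas;
point estimates are OLS. For each predictor X_k: residualize X_k on the
remaining predictors, embed the residuals back into matrix form, draw
node permutations (rows and columns jointly — the QAP null), refit the
model with the permuted residual in X_k's place, and report the two-tailed
add-one p = (#{|β*| ≥ |β̂|} + 1)/(n_perm + 1). Permuting residuals rather
than the raw predictor is what makes the test robust to network
autocorrelation and skew. Because the coefficient on the residualized
predictor equals the full-model coefficient (Frisch–Waugh), the permuted
betas are on the observed beta's scale without rescaling. Dyads with any
missing value are dropped listwise, and again after each permutation maps
residuals onto missing cells. Defaults: 2000 permutations for MRQAP,
10 000 for node-level regression (which permutes the outcome vector across
nodes). Both are bit-reproducible given a seed. Near-duplicate predictors
(|r| > 0.9999) raise an error naming the pair.

The add-one convention keeps p in (0, 1] and makes the null size exact on
the permutation grid: at 199 permutations, rejecting at p ≤ 0.05 has size
exactly 10/200.

## Mixed models

Binary responses use a binomial-logit random-intercept model with focal
identity as the grouping factor. The marginal likelihood integrates the
1-D random intercept per group with 25-point Gauss–Hermite quadrature and
is maximized with L-BFGS-B (log-s.d. parametrization bounded in [−6, 3],
with a Nelder–Mead polish if line search stalls); standard errors come
from the numerical Hessian at the optimum and p-values from the Wald
normal approximation. Coefficients beyond ±15 on the logit scale trigger a
quasi-separation diagnostic. Continuous responses use statsmodels
`MixedLM` with full maximum likelihood — the family for continuous
responses is this package's documented assumption (gaussian identity).
Random slopes are deliberately not implemented. Non-convergence is
reported on the result object, never silently.

## Synthetic-data generator

The generator's defaults are the study conditions: 12 adults (six per
sex), catalog sizes visual 30 / tactile 12 / auditory short 8 / auditory
long 10, nine 2-minute scans per follow, and 120 follows at 4.5 gesture
sequences per follow, which yields roughly 500 sequences — the volume a
field season of this design produces.

**Repertoires.** Per modality, the target repertoire size is
`repertoire_fraction` (default 0.55) of the catalog; a group-wide core is
`overlap_core` (default 0.4) of that repertoire size, and the remainder is
individual-specific, with sizes jittered by `dyad_overlap_sd` (default 2
types). The core is defined as a fraction of the repertoire, not of the
catalog, so `overlap_core = 1` yields identical but non-constant
repertoires (κ = 1 exactly); a full-catalog core would make κ undefined.
Individual-specific types are partitioned disjointly from the non-core
pool when it is large enough (so `overlap_core = 0` can give fully
disjoint repertoires) and sampled independently otherwise; the expected
shared-type count core + (R−core)²/(S−core) is increasing in the core
size in either regime. At the defaults the mean pairwise κ lands near
0.22 and median repertoire size near 34 of 60 types — values a field
researcher would recognize as realistic for this design.

**Follows.** Fission–fusion is modelled as per-follow party draws with
dyad-specific inclusion probabilities (base 0.55 plus symmetric noise);
the focal rotates through the population. Within a scan, each party member
is within 10 m with probability 0.75; the nearest neighbour is drawn from
the 10 m set, and is within 2 m with probability
clip(0.25 + bonding_effect · κ̃, 0.02, 0.95), where κ̃ is the dyad's
standardized κ. `bonding_effect = 0.10` (the default) produces a realized
standardized dyadic effect of ≈ 0.5 between the κ network and the
proximity-rate network; `bonding_effect = 0` is an exact null. Activities
are drawn from a fixed categorical distribution with reciprocal matching
(e.g. focal `groom_give` pairs with neighbour `groom_receive`) when the
pair is within 2 m.

**Gestures.** Sequences per follow are Poisson(4.5); lengths 1–3 with
probabilities 0.65/0.25/0.10; the recipient is the scan's nearest
neighbour when present; gesture types are sampled uniformly from the
signaller's repertoire. Responses implement the planted homogeneity rule:
a homogeneous gesture (present in the recipient's repertoire) is responded
to with probability 0.60 and the response is emotional with probability
`emotional_response_prob_homog` (default 0.60); a heterogeneous gesture is
responded to with probability 0.45 and the response is goal-directed with
probability `goal_response_prob_heterog` (default 0.75).

**Randomness.** One root seed; the population and every follow use
sub-streams derived deterministically from it, so outputs are
byte-identical across runs.

**What the generator does not emulate.** Real ranging and ecology,
oestrous-cycle dynamics (status is static), within-follow party turnover
(parties are fixed per follow, so the party-level scan-independence check
is degenerate on synthetic data by construction), observation error in
identities or distances, and repertoire change over time. Passing tests on
synthetic data therefore demonstrate that the estimators and tests recover
planted structure under the sampling design — not that any particular
field dataset satisfies the generator's assumptions.

## Problem sizes used in the test suite

The statistical acceptance checks run at sizes chosen to make Monte-Carlo
error small relative to the tolerance while keeping the suite quick on a
single core: MRQAP null calibration uses 500 replicates of independent
12-node matrices at 199 permutations; power uses 200 full generator
replicates at the default conditions; GLMM recovery uses 200 replicates of
12 groups × 50 observations. The unit fixtures use 6–8 individuals and a
few dozen follows.

## Known limitations

- MRQAP variants that permute the outcome or the raw predictor matrices
  are not provided; double semi-partialling is the only tested procedure.
- The binomial GLMM supports a single random intercept (focal identity),
  matching the target analyses; crossed or nested random effects are out
  of scope.
- κ-undefined dyads are excluded rather than imputed; with very sparse
  data whole modalities can drop out of the networks.
- The normalized-degree convention divides by the number of *defined*
  ties; tools that zero-fill missing ties will differ unless `zero_fill`
  is set.
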