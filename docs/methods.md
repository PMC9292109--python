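# Methods

## The causal model

The package ships a directed acyclic graph over 17 variables describing how
a non-progressive brain injury degrades gross motor function in children
with spastic cerebral palsy. Four nodes are latent: the injury itself
(`Injury`), overall motor control (`MC`), and shared tendencies toward
contracture (`Contracture`) and long-bone torsion (`Torsion`). The 13
observed nodes are the measures a routine clinical gait analysis produces:
age; selective motor control (SCALE, 0–10); dynamic motor control
(Walk-DMC, scaled to mean 100/SD 10 in typically developing children);
composite strength (0–5) and spasticity (0–5) scales; four sagittal joint
contractures in degrees of deviation from typically developing end range
(ankle dorsiflexion 21.3°, knee extension 4° recurvatum, popliteal 25.6°,
hip extension 0°); femoral anteversion and tibial torsion in degrees of
deviation from typical (26.9° and 16.0°, inward positive); the Gait
Deviation Index (GDI, mean 100/SD 10 in typically developing children); and
GMFM-66, the outcome.

Structure worth flagging because it drives the results:

* `Age → Strength` is deliberately absent: the strength composite is
  age-normalized at measurement, so the graph treats them as independent.
  This produces the model's only unconditional implied independence.
* Torsions have no direct edge into GMFM-66 — their influence is assumed
  fully mediated by gait pattern (GDI). This produces the two implied
  independencies `TibRot ⟂ GMFM | …GDI…` and `FemRot ⟂ GMFM | …GDI…`.
* Selective motor control affects strength only through the latent `MC`,
  not via a `SCALE → Strength` edge; the builtin follows the tabular model
  specification. Users can restore either edge in a YAML config (the loader
  accepts arbitrary DAGs).

## Assumptions

All analyses assume linearity with main effects only (no interactions or
splines — notably no growth-curve modelling of the age response), complete
cases (missing values are a hard error, never imputed), and acyclicity.
Latent confounding is represented by explicit latent nodes rather than
bidirected edges; instrument- or front-door-based identification is out of
scope, as is structure learning.

## Identification conventions

**Implied independencies** use the missing-edge basis: one statement per
non-adjacent pair of observed variables that admits an observed separating
set. The separator is made deterministic by starting from the candidate
pool restricted to ancestors of the pair (a subset of the pool separates
the pair iff this restriction does) and greedily deleting nodes in
lexicographic order while separation holds; the result is
inclusion-minimal. Pairs separable only by conditioning on a latent
variable yield no statement. On the builtin model this basis has exactly 11
statements. A full (exponential) enumeration of every implied independence
is available behind `enumerate_all_independencies` for small graphs.

**Total effects** use the generalized adjustment criterion: a set is valid
iff it contains no descendant of a node on a proper causal path from the
exposure and it d-separates exposure from outcome in the proper backdoor
graph (the graph with the exposure's edges onto causal-path nodes removed).
**Direct effects** are controlled direct effects under linearity,
identified by the single-door criterion: valid sets block every path other
than the direct edge and contain no descendant of the outcome. All minimal
valid observed sets are enumerated (subset enumeration over at most 16
candidates after removing forbidden nodes — ample for this model family);
the set used downstream is the smallest, ties broken lexicographically.
Non-identifiable requests raise an error rather than returning a best
effort.

Two d-separation routines exist on purpose: the production implementation
(reachability in the moralized ancestral subgraph, bitmask-based) and a
brute-force simple-path enumerator with per-path chain/fork/collider rules.
The second is a test oracle only; it refuses graphs beyond 2^16 simple
paths, which includes the full 66-edge builtin model — there the test suite
cross-checks against a third, independently developed implementation
(networkx's d-separation) instead.

## Estimation choices

* Standardization uses the sample SD (n−1). After z-scoring, variables
  whose raw coding has larger = more impaired (spasticity, inward torsion)
  are negated so that every coefficient reads "per SD of improvement";
  age is standardized but never flipped.
* Effect sizes are OLS coefficients on the standardized table: total
  effects adjust for the chosen minimal set; direct effects adjust for the
  outcome's other observed direct causes; bivariate effects adjust for
  nothing and exist to quantify the inflation a naive analysis reports
  (`bivariate − total` is emitted per exposure).
* 95% CIs are `β ± 1.96·SE` (normal quantile; at n≈300 the t correction is
  negligible and the reported intervals are generic large-sample CIs).
* Implied-independence tests use the Fisher z transform,
  `z = atanh(r)·√(n−k−3)`, two-sided, α = 0.05 by default, with no
  multiplicity correction — each statement is an individual claim of the
  model, and correcting would only make the plausibility bar lower.
* The predictive model is per-unit, not standardized: GMFM-66 is regressed
  on all 12 observed predictors with contractures re-expressed as
  nonnegative limitation degrees (negated raw deviations), so coefficients
  read "GMFM-66 points per degree/point/year". It deliberately includes
  the torsions even though they carry no direct causal edge — prediction
  may exploit any association.
* Cross-validation assigns folds by simple seeded random permutation
  (sizes differing by at most one, every subject predicted exactly once)
  and pools out-of-sample predictions: `r² = 1 − SSE/SST` with SST about
  the full-sample mean, MAE in GMFM-66 points. Standardization parameters
  are computed once on the full sample rather than within folds, matching
  the sequencing of the original analysis (transform first, model second);
  the per-unit predictive model refit in each fold does not otherwise leak
  across folds.

## The synthetic cohort generator

`SEMSpec` defines a linear-Gaussian structural equation system over any
`CausalGraph`: each node is `intercept + Σ coeff·parent + N(0, σ)`,
generated in topological order with one deterministic substream per node
from a single seed. Because the distribution is jointly Gaussian and
generated faithfully from the graph, every d-separation is an exact
conditional independence — making the simulator a ground-truth oracle for
the identification and estimation layers. Closed forms are available for
the implied mean/covariance (`(I−B)⁻¹` algebra), the raw and standardized
total effect (path-product sums), and the bivariate slope.

The default calibration emulates a gait-lab cohort at moderate severity
(GMFCS level II; `cohort_fixture` selects level I, II or III). The
coefficients of the equations feeding GMFM-66 are the published per-unit
predictive betas (sign-adjusted to raw conventions); coefficients upstream
— injury into motor control/strength/spasticity, neurological measures
into contractures, torsions and GDI — are fixed package constants chosen
once to give plausible confounding strength. Intercepts are then solved so
implied marginal means equal the published cohort table for the chosen
severity level, and noise SDs so implied marginal SDs match the published
SDs, with a floor of 0.15× the target SD where parent-transmitted variance
already exceeds the target. That floor binds for GMFM-66: the published
betas plus this latent structure transmit more variance than the published
7-point SD, so the simulated GMFM-66 SD is ≈10 points and simulated
cohorts are easier to predict (CV r² ≈ 0.99) than a real cohort. The
generator reproduces first and second moments only — no floor/ceiling
effects, ordinal granularity, severity-mixture bimodality, or non-Gaussian
tails — so passing tests demonstrate correctness of the machinery on
model-faithful data, not robustness to real-data pathologies.

## Problem sizes and tolerances

The test suite validates the two d-separation algorithms on all (x, y, z)
triples of 1,000 random DAGs of 3–8 nodes (≈480k queries); effect-size
recovery on 20 replicate cohorts of n = 20,000 against closed-form truths
at 3 Monte-Carlo SE; test calibration on 500 replicate cohorts at the
study's n = 300 (pooled rejection rate within 0.035–0.065 at α = 0.05);
simulator faithfulness at n = 100,000 (implied partial correlations below
0.02, implied vs sample SDs within 2%). Partial correlations match the
single-conditioner recursive formula to 1e-12; reports serialize floats at
6 significant digits and are byte-stable given seed and inputs (timestamp
aside).

## Known limitations

Linearity throughout; no ordinal treatment of the 0–5/0–10 scales;
complete-case only; the generator's latent-path coefficients are
calibration constants, not estimates, so simulated effect sizes do not
reproduce the published cohort's effect sizes (reproducing those requires
the real subject-level table, which triggers a dedicated test when present
at `data/study_cohort.csv`); adjustment-set enumeration is exponential and
capped at 16 candidate covariates, which suffices for models of this size
but not for much larger graphs.
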