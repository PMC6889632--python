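# Methods

This note records the statistical model, the algorithmic choices, and the
reasoning behind every default. Symbols: n specimens, x = log10 femur
length (FL, body-size proxy), y = log10 humerus length (HL), V an n×n
phylogenetic covariance, m trees in an ensemble.

## 1. Regression model

```
y = a + b x + e,    e ~ N(0, sigma^2 V)
```

fit by generalized least squares via Cholesky whitening: with V = L Lᵀ,
regress L⁻¹y on L⁻¹[1, x] by ordinary least squares. σ² is profiled out:
σ̂² = RSS_w / (n − p) where RSS_w is the whitened residual sum of squares
and p = 2. Standard errors come from σ̂² (Xᵀ V⁻¹ X)⁻¹; slope confidence
intervals use Student-t with n − 2 degrees of freedom.

The signal parameter (λ or α) is estimated by maximizing the restricted
likelihood (REML),

```
-2 logL_R = (n - p) log(2 pi sigma^2) + log|V| + log|X' V^-1 X| + (n - p)
```

with plain ML available as an option. **REML is the default** because the
signal estimate enters the covariance that the slope's standard error is
computed under; ML's downward-biased variance estimates propagate into
overconfident slope intervals, and the bias is material at the ensemble
sizes used here. The implementation was verified to agree with an
independent GLS implementation in R (`nlme::gls` with a Pagel correlation
and fixed tip-depth variance weights) to 8+ digits on λ, coefficients,
standard errors and the REML log-likelihood.

### Covariance families

- **Brownian motion (BM).** `V[i,j]` = root-to-MRCA path length
  (diagonal = root-to-tip depth). Defined on non-ultrametric trees.
- **Pagel's λ.** Off-diagonal entries of the BM matrix multiplied by
  λ ∈ [0, 1]; diagonal unchanged. λ = 0 is a star phylogeny (OLS up to
  tip-depth weights), λ = 1 pure BM. Note this transform is applied to the
  *covariance* matrix, not a correlation matrix; implementations that
  normalize to correlation scale differ on non-ultrametric trees unless
  tip-depth variance weights are added.
- **Ornstein–Uhlenbeck (OU), stationary at the root.**
  `V[i,j] = exp(-alpha d_ij) (1 - exp(-2 alpha s_ij)) / (2 alpha)` with
  d the patristic distance and s the root-to-MRCA depth. This form is
  valid on fossil (non-ultrametric) trees and converges entrywise to BM as
  α → 0, which the tests exploit as an oracle.

### Optimization and fallbacks

λ is profiled on a 21-point grid over [0, 1] followed by bounded local
refinement (xatol 1e-6); the grid guards against local optima that a
single bracketed search can fall into. α is profiled the same way on a
log10 grid over [1e-6, 1e2] per-My. Estimates at the α search boundary are
flagged `caution` (no interior optimum — typically "everything
independent" when intraspecific scatter dominates), as are α < 0.05 or
n < 50, regimes where OU slope inference is known to be unreliable.

When the profile likelihood is non-finite over the whole λ range (e.g.
singular covariance or a perfect fit), the estimator returns a bracketing
fallback pair — a fixed λ = 1 fit and an OLS (λ = 0) fit — both marked
non-converged so that pooling can count them as attrition instead of
silently mixing them with estimated fits.

## 2. Specimen table and dataset variants

A measurement table row carries specimen id, species, genus, clade
labels, FL and HL in mm, a stratigraphic age range (Ma), and an
ontogenetic status (`adult` / `subadult` / `juvenile` / `unknown`). Rows
missing FL or HL are dropped with a log message; implausible sizes
(outside 1–2500 mm) warn but are kept — validation should flag, not
silently rewrite data. Four variants of a loaded table:

- **complete** — every specimen;
- **reduced** — one specimen per species: the largest FL (ties broken by
  specimen id for determinism);
- **adult** — adults plus subadult/unknown (i.e. juveniles removed);
- **juvenile** — juveniles only.

## 3. Tree ensemble

Base topologies are rooted Newick trees, possibly with polytomies and
without branch lengths. Per base topology, each ensemble tree is built by:

1. **Uniform polytomy resolution.** Each polytomy is resolved by
   sequential uniform edge insertion (the root edge included), which makes
   all (2k−3)!! rooted binary resolutions of a degree-k polytomy equally
   likely — verified by chi-square over all 105 resolutions of a 5-star.
   Library resolvers were not used because the common implementations are
   *not* uniform over resolutions.
2. **Time calibration** under a simplified birth–death–sampling model.
   Tip ages are drawn uniformly in the species' stratigraphic range
   (pooled over its specimens). Node ages are assigned in postorder: each
   internal node sits `max(children ages) + Exp(b + mu + psi)` Ma, the
   exponential rate being the sum of birth, extinction and sampling rates.
   By default b = μ = ψ = 0.03 per lineage-My. A constant (+1 My, the
   `branch_constant`) is then added to every branch so that zero-length
   branches cannot produce singular covariances. This is a deliberate
   simplification of full cal3-style calibration: it keeps the
   qualitative behavior (hidden-lineage gaps shrink as total rate grows)
   without conditioning on the sampling process, which would add heavy
   machinery the downstream pooling is insensitive to. A `uniform` null
   mode sets every branch to 1 My instead, to check how much the
   calibration model matters.
3. **Conspecific expansion.** Species tips with multiple specimens become
   polytomies of specimen tips on branches of ε = 1e-6 My. The ε (rather
   than exactly 0) keeps every covariance family positive definite; 1e-6
   My is far below any biological signal. Missing age ranges fall back to
   the sister group's pooled range (or error, if fallback is disabled).

Each tree's random draws descend from `default_rng([seed, topology_index,
replicate])`, so ensembles are reproducible and individual trees
re-derivable in isolation.

## 4. Pooling across trees (Rubin's rules)

Each tree is one plausible phylogenetic hypothesis; per-tree fits are
pooled like analyses of multiply-imputed data. For an estimate Q with
within-fit variance Var:

```
Qbar = mean(Q_i)                 B = var(Q_i)        (ddof = 1)
Wbar = mean(Var_i)               T = Wbar + (1 + 1/m) B
df   = (m - 1) (1 + Wbar / ((1 + 1/m) B))^2
```

with a t(df) interval around Qbar; B = 0 collapses to a normal interval.
The Barnard–Rubin small-sample df correction is available as an option.
Slope and intercept are pooled this way; the signal parameter is pooled
as a simple mean (it has no comparable within-fit variance under profile
estimation and is reported descriptively). Non-converged fits are
excluded by default and surfaced as an attrition rate, never silently.
Pools are reported per topology and overall ("all").

## 5. Deviating clades (phylogenetic ANCOVA)

For each candidate clade, nested GLS designs

```
null:  [1, x]        full:  [1, x, g, g*x]      (g = membership)
```

are compared by the F statistic `((RSS0 - RSS1)/q) / (RSS1/(n - p1))`
computed in the whitened space, q = 2 for the joint intercept-and-slope
test (single-term variants available). The signal parameter is estimated
**once under the null per tree** and shared by both designs, so the test
compares mean structures under one covariance rather than letting the
covariance chase the alternative.

P-values from different trees of one topology reuse the same specimens
and are therefore strongly dependent. They are combined with a
dependence-corrected Stouffer rule,

```
z_pool = sum(z_i) / sqrt(m + m (m - 1) rho)
```

where ρ is the mean pairwise correlation of z-scores across trees,
estimated from the z matrix over all candidate clades (falling back to a
conservative 0.5 when fewer than three clades are testable; ρ = 1 would
mean repeated trees add no evidence, ρ = 0 recovers classical Stouffer).
The harmonic-mean p-value is available as a sensitivity alternative.

A clade deviates **consistently** when its pooled p-value is below the
threshold (default 0.05) in *every* topology. The exclusion loop removes
all consistent clades, re-tests the remaining candidates on the reduced
data, and repeats until a round finds nothing new; it aborts rather than
continue below a minimum remaining sample size (default 10). Manual
("forced") exclusions — e.g. a single autapomorphic specimen the F test
cannot see — are applied up front and logged as round 0. After the loop
the main regression is refit and pooled on the kept specimens.

PANCOVA rounds use a per-topology subset of trees (default 200) because
the F statistics vary little across calibrations of one topology; the
subset bounds runtime without changing decisions in practice.

## 6. Synthetic data generator

The generator is a first-class module, not a test helper, because every
end-to-end claim the package makes is calibrated against data with known
truth. It produces:

- a forward-simulated birth–death tree **keeping extinct lineages as
  fossil tips** (Gillespie simulation over the study window, subsampled
  uniformly to the requested species count), tips carrying true ages and
  stratigraphic ranges widened by uniform slack;
- log FL by Brownian motion along the tree; residuals for log HL drawn
  multivariate normal with the λ- or α-structured covariance (normalized
  to unit mean diagonal so `residual_scale` is in log10 trait units);
- named deviating clades (intercept and/or slope offsets applied to the
  nearest-size subtree) plus unaffected labeled "null clades" so that
  detection specificity is measurable;
- conspecific specimen groups: per multi-specimen species, FL offsets
  drawn around the species value, HL following the species' own
  (clade-adjusted) allometric slope plus individual scatter
  (`intra_hl_sd`); the largest specimen is the adult. The scatter default
  (0.015 log10 units) is deliberately nonzero: exactly collinear
  conspecifics on ε-length branches would pin the GLS fit to the
  within-species slope with zero variance, a degenerate regime real
  measurements never occupy;
- polytomies injected by collapsing a random fraction of internal
  branches, and the lengthless base topology exported alongside the true
  calibrated tree, ages table, and a `truth.json`.

Realism limits, stated plainly: trait evolution is homogeneous (no rate
shifts), deviating clades are single subtrees with additive offsets,
measurement error is off by default, and stratigraphic ranges are
symmetric around the true age. These are the dimensions along which the
generator is easiest to extend.

## 7. Defaults and problem sizes

| parameter | default | why |
| --- | --- | --- |
| sampling/birth/extinction rate | 0.03 /lineage-My each | sparse fossil-record regime; equal rates keep the offset rate interpretation simple |
| branch constant | +1 My | floor on branch durations; removes singular covariances from zero-length calibrated branches |
| ε (conspecific branches) | 1e-6 My | positive definiteness at a scale far below biological signal |
| estimation criterion | REML | unbiased variance components → honest slope intervals |
| λ grid / α grid | 21 points on [0,1] / log10 [1e-6, 1e2] | global scan before refinement; α bounds span "pure BM" to "fully independent" on My scales |
| trees per topology | 1000 (pipeline), smaller in tests | pooled quantities stabilize well below this; B dominates T early |
| PANCOVA subset | 200 trees/topology | F varies little across calibrations; bounds runtime |
| threshold | 0.05 pooled, all topologies | consistency across topologies is the real filter |
| n_species (simulator) | 110 | typical desk-scale comparative dataset; large enough for λ to be estimable, small enough for minute-scale suites |
| residual_scale | 0.06 log10 | realistic scatter around limb allometries |
| intra_fl_sd / intra_hl_sd | 0.04 / 0.015 | ontogenetic size spread vs individual deviation from the growth line |

Typical runtimes on one CPU: full test suite ~2 min (the acceptance
criteria tests dominate); `scripts/acceptance.py` ~1 min; a 6-topology ×
1000-tree pipeline run on ~160 specimens, minutes.
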