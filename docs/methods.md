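# Methods

This note documents the statistical procedure the package implements, the
choices that were genuinely open, and what the synthetic validation does
and does not establish.

## Data model and ingestion

The unit of analysis is a wide person × item table of ordinal Likert
responses from two instruments, each item carrying metadata (instrument,
community label, Likert range, reverse-coding flag) declared in a YAML
sidecar. Reverse-coded items are reflected at load time
(v ↦ min + max − v) from metadata only — orientation is never inferred
from the data — and the flag is consumed so a second application is the
identity.

Missing cells are assumed missing completely at random and handled by
pairwise-complete correlations, mirroring designs that retain partially
missing respondents at the item level. If pairwise deletion leaves the
correlation matrix indefinite, it is projected to the nearest positive
semidefinite matrix (eigenvalue clipping at 1e−8, diagonal restored to 1)
with a warning.

**Correlation choice.** Spearman rank correlation is the default:
responses are ordinal, the downstream estimator only needs a
monotone-faithful association measure, and rank correlations are
deterministic and assumption-light. Pearson is available by flag.
Polychoric correlations would be the textbook choice for few-level items
but bring an estimation layer (and failure modes) of their own; they are
deliberately out of scope.

## Redundant-item screening

Networks assume each node measures a distinct construct, so near-duplicate
items are removed first. For a candidate pair (A, B), every third item C
provides a test of H0: ρ(A,C) = ρ(B,C) for dependent correlations sharing
one variable: with z₁ = atanh r_AC, z₂ = atanh r_BC, r̄ = tanh((z₁+z₂)/2),

    c = [r_AB(1 − 2r̄²) − ½ r̄²(1 − 2r̄² − r_AB²)] / (1 − r̄²)²,
    Z = (z₁ − z₂) √(n − 3) / √(2 − 2c),

two-sided normal p-value. A pair is *bad* when fewer than 25% of these
tests reject at p < 0.05 (defaults: the pair "shares ≥ 75% of its
correlations") **and** r(A,B) ≥ 0.5. The second gate is essential: two
items cannot plausibly measure one construct while being weakly
correlated, and without the gate any pair of near-independent items —
whose correlation profiles are all flat — would be declared redundant. On
weak-signal data that failure mode removes most of the item pool.

**Removal policy** (the method literature is silent): iteratively remove
the item participating in the most remaining bad pairs; break ties by the
lower total absolute correlation with all other items (keep the more
informative node), then lexicographically. Every removal and its
justification is recorded in the redundancy report. On chain structures
this greedy rule attains the minimum removal set; on arbitrary overlap
graphs it is only guaranteed to produce a valid cover.

## Network estimation

The graphical lasso maximizes log det Θ − tr(SΘ) − ρΣ_{i≠j}|Θ_ij| with the
penalty on off-diagonal entries only (variances unpenalized, so
diag(Θ⁻¹) = diag(S) exactly). The solver is a block coordinate-descent
("regress each variable on the rest with an L1 penalty") implementation
compiled with numba. It is written in-package because generic dense
solvers proved numerically unreliable in the target regime — more items
than respondents, hence a singular S — where this algorithm is stable.
The test suite cross-checks it against an independent implementation on
well-conditioned problems and verifies the KKT stationarity conditions
directly (residual ≤ 1e−4 demanded; ~1e−8 achieved at default tolerance).

Numerical choices: convergence is declared when the mean absolute change
of the working covariance per cycle falls below tol × mean|S_offdiag|
(default tol 1e−6, max 1000 cycles; non-convergence raises with
diagnostics); inner lasso threshold is 0.1 × that, capped at 1e−7; ρ = 0
falls back to the analytic inverse and requires S positive definite;
entries below 1e−12 are treated as structural zeros.

**Penalty selection.** ρ runs down a log-spaced path from
λ_max = max|S_ij| (the empty network, by the KKT bound) to λ_max × 0.01
in 100 points (library defaults), with warm starts; the model minimizing
the extended BIC at γ = 0.25 is selected. The γ = 0.25 default follows
the convention of the R tooling this analysis style comes from, where the
"tuning parameter" quoted in applied reports on a 0–0.5 scale is the EBIC
hyperparameter, not a literal penalty value; a literal fixed-λ mode is
provided for designs that do mean ρ itself, and the run report records
which was used. Edge weights are W_ij = −Θ_ij/√(Θ_ii Θ_jj); no post-hoc
thresholding beyond the lasso's own sparsity.

## Centrality

EI1, EI2, bridge EI1, bridge EI2 as defined in the README. Two open
algebraic details, fixed as follows and recorded here so an alternative
can be compared: (1) the two-step sums include the back-edge through the
node itself inside the neighbor's one-step term — the purely additive
reading of "secondary influence via immediate neighbors"; (2) z-scores
are computed per metric across all nodes, not within community.
Communities come from instrument membership; arbitrary partitions are
supported. The identity EI1 = bridge-EI1 + within-community-EI1 holds
exactly for every labeling and is asserted in tests. Ranking ties break
lexicographically by item id.

## Bootstrap accuracy and stability

- **Edge accuracy**: nonparametric bootstrap (resample respondents with
  replacement, re-estimate, B = 1000 by default), 95% percentile CIs.
  Interval endpoints are taken as order statistics of the draws (largest
  not exceeding the α/2 quantile, smallest not below 1 − α/2), so they
  are exactly recomputable and weakly conservative.
- **Stability**: case-dropping bootstrap over drop fractions 0.1–0.9
  (levels whose retained subset would fall below p/2 respondents are
  skipped); the CS coefficient is the largest drop fraction at which the
  correlation between subset and full-sample statistic vectors is ≥ 0.7
  with ≥ 95% empirical probability — the strict probability form of the
  usual "retain a correlation > 0.7" rule; threshold and probability are
  configurable.
- **Difference tests**: paired percentile CIs of within-replicate
  differences; significant iff 0 falls outside the closed interval. With
  α = 1 the interval degenerates to the median difference, so any nonzero
  median is flagged (boundary convention, documented here).

Replicate randomness derives from per-replicate seed sequences
(master seed, stream tag, replicate index), so results are bit-identical
regardless of execution order. Item selection is run **once** on the full
sample and the retained node set is held fixed across all replicates:
re-screening per replicate would change the node set and make statistic
vectors non-comparable. Estimation failures inside a replicate (e.g. a
zero-variance item after resampling) are excluded and counted; more than
5% failures aborts.

The pipeline recomputes all stages in memory on each run rather than
maintaining a resumable on-disk stage cache; at the problem sizes the
package ships, a full run takes minutes, and a cache's invalidation
hazards outweigh the savings.

## Synthetic data generator

The generator emulates the target study design: two communities of 22
seven-level and 65 four-level items, n = 101, ~0.08% missing cells, one
reverse-coded item, and four near-duplicate pairs (defaults; all
configurable). Ground truth is a sparse precision matrix with
within-community edges planted uniformly at random at density 0.1, four
cross-community bridge edges, and partial-correlation magnitudes drawn
from 0.2–0.4 with random signs; positive definiteness is enforced by
diagonal loading to a minimum eigenvalue of 0.05 (which attenuates the
realized partial correlations — the recorded ground truth is the implied
matrix after loading). Responses are multivariate normal draws
discretized at equal-probability normal quantiles; redundant partners are
noisy copies of another item's latent variable re-discretized through the
same thresholds. Density 0.1 corresponds to roughly chain-graph sparsity
per community, a common stand-in for symptom-network simulations; the
true dependence structure of the real instruments is unknown (data
non-public), so the preset is a structural stand-in, not a calibrated
emulation.

What passing tests therefore show: the pipeline recovers planted sparse
monotone-latent structure (sensitivity ≈ 1, specificity ≈ 0.93, exact
sign agreement at n = 2000), flags planted duplicates without false
alarms, and its resampling machinery is calibrated and reproducible. What
they do not show: behavior under skewed margins/floor effects (a skewed
threshold option exists but is off by default), response styles,
informative missingness, or the edge strengths of real clinical data. In
particular, at n = 101 with planted partials ≤ 0.4, EBIC-γ = 0.25 selects
very sparse (sometimes empty) networks and bridge-EI stability is poor —
so the preset's CS values are expected to sit well below those reported
for real data, where inter-item coupling is stronger.

## Runtime-conscious preset

The bundled study-like preset uses a 15-point penalty path down to
λ_max × 0.2, B = 200 bootstrap replicates and five drop levels
(0.1–0.9), which completes a full run in about two minutes on one core;
the library defaults (100-point path to λ_max × 0.01, B = 1000, nine
levels) remain available through `RunConfig`. Since EBIC-selected
penalties sit far above the truncated path floor in this regime, the
shorter path does not change the selected model in practice.

## Known limitations

- Pairwise-complete correlation + PSD projection is principled only for
  small MCAR missingness; no imputation is provided.
- The dependent-correlation test relies on Fisher-transform asymptotics;
  |r| = 1 is rejected as degenerate, and near-collinear geometries where
  the variance term turns non-positive are treated as maximally
  different.
- Greedy redundancy removal is not globally minimal on arbitrary bad-pair
  graphs.
- No graphical layout/plotting; exports (edge list, adjacency, GraphML
  with community and sign attributes) are intended for external tools.
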