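# Methods

## Problem setting

A designed extraction experiment for a two-herb botanical injection
(Danshen, *Salviae miltiorrhizae*, and Honghua, *Carthami flos*) relates
three critical process parameters (CPPs) — extraction time (h), the mass
ratio of water to plant material (W/M, g/g) and the number of successive
extractions — to six critical quality attributes (CQAs): the yields of
Danshensu, hydroxysafflor yellow A, rosmarinic acid, lithospermic acid and
salvianolic acid B, and the total dry-matter yield (a proxy for
co-extracted impurities).  Each CQA carries acceptance limits.  The goal is
a *probability-based design space*: the region of CPP settings where the
probability that all six CQAs meet their limits simultaneously is at least
an acceptance level (0.95).

## Factor coding

Factors are coded affinely, `x = (u - center) / half_range`, with the
center at the midpoint of the extreme levels, so the design's extremes map
to ±1.  The packaged study uses time center 1.25 h / half-range 0.75 h,
W/M center 8 / half-range 2 g/g, and extraction-number center 2 /
half-range 1.  Because the time levels (0.5, 1, 2 h) are unequally spaced,
the middle level codes to −1/3 rather than 0; the affine map is the only
coding consistent with the published design table.  Extraction number is
carried as a real variable in the models but flagged discrete: design
spaces are computed as two-dimensional slices at its coded levels
{−1, 0, +1} (1, 2 or 3 extractions).

## Response-surface models

Every CQA is modelled as the full quadratic polynomial in the coded
factors (intercept, three linear, three pairwise-interaction and three
quadratic terms), pruned by bidirectional p-value stepwise regression:
starting from the intercept-only model, each sweep admits the candidate
term with the smallest p-value if it is below `alpha_enter` and then drops
the included term with the largest p-value if it is above `alpha_remove`.
The two levels are equal by default.  Ties are broken toward the earlier
term in the canonical order (X1, X2, X3, X1X2, X1X3, X2X3, X1², X2², X3²),
which makes the procedure deterministic.  No model hierarchy is enforced —
the published hydroxysafflor yellow A model keeps X1² while dropping the
X1 linear term, so hierarchy enforcement would contradict the study this
package reproduces.  An intercept-only outcome is allowed (predictions are
then constant); selection that still oscillates after `max_sweeps` raises
a convergence error, and inside the Monte-Carlo ensemble such data sets
are recorded and dropped (a run fails if more than 1% drop).

Model quality uses the standard definitions: R² = 1 − SSE/SST (SST about
the mean), adjusted R² = 1 − (SSE/(n−p))/(SST/(n−1)), predicted
R² = 1 − PRESS/SST with PRESS from leave-one-out residuals computed by the
hat-matrix shortcut e_i/(1−h_ii), AIC = n·ln(SSE/n) + 2p and
BIC = n·ln(SSE/n) + p·ln n, where p counts the intercept.  These are the
conventional response-surface formulas; the study names the criteria
without defining them, so trends (not absolute AIC/BIC values) are the
meaningful comparison.

All modelling happens in coded units; predictions at uncoded settings are
coded internally.

## Measurement-noise model

The only replicated condition is the center point (three runs).  Per CQA,
the sample mean and SD (n−1) of the center replicates define a relative
standard deviation (RSD ≈ 2–8% here), which is assumed to hold at every
run: a run measured at value v is regenerated with distribution mean v and
SD = RSD·v, while the three center runs are regenerated from the common
center distribution.  Four families are supported, each moment-matched so
the distribution's mean and SD equal those targets:

- **normal** — direct.  Negative draws are theoretically possible but at
  the study's RSDs occur with probability < 10⁻³⁰ and are kept as-is to
  avoid truncation bias.
- **lognormal** — ln X normal; closed form σ² = ln(1 + s²/m²),
  μ = ln m − σ²/2.
- **sqrt-normal** — √X normal, X = Z² with Z ~ N(μ, σ).  From
  E X = μ² + σ² and Var X = 4μ²σ² + 2σ⁴ the match is also closed form:
  σ² = m − √(m² − s²/2) (real whenever RSD ≤ √2), μ² = m − σ².
- **reciprocal-normal** — 1/X normal.  The moments of 1/Z exist only with
  Z bounded away from zero; since the coefficient of variation of 1/Z
  depends only on that of Z, matching reduces to a one-dimensional root
  find on cv(Z), with the conditional moments evaluated by 201-node
  Gauss–Hermite quadrature restricted to the positive-argument region.
  At the RSDs used here the restriction removes negligible mass.

## Monte-Carlo design space

One computation regenerates the full 15-run response table `n_sims` times,
stepwise-refits all six CQA models on every regenerated table (the same
entry/removal level for all), and evaluates the ensemble over a coded grid
spanning [−1, 1]² in the two free factors (step 0.01, i.e. 201 × 201
nodes, both endpoints included) at a fixed slice of the discrete factor.
A cell's probability is the exact empirical fraction of simulated data
sets whose six refitted models *jointly* predict all CQAs within limits —
the six predictions of one simulation are evaluated together, not
per-CQA-independently.  Predictions are model means; no residual noise is
added at prediction time, so the probability quantifies model uncertainty
propagated from measurement uncertainty.  The design space is the set of
cells with probability ≥ 0.95.

The dimensionless design-space size (DSS) is the masked fraction of the
grid.  Stability is summarised by repeating the entire computation
(fresh draws, fresh refits, fresh map) `n_repeats = 10` times from
independent substreams of one master seed: ADSS is the mean DSS and
RSDDSS = 100·sd/mean (%).  RSDDSS is invariant to the normalization
constant of DSS, which is why it is the robust cross-implementation
stability metric; ADSS magnitudes depend on how the size is normalized
and are comparable only within one implementation.

Randomness follows a single-master-seed contract: `SeedSequence(seed)`
deterministically derives per-repeat substreams, so identical
configuration plus seed reproduces every output byte-for-byte.

### Default simulation conditions

| parameter | default | meaning |
| --- | --- | --- |
| `n_sims` | 10000 | simulated data sets per computation; at this size RSDDSS < 0.5% |
| `step_length` | 0.01 | coded grid step (201 nodes per axis) |
| `alpha` | 0.35 | stepwise entry/removal level for final models (0.15 in the stability study) |
| `threshold` | 0.95 | joint-acceptance probability defining the design space |
| `family` | normal | draw distribution; the normal family gives the smallest (most conservative) space |
| `n_repeats` | 10 | full recomputations behind ADSS/RSDDSS |

The 0.35 significance level is where the mean adjusted R² (and the
AIC/BIC minima) of stepwise-refit ensembles turn over as the level is
swept — larger levels overfit, smaller ones underfit; the package's
`alpha_sweep` reproduces this turning behaviour.

## Synthetic data

`generate_synthetic` builds design tables on the same 15-run layout
(including the three center replicates) from user-specified quadratic
coefficients with multiplicative normal noise, `y = surface · (1 + ε)`,
ε ~ N(0, rsd), mirroring the RSD-proportional error model; the default
ground truth uses two responses with effects spanning strong to null at
5% RSD, a level typical of the HPLC yield measurements being emulated.
The generator reproduces the *structure* of real designed data — layout,
replicates, proportional noise — but not everything real extracts do:
noise is exactly multiplicative-normal and runs are independent, with no
drift, batch effects or correlated analytical error across CQAs.  Tests
passing on synthetic tables therefore validate the estimation machinery,
not the chemistry.

## Numerical choices and edge cases

- OLS is solved through cached normal-equation factorizations per term
  subset (the design is fixed while thousands of simulated responses pass
  through); rank deficiency is detected via the eigenvalue spectrum of
  X'X and reported with the offending term set.
- Stepwise selection inside the ensemble compares |t| statistics against
  cached critical values t₁₋α/₂,df — identical decisions to the p-value
  formulation at fixed degrees of freedom, without per-candidate tail
  evaluations.  Exact-interpolation fits (zero residual) treat nonzero
  coefficients as infinitely significant and zero ones as never entering.
- Probability maps are evaluated in (points × simulations) blocks with
  preallocated buffers; cell probabilities are exact rational counts
  `k/n_sims`.
- Grid cells are lattice-node evaluations including both endpoints;
  because the design-space region of the packaged study covers only ~23%
  of the slice under this package's normalization, the relative
  discretization sensitivity of DSS to the step length is a few times
  larger than it would be for a region covering most of the slice —
  steps 0.008–0.02 agree within ~1%, while 0.04 sits ~2% lower.
- A probability threshold above 1 is permitted and yields an empty design
  space with a warning rather than an error.
- Degenerate replicates (identical values, RSD 0) are flagged; such CQAs
  are regenerated unperturbed.

## Problem sizes used in the shipped checks

The packaged study is 15 runs × 6 CQAs × 3 factors.  The shipped tests
and the reproduction script use 10000-simulation ensembles for
probability and stability claims (10 full repeats for RSDDSS), 1000
simulations per significance level for the criteria sweep, and a coarser
0.04-step grid for the repeated-replication dispersion ladder, sizes at
which the reported quantities are stable to well within their stated
tolerances.

## Known limitations

- Only the center point's RSD informs the noise model; if that estimate
  is off, the design space moves accordingly (a caveat inherited from the
  method itself).
- Three-factor quadratic basis only; no blocking, categorical factors
  with more than three levels, lack-of-fit ANOVA or Box–Cox transforms.
- ADSS magnitudes are normalization-specific (see above); compare RSDDSS
  across implementations, not ADSS.
- The stepwise path matches the add-then-remove order described above;
  other software's stepwise may differ at borderline p-values, which is
  why reproduction checks pin the published term sets where exactness
  matters.
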