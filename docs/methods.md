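# Methods

## The model

Q methodology treats a person's complete ranking of S statements on a
forced quasi-normal grid as one observation of their viewpoint.  Because
every sort obeys the same grid, all sorts share one mean and one
variance (for the packaged symmetric grid, mean 0 and variance
Σ capacity(r)·r²/S), so by-person Pearson correlation is a scaled inner
product of rank vectors and the P×P correlation matrix `R` is well
conditioned for principal-component extraction.

Loadings are `a_j = sqrt(λ_j)·v_j` for eigenpairs `(λ_j, v_j)` of `R`.
The full spectrum is retained (trace = P, so `%variance = 100·λ/P`
exactly); by default min(8, P−1) components are carried into retention,
echoing common Q-analysis practice of extracting seven or eight and
keeping fewer.

### Retention

Two mechanical rules decide k: every retained factor must have
eigenvalue > 1.00, and — after Varimax rotation of the k leading
components — at least two sorts must load significantly on it and on it
alone.  The implementation searches k downward from the largest
eigenvalue-admissible count and accepts the first k where all k factors
clear the two-exemplar rule; every rejected candidate is recorded in
the retention rationale.  The scree table is advisory output only: no
automatic elbow detection is attempted, and a fixed k can always be
forced.  At very low signal-to-noise the mechanical rules can
over-retain (noise components occasionally attract two significant
loaders); this is a property of the rules, not of the implementation,
and is why the rationale is always written out.

### Rotation

Varimax is implemented as cyclic pairwise sweeps with Kaiser's
closed-form planar angle, `tan 4φ = (D − 2AB/n)/(C − (A² − B²)/n)` with
`u = x² − y²`, `v = 2xy`.  The criterion (summed per-column variance of
squared loadings) is non-decreasing within every sweep because each
planar angle is exactly optimal for its pair; sweeps stop when a full
sweep improves the criterion by less than `tol` (default 1e−8, at most
1000 sweeps — non-convergence is recorded and warned, not fatal).
Kaiser normalization (rows scaled to unit communality before rotation)
is on by default; zero-communality rows pass through unscaled.  After
convergence, columns are reordered by explained variance and signed so
each column's largest-magnitude entry is positive; the permutation and
signs are folded into the returned rotation matrix, so
`rotated = unrotated @ rotation` holds exactly and row communalities
are preserved to machine precision.  For k = 2 the sweep solution is
checked in the tests against an independent 0.001°-step grid search
over the rotation angle, and against statsmodels' Varimax.

### Flagging, weighting, quantization

A sort is flagged on factor j iff `|a_j| ≥ z_α/√S` there and nowhere
else (pure-loader rule; `z_0.01 = 2.58`, `z_0.05 = 1.96`, used unrounded).
Sorts significant on two or more factors are "confounded", on none
"non-significant"; neither contributes to scores.  The PQMethod-style
auto-flag variant (additionally requiring `a² > h²/2`) is available as
an option because study reports often do not state which rule their
software applied.  Negative (bipolar) loaders are flagged with their
sign but excluded from score estimation by default — the published
study discusses its single negative loader narratively rather than
merging it — and can be included rank-negated with `bipolar="include"`.

Factor scores use Spearman-style exemplar weights `w = f/(1 − f²)`,
with `|f|` clamped at 0.999 to keep weights finite for (near-)perfect
loadings; the weighted rank sums are standardized across statements
(population SD) to z-scores.  Quantization fills the grid from the top
rank down in descending-z order; exact z ties are broken by ascending
statement id (lower id takes the higher rank) — deterministic and
documented, and exactly the rule the simulator uses, so a factor with a
single positive exemplar reproduces that exemplar's sort bit-for-bit.

### Distinguishing and consensus statements

Composite reliability of a p-exemplar factor is
`r = 0.80·p/(1 + (p−1)·0.80)` with the conventional 0.80 single-sort
reliability; `SE = sqrt(1 − r)` and `SED_fg = sqrt(SE_f² + SE_g²)`.  A
statement distinguishes factor f at level α when `|z_f − z_g|` exceeds
`z_α·SED_fg` against every other factor g; consensus statements
distinguish no factor at α = 0.05.

## The packaged study fixture

The packaged instrument is a 110-participant study of lay
conceptions of health in China: 42 statements sorted under the prompt
"When judging a person's health, how important is it to know about
their ___?" on a −5..+5 grid.  The grid's printed figure is not
machine-readable; its capacities (1,2,3,5,6,8,6,5,3,2,1) are derived by
counting rank frequencies in the five published factor arrays, which
agree with each other and with the prose description (one card at +5,
two at +4).  The fixture loader re-derives the grid from every array
column on each load, so the packaged data cannot silently drift.

Demographic tables are stored as printed.  Two blocks sum to 109 rather
than 110 (EQ-5D profile and VAS — one participant skipped the
questionnaire, per the published footnote; the education block also
totals 109 as printed).  In the exemplar table the factor-2 EQ-5D and
VAS columns sum to 24 of 25, consistent with that same non-response.
Percentages are integers computed against the full sample
(denominator 110), rounded half away from zero, which reproduces the
published 52 %/48 %/38 % figures.

## The simulator

`simulate_panel` emulates the statistical structure of a Q study, not
any particular dataset: K latent viewpoints are grid-conforming
prototype arrays drawn by rejection sampling until all pairwise
Spearman correlations are ≤ 0.3 (budget 10,000 draws); each pure
participant is the prototype's standardized ranks plus iid
N(0, noise_sd), re-quantized onto the grid; confounded participants mix
two distinct prototypes 50/50 before noise; negative participants start
from the negated prototype.  Noise on the standardized-rank scale
means `noise_sd = 1` is a one-to-one signal-to-noise ratio.  All
randomness flows from a single seed.

What the simulator deliberately omits: demographic covariates, response
styles, participant-specific reliability, and any relationship between
viewpoint content and statement wording.  Recovery results therefore
show that the pipeline identifies well-separated latent viewpoints of
known number under symmetric noise — they do not certify behaviour on
real panels with weakly separated or unequal-variance viewpoints.

## Problem sizes and defaults

Recovery experiments use K = 4 prototypes × 15 pure sorts (60
participants), matching the order of magnitude of a typical Q panel
while keeping full 50-seed sweeps fast; noise_sd = 1.0 is the stress
condition and 0 the exactness condition.  Under those conditions
auto-retention returns k = 4 with mean matched |Spearman| ≈ 0.95, and
noiseless runs recover the prototypes exactly with confounded sorts
never flagged.  Numerical tolerances: rotation convergence 1e−8,
communality/trace checks 1e−8, oracle agreement 1e−6 (the grid search's
own resolution limit).

## Known limitations

- Retention is purely mechanical; the "reasonable interpretability"
  judgement that practitioners apply on top of the two rules is out of
  scope.
- Centroid extraction, judgmental rotation and oblique rotations are
  not implemented (the supported workflow is PCA + Varimax).
- The exact rotated solution of the packaged study is unrecoverable —
  its raw sorts were never deposited — so fidelity to that study is
  established through its printed instrument, arrays and summary
  tables, plus simulation-based recovery, not by re-running its data.
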