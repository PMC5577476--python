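# Methods

This note documents the models, defaults and numerical choices behind the
`neckteeth` package, and what the synthetic experiments do and do not
establish about real data.

## The phenotype and its decomposition

Neckteeth expression in juvenile *Daphnia pulex* is recorded per instar as
a pedestal class and a spike count. The scoring rule is linear in its
parts: 0/30/50 points for an absent/small/large pedestal plus 10 points
per spike. An individual's raw score is the maximum over its instars
(induction typically peaks in the 2nd or 3rd instar; the analysis uses the
strongest expression wherever it occurs), and scores are normalized to a
0–100 induction level against the dataset's observed maximum raw score.
The strongest expression a dataset of this kind is expected to contain —
a large pedestal with eight spikes — scores 130 points, and
`scoring.REFERENCE_MAX_SCORE = 130` can be supplied as a fixed
normalization constant when comparability across datasets matters more
than the dataset-relative rule.

The reaction norm along the cue gradient x is the three-parameter
logistic

    y(x) = A / (1 + exp((m − x) / s)),   A ∈ [0, 120], m ∈ [0, 2·x_max],
                                         s ∈ [1e-4, 2]

with asymptote A ("maximum"), inflection m ("sensitivity") and scale s
("reactivity"). The sign convention makes a *small* s a steep,
threshold-like response. The A bound allows modest overshoot of the 0–100
score range so that near-saturated lines are not pinned to the boundary;
the m bound keeps fits identifiable on a 0–2 µl ml⁻¹ gradient.

### Fitting

Each maternal line (its replicates pooled across doses) is fit by bounded
trust-region least squares, multi-started from every observed dose as an
m candidate crossed with s ∈ {0.02, 0.1, 0.5}, with the observed maximum
induction as the A start. Ties among converged starts break on lowest
residual sum of squares, then smallest s. A fit is accepted only if its
RSS does not exceed that of the best constant fit. Lines whose induction
values are all identical are non-identifiable and are excluded with a
logged reason, as are lines observed at fewer than four distinct doses.

A caveat worth knowing: on a seven-dose design, s is weakly identified
whenever the inflection sits close to an observed dose and the response is
steep — predictions under s = 0.05 and s → 0 then differ by less than one
induction unit at the flanking doses. With noisy data the fitted s can
therefore collapse toward its lower bound even though the curve through
the data is essentially unchanged. This is a property of the design, not
the optimizer; the test suite's noisy-recovery checks are derandomized at
a typical-case seed and additionally verify the optimizer against an
exhaustive grid-search oracle, which is seed-independent.

## G-matrix estimation

The 36 maternal-line trait triples are standardized per trait to mean 0,
sd 1 (pooled across ponds; the record is kept for back-transformation) and
modelled as

    y_i = B' x_i + u_clone(i) + e_i,  u_j ~ N(0, G),  e_i ~ N(0, R)

with pond as the fixed effect. The clone is the random grouping factor:
with iso-female lines the among-clone covariance is the broad-sense
genetic covariance, and mothers within a clone are treated as replicates
(maternal identity is not modelled as a nested effect).

Sampling is Gibbs, with a parameter-expanded representation of the clone
effects, u_j = diag(α) v_j: v_j has working covariance G_v ~ IW(ν = 3,
V = I) and the expansion vector α has prior N(0, 1000·I), which keeps the
chain mobile when clone variances approach zero (plain inverse-Wishart
Gibbs samplers stick near zero variance). The residual prior is
IW(ν = 3.002, V = I/3), weakly informative for three traits. Reported G
draws are diag(α) G_v diag(α). Fixed effects get a flat prior and a
matrix-normal conditional; balanced designs use a single Cholesky shared
across clones per sweep. Default chain settings are 180 000 iterations,
45 000 burn-in, thinning 200 — note these yield (180000 − 45000)/200 = 675
kept draws; the package reports the actual kept count rather than a
nominal one. Scalar summaries are the posterior mode (Gaussian KDE,
Silverman bandwidth, maximized over the sample points) and the 95% HPD
(shortest sorted-window interval); broad-sense heritability is computed
per draw as H²_i = G_ii/(G_ii + R_ii). Convergence diagnostics report an
initial-positive-sequence effective sample size and the lag-1
autocorrelation per G element.

### Model comparison

Three models are compared: unstructured G, diagonal G (independent clone
variances, drawn element-wise from univariate inverse-Wishart
conditionals), and no random effect. DIC = D̄ + pD with pD = D̄ − D(θ̄)
uses the *marginal* likelihood focus: the clone effects are integrated
out, so one clone's rows are jointly Gaussian with covariance
I ⊗ R + J ⊗ G and the deviance depends on (B, G, R) directly, with the
plug-in at their posterior means. This focus was chosen deliberately: with
the deviance conditioned on the realized clone effects, the comparison
has almost no power to reject an unnecessary random effect (the random
effects absorb noise and pD rises by roughly the same amount), whereas the
marginal focus penalizes the covariance parameters themselves and cleanly
prefers no-random under zero clone variance and unstructured G under
strong genetic correlation.

## Selection analysis

Fitness is proxied by w = ln(clutch/age): it rises with first-clutch
fecundity and with earlier maturation, and tracks population growth rate
in an expanding population. The quotient's direction (clutch over age) is
a package decision; any positive rescaling of w is immaterial downstream
because every composite gradient is normalized to unit length, which also
sidesteps relativizing by a possibly non-positive mean of a log quotient.
The maternal line is the unit of analysis — traits exist per line, so each
line's w is the mean proxy over its replicates.

β comes from the first-order least-squares fit of w on the standardized
traits; γ from the full second-order fit, with the fitted quadratic
coefficients doubled on the diagonal (cross-term coefficients are used
as-is) so the matrix estimates the curvature of the selection surface
without the factor-of-two bias. Significance is by randomization:
fitness is permuted across lines for the linear gradients, while the
nonlinear gradients permute the first-order residuals and add them back to
the first-order fitted values before refitting the second-order model,
respecting the dependence of the quadratic terms on the linear fit.
Two-tailed p = (1 + #{|perm| ≥ |obs|})/(B + 1); default B = 10 000.
Calibration on null data (n = 36, B = 200, 1000 datasets) puts the
empirical type-I error at 0.044–0.055 for β and 0.054–0.068 for γ at
α = 0.05 — residual permutation runs slightly liberal, a known property of
the scheme.

The canonical analysis is the symmetric eigendecomposition of the
doubled-diagonal γ (M's columns unit-norm, signs fixed so each column's
largest-magnitude loading is positive; λ sorted descending). Feeding the
doubled matrix to the rotation is the standard post-doubling convention;
eigenvalue significance reuses the residual-permutation null with
rank-matched eigenvalues, since no canonical-specific test is standard.
Mixed-sign λ classify the surface as a saddle.

## Response to selection

Survival selection is not estimated from data; it enters as sign templates
from size-selective predation theory: midge larvae (gape-limited, small
size-selective) favour (+1, −1, +1) on (maximum, sensitivity, reactivity)
— more defence, triggered at lower doses, faster; fish (large
size-selective) disfavour the defence, (−1, +1, 0), with no survival
pressure on reactivity. Reproduction and survival gradients are each
normalized to unit length, combined with weights (1,0), (1,0.5), (1,1),
(0.5,1), (0,1), and renormalized, so the five composites differ in
direction only.

Each posterior G draw is pushed through Δz = Gβ and decomposed per trait
into direct (G_ii β_i) and indirect (Σ_{j≠i} G_ij β_j) parts; total =
direct + indirect holds exactly per draw. Components are summarized by
posterior mode and 95% HPD, flagged when the HPD excludes zero, and the
angle between β and Δz is summarized the same way. Δz is reported on the
standardized-trait scale throughout; only the reaction-norm projection
back-transforms (shifted standardized means × trait sd + mean), clipping
the maximum to [0, 100] and flooring sensitivity/reactivity at 10⁻⁴ with a
warning. One generation only; G is assumed constant.

## The synthetic experiment

The generator reproduces the reference design: 12 clones (7 assigned to a
midge-only pond, 5 to a fish-and-midge pond), 3 mothers per clone, 5
neonates per mother per concentration on the gradient (0, 0.1, 0.25, 0.5,
0.75, 1, 2) µl ml⁻¹ — 1260 individuals — with an optional extra-dose clone
(four added concentrations) mirroring the extended gradient sometimes run
on a single genotype. Defaults:

| parameter | default | meaning |
|---|---|---|
| pond trait means | midge (74, 0.13, 0.05); fish–midge (55, 0.42, 0.08) | natural units: induction 0–100, µl ml⁻¹, µl ml⁻¹ |
| `trait_sd` | (10, 0.10, 0.02) | natural-unit sd per standardized unit; maps standardized deviates onto trait units |
| `G_true` | diag (0.18, 0.35, 0.02); cov(max, sens) = −0.12, cov(sens, react) = 0.03, cov(max, react) = −0.001 | clone-level covariance, standardized scale |
| `maternal_var` | (0.05, 0.05, 0.05) | independent (diagonal) maternal deviations |
| `residual_sd_induction` | 8 | Gaussian score noise, induction units |
| `beta_true`, `gamma_true` | (0.029, 0.016, 0.008); saddle-shaped γ with doubled diagonal (0.189, 0.095, 0.096) | true reproduction-selection surface |
| `fitness_noise_sd` | 0.1 | per-individual noise on w |
| age grid | 5–15 d in 0.5-d steps | ages at first reproduction |

Line traits are pond mean + trait_sd × (clone deviate + maternal deviate),
with clone deviates drawn from G_true; sensitivity and reactivity are
floored at 10⁻³ to stay positive. Induction noise is *truncated* to
[0, 100] rather than resampled, which preserves the sigmoid mean structure
near the bounds in the way score saturation does. Induction levels are
then emitted as per-instar pedestal/spike observations (strongest in the
2nd instar, attenuated neighbours) whose scores quantize the intended
level to the nearest 10 raw points — the same ~4-unit granularity real
scoring has. Life histories invert the fitness proxy: each individual's
w = line w + noise is turned into an (age, clutch) pair with clutch =
round(age·eʷ), so the mean per-line proxy recovers the line's true w up to
clutch rounding. One random stream per concern (traits, induction, life
history), split deterministically from the master seed; identical
configurations are byte-identical.

What the generator does *not* emulate: instar-by-instar growth dynamics,
actual survival under predation, non-Gaussian score noise (the Gaussian
choice is an assumption, not an empirical fact), dose-dependent variance,
and between-pond differences in G. Passing tests therefore demonstrate
that the analysis chain recovers known structure under its own model
assumptions — they do not validate those assumptions against real
*Daphnia* data.

## Test-scale choices and statistical limits

Simulation studies in the test suite run at sizes chosen to make their
statistics decisive: HPD-coverage of G elements uses 20 replicates of the
12-clone design at 20 000 MCMC iterations; DIC orderings use 20 replicates
at 4 000 iterations; permutation calibration uses 1000 null datasets at
B = 200. Two recovery checks deserve a note on their tolerances. The
empirical clone covariance converges to G_true at ~sqrt(2/q) relative
noise per diagonal element, so the 500-clone generator check (15%
tolerance ≈ 2.4 sd) uses a covariance whose elements are all of magnitude
≥ 0.3 — a near-zero element like the default −0.001 admits no finite
relative tolerance. Likewise, a single 100-clone dataset cannot pin
posterior modes of G to 20% (clone sampling alone contributes ~14%), so
the scaled-up recovery test averages modes over three replicate datasets,
which isolates what such a test can actually measure: estimator bias.

## Known limitations

* Broad-sense (clonal) genetic covariance only; no pedigree/animal model,
  no narrow-sense heritability.
* Selection on survival is hypothetical by construction; only the
  reproduction gradient is estimated from (synthetic or real) data.
* The G-matrix model assumes multivariate Gaussian traits; reaction-norm
  parameters from saturated or flat lines can violate this.
* One-generation responses; no evolution of G, no iterated selection.
* DIC is reported under the marginal focus described above; its values are
  not comparable to conditional-focus DICs from other software.
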