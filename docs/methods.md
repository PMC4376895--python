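# Methods

## Model

Observations `z_i = f(x_i, y_i) + eps_i` with `eps_i ~ N(0, sigma^2)` are
fitted by penalized least squares in a reproducing-kernel Hilbert space:

    min_f  sum_i (z_i - f(x_i, y_i))^2 + lambda * J(f),

where `J` is a quadratic roughness penalty. By the representer theorem the
minimizer is a finite combination of kernel sections plus the penalty's
null space, `f = sum_j alpha_j R(., t_j) + sum_k beta_k phi_k`, so the fit
reduces to a ridge-type linear system. The coefficient posterior
`N((alpha, beta), Sigma)` under the standard Gaussian-process reading of
the penalty supplies pointwise variances for everything downstream.

Two kernel families are built in:

* **Thin-plate spline** (`ThinPlateKernel`): radial basis
  `r^2 log(r)/(8*pi)`, null space `{1, x, y}`, penalizing the
  rotation-invariant integral of squared second derivatives
  (`f_xx^2 + 2 f_xy^2 + f_yy^2`). The mixed-derivative weight 2 is what
  makes the penalty isotropic; the `1/(8*pi)` normalization is absorbed
  into `lambda`. This kernel encodes the prior that the surface is equally
  smooth in every direction of the plane.
* **Cubic marginal / tensor product** (`MarginalCubicKernel`,
  `TensorProductKernel`): the cubic-smoothing-spline kernel on an interval,
  written with scaled Bernoulli polynomials
  `R = 1 + k1(s)k1(t) + [k2(s)k2(t) - k4(|s-t|)]` so that the linear and
  smooth blocks have exact zero mean under the uniform measure. The tensor
  model carries one kernel block per ANOVA subspace — intercept, x main
  effect, y main effect, interaction — each weighted by `theta_b`
  (`theta_0 = inf`: unpenalized intercept). It makes no isotropy
  assumption.

Covariates are affinely rescaled to `[0, 1]` per axis inside every kernel;
results are reported on the original scale.

## Functional ANOVA decomposition

A fitted surface is decomposed uniquely as
`f = c + f_x(x) + f_y(y) + f_xy(x, y)` with zero-mean main effects and a
zero-marginal interaction, via the averaging operators
`A_y f(x) = ∫ f(x, y) dmu_y(y)` (and symmetrically `A_x`):

    c    = A_x A_y f,          f_x = A_y (1 - A_x) f,
    f_y  = A_x (1 - A_y) f,    f_xy = (1 - A_x)(1 - A_y) f.

Two routes are implemented and agree identically when the kernel is a
tensor product:

* `classic_ssanova` builds the decomposition into the basis (one block per
  subspace) and reads components off the blocks;
* `posthoc_decompose` applies the operators to *any* fitted bivariate
  spline — thin-plate included — by integrating the kernel sections and
  null-space functions numerically. Each component is then a linear
  functional `M (alpha, beta)` of the coefficients, so its pointwise
  posterior variance is `diag(M Sigma M')`; for the intercept this is the
  `R0 Sigma R0'` form with `R0_j = A_x A_y R(., t_j)`.

The averaging measures default to Lebesgue on the rescaled unit square
(Gauss–Legendre, order 32 per axis); an empirical measure at the observed
covariates is available for the "distribution of the data" variant.
Because centering and averaging reuse one quadrature rule, the projector
identities (components sum to the fit, zero means, zero marginals,
idempotence) hold to machine precision rather than merely to quadrature
tolerance, and the classic-vs-post-hoc equivalence on tensor fits is exact
to ~1e-12. Closed-form kernel averages are deliberately not used; a
quadrature-refinement check (`average_kernel(..., check=True)`) doubles
the order and verifies stability, and an analytic override could be
slotted in per kernel if ever needed.

## Fitting and smoothing selection

`PenalizedSystem` solves the constrained penalized LS problem in a
numerically hardened form: the side condition `T' alpha = 0` (needed for
the conditionally positive definite thin-plate kernel) is absorbed by a QR
null-space basis; the penalty Gram is eigen-factored and the penalized
coefficients rescaled to spherical coordinates in which the penalty is
`lambda ||u||^2`; unpenalized columns are projected out and the remaining
design SVD'd. Every per-`lambda` quantity (edf, RSS, GCV, REML) is then a
sum of non-negative terms — no cancellation — which matters because
kernel-section bases are extremely ill-conditioned near the unpenalized
limit. Directions with numerically zero penalty (duplicate representers)
are dropped; genuinely collinear unpenalized columns raise an error.

Representers default to the observation points for `n <= 1000` and to a
~200-point grid of marginal quantiles (14 x 14 for bivariate data) above
that, keeping the exact solve `O(n m^2)`.

`select_lambda` minimizes GCV (default) or REML on a log grid spanning 14
orders of magnitude around the spectrum of the whitened design, then
refines by golden section. The minimizer is taken as the **first
significant valley scanning from the smooth end** (a rise of more than
0.5% ends the scan): flexible RKHS bases give plain GCV a genuine second
dip near the unpenalized limit at moderate n, and stopping at the first
valley keeps the selection on the statistically meaningful branch while
preserving classical GCV behavior whenever the curve is unimodal. The
Kim–Gu inflated variant (`gcv(lam, rho=1.4)`) is available but not the
default: it noticeably oversmooths small samples. `sigma^2` is estimated
as `RSS/(n - edf)`.

For the tensor model, `theta_x` is fixed at 1 (the overall scale is
redundant with `lambda`) and `(theta_y, theta_xy)` are selected on the log
grid `10^{-2..3}` with one half-decade 3x3 refinement, `lambda` profiled
out by the criterion at each grid point.

## Simulation harness

Two closed-form surfaces on the unit square:

* example 1: `2(x-1/2) + sin(2*pi*y) + sin(2*pi*x)cos(2*pi*y)` — almost
  but not exactly isotropic; closed-form ANOVA components (all full-period
  trigonometric means vanish);
* example 2: `2(x-1/2) + 2(1/2-y) + exp(-((x-1/2)^2+(y-1/2)^2)/0.08)` —
  isotropic by construction (radial Gaussian bump); components obtained by
  order-128 quadrature (the bump factorizes, so an erf-based closed form
  cross-checks it in the tests).

Studies draw 100 replicates (default) of n in {30, 300}, covariates iid
uniform on the unit square, noise `N(0, 1/4)`; replicate r of a study with
seed s uses the independent stream seeded by `(s, r)`. Each replicate is
fitted by both routes and all components are evaluated on fixed grids
(101 points per axis for main effects, 21 x 21 for the interaction; MSB is
a grid mean and hence resolution-insensitive, and traces are also
available per grid point). Metrics:

* `trace_variability`: trace of the across-replicate covariance of grid
  values = summed pointwise variance (ddof = 1);
* `mean_squared_bias`: grid mean of (across-replicate mean - truth)^2.
  Note the estimator of MSB carries a Monte-Carlo floor of
  `trace/(n_grid * reps)` from the finite replicate count.

The qualitative findings this harness reproduces: at n=30 the post-hoc
thin-plate route estimates the x main effect (which satisfies the
isotropy prior) with much smaller bias and variability than the tensor
route, while its y main effect — a full-amplitude sine, exactly the
anisotropy the prior penalizes — picks up extra bias; at n=300 the two
routes converge. On the isotropic example 2 the post-hoc route has
uniformly smaller variability at both sample sizes.

## Additive mixed model

`fit_amm` fits `z = c0 + sum_t f_t + sum_g r_g + eps` by one joint
penalized LS system: smooth terms are centered under their Lebesgue
measures (absorbing the intercept confound), pre-whitened per block so the
block penalty is `lambda_b I`, and random intercepts enter as ridge-
penalized dummy blocks with the classical identity
`lambda_g = sigma^2 / sigma_g^2`. Term kinds: univariate cubic (20
quantile knots), bivariate thin-plate (7 x 7 quantile-grid knots, its
unpenalized centered-linear plane kept as fixed columns), and an
interaction-only tensor block (zero mean and zero marginals by
construction — pair it with explicit cubic mains for the classic layout).
Smoothing parameters are selected by coordinate-wise golden-section
optimization of REML (default; the mixed-model convention for variance
components) or GCV. `decompose_pair` repackages a thin-plate pair term
(coefficients + covariance sub-block) as a stand-alone fitted spline and
reuses the post-hoc machinery; its main effects are partial effects.

Two thin-plate pair terms sharing a covariate alias in their unpenalized
linear parts and raise a rank-deficiency error naming the terms; the
synthetic studies use one pair per model.

### Synthetic reading data

`synth_reading_data` emulates the *structure* of a single-fixation reading
corpus: log fixation duration as response; incoming saccade amplitude (1 -
12 letters); log word lengths and log frequencies of the previous, fixated
and upcoming word on `[0, 3]`; crossed reader and word random intercepts
(defaults `sigma_id = 0.2`, `sigma_w = 0.1`, `sigma_eps = 0.3`, intercept
5.3 ~ log 200 ms — magnitudes typical of reading corpora). Default effect
shapes are monotone for the previous word's frequency, clearly
non-monotone for the fixated word's, and weak for the upcoming word's;
effect sizes ~0.1 log units. The fixated word's length and frequency are
word attributes (shared by all fixations on that word); neighbor
covariates are drawn independently per fixation. What it does *not*
emulate: serial correlation along a sentence, reader-by-word interaction,
skewness of duration distributions, and correlated length/frequency
within words — so passing tests show the estimator recovers the model it
assumes, not that the model suffices for real eye-movement data.

`subset_study` refits both model layouts on random subsets (drawn without
replacement) and compares across-subset component variability; it uses
GCV because REML at subset sizes of a few hundred correctly shrinks a
truly absent interaction to exactly zero in both layouts, which would make
the variability comparison degenerate.

## Numerical choices, degenerate inputs, limitations

* Quadrature: Gauss–Legendre order 32 per axis for decomposition
  measures; 24 within AMM terms; 128 for example-2 ground truth. The
  thin-plate kernel's `r^2 log r` kink is mild; order-doubling changes
  averaged values by < 1e-6.
* Ties/duplicates: duplicate representers are dropped with a warning;
  duplicate covariate values are harmless (the penalty absorbs them).
* `z = 0` yields exactly zero coefficients and `sigma^2 = 0`; monotone
  criteria over the grid return the boundary with a warning.
* Significance masks use `|mean| >= k * sd` (boundary inclusive), k = 2 by
  default; interval multipliers are pointwise only — no across-grid
  multiplicity correction.
* The decomposition API is bivariate; higher-dimensional smooths are out
  of scope except through per-pair decomposition of AMM terms.
* Printed-table reproduction is inherently limited by the unknown
  smoothing-selection details behind the published study; see the README
  for which quantities are reproduced and to what tolerance.
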