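# Methods

## Data model

Deaths and person-years are tabulated on a Lexis grid of ten 5-year age
groups (lower edges 30, 35, ..., 75; the last group open-ended "75+") by
six 5-year calendar periods (1976-1980 ... 2001-2005).  With 1-based
indices and A age groups, cell (a, p) lies on cohort diagonal
c = A - a + p, giving A + P - 1 = 15 overlapping 10-year birth cohorts.
Cohort labels are derived, not data: the centre year of cohort c is
(period centre) - (age-group centre) along the diagonal, rounded to the
nearest multiple of the 5-year grid width, which puts cohort 1 at 1900,
the central (reference) cohort 8 at 1935 and cohort 10 at 1945; the
open-ended age group uses the nominal centre 77.5.  Consecutive cohorts
are exactly 5 years apart and each spans centre +/- 5 years.

IHD deaths are identified from ICD codes: revisions 8 and 9 match on the
leading three-digit rubric 410-414 after punctuation stripping (decimal
subcodes inherit the parent rubric), revision 10 on I20-I25 including
subcodes.  Codes that fail to parse are flagged and reported, never
silently treated as non-IHD; the aggregation step likewise reports counts
of records dropped for age below 30, year outside the study window, or a
missing income assignment, so retained + dropped always equals input.

## Socio-economic classification

Neighbourhoods (TPUs) are classified per census year by an unweighted
median split of TPU-level median household income per capita: strictly
below the cutoff is "low", at or above it "high".  For an even number of
TPUs the cutoff is the lower of the two middle order statistics, so at
least one TPU sits exactly at the cutoff and the "equal to or above"
rule is never vacuous (with n = 2 distinct incomes this labels both TPUs
high; from n >= 3 both strata are populated whenever incomes differ).
Deaths and populations are linked to the census year nearest the event
year, with equidistant ties resolved to the earlier census — a declared
convention, since the original linkage rule is not recoverable from the
study design.  The classification is relative (a different cut point per
census) and therefore scale-invariant within a census year.

## The Bayesian APC model

Cell counts are modelled as D_ap ~ Poisson(N_ap exp(eta_ap)) with
eta_ap = mu + alpha_a + beta_p + gamma_c.  Each effect vector carries a
forward second-order autoregressive (RW2) prior, flat on its first two
elements and N(2 e_{k-1} - e_{k-2}, sigma^2) thereafter — equivalently a
Gaussian penalty on second differences — so the prior's predictive
continuation of a series is its linear extrapolation.  The RW2
precisions 1/sigma^2 get Gamma(0.001, 0.001) hyperpriors (the
WinBUGS-era weakly-informative convention; both parameters are exposed
in configuration), and the intercept a diffuse N(0, 1e6) prior.

Identifiability.  Because c = A - a + p, adding an affine function of
period to beta and subtracting the matching pieces from mu, alpha and
gamma leaves every fitted rate unchanged.  The model pins the second and
penultimate period effects and the central cohort effect to zero; the
age curve is additionally centred to mean zero against the intercept so
that every monitored parameter is identified (otherwise mu and the alpha
level drift freely and convergence diagnostics on them are meaningless).
Constraints are enforced by the exact affine transform each iteration —
an affine shift leaves second differences, and hence the RW2 prior,
untouched — and the transform's rate-invariance is unit-tested to
1e-12.  For submodels (the DIC comparison grid) the two-point period
detilt applies only when all three dimensions are present, since the
trend aliasing only exists then; otherwise each included effect loses
only its level.  Only second-order features (changes of slope) of the
effect series are interpretable; levels and linear trends are
constraint-dependent.

Sampling.  The kernel is Metropolis-within-Gibbs with all chains
advanced in lock-step: adaptive random-walk Metropolis on each scalar
(step sizes tuned toward 0.44 acceptance during burn-in only), plus one
joint Metropolis-Hastings update per effect vector per iteration using a
Gaussian proposal matched to the gradient and Hessian of the
Poisson-plus-RW2 conditional at the current point (an IWLS-style Taylor
proposal with the exact accept-reject correction), and conjugate Gibbs
updates for the RW2 precisions.  The block updates are what make the
strongly RW2-coupled effects mix quickly; without them split R-hat stays
above 1.05 for tens of thousands of iterations on these grids.  Chains
start from crude-rate-based values with chain-specific over-dispersion.
Burn-in is adaptive: after a configurable minimum, split-chain
Gelman-Rubin R-hat is computed over a moving window for every identified
parameter (reference entries excluded) and sampling starts once all are
below 1.05 (configurable), up to a maximum; if the criterion is still
unmet the result is returned flagged `converged=False` with its R-hat
table, and the CLI `fit` command exits non-zero.  Default budget: 5
chains, 40,000 retained draws total; the test suite and acceptance
script run 2-3 chains with 400-2,400 retained draws, which the R-hat
gate shows is sufficient on the default 10 x 6 grids.

DIC.  Deviance is computed as -2 sum [D log(N lambda) - N lambda],
omitting the data-only log D! term consistently across all compared
models, so DIC *differences* are unaffected but absolute DIC values are
not comparable with tabulations that include the saturated term.
pD = Dbar - D(posterior mean); posterior means of constrained draws are
themselves constrained (the constraints are linear), so D(mean) is well
defined.

## Projection

Period and cohort effects are extended three steps by sampling the RW2
predictive per retained draw: new = 2 prev - prev2 + N(0, sigma2_draw),
using each draw's own innovation variance so hyperparameter uncertainty
propagates; with sigma2 = 0 the extension is exactly linear.  Projecting
h periods consumes exactly h new cohort diagonals (the youngest age group
in the last projected period sits on cohort K + h), which the code
verifies explicitly.  Future periods are 2006-2010, 2011-2015 and
2016-2020 (centres 2008, 2013, 2018).  Projected ASRs need no population
forecasts because the ASR is a function of rates alone; projected death
counts are deliberately out of scope.

## Age standardisation

ASRs are direct: sum of age-specific rates weighted by the WHO World
Standard Population (Ahmad et al. 2001), embedded as constants in 5-year
groups 0-4 ... 85+.  The standard is restricted to the grid (weights
below 30 dropped, 75+ collapsed from the 75-79/80-84/85+ entries) and
renormalised, so every reported figure is a 30+ ASR; no back-extrapolation
of rates below age 30 is attempted.  Credible intervals are equal-tailed
2.5/97.5 empirical quantiles (linear interpolation) across draws.

## Joinpoint analysis

Effect series (posterior-mean log relative risks by default, unweighted;
inverse-variance weighting is available in configuration) are fitted by
continuous broken-line least squares on the basis {1, x, (x - tau)+}.
Candidate joinpoints are the observed interior x-values, searched
exhaustively per k with at least 2 observations per segment; k is chosen
by BIC_k = n ln(SSE_k / n) + (2 + 2k) ln n, counting each joinpoint's
position and slope change as free parameters, with exact ties (including
exact fits) resolved to the smaller k.  An SSE below 1e-12 of the series'
total sum of squares counts as an exact fit.  Known limitation: with
searched positions this BIC is anti-conservative at series length 15 —
the marginal penalty 2 ln 15 ~ 5.4 is beaten by the best spurious knot
in roughly a fifth of pure-noise series, the same behaviour as the BIC
mode of the standard joinpoint tool (whose conservative alternative is a
permutation test, deliberately out of scope here).

## Synthetic scenario

The generator is the model's generative twin: fixed truth curves per
sex x income stratum, Poisson counts on the grid, and an expansion to
individual death records (ages/years uniform within cells,
era-appropriate ICD codes: ICD-8 to 1979, ICD-9 1980-2000, ICD-10 from
2001), TPU income tables whose relative ranks are constant across
censuses (so labels never flip), and population tables that aggregate
back exactly to the truth's person-years.  The default curves encode the
study-like features: log-linear age effects with the slope jumping from
0.45 to 0.62 per group at 50-54; male cohort effects peaking early, with
a downturn around the 1910-15 cohorts and an upturn kink at the 1945
cohort (second difference +0.22 for low income, +0.12 for high); female
cohort effects with a 1920-25 downturn, at most a slight high-income
upturn near 1940 and none at 1945; small period effects with a
low-income-only dip in 1991-95 and recovery after; and first-period 30+
ASR anchors of 33/40/55/65 per 100,000 (women low/high, men low/high)
with faster high-income decline, so the income ordering reverses inside
the observed window.  Person-years per cell are 10^4-10^6 (annual
populations of 8,000-110,000 per age group and stratum, scaled by period
growth factors 0.75-1.3), giving expected deaths of ~3-200 per cell and
~3,000-4,600 per stratum over the study window — sparse-to-moderate
counts of realistic magnitude, though smaller than a full territory-wide
registry would supply.  What the generator does not emulate: migration,
ICD-revision comparability artefacts, overdispersion, TPU boundary
changes, or within-cell age/period gradients.  Passing recovery tests
therefore demonstrate correctness of the inferential machinery under the
model's own assumptions, not robustness to those real-data features.

A consequence of the count scale worth stating plainly: with ~1-200
expected deaths per cell, the posterior shrinks a single-cohort
curvature spike of +0.22 by a factor of ~8 (the likelihood sd of one
second difference is ~0.17 against a fitted RW2 prior sd of ~0.06), so
while 95% credible intervals for cohort RRs cover the truth at the
nominal rate, the *argmax* of posterior-mean curvature is
noise-dominated and lands within one cohort of the true kink far more
often than exactly on it.

## Numerical choices

* Quantiles: linear interpolation (numpy default) throughout.
* Split R-hat: chains halved, R = sqrt(((m-1)/m W + B/m)/W); zero
  within-sequence variance reports 1.0 (sequences agree) or +inf
  (distinct constants), never NaN.  Identical chains give sqrt((m-1)/m),
  i.e. 1 - O(1/m).
* The eta/expected-count caches are refreshed from the parameters every
  200 iterations to bound floating-point drift from incremental updates.
* Adaptation uses a Robbins-Monro step on log step sizes, frozen after
  burn-in, clipped to [e^-12, e^3].
* Single-chain runs cannot be R-hat-monitored and are treated as
  converged by construction; use >= 2 chains for anything that matters.
* Reproducibility is exact: one seeded generator drives all chains, so
  identical configuration and seed give bit-identical retained draws.
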