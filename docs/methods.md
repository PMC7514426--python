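# Methods

## The model

The package estimates lagged-regression (transfer-function) models linking a
monthly response series to one exogenous input, in two parameterizations.

**Time-varying coefficients.** With rescaled time $u = t/T \in (0, 1]$,

$$Y_{t,T} = \sum_{i=1}^{m} \delta_i(u)\, Y_{t-i,T}
          + \sum_{j=0}^{n} \omega_j(u)\, X_{t-j,T} + \varepsilon_t,
\qquad \varepsilon_t \sim \text{i.i.d.}(0, \sigma^2).$$

This is the locally stationary device: the coefficient curves live on the
fixed interval $[0,1]$, so longer records refine rather than extend them, and
smoothness of $\delta_i, \omega_j$ is the assumption that the input–response
relationship drifts slowly relative to the sampling rate. Each curve is
expanded in a periodized Daubechies orthonormal series,

$$f(u) \approx \alpha_{0,0} + \sum_{j \in L} \sum_{k=0}^{2^j-1}
  \beta_{j,k}\, \tilde\psi_{j,k}(u),$$

where $L \subseteq \{0, \dots, J-1\}$ is the retained level set and the
periodized scaling function at the coarsest scale is the constant 1.
Substituting the expansions makes the model linear in the wavelet
coefficients; each design column is a basis function sampled at $t/T$ times a
lagged series value. With all levels of $J = \log_2 T$ retained the design is
square ($T{-}v$ rows by $2^J$ columns per regressor, $v = \max(m,n)$ leading
rows dropped, never back-cast).

**Constant coefficients.** The Box–Jenkins rational form
$Y_t = \delta(B) B^d \omega(B)^{-1} X_t + \eta_t$ with
$\omega(B) = 1 - \omega_1 B - \dots - \omega_r B^r$, ARMA noise $\eta_t$, and
pure delay $d$; stability requires the roots of $\omega$ outside the unit
circle.

## Estimation

**Two-stage least squares (time-varying family).** Stage 1 regresses $Y_t$ on
the wavelet-expanded observed lagged responses and inputs. Stage 2 repeats
the regression with the response-lag columns built from the stage-1 fitted
values $\hat Y_{t-i}$ (observed values are kept for the first $v$ points,
where no fitted value exists). Both solves use an SVD minimum-norm least
squares rather than the normal-equations inverse: the level-complete sampled
basis is severely ill-conditioned (see below), and explicit inversion of a
$512 \times 512$ Gram matrix is numerically indefensible. Rank deficiency
produces a warning and the minimum-norm solution by default; a strict mode
raises with the condition number instead. Curves are recovered by evaluating
the basis expansion on the training grid — reconstruction is exact by
construction, so `delta_curves` always equals the basis matrix times the
coefficient vector.

**Stage-2 error structure.** For $m = 1$, substituting
$\hat Y_{t-1} = Y_{t-1} - e^{(1)}_{t-1}$ (stage-1 residual $e^{(1)}$) into the
stage-2 regression gives the exact decomposition

$$e^{(2)}_t = \varepsilon_t + \delta_1(u_t)\, e^{(1)}_{t-1},$$

a first-order moving-average-type error whose lag-1 autocorrelation is
approximately $\bar\delta_1 / (1 + \bar\delta_1^2)$. A widely quoted
reduction instead writes $e^{(2)}_t = \varepsilon_t - \delta_1^2(u_t)
\varepsilon_{t-2}$, a locally stationary MA(2); that form drops the
first-order term and, in simulation, inverting the implied filter
$(1 - \hat\delta_1^2 B^2)$ does *not* whiten the residuals (the combined
filter telescopes to $1/(1 - \delta_1 B)$, leaving lag-2 autocorrelation of
roughly $\bar\delta_1^2$). Fitted models expose both sequences —
`innovations` (the MA(2)-inverse form, for continuity with that convention)
and `innovations_exact` (the decomposition above) — and the test suite
records the empirical behaviour of each. Even the exact form is not
perfectly white at finite $T$: the truncated basis cannot represent a generic
smooth curve exactly, and the smoothing bias leaks a small autocorrelated
signal component into the residuals.

**Five-step procedure (constant family).** (i) ARMA($p,q$) maximum-likelihood
fit to the input (statsmodels, no trend term); (ii) the fitted operator
$\hat\phi(B)/\hat\Theta(B)$ applied to both series via a linear filter;
(iii) the sample cross-correlation of the filtered pair, whose lag-$h$ value
is proportional to the impulse weight $\alpha_h$; lags exceeding $2/\sqrt T$
are flagged and the smallest flagged non-negative lag proposed as $d$
(negative lags are reported, never proposed — causality); (iv) the rational
form linearised as a finite lagged regression ($r$ response lags, $s{+}1$
input lags from $d$) and solved by least squares, raising on a numerically
collinear design; (v) ARMA fit to the step-(iv) residuals. Orders are caller
configuration throughout; the synthetic experiments state their own.

**Prediction.** Both families forecast through the fitted difference
equation. `one_step` uses observed lagged responses (for test windows where
the record exists); `recursive` feeds forecasts back in. Beyond the training
window the time-varying curves are frozen at their $u = 1$ boundary values —
the curves have support $[0,1]$ and any extrapolation rule would be
invention; freezing is the conservative boundary extension.

## Numerical realisation of the basis

Non-Haar Daubechies functions have no closed form; they are evaluated by the
cascade algorithm at $2^{12}$ points per unit interval and linearly
interpolated, then periodized by summing the finitely many integer translates
whose compact support intersects the point. Haar is evaluated exactly, with
the right-open convention ($\psi = +1$ on $[0, \tfrac12)$). $T$ need not be a
power of two; the maximum level is capped at $\lfloor \log_2 T \rfloor$.

A caution on sampled orthonormality: the basis sampled on $\{t/T\}$ with
$T = 2^J$ has an exactly orthonormal Gram for Haar (piecewise-constant on the
sampling cells), but for smoother orders the finest levels are sampled at
only two points per oscillation and their Riemann sums do not approximate the
continuous inner products — per-entry Gram errors reach $O(1)$ at level
$J{-}1$ regardless of $T$. Orthonormality holds to a few percent only for
levels three to four octaves below the sampling rate. This is why the solver
is minimum-norm SVD and why the default selection grid uses levels 1–5 at
$T = 512$ rather than the level-complete square system.

## Model selection

The grid crosses Daubechies orders 1–10 with every non-empty subset of levels
$\{1,\dots,5\}$ (31 subsets, 310 candidates). Stage 1 searches the full
grid; stage 2 keeps the stage-1 winner's filter and searches the level sets
again around its model. Each candidate records the six-metric panel for the
fit phase and, when a held-out window is supplied, the forecast phase.

"Minimise RMSE and MAE while maximising correlation" is not a total order, so
selection is lexicographic: maximise fit-phase $R^2$, break ties by smaller
MAE, then smaller level set, then lower filter order. $R^2$ and MAE are
rounded to nine decimals before comparison so that exact ties (every superset
of a perfectly fitting level set attains $R^2 = 1$) fall through to the
parsimony tie-breaks rather than being ranked by floating-point dust. Note
that under noise the SSE-nesting property makes larger level sets weakly
better on fit $R^2$ by construction; the min-MAE and max-$R^2$ optima can
disagree, and both are exposed (`GridResult.best_by`). Forecast-phase
metrics never participate in selection — selecting on the held-out window
would leak it into the model choice. Fit-phase $R^2$ is $1 -
\mathrm{SSE}/\mathrm{SST}$; forecast-phase $R^2$ is the squared Pearson
correlation of forecasts with held-out observations.

## Transformations

Anomalization maps each value to $(x - \bar x_i)/s_i$ with the calendar-month
mean and *sample* ($n-1$) standard deviation computed over a declared base
period — a 49-year base divides each month's squared deviations by 48.
Standardization does the same with the global base-period mean and sd (a
588-month base divides by 587). The log transform is the natural log.
Values outside the base period (a held-out test window) are transformed with
base-period statistics, so forecasts are comparable across the split; in the
pipeline the base period is exactly the training window, at month resolution,
so no held-out value can enter any statistic. Every step's parameters are
recorded on the series (and in a JSON sidecar next to CSV output), making
`invert` an exact round trip. Missing months are rejected, not imputed.

## Synthetic data

`generate_tvtf` simulates the time-varying recursion with named parametric
curves (constant, linear, cosine, step), an AR(1)/ARMA or seasonal-climatology
input, and Gaussian innovations; explosive specifications
($\sup_u \sum_i |\delta_i(u)| \ge 1$) are rejected. `generate_polytf`
simulates the rational form plus ARMA noise and returns the implied impulse
weights $\alpha_0 \dots \alpha_{20}$ for oracle checks. Both discard a
100-sample burn-in and are bitwise deterministic under their seed.

`generate_fisheries_like` emits a 588-month (1963-01 … 2011-12) table with
nine climate proxies (seasonal climatology plus AR(1) anomalies, two of them
strongly cross-correlated the way neighbouring Pacific SST indices are) and
two strictly positive landings series: one driven by lagged inputs through
time-varying coefficients, one whose log follows a constant-coefficient
two-input transfer function with AR(1) noise. Coefficient magnitudes put
prewhitened cross-correlations in the 0.1–0.6 band so the significance
threshold $2/\sqrt T$ is exercised realistically. The chronological split at
2005-08/2005-09 gives 512 training and 76 test months.

What the generators do **not** emulate: real ENSO dynamics or regime shifts,
heavy-tailed or non-Gaussian innovations, fishing-effort interventions,
missing records. Passing recovery tests therefore demonstrates correctness
of the estimators under their own assumptions, not forecasting skill on real
registers.

Gaussian innovations are a testability choice; the time-varying model itself
assumes only i.i.d. $(0, \sigma^2)$ errors.

## Problem sizes

The simulation studies use the scales at which their conclusions stabilise:
coefficient-recovery curves over $T \in \{256, 512, 1024\}$ with 50
replicates; whitening and delay-identification rates over 100 seeded runs at
$T = 512$ and $T = 1000$; the full 310-candidate grid at $T = 512$ runs in a
few seconds.

## Known limitations

* Single exogenous input in the time-varying estimator; multiple inputs are a
  documented extension by column concatenation (the constant-coefficient
  regression already accepts several branches).
* No wavelet-coefficient thresholding or shrinkage, and no entropy-based
  level selection; the grid search is exhaustive over its configured sets.
* The delay proposal takes the *smallest* flagged non-negative lag; with
  ~4.6% per-lag false-flag probability at the $2/\sqrt T$ bound, records with
  many pre-delay lags will occasionally propose too early a lag.
* Forecast uncertainty is not quantified (no intervals, no bootstrap).
* Seasonal ARIMA transfer functions, intervention analysis and automatic
  differencing are out of scope; stationarity of inputs to the five-step
  procedure is the caller's responsibility.
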