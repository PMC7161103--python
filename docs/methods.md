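# Methods

## The model

The package fits a linear-Gaussian model of DNA methylation across age.  For
n CpG sites indexed by i and m individuals indexed by j, the observed
methylation level is

    s_hat[i, j] = s0_i + r_i * t_j + eps[i, j],      eps ~ N(0, sigma^2) i.i.d.

where `r_i` is the site's methylation rate (level per time unit), `s0_i` its
level at t = 0, and `t_j` the individual's age.  Two nested variants are
fitted:

* **Molecular clock (MC)** — `t_j` is the chronological age; only the 2n
  site parameters are free.
* **Epigenetic Pacemaker (EPM)** — each individual's sites may change rate
  in concert, which is equivalent to replacing the chronological age by a
  free per-individual *epigenetic age* `t_j`; the m time parameters are
  estimated jointly with the 2n site parameters.

Minimizing the residual sum of squares

    RSS = sum_i sum_j (s_hat[i, j] - s0_i - r_i * t_j)^2

is equivalent to maximizing the Gaussian likelihood, so all fitting is
least-squares.

## Closed-form site step

For fixed times, the MC problem is a least-squares system with an nm x 2n
design matrix in which each row touches exactly one site's pair of unknowns.
The 2n x 2n normal matrix therefore consists of four n x n diagonal blocks
carrying just three scalars — `sum t`, `sum t^2`, and m — and its inverse
factors through the single scalar

    lam = 1 / ((sum t)^2 - m * sum t^2),

strictly negative whenever at least two ages differ (Cauchy–Schwarz).  The
least-squares projector then has one m-wide band per output coordinate whose
coefficients depend only on the individual index:

    u_j = -m * t_j + sum t           (rate coordinates)
    l_j = t_j * sum t - sum t^2      (start-state coordinates)

so each site's estimates are two banded dot products scaled by lam:

    r_i  = lam * sum_j u_j * s_hat[i, j]
    s0_i = lam * sum_j l_j * s_hat[i, j]

This is O(nm) time and space; no matrix is constructed, multiplied, or
inverted.  Algebraically each site's `(r_i, s0_i)` equals the simple-
regression closed form `r_i = cov(t, s_i)/var(t)`, `s0_i = mean(s_i) -
r_i*mean(t)`; the test suite checks both identities and full elementwise
agreement with an explicit design-matrix `lstsq` solve.

The band indices are half-open, `[(k-1)m, km)` in 0-based terms, giving
exactly m entries per band.  Accumulation runs in ascending j and `lam` is
applied once after accumulation, which keeps results bit-reproducible and
avoids rescaling every coefficient.

## Closed-form time step

For fixed site parameters the RSS is quadratic in each `t_j` separately, so
its unique coordinate minimizer has the rational closed form

    t_j = sum_i r_i * (s_hat[i, j] - s0_i) / sum_i r_i^2,

computed with `sum r^2` as a one-time preprocessing pass — O(nm) in total.
It requires at least one non-zero rate; a squared-rate sum below 1e-300
(effective underflow) is treated as the all-zero error case.  Estimated ages
are returned unconstrained: negative or super-chronological values express
age deceleration/acceleration and are not clipped.

## Operation-count instrumentation

The complexity claims are verified as literal multiplication counts, not
wall-clock times.  The counters tally:

* site step: band construction (`-m*t_j` and `t_j*sum t`, one multiplication
  each, 2m total) plus band application (2nm products with the data), i.e.
  exactly `2nm + 2m`;
* time step: the per-entry products `r_i * (s_hat - s0)` (nm) plus the
  `sum r^2` preprocessing (n), i.e. exactly `nm + n`.

The m squarings inside `sum t^2` and the final 2n scalings by `lam` sit
outside this accounting; they do not change the O(nm) bound and the
convention mirrors how the banded solution's cost is usually stated.

## The CEM driver

The EPM fit alternates exact conditional minimizations — site step, then
time step — starting from the chronological ages (site step first, because
the times are the quantity initialized).  Each half-step is an exact
minimizer of the RSS in its own block, so the RSS trace is non-increasing
and the iteration reaches a local optimum; the trace records both half-steps
to make this maximally visible.  Stopping: the fit ends when the
per-iteration RSS improvement drops to `delta_cem` (default 1e-6, absolute;
a relative mode divides by the iteration's starting RSS for scale
robustness) or after `max_iters` (default 100).  In practice a handful of
iterations suffice on clean pacemaker-structured data.

Because the MC solution is a point in the EPM feasible set, the converged
EPM RSS never exceeds the MC RSS, which is what makes the likelihood-ratio
statistic nonnegative.

### Gauge freedom

For any a != 0 and b, the map `(t, r, s0) -> (a*t + b, r/a, s0 - (b/a)*r)`
leaves every fitted level — and hence the RSS — unchanged.  The model
therefore identifies epigenetic ages only up to an affine frame, pinned in
practice by the chronological-age initialization.  The gauge is deliberately
not penalized or constrained; determinism comes from the fixed
initialization and deterministic half-steps.  All comparisons of estimated
to true e-ages are made after a least-squares affine alignment, and the
headline recovery metric is the Pearson correlation of the aligned
estimates, which is gauge-invariant.

## Model comparison

With Gaussian residuals, twice the log likelihood ratio of the nested fits
is

    chi2 = n*m * ln(RSS_MC / RSS_EPM),

referred to a chi-square distribution with df = m, the number of time
parameters freed under EPM; df is overridable for sensitivity analyses.
Degenerate corner cases: if both RSS are below 1e-20 both models fit to
round-off and the test returns chi2 = 0, p = 1 (no evidence either way); a
zero EPM RSS against a positive MC RSS reports chi2 = +inf with p = 0 and a
warning; an EPM RSS exceeding the MC RSS by more than 1e-9 relative is a
nesting violation and errors, smaller excesses are clamped to ratio 1.  The
asymptotic chi-square calibration is taken on trust at small sample sizes —
the package reports the statistic but makes no small-sample correction.

## Synthetic data

`simulate_mc` and `simulate_epm` generate matrices with the exact structure
the estimator assumes: linear site trajectories, i.i.d. Gaussian noise, and
(EPM mode) a per-individual positive dilation multiplier `c_j` applied to
the chronological age, so the true epigenetic age is `t*_j = c_j * t_j`.
All draws come from one seeded `numpy.random.Generator` in the fixed order
ages, rates, start states, dilations, noise; an EPM run whose dilation
distribution is degenerate at 1 reproduces the MC run for the same seed
draw-for-draw.

Default distributions, chosen as plausible magnitudes for age-informative
array CpGs and used by all tests and demos:

| quantity | default | rationale |
|---|---|---|
| chronological ages | uniform [0, 100] yr | full human lifespan |
| rates | sign * uniform [0.001, 0.01] /yr | ~0.1–1 beta-units over a lifetime; the dead zone below 0.001 keeps every site informative so times stay identifiable |
| start states | uniform [0.1, 0.9] | away from the beta-value rails |
| dilation `c_j` | log-normal, sigma_log = 0.2, median 1 | ~±20% pacemaker tick-rate spread |
| noise sigma | 0.02 | ~a tenth of a typical site's dynamic range |

`sigma_for_snr` derives a noise level from a target mean per-site
signal-to-noise ratio (|r_i| * sd(t*) / sigma averaged over sites); the
headline recovery experiment uses n = 1000 sites, m = 200 individuals and
SNR 5, a size a laptop fits in about a second and large enough for the
time-step averaging (error sd ~ sigma / sqrt(sum r^2)) to make e-ages
sharply identified.

Levels are **not** clipped to [0, 1] by default: the estimator is
linear-Gaussian and clipping breaks the model it assumes.  A `clip` flag
exists for realism demonstrations only.  What the generator does not
emulate: beta-value compression near the rails, batch effects, probe
artifacts, missingness, or correlated noise across sites.  Passing the
recovery tests therefore shows the estimator is correct under its own model
assumptions, not that real 450K data satisfies them.

## Numerical choices and degenerate inputs

* All-equal ages make the normal matrix singular; they are rejected at
  `AgeVector` construction and again in `compute_time_moments`.
* Missing matrix entries are rejected, never imputed — the objective sums
  over all (i, j) pairs and the closed forms assume a complete matrix.
* Site selection (`select_sites`) ranks by |Pearson r| by default (signed
  ranking behind a flag), excludes zero-variance sites, and breaks ties by
  original site order via a stable sort, so results are deterministic and
  invariant under consistent column permutations.
* RSS-trace monotonicity is exact in exact arithmetic; tests allow a 1e-12
  relative slack for accumulation-order round-off.
* The naive design-matrix engine refuses instances whose explicit X would
  exceed 5e7 entries; it exists as a correctness oracle, not a fitter.
* Text round-trips use 17-significant-digit formatting, so write/read cycles
  are bit-stable.

## Known limitations

* The CEM converges to a local optimum; no multi-start or global search is
  attempted.
* Epigenetic ages are identified only up to the affine gauge (see above);
  absolute values depend on the chronological-age anchor.
* The LRT relies on asymptotic chi-square calibration.
* No array-platform preprocessing (IDAT parsing, normalization, batch
  correction) is provided; inputs are assumed to be clean numeric matrices.
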