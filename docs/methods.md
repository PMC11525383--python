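# Methods

## Measurement model

The measurand is the total testosterone concentration C_S (nmol/L) in a
serum sample, measured by triple isotope-dilution LC-MS/MS with bracketing
calibration.  Two standard blends (low/high) and one sample blend are
prepared gravimetrically; each blend's analyte/internal-standard peak area
ratio (R_L, R_H, R_S) is measured, and the sample ratio is linearly
interpolated between the two standards:

    A(R) = (A_H − A_L)/(R_H − R_L) · (R − R_L) + A_L,
    A_H = S_MH·S_C/I_MH,   A_L = S_ML·S_C/I_ML,

    C_S = A(R_S) · (I_MS/W_S) · D_S · (1000/M_W) · P.

Symbols: S_MH, S_ML — mass of standard working solution in the two blends
(mg); I_MH, I_ML, I_MS — internal-standard solution masses in the blends
and sample (mg); W_S — sample mass (mg); D_S — sample density (g/mL);
P — purity of the certified reference material (fraction); M_W — relative
molecular weight (g/mol, carried without uncertainty).  S_C is the mass
fraction (g/g) of analyte in the standard working solution, taken as the
product of the four transfer/total ratios of the gravimetric dilution
chain, S_C = ∏(Q_Si/Q_STi).  The chain formula is an assumption of this
package — the published budget lists the eight masses but not the combining
formula — justified because it is the standard serial-dilution expression
and reproduces the published estimate of 16.019 nmol/L exactly.

Unit bookkeeping: all masses in mg cancel pairwise; the bracket carries g
analyte per g sample, D_S·1000/M_W converts to mol/L, and a single explicit
1e9 factor reports nmol/L.  A unit test pins the worked example so the
conversion cannot silently drift.

The shipped fixture holds the published 20-symbol budget.  Two recorded
fixture notes: (i) the published budget prints the I_ML estimate as 88.98 mg
but its PDF mean as 89.98; the fixture uses 88.98 for both, which is the
value that reproduces every published result (89.98 gives ≈ 15.91 nmol/L);
(ii) purity is stored on the percent scale (94.90 %, u = 0.95 %) with unit
tag `%`, and the loader converts %-tagged quantities to fractions for the
model, so the record stays internally consistent (value = PDF expectation)
while the equation multiplies by 0.949.

## Input-quantity PDFs

* Type A (peak ratios): two runs of five replicate injections; the PDF is
  Gaussian with the replicate mean as estimate and the experimental
  standard deviation of the mean (s/√n, all observations pooled) as
  standard uncertainty.  Zero-dispersion replicate sets raise an error
  rather than assigning u = 0, which would break propagation.
* Type B, balance: Gaussian with the calibration-derived uncertainty
  (0.01 mg for blend and sample weighings, 0.005 mg for solution totals).
* Type B, limits: rectangular R(a, b) with expectation (a+b)/2 and
  standard uncertainty (b−a)/(2√3) — the sample density, R(1.022, 1.026)
  g/mL, u ≈ 0.00115 (rounds to 0.0012).
* Type B, certificate: Gaussian with u = U/k from an expanded uncertainty
  and coverage factor — purity 94.9 % ± 1.9 % (k = 2), u = 0.95 %.

All inputs are treated as mutually independent; t-distributed, asymmetric
or correlated inputs are out of scope.

## Monte Carlo propagation

A block of M trials draws each stochastic input from its PDF, evaluates
the (vectorized) model, and summarizes the M model values by their mean
(estimate), standard deviation with ddof = 1 (standard uncertainty) and a
probabilistically symmetric coverage interval from the sorted values: with
q = floor(p·M), the interval is the pair of order statistics at 1-based
ranks (r, r+q), r = (M−q)/2 rounded to the nearest integer (minimum 1).
This nearest-rank construction is interpolation-free, exactly testable,
and covers at least a fraction p of the sample by construction.

Random streams are split per (root seed, symbol, block index) using
`numpy` `SeedSequence` keyed on a CRC of the symbol.  Consequences: runs
are bitwise reproducible; adding a quantity to a set never perturbs the
draws of the others; and blocks are statistically independent without any
shared-stream bookkeeping.

## Adaptive procedure

Fixed-size Monte Carlo provides no self-diagnosis of how many trials
suffice.  The adaptive procedure repeats blocks and, after block h ≥ 2,
computes for each tracked statistic v ∈ {y, u(y), y_low, y_high} the
standard deviation of the mean of its per-block values,
s = √(Σ(v(r) − v̄)²/(h(h−1))), terminating when 2s ≤ δ for all four.  All
h·M pooled model values then yield the final result.  The tolerance δ is
half a unit in the last meaningful digit of the reported standard
uncertainty: u ≈ 0.30 with two significant digits gives δ = 0.005; the
headline runs tighten this to δ = 0.001.

Parameters and defaults:

* `block_size` — max(⌈100/(1−p)⌉, 10⁴) = 10⁴ at p = 0.95.  The published
  evaluation does not state its per-block M, so only the order of magnitude
  of M_total is comparable: this implementation needs ≈ 2.8 × 10⁶ trials at
  δ = 0.001 and ≈ 1.3 × 10⁵ at δ = 0.005, a ratio near the theoretical
  (δ/δ′)² = 25.
* `max_blocks` — 10⁴; hitting it returns an explicit `converged=False`
  result instead of a silent pass.
* `p` — 0.95; the four statistics are tracked on the reporting scale
  (nmol/L), the same scale as δ.

The per-block trace (h, cumulative M, the four stabilization SDs, running
statistics) is retained on every result and exportable as CSV.  Note that
the h = 2 stabilization SDs are estimated from two blocks only and are
extremely noisy: a statistic can dip under δ at h = 2 and rise again, so
"stabilized fastest/slowest" comparisons should use the last excursion of
2s above δ, not the first dip below it.  Under that reading, the SD of
u(y) stabilizes fastest and that of y_high slowest in a majority of seeded
runs, reflecting the slight right tail of the output distribution.

## GUM route and validation

Sensitivity coefficients are central differences with a step of one
standard uncertainty per input, cᵢ = [f(xᵢ+uᵢ) − f(xᵢ−uᵢ)]/(2uᵢ) — a
scale-free choice in the finite-increment spirit of the framework; for
this nearly linear model they match analytic derivatives to ~10⁻⁴
relative.  Combined uncertainty u_c = √Σ(cᵢuᵢ)², expanded interval
y ± k·u_c with k = 1.96 for p = 0.95 (k = 2 selectable).  The budget ranks
components by |cᵢuᵢ|; on the shipped budget the dominant terms are R_S
(0.199), P (0.160), R_L (0.104), R_H (0.096) and Q_S1 (0.044) nmol/L, and
u_c = 0.2955 nmol/L.

Validation compares interval endpoints: d_low = |(y−U) − y_low|,
d_high = |(y+U) − y_high|, favorable iff both ≤ δ.  `validate_gum` accepts
any externally supplied GUM interval, because a previously reported GUM
result need not be reconstructible from the current budget: the published
evaluation reports u_c = 0.320 nmol/L, about 7 % above the first-principles
LPU value on its own budget, and that budget is not itemized, so the source
of the excess is unrecoverable.  The published "not pass" verdict
(d_low = 0.056, d_high = 0.026 at δ = 0.001) reproduces exactly from the
printed interval against a fresh adaptive run.

## Synthetic raw data

`SyntheticDesign` emulates the acquisitions behind the budget: Gaussian
replicate ratios (2 runs × 5 replicates) whose per-observation SD is
back-calculated as u·√n from the target uncertainty of the mean (only the
means' uncertainties are reported for real data); Gaussian balance
readings at the two calibration tiers; rectangular density limits; and a
certificate purity with expanded uncertainty and coverage factor.  Its
defaults are the study conditions.  A quantity set built entirely from
synthetic raw data recovers the generating concentration within 3 pooled
standard uncertainties in ≥ 95 % of seeded end-to-end runs.

What the generator does not emulate: chromatographic peak integration,
isotope-pattern interference, run-to-run ratio drift (observations are
i.i.d. across runs), balance nonlinearity, or any input correlation.
Passing recovery tests therefore demonstrate the correctness of the
evaluation chain under the stated statistical model, not robustness to
instrument artifacts.

## Numerical choices and limitations

* Problem sizes in the shipped tests and acceptance script: 10⁴-trial
  blocks, one δ = 0.001 run (~2.8 × 10⁶ trials) for the headline
  statistics, ten seeds per tolerance for the cost-scaling ratio, twenty
  seeds at δ = 0.005 for parameter recovery — all chosen so a full
  reproduction runs in well under a minute on one CPU while leaving the
  Monte Carlo standard errors far below the comparison tolerances.
* Degenerate inputs fail loudly: R_H = R_L (undefined bracket), transfer
  mass exceeding its total, zero replicate dispersion, non-positive
  uncertainties.  A scalar R_S outside [R_L, R_H] warns but proceeds,
  since Monte Carlo draws legitimately cross the bracket.
* Ties in the budget ranking keep quantity-set order; budget shares are
  invariant to rescaling the measurand's unit.
* Out of scope: quasi-random or importance sampling, shortest (vs
  symmetric) coverage intervals, second-order GUM terms, correlated
  inputs, effective degrees of freedom, and plotting (histogram and trace
  data are exported as CSV for external tools).
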