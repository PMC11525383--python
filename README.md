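# mcuncert

Measurement-uncertainty evaluation for isotope-dilution mass spectrometry
(IDMS) reference measurements, by two routes:

* an **adaptive Monte Carlo** propagation of distributions (JCGM-101 style):
  repeat fixed-size Monte Carlo blocks until the estimate, the standard
  uncertainty and both coverage-interval endpoints have stabilized to a
  numerical tolerance δ, then pool all trials; and
* the **GUM law of propagation of uncertainty** (LPU): first-order
  combination u_c² = Σ(cᵢ·uᵢ)² with numerical sensitivity coefficients,
  a ranked uncertainty budget, and an endpoint-difference validation of a
  GUM interval against the Monte Carlo one.

The worked measurement is a triple isotope-dilution LC-MS/MS reference
measurement procedure for total testosterone in human serum.  The sample
blend's analyte/internal-standard peak ratio R_S is bracketed between two
standard blends (ratios R_L < R_H), giving the measurand

```
C_S = { [(S_MH·S_C/I_MH − S_ML·S_C/I_ML)/(R_H − R_L)]·(R_S − R_L)
        + S_ML·S_C/I_ML } · (I_MS/W_S) · D_S · (1000/M_W) · P     [nmol/L]
```

with S_C = ∏ᵢ(Q_Si/Q_STi) the mass fraction of analyte in the working
solution from a four-step gravimetric dilution.  The package ships the full
19-component input budget of this measurement (masses with balance-derived
Gaussian uncertainties, type-A replicate peak ratios, rectangular sample
density, certificate purity) as a loadable fixture, and a synthetic-data
generator that emulates the raw acquisitions so the entire evaluation chain
is testable against known ground truth.

Intended users: metrologists and clinical reference-laboratory scientists
who need a tested, scriptable uncertainty engine rather than a spreadsheet
or one-off MATLAB listing.

## Worked example

```sh
$ mcuncert adaptive --delta 0.001 --seed 1
y = 16.023 nmol/L
u(y) = 0.2985 nmol/L
95% CI = [15.448, 16.620] nmol/L
M_total = 2770000 (277 blocks of 10000), delta = 0.001, converged = True
```

The adaptive run added 10⁴-trial blocks until twice the across-block
standard deviation of each of the four tracked statistics fell below
δ = 0.001 nmol/L; the 2.77 × 10⁶ pooled model values give the estimate,
its standard uncertainty and the probabilistically symmetric 95% coverage
interval.  The GUM route on the same budget:

```sh
$ mcuncert gum
y = 16.019 nmol/L
u_c = 0.2955 nmol/L
U = 0.5791 nmol/L (k = 1.96)
interval = [15.440, 16.599] nmol/L
```

and the endpoint comparison of an externally reported GUM interval against
a fresh adaptive run:

```sh
$ mcuncert validate --gum-interval 15.392 16.646 --delta 0.001 --seed 1
aMCM interval: [15.448, 16.620]
d_low = 0.056, d_high = 0.026, delta = 0.001
verdict: not pass
```

Both endpoint differences exceed δ, so that GUM interval is not validated
by the Monte Carlo result: the Monte Carlo output distribution is slightly
asymmetric and narrower than the symmetric y ± 1.96·u_c interval.

The same operations are available as library calls
(`mcuncert.run_adaptive`, `mcuncert.evaluate_gum`, `mcuncert.validate_gum`,
…) and accept any quantity-set JSON, not just the shipped budget.
`mcuncert budget` exports the ranked uncertainty budget (the purity P, the
three peak ratios and the first dilution mass Q_S1 dominate);
`mcuncert simulate` writes synthetic raw replicate/weighing CSVs.

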