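# Methods

This note documents the models implemented in `volatilo`, the assumptions
behind the synthetic-data generator, the parameters that matter, and the
design choices made where the underlying science leaves the design open.

## The measurement being modelled

A headspace sampler injects the volatiles of a milled hop-pellet suspension
onto one GC column whose effluent is split between two detectors: a
drift-tube ion mobility spectrometer (IMS; soft chemical ionisation from a
tritium source, separation by ion mobility) and an EI quadrupole MS (hard
70 eV ionisation, separation by *m/z* over the 50–550 scan range). Each
injection therefore yields a *paired* pair of 2D maps sharing one retention
time axis. In the IMS channel a reactant ion peak (RIP) — the ionised drift
gas — is always present; analytes acquire charge from it by proton
transfer, so product-ion intensity comes at the expense of RIP intensity,
and at high concentration proton-bound dimer (cluster) ions appear in
addition to monomers. Drift times are reported relative to the RIP, which
cancels drift-field and temperature fluctuations.

## Reduced mobility

`mobility.reduced_mobility` implements K = L/(t_d·E) with E = U/L and
K0 = K·(273/T)·(P/760). Defaults: L = 9.8 cm, U = 5000 V, T = 363.15 K
(90 °C), P = 760 Torr (pressure unreported for the reference instrument, so
the correction is unity by default; configurable). The 273 constant is the
conventional reduced-mobility normalisation and is used verbatim, not
273.15. Because K0 ∝ 1/t_d and the RIP drift time cancels in RIP-relative
units, `k0_from_anchor` converts any dt_rel via K0 = k0_a·dt_rel_a/dt_rel;
the default anchor is the shared monoterpene monomer (1.258, 1.630 cm²/Vs).
The packaged seven-compound reference table is consistent with this law:
k0·dt_rel (the implied RIP mobility, ≈ 2.0505 cm²/Vs) varies by less than
0.003 across all thirteen ion species, and anchored recomputation
reproduces every tabulated K0 within 0.002 (rounding of the printed
values).

Peak annotation assigns a detected (rt, dt_rel) apex to a library entry
when both |Δrt| ≤ rt_tol and |Δdt_rel| ≤ dt_tol for some ion species, with
ties broken by the smallest |Δrt|/rt_tol + |Δdt|/dt_tol. The tie-break rule
is our choice (no procedure is standard); it makes annotation deterministic
and invariant to library order. MS match-quality scores carried by the
library are vendor metadata and play no algorithmic role.

## Synthetic data generator

No public raw data exist for this kind of dual-detector hop study, so the
generator is the package's study-condition definition, not a mock. Default
scale: 65 samples spanning 1–18.1 % w/w α-acid, duplicate injections, grids
of 800 RT points (0–16 min, 0.02 min) × 256 drift points (dt_rel 0.9–2.1)
and 501 unit m/z channels (50–550). These desk-scale grids are ~5× coarser
per axis than a real campaign's cubes; all sizes are configurable.

Structure emulated, and how:

* **Charge conservation / RIP depletion.** Each RT row carries a fixed total
  ion charge (default 1000). Product-ion intensity is subtracted from the
  RIP exactly, capped at 95 % depletion so the RIP never vanishes. With
  noise off, row sums equal the total to machine precision — this is the
  generator's strongest invariant and the reason the IMS total ion current
  is uninformative for alignment (see below).
* **Monomer/dimer chemistry.** The cluster-ion fraction follows the
  saturating law f = c/(c + threshold), the simplest form consistent with
  cluster ions growing with concentration; the dimer/monomer ratio f/(1−f)
  = c/threshold is strictly increasing. Per-compound thresholds sit at the
  compound's own concentration scale so both regimes are exercised.
* **Composition ↔ α-acid.** Expected concentrations are affine in α-acid:
  ±70 % swing over the α range, positive for α-/β-pinene, myrcene, limonene
  and β-caryophyllene, negative for linalool and α-humulene, flat for the
  ketones. Myrcene's scale is 25× the next compound (its extreme dominance
  is the defining feature of hop MS data). On top sit multiplicative
  lognormal cultivar (σ = 0.04) and harvest-year (σ = 0.02) random effects
  and per-sample noise (σ = 0.06), all mean-corrected so expectations are
  exact. These magnitudes are free parameters of the simulation (no
  quantitative effect sizes exist to copy); they were calibrated once so
  that the reference analysis below lands at the error scale real IMS
  calibrations of this design report (RMSEP ≈ 1 % α-acid, RE ≈ 10 %).
* **Jitter.** RT jitter is Gaussian (σ = 0.03 min) per injection and shared
  exactly between the IMS and MS cube of that injection (one column feeds
  both detectors). Drift-time variation is *multiplicative* — drift-field
  and temperature fluctuations scale all drift times by a common factor
  (parameterised as grid steps at the RIP, σ = 0.8) — which is precisely
  the disturbance RIP-relative normalisation cancels. An additive
  drift-index shift would be physically wrong and uncorrectable by design.
* **Detector noise.** Additive Gaussian per cell (σ = 0.1) plus a per-run
  lognormal gain (σ = 0.01). The gain term is kept small because a sealed
  tritium source with regulated gas flows is very stable; a large coherent
  gain noise on the intense RIP column would otherwise dominate the PCA
  variance with a chemically meaningless direction.
* **RT marker.** A fixed-intensity early peak (0.5 min, dt_rel 1.12; single
  EI channel at the low scan edge) appears in every run and anchors RT
  alignment. Its identity in real data (a permanent-gas ionisation product)
  is irrelevant to the algorithm; only its constancy matters.
* **Reproducibility.** One root seed; per-injection substreams are derived
  by counter (sample index, replicate), so equal configurations give
  bit-identical cubes and adding samples never perturbs earlier ones.

What the generator does *not* emulate: IMS peak tailing and asymmetry, real
EI fragmentation physics (patterns are fixed stylised vectors), baseline
drift, column bleed, co-elution beyond the compounds listed, and
between-lot heterogeneity of pelletised hops. Passing tests therefore
demonstrate that the pipeline recovers structure *of the kind the analysis
assumes*, not that it is robust to every artefact of real instruments.

## Preprocessing chain

IMS: Savitzky–Golay smoothing (window 7, order 2, along RT — parameters are
our defaults, exposed in config) → RIP location (argmax of the
median-over-RT drift profile, refined to sub-grid precision by parabolic
interpolation) → drift axis divided by the RIP drift time (RIP ≡ 1.0) →
linear interpolation onto a common RIP-relative grid → rigid RT alignment
to the marker → extraction of the closed interval [1.3, 15] min →
replicate mean → unfold (RT outer, drift inner) → mean centering, with
Pareto scaling (x/√s, fitted on training rows only) for regression.
MS: smoothing → RT alignment → clip negatives → log10(1+x) → region →
mean → unfold → centering.

Two non-obvious choices:

* **Marker detection excludes the RIP region.** Charge conservation makes
  the IMS total ion current flat in RT, so the marker apex is found on the
  product-ion region (dt_rel > 1.05) only. On MS cubes the full channel sum
  is used.
* **Single-anchor rigid alignment.** One marker (RT) and one anchor (RIP,
  DT) are the only references the measurement provides, so alignment is a
  rigid shift / a single rescale, not warping. Shifts are recovered with
  parabolic apex refinement and recorded in the provenance log (JSON
  lines); recovery is within one grid step for shifts up to ±5 steps in
  ≥ 95 % of runs (tested).

log10(1+x) (rather than bare log) tolerates empty channels; zero-variance
columns pass through Pareto unscaled so the refold map keeps full length.

## Chemometrics

PCA is computed by SVD of the centered matrix; explained variance is
reported against the total variance so truncated models sum below 100 %.
Hierarchical clustering uses Ward's minimum-variance criterion with
Euclidean distances on the first five PC scores (scipy linkage; a naive
O(n³) Lance–Williams implementation serves as the test oracle). The
train/test split is rank-stratified over the response: the global extremes
are reserved for training, the remaining order statistics divided into
n_test strata with one draw each, so the test set covers the calibration
range while all test predictions are interpolations.

PLS1 is fitted by classical NIPALS: w = X'y/‖X'y‖, t = Xw, p = X't/t't,
q = y't/t't, deflation of X and y, regression vector B = W(P'W)⁻¹q, with
column centering (optionally Pareto) stored in the model and applied to new
samples. Requesting more latent variables than the residual rank raises a
rank error. Stepwise LV selection fits 1…lv_max, and returns the smallest
count whose external RMSEP is within 5 % (relative; our formalisation of
"increase LVs while validation improves") of the curve minimum, flagging
overfitting (RMSEP rising while RMSEC falls) and flat curves (no real gain
over one LV — a warning that the response may be uncorrelated).

Figures of merit: R² and RMSEC are training-fit quantities (R² is paired
with RMSEC as in calibration reporting practice); RMSEP, Bias, SEP
(bias-corrected, n−1 denominator) and RE (%) are test-set quantities. The
identity RMSEP² = Bias² + SEP²(n−1)/n holds to 1e−10 and is property-tested.
Group ellipses use the χ² quantile with 2 df (7.378 at 97.5 %) on the
squared Mahalanobis distance — the asymptotic version, not the small-sample
F-based one. α-acid groups: low ≤ 6.9, middle 7.0–10, high > 10 (% w/w),
with values rounded to one decimal first so the gap (6.9, 7.0) cannot fall
between groups; 10.0 is middle (the middle interval is closed above).

## Reference analysis and problem sizes

The package's reference experiment — run by `tests/test_acceptance.py` and
reproducible from the README example — simulates 65-sample duplicate
studies at the default desk-scale grids, applies the full IMS chain, and
fits the 5-LV Pareto-scaled PLSR on the 55/10 split. Across 20 seeded
repetitions the prediction R² is ≥ 0.9 and RE ≤ 15 % in at least 90 % of
runs, and the low/middle/high α-acid group means are monotonically ordered
along PC1. Each repetition takes a few seconds at these grid sizes, chosen
so the whole reference analysis completes in minutes on one CPU.

## Known limitations

* The EI fragment patterns are stylised; spectral-library matching against
  real spectra is out of scope (vendor match algorithms are proprietary).
* Alignment is rigid; retention-time warping (COW/DTW) is deliberately not
  implemented.
* The absolute figures of merit of any real campaign depend on reference
  α-acid values (typically taken from package labelling, with their own
  error) and are not recoverable from simulation; only the *structure* of
  the analysis and the scale of achievable errors are.
* `select_lv` uses a single external split, mirroring the single-split
  validation design; a cross-validation utility is intentionally absent.
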