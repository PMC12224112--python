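# Methods

This package analyses 1:1 host–guest binding of fluorescent probes to a
macrocyclic host (cucurbit[7]uril, CB7) and the indicator displacement
assay (IDA) built on such a probe. Everything is driven by two
equilibria and standard photophysical and thermodynamic relations; this
note records the models, the numerical choices, and what the synthetic
data do and do not establish.

## Equilibrium models

**Binary.** H + G ⇌ HG with association constant
K_b = [HG]/([H][G]) (L/mol). Given totals H_T, G_T, the free host h
satisfies the quadratic

    K h² + (1 + K (G_T − H_T)) h − H_T = 0 ,

whose unique non-negative root is evaluated with the cancellation-free
q-formulation (q = −½(b + sign(b)√(b²−4ac))). Solving for *free host*
rather than for [HG] matters numerically: with K up to 10⁸ L/mol at
micromolar totals, [HG] approaches min(H_T, G_T) and the free species
computed by subtraction lose most of their significant digits, whereas
[G] = G_T/(1+Kh) and [HG] = Kh[G] reproduce K exactly by construction.
The textbook quadratic in [HG] has two positive roots; the free-host
formulation selects the physical one (0 ≤ [HG] ≤ min(H_T, G_T))
automatically.

**Competitive.** An indicator I and a guest G compete for H with
stepwise constants K1 = [HI]/([H][I]) and K2 = [HG]/([H][G]).
Eliminating [I] and [G] via their mass balances turns the host balance
into a cubic in free host:

    K1K2 h³ + [K1 + K2 + K1K2(I_T + G_T − H_T)] h²
            + [1 + K1(I_T − H_T) + K2(G_T − H_T)] h − H_T = 0 .

This cubic was derived here directly from the two equilibrium
definitions and three mass balances; published forms of the same
displacement cubic in terms of [HI] circulate with typographical
inconsistencies in the coefficient symbols and do not unit-check as
printed, so the derivation above is the normative algebra and is
validated against an independent oracle. The solver takes the
companion-matrix roots, keeps the root in [0, H_T] (the host balance is
strictly increasing in h, so exactly one exists), polishes it with
Newton steps, and falls back to the oracle with a logged warning if
root classification is ever ambiguous.

**Oracle.** `oracle_equilibrium` brackets the free-host balance on
[0, H_T] with Brent's method plus one Newton step. It is deliberately
independent of the closed forms and is the ground truth in the test
suite (10³ random systems agree to 10⁻⁹ relative; mass-balance
residuals stay below 10⁻¹² × totals).

Scope: 1:1 complexes only; activities equal concentrations; no
ionic-strength corrections.

## Titration fitting

Observed fluorescence is modelled as a speciation-weighted sum of
limiting intensities:

* direct (host titrated into reporter): I = X_HG·I_HG + X_G·I_G with X
  the reporter mole fractions (they sum to 1 exactly because both come
  from one speciation call);
* displacement (guest titrated into host+indicator):
  I = ([HI]·I_HI + [I]·I_I)/I_T;
* pH titrations use the single-protonation sigmoid
  A(pH) = (A_acid + A_base·10^(pH−pKa))/(1 + 10^(pH−pKa)); at the
  fitted pKa the curve equals the mean of the plateaus identically.

Fits are bounded nonlinear least squares (scipy `least_squares`, TRF)
over (log₁₀K, two intensities). log-parameterizing K conditions the
problem; K is reported in L/mol. Five log-spaced starts across
10⁴–10⁹ L/mol guard against flat-in-log-K objectives; the best-so-far
cost after each start is recorded and is non-increasing by
construction. Ties are broken toward the smaller log K. Both limiting
intensities float by default (an `init` argument can pin them). The
displacement fit holds K1 fixed — the two-step procedure in which the
indicator is characterized first — rather than fitting K1 and K2
jointly.

Weighting: unweighted residuals by default (the appropriate choice when
the instrument noise model is unknown). `weighting="relative"`
minimizes relative residuals and is the right choice for the synthetic
data, whose declared noise model is proportional Gaussian; weights are
re-derived from the fitted curve in two reweighting passes (IRLS),
because weighting by the noisy observations themselves biases a
relative-error fit.

Uncertainty: residual-resampling bootstrap (percentile 95% intervals,
≥200 resamples, seed-deterministic bit for bit; refits start from the
point estimate with the original weights held fixed). Curvature-based
intervals from the Jacobian are attached to every fit but labelled
approximate. A coverage simulation (100 outer replicates of the
strong-binder design at 2% noise, 500 resamples) keeps empirical
coverage of the 95% interval at or above 90%.

Degenerate and pathological inputs: a (near-)constant signal raises a
degenerate-data error rather than returning an unidentified K; pH fits
are flagged unreliable when the sampled range spans < 2 units or the
fitted pKa leaves the sampled range by > 1 unit; a displacement series
whose signal *rises* with added guest warns that the direction is
inconsistent with a turn-on indicator.

## Photophysics

Relative quantum yields follow the gradient method:
ϕ_x = ϕ_s (Grad_x/Grad_s)(n_x²/n_s²), with Grad the OLS slope of
integrated emission versus absorbance (intercept floated to absorb
instrumental background) and n the refractive indices, which are
explicit inputs. Absorbances above 0.1 trigger an inner-filter
warning; computed yields above 1 are an error, never clipped. The
reference standard in the reproduced study is Coumarin-153 in ethanol
(ϕ_s = 0.53).

Time-resolved decays are fitted by iterative reconvolution: the model
is the discrete convolution of the measured IRF (normalized to unit
area, with a fitted global time shift) with a one- or two-exponential
decay. The fit maximizes the Poisson likelihood, implemented as least
squares on signed square-root deviance residuals. This choice was
validated on synthetic data: chi-square weighting by the observed
counts (1/max(y,1)) biased the short lifetime of the two-component
benchmark by −20 to −37% at 10⁵ total counts — far beyond the 6.8%
Cramér–Rao bound — while the likelihood fit is unbiased to within that
bound. Goodness of fit is the reduced deviance (≈1 when the model
holds; > 2 warns). Reported `fractions` are intensity fractions
(percent of detected photons per component, a_iτ_i/Σa_jτ_j), the
quantity commercial TCSPC software prints beside each lifetime; they
sum to 100 exactly. A shortest lifetime below one bin width flags
probable scatter. Component count is user-chosen (1 or 2), never
selected automatically.

## Thermodynamics, window, calibration

ΔG = −RT ln K with R = 1.9872×10⁻³ kcal mol⁻¹ K⁻¹ and a 1 mol/L
standard state. Calorimetric conversions default to 298.15 K; binding
constants derived from molecular-dynamics free energies use 300 K, the
simulation temperature, which reproduces the published theoretical
constants to −1.5% and −0.4% (298.15 K does not). Consistency checks
flag discrepancies above 0.1 kcal/mol between ΔG, ΔH + (−TΔS) and
−RT ln K, and classify binding as enthalpy-driven when |ΔH| > |TΔS|.

An IDA can quantify analytes with log K_HI − 2 ≤ log K_HG ≤
log K_HI + 1 — a window exactly three decades wide around the
indicator's constant.

Calibration is ordinary least squares with σ = √(SSR/(n−2)); the
detection limit is 3σ/|slope| by default (3.3σ available by flag).
With absorbance as signal and a 1 cm path the same routine extracts a
Beer–Lambert molar absorptivity.

## Synthetic data: what it emulates and what it does not

Each generator mirrors one experiment with known ground truth and an
explicit seed (one named numpy generator per call; bit-reproducible).
Fluorescence titrations default to 2% proportional Gaussian noise — a
typical photometric repeatability; TCSPC histograms carry true Poisson
statistics by construction (photon arrival times are sampled as an
exponential mixture convolved with a Gaussian IRF, with out-of-window
arrivals redrawn so the histogram holds exactly the requested counts;
component i contributes `fractions_percent[i]`% of the photons, the
same intensity-fraction convention the fitter reports).

The replica designs bundle the study's own compositions (reporter
1.6 µM with host 0–70 µM; reporter 1 µM with host 0–3 µM; indicator
and host 1 µM with guest 0–5 µM; calibration 0.5–3 µM designed so the
constructed detection limit is 0.24 µM; biexponential decay at
τ = 1.21/3.56 ns, 13.68/86.32%). Within each published concentration
range the 15 injection points are placed by local D-optimality for the
binding constant: clusters at zero, near the equivalence point, and on
the plateau, the way one designs a titration for constant estimation
rather than curve display. Even so, the information content of a
single 15-point titration at 2% proportional noise is limited: the
Cramér–Rao bound on K is ≈10% relative sd for the two direct designs
and ≈5% for the displacement design, i.e. comparable to the published
uncertainties (±0.8×10⁶ on 7.5×10⁶; ±0.1×10⁷ on 1.1×10⁷). Recovery of
the generating constant on any *single* seeded realization therefore
scatters across the published error bars by construction; the fitters
themselves are unbiased (Monte-Carlo bias ≤ 0.5%) and sit at the
information limit. Noiseless generator output is inverted by every
fitter to 10⁻⁴ relative.

What the generators do **not** emulate: full emission spectra,
inner-filter effects, photobleaching, baseline drift, detector
afterpulsing or color shift, pipetting (x-axis) error, or pH-electrode
error. Passing round-trip tests therefore demonstrates correctness of
the estimators under the declared noise models, not robustness to
every artifact of real instruments.

The pH-titration ground truths (pKa 5.0 free, 3.5 complexed) are
plausible mid-acidic values chosen for round-trip studies; the
reproduced study reports the shift qualitatively (negative, unusually
large) without printed pKa values.

## Numerical details

* Quadratic/cubic root selection as above; competitive cubic polished
  by 3 Newton steps; oracle tolerance `brentq` at machine precision
  plus one Newton step.
* `least_squares` tolerances 10⁻¹⁵ (titration) / 10⁻¹² (decay);
  decay amplitudes bounded ≥ 0, lifetimes ≥ 10⁻³ bin widths, shift
  within ±20 bins.
* Bootstrap refit failures above 20% attach a warning to the
  intervals; failed refits are excluded.
* All concentrations are mol/L internally and in files; a `--units uM`
  flag rescales on read. No unit inference from column names.
* Problem sizes used by the reproduction pipeline: 15-point
  titrations, 10⁴-count decay histograms (10⁵ in recovery tests,
  2×10⁶ in the high-count limit test), 500 bootstrap resamples, 100
  coverage replicates.

## Known limitations

* Single-wavelength models only; no global multi-wavelength fitting.
* 1:1 stoichiometry only; no 2:1/1:2 or cooperative models.
* The displacement fit requires a trustworthy K1; errors in K1
  propagate into K2 and are not reflected in its intervals.
* ITC enthalpograms are not fitted; only published ΔH/ΔG/K values are
  consumed.
* Lifetime analysis offers no automatic model selection and no
  lifetime-distribution methods.
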