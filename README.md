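# hgida — host–guest binding analysis for fluorescent indicator displacement assays

`hgida` is a small analysis toolkit for supramolecular binding studies
in which a fluorescent probe forms a 1:1 inclusion complex with a
macrocyclic host (here cucurbit[7]uril, CB7) and is then used as the
indicator of a displacement assay (IDA) for a competing analyte such as
methyl viologen. It is written for the bench scientist who has
titration curves, pH scans, quantum-yield tables and TCSPC histograms
and wants binding constants, pKa shifts, lifetimes and detection limits
with honest uncertainties.

The core quantities:

* **1:1 binding**, H + G ⇌ HG, K_b = [HG]/([H][G]); the observed
  intensity of a direct titration is I = X_HG·I_HG + X_G·I_G with X the
  reporter mole fractions from the exact speciation.
* **Competitive displacement**, H + I ⇌ HI and H + G ⇌ HG; free host
  solves a cubic derived from the two equilibria and three mass
  balances, and I = ([HI]·I_HI + [I]·I_I)/I_T. The analyte constant K2
  is fitted with the indicator constant K1 held fixed. An IDA resolves
  analytes within log K_HI − 2 ≤ log K_HG ≤ log K_HI + 1.
* **Thermodynamics**, ΔG = −RT ln K and ΔG = ΔH − TΔS
  (R = 1.9872×10⁻³ kcal mol⁻¹ K⁻¹), with cross-consistency checks.
* **Photophysics**, relative quantum yields
  ϕ_x = ϕ_s(Grad_x/Grad_s)(n_x²/n_s²) and lifetimes by Poisson-likelihood
  IRF-reconvolution fitting of TCSPC histograms.
* **Calibration**, OLS line with LOD = 3σ/|slope|.

A seeded synthetic-data module generates every input with known ground
truth (configurable noise), so the whole pipeline is testable without
instrument data.

## Worked example

Simulate the strong-binder direct titration (reporter 1 µM, host
0–3 µM, true K = 1.1×10⁷ L/mol, 2% relative noise) and fit it:

```bash
$ hgida simulate direct_dq2 --out dq2.csv --seed 7
wrote dq2.csv and dq2.meta.json

$ hgida fit-direct dq2.csv --reporter-total 1e-6 --weighting relative \
        --bootstrap 500 --seed 7
{
  "k_bind": 10993164.926896222,
  "i_free": 99.99358519270348,
  "i_bound": 1794.823573537755,
  ...
  "bootstrap_ci_95": {
    "k_bind": [9458125.886985771, 12706684.949163407],
    ...
  }
}
```

The fitted constant 1.10×10⁷ L/mol recovers the generating value
(truth recorded in `dq2.meta.json`); the bootstrap interval
[0.95, 1.27]×10⁷ reflects the real dispersion of a 15-point titration
at 2% noise. The limiting intensities are the free-probe and complex
emission levels. The applicability window of an IDA built on this
indicator:

```bash
$ hgida ida-window 1.1e7
{
  "log_lower": 5.041392685158225,
  "log_upper": 8.041392685158225,
  "width": 3.0
}
```

i.e. analytes binding between ~10⁵ and ~10⁸ L/mol can be quantified.

Other commands: `fit-ida`, `fit-pka`, `qyield`, `lifetime`,
`thermo check`, `calibrate`, `simulate`, `repro` (see `hgida --help`).

## Analysis pipeline

The `analysis/` scripts re-derive the study's numbers end to end and
write tables under `results/`:

1. `01_simulate_experiments.py` — seeded synthetic replicas of every
   experiment (titrations, pH scans, calibration, TCSPC pair).
2. `02_thermo_consistency.py` — thermodynamic cross-checks and
   MD-to-constant conversions.
3. `03_binding_fits.py` — direct-titration fits with bootstrap CIs.
4. `04_ida_assay.py` — displacement fit, window check, LOD, pKa shift.
5. `05_photophysics.py` — quantum-yield fold changes and lifetime fit.

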