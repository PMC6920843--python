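# nmrdfit

Analysis of ¹H spin–lattice relaxation dispersion (NMRD) profiles of solid
proteins measured by fast-field-cycling relaxometry:

* **Forward models** (`nmrdfit.models`) — the homonuclear ¹H–¹H "model-free"
  contribution (three Lorentzian dispersion terms + a frequency-independent
  offset *A*), the closed-form ¹H–¹⁴N contribution carrying the quadrupole
  relaxation enhancement (QRE) peaks at the ¹⁴N transition frequencies
  ν₋, ν₊, ν₀, its extreme-narrowing limit, and dipolar-constant ↔
  inter-spin-distance conversions.
* **Stochastic-Liouville solver** (`nmrdfit.sle`) — reference computation of
  the ¹H–¹⁴N rate valid at arbitrary ω_Q·τ_Q, used to map the validity range
  of the closed-form expression (`validity_scan`).
* **Staged fitting pipeline** (`nmrdfit.fitting`) — quadrupole-peak detection
  on a baseline-subtracted profile → (a_Q, η) fixed from the peak positions →
  τ_Q initialized from the peak widths (adjustable by at most ±10%) →
  weighted nonlinear least squares of the ten adjustable model parameters →
  per-component decomposition.
* **Synthetic data** (`nmrdfit.synthetic`) — canonical parameter sets for the
  four samples (elastin, AHP, BSA, lysozyme) and a reproducible profile
  generator (log-spaced grid, peak-window densification, multiplicative
  Gaussian noise).
* **I/O + CLI** (`nmrdfit.io`, `nmrdfit.cli`) — schema-versioned profile CSV
  and fit JSON formats with config echo and checksums.

Unit conventions: frequencies in MHz at every interface (ω = 2πν internally),
rates in s⁻¹, correlation times in s, angles in degrees, dipolar relaxation
constants in rad² s⁻².

## CLI

```bash
# synthetic profile for one of the canonical parameter sets
nmrdfit simulate --protein lysozyme --noise-cv 0.02 --seed 7 --out profile.csv

# quadrupole-peak detection -> (a_Q, eta) and initial tau_Q
nmrdfit peaks --in profile.csv --window 0.5:3.5 --out peaks.json

# staged ten-parameter fit (optionally with fixed quadrupole parameters)
nmrdfit fit --in profile.csv --peak-window 0.5:3.5 --out fit.json
nmrdfit fit --in profile.csv --fix-aq 3.36 --fix-eta 0.42 --out fit.json

# per-component curves of a stored fit
nmrdfit decompose --fit fit.json --out components.csv

# SLE vs closed-form validity scan
nmrdfit sle-validate --aq 3.4 --eta 0.4 --x 1,2,25 --out scan.csv \
    --summary-out summary.csv

# dispersion/decomposition/peak-window plots
nmrdfit report --in profile.csv --fit fit.json --out plots/
```

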