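# dsbkin

Kinetic modelling of radiation-induced DNA double-strand-break (DSB)
rejoining in *Saccharomyces cerevisiae*, with maximum-likelihood fitting
and information-theoretic model selection.

## The problem

After ionizing radiation, most DSBs are rejoined within 1–2 h, some only
over many hours, and some essentially never. How these fractions depend
on radiation dose and dose rate matters for modelling cytotoxicity (for
example in radiotherapy). The large pulsed yeast datasets — sparsely
ionizing 30 MeV electrons at 7800 Gy/h (single and split doses) plus
⁶⁰Co γ-rays at ≈33 Gy/h, and densely ionizing α-particles at 1400 Gy/h —
show *upwardly curving* dose responses for DSBs remaining at long times,
which classical quadratic-interaction models cannot reproduce.

`dsbkin` implements three compartmental models of the mean DSBs per cell
in three classes (quickly rejoinable DSB₁, slowly rejoinable DSB₂,
unrejoinable DSB₃) during and after exposure at piecewise-constant dose
rate R (Gy/h):

**Radiation-dependent conversion (RD)** — radiation converts DSB classes
into harder-to-rejoin ones at rates proportional to dose rate:

```
dDSB₁/dt = k₁R − (v₁ + q₁R)·DSB₁
dDSB₂/dt = k₂R − (v₂ + q₂R)·DSB₂ + q₁R·DSB₁
dDSB₃/dt = k₃R + q₂R·DSB₂
```

with yields k᎐ (Gy⁻¹), rejoining rates v᎐ (h⁻¹) and conversion
coefficients q᎐ (Gy⁻¹); 7 parameters. The system is linear on each
constant-R segment and is solved in closed form (exponential cascade with
guarded degenerate cases).

**Two-lesion kinetic (TLK)** — linear rejoining λ᎐, radiation-independent
fixation ε᎐ into the unrejoinable class, and pairwise DSB interactions
η₁, η₂, η₁₂ (quadratic removal); 10 parameters, solved numerically.

**LPL-type reduction** — one rejoinable class with linear + quadratic
removal plus an unrejoinable class; 4 parameters.

Fitting maximizes the profiled Gaussian log-likelihood

```
LL = −(N/2)·( ln(SSE/N) + ln 2π + 1 )
```

over parameters constrained ≥ 0, from many random starts (SQP-type local
optimizer). Model ranking uses AICc = −2LL + 2K + 2K(K+1)/(N−K−1) and
evidence ratios exp(−ΔAICc/2); 95% CIs come from Monte-Carlo sampling of
the likelihood within the χ²₁(0.95)/2 contour. A synthetic-data module
generates datasets at the published exposure designs with additive
Gaussian noise for end-to-end validation.

## Worked example

```python
from dsbkin import ExposureProtocol, rd_predict, tlk_predict
from dsbkin import reference

hdr = ExposureProtocol.single_dose(2400, 7800, 72)   # 2400 Gy, 7800 Gy/h, assay 72 h later
ldr = ExposureProtocol.single_dose(1650, 33, 22)     # protracted γ exposure

print(round(rd_predict(reference.RD_SPARSE, hdr), 1))   # 28.4
print(round(tlk_predict(reference.TLK_SPARSE, hdr), 1)) # 19.5
print(round(rd_predict(reference.RD_SPARSE, ldr), 1))   # 4.0
print(round(tlk_predict(reference.TLK_SPARSE, ldr), 1)) # 16.8
```

With the published joint-fit parameters, the RD model predicts 28.4
unrejoined DSBs/cell 72 h after the acute 2400 Gy exposure (measured
mean: 30.2), while the TLK model predicts only 19.5 — it misses the
upward curvature at high dose. After the protracted low-dose-rate
exposure the RD model predicts 4.0 (measured: 5.6) whereas the TLK model
overshoots at 16.8: a single TLK parameter set cannot describe high- and
low-dose-rate data together.

The same is available from the shell:

```sh
dsbkin predict --model rd --dose 2400 --dose-rate 7800 --time 72   # 28.42
dsbkin simulate --radiation-class sparsely_ionizing --seed 1 --out data.csv
dsbkin fit --model rd --data data.csv --starts 100 --seed 1 --out fit_rd.json
dsbkin fit --model tlk --data data.csv --starts 100 --seed 1 --out fit_tlk.json
dsbkin compare --data data.csv --fit-file fit_rd.json --fit-file fit_tlk.json
```

An end-to-end simulate → fit → compare run on RD-generated data ranks
the RD model first by hundreds of AICc units over both the TLK model and
an RD variant whose class conversion is made independent of dose rate —
the model-selection signature that identifies radiation-driven
conversion as the operative mechanism.

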