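# bactoseries

Seasonal/trend decomposition and standing-stock analysis of coastal
bacterioplankton monitoring time series.

## The problem

Monthly oceanographic monitoring of temperate coastal waters produces a
decade-scale record of heterotrophic bacterioplankton standing stocks:
flow-cytometric abundance, mean cell size and biomass of the low (LNA)
and high nucleic-acid content (HNA) groups, alongside temperature,
stratification, nutrients and chlorophyll averaged over the upper mixed
layer. Two ecological rules organize the expectations for such records:
the temperature–size rule (TSR: warmer water, smaller cells) and the
abundance–size rule (ASR: more cells, smaller cells). Testing them on
monthly data requires separating seasonality, decadal trends and
month-to-month persistence before any cross-variable correlation is
believed — otherwise two series that merely share an annual cycle appear
strongly "correlated".

`bactoseries` implements that full workflow as a tested library:

* **synthetic** — generators for every input (monthly series, CTD casts,
  cytogram event tables, incubation tables) with known ground truth;
* **hydrography** — mixed-layer depth by the 0.05 kg m⁻³-per-5 m density
  criterion, stratification index (T₀ − T₇₅)/75, upper-mixed-layer means;
* **cytometry** — LNA/HNA gating on green fluorescence × right-angle
  light scatter, abundance from calibrated flow rates, cell volume from a
  power-law RALS→diameter calibration, carbon via
  pg C cell⁻¹ = 0.12 · V^0.72;
* **decomposition** — the additive model
  x_t = x̄ + b·t + Σᵢ Aᵢ·cos(2πt/Tᵢ − θᵢ) + η_t, η_t = φ·η_{t−lag} + ε_t,
  with Fisher G-test periodicity detection, an exact %-of-variance ledger
  per retained component, and the month of the cycle maximum
  T_max = θT/2π;
* **residuals** — pre-whitened (ε_t) Pearson correlation matrices with
  0.001/0.01/0.05 star bands;
* **experiments** — model I regressions of bottle mean cell size on
  incubation temperature (µm³ °C⁻¹), cross-group slope coupling,
  April–July window means and decadal warming trends, and projected
  community size change under a warming scenario.

## Worked example

```python
from bactoseries import decompose, generate_series
from bactoseries.synthetic import decadal_scenario

series = generate_series(decadal_scenario(seed=1)["temperature"])
fit = decompose(series)
```

Running `python examples/01_simulate_and_decompose.py` prints:

```
climatological mean: 15.60 degC (truth 15.7)
harmonic: T=12 mo, A=3.85 degC, theta=4.32 rad, peaks at month 8.26, 78.6% of variance
AR term: lag 1, phi=0.31, 1.8% of variance
total explained: 80.4%
```

The generated decade had a true annual cycle of amplitude 3.89 °C peaking
8.14 months after the April start (late summer), lag-1 autocorrelation
0.34, and noise calibrated so the cycle carries ~80% of the variance; the
fit recovers all of it, and the ledger total is the exact sum of the
component shares. The other scripts in `examples/` walk through gating
(`02`), hydrography (`03`), the temperature–size incubations (`04`),
pre-whitened correlation (`05`) and the end-to-end pipeline (`06`).

A thin CLI mirrors the stages:

```bash
bactoseries all --seed 5 --out-dir out/       # full synthetic pipeline
bactoseries decompose out/inputs/uml_series.csv --out-dir out/
```

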