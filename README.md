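# ftranskit

Signal processing for continuous, label-free optical biosensing with
resonant-nanostructure transducers, built around the **Ftrans-area
readout**: instead of tracking the resonance wavelength frame by frame, each
acquired spectrum is divided by a fixed reference spectrum and the per-unit
ratio

```
Ftrans(λ, t) = I_sig(λ, t) / I_ref(λ)
```

is integrated over a fixed wavelength window Δλ (default 554–580 nm):

```
A(t) = ∫_Δλ Ftrans(λ, t) dλ          [nm]
```

`A(t)` forms a sensogram whose plateau steps calibrate the assay:

* analyte sensitivity  `m = ΔA / ΔC`  (nm per µg/mL),
* readout uncertainty  `U = Δλ · ΔI`  (window width × baseline
  peak-to-peak Ftrans variation, nm),
* limit of detection  `LoD = U / m`  (µg/mL).

The package is for analytical scientists and instrument developers working
with refractometric sensors (resonant nanopillar arrays, photonic-crystal
cavities, and similar narrow-resonance transducers) who need a tested,
reproducible path from raw time-stamped spectra to sensitivity and LoD
figures. Because no public spectral datasets exist for this device class, a
fully parameterized instrument simulator — resonance line shape, bulk and
surface transduction, plug-flow transport delay, Langmuir binding with acid
regeneration, and multiplicative detector noise — is part of the package
and backs the test suite.

## Worked example

Simulate the default antibody/antigen run (buffer → anti-IL-8 at 50 µg/mL →
IL-8 at 5 µg/mL → acid regeneration → second IL-8 association, through a
126 µL chamber at 50 µL/min), process it to a sensogram, and calibrate:

```
ftranskit simulate --seed 1 --stack stack.csv --reference ref.csv \
                   --write-scenario scenario.yaml
ftranskit process  --stack stack.csv --reference ref.csv \
                   --scenario scenario.yaml \
                   --sensogram sensogram.csv --segments segments.json
ftranskit calibrate --sensogram sensogram.csv --segments segments.json \
                    --concentration 5 --report report.json
ftranskit report --report report.json
```

which prints:

```
| quantity | value |
| --- | --- |
| bulk sensitivity S (nm/RIU) | n/a |
| analyte sensitivity m (nm per ug/mL) | 0.092 |
| window width (nm) | 26 |
| baseline p2p (per-unit) | 1.82e-05 |
| uncertainty U (nm) | 0.000472 |
| LoD (ug/mL) | 0.00513 |
| LoD (ng/mL) | 5.13 |
```

Reading the numbers: the baseline sensogram sits at the window width
(26 nm); antibody immobilization raises the area by 0.92 nm (plateau
26.92 nm) and antigen recognition by a further 0.46 nm (plateau 27.38 nm),
so the two-point sensitivity is `m = 0.46 nm / 5 µg/mL = 0.092 nm per
µg/mL`. At the simulated noise level (multiplicative sd 5e-5) the baseline
area variation gives `U = 4.7e-4 nm` and hence an LoD of ~5 ng/mL; LoD
scales linearly with the injected noise. The same computation with the
classic worked-example inputs (`ΔA = 0.44 nm`, `ΔC = 5 µg/mL`,
`U = 0.002 nm`) gives `m = 0.088` and `LoD = 22.7 ng/mL`.

The same functions are importable directly:

```python
import ftranskit as fk

scenario = fk.il8_scenario(seed=1)
stack, truth = scenario.run(seed=1)
sensogram = fk.build_sensogram(stack, scenario.reference_spectrum())
segments = fk.segment_phases(sensogram, schedule=scenario.schedule)
report = fk.calibration_report(sensogram, segments,
                               analyte_concentration_ug_mL=5.0)
print(report.analyte_sensitivity_nm_per_ug_mL)   # 0.0920 (true value 0.092)
```

Bulk (refractometric) calibration works the same way: simulate or load a
liquid series, track the resonance, and fit:

```python
readings = [fk.BulkReading(1.33, 566.0), fk.BulkReading(1.37, 580.0)]
fk.bulk_sensitivity(readings)                    # 350.0 nm/RIU
```

See `docs/methods.md` for the model, its assumptions, all defaults, and
known limitations.

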