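# Methods

## The readout

A resonant-nanostructure transducer (a Bragg-stack nanopillar array with a
central cavity) transmits light only in a narrow resonance inside a photonic
stop band. The resonance wavelength shifts with the bulk refractive index of
the surrounding medium and with the mass bound to the sensor surface. Rather
than tracking the resonance position frame by frame, the readout implemented
here forms the per-unit spectral ratio

    Ftrans(λ, t) = I_sig(λ, t) / I_ref(λ)

against a fixed reference spectrum (the bare sensor in buffer) and integrates
it over a fixed wavelength window Δλ = [554, 580] nm:

    A(t) = ∫_Δλ Ftrans(λ, t) dλ      [nm]

For identical signal and reference, `Ftrans ≡ 1` and `A` equals the window
width (26 nm). When the resonance in the signal spectrum shifts relative to
the reference, the ratio develops a dispersive peak/dip pair; because the
peak lobe (where the reference feature divides a small number) outweighs the
dip lobe, the area rises monotonically with the shift for shifts up to about
one FWHM. This is verified numerically (`area_shift_response`) rather than
assumed. Averaging over the whole window is what makes the statistic less
noisy than any single-wavelength or peak-position readout.

The sensogram `A(t)` is segmented into baseline / association / plateau /
regeneration phases; plateau step amplitudes calibrate the analyte
sensitivity `m = ΔA / ΔC` (nm per µg/mL) and, with the baseline uncertainty
`U = Δλ · ΔI` (window width times the baseline peak-to-peak Ftrans
variation), the limit of detection `LoD = U / m`.

## Numerical choices

* **Quadrature.** Composite trapezoid on the native wavelength grid, with
  linear interpolation of the curve at the window endpoints. The rule is
  exact for the unit curve on grid-aligned windows and bit-reproducible; a
  grid-refinement test bounds the discretization error of smooth curves at
  <1e-4 relative.
* **Ratio clamping.** Reference intensities below `ε = 1e-9 · max(ref)` are
  clamped (with a warning) so the ratio stays finite near detector dark
  levels.
* **Peak localization.** The extremal sample inside the search window is
  refined by a 3-point parabolic fit, which is exact for quadratic signals
  and within 0.02 nm of a 100×-denser-grid argmax for Lorentzian features
  wider than ~10 grid steps. An extremum on the window edge returns the raw
  sample with a warning; a flat window raises "no resonance".
* **Peak-to-peak.** Literal max−min by default (the convention used for
  baseline variation); a quantile mode (0.5%–99.5%) is available because the
  literal statistic is unbounded under heavy-tailed noise.
* **Grid identity.** Two grids are "the same" within 1e-6 nm; spectra from
  one acquisition share a grid by construction.
* **Areas are reported raw** (baseline ≈ window width, e.g. ~26 nm), not
  baseline-subtracted; `excess_area` provides the subtracted view for
  plotting only.

## The synthetic instrument

No public spectral data exist for this class of device, so the package ships
a forward model used both as the test fixture generator and as a study tool.

* **Line shape.** Lorentzian dip (default) or Fano profile of FWHM 2 nm and
  fractional depth 0.8 on a unit background, centred at 566 nm inside a
  550–588 nm stop band. The depth is chosen so that the area–shift response
  spans ~2 nm of dynamic range — comfortably covering the ~1.4 nm of
  combined immobilization + recognition signal — while staying monotone over
  one FWHM. The deliberately simple profile means the simulator probes the
  signal-processing chain, not electromagnetic realism.
* **Transduction.** `shift = S·(RI − RI_ref) + σ_rec·Γ_rec + σ_ana·Γ_ana`
  with bulk sensitivity S = 350 nm/RIU at RI_ref = 1.33 (water) and one
  surface coefficient per bound species (receptor and analyte), clipped at a
  ±50 nm guard. Linearity in both terms is an explicit modelling assumption.
* **Transport.** Plug flow: a reagent switched at the pump reaches the
  sensor after `t_d = 60·V/Q` seconds (126 µL chamber at 50 µL/min →
  151.2 s, matching the ~150 s fill delay seen on the instrument). No Taylor
  dispersion: concentration changes are instantaneous after the delay.
* **Kinetics.** First-order Langmuir binding
  `dΓ/dt = kon·C·(Γmax − Γ) − koff·Γ`, propagated with the exact closed form
  within each constant-concentration interval (tested against an independent
  RK4 integrator to <1e-6). Receptor immobilization uses the same law with
  its own constants (kon = 1.5e-3 /(µg/mL)/s, koff = 0 — covalent
  attachment) and is untouched by regeneration; the analyte
  (kon = 2e-3 /(µg/mL)/s, koff = 1e-4 /s, so KD = 0.05 µg/mL) is stripped by
  a configurable fraction (default 0.66, i.e. partial regeneration) at the
  regeneration segment's start. The strip is applied un-delayed because the
  acid pulse it models is a fast manual injection that bypasses the pump
  path; segment boundaries in schedule-based segmentation honour the same
  convention. A consequence of keeping the *concentration* switch delayed is
  that residual analyte rebinds during the dead time after a strip, so the
  post-regeneration plateau recovers part of the step — qualitatively the
  partial-dissociation behaviour seen on real sensors.
* **Noise.** Multiplicative i.i.d. Gaussian per spectral sample
  (`1 + sd·z + drift·t`), seeded per (run seed, frame index) so stacks are
  bit-reproducible. The default sd 5e-5 yields a baseline Ftrans
  peak-to-peak across the window of ~2–4e-4 per-unit, the order observed on
  the real readout. Not modelled: wavelength jitter, correlated drift,
  shot-noise scaling with intensity, temperature.
* **Default scenario.** `il8_scenario()` reproduces the antibody/antigen
  flow order (buffer 500 s → antibody 50 µg/mL, 3000 s → antigen 5 µg/mL,
  2000 s → 5 s acid pulse → buffer rinse → second antigen association, all
  at 50 µL/min) and *calibrates its two surface coefficients by inverting
  the noiseless area–shift response* so the equilibrium plateaus produce
  exactly the requested area steps (defaults 0.92 nm immobilization, 0.46 nm
  recognition). The generator's ground truth therefore has a known target
  `m = 0.46/5 = 0.092 nm per µg/mL` that the pipeline must recover blind.

What passing these tests shows: the processing chain is unbiased and
noise-scaled on data obeying the model above. What it does not show:
robustness to matrix effects, drift, mass-transport limitation, or
non-linear transduction — none of which the generator emulates.

## Segmentation

Without a schedule, each sample is classified by the least-squares slope of
an 11-sample rolling window (threshold 1e-4 nm/s): |slope| below threshold →
plateau, rising → association, falling → dissociation. Runs are merged,
plateaus shorter than `min_plateau_s` (default 30 s) absorbed, and each
boundary refined to the intersection of the line fits of the two adjacent
runs — exact for flat-then-ramp change points in the noiseless case and
within a few samples at the default noise. With a flow schedule, boundaries
instead snap to pump-switch times plus the dead time (regeneration:
un-delayed) and labels follow the reagent roles; buffer rinses after the
first reagent are labelled as part of the adjacent plateau. Plateau values
are the median of a segment's trailing 10 samples.

## Calibration conventions

* Bulk sensitivity uses the endpoint difference quotient between the
  lowest- and highest-RI readings by default (the Δy/Δx convention);
  a least-squares fit over all readings is available. Because the measured
  liquid positions are not perfectly collinear (ethanol in particular sits
  off the water–hexane line), the two estimators differ; the endpoint form
  is the default because it matches the convention the 350 nm/RIU figure
  comes from. Air readings sit far off the liquid trend and are excluded
  from the shipped examples.
* `LoD = U/m` by default; a `lod_multiplier` parameter (e.g. 3.3) exposes
  the stricter IUPAC-style convention without changing the default.
* When only a sensogram is available, the baseline per-unit variation ΔI is
  estimated as the baseline-segment *area* peak-to-peak divided by the
  window width. This spatially averaged estimator is smaller than the
  per-wavelength curve peak-to-peak (averaging suppresses independent
  noise); both routes are exposed, and `calibration_report` records which
  one produced its U.
* All results carry full floating precision; rounding to 2–3 significant
  figures happens only in the Markdown rendering.

## Problem sizes

The shipped scenario samples a 7500 s run every 5 s on a 548–590 nm grid at
0.1 nm (1501 frames × 421 samples); the test suite aggregates 20 seeded
end-to-end runs for step/sensitivity recovery and 5 noise levels × 3 seeds
for the LoD–noise scaling, sizes at which the recovery statistics are stable
to well within the tolerances tested.

## Known limitations

* The linear transduction cannot reproduce a measured liquid series that is
  itself non-collinear; simulated bulk runs land on the model line.
* Plateau detection assumes the association has effectively equilibrated
  within its segment; very slow kinetics would bias plateau medians low.
* The area readout's baseline sits at the window width by construction;
  instruments whose reference state differs from the first-buffer state can
  show baselines below the width, which the simulator does not emulate.
* No kinetic-constant fitting (kon/koff estimation) — the sensogram is
  consumed for calibration, not kinetics.
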