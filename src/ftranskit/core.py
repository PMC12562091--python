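"""Continuous label-free optical biosensing with the Ftrans-area readout.

A resonant nanostructure transducer shows a narrow optical resonance whose
wavelength shifts with the bulk refractive index of the medium and with the
mass bound to its surface.  Instead of tracking the resonance position
directly, the readout used here divides each acquired spectrum by a fixed
reference spectrum (the per-unit ratio ``Ftrans = Isig / Iref``) and
integrates that ratio over a fixed wavelength window.  The resulting
area (in nm) is tracked in time to form a sensogram, which is segmented
into baseline / association / plateau / regeneration phases; plateau step
amplitudes calibrate the analyte sensitivity ``m`` and, together with the
baseline noise, the limit of detection ``LoD = U / m``.

The module is laid out in the order the method runs:

1.  configuration & logging defaults
2.  spectral core       -- Spectrum, FtransCurve, area statistic, peak finding
3.  synthetic data      -- instrument simulator (resonance line shape,
                           bulk/surface transduction, flow schedule with
                           dead volume, Langmuir binding, noise)
4.  sensogram pipeline  -- stack -> sensogram -> phase segments -> plateaus
5.  calibration         -- bulk sensitivity, m, U, LoD
6.  file I/O            -- CSV/YAML/JSON readers and writers
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd
import yaml
from scipy.optimize import brentq

__all__ = [
    # spectral core
    "Spectrum", "WavelengthWindow", "FtransCurve", "SpectralStack",
    "compute_ftrans", "ftrans_area", "excess_area", "resonance_position",
    "peak_to_peak",
    # synthetic data
    "ResonanceModel", "TransductionModel", "BindingModel", "FlowSegment",
    "FlowSchedule", "NoiseModel", "GroundTruth", "Scenario",
    "rnp_shift", "generate_spectrum", "dead_time", "simulate_binding",
    "simulate_experiment", "bulk_series", "area_shift_response",
    "shift_for_area_step", "il8_scenario",
    # sensogram pipeline
    "Sensogram", "PhaseSegment", "build_sensogram", "segment_phases",
    "plateau_value", "step_amplitude", "baseline_uncertainty",
    # calibration
    "BulkReading", "CalibrationResult", "bulk_sensitivity",
    "analyte_sensitivity", "area_uncertainty", "limit_of_detection",
    "calibration_report", "render_report_markdown",
    # io
    "read_spectrum", "write_spectrum", "read_spectral_stack",
    "write_spectral_stack", "read_ftrans_curve", "write_ftrans_curve",
    "write_sensogram", "read_sensogram", "write_segments", "read_segments",
]

# ----------------------------------------------------------------------------
# configuration & logging
# ----------------------------------------------------------------------------

logger = logging.getLogger("ftranskit")

#: analysis window used throughout: 554-580 nm, width 26 nm
DEFAULT_WINDOW_NM = (554.0, 580.0)

#: two wavelength grids are "the same grid" if they agree to this (nm)
GRID_TOLERANCE_NM = 1e-6

#: chamber volume of the default fluidic chip (14 x 6 x 1.5 mm mold), uL
DEFAULT_CHAMBER_VOLUME_UL = 126.0

#: rolling window (samples) for the slope classifier in segment_phases
DEFAULT_SLOPE_WINDOW = 11

#: default |slope| threshold separating plateau from drift, nm/s
DEFAULT_SLOPE_THRESHOLD = 1e-4

#: trailing samples used for a plateau estimate
DEFAULT_PLATEAU_SAMPLES = 10


def _as_1d(x, name: str) -> np.ndarray:
    arr = np.asarray(x, dtype=float)
    if arr.ndim != 1:
        raise ValueError(f"{name} must be one-dimensional")
    return arr


# ----------------------------------------------------------------------------
# spectral core
# ----------------------------------------------------------------------------

@dataclass(frozen=True)
class WavelengthWindow:
    """A closed wavelength interval [lo_nm, hi_nm] used for integration."""

    lo_nm: float
    hi_nm: float

    def __post_init__(self) -> None:
        if not (np.isfinite(self.lo_nm) and np.isfinite(self.hi_nm)):
            raise ValueError("window bounds must be finite")
        if not self.lo_nm < self.hi_nm:
            raise ValueError(
                f"window requires lo_nm < hi_nm, got [{self.lo_nm}, {self.hi_nm}]"
            )

    @property
    def width_nm(self) -> float:
        return self.hi_nm - self.lo_nm

    @classmethod
    def default(cls) -> "WavelengthWindow":
        return cls(*DEFAULT_WINDOW_NM)


@dataclass
class Spectrum:
    """One optical spectrum: intensity versus wavelength at one timepoint.

    Wavelengths are in nm and strictly increasing; intensities are
    non-negative finite detector counts (or per-unit values).
    """

    wavelengths_nm: np.ndarray
    intensities: np.ndarray
    timestamp_s: float | None = None
    label: str = ""

    def __post_init__(self) -> None:
        self.wavelengths_nm = _as_1d(self.wavelengths_nm, "wavelengths_nm")
        self.intensities = _as_1d(self.intensities, "intensities")
        if self.wavelengths_nm.size != self.intensities.size:
            raise ValueError("wavelengths and intensities differ in length")
        if self.wavelengths_nm.size < 3:
            raise ValueError("a spectrum needs at least 3 samples")
        if not np.all(np.diff(self.wavelengths_nm) > 0):
            raise ValueError("wavelengths must be strictly increasing")
        if not np.all(np.isfinite(self.intensities)):
            raise ValueError("intensities must be finite")
        if np.any(self.intensities < 0):
            raise ValueError("intensities must be non-negative")
        if self.timestamp_s is not None and self.timestamp_s < 0:
            raise ValueError("timestamp_s must be >= 0")


@dataclass
class FtransCurve:
    """Per-unit ratio of a signal spectrum to a reference spectrum.

    Values hover around 1 where signal and reference agree and deviate
    (dispersively) where the resonance has shifted or reshaped.
    """

    wavelengths_nm: np.ndarray
    values: np.ndarray
    timestamp_s: float | None = None

    def __post_init__(self) -> None:
        self.wavelengths_nm = _as_1d(self.wavelengths_nm, "wavelengths_nm")
        self.values = _as_1d(self.values, "values")
        if self.wavelengths_nm.size != self.values.size:
            raise ValueError("wavelengths and values differ in length")
        if self.wavelengths_nm.size < 3:
            raise ValueError("an Ftrans curve needs at least 3 samples")
        if not np.all(np.diff(self.wavelengths_nm) > 0):
            raise ValueError("wavelengths must be strictly increasing")
        if not np.all(np.isfinite(self.values)) or np.any(self.values <= 0):
            raise ValueError("Ftrans values must be finite and positive")


@dataclass
class SpectralStack:
    """A continuous acquisition: many spectra sharing one wavelength grid."""

    wavelengths_nm: np.ndarray
    timestamps_s: np.ndarray
    intensities: np.ndarray          # shape (n_times, n_wavelengths)

    def __post_init__(self) -> None:
        self.wavelengths_nm = _as_1d(self.wavelengths_nm, "wavelengths_nm")
        self.timestamps_s = _as_1d(self.timestamps_s, "timestamps_s")
        self.intensities = np.asarray(self.intensities, dtype=float)
        if self.intensities.ndim != 2:
            raise ValueError("intensities must be 2-D (time x wavelength)")
        if self.intensities.shape != (self.timestamps_s.size, self.wavelengths_nm.size):
            raise ValueError("intensities shape must be (n_times, n_wavelengths)")
        if not np.all(np.diff(self.wavelengths_nm) > 0):
            raise ValueError("wavelengths must be strictly increasing")
        if self.timestamps_s.size and not np.all(np.diff(self.timestamps_s) > 0):
            raise ValueError("timestamps must be strictly increasing")
        if not np.all(np.isfinite(self.intensities)):
            raise ValueError("intensities must be finite")

    def __len__(self) -> int:
        return self.timestamps_s.size

    def spectrum(self, i: int) -> Spectrum:
        return Spectrum(self.wavelengths_nm, self.intensities[i],
                        timestamp_s=float(self.timestamps_s[i]))


def _same_grid(a: np.ndarray, b: np.ndarray) -> bool:
    return a.size == b.size and np.allclose(a, b, rtol=0.0, atol=GRID_TOLERANCE_NM)


def compute_ftrans(signal: Spectrum, reference: Spectrum,
                   epsilon: float | None = None) -> FtransCurve:
    """Pointwise ratio signal/reference on a shared wavelength grid.

    Reference intensities below ``epsilon`` are clamped to ``epsilon``
    (with a warning) so the ratio stays finite; by default epsilon is
    1e-9 x max(reference), a proxy for the detector dark floor.
    """
    if not _same_grid(signal.wavelengths_nm, reference.wavelengths_nm):
        raise ValueError("signal and reference are on different wavelength grids")
    if epsilon is None:
        epsilon = 1e-9 * float(np.max(reference.intensities))
    if not epsilon > 0:
        raise ValueError("epsilon must be positive")
    ref = reference.intensities
    n_low = int(np.count_nonzero(ref < epsilon))
    if n_low:
        logger.warning("clamping %d reference samples below epsilon=%.3g",
                       n_low, epsilon)
        warnings.warn(f"{n_low} reference intensities below epsilon were clamped",
                      RuntimeWarning, stacklevel=2)
    values = signal.intensities / np.maximum(ref, epsilon)
    return FtransCurve(signal.wavelengths_nm.copy(), values,
                       timestamp_s=signal.timestamp_s)


def ftrans_area(curve: FtransCurve, window: WavelengthWindow | None = None) -> float:
    """Trapezoidal integral of the Ftrans curve over the window, in nm.

    The window must lie inside the curve's grid; values at the window
    endpoints are obtained by linear interpolation.  For a curve
    identically 1 the area equals the window width (26 nm for the
    default 554-580 nm window), so the readout baseline sits near the
    width and binding shows up as small excursions above it.
    """
    if window is None:
        window = WavelengthWindow.default()
    wl, v = curve.wavelengths_nm, curve.values
    if window.lo_nm < wl[0] - GRID_TOLERANCE_NM or window.hi_nm > wl[-1] + GRID_TOLERANCE_NM:
        raise ValueError(
            f"window [{window.lo_nm}, {window.hi_nm}] extends beyond grid "
            f"coverage [{wl[0]}, {wl[-1]}]"
        )
    lo = max(window.lo_nm, wl[0])
    hi = min(window.hi_nm, wl[-1])
    inside = (wl > lo) & (wl < hi)
    xs = np.concatenate(([lo], wl[inside], [hi]))
    ys = np.concatenate(([np.interp(lo, wl, v)], v[inside], [np.interp(hi, wl, v)]))
    return float(np.trapezoid(ys, xs))


def excess_area(curve: FtransCurve, window: WavelengthWindow | None = None) -> float:
    """Area minus window width: the deviation from a flat unit baseline.

    Convenience view for plotting; areas are otherwise reported raw.
    """
    if window is None:
        window = WavelengthWindow.default()
    return ftrans_area(curve, window) - window.width_nm


def resonance_position(spectrum: Spectrum | FtransCurve,
                       search: WavelengthWindow,
                       sense: Literal["peak", "dip"] = "dip") -> float:
    """Wavelength of the resonance extremum inside ``search``, in nm.

    The extremal sample is refined to sub-grid precision by fitting a
    parabola through it and its two neighbours.  If the extremum sits on
    the window edge the raw sample wavelength is returned with a warning.
    """
    if sense not in ("peak", "dip"):
        raise ValueError("sense must be 'peak' or 'dip'")
    wl = spectrum.wavelengths_nm
    y = spectrum.values if isinstance(spectrum, FtransCurve) else spectrum.intensities
    if search.lo_nm < wl[0] - GRID_TOLERANCE_NM or search.hi_nm > wl[-1] + GRID_TOLERANCE_NM:
        raise ValueError("search window extends beyond the wavelength grid")
    mask = (wl >= search.lo_nm) & (wl <= search.hi_nm)
    idx = np.flatnonzero(mask)
    if idx.size < 3:
        raise ValueError("need at least 3 samples inside the search window")
    seg = y[idx]
    if np.ptp(seg) == 0.0:
        raise ValueError("no resonance: signal is flat inside the search window")
    k = int(np.argmin(seg) if sense == "dip" else np.argmax(seg))
    if k == 0 or k == idx.size - 1:
        warnings.warn("resonance extremum sits at the search-window edge; "
                      "returning the raw sample wavelength", RuntimeWarning,
                      stacklevel=2)
        return float(wl[idx[k]])
    i = idx[k]
    x0, x1, x2 = wl[i - 1], wl[i], wl[i + 1]
    y0, y1, y2 = y[i - 1], y[i], y[i + 1]
    # vertex of the parabola through the three samples (exact for uneven grids)
    denom = (x0 - x1) * (x0 - x2) * (x1 - x2)
    a = (x2 * (y1 - y0) + x1 * (y0 - y2) + x0 * (y2 - y1)) / denom
    b = (x2**2 * (y0 - y1) + x1**2 * (y2 - y0) + x0**2 * (y1 - y2)) / denom
    if a == 0.0:
        return float(x1)
    return float(-b / (2.0 * a))


def peak_to_peak(values: Sequence[float],
                 mode: Literal["literal", "robust"] = "literal",
                 robust_quantiles: tuple[float, float] = (0.005, 0.995)) -> float:
    """Peak-to-peak spread of a sequence (per-unit).

    ``literal`` is max - min, the convention used for baseline Ftrans
    variation; ``robust`` is an inter-quantile range (default
    0.5%-99.5%) for heavy-tailed noise.
    """
    arr = _as_1d(values, "values")
    if arr.size < 2:
        raise ValueError("peak_to_peak needs at least 2 values")
    if not np.all(np.isfinite(arr)):
        raise ValueError("values must be finite")
    if mode == "literal":
        return float(arr.max() - arr.min())
    if mode == "robust":
        lo, hi = robust_quantiles
        if not (0.0 < lo < hi < 1.0):
            raise ValueError("robust_quantiles must satisfy 0 < lo < hi < 1")
        qlo, qhi = np.quantile(arr, [lo, hi])
        return float(qhi - qlo)
    raise ValueError("mode must be 'literal' or 'robust'")


# ----------------------------------------------------------------------------
# synthetic data: instrument simulator
# ----------------------------------------------------------------------------

@dataclass
class ResonanceModel:
    """Phenomenological line shape of the transducer resonance.

    A narrow Lorentzian (or Fano) feature of the given FWHM and
    fractional depth sits on a flat background inside a photonic stop
    band; the feature is a dip in transmission-style spectra or a peak
    in reflection-style spectra.
    """

    center_nm: float = 566.0
    fwhm_nm: float = 2.0
    depth: float = 0.8
    sense: Literal["peak", "dip"] = "dip"
    shape: Literal["lorentzian", "fano"] = "lorentzian"
    fano_q: float = 2.0
    background_level: float = 1.0
    stopband: WavelengthWindow = field(
        default_factory=lambda: WavelengthWindow(550.0, 588.0))

    def __post_init__(self) -> None:
        if not (0.0 < self.depth <= 1.0):
            raise ValueError("depth must be in (0, 1]")
        if self.fwhm_nm <= 0:
            raise ValueError("fwhm_nm must be positive")
        if self.background_level <= 0:
            raise ValueError("background_level must be positive")
        if not (self.stopband.lo_nm < self.center_nm < self.stopband.hi_nm):
            raise ValueError("resonance center must lie inside the stop band")
        if self.fwhm_nm >= self.stopband.width_nm:
            raise ValueError("fwhm_nm must be smaller than the stop-band width")


@dataclass
class TransductionModel:
    """Linear transduction from medium RI and surface coverage to a shift.

    ``shift = S * (RI - reference_RI) + sigma * coverage`` where S is the
    bulk sensitivity in nm/RIU and sigma the surface coefficient in nm
    per unit fractional coverage.
    """

    bulk_sensitivity_nm_per_RIU: float = 350.0
    reference_RI: float = 1.33
    surface_coeff_nm_per_unit_coverage: float = 0.0
    max_shift_nm: float = 50.0

    def __post_init__(self) -> None:
        if self.bulk_sensitivity_nm_per_RIU <= 0:
            raise ValueError("bulk sensitivity S must be positive")
        if self.surface_coeff_nm_per_unit_coverage < 0:
            raise ValueError("surface coefficient must be >= 0")
        if self.max_shift_nm <= 0:
            raise ValueError("max_shift_nm must be positive")


@dataclass
class BindingModel:
    """First-order (Langmuir) binding kinetics.

    dG/dt = kon * C * (gamma_max - G) - koff * G, with C in ug/mL.
    """

    kon_per_ugmL_per_s: float
    koff_per_s: float
    gamma_max: float = 1.0

    def __post_init__(self) -> None:
        if self.kon_per_ugmL_per_s <= 0:
            raise ValueError("kon must be positive")
        if self.koff_per_s < 0:
            raise ValueError("koff must be >= 0")
        if self.gamma_max <= 0:
            raise ValueError("gamma_max must be positive")

    @property
    def KD_ugmL(self) -> float:
        """Equilibrium dissociation constant koff/kon, in ug/mL."""
        return self.koff_per_s / self.kon_per_ugmL_per_s


SegmentRole = Literal["buffer", "receptor", "analyte", "regeneration"]


@dataclass
class FlowSegment:
    """One constant-composition interval of the flow schedule."""

    reagent: str
    concentration_ug_mL: float
    flow_rate_uL_per_min: float
    duration_s: float
    role: SegmentRole = "buffer"
    stripping_efficiency: float = 0.0
    medium_RI: float | None = None       # None -> the transduction reference RI

    def __post_init__(self) -> None:
        if self.duration_s <= 0:
            raise ValueError("segment duration must be positive")
        if self.flow_rate_uL_per_min <= 0:
            raise ValueError("flow rate must be positive")
        if self.concentration_ug_mL < 0:
            raise ValueError("concentration must be >= 0")
        if not (0.0 <= self.stripping_efficiency <= 1.0):
            raise ValueError("stripping_efficiency must be in [0, 1]")


@dataclass
class FlowSchedule:
    """Ordered reagent segments flowing through a fixed-volume chamber."""

    segments: list[FlowSegment]
    chamber_volume_uL: float = DEFAULT_CHAMBER_VOLUME_UL

    def __post_init__(self) -> None:
        if not self.segments:
            raise ValueError("a flow schedule needs at least one segment")
        if self.chamber_volume_uL <= 0:
            raise ValueError("chamber volume must be positive")

    @property
    def total_duration_s(self) -> float:
        return float(sum(s.duration_s for s in self.segments))

    def start_times_s(self) -> np.ndarray:
        durs = [s.duration_s for s in self.segments]
        return np.concatenate(([0.0], np.cumsum(durs)[:-1]))

    def switch_times_s(self) -> np.ndarray:
        """Times at which a new reagent starts being pumped (excluding t=0)."""
        return self.start_times_s()[1:]


@dataclass
class NoiseModel:
    """Multiplicative i.i.d. Gaussian intensity noise plus linear drift.

    Each spectrum sample is multiplied by ``1 + sd * z + drift * t``;
    draws are reproducible given (seed, frame index).
    """

    multiplicative_sd: float = 5e-5
    drift_per_s: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.multiplicative_sd < 0:
            raise ValueError("multiplicative_sd must be >= 0")

    def factors(self, n: int, frame_index: int, time_s: float) -> np.ndarray:
        out = np.full(n, 1.0 + self.drift_per_s * time_s)
        if self.multiplicative_sd > 0:
            rng = np.random.default_rng(
                np.random.SeedSequence([int(self.seed) & 0x7FFFFFFF, int(frame_index)]))
            out = out + self.multiplicative_sd * rng.standard_normal(n)
        return out


def rnp_shift(medium_RI: float, coverage: float,
              model: TransductionModel) -> float:
    """Resonance shift (nm) for a given bulk RI and fractional coverage."""
    if not (0.0 <= coverage <= 1.0):
        raise ValueError("coverage must be in [0, 1]")
    s = (model.bulk_sensitivity_nm_per_RIU * (medium_RI - model.reference_RI)
         + model.surface_coeff_nm_per_unit_coverage * coverage)
    if abs(s) > model.max_shift_nm:
        warnings.warn(f"shift {s:.3g} nm exceeds the max-shift guard "
                      f"{model.max_shift_nm} nm and was clipped",
                      RuntimeWarning, stacklevel=2)
        s = float(np.clip(s, -model.max_shift_nm, model.max_shift_nm))
    return float(s)


def _lineshape(wl: np.ndarray, model: ResonanceModel, shift_nm: float) -> np.ndarray:
    c = model.center_nm + shift_nm
    half = model.fwhm_nm / 2.0
    if model.shape == "lorentzian":
        feat = half**2 / ((wl - c) ** 2 + half**2)
    elif model.shape == "fano":
        eps = (wl - c) / half
        q = model.fano_q
        feat = (q + eps) ** 2 / ((1.0 + eps**2) * (1.0 + q**2))
    else:
        raise ValueError("shape must be 'lorentzian' or 'fano'")
    if model.sense == "dip":
        return model.background_level * (1.0 - model.depth * feat)
    return model.background_level * (1.0 + model.depth * feat)


def generate_spectrum(model: ResonanceModel, shift_nm: float,
                      grid_nm: np.ndarray,
                      noise: NoiseModel | None = None,
                      time_s: float = 0.0,
                      frame_index: int = 0) -> Spectrum:
    """Synthesize one spectrum with the resonance displaced by ``shift_nm``.

    If the shifted center leaves the stop band the spectrum is still
    produced, with a warning (a real instrument would show the mode
    running into the band edge).
    """
    grid_nm = _as_1d(grid_nm, "grid_nm")
    if grid_nm[0] > model.stopband.lo_nm or grid_nm[-1] < model.stopband.hi_nm:
        raise ValueError("wavelength grid must cover the stop band")
    c = model.center_nm + shift_nm
    if not (model.stopband.lo_nm < c < model.stopband.hi_nm):
        warnings.warn(f"shifted resonance center {c:.2f} nm is outside the "
                      "stop band", RuntimeWarning, stacklevel=2)
    intens = _lineshape(grid_nm, model, shift_nm)
    if noise is not None:
        intens = intens * noise.factors(grid_nm.size, frame_index, time_s)
    intens = np.maximum(intens, 0.0)
    return Spectrum(grid_nm.copy(), intens, timestamp_s=max(time_s, 0.0))


def dead_time(chamber_volume_uL: float, flow_rate_uL_per_min: float) -> float:
    """Plug-flow transport delay (s) before a new fluid fills the chamber.

    126 uL at 50 uL/min gives 151.2 s, consistent with the ~150 s delay
    observed between pump start and signal change.
    """
    if chamber_volume_uL <= 0 or flow_rate_uL_per_min <= 0:
        raise ValueError("chamber volume and flow rate must be positive")
    return 60.0 * chamber_volume_uL / flow_rate_uL_per_min


def _concentration_events(schedule: FlowSchedule, role: SegmentRole,
                          stripped_by_regeneration: bool):
    """(time, kind, value) events for the species driven by ``role``.

    Concentration switches are delayed by each segment's dead time;
    regeneration strips are applied un-delayed at the segment start
    (modelling a fast manual injection).
    """
    events: list[tuple[float, str, float]] = []
    for start, seg in zip(schedule.start_times_s(), schedule.segments):
        arrival = start + dead_time(schedule.chamber_volume_uL,
                                    seg.flow_rate_uL_per_min)
        conc = seg.concentration_ug_mL if seg.role == role else 0.0
        events.append((arrival, "conc", conc))
        if seg.role == "regeneration" and stripped_by_regeneration:
            events.append((start, "strip", seg.stripping_efficiency))
    events.sort(key=lambda e: (e[0], e[1] == "conc"))   # strips before conc at ties
    return events


def simulate_binding(schedule: FlowSchedule, binding: BindingModel,
                     dt_s: float, role: SegmentRole = "analyte",
                     stripped_by_regeneration: bool = True,
                     gamma0: float = 0.0) -> tuple[np.ndarray, np.ndarray]:
    """Fractional coverage versus time under the flow schedule.

    Within every interval of constant effective concentration C the
    coverage follows the closed-form first-order solution

        G(t) = Geq + (G(t0) - Geq) * exp(-(kon*C + koff)(t - t0)),
        Geq  = gamma_max * kon*C / (kon*C + koff),

    where C is the concentration of segments whose role matches ``role``,
    delayed by the chamber dead time.  A regeneration segment multiplies
    the current coverage by (1 - stripping_efficiency) at its start when
    ``stripped_by_regeneration`` is true (the analyte; an immobilized
    receptor is covalently bound and passes ``False``).

    Returns (times_s, coverage) on a uniform grid of step ``dt_s``.
    """
    if dt_s <= 0:
        raise ValueError("dt_s must be positive")
    total = schedule.total_duration_s
    times = np.arange(0.0, total + dt_s / 2, dt_s)
    events = _concentration_events(schedule, role, stripped_by_regeneration)

    coverage = np.empty_like(times)
    t0, g0, conc = 0.0, float(gamma0), 0.0
    kon, koff, gmax = (binding.kon_per_ugmL_per_s, binding.koff_per_s,
                       binding.gamma_max)

    def closed_form(t: np.ndarray | float, t_ref: float, g_ref: float,
                    c: float) -> np.ndarray | float:
        rate = kon * c + koff
        geq = gmax * kon * c / rate if rate > 0 else g_ref
        return geq + (g_ref - geq) * np.exp(-rate * np.asarray(t - t_ref))

    ei, n_ev = 0, len(events)
    for i, t in enumerate(times):
        while ei < n_ev and events[ei][0] <= t:
            et, kind, val = events[ei]
            g0 = float(closed_form(et, t0, g0, conc))
            t0 = et
            if kind == "conc":
                conc = val
            else:                                   # strip
                g0 *= (1.0 - val)
            ei += 1
        coverage[i] = closed_form(t, t0, g0, conc)
    return times, np.clip(coverage, 0.0, gmax)


@dataclass
class GroundTruth:
    """Everything the simulator knows that the pipeline must recover."""

    times_s: np.ndarray
    shift_nm: np.ndarray
    analyte_coverage: np.ndarray
    receptor_coverage: np.ndarray
    medium_RI: np.ndarray
    true_area_nm: np.ndarray             # noiseless Ftrans area trace
    bulk_sensitivity_nm_per_RIU: float
    analyte_surface_coeff_nm: float
    receptor_surface_coeff_nm: float
    seed: int
    extras: dict = field(default_factory=dict)

    def to_json_dict(self) -> dict:
        d = {
            "times_s": self.times_s.tolist(),
            "shift_nm": self.shift_nm.tolist(),
            "analyte_coverage": self.analyte_coverage.tolist(),
            "receptor_coverage": self.receptor_coverage.tolist(),
            "medium_RI": self.medium_RI.tolist(),
            "true_area_nm": self.true_area_nm.tolist(),
            "bulk_sensitivity_nm_per_RIU": self.bulk_sensitivity_nm_per_RIU,
            "analyte_surface_coeff_nm": self.analyte_surface_coeff_nm,
            "receptor_surface_coeff_nm": self.receptor_surface_coeff_nm,
            "seed": self.seed,
            "extras": self.extras,
        }
        return d


def _medium_ri_trace(schedule: FlowSchedule, reference_RI: float,
                     times: np.ndarray) -> np.ndarray:
    """Bulk RI seen by the sensor (segment RI delayed by the dead time)."""
    out = np.full_like(times, reference_RI)
    events = []
    for start, seg in zip(schedule.start_times_s(), schedule.segments):
        arrival = start + dead_time(schedule.chamber_volume_uL,
                                    seg.flow_rate_uL_per_min)
        ri = reference_RI if seg.medium_RI is None else seg.medium_RI
        events.append((arrival, ri))
    for arrival, ri in events:
        out[times >= arrival] = ri
    return out


def simulate_experiment(resonance: ResonanceModel,
                        transduction: TransductionModel,
                        binding: BindingModel | None,
                        schedule: FlowSchedule,
                        noise: NoiseModel | None = None,
                        sampling_period_s: float = 5.0,
                        grid_nm: np.ndarray | None = None,
                        receptor_binding: BindingModel | None = None,
                        receptor_surface_coeff_nm: float | None = None,
                        window: WavelengthWindow | None = None,
                        ) -> tuple[SpectralStack, GroundTruth]:
    """Run the full instrument forward model over a flow schedule.

    For each sample time: Langmuir coverage (receptor + analyte, each
    driven by the segments of its role) -> resonance shift (bulk RI term
    plus one surface term per species) -> spectrum with noise.  The
    ground-truth record carries the true shift and coverage traces, the
    noiseless Ftrans-area trace, and all transduction coefficients.
    """
    if sampling_period_s <= 0:
        raise ValueError("sampling_period_s must be positive")
    if grid_nm is None:
        grid_nm = np.arange(548.0, 590.0 + 1e-9, 0.1)
    grid_nm = _as_1d(grid_nm, "grid_nm")
    if window is None:
        window = WavelengthWindow.default()

    times = np.arange(0.0, schedule.total_duration_s + sampling_period_s / 2,
                      sampling_period_s)
    if binding is not None:
        _, g_ana = simulate_binding(schedule, binding, sampling_period_s,
                                    role="analyte", stripped_by_regeneration=True)
    else:
        g_ana = np.zeros_like(times)
    if receptor_binding is not None:
        _, g_rec = simulate_binding(schedule, receptor_binding, sampling_period_s,
                                    role="receptor", stripped_by_regeneration=False)
    else:
        g_rec = np.zeros_like(times)
    g_ana, g_rec = g_ana[:times.size], g_rec[:times.size]

    sig_rec = (transduction.surface_coeff_nm_per_unit_coverage
               if receptor_surface_coeff_nm is None else receptor_surface_coeff_nm)
    ri = _medium_ri_trace(schedule, transduction.reference_RI, times)
    shift = (transduction.bulk_sensitivity_nm_per_RIU * (ri - transduction.reference_RI)
             + transduction.surface_coeff_nm_per_unit_coverage * g_ana
             + sig_rec * g_rec)
    clipped = np.abs(shift) > transduction.max_shift_nm
    if np.any(clipped):
        warnings.warn("some shifts exceed the max-shift guard and were clipped",
                      RuntimeWarning, stacklevel=2)
        shift = np.clip(shift, -transduction.max_shift_nm, transduction.max_shift_nm)

    reference = generate_spectrum(resonance, 0.0, grid_nm, noise=None)
    intens = np.empty((times.size, grid_nm.size))
    true_area = np.empty(times.size)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        for i, (t, s) in enumerate(zip(times, shift)):
            clean = generate_spectrum(resonance, float(s), grid_nm, noise=None,
                                      time_s=float(t), frame_index=i)
            true_area[i] = ftrans_area(compute_ftrans(clean, reference), window)
            if noise is not None:
                intens[i] = clean.intensities * noise.factors(
                    grid_nm.size, i, float(t))
            else:
                intens[i] = clean.intensities
    intens = np.maximum(intens, 0.0)

    stack = SpectralStack(grid_nm.copy(), times, intens)
    truth = GroundTruth(
        times_s=times, shift_nm=shift, analyte_coverage=g_ana,
        receptor_coverage=g_rec, medium_RI=ri, true_area_nm=true_area,
        bulk_sensitivity_nm_per_RIU=transduction.bulk_sensitivity_nm_per_RIU,
        analyte_surface_coeff_nm=transduction.surface_coeff_nm_per_unit_coverage,
        receptor_surface_coeff_nm=sig_rec,
        seed=(noise.seed if noise is not None else 0),
    )
    return stack, truth


def bulk_series(RIs: Sequence[float], durations_s: Sequence[float],
                resonance: ResonanceModel | None = None,
                transduction: TransductionModel | None = None,
                noise: NoiseModel | None = None,
                sampling_period_s: float = 5.0,
                flow_rate_uL_per_min: float = 50.0,
                chamber_volume_uL: float = DEFAULT_CHAMBER_VOLUME_UL,
                grid_nm: np.ndarray | None = None,
                ) -> tuple[SpectralStack, GroundTruth]:
    """Refractometric (bulk) calibration run: a sequence of pure liquids.

    Coverage is pinned to zero; each liquid's RI drives the resonance
    through the bulk term only.
    """
    RIs = list(RIs)
    durations_s = list(durations_s)
    if not RIs:
        raise ValueError("need at least one refractive index")
    if len(RIs) != len(durations_s):
        raise ValueError("RIs and durations differ in length")
    if resonance is None:
        resonance = ResonanceModel()
    if transduction is None:
        transduction = TransductionModel()
    segments = [FlowSegment(reagent=f"liquid_{i}", concentration_ug_mL=0.0,
                            flow_rate_uL_per_min=flow_rate_uL_per_min,
                            duration_s=d, role="buffer", medium_RI=ri)
                for i, (ri, d) in enumerate(zip(RIs, durations_s))]
    schedule = FlowSchedule(segments, chamber_volume_uL=chamber_volume_uL)
    return simulate_experiment(resonance, transduction, None, schedule,
                               noise=noise, sampling_period_s=sampling_period_s,
                               grid_nm=grid_nm)


def area_shift_response(resonance: ResonanceModel,
                        shifts_nm: np.ndarray,
                        grid_nm: np.ndarray | None = None,
                        window: WavelengthWindow | None = None) -> np.ndarray:
    """Noiseless Ftrans area as a function of the resonance shift.

    With both the shifted feature and the reference feature inside the
    window, the area signal comes from the dispersive shape of the
    ratio, not from the feature leaving the window: the peak lobe (where
    the reference dips) outweighs the dip lobe because 1/(1-d) grows
    faster than 1-d falls, so the area rises monotonically with |shift|
    for shifts up to about one FWHM.
    """
    if grid_nm is None:
        grid_nm = np.arange(548.0, 590.0 + 1e-9, 0.1)
    if window is None:
        window = WavelengthWindow.default()
    reference = generate_spectrum(resonance, 0.0, grid_nm)
    out = np.empty(np.asarray(shifts_nm).size)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        for i, s in enumerate(np.atleast_1d(shifts_nm)):
            sig = generate_spectrum(resonance, float(s), grid_nm)
            out[i] = ftrans_area(compute_ftrans(sig, reference), window)
    return out


def shift_for_area_step(resonance: ResonanceModel, target_area_step_nm: float,
                        grid_nm: np.ndarray | None = None,
                        window: WavelengthWindow | None = None,
                        max_shift_nm: float = 6.0) -> float:
    """Invert the area-shift response: shift producing a given area rise."""
    if target_area_step_nm < 0:
        raise ValueError("target area step must be >= 0")
    if target_area_step_nm == 0:
        return 0.0
    base = float(area_shift_response(resonance, np.array([0.0]), grid_nm, window)[0])

    def f(s: float) -> float:
        return float(area_shift_response(resonance, np.array([s]), grid_nm,
                                         window)[0]) - base - target_area_step_nm

    hi = max_shift_nm
    if f(hi) < 0:
        raise ValueError("target area step unreachable within max_shift_nm")
    return float(brentq(f, 0.0, hi, xtol=1e-10))


@dataclass
class Scenario:
    """A complete simulation configuration, serializable to YAML."""

    resonance: ResonanceModel
    transduction: TransductionModel
    binding: BindingModel | None
    schedule: FlowSchedule
    noise: NoiseModel
    receptor_binding: BindingModel | None = None
    receptor_surface_coeff_nm: float = 0.0
    sampling_period_s: float = 5.0
    grid_start_nm: float = 548.0
    grid_stop_nm: float = 590.0
    grid_step_nm: float = 0.1
    window: WavelengthWindow = field(default_factory=WavelengthWindow.default)

    def grid(self) -> np.ndarray:
        return np.arange(self.grid_start_nm, self.grid_stop_nm + 1e-9,
                         self.grid_step_nm)

    def run(self, seed: int | None = None) -> tuple[SpectralStack, GroundTruth]:
        noise = self.noise
        if seed is not None:
            noise = NoiseModel(noise.multiplicative_sd, noise.drift_per_s, seed)
        return simulate_experiment(
            self.resonance, self.transduction, self.binding, self.schedule,
            noise=noise, sampling_period_s=self.sampling_period_s,
            grid_nm=self.grid(), receptor_binding=self.receptor_binding,
            receptor_surface_coeff_nm=self.receptor_surface_coeff_nm,
            window=self.window)

    def reference_spectrum(self) -> Spectrum:
        return generate_spectrum(self.resonance, 0.0, self.grid())

    # -- YAML round trip -----------------------------------------------------

    def to_dict(self) -> dict:
        d = {
            "resonance": {**asdict(self.resonance),
                          "stopband": [self.resonance.stopband.lo_nm,
                                       self.resonance.stopband.hi_nm]},
            "transduction": asdict(self.transduction),
            "binding": asdict(self.binding) if self.binding else None,
            "receptor_binding": (asdict(self.receptor_binding)
                                 if self.receptor_binding else None),
            "receptor_surface_coeff_nm": self.receptor_surface_coeff_nm,
            "schedule": {
                "chamber_volume_uL": self.schedule.chamber_volume_uL,
                "segments": [asdict(s) for s in self.schedule.segments],
            },
            "noise": asdict(self.noise),
            "acquisition": {
                "grid_start_nm": self.grid_start_nm,
                "grid_stop_nm": self.grid_stop_nm,
                "grid_step_nm": self.grid_step_nm,
                "sampling_period_s": self.sampling_period_s,
                "window": [self.window.lo_nm, self.window.hi_nm],
            },
        }
        return d

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))

    @classmethod
    def from_dict(cls, d: dict) -> "Scenario":
        res = dict(d["resonance"])
        res["stopband"] = WavelengthWindow(*res["stopband"])
        acq = d["acquisition"]
        sched = d["schedule"]
        return cls(
            resonance=ResonanceModel(**res),
            transduction=TransductionModel(**d["transduction"]),
            binding=BindingModel(**d["binding"]) if d.get("binding") else None,
            receptor_binding=(BindingModel(**d["receptor_binding"])
                              if d.get("receptor_binding") else None),
            receptor_surface_coeff_nm=d.get("receptor_surface_coeff_nm", 0.0),
            schedule=FlowSchedule(
                [FlowSegment(**s) for s in sched["segments"]],
                chamber_volume_uL=sched.get("chamber_volume_uL",
                                            DEFAULT_CHAMBER_VOLUME_UL)),
            noise=NoiseModel(**d["noise"]),
            sampling_period_s=acq["sampling_period_s"],
            grid_start_nm=acq["grid_start_nm"],
            grid_stop_nm=acq["grid_stop_nm"],
            grid_step_nm=acq["grid_step_nm"],
            window=WavelengthWindow(*acq["window"]),
        )

    @classmethod
    def from_yaml(cls, path: str | Path) -> "Scenario":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))


def il8_scenario(immobilization_step_nm: float = 0.92,
                 recognition_step_nm: float = 0.46,
                 noise_sd: float = 5e-5,
                 seed: int = 0,
                 sampling_period_s: float = 5.0,
                 stripping_efficiency: float = 0.66) -> Scenario:
    """The default antibody/antigen continuous-detection scenario.

    Flow order mirrors the IL-8 immunoassay run: buffer 500 s, antibody
    (anti-IL-8, 50 ug/mL) to saturation, antigen (IL-8, 5 ug/mL)
    association, a 5 s acid regeneration pulse, buffer rinse, and a
    second antigen association.  Surface coefficients are chosen by
    inverting the noiseless area-shift response so that the equilibrium
    plateaus produce exactly the requested area steps (defaults 0.92 nm
    for immobilization and 0.46 nm for recognition).
    """
    resonance = ResonanceModel()
    receptor_binding = BindingModel(kon_per_ugmL_per_s=1.5e-3, koff_per_s=0.0)
    analyte_binding = BindingModel(kon_per_ugmL_per_s=2e-3, koff_per_s=1e-4)
    segments = [
        FlowSegment("PBS", 0.0, 50.0, 500.0, role="buffer"),
        FlowSegment("anti-IL-8", 50.0, 50.0, 3000.0, role="receptor"),
        FlowSegment("IL-8", 5.0, 50.0, 2000.0, role="analyte"),
        FlowSegment("HCl", 0.0, 50.0, 5.0, role="regeneration",
                    stripping_efficiency=stripping_efficiency),
        FlowSegment("PBS", 0.0, 50.0, 695.0, role="buffer"),
        FlowSegment("IL-8", 5.0, 50.0, 1300.0, role="analyte"),
    ]
    schedule = FlowSchedule(segments)

    # realized coverages at the end of the immobilization / recognition steps
    _, g_rec = simulate_binding(schedule, receptor_binding, sampling_period_s,
                                role="receptor", stripped_by_regeneration=False)
    _, g_ana = simulate_binding(schedule, analyte_binding, sampling_period_s,
                                role="analyte", stripped_by_regeneration=True)
    times = np.arange(0.0, schedule.total_duration_s + sampling_period_s / 2,
                      sampling_period_s)
    # sample just before the pump switch / regeneration strip
    i_imm = int(np.searchsorted(times, 3500.0)) - 1
    i_rec = int(np.searchsorted(times, 5500.0)) - 1
    g_rec_plateau = float(g_rec[i_imm])
    g_ana_plateau = float(g_ana[i_rec])

    s1 = shift_for_area_step(resonance, immobilization_step_nm)
    s2 = shift_for_area_step(resonance,
                             immobilization_step_nm + recognition_step_nm)
    sigma_rec = s1 / g_rec_plateau
    sigma_ana = (s2 - sigma_rec * float(g_rec[i_rec])) / g_ana_plateau

    transduction = TransductionModel(
        bulk_sensitivity_nm_per_RIU=350.0, reference_RI=1.33,
        surface_coeff_nm_per_unit_coverage=sigma_ana)
    return Scenario(
        resonance=resonance, transduction=transduction,
        binding=analyte_binding, schedule=schedule,
        noise=NoiseModel(multiplicative_sd=noise_sd, seed=seed),
        receptor_binding=receptor_binding,
        receptor_surface_coeff_nm=sigma_rec,
        sampling_period_s=sampling_period_s)


# ----------------------------------------------------------------------------
# sensogram pipeline
# ----------------------------------------------------------------------------

@dataclass
class Sensogram:
    """Time series of the Ftrans-area readout (nm)."""

    timestamps_s: np.ndarray
    area_nm: np.ndarray
    window: WavelengthWindow
    mode_position_nm: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.timestamps_s = _as_1d(self.timestamps_s, "timestamps_s")
        self.area_nm = _as_1d(self.area_nm, "area_nm")
        if self.timestamps_s.size != self.area_nm.size:
            raise ValueError("timestamps and areas differ in length")
        if self.timestamps_s.size > 1 and not np.all(np.diff(self.timestamps_s) > 0):
            raise ValueError("timestamps must be strictly increasing")
        if not np.all(np.isfinite(self.area_nm)):
            raise ValueError("areas must be finite")
        if self.mode_position_nm is not None:
            self.mode_position_nm = _as_1d(self.mode_position_nm,
                                           "mode_position_nm")
            if self.mode_position_nm.size != self.timestamps_s.size:
                raise ValueError("mode positions and timestamps differ in length")

    def __len__(self) -> int:
        return self.timestamps_s.size


@dataclass
class PhaseSegment:
    """One labelled phase of a sensogram."""

    label: Literal["baseline", "association", "plateau", "dissociation",
                   "regeneration"]
    start_s: float
    end_s: float
    plateau_value_nm: float | None = None
    reagent: str | None = None

    def __post_init__(self) -> None:
        if not self.start_s < self.end_s:
            raise ValueError("segment requires start_s < end_s")


def build_sensogram(stack: SpectralStack, reference: Spectrum,
                    window: WavelengthWindow | None = None,
                    track_mode: bool = False,
                    mode_sense: Literal["peak", "dip"] = "dip") -> Sensogram:
    """Reduce a spectral stack to the Ftrans-area time series.

    Per timepoint: ``area[t] = ftrans_area(compute_ftrans(S_t, ref), window)``.
    Optionally also tracks the resonance position inside the window.
    """
    if window is None:
        window = WavelengthWindow.default()
    areas = np.empty(len(stack))
    modes = np.empty(len(stack)) if track_mode else None
    for i in range(len(stack)):
        curve = compute_ftrans(stack.spectrum(i), reference)
        areas[i] = ftrans_area(curve, window)
        if track_mode:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", RuntimeWarning)
                modes[i] = resonance_position(stack.spectrum(i), window,
                                              sense=mode_sense)
    return Sensogram(stack.timestamps_s.copy(), areas, window,
                     mode_position_nm=modes)


def _rolling_slopes(t: np.ndarray, y: np.ndarray, win: int) -> np.ndarray:
    """Centered least-squares slope of y(t) over a rolling window."""
    n = t.size
    win = min(win, n if n % 2 == 1 else n - 1)
    win = max(win, 3)
    half = win // 2
    slopes = np.empty(n)
    for i in range(n):
        lo, hi = max(0, i - half), min(n, i + half + 1)
        tt, yy = t[lo:hi], y[lo:hi]
        tc = tt - tt.mean()
        denom = float(tc @ tc)
        slopes[i] = float(tc @ (yy - yy.mean())) / denom if denom > 0 else 0.0
    return slopes


def _refine_boundary(t: np.ndarray, y: np.ndarray, left: tuple[int, int],
                     right: tuple[int, int], guess_idx: int, half: int) -> int:
    """Move a run boundary to the intersection of the two fitted lines.

    Each side is fit away from the boundary (dropping ``half`` samples of
    guard band); for a flat-then-ramp pair the intersection recovers the
    true change point exactly in the noiseless case.
    """
    def fit(lo: int, hi: int):
        tt, yy = t[lo:hi], y[lo:hi]
        if tt.size < 2:
            return None
        A = np.vstack([tt, np.ones_like(tt)]).T
        coef, *_ = np.linalg.lstsq(A, yy, rcond=None)
        return coef   # slope, intercept

    lf = fit(left[0], max(left[0] + 2, left[1] - half))
    rf = fit(min(right[1] - 2, right[0] + half), right[1])
    if lf is None or rf is None:
        return guess_idx
    ds = lf[0] - rf[0]
    span = t[min(right[1] - 1, t.size - 1)] - t[left[0]]
    if abs(ds) * span < 10 * np.finfo(float).eps * (abs(y).max() + 1):
        return guess_idx
    t_star = (rf[1] - lf[1]) / ds
    if not (t[left[0]] <= t_star <= t[right[1] - 1]):
        return guess_idx
    return int(np.clip(np.searchsorted(t, t_star), left[0] + 1, right[1] - 1))


def segment_phases(s: Sensogram,
                   slope_threshold_nm_per_s: float = DEFAULT_SLOPE_THRESHOLD,
                   min_plateau_s: float = 30.0,
                   schedule: FlowSchedule | None = None,
                   slope_window: int = DEFAULT_SLOPE_WINDOW,
                   ) -> list[PhaseSegment]:
    """Split a sensogram into labelled binding phases.

    Without a schedule, a rolling least-squares slope classifies every
    sample (|slope| < threshold -> plateau, rising -> association,
    falling -> dissociation); runs are merged, short plateaus absorbed,
    and each boundary refined by intersecting the line fits of the two
    adjacent runs.  With a schedule, boundaries snap to the reagent
    switch times plus the chamber dead time and labels follow the
    segment roles (buffer -> baseline before any reagent, plateau after;
    receptor/analyte -> association; regeneration -> regeneration).
    """
    if slope_threshold_nm_per_s <= 0 or min_plateau_s <= 0:
        raise ValueError("thresholds must be positive")
    if len(s) < 5:
        raise ValueError("sensogram too short to segment (need >= 5 samples)")
    t, y = s.timestamps_s, s.area_nm

    if schedule is not None:
        return _segment_by_schedule(s, schedule)

    slopes = _rolling_slopes(t, y, slope_window)
    labels = np.where(np.abs(slopes) < slope_threshold_nm_per_s, 0,
                      np.where(slopes > 0, 1, -1))
    # merge consecutive equal labels into runs [start, stop)
    runs: list[list[int]] = []
    start = 0
    for i in range(1, t.size + 1):
        if i == t.size or labels[i] != labels[start]:
            runs.append([start, i, int(labels[start])])
            start = i
    # absorb plateau runs shorter than min_plateau_s into their neighbours
    dt = float(np.median(np.diff(t))) if t.size > 1 else 1.0
    min_run = max(2, int(round(min_plateau_s / dt)))
    merged: list[list[int]] = []
    for run in runs:
        if (run[2] == 0 and run[1] - run[0] < min_run and merged):
            merged[-1][1] = run[1]
        elif merged and merged[-1][2] == run[2]:
            merged[-1][1] = run[1]
        else:
            merged.append(run)
    runs = merged
    # refine boundaries between adjacent runs by line intersection
    half = max(1, min(slope_window, t.size) // 2)
    for k in range(len(runs) - 1):
        b = _refine_boundary(t, y, (runs[k][0], runs[k][1]),
                             (runs[k + 1][0], runs[k + 1][1]), runs[k][1], half)
        runs[k][1] = b
        runs[k + 1][0] = b

    label_map = {0: "plateau", 1: "association", -1: "dissociation"}
    segments: list[PhaseSegment] = []
    for j, (lo, hi, lab) in enumerate(runs):
        if hi - lo < 1:
            continue
        name = label_map[lab]
        if name == "plateau" and j == 0 and len(runs) > 1:
            name = "baseline"
        end = t[hi - 1] if hi - 1 > lo else t[min(hi, t.size - 1)]
        if end <= t[lo]:
            continue
        seg = PhaseSegment(name, float(t[lo]), float(end))
        if name in ("baseline", "plateau"):
            seg.plateau_value_nm = plateau_value(s, seg)
        segments.append(seg)
    return segments


_ROLE_LABEL = {"receptor": "association", "analyte": "association",
               "regeneration": "regeneration"}


def _segment_by_schedule(s: Sensogram, schedule: FlowSchedule) -> list[PhaseSegment]:
    t = s.timestamps_s
    segments: list[PhaseSegment] = []
    starts = schedule.start_times_s()
    seen_reagent = False

    def effective_start(i: int) -> float:
        # regeneration strips un-delayed at the pump switch; everything
        # else reaches the sensor after the chamber dead time
        seg = schedule.segments[i]
        if i == 0:
            return float(starts[i])
        if seg.role == "regeneration":
            return float(starts[i])
        return float(starts[i]) + dead_time(schedule.chamber_volume_uL,
                                            seg.flow_rate_uL_per_min)

    for i, seg in enumerate(schedule.segments):
        lo = effective_start(i)
        hi = (effective_start(i + 1) if i + 1 < len(schedule.segments)
              else float(t[-1]))
        lo, hi = max(lo, float(t[0])), min(hi, float(t[-1]))
        if hi <= lo:
            continue
        if seg.role == "buffer":
            label = "plateau" if seen_reagent else "baseline"
        else:
            label = _ROLE_LABEL[seg.role]
            seen_reagent = True
        phase = PhaseSegment(label, lo, hi, reagent=seg.reagent)
        if np.count_nonzero((t >= lo) & (t <= hi)):
            phase.plateau_value_nm = plateau_value(s, phase)
        segments.append(phase)
    return segments


def plateau_value(s: Sensogram, segment: PhaseSegment,
                  k: int = DEFAULT_PLATEAU_SAMPLES) -> float:
    """Plateau estimate: median of the segment's trailing ``k`` samples."""
    if k < 1:
        raise ValueError("k must be >= 1")
    mask = (s.timestamps_s >= segment.start_s) & (s.timestamps_s <= segment.end_s)
    vals = s.area_nm[mask]
    if vals.size == 0:
        raise ValueError("segment contains no sensogram samples")
    if vals.size < k:
        warnings.warn(f"segment has only {vals.size} samples; using all of them",
                      RuntimeWarning, stacklevel=2)
        k = vals.size
    return float(np.median(vals[-k:]))


def step_amplitude(before_nm: float, after_nm: float) -> float:
    """Signed plateau-to-plateau step: after - before (nm)."""
    if not (np.isfinite(before_nm) and np.isfinite(after_nm)):
        raise ValueError("plateau values must be finite")
    return float(after_nm - before_nm)


def baseline_uncertainty(baseline_ftrans_values: Sequence[float],
                         window: WavelengthWindow | None = None,
                         mode: Literal["literal", "robust"] = "literal",
                         robust_quantiles: tuple[float, float] = (0.005, 0.995),
                         ) -> float:
    """Readout uncertainty U = window width x baseline peak-to-peak (nm)."""
    if window is None:
        window = WavelengthWindow.default()
    return window.width_nm * peak_to_peak(baseline_ftrans_values, mode,
                                          robust_quantiles)


# ----------------------------------------------------------------------------
# calibration
# ----------------------------------------------------------------------------

@dataclass(frozen=True)
class BulkReading:
    """One (refractive index, resonance position) calibration point."""

    refractive_index: float
    position_nm: float

    def __post_init__(self) -> None:
        if not (1.0 <= self.refractive_index <= 2.0):
            raise ValueError("refractive index outside the plausible optical "
                             "range 1.0-2.0")
        if not np.isfinite(self.position_nm):
            raise ValueError("position must be finite")


@dataclass
class CalibrationResult:
    """All analytical figures of merit, with full internal precision."""

    bulk_sensitivity_nm_per_RIU: float | None
    analyte_sensitivity_nm_per_ug_mL: float
    window_width_nm: float
    baseline_p2p_per_unit: float
    uncertainty_nm: float
    lod_ug_mL: float
    lod_ng_mL: float
    lod_multiplier: float = 1.0
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not np.isclose(self.lod_ng_mL, 1000.0 * self.lod_ug_mL):
            raise ValueError("lod_ng_mL must equal 1000 x lod_ug_mL")
        if not np.isclose(self.uncertainty_nm,
                          self.window_width_nm * self.baseline_p2p_per_unit):
            raise ValueError("U must equal window width x baseline p2p")
        if not np.isclose(self.lod_ug_mL * self.analyte_sensitivity_nm_per_ug_mL,
                          self.lod_multiplier * self.uncertainty_nm):
            raise ValueError("lod_ug_mL must equal multiplier x U / m")

    def to_json_dict(self) -> dict:
        d = asdict(self)
        return d


def bulk_sensitivity(readings: Iterable[BulkReading],
                     method: Literal["endpoint", "least_squares"] = "endpoint",
                     ) -> float:
    """Bulk sensitivity S (nm/RIU) from refractometric readings.

    ``endpoint`` (default) is the difference quotient between the lowest-
    and highest-RI readings — the field's Δy/Δx convention; for the
    water/hexane pair (566 nm @ 1.33, 580 nm @ 1.37) it gives 350 nm/RIU.
    ``least_squares`` fits a line through all readings instead.
    """
    pts = sorted(readings, key=lambda r: r.refractive_index)
    if len(pts) < 2:
        raise ValueError("need at least 2 readings")
    x = np.array([r.refractive_index for r in pts])
    y = np.array([r.position_nm for r in pts])
    if x[-1] - x[0] <= 0:
        raise ValueError("readings must span a nonzero refractive-index range")
    if method == "endpoint":
        return float((y[-1] - y[0]) / (x[-1] - x[0]))
    if method == "least_squares":
        xc = x - x.mean()
        return float((xc @ (y - y.mean())) / (xc @ xc))
    raise ValueError("method must be 'endpoint' or 'least_squares'")


def analyte_sensitivity(delta_area_nm: float,
                        delta_concentration_ug_mL: float) -> float:
    """Analyte sensitivity m = delta_area / delta_concentration.

    The two-point slope of the readout against concentration, in nm per
    ug/mL (0.44 nm over 5 ug/mL gives 0.088).
    """
    if delta_concentration_ug_mL <= 0:
        raise ValueError("concentration delta must be positive")
    return float(delta_area_nm) / float(delta_concentration_ug_mL)


def area_uncertainty(window_width_nm: float, p2p_per_unit: float) -> float:
    """Area uncertainty U = window width x baseline peak-to-peak (nm)."""
    if window_width_nm < 0 or p2p_per_unit < 0:
        raise ValueError("inputs must be >= 0")
    return float(window_width_nm) * float(p2p_per_unit)


def limit_of_detection(U_nm: float, m_nm_per_ug_mL: float,
                       multiplier: float = 1.0) -> tuple[float, float]:
    """Limit of detection LoD = multiplier * U / m.

    Returns (ug/mL, ng/mL).  The default multiplier 1.0 follows the
    U/m convention; setting it to 3.3 gives the stricter IUPAC-style
    3.3 sigma/slope bound.
    """
    if m_nm_per_ug_mL <= 0:
        raise ValueError("sensitivity m must be positive")
    if U_nm < 0:
        raise ValueError("uncertainty U must be >= 0")
    lod_ug = multiplier * U_nm / m_nm_per_ug_mL
    return float(lod_ug), float(1000.0 * lod_ug)


def calibration_report(sensogram: Sensogram,
                       segmentation: Sequence[PhaseSegment],
                       analyte_concentration_ug_mL: float,
                       bulk_readings: Sequence[BulkReading] | None = None,
                       baseline_ftrans_values: Sequence[float] | None = None,
                       bulk_method: Literal["endpoint", "least_squares"] = "endpoint",
                       p2p_mode: Literal["literal", "robust"] = "literal",
                       plateau_samples: int = DEFAULT_PLATEAU_SAMPLES,
                       lod_multiplier: float = 1.0) -> CalibrationResult:
    """Assemble a full calibration from pipeline outputs.

    ΔA is the step from the plateau at the end of the receptor
    (immobilization) association to the plateau at the end of the first
    analyte (recognition) association; m = ΔA / C.  ΔI comes from the
    supplied baseline Ftrans values, or — when only the sensogram is
    available — from the baseline-segment area variation divided by the
    window width.  U = Δλ x ΔI and LoD = U / m.
    """
    pre = _find_plateau(sensogram, segmentation, "receptor", plateau_samples)
    post = _find_plateau(sensogram, segmentation, "analyte", plateau_samples)
    if pre is None:
        raise ValueError("missing immobilization (receptor) plateau: cannot "
                         "define the pre-recognition level")
    if post is None:
        raise ValueError("missing recognition (analyte) plateau: cannot "
                         "define the post-recognition level")
    delta_area = step_amplitude(pre[1], post[1])
    m = analyte_sensitivity(delta_area, analyte_concentration_ug_mL)

    width = sensogram.window.width_nm
    if baseline_ftrans_values is not None:
        p2p = peak_to_peak(baseline_ftrans_values, mode=p2p_mode)
    else:
        base = [seg for seg in segmentation if seg.label == "baseline"]
        if not base:
            raise ValueError("no baseline segment and no baseline Ftrans "
                             "values supplied")
        mask = ((sensogram.timestamps_s >= base[0].start_s)
                & (sensogram.timestamps_s <= base[0].end_s))
        vals = sensogram.area_nm[mask]
        if vals.size < 2:
            raise ValueError("baseline segment holds fewer than 2 samples")
        p2p = peak_to_peak(vals, mode=p2p_mode) / width
    U = area_uncertainty(width, p2p)
    lod_ug, lod_ng = limit_of_detection(U, m, multiplier=lod_multiplier)

    S = (bulk_sensitivity(bulk_readings, method=bulk_method)
         if bulk_readings else None)
    return CalibrationResult(
        bulk_sensitivity_nm_per_RIU=S,
        analyte_sensitivity_nm_per_ug_mL=m,
        window_width_nm=width,
        baseline_p2p_per_unit=p2p,
        uncertainty_nm=U,
        lod_ug_mL=lod_ug,
        lod_ng_mL=lod_ng,
        lod_multiplier=lod_multiplier,
        provenance={
            "pre_plateau_nm": pre[1], "post_plateau_nm": post[1],
            "pre_plateau_reagent": pre[0], "post_plateau_reagent": post[0],
            "delta_area_nm": delta_area,
            "analyte_concentration_ug_mL": analyte_concentration_ug_mL,
            "window": [sensogram.window.lo_nm, sensogram.window.hi_nm],
            "bulk_method": bulk_method, "p2p_mode": p2p_mode,
            "lod_multiplier": lod_multiplier,
            "baseline_source": ("ftrans_values" if baseline_ftrans_values
                                is not None else "sensogram_baseline"),
        })


def _find_plateau(sensogram: Sensogram, segmentation: Sequence[PhaseSegment],
                  role: str, k: int) -> tuple[str | None, float] | None:
    """Trailing plateau of the first association segment matching a role.

    Role matching uses the segment's reagent tag when present (schedule
    mode); otherwise the first/second association segments are taken as
    immobilization/recognition in order.
    """
    assoc = [seg for seg in segmentation if seg.label == "association"]
    if not assoc:
        return None
    tagged = [seg for seg in assoc if seg.reagent is not None]
    if tagged:
        # schedule mode: receptor = first association, analyte = the next one
        if role == "receptor":
            seg = assoc[0]
        else:
            if len(assoc) < 2:
                return None
            seg = assoc[1]
    else:
        order = {"receptor": 0, "analyte": 1}[role]
        if len(assoc) <= order:
            return None
        seg = assoc[order]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        return seg.reagent, plateau_value(sensogram, seg, k=k)


def render_report_markdown(result: CalibrationResult) -> str:
    """Human-readable calibration summary (3 significant figures)."""
    def sig3(x):
        return "n/a" if x is None else f"{x:.3g}"

    lines = [
        "# Calibration report",
        "",
        "| quantity | value |",
        "| --- | --- |",
        f"| bulk sensitivity S (nm/RIU) | {sig3(result.bulk_sensitivity_nm_per_RIU)} |",
        f"| analyte sensitivity m (nm per ug/mL) | {sig3(result.analyte_sensitivity_nm_per_ug_mL)} |",
        f"| window width (nm) | {sig3(result.window_width_nm)} |",
        f"| baseline p2p (per-unit) | {sig3(result.baseline_p2p_per_unit)} |",
        f"| uncertainty U (nm) | {sig3(result.uncertainty_nm)} |",
        f"| LoD (ug/mL) | {sig3(result.lod_ug_mL)} |",
        f"| LoD (ng/mL) | {sig3(result.lod_ng_mL)} |",
        "",
        "Provenance: " + json.dumps(result.provenance, sort_keys=True),
        "",
    ]
    return "\n".join(lines)


# ----------------------------------------------------------------------------
# file I/O
# ----------------------------------------------------------------------------

def write_spectrum(spectrum: Spectrum, path: str | Path) -> None:
    pd.DataFrame({"wavelength_nm": spectrum.wavelengths_nm,
                  "intensity": spectrum.intensities}).to_csv(path, index=False)


def read_spectrum(path: str | Path) -> Spectrum:
    df = pd.read_csv(path)
    _require_columns(df, ["wavelength_nm", "intensity"], path)
    _reject_bad_rows(df, path)
    return Spectrum(df["wavelength_nm"].to_numpy(),
                    df["intensity"].to_numpy(), label=str(path))


def write_ftrans_curve(curve: FtransCurve, path: str | Path) -> None:
    pd.DataFrame({"wavelength_nm": curve.wavelengths_nm,
                  "ftrans": curve.values}).to_csv(path, index=False)


def read_ftrans_curve(path: str | Path) -> FtransCurve:
    df = pd.read_csv(path)
    _require_columns(df, ["wavelength_nm", "ftrans"], path)
    _reject_bad_rows(df, path)
    return FtransCurve(df["wavelength_nm"].to_numpy(), df["ftrans"].to_numpy())


def _require_columns(df: pd.DataFrame, cols: list[str], path) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required column(s) {missing}")


def _reject_bad_rows(df: pd.DataFrame, path) -> None:
    bad = df.index[df.isna().any(axis=1) | ~np.isfinite(
        df.select_dtypes("number")).all(axis=1)]
    if len(bad):
        # +2: header line plus 1-based numbering
        rows = ", ".join(str(i + 2) for i in bad[:10])
        raise ValueError(f"{path}: non-numeric or non-finite values at "
                         f"line(s) {rows}")


def write_spectral_stack(stack: SpectralStack, path: str | Path,
                         dialect: Literal["long", "wide"] = "long") -> None:
    """Serialize a stack; long (`time_s,wavelength_nm,intensity`) is canonical."""
    if dialect == "long":
        n_t, n_w = stack.intensities.shape
        df = pd.DataFrame({
            "time_s": np.repeat(stack.timestamps_s, n_w),
            "wavelength_nm": np.tile(stack.wavelengths_nm, n_t),
            "intensity": stack.intensities.ravel(),
        })
        df.to_csv(path, index=False)
    elif dialect == "wide":
        df = pd.DataFrame(stack.intensities.T,
                          columns=[repr(float(t)) for t in stack.timestamps_s])
        df.insert(0, "wavelength_nm", stack.wavelengths_nm)
        df.to_csv(path, index=False)
    else:
        raise ValueError("dialect must be 'long' or 'wide'")


def read_spectral_stack(path: str | Path,
                        dialect: Literal["long", "wide"] = "long") -> SpectralStack:
    """Parse a stack CSV, validating the common grid and timestamps.

    Malformed rows (NaN, non-numeric) are rejected with their line
    numbers; wide files with shuffled timestamp columns are sorted with
    a warning; duplicate timestamps are rejected.
    """
    if dialect == "long":
        df = pd.read_csv(path)
        _require_columns(df, ["time_s", "wavelength_nm", "intensity"], path)
        _reject_bad_rows(df, path)
        times = np.array(sorted(df["time_s"].unique()))
        grids = []
        intens = []
        for t in times:
            sub = df[df["time_s"] == t].sort_values("wavelength_nm")
            grids.append(sub["wavelength_nm"].to_numpy())
            intens.append(sub["intensity"].to_numpy())
        grid = grids[0]
        for i, g in enumerate(grids[1:], 1):
            if not _same_grid(grid, g):
                raise ValueError(f"{path}: timepoint {times[i]} is on a "
                                 "different wavelength grid")
        return SpectralStack(grid, times, np.vstack(intens))
    if dialect == "wide":
        df = pd.read_csv(path)
        _require_columns(df, ["wavelength_nm"], path)
        _reject_bad_rows(df, path)
        tcols = [c for c in df.columns if c != "wavelength_nm"]
        try:
            times = np.array([float(c) for c in tcols])
        except ValueError as exc:
            raise ValueError(f"{path}: timestamp columns must be numeric") from exc
        if np.unique(times).size != times.size:
            raise ValueError(f"{path}: duplicate timestamps")
        order = np.argsort(times)
        if not np.all(order == np.arange(times.size)):
            warnings.warn(f"{path}: timestamp columns were not sorted; "
                          "sorting ascending", RuntimeWarning, stacklevel=2)
        times = times[order]
        intens = df[tcols].to_numpy().T[order]
        return SpectralStack(df["wavelength_nm"].to_numpy(), times, intens)
    raise ValueError("dialect must be 'long' or 'wide'")


def write_sensogram(s: Sensogram, path: str | Path) -> None:
    data = {"time_s": s.timestamps_s, "ftrans_area_nm": s.area_nm}
    if s.mode_position_nm is not None:
        data["mode_position_nm"] = s.mode_position_nm
    pd.DataFrame(data).to_csv(path, index=False, float_format="%.12g")


def read_sensogram(path: str | Path,
                   window: WavelengthWindow | None = None) -> Sensogram:
    df = pd.read_csv(path)
    _require_columns(df, ["time_s", "ftrans_area_nm"], path)
    _reject_bad_rows(df, path)
    return Sensogram(
        df["time_s"].to_numpy(), df["ftrans_area_nm"].to_numpy(),
        window if window is not None else WavelengthWindow.default(),
        mode_position_nm=(df["mode_position_nm"].to_numpy()
                          if "mode_position_nm" in df.columns else None))


def write_segments(segments: Sequence[PhaseSegment], path: str | Path) -> None:
    Path(path).write_text(json.dumps(
        [{"label": s.label, "start_s": s.start_s, "end_s": s.end_s,
          "plateau_value_nm": s.plateau_value_nm, "reagent": s.reagent}
         for s in segments], indent=2))


def read_segments(path: str | Path) -> list[PhaseSegment]:
    raw = json.loads(Path(path).read_text())
    return [PhaseSegment(**d) for d in raw]
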