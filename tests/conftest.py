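import numpy as np
import pytest

import ftranskit as fk


@pytest.fixture(scope="session")
def grid():
    return np.arange(548.0, 590.0 + 1e-9, 0.1)


@pytest.fixture(scope="session")
def resonance():
    return fk.ResonanceModel()


@pytest.fixture(scope="session")
def reference(resonance, grid):
    return fk.generate_spectrum(resonance, 0.0, grid)


@pytest.fixture(scope="session")
def window():
    return fk.WavelengthWindow.default()


def run_il8_pipeline(seed: int, noise_sd: float = 5e-5):
    """One full synthetic antibody/antigen run through the whole pipeline."""
    scenario = fk.il8_scenario(noise_sd=noise_sd, seed=seed)
    stack, truth = scenario.run(seed=seed)
    sensogram = fk.build_sensogram(stack, scenario.reference_spectrum())
    segments = fk.segment_phases(sensogram, schedule=scenario.schedule)
    report = fk.calibration_report(sensogram, segments,
                                   analyte_concentration_ug_mL=5.0)
    baseline = next(s for s in segments if s.label == "baseline")
    imm_step = fk.step_amplitude(baseline.plateau_value_nm,
                                 report.provenance["pre_plateau_nm"])
    rec_step = report.provenance["delta_area_nm"]
    return {"imm_step": imm_step, "rec_step": rec_step,
            "m": report.analyte_sensitivity_nm_per_ug_mL,
            "lod_ng_mL": report.lod_ng_mL, "truth": truth,
            "sensogram": sensogram, "segments": segments}


@pytest.fixture(scope="session")
def il8_runs():
    """Twenty seeded end-to-end runs at the default noise level."""
    return [run_il8_pipeline(seed) for seed in range(20)]
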