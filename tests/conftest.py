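"""Shared simulation fixtures.

The heavier simulations (1600 s records through the full extraction chain)
are session-scoped so the modules that probe different aspects of the same
study conditions reuse one realization.
"""

import warnings

import numpy as np
import pytest

from pttsaw import ptt, synth


@pytest.fixture(scope="session")
def skew_subject():
    """1600 s subject with default physiology and the 100 s artifact preset."""
    cfg = synth.SimulationConfig(duration=1600.0, seed=5)
    clock = synth.preset_clock("skwhsmh")
    ecg, ppg, truth = synth.simulate_subject(cfg, clock)
    series, ann = ptt.extract_ptt_series(ecg, ppg)
    return {
        "config": cfg,
        "clock": clock,
        "ecg": ecg,
        "ppg": ppg,
        "truth": truth,
        "series": series,
        "annotations": ann,
    }


@pytest.fixture(scope="session")
def flat_ptt_skew_subject():
    """1600 s subject with constant true PTT (0.25 s) and the 100 s artifact.

    Isolates the clock artifact: any oscillation in the extracted PTT is
    either the sawtooth or extraction noise.
    """
    cfg = synth.SimulationConfig(duration=1600.0, ptt_modulations=(), seed=1)
    clock = synth.preset_clock("skwhsmh")
    ecg, ppg, truth = synth.simulate_subject(cfg, clock)
    series, _ = ptt.extract_ptt_series(ecg, ppg)
    return {"config": cfg, "clock": clock, "truth": truth, "series": series}


@pytest.fixture(scope="session")
def clean_subject():
    """1600 s subject with zero clock drift (physiology + noise only)."""
    cfg = synth.SimulationConfig(duration=1600.0, seed=7)
    ecg, ppg, truth = synth.simulate_subject(cfg, None)
    series, _ = ptt.extract_ptt_series(ecg, ppg)
    return {"config": cfg, "truth": truth, "series": series}


@pytest.fixture(autouse=True)
def _quiet_low_cycle_warning():
    """The default dsSTFT band bottom holds <2 cycles per window by design."""
    with warnings.catch_warnings():
        warnings.filterwarnings(
            "ignore", message="window holds only", category=UserWarning
        )
        yield


@pytest.fixture
def rng():
    return np.random.default_rng(0)
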