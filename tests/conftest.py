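import numpy as np
import pytest

from smo2kinetics.preprocess import UniformWindow
from smo2kinetics.segmentation import ExercisePhaseFit, LineSegment
from smo2kinetics.simulate import preset_scenarios, simulate_session, three_phase_values


@pytest.fixture(scope="session")
def spar_record():
    truth = preset_scenarios("spar", seed=11)
    return simulate_session(truth), truth


def make_round_window(td, fdr, dd, level=70.0, duration=180, delay_slope=0.0,
                      ss_slope=0.0, noise_sd=0.0, seed=0, hr=None):
    """Round window sampled at 1 Hz from the three-phase generating model."""
    t = np.arange(float(duration))
    y = three_phase_values(t, td, td + dd, level, delay_slope, fdr, ss_slope)
    if noise_sd > 0:
        y = y + np.random.default_rng(seed).normal(0, noise_sd, t.size)
    return UniformWindow("round", 1, "lead", t, y, hr, 0.0)


def make_rest_window(rd, frr, frd, level=30.0, duration=60, sr_slope=0.05,
                     noise_sd=0.0, seed=0, hr=None):
    t = np.arange(float(duration))
    y = three_phase_values(t, rd, rd + frd, level, 0.0, frr, sr_slope)
    if noise_sd > 0:
        y = y + np.random.default_rng(seed).normal(0, noise_sd, t.size)
    return UniformWindow("rest", 1, "lead", t, y, hr, 0.0)


def make_exercise_fit(td, fdr, dd, level=70.0):
    """Minimal ExercisePhaseFit for metric tests (segments are placeholders)."""
    segs = (
        LineSegment(level, 0.0, (0.0, td), int(td)),
        LineSegment(level + fdr * -td, fdr, (td, td + dd), int(dd)),
        LineSegment(level + fdr * dd, 0.0, (td + dd, 180.0), int(180 - td - dd)),
    )
    return ExercisePhaseFit(
        TD=td, FDR=fdr, DD=dd, SS_level=level + fdr * dd,
        HRS=np.nan, HRE=np.nan, MAD_FD=0.0, MAD_Eq=0.0,
        segments=segs, sse=0.0,
    )
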