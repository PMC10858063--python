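"""Simulator contracts: determinism, noiseless identity, preset realism."""

from dataclasses import replace

import numpy as np
import pytest

from smo2kinetics.preprocess import extract_windows, filter_record
from smo2kinetics.simulate import (
    ChromophoreState,
    GroundTruth,
    HeartRateParams,
    RestKinetics,
    RoundKinetics,
    compute_smo2,
    preset_scenarios,
    simulate_cohort,
    simulate_session,
    three_phase_values,
    _mean_smo2,
)


class TestChromophoreRatio:
    @pytest.mark.parametrize(
        "state, expected",
        [
            (ChromophoreState(40, 10, 30, 20), 50.0),
            (ChromophoreState(40, 10, 0, 0), 100.0),
            (ChromophoreState(0, 0, 30, 20), 0.0),
        ],
    )
    def test_ratio(self, state, expected):
        assert compute_smo2(state) == pytest.approx(expected)

    def test_all_zero_state_undefined(self):
        with pytest.raises(ValueError):
            compute_smo2(ChromophoreState(0, 0, 0, 0))

    def test_negative_amplitude_rejected(self):
        with pytest.raises(ValueError):
            ChromophoreState(-1, 1, 1, 1)


def noiseless_truth(**overrides):
    """Hand-built truth with integer breakpoints so the 1 Hz export sits
    exactly on the generating piecewise-linear mean."""
    rounds = tuple(RoundKinetics(td=12, fdr=-1.5, dd=20) for _ in range(6))
    rests = tuple(RestKinetics(rd=10, frr=0.9, frd=30) for _ in range(6))
    kw = dict(
        modality="bag",
        rounds={"lead": rounds, "rear": rounds},
        rests={"lead": rests, "rear": rests},
        hr=HeartRateParams(),
        punch_rates={"TD": 1.0, "FD": 1.0, "SS": 1.0},
        start_level={"lead": 70.0, "rear": 70.0},
        noise_sd=0.0,
        artifact_rate=0.0,
        seed=1,
    )
    kw.update(overrides)
    return GroundTruth(**kw)


class TestSimulateSession:
    def test_same_seed_gives_identical_records(self):
        truth = preset_scenarios("pad", seed=21)
        a = simulate_session(truth)
        b = simulate_session(truth)
        for leg in ("lead", "rear"):
            np.testing.assert_array_equal(a.series[leg].smo2, b.series[leg].smo2)
            np.testing.assert_array_equal(a.series[leg].hr, b.series[leg].hr)
        np.testing.assert_array_equal(a.punches.event_times, b.punches.event_times)

    def test_different_seed_differs(self):
        truth = preset_scenarios("pad", seed=21)
        b = simulate_session(truth, seed=22)
        a = simulate_session(truth)
        assert not np.array_equal(a.series["lead"].smo2, b.series["lead"].smo2)

    def test_noiseless_trace_equals_generating_mean(self):
        rec = simulate_session(noiseless_truth())
        s = rec.series["lead"]
        np.testing.assert_allclose(
            s.smo2, _mean_smo2(noiseless_truth(), "lead", s.time), atol=1e-9
        )

    def test_smo2_stays_in_range_with_noise_and_artifacts(self):
        truth = replace(preset_scenarios("bag", seed=2), artifact_rate=0.05)
        rec = simulate_session(truth)
        for leg in ("lead", "rear"):
            assert rec.series[leg].smo2.min() >= 0.0
            assert rec.series[leg].smo2.max() <= 100.0

    def test_overlong_phase_rejected(self):
        with pytest.raises(ValueError):
            noiseless_truth(
                rounds={
                    "lead": tuple(RoundKinetics(td=100, fdr=-1, dd=100) for _ in range(6)),
                    "rear": tuple(RoundKinetics(td=12, fdr=-1, dd=20) for _ in range(6)),
                }
            )

    def test_isolated_spike_removed_exactly_on_flat_trace(self):
        # piecewise-constant phase: the 5 s median restores every sample
        from smo2kinetics.preprocess import median_filter
        from smo2kinetics.session import SampleSeries

        clean = simulate_session(noiseless_truth()).series["lead"]
        spiked = clean.smo2.copy()
        flat_idx = 100  # well inside round 1 steady state
        spiked[flat_idx] -= 30.0
        filt = median_filter(SampleSeries(clean.time, spiked))
        np.testing.assert_allclose(filt.smo2[flat_idx - 3: flat_idx + 4],
                                   clean.smo2[flat_idx - 3: flat_idx + 4],
                                   atol=1e-9)


class TestPresets:
    def test_unknown_preset_rejected(self):
        with pytest.raises(ValueError):
            preset_scenarios("shadow")

    @pytest.mark.parametrize("name", ["bag", "pad", "spar"])
    def test_slope_signs(self, name):
        truth = preset_scenarios(name)
        for leg in ("lead", "rear"):
            assert all(k.fdr < 0 for k in truth.rounds[leg])
            assert all(k.frr > 0 for k in truth.rests[leg])

    def test_pad_fast_phase_punch_rate_exceeds_spar(self):
        assert (preset_scenarios("pad").punch_rates["FD"]
                > preset_scenarios("spar").punch_rates["FD"])

    def test_round_total_punch_counts_by_modality(self):
        # spar is far less punch-dense than bag work
        means = {}
        for name, lo, hi in (("spar", 40, 80), ("bag", 150, 200)):
            totals = []
            for s in range(25):
                truth = preset_scenarios(name, seed=300 + s)
                rec = simulate_session(truth)
                totals.append(rec.punches.event_times.size / truth.n_rounds)
            means[name] = np.mean(totals)
            assert lo <= means[name] <= hi, means

    def test_punch_expectation_matches_rates(self):
        truth = preset_scenarios("spar")
        expect = 0.0
        for k in truth.rounds["lead"]:
            expect += truth.punch_rates["TD"] * k.td
            expect += truth.punch_rates["FD"] * k.dd
            expect += truth.punch_rates["SS"] * (truth.round_duration - k.td - k.dd)
        counts = [
            simulate_session(preset_scenarios("spar", seed=500 + s)).punches.event_times.size
            for s in range(30)
        ]
        se = np.std(counts, ddof=1) / np.sqrt(len(counts))
        assert abs(np.mean(counts) - expect) < 4 * se + 1e-9

    def test_mean_trace_stays_physiological(self):
        t = np.arange(0.0, 1440.0, 0.5)
        for name in ("bag", "pad", "spar"):
            truth = preset_scenarios(name)
            for leg in ("lead", "rear"):
                mean = _mean_smo2(truth, leg, t)
                assert mean.min() > 5.0 and mean.max() < 95.0


class TestCohort:
    def test_cohort_shape_and_determinism(self):
        a = simulate_cohort(2, seed=5)
        b = simulate_cohort(2, seed=5)
        assert len(a) == 2 * 3
        assert {m for _, m, _, _ in a} == {"bag", "pad", "spar"}
        np.testing.assert_array_equal(
            a[0][2].series["lead"].smo2, b[0][2].series["lead"].smo2
        )

    def test_athlete_effects_shared_across_modalities(self):
        cohort = simulate_cohort(2, seed=5)
        by_athlete = {}
        for athlete, modality, _, truth in cohort:
            by_athlete.setdefault(athlete, {})[modality] = truth
        for truths in by_athlete.values():
            # same athlete-level HR offset applied to each modality's preset
            # (kinetics additionally carry round-to-round session jitter)
            shifts = {
                m: truths[m].hr.start - preset_scenarios(m).hr.start
                for m in truths
            }
            vals = list(shifts.values())
            assert max(vals) - min(vals) < 1e-9
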