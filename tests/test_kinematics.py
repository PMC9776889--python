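"""Cycle detection, diastolic peaks, correlations, torsion correlation,
retrospective-cine emulation."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from lvtrack.errors import AnalysisError, ClassificationError, NoCyclesFound
from lvtrack.kinematics import (CycleSegmentation, detect_cycles,
                                diastolic_peak_velocities, emulate_retro_cine,
                                classify_slices, slice_correlation,
                                torsion_correlation)
from lvtrack.tracking import BoundaryTrajectories, VelocityTraces


def area_trace(periods_ms, dt=20.0, base=1500.0, depth=800.0, sf=0.35):
    """Pool-area trace over full cycles, starting/ending at end-diastole."""
    from lvtrack.phantom import contraction_waveform
    bounds = np.concatenate([[0.0], np.cumsum(periods_ms)])
    t = np.arange(0.0, bounds[-1] + dt / 2, dt)
    k = np.clip(np.searchsorted(bounds, t, side="right") - 1,
                0, len(periods_ms) - 1)
    phase = (t - bounds[k]) / np.asarray(periods_ms)[k]
    return base - depth * contraction_waveform(phase, sf), t, bounds


class TestDetectCycles:
    def test_constant_trace(self):
        with pytest.raises(NoCyclesFound):
            detect_cycles(np.full(300, 10.0), np.arange(300) * 20.0)

    def test_eight_uniform_cycles(self):
        area, t, bounds = area_trace([900.0] * 8)
        cycles = detect_cycles(area, t)
        assert cycles.n_cycles == 8
        assert np.all(np.abs(cycles.periods_ms - 900.0) <= 20.0)
        # end-systole sits strictly inside each cycle
        assert np.all(cycles.es_frames > cycles.boundaries[:-1])
        assert np.all(cycles.es_frames < cycles.boundaries[1:])

    def test_jittered_periods_recovered(self, rng):
        periods = 900.0 * (1 + rng.uniform(-0.1, 0.1, size=8))
        area, t, bounds = area_trace(list(periods))
        cycles = detect_cycles(area, t)
        assert cycles.n_cycles == 8
        assert np.all(np.abs(cycles.periods_ms - periods) <= 20.0 + 1e-9)

    def test_too_short_trace(self):
        with pytest.raises(NoCyclesFound):
            detect_cycles(np.sin(np.arange(10)), np.arange(10) * 20.0)


def _traces(v_rad, v_circ, dt=20.0):
    n = len(v_rad)
    return VelocityTraces((np.arange(n) + 0.5) * dt, np.asarray(v_rad,
                          dtype=float), np.asarray(v_circ, dtype=float))


def _cycles_for(n_samples, period_frames, dt=20.0, sf=0.35):
    n_cycles = n_samples // period_frames
    bounds = np.arange(n_cycles + 1) * period_frames
    es = bounds[:-1] + int(sf * period_frames)
    return CycleSegmentation(bounds, es, np.arange(n_samples + 1) * dt)


class TestPeaks:
    def test_zero_traces_zero_peaks(self):
        tr = _traces(np.zeros(90), np.zeros(90))
        cy = _cycles_for(90, 45)
        out = diastolic_peak_velocities([tr], [cy], [-1.0])
        assert out.subject_radial == 0.0
        assert out.subject_circ == 0.0

    def test_sinusoid_peak_amplitude(self):
        # diastole covers the half-cycle where the outward velocity > 0
        T = 45
        t = np.arange(2 * T)
        v = 10.0 * np.sin(2 * np.pi * (t - T * 0.35) / T)
        tr = _traces(v, -v)
        cy = _cycles_for(2 * T, T)
        out = diastolic_peak_velocities([tr], [cy], [+1.0])
        assert out.subject_radial == pytest.approx(10.0, rel=0.01)
        assert out.subject_circ == pytest.approx(10.0, rel=0.01)

    def test_recoil_direction_sign(self):
        """The circumferential peak is taken opposite to the systolic
        rotation: a clockwise (basal) slice reads the counter-clockwise
        recoil and vice versa."""
        T = 40
        cycle = np.zeros(T)
        cycle[14:27] = -5.0        # early diastole
        cycle[27:] = +3.0          # late diastole
        tr = _traces(np.ones(2 * T), np.tile(cycle, 2))
        cy = _cycles_for(2 * T, T)
        basal = diastolic_peak_velocities([tr], [cy], [-1.0])
        apical = diastolic_peak_velocities([tr], [cy], [+1.0])
        assert basal.subject_circ == pytest.approx(3.0)
        assert apical.subject_circ == pytest.approx(5.0)


class TestSliceCorrelation:
    def test_proportional_traces(self, rng):
        v = rng.normal(size=90)
        cy = _cycles_for(90, 45)
        assert slice_correlation(_traces(v, 2 * v), cy) == pytest.approx(1.0)
        assert slice_correlation(_traces(v, -v), cy) == pytest.approx(-1.0)

    def test_orthogonal_sinusoids(self):
        t = np.arange(360)
        v1 = np.sin(2 * np.pi * t / 45)
        v2 = np.cos(2 * np.pi * t / 45)
        cy = _cycles_for(360, 45)
        assert abs(slice_correlation(_traces(v1, v2), cy)) < 0.02

    def test_zero_variance_flagged_nan(self, rng):
        v = rng.normal(size=90)
        cy = _cycles_for(90, 45)
        assert np.isnan(slice_correlation(_traces(v, np.zeros(90)), cy))

    def test_too_few_samples(self):
        with pytest.raises(AnalysisError):
            slice_correlation(_traces(np.arange(4.0), np.arange(4.0)),
                              mode="single_cycle")


def _rot_traj(net_angle, n_frames=91, n_points=8):
    """Trajectories whose mean angle swings by net_angle at end-systole."""
    from lvtrack.phantom import contraction_waveform
    phase = np.linspace(0, 2, n_frames, endpoint=False)
    ang = net_angle * contraction_waveform(phase)
    angle = np.tile(np.arange(n_points) * 2 * np.pi / n_points,
                    (n_frames, 1)) + ang[:, None]
    radius = np.full((n_frames, n_points), 12.0)
    return BoundaryTrajectories(radius, angle,
                                np.ones((n_frames - 1, n_points)),
                                np.arange(n_frames) * 20.0)


class TestClassification:
    def test_rotation_sign_maps_to_level(self):
        cy = _cycles_for(90, 45)
        labels = classify_slices([_rot_traj(-0.1), _rot_traj(+0.1),
                                  _rot_traj(0.001)], [cy, cy, cy])
        assert labels == ["basal", "apical", "excluded"]

    def test_all_excluded_raises(self):
        cy = _cycles_for(90, 45)
        with pytest.raises(ClassificationError):
            classify_slices([_rot_traj(0.0)], [cy])

    def test_phantom_slices_classified_by_design(self, small_subject):
        from lvtrack.pipeline import analyze_subject
        res = analyze_subject(small_subject.series)
        assert res.classification == ["basal", "apical"]


class TestTorsionCorrelation:
    def test_bound_case(self):
        res = torsion_correlation([1, 1, 1, -1, -1, -1],
                                  ["basal"] * 3 + ["apical"] * 3)
        assert res.tc == pytest.approx(2.0)

    def test_zero_case(self):
        res = torsion_correlation([0, 0], ["basal", "apical"])
        assert res.tc == 0.0

    def test_worked_arithmetic(self):
        res = torsion_correlation([0.7, 0.5, -0.3, -0.5],
                                  ["basal", "basal", "apical", "apical"])
        assert res.mean_r_basal == pytest.approx(0.6)
        assert res.mean_r_apical == pytest.approx(-0.4)
        assert res.tc == pytest.approx(1.0)

    def test_excluded_and_nan_omitted(self):
        res = torsion_correlation([0.8, np.nan, 0.9, -0.2],
                                  ["basal", "basal", "excluded", "apical"])
        assert res.mean_r_basal == pytest.approx(0.8)
        assert res.tc == pytest.approx(1.0)

    def test_empty_side_raises(self):
        with pytest.raises(AnalysisError):
            torsion_correlation([0.5, 0.4], ["basal", "basal"])

    @given(st.lists(st.floats(-1, 1), min_size=2, max_size=8),
           st.floats(0.1, 10.0))
    @settings(max_examples=60, deadline=None, derandomize=True)
    def test_identity_bounds_and_scale_invariance(self, rs, scale):
        """TC equals the difference of the two means, lies in [-2, 2], and
        is invariant to positive rescaling of the circumferential traces
        (robustness to the angular-vs-linear ambiguity)."""
        labels = ["basal" if i % 2 == 0 else "apical"
                  for i in range(len(rs))]
        if len(rs) < 2:
            return
        res = torsion_correlation(rs + [0.5, -0.5],
                                  labels + ["basal", "apical"])
        assert res.tc == res.mean_r_basal - res.mean_r_apical
        assert -2.0 <= res.tc <= 2.0
        # rescaling v_circ rescales nothing: r is scale-free
        rng_l = np.random.default_rng(0)
        v1 = rng_l.normal(size=50)
        v2 = rng_l.normal(size=50) + 0.5 * v1
        tr1 = _traces(v1, v2, dt=20.0)
        tr2 = _traces(v1, scale * v2, dt=20.0)
        r1 = slice_correlation(tr1, mode="single_cycle")
        r2 = slice_correlation(tr2, mode="single_cycle")
        assert r1 == pytest.approx(r2, abs=1e-12)


class TestRetroCine:
    def test_identical_cycles_reproduced(self):
        T = 45
        v = np.sin(2 * np.pi * np.arange(T) / T)
        tr = _traces(np.tile(v, 4), np.tile(-v, 4))
        cy = _cycles_for(4 * T, T)
        cine = emulate_retro_cine(tr, cy, n_phases=15)
        single = v[::3][:15]
        assert len(cine.v_rad) == 15
        assert np.allclose(cine.v_rad, np.convolve(
            np.tile(v, 2), np.ones(3) / 3, "full")[2:3 * 15:3], atol=0.15)
        assert np.corrcoef(cine.v_rad, -cine.v_circ)[0, 1] > 0.999

    def test_needs_two_cycles(self):
        tr = _traces(np.ones(45), np.ones(45))
        cy = _cycles_for(45, 45)
        with pytest.raises(ValueError):
            emulate_retro_cine(tr, cy)

    def test_averaging_restores_coupling(self):
        """Two cycles with equal-and-opposite timing jitter on the
        circumferential trace: the virtual cycle is better coupled than
        either single cycle."""
        T = 48
        t = np.arange(T)
        v = np.sin(2 * np.pi * t / T)
        shift = 4
        v_c1 = np.roll(v, +shift)
        v_c2 = np.roll(v, -shift)
        tr = _traces(np.tile(v, 2), np.concatenate([v_c1, v_c2]))
        cy = _cycles_for(2 * T, T)
        per_cycle = []
        for k in range(2):
            s = slice(k * T, (k + 1) * T)
            per_cycle.append(abs(np.corrcoef(tr.v_rad[s],
                                             tr.v_circ[s])[0, 1]))
        cine = emulate_retro_cine(tr, cy, n_phases=16)
        r_cine = abs(slice_correlation(cine, mode="single_cycle"))
        assert r_cine >= np.mean(per_cycle)
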