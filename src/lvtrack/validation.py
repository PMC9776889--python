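"""Reference validation experiments on phantoms with known ground truth.

These functions define the package's standard self-validation: velocity
recovery against the analytic truth, the basal/apical sign structure of the
radial-circumferential correlation, the real-time vs retrospective-cine
torsion-correlation contrast on seeded cohorts, and volumetric accuracy.
They are exercised by the test suite and by ``scripts/acceptance.py``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import kinematics, phantom, pipeline
from .segmentation import segment_series
from .stats import one_way_anova
from .tracking import track_series, trajectories_to_velocity
from .volumetrics import lv_volumes, pick_phases

__all__ = [
    "SNR20_NOISE_SD",
    "velocity_recovery",
    "healthy_sign_structure",
    "cohort_tc_experiment",
    "pipeline_ef_error",
    "cycle_detection_check",
]

#: additive noise SD giving SNR 20 with the default myocardial signal
#: (SNR = mean tissue intensity / noise SD, the usual MRI convention)
SNR20_NOISE_SD = phantom.RenderSettings().myo_intensity / 20.0


def _default_subject(seed: int, noise_sd: float) -> phantom.PhantomSubject:
    """The reference phantom: 6 slices, 8 cycles, 96 x 96 px, default
    healthy coupled motion."""
    params = phantom.default_slice_params(6)
    settings = phantom.RenderSettings(noise_sd=noise_sd)
    return phantom.generate_subject(params, n_cycles=8, seed=seed,
                                    settings=settings)


@dataclass
class VelocityRecovery:
    """Worst-slice RMS velocity errors as fractions of the true peaks."""

    rms_vrad: list
    rms_vcirc: list
    subject: phantom.PhantomSubject

    @property
    def worst_vrad(self) -> float:
        return max(self.rms_vrad)

    @property
    def worst_vcirc(self) -> float:
        return max(self.rms_vcirc)


def velocity_recovery(seed: int = 1, noise_sd: float = 0.0,
                      subject: phantom.PhantomSubject | None = None
                      ) -> VelocityRecovery:
    """Track the reference phantom and compare slice-averaged velocities
    with the analytic truth.

    The per-slice error is the RMS of (estimated - true) over all frame
    midpoints, normalised by the true peak of that component.
    """
    subject = subject or _default_subject(seed, noise_sd)
    rms_r, rms_c = [], []
    for ser, gt in zip(subject.series, subject.truth):
        contours, _ = segment_series(ser)
        traj = track_series(ser, contours)
        traces = trajectories_to_velocity(traj, ser.pixel_spacing)
        rms_r.append(float(np.sqrt(np.mean((traces.v_rad - gt.v_rad) ** 2))
                           / np.abs(gt.v_rad).max()))
        rms_c.append(float(np.sqrt(np.mean((traces.v_circ - gt.v_circ) ** 2))
                           / np.abs(gt.v_circ).max()))
    return VelocityRecovery(rms_r, rms_c, subject)


def healthy_sign_structure(seed: int = 1,
                           subject: phantom.PhantomSubject | None = None):
    """Per-slice radial-circumferential Pearson r of a healthy coupled
    phantom, with the basal/apical classification.

    Returns ``(r_per_slice, classification, result)``.
    """
    subject = subject or _default_subject(seed, noise_sd=0.0)
    res = pipeline.analyze_subject(subject.series, label=subject.label,
                                   group="healthy")
    return [s.r_realtime for s in res.slices], res.classification, res


@dataclass
class CohortTcResult:
    tc_rt_healthy: list
    tc_rt_decoupled: list
    tc_cine_healthy: list
    tc_cine_decoupled: list

    @property
    def realtime_gap(self) -> float:
        return float(np.mean(self.tc_rt_healthy)
                     - np.mean(self.tc_rt_decoupled))

    @property
    def cine_gap(self) -> float:
        return float(np.mean(self.tc_cine_healthy)
                     - np.mean(self.tc_cine_decoupled))

    @property
    def anova_p_realtime(self) -> float:
        return one_way_anova({"healthy": self.tc_rt_healthy,
                              "decoupled": self.tc_rt_decoupled}).p

    @property
    def gap_ratio(self) -> float:
        """Cine between-group gap as a fraction of the realtime gap."""
        return self.cine_gap / self.realtime_gap


def cohort_tc_experiment(n_per_group: int = 10, base_seed: int = 1,
                         decouple_sd: float = 60.0) -> CohortTcResult:
    """The real-time vs retrospective-cine contrast on seeded cohorts.

    Healthy (coupled) and decoupled regimes share subject seeds
    ``base_seed .. base_seed + n - 1``; the decoupled regime carries a
    per-cycle rotation-timing offset (SD ``decouple_sd`` ms) and rotation
    amplitude jitter that real-time analysis sees but multi-cycle cine
    averaging hides.
    """
    out = {"healthy": ([], []), "decoupled": ([], [])}
    for regime in out:
        subjects = phantom.generate_cohort(regime, n_per_group,
                                           base_seed=base_seed,
                                           decouple_sd=decouple_sd)
        for subj in subjects:
            res = pipeline.analyze_subject(subj.series, label=subj.label,
                                           group=regime)
            out[regime][0].append(res.tc_realtime)
            out[regime][1].append(res.tc_cine)
    return CohortTcResult(out["healthy"][0], out["decoupled"][0],
                          out["healthy"][1], out["decoupled"][1])


def pipeline_ef_error(subject: phantom.PhantomSubject) -> tuple:
    """Full-pipeline EF vs the geometric truth EF, in percentage points.

    Returns ``(ef_pct, truth_ef_pct, error_pct_points)``.
    """
    areas = []
    for ser in subject.series:
        _, a = segment_series(ser)
        areas.append(a)
    areas = np.vstack(areas)
    ed, es, _ = pick_phases(areas, subject.series[0].frame_times)
    vols = lv_volumes(areas[:, ed], areas[:, es],
                      subject.thickness, subject.gap)
    truth_pct = 100.0 * subject.truth_ef
    return vols.ef_pct, truth_pct, vols.ef_pct - truth_pct


def cycle_detection_check(seed: int = 1, n_cycles: int = 8,
                          period: float = 900.0, dt: float = 20.0,
                          jitter: float = 0.10) -> tuple:
    """Cycle detection on a constructed area trace with jittered periods.

    Returns ``(n_detected, max_period_error_ms, true_periods)``.
    """
    rng = np.random.default_rng(seed)
    periods = period * (1.0 + rng.uniform(-jitter, jitter, n_cycles))
    bounds = np.concatenate([[0.0], np.cumsum(periods)])
    t = np.arange(0.0, bounds[-1] + dt / 2, dt)
    k = np.clip(np.searchsorted(bounds, t, side="right") - 1, 0,
                n_cycles - 1)
    phase = (t - bounds[k]) / periods[k]
    area = 1500.0 - 800.0 * phantom.contraction_waveform(phase)
    cycles = kinematics.detect_cycles(area, t)
    err = np.abs(cycles.periods_ms - periods[:cycles.n_cycles]).max() \
        if cycles.n_cycles == n_cycles else float("inf")
    return cycles.n_cycles, float(err), periods
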