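"""Cycle-resolved wall-motion analysis.

Real-time series are ungated, so cardiac cycles are found from the blood-
pool area trace: smoothed local maxima are end-diastole boundaries and the
minimum between consecutive boundaries is end-systole.  On top of the cycle
segmentation this module measures diastolic peak velocities, the per-slice
Pearson correlation between radial and circumferential velocity, classifies
slices as basal (net clockwise systolic rotation) or apical (counter-
clockwise), and forms the torsion-correlation index

    TC = mean(r over basal slices) - mean(r over apical slices),

which is large in a healthy ventricle (both means near +/-1 with opposite
signs) and shrinks when the radial and torsional components lose their
beat-to-beat temporal coupling.  A retrospective-cine emulation averages
the velocity traces of all cycles into one virtual cycle, reproducing the
multi-cycle data combination of gated imaging at the motion level.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage, signal, stats

from .errors import AnalysisError, ClassificationError, NoCyclesFound
from .tracking import VelocityTraces

__all__ = [
    "CycleSegmentation",
    "PeakVelocitySummary",
    "TorsionCorrelationResult",
    "detect_cycles",
    "diastolic_peak_velocities",
    "slice_correlation",
    "classify_slices",
    "torsion_correlation",
    "emulate_retro_cine",
]


@dataclass
class CycleSegmentation:
    """End-diastole boundaries and per-cycle end-systole frames.

    boundaries : (K+1,) frame indices of end-diastole, strictly increasing
    es_frames  : (K,) frame index of end-systole inside each cycle
    frame_times: (T,) ms, to convert indices to times
    refined_boundary_times : (K+1,) ms, sub-frame (parabolic) refinement of
        the boundary positions; used for period estimates so they are not
        quantised to the frame grid
    """

    boundaries: np.ndarray
    es_frames: np.ndarray
    frame_times: np.ndarray
    refined_boundary_times: np.ndarray | None = None

    @property
    def n_cycles(self) -> int:
        return len(self.boundaries) - 1

    @property
    def periods_ms(self) -> np.ndarray:
        if self.refined_boundary_times is not None:
            return np.diff(self.refined_boundary_times)
        return np.diff(self.frame_times[self.boundaries])

    @property
    def boundary_times(self) -> np.ndarray:
        return self.frame_times[self.boundaries]


def detect_cycles(area_trace: np.ndarray, frame_times: np.ndarray,
                  min_period: float = 500.0,
                  smooth_sigma: float = 1.0) -> CycleSegmentation:
    """Segment cardiac cycles from a pool-area trace.

    End-diastole boundaries are local maxima of the smoothed trace separated
    by at least ``min_period`` ms; a maximum sitting exactly on the first or
    last sample is kept, so a series that starts and ends at end-diastole
    yields all its cycles.  Partial cycles beyond the outermost maxima are
    discarded.
    """
    area = np.asarray(area_trace, dtype=float)
    times = np.asarray(frame_times, dtype=float)
    if len(area) != len(times):
        raise ValueError("area trace and frame times differ in length")
    dt = float(np.median(np.diff(times)))
    if len(area) < 3 * min_period / dt:
        raise NoCyclesFound("trace too short for the requested minimum period")
    if np.ptp(area) <= 1e-9 * max(1.0, abs(area).max()):
        raise NoCyclesFound("constant area trace")
    smoothed = ndimage.gaussian_filter1d(area, smooth_sigma) \
        if smooth_sigma else area
    distance = max(1, int(round(min_period / dt)))
    prominence = 0.1 * np.ptp(smoothed)
    peaks, _ = signal.find_peaks(smoothed, distance=distance,
                                 prominence=prominence)
    peaks = list(peaks)
    # endpoint maxima: find_peaks cannot return 0 or len-1
    if (not peaks or peaks[0] >= distance) and smoothed[0] >= smoothed[1]:
        peaks.insert(0, 0)
    if (not peaks or len(smoothed) - 1 - peaks[-1] >= distance) \
            and smoothed[-1] >= smoothed[-2]:
        peaks.append(len(smoothed) - 1)
    if len(peaks) < 2:
        raise NoCyclesFound("fewer than one complete cycle detected")
    boundaries = np.asarray(peaks, dtype=int)
    es = np.array([b0 + int(np.argmin(smoothed[b0:b1 + 1]))
                   for b0, b1 in zip(boundaries[:-1], boundaries[1:])])
    keep = (es > boundaries[:-1]) & (es < boundaries[1:])
    if not keep.all():
        bad = np.flatnonzero(~keep)
        raise NoCyclesFound(f"degenerate cycles (monotone area) at {bad}")
    # sub-frame boundary refinement: parabola through the smoothed samples
    # around each peak, so period estimates are not frame-quantised
    refined = times[boundaries].astype(float)
    dt_local = np.diff(times)
    for j, b in enumerate(boundaries):
        if 0 < b < len(smoothed) - 1:
            sm1, s0, sp1 = smoothed[b - 1], smoothed[b], smoothed[b + 1]
            denom = sm1 - 2 * s0 + sp1
            if denom < 0:
                off = np.clip(0.5 * (sm1 - sp1) / denom, -0.5, 0.5)
                refined[j] = times[b] + off * dt_local[min(b,
                                                           len(dt_local) - 1)]
    return CycleSegmentation(boundaries, es, times, refined)


@dataclass
class PeakVelocitySummary:
    """Diastolic peak velocities per slice and cycle, plus subject averages.

    radial_peaks / circ_peaks : (n_slices, n_cycles) mm/s; the
    circumferential peak is the magnitude of the untwisting recoil, i.e.
    the peak of the velocity component opposite to the slice's systolic
    rotation direction.
    """

    radial_peaks: np.ndarray
    circ_peaks: np.ndarray

    @property
    def subject_radial(self) -> float:
        return float(self.radial_peaks.mean())

    @property
    def subject_circ(self) -> float:
        return float(self.circ_peaks.mean())


def _diastole_mask(traces: VelocityTraces, cycles: CycleSegmentation,
                   k: int) -> np.ndarray:
    t_es = cycles.frame_times[cycles.es_frames[k]]
    t_ed = cycles.frame_times[cycles.boundaries[k + 1]]
    return (traces.times_ms >= t_es) & (traces.times_ms <= t_ed)


def diastolic_peak_velocities(traces_by_slice, cycles_by_slice,
                              rotation_signs) -> PeakVelocitySummary:
    """Peak diastolic velocities for a subject.

    ``rotation_signs`` gives each slice's systolic rotation direction
    (-1 = clockwise/basal, +1 = counter-clockwise/apical); the diastolic
    circumferential peak is taken in the recoil direction, -sign * v_circ.
    Diastole spans end-systole to the next end-diastole within each cycle.
    """
    n_cycles = min(c.n_cycles for c in cycles_by_slice)
    if n_cycles < 1:
        raise AnalysisError("no complete cycles")
    rad = np.empty((len(traces_by_slice), n_cycles))
    cir = np.empty_like(rad)
    for s, (tr, cy, sign) in enumerate(zip(traces_by_slice, cycles_by_slice,
                                           rotation_signs)):
        for k in range(n_cycles):
            m = _diastole_mask(tr, cy, k)
            if not m.any():
                raise AnalysisError(f"empty diastolic window, slice {s} cycle {k}")
            rad[s, k] = tr.v_rad[m].max()
            cir[s, k] = (-float(sign) * tr.v_circ[m]).max()
    return PeakVelocitySummary(rad, cir)


def slice_correlation(traces: VelocityTraces,
                      cycles: CycleSegmentation | None = None,
                      mode: str = "realtime") -> float:
    """Pearson r between the radial and circumferential velocity of a slice.

    ``realtime`` uses all samples of all complete cycles concatenated;
    ``single_cycle`` uses the trace as given (one real or virtual cycle).
    Returns NaN when either trace has zero variance.
    """
    if mode == "realtime":
        if cycles is None:
            raise ValueError("realtime mode needs a cycle segmentation")
        t0 = cycles.frame_times[cycles.boundaries[0]]
        t1 = cycles.frame_times[cycles.boundaries[-1]]
        m = (traces.times_ms >= t0) & (traces.times_ms <= t1)
        x, y = traces.v_rad[m], traces.v_circ[m]
    elif mode == "single_cycle":
        x, y = traces.v_rad, traces.v_circ
    else:
        raise ValueError(f"unknown mode {mode!r}")
    if len(x) < 8:
        raise AnalysisError("fewer than 8 velocity samples in scope")
    if np.std(x) == 0 or np.std(y) == 0:
        return float("nan")
    return float(stats.pearsonr(x, y).statistic)


def classify_slices(traj_by_slice, cycles_by_slice,
                    min_rotation: float = 0.02) -> list:
    """Classify slices by net systolic rotation direction.

    Net end-diastole -> end-systole angular displacement of the slice-mean
    angle, averaged over cycles: negative (clockwise) -> ``"basal"``,
    positive -> ``"apical"``, magnitude below ``min_rotation`` rad ->
    ``"excluded"``.
    """
    labels = []
    for traj, cycles in zip(traj_by_slice, cycles_by_slice):
        if cycles.n_cycles < 1:
            raise AnalysisError("no complete cycles")
        m = traj.mean_angle()
        deltas = [m[cycles.es_frames[k]] - m[cycles.boundaries[k]]
                  for k in range(cycles.n_cycles)]
        net = float(np.mean(deltas))
        if abs(net) < min_rotation:
            labels.append("excluded")
        else:
            labels.append("basal" if net < 0 else "apical")
    if all(lab == "excluded" for lab in labels):
        raise ClassificationError("all slices below the rotation threshold")
    return labels


@dataclass
class TorsionCorrelationResult:
    """Per-slice correlations and the torsion-correlation index."""

    r_per_slice: np.ndarray
    classification: list
    mean_r_basal: float
    mean_r_apical: float

    @property
    def tc(self) -> float:
        return self.mean_r_basal - self.mean_r_apical


def torsion_correlation(r_per_slice, classification) -> TorsionCorrelationResult:
    """TC = mean basal r - mean apical r.

    Slices classified ``excluded`` or with undefined (NaN) r are omitted
    from both means; an empty basal or apical set raises.
    """
    r = np.asarray(r_per_slice, dtype=float)
    if len(r) != len(classification):
        raise ValueError("r and classification lengths differ")
    basal = [ri for ri, c in zip(r, classification)
             if c == "basal" and np.isfinite(ri)]
    apical = [ri for ri, c in zip(r, classification)
              if c == "apical" and np.isfinite(ri)]
    if not basal or not apical:
        raise AnalysisError("need at least one basal and one apical slice "
                            "with a defined correlation")
    return TorsionCorrelationResult(r, list(classification),
                                    float(np.mean(basal)),
                                    float(np.mean(apical)))


def emulate_retro_cine(traces: VelocityTraces, cycles: CycleSegmentation,
                       n_phases: int = 30) -> VelocityTraces:
    """Average the velocity traces of all cycles into one virtual cycle.

    Each complete cycle is normalised to phase in [0, 1), samples are binned
    into ``n_phases`` phase bins and averaged across cycles -- the motion-
    level analogue of retrospective gated reconstruction, which keeps motion
    consistent across cycles and suppresses beat-to-beat variation.
    """
    if cycles.n_cycles < 2:
        raise ValueError("cine emulation needs at least 2 complete cycles")
    if n_phases < 8:
        raise ValueError("n_phases must be >= 8")
    bt = cycles.boundary_times
    sums = np.zeros((2, n_phases))
    counts = np.zeros(n_phases)
    for k in range(cycles.n_cycles):
        t0, t1 = bt[k], bt[k + 1]
        m = (traces.times_ms >= t0) & (traces.times_ms < t1)
        phase = (traces.times_ms[m] - t0) / (t1 - t0)
        b = np.minimum((phase * n_phases).astype(int), n_phases - 1)
        np.add.at(sums[0], b, traces.v_rad[m])
        np.add.at(sums[1], b, traces.v_circ[m])
        np.add.at(counts, b, 1)
    filled = counts > 0
    if not filled.all():
        # interpolate empty bins cyclically from the filled neighbours
        idx = np.arange(n_phases)
        for row in range(2):
            sums[row, filled] /= counts[filled]
            sums[row, ~filled] = np.interp(
                idx[~filled], idx[filled], sums[row, filled], period=n_phases)
        v_rad, v_circ = sums
    else:
        v_rad, v_circ = sums / counts
    mean_period = float(np.mean(np.diff(bt)))
    times = (np.arange(n_phases) + 0.5) / n_phases * mean_period
    return VelocityTraces(times, v_rad, v_circ)
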