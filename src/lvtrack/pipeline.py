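"""Subject- and cohort-level orchestration of the full analysis chain:
segment -> track -> cycles -> velocities -> correlations / torsion
correlation -> peaks -> volumetrics.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import kinematics, volumetrics
from .errors import AnalysisError
from .imageio import ResultTable
from .segmentation import segment_series
from .tracking import TrackParams, track_series, trajectories_to_velocity

__all__ = ["AnalysisParams", "SliceResult", "SubjectResult",
           "analyze_subject", "cohort_table"]


@dataclass(frozen=True)
class AnalysisParams:
    """End-to-end analysis controls (see the per-stage modules)."""

    n_points: int = 64
    roi_scale: float = 2.0
    track: TrackParams = field(default_factory=TrackParams)
    smooth_window: int = 5
    min_period: float = 500.0
    min_rotation: float = 0.02
    n_phases: int = 30


@dataclass
class SliceResult:
    contours: list
    area_mm2: np.ndarray
    cycles: object
    trajectories: object
    traces: object
    cine_traces: object
    r_realtime: float
    r_cine: float
    classification: str = "unclassified"


@dataclass
class SubjectResult:
    label: str
    group: str
    slices: list
    classification: list
    tc_realtime: float
    tc_cine: float
    peaks: object
    volumes: object

    def to_rows(self, table: ResultTable) -> None:
        """Append this subject's indices to a result table."""
        add = lambda name, value: table.add(self.label, self.group, name, value)
        add("EDV", self.volumes.edv_ml)
        add("ESV", self.volumes.esv_ml)
        add("SV", self.volumes.sv_ml)
        add("EF", self.volumes.ef)
        add("peak_v_rad", self.peaks.subject_radial)
        add("peak_v_circ", self.peaks.subject_circ)
        add("torsion_correlation", self.tc_realtime)
        add("torsion_correlation_cine", self.tc_cine)


def analyze_subject(series_by_slice, params: AnalysisParams | None = None,
                    label: str = "subject", group: str = "unknown",
                    thickness: float | None = None,
                    gap: float | None = None) -> SubjectResult:
    """Run the full single-subject analysis on a base->apex list of series."""
    params = params or AnalysisParams()
    series_by_slice = list(series_by_slice)
    if thickness is None:
        thickness = series_by_slice[0].thickness
    if gap is None:
        gap = series_by_slice[0].gap

    slices: list[SliceResult] = []
    for series in series_by_slice:
        contours, areas = segment_series(series, n_points=params.n_points,
                                         roi_scale=params.roi_scale)
        cycles = kinematics.detect_cycles(areas, series.frame_times,
                                          params.min_period)
        traj = track_series(series, contours, params.track)
        traces = trajectories_to_velocity(traj, series.pixel_spacing,
                                          params.smooth_window)
        r_rt = kinematics.slice_correlation(traces, cycles, "realtime")
        if cycles.n_cycles >= 2:
            cine = kinematics.emulate_retro_cine(traces, cycles,
                                                 params.n_phases)
            r_cine = kinematics.slice_correlation(cine, mode="single_cycle")
        else:
            cine, r_cine = None, float("nan")
        slices.append(SliceResult(contours, areas, cycles, traj, traces,
                                  cine, r_rt, r_cine))

    classification = kinematics.classify_slices(
        [s.trajectories for s in slices], [s.cycles for s in slices],
        params.min_rotation)
    for s, c in zip(slices, classification):
        s.classification = c

    tc_rt = kinematics.torsion_correlation(
        [s.r_realtime for s in slices], classification).tc
    try:
        tc_cine = kinematics.torsion_correlation(
            [s.r_cine for s in slices], classification).tc
    except AnalysisError:
        tc_cine = float("nan")

    signs = [-1.0 if c == "basal" else 1.0 for c in classification]
    peaks = kinematics.diastolic_peak_velocities(
        [s.traces for s in slices], [s.cycles for s in slices], signs)

    frame_times = series_by_slice[0].frame_times
    area_matrix = np.vstack([s.area_mm2 for s in slices])
    ed, es, _ = volumetrics.pick_phases(area_matrix, frame_times,
                                        min_period=params.min_period)
    vols = volumetrics.lv_volumes(area_matrix[:, ed], area_matrix[:, es],
                                  thickness, gap)
    return SubjectResult(label, group, slices, classification,
                         tc_rt, tc_cine, peaks, vols)


def cohort_table(results) -> ResultTable:
    """Collect per-subject results into a long-format table."""
    table = ResultTable()
    for res in results:
        res.to_rows(table)
    return table
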