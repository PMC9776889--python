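"""LV volumetric indices from per-slice blood-pool areas.

Volumes follow the slice-summation (Simpson) convention: each short-axis
slice contributes area x (thickness + gap), so the stack tiles the
ventricle without double counting.  End-diastole and end-systole are picked
globally from the summed area across slices within one selected cycle (the
cycle whose period is closest to the subject median -- a deterministic
surrogate for manual best-quality cycle selection), then applied per slice.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import IntegrityError, PhasePickError
from .kinematics import CycleSegmentation, detect_cycles

__all__ = ["VolumetricIndices", "lv_volumes", "pick_phases", "select_cycle"]


@dataclass(frozen=True)
class VolumetricIndices:
    """EDV/ESV in mL, SV = EDV - ESV, EF = SV/EDV (fraction)."""

    edv_ml: float
    esv_ml: float

    @property
    def sv_ml(self) -> float:
        return self.edv_ml - self.esv_ml

    @property
    def ef(self) -> float:
        return self.sv_ml / self.edv_ml

    @property
    def ef_pct(self) -> float:
        return 100.0 * self.ef


def lv_volumes(areas_ed, areas_es, thickness: float = 8.0,
               gap: float = 2.0) -> VolumetricIndices:
    """Sum per-slice areas (mm^2) into volumes (mL).

    V = sum_slices area * (thickness + gap), mm^3 -> mL.
    """
    areas_ed = np.asarray(areas_ed, dtype=float)
    areas_es = np.asarray(areas_es, dtype=float)
    if areas_ed.size < 1 or areas_ed.size != areas_es.size:
        raise ValueError("need matching per-slice ED and ES areas")
    if np.any(areas_ed < 0) or np.any(areas_es < 0):
        raise ValueError("areas must be non-negative")
    height = thickness + gap
    edv = areas_ed.sum() * height / 1000.0
    esv = areas_es.sum() * height / 1000.0
    if edv <= 0:
        raise ValueError("end-diastolic area sum must be positive")
    if esv > edv:
        raise IntegrityError(
            f"ESV ({esv:.1f} mL) exceeds EDV ({edv:.1f} mL): "
            "phases likely swapped")
    return VolumetricIndices(float(edv), float(esv))


def select_cycle(cycles: CycleSegmentation) -> int:
    """Index of the cycle whose period is closest to the median period
    (earlier cycle on ties)."""
    periods = cycles.periods_ms
    med = np.median(periods)
    return int(np.argmin(np.abs(periods - med)))


def pick_phases(area_traces_by_slice, frame_times,
                cycles: CycleSegmentation | None = None,
                min_period: float = 500.0):
    """Pick global end-diastole / end-systole frames for a subject.

    Works on the summed area across slices: within the selected cycle the
    ED frame maximises and the ES frame minimises the summed area (earlier
    frame on ties).  Returns ``(ed_frame, es_frame, cycles)``.
    """
    traces = np.asarray(area_traces_by_slice, dtype=float)
    if traces.ndim != 2:
        raise ValueError("expect a (n_slices, n_frames) array of areas")
    total = traces.sum(axis=0)
    if np.ptp(total) <= 0:
        raise PhasePickError("flat summed-area trace")
    if cycles is None:
        cycles = detect_cycles(total, frame_times, min_period)
    k = select_cycle(cycles)
    b0, b1 = cycles.boundaries[k], cycles.boundaries[k + 1]
    window = total[b0:b1 + 1]
    ed = b0 + int(np.argmax(window))
    es = b0 + int(np.argmin(window))
    if ed == es:
        raise PhasePickError("flat area trace within the selected cycle")
    return ed, es, cycles
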