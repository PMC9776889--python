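"""Synthetic rotating/contracting left-ventricle phantom.

Generates multi-slice, multi-cycle short-axis image series with analytically
known endocardial motion: inward radial contraction plus slice-dependent
rotation (clockwise in basal slices, counter-clockwise in apical slices, i.e.
twist), rendered as a bright blood pool inside a textured myocardial ring.

The motion model is separable per slice:

    radius(t) = r_ed - (r_ed - r_es) * a_k * c(phase_r)
    angle(t)  = theta_amp * b_k * c(phase_c)

where ``c`` is a raised-cosine contraction waveform rising 0 -> 1 over the
systolic fraction of the cycle and relaxing back to 0 over the remainder,
``k`` indexes the cardiac cycle containing ``t``, ``a_k`` / ``b_k`` are
per-cycle amplitude multipliers, and the rotation phase may carry a per-cycle
timing offset ``delta_k`` (the "decoupling" jitter) relative to the radial
phase.  All per-cycle draws live in a :class:`CycleSchedule` shared by every
slice of a subject, so the whole subject beats on one clock.

Cohort regimes:

``healthy``    coupled motion (no timing offset, no amplitude jitter),
               normal contraction (geometric EF ~ 64%) and twist amplitude.
``reduced``    contraction and twist amplitudes scaled down so the geometric
               EF falls below 50% (systolic dysfunction).
``decoupled``  normal amplitudes and EF, but the rotation waveform carries a
               per-cycle timing offset (SD ``decouple_sd`` ms) and per-cycle
               amplitude jitter on rotation only -- an HFpEF-like loss of
               radial/torsional coordination that EF cannot see.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .errors import GeometryError, LvtrackError
from .imageio import ImageSeries

__all__ = [
    "MotionParams",
    "CycleSchedule",
    "RenderSettings",
    "GroundTruthMotion",
    "PhantomSubject",
    "contraction_waveform",
    "contraction_waveform_rate",
    "draw_schedule",
    "motion_model",
    "simulate_truth",
    "generate_subject",
    "generate_cohort",
    "default_slice_params",
]

REGIMES = ("healthy", "reduced", "decoupled")


@dataclass(frozen=True)
class MotionParams:
    """Per-slice motion parameters.

    r_ed, r_es        : end-diastolic / end-systolic endocardial radius (mm)
    theta_amp         : peak rotation (rad); negative = clockwise (basal)
    period            : nominal cycle length (ms)
    systole_fraction  : fraction of the cycle spent contracting
    decouple_sd       : SD of the per-cycle rotation timing offset (ms)
    amp_jitter_sd     : SD of the per-cycle amplitude multiplier
    period_jitter_sd  : SD of the per-cycle period (ms)
    """

    r_ed: float = 25.0
    r_es: float = 15.0
    theta_amp: float = -0.15
    period: float = 900.0
    systole_fraction: float = 0.35
    decouple_sd: float = 0.0
    amp_jitter_sd: float = 0.0
    period_jitter_sd: float = 0.0

    def __post_init__(self) -> None:
        if not self.r_es < self.r_ed:
            raise ValueError("r_es must be smaller than r_ed")
        if not 0.0 < self.systole_fraction < 1.0:
            raise ValueError("systole_fraction must lie in (0, 1)")
        if min(self.decouple_sd, self.amp_jitter_sd, self.period_jitter_sd) < 0:
            raise ValueError("jitter SDs must be non-negative")
        if self.period <= 0:
            raise ValueError("period must be positive")


def contraction_waveform(phase, systole_fraction: float = 0.35):
    """Raised-cosine contraction waveform on cycle phase in [0, 1).

    Rises smoothly 0 -> 1 over ``systole_fraction`` of the cycle and relaxes
    back to 0 over the remainder; evaluated periodically (phase mod 1), with
    zero slope at the cycle boundary and at peak contraction.
    """
    u = np.asarray(phase, dtype=float) % 1.0
    sf = float(systole_fraction)
    rise = 0.5 * (1.0 - np.cos(np.pi * u / sf))
    fall = 0.5 * (1.0 + np.cos(np.pi * (u - sf) / (1.0 - sf)))
    return np.where(u < sf, rise, fall)


def contraction_waveform_rate(phase, systole_fraction: float = 0.35):
    """d/dphase of :func:`contraction_waveform` (per unit phase)."""
    u = np.asarray(phase, dtype=float) % 1.0
    sf = float(systole_fraction)
    rise = 0.5 * np.pi / sf * np.sin(np.pi * u / sf)
    fall = -0.5 * np.pi / (1.0 - sf) * np.sin(np.pi * (u - sf) / (1.0 - sf))
    return np.where(u < sf, rise, fall)


@dataclass(frozen=True)
class CycleSchedule:
    """Per-cycle random draws shared by all slices of a subject.

    start_times : (K+1,) cycle boundary times in ms, first at 0
    delta       : (K,) rotation timing offsets (ms)
    amp_radial  : (K,) radial amplitude multipliers
    amp_rot     : (K,) rotation amplitude multipliers
    """

    start_times: np.ndarray
    delta: np.ndarray
    amp_radial: np.ndarray
    amp_rot: np.ndarray

    @property
    def n_cycles(self) -> int:
        return len(self.start_times) - 1

    @property
    def periods(self) -> np.ndarray:
        return np.diff(self.start_times)

    @property
    def span(self) -> float:
        return float(self.start_times[-1])


def draw_schedule(params: MotionParams, n_cycles: int,
                  rng: np.random.Generator,
                  amp_jitter_on: str = "rotation") -> CycleSchedule:
    """Draw a cycle schedule from the jitter fields of ``params``.

    ``amp_jitter_on`` selects where the amplitude jitter applies:
    ``"rotation"`` (default; radial amplitude stays 1, which decouples the
    two components), ``"shared"`` (one draw scales both, preserving
    coupling) or ``"radial"``.
    """
    if n_cycles < 1:
        raise ValueError("n_cycles must be >= 1")
    periods = params.period + rng.normal(0.0, params.period_jitter_sd, n_cycles)
    periods = np.clip(periods, 0.5 * params.period, 1.5 * params.period)
    start = np.concatenate([[0.0], np.cumsum(periods)])
    delta = rng.normal(0.0, params.decouple_sd, n_cycles)
    jitter = np.clip(rng.normal(1.0, params.amp_jitter_sd, n_cycles), 0.1, None)
    ones = np.ones(n_cycles)
    if amp_jitter_on == "rotation":
        amp_radial, amp_rot = ones, jitter
    elif amp_jitter_on == "radial":
        amp_radial, amp_rot = jitter, ones
    elif amp_jitter_on == "shared":
        amp_radial, amp_rot = jitter, jitter.copy()
    else:
        raise ValueError(f"unknown amp_jitter_on: {amp_jitter_on!r}")
    return CycleSchedule(start, delta, amp_radial, amp_rot)


def motion_model(t, params: MotionParams, schedule: CycleSchedule):
    """Evaluate the analytic motion at times ``t`` (ms).

    Returns ``(radius_mm, angle_rad)`` arrays.  Times must lie within the
    schedule span ``[0, start_times[-1]]``.
    """
    t = np.asarray(t, dtype=float)
    if np.any(t < 0) or np.any(t > schedule.span + 1e-9):
        raise ValueError("t outside the generated time span")
    k = np.clip(np.searchsorted(schedule.start_times, t, side="right") - 1,
                0, schedule.n_cycles - 1)
    periods = schedule.periods
    phase_r = (t - schedule.start_times[k]) / periods[k]
    phase_c = (t - schedule.start_times[k] - schedule.delta[k]) / periods[k]
    c_r = contraction_waveform(phase_r, params.systole_fraction)
    c_c = contraction_waveform(phase_c, params.systole_fraction)
    radius = params.r_ed - (params.r_ed - params.r_es) * schedule.amp_radial[k] * c_r
    angle = params.theta_amp * schedule.amp_rot[k] * c_c
    return radius, angle


@dataclass
class GroundTruthMotion:
    """Analytic motion of one slice sampled on the frame grid.

    Velocities are finite differences of the analytic radius/angle traces at
    frame midpoints, in mm/s: ``v_rad = d(radius)/dt`` (outward positive) and
    ``v_circ = r_mid * d(angle)/dt`` (counter-clockwise positive, linear).
    """

    frame_times: np.ndarray        # ms
    radius_mm: np.ndarray
    angle_rad: np.ndarray
    cycle_times: np.ndarray        # ms, K+1 boundaries

    @property
    def mid_times(self) -> np.ndarray:
        return 0.5 * (self.frame_times[1:] + self.frame_times[:-1])

    @property
    def v_rad(self) -> np.ndarray:
        dt = np.diff(self.frame_times)
        return np.diff(self.radius_mm) / dt * 1e3

    @property
    def v_circ(self) -> np.ndarray:
        dt = np.diff(self.frame_times)
        r_mid = 0.5 * (self.radius_mm[1:] + self.radius_mm[:-1])
        return r_mid * np.diff(self.angle_rad) / dt * 1e3

    def to_frame(self, slice_index: int = 0):
        import pandas as pd
        return pd.DataFrame({
            "slice": slice_index,
            "frame": np.arange(len(self.frame_times)),
            "time_ms": self.frame_times,
            "radius_mm": self.radius_mm,
            "angle_rad": self.angle_rad,
        })


def simulate_truth(params: MotionParams, schedule: CycleSchedule,
                   frame_times: np.ndarray) -> GroundTruthMotion:
    radius, angle = motion_model(frame_times, params, schedule)
    return GroundTruthMotion(np.asarray(frame_times, float), radius, angle,
                             schedule.start_times.copy())


# --------------------------------------------------------------------------
# rendering

@dataclass(frozen=True)
class RenderSettings:
    """Rendering controls, intensities in uint16 digital numbers (DN).

    The blood pool is bright, the myocardial ring darker with a band-limited
    material texture advected by the analytic motion, the background darkest.
    ``edge_width_px = 0`` gives hard region assignment (used by render-
    equation oracles); otherwise edges blend over a logistic ramp.
    """

    image_size: int = 96
    pixel_spacing: float = 1.8
    pool_intensity: float = 9000.0
    myo_intensity: float = 3500.0
    background: float = 1000.0
    texture_amp: float = 1200.0
    wall_thickness: float = 10.0   # mm, at end-diastole
    edge_width_px: float = 0.6
    psf_sigma_px: float = 0.7
    noise_sd: float = 120.0

    @property
    def contrast(self) -> float:
        """Pool minus myocardium mean intensity (DN)."""
        return self.pool_intensity - self.myo_intensity


_TEX_NR, _TEX_NPHI = 48, 192


def _texture_field(rng: np.random.Generator) -> np.ndarray:
    """Band-limited zero-mean random field on a material polar grid.

    The correlation length (~1.5 grid cells radially, ~2.5 azimuthally,
    i.e. roughly one image voxel after the point-spread blur) emulates
    voxel-scale myocardial speckle, the structure feature tracking relies
    on in real images.
    """
    g = rng.standard_normal((_TEX_NR, _TEX_NPHI))
    g = ndimage.gaussian_filter(g, (1.5, 2.5), mode="wrap")
    g -= g.mean()
    sd = g.std()
    return g / sd if sd > 0 else g


class _SliceRenderer:
    """Renders frames of one slice; precomputes the pixel polar grid."""

    def __init__(self, params: MotionParams, settings: RenderSettings,
                 texture: np.ndarray):
        n = settings.image_size
        half = (n - 1) / 2.0
        rows, cols = np.mgrid[0:n, 0:n]
        self.x = (cols - half) * settings.pixel_spacing
        self.y = (rows - half) * settings.pixel_spacing
        self.r = np.hypot(self.y, self.x)
        self.phi = np.arctan2(self.y, self.x)
        self.params = params
        self.settings = settings
        self.texture = np.concatenate([texture, texture[:, :2]], axis=1)
        self.r_max_mat = params.r_ed + settings.wall_thickness + 10.0
        epi_ed = params.r_ed + settings.wall_thickness
        if epi_ed >= half * settings.pixel_spacing - 2 * settings.pixel_spacing:
            raise GeometryError(
                f"epicardial radius {epi_ed:.1f} mm exceeds the frame "
                f"half-extent at {n} px / {settings.pixel_spacing} mm")

    def render(self, radius_mm: float, angle: float,
               rng: np.random.Generator | None,
               offset_mm: tuple = (0.0, 0.0)) -> np.ndarray:
        st = self.settings
        p = self.params
        if offset_mm != (0.0, 0.0):
            # whole-frame translation (breathing): shift the polar grid
            y = self.y - offset_mm[0]
            x = self.x - offset_mm[1]
            r_pix = np.hypot(y, x)
            phi = np.arctan2(y, x)
        else:
            r_pix, phi = self.r, self.phi
        # incompressible ring: the myocardium conserves area, so the wall
        # thickens as the pool contracts (r^2 - r_endo^2 is material)
        epi_ed = p.r_ed + st.wall_thickness
        r_epi = np.sqrt(epi_ed ** 2 - p.r_ed ** 2 + radius_mm ** 2)
        r0 = np.sqrt(np.maximum(r_pix ** 2 - radius_mm ** 2 + p.r_ed ** 2,
                                0.0))
        phi0 = (phi - angle) % (2 * np.pi)
        ri = np.clip(r0 / self.r_max_mat * (_TEX_NR - 1), 0, _TEX_NR - 1)
        pi_ = phi0 / (2 * np.pi) * _TEX_NPHI
        tex = ndimage.map_coordinates(self.texture, [ri, pi_],
                                      order=1, mode="nearest")
        if st.edge_width_px > 0:
            w = st.edge_width_px * st.pixel_spacing
            f_pool = 1.0 / (1.0 + np.exp(-(radius_mm - r_pix) / w))
            f_epi = 1.0 / (1.0 + np.exp(-(r_epi - r_pix) / w))
        else:
            f_pool = (r_pix <= radius_mm).astype(float)
            f_epi = (r_pix <= r_epi).astype(float)
        myo = st.myo_intensity + st.texture_amp * tex
        img = st.background + (myo - st.background) * f_epi \
            + (st.pool_intensity - myo) * f_pool
        if st.psf_sigma_px > 0:
            img = ndimage.gaussian_filter(img, st.psf_sigma_px)
        if rng is not None and st.noise_sd > 0:
            img = img + rng.normal(0.0, st.noise_sd, img.shape)
        return np.clip(np.round(img), 0, 65535).astype(np.uint16)


# --------------------------------------------------------------------------
# subjects and cohorts

@dataclass
class PhantomSubject:
    """A rendered multi-slice subject with its ground truth."""

    label: str
    seed: int
    regime: str
    params: list                       # MotionParams per slice, base -> apex
    schedule: CycleSchedule
    series: list                       # ImageSeries per slice
    truth: list                        # GroundTruthMotion per slice
    thickness: float = 8.0
    gap: float = 2.0

    @property
    def n_slices(self) -> int:
        return len(self.series)

    @property
    def truth_ef(self) -> float:
        """Geometric slice-area ejection fraction of the nominal motion."""
        ed = sum(p.r_ed ** 2 for p in self.params)
        es = sum(p.r_es ** 2 for p in self.params)
        return 1.0 - es / ed


def frame_time_grid(schedule: CycleSchedule, frame_interval: float) -> np.ndarray:
    """Uniform frame times covering the schedule span (endpoints included
    when the span is a multiple of the interval)."""
    n = int(np.floor(schedule.span / frame_interval + 1e-9)) + 1
    return np.arange(n) * frame_interval


def generate_subject(params_per_slice, n_cycles: int = 8,
                     frame_interval: float = 20.0,
                     settings: RenderSettings | None = None,
                     seed: int | None = 0,
                     rng: np.random.Generator | None = None,
                     label: str = "subject", regime: str = "healthy",
                     amp_jitter_on: str = "rotation",
                     thickness: float = 8.0, gap: float = 2.0,
                     breathing_amp_mm: float = 0.0,
                     breathing_period_ms: float = 4000.0,
                     render: bool = True) -> PhantomSubject:
    """Render one subject: all slices share a single cycle schedule.

    ``breathing_amp_mm`` > 0 adds a slow sinusoidal whole-frame translation
    (free-breathing surrogate; default off).  The analysis removes it by
    measuring about the per-frame pool centroid, which the tests verify.
    With ``render=False`` only the analytic truth is produced (series empty),
    which is cheap and useful for motion-level experiments.
    """
    params_per_slice = list(params_per_slice)
    if len(params_per_slice) < 2:
        raise ValueError("a subject needs at least 2 slices")
    settings = settings or RenderSettings()
    base = params_per_slice[0]
    if frame_interval > base.period / 10.0:
        raise ValueError("frame_interval too coarse: need >= 10 phases/cycle")
    if rng is None:
        rng = np.random.default_rng(seed)
    schedule = draw_schedule(base, n_cycles, rng, amp_jitter_on)
    times = frame_time_grid(schedule, frame_interval)
    if breathing_amp_mm > 0:
        phase = 2 * np.pi * times / breathing_period_ms
        offsets = [(breathing_amp_mm * np.sin(ph),
                    0.3 * breathing_amp_mm * np.sin(0.8 * ph))
                   for ph in phase]
    else:
        offsets = [(0.0, 0.0)] * len(times)

    series, truth = [], []
    for s_idx, p in enumerate(params_per_slice):
        gt = simulate_truth(p, schedule, times)
        truth.append(gt)
        if render:
            renderer = _SliceRenderer(p, settings, _texture_field(rng))
            frames = np.stack([
                renderer.render(gt.radius_mm[i], gt.angle_rad[i], rng,
                                offsets[i])
                for i in range(len(times))
            ])
            series.append(ImageSeries(
                frames=frames, frame_times=times,
                pixel_spacing=settings.pixel_spacing,
                slice_index=s_idx,
                slice_position=s_idx * (thickness + gap),
                thickness=thickness, gap=gap))
    return PhantomSubject(label=label, seed=seed if seed is not None else -1,
                          regime=regime, params=params_per_slice,
                          schedule=schedule, series=series, truth=truth,
                          thickness=thickness, gap=gap)


def default_slice_params(n_slices: int = 6, r_ed: float = 25.0,
                         r_es: float = 15.0, theta_mag: float = 0.15,
                         **kwargs) -> list:
    """Default stack: first half basal (clockwise, theta < 0), second half
    apical (counter-clockwise, theta > 0), constant magnitude."""
    out = []
    for s in range(n_slices):
        sign = -1.0 if s < n_slices // 2 else 1.0
        out.append(MotionParams(r_ed=r_ed, r_es=r_es,
                                theta_amp=sign * theta_mag, **kwargs))
    return out


def _regime_params(regime: str, rng: np.random.Generator,
                   n_slices: int, decouple_sd: float,
                   rot_amp_jitter_sd: float) -> list:
    """Draw per-subject slice parameters for a cohort regime."""
    r_ed = float(np.clip(25.0 * (1.0 + 0.04 * rng.standard_normal()), 20, 32))
    period = float(np.clip(rng.normal(900.0, 40.0), 750, 1100))
    if regime == "reduced":
        ef = float(np.clip(rng.normal(0.30, 0.04), 0.15, 0.45))
        theta_mag = float(np.clip(rng.normal(0.06, 0.010), 0.02, 0.10))
    else:
        ef = float(np.clip(rng.normal(0.64, 0.03), 0.55, 0.72))
        theta_mag = float(np.clip(rng.normal(0.15, 0.015), 0.08, 0.22))
    r_es = r_ed * float(np.sqrt(1.0 - ef))
    extra = dict(period=period, period_jitter_sd=15.0)
    if regime == "decoupled":
        extra.update(decouple_sd=decouple_sd,
                     amp_jitter_sd=rot_amp_jitter_sd)
    return default_slice_params(n_slices, r_ed=r_ed, r_es=r_es,
                                theta_mag=theta_mag, **extra)


def generate_cohort(regime: str, n_subjects: int, base_seed: int = 1,
                    n_slices: int = 6, n_cycles: int = 8,
                    frame_interval: float = 20.0,
                    settings: RenderSettings | None = None,
                    decouple_sd: float = 60.0,
                    rot_amp_jitter_sd: float = 0.25,
                    render: bool = True) -> list:
    """Generate ``n_subjects`` phantoms of one regime.

    Subject ``i`` is fully determined by ``base_seed + i``; rerunning with
    the same arguments reproduces the cohort bit for bit.
    """
    if regime not in REGIMES:
        raise LvtrackError(f"unknown regime {regime!r}; expected one of {REGIMES}")
    if n_subjects < 1:
        raise ValueError("n_subjects must be >= 1")
    subjects = []
    for i in range(n_subjects):
        seed = base_seed + i
        rng = np.random.default_rng(seed)
        params = _regime_params(regime, rng, n_slices, decouple_sd,
                                rot_amp_jitter_sd)
        subjects.append(generate_subject(
            params, n_cycles=n_cycles, frame_interval=frame_interval,
            settings=settings, seed=seed, rng=rng,
            label=f"{regime}_{i:02d}", regime=regime,
            amp_jitter_on="rotation", render=render))
    return subjects
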