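"""Border-anchored feature tracking of the endocardium.

For every frame, 1D intensity profiles ("line cuts") are interpolated along
the inward-outward normal through each border point.  A feature image for a
border point stacks the W adjacent line cuts; correspondence to the next
frame is the candidate index (within a cyclic search window on the next
frame's re-segmented contour) whose feature image maximises the normalised
cross-correlation, refined to fractional cuts by parabolic interpolation of
the score.  Chaining correspondences yields per-point (radius, angle)
trajectories about the per-frame pool centroid, which removes in-plane
translation; dividing radius/angle changes by the frame interval gives
radial and circumferential velocities.

Sign conventions (see :mod:`lvtrack.imageio`): radial velocity is outward
positive, circumferential velocity counter-clockwise positive; during
systole a healthy basal slice has both negative (inward motion + clockwise
rotation), i.e. the two traces are in phase.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage, signal

from .errors import GeometryError
from .imageio import ImageSeries
from .segmentation import BorderContour

__all__ = [
    "TrackParams",
    "LineCutSet",
    "FeatureImage",
    "BoundaryTrajectories",
    "VelocityTraces",
    "interpolate_line_cuts",
    "build_feature_image",
    "match_features",
    "track_series",
    "trajectories_to_velocity",
]


@dataclass(frozen=True)
class TrackParams:
    """Tracking controls.

    cut_len          : samples per line cut (odd; border point at centre)
    cut_step         : sample spacing along the normal, px
    window           : adjacent cuts per feature image (odd)
    search_half_width: cyclic search range in cuts on the next contour
    min_score        : NCC below which a match is flagged low-confidence
    """

    cut_len: int = 17
    cut_step: float = 0.75
    window: int = 7
    search_half_width: int = 5
    min_score: float = 0.3

    def __post_init__(self) -> None:
        if self.cut_len % 2 == 0:
            raise ValueError("cut_len must be odd")
        if self.window % 2 == 0:
            raise ValueError("window must be odd")
        if self.search_half_width < 1:
            raise ValueError("search_half_width must be >= 1")


@dataclass
class LineCutSet:
    """Line-cut profiles of one frame.

    profiles : (N, L) intensity profiles, inward (index 0) to outward
    radii_px : (N,) border-point radius about the contour centroid
    angles   : (N,) unwrapped border-point angle, increasing along the contour
    oob      : (N, L) True where a sample fell outside the frame
    """

    frame_index: int
    profiles: np.ndarray
    radii_px: np.ndarray
    angles: np.ndarray
    oob: np.ndarray
    step_px: float
    centroid: tuple

    @property
    def n_cuts(self) -> int:
        return len(self.profiles)


@dataclass
class FeatureImage:
    """W stacked line cuts around one border point, with match stats."""

    point_index: int
    patch: np.ndarray          # (W, L)
    mean: float
    sd: float


@dataclass
class BoundaryTrajectories:
    """Tracked (radius, angle) paths of the initial border points.

    radius_px : (T, N) point radius about the per-frame centroid, px
    angle_rad : (T, N) continuous (unwrapped) point angle
    score     : (T-1, N) NCC of the match used for each step
    """

    radius_px: np.ndarray
    angle_rad: np.ndarray
    score: np.ndarray
    frame_times: np.ndarray
    warnings: list = field(default_factory=list)

    @property
    def n_frames(self) -> int:
        return self.radius_px.shape[0]

    @property
    def n_points(self) -> int:
        return self.radius_px.shape[1]

    def mean_angle(self) -> np.ndarray:
        return self.angle_rad.mean(axis=1)


@dataclass
class VelocityTraces:
    """Slice-averaged radial/circumferential velocity vs time.

    times_ms : midpoints of the frame intervals
    v_rad    : mm/s, outward positive
    v_circ   : mm/s, counter-clockwise positive (linear: mid radius x
               angular rate)
    """

    times_ms: np.ndarray
    v_rad: np.ndarray
    v_circ: np.ndarray
    v_rad_points: np.ndarray | None = None
    v_circ_points: np.ndarray | None = None

    def __len__(self) -> int:
        return len(self.times_ms)


def interpolate_line_cuts(frame: np.ndarray, contour: BorderContour,
                          cut_len: int = 17,
                          cut_step: float = 0.75) -> LineCutSet:
    """Sample line cuts normal to the border (along centroid->point rays)."""
    if cut_len % 2 == 0:
        raise ValueError("cut_len must be odd so the border point is central")
    frame = np.asarray(frame, dtype=float)
    pts = contour.points
    c = np.asarray(contour.centroid)
    d = pts - c
    radii = np.hypot(d[:, 0], d[:, 1])
    if np.any(radii < 1e-6):
        raise GeometryError("contour centroid lies on the border")
    u = d / radii[:, None]
    offsets = (np.arange(cut_len) - (cut_len - 1) / 2.0) * cut_step
    coords = pts[:, None, :] + offsets[None, :, None] * u[:, None, :]
    rr, cc = coords[..., 0], coords[..., 1]
    h, w = frame.shape
    oob = (rr < 0) | (rr > h - 1) | (cc < 0) | (cc > w - 1)
    profiles = ndimage.map_coordinates(
        frame, [rr.ravel(), cc.ravel()], order=1, mode="nearest"
    ).reshape(rr.shape)
    angles = np.unwrap(np.arctan2(d[:, 0], d[:, 1]))
    return LineCutSet(contour.frame_index, profiles, radii, angles, oob,
                      cut_step, contour.centroid)


def _window_index(n: int, window: int) -> np.ndarray:
    half = (window - 1) // 2
    return (np.arange(n)[:, None] + np.arange(-half, half + 1)[None, :]) % n


def _feature_matrix(cuts: LineCutSet, window: int):
    """All feature images of a frame as normalised row vectors.

    The per-frame mean profile (the angularly uniform component, dominated
    by the pool/myocardium edge itself) is subtracted first: the edge looks
    identical at every candidate shift and would otherwise flatten the
    correlation peak, leaving sub-cut localisation to noise.  What remains
    is the material texture, which actually moves with the wall.

    Returns ``(Z, sd)`` where row i of Z is the zero-mean, unit-SD feature
    vector of border point i (zeros where the patch is featureless).
    """
    P = cuts.profiles - cuts.profiles.mean(axis=0, keepdims=True)
    idx = _window_index(cuts.n_cuts, window)
    F = P[idx].reshape(cuts.n_cuts, -1)
    mu = F.mean(axis=1, keepdims=True)
    sd = F.std(axis=1)
    safe = np.where(sd > 0, sd, 1.0)
    Z = (F - mu) / safe[:, None]
    Z[sd == 0] = 0.0
    # sub-cut refinement operates on matched-filtered profiles: smoothing at
    # roughly the texture correlation scale suppresses noise-only gradients
    # (e.g. over the featureless pool half of each cut) that would otherwise
    # pollute the least-squares fit
    Psm = ndimage.gaussian_filter(P, (0.75, 1.0), mode=("wrap", "nearest"))
    return Z, sd, Psm


_WARP_MARGIN = 12


def _refine_warp(Psm_t: np.ndarray, Psm_next: np.ndarray,
                 int_disp: np.ndarray, window: int,
                 iters: int = 3) -> np.ndarray:
    """Fractional displacement by iterative warp-based least squares.

    For each point the query patch A (frame t, integer grid) is compared
    with the next frame's profiles resampled (cubic) at a trial offset
    along the cut index (angular) and the cut samples (radial); Newton
    steps drive the residual projection to zero.  Warping makes the fixed
    point bias-free: a one-shot gradient step systematically overshoots,
    because finite-difference gradients attenuate the high-frequency part
    of the texture that the residual still contains.
    """
    n, L = Psm_t.shape
    half = (window - 1) // 2
    idx = _window_index(n, window)
    A = Psm_t[idx]                              # (n, W, L)
    m = _WARP_MARGIN
    # pad generously on both axes so every sampled coordinate stays well
    # inside the array: cubic-spline evaluation is only exact away from the
    # boundary of the prefiltered grid
    pad = np.pad(Psm_next, ((m, m), (0, 0)), mode="wrap")
    pad = np.pad(pad, ((0, 0), (m, m)), mode="edge")
    spl = ndimage.spline_filter(pad, order=3)
    woff = np.arange(-half, half + 1)
    cols = np.arange(L, dtype=float) + m
    ds_k = np.zeros(n)
    dr_k = np.zeros(n)
    base = np.arange(n) + int_disp
    for _ in range(iters):
        rows = (base + ds_k)[:, None, None] + woff[None, :, None] + m
        ccols = np.broadcast_to(cols[None, None, :] + dr_k[:, None, None],
                                rows.shape[:2] + (L,))
        rows = np.broadcast_to(rows, ccols.shape)
        B = ndimage.map_coordinates(spl, [rows.ravel(), ccols.ravel()],
                                    order=3, prefilter=False,
                                    mode="nearest").reshape(n, window, L)
        dBs = 0.5 * (np.roll(B, -1, axis=1) - np.roll(B, 1, axis=1))
        dBs[:, 0, :] = B[:, 1, :] - B[:, 0, :]
        dBs[:, -1, :] = B[:, -1, :] - B[:, -2, :]
        dBr = np.gradient(B, axis=2)
        r = (A - B).reshape(n, -1)
        ds = dBs.reshape(n, -1)
        dr = dBr.reshape(n, -1)
        ss = np.einsum("ij,ij->i", ds, ds)
        rr = np.einsum("ij,ij->i", dr, dr)
        sr = np.einsum("ij,ij->i", ds, dr)
        rs_ = np.einsum("ij,ij->i", r, ds)
        rr_ = np.einsum("ij,ij->i", r, dr)
        det = ss * rr - sr ** 2
        ok = det > 1e-9 * np.maximum(ss * rr, 1e-300)
        step_s = np.zeros(n)
        step_r = np.zeros(n)
        step_s[ok] = (rr[ok] * rs_[ok] - sr[ok] * rr_[ok]) / det[ok]
        step_r[ok] = (ss[ok] * rr_[ok] - sr[ok] * rs_[ok]) / det[ok]
        only_s = ~ok & (ss > 0)
        step_s[only_s] = rs_[only_s] / ss[only_s]
        ds_k = np.clip(ds_k + np.clip(step_s, -0.6, 0.6), -1.0, 1.0)
        dr_k = np.clip(dr_k + np.clip(step_r, -0.8, 0.8), -2.0, 2.0)
    return ds_k


def build_feature_image(cuts: LineCutSet, point_index: int,
                        window: int = 7) -> FeatureImage:
    """Stack the ``window`` cuts around ``point_index`` (cyclic)."""
    if window % 2 == 0:
        raise ValueError("window must be odd")
    if window > cuts.n_cuts:
        raise ValueError("window larger than the number of cuts")
    idx = _window_index(cuts.n_cuts, window)[point_index % cuts.n_cuts]
    patch = cuts.profiles[idx]
    return FeatureImage(point_index, patch,
                        float(patch.mean()), float(patch.std()))


def _shift_orders(search_half_width: int):
    """Candidate shifts in natural order and the tie-preference permutation
    (zero displacement first, then smaller |shift|, negative before
    positive, i.e. lower candidate index)."""
    s = search_half_width
    natural = np.arange(-s, s + 1)
    pref = sorted(range(len(natural)), key=lambda j: (abs(natural[j]), natural[j]))
    return natural, np.array(pref)


def _match_all(feat_t, feat_next, search_half_width: int, min_score: float,
               refine: bool = True):
    """Vectorised matching of every point of frame t onto frame t+1.

    The best integer shift maximises the NCC over the cyclic search window;
    :func:`_refine_warp` then adds the fractional part.

    Returns ``(disp, score, low_conf)`` where ``disp`` is the fractional
    cut-index displacement of each point.
    """
    Zt, sdt, Psm_t = feat_t
    Znext, sdnext, Psm_next = feat_next
    n, m = Zt.shape
    window = m // Psm_t.shape[1]
    shifts, pref = _shift_orders(search_half_width)
    scores = np.empty((n, len(shifts)))
    for j, d in enumerate(shifts):
        scores[:, j] = np.einsum("ij,ij->i", Zt, np.roll(Znext, -d, axis=0)) / m
    # argmax with deterministic tie-breaking via the preference order
    best_pref = np.argmax(scores[:, pref], axis=1)
    best = pref[best_pref]
    score = scores[np.arange(n), best]

    disp = shifts[best].astype(float)
    if refine:
        disp += _refine_warp(Psm_t, Psm_next, shifts[best], window)

    featureless = (sdt == 0)
    cand_sd = np.stack([np.roll(sdnext, -d) for d in shifts], axis=1)
    all_flat = (cand_sd == 0).all(axis=1)
    low_conf = featureless | all_flat | (score < min_score)
    disp[featureless | all_flat] = 0.0
    return disp, score, low_conf


def match_features(fi: FeatureImage, candidates: LineCutSet,
                   search_half_width: int = 5,
                   min_score: float = 0.3):
    """Match one feature image onto the next frame's line cuts.

    Returns ``(best_index, score, low_confidence)`` at whole-cut
    resolution; the sub-cut refinement of :func:`track_series` needs both
    frames' cut sets and is not applied here.
    """
    window = fi.patch.shape[0]
    feat_next = _feature_matrix(candidates, window)
    # centre the query with the candidate frame's mean profile (equal to the
    # query frame's for the exact-match constructions, and nearly so between
    # neighbouring frames)
    patch = (fi.patch - candidates.profiles.mean(axis=0)).reshape(1, -1)
    sd = float(patch.std())
    Zt = np.zeros_like(patch) if sd == 0 else (patch - patch.mean()) / sd
    # place the query in row `point_index` of an otherwise flat frame,
    # matching _match_all's per-row shift convention
    n = candidates.n_cuts
    Zq = np.zeros((n, Zt.shape[1]))
    sdq = np.zeros(n)
    i = fi.point_index % n
    Zq[i], sdq[i] = Zt, sd
    disp, score, low = _match_all((Zq, sdq, feat_next[2]), feat_next,
                                  search_half_width, min_score,
                                  refine=False)
    return (i + disp[i]) % n, float(score[i]), bool(low[i])


def _cyclic_interp(values: np.ndarray, pos: np.ndarray) -> np.ndarray:
    n = len(values)
    i0 = np.floor(pos).astype(int) % n
    i1 = (i0 + 1) % n
    w = pos - np.floor(pos)
    return values[i0] * (1 - w) + values[i1] * w


def _angle_at(angles: np.ndarray, pos: np.ndarray) -> np.ndarray:
    """Continuous angle as a function of fractional cut index.

    ``angles`` is the unwrapped per-point angle (spanning 2*pi over one
    revolution of the contour); positions outside [0, N) pick up whole
    turns."""
    n = len(angles)
    ext = np.concatenate([angles, [angles[0] + 2 * np.pi]])
    base = np.floor(pos / n)
    frac_pos = pos - base * n
    i0 = np.floor(frac_pos).astype(int)
    w = frac_pos - i0
    vals = ext[i0] * (1 - w) + ext[np.minimum(i0 + 1, n)] * w
    return vals + 2 * np.pi * base


def track_series(series: ImageSeries, contours,
                 params: TrackParams | None = None) -> BoundaryTrajectories:
    """Track every border point of the first frame through the series."""
    params = params or TrackParams()
    if len(contours) != series.n_frames:
        raise ValueError("need exactly one contour per frame")
    cutsets = [interpolate_line_cuts(series.frames[t], contours[t],
                                     params.cut_len, params.cut_step)
               for t in range(series.n_frames)]
    feats = [_feature_matrix(cs, params.window) for cs in cutsets]

    n = cutsets[0].n_cuts
    T = series.n_frames
    radius = np.empty((T, n))
    angle = np.empty((T, n))
    score = np.empty((T - 1, n))
    warnings: list[str] = []

    pos = np.arange(n, dtype=float)
    radius[0] = cutsets[0].radii_px
    angle[0] = cutsets[0].angles
    for t in range(T - 1):
        disp, sc, low = _match_all(feats[t], feats[t + 1],
                                   params.search_half_width, params.min_score)
        if low.mean() > 0.25:
            warnings.append(
                f"frame pair {t}->{t + 1}: {low.mean():.0%} low-confidence")
        pos = pos + _cyclic_interp(disp, pos)
        radius[t + 1] = _cyclic_interp(cutsets[t + 1].radii_px, pos)
        angle[t + 1] = _angle_at(cutsets[t + 1].angles, pos)
        score[t] = _cyclic_interp(sc, pos)
    return BoundaryTrajectories(radius, angle, score,
                                np.asarray(series.frame_times, float),
                                warnings)


def trajectories_to_velocity(traj: BoundaryTrajectories, spacing: float,
                             smooth_window: int | None = 5) -> VelocityTraces:
    """Convert trajectories to slice-averaged velocity traces.

    v_rad  = d(radius)/dt * spacing          (mm/s, outward positive)
    v_circ = r_mid * d(angle)/dt * spacing   (mm/s, CCW positive)

    The slice-averaged traces are lightly smoothed with a Savitzky-Golay
    filter (``smooth_window`` samples, order 2; None or 0 disables it) to
    suppress sub-cut quantisation noise without biasing the peaks.
    """
    dt = np.diff(traj.frame_times)
    if np.any(dt <= 0):
        raise ValueError("frame times must be strictly increasing")
    dts = dt[:, None]
    v_rad_pts = np.diff(traj.radius_px, axis=0) * spacing / dts * 1e3
    r_mid = 0.5 * (traj.radius_px[1:] + traj.radius_px[:-1]) * spacing
    v_circ_pts = r_mid * np.diff(traj.angle_rad, axis=0) / dts * 1e3
    v_rad = v_rad_pts.mean(axis=1)
    v_circ = v_circ_pts.mean(axis=1)
    if smooth_window and smooth_window >= 3 and len(v_rad) >= smooth_window:
        win = smooth_window + 1 - smooth_window % 2   # force odd
        v_rad = signal.savgol_filter(v_rad, win, 2)
        v_circ = signal.savgol_filter(v_circ, win, 2)
    mid = 0.5 * (traj.frame_times[1:] + traj.frame_times[:-1])
    return VelocityTraces(mid, v_rad, v_circ, v_rad_pts, v_circ_pts)
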