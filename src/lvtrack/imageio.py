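"""File I/O for image series, contours, ground-truth tables and result tables.

Native container is a multi-page TIFF (one page per time frame, uint16) with a
JSON sidecar carrying the physical metadata (pixel spacing in mm, frame times
in ms, slice geometry).  3D NIfTI volumes are accepted as input, with frame
times taken from the sidecar.

Coordinate convention used throughout the package: pixel indices are 0-based
``(row, col)``; physical ``x = col * spacing`` and ``y = row * spacing``;
angles are measured about the pool centroid as ``atan2(row - r0, col - c0)``
and called counter-clockwise-positive in image coordinates.  Clockwise
rotation therefore carries a negative sign.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .errors import IntegrityError, SchemaError

__all__ = [
    "ImageSeries",
    "ResultTable",
    "RESULT_INDEX_NAMES",
    "read_image_series",
    "write_image_series",
    "read_contours",
    "write_contours",
    "export_results",
    "read_results",
]

_SIDE_CAR_FIELDS = ("pixel_spacing", "frame_times", "slice_index",
                    "slice_position", "thickness", "gap")

#: canonical per-subject index names used in result tables
RESULT_INDEX_NAMES = (
    "EDV", "ESV", "SV", "EF",
    "peak_v_rad", "peak_v_circ", "torsion_correlation",
)


@dataclass
class ImageSeries:
    """One short-axis slice as a 2D+time stack with physical metadata.

    frames        : (T, H, W) array, one 2D frame per time point
    frame_times   : (T,) times in ms, strictly increasing
    pixel_spacing : isotropic in-plane spacing, mm/px
    slice_index   : integer position in the stack, 0 = most basal
    slice_position: distance of slice centre from the base, mm
    thickness     : slice thickness, mm
    gap           : inter-slice gap, mm
    """

    frames: np.ndarray
    frame_times: np.ndarray
    pixel_spacing: float
    slice_index: int = 0
    slice_position: float = 0.0
    thickness: float = 8.0
    gap: float = 2.0

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames)
        self.frame_times = np.asarray(self.frame_times, dtype=float)
        if self.frames.ndim != 3:
            raise IntegrityError("frames must be a (T, H, W) stack")
        if len(self.frame_times) != self.frames.shape[0]:
            raise IntegrityError(
                f"{self.frames.shape[0]} frames but "
                f"{len(self.frame_times)} frame times")
        if len(self.frame_times) > 1 and np.any(np.diff(self.frame_times) <= 0):
            raise IntegrityError("frame_times must be strictly increasing")
        if not self.pixel_spacing > 0:
            raise IntegrityError("pixel_spacing must be positive")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def shape(self) -> tuple[int, int]:
        return self.frames.shape[1:]

    def metadata(self) -> dict:
        return {
            "pixel_spacing": float(self.pixel_spacing),
            "frame_times": [float(t) for t in self.frame_times],
            "slice_index": int(self.slice_index),
            "slice_position": float(self.slice_position),
            "thickness": float(self.thickness),
            "gap": float(self.gap),
        }


def write_image_series(series: ImageSeries, path: str | Path,
                       sidecar_path: str | Path | None = None) -> Path:
    """Write a series as one multi-page TIFF plus a JSON sidecar.

    Lossless for integer pixel data.  Returns the sidecar path.
    """
    path = Path(path)
    sidecar = Path(sidecar_path) if sidecar_path else path.with_suffix(".json")
    frames = series.frames
    if not np.issubdtype(frames.dtype, np.integer):
        frames = frames.astype(np.float32)
    tifffile.imwrite(path, frames)
    sidecar.write_text(json.dumps(series.metadata(), indent=1))
    return sidecar


def read_image_series(path: str | Path,
                      sidecar_path: str | Path | None = None) -> ImageSeries:
    """Read a multi-page TIFF or 3D NIfTI series with its JSON sidecar."""
    path = Path(path)
    suffixes = "".join(path.suffixes)
    if sidecar_path is None:
        if suffixes.endswith(".nii.gz"):
            sidecar_path = path.with_name(path.name[:-7] + ".json")
        else:
            sidecar_path = path.with_suffix(".json")
    sidecar_path = Path(sidecar_path)
    if not sidecar_path.exists():
        raise SchemaError(f"sidecar not found: {sidecar_path}")
    meta = json.loads(sidecar_path.read_text())
    missing = [f for f in _SIDE_CAR_FIELDS if f not in meta]
    if missing:
        raise SchemaError(f"sidecar missing fields: {missing}")

    if ".nii" in suffixes:
        import nibabel as nib
        vol = np.asanyarray(nib.load(str(path)).dataobj)
        if vol.ndim != 3:
            raise IntegrityError("NIfTI input must be 3D (x, y, t)")
        frames = np.moveaxis(vol, -1, 0)
    else:
        frames = tifffile.imread(path)
        if frames.ndim == 2:
            frames = frames[None]
    if frames.shape[0] != len(meta["frame_times"]):
        raise IntegrityError(
            f"{frames.shape[0]} frames on disk but sidecar lists "
            f"{len(meta['frame_times'])} frame times")
    return ImageSeries(
        frames=frames,
        frame_times=np.asarray(meta["frame_times"], dtype=float),
        pixel_spacing=float(meta["pixel_spacing"]),
        slice_index=int(meta["slice_index"]),
        slice_position=float(meta["slice_position"]),
        thickness=float(meta["thickness"]),
        gap=float(meta["gap"]),
    )


def write_contours(contours, path: str | Path) -> None:
    """Write border contours as CSV (frame, point_index, row_px, col_px)."""
    rows = []
    for c in contours:
        for j, (r, col) in enumerate(c.points):
            rows.append((c.frame_index, j, r, col))
    pd.DataFrame(rows, columns=["frame", "point_index", "row_px", "col_px"]
                 ).to_csv(path, index=False)


def read_contours(path: str | Path):
    """Read a contour CSV back into a list of :class:`BorderContour`."""
    from .segmentation import BorderContour

    df = pd.read_csv(path)
    required = {"frame", "point_index", "row_px", "col_px"}
    if not required.issubset(df.columns):
        raise SchemaError(f"contour CSV needs columns {sorted(required)}")
    contours = []
    for frame, grp in df.groupby("frame", sort=True):
        grp = grp.sort_values("point_index")
        pts = grp[["row_px", "col_px"]].to_numpy(dtype=float)
        contours.append(BorderContour.from_points(int(frame), pts))
    return contours


@dataclass
class ResultTable:
    """Long-format per-subject index measurements.

    One row per (subject, group, index, value); duplicate (subject, index)
    pairs are rejected.  Canonical index names are listed in
    :data:`RESULT_INDEX_NAMES`; mode-qualified variants (for example a cine
    counterpart of the torsion correlation) are allowed.
    """

    rows: list = field(default_factory=list)

    def add(self, subject: str, group: str, index: str, value: float) -> None:
        if any(r[0] == subject and r[2] == index for r in self.rows):
            raise IntegrityError(f"duplicate entry for ({subject}, {index})")
        self.rows.append((str(subject), str(group), str(index), float(value)))

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.rows,
                          columns=["subject", "group", "index", "value"])
        return df.sort_values(["subject", "index"],
                              kind="stable").reset_index(drop=True)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "ResultTable":
        table = cls()
        for _, r in df.iterrows():
            table.add(r["subject"], r["group"], r["index"], r["value"])
        return table


def export_results(table: ResultTable, path: str | Path,
                   header_comment: str | None = None) -> None:
    """Write a result table as CSV, sorted by (subject, index)."""
    path = Path(path)
    df = table.to_frame()
    with open(path, "w") as fh:
        if header_comment:
            fh.write(f"# {header_comment}\n")
        df.to_csv(fh, index=False)


def read_results(path: str | Path) -> ResultTable:
    df = pd.read_csv(path, comment="#")
    required = {"subject", "group", "index", "value"}
    if not required.issubset(df.columns):
        raise SchemaError(f"result CSV needs columns {sorted(required)}")
    return ResultTable.from_frame(df)
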