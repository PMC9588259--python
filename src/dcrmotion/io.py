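"""Readers and writers for the formats the pipeline touches.

Frame stacks move as multi-frame DICOM files or directories of
single-frame DICOM/PNG/TIFF images (16-bit grayscale preserved);
trajectories move as comma-separated values with one row per frame.
8-bit conversion for video-style viewing applies one global intensity
window to the whole stack so inter-frame correlation is not corrupted
by per-frame rescaling.

All writers are deterministic: identical inputs produce byte-identical
outputs (UTF-8, LF line endings, "." decimal separator for CSV).
"""

from __future__ import annotations

import csv
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pydicom
from pydicom.dataset import Dataset, FileMetaDataset
from pydicom.uid import ExplicitVRLittleEndian, generate_uid

from .phantom import FrameStack
from .tracking import STATUS_TRACKED, Trajectory

__all__ = [
    "read_frames",
    "write_frames",
    "to_8bit",
    "write_trajectory",
    "read_trajectory",
]

_IMAGE_SUFFIXES = (".png", ".tif", ".tiff")
_CSV_COLUMNS = ("time_ms", "x_px", "y_px", "ncc_score", "status")


# ---------------------------------------------------------------------------
# Frame stacks
# ---------------------------------------------------------------------------

def _dicom_pitch(ds) -> float | None:
    for attr in ("PixelSpacing", "ImagerPixelSpacing"):
        val = getattr(ds, attr, None)
        if val:
            return float(val[0])
    return None


def _dicom_rate(ds) -> float | None:
    ft = getattr(ds, "FrameTime", None)  # ms per frame
    if ft:
        return 1000.0 / float(ft)
    cine = getattr(ds, "CineRate", None) or getattr(ds, "RecommendedDisplayFrameRate", None)
    if cine:
        return float(cine)
    return None


def read_frames(
    path: str | Path,
    pixel_pitch_mm: float | None = None,
    frame_rate_hz: float | None = None,
) -> FrameStack:
    """Load a frame stack from a DICOM file or an image directory.

    ``path`` may be a multi-frame DICOM file or a directory holding
    single-frame DICOM, PNG or TIFF images.  DICOM frames are ordered by
    instance number (metadata order wins over file names); plain images
    by sorted file name.  Pixel pitch and frame rate come from DICOM
    metadata when present, otherwise they must be supplied.
    """
    path = Path(path)
    pitch, rate = pixel_pitch_mm, frame_rate_hz
    if path.is_file():
        ds = pydicom.dcmread(path)
        arr = ds.pixel_array
        if arr.ndim == 2:
            arr = arr[None]
        pitch = pitch or _dicom_pitch(ds)
        rate = rate or _dicom_rate(ds)
    elif path.is_dir():
        dcm_files = sorted(path.glob("*.dcm"))
        img_files = sorted(p for p in path.iterdir() if p.suffix.lower() in _IMAGE_SUFFIXES)
        if dcm_files:
            datasets = [pydicom.dcmread(p) for p in dcm_files]
            datasets.sort(key=lambda d: int(getattr(d, "InstanceNumber", 0)))
            frames = [d.pixel_array for d in datasets]
            pitch = pitch or _dicom_pitch(datasets[0])
            rate = rate or _dicom_rate(datasets[0])
        elif img_files:
            frames = [iio.imread(p) for p in img_files]
        else:
            raise ValueError(f"no DICOM/PNG/TIFF frames found in {path}")
        shapes = {f.shape for f in frames}
        if len(shapes) != 1:
            raise ValueError(f"frames have mixed dimensions: {sorted(shapes)}")
        arr = np.stack(frames)
    else:
        raise FileNotFoundError(path)
    if pitch is None or rate is None:
        raise ValueError("pixel pitch / frame rate absent from metadata; supply them explicitly")
    bit_depth = 8 if arr.dtype == np.uint8 else 16
    return FrameStack(frames=np.ascontiguousarray(arr), pixel_pitch_mm=float(pitch),
                      frame_rate_hz=float(rate), bit_depth=bit_depth)


def write_frames(stack: FrameStack, path: str | Path, fmt: str = "png") -> Path:
    """Write a frame stack as numbered images or a multi-frame DICOM.

    ``fmt``: ``"png"``/``"tiff"`` write one 16-bit image per frame into
    the directory ``path``; ``"dcm"`` writes one multi-frame DICOM file.
    """
    path = Path(path)
    if fmt in ("png", "tiff"):
        path.mkdir(parents=True, exist_ok=True)
        suffix = ".png" if fmt == "png" else ".tif"
        for k in range(len(stack)):
            iio.imwrite(path / f"frame_{k:04d}{suffix}", stack.frames[k])
        return path
    if fmt == "dcm":
        return _write_multiframe_dicom(stack, path)
    raise ValueError(f"unknown format {fmt!r}")


def _write_multiframe_dicom(stack: FrameStack, path: Path) -> Path:
    frames = np.ascontiguousarray(stack.frames)
    meta = FileMetaDataset()
    meta.MediaStorageSOPClassUID = pydicom.uid.SecondaryCaptureImageStorage
    meta.MediaStorageSOPInstanceUID = generate_uid()
    meta.TransferSyntaxUID = ExplicitVRLittleEndian
    ds = Dataset()
    ds.file_meta = meta
    ds.SOPClassUID = meta.MediaStorageSOPClassUID
    ds.SOPInstanceUID = meta.MediaStorageSOPInstanceUID
    ds.Modality = "OT"
    ds.SamplesPerPixel = 1
    ds.PhotometricInterpretation = "MONOCHROME2"
    ds.NumberOfFrames = frames.shape[0]
    ds.Rows, ds.Columns = frames.shape[1:]
    ds.BitsAllocated = 16 if frames.dtype != np.uint8 else 8
    ds.BitsStored = ds.BitsAllocated
    ds.HighBit = ds.BitsAllocated - 1
    ds.PixelRepresentation = 0
    ds.ImagerPixelSpacing = [stack.pixel_pitch_mm, stack.pixel_pitch_mm]
    ds.FrameTime = 1000.0 / stack.frame_rate_hz
    ds.PixelData = frames.tobytes()
    ds.save_as(path, enforce_file_format=True)
    return path


def to_8bit(stack: FrameStack, lo: float | None = None, hi: float | None = None) -> FrameStack:
    """Window a 16-bit stack to 8 bits with one global intensity window.

    ``[lo, hi]`` maps linearly to ``[0, 255]`` with clipping and
    half-up rounding; the defaults are the global min/max over the whole
    stack, so every frame shares the same window (no flicker).  The
    mapping is monotone.
    """
    data = stack.frames.astype(np.float64)
    if lo is None:
        lo = float(data.min())
    if hi is None:
        hi = float(data.max())
    if hi <= lo:
        raise ValueError(
            "degenerate intensity window (constant stack?); pass an explicit lo/hi window"
        )
    scaled = np.clip((data - lo) / (hi - lo) * 255.0, 0.0, 255.0)
    out = np.floor(scaled + 0.5).astype(np.uint8)  # round half up
    return FrameStack(frames=out, pixel_pitch_mm=stack.pixel_pitch_mm,
                      frame_rate_hz=stack.frame_rate_hz, bit_depth=8)


# ---------------------------------------------------------------------------
# Trajectory CSV
# ---------------------------------------------------------------------------

def write_trajectory(path: str | Path, traj: Trajectory) -> Path:
    """Write a trajectory as CSV (time_ms, x_px, y_px, ncc_score, status)."""
    path = Path(path)
    with open(path, "w", newline="\n", encoding="utf-8") as fh:
        writer = csv.writer(fh, lineterminator="\n")
        writer.writerow(_CSV_COLUMNS)
        for i in range(len(traj)):
            writer.writerow([
                f"{traj.time_ms[i]:.3f}",
                _fmt(traj.x_px[i]),
                _fmt(traj.y_px[i]),
                _fmt(traj.ncc_score[i], 6),
                str(traj.status[i]),
            ])
    return path


def _fmt(v: float, nd: int = 3) -> str:
    return "" if not np.isfinite(v) else f"{v:.{nd}f}"


def read_trajectory(path: str | Path) -> Trajectory:
    """Read a trajectory CSV; tolerant of absent optional columns.

    ``ncc_score`` defaults to NaN and ``status`` to ``tracked`` when the
    columns are missing.  Malformed rows raise with their line number.
    """
    path = Path(path)
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.reader(fh)
        try:
            header = next(reader)
        except StopIteration:
            raise ValueError(f"{path}: empty file") from None
        header = [h.strip() for h in header]
        for required in ("time_ms", "x_px", "y_px"):
            if required not in header:
                raise ValueError(f"{path}: missing required column {required!r}")
        idx = {name: header.index(name) for name in header}
        rows = []
        for lineno, row in enumerate(reader, start=2):
            if not row:
                continue
            try:
                time_ms = float(row[idx["time_ms"]])
                x = _parse(row[idx["x_px"]])
                y = _parse(row[idx["y_px"]])
                score = _parse(row[idx["ncc_score"]]) if "ncc_score" in idx else np.nan
                status = row[idx["status"]] if "status" in idx else STATUS_TRACKED
            except (ValueError, IndexError) as exc:
                raise ValueError(f"{path}: malformed row at line {lineno}: {row!r}") from exc
            rows.append((time_ms, x, y, score, status))
    if not rows:
        raise ValueError(f"{path}: no data rows")
    time_ms, x, y, score, status = zip(*rows)
    return Trajectory(
        frame_index=np.arange(len(rows)),
        time_ms=np.asarray(time_ms), x_px=np.asarray(x), y_px=np.asarray(y),
        ncc_score=np.asarray(score), status=np.asarray(status, dtype=object),
    )


def _parse(text: str) -> float:
    return np.nan if text == "" else float(text)
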