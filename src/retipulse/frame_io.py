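"""Fundus-video frame handling and green-channel series extraction.

A recording is an ordered stack of 8-bit RGB frames (typically ~70 frames
covering three cardiac cycles at 25 fps).  The pulse signal of a vessel
segment is the per-frame mean of the green channel over a binary vessel
template, after discarding pixels whose mean RGB intensity sits within 1% of
pure black or pure white (sensor noise and the central vessel light reflex).
For spatial mapping the same reduction is applied to a regular tiling of the
frame into 2x2 or 5x5 pixel clusters.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from PIL import Image
import tifffile

from .exceptions import DegenerateDataError, FormatError
from .harmonic import CycleTiming

__all__ = [
    "FrameSequence",
    "VesselTemplate",
    "ChannelSeries",
    "ClusterGrid",
    "load_frames",
    "excluded_pixel_mask",
    "extract_template_series",
    "extract_cluster_series",
    "align_frames",
    "EXCLUSION_LOW",
    "EXCLUSION_HIGH",
]

# "within 1% of either extreme" on the 0-255 scale
EXCLUSION_LOW = 2.55
EXCLUSION_HIGH = 255.0 - 2.55


@dataclass
class FrameSequence:
    """Ordered RGB frame stack of one recording."""

    frames: np.ndarray  # (M, H, W, 3), values on the 0-255 scale
    frame_rate: float = 25.0
    recording_id: str = ""

    def __post_init__(self):
        frames = np.asarray(self.frames)
        if frames.ndim != 4 or frames.shape[-1] != 3:
            raise FormatError("frames must have shape (M, H, W, 3)")
        if frames.shape[0] < 2:
            raise FormatError("a recording needs at least 2 frames")
        if frames.min() < 0 or frames.max() > 255:
            raise FormatError("intensities must lie in [0, 255]")
        self.frames = frames

    @property
    def M(self) -> int:
        return self.frames.shape[0]

    @property
    def shape(self):
        return self.frames.shape[1:3]

    def green(self) -> np.ndarray:
        """Green channel, shape (M, H, W), float."""
        return self.frames[..., 1].astype(float)


@dataclass
class VesselTemplate:
    """Binary vessel mask used to pool pixels into one series."""

    mask: np.ndarray
    label: str = ""
    vessel_type: str = "vein"  # artery | vein

    def __post_init__(self):
        mask = np.asarray(self.mask).astype(bool)
        if mask.ndim != 2:
            raise FormatError("mask must be 2-D")
        if not mask.any():
            raise DegenerateDataError(f"vessel template {self.label!r} is empty")
        self.mask = mask


@dataclass
class ChannelSeries:
    """Mean green-intensity series of one template or cluster."""

    t: np.ndarray
    g: np.ndarray
    source: str = ""
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        t = np.asarray(self.t, dtype=float)
        g = np.asarray(self.g, dtype=float)
        if t.shape != g.shape:
            raise FormatError("t and g must have equal length")
        if np.any(np.diff(t) <= 0):
            raise FormatError("t must be strictly increasing")
        self.t, self.g = t, g

    def __len__(self) -> int:
        return len(self.t)


@dataclass
class ClusterGrid:
    """Per-cluster series on a regular tiling of the frame.

    ``g[r, c]`` holds the series of the tile anchored at pixel
    ``(r * cluster_size, c * cluster_size)``; tiles in which every pixel was
    excluded in some frame are flagged in ``missing`` and NaN-filled.
    """

    t: np.ndarray
    g: np.ndarray  # (rows, cols, M)
    missing: np.ndarray  # (rows, cols) bool
    cluster_size: int
    origin: tuple = (0, 0)

    @property
    def grid_shape(self):
        return self.g.shape[:2]

    def series(self, row: int, col: int, metadata=None) -> ChannelSeries:
        if self.missing[row, col]:
            raise DegenerateDataError(f"cluster ({row}, {col}) is missing")
        return ChannelSeries(
            t=self.t,
            g=self.g[row, col],
            source=f"cluster[{row},{col}]",
            metadata=dict(metadata or {}),
        )


def _read_image(path: Path) -> np.ndarray:
    path = Path(path)
    try:
        if path.suffix.lower() in (".tif", ".tiff"):
            arr = tifffile.imread(path)
        else:
            with Image.open(path) as img:
                arr = np.asarray(img.convert("RGB"))
    except Exception as exc:  # noqa: BLE001 - re-raise with the file name
        raise OSError(f"could not read frame file {path}: {exc}") from exc
    arr = np.asarray(arr)
    if arr.ndim == 2:  # grayscale: replicate into RGB
        arr = np.stack([arr] * 3, axis=-1)
    if arr.shape[-1] == 4:
        arr = arr[..., :3]
    return arr


def load_frames(paths, roi=None, frame_rate: float = 25.0,
                recording_id: str = "") -> FrameSequence:
    """Load ordered frame image files into a :class:`FrameSequence`.

    Parameters
    ----------
    paths : sequence of path-like
        Frame files (TIFF or PNG); sorted by filename to restore frame order.
    roi : tuple or None
        Crop ``(row_start, row_stop, col_start, col_stop)`` applied to every
        frame.
    """
    paths = sorted(Path(p) for p in paths)
    if not paths:
        raise FormatError("no frame files given")
    frames = []
    shape = None
    for p in paths:
        arr = _read_image(p)
        if shape is None:
            shape = arr.shape
        elif arr.shape != shape:
            raise FormatError(
                f"frame {p} has shape {arr.shape}, expected {shape}"
            )
        frames.append(arr)
    stack = np.stack(frames)
    if roi is not None:
        r0, r1, c0, c1 = roi
        stack = stack[:, r0:r1, c0:c1]
    return FrameSequence(stack, frame_rate=frame_rate, recording_id=recording_id)


def excluded_pixel_mask(frame: np.ndarray) -> np.ndarray:
    """True where a pixel's mean RGB intensity is within 1% of pure black or
    pure white (0-255 scale): mean <= 2.55 or mean >= 252.45."""
    frame = np.asarray(frame, dtype=float)
    mean_rgb = frame.mean(axis=-1)
    return (mean_rgb <= EXCLUSION_LOW) | (mean_rgb >= EXCLUSION_HIGH)


def extract_template_series(
    frames: FrameSequence,
    template: VesselTemplate,
    timing: CycleTiming,
    metadata=None,
) -> ChannelSeries:
    """Mean green intensity over (template AND NOT excluded) per frame."""
    if template.mask.shape != frames.shape:
        raise FormatError(
            f"template shape {template.mask.shape} != frame shape {frames.shape}"
        )
    if timing.n_frames != frames.M:
        raise FormatError(
            f"timing covers {timing.n_frames} frames, recording has {frames.M}"
        )
    green = frames.green()
    g = np.empty(frames.M)
    for k in range(frames.M):
        keep = template.mask & ~excluded_pixel_mask(frames.frames[k])
        if not keep.any():
            raise DegenerateDataError(
                f"template {template.label!r}: all pixels excluded in frame {k}"
            )
        g[k] = green[k][keep].mean()
    meta = dict(metadata or {})
    meta.setdefault("vessel_type", template.vessel_type)
    return ChannelSeries(t=timing.times(), g=g, source=template.label, metadata=meta)


def extract_cluster_series(
    frames: FrameSequence,
    cluster_size: int,
    timing: CycleTiming,
) -> ClusterGrid:
    """Reduce the stack to one series per non-overlapping pixel cluster.

    The frame is tiled into ``cluster_size x cluster_size`` tiles anchored at
    the top-left pixel; trailing partial rows/columns are dropped.  Excluded
    pixels are removed from each tile mean; a tile whose pixels are all
    excluded in any frame is flagged missing.
    """
    if cluster_size < 1:
        raise FormatError("cluster_size must be >= 1")
    if timing.n_frames != frames.M:
        raise FormatError(
            f"timing covers {timing.n_frames} frames, recording has {frames.M}"
        )
    H, W = frames.shape
    rows, cols = H // cluster_size, W // cluster_size
    Hc, Wc = rows * cluster_size, cols * cluster_size
    green = frames.green()[:, :Hc, :Wc]
    keep = ~np.stack(
        [excluded_pixel_mask(f) for f in frames.frames]
    )[:, :Hc, :Wc]

    # tile sums via reshape: (M, rows, s, cols, s)
    s = cluster_size
    g_tiles = green.reshape(frames.M, rows, s, cols, s)
    k_tiles = keep.reshape(frames.M, rows, s, cols, s)
    sums = (g_tiles * k_tiles).sum(axis=(2, 4))
    counts = k_tiles.sum(axis=(2, 4))
    missing = (counts == 0).any(axis=0)  # (rows, cols)
    with np.errstate(invalid="ignore", divide="ignore"):
        means = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
    g = np.transpose(means, (1, 2, 0))  # (rows, cols, M)
    g[missing] = np.nan
    return ClusterGrid(
        t=timing.times(), g=g, missing=missing, cluster_size=cluster_size
    )


def align_frames(frames: FrameSequence, enabled: bool = False) -> FrameSequence:
    """Optionally register frames to frame 1 by integer-pixel translation.

    Each frame is shifted (circularly) by the integer displacement that
    maximizes the green-channel cross-correlation with the first frame.
    Off by default: registration quality is not part of the analysis surface
    and well-acquired stacks need no alignment.
    """
    if not enabled:
        return frames
    from skimage.registration import phase_cross_correlation

    green = frames.green()
    ref = green[0]
    out = frames.frames.copy()
    for k in range(1, frames.M):
        shift, _, _ = phase_cross_correlation(ref, green[k], upsample_factor=1)
        dy, dx = int(round(shift[0])), int(round(shift[1]))
        out[k] = np.roll(np.roll(frames.frames[k], dy, axis=0), dx, axis=1)
    return FrameSequence(
        out, frame_rate=frames.frame_rate, recording_id=frames.recording_id
    )
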