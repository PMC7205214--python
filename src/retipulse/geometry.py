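"""Vessel centerline geometry: distance along the vessel in disc diameters.

V_Dist of an image point is defined as the arc length from the optic-disc
center to the point's projection on the digitized vessel centerline, divided
by the disc diameter in pixels.  When the centerline starts at the disc
margin rather than the disc center, the straight-line gap from the disc
center to the centerline start is added.  Coordinates are 0-based (row, col)
pixel indices; arc length is the Euclidean sum over polyline segments.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage, stats

from .exceptions import ConfigurationError, DegenerateDataError, ProjectionError

__all__ = [
    "VesselGeometry",
    "v_dist",
    "point_of_max_pulsation",
    "max_pulsation_shift_vs_odf",
]


@dataclass
class VesselGeometry:
    """Disc and centerline geometry of one vessel."""

    disc_center: tuple  # (row, col) pixels
    disc_diameter_px: float
    centerline: np.ndarray  # (n, 2) ordered (row, col), starting nearest disc
    vessel_type: str = "vein"
    hemiretina: str = "superior"

    def __post_init__(self):
        if self.disc_diameter_px <= 0:
            raise ConfigurationError("disc_diameter_px must be > 0")
        cl = np.asarray(self.centerline, dtype=float)
        if cl.ndim != 2 or cl.shape[0] < 2 or cl.shape[1] != 2:
            raise ConfigurationError("centerline needs >= 2 (row, col) points")
        seg = np.diff(cl, axis=0)
        seg_len = np.hypot(seg[:, 0], seg[:, 1])
        if np.any(seg_len <= 0):
            raise ConfigurationError(
                "centerline arc length must be strictly increasing "
                "(duplicate consecutive points)"
            )
        self.centerline = cl
        self._seg = seg
        self._seg_len = seg_len
        self._arc0 = np.concatenate([[0.0], np.cumsum(seg_len)])
        self._start_gap = float(
            np.hypot(*(cl[0] - np.asarray(self.disc_center, dtype=float)))
        )


def v_dist(geometry: VesselGeometry, point, max_projection_px: float = 10.0) -> float:
    """Distance of ``point`` along the vessel from the disc center, in DD.

    The point is projected onto the nearest centerline segment; V_Dist is
    (arc length to the projection + disc-center-to-centerline-start gap)
    divided by the disc diameter.
    """
    p = np.asarray(point, dtype=float)
    cl = geometry.centerline
    # projection parameter on each segment, clamped to [0, 1]
    rel = p[None, :] - cl[:-1]
    tpar = np.einsum("ij,ij->i", rel, geometry._seg) / geometry._seg_len**2
    tpar = np.clip(tpar, 0.0, 1.0)
    proj = cl[:-1] + tpar[:, None] * geometry._seg
    d = np.hypot(*(p[None, :] - proj).T)
    i = int(np.argmin(d))
    if d[i] > max_projection_px:
        raise ProjectionError(
            f"point {tuple(p)} is {d[i]:.1f} px from the centerline "
            f"(limit {max_projection_px})"
        )
    arc = geometry._arc0[i] + tpar[i] * geometry._seg_len[i]
    return float((arc + geometry._start_gap) / geometry.disc_diameter_px)


def point_of_max_pulsation(samples) -> float:
    """V_Dist of the maximal smoothed log amplitude along one vessel.

    ``samples``: iterable of (V_Dist, log10 HRW_a).  The amplitude profile is
    smoothed with a moving median of window 3 (endpoints use nearest
    padding) before taking the argmax; ties resolve to the smallest V_Dist.
    """
    arr = np.asarray(list(samples), dtype=float)
    if arr.ndim != 2 or arr.shape[0] < 3:
        raise DegenerateDataError("need >= 3 (V_Dist, log amplitude) samples")
    order = np.argsort(arr[:, 0], kind="stable")
    vd, amp = arr[order, 0], arr[order, 1]
    smooth = ndimage.median_filter(amp, size=3, mode="nearest")
    best = int(np.argmax(smooth))  # argmax returns the first (smallest V_Dist)
    return float(vd[best])


def max_pulsation_shift_vs_odf(maxima):
    """OLS slope of the per-run maximum-pulsation location on ODF.

    ``maxima``: iterable of (ODF grams, V_Dist of maximum).  Returns
    ``(slope, stderr, p_value)`` from a two-sided t-test of zero slope.
    """
    arr = np.asarray(list(maxima), dtype=float)
    if arr.shape[0] < 3:
        raise DegenerateDataError("need >= 3 runs")
    odf, vmax = arr[:, 0], arr[:, 1]
    if np.ptp(odf) == 0:
        raise DegenerateDataError("ODF does not vary across runs")
    res = stats.linregress(odf, vmax)
    return float(res.slope), float(res.stderr), float(res.pvalue)
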