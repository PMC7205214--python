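"""Synthetic fundus-pulsation studies with known ground truth.

The generator emulates the statistical structure the downstream analysis
assumes: each (eye, run, vessel-position) produces a mean green-intensity
series that is the sum of

* a two-harmonic cardiac waveform whose peak-to-trough amplitude follows the
  log-linear attenuation law
  ``log10 A = I0 + C_VD*V_Dist + C_ODF*ODF + C_VDxODF*V_Dist*ODF``
  plus per-eye random intercept/slope deviations,
* a piecewise-linear drift artifact with knots exactly at cycle boundaries
  t = 1 and t = 2 (so drift is exactly representable by the estimator's
  spline, isolating estimator correctness from model mismatch), and
* AR(1) noise with lag-1 correlation ``rho`` and marginal standard deviation
  ``noise_sd``.

Default fixed coefficients are the interaction-model values for retinal
veins (0.90, -0.34, 0.0015, -0.00084) and arteries (0.66, -0.13, 0.0007,
-0.0005); the default waveform shape follows the observed sign pattern of
the Fourier coefficients (dominant positive first-harmonic cosine, negative
first-harmonic sine, smaller second harmonic) and is rescaled to unit
peak-to-trough before amplitude scaling.

``render_frames`` additionally rasterizes one recording as an 8-bit RGB
frame stack showing a darker pulsating vessel on a brighter background,
with a matching binary template mask and centerline polyline, closing the
loop frame-stack -> extraction -> harmonic fit -> amplitude map.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .exceptions import ConfigurationError
from .frame_io import ChannelSeries, FrameSequence, VesselTemplate
from .harmonic import CycleTiming, peak_to_trough, periodic_waveform

__all__ = [
    "SyntheticStudyConfig",
    "SyntheticGroundTruth",
    "RenderedScene",
    "VENOUS_COEFFS",
    "ARTERIAL_COEFFS",
    "generate_series",
    "generate_attenuation_records",
    "render_frames",
    "series_to_dataframe",
    "save_scene",
]

#: interaction-model fixed effects (I0, C_VD, C_ODF, C_VDxODF)
VENOUS_COEFFS = (0.90, -0.34, 0.0015, -0.00084)
ARTERIAL_COEFFS = (0.66, -0.13, 0.0007, -0.0005)

#: relative two-harmonic shape (a1, b1, a2, b2) before unit-amplitude scaling
DEFAULT_WAVEFORM = (0.93, -0.81, -0.24, 0.09)


@dataclass(frozen=True)
class SyntheticStudyConfig:
    """Parameters of a synthetic ophthalmodynamometric pulsation study.

    Defaults reproduce the study conditions: 28 eyes (two per subject), 9
    runs per eye spanning 0-180 g of ophthalmodynamometric force, three
    cardiac cycles of ~23 frames at 25 fps, and venous attenuation
    coefficients.  ``random_effect_sd`` and ``log_residual_sd`` are chosen
    so the interaction model recovers the study's variance split
    (marginal R^2 ~0.2, conditional ~0.65); see the methods note.
    """

    n_eyes: int = 28
    runs_per_eye: int = 9
    odf_range_g: tuple = (0.0, 180.0)
    points_per_vessel: int = 20
    frames_per_cycle: int = 23
    cycle_jitter: int = 2
    n_cycles: int = 3
    vessel_type: str = "vein"
    fixed_coeffs: tuple | None = None  # (I0, C_VD, C_ODF, C_VDxODF)
    waveform_coeffs: tuple = DEFAULT_WAVEFORM
    rho: float = 0.3
    noise_sd: float = 1.0
    drift_sd: float = 1.0
    random_effect_sd: tuple = (0.17, 0.17)
    log_residual_sd: float = 0.17
    mean_intensity: float = 120.0
    frame_rate: float = 25.0
    seed: int = 0

    def __post_init__(self):
        for name in ("n_eyes", "runs_per_eye", "points_per_vessel",
                     "frames_per_cycle", "n_cycles"):
            if int(getattr(self, name)) < 1:
                raise ConfigurationError(f"{name} must be >= 1")
        lo, hi = self.odf_range_g
        if not (0 <= lo <= hi <= 300):
            raise ConfigurationError("odf_range_g must lie within [0, 300]")
        if not abs(self.rho) < 1:
            raise ConfigurationError("rho must satisfy |rho| < 1")
        for name in ("noise_sd", "drift_sd", "log_residual_sd"):
            if getattr(self, name) < 0:
                raise ConfigurationError(f"{name} must be >= 0")
        if any(s < 0 for s in self.random_effect_sd):
            raise ConfigurationError("random_effect_sd must be >= 0")
        if self.cycle_jitter < 0:
            raise ConfigurationError("cycle_jitter must be >= 0")
        if self.frames_per_cycle - self.cycle_jitter < 4:
            raise ConfigurationError(
                "frames_per_cycle - cycle_jitter must leave >= 4 frames"
            )
        if self.vessel_type not in ("vein", "artery"):
            raise ConfigurationError("vessel_type must be 'vein' or 'artery'")

    @property
    def coeffs(self) -> tuple:
        """Fixed effects in use (explicit, or the vessel-type default)."""
        if self.fixed_coeffs is not None:
            return tuple(self.fixed_coeffs)
        return VENOUS_COEFFS if self.vessel_type == "vein" else ARTERIAL_COEFFS

    def odf_values(self) -> np.ndarray:
        """ODF per run: a 0-force baseline plus uniform increments."""
        lo, hi = self.odf_range_g
        if self.runs_per_eye == 1:
            return np.array([lo])
        if lo == 0:
            return np.linspace(0.0, hi, self.runs_per_eye)
        return np.concatenate(
            [[0.0], np.linspace(lo, hi, self.runs_per_eye - 1)]
        )

    def v_dist_points(self) -> np.ndarray:
        if self.points_per_vessel == 1:
            return np.array([0.0])
        return np.linspace(0.0, 1.0, self.points_per_vessel)

    def unit_waveform(self) -> tuple:
        """(a, b) arrays of the two-harmonic shape scaled to unit
        peak-to-trough."""
        a1, b1, a2, b2 = self.waveform_coeffs
        a = np.array([a1, a2])
        b = np.array([b1, b2])
        scale = peak_to_trough(a, b)
        if scale == 0:
            return a, b
        return a / scale, b / scale


@dataclass
class SyntheticGroundTruth:
    """Everything the generator knows that the analysis must recover."""

    config: SyntheticStudyConfig
    eye_effects: np.ndarray  # (n_eyes, 2): intercept, V_Dist-slope deviations
    odf_values: np.ndarray  # per run
    v_dist_points: np.ndarray
    table: pd.DataFrame  # one row per series with truth columns
    cycle_counts: dict  # (eye, run) -> tuple of frame counts
    unit_a: np.ndarray
    unit_b: np.ndarray

    def true_log10_amplitude(self, eye: int, v_dist, odf) -> np.ndarray:
        i0, cvd, codf, cint = self.config.coeffs
        u0, u1 = self.eye_effects[eye]
        v = np.asarray(v_dist, dtype=float)
        o = np.asarray(odf, dtype=float)
        return i0 + u0 + (cvd + u1) * v + codf * o + cint * v * o


def _drift(t: np.ndarray, slopes: np.ndarray) -> np.ndarray:
    """Piecewise-linear drift with knots at t = 1 and t = 2."""
    return (
        slopes[0] * t
        + slopes[1] * np.maximum(t - 1.0, 0.0)
        + slopes[2] * np.maximum(t - 2.0, 0.0)
    )


def _ar1_noise(rng, n: int, rho: float, sd: float) -> np.ndarray:
    """Stationary AR(1) noise with marginal standard deviation ``sd``."""
    if sd == 0:
        return np.zeros(n)
    e = np.empty(n)
    e[0] = rng.normal(0.0, sd)
    innov_sd = sd * np.sqrt(1.0 - rho * rho)
    u = rng.normal(0.0, innov_sd, size=n - 1)
    for k in range(1, n):
        e[k] = rho * e[k - 1] + u[k - 1]
    return e


def generate_series(config: SyntheticStudyConfig):
    """Generate all per-position series of a synthetic study.

    Returns ``(series_list, ground_truth)`` with one
    :class:`~retipulse.frame_io.ChannelSeries` per (eye, run, V_Dist point).
    Identical config (including seed) gives bit-identical output.
    """
    rng = np.random.default_rng(config.seed)
    n_eyes = config.n_eyes
    sd0, sd1 = config.random_effect_sd
    eye_effects = np.column_stack(
        [rng.normal(0.0, sd0, n_eyes) if sd0 > 0 else np.zeros(n_eyes),
         rng.normal(0.0, sd1, n_eyes) if sd1 > 0 else np.zeros(n_eyes)]
    )
    odf = config.odf_values()
    vpts = config.v_dist_points()
    unit_a, unit_b = config.unit_waveform()
    i0, cvd, codf, cint = config.coeffs

    series_list = []
    rows = []
    cycle_counts = {}
    for eye in range(n_eyes):
        subject = eye // 2
        u0, u1 = eye_effects[eye]
        for run in range(config.runs_per_eye):
            if config.cycle_jitter > 0:
                jit = rng.integers(
                    -config.cycle_jitter, config.cycle_jitter + 1,
                    size=config.n_cycles,
                )
            else:
                jit = np.zeros(config.n_cycles, dtype=int)
            counts = tuple(int(config.frames_per_cycle + j) for j in jit)
            cycle_counts[(eye, run)] = counts
            timing = CycleTiming(counts)
            t = timing.times()
            for v in vpts:
                logA = (i0 + u0 + (cvd + u1) * v
                        + codf * odf[run] + cint * v * odf[run])
                A = 10.0 ** logA
                slopes = (rng.normal(0.0, config.drift_sd, 3)
                          if config.drift_sd > 0 else np.zeros(3))
                noise = _ar1_noise(rng, len(t), config.rho, config.noise_sd)
                g = (config.mean_intensity
                     + A * periodic_waveform(t, unit_a, unit_b)
                     + _drift(t, slopes)
                     + noise)
                meta = {
                    "subject_id": f"S{subject:02d}",
                    "eye_id": f"E{eye:02d}",
                    "run_id": run,
                    "odf_g": float(odf[run]),
                    "v_dist_dd": float(v),
                    "vessel_type": config.vessel_type,
                }
                series_list.append(ChannelSeries(
                    t=t, g=g,
                    source=f"eye{eye}_run{run}_v{v:.3f}",
                    metadata=meta,
                ))
                rows.append({
                    **meta,
                    "true_log10_amp": float(logA),
                    "true_a1": float(A * unit_a[0]),
                    "true_b1": float(A * unit_b[0]),
                    "true_a2": float(A * unit_a[1]),
                    "true_b2": float(A * unit_b[1]),
                    "true_rho": config.rho,
                    "drift_s1": float(slopes[0]),
                    "drift_s2": float(slopes[1]),
                    "drift_s3": float(slopes[2]),
                })
    truth = SyntheticGroundTruth(
        config=config,
        eye_effects=eye_effects,
        odf_values=odf,
        v_dist_points=vpts,
        table=pd.DataFrame(rows),
        cycle_counts=cycle_counts,
        unit_a=unit_a,
        unit_b=unit_b,
    )
    return series_list, truth


def generate_attenuation_records(config: SyntheticStudyConfig) -> pd.DataFrame:
    """Draw study records directly at the amplitude level.

    Each (eye, run, point) yields one record whose ``log_hrwa`` is the true
    amplitude law plus N(0, ``log_residual_sd``) measurement error — the
    study-scale generator for the mixed-effects recovery analyses, skipping
    the per-series time-domain stage.  Fourier-coefficient columns carry the
    noisy amplitude split by the unit waveform shape.
    """
    rng = np.random.default_rng(config.seed)
    n_eyes = config.n_eyes
    sd0, sd1 = config.random_effect_sd
    eye_effects = np.column_stack(
        [rng.normal(0.0, sd0, n_eyes) if sd0 > 0 else np.zeros(n_eyes),
         rng.normal(0.0, sd1, n_eyes) if sd1 > 0 else np.zeros(n_eyes)]
    )
    odf = config.odf_values()
    vpts = config.v_dist_points()
    unit_a, unit_b = config.unit_waveform()
    i0, cvd, codf, cint = config.coeffs

    eye_idx, run_idx, pt_idx = np.meshgrid(
        np.arange(n_eyes), np.arange(config.runs_per_eye),
        np.arange(len(vpts)), indexing="ij",
    )
    eye_idx = eye_idx.ravel()
    o = odf[run_idx.ravel()]
    v = vpts[pt_idx.ravel()]
    true_log = (i0 + eye_effects[eye_idx, 0]
                + (cvd + eye_effects[eye_idx, 1]) * v
                + codf * o + cint * v * o)
    noise = (rng.normal(0.0, config.log_residual_sd, len(true_log))
             if config.log_residual_sd > 0 else 0.0)
    log_hrwa = true_log + noise
    amp = 10.0 ** log_hrwa
    return pd.DataFrame({
        "subject_id": [f"S{e // 2:02d}" for e in eye_idx],
        "eye_id": [f"E{e:02d}" for e in eye_idx],
        "run_id": run_idx.ravel(),
        "odf_g": o,
        "v_dist_dd": v,
        "vessel_type": config.vessel_type,
        "hrw_a": amp,
        "log_hrwa": log_hrwa,
        "true_log10_amp": true_log,
        "a1": amp * unit_a[0],
        "b1": amp * unit_b[0],
        "a2": amp * unit_a[1],
        "b2": amp * unit_b[1],
    })


@dataclass
class RenderedScene:
    """A rasterized synthetic recording with its generating truth."""

    frames: FrameSequence
    template: VesselTemplate
    centerline: np.ndarray  # (n, 2) (row, col) pixel coordinates
    timing: CycleTiming
    disc_center: tuple
    disc_diameter_px: float
    series: list  # the per-point ChannelSeries rendered
    truth: SyntheticGroundTruth


def render_frames(
    config: SyntheticStudyConfig,
    eye: int = 0,
    run: int = 0,
    image_shape: tuple = (96, 96),
    vessel_half_width: float = 3.0,
    background_green: float = 160.0,
    margin: int = 8,
) -> RenderedScene:
    """Rasterize one recording of the synthetic study as an RGB frame stack.

    A gently curved vessel runs diagonally across the image; its green
    intensity at arc position s oscillates with the generated series of the
    nearest V_Dist sample points (linearly interpolated).  The centerline
    starts at the optic-disc center and its total arc length equals one disc
    diameter, so arc position in pixels maps directly to V_Dist in DD.
    The returned binary template covers the fully-shaded vessel core (edge
    pixels are anti-aliased and left out of the template).
    """
    H, W = image_shape
    if H < 2 * margin + 4 or W < 2 * margin + 4:
        raise ConfigurationError(
            f"image_shape {image_shape} too small to contain the vessel"
        )
    series_all, truth = generate_series(config)
    per_run = [
        s for s in series_all
        if s.metadata["eye_id"] == f"E{eye:02d}" and s.metadata["run_id"] == run
    ]
    if not per_run:
        raise ConfigurationError(f"no series for eye {eye}, run {run}")
    timing = CycleTiming(truth.cycle_counts[(eye, run)])
    vpts = truth.v_dist_points
    S = np.stack([s.g for s in per_run])  # (P, M)

    # dense centerline: diagonal with a gentle sinusoidal bow
    s_dense = np.linspace(0.0, 1.0, 600)
    rows_c = margin + s_dense * (H - 2 * margin)
    cols_c = margin + s_dense * (W - 2 * margin) + 4.0 * np.sin(np.pi * s_dense)
    centerline = np.column_stack([rows_c, cols_c])
    seg = np.diff(centerline, axis=0)
    arc = np.concatenate([[0.0], np.cumsum(np.hypot(seg[:, 0], seg[:, 1]))])
    disc_diameter_px = float(arc[-1])  # endpoint sits at V_Dist = 1 DD
    v_of_vertex = arc / disc_diameter_px

    rr, cc = np.meshgrid(np.arange(H), np.arange(W), indexing="ij")
    px = np.column_stack([rr.ravel(), cc.ravel()]).astype(float)
    d2 = ((px[:, None, :] - centerline[None, :, :]) ** 2).sum(axis=2)
    nearest = d2.argmin(axis=1)
    dist = np.sqrt(d2[np.arange(len(px)), nearest]).reshape(H, W)
    v_px = v_of_vertex[nearest].reshape(H, W)

    coverage = np.clip(vessel_half_width + 0.5 - dist, 0.0, 1.0)
    mask = dist <= vessel_half_width - 1.0  # fully covered core

    M = timing.n_frames
    frames = np.empty((M, H, W, 3), dtype=np.uint8)
    for k in range(M):
        vessel_val = np.interp(v_px, vpts, S[:, k]) if len(vpts) > 1 \
            else np.full_like(v_px, S[0, k])
        green = background_green * (1.0 - coverage) + vessel_val * coverage
        red = 190.0 * (1.0 - 0.5 * coverage)
        blue = 70.0 * (1.0 - 0.5 * coverage)
        frames[k, ..., 0] = np.clip(np.round(red), 0, 255)
        frames[k, ..., 1] = np.clip(np.round(green), 0, 255)
        frames[k, ..., 2] = np.clip(np.round(blue), 0, 255)

    seq = FrameSequence(
        frames, frame_rate=config.frame_rate,
        recording_id=f"synthetic_eye{eye}_run{run}",
    )
    template = VesselTemplate(
        mask=mask, label="synthetic_vessel", vessel_type=config.vessel_type
    )
    return RenderedScene(
        frames=seq,
        template=template,
        centerline=centerline,
        timing=timing,
        disc_center=(float(rows_c[0]), float(cols_c[0])),
        disc_diameter_px=disc_diameter_px,
        series=per_run,
        truth=truth,
    )


def series_to_dataframe(series_list) -> pd.DataFrame:
    """Long-format table (one row per sample) of a series collection."""
    parts = []
    for s in series_list:
        df = pd.DataFrame({"t": s.t, "green_mean": s.g})
        for key, val in s.metadata.items():
            df[key] = val
        parts.append(df)
    return pd.concat(parts, ignore_index=True)


def save_scene(scene: RenderedScene, outdir) -> dict:
    """Write a rendered scene to disk (PNG frames, PNG mask, CSVs, JSON).

    Returns the paths written.
    """
    from PIL import Image

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    frame_paths = []
    for k in range(scene.frames.M):
        p = outdir / f"frame_{k:04d}.png"
        Image.fromarray(scene.frames.frames[k]).save(p)
        frame_paths.append(str(p))
    mask_path = outdir / "vessel_mask.png"
    Image.fromarray((scene.template.mask * 255).astype(np.uint8)).save(mask_path)
    centerline_path = outdir / "centerline.csv"
    pd.DataFrame(scene.centerline, columns=["row", "col"]).to_csv(
        centerline_path, index=False
    )
    series_path = outdir / "series.csv"
    series_to_dataframe(scene.series).to_csv(series_path, index=False)
    truth_path = outdir / "ground_truth.json"
    truth = {
        "config": asdict(scene.truth.config),
        "disc_center": list(scene.disc_center),
        "disc_diameter_px": scene.disc_diameter_px,
        "cycle_frame_counts": list(scene.timing.cycle_frame_counts),
        "eye_effects": scene.truth.eye_effects.tolist(),
        "odf_values": scene.truth.odf_values.tolist(),
        "v_dist_points": scene.truth.v_dist_points.tolist(),
    }
    truth_path.write_text(json.dumps(truth, indent=2))
    return {
        "frames": frame_paths,
        "mask": str(mask_path),
        "centerline": str(centerline_path),
        "series": str(series_path),
        "ground_truth": str(truth_path),
    }
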