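"""Image-quality and channel-SNR metrics for beamformed photoacoustic data.

All image metrics operate on the normalized pre-log image (after
normalization, before log compression):

* gCNR = 1 - sum_bins min{p_in, p_out}, the histogram-overlap probability
  of discriminating target from background (256 bins by default).
* Lateral width r_delta = FWHM of the lateral line profile through the
  target center, with sub-pixel interpolation at the half-max crossings.
* Image SNR = mu_in / sigma_out over a target ROI and five independent
  background ROIs (mean +/- std over the five ratios).
* Channel SNR (dB) = 20*log10(rms(signal)/rms(noise)) over entire frames.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from . import beamform as bf
from .simulate import ChannelData

__all__ = [
    "ROISpec",
    "MetricReport",
    "NoTargetError",
    "UnresolvableWidthError",
    "DegenerateBackgroundError",
    "gcnr",
    "locate_target",
    "default_rois",
    "lateral_fwhm",
    "image_snr",
    "channel_snr",
    "add_noise_to_channel",
    "sweep_beamforming_params",
]


class NoTargetError(ValueError):
    """Raised when an all-zero image offers no brightest pixel."""


class UnresolvableWidthError(ValueError):
    """Raised when a line profile never drops below half its maximum."""


class DegenerateBackgroundError(ValueError):
    """Raised when a background ROI has zero standard deviation."""


@dataclass(frozen=True)
class ROISpec:
    """Axis-aligned rectangle in physical coordinates (mm)."""

    center_lateral_mm: float
    center_axial_mm: float
    width_mm: float = 3.0
    height_mm: float = 3.0

    def __post_init__(self) -> None:
        if self.width_mm <= 0 or self.height_mm <= 0:
            raise ValueError("ROI extents must be positive")

    def overlaps(self, other: "ROISpec") -> bool:
        return (
            abs(self.center_lateral_mm - other.center_lateral_mm)
            < (self.width_mm + other.width_mm) / 2
            and abs(self.center_axial_mm - other.center_axial_mm)
            < (self.height_mm + other.height_mm) / 2
        )


@dataclass
class MetricReport:
    """One row of image-quality results for a parameter combination."""

    cumulative_lag: int
    axial_kernel: int
    depth_mm: float
    gcnr: float
    fwhm_mm: float
    snr_mean: float
    snr_std: float
    channel_snr_db: float
    seed: int | None = None


def _roi_values(img: bf.BeamformedImage, roi: ROISpec) -> np.ndarray:
    x = img.lateral_positions_mm
    z = img.axial_positions_mm
    if (
        roi.center_lateral_mm - roi.width_mm / 2 < x[0]
        or roi.center_lateral_mm + roi.width_mm / 2 > x[-1]
        or roi.center_axial_mm - roi.height_mm / 2 < z[0]
        or roi.center_axial_mm + roi.height_mm / 2 > z[-1]
    ):
        raise ValueError(f"ROI {roi} extends outside the image")
    xm = np.abs(x - roi.center_lateral_mm) <= roi.width_mm / 2
    zm = np.abs(z - roi.center_axial_mm) <= roi.height_mm / 2
    return img.values[np.ix_(xm, zm)].ravel()


def gcnr(
    img: bf.BeamformedImage,
    roi_in: ROISpec,
    roi_out: ROISpec,
    bins: int = 256,
) -> float:
    """Generalized contrast-to-noise ratio between two ROIs.

    Histograms share ``bins`` equal-width bins spanning the pooled range of
    both ROIs, so the overlap integral is well defined; the result lies in
    [0, 1] and is invariant to monotonic rescaling applied to both ROIs.
    """
    if roi_in.overlaps(roi_out):
        raise ValueError("inside and outside ROIs overlap")
    vin = _roi_values(img, roi_in)
    vout = _roi_values(img, roi_out)
    lo = min(vin.min(), vout.min())
    hi = max(vin.max(), vout.max())
    if hi == lo:  # all values identical -> identical distributions
        return 0.0
    edges = np.linspace(lo, hi, bins + 1)
    p_in, _ = np.histogram(vin, bins=edges)
    p_out, _ = np.histogram(vout, bins=edges)
    overlap = np.minimum(p_in / vin.size, p_out / vout.size).sum()
    return float(1.0 - overlap)


def locate_target(img: bf.BeamformedImage) -> tuple[float, float]:
    """Brightest-pixel target center (lateral mm, axial mm).

    Ties resolve to the smallest axial, then smallest lateral index.
    """
    vals = img.values
    peak = vals.max(initial=0.0)
    if peak <= 0:
        raise NoTargetError("image is all zero; no target to locate")
    xs, zs = np.nonzero(vals == peak)
    order = np.lexsort((xs, zs))  # axial first, then lateral
    xi, zi = xs[order[0]], zs[order[0]]
    return (
        float(img.lateral_positions_mm[xi]),
        float(zi * img.axial_spacing_mm),
    )


def default_rois(
    target_center: tuple[float, float],
    size_mm: float = 3.0,
    outside_shift_mm: float = 5.0,
) -> tuple[ROISpec, ROISpec]:
    """Inside ROI on the target; outside ROI shifted laterally (same depth)."""
    cx, cz = target_center
    roi_in = ROISpec(cx, cz, size_mm, size_mm)
    roi_out = ROISpec(cx + outside_shift_mm, cz, size_mm, size_mm)
    return roi_in, roi_out


def lateral_fwhm(img: bf.BeamformedImage, target_center: tuple[float, float]) -> float:
    """Full width at half maximum of the lateral profile through the target."""
    zi = int(round(target_center[1] / img.axial_spacing_mm))
    zi = min(max(zi, 0), img.values.shape[1] - 1)
    profile = img.values[:, zi].astype(float)
    x = img.lateral_positions_mm
    pk = int(np.argmax(profile))
    half = profile[pk] / 2.0
    if profile[pk] <= 0:
        raise UnresolvableWidthError("profile has no positive maximum")

    def crossing(direction: int) -> float:
        j = pk
        while 0 <= j + direction < len(profile):
            jn = j + direction
            if profile[jn] < half:
                # interpolate between j (>= half) and jn (< half)
                frac = (profile[j] - half) / (profile[j] - profile[jn])
                return float(x[j] + frac * (x[jn] - x[j]))
            j = jn
        raise UnresolvableWidthError(
            "profile never falls below half max within the image"
        )

    return crossing(+1) - crossing(-1)


def _background_rois(
    target_center: tuple[float, float],
    size_mm: float,
    offsets_mm: Sequence[float],
) -> list[ROISpec]:
    cx, cz = target_center
    return [ROISpec(cx + off, cz, size_mm, size_mm) for off in offsets_mm]


def image_snr(
    img: bf.BeamformedImage,
    target_center: tuple[float, float],
    roi_size_mm: float = 2.5,
    background_offsets_mm: Sequence[float] = (-10.0, -11.25, -12.5, -13.75, -15.0),
) -> tuple[float, float]:
    """SNR = mu_in / sigma_out against five independent background ROIs.

    Returns the mean and standard deviation of the five ratios.  The
    background ROIs sit 10 to 15 mm to the left of the target at the same
    depth by default.
    """
    cx, cz = target_center
    roi_in = ROISpec(cx, cz, roi_size_mm, roi_size_mm)
    mu_in = float(np.mean(_roi_values(img, roi_in)))
    snrs = []
    for roi in _background_rois(target_center, roi_size_mm, background_offsets_mm):
        sigma = float(np.std(_roi_values(img, roi)))
        if sigma == 0.0:
            raise DegenerateBackgroundError(f"zero-variance background ROI {roi}")
        snrs.append(mu_in / sigma)
    return float(np.mean(snrs)), float(np.std(snrs))


def channel_snr(signal: ChannelData | np.ndarray, noise: np.ndarray) -> float:
    """Channel SNR in dB: 20*log10(rms(signal)/rms(noise)).

    The signal is the entire (noise-free) channel-data recording and the
    noise the matrix that was added to it.  Zero noise rms yields +inf.
    """
    sig = signal.samples if isinstance(signal, ChannelData) else np.asarray(signal)
    noise = np.asarray(noise)
    rms_n = np.sqrt(np.mean(noise**2))
    rms_s = np.sqrt(np.mean(sig**2))
    if rms_n == 0.0:
        return math.inf
    if rms_s == 0.0:
        return -math.inf
    return 20.0 * math.log10(rms_s / rms_n)


def add_noise_to_channel(
    frame: ChannelData, target_snr_db: float, seed: int
) -> tuple[ChannelData, np.ndarray]:
    """Add Gaussian noise so the channel SNR equals the target exactly.

    Emulates decreasing the laser energy by corrupting the raw channel
    data.  Returns the noisy frame and the noise matrix itself.
    """
    rms_sig = np.sqrt(np.mean(frame.samples**2))
    if rms_sig == 0.0:
        raise ValueError("cannot set a channel SNR on an all-zero frame")
    rng = np.random.default_rng(seed)
    noise = rng.standard_normal(frame.samples.shape)
    noise *= rms_sig * 10.0 ** (-target_snr_db / 20.0) / np.sqrt(np.mean(noise**2))
    noisy = ChannelData(
        samples=frame.samples + noise,
        geometry=frame.geometry,
        depth_mm=frame.depth_mm,
        frame_index=frame.frame_index,
        source=frame.source,
    )
    return noisy, noise


def sweep_beamforming_params(
    frame: ChannelData,
    m_values: Sequence[int] = (5, 10, 15, 20, 25, 30, 35),
    k_values: Sequence[int] = (3, 11, 19, 31),
    num_scanlines: int | None = None,
    filt: bf.FilterSpec | None = None,
    channel_snr_db: float = math.nan,
    seed: int | None = None,
    with_image_snr: bool = False,
    target_center: tuple[float, float] | None = None,
) -> pd.DataFrame:
    """Full-factorial (M, k) image-quality sweep on one channel-data frame.

    For each axial kernel the per-lag coherence terms are accumulated once,
    so the sweep costs four SLSC evaluations at the largest M rather than
    28.  Emits one row per (M, k) with gCNR and lateral FWHM (and image SNR
    when the background ROIs fit in the image).

    ``target_center`` fixes the target position (e.g., the simulation
    ground truth); when omitted, each image's brightest pixel is used.  In
    strictly noise-free simulations the brightest SLSC pixel can fall on a
    coherence ghost rather than the source, so supplying the ground truth
    is recommended there.
    """
    filtered = bf.remove_dc(frame, filt)
    analytic = bf.analytic_signal(filtered)
    table = bf.compute_receive_delays(
        frame.geometry, frame.num_axial_samples, num_scanlines
    )
    cube = bf.apply_delays(analytic, table)
    rows = []
    for k in k_values:
        images = bf.slsc_images(cube, m_values, k)
        for m in m_values:
            norm = bf.normalize(images[m])
            center = target_center if target_center is not None else locate_target(norm)
            roi_in, roi_out = default_rois(center)
            row = MetricReport(
                cumulative_lag=m,
                axial_kernel=k,
                depth_mm=frame.depth_mm,
                gcnr=gcnr(norm, roi_in, roi_out),
                fwhm_mm=lateral_fwhm(norm, center),
                snr_mean=math.nan,
                snr_std=math.nan,
                channel_snr_db=channel_snr_db,
                seed=seed,
            )
            if with_image_snr:
                row.snr_mean, row.snr_std = image_snr(norm, center)
            rows.append(row)
    df = pd.DataFrame(
        [
            {
                "M": r.cumulative_lag,
                "k": r.axial_kernel,
                "d_mm": r.depth_mm,
                "gCNR": r.gcnr,
                "fwhm_mm": r.fwhm_mm,
                "snr_mean": r.snr_mean,
                "snr_std": r.snr_std,
                "snrc_db": r.channel_snr_db,
                "seed": r.seed,
            }
            for r in rows
        ]
    )
    return df
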