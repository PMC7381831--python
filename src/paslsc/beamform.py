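"""Photoacoustic receive beamforming: DAS and short-lag spatial coherence.

The processing chain mirrors a real-time scanner workflow: channel
regrouping, DC removal by axial FIR high-pass filtering, analytic-signal
(Hilbert) transform, synthetic receive-aperture delays with 2-D linear
interpolation, then either delay-and-sum (DAS) envelope detection or the
short-lag spatial coherence (SLSC) ensemble correlation, followed by
normalization and log compression for display.

SLSC images the normalized spatial correlation of the delayed aperture
signals rather than their amplitude.  Per lag ``m`` the ensemble coherence
factors are

    Cij(z,x,m) = sum_{i=1}^{Ni-m} s_i(z,x) * conj(s_{i+m}(z,x))
    Cii(z,x,m) = sum_{i=1}^{Ni-m} |s_i(z,x)|^2
    Cjj(z,x,m) = sum_{i=1}^{Ni-m} |s_{i+m}(z,x)|^2

and the image compounds them over an axial kernel of ``k`` samples and the
first ``M`` lags:

    SLSC(z,x) = sum_{m=1}^{M} Re{ sum_k Cij } / sqrt( sum_k Cii * sum_k Cjj )

with negative values clipped to zero.  Each per-lag term is a correlation
coefficient in [-1, 1] (Cauchy-Schwarz), so the pre-clip image lies in
[-M, M] and equals M at a perfectly coherent pixel.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from scipy.ndimage import convolve1d
from scipy.signal import firwin, hilbert

from .simulate import ArrayGeometry, ChannelData

__all__ = [
    "FilterSpec",
    "SLSCParams",
    "DelayTable",
    "ApertureDataCube",
    "CoherenceFactors",
    "BeamformedImage",
    "DisplayImage",
    "default_highpass",
    "regroup_channels",
    "remove_dc",
    "analytic_signal",
    "compute_receive_delays",
    "apply_delays",
    "das_beamform",
    "slsc_coherence",
    "slsc_image",
    "slsc_images",
    "normalize",
    "normalize_log_compress",
    "beamform_frame",
]

#: Pixels whose auto-coherence sum falls below this fraction of the image's
#: maximum auto-coherence yield 0 instead of NaN.  The guard is relative so
#: that SLSC stays exactly invariant under amplitude rescaling.
DENOMINATOR_GUARD = 1e-30


@dataclass(frozen=True)
class FilterSpec:
    """Linear-phase FIR high-pass used for DC removal along the axial axis."""

    coefficients: np.ndarray
    cutoff_mhz: float | None = None

    def __post_init__(self) -> None:
        coeff = np.asarray(self.coefficients, dtype=np.float64)
        object.__setattr__(self, "coefficients", coeff)
        if coeff.ndim != 1 or coeff.size % 2 == 0:
            raise ValueError("filter must be a 1-D odd-length vector")
        if not (
            np.allclose(coeff, coeff[::-1]) or np.allclose(coeff, -coeff[::-1])
        ):
            raise ValueError("filter must be linear phase (symmetric coefficients)")
        if abs(coeff.sum()) > 1e-3:
            raise ValueError("filter DC gain exceeds 1e-3")

    @property
    def num_taps(self) -> int:
        return self.coefficients.size


def default_highpass(
    sampling_frequency_mhz: float = 40.0,
    cutoff_mhz: float = 0.5,
    num_taps: int = 33,
) -> FilterSpec:
    """Windowed-sinc high-pass (Hamming), zero gain at DC."""
    coeff = firwin(
        num_taps, cutoff_mhz, fs=sampling_frequency_mhz, pass_zero=False
    )
    # firwin scales for unit Nyquist gain; null the residual DC leakage
    # exactly so a constant column is rejected to machine precision.
    coeff = coeff - coeff.sum() / num_taps
    return FilterSpec(coefficients=coeff, cutoff_mhz=cutoff_mhz)


@dataclass(frozen=True)
class SLSCParams:
    """Cumulative lag M, odd axial kernel k, and scanline count Nx."""

    cumulative_lag: int = 25
    axial_kernel: int = 11
    num_scanlines: int | None = None  # None -> one line per element

    def __post_init__(self) -> None:
        if self.cumulative_lag < 1:
            raise ValueError("cumulative lag M must be >= 1")
        if self.axial_kernel < 1 or self.axial_kernel % 2 == 0:
            raise ValueError("axial kernel k must be odd and >= 1")
        if self.num_scanlines is not None and self.num_scanlines < 1:
            raise ValueError("num_scanlines must be >= 1")


@dataclass
class DelayTable:
    """Receive delays in fractional samples, shape (element, scanline, axial)."""

    delays: np.ndarray
    scanline_positions_mm: np.ndarray
    geometry: ArrayGeometry


@dataclass
class ApertureDataCube:
    """Delayed analytic signals s_i(z, x), shape (element, scanline, axial)."""

    values: np.ndarray
    scanline_positions_mm: np.ndarray
    geometry: ArrayGeometry

    @property
    def num_elements(self) -> int:
        return self.values.shape[0]


@dataclass
class CoherenceFactors:
    """Ensemble sums Cij, Cii, Cjj at one lag, each shape (scanline, axial)."""

    cij: np.ndarray
    cii: np.ndarray
    cjj: np.ndarray
    lag: int


@dataclass
class BeamformedImage:
    """Nonnegative pre-log image, shape (scanline, axial), physical spacing."""

    values: np.ndarray
    lateral_positions_mm: np.ndarray
    axial_spacing_mm: float
    normalized: bool = False
    method: str = ""

    @property
    def lateral_spacing_mm(self) -> float:
        x = self.lateral_positions_mm
        return float(x[1] - x[0]) if len(x) > 1 else 0.0

    @property
    def axial_positions_mm(self) -> np.ndarray:
        return np.arange(self.values.shape[1]) * self.axial_spacing_mm


@dataclass
class DisplayImage:
    """Log-compressed image in dB, values in [-dynamic_range, 0]."""

    values_db: np.ndarray
    dynamic_range_db: float
    lateral_positions_mm: np.ndarray
    axial_spacing_mm: float


def regroup_channels(acquisitions: Sequence[np.ndarray], num_elements: int) -> np.ndarray:
    """Concatenate Nc-channel acquisition blocks into one Ni-element frame.

    The number of acquisitions is the integer NA = Ni/Nc; blocks are joined
    along the element axis in acquisition order.  Each block is (axial, Nc).
    """
    if not acquisitions:
        raise ValueError("no acquisition blocks given")
    blocks = [np.asarray(b) for b in acquisitions]
    nc = blocks[0].shape[1]
    if num_elements % nc != 0:
        raise ValueError(f"Ni={num_elements} is not divisible by Nc={nc}")
    na = num_elements // nc
    if len(blocks) != na:
        raise ValueError(f"expected NA={na} blocks, got {len(blocks)}")
    if any(b.shape != blocks[0].shape for b in blocks):
        raise ValueError("acquisition blocks must share one shape")
    return np.concatenate(blocks, axis=1)


def remove_dc(frame: ChannelData, filt: FilterSpec | None = None) -> ChannelData:
    """High-pass filter each element column axially (same-length, zero-padded)."""
    if filt is None:
        filt = default_highpass(frame.geometry.sampling_frequency_mhz)
    if filt.num_taps >= frame.num_axial_samples:
        raise ValueError("filter longer than the axial recording")
    out = convolve1d(
        frame.samples, filt.coefficients, axis=0, mode="constant", cval=0.0
    )
    return ChannelData(
        samples=out,
        geometry=frame.geometry,
        depth_mm=frame.depth_mm,
        frame_index=frame.frame_index,
        source=frame.source,
    )


def analytic_signal(frame: ChannelData | np.ndarray) -> np.ndarray:
    """Discrete analytic signal of each element column (FFT Hilbert transform)."""
    data = frame.samples if isinstance(frame, ChannelData) else np.asarray(frame)
    if data.shape[0] < 2:
        raise ValueError("need at least 2 axial samples")
    return hilbert(data, axis=0)


def scanline_positions(geometry: ArrayGeometry, num_scanlines: int | None = None) -> np.ndarray:
    """Scanline lateral positions; at line density 1 they coincide with elements."""
    nx = geometry.num_elements if num_scanlines is None else num_scanlines
    spacing = geometry.num_elements * geometry.pitch_mm / nx
    return (np.arange(nx) - (nx - 1) / 2) * spacing


def compute_receive_delays(
    geometry: ArrayGeometry,
    num_axial_samples: int,
    num_scanlines: int | None = None,
) -> DelayTable:
    """One-way synthetic receive-aperture delays in fractional samples.

    delay(i, l, t) = sqrt(z_t^2 + (x_l - x_i)^2) / c * fs  with z_t = c*t/fs,
    i.e. hypot(t, lateral_offset_in_samples); always >= t.
    """
    if num_axial_samples <= 0:
        raise ValueError("number of axial samples must be positive")
    lines = scanline_positions(geometry, num_scanlines)
    dz = geometry.axial_spacing_mm
    dx_samples = (lines[None, :] - geometry.element_positions_mm[:, None]) / dz
    t = np.arange(num_axial_samples, dtype=np.float64)
    delays = np.hypot(t[None, None, :], dx_samples[:, :, None])
    return DelayTable(delays=delays, scanline_positions_mm=lines, geometry=geometry)


def apply_delays(analytic: np.ndarray, table: DelayTable) -> ApertureDataCube:
    """Sample each element's analytic signal at its fractional receive delay.

    2-D linear interpolation along the axial axis; delays that need data
    beyond the recording yield 0.
    """
    analytic = np.asarray(analytic)
    nz, ni = analytic.shape
    if table.delays.shape[0] != ni:
        raise ValueError("delay table and data disagree on element count")
    if not np.all(np.isfinite(table.delays)):
        raise ValueError("delays must be finite")
    nx = table.delays.shape[1]
    cube = np.empty((ni, nx, table.delays.shape[2]), dtype=analytic.dtype)
    for i in range(ni):  # per element keeps the temporaries small
        d = table.delays[i]
        i0 = np.clip(np.floor(d).astype(np.intp), 0, nz - 2)
        w = d - i0
        col = analytic[:, i]
        vals = col[i0] * (1.0 - w) + col[i0 + 1] * w
        cube[i] = np.where((d >= 0) & (d <= nz - 1), vals, 0)
    return ApertureDataCube(
        values=cube,
        scanline_positions_mm=table.scanline_positions_mm,
        geometry=table.geometry,
    )


def das_beamform(cube: ApertureDataCube) -> BeamformedImage:
    """Delay-and-sum: envelope (magnitude) of the coherent element sum."""
    img = np.abs(cube.values.sum(axis=0))
    return BeamformedImage(
        values=img,
        lateral_positions_mm=cube.scanline_positions_mm,
        axial_spacing_mm=cube.geometry.axial_spacing_mm,
        method="das",
    )


def slsc_coherence(cube: ApertureDataCube, lag: int) -> CoherenceFactors:
    """Ensemble coherence factors at one lag, summed over the first Ni-m pairs."""
    ni = cube.num_elements
    if not 1 <= lag <= ni - 1:
        raise ValueError(f"lag must be in [1, {ni - 1}]")
    a = cube.values[: ni - lag]
    b = cube.values[lag:]
    cij = np.sum(a * np.conj(b), axis=0)
    cii = np.sum(np.abs(a) ** 2, axis=0)
    cjj = np.sum(np.abs(b) ** 2, axis=0)
    return CoherenceFactors(cij=cij, cii=cii, cjj=cjj, lag=lag)


def _axial_sum(arr: np.ndarray, k: int) -> np.ndarray:
    """Sum over a k-sample axial window, truncated at the image edges."""
    if k == 1:
        return arr
    if np.iscomplexobj(arr):
        return _axial_sum(arr.real, k) + 1j * _axial_sum(arr.imag, k)
    return convolve1d(arr, np.ones(k), axis=-1, mode="constant", cval=0.0)


def _lag_term(cf: CoherenceFactors, k: int) -> np.ndarray:
    """Axially compounded correlation coefficient for one lag."""
    num = _axial_sum(cf.cij, k).real
    sii = _axial_sum(cf.cii, k)
    sjj = _axial_sum(cf.cjj, k)
    guard = (sii <= DENOMINATOR_GUARD * sii.max(initial=0.0)) | (
        sjj <= DENOMINATOR_GUARD * sjj.max(initial=0.0)
    )
    den = np.where(guard, 1.0, np.sqrt(sii * sjj))
    return np.where(guard, 0.0, num / den)


def slsc_image(
    cube: ApertureDataCube, params: SLSCParams, clip_negative: bool = True
) -> BeamformedImage:
    """Short-lag spatial coherence image, compounded over k samples and M lags."""
    ni = cube.num_elements
    if params.cumulative_lag > ni - 1:
        raise ValueError("cumulative lag M must be <= Ni - 1")
    acc = np.zeros(cube.values.shape[1:], dtype=np.float64)
    for m in range(1, params.cumulative_lag + 1):
        acc += _lag_term(slsc_coherence(cube, m), params.axial_kernel)
    if clip_negative:
        acc = np.maximum(acc, 0.0)
    return BeamformedImage(
        values=acc,
        lateral_positions_mm=cube.scanline_positions_mm,
        axial_spacing_mm=cube.geometry.axial_spacing_mm,
        method="slsc",
    )


def slsc_images(
    cube: ApertureDataCube, m_values: Iterable[int], axial_kernel: int
) -> dict[int, BeamformedImage]:
    """SLSC images for several cumulative lags M sharing one axial kernel.

    The per-lag terms are accumulated once up to max(M), so a full M-sweep
    costs the same as a single image at the largest M.
    """
    m_values = sorted(set(int(m) for m in m_values))
    ni = cube.num_elements
    if m_values[0] < 1 or m_values[-1] > ni - 1:
        raise ValueError("all M must be in [1, Ni - 1]")
    out: dict[int, BeamformedImage] = {}
    acc = np.zeros(cube.values.shape[1:], dtype=np.float64)
    targets = set(m_values)
    for m in range(1, m_values[-1] + 1):
        acc += _lag_term(slsc_coherence(cube, m), axial_kernel)
        if m in targets:
            out[m] = BeamformedImage(
                values=np.maximum(acc, 0.0),
                lateral_positions_mm=cube.scanline_positions_mm,
                axial_spacing_mm=cube.geometry.axial_spacing_mm,
                method="slsc",
            )
    return out


def normalize(img: BeamformedImage) -> BeamformedImage:
    """Scale to unit maximum (all-zero images pass through unchanged)."""
    peak = float(img.values.max(initial=0.0))
    vals = img.values / peak if peak > 0 else img.values.copy()
    return BeamformedImage(
        values=vals,
        lateral_positions_mm=img.lateral_positions_mm,
        axial_spacing_mm=img.axial_spacing_mm,
        normalized=True,
        method=img.method,
    )


def normalize_log_compress(
    img: BeamformedImage, dynamic_range_db: float = 15.0
) -> DisplayImage:
    """Normalize by the global maximum and log-compress to [-DR, 0] dB."""
    if dynamic_range_db <= 0:
        raise ValueError("dynamic range must be positive")
    peak = float(img.values.max(initial=0.0))
    if peak <= 0:
        db = np.full_like(img.values, -dynamic_range_db, dtype=np.float64)
    else:
        with np.errstate(divide="ignore"):
            db = 20.0 * np.log10(img.values / peak)
        db = np.maximum(db, -dynamic_range_db)
    return DisplayImage(
        values_db=db,
        dynamic_range_db=dynamic_range_db,
        lateral_positions_mm=img.lateral_positions_mm,
        axial_spacing_mm=img.axial_spacing_mm,
    )


def beamform_frame(
    frame: ChannelData,
    method: str = "slsc",
    params: SLSCParams | None = None,
    filt: FilterSpec | None = None,
    dynamic_range_db: float = 15.0,
    delay_table: DelayTable | None = None,
) -> tuple[BeamformedImage, DisplayImage]:
    """Full pipeline: DC removal -> Hilbert -> delays -> DAS/SLSC -> display.

    Returns the normalized pre-log image (the input to all image-quality
    metrics and to segmentation) and the log-compressed display image.
    A precomputed ``delay_table`` may be reused across frames that share
    geometry and depth.
    """
    if method not in ("das", "slsc"):
        raise ValueError(f"unknown beamforming method {method!r}")
    params = params or SLSCParams()
    filtered = remove_dc(frame, filt)
    analytic = analytic_signal(filtered)
    if delay_table is None:
        delay_table = compute_receive_delays(
            frame.geometry, frame.num_axial_samples, params.num_scanlines
        )
    cube = apply_delays(analytic, delay_table)
    if method == "das":
        img = das_beamform(cube)
    else:
        img = slsc_image(cube, params)
    norm = normalize(img)
    disp = normalize_log_compress(img, dynamic_range_db)
    return norm, disp
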