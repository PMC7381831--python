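"""Synthetic photoacoustic channel data for a linear receive array.

A photoacoustic point source (e.g., the tip of an optical fiber) emits a
single bandlimited acoustic pulse that propagates one way to every element
of a linear ultrasound array.  Element ``i`` therefore records a copy of
the shared pulse delayed by the geometric time of flight

    t_i = sqrt((x_s - x_i)^2 + s^2) / c,

where ``(x_s, s)`` is the source position and ``c`` the sound speed.  The
received wavefront is perfectly coherent across the aperture; incoherent
channel noise is modeled as i.i.d. zero-mean Gaussian samples scaled to a
requested channel SNR, defined as 20*log10(rms(signal)/rms(noise)) over
the entire frame.

Frame sequences with a laterally moving source emulate the probe-centering
and fiber-tracking scenarios used to exercise visual servoing.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from scipy.signal import gausspulse

__all__ = [
    "ArrayGeometry",
    "SourceSpec",
    "ChannelData",
    "Trajectory",
    "simulate_channel_data",
    "coherent_aperture_cube",
    "make_trajectory",
    "simulate_sequence",
]


@dataclass(frozen=True)
class ArrayGeometry:
    """Linear receive array plus the acquisition clock.

    Elements are centered on lateral position 0 with uniform pitch:
    ``x_i = (i - (Ni-1)/2) * pitch``.  Lengths are millimetres, times
    microseconds, frequencies MHz; ``sound_speed`` is accepted in m/s
    (the customary unit) and converted internally to mm/us.
    """

    num_elements: int = 128
    pitch_mm: float = 0.3
    sampling_frequency_mhz: float = 40.0
    sound_speed_m_s: float = 1540.0
    center_frequency_mhz: float = 5.0
    fractional_bandwidth: float = 0.6

    def __post_init__(self) -> None:
        if self.num_elements < 2:
            raise ValueError("num_elements must be >= 2")
        if self.pitch_mm <= 0:
            raise ValueError("pitch_mm must be positive")
        f_max = self.center_frequency_mhz * (1 + self.fractional_bandwidth / 2)
        if self.sampling_frequency_mhz <= 2 * f_max:
            raise ValueError(
                f"sampling frequency {self.sampling_frequency_mhz} MHz violates "
                f"Nyquist for pulse extending to {f_max} MHz"
            )

    @property
    def sound_speed_mm_us(self) -> float:
        return self.sound_speed_m_s / 1000.0

    @property
    def element_positions_mm(self) -> np.ndarray:
        n = self.num_elements
        return (np.arange(n) - (n - 1) / 2) * self.pitch_mm

    @property
    def axial_spacing_mm(self) -> float:
        """Depth increment per sample, z = c*t/fs (one-way mapping)."""
        return self.sound_speed_mm_us / self.sampling_frequency_mhz


@dataclass(frozen=True)
class SourceSpec:
    """A photoacoustic point source at lateral ``x_mm``, depth ``depth_mm``."""

    x_mm: float = 0.0
    depth_mm: float = 40.0
    amplitude: float = 1.0
    pulse: str = "gaussian"  # gaussian-modulated sinusoid | "nshape"

    def __post_init__(self) -> None:
        if self.depth_mm <= 0:
            raise ValueError("source depth must be positive")
        if self.amplitude < 0:
            raise ValueError("amplitude must be >= 0")
        if self.pulse not in ("gaussian", "nshape"):
            raise ValueError(f"unknown pulse model {self.pulse!r}")


@dataclass
class ChannelData:
    """One frame of raw RF channel data, ``samples[axial, element]``."""

    samples: np.ndarray
    geometry: ArrayGeometry
    depth_mm: float
    frame_index: int = 0
    source: SourceSpec | None = None

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=np.float64)
        if self.samples.ndim != 2:
            raise ValueError("samples must be a 2-D (axial x element) matrix")
        if self.samples.shape[1] != self.geometry.num_elements:
            raise ValueError(
                f"samples have {self.samples.shape[1]} columns, geometry has "
                f"{self.geometry.num_elements} elements"
            )
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("samples must be finite")

    @property
    def num_axial_samples(self) -> int:
        return self.samples.shape[0]


@dataclass(frozen=True)
class Trajectory:
    """Lateral source path sampled at the laser pulse-repetition clock."""

    kind: str
    times_s: np.ndarray
    positions_mm: np.ndarray
    frame_interval_s: float

    def __post_init__(self) -> None:
        object.__setattr__(self, "times_s", np.asarray(self.times_s, dtype=float))
        object.__setattr__(
            self, "positions_mm", np.asarray(self.positions_mm, dtype=float)
        )
        if self.frame_interval_s <= 0:
            raise ValueError("frame interval must be positive")
        if len(self.times_s) != len(self.positions_mm):
            raise ValueError("times and positions must have equal length")
        if len(self.times_s) > 1 and not np.all(np.diff(self.times_s) > 0):
            raise ValueError("times must be strictly increasing")

    def __len__(self) -> int:
        return len(self.times_s)


def _pulse_waveform(t_us: np.ndarray, geometry: ArrayGeometry, model: str) -> np.ndarray:
    """Evaluate the shared acoustic pulse at (possibly fractional) times."""
    if model == "gaussian":
        return gausspulse(
            t_us,
            fc=geometry.center_frequency_mhz,
            bw=geometry.fractional_bandwidth,
        )
    # N-shaped wave of one carrier period: linear down-ramp with sharp edges.
    period = 1.0 / geometry.center_frequency_mhz
    half = period / 2
    out = np.where(np.abs(t_us) <= half, -t_us / half, 0.0)
    return out


def num_axial_samples(geometry: ArrayGeometry, depth_mm: float) -> int:
    """Nz = round(d / (c/fs)) under the one-way depth mapping z = c*t."""
    return int(round(depth_mm / geometry.axial_spacing_mm))


def simulate_channel_data(
    geometry: ArrayGeometry,
    source: SourceSpec,
    depth_mm: float,
    noise_snr_db: float | None = None,
    seed: int | None = None,
    spherical_spreading: bool = False,
) -> ChannelData:
    """Simulate one frame of point-source photoacoustic channel data.

    Element ``i`` receives the shared pulse delayed by its one-way time of
    flight; the waveform is identical across elements up to the delay and,
    optionally, 1/r spherical-spreading decay (referenced to the source
    depth so the on-axis amplitude is unchanged).  If ``noise_snr_db`` is
    given, i.i.d. Gaussian noise is added and rescaled so the channel SNR
    (20*log10 rms ratio over the whole frame) matches it exactly.

    Raises
    ------
    ValueError
        If the source lies outside the field of view (laterally beyond the
        aperture or deeper than the imaging depth), or noise is requested
        without a seed.
    """
    if source.depth_mm >= depth_mm:
        raise ValueError("source depth must be shallower than the imaging depth")
    x = geometry.element_positions_mm
    if not (x[0] <= source.x_mm <= x[-1]):
        raise ValueError("source lies laterally outside the array aperture")
    if noise_snr_db is not None and seed is None:
        raise ValueError("a seed is required when noise is requested")

    nz = num_axial_samples(geometry, depth_mm)
    fs = geometry.sampling_frequency_mhz
    c = geometry.sound_speed_mm_us
    t = np.arange(nz) / fs  # us
    r = np.hypot(source.x_mm - x, source.depth_mm)  # mm, per element
    tof = r / c  # us

    if source.amplitude == 0.0:
        samples = np.zeros((nz, geometry.num_elements))
    else:
        samples = source.amplitude * _pulse_waveform(
            t[:, None] - tof[None, :], geometry, source.pulse
        )
        if spherical_spreading:
            samples = samples * (source.depth_mm / r)[None, :]

    if noise_snr_db is not None:
        rms_sig = np.sqrt(np.mean(samples**2))
        if rms_sig == 0.0:
            raise ValueError("channel SNR is undefined for an all-zero signal")
        rng = np.random.default_rng(seed)
        noise = rng.standard_normal(samples.shape)
        target_rms = rms_sig * 10.0 ** (-noise_snr_db / 20.0)
        noise *= target_rms / np.sqrt(np.mean(noise**2))
        samples = samples + noise

    return ChannelData(samples=samples, geometry=geometry, depth_mm=depth_mm, source=source)


def coherent_aperture_cube(
    geometry: ArrayGeometry,
    source: SourceSpec,
    depth_mm: float,
    num_scanlines: int | None = None,
) -> np.ndarray:
    """Aperture data cube of a point source in its exact coherent limit.

    Returns the complex (element x scanline x axial) cube obtained when the
    receive delays cancel the arrival times exactly (no interpolation
    error): every element carries the identical delayed analytic pulse,
    placed on the scanline and axial sample nearest the source.  This is
    the reference input for coherence-limit checks, where the normalized
    per-lag coherence at the source pixel equals 1 by construction.
    """
    nz = num_axial_samples(geometry, depth_mm)
    nx = geometry.num_elements if num_scanlines is None else num_scanlines
    fs = geometry.sampling_frequency_mhz
    t = np.arange(nz) / fs
    t0 = source.depth_mm / geometry.sound_speed_mm_us
    env = gausspulse(
        t - t0,
        fc=geometry.center_frequency_mhz,
        bw=geometry.fractional_bandwidth,
        retenv=True,
    )[1]
    carrier = np.exp(2j * np.pi * geometry.center_frequency_mhz * (t - t0))
    pulse = source.amplitude * env * carrier
    spacing = geometry.num_elements * geometry.pitch_mm / nx
    lines = (np.arange(nx) - (nx - 1) / 2) * spacing
    line = int(np.argmin(np.abs(lines - source.x_mm)))
    cube = np.zeros((geometry.num_elements, nx, nz), dtype=complex)
    cube[:, line, :] = pulse[None, :]
    return cube


def make_trajectory(
    kind: str,
    prf_hz: float,
    offset_mm: float = 6.0,
    distance_mm: float = 10.0,
    duration_s: float | None = None,
    start_mm: float = 0.0,
) -> Trajectory:
    """Build a probe-centering or fiber-tracking source trajectory.

    ``centering`` holds the source at a constant lateral offset (default
    6 mm) from the image center; ``tracking`` ramps the source linearly
    over ``distance_mm`` (default 10 mm) across the captured duration.
    The frame interval is the laser pulse repetition period ``1/prf_hz``.
    """
    if prf_hz <= 0:
        raise ValueError("prf must be positive")
    if kind == "centering":
        duration = 20.0 if duration_s is None else duration_s
    elif kind == "tracking":
        duration = 40.0 if duration_s is None else duration_s
    else:
        raise ValueError(f"unknown trajectory kind {kind!r}")
    n = max(1, int(round(duration * prf_hz)))
    times = np.arange(n) / prf_hz
    if kind == "centering":
        positions = np.full(n, start_mm + offset_mm)
    else:
        positions = start_mm + np.linspace(0.0, distance_mm, n)
    return Trajectory(
        kind=kind, times_s=times, positions_mm=positions, frame_interval_s=1.0 / prf_hz
    )


def simulate_sequence(
    geometry: ArrayGeometry,
    trajectory: Trajectory,
    source: SourceSpec,
    depth_mm: float,
    noise_snr_db: float | None = None,
    seed: int | None = None,
) -> list[ChannelData]:
    """One frame per trajectory point; fresh seeded noise draw per frame."""
    if len(trajectory) == 0:
        raise ValueError("trajectory is empty")
    if noise_snr_db is not None and seed is None:
        raise ValueError("a seed is required when noise is requested")
    if seed is not None:
        frame_seeds = np.random.SeedSequence(seed).spawn(len(trajectory))
    else:
        frame_seeds = [None] * len(trajectory)
    frames = []
    for idx, (pos, fseed) in enumerate(zip(trajectory.positions_mm, frame_seeds)):
        frame = simulate_channel_data(
            geometry,
            replace(source, x_mm=float(pos)),
            depth_mm,
            noise_snr_db=noise_snr_db,
            seed=None if fseed is None else fseed.generate_state(1)[0],
        )
        frame.frame_index = idx
        frames.append(frame)
    return frames
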