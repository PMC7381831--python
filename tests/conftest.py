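import numpy as np
import pytest

import paslsc as P


@pytest.fixture(scope="session")
def small_geometry() -> P.ArrayGeometry:
    """Compact linear array used for end-to-end experiments in the suite.

    48 elements at 0.3 mm pitch keep a full simulate -> beamform ->
    segment frame fast; 40 MHz sampling (8 samples per carrier cycle)
    preserves the delay-interpolation fidelity the coherence beamformer
    relies on.
    """
    return P.ArrayGeometry(
        num_elements=48,
        pitch_mm=0.3,
        sampling_frequency_mhz=40.0,
        sound_speed_m_s=1540.0,
        center_frequency_mhz=5.0,
        fractional_bandwidth=0.6,
    )


@pytest.fixture(scope="session")
def on_grid_source(small_geometry) -> P.SourceSpec:
    """Point source placed exactly on a scanline lateral position."""
    lines = P.beamform.scanline_positions(small_geometry)
    x = float(lines[len(lines) // 2])  # 0.15 mm for an even element count
    return P.SourceSpec(x_mm=x, depth_mm=22.0, amplitude=1.0)


@pytest.fixture(scope="session")
def depth_mm() -> float:
    return 30.0


@pytest.fixture(scope="session")
def point_frame(small_geometry, on_grid_source, depth_mm) -> P.ChannelData:
    """One noiseless point-source frame."""
    return P.simulate_channel_data(small_geometry, on_grid_source, depth_mm)


@pytest.fixture(scope="session")
def aperture_cube(small_geometry, point_frame):
    """Delayed analytic-signal cube of the noiseless point-source frame."""
    filt = P.default_highpass(small_geometry.sampling_frequency_mhz)
    analytic = P.analytic_signal(P.remove_dc(point_frame, filt))
    table = P.compute_receive_delays(small_geometry, point_frame.num_axial_samples)
    return P.apply_delays(analytic, table)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(2024)


def random_cube(
    rng: np.random.Generator,
    num_elements: int = 8,
    num_scanlines: int = 4,
    num_samples: int = 64,
    geometry: P.ArrayGeometry | None = None,
) -> P.ApertureDataCube:
    """Seeded random complex aperture cube for oracle comparisons."""
    geometry = geometry or P.ArrayGeometry(
        num_elements=num_elements, pitch_mm=0.3, sampling_frequency_mhz=40.0
    )
    vals = rng.standard_normal(
        (num_elements, num_scanlines, num_samples)
    ) + 1j * rng.standard_normal((num_elements, num_scanlines, num_samples))
    lines = P.beamform.scanline_positions(geometry, num_scanlines)
    return P.ApertureDataCube(
        values=vals, scanline_positions_mm=lines, geometry=geometry
    )


def naive_slsc(values: np.ndarray, m_max: int, k: int) -> np.ndarray:
    """Literal triple-loop SLSC reference: ensemble coherence factors per
    lag, compounded over a truncated axial window of k samples and the
    first M lags, with negative values clipped to zero."""
    ni, nx, nz = values.shape
    out = np.zeros((nx, nz))
    half = k // 2
    for x in range(nx):
        for z in range(nz):
            lo, hi = max(0, z - half), min(nz, z + half + 1)
            total = 0.0
            for m in range(1, m_max + 1):
                cij = 0.0 + 0.0j
                cii = 0.0
                cjj = 0.0
                for zz in range(lo, hi):
                    for i in range(ni - m):
                        si = values[i, x, zz]
                        sj = values[i + m, x, zz]
                        cij += si * np.conj(sj)
                        cii += abs(si) ** 2
                        cjj += abs(sj) ** 2
                den = np.sqrt(cii * cjj)
                if den > 1e-30:
                    total += cij.real / den
            out[x, z] = max(total, 0.0)
    return out
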