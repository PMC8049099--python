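"""Time/frequency grids for FID signals.

A single :class:`SpectralAxis` is shared by every signal in a study: it fixes
the number of FID samples, the spectral bandwidth (hence the dwell time), the
spectrometer frequency used for ppm <-> Hz conversion and the ppm value of the
rotating-frame reference (water).

Sign convention (used everywhere in the package): increasing chemical shift
(ppm) maps to increasing frequency offset in Hz relative to the reference,

    f_hz = (ppm - ref_ppm) * field_mhz.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["SpectralAxis"]


@dataclass(frozen=True)
class SpectralAxis:
    """Shared time/frequency grid of a spectroscopic acquisition.

    Parameters
    ----------
    n_points:
        Number of complex FID samples ``T``.
    bandwidth:
        Spectral bandwidth in Hz; the dwell time is ``1 / bandwidth``.
    field_mhz:
        Spectrometer frequency in MHz (e.g. ~127.7 at 3 T for protons);
        scales the ppm <-> Hz conversion.
    ref_ppm:
        Chemical shift assigned to 0 Hz offset (water, 4.7 ppm).
    """

    n_points: int = 512
    bandwidth: float = 2000.0
    field_mhz: float = 127.7
    ref_ppm: float = 4.7

    def __post_init__(self) -> None:
        if self.n_points < 1:
            raise ValueError("n_points must be a positive integer")
        if self.bandwidth <= 0:
            raise ValueError("bandwidth must be positive")
        if self.field_mhz <= 0:
            raise ValueError("field_mhz must be positive")

    @property
    def dwell(self) -> float:
        """Dwell time (sampling interval) in seconds."""
        return 1.0 / self.bandwidth

    @property
    def time(self) -> np.ndarray:
        """Time grid ``t = 0, dt, ..., (T-1) dt`` in seconds (t=0 is the first sample)."""
        return np.arange(self.n_points) / self.bandwidth

    @property
    def freq_hz(self) -> np.ndarray:
        """Centered frequency axis in Hz matching an fftshift-ed DFT of the FID."""
        return np.fft.fftshift(np.fft.fftfreq(self.n_points, d=self.dwell))

    @property
    def ppm(self) -> np.ndarray:
        """Centered chemical-shift axis in ppm (same ordering as :attr:`freq_hz`)."""
        return self.hz_to_ppm(self.freq_hz)

    def ppm_to_hz(self, ppm: float | np.ndarray) -> float | np.ndarray:
        """Frequency offset in Hz of a resonance at chemical shift ``ppm``."""
        return (np.asarray(ppm, dtype=float) - self.ref_ppm) * self.field_mhz

    def hz_to_ppm(self, hz: float | np.ndarray) -> float | np.ndarray:
        """Inverse of :meth:`ppm_to_hz`."""
        return np.asarray(hz, dtype=float) / self.field_mhz + self.ref_ppm

    def zero_filled(self, factor: int) -> "SpectralAxis":
        """Return an axis with ``factor``-times more points at the same bandwidth.

        Zero-filling the FID onto this axis refines the frequency grid by
        ``factor`` (used for sub-bin linewidth measurements).
        """
        if factor < 1:
            raise ValueError("zero-fill factor must be >= 1")
        return SpectralAxis(self.n_points * factor, self.bandwidth,
                            self.field_mhz, self.ref_ppm)

    def spectrum(self, fid: np.ndarray, zero_fill: int = 1) -> np.ndarray:
        """Unitary DFT of an FID (last axis), fftshift-ed to the centered grid.

        The unitary ("ortho") normalization is the package-wide convention:
        white noise of std sigma in the time domain stays std sigma in the
        spectral domain.
        """
        fid = np.asarray(fid)
        n = self.n_points * zero_fill
        if fid.shape[-1] != self.n_points:
            raise ValueError(
                f"FID length {fid.shape[-1]} does not match axis n_points {self.n_points}")
        spec = np.fft.fft(fid, n=n, axis=-1) / np.sqrt(self.n_points)
        return np.fft.fftshift(spec, axes=-1)
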