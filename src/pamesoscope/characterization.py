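"""Sensor-bench computations: frequency response, directivity map, NEP.

These operations apply equally to simulated waveforms and recorded ones; they
reproduce the standard bench characterization of a broadband ultrasound sensor:
FFT magnitude spectrum with a -3 dB amplitude bandwidth read off by linear
interpolation, an angular directivity map from a -90..90 degree sweep, and the
full-band noise-equivalent pressure as the standard deviation of a calibrated
noise record.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np

__all__ = [
    "FrequencyResponse",
    "DirectivityMap",
    "frequency_response",
    "directivity_map",
    "estimate_nep",
]


@dataclass(frozen=True)
class FrequencyResponse:
    """Magnitude spectrum normalized to its peak (so ``magnitude_db <= 0``)."""

    freqs: np.ndarray
    magnitude_db: np.ndarray
    bw_3db: float

    @property
    def bin_width(self) -> float:
        return float(self.freqs[1] - self.freqs[0])


@dataclass(frozen=True)
class DirectivityMap:
    """Per-angle magnitude spectra, normalized to 1 at each frequency's peak."""

    angles: np.ndarray
    freqs: np.ndarray
    gain: np.ndarray  # [angle, freq]
    coverage_deg: float
    coverage_threshold: float


def frequency_response(waveform, fs: float) -> FrequencyResponse:
    """FFT magnitude spectrum of a pulse and its -3 dB amplitude bandwidth.

    The bandwidth is the lowest frequency above the spectral peak where the
    magnitude first crosses -3 dB (amplitude convention), located by linear
    interpolation between frequency bins on the dB curve.  Raises
    ``ValueError`` for an all-zero record.
    """
    w = np.asarray(waveform, dtype=float)
    if w.ndim != 1 or w.size < 2:
        raise ValueError("waveform must be a 1-D series with >= 2 samples")
    if not np.all(np.isfinite(w)):
        raise ValueError("waveform must be finite")
    mag = np.abs(np.fft.rfft(w))
    peak = mag.max()
    if peak == 0.0:
        raise ValueError("all-zero waveform has no defined frequency response")
    freqs = np.fft.rfftfreq(w.size, d=1.0 / fs)
    with np.errstate(divide="ignore"):
        mag_db = 20.0 * np.log10(mag / peak)
    ipk = int(np.argmax(mag))
    below = np.nonzero(mag_db[ipk:] < -3.0)[0]
    if below.size == 0:
        bw = float(freqs[-1])  # never drops below -3 dB within Nyquist
    else:
        j = ipk + below[0]
        f1, f2 = freqs[j - 1], freqs[j]
        m1, m2 = mag_db[j - 1], mag_db[j]
        bw = float(f1 + ((-3.0) - m1) * (f2 - f1) / (m2 - m1))
    return FrequencyResponse(freqs=freqs, magnitude_db=mag_db, bw_3db=bw)


def directivity_map(
    sweep: Sequence[tuple[float, np.ndarray]],
    fs: float,
    coverage_band: tuple[float, float] | None = None,
    coverage_threshold: float = 0.5,
) -> DirectivityMap:
    """Stack per-angle magnitude spectra into an angle-frequency gain map.

    ``sweep`` is a list of ``(angle_deg, waveform)`` with strictly increasing
    angles in [-90, 90].  Gains are normalized per frequency column to that
    column's maximum.  The angular coverage is the widest contiguous angle span
    whose gain stays at or above ``coverage_threshold`` (default 0.5, i.e.
    -6 dB power) at every frequency inside ``coverage_band`` (default: the
    whole sampled band excluding DC).
    """
    if len(sweep) < 2:
        raise ValueError("sweep needs at least two angles")
    angles = np.array([float(a) for a, _ in sweep])
    if np.any(np.diff(angles) <= 0):
        raise ValueError("angles must be strictly increasing (no duplicates)")
    if angles[0] < -90.0 or angles[-1] > 90.0:
        raise ValueError("angles must lie within [-90, 90] degrees")
    n = max(len(np.asarray(w)) for _, w in sweep)
    spectra = np.stack(
        [np.abs(np.fft.rfft(np.asarray(w, dtype=float), n=n)) for _, w in sweep]
    )
    freqs = np.fft.rfftfreq(n, d=1.0 / fs)
    colmax = spectra.max(axis=0)
    gain = np.divide(spectra, colmax, out=np.zeros_like(spectra), where=colmax > 0)

    if coverage_band is None:
        coverage_band = (freqs[1] if n > 2 else 0.0, freqs[-1])
    sel = (freqs >= coverage_band[0]) & (freqs <= coverage_band[1])
    ok = np.all(gain[:, sel] >= coverage_threshold, axis=1)
    coverage = _widest_run_span(angles, ok)
    return DirectivityMap(
        angles=angles,
        freqs=freqs,
        gain=gain,
        coverage_deg=coverage,
        coverage_threshold=coverage_threshold,
    )


def _widest_run_span(angles: np.ndarray, ok: np.ndarray) -> float:
    best = 0.0
    i = 0
    n = len(ok)
    while i < n:
        if ok[i]:
            j = i
            while j + 1 < n and ok[j + 1]:
                j += 1
            best = max(best, float(angles[j] - angles[i]))
            i = j + 1
        else:
            i += 1
    return best


def estimate_nep(noise_record, calibration_gain: float = 1.0) -> float:
    """Full-band noise-equivalent pressure: std of the calibrated noise record.

    The record must contain no signal epoch; fewer than 100 samples is
    rejected as insufficient data.
    """
    r = np.asarray(noise_record, dtype=float)
    if r.size < 100:
        raise ValueError("insufficient data: need >= 100 noise samples")
    if not np.all(np.isfinite(r)):
        raise ValueError("noise record must be finite")
    return float(np.std(r * calibration_gain, ddof=1))
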