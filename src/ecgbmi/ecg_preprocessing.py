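"""From a 12-lead record to network inputs.

Two input forms are produced: the short-time Fourier transform (STFT) of
the full 10-second trace, and the STFT of the averaged single beat
(1-second segments aligned with the R peak at the segment center). Both
yield a time x frequency x lead power tensor restricted to 5-55 Hz — the
range covering QRS (~8-50 Hz), T (~0-10 Hz) and P (~5-30 Hz) energy — plus
36 band-power features (12 leads x 3 overlapping bands: 10-25, 20-35 and
30-50 Hz), defined as the sum of tensor entries over all windows and the
band's frequency bins.

Windowing uses centered Hann windows with zero padding at the edges so the
number of windows is exactly duration/shift: 100 windows for the full trace
(0.5 s window, 0.1 s shift) and 100 for the averaged beat (0.2 s window,
0.01 s shift). The full-trace FFT is zero-padded to 1 s so the frequency
grid is 1 Hz and [5, 55) Hz yields 50 bins; the averaged beat uses its
native 5 Hz grid, yielding 10 bins.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import numpy as np
from scipy import signal as sps

from .synthetic_cohort import ECGRecord


@lru_cache(maxsize=8)
def _qrs_sos(fs: float):
    return sps.butter(2, (5.0, 15.0), btype="band", fs=fs, output="sos")

__all__ = [
    "FULL_TRACE",
    "AVERAGED_BEAT",
    "BANDS",
    "FeatureTensor",
    "BeatSet",
    "detect_r_peaks",
    "average_beat",
    "stft_tensor",
    "band_power_features",
    "extract_features",
]

FULL_TRACE = "full_trace"
AVERAGED_BEAT = "averaged_beat"

# (window length s, shift s, expected input duration s, FFT length s)
_STFT_PARAMS = {
    FULL_TRACE: (0.5, 0.1, 10.0, 1.0),
    AVERAGED_BEAT: (0.2, 0.01, 1.0, 0.2),
}

BANDS = [(10.0, 25.0), (20.0, 35.0), (30.0, 50.0)]  # Hz, closed intervals
FREQ_RANGE = (5.0, 55.0)  # half-open [5, 55)


@dataclass
class FeatureTensor:
    """STFT power tensor plus band-power vector for one record."""

    x: np.ndarray  # (N_T, N_f, 12), spectral power
    freqs: np.ndarray  # (N_f,) bin center frequencies, Hz
    band_power: np.ndarray | None  # (36,), lead-major then band
    input_form: str
    fs: float

    def __post_init__(self):
        expected_nf = 50 if self.input_form == FULL_TRACE else 10
        if self.x.shape[0] != 100 or self.x.shape[1] != expected_nf or self.x.shape[2] != 12:
            raise ValueError(
                f"{self.input_form} tensor must be (100, {expected_nf}, 12), got {self.x.shape}"
            )
        if self.band_power is not None and len(self.band_power) != 36:
            raise ValueError("band_power must have length 36")


@dataclass
class BeatSet:
    r_peaks: np.ndarray  # sample indices used (after edge filtering)
    beats: np.ndarray  # (K, 12, n_seg), 1-s segments, R at center
    averaged_beat: np.ndarray  # (12, n_seg)


def detect_r_peaks(record: ECGRecord, lead: int = 1) -> np.ndarray:
    """Pan-Tompkins-style R peak detection on one lead (default lead II).

    Bandpass 5-15 Hz, differentiate, square, 150 ms moving-window
    integration, adaptive threshold, 200 ms refractory spacing; peak
    positions are refined to the raw-signal extremum within ±100 ms.
    Returns an empty array when no beat exceeds the threshold.
    """
    if record.duration < 2.0:
        raise ValueError("record must be at least 2 s long")
    fs = record.fs
    x = record.signal[lead]
    if np.ptp(x) == 0.0:
        return np.array([], dtype=int)  # flat signal: no beats
    bp = sps.sosfiltfilt(_qrs_sos(fs), x)
    sq = np.gradient(bp) ** 2
    win = max(int(round(0.150 * fs)), 1)
    mwi = np.convolve(sq, np.ones(win) / win, mode="same")
    height = 0.2 * np.percentile(mwi, 98)
    if height <= 0:
        return np.array([], dtype=int)
    refractory = int(round(0.200 * fs))
    locs, _ = sps.find_peaks(mwi, height=height, distance=refractory)
    if len(locs) == 0:
        return np.array([], dtype=int)
    # refine to raw-amplitude extremum near each integrated-energy peak
    half = int(round(0.100 * fs))
    refined = []
    for loc in locs:
        lo, hi = max(loc - half, 0), min(loc + half, len(x))
        refined.append(lo + int(np.argmax(np.abs(x[lo:hi]))))
    peaks = np.unique(refined)
    # enforce the refractory constraint after refinement
    kept = [int(peaks[0])]
    for p in peaks[1:]:
        if p - kept[-1] >= refractory:
            kept.append(int(p))
    return np.asarray(kept, dtype=int)


def average_beat(record: ECGRecord, r_peaks: np.ndarray) -> BeatSet:
    """Segment 1-s beats (R at center) on all 12 leads and average them.

    Peaks whose 1-s window would overrun the record edges are dropped.
    All leads are segmented on the same peak indices.
    """
    n_seg = int(round(record.fs))
    half = n_seg // 2
    n = record.signal.shape[1]
    retained = [int(r) for r in np.asarray(r_peaks, dtype=int) if r - half >= 0 and r - half + n_seg <= n]
    if not retained:
        raise ValueError("no beat has a full 0.5 s margin on each side of its R peak")
    beats = np.stack([record.signal[:, r - half : r - half + n_seg] for r in retained])
    return BeatSet(
        r_peaks=np.asarray(retained, dtype=int),
        beats=beats,
        averaged_beat=beats.mean(axis=0),
    )


def _stft_grid(input_form: str, fs: float):
    wlen_s, shift_s, dur_s, nfft_s = _STFT_PARAMS[input_form]
    wlen = int(round(wlen_s * fs))
    nfft = int(round(nfft_s * fs))
    n_windows = int(round(dur_s / shift_s))
    freqs_all = np.fft.rfftfreq(nfft, d=1.0 / fs)
    sel = (freqs_all >= FREQ_RANGE[0]) & (freqs_all < FREQ_RANGE[1])
    return wlen, shift_s, n_windows, nfft, freqs_all, sel


def stft_tensor(signal: np.ndarray, input_form: str, fs: float) -> FeatureTensor:
    """Compute the (N_T, N_f, 12) spectral-power tensor for one input.

    `signal` is (12, L): the full 10-s trace for `full_trace`, or the 1-s
    averaged beat for `averaged_beat`. Entries are squared magnitudes of
    Hann-windowed, zero-padded DFTs; windows are centered at
    (k + 1/2) * shift with zero padding beyond the signal edges.
    """
    if input_form not in _STFT_PARAMS:
        raise ValueError(f"unknown input_form {input_form!r}")
    wlen_s, shift_s, dur_s, _ = _STFT_PARAMS[input_form]
    signal = np.asarray(signal, dtype=float)
    expected_len = int(round(dur_s * fs))
    if signal.ndim != 2 or signal.shape[0] != 12 or signal.shape[1] != expected_len:
        raise ValueError(
            f"{input_form} expects a (12, {expected_len}) signal at fs={fs}, got {signal.shape}"
        )
    wlen, shift_s, n_windows, nfft, freqs_all, sel = _stft_grid(input_form, fs)
    window = sps.windows.hann(wlen, sym=False)
    n = signal.shape[1]
    # gather the (possibly clipped) sample block for each window center
    frames = np.zeros((n_windows, 12, wlen))
    for k in range(n_windows):
        center = (k + 0.5) * shift_s
        start = int(round(center * fs)) - wlen // 2
        lo, hi = max(start, 0), min(start + wlen, n)
        frames[k, :, lo - start : hi - start] = signal[:, lo:hi]
    spec = np.fft.rfft(frames * window, n=nfft, axis=-1)
    power = np.abs(spec) ** 2  # (N_T, 12, n_bins)
    x = power[:, :, sel].transpose(0, 2, 1)  # (N_T, N_f, 12)
    return FeatureTensor(x=x, freqs=freqs_all[sel], band_power=None, input_form=input_form, fs=fs)


def band_power_features(tensor: FeatureTensor) -> np.ndarray:
    """36-vector of band powers, ordered lead-major then band.

    Element (lead, band) sums the tensor over all windows and over the
    frequency bins whose centers lie in the closed band interval.
    """
    out = np.empty(36)
    for lead in range(12):
        for b, (lo, hi) in enumerate(BANDS):
            mask = (tensor.freqs >= lo) & (tensor.freqs <= hi)
            out[lead * 3 + b] = tensor.x[:, mask, lead].sum()
    return out


def extract_features(record: ECGRecord, input_form: str) -> FeatureTensor:
    """Full front end for one record: STFT tensor plus band powers.

    For `averaged_beat`, R peaks are detected on lead II and all leads are
    segmented on those peaks before averaging.
    """
    if input_form == FULL_TRACE:
        tensor = stft_tensor(record.signal, FULL_TRACE, record.fs)
    else:
        peaks = detect_r_peaks(record, lead=1)
        if len(peaks) == 0:
            raise ValueError(f"no beats detected in record {record.subject_id}")
        beat = average_beat(record, peaks).averaged_beat
        tensor = stft_tensor(beat, AVERAGED_BEAT, record.fs)
    tensor.band_power = band_power_features(tensor)
    return tensor
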