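"""Recording preprocessing: band-pass filtering, denoising, phase segmentation.

The analysis band for tracheal breathing sounds is 75-3000 Hz; recordings
are band-limited with a zero-phase fourth-order Butterworth filter,
optionally denoised by spectral subtraction, and segmented into
inspiratory/expiratory phases with the LogVar method (log of windowed
sample variance thresholded against its dynamic range).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import signal as sps

from tbscreen.cohort import BreathRecording


@dataclass
class BreathPhaseSet:
    """Sorted, non-overlapping half-open [start, end) phase intervals."""

    phases: list  # (start_sample, end_sample, kind) with kind in {inspiration, expiration}
    rate: int

    def __post_init__(self) -> None:
        prev_end = 0
        for start, end, kind in self.phases:
            if kind not in ("inspiration", "expiration"):
                raise ValueError(f"bad phase kind {kind!r}")
            if start < prev_end or end <= start:
                raise ValueError("phases must be sorted, non-overlapping, non-empty")
            prev_end = end

    def __len__(self) -> int:
        return len(self.phases)

    def extract(self, recording: BreathRecording):
        """Yield (kind, samples) per phase."""
        for start, end, kind in self.phases:
            yield kind, recording.samples[start:end]


def bandpass(
    recording: BreathRecording,
    low: float = 75.0,
    high: float = 3000.0,
    order: int = 4,
) -> BreathRecording:
    """Zero-phase (forward-backward) Butterworth band-pass filter.

    Defaults to the 75-3000 Hz analysis band with a fourth-order design;
    forward-backward application squares the magnitude response and cancels
    phase distortion, so breath-onset timing is preserved.
    """
    nyq = recording.rate / 2
    if not (0 < low < high < nyq):
        raise ValueError(f"need 0 < low < high < Nyquist ({nyq} Hz)")
    sos = sps.butter(order, [low, high], btype="bandpass", fs=recording.rate,
                     output="sos")
    filtered = sps.sosfiltfilt(sos, recording.samples)
    return BreathRecording(samples=filtered, rate=recording.rate, route=recording.route)


def butterworth_bandpass_gain(f: float, low: float, high: float, order: int,
                              zero_phase: bool = True,
                              rate: float | None = None) -> float:
    """Closed-form magnitude gain of the (forward-backward) band-pass.

    An order-n Butterworth band-pass has |H(f)|^2 = 1 / (1 + w(f)^(2n)) with
    the band-pass frequency warp w(f) = (f^2 - f0^2) / (f * B), where
    f0 = sqrt(low*high) and B = high - low.  Forward-backward filtering
    applies |H|^2.

    When ``rate`` is given, frequencies are bilinear-prewarped
    (x -> tan(pi*x/rate)) so the value matches the digital filter designed
    at that sampling rate exactly, not just near the band edges.  The edge
    gains are 0.5 (zero-phase) either way, since the digital design
    prewarps its corner frequencies.
    """
    if rate is not None:
        f, low, high = (np.tan(np.pi * x / rate) for x in (f, low, high))
    f0 = np.sqrt(low * high)
    bw = high - low
    w = (f**2 - f0**2) / (f * bw)
    h2 = 1.0 / (1.0 + w ** (2 * order))
    return h2 if zero_phase else np.sqrt(h2)


def logvar_segment(
    recording: BreathRecording,
    window_ms: float = 50.0,
    overlap_fraction: float = 0.5,
    threshold_fraction: float = 0.25,
    min_phase_ms: float = 200.0,
) -> BreathPhaseSet:
    """Segment a band-passed recording into breath phases via LogVar.

    The log of the sample variance is computed in sliding windows; frames
    whose LogVar exceeds ``threshold_fraction`` of the (max - min) dynamic
    range above the minimum are sound-active.  Active runs separated by
    gaps shorter than ``min_phase_ms`` are merged, runs shorter than
    ``min_phase_ms`` are dropped, and the survivors are labelled
    inspiration/expiration alternately starting with inspiration (the
    protocol begins with an inspiration).
    """
    if not (0 < overlap_fraction < 1):
        raise ValueError("overlap_fraction must lie in (0, 1)")
    x = recording.samples
    rate = recording.rate
    win = max(int(round(window_ms * 1e-3 * rate)), 2)
    hop = max(int(round(win * (1 - overlap_fraction))), 1)
    n_frames = max((len(x) - win) // hop + 1, 0)
    if n_frames == 0:
        warnings.warn("recording shorter than one analysis window")
        return BreathPhaseSet(phases=[], rate=rate)
    idx = np.arange(win)[None, :] + hop * np.arange(n_frames)[:, None]
    frames = x[idx]
    logvar = np.log(frames.var(axis=1) + 1e-20)
    rng_ = logvar.max() - logvar.min()
    if rng_ < 1.0:  # flat profile: silence or constant signal
        warnings.warn("flat LogVar profile; no phases detected")
        return BreathPhaseSet(phases=[], rate=rate)
    thresh = logvar.min() + threshold_fraction * rng_
    active = logvar > thresh

    # frame runs -> sample intervals
    runs = []
    start = None
    for i, a in enumerate(active):
        if a and start is None:
            start = i
        elif not a and start is not None:
            runs.append((start, i))
            start = None
    if start is not None:
        runs.append((start, len(active)))
    intervals = [(s * hop, min((e - 1) * hop + win, len(x))) for s, e in runs]

    # merge gaps shorter than min_phase_ms
    min_len = int(round(min_phase_ms * 1e-3 * rate))
    merged = []
    for s, e in intervals:
        if merged and s - merged[-1][1] < min_len:
            merged[-1] = (merged[-1][0], e)
        else:
            merged.append((s, e))
    kept = [(s, e) for s, e in merged if e - s >= min_len]

    kinds = ["inspiration", "expiration"]
    phases = [(s, e, kinds[i % 2]) for i, (s, e) in enumerate(kept)]
    return BreathPhaseSet(phases=phases, rate=rate)


def denoise(
    recording: BreathRecording,
    frame_ms: float = 32.0,
    oversubtract: float = 1.0,
    floor: float = 0.05,
    snr_skip_db: float = 35.0,
) -> BreathRecording:
    """Spectral-subtraction denoising using the quietest 10% of frames.

    The noise magnitude spectrum is estimated from the lowest-energy decile
    of STFT frames and subtracted from every frame (flooring at ``floor``
    times the noisy magnitude).  When the estimated SNR already exceeds
    ``snr_skip_db`` the recording is returned unchanged.
    """
    x = recording.samples
    rate = recording.rate
    nper = int(round(frame_ms * 1e-3 * rate))
    nper = max(64, nper)
    f, t, Z = sps.stft(x, fs=rate, nperseg=nper, noverlap=nper // 2)
    mag = np.abs(Z)
    energy = (mag**2).sum(axis=0)
    n_quiet = max(int(0.1 * len(energy)), 1)
    quiet = np.argsort(energy)[:n_quiet]
    noise_mag = mag[:, quiet].mean(axis=1, keepdims=True)
    noise_pow = float((noise_mag**2).sum())
    sig_pow = float(np.mean(energy))
    snr_db = 10 * np.log10(sig_pow / (noise_pow + 1e-30) + 1e-30)
    if snr_db > snr_skip_db:
        return BreathRecording(samples=x.copy(), rate=rate, route=recording.route)
    clean_mag = np.maximum(mag - oversubtract * noise_mag, floor * mag)
    phase = Z / np.maximum(mag, 1e-30)
    _, y = sps.istft(clean_mag * phase, fs=rate, nperseg=nper, noverlap=nper // 2)
    y = y[: len(x)]
    if len(y) < len(x):
        y = np.pad(y, (0, len(x) - len(y)))
    return BreathRecording(samples=y, rate=rate, route=recording.route)


def phase_table(subject_id: str, route: str, phases: BreathPhaseSet):
    """Long-format phase rows for CSV export."""
    import pandas as pd

    return pd.DataFrame(
        [
            dict(subject_id=subject_id, route=route, phase_index=i, kind=kind,
                 start_sample=s, end_sample=e)
            for i, (s, e, kind) in enumerate(phases.phases)
        ]
    )
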