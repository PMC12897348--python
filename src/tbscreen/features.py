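"""Acoustic feature families computed per breath phase.

Six families are extracted from each inspiratory/expiratory phase of each
(nose/mouth) recording and mean-aggregated to one named vector per subject:

* spectral    — Welch band powers over octave-spaced sub-bands of 75-3000 Hz,
                band ratios, centroid, normalized spectral entropy;
* hos         — direct (segment-averaged FFT) bispectrum magnitude statistics
                and mean squared bicoherence over the principal bifrequency
                triangle;
* time        — Higuchi and Katz fractal dimensions, zero-crossing rate,
                envelope-peak statistics;
* tf          — 4-level Symlet-4 wavelet sub-band energies/entropies and a
                constant-Q filterbank energy summary (12 bins/octave);
* nonlinear   — recurrence quantification (determinism, laminarity, longest
                diagonal) and the largest Lyapunov exponent (Rosenstein);
* perturbation— cycle-to-cycle jitter and shimmer from envelope peak marks,
                computed once per recording.

A feature that cannot be computed (phase too short, degenerate signal) is
*absent* from the returned dict; the subject-level aggregator records it as
explicitly missing, never as a silent NaN.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import pywt
from scipy import signal as sps

from tbscreen.cohort import (
    SubjectRecord,
    anthropometric_frame,
    SEVERITIES,
)
from tbscreen.signal_prep import bandpass, denoise, logvar_segment
from tbscreen.table import FeatureTable, ANTHROPOMETRIC_COLUMNS

BAND_EDGES = (75.0, 150.0, 300.0, 600.0, 1200.0, 2400.0, 3000.0)
FAMILIES = ("spectral", "hos", "time", "tf", "nonlinear")

DICTIONARY_VERSION = "1.0"


# ---------------------------------------------------------------------------
# spectral
# ---------------------------------------------------------------------------

def spectral_features(x: np.ndarray, rate: int, nperseg: int = 256) -> dict:
    """Welch-PSD band powers, ratios, centroid, normalized spectral entropy."""
    x = np.asarray(x, dtype=float)
    if len(x) < nperseg:
        return {}
    f, psd = sps.welch(x, fs=rate, window="hann", nperseg=nperseg,
                       noverlap=nperseg // 2)
    out = {}
    df = f[1] - f[0]
    band_powers = []
    for i in range(len(BAND_EDGES) - 1):
        lo, hi = BAND_EDGES[i], BAND_EDGES[i + 1]
        sel = (f >= lo) & (f < hi)
        band_powers.append(float(psd[sel].sum() * df))
    total = sum(band_powers)
    for i, bp in enumerate(band_powers, start=1):
        out[f"band_power_{i}"] = bp
        out[f"band_ratio_{i}"] = bp / total if total > 0 else 0.0
    out["total_power"] = total
    psum = psd.sum()
    if psum > 0:
        out["spectral_centroid"] = float((f * psd).sum() / psum)
        p = psd / psum
        nz = p[p > 0]
        out["spectral_entropy"] = float(-(nz * np.log(nz)).sum() / np.log(len(p)))
    return out


# ---------------------------------------------------------------------------
# higher-order spectra
# ---------------------------------------------------------------------------

def _segment_ffts(x: np.ndarray, nfft: int, overlap: float = 0.5) -> np.ndarray:
    hop = max(int(nfft * (1 - overlap)), 1)
    n_seg = (len(x) - nfft) // hop + 1 if len(x) >= nfft else 0
    if n_seg < 1:
        return np.empty((0, nfft))
    idx = np.arange(nfft)[None, :] + hop * np.arange(n_seg)[:, None]
    segs = x[idx]
    segs = segs - segs.mean(axis=1, keepdims=True)
    return np.fft.fft(segs, axis=1)


def bispectrum_matrix(x: np.ndarray, nfft: int = 256, overlap: float = 0.5,
                      max_segments: int = 64):
    """Direct bispectrum and squared-bicoherence estimates on the FFT grid.

    Returns ``(B, b2, n_seg)`` where ``B[f1, f2]`` averages
    ``X(f1) X(f2) conj(X(f1+f2))`` over segments and ``b2`` is
    ``|B|^2 / (E|X(f1)X(f2)|^2 E|X(f1+f2)|^2)``, both on the quarter grid
    ``0 <= f1, f2 <= nfft/4`` (so f1+f2 stays below Nyquist).
    """
    X = _segment_ffts(np.asarray(x, dtype=float), nfft, overlap)
    if len(X) > max_segments:  # evenly spread subset keeps the estimate cheap
        X = X[np.linspace(0, len(X) - 1, max_segments).round().astype(int)]
    n_seg = len(X)
    q = nfft // 4
    if n_seg == 0:
        return None, None, 0
    i = np.arange(q + 1)
    X1 = X[:, i][:, :, None]          # (seg, f1, 1)
    X2 = X[:, i][:, None, :]          # (seg, 1, f2)
    X12 = X1 * X2
    sum_idx = i[:, None] + i[None, :]
    X3 = X[:, sum_idx]                # (seg, f1, f2)
    B = (X12 * np.conj(X3)).mean(axis=0)
    p12 = (np.abs(X12) ** 2).mean(axis=0)
    p3 = (np.abs(X3) ** 2).mean(axis=0)
    denom = p12 * p3
    with np.errstate(divide="ignore", invalid="ignore"):
        b2 = np.where(denom > 0, np.abs(B) ** 2 / denom, 0.0)
    return B, b2, n_seg


def hos_features(x: np.ndarray, rate: int, nfft: int = 256,
                 min_segments: int = 8) -> dict:
    """Bispectrum magnitude statistics and mean squared bicoherence."""
    B, b2, n_seg = bispectrum_matrix(x, nfft=nfft)
    if n_seg < min_segments:
        return {}
    q = B.shape[0] - 1
    f1, f2 = np.meshgrid(np.arange(q + 1), np.arange(q + 1), indexing="ij")
    tri = (f2 <= f1) & (f1 + f2 <= q) & (f1 + f2 > 0)  # principal triangle
    mag = np.abs(B)[tri]
    out = {
        "bispec_mean": float(mag.mean()),
        "bispec_max": float(mag.max()),
        "bicoherence_mean": float(b2[tri].mean()),
    }
    s = mag.sum()
    if s > 0:
        p = mag / s
        nz = p[p > 0]
        out["bispec_entropy"] = float(-(nz * np.log(nz)).sum() / np.log(len(p)))
    return out


# ---------------------------------------------------------------------------
# time domain
# ---------------------------------------------------------------------------

def higuchi_fd(x: np.ndarray, k_max: int = 8) -> float:
    """Higuchi fractal dimension; ~1 for smooth curves, ~2 for white noise."""
    x = np.asarray(x, dtype=float)
    n = len(x)
    lk = []
    ks = []
    for k in range(1, k_max + 1):
        lengths = []
        for m in range(k):
            seg = x[m::k]
            if len(seg) < 2:
                continue
            lm = np.abs(np.diff(seg)).sum() * (n - 1) / (len(seg) - 1) / k
            lengths.append(lm / k)
        if lengths:
            lk.append(np.log(np.mean(lengths)))
            ks.append(np.log(1.0 / k))
    if len(lk) < 2:
        return np.nan
    slope = np.polyfit(ks, lk, 1)[0]
    return float(slope)


def katz_fd(x: np.ndarray) -> float:
    x = np.asarray(x, dtype=float)
    n = len(x) - 1
    if n < 1:
        return np.nan
    dists = np.hypot(np.diff(x), 1.0)
    L = dists.sum()
    d = np.max(np.hypot(x - x[0], np.arange(len(x))))
    if d <= 0 or L <= 0:
        return np.nan
    return float(np.log10(n) / (np.log10(n) + np.log10(d / L)))


def _envelope(x: np.ndarray, rate: int, smooth_ms: float = 25.0) -> np.ndarray:
    from scipy.fft import next_fast_len
    from scipy.ndimage import uniform_filter1d

    n = len(x)
    env = np.abs(sps.hilbert(x, N=next_fast_len(n)))[:n]
    w = max(int(smooth_ms * 1e-3 * rate), 1)
    return uniform_filter1d(env, size=w, mode="nearest")


def time_features(x: np.ndarray, rate: int = 1) -> dict:
    """Fractal dimensions, zero-crossing rate, envelope-peak statistics."""
    x = np.asarray(x, dtype=float)
    if len(x) < 10:
        return {}
    out = {}
    if np.ptp(x) > 0:
        hfd = higuchi_fd(x)
        if np.isfinite(hfd):
            out["higuchi_fd"] = hfd
        kfd = katz_fd(x)
        if np.isfinite(kfd):
            out["katz_fd"] = kfd
        out["zcr"] = float(np.mean(np.abs(np.diff(np.signbit(x - x.mean())))))
    env = _envelope(x, rate) if rate > 1 else np.abs(x)
    peaks, props = sps.find_peaks(env, prominence=0.25 * np.ptp(env))
    out["env_peak_count"] = float(len(peaks))
    if len(peaks):
        out["env_peak_mean"] = float(env[peaks].mean())
        out["env_peak_sd"] = float(env[peaks].std(ddof=0))
    return out


# ---------------------------------------------------------------------------
# time-frequency
# ---------------------------------------------------------------------------

def tf_features(x: np.ndarray, rate: int, wavelet: str = "sym4",
                level: int = 4, bins_per_octave: int = 12) -> dict:
    """Symlet-4 DWT sub-band energies/entropies and constant-Q summaries."""
    x = np.asarray(x, dtype=float)
    wav = pywt.Wavelet(wavelet)
    if len(x) < (2**level) * wav.dec_len:
        return {}
    coeffs = pywt.wavedec(x, wav, level=level)
    names = ["a4"] + [f"d{level - i + 1}" for i in range(1, level + 1)]
    energies = np.array([float((c**2).sum()) for c in coeffs])
    total = energies.sum()
    out = {}
    for name, e, c in zip(names, energies, coeffs):
        out[f"dwt_relenergy_{name}"] = float(e / total) if total > 0 else 0.0
        e_i = c**2
        s = e_i.sum()
        if s > 0:
            p = e_i / s
            nz = p[p > 0]
            out[f"dwt_logent_{name}"] = float(-(nz * np.log(nz)).sum() / np.log(len(p)))
        else:
            out[f"dwt_logent_{name}"] = 0.0

    # constant-Q filterbank energy summary (energies only, not invertible)
    spec = np.abs(np.fft.rfft(x)) ** 2
    freqs = np.fft.rfftfreq(len(x), 1.0 / rate)
    Q = 1.0 / (2 ** (1.0 / bins_per_octave) - 1)
    fmin, fmax = BAND_EDGES[0], BAND_EDGES[-1]
    n_bins = int(np.floor(bins_per_octave * np.log2(fmax / fmin)))
    centers = fmin * 2 ** (np.arange(n_bins) / bins_per_octave)
    cq = np.empty(n_bins)
    for k, fc in enumerate(centers):
        bw = fc / Q
        sel = (freqs >= fc - bw / 2) & (freqs < fc + bw / 2)
        cq[k] = spec[sel].sum() if sel.any() else 0.0
    octave = np.floor(np.log2(centers / fmin)).astype(int)
    for o in range(octave.max() + 1):
        out[f"cqt_oct{o + 1}_mean"] = float(cq[octave == o].mean())
    out["cqt_sd"] = float(cq.std(ddof=0))
    return out


# ---------------------------------------------------------------------------
# nonlinear dynamics
# ---------------------------------------------------------------------------

def _embed(x: np.ndarray, dim: int, tau: int) -> np.ndarray:
    n = len(x) - (dim - 1) * tau
    if n < 2:
        return np.empty((0, dim))
    return np.column_stack([x[i * tau: i * tau + n] for i in range(dim)])


def _delay_from_autocorr(x: np.ndarray, max_lag: int | None = None) -> int:
    x = x - x.mean()
    denom = float((x * x).sum())
    if denom <= 0:
        return 1
    max_lag = max_lag or max(len(x) // 4, 2)
    for lag in range(1, max_lag):
        r = float((x[:-lag] * x[lag:]).sum()) / denom
        if r <= 0:
            return lag
    return max_lag


def nonlinear_features(
    x: np.ndarray,
    max_points: int = 400,
    dim: int = 3,
    target_rr: float = 0.10,
    min_line: int = 2,
) -> dict:
    """Recurrence quantification and largest Lyapunov exponent.

    The signal is FFT-resampled to at most ``max_points`` samples, embedded
    with dimension ``dim`` and delay set by the first autocorrelation zero;
    the recurrence radius is the distance quantile achieving the target
    recurrence rate (default 10%).  Degenerate (constant) inputs are
    reported as missing.
    """
    x = np.asarray(x, dtype=float)
    if len(x) < 50 or np.ptp(x) == 0:
        return {}
    if len(x) > max_points:
        x = sps.resample(x, max_points)
    x = (x - x.mean()) / (x.std(ddof=0) + 1e-30)
    tau = _delay_from_autocorr(x)
    emb = _embed(x, dim, tau)
    if len(emb) < 10:
        return {}
    d = np.sqrt(((emb[:, None, :] - emb[None, :, :]) ** 2).sum(axis=-1))
    n = len(emb)
    off = ~np.eye(n, dtype=bool)
    radius = np.quantile(d[off], target_rr)
    R = (d <= radius) & off

    out = {}
    # diagonal line structures (excluding the line of identity)
    diag_hist = _run_lengths_many([np.diagonal(R, offset=k) for k in range(1, n)])
    rec_points = R.sum()
    if rec_points > 0 and len(diag_hist):
        in_lines = diag_hist[diag_hist >= min_line].sum()
        out["rqa_determinism"] = float(2 * in_lines / rec_points)
        out["rqa_max_diag"] = float(diag_hist.max())
    # vertical line structures
    vert_hist = _run_lengths_many([R[:, j] for j in range(n)])
    if rec_points > 0 and len(vert_hist):
        out["rqa_laminarity"] = float(vert_hist[vert_hist >= min_line].sum() / rec_points)

    lyap = rosenstein_lyapunov(x, dim=dim, tau=tau, dists=d)
    if np.isfinite(lyap):
        out["lyapunov"] = lyap
    return out


def _run_lengths(mask: np.ndarray) -> np.ndarray:
    return _run_lengths_many([np.asarray(mask, dtype=bool)])


def _run_lengths_many(arrays: list) -> np.ndarray:
    """Run lengths of True in each 1-D bool array, pooled (vectorized)."""
    if not arrays:
        return np.empty(0, dtype=int)
    sep = np.zeros(1, dtype=bool)
    cat = np.concatenate([piece for a in arrays for piece in (a, sep)])
    d = np.diff(cat.astype(np.int8), prepend=np.int8(0))
    starts = np.flatnonzero(d == 1)
    ends = np.flatnonzero(d == -1)
    return ends - starts


def rosenstein_lyapunov(x: np.ndarray, dim: int = 3, tau: int = 1,
                        fit_steps: int = 15, dists: np.ndarray | None = None
                        ) -> float:
    """Largest Lyapunov exponent by the Rosenstein nearest-neighbor method."""
    emb = _embed(np.asarray(x, dtype=float), dim, tau)
    n = len(emb)
    if n < 2 * fit_steps + 4:
        return np.nan
    if dists is not None and dists.shape == (n, n):
        d = dists
    else:
        d = np.sqrt(((emb[:, None, :] - emb[None, :, :]) ** 2).sum(axis=-1))
    window = max(tau * dim, 1)  # Theiler exclusion
    idx = np.arange(n)
    excl = np.abs(idx[:, None] - idx[None, :]) <= window
    d_mask = d.copy()
    d_mask[excl] = np.inf
    nn = d_mask.argmin(axis=1)
    steps = min(fit_steps, n - 1)
    log_div = np.full(steps, np.nan)
    for i in range(steps):
        valid = (idx + i < n) & (nn + i < n)
        if valid.sum() < 2:
            break
        dist = np.linalg.norm(emb[idx[valid] + i] - emb[nn[valid] + i], axis=1)
        dist = dist[dist > 0]
        if len(dist) < 2:
            continue
        log_div[i] = np.mean(np.log(dist))
    ok = np.isfinite(log_div)
    if ok.sum() < 3:
        return np.nan
    slope = np.polyfit(np.flatnonzero(ok), log_div[ok], 1)[0]
    return float(slope)


# ---------------------------------------------------------------------------
# perturbation (per recording)
# ---------------------------------------------------------------------------

def perturbation_features(x: np.ndarray, rate: int,
                          min_cycles: int = 3) -> dict:
    """Cycle-to-cycle jitter and shimmer from envelope peak marks.

    Cycle marks are the dominant envelope peaks (one per breath cycle);
    local jitter is mean |T_i - T_{i+1}| / mean T over consecutive periods,
    local shimmer the analogous quantity on peak amplitudes.
    """
    x = np.asarray(x, dtype=float)
    env = _envelope(x, rate, smooth_ms=200.0)
    if np.ptp(env) == 0:
        return {}
    peaks, _ = sps.find_peaks(env, height=0.8 * env.max(),
                              distance=int(1.5 * rate))
    if len(peaks) < min_cycles:
        return {}
    periods = np.diff(peaks) / rate
    amps = env[peaks]
    out = {"cycle_count": float(len(peaks))}
    if len(periods) >= 2:
        out["jitter"] = float(np.mean(np.abs(np.diff(periods))) / np.mean(periods))
    out["shimmer"] = float(np.mean(np.abs(np.diff(amps))) / np.mean(amps))
    return out


def envelope_peak_count(x: np.ndarray, rate: int) -> int:
    """Number of dominant (inspiratory) envelope peaks in a recording."""
    env = _envelope(np.asarray(x, dtype=float), rate, smooth_ms=200.0)
    if np.ptp(env) == 0:
        return 0
    peaks, _ = sps.find_peaks(env, height=0.8 * env.max(), distance=int(1.5 * rate))
    return len(peaks)


# ---------------------------------------------------------------------------
# aggregation and orchestration
# ---------------------------------------------------------------------------

PHASE_FAMILY_FUNCS = {
    "spectral": lambda x, rate: spectral_features(x, rate),
    "hos": lambda x, rate: hos_features(x, rate),
    "time": lambda x, rate: time_features(x, rate),
    "tf": lambda x, rate: tf_features(x, rate),
    "nonlinear": lambda x, rate: nonlinear_features(x),
}

_PHASE_FEATURE_NAMES = {
    "spectral": [f"band_power_{i}" for i in range(1, 7)]
    + [f"band_ratio_{i}" for i in range(1, 7)]
    + ["total_power", "spectral_centroid", "spectral_entropy"],
    "hos": ["bispec_mean", "bispec_max", "bispec_entropy", "bicoherence_mean"],
    "time": ["higuchi_fd", "katz_fd", "zcr", "env_peak_count", "env_peak_mean",
             "env_peak_sd"],
    "tf": [f"dwt_relenergy_{b}" for b in ("a4", "d4", "d3", "d2", "d1")]
    + [f"dwt_logent_{b}" for b in ("a4", "d4", "d3", "d2", "d1")]
    + [f"cqt_oct{o}_mean" for o in range(1, 7)]
    + ["cqt_sd"],
    "nonlinear": ["rqa_determinism", "rqa_laminarity", "rqa_max_diag", "lyapunov"],
}

ROUTE_PHASE_PREFIXES = ("nose_insp", "nose_exp", "mouth_insp", "mouth_exp")


def feature_dictionary(families: tuple = FAMILIES,
                       include_perturbation: bool = True) -> list[str]:
    """The versioned, named acoustic feature dictionary (aggregate level)."""
    names = []
    for prefix in ROUTE_PHASE_PREFIXES:
        for fam in families:
            names += [f"{prefix}_{n}" for n in _PHASE_FEATURE_NAMES[fam]]
    if include_perturbation:
        for route in ("nose", "mouth"):
            names += [f"{route}_jitter", f"{route}_shimmer"]
    return names


def feature_family_map(families: tuple = FAMILIES,
                       include_perturbation: bool = True) -> dict[str, str]:
    fam_map = {}
    for prefix in ROUTE_PHASE_PREFIXES:
        for fam in families:
            for n in _PHASE_FEATURE_NAMES[fam]:
                fam_map[f"{prefix}_{n}"] = fam
    if include_perturbation:
        for route in ("nose", "mouth"):
            fam_map[f"{route}_jitter"] = "perturbation"
            fam_map[f"{route}_shimmer"] = "perturbation"
    return fam_map


def aggregate_subject(phase_vectors: dict) -> dict:
    """Mean per feature across phases within each route x phase-kind group.

    ``phase_vectors`` maps ``(route, kind)`` -> list of per-phase feature
    dicts; kinds are 'inspiration'/'expiration'.  Output keys carry
    route/phase prefixes.  Features absent from every phase of a group are
    simply absent from the output (explicitly missing downstream).
    """
    out = {}
    for (route, kind), dicts in phase_vectors.items():
        prefix = f"{route}_{'insp' if kind == 'inspiration' else 'exp'}"
        keys = set()
        for d in dicts:
            keys |= set(d)
        for key in keys:
            vals = [d[key] for d in dicts if key in d]
            if vals:
                out[f"{prefix}_{key}"] = float(np.mean(vals))
    return out


def extract_subject_features(subject: SubjectRecord,
                             families: tuple = FAMILIES,
                             denoise_audio: bool = False) -> dict:
    phase_vectors: dict = {}
    perturb: dict = {}
    for rec in subject.recordings:
        filtered = bandpass(rec)
        if denoise_audio:
            filtered = denoise(filtered)
        phases = logvar_segment(filtered)
        for kind, seg in phases.extract(filtered):
            vec = {}
            for fam in families:
                vec.update(PHASE_FAMILY_FUNCS[fam](seg, filtered.rate))
            phase_vectors.setdefault((rec.route, kind), []).append(vec)
        p = perturbation_features(filtered.samples, filtered.rate)
        for key in ("jitter", "shimmer"):
            if key in p:
                perturb[f"{rec.route}_{key}"] = p[key]
    out = aggregate_subject(phase_vectors)
    out.update(perturb)
    return out


def extract_features(subjects: list[SubjectRecord],
                     families: tuple = FAMILIES,
                     denoise_audio: bool = False) -> FeatureTable:
    """Extract the full dictionary for a cohort into a FeatureTable."""
    names = feature_dictionary(families)
    rows = []
    for s in subjects:
        vec = extract_subject_features(s, families=families,
                                       denoise_audio=denoise_audio)
        rows.append([vec.get(n, np.nan) for n in names])
    index = [s.subject_id for s in subjects]
    values = pd.DataFrame(rows, columns=names, index=index)
    anthro = anthropometric_frame(subjects)
    values = pd.concat([values, anthro], axis=1)
    labels = pd.Series([s.severity for s in subjects], index=index, name="severity")
    fam_map = feature_family_map(families)
    fam_map.update({c: "anthropometric" for c in ANTHROPOMETRIC_COLUMNS})
    return FeatureTable(values=values, labels=labels, family=fam_map)
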