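"""Synthetic cohorts of deep-breathing subjects with OSA severity labels.

Emulates the study population downstream stages are designed for: four
severity classes defined by apnea-hypopnea-index (AHI) cut-offs, published
per-class anthropometric distributions, a recording protocol of five deep
nose-breathing plus five mouth-breathing cycles per subject, and a
configurable acoustic separation between classes.  The generator is the
test bed for the whole pipeline; it makes no claim of physiological airway
acoustics fidelity.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import yaml
from scipy import signal as sps
from scipy.io import wavfile

from tbscreen.table import FeatureTable, ANTHROPOMETRIC_COLUMNS

SEVERITIES = ("non", "mild", "moderate", "severe")
SEVERITY_RANK = {s: i for i, s in enumerate(SEVERITIES)}

#: AHI intervals (events/h) delimiting the severity classes; the severe
#: class is capped at 150 events/h for sampling purposes only.
AHI_INTERVALS = {
    "non": (0.0, 5.0),
    "mild": (5.0, 15.0),
    "moderate": (15.0, 30.0),
    "severe": (30.0, 150.0),
}

#: Published per-class cohort statistics the default generator matches:
#: subject count, AHI mean/SD, age mean/SD, P(male), BMI mean/SD,
#: Mallampati-score category probabilities, neck-circumference mean/SD.
CLASS_PARAMS = {
    "non": dict(n=74, ahi=(1.18, 1.26), age=(46.84, 12.89), p_male=29 / 74,
                bmi=(30.61, 6.29), mps_probs=(41, 19, 6, 8), nc=(38.78, 4.04)),
    "mild": dict(n=35, ahi=(8.69, 2.58), age=(52.31, 11.57), p_male=21 / 35,
                 bmi=(34.29, 8.41), mps_probs=(18, 6, 9, 1), nc=(42.09, 6.49)),
    "moderate": dict(n=50, ahi=(21.51, 4.23), age=(54.74, 11.33), p_male=36 / 50,
                     bmi=(33.78, 6.39), mps_probs=(17, 17, 8, 8), nc=(43.10, 3.43)),
    "severe": dict(n=40, ahi=(69.54, 33.26), age=(48.98, 11.15), p_male=30 / 40,
                   bmi=(39.75, 8.65), mps_probs=(5, 13, 14, 8), nc=(45.28, 3.64)),
}

# physiologic truncation bounds for continuous anthropometrics
BOUNDS = {"age": (18.0, 90.0), "bmi": (15.0, 60.0), "nc": (25.0, 60.0)}

DEFAULT_RATE = 16000

# breath-cycle timing (s): inspiration, intra-cycle pause, expiration,
# inter-cycle pause.  Deep-breathing plausible values.
CYCLE_TIMING = (1.2, 0.3, 1.6, 0.4)
N_CYCLES = 5


def severity_from_ahi(ahi: float) -> str:
    """Map an AHI (events/h) to its severity class.

    Intervals are left-closed: non < 5 <= mild < 15 <= moderate < 30 <= severe.
    """
    if not np.isfinite(ahi) or ahi < 0:
        raise ValueError(f"AHI must be a non-negative real, got {ahi!r}")
    if ahi < 5:
        return "non"
    if ahi < 15:
        return "mild"
    if ahi < 30:
        return "moderate"
    return "severe"


@dataclass
class BreathRecording:
    samples: np.ndarray
    rate: int
    route: str  # 'nose' or 'mouth'

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.route not in ("nose", "mouth"):
            raise ValueError("route must be 'nose' or 'mouth'")
        if self.samples.size == 0:
            raise ValueError("empty recording")
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("recording contains non-finite samples")

    @property
    def duration(self) -> float:
        return len(self.samples) / self.rate


@dataclass
class SubjectRecord:
    subject_id: str
    ahi: float
    severity: str
    age: float
    sex: str  # 'M'/'F'
    bmi: float
    nc: float
    mps: int
    recordings: list = field(default_factory=list)


@dataclass
class CohortSpec:
    """Configuration of a synthetic cohort; defaults emulate the study cohort."""

    class_sizes: dict = field(
        default_factory=lambda: {s: CLASS_PARAMS[s]["n"] for s in SEVERITIES}
    )
    acoustic_effect_size: float = 1.0
    missing_rate: float = 0.0
    seed: int = 0
    rate: int = DEFAULT_RATE
    with_recordings: bool = True

    def __post_init__(self) -> None:
        if any(n < 0 for n in self.class_sizes.values()):
            raise ValueError("class sizes must be non-negative")
        if not (0 <= self.missing_rate < 1):
            raise ValueError("missing_rate must lie in [0, 1)")
        if self.acoustic_effect_size < 0:
            raise ValueError("acoustic_effect_size must be >= 0")

    def scaled(self, factor: float) -> "CohortSpec":
        sizes = {s: int(round(n * factor)) for s, n in self.class_sizes.items()}
        return replace(self, class_sizes=sizes)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(
                {
                    "class_sizes": dict(self.class_sizes),
                    "acoustic_effect_size": self.acoustic_effect_size,
                    "missing_rate": self.missing_rate,
                    "seed": self.seed,
                    "rate": self.rate,
                },
                fh,
            )


def _truncated_normal(rng, mean, sd, lo, hi, size):
    out = np.empty(size)
    filled = 0
    while filled < size:
        draw = rng.normal(mean, sd, size=size)
        ok = draw[(draw >= lo) & (draw <= hi)]
        take = min(len(ok), size - filled)
        out[filled:filled + take] = ok[:take]
        filled += take
    return out


def _truncated_lognormal(rng, mean, sd, lo, hi, size):
    # moment-matched log-normal, rejection-sampled into the class interval
    sigma2 = np.log1p((sd / mean) ** 2)
    mu = np.log(mean) - sigma2 / 2
    out = np.empty(size)
    filled = 0
    while filled < size:
        draw = rng.lognormal(mu, np.sqrt(sigma2), size=max(size, 8))
        ok = draw[(draw >= lo) & (draw < hi)]
        take = min(len(ok), size - filled)
        out[filled:filled + take] = ok[:take]
        filled += take
    return out


def synth_breath_recording(
    severity: str,
    route: str,
    effect_size: float,
    seed,
    rate: int = DEFAULT_RATE,
) -> BreathRecording:
    """Synthesize one deep-breathing recording of five breath cycles.

    Each cycle is an inspiratory burst (louder) followed, after a short
    intra-cycle pause, by an expiratory burst; cycles are separated by a
    longer pause.  Bursts are pink-ish noise shaped by two resonances whose
    center frequencies shift linearly with the severity index scaled by
    ``effect_size``; a small amount of white sensor noise is added.  With
    ``effect_size = 0`` all classes are identical in distribution.
    """
    if effect_size < 0:
        raise ValueError("effect_size must be >= 0")
    rng = np.random.default_rng(seed)
    k = SEVERITY_RANK[severity]
    insp_s, gap_s, exp_s, pause_s = CYCLE_TIMING

    # class- and route-dependent resonances (Hz)
    route_shift = 120.0 if route == "mouth" else 0.0
    f1 = 450.0 + 90.0 * k * effect_size + route_shift
    f2 = 1300.0 + 180.0 * k * effect_size + 1.5 * route_shift
    tilt = 0.5 + 0.06 * k * effect_size  # 1/f^tilt spectral slope

    def burst(dur, gain):
        n = int(round(dur * rate))
        white = rng.standard_normal(n)
        # pink-ish tilt via frequency-domain shaping
        spec = np.fft.rfft(white)
        freqs = np.fft.rfftfreq(n, 1 / rate)
        shaping = 1.0 / np.maximum(freqs, 40.0) ** tilt
        x = np.fft.irfft(spec * shaping, n)
        # two resonances via peaking IIR filters
        for fc, q in ((f1, 4.0), (f2, 6.0)):
            b, a = sps.iirpeak(fc, q, fs=rate)
            x = x + 2.0 * sps.lfilter(b, a, x)
        x /= np.sqrt(np.mean(x**2)) + 1e-12
        # smooth onset/offset envelope
        env = np.ones(n)
        ramp = max(int(0.08 * rate), 2)
        env[:ramp] = np.sin(np.linspace(0, np.pi / 2, ramp)) ** 2
        env[-ramp:] = np.sin(np.linspace(np.pi / 2, 0, ramp)) ** 2
        return gain * env * x

    pieces = []
    for _ in range(N_CYCLES):
        pieces.append(burst(insp_s, 1.0))
        pieces.append(np.zeros(int(gap_s * rate)))
        pieces.append(burst(exp_s, 0.6))
        pieces.append(np.zeros(int(pause_s * rate)))
    x = np.concatenate(pieces)
    x += 0.01 * rng.standard_normal(len(x))  # sensor noise floor
    return BreathRecording(samples=x, rate=rate, route=route)


def generate_cohort(spec: CohortSpec) -> list[SubjectRecord]:
    """Draw a cohort of subjects matching ``spec``.

    Per-class counts are exact; AHI comes from a class-interval-truncated
    moment-matched log-normal, continuous anthropometrics from truncated
    normals, sex/Mallampati from per-class category probabilities.  Each
    subject owns an RNG stream derived from (cohort seed, severity, index
    within class) so cohorts are stable under class-size edits.
    """
    subjects: list[SubjectRecord] = []
    for sev in SEVERITIES:
        n = spec.class_sizes.get(sev, 0)
        if n == 0:
            warnings.warn(f"class {sev!r} has zero subjects; later stratification may fail")
            continue
        p = CLASS_PARAMS[sev]
        k = SEVERITY_RANK[sev]
        for i in range(n):
            ss = np.random.SeedSequence(entropy=spec.seed, spawn_key=(k, i))
            rng = np.random.default_rng(ss)
            lo, hi = AHI_INTERVALS[sev]
            ahi = float(_truncated_lognormal(rng, *p["ahi"], lo, hi, 1)[0])
            age = float(_truncated_normal(rng, *p["age"], *BOUNDS["age"], 1)[0])
            bmi = float(_truncated_normal(rng, *p["bmi"], *BOUNDS["bmi"], 1)[0])
            nc = float(_truncated_normal(rng, *p["nc"], *BOUNDS["nc"], 1)[0])
            sex = "M" if rng.random() < p["p_male"] else "F"
            mps_p = np.asarray(p["mps_probs"], dtype=float)
            mps = int(rng.choice([1, 2, 3, 4], p=mps_p / mps_p.sum()))
            recs = []
            if spec.with_recordings:
                for route in ("nose", "mouth"):
                    recs.append(
                        synth_breath_recording(
                            sev, route, spec.acoustic_effect_size,
                            seed=np.random.SeedSequence(
                                entropy=spec.seed,
                                spawn_key=(k, i, 0 if route == "nose" else 1),
                            ),
                            rate=spec.rate,
                        )
                    )
            subjects.append(
                SubjectRecord(
                    subject_id=f"{sev}-{i:03d}",
                    ahi=ahi,
                    severity=severity_from_ahi(ahi),
                    age=age,
                    sex=sex,
                    bmi=bmi,
                    nc=nc,
                    mps=mps,
                    recordings=recs,
                )
            )
    return subjects


def cohort_manifest(subjects: list[SubjectRecord]) -> pd.DataFrame:
    rows = [
        dict(subject_id=s.subject_id, ahi=s.ahi, severity=s.severity, age=s.age,
             sex=s.sex, bmi=s.bmi, nc=s.nc, mps=s.mps)
        for s in subjects
    ]
    return pd.DataFrame(rows).set_index("subject_id")


def anthropometric_frame(subjects: list[SubjectRecord]) -> pd.DataFrame:
    """Numeric anthropometric design columns (sex encoded M=1/F=0)."""
    m = cohort_manifest(subjects)
    out = pd.DataFrame(index=m.index)
    out["age"] = m["age"]
    out["sex"] = (m["sex"] == "M").astype(float)
    out["bmi"] = m["bmi"]
    out["nc"] = m["nc"]
    out["mps"] = m["mps"].astype(float)
    return out


# ---------------------------------------------------------------------------
# feature-level cohort (tabular shortcut around the audio chain)
# ---------------------------------------------------------------------------

def generate_feature_cohort(
    spec: CohortSpec,
    feature_names: list[str] | None = None,
    n_informative: int | None = None,
) -> FeatureTable:
    """Draw a cohort directly at the feature-table level.

    Uses the same severity/anthropometric machinery as :func:`generate_cohort`
    but replaces audio synthesis + extraction with class-conditional Gaussian
    acoustic features: feature j of a class-k subject is
    ``loading_j * k * effect_size + N(0, 1)``, with per-feature loadings
    fixed by the feature dictionary (independent of the cohort seed).  This
    is the desk-scale path for questions about tabular pipeline behaviour
    (selection widths, conformal coverage replications) where the audio
    chain adds cost but no information.
    """
    from tbscreen.features import feature_dictionary  # deferred: avoids cycle

    if feature_names is None:
        feature_names = feature_dictionary()
    d = len(feature_names)
    # loadings keyed to the dictionary, not the cohort seed
    load_rng = np.random.default_rng(np.random.SeedSequence(12345))
    loadings = load_rng.normal(0.0, 0.35, size=d)
    if n_informative is not None and n_informative < d:
        loadings[n_informative:] = 0.0

    subjects = generate_cohort(replace(spec, with_recordings=False))
    rng = np.random.default_rng(np.random.SeedSequence(entropy=spec.seed, spawn_key=(99,)))
    rows = []
    for s in subjects:
        k = SEVERITY_RANK[s.severity]
        rows.append(loadings * k * spec.acoustic_effect_size + rng.standard_normal(d))
    values = pd.DataFrame(rows, columns=feature_names,
                          index=[s.subject_id for s in subjects])
    anthro = anthropometric_frame(subjects)
    values = pd.concat([values, anthro], axis=1)
    labels = pd.Series([s.severity for s in subjects], index=values.index, name="severity")
    family = {c: "synthetic" for c in feature_names}
    family.update({c: "anthropometric" for c in ANTHROPOMETRIC_COLUMNS})
    table = FeatureTable(values=values, labels=labels, family=family)
    if spec.missing_rate > 0:
        table = inject_missingness(table, spec.missing_rate, seed=spec.seed)
    return table


def inject_missingness(table: FeatureTable, rate: float, seed: int) -> FeatureTable:
    """Mask anthropometric cells independently with probability ``rate`` (MCAR)."""
    if not (0 <= rate < 1):
        raise ValueError("rate must lie in [0, 1)")
    out = table.copy()
    if rate == 0:
        return out
    rng = np.random.default_rng(seed)
    cols = out.anthropometric_names
    mask = rng.random((len(out.values), len(cols))) < rate
    block = out.values[cols].to_numpy(dtype=float)
    block[mask] = np.nan
    out.values[cols] = block
    out.mask = out.values.isna()
    return out


# ---------------------------------------------------------------------------
# disk I/O
# ---------------------------------------------------------------------------

def write_cohort(subjects: list[SubjectRecord], out_dir, spec: CohortSpec | None = None):
    """Persist a cohort: PCM-16 mono WAVs, manifest CSV, spec YAML."""
    import os

    os.makedirs(out_dir, exist_ok=True)
    manifest = cohort_manifest(subjects).reset_index()
    paths = {"nose": [], "mouth": []}
    for s in subjects:
        for rec in s.recordings:
            rel = f"{s.subject_id}_{rec.route}.wav"
            peak = np.max(np.abs(rec.samples)) or 1.0
            pcm = np.round(rec.samples / peak * 32000).astype(np.int16)
            wavfile.write(os.path.join(out_dir, rel), rec.rate, pcm)
            paths[rec.route].append(rel)
    if paths["nose"]:
        manifest["nose_wav"] = paths["nose"]
        manifest["mouth_wav"] = paths["mouth"]
    manifest.to_csv(os.path.join(out_dir, "manifest.csv"), index=False)
    if spec is not None:
        spec.to_yaml(os.path.join(out_dir, "spec.yaml"))
    return out_dir


def read_cohort(in_dir) -> list[SubjectRecord]:
    """Load a cohort written by :func:`write_cohort`."""
    import os

    manifest = pd.read_csv(os.path.join(in_dir, "manifest.csv"))
    subjects = []
    for _, row in manifest.iterrows():
        recs = []
        for route in ("nose", "mouth"):
            col = f"{route}_wav"
            if col in manifest.columns and isinstance(row[col], str):
                rate, pcm = wavfile.read(os.path.join(in_dir, row[col]))
                recs.append(BreathRecording(pcm.astype(float) / 32000.0, rate, route))
        subjects.append(
            SubjectRecord(
                subject_id=row["subject_id"], ahi=float(row["ahi"]),
                severity=row["severity"], age=float(row["age"]), sex=row["sex"],
                bmi=float(row["bmi"]), nc=float(row["nc"]), mps=int(row["mps"]),
                recordings=recs,
            )
        )
    return subjects
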