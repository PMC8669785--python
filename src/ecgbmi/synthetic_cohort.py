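"""Synthetic cohort generator: phenotypes plus 12-lead ECGs.

Emulates the statistical structure a prediction-residual adiposity analysis
relies on: sex-stratified BMI and age distributions, a visceral adipose
tissue (VAT) volume that is partly explained by BMI and partly independent,
comorbidity labels driven by a latent adiposity score, and ECG morphology
(amplitudes and intervals) driven by the same latent score. Because the
latent score mixes BMI with the BMI-independent VAT residual, a network
predicting BMI from the ECG absorbs VAT signal, and the prediction residual
(predicted minus measured BMI) carries VAT information by construction.

The beat model is a sum of Gaussian wavelets (P, Q, R, S, T) per lead with
fixed lead templates. Adiposity acts on morphology in the directions
reported for obesity: global amplitude attenuation (higher thoracic
impedance) and PR/QRS/QT prolongation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np
from scipy import signal as sps


@lru_cache(maxsize=8)
def _noise_sos(fs: float):
    return sps.butter(4, 45.0, btype="low", fs=fs, output="sos")

__all__ = [
    "LEAD_NAMES",
    "SubjectPhenotype",
    "CohortSpec",
    "ECGRecord",
    "generate_cohort",
    "synthesize_ecg",
    "write_cohort",
]

LEAD_NAMES = ["I", "II", "III", "aVR", "aVL", "aVF", "V1", "V2", "V3", "V4", "V5", "V6"]

COMORBIDITIES = ["htn", "chd", "dm", "dyslip"]

# Per-lead wavelet template amplitudes in mV, columns (P, Q, R, S, T).
# Plausible adult sinus-rhythm morphology: aVR inverted, rS in V1-V2,
# R-wave progression across the precordial leads.
LEAD_TEMPLATES = np.array(
    [
        [0.08, -0.05, 0.70, -0.15, 0.25],  # I
        [0.15, -0.10, 1.10, -0.20, 0.30],  # II
        [0.07, -0.06, 0.50, -0.10, 0.10],  # III
        [-0.12, 0.05, -0.80, 0.15, -0.25],  # aVR
        [0.04, -0.03, 0.35, -0.10, 0.10],  # aVL
        [0.10, -0.08, 0.80, -0.15, 0.20],  # aVF
        [0.05, 0.00, 0.25, -0.90, -0.10],  # V1
        [0.06, 0.00, 0.50, -1.10, 0.35],  # V2
        [0.07, -0.02, 0.80, -0.80, 0.40],  # V3
        [0.09, -0.05, 1.30, -0.50, 0.40],  # V4
        [0.10, -0.08, 1.20, -0.30, 0.35],  # V5
        [0.10, -0.08, 1.00, -0.20, 0.30],  # V6
    ]
)


@dataclass
class SubjectPhenotype:
    """One subject's phenotype row.

    `latent_adiposity` is the hidden generative score driving both the
    comorbidity labels and the ECG morphology; it is never exposed to the
    models (it is excluded from the phenotype CSV).
    """

    subject_id: str
    sex: str  # "male" | "female"
    age: float  # years
    bmi: float  # kg/m^2
    vat: float | None  # litres; None when unmeasured
    htn: int
    chd: int
    dm: int
    dyslip: int
    latent_adiposity: float = 0.0

    def __post_init__(self):
        if not (10.0 < self.bmi < 70.0):
            raise ValueError(f"bmi {self.bmi} outside (10, 70)")
        if self.vat is not None and self.vat < 0:
            raise ValueError("vat must be non-negative")
        if not (40.0 <= self.age <= 80.0):
            raise ValueError(f"age {self.age} outside [40, 80]")


@dataclass
class CohortSpec:
    """Generative parameters for a synthetic cohort.

    Defaults follow the study-population moments of the source cohort:
    male age 63±8 y and BMI 26±5 kg/m², female age 61±7 y and BMI 27±4
    kg/m², 52% female. `morph_coupling` gives the weights of standardized
    BMI and of the standardized BMI-independent VAT residual in the latent
    adiposity score; `(w, 0.0)` switches the VAT signal off.
    """

    n_subjects: int = 1000
    sex_ratio: float = 0.52  # fraction female
    seed: int = 0
    bmi_mean: dict = field(default_factory=lambda: {"male": 26.0, "female": 27.0})
    bmi_sd: dict = field(default_factory=lambda: {"male": 5.0, "female": 4.0})
    age_mean: dict = field(default_factory=lambda: {"male": 63.0, "female": 61.0})
    age_sd: dict = field(default_factory=lambda: {"male": 8.0, "female": 7.0})
    vat_slope: float = 0.2  # L per kg/m^2
    vat_noise_sd: float = 1.0  # L
    morph_coupling: tuple = (0.8, 0.6)  # weights of (bmi, vat residual)
    comorbidity_logit_params: dict = field(
        default_factory=lambda: {
            "htn": (-1.0, 0.9),
            "chd": (-2.3, 0.35),
            "dm": (-2.2, 0.5),
            "dyslip": (-1.2, 0.6),
        }
    )

    def __post_init__(self):
        if self.n_subjects < 8:
            raise ValueError(
                f"n_subjects={self.n_subjects} too small: at least 8 subjects are "
                "needed to fill 4 cross-validation folds with >= 2 subjects each"
            )
        for d in (self.bmi_sd, self.age_sd):
            if any(v <= 0 for v in d.values()):
                raise ValueError("all SDs must be positive")
        if self.vat_noise_sd < 0:
            raise ValueError("vat_noise_sd must be >= 0")


@dataclass
class ECGRecord:
    """One subject's 12-lead signal matrix in millivolts."""

    subject_id: str
    fs: float  # Hz
    signal: np.ndarray  # (12, L)

    def __post_init__(self):
        self.signal = np.asarray(self.signal, dtype=float)
        if self.signal.ndim != 2 or self.signal.shape[0] != 12:
            raise ValueError(f"signal must be 12 x L, got {self.signal.shape}")

    @property
    def duration(self) -> float:
        return self.signal.shape[1] / self.fs


def _latent_adiposity(z_bmi: np.ndarray, z_resid: np.ndarray, coupling: tuple) -> np.ndarray:
    wb, wv = coupling
    norm = float(np.hypot(wb, wv))
    if norm == 0.0:
        return np.zeros_like(z_bmi)
    return (wb * z_bmi + wv * z_resid) / norm


def generate_cohort(spec: CohortSpec) -> list[SubjectPhenotype]:
    """Draw a cohort of phenotypes, deterministically in `spec.seed`.

    Per sex: BMI and age are normal draws (clipped to the physiological
    ranges), VAT is `vat_slope * bmi + eps` with eps ~ N(0, vat_noise_sd),
    latent adiposity is the normalized `morph_coupling` mix of standardized
    BMI and the standardized VAT residual eps, and each comorbidity flag is
    Bernoulli(logistic(intercept + slope * latent)).
    """
    rng = np.random.default_rng(spec.seed)
    n_female = int(round(spec.n_subjects * spec.sex_ratio))
    sexes = ["female"] * n_female + ["male"] * (spec.n_subjects - n_female)
    out: list[SubjectPhenotype] = []
    for i, sex in enumerate(sexes):
        bmi = float(np.clip(rng.normal(spec.bmi_mean[sex], spec.bmi_sd[sex]), 14.0, 60.0))
        age = float(np.clip(rng.normal(spec.age_mean[sex], spec.age_sd[sex]), 40.0, 80.0))
        eps = float(rng.normal(0.0, spec.vat_noise_sd)) if spec.vat_noise_sd > 0 else 0.0
        vat = max(spec.vat_slope * bmi + eps, 0.0)
        z_bmi = (bmi - spec.bmi_mean[sex]) / spec.bmi_sd[sex]
        z_resid = eps / spec.vat_noise_sd if spec.vat_noise_sd > 0 else 0.0
        latent = float(_latent_adiposity(np.float64(z_bmi), np.float64(z_resid), spec.morph_coupling))
        flags = {}
        for cond in COMORBIDITIES:
            a, b = spec.comorbidity_logit_params[cond]
            p = 1.0 / (1.0 + np.exp(-(a + b * latent)))
            flags[cond] = int(rng.random() < p)
        out.append(
            SubjectPhenotype(
                subject_id=f"S{i:05d}",
                sex=sex,
                age=age,
                bmi=bmi,
                vat=vat,
                latent_adiposity=latent,
                **flags,
            )
        )
    return out


def _gauss_add(sig: np.ndarray, t: np.ndarray, amps: np.ndarray, center: float, sigma: float):
    """Add a Gaussian wavelet (one amplitude per lead) onto `sig` in place."""
    lo = np.searchsorted(t, center - 5 * sigma)
    hi = np.searchsorted(t, center + 5 * sigma)
    if hi <= lo:
        return
    g = np.exp(-0.5 * ((t[lo:hi] - center) / sigma) ** 2)
    sig[:, lo:hi] += amps[:, None] * g


def synthesize_ecg(
    phenotype: SubjectPhenotype,
    fs: float = 500.0,
    duration: float = 10.0,
    seed: int = 0,
    k_amp: float = 0.15,
    noise_sd: float = 0.02,
) -> ECGRecord:
    """Synthesize a 12-lead sinus-rhythm record for one subject.

    Let z be the subject's latent adiposity. Morphology rules:

    * global amplitude scale = exp(-k_amp * z)  (impedance attenuation),
    * PR  = 160 + 8 z ms  (clipped to [100, 220]),
    * QRS =  90 + 6 z ms  (clipped to [60, 140]),
    * QT  = 400 + 10 z ms (clipped to [300, 500]),

    heart rate ~ N(62, 6) bpm clipped to [45, 100], R peaks equally spaced
    starting at half a period, plus band-limited additive noise (white noise
    low-passed at 45 Hz, SD `noise_sd` mV). Deterministic given `seed`.
    """
    if fs < 250:
        raise ValueError(f"fs must be >= 250 Hz, got {fs}")
    rng = np.random.default_rng(seed)
    hr = float(np.clip(rng.normal(62.0, 6.0), 45.0, 100.0))
    period = 60.0 / hr
    if duration < period:
        raise ValueError(
            f"duration {duration} s too short for one beat at {hr:.0f} bpm"
        )
    z = phenotype.latent_adiposity
    pr = float(np.clip(160.0 + 8.0 * z, 100.0, 220.0)) / 1000.0
    qrs = float(np.clip(90.0 + 6.0 * z, 60.0, 140.0)) / 1000.0
    qt = float(np.clip(400.0 + 10.0 * z, 300.0, 500.0)) / 1000.0
    scale = float(np.exp(-k_amp * z))

    n = int(round(fs * duration))
    t = np.arange(n) / fs
    sig = np.zeros((12, n))
    amps = LEAD_TEMPLATES * scale
    r_centers = np.arange(period / 2.0, duration, period)
    # (center offset from R, width) per wavelet, in seconds
    waves = [
        (-pr, 0.025, amps[:, 0]),  # P
        (-0.40 * qrs, qrs / 10.0, amps[:, 1]),  # Q
        (0.0, qrs / 6.0, amps[:, 2]),  # R
        (0.40 * qrs, qrs / 10.0, amps[:, 3]),  # S
        (0.70 * qt, qt / 8.0, amps[:, 4]),  # T
    ]
    for rc in r_centers:
        for off, sigma, a in waves:
            _gauss_add(sig, t, a, rc + off, sigma)

    if noise_sd > 0:
        white = rng.normal(0.0, 1.0, size=(12, n))
        noise = sps.sosfiltfilt(_noise_sos(fs), white, axis=1)
        noise *= noise_sd / noise.std()
        sig += noise

    return ECGRecord(subject_id=phenotype.subject_id, fs=fs, signal=sig)


def true_r_centers(fs: float, duration: float, seed: int) -> np.ndarray:
    """Oracle: the R-peak sample indices `synthesize_ecg` places for `seed`."""
    rng = np.random.default_rng(seed)
    hr = float(np.clip(rng.normal(62.0, 6.0), 45.0, 100.0))
    period = 60.0 / hr
    return np.round(np.arange(period / 2.0, duration, period) * fs).astype(int)


def write_cohort(
    phenotypes: list[SubjectPhenotype],
    records: list[ECGRecord],
    out_dir,
) -> dict:
    """Write WFDB records, the phenotype CSV and a JSON manifest.

    Returns the manifest dict. Signals round-trip through
    `cli_io.read_wfdb_record` within the WFDB integer quantization step.
    """
    from . import cli_io  # deferred: cli_io imports the pipeline modules

    return cli_io.write_cohort_files(phenotypes, records, out_dir)
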