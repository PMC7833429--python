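"""Synthetic ECG segments, artefact injection and covariate-shifted features.

Two tiers of synthesis make the whole pipeline testable without any
recording hardware or dataset download:

* **signal level** — clean quasi-periodic ECG built from a per-beat sum
  of five Gaussian waves (P, Q, R, S, T) on a jittered RR grid, plus six
  artefact classes modelled on what contact and capacitive recordings
  exhibit: flat lines, narrow/wide high-amplitude spikes, EMG-band
  (20-40 Hz) noise, low-frequency baseline excursions, amplifier
  saturation, and "floating" records (device on, no subject: pure
  coloured noise);
* **feature level** — Gaussian-mixture draws directly in the 3-D
  (FMin, MAmp, Sim) space for a source ("contact") and a target
  ("capacitive") dataset.  The default target distribution is shifted so
  that the noisy class migrates toward the source's clean region — the
  covariate shift that makes a source-trained classifier lose
  specificity on the target while the two target classes remain
  separable, which is exactly the regime transfer learning addresses.

Dataset profiles mirror the class imbalance of the three study
conditions: polysomnography-like recordings are almost all clean (96.8%
clean), handheld recordings mixed (62.3% clean) and capacitive
recordings mostly noisy (19.5% clean, dominated by floating records).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.signal import butter, sosfilt

from .ingest import EcgSegment

__all__ = [
    "SynthConfig",
    "FeatureShiftConfig",
    "generate_clean_ecg",
    "inject_artefact",
    "generate_dataset",
    "generate_feature_shift",
    "ARTEFACT_KINDS",
    "PROFILE_CLEAN_FRACTION",
]

# (amplitude mV, centre offset from R in s, width in s) of the five waves
PQRST_WAVES = (
    ("P", 0.12, -0.200, 0.025),
    ("Q", -0.12, -0.040, 0.010),
    ("R", 1.00, 0.000, 0.012),
    ("S", -0.25, 0.030, 0.010),
    ("T", 0.30, 0.250, 0.045),
)

ARTEFACT_KINDS = ("flatline", "spike", "emg", "baseline", "saturation",
                  "floating")

PROFILE_CLEAN_FRACTION = {"psg_like": 0.968, "hh_like": 0.623,
                          "cc_like": 0.195}

# per-profile artefact mixture; the capacitive profile is floating-heavy
PROFILE_ARTEFACT_MIX = {
    "psg_like": {"spike": 0.3, "emg": 0.3, "baseline": 0.3, "flatline": 0.1},
    "hh_like": {"spike": 0.35, "emg": 0.35, "baseline": 0.2, "saturation": 0.1},
    "cc_like": {"floating": 0.45, "spike": 0.2, "flatline": 0.15,
                "saturation": 0.1, "emg": 0.1},
}


@dataclass
class SynthConfig:
    """Signal-level dataset recipe."""

    n_segments: int = 100
    duration: float = 15.0
    fs: float = 512.0
    clean_fraction: float | None = None
    artefact_mix: dict[str, float] | None = None
    profile: str = "cc_like"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.profile not in PROFILE_CLEAN_FRACTION:
            raise ValueError(f"unknown profile {self.profile!r}")
        if self.clean_fraction is None:
            self.clean_fraction = PROFILE_CLEAN_FRACTION[self.profile]
        if not 0 <= self.clean_fraction <= 1:
            raise ValueError("clean_fraction must lie in [0, 1]")
        if self.artefact_mix is None:
            self.artefact_mix = dict(PROFILE_ARTEFACT_MIX[self.profile])
        total = sum(self.artefact_mix.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"artefact mix weights sum to {total}, not 1")
        unknown = set(self.artefact_mix) - set(ARTEFACT_KINDS)
        if unknown:
            raise ValueError(f"unknown artefact kinds {sorted(unknown)}")


def generate_clean_ecg(duration: float = 15.0, fs: float = 512.0,
                       heart_rate_bpm: float = 60.0,
                       rr_jitter_sd: float = 0.03,
                       seed: int | np.random.Generator = 0,
                       segment_id: str = "synthetic",
                       modality: str = "synthetic") -> EcgSegment:
    """Clean quasi-periodic ECG: Gaussian PQRST beats on a jittered RR grid.

    ``rr_jitter_sd`` is the per-beat standard deviation of the RR
    interval in seconds (sinus-rhythm variability); a trace of broadband
    measurement noise (10 uV) keeps windows from being exactly periodic.
    """
    if duration < 5:
        raise ValueError("duration must be at least 5 s")
    if not 30 <= heart_rate_bpm <= 200:
        raise ValueError("heart rate must lie in [30, 200] bpm")
    rng = np.random.default_rng(seed) if not isinstance(
        seed, np.random.Generator) else seed
    n = int(round(duration * fs))
    t = np.arange(n) / fs
    rr = 60.0 / heart_rate_bpm
    beats = []
    pos = 0.3 * rr
    while pos < duration + rr:
        beats.append(pos)
        pos += max(0.3, rr + rng.normal(0.0, rr_jitter_sd))
    x = np.zeros(n)
    for beat in beats:
        for _, amp, offset, width in PQRST_WAVES:
            centre = beat + offset
            lo = max(0, int((centre - 5 * width) * fs))
            hi = min(n, int((centre + 5 * width) * fs) + 1)
            if lo < hi:
                x[lo:hi] += amp * np.exp(-0.5 * ((t[lo:hi] - centre) / width) ** 2)
    x += rng.normal(0.0, 0.01, n)
    return EcgSegment(samples=x, fs=fs, label=+1, segment_id=segment_id,
                      modality=modality)


def _bandlimited_noise(n: int, fs: float, lo: float, hi: float,
                       rng: np.random.Generator) -> np.ndarray:
    sos = butter(4, [lo, hi], "bandpass", fs=fs, output="sos")
    noise = sosfilt(sos, rng.standard_normal(n + int(fs)))[int(fs):]
    sd = noise.std()
    return noise / sd if sd > 0 else noise


def inject_artefact(seg: EcgSegment, kind: str, severity: float = 0.5,
                    seed: int | np.random.Generator = 0) -> EcgSegment:
    """Corrupt a copy of a segment with one artefact class (label -1).

    ``severity`` in (0, 1] controls both the corrupted fraction of the
    segment (flatline, spike burst span, EMG, saturation) and the
    artefact amplitude relative to the clean signal.
    """
    if kind not in ARTEFACT_KINDS:
        raise ValueError(f"unknown artefact kind {kind!r}")
    if not 0 < severity <= 1:
        raise ValueError("severity must lie in (0, 1]")
    rng = np.random.default_rng(seed) if not isinstance(
        seed, np.random.Generator) else seed
    x = seg.samples.copy()
    n = x.size
    fs = seg.fs
    span = max(int(severity * n), int(fs))        # corrupted stretch >= 1 s
    span = min(span, n)
    start = int(rng.integers(0, n - span + 1))
    sl = slice(start, start + span)
    scale = max(np.std(x), 1e-3)

    if kind == "flatline":
        x[sl] = 0.0
    elif kind == "spike":
        # high-amplitude electrode-motion transients, mixed narrow (20 ms)
        # and wide (300-600 ms) Gaussian pulses; the pulse drives the
        # amplifier, so it replaces the ECG over its support rather than
        # adding to it
        t = np.arange(n) / fs
        n_pulses = 1 + int(rng.integers(0, 3))
        for _ in range(n_pulses):
            centre = (start + rng.uniform(0, span)) / fs
            width = float(rng.choice([0.020, rng.uniform(0.300, 0.600)]))
            amp = rng.uniform(8, 20) * scale * severity * rng.choice([-1, 1])
            pulse = amp * np.exp(-0.5 * ((t - centre) / width) ** 2)
            support = np.abs(t - centre) < 3 * width
            x[support] = pulse[support]
    elif kind == "emg":
        x[sl] += 3.0 * severity * scale * _bandlimited_noise(span, fs, 20.0,
                                                             40.0, rng)
    elif kind == "baseline":
        t = np.arange(span) / fs
        f1, f2 = rng.uniform(0.3, 0.8), rng.uniform(0.8, 1.6)
        x[sl] += 4.0 * severity * scale * (np.sin(2 * np.pi * f1 * t + rng.uniform(0, 2 * np.pi))
                                           + 0.5 * np.sin(2 * np.pi * f2 * t))
    elif kind == "saturation":
        ceil = (1.05 - severity) * np.max(np.abs(x[sl])) + 1e-6
        x[sl] = np.clip(x[sl], -ceil, ceil)
    elif kind == "floating":
        # device on, no subject: coloured (AR(1)) noise replaces everything
        rho = 0.995
        e = rng.standard_normal(n + 500)
        ar = np.empty_like(e)
        ar[0] = e[0]
        for i in range(1, e.size):
            ar[i] = rho * ar[i - 1] + e[i]
        ar = ar[500:]
        x = severity * scale * ar / max(ar.std(), 1e-12)
    return EcgSegment(samples=x, fs=fs, label=-1,
                      segment_id=f"{seg.segment_id}-{kind}",
                      modality=seg.modality)


def generate_dataset(cfg: SynthConfig) -> list[EcgSegment]:
    """Labelled segment list with the profile's class ratio (after rounding).

    Clean segments are never artefact-injected; noisy segments draw their
    artefact kind from the profile mixture.  Deterministic given the
    config seed.
    """
    if cfg.n_segments < 10:
        raise ValueError("need at least 10 segments")
    rng = np.random.default_rng(cfg.seed)
    n_clean = int(round(cfg.clean_fraction * cfg.n_segments))
    kinds = sorted(cfg.artefact_mix)
    probs = np.array([cfg.artefact_mix[k] for k in kinds])
    segments = []
    for i in range(cfg.n_segments):
        hr = rng.uniform(50, 90)
        seg = generate_clean_ecg(cfg.duration, cfg.fs, heart_rate_bpm=hr,
                                 seed=rng, segment_id=f"{cfg.profile}-{i:05d}",
                                 modality=cfg.profile)
        if i >= n_clean:
            kind = kinds[int(rng.choice(len(kinds), p=probs))]
            seg = inject_artefact(seg, kind,
                                  severity=float(rng.uniform(0.4, 1.0)),
                                  seed=rng)
        segments.append(seg)
    return segments


@dataclass
class FeatureShiftConfig:
    """Gaussian-mixture recipe for source/target 3-D feature sets.

    Means and covariances are in raw feature units (FMin ms, MAmp, Sim).
    The default target places the noisy class between the source classes
    — capacitive artefacts look far more "clean-like" in ACF features
    than contact artefacts do — while the target classes themselves stay
    separable.  ``shift`` is the translation applied to the source clean
    mean to obtain the target clean mean.
    """

    source_clean_mean: np.ndarray = field(
        default_factory=lambda: np.array([35.0, -0.45, 0.6]))
    source_clean_cov: np.ndarray = field(
        default_factory=lambda: np.diag([8.0, 0.14, 0.40]) ** 2)
    source_noisy_mean: np.ndarray = field(
        default_factory=lambda: np.array([90.0, 0.15, 2.8]))
    source_noisy_cov: np.ndarray = field(
        default_factory=lambda: np.diag([40.0, 0.30, 1.10]) ** 2)
    shift: np.ndarray = field(
        default_factory=lambda: np.array([-10.0, -0.10, -0.25]))
    target_clean_mean: np.ndarray | None = None
    target_clean_cov: np.ndarray | None = None
    target_noisy_mean: np.ndarray | None = field(
        default_factory=lambda: np.array([55.0, -0.15, 1.30]))
    target_noisy_cov: np.ndarray | None = field(
        default_factory=lambda: np.diag([15.0, 0.20, 0.60]) ** 2)
    n_source: int = 600
    n_target: int = 3000
    source_clean_fraction: float = 0.623     # handheld-like source
    target_clean_fraction: float = 0.195     # capacitive-like target
    seed: int = 0

    def __post_init__(self) -> None:
        # unspecified target parameters follow the source translated by the
        # shift vector, with mildly inflated covariance (more class overlap
        # in the capacitive modality)
        if self.target_clean_mean is None:
            self.target_clean_mean = self.source_clean_mean + self.shift
        if self.target_clean_cov is None:
            self.target_clean_cov = 1.3 * self.source_clean_cov
        if self.target_noisy_mean is None:
            self.target_noisy_mean = self.source_noisy_mean + self.shift
        if self.target_noisy_cov is None:
            self.target_noisy_cov = 1.3 * self.source_noisy_cov
        for cov in (self.source_clean_cov, self.source_noisy_cov,
                    self.target_clean_cov, self.target_noisy_cov):
            if np.any(np.linalg.eigvalsh(np.asarray(cov)) <= 0):
                raise ValueError("covariances must be positive definite")


def _draw_class_mixture(rng, n, clean_fraction, clean_mean, clean_cov,
                        noisy_mean, noisy_cov):
    n_clean = int(round(clean_fraction * n))
    Xc = rng.multivariate_normal(clean_mean, clean_cov, size=n_clean)
    Xn = rng.multivariate_normal(noisy_mean, noisy_cov, size=n - n_clean)
    X = np.vstack([Xc, Xn])
    # FMin and Sim are non-negative by construction; clip tail draws
    X[:, 0] = np.clip(X[:, 0], 1.0, 250.0)
    X[:, 1] = np.clip(X[:, 1], -1.0, 1.0)
    X[:, 2] = np.maximum(X[:, 2], 0.0)
    y = np.concatenate([np.ones(n_clean), -np.ones(n - n_clean)])
    order = rng.permutation(n)
    return X[order], y[order]


def generate_feature_shift(cfg: FeatureShiftConfig | None = None
                           ) -> tuple[np.ndarray, np.ndarray,
                                      np.ndarray, np.ndarray]:
    """Draw (X_source, y_source, X_target, y_target); seeded."""
    cfg = cfg or FeatureShiftConfig()
    rng = np.random.default_rng(cfg.seed)
    Xs, ys = _draw_class_mixture(rng, cfg.n_source, cfg.source_clean_fraction,
                                 cfg.source_clean_mean, cfg.source_clean_cov,
                                 cfg.source_noisy_mean, cfg.source_noisy_cov)
    Xt, yt = _draw_class_mixture(rng, cfg.n_target, cfg.target_clean_fraction,
                                 cfg.target_clean_mean, cfg.target_clean_cov,
                                 cfg.target_noisy_mean, cfg.target_noisy_cov)
    return Xs, ys, Xt, yt
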