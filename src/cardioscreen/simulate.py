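"""Seeded synthetic phonocardiogram cohort generator.

Emulates an adult echocardiography-referral population: ~45% prevalence of
clinically significant valvular heart disease, ~10% atrial fibrillation,
per-lesion severity frequencies matching a degenerative-VHD case mix, four
auscultation sites with occasional missing recordings (A/T/M jointly present
in ~99% of patients), two electronic-stethoscope colourations, ambient noise
and friction spikes.

Acoustic model (a simulator convention, not a haemodynamic model):

* S1/S2 heart sounds: Gaussian-enveloped damped sinusoids (~45 and ~60 Hz).
* Murmurs: white noise band-passed to a lesion-specific band and shaped by a
  lesion-specific temporal envelope --

  - outflow stenosis (AS/PS): systolic crescendo-decrescendo, 150-400 Hz
  - atrioventricular regurgitation (MR/TR): holosystolic plateau, 100-400 Hz
  - semilunar regurgitation (AR/PR): early-diastolic decrescendo, 200-500 Hz
  - atrioventricular stenosis (MS/TS): mid-diastolic rumble, 40-150 Hz

* Murmur loudness: grade-dependent SNR relative to the S1 RMS
  (mild -6 dB, moderate 0 dB, severe +6 dB) multiplied by a site-specific
  radiation gain, so e.g. aortic stenosis is loudest at the aortic site and
  radiates toward the tricuspid site while mitral regurgitation is loudest
  at the apex.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import signal as sps

from .cohort import (
    AgeBand,
    EchoReport,
    Lesion,
    PatientRecord,
    Recording,
    Rhythm,
    Setting,
    SeverityGrade,
    Sex,
    Site,
    classify_significance,
)

__all__ = [
    "SimConfig",
    "simulate_cycle_times",
    "synthesize_recording",
    "simulate_cohort",
    "simulate_isolated_cohort",
    "murmur_audible",
    "GRADE_FREQUENCIES",
    "RADIATION_GAINS",
    "MURMUR_BANDS",
]

# Per-slot severity frequencies [none/trace, mild, moderate, severe] from the
# emulated case mix (counts out of 1767 patients).
_GRADE_COUNTS: dict[Lesion, tuple[int, int, int, int]] = {
    Lesion.AS: (1442, 61, 91, 173),
    Lesion.AR: (1197, 384, 157, 29),
    Lesion.MS: (1727, 19, 11, 10),
    Lesion.MR: (950, 530, 212, 75),
    Lesion.PS: (1764, 2, 1, 0),
    Lesion.PR: (1450, 284, 32, 1),
    Lesion.TS: (1767, 0, 0, 0),
    Lesion.TR: (1012, 476, 194, 85),
}
GRADE_FREQUENCIES: dict[Lesion, np.ndarray] = {
    slot: np.asarray(counts, dtype=float) / sum(counts) for slot, counts in _GRADE_COUNTS.items()
}

# Linear radiation gain of each lesion's murmur at each site.  Follows
# auscultation teaching: AS radiates from the aortic site through the
# tricuspid site, MR is loudest at the apex, etc.
RADIATION_GAINS: dict[Lesion, dict[Site, float]] = {
    Lesion.AS: {Site.A: 1.0, Site.P: 0.7, Site.T: 0.8, Site.M: 0.5},
    Lesion.AR: {Site.A: 1.0, Site.P: 0.7, Site.T: 0.6, Site.M: 0.4},
    Lesion.MS: {Site.M: 1.0, Site.T: 0.5, Site.A: 0.3, Site.P: 0.3},
    Lesion.MR: {Site.M: 1.0, Site.T: 0.6, Site.A: 0.4, Site.P: 0.4},
    Lesion.PS: {Site.P: 1.0, Site.A: 0.7, Site.T: 0.5, Site.M: 0.4},
    Lesion.PR: {Site.P: 1.0, Site.A: 0.6, Site.T: 0.5, Site.M: 0.4},
    Lesion.TS: {Site.T: 1.0, Site.M: 0.6, Site.A: 0.4, Site.P: 0.4},
    Lesion.TR: {Site.T: 1.0, Site.M: 0.7, Site.A: 0.5, Site.P: 0.5},
}

# (f_lo Hz, f_hi Hz, envelope kind) per lesion.
MURMUR_BANDS: dict[Lesion, tuple[float, float, str]] = {
    Lesion.AS: (150.0, 400.0, "systolic_cd"),
    Lesion.PS: (150.0, 400.0, "systolic_cd"),
    Lesion.MR: (100.0, 400.0, "holosystolic"),
    Lesion.TR: (100.0, 400.0, "holosystolic"),
    Lesion.AR: (200.0, 500.0, "early_diastolic"),
    Lesion.PR: (200.0, 500.0, "early_diastolic"),
    Lesion.MS: (40.0, 150.0, "mid_diastolic"),
    Lesion.TS: (40.0, 150.0, "mid_diastolic"),
}

# Conditional rhythm shares given significance (AF enriched in disease).
_RHYTHM_SHARES_SIG = {Rhythm.SINUS: 577, Rhythm.ATRIAL_FIBRILLATION: 154, Rhythm.PACED: 24, Rhythm.OTHER: 29}
_RHYTHM_SHARES_CTL = {Rhythm.SINUS: 920, Rhythm.ATRIAL_FIBRILLATION: 28, Rhythm.PACED: 12, Rhythm.OTHER: 9}
_AF_MARGINAL_DEFAULT = 182.0 / 1767.0

_AGE_BAND_P = {AgeBand.UNDER_45: 119, AgeBand.FROM_45_TO_65: 277, AgeBand.FROM_65_TO_80: 994, AgeBand.OVER_80: 377}
_P_ACUTE_GIVEN_SIG = 692.0 / 793.0
_P_ACUTE_GIVEN_CTL = 312.0 / 974.0


@dataclass
class SimConfig:
    """All knobs of the synthetic cohort generator (seeded, fully deterministic)."""

    n_patients: int = 600
    prevalence_significant: float = 0.45
    af_fraction: float = _AF_MARGINAL_DEFAULT
    grade_frequencies: dict[Lesion, np.ndarray] = field(
        default_factory=lambda: {k: v.copy() for k, v in GRADE_FREQUENCIES.items()}
    )
    site_presence: dict[Site, float] = field(
        default_factory=lambda: {Site.A: 0.9967, Site.P: 0.70, Site.T: 0.9967, Site.M: 0.9967}
    )
    n_recordings_per_site: int = 1
    heart_rate_range: tuple[float, float] = (55.0, 95.0)
    systole_fraction: float = 0.35
    duration: float = 8.0
    fs: float = 4000.0
    murmur_snr_by_grade: dict[SeverityGrade, float] = field(
        default_factory=lambda: {
            SeverityGrade.MILD: -6.0,
            SeverityGrade.MODERATE: 0.0,
            SeverityGrade.SEVERE: 6.0,
        }
    )
    radiation_gains: dict[Lesion, dict[Site, float]] = field(
        default_factory=lambda: {k: dict(v) for k, v in RADIATION_GAINS.items()}
    )
    audibility_floor_db: float = -16.0
    noise_db: float = -20.0
    spike_rate: float = 0.1
    seed: int = 0

    def validate(self) -> None:
        if self.n_patients < 0:
            raise ValueError("n_patients must be non-negative")
        for name, p in [
            ("prevalence_significant", self.prevalence_significant),
            ("af_fraction", self.af_fraction),
        ]:
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{name} must be a probability, got {p}")
        for site, p in self.site_presence.items():
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"site_presence[{site}] must be a probability")
        for slot, freqs in self.grade_frequencies.items():
            f = np.asarray(freqs, dtype=float)
            if f.shape != (4,) or np.any(f < 0) or not math.isclose(float(f.sum()), 1.0, abs_tol=1e-6):
                raise ValueError(f"grade frequencies for {slot} must be 4 non-negative values summing to 1")
        snrs = [self.murmur_snr_by_grade[g] for g in (SeverityGrade.MILD, SeverityGrade.MODERATE, SeverityGrade.SEVERE)]
        if any(b < a for a, b in zip(snrs, snrs[1:])):
            raise ValueError("murmur SNR must be non-decreasing in grade")
        if not 0 < self.duration <= 15.0:
            raise ValueError("duration must be in (0, 15] s")
        if self.fs <= 0:
            raise ValueError("fs must be positive")


def simulate_cycle_times(
    heart_rate: float,
    rhythm: Rhythm,
    duration: float,
    seed: int | np.random.Generator = 0,
    systole_fraction: float = 0.35,
) -> list[tuple[float, float]]:
    """Sample (S1 onset, S2 onset) pairs covering ``duration`` seconds.

    Sinus rhythm jitters RR intervals with ~2% coefficient of variation;
    atrial fibrillation draws i.i.d. log-normal RR intervals with CV 0.2;
    paced rhythm is near-metronomic; other rhythms reuse sinus timing.
    Systole occupies a fixed fraction (0.35) of the running RR interval.
    """
    if not 30.0 <= heart_rate <= 200.0:
        raise ValueError(f"heart rate {heart_rate} outside the supported 30-200 bpm range")
    if duration < 0:
        raise ValueError("duration must be non-negative")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    rr_mean = 60.0 / heart_rate
    cycles: list[tuple[float, float]] = []
    t = 0.0
    while t < duration:
        if rhythm is Rhythm.ATRIAL_FIBRILLATION:
            cv = 0.2
            sigma = math.sqrt(math.log(1.0 + cv * cv))
            rr = rr_mean * float(np.exp(rng.normal(-0.5 * sigma * sigma, sigma)))
        elif rhythm is Rhythm.PACED:
            rr = rr_mean * float(1.0 + rng.normal(0.0, 0.002))
        else:  # sinus and "other"
            rr = rr_mean * float(1.0 + rng.normal(0.0, 0.02))
        rr = max(rr, 0.25)
        if t + 0.5 * rr > duration:  # a cycle is emitted only if half of it fits
            break
        cycles.append((t, t + systole_fraction * rr))
        t += rr
    return cycles


def _transient(t: np.ndarray, onset: float, freq: float, width: float, amp: float) -> np.ndarray:
    """Gaussian-enveloped damped sinusoid modelling a heart sound."""
    rel = t - onset
    env = np.exp(-0.5 * (rel / width) ** 2)
    return amp * env * np.sin(2.0 * np.pi * freq * rel)


def _murmur_envelope(
    kind: str, t: np.ndarray, cycles: list[tuple[float, float]], duration: float
) -> np.ndarray:
    env = np.zeros_like(t)
    n = len(cycles)
    for i, (s1, s2) in enumerate(cycles):
        next_s1 = cycles[i + 1][0] if i + 1 < n else min(duration, s1 + (s2 - s1) / 0.35)
        if kind in ("systolic_cd", "holosystolic"):
            a, b = s1 + 0.03, s2 - 0.01
            if b <= a:
                continue
            u = (t - a) / (b - a)
            mask = (u >= 0) & (u <= 1)
            if kind == "systolic_cd":
                env[mask] += np.sin(np.pi * u[mask]) ** 2
            else:
                # plateau with raised-cosine edges (15% each side)
                e = np.ones(mask.sum())
                uu = u[mask]
                lo = uu < 0.15
                hi = uu > 0.85
                e[lo] = 0.5 * (1 - np.cos(np.pi * uu[lo] / 0.15))
                e[hi] = 0.5 * (1 - np.cos(np.pi * (1 - uu[hi]) / 0.15))
                env[mask] += e
        elif kind == "early_diastolic":
            a = s2 + 0.04
            b = a + 0.55 * max(next_s1 - s2, 0.05)
            u = (t - a) / max(b - a, 1e-6)
            mask = (u >= 0) & (u <= 1)
            env[mask] += np.exp(-3.0 * u[mask])
        elif kind == "mid_diastolic":
            dia = max(next_s1 - s2, 0.05)
            a = s2 + 0.35 * dia
            b = s2 + 0.9 * dia
            u = (t - a) / max(b - a, 1e-6)
            mask = (u >= 0) & (u <= 1)
            env[mask] += np.sin(np.pi * u[mask]) ** 2
        else:  # pragma: no cover - guarded by MURMUR_BANDS
            raise ValueError(f"unknown envelope kind {kind}")
    return np.clip(env, 0.0, 1.0)


def _windowed_rms(x: np.ndarray, window: np.ndarray, floor: float = 0.05) -> float:
    mask = window > floor * window.max() if window.max() > 0 else np.zeros_like(window, dtype=bool)
    if not mask.any():
        return 0.0
    return float(np.sqrt(np.mean(x[mask] ** 2)))


def _stethoscope_filter(x: np.ndarray, fs: float, variant: int) -> np.ndarray:
    """Two mild IIR colourations emulating different electronic stethoscopes."""
    if variant % 2 == 0:
        sos = sps.butter(1, 900.0, btype="low", fs=fs, output="sos")
        return sps.sosfilt(sos, x)
    sos = sps.butter(1, 150.0, btype="high", fs=fs, output="sos")
    return 0.65 * x + 0.7 * sps.sosfilt(sos, x)


def murmur_audible(echo: EchoReport, site: Site, cfg: SimConfig) -> bool:
    """Would the generator inject any murmur component at this site?

    A lesion contributes iff its grade is at least mild and its effective
    level (grade SNR + radiation gain in dB) clears the audibility floor.
    """
    for slot in Lesion:
        grade = echo.grades[slot]
        if grade < SeverityGrade.MILD:
            continue
        gain = cfg.radiation_gains[slot][site]
        if gain <= 0:
            continue
        eff_db = cfg.murmur_snr_by_grade[grade] + 20.0 * math.log10(gain)
        if eff_db >= cfg.audibility_floor_db:
            return True
    return False


def synthesize_recording(
    echo: EchoReport,
    site: Site,
    cfg: SimConfig,
    seed: int | np.random.Generator = 0,
    *,
    heart_rate: float | None = None,
    stethoscope: int = 0,
    duration: float | None = None,
) -> tuple[Recording, bool]:
    """Render one auscultation-site recording for a given echo report.

    Returns the recording and the generator-known murmur flag: True iff at
    least one murmur component of grade >= mild was injected at this site.
    """
    cfg.validate()
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    duration = cfg.duration if duration is None else duration
    fs = cfg.fs
    n = int(round(duration * fs))
    t = np.arange(n) / fs
    if heart_rate is None:
        heart_rate = float(rng.uniform(*cfg.heart_rate_range))
    cycles = simulate_cycle_times(heart_rate, echo.rhythm, duration, rng, cfg.systole_fraction)

    # Heart sounds (peak amplitude 1 before colouration/normalisation).
    s1s2 = np.zeros(n)
    for s1, s2 in cycles:
        s1s2 += _transient(t, s1 + 0.01, 45.0, 0.012, 1.0)
        s1s2 += _transient(t, s2 + 0.01, 60.0, 0.009, 0.8)
    s1_env = np.zeros(n)
    for s1, _ in cycles:
        s1_env += np.exp(-0.5 * ((t - s1 - 0.01) / 0.012) ** 2)
    ref_rms = _windowed_rms(s1s2, s1_env, floor=0.05)
    if ref_rms == 0.0:
        ref_rms = 1e-3

    wave = s1s2.copy()
    murmur_flag = False
    for slot in Lesion:
        grade = echo.grades[slot]
        if grade < SeverityGrade.MILD:
            continue
        gain = cfg.radiation_gains[slot][site]
        if gain <= 0:
            continue
        eff_db = cfg.murmur_snr_by_grade[grade] + 20.0 * math.log10(gain)
        carrier = rng.standard_normal(n)  # always drawn, so seeds stay aligned across sites
        if eff_db < cfg.audibility_floor_db:
            continue
        f_lo, f_hi, env_kind = MURMUR_BANDS[slot]
        sos = sps.butter(4, [f_lo, f_hi], btype="bandpass", fs=fs, output="sos")
        band = sps.sosfilt(sos, carrier)
        env = _murmur_envelope(env_kind, t, cycles, duration)
        murmur = band * env
        cur = _windowed_rms(murmur, env)
        if cur > 0:
            target = ref_rms * 10.0 ** (eff_db / 20.0)
            wave += murmur * (target / cur)
            murmur_flag = True

    noise = rng.standard_normal(n) * ref_rms * 10.0 ** (cfg.noise_db / 20.0)
    wave = _stethoscope_filter(wave + noise, fs, stethoscope)

    n_spikes = rng.poisson(cfg.spike_rate * duration)
    for _ in range(n_spikes):
        pos = int(rng.integers(0, n))
        width = int(0.004 * fs)
        amp = float(rng.uniform(2.0, 4.0)) * (1 if rng.random() < 0.5 else -1)
        end = min(pos + width, n)
        wave[pos:end] += amp * np.sin(np.pi * np.arange(end - pos) / width)

    wave = np.clip(wave, -1.0, 1.0)
    return Recording(site=site, samples=wave, fs=fs), murmur_flag


def _sample_echo(rng: np.random.Generator, cfg: SimConfig, target_significant: bool, rhythm: Rhythm) -> EchoReport:
    """Rejection-sample a grade grid from the per-slot marginals, conditional on
    the significance label (the marginals alone imply ~51% prevalence; the
    cohort-level prevalence is set explicitly)."""
    slots = list(Lesion)
    for _ in range(100_000):
        grades = {
            slot: SeverityGrade(int(rng.choice(4, p=cfg.grade_frequencies[slot]))) for slot in slots
        }
        echo = EchoReport(grades=grades, rhythm=rhythm)
        if classify_significance(echo) == target_significant:
            return echo
    raise RuntimeError("echo rejection sampling failed; check grade frequencies")


def _rhythm_probs(cfg: SimConfig, significant: bool) -> tuple[list[Rhythm], np.ndarray]:
    shares = _RHYTHM_SHARES_SIG if significant else _RHYTHM_SHARES_CTL
    total = sum(shares.values())
    base = {r: c / total for r, c in shares.items()}
    scale = cfg.af_fraction / _AF_MARGINAL_DEFAULT
    p_af = min(base[Rhythm.ATRIAL_FIBRILLATION] * scale, 1.0)
    others = [r for r in base if r is not Rhythm.ATRIAL_FIBRILLATION]
    rest = sum(base[r] for r in others)
    probs = {Rhythm.ATRIAL_FIBRILLATION: p_af}
    for r in others:
        probs[r] = base[r] / rest * (1.0 - p_af)
    order = [Rhythm.SINUS, Rhythm.ATRIAL_FIBRILLATION, Rhythm.PACED, Rhythm.OTHER]
    return order, np.asarray([probs[r] for r in order])


def simulate_cohort(cfg: SimConfig, render_audio: bool = True) -> list[PatientRecord]:
    """Generate a full labelled cohort (deterministic for a given config).

    With ``render_audio=False`` only echo reports, demographics and murmur
    flags are produced -- enough for allocation and evaluation experiments
    that do not need waveforms.
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    age_bands = list(_AGE_BAND_P)
    age_p = np.asarray([_AGE_BAND_P[b] for b in age_bands], dtype=float)
    age_p /= age_p.sum()

    patients: list[PatientRecord] = []
    for i in range(cfg.n_patients):
        significant = bool(rng.random() < cfg.prevalence_significant)
        order, rprobs = _rhythm_probs(cfg, significant)
        rhythm = order[int(rng.choice(len(order), p=rprobs))]
        echo = _sample_echo(rng, cfg, significant, rhythm)
        sex = Sex.FEMALE if rng.random() < 0.48 else Sex.MALE
        age_band = age_bands[int(rng.choice(len(age_bands), p=age_p))]
        p_acute = _P_ACUTE_GIVEN_SIG if significant else _P_ACUTE_GIVEN_CTL
        setting = Setting.ACUTE_HOSPITAL if rng.random() < p_acute else Setting.PRIMARY_CARE
        heart_rate = float(rng.uniform(*cfg.heart_rate_range))
        stetho = int(rng.integers(0, 2))

        present = [s for s in Site if rng.random() < cfg.site_presence[s]]
        if not present:
            present = [Site.M]

        recordings: dict[Site, list[Recording]] = {}
        murmur_truth: dict[Site, bool] = {}
        for site in Site:
            if site not in present:
                recordings[site] = []
                murmur_truth[site] = False
                continue
            if render_audio:
                recs = []
                flag = False
                for _k in range(cfg.n_recordings_per_site):
                    sub = np.random.default_rng(rng.integers(0, 2**31))
                    rec, f = synthesize_recording(
                        echo, site, cfg, sub, heart_rate=heart_rate, stethoscope=stetho
                    )
                    recs.append(rec)
                    flag = flag or f
                recordings[site] = recs
                murmur_truth[site] = flag
            else:
                recordings[site] = []
                murmur_truth[site] = murmur_audible(echo, site, cfg)
        patients.append(
            PatientRecord(
                id=f"P{i:05d}",
                sex=sex,
                age_band=age_band,
                setting=setting,
                echo=echo,
                recordings=recordings,
                murmur_truth=murmur_truth,
                heart_rate=heart_rate,
                stethoscope=stetho,
            )
        )
    return patients


def simulate_isolated_cohort(
    lesion: Lesion,
    grade: SeverityGrade,
    n: int,
    cfg: SimConfig,
    seed: int = 0,
) -> list[PatientRecord]:
    """Cohort in which every patient carries exactly one lesion at one grade
    (or a clean echo for grade none/trace); used for severity-response and
    radiation analyses."""
    base = replace(cfg, n_patients=n, seed=seed)
    rng = np.random.default_rng(seed)
    echo = EchoReport.from_grades(**{lesion.value: grade}) if grade > 0 else EchoReport.from_grades()
    patients = []
    for i in range(n):
        heart_rate = float(rng.uniform(*base.heart_rate_range))
        stetho = int(rng.integers(0, 2))
        recordings: dict[Site, list[Recording]] = {}
        murmur_truth: dict[Site, bool] = {}
        for site in Site:
            sub = np.random.default_rng(rng.integers(0, 2**31))
            rec, flag = synthesize_recording(
                echo, site, base, sub, heart_rate=heart_rate, stethoscope=stetho
            )
            recordings[site] = [rec]
            murmur_truth[site] = flag
        patients.append(
            PatientRecord(
                id=f"I{lesion.value}{int(grade)}_{i:04d}",
                sex=Sex.FEMALE if rng.random() < 0.5 else Sex.MALE,
                age_band=AgeBand.FROM_65_TO_80,
                setting=Setting.PRIMARY_CARE,
                echo=echo,
                recordings=recordings,
                murmur_truth=murmur_truth,
                heart_rate=heart_rate,
                stethoscope=stetho,
            )
        )
    return patients
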