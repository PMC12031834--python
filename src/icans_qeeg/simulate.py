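"""Synthetic EEG signals, evaluation forms and patient cohorts.

The study design this emulates: B-cell lymphoma patients receive CAR T-cells
on day 0 and undergo routine EEGs at a baseline visit 15-20 days before
infusion and on days +1, +3, +7 and +14; immune effector cell-associated
neurotoxicity (ICANS) strikes roughly a third of patients within the first
two weeks. The generator produces

* multichannel band-structured EEG (posterior-dominant alpha vs. diffuse
  theta/delta slowing) with 1/f background noise, optional lagged
  inter-channel coupling, and annotated high-amplitude artifact bursts;
* visual-read evaluation forms drawn uniformly from the descriptor
  combinations consistent with a target grade;
* whole cohorts in which a latent "slowing" severity drives, coherently,
  (a) the hazard of ICANS through a log-linear proportional-hazards model
  with piecewise-constant covariates updated at each EEG day, (b) the
  qualitative grade of the paired evaluation form, and (c) the theta/delta
  oscillator amplitudes (hence the quantitative band energies) of the paired
  EEG — so the qualitative and quantitative arms of the analysis agree by
  construction and direction-of-effect claims are testable.

Default cohort parameters reproduce the study conditions: ~32% ICANS
incidence with onsets concentrated in days 0-15, baseline grade mix 60:6:2
(grades 0:1:2) per 68 patients, censoring at day 30.
"""
from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from . import grading
from .exceptions import ConfigError
from .features import BANDS, RecordFeatures
from .records import CHANNELS_1020, EEGRecord, PatientTimeline


@dataclass
class EEGSimSpec:
    """Parameters of one simulated multichannel EEG record.

    ``band_amplitudes`` maps band name (delta/theta/alpha/beta) to oscillator
    amplitude in µV; each channel receives one sinusoid per band at a random
    frequency inside the band with random phase. ``couplings`` entries are
    (source_channel, target_channel, lag_samples, gain): the target receives a
    lagged, scaled copy of the source's oscillatory content. ``pink_noise_amp``
    is the RMS (µV) of the 1/f background. ``artifact_fraction`` of the
    duration is covered by annotated high-amplitude transient bursts.
    """

    n_channels: int = 19
    fs: float = 256.0
    duration: float = 60.0
    band_amplitudes: dict[str, float] = field(
        default_factory=lambda: {"delta": 1.0, "theta": 2.0, "alpha": 8.0, "beta": 2.0})
    pink_noise_amp: float = 2.0
    couplings: Sequence[tuple[int, int, int, float]] = ()
    artifact_fraction: float = 0.0
    seed: int = 0
    channel_labels: tuple[str, ...] = CHANNELS_1020

    def __post_init__(self):
        if self.fs < 2 * 40.0:
            raise ConfigError("fs must be at least 80 Hz to represent 0.5-40 Hz content")
        if self.duration <= 0:
            raise ConfigError("duration must be positive")
        if not 0 <= self.artifact_fraction < 1:
            raise ConfigError("artifact_fraction must lie in [0, 1)")
        for src, dst, lag, _gain in self.couplings:
            if not (0 <= src < self.n_channels and 0 <= dst < self.n_channels):
                raise ConfigError(f"coupling ({src}->{dst}) references invalid channel")
            if lag < 0:
                raise ConfigError("coupling lag must be non-negative")
        unknown = set(self.band_amplitudes) - set(BANDS)
        if unknown:
            raise ConfigError(f"unknown bands in band_amplitudes: {sorted(unknown)}")
        self.channel_labels = tuple(self.channel_labels[:self.n_channels])


def _pink_noise(n: int, rng: np.random.Generator) -> np.ndarray:
    """Unit-RMS 1/f noise via spectral shaping of white noise."""
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    freqs = np.fft.rfftfreq(n)
    spec[1:] /= np.sqrt(freqs[1:])
    spec[0] = 0.0
    x = np.fft.irfft(spec, n)
    return x / np.sqrt(np.mean(x ** 2))


def simulate_eeg(spec: EEGSimSpec) -> tuple[EEGRecord, list[tuple[float, float, str]]]:
    """Simulate one record; returns (record, artifact annotations).

    Annotations are (onset_s, duration_s, label) tuples covering approximately
    ``artifact_fraction`` of the duration with 0.5-3 s bursts of ~10x the
    oscillatory amplitude. Bit-identical under a fixed spec (including seed).
    """
    rng = np.random.default_rng(spec.seed)
    n = int(round(spec.duration * spec.fs))
    t = np.arange(n) / spec.fs

    osc = np.zeros((spec.n_channels, n))
    for ch in range(spec.n_channels):
        for band, amp in spec.band_amplitudes.items():
            if amp <= 0:
                continue
            lo, hi = BANDS[band]
            f = rng.uniform(lo + 0.1 * (hi - lo), hi - 0.1 * (hi - lo))
            phi = rng.uniform(0, 2 * np.pi)
            osc[ch] += amp * np.sin(2 * np.pi * f * t + phi)

    signal = osc.copy()
    for src, dst, lag, gain in spec.couplings:
        signal[dst] += gain * np.roll(osc[src], lag)
    if spec.pink_noise_amp > 0:
        for ch in range(spec.n_channels):
            signal[ch] += spec.pink_noise_amp * _pink_noise(n, rng)

    annotations: list[tuple[float, float, str]] = []
    if spec.artifact_fraction > 0:
        scale = 10.0 * max(max(spec.band_amplitudes.values(), default=1.0),
                           spec.pink_noise_amp, 1.0)
        target = spec.artifact_fraction * spec.duration
        covered = 0.0
        occupied: list[tuple[float, float]] = []
        attempts = 0
        while covered < target and attempts < 10_000:
            attempts += 1
            dur = min(rng.uniform(0.5, 3.0), target - covered + 0.5)
            onset = rng.uniform(0, spec.duration - dur)
            if any(onset < e and onset + dur > s for s, e in occupied):
                continue
            occupied.append((onset, onset + dur))
            i0, i1 = int(onset * spec.fs), int((onset + dur) * spec.fs)
            signal[:, i0:i1] += scale * rng.standard_normal((spec.n_channels, i1 - i0))
            annotations.append((onset, dur, "artifact"))
            covered += dur
        annotations.sort()

    record = EEGRecord(signal=signal, fs=spec.fs,
                       channel_labels=spec.channel_labels)
    return record, annotations


# ---------------------------------------------------------------------------
# Evaluation forms
# ---------------------------------------------------------------------------

_FORM_BUCKETS: Optional[dict[int, list]] = None


def _form_buckets() -> dict[int, list]:
    global _FORM_BUCKETS
    if _FORM_BUCKETS is None:
        _FORM_BUCKETS = grading.forms_by_grade()
    return _FORM_BUCKETS


def simulate_eval_form(target_grade: int,
                       seed: int | np.random.Generator = 0) -> grading.EEGEvalForm:
    """Draw an evaluation form that grades exactly to ``target_grade``.

    Sampling is uniform over the grade-relevant descriptor combinations
    consistent with the target grade; descriptors with no grading weight
    (symmetry, PDR, continuity, voltage, EA morphology) are drawn
    independently at random.
    """
    if target_grade not in (0, 1, 2, 3):
        raise ConfigError("target_grade must be 0, 1, 2 or 3")
    rng = (seed if isinstance(seed, np.random.Generator)
           else np.random.default_rng(seed))
    bucket = _form_buckets()[target_grade]
    core = bucket[int(rng.integers(len(bucket)))]
    ea_type = (str(rng.choice(grading.EA_TYPES[:2]))
               if core.ea_prevalence != "none" else None)
    return replace(
        core,
        ea_type=ea_type,
        symmetry=str(rng.choice(grading.SYMMETRY_LEVELS)),
        pdr_present=bool(rng.integers(2)) if core.pbf in grading.NORMAL_PBF else False,
        continuity=str(rng.choice(grading.CONTINUITY_LEVELS[:2])),
        voltage=str(rng.choice(grading.VOLTAGE_LEVELS[:2])),
    )


# ---------------------------------------------------------------------------
# Cohorts
# ---------------------------------------------------------------------------

@dataclass
class CohortSimSpec:
    """Parameters of a simulated CAR T-cell cohort.

    ``schedule`` lists post-infusion EEG days; the baseline EEG day is drawn
    uniformly in [-20, -15] (the pre-infusion assessment window). ``beta``
    maps covariate names to log-hazard coefficients; supported covariates are
    ``slowing`` (latent encephalopathy severity, piecewise-constant, updated
    at each EEG day) and ``group`` (a static Bernoulli(0.5) binary, useful for
    parameter-recovery experiments). ``baseline_hazard`` is the per-day event
    rate at covariate zero; the hazard is confined to the first
    ``risk_window_days`` after infusion (ICANS is an acute toxicity — onsets
    cluster in the first two weeks); non-events are censored at
    ``censor_day``. ``grade_mix`` is the distribution of baseline grades.
    Defaults reproduce ≈32% incidence with onsets in days 0-15.
    """

    n_patients: int = 68
    schedule: tuple[float, ...] = (1.0, 3.0, 7.0, 14.0)
    beta: dict[str, float] = field(default_factory=lambda: {"slowing": 0.8})
    baseline_hazard: float = 0.013
    risk_window_days: Optional[float] = 15.0
    censor_day: float = 30.0
    grade_mix: dict[int, float] = field(
        default_factory=lambda: {0: 60 / 68, 1: 6 / 68, 2: 2 / 68})
    slowing_drift: float = 0.10
    slowing_sd: float = 0.35
    feature_noise_sd: float = 0.25
    seed: int = 0

    def __post_init__(self):
        if self.baseline_hazard < 0:
            raise ConfigError("baseline_hazard must be non-negative")
        if self.censor_day <= 0:
            raise ConfigError("censor_day must be positive")
        if list(self.schedule) != sorted(self.schedule):
            raise ConfigError("schedule must be sorted")
        if self.risk_window_days is not None and self.risk_window_days <= 0:
            raise ConfigError("risk_window_days must be positive")
        unknown = set(self.beta) - {"slowing", "group"}
        if unknown:
            raise ConfigError(f"unknown covariates in beta: {sorted(unknown)}")


def _slowing_to_amplitudes(s: float) -> dict[str, float]:
    """Monotone link from latent slowing to band oscillator amplitudes (µV).

    Theta (and beyond grade ~1, delta) amplitude rises with slowing while the
    posterior alpha attenuates — diffuse background slowing.
    """
    return {
        "delta": 1.0 + 2.0 * max(0.0, s - 1.0),
        "theta": 2.0 + 3.0 * s,
        "alpha": max(1.5, 8.0 - 1.5 * s),
        "beta": max(0.5, 2.0 - 0.3 * s),
    }


def _amplitudes_to_features(amps: dict[str, float], rng: np.random.Generator,
                            noise_sd: float, slowing: float) -> RecordFeatures:
    """Band energies implied by the oscillator amplitudes (A²/2 per band plus a
    1/f floor), with multiplicative log-normal measurement noise."""
    floor = {"delta": 0.8, "theta": 0.5, "alpha": 0.3, "beta": 0.2}
    e = {}
    for band in BANDS:
        noise = float(np.exp(rng.normal(0.0, noise_sd)))
        e[band] = (amps[band] ** 2 / 2.0 + floor[band]) * noise
    ent = 3.0 - 0.3 * slowing + float(rng.normal(0.0, 0.15))
    fd = float(np.clip(1.7 - 0.12 * slowing + rng.normal(0.0, 0.05), 1.0, 2.0))
    return RecordFeatures(
        med_e_delta=e["delta"], med_e_theta=e["theta"],
        med_e_alpha=e["alpha"], med_e_beta=e["beta"],
        dtar=(e["delta"] + e["theta"]) / e["alpha"],
        med_entropy=ent, med_fractal=fd,
    )


def _slowing_to_grade(s: float) -> int:
    return int(np.clip(np.floor(s), 0, 3))


def _sample_event_time(knots: list[float], rates: list[float], end: float,
                       rng: np.random.Generator) -> Optional[float]:
    """Inverse-transform sample from a piecewise-exponential hazard.

    ``knots`` are the left edges of the constant-rate intervals (first knot 0,
    last interval extends to ``end``, where the hazard stops); returns the
    event time or None if no event occurs by ``end``.
    """
    e = rng.exponential()
    acc = 0.0
    edges = list(knots) + [end]
    for k in range(len(rates)):
        width = edges[k + 1] - edges[k]
        if width <= 0:
            continue
        if acc + rates[k] * width >= e:
            if rates[k] == 0:
                continue
            return edges[k] + (e - acc) / rates[k]
        acc += rates[k] * width
    return None


def simulate_cohort(spec: CohortSimSpec) -> list[PatientTimeline]:
    """Simulate a cohort of patient timelines under a proportional-hazards model.

    For each patient a latent slowing trajectory (baseline value set by the
    drawn baseline grade, random drift at each post-infusion EEG) defines a
    piecewise-constant covariate vector x(t), updated at each EEG day; the
    ICANS onset time is drawn from the hazard
    h(t) = baseline_hazard * exp(beta . x(t)), censored at ``censor_day``.
    Each EEG day gets a grade, an evaluation form consistent with that grade,
    a parametric feature set, and an :class:`EEGSimSpec` whose theta/delta
    amplitudes rise monotonically with the slowing covariate.
    """
    rng = np.random.default_rng(spec.seed)
    grades_mix = sorted(spec.grade_mix.items())
    mix_vals = [g for g, _ in grades_mix]
    mix_p = np.array([p for _, p in grades_mix], dtype=float)
    mix_p = mix_p / mix_p.sum()

    timelines = []
    for pid in range(spec.n_patients):
        baseline_day = float(rng.uniform(-20.0, -15.0))
        eeg_days = [baseline_day] + [float(d) for d in spec.schedule]

        g0 = int(rng.choice(mix_vals, p=mix_p))
        s = g0 + float(rng.uniform(0.0, 1.0)) if g0 > 0 else float(rng.uniform(0.0, 0.8))
        slowing = [s]
        for _ in spec.schedule:
            s = max(0.0, s + spec.slowing_drift + float(rng.normal(0.0, spec.slowing_sd)))
            slowing.append(s)
        group = int(rng.integers(2))

        # Hazard knots: day 0 (baseline covariate applies) then each EEG day;
        # the hazard runs out at the end of the acute risk window.
        risk_end = spec.censor_day
        if spec.risk_window_days is not None:
            risk_end = min(risk_end, spec.risk_window_days)
        knots = [0.0] + [d for d in spec.schedule if d < risk_end]
        rates = []
        for k, knot in enumerate(knots):
            x = {"slowing": slowing[k], "group": float(group)}
            lp = sum(spec.beta.get(name, 0.0) * x[name] for name in spec.beta)
            rates.append(spec.baseline_hazard * float(np.exp(lp)))
        icans_day = _sample_event_time(knots, rates, risk_end, rng)

        grades, forms, feats, specs = [], [], [], []
        for idx, s_val in enumerate(slowing):
            g = _slowing_to_grade(s_val)
            grades.append(g)
            forms.append(simulate_eval_form(g, rng))
            amps = _slowing_to_amplitudes(s_val)
            feats.append(_amplitudes_to_features(amps, rng,
                                                 spec.feature_noise_sd, s_val))
            specs.append(EEGSimSpec(
                band_amplitudes=amps, duration=60.0,
                seed=int(rng.integers(2 ** 31))))

        timelines.append(PatientTimeline(
            patient_id=f"P{pid:04d}", eeg_days=eeg_days, grades=grades,
            features=feats, icans_day=icans_day, censor_day=spec.censor_day,
            forms=forms, eeg_specs=specs,
            covariates={"slowing": slowing, "group": float(group)},
        ))
    return timelines


# ---------------------------------------------------------------------------
# On-disk formats: EDF, annotation CSV, cohort CSV, form JSON
# ---------------------------------------------------------------------------

def write_edf(path, record: EEGRecord) -> None:
    """Write an :class:`EEGRecord` as a 16-bit EDF file (1 s data records).

    Minimal but conformant writer: ASCII header, per-channel physical range
    taken from the data, samples quantized to the full digital range.
    Requires an integer sampling rate; the signal is zero-padded to a whole
    number of seconds.
    """
    fs = int(round(record.fs))
    if abs(fs - record.fs) > 1e-9:
        raise ConfigError("EDF writer requires an integer sampling rate")
    n_ch = record.n_channels
    n_rec = int(np.ceil(record.n_samples / fs))
    data = np.zeros((n_ch, n_rec * fs))
    data[:, :record.n_samples] = record.signal

    phys_min = np.floor(data.min(axis=1)) - 1.0
    phys_max = np.ceil(data.max(axis=1)) + 1.0
    dig_min, dig_max = -32768, 32767

    def pad(value, width):
        s = str(value)[:width]
        return s.ljust(width)

    header = "".join([
        pad("0", 8),                       # version
        pad(record.patient_id or "X", 80),  # patient id
        pad("synthetic", 80),              # recording id
        pad("01.01.20", 8), pad("00.00.00", 8),
        pad(256 + 256 * n_ch, 8),          # header bytes
        pad("", 44),
        pad(n_rec, 8), pad("1", 8), pad(n_ch, 4),
    ])
    header += "".join(pad(f"EEG {lab}", 16) for lab in record.channel_labels)
    header += "".join(pad("AgAgCl", 80) for _ in range(n_ch))
    header += "".join(pad("uV", 8) for _ in range(n_ch))
    header += "".join(pad(f"{phys_min[c]:.0f}", 8) for c in range(n_ch))
    header += "".join(pad(f"{phys_max[c]:.0f}", 8) for c in range(n_ch))
    header += "".join(pad(dig_min, 8) for _ in range(n_ch))
    header += "".join(pad(dig_max, 8) for _ in range(n_ch))
    header += "".join(pad("", 80) for _ in range(n_ch))
    header += "".join(pad(fs, 8) for _ in range(n_ch))
    header += "".join(pad("", 32) for _ in range(n_ch))

    gain = (phys_max - phys_min) / (dig_max - dig_min)
    with open(path, "wb") as fh:
        fh.write(header.encode("ascii"))
        for r in range(n_rec):
            chunk = data[:, r * fs:(r + 1) * fs]
            dig = np.round((chunk - phys_min[:, None]) / gain[:, None] + dig_min)
            fh.write(dig.astype("<i2").tobytes())


def write_annotations_csv(path, annotations) -> None:
    pd.DataFrame(annotations, columns=["onset_s", "duration_s", "label"]).to_csv(
        path, index=False)


def read_annotations_csv(path) -> list[tuple[float, float]]:
    df = pd.read_csv(path)
    return list(zip(df["onset_s"].astype(float), df["duration_s"].astype(float)))


def cohort_to_frame(timelines: list[PatientTimeline]) -> pd.DataFrame:
    """Long-format cohort table: one row per (patient, EEG day)."""
    rows = []
    for tl in timelines:
        excluded = tl.excluded
        for k, day in enumerate(tl.eeg_days):
            row = {
                "patient_id": tl.patient_id, "day": day,
                "grade": tl.grades[k], "excluded": excluded[k],
                "icans_day": tl.icans_day if tl.icans_day is not None else np.nan,
                "censor_day": tl.censor_day,
            }
            row.update(tl.features[k].as_dict())
            rows.append(row)
    return pd.DataFrame(rows)


def write_forms_json(path, timelines: list[PatientTimeline]) -> None:
    from dataclasses import asdict
    payload = {
        tl.patient_id: [
            {"day": day, **asdict(form)}
            for day, form in zip(tl.eeg_days, tl.forms)
        ]
        for tl in timelines
    }
    Path(path).write_text(json.dumps(payload, indent=1))
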