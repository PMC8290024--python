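"""Seeded simulator of week-long ambulatory circadian monitoring recordings.

Emulates the two-logger setup of an ACM study: wrist skin temperature
sampled every 10 min and arm tilt sampled every 30 s, for healthy sleepers
and sleep-disordered-breathing (SDB) phenotypes of increasing severity,
plus a post-CPAP condition.

The generative model, per subject:

* a nightly sleep window (default onset 23:30 + Gaussian day-to-day jitter,
  8 h duration) during which the arm is near-horizontal and quiet;
* daytime wake with large sample-to-sample tilt fluctuations (high motor
  activity) around an upright posture, and an optional afternoon nap that
  lowers posture only;
* nocturnal arousal bursts as a homogeneous Poisson process within the
  sleep window at rate ``arousal_gain * ahi * cpap_factor`` bursts/hour
  (default gain 0.25 bursts per respiratory event-hour), each burst
  raising the tilt angle for 1-3 samples with exponentially distributed
  amplitude — the actigraphic signature of apnoea-related arousals;
* an inverse circadian wrist-temperature profile (warm in the sleep
  window, cooler by day) with a transient 0.5 degC drop after each arousal,
  decaying over ~20 min, mimicking sympathetic vasoconstriction.

Severity bins follow the clinical AHI strata: mild < 15, moderate 15-30,
severe > 30 events/hour.  Identical (spec, days, seed) yields bit-identical
recordings.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import AcmRecording, RawSamples, write_tilt_log, write_wt_log

#: arbitrary but fixed recording epoch (a Monday); all series start at midnight
EPOCH = pd.Timestamp("2022-03-07 00:00:00")

TILT_STEP_S = 30
WT_STEP_MIN = 10

LABELS = ("healthy", "mild", "moderate", "severe", "cpap")

#: default AHI per phenotype, events/hour (mid-bin values for the strata)
DEFAULT_AHI = {"healthy": 2.0, "mild": 8.0, "moderate": 22.0, "severe": 40.0}


@dataclass(frozen=True)
class PhenotypeSpec:
    """Simulator parameters for one phenotype.

    ``arousal_rate`` (bursts/hour of sleep) is derived as
    ``arousal_gain * ahi`` and further multiplied by ``cpap_factor``
    at generation time.
    """

    label: str
    ahi: float
    arousal_gain: float = 0.25
    phase_jitter_sd: float = 30.0  # minutes
    sleep_onset: float = 23.5  # clock hours
    sleep_duration: float = 8.0  # hours
    nap_probability: float = 0.3  # per day
    cpap_factor: float = 1.0
    wt_noise_sd: float = 0.3  # degC
    sleep_tilt_sd: float = 1.5  # deg per 30-s sample
    wake_tilt_sd: float = 20.0  # deg per 30-s sample
    burst_amplitude: float = 35.0  # deg, exponential mean
    wt_arousal_drop: float = 0.5  # degC
    wt_arousal_tau: float = 20.0  # minutes

    def __post_init__(self) -> None:
        if self.label not in LABELS:
            raise ValueError(f"unknown phenotype label {self.label!r}")
        for name in (
            "ahi",
            "arousal_gain",
            "phase_jitter_sd",
            "nap_probability",
            "wt_noise_sd",
            "sleep_tilt_sd",
            "wake_tilt_sd",
            "burst_amplitude",
            "wt_arousal_drop",
            "wt_arousal_tau",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if not 0.0 <= self.cpap_factor <= 1.0:
            raise ValueError("cpap_factor must lie in [0, 1]")
        if self.cpap_factor != 1.0 and self.label != "cpap":
            raise ValueError("cpap_factor < 1 requires label 'cpap'")
        if self.label == "mild" and not self.ahi < 15:
            raise ValueError("mild phenotype requires ahi < 15")
        if self.label == "moderate" and not 15 <= self.ahi <= 30:
            raise ValueError("moderate phenotype requires 15 <= ahi <= 30")
        if self.label == "severe" and not self.ahi > 30:
            raise ValueError("severe phenotype requires ahi > 30")
        if not 0 < self.sleep_duration < 24:
            raise ValueError("sleep_duration must lie in (0, 24) hours")

    @property
    def arousal_rate(self) -> float:
        """Nocturnal arousal-burst rate before CPAP attenuation, bursts/hour."""
        return self.arousal_gain * self.ahi


def phenotype(label: str, **overrides) -> PhenotypeSpec:
    """Default :class:`PhenotypeSpec` for a named phenotype.

    ``cpap`` defaults to a severe baseline with ``cpap_factor = 0.2``.
    """
    if label == "cpap":
        kw = {"ahi": DEFAULT_AHI["severe"], "cpap_factor": 0.2}
    else:
        kw = {"ahi": DEFAULT_AHI[label]}
    kw.update(overrides)
    return PhenotypeSpec(label=label, **kw)


def apply_cpap(spec: PhenotypeSpec, factor: float) -> PhenotypeSpec:
    """Copy of ``spec`` under CPAP: arousal rate scaled by ``factor`` in [0, 1]."""
    if not 0.0 <= factor <= 1.0:
        raise ValueError("CPAP factor must lie in [0, 1]")
    return dataclasses.replace(spec, label="cpap", cpap_factor=factor)


@dataclass(frozen=True)
class CohortSpec:
    """A simulated cohort: (phenotype, n) groups with shared recording length."""

    groups: tuple[tuple[PhenotypeSpec, int], ...]
    days: int = 7
    seed: int = 0
    age_range: tuple[float, float] = (40.0, 65.0)
    male_fraction: float = 0.7
    bmi_range: tuple[float, float] = (24.0, 36.0)

    def __post_init__(self) -> None:
        object.__setattr__(self, "groups", tuple((s, int(n)) for s, n in self.groups))
        if not self.groups:
            raise ValueError("cohort needs at least one group")
        if self.days < 6:
            raise ValueError("need >= 6 recording days for reliable non-parametric analysis")
        for spec, n in self.groups:
            if n < 2:
                raise ValueError(f"group {spec.label!r} needs n >= 2 for group summaries")


def _sleep_windows(spec: PhenotypeSpec, days: int, rng: np.random.Generator) -> np.ndarray:
    """(start_min, end_min) of each night's sleep window on the recording clock.

    Night d starts near hour ``sleep_onset`` of day d; night -1 covers the
    recording's first morning.
    """
    out = []
    for d in range(-1, days):
        onset = d * 1440 + spec.sleep_onset * 60 + rng.normal(0.0, spec.phase_jitter_sd)
        out.append((onset, onset + spec.sleep_duration * 60))
    return np.array(out)


def generate_subject(
    spec: PhenotypeSpec,
    days: int = 7,
    seed: int = 0,
    subject_id: str | None = None,
) -> AcmRecording:
    """Simulate one subject's week of WT (10-min) and tilt (30-s) logs."""
    if days < 1:
        raise ValueError("days must be >= 1")
    rng = np.random.default_rng(seed)
    total_min = days * 1440

    windows = _sleep_windows(spec, days, rng)

    # tilt channel, 30-s cadence
    n_tilt = days * 86400 // TILT_STEP_S
    t_tilt = np.arange(n_tilt) * (TILT_STEP_S / 60.0)  # minutes
    asleep = np.zeros(n_tilt, dtype=bool)
    for s, e in windows:
        asleep |= (t_tilt >= s) & (t_tilt < e)

    napping = np.zeros(n_tilt, dtype=bool)
    for d in range(days):
        if rng.random() < spec.nap_probability:
            nap_start = d * 1440 + rng.uniform(14.0, 16.0) * 60
            nap_end = nap_start + rng.uniform(30.0, 90.0)
            napping |= (t_tilt >= nap_start) & (t_tilt < nap_end)
    napping &= ~asleep

    angle = 45.0 + rng.normal(0.0, spec.wake_tilt_sd, n_tilt)
    sleep_base = 5.0 + rng.normal(0.0, spec.sleep_tilt_sd, n_tilt)
    nap_base = 10.0 + rng.normal(0.0, 3.0, n_tilt)
    angle[asleep] = sleep_base[asleep]
    angle[napping] = nap_base[napping]

    # nocturnal arousal bursts: Poisson in each sleep window
    rate = spec.arousal_rate * spec.cpap_factor  # bursts/hour
    arousal_times: list[float] = []
    for s, e in windows:
        lo, hi = max(s, 0.0), min(e, total_min)
        if hi <= lo:
            continue
        n_ev = rng.poisson(rate * (hi - lo) / 60.0)
        times = np.sort(rng.uniform(lo, hi, n_ev))
        lengths = rng.integers(1, 4, n_ev)  # 1-3 samples of 30 s
        amps = rng.exponential(spec.burst_amplitude, n_ev)
        for t0, ln, amp in zip(times, lengths, amps):
            i0 = int(t0 * 60 // TILT_STEP_S)
            angle[i0 : i0 + ln] = 5.0 + amp
        arousal_times.extend(times)
    angle = np.clip(angle, 0.0, 90.0)

    # wrist temperature, 10-min cadence: inverse profile (warm asleep)
    n_wt = total_min // WT_STEP_MIN
    t_wt = np.arange(n_wt) * float(WT_STEP_MIN)
    wt_asleep = np.zeros(n_wt, dtype=bool)
    for s, e in windows:
        wt_asleep |= (t_wt >= s) & (t_wt < e)
    wt = np.where(wt_asleep, 35.5, 33.5)
    # ~1 h raised transitions so onsets/offsets are not step functions
    kernel = np.ones(5) / 5.0
    wt = np.convolve(np.pad(wt, 2, mode="edge"), kernel, mode="valid")
    for t0 in arousal_times:
        after = t_wt >= t0
        wt[after] -= spec.wt_arousal_drop * np.exp(-(t_wt[after] - t0) / spec.wt_arousal_tau)
    wt += rng.normal(0.0, spec.wt_noise_sd, n_wt)
    wt = np.clip(wt, 20.0, 40.0)

    sid = subject_id or f"{spec.label}_s{seed}"
    meta = {"group": spec.label, "seed": seed, "ahi": spec.ahi, "days": days}
    wt_raw = RawSamples(
        EPOCH + pd.to_timedelta(t_wt, unit="m"), wt, units="degC"
    )
    tilt_raw = RawSamples(
        EPOCH + pd.to_timedelta(t_tilt, unit="m"), angle, units="deg"
    )
    return AcmRecording(subject_id=sid, wt_raw=wt_raw, tilt_raw=tilt_raw, metadata=meta)


def subject_seed(cohort_seed: int, index: int) -> int:
    """Deterministic per-subject seed derived from the cohort seed."""
    ss = np.random.SeedSequence([int(cohort_seed), int(index)])
    return int(ss.generate_state(1)[0] % (2**31))


def generate_cohort(spec: CohortSpec) -> tuple[list[AcmRecording], pd.DataFrame]:
    """Simulate all subjects of a cohort plus its manifest.

    Per-subject seeds derive deterministically from the cohort seed; the
    demographics in the manifest are decorative covariates, drawn from the
    cohort ranges and unused by generation.
    """
    demo_rng = np.random.default_rng(np.random.SeedSequence([int(spec.seed), 987654321]))
    recordings: list[AcmRecording] = []
    rows = []
    index = 0
    for pheno, n in spec.groups:
        for j in range(n):
            seed = subject_seed(spec.seed, index)
            sid = f"{pheno.label}_{j:03d}"
            rec = generate_subject(pheno, days=spec.days, seed=seed, subject_id=sid)
            age = demo_rng.uniform(*spec.age_range)
            sex = "M" if demo_rng.random() < spec.male_fraction else "W"
            bmi = demo_rng.uniform(*spec.bmi_range)
            rec.metadata.update({"age": round(age, 1), "sex": sex, "bmi": round(bmi, 1)})
            recordings.append(rec)
            rows.append(
                {
                    "subject_id": sid,
                    "group": pheno.label,
                    "age": round(age, 1),
                    "sex": sex,
                    "bmi": round(bmi, 1),
                    "seed": seed,
                }
            )
            index += 1
    return recordings, pd.DataFrame(rows)


def write_cohort(recordings: list[AcmRecording], manifest: pd.DataFrame, outdir) -> None:
    """Write device-dialect CSVs and the cohort manifest to a directory."""
    import os

    os.makedirs(outdir, exist_ok=True)
    for rec in recordings:
        write_wt_log(os.path.join(outdir, f"{rec.subject_id}_wt.csv"), rec.wt_raw)
        write_tilt_log(os.path.join(outdir, f"{rec.subject_id}_tilt.csv"), rec.tilt_raw)
    manifest.to_csv(os.path.join(outdir, "manifest.csv"), index=False)
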