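"""Synthetic overnight RR cohorts with prescribed apnea severity.

The generator emulates the structure of a dual-sensor clinical study: every
subject has one underlying whole-night beat process, rendered twice — once
for a wearable textile-electrode ECG belt and once for conventional patched
(gel-electrode) ECG — with sensor-specific artifact burdens (belt >> patch).

The instantaneous RR trajectory of a subject is

    rr(t) = baseline + LF sinusoid (~0.1 Hz) + respiratory sinus arrhythmia
            (~0.25 Hz) + per-event cyclic bradycardia–tachycardia swing,

where apnea events are placed as a homogeneous Poisson process at the
subject's AHI rate; during each event the RR interval lengthens through a
half-cosine ramp (bradycardia) and recovers with a sharp post-event
tachycardic undershoot.  Beats are generated by integrate-and-fire over this
trajectory so that event timing and tachogram spectra are physically
consistent: event power lands in the ULF/VLF bands, in proportion to the
event rate.

Clinical variables: AHI is drawn from a two-component lognormal mixture —
a "no apnea detected" fraction with low AHI and an apnea-patient component —
calibrated to a referral-cohort profile (median AHI ~21/h, IQR ~7–40/h,
~18% without apnea).  ODI is a noisy linear function of AHI; ESS (daytime
sleepiness) is drawn independently of AHI, so sleepiness carries no HRV
signal by construction.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .rr_io import APNEA_TYPES, CohortManifest, RRSeries

logger = logging.getLogger(__name__)

# substream tags, kept distinct so sensor renderings share the beat process
_STREAM_CLINICAL = 101
_STREAM_BEATS = 202
_STREAM_EVENTS = 303
_STREAM_ARTIFACTS = 404

#: apnea-type frequencies among apnea patients (obstructive, central, mixed)
_APNEA_TYPE_P = (157 / 197, 5 / 197, 35 / 197)


@dataclass
class SyntheticConfig:
    """Study conditions for the synthetic cohort.

    Rates and amplitudes are per-subject population values; per-subject
    variability (baseline RR, amplitude jitter) models inter-individual
    physiology and keeps classification non-trivial.
    """

    n_subjects: int = 200
    night_duration_s: float = 25200.0          # 7 h
    mean_rr_ms: float = 1000.0
    mean_rr_sd_ms: float = 80.0                # inter-subject baseline spread
    lf_amp_ms: float = 25.0
    lf_freq_hz: float = 0.10
    hf_amp_ms: float = 20.0                    # respiratory sinus arrhythmia
    hf_freq_hz: float = 0.25
    amp_jitter: float = 0.3                    # +-30% per-subject amplitude scatter
    jitter_ms: float = 8.0                     # per-beat white RR jitter
    apnea_cycle_s: tuple[float, float] = (30.0, 80.0)
    apnea_swing_ms: float = 120.0              # peak RR lengthening per event
    # AHI mixture: apnea patients ~ lognormal(mu, sigma); a no-apnea fraction
    # draws from a low-AHI component. Calibrated to median ~21/h, IQR ~7-40/h.
    ahi_lognormal_mu: float = 3.30
    ahi_lognormal_sigma: float = 0.98
    no_apnea_fraction: float = 0.18
    no_apnea_ahi_mu: float = 0.69
    no_apnea_ahi_sigma: float = 0.6
    odi_slope: float = 0.8
    odi_noise_sd: float = 5.0
    ess_range: tuple[float, float] = (0.0, 24.0)
    ess_mean: float = 9.0
    ess_sd: float = 4.4
    artifact_rate_belt: float = 30.0           # events per hour
    artifact_rate_patch: float = 3.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subjects < 1:
            raise ValueError("n_subjects must be >= 1")
        if self.night_duration_s < 300.0:
            raise ValueError("night_duration_s must cover at least one 300 s spectral window")
        for name in ("mean_rr_ms", "lf_amp_ms", "hf_amp_ms", "apnea_swing_ms",
                     "lf_freq_hz", "hf_freq_hz", "jitter_ms", "odi_noise_sd",
                     "artifact_rate_belt", "artifact_rate_patch",
                     "ahi_lognormal_sigma", "no_apnea_ahi_sigma"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.artifact_rate_belt < self.artifact_rate_patch:
            raise ValueError("artifact_rate_belt must be >= artifact_rate_patch")
        if not 0 <= self.no_apnea_fraction <= 1:
            raise ValueError("no_apnea_fraction must be in [0, 1]")
        lo, hi = self.apnea_cycle_s
        if not 0 < lo <= hi:
            raise ValueError("apnea_cycle_s must be a positive (low, high) range")


@dataclass
class SubjectRecord:
    """Clinical variables plus the per-sensor RR recordings of one subject."""

    subject_id: str
    clinical: dict = field(repr=False)
    recordings: dict[str, RRSeries] = field(repr=False)


def _rng(config_seed: int, *tags: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence((int(config_seed), *map(int, tags))))


def sample_clinical(config: SyntheticConfig, n: int) -> pd.DataFrame:
    """Draw clinical variables for ``n`` subjects.

    AHI ~ two-component lognormal mixture; ODI = slope*AHI + noise truncated
    at 0; ESS drawn independently of AHI (clipped, integer-scored); BMI, age
    and sex follow the cohort profile.  Reproducible from ``config.seed``.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = _rng(config.seed, _STREAM_CLINICAL)
    no_apnea = rng.random(n) < config.no_apnea_fraction
    ahi = np.where(
        no_apnea,
        rng.lognormal(config.no_apnea_ahi_mu, config.no_apnea_ahi_sigma, n),
        rng.lognormal(config.ahi_lognormal_mu, config.ahi_lognormal_sigma, n),
    )
    odi = np.maximum(0.0, config.odi_slope * ahi + rng.normal(0.0, config.odi_noise_sd, n))
    lo, hi = config.ess_range
    ess = np.clip(np.round(rng.normal(config.ess_mean, config.ess_sd, n)), lo, hi)
    bmi = np.clip(rng.normal(44.0, 25.0, n), 16.0, 90.0)
    age = np.clip(np.round(rng.normal(51.0, 13.0, n)), 18, 95)
    sex = np.where(rng.random(n) < 0.76, "male", "female")
    type_idx = rng.choice(3, size=n, p=_APNEA_TYPE_P)
    apnea_type = np.where(
        no_apnea, "none", np.asarray(APNEA_TYPES)[type_idx]
    )
    return pd.DataFrame(
        {
            "ahi": ahi, "odi": odi, "ess": ess, "bmi": bmi, "age": age,
            "sex": sex, "apnea_type": apnea_type,
        }
    )


def _event_shape(u: np.ndarray) -> np.ndarray:
    """Unit bradycardia–tachycardia cycle on u in [0, 1].

    Half-cosine lengthening to +1 over the first 85% of the cycle, a sharp
    drop to a -0.4 tachycardic undershoot, then recovery to baseline.
    """
    out = np.zeros_like(u)
    rise = u < 0.85
    out[rise] = 0.5 * (1.0 - np.cos(np.pi * u[rise] / 0.85))
    drop = (u >= 0.85) & (u < 0.95)
    out[drop] = 1.0 - 1.4 * (u[drop] - 0.85) / 0.10
    tail = u >= 0.95
    out[tail] = -0.4 * (1.0 - (u[tail] - 0.95) / 0.05)
    return out


_GRID_DT = 0.25  # s; resolution of the instantaneous-RR trajectory


def _instantaneous_rr(clinical: dict, config: SyntheticConfig,
                      seed: int) -> np.ndarray:
    """Instantaneous RR trajectory sampled on a regular grid (ms)."""
    T = config.night_duration_s
    t = np.arange(0.0, T + _GRID_DT, _GRID_DT)

    rng_b = _rng(seed, _STREAM_BEATS)
    base = rng_b.normal(config.mean_rr_ms, config.mean_rr_sd_ms)
    base = float(np.clip(base, 600.0, 1400.0))
    j = config.amp_jitter
    lf_amp = config.lf_amp_ms * rng_b.uniform(1 - j, 1 + j)
    hf_amp = config.hf_amp_ms * rng_b.uniform(1 - j, 1 + j)
    ph1, ph2 = rng_b.uniform(0, 2 * np.pi, 2)

    traj = (
        base
        + lf_amp * np.sin(2 * np.pi * config.lf_freq_hz * t + ph1)
        + hf_amp * np.sin(2 * np.pi * config.hf_freq_hz * t + ph2)
    )

    ahi = float(clinical["ahi"])
    rng_e = _rng(seed, _STREAM_EVENTS)
    n_events = rng_e.poisson(ahi * T / 3600.0)
    if n_events > 0:
        starts = np.sort(rng_e.uniform(0.0, T, n_events))
        lengths = rng_e.uniform(*config.apnea_cycle_s, n_events)
        swing = config.apnea_swing_ms * (0.7 + 0.01 * min(ahi, 80.0))
        for s, L in zip(starts, lengths):
            i0 = int(s / _GRID_DT)
            i1 = min(int((s + L) / _GRID_DT) + 1, t.size)
            u = (t[i0:i1] - s) / L
            valid = (u >= 0) & (u < 1)
            traj[i0:i1][valid] += swing * _event_shape(u[valid])
    np.clip(traj, 400.0, 1450.0, out=traj)
    return traj


def simulate_night(clinical: dict, config: SyntheticConfig, seed: int) -> RRSeries:
    """Generate one clean whole-night RR series by integrate-and-fire.

    Beats are stepped through the instantaneous RR trajectory: each interval
    equals the trajectory value at the time of the previous beat plus white
    per-beat jitter, so onsets are exactly the cumulative sum of intervals.
    """
    traj = _instantaneous_rr(clinical, config, seed)
    T = config.night_duration_s
    min_rr_s = 0.35  # trajectory is clipped at 400 ms; bound the beat count
    rng_j = _rng(seed, _STREAM_BEATS, 1)
    jitter = (
        rng_j.normal(0.0, config.jitter_ms, int(T / min_rr_s) + 16)
        if config.jitter_ms > 0
        else np.zeros(int(T / min_rr_s) + 16)
    )

    traj_list = traj.tolist()  # plain-float access is ~3x faster in the loop
    rr: list[float] = []
    t = 0.0
    k = 0
    inv_dt = 1.0 / _GRID_DT
    while True:
        r = traj_list[int(t * inv_dt)] + jitter[k]
        if r < 350.0:
            r = 350.0
        t += r / 1000.0
        if t > T:
            break
        rr.append(r)
        k += 1
    rr_ms = np.asarray(rr)
    onsets = np.cumsum(rr_ms) / 1000.0
    return RRSeries(
        subject_id=str(clinical.get("subject_id", "synthetic")),
        sensor="patch",
        onsets_s=onsets,
        rr_ms=rr_ms,
        filtered=False,
    )


def inject_artifacts(series: RRSeries, rate_per_h: float, seed: int) -> RRSeries:
    """Corrupt a series with Poisson-placed missed-beat / false-beat artifacts.

    At each artifact, with equal probability either two adjacent intervals
    are merged into one of summed duration (missed R peak) or one interval is
    split into two unequal parts (false detection).  Total elapsed time is
    conserved; ``rate_per_h = 0`` returns the series unchanged.
    """
    if rate_per_h < 0:
        raise ValueError("rate_per_h must be >= 0")
    if rate_per_h == 0 or series.n_beats < 3:
        return replace(series)
    rng = _rng(seed, _STREAM_ARTIFACTS)
    hours = (series.onsets_s[-1] - series.onsets_s[0] + series.rr_ms[0] / 1000.0) / 3600.0
    n_art = rng.poisson(rate_per_h * hours)
    rr = series.rr_ms.tolist()
    for _ in range(n_art):
        if len(rr) < 3:
            break
        if rng.random() < 0.5:  # missed beat: merge i and i+1
            i = int(rng.integers(0, len(rr) - 1))
            rr[i] = rr[i] + rr[i + 1]
            del rr[i + 1]
        else:  # false beat: split i into unequal parts
            i = int(rng.integers(0, len(rr)))
            f = rng.uniform(0.15, 0.45)
            a = f * rr[i]
            b = rr[i] - a
            rr[i:i + 1] = [a, b]
    rr_ms = np.asarray(rr)
    onsets = np.cumsum(rr_ms) / 1000.0 + (series.onsets_s[0] - series.rr_ms[0] / 1000.0)
    return RRSeries(
        subject_id=series.subject_id,
        sensor=series.sensor,
        onsets_s=onsets,
        rr_ms=rr_ms,
        filtered=False,
    )


def generate_cohort(config: SyntheticConfig,
                    sensors: tuple[str, ...] = ("belt", "patch"),
                    ) -> tuple[list[SubjectRecord], CohortManifest]:
    """Generate a full cohort: clinical table plus per-sensor RR renderings.

    Each subject gets one clean beat process; the requested sensors are
    rendered from it by artifact injection at the sensor-specific rates.
    Fully reproducible from ``config.seed``.
    """
    clinical = sample_clinical(config, config.n_subjects)
    rates = {"belt": config.artifact_rate_belt, "patch": config.artifact_rate_patch}
    records: list[SubjectRecord] = []
    for i in range(config.n_subjects):
        sid = f"S{i + 1:04d}"
        row = clinical.iloc[i].to_dict()
        row["subject_id"] = sid
        subject_seed = int(
            np.random.SeedSequence((config.seed, 7, i)).generate_state(1)[0] % (2**31)
        )
        clean = simulate_night(row, config, seed=subject_seed)
        recordings = {
            sensor: inject_artifacts(
                clean.with_sensor(sensor), rates[sensor],
                seed=subject_seed + {"belt": 1, "patch": 2}[sensor],
            )
            for sensor in sensors
        }
        records.append(SubjectRecord(subject_id=sid, clinical=row, recordings=recordings))
    table = clinical.copy()
    table.insert(0, "subject_id", [r.subject_id for r in records])
    manifest = CohortManifest(table=table)
    return records, manifest


def write_cohort(records: list[SubjectRecord], manifest: CohortManifest,
                 out_dir) -> None:
    """Write a cohort to disk in the native formats (RR text + manifest CSV)."""
    from pathlib import Path

    from .rr_io import write_manifest, write_rr

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    table = manifest.table.copy()
    for sensor in ("belt", "patch"):
        table[f"rr_{sensor}"] = ""
    for rec in records:
        for sensor, series in rec.recordings.items():
            rel = f"{rec.subject_id}_{sensor}.rr"
            write_rr(series, out / rel)
            table.loc[table["subject_id"] == rec.subject_id, f"rr_{sensor}"] = rel
    write_manifest(CohortManifest(table=table), out / "manifest.csv")
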