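"""Synthetic actigraphy cohorts for palliative-care survival prediction.

Generates seeded cohorts of three-channel wrist-actigraphy recordings
(physical activity, angular change, spin) together with the clinical metadata
used by cutoff-based prognostic comparators (outcome, KPS, PPI, stay length).

The generative model couples everything to a single latent *frailty* f per
patient, drawn from a Normal(mu_group, 1) whose mean differs between patients
who die in hospital and patients discharged in stable condition:

* activity(t) = max(0, M·g(f) + A·g(f)·cos(2*pi*(t - acrophase)/24 h) + AR(1) noise)
  where (M, A) are the group's cosinor mesor and amplitude and g is a
  decreasing function of frailty, so frailer patients move less and with a
  flatter circadian rhythm;
* angle and spin are bounded, noisy monotone transforms of activity
  (the device reports per-epoch angular-change statistics, not posture);
* KPS = 100 - 25 f plus observer noise, rounded to the 10-point scale;
* PPI = 1.6 + 2.2 f plus noise, clipped to [0, 15] on the half-point scale.

Because KPS, PPI and the activity signal share the latent frailty, score-based
and signal-based outcome prediction are consistent with each other, which is
the structure the downstream comparisons assume.

Device-removal gaps ("off-wrist") are drawn as a Poisson process; off-wrist
samples carry worn=False and NaN in every signal channel, so imputation is a
preprocessing decision, never a simulation one.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from datetime import datetime, timedelta
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.signal import lfilter

__all__ = [
    "CohortSimParams",
    "ActigraphySeries",
    "PatientMeta",
    "simulate_patient",
    "simulate_cohort",
    "write_series_csv",
    "read_series_csv",
    "write_cohort_csv",
    "read_cohort_csv",
]

#: baseline admission timestamp for simulated stays
_BASE_ADMISSION = datetime(2020, 1, 1, 0, 0, 0)


@dataclass(frozen=True)
class CohortSimParams:
    """Parameters of the synthetic cohort generator.

    Group-pair fields are ordered ``(death, stable)``.  Defaults encode the
    contrast the study design assumes: the death group's mesor is 0.5x and
    its circadian amplitude 0.3x the stable group's, and the death group is
    frailer (higher latent frailty mean), which drives lower KPS and higher
    PPI scores.
    """

    n_patients: int = 60
    p_death: float = 28 / 60
    sampling_interval_s: float = 1.0
    stay_days_range: tuple[int, int] = (3, 10)
    mesor_by_group: tuple[float, float] = (1.0, 2.0)
    amplitude_by_group: tuple[float, float] = (0.45, 1.5)
    acrophase_h: float = 14.0
    ar1_coef: float = 0.9
    noise_sd: float = 0.5
    offwrist_rate_per_day: float = 1.5
    offwrist_duration_minutes: tuple[float, float] = (15.0, 65.0)
    frailty_mu_by_group: tuple[float, float] = (2.6, 0.8)
    frailty_signal_slope: float = 0.25
    kps_noise_sd: float = 5.0
    ppi_noise_sd: float = 0.8
    kps_missing_rate: float = 1 / 60
    ppi_missing_rate: float = 40 / 60
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_patients < 1:
            raise ValueError("n_patients must be a positive integer")
        if not 0.0 <= self.p_death <= 1.0:
            raise ValueError("p_death must lie in [0, 1]")
        if self.sampling_interval_s <= 0:
            raise ValueError("sampling_interval_s must be positive")
        lo, hi = self.stay_days_range
        if lo < 1 or hi < lo:
            raise ValueError("stay_days_range must satisfy 1 <= min <= max")
        if self.mesor_by_group[0] > self.mesor_by_group[1]:
            raise ValueError(
                "mesor_by_group: death-group mesor must not exceed stable-group mesor"
            )
        if self.amplitude_by_group[0] > self.amplitude_by_group[1]:
            raise ValueError(
                "amplitude_by_group: death-group amplitude must not exceed "
                "stable-group amplitude"
            )
        if min(self.mesor_by_group) < 0 or min(self.amplitude_by_group) < 0:
            raise ValueError("mesor_by_group and amplitude_by_group must be nonnegative")
        if not 0.0 <= self.acrophase_h < 24.0:
            raise ValueError("acrophase_h must lie in [0, 24)")
        if not 0.0 <= self.ar1_coef < 1.0:
            raise ValueError("ar1_coef must lie in [0, 1)")
        for name in ("noise_sd", "offwrist_rate_per_day", "kps_noise_sd", "ppi_noise_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be nonnegative")
        dlo, dhi = self.offwrist_duration_minutes
        if dlo < 0 or dhi < dlo:
            raise ValueError("offwrist_duration_minutes must satisfy 0 <= min <= max")
        for name in ("kps_missing_rate", "ppi_missing_rate"):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")


@dataclass
class ActigraphySeries:
    """One patient's regularly sampled three-channel actigraphy recording.

    Samples where ``worn`` is False carry NaN in all three channels.
    """

    patient_id: str
    start_time: datetime
    interval_s: float
    activity: np.ndarray
    angle: np.ndarray
    spin: np.ndarray
    worn: np.ndarray

    def __post_init__(self) -> None:
        n = len(self.activity)
        if not (len(self.angle) == len(self.spin) == len(self.worn) == n):
            raise ValueError("all per-sample vectors must have equal length")
        worn = np.asarray(self.worn, dtype=bool)
        act = np.asarray(self.activity, dtype=float)
        if np.any(act[worn] < 0):
            raise ValueError("activity must be nonnegative wherever worn is true")

    def __len__(self) -> int:
        return len(self.activity)

    @property
    def duration_h(self) -> float:
        """Recording span in hours (sample count times sampling interval)."""
        return len(self) * self.interval_s / 3600.0

    def timestamps(self) -> pd.DatetimeIndex:
        return pd.date_range(
            self.start_time, periods=len(self), freq=pd.Timedelta(seconds=self.interval_s)
        )

    def hours_since_start(self) -> np.ndarray:
        return np.arange(len(self)) * (self.interval_s / 3600.0)


@dataclass
class PatientMeta:
    """Clinical side of a record: outcome label, prognostic scores, stay length."""

    patient_id: str
    outcome: int  # 1 = death, 0 = discharged in stable condition
    kps: Optional[int]
    ppi: Optional[float]
    stay_days: int

    def __post_init__(self) -> None:
        if self.outcome not in (0, 1):
            raise ValueError("outcome must be 0 or 1")
        if self.kps is not None and (self.kps % 10 != 0 or not 0 <= self.kps <= 100):
            raise ValueError("kps must be a multiple of 10 in [0, 100] when present")
        if self.ppi is not None and not 0.0 <= self.ppi <= 15.0:
            raise ValueError("ppi must lie in [0, 15] when present")
        if self.stay_days < 1:
            raise ValueError("stay_days must be a positive integer")


def _frailty_modifier(f: float, params: CohortSimParams) -> float:
    """Decreasing multiplier g(f) applied to mesor and amplitude.

    Centred at the midpoint of the two groups' frailty means so that an
    average patient has g = 1.
    """
    f_ref = 0.5 * (params.frailty_mu_by_group[0] + params.frailty_mu_by_group[1])
    return float(np.exp(-params.frailty_signal_slope * (f - f_ref)))


def _ar1_noise(n: int, coef: float, sd: float, rng: np.random.Generator) -> np.ndarray:
    """Stationary AR(1) noise with marginal standard deviation ``sd``."""
    if sd == 0.0 or n == 0:
        return np.zeros(n)
    innov_sd = sd * np.sqrt(1.0 - coef**2)
    eps = rng.normal(0.0, innov_sd, size=n)
    eps[0] = rng.normal(0.0, sd)  # draw x_0 from the stationary distribution
    return lfilter([1.0], [1.0, -coef], eps)


def _draw_clinical(
    params: CohortSimParams, outcome: int, rng: np.random.Generator, patient_id: str
) -> tuple[int, float, PatientMeta]:
    """Draw stay length, latent frailty, and the clinical metadata.

    Runs before any signal-sized draw so that metadata are bit-identical
    whether or not the signal itself is generated afterwards.
    """
    group = 0 if outcome == 1 else 1  # pair fields are (death, stable)
    stay_days = int(rng.integers(params.stay_days_range[0], params.stay_days_range[1] + 1))
    frailty = float(rng.normal(params.frailty_mu_by_group[group], 1.0))

    kps: Optional[int]
    if rng.random() < params.kps_missing_rate:
        kps = None
    else:
        raw = 100.0 - 25.0 * frailty + rng.normal(0.0, params.kps_noise_sd)
        kps = int(np.clip(10 * round(raw / 10.0), 0, 100))
    ppi: Optional[float]
    if rng.random() < params.ppi_missing_rate:
        ppi = None
    else:
        raw = 1.6 + 2.2 * frailty + rng.normal(0.0, params.ppi_noise_sd)
        ppi = float(np.clip(round(raw * 2.0) / 2.0, 0.0, 15.0))
    meta = PatientMeta(
        patient_id=patient_id, outcome=outcome, kps=kps, ppi=ppi, stay_days=stay_days
    )
    return stay_days, frailty, meta


def simulate_patient(
    params: CohortSimParams,
    outcome: int,
    rng: np.random.Generator,
    patient_id: str = "P000",
    start_time: Optional[datetime] = None,
) -> tuple[ActigraphySeries, PatientMeta]:
    """Simulate one patient's actigraphy recording and clinical metadata.

    Parameters
    ----------
    params
        Generator parameters; validated on construction.
    outcome
        1 for in-hospital death, 0 for discharge in stable condition.
    rng
        Seeded numpy generator; the sole source of randomness, so identical
        (params, outcome, rng state) give bit-identical output.
    """
    if outcome not in (0, 1):
        raise ValueError("outcome must be 0 or 1")
    group = 0 if outcome == 1 else 1  # pair fields are (death, stable)

    stay_days, frailty, meta = _draw_clinical(params, outcome, rng, patient_id)
    n = int(round(stay_days * 86400.0 / params.sampling_interval_s))
    if start_time is None:
        start_time = _BASE_ADMISSION

    g = _frailty_modifier(frailty, params)
    mesor = params.mesor_by_group[group] * g
    amplitude = params.amplitude_by_group[group] * g

    start_h = start_time.hour + start_time.minute / 60.0 + start_time.second / 3600.0
    t_h = start_h + np.arange(n) * (params.sampling_interval_s / 3600.0)
    clean = mesor + amplitude * np.cos(2.0 * np.pi * (t_h - params.acrophase_h) / 24.0)
    activity = np.maximum(
        0.0, clean + _ar1_noise(n, params.ar1_coef, params.noise_sd, rng)
    )

    # angle/spin are per-epoch angular-change magnitudes: bounded, noisy,
    # monotone in gross activity
    angle = 6.0 * np.tanh(activity / 2.0) + rng.normal(0.0, 1.5, size=n)
    spin = 10.0 * np.tanh(activity / 3.0) + rng.normal(0.0, 2.0, size=n)

    worn = np.ones(n, dtype=bool)
    n_gaps = rng.poisson(params.offwrist_rate_per_day * stay_days)
    if n_gaps > 0:
        starts = rng.uniform(0.0, n * params.sampling_interval_s, size=n_gaps)
        durations = (
            rng.uniform(*params.offwrist_duration_minutes, size=n_gaps) * 60.0
        )
        for s, d in zip(starts, durations):
            # round to the sample grid so quantisation does not bias gap length
            i0 = int(round(s / params.sampling_interval_s))
            i1 = min(n, int(round((s + d) / params.sampling_interval_s)))
            worn[i0:i1] = False

    activity = activity.astype(np.float32)
    angle = angle.astype(np.float32)
    spin = spin.astype(np.float32)
    for channel in (activity, angle, spin):
        channel[~worn] = np.nan

    series = ActigraphySeries(
        patient_id=patient_id,
        start_time=start_time,
        interval_s=params.sampling_interval_s,
        activity=activity,
        angle=angle,
        spin=spin,
        worn=worn,
    )
    return series, meta


def simulate_cohort(
    params: CohortSimParams, include_signals: bool = True
) -> list[tuple[Optional[ActigraphySeries], PatientMeta]]:
    """Simulate a full cohort with a deterministic outcome composition.

    The number of deaths is ``round(n_patients * p_death)`` by construction
    (not a Bernoulli draw), so class counts are reproducible exactly.  With
    ``include_signals=False`` only the clinical metadata are generated, which
    makes large metadata-only Monte-Carlo sweeps cheap; the per-patient random
    streams are unaffected, so metadata match the full simulation.
    """
    if params.n_patients < 2:
        raise ValueError("n_patients must be at least 2 for a cohort")
    n = params.n_patients
    n_death = int(round(n * params.p_death))
    if n_death == 0 or n_death == n:
        warnings.warn(
            "cohort has only one outcome class "
            f"(n={n}, p_death={params.p_death}); downstream stratified "
            "operations may fail",
            stacklevel=2,
        )
    outcomes = np.zeros(n, dtype=int)
    outcomes[:n_death] = 1

    width = max(3, len(str(n)))
    children = np.random.SeedSequence(params.seed).spawn(n)
    out: list[tuple[Optional[ActigraphySeries], PatientMeta]] = []
    for i, (outcome, child) in enumerate(zip(outcomes, children)):
        rng = np.random.default_rng(child)
        pid = f"P{i + 1:0{width}d}"
        start = _BASE_ADMISSION + timedelta(
            days=i, hours=float(rng.uniform(8.0, 20.0))
        )
        if include_signals:
            series, meta = simulate_patient(
                params, int(outcome), rng, patient_id=pid, start_time=start
            )
        else:
            series, meta = _simulate_meta_only(params, int(outcome), rng, pid, start)
        out.append((series, meta))
    return out


def _simulate_meta_only(
    params: CohortSimParams,
    outcome: int,
    rng: np.random.Generator,
    patient_id: str,
    start_time: datetime,  # noqa: ARG001 - kept for signature symmetry
) -> tuple[None, PatientMeta]:
    """Clinical metadata only; skips the (expensive) signal draws.

    Clinical draws precede signal draws in :func:`simulate_patient`, so the
    metadata produced here are bit-identical to the full simulation's.
    """
    _, _, meta = _draw_clinical(params, outcome, rng, patient_id)
    return None, meta


# ---------------------------------------------------------------------------
# CSV interchange


def write_series_csv(series: ActigraphySeries, path: str | Path) -> None:
    """Write one patient's recording as `timestamp,activity,angle,spin,worn`."""
    df = pd.DataFrame(
        {
            "timestamp": series.timestamps().strftime("%Y-%m-%dT%H:%M:%S"),
            "activity": series.activity,
            "angle": series.angle,
            "spin": series.spin,
            "worn": series.worn.astype(int),
        }
    )
    df.to_csv(path, index=False)


def read_series_csv(path: str | Path, patient_id: Optional[str] = None) -> ActigraphySeries:
    df = pd.read_csv(path)
    ts = pd.to_datetime(df["timestamp"])
    if len(ts) < 2:
        interval = 1.0
    else:
        interval = float((ts.iloc[1] - ts.iloc[0]).total_seconds())
    if patient_id is None:
        patient_id = Path(path).stem
    return ActigraphySeries(
        patient_id=patient_id,
        start_time=ts.iloc[0].to_pydatetime(),
        interval_s=interval,
        activity=df["activity"].to_numpy(np.float32),
        angle=df["angle"].to_numpy(np.float32),
        spin=df["spin"].to_numpy(np.float32),
        worn=df["worn"].to_numpy(bool),
    )


def write_cohort_csv(metas: Sequence[PatientMeta], path: str | Path) -> None:
    """Write the cohort table `patient_id,outcome,kps,ppi,stay_days`."""
    df = pd.DataFrame(
        {
            "patient_id": [m.patient_id for m in metas],
            "outcome": [m.outcome for m in metas],
            "kps": [m.kps for m in metas],
            "ppi": [m.ppi for m in metas],
            "stay_days": [m.stay_days for m in metas],
        }
    )
    df.to_csv(path, index=False)


def read_cohort_csv(path: str | Path) -> list[PatientMeta]:
    df = pd.read_csv(path)
    metas = []
    for row in df.itertuples(index=False):
        kps = None if pd.isna(row.kps) else int(row.kps)
        ppi = None if pd.isna(row.ppi) else float(row.ppi)
        metas.append(
            PatientMeta(
                patient_id=str(row.patient_id),
                outcome=int(row.outcome),
                kps=kps,
                ppi=ppi,
                stay_days=int(row.stay_days),
            )
        )
    return metas
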