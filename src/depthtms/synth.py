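"""Synthetic cohorts and EEG sessions with planted, recoverable structure.

The clinical generator emulates the trial's two-arm design: baseline HDRS-21
item vectors (eligibility total >= 20), a logistic responder model whose
log-odds depend on the patient's true cluster score with arm-specific slopes
(opposite signs plant the qualitative interaction in which high-cluster
patients favor lateral stimulation), and weekly item-level trajectories that
respect the response/remission endpoint semantics.

The EEG generator produces 10-20 montage sessions: 1/f background, narrowband
alpha with configurable hemispheric lateralization, midline low-gamma, an
18 Hz on/off train structure with saturating square-burst artifacts, and
optional post-train band-specific gain modulation used to plant correlations
between deviated band metrics and clinical improvement.

All randomness derives from a single integer seed; sub-streams use fixed
offsets, so identical seeds reproduce identical outputs bit for bit.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .datamodel import (
    ARMS,
    CHANNELS_1020_19,
    HDRS_ITEM_MAXIMA,
    LEFT_CHANNELS,
    MIDLINE_CHANNELS,
    RIGHT_CHANNELS,
    ClusterDefinition,
    EEGSession,
    HDRSVisitRecord,
    OPTIMIZED_CLUSTER,
    PatientOutcome,
    ValidationError,
)
from .spectral import TrainSchedule
from .trial import classify_outcomes

__all__ = [
    "CohortSimParams",
    "simulate_cohort",
    "EEGSimParams",
    "simulate_eeg_session",
    "simulate_eeg_cohort",
    "draw_metric_improvement",
    "TARGET_METRICS",
    "default_item_weights",
]

#: Fixed improvement ramp: fraction of the patient's full responder depth
#: realized at BL, W1..W6.
IMPROVEMENT_RAMP = (0.0, 0.15, 0.30, 0.45, 0.60, 0.70, 0.75)
VISIT_LABELS = ("BL", "W1", "W2", "W3", "W4", "W5", "W6")


def default_item_weights() -> dict[int, tuple[float, ...]]:
    """Per-item categorical score weights for a moderately severe MDD cohort.

    Tuned so baseline totals centre in the mid 20s (the eligibility floor is
    20), with the 0-4 mood/anxiety items around 1.7 and somatic 0-2 items
    around 0.7.
    """
    weights: dict[int, tuple[float, ...]] = {}
    for item, maximum in HDRS_ITEM_MAXIMA.items():
        if maximum == 4:
            weights[item] = (0.25, 0.30, 0.25, 0.12, 0.08)
        elif maximum == 3:
            weights[item] = (0.30, 0.35, 0.25, 0.10)
        else:
            weights[item] = (0.45, 0.40, 0.15)
    return weights


@dataclass
class CohortSimParams:
    """Study conditions for the clinical simulator.

    ``beta_c`` maps arm to the slope of the true cluster score (centred at
    the 0.5 decision threshold) on the log-odds of response; choosing
    beta_c["H1"] > 0 > beta_c["H7"] plants the differential-response
    interaction.  Intercepts set each arm's response rate at the threshold.
    """

    n_per_arm: int = 85
    seed: int = 0
    item_weights: Mapping[int, Sequence[float]] = field(
        default_factory=default_item_weights)
    #: SD of the patient-level severity factor and the per-item exponential
    #: tilt it applies (items share the default loading unless mapped
    #: individually; a zero loading makes an item pure noise w.r.t. severity).
    severity_sd: float = 1.0
    severity_loading: float | Mapping[int, float] = 1.5
    #: "linear": log-odds slope in (c - 0.5); "switch": the interaction flips
    #: sign at the 0.5 threshold (log-odds shifted by +-beta_c/2 per side).
    interaction_form: str = "linear"
    intercepts: Mapping[str, float] = field(
        default_factory=lambda: {"H1": 0.5, "H7": 0.5})
    beta_c: Mapping[str, float] = field(
        default_factory=lambda: {"H1": 4.0, "H7": -2.0})
    effect_cluster: ClusterDefinition = field(
        default_factory=lambda: OPTIMIZED_CLUSTER)
    trajectory_noise_sd: float = 1.0
    dropout_prob: float = 0.11
    n_sites: int = 3
    min_baseline_total: int = 20

    def validate(self) -> None:
        if self.n_per_arm < 1:
            raise ValidationError("n_per_arm must be positive")
        if not 0 <= self.dropout_prob <= 1:
            raise ValidationError("dropout probability must lie in [0, 1]")
        for item, w in self.item_weights.items():
            w = np.asarray(w, dtype=float)
            if len(w) != HDRS_ITEM_MAXIMA[item] + 1:
                raise ValidationError(
                    f"item {item}: need {HDRS_ITEM_MAXIMA[item] + 1} weights")
            if w.sum() <= 0 or (w < 0).any():
                raise ValidationError(f"item {item}: degenerate score weights")


def _apportion(total: int, weights: np.ndarray, caps: np.ndarray) -> np.ndarray:
    """Largest-remainder apportionment of ``total`` under per-item caps."""
    total = int(min(total, caps.sum()))
    if total <= 0:
        return np.zeros_like(caps)
    w = weights.astype(float)
    if w.sum() <= 0:
        w = caps.astype(float)
    quota = total * w / w.sum()
    alloc = np.minimum(np.floor(quota).astype(int), caps)
    remainder = quota - np.floor(quota)
    order = np.argsort(-remainder, kind="stable")
    # hand out remaining points by largest fractional part, cycling while slack
    while alloc.sum() < total:
        progressed = False
        for idx in order:
            if alloc.sum() >= total:
                break
            if alloc[idx] < caps[idx]:
                alloc[idx] += 1
                progressed = True
        if not progressed:
            break
    return alloc


def _sigmoid(z: float) -> float:
    return 1.0 / (1.0 + math.exp(-z))


def _item_loading(params: CohortSimParams, item: int) -> float:
    if isinstance(params.severity_loading, Mapping):
        return float(params.severity_loading.get(item, 0.0))
    return float(params.severity_loading)


def _draw_baseline_items(params: CohortSimParams,
                         rng: np.random.Generator) -> np.ndarray:
    """Draw one patient's baseline item vector.

    Item scores are categorical draws exponentially tilted by a shared
    patient severity factor u: P(s) proportional to w_s * exp(lambda_i u s/m_i).
    The shared factor correlates items within a patient, widening the
    between-patient spread of cluster scores the way co-varying symptom
    severity does in real cohorts.  Resamples until the eligibility floor on
    the total is met.
    """
    maxima = HDRS_ITEM_MAXIMA
    for _ in range(1000):
        u = rng.normal(0.0, params.severity_sd)
        items = np.empty(21, dtype=int)
        for i in range(1, 22):
            w = np.asarray(params.item_weights[i], dtype=float)
            scores = np.arange(maxima[i] + 1)
            tilted = w * np.exp(_item_loading(params, i) * u * scores / maxima[i])
            items[i - 1] = rng.choice(maxima[i] + 1, p=tilted / tilted.sum())
        if items.sum() >= params.min_baseline_total:
            return items
    raise ValidationError(
        "could not reach the baseline eligibility floor; item weights too low")


def simulate_cohort(
    params: CohortSimParams,
) -> tuple[list[HDRSVisitRecord], list[PatientOutcome], pd.DataFrame]:
    """Generate item-level visit records, endpoint outcomes, and latent truth.

    Responders (Bernoulli draw from the logistic model) receive a deep
    improvement trajectory whose week-6 total falls below half of baseline;
    non-responders stay above it.  The latent table records each patient's
    true cluster score, response probability, responder draw, and trajectory
    depth.  Fully reproducible from ``params.seed``.
    """
    params.validate()
    rng = np.random.default_rng([params.seed, 11])
    maxima = HDRS_ITEM_MAXIMA
    caps = np.array([maxima[i] for i in range(1, 22)])

    records: list[HDRSVisitRecord] = []
    latent_rows = []
    for arm_index, arm in enumerate(ARMS):
        for k in range(params.n_per_arm):
            pid = f"{arm}-{k:04d}"
            site = f"S{rng.integers(params.n_sites) + 1}"
            items = _draw_baseline_items(params, rng)
            baseline_total = int(items.sum())
            cluster = params.effect_cluster
            c = float(np.mean([items[i - 1] / cluster.maxima[i]
                               for i in cluster.items]))
            if params.interaction_form == "switch":
                drive = 0.5 if c > 0.5 else -0.5
            elif params.interaction_form == "linear":
                drive = c - 0.5
            else:
                raise ValidationError(
                    f"unknown interaction form {params.interaction_form!r}")
            p_resp = _sigmoid(params.intercepts[arm]
                              + params.beta_c[arm] * drive)
            responder = bool(rng.random() < p_resp)
            depth = float(rng.uniform(0.75, 1.0) if responder
                          else rng.uniform(0.0, 0.55))
            dropped = bool(rng.random() < params.dropout_prob)
            last_week = int(rng.integers(1, 6)) if dropped else 6

            for week, frac in enumerate(IMPROVEMENT_RAMP):
                if week > last_week:
                    break
                if week == 0:
                    week_items = items
                else:
                    target = baseline_total * (1 - frac * depth)
                    target += rng.normal(0, params.trajectory_noise_sd)
                    total = int(np.clip(round(target), 0, baseline_total))
                    week_items = _apportion(total, items.astype(float), caps)
                records.append(HDRSVisitRecord(
                    patient_id=pid, site_id=site, arm=arm,
                    visit=VISIT_LABELS[week],
                    items=tuple(int(v) for v in week_items)))
            latent_rows.append({
                "patient_id": pid, "arm": arm, "site_id": site,
                "cdepth_true": c, "p_response": p_resp,
                "responder": responder, "depth": depth,
                "baseline_total": baseline_total, "dropped": dropped,
            })
    outcomes, _ = classify_outcomes(records)
    latent = pd.DataFrame(latent_rows)
    return records, outcomes, latent


# ---------------------------------------------------------------------------
# EEG simulation
# ---------------------------------------------------------------------------

@dataclass
class EEGSimParams:
    """Spectral content of a simulated session.

    Oscillation amplitudes are equivalent-sinusoid amplitudes in microvolts
    (band power A^2/2); oscillations are synthesized as narrowband Gaussian
    processes so that phase relations decorrelate across epochs.
    """

    seed: int = 0
    sampling_rate: float = 500.0
    channels: tuple[str, ...] = CHANNELS_1020_19
    background_exponent: float = 1.0
    background_rms: float = 1.0            # microvolts
    alpha_amp_left: float = 4.0
    alpha_amp_right: float = 4.0
    alpha_amp_mid: float = 4.0
    alpha_freq: float = 10.0
    alpha_bw: float = 1.2                  # Gaussian bump SD, Hz (FWHM ~2.8)
    gamma_amp_mid: float = 2.0
    gamma_freq: float = 35.0
    gamma_bw: float = 3.0                  # low-gamma is broadband in vivo
    artifact_amp: float = 2000.0           # saturating burst amplitude
    duration: float = 120.0                # resting-session length, s

    def validate(self) -> None:
        if self.sampling_rate <= 2.5 * 40.0:
            raise ValidationError(
                "sampling rate too low to resolve the low-gamma band")
        if min(self.alpha_amp_left, self.alpha_amp_right,
               self.alpha_amp_mid, self.gamma_amp_mid) < 0:
            raise ValidationError("oscillation amplitudes must be nonnegative")


def _shaped_noise(rng: np.random.Generator, n: int, fs: float,
                  exponent: float, rms: float) -> np.ndarray:
    """1/f^exponent background by spectral shaping of white noise."""
    white = rng.standard_normal(n)
    spectrum = np.fft.rfft(white)
    freqs = np.fft.rfftfreq(n, 1 / fs)
    shape = np.ones_like(freqs)
    nonzero = freqs > 0
    shape[nonzero] = freqs[nonzero] ** (-exponent / 2)
    shape[0] = 0.0
    x = np.fft.irfft(spectrum * shape, n)
    sd = x.std()
    return x * (rms / sd) if sd > 0 else x


def _narrowband(rng: np.random.Generator, n: int, fs: float,
                center: float, bw: float, amplitude: float) -> np.ndarray:
    """Narrowband Gaussian oscillation with power amplitude^2 / 2."""
    if amplitude == 0:
        return np.zeros(n)
    white = rng.standard_normal(n)
    spectrum = np.fft.rfft(white)
    freqs = np.fft.rfftfreq(n, 1 / fs)
    bump = np.exp(-0.5 * ((freqs - center) / bw) ** 2)
    x = np.fft.irfft(spectrum * bump, n)
    sd = x.std()
    target_rms = amplitude / math.sqrt(2)
    return x * (target_rms / sd) if sd > 0 else x


DEFAULT_GAINS = {"alpha_left": 1.0, "alpha_right": 1.0,
                 "alpha_mid": 1.0, "gamma_mid": 1.0}

#: post-train window (relative to train offset) in which gains apply;
#: covers the analysis epoch [offset+1, offset+3) with margin.
GAIN_WINDOW = (0.5, 3.5)


def _gain_envelope(n: int, fs: float, offsets: Sequence[float],
                   gain: float) -> np.ndarray:
    env = np.ones(n)
    if gain == 1.0:
        return env
    for off in offsets:
        a = int(round((off + GAIN_WINDOW[0]) * fs))
        b = int(round((off + GAIN_WINDOW[1]) * fs))
        env[max(a, 0):min(b, n)] = gain
    return env


def simulate_eeg_session(
    params: EEGSimParams,
    schedule: Optional[TrainSchedule] = None,
    *,
    condition: str = "treatment",
    gains: Optional[Mapping[str, float]] = None,
    patient_id: str = "SIM",
    site_id: str = "S1",
    arm: str = "H1",
    stream: int = 0,
) -> EEGSession:
    """Synthesize one session; treatment condition requires a train schedule.

    Signal = 1/f background + lateralized narrowband alpha + midline
    low-gamma + saturating square-burst artifacts inside train windows.
    ``gains`` multiplies the named oscillation's amplitude inside a window
    following each train, planting post-train responsivity that the deviated
    spectra recover as gain^2.
    """
    params.validate()
    if condition == "treatment":
        if schedule is None:
            raise ValidationError("treatment simulation requires a schedule")
        duration = schedule.session_length
    else:
        duration = params.duration
    fs = params.sampling_rate
    n = int(round(duration * fs))
    g = dict(DEFAULT_GAINS)
    if gains:
        g.update(gains)
    rng = np.random.default_rng([params.seed, 17, stream])

    offsets = schedule.offsets if (schedule and condition == "treatment") else ()
    env = {key: _gain_envelope(n, fs, offsets, g[key]) for key in g}

    data = np.empty((len(params.channels), n))
    t = np.arange(n) / fs
    for ci, ch in enumerate(params.channels):
        x = _shaped_noise(rng, n, fs, params.background_exponent,
                          params.background_rms)
        if ch in LEFT_CHANNELS:
            amp, akey = params.alpha_amp_left, "alpha_left"
        elif ch in RIGHT_CHANNELS:
            amp, akey = params.alpha_amp_right, "alpha_right"
        else:
            amp, akey = params.alpha_amp_mid, "alpha_mid"
        x = x + _narrowband(rng, n, fs, params.alpha_freq, params.alpha_bw,
                            amp) * env[akey]
        if ch in MIDLINE_CHANNELS:
            x = x + _narrowband(rng, n, fs, params.gamma_freq, params.gamma_bw,
                                params.gamma_amp_mid) * env["gamma_mid"]
        data[ci] = x

    events: list[tuple[int, str]] = []
    if condition == "treatment" and schedule is not None:
        square = np.sign(np.sin(2 * np.pi * schedule.stim_frequency * t))
        mask = np.zeros(n)
        for onset in schedule.onsets:
            a = int(round(onset * fs))
            b = int(round((onset + schedule.train_duration) * fs))
            mask[a:min(b, n)] = 1.0
            events.append((a, "Train"))
        data += params.artifact_amp * square * mask

    session = EEGSession(
        patient_id=patient_id, site_id=site_id, arm=arm,
        sampling_rate=fs, channel_names=tuple(params.channels),
        data=data, events=events, condition=condition,
    )
    session.validate()
    return session


# ---------------------------------------------------------------------------
# cohort-level EEG with planted metric-outcome correlation
# ---------------------------------------------------------------------------

#: target metric name -> (eoi-report metric, electrode, gain key(s))
TARGET_METRICS = {
    "alpha_asymmetry_f3f4": ("asymmetry", "F3/F4", ("alpha_left",)),
    "alpha_fz": ("alpha", "FZ", ("alpha_mid",)),
    "gamma_fz": ("gamma", "FZ", ("gamma_mid",)),
    "gamma_alpha_ratio_fz": ("ratio", "FZ", ("gamma_mid",)),
}


def draw_metric_improvement(
    n: int,
    rho: float,
    seed: int,
    *,
    improvements: Optional[Sequence[float]] = None,
    metric_log_sd: float = 0.5,
    improvement_mean: float = 0.45,
    improvement_sd: float = 0.20,
    exact: bool = True,
) -> pd.DataFrame:
    """Draw per-patient (metric, improvement) pairs at correlation ``rho``.

    Metric values are lognormal around 1 (log-scale SD ``metric_log_sd``).
    With ``exact`` (default) the noise component is orthogonalized against
    the improvement scores so the realized log-metric / improvement sample
    correlation equals ``rho`` exactly — the standard construction for
    parameter-recovery simulations, which keeps the plant free of draw-level
    sampling error.  If ``improvements`` is given the metric is drawn
    against the standardized observed improvements; otherwise improvements
    are drawn too.
    """
    if not -1.0 <= rho <= 1.0:
        raise ValidationError("|rho| must be <= 1")
    if n < 4:
        raise ValidationError("need at least 4 patients for a correlation")
    rng = np.random.default_rng([seed, 23])
    if improvements is None:
        z1 = rng.standard_normal(n)
        impr = np.clip(improvement_mean + improvement_sd * z1, -0.4, 0.95)
        z1 = impr.copy()  # correlate against the clipped, realized values
    else:
        impr = np.asarray(improvements, dtype=float)
        if len(impr) != n:
            raise ValidationError("improvements length mismatch")
        z1 = impr.copy()
    sd = z1.std()
    if sd == 0:
        raise ValidationError("improvements have zero variance")
    z1 = (z1 - z1.mean()) / sd
    eps = rng.standard_normal(n)
    if exact:
        # Gram-Schmidt: make the noise empirically orthonormal to z1
        eps = eps - eps.mean() - (eps @ z1) / (z1 @ z1) * z1
        eps /= eps.std()
        z1 = z1 / z1.std()  # ensure unit empirical SD
    z2 = rho * z1 + math.sqrt(max(0.0, 1 - rho ** 2)) * eps
    metric = np.exp(metric_log_sd * z2)
    return pd.DataFrame({"improvement": impr, "metric": metric})


def simulate_eeg_cohort(
    params: EEGSimParams,
    schedule: TrainSchedule,
    rho: float,
    target_metric: str = "gamma_alpha_ratio_fz",
    *,
    n: Optional[int] = None,
    outcomes: Optional[Sequence[PatientOutcome]] = None,
    arm: str = "H7",
) -> tuple[list[EEGSession], list[PatientOutcome], pd.DataFrame]:
    """Sessions whose chosen deviated band metric correlates with improvement.

    Per-patient metric values and percent improvements are drawn jointly at
    correlation ``rho`` (conditionally on supplied outcomes, if any); each
    session's post-train gains are set so the deviated metric recovers the
    drawn value up to spectral-estimation noise and background dilution.
    """
    if target_metric not in TARGET_METRICS:
        raise ValidationError(f"unknown target metric {target_metric!r}; "
                              f"choose from {sorted(TARGET_METRICS)}")
    _, _, gain_keys = TARGET_METRICS[target_metric]
    if outcomes is not None:
        n = len(outcomes)
        improvements = [o.percent_improvement for o in outcomes]
    else:
        if n is None:
            raise ValidationError("supply n or outcomes")
        improvements = None
    truth = draw_metric_improvement(n, rho, params.seed,
                                    improvements=improvements)

    sessions: list[EEGSession] = []
    out_list: list[PatientOutcome] = []
    baseline = 40
    for i, row in truth.iterrows():
        if outcomes is not None:
            out = outcomes[i]
        else:
            endpoint = int(np.clip(round(baseline * (1 - row["improvement"])),
                                   0, 63))
            impr = (baseline - endpoint) / baseline
            out = PatientOutcome(
                patient_id=f"E{i:04d}", arm=arm, site_id="S1",
                baseline_total=baseline, endpoint_total=endpoint,
                percent_improvement=impr, response=impr >= 0.5,
                remission=endpoint < 10, analysis_set="CO")
        gains = {key: math.sqrt(row["metric"]) for key in gain_keys}
        sessions.append(simulate_eeg_session(
            params, schedule, condition="treatment", gains=gains,
            patient_id=out.patient_id, site_id=out.site_id, arm=out.arm,
            stream=i + 1))
        out_list.append(out)
    truth = truth.assign(patient_id=[o.patient_id for o in out_list])
    return sessions, out_list, truth
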