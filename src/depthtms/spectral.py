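"""Inter-train EEG spectral metrics for a marked Deep TMS treatment session.

The stimulation protocol (18 Hz trains, 2 s on / 20 s off, 20 minutes) leaves
inter-train windows from which artifact-free activity is sampled: a 2 s
post-train epoch starting 1 s after each train ends and a 1 s pre-train
epoch immediately before the next train begins.  Per-train Welch spectra of
the post epoch are deviated by the matching pre epoch (ratio by default,
yielding unitless, scale-invariant responsivity values), averaged across
trains, and reduced to alpha (8-12 Hz) and low-gamma (30-40 Hz) band powers,
homologous-pair asymmetries and gamma/alpha ratios under the average (AVR) or
current-source-density (CSD) reference.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy import signal as sps

from .datamodel import (
    EEGSession,
    ProtocolParams,
    StudyConfig,
    ValidationError,
    homologous_pair_map,
)

__all__ = [
    "TrainSchedule",
    "derive_train_schedule",
    "EpochSet",
    "extract_epochs",
    "fixed_epochs",
    "rereference",
    "welch_psd",
    "baseline_deviate",
    "band_power",
    "asymmetry_scores",
    "gamma_alpha_ratio",
    "BandMetrics",
    "analyze_treatment",
    "analyze_resting",
]

POST_GAP = 1.0     # s between train end and post-epoch start
POST_LEN = 2.0     # s
PRE_LEN = 1.0      # s immediately before train onset


@dataclass(frozen=True)
class TrainSchedule:
    """Stimulation-train timing for one session.

    Onsets are seconds from recording start; each train occupies
    [onset, onset + train_duration).
    """

    stim_frequency: float
    train_duration: float
    inter_train_interval: float
    session_length: float
    onsets: tuple[float, ...]

    @property
    def n_trains(self) -> int:
        return len(self.onsets)

    @property
    def pulses_per_train(self) -> int:
        return int(round(self.stim_frequency * self.train_duration))

    @property
    def total_pulses(self) -> int:
        return self.n_trains * self.pulses_per_train

    @property
    def offsets(self) -> tuple[float, ...]:
        return tuple(t + self.train_duration for t in self.onsets)

    def validate(self) -> None:
        gaps = np.diff(self.onsets)
        if (gaps < self.train_duration + self.inter_train_interval - 1e-9).any():
            raise ValidationError("train onsets closer than t_on + t_off")


def derive_train_schedule(
    protocol: ProtocolParams,
    session_length: Optional[float] = None,
) -> TrainSchedule:
    """Nominal schedule: trains at k*(t_on + t_off) while the on-window fits.

    The 18 Hz / 2 s / 20 s protocol over 20 minutes yields 55 trains of 36
    pulses, 1,980 stimuli in total.
    """
    protocol.validate()
    T = protocol.session_length if session_length is None else session_length
    period = protocol.train_duration + protocol.inter_train_interval
    onsets = []
    k = 0
    while k * period + protocol.train_duration <= T + 1e-9:
        onsets.append(k * period)
        k += 1
    return TrainSchedule(
        stim_frequency=protocol.stim_frequency,
        train_duration=protocol.train_duration,
        inter_train_interval=protocol.inter_train_interval,
        session_length=T,
        onsets=tuple(onsets),
    )


@dataclass
class EpochSet:
    """Matched pre/post inter-train epochs per train, with rejection flags.

    ``pre`` and ``post`` are (n_trains, n_channels, n_samples) arrays; trains
    whose epoch would exceed the recording bounds carry ``*_ok = False`` and a
    zero-filled slot.  Amplitude rejection marks any epoch containing a sample
    beyond the configured absolute threshold.
    """

    fs: float
    channel_names: tuple[str, ...]
    train_onsets: np.ndarray        # samples
    pre: np.ndarray
    post: np.ndarray
    pre_ok: np.ndarray
    post_ok: np.ndarray
    pre_reject: np.ndarray
    post_reject: np.ndarray

    @property
    def usable(self) -> np.ndarray:
        """Trains with both epochs in bounds and neither rejected."""
        return (self.pre_ok & self.post_ok
                & ~self.pre_reject & ~self.post_reject)

    @property
    def n_trains(self) -> int:
        return len(self.train_onsets)


def _slice_epochs(
    data: np.ndarray,
    starts: np.ndarray,
    length: int,
) -> tuple[np.ndarray, np.ndarray]:
    n_ch, n_samp = data.shape
    out = np.zeros((len(starts), n_ch, length))
    ok = np.zeros(len(starts), dtype=bool)
    for i, s in enumerate(starts):
        if s >= 0 and s + length <= n_samp:
            out[i] = data[:, s:s + length]
            ok[i] = True
    return out, ok


def extract_epochs(
    session: EEGSession,
    schedule: Optional[TrainSchedule] = None,
    train_duration: Optional[float] = None,
    reject_uv: float = 150.0,
) -> EpochSet:
    """Extract matched pre/post epochs around every train.

    Measured markers in ``session.events`` take precedence over the nominal
    schedule.  Post epochs cover [offset + 1 s, offset + 3 s) and pre epochs
    [onset - 1 s, onset); epochs outside the recording are dropped, and any
    epoch with a sample exceeding ``reject_uv`` (absolute, post-reference
    microvolts) is flagged rejected.
    """
    fs = session.sampling_rate
    if session.events:
        onset_samples = np.array([s for s, _ in session.events], dtype=int)
        t_on = train_duration if train_duration is not None else (
            schedule.train_duration if schedule is not None else 2.0)
    elif schedule is not None:
        onset_samples = np.round(np.asarray(schedule.onsets) * fs).astype(int)
        t_on = schedule.train_duration
    else:
        raise ValidationError("no train markers and no nominal schedule supplied")
    if onset_samples.size == 0:
        raise ValidationError("no trains to epoch")

    n_pre = int(round(PRE_LEN * fs))
    n_post = int(round(POST_LEN * fs))
    offset_samples = onset_samples + int(round(t_on * fs))
    post_starts = offset_samples + int(round(POST_GAP * fs))
    pre_starts = onset_samples - n_pre

    pre, pre_ok = _slice_epochs(session.data, pre_starts, n_pre)
    post, post_ok = _slice_epochs(session.data, post_starts, n_post)
    pre_reject = np.array([pre_ok[i] and bool(np.abs(pre[i]).max() > reject_uv)
                           for i in range(len(pre))])
    post_reject = np.array([post_ok[i] and bool(np.abs(post[i]).max() > reject_uv)
                            for i in range(len(post))])
    epochs = EpochSet(
        fs=fs, channel_names=session.channel_names,
        train_onsets=onset_samples,
        pre=pre, post=post, pre_ok=pre_ok, post_ok=post_ok,
        pre_reject=pre_reject, post_reject=post_reject,
    )
    if not epochs.usable.any():
        raise ValidationError("no usable (in-bounds, unrejected) epoch pairs")
    return epochs


def fixed_epochs(
    session: EEGSession,
    length: float = 2.0,
    reject_uv: float = 150.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Consecutive non-overlapping epochs for resting recordings.

    Returns (epochs, accepted) where epochs is (n, ch, samples) and accepted
    flags epochs passing the amplitude criterion.
    """
    n = int(round(length * session.sampling_rate))
    n_epochs = session.n_samples // n
    if n_epochs == 0:
        raise ValidationError("recording shorter than one epoch")
    trimmed = session.data[:, :n_epochs * n]
    epochs = trimmed.reshape(session.data.shape[0], n_epochs, n).transpose(1, 0, 2)
    accepted = np.array([np.abs(e).max() <= reject_uv for e in epochs])
    return epochs, accepted


# ---------------------------------------------------------------------------
# referencing
# ---------------------------------------------------------------------------

def rereference(session: EEGSession, scheme: str = "AVR") -> EEGSession:
    """Re-reference a session: common average (AVR) or surface Laplacian (CSD).

    AVR subtracts the instantaneous mean across channels (idempotent).  CSD
    applies a spherical-spline surface Laplacian (spline stiffness 4,
    regularization 1e-5, 50 Legendre terms) on standard 10-20 positions;
    output units are arbitrary but consistent, which the ratio-based metrics
    downstream do not depend on.
    """
    from dataclasses import replace

    if scheme == "AVR":
        data = session.data - session.data.mean(axis=0, keepdims=True)
        return replace(session, data=data)
    if scheme != "CSD":
        raise ValidationError(f"unknown reference scheme {scheme!r}")

    import mne

    if len(session.channel_names) < 16:
        raise ValidationError("CSD requires at least 16 channels with positions")
    montage = mne.channels.make_standard_montage("standard_1020")
    by_upper = {name.upper(): name for name in montage.ch_names}
    try:
        canonical = [by_upper[ch] for ch in session.channel_names]
    except KeyError as exc:
        raise ValidationError(f"channel {exc} has no known 10-20 position")
    info = mne.create_info(canonical, session.sampling_rate, ch_types="eeg",
                           verbose="error")
    raw = mne.io.RawArray(session.data * 1e-6, info, verbose="error")
    raw.set_montage(montage, verbose="error")
    csd = mne.preprocessing.compute_current_source_density(raw, verbose="error")
    return replace(session, data=csd.get_data() * 1e6)


# ---------------------------------------------------------------------------
# spectra
# ---------------------------------------------------------------------------

def welch_psd(
    epoch: np.ndarray,
    fs: float,
    segment_seconds: float = 1.0,
    overlap: float = 0.5,
    window: str = "hamming",
) -> tuple[np.ndarray, np.ndarray]:
    """Welch power spectral density along the last axis.

    Density-normalized so the integral over frequency approximates the signal
    variance.  One-second segments give a 1 Hz grid that tiles both analysis
    bands; a 1 s epoch reduces to a single full-length segment.
    """
    nperseg = int(round(segment_seconds * fs))
    if epoch.shape[-1] < nperseg:
        raise ValidationError("epoch shorter than the Welch segment")
    freqs, psd = sps.welch(
        epoch, fs=fs, window=window, nperseg=nperseg,
        noverlap=int(round(overlap * nperseg)), scaling="density", axis=-1,
    )
    return freqs, psd


def baseline_deviate(
    post_psd: np.ndarray,
    pre_psd: np.ndarray,
    usable: Optional[np.ndarray] = None,
    mode: str = "ratio",
) -> np.ndarray:
    """Train-wise deviation of post-train spectra by pre-train spectra.

    ``post_psd``/``pre_psd`` are (n_units, n_channels, n_freqs) on a common
    grid, one unit per matched post/pre spectral estimate.  Ratio mode
    (default) divides bin-wise — unitless and scale invariant — and
    aggregates across units by the geometric mean: per-bin ratios of
    low-dof spectral estimates are heavy-tailed (near-zero denominator bins
    dominate an arithmetic mean), while the log-domain mean is the natural
    location estimate for multiplicative deviations and is unbiased when
    post and pre estimators carry equal degrees of freedom.  Difference mode
    subtracts and aggregates by the arithmetic mean.  Zero-power pre (or
    post, in ratio mode) bins are flagged (NaN) and excluded from the
    aggregate.
    """
    if post_psd.shape != pre_psd.shape:
        raise ValidationError("pre and post spectra must share a common grid")
    if mode not in ("ratio", "difference"):
        raise ValidationError(f"unknown deviation mode {mode!r}")
    if usable is None:
        usable = np.ones(post_psd.shape[0], dtype=bool)
    if not usable.any():
        raise ValidationError("no usable trains to aggregate")
    post = post_psd[usable]
    pre = pre_psd[usable]
    if mode == "ratio":
        with np.errstate(divide="ignore", invalid="ignore"):
            logratio = np.where((pre > 0) & (post > 0),
                                np.log(post) - np.log(pre), np.nan)
        return np.exp(np.nanmean(logratio, axis=0))
    return np.nanmean(post - pre, axis=0)


def band_power(freqs: np.ndarray, spectrum: np.ndarray,
               band: tuple[float, float]) -> np.ndarray:
    """Mean spectral value over bins with frequency in [low, high].

    The mean (rather than the sum) keeps bands of unequal width comparable.
    Works on the last axis of ``spectrum``.
    """
    lo, hi = band
    mask = (freqs >= lo) & (freqs <= hi)
    if not mask.any():
        raise ValidationError(f"no spectral bins inside band [{lo}, {hi}] Hz")
    return np.nanmean(np.asarray(spectrum)[..., mask], axis=-1)


def asymmetry_scores(
    powers: dict[str, float],
    channels: Optional[Sequence[str]] = None,
) -> dict[str, float]:
    """Left/right homologous-pair power ratios (left in the numerator).

    Keys are "LEFT/RIGHT" pair labels; pairs with a missing member or
    nonpositive power are omitted.
    """
    from .datamodel import HOMOLOGOUS_PAIRS

    present = {c.upper() for c in (channels if channels is not None else powers)}
    out: dict[str, float] = {}
    for left, right in HOMOLOGOUS_PAIRS:
        if left in present and right in present:
            if left in powers and right in powers \
                    and powers[left] > 0 and powers[right] > 0:
                out[f"{left}/{right}"] = powers[left] / powers[right]
    return out


def gamma_alpha_ratio(alpha: dict[str, float], gamma: dict[str, float]
                      ) -> dict[str, float]:
    """Per-channel low-gamma / alpha power ratio."""
    out = {}
    for ch in alpha:
        if alpha[ch] <= 0:
            raise ValidationError(f"zero or negative alpha power at {ch}")
        if ch in gamma:
            out[ch] = gamma[ch] / alpha[ch]
    return out


@dataclass
class BandMetrics:
    """Per-electrode band powers and pair asymmetries for one session."""

    patient_id: str
    condition: str
    reference_scheme: str
    alpha: dict[str, float]
    gamma: dict[str, float]
    ratio: dict[str, float]
    asymmetry: dict[str, float]        # "F3/F4" -> P(F3)/P(F4), left numerator
    n_epochs_used: int
    low_epoch_warning: bool = False

    def value(self, metric: str, electrode: str) -> float:
        """Look up a named metric (alpha/gamma/ratio/asymmetry) at an electrode
        or pair label."""
        table = {"alpha": self.alpha, "gamma": self.gamma,
                 "ratio": self.ratio, "asymmetry": self.asymmetry}[metric]
        key = electrode.upper()
        if key not in table:
            raise ValidationError(f"{metric} not available at {electrode}")
        return table[key]


def _metrics_from_spectrum(
    session: EEGSession,
    freqs: np.ndarray,
    spectrum: np.ndarray,      # (n_channels, n_freqs)
    config: StudyConfig,
    n_epochs: int,
    scheme: str,
    low_epoch_warning: bool = False,
) -> BandMetrics:
    alpha_vals = band_power(freqs, spectrum, config.alpha_band)
    gamma_vals = band_power(freqs, spectrum, config.gamma_band)
    alpha = {ch: float(v) for ch, v in zip(session.channel_names, alpha_vals)}
    gamma = {ch: float(v) for ch, v in zip(session.channel_names, gamma_vals)}
    return BandMetrics(
        patient_id=session.patient_id,
        condition=session.condition,
        reference_scheme=scheme,
        alpha=alpha,
        gamma=gamma,
        ratio=gamma_alpha_ratio(alpha, gamma),
        asymmetry=asymmetry_scores(alpha, session.channel_names),
        n_epochs_used=n_epochs,
        low_epoch_warning=low_epoch_warning,
    )


def analyze_treatment(
    session: EEGSession,
    config: Optional[StudyConfig] = None,
    schedule: Optional[TrainSchedule] = None,
    scheme: Optional[str] = None,
    mode: str = "ratio",
) -> BandMetrics:
    """Full treatment-session pipeline: reference, epoch, deviate, reduce.

    Band powers are computed on the across-train aggregate of the baseline-
    deviated spectra, so they quantify post-train responsivity relative to
    the immediately preceding pre-train activity.
    """
    config = config or StudyConfig()
    scheme = scheme or config.reference_scheme
    if session.condition == "resting":
        return analyze_resting(session, config, scheme=scheme)
    ref = rereference(session, scheme)
    epochs = extract_epochs(ref, schedule=schedule,
                            train_duration=config.protocol.train_duration,
                            reject_uv=config.epoch_reject_uv)
    # Split each 2 s post epoch into two non-overlapping 1 s segments and
    # deviate each by the train's 1 s pre spectrum: matched estimators keep
    # the ratio aggregate unbiased in the log domain.
    n_half = epochs.pre.shape[-1]
    freqs, post_a = welch_psd(epochs.post[..., :n_half], epochs.fs)
    _, post_b = welch_psd(epochs.post[..., n_half:2 * n_half], epochs.fs)
    _, pre_psd = welch_psd(epochs.pre, epochs.fs)
    post_units = np.concatenate([post_a, post_b], axis=0)
    pre_units = np.concatenate([pre_psd, pre_psd], axis=0)
    usable_units = np.concatenate([epochs.usable, epochs.usable])
    aggregate = baseline_deviate(post_units, pre_units, usable=usable_units,
                                 mode=mode)
    return _metrics_from_spectrum(
        session, freqs, aggregate, config,
        n_epochs=int(epochs.usable.sum()), scheme=scheme,
    )


def analyze_resting(
    session: EEGSession,
    config: Optional[StudyConfig] = None,
    scheme: Optional[str] = None,
) -> BandMetrics:
    """Resting-state pipeline: absolute band powers, no baseline deviation."""
    config = config or StudyConfig()
    scheme = scheme or config.reference_scheme
    ref = rereference(session, scheme)
    epochs, accepted = fixed_epochs(ref, length=POST_LEN,
                                    reject_uv=config.epoch_reject_uv)
    if not accepted.any():
        raise ValidationError("all resting epochs rejected")
    freqs, psd = welch_psd(epochs[accepted], session.sampling_rate)
    mean_psd = psd.mean(axis=0)
    return _metrics_from_spectrum(
        session, freqs, mean_psd, config,
        n_epochs=int(accepted.sum()), scheme=scheme,
        low_epoch_warning=bool(accepted.sum() < 10),
    )
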