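"""Shared domain types for the H1-vs-H7 Deep TMS differential-predictor analysis.

The clinical atom is a single patient-visit's 21-item Hamilton Depression
Rating Scale (HDRS-21) record; the electrophysiological atom is a marked
multichannel EEG session from the first treatment day.  Everything downstream
(C-DEPTH scoring, subgroup statistics, spectral metrics) consumes these types.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np

__all__ = [
    "ValidationError",
    "FormatError",
    "HDRS_ITEM_MAXIMA",
    "ARMS",
    "VISITS",
    "HOMOLOGOUS_PAIRS",
    "CHANNELS_1020_19",
    "homologous_pair_map",
    "HDRSVisitRecord",
    "PatientOutcome",
    "EEGSession",
    "ClusterDefinition",
    "FULL_CLUSTER",
    "OPTIMIZED_CLUSTER",
    "ProtocolParams",
    "StudyConfig",
]


class ValidationError(ValueError):
    """A record or table violates a documented invariant."""


class FormatError(ValueError):
    """A file does not conform to the expected external format."""


# Standard HDRS-21 per-item maxima.  Items scored 0-4 are the core mood /
# anxiety items; 0-2 items are mostly somatic/insight; insight-adjacent items
# 16 and 20 run 0-3.  Configurable, but this is the instrument default.
HDRS_ITEM_MAXIMA: dict[int, int] = {
    1: 4, 2: 4, 3: 4, 4: 2, 5: 2, 6: 2, 7: 4, 8: 4, 9: 4, 10: 4,
    11: 4, 12: 2, 13: 2, 14: 2, 15: 4, 16: 3, 17: 2, 18: 2, 19: 4,
    20: 3, 21: 2,
}

ARMS = ("H1", "H7")
#: Baseline plus weekly visits; BL is week 0.
VISITS = ("BL", "W1", "W2", "W3", "W4", "W5", "W6")

#: 10-20 homologous electrode pairs (left, right); midline has no pair.
HOMOLOGOUS_PAIRS: tuple[tuple[str, str], ...] = (
    ("FP1", "FP2"), ("AF3", "AF4"), ("F3", "F4"), ("F7", "F8"),
    ("FC1", "FC2"), ("FC5", "FC6"), ("C3", "C4"), ("T7", "T8"),
    ("CP1", "CP2"), ("CP5", "CP6"), ("P3", "P4"), ("P7", "P8"),
    ("PO3", "PO4"), ("O1", "O2"),
)

#: The default 19-channel 10-20 montage used by the simulator.
CHANNELS_1020_19 = (
    "FP1", "FP2", "F7", "F3", "FZ", "F4", "F8", "T7", "C3", "CZ",
    "C4", "T8", "P7", "P3", "PZ", "P4", "P8", "O1", "O2",
)

MIDLINE_CHANNELS = ("FPZ", "AFZ", "FZ", "FCZ", "CZ", "CPZ", "PZ", "POZ", "OZ")

LEFT_CHANNELS = frozenset(l for l, _ in HOMOLOGOUS_PAIRS)
RIGHT_CHANNELS = frozenset(r for _, r in HOMOLOGOUS_PAIRS)


def homologous_pair_map(channels: Sequence[str]) -> dict[str, str]:
    """Map each lateral channel present in ``channels`` to its homologue.

    Returns a symmetric mapping (F3 -> F4 and F4 -> F3); midline channels and
    channels whose partner is absent are omitted.
    """
    present = {c.upper() for c in channels}
    out: dict[str, str] = {}
    for left, right in HOMOLOGOUS_PAIRS:
        if left in present and right in present:
            out[left] = right
            out[right] = left
    return out


@dataclass(frozen=True)
class HDRSVisitRecord:
    """One patient-visit's 21 HDRS item scores plus identifiers."""

    patient_id: str
    site_id: str
    arm: str
    visit: str
    items: tuple[int, ...]

    @property
    def total(self) -> int:
        return int(sum(self.items))

    def item(self, index: int) -> int:
        """1-based item accessor (HDRS items are numbered 1..21)."""
        if not 1 <= index <= len(self.items):
            raise ValidationError(f"HDRS item {index} does not exist")
        return self.items[index - 1]

    def validate(self, maxima: Mapping[int, int] = HDRS_ITEM_MAXIMA) -> None:
        if self.arm not in ARMS:
            raise ValidationError(
                f"patient {self.patient_id}: unknown arm {self.arm!r}")
        if self.visit not in VISITS:
            raise ValidationError(
                f"patient {self.patient_id}: unknown visit {self.visit!r}")
        if len(self.items) != 21:
            raise ValidationError(
                f"patient {self.patient_id} visit {self.visit}: expected 21 "
                f"items, got {len(self.items)}")
        for i, score in enumerate(self.items, start=1):
            if int(score) != score:
                raise ValidationError(
                    f"patient {self.patient_id} visit {self.visit}: "
                    f"item_{i} = {score!r} is not an integer")
            if not 0 <= score <= maxima[i]:
                raise ValidationError(
                    f"patient {self.patient_id} visit {self.visit}: "
                    f"item_{i} = {score} outside [0, {maxima[i]}]")


def validate_records(
    records: Sequence[HDRSVisitRecord],
    maxima: Mapping[int, int] = HDRS_ITEM_MAXIMA,
) -> None:
    """Validate every record and the dataset-level uniqueness invariant."""
    seen: set[tuple[str, str]] = set()
    for rec in records:
        rec.validate(maxima)
        key = (rec.patient_id, rec.visit)
        if key in seen:
            raise ValidationError(f"duplicate (patient, visit) pair {key}")
        seen.add(key)


@dataclass(frozen=True)
class PatientOutcome:
    """Endpoint classification of one patient.

    ``percent_improvement`` is (baseline - endpoint) / baseline, so 1.0 is a
    complete resolution and negative values denote worsening.  Response is a
    >= 50% reduction; remission is an endpoint total strictly below 10.
    """

    patient_id: str
    arm: str
    site_id: str
    baseline_total: int
    endpoint_total: int
    percent_improvement: float
    response: bool
    remission: bool
    analysis_set: str = "ITT"

    def validate(self) -> None:
        if self.baseline_total <= 0:
            raise ValidationError(
                f"patient {self.patient_id}: nonpositive baseline total")
        expected = (self.baseline_total - self.endpoint_total) / self.baseline_total
        if abs(expected - self.percent_improvement) > 1e-9:
            raise ValidationError(
                f"patient {self.patient_id}: inconsistent percent improvement")
        if self.response != (self.percent_improvement >= 0.5):
            raise ValidationError(
                f"patient {self.patient_id}: response flag inconsistent")
        if self.remission != (self.endpoint_total < 10):
            raise ValidationError(
                f"patient {self.patient_id}: remission flag inconsistent")


@dataclass
class EEGSession:
    """A multichannel scalp EEG recording with stimulation-train markers.

    ``data`` is channels x samples in microvolts; ``events`` are 0-based
    (sample_index, label) markers, sorted by sample index.
    """

    patient_id: str
    site_id: str
    arm: str
    sampling_rate: float
    channel_names: tuple[str, ...]
    data: np.ndarray
    events: list[tuple[int, str]] = field(default_factory=list)
    condition: str = "treatment"

    def validate(self) -> None:
        if self.sampling_rate <= 80.0:
            raise ValidationError(
                "sampling rate must exceed 80 Hz to resolve the 30-40 Hz band")
        if len(set(self.channel_names)) != len(self.channel_names):
            raise ValidationError("channel names must be unique")
        if self.data.shape[0] != len(self.channel_names):
            raise ValidationError("data rows must match channel count")
        idx = [s for s, _ in self.events]
        if any(b <= a for a, b in zip(idx, idx[1:])):
            raise ValidationError("event sample indices must strictly increase")
        if self.condition not in ("resting", "treatment"):
            raise ValidationError(f"unknown condition {self.condition!r}")

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration(self) -> float:
        return self.n_samples / self.sampling_rate

    def event_onsets_seconds(self) -> np.ndarray:
        return np.array([s / self.sampling_rate for s, _ in self.events])


@dataclass(frozen=True)
class ClusterDefinition:
    """A set of HDRS items defining a cluster score, with per-item maxima.

    ``sublabels`` tags the core items as depression- or anxiety-related;
    items without a tag contribute to the score but to neither subcluster.
    """

    items: tuple[int, ...]
    maxima: Mapping[int, int] = field(default_factory=lambda: dict(HDRS_ITEM_MAXIMA))
    sublabels: Mapping[int, str] = field(
        default_factory=lambda: {1: "depression", 7: "depression", 8: "depression",
                                 9: "anxiety", 10: "anxiety", 11: "anxiety"})

    def __post_init__(self) -> None:
        object.__setattr__(self, "items", tuple(sorted(set(self.items))))
        for i in self.items:
            if i not in self.maxima:
                raise ValidationError(f"no maximum defined for cluster item {i}")
            if self.maxima[i] <= 0:
                raise ValidationError(f"item {i} maximum must be positive")

    def drop(self, item: int) -> "ClusterDefinition":
        if item not in self.items:
            raise ValidationError(f"item {item} not in cluster")
        return dataclasses.replace(self, items=tuple(i for i in self.items if i != item))

    def subcluster_items(self, label: str) -> tuple[int, ...]:
        return tuple(i for i in self.items if self.sublabels.get(i) == label)


#: Mood-and-anxiety cluster from the factor-analytic literature.
FULL_CLUSTER = ClusterDefinition(items=(1, 7, 8, 9, 10, 11, 13, 15))
#: The leave-one-feature-out optimized cluster (items 13 and 15 removed).
OPTIMIZED_CLUSTER = ClusterDefinition(items=(1, 7, 8, 9, 10, 11))


@dataclass(frozen=True)
class ProtocolParams:
    """High-frequency Deep TMS session schedule parameters."""

    stim_frequency: float = 18.0   # Hz
    train_duration: float = 2.0    # s on
    inter_train_interval: float = 20.0  # s off
    session_length: float = 1200.0  # 20 minutes

    def validate(self) -> None:
        if min(self.stim_frequency, self.train_duration,
               self.inter_train_interval, self.session_length) <= 0:
            raise ValidationError("protocol parameters must be positive")


@dataclass
class StudyConfig:
    """Analysis configuration: cluster, bands, protocol, thresholds, EOIs."""

    cluster: ClusterDefinition = field(default_factory=lambda: OPTIMIZED_CLUSTER)
    cdepth_threshold: float = 0.5
    alpha_band: tuple[float, float] = (8.0, 12.0)
    gamma_band: tuple[float, float] = (30.0, 40.0)
    protocol: ProtocolParams = field(default_factory=ProtocolParams)
    noninferiority_margin: float = 3.0
    eoi_h1: str = "F3"
    eoi_h7: str = "FZ"
    outlier_sd: float = 3.0
    reference_scheme: str = "AVR"
    epoch_reject_uv: float = 150.0

    def validate(self) -> None:
        for name, (lo, hi) in (("alpha", self.alpha_band), ("gamma", self.gamma_band)):
            if not lo < hi:
                raise ValidationError(f"{name} band must have positive width")
        a_lo, a_hi = self.alpha_band
        g_lo, g_hi = self.gamma_band
        if max(a_lo, g_lo) < min(a_hi, g_hi):
            raise ValidationError("alpha and gamma bands must not overlap")
        if not 0.0 <= self.cdepth_threshold <= 1.0:
            raise ValidationError("C-DEPTH threshold must lie in [0, 1]")
        if self.reference_scheme not in ("AVR", "CSD"):
            raise ValidationError(f"unknown reference scheme {self.reference_scheme!r}")
        self.protocol.validate()
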