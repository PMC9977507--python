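"""Readers and writers: clinical CSV tables, EEG recordings, config, results.

Clinical tables are UTF-8 CSV with columns
``patient_id,site,arm,visit,item_1..item_21``.  EEG is read through MNE
(EDF and BrainVision); a minimal BrainVision writer is provided so synthetic
sessions can round-trip through the same reader used for real recordings.
Results serialize to JSON with deterministic key order and fixed float
precision, or to wide CSV for tabular metrics.
"""

from __future__ import annotations

import dataclasses
import json
import re
from pathlib import Path
from typing import Any, Iterable, Sequence

import numpy as np
import pandas as pd
import yaml

from .datamodel import (
    ARMS,
    HDRS_ITEM_MAXIMA,
    ClusterDefinition,
    EEGSession,
    FormatError,
    HDRSVisitRecord,
    ProtocolParams,
    StudyConfig,
    ValidationError,
    validate_records,
)

__all__ = [
    "read_hdrs_table",
    "write_hdrs_table",
    "read_eeg",
    "write_brainvision",
    "write_results",
    "read_results",
    "load_config",
    "save_config",
    "NoEventsError",
]

ITEM_COLUMNS = [f"item_{i}" for i in range(1, 22)]
REQUIRED_COLUMNS = ["patient_id", "site", "arm", "visit"] + ITEM_COLUMNS

#: Default annotation pattern recognized as a stimulation-train onset.
TRAIN_MARKER_PATTERN = r"(?i)train|stimulus"

FLOAT_DECIMALS = 10  # fixed precision for serialized floats


class NoEventsError(FormatError):
    """A treatment-condition recording carries no train markers."""


# ---------------------------------------------------------------------------
# clinical tables
# ---------------------------------------------------------------------------

def read_hdrs_table(path: str | Path) -> list[HDRSVisitRecord]:
    """Read and validate a clinical HDRS-21 item table.

    Raises :class:`FormatError` if a required column is missing and
    :class:`ValidationError` naming row and item for out-of-range or
    non-integer scores.  An empty table (header only) returns ``[]``.
    """
    try:
        frame = pd.read_csv(path, dtype={"patient_id": str, "site": str})
    except pd.errors.EmptyDataError:
        raise FormatError(f"{path}: empty file without header")
    missing = [c for c in REQUIRED_COLUMNS if c not in frame.columns]
    if missing:
        raise FormatError(f"{path}: missing required column(s) {missing}")

    records: list[HDRSVisitRecord] = []
    problems: list[str] = []
    for row_number, row in enumerate(frame.itertuples(index=False), start=2):
        row = row._asdict()
        items: list[int] = []
        for i, col in enumerate(ITEM_COLUMNS, start=1):
            value = row[col]
            if pd.isna(value) or float(value) != int(value):
                problems.append(f"row {row_number}: {col} = {value!r} is not an integer")
                continue
            score = int(value)
            if not 0 <= score <= HDRS_ITEM_MAXIMA[i]:
                problems.append(
                    f"row {row_number}: {col} = {score} outside "
                    f"[0, {HDRS_ITEM_MAXIMA[i]}]")
                continue
            items.append(score)
        if len(items) == 21:
            records.append(HDRSVisitRecord(
                patient_id=str(row["patient_id"]),
                site_id=str(row["site"]),
                arm=str(row["arm"]),
                visit=str(row["visit"]),
                items=tuple(items),
            ))
    if problems:
        raise ValidationError("; ".join(problems))
    validate_records(records)
    return records


def write_hdrs_table(records: Iterable[HDRSVisitRecord], path: str | Path) -> Path:
    rows = []
    for rec in records:
        row = {"patient_id": rec.patient_id, "site": rec.site_id,
               "arm": rec.arm, "visit": rec.visit}
        row.update({col: score for col, score in zip(ITEM_COLUMNS, rec.items)})
        rows.append(row)
    frame = pd.DataFrame(rows, columns=REQUIRED_COLUMNS)
    path = Path(path)
    frame.to_csv(path, index=False)
    return path


# ---------------------------------------------------------------------------
# EEG
# ---------------------------------------------------------------------------

def read_eeg(
    path: str | Path,
    *,
    patient_id: str = "",
    site_id: str = "",
    arm: str = "",
    condition: str = "treatment",
    marker_pattern: str = TRAIN_MARKER_PATTERN,
) -> EEGSession:
    """Read an EDF or BrainVision recording into an :class:`EEGSession`.

    Channel labels are uppercased and data converted to microvolts.  Events
    are annotation onsets whose description matches ``marker_pattern``.  A
    treatment-condition file without any matching marker is an error; a
    resting file is accepted with no events.
    """
    import mne

    path = Path(path)
    suffix = path.suffix.lower()
    try:
        if suffix == ".edf":
            raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
        elif suffix == ".vhdr":
            raw = mne.io.read_raw_brainvision(path, preload=True, verbose="error")
        else:
            raise FormatError(f"{path}: unsupported EEG format {suffix!r}")
    except FormatError:
        raise
    except Exception as exc:  # noqa: BLE001 - surface reader failures uniformly
        raise FormatError(f"{path}: unreadable EEG file ({exc})") from exc

    fs = float(raw.info["sfreq"])
    data_uv = raw.get_data() * 1e6  # MNE uses volts internally
    channels = tuple(name.upper() for name in raw.ch_names)

    pattern = re.compile(marker_pattern)
    events: list[tuple[int, str]] = []
    for onset, desc in zip(raw.annotations.onset, raw.annotations.description):
        if pattern.search(desc):
            events.append((int(round(onset * fs)), str(desc)))
    events.sort(key=lambda e: e[0])

    if condition == "treatment" and not events:
        raise NoEventsError(
            f"{path}: treatment-condition recording has no train markers")

    session = EEGSession(
        patient_id=patient_id or path.stem,
        site_id=site_id,
        arm=arm,
        sampling_rate=fs,
        channel_names=channels,
        data=data_uv,
        events=events,
        condition=condition,
    )
    session.validate()
    return session


def write_brainvision(session: EEGSession, basename: str | Path) -> Path:
    """Write a session as a BrainVision triplet (.vhdr / .vmrk / .eeg).

    Data are stored as multiplexed IEEE float32 microvolts with resolution 1,
    markers as ``Stimulus`` entries at 1-based sample positions.  Returns the
    .vhdr path, which is what :func:`read_eeg` consumes.
    """
    base = Path(basename)
    if base.suffix:  # accept "name.vhdr" or bare "name"
        base = base.with_suffix("")
    vhdr, vmrk, eeg = (base.with_suffix(s) for s in (".vhdr", ".vmrk", ".eeg"))

    n_ch = len(session.channel_names)
    sampling_interval_us = 1e6 / session.sampling_rate
    header = [
        "Brain Vision Data Exchange Header File Version 1.0",
        "",
        "[Common Infos]",
        "Codepage=UTF-8",
        f"DataFile={eeg.name}",
        f"MarkerFile={vmrk.name}",
        "DataFormat=BINARY",
        "DataOrientation=MULTIPLEXED",
        f"NumberOfChannels={n_ch}",
        f"SamplingInterval={sampling_interval_us:g}",
        "",
        "[Binary Infos]",
        "BinaryFormat=IEEE_FLOAT_32",
        "",
        "[Channel Infos]",
    ]
    header += [f"Ch{i}={name},,1,µV"
               for i, name in enumerate(session.channel_names, start=1)]
    vhdr.write_text("\n".join(header) + "\n", encoding="utf-8")

    markers = [
        "Brain Vision Data Exchange Marker File, Version 1.0",
        "",
        "[Common Infos]",
        "Codepage=UTF-8",
        f"DataFile={eeg.name}",
        "",
        "[Marker Infos]",
        "Mk1=New Segment,,1,1,0,0",
    ]
    for k, (sample, label) in enumerate(session.events, start=2):
        markers.append(f"Mk{k}=Stimulus,{label},{sample + 1},1,0")
    vmrk.write_text("\n".join(markers) + "\n", encoding="utf-8")

    session.data.astype("<f4").T.tofile(eeg)  # multiplexed: sample-major
    return vhdr


# ---------------------------------------------------------------------------
# results
# ---------------------------------------------------------------------------

def _jsonable(obj: Any) -> Any:
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {k: _jsonable(v) for k, v in dataclasses.asdict(obj).items()}
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return _jsonable(obj.tolist())
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating, float)):
        value = float(obj)
        return value if not np.isfinite(value) else round(value, FLOAT_DECIMALS)
    if isinstance(obj, (np.bool_,)):
        return bool(obj)
    return obj


def write_results(results: Any, path: str | Path) -> Path:
    """Serialize a stage output deterministically.

    ``.csv`` paths expect a DataFrame (floats at fixed precision); everything
    else is written as JSON with sorted keys so reruns are byte-identical.
    """
    path = Path(path)
    if path.suffix.lower() == ".csv":
        if not isinstance(results, pd.DataFrame):
            raise TypeError("CSV output requires a pandas DataFrame")
        results.to_csv(path, index=False, float_format=f"%.{FLOAT_DECIMALS}g")
        return path
    payload = _jsonable(results)
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(payload, fh, sort_keys=True, indent=2, allow_nan=True)
        fh.write("\n")
    return path


def read_results(path: str | Path) -> Any:
    path = Path(path)
    if path.suffix.lower() == ".csv":
        return pd.read_csv(path)
    with open(path, encoding="utf-8") as fh:
        return json.load(fh)


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------

def load_config(path: str | Path) -> StudyConfig:
    """Load a YAML study configuration; every field has an overridable default."""
    with open(path, encoding="utf-8") as fh:
        raw = yaml.safe_load(fh) or {}
    config = StudyConfig()
    if "cluster" in raw:
        cl = raw["cluster"]
        kwargs: dict[str, Any] = {"items": tuple(cl["items"])}
        if "maxima" in cl:
            kwargs["maxima"] = {int(k): int(v) for k, v in cl["maxima"].items()}
        if "sublabels" in cl:
            kwargs["sublabels"] = {int(k): str(v) for k, v in cl["sublabels"].items()}
        config.cluster = ClusterDefinition(**kwargs)
    if "protocol" in raw:
        config.protocol = ProtocolParams(**raw["protocol"])
    for key in ("cdepth_threshold", "noninferiority_margin", "eoi_h1", "eoi_h7",
                "outlier_sd", "reference_scheme", "epoch_reject_uv"):
        if key in raw:
            setattr(config, key, raw[key])
    for key in ("alpha_band", "gamma_band"):
        if key in raw:
            setattr(config, key, tuple(float(v) for v in raw[key]))
    config.validate()
    return config


def save_config(config: StudyConfig, path: str | Path) -> Path:
    payload = {
        "cluster": {
            "items": list(config.cluster.items),
            "maxima": {int(k): int(v) for k, v in config.cluster.maxima.items()},
            "sublabels": dict(config.cluster.sublabels),
        },
        "cdepth_threshold": config.cdepth_threshold,
        "alpha_band": list(config.alpha_band),
        "gamma_band": list(config.gamma_band),
        "protocol": dataclasses.asdict(config.protocol),
        "noninferiority_margin": config.noninferiority_margin,
        "eoi_h1": config.eoi_h1,
        "eoi_h7": config.eoi_h7,
        "outlier_sd": config.outlier_sd,
        "reference_scheme": config.reference_scheme,
        "epoch_reject_uv": config.epoch_reject_uv,
    }
    path = Path(path)
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(payload, fh, sort_keys=True)
    return path
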