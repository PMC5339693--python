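"""Domain types and the on-disk recording format.

A recording couples three electrophysiological streams on a common 512 Hz
clock (64-channel EEG, 2-channel EOG, 2-channel ECG, all in microvolts) with
continuous-wave NIRS oxy-/deoxy-hemoglobin concentration changes (8 frontal
channels at 10 Hz, in mM/DPF — molar concentration change divided by the
differential pathlength factor).  Time is expressed in seconds from recording
start; sample ``i`` of a stream sampled at ``fs`` sits at ``i / fs`` (0-based).

On disk a recording is a directory of plain CSV files (header row = channel
labels, one row per sample) plus two JSON sidecars::

    eeg.csv  eog.csv  ecg.csv  nirs_hbo.csv  nirs_hb.csv
    meta.json    # fs_eeg, fs_nirs, channel_map, units, t0
    events.json  # [{"kind": ..., "onset_s": ..., "duration_s": ...}, ...]
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "DrowsikitError",
    "MissingStreamError",
    "SampleCountMismatchError",
    "UnknownChannelError",
    "MalformedSidecarError",
    "AnnotationRangeError",
    "Annotation",
    "ChannelMap",
    "BandSet",
    "MultimodalRecording",
    "BIOSEMI64_LABELS",
    "NIRS_LABELS",
    "REGIONS",
    "default_channel_map",
    "default_band_set",
    "read_recording",
    "write_recording",
    "read_events",
    "write_events",
]


# ---------------------------------------------------------------------------
# Errors

class DrowsikitError(Exception):
    """Base class for all package errors."""


class MissingStreamError(DrowsikitError):
    """A required stream file is absent from a recording bundle."""


class SampleCountMismatchError(DrowsikitError):
    """Streams that share a clock disagree on sample count."""


class UnknownChannelError(DrowsikitError):
    """A channel label is not present in the channel map."""


class MalformedSidecarError(DrowsikitError):
    """meta.json or events.json cannot be parsed into the expected schema."""


class AnnotationRangeError(DrowsikitError):
    """An annotation lies outside the recording or has a negative duration."""


# ---------------------------------------------------------------------------
# Channel geometry

REGIONS = ("frontal", "central", "temporal", "parietal", "occipital")

# Biosemi ActiveTwo 64-channel montage (10-10 names, A1..B32 ordering).
BIOSEMI64_LABELS: tuple[str, ...] = (
    "Fp1", "AF7", "AF3", "F1", "F3", "F5", "F7", "FT7",
    "FC5", "FC3", "FC1", "C1", "C3", "C5", "T7", "TP7",
    "CP5", "CP3", "CP1", "P1", "P3", "P5", "P7", "P9",
    "PO7", "PO3", "O1", "Iz", "Oz", "POz", "Pz", "CPz",
    "Fpz", "Fp2", "AF8", "AF4", "AFz", "Fz", "F2", "F4",
    "F6", "F8", "FT8", "FC6", "FC4", "FC2", "FCz", "Cz",
    "C2", "C4", "C6", "T8", "TP8", "CP6", "CP4", "CP2",
    "P2", "P4", "P6", "P8", "P10", "PO8", "PO4", "O2",
)

# Region partition of the 64 labels: frontal 17, central 14, temporal 6,
# parietal 17, occipital 10.  Left/right symmetric; P9/P10 are grouped with
# the occipital ring, POz with the parietal midline.
_REGION_SETS: dict[str, tuple[str, ...]] = {
    "frontal": (
        "Fp1", "Fpz", "Fp2", "AF7", "AF3", "AFz", "AF4", "AF8",
        "F7", "F5", "F3", "F1", "Fz", "F2", "F4", "F6", "F8",
    ),
    "central": (
        "FC5", "FC3", "FC1", "FCz", "FC2", "FC4", "FC6",
        "C5", "C3", "C1", "Cz", "C2", "C4", "C6",
    ),
    "temporal": ("FT7", "T7", "TP7", "FT8", "T8", "TP8"),
    "parietal": (
        "CP5", "CP3", "CP1", "CPz", "CP2", "CP4", "CP6",
        "P7", "P5", "P3", "P1", "Pz", "P2", "P4", "P6", "P8", "POz",
    ),
    "occipital": (
        "P9", "P10", "PO7", "PO3", "PO4", "PO8", "O1", "Oz", "O2", "Iz",
    ),
}

NIRS_LABELS: tuple[str, ...] = tuple(f"N{i}" for i in range(1, 9))

EOG_LABELS: tuple[str, ...] = ("EOG1", "EOG2")
ECG_LABELS: tuple[str, ...] = ("ECG1", "ECG2")


@dataclass(frozen=True)
class ChannelMap:
    """Label → scalp-region lookup plus the two analysis channel groups.

    ``occipital_alpha_set`` feeds the per-minute occipital alpha power and
    ``frontal_beta_set`` the frontal beta power / beta RPL features.
    """

    region_of: dict[str, str]
    occipital_alpha_set: tuple[str, ...]
    frontal_beta_set: tuple[str, ...]

    def __post_init__(self) -> None:
        bad = {r for r in self.region_of.values()} - set(REGIONS)
        if bad:
            raise UnknownChannelError(f"unknown regions in channel map: {sorted(bad)}")
        for label in (*self.occipital_alpha_set, *self.frontal_beta_set):
            if label not in self.region_of:
                raise UnknownChannelError(f"group label {label!r} not in channel map")

    @property
    def labels(self) -> tuple[str, ...]:
        return tuple(self.region_of)

    def region_labels(self, region: str) -> tuple[str, ...]:
        if region not in REGIONS:
            raise UnknownChannelError(f"unknown region {region!r}")
        return tuple(l for l, r in self.region_of.items() if r == region)

    def indices_of(self, labels: Sequence[str]) -> np.ndarray:
        order = {l: i for i, l in enumerate(self.labels)}
        try:
            return np.array([order[l] for l in labels], dtype=int)
        except KeyError as exc:
            raise UnknownChannelError(f"channel label {exc.args[0]!r} not in map") from exc

    def to_dict(self) -> dict:
        return {
            "region_of": dict(self.region_of),
            "occipital_alpha_set": list(self.occipital_alpha_set),
            "frontal_beta_set": list(self.frontal_beta_set),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ChannelMap":
        try:
            return cls(
                region_of=dict(d["region_of"]),
                occipital_alpha_set=tuple(d["occipital_alpha_set"]),
                frontal_beta_set=tuple(d["frontal_beta_set"]),
            )
        except (KeyError, TypeError) as exc:
            raise MalformedSidecarError(f"bad channel_map in sidecar: {exc}") from exc


def default_channel_map() -> ChannelMap:
    """The Biosemi-64 map with the region partition 17/14/6/17/10."""
    region_of = {l: r for r in REGIONS for l in _REGION_SETS[r]}
    # restore electrode ordering
    region_of = {l: region_of[l] for l in BIOSEMI64_LABELS}
    return ChannelMap(
        region_of=region_of,
        occipital_alpha_set=_REGION_SETS["occipital"],
        frontal_beta_set=_REGION_SETS["frontal"],
    )


# ---------------------------------------------------------------------------
# Frequency bands

@dataclass(frozen=True)
class BandSet:
    """Five contiguous, non-overlapping EEG bands tiling 1–50 Hz."""

    bands: tuple[tuple[str, float, float], ...] = (
        ("delta", 1.0, 4.0),
        ("theta", 4.0, 8.0),
        ("alpha", 8.0, 13.0),
        ("beta", 13.0, 30.0),
        ("gamma", 30.0, 50.0),
    )

    def __post_init__(self) -> None:
        if len(self.bands) != 5:
            raise ValueError("a BandSet has exactly five bands")
        for (_, lo, hi), (_, lo2, _) in zip(self.bands, self.bands[1:]):
            if hi != lo2:
                raise ValueError("bands must be contiguous and non-overlapping")
            if lo >= hi:
                raise ValueError("band edges must satisfy lo < hi")

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(name for name, _, _ in self.bands)

    @property
    def edges(self) -> tuple[float, float]:
        return self.bands[0][1], self.bands[-1][2]

    def index(self, name: str) -> int:
        return self.names.index(name)

    def __iter__(self):
        return iter(self.bands)


def default_band_set() -> BandSet:
    return BandSet()


# ---------------------------------------------------------------------------
# Annotations

ANNOTATION_KINDS = ("eye_closure", "state_mark", "detection")


@dataclass(frozen=True, order=True)
class Annotation:
    """A timed event: eye closure, state mark, or detector output."""

    onset_s: float
    duration_s: float = 0.0
    kind: str = "eye_closure"

    def __post_init__(self) -> None:
        if self.kind not in ANNOTATION_KINDS:
            raise AnnotationRangeError(f"unknown annotation kind {self.kind!r}")
        if self.duration_s < 0:
            raise AnnotationRangeError(
                f"annotation at {self.onset_s} s has negative duration {self.duration_s}"
            )

    @property
    def end_s(self) -> float:
        return self.onset_s + self.duration_s


# ---------------------------------------------------------------------------
# The recording container

@dataclass
class MultimodalRecording:
    """Synchronized EEG/EOG/ECG/NIRS streams with annotations.

    ``eeg``/``eog``/``ecg`` share the ``fs_eeg`` clock and one sample count;
    ``hbo``/``hb`` share the ``fs_nirs`` clock.  All matrices are
    channels × samples.
    """

    eeg: np.ndarray
    eog: np.ndarray
    ecg: np.ndarray
    hbo: np.ndarray
    hb: np.ndarray
    fs_eeg: float = 512.0
    fs_nirs: float = 10.0
    t0: float = 0.0
    channel_map: ChannelMap = field(default_factory=default_channel_map)
    annotations: list[Annotation] = field(default_factory=list)
    units: dict[str, str] = field(
        default_factory=lambda: {"eeg": "uV", "eog": "uV", "ecg": "uV", "nirs": "mM/DPF"}
    )

    def __post_init__(self) -> None:
        self.eeg = np.asarray(self.eeg, dtype=float)
        self.eog = np.asarray(self.eog, dtype=float)
        self.ecg = np.asarray(self.ecg, dtype=float)
        self.hbo = np.asarray(self.hbo, dtype=float)
        self.hb = np.asarray(self.hb, dtype=float)
        self.validate()

    # -- invariants --------------------------------------------------------
    def validate(self) -> None:
        if not (self.fs_eeg > 0 and self.fs_nirs > 0):
            raise DrowsikitError("sampling rates must be positive")
        n = self.eeg.shape[1]
        if self.eog.shape[1] != n or self.ecg.shape[1] != n:
            raise SampleCountMismatchError(
                f"EEG-clock streams disagree on sample count: "
                f"eeg={n}, eog={self.eog.shape[1]}, ecg={self.ecg.shape[1]}"
            )
        if self.hbo.shape != self.hb.shape:
            raise SampleCountMismatchError(
                f"hbo shape {self.hbo.shape} != hb shape {self.hb.shape}"
            )
        if self.eeg.shape[0] != len(self.channel_map.labels):
            raise UnknownChannelError(
                f"eeg has {self.eeg.shape[0]} rows but the channel map defines "
                f"{len(self.channel_map.labels)} labels"
            )
        dur = self.duration_s
        for ann in self.annotations:
            if ann.onset_s < 0 or ann.end_s > dur + 1e-9:
                raise AnnotationRangeError(
                    f"annotation {ann.kind} at {ann.onset_s} s (end {ann.end_s} s) "
                    f"outside recording of {dur} s"
                )

    @property
    def duration_s(self) -> float:
        """Recording length on the EEG clock, in seconds."""
        return self.eeg.shape[1] / self.fs_eeg

    @property
    def duration_nirs_s(self) -> float:
        return self.hbo.shape[1] / self.fs_nirs

    def eye_closures(self, min_duration_s: float = 2.0) -> list[Annotation]:
        """Eye-closure annotations at least ``min_duration_s`` long."""
        return [
            a
            for a in self.annotations
            if a.kind == "eye_closure" and a.duration_s >= min_duration_s
        ]


# ---------------------------------------------------------------------------
# Bundle readers / writers

_STREAM_FILES = {
    "eeg": "eeg.csv",
    "eog": "eog.csv",
    "ecg": "ecg.csv",
    "hbo": "nirs_hbo.csv",
    "hb": "nirs_hb.csv",
}


def write_recording(rec: MultimodalRecording, path: str | Path) -> None:
    """Write ``rec`` as a CSV + JSON bundle under the directory ``path``.

    The sidecars are written with a fixed field order, so a given recording
    always produces byte-identical metadata.
    """
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    streams = {
        "eeg": (rec.eeg, rec.channel_map.labels),
        "eog": (rec.eog, EOG_LABELS),
        "ecg": (rec.ecg, ECG_LABELS),
        "hbo": (rec.hbo, NIRS_LABELS[: rec.hbo.shape[0]]),
        "hb": (rec.hb, NIRS_LABELS[: rec.hb.shape[0]]),
    }
    for key, (mat, labels) in streams.items():
        df = pd.DataFrame(mat.T, columns=list(labels))
        df.to_csv(path / _STREAM_FILES[key], index=False)
    meta = {
        "fs_eeg": rec.fs_eeg,
        "fs_nirs": rec.fs_nirs,
        "t0": rec.t0,
        "units": rec.units,
        "channel_map": rec.channel_map.to_dict(),
    }
    (path / "meta.json").write_text(json.dumps(meta, indent=2) + "\n")
    write_events(rec.annotations, path / "events.json")


def read_recording(path: str | Path) -> MultimodalRecording:
    """Read a recording bundle written by :func:`write_recording`."""
    path = Path(path)
    for fname in (*_STREAM_FILES.values(), "meta.json"):
        if not (path / fname).exists():
            raise MissingStreamError(f"missing {fname} in bundle {path}")
    try:
        meta = json.loads((path / "meta.json").read_text())
        fs_eeg = float(meta["fs_eeg"])
        fs_nirs = float(meta["fs_nirs"])
        t0 = float(meta.get("t0", 0.0))
        units = dict(meta.get("units", {}))
        cmap = ChannelMap.from_dict(meta["channel_map"])
    except (json.JSONDecodeError, KeyError, TypeError, ValueError) as exc:
        if isinstance(exc, MalformedSidecarError):
            raise
        raise MalformedSidecarError(f"cannot parse meta.json: {exc}") from exc
    mats = {}
    for key, fname in _STREAM_FILES.items():
        df = pd.read_csv(path / fname)
        mats[key] = df.to_numpy(dtype=float).T
    if tuple(pd.read_csv(path / _STREAM_FILES["eeg"], nrows=0).columns) != cmap.labels:
        raise UnknownChannelError("eeg.csv header does not match the channel map labels")
    events_path = path / "events.json"
    annotations = read_events(events_path) if events_path.exists() else []
    return MultimodalRecording(
        eeg=mats["eeg"],
        eog=mats["eog"],
        ecg=mats["ecg"],
        hbo=mats["hbo"],
        hb=mats["hb"],
        fs_eeg=fs_eeg,
        fs_nirs=fs_nirs,
        t0=t0,
        channel_map=cmap,
        annotations=annotations,
        units=units or {"eeg": "uV", "eog": "uV", "ecg": "uV", "nirs": "mM/DPF"},
    )


def read_events(path: str | Path) -> list[Annotation]:
    """Read an events JSON file; annotations are returned sorted by onset."""
    try:
        raw = json.loads(Path(path).read_text())
        anns = [
            Annotation(
                onset_s=float(e["onset_s"]),
                duration_s=float(e["duration_s"]),
                kind=str(e["kind"]),
            )
            for e in raw
        ]
    except AnnotationRangeError:
        raise
    except (json.JSONDecodeError, KeyError, TypeError, ValueError) as exc:
        raise MalformedSidecarError(f"cannot parse events file {path}: {exc}") from exc
    return sorted(anns, key=lambda a: (a.onset_s, a.duration_s))


def write_events(annotations: Sequence[Annotation], path: str | Path) -> None:
    payload = [
        {"kind": a.kind, "onset_s": a.onset_s, "duration_s": a.duration_s}
        for a in sorted(annotations, key=lambda a: (a.onset_s, a.duration_s))
    ]
    Path(path).write_text(json.dumps(payload, indent=2) + "\n")
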