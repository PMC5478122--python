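"""Reading and writing iEEG clip files, manifests, and prediction CSVs.

Two on-disk dialects are supported:

``kaggle_mat``
    The seizure-prediction contest layout: one MAT v5 file per ten-minute
    segment, holding a single top-level structure whose name embeds the
    segment kind and index (e.g. ``interictal_segment_0001``) with fields
    ``data`` (channels x samples), ``sampling_frequency``,
    ``data_length_sec``, ``channels`` (labels) and ``sequence``.  Readers
    accept any top-level structure exposing those fields and ignore extras,
    because structure naming varies between subjects.

``native``
    A self-describing container: a JSON header line followed by the raw
    float32 sample matrix.  It exists so that tests and synthetic pipelines
    never depend on MAT tooling.

Class labels (interictal / preictal / test) are always derived from the
file name or the manifest, never from file contents, mirroring the contest
layout where test files carry no label.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.io import loadmat, savemat

SEGMENT_KINDS = ("interictal", "preictal", "test")

_MANIFEST_COLUMNS = ["path", "subject_id", "segment_kind", "segment_index", "sequence_index"]


class ClipFormatError(ValueError):
    """A clip file is unreadable or violates the clip invariants."""


@dataclass
class IEEGClip:
    """One labeled multichannel iEEG recording segment (the unit of prediction).

    ``data`` is a real matrix of shape ``(channels, samples)`` in microvolts.
    ``sequence_index`` is the 1-based position of this ten-minute segment
    within its one-hour sequence.
    """

    subject_id: str
    segment_kind: str
    segment_index: int
    sequence_index: int
    sampling_rate_hz: float
    channel_labels: list[str]
    data: np.ndarray
    duration_sec: float

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.segment_kind not in SEGMENT_KINDS:
            raise ClipFormatError(f"unknown segment kind {self.segment_kind!r}")
        if self.data.ndim != 2:
            raise ClipFormatError(f"data must be 2-D (channels x samples), got ndim={self.data.ndim}")
        if self.data.shape[0] == 0:
            raise ClipFormatError("empty channel axis")
        if self.data.shape[0] != len(self.channel_labels):
            raise ClipFormatError(
                f"channel mismatch: data has {self.data.shape[0]} rows, "
                f"{len(self.channel_labels)} labels"
            )
        if self.sampling_rate_hz <= 0:
            raise ClipFormatError("sampling_rate_hz must be positive")
        expected = round(self.duration_sec * self.sampling_rate_hz)
        if self.data.shape[1] != expected:
            raise ClipFormatError(
                f"sample-count mismatch: data has {self.data.shape[1]} samples, "
                f"duration x rate gives {expected}"
            )
        if not np.isfinite(self.data).all():
            raise ClipFormatError("data contains NaN or Inf")
        if self.segment_index < 1:
            raise ClipFormatError("segment_index must be >= 1")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def name(self) -> str:
        """Canonical clip name, e.g. ``Dog_1_preictal_segment_0003``."""
        return f"{self.subject_id}_{self.segment_kind}_segment_{self.segment_index:04d}"


_NAME_RE = re.compile(
    r"(?P<subject>.+?)_(?P<kind>interictal|preictal|test)_segment_(?P<index>\d+)",
    re.IGNORECASE,
)


def parse_clip_name(name: str) -> tuple[str, str, int]:
    """Extract ``(subject_id, segment_kind, segment_index)`` from a clip file name."""
    m = _NAME_RE.search(Path(name).stem)
    if m is None:
        raise ClipFormatError(
            f"cannot parse subject/kind/index from file name {name!r}; expected "
            "'<subject>_<interictal|preictal|test>_segment_<n>'"
        )
    return m.group("subject"), m.group("kind").lower(), int(m.group("index"))


# ---------------------------------------------------------------------------
# Kaggle MAT dialect


def _mat_struct_fields(entry) -> dict:
    """Field access for both struct_as_record layouts scipy may produce."""
    arr = np.asarray(entry)
    while arr.dtype == object and arr.size == 1 and arr.dtype.names is None:
        arr = np.asarray(arr.item())
    if arr.dtype.names is None:
        raise ClipFormatError("top-level MAT entry is not a structure")
    rec = arr.reshape(-1)[0]
    return {name: rec[name] for name in arr.dtype.names}


def _scalar(value, name: str) -> float:
    arr = np.asarray(value, dtype=float).reshape(-1)
    if arr.size != 1:
        raise ClipFormatError(f"field {name!r} is not a scalar")
    return float(arr[0])


def _read_kaggle_mat(path: Path) -> IEEGClip:
    subject, kind, index = parse_clip_name(path.name)
    try:
        contents = loadmat(str(path), squeeze_me=False, struct_as_record=True)
    except Exception as exc:  # scipy raises a zoo of error types
        raise ClipFormatError(f"unreadable MAT file {path}: {exc}") from exc
    structs = {k: v for k, v in contents.items() if not k.startswith("__")}
    if not structs:
        raise ClipFormatError(f"no data structure in {path}")
    # Prefer a structure whose name matches the file; else take the only one.
    key = next((k for k in structs if kind in k.lower()), next(iter(structs)))
    fields = _mat_struct_fields(structs[key])
    for required in ("data", "sampling_frequency", "data_length_sec", "channels", "sequence"):
        if required not in fields:
            raise ClipFormatError(f"missing field {required!r} in {path}")
    data = np.asarray(fields["data"], dtype=float)
    if data.ndim != 2:
        raise ClipFormatError(f"field 'data' must be a matrix in {path}")
    channels_raw = np.asarray(fields["channels"]).reshape(-1)
    labels = []
    for c in channels_raw:
        while isinstance(c, np.ndarray):
            c = c.reshape(-1)[0] if c.size else ""
        labels.append(str(c))
    return IEEGClip(
        subject_id=subject,
        segment_kind=kind,
        segment_index=index,
        sequence_index=int(_scalar(fields["sequence"], "sequence")),
        sampling_rate_hz=_scalar(fields["sampling_frequency"], "sampling_frequency"),
        channel_labels=labels,
        data=data,
        duration_sec=_scalar(fields["data_length_sec"], "data_length_sec"),
    )


def _write_kaggle_mat(clip: IEEGClip, path: Path) -> None:
    struct = {
        "data": clip.data,
        "sampling_frequency": float(clip.sampling_rate_hz),
        "data_length_sec": float(clip.duration_sec),
        "channels": np.array(clip.channel_labels, dtype=object),
        "sequence": float(clip.sequence_index),
    }
    key = f"{clip.segment_kind}_segment_{clip.segment_index}"
    savemat(str(path), {key: struct})


# ---------------------------------------------------------------------------
# Native dialect: one JSON header line, then raw little-endian float32 samples.


def _read_native(path: Path) -> IEEGClip:
    with open(path, "rb") as fh:
        header_line = fh.readline()
        try:
            header = json.loads(header_line.decode("utf-8"))
        except (UnicodeDecodeError, json.JSONDecodeError) as exc:
            raise ClipFormatError(f"bad native header in {path}: {exc}") from exc
        for required in (
            "subject_id", "segment_kind", "segment_index", "sequence_index",
            "sampling_rate_hz", "channel_labels", "duration_sec", "shape",
        ):
            if required not in header:
                raise ClipFormatError(f"missing field {required!r} in {path}")
        shape = tuple(header["shape"])
        data = np.fromfile(fh, dtype="<f4", count=int(np.prod(shape)))
    if data.size != int(np.prod(shape)):
        raise ClipFormatError(f"truncated data matrix in {path}")
    return IEEGClip(
        subject_id=header["subject_id"],
        segment_kind=header["segment_kind"],
        segment_index=int(header["segment_index"]),
        sequence_index=int(header["sequence_index"]),
        sampling_rate_hz=float(header["sampling_rate_hz"]),
        channel_labels=list(header["channel_labels"]),
        data=data.reshape(shape).astype(float),
        duration_sec=float(header["duration_sec"]),
    )


def _write_native(clip: IEEGClip, path: Path) -> None:
    header = {
        "subject_id": clip.subject_id,
        "segment_kind": clip.segment_kind,
        "segment_index": clip.segment_index,
        "sequence_index": clip.sequence_index,
        "sampling_rate_hz": clip.sampling_rate_hz,
        "channel_labels": clip.channel_labels,
        "duration_sec": clip.duration_sec,
        "shape": list(clip.data.shape),
    }
    with open(path, "wb") as fh:
        fh.write((json.dumps(header) + "\n").encode("utf-8"))
        clip.data.astype("<f4").tofile(fh)


def read_clip(path, dialect: str = "kaggle_mat") -> IEEGClip:
    """Read one clip file under the named dialect.

    The label (interictal/preictal/test), subject and segment index come from
    the file name; the signal matrix, rate and sequence index from the file.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if dialect == "kaggle_mat":
        return _read_kaggle_mat(path)
    if dialect == "native":
        clip = _read_native(path)
        # file name wins over the stored label when it parses
        try:
            subject, kind, index = parse_clip_name(path.name)
        except ClipFormatError:
            return clip
        clip.subject_id, clip.segment_kind, clip.segment_index = subject, kind, index
        return clip
    raise ValueError(f"unknown dialect {dialect!r}")


def write_clip(clip: IEEGClip, path, dialect: str = "kaggle_mat") -> None:
    """Write one clip; ``read_clip(write_clip(c))`` recovers ``c`` up to float32 in native."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    if dialect == "kaggle_mat":
        _write_kaggle_mat(clip, path)
    elif dialect == "native":
        _write_native(clip, path)
    else:
        raise ValueError(f"unknown dialect {dialect!r}")


# ---------------------------------------------------------------------------
# Manifest


@dataclass
class ClipManifest:
    """Ordered index of clip files with their labels.

    Rows are kept sorted lexicographically by (subject, kind, index) so that
    enumeration order is deterministic regardless of filesystem order.
    """

    rows: pd.DataFrame = field(default_factory=lambda: pd.DataFrame(columns=_MANIFEST_COLUMNS))

    def __post_init__(self) -> None:
        df = pd.DataFrame(self.rows, columns=_MANIFEST_COLUMNS).copy()
        df["segment_index"] = df["segment_index"].astype(int)
        df["sequence_index"] = df["sequence_index"].astype(int)
        df = df.sort_values(["subject_id", "segment_kind", "segment_index"], kind="stable")
        df = df.reset_index(drop=True)
        dup = df.duplicated(["subject_id", "segment_kind", "segment_index"])
        if dup.any():
            first = df[dup].iloc[0]
            raise ValueError(
                "duplicate manifest entry "
                f"({first.subject_id}, {first.segment_kind}, {first.segment_index})"
            )
        self.rows = df

    @classmethod
    def from_directory(cls, directory, dialect: str = "kaggle_mat") -> "ClipManifest":
        """Build a manifest by scanning a directory for parseable clip names."""
        suffix = ".mat" if dialect == "kaggle_mat" else ".ieeg"
        records = []
        for path in sorted(Path(directory).glob(f"*{suffix}")):
            try:
                subject, kind, index = parse_clip_name(path.name)
            except ClipFormatError:
                continue
            clip = read_clip(path, dialect)
            records.append((str(path), subject, kind, index, clip.sequence_index))
        return cls(pd.DataFrame(records, columns=_MANIFEST_COLUMNS))

    @classmethod
    def read_csv(cls, path) -> "ClipManifest":
        return cls(pd.read_csv(path))

    def write_csv(self, path) -> None:
        self.rows.to_csv(path, index=False)

    def subjects(self) -> list[str]:
        return sorted(self.rows["subject_id"].unique())

    def select(self, subject_id: str | None = None, segment_kind: str | None = None) -> pd.DataFrame:
        df = self.rows
        if subject_id is not None:
            df = df[df["subject_id"] == subject_id]
        if segment_kind is not None:
            df = df[df["segment_kind"] == segment_kind]
        return df.reset_index(drop=True)

    def validate_files(self) -> None:
        missing = [p for p in self.rows["path"] if not Path(p).exists()]
        if missing:
            raise FileNotFoundError(f"{len(missing)} manifest files missing, first: {missing[0]}")

    def __len__(self) -> int:
        return len(self.rows)


# ---------------------------------------------------------------------------
# Predictions


@dataclass(frozen=True)
class PredictionRecord:
    clip_name: str
    preictal_probability: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.preictal_probability <= 1.0:
            raise ValueError(
                f"probability {self.preictal_probability} for {self.clip_name} outside [0, 1]"
            )


def write_predictions(records: Sequence[PredictionRecord], path) -> None:
    """Write contest-format predictions: header ``clip,preictal``, >= 6 sig digits."""
    names = [r.clip_name for r in records]
    if len(set(names)) != len(names):
        seen, dup = set(), None
        for n in names:
            if n in seen:
                dup = n
                break
            seen.add(n)
        raise ValueError(f"duplicate clip name {dup!r}")
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("clip,preictal\n")
        for r in records:
            fh.write(f"{r.clip_name},{r.preictal_probability:.8g}\n")


def read_predictions(path) -> list[PredictionRecord]:
    df = pd.read_csv(path)
    if list(df.columns[:2]) != ["clip", "preictal"]:
        raise ValueError(f"expected columns clip,preictal in {path}, got {list(df.columns)}")
    return [PredictionRecord(str(r.clip), float(r.preictal)) for r in df.itertuples()]
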