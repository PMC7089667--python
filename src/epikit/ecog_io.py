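"""Session storage, chunking, chunk labeling and training-library assembly.

Chronic single-channel ECoG telemetry is stored as hour-long sessions of
uniformly sampled voltage (µV).  Seizure annotations are half-open intervals
in 0-based seconds from session start, labeled ``ictal`` or ``interictal``.
Detection operates on fixed-length chunks (default 5 s), so this module owns
the chunk grid and the rule mapping interval annotations onto chunk labels.

On-disk dialects:

* HDF5 — datasets ``samples`` plus attrs ``fs``, ``session_start``,
  ``channel_id``, ``animal_id``, ``unit`` (lossless round trip).
* EDF — single-signal European Data Format, physical dimension µV,
  1-second data records of 16-bit integers (round trip exact to one
  quantization step of the declared physical range).
* Annotations — CSV with columns ``start_s,end_s,state,provenance``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

INTERICTAL = "interictal"
ICTAL = "ictal"
_STATES = (INTERICTAL, ICTAL)

__all__ = [
    "EcogRecording",
    "AnnotationSet",
    "ChunkIndex",
    "SeizureLibrary",
    "chunk_recording",
    "label_chunks",
    "build_library",
    "read_session",
    "write_session",
    "read_annotations",
    "write_annotations",
    "INTERICTAL",
    "ICTAL",
]


@dataclass
class EcogRecording:
    """Uniformly sampled single-channel voltage series in µV."""

    samples: np.ndarray
    fs: float
    session_start: str = "1970-01-01T00:00:00"
    channel_id: str = "ecog0"
    animal_id: str = "animal0"

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.fs <= 0:
            raise ValueError(f"fs must be positive, got {self.fs}")
        if self.samples.ndim != 1 or self.samples.size < 1:
            raise ValueError("samples must be a non-empty 1-D array")
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("samples must be finite")

    @property
    def duration_s(self) -> float:
        return self.samples.size / self.fs


@dataclass
class AnnotationSet:
    """Labeled half-open intervals ``(start_s, end_s, state)``.

    ``provenance`` records how the labels were produced: ``human`` (visual
    inspection), ``detector`` (automated), or ``verified`` (detector output
    reviewed by a human).
    """

    intervals: list[tuple[float, float, str]] = field(default_factory=list)
    provenance: str = "human"

    def __post_init__(self) -> None:
        ivs = [(float(s), float(e), str(st)) for s, e, st in self.intervals]
        for s, e, st in ivs:
            if e <= s:
                raise ValueError(f"interval ({s}, {e}) has end <= start")
            if st not in _STATES:
                raise ValueError(f"unknown state {st!r}; expected one of {_STATES}")
        for st in _STATES:
            same = sorted((s, e) for s, e, x in ivs if x == st)
            for (s1, e1), (s2, e2) in zip(same, same[1:]):
                if s2 < e1:
                    raise ValueError(
                        f"overlapping {st} intervals ({s1}, {e1}) and ({s2}, {e2})"
                    )
        self.intervals = sorted(ivs)

    def ictal_intervals(self) -> list[tuple[float, float]]:
        return [(s, e) for s, e, st in self.intervals if st == ICTAL]

    def __len__(self) -> int:
        return len(self.intervals)


@dataclass
class ChunkIndex:
    """Half-open sample windows tiling a recording on a fixed chunk grid."""

    chunk_s: float
    fs: float
    windows: list[tuple[int, int]]
    labels: np.ndarray | None = None

    @property
    def n_chunks(self) -> int:
        return len(self.windows)

    def window_times(self) -> np.ndarray:
        """(n, 2) array of half-open chunk time spans in seconds."""
        return np.array([(i0 / self.fs, i1 / self.fs) for i0, i1 in self.windows])


def chunk_recording(rec: EcogRecording, chunk_s: float = 5.0) -> ChunkIndex:
    """Tile a recording into consecutive fixed-length windows.

    Windows are half-open sample ranges ``[i*L, (i+1)*L)`` with
    ``L = chunk_s * fs`` samples; a trailing partial window is dropped so every
    chunk yields a fixed-length feature vector.
    """
    length = chunk_s * rec.fs
    if abs(length - round(length)) > 1e-9:
        raise ValueError(
            f"chunk_s * fs = {length} is not an integer number of samples"
        )
    length = int(round(length))
    n = rec.samples.size // length
    if n == 0:
        warnings.warn(
            f"chunk ({chunk_s} s) longer than recording "
            f"({rec.duration_s:.3f} s); zero windows",
            stacklevel=2,
        )
    windows = [(i * length, (i + 1) * length) for i in range(n)]
    return ChunkIndex(chunk_s=chunk_s, fs=rec.fs, windows=windows)


def label_chunks(idx: ChunkIndex, ann: AnnotationSet) -> np.ndarray:
    """Label each chunk 1 (ictal) iff it overlaps any ictal interval by > 0 s.

    The overlap rule is strict (> 0 s): a chunk whose window merely touches an
    interval boundary stays interictal (both chunk windows and annotation
    intervals are half-open).
    """
    labels = np.zeros(idx.n_chunks, dtype=int)
    if idx.n_chunks == 0:
        return labels
    spans = idx.window_times()
    for s, e in ann.ictal_intervals():
        hit = (spans[:, 0] < e) & (spans[:, 1] > s)
        labels[hit] = 1
    return labels


@dataclass
class SeizureLibrary:
    """Training corpus: sessions with chunk grids and per-chunk labels.

    Every session that contains at least one seizure is retained in full (the
    entire session, not just the ictal chunks), plus any explicitly added
    seizure-free sessions, so the interictal class is sampled from realistic
    context around each seizure.
    """

    session_ids: list[str]
    recordings: list[EcogRecording]
    annotations: list[AnnotationSet]
    chunk_indices: list[ChunkIndex]
    chunk_labels: list[np.ndarray]
    chunk_s: float
    feature_matrix: np.ndarray | None = None

    @property
    def n_sessions(self) -> int:
        return len(self.session_ids)

    def all_labels(self) -> np.ndarray:
        return np.concatenate(self.chunk_labels) if self.chunk_labels else np.array([])

    def session_index_per_chunk(self) -> np.ndarray:
        """Session index of every chunk, aligned with :meth:`all_labels`."""
        return np.concatenate(
            [np.full(lbl.size, i) for i, lbl in enumerate(self.chunk_labels)]
        ) if self.chunk_labels else np.array([], dtype=int)

    def class_balance(self) -> dict[str, int]:
        lbl = self.all_labels()
        return {
            INTERICTAL: int(np.sum(lbl == 0)),
            ICTAL: int(np.sum(lbl == 1)),
        }


def build_library(
    sessions: list[tuple[str, EcogRecording, AnnotationSet]],
    chunk_s: float = 5.0,
    include_seizure_free: tuple[str, ...] = (),
    expected_duration_s: float | None = None,
) -> SeizureLibrary:
    """Assemble the training library from annotated sessions.

    Sessions containing >= 1 ictal interval are retained in full; sessions
    without seizures are retained only if listed in ``include_seizure_free``.
    ``expected_duration_s`` optionally enforces that every seizure-containing
    session is a full-length record (e.g. the hour-long files of a chronic
    telemetry deployment).
    """
    seen: set[str] = set()
    ids, recs, anns, idxs, labels = [], [], [], [], []
    for item in sessions:
        if len(item) != 3:
            raise ValueError(
                "each session must be a (session_id, recording, annotations) triple"
            )
        sid, rec, ann = item
        if ann is None:
            raise ValueError(f"session {sid!r} has no annotations")
        if sid in seen:
            raise ValueError(f"duplicate session id {sid!r}")
        seen.add(sid)
        has_seizure = len(ann.ictal_intervals()) > 0
        if not has_seizure and sid not in include_seizure_free:
            continue
        if has_seizure and expected_duration_s is not None:
            if abs(rec.duration_s - expected_duration_s) > chunk_s:
                raise ValueError(
                    f"session {sid!r} with seizures is {rec.duration_s:.1f} s, "
                    f"expected a full {expected_duration_s:.1f} s record"
                )
        idx = chunk_recording(rec, chunk_s)
        ids.append(sid)
        recs.append(rec)
        anns.append(ann)
        idxs.append(idx)
        labels.append(label_chunks(idx, ann))
    return SeizureLibrary(
        session_ids=ids,
        recordings=recs,
        annotations=anns,
        chunk_indices=idxs,
        chunk_labels=labels,
        chunk_s=chunk_s,
    )


# ---------------------------------------------------------------------------
# Annotation CSV I/O

def write_annotations(ann: AnnotationSet, path: str | Path) -> None:
    df = pd.DataFrame(
        [(s, e, st, ann.provenance) for s, e, st in ann.intervals],
        columns=["start_s", "end_s", "state", "provenance"],
    )
    df.to_csv(path, index=False)


def read_annotations(path: str | Path) -> AnnotationSet:
    df = pd.read_csv(path)
    required = {"start_s", "end_s", "state"}
    if not required.issubset(df.columns):
        raise ValueError(f"annotation CSV missing columns {required - set(df.columns)}")
    prov = "human"
    if "provenance" in df.columns and len(df):
        prov = str(df["provenance"].iloc[0])
    intervals = [
        (float(r.start_s), float(r.end_s), str(r.state)) for r in df.itertuples()
    ]
    return AnnotationSet(intervals=intervals, provenance=prov)


# ---------------------------------------------------------------------------
# HDF5 dialect

_UNIT = "uV"


def _write_h5(rec: EcogRecording, path: Path) -> None:
    with h5py.File(path, "w") as f:
        d = f.create_dataset("samples", data=rec.samples)
        d.attrs["unit"] = _UNIT
        f.attrs["fs"] = rec.fs
        f.attrs["session_start"] = rec.session_start
        f.attrs["channel_id"] = rec.channel_id
        f.attrs["animal_id"] = rec.animal_id


def _read_h5(path: Path) -> EcogRecording:
    with h5py.File(path, "r") as f:
        if "samples" not in f:
            raise ValueError(f"{path}: missing 'samples' dataset")
        unit = f["samples"].attrs.get("unit", _UNIT)
        if isinstance(unit, bytes):
            unit = unit.decode()
        if unit != _UNIT:
            raise ValueError(f"{path}: unit metadata {unit!r}, expected {_UNIT!r}")
        return EcogRecording(
            samples=f["samples"][()],
            fs=float(f.attrs["fs"]),
            session_start=str(f.attrs.get("session_start", "")),
            channel_id=str(f.attrs.get("channel_id", "ecog0")),
            animal_id=str(f.attrs.get("animal_id", "animal0")),
        )


# ---------------------------------------------------------------------------
# EDF dialect (single signal, 1-second records, int16)
#
# Layout: 256-byte fixed ASCII header, one 256-byte signal header, then
# n_records * fs little-endian int16 samples.  The true sample count is kept
# in the reserved field so the trailing zero-padding of the last record can
# be stripped on read.


def _ascii(s: str, width: int) -> bytes:
    b = s.encode("ascii")[:width]
    return b + b" " * (width - len(b))


def _write_edf(rec: EcogRecording, path: Path) -> None:
    fs = rec.fs
    if abs(fs - round(fs)) > 1e-9:
        raise ValueError(f"EDF dialect requires an integer sampling rate, got {fs}")
    spr = int(round(fs))  # samples per 1-s record
    x = rec.samples
    n = x.size
    n_rec = -(-n // spr)
    phys_max = max(1.0, float(np.max(np.abs(x)))) * 1.000001
    dig_max, dig_min = 32767, -32768
    scale = (dig_max - dig_min) / (2 * phys_max)
    padded = np.zeros(n_rec * spr)
    padded[:n] = x
    digital = np.clip(
        np.round((padded + phys_max) * scale + dig_min), dig_min, dig_max
    ).astype("<i2")

    hdr = b"".join(
        [
            _ascii("0", 8),
            _ascii(rec.animal_id, 80),
            _ascii(rec.channel_id, 80),
            _ascii("01.01.00", 8),
            _ascii("00.00.00", 8),
            _ascii(str(256 + 256), 8),
            _ascii(f"NSAMPLES={n}", 44),
            _ascii(str(n_rec), 8),
            _ascii("1", 8),
            _ascii("1", 4),
        ]
    )
    sig = b"".join(
        [
            _ascii(rec.channel_id, 16),
            _ascii("", 80),
            _ascii(_UNIT, 8),
            _ascii(f"{-phys_max:.6g}"[:8], 8),
            _ascii(f"{phys_max:.6g}"[:8], 8),
            _ascii(str(dig_min), 8),
            _ascii(str(dig_max), 8),
            _ascii("BP:1-160Hz", 80),
            _ascii(str(spr), 8),
            _ascii("", 32),
        ]
    )
    with open(path, "wb") as f:
        f.write(hdr)
        f.write(sig)
        f.write(digital.tobytes())


def _read_edf(path: Path) -> EcogRecording:
    with open(path, "rb") as f:
        hdr = f.read(256)
        if len(hdr) < 256:
            raise ValueError(f"{path}: truncated EDF header")
        animal = hdr[8:88].decode("ascii").strip()
        channel = hdr[88:168].decode("ascii").strip()
        reserved = hdr[192:236].decode("ascii").strip()
        n_rec = int(hdr[236:244].decode("ascii").strip())
        rec_dur = float(hdr[244:252].decode("ascii").strip())
        ns = int(hdr[252:256].decode("ascii").strip())
        if ns != 1:
            raise ValueError(f"{path}: expected a single EDF signal, found {ns}")
        sig = f.read(256)
        label = sig[0:16].decode("ascii").strip()
        dim = sig[96:104].decode("ascii").strip()
        if dim != _UNIT:
            raise ValueError(f"{path}: physical dimension {dim!r}, expected {_UNIT!r}")
        phys_min = float(sig[104:112].decode("ascii").strip())
        phys_max = float(sig[112:120].decode("ascii").strip())
        dig_min = int(sig[120:128].decode("ascii").strip())
        dig_max = int(sig[128:136].decode("ascii").strip())
        spr = int(sig[216:224].decode("ascii").strip())
        raw = np.frombuffer(f.read(2 * n_rec * spr), dtype="<i2").astype(float)
    gain = (phys_max - phys_min) / (dig_max - dig_min)
    x = (raw - dig_min) * gain + phys_min
    n = raw.size
    if reserved.startswith("NSAMPLES="):
        n = int(reserved.split("=", 1)[1])
    fs = spr / rec_dur
    return EcogRecording(
        samples=x[:n], fs=fs, channel_id=label or channel, animal_id=animal
    )


def write_session(rec: EcogRecording, path: str | Path) -> None:
    """Write a session to EDF (``.edf``) or HDF5 (``.h5``/``.hdf5``)."""
    path = Path(path)
    if path.suffix.lower() == ".edf":
        _write_edf(rec, path)
    elif path.suffix.lower() in (".h5", ".hdf5"):
        _write_h5(rec, path)
    else:
        raise ValueError(f"unrecognized session format {path.suffix!r}")


def read_session(path: str | Path) -> EcogRecording:
    """Read a session from EDF or HDF5 (dispatch on extension)."""
    path = Path(path)
    if path.suffix.lower() == ".edf":
        return _read_edf(path)
    if path.suffix.lower() in (".h5", ".hdf5"):
        return _read_h5(path)
    raise ValueError(f"unrecognized session format {path.suffix!r}")
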