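"""Domain types and IO for multi-channel EMG records.

A record is an ``m x N`` array (channels by samples) in volts with
subject / motion / side / trial labels and a sampling rate.  On disk a
record is a delimited numeric text file with one column per channel; a
manifest CSV binds file paths to labels.  Channel concatenation turns a
record into the single long vector ``X = [x_1, x_2, ..., x_m]`` that the
scalogram stream analyzes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

__all__ = [
    "EmgFormatError",
    "MultichannelEmgRecord",
    "ManifestEntry",
    "DatasetManifest",
    "SplitSpec",
    "read_record",
    "write_record",
    "read_manifest",
    "write_manifest",
    "concat_channels",
    "resample_to_length",
    "build_split",
]


class EmgFormatError(ValueError):
    """Raised when an on-disk signal or manifest violates the expected format."""


@dataclass(frozen=True)
class MultichannelEmgRecord:
    """A labelled multi-channel EMG signal.

    Parameters
    ----------
    subject_id, motion_id : str
        Identity and motion labels.
    trial : int
        Repetition index (1-based in manifests).
    sampling_rate : float
        Samples per second, > 0.
    signal : ndarray of shape (m, N)
        Channel-by-sample amplitudes in volts; all channels share N >= 2.
    side : str, optional
        Recording side ("left"/"right") where the protocol uses both arms.
    session : int, optional
        Acquisition session index.
    """

    subject_id: str
    motion_id: str
    trial: int
    sampling_rate: float
    signal: np.ndarray
    side: str | None = None
    session: int | None = None

    def __post_init__(self) -> None:
        sig = np.asarray(self.signal, dtype=float)
        if sig.ndim != 2:
            raise ValueError(f"signal must be 2-D (channels x samples), got ndim={sig.ndim}")
        if sig.shape[0] < 1:
            raise ValueError("record needs at least one channel")
        if sig.shape[1] < 2:
            raise ValueError(f"record needs at least 2 samples per channel, got {sig.shape[1]}")
        if not np.all(np.isfinite(sig)):
            raise ValueError("signal contains non-finite values")
        if not self.sampling_rate > 0:
            raise ValueError(f"sampling_rate must be > 0, got {self.sampling_rate}")
        object.__setattr__(self, "signal", sig)

    @property
    def n_channels(self) -> int:
        return self.signal.shape[0]

    @property
    def n_samples(self) -> int:
        return self.signal.shape[1]

    @property
    def duration(self) -> float:
        """Record length in seconds."""
        return self.n_samples / self.sampling_rate

    @property
    def key(self) -> tuple:
        return (self.subject_id, self.motion_id, self.side, self.trial)


@dataclass(frozen=True)
class ManifestEntry:
    """One manifest row: a file path (or in-memory record) plus its labels."""

    subject_id: str
    motion_id: str
    trial: int
    sampling_rate: float
    path: Path | None = None
    side: str | None = None
    session: int | None = None
    record: MultichannelEmgRecord | None = None

    @property
    def key(self) -> tuple:
        return (self.subject_id, self.motion_id, self.side, self.trial)

    def load(self) -> MultichannelEmgRecord:
        if self.record is not None:
            return self.record
        if self.path is None:
            raise ValueError("manifest entry has neither an in-memory record nor a path")
        return read_record(
            self.path,
            subject_id=self.subject_id,
            motion_id=self.motion_id,
            trial=self.trial,
            sampling_rate=self.sampling_rate,
            side=self.side,
            session=self.session,
        )


@dataclass
class DatasetManifest:
    """The set of records making up a dataset.

    Uniqueness of the (subject, motion, side, trial) key is enforced so a
    trial-index split partitions the dataset unambiguously.
    """

    entries: list[ManifestEntry] = field(default_factory=list)

    def __post_init__(self) -> None:
        keys = [e.key for e in self.entries]
        if len(set(keys)) != len(keys):
            seen: set = set()
            for k in keys:
                if k in seen:
                    raise ValueError(f"duplicate manifest key {k}")
                seen.add(k)

    def __len__(self) -> int:
        return len(self.entries)

    def __iter__(self):
        return iter(self.entries)

    @property
    def subjects(self) -> list[str]:
        return sorted({e.subject_id for e in self.entries})

    @property
    def motions(self) -> list[str]:
        return sorted({e.motion_id for e in self.entries})

    @property
    def sides(self) -> list[str | None]:
        return sorted({e.side for e in self.entries}, key=lambda s: (s is not None, s))

    @property
    def trials(self) -> list[int]:
        return sorted({e.trial for e in self.entries})

    @property
    def n_subjects(self) -> int:
        return len(self.subjects)

    @property
    def n_motions(self) -> int:
        return len(self.motions)

    def cells(self) -> list[tuple]:
        """Distinct (subject, motion, side) groups."""
        return sorted({(e.subject_id, e.motion_id, e.side) for e in self.entries},
                      key=lambda c: (c[0], c[1], str(c[2])))


@dataclass(frozen=True)
class SplitSpec:
    """Disjoint, nonempty train / test trial-index sets (1-based)."""

    train_trials: frozenset
    test_trials: frozenset

    def __init__(self, train_trials: Iterable[int], test_trials: Iterable[int]):
        object.__setattr__(self, "train_trials", frozenset(int(t) for t in train_trials))
        object.__setattr__(self, "test_trials", frozenset(int(t) for t in test_trials))
        if not self.train_trials or not self.test_trials:
            raise ValueError("train and test trial sets must both be nonempty")
        if self.train_trials & self.test_trials:
            raise ValueError(
                f"train/test trial sets overlap: {sorted(self.train_trials & self.test_trials)}"
            )


def _sniff_delimiter(path: Path) -> str | None:
    with open(path) as fh:
        for line in fh:
            if line.strip():
                if "," in line:
                    return ","
                if "\t" in line:
                    return "\t"
                return None  # whitespace
    return None


def read_record(
    path,
    *,
    subject_id: str,
    motion_id: str,
    trial: int,
    sampling_rate: float,
    side: str | None = None,
    session: int | None = None,
    delimiter: str | None = "auto",
) -> MultichannelEmgRecord:
    """Read a delimited-text signal file (one column per channel).

    ``delimiter="auto"`` sniffs comma / tab / whitespace from the first
    non-blank line.  Ragged rows or non-numeric cells raise
    :class:`EmgFormatError`.
    """
    path = Path(path)
    if path.stat().st_size == 0 or not path.read_text().strip():
        raise EmgFormatError(f"{path}: empty signal file")
    if delimiter == "auto":
        delimiter = _sniff_delimiter(path)
    try:
        data = np.loadtxt(path, delimiter=delimiter, ndmin=2)
    except ValueError as exc:
        raise EmgFormatError(f"{path}: {exc}") from exc
    if data.size == 0:
        raise EmgFormatError(f"{path}: empty signal file")
    # rows are samples on disk; in memory channels are rows
    return MultichannelEmgRecord(
        subject_id=subject_id,
        motion_id=motion_id,
        trial=trial,
        sampling_rate=sampling_rate,
        signal=data.T,
        side=side,
        session=session,
    )


def write_record(path, record: MultichannelEmgRecord, delimiter: str = ",") -> None:
    """Write a record as delimited text, one row per sample, full float precision."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    np.savetxt(path, record.signal.T, fmt="%.17g", delimiter=delimiter)


_MANIFEST_COLUMNS = ["path", "subject", "motion", "side", "session", "trial", "rate"]


def write_manifest(path, manifest: DatasetManifest) -> None:
    rows = []
    for e in manifest.entries:
        rows.append(
            {
                "path": str(e.path) if e.path is not None else "",
                "subject": e.subject_id,
                "motion": e.motion_id,
                "side": e.side if e.side is not None else "",
                "session": e.session if e.session is not None else "",
                "trial": e.trial,
                "rate": e.sampling_rate,
            }
        )
    pd.DataFrame(rows, columns=_MANIFEST_COLUMNS).to_csv(path, index=False)


def read_manifest(path, *, relative_to: Path | None = None) -> DatasetManifest:
    """Load a manifest CSV; relative signal paths resolve against ``relative_to``
    (default: the manifest's own directory)."""
    path = Path(path)
    base = Path(relative_to) if relative_to is not None else path.parent
    df = pd.read_csv(path, dtype={"subject": str, "motion": str})
    missing = [c for c in _MANIFEST_COLUMNS if c not in df.columns]
    if missing:
        raise EmgFormatError(f"{path}: manifest missing columns {missing}")
    entries = []
    for row in df.itertuples(index=False):
        p = Path(str(row.path))
        if not p.is_absolute():
            p = base / p
        side = None if pd.isna(row.side) or row.side == "" else str(row.side)
        session = None if pd.isna(row.session) or row.session == "" else int(row.session)
        entries.append(
            ManifestEntry(
                subject_id=str(row.subject),
                motion_id=str(row.motion),
                trial=int(row.trial),
                sampling_rate=float(row.rate),
                path=p,
                side=side,
                session=session,
            )
        )
    return DatasetManifest(entries)


def concat_channels(record: MultichannelEmgRecord) -> np.ndarray:
    """Concatenate channels in channel order: ``X = [x_1, x_2, ..., x_m]``.

    Returns a 1-D array of length ``m * N`` (channel 1's samples first).
    """
    return record.signal.reshape(-1).copy()


def resample_to_length(signal: np.ndarray, target_len: int) -> np.ndarray:
    """Resample a 1-D signal to ``target_len`` samples by linear interpolation.

    Endpoints are preserved; no cropping or padding is involved, mirroring
    the "resize linearly without crops" convention used for images.
    """
    x = np.asarray(signal, dtype=float)
    if x.ndim != 1:
        raise ValueError("signal must be 1-D")
    if x.size < 2:
        raise ValueError("signal must have at least 2 samples")
    target_len = int(target_len)
    if target_len < 2:
        raise ValueError(f"target_len must be >= 2, got {target_len}")
    if target_len == x.size:
        return x.copy()
    old = np.linspace(0.0, 1.0, x.size)
    new = np.linspace(0.0, 1.0, target_len)
    return np.interp(new, old, x)


def build_split(
    manifest: DatasetManifest, spec: SplitSpec
) -> tuple[list[ManifestEntry], list[ManifestEntry]]:
    """Deterministically partition a manifest by trial index.

    Every (subject, motion, side) cell must contain every trial index named
    in the split; the partition is then a pure product, so
    ``len(train) == n_cells * len(train_trials)``.
    """
    by_cell: dict[tuple, dict[int, ManifestEntry]] = {}
    for e in manifest.entries:
        by_cell.setdefault((e.subject_id, e.motion_id, e.side), {})[e.trial] = e
    needed = sorted(spec.train_trials | spec.test_trials)
    for cell, trials in sorted(by_cell.items(), key=lambda kv: (kv[0][0], kv[0][1], str(kv[0][2]))):
        for t in needed:
            if t not in trials:
                raise ValueError(
                    f"trial {t} missing for cell (subject={cell[0]}, motion={cell[1]}, side={cell[2]})"
                )
    train = [e for e in manifest.entries if e.trial in spec.train_trials]
    test = [e for e in manifest.entries if e.trial in spec.test_trials]
    return train, test
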