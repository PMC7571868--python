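"""Signal containers and plain-text record I/O.

A *record* is a directory holding one delimited-text file per channel
(``<channel>.tsv``).  Each file starts with comment-style header lines
declaring the sampling rate and units, followed by one sample per line::

    # fs=1000.0
    # units=mV
    0.0123
    ...

An optional ``ground_truth.tsv`` sidecar stores per-beat annotations
(R time, beat type, Q/S/T-end fiducials) as tab-separated columns.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import FormatError, InputError

#: channel roles the pipeline understands
KNOWN_ROLES = ("bcg", "ecg", "ecg_sync", "sbp", "dbp")


@dataclasses.dataclass
class SignalRecord:
    """A single named channel: samples, sampling rate and units."""

    name: str
    samples: np.ndarray
    fs: float
    units: str = "a.u."

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 1:
            raise InputError(f"channel {self.name!r}: samples must be 1-D")
        if not self.fs > 0:
            raise InputError(f"channel {self.name!r}: fs must be positive, got {self.fs}")

    @property
    def n(self) -> int:
        return self.samples.size

    @property
    def duration(self) -> float:
        """Record length in seconds."""
        return self.n / self.fs

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.n) / self.fs

    def copy_with(self, samples: np.ndarray, fs: float | None = None) -> "SignalRecord":
        return SignalRecord(self.name, np.asarray(samples, dtype=float),
                            self.fs if fs is None else fs, self.units)


def write_channel(path: Path | str, rec: SignalRecord) -> None:
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(f"# fs={rec.fs!r}\n# units={rec.units}\n")
        np.savetxt(fh, rec.samples, fmt="%.10g")


def read_channel(path: Path | str, name: str | None = None) -> SignalRecord:
    path = Path(path)
    fs = None
    units = "a.u."
    n_header = 0
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            n_header += 1
            key, _, val = line[1:].strip().partition("=")
            if key.strip() == "fs":
                fs = float(val)
            elif key.strip() == "units":
                units = val.strip()
    if fs is None:
        raise FormatError(f"{path}: no '# fs=' header line — sampling rate is mandatory")
    samples = np.loadtxt(path, comments="#", ndmin=1)
    return SignalRecord(name or path.stem, samples, fs, units)


def write_record(directory: Path | str, channels: dict[str, SignalRecord]) -> None:
    """Write one ``<role>.tsv`` file per channel into *directory*."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    for role, rec in channels.items():
        write_channel(directory / f"{role}.tsv", rec)


def read_record(directory: Path | str) -> dict[str, SignalRecord]:
    """Read every channel file of a record directory, keyed by role.

    Unknown channel roles are kept with a warning; a missing sampling-rate
    header raises :class:`FormatError`.
    """
    import warnings

    directory = Path(directory)
    if not directory.is_dir():
        raise InputError(f"record directory not found: {directory}")
    channels: dict[str, SignalRecord] = {}
    for path in sorted(directory.glob("*.tsv")):
        with open(path) as fh:
            first = fh.readline()
        if not first.startswith("#"):
            continue  # sidecar table (ground truth, beat-to-beat BP, cuff)
        role = path.stem
        if role not in KNOWN_ROLES:
            warnings.warn(f"{directory.name}: unknown channel role {role!r}, kept as-is")
        channels[role] = read_channel(path, name=role)
    if not channels:
        raise FormatError(f"no channel files in {directory}")
    return channels


def write_beat_table(path: Path | str, table: pd.DataFrame) -> None:
    table.to_csv(path, sep="\t", index=False, float_format="%.10g")


def read_beat_table(path: Path | str) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
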