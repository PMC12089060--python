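"""Reading and writing the CSV(+TSV header) EEG dialect.

The on-disk layout is one row per time sample and one column per channel,
comma-delimited with ``.`` decimals.  Channel names come either from the
CSV's own first row or from a companion single-row tab-separated header
file.  An optional extra column carries a per-sample event label (e.g.
``TASK1T1`` or ``S 4``); it is lifted into :attr:`EEGRecording.labels`
rather than kept in the signal matrix, so label-based row filtering remains
possible downstream.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .exceptions import EmptySelectionError, FormatError, ParseError, UsageError

__all__ = [
    "EEGRecording",
    "read_eeg_csv",
    "write_eeg_csv",
    "filter_by_labels",
    "intersect_channels",
    "select_prefix_channels",
]


@dataclass
class EEGRecording:
    """A named multichannel signal with sample rate and optional event labels.

    Parameters
    ----------
    channel_names : list of str
        Unique channel names, one per row of ``data``. Conventionally 10-20
        montage names (``C3``, ``C4``, ``Cz``, ...).
    sample_rate : float
        Sampling frequency in Hz, strictly positive.
    data : ndarray of shape (n_channels, n_samples)
        The signal matrix; every value must be finite.
    labels : sequence of str, optional
        Per-sample event labels, length ``n_samples``.
    """

    channel_names: list
    sample_rate: float
    data: np.ndarray
    labels: Optional[list] = None

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise UsageError(f"data must be 2-D (channels x samples), got ndim={self.data.ndim}")
        self.channel_names = [str(c) for c in self.channel_names]
        if len(self.channel_names) != self.data.shape[0]:
            raise UsageError(
                f"{len(self.channel_names)} channel names for {self.data.shape[0]} data rows"
            )
        if len(set(self.channel_names)) != len(self.channel_names):
            raise UsageError("channel names must be unique")
        if not self.sample_rate > 0:
            raise UsageError(f"sample_rate must be positive, got {self.sample_rate}")
        if not np.all(np.isfinite(self.data)):
            raise UsageError("data contains non-finite values")
        if self.labels is not None:
            self.labels = [str(l) for l in self.labels]
            if len(self.labels) != self.data.shape[1]:
                raise UsageError(
                    f"{len(self.labels)} labels for {self.data.shape[1]} samples"
                )

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration(self) -> float:
        """Recording length in seconds."""
        return self.n_samples / self.sample_rate

    def copy(self) -> "EEGRecording":
        return EEGRecording(
            channel_names=list(self.channel_names),
            sample_rate=self.sample_rate,
            data=self.data.copy(),
            labels=None if self.labels is None else list(self.labels),
        )


def _read_header_tsv(header_path) -> list:
    text = Path(header_path).read_text()
    first_line = text.splitlines()[0] if text.splitlines() else ""
    names = [c.strip() for c in first_line.split("\t") if c.strip() != ""]
    if not names:
        raise FormatError(f"header file {header_path} contains no channel names")
    return names


def read_eeg_csv(
    csv_path,
    header_path=None,
    sample_rate: float = 128.0,
    label_column: Optional[str] = None,
) -> EEGRecording:
    """Read a samples-by-channels CSV into an :class:`EEGRecording`.

    Parameters
    ----------
    csv_path : path-like
        CSV file, one row per sample, one column per channel.
    header_path : path-like, optional
        Single-row TSV listing column names. When given, the CSV is read as
        headerless data and these names are used; its length must match the
        CSV column count.
    sample_rate : float
        Sampling frequency in Hz (the files carry no timing metadata).
    label_column : str, optional
        Name of the column holding per-sample event labels. The column is
        removed from the signal matrix and stored as ``labels``.

    Raises
    ------
    FormatError
        If the header column count does not match the CSV.
    ParseError
        If a signal cell is not numeric (the message names row and column).
    """
    csv_path = Path(csv_path)
    if header_path is not None:
        names = _read_header_tsv(header_path)
        df = pd.read_csv(csv_path, header=None, dtype=str)
        if df.shape[1] != len(names):
            raise FormatError(
                f"{csv_path}: {df.shape[1]} columns but header file lists "
                f"{len(names)} channel names"
            )
        df.columns = names
    else:
        df = pd.read_csv(csv_path, header=0, dtype=str)
        df.columns = [str(c).strip() for c in df.columns]

    labels = None
    if label_column is not None:
        if label_column not in df.columns:
            raise FormatError(f"{csv_path}: no column named {label_column!r}")
        labels = [str(v) for v in df[label_column]]
        df = df.drop(columns=[label_column])

    numeric = df.apply(pd.to_numeric, errors="coerce")
    bad = numeric.isna() & df.notna()
    if bad.to_numpy().any():
        r, c = np.argwhere(bad.to_numpy())[0]
        raise ParseError(
            f"{csv_path}: non-numeric value {df.iat[r, c]!r} at data row {r}, "
            f"column {df.columns[c]!r}"
        )
    if numeric.isna().to_numpy().any():
        r, c = np.argwhere(numeric.isna().to_numpy())[0]
        raise ParseError(f"{csv_path}: missing value at data row {r}, column {df.columns[c]!r}")

    # numpy's string parser is correctly rounded (pandas' fast path is not),
    # which keeps the read/write round trip lossless at 17 significant digits
    data = df.to_numpy(dtype=str).astype(np.float64).T
    return EEGRecording(
        channel_names=list(df.columns),
        sample_rate=sample_rate,
        data=data,
        labels=labels,
    )


def write_eeg_csv(rec: EEGRecording, csv_path, header_path=None, label_column: str = "label"):
    """Write a recording back to the CSV dialect read by :func:`read_eeg_csv`.

    Values are written with 17 significant digits so a read/write round trip
    is lossless for float64. If ``header_path`` is given the channel names go
    to the TSV file and the CSV is emitted headerless; otherwise the names
    form the CSV's first row. Labels (if present) are appended as a final
    column named ``label_column``.
    """
    csv_path = Path(csv_path)
    columns = {name: rec.data[i] for i, name in enumerate(rec.channel_names)}
    df = pd.DataFrame(columns)
    if rec.labels is not None:
        df[label_column] = rec.labels
    if header_path is not None:
        Path(header_path).write_text("\t".join(df.columns) + "\n")
        df.to_csv(csv_path, header=False, index=False, float_format="%.17g")
    else:
        df.to_csv(csv_path, header=True, index=False, float_format="%.17g")


def filter_by_labels(rec: EEGRecording, keep) -> EEGRecording:
    """Keep only samples whose event label is in ``keep``, order preserved.

    Matching is exact string equality (labels like ``"S 4"`` keep their
    embedded space). Raises :class:`UsageError` when the recording has no
    labels and :class:`EmptySelectionError` when nothing survives, which
    usually signals an over-restrictive label set.
    """
    if rec.labels is None:
        raise UsageError("filter_by_labels requires a recording with labels")
    keep = {str(k) for k in keep}
    idx = [i for i, lab in enumerate(rec.labels) if lab in keep]
    if not idx:
        raise EmptySelectionError(
            f"no samples with labels in {sorted(keep)}; present labels include "
            f"{sorted(set(rec.labels))[:8]}"
        )
    return EEGRecording(
        channel_names=list(rec.channel_names),
        sample_rate=rec.sample_rate,
        data=rec.data[:, idx],
        labels=[rec.labels[i] for i in idx],
    )


def intersect_channels(a: EEGRecording, b: EEGRecording):
    """Restrict both recordings to their shared channels.

    The surviving channels appear in ``a``'s order in both outputs, so the
    two returned recordings are directly comparable row by row.
    """
    shared = [name for name in a.channel_names if name in set(b.channel_names)]
    if not shared:
        raise EmptySelectionError(
            f"no shared channels between {a.channel_names} and {b.channel_names}"
        )

    def _take(rec):
        idx = [rec.channel_names.index(name) for name in shared]
        return EEGRecording(
            channel_names=list(shared),
            sample_rate=rec.sample_rate,
            data=rec.data[idx],
            labels=None if rec.labels is None else list(rec.labels),
        )

    return _take(a), _take(b)


def select_prefix_channels(rec: EEGRecording, prefix: str = "C") -> EEGRecording:
    """Keep channels whose (whitespace-trimmed) name starts with ``prefix``.

    Case-sensitive: 10-20 montage names are case-significant by convention
    (``Cz`` vs ``CZ``). The default ``"C"`` retains the sensorimotor strip
    (C3, C4, Cz, CP1, ...).
    """
    idx = [i for i, name in enumerate(rec.channel_names) if name.strip().startswith(prefix)]
    if not idx:
        raise EmptySelectionError(
            f"no channel name starts with {prefix!r} in {rec.channel_names}"
        )
    return EEGRecording(
        channel_names=[rec.channel_names[i] for i in idx],
        sample_rate=rec.sample_rate,
        data=rec.data[idx],
        labels=None if rec.labels is None else list(rec.labels),
    )
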