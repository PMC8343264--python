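"""Core containers: the hypnogram, seizure event tables, and shared errors.

A hypnogram is a sequence of 30-s epochs, each scored into one of six
labels: WAKE, N1, N2, N3, REM (the four sleep stages), or UNKNOWN for
epochs that could not be scored (artefacts, data dropouts). All modules in
this package exchange hypnograms through the :class:`Hypnogram` container
and seizure catalogues through plain pandas DataFrames with ``onset``
(timestamp) and ``duration_s`` columns.
"""

from __future__ import annotations

from typing import Iterable, Sequence

import numpy as np
import pandas as pd

#: Canonical stage vocabulary, in fixed order.
STAGES: tuple[str, ...] = ("WAKE", "N1", "N2", "N3", "REM", "UNKNOWN")

#: Stages that count as sleep.
SLEEP_STAGES: tuple[str, ...] = ("N1", "N2", "N3", "REM")

#: Default scoring epoch length in seconds.
EPOCH_S: int = 30


class ParameterError(ValueError):
    """Invalid model or simulator parameters."""


class DegenerateSignalError(ValueError):
    """Signal with no usable power (all-zero, constant, or non-finite)."""


class SchemaError(ValueError):
    """Input table is missing required columns or is misaligned."""


class Hypnogram:
    """A timestamped sequence of 30-s sleep-stage labels.

    Parameters
    ----------
    labels : sequence of str
        One entry per epoch, each a member of :data:`STAGES`.
    start : timestamp-like
        Time of the first epoch's left edge.
    epoch_s : int, default 30
        Epoch duration in seconds.
    """

    def __init__(self, labels: Sequence[str], start, epoch_s: int = EPOCH_S):
        labels = np.asarray(labels, dtype=object)
        bad = set(np.unique(labels)) - set(STAGES)
        if bad:
            raise ParameterError(f"unknown stage labels: {sorted(bad)}")
        self.labels = labels.astype("U7")
        self.start = pd.Timestamp(start)
        self.epoch_s = int(epoch_s)

    # -- basic protocol ----------------------------------------------------
    def __len__(self) -> int:
        return self.labels.size

    def __eq__(self, other) -> bool:
        return (
            isinstance(other, Hypnogram)
            and self.start == other.start
            and self.epoch_s == other.epoch_s
            and np.array_equal(self.labels, other.labels)
        )

    def __repr__(self) -> str:
        return (
            f"Hypnogram(n_epochs={len(self)}, start={self.start.isoformat()}, "
            f"epoch_s={self.epoch_s})"
        )

    # -- time handling -----------------------------------------------------
    @property
    def times(self) -> pd.DatetimeIndex:
        """Left-edge timestamp of every epoch."""
        return self.start + pd.to_timedelta(
            np.arange(len(self)) * self.epoch_s, unit="s"
        )

    @property
    def end(self) -> pd.Timestamp:
        return self.start + pd.Timedelta(seconds=len(self) * self.epoch_s)

    def epoch_at(self, when) -> int:
        """Index of the epoch containing ``when``; raises if outside the span."""
        when = pd.Timestamp(when)
        idx = int((when - self.start).total_seconds() // self.epoch_s)
        if not 0 <= idx < len(self):
            raise ParameterError(f"{when} lies outside the hypnogram span")
        return idx

    def day_slices(self, boundary_hour: int = 12) -> list[tuple[pd.Timestamp, slice]]:
        """Partition epochs into 24-h windows anchored at ``boundary_hour``.

        Returns ``(window_start, slice)`` pairs; windows at the edges of the
        recording may be partial.
        """
        first = self.start.normalize() + pd.Timedelta(hours=boundary_hour)
        if first > self.start:
            first -= pd.Timedelta(days=1)
        out = []
        t0 = first
        while t0 < self.end:
            t1 = t0 + pd.Timedelta(days=1)
            i0 = max(0, int(np.ceil((t0 - self.start).total_seconds() / self.epoch_s)))
            i1 = min(
                len(self),
                int(np.ceil((t1 - self.start).total_seconds() / self.epoch_s)),
            )
            if i1 > i0:
                out.append((t0, slice(i0, i1)))
            t0 = t1
        return out

    # -- I/O -----------------------------------------------------------------
    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"timestamp_iso8601": self.times, "label": self.labels})

    def to_csv(self, path) -> None:
        df = self.to_frame()
        df["timestamp_iso8601"] = df["timestamp_iso8601"].dt.strftime(
            "%Y-%m-%dT%H:%M:%S"
        )
        df.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "Hypnogram":
        df = pd.read_csv(path)
        required = {"timestamp_iso8601", "label"}
        if not required.issubset(df.columns):
            raise SchemaError(f"hypnogram CSV needs columns {sorted(required)}")
        times = pd.to_datetime(df["timestamp_iso8601"])
        if len(df) > 1:
            steps = np.diff(times.values).astype("timedelta64[s]").astype(int)
            if len(set(steps)) != 1:
                raise SchemaError("hypnogram epochs are not equally spaced")
            epoch_s = int(steps[0])
        else:
            epoch_s = EPOCH_S
        return cls(df["label"].tolist(), times.iloc[0], epoch_s=epoch_s)

    def copy(self) -> "Hypnogram":
        return Hypnogram(self.labels.copy(), self.start, self.epoch_s)


def seizures_to_csv(seizures: pd.DataFrame, path) -> None:
    """Write a seizure catalogue as ``onset_iso8601,duration_s``."""
    out = pd.DataFrame(
        {
            "onset_iso8601": pd.to_datetime(seizures["onset"]).dt.strftime(
                "%Y-%m-%dT%H:%M:%S"
            ),
            "duration_s": seizures["duration_s"],
        }
    )
    out.to_csv(path, index=False)


def seizures_from_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    required = {"onset_iso8601", "duration_s"}
    if not required.issubset(df.columns):
        raise SchemaError(f"seizure CSV needs columns {sorted(required)}")
    return pd.DataFrame(
        {
            "onset": pd.to_datetime(df["onset_iso8601"]),
            "duration_s": df["duration_s"].astype(float),
        }
    )


def labels_from_runs(runs: Iterable[tuple[str, int]]) -> np.ndarray:
    """Expand ``(label, n_epochs)`` run-length pairs into a label array.

    Convenience for constructing toy hypnograms in tests and examples.
    """
    parts = []
    for label, n in runs:
        parts.extend([label] * int(n))
    return np.asarray(parts, dtype="U7")
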