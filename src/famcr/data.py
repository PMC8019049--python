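"""Encounter-history containers.

A :class:`FamilyHistory` is the ordered record of one family unit from
its first capture to the last sampling occasion: one ``(occasion,
day-of-year, event)`` triple per occasion, with event 0 / missing date
on occasions where the unit was not observed. A :class:`Dataset` is a
collection of such histories over ``T`` occasions.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .states import event_to_index


@dataclass(frozen=True)
class FamilyHistory:
    """One family unit's ordered (occasion, doy, event) records."""

    family_id: str
    records: tuple[tuple[int, float | None, int], ...]

    def __post_init__(self) -> None:
        records = tuple((int(o), None if d is None else float(d), int(e))
                        for o, d, e in self.records)
        object.__setattr__(self, "records", records)
        if not records:
            raise ValueError(f"family {self.family_id}: empty history")
        if records[0][2] == 0:
            raise ValueError(
                f"family {self.family_id}: first record must be a capture")
        occs = [o for o, _, _ in records]
        if any(b <= a for a, b in zip(occs, occs[1:])):
            raise ValueError(
                f"family {self.family_id}: occasions must be strictly increasing")
        for o, d, e in records:
            if not 0 <= e <= 11:
                raise ValueError(
                    f"family {self.family_id}: event {e} outside 0..11")
            if e != 0 and d is None:
                raise ValueError(
                    f"family {self.family_id}: capture at occasion {o} lacks a date")

    @property
    def first_occasion(self) -> int:
        return self.records[0][0]

    def __len__(self) -> int:
        return len(self.records)


@dataclass(frozen=True)
class Dataset:
    """Encounter histories of independent family units over T occasions."""

    histories: tuple[FamilyHistory, ...]
    T: int

    def __post_init__(self) -> None:
        object.__setattr__(self, "histories", tuple(self.histories))
        if not self.histories:
            raise ValueError("dataset must contain at least one history")
        for h in self.histories:
            if h.records[-1][0] > self.T:
                raise ValueError(
                    f"family {h.family_id}: occasion beyond T={self.T}")

    def __len__(self) -> int:
        return len(self.histories)

    def to_frame(self) -> pd.DataFrame:
        """Long-format table: family_id, occasion, doy, event."""
        rows = [(h.family_id, o, d, e)
                for h in self.histories for o, d, e in h.records]
        return pd.DataFrame(rows, columns=["family_id", "occasion", "doy", "event"])

    @classmethod
    def from_frame(cls, df: pd.DataFrame, T: int | None = None) -> "Dataset":
        """Build a Dataset from a long-format table (see :meth:`to_frame`)."""
        required = {"family_id", "occasion", "doy", "event"}
        missing = required - set(df.columns)
        if missing:
            raise ValueError(f"missing columns: {sorted(missing)}")
        histories = []
        for fid, grp in df.groupby("family_id", sort=False):
            grp = grp.sort_values("occasion")
            recs = [(int(o), None if pd.isna(d) else float(d), int(e))
                    for o, d, e in zip(grp["occasion"], grp["doy"], grp["event"])]
            histories.append(FamilyHistory(str(fid), tuple(recs)))
        if T is None:
            T = int(df["occasion"].max())
        return cls(tuple(histories), T)


class CompiledData:
    """Array form of a Dataset for the vectorised forward algorithm.

    ``event_idx[h, t]`` holds the 0-based internal event column (11 for
    nonobservation) for occasion t+1, or -1 before the family's first
    capture; ``doy`` holds capture dates (NaN elsewhere).
    """

    def __init__(self, data: Dataset):
        H, T = len(data.histories), data.T
        self.T = T
        self.event_idx = np.full((H, T), -1, dtype=np.int64)
        self.doy = np.full((H, T), np.nan)
        self.first = np.empty(H, dtype=np.int64)
        for h, hist in enumerate(data.histories):
            self.first[h] = hist.first_occasion - 1
            # occasions between records (and after the last) are nonobservations
            self.event_idx[h, self.first[h]:] = 11
            for o, d, e in hist.records:
                self.event_idx[h, o - 1] = event_to_index(e)
                if d is not None:
                    self.doy[h, o - 1] = d
        self.first_class = self.event_idx[np.arange(H), self.first]
        self.first_doy = self.doy[np.arange(H), self.first]
        # per-event-column masks for occasions after first capture
        after = np.zeros((H, T), dtype=bool)
        for h in range(H):
            after[h, self.first[h] + 1:] = True
        self.capture_cells = []  # (class index c, rows, cols, dates)
        for c in range(11):
            m = after & (self.event_idx == c)
            rows, cols = np.nonzero(m)
            self.capture_cells.append((c, rows, cols, self.doy[rows, cols]))
        m0 = after & (self.event_idx == 11)
        self.noncapture_rows, self.noncapture_cols = np.nonzero(m0)
        self.start_rows = [np.nonzero(self.first == t)[0] for t in range(T)]
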