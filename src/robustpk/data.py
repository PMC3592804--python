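"""Long-format concentration-time data containers and delimited-text I/O.

The on-disk dialect is comma-delimited UTF-8 with a mandatory header and
columns ``subject_id,time,conc,dose`` (NONMEM-adjacent names); times are
hours, concentrations mass/volume, dose mass.  Parsing is strict: any
malformed cell or positivity violation is reported with its 1-based file
row number.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from typing import Iterable, List

import numpy as np
import pandas as pd

from .exceptions import DataValidationError

__all__ = ["ObservationBlock", "PKDataset", "read_pk_csv", "write_pk_csv"]

REQUIRED_COLUMNS = ("subject_id", "time", "conc", "dose")


@dataclass(frozen=True)
class ObservationBlock:
    """All observations for one subject.

    times must be strictly increasing and positive; concentrations
    strictly positive (the model works on the log scale); dose is the
    administered amount shared by the block.
    """

    subject_id: str
    times: np.ndarray
    concentrations: np.ndarray
    dose: float

    def __post_init__(self):
        t = np.asarray(self.times, dtype=float)
        c = np.asarray(self.concentrations, dtype=float)
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "concentrations", c)
        if t.ndim != 1 or c.ndim != 1 or t.size != c.size:
            raise DataValidationError(
                f"subject {self.subject_id}: times and concentrations must be "
                f"1-d and equally long (got {t.size} vs {c.size})"
            )
        if t.size < 2:
            raise DataValidationError(
                f"subject {self.subject_id}: at least 2 observations required"
            )
        if np.any(t <= 0):
            raise DataValidationError(
                f"subject {self.subject_id}: times must be strictly positive"
            )
        if np.any(np.diff(t) <= 0):
            raise DataValidationError(
                f"subject {self.subject_id}: times must be strictly increasing"
            )
        if np.any(c <= 0):
            raise DataValidationError(
                f"subject {self.subject_id}: concentrations must be strictly "
                "positive (log-scale model)"
            )
        if not np.isfinite(self.dose) or self.dose <= 0:
            raise DataValidationError(
                f"subject {self.subject_id}: dose must be positive"
            )

    @property
    def n_obs(self) -> int:
        return self.times.size

    @property
    def log_conc(self) -> np.ndarray:
        return np.log(self.concentrations)


@dataclass(frozen=True)
class PKDataset:
    """Ordered collection of per-subject observation blocks."""

    subjects: List[ObservationBlock] = field(default_factory=list)

    def __post_init__(self):
        subjects = list(self.subjects)
        object.__setattr__(self, "subjects", subjects)
        if not subjects:
            raise DataValidationError("dataset must contain at least one subject")
        ids = [s.subject_id for s in subjects]
        if len(set(ids)) != len(ids):
            raise DataValidationError("duplicate subject ids in dataset")

    def __len__(self) -> int:
        return len(self.subjects)

    def __iter__(self):
        return iter(self.subjects)

    @property
    def n_subjects(self) -> int:
        return len(self.subjects)

    @property
    def n_obs(self) -> int:
        return sum(s.n_obs for s in self.subjects)

    @property
    def subject_ids(self) -> List[str]:
        return [s.subject_id for s in self.subjects]

    def to_dataframe(self) -> pd.DataFrame:
        rows = []
        for s in self.subjects:
            for t, c in zip(s.times, s.concentrations):
                rows.append((s.subject_id, t, c, s.dose))
        return pd.DataFrame(rows, columns=list(REQUIRED_COLUMNS))

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame) -> "PKDataset":
        missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
        if missing:
            raise DataValidationError(f"missing required columns: {missing}")
        blocks = []
        for sid, grp in df.groupby("subject_id", sort=False):
            dose = np.unique(np.asarray(grp["dose"], dtype=float))
            if dose.size != 1:
                raise DataValidationError(
                    f"subject {sid}: dose must be constant within subject"
                )
            blocks.append(
                ObservationBlock(
                    subject_id=str(sid),
                    times=np.asarray(grp["time"], dtype=float),
                    concentrations=np.asarray(grp["conc"], dtype=float),
                    dose=float(dose[0]),
                )
            )
        return cls(blocks)


def read_pk_csv(path) -> PKDataset:
    """Read a long-format concentration table, validating row by row.

    Violations are reported with the 1-based file row (header is row 1).
    """
    rows = {}
    order = []
    with open(path, "r", encoding="utf-8", newline="") as fh:
        reader = csv.reader(fh)
        try:
            header = next(reader)
        except StopIteration:
            raise DataValidationError(f"{path}: empty file") from None
        header = [h.strip() for h in header]
        missing = [c for c in REQUIRED_COLUMNS if c not in header]
        if missing:
            raise DataValidationError(f"{path}: missing columns {missing}")
        idx = {c: header.index(c) for c in REQUIRED_COLUMNS}
        for rownum, row in enumerate(reader, start=2):
            if not row or all(not cell.strip() for cell in row):
                continue
            if len(row) < len(header):
                raise DataValidationError(
                    f"{path}: row {rownum}: expected {len(header)} fields, "
                    f"got {len(row)}"
                )
            sid = row[idx["subject_id"]].strip()
            vals = {}
            for col in ("time", "conc", "dose"):
                cell = row[idx[col]].strip()
                try:
                    vals[col] = float(cell)
                except ValueError:
                    raise DataValidationError(
                        f"{path}: row {rownum}: non-numeric {col} value "
                        f"{cell!r}"
                    ) from None
            if vals["time"] <= 0:
                raise DataValidationError(
                    f"{path}: row {rownum}: non-positive time {vals['time']}"
                )
            if vals["conc"] <= 0:
                raise DataValidationError(
                    f"{path}: row {rownum}: non-positive concentration "
                    f"{vals['conc']}"
                )
            if vals["dose"] <= 0:
                raise DataValidationError(
                    f"{path}: row {rownum}: non-positive dose {vals['dose']}"
                )
            if sid not in rows:
                rows[sid] = []
                order.append(sid)
            rows[sid].append((rownum, vals["time"], vals["conc"], vals["dose"]))
    if not order:
        raise DataValidationError(f"{path}: no data rows")
    blocks = []
    for sid in order:
        recs = rows[sid]
        doses = {r[3] for r in recs}
        if len(doses) != 1:
            raise DataValidationError(
                f"{path}: subject {sid}: dose varies within subject "
                f"(rows {[r[0] for r in recs]})"
            )
        times = np.array([r[1] for r in recs])
        if np.any(np.diff(times) <= 0):
            bad = int(np.flatnonzero(np.diff(times) <= 0)[0])
            raise DataValidationError(
                f"{path}: row {recs[bad + 1][0]}: times not strictly "
                f"increasing for subject {sid}"
            )
        blocks.append(
            ObservationBlock(
                subject_id=sid,
                times=times,
                concentrations=np.array([r[2] for r in recs]),
                dose=recs[0][3],
            )
        )
    return PKDataset(blocks)


def write_pk_csv(dataset: PKDataset, path) -> None:
    """Write a dataset in the canonical long format (full float precision)."""
    with open(path, "w", encoding="utf-8", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(REQUIRED_COLUMNS)
        for s in dataset:
            for t, c in zip(s.times, s.concentrations):
                writer.writerow([s.subject_id, repr(float(t)), repr(float(c)),
                                 repr(float(s.dose))])
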