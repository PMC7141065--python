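"""Reading and writing the external formats used throughout the toolkit.

Formats
-------
* **Fixation tables** — tab-separated, UTF-8, one header row.  Canonical
  column names are ``participant``, ``stimulus``, ``onset_ms``, ``x``, ``y``,
  ``duration_ms``; a column mapping lets Tobii-style exports be adapted
  without rewriting the file.
* **AOI definitions** — CSV with columns
  ``stimulus, label, x0, y0, x1, y1, stim_w, stim_h``.
* **Group assignments** — CSV with columns ``participant, stimulus, group``
  where ``group`` is ``correct`` or ``incorrect``.
* **Matrices** — labelled CSV (header row and leading label column) written
  at full ``repr`` precision so a write/read round trip is lossless.

Coordinates are stimulus pixels with the origin at the top-left corner and
``y`` increasing downward (the usual eye-tracker convention).  AOI rectangles
are half-open, ``[x0, x1) x [y0, y1)``, so AOIs that tile a stimulus never
double-claim a point.

Invalid fixation rows (non-numeric fields, non-positive durations,
out-of-order onsets) are reported and skipped rather than aborting the parse:
real gaze exports routinely contain dropouts.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, NamedTuple, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "Fixation",
    "Aoi",
    "AoiSet",
    "GroupAssignment",
    "RowError",
    "FixationParseResult",
    "FormatError",
    "GROUP_LABELS",
    "read_fixations",
    "write_fixations",
    "read_aois",
    "write_aois",
    "read_groups",
    "write_groups",
    "read_matrix",
    "write_matrix",
]

GROUP_LABELS = ("correct", "incorrect")

#: canonical fixation-table column names, in file order
FIXATION_COLUMNS = ("participant", "stimulus", "onset_ms", "x", "y", "duration_ms")


class FormatError(ValueError):
    """A file does not conform to its expected dialect."""


@dataclass(frozen=True)
class Fixation:
    """One gaze fixation: who looked where, when, and for how long.

    ``onset`` and ``duration`` are milliseconds; ``x``/``y`` are stimulus
    pixels (origin top-left, y downward).  ``duration`` must be positive and
    ``onset`` non-negative.
    """

    participant_id: str
    stimulus_id: str
    onset: float
    x: float
    y: float
    duration: float

    def __post_init__(self) -> None:
        if self.duration <= 0:
            raise ValueError(f"fixation duration must be > 0, got {self.duration}")
        if self.onset < 0:
            raise ValueError(f"fixation onset must be >= 0, got {self.onset}")


@dataclass(frozen=True)
class Aoi:
    """A labelled axis-aligned rectangle, half-open: [x0, x1) x [y0, y1)."""

    label: str
    x0: float
    y0: float
    x1: float
    y1: float

    def __post_init__(self) -> None:
        if not (self.x1 > self.x0 and self.y1 > self.y0):
            raise ValueError(
                f"degenerate AOI rect {self.label!r}: "
                f"({self.x0},{self.y0},{self.x1},{self.y1})"
            )

    def contains(self, x: float, y: float) -> bool:
        return self.x0 <= x < self.x1 and self.y0 <= y < self.y1


@dataclass(frozen=True)
class AoiSet:
    """An ordered set of labelled rectangles over one stimulus."""

    stimulus_id: str
    width: float
    height: float
    aois: tuple[Aoi, ...]

    def __post_init__(self) -> None:
        labels = [a.label for a in self.aois]
        if len(set(labels)) != len(labels):
            dupes = sorted({l for l in labels if labels.count(l) > 1})
            raise ValueError(f"duplicate AOI labels {dupes} in stimulus {self.stimulus_id!r}")
        for a in self.aois:
            if a.x0 < 0 or a.y0 < 0 or a.x1 > self.width or a.y1 > self.height:
                raise ValueError(
                    f"AOI {a.label!r} exceeds stimulus bounds "
                    f"{self.width}x{self.height}"
                )

    @property
    def labels(self) -> tuple[str, ...]:
        return tuple(a.label for a in self.aois)

    def __len__(self) -> int:
        return len(self.aois)

    def __iter__(self):
        return iter(self.aois)


@dataclass
class GroupAssignment:
    """Maps (participant, stimulus) to ``correct`` or ``incorrect``."""

    assignments: dict[tuple[str, str], str] = field(default_factory=dict)

    def add(self, participant_id: str, stimulus_id: str, group: str) -> None:
        if group not in GROUP_LABELS:
            raise ValueError(f"unknown group {group!r}; expected one of {GROUP_LABELS}")
        key = (participant_id, stimulus_id)
        if key in self.assignments:
            raise ValueError(f"duplicate group assignment for {key}")
        self.assignments[key] = group

    def group_of(self, participant_id: str, stimulus_id: str) -> str:
        return self.assignments[(participant_id, stimulus_id)]

    def participants(self, stimulus_id: str, group: str | None = None) -> list[str]:
        """Participant ids for one stimulus, optionally restricted to a group."""
        out = [
            p
            for (p, s), g in self.assignments.items()
            if s == stimulus_id and (group is None or g == group)
        ]
        return out

    def __len__(self) -> int:
        return len(self.assignments)

    def __contains__(self, key: tuple[str, str]) -> bool:
        return key in self.assignments


class RowError(NamedTuple):
    """A rejected fixation-table row: 1-based line number plus reason."""

    line: int
    reason: str


class FixationParseResult(NamedTuple):
    fixations: list[Fixation]
    rejected: list[RowError]


# ---------------------------------------------------------------------------
# fixation tables


def read_fixations(
    path: str | Path,
    column_map: Mapping[str, str] | None = None,
) -> FixationParseResult:
    """Parse a tab-separated fixation table.

    Parameters
    ----------
    path
        TSV file with a header row.
    column_map
        Optional mapping from canonical column names (``participant``,
        ``stimulus``, ``onset_ms``, ``x``, ``y``, ``duration_ms``) to the
        names actually used in the file, e.g. Tobii-style exports.

    Returns
    -------
    FixationParseResult
        ``fixations`` in file order plus a list of rejected rows with the
        1-based line number and reason.  ``len(fixations) + len(rejected)``
        equals the number of data rows.

    Raises
    ------
    FormatError
        If a required column is absent from the header.
    """
    path = Path(path)
    colmap = {c: c for c in FIXATION_COLUMNS}
    if column_map:
        colmap.update(column_map)

    with path.open(newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        header = reader.fieldnames or []
        for canonical, actual in colmap.items():
            if actual not in header:
                raise FormatError(
                    f"{path}: missing required column {actual!r} (for {canonical!r})"
                )

        fixations: list[Fixation] = []
        rejected: list[RowError] = []
        # last accepted onset per (participant, stimulus), for monotonicity
        last_onset: dict[tuple[str, str], float] = {}
        for lineno, row in enumerate(reader, start=2):
            pid = row[colmap["participant"]]
            sid = row[colmap["stimulus"]]
            try:
                onset = float(row[colmap["onset_ms"]])
                x = float(row[colmap["x"]])
                y = float(row[colmap["y"]])
                duration = float(row[colmap["duration_ms"]])
            except (TypeError, ValueError):
                rejected.append(RowError(lineno, "non-numeric field"))
                continue
            if duration <= 0:
                rejected.append(RowError(lineno, f"duration {duration} <= 0"))
                continue
            if onset < 0:
                rejected.append(RowError(lineno, f"onset {onset} < 0"))
                continue
            key = (pid, sid)
            if key in last_onset and onset <= last_onset[key]:
                rejected.append(
                    RowError(lineno, f"onset {onset} not after previous {last_onset[key]}")
                )
                continue
            last_onset[key] = onset
            fixations.append(Fixation(pid, sid, onset, x, y, duration))
    return FixationParseResult(fixations, rejected)


def write_fixations(fixations: Iterable[Fixation], path: str | Path) -> None:
    """Write fixations as the canonical TSV dialect."""
    path = Path(path)
    with path.open("w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(FIXATION_COLUMNS)
        for f in fixations:
            writer.writerow(
                [f.participant_id, f.stimulus_id, repr(f.onset), repr(f.x), repr(f.y), repr(f.duration)]
            )


# ---------------------------------------------------------------------------
# AOI definitions


def read_aois(path: str | Path, stimulus_id: str | None = None) -> AoiSet:
    """Read AOI rectangles for one stimulus from a CSV definition file.

    The file may describe several stimuli; pass ``stimulus_id`` to select
    one, otherwise the file must contain exactly one stimulus.  AOI order is
    preserved from the file (it defines the label alphabet ordering).
    """
    path = Path(path)
    df = pd.read_csv(path, dtype={"stimulus": str, "label": str})
    required = {"stimulus", "label", "x0", "y0", "x1", "y1", "stim_w", "stim_h"}
    missing = required - set(df.columns)
    if missing:
        raise FormatError(f"{path}: missing AOI columns {sorted(missing)}")
    if stimulus_id is None:
        stimuli = df["stimulus"].unique()
        if len(stimuli) != 1:
            raise FormatError(
                f"{path}: contains {len(stimuli)} stimuli; pass stimulus_id to select one"
            )
        stimulus_id = stimuli[0]
    sub = df[df["stimulus"] == stimulus_id]
    if sub.empty:
        raise FormatError(f"{path}: no AOIs for stimulus {stimulus_id!r}")
    widths = sub["stim_w"].unique()
    heights = sub["stim_h"].unique()
    if len(widths) != 1 or len(heights) != 1:
        raise FormatError(f"{path}: inconsistent stimulus dimensions for {stimulus_id!r}")
    aois = tuple(
        Aoi(str(r.label), float(r.x0), float(r.y0), float(r.x1), float(r.y1))
        for r in sub.itertuples()
    )
    return AoiSet(str(stimulus_id), float(widths[0]), float(heights[0]), aois)


def write_aois(aoiset: AoiSet, path: str | Path) -> None:
    rows = [
        {
            "stimulus": aoiset.stimulus_id,
            "label": a.label,
            "x0": a.x0,
            "y0": a.y0,
            "x1": a.x1,
            "y1": a.y1,
            "stim_w": aoiset.width,
            "stim_h": aoiset.height,
        }
        for a in aoiset
    ]
    pd.DataFrame(rows).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# group assignments


def read_groups(path: str | Path) -> GroupAssignment:
    """Read a participant x stimulus -> group table (CSV)."""
    path = Path(path)
    df = pd.read_csv(path, dtype=str)
    required = {"participant", "stimulus", "group"}
    missing = required - set(df.columns)
    if missing:
        raise FormatError(f"{path}: missing group columns {sorted(missing)}")
    ga = GroupAssignment()
    for r in df.itertuples():
        ga.add(str(r.participant), str(r.stimulus), str(r.group))
    return ga


def write_groups(groups: GroupAssignment, path: str | Path) -> None:
    rows = [
        {"participant": p, "stimulus": s, "group": g}
        for (p, s), g in groups.assignments.items()
    ]
    pd.DataFrame(rows).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# labelled matrices


def write_matrix(
    matrix: np.ndarray, labels: Sequence[str], path: str | Path
) -> None:
    """Write a square labelled matrix as CSV (header row + label column).

    Values are written at full ``repr`` precision, so reading the file back
    with :func:`read_matrix` reproduces them exactly.
    """
    matrix = np.asarray(matrix)
    if matrix.ndim != 2 or matrix.shape[0] != matrix.shape[1]:
        raise ValueError(f"matrix must be square, got shape {matrix.shape}")
    if len(labels) != matrix.shape[0]:
        raise ValueError(
            f"{len(labels)} labels for matrix of order {matrix.shape[0]}"
        )
    with Path(path).open("w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh, lineterminator="\n")
        writer.writerow(["", *labels])
        for lab, row in zip(labels, matrix):
            writer.writerow([lab, *(repr(float(v)) for v in row)])


def read_matrix(path: str | Path) -> tuple[np.ndarray, list[str]]:
    """Read a labelled matrix CSV written by :func:`write_matrix`."""
    df = pd.read_csv(path, index_col=0, float_precision="round_trip")
    labels = [str(l) for l in df.index]
    if labels != [str(c) for c in df.columns]:
        raise FormatError(f"{path}: row and column labels disagree")
    return df.to_numpy(dtype=float), labels
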