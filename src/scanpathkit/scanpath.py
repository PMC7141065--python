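"""AOI token sequences (scanpaths) and their string-edit comparison.

A scanpath represents one participant's viewing of one stimulus as the
ordered sequence of AOI labels their fixations landed in, e.g.
``M,M,I,I,M,G,G,E,E,B,A,A,M,M,I,I``.  Repeated consecutive tokens encode
fixation frequency; *truncating* collapses each maximal run to a single
token, leaving only the visit order.

Dissimilarity between two scanpaths is the Levenshtein distance: the minimum
number of unit-cost insertions, deletions and substitutions transforming one
token sequence into the other.  All-pairs distances over the participants
viewing one stimulus form a symmetric matrix which can be max-normalized to
[0, 1] so several matrices share one visual scale.

By default distances are computed on un-truncated scanpaths; truncation is
an explicit preprocessing step.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, replace
from typing import Iterable, Sequence

import numpy as np

from .io import AoiSet, Fixation

__all__ = [
    "OFF_AOI",
    "Scanpath",
    "DistanceMatrix",
    "LengthSummary",
    "assign_aoi",
    "build_scanpath",
    "truncate",
    "levenshtein",
    "pairwise_distances",
    "normalize",
    "length_summary",
]

#: sentinel token for fixations that land outside every AOI
OFF_AOI = "*"


@dataclass(frozen=True)
class Scanpath:
    """An ordered AOI token sequence for one participant x stimulus."""

    participant_id: str
    stimulus_id: str
    tokens: tuple[str, ...]
    truncated: bool = False

    def __len__(self) -> int:
        return len(self.tokens)

    def __str__(self) -> str:
        return ",".join(self.tokens)


@dataclass(frozen=True)
class DistanceMatrix:
    """Symmetric pairwise distances between participants' scanpaths.

    ``labels`` gives the participant order along both axes.  ``normalized``
    marks whether values have been divided by the matrix maximum.
    """

    labels: tuple[str, ...]
    values: np.ndarray
    normalized: bool = False

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise ValueError(f"distance matrix must be square, got {v.shape}")
        if v.shape[0] != len(self.labels):
            raise ValueError("label count does not match matrix order")
        object.__setattr__(self, "values", v)


@dataclass(frozen=True)
class LengthSummary:
    """Mean / sample SD / mode / range of scanpath lengths.

    The mode is the most frequent attained length (smallest on a tie); the
    range is the single number ``max - min``; SD uses the n-1 denominator
    and is reported as 0 for n = 1.
    """

    mean: float
    sd: float
    mode: int
    range: int
    n: int


def assign_aoi(x: float, y: float, aoiset: AoiSet) -> str:
    """Label of the first AOI (in definition order) containing (x, y).

    AOI rectangles are half-open, so a point on a shared edge belongs to the
    rectangle whose interior lies to its right/below.  Returns the
    :data:`OFF_AOI` sentinel when no AOI contains the point.
    """
    for aoi in aoiset:
        if aoi.contains(x, y):
            return aoi.label
    return OFF_AOI


def build_scanpath(
    fixations: Sequence[Fixation],
    aoiset: AoiSet,
    off_policy: str = "drop",
) -> Scanpath:
    """Map a participant's fixations to an AOI token sequence.

    ``off_policy`` controls fixations outside every AOI: ``"drop"`` (default)
    removes them from the sequence, ``"keep"`` retains the sentinel token.
    Fixations must belong to one participant x stimulus and be sorted by
    onset.
    """
    if off_policy not in ("drop", "keep"):
        raise ValueError(f"off_policy must be 'drop' or 'keep', got {off_policy!r}")
    if not fixations:
        return Scanpath("", aoiset.stimulus_id, ())
    pids = {f.participant_id for f in fixations}
    sids = {f.stimulus_id for f in fixations}
    if len(pids) != 1 or len(sids) != 1:
        raise ValueError(
            f"fixations mix participants {sorted(pids)} / stimuli {sorted(sids)}"
        )
    onsets = [f.onset for f in fixations]
    if any(b <= a for a, b in zip(onsets, onsets[1:])):
        raise ValueError("fixations must be sorted by strictly increasing onset")
    tokens = [assign_aoi(f.x, f.y, aoiset) for f in fixations]
    if off_policy == "drop":
        tokens = [t for t in tokens if t != OFF_AOI]
    return Scanpath(pids.pop(), sids.pop(), tuple(tokens))


def truncate(scanpath: Scanpath) -> Scanpath:
    """Collapse each maximal run of equal consecutive tokens to one token.

    Removes fixation frequency while preserving visit order; idempotent.
    """
    tokens: list[str] = []
    for t in scanpath.tokens:
        if not tokens or tokens[-1] != t:
            tokens.append(t)
    return replace(scanpath, tokens=tuple(tokens), truncated=True)


def levenshtein(a: Sequence[str], b: Sequence[str]) -> int:
    """Unit-cost edit distance between two token sequences.

    Standard dynamic programme over the (len(a)+1) x (len(b)+1) lattice,
    kept to two rows.  Symmetric, satisfies the triangle inequality, and is
    zero iff the sequences are equal.
    """
    a = tuple(a)
    b = tuple(b)
    if len(a) < len(b):  # iterate over the longer, keep the shorter row
        a, b = b, a
    if not b:
        return len(a)
    prev = list(range(len(b) + 1))
    for i, ta in enumerate(a, start=1):
        curr = [i] + [0] * len(b)
        for j, tb in enumerate(b, start=1):
            cost = 0 if ta == tb else 1
            curr[j] = min(prev[j] + 1, curr[j - 1] + 1, prev[j - 1] + cost)
        prev = curr
    return prev[-1]


def pairwise_distances(scanpaths: Sequence[Scanpath]) -> DistanceMatrix:
    """All-pairs Levenshtein distances between participants' scanpaths.

    Requires at least two scanpaths for the same stimulus, one per
    participant.  The result is symmetric with a zero diagonal and is not
    normalized.
    """
    if len(scanpaths) < 2:
        raise ValueError("need at least two scanpaths")
    pids = [s.participant_id for s in scanpaths]
    if len(set(pids)) != len(pids):
        dupes = sorted({p for p in pids if pids.count(p) > 1})
        raise ValueError(f"duplicate participants {dupes}")
    sids = {s.stimulus_id for s in scanpaths}
    if len(sids) != 1:
        raise ValueError(f"scanpaths span multiple stimuli {sorted(sids)}")
    n = len(scanpaths)
    values = np.zeros((n, n), dtype=float)
    for i in range(n):
        for j in range(i + 1, n):
            d = levenshtein(scanpaths[i].tokens, scanpaths[j].tokens)
            values[i, j] = values[j, i] = d
    return DistanceMatrix(tuple(pids), values, normalized=False)


def normalize(matrix: DistanceMatrix) -> DistanceMatrix:
    """Divide every entry by the matrix maximum, mapping into [0, 1].

    A degenerate all-zero matrix is returned unchanged apart from the
    ``normalized`` flag.  Entry ordering is preserved.
    """
    if matrix.normalized:
        raise ValueError("matrix is already normalized")
    vmax = float(matrix.values.max(initial=0.0))
    if vmax == 0.0:
        return replace(matrix, normalized=True)
    return replace(matrix, values=matrix.values / vmax, normalized=True)


def length_summary(
    scanpaths: Iterable[Scanpath], truncated: bool = False
) -> LengthSummary:
    """Summarize scanpath lengths: mean, sample SD, mode, range.

    With ``truncated=True`` lengths are taken after collapsing consecutive
    repeats; otherwise raw sequence lengths are used.
    """
    paths = list(scanpaths)
    if not paths:
        raise ValueError("length_summary requires at least one scanpath")
    lengths = [
        len(truncate(s)) if truncated and not s.truncated else len(s) for s in paths
    ]
    arr = np.asarray(lengths)
    counts = Counter(lengths)
    top = max(counts.values())
    mode = min(l for l, c in counts.items() if c == top)
    sd = float(arr.std(ddof=1)) if len(arr) > 1 else 0.0
    return LengthSummary(
        mean=float(arr.mean()),
        sd=sd,
        mode=int(mode),
        range=int(arr.max() - arr.min()),
        n=len(arr),
    )
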