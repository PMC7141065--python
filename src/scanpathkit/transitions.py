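"""Directed AOI-to-AOI transition counts, including self-transitions.

A transition is an ordered pair of consecutive scanpath tokens, so a
scanpath of n tokens contributes n - 1 transitions.  Self-transitions
(consecutive fixations within one AOI) are counted, which requires
un-truncated scanpaths; on a truncated scanpath the diagonal is zero by
construction.  Aggregated matrices and filtered edge lists feed the chord
diagram rendering and the group transition totals.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple, Sequence

import numpy as np

from .scanpath import Scanpath

__all__ = [
    "TransitionMatrix",
    "Edge",
    "transition_matrix",
    "aggregate_transitions",
    "subset_and_edges",
    "write_edges",
]


@dataclass(frozen=True)
class TransitionMatrix:
    """counts[from][to] over a fixed AOI alphabet order."""

    labels: tuple[str, ...]
    counts: np.ndarray

    def __post_init__(self) -> None:
        c = np.asarray(self.counts, dtype=int)
        if c.shape != (len(self.labels), len(self.labels)):
            raise ValueError("counts shape does not match alphabet")
        if (c < 0).any():
            raise ValueError("transition counts must be non-negative")
        object.__setattr__(self, "counts", c)

    @property
    def total(self) -> int:
        return int(self.counts.sum())


class Edge(NamedTuple):
    source: str
    target: str
    count: int


def transition_matrix(scanpath: Scanpath, alphabet: Sequence[str]) -> TransitionMatrix:
    """Tally adjacent token pairs of one scanpath over ``alphabet``.

    Self-pairs are counted; the total equals ``len(scanpath) - 1`` (0 for
    scanpaths of at most one token).  Tokens outside the alphabet are an
    error.
    """
    labels = tuple(alphabet)
    index = {lab: i for i, lab in enumerate(labels)}
    unknown = set(scanpath.tokens) - set(labels)
    if unknown:
        raise ValueError(f"scanpath tokens {sorted(unknown)} not in alphabet")
    counts = np.zeros((len(labels), len(labels)), dtype=int)
    for a, b in zip(scanpath.tokens, scanpath.tokens[1:]):
        counts[index[a], index[b]] += 1
    return TransitionMatrix(labels, counts)


def aggregate_transitions(
    scanpaths: Sequence[Scanpath], alphabet: Sequence[str]
) -> TransitionMatrix:
    """Elementwise sum of per-scanpath transition matrices.

    The aggregate total equals the sum over scanpaths of (length - 1).
    """
    labels = tuple(alphabet)
    counts = np.zeros((len(labels), len(labels)), dtype=int)
    for sp in scanpaths:
        counts += transition_matrix(sp, labels).counts
    return TransitionMatrix(labels, counts)


def subset_and_edges(
    matrix: TransitionMatrix, keep_labels: Sequence[str]
) -> list[Edge]:
    """Nonzero directed edges among a subset of AOI labels.

    Self-loops are included; zero-count edges are omitted.  Edge order is
    deterministic: by source then target, in alphabet order.
    """
    keep = list(keep_labels)
    unknown = set(keep) - set(matrix.labels)
    if unknown:
        raise ValueError(f"labels {sorted(unknown)} not in matrix alphabet")
    keep_in_order = [lab for lab in matrix.labels if lab in set(keep)]
    index = {lab: i for i, lab in enumerate(matrix.labels)}
    edges = []
    for a in keep_in_order:
        for b in keep_in_order:
            c = int(matrix.counts[index[a], index[b]])
            if c > 0:
                edges.append(Edge(a, b, c))
    return edges


def write_edges(edges: Sequence[Edge], path) -> None:
    """Write an edge list as CSV (from, to, count) for chord renderers."""
    import csv
    from pathlib import Path

    with Path(path).open("w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh, lineterminator="\n")
        writer.writerow(["from", "to", "count"])
        for e in edges:
            writer.writerow([e.source, e.target, e.count])
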