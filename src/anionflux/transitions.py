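"""Row-stochastic compartment transition matrices from label series.

``transition_matrix`` pools (frame, frame+lag) label pairs over all anions
and row-normalizes the counts; each row gives the probability of migrating
from one compartment to any of the three after ``lag`` saved frames.  Rows
with no observations are reported as undefined (NaN) rather than filled.
Row/column order is (octahedral, interface, tetrahedral).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from anionflux.compartments import INTERFACE, OCTAHEDRAL, TETRAHEDRAL, LabelSeries

_ORDER = (OCTAHEDRAL, INTERFACE, TETRAHEDRAL)


@dataclass
class TransitionMatrix:
    P: np.ndarray  # (3, 3) probabilities, NaN rows where undefined
    counts: np.ndarray  # (3, 3) int
    lag: int
    defined_rows: np.ndarray  # (3,) bool
    mode: str = "frame"  # "frame" | "event"

    def __post_init__(self) -> None:
        for i in range(3):
            if self.defined_rows[i]:
                assert abs(self.P[i].sum() - 1.0) < 1e-12

    def to_dict(self) -> dict:
        return {
            "order": ["octahedral", "interface", "tetrahedral"],
            "lag": self.lag,
            "mode": self.mode,
            "counts": self.counts.tolist(),
            "P": [
                [None if np.isnan(v) else v for v in row] for row in self.P
            ],
            "defined_rows": self.defined_rows.tolist(),
        }


def transition_matrix(
    labels: LabelSeries, lag: int = 1, per_anion: bool = False
) -> TransitionMatrix | list[TransitionMatrix]:
    """Lag-``lag`` transition matrix pooled over anions (or one per anion)."""
    if lag < 1:
        raise ValueError("lag must be >= 1")
    if lag >= labels.n_frames:
        raise ValueError(f"lag {lag} must be smaller than n_frames {labels.n_frames}")
    if per_anion:
        return [
            _count_matrix(labels.labels[i : i + 1], lag) for i in range(labels.n_anions)
        ]
    return _count_matrix(labels.labels, lag)


def _count_matrix(arr: np.ndarray, lag: int) -> TransitionMatrix:
    src = arr[:, :-lag].ravel()
    dst = arr[:, lag:].ravel()
    counts = np.zeros((3, 3), dtype=np.int64)
    np.add.at(counts, (src, dst), 1)
    return _normalize(counts, lag, "frame")


def _normalize(counts: np.ndarray, lag: int, mode: str) -> TransitionMatrix:
    row_sums = counts.sum(axis=1)
    defined = row_sums > 0
    P = np.full((3, 3), np.nan)
    for i in range(3):
        if defined[i]:
            P[i] = counts[i] / row_sums[i]
    return TransitionMatrix(P=P, counts=counts, lag=lag, defined_rows=defined, mode=mode)


def event_transition_matrix(labels: LabelSeries) -> TransitionMatrix:
    """Transitions between consecutive *distinct* compartment residences.

    Alternative to the frame-lag construction: each anion's label sequence is
    compressed to its run-length encoding and successive (compartment,
    next-compartment) pairs are counted.  The diagonal is structurally zero.
    """
    counts = np.zeros((3, 3), dtype=np.int64)
    for row in labels.labels:
        changes = np.flatnonzero(np.diff(row) != 0)
        seq = row[np.concatenate([[0], changes + 1])]
        if len(seq) > 1:
            np.add.at(counts, (seq[:-1], seq[1:]), 1)
    return _normalize(counts, lag=1, mode="event")


def occupancy(labels: LabelSeries) -> np.ndarray:
    """Fraction of all (anion, frame) cells per compartment, order (O, I, T)."""
    if labels.labels.size == 0:
        raise ValueError("empty label series")
    total = labels.labels.size
    return np.array([np.sum(labels.labels == c) for c in _ORDER]) / total
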