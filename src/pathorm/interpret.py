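"""Attention-derived base-importance scoring.

A transformer's self-attention matrix over a host sequence measures pairwise
dependencies among positions.  Each position's raw importance is the sum of
its attention weights to the *other* positions (diagonal self-attention
excluded); min-max scaling maps the profile to [0,1].  High-importance
windows can be exported as FASTA for external motif discovery.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core_io import SequenceRecord, ValidationError


@dataclass
class AttentionMatrix:
    sequence_id: str
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2 or self.values.shape[0] != self.values.shape[1]:
            raise ValidationError("attention matrix must be square")
        if np.any(self.values < 0):
            raise ValidationError("attention entries must be nonnegative")


@dataclass
class ImportanceScores:
    sequence_id: str
    scores: np.ndarray


def attention_importance(att: AttentionMatrix) -> ImportanceScores:
    """Off-diagonal row sums, min-max scaled to [0,1].

    An all-equal raw profile (no position stands out) maps to the neutral
    constant 0.5.
    """
    L = att.values.shape[0]
    if L < 2:
        raise ValidationError("attention matrix must cover at least 2 positions")
    raw = att.values.sum(axis=1) - np.diag(att.values)
    lo, hi = raw.min(), raw.max()
    if hi > lo:
        scores = (raw - lo) / (hi - lo)
    else:
        scores = np.full(L, 0.5)
    return ImportanceScores(att.sequence_id, scores)


def top_window(
    record: SequenceRecord, scores: ImportanceScores, width: int
) -> tuple[int, str]:
    """Highest-total-importance window of the given width; returns (start, seq)."""
    L = len(record.ref_seq)
    if scores.scores.shape[0] != L:
        raise ValidationError("importance length does not match sequence length")
    if not 1 <= width <= L:
        raise ValidationError(f"window width must be in [1, {L}]")
    sums = np.convolve(scores.scores, np.ones(width), mode="valid")
    start = int(np.argmax(sums))
    return start, record.ref_seq[start : start + width]
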