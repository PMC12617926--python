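"""Per-entity feature views.

Sites get three views: a nucleotide-chemical-property (NCP) binary encoding,
an accumulated nucleotide frequency (ANF) profile, and a semantic embedding
supplied as a matrix (the output of a fine-tuned sequence language model,
consumed here as data).  Diseases get two views: a binary GO feature matrix
and a semantic embedding (text language model output, also consumed as data).
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum

import numpy as np

from .core_io import AlignmentError, NamedMatrix, SequenceRecord, ValidationError


class ViewKind(str, Enum):
    CHEMICAL = "chemical"
    STATISTICAL = "statistical"
    SEMANTIC = "semantic"
    GO = "go"


# Per-base (ring structure, hydrogen-bond strength, functional group) triples.
# Purines (A,G) carry ring bit 1; the remaining bits make the map injective.
NCP_TABLE: dict[str, tuple[int, int, int]] = {
    "A": (1, 1, 1),
    "C": (0, 1, 0),
    "G": (1, 0, 0),
    "U": (0, 0, 1),
}


@dataclass
class FeatureView:
    kind: ViewKind
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValidationError("view values must be 2-D")
        if not np.all(np.isfinite(self.values)):
            raise ValidationError("non-finite view entries")
        if self.kind in (ViewKind.CHEMICAL, ViewKind.GO):
            if not np.isin(self.values, (0.0, 1.0)).all():
                raise ValidationError(f"{self.kind.value} view must be binary 0/1")
        if self.kind is ViewKind.STATISTICAL:
            if self.values.min() < 0.0 or self.values.max() > 1.0:
                raise ValidationError("statistical view entries must lie in [0,1]")

    @property
    def dim(self) -> int:
        return self.values.shape[1]


@dataclass
class MultiViewSet:
    """Row-aligned feature views of one entity type (sites or diseases)."""

    entity_ids: list[str]
    views: list[FeatureView]

    def __post_init__(self) -> None:
        if not self.views:
            raise ValidationError("MultiViewSet needs at least one view")
        m = len(self.entity_ids)
        for v in self.views:
            if v.values.shape[0] != m:
                raise AlignmentError(
                    f"view with {v.values.shape[0]} rows != {m} entity ids"
                )

    @property
    def n_entities(self) -> int:
        return len(self.entity_ids)

    @property
    def n_views(self) -> int:
        return len(self.views)


def _check_alphabet(seq: str) -> None:
    bad = set(seq) - set(NCP_TABLE)
    if bad:
        raise ValidationError(f"invalid RNA characters {sorted(bad)}")


def ncp_encode(seq: str) -> np.ndarray:
    """Binary chemical-property encoding, 3 bits per base, 5'->3'."""
    _check_alphabet(seq)
    out = np.empty(3 * len(seq))
    for i, base in enumerate(seq):
        out[3 * i : 3 * i + 3] = NCP_TABLE[base]
    return out


def anf_encode(seq: str) -> np.ndarray:
    """Accumulated nucleotide frequency: prefix frequency of each position's base.

    Position i (1-based) receives count(seq[i] in seq[1..i]) / i, so every
    entry lies in (0, 1] and position 1 is exactly 1.0.
    """
    _check_alphabet(seq)
    out = np.empty(len(seq))
    counts = {b: 0 for b in NCP_TABLE}
    for i, base in enumerate(seq, start=1):
        counts[base] += 1
        out[i - 1] = counts[base] / i
    return out


def build_site_views(
    records: list[SequenceRecord],
    semantic: NamedMatrix,
    use_alt: bool = False,
) -> MultiViewSet:
    """Stack the chemical, statistical and semantic views for RM sites.

    With ``use_alt`` the chemical/statistical views are the concatenation of
    the reference and alternative encodings; by default only the reference
    sequence feeds the encoders.
    """
    if not records:
        raise ValidationError("no sequence records")
    window = len(records[0].ref_seq)
    for r in records:
        if len(r.ref_seq) != window:
            raise ValidationError(
                f"{r.site_id}: window {len(r.ref_seq)} != {window}"
            )
        if use_alt and r.alt_seq is None:
            raise ValidationError(f"{r.site_id}: use_alt requested but no alt_seq")
    ids = [r.site_id for r in records]

    def enc(fn):
        rows = []
        for r in records:
            row = fn(r.ref_seq)
            if use_alt:
                row = np.concatenate([row, fn(r.alt_seq)])
            rows.append(row)
        return np.vstack(rows)

    sem = semantic.reorder(ids)
    return MultiViewSet(
        ids,
        [
            FeatureView(ViewKind.CHEMICAL, enc(ncp_encode)),
            FeatureView(ViewKind.STATISTICAL, enc(anf_encode)),
            FeatureView(ViewKind.SEMANTIC, sem.values),
        ],
    )


def build_disease_views(go: NamedMatrix, semantic: NamedMatrix) -> MultiViewSet:
    """Two-view disease set (binary GO, continuous semantic), row-aligned."""
    if set(go.row_ids) != set(semantic.row_ids):
        missing = set(go.row_ids) ^ set(semantic.row_ids)
        raise AlignmentError(f"GO/semantic disease ids differ: {sorted(missing)[:5]}")
    ids = list(go.row_ids)
    sem = semantic.reorder(ids)
    return MultiViewSet(
        ids,
        [
            FeatureView(ViewKind.GO, go.values),
            FeatureView(ViewKind.SEMANTIC, sem.values),
        ],
    )
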