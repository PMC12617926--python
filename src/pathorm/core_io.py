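"""Readers and writers for on-disk artifacts.

Everything downstream consumes the containers defined here: fixed-width RNA
host-sequence records, site-disease association tables and dense named
matrices (semantic embeddings, GO features, attention matrices).  All readers
are strict — misaligned ids, ragged rows or foreign alphabet characters raise
immediately rather than propagating silently.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from Bio import SeqIO


class FormatError(ValueError):
    """Malformed file structure (ragged rows, missing columns, bad FASTA)."""


class ValidationError(ValueError):
    """Well-formed file whose content violates a contract."""


class AlignmentError(ValueError):
    """Identifiers do not line up across artifacts."""


_RNA_ALPHABET = frozenset("ACGU")

ALT_SUFFIX = "_alt"


@dataclass(frozen=True)
class SequenceRecord:
    """One RM site's host sequence window.

    ``ref_seq`` (and ``alt_seq`` when the variant-carrying form is supplied)
    is an RNA string over {A,C,G,U} of odd length, centered on the modified
    nucleotide at ``center_index``.
    """

    site_id: str
    ref_seq: str
    alt_seq: str | None = None
    center_index: int = field(default=-1)

    def __post_init__(self) -> None:
        if len(self.ref_seq) % 2 == 0:
            raise ValidationError(
                f"{self.site_id}: window length {len(self.ref_seq)} is not odd"
            )
        bad = set(self.ref_seq) - _RNA_ALPHABET
        if bad:
            raise ValidationError(
                f"{self.site_id}: non-ACGU characters {sorted(bad)} in ref_seq"
            )
        if self.alt_seq is not None:
            if len(self.alt_seq) != len(self.ref_seq):
                raise ValidationError(
                    f"{self.site_id}: alt_seq length {len(self.alt_seq)} != "
                    f"ref_seq length {len(self.ref_seq)}"
                )
            bad = set(self.alt_seq) - _RNA_ALPHABET
            if bad:
                raise ValidationError(
                    f"{self.site_id}: non-ACGU characters {sorted(bad)} in alt_seq"
                )
        if self.center_index == -1:
            object.__setattr__(self, "center_index", len(self.ref_seq) // 2)


@dataclass
class AssociationTable:
    """Validated positive pairs, sampled negatives and the entity indices."""

    positives: set[tuple[str, str]]
    negatives: set[tuple[str, str]]
    site_index: list[str]
    disease_index: list[str]

    def __post_init__(self) -> None:
        overlap = self.positives & self.negatives
        if overlap:
            raise ValidationError(f"pairs both positive and negative: {sorted(overlap)[:5]}")
        sites = set(self.site_index)
        diseases = set(self.disease_index)
        if len(sites) != len(self.site_index) or len(diseases) != len(self.disease_index):
            raise ValidationError("duplicate ids in site or disease index")
        for s, d in self.positives | self.negatives:
            if s not in sites:
                raise AlignmentError(f"unknown site_id {s!r} in association pair")
            if d not in diseases:
                raise AlignmentError(f"unknown disease_id {d!r} in association pair")

    @property
    def m(self) -> int:
        return len(self.site_index)

    @property
    def n(self) -> int:
        return len(self.disease_index)

    def with_indices(self, site_ids: list[str], disease_ids: list[str]) -> "AssociationTable":
        """Same pairs over explicit entity universes (supersets of the current
        indices); used to include sites/diseases that have no validated pair."""
        missing_s = set(self.site_index) - set(site_ids)
        missing_d = set(self.disease_index) - set(disease_ids)
        if missing_s or missing_d:
            raise AlignmentError(
                f"new indices drop ids: {sorted(missing_s | missing_d)[:5]}"
            )
        return AssociationTable(
            set(self.positives), set(self.negatives), list(site_ids), list(disease_ids)
        )

    def pair_indices(self, pairs) -> np.ndarray:
        """(len(pairs), 2) integer array of (site row, disease col)."""
        srow = {s: i for i, s in enumerate(self.site_index)}
        dcol = {d: j for j, d in enumerate(self.disease_index)}
        return np.array([[srow[s], dcol[d]] for s, d in pairs], dtype=int).reshape(-1, 2)


@dataclass
class NamedMatrix:
    """Dense real matrix with row identifiers (embeddings, GO, attention)."""

    row_ids: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValidationError("NamedMatrix values must be 2-D")
        if len(self.row_ids) != self.values.shape[0]:
            raise ValidationError(
                f"{len(self.row_ids)} row ids but {self.values.shape[0]} rows"
            )
        if not np.all(np.isfinite(self.values)):
            raise ValidationError("non-finite entries in matrix")

    def reorder(self, ids: list[str]) -> "NamedMatrix":
        """Rows re-aligned to ``ids``; missing ids raise AlignmentError."""
        pos = {r: i for i, r in enumerate(self.row_ids)}
        try:
            idx = [pos[i] for i in ids]
        except KeyError as e:
            raise AlignmentError(f"matrix has no row for id {e.args[0]!r}") from e
        return NamedMatrix(list(ids), self.values[idx])


def _normalize_seq(raw: str) -> str:
    return raw.upper().replace("T", "U")


def read_fasta(path, window: int) -> list[SequenceRecord]:
    """Read RM host sequences; pair ``<id>_alt`` records with their reference.

    Sequences are upper-cased and DNA T is mapped to RNA U on read.  Records
    whose length differs from ``window`` are rejected.  Output order follows
    the file order of reference records.
    """
    if window < 1 or window % 2 == 0:
        raise ValidationError(f"window must be a positive odd integer, got {window}")
    refs: dict[str, str] = {}
    alts: dict[str, str] = {}
    order: list[str] = []
    for rec in SeqIO.parse(str(path), "fasta"):
        sid = rec.id
        seq = _normalize_seq(str(rec.seq))
        if len(seq) != window:
            raise ValidationError(
                f"{sid}: sequence length {len(seq)} != window {window}"
            )
        bad = set(seq) - _RNA_ALPHABET
        if bad:
            raise ValidationError(f"{sid}: non-ACGTU characters {sorted(bad)}")
        if sid.endswith(ALT_SUFFIX):
            base = sid[: -len(ALT_SUFFIX)]
            if base in alts:
                raise FormatError(f"duplicate alt record for {base!r}")
            alts[base] = seq
        else:
            if sid in refs:
                raise FormatError(f"duplicate record id {sid!r}")
            refs[sid] = seq
            order.append(sid)
    orphan = set(alts) - set(refs)
    if orphan:
        raise AlignmentError(f"alt records without reference: {sorted(orphan)}")
    return [SequenceRecord(sid, refs[sid], alts.get(sid)) for sid in order]


def write_fasta(records: list[SequenceRecord], path) -> None:
    with open(path, "w") as fh:
        for r in records:
            fh.write(f">{r.site_id}\n{r.ref_seq}\n")
            if r.alt_seq is not None:
                fh.write(f">{r.site_id}{ALT_SUFFIX}\n{r.alt_seq}\n")


def read_association_table(path) -> AssociationTable:
    """Two-column TSV (site_id, disease_id[, label in {0,1}]).

    Label 1 or a missing label marks a positive pair, 0 a negative pair.
    Duplicates collapse; entity indices follow first appearance.
    """
    positives: set[tuple[str, str]] = set()
    negatives: set[tuple[str, str]] = set()
    site_index: list[str] = []
    disease_index: list[str] = []
    seen_s: set[str] = set()
    seen_d: set[str] = set()
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line:
                continue
            cols = line.split("\t")
            if len(cols) < 2:
                raise FormatError(f"line {lineno}: expected >=2 tab-separated columns")
            s, d = cols[0], cols[1]
            label = 1
            if len(cols) >= 3 and cols[2] != "":
                if cols[2] not in ("0", "1"):
                    raise ValidationError(
                        f"line {lineno}: label {cols[2]!r} not in {{0,1}}"
                    )
                label = int(cols[2])
            if s not in seen_s:
                seen_s.add(s)
                site_index.append(s)
            if d not in seen_d:
                seen_d.add(d)
                disease_index.append(d)
            (positives if label == 1 else negatives).add((s, d))
    return AssociationTable(positives, negatives, site_index, disease_index)


def write_association_table(table: AssociationTable, path) -> None:
    """Inverse of :func:`read_association_table` (labels written explicitly)."""
    with open(path, "w") as fh:
        for s in table.site_index:
            for d in table.disease_index:
                if (s, d) in table.positives:
                    fh.write(f"{s}\t{d}\t1\n")
                elif (s, d) in table.negatives:
                    fh.write(f"{s}\t{d}\t0\n")


def read_named_matrix(path) -> NamedMatrix:
    """Header-free TSV: first column row_id, remaining columns numeric."""
    row_ids: list[str] = []
    rows: list[list[float]] = []
    width = None
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line:
                continue
            cols = line.split("\t")
            if len(cols) < 2:
                raise FormatError(f"line {lineno}: expected id plus >=1 numeric column")
            if width is None:
                width = len(cols)
            elif len(cols) != width:
                raise FormatError(
                    f"line {lineno}: ragged row ({len(cols)} columns, expected {width})"
                )
            vals = []
            for j, cell in enumerate(cols[1:], start=2):
                try:
                    v = float(cell)
                except ValueError:
                    raise FormatError(
                        f"line {lineno}, column {j}: non-numeric cell {cell!r}"
                    ) from None
                if not math.isfinite(v):
                    raise ValidationError(f"line {lineno}, column {j}: non-finite value")
                vals.append(v)
            row_ids.append(cols[0])
            rows.append(vals)
    return NamedMatrix(row_ids, np.array(rows, dtype=float).reshape(len(rows), -1))


def write_named_matrix(mat: NamedMatrix, path) -> None:
    with open(path, "w") as fh:
        for rid, row in zip(mat.row_ids, mat.values):
            fh.write(rid + "\t" + "\t".join(repr(float(v)) for v in row) + "\n")
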