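"""Alignment I/O, reference-coordinate mapping and diverse-subset selection.

Multi-pass ER glycosyltransferase families are analysed on the residue
numbering of a designated reference sequence (typically the human enzyme).
This module reads aligned families in FASTA/Stockholm/Clustal dialects,
builds the column -> reference-position map, removes insertion columns
relative to the reference, and selects maximally diverse homolog subsets
by greedy farthest-point (maximin) selection on pairwise identity distance.

Coordinates are 1-based inclusive throughout.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Optional, Sequence

import numpy as np
from Bio import AlignIO, SeqIO
from Bio.Align import MultipleSeqAlignment
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord as _BioSeqRecord

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
#: sentinel used in column_map for columns where the reference carries a gap
GAP_IN_REFERENCE = 0

_FORMATS = {"fasta": "fasta", "stockholm": "stockholm", "clustal": "clustal"}


class MalformedInputError(ValueError):
    """Raised when an input file violates the format's structural invariants."""


@dataclass(frozen=True)
class SequenceRecord:
    """A named protein sequence (aligned strings may contain '-')."""

    id: str
    residues: str

    def __post_init__(self) -> None:
        if not self.residues:
            raise ValueError(f"record {self.id!r}: empty residue string")
        bad = set(self.residues.upper()) - set(AMINO_ACIDS + "X-")
        if bad:
            raise ValueError(
                f"record {self.id!r}: invalid residue(s) {sorted(bad)!r}"
            )

    @property
    def has_unknown(self) -> bool:
        """True when the sequence contains 'X' placeholders."""
        return "X" in self.residues

    def ungapped(self) -> str:
        return self.residues.replace("-", "")


@dataclass(frozen=True)
class AlignedFamily:
    """An MSA with an optional designated reference and column map.

    ``column_map[c]`` is the 1-based reference residue position of column
    ``c`` (0-based), or :data:`GAP_IN_REFERENCE` where the reference has a gap.
    """

    records: tuple[SequenceRecord, ...]
    reference_id: Optional[str] = None
    column_map: Optional[tuple[int, ...]] = None

    def __post_init__(self) -> None:
        if not self.records:
            raise ValueError("alignment has no records")
        L = len(self.records[0].residues)
        for r in self.records:
            if len(r.residues) != L:
                raise MalformedInputError(
                    f"record {r.id!r} has length {len(r.residues)}, expected {L}"
                )
        if self.reference_id is not None and self.reference_id not in self.ids:
            raise KeyError(f"reference {self.reference_id!r} not in alignment")

    @property
    def ids(self) -> tuple[str, ...]:
        return tuple(r.id for r in self.records)

    @property
    def length(self) -> int:
        """Aligned (column) length."""
        return len(self.records[0].residues)

    @property
    def n(self) -> int:
        return len(self.records)

    @property
    def reference(self) -> SequenceRecord:
        if self.reference_id is None:
            raise RuntimeError("reference sequence not set")
        return next(r for r in self.records if r.id == self.reference_id)

    def column(self, c: int) -> str:
        """Residues of 0-based column ``c``, one per record."""
        return "".join(r.residues[c] for r in self.records)


@dataclass(frozen=True)
class DistanceMatrix:
    """Symmetric pairwise identity distances in [0, 1]."""

    ids: tuple[str, ...]
    d: np.ndarray

    def __post_init__(self) -> None:
        n = len(self.ids)
        if self.d.shape != (n, n):
            raise ValueError("distance matrix shape does not match ids")

    def get(self, a: str, b: str) -> float:
        i, j = self.ids.index(a), self.ids.index(b)
        return float(self.d[i, j])


# ---------------------------------------------------------------------------
# reading / writing


def read_alignment(path: str | Path, format: str = "fasta") -> AlignedFamily:
    """Read an alignment file; the reference is left unset.

    Parameters
    ----------
    path:
        Alignment file.
    format:
        One of ``fasta``, ``stockholm``, ``clustal``.
    """
    if format not in _FORMATS:
        raise ValueError(
            f"unknown alignment format {format!r}; expected one of {sorted(_FORMATS)}"
        )
    try:
        msa = AlignIO.read(str(path), _FORMATS[format])
    except ValueError as exc:
        # Biopython reports ragged alignments (and parse failures) as ValueError;
        # FASTA needs an explicit length check because SeqIO tolerates ragged input.
        if format == "fasta":
            recs = list(SeqIO.parse(str(path), "fasta"))
            lengths = {len(r.seq) for r in recs}
            if recs and len(lengths) > 1:
                L = len(recs[0].seq)
                bad = next(r.id for r in recs if len(r.seq) != L)
                raise MalformedInputError(
                    f"ragged alignment: record {bad!r} differs in length"
                ) from exc
        raise MalformedInputError(f"cannot parse {path} as {format}: {exc}") from exc
    records = tuple(
        SequenceRecord(id=r.id, residues=str(r.seq).upper()) for r in msa
    )
    return AlignedFamily(records=records)


def write_alignment(
    family: AlignedFamily, path: str | Path, format: str = "fasta"
) -> None:
    """Write the alignment in the named dialect (round-trips with read)."""
    if format not in _FORMATS:
        raise ValueError(f"unknown alignment format {format!r}")
    msa = MultipleSeqAlignment(
        [
            _BioSeqRecord(Seq(r.residues), id=r.id, description="")
            for r in family.records
        ]
    )
    AlignIO.write(msa, str(path), _FORMATS[format])


def read_fasta(path: str | Path, keep_gaps: bool = False) -> list[SequenceRecord]:
    """Read protein FASTA records (gaps stripped unless ``keep_gaps``)."""
    out = []
    for r in SeqIO.parse(str(path), "fasta"):
        seq = str(r.seq).upper()
        if not keep_gaps:
            seq = seq.replace("-", "")
        out.append(SequenceRecord(id=r.id, residues=seq))
    return out


# ---------------------------------------------------------------------------
# reference coordinates


def set_reference(family: AlignedFamily, ref_id: str) -> AlignedFamily:
    """Designate ``ref_id`` as reference and compute the column map.

    The k-th non-gap reference column receives value ``k`` (1-based);
    columns where the reference is gapped are marked gap-in-reference.
    """
    if ref_id not in family.ids:
        raise KeyError(f"reference {ref_id!r} not in alignment")
    ref = next(r for r in family.records if r.id == ref_id)
    cmap: list[int] = []
    k = 0
    for ch in ref.residues:
        if ch == "-":
            cmap.append(GAP_IN_REFERENCE)
        else:
            k += 1
            cmap.append(k)
    return replace(family, reference_id=ref_id, column_map=tuple(cmap))


def degap_to_reference(family: AlignedFamily) -> AlignedFamily:
    """Drop every column where the reference is gapped.

    Insertions relative to the reference are deleted so positions keep the
    reference numbering; residue content of retained columns is unchanged.
    The output has aligned length equal to the reference's ungapped length.
    """
    if family.column_map is None:
        raise RuntimeError("reference not set: call set_reference first")
    keep = [c for c, v in enumerate(family.column_map) if v != GAP_IN_REFERENCE]
    records = tuple(
        SequenceRecord(id=r.id, residues="".join(r.residues[c] for c in keep))
        for r in family.records
    )
    return AlignedFamily(
        records=records,
        reference_id=family.reference_id,
        column_map=tuple(range(1, len(keep) + 1)),
    )


def column_map_table(family: AlignedFamily):
    """Column map as a DataFrame (column, reference_position) for TSV export."""
    import pandas as pd

    if family.column_map is None:
        raise RuntimeError("reference not set")
    return pd.DataFrame(
        {
            "column": np.arange(1, family.length + 1),
            "reference_position": [
                v if v != GAP_IN_REFERENCE else "gap" for v in family.column_map
            ],
        }
    )


# ---------------------------------------------------------------------------
# diversity selection


def pairwise_distances(records: Sequence[SequenceRecord]) -> DistanceMatrix:
    """1 - fractional identity over mutually non-gap, non-X positions.

    Pairs with no comparable position get distance 1.  Unaligned inputs of
    equal length are compared positionally; mixed lengths are rejected.
    """
    lengths = {len(r.residues) for r in records}
    if len(lengths) > 1:
        raise ValueError("records must share one (aligned) length")
    arr = np.array([list(r.residues) for r in records])
    valid = (arr != "-") & (arr != "X")
    n = len(records)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            both = valid[i] & valid[j]
            m = int(both.sum())
            if m == 0:
                dij = 1.0
            else:
                ident = int((arr[i][both] == arr[j][both]).sum())
                dij = 1.0 - ident / m
            d[i, j] = d[j, i] = dij
    return DistanceMatrix(ids=tuple(r.id for r in records), d=d)


def select_diverse(
    records: Sequence[SequenceRecord],
    k: int,
    seed_id: Optional[str] = None,
    include: Iterable[str] = (),
) -> list[str]:
    """Greedy maximin (farthest-point) selection of ``k`` diverse identifiers.

    Starts from ``seed_id`` if given, else from the most distant pair; then
    repeatedly adds the record whose minimum distance to the chosen set is
    maximal.  Ties break on the lexicographically smallest id, which makes the
    result invariant to input order.  ``include`` forces identifiers into the
    selection before greedy growth (e.g. known paralogs).
    """
    if k > len(records):
        raise ValueError(f"k={k} exceeds number of records ({len(records)})")
    if k <= 0:
        raise ValueError("k must be positive")
    dm = pairwise_distances(records)
    ids = list(dm.ids)
    index = {s: i for i, s in enumerate(ids)}
    chosen: list[str] = []
    for s in include:
        if s not in index:
            raise KeyError(f"include id {s!r} not among records")
        if s not in chosen:
            chosen.append(s)
    if seed_id is not None:
        if seed_id not in index:
            raise KeyError(f"seed id {seed_id!r} not among records")
        if seed_id not in chosen:
            chosen.insert(0, seed_id)
    if len(chosen) > k:
        raise ValueError("include/seed lists exceed k")
    if not chosen:
        # most distant pair; ties -> lexicographically smallest (i, j) id pair
        best = (-1.0, ("", ""))
        for i in range(len(ids)):
            for j in range(i + 1, len(ids)):
                key = (dm.d[i, j], tuple(sorted((ids[i], ids[j]))))
                if key[0] > best[0] or (key[0] == best[0] and key[1] < best[1]):
                    best = key
        pair = sorted(best[1])
        chosen = pair[: min(k, 2)]
    while len(chosen) < k:
        chosen_idx = [index[s] for s in chosen]
        remaining = sorted(s for s in ids if s not in chosen)
        best_id, best_score = None, -1.0
        for s in remaining:
            score = float(dm.d[index[s], chosen_idx].min())
            if score > best_score:
                best_id, best_score = s, score
        chosen.append(best_id)  # type: ignore[arg-type]
    return chosen
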