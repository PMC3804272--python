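"""Input parsing and validation for all pipeline file formats.

Formats handled here:

* proteome FASTA (one record per protein; header token up to the first
  whitespace is the sequence id),
* domain-assignment TSV with columns ``seq_id``, ``fsf_id``, ``regions``,
  where ``regions`` is a comma-separated list of 1-based inclusive
  ``start-end`` segments (split domains have several segments),
* homolog-pair TSV with columns ``id_a``, ``id_b``,
* the packaged barophily reference table (amino-acid class B/N/I and
  barophily rank).

Coordinates in files follow the 1-based inclusive convention of structural
domain censuses; in memory every interval is 0-based half-open.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd
from Bio import SeqIO

#: The 20 standard amino acids, alphabetical by one-letter code.
AMINO_ACIDS: str = "ACDEFGHIKLMNPQRSTVWY"

#: Ambiguity/non-standard letters tolerated on input but excluded from
#: composition counts (both numerator and denominator).
AMBIGUOUS_LETTERS: frozenset[str] = frozenset("XBZU")

_VALID_LETTERS = frozenset(AMINO_ACIDS) | AMBIGUOUS_LETTERS

Interval = tuple[int, int]  # 0-based half-open


class FormatError(ValueError):
    """Raised when an input file violates its format contract."""


@dataclass(frozen=True)
class ProteinRecord:
    """A single protein sequence with its identifier."""

    seq_id: str
    sequence: str

    def __post_init__(self) -> None:
        if not self.seq_id:
            raise FormatError("empty sequence id")
        if not self.sequence:
            raise FormatError(f"empty sequence for id {self.seq_id!r}")
        bad = set(self.sequence) - _VALID_LETTERS
        if bad:
            raise FormatError(
                f"sequence {self.seq_id!r} contains non-amino-acid letters: "
                f"{sorted(bad)}"
            )

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class DomainAssignment:
    """One fold-superfamily (FSF) domain assignment on a sequence.

    ``intervals`` are 0-based half-open segments, sorted and non-overlapping;
    a multi-segment list encodes a split (discontinuous) domain.
    """

    seq_id: str
    fsf_id: str
    intervals: tuple[Interval, ...]

    def __post_init__(self) -> None:
        if not self.intervals:
            raise FormatError(f"assignment of {self.fsf_id} on {self.seq_id}: no intervals")
        prev_end = -1
        for start, end in self.intervals:
            if start < 0 or end <= start:
                raise FormatError(
                    f"assignment of {self.fsf_id} on {self.seq_id}: "
                    f"invalid interval ({start}, {end})"
                )
            if start < prev_end:
                raise FormatError(
                    f"assignment of {self.fsf_id} on {self.seq_id}: "
                    "intervals overlap or are unsorted"
                )
            prev_end = end

    @property
    def n_residues(self) -> int:
        return sum(end - start for start, end in self.intervals)


@dataclass(frozen=True)
class HomologPair:
    """A pair of homologous sequence ids (species A = barophile first)."""

    id_a: str
    id_b: str


@dataclass(frozen=True)
class BarophilyReference:
    """Amino-acid barophily classes and ranks.

    Each of the 20 standard amino acids carries a class — B (barophilic),
    N (nonbarophilic) or I (indifferent) — and, for classes B and N, an
    integer barophily rank BR (20 = most barophilic, 1 = least).
    """

    classes: Mapping[str, str]
    ranks: Mapping[str, int | None]

    def aa_class(self, aa: str) -> str:
        return self.classes[aa]

    def rank(self, aa: str) -> int | None:
        return self.ranks[aa]

    @property
    def barophilic(self) -> tuple[str, ...]:
        return tuple(a for a in self.table_order() if self.classes[a] == "B")

    @property
    def nonbarophilic(self) -> tuple[str, ...]:
        return tuple(a for a in self.table_order() if self.classes[a] == "N")

    @property
    def indifferent(self) -> tuple[str, ...]:
        return tuple(a for a in self.table_order() if self.classes[a] == "I")

    def table_order(self) -> tuple[str, ...]:
        """Amino acids ordered by descending BR, unranked ones last, alphabetical."""
        ranked = sorted(
            (a for a in AMINO_ACIDS if self.ranks[a] is not None),
            key=lambda a: -self.ranks[a],  # type: ignore[operator]
        )
        unranked = sorted(a for a in AMINO_ACIDS if self.ranks[a] is None)
        return tuple(ranked + unranked)


# ---------------------------------------------------------------------------
# coordinate conversions

def interval_from_inclusive(start: int, end: int) -> Interval:
    """Convert a 1-based inclusive (start, end) to 0-based half-open."""
    if start < 1 or end < start:
        raise FormatError(f"invalid 1-based interval {start}-{end}")
    return (start - 1, end)


def interval_to_inclusive(interval: Interval) -> tuple[int, int]:
    start, end = interval
    return (start + 1, end)


# ---------------------------------------------------------------------------
# readers / writers

def read_fasta(path: str | Path) -> list[ProteinRecord]:
    """Read a proteome FASTA into validated :class:`ProteinRecord` objects.

    The seq_id is the header token up to the first whitespace; sequences are
    uppercased. Duplicate ids, empty sequences and letters outside the 20
    standard codes plus X/B/Z/U are hard errors.
    """
    records: list[ProteinRecord] = []
    seen: set[str] = set()
    for entry in SeqIO.parse(str(path), "fasta"):
        seq_id = entry.id
        if seq_id in seen:
            raise FormatError(f"duplicate sequence id {seq_id!r} in {path}")
        seen.add(seq_id)
        records.append(ProteinRecord(seq_id, str(entry.seq).upper()))
    return records


def write_fasta(records: Iterable[ProteinRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f">{rec.seq_id}\n")
            for i in range(0, len(rec.sequence), 70):
                fh.write(rec.sequence[i : i + 70] + "\n")


def _parse_regions(regions: str, context: str) -> tuple[Interval, ...]:
    intervals = []
    for segment in regions.split(","):
        segment = segment.strip()
        try:
            start_s, end_s = segment.split("-")
            start, end = int(start_s), int(end_s)
        except ValueError as exc:
            raise FormatError(f"{context}: malformed region segment {segment!r}") from exc
        if start > end:
            raise FormatError(f"{context}: inverted interval {segment!r}")
        intervals.append(interval_from_inclusive(start, end))
    return tuple(sorted(intervals))


def read_domain_assignments(path: str | Path) -> list[DomainAssignment]:
    """Read a domain-assignment TSV (seq_id, fsf_id, regions)."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"seq_id", "fsf_id", "regions"}
    if not required.issubset(df.columns):
        raise FormatError(
            f"{path}: expected columns {sorted(required)}, found {list(df.columns)}"
        )
    assignments = []
    for row in df.itertuples(index=False):
        intervals = _parse_regions(row.regions, f"{path}:{row.seq_id}/{row.fsf_id}")
        assignments.append(DomainAssignment(row.seq_id, row.fsf_id, intervals))
    return assignments


def write_domain_assignments(
    assignments: Iterable[DomainAssignment], path: str | Path
) -> None:
    rows = []
    for a in assignments:
        regions = ",".join(
            f"{s}-{e}" for s, e in (interval_to_inclusive(iv) for iv in a.intervals)
        )
        rows.append((a.seq_id, a.fsf_id, regions))
    pd.DataFrame(rows, columns=["seq_id", "fsf_id", "regions"]).to_csv(
        path, sep="\t", index=False
    )


def read_homolog_pairs(path: str | Path) -> list[HomologPair]:
    """Read a two-column homolog-pair TSV; a seq_id may appear in one pair only."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    if df.shape[1] < 2:
        raise FormatError(f"{path}: expected two id columns")
    col_a, col_b = df.columns[:2]
    for col in (col_a, col_b):
        dup = df[col][df[col].duplicated()]
        if not dup.empty:
            raise FormatError(
                f"{path}: sequence id(s) in more than one pair: {sorted(set(dup))}"
            )
    return [HomologPair(a, b) for a, b in zip(df[col_a], df[col_b])]


def write_homolog_pairs(pairs: Iterable[HomologPair], path: str | Path) -> None:
    pd.DataFrame(
        [(p.id_a, p.id_b) for p in pairs], columns=["id_a", "id_b"]
    ).to_csv(path, sep="\t", index=False)


def load_barophily_reference() -> BarophilyReference:
    """Load the packaged amino-acid barophily class/rank table."""
    resource = importlib.resources.files("barocomp").joinpath(
        "data/barophily_reference.tsv"
    )
    with resource.open() as fh:
        df = pd.read_csv(fh, sep="\t", dtype={"aa": str, "class": str})
    classes = dict(zip(df["aa"], df["class"]))
    ranks = {
        aa: (int(r) if pd.notna(r) else None) for aa, r in zip(df["aa"], df["rank"])
    }
    if set(classes) != set(AMINO_ACIDS):
        raise FormatError("barophily reference must cover exactly the 20 amino acids")
    return BarophilyReference(classes=classes, ranks=ranks)
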