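"""Partition protein sequences into structural contexts.

A residue belongs to exactly one of three disjoint contexts:

* ``domain_shared`` — covered by an assignment whose FSF occurs in both
  species' repertoires (shared wins when shared and species-specific
  assignments overlap),
* ``domain_specific`` — covered only by species-specific-FSF assignments,
* ``intervening`` — covered by no assignment (the "connecting" sequence
  between domains).

``domain_all`` and ``whole`` are the obvious unions. All intervals here are
0-based half-open.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

from .io import DomainAssignment, Interval, ProteinRecord

WHOLE = "whole"
DOMAIN_ALL = "domain_all"
DOMAIN_SHARED = "domain_shared"
DOMAIN_SPECIFIC = "domain_specific"
INTERVENING = "intervening"

CONTEXTS = (WHOLE, DOMAIN_ALL, DOMAIN_SHARED, DOMAIN_SPECIFIC, INTERVENING)


def merge_intervals(intervals: Iterable[Interval]) -> list[Interval]:
    """Merge overlapping or adjacent half-open intervals into a minimal disjoint set."""
    merged: list[Interval] = []
    for start, end in sorted(intervals):
        if merged and start <= merged[-1][1]:
            merged[-1] = (merged[-1][0], max(merged[-1][1], end))
        else:
            merged.append((start, end))
    return merged


def subtract_intervals(
    intervals: Sequence[Interval], holes: Sequence[Interval]
) -> list[Interval]:
    """Residues in ``intervals`` but not in ``holes`` (both assumed merged)."""
    result: list[Interval] = []
    for start, end in intervals:
        pos = start
        for h_start, h_end in holes:
            if h_end <= pos or h_start >= end:
                continue
            if h_start > pos:
                result.append((pos, h_start))
            pos = max(pos, h_end)
            if pos >= end:
                break
        if pos < end:
            result.append((pos, end))
    return result


def complement_intervals(intervals: Sequence[Interval], length: int) -> list[Interval]:
    return subtract_intervals([(0, length)], merge_intervals(intervals))


def total_length(intervals: Iterable[Interval]) -> int:
    return sum(end - start for start, end in intervals)


def extract(sequence: str, intervals: Iterable[Interval]) -> str:
    return "".join(sequence[start:end] for start, end in intervals)


@dataclass(frozen=True)
class SequencePartition:
    """Per-context subsequences and interval sets for one protein."""

    seq_id: str
    subsequences: Mapping[str, str]
    intervals: Mapping[str, tuple[Interval, ...]]

    def residue_count(self, context: str) -> int:
        return len(self.subsequences[context])


def partition_sequence(
    record: ProteinRecord,
    assignments: Sequence[DomainAssignment],
    shared_fsf_set: set[str] | frozenset[str],
) -> SequencePartition:
    """Split one sequence into shared-FSF, specific-FSF and intervening contexts.

    Precedence: a residue covered by both a shared-FSF and a specific-FSF
    assignment counts as shared, keeping the three contexts disjoint. An
    assignment extending past the end of the sequence is an error.
    """
    length = len(record.sequence)
    shared_raw: list[Interval] = []
    specific_raw: list[Interval] = []
    for a in assignments:
        if a.seq_id != record.seq_id:
            raise ValueError(
                f"assignment for {a.seq_id!r} passed with record {record.seq_id!r}"
            )
        if a.intervals[-1][1] > length:
            raise ValueError(
                f"assignment of {a.fsf_id} on {a.seq_id} exceeds sequence length "
                f"({a.intervals[-1][1]} > {length})"
            )
        (shared_raw if a.fsf_id in shared_fsf_set else specific_raw).extend(a.intervals)

    shared = merge_intervals(shared_raw)
    specific = subtract_intervals(merge_intervals(specific_raw), shared)
    domain_all = merge_intervals(shared_raw + specific_raw)
    intervening = complement_intervals(domain_all, length)

    intervals = {
        WHOLE: ((0, length),),
        DOMAIN_ALL: tuple(domain_all),
        DOMAIN_SHARED: tuple(shared),
        DOMAIN_SPECIFIC: tuple(specific),
        INTERVENING: tuple(intervening),
    }
    subsequences = {
        context: extract(record.sequence, ivs) for context, ivs in intervals.items()
    }
    return SequencePartition(record.seq_id, subsequences, intervals)


def partition_to_bed_rows(partition: SequencePartition) -> list[tuple[str, int, int, str]]:
    """BED-like rows (seq_id, start, end, context) for the disjoint contexts."""
    rows = []
    for context in (DOMAIN_SHARED, DOMAIN_SPECIFIC, INTERVENING):
        for start, end in partition.intervals[context]:
            rows.append((partition.seq_id, start, end, context))
    return sorted(rows, key=lambda r: (r[0], r[1]))
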