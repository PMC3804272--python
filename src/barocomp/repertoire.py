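"""Fold-superfamily repertoires, Venn comparison and proteome summaries."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np

from .io import DomainAssignment, ProteinRecord
from .regions import merge_intervals, total_length


@dataclass(frozen=True)
class FSFRepertoire:
    species: str
    fsf_ids: frozenset[str]

    def __len__(self) -> int:
        return len(self.fsf_ids)


@dataclass(frozen=True)
class ProteomeSummary:
    """Headline proteome statistics: sequence counts, length distribution,
    fraction of residues inside FSF domain regions, FSF counts."""

    species: str
    n_sequences: int
    n_with_assignment: int
    mean_length: float
    sd_length: float
    min_length: int
    max_length: int
    fraction_in_fsf: float
    n_fsfs: int
    n_specific_fsfs: int | None = None


def build_repertoire(
    assignments: Iterable[DomainAssignment], species: str
) -> FSFRepertoire:
    return FSFRepertoire(species, frozenset(a.fsf_id for a in assignments))


def compare_repertoires(
    a: FSFRepertoire, b: FSFRepertoire
) -> tuple[frozenset[str], frozenset[str], frozenset[str]]:
    """(shared, only_a, only_b) FSF id sets."""
    shared = a.fsf_ids & b.fsf_ids
    return frozenset(shared), frozenset(a.fsf_ids - shared), frozenset(b.fsf_ids - shared)


def proteome_summary(
    records: Sequence[ProteinRecord],
    assignments: Sequence[DomainAssignment],
    species: str = "",
    n_specific_fsfs: int | None = None,
) -> ProteomeSummary:
    lengths = np.array([len(r) for r in records])
    by_seq: dict[str, list] = {}
    for a in assignments:
        by_seq.setdefault(a.seq_id, []).extend(a.intervals)
    total_residues = int(lengths.sum()) if len(records) else 0
    covered = sum(
        total_length(merge_intervals(ivs)) for ivs in by_seq.values()
    )
    return ProteomeSummary(
        species=species,
        n_sequences=len(records),
        n_with_assignment=len(by_seq),
        mean_length=float(lengths.mean()) if len(records) else 0.0,
        sd_length=float(lengths.std(ddof=1)) if len(records) > 1 else 0.0,
        min_length=int(lengths.min()) if len(records) else 0,
        max_length=int(lengths.max()) if len(records) else 0,
        fraction_in_fsf=covered / total_residues if total_residues else 0.0,
        n_fsfs=len({a.fsf_id for a in assignments}),
        n_specific_fsfs=n_specific_fsfs,
    )


def tally_functions(
    fsf_set: Iterable[str], category_map: Mapping[str, str]
) -> dict[str, int]:
    """Count FSFs per functional category; unmapped ids fall under 'unknown'."""
    counts: dict[str, int] = {}
    for fsf in fsf_set:
        category = category_map.get(fsf, "unknown")
        counts[category] = counts.get(category, 0) + 1
    return counts
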