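"""Homologous sequence pairs: category classification and matched-FSF analysis.

Homolog pairs fall into 5 categories by their FSF assignment multisets:

1. neither sequence has FSF assignments,
2. assignments in one sequence but not the other,
3. extra assignments in one sequence (strict multiset containment — an
   extra repeat of a shared FSF counts as extra),
4. completely different assignments (neither multiset contains the other),
5. identical assignments.

Only category-5 pairs enter the matched-FSF analysis: for each FSF of such
a pair, the composition of its region is computed in both orthologs
(multiple repeats of the FSF within one sequence are averaged, not pooled),
giving one matched observation per (pair, FSF). Observations sharing an FSF
are averaged first, and the resulting per-FSF species means are compared
with the Welch two-sample test — optionally restricted to an age stratum.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from . import chronology
from .composition import (
    AA_INDEX,
    compare_groups,
    relative_abundance,
    significance_stars,
)
from .io import BarophilyReference, DomainAssignment, HomologPair, ProteinRecord
from .regions import extract


def classify_pair(
    assign_a: Sequence[DomainAssignment], assign_b: Sequence[DomainAssignment]
) -> int:
    """Category 1-5 of a homolog pair from its two FSF assignment multisets."""
    ms_a = Counter(a.fsf_id for a in assign_a)
    ms_b = Counter(a.fsf_id for a in assign_b)
    if not ms_a and not ms_b:
        return 1
    if not ms_a or not ms_b:
        return 2
    if ms_a == ms_b:
        return 5
    a_contains_b = all(ms_a[f] >= n for f, n in ms_b.items())
    b_contains_a = all(ms_b[f] >= n for f, n in ms_a.items())
    if a_contains_b or b_contains_a:
        return 3
    return 4


def per_sequence_fsf_composition(
    record: ProteinRecord, assignments: Sequence[DomainAssignment]
) -> np.ndarray | None:
    """Composition of one FSF on one sequence, averaging over repeats.

    Each assignment is one repeat; its segments are concatenated and the
    per-repeat relative abundances are averaged (not pooled), so a short
    repeat weighs as much as a long one. Returns None if every repeat is
    empty after ambiguity filtering.
    """
    if not assignments:
        raise ValueError("per_sequence_fsf_composition needs >= 1 assignment")
    fsfs = {a.fsf_id for a in assignments}
    if len(fsfs) != 1:
        raise ValueError(f"assignments span multiple FSFs: {sorted(fsfs)}")
    repeats = []
    for a in assignments:
        vec = relative_abundance(extract(record.sequence, a.intervals))
        if vec is not None:
            repeats.append(vec)
    if not repeats:
        return None
    return np.mean(repeats, axis=0)


@dataclass(frozen=True)
class MatchedFSFObservation:
    """One (homolog pair, FSF) matched-composition observation."""

    fsf_id: str
    id_a: str
    id_b: str
    comp_a: np.ndarray
    comp_b: np.ndarray

    @property
    def diff(self) -> np.ndarray:
        return self.comp_a - self.comp_b


def matched_fsf_dataset(
    pairs: Sequence[HomologPair],
    records_a: Mapping[str, ProteinRecord],
    records_b: Mapping[str, ProteinRecord],
    assignments_a: Mapping[str, Sequence[DomainAssignment]],
    assignments_b: Mapping[str, Sequence[DomainAssignment]],
) -> list[MatchedFSFObservation]:
    """Matched observations for category-5 pairs (one per pair x FSF).

    ``assignments_*`` map seq_id to that sequence's assignments. Passing a
    pair that is not category 5 is an error.
    """
    observations = []
    for pair in pairs:
        asg_a = list(assignments_a.get(pair.id_a, ()))
        asg_b = list(assignments_b.get(pair.id_b, ()))
        if classify_pair(asg_a, asg_b) != 5:
            raise ValueError(
                f"pair ({pair.id_a}, {pair.id_b}) does not have identical "
                "FSF assignments (category 5 required)"
            )
        for fsf in sorted({a.fsf_id for a in asg_a}):
            comp_a = per_sequence_fsf_composition(
                records_a[pair.id_a], [a for a in asg_a if a.fsf_id == fsf]
            )
            comp_b = per_sequence_fsf_composition(
                records_b[pair.id_b], [a for a in asg_b if a.fsf_id == fsf]
            )
            if comp_a is None or comp_b is None:
                continue  # empty region after ambiguity filtering
            observations.append(
                MatchedFSFObservation(fsf, pair.id_a, pair.id_b, comp_a, comp_b)
            )
    return observations


def per_fsf_means(
    observations: Sequence[MatchedFSFObservation],
) -> tuple[list[str], list[np.ndarray], list[np.ndarray]]:
    """Average matched observations over pairs within each FSF."""
    by_fsf: dict[str, list[MatchedFSFObservation]] = {}
    for obs in observations:
        by_fsf.setdefault(obs.fsf_id, []).append(obs)
    fsf_ids = sorted(by_fsf)
    means_a = [np.mean([o.comp_a for o in by_fsf[f]], axis=0) for f in fsf_ids]
    means_b = [np.mean([o.comp_b for o in by_fsf[f]], axis=0) for f in fsf_ids]
    return fsf_ids, means_a, means_b


def matched_comparison(
    observations: Sequence[MatchedFSFObservation],
    ref: BarophilyReference,
    age_table: pd.DataFrame | None = None,
    stratum: str | None = None,
    test: str = "welch",
) -> pd.DataFrame:
    """Species comparison over per-FSF mean compositions.

    With ``stratum`` ("ancient" or "recent") and an ``age_table`` (from
    :func:`barocomp.chronology.build_age_table`), only FSFs whose nd falls
    in the stratum are kept. ``test`` selects the default Welch two-sample
    test on the two per-FSF mean sets, or ``"paired"`` for a one-sample
    t-test on the per-FSF mean differences.
    """
    if stratum is not None:
        if age_table is None:
            raise ValueError("stratum filtering requires an age_table")
        keep = set(age_table.index[age_table["stratum"] == stratum])
        observations = [o for o in observations if o.fsf_id in keep]
    if not observations:
        raise ValueError(f"no matched observations in stratum {stratum!r}")
    fsf_ids, means_a, means_b = per_fsf_means(observations)
    if len(fsf_ids) < 2:
        raise ValueError(
            f"need >= 2 FSFs for a comparison, got {len(fsf_ids)}"
            + (f" in stratum {stratum!r}" if stratum else "")
        )
    if test == "welch":
        return compare_groups(means_a, means_b, ref)
    if test == "paired":
        return _paired_comparison(means_a, means_b, ref)
    raise ValueError(f"unknown test {test!r}")


def _paired_comparison(
    means_a: Sequence[np.ndarray],
    means_b: Sequence[np.ndarray],
    ref: BarophilyReference,
) -> pd.DataFrame:
    diffs = np.asarray(means_a) - np.asarray(means_b)
    mat_a, mat_b = np.asarray(means_a), np.asarray(means_b)
    rows = []
    for aa in ref.table_order():
        i = AA_INDEX[aa]
        d = diffs[:, i]
        if np.allclose(d.var(ddof=1), 0.0):
            if np.isclose(d.mean(), 0):
                t, df, p = 0.0, float(len(d) - 1), 1.0
            else:  # constant nonzero difference
                t, df, p = float(np.sign(d.mean()) * np.inf), float(len(d) - 1), 0.0
        else:
            res = stats.ttest_1samp(d, 0.0)
            t, df, p = float(res.statistic), float(len(d) - 1), float(res.pvalue)
        rows.append(
            {
                "aa": aa,
                "class": ref.aa_class(aa),
                "rank": ref.rank(aa),
                "maa_a": mat_a[:, i].mean(),
                "maa_b": mat_b[:, i].mean(),
                "diff": d.mean(),
                "sd_a": mat_a[:, i].std(ddof=1),
                "sd_b": mat_b[:, i].std(ddof=1),
                "sem_a": mat_a[:, i].std(ddof=1) / np.sqrt(len(d)),
                "sem_b": mat_b[:, i].std(ddof=1) / np.sqrt(len(d)),
                "t": t,
                "df": df,
                "p": p,
                "stars": significance_stars(p),
                "n_a": len(d),
                "n_b": len(d),
            }
        )
    return pd.DataFrame(rows).set_index("aa")
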