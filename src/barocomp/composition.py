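"""Relative amino-acid abundance statistics and Welch group comparisons.

The relative abundance of an amino acid in a region is the number of its
occurrences divided by the number of standard residues in the region
(ambiguity letters X/B/Z/U are excluded from numerator and denominator, so
the 20 abundances always sum to 1). Averaging such vectors over the
sequences of a group gives the mean relative amino-acid abundance (MAA).
Species are compared per amino acid with the two-sided Welch two-sample
t-test on the per-sequence abundances; differences are reported as
barophile minus nonbarophile, so positive means "used more by the
barophile".
"""

from __future__ import annotations

from collections import Counter
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .io import AMINO_ACIDS, BarophilyReference

#: Composition vectors are float arrays of length 20 in this fixed order.
AA_INDEX: dict[str, int] = {aa: i for i, aa in enumerate(AMINO_ACIDS)}

#: Significance tiers: no 0.05 tier exists in this star scheme.
STAR_TIERS: tuple[tuple[float, str], ...] = (
    (1e-4, "****"),
    (1e-3, "***"),
    (1e-2, "**"),
    (1e-1, "*"),
)


class DegenerateComparisonError(ValueError):
    """Both samples have zero variance but different means."""


def relative_abundance(subsequence: str) -> np.ndarray | None:
    """Composition vector of a region, or None if it has no standard residue."""
    counts = Counter(subsequence)
    total = sum(counts[aa] for aa in AMINO_ACIDS)
    if total == 0:
        return None
    vec = np.zeros(len(AMINO_ACIDS))
    for aa, n in counts.items():
        idx = AA_INDEX.get(aa)
        if idx is not None:
            vec[idx] = n / total
    return vec


def group_mean(vectors: Sequence[np.ndarray]) -> np.ndarray:
    """Unweighted arithmetic mean of composition vectors (the MAA vector)."""
    if len(vectors) == 0:
        raise ValueError("group_mean of an empty group")
    return np.mean(np.asarray(vectors), axis=0)


def welch_t(x: Sequence[float], y: Sequence[float]) -> tuple[float, float, float]:
    """Welch two-sample t-test: returns (t, Welch–Satterthwaite df, two-sided p).

    When both samples have zero variance: equal means give the degenerate
    null result (t=0, p=1, df = nx+ny-2); unequal means raise
    :class:`DegenerateComparisonError`.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 2 or len(y) < 2:
        raise ValueError("welch_t needs at least 2 observations per sample")
    if x.var(ddof=1) == 0.0 and y.var(ddof=1) == 0.0:
        if np.isclose(x.mean(), y.mean()):
            return 0.0, float(len(x) + len(y) - 2), 1.0
        raise DegenerateComparisonError(
            "zero variance in both samples with unequal means"
        )
    res = stats.ttest_ind(x, y, equal_var=False)
    return float(res.statistic), float(res.df), float(res.pvalue)


def significance_stars(p: float) -> str:
    if not 0.0 <= p <= 1.0:
        raise ValueError(f"p-value out of range: {p}")
    for threshold, stars in STAR_TIERS:
        if p < threshold:
            return stars
    return ""


def compare_groups(
    obs_a: Sequence[np.ndarray],
    obs_b: Sequence[np.ndarray],
    ref: BarophilyReference,
) -> pd.DataFrame:
    """Per-amino-acid Welch comparison of two sets of composition vectors.

    ``obs_a`` is the barophile group, ``obs_b`` the nonbarophile; ``diff``
    is ``maa_a - maa_b``. Rows are indexed by one-letter amino acid in
    barophily-rank order (descending BR, then unranked alphabetical) with
    columns maa_a, maa_b, diff, sd/sem per group, t, df, p, stars, class,
    rank, n_a, n_b.
    """
    if len(obs_a) < 2 or len(obs_b) < 2:
        raise ValueError("compare_groups needs >= 2 observations per group")
    mat_a = np.asarray(obs_a)
    mat_b = np.asarray(obs_b)
    rows = []
    for aa in ref.table_order():
        i = AA_INDEX[aa]
        x, y = mat_a[:, i], mat_b[:, i]
        t, df, p = welch_t(x, y)
        rows.append(
            {
                "aa": aa,
                "class": ref.aa_class(aa),
                "rank": ref.rank(aa),
                "maa_a": x.mean(),
                "maa_b": y.mean(),
                "diff": x.mean() - y.mean(),
                "sd_a": x.std(ddof=1),
                "sd_b": y.std(ddof=1),
                "sem_a": x.std(ddof=1) / np.sqrt(len(x)),
                "sem_b": y.std(ddof=1) / np.sqrt(len(y)),
                "t": t,
                "df": df,
                "p": p,
                "stars": significance_stars(p),
                "n_a": len(x),
                "n_b": len(y),
            }
        )
    return pd.DataFrame(rows).set_index("aa")


def collect_observations(subsequences: Iterable[str]) -> list[np.ndarray]:
    """Composition vectors for each region with at least one standard residue."""
    out = []
    for sub in subsequences:
        vec = relative_abundance(sub)
        if vec is not None:
            out.append(vec)
    return out


def preference_summary(
    comparisons: Mapping[str, pd.DataFrame],
    ref: BarophilyReference,
    alpha: float = 0.1,
) -> pd.DataFrame:
    """Preference grid over contexts, with a per-amino-acid consistency flag.

    A cell carries ``B`` when the barophile uses the amino acid significantly
    more (diff > 0, p < alpha), ``N`` when significantly less, else blank.
    An amino acid is flagged consistent when at least 4 contexts carry a
    letter congruent with its barophily class and no context carries an
    incongruent one; indifferent amino acids are never flagged.
    """
    contexts = list(comparisons)
    rows = []
    for aa in ref.table_order():
        cls = ref.aa_class(aa)
        letters = {}
        congruent = incongruent = 0
        for context in contexts:
            comp = comparisons[context]
            letter = ""
            if aa in comp.index and comp.loc[aa, "p"] < alpha:
                letter = "B" if comp.loc[aa, "diff"] > 0 else "N"
            letters[context] = letter
            if letter:
                if letter == cls:
                    congruent += 1
                else:
                    incongruent += 1
        rows.append(
            {
                "aa": aa,
                "class": cls,
                "rank": ref.rank(aa),
                **letters,
                "consistent": congruent >= 4 and incongruent == 0,
            }
        )
    return pd.DataFrame(rows).set_index("aa")
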