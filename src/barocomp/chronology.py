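"""Evolutionary ages of fold superfamilies from a rooted phylogenomic tree.

The age proxy is the node distance nd: for a leaf a of a rooted tree with
root r, the raw distance is the number of internal nodes strictly between r
and a (excluding both endpoints), normalized by the maximum raw distance
over all leaves. The most ancestral leaf (attached directly to the root
lineage) gets nd = 0 and the most derived leaf nd = 1. nd is a pure
topology statistic — branch lengths are ignored.

A linear molecular clock maps nd to geological age in billions of years
(Gy): t = -3.831 * nd + 3.628. Age strata used for stratified comparisons
are "ancient" (nd in [0, 0.2]) and "recent" (nd in [0.6, 1.0]).
"""

from __future__ import annotations

import warnings
from pathlib import Path
from typing import Mapping, Sequence

import dendropy
import pandas as pd

CLOCK_SLOPE = -3.831
CLOCK_INTERCEPT = 3.628

ANCIENT = "ancient"
RECENT = "recent"
NEITHER = "neither"

#: Closed stratum bounds on the nd scale.
ANCIENT_BOUNDS = (0.0, 0.2)
RECENT_BOUNDS = (0.6, 1.0)


class DegenerateTreeError(ValueError):
    """All leaves at equal raw depth: nd is undefined (e.g. a star tree)."""


def load_tree(source: str | Path | dendropy.Tree) -> dendropy.Tree:
    if isinstance(source, dendropy.Tree):
        return source
    source = str(source)
    if source.lstrip().startswith("("):
        return dendropy.Tree.get(
            data=source, schema="newick", preserve_underscores=True
        )
    return dendropy.Tree.get(
        path=source, schema="newick", preserve_underscores=True
    )


def node_distances(tree: str | Path | dendropy.Tree) -> dict[str, float]:
    """Normalized node distance per leaf label.

    Raw distance counts internal nodes strictly between the root and the
    leaf; normalization divides by the maximum raw distance, so a leaf
    attached directly to the root gets 0 and the deepest leaf gets 1.
    """
    tree = load_tree(tree)
    raw: dict[str, int] = {}
    for leaf in tree.leaf_node_iter():
        depth = 0
        node = leaf.parent_node
        while node is not None and node.parent_node is not None:
            depth += 1
            node = node.parent_node
        label = leaf.taxon.label if leaf.taxon is not None else None
        if label is None:
            raise ValueError("unlabeled leaf in tree")
        if label in raw:
            raise ValueError(f"duplicate leaf label {label!r}")
        raw[label] = depth
    if len(raw) < 2:
        raise ValueError("tree must have at least 2 leaves")
    max_raw = max(raw.values())
    if max_raw == 0:
        raise DegenerateTreeError("degenerate tree: nd undefined")
    return {label: depth / max_raw for label, depth in raw.items()}


def clock_age(nd: float) -> float:
    """Geological age in Gy from the linear FSF molecular clock.

    Negative ages (possible for nd close to 1) are returned as-is with a
    warning rather than clamped.
    """
    if not 0.0 <= nd <= 1.0:
        raise ValueError(f"nd out of [0, 1]: {nd}")
    age = CLOCK_SLOPE * nd + CLOCK_INTERCEPT
    if age < 0:
        warnings.warn(
            f"clock age negative ({age:.4f} Gy) at nd={nd:.4f}", stacklevel=2
        )
    return age


def age_bin(nd: float) -> str:
    """Stratum of an nd value: ancient [0, 0.2], recent [0.6, 1], else neither."""
    if not 0.0 <= nd <= 1.0:
        raise ValueError(f"nd out of [0, 1]: {nd}")
    if ANCIENT_BOUNDS[0] <= nd <= ANCIENT_BOUNDS[1]:
        return ANCIENT
    if RECENT_BOUNDS[0] <= nd <= RECENT_BOUNDS[1]:
        return RECENT
    return NEITHER


def build_age_table(tree: str | Path | dendropy.Tree) -> pd.DataFrame:
    """fsf_id-indexed table with columns nd, age_gy, stratum."""
    nds = node_distances(tree)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        rows = [
            {"fsf_id": fsf, "nd": nd, "age_gy": clock_age(nd), "stratum": age_bin(nd)}
            for fsf, nd in sorted(nds.items())
        ]
    return pd.DataFrame(rows).set_index("fsf_id")


def cumulative_accumulation(
    age_table: pd.DataFrame | Mapping[str, float],
    venn: tuple[Sequence[str], Sequence[str], Sequence[str]],
) -> dict[str, pd.DataFrame]:
    """Cumulative FSF counts along nd for the shared / only_a / only_b classes.

    Each class yields a frame with columns nd (ascending distinct values)
    and cumulative (count of class FSFs with nd <= that value). Every FSF
    in the Venn sets must have an nd.
    """
    if isinstance(age_table, pd.DataFrame):
        nd_map = age_table["nd"].to_dict()
    else:
        nd_map = dict(age_table)
    curves = {}
    for name, fsfs in zip(("shared", "only_a", "only_b"), venn):
        missing = sorted(set(fsfs) - set(nd_map))
        if missing:
            raise ValueError(f"FSFs without nd in class {name}: {missing}")
        nds = sorted(nd_map[f] for f in fsfs)
        distinct = sorted(set(nds))
        cumulative = []
        count = 0
        it = iter(nds)
        buffered = next(it, None)
        for x in distinct:
            while buffered is not None and buffered <= x:
                count += 1
                buffered = next(it, None)
            cumulative.append(count)
        curves[name] = pd.DataFrame({"nd": distinct, "cumulative": cumulative})
    return curves
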