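"""End-to-end orchestration: from input files to report tables.

The analysis reproduces, on arbitrary inputs, the comparative design of
the barophile/nonbarophile study: proteome summaries, the FSF repertoire
Venn, per-context MAA comparisons (complete sequences, intervening
regions, shared-FSF and specific-FSF domain regions), the matched-FSF
analysis of homologous pairs (overall and stratified by domain age), the
preference grid with consistency flags, and cumulative domain-accumulation
curves.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd
import yaml

from . import __version__, chronology, composition, homology, regions, repertoire
from .chronology import ANCIENT, RECENT, build_age_table, cumulative_accumulation
from .composition import collect_observations, compare_groups, preference_summary
from .io import (
    BarophilyReference,
    DomainAssignment,
    HomologPair,
    ProteinRecord,
    load_barophily_reference,
    read_domain_assignments,
    read_fasta,
    read_homolog_pairs,
)

#: Report-context labels (keys of AnalysisResult.comparisons).
COMPLETE = "complete"
INTERVENING = "intervening"
SHARED_FSF = "shared_fsf"
SPECIFIC_FSF = "specific_fsf"
HOM_ALL = "homologous_all"
HOM_ANCIENT = "homologous_ancient"
HOM_RECENT = "homologous_recent"

#: Contexts entering the preference grid (in its column order).
SUMMARY_CONTEXTS = (COMPLETE, SHARED_FSF, SPECIFIC_FSF, HOM_ALL, HOM_ANCIENT, HOM_RECENT)

_CONTEXT_TO_REGION = {
    COMPLETE: regions.WHOLE,
    INTERVENING: regions.INTERVENING,
    SHARED_FSF: regions.DOMAIN_SHARED,
    SPECIFIC_FSF: regions.DOMAIN_SPECIFIC,
}


@dataclass
class RunConfig:
    """File-level configuration of one analysis run.

    ``barophile`` names which species label is the barophile; internally
    species A is always the barophile, so inputs are swapped if needed.
    """

    fasta_a: str
    fasta_b: str
    assignments_a: str
    assignments_b: str
    pairs: str
    tree: str | None = None
    age_table: str | None = None
    species_a: str = "barophile"
    species_b: str = "nonbarophile"
    barophile: str | None = None
    alpha: float = 0.1
    seed: int | None = None

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text())
        cfg = cls(**raw)
        if cfg.barophile is not None and cfg.barophile not in (
            cfg.species_a,
            cfg.species_b,
        ):
            raise ValueError(
                f"barophile {cfg.barophile!r} matches neither species label"
            )
        if cfg.barophile == cfg.species_b:  # swap so A is the barophile
            cfg = cls(
                fasta_a=cfg.fasta_b,
                fasta_b=cfg.fasta_a,
                assignments_a=cfg.assignments_b,
                assignments_b=cfg.assignments_a,
                pairs=cfg.pairs,
                tree=cfg.tree,
                age_table=cfg.age_table,
                species_a=cfg.species_b,
                species_b=cfg.species_a,
                barophile=cfg.barophile,
                alpha=cfg.alpha,
                seed=cfg.seed,
            )
        return cfg


@dataclass
class AnalysisResult:
    summaries: dict[str, repertoire.ProteomeSummary]
    venn: tuple[frozenset[str], frozenset[str], frozenset[str]]
    comparisons: dict[str, pd.DataFrame]
    preference: pd.DataFrame
    pair_categories: dict[int, int]
    matched_n_fsfs: int
    curves: dict[str, pd.DataFrame] | None
    counts: dict[str, int]
    messages: list[str] = field(default_factory=list)


def _group_assignments(
    assignments: Sequence[DomainAssignment],
) -> dict[str, list[DomainAssignment]]:
    grouped: dict[str, list[DomainAssignment]] = {}
    for a in assignments:
        grouped.setdefault(a.seq_id, []).append(a)
    return grouped


def analyze(
    records_a: Sequence[ProteinRecord],
    records_b: Sequence[ProteinRecord],
    assignments_a: Sequence[DomainAssignment],
    assignments_b: Sequence[DomainAssignment],
    pairs: Sequence[HomologPair],
    age_table: pd.DataFrame | None = None,
    ref: BarophilyReference | None = None,
    alpha: float = 0.1,
    species_a: str = "barophile",
    species_b: str = "nonbarophile",
) -> AnalysisResult:
    """Run the full comparative analysis on in-memory inputs.

    Species A is the barophile; all differences are A minus B. ``age_table``
    (from :func:`barocomp.chronology.build_age_table`) enables the
    age-stratified matched comparisons and the accumulation curves.
    """
    ref = ref or load_barophily_reference()
    messages: list[str] = []

    rep_a = repertoire.build_repertoire(assignments_a, species_a)
    rep_b = repertoire.build_repertoire(assignments_b, species_b)
    shared, only_a, only_b = repertoire.compare_repertoires(rep_a, rep_b)
    summaries = {
        species_a: repertoire.proteome_summary(
            records_a, assignments_a, species_a, len(only_a)
        ),
        species_b: repertoire.proteome_summary(
            records_b, assignments_b, species_b, len(only_b)
        ),
    }

    grouped_a = _group_assignments(assignments_a)
    grouped_b = _group_assignments(assignments_b)
    obs: dict[str, dict[str, list]] = {c: {} for c in _CONTEXT_TO_REGION}
    for species, records, grouped in (
        (species_a, records_a, grouped_a),
        (species_b, records_b, grouped_b),
    ):
        parts = [
            regions.partition_sequence(r, grouped.get(r.seq_id, []), shared)
            for r in records
        ]
        for context, region_name in _CONTEXT_TO_REGION.items():
            obs[context][species] = collect_observations(
                p.subsequences[region_name] for p in parts
            )

    comparisons: dict[str, pd.DataFrame] = {}
    for context in (COMPLETE, INTERVENING, SHARED_FSF, SPECIFIC_FSF):
        x, y = obs[context][species_a], obs[context][species_b]
        if len(x) >= 2 and len(y) >= 2:
            comparisons[context] = compare_groups(x, y, ref)
        else:
            messages.append(
                f"context {context}: too few observations ({len(x)}, {len(y)}); skipped"
            )

    # homologous pairs
    pair_categories: dict[int, int] = {c: 0 for c in range(1, 6)}
    cat5_pairs = []
    for pair in pairs:
        category = homology.classify_pair(
            grouped_a.get(pair.id_a, []), grouped_b.get(pair.id_b, [])
        )
        pair_categories[category] += 1
        if category == 5 and grouped_a.get(pair.id_a):
            cat5_pairs.append(pair)
    rec_map_a = {r.seq_id: r for r in records_a}
    rec_map_b = {r.seq_id: r for r in records_b}
    observations = homology.matched_fsf_dataset(
        cat5_pairs, rec_map_a, rec_map_b, grouped_a, grouped_b
    )
    matched_n_fsfs = len({o.fsf_id for o in observations})
    if len({o.fsf_id for o in observations}) >= 2:
        comparisons[HOM_ALL] = homology.matched_comparison(observations, ref)
    else:
        messages.append("matched-FSF comparison skipped: fewer than 2 matched FSFs")
    if age_table is not None:
        for context, stratum in ((HOM_ANCIENT, ANCIENT), (HOM_RECENT, RECENT)):
            try:
                comparisons[context] = homology.matched_comparison(
                    observations, ref, age_table=age_table, stratum=stratum
                )
            except ValueError as exc:
                messages.append(f"context {context}: {exc}")

    preference = preference_summary(
        {c: comparisons[c] for c in SUMMARY_CONTEXTS if c in comparisons},
        ref,
        alpha=alpha,
    )

    curves = None
    if age_table is not None:
        try:
            curves = cumulative_accumulation(age_table, (shared, only_a, only_b))
        except ValueError as exc:
            messages.append(f"accumulation curves skipped: {exc}")

    counts = {
        "n_sequences_a": len(records_a),
        "n_sequences_b": len(records_b),
        "n_pairs": len(pairs),
        "n_category5_pairs": len(cat5_pairs),
        "n_matched_fsfs": matched_n_fsfs,
        "n_shared_fsfs": len(shared),
        "n_specific_fsfs_a": len(only_a),
        "n_specific_fsfs_b": len(only_b),
    }
    for context in (COMPLETE, INTERVENING, SHARED_FSF, SPECIFIC_FSF):
        for species in (species_a, species_b):
            counts[f"n_obs_{context}_{species}"] = len(obs[context][species])

    return AnalysisResult(
        summaries=summaries,
        venn=(shared, only_a, only_b),
        comparisons=comparisons,
        preference=preference,
        pair_categories=pair_categories,
        matched_n_fsfs=matched_n_fsfs,
        curves=curves,
        counts=counts,
        messages=messages,
    )


def run_analysis(config: RunConfig, outdir: str | Path) -> AnalysisResult:
    """File-to-file analysis run: read inputs, analyze, write report tables."""
    records_a = read_fasta(config.fasta_a)
    records_b = read_fasta(config.fasta_b)
    assignments_a = read_domain_assignments(config.assignments_a)
    assignments_b = read_domain_assignments(config.assignments_b)
    pairs = read_homolog_pairs(config.pairs)
    age_table = None
    if config.age_table is not None:
        age_table = pd.read_csv(config.age_table, sep="\t").set_index("fsf_id")
        if "stratum" not in age_table.columns:
            age_table["stratum"] = age_table["nd"].map(chronology.age_bin)
    elif config.tree is not None:
        age_table = build_age_table(config.tree)
    result = analyze(
        records_a,
        records_b,
        assignments_a,
        assignments_b,
        pairs,
        age_table=age_table,
        alpha=config.alpha,
        species_a=config.species_a,
        species_b=config.species_b,
    )
    write_report(result, outdir, config=config)
    return result


def write_report(
    result: AnalysisResult, outdir: str | Path, config: RunConfig | None = None
) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for context, comp in result.comparisons.items():
        comp.to_csv(outdir / f"comparison_{context}.tsv", sep="\t")
    result.preference.to_csv(outdir / "preference_summary.tsv", sep="\t")
    pd.DataFrame(
        [
            {"species": s.species, **{k: v for k, v in vars(s).items() if k != "species"}}
            for s in result.summaries.values()
        ]
    ).to_csv(outdir / "proteome_summary.tsv", sep="\t", index=False)
    shared, only_a, only_b = result.venn
    pd.DataFrame(
        [("shared", f) for f in sorted(shared)]
        + [("only_a", f) for f in sorted(only_a)]
        + [("only_b", f) for f in sorted(only_b)],
        columns=["class", "fsf_id"],
    ).to_csv(outdir / "venn_fsf.tsv", sep="\t", index=False)
    pd.DataFrame(
        sorted(result.pair_categories.items()), columns=["category", "n_pairs"]
    ).to_csv(outdir / "pair_categories.tsv", sep="\t", index=False)
    if result.curves is not None:
        for name, curve in result.curves.items():
            curve.to_csv(outdir / f"accumulation_{name}.tsv", sep="\t", index=False)
    manifest = {
        "barocomp_version": __version__,
        "counts": result.counts,
        "messages": result.messages,
        "alpha": config.alpha if config else None,
        "seed": config.seed if config else None,
        "inputs": {
            k: getattr(config, k)
            for k in (
                "fasta_a",
                "fasta_b",
                "assignments_a",
                "assignments_b",
                "pairs",
                "tree",
                "age_table",
            )
        }
        if config
        else None,
    }
    (outdir / "run_manifest.yaml").write_text(yaml.safe_dump(manifest, sort_keys=False))
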