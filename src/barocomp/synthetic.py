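"""Synthetic proteome pairs with planted barophily biases.

The generator emits exactly the inputs the pipeline consumes — two proteome
FASTAs, two domain-assignment tables, a homolog-pair table and a rooted
FSF tree — together with a truth record, so that every analysis stage can
be checked by parameter recovery.

The planted model mirrors the statistical structure the pipeline is meant
to detect. Residues inside domain regions are drawn i.i.d. from a tilted
background: in the barophile, class-B amino acids have probability
proportional to p(aa)*(1+delta_eff) and class-N to p(aa)*(1-delta_eff);
the nonbarophile mirrors the tilt; indifferent amino acids and all
intervening-region residues are untilted. delta_eff is the global bias
delta scaled by a per-stratum multiplier of the domain's FSF age
(ancient / neither / recent), which lets biases be confined to, or erased
in, an age stratum. Homolog pairs are generated mostly with identical
domain architectures (category 5) with small configurable rates of the
degenerate categories 1-4.

No positional or phylogenetic autocorrelation is simulated: the analysis
consumes composition only, so i.i.d. sampling is sufficient for testing.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Sequence

import dendropy
import numpy as np
import pandas as pd
import yaml

from . import chronology
from .chronology import ANCIENT, NEITHER, RECENT, build_age_table
from .io import (
    AMINO_ACIDS,
    BarophilyReference,
    DomainAssignment,
    HomologPair,
    ProteinRecord,
    load_barophily_reference,
    write_domain_assignments,
    write_fasta,
    write_homolog_pairs,
)

_AA_ARRAY = np.array(list(AMINO_ACIDS))


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for one simulated proteome pair.

    Lengths are (mean, sd, minimum) of truncated normals in residues.
    ``category_rates`` are the probabilities of planting homolog-pair
    categories 1-4 (the remainder is category 5, identical architectures).
    """

    n_pairs: int = 300
    n_unpaired: int = 40
    n_fsf: int = 60
    shared_fraction: float = 0.8
    domain_length: tuple[float, float, int] = (200.0, 40.0, 30)
    intervening_length: tuple[float, float, int] = (50.0, 20.0, 5)
    background: tuple[float, ...] | None = None  # AMINO_ACIDS order; uniform if None
    delta: float = 0.2
    bias_by_stratum: Mapping[str, float] = field(
        default_factory=lambda: {ANCIENT: 1.0, NEITHER: 1.0, RECENT: 1.0}
    )
    category_rates: Mapping[int, float] = field(
        default_factory=lambda: {1: 0.02, 2: 0.02, 3: 0.02, 4: 0.02}
    )
    p_two_domains: float = 0.3
    p_repeat: float = 0.1
    p_specific_unpaired: float = 0.5
    species_a: str = "BARO"
    species_b: str = "NONB"
    seed: int = 0

    def background_array(self) -> np.ndarray:
        if self.background is None:
            return np.full(len(AMINO_ACIDS), 1.0 / len(AMINO_ACIDS))
        arr = np.asarray(self.background, dtype=float)
        if arr.shape != (len(AMINO_ACIDS),) or not np.isclose(arr.sum(), 1.0):
            raise ValueError("background must be 20 frequencies summing to 1")
        return arr

    def __post_init__(self) -> None:
        if not 0.0 <= self.delta < 1.0:
            raise ValueError("delta must be in [0, 1)")
        if not 0.0 <= self.shared_fraction <= 1.0:
            raise ValueError("shared_fraction must be in [0, 1]")
        if sum(self.category_rates.values()) >= 1.0:
            raise ValueError("category rates 1-4 must sum to < 1")
        self.background_array()


@dataclass
class SimBundle:
    """Everything one simulation run produces, plus the planted truth."""

    config: SimConfig
    tree_newick: str
    age_table: pd.DataFrame
    records_a: list[ProteinRecord]
    records_b: list[ProteinRecord]
    assignments_a: list[DomainAssignment]
    assignments_b: list[DomainAssignment]
    pairs: list[HomologPair]
    planted_categories: list[int]
    fsf_truth: pd.DataFrame  # per FSF: pool, nd, stratum, delta_eff
    truth: pd.DataFrame  # per aa x context: expected MAA difference

    @property
    def shared_pool(self) -> frozenset[str]:
        return frozenset(self.fsf_truth.index[self.fsf_truth["pool"] == "shared"])


def simulate_tree(n_fsf: int, seed: int, imbalance: float = 0.75) -> str:
    """Random rooted binary tree over fsf_0..fsf_{n-1}, as a Newick string.

    Grown by sequential leaf splitting. With probability ``imbalance`` the
    most recently added leaf is split (caterpillar-like growth), otherwise
    a uniformly chosen leaf; real phylogenomic trees of domain structures
    are highly unbalanced, which spreads leaf depths across the whole nd
    range. The first leaf (a direct child of the root) is never split, so
    every tree retains a most-ancestral lineage with zero internal nodes
    between root and leaf — the basal structure of the timeline.
    """
    if n_fsf < 2:
        raise ValueError("need at least 2 leaves")
    rng = np.random.default_rng(seed)
    tree = dendropy.Tree()
    root = tree.seed_node
    leaves = [root.new_child(), root.new_child()]
    while len(leaves) < n_fsf:
        if rng.random() < imbalance:
            idx = len(leaves) - 1
        else:
            idx = int(rng.integers(1, len(leaves)))  # leaf 0 is protected
        node = leaves[idx]
        left, right = node.new_child(), node.new_child()
        leaves[idx] = left
        leaves.append(right)
    for i, leaf in enumerate(leaves):
        leaf.taxon = tree.taxon_namespace.new_taxon(label=f"fsf_{i}")
    return tree.as_string(
        schema="newick", suppress_rooting=True, unquoted_underscores=True
    ).strip()


def class_signs(ref: BarophilyReference) -> np.ndarray:
    """+1 for class-B, -1 for class-N, 0 for indifferent, in AMINO_ACIDS order."""
    return np.array(
        [
            {"B": 1.0, "N": -1.0, "I": 0.0}[ref.aa_class(aa)]
            for aa in AMINO_ACIDS
        ]
    )


def tilted_frequencies(
    background: np.ndarray, delta_eff: float, signs: np.ndarray, barophile: bool
) -> np.ndarray:
    direction = 1.0 if barophile else -1.0
    weights = background * (1.0 + direction * delta_eff * signs)
    return weights / weights.sum()


def expected_maa_difference(
    config: SimConfig,
    aa: str,
    context: str,
    ref: BarophilyReference | None = None,
) -> float:
    """Analytic expected barophile-minus-nonbarophile abundance difference.

    ``context`` is one of domain / shared / specific (full bias), the age
    strata ancient / neither / recent (bias scaled by the stratum
    multiplier), or intervening (no bias). Zero for indifferent amino
    acids and whenever the effective bias is zero.
    """
    ref = ref or load_barophily_reference()
    if context == "intervening":
        multiplier = 0.0
    elif context in (ANCIENT, NEITHER, RECENT):
        multiplier = float(config.bias_by_stratum.get(context, 1.0))
    elif context in ("domain", "shared", "specific"):
        multiplier = 1.0
    else:
        raise ValueError(f"unknown context {context!r}")
    delta_eff = config.delta * multiplier
    signs = class_signs(ref)
    p = config.background_array()
    s = signs[AMINO_ACIDS.index(aa)]
    if s == 0.0 or delta_eff == 0.0:
        return 0.0
    mass_gap = float(p @ signs)  # P_B - P_N
    z_a = 1.0 + delta_eff * mass_gap
    z_b = 1.0 - delta_eff * mass_gap
    p_aa = p[AMINO_ACIDS.index(aa)]
    return float(p_aa * ((1 + s * delta_eff) / z_a - (1 - s * delta_eff) / z_b))


def _draw_length(rng: np.random.Generator, spec: tuple[float, float, int]) -> int:
    mean, sd, minimum = spec
    return max(int(minimum), int(round(rng.normal(mean, sd))))


def _draw_residues(rng: np.random.Generator, n: int, freqs: np.ndarray) -> str:
    return "".join(_AA_ARRAY[rng.choice(len(_AA_ARRAY), size=n, p=freqs)])


class _SequenceBuilder:
    """Assemble one sequence as alternating intervening/domain segments."""

    def __init__(self, rng, config, seq_id, barophile, signs, delta_by_fsf):
        self.rng = rng
        self.config = config
        self.seq_id = seq_id
        self.barophile = barophile
        self.signs = signs
        self.delta_by_fsf = delta_by_fsf
        self.background = config.background_array()
        self.parts: list[str] = []
        self.pos = 0
        self.assignments: list[DomainAssignment] = []
        self._intervening()

    def _intervening(self) -> None:
        n = _draw_length(self.rng, self.config.intervening_length)
        self.parts.append(_draw_residues(self.rng, n, self.background))
        self.pos += n

    def add_domain(self, fsf_id: str) -> None:
        n = _draw_length(self.rng, self.config.domain_length)
        freqs = tilted_frequencies(
            self.background, self.delta_by_fsf[fsf_id], self.signs, self.barophile
        )
        self.parts.append(_draw_residues(self.rng, n, freqs))
        self.assignments.append(
            DomainAssignment(self.seq_id, fsf_id, ((self.pos, self.pos + n),))
        )
        self.pos += n
        self._intervening()

    def finish(self, record_assignments: bool = True):
        record = ProteinRecord(self.seq_id, "".join(self.parts))
        return record, (self.assignments if record_assignments else [])


def simulate_proteome_pair(config: SimConfig) -> SimBundle:
    """Generate a full synthetic bundle under the planted-bias model."""
    ref = load_barophily_reference()
    signs = class_signs(ref)
    rng = np.random.default_rng(config.seed)
    tree_newick = simulate_tree(config.n_fsf, int(rng.integers(2**31)))
    age_table = build_age_table(tree_newick)

    fsf_ids = [f"fsf_{i}" for i in range(config.n_fsf)]
    order = [fsf_ids[i] for i in rng.permutation(config.n_fsf)]
    n_shared = int(round(config.n_fsf * config.shared_fraction))
    shared = order[:n_shared]
    rest = order[n_shared:]
    specific_a = rest[: len(rest) // 2]
    specific_b = rest[len(rest) // 2 :]
    pool_of = {f: "shared" for f in shared}
    pool_of.update({f: "specific_a" for f in specific_a})
    pool_of.update({f: "specific_b" for f in specific_b})

    delta_by_fsf = {
        f: config.delta
        * float(config.bias_by_stratum.get(age_table.loc[f, "stratum"], 1.0))
        for f in fsf_ids
    }

    categories = list(config.category_rates)
    cat_probs = [config.category_rates[c] for c in categories]
    cat_probs.append(1.0 - sum(cat_probs))
    categories.append(5)

    records_a, records_b = [], []
    assignments_a, assignments_b = [], []
    pairs, planted = [], []

    def pick(pool: Sequence[str], fallback: Sequence[str]) -> str:
        src = pool if pool else fallback
        return src[int(rng.integers(len(src)))]

    for i in range(config.n_pairs):
        id_a = f"{config.species_a}_{i:05d}"
        id_b = f"{config.species_b}_{i:05d}"
        category = int(rng.choice(categories, p=cat_probs))
        base = [pick(shared, fsf_ids)]
        if rng.random() < config.p_two_domains:
            base.append(
                base[0] if rng.random() < config.p_repeat else pick(shared, fsf_ids)
            )
        arch_a, arch_b = list(base), list(base)
        drop_a = drop_b = False
        if category == 1:
            arch_a, arch_b = [], []
        elif category == 2:
            if rng.random() < 0.5:
                arch_a = []
            else:
                arch_b = []
        elif category == 3:
            if rng.random() < 0.5:
                arch_a.append(pick(specific_a, shared))
            else:
                arch_b.append(pick(specific_b, shared))
        elif category == 4:
            arch_a = [pick(specific_a, shared)]
            arch_b = [pick(specific_b, [f for f in shared if f not in arch_a])]

        for arch, seq_id, barophile, records, assignments in (
            (arch_a, id_a, True, records_a, assignments_a),
            (arch_b, id_b, False, records_b, assignments_b),
        ):
            builder = _SequenceBuilder(
                rng, config, seq_id, barophile, signs, delta_by_fsf
            )
            for fsf in arch:
                builder.add_domain(fsf)
            record, asg = builder.finish()
            records.append(record)
            assignments.extend(asg)
        pairs.append(HomologPair(id_a, id_b))
        planted.append(category)

    for species, barophile, pool, records, assignments in (
        (config.species_a, True, specific_a, records_a, assignments_a),
        (config.species_b, False, specific_b, records_b, assignments_b),
    ):
        for j in range(config.n_unpaired):
            seq_id = f"{species}_U{j:05d}"
            builder = _SequenceBuilder(
                rng, config, seq_id, barophile, signs, delta_by_fsf
            )
            n_dom = 1 + int(rng.random() < config.p_two_domains)
            for _ in range(n_dom):
                use_specific = rng.random() < config.p_specific_unpaired
                builder.add_domain(pick(pool if use_specific else shared, shared))
            record, asg = builder.finish()
            records.append(record)
            assignments.extend(asg)

    fsf_truth = pd.DataFrame(
        {
            "fsf_id": fsf_ids,
            "pool": [pool_of[f] for f in fsf_ids],
            "nd": [age_table.loc[f, "nd"] for f in fsf_ids],
            "stratum": [age_table.loc[f, "stratum"] for f in fsf_ids],
            "delta_eff": [delta_by_fsf[f] for f in fsf_ids],
        }
    ).set_index("fsf_id")

    contexts = ("domain", "shared", "specific", "intervening", ANCIENT, NEITHER, RECENT)
    truth = pd.DataFrame(
        [
            {
                "aa": aa,
                "context": ctx,
                "expected_diff": expected_maa_difference(config, aa, ctx, ref),
            }
            for aa in AMINO_ACIDS
            for ctx in contexts
        ]
    )

    return SimBundle(
        config=config,
        tree_newick=tree_newick,
        age_table=age_table,
        records_a=records_a,
        records_b=records_b,
        assignments_a=assignments_a,
        assignments_b=assignments_b,
        pairs=pairs,
        planted_categories=planted,
        fsf_truth=fsf_truth,
        truth=truth,
    )


def write_bundle(bundle: SimBundle, outdir: str | Path) -> dict[str, Path]:
    """Write a bundle in exactly the formats the pipeline reads."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "fasta_a": outdir / "proteome_a.fasta",
        "fasta_b": outdir / "proteome_b.fasta",
        "assignments_a": outdir / "assignments_a.tsv",
        "assignments_b": outdir / "assignments_b.tsv",
        "pairs": outdir / "homolog_pairs.tsv",
        "tree": outdir / "fsf_tree.nwk",
        "age_table": outdir / "fsf_ages.tsv",
        "fsf_truth": outdir / "truth_fsf.tsv",
        "truth": outdir / "truth_expected_diff.tsv",
        "config": outdir / "sim_config.yaml",
    }
    write_fasta(bundle.records_a, paths["fasta_a"])
    write_fasta(bundle.records_b, paths["fasta_b"])
    write_domain_assignments(bundle.assignments_a, paths["assignments_a"])
    write_domain_assignments(bundle.assignments_b, paths["assignments_b"])
    write_homolog_pairs(bundle.pairs, paths["pairs"])
    paths["tree"].write_text(bundle.tree_newick + "\n")
    bundle.age_table.to_csv(paths["age_table"], sep="\t")
    bundle.fsf_truth.to_csv(paths["fsf_truth"], sep="\t")
    bundle.truth.to_csv(paths["truth"], sep="\t", index=False)
    cfg = asdict(bundle.config)
    cfg["bias_by_stratum"] = dict(cfg["bias_by_stratum"])
    cfg["category_rates"] = {int(k): v for k, v in cfg["category_rates"].items()}
    cfg["domain_length"] = list(cfg["domain_length"])
    cfg["intervening_length"] = list(cfg["intervening_length"])
    paths["config"].write_text(yaml.safe_dump(cfg, sort_keys=True))
    return paths
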