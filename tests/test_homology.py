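import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from barocomp.composition import AA_INDEX
from barocomp.homology import (
    classify_pair,
    matched_comparison,
    matched_fsf_dataset,
    per_fsf_means,
    per_sequence_fsf_composition,
)
from barocomp.io import DomainAssignment, HomologPair, ProteinRecord


def _asg(seq_id, fsf, *intervals):
    return DomainAssignment(seq_id, fsf, tuple(intervals))


def _multiset_assignments(seq_id, fsf_ids):
    out = []
    pos = 0
    for fsf in fsf_ids:
        out.append(_asg(seq_id, fsf, (pos, pos + 5)))
        pos += 5
    return out


class TestClassifyPair:
    @pytest.mark.parametrize(
        "fsfs_a,fsfs_b,category",
        [
            ([], [], 1),
            (["x"], [], 2),
            ([], ["x"], 2),
            (["x", "y"], ["x"], 3),
            (["x", "x"], ["x"], 3),  # extra repeat counts as extra assignment
            (["x"], ["y"], 4),
            (["x", "y"], ["x", "z"], 4),
            (["x"], ["x"], 5),
            (["x", "y", "x"], ["y", "x", "x"], 5),  # multiset, order-free
        ],
    )
    def test_categories(self, fsfs_a, fsfs_b, category):
        a = _multiset_assignments("a", fsfs_a)
        b = _multiset_assignments("b", fsfs_b)
        assert classify_pair(a, b) == category
        assert classify_pair(b, a) == category  # symmetric in category

    @settings(max_examples=100, derandomize=True, deadline=None)
    @given(
        st.lists(st.sampled_from("xyz"), max_size=4),
        st.lists(st.sampled_from("xyz"), max_size=4),
    )
    def test_exactly_one_category_and_symmetry(self, fsfs_a, fsfs_b):
        a = _multiset_assignments("a", fsfs_a)
        b = _multiset_assignments("b", fsfs_b)
        category = classify_pair(a, b)
        assert category in {1, 2, 3, 4, 5}
        assert classify_pair(b, a) == category


class TestRepeatAveraging:
    def test_two_repeats_averaged(self):
        rec = ProteinRecord("s1", "RRRD")
        comp = per_sequence_fsf_composition(
            rec, [_asg("s1", "x", (0, 2)), _asg("s1", "x", (2, 4))]
        )
        assert comp[AA_INDEX["R"]] == pytest.approx(0.75)
        assert comp[AA_INDEX["D"]] == pytest.approx(0.25)

    def test_single_repeat_identity(self):
        rec = ProteinRecord("s1", "RKDD")
        comp = per_sequence_fsf_composition(rec, [_asg("s1", "x", (0, 4))])
        assert comp[AA_INDEX["D"]] == pytest.approx(0.5)

    def test_averaging_is_not_pooling(self):
        # repeats "R" and "DD": averaged R = 0.5, pooled would be 1/3
        rec = ProteinRecord("s1", "RDD")
        comp = per_sequence_fsf_composition(
            rec, [_asg("s1", "x", (0, 1)), _asg("s1", "x", (1, 3))]
        )
        assert comp[AA_INDEX["R"]] == pytest.approx(0.5)
        assert comp[AA_INDEX["R"]] != pytest.approx(1 / 3)

    def test_all_ambiguous_repeat_dropped(self):
        rec = ProteinRecord("s1", "XXRD")
        comp = per_sequence_fsf_composition(
            rec, [_asg("s1", "x", (0, 2)), _asg("s1", "x", (2, 4))]
        )
        assert comp[AA_INDEX["R"]] == pytest.approx(0.5)

    def test_mixed_fsfs_is_error(self):
        rec = ProteinRecord("s1", "RRRD")
        with pytest.raises(ValueError, match="multiple FSFs"):
            per_sequence_fsf_composition(
                rec, [_asg("s1", "x", (0, 2)), _asg("s1", "y", (2, 4))]
            )


def _pair_data(architectures):
    """Build records/assignments for category-5 pairs given per-pair FSF lists."""
    records_a, records_b, asg_a, asg_b, pairs = {}, {}, {}, {}, []
    for i, fsfs in enumerate(architectures):
        id_a, id_b = f"a{i}", f"b{i}"
        n = max(5 * len(fsfs), 5)
        # rotate per pair so compositions vary across pairs/FSFs
        base_a = "RKDGSAW"[i % 7 :] + "RKDGSAW"[: i % 7]
        base_b = "NKPITQW"[i % 7 :] + "NKPITQW"[: i % 7]
        records_a[id_a] = ProteinRecord(id_a, base_a * n)
        records_b[id_b] = ProteinRecord(id_b, base_b * n)
        asg_a[id_a] = _multiset_assignments(id_a, fsfs)
        asg_b[id_b] = _multiset_assignments(id_b, fsfs)
        pairs.append(HomologPair(id_a, id_b))
    return pairs, records_a, records_b, asg_a, asg_b


class TestMatchedDataset:
    @pytest.mark.parametrize(
        "architectures,n_obs,n_distinct",
        [
            ([["x"]], 1, 1),
            ([["x"], ["x"]], 2, 1),
            ([["x", "y"]], 2, 2),
            ([["x", "x"]], 1, 1),  # repeats collapse to one observation
        ],
    )
    def test_observation_counts(self, architectures, n_obs, n_distinct):
        data = _pair_data(architectures)
        observations = matched_fsf_dataset(*data)
        assert len(observations) == n_obs
        assert len({o.fsf_id for o in observations}) == n_distinct

    def test_non_category5_pair_is_error(self):
        pairs, ra, rb, aa, ab = _pair_data([["x"]])
        ab["b0"] = []  # make it category 2
        with pytest.raises(ValueError, match="category 5"):
            matched_fsf_dataset(pairs, ra, rb, aa, ab)

    def test_diff_is_comp_difference(self):
        observations = matched_fsf_dataset(*_pair_data([["x"]]))
        obs = observations[0]
        assert np.allclose(obs.diff, obs.comp_a - obs.comp_b)
        assert np.all(np.abs(obs.diff) <= 1.0)


class TestMatchedComparison:
    def test_per_fsf_averaging_over_pairs(self):
        observations = matched_fsf_dataset(*_pair_data([["x"], ["x"], ["y"]]))
        fsf_ids, means_a, means_b = per_fsf_means(observations)
        assert fsf_ids == ["x", "y"]
        assert len(means_a) == 2

    def test_antisymmetry_under_species_swap(self, ref, small_bundle):
        from barocomp.homology import MatchedFSFObservation

        b = small_bundle
        grouped_a, grouped_b = {}, {}
        for a in b.assignments_a:
            grouped_a.setdefault(a.seq_id, []).append(a)
        for a in b.assignments_b:
            grouped_b.setdefault(a.seq_id, []).append(a)
        cat5 = [
            p
            for p in b.pairs
            if classify_pair(grouped_a.get(p.id_a, []), grouped_b.get(p.id_b, []))
            == 5
            and grouped_a.get(p.id_a)
        ]
        rec_a = {r.seq_id: r for r in b.records_a}
        rec_b = {r.seq_id: r for r in b.records_b}
        observations = matched_fsf_dataset(cat5, rec_a, rec_b, grouped_a, grouped_b)
        swapped = [
            MatchedFSFObservation(o.fsf_id, o.id_b, o.id_a, o.comp_b, o.comp_a)
            for o in observations
        ]
        fwd = matched_comparison(observations, ref)
        rev = matched_comparison(swapped, ref)
        assert np.allclose(fwd["diff"], -rev["diff"])
        assert np.allclose(fwd["p"], rev["p"])

    def test_empty_stratum_is_error(self, ref, small_bundle):
        import pandas as pd

        observations = matched_fsf_dataset(*_pair_data([["x"], ["y"]]))
        age = pd.DataFrame(
            {"fsf_id": ["x", "y"], "nd": [0.5, 0.5], "stratum": ["neither"] * 2}
        ).set_index("fsf_id")
        with pytest.raises(ValueError, match="stratum"):
            matched_comparison(observations, ref, age_table=age, stratum="ancient")

    def test_paired_test_agrees_in_sign(self, ref):
        observations = matched_fsf_dataset(*_pair_data([["x"], ["y"], ["z"]]))
        welch = matched_comparison(observations, ref, test="welch")
        paired = matched_comparison(observations, ref, test="paired")
        assert np.allclose(welch["diff"], paired["diff"])
        meaningful = welch["diff"].abs() > 1e-9
        assert (
            np.sign(welch.loc[meaningful, "t"])
            == np.sign(paired.loc[meaningful, "t"])
        ).all()
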