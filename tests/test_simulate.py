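import math

import numpy as np
import pytest

from lshclust.align import ClusterCriteria, PairAligner
from lshclust.alphabet import SequenceRecord
from lshclust.graph import Clustering
from lshclust.simulate import (
    FamilySpec,
    clustered_fraction_curve,
    generate_families,
    inter_representative_identities,
    nn_identity_oracle,
    substitution_rate_for_identity,
    truth_recall_precision,
)


class TestGenerator:
    def test_zero_substitution_rate_gives_identical_members(self):
        records, truth = generate_families(
            FamilySpec(n_families=2, members_per_family=3,
                       target_identity=1.0, n_singletons=0, seed=1)
        )
        by_fam = {}
        for r in records:
            by_fam.setdefault(truth[r.id], set()).add(r.residues)
        assert all(len(seqs) == 1 for seqs in by_fam.values())

    def test_same_seed_reproduces_identical_records(self):
        spec = FamilySpec(seed=9)
        assert generate_families(spec) == generate_families(spec)

    def test_truth_is_total_and_singletons_unique(self):
        records, truth = generate_families(
            FamilySpec(n_families=2, members_per_family=3, n_singletons=4,
                       seed=2)
        )
        assert set(truth) == {r.id for r in records}
        singleton_labels = [v for v in truth.values() if v.startswith("U_")]
        assert len(singleton_labels) == len(set(singleton_labels)) == 4

    def test_lengths_respect_bounds(self):
        records, _ = generate_families(FamilySpec(seed=3))
        assert all(150 <= r.length <= 400 for r in records)

    def test_calibration_tracks_target_identity(self):
        """Realized mean within-family identity is within +-0.03 of the
        target at length >= 300 (law of large numbers)."""
        spec = FamilySpec(
            n_families=1, members_per_family=12, target_identity=0.9,
            length_mean=300, length_sd=0, length_min=300, length_max=300,
            n_singletons=0, seed=4,
        )
        records, _ = generate_families(spec)
        aligner = PairAligner(ClusterCriteria(0.3, 0.8))
        idents = [
            aligner.align(a, b).identity
            for i, a in enumerate(records)
            for b in records[i + 1 :]
        ]
        assert abs(float(np.mean(idents)) - 0.9) <= 0.03

    def test_indels_change_lengths_but_keep_homology(self):
        spec = FamilySpec(
            n_families=1, members_per_family=4, target_identity=0.95,
            indel_rate=0.02, n_singletons=0, seed=5,
        )
        records, _ = generate_families(spec)
        assert len({r.length for r in records}) > 1
        aligner = PairAligner(ClusterCriteria(0.5, 0.8))
        assert aligner.align(records[0], records[1]).accepted

    def test_infeasible_spec_rejected(self):
        with pytest.raises(ValueError):
            FamilySpec(target_identity=0.0)
        with pytest.raises(ValueError):
            FamilySpec(length_min=0)


class TestSubstitutionRate:
    @pytest.mark.parametrize("target", [0.5, 0.7, 0.9, 0.95, 1.0])
    def test_rate_solves_two_copy_identity_equation(self, target):
        p = substitution_rate_for_identity(target)
        assert 0.0 <= p < 1.0
        assert (1 - p) ** 2 + p**2 / 19 == pytest.approx(target)


class TestNNOracle:
    def test_identical_pair_has_nn_identity_one(self):
        seq = "MKVLATTPESGQWLRD" * 5
        nn, table = nn_identity_oracle(
            [SequenceRecord("a", seq), SequenceRecord("b", seq)]
        )
        assert nn == {"a": 1.0, "b": 1.0}
        assert len(table) == 1

    def test_single_sequence_nn_undefined(self):
        nn, _ = nn_identity_oracle([SequenceRecord("a", "MKVLA" * 10)])
        assert math.isnan(nn["a"])

    def test_planted_pair_found_among_singletons(self):
        records, _ = generate_families(
            FamilySpec(n_families=0, n_singletons=10, seed=6)
        )
        # plant a pair at hand-built identity 0.9 (one substitution per 10)
        base = records[0].residues
        mutated = list(base)
        for i in range(0, len(mutated) - 9, 10):
            mutated[i] = "W" if mutated[i] != "W" else "Y"
        planted = SequenceRecord("planted", "".join(mutated))
        nn, _ = nn_identity_oracle(records + [planted])
        assert nn["planted"] == pytest.approx(0.9, abs=0.02)
        assert nn[records[0].id] == pytest.approx(nn["planted"], abs=1e-9)

    def test_scale_guard(self):
        records = [SequenceRecord(f"s{i}", "MKVLA") for i in range(11)]
        with pytest.raises(ValueError, match="guard"):
            nn_identity_oracle(records, max_n=10)


class TestCurve:
    def _nn(self, values):
        return dict(values)

    def test_all_singletons_give_zero_fraction(self):
        clustering = Clustering({"a": "a", "b": "b"})
        nn = {"a": 0.95, "b": 0.5}
        curve = clustered_fraction_curve(clustering, nn)
        populated = curve.dropna(subset=["fraction"])
        assert (populated["fraction"] == 0.0).all()

    def test_single_cluster_gives_unit_fraction(self):
        clustering = Clustering({"a": "a", "b": "a", "c": "a"})
        nn = {"a": 0.95, "b": 0.6, "c": 0.33}
        curve = clustered_fraction_curve(clustering, nn)
        populated = curve.dropna(subset=["fraction"])
        assert (populated["fraction"] == 1.0).all()
        assert populated["n"].sum() == 3

    def test_id_mismatch_rejected(self):
        with pytest.raises(ValueError):
            clustered_fraction_curve(Clustering({"a": "a"}), {"b": 0.5})


class TestInterRepresentative:
    def test_single_representative_flagged_empty(self):
        idents, frac = inter_representative_identities(
            Clustering({"a": "a", "b": "a"}),
            {"a": SequenceRecord("a", "MKVLA"), "b": SequenceRecord("b", "MKVLA")},
        )
        assert idents.size == 0 and math.isnan(frac)

    def test_duplicate_sequences_in_distinct_clusters_detected(self):
        seq = "MKVLATTPESGQWLRD" * 5
        records = {
            "a": SequenceRecord("a", seq),
            "b": SequenceRecord("b", seq),
        }
        clustering = Clustering({"a": "a", "b": "b"},
                                criteria=ClusterCriteria(0.9, 0.8))
        idents, frac = inter_representative_identities(clustering, records)
        assert idents.max() == 1.0 and frac == 1.0


class TestRecallPrecision:
    def test_perfect_clustering(self):
        truth = {"a": "F", "b": "F", "c": "G", "d": "G"}
        clustering = Clustering({"a": "a", "b": "a", "c": "c", "d": "c"})
        assert truth_recall_precision(clustering, truth) == (1.0, 1.0)

    def test_all_singletons(self):
        truth = {"a": "F", "b": "F"}
        clustering = Clustering({"a": "a", "b": "b"})
        recall, precision = truth_recall_precision(clustering, truth)
        assert recall == 0.0 and math.isnan(precision)

    def test_merged_families_closed_form_precision(self):
        # one super-cluster over two families of size m: recall 1,
        # precision = 2*C(m,2)/C(2m,2)
        m = 4
        truth = {f"x{i}": "F" for i in range(m)}
        truth.update({f"y{i}": "G" for i in range(m)})
        clustering = Clustering({sid: "x0" for sid in truth})
        recall, precision = truth_recall_precision(clustering, truth)
        expected = 2 * math.comb(m, 2) / math.comb(2 * m, 2)
        assert recall == 1.0
        assert precision == pytest.approx(expected)
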