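"""Within/between scores, motif classification, null filling, histograms."""

import numpy as np
import pytest

from dtipair import (
    InteractionNetwork,
    Motif,
    ValidationError,
    classify_motif,
    drug_view_scores,
    feature_matrix,
    pair_feature,
    score_histograms,
    target_view_scores,
)
from dtipair.features import HISTOGRAM_EDGES, PairFeature

from conftest import random_network, random_similarity


def brute_scores(A, S, anchor_axis, query, anchor, exclude_pair):
    """Enumerate interacting / non-interacting sets explicitly and take maxima.

    anchor_axis 0: anchor is a drug (row), query a target (target view).
    anchor_axis 1: anchor is a target (column), query a drug (drug view).
    """
    profile = A[anchor] if anchor_axis == 0 else A[:, anchor]
    inter = [i for i in range(len(profile)) if profile[i] == 1]
    if exclude_pair:
        inter = [i for i in inter if i != query]
    comp = [i for i in range(len(profile)) if profile[i] == 0 and i != query]
    within = max((S[query, i] for i in inter), default=None)
    between = max((S[query, i] for i in comp), default=None)
    return within, between


class TestViewScores:
    def test_target_view_hand_example(self):
        # d0 -> {t0, t1}; query t2 with St(t2,t0)=0.4, St(t2,t1)=0.7
        A = np.array([[1, 1, 0]])
        net = InteractionNetwork(["d0"], ["t0", "t1", "t2"], A)
        St = np.array([[1, 0.2, 0.4], [0.2, 1, 0.7], [0.4, 0.7, 1]])
        ctw, ctb = target_view_scores(net, St, 2, 0)
        assert ctw == pytest.approx(0.7)
        assert ctb is None  # only non-interacting target is t2 itself

    def test_drug_view_hand_example(self):
        # t0 drugs {d0, d1}; query d2 with Sd(d2,d0)=0.9, Sd(d2,d1)=0.1
        A = np.array([[1], [1], [0]])
        net = InteractionNetwork(["d0", "d1", "d2"], ["t0"], A)
        Sd = np.array([[1, 0.3, 0.9], [0.3, 1, 0.1], [0.9, 0.1, 1]])
        cdw, cdb = drug_view_scores(net, Sd, 2, 0)
        assert cdw == pytest.approx(0.9)
        assert cdb is None

    def test_between_null_when_drug_covers_all_other_targets(self):
        A = np.array([[1, 1, 1, 0]])
        net = InteractionNetwork(["d0"], list("wxyz"), A)
        St = np.full((4, 4), 0.5)
        np.fill_diagonal(St, 1.0)
        ctw, ctb = target_view_scores(net, St, 3, 0)
        assert ctw == 0.5 and ctb is None

    def test_exclusion_of_sole_interaction_gives_null_within(self):
        A = np.array([[0, 0, 0, 1]])
        net = InteractionNetwork(["d0"], list("wxyz"), A)
        St = np.full((4, 4), 0.5)
        np.fill_diagonal(St, 1.0)
        ctw, ctb = target_view_scores(net, St, 3, 0, exclude_pair=True)
        assert ctw is None and ctb == 0.5

    def test_new_target_has_null_within_drug_view(self, rng):
        net = random_network(rng, 4, 3, p=0.5)
        net.A[:, 2] = 0  # t2 has no known drugs
        net = InteractionNetwork(net.drug_ids, net.target_ids, net.A)
        Sd = random_similarity(rng, net.drug_ids)
        cdw, cdb = drug_view_scores(net, Sd, 1, 2)
        assert cdw is None
        assert cdb == pytest.approx(max(Sd.S[1, i] for i in (0, 2, 3)))

    def test_matches_bruteforce_enumeration(self, rng):
        for _ in range(30):
            D, T = rng.integers(2, 8, size=2)
            net = random_network(rng, int(D), int(T), p=float(rng.random()))
            St = random_similarity(rng, net.target_ids).S
            Sd = random_similarity(rng, net.drug_ids).S
            for y in range(int(D)):
                for x in range(int(T)):
                    excl = bool(net.A[y, x])
                    assert target_view_scores(net, St, x, y, excl) == brute_scores(
                        net.A, St, 0, x, y, excl
                    )
                    assert drug_view_scores(net, Sd, y, x, excl) == brute_scores(
                        net.A, Sd, 1, y, x, excl
                    )


class TestMotifs:
    def test_four_motifs(self, toy_network):
        net = toy_network
        # d0 (deg 2) - t1 (deg 2): both > 1
        assert classify_motif(net, 0, 1) is Motif.MULTIPLE
        # d0 (deg 2) - t0 (deg 1): drug hub, sole-link target
        assert classify_motif(net, 0, 0) is Motif.DRUG_CENTERED
        # d2 (deg 1) - t3 (deg 1): isolated pair
        assert classify_motif(net, 2, 3) is Motif.SINGLE

    def test_target_centered(self):
        A = np.array([[1], [1]])
        net = InteractionNetwork(["d0", "d1"], ["t0"], A)
        assert classify_motif(net, 0, 0) is Motif.TARGET_CENTERED

    def test_unapproved_pair_rejected(self, toy_network):
        with pytest.raises(ValidationError):
            classify_motif(toy_network, 0, 2)


class TestPairFeature:
    def test_single_motif_null_pattern(self, toy_network, rng):
        sd = random_similarity(rng, toy_network.drug_ids)
        st = random_similarity(rng, toy_network.target_ids)
        f = pair_feature(toy_network, sd, st, 2, 3, combiner="primary")
        assert f.motif is Motif.SINGLE
        assert f.null_mask.tolist() == [True, False, True, False]
        assert f.scores[0] == 1.0 and f.scores[2] == 1.0

    def test_drug_centered_null_pattern(self, toy_network, rng):
        sd = random_similarity(rng, toy_network.drug_ids)
        st = random_similarity(rng, toy_network.target_ids)
        f = pair_feature(toy_network, sd, st, 0, 0, combiner="primary")
        assert f.motif is Motif.DRUG_CENTERED
        assert f.null_mask.tolist() == [False, False, True, False]

    def test_unapproved_pair_all_scores_present(self, toy_network, rng):
        sd = random_similarity(rng, toy_network.drug_ids)
        st = random_similarity(rng, toy_network.target_ids)
        f = pair_feature(toy_network, sd, st, 1, 0, combiner="primary")
        assert f.motif is None and not f.is_known
        assert not f.null_mask.any()
        assert np.all((f.scores >= 0) & (f.scores <= 1))

    @pytest.mark.parametrize("combiner,alpha", [
        ("primary", None), ("topo", None), ("adaptive", None), ("linear", 0.3),
    ])
    def test_feature_matrix_agrees_with_per_pair_path(self, combiner, alpha, rng):
        """The vectorised batch computation must reproduce the per-pair one."""
        for _ in range(8):
            D, T = rng.integers(2, 7, size=2)
            net = random_network(rng, int(D), int(T), p=0.45)
            sd = random_similarity(rng, net.drug_ids)
            st = random_similarity(rng, net.target_ids)
            table = feature_matrix(net, sd, st, combiner=combiner, alpha=alpha)
            assert len(table) == int(D) * int(T)
            for idx in range(len(table)):
                y, x = divmod(idx, int(T))
                single = pair_feature(net, sd, st, y, x, combiner=combiner, alpha=alpha)
                batch = table[idx]
                assert batch.drug_id == single.drug_id
                assert batch.target_id == single.target_id
                assert batch.is_known == single.is_known
                assert batch.motif == single.motif
                assert np.array_equal(batch.scores, single.scores)
                assert np.array_equal(batch.null_mask, single.null_mask)

    def test_null_pattern_theorem(self, rng):
        """For every known pair the within-score nulls match its motif and
        between-score nulls occur exactly when the complement set is empty."""
        for _ in range(30):
            D, T = rng.integers(2, 8, size=2)
            net = random_network(rng, int(D), int(T), p=0.5)
            sd = random_similarity(rng, net.drug_ids)
            st = random_similarity(rng, net.target_ids)
            table = feature_matrix(net, sd, st, combiner="primary")
            for y, x in net.known_pairs():
                f = table[int(y) * int(T) + int(x)]
                deg_d = net.drug_degrees[y]
                deg_t = net.target_degrees[x]
                assert f.null_mask[0] == (deg_d == 1)  # C_t^w null iff sole target
                assert f.null_mask[2] == (deg_t == 1)  # C_d^w null iff sole drug
                assert f.null_mask[1] == (deg_d == int(T))
                assert f.null_mask[3] == (deg_t == int(D))
                if f.motif is Motif.MULTIPLE:
                    assert not f.null_mask[0] and not f.null_mask[2]
                elif f.motif is Motif.DRUG_CENTERED:
                    assert f.null_mask[2] and not f.null_mask[0]
                elif f.motif is Motif.TARGET_CENTERED:
                    assert f.null_mask[0] and not f.null_mask[2]
                else:
                    assert f.null_mask[0] and f.null_mask[2]

    def test_all_vectors_in_unit_hypercube(self, rng):
        net = random_network(rng, 6, 5, p=0.4)
        sd = random_similarity(rng, net.drug_ids)
        st = random_similarity(rng, net.target_ids)
        for combiner in ("adaptive", "primary", "topo"):
            table = feature_matrix(net, sd, st, combiner=combiner)
            assert table.scores.min() >= 0.0 and table.scores.max() <= 1.0

    def test_permuting_drug_order_permutes_features(self, rng):
        net = random_network(rng, 5, 4, p=0.5)
        sd = random_similarity(rng, net.drug_ids)
        st = random_similarity(rng, net.target_ids)
        t1 = feature_matrix(net, sd, st, combiner="adaptive")
        perm = rng.permutation(5)
        net2 = InteractionNetwork(
            [net.drug_ids[i] for i in perm], net.target_ids, net.A[perm]
        )
        sd2 = sd.reorder(net2.drug_ids)
        t2 = feature_matrix(net2, sd2, st, combiner="adaptive")
        by_pair_1 = {(f.drug_id, f.target_id): f.scores.tolist() for f in t1}
        by_pair_2 = {(f.drug_id, f.target_id): f.scores.tolist() for f in t2}
        assert by_pair_1 == by_pair_2


class TestHistograms:
    def make_features(self, values, known=False):
        return [
            PairFeature(
                drug_id=f"d{i}", target_id="t0", is_known=known,
                motif=Motif.MULTIPLE if known else None,
                scores=np.array([v, v, v, v]), null_mask=np.zeros(4, dtype=bool),
            )
            for i, v in enumerate(values)
        ]

    def test_edges_cover_expected_range(self):
        assert len(HISTOGRAM_EDGES) == 39
        assert HISTOGRAM_EDGES[0] == pytest.approx(0.35)
        assert HISTOGRAM_EDGES[1] == pytest.approx(0.37)
        assert HISTOGRAM_EDGES[-1] >= 1.1

    def test_point_mass_in_single_bin(self):
        frame = score_histograms(self.make_features([1.0, 1.0, 1.0]), 1)
        unapp = frame[frame.group == "unapproved"]
        assert unapp.height.sum() == pytest.approx(1.0)
        assert (unapp.height > 0).sum() == 1

    def test_empty_group_flagged(self):
        frame = score_histograms(self.make_features([0.5]), 1)
        singles = frame[frame.group == "single"]
        assert (singles.group_total == 0).all()
        assert (singles.height == 0).all()

    def test_disjoint_supports_do_not_overlap(self):
        feats = self.make_features([0.40, 0.42], known=True) + self.make_features([0.9, 0.92])
        frame = score_histograms(feats, 1)
        multi = frame[frame.group == "multiple"].height.to_numpy()
        unapp = frame[frame.group == "unapproved"].height.to_numpy()
        assert float(np.minimum(multi, unapp).sum()) == 0.0

    def test_out_of_range_values_clamp(self):
        frame = score_histograms(self.make_features([0.0, 1.0999, 1.1]), 1)
        unapp = frame[frame.group == "unapproved"]
        assert unapp.height.iloc[0] == pytest.approx(1 / 3)
        assert unapp.height.iloc[-1] == pytest.approx(2 / 3)
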