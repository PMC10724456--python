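"""TFSEE scoring, clustering, and differential TF ranking."""

import numpy as np
import pandas as pd
import pytest
from scipy.cluster import hierarchy

from placenta_enhancers import (
    SignalMatrix,
    build_motif_matrix,
    cluster_samples,
    differential_tfsee,
    enhancer_activity,
    minmax_normalize,
    tfsee_scores,
)


def df(rows, index, columns):
    return pd.DataFrame(rows, index=index, columns=columns, dtype=float)


class TestMinmaxNormalize:
    def test_row_formula_and_constant_rule(self):
        m = df([[1, 3, 5], [2, 2, 2]], ["a", "b"], ["x", "y", "z"])
        out = minmax_normalize(m, "per-feature")
        assert out.loc["a"].tolist() == [0.0, 0.5, 1.0]
        assert out.loc["b"].tolist() == [0.0, 0.0, 0.0]

    def test_non_constant_slices_span_unit_interval(self):
        rng = np.random.default_rng(2)
        m = pd.DataFrame(rng.normal(size=(10, 6)))
        out = minmax_normalize(m, "per-feature")
        assert np.allclose(out.min(axis=1), 0) and np.allclose(out.max(axis=1), 1)
        outg = minmax_normalize(m, "global")
        assert outg.to_numpy().min() == 0.0 and outg.to_numpy().max() == 1.0


class TestEnhancerActivity:
    def _sm(self, rows, samples=("s1", "s2")):
        return SignalMatrix(df(rows, ["e1"], list(samples)), "counts")

    def test_hand_worked_two_sample_case(self):
        # eRNA (0,4) -> (0,1); K27ac constant -> zeros; K4me1 (0,10) -> (0,1)
        # A = N(eRNA) * (N(K27)+N(K4))/2 = (0, 1 * (0+1)/2) = (0, 0.5)
        act = enhancer_activity(
            self._sm([[0, 4]]), self._sm([[2, 2]]), self._sm([[0, 10]])
        )
        assert act["e1"].tolist() == [0.0, 0.5]

    def test_zero_erna_forces_zero_activity(self):
        act = enhancer_activity(
            self._sm([[0, 4]]), self._sm([[9, 1]]), self._sm([[8, 2]])
        )
        assert act.loc["s1", "e1"] == 0.0

    def test_max_everywhere_gives_unit_activity(self):
        act = enhancer_activity(
            self._sm([[1, 4]]), self._sm([[1, 3]]), self._sm([[2, 10]])
        )
        assert act.loc["s2", "e1"] == 1.0

    def test_index_mismatch_rejected(self):
        a = self._sm([[0, 4]])
        b = SignalMatrix(df([[1, 2]], ["eX"], ["s1", "s2"]), "counts")
        with pytest.raises(ValueError, match="k27ac"):
            enhancer_activity(a, b, a)

    def test_entries_always_in_unit_interval(self):
        rng = np.random.default_rng(8)
        mk = lambda: SignalMatrix(
            pd.DataFrame(
                rng.gamma(2, 10, size=(12, 7)),
                index=[f"e{i}" for i in range(12)],
                columns=[f"s{i}" for i in range(7)],
            ),
            "counts",
        )
        act = enhancer_activity(mk(), mk(), mk())
        assert (act.to_numpy() >= 0).all() and (act.to_numpy() <= 1).all()


class TestBuildMotifMatrix:
    def test_single_hit_normalizes_to_one(self):
        hits = pd.DataFrame(
            {"enhancer_id": ["e1"], "tf_id": ["tfA"], "match_p": [1e-8]}
        )
        m = build_motif_matrix(hits, ["tfA", "tfB"], enhancer_ids=["e1", "e2"])
        assert m.loc["e1", "tfA"] == 1.0
        assert m.to_numpy().sum() == 1.0

    def test_top_k_truncation_drops_weakest(self):
        hits = pd.DataFrame(
            {
                "enhancer_id": ["e1"] * 25,
                "tf_id": [f"tf{i:02d}" for i in range(25)],
                "match_p": [10.0 ** -(30 - i) for i in range(25)],  # tf00 strongest
            }
        )
        m = build_motif_matrix(
            hits,
            [f"tf{i:02d}" for i in range(25)],
            top_k=20,
            enhancer_ids=["e1", "e2"],  # zero row keeps per-TF scaling non-degenerate
        )
        kept = (m.loc["e1"] > 0).sum()
        assert kept == 20
        assert (m.loc["e1", [f"tf{i:02d}" for i in range(20, 25)]] == 0).all()

    def test_equal_strength_ties_within_cap_both_kept(self):
        hits = pd.DataFrame(
            {
                "enhancer_id": ["e1", "e1"],
                "tf_id": ["tfA", "tfB"],
                "match_p": [1e-6, 1e-6],
            }
        )
        m = build_motif_matrix(
            hits, ["tfA", "tfB"], top_k=20, enhancer_ids=["e1", "e2"]
        )
        assert (m.loc["e1"] > 0).all()

    def test_unknown_tf_rejected(self):
        hits = pd.DataFrame(
            {"enhancer_id": ["e1"], "tf_id": ["mystery"], "match_p": [1e-8]}
        )
        with pytest.raises(ValueError, match="mystery"):
            build_motif_matrix(hits, ["tfA"])


class TestTfseeScores:
    def test_one_enhancer_one_tf(self):
        A = df([[0.0], [1.0]], ["s1", "s2"], ["e1"])
        M = df([[1.0]], ["e1"], ["tfA"])
        E = SignalMatrix(df([[0.0, 5.0]], ["tfA"], ["s1", "s2"]), "normalized")
        s = tfsee_scores(A, M, E).scores
        assert s["tfA"].tolist() == [0.0, 1.0]

    def test_hand_worked_two_by_two(self):
        A = df([[1, 0], [0, 1]], ["s1", "s2"], ["e1", "e2"])
        M = df([[1, 0], [1, 1]], ["e1", "e2"], ["tfA", "tfB"])
        E = SignalMatrix(df([[2, 4], [1, 3]], ["tfA", "tfB"], ["s1", "s2"]), "normalized")
        s = tfsee_scores(A, M, E).scores
        # I = A M = ((1,0),(1,1)); N(E) per TF = ((0,1),(0,1)) over samples
        # S_raw = ((0,0),(1,1)); per-TF min-max -> ((0,0),(1,1))
        assert s.loc["s1"].tolist() == [0.0, 0.0]
        assert s.loc["s2"].tolist() == [1.0, 1.0]

    def test_zero_expression_tf_scores_zero(self):
        A = df([[0.5], [1.0]], ["s1", "s2"], ["e1"])
        M = df([[1.0]], ["e1"], ["tfA"])
        E = SignalMatrix(df([[0.0, 0.0]], ["tfA"], ["s1", "s2"]), "normalized")
        s = tfsee_scores(A, M, E).scores
        assert (s["tfA"] == 0).all()

    def test_invariant_to_rescaling_one_enhancer_row(self):
        rng = np.random.default_rng(5)
        samples = [f"s{i}" for i in range(6)]
        enh = [f"e{i}" for i in range(4)]
        tfs = ["tfA", "tfB"]
        erna = pd.DataFrame(rng.gamma(3, 8, (4, 6)), index=enh, columns=samples)
        k27 = pd.DataFrame(rng.gamma(3, 8, (4, 6)), index=enh, columns=samples)
        k4 = pd.DataFrame(rng.gamma(3, 8, (4, 6)), index=enh, columns=samples)
        E = SignalMatrix(
            pd.DataFrame(rng.gamma(3, 8, (2, 6)), index=tfs, columns=samples),
            "normalized",
        )
        M = df([[1, 0], [0.5, 1], [0, 1], [0.2, 0.7]], enh, tfs)

        def score(er):
            from placenta_enhancers import enhancer_activity

            A = enhancer_activity(
                SignalMatrix(er, "counts"),
                SignalMatrix(k27, "counts"),
                SignalMatrix(k4, "counts"),
            )
            return tfsee_scores(A, M, E).scores

        s1 = score(erna)
        scaled = erna.copy()
        scaled.loc["e2"] *= 37.5  # positive rescaling of one eRNA row
        s2 = score(scaled)
        assert np.allclose(s1, s2)


class TestClusterSamples:
    def test_duplicated_sample_merges_first_at_zero_height(self):
        s = df(
            [[1, 2, 3], [1, 2, 3], [9, 1, 4], [2, 8, 1]],
            ["a", "a2", "b", "c"],
            ["t1", "t2", "t3"],
        )
        out = cluster_samples(s)
        z = out["linkage"]
        assert z[0, 2] == pytest.approx(0.0)
        assert sorted(int(i) for i in z[0, :2]) == [0, 1]

    def test_three_leaf_upgma_heights_match_hand_arithmetic(self):
        # score rows chosen so the 1-Pearson distances are hand-computable
        s = df(
            [[0, 1, 2], [0, 1, 2.5], [2, 1, 0]],
            ["a", "b", "c"],
            ["t1", "t2", "t3"],
        )
        v = s.to_numpy()
        d = lambda i, j: 1 - np.corrcoef(v[i], v[j])[0, 1]
        out = cluster_samples(s)
        z = out["linkage"]
        # first merge: closest pair (a,b); second height = mean of d(a,c), d(b,c)
        assert z[0, 2] == pytest.approx(d(0, 1))
        assert z[1, 2] == pytest.approx((d(0, 2) + d(1, 2)) / 2)

    def test_root_cut_recovers_two_well_separated_pairs(self):
        s = df(
            [[10, 1, 1], [11, 1.2, 0.9], [1, 10, 9], [0.8, 11, 10]],
            ["a1", "a2", "b1", "b2"],
            ["t1", "t2", "t3"],
        )
        out = cluster_samples(s)
        parts = [set(v) for v in out["clades"].values()]
        assert {"a1", "a2"} in parts and {"b1", "b2"} in parts

    def test_constant_score_vector_names_the_sample(self):
        s = df([[1, 1, 1], [1, 2, 3]], ["flat", "ok"], ["t1", "t2", "t3"])
        with pytest.raises(ValueError, match="flat"):
            cluster_samples(s)


class TestDifferentialTfsee:
    def test_label_permutation_of_identical_values_is_null(self):
        s = df([[0.5], [0.5], [0.5], [0.5]], ["a", "b", "c", "d"], ["tfA"])
        out = differential_tfsee(s, ["a", "b"], ["c", "d"])
        assert out.iloc[0]["delta_tfsee"] == 0.0
        assert out.iloc[0]["p_value"] == pytest.approx(1.0)

    def test_swapping_groups_negates_delta(self):
        rng = np.random.default_rng(19)
        s = pd.DataFrame(
            rng.random((6, 5)),
            index=list("abcdef"),
            columns=[f"tf{i}" for i in range(5)],
        )
        fwd = differential_tfsee(s, list("abc"), list("def")).set_index("tf_id")
        rev = differential_tfsee(s, list("def"), list("abc")).set_index("tf_id")
        assert np.allclose(
            fwd["delta_tfsee"], -rev.loc[fwd.index, "delta_tfsee"]
        )

    def test_rank_is_permutation_ascending_in_delta(self):
        rng = np.random.default_rng(20)
        s = pd.DataFrame(
            rng.random((6, 8)),
            index=list("abcdef"),
            columns=[f"tf{i}" for i in range(8)],
        )
        out = differential_tfsee(s, list("abc"), list("def"))
        assert sorted(out["rank"]) == list(range(1, 9))
        assert out["delta_tfsee"].is_monotonic_increasing

    def test_overlapping_groups_rejected(self):
        s = df([[0.1], [0.2], [0.3], [0.4]], list("abcd"), ["tfA"])
        with pytest.raises(ValueError, match="overlap"):
            differential_tfsee(s, ["a", "b"], ["b", "c"])
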