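"""Normalization and gestational expression dynamics."""

import numpy as np
import pandas as pd
import pytest

from placenta_enhancers import (
    SampleRecord,
    SignalMatrix,
    bh_adjust,
    correlate_with_age,
    epoch_trends,
    fold_change_ddct,
    pairwise_differential,
    signature_score,
    size_factors,
)
from placenta_enhancers.dynamics import assign_epoch_bins


def matrix(rows, samples=None, units="counts"):
    df = pd.DataFrame(rows).T if isinstance(rows, dict) else pd.DataFrame(rows)
    if samples is not None:
        df.columns = samples
    return SignalMatrix(df, units)


def make_samples(ages, prefix="s"):
    from placenta_enhancers.core import trimester_of_age

    return [
        SampleRecord(f"{prefix}{i + 1}", a, trimester_of_age(a))
        for i, a in enumerate(ages)
    ]


class TestSizeFactors:
    def test_identical_libraries_give_unit_factors(self):
        m = matrix({"f1": [4.0, 4.0], "f2": [1.0, 1.0]}, ["a", "b"])
        assert np.allclose(size_factors(m), 1.0)

    def test_doubled_library_has_doubled_factor_ratio(self):
        m = matrix({"f1": [4.0, 8.0], "f2": [1.0, 2.0]}, ["a", "b"])
        s = size_factors(m)
        assert s["b"] / s["a"] == pytest.approx(2.0)
        # hand computation: geomeans sqrt(32)=5.657, sqrt(2)=1.414;
        # ratios per sample (1/sqrt 2, sqrt 2)
        assert s["a"] == pytest.approx(1 / np.sqrt(2))
        assert s["b"] == pytest.approx(np.sqrt(2))

    def test_common_rescaling_leaves_factors_unchanged(self):
        # median-of-ratios uses the geometric-mean pseudo-reference, so a
        # common scale on every library cancels: only relative depth is
        # identified.
        rng = np.random.default_rng(1)
        df = pd.DataFrame(
            rng.poisson(50, size=(200, 6)) + 1.0, columns=list("abcdef")
        )
        s1 = size_factors(SignalMatrix(df, "counts"))
        s2 = size_factors(SignalMatrix(df * 7.0, "counts"))
        assert np.allclose(s1, s2)

    def test_all_zero_row_matrix_errors(self):
        m = matrix({"f1": [0.0, 3.0]}, ["a", "b"])
        with pytest.raises(ValueError, match="nonzero"):
            size_factors(m)


class TestCorrelateWithAge:
    def test_exactly_linear_gene_is_classified_increasing(self):
        ages = [6, 10, 16, 22, 30, 39]
        expr = matrix(
            {"up": [2 * a + 1.0 for a in ages], "flat": [5.0] * 6},
            [f"s{i + 1}" for i in range(6)],
            "normalized",
        )
        res = correlate_with_age(expr, make_samples(ages))
        up = res.set_index("gene_id").loc["up"]
        assert up["pearson_r"] == pytest.approx(1.0)
        assert up["class"] == "increasing"
        flat = res.set_index("gene_id").loc["flat"]
        assert not flat["testable"] and flat["class"] == "unclassified"
        assert res.attrs["n_tested"] == 1  # constant gene excluded from m

    def test_matches_covariance_formula_oracle(self):
        ages = [8.0, 12.0, 20.0, 33.0, 39.0]
        y = [3.0, 1.0, 4.0, 1.0, 5.0]
        expr = matrix({"g": y}, [f"s{i + 1}" for i in range(5)], "normalized")
        res = correlate_with_age(expr, make_samples(ages)).iloc[0]
        x = np.array(ages)
        yv = np.array(y)
        r_oracle = ((x - x.mean()) * (yv - yv.mean())).sum() / np.sqrt(
            ((x - x.mean()) ** 2).sum() * ((yv - yv.mean()) ** 2).sum()
        )
        slope_oracle = ((x - x.mean()) * (yv - yv.mean())).sum() / (
            (x - x.mean()) ** 2
        ).sum()
        assert res["pearson_r"] == pytest.approx(r_oracle, abs=1e-12)
        assert res["slope"] == pytest.approx(slope_oracle, abs=1e-12)
        # p from the t transform with n-2 df
        from scipy import stats

        t = r_oracle * np.sqrt(3 / (1 - r_oracle**2))
        assert res["p_value"] == pytest.approx(2 * stats.t.sf(abs(t), 3), rel=1e-9)

    def test_too_few_distinct_ages_errors(self):
        expr = matrix({"g": [1.0, 2.0, 3.0]}, ["s1", "s2", "s3"], "normalized")
        with pytest.raises(ValueError, match="distinct"):
            correlate_with_age(expr, make_samples([8.0, 8.0, 8.0]))


def bh_stepup_oracle(p):
    """Reference step-up: q_(i) = min_{j>=i} m p_(j) / j, capped at 1."""
    p = np.asarray(p, float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    q_sorted = np.minimum.accumulate(
        (m * p[order] / np.arange(1, m + 1))[::-1]
    )[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


class TestBhAdjust:
    def test_single_and_tied_pvalues(self):
        assert bh_adjust([0.03]) == pytest.approx([0.03])
        assert bh_adjust([0.2, 0.2, 0.2]) == pytest.approx([0.2, 0.2, 0.2])

    def test_hand_worked_step_up(self):
        assert bh_adjust([0.01, 0.02, 0.03, 0.04]) == pytest.approx(
            [0.04, 0.04, 0.04, 0.04]
        )

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.2])

    def test_matches_reference_step_up_on_random_vectors(self):
        rng = np.random.default_rng(12)
        for _ in range(1000):
            n = int(rng.integers(1, 40))
            p = rng.random(n).round(int(rng.integers(1, 4)))
            assert bh_adjust(p) == pytest.approx(bh_stepup_oracle(p), abs=1e-12)


class TestPairwiseDifferential:
    def test_constant_feature_is_null(self):
        m = matrix({"g": [5.0] * 6}, list("abcdef"), "normalized")
        row = pairwise_differential(m, ["a", "b", "c"], ["d", "e", "f"]).iloc[0]
        assert row["log2_fold_change"] == 0.0
        assert not row["significant"]

    def test_swapping_groups_negates_log2fc(self):
        rng = np.random.default_rng(4)
        m = matrix(
            pd.DataFrame(rng.gamma(3, 5, size=(30, 8)), columns=list("abcdefgh")),
            units="normalized",
        )
        fwd = pairwise_differential(m, list("abcd"), list("efgh"))
        rev = pairwise_differential(m, list("efgh"), list("abcd"))
        assert np.allclose(fwd["log2_fold_change"], -rev["log2_fold_change"])
        assert np.allclose(fwd["p_value"], rev["p_value"])

    def test_overlapping_groups_rejected(self):
        m = matrix({"g": [1.0] * 4}, list("abcd"), "normalized")
        with pytest.raises(ValueError, match="overlap"):
            pairwise_differential(m, ["a", "b"], ["b", "c"])

    def test_planted_fourfold_difference_detected(self, default_dataset):
        """Enhancer-coupled genes with a planted 4x early/late step come out
        significant with log2FC near 2 between trimesters I and III."""
        ds = default_dataset
        early_genes = [
            p["target_gene"]
            for p in ds.truth.enhancer_program.values()
            if p["class"] == "early"
        ]
        tab = pairwise_differential(
            ds.gene_expression,
            ds.samples_of_trimester("III"),
            ds.samples_of_trimester("I"),
        ).set_index("feature_id")
        sub = tab.loc[early_genes]
        assert sub["significant"].all()
        assert np.allclose(sub["log2_fold_change"], 2.0, atol=0.35)


class TestEpochTrends:
    def test_bin_sizes_earlier_bins_take_remainder(self):
        ages = list(np.linspace(6, 13, 12)) + list(np.linspace(14, 27, 12)) + [39.0] * 12
        bins = assign_epoch_bins(make_samples(ages), n_bins=5)
        sizes = bins.value_counts().sort_index().tolist()
        assert sizes == [8, 7, 7, 7, 7]

    def test_zscores_and_monotone_gene(self):
        ages = [6.0, 10.0, 16.0, 22.0, 30.0, 39.0]
        expr = matrix(
            {"lin": [float(a) for a in ages], "flat": [2.0] * 6},
            [f"s{i + 1}" for i in range(6)],
            "normalized",
        )
        with pytest.warns(UserWarning, match="constant"):
            out = epoch_trends(expr, make_samples(ages), n_bins=3)
        z = out["zscores"]
        assert "flat" not in z.index
        assert abs(z.loc["lin"].mean()) < 1e-12
        means = out["bin_summary"]["mean_z"].tolist()
        assert means == sorted(means)  # strictly increasing for a linear gene
        assert means[0] < means[-1]


class TestSignatureScore:
    def _setup(self):
        ages = [8.0, 9.0, 20.0, 21.0, 39.0, 39.0]
        expr = matrix(
            {
                "g1": [1.0, 2.0, 3.0, 4.0, 5.0, 6.0],
                "g2": [6.0, 5.0, 4.0, 3.0, 2.0, 1.0],
            },
            [f"s{i + 1}" for i in range(6)],
            "normalized",
        )
        return expr, make_samples(ages)

    def test_single_gene_set_equals_that_gene(self):
        expr, samples = self._setup()
        out = signature_score(expr, {"sig": ["g1"]}, samples)
        assert np.allclose(out["scores"].loc["sig"], expr.data.loc["g1"])

    def test_duplicate_sets_identical_and_empty_set_errors(self):
        expr, samples = self._setup()
        out = signature_score(expr, {"a": ["g1", "g2"], "b": ["g2", "g1"]}, samples)
        assert np.allclose(out["scores"].loc["a"], out["scores"].loc["b"])
        with pytest.raises(ValueError, match="nope"):
            signature_score(expr, {"nope": ["gX"]}, samples)

    def test_planted_term_signature_detected(self, small_dataset):
        """A gene set coupled to late-active enhancers scores significantly
        higher in trimester III than trimester I."""
        ds = small_dataset
        late_genes = [
            p["target_gene"]
            for p in ds.truth.enhancer_program.values()
            if p["class"] == "late"
        ]
        out = signature_score(ds.gene_expression, {"ST_like": late_genes}, ds.samples)
        comp = out["comparisons"]["I_vs_III"].iloc[0]
        assert comp["significant"]
        assert comp["log2_fold_change"] > 1.0


class TestDeltaDeltaCt:
    @pytest.mark.parametrize(
        "args,expected",
        [
            ((20.0, 18.0, 21.0, 19.0), 1.0),  # ddCt = 0
            ((20.0, 18.0, 19.0, 18.0), 2.0),  # ddCt = -1
            ((20.0, 18.0, 24.0, 20.0), 0.25),  # ddCt = 2
        ],
    )
    def test_definition(self, args, expected):
        assert fold_change_ddct(*args) == pytest.approx(expected)

    def test_nonfinite_ct_rejected(self):
        with pytest.raises(ValueError):
            fold_change_ddct(np.nan, 1.0, 1.0, 1.0)
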