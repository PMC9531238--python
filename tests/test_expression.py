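"""Normalization, low-expression filtering, NB Wald test, 2^-ddCt."""
from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mtgnet import (
    CountMatrix,
    SimulationConfig,
    call_status,
    ddct,
    generate_truth,
    low_expression_filter,
    nb_de_test,
    normalize,
    simulate_counts,
)


def _matrix(counts: dict, kind="gene", lengths=None, groups=None):
    df = pd.DataFrame(counts)
    if groups is None:
        half = len(df.columns) // 2
        groups = pd.Series(
            ["control"] * half + ["treated"] * (len(df.columns) - half), index=df.columns
        )
    lengths = pd.Series(lengths, index=df.index) if lengths is not None else None
    return CountMatrix(counts=df, feature_kind=kind, groups=groups, lengths=lengths)


class TestNormalize:
    def test_single_feature_gets_the_whole_million(self):
        m = _matrix({"s1": [7], "s2": [3]}, lengths=[100])
        out = normalize(m, "TPM")
        assert np.allclose(out.values.to_numpy(), 1e6)

    def test_tpm_hand_example_with_unequal_lengths(self):
        m = _matrix({"s1": [10, 10], "s2": [10, 10]}, lengths=[1000, 2000])
        out = normalize(m, "TPM")
        np.testing.assert_allclose(out.values["s1"], [666666.6667, 333333.3333], rtol=1e-6)

    def test_rpm_ignores_length(self):
        m = _matrix({"s1": [30, 10], "s2": [5, 15]}, kind="miRNA")
        out = normalize(m, "RPM")
        np.testing.assert_allclose(out.values["s1"], [750000.0, 250000.0])

    def test_all_zero_column_stays_zero(self):
        m = _matrix({"s1": [0, 0], "s2": [1, 1]}, lengths=[100, 100])
        out = normalize(m, "TPM")
        assert (out.values["s1"] == 0).all()

    def test_tpm_without_lengths_raises(self):
        m = _matrix({"s1": [1], "s2": [2]}, kind="miRNA")
        with pytest.raises(ValueError, match="lengths"):
            normalize(m, "TPM")

    @settings(max_examples=50, deadline=None)
    @given(
        st.lists(
            st.lists(st.integers(min_value=0, max_value=10_000), min_size=2, max_size=6),
            min_size=2,
            max_size=8,
        ).filter(lambda rows: len({len(r) for r in rows}) == 1)
    )
    def test_tpm_columns_always_sum_to_one_million(self, rows):
        df = pd.DataFrame(rows, index=[f"g{i}" for i in range(len(rows))])
        df.columns = [f"s{j}" for j in df.columns]
        groups = pd.Series(
            ["control"] * (len(df.columns) // 2 or 1)
            + ["treated"] * (len(df.columns) - (len(df.columns) // 2 or 1)),
            index=df.columns,
        )
        if not {"control", "treated"} <= set(groups):
            return
        m = CountMatrix(
            counts=df, feature_kind="gene", groups=groups,
            lengths=pd.Series(np.arange(1, len(df) + 1) * 100, index=df.index),
        )
        sums = normalize(m, "TPM").values.sum(axis=0)
        nonzero = df.sum(axis=0) > 0
        np.testing.assert_allclose(sums[nonzero], 1e6, rtol=1e-6)
        assert (sums[~nonzero] == 0).all()


class TestLowExpressionFilter:
    def test_all_zero_features_dropped(self):
        m = _matrix({"s1": [0, 0], "s2": [0, 0]}, kind="miRNA")
        norm = normalize(m, "RPM")
        assert low_expression_filter(norm) == []

    def test_boundary_mean_exactly_at_cutoff_is_retained(self):
        from mtgnet.expression import NormalizedMatrix

        values = pd.DataFrame({"s1": [0.05, 0.04], "s2": [0.05, 0.04]}, index=["a", "b"])
        kept = low_expression_filter(NormalizedMatrix(values=values, unit="RPM"))
        assert kept == ["a"]

    def test_matches_brute_force_mean_comparison(self):
        rng = np.random.default_rng(0)
        values = pd.DataFrame(
            rng.uniform(0, 3, size=(30, 4)), index=[f"g{i}" for i in range(30)]
        )
        from mtgnet.expression import NormalizedMatrix

        kept = low_expression_filter(NormalizedMatrix(values=values, unit="TPM"))
        expected = [g for g in values.index if values.loc[g].mean() >= 1.0]
        assert kept == expected


class TestNbDeTest:
    def test_identical_groups_give_zero_lfc_and_p_one(self):
        m = _matrix({"c1": [10, 50], "c2": [20, 60], "t1": [10, 50], "t2": [20, 60]},
                    lengths=[100, 100])
        res = nb_de_test(m)
        np.testing.assert_allclose(res["log2fc"], 0.0)
        np.testing.assert_allclose(res["p_value"], 1.0)

    def test_swapping_group_labels_negates_lfc_keeps_p(self):
        cfg = SimulationConfig(n_genes=60, n_tfs=5, n_mirnas=2, seed=23)
        truth = generate_truth(cfg)
        _, mrna = simulate_counts(truth, cfg)
        res = nb_de_test(mrna)
        flipped = CountMatrix(
            counts=mrna.counts,
            feature_kind="gene",
            groups=mrna.groups.map({"control": "treated", "treated": "control"}),
            lengths=mrna.lengths,
        )
        res2 = nb_de_test(flipped)
        np.testing.assert_allclose(res2["log2fc"], -res["log2fc"], atol=1e-12)
        np.testing.assert_allclose(res2["p_value"], res["p_value"], atol=1e-12)

    def test_single_sample_group_rejected(self):
        m = _matrix(
            {"c1": [5], "c2": [5], "t1": [5]},
            lengths=[100],
            groups=pd.Series(["control", "control", "treated"], index=["c1", "c2", "t1"]),
        )
        with pytest.raises(ValueError, match=">= 2 samples"):
            nb_de_test(m)

    def test_all_zero_library_rejected(self):
        m = _matrix({"c1": [0], "c2": [1], "t1": [1], "t2": [1]}, lengths=[100])
        with pytest.raises(ValueError, match="library"):
            nb_de_test(m)

    def test_planted_effect_recovered_without_bias(self):
        # signed +-2 effects among nulls; mean signed recovery within [1.8, 2.2]
        rng = np.random.default_rng(31)
        n_feat, n_de, n = 2500, 500, 3
        lfc = np.zeros(n_feat)
        de_idx = rng.choice(n_feat, size=n_de, replace=False)
        signs = rng.choice([-1.0, 1.0], size=n_de)
        lfc[de_idx] = 2.0 * signs
        r = 1 / 0.1
        mu_c = np.full((n_feat, n), 500.0)
        mu_t = 500.0 * 2.0 ** lfc[:, None] * np.ones((n_feat, n))
        counts = np.hstack([
            rng.negative_binomial(r, r / (r + mu_c)),
            rng.negative_binomial(r, r / (r + mu_t)),
        ])
        cols = [f"c{i}" for i in range(n)] + [f"t{i}" for i in range(n)]
        m = CountMatrix(
            counts=pd.DataFrame(counts, columns=cols),
            feature_kind="miRNA",
            groups=pd.Series(["control"] * n + ["treated"] * n, index=cols),
        )
        res = nb_de_test(m)
        recovered = (res["log2fc"].to_numpy()[de_idx] * signs).mean()
        assert 1.8 <= recovered <= 2.2


class TestCallStatus:
    @pytest.mark.parametrize(
        "feature, lfc, p, expected",
        [
            ("miR-122-5p", 4.05, 0.0118, "up"),
            ("Plec", -3.53, 0.00666, "down"),
            ("miR-10b-5p", -1.46, 0.0568, "ns"),  # fails P < 0.05 under the stated rule
            ("boundary_lfc", 1.0, 0.01, "ns"),  # |lfc| must exceed 1, strictly
            ("boundary_p", 2.0, 0.05, "ns"),  # p must be below 0.05, strictly
        ],
    )
    def test_published_and_boundary_calls(self, feature, lfc, p, expected):
        df = pd.DataFrame({"log2fc": [lfc], "p_value": [p]}, index=[feature])
        assert call_status(df)["status"].iloc[0] == expected

    def test_low_expression_flag_wins(self):
        df = pd.DataFrame({"log2fc": [5.0], "p_value": [0.001]}, index=["g1"])
        out = call_status(df, low_expression={"g1"})
        assert out["status"].iloc[0] == "low_expression"

    @settings(max_examples=100, deadline=None)
    @given(
        lfc=st.floats(-6, 6, allow_nan=False),
        p=st.floats(0, 1, allow_nan=False),
        dlfc=st.floats(0, 2),
        dp=st.floats(0, 1),
    )
    def test_monotone_in_significance(self, lfc, p, dlfc, dp):
        # raising |lfc| and lowering p never turns significant into ns
        before = call_status(pd.DataFrame({"log2fc": [lfc], "p_value": [p]}))["status"][0]
        stronger_lfc = lfc + dlfc if lfc >= 0 else lfc - dlfc
        after = call_status(
            pd.DataFrame({"log2fc": [stronger_lfc], "p_value": [max(p - dp, 0.0)]})
        )["status"][0]
        if before in ("up", "down"):
            assert after == before


class TestDdct:
    @pytest.mark.parametrize(
        "cts, expected",
        [
            ((20, 20, 20, 20), 1.0),  # no change anywhere
            ((19, 20, 20, 20), 2.0),  # target one cycle earlier in treated
            ((20, 15, 22, 15), 4.0),  # ddCt = 5 - 7 = -2
        ],
    )
    def test_fold_change_examples(self, cts, expected):
        assert ddct(*cts) == pytest.approx(expected)

    def test_nonfinite_ct_rejected(self):
        with pytest.raises(ValueError):
            ddct(np.nan, 20, 20, 20)
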