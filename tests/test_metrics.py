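"""Evaluation battery: shape/trend scores, diagnostics, privacy, efficacy.

Brute-force oracle implementations live at the top of this module and are
kept deliberately independent of the library code paths they check.
"""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from twinsift.metrics import (detection_score, diagnostic_report,
                              inference_privacy_categorical,
                              inference_privacy_numeric, ks_complement,
                              ml_efficacy, new_row_synthesis, overall_privacy,
                              pair_trend, quality_report, table_structure,
                              tv_complement)
from twinsift.metrics import quality_overall


# ---------------------------------------------------------------------------
# Independent brute-force oracles
# ---------------------------------------------------------------------------

def ks_oracle(a, b):
    """Sup distance between ECDFs evaluated at every observed point."""
    pts = sorted(set(a) | set(b))
    sup = max(abs(sum(x <= p for x in a) / len(a)
                  - sum(x <= p for x in b) / len(b)) for p in pts)
    return 1.0 - sup


def tv_oracle(a, b):
    cats = set(a) | set(b)
    tv = 0.5 * sum(abs(list(a).count(c) / len(a) - list(b).count(c) / len(b))
                   for c in cats)
    return 1.0 - tv


def contingency_oracle(ra, rb, sa, sb):
    cells = set(zip(ra, rb)) | set(zip(sa, sb))
    n_r, n_s = len(ra), len(sa)
    tv = 0.5 * sum(abs(list(zip(ra, rb)).count(c) / n_r
                       - list(zip(sa, sb)).count(c) / n_s) for c in cells)
    return 1.0 - tv


def new_row_oracle(real, synthetic, numeric_cols, tol_frac=0.01):
    unmatched = 0
    tols = {c: tol_frac * (real[c].max() - real[c].min()) for c in numeric_cols}
    for _, srow in synthetic.iterrows():
        matched = False
        for _, rrow in real.iterrows():
            ok = True
            for c in real.columns:
                if c in numeric_cols:
                    if abs(srow[c] - rrow[c]) > tols[c]:
                        ok = False
                        break
                elif srow[c] != rrow[c]:
                    ok = False
                    break
            if ok:
                matched = True
                break
        if not matched:
            unmatched += 1
    return unmatched / len(synthetic)


# ---------------------------------------------------------------------------
# Column shapes
# ---------------------------------------------------------------------------

class TestKsComplement:
    def test_identical_columns(self, rng):
        x = pd.Series(rng.normal(size=50))
        assert ks_complement(x, x.copy()) == pytest.approx(1.0)

    def test_disjoint_supports(self):
        assert ks_complement(pd.Series([0.0] * 10), pd.Series([1.0] * 10)) == 0.0

    def test_half_overlap_example(self):
        real = pd.Series([0, 1, 2, 3], dtype=float)
        syn = pd.Series([0, 1], dtype=float)
        assert ks_complement(real, syn) == pytest.approx(0.5)

    def test_non_numeric_rejected(self):
        with pytest.raises(TypeError):
            ks_complement(pd.Series(["a", "b"]), pd.Series(["a", "b"]))

    def test_agrees_with_brute_force(self, rng):
        for _ in range(5):
            a = rng.normal(size=int(rng.integers(5, 100)))
            b = rng.normal(0.3, 1.2, size=int(rng.integers(5, 100)))
            assert ks_complement(pd.Series(a), pd.Series(b)) == pytest.approx(
                ks_oracle(list(a), list(b)), abs=1e-9)


class TestTvComplement:
    def test_identical_frequency_tables(self):
        a = pd.Series(["x", "x", "y"])
        assert tv_complement(a, pd.Series(["y", "x", "x"])) == pytest.approx(1.0)

    def test_half_mass_moved(self):
        real = pd.Series(["A", "B"])
        syn = pd.Series(["A", "A"])
        assert tv_complement(real, syn) == pytest.approx(0.5)

    def test_disjoint_categories(self):
        assert tv_complement(pd.Series(["a"]), pd.Series(["b"])) == 0.0

    def test_agrees_with_brute_force(self, rng):
        for _ in range(5):
            a = rng.choice(list("abcd"), size=int(rng.integers(5, 100)))
            b = rng.choice(list("abde"), size=int(rng.integers(5, 100)))
            assert tv_complement(pd.Series(a), pd.Series(b)) == pytest.approx(
                tv_oracle(list(a), list(b)), abs=1e-9)


class TestPairTrend:
    def test_copy_scores_one(self, mixed_table):
        for a, b in itertools.combinations(mixed_table.columns, 2):
            assert pair_trend(mixed_table, mixed_table.copy(), a, b) == \
                pytest.approx(1.0)

    def test_opposite_correlations_score_zero(self, rng):
        x = rng.normal(size=200)
        real = pd.DataFrame({"a": x, "b": x + 1e-9 * rng.normal(size=200)})
        syn = pd.DataFrame({"a": x, "b": -x + 1e-9 * rng.normal(size=200)})
        assert pair_trend(real, syn, "a", "b") == pytest.approx(0.0, abs=1e-6)

    def test_crossed_joint_categories_score_zero(self):
        real = pd.DataFrame({"u": ["A", "B"] * 5, "v": ["A", "B"] * 5})
        syn = pd.DataFrame({"u": ["A", "B"] * 5, "v": ["B", "A"] * 5})
        assert pair_trend(real, syn, "u", "v") == pytest.approx(0.0)

    def test_constant_numeric_falls_back_to_contingency(self):
        real = pd.DataFrame({"a": [1.0] * 10, "c": ["x", "y"] * 5})
        syn = pd.DataFrame({"a": [1.0] * 10, "c": ["x"] * 10})
        score = pair_trend(real, syn, "a", "c")
        assert 0.0 <= score <= 1.0

    def test_contingency_branch_agrees_with_brute_force(self, rng):
        for _ in range(5):
            n = int(rng.integers(10, 100))
            real = pd.DataFrame({"c": rng.choice(list("ab"), n),
                                 "d": rng.choice(list("xyz"), n)})
            syn = pd.DataFrame({"c": rng.choice(list("ab"), n),
                                "d": rng.choice(list("xyz"), n)})
            got = pair_trend(real, syn, "c", "d")
            want = contingency_oracle(real["c"], real["d"], syn["c"], syn["d"])
            assert got == pytest.approx(want, abs=1e-9)


class TestQualityReport:
    def test_self_comparison_scores_one(self, mixed_table):
        rep = quality_report(mixed_table, mixed_table.copy(), id_columns=())
        assert rep.quality_overall == pytest.approx(1.0)
        assert rep.shapes_overall == pytest.approx(1.0)

    def test_overall_is_mean_of_subscores(self, analytical):
        from twinsift.sifter import preset, sift
        twin = sift(analytical, preset("medium", seed=0)).data
        rep = quality_report(analytical, twin)
        assert rep.quality_overall == pytest.approx(
            (rep.shapes_overall + rep.trends_overall) / 2.0, abs=1e-12)

    def test_printed_subscore_aggregation(self):
        # published overall values are truncated at 7 digits, so agreement is
        # to one unit in the last printed digit
        assert quality_overall(0.9659954, 0.9629643) == pytest.approx(
            0.9644798, abs=1e-7)
        assert quality_overall(0.8445582, 0.8120159) == pytest.approx(
            0.8282870, abs=1e-7)

    def test_schema_mismatch_rejected(self, mixed_table):
        with pytest.raises(ValueError):
            quality_report(mixed_table, mixed_table.drop(columns=["x"]),
                           id_columns=())

    def test_pair_matrix_symmetric(self, mixed_table):
        rep = quality_report(mixed_table, mixed_table.sample(frac=1.0, random_state=0),
                             id_columns=())
        m = rep.pair_trends.to_numpy()
        assert np.allclose(m, m.T)


class TestDiagnosticReport:
    def test_self_comparison(self, mixed_table):
        rep = diagnostic_report(mixed_table, mixed_table.copy(), id_columns=())
        assert rep.validity_overall == 1.0
        assert rep.structure_score == 1.0
        assert rep.diagnostic_overall == 1.0

    def test_renamed_column_structure_score(self):
        real = pd.DataFrame({f"c{i}": [1] for i in range(10)})
        syn = real.rename(columns={"c0": "renamed"})
        assert table_structure(real, syn) == pytest.approx(9 / 11)

    def test_out_of_range_values_zero_validity(self):
        real = pd.DataFrame({"x": [0.0, 1.0]})
        syn = pd.DataFrame({"x": [5.0, 6.0]})
        rep = diagnostic_report(real, syn, id_columns=())
        assert rep.validity["x"] == 0.0

    def test_unseen_category_lowers_adherence(self):
        real = pd.DataFrame({"c": ["a", "b", "a", "b"]})
        syn = pd.DataFrame({"c": ["a", "b", "z", "z"]})
        rep = diagnostic_report(real, syn, id_columns=())
        assert rep.validity["c"] == pytest.approx(0.5)


# ---------------------------------------------------------------------------
# Privacy
# ---------------------------------------------------------------------------

class TestNewRowSynthesis:
    def test_verbatim_copy_scores_zero(self, mixed_table):
        assert new_row_synthesis(mixed_table, mixed_table.copy(),
                                 id_columns=()) == 0.0

    def test_unseen_category_everywhere_scores_one(self, mixed_table):
        syn = mixed_table.copy()
        syn["cat"] = "unseen"
        assert new_row_synthesis(mixed_table, syn, id_columns=()) == 1.0

    def test_half_matched(self):
        real = pd.DataFrame({"c": ["a", "b"], "x": [0.0, 1.0]})
        syn = pd.DataFrame({"c": ["a", "z"], "x": [0.0, 1.0]})
        assert new_row_synthesis(real, syn, id_columns=()) == 0.5

    def test_agrees_with_brute_force(self, rng):
        n = 40
        real = pd.DataFrame({"x": rng.normal(size=n).round(1),
                             "c": rng.choice(["a", "b"], n)})
        syn = pd.DataFrame({"x": rng.normal(size=n).round(1),
                            "c": rng.choice(["a", "b"], n)})
        got = new_row_synthesis(real, syn, id_columns=())
        want = new_row_oracle(real, syn, numeric_cols=["x"])
        assert got == pytest.approx(want, abs=1e-9)


class TestDetectionScore:
    def test_same_distribution_indistinguishable(self):
        scores = []
        for seed in range(3):
            rng = np.random.default_rng(seed)
            x = pd.DataFrame({"a": rng.normal(size=600),
                              "b": rng.normal(size=600)})
            scores.append(detection_score(x.iloc[:300], x.iloc[300:],
                                          "logistic", seed=seed, id_columns=()))
        assert np.mean(scores) >= 0.85

    def test_large_shift_perfectly_separable(self, rng):
        real = pd.DataFrame({"a": rng.normal(size=200)})
        syn = pd.DataFrame({"a": rng.normal(size=200) + 100.0})
        assert detection_score(real, syn, "logistic", id_columns=()) <= 0.05

    def test_monotone_response_to_mean_shift(self, rng):
        base = pd.DataFrame({"a": rng.normal(size=300),
                             "b": rng.normal(size=300)})
        scores = []
        for shift in (0.0, 1.0, 3.0, 10.0):
            syn = base.copy()
            syn["a"] = syn["a"] + shift
            scores.append(detection_score(base, syn, "logistic", seed=1,
                                          id_columns=()))
        assert all(s1 >= s2 - 1e-9 for s1, s2 in zip(scores, scores[1:]))

    def test_svc_variant_runs(self, rng):
        real = pd.DataFrame({"a": rng.normal(size=100)})
        syn = pd.DataFrame({"a": rng.normal(size=100) + 50.0})
        assert detection_score(real, syn, "svc", id_columns=()) <= 0.1

    def test_too_few_rows_rejected(self):
        small = pd.DataFrame({"a": [1.0] * 5})
        with pytest.raises(ValueError):
            detection_score(small, small, "logistic", id_columns=())


class TestInferenceAttacks:
    def test_copy_with_identifying_keys_scores_zero(self, rng):
        n = 50
        real = pd.DataFrame({"k": np.arange(n), "s": rng.choice(["a", "b"], n)})
        assert inference_privacy_categorical(real, real.copy(), ["k"], "s") == 0.0

    def test_permuted_sensitive_near_chance(self):
        rng = np.random.default_rng(4)
        n = 4000
        real = pd.DataFrame({"k": rng.integers(0, 10, n),
                             "s": rng.choice(["a", "b"], n)})
        syn = real.copy()
        syn["s"] = rng.permutation(syn["s"].to_numpy())
        score = inference_privacy_categorical(real, syn, ["k"], "s")
        assert score == pytest.approx(0.5, abs=0.06)

    def test_no_key_overlap_fully_protected(self):
        real = pd.DataFrame({"k": [1, 2], "s": ["a", "b"]})
        syn = pd.DataFrame({"k": [8, 9], "s": ["a", "b"]})
        assert inference_privacy_categorical(real, syn, ["k"], "s") == 1.0

    def test_sensitive_among_keys_rejected(self):
        df = pd.DataFrame({"k": [1], "s": ["a"]})
        with pytest.raises(ValueError):
            inference_privacy_categorical(df, df, ["k", "s"], "s")

    def test_numeric_attack_deterministic_relation(self, rng):
        n = 400
        k = rng.normal(size=n)
        real = pd.DataFrame({"k": k, "s": 3.0 * k})
        score = inference_privacy_numeric(real, real.copy(), ["k"], "s")
        assert score < 0.05

    def test_numeric_attack_independent_sensitive(self):
        rng = np.random.default_rng(5)
        n = 1000
        real = pd.DataFrame({"k": rng.normal(size=n), "s": rng.normal(size=n)})
        syn = pd.DataFrame({"k": rng.normal(size=n), "s": rng.normal(size=n)})
        assert inference_privacy_numeric(real, syn, ["k"], "s") > 0.9

    def test_zero_variance_sensitive_convention(self):
        df = pd.DataFrame({"k": [1.0, 2.0], "s": [5.0, 5.0]})
        with pytest.warns(UserWarning):
            assert inference_privacy_numeric(df, df, ["k"], "s") == 0.0


class TestMlEfficacy:
    def test_learnable_rule_recovered(self):
        rng = np.random.default_rng(6)
        n = 400
        x = rng.normal(size=n)
        table = pd.DataFrame({"x": x, "z": rng.normal(size=n),
                              "t": np.where(x > 0, "pos", "neg")})
        rep = ml_efficacy(table, table.copy(), "t", id_columns=())
        assert rep["target_type"] == "binary"
        assert set(rep["scores"]) == {"adaboost", "decision_tree",
                                      "logistic_regression", "mlp"}
        assert rep["overall"] >= 0.9

    def test_shuffled_target_near_chance(self):
        rng = np.random.default_rng(7)
        n = 400
        x = rng.normal(size=n)
        real = pd.DataFrame({"x": x, "t": np.where(x > 0, "pos", "neg")})
        syn = real.copy()
        syn["t"] = rng.permutation(syn["t"].to_numpy())
        rep = ml_efficacy(real, syn, "t", id_columns=())
        assert rep["overall"] < 0.65

    def test_numeric_target_single_algorithm(self, rng):
        n = 300
        x = rng.normal(size=n)
        table = pd.DataFrame({"x": x, "y": 2.0 * x + rng.normal(0, 0.1, n)})
        rep = ml_efficacy(table, table.copy(), "y", id_columns=())
        assert rep["target_type"] == "numeric"
        assert list(rep["scores"]) == ["linear_regression"]
        assert rep["overall"] > 0.9

    def test_multiclass_uses_two_algorithms(self, rng):
        n = 300
        table = pd.DataFrame({"x": rng.normal(size=n),
                              "t": rng.choice(["a", "b", "c"], n)})
        rep = ml_efficacy(table, table.copy(), "t", id_columns=())
        assert rep["target_type"] == "multiclass"
        assert set(rep["scores"]) == {"decision_tree", "mlp"}

    def test_constant_synthetic_target_scores_zero(self, rng):
        n = 100
        real = pd.DataFrame({"x": rng.normal(size=n),
                             "t": rng.choice(["a", "b"], n)})
        syn = real.copy()
        syn["t"] = "a"
        with pytest.warns(UserWarning):
            rep = ml_efficacy(real, syn, "t", id_columns=())
        assert rep["overall"] == 0.0


class TestOverallPrivacy:
    @pytest.mark.parametrize("parts,expected", [
        ((1, 1, 1, 1), 1.0),
        ((0, 0, 0, 1), 0.25),
        ((0.9, 0.8, 0.7, 1.0), 0.85),
    ])
    def test_arithmetic_mean(self, parts, expected):
        assert overall_privacy(*parts) == pytest.approx(expected)

    def test_missing_component_rejected(self):
        with pytest.raises(ValueError):
            overall_privacy(0.5, float("nan"), 0.5, 1.0)


# ---------------------------------------------------------------------------
# Property tests
# ---------------------------------------------------------------------------

@settings(max_examples=50, deadline=None, derandomize=True)
@given(st.lists(st.sampled_from("abc"), min_size=1, max_size=30),
       st.lists(st.sampled_from("abcd"), min_size=1, max_size=30))
def test_tv_complement_in_unit_interval(a, b):
    score = tv_complement(pd.Series(a), pd.Series(b))
    assert 0.0 <= score <= 1.0 + 1e-12


@settings(max_examples=50, deadline=None, derandomize=True)
@given(st.lists(st.floats(-1e6, 1e6), min_size=2, max_size=30),
       st.lists(st.floats(-1e6, 1e6), min_size=2, max_size=30))
def test_ks_complement_in_unit_interval(a, b):
    score = ks_complement(pd.Series(a, dtype=float), pd.Series(b, dtype=float))
    assert 0.0 <= score <= 1.0 + 1e-12
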