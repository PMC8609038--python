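"""LFQ normalization, fold changes, set overlap, correlation and clustering."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from aggrescreen import omicsets as om
from aggrescreen.errors import ConfigurationError, SchemaError, UndefinedValueError
from aggrescreen.synthdata import (
    OmicsSimConfig,
    planted_sets_with_overlap,
    simulate_omics,
)


def toy_matrix(values: np.ndarray, treatments: list[str]) -> om.OmicsMatrix:
    samples = [f"s{i}" for i in range(values.shape[1])]
    frame = pd.DataFrame(values, columns=samples,
                         index=[f"F{i}" for i in range(values.shape[0])])
    ann = pd.DataFrame({"treatment": treatments, "replicate": 1}, index=samples)
    return om.OmicsMatrix(values=frame, samples=ann)


class TestContainer:
    def test_duplicate_features_rejected(self):
        frame = pd.DataFrame(np.ones((2, 2)), index=["a", "a"], columns=["s0", "s1"])
        ann = pd.DataFrame({"treatment": ["x", "x"]}, index=["s0", "s1"])
        with pytest.raises(SchemaError, match="duplicate"):
            om.OmicsMatrix(values=frame, samples=ann)

    def test_unannotated_sample_rejected(self):
        frame = pd.DataFrame(np.ones((2, 2)), index=["a", "b"], columns=["s0", "s1"])
        ann = pd.DataFrame({"treatment": ["x"]}, index=["s0"])
        with pytest.raises(SchemaError, match="s1"):
            om.OmicsMatrix(values=frame, samples=ann)


class TestNormalizeLFQ:
    def test_hand_computed_matrix(self):
        """[[2,8],[8,2],[32,8]] -> log2 [[1,3],[3,1],[5,3]] -> centered."""
        m = toy_matrix(np.array([[2.0, 8.0], [8.0, 2.0], [32.0, 8.0]]), ["a", "a"])
        out = om.normalize_lfq(m)
        expected = np.array([[-2.0, 0.0], [0.0, -2.0], [2.0, 0.0]])
        np.testing.assert_allclose(out.values.to_numpy(), expected, atol=1e-12)

    def test_constant_sample_becomes_zero(self):
        m = toy_matrix(np.full((4, 2), 16.0), ["a", "a"])
        out = om.normalize_lfq(m)
        np.testing.assert_allclose(out.values.to_numpy(), 0.0, atol=1e-12)

    def test_sample_medians_zero(self):
        matrix, _ = simulate_omics(OmicsSimConfig(n_features=200, seed=1))
        out = om.normalize_lfq(matrix)
        np.testing.assert_allclose(out.values.median(axis=0).to_numpy(), 0.0, atol=1e-12)

    def test_idempotent(self):
        matrix, _ = simulate_omics(OmicsSimConfig(n_features=100, seed=2))
        once = om.normalize_lfq(matrix)
        twice = om.normalize_lfq(once)
        np.testing.assert_allclose(
            once.values.to_numpy(), twice.values.to_numpy(), atol=1e-12
        )

    def test_nonpositive_raw_rejected(self):
        with pytest.raises(UndefinedValueError):
            om.normalize_lfq(toy_matrix(np.array([[1.0, -2.0]]).T.reshape(2, 1).repeat(2, 1),
                                        ["a", "a"]))

    def test_sparse_sample_rejected(self):
        values = np.full((3, 2), np.nan)
        values[:, 0] = [2.0, 4.0, 8.0]
        values[0, 1] = 2.0
        with pytest.raises(UndefinedValueError):
            om.normalize_lfq(toy_matrix(values, ["a", "a"]))


class TestLog2FC:
    def test_identical_groups_zero(self):
        values = np.tile([[4.0], [16.0]], (1, 4))
        m = toy_matrix(values, ["ctrl", "ctrl", "trt", "trt"])
        fc = om.log2fc(m, "trt", "ctrl")
        np.testing.assert_allclose(fc.to_numpy(), 0.0, atol=1e-12)

    def test_doubling_of_one_feature_gives_unit_fc(self):
        # one feature doubles; the stable majority anchors the sample medians
        base = np.array(
            [
                [4.0, 4.0, 8.0, 8.0],  # doubled in treatment
                [16.0, 16.0, 16.0, 16.0],
                [64.0, 64.0, 64.0, 64.0],
                [256.0, 256.0, 256.0, 256.0],
            ]
        )
        m = toy_matrix(base, ["ctrl", "ctrl", "trt", "trt"])
        fc = om.log2fc(m, "trt", "ctrl")
        assert fc.iloc[0] == pytest.approx(1.0, abs=1e-12)
        np.testing.assert_allclose(fc.iloc[1:].to_numpy(), 0.0, atol=1e-12)

    def test_planted_shift_recovered(self):
        config = OmicsSimConfig(
            n_features=1000,
            groups={"control": 3, "drugA": 3},
            effect_sd=0.8,
            noise_sd=0.2,
            planted_sets={"drugA": frozenset(range(50))},
            seed=3,
        )
        matrix, truth = simulate_omics(config)
        fc = om.log2fc(matrix, "drugA", "control")
        se = config.noise_sd * np.sqrt(2.0 / 3.0)
        for fid in truth.planted_ids("drugA"):
            assert abs(abs(fc[fid]) - 0.8) <= 3 * se

    def test_underobserved_feature_flagged_nan(self):
        values = 2.0 ** np.random.default_rng(0).normal(10, 1, (3, 4))
        values[0, 2] = np.nan
        values[0, 3] = np.nan
        m = toy_matrix(values, ["ctrl", "ctrl", "trt", "trt"])
        fc = om.log2fc(m, "trt", "ctrl")
        assert np.isnan(fc.iloc[0])
        assert fc.iloc[1:].notna().all()


class TestAlteredSet:
    def test_no_flags_errors_with_guidance(self):
        m, _ = simulate_omics(OmicsSimConfig(n_features=20, seed=0))
        with pytest.raises(ConfigurationError, match="welch_flags"):
            om.altered_set(m, "drugA", "control")

    def test_zero_fc_empty(self):
        values = np.tile([[4.0], [16.0], [64.0]], (1, 4))
        m = toy_matrix(values, ["ctrl", "ctrl", "trt", "trt"])
        flags = pd.Series(True, index=m.values.index)
        assert len(om.altered_set(m, "trt", "ctrl", flags=flags)) == 0

    def test_boundary_inclusive(self):
        values = np.array(
            [[16.0, 16.0, 16.0 * 2**0.5, 16.0 * 2**0.5], [16.0, 16.0, 16.0, 16.0]]
        )
        m = om.OmicsMatrix(
            values=pd.DataFrame(np.log2(values), columns=["s0", "s1", "s2", "s3"],
                                index=["hit", "null"]),
            samples=pd.DataFrame({"treatment": ["c", "c", "t", "t"]},
                                 index=["s0", "s1", "s2", "s3"]),
            log_scale=True,
            median_centered=True,
        )
        flags = pd.Series(True, index=m.values.index)
        selected = om.altered_set(m, "t", "c", flags=flags).features
        assert selected == frozenset({"hit"})

    def test_size_monotone_in_cutoff(self):
        matrix, _ = simulate_omics(
            OmicsSimConfig(
                n_features=500,
                groups={"control": 3, "drugA": 3},
                effect_sd=1.0,
                planted_sets={"drugA": frozenset(range(100))},
                seed=4,
            )
        )
        flags = pd.Series(True, index=matrix.values.index)
        sizes = [
            len(om.altered_set(matrix, "drugA", "control", min_abs_log2fc=c, flags=flags))
            for c in (0.0, 0.25, 0.5, 0.75, 1.0, 1.5)
        ]
        assert sizes == sorted(sizes, reverse=True)

    def test_high_effect_recovers_planted_set(self):
        sets = planted_sets_with_overlap(("drugA", "drugB"), 800, 80, 0.5, seed=7)
        matrix, truth = simulate_omics(
            OmicsSimConfig(n_features=800, planted_sets=sets,
                           effect_sd=3.0, noise_sd=0.1, seed=7)
        )
        norm = om.normalize_lfq(matrix)
        for treatment in ("drugA", "drugB"):
            flags = om.welch_flags(norm, treatment, "control")
            recovered = om.altered_set(norm, treatment, "control", flags=flags)
            assert recovered.features == truth.planted_ids(treatment)


class TestOverlap:
    def test_identical_sets(self):
        s = frozenset({"a", "b", "c"})
        assert om.overlap_percent(s, s) == 100.0

    def test_disjoint_sets(self):
        assert om.overlap_percent(frozenset({"a"}), frozenset({"b"})) == 0.0

    def test_venn_arithmetic(self):
        assert om.overlap_percent(frozenset({1, 2}), frozenset({2, 3})) == pytest.approx(
            100.0 / 3.0
        )

    def test_both_empty_undefined(self):
        with pytest.raises(UndefinedValueError):
            om.overlap_percent(frozenset(), frozenset())

    def test_per_set_fractions(self):
        out = om.overlap_fractions(frozenset({1, 2, 3, 4}), frozenset({3, 4}))
        assert out == {"of_a": 50.0, "of_b": 100.0}

    @settings(deadline=None, max_examples=50)
    @given(
        a=st.frozensets(st.integers(0, 30), min_size=1, max_size=20),
        b=st.frozensets(st.integers(0, 30), max_size=20),
    )
    def test_symmetric_bounded_and_equality_iff_100(self, a, b):
        p = om.overlap_percent(a, b)
        assert p == om.overlap_percent(b, a)
        assert 0.0 <= p <= 100.0
        assert (p == 100.0) == (a == b)


class TestReplicateCorrelation:
    def test_duplicated_sample_unit_correlation(self):
        rng = np.random.default_rng(0)
        col = 2.0 ** rng.normal(10, 1, 30)
        m = toy_matrix(np.column_stack([col, col, 2.0 ** rng.normal(10, 1, 30)]),
                       ["a", "a", "b"])
        corr = om.replicate_correlation(m)
        assert corr.iloc[0, 1] == pytest.approx(1.0, abs=1e-12)

    def test_negated_sample(self):
        rng = np.random.default_rng(1)
        col = rng.normal(0, 1, 30)
        m = toy_matrix(np.column_stack([col, -col]), ["a", "a"])
        m.log_scale = True
        assert om.replicate_correlation(m).iloc[0, 1] == pytest.approx(-1.0, abs=1e-12)

    def test_matches_summation_oracle(self):
        from .test_imquant import pearson_oracle

        rng = np.random.default_rng(2)
        values = rng.normal(0, 1, (40, 5))
        m = toy_matrix(values, ["a"] * 5)
        corr = om.replicate_correlation(m)
        for i in range(5):
            for j in range(5):
                expect = 1.0 if i == j else pearson_oracle(values[:, i], values[:, j])
                assert corr.iloc[i, j] == pytest.approx(expect, abs=1e-12)

    def test_positive_semidefinite_when_complete(self):
        matrix, _ = simulate_omics(OmicsSimConfig(n_features=300, seed=5))
        corr = om.replicate_correlation(om.normalize_lfq(matrix))
        eigenvalues = np.linalg.eigvalsh(corr.to_numpy())
        assert eigenvalues.min() > -1e-10

    def test_sparse_pair_flagged_missing(self):
        values = np.full((5, 2), np.nan)
        values[:, 0] = [1, 2, 3, 4, 5]
        values[:2, 1] = [1.0, 2.0]
        m = toy_matrix(values, ["a", "a"])
        m.log_scale = True
        assert np.isnan(om.replicate_correlation(m).iloc[0, 1])


class TestClustering:
    def test_identical_profiles_merge_first_at_zero(self):
        rng = np.random.default_rng(0)
        a = rng.normal(0, 1, 50)
        profiles = pd.DataFrame({"p1": a, "p2": a, "p3": rng.normal(0, 1, 50)})
        dendro = om.cluster_samples(profiles)
        first = dendro.linkage[0]
        assert {int(first[0]), int(first[1])} == {0, 1}
        assert first[2] == pytest.approx(0.0, abs=1e-12)

    def test_too_few_profiles_rejected(self):
        with pytest.raises(UndefinedValueError):
            om.cluster_samples(pd.DataFrame(np.random.default_rng(0).random((10, 2))))

    def test_permutation_gives_same_partitions(self):
        matrix, _ = simulate_omics(OmicsSimConfig(n_features=300, effect_sd=2.0,
                                                  noise_sd=0.15, seed=6,
                                                  planted_sets={"drugA": frozenset(range(60)),
                                                                "drugB": frozenset(range(60, 120))}))
        profiles = om.log2fc_profiles(matrix, "control")
        d1 = om.cluster_samples(profiles)
        shuffled = profiles[list(profiles.columns[::-1])]
        d2 = om.cluster_samples(shuffled)
        assert d1.cut(2).items() >= {}.items()  # well-formed
        groups1 = {}
        for label, c in d1.cut(2).items():
            groups1.setdefault(c, set()).add(label)
        groups2 = {}
        for label, c in d2.cut(2).items():
            groups2.setdefault(c, set()).add(label)
        assert set(map(frozenset, groups1.values())) == set(map(frozenset, groups2.values()))

    def test_two_planted_groups_separate(self):
        """First split isolates the two treatment groups (several seeds)."""
        for seed in range(5):
            sets = planted_sets_with_overlap(("drugA", "drugB"), 400, 60, 0.0, seed=seed)
            matrix, _ = simulate_omics(
                OmicsSimConfig(n_features=400, planted_sets=sets,
                               effect_sd=2.0, noise_sd=0.2, seed=seed)
            )
            dendro = om.cluster_samples(om.log2fc_profiles(matrix, "control"))
            clusters = dendro.cut(2)
            by_group = {}
            for sample, c in clusters.items():
                by_group.setdefault(sample.split("_")[0], set()).add(c)
            assert all(len(v) == 1 for v in by_group.values())
            assert by_group["drugA"] != by_group["drugB"]

    def test_newick_contains_all_labels(self):
        rng = np.random.default_rng(3)
        profiles = pd.DataFrame(rng.normal(0, 1, (30, 4)), columns=list("abcd"))
        nwk = om.cluster_samples(profiles).newick()
        assert nwk.endswith(";")
        for label in "abcd":
            assert label in nwk
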