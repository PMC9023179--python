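import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from periopredict.preprocess import (
    AugmentationConfig,
    BalancePlan,
    BinningScheme,
    CategoryCounts,
    CleaningRules,
    EMERGENCE_SCHEME,
    EncodedDataset,
    PROV_AUGMENTED,
    PROV_ORIGINAL,
    PROV_REPLICA,
    PipelineConfig,
    SURGERY_SCHEME,
    SplitSpec,
    apply_balance,
    apply_normalization,
    augment,
    bin_duration,
    build_balance_plan,
    category_counts,
    clean,
    compute_balance_multiple,
    default_rules,
    fit_normalization,
    invert_normalization,
    one_hot,
    partition,
    preprocess_pipeline,
    un_hot,
)


def brute_force_multiple(n_i: int, n_max: int) -> int:
    """Independent oracle: argmin over m of |m*n_i - n_max|, ties -> larger m."""
    best_m, best_diff = None, None
    for m in range(1, 2 * n_max // n_i + 3):
        diff = abs(m * n_i - n_max)
        if best_diff is None or diff < best_diff or diff == best_diff:
            best_m, best_diff = m, diff
    return best_m


def make_dataset(classes, rng, width=24, ids=None):
    classes = np.asarray(classes)
    return EncodedDataset(
        rng.uniform(0.1, 0.9, size=(len(classes), width)),
        one_hot(classes),
        np.full(len(classes), PROV_ORIGINAL, dtype=object),
        ids,
    )


class TestClean:
    def test_excludes_over_cap_surgery(self, small_surgery_view):
        records = small_surgery_view.copy()
        records.loc[records.index[0], "duration_minutes"] = 250.0
        kept, n_removed = clean(records, default_rules("surgery"))
        assert n_removed == 1
        assert len(kept) == len(records) - 1

    def test_empty_input(self):
        empty = pd.DataFrame(columns=["A1", "duration_minutes"])
        kept, n_removed = clean(empty, default_rules("surgery"))
        assert len(kept) == 0 and n_removed == 0

    def test_count_matches_direct_filter(self, small_emergence_view):
        records = small_emergence_view.head(100).copy()
        idx = records.index[:7]
        records.loc[idx, "duration_minutes"] = 61.0  # 7 over-cap emergence durations
        kept, n_removed = clean(records, default_rules("emergence"))
        assert len(kept) == 93
        assert n_removed == 7

    def test_unknown_rule_attribute_errors(self, small_surgery_view):
        rules = CleaningRules(240.0, {"A99": (1, 2)})
        with pytest.raises(KeyError, match="A99"):
            clean(small_surgery_view, rules)

    def test_level_set_violations_removed(self, small_surgery_view):
        records = small_surgery_view.copy()
        records.loc[records.index[0], "A19"] = 9
        _, n_removed = clean(records, default_rules("surgery"))
        assert n_removed == 1


class TestNormalization:
    def test_endpoints(self):
        df = pd.DataFrame({"A1": [0.0, 5.0, 10.0]})
        params = fit_normalization(df, columns=("A1",))
        out = apply_normalization(df, params)
        assert out[0, 0] == pytest.approx(0.1)
        assert out[1, 0] == pytest.approx(0.5)
        assert out[2, 0] == pytest.approx(0.9)

    def test_constant_attribute_maps_to_midpoint(self):
        df = pd.DataFrame({"A1": [3.0, 3.0]})
        out = apply_normalization(df, fit_normalization(df, columns=("A1",)))
        assert (out == 0.5).all()

    def test_round_trip(self, rng):
        df = pd.DataFrame(rng.normal(size=(50, 4)) * 100, columns=["A1", "A2", "A3", "A4"])
        params = fit_normalization(df)
        back = invert_normalization(apply_normalization(df, params), params)
        np.testing.assert_allclose(back, df.to_numpy(), atol=1e-9)

    def test_missing_attribute_errors(self):
        df = pd.DataFrame({"A1": [1.0, 2.0]})
        params = fit_normalization(df)
        with pytest.raises(KeyError):
            apply_normalization(pd.DataFrame({"A2": [1.0]}), params)

    @given(
        st.lists(st.integers(-10**6, 10**6), min_size=2, max_size=30, unique=True).map(sorted)
    )
    @settings(max_examples=50, deadline=None)
    def test_monotone_and_in_range(self, values):
        df = pd.DataFrame({"A1": np.asarray(values, dtype=float)})
        out = apply_normalization(df, fit_normalization(df))[:, 0]
        assert (np.diff(out) > 0).all()
        assert out.min() == pytest.approx(0.1) and out.max() == pytest.approx(0.9)


class TestBinning:
    def test_surgery_30min_is_class_1(self):
        assert bin_duration(30.0, SURGERY_SCHEME) == 1

    def test_right_closed_boundary(self):
        assert bin_duration(60.0, SURGERY_SCHEME) == 1
        assert bin_duration(60.0001, SURGERY_SCHEME) == 2

    def test_emergence_45min_is_class_3(self):
        assert bin_duration(45.0, EMERGENCE_SCHEME) == 3

    def test_out_of_range_errors(self):
        for bad in (0.0, -5.0, 240.5):
            with pytest.raises(ValueError):
                bin_duration(bad, SURGERY_SCHEME)

    def test_scheme_validation(self):
        with pytest.raises(ValueError):
            BinningScheme((0.0, 60.0, 60.0, 180.0, 240.0))
        with pytest.raises(ValueError):
            BinningScheme((0.0, 60.0, 120.0))


class TestOneHot:
    def test_printed_codes(self):
        assert one_hot(1).tolist() == [1, 0, 0, 0]
        assert one_hot(4).tolist() == [0, 0, 0, 1]

    @pytest.mark.parametrize("c", [1, 2, 3, 4])
    def test_inverse(self, c):
        assert un_hot(one_hot(c)) == c

    def test_malformed_vector_rejected(self):
        with pytest.raises(ValueError):
            un_hot([1, 1, 0, 0])
        with pytest.raises(ValueError):
            un_hot([0, 0, 0, 0])

    def test_out_of_range_class_rejected(self):
        with pytest.raises(ValueError):
            one_hot(5)


class TestBalanceMultiple:
    @pytest.mark.parametrize(
        "n_i,n_max,expected",
        [(60, 100, 2), (30, 100, 3), (100, 100, 1), (40, 100, 3)],
    )
    def test_worked_examples(self, n_i, n_max, expected):
        assert compute_balance_multiple(n_i, n_max) == expected

    def test_domain_errors(self):
        with pytest.raises(ValueError):
            compute_balance_multiple(0, 100)
        with pytest.raises(ValueError):
            compute_balance_multiple(101, 100)

    @given(st.integers(1, 500), st.integers(1, 500))
    @settings(max_examples=300, deadline=None)
    def test_oracle_equivalence(self, a, b):
        n_i, n_max = min(a, b), max(a, b)
        assert compute_balance_multiple(n_i, n_max) == brute_force_multiple(n_i, n_max)


class TestBalancePlan:
    def test_worked_example_plan_and_sizes(self, rng):
        classes = np.array([1] * 60 + [2] * 30 + [3] * 100)
        ds = make_dataset(classes, rng)
        plan = build_balance_plan(category_counts(ds.classes))
        assert plan.multiples == {1: 2, 2: 3, 3: 1}  # class 4 empty, skipped
        balanced = apply_balance(ds, plan)
        counts = category_counts(balanced.classes)
        assert counts.n_i[1] == 120 and counts.n_i[2] == 90 and counts.n_i[3] == 100

    def test_balanced_input_is_identity(self, rng):
        ds = make_dataset([1] * 25 + [2] * 25 + [3] * 25 + [4] * 25, rng)
        plan = build_balance_plan(category_counts(ds.classes))
        assert set(plan.multiples.values()) == {1}
        assert len(apply_balance(ds, plan)) == len(ds)

    def test_replicas_are_exact_tagged_copies(self, rng):
        ds = make_dataset([1] * 10 + [2] * 40, rng)
        balanced = apply_balance(ds, build_balance_plan(category_counts(ds.classes)))
        replicas = balanced.provenance == PROV_REPLICA
        assert replicas.sum() == 30  # class 1 multiplied by 4: three extra copies
        originals = balanced.X[(balanced.classes == 1) & (balanced.provenance == PROV_ORIGINAL)]
        for row in balanced.X[replicas]:
            assert any(np.array_equal(row, orig) for orig in originals)

    def test_multiple_minimizes_residual(self, rng):
        ds = make_dataset([1] * 17 + [2] * 61 + [3] * 5 + [4] * 100, rng)
        counts = category_counts(ds.classes)
        plan = build_balance_plan(counts)
        for cls, m in plan.multiples.items():
            n_i = counts.n_i[cls]
            residual = abs(m * n_i - counts.n_max)
            for other in range(1, counts.n_max + 1):
                assert residual <= abs(other * n_i - counts.n_max)

    def test_empty_class_skipped_with_warning(self, rng, caplog):
        ds = make_dataset([1] * 10 + [2] * 5, rng)
        with caplog.at_level("WARNING", logger="periopredict.preprocess"):
            plan = build_balance_plan(category_counts(ds.classes))
        assert 3 not in plan.multiples and 4 not in plan.multiples
        assert "undefined" in caplog.text

    def test_plan_validation(self):
        with pytest.raises(ValueError):
            BalancePlan({1: 0})
        with pytest.raises(ValueError):
            CategoryCounts({1: -1})


class TestAugment:
    def test_total_size_reading(self, rng):
        ds = make_dataset([1] * 5 + [2] * 5, rng)
        out = augment(ds, AugmentationConfig(multiple=3, seed=0))
        assert len(out) == 30
        assert (out.provenance == PROV_AUGMENTED).sum() == 20

    def test_additive_reading(self, rng):
        ds = make_dataset([1] * 10, rng)
        out = augment(ds, AugmentationConfig(multiple=3, seed=0, additive=True))
        assert len(out) == 40

    def test_m1_is_identity(self, rng):
        ds = make_dataset([1, 2, 3, 4], rng)
        assert augment(ds, AugmentationConfig(multiple=1, seed=0)) is ds

    def test_noise_bound(self, rng):
        ds = make_dataset([1] * 50, rng)
        out = augment(ds, AugmentationConfig(multiple=10, seed=5))
        src = np.tile(ds.X, (10, 1))
        assert np.abs(out.X - src).max() <= 0.03

    def test_targets_unchanged(self, rng):
        classes = [1, 2, 3, 4] * 10
        ds = make_dataset(classes, rng)
        out = augment(ds, AugmentationConfig(multiple=4, seed=1))
        np.testing.assert_array_equal(out.Y, np.tile(ds.Y, (4, 1)))

    def test_seeded_reproducibility(self, rng):
        ds = make_dataset([1] * 20, rng)
        a = augment(ds, AugmentationConfig(multiple=3, seed=9))
        b = augment(ds, AugmentationConfig(multiple=3, seed=9))
        np.testing.assert_array_equal(a.X, b.X)

    def test_invalid_multiple(self):
        with pytest.raises(ValueError):
            AugmentationConfig(multiple=0)


class TestPartition:
    def test_printed_sizes(self, rng):
        ds = make_dataset(rng.integers(1, 5, size=1000), rng)
        train, test, val = partition(ds, SplitSpec(seed=0))
        assert (len(train), len(test), len(val)) == (600, 200, 200)

    def test_single_record(self, rng):
        ds = make_dataset([2], rng)
        train, test, val = partition(ds, SplitSpec(seed=0))
        assert (len(train), len(test), len(val)) == (0, 0, 1)

    def test_conservation_and_disjointness(self, rng):
        n = 157
        ds = make_dataset(rng.integers(1, 5, size=n), rng, ids=np.arange(n))
        train, test, val = partition(ds, SplitSpec(seed=3))
        all_ids = np.concatenate([train.ids, test.ids, val.ids])
        assert sorted(all_ids) == list(range(n))

    def test_bad_ratios(self):
        with pytest.raises(ValueError):
            SplitSpec(ratios=(0.5, 0.2, 0.2))


class TestPipeline:
    def test_worked_example_counts_before_partition(self, rng):
        # classes 60/30/100 with M=1: balanced sizes 120/90/100 = 310 total
        minutes = np.concatenate([
            rng.uniform(1, 60, 60), rng.uniform(61, 120, 30), rng.uniform(121, 180, 100),
        ])
        records = pd.DataFrame({
            "case_id": np.arange(190),
            **{f"A{i}": rng.uniform(0, 1, 190) for i in range(1, 25)},
            "duration_minutes": minutes,
        })
        cfg = PipelineConfig(
            system="surgery", enrichment_multiple=1, seed=0,
            rules=CleaningRules(240.0),
        )
        result = preprocess_pipeline(records, cfg)
        assert result.report["after_balance"] == 310
        counts = category_counts(
            np.concatenate([result.train.classes, result.test.classes, result.validation.classes])
        )
        assert counts.n_i == {1: 120, 2: 90, 3: 100, 4: 0}

    def test_m3_split_arithmetic(self, rng):
        # 310 balanced records, M=3 -> 930 split 558/186/186
        minutes = np.concatenate([
            rng.uniform(1, 60, 60), rng.uniform(61, 120, 30), rng.uniform(121, 180, 100),
        ])
        records = pd.DataFrame({
            "case_id": np.arange(190),
            **{f"A{i}": rng.uniform(0, 1, 190) for i in range(1, 25)},
            "duration_minutes": minutes,
        })
        cfg = PipelineConfig(
            system="surgery", enrichment_multiple=3, seed=0, rules=CleaningRules(240.0),
        )
        result = preprocess_pipeline(records, cfg)
        assert result.report["after_augment"] == 930
        sizes = (len(result.train), len(result.test), len(result.validation))
        assert sizes == (558, 186, 186)

    def test_identity_path_is_pure_split(self, small_surgery_view):
        cfg = PipelineConfig(
            system="surgery", enrichment_multiple=1, balance=False, seed=2,
        )
        result = preprocess_pipeline(small_surgery_view, cfg)
        total = len(result.train) + len(result.test) + len(result.validation)
        assert total == result.report["after_clean"]
        for ds in (result.train, result.test, result.validation):
            assert (ds.provenance == PROV_ORIGINAL).all()

    def test_leakage_safe_keeps_replicas_in_train(self, small_surgery_view):
        cfg = PipelineConfig(system="surgery", enrichment_multiple=3, mode="leakage_safe", seed=2)
        result = preprocess_pipeline(small_surgery_view, cfg)
        assert (result.test.provenance == PROV_ORIGINAL).all()
        assert (result.validation.provenance == PROV_ORIGINAL).all()
        assert (result.train.provenance != PROV_ORIGINAL).any()
        # no source record crosses split boundaries
        assert set(result.train.ids) & set(result.test.ids) == set()
        assert set(result.train.ids) & set(result.validation.ids) == set()

    def test_unknown_mode_errors(self, small_surgery_view):
        with pytest.raises(ValueError, match="mode"):
            preprocess_pipeline(small_surgery_view, PipelineConfig(mode="bogus"))

    def test_label_preservation(self, small_surgery_view):
        cfg = PipelineConfig(system="surgery", enrichment_multiple=3, seed=5)
        result = preprocess_pipeline(small_surgery_view, cfg)
        for ds in (result.train, result.test, result.validation):
            assert (ds.Y.sum(axis=1) == 1).all()
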