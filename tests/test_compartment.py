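import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from _oracle import oracle_per_million
from clonalhsc._constants import CELL_TYPES, FRACTIONS
from clonalhsc.compartment import (
    ClonalCompartmentModel,
    FractionFrequencies,
    aggregate_groups,
    aging_table,
    bootstrap_ci,
    composition,
    composition_chisq,
    estimate_per_million,
    fold_change,
)
from clonalhsc.reference import GROUPS, published_frequencies


def calls_frame(entries):
    """entries: list of (cell_type, fraction) or (cell_type, fraction, n)."""
    rows = []
    i = 0
    for e in entries:
        cell_type, fraction, n = (*e, 1) if len(e) == 2 else e
        for _ in range(n):
            rows.append(
                {
                    "clone_id": f"c{i:04d}",
                    "age_group": "young",
                    "fraction": fraction,
                    "cell_type": cell_type,
                    "latent": cell_type == "latent-HSC",
                }
            )
            i += 1
    return pd.DataFrame(rows)


def random_calls(rng, n_per_fraction=(5, 30)):
    entries = []
    types = list(CELL_TYPES)
    for f in FRACTIONS:
        n = int(rng.integers(*n_per_fraction))
        for t in rng.choice(types, size=n):
            entries.append((t, f))
    return calls_frame(entries)


def random_freqs(rng):
    raw = rng.uniform(0.05, 1.0, size=3)
    shares = raw / raw.sum() * rng.uniform(0.6, 1.0)
    return FractionFrequencies(
        age_group="young",
        phsc_per_million=float(rng.uniform(10, 1000)),
        shares=dict(zip(FRACTIONS, shares.tolist())),
    )


class TestComposition:
    def test_proportions_within_fraction(self):
        calls = calls_frame([("LT-HSC", "F1", 6), ("ST-MkRP", "F1", 4)])
        p = composition(calls)
        assert p.loc["LT-HSC", "F1"] == pytest.approx(0.6)
        assert p.loc["ST-MkRP", "F1"] == pytest.approx(0.4)
        assert p["F1"].sum() == pytest.approx(1.0)

    def test_single_type_identity(self):
        calls = calls_frame([("ST-HSC", f, 3) for f in FRACTIONS])
        p = composition(calls)
        assert (p.loc["ST-HSC"] == 1.0).all()

    def test_row_permutation_invariance(self):
        calls = calls_frame(
            [("LT-HSC", "F1", 3), ("other", "F2", 2), ("ST-MkRP", "F3", 4)]
        )
        shuffled = calls.sample(frac=1.0, random_state=1)
        pd.testing.assert_frame_equal(composition(calls), composition(shuffled))

    def test_empty_required_fraction_named_in_error(self):
        calls = calls_frame([("LT-HSC", "F1", 3)])
        with pytest.raises(ValueError, match="F2"):
            composition(calls, fractions=FRACTIONS)

    def test_non_fraction_labels_rejected(self):
        calls = calls_frame([("LT-HSC", "F1", 2)])
        calls.loc[0, "fraction"] = "CD34-KSL"
        with pytest.raises(ValueError, match="non-fraction"):
            composition(calls)


class TestEstimatePerMillion:
    def test_conservation_when_shares_cover_compartment(self):
        calls = calls_frame([("IT-HSC", f, 4) for f in FRACTIONS])
        freqs = FractionFrequencies(
            "young", 100.0, {"F1": 0.5, "F2": 0.3, "F3": 0.2}
        )
        est = estimate_per_million(composition(calls), freqs)
        assert est.per_million["IT-HSC"] == pytest.approx(100.0)
        assert est.per_million.sum() == pytest.approx(100.0)

    def test_single_fraction_arithmetic(self):
        calls = calls_frame([("LT-HSC", "F1", 2), ("other", "F1", 8)])
        freqs = FractionFrequencies("young", 100.0, {"F1": 0.5})
        est = estimate_per_million(composition(calls), freqs)
        assert est.per_million["LT-HSC"] == pytest.approx(10.0)

    def test_mismatched_fraction_keys_rejected(self):
        calls = calls_frame([("LT-HSC", "F1", 2)])
        freqs = FractionFrequencies("young", 100.0, {"F1": 0.4, "F2": 0.4})
        with pytest.raises(ValueError, match="F2"):
            estimate_per_million(composition(calls), freqs)

    @pytest.mark.parametrize("seed", range(4))
    def test_matches_per_clone_weight_oracle(self, seed):
        rng = np.random.default_rng(seed)
        for _ in range(30):
            calls = random_calls(rng)
            freqs = random_freqs(rng)
            est = estimate_per_million(
                composition(calls, fractions=FRACTIONS), freqs
            )
            expected = oracle_per_million(
                calls, freqs.phsc_per_million, freqs.shares
            )
            for t in CELL_TYPES:
                assert est.per_million[t] == pytest.approx(
                    expected.get(t, 0.0), abs=1e-9
                ), t

    @given(
        n1=st.integers(1, 20), n2=st.integers(1, 20), n3=st.integers(1, 20),
        scale=st.floats(0.1, 100.0),
    )
    @settings(max_examples=30, deadline=None)
    def test_conservation_and_scale_equivariance(self, n1, n2, n3, scale):
        """sum_t F_t = N * sum_f s_f exactly; scaling N scales F_t and leaves
        fold changes unchanged."""
        rng = np.random.default_rng(n1 * 441 + n2 * 21 + n3)
        calls = calls_frame(
            [("LT-HSC", "F1", n1), ("ST-MkRP", "F2", n2), ("other", "F3", n3)]
        )
        freqs = random_freqs(rng)
        p = composition(calls, fractions=FRACTIONS)
        est = estimate_per_million(p, freqs)
        total = freqs.phsc_per_million * freqs.total_share
        assert est.per_million.sum() == pytest.approx(total, rel=1e-12)
        assert est.composition.sum() == pytest.approx(1.0, rel=1e-12)

        scaled = FractionFrequencies(
            "young", freqs.phsc_per_million * scale, freqs.shares
        )
        est2 = estimate_per_million(p, scaled)
        np.testing.assert_allclose(
            est2.per_million.to_numpy(), est.per_million.to_numpy() * scale
        )


class TestFoldChange:
    @pytest.mark.parametrize(
        "young, aged, expected",
        [(7.3, 21.0, 2.9), (10.8, 52.4, 4.9), (0.0, 2.0, "n/a"), (6.7, 35.1, 5.2)],
    )
    def test_reported_arithmetic(self, young, aged, expected):
        assert fold_change(young, aged) == expected

    def test_half_away_from_zero_rounding(self):
        assert fold_change(2.0, 4.9) == 2.5  # 2.45 rounds up, not to even
        assert fold_change(1.0, 0.25) == 0.3

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            fold_change(-1.0, 2.0)


class TestAggregateGroups:
    def test_published_group_folds(self):
        pub = published_frequencies()
        grouped = aggregate_groups(pub, GROUPS)
        assert grouped.loc["HSC", "fold"] == 5.2
        assert grouped.loc["ST-MyRP", "fold"] == 7.5

    def test_unknown_label_rejected(self):
        pub = published_frequencies()
        with pytest.raises(KeyError):
            aggregate_groups(pub, {"bad": ("nonexistent",)})

    def test_label_in_two_groups_rejected(self):
        pub = published_frequencies()
        with pytest.raises(ValueError, match="assigned to both"):
            aggregate_groups(
                pub, {"a": ("LT-HSC",), "b": ("LT-HSC", "IT-HSC")}
            )


class TestBootstrapCI:
    def test_degenerate_composition_gives_zero_width(self):
        calls = calls_frame([("IT-HSC", f, 5) for f in FRACTIONS])
        freqs = FractionFrequencies("young", 80.0, {"F1": 0.5, "F2": 0.25, "F3": 0.25})
        ci = bootstrap_ci(calls, freqs, B=200, seed=0)
        assert ci.loc["IT-HSC", "lower"] == pytest.approx(80.0)
        assert ci.loc["IT-HSC", "upper"] == pytest.approx(80.0)
        assert (ci.drop("IT-HSC")[["lower", "upper"]] == 0).all().all()

    def test_deterministic_per_seed_and_stable_in_B(self):
        rng = np.random.default_rng(7)
        calls = random_calls(rng, n_per_fraction=(20, 40))
        freqs = random_freqs(rng)
        ci_a = bootstrap_ci(calls, freqs, B=1000, seed=5)
        ci_b = bootstrap_ci(calls, freqs, B=1000, seed=5)
        pd.testing.assert_frame_equal(ci_a, ci_b)
        ci_2B = bootstrap_ci(calls, freqs, B=2000, seed=6)
        width = (ci_a["upper"] - ci_a["lower"]).replace(0, np.nan).dropna()
        for t in width.index:
            tol = 0.35 * width[t] + 1e-9
            assert abs(ci_2B.loc[t, "lower"] - ci_a.loc[t, "lower"]) < tol
            assert abs(ci_2B.loc[t, "upper"] - ci_a.loc[t, "upper"]) < tol

    def test_tiny_fraction_flagged_unreliable(self):
        calls = calls_frame(
            [("LT-HSC", "F1", 10), ("LT-HSC", "F2", 1), ("other", "F3", 10)]
        )
        freqs = FractionFrequencies("young", 50.0, {"F1": 0.4, "F2": 0.3, "F3": 0.3})
        ci = bootstrap_ci(calls, freqs, B=200, seed=0)
        assert ci.attrs["unreliable"]

    def test_rejects_bad_parameters(self):
        calls = calls_frame([("LT-HSC", f, 5) for f in FRACTIONS])
        freqs = random_freqs(np.random.default_rng(0))
        with pytest.raises(ValueError):
            bootstrap_ci(calls, freqs, B=10)
        with pytest.raises(ValueError):
            bootstrap_ci(calls, freqs, B=200, level=1.5)


class TestCompositionChisq:
    def test_identical_compositions(self):
        y = np.array([10, 5, 3])
        stat, df, p = composition_chisq(y, y)
        assert stat == pytest.approx(0.0)
        assert p == pytest.approx(1.0)
        assert df == 2

    def test_disjoint_two_by_two(self):
        stat, df, p = composition_chisq(np.array([10, 0]), np.array([0, 10]))
        assert stat == pytest.approx(20.0)
        assert df == 1

    def test_matches_closed_form_pearson(self):
        rng = np.random.default_rng(3)
        for _ in range(20):
            k = int(rng.integers(2, 8))
            y = rng.integers(0, 30, size=k).astype(float)
            a = rng.integers(0, 30, size=k).astype(float)
            if y.sum() == 0 or a.sum() == 0 or ((y + a) > 0).sum() < 2:
                continue
            stat, df, p = composition_chisq(y, a)
            keep = (y + a) > 0
            yk, ak = y[keep], a[keep]
            col = yk + ak
            grand = col.sum()
            expected_stat = 0.0
            for row, row_total in ((yk, yk.sum()), (ak, ak.sum())):
                e = col * row_total / grand
                expected_stat += ((row - e) ** 2 / e).sum()
            assert stat == pytest.approx(expected_stat, rel=1e-10)
            assert df == keep.sum() - 1

    def test_empty_categories_ignored(self):
        y = np.array([10, 5, 0, 3])
        a = np.array([8, 9, 0, 1])
        stat1, df1, _ = composition_chisq(y, a)
        stat2, df2, _ = composition_chisq(y[[0, 1, 3]], a[[0, 1, 3]])
        assert stat1 == pytest.approx(stat2)
        assert df1 == df2

    def test_all_zero_rejected(self):
        with pytest.raises(ValueError):
            composition_chisq(np.zeros(3), np.array([1.0, 2.0, 3.0]))


class TestModelResults:
    def test_fit_summary_and_intervals(self):
        calls = calls_frame(
            [("LT-HSC", "F1", 12), ("ST-MkRP", "F2", 8), ("other", "F3", 10),
             ("non-reconstituting", "F1", 6)]
        )
        freqs = FractionFrequencies("young", 67.3, {"F1": 0.45, "F2": 0.03, "F3": 0.52})
        res = ClonalCompartmentModel(calls, freqs).fit(bootstrap=200, seed=1)
        assert res.n_clones == 36
        assert res.per_million.sum() == pytest.approx(67.3)
        ci = res.conf_int()
        assert (ci["lower"] <= res.per_million + 1e-9).all()
        assert (res.per_million <= ci["upper"] + 1e-9).all()
        text = res.summary()
        assert "young" in text and "LT-HSC" in text

    def test_unfractionated_clones_excluded_from_estimation(self):
        calls = calls_frame([("LT-HSC", f, 5) for f in FRACTIONS])
        extra = calls_frame([("LT-HSC", "F1", 2)])
        extra["fraction"] = "CD34-KSL"
        model = ClonalCompartmentModel(
            pd.concat([calls, extra], ignore_index=True),
            FractionFrequencies("young", 50.0, {"F1": 0.4, "F2": 0.3, "F3": 0.3}),
        )
        assert model.n_unfractionated == 2
        assert len(model.calls) == 15

    def test_aging_table_folds_and_groups(self):
        freqs_y = FractionFrequencies("young", 100.0, {"F1": 1.0})
        freqs_a = FractionFrequencies("aged", 300.0, {"F1": 1.0})
        calls_y = calls_frame([("LT-HSC", "F1", 5), ("ST-HSC", "F1", 5)])
        calls_a = calls_frame([("LT-HSC", "F1", 5), ("ST-HSC", "F1", 5)])
        res_y = ClonalCompartmentModel(calls_y, freqs_y).fit(bootstrap=None)
        res_a = ClonalCompartmentModel(calls_a, freqs_a).fit(bootstrap=None)
        table = aging_table(res_y, res_a, groups={"HSC": ("LT-HSC", "ST-HSC")})
        assert table.loc["LT-HSC", "fold"] == 3.0
        assert table.loc["HSC", "young"] == pytest.approx(100.0)
        assert table.loc["HSC", "fold"] == 3.0
        assert table.loc["IT-MkSC", "fold"] == "n/a"


class TestParameterRecovery:
    def test_truth_inside_bootstrap_interval_for_most_types(self, presets):
        """On preset cohorts (2,000 clones/age) the true per-million
        frequency lies within the 95% bootstrap CI for >= 90% of types."""
        from clonalhsc.classify import classify_cohort
        from clonalhsc.simulate import simulate_cohort

        for scen, seed in zip(presets, (51, 52)):
            cohort, _ = simulate_cohort(scen, 2000, seed=seed)
            calls = classify_cohort(cohort)
            res = ClonalCompartmentModel(
                calls, scen.fraction_frequencies
            ).fit(bootstrap=1000, seed=seed)
            ci = res.conf_int()
            truth = scen.expected_per_million()
            covered = sum(
                ci.loc[t, "lower"] - 1e-9 <= truth.get(t, 0.0) <= ci.loc[t, "upper"] + 1e-9
                for t in CELL_TYPES
            )
            assert covered / len(CELL_TYPES) >= 0.9, scen.age_group
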