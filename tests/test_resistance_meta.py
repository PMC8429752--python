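"""Effect-size arithmetic, resistance classes, mixed model, quantiles, bias."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import coldrange as cr
from coldrange import InvalidInputError
from coldrange.resistance_meta import compute_effect_sizes, records_to_frame


def make_record(rr=10.0, lc_f=2.0, lc_s=0.2, se_f=0.5, se_s=0.05,
                n_f=200, n_s=200, year=2008, lat=30.0, lon=0.0,
                pesticide="p0", drop_ci_field=False):
    ci_f = None if drop_ci_field else (lc_f - 1.96 * se_f, lc_f + 1.96 * se_f)
    return cr.ResistanceRecord(
        pesticide=pesticide, moa_group="moa_0", latitude=lat, longitude=lon,
        year=year, rr=rr, lc50_field=lc_f, lc50_susceptible=lc_s,
        ci_field=ci_f, ci_susceptible=(lc_s - 1.96 * se_s, lc_s + 1.96 * se_s),
        n_field=n_f, n_susceptible=n_s,
    )


class TestSeFromCi:
    @pytest.mark.parametrize("ci,expected", [((1.0, 4.92), 1.0), ((5, 5), 0.0),
                                             ((0, 7.84), 2.0)])
    def test_values(self, ci, expected):
        assert cr.se_from_ci(ci) == pytest.approx(expected)

    def test_inverted_ci_rejected(self):
        with pytest.raises(InvalidInputError):
            cr.se_from_ci((2.0, 1.0))


class TestPooledVariance:
    def test_hand_computed_value(self):
        # field term 2^2/(4*1^2) = 1, susceptible term 0
        rec = make_record(lc_f=1.0, se_f=2.0, n_f=4, se_s=0.0, n_s=3, lc_s=5.0)
        assert cr.pooled_variance(rec) == pytest.approx(1.0, abs=1e-12)

    def test_zero_ses_give_zero(self):
        rec = make_record(se_f=0.0, se_s=0.0)
        assert cr.pooled_variance(rec) == 0.0

    def test_symmetric_in_population_roles(self):
        a = make_record(lc_f=2.0, se_f=0.4, n_f=100, lc_s=0.5, se_s=0.1, n_s=50)
        b = make_record(lc_f=0.5, se_f=0.1, n_f=50, lc_s=2.0, se_s=0.4, n_s=100)
        assert cr.pooled_variance(a) == pytest.approx(cr.pooled_variance(b))

    def test_missing_ingredient_signals_nan(self):
        assert np.isnan(cr.pooled_variance(make_record(drop_ci_field=True)))


class TestImputation:
    def test_mean_of_complete_entries(self):
        filled, flags = cr.impute_variance([1.0, np.nan, 3.0])
        assert filled.tolist() == [1.0, 2.0, 3.0]
        assert flags.tolist() == [False, True, False]

    def test_no_missing_unchanged(self):
        filled, flags = cr.impute_variance([0.5, 1.5])
        assert filled.tolist() == [0.5, 1.5]
        assert not flags.any()

    def test_single_complete_entry_propagates(self):
        filled, _ = cr.impute_variance([np.nan, 4.0, np.nan])
        assert filled.tolist() == [4.0, 4.0, 4.0]

    def test_all_missing_rejected(self):
        with pytest.raises(InvalidInputError):
            cr.impute_variance([np.nan, np.nan])


class TestEffectSize:
    def test_identity_ratio(self):
        e = cr.effect_size(make_record(rr=1.0), v=1.0)
        assert e.log_rr == 0.0 and e.wlog_rr == 0.0

    def test_weight_is_inverse_root_variance(self):
        assert cr.effect_size(make_record(), v=4.0).w == pytest.approx(0.5)

    def test_unit_weighted_effect(self):
        e = cr.effect_size(make_record(rr=float(np.e)), v=1.0)
        assert e.wlog_rr == pytest.approx(1.0)

    def test_chain_integrity_on_random_records(self, rng):
        """Hand-composed SE -> V -> w -> wlogRR matches effect_size to 1e-12."""
        for _ in range(50):
            rec = make_record(
                rr=float(rng.lognormal(2, 1.5)),
                lc_f=float(rng.lognormal(0, 1)), lc_s=float(rng.lognormal(-2, 1)),
                se_f=float(rng.uniform(0.01, 1)), se_s=float(rng.uniform(0.001, 0.1)),
                n_f=int(rng.integers(50, 500)), n_s=int(rng.integers(50, 500)),
            )
            v_hand = (cr.se_from_ci(rec.ci_field) ** 2
                      / (rec.n_field * rec.lc50_field ** 2)
                      + cr.se_from_ci(rec.ci_susceptible) ** 2
                      / (rec.n_susceptible * rec.lc50_susceptible ** 2))
            e = cr.effect_size(rec, cr.pooled_variance(rec))
            assert e.v == pytest.approx(v_hand, abs=1e-12)
            assert e.wlog_rr == pytest.approx(np.log(rec.rr) / np.sqrt(v_hand), rel=1e-12)


class TestClassification:
    @pytest.mark.parametrize("rr,level", [
        (0.5, "susceptible"), (1.0, "susceptible"), (1.0001, "low"),
        (9.999, "low"), (10.0, "moderate"), (99.9, "moderate"),
        (100.0, "high"), (999.9, "high"), (1000.0, "extremely_high"),
        (1e6, "extremely_high"),
    ])
    def test_boundaries(self, rr, level):
        assert cr.classify_resistance(rr) == level

    def test_nonpositive_rejected(self):
        with pytest.raises(InvalidInputError):
            cr.classify_resistance(0.0)

    @settings(deadline=None, max_examples=100)
    @given(rr=st.floats(1e-6, 1e9, allow_nan=False))
    def test_partition_property(self, rr):
        assert cr.classify_resistance(rr) in cr.resistance_meta.RESISTANCE_LEVELS


class TestWeightedMeanRR:
    def frame(self, rrs, ws, groups):
        return pd.DataFrame({"rr": rrs, "log_rr": np.log(rrs), "w": ws,
                             "ow_type": groups})

    def test_all_equal_rr_returns_it(self):
        df = self.frame([7.0, 7.0, 7.0], [1.0, 2.0, 5.0], ["a"] * 3)
        assert cr.weighted_mean_rr(df)["a"] == pytest.approx(7.0)

    def test_equal_weights_geometric_mean(self):
        df = self.frame([1.0, 100.0], [3.0, 3.0], ["a", "a"])
        assert cr.weighted_mean_rr(df)["a"] == pytest.approx(10.0)

    def test_invariant_to_order_and_weight_scale(self, rng):
        rrs = rng.lognormal(1, 1, size=30)
        ws = rng.uniform(0.5, 5, size=30)
        groups = rng.choice(["a", "b"], size=30)
        df = self.frame(rrs, ws, groups)
        shuffled = df.sample(frac=1, random_state=0)
        scaled = self.frame(rrs, 10 * ws, groups)
        base = cr.weighted_mean_rr(df)
        assert np.allclose(base, cr.weighted_mean_rr(shuffled).loc[base.index])
        assert np.allclose(base, cr.weighted_mean_rr(scaled).loc[base.index])


class TestLevelFrequencies:
    def test_single_record_is_certain(self):
        df = pd.DataFrame({"level": ["high"], "ow_type": ["permanent"]})
        freq = cr.level_frequencies(df)
        assert freq.loc["permanent", "high"] == 1.0

    def test_rows_sum_to_one(self, annotated_records):
        freq = cr.level_frequencies(annotated_records)
        assert np.allclose(freq.sum(axis=1), 1.0)


class TestAnnotation:
    def test_same_site_year_identical(self, toy_grid, lab_model):
        recs = [make_record(lat=float(toy_grid.lats[2]), lon=float(toy_grid.lons[1]))
                for _ in range(2)]
        ann = cr.annotate_sites(compute_effect_sizes(recs), toy_grid, lab_model)
        assert ann["ltdd_5yr"].nunique() == 1
        assert ann["ow_type"].nunique() == 1

    def test_warm_site_is_permanent(self, toy_grid, lab_model):
        equator_lat = float(toy_grid.lats[np.argmin(np.abs(toy_grid.lats))])
        rec = make_record(lat=equator_lat)
        ann = cr.annotate_sites(compute_effect_sizes([rec]), toy_grid, lab_model)
        assert ann["ow_type"].iloc[0] == "permanent"

    def test_uncovered_year_dropped_not_fatal(self, toy_grid, lab_model):
        good = make_record(lat=0.0, year=2008)
        bad = make_record(lat=0.0, year=1990)
        ann = cr.annotate_sites(compute_effect_sizes([good, bad]), toy_grid, lab_model)
        assert len(ann) == 1
        assert ann.attrs["n_dropped_coverage"] == 1

    def test_ow_type_consistent_with_survival(self, annotated_records):
        s = annotated_records["winter_survival_5yr"]
        t = annotated_records["ow_type"]
        assert ((s >= 0.05) == (t == "permanent")).all()
        assert (((s >= 0.01) & (s < 0.05)) == (t == "marginal")).all()


class TestMixedModel:
    def test_term_table_shape_and_pvalues(self, annotated_records):
        res = cr.mixed_model_anova(annotated_records)
        table = res["table"]
        assert list(table["source"]) == [
            "overwintering type", "pesticide variety", "ETDD",
            "pesticide variety:overwintering type", "ETDD:pesticide variety",
        ]
        assert ((table["p"] >= 0) & (table["p"] <= 1)).all()
        assert (table["chi2"] >= 0).all()
        assert res["converged"]

    def test_strong_injected_effect_detected(self, annotated_records):
        res = cr.mixed_model_anova(annotated_records)
        ow = res["table"].set_index("source").loc["overwintering type"]
        assert ow["p"] < 0.05  # generator injects a ~158-fold contrast

    def test_wald_matches_ols_z_when_no_grouping_variance(self, rng):
        """With one record per group the fit degenerates to OLS; the
        2-level factor's Wald chi2 must match the OLS squared z."""
        import statsmodels.api as sm

        n = 400
        ow = rng.choice(["permanent", "transient"], size=n)
        pest = rng.choice(["pa", "pb"], size=n)
        etdd = rng.normal(0, 1, size=n)
        y = 1.0 * (ow == "permanent") + 0.5 * (pest == "pb") + 0.2 * etdd \
            + rng.normal(0, 1, size=n)
        df = pd.DataFrame({
            "wlog_rr": y, "ow_type": ow, "pesticide": pest,
            "etdd_5yr": etdd, "site_year": [f"g{i}" for i in range(n)],
        })
        res = cr.mixed_model_anova(df)
        ow_chi2 = res["table"].set_index("source").loc["overwintering type", "chi2"]

        etdd_c = (etdd - etdd.mean()) / etdd.std()
        X = np.column_stack([
            np.ones(n), ow == "transient", pest == "pb", etdd_c,
            (pest == "pb") & (ow == "transient"), etdd_c * (pest == "pb"),
        ]).astype(float)
        ols = sm.OLS(y, X).fit()
        z2 = (ols.params[1] / ols.bse[1]) ** 2
        assert ow_chi2 == pytest.approx(z2, rel=0.05)

    def test_single_level_factor_rejected(self):
        df = pd.DataFrame({"wlog_rr": [1.0, 2.0], "ow_type": ["a", "a"],
                           "pesticide": ["p", "q"], "etdd_5yr": [1.0, 2.0],
                           "site_year": ["g1", "g2"]})
        with pytest.raises(InvalidInputError):
            cr.mixed_model_anova(df)


class TestQuantileModel:
    def test_constant_rr_gives_zero_slope(self):
        df = pd.DataFrame({"rr": [10.0] * 20, "ltdd_5yr": np.linspace(0, 100, 20)})
        res = cr.quantile_model(df, tau=0.85)
        assert res["slope"] == pytest.approx(0.0, abs=1e-8)

    def test_median_matches_l1_brute_force(self, rng):
        """tau=0.5 equals the best L1 line found by enumerating point pairs."""
        n = 50
        x = rng.uniform(0, 1000, size=n)
        y = 2.0 - 0.001 * x + rng.standard_t(df=4, size=n) * 0.4
        df = pd.DataFrame({"rr": 10.0**y, "ltdd_5yr": x})
        res = cr.quantile_model(df, tau=0.5)

        best = np.inf
        for i in range(n):
            for j in range(i + 1, n):
                if x[i] == x[j]:
                    continue
                slope = (y[j] - y[i]) / (x[j] - x[i])
                intercept = y[i] - slope * x[i]
                best = min(best, np.abs(y - intercept - slope * x).sum())
        got = np.abs(y - res["intercept"] - res["slope"] * x).sum()
        assert got == pytest.approx(best, rel=1e-6)

    def test_degenerate_design_rejected(self):
        df = pd.DataFrame({"rr": np.linspace(1, 5, 15), "ltdd_5yr": np.ones(15)})
        with pytest.raises(InvalidInputError):
            cr.quantile_model(df)


class TestResistanceMap:
    def test_zero_slope_constant_over_unmasked(self):
        qm = {"intercept": 2.0, "slope": 0.0}
        host = cr.HostMask(np.array([[0.9, 0.1], [0.5, 0.95]]))
        out = cr.predict_resistance_map(qm, np.array([[0.0, 10.0], [5.0, 50.0]]),
                                        host, np.array([0.0, 1.0]), np.array([0.0, 1.0]))
        assert len(out) == 3  # masked cell excluded
        assert np.allclose(out["log10_rr_top"], 2.0)

    def test_single_cell_matches_scalar_prediction(self):
        qm = {"intercept": 1.0, "slope": 0.002}
        host = cr.HostMask(np.array([[0.8]]))
        out = cr.predict_resistance_map(qm, np.array([[300.0]]), host,
                                        np.array([10.0]), np.array([20.0]))
        assert out["log10_rr_top"].iloc[0] == pytest.approx(1.6)

    def test_geometry_mismatch_rejected(self):
        with pytest.raises(InvalidInputError):
            cr.predict_resistance_map({"intercept": 0, "slope": 0},
                                      np.zeros((2, 2)), cr.HostMask(np.zeros((3, 3))),
                                      np.zeros(2), np.zeros(2))


class TestPublicationBias:
    def frame(self, log_rr, n_field):
        return pd.DataFrame({"log_rr": log_rr, "n_field": n_field})

    def test_perfect_monotone_gives_tau_one(self):
        df = self.frame(np.arange(12, dtype=float), np.arange(12) * 10 + 50)
        res = cr.publication_bias(df)
        assert res["kendall_tau"] == pytest.approx(1.0)

    def test_reversal_negates_tau(self, rng):
        x = rng.normal(size=20)
        n = rng.integers(50, 500, size=20).astype(float)
        t1 = cr.publication_bias(self.frame(x, n))["kendall_tau"]
        t2 = cr.publication_bias(self.frame(x, n[::-1] * 0 + n.max() - n + 50))["kendall_tau"]
        assert t2 == pytest.approx(-t1)

    def test_tied_inputs_flagged(self):
        df = self.frame(np.ones(12), np.arange(12, dtype=float))
        res = cr.publication_bias(df)
        assert res["degenerate"] and np.isnan(res["kendall_tau"])


def test_effect_size_table_pipeline(rng):
    recs = [make_record(rr=float(rng.lognormal(1, 1)),
                        drop_ci_field=(i % 5 == 0)) for i in range(20)]
    df = compute_effect_sizes(recs)
    assert df["imputed_v"].sum() == 4
    assert (df["w"] > 0).all()
    assert np.allclose(df["wlog_rr"], df["log_rr"] * df["w"])
    complete = df.loc[~df["imputed_v"], "v"]
    assert np.allclose(df.loc[df["imputed_v"], "v"], complete.mean())
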