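"""Dip statistic, bimodality filtering, GCV weighting and model
averaging."""

import numpy as np
import pytest

from scaaverage._unimodal_oracle import dip_lp_oracle
from scaaverage.ensemble import (
    ModelVariant,
    dip_statistic,
    dip_test,
    filter_variants,
    gcv_weights,
    model_average,
    summarize_ensemble,
)


def make_variant(label_id, mortality, harvest_rates, gcvs=None, n_years=3):
    """Variant whose iterations end at the given final-year harvest rates."""
    harvest_rates = np.asarray(harvest_rates, dtype=float)
    iterations = [
        {
            "recruitment": np.full(n_years, 1.0 + i),
            "ssb": np.full(n_years, 10.0 + i),
            "fbar": np.full(n_years, 0.1 * (i + 1)),
            "catch": np.full(n_years, 5.0),
            "harvest_rate": np.linspace(0.1, hr, n_years),
        }
        for i, hr in enumerate(harvest_rates)
    ]
    gcvs = np.ones(harvest_rates.size) if gcvs is None else np.asarray(gcvs, float)
    return ModelVariant(
        sa_config_id=label_id, mortality_model=mortality, iterations=iterations,
        gcvs=gcvs, years=np.arange(2000, 2000 + n_years),
    )


class TestDipStatistic:
    def test_two_point_masses(self):
        assert dip_statistic([0, 0, 1, 1]) == pytest.approx(0.25)

    def test_lower_bound_any_sample(self):
        rng = np.random.default_rng(0)
        for n in (2, 5, 17, 100):
            s = rng.normal(size=n)
            assert dip_statistic(s) >= 1.0 / (2 * n) - 1e-12

    def test_constant_sample_at_lower_bound(self):
        assert dip_statistic(np.full(20, 3.0)) == pytest.approx(1 / 40)

    def test_too_small_rejected(self):
        with pytest.raises(ValueError):
            dip_statistic([1.0])

    @pytest.mark.parametrize("seed", range(20))
    def test_matches_lp_oracle_small_samples(self, seed):
        """Exact agreement with the brute-force linear-programming oracle on
        random samples of size 4..8 (ties included)."""
        rng = np.random.default_rng(seed)
        n = int(rng.integers(4, 9))
        if seed % 3 == 0:
            s = rng.integers(0, 3, size=n).astype(float)  # heavy ties
        else:
            s = rng.normal(size=n)
        want = max(dip_lp_oracle(s), 1.0 / (2 * n))
        assert dip_statistic(s) == pytest.approx(want, abs=1e-6)

    def test_matches_lp_oracle_medium_sample(self):
        rng = np.random.default_rng(123)
        s = np.r_[rng.normal(-2, 0.5, 20), rng.normal(2, 0.5, 20)]
        assert dip_statistic(s) == pytest.approx(dip_lp_oracle(s), abs=1e-9)


class TestDipTest:
    def test_bimodal_mixture_rejected(self):
        rng = np.random.default_rng(5)
        s = np.r_[rng.normal(0, 0.1, 250), rng.normal(10, 0.1, 250)]
        res = dip_test(s, n_boot=200, seed=1)
        assert res.rejected and res.p_value < 0.01

    def test_unimodal_normal_not_rejected(self):
        rng = np.random.default_rng(6)
        res = dip_test(rng.normal(size=500), n_boot=200, seed=2)
        assert not res.rejected

    def test_constant_sample_not_rejected(self):
        res = dip_test(np.full(50, 1.0), n_boot=200, seed=3)
        assert res.dip == pytest.approx(1 / 100)
        assert not res.rejected

    def test_input_validation(self):
        with pytest.raises(ValueError):
            dip_test(np.ones(5), n_boot=200)
        with pytest.raises(ValueError):
            dip_test(np.ones(50), n_boot=50)


class TestFilterVariants:
    def test_bimodal_variant_rejected_unimodal_retained(self):
        rng = np.random.default_rng(7)
        good = make_variant(1, "constant", rng.normal(0.5, 0.05, 100))
        bad = make_variant(2, "gislason", np.r_[rng.normal(0.2, 0.01, 50), rng.normal(1.5, 0.01, 50)])
        retained, report = filter_variants([good, bad], n_boot=200, seed=0)
        assert [v.sa_config_id for v in retained] == [1]
        assert report.loc[report.variant == bad.label, "rejected"].item()

    def test_insufficient_iterations_rejected_with_reason(self):
        small = make_variant(3, "constant", [0.5, 0.6])
        retained, report = filter_variants([small], n_boot=200, seed=0)
        assert retained == []
        assert report["reason"].iloc[0] == "insufficient iterations"

    def test_empty_input(self):
        retained, report = filter_variants([], n_boot=200, seed=0)
        assert retained == [] and report.empty


class TestGcvWeights:
    def test_inverse_median_weighting(self):
        a = make_variant(1, "constant", np.full(12, 0.5), gcvs=np.full(12, 1.0))
        b = make_variant(2, "constant", np.full(12, 0.5), gcvs=np.full(12, 3.0))
        w = gcv_weights([a, b])
        np.testing.assert_allclose(w, [0.75, 0.25])

    def test_equal_medians_equal_weights(self):
        vs = [make_variant(i, "constant", np.full(12, 0.5), gcvs=np.full(12, 2.0)) for i in range(3)]
        np.testing.assert_allclose(gcv_weights(vs), 1 / 3)

    def test_single_variant_weight_one(self):
        v = make_variant(1, "constant", np.full(12, 0.5))
        np.testing.assert_allclose(gcv_weights([v]), [1.0])

    def test_sum_to_one_and_rescale_invariance(self):
        rng = np.random.default_rng(8)
        vs = [
            make_variant(i, "constant", np.full(12, 0.5), gcvs=rng.lognormal(0, 1, 12))
            for i in range(5)
        ]
        w = gcv_weights(vs)
        assert abs(w.sum() - 1.0) < 1e-12
        scaled = [
            ModelVariant(v.sa_config_id, v.mortality_model, v.iterations, v.gcvs * 17.3, v.years)
            for v in vs
        ]
        np.testing.assert_allclose(gcv_weights(scaled), w, rtol=1e-12)

    def test_non_positive_gcv_rejected(self):
        v = make_variant(1, "constant", np.full(12, 0.5), gcvs=np.zeros(12))
        with pytest.raises(ValueError):
            gcv_weights([v])


class TestModelAverage:
    def test_degenerate_weights_select_single_variant(self):
        a = make_variant(1, "constant", np.full(20, 0.5))
        b = make_variant(2, "gislason", np.full(20, 0.7))
        res = model_average([a, b], np.array([1.0, 0.0]), n_select=15, seed=0)
        assert all(v == a.label for v, _ in res.provenance)

    def test_selection_frequencies_match_weights(self):
        """Across 10^4 selections, per-variant frequencies are within 2% of
        the weights."""
        n = 12_000
        a = make_variant(1, "constant", np.full(n, 0.5))
        b = make_variant(2, "gislason", np.full(n, 0.7))
        res = model_average([a, b], np.array([0.7, 0.3]), n_select=10_000, seed=1)
        freq_a = np.mean([v == a.label for v, _ in res.provenance])
        assert abs(freq_a - 0.7) < 0.02

    def test_no_iteration_selected_twice(self):
        a = make_variant(1, "constant", np.linspace(0.2, 0.8, 50))
        b = make_variant(2, "gislason", np.linspace(0.2, 0.8, 60))
        res = model_average([a, b], np.array([0.5, 0.5]), n_select=50, seed=2)
        assert len(set(res.provenance)) == len(res.provenance)

    def test_n_select_beyond_minimum_rejected(self):
        a = make_variant(1, "constant", np.full(20, 0.5))
        with pytest.raises(ValueError):
            model_average([a], np.array([1.0]), n_select=21, seed=0)

    def test_reproducible_under_seed(self):
        a = make_variant(1, "constant", np.linspace(0.2, 0.8, 30))
        b = make_variant(2, "gislason", np.linspace(0.2, 0.8, 30))
        r1 = model_average([a, b], np.array([0.6, 0.4]), n_select=20, seed=9)
        r2 = model_average([a, b], np.array([0.6, 0.4]), n_select=20, seed=9)
        assert r1.provenance == r2.provenance


class TestSummarizeEnsemble:
    def test_single_iteration_all_quantiles_equal(self):
        v = make_variant(1, "constant", [0.5])
        res = model_average([v], np.array([1.0]), n_select=1, seed=0)
        df = summarize_ensemble(res, quantiles=(0.1, 0.5, 0.9))
        for (_, year), grp in df.groupby(["quantity", "year"]):
            assert grp["value"].nunique() == 1

    def test_quantiles_monotone(self):
        v = make_variant(1, "constant", np.linspace(0.1, 0.9, 40))
        res = model_average([v], np.array([1.0]), n_select=40, seed=0)
        df = summarize_ensemble(res, quantiles=(0.1, 0.5, 0.9))
        for (_, year), grp in df.groupby(["quantity", "year"]):
            vals = grp.sort_values("quantile")["value"].to_numpy()
            assert np.all(np.diff(vals) >= -1e-12)

    def test_median_of_three(self):
        vals = np.quantile([1.0, 2.0, 3.0], 0.5)
        assert vals == 2.0
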