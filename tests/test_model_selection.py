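"""AICc, Akaike weights, evidence ratios, peaks, bins, and comparisons."""

import math

import numpy as np
import pytest

from densimm.candidate_models import CANONICAL_ORDER, FitResult, mean_function
from densimm.experiment_io import RemovalEvent, SiteSeries
from densimm.model_selection import (
    BinStat,
    DensityDependenceSelector,
    aicc,
    akaike_weights,
    bin_summary,
    compare_site,
    cross_site_summary,
    evidence_ratio,
    peak_location,
    vacancy_fill_summary,
)
from densimm.published import SITE_ORDER, aicc_column
from densimm.scaling import ScaledPoint, ScaledSeries


def _dummy_fit(name: str, aicc_value: float, a=1.0, b=1.0) -> FitResult:
    K = 2 if name == "DI" else 3
    return FitResult(
        function=name,
        family="negative_binomial",
        a=None if name == "DI" else a,
        b=b,
        nuisance=1.0,
        loglik=0.0,
        k_params=K,
        n=12,
        aicc=aicc_value,
        converged=True,
    )


class TestAICc:
    @pytest.mark.parametrize(
        "logL,K,n,expected",
        [
            (0.0, 2, 12, 4 + 12 / 9),  # 5.3333
            (-10.0, 3, 14, 20 + 6 + 2.4),  # 28.4
        ],
    )
    def test_formula(self, logL, K, n, expected):
        assert aicc(logL, K, n) == pytest.approx(expected, rel=1e-12)

    def test_large_n_limit_is_aic(self):
        # at n = 1e7 the small-sample correction is 2K(K+1)/(n-K-1) ~ 2.4e-6
        assert aicc(-5.0, 3, 10**7) == pytest.approx(10 + 6, abs=1e-5)

    def test_domain_error(self):
        with pytest.raises(ValueError):
            aicc(0.0, 3, 4)


class TestAkaikeWeights:
    def test_published_hb3_column(self):
        w = akaike_weights([51.20, 49.91, 50.17, 54.23, 62.31, 41.29])
        assert np.round(w, 3).tolist() == [0.007, 0.013, 0.011, 0.001, 0.000, 0.967]

    def test_symmetry(self):
        assert akaike_weights([10.0, 10.0, 10.0]) == pytest.approx([1 / 3] * 3)

    def test_two_unit_gaps(self):
        w = akaike_weights([10.0, 12.0, 14.0])
        # exp(0), exp(-1), exp(-2) normalised
        e = np.exp([0.0, -1.0, -2.0])
        assert w == pytest.approx(e / e.sum(), abs=1e-10)
        assert np.round(w, 4).tolist() == [0.6652, 0.2447, 0.0900]

    def test_sum_and_shift_invariance(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            scores = rng.uniform(10, 90, size=int(rng.integers(2, 9)))
            w = akaike_weights(scores)
            assert w.sum() == pytest.approx(1.0, abs=1e-12)
            assert akaike_weights(scores + 123.4) == pytest.approx(w, abs=1e-12)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            akaike_weights([])


class TestEvidenceRatio:
    def test_from_published_weights(self):
        assert evidence_ratio(0.967, 0.007) == pytest.approx(138.14, abs=0.01)
        assert evidence_ratio(0.008, 0.623) == pytest.approx(0.0128, abs=0.0001)

    def test_self_comparison_is_one(self):
        assert evidence_ratio(0.4, 0.4) == 1.0

    def test_zero_denominator_is_infinity_not_error(self):
        assert math.isinf(evidence_ratio(0.5, 0.0))


class TestCompareSite:
    def test_best_di_for_hb2_column(self):
        fits = {n: _dummy_fit(n, v) for n, v in zip(CANONICAL_ORDER, aicc_column("HB2"))}
        table = compare_site(fits, site_id="HB2", scaling="per_site")
        assert table.best == "DI"
        assert [r.function for r in table.rows] == list(CANONICAL_ORDER)
        assert table.weight("DI") == pytest.approx(0.380, abs=0.001)

    def test_best_rdd_for_hb3_column(self):
        fits = {n: _dummy_fit(n, v) for n, v in zip(CANONICAL_ORDER, aicc_column("HB3"))}
        assert compare_site(fits).best == "RDD"

    def test_tie_breaks_toward_fewer_parameters(self):
        aiccs = [30.0, 30.0, 31.0, 32.0, 33.0, 34.0]  # DI and LDD tied
        fits = {n: _dummy_fit(n, v) for n, v in zip(CANONICAL_ORDER, aiccs)}
        assert compare_site(fits).best == "DI"

    def test_non_converged_fit_flagged_and_excluded(self):
        fits = {n: _dummy_fit(n, v) for n, v in zip(CANONICAL_ORDER, aicc_column("HB3"))}
        fits["RDD"].converged = False
        with pytest.warns(UserWarning, match="RDD"):
            table = compare_site(fits)
        assert table.best != "RDD"
        assert not table.row("RDD").converged
        # weights over converged rows still sum to 1
        assert sum(r.weight for r in table.rows) == pytest.approx(1.0, abs=1e-9)


class TestCrossSiteSummary:
    def _tables(self):
        tables = []
        for site in SITE_ORDER:
            fits = {n: _dummy_fit(n, v) for n, v in zip(CANONICAL_ORDER, aicc_column(site))}
            tables.append(compare_site(fits, site_id=site, scaling="per_site"))
        return tables

    def test_published_columns_mean_ratio(self):
        """Weights recomputed from the printed AICc columns reproduce the
        study's cross-site summary (31.3, range 0.01-142.0)."""
        summary = cross_site_summary(self._tables(), "RDD", "DI")
        assert summary.mean == pytest.approx(31.3, rel=0.02)
        assert summary.sd == pytest.approx(51.3, rel=0.02)
        assert summary.min == pytest.approx(0.01, abs=0.005)
        assert summary.max == pytest.approx(142.0, rel=0.02)

    def test_single_table(self):
        t = self._tables()[:1]
        s = cross_site_summary(t, "RDD", "DI")
        assert s.sd == 0.0
        assert s.min == s.max == pytest.approx(s.mean)

    def test_equal_ratios_give_zero_sd(self):
        fits = {n: _dummy_fit(n, v) for n, v in zip(CANONICAL_ORDER, [10, 11, 12, 13, 14, 15])}
        t1 = compare_site(fits, site_id="a")
        t2 = compare_site(fits, site_id="b")
        s = cross_site_summary([t1, t2], "RDD", "DI")
        assert s.sd == 0.0

    def test_infinite_ratio_flagged(self):
        fits = {n: _dummy_fit(n, v) for n, v in zip(CANONICAL_ORDER, [10, 11, 12, 13, 14, 15])}
        good = compare_site(fits, site_id="good")
        bad = compare_site(fits, site_id="bad")
        bad.rows[0].weight = 0.0  # denominator weight hits zero after rounding
        with pytest.warns(UserWarning, match="infinite"):
            s = cross_site_summary([good, bad], "RDD", "DI")
        assert s.n_infinite == 1


class TestPeakLocation:
    def test_rdd_peak(self):
        fit = _dummy_fit("RDD", 0.0, a=2.0, b=0.1)
        peak = peak_location(fit, n_initial=50)
        assert peak.density == pytest.approx(10.0)
        assert peak.value == pytest.approx(2.0 * 10.0 * math.exp(-1.0), rel=1e-9)
        assert peak.proportion == pytest.approx(0.20)

    def test_pdd_vertex(self):
        fit = _dummy_fit("PDD", 0.0, a=0.05, b=2.0)
        peak = peak_location(fit, n_initial=100)
        assert peak.density == pytest.approx(20.0)
        assert peak.value == pytest.approx(20.0)

    def test_monotone_functions_have_no_peak(self):
        for name in ("DI", "LDD", "EDD", "SDD"):
            assert peak_location(_dummy_fit(name, 0.0), 60) == (None, None, None)

    def test_rdd_without_interior_peak_flagged(self):
        assert peak_location(_dummy_fit("RDD", 0.0, a=2.0, b=0.0), 60).density is None

    def test_matches_dense_grid_argmax(self):
        """Closed-form peaks agree with a brute-force grid search."""
        rng = np.random.default_rng(21)
        for _ in range(20):
            name = "RDD" if rng.random() < 0.5 else "PDD"
            a = float(rng.uniform(0.02, 3.0))
            b = float(rng.uniform(0.02, 1.0))
            fit = _dummy_fit(name, 0.0, a=a, b=b)
            peak = peak_location(fit, n_initial=60)
            grid = np.linspace(0, 200, 400_001)
            vals = mean_function(name, a, b, grid)
            d_star = grid[np.argmax(vals)]
            assert peak.density == pytest.approx(d_star, abs=grid[1] - grid[0])
            # grid argmax undershoots the true maximum by O(curvature * step^2)
            assert peak.value == pytest.approx(vals.max(), rel=1e-5, abs=1e-7)


class TestBinSummary:
    def test_two_points_one_bin(self):
        s = ScaledSeries("A", "per_site", [ScaledPoint(0.05, 1.0), ScaledPoint(0.08, 3.0)])
        out = bin_summary(s, 0.1)
        assert out == [BinStat(0.05, 2.0, 1.0, 2)]

    def test_singleton_bin_has_zero_se(self):
        s = ScaledSeries("A", "per_site", [ScaledPoint(0.25, 4.0)])
        assert bin_summary(s, 0.1) == [BinStat(0.25, 4.0, 0.0, 1)]

    def test_zero_density_is_its_own_bin(self):
        s = ScaledSeries(
            "A",
            "per_site",
            [ScaledPoint(0.0, 0.0), ScaledPoint(0.0, 2.0), ScaledPoint(0.05, 5.0)],
        )
        out = bin_summary(s, 0.1)
        assert out[0].center == 0.0 and out[0].mean == 1.0 and out[0].n == 2
        assert out[1].center == pytest.approx(0.05) and out[1].n == 1

    def test_empty_series_gives_empty_list(self):
        assert bin_summary(ScaledSeries("A", "per_site", []), 0.1) == []


class TestVacancyFill:
    def test_median_of_simple_fills(self):
        sites = [
            SiteSeries(
                "A",
                12,
                [
                    RemovalEvent(1, 4, 8, 0),
                    RemovalEvent(2, 4, 4, 1),
                    RemovalEvent(3, 4, 1, 2),
                ],
            )
        ]
        med, lo, hi, n = vacancy_fill_summary(sites, bootstrap_reps=200, seed=0)
        assert med == pytest.approx(0.25)
        assert n == 3

    def test_degenerate_bootstrap_ci(self):
        # a single event: every bootstrap resample is identical
        one = [SiteSeries("B", 5, [RemovalEvent(1, 4, 1, 1)])]
        med, lo, hi, n = vacancy_fill_summary(one, bootstrap_reps=100, seed=1)
        assert med == lo == hi == 0.25

    def test_beta_binomial_regime_recovers_study_median(self):
        """77 events with fills around 0.25: the pooled median lands inside
        its own bootstrap CI and near the generating median."""
        rng = np.random.default_rng(42)
        p = rng.beta(2.0, 6.0, 77)  # mean 0.25, overdispersed
        removed = rng.integers(7, 11, 77)
        events, prev = [], None
        sites = []
        for i, (pi, r) in enumerate(zip(p, removed)):
            imm = rng.binomial(r, pi)
            sites.append(
                SiteSeries(
                    f"s{i}", int(r) + 1, [RemovalEvent(1, int(r), 1, int(imm))]
                )
            )
        med, lo, hi, n = vacancy_fill_summary(sites, bootstrap_reps=2000, seed=7)
        assert n == 77
        assert lo <= med <= hi
        assert med == pytest.approx(0.25, abs=0.1)

    def test_no_qualifying_events_is_error(self):
        sites = [SiteSeries("A", 6, [RemovalEvent(0, 0, 6, 0)])]
        with pytest.raises(ValueError):
            vacancy_fill_summary(sites)


class TestSelector:
    def test_selector_finds_hump_on_clean_ricker_counts(self):
        rng = np.random.default_rng(17)
        D = np.tile(np.arange(0.0, 61.0, 4.0), 3)
        mu = 2.0 * D * np.exp(-0.1 * D)
        y = rng.poisson(mu).astype(float)
        sel = DensityDependenceSelector(family="negative_binomial").fit(D, y)
        assert sel.best_function_ == "RDD"
        assert sel.weights_["RDD"] > 0.5
        assert (sel.predict(D) >= 0).all()
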