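"""Trait-table pipeline: cleaning, density fitting, diversity, regression,
abundance randomization, and the synthetic fixture generator."""

import numpy as np
import pandas as pd
import pytest

from ecoevodiv import (
    GridSpec,
    TraitTable,
    abundance_randomization,
    clean,
    fit_species_density,
    generate_fixture,
    sd_fd_regression,
    subcommunity_summary,
)
from ecoevodiv.empirical import BinormalDensity, summaries_to_frame


def _toy_table():
    rng = np.random.default_rng(0)
    rows = []
    for island, zone, species_counts in [
        ("FL", "arid", {"a": 20, "b": 20}),
        ("FL", "humid", {"c": 15}),
        ("CH", "arid", {"d": 10}),
        ("ES", "humid", {"e": 12, "rare": 2}),
    ]:
        for sp, n in species_counts.items():
            pts = rng.normal(size=(n, 2)) * 0.3 + rng.uniform(-1, 1, 2)
            for x, y in pts:
                rows.append({"species": sp, "island": island, "zone": zone,
                             "size": x, "shapePC1": y})
    hp = {("FL", "arid"): 4, ("FL", "humid"): 6, ("CH", "arid"): 3,
          ("ES", "humid"): 5}
    return TraitTable(data=pd.DataFrame(rows), host_plants=hp)


class TestClean:
    def test_excluded_island_removed(self):
        cleaned, report = clean(_toy_table())
        assert "CH" not in set(cleaned.data["island"])
        assert report.n_island_excluded == 10
        assert report.excluded_islands == ("CH",)

    def test_undersampled_species_removed(self):
        cleaned, report = clean(_toy_table())
        assert "rare" not in set(cleaned.data["species"])
        assert report.n_rare_species_excluded == 2
        assert "rare" in report.excluded_species

    def test_clean_table_unchanged_with_zero_report(self):
        cleaned, _ = clean(_toy_table())
        again, report = clean(cleaned)
        assert report.n_island_excluded == 0
        assert report.n_rare_species_excluded == 0
        assert again.data.equals(cleaned.data)

    def test_everything_excluded_raises(self):
        t = _toy_table()
        with pytest.raises(ValueError):
            clean(t, excluded_islands={"FL", "CH", "ES"})


class TestFitSpeciesDensity:
    def test_ml_covariance_of_corner_points(self):
        """Four points at (+-1, +-1): mean 0, 1/n covariance identity."""
        pts = np.array([[1, 1], [1, -1], [-1, 1], [-1, -1]], dtype=float)
        dens = fit_species_density(pts, "binormal_mle")
        np.testing.assert_allclose(dens.mean, [0, 0])
        np.testing.assert_allclose(dens.cov, np.eye(2))

    def test_identical_points_raise_singular(self):
        pts = np.ones((5, 2))
        with pytest.raises(ValueError, match="kde"):
            fit_species_density(pts, "binormal_mle")

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError):
            fit_species_density(np.zeros((2, 2)), "binormal_mle")

    def test_parameter_recovery_within_3se(self, rng):
        mean = np.array([0.3, -0.2])
        cov = np.array([[0.04, 0.01], [0.01, 0.02]])
        n = 4000
        pts = rng.multivariate_normal(mean, cov, size=n)
        dens = fit_species_density(pts, "binormal_mle")
        se_mean = np.sqrt(np.diag(cov) / n)
        np.testing.assert_array_less(np.abs(dens.mean - mean), 3 * se_mean)
        # covariance entries: SE ~ sqrt((c_ii c_jj + c_ij^2)/n)
        for i in range(2):
            for j in range(2):
                se = np.sqrt((cov[i, i] * cov[j, j] + cov[i, j] ** 2) / n)
                assert abs(dens.cov[i, j] - cov[i, j]) < 3 * se

    def test_binormal_pdf_normalized(self):
        dens = BinormalDensity(mean=np.zeros(2), cov=np.diag([0.04, 0.09]))
        g = GridSpec(L=2, bins_per_dim=161, lo=-2, hi=2)
        total = dens.pdf(g.centers()).sum() * g.cell_width**2
        assert total == pytest.approx(1.0, abs=1e-4)

    def test_kde_runs_and_normalizes(self, rng):
        pts = rng.normal(size=(200, 2)) * 0.2
        dens = fit_species_density(pts, "kde")
        g = GridSpec(L=2, bins_per_dim=121, lo=-2, hi=2)
        total = dens.pdf(g.centers()).sum() * g.cell_width**2
        assert total == pytest.approx(1.0, abs=1e-2)


class TestSubcommunitySummary:
    def test_single_species_diversity_one(self):
        cleaned, _ = clean(_toy_table())
        summaries = subcommunity_summary(cleaned)
        by_key = {(s.island, s.zone): s for s in summaries}
        s = by_key[("FL", "humid")]
        assert s.S == 1
        assert s.species_diversity_q2 == pytest.approx(1.0)
        assert s.normalized_diversity == pytest.approx(1 / 6)

    def test_equal_abundances_and_hostplant_normalization(self):
        cleaned, _ = clean(_toy_table())
        summaries = subcommunity_summary(cleaned)
        s = {(x.island, x.zone): x for x in summaries}[("FL", "arid")]
        assert s.species_diversity_q2 == pytest.approx(2.0)  # 20/20 split
        assert s.normalized_diversity == pytest.approx(0.5)  # host plants = 4
        assert 0 < s.functional_diversity <= 1

    def test_zones_never_pooled(self):
        cleaned, _ = clean(_toy_table())
        summaries = subcommunity_summary(cleaned)
        keys = {(s.island, s.zone) for s in summaries}
        assert ("FL", "arid") in keys and ("FL", "humid") in keys

    def test_fd_close_to_truth_on_well_sampled_fixture(self, rng):
        """Plug-in FD from fitted densities tracks FD from the true densities."""
        from ecoevodiv.empirical import _rescale, _shared_frame
        from ecoevodiv.metrics import functional_diversity_from_values

        table, truth = generate_fixture(
            n_subcommunities=4, species_per_subcommunity=[6, 6, 6, 6],
            n_per_species=500, sd_fd_slope_sign=1, rng=rng, sampling_jitter=0.0,
        )
        grid = GridSpec(L=2)
        summaries = subcommunity_summary(table, grid)
        lo, hi = _shared_frame(table.data)
        scale = 2.0 / (hi - lo)
        for s in summaries:
            info = truth[(s.island, s.zone)]
            dens = np.zeros(grid.C)
            S = len(info["species"])
            for spec in info["species"].values():
                m = _rescale(spec["mean"], lo, hi)
                cov = spec["cov"] * np.outer(scale, scale)
                dens += BinormalDensity(mean=m, cov=cov).pdf(grid.centers()) / S
            fd_true = functional_diversity_from_values(dens, 2.0, grid)
            assert s.functional_diversity == pytest.approx(fd_true, rel=0.02)

    def test_binormal_and_kde_agree_on_well_sampled_clusters(self, rng):
        table, _ = generate_fixture(
            n_subcommunities=3, species_per_subcommunity=3, n_per_species=2000,
            sd_fd_slope_sign=1, rng=rng,
        )
        a = subcommunity_summary(table, density_method="binormal_mle")
        b = subcommunity_summary(table, density_method="kde")
        for sa, sb in zip(a, b):
            assert sa.functional_diversity == pytest.approx(
                sb.functional_diversity, rel=0.10
            )


class TestRegression:
    def _summaries_from_xy(self, x, y):
        from ecoevodiv.empirical import SubcommunitySummary

        return [
            SubcommunitySummary(
                island=f"I{i}", zone="arid", S=2, n_individuals=10,
                species_diversity_q2=xi * 5, host_plants=5,
                normalized_diversity=xi, functional_diversity=yi,
            )
            for i, (xi, yi) in enumerate(zip(x, y))
        ]

    def test_exact_line_recovered(self):
        x = np.array([0.1, 0.2, 0.3, 0.4])
        res = sd_fd_regression(self._summaries_from_xy(x, 2 * x + 1))
        assert res.slope == pytest.approx(2.0)
        assert res.p_value < 1e-10

    def test_constant_response_gives_zero_slope(self):
        x = np.array([0.1, 0.2, 0.3, 0.4])
        res = sd_fd_regression(self._summaries_from_xy(x, np.full(4, 0.5)))
        assert res.slope == pytest.approx(0.0, abs=1e-12)

    def test_degenerate_predictor_rejected(self):
        x = np.full(4, 0.2)
        with pytest.raises(ValueError, match="variance"):
            sd_fd_regression(self._summaries_from_xy(x, x))


class TestAbundanceRandomization:
    def test_deterministic_given_seed(self):
        table, _ = generate_fixture(
            n_subcommunities=5, species_per_subcommunity=4, n_per_species=30,
            sd_fd_slope_sign=-1, rng=np.random.default_rng(3),
        )
        a = abundance_randomization(table, 5, np.random.default_rng(7))
        b = abundance_randomization(table, 5, np.random.default_rng(7))
        np.testing.assert_array_equal(a.slopes, b.slopes)

    def test_strong_negative_gradient_retained(self):
        table, _ = generate_fixture(
            n_subcommunities=8, species_per_subcommunity=8, n_per_species=40,
            sd_fd_slope_sign=-1, rng=np.random.default_rng(11),
        )
        res = abundance_randomization(table, 60, np.random.default_rng(4))
        assert res.fraction_negative > 0.9

    def test_multinomial_mode_runs(self):
        table, _ = generate_fixture(
            n_subcommunities=4, species_per_subcommunity=4, n_per_species=30,
            sd_fd_slope_sign=-1, rng=np.random.default_rng(5),
        )
        res = abundance_randomization(
            table, 10, np.random.default_rng(1), mode="multinomial"
        )
        assert 0.0 <= res.fraction_negative <= 1.0


class TestGenerateFixture:
    def test_record_counts_without_jitter(self):
        table, truth = generate_fixture(
            n_subcommunities=3, species_per_subcommunity=[2, 3, 4],
            n_per_species=20, sd_fd_slope_sign=-1,
            rng=np.random.default_rng(0), sampling_jitter=0.0,
        )
        assert len(table.data) == 20 * (2 + 3 + 4)
        assert len(table.subcommunities) == 3

    def test_ground_truth_matches_table(self):
        table, truth = generate_fixture(
            n_subcommunities=3, species_per_subcommunity=4, n_per_species=25,
            sd_fd_slope_sign=-1, rng=np.random.default_rng(2),
        )
        for key, info in truth.items():
            sub = table.data[(table.data["island"] == key[0])
                             & (table.data["zone"] == key[1])]
            for name, spec in info["species"].items():
                assert (sub["species"] == name).sum() == spec["n"]

    @pytest.mark.parametrize("sign", [-1, 1])
    def test_requested_slope_sign_realized(self, sign):
        table, _ = generate_fixture(
            n_subcommunities=8, species_per_subcommunity=8, n_per_species=60,
            sd_fd_slope_sign=sign, rng=np.random.default_rng(8),
        )
        res = sd_fd_regression(subcommunity_summary(table))
        assert np.sign(res.slope) == sign

    def test_density_recovery_from_fixture(self, rng):
        """Fitted binormal parameters sit within 3 SE of the generating ones."""
        from ecoevodiv.empirical import _rescale, _shared_frame

        table, truth = generate_fixture(
            n_subcommunities=2, species_per_subcommunity=2, n_per_species=200,
            sd_fd_slope_sign=1, rng=rng, sampling_jitter=0.0,
        )
        lo, hi = _shared_frame(table.data)
        scale = 2.0 / (hi - lo)
        for (island, zone), info in truth.items():
            sub = table.data[(table.data["island"] == island)
                             & (table.data["zone"] == zone)]
            for name, spec in info["species"].items():
                pts = sub.loc[sub["species"] == name, ["size", "shapePC1"]].to_numpy()
                dens = fit_species_density(_rescale(pts, lo, hi), "binormal_mle")
                m_true = _rescale(spec["mean"], lo, hi)
                c_true = spec["cov"] * np.outer(scale, scale)
                n = spec["n"]
                se = np.sqrt(np.diag(c_true) / n)
                np.testing.assert_array_less(np.abs(dens.mean - m_true), 3 * se + 1e-12)

    def test_pipeline_deterministic(self):
        t1, _ = generate_fixture(4, 4, 30, -1, np.random.default_rng(9))
        t2, _ = generate_fixture(4, 4, 30, -1, np.random.default_rng(9))
        assert t1.data.equals(t2.data)
        s1 = summaries_to_frame(subcommunity_summary(t1))
        s2 = summaries_to_frame(subcommunity_summary(t2))
        assert s1.equals(s2)


class TestTraitTableValidation:
    def test_missing_hostplants_rejected(self):
        df = pd.DataFrame([{"species": "a", "island": "FL", "zone": "arid",
                            "size": 0.1, "shapePC1": 0.2}])
        with pytest.raises(ValueError, match="host_plants"):
            TraitTable(data=df, host_plants={})

    def test_unknown_zone_rejected(self):
        df = pd.DataFrame([{"species": "a", "island": "FL", "zone": "alpine",
                            "size": 0.1, "shapePC1": 0.2}])
        with pytest.raises(ValueError, match="zone"):
            TraitTable(data=df, host_plants={("FL", "alpine"): 3})

    def test_csv_round_trip(self, tmp_path):
        table, _ = generate_fixture(2, 2, 10, -1, np.random.default_rng(1))
        traits = tmp_path / "traits.csv"
        hp = tmp_path / "hostplants.csv"
        table.data.to_csv(traits, index=False)
        pd.DataFrame(
            [{"island": k[0], "zone": k[1], "n_hostplants": v}
             for k, v in table.host_plants.items()]
        ).to_csv(hp, index=False)
        back = TraitTable.from_csv(traits, hp)
        assert len(back.data) == len(table.data)
        assert back.host_plants == table.host_plants
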