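"""Generators and the dispersion ground truth."""

import io

import numpy as np
import pandas as pd
import pytest

import peilink as pl
from peilink.geometry import write_geojson_polygons
from peilink.synthetic import (
    CHEMICALS,
    EmissionInventory,
    generate_outcomes,
    oracle_at_points,
)

from conftest import make_flat_terrain, make_uniform_climate


def shoelace(coords):
    x = np.array([c[0] for c in coords])
    y = np.array([c[1] for c in coords])
    return 0.5 * abs(np.sum(x * np.roll(y, -1) - np.roll(x, -1) * y))


class TestRegion:
    def test_partition_area_matches_extent(self):
        region = pl.generate_region(seed=1, n_areas=108, n_tracts=50,
                                    extent_km=(400, 400))
        assert len(region.areas) == 108
        total = sum(shoelace(p.exterior.coords) for p in region.areas)
        assert total == pytest.approx(400e3 * 400e3, rel=1e-9)
        assert region.partition_coverage_error() < 1e-6

    def test_single_area_is_extent_rectangle(self):
        region = pl.generate_region(seed=1, n_areas=1, n_tracts=1,
                                    extent_km=(50, 80))
        assert shoelace(region.areas[0].exterior.coords) == pytest.approx(50e3 * 80e3)

    def test_deterministic_serialization(self, tmp_path):
        files = []
        for i in range(2):
            r = pl.generate_region(seed=9, n_areas=15, n_tracts=20, extent_km=(100, 100))
            p = tmp_path / f"areas{i}.geojson"
            write_geojson_polygons(p, r.area_ids, r.areas)
            files.append(p.read_bytes())
        assert files[0] == files[1]

    def test_rejects_bad_dimensions(self):
        with pytest.raises(ValueError):
            pl.generate_region(seed=0, n_areas=0)
        with pytest.raises(ValueError):
            pl.generate_region(seed=0, extent_km=(10, 400))


class TestEmissions:
    def test_chemical_labels(self, world):
        inv = world["inventory"]
        assert set(inv.emissions["chemical"]) <= set(CHEMICALS)
        assert len(inv.chemicals) == 10

    def test_all_zero_fraction(self, world):
        inv = pl.generate_emissions(world["region"], n_facilities=20, seed=0,
                                    zero_fraction=1.0)
        assert len(inv.emissions) == 0
        assert len(inv.absent_pairs()) == 10 * len(world["region"].years)

    def test_log_mean_within_three_se(self, world):
        mu, sd, jit = 5.0, 1.5, 0.2
        inv = pl.generate_emissions(world["region"], n_facilities=1000, seed=3,
                                    chemicals=("lead",), zero_fraction=0.0,
                                    log_mean_kg=mu, log_sd_kg=sd, year_jitter_sd=jit)
        year = world["region"].years[0]
        em = inv.emissions.query("year == @year")
        logs = np.log(em["fugitive_kg"] + em["stack_kg"])
        se = np.sqrt(sd**2 + jit**2) / np.sqrt(len(logs))
        assert abs(logs.mean() - mu) < 3 * se

    def test_negative_inputs_rejected(self, world):
        with pytest.raises(ValueError):
            pl.generate_emissions(world["region"], n_facilities=0)
        bad = pd.DataFrame({"facility_id": ["F1"], "chemical": ["lead"],
                            "year": [2012], "fugitive_kg": [-1.0], "stack_kg": [0.0]})
        fac = pd.DataFrame({"facility_id": ["F1"], "x": [0.0], "y": [0.0]})
        with pytest.raises(ValueError):
            EmissionInventory(facilities=fac, emissions=bad,
                              chemicals=("lead",), years=(2012,))


def _single_source_world(extent=(0.0, 0.0, 60e3, 60e3), em=100.0, year=2012,
                         sector_freqs=None, source_xy=(30e3, 30e3)):
    fac = pd.DataFrame({"facility_id": ["F1"], "x": [source_xy[0]], "y": [source_xy[1]]})
    ems = pd.DataFrame({"facility_id": ["F1"], "chemical": ["lead"], "year": [year],
                        "fugitive_kg": [em / 2], "stack_kg": [em / 2]})
    inv = EmissionInventory(facilities=fac, emissions=ems,
                            chemicals=("lead",), years=(year,))
    climate = make_uniform_climate(extent, [year], sector_freqs=sector_freqs)
    terrain = make_flat_terrain(extent)
    return inv, climate, terrain


class TestOracle:
    def test_receptor_at_source_closed_form(self):
        inv, climate, terrain = _single_source_world()
        params = pl.DispersionParams()
        got = pl.dispersion_oracle(inv, climate, terrain, (30e3, 30e3), "lead", 2012, params)
        m = params.climate_modifier(15.0, 0.4)
        expected = params.output_scale * 100.0 * m * 1.0  # flat terrain: u=1, D=0: align=1
        assert got == pytest.approx(float(expected), rel=1e-12)

    def test_additivity_over_inventory_split(self, world):
        inv = world["inventory"]
        ids = inv.facilities["facility_id"].tolist()
        a, b = ids[::2], ids[1::2]
        x = np.array([40e3, 90e3])
        y = np.array([60e3, 30e3])
        whole = oracle_at_points(inv, world["climate"], world["terrain"],
                                 x, y, "zinc", 2013, world["params"])
        parts = sum(oracle_at_points(inv.subset(s), world["climate"], world["terrain"],
                                     x, y, "zinc", 2013, world["params"])
                    for s in (a, b))
        # additive by construction; only float re-association separates the sums
        np.testing.assert_allclose(whole, parts, rtol=1e-12)

    def test_downwind_exceeds_upwind(self):
        freqs = np.zeros(16)
        freqs[0] = 1.0  # all wind blows toward +x
        inv, climate, terrain = _single_source_world(sector_freqs=freqs)
        params = pl.DispersionParams()
        lam = params.decay_km * 1e3
        down = pl.dispersion_oracle(inv, climate, terrain, (30e3 + lam, 30e3),
                                    "lead", 2012, params)
        up = pl.dispersion_oracle(inv, climate, terrain, (30e3 - lam, 30e3),
                                  "lead", 2012, params)
        assert down > up

    def test_monotone_decay_along_bearing(self):
        # strictly positive distances: at D=0 the alignment factor is pinned
        # to 1 by convention, so monotonicity starts away from the source
        inv, climate, terrain = _single_source_world(source_xy=(5e3, 5e3))
        d = np.linspace(1e3, 50e3, 20)
        vals = oracle_at_points(inv, climate, terrain, 5e3 + d * 0.6, 5e3 + d * 0.8,
                                "lead", 2012)
        assert (np.diff(vals) < 0).all()

    def test_outside_extent_rejected(self, world):
        with pytest.raises(ValueError, match="outside"):
            pl.dispersion_oracle(world["inventory"], world["climate"],
                                 world["terrain"], (-10.0, 5e3), "lead", 2012)

    def test_zero_inventory_gives_zero(self, world):
        inv = pl.generate_emissions(world["region"], n_facilities=5, seed=0,
                                    zero_fraction=1.0)
        v = oracle_at_points(inv, world["climate"], world["terrain"],
                             np.array([50e3]), np.array([50e3]), "lead", 2012)
        assert v[0] == 0.0


class TestMonitors:
    def test_noiseless_equals_oracle(self, world):
        mon = world["monitors"]
        sub = mon[(mon["chemical"] == "copper") & (mon["year"] == 2014)]
        truth = world["oracle"](sub["x"].to_numpy(), sub["y"].to_numpy(),
                                "copper", 2014)
        np.testing.assert_array_equal(sub["measured_value"].to_numpy(), truth)

    def test_full_coverage_count(self, world):
        assert len(world["monitors"]) == 15 * 10 * 5

    def test_deterministic(self, world):
        again = pl.sample_monitors(world["region"], world["oracle"], n_sites=15,
                                   noise_cv=0.0, seed=15)
        pd.testing.assert_frame_equal(again, world["monitors"])

    def test_noise_is_nonnegative_and_unbiased_scale(self, world):
        noisy = pl.sample_monitors(world["region"], world["oracle"], n_sites=15,
                                   noise_cv=0.4, seed=2, chemicals=("zinc",))
        assert (noisy["measured_value"] >= 0).all()


def _fake_exposures(region, rng, chemicals=("mercury",)):
    rows = []
    for chem in chemicals:
        base = rng.lognormal(0.0, 1.0, len(region.area_ids))
        for year in region.years:
            rows.append(pd.DataFrame({"area_id": region.area_ids, "chemical": chem,
                                      "year": year,
                                      "exposure": base * rng.lognormal(0, 0.05, len(base))}))
    return pd.concat(rows, ignore_index=True)


def _fake_covariates(region, rng):
    n = len(region.area_ids)
    race = rng.dirichlet([4, 4, 2, 1], size=n)
    return pd.DataFrame({
        "area_id": region.area_ids,
        "population": rng.uniform(5e3, 5e4, n),
        "pct_female": rng.normal(50, 1, n),
        "pct_less_than_hs": rng.uniform(5, 35, n),
        "pct_unmarried": rng.uniform(20, 60, n),
        "race_hispanic": race[:, 0], "race_white": race[:, 1],
        "race_native_american": race[:, 2], "race_other": race[:, 3],
    })


class TestOutcomes:
    def test_constant_when_everything_off(self):
        region = pl.generate_region(seed=3, n_areas=10, n_tracts=12, extent_km=(60, 60))
        rng = np.random.default_rng(0)
        table, truth = generate_outcomes(
            region, _fake_exposures(region, rng), effects_per_iqr={},
            covariate_coefs={}, noise_sd=0.0, baseline_rate=9.0,
            area_covariates=_fake_covariates(region, rng))
        np.testing.assert_allclose(table["lbw_rate"], 9.0)

    def test_injected_effect_recovered_exactly(self):
        from peilink.association import fit_single_pollutant

        region = pl.generate_region(seed=4, n_areas=40, n_tracts=60, extent_km=(150, 150))
        rng = np.random.default_rng(1)
        exp = _fake_exposures(region, rng)
        covs = _fake_covariates(region, rng)
        table, truth = generate_outcomes(region, exp,
                                         effects_per_iqr={"mercury": 0.43},
                                         noise_sd=0.0, area_covariates=covs)
        xbar = truth.mean_exposure.set_index("area_id")["mercury"]
        res = fit_single_pollutant(xbar, table["lbw_rate"], covs, chemical="mercury")
        assert abs(res.effect - 0.43) < 1e-8

    def test_noise_sd_scales_residuals(self):
        region = pl.generate_region(seed=5, n_areas=500, n_tracts=10, extent_km=(300, 300))
        rng = np.random.default_rng(2)
        exp = _fake_exposures(region, rng)
        covs = _fake_covariates(region, rng)
        import statsmodels.api as sm

        sds = {}
        for noise in (0.5, 1.0):
            table, truth = generate_outcomes(region, exp, noise_sd=noise, seed=77,
                                             area_covariates=covs)
            xbar = truth.mean_exposure.set_index("area_id")["mercury"].to_numpy()
            X = sm.add_constant(np.column_stack(
                [xbar / truth.iqr["mercury"]]
                + [covs[c].to_numpy() for c in
                   ("pct_female", "pct_less_than_hs", "pct_unmarried",
                    "race_hispanic", "race_native_american", "race_other")]))
            res = sm.OLS(table["lbw_rate"].to_numpy(), X).fit()
            sds[noise] = np.sqrt(res.mse_resid)
        assert sds[1.0] / sds[0.5] == pytest.approx(2.0, rel=0.10)

    def test_default_rates_plausible_range(self, world):
        texp = pl.true_area_exposures(world["region"], world["oracle"],
                                      chemicals=("mercury",), cell_m=8100)
        table, _ = generate_outcomes(world["region"], texp, seed=0)
        assert table["lbw_rate"].between(3.0, 17.0).all()
        assert table["lbw_rate"].max() - table["lbw_rate"].min() > 1.0
        shares = table[[c for c in table.columns if c.startswith("race_")]].sum(axis=1)
        np.testing.assert_allclose(shares, 1.0, atol=1e-9)

    def test_negative_noise_rejected(self, world):
        texp = _fake_exposures(world["region"], np.random.default_rng(0))
        with pytest.raises(ValueError):
            generate_outcomes(world["region"], texp, noise_sd=-0.1)
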