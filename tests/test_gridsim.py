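"""Gridded simulation: vectorized-vs-scalar equivalence and zone diagnostics."""

import dataclasses

import numpy as np
import pytest

from h2sink import (
    DepositionField,
    ForcingGrid,
    RetentionCurve,
    SyntheticSpec,
    UptakeParams,
    ZONES,
    conductance_snow,
    conductance_soil,
    deposition_velocity,
    epoch_change,
    gen_forcing,
    inhibition_fraction,
    mean_vd,
    run_grid,
    zone_contributions,
)
from h2sink.errors import InputError


def single_cell_grid(saturation, t_soil=20.0, snow=0.0, zone="temperate",
                     n_times=5, psi_e=-0.003, b=5.0):
    nt = n_times
    return ForcingGrid(
        cell_ids=[0],
        area_weights=[1.0],
        zone_labels=[zone],
        times=np.arange(nt, dtype=float),
        saturation=np.full((1, nt), saturation),
        t_soil=np.full((1, nt), t_soil),
        snow_depth=np.full((1, nt), snow),
        soc=[2.0],
        psi_e=[psi_e],
        b=[b],
        porosity=[0.45],
    )


class TestRunGrid:
    def test_too_dry_cell_gives_zero_everywhere(self, params):
        grid = single_cell_grid(saturation=0.001)
        field = run_grid(grid, params)
        assert np.all(field.v_d == 0.0)

    def test_constant_forcing_gives_constant_gs(self, params):
        grid = single_cell_grid(saturation=0.3)
        field = run_grid(grid, params)
        curve = RetentionCurve(psi_e=-0.003, b=5.0)
        g_s = conductance_soil(params, 0.3, 20.0, 2.0, 0.45, curve)
        assert np.allclose(field.v_d, g_s * 1000.0, rtol=1e-12)

    def test_matches_scalar_cell_by_cell_loop(self, small_forcing, params):
        field = run_grid(small_forcing, params)
        f = small_forcing
        for i in range(f.n_cells):
            curve = RetentionCurve(psi_e=f.psi_e[i], b=f.b[i])
            for j in range(0, f.n_times, 37):  # stride keeps the loop cheap
                g_s = conductance_soil(
                    params,
                    f.saturation[i, j],
                    f.t_soil[i, j],
                    f.soc[i],
                    f.porosity[i],
                    curve,
                    f.pressure,
                )
                g_snow = conductance_snow(
                    f.snow_depth[i, j], params, f.t_soil[i, j], f.pressure
                )
                expected = deposition_velocity(
                    g_s, g_snow, params.canopy_conductance
                )
                assert field.v_d[i, j] == pytest.approx(expected, rel=1e-12,
                                                        abs=1e-15)

    def test_permutation_invariance_over_cells(self, small_forcing, params):
        f = small_forcing
        perm = np.random.default_rng(0).permutation(f.n_cells)
        shuffled = ForcingGrid(
            cell_ids=f.cell_ids[perm],
            area_weights=f.area_weights[perm],
            zone_labels=f.zone_labels[perm],
            times=f.times,
            saturation=f.saturation[perm],
            t_soil=f.t_soil[perm],
            snow_depth=f.snow_depth[perm],
            soc=f.soc[perm],
            psi_e=f.psi_e[perm],
            b=f.b[perm],
            porosity=f.porosity[perm],
        )
        a = run_grid(f, params).v_d
        b = run_grid(shuffled, params).v_d
        np.testing.assert_array_equal(a[perm], b)
        assert mean_vd(run_grid(f, params), f.area_weights) == pytest.approx(
            mean_vd(run_grid(shuffled, params), shuffled.area_weights), rel=1e-12
        )

    def test_exactly_reproducible(self, small_forcing, params):
        a = run_grid(small_forcing, params).v_d
        b = run_grid(small_forcing, params).v_d
        np.testing.assert_array_equal(a, b)


class TestMeanVd:
    def test_uniform_field(self, params):
        field = DepositionField(np.full((3, 4), 0.07), "e", params)
        assert mean_vd(field, np.full(3, 1 / 3)) == pytest.approx(0.07)

    def test_two_equal_cells(self, params):
        field = DepositionField(np.array([[0.0, 0.0], [0.2, 0.2]]), "e", params)
        assert mean_vd(field, np.array([0.5, 0.5])) == pytest.approx(0.1)

    def test_matches_double_loop_oracle(self, params, rng):
        v = rng.uniform(0, 0.3, size=(6, 9))
        w = rng.uniform(0.1, 1.0, 6)
        w /= w.sum()
        field = DepositionField(v, "e", params)
        oracle = sum(
            w[i] * sum(v[i, j] for j in range(9)) / 9.0 for i in range(6)
        )
        assert mean_vd(field, w) == pytest.approx(oracle, abs=1e-12)

    def test_weight_mismatch_rejected(self, params):
        field = DepositionField(np.zeros((3, 4)), "e", params)
        with pytest.raises(InputError):
            mean_vd(field, np.array([0.5, 0.5]))
        with pytest.raises(InputError):
            mean_vd(field, np.array([0.5, 0.2, 0.2]))


class TestZoneContributions:
    def two_zone_grid(self, v_ratio):
        grid = ForcingGrid(
            cell_ids=[0, 1],
            area_weights=[0.5, 0.5],
            zone_labels=["desert", "temperate"],
            times=np.arange(3, dtype=float),
            saturation=np.full((2, 3), 0.3),
            t_soil=np.full((2, 3), 20.0),
            snow_depth=np.zeros((2, 3)),
            soc=[1.0, 1.0],
            psi_e=[-0.003, -0.003],
            b=[5.0, 5.0],
        )
        v = np.vstack([np.full(3, v_ratio), np.full(3, 1.0)])
        return grid, DepositionField(v, "e", UptakeParams())

    def test_single_active_zone_takes_all(self):
        grid, field = self.two_zone_grid(0.0)
        shares = zone_contributions(field, grid)
        assert shares["temperate"] == pytest.approx(1.0)
        assert shares["desert"] == 0.0

    def test_three_to_one_ratio(self):
        grid, field = self.two_zone_grid(3.0)
        shares = zone_contributions(field, grid)
        assert shares["desert"] == pytest.approx(0.75)
        assert shares["temperate"] == pytest.approx(0.25)

    def test_shares_sum_to_one(self, small_forcing, params):
        field = run_grid(small_forcing, params)
        shares = zone_contributions(field, small_forcing)
        assert sum(shares.values()) == pytest.approx(1.0, abs=1e-12)

    def test_all_zero_field_is_error(self, params):
        grid, _ = self.two_zone_grid(0.0)
        field = DepositionField(np.zeros((2, 3)), "e", params)
        with pytest.raises(InputError):
            zone_contributions(field, grid)

    def test_arid_share_grows_with_lower_threshold(self, params):
        spec = SyntheticSpec(
            seed=2,
            n_cells=60,
            n_times=600,
            zone_mix={"desert": 0.35, "semi-arid": 0.3, "temperate": 0.2,
                      "continental": 0.15},
        )
        forcing = gen_forcing(spec)
        shares = {}
        for psi_ws in (-3.0, -100.0):
            p = dataclasses.replace(params, psi_ws=psi_ws)
            shares[psi_ws] = zone_contributions(run_grid(forcing, p), forcing)
        arid = lambda s: s["desert"] + s["semi-arid"]
        assert arid(shares[-100.0]) > arid(shares[-3.0])


class TestInhibition:
    def test_always_wet_enough_zone_is_zero(self, params):
        grid = single_cell_grid(saturation=0.3, zone="temperate")
        out = inhibition_fraction(grid, params)
        assert out["fractions"]["temperate"] == 0.0

    def test_always_too_dry_zone_is_one(self, params):
        grid = single_cell_grid(saturation=0.001, zone="desert")
        for mode in ("area", "area_time"):
            out = inhibition_fraction(grid, params, mode=mode)
            assert out["fractions"]["desert"] == 1.0
            assert out["mode"] == mode

    def test_lowering_threshold_never_increases_inhibition(self):
        for seed in range(10):
            forcing = gen_forcing(SyntheticSpec(seed=seed, n_cells=40,
                                                n_times=300))
            frac = {}
            for psi_ws in (-3.0, -100.0):
                p = UptakeParams(psi_ws=psi_ws)
                frac[psi_ws] = inhibition_fraction(forcing, p,
                                                   mode="area_time")["fractions"]
            for z in ZONES:
                if not np.isnan(frac[-3.0][z]):
                    assert frac[-100.0][z] <= frac[-3.0][z] + 1e-15


class TestEpochChange:
    def test_identical_epochs_change_zero(self, small_forcing, params):
        field = run_grid(small_forcing, params)
        change = epoch_change(field, field, small_forcing)
        for z, v in change.items():
            if not np.isnan(v):
                assert v == pytest.approx(0.0, abs=1e-15)

    def test_uniform_scaling_gives_uniform_change(self, small_forcing, params):
        a = run_grid(small_forcing, params)
        b = DepositionField(1.1 * a.v_d, "late", params)
        change = epoch_change(a, b, small_forcing)
        for z, v in change.items():
            if not np.isnan(v):
                assert v == pytest.approx(0.10, rel=1e-12)

    def test_drying_trend_reduces_arid_uptake(self, params):
        spec = SyntheticSpec(seed=4, n_cells=60, n_times=600,
                             drying_trend=0.05)
        early = gen_forcing(spec, epoch="early")
        late = gen_forcing(spec, epoch="late")
        p = dataclasses.replace(params, psi_ws=-100.0)
        fa = run_grid(early, p)
        fb = DepositionField(run_grid(late, p).v_d, "late", p)
        change = epoch_change(fa, fb, early)
        assert change["desert"] < 0
        # scalar recomputation of the global change
        w = early.area_weights
        oracle = (w @ fb.v_d.mean(axis=1)) / (w @ fa.v_d.mean(axis=1)) - 1
        assert change["global"] == pytest.approx(oracle, rel=1e-12)

    def test_mismatched_grids_rejected(self, small_forcing, params):
        a = run_grid(small_forcing, params)
        b = DepositionField(a.v_d[:, :-1], "late", params)
        with pytest.raises(InputError):
            epoch_change(a, b, small_forcing)


class TestForcingGridValidation:
    def test_netcdf_round_trip(self, small_forcing, tmp_path):
        path = tmp_path / "forcing.nc"
        small_forcing.to_netcdf(path)
        back = ForcingGrid.from_netcdf(path)
        np.testing.assert_allclose(back.saturation, small_forcing.saturation)
        np.testing.assert_allclose(back.area_weights, small_forcing.area_weights)
        assert list(back.zone_labels) == list(small_forcing.zone_labels)
        np.testing.assert_allclose(back.porosity, small_forcing.porosity)

    def test_bad_weights_rejected(self):
        with pytest.raises(InputError):
            ForcingGrid(
                cell_ids=[0, 1],
                area_weights=[0.6, 0.6],
                zone_labels=["desert", "polar"],
                times=[0.0],
                saturation=np.full((2, 1), 0.5),
                t_soil=np.zeros((2, 1)),
                snow_depth=np.zeros((2, 1)),
                soc=[1, 1],
                psi_e=[-0.01, -0.01],
                b=[4, 4],
            )

    def test_missing_values_rejected(self, small_forcing):
        sat = small_forcing.saturation.copy()
        sat[0, 0] = np.nan
        with pytest.raises(InputError, match="missing"):
            ForcingGrid(
                cell_ids=small_forcing.cell_ids,
                area_weights=small_forcing.area_weights,
                zone_labels=small_forcing.zone_labels,
                times=small_forcing.times,
                saturation=sat,
                t_soil=small_forcing.t_soil,
                snow_depth=small_forcing.snow_depth,
                soc=small_forcing.soc,
                psi_e=small_forcing.psi_e,
                b=small_forcing.b,
                porosity=small_forcing.porosity,
            )

    def test_unknown_zone_rejected(self):
        with pytest.raises(InputError, match="zone"):
            single_cell_grid(0.5, zone="mediterranean")
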