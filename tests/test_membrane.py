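"""Membrane metrics: packing, thickness, order, interior water, partitioning."""

import numpy as np
import pandas as pd
import pytest

from memdiffkit import (
    AnalysisError,
    aggregate_conditions,
    area_per_lipid,
    bilayer_thickness,
    deuterium_order_parameters,
    generate_bilayer_ensemble,
    insertion_depth,
    interior_water_count,
    partition_fraction,
    percent_change,
    significant_difference,
    solvent_composition,
)
from memdiffkit.particles import TABLE_COLUMNS, ParticleEnsemble
from memdiffkit.profiles import IntervalEstimate
from memdiffkit.synth import AlcoholSpec, BilayerSpec

from conftest import add_particles, make_ensemble


class TestAreaPerLipid:
    def test_single_frame_arithmetic(self):
        ens = make_ensemble([[0.0]], box=(5.83, 5.83, 9.0))
        est = area_per_lipid(ens, 64)
        assert est.value == pytest.approx(5.83**2 / 64, abs=1e-9)
        assert round(est.value, 3) == 0.531

    def test_constant_box_zero_width(self):
        ens = make_ensemble([[0.0]] * 20, box=(6.0, 6.0, 9.0))
        est = area_per_lipid(ens, 64)
        assert est.width == pytest.approx(0.0)

    def test_rejects_nonpositive_lipid_count(self):
        ens = make_ensemble([[0.0]])
        with pytest.raises(AnalysisError):
            area_per_lipid(ens, 0)


class TestThickness:
    def test_delta_layers_recovered_to_bin_tolerance(self):
        rng = np.random.default_rng(0)
        frames = [
            np.concatenate([np.full(200, 2.0), np.full(200, -2.0)]) for _ in range(12)
        ]
        ens = make_ensemble(frames, box=(6.0, 6.0, 10.0), role="phosphate")
        est = bilayer_thickness(ens, bin_width=0.1)
        assert est.value == pytest.approx(4.0, abs=0.1)

    def test_generator_thickness_matches_peak_separation(self, plain_ensemble):
        est = bilayer_thickness(plain_ensemble)
        assert est.value == pytest.approx(3.8, abs=0.1)

    def test_linear_response_to_leaflet_separation(self):
        base = BilayerSpec.small(seed=21, n_frames=40)
        thin = BilayerSpec.small(
            seed=21, n_frames=40, phosphate_peak_z=1.9 * 0.95,
            glycerol_offset=0.3, water_ramp_start=1.3,
        )
        t0 = bilayer_thickness(generate_bilayer_ensemble(base)).value
        t1 = bilayer_thickness(generate_bilayer_ensemble(thin)).value
        assert (t0 - t1) / t0 == pytest.approx(0.05, abs=0.03)


def chain_ensemble(directions, n_frames=4, n_chains=6, n_carbons=5):
    """Bilayer-free ensemble of straight chains with prescribed C-H directions.

    ``directions`` is a callable (rng, n) -> (n, 3) unit vectors for the two
    hydrogens of every carbon.
    """
    rng = np.random.default_rng(77)
    rows = []
    for f in range(n_frames):
        for m in range(n_chains):
            x0, y0 = 2.0 + 0.3 * m, 2.0
            for ci in range(1, n_carbons + 1):
                cz = 1.0 - 0.12 * ci
                rows.append((f, m + 1, "IPC", "tail_carbon", 1, ci, x0, y0, cz))
                for d in directions(rng, 2):
                    rows.append(
                        (
                            f,
                            m + 1,
                            "IPC",
                            "tail_hydrogen",
                            1,
                            ci,
                            x0 + 0.109 * d[0],
                            y0 + 0.109 * d[1],
                            cz + 0.109 * d[2],
                        )
                    )
    table = pd.DataFrame(rows, columns=list(TABLE_COLUMNS))
    boxes = np.tile([8.0, 8.0, 10.0], (n_frames, 1))
    return ParticleEnsemble(table, boxes)


class TestOrderParameters:
    def test_bonds_perpendicular_to_normal_give_minus_half(self):
        def perp(rng, n):
            phi = rng.uniform(0, 2 * np.pi, n)
            return np.stack([np.cos(phi), np.sin(phi), np.zeros(n)], axis=1)

        res = deuterium_order_parameters(chain_ensemble(perp))
        for est in res.per_carbon.values():
            assert est.value == pytest.approx(-0.5, abs=1e-12)

    def test_bonds_parallel_to_normal_give_one(self):
        def para(rng, n):
            s = rng.choice([-1.0, 1.0], n)
            return np.stack([np.zeros(n), np.zeros(n), s], axis=1)

        res = deuterium_order_parameters(chain_ensemble(para))
        for est in res.per_carbon.values():
            assert est.value == pytest.approx(1.0, abs=1e-12)

    def test_isotropic_bonds_give_zero_within_monte_carlo_error(self):
        def iso(rng, n):
            v = rng.normal(size=(n, 3))
            return v / np.linalg.norm(v, axis=1, keepdims=True)

        ens = chain_ensemble(iso, n_frames=30, n_chains=10)
        res = deuterium_order_parameters(ens)
        n_samples = 30 * 10 * 2
        for est in res.per_carbon.values():
            assert abs(est.value) < 3.0 / np.sqrt(n_samples)

    def test_estimator_matches_direct_bond_average(self):
        """Position-based estimate equals direct averaging of the drawn bonds."""
        drawn = []

        def tilted(rng, n):
            u = rng.uniform(-0.9, 0.9, n)
            phi = rng.uniform(0, 2 * np.pi, n)
            s = np.sqrt(1 - u**2)
            drawn.append(u)
            return np.stack([s * np.cos(phi), s * np.sin(phi), u], axis=1)

        ens = chain_ensemble(tilted, n_frames=6, n_chains=4)
        res = deuterium_order_parameters(ens)
        cos = np.concatenate(drawn)
        oracle = 0.5 * (3 * cos**2 - 1)
        chain_means = np.mean(oracle)  # same weight per bond across equal counts
        est_mean = np.mean([e.value for e in res.per_carbon.values()])
        assert est_mean == pytest.approx(chain_means, abs=1e-9)

    def test_axis_fallback_used_without_hydrogens(self, plain_ensemble):
        table = plain_ensemble.table
        stripped = ParticleEnsemble(
            table[table["role"] != "tail_hydrogen"].reset_index(drop=True),
            plain_ensemble.boxes,
            dict(plain_ensemble.metadata),
        )
        res = deuterium_order_parameters(stripped)
        assert res.method == "axis_reconstruction"
        assert all(-0.5 <= e.value <= 1.0 for e in res.per_carbon.values())

    def test_short_chain_rejected(self):
        def perp(rng, n):
            return np.tile([1.0, 0.0, 0.0], (n, 1))

        ens = chain_ensemble(perp, n_carbons=2)
        with pytest.raises(AnalysisError):
            deuterium_order_parameters(ens)


class TestInteriorWater:
    def test_zero_interior_water_measures_near_zero(self):
        ens = generate_bilayer_ensemble(
            BilayerSpec.small(seed=31, n_frames=30, interior_water_target=0)
        )
        est = interior_water_count(ens, seed=1)
        assert est.value < 1.0

    def test_generator_target_recovered(self, butanol_ensemble):
        est = interior_water_count(butanol_ensemble, seed=2)
        assert est.value == pytest.approx(40.0, abs=3.0)

    def test_slab_counting_matches_profile_integration(self, butanol_ensemble):
        """Direct counting agrees with integrating the density profile."""
        from memdiffkit.membrane import IPC_TAIL_SEL, WATER_SEL
        from memdiffkit.profiles import _single_crossing, density_profile

        est = interior_water_count(butanol_ensemble, seed=3)
        water = density_profile(butanol_ensemble, WATER_SEL, 0.1)
        tail = density_profile(butanol_ensemble, IPC_TAIL_SEL, 0.1)
        half = water.bin_edges[-1]
        diff = tail.density - water.density
        z_lo = _single_crossing(water.centers, diff, (-half, 0.0))
        z_hi = _single_crossing(water.centers, diff, (0.0, half))
        # integrate the water profile over the interior with fractional bins
        edges = water.bin_edges
        overlap = np.clip(
            np.minimum(edges[1:], z_hi) - np.maximum(edges[:-1], z_lo), 0.0, None
        )
        integral = float(np.sum(water.density * overlap) * water.mean_area)
        assert abs(integral - est.value) <= max(est.width, 1.0)


class TestPartitionAndDepth:
    def test_all_hydroxyls_at_midplane_gives_100_percent(self, plain_ensemble):
        ens = add_particles(plain_ensemble, "BUTANOL", "hydroxyl_oxygen", np.zeros(30))
        est = partition_fraction(ens, "BUTANOL", seed=1)
        assert est.value == pytest.approx(100.0)

    def test_all_hydroxyls_in_far_bulk_gives_0_percent(self, plain_ensemble):
        z = np.linspace(3.2, 4.2, 30)
        ens = add_particles(plain_ensemble, "BUTANOL", "hydroxyl_oxygen", z)
        est = partition_fraction(ens, "BUTANOL", seed=1)
        assert est.value == pytest.approx(0.0)

    def test_membrane_and_bulk_fractions_sum_to_one(self, butanol_ensemble):
        est = partition_fraction(butanol_ensemble, "BUTANOL", seed=4)
        bulk = 100.0 - est.value
        assert 0.0 <= est.value <= 100.0 and 0.0 <= bulk <= 100.0

    def test_absent_species_raises(self, plain_ensemble):
        from memdiffkit import SelectionError

        with pytest.raises(SelectionError):
            partition_fraction(plain_ensemble, "ETHANOL")

    def test_group_coincident_with_glycerol_has_zero_depth(self, plain_ensemble):
        rng = np.random.default_rng(8)
        ens = plain_ensemble
        z = np.concatenate([rng.normal(1.6, 0.05, 40), rng.normal(-1.6, 0.05, 40)])
        ens = add_particles(ens, "ETHANOL", "hydroxyl_oxygen", z)
        est = insertion_depth(ens, "ETHANOL", "hydroxyl_oxygen", seed=5)
        assert est.value == pytest.approx(0.0, abs=0.06)

    def test_generator_methyl_depth_recovered(self, butanol_ensemble):
        est = insertion_depth(butanol_ensemble, "BUTANOL", "terminal_methyl", seed=6)
        assert est.value == pytest.approx(0.40, abs=0.08)

    def test_rigid_orientation_depth_difference_equals_length(self):
        spec = BilayerSpec.small(
            seed=41,
            n_frames=60,
            alcohol=AlcoholSpec(
                "BUTANOL", 200, 1.0, hydroxyl_depth=0.05, orientation_noise=0.0
            ),
        )
        ens = generate_bilayer_ensemble(spec)
        d_me = insertion_depth(ens, "BUTANOL", "terminal_methyl", seed=1).value
        d_oh = insertion_depth(ens, "BUTANOL", "hydroxyl_oxygen", seed=2).value
        assert d_me - d_oh == pytest.approx(0.37, abs=0.06)


class TestSolventComposition:
    @pytest.mark.parametrize(
        "conc,species,expected",
        [(8.0, "ETHANOL", 0.13), (8.0, "BUTANOL", 0.08)],
    )
    def test_alcohol_per_lipid_ratios(self, conc, species, expected):
        comp = solvent_composition(conc, species)
        assert round(comp.alcohol_per_lipid, 2) == expected

    def test_zero_concentration(self):
        comp = solvent_composition(0.0, "ETHANOL")
        assert comp == (0, 5210, 0.0)

    def test_counts_are_complementary(self):
        comp = solvent_composition(40.0, "BUTANOL")
        assert comp.n_alcohol + comp.n_water == 5210

    def test_negative_concentration_rejected(self):
        with pytest.raises(AnalysisError):
            solvent_composition(-1.0, "ETHANOL")

    def test_high_concentration_warns(self):
        with pytest.warns(UserWarning, match="diverge"):
            solvent_composition(120.0, "ETHANOL")


class TestDeskArithmetic:
    @pytest.mark.parametrize(
        "control,treated,expected",
        [(0.53, 0.79, 49.0), (0.53, 0.89, 68.0), (1.7, 1.7, 0.0)],
    )
    def test_percent_change(self, control, treated, expected):
        assert percent_change(control, treated) == expected

    def test_percent_change_zero_control_rejected(self):
        with pytest.raises(AnalysisError):
            percent_change(0.0, 1.0)

    def test_aggregate_partitioning_columns(self):
        ethanol = [61, 56, 57, 56, 54, 58, 62, 59, 65]
        butanol = [84, 99, 98, 90, 89, 95, 96, 95, 97]
        mean_e, _ = aggregate_conditions(ethanol)
        mean_b, sd_b = aggregate_conditions(butanol)
        assert round(mean_e) == 59
        assert round(mean_b) == 94
        assert round(sd_b) == 5

    def test_single_value_has_undefined_sd(self):
        mean, sd = aggregate_conditions([42.0])
        assert mean == 42.0 and np.isnan(sd)

    def test_empty_rejected(self):
        with pytest.raises(AnalysisError):
            aggregate_conditions([])


class TestSignificance:
    def test_disjoint_intervals_significant(self):
        a = IntervalEstimate(1.5, 1.0, 2.0, "block", 5)
        b = IntervalEstimate(3.5, 3.0, 4.0, "block", 5)
        assert significant_difference(a, b) is True

    def test_overlapping_intervals_not_significant(self):
        a = IntervalEstimate(2.0, 1.0, 3.0, "block", 5)
        b = IntervalEstimate(3.0, 2.0, 4.0, "block", 5)
        assert significant_difference(a, b) is False
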