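"""Lattice stage: synthetic n-tuples, deposition, diffusion and yields."""

import numpy as np
import pytest
from scipy.integrate import solve_ivp

from flashkin.beam import AVOGADRO, GValueSet, pulses_for
from flashkin.hetero import (
    DtPolicy,
    SpeciesField,
    SpeciesNTuple,
    deposit,
    evolve_lattice,
    generate_synthetic_ntuple,
    sample_arrival_times,
    yields_at_1us,
)
from flashkin.reaction_network import Reaction, ReactionSystem, Species


class TestSyntheticNTuple:
    def test_deterministic_per_seed(self):
        g = GValueSet({"OH": 2.8, "e_aq": 2.7})
        a = generate_synthetic_ntuple(10, g, seed=7)
        b = generate_synthetic_ntuple(10, g, seed=7)
        assert np.array_equal(a.x_nm, b.x_nm)
        assert np.array_equal(a.species, b.species)
        c = generate_synthetic_ntuple(10, g, seed=8)
        assert len(c) == 0 or not np.array_equal(a.x_nm[: len(c.x_nm)], c.x_nm)

    def test_counts_match_expected_yield(self):
        # 100 keV per history at G = 1.0 -> Poisson mean 1000 molecules
        g = GValueSet({"OH": 1.0})
        nt = generate_synthetic_ntuple(
            200, g, track_model={"energy_per_history_keV": 100.0}, seed=3
        )
        mean = 200 * 1000
        assert abs(len(nt) - mean) < 5 * np.sqrt(mean)

    def test_zero_yields_records_dose_only(self):
        nt = generate_synthetic_ntuple(4, GValueSet({}), seed=0)
        assert len(nt) == 0
        assert nt.total_dose > 0

    def test_csv_round_trip(self, tmp_path):
        g = GValueSet({"OH": 2.8})
        nt = generate_synthetic_ntuple(3, g, seed=1)
        nt.write_csv(tmp_path / "nt.csv")
        back = SpeciesNTuple.read_csv(tmp_path / "nt.csv")
        assert len(back) == len(nt)
        assert np.allclose(back.x_nm, nt.x_nm, atol=1e-3)
        assert back.total_dose == pytest.approx(nt.total_dose)

    def test_arrival_times_fall_inside_pulses(self, rng):
        sched = pulses_for(100.0, 10.0, 100.0, 1.8e-6)
        times = sample_arrival_times(sched, 500, rng)
        rates = sched.dose_rate_at(times)
        assert np.all(rates > 0)  # every arrival lands inside a pulse


def _tiny_system(names=("A",), diffusion=1.0e-9, reactions=()):
    species = [Species(n, diffusion_coeff=diffusion) for n in names]
    return ReactionSystem(species, list(reactions))


class TestDeposit:
    def test_single_molecule_concentration(self):
        system = _tiny_system()
        field = SpeciesField.uniform(system, shape=(4, 4, 4))
        nt = SpeciesNTuple(
            history=np.array([0]),
            species=np.array(["A"], dtype=object),
            x_nm=np.array([150.0]),
            y_nm=np.array([50.0]),
            z_nm=np.array([250.0]),
            history_dose={0: 1.0},
            phantom_edge_nm=400.0,
        )
        assert deposit(nt, field) == 0
        expected = 1.0 / (AVOGADRO * 1e-18)  # one molecule in 1e-18 L
        assert field.conc[0, 1, 0, 2] == pytest.approx(expected)
        assert expected == pytest.approx(1.66e-6, rel=1e-2)
        deposit(nt, field)  # second identical molecule: exactly double
        assert field.conc[0, 1, 0, 2] == pytest.approx(2 * expected)

    def test_outside_lattice_rejected_with_count(self):
        system = _tiny_system()
        field = SpeciesField.uniform(system, shape=(4, 4, 4))
        nt = SpeciesNTuple(
            history=np.array([0, 0]),
            species=np.array(["A", "A"], dtype=object),
            x_nm=np.array([50.0, 450.0]),  # second is past the 400 nm edge
            y_nm=np.array([50.0, 50.0]),
            z_nm=np.array([50.0, 50.0]),
            history_dose={0: 1.0},
            phantom_edge_nm=400.0,
        )
        assert deposit(nt, field) == 1

    def test_corner_record_uses_half_open_cells(self):
        system = _tiny_system()
        field = SpeciesField.uniform(system, shape=(4, 4, 4))
        nt = SpeciesNTuple(
            history=np.array([0]),
            species=np.array(["A"], dtype=object),
            x_nm=np.array([0.0]),
            y_nm=np.array([0.0]),
            z_nm=np.array([0.0]),
            history_dose={0: 1.0},
            phantom_edge_nm=400.0,
        )
        assert deposit(nt, field) == 0
        assert field.conc[0, 0, 0, 0] > 0


class TestEvolveLattice:
    def test_mass_conserved_under_periodic_diffusion(self):
        """Non-reacting point mass spread by periodic diffusion: total
        amount drifts by < 1e-9 relative over 1e4 steps."""
        system = _tiny_system(diffusion=2.0e-9)
        field = SpeciesField.uniform(system, shape=(8, 8, 8))
        field.conc[0, 3, 4, 2] = 1e-3
        total0 = field.totals()[0]
        _, _trace = evolve_lattice(
            field, system, t_end=1e-4, dt_policy=DtPolicy(dt_max=1e-8)
        )
        assert _trace.metadata["n_steps"] == 10000
        assert abs(field.totals()[0] - total0) / total0 < 1e-9

    def test_matches_per_cell_ode_with_diffusion_off(self, water_sys):
        """With all diffusion disabled every cell is an independent 0-D
        kinetics problem; the lattice integrator must agree with a stiff
        ODE solution cell by cell to < 1e-4."""
        sp = [
            Species(s.name, 0.0, s.initial_conc, s.clamped, s.boundary_clamped)
            for s in water_sys.species
        ]
        system = ReactionSystem(sp, water_sys.reactions)
        system = system.with_species_conc({"O2": 50e-6})
        field = SpeciesField.uniform(system, shape=(4, 4, 4))
        rng = np.random.default_rng(42)
        for name in ("e_aq", "OH", "H"):
            i = system.species_index(name)
            field.conc[i] = rng.uniform(0.2e-6, 3e-6, size=(4, 4, 4))
        start = field.conc.copy()
        field, _ = evolve_lattice(
            field, system, t_end=1e-6,
            dt_policy=DtPolicy(dt_max=2e-7, rxn_rtol=1e-7),
        )
        # interior cells are never touched by the boundary oxygen reset, so
        # they must follow the free 0-D kinetics cell by cell
        for idx in [(1, 1, 1), (1, 2, 2), (2, 1, 2), (2, 2, 1)]:
            c0 = start[(slice(None), *idx)]
            sol = solve_ivp(
                lambda t, y: system.rate_law_unchecked(y),
                (0.0, 1e-6), c0, method="BDF",
                jac=lambda t, y: system.jacobian(y),
                rtol=1e-10, atol=1e-16,
            )
            ref = sol.y[:, -1]
            got = field.conc[(slice(None), *idx)]
            scale = np.abs(ref) + 1e-9
            assert np.max(np.abs(got - ref) / scale) < 1e-4

    def test_uniform_field_stays_uniform(self, water_sys):
        system = water_sys.with_species_conc({"O2": 50e-6, "H2O2": 1e-6})
        field = SpeciesField.uniform(system, shape=(4, 4, 4))
        field, trace = evolve_lattice(field, system, t_end=1e-6)
        for s in range(field.conc.shape[0]):
            block = field.conc[s]
            assert np.ptp(block) <= 1e-12 * max(block.max(), 1e-30)

    def test_oxygen_border_held_at_ambient(self, water_sys):
        system = water_sys.with_species_conc({"O2": 50e-6})
        field = SpeciesField.uniform(system, shape=(6, 6, 6))
        i_e = system.species_index("e_aq")
        field.conc[i_e, 3, 3, 3] = 5e-5  # interior electron spike eats O2
        field, _ = evolve_lattice(
            field, system, t_end=1e-6,
            dt_policy=DtPolicy(rxn_rtol=1e-3, rxn_atol=1e-13),
        )
        i_o2 = system.species_index("O2")
        border = np.ones((6, 6, 6), dtype=bool)
        border[1:-1, 1:-1, 1:-1] = False
        assert np.all(field.conc[i_o2][border] == 50e-6)

    def test_stability_cap_reduces_requested_dt(self):
        system = _tiny_system(diffusion=5.0e-9)
        field = SpeciesField.uniform(system, shape=(4, 4, 4))
        _, trace = evolve_lattice(
            field, system, t_end=1e-5, dt_policy=DtPolicy(dt_max=1e-5)
        )
        dx = 1e-7
        assert trace.metadata["dt"] <= dx * dx / (6 * 5.0e-9)


class TestYields:
    def test_round_trip_from_production(self):
        # c = D * rho * G / (f_c N_av) inverts back to G exactly
        from flashkin.beam import F_C

        g_true, dose = 2.8, 10.0
        c = dose * g_true / (F_C * AVOGADRO)
        g = yields_at_1us({"OH": c}, total_dose=dose)
        assert g["OH"] == pytest.approx(g_true, rel=1e-12)

    def test_linear_in_dose_without_second_order_losses(self):
        from flashkin.beam import F_C

        c = 10.0 * 2.8 / (F_C * AVOGADRO)
        g1 = yields_at_1us({"OH": c}, total_dose=10.0)
        g2 = yields_at_1us({"OH": 2 * c}, total_dose=20.0)
        assert g2["OH"] == pytest.approx(g1["OH"], rel=1e-12)

    def test_zero_dose_rejected(self):
        with pytest.raises(ValueError):
            yields_at_1us({"OH": 1e-6}, total_dose=0.0)

    def test_recombination_lowers_yield_at_higher_track_density(self, water_sys):
        """Denser energy deposition per history boosts second-order
        intra-track losses, so the 1-us yield per 100 eV drops."""
        g_seed = GValueSet({"OH": 4.8})
        results = []
        for e_kev in (1.0, 20.0):
            nt = generate_synthetic_ntuple(
                60, g_seed,
                track_model={"energy_per_history_keV": e_kev,
                             "cylinder_radius_nm": 5.0},
                seed=11, phantom_edge_nm=1600.0,
            )
            system = water_sys.with_species_conc({"O2": 50e-6})
            field = SpeciesField.uniform(system, shape=(16, 16, 16))
            deposit(nt, field)
            baseline = dict(zip(system.names, system.initial_concentrations()))
            field, trace = evolve_lattice(
                field, system, t_end=1e-6,
                dt_policy=DtPolicy(rxn_rtol=1e-3, rxn_atol=1e-13),
            )
            g_out = yields_at_1us(trace, nt.total_dose, baseline=baseline)
            results.append(g_out["OH"])
        assert results[1] < results[0]
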