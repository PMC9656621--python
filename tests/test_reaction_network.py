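"""Reaction tables, the mass-action rate law and its invariants."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.integrate import solve_ivp

from flashkin.reaction_network import (
    Reaction,
    ReactionSystem,
    SchemaError,
    Species,
    ValidationError,
    WATER_MOLARITY,
    load_reaction_system,
)


def _rx(system, rid):
    return next(r for r in system.reactions if r.id == rid)


class TestShippedTables:
    def test_water_reaction_count_and_rates(self, water_sys):
        assert len(water_sys.reactions) == 39
        assert water_sys.medium == "water_only"
        r8 = _rx(water_sys, 8)
        assert r8.reactants == ("e_aq", "O2")
        assert r8.rate_constant == pytest.approx(1.90e10)

    def test_biological_extends_water(self, bio_sys):
        assert len(bio_sys.reactions) == 53
        assert bio_sys.medium == "biological"
        assert {r.id for r in bio_sys.reactions} == set(range(1, 54))
        r46 = _rx(bio_sys, 46)
        assert set(r46.reactants) == {"R", "O2"}
        assert r46.rate_constant == pytest.approx(5.00e7)
        # biomolecule pools at their tabulated concentrations
        conc = dict(zip(bio_sys.names, bio_sys.initial_concentrations()))
        assert conc["RH"] == pytest.approx(1.0)
        assert conc["GSH"] == pytest.approx(6.5e-3)
        assert conc["Fe2+"] == pytest.approx(8.9e-7)
        assert conc["lipid"] == pytest.approx(1e-6)
        assert conc["catalase"] == pytest.approx(8e-8)

    def test_water_pool_is_explicit_and_clamped(self, water_sys):
        h2o = water_sys.species[water_sys.species_index("H2O")]
        assert h2o.clamped and h2o.initial_conc == pytest.approx(WATER_MOLARITY)

    def test_empty_reaction_table_is_inert(self, water_sys, tmp_path):
        rt = tmp_path / "rx.tsv"
        rt.write_text("id\treactant1\treactant2\tproducts\tk\tk_units\n")
        st_path = tmp_path / "sp.tsv"
        st_path.write_text(
            "name\tdiffusion_1e-9_m2_s\tinitial_conc_M\tclamped\tboundary_clamped\n"
            "A\t1.0\t1e-6\t0\t0\n"
        )
        sys0 = load_reaction_system(st_path, rt)
        assert len(sys0.reactions) == 0
        assert np.allclose(sys0.rate_law(sys0.initial_concentrations()), 0.0)

    def test_unknown_species_is_schema_error(self, tmp_path):
        sp = tmp_path / "sp.tsv"
        sp.write_text(
            "name\tdiffusion_1e-9_m2_s\tinitial_conc_M\tclamped\tboundary_clamped\n"
            "A\t0\t0\t0\t0\n"
        )
        rt = tmp_path / "rx.tsv"
        rt.write_text(
            "id\treactant1\treactant2\tproducts\tk\tk_units\n"
            "1\tA\tB\t\t1e9\tM-1s-1\n"
        )
        with pytest.raises(SchemaError, match="unknown species"):
            load_reaction_system(sp, rt)

    def test_nonpositive_rate_is_validation_error(self):
        with pytest.raises(ValidationError, match="positive"):
            Reaction(id=1, reactants=("A",), rate_constant=0.0)


class TestRateLaw:
    def test_single_bimolecular_reaction_oracle(self, water_sys):
        # e_aq + O2 -> O2- alone: hand evaluation of the mass-action law
        sys8 = water_sys.subset([8])
        c = np.zeros(sys8.n_species)
        c[sys8.species_index("e_aq")] = 1e-6
        c[sys8.species_index("O2")] = 5e-5
        dc = sys8.rate_law(c)
        rate = 1.9e10 * 1e-6 * 5e-5  # 0.95 M/s
        assert dc[sys8.species_index("e_aq")] == pytest.approx(-rate)
        assert dc[sys8.species_index("O2")] == pytest.approx(-rate)
        assert dc[sys8.species_index("O2-")] == pytest.approx(+rate)

    def test_self_reaction_consumes_two(self, water_sys):
        # OH + OH -> H2O2 at [OH] = c: d[OH]/dt = -2kc^2, d[H2O2]/dt = +kc^2
        sys3 = water_sys.subset([3])
        c = np.zeros(sys3.n_species)
        c[sys3.species_index("OH")] = 2e-6
        dc = sys3.rate_law(c)
        kc2 = 4.75e9 * (2e-6) ** 2
        assert dc[sys3.species_index("OH")] == pytest.approx(-2 * kc2)
        assert dc[sys3.species_index("H2O2")] == pytest.approx(+kc2)

    def test_all_zero_concentrations_give_zero_rates(self, bio_sys):
        assert np.all(bio_sys.rate_law(np.zeros(bio_sys.n_species)) == 0.0)

    def test_clamped_species_have_zero_rate(self, bio_sys):
        c = bio_sys.initial_concentrations()
        c[bio_sys.species_index("H2O2")] = 1e-5  # feeds the catalase/Fenton pool
        dc = bio_sys.rate_law(c)
        for name in ("H2O", "XSH", "Fe2+", "catalase"):
            assert dc[bio_sys.species_index(name)] == 0.0

    def test_negative_concentration_rejected(self, water_sys):
        c = np.zeros(water_sys.n_species)
        c[0] = -1e-9
        with pytest.raises(ValueError, match="negative"):
            water_sys.rate_law(c)

    def test_atom_conservation_in_closed_subnetwork(self):
        # H + H -> H2, OH + OH -> H2O2, H + OH -> H2O conserve H and O
        species = [Species(n) for n in ("H", "OH", "H2", "H2O2", "H2O")]
        rxns = [
            Reaction(1, ("H", "H"), ("H2",), 5.03e9),
            Reaction(2, ("OH", "OH"), ("H2O2",), 4.75e9),
            Reaction(3, ("H", "OH"), ("H2O",), 1.44e10),
        ]
        system = ReactionSystem(species, rxns)
        c = np.array([3e-6, 2e-6, 1e-7, 0.0, 5e-8])
        dc = system.rate_law(c)
        w_h = np.array([1, 1, 2, 2, 2])
        w_o = np.array([0, 1, 0, 2, 1])
        scale = np.abs(dc).max()
        assert abs(w_h @ dc) < 1e-14 * scale
        assert abs(w_o @ dc) < 1e-14 * scale

    def test_water_autoionization_fixed_point(self, water_sys):
        # only H2O <-> H+ + OH-: steady state at [H+][OH-] = k21 [H2O] / k20
        sub = water_sys.subset([20, 21])
        c0 = sub.initial_concentrations()
        sol = solve_ivp(
            lambda t, y: sub.rate_law_unchecked(y),
            (0.0, 10.0),
            c0,
            method="BDF",
            jac=lambda t, y: sub.jacobian(y),
            rtol=1e-10,
            atol=1e-18,
        )
        cf = sol.y[:, -1]
        prod = cf[sub.species_index("H+")] * cf[sub.species_index("OH-")]
        expected = 1.29e-5 * WATER_MOLARITY / 1.00e11  # ~7.13e-15, pH 7.07
        assert prod == pytest.approx(expected, rel=1e-3)

    @settings(derandomize=True, max_examples=25, deadline=None)
    @given(lam=st.floats(0.05, 20.0))
    def test_quadratic_homogeneity_of_bimolecular_network(self, lam):
        # scaling all concentrations by lambda scales all rates by lambda^2
        system = water_system_bimolecular()
        c = np.linspace(1e-7, 1e-5, system.n_species)
        assert np.allclose(
            system.rate_law(lam * c), lam**2 * system.rate_law(c),
            rtol=1e-12, atol=0,
        )


def water_system_bimolecular():
    from flashkin.reaction_network import water_system

    ws = water_system()
    bimol = [r.id for r in ws.reactions if r.order == 2]
    # drop H2O-containing reactions: the clamped pool breaks pure homogeneity
    bimol = [
        i for i in bimol
        if "H2O" not in _rx(ws, i).reactants
    ]
    sp = [Species(s.name, s.diffusion_coeff, s.initial_conc) for s in ws.species]
    return ReactionSystem(sp, [_rx(ws, i) for i in bimol])
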