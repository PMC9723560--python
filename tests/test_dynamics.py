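"""Process rates, limitation factors, dormancy and ledger closure."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from fluxnet.config import Param
from fluxnet.dynamics import CompiledModel, Forcing

from conftest import build_tiny_forcing, build_tiny_spec


def optimal_conditions_spec():
    """Saturating nutrients, optimal light/temperature/salinity, no shading."""
    spec = build_tiny_spec()
    spec.environment["background_extinction"] = Param(0.0)
    spec.components["phy"].params["shade"] = Param(0.0)
    spec.components["nit"].c0 = Param(1e15)
    spec.components["pho4"].c0 = Param(1e15)
    spec.components["mic"].c0 = Param(1e15)
    return spec


def optimal_forcing():
    return Forcing.constant(0.0, 1000.0, temperature=16.0, light=1.0,
                            salinity=32.0, dilution=0.0)


class TestLimitationFactors:
    def test_saturation_gives_unit_photosynthesis_factor(self):
        model = CompiledModel(optimal_conditions_spec())
        L = model.limitation_factors(0.0, model.c0_vector(), optimal_forcing())
        assert L.Lp[0] == pytest.approx(1.0, abs=1e-12)

    def test_macronutrient_monod_midpoint(self):
        spec = optimal_conditions_spec()
        spec.components["nit"].c0 = Param(1.0)   # == its Ks for phy
        model = CompiledModel(spec)
        L = model.limitation_factors(0.0, model.c0_vector(), optimal_forcing())
        assert L.nutrient[0] == pytest.approx(0.5, abs=1e-12)

    def test_micronutrients_combine_by_minimum(self):
        spec = optimal_conditions_spec()
        spec.components["mic2"] = type(spec.components["mic"])("mic2", "micronutrient", Param(0.0))
        phy = spec.components["phy"]
        # sub-factors 0.3 and 0.7: C = Ks*f/(1-f)
        phy.tables["KsM"] = {"mic": Param(1.0), "mic2": Param(1.0)}
        spec.components["mic"].c0 = Param(0.3 / 0.7)
        spec.components["mic2"].c0 = Param(0.7 / 0.3)
        model = CompiledModel(spec)
        L = model.limitation_factors(0.0, model.c0_vector(), optimal_forcing())
        assert L.micronutrient[0] == pytest.approx(0.3, abs=1e-12)

    def test_death_bell_bounded_and_peaked(self, tiny_spec, tiny_forcing):
        model = CompiledModel(tiny_spec)
        C = model.c0_vector()
        vals = [model.limitation_factors(t, C, tiny_forcing).Lu[0] for t in range(0, 365, 5)]
        assert max(vals) <= 1.0 + 1e-12
        assert np.argmax(vals) * 5 == pytest.approx(150, abs=5)


class TestUptake:
    def test_single_substrate_monod_midpoint(self):
        spec = build_tiny_spec()
        del spec.components["bac"].tables["Ksh"]["dgl"]
        spec.components["dch"].c0 = Param(5.0)   # == Ksh
        model = CompiledModel(spec)
        U = model.uptake_matrix(model.c0_vector(), np.ones(1))
        kh, cb = 4.0, 0.5
        assert U.sum() == pytest.approx(kh * cb / 2.0, abs=1e-12)

    def test_absent_pair_excluded_from_denominator(self):
        spec = build_tiny_spec()
        model_full = CompiledModel(spec)
        del spec.components["bac"].tables["Ksh"]["dgl"]
        model_cut = CompiledModel(spec)
        C = model_full.c0_vector()
        U_full = model_full.uptake_matrix(C, np.ones(1))
        U_cut = model_cut.uptake_matrix(C, np.ones(1))
        j_dgl = list(model_full.iD).index(model_full.index["dgl"])
        j_dch = list(model_full.iD).index(model_full.index["dch"])
        assert U_cut[0, j_dgl] == 0.0
        # removing a substrate raises uptake of the remaining one (shared denominator)
        assert U_cut[0, j_dch] > U_full[0, j_dch]

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=25, deadline=None)
    def test_matches_scalar_loop_oracle(self, seed):
        spec = build_tiny_spec()
        spec.components["dx"] = type(spec.components["dch"])("dx", "DOM", Param(1.0))
        rng = np.random.default_rng(seed)
        ksh = {d: float(rng.uniform(0.5, 20)) for d in ("dch", "dgl", "dx")}
        spec.components["bac"].tables["Ksh"] = {k: Param(v) for k, v in ksh.items()}
        model = CompiledModel(spec)
        C = rng.uniform(0.01, 20.0, model.n)
        Lh = float(rng.uniform(0.2, 1.5))
        U = model.uptake_matrix(C, np.array([Lh]))
        kh = 4.0
        cb = C[model.index["bac"]]
        den = 1.0 + sum(C[model.index[d]] / ksh[d] for d in ksh)
        for j, gd in enumerate(model.iD):
            d = model.ids[gd]
            expect = kh * (C[model.index[d]] / ksh[d]) / den * Lh * cb
            assert U[0, j] == pytest.approx(expect, rel=1e-14)
        assert U.sum() <= kh * Lh * cb + 1e-12


class TestDerivatives:
    def test_extinction_fixed_point(self, tiny_spec):
        model = CompiledModel(tiny_spec)
        forcing = Forcing.constant(0, 10, dilution=0.0, load_N=0.0, load_P=0.0)
        dC, _ = model.derivatives(0.0, np.zeros(model.n), forcing)
        assert np.all(dC == 0.0)

    def test_pure_washout(self, tiny_spec):
        for c in tiny_spec.components.values():
            for p in c.params.values():
                p.value = 0.0
            for table in c.tables.values():
                for p in table.values():
                    p.value = 0.0
        model = CompiledModel(tiny_spec)
        forcing = Forcing.constant(0, 10, dilution=0.13, load_N=0.0, load_P=0.0)
        C = np.linspace(1, 9, model.n)
        dC, _ = model.derivatives(0.0, C, forcing)
        assert dC == pytest.approx(-0.13 * C, rel=1e-12)

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=25, deadline=None)
    def test_ledger_closure_is_bit_exact(self, seed):
        """dC/dt equals gains-minus-losses replayed from the ledger records
        of each component, with identical floating-point accumulation."""
        model = CompiledModel(build_tiny_spec())
        forcing = build_tiny_forcing()
        rng = np.random.default_rng(seed)
        C = rng.uniform(0.0, 15.0, model.n)
        t = float(rng.uniform(0, 700))
        dC, records = model.derivatives(t, C, forcing)
        idx = {cid: i for i, cid in enumerate(model.ids)}
        gains = np.zeros(model.n)
        losses = np.zeros(model.n)
        for (_, src, dst, _, rate) in records:
            if dst in idx:
                gains[idx[dst]] += rate
            if src in idx:
                losses[idx[src]] += rate
        assert np.array_equal(gains - losses, dC)

    def test_kernel_matches_reference_implementation(self, tiny_spec, tiny_forcing):
        model = CompiledModel(tiny_spec)
        rng = np.random.default_rng(0)
        for _ in range(10):
            C = rng.uniform(0.0, 20.0, model.n)
            t = float(rng.uniform(0, 700))
            R_fast = model.rates(t, C, tiny_forcing)
            R_ref = model.rates_reference(t, C, tiny_forcing)
            np.testing.assert_allclose(R_fast, R_ref, rtol=1e-12, atol=1e-14)

    def test_biomass_linearity_for_bacteria(self, tiny_spec, tiny_forcing):
        """Doubling a bacterium's concentration doubles each of its
        per-process rates (per-capita rates depend only on the environment)."""
        model = CompiledModel(tiny_spec)
        C = model.c0_vector()
        b = model.index["bac"]
        R1 = model.rates(50.0, C, tiny_forcing, dormancy=False)
        C2 = C.copy()
        C2[b] *= 2.0
        R2 = model.rates(50.0, C2, tiny_forcing, dormancy=False)
        own = (model.ch_src == b) | (model.ch_dst == b)
        np.testing.assert_allclose(R2[own], 2.0 * R1[own], rtol=1e-12)


class TestDormancy:
    def test_floor_hold(self, tiny_spec):
        model = CompiledModel(tiny_spec)
        forcing = Forcing.constant(0, 10, light=0.0, dilution=0.2)  # losses only
        C = model.c0_vector()
        C[model.index["phy"]] = 0.01     # exactly at the floor
        dC, _ = model.derivatives(0.0, C, forcing)
        assert dC[model.index["phy"]] >= -1e-15

    def test_inactive_above_floor(self, tiny_spec, tiny_forcing):
        model = CompiledModel(tiny_spec)
        C = model.c0_vector()           # phy at 5.0 = 500 x floor
        R_raw = model.rates(10.0, C, tiny_forcing, dormancy=False)
        R = model.rates(10.0, C, tiny_forcing, dormancy=True)
        np.testing.assert_array_equal(R, R_raw)

    def test_trajectory_never_underflows_floor(self, tiny_spec):
        from fluxnet.simulate import integrate
        spec = tiny_spec
        spec.components["phy"].c0 = Param(0.012)   # just above floor, big losses
        forcing = Forcing.constant(0, 120, light=0.05, dilution=0.3)
        traj = integrate(spec, forcing, (0, 120), output_dt=0.5, with_ledger=False)
        flr = 0.01
        assert traj.series("phy").min() >= flr * (1 - 1e-9)


class TestInhibition:
    def test_zero_inhibitor_zero_kill(self, tiny_spec, tiny_forcing):
        model = CompiledModel(tiny_spec)
        C = model.c0_vector()
        C[model.index["inh"]] = 0.0
        R = model.rates(0.0, C, tiny_forcing)
        kill = R[model.ch_proc == "inhibition-kill"]
        assert np.all(kill == 0.0)

    def test_monod_midpoint_kill(self, tiny_spec, tiny_forcing):
        model = CompiledModel(tiny_spec)
        C = model.c0_vector()
        C[model.index["inh"]] = 2.0     # == ZK
        R = model.rates(0.0, C, tiny_forcing, dormancy=False)
        kill = R[(model.ch_proc == "inhibition-kill")].sum()
        kmax, c_phy = 0.3, 5.0
        assert kill == pytest.approx(kmax * c_phy / 2.0, rel=1e-12)

    def test_two_inhibitors_additive(self, tiny_forcing):
        spec = build_tiny_spec()
        spec.components["inh2"] = type(spec.components["inh"])("inh2", "inhibitor", Param(0.0))
        spec.components["inh2"].params["kdec"] = Param(0.05)
        phy = spec.components["phy"]
        phy.tables["Zkill"]["inh2"] = Param(0.2)
        phy.tables["ZK"]["inh2"] = Param(1.0)
        model = CompiledModel(spec)
        C = model.c0_vector()
        C[model.index["inh"]] = 3.0
        C[model.index["inh2"]] = 0.7
        R = model.rates(0.0, C, tiny_forcing, dormancy=False)
        phy_kill = R[(model.ch_proc == "inhibition-kill")
                     & (model.ch_src == model.index["phy"])].sum()
        expect = (0.3 * 3.0 / (2.0 + 3.0) + 0.2 * 0.7 / (1.0 + 0.7)) * 5.0
        assert phy_kill == pytest.approx(expect, rel=1e-12)
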