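"""Integration, trajectory invariants and observation mapping."""

import numpy as np
import pytest

from fluxnet.config import ComponentSpec, ModelSpec, ObservationMapping, Param, delump
from fluxnet.dynamics import Forcing
from fluxnet.simulate import IntegrationError, integrate, observe

from conftest import build_tiny_forcing, build_tiny_spec


def washout_spec(n=3):
    spec = ModelSpec()
    for k in range(n):
        spec.components[f"d{k}"] = ComponentSpec(f"d{k}", "DOM", Param(float(k + 1)))
    return spec


class TestIntegrate:
    def test_washout_closed_form(self):
        spec = washout_spec()
        forcing = Forcing.constant(0, 10, dilution=0.1)
        traj = integrate(spec, forcing, (0, 10), output_dt=1.0, with_ledger=False,
                         rtol=1e-10, atol=1e-12)
        expect = np.array([1.0, 2.0, 3.0]) * np.exp(-1.0)
        np.testing.assert_allclose(traj.C[-1], expect, rtol=1e-8)

    def test_matches_fine_fixed_step_reference(self):
        """Logistic-like single phytoplankton drawing down one nutrient
        agrees with an independent fixed-step RK4 integration."""
        spec = ModelSpec()
        spec.environment = {"background_extinction": Param(0.0), "depth": Param(10.0)}
        spec.stoichiometry = {"phytoplankton": {"n_to_c": 0.15, "p_to_c": 0.0}}
        phy = ComponentSpec("phy", "phytoplankton", Param(0.5))
        phy.params = {"kp": Param(1.0), "kr": Param(0.05), "I_opt": Param(1.0),
                      "Topt": Param(15.0), "shade": Param(0.0)}
        phy.tables = {"KsN": {"n": Param(2.0)}}
        spec.components["phy"] = phy
        spec.components["n"] = ComponentSpec("n", "nutrient", Param(20.0), dom_class="N")
        forcing = Forcing.constant(0, 60, temperature=15.0, light=1.0, dilution=0.0,
                                   load_N=0.0)
        traj = integrate(spec, forcing, (0, 60), output_dt=2.0, with_ledger=False,
                         rtol=1e-10, atol=1e-12)

        from fluxnet.dynamics import CompiledModel
        model = CompiledModel(spec)
        y = model.c0_vector()
        h = 0.002
        out = [y.copy()]
        t = 0.0
        for k in range(int(60 / h)):
            k1 = model.rhs(t, y, forcing)
            k2 = model.rhs(t + h / 2, y + h / 2 * k1, forcing)
            k3 = model.rhs(t + h / 2, y + h / 2 * k2, forcing)
            k4 = model.rhs(t + h, y + h * k3, forcing)
            y = y + h / 6 * (k1 + 2 * k2 + 2 * k3 + k4)
            t += h
            if (k + 1) % 1000 == 0:
                out.append(y.copy())
        ref = np.array(out)
        np.testing.assert_allclose(traj.C, ref, rtol=1e-6, atol=1e-8)

    def test_forcing_gap_reported(self, tiny_spec):
        forcing = Forcing.constant(0, 5)
        with pytest.raises(IntegrationError, match="cover"):
            integrate(tiny_spec, forcing, (0, 10))

    def test_deterministic(self, tiny_spec, tiny_forcing):
        a = integrate(tiny_spec, tiny_forcing, (0, 100), output_dt=2.0)
        b = integrate(tiny_spec, tiny_forcing, (0, 100), output_dt=2.0)
        np.testing.assert_array_equal(a.C, b.C)
        assert a.ledger.equals(b.ledger)

    def test_output_dt_invariance(self, tiny_spec, tiny_forcing):
        a = integrate(tiny_spec, tiny_forcing, (0, 100), output_dt=2.0, with_ledger=False)
        b = integrate(tiny_spec, tiny_forcing, (0, 100), output_dt=10.0, with_ledger=False)
        shared = np.isin(a.t, b.t)
        scale = np.abs(a.C).max(axis=0) + 1e-12
        dev = np.abs(a.C[shared] - b.C) / scale
        assert dev.max() < 1e-5

    def test_interval_ledger_closure(self, tiny_spec, tiny_forcing):
        traj = integrate(tiny_spec, tiny_forcing, (0, 200), output_dt=2.0)
        led = traj.ledger
        dt = np.diff(traj.t)
        for i, cid in enumerate(traj.ids):
            net = np.zeros(len(traj.t) - 1)
            gains = led[led.sink == cid].groupby("t0").rate.sum()
            losses = led[led.source == cid].groupby("t0").rate.sum()
            for k, t0 in enumerate(traj.t[:-1]):
                net[k] = gains.get(t0, 0.0) - losses.get(t0, 0.0)
            dC = np.diff(traj.C[:, i])
            tol = 1e-6 * max(np.abs(traj.C[:, i]).max(), 1e-12)
            assert np.abs(dC - net * dt).max() <= tol

    def test_whole_system_carbon_budget(self, tiny_spec, tiny_forcing):
        """Photosynthesis input balances standing-stock change plus all
        carbon sinks over the window."""
        traj = integrate(tiny_spec, tiny_forcing, (0, 400), output_dt=2.0)
        led = traj.ledger
        organic = [c.id for c in tiny_spec.components.values()
                   if c.compartment in ("phytoplankton", "bacteria", "DOM", "POM")]
        dt = led.t1 - led.t0
        pho = (led[led.process == "photosynthesis"].rate
               * dt[led.process == "photosynthesis"]).sum()
        sinks = led[led.sink.str.startswith("sink:") & led.source.isin(organic)]
        out = (sinks.rate * (sinks.t1 - sinks.t0)).sum()
        idx = [traj.ids.index(c) for c in organic]
        dC = traj.C[-1, idx].sum() - traj.C[0, idx].sum()
        assert pho == pytest.approx(dC + out, rel=1e-6, abs=1e-8)


class TestDelumpNeutrality:
    def test_daughter_sum_equals_parent(self, tiny_spec, tiny_forcing):
        parent = integrate(tiny_spec, tiny_forcing, (0, 365), output_dt=2.0,
                           with_ledger=False)
        split = delump(tiny_spec)
        twin = integrate(split, tiny_forcing, (0, 365), output_dt=2.0,
                         with_ledger=False)
        for cid in tiny_spec.components:
            kids = split.leaves_under(cid)
            s = sum(twin.series(k) for k in kids)
            p = parent.series(cid)
            assert np.abs(s - p).max() <= 1e-6 * max(p.max(), 1e-9)


class TestObserve:
    def test_chlorophyll_weighted_sum(self, tiny_spec, tiny_forcing):
        tiny_spec.mappings = [ObservationMapping("chl", [("@phytoplankton", 0.02)])]
        traj = integrate(tiny_spec, tiny_forcing, (0, 50), output_dt=5.0,
                         with_ledger=False)
        out = observe(traj)
        np.testing.assert_allclose(out["chl"], 0.02 * traj.series("phy"))

    def test_total_bacteria_sum(self, tiny_spec, tiny_forcing):
        tiny_spec.mappings = [ObservationMapping("dap", [("@bacteria", 50.0)])]
        traj = integrate(tiny_spec, tiny_forcing, (0, 50), output_dt=5.0,
                         with_ledger=False)
        np.testing.assert_allclose(observe(traj)["dap"], 50.0 * traj.series("bac"))

    def test_composed_particulate_mapping(self, tiny_spec, tiny_forcing):
        """Particulate storage compound = POM pool plus the phytoplankton's
        internal content (composition fraction times biomass)."""
        fx = tiny_spec.components["phy"].tables["Fx"]["dch"].value
        tiny_spec.mappings = [ObservationMapping(
            "lam", [("pch", 1.0), ("phy", fx)])]
        traj = integrate(tiny_spec, tiny_forcing, (0, 50), output_dt=5.0,
                         with_ledger=False)
        expect = traj.series("pch") + fx * traj.series("phy")
        np.testing.assert_allclose(observe(traj)["lam"], expect)

    def test_lineage_resolution_up_and_down(self, tiny_spec, tiny_forcing):
        split = delump(tiny_spec)
        # downward: a parent id maps to the sum of its daughters
        split.mappings = [ObservationMapping("phy_tot", [("phy", 1.0)])]
        traj = integrate(split, tiny_forcing, (0, 20), output_dt=5.0, with_ledger=False)
        expect = traj.series("phy.a") + traj.series("phy.b")
        np.testing.assert_allclose(observe(traj)["phy_tot"], expect)
        # upward: a future leaf id maps onto its current ancestor
        tiny_spec.mappings = [ObservationMapping("leaf", [("phy.a.a", 3.0)])]
        traj2 = integrate(tiny_spec, tiny_forcing, (0, 20), output_dt=5.0,
                          with_ledger=False)
        np.testing.assert_allclose(observe(traj2)["leaf"], 3.0 * traj2.series("phy"))
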