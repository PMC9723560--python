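import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("repro", derandomize=True, deadline=None)
settings.load_profile("repro")

from fluxnet.config import ComponentSpec, ModelSpec, Param
from fluxnet.dynamics import Forcing
from fluxnet.fixtures import FixtureRecipe, generate_observations, make_truth
from fluxnet.simulate import integrate


def build_tiny_spec() -> ModelSpec:
    """Hand-built 9-component ecosystem used across unit tests."""
    spec = ModelSpec(name="tiny")
    spec.environment = {k: Param(v) for k, v in dict(
        depth=10.0, background_extinction=0.15, kappa_r=0.07,
        kappa_f=0.05, Tref=20.0).items()}
    spec.stoichiometry = {"phytoplankton": {"n_to_c": 0.15, "p_to_c": 0.009},
                          "bacteria": {"n_to_c": 0.2, "p_to_c": 0.0125}}

    def comp(id, compartment, c0, params=None, tables=None, **kw):
        c = ComponentSpec(id, compartment, Param(c0))
        for k, v in (params or {}).items():
            c.params[k] = Param(v)
        for tn, tb in (tables or {}).items():
            c.tables[tn] = {k: Param(v) for k, v in tb.items()}
        for k, v in kw.items():
            setattr(c, k, v)
        spec.components[id] = c
        return c

    comp("phy", "phytoplankton", 5.0, params=dict(
        kp=1.2, kr=0.08, ke=0.03, ef=0.15, ku=0.4, vs=0.3, Cflr=0.01,
        I_opt=1.0, Topt=16, T_kappa=0.06, T_sigma=4, S_opt=32, S_sigma=5,
        death_peak=150, death_width=40, death_base=0.15, shade=0.01),
        tables=dict(Fe={"dch": 0.6, "dgl": 0.4}, Fx={"dch": 0.35, "dgl": 0.2},
                    Pom={"pch": 1.0}, KsN={"nit": 1.0, "pho4": 0.06},
                    KsM={"mic": 0.05}, Mcons={"mic": 0.001},
                    Zkill={"inh": 0.3}, ZK={"inh": 2.0}))
    comp("dch", "DOM", 1.0, dom_class="storage")
    comp("dgl", "DOM", 1.0, dom_class="cell_wall")
    comp("pch", "POM", 2.0, pom_partner="dch", params=dict(kf=0.08, vs=0.5))
    comp("bac", "bacteria", 0.5, params=dict(
        kh=4.0, Yh=0.3, ku=0.15, Cflr=0.005, Topt=18, T_kappa=0.05, T_sigma=6),
        tables=dict(Ksh={"dch": 5.0, "dgl": 8.0}, Fx={"dgl": 0.3}, Pom={"pch": 1.0},
                    Mexu={"mic": 0.01}, Zexu={"inh": 0.002}))
    comp("nit", "nutrient", 8.0, dom_class="N")
    comp("pho4", "nutrient", 0.5, dom_class="P")
    comp("mic", "micronutrient", 1.0)
    comp("inh", "inhibitor", 0.0, params=dict(kdec=0.05))
    return spec


def build_tiny_forcing(t1=800.0) -> Forcing:
    t = np.arange(0.0, t1, 2.0)
    return Forcing(t=t, series={
        "temperature": 12 + 8 * np.sin(2 * np.pi * (t - 120) / 365),
        "light": 1.0 + 0.8 * np.sin(2 * np.pi * (t - 80) / 365),
        "salinity": np.full_like(t, 32.0),
        "dilution": np.full_like(t, 0.05),
        "load_N": np.full_like(t, 0.5),
        "load_P": np.full_like(t, 0.03),
    })


@pytest.fixture()
def tiny_spec():
    return build_tiny_spec()


@pytest.fixture()
def tiny_forcing():
    return build_tiny_forcing()


@pytest.fixture(scope="session")
def truth_bundle():
    """Default noiseless known-truth ecosystem (seeded)."""
    return make_truth(FixtureRecipe(noise_sd=0.0, gap_prob=0.0, seed=0))


@pytest.fixture(scope="session")
def truth_traj(truth_bundle):
    """Ledgered reference simulation of the truth ecosystem."""
    tb = truth_bundle
    return integrate(tb.truth_spec, tb.forcing, tb.window, output_dt=2.0,
                     with_ledger=True)


@pytest.fixture(scope="session")
def noiseless_obs(truth_bundle):
    """Noiseless observations at the calibration's own evaluation settings."""
    tb = truth_bundle
    traj = integrate(tb.truth_spec, tb.forcing, tb.window,
                     output_dt=tb.recipe.cadence, with_ledger=False,
                     rtol=1e-5, atol=1e-3)
    return generate_observations(traj, tb.recipe)
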