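"""Flux-network extraction, diet aggregates and recurrence statistics."""

import math

import numpy as np
import pandas as pd
import pytest

from fluxnet.dynamics import CompiledModel, Forcing
from fluxnet.network import (
    FluxNetworkSnapshot,
    bloom_windows,
    conc_flux_regression,
    extract_network,
    growth_rates,
    network_recurrence,
    oligotroph_weight,
    turnover_time,
)
from fluxnet.simulate import StateTrajectory

from conftest import build_tiny_spec


def synthetic_trajectory(ledger_rows, C=None, t=(0.0, 1.0, 2.0)):
    """A StateTrajectory around a hand-written ledger (synthetic stand-in)."""
    spec = build_tiny_spec()
    model = CompiledModel(spec)
    t = np.asarray(t)
    if C is None:
        C = np.tile(model.c0_vector(), (len(t), 1))
    led = pd.DataFrame(ledger_rows, columns=["t0", "t1", "source", "sink",
                                             "process", "rate"])
    return StateTrajectory(ids=list(model.ids), t=t, C=C, ledger=led, model=model)


class TestExtractNetwork:
    def test_single_path_steady_state(self):
        rows = [(0, 1, "phy", "dch", "exudation", 1.0),
                (0, 1, "dch", "bac", "heterotrophy", 1.0)]
        traj = synthetic_trajectory(rows)
        snap = extract_network(traj, (0, 1), traced=True)
        e = snap.edges
        got = e[(e.source == "phy") & (e.sink == "bac")].flux.iloc[0]
        assert got == pytest.approx(1.0)

    def test_proportional_attribution(self):
        rows = [(0, 1, "phy", "dch", "exudation", 0.3),
                (0, 1, "bac", "dch", "death", 0.7),
                (0, 1, "dch", "bac", "heterotrophy", 2.0)]
        traj = synthetic_trajectory(rows)
        snap = extract_network(traj, (0, 1), traced=True)
        e = snap.edges.set_index(["source", "sink"]).flux
        assert e[("phy", "bac")] == pytest.approx(0.6)
        assert e[("bac", "bac")] == pytest.approx(1.4)

    def test_pom_sources_resolve_to_microbes(self):
        rows = [(0, 1, "phy", "pch", "death", 1.0),
                (0, 1, "pch", "dch", "dissolution", 0.5),
                (0, 1, "dch", "bac", "heterotrophy", 0.4)]
        traj = synthetic_trajectory(rows)
        snap = extract_network(traj, (0, 1), traced=True)
        e = snap.edges.set_index(["source", "sink"]).flux
        assert e[("phy", "bac")] == pytest.approx(0.4)

    def test_traced_attribution_conserves_uptake(self):
        """Random producer/OM/consumer ledger: traced totals equal untraced."""
        rng = np.random.default_rng(7)
        rows = []
        producers = ["phy", "bac"]
        pools = ["dch", "dgl", "pch"]
        for p in producers:
            for q in pools:
                rows.append((0, 1, p, q, "death", float(rng.uniform(0.1, 2))))
        rows.append((0, 1, "pch", "dch", "dissolution", float(rng.uniform(0.1, 1))))
        uptake = 0.0
        for q in ("dch", "dgl"):
            u = float(rng.uniform(0.1, 2))
            uptake += u
            rows.append((0, 1, q, "bac", "heterotrophy", u))
        traj = synthetic_trajectory(rows)
        snap = extract_network(traj, (0, 1), traced=True)
        into_bac = snap.edges[snap.edges.sink == "bac"].flux.sum()
        assert into_bac == pytest.approx(uptake, rel=1e-12)

    def test_cutoff_applied_after_totals(self):
        rows = [(0, 1, "phy", "dch", "exudation", 100.0),
                (0, 1, "phy", "dgl", "exudation", 0.001)]
        traj = synthetic_trajectory(rows)
        snap = extract_network(traj, (0, 1), cutoff=1e-3)
        assert len(snap.edges) == 1
        assert snap.nodes.set_index("component").outflux["phy"] == pytest.approx(100.001)

    def test_empty_window_rejected(self):
        traj = synthetic_trajectory([(0, 1, "phy", "dch", "exudation", 1.0)])
        with pytest.raises(ValueError, match="window"):
            extract_network(traj, (5.0, 5.0))


class TestTurnover:
    def test_definition(self):
        rows = [(0, 1, "phy", "dch", "exudation", 0.25),
                (0, 1, "dch", "bac", "heterotrophy", 0.25)]
        C = np.ones((3, 9))
        traj = synthetic_trajectory(rows, C=C)
        traj.C[:, traj.ids.index("dch")] = 1.0
        assert turnover_time(traj, "dch", (0, 1)) == pytest.approx(4.0)

    def test_conventions_agree_at_steady_state(self):
        rows = [(0, 1, "phy", "dch", "exudation", 0.5),
                (0, 1, "dch", "bac", "heterotrophy", 0.5)]
        traj = synthetic_trajectory(rows)
        vals = {c: turnover_time(traj, "dch", (0, 1), convention=c)
                for c in ("in", "out", "mean")}
        assert vals["in"] == vals["out"] == vals["mean"]

    def test_zero_flux_flagged_infinite(self):
        traj = synthetic_trajectory([(0, 1, "phy", "dch", "exudation", 1.0)])
        assert math.isinf(turnover_time(traj, "dgl", (0, 1)))


class TestOligotrophWeight:
    def test_midpoint(self):
        assert oligotroph_weight(0.2, 0.2) == pytest.approx(0.5)

    def test_nongrower_is_fully_oligotrophic(self):
        assert oligotroph_weight(0.0, 0.3) == 1.0
        assert oligotroph_weight(-0.5, 0.3) == 1.0   # floored before powers

    def test_double_average_growth(self):
        assert oligotroph_weight(0.4, 0.2, n=5) == pytest.approx(1.0 / 33.0)

    def test_invalid_average_rejected(self):
        with pytest.raises(ValueError):
            oligotroph_weight(0.1, 0.0)


class TestGrowthAndBlooms:
    def test_growth_rate_from_biomass_change_plus_dilution(self):
        t = np.arange(0.0, 11.0)
        traj = synthetic_trajectory([(0, 1, "phy", "dch", "exudation", 0.0)], t=t,
                                    C=np.ones((11, 9)))
        i = traj.ids.index("bac")
        traj.C[:, i] = np.exp(0.23 * t)
        kg = growth_rates(traj, ["bac"], (0, 10), dilution=0.05)
        assert kg["bac"] == pytest.approx(0.28)

    def test_bloom_window_definition(self):
        t = np.arange(0.0, 730.0, 1.0)
        chl = 1.0 + 4.0 * np.exp(-0.5 * ((t % 365 - 130) / 12.0) ** 2)
        wins = bloom_windows(t, chl, threshold=3.0, duration=28.0)
        assert len(wins) == 2
        start = wins[0][0]
        assert wins[0][1] == start + 28.0
        assert chl[int(start)] > 3.0 and chl[int(start) - 1] <= 3.0


class TestRegression:
    def test_exact_power_law(self):
        rng = np.random.default_rng(0)
        rows = []
        t = np.arange(0.0, 30.0)
        C = np.ones((len(t), 9))
        for k in range(len(t) - 1):
            conc = float(rng.uniform(0.5, 20))
            C[k, 8 - 4] = conc   # bac index is 4 in tiny spec order
            rows.append((float(k), float(k + 1), "dch", "bac", "heterotrophy",
                         0.1 * conc ** 0.9))
        traj = synthetic_trajectory(rows, C=C, t=t)
        i = traj.ids.index("bac")
        traj.C[:, i] = C[:, 4]
        out = conc_flux_regression(traj, [(0.0, 29.0)])
        slope, intercept, r2, n = out["all"]
        assert slope == pytest.approx(0.9, abs=1e-9)
        assert intercept == pytest.approx(-1.0, abs=1e-9)
        assert r2 == pytest.approx(1.0)

    def test_shuffled_flux_destroys_correlation(self):
        rng = np.random.default_rng(1)
        rows = []
        t = np.arange(0.0, 202.0)
        C = np.ones((len(t), 9))
        concs = rng.uniform(0.5, 20, len(t) - 1)
        fluxes = 0.1 * concs ** 0.9
        rng.shuffle(fluxes)
        for k in range(len(t) - 1):
            C[k, 4] = concs[k]
            rows.append((float(k), float(k + 1), "dch", "bac", "heterotrophy",
                         float(fluxes[k])))
        traj = synthetic_trajectory(rows, C=C, t=t)
        out = conc_flux_regression(traj, [(0.0, 201.0)])
        assert out["all"][2] < 0.05


class TestRecurrence:
    @staticmethod
    def snap_from_vec(vec, compartment="DOM"):
        nodes = pd.DataFrame({
            "component": list(vec),
            "compartment": compartment,
            "influx": list(vec.values()),
            "outflux": [0.0] * len(vec),
        })
        return FluxNetworkSnapshot(window=(0, 1), nodes=nodes,
                                   edges=pd.DataFrame(columns=["source", "sink", "flux"]),
                                   cutoff=0.0, traced=False)

    def test_identical_snapshots_similarity_one(self):
        v = {"a": 1.0, "b": 2.0, "c": 0.5}
        S, rec = network_recurrence([self.snap_from_vec(v)] * 3, "dom")
        assert np.allclose(S, 1.0)
        assert rec[0] == "b"

    def test_disjoint_supports_similarity_zero(self):
        a = self.snap_from_vec({"a": 1.0, "b": 0.0})
        b = self.snap_from_vec({"a": 0.0, "b": 2.0})
        S, rec = network_recurrence([a, b], "dom")
        assert S[0, 1] == pytest.approx(0.0)
        assert rec == []

    def test_matches_textbook_bray_curtis(self):
        rng = np.random.default_rng(3)
        for _ in range(100):
            x = rng.uniform(0, 5, 6)
            y = rng.uniform(0, 5, 6)
            a = self.snap_from_vec({f"c{k}": x[k] for k in range(6)})
            b = self.snap_from_vec({f"c{k}": y[k] for k in range(6)})
            S, _ = network_recurrence([a, b], "dom")
            expect = 1.0 - np.abs(x - y).sum() / (x + y).sum()
            assert S[0, 1] == pytest.approx(expect, rel=1e-12)

    def test_symmetry_and_unit_diagonal(self):
        rng = np.random.default_rng(4)
        snaps = [self.snap_from_vec({f"c{k}": float(rng.uniform(0, 3)) for k in range(5)})
                 for _ in range(4)]
        S, _ = network_recurrence(snaps, "dom")
        assert np.allclose(S, S.T)
        assert np.allclose(np.diag(S), 1.0)
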