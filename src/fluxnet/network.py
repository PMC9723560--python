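"""From flux ledger to carbon-flux networks and their summary statistics.

The ledger records every process-resolved carbon transfer; this module
window-averages it into component-to-component networks (optionally
tracing fluxes through the DOM/POM pools back to their producers),
computes pool turnover times, oligotroph/copiotroph diet aggregates over
bloom windows, concentration-flux regressions, and year-to-year network
recurrence via Bray-Curtis similarity.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd
from scipy.spatial.distance import braycurtis
from scipy.stats import linregress

from .simulate import StateTrajectory

__all__ = [
    "FluxNetworkSnapshot",
    "extract_network",
    "turnover_time",
    "oligotroph_weight",
    "growth_rates",
    "bloom_windows",
    "dom_origin_fractions",
    "bloom_aggregates",
    "conc_flux_regression",
    "network_recurrence",
]

ORGANIC = ("phytoplankton", "bacteria", "DOM", "POM")


@dataclass
class FluxNetworkSnapshot:
    """Component-to-component carbon fluxes averaged over a time window."""

    window: tuple[float, float]
    nodes: pd.DataFrame       # component, compartment, influx, outflux (µmolC/L/d)
    edges: pd.DataFrame       # source, sink, flux (µmolC/L/d)
    cutoff: float
    traced: bool

    def graph(self) -> nx.DiGraph:
        g = nx.DiGraph()
        for r in self.nodes.itertuples():
            g.add_node(r.component, compartment=r.compartment,
                       influx=r.influx, outflux=r.outflux)
        for r in self.edges.itertuples():
            g.add_edge(r.source, r.sink, flux=r.flux)
        return g

    def layer_vector(self, layer: str) -> pd.Series:
        """Named flux vector for recurrence comparisons.

        layers: "producers" (phytoplankton out-flux), "dom" (DOM exchanged,
        in+out), "consumers" (bacteria in-flux), "coupling_abs" /
        "coupling_rel" (traced producer-consumer pairs, absolute µmolC/L/d
        or fraction of the consumer's carbon supply).
        """
        nodes = self.nodes.set_index("component")
        if layer == "producers":
            sel = nodes[nodes.compartment == "phytoplankton"]
            return sel.outflux
        if layer == "dom":
            sel = nodes[nodes.compartment == "DOM"]
            return sel.influx + sel.outflux
        if layer == "consumers":
            sel = nodes[nodes.compartment == "bacteria"]
            return sel.influx
        if layer in ("coupling_abs", "coupling_rel"):
            if not self.traced:
                raise ValueError("coupling layers need a traced snapshot")
            comp = nodes.compartment
            e = self.edges
            mask = e.source.map(comp).eq("phytoplankton") & e.sink.map(comp).eq("bacteria")
            ee = e[mask]
            v = ee.set_index(ee.source + ">" + ee.sink).flux
            if layer == "coupling_rel":
                tot = ee.groupby("sink").flux.transform("sum")
                v = (ee.flux / tot).set_axis(v.index)
            return v
        raise ValueError(f"unknown layer {layer!r}")


def _window_mean_fluxes(traj: StateTrajectory, window) -> pd.DataFrame:
    """Time-weighted mean rate per (source, sink, process) over the window."""
    led = traj.ledger
    if led is None:
        raise ValueError("trajectory has no ledger (integrate with with_ledger=True)")
    t0, t1 = float(window[0]), float(window[1])
    if t1 <= t0:
        raise ValueError("empty window")
    ov = np.minimum(led.t1.to_numpy(), t1) - np.maximum(led.t0.to_numpy(), t0)
    m = ov > 0
    if not m.any():
        raise ValueError(f"ledger does not cover window [{t0}, {t1}]")
    df = led.loc[m, ["source", "sink", "process"]].copy()
    df["flux"] = led.rate.to_numpy()[m] * ov[m] / (t1 - t0)
    return df.groupby(["source", "sink", "process"], as_index=False).flux.sum()


def _producer_shares(mean_fluxes: pd.DataFrame, compartment: dict[str, str]) -> dict[str, dict[str, float]]:
    """First-order provenance: who supplied each OM pool's inflow.

    POM inflow sources are resolved through to their own producers, so the
    shares of a DOM pool always point at microbes (or at the pool's
    standing stock where it had no inflow in the window).
    """
    pools = [c for c, comp in compartment.items() if comp in ("DOM", "POM")]
    inflow: dict[str, dict[str, float]] = {p: {} for p in pools}
    for r in mean_fluxes.itertuples():
        if r.sink in inflow and r.source in compartment:
            inflow[r.sink][r.source] = inflow[r.sink].get(r.source, 0.0) + r.flux
    shares: dict[str, dict[str, float]] = {}

    def resolve(pool: str) -> dict[str, float]:
        if pool in shares:
            return shares[pool]
        shares[pool] = {}     # placeholder breaks would-be cycles
        src = inflow[pool]
        tot = sum(src.values())
        out: dict[str, float] = {}
        if tot <= 0:
            out[f"stock:{pool}"] = 1.0
        else:
            for s, f in src.items():
                frac = f / tot
                if compartment.get(s) in ("DOM", "POM"):
                    for p2, f2 in resolve(s).items():
                        out[p2] = out.get(p2, 0.0) + frac * f2
                else:
                    out[s] = out.get(s, 0.0) + frac
        shares[pool] = out
        return out

    for p in pools:
        resolve(p)
    return shares


def extract_network(traj: StateTrajectory, window, cutoff: float = 0.0,
                    traced: bool = False) -> FluxNetworkSnapshot:
    """Carbon-flux network over a window.

    Direct mode lists the producer->OM and OM->consumer edges as ledgered.
    Traced mode attributes each DOM->bacterium flux to upstream producers
    in proportion to their share of that DOM's window inflow, yielding
    phytoplankton->bacterium edges.  ``cutoff`` drops edges below that
    fraction of the total edge flux (applied after totals are computed).
    """
    spec = traj.model.spec
    compartment = {c.id: c.compartment for c in spec.components.values()}
    mf = _window_mean_fluxes(traj, window)
    carbon = mf[[compartment.get(s) in ORGANIC or compartment.get(k) in ORGANIC
                 for s, k in zip(mf.source, mf.sink)]]

    inter = carbon[[s in compartment and k in compartment
                    for s, k in zip(carbon.source, carbon.sink)]]
    if traced:
        shares = _producer_shares(carbon, compartment)
        rows = []
        for r in inter.itertuples():
            if compartment[r.source] in ("DOM", "POM") and compartment[r.sink] == "bacteria":
                for prod, frac in shares[r.source].items():
                    rows.append((prod, r.sink, frac * r.flux))
            elif compartment[r.source] in ("DOM", "POM") or \
                    compartment[r.sink] in ("DOM", "POM"):
                continue       # producer->OM and OM->OM folded into traced edges
            else:
                rows.append((r.source, r.sink, r.flux))
        edges = pd.DataFrame(rows, columns=["source", "sink", "flux"])
    else:
        edges = inter.rename(columns={})[["source", "sink", "flux"]]
    edges = edges.groupby(["source", "sink"], as_index=False).flux.sum()

    node_in = carbon.groupby("sink").flux.sum()
    node_out = carbon.groupby("source").flux.sum()
    ids = [c for c, comp in compartment.items() if comp in ORGANIC]
    nodes = pd.DataFrame({
        "component": ids,
        "compartment": [compartment[c] for c in ids],
        "influx": [float(node_in.get(c, 0.0)) for c in ids],
        "outflux": [float(node_out.get(c, 0.0)) for c in ids],
    })
    total = edges.flux.sum()
    if cutoff > 0 and total > 0:
        edges = edges[edges.flux >= cutoff * total].reset_index(drop=True)
    return FluxNetworkSnapshot(window=(float(window[0]), float(window[1])),
                               nodes=nodes, edges=edges, cutoff=cutoff, traced=traced)


def turnover_time(traj: StateTrajectory, component: str, window,
                  convention: str = "mean") -> float:
    """Standing stock / through-flux, in days.

    Through-flux is the mean of total inflow and outflow ("mean", default),
    or either one ("in"/"out").  Zero through-flux is flagged as inf.
    """
    mf = _window_mean_fluxes(traj, window)
    fin = mf[mf.sink == component].flux.sum()
    fout = mf[mf.source == component].flux.sum()
    through = {"mean": 0.5 * (fin + fout), "in": fin, "out": fout}[convention]
    t0, t1 = window
    m = (traj.t >= t0) & (traj.t <= t1)
    cbar = float(traj.series(component)[m].mean())
    if through <= 0:
        return math.inf
    return cbar / through


def oligotroph_weight(kg_i, kg_ave: float, n: int = 5):
    """Continuous oligotrophy weight from growth rates.

    fOLI_i = kg_ave^n / (kg_ave^n + kg_i^n); slow growers (kg below the
    community average) score above 0.5.  Negative growth rates are floored
    at zero before exponentiation.
    """
    if kg_ave <= 0:
        raise ValueError("kg_ave must be > 0")
    kg = np.maximum(np.asarray(kg_i, dtype=float), 0.0)
    out = kg_ave ** n / (kg_ave ** n + kg ** n)
    return float(out) if np.isscalar(kg_i) or np.ndim(kg_i) == 0 else out


def growth_rates(traj: StateTrajectory, ids: list[str], window,
                 dilution: float = 0.0) -> dict[str, float]:
    """Window-average net growth rate from biomass change, plus dilution:
    kg = (ln C(t_end) - ln C(t_start)) / (t_end - t_start) + Q/V."""
    t0, t1 = window
    m = (traj.t >= t0) & (traj.t <= t1)
    tt = traj.t[m]
    out = {}
    for cid in ids:
        c = np.maximum(traj.series(cid)[m], 1e-12)
        out[cid] = (math.log(c[-1]) - math.log(c[0])) / (tt[-1] - tt[0]) + dilution
    return out


def bloom_windows(t: np.ndarray, chl: np.ndarray, threshold: float = 3.0,
                  duration: float = 28.0) -> list[tuple[float, float]]:
    """Spring blooms: first exceedance of the chlorophyll threshold each
    year, extended by the fixed duration."""
    t = np.asarray(t, dtype=float)
    chl = np.asarray(chl, dtype=float)
    out = []
    for year in np.unique((t // 365.0).astype(int)):
        m = (t >= year * 365.0) & (t < (year + 1) * 365.0)
        hits = np.nonzero(m & (chl > threshold))[0]
        if hits.size:
            start = t[hits[0]]
            out.append((start, start + duration))
    return out


def dom_origin_fractions(traj: StateTrajectory) -> pd.DataFrame:
    """Origin composition of each OM pool's standing stock over time.

    Each DOM/POM pool carries fractions by origin process (exudation,
    death+inhibition, dissolution resolved through POM, initial stock),
    updated by inflow-proportional mixing: outflows remove all origins in
    proportion to their current share.  Returns a tidy frame
    (time, component, origin, fraction).
    """
    model = traj.model
    spec = model.spec
    compartment = {c.id: c.compartment for c in spec.components.values()}
    pools = [c for c, comp in compartment.items() if comp in ("DOM", "POM")]
    origins = ("exudation", "death", "initial")
    led = traj.ledger
    if led is None:
        raise ValueError("needs a ledger")

    Q = {p: {o: 0.0 for o in origins} for p in pools}
    for p in pools:
        Q[p]["initial"] = float(traj.C[0, traj.ids.index(p)])
    rows = []
    t_edges = np.unique(led.t0)
    by_t = dict(tuple(led.groupby("t0")))
    proc_of = {"exudation": "exudation", "death": "death", "inhibition-kill": "death"}
    for te in t_edges:
        sub = by_t[te]
        dt = float(sub.t1.iloc[0] - te)
        inflow = {p: {o: 0.0 for o in origins} for p in pools}
        outflow = {p: 0.0 for p in pools}
        for r in sub.itertuples():
            if r.sink in Q:
                if r.process == "dissolution" and r.source in Q:
                    srcQ = Q[r.source]
                    tot = sum(srcQ.values())
                    for o in origins:
                        share = srcQ[o] / tot if tot > 0 else (o == "initial")
                        inflow[r.sink][o] += r.rate * share
                else:
                    o = proc_of.get(r.process, "initial")
                    inflow[r.sink][o] += r.rate
            if r.source in Q:
                outflow[r.source] += r.rate
        for p in pools:
            tot = sum(Q[p].values())
            for o in origins:
                loss = outflow[p] * (Q[p][o] / tot if tot > 0 else 0.0)
                Q[p][o] = max(Q[p][o] + (inflow[p][o] - loss) * dt, 0.0)
            tot2 = sum(Q[p].values())
            for o in origins:
                rows.append((float(sub.t1.iloc[0]), p, o,
                             Q[p][o] / tot2 if tot2 > 0 else 0.0))
    return pd.DataFrame(rows, columns=["time", "component", "origin", "fraction"])


def bloom_aggregates(traj: StateTrajectory, windows: list[tuple[float, float]],
                     dilution: float = 0.0, n_foli: int = 5) -> pd.DataFrame:
    """Per-day diet aggregates over bloom windows.

    Columns: time, days_into_bloom, olig_fraction (fOLI-weighted share of
    total DOM uptake), exudate_fraction (exudate share of the DOM standing
    stock), cw_storage_ratio (cell-wall / storage compound consumption).
    """
    if not windows:
        raise ValueError("no bloom windows detected")
    spec = traj.model.spec
    bacteria = spec.ids("bacteria")
    dom_ids = list(spec.ids("DOM"))
    dom_class = {c.id: c.dom_class for c in spec.components.values()
                 if c.compartment == "DOM"}
    led = traj.ledger
    upt = led[(led.process == "heterotrophy")]
    origin = dom_origin_fractions(traj)
    exu = origin[(origin.origin == "exudation")
                 & origin.component.isin(dom_ids)]
    dom_idx = [traj.ids.index(d) for d in dom_ids]

    rows = []
    for (b0, b1) in windows:
        kg = growth_rates(traj, bacteria, (b0, b1), dilution)
        kg_ave = float(np.mean([max(v, 0.0) for v in kg.values()]))
        if kg_ave <= 0:
            kg_ave = 1e-6
        w = {b: oligotroph_weight(kg[b], kg_ave, n_foli) for b in bacteria}
        sub = upt[(upt.t0 >= b0) & (upt.t1 <= b1 + 1e-9)]
        for te, day in sub.groupby("t0"):
            tot = day.rate.sum()
            olig = sum(w[r.sink] * r.rate for r in day.itertuples()) / tot if tot > 0 else np.nan
            cw = day[day.source.map(dom_class).eq("cell_wall")].rate.sum()
            st = day[day.source.map(dom_class).eq("storage")].rate.sum()
            ratio = cw / st if st > 0 else np.nan
            em = exu[np.isclose(exu.time, day.t1.iloc[0])]
            if len(em):
                Cd = traj.C[np.searchsorted(traj.t, day.t1.iloc[0])][dom_idx]
                fr = em.set_index("component").fraction
                stock = {c: Cd[k] for k, c in zip(range(len(dom_idx)), dom_ids)}
                tot_stock = sum(stock.values())
                exu_frac = sum(fr.get(c, 0.0) * stock[c] for c in dom_ids) / tot_stock \
                    if tot_stock > 0 else np.nan
            else:
                exu_frac = np.nan
            rows.append((float(te), float(te - b0), olig, exu_frac, ratio))
    return pd.DataFrame(rows, columns=[
        "time", "days_into_bloom", "olig_fraction", "exudate_fraction",
        "cw_storage_ratio"])


def conc_flux_regression(traj: StateTrajectory, windows, groups: dict[str, str] | None = None,
                         dilution: float = 0.0):
    """log10 flux vs log10 concentration OLS for bacteria over bloom days.

    Pools (concentration, total uptake) pairs per bacterium per ledger
    interval inside the windows; fits ordinary least squares per group
    ("all" plus any labels in ``groups``: e.g. "olig"/"copi").  Returns
    {group: (slope, intercept, r2, n)}.
    """
    spec = traj.model.spec
    bacteria = spec.ids("bacteria")
    led = traj.ledger
    upt = led[led.process == "heterotrophy"]
    xs: dict[str, list] = {"all": []}
    ys: dict[str, list] = {"all": []}
    for (b0, b1) in windows:
        sub = upt[(upt.t0 >= b0) & (upt.t1 <= b1 + 1e-9)]
        per_b = sub.groupby(["t0", "sink"]).rate.sum()
        for (te, b), flux in per_b.items():
            conc = float(traj.series(b)[np.searchsorted(traj.t, te)])
            if flux <= 0 or conc <= 0:
                continue
            for g in ("all", groups.get(b) if groups else None):
                if g is None:
                    continue
                xs.setdefault(g, []).append(math.log10(conc))
                ys.setdefault(g, []).append(math.log10(flux))
    out = {}
    for g in xs:
        x, y = np.asarray(xs[g]), np.asarray(ys[g])
        if len(x) < 3 or np.ptp(x) == 0:
            raise ValueError(f"group {g!r}: too few points or degenerate x")
        res = linregress(x, y)
        out[g] = (float(res.slope), float(res.intercept), float(res.rvalue ** 2), len(x))
    return out


def network_recurrence(snapshots: list[FluxNetworkSnapshot], layer: str):
    """Pairwise Bray-Curtis similarity (1 - dissimilarity) of a network
    layer across snapshots, plus components recurring in the top quartile
    of every snapshot (ordered by average rank).
    """
    if len(snapshots) < 2:
        raise ValueError("need at least 2 snapshots")
    vecs = [s.layer_vector(layer) for s in snapshots]
    universe = sorted(set().union(*[v.index for v in vecs]))
    M = np.array([[float(v.get(c, 0.0)) for c in universe] for v in vecs])
    n = len(snapshots)
    S = np.ones((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            if M[i].sum() == 0 or M[j].sum() == 0:
                raise ValueError("all-zero layer vector")
            S[i, j] = S[j, i] = 1.0 - float(braycurtis(M[i], M[j]))
    ranks = np.argsort(np.argsort(-M, axis=1), axis=1)  # 0 = largest
    q = max(1, int(math.ceil(len(universe) / 4)))
    in_top = (ranks < q).all(axis=0)
    rec = [(universe[k], ranks[:, k].mean()) for k in range(len(universe)) if in_top[k]]
    rec.sort(key=lambda x: x[1])
    return S, [c for c, _ in rec]
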