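"""Time integration, trajectory containers and observation mapping.

The integrator is adaptive and stiff-capable (LSODA).  When a flux ledger
is requested the state is augmented with the cumulative integral of every
flux channel; because each concentration derivative is an exact linear
combination of channel rates (see :mod:`fluxnet.dynamics`), the integrated
concentration increments and the integrated ledger fluxes agree to
round-off at every output step — the ledger closes by construction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.integrate import odeint, solve_ivp

from .config import ModelSpec
from .dynamics import CompiledModel, Forcing

__all__ = ["StateTrajectory", "IntegrationError", "integrate", "observe"]


class IntegrationError(RuntimeError):
    pass


@dataclass
class StateTrajectory:
    """Concentrations on a uniform output grid plus the interval flux ledger."""

    ids: list[str]
    t: np.ndarray                      # output grid (d), strictly increasing
    C: np.ndarray                      # (n_t, n_comp)
    ledger: pd.DataFrame | None        # t0, t1, source, sink, process, rate
    model: CompiledModel

    def series(self, cid: str) -> np.ndarray:
        return self.C[:, self.ids.index(cid)]

    def frame(self) -> pd.DataFrame:
        """Tidy (time, component, value) frame."""
        n_t, n_c = self.C.shape
        return pd.DataFrame({
            "time": np.repeat(self.t, n_c),
            "component": np.tile(self.ids, n_t),
            "value": self.C.ravel(),
        })


def integrate(
    spec_or_model: ModelSpec | CompiledModel,
    forcing: Forcing,
    window: tuple[float, float],
    output_dt: float = 1.0,
    with_ledger: bool = True,
    rtol: float = 1e-8,
    atol: float = 1e-10,
    c0: np.ndarray | None = None,
    max_step: float = np.inf,
) -> StateTrajectory:
    """Integrate the ecosystem over ``window`` and sample on a uniform grid.

    Deterministic given identical inputs.  Raises :class:`IntegrationError`
    on solver failure or a non-finite state (reporting time and component).
    """
    model = spec_or_model if isinstance(spec_or_model, CompiledModel) else CompiledModel(spec_or_model)
    t0, t1 = float(window[0]), float(window[1])
    if not forcing.covers(t0, t1):
        raise IntegrationError(f"forcing does not cover window [{t0}, {t1}]")
    grid = np.arange(t0, t1 + 0.5 * output_dt, output_dt)
    grid[-1] = min(grid[-1], t1)
    y0 = model.c0_vector() if c0 is None else np.asarray(c0, dtype=float)
    n = model.n

    if with_ledger:
        def fun(t, y):
            R, dC = model.rates_and_rhs(t, y[:n], forcing)
            return np.concatenate([dC, R])
        y0 = np.concatenate([y0, np.zeros(model.n_ch)])
        sol = solve_ivp(fun, (t0, t1), y0, method="LSODA", t_eval=grid,
                        rtol=rtol, atol=atol, max_step=max_step)
        if not sol.success:
            raise IntegrationError(f"integration failed: {sol.message}")
        Y = sol.y.T
    else:
        # same LSODA core through the lower-overhead odeint driver
        def fun(t, y):
            return model.rhs(t, y, forcing)
        with np.errstate(all="ignore"):
            Y, info = odeint(fun, y0, grid, tfirst=True, rtol=rtol, atol=atol,
                             hmax=max_step if np.isfinite(max_step) else 0.0,
                             full_output=True, mxstep=100_000)
        if info["message"] != "Integration successful.":
            raise IntegrationError(f"integration failed: {info['message']}")
    C = Y[:, :n]
    bad = np.argwhere(~np.isfinite(C))
    if bad.size:
        it, ic = bad[0]
        raise IntegrationError(
            f"non-finite state for component {model.ids[ic]!r} at t={grid[it]}")

    ledger = None
    if with_ledger:
        F = Y[:, n:]
        dF = np.diff(F, axis=0)                  # µmolC/L per interval
        dt = np.diff(grid)
        n_int = dF.shape[0]
        ledger = pd.DataFrame({
            "t0": np.repeat(grid[:-1], model.n_ch),
            "t1": np.repeat(grid[1:], model.n_ch),
            "source": np.tile(model.ch_src_name, n_int),
            "sink": np.tile(model.ch_dst_name, n_int),
            "process": np.tile(model.ch_proc, n_int),
            "rate": (dF / dt[:, None]).ravel(),  # interval-mean rate, /d
        })
    return StateTrajectory(ids=list(model.ids), t=grid, C=C, ledger=ledger, model=model)


def _resolve_targets(spec: ModelSpec, targets: list[tuple[str, float]]) -> list[tuple[str, float]]:
    """Expand compartment wildcards and map ids through the de-lump lineage.

    A target id is resolved first downward (to its current descendants,
    whose sum equals the split pool) and otherwise upward to the nearest
    existing ancestor (the lumped pool currently representing it).
    """
    out: list[tuple[str, float]] = []
    for tid, coef in targets:
        if tid.startswith("@"):
            for cid in spec.ids(tid[1:]):
                out.append((cid, coef))
            continue
        down = spec.leaves_under(tid)
        if down:
            for cid in down:
                out.append((cid, coef))
            continue
        cur = spec.resolve_id(tid)
        if cur is None:
            raise KeyError(f"observation target {tid!r} does not resolve")
        out.append((cur, coef))
    return out


def observe(traj: StateTrajectory, mappings=None) -> dict[str, np.ndarray]:
    """Modeled observation series: value(series, t) = sum(coef * C_i).

    Coefficients are in observation units per µmolC/L (the registry's
    carbon_per_unit conversions are baked into them when configs are
    generated).  Returns {series_id: values on traj.t}.
    """
    spec = traj.model.spec
    if mappings is None:
        mappings = spec.mappings
    out: dict[str, np.ndarray] = {}
    for m in mappings:
        v = np.zeros(len(traj.t))
        for cid, coef in _resolve_targets(spec, m.targets):
            v += coef * traj.series(cid)
        out[m.series_id] = v
    return out
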