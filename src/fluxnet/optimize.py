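"""De-lumping calibration engine.

The calibration loop mimics speciation: the fully lumped model (one
component per ecological compartment) is optimized until a convergence
threshold, then every splittable component is de-lumped into two daughters
that inherit the parent's parameters, and optimization continues on the
larger model.  Within a level each iteration runs

    single-parameter sweeps  ->  sweeps on the most sensitive subset
    ->  Nelder-Mead on dependent-parameter subsets  ->  Latin-hypercube scans

accepting a candidate only if the total error strictly decreases, so the
best-so-far error is non-increasing within a level.  Several replicate
runs with independent seeds are managed together; the elite fraction (by
final total error) provides flux/parameter uncertainty estimates.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.stats import qmc

from .config import ConstraintSet, ModelSpec, delump
from .dynamics import CompiledModel, Forcing
from .objective import ObservationSeries, total_error
from .simulate import IntegrationError, integrate, observe

__all__ = [
    "ParamRef",
    "LevelPlan",
    "OptimizationSchedule",
    "RunTrace",
    "CalibrationProblem",
    "single_param_sweep",
    "refine_sensitive",
    "nelder_mead_subset",
    "lhs_scan",
    "run_delump_schedule",
    "run_flat",
    "replicate_manager",
]


# --------------------------------------------------------------------------
# parameter handles
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class ParamRef:
    """Address of one scalar parameter inside a ModelSpec."""

    comp: str               # component id or "@env"
    name: str               # parameter or table name ("kp", "Ksh", ...)
    key: str | None = None  # table key (target component id) or None

    def get(self, spec: ModelSpec):
        if self.comp == "@env":
            return spec.environment[self.name]
        c = spec.components[self.comp]
        if self.key is None:
            return c.c0 if self.name == "c0" else c.params[self.name]
        return c.tables[self.name][self.key]

    def value(self, spec: ModelSpec) -> float:
        return self.get(spec).value

    def set(self, spec: ModelSpec, value: float) -> None:
        prm = self.get(spec)
        prm.value = float(min(max(value, prm.lo), prm.hi))

    def bounds(self, spec: ModelSpec) -> tuple[float, float]:
        prm = self.get(spec)
        return prm.lo, prm.hi

    def __str__(self):
        return f"{self.comp}.{self.name}" + (f"[{self.key}]" if self.key else "")


def collect_optimizable(spec: ModelSpec) -> list[ParamRef]:
    refs: list[ParamRef] = []
    for name, prm in spec.environment.items():
        if prm.optimize:
            refs.append(ParamRef("@env", name))
    for c in spec.components.values():
        if c.c0.optimize:
            refs.append(ParamRef(c.id, "c0"))
        for name, prm in c.params.items():
            if prm.optimize:
                refs.append(ParamRef(c.id, name))
        for tname, table in c.tables.items():
            for key, prm in table.items():
                if prm.optimize:
                    refs.append(ParamRef(c.id, tname, key))
    return refs


def auto_subsets(spec: ModelSpec, refs: list[ParamRef]) -> dict[str, list[ParamRef]]:
    """Dependent-parameter groups: per-component bundles of its own knobs.

    A bacterium's max heterotrophy rate and its substrate half-saturations
    are jointly identifiable only as an affinity, so they form one subset;
    a phytoplankton's growth/exudation parameters likewise.
    """
    groups: dict[str, list[ParamRef]] = {}
    for r in refs:
        groups.setdefault(r.comp, []).append(r)
    return {f"subset:{k}": v for k, v in groups.items() if len(v) >= 2}


# --------------------------------------------------------------------------
# schedule and trace
# --------------------------------------------------------------------------

@dataclass
class LevelPlan:
    """One de-lump level: which components split *into* this level, plus
    the optimization effort spent at it."""

    split: list[str] | None = None        # None = all splittable compartments
    overrides: ConstraintSet | None = None
    threshold: float = 0.01               # relative improvement per iteration
    max_iters: int = 3
    sweep_points: int = 5
    refine_iters: int = 8                 # golden-section depth inside sweeps
    nm_maxiter: int = 40
    lhs_n: int = 0
    max_evals: int = 10_000


@dataclass
class OptimizationSchedule:
    levels: list[LevelPlan] = field(default_factory=list)  # levels[0] = lumped stage
    seed: int = 0
    replicates: int = 128
    elite_frac: float = 0.05
    jitter: float = 0.0                   # post-split symmetry-breaking, off by default
    top_fraction: float = 0.3             # sensitive-subset refinement share
    randomize_start: bool = True          # LHS draw of the starting vector per replicate
    init_c0_from_obs: bool = True
    rtol: float = 1e-5
    atol: float = 1e-3          # dormancy floors are ~1e-2 µmolC/L and carry
                                # negligible NRMSE weight; no need to resolve finer
    output_dt: float = 2.0
    k_ch: float = 0.1
    search_window: float | None = 60.0    # ES speed path (None = exact global min)
    total_budget: int | None = None       # overall evaluation cap (all levels)


@dataclass
class RunTrace:
    rows: list[dict] = field(default_factory=list)
    converged: bool = True

    def log(self, **kw):
        self.rows.append(kw)

    def frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.rows)

    def best_by_level(self) -> pd.DataFrame:
        df = self.frame()
        return df.groupby("level")["best_error"].min()


# --------------------------------------------------------------------------
# objective wrapper
# --------------------------------------------------------------------------

class CalibrationProblem:
    """Couples a spec structure to data: evaluate(spec) -> total error."""

    def __init__(self, observations: list[ObservationSeries], forcing: Forcing,
                 window: tuple[float, float], schedule: OptimizationSchedule,
                 budget: int | None = None):
        self.observations = observations
        self.forcing = forcing
        self.window = window
        self.s = schedule
        self.budget = budget
        self.n_evals = 0
        self._agg_key = None
        self._agg: list[tuple[ObservationSeries, str]] = []

    @property
    def exhausted(self) -> bool:
        return self.budget is not None and self.n_evals >= self.budget

    def _aggregated(self, spec: ModelSpec) -> list[tuple[ObservationSeries, str]]:
        """Observation set for the current de-lump level.

        Species-level series whose targets are currently represented by
        the same lumped ancestor are summed into one aggregate series
        (union of time points, linear interpolation), so coarse levels
        fit aggregates instead of charging each species against the whole
        pool.  Returns (series, key-of-the-modeled-series) pairs.
        """
        key = tuple(spec.components)
        if self._agg_key == key:
            return self._agg
        by_id = {m.series_id: m for m in spec.mappings}
        groups: dict[tuple[str, float], list[ObservationSeries]] = {}
        order: list[tuple[str, float] | None] = []
        singles: list[ObservationSeries] = []
        for o in self.observations:
            m = by_id.get(o.series_id)
            anc = None
            if m and len(m.targets) == 1 and not m.targets[0][0].startswith("@"):
                tid, coef = m.targets[0]
                if not spec.leaves_under(tid):
                    up = spec.resolve_id(tid)
                    if up is not None:
                        anc = (up, coef)
            if anc is None:
                singles.append(o)
            else:
                groups.setdefault(anc, []).append(o)
        out: list[tuple[ObservationSeries, str]] = [(o, o.series_id) for o in singles]
        for (up, coef), members in groups.items():
            if len(members) == 1:
                out.append((members[0], members[0].series_id))
                continue
            tt = np.unique(np.concatenate([m.t for m in members]))
            vv = np.zeros_like(tt)
            for m2 in members:
                vv += np.interp(tt, m2.t, m2.v)
            agg = ObservationSeries(f"agg:{up}", tt, vv,
                                    weight=sum(m2.weight for m2 in members),
                                    k_ch=members[0].k_ch)
            out.append((agg, members[0].series_id))
        self._agg_key, self._agg = key, out
        return out

    def evaluate(self, spec: ModelSpec) -> float:
        if self.exhausted:
            # budget spent: report "no improvement" so moves unwind cheaply
            return math.inf
        self.n_evals += 1
        try:
            traj = integrate(spec, self.forcing, self.window,
                             output_dt=self.s.output_dt, with_ledger=False,
                             rtol=self.s.rtol, atol=self.s.atol)
        except (IntegrationError, FloatingPointError):
            return math.inf
        modeled = observe(traj)
        pairs = self._aggregated(spec)
        obs_list = [o for o, _ in pairs]
        mod = {o.series_id: (traj.t, modeled[mkey]) for o, mkey in pairs}
        try:
            rep = total_error(obs_list, mod, search_window=self.s.search_window)
        except (KeyError, ValueError):
            return math.inf
        return rep.total if math.isfinite(rep.total) else math.inf

    def init_c0(self, spec: ModelSpec) -> None:
        """Set component initial concentrations from t0 observations.

        A species-level series whose mapping is a single resolvable target
        pins that component's (or, lumped, its ancestor's pooled) C0.
        """
        t0 = self.window[0]
        obs_by_id = {o.series_id: o for o in self.observations}
        pools: dict[str, float] = {}
        for m in spec.mappings:
            o = obs_by_id.get(m.series_id)
            if o is None or o.t.size == 0 or abs(o.t[0] - t0) > 3.0:
                continue
            ids = {tid for tid, _ in m.targets if not tid.startswith("@")}
            res = {spec.resolve_id(t) for t in ids}
            res.discard(None)
            if len(res) != 1 or len({c for _, c in m.targets}) != 1:
                continue
            cid = res.pop()
            coef = m.targets[0][1]
            # several species-level series may resolve to one lumped pool
            pools[cid] = pools.get(cid, 0.0) + o.v[0] / coef
        for cid, val in pools.items():
            leaves = spec.leaves_under(cid)
            for leaf in leaves:
                c0 = spec.components[leaf].c0
                c0.value = max(val, 0.0) / len(leaves)
                c0.lo = min(c0.lo, c0.value)    # data-initialized ICs may sit
                c0.hi = max(c0.hi, c0.value)    # outside the configured bounds


# --------------------------------------------------------------------------
# optimization moves (each returns the new best error; specs edited in place)
# --------------------------------------------------------------------------

def _golden_refine(f, lo, hi, x0, f0, tol, max_iter=24):
    """Golden-section descent on [lo, hi] seeded at x0 (best grid cell)."""
    gr = (math.sqrt(5.0) - 1.0) / 2.0
    a, b = lo, hi
    best_x, best_f = x0, f0
    c = b - gr * (b - a)
    d = a + gr * (b - a)
    fc, fd = f(c), f(d)
    for _ in range(max_iter):
        if fc < fd:
            b, d, fd = d, c, fc
            c = b - gr * (b - a)
            fc = f(c)
            if fc < best_f:
                best_x, best_f = c, fc
        else:
            a, c, fc = c, d, fd
            d = a + gr * (b - a)
            fd = f(d)
            if fd < best_f:
                best_x, best_f = d, fd
        if abs(b - a) < tol * max(1.0, abs(b) + abs(a)):
            break
    return best_x, best_f


def single_param_sweep(spec: ModelSpec, problem: CalibrationProblem,
                       refs: list[ParamRef], best: float,
                       sweep_points: int = 5, refine: bool = True,
                       refine_iters: int = 24,
                       trace: RunTrace | None = None, level: int = 0,
                       ) -> tuple[float, dict[ParamRef, float]]:
    """Scan each parameter on its bounded grid; accept strict improvements.

    Returns (best error, per-parameter sensitivity = error reduction achieved).
    """
    sens: dict[ParamRef, float] = {}
    for ref in refs:
        lo, hi = ref.bounds(spec)
        if not (math.isfinite(lo) and math.isfinite(hi)):
            raise ValueError(f"{ref}: sweep requires finite bounds")
        x_cur = ref.value(spec)
        before = best

        def f(x, _ref=ref):
            _ref.set(spec, x)
            e = problem.evaluate(spec)
            return e

        if lo > 0 and hi / lo >= 20.0:
            grid = np.geomspace(lo, hi, sweep_points)   # wide positive range
        else:
            grid = np.linspace(lo, hi, sweep_points)
        vals = [f(x) for x in grid]
        k = int(np.argmin(vals))
        best_x, best_f = grid[k], vals[k]
        # refine on strict improvement, or on a tie when the grid shows
        # curvature (the interior optimum may sit between grid points)
        worth = best_f < best or (best_f == best and min(vals) < max(vals))
        if refine and worth:
            a = grid[max(k - 1, 0)]
            b = grid[min(k + 1, len(grid) - 1)]
            best_x, best_f = _golden_refine(f, a, b, best_x, best_f, 1e-4,
                                            max_iter=refine_iters)
        if best_f < best:
            ref.set(spec, best_x)
            sens[ref] = before - best_f
            best = best_f
        else:
            ref.set(spec, x_cur)
            sens[ref] = 0.0
        if trace is not None:
            trace.log(level=level, evals=problem.n_evals, move="sweep",
                      param=str(ref), best_error=best)
    return best, sens


def refine_sensitive(spec: ModelSpec, problem: CalibrationProblem,
                     sens: dict[ParamRef, float], best: float,
                     top_fraction: float, sweep_points: int = 5,
                     refine_iters: int = 24,
                     trace: RunTrace | None = None, level: int = 0) -> float:
    """Repeat sweeps on the most sensitive fraction of parameters."""
    if top_fraction <= 0 or not sens:
        return best
    n = max(1, int(math.ceil(top_fraction * len(sens)))) if top_fraction < 1 else len(sens)
    top = sorted(sens, key=lambda r: -sens[r])[:n]
    top = [r for r in top if sens[r] > 0] or top[:1]
    best, _ = single_param_sweep(spec, problem, top, best, sweep_points,
                                 refine_iters=refine_iters, trace=trace, level=level)
    return best


def _log_scaled(lo, hi):
    """Wide positive ranges are searched geometrically."""
    return (lo > 0) & (hi / np.where(lo > 0, lo, 1.0) >= 20.0)


def _from_unit(u, lo, hi):
    """Logit box transform; log-scaled interior for wide positive ranges."""
    p = 1.0 / (1.0 + np.exp(-np.asarray(u)))
    logm = _log_scaled(lo, hi)
    lin = lo + (hi - lo) * p
    with np.errstate(invalid="ignore"):
        geo = np.where(logm, lo * (hi / np.where(lo > 0, lo, 1.0)) ** p, lin)
    return np.where(logm, geo, lin)


def _to_logit(x, lo, hi):
    logm = _log_scaled(lo, hi)
    x = np.asarray(x, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        p_geo = np.log(np.maximum(x, 1e-300) / np.where(lo > 0, lo, 1.0)) \
            / np.log(np.where(logm, hi / np.where(lo > 0, lo, 1.0), 2.0))
    p = np.where(logm, p_geo, (x - lo) / (hi - lo))
    p = np.clip(p, 1e-9, 1 - 1e-9)
    return np.log(p / (1 - p))


def nelder_mead_subset(spec: ModelSpec, problem: CalibrationProblem,
                       refs: list[ParamRef], best: float, maxiter: int = 40,
                       rng: np.random.Generator | None = None,
                       trace: RunTrace | None = None, level: int = 0) -> float:
    """Bounded Nelder-Mead on one dependent-parameter subset.

    Works in a logit-transformed box so all proposals respect bounds;
    accepted only if the total error strictly decreases.  A degenerate
    simplex triggers one restart from a Latin-hypercube point.
    """
    if len(refs) < 2:
        raise ValueError("subset Nelder-Mead needs at least 2 parameters")
    for r in refs:
        if not r.get(spec).optimize:
            raise ValueError(f"{r}: not an optimizable parameter")
    lo = np.array([r.bounds(spec)[0] for r in refs])
    hi = np.array([r.bounds(spec)[1] for r in refs])
    x0 = np.array([r.value(spec) for r in refs])

    def f(u):
        x = _from_unit(u, lo, hi)
        for r, v in zip(refs, x):
            r.set(spec, v)
        return problem.evaluate(spec)

    u0 = _to_logit(x0, lo, hi)
    with np.errstate(invalid="ignore"):   # inf objective values are routine
        res = minimize(f, u0, method="Nelder-Mead",
                       options={"maxiter": maxiter, "xatol": 1e-3, "fatol": 1e-10})
        if not np.all(np.isfinite(res.x)) and rng is not None:
            u0 = _to_logit(lo + qmc.LatinHypercube(len(refs), seed=rng).random(1)[0] * (hi - lo), lo, hi)
            res = minimize(f, u0, method="Nelder-Mead", options={"maxiter": maxiter})
    if res.fun < best:
        best = res.fun
        xb = _from_unit(res.x, lo, hi)
    else:
        xb = x0
    for r, v in zip(refs, xb):
        r.set(spec, v)
    if trace is not None:
        trace.log(level=level, evals=problem.n_evals, move="nelder-mead",
                  param=";".join(str(r) for r in refs[:3]), best_error=best)
    return best


def lhs_scan(spec: ModelSpec, problem: CalibrationProblem,
             refs: list[ParamRef], best: float, n: int,
             rng: np.random.Generator,
             trace: RunTrace | None = None, level: int = 0) -> float:
    """Latin-hypercube scan over the subset's box; keeps the best strict improvement."""
    if n < 1 or not refs:
        return best
    lo = np.array([r.bounds(spec)[0] for r in refs])
    hi = np.array([r.bounds(spec)[1] for r in refs])
    x_cur = np.array([r.value(spec) for r in refs])
    sampler = qmc.LatinHypercube(d=len(refs), seed=rng)
    U = sampler.random(n)
    logm = _log_scaled(lo, hi)
    with np.errstate(invalid="ignore"):
        X = np.where(logm[None, :],
                     lo * (hi / np.where(lo > 0, lo, 1.0)) ** U,
                     lo + U * (hi - lo))
    best_x = x_cur
    for x in X:
        for r, v in zip(refs, x):
            r.set(spec, v)
        e = problem.evaluate(spec)
        if e < best:
            best, best_x = e, x
    for r, v in zip(refs, best_x):
        r.set(spec, v)
    if trace is not None:
        trace.log(level=level, evals=problem.n_evals, move="lhs", param="", best_error=best)
    return best


# --------------------------------------------------------------------------
# level loop and schedules
# --------------------------------------------------------------------------

def _optimize_level(spec, problem, plan: LevelPlan, sched: OptimizationSchedule,
                    rng, trace, level) -> float:
    refs = collect_optimizable(spec)
    best = problem.evaluate(spec)
    trace.log(level=level, evals=problem.n_evals, move="start",
              param=f"n_comp={len(spec.components)};n_par={len(refs)}", best_error=best)
    if not refs:
        return best
    start_evals = problem.n_evals
    subsets = auto_subsets(spec, refs)
    for it in range(plan.max_iters):
        e0 = best
        best, sens = single_param_sweep(spec, problem, refs, best,
                                        plan.sweep_points, refine_iters=plan.refine_iters,
                                        trace=trace, level=level)
        best = refine_sensitive(spec, problem, sens, best, sched.top_fraction,
                                plan.sweep_points, refine_iters=plan.refine_iters,
                                trace=trace, level=level)
        for name, subset in subsets.items():
            if plan.lhs_n:
                best = lhs_scan(spec, problem, subset, best, plan.lhs_n, rng,
                                trace=trace, level=level)
            best = nelder_mead_subset(spec, problem, subset, best,
                                      plan.nm_maxiter, rng, trace=trace, level=level)
            if problem.exhausted:
                break
        if problem.exhausted or problem.n_evals - start_evals > plan.max_evals:
            trace.converged = problem.n_evals - start_evals <= plan.max_evals
            break
        if e0 > 0 and math.isfinite(e0) and (e0 - best) / e0 < plan.threshold:
            break
    return best


def run_delump_schedule(
    initial_spec: ModelSpec,
    schedule: OptimizationSchedule,
    observations: list[ObservationSeries],
    forcing: Forcing,
    window: tuple[float, float],
    seed: int | None = None,
) -> tuple[ModelSpec, RunTrace]:
    """Full de-lumping calibration: optimize, split, repeat.

    levels[0] is the lumped stage (no split applied before it); each later
    level first applies its split + overrides, then optimizes.  Returns the
    calibrated spec and the evaluation trace.
    """
    rng = np.random.default_rng(schedule.seed if seed is None else seed)
    for o in observations:
        o.k_ch = schedule.k_ch
    problem = CalibrationProblem(observations, forcing, window, schedule,
                                 budget=schedule.total_budget)
    trace = RunTrace()
    spec = initial_spec.copy()

    if schedule.randomize_start:
        for r in collect_optimizable(spec):
            lo, hi = r.bounds(spec)
            if math.isfinite(lo) and math.isfinite(hi):
                r.set(spec, lo + rng.random() * (hi - lo))

    for level, plan in enumerate(schedule.levels):
        if level > 0:
            spec = delump(spec, overrides=plan.overrides, split=plan.split,
                          jitter=schedule.jitter, rng=rng)
        if schedule.init_c0_from_obs:
            problem.init_c0(spec)
        _optimize_level(spec, problem, plan, schedule, rng, trace, level)
        if problem.exhausted:
            trace.converged = False
            break
    return spec, trace


def run_flat(
    final_structure: ModelSpec,
    schedule: OptimizationSchedule,
    observations: list[ObservationSeries],
    forcing: Forcing,
    window: tuple[float, float],
    seed: int | None = None,
) -> tuple[ModelSpec, RunTrace]:
    """No-delump control: calibrate the full-structure model directly.

    The structure is expanded up front (all splits applied, no optimization
    in between), then the whole parameter set is optimized with the same
    moves and evaluation budget semantics as the de-lumping run.
    """
    flat_sched = OptimizationSchedule(
        levels=[LevelPlan(threshold=0.0,
                          max_iters=10**6,
                          sweep_points=schedule.levels[-1].sweep_points,
                          nm_maxiter=schedule.levels[-1].nm_maxiter,
                          lhs_n=schedule.levels[-1].lhs_n,
                          max_evals=schedule.total_budget or 10**9)],
        seed=schedule.seed, jitter=0.0, top_fraction=schedule.top_fraction,
        randomize_start=schedule.randomize_start,
        init_c0_from_obs=schedule.init_c0_from_obs,
        rtol=schedule.rtol, atol=schedule.atol, output_dt=schedule.output_dt,
        k_ch=schedule.k_ch, total_budget=schedule.total_budget)
    return run_delump_schedule(final_structure, flat_sched, observations,
                               forcing, window, seed=seed)


def expand_structure(spec: ModelSpec, schedule: OptimizationSchedule) -> ModelSpec:
    """Apply every level's split + overrides without optimizing (for run_flat)."""
    out = spec.copy()
    for plan in schedule.levels[1:]:
        out = delump(out, overrides=plan.overrides, split=plan.split)
    return out


# --------------------------------------------------------------------------
# replicates
# --------------------------------------------------------------------------

@dataclass
class ReplicateResult:
    seed: int
    error: float
    spec: ModelSpec
    trace: RunTrace


def replicate_manager(run_one, seeds: list[int], elite_frac: float = 0.05):
    """Run independent replicates and select the elite set by total error.

    ``run_one(seed) -> (spec, trace, error)``; replicates share nothing but
    inputs.  Returns (elite list, all results).  Elite statistics
    (mean ± sd of any flux or parameter) are computed by the caller from
    the elite specs; with a single replicate the sd is undefined (NaN).
    """
    results: list[ReplicateResult] = []
    for s in seeds:
        spec, trace, err = run_one(s)
        results.append(ReplicateResult(s, err, spec, trace))
    ok = [r for r in results if math.isfinite(r.error)]
    if not ok:
        raise RuntimeError("all replicates failed")
    ok.sort(key=lambda r: r.error)
    n_elite = max(1, int(math.ceil(elite_frac * len(ok))))
    return ok[:n_elite], results


def elite_stats(values: list[float]) -> tuple[float, float]:
    """Mean and sd across the elite set (sd NaN for a single member)."""
    v = np.asarray(values, dtype=float)
    return float(v.mean()), float(v.std(ddof=1)) if v.size > 1 else math.nan
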