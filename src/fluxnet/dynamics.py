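"""ODE right-hand side with a complete carbon-flux ledger.

Every process rate — photosynthesis, respiration, exudation, death,
inhibition kill, POM dissolution, multi-substrate heterotrophy, settling,
outflow, plus the non-carbon nutrient/micronutrient/inhibitor bookkeeping —
is computed into a fixed vector of *flux channels* (source, sink, process).
The state derivative is then assembled as gains-minus-losses over exactly
those channel rates, so for every component and instant

    dC/dt == sum(in-channels) - sum(out-channels)

holds bit-exactly: the ledger *is* the model.

Process model (per compartment; L* are limitation factors):

* phytoplankton i:  +kp·Lp·C  −kr·Lr·C  −(ke+ef·kp·Lp)·C  −ku·Lu·C
                    −inhibition  −(vs/H)·C  −(Q/V)·C
* DOM j:            +Σ_i Fe_ij·E_i  +Σ_m Fx_mj·D_m  +kf·Lf·C_pom
                    −Σ_b uptake(b,j)  −(Q/V)·C
* POM p:            +death/exudation remainders  −kf·Lf·C  −(vs/H)·C  −(Q/V)·C
* bacteria b:       +Yh·Σ_j uptake(b,j)  −ku·Lu·C  −inhibition  −(Q/V)·C

Heterotrophic uptake uses shared-denominator multi-substrate Monod
kinetics:  uptake(b,j) = kh·(C_j/Ksh_bj)/(1+Σ_j' C_j'/Ksh_bj')·Lh·C_b.
A bacterium-substrate pair absent from the Ksh table cannot take up that
substrate (the pair is excluded from numerator and denominator).

Dormancy: any microbe with concentration at or below its floor Cflr has all
its loss channels scaled by a common factor so the net derivative is >= 0
at the floor; the scaling ramps smoothly over [Cflr, 1.05·Cflr] to keep the
right-hand side continuous for the integrator.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .config import ModelSpec

__all__ = [
    "Forcing",
    "LimitationFactors",
    "CompiledModel",
    "EXT",
    "SINKS",
]

EXT = "external"
SINK_RESP = "sink:respiration"
SINK_SED = "sink:sediment"
SINK_OUT = "sink:outflow"
SINK_ASSIM = "sink:assimilation"
SINK_CONS = "sink:consumption"
SINK_DECAY = "sink:decay"
SINKS = (SINK_RESP, SINK_SED, SINK_OUT, SINK_ASSIM, SINK_CONS, SINK_DECAY)

_DAYS_PER_YEAR = 365.0


@dataclass
class Forcing:
    """Piecewise-linear environmental forcing (time in days).

    Variables: temperature (degC), light (surface irradiance, arbitrary
    units relative to I_opt), salinity, dilution (Q/V, 1/d), load_N and
    load_P (µmol/L/d), iss (inorganic suspended solids, shading units).
    Missing variables fall back to constants in ``defaults``.
    """

    t: np.ndarray
    series: dict[str, np.ndarray] = field(default_factory=dict)
    defaults: dict[str, float] = field(default_factory=lambda: {
        "temperature": 15.0, "light": 1.0, "salinity": 32.0,
        "dilution": 0.0, "load_N": 0.0, "load_P": 0.0, "iss": 0.0,
    })

    VARS = ("temperature", "light", "salinity", "dilution", "load_N", "load_P", "iss")

    def __post_init__(self):
        self.t = np.asarray(self.t, dtype=float)
        self.series = {k: np.asarray(v, dtype=float) for k, v in self.series.items()}
        self._mat = None

    def at(self, name: str, t: float) -> float:
        v = self.series.get(name)
        if v is None:
            return self.defaults.get(name, 0.0)
        return float(np.interp(t, self.t, v))

    def _packed(self) -> np.ndarray:
        if self._mat is None:
            rows = []
            for name in self.VARS:
                v = self.series.get(name)
                if v is None:
                    rows.append(np.full(self.t.size, self.defaults.get(name, 0.0)))
                else:
                    rows.append(v)
            self._mat = np.array(rows)
        return self._mat

    def sample(self, t: float) -> np.ndarray:
        """All VARS linearly interpolated at t, as one vector (hot path)."""
        mat = self._packed()
        tt = self.t
        i = int(np.searchsorted(tt, t, side="right")) - 1
        if i < 0:
            return mat[:, 0].copy()
        if i >= tt.size - 1:
            return mat[:, -1].copy()
        w = (t - tt[i]) / (tt[i + 1] - tt[i])
        return mat[:, i] * (1.0 - w) + mat[:, i + 1] * w

    def covers(self, t0: float, t1: float) -> bool:
        return self.t.size > 0 and self.t[0] <= t0 and self.t[-1] >= t1

    @staticmethod
    def constant(t0: float, t1: float, **values) -> "Forcing":
        f = Forcing(t=np.array([t0, t1]))
        f.defaults.update(values)
        return f


@dataclass
class LimitationFactors:
    """Dimensionless process modifiers at one instant."""

    Lp: np.ndarray      # photosynthesis, per phytoplankton
    Lr: np.ndarray      # respiration, per phytoplankton
    Lu: np.ndarray      # death, per microbe (phyto then bacteria)
    Lf: np.ndarray      # dissolution, per POM
    Lh: np.ndarray      # heterotrophy, per bacterium
    light: np.ndarray = None
    nutrient: np.ndarray = None
    micronutrient: np.ndarray = None


def _steele_depth_avg(x0: np.ndarray, kH: float) -> np.ndarray:
    """Depth-averaged Steele photoinhibition factor.

    x0 = I0/I_opt at the surface, kH = extinction x depth.  Averages
    (I/I_opt)·exp(1-I/I_opt) over depth with I(z) = I0·exp(-kex·z);
    evaluated in a cancellation-free form so the kH -> 0 limit
    x0·exp(1-x0) is met to machine precision.
    """
    x0 = np.asarray(x0, dtype=float)
    if kH < 1e-9:
        return x0 * np.exp(1.0 - x0)
    q = -math.expm1(-kH)           # 1 - exp(-kH)
    return np.exp(1.0 - x0) * np.expm1(x0 * q) / kH


def _temp_curve(T: float, Topt: np.ndarray, kappa: np.ndarray, sigma: np.ndarray) -> np.ndarray:
    """Exponential rise below the optimum, Gaussian decline above it."""
    below = np.exp(kappa * (T - Topt))
    with np.errstate(divide="ignore", invalid="ignore"):
        above = np.where(sigma > 0, np.exp(-0.5 * ((T - Topt) / np.where(sigma > 0, sigma, 1.0)) ** 2), 1.0)
    return np.where(T <= Topt, below, above)


def _gauss_window(x: float, opt: np.ndarray, sigma: np.ndarray) -> np.ndarray:
    return np.where(sigma > 0, np.exp(-0.5 * ((x - opt) / np.where(sigma > 0, sigma, 1.0)) ** 2), 1.0)


def _season_bell(t: float, peak: np.ndarray, width: np.ndarray, base: np.ndarray) -> np.ndarray:
    """Wrapped Gaussian in day-of-year, lifted by a baseline in (0, 1]."""
    doy = t % _DAYS_PER_YEAR
    d = np.abs(doy - peak)
    d = np.minimum(d, _DAYS_PER_YEAR - d)
    bell = np.where(width > 0, np.exp(-0.5 * (d / np.where(width > 0, width, 1.0)) ** 2), 1.0)
    return base + (1.0 - base) * bell


def _param_array(comps, name, default=0.0):
    return np.array([c.p(name, default) for c in comps], dtype=float)


class CompiledModel:
    """A ModelSpec compiled to flat arrays and a fixed flux-channel list."""

    def __init__(self, spec: ModelSpec):
        self.spec = spec
        self.ids = list(spec.components)
        self.index = {cid: i for i, cid in enumerate(self.ids)}
        self.n = len(self.ids)
        comps = list(spec.components.values())
        self.compartment = np.array([c.compartment for c in comps])

        def idx(comp):
            return np.array([i for i, c in enumerate(comps) if c.compartment == comp], dtype=int)

        self.iP = idx("phytoplankton")
        self.iB = idx("bacteria")
        self.iD = idx("DOM")
        self.iM = idx("POM")
        self.iN = idx("nutrient")
        self.iU = idx("micronutrient")
        self.iZ = idx("inhibitor")
        self.iMic = np.concatenate([self.iP, self.iB])
        P = [comps[i] for i in self.iP]
        B = [comps[i] for i in self.iB]
        D = [comps[i] for i in self.iD]
        POM = [comps[i] for i in self.iM]
        NUT = [comps[i] for i in self.iN]
        MIC = [comps[i] for i in self.iMic]
        nP, nB, nD, nM = len(P), len(B), len(D), len(POM)
        self.nP, self.nB, self.nD, self.nM = nP, nB, nD, nM

        env = spec.environment
        self.H = spec.env("depth", 10.0)
        self.kbg = spec.env("background_extinction", 0.1)
        self.iss_shade = spec.env("iss_shading", 0.0)
        self.kappa_r = spec.env("kappa_r", 0.07)
        self.kappa_f = spec.env("kappa_f", 0.05)
        self.Tref = spec.env("Tref", 20.0)

        # --- per-group parameter arrays ---------------------------------
        self.kp = _param_array(P, "kp")
        self.kr = _param_array(P, "kr")
        self.ke = _param_array(P, "ke")
        self.ef = _param_array(P, "ef")
        self.Iopt = _param_array(P, "I_opt", 1.0)
        self.ToptP = _param_array(P, "Topt", 18.0)
        self.TkapP = _param_array(P, "T_kappa", 0.0)
        self.TsigP = _param_array(P, "T_sigma", 0.0)
        self.SoptP = _param_array(P, "S_opt", 32.0)
        self.SsigP = _param_array(P, "S_sigma", 0.0)

        self.kh = _param_array(B, "kh")
        self.Yh = _param_array(B, "Yh", 1.0)
        self.ToptB = _param_array(B, "Topt", 18.0)
        self.TkapB = _param_array(B, "T_kappa", 0.0)
        self.TsigB = _param_array(B, "T_sigma", 0.0)
        self.SoptB = _param_array(B, "S_opt", 32.0)
        self.SsigB = _param_array(B, "S_sigma", 0.0)

        self.ku = _param_array(MIC, "ku")
        self.Cflr = _param_array(MIC, "Cflr")
        self.dpeak = _param_array(MIC, "death_peak", 150.0)
        self.dwidth = _param_array(MIC, "death_width", 0.0)
        self.dbase = _param_array(MIC, "death_base", 1.0)
        self.SoptM = np.concatenate([self.SoptP, self.SoptB]) if nP + nB else np.zeros(0)
        self.SsigM = np.concatenate([self.SsigP, self.SsigB]) if nP + nB else np.zeros(0)

        self.kf = _param_array(POM, "kf")
        self.pom_partner = np.array(
            [self.index[c.pom_partner] for c in POM], dtype=int) if nM else np.zeros(0, int)
        self.shade = _param_array(comps, "shade")

        vsP = _param_array(P, "vs")
        vsM = _param_array(POM, "vs")
        self.vs_idx = np.concatenate([self.iP, self.iM]).astype(int)
        self.vs_over_H = np.concatenate([vsP, vsM]) / self.H if self.vs_idx.size else np.zeros(0)

        # --- keyed tables to matrices -----------------------------------
        def table_matrix(rows, tname, cols_idx):
            mat = np.zeros((len(rows), len(cols_idx)))
            colmap = {self.ids[j]: k for k, j in enumerate(cols_idx)}
            for r, c in enumerate(rows):
                for key, prm in c.tables.get(tname, {}).items():
                    if key in colmap:
                        mat[r, colmap[key]] = prm.value
            return mat

        self.Fe = table_matrix(P, "Fe", self.iD)                 # nP x nD
        self.Fx = table_matrix(MIC, "Fx", self.iD)               # (nP+nB) x nD
        self.Pom = table_matrix(MIC, "Pom", self.iM)             # (nP+nB) x nM
        # normalize POM composition rows (pro-rata split of the remainder)
        rs = self.Pom.sum(axis=1, keepdims=True)
        self.Pom = np.divide(self.Pom, np.where(rs > 0, rs, 1.0))
        if nM and nP + nB:
            # rows with no POM entry default to the first POM pool
            self.Pom[(rs[:, 0] == 0), 0] = 1.0
        self.KsN = table_matrix(P, "KsN", self.iN)               # 0 = not limiting
        self.KsM = table_matrix(P, "KsM", self.iU)
        self.Mcons = table_matrix(P, "Mcons", self.iU)
        self.Mexu = table_matrix(B, "Mexu", self.iU)
        self.Zexu = table_matrix(MIC, "Zexu", self.iZ)
        self.Zkill = table_matrix(MIC, "Zkill", self.iZ)
        self.ZK = table_matrix(MIC, "ZK", self.iZ)
        Ksh = table_matrix(B, "Ksh", self.iD)
        with np.errstate(divide="ignore"):
            self.invKsh = np.where(Ksh > 0, 1.0 / np.where(Ksh > 0, Ksh, 1.0), 0.0)

        # stoichiometry (mol N or P per mol C) per microbe and group
        def stoich(which):
            out = np.zeros(nP + nB)
            for r, c in enumerate(MIC):
                out[r] = spec.stoichiometry.get(c.compartment, {}).get(which, 0.0)
            return out

        self.NtoC = stoich("n_to_c")
        self.PtoC = stoich("p_to_c")
        self.nut_role = [c.dom_class for c in NUT]
        self.kdec = _param_array([comps[i] for i in self.iZ], "kdec")

        # precomputed guards for the hot path (sigma == 0 means "no effect")
        def safe(a):
            return (a > 0), np.where(a > 0, a, 1.0)

        self._mTsigP, self._sTsigP = safe(self.TsigP)
        self._mTsigB, self._sTsigB = safe(self.TsigB)
        self._mSsigP, self._sSsigP = safe(self.SsigP)
        self._mSsigB, self._sSsigB = safe(self.SsigB)
        self._mSsigM, self._sSsigM = safe(self.SsigM)
        self._mDw, self._sDw = safe(self.dwidth)
        self._mKsN = self.KsN > 0
        self._sKsN = np.where(self._mKsN, self.KsN, 1.0)
        self._mKsM = self.KsM > 0
        self._sKsM = np.where(self._mKsM, self.KsM, 1.0)
        self._mZK = self.ZK > 0
        self._sZK = np.where(self._mZK, self.ZK, 1.0)
        self._flr_pos = self.Cflr > 0
        self._flr_safe = np.where(self._flr_pos, self.Cflr, 1.0)
        self._has_micro_floor = bool(np.any(self._flr_pos))

        self._build_channels()

    # ------------------------------------------------------------------
    def _build_channels(self):
        """Enumerate flux channels; record index arrays for vectorized fill."""
        src: list[int] = []
        dst: list[int] = []
        proc: list[str] = []
        blocks: dict[str, slice] = {}
        gather: dict[str, tuple] = {}

        def open_block(name):
            blocks[name] = len(src)

        def close_block(name):
            blocks[name] = slice(blocks[name], len(src))

        def add(s, d, p):
            src.append(s)
            dst.append(d)
            proc.append(p)

        iP, iB, iD, iM = self.iP, self.iB, self.iD, self.iM
        sink_id = {name: -(k + 2) for k, name in enumerate(SINKS)}  # encode sinks < -1
        self._sink_id = sink_id

        open_block("pho")
        for i in iP:
            add(-1, i, "photosynthesis")
        close_block("pho")

        open_block("res")
        for i in iP:
            add(i, sink_id[SINK_RESP], "respiration")
        close_block("res")

        # exudation to DOM (nonzero Fe entries)
        rows, cols = np.nonzero(self.Fe)
        gather["exu_dom"] = (rows.copy(), self.Fe[rows, cols].copy())
        open_block("exu_dom")
        for r, c in zip(rows, cols):
            add(iP[r], iD[c], "exudation")
        close_block("exu_dom")

        # exudation remainder to POM
        feR = np.clip(1.0 - self.Fe.sum(axis=1), 0.0, None)
        coefE = feR[:, None] * self.Pom[: self.nP] if self.nM else np.zeros((self.nP, 0))
        rows, cols = np.nonzero(coefE)
        gather["exu_pom"] = (rows.copy(), coefE[rows, cols].copy())
        open_block("exu_pom")
        for r, c in zip(rows, cols):
            add(iP[r], iM[c], "exudation")
        close_block("exu_pom")

        # death / inhibition-kill partition over DOM and POM, per microbe
        fxR = np.clip(1.0 - self.Fx.sum(axis=1), 0.0, None)
        coefX = fxR[:, None] * self.Pom if self.nM else np.zeros((self.nP + self.nB, 0))
        for pname, bname in (("death", "dea"), ("inhibition-kill", "kil")):
            rows, cols = np.nonzero(self.Fx)
            gather[bname + "_dom"] = (rows.copy(), self.Fx[rows, cols].copy())
            open_block(bname + "_dom")
            for r, c in zip(rows, cols):
                add(self.iMic[r], iD[c], pname)
            close_block(bname + "_dom")
            rows, cols = np.nonzero(coefX)
            gather[bname + "_pom"] = (rows.copy(), coefX[rows, cols].copy())
            open_block(bname + "_pom")
            for r, c in zip(rows, cols):
                add(self.iMic[r], iM[c], pname)
            close_block(bname + "_pom")

        open_block("dis")
        for k, i in enumerate(iM):
            add(i, self.pom_partner[k], "dissolution")
        close_block("dis")

        open_block("set")
        keep = np.nonzero(self.vs_over_H)[0]
        gather["set"] = (keep.copy(),)
        for k in keep:
            add(self.vs_idx[k], sink_id[SINK_SED], "settling")
        close_block("set")

        open_block("out")
        for i in range(self.n):
            add(i, sink_id[SINK_OUT], "outflow")
        close_block("out")

        # heterotrophy: active bacterium-substrate pairs
        rows, cols = np.nonzero(self.invKsh)
        gather["upt"] = (rows.copy(), cols.copy())
        open_block("upt")
        for r, c in zip(rows, cols):
            add(iD[c], iB[r], "heterotrophy")
        close_block("upt")
        open_block("upr")
        for r, c in zip(rows, cols):
            add(iD[c], sink_id[SINK_RESP], "respiration")
        close_block("upr")

        open_block("nload")
        for i in self.iN:
            add(-1, i, "load")
        close_block("nload")
        open_block("nrem")
        for i in self.iN:
            add(-1, i, "remineralization")
        close_block("nrem")
        open_block("nupt")
        for i in self.iN:
            add(i, sink_id[SINK_ASSIM], "nutrient-uptake")
        close_block("nupt")

        open_block("mex")
        for i in self.iU:
            add(-1, i, "exudation")
        close_block("mex")
        open_block("mcon")
        for i in self.iU:
            add(i, sink_id[SINK_CONS], "consumption")
        close_block("mcon")

        open_block("zex")
        for i in self.iZ:
            add(-1, i, "exudation")
        close_block("zex")
        open_block("zdec")
        for i in self.iZ:
            add(i, sink_id[SINK_DECAY], "decay")
        close_block("zdec")

        self.ch_src = np.array(src, dtype=int)
        self.ch_dst = np.array(dst, dtype=int)
        self.ch_proc = np.array(proc)
        self.n_ch = len(src)
        self.blocks = blocks
        self.gather = gather

        def name_of(code):
            if code == -1:
                return EXT
            if code < -1:
                return SINKS[-code - 2]
            return self.ids[code]

        self.ch_src_name = np.array([name_of(s) for s in src])
        self.ch_dst_name = np.array([name_of(d) for d in dst])
        self.ch_carbon = np.array([
            (s >= 0 and self.compartment[s] in ("phytoplankton", "bacteria", "DOM", "POM"))
            or (d >= 0 and self.compartment[d] in ("phytoplankton", "bacteria", "DOM", "POM"))
            for s, d in zip(src, dst)
        ])

        # dormancy bookkeeping: channels that are losses/gains of each microbe
        micro_of = {int(g): k for k, g in enumerate(self.iMic)}
        loss_idx = [j for j in range(self.n_ch) if int(self.ch_src[j]) in micro_of]
        self.dorm_loss_ch = np.array(loss_idx, dtype=int)
        self.dorm_loss_owner = np.array([micro_of[int(self.ch_src[j])] for j in loss_idx], dtype=int)
        gain_idx = [j for j in range(self.n_ch) if int(self.ch_dst[j]) in micro_of]
        self.dorm_gain_ch = np.array(gain_idx, dtype=int)
        self.dorm_gain_owner = np.array([micro_of[int(self.ch_dst[j])] for j in gain_idx], dtype=int)

        self._gain_mask = self.ch_dst >= 0
        self._loss_mask = self.ch_src >= 0
        self._gain_dst = self.ch_dst[self._gain_mask]
        self._loss_src = self.ch_src[self._loss_mask]
        self._gain_ch = np.nonzero(self._gain_mask)[0]
        self._loss_ch = np.nonzero(self._loss_mask)[0]
        self._pack_kernel_args()

    def _pack_kernel_args(self):
        """Flatten everything the compiled RHS needs into argument tuples."""
        from . import _kernel

        self._kernel = _kernel.kernel if _kernel.HAVE_NUMBA else None

        def I(a):
            return np.ascontiguousarray(np.asarray(a, dtype=np.int64))

        def F(a):
            return np.ascontiguousarray(np.asarray(a, dtype=np.float64))

        def F2(a, ncols):
            a = np.asarray(a, dtype=np.float64)
            if a.size == 0:
                a = a.reshape(0, ncols)
            return np.ascontiguousarray(a)

        bl, ga = self.blocks, self.gather
        role_map = {"N": 1, "P": 2}
        nut_role = I([role_map.get(r, 0) for r in self.nut_role])
        self._forcing_key = None
        self._kargs1 = (
            float(self.H), float(self.kbg), float(self.iss_shade),
            float(self.kappa_r), float(self.kappa_f), float(self.Tref),
            I(self.iP), I(self.iB), I(self.iD), I(self.iM), I(self.iMic),
            I(self.iN), I(self.iU), I(self.iZ),
            F(self.kp), F(self.kr), F(self.ke), F(self.ef), F(self.Iopt),
            F(self.ToptP), F(self.TkapP), F(self.TsigP), F(self.SoptP), F(self.SsigP),
            F(self.kh), F(self.Yh), F(self.ToptB), F(self.TkapB), F(self.TsigB),
            F(self.SoptB), F(self.SsigB),
            F(self.ku), F(self.Cflr), F(self.dpeak), F(self.dwidth), F(self.dbase),
            F(self.SoptM), F(self.SsigM),
            F(self.kf), F(self.shade), I(self.vs_idx), F(self.vs_over_H),
            F(self.kdec), nut_role,
            F2(self.KsN, max(self.iN.size, 1)), F2(self.KsM, max(self.iU.size, 1)),
            F2(self.Mcons, max(self.iU.size, 1)), F2(self.Mexu, max(self.iU.size, 1)),
            F2(self.Zexu, max(self.iZ.size, 1)), F2(self.Zkill, max(self.iZ.size, 1)),
            F2(self.ZK, max(self.iZ.size, 1)), F2(self.invKsh, max(self.nD, 1)),
            F(self.NtoC), F(self.PtoC),
            int(self.n_ch), int(bl["pho"].start), int(bl["res"].start),
            int(bl["exu_dom"].start), I(ga["exu_dom"][0]), F(ga["exu_dom"][1]),
            int(bl["exu_pom"].start), I(ga["exu_pom"][0]), F(ga["exu_pom"][1]),
            int(bl["dea_dom"].start), I(ga["dea_dom"][0]), F(ga["dea_dom"][1]),
            int(bl["dea_pom"].start), I(ga["dea_pom"][0]), F(ga["dea_pom"][1]),
            int(bl["kil_dom"].start), int(bl["kil_pom"].start),
            int(bl["dis"].start), int(bl["set"].start), I(ga["set"][0]),
            int(bl["out"].start),
            int(bl["upt"].start), I(ga["upt"][0]), I(ga["upt"][1]),
            int(bl["upr"].start),
            int(bl["nload"].start), int(bl["nrem"].start), int(bl["nupt"].start),
            int(bl["mex"].start), int(bl["mcon"].start),
            int(bl["zex"].start), int(bl["zdec"].start),
        )
        self._kargs2 = (
            I(self.dorm_gain_ch), I(self.dorm_gain_owner),
            I(self.dorm_loss_ch), I(self.dorm_loss_owner),
            I(self._gain_ch), I(self._gain_dst), I(self._loss_ch), I(self._loss_src),
        )

    def _kernel_call(self, t: float, C: np.ndarray, forcing: Forcing,
                     dormancy: bool = True):
        fmat = forcing._packed()
        return self._kernel(float(t), np.ascontiguousarray(C, dtype=np.float64),
                            forcing.t, fmat, *self._kargs1,
                            bool(dormancy and self._has_micro_floor),
                            *self._kargs2)

    # ------------------------------------------------------------------
    def _limits(self, t: float, Cc: np.ndarray, fvals: np.ndarray):
        """(Lp, lr, Lu, lf, Lh, light, nut, micro) with scalar lr/lf."""
        T, I0, S = fvals[0], fvals[1], fvals[2]
        iss = fvals[6]

        kex = self.kbg + float(self.shade @ Cc) + self.iss_shade * iss
        light = _steele_depth_avg(I0 / self.Iopt, kex * self.H)

        nut = np.ones(self.nP)
        micro = np.ones(self.nP)
        if self.iN.size and self.nP:
            Cn = Cc[self.iN]
            mac = np.where(self._mKsN, Cn / (self._sKsN + Cn), 1.0)
            nut = np.minimum(nut, mac.min(axis=1))
        if self.iU.size and self.nP:
            Cu = Cc[self.iU]
            mic = np.where(self._mKsM, Cu / (self._sKsM + Cu), 1.0)
            micro = mic.min(axis=1)
            nut = np.minimum(nut, micro)

        dTP = T - self.ToptP
        LTp = np.where(dTP <= 0, np.exp(self.TkapP * dTP),
                       np.where(self._mTsigP, np.exp(-0.5 * (dTP / self._sTsigP) ** 2), 1.0))
        dSP = S - self.SoptP
        LsP = np.where(self._mSsigP, np.exp(-0.5 * (dSP / self._sSsigP) ** 2), 1.0)
        Lp = light * nut * LTp * LsP
        lr = math.exp(self.kappa_r * (T - self.Tref))

        doy = t % _DAYS_PER_YEAR
        d = np.abs(doy - self.dpeak)
        d = np.minimum(d, _DAYS_PER_YEAR - d)
        bell = np.where(self._mDw, np.exp(-0.5 * (d / self._sDw) ** 2), 1.0)
        dSM = S - self.SoptM
        LsM = np.where(self._mSsigM, np.exp(-0.5 * (dSM / self._sSsigM) ** 2), 1.0)
        Lu = (self.dbase + (1.0 - self.dbase) * bell) * LsM

        lf = math.exp(self.kappa_f * (T - self.Tref))
        dTB = T - self.ToptB
        LTb = np.where(dTB <= 0, np.exp(self.TkapB * dTB),
                       np.where(self._mTsigB, np.exp(-0.5 * (dTB / self._sTsigB) ** 2), 1.0))
        dSB = S - self.SoptB
        LsB = np.where(self._mSsigB, np.exp(-0.5 * (dSB / self._sSsigB) ** 2), 1.0)
        Lh = LTb * LsB
        return Lp, lr, Lu, lf, Lh, light, nut, micro

    def limitation_factors(self, t: float, C: np.ndarray, forcing: Forcing) -> LimitationFactors:
        Cc = np.maximum(np.asarray(C, dtype=float), 0.0)
        Lp, lr, Lu, lf, Lh, light, nut, micro = self._limits(t, Cc, forcing.sample(t))
        return LimitationFactors(Lp=Lp, Lr=np.full(self.nP, lr), Lu=Lu,
                                 Lf=np.full(self.nM, lf), Lh=Lh,
                                 light=light, nutrient=nut, micronutrient=micro)

    def uptake_matrix(self, C: np.ndarray, Lh: np.ndarray) -> np.ndarray:
        """Shared-denominator multi-substrate Monod uptake (nB x nD), µmolC/L/d."""
        Cc = np.maximum(np.asarray(C, dtype=float), 0.0)
        Cd = Cc[self.iD] if self.iD.size else np.zeros(0)
        A = self.invKsh * Cd[None, :]
        den = 1.0 + A.sum(axis=1)
        tot = self.kh * np.asarray(Lh) * Cc[self.iB] / den
        return tot[:, None] * A

    # ------------------------------------------------------------------
    def rates(self, t: float, C: np.ndarray, forcing: Forcing,
              dormancy: bool = True) -> np.ndarray:
        """Channel rate vector at (t, C); dormancy scaling applied if requested."""
        if self._kernel is not None:
            R, _ = self._kernel_call(t, C, forcing, dormancy)
            return R
        return self.rates_reference(t, C, forcing, dormancy)

    def rates_reference(self, t: float, C: np.ndarray, forcing: Forcing,
                        dormancy: bool = True) -> np.ndarray:
        """Pure-numpy reference implementation of :meth:`rates`."""
        Cc = np.maximum(np.asarray(C, dtype=float), 0.0)
        fvals = forcing.sample(t)
        Lp, lr, Lu, lf, Lh, _, _, _ = self._limits(t, Cc, fvals)
        dil = fvals[3]
        R = np.empty(self.n_ch)
        bl, ga = self.blocks, self.gather

        Cp = Cc[self.iP]
        Cb = Cc[self.iB]
        Cm = Cc[self.iMic]

        kpLp = self.kp * Lp
        P = kpLp * Cp                                # photosynthesis
        E = (self.ke + self.ef * kpLp) * Cp          # exudation
        Dth = self.ku * Lu * Cm                      # death, per microbe
        if self.iZ.size and self.iMic.size:
            Cz = Cc[self.iZ]
            mon = np.where(self._mZK, Cz / (self._sZK + Cz), 0.0)
            Kill = (self.Zkill * mon).sum(axis=1) * Cm
        else:
            Kill = np.zeros(self.iMic.size)
        if self.nB:
            A = self.invKsh * Cc[self.iD][None, :]
            den = 1.0 + A.sum(axis=1)
            U = (self.kh * Lh * Cb / den)[:, None] * A
        else:
            U = np.zeros((0, self.nD))

        R[bl["pho"]] = P
        R[bl["res"]] = self.kr * lr * Cp
        r, coef = ga["exu_dom"]
        R[bl["exu_dom"]] = coef * E[r]
        r, coef = ga["exu_pom"]
        R[bl["exu_pom"]] = coef * E[r]
        r, coef = ga["dea_dom"]
        R[bl["dea_dom"]] = coef * Dth[r]
        r, coef = ga["dea_pom"]
        R[bl["dea_pom"]] = coef * Dth[r]
        r, coef = ga["kil_dom"]
        R[bl["kil_dom"]] = coef * Kill[r]
        r, coef = ga["kil_pom"]
        R[bl["kil_pom"]] = coef * Kill[r]
        if self.nM:
            R[bl["dis"]] = self.kf * lf * Cc[self.iM]
        (keep,) = ga["set"]
        R[bl["set"]] = self.vs_over_H[keep] * Cc[self.vs_idx[keep]]
        R[bl["out"]] = dil * Cc
        rr, cc = ga["upt"]
        R[bl["upt"]] = self.Yh[rr] * U[rr, cc]
        R[bl["upr"]] = (1.0 - self.Yh[rr]) * U[rr, cc]

        if self.iN.size:
            Utot = U.sum(axis=1) if self.nB else np.zeros(0)
            respC = ((1.0 - self.Yh) * Utot) if self.nB else np.zeros(0)
            retM = Dth.copy() + Kill
            retM[self.nP:] += respC
            for k, role in enumerate(self.nut_role):
                stv = self.NtoC if role == "N" else self.PtoC if role == "P" else None
                if stv is None:
                    load = rem = upt = 0.0
                else:
                    load = fvals[4] if role == "N" else fvals[5]
                    rem = float(stv @ retM)
                    upt = float((stv[: self.nP] * P).sum()) if self.nP else 0.0
                R[bl["nload"].start + k] = load
                R[bl["nrem"].start + k] = rem
                R[bl["nupt"].start + k] = upt
        if self.iU.size:
            R[bl["mex"]] = self.Mexu.T @ Cb if self.nB else 0.0
            R[bl["mcon"]] = self.Mcons.T @ P if self.nP else 0.0
        if self.iZ.size:
            R[bl["zex"]] = self.Zexu.T @ Cm if self.iMic.size else 0.0
            R[bl["zdec"]] = self.kdec * Cc[self.iZ]

        if dormancy and self._has_micro_floor and self.dorm_loss_ch.size:
            R = self.apply_dormancy(Cc, R)
        return R

    def apply_dormancy(self, C: np.ndarray, R: np.ndarray) -> np.ndarray:
        """Scale loss channels of microbes at their floor so net dC/dt >= 0."""
        Cm = C[self.iMic]
        x = np.where(self._flr_pos, (Cm - self.Cflr) / (0.05 * self._flr_safe), 2.0)
        if x.min() >= 1.0:          # everyone comfortably above the floor
            return R
        nm = self.iMic.size
        G = np.bincount(self.dorm_gain_owner, weights=R[self.dorm_gain_ch], minlength=nm)
        Lo = np.bincount(self.dorm_loss_owner, weights=R[self.dorm_loss_ch], minlength=nm)
        w = np.clip(x, 0.0, 1.0)
        w = w * w * (3.0 - 2.0 * w)
        s_floor = np.minimum(1.0, G / np.maximum(Lo, 1e-300))
        s = w + (1.0 - w) * s_floor
        if np.any(s < 1.0):
            R = R.copy()
            R[self.dorm_loss_ch] *= s[self.dorm_loss_owner]
        return R

    def assemble(self, R: np.ndarray) -> np.ndarray:
        """dC/dt from channel rates: gains accumulated, then losses subtracted.

        bincount sums in channel order, so a closure oracle replaying the
        ledger records of one component in order reproduces dC/dt bit-exactly.
        """
        gains = np.bincount(self._gain_dst, weights=R[self._gain_mask], minlength=self.n)
        losses = np.bincount(self._loss_src, weights=R[self._loss_mask], minlength=self.n)
        return gains - losses

    def rhs(self, t: float, C: np.ndarray, forcing: Forcing) -> np.ndarray:
        if self._kernel is not None:
            _, dC = self._kernel_call(t, C, forcing)
            return dC
        return self.assemble(self.rates_reference(t, C, forcing))

    def rates_and_rhs(self, t: float, C: np.ndarray, forcing: Forcing):
        if self._kernel is not None:
            return self._kernel_call(t, C, forcing)
        R = self.rates_reference(t, C, forcing)
        return R, self.assemble(R)

    def derivatives(self, t: float, C: np.ndarray, forcing: Forcing):
        """(dC/dt, ledger records) at one instant; raises on non-finite rates."""
        R, dC = self.rates_and_rhs(t, C, forcing)
        bad = np.nonzero(~np.isfinite(dC))[0]
        if bad.size:
            raise FloatingPointError(
                f"non-finite derivative for component(s) {[self.ids[i] for i in bad]} at t={t}")
        records = [
            (t, self.ch_src_name[j], self.ch_dst_name[j], self.ch_proc[j], R[j])
            for j in range(self.n_ch)
        ]
        return dC, records

    def c0_vector(self) -> np.ndarray:
        return np.array([c.c0.value for c in self.spec.components.values()])
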