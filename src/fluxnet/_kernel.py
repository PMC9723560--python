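"""Compiled inner loop for the ecosystem right-hand side.

The channelized rate computation of :mod:`fluxnet.dynamics` is numerically
identical to the pure-numpy reference implementation there (same formulas,
scalar loops instead of vector ops); it exists because calibration spends
essentially all of its time in this function.  Falls back transparently
when numba is unavailable.
"""

from __future__ import annotations

import math

import numpy as np

try:
    from numba import njit

    HAVE_NUMBA = True
except ImportError:                                       # pragma: no cover
    HAVE_NUMBA = False

    def njit(*a, **k):
        def deco(f):
            return f
        return deco if not (len(a) == 1 and callable(a[0])) else a[0]


@njit(cache=True)
def kernel(t, y,
           # forcing
           f_t, f_mat,
           # scalars
           H, kbg, iss_shade, kappa_r, kappa_f, Tref,
           # group index arrays (positions in C)
           iP, iB, iD, iM, iMic, iN, iU, iZ,
           # phyto params
           kp, kr, ke, ef, Iopt, ToptP, TkapP, TsigP, SoptP, SsigP,
           # bacteria params
           kh, Yh, ToptB, TkapB, TsigB, SoptB, SsigB,
           # microbe params
           ku, Cflr, dpeak, dwidth, dbase, SoptM, SsigM,
           # pom / misc
           kf, shade, vs_idx, vs_over_H, kdec, nut_role,
           # matrices
           KsN, KsM, Mcons, Mexu, Zexu, Zkill, ZK, invKsh, NtoC, PtoC,
           # channel layout
           n_ch, pho_s, res_s, exu_dom_s, exu_dom_rows, exu_dom_coef,
           exu_pom_s, exu_pom_rows, exu_pom_coef,
           dea_dom_s, dea_dom_rows, dea_dom_coef,
           dea_pom_s, dea_pom_rows, dea_pom_coef,
           kil_dom_s, kil_pom_s, dis_s, set_s, set_keep, out_s,
           upt_s, upt_rows, upt_cols, upr_s,
           nload_s, nrem_s, nupt_s, mex_s, mcon_s, zex_s, zdec_s,
           # dormancy / assembly
           use_dormancy, dorm_gain_ch, dorm_gain_owner, dorm_loss_ch,
           dorm_loss_owner, gain_ch, gain_dst, loss_ch, loss_src):
    n = len(iP) + len(iB) + len(iD) + len(iM) + len(iN) + len(iU) + len(iZ)
    n = y.shape[0] if y.shape[0] < n else n     # y may be augmented
    nP, nB, nD, nM = len(iP), len(iB), len(iD), len(iM)
    nMic = len(iMic)

    C = np.empty(n)
    for i in range(n):
        c = y[i]
        C[i] = c if c > 0.0 else 0.0

    # ---- forcing (linear interpolation of the packed matrix) ----------
    nt = f_t.shape[0]
    j = np.searchsorted(f_t, t) - 1
    if j < 0:
        j = 0
    if j > nt - 2:
        j = nt - 2
    w = (t - f_t[j]) / (f_t[j + 1] - f_t[j])
    if w < 0.0:
        w = 0.0
    if w > 1.0:
        w = 1.0
    T = f_mat[0, j] * (1 - w) + f_mat[0, j + 1] * w
    I0 = f_mat[1, j] * (1 - w) + f_mat[1, j + 1] * w
    S = f_mat[2, j] * (1 - w) + f_mat[2, j + 1] * w
    dil = f_mat[3, j] * (1 - w) + f_mat[3, j + 1] * w
    loadN = f_mat[4, j] * (1 - w) + f_mat[4, j + 1] * w
    loadP = f_mat[5, j] * (1 - w) + f_mat[5, j + 1] * w
    iss = f_mat[6, j] * (1 - w) + f_mat[6, j + 1] * w

    # ---- limitation factors ------------------------------------------
    kex = kbg + iss_shade * iss
    for i in range(n):
        kex += shade[i] * C[i]
    kH = kex * H

    lr = math.exp(kappa_r * (T - Tref))
    lf = math.exp(kappa_f * (T - Tref))

    Lp = np.empty(nP)
    for p in range(nP):
        if Iopt[p] <= 0.0:
            light = 0.0
        else:
            x0 = I0 / Iopt[p]
            if kH < 1e-9:
                light = x0 * math.exp(1.0 - x0)
            else:
                q = -math.expm1(-kH)
                light = math.exp(1.0 - x0) * math.expm1(x0 * q) / kH
        nut = 1.0
        for k in range(len(iN)):
            if KsN[p, k] > 0.0:
                cn = C[iN[k]]
                mv = cn / (KsN[p, k] + cn)
                if mv < nut:
                    nut = mv
        for k in range(len(iU)):
            if KsM[p, k] > 0.0:
                cu = C[iU[k]]
                mv = cu / (KsM[p, k] + cu)
                if mv < nut:
                    nut = mv
        dT = T - ToptP[p]
        if dT <= 0.0:
            LT = math.exp(TkapP[p] * dT)
        elif TsigP[p] > 0.0:
            LT = math.exp(-0.5 * (dT / TsigP[p]) ** 2)
        else:
            LT = 1.0
        if SsigP[p] > 0.0:
            Ls = math.exp(-0.5 * ((S - SoptP[p]) / SsigP[p]) ** 2)
        else:
            Ls = 1.0
        Lp[p] = light * nut * LT * Ls

    doy = t % 365.0
    Lu = np.empty(nMic)
    for m in range(nMic):
        d = abs(doy - dpeak[m])
        if 365.0 - d < d:
            d = 365.0 - d
        bell = math.exp(-0.5 * (d / dwidth[m]) ** 2) if dwidth[m] > 0.0 else 1.0
        if SsigM[m] > 0.0:
            Ls = math.exp(-0.5 * ((S - SoptM[m]) / SsigM[m]) ** 2)
        else:
            Ls = 1.0
        Lu[m] = (dbase[m] + (1.0 - dbase[m]) * bell) * Ls

    Lh = np.empty(nB)
    for b in range(nB):
        dT = T - ToptB[b]
        if dT <= 0.0:
            LT = math.exp(TkapB[b] * dT)
        elif TsigB[b] > 0.0:
            LT = math.exp(-0.5 * (dT / TsigB[b]) ** 2)
        else:
            LT = 1.0
        if SsigB[b] > 0.0:
            Ls = math.exp(-0.5 * ((S - SoptB[b]) / SsigB[b]) ** 2)
        else:
            Ls = 1.0
        Lh[b] = LT * Ls

    # ---- process rates ------------------------------------------------
    P = np.empty(nP)
    E = np.empty(nP)
    for p in range(nP):
        cp = C[iP[p]]
        kpLp = kp[p] * Lp[p]
        P[p] = kpLp * cp
        E[p] = (ke[p] + ef[p] * kpLp) * cp

    Dth = np.empty(nMic)
    Kill = np.empty(nMic)
    for m in range(nMic):
        cm = C[iMic[m]]
        Dth[m] = ku[m] * Lu[m] * cm
        kl = 0.0
        for z in range(len(iZ)):
            if ZK[m, z] > 0.0:
                cz = C[iZ[z]]
                kl += Zkill[m, z] * cz / (ZK[m, z] + cz)
        Kill[m] = kl * cm

    U = np.zeros((nB, nD))
    Utot = np.zeros(nB)
    for b in range(nB):
        den = 1.0
        for d in range(nD):
            den += invKsh[b, d] * C[iD[d]]
        pref = kh[b] * Lh[b] * C[iB[b]] / den
        for d in range(nD):
            u = pref * invKsh[b, d] * C[iD[d]]
            U[b, d] = u
            Utot[b] += u

    R = np.zeros(n_ch)
    for p in range(nP):
        R[pho_s + p] = P[p]
        R[res_s + p] = kr[p] * lr * C[iP[p]]
    for k in range(len(exu_dom_rows)):
        R[exu_dom_s + k] = exu_dom_coef[k] * E[exu_dom_rows[k]]
    for k in range(len(exu_pom_rows)):
        R[exu_pom_s + k] = exu_pom_coef[k] * E[exu_pom_rows[k]]
    for k in range(len(dea_dom_rows)):
        R[dea_dom_s + k] = dea_dom_coef[k] * Dth[dea_dom_rows[k]]
        R[kil_dom_s + k] = dea_dom_coef[k] * Kill[dea_dom_rows[k]]
    for k in range(len(dea_pom_rows)):
        R[dea_pom_s + k] = dea_pom_coef[k] * Dth[dea_pom_rows[k]]
        R[kil_pom_s + k] = dea_pom_coef[k] * Kill[dea_pom_rows[k]]
    for m in range(nM):
        R[dis_s + m] = kf[m] * lf * C[iM[m]]
    for k in range(len(set_keep)):
        kk = set_keep[k]
        R[set_s + k] = vs_over_H[kk] * C[vs_idx[kk]]
    for i in range(n):
        R[out_s + i] = dil * C[i]
    for k in range(len(upt_rows)):
        b = upt_rows[k]
        u = U[b, upt_cols[k]]
        R[upt_s + k] = Yh[b] * u
        R[upr_s + k] = (1.0 - Yh[b]) * u

    for k in range(len(iN)):
        role = nut_role[k]
        if role == 1 or role == 2:
            load = loadN if role == 1 else loadP
            rem = 0.0
            upt = 0.0
            for m in range(nMic):
                stv = NtoC[m] if role == 1 else PtoC[m]
                ret = Dth[m] + Kill[m]
                if m >= nP:
                    ret += (1.0 - Yh[m - nP]) * Utot[m - nP]
                rem += stv * ret
                if m < nP:
                    upt += stv * P[m]
            R[nload_s + k] = load
            R[nrem_s + k] = rem
            R[nupt_s + k] = upt
    for k in range(len(iU)):
        ex = 0.0
        for b in range(nB):
            ex += Mexu[b, k] * C[iB[b]]
        con = 0.0
        for p in range(nP):
            con += Mcons[p, k] * P[p]
        R[mex_s + k] = ex
        R[mcon_s + k] = con
    for k in range(len(iZ)):
        ex = 0.0
        for m in range(nMic):
            ex += Zexu[m, k] * C[iMic[m]]
        R[zex_s + k] = ex
        R[zdec_s + k] = kdec[k] * C[iZ[k]]

    # ---- dormancy ------------------------------------------------------
    if use_dormancy:
        need = False
        for m in range(nMic):
            if Cflr[m] > 0.0 and C[iMic[m]] < 1.05 * Cflr[m]:
                need = True
                break
        if need:
            G = np.zeros(nMic)
            Lo = np.zeros(nMic)
            for k in range(len(dorm_gain_ch)):
                G[dorm_gain_owner[k]] += R[dorm_gain_ch[k]]
            for k in range(len(dorm_loss_ch)):
                Lo[dorm_loss_owner[k]] += R[dorm_loss_ch[k]]
            s = np.ones(nMic)
            for m in range(nMic):
                if Cflr[m] <= 0.0:
                    continue
                x = (C[iMic[m]] - Cflr[m]) / (0.05 * Cflr[m])
                if x >= 1.0:
                    continue
                if x < 0.0:
                    x = 0.0
                w2 = x * x * (3.0 - 2.0 * x)
                sf = 1.0
                if Lo[m] > 0.0:
                    sf = G[m] / Lo[m]
                    if sf > 1.0:
                        sf = 1.0
                s[m] = w2 + (1.0 - w2) * sf
            for k in range(len(dorm_loss_ch)):
                R[dorm_loss_ch[k]] *= s[dorm_loss_owner[k]]

    # ---- assembly: gains accumulated, then losses subtracted ----------
    gains = np.zeros(n)
    losses = np.zeros(n)
    for k in range(len(gain_ch)):
        gains[gain_dst[k]] += R[gain_ch[k]]
    for k in range(len(loss_ch)):
        losses[loss_src[k]] += R[loss_ch[k]]
    dC = gains - losses
    return R, dC
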