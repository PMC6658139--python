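"""Numba kernels: growth laws, within-step chemical integration, maturation.

The agent simulation advances one community through many short time steps
(default 0.05 time units).  Within a step, cell biomasses are frozen and the
Resource/Byproduct pool is integrated with an embedded Cash–Karp 4(5) pair;
the cumulative growth integral of every phenotype group is carried as an
augmented ODE state so that it is consistent with the evolving chemicals.
The full growth → death → division → mutation cycle for one community is
compiled as a single kernel (`mature_kernel`) for speed; the pure
numpy/Python composition of the same operations lives in `commsel.agents`
and the two are held equivalent by tests.

All stochasticity inside `mature_kernel` flows through numba's Mersenne
Twister seeded once per community, so a maturation is exactly replayable
from its logged seed.
"""

from __future__ import annotations

import math

import numpy as np
from numba import njit

# --------------------------------------------------------------------------
# growth-rate laws
# --------------------------------------------------------------------------


@njit(cache=True, inline="always")
def monod(R, g_max, aff):
    """Monod rate g_max * R / (R + 1/aff); 0 at zero affinity (K -> inf)."""
    if aff <= 0.0 or R <= 0.0:
        return 0.0
    return g_max * R / (R + 1.0 / aff)


@njit(cache=True, inline="always")
def mankad_bungay(R, B, g_max, aff_R, aff_B):
    """Dual-substrate Mankad–Bungay rate in scaled substrate units."""
    RM = R * aff_R
    BM = B * aff_B
    if RM <= 0.0 or BM <= 0.0:
        return 0.0
    return g_max * (RM * BM / (RM + BM)) * (1.0 / (RM + 1.0) + 1.0 / (BM + 1.0))


@njit(cache=True, inline="always")
def sample_delta(u2, s_plus, s_minus):
    """Inverse-CDF draw of the bilateral-exponential relative mutation effect.

    The negative branch is truncated at -1 (a mutation cannot push a
    phenotype below 0), which contributes the exp(-1/s_minus) term.
    """
    em = math.exp(-1.0 / s_minus)
    A = s_plus + s_minus * (1.0 - em)
    C0 = s_minus * (1.0 - em) / A
    if u2 <= C0:
        return s_minus * math.log(u2 * A / s_minus + em)
    return -s_plus * math.log((1.0 - u2) * A / s_plus)


# --------------------------------------------------------------------------
# within-step chemical integration (Cash–Karp 4(5), adaptive)
# --------------------------------------------------------------------------


@njit(cache=True)
def _chem_rhs(y, dy, Hb, Hg, Ha, Mb, Mg, Mar, Mab, c_RM, c_RH, c_BM, b0_inv, excess_B):
    R = y[0]
    B = y[1]
    if R < 0.0:
        R = 0.0
    if B < 0.0:
        B = 0.0
    inhib = math.exp(-B * b0_inv) if b0_inv > 0.0 else 1.0
    nH = Hb.shape[0]
    nM = Mb.shape[0]
    dR = 0.0
    dB = 0.0
    for i in range(nH):
        gh = monod(R, Hg[i], Ha[i]) * inhib
        dy[2 + i] = gh
        dR -= c_RH * gh * Hb[i]
        dB += gh * Hb[i]
    for j in range(nM):
        if excess_B:
            gm = monod(R, Mg[j], Mar[j])
        else:
            gm = mankad_bungay(R, B, Mg[j], Mar[j], Mab[j])
        dy[2 + nH + j] = gm
        dR -= c_RM * gm * Mb[j]
        dB -= c_BM * gm * Mb[j]
    dy[0] = dR
    dy[1] = dB


@njit(cache=True)
def chem_step(R, B, Hb, Hg, Ha, Mb, Mg, Mar, Mab,
              c_RM, c_RH, c_BM, b0_inv, excess_B, dt, rtol, atol):
    """Integrate Resource/Byproduct over one step with frozen biomasses.

    Returns the state vector [R', B', IH_0.., IM_0..] where IH/IM are the
    per-group cumulative growth integrals int g dt over the step.
    """
    n = 2 + Hb.shape[0] + Mb.shape[0]
    y = np.zeros(n)
    y[0] = R
    y[1] = B
    k1 = np.empty(n)
    k2 = np.empty(n)
    k3 = np.empty(n)
    k4 = np.empty(n)
    k5 = np.empty(n)
    k6 = np.empty(n)
    yt = np.empty(n)
    y5 = np.empty(n)
    y4 = np.empty(n)
    t = 0.0
    h = dt
    while t < dt - 1e-14 * dt:
        if h > dt - t:
            h = dt - t
        _chem_rhs(y, k1, Hb, Hg, Ha, Mb, Mg, Mar, Mab, c_RM, c_RH, c_BM, b0_inv, excess_B)
        for i in range(n):
            yt[i] = y[i] + h * 0.2 * k1[i]
        _chem_rhs(yt, k2, Hb, Hg, Ha, Mb, Mg, Mar, Mab, c_RM, c_RH, c_BM, b0_inv, excess_B)
        for i in range(n):
            yt[i] = y[i] + h * (0.075 * k1[i] + 0.225 * k2[i])
        _chem_rhs(yt, k3, Hb, Hg, Ha, Mb, Mg, Mar, Mab, c_RM, c_RH, c_BM, b0_inv, excess_B)
        for i in range(n):
            yt[i] = y[i] + h * (0.3 * k1[i] - 0.9 * k2[i] + 1.2 * k3[i])
        _chem_rhs(yt, k4, Hb, Hg, Ha, Mb, Mg, Mar, Mab, c_RM, c_RH, c_BM, b0_inv, excess_B)
        for i in range(n):
            yt[i] = y[i] + h * (-11.0 / 54.0 * k1[i] + 2.5 * k2[i]
                                - 70.0 / 27.0 * k3[i] + 35.0 / 27.0 * k4[i])
        _chem_rhs(yt, k5, Hb, Hg, Ha, Mb, Mg, Mar, Mab, c_RM, c_RH, c_BM, b0_inv, excess_B)
        for i in range(n):
            yt[i] = y[i] + h * (1631.0 / 55296.0 * k1[i] + 175.0 / 512.0 * k2[i]
                                + 575.0 / 13824.0 * k3[i] + 44275.0 / 110592.0 * k4[i]
                                + 253.0 / 4096.0 * k5[i])
        _chem_rhs(yt, k6, Hb, Hg, Ha, Mb, Mg, Mar, Mab, c_RM, c_RH, c_BM, b0_inv, excess_B)
        errmax = 0.0
        for i in range(n):
            y5[i] = y[i] + h * (37.0 / 378.0 * k1[i] + 250.0 / 621.0 * k3[i]
                                + 125.0 / 594.0 * k4[i] + 512.0 / 1771.0 * k6[i])
            y4[i] = y[i] + h * (2825.0 / 27648.0 * k1[i] + 18575.0 / 48384.0 * k3[i]
                                + 13525.0 / 55296.0 * k4[i] + 277.0 / 14336.0 * k5[i]
                                + 0.25 * k6[i])
            sc = atol + rtol * max(abs(y[i]), abs(y5[i]))
            e = abs(y5[i] - y4[i]) / sc
            if e > errmax:
                errmax = e
        if errmax <= 1.0 or h <= 1e-12 * dt:
            t += h
            for i in range(n):
                y[i] = y5[i]
            if y[0] < 0.0:
                y[0] = 0.0
            if y[1] < 0.0:
                y[1] = 0.0
        if errmax > 1e-30:
            fac = 0.9 * errmax ** -0.2
            if fac < 0.1:
                fac = 0.1
            elif fac > 5.0:
                fac = 5.0
            h *= fac
        else:
            h *= 5.0
    return y


# --------------------------------------------------------------------------
# maturation kernel
# --------------------------------------------------------------------------


@njit(cache=True, inline="always")
def _find_or_add_h(HgP, nHg, g, a):
    for k in range(nHg):
        if HgP[k, 0] == g and HgP[k, 1] == a:
            return k, nHg
    HgP[nHg, 0] = g
    HgP[nHg, 1] = a
    return nHg, nHg + 1


@njit(cache=True, inline="always")
def _find_or_add_m(MgP, nMg, g, ar, ab):
    for k in range(nMg):
        if MgP[k, 0] == g and MgP[k, 1] == ar and MgP[k, 2] == ab:
            return k, nMg
    MgP[nMg, 0] = g
    MgP[nMg, 1] = ar
    MgP[nMg, 2] = ab
    return nMg, nMg + 1


@njit(cache=True, inline="always")
def _mutated_value(value, ub, p_null, s_plus, s_minus):
    """Apply one phenotype-altering mutation: null or bilateral-exponential."""
    if np.random.random() < p_null:
        return 0.0
    d = sample_delta(np.random.random(), s_plus, s_minus)
    v = value * (1.0 + d)
    if v < 0.0:
        v = 0.0
    elif v > ub:
        v = ub
    return v


@njit(cache=True)
def mature_kernel(species, L0, gmax0, affR0, affB0, fP0,
                  R, B, P,
                  c_RM, c_RH, c_BM, delta_M, delta_H, b0_inv, excess_B,
                  T, dtau, rtol, atol,
                  P_mut, p_null, s_plus, s_minus, epi_g, fP_init,
                  mutable, ub, seed):
    """Advance one Newborn community to Adulthood.

    ``mutable`` is a 6-vector of {0,1} flags and ``ub`` the matching upper
    bounds, both ordered (g_Hmax, aff_HR, g_Mmax, aff_MR, aff_MB, f_P).
    Returns (species, L, gmax, affR, affB, fP, R, B, P, extinct_flag).
    """
    np.random.seed(seed)
    n = species.shape[0]
    cap = n * 2 + 64
    sp = np.empty(cap, np.int8)
    L = np.empty(cap)
    gmax = np.empty(cap)
    affR = np.empty(cap)
    affB = np.empty(cap)
    fP = np.empty(cap)
    gidx = np.empty(cap, np.int64)
    for i in range(n):
        sp[i] = species[i]
        L[i] = L0[i]
        gmax[i] = gmax0[i]
        affR[i] = affR0[i]
        affB[i] = affB0[i]
        fP[i] = fP0[i]

    gcap = 16384
    HgP = np.empty((gcap, 2))
    MgP = np.empty((gcap, 3))
    nHg = 0
    nMg = 0
    for i in range(n):
        if sp[i] == 0:
            k, nHg = _find_or_add_h(HgP, nHg, gmax[i], affR[i])
        else:
            k, nMg = _find_or_add_m(MgP, nMg, gmax[i], affR[i], affB[i])
        gidx[i] = k

    div_buf = np.empty(cap, np.int64)
    nsteps = int(round(T / dtau))
    pdie_H = delta_H * dtau
    pdie_M = delta_M * dtau
    ever_extinct = n == 0

    for _step in range(nsteps):
        if n == 0:
            # no cells: chemicals are inert (all rates carry a biomass factor)
            continue
        # -- chemistry with frozen biomasses --------------------------------
        Hb = np.zeros(nHg)
        Mb = np.zeros(nMg)
        for i in range(n):
            if sp[i] == 0:
                Hb[gidx[i]] += L[i]
            else:
                Mb[gidx[i]] += L[i]
        y = chem_step(R, B, Hb, HgP[:nHg, 0], HgP[:nHg, 1],
                      Mb, MgP[:nMg, 0], MgP[:nMg, 1], MgP[:nMg, 2],
                      c_RM, c_RH, c_BM, b0_inv, excess_B, dtau, rtol, atol)
        R = y[0]
        B = y[1]
        # -- growth, death, division (single compacting pass) ---------------
        w = 0
        ndiv = 0
        for i in range(n):
            li = L[i]
            if sp[i] == 0:
                li *= math.exp(y[2 + gidx[i]])
                pdie = pdie_H
            else:
                f = fP[i]
                integ = y[2 + nHg + gidx[i]]
                if f >= 1.0:
                    # limit form of the Product bookkeeping at full cost
                    P += li * integ
                else:
                    lnew = li * math.exp((1.0 - f) * integ)
                    P += f / (1.0 - f) * (lnew - li)
                    li = lnew
                pdie = pdie_M
            if np.random.random() < pdie:
                continue
            sp[w] = sp[i]
            L[w] = li
            gmax[w] = gmax[i]
            affR[w] = affR[i]
            affB[w] = affB[i]
            fP[w] = fP[i]
            gidx[w] = gidx[i]
            if li >= 2.0:
                div_buf[ndiv] = w
                ndiv += 1
            w += 1
        n = w
        if n == 0:
            ever_extinct = True
            continue
        # -- division: mothers halve, daughters appended in mother order ----
        if n + ndiv > cap:
            newcap = 2 * (n + ndiv) + 64
            sp2 = np.empty(newcap, np.int8)
            L2 = np.empty(newcap)
            g2 = np.empty(newcap)
            aR2 = np.empty(newcap)
            aB2 = np.empty(newcap)
            f2 = np.empty(newcap)
            gi2 = np.empty(newcap, np.int64)
            for i in range(n):
                sp2[i] = sp[i]
                L2[i] = L[i]
                g2[i] = gmax[i]
                aR2[i] = affR[i]
                aB2[i] = affB[i]
                f2[i] = fP[i]
                gi2[i] = gidx[i]
            sp = sp2
            L = L2
            gmax = g2
            affR = aR2
            affB = aB2
            fP = f2
            gidx = gi2
            cap = newcap
            db2 = np.empty(newcap, np.int64)
            for i in range(ndiv):
                db2[i] = div_buf[i]
            div_buf = db2
        for d in range(ndiv):
            i = div_buf[d]
            L[i] *= 0.5
            j = n + d
            sp[j] = sp[i]
            L[j] = L[i]
            gmax[j] = gmax[i]
            affR[j] = affR[i]
            affB[j] = affB[i]
            fP[j] = fP[i]
            gidx[j] = gidx[i]
        nfirst = n
        n += ndiv
        if P_mut <= 0.0:
            continue
        # -- mutation: each mutable phenotype of mother and daughter --------
        for d in range(ndiv):
            for c in range(2):
                idx = div_buf[d] if c == 0 else nfirst + d
                changed = False
                if sp[idx] == 0:
                    if mutable[0] == 1 and np.random.random() < P_mut:
                        gmax[idx] = _mutated_value(gmax[idx], ub[0], p_null, s_plus, s_minus)
                        changed = True
                    if mutable[1] == 1 and np.random.random() < P_mut:
                        affR[idx] = _mutated_value(affR[idx], ub[1], p_null, s_plus, s_minus)
                        changed = True
                    if changed:
                        k, nHg = _find_or_add_h(HgP, nHg, gmax[idx], affR[idx])
                        gidx[idx] = k
                else:
                    if mutable[2] == 1 and np.random.random() < P_mut:
                        gmax[idx] = _mutated_value(gmax[idx], ub[2], p_null, s_plus, s_minus)
                        changed = True
                    if mutable[3] == 1 and np.random.random() < P_mut:
                        affR[idx] = _mutated_value(affR[idx], ub[3], p_null, s_plus, s_minus)
                        changed = True
                    if mutable[4] == 1 and np.random.random() < P_mut:
                        affB[idx] = _mutated_value(affB[idx], ub[4], p_null, s_plus, s_minus)
                        changed = True
                    if mutable[5] == 1 and np.random.random() < P_mut:
                        sp_eff = s_plus
                        sm_eff = s_minus
                        if epi_g > 0.0:
                            fac = 1.0 + epi_g * (fP[idx] / fP_init - 1.0)
                            sp_eff = s_plus / fac
                            sm_eff = s_minus * fac
                        fP[idx] = _mutated_value(fP[idx], ub[5], p_null, sp_eff, sm_eff)
                    if changed:
                        k, nMg = _find_or_add_m(MgP, nMg, gmax[idx], affR[idx], affB[idx])
                        gidx[idx] = k
        # -- rebuild phenotype-group tables if they ever fill up ------------
        if nHg > gcap - 64 or nMg > gcap - 64:
            nHg = 0
            nMg = 0
            for i in range(n):
                if sp[i] == 0:
                    k, nHg = _find_or_add_h(HgP, nHg, gmax[i], affR[i])
                else:
                    k, nMg = _find_or_add_m(MgP, nMg, gmax[i], affR[i], affB[i])
                gidx[i] = k

    if n == 0:
        ever_extinct = True
    return (sp[:n].copy(), L[:n].copy(), gmax[:n].copy(), affR[:n].copy(),
            affB[:n].copy(), fP[:n].copy(), R, B, P, ever_extinct)


# --------------------------------------------------------------------------
# coupled continuous-biomass dynamics (deterministic analyses)
# --------------------------------------------------------------------------


@njit(cache=True)
def coupled_rhs(t, y, Hg, Ha, Mg, Mar, Mab, MfP,
                c_RM, c_RH, c_BM, delta_M, delta_H, b0_inv, excess_B):
    """Right-hand side of the fully coupled scaled equations.

    State layout: [H_1..H_nh, M_1..M_nm, P, R, B]; every Helper and
    Manufacturer phenotype group carries its own growth parameters and (for
    M) cost fraction.
    """
    nH = Hg.shape[0]
    nM = Mg.shape[0]
    R = y[nH + nM + 1]
    B = y[nH + nM + 2]
    if R < 0.0:
        R = 0.0
    if B < 0.0:
        B = 0.0
    inhib = math.exp(-B * b0_inv) if b0_inv > 0.0 else 1.0
    out = np.empty_like(y)
    dR = 0.0
    dB = 0.0
    dP = 0.0
    for i in range(nH):
        gh = monod(R, Hg[i], Ha[i]) * inhib
        H = y[i]
        out[i] = gh * H - delta_H * H
        dR -= c_RH * gh * H
        dB += gh * H
    for j in range(nM):
        if excess_B:
            gm = monod(R, Mg[j], Mar[j])
        else:
            gm = mankad_bungay(R, B, Mg[j], Mar[j], Mab[j])
        M = y[nH + j]
        out[nH + j] = (1.0 - MfP[j]) * gm * M - delta_M * M
        dP += MfP[j] * gm * M
        dR -= c_RM * gm * M
        dB -= c_BM * gm * M
    out[nH + nM] = dP
    out[nH + nM + 1] = dR
    out[nH + nM + 2] = dB
    return out
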