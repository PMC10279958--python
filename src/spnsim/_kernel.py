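"""Compiled right-hand side of the segment polarity network ODEs.

The kernel works on a flat state vector laid out cell-by-cell, 33 species per
cell: 5 mRNAs (en, wg, ptc, ci, hh), 4 cytosolic proteins (EN, IWG, CI, CN)
and 4 membrane proteins x 6 hexagon sides (EWG_j, PTC_j, HH_j, PH_j).  The
parameter vector follows the registry order of :mod:`spnsim.params`.

The same source is executed either through numba's nopython JIT (default,
used for screens and censuses) or as plain Python (fallback when numba is
unavailable); both paths share identical arithmetic.
"""

from __future__ import annotations

import math

import numpy as np

LN2 = math.log(2.0)

# species offsets within a cell block
S_EN_M, S_WG_M, S_PTC_M, S_CI_M, S_HH_M = 0, 1, 2, 3, 4
S_EN, S_IWG, S_CI, S_CN = 5, 6, 7, 8
S_EWG, S_PTC, S_HH, S_PH = 9, 15, 21, 27
N_PER_CELL = 33

# parameter indices (registry order)
P_H_EN_M, P_H_EN, P_H_WG_M, P_H_IWG, P_H_EWG = 0, 1, 2, 3, 4
P_H_PTC_M, P_H_PTC, P_H_CI_M, P_H_CI, P_H_CN = 5, 6, 7, 8, 9
P_H_HH_M, P_H_HH, P_H_PH = 10, 11, 12
P_K_WGEN, P_N_WGEN, P_K_CNEN, P_N_CNEN = 13, 14, 15, 16
P_K_CIWG, P_N_CIWG, P_K_CNWG, P_N_CNWG, P_K_WGWG, P_N_WGWG = 17, 18, 19, 20, 21, 22
P_K_CIPTC, P_N_CIPTC, P_K_CNPTC, P_N_CNPTC = 23, 24, 25, 26
P_K_ENCI, P_N_ENCI, P_K_PTCCI, P_N_PTCCI = 27, 28, 29, 30
P_K_ENHH, P_N_ENHH, P_K_CNHH, P_N_CNHH = 31, 32, 33, 34
P_ALPHA_CIWG, P_ALPHA_WGWG, P_C_CI, P_K_PTCHH = 35, 36, 37, 38
P_R_EXO, P_R_ENDO, P_R_MXFER_WG = 39, 40, 41
P_R_LM_WG, P_R_LM_PTC, P_R_LM_HH, P_R_LM_PH = 42, 43, 44, 45
P_PTC0, P_HH0 = 46, 47
P_B_CI, P_V_MAX, P_P_TRANS, P_R_MXFER_PTC, P_R_MXFER_HH = 48, 49, 50, 51, 52


def _rpow(base, exponent):
    """base**exponent with IEEE semantics: NaN for negative base, fractional exponent."""
    if base >= 0.0:
        return base ** exponent
    if exponent == math.floor(exponent):
        return base ** exponent
    return np.nan


def _phi(x, kappa, nu, guard, eps):
    """Activating Hill function; state base guarded, constant base bare."""
    if guard:
        x = max(eps, x)
    xn = _rpow(x, nu)
    return xn / (kappa ** nu + xn)


def _psi(x, kappa, nu, guard, eps):
    """Repressing Hill function 1 - phi, outer factor clamped to >= eps."""
    r = 1.0 - _phi(x, kappa, nu, guard, eps)
    if guard:
        r = max(eps, r)
    return r


def _tir(I, R, kI, nI, kR, nR, guard, eps):
    """Inducer-repressor transcription activity in [0, 1] (V applied by caller)."""
    ibar = I * _psi(R, kR, nR, guard, eps)
    if guard:
        ibar = max(eps, ibar)
    num = _rpow(ibar, nI)
    return num / (kI ** nI + num)


def rhs_kernel(y, dy, p, neigh, bEWG, bPTC, bHH, guard, eps):
    """Write the state derivative into ``dy``; return the non-finite count.

    ``neigh`` is the (n_cells, 6) apposed-cell index table with -1 marking a
    fixed boundary (single-cell model); ``bEWG/bPTC/bHH`` then give, per side
    j of the cell, the concentration of the apposed neighbour pool.
    """
    n_cells = neigh.shape[0]
    for c in range(n_cells):
        b = c * N_PER_CELL
        en_m = y[b + S_EN_M]
        wg_m = y[b + S_WG_M]
        ptc_m = y[b + S_PTC_M]
        ci_m = y[b + S_CI_M]
        hh_m = y[b + S_HH_M]
        EN = y[b + S_EN]
        IWG = y[b + S_IWG]
        CI = y[b + S_CI]
        CN = y[b + S_CN]

        ptc_T = 0.0
        ewg_sum = 0.0
        ewg_T = 0.0
        for j in range(6):
            ptc_T += y[b + S_PTC + j]
            ewg_sum += y[b + S_EWG + j]
            nb = neigh[c, j]
            js = (j + 3) % 6
            if nb >= 0:
                ewg_T += y[nb * N_PER_CELL + S_EWG + js]
            else:
                ewg_T += bEWG[j]

        vmax = p[P_V_MAX]
        ptr = p[P_P_TRANS]

        # transcription activities
        a_en = _tir(ewg_T, CN, p[P_K_WGEN], p[P_N_WGEN], p[P_K_CNEN], p[P_N_CNEN],
                    guard, eps)
        w_ci = p[P_ALPHA_CIWG] * _phi(CI, p[P_K_CIWG], p[P_N_CIWG], guard, eps) \
            * _psi(CN, p[P_K_CNWG], p[P_N_CNWG], guard, eps)
        w_wg = p[P_ALPHA_WGWG] * _phi(IWG, p[P_K_WGWG], p[P_N_WGWG], guard, eps)
        a_wg = (w_ci + w_wg) / (1.0 + w_ci + w_wg)
        a_ptc = _tir(CI, CN, p[P_K_CIPTC], p[P_N_CIPTC], p[P_K_CNPTC], p[P_N_CNPTC],
                     guard, eps)
        a_ci = p[P_B_CI] * _psi(EN, p[P_K_ENCI], p[P_N_ENCI], guard, eps)
        a_hh = _tir(EN, CN, p[P_K_ENHH], p[P_N_ENHH], p[P_K_CNHH], p[P_N_CNHH],
                    guard, eps)

        dy[b + S_EN_M] = LN2 / p[P_H_EN_M] * (vmax * a_en - en_m)
        dy[b + S_WG_M] = LN2 / p[P_H_WG_M] * (vmax * a_wg - wg_m)
        dy[b + S_PTC_M] = LN2 / p[P_H_PTC_M] * (vmax * a_ptc - ptc_m)
        dy[b + S_CI_M] = LN2 / p[P_H_CI_M] * (vmax * a_ci - ci_m)
        dy[b + S_HH_M] = LN2 / p[P_H_HH_M] * (vmax * a_hh - hh_m)

        cleave = p[P_C_CI] * CI * _phi(ptc_T, p[P_K_PTCCI], p[P_N_PTCCI], guard, eps)
        dy[b + S_EN] = LN2 / p[P_H_EN] * (ptr * en_m - EN)
        dy[b + S_IWG] = (LN2 / p[P_H_IWG] * (ptr * wg_m - IWG)
                         - p[P_R_EXO] * IWG + p[P_R_ENDO] * ewg_sum)
        dy[b + S_CI] = LN2 / p[P_H_CI] * (ptr * ci_m - CI) - cleave
        dy[b + S_CN] = cleave - LN2 / p[P_H_CN] * CN

        for j in range(6):
            nb = neigh[c, j]
            js = (j + 3) % 6
            if nb >= 0:
                nbb = nb * N_PER_CELL
                n_ewg = y[nbb + S_EWG + js]
                n_ptc = y[nbb + S_PTC + js]
                n_hh = y[nbb + S_HH + js]
            else:
                n_ewg = bEWG[j]
                n_ptc = bPTC[j]
                n_hh = bHH[j]
            jl = (j + 5) % 6
            jr = (j + 1) % 6
            ewg_j = y[b + S_EWG + j]
            ptc_j = y[b + S_PTC + j]
            hh_j = y[b + S_HH + j]
            ph_j = y[b + S_PH + j]

            lap_ewg = y[b + S_EWG + jl] + y[b + S_EWG + jr] - 2.0 * ewg_j
            lap_ptc = y[b + S_PTC + jl] + y[b + S_PTC + jr] - 2.0 * ptc_j
            lap_hh = y[b + S_HH + jl] + y[b + S_HH + jr] - 2.0 * hh_j
            lap_ph = y[b + S_PH + jl] + y[b + S_PH + jr] - 2.0 * ph_j

            # PTC_j + apposed HH -> PH_j, normalized-scale fluxes
            bind = p[P_K_PTCHH] * ptc_j * n_hh
            lost = p[P_K_PTCHH] * n_ptc * hh_j

            dy[b + S_EWG + j] = (p[P_R_EXO] / 6.0 * IWG - p[P_R_ENDO] * ewg_j
                                 + p[P_R_LM_WG] * lap_ewg
                                 + p[P_R_MXFER_WG] * (n_ewg - ewg_j)
                                 - LN2 / p[P_H_EWG] * ewg_j)
            dy[b + S_PTC + j] = (LN2 / p[P_H_PTC] * (ptr * ptc_m / 6.0 - ptc_j)
                                 + p[P_R_LM_PTC] * lap_ptc
                                 + p[P_R_MXFER_PTC] * (n_ptc - ptc_j)
                                 - p[P_HH0] * bind)
            dy[b + S_HH + j] = (LN2 / p[P_H_HH] * (ptr * hh_m / 6.0 - hh_j)
                                + p[P_R_LM_HH] * lap_hh
                                + p[P_R_MXFER_HH] * (n_hh - hh_j)
                                - p[P_PTC0] * lost)
            dy[b + S_PH + j] = (p[P_HH0] * bind
                                + p[P_R_LM_PH] * lap_ph
                                - LN2 / p[P_H_PH] * ph_j)

    bad = 0
    for i in range(n_cells * N_PER_CELL):
        if not np.isfinite(dy[i]):
            bad += 1
    return bad


def _dphi(x, kappa, nu, guard, eps):
    """(phi, dphi/dx) of the guarded activating Hill function.

    Below the guard floor the function is flat in x, so the derivative is 0.
    """
    clipped = guard and x < eps
    if clipped:
        x = eps
    kn = kappa ** nu
    xn = _rpow(x, nu)
    den = kn + xn
    f = xn / den
    if clipped:
        return f, 0.0
    return f, nu * kn * _rpow(x, nu - 1.0) / (den * den)


def _dpsi(x, kappa, nu, guard, eps):
    """(psi, dpsi/dx) with the outer max(eps, 1 - phi) clamp."""
    f, df = _dphi(x, kappa, nu, guard, eps)
    r = 1.0 - f
    if guard and r < eps:
        return eps, 0.0
    return r, -df


def _dtir(I, R, kI, nI, kR, nR, guard, eps):
    """(activity, d/dI, d/dR) of the inducer-repressor transcription law."""
    psi, dpsi = _dpsi(R, kR, nR, guard, eps)
    ibar = I * psi
    clipped = guard and ibar < eps
    if clipped:
        ibar = eps
    kn = kI ** nI
    xn = _rpow(ibar, nI)
    den = kn + xn
    a = xn / den
    if clipped:
        return a, 0.0, 0.0
    dad = nI * kn * _rpow(ibar, nI - 1.0) / (den * den)
    return a, dad * psi, dad * I * dpsi


def jac_kernel(y, J, p, neigh, bEWG, bPTC, bHH, guard, eps):
    """Analytic Jacobian J[i, k] = d(dy_i)/d(y_k) of :func:`rhs_kernel`."""
    n_cells = neigh.shape[0]
    n = n_cells * N_PER_CELL
    for i in range(n):
        for k in range(n):
            J[i, k] = 0.0
    for c in range(n_cells):
        b = c * N_PER_CELL
        ptc_m = y[b + S_PTC_M]
        hh_m = y[b + S_HH_M]
        EN = y[b + S_EN]
        IWG = y[b + S_IWG]
        CI = y[b + S_CI]
        CN = y[b + S_CN]

        ptc_T = 0.0
        ewg_T = 0.0
        for j in range(6):
            ptc_T += y[b + S_PTC + j]
            nb = neigh[c, j]
            js = (j + 3) % 6
            if nb >= 0:
                ewg_T += y[nb * N_PER_CELL + S_EWG + js]
            else:
                ewg_T += bEWG[j]

        vmax = p[P_V_MAX]
        ptr = p[P_P_TRANS]
        L_en = LN2 / p[P_H_EN_M]
        L_wg = LN2 / p[P_H_WG_M]
        L_ptcm = LN2 / p[P_H_PTC_M]
        L_cim = LN2 / p[P_H_CI_M]
        L_hhm = LN2 / p[P_H_HH_M]

        # en mRNA
        _, den_dI, den_dR = _dtir(ewg_T, CN, p[P_K_WGEN], p[P_N_WGEN],
                                  p[P_K_CNEN], p[P_N_CNEN], guard, eps)
        J[b + S_EN_M, b + S_EN_M] = -L_en
        J[b + S_EN_M, b + S_CN] = L_en * vmax * den_dR
        for j in range(6):
            nb = neigh[c, j]
            if nb >= 0:
                js = (j + 3) % 6
                J[b + S_EN_M, nb * N_PER_CELL + S_EWG + js] += L_en * vmax * den_dI

        # wg mRNA: W/(1+W), W = alpha*phi(CI)*psi(CN) + beta*phi(IWG)
        fci, dfci = _dphi(CI, p[P_K_CIWG], p[P_N_CIWG], guard, eps)
        pcn, dpcn = _dpsi(CN, p[P_K_CNWG], p[P_N_CNWG], guard, eps)
        fwg, dfwg = _dphi(IWG, p[P_K_WGWG], p[P_N_WGWG], guard, eps)
        W = p[P_ALPHA_CIWG] * fci * pcn + p[P_ALPHA_WGWG] * fwg
        gW = 1.0 / ((1.0 + W) * (1.0 + W))
        J[b + S_WG_M, b + S_WG_M] = -L_wg
        J[b + S_WG_M, b + S_CI] = L_wg * vmax * gW * p[P_ALPHA_CIWG] * dfci * pcn
        J[b + S_WG_M, b + S_CN] = L_wg * vmax * gW * p[P_ALPHA_CIWG] * fci * dpcn
        J[b + S_WG_M, b + S_IWG] = L_wg * vmax * gW * p[P_ALPHA_WGWG] * dfwg

        # ptc mRNA
        _, dptc_dI, dptc_dR = _dtir(CI, CN, p[P_K_CIPTC], p[P_N_CIPTC],
                                    p[P_K_CNPTC], p[P_N_CNPTC], guard, eps)
        J[b + S_PTC_M, b + S_PTC_M] = -L_ptcm
        J[b + S_PTC_M, b + S_CI] = L_ptcm * vmax * dptc_dI
        J[b + S_PTC_M, b + S_CN] = L_ptcm * vmax * dptc_dR

        # ci mRNA
        _, dpen = _dpsi(EN, p[P_K_ENCI], p[P_N_ENCI], guard, eps)
        J[b + S_CI_M, b + S_CI_M] = -L_cim
        J[b + S_CI_M, b + S_EN] = L_cim * vmax * p[P_B_CI] * dpen

        # hh mRNA
        _, dhh_dI, dhh_dR = _dtir(EN, CN, p[P_K_ENHH], p[P_N_ENHH],
                                  p[P_K_CNHH], p[P_N_CNHH], guard, eps)
        J[b + S_HH_M, b + S_HH_M] = -L_hhm
        J[b + S_HH_M, b + S_EN] = L_hhm * vmax * dhh_dI
        J[b + S_HH_M, b + S_CN] = L_hhm * vmax * dhh_dR

        # EN
        L_EN = LN2 / p[P_H_EN]
        J[b + S_EN, b + S_EN_M] = L_EN * ptr
        J[b + S_EN, b + S_EN] = -L_EN

        # IWG
        L_IWG = LN2 / p[P_H_IWG]
        J[b + S_IWG, b + S_WG_M] = L_IWG * ptr
        J[b + S_IWG, b + S_IWG] = -L_IWG - p[P_R_EXO]
        for j in range(6):
            J[b + S_IWG, b + S_EWG + j] = p[P_R_ENDO]

        # CI / CN (cleavage reads the free-PTC total)
        L_CI = LN2 / p[P_H_CI]
        L_CN = LN2 / p[P_H_CN]
        fp, dfp = _dphi(ptc_T, p[P_K_PTCCI], p[P_N_PTCCI], guard, eps)
        C = p[P_C_CI]
        J[b + S_CI, b + S_CI_M] = L_CI * ptr
        J[b + S_CI, b + S_CI] = -L_CI - C * fp
        J[b + S_CN, b + S_CI] = C * fp
        J[b + S_CN, b + S_CN] = -L_CN
        for j in range(6):
            J[b + S_CI, b + S_PTC + j] = -C * CI * dfp
            J[b + S_CN, b + S_PTC + j] = C * CI * dfp

        L_EWG = LN2 / p[P_H_EWG]
        L_PTC = LN2 / p[P_H_PTC]
        L_HH = LN2 / p[P_H_HH]
        L_PH = LN2 / p[P_H_PH]
        kb = p[P_K_PTCHH]
        for j in range(6):
            nb = neigh[c, j]
            js = (j + 3) % 6
            nbb = nb * N_PER_CELL
            if nb >= 0:
                n_ptc = y[nbb + S_PTC + js]
                n_hh = y[nbb + S_HH + js]
            else:
                n_ptc = bPTC[j]
                n_hh = bHH[j]
            jl = (j + 5) % 6
            jr = (j + 1) % 6
            ewg_j = y[b + S_EWG + j]
            ptc_j = y[b + S_PTC + j]
            hh_j = y[b + S_HH + j]

            r = b + S_EWG + j
            J[r, b + S_IWG] = p[P_R_EXO] / 6.0
            J[r, r] += -p[P_R_ENDO] - 2.0 * p[P_R_LM_WG] - p[P_R_MXFER_WG] - L_EWG
            J[r, b + S_EWG + jl] += p[P_R_LM_WG]
            J[r, b + S_EWG + jr] += p[P_R_LM_WG]
            if nb >= 0:
                J[r, nbb + S_EWG + js] += p[P_R_MXFER_WG]

            r = b + S_PTC + j
            J[r, b + S_PTC_M] = L_PTC * ptr / 6.0
            J[r, r] += -L_PTC - 2.0 * p[P_R_LM_PTC] - p[P_R_MXFER_PTC] \
                - p[P_HH0] * kb * n_hh
            J[r, b + S_PTC + jl] += p[P_R_LM_PTC]
            J[r, b + S_PTC + jr] += p[P_R_LM_PTC]
            if nb >= 0:
                J[r, nbb + S_PTC + js] += p[P_R_MXFER_PTC]
                J[r, nbb + S_HH + js] += -p[P_HH0] * kb * ptc_j

            r = b + S_HH + j
            J[r, b + S_HH_M] = L_HH * ptr / 6.0
            J[r, r] += -L_HH - 2.0 * p[P_R_LM_HH] - p[P_R_MXFER_HH] \
                - p[P_PTC0] * kb * n_ptc
            J[r, b + S_HH + jl] += p[P_R_LM_HH]
            J[r, b + S_HH + jr] += p[P_R_LM_HH]
            if nb >= 0:
                J[r, nbb + S_HH + js] += p[P_R_MXFER_HH]
                J[r, nbb + S_PTC + js] += -p[P_PTC0] * kb * hh_j

            r = b + S_PH + j
            J[r, b + S_PTC + j] += p[P_HH0] * kb * n_hh
            if nb >= 0:
                J[r, nbb + S_HH + js] += p[P_HH0] * kb * ptc_j
            J[r, r] += -L_PH - 2.0 * p[P_R_LM_PH]
            J[r, b + S_PH + jl] += p[P_R_LM_PH]
            J[r, b + S_PH + jr] += p[P_R_LM_PH]


rhs_kernel_py = rhs_kernel
jac_kernel_py = jac_kernel

try:  # pragma: no cover - exercised implicitly everywhere
    import numba

    _nj = numba.njit(cache=True, fastmath=False)
    _rpow = _nj(_rpow)
    _phi = _nj(_phi)
    _psi = _nj(_psi)
    _tir = _nj(_tir)
    _dphi = _nj(_dphi)
    _dpsi = _nj(_dpsi)
    _dtir = _nj(_dtir)
    rhs_kernel = _nj(rhs_kernel)
    jac_kernel = _nj(jac_kernel)
    HAVE_NUMBA = True
except ImportError:  # pragma: no cover
    HAVE_NUMBA = False
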