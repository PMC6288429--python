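"""Extended human ventricular myocyte model with heart-failure microdomain
remodeling.

The cell is the O'Hara–Rudy endocardial myocyte (see
:mod:`hfmicro.ord_reference`) extended with:

* a sub-sarcolemmal Ca compartment (``casl``) under the surface (non-tubular)
  membrane, where redistributed L-type channels and NCX sense and deposit Ca;
* six L-type Ca channel (LTCC) subpopulations A–F, weighted by subgroup
  fractions: A–C reside in the T-tubular membrane and sense dyadic Ca
  (``cass``), D–F reside in the surface membrane and sense ``casl``;
* binary PKA phosphorylation of each subpopulation (phosphorylated channels
  carry 2.5x amplitude) and of seven further targets (RyR, PLB, IKs, INa,
  INaK, IKb, TnI), each split into phosphorylated / unphosphorylated
  populations whose currents are summed;
* a constant CaMKII-phosphorylated fraction of the surface LTCC populations
  (T-tubular channels keep the baseline dynamic CaMKII handling);
* NCX redistribution and RyR orphaning proportional to T-tubule loss.

State vector: the 41 baseline states followed by ``casl`` (mM), ``ncasl``
(CaM-mode fraction of surface LTCCs) and ``Jrelo`` (orphaned-RyR release
flux state, mM/ms).  All model switches travel in a flat float64 parameter
pack (see ``P_*`` indices) so the right-hand side stays jit-compilable.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .ord_reference import (
    ACAP, CAO, FDAY, INITIAL_STATE, KO, NAO, RGAS, STATE_NAMES, TEMP,
    VCELL, VJSR, VMYO, VNSR, VSS, njit,
)

# ------------------------------------------------------------------
# state vector layout
# ------------------------------------------------------------------

EXT_STATE_NAMES = STATE_NAMES + ("casl", "ncasl", "Jrelo", "dp")
N_STATES = len(EXT_STATE_NAMES)
_IDX = {name: k for k, name in enumerate(EXT_STATE_NAMES)}

GATE_NAMES = tuple(
    n for n in EXT_STATE_NAMES
    if n not in ("v", "nai", "nass", "ki", "kss", "cai", "cass", "cansr",
                 "cajsr", "casl", "Jrelnp", "Jrelp", "Jrelo", "CaMKt")
)
CONCENTRATION_NAMES = ("nai", "nass", "ki", "kss", "cai", "cass", "cansr",
                       "cajsr", "casl")


def initial_state() -> np.ndarray:
    """Endocardial resting state extended with the new compartment."""
    y = np.empty(N_STATES)
    y[:41] = INITIAL_STATE
    y[_IDX["casl"]] = INITIAL_STATE[_IDX["cai"]]
    y[_IDX["ncasl"]] = INITIAL_STATE[_IDX["nca"]]
    y[_IDX["Jrelo"]] = 0.0
    y[_IDX["dp"]] = INITIAL_STATE[_IDX["d"]]
    return y


# ------------------------------------------------------------------
# parameter pack layout
# ------------------------------------------------------------------

P_WA, P_WB, P_WC, P_WD, P_WE, P_WF = 0, 1, 2, 3, 4, 5
P_PA, P_PB, P_PC, P_PD, P_PE, P_PF = 6, 7, 8, 9, 10, 11
P_CAMK_SL = 12          # constant CaMKII-phosphorylated fraction, surface LTCC
P_LTCC_AMP = 13         # PKA amplitude factor on LTCC (2.5)
P_TARGETS = 14          # PKA-phosphorylated fraction of the seven targets
P_IKS_MULT = 15
P_INA_MULT = 16
P_INAK_KNAI_MULT = 17
P_IKB_MULT = 18
P_RYR_MULT = 19
P_PLB_KM_MULT = 20
P_TNI_KM_MULT = 21
P_FTT = 22              # T-tubule integrity fraction
P_TAU_CASL = 23         # sub-sarcolemma <-> myoplasm diffusion tau (ms)
P_VSL_FRAC = 24         # sub-sarcolemmal volume fraction of cell volume
P_CLAMP = 25            # 1.0 -> membrane potential clamped (dV/dt = 0)
P_IST = 26              # applied stimulus current (uA/uF)
P_ZERO_CA = 27          # 1.0 -> all sarcolemmal Ca fluxes zeroed
P_AREL_ORPH = 28        # orphaned-RyR release gain (mM/ms)
P_KORPH = 29            # half-activation of orphaned release trigger (mM)
P_SL_ACTIVE = 30        # 1.0 -> sub-sarcolemmal pool exchanges with myoplasm
P_DSHIFT = 31           # hyperpolarizing activation shift of
                        # PKA-phosphorylated LTCCs (mV, >= 0)
N_PARAMS = 32


def baseline_params() -> np.ndarray:
    """Pack that reduces the extended model to unmodified ORd exactly.

    All channels in subgroup A, every phosphorylation fraction zero, all
    PKA effect multipliers identity, intact T-tubules, sub-sarcolemmal pool
    inactive.
    """
    p = np.zeros(N_PARAMS)
    p[P_WA] = 1.0
    p[P_LTCC_AMP] = 2.5
    p[P_IKS_MULT] = 1.0
    p[P_INA_MULT] = 1.0
    p[P_INAK_KNAI_MULT] = 1.0
    p[P_IKB_MULT] = 1.0
    p[P_RYR_MULT] = 1.0
    p[P_PLB_KM_MULT] = 1.0
    p[P_TNI_KM_MULT] = 1.0
    p[P_FTT] = 1.0
    p[P_TAU_CASL] = 0.177
    p[P_VSL_FRAC] = 0.02
    p[P_AREL_ORPH] = 4.0
    p[P_KORPH] = 9.0e-4
    p[P_SL_ACTIVE] = 0.0
    p[P_DSHIFT] = 0.0
    return p


# ------------------------------------------------------------------
# observables layout
# ------------------------------------------------------------------

OBS_NAMES = (
    "ICaL_tt", "ICaL_sl", "ICaL_total", "ICaL_ca_total",
    "INaCa", "Jrel_coupled", "Jrel_orphan", "Jrel",
    "cai", "cass", "casl", "cansr", "cajsr",
    "INa", "INaL", "Ito", "IKr", "IKs", "IK1", "INaK", "CaMKa", "v",
)
N_OBS = len(OBS_NAMES)
OBS_IDX = {name: k for k, name in enumerate(OBS_NAMES)}


@njit(cache=True)
def _ncx_core(v, vfrt, ca, na):
    """ORd NCX turnover for one membrane pool sensing (ca, na).

    Returns the current for unit Gncx weight (uA/uF per unit weight).
    """
    kna1 = 15.0
    kna2 = 5.0
    kna3 = 88.12
    kasymm = 12.5
    wna = 6.0e4
    wca = 6.0e4
    wnaca = 5.0e3
    kcaon = 1.5e6
    kcaoff = 5.0e3
    qna = 0.5224
    qca = 0.1670
    hca = np.exp(qca * vfrt)
    hna = np.exp(qna * vfrt)
    h1 = 1.0 + na / kna3 * (1.0 + hna)
    h2 = (na * hna) / (kna3 * h1)
    h3 = 1.0 / h1
    h4 = 1.0 + na / kna1 * (1.0 + na / kna2)
    h5 = na * na / (h4 * kna1 * kna2)
    h6 = 1.0 / h4
    h7 = 1.0 + NAO / kna3 * (1.0 + 1.0 / hna)
    h8 = NAO / (kna3 * hna * h7)
    h9 = 1.0 / h7
    h10 = kasymm + 1.0 + NAO / kna1 * (1.0 + NAO / kna2)
    h11 = NAO * NAO / (h10 * kna1 * kna2)
    h12 = 1.0 / h10
    k1 = h12 * CAO * kcaon
    k2 = kcaoff
    k3p = h9 * wca
    k3pp = h8 * wnaca
    k3 = k3p + k3pp
    k4p = h3 * wca / hca
    k4pp = h2 * wnaca
    k4 = k4p + k4pp
    k5 = kcaoff
    k6 = h6 * ca * kcaon
    k7 = h5 * h2 * wna
    k8 = h8 * h11 * wna
    x1 = k2 * k4 * (k7 + k6) + k5 * k7 * (k2 + k3)
    x2 = k1 * k7 * (k4 + k5) + k4 * k6 * (k1 + k8)
    x3 = k1 * k3 * (k7 + k6) + k8 * k6 * (k2 + k3)
    x4 = k2 * k8 * (k4 + k5) + k3 * k5 * (k1 + k8)
    s = x1 + x2 + x3 + x4
    E1 = x1 / s
    E2 = x2 / s
    E3 = x3 / s
    E4 = x4 / s
    KmCaAct = 150.0e-6
    allo = 1.0 / (1.0 + (KmCaAct / ca) ** 2)
    JncxNa = 3.0 * (E4 * k7 - E1 * k8) + E3 * k4pp - E2 * k3pp
    JncxCa = E2 * k2 - E1 * k1
    Gncx = 0.0008
    return Gncx * allo * (1.0 * JncxNa + 2.0 * JncxCa)


@njit(cache=True)
def _inak(v, vfrt, nai, ki, knai_mult):
    k1p = 949.5
    k1m = 182.4
    k2p = 687.2
    k2m = 39.4
    k3p = 1899.0
    k3m = 79300.0
    k4p = 639.0
    k4m = 40.0
    Knai0 = 9.073 * knai_mult
    Knao0 = 27.78
    delta = -0.1550
    Knai = Knai0 * np.exp(delta * vfrt / 3.0)
    Knao = Knao0 * np.exp((1.0 - delta) * vfrt / 3.0)
    Kki = 0.5
    Kko = 0.3582
    MgADP = 0.05
    MgATP = 9.8
    Kmgatp = 1.698e-7
    H = 1.0e-7
    eP = 4.2
    Khp = 1.698e-7
    Knap = 224.0
    Kxkur = 292.0
    P = eP / (1.0 + H / Khp + nai / Knap + ki / Kxkur)
    a1 = (k1p * (nai / Knai) ** 3) \
        / ((1.0 + nai / Knai) ** 3 + (1.0 + ki / Kki) ** 2 - 1.0)
    b1 = k1m * MgADP
    a2 = k2p
    b2 = (k2m * (NAO / Knao) ** 3) \
        / ((1.0 + NAO / Knao) ** 3 + (1.0 + KO / Kko) ** 2 - 1.0)
    a3 = (k3p * (KO / Kko) ** 2) \
        / ((1.0 + NAO / Knao) ** 3 + (1.0 + KO / Kko) ** 2 - 1.0)
    b3 = (k3m * P * H) / (1.0 + MgATP / Kmgatp)
    a4 = (k4p * MgATP / Kmgatp) / (1.0 + MgATP / Kmgatp)
    b4 = (k4m * (ki / Kki) ** 2) \
        / ((1.0 + nai / Knai) ** 3 + (1.0 + ki / Kki) ** 2 - 1.0)
    x1 = a4 * a1 * a2 + b2 * b4 * b3 + a2 * b4 * b3 + b3 * a1 * a2
    x2 = b2 * b1 * b4 + a1 * a2 * a3 + a3 * b1 * b4 + a2 * a3 * b4
    x3 = a2 * a3 * a4 + b3 * b2 * b1 + b2 * b1 * a4 + a3 * a4 * b1
    x4 = b4 * b3 * b2 + a3 * a4 * a1 + b2 * a4 * a1 + b3 * b2 * a1
    s = x1 + x2 + x3 + x4
    E1 = x1 / s
    E2 = x2 / s
    E3 = x3 / s
    E4 = x4 / s
    JnakNa = 3.0 * (E1 * a3 - E2 * b3)
    JnakK = 2.0 * (E4 * b1 - E3 * a1)
    Pnak = 30.0
    return Pnak * (JnakNa + JnakK)


@njit(cache=True)
def _eval(y, p):
    """Derivatives and observables of the extended model."""
    v = y[0]
    nai = y[1]
    nass = y[2]
    ki = y[3]
    kss = y[4]
    cai = y[5]
    cass = y[6]
    cansr = y[7]
    cajsr = y[8]
    m = y[9]
    hf = y[10]
    hs = y[11]
    j = y[12]
    hsp = y[13]
    jp = y[14]
    mL = y[15]
    hL = y[16]
    hLp = y[17]
    a = y[18]
    iF = y[19]
    iS = y[20]
    ap = y[21]
    iFp = y[22]
    iSp = y[23]
    d = y[24]
    ff = y[25]
    fs = y[26]
    fcaf = y[27]
    fcas = y[28]
    jca = y[29]
    nca = y[30]
    ffp = y[31]
    fcafp = y[32]
    xrf = y[33]
    xrs = y[34]
    xs1 = y[35]
    xs2 = y[36]
    xk1 = y[37]
    Jrelnp = y[38]
    Jrelp = y[39]
    CaMKt = y[40]
    casl = y[41]
    ncasl = y[42]
    Jrelo = y[43]
    dp = y[44]

    ist = p[P_IST]
    ftt = p[P_FTT]
    # dyads are lost with the T-tubules: the dyadic subspace volume
    # scales with f_TT so the remaining dyads keep their local geometry
    vss = VSS * max(ftt, 1.0e-3)
    pt = p[P_TARGETS]
    amp = p[P_LTCC_AMP]
    zero_ca = p[P_ZERO_CA] > 0.5
    sl_active = p[P_SL_ACTIVE] > 0.5
    vsl = p[P_VSL_FRAC] * VCELL

    frt = FDAY / (RGAS * TEMP)
    vfrt = v * frt
    vffrt = v * FDAY * frt

    # CaMKII (driven by dyadic Ca, as in baseline)
    KmCaMK = 0.15
    aCaMK = 0.05
    bCaMK = 0.00068
    CaMKo = 0.05
    KmCaM = 0.0015
    CaMKb = CaMKo * (1.0 - CaMKt) / (1.0 + KmCaM / cass)
    CaMKa = CaMKb + CaMKt
    dCaMKt = aCaMK * CaMKb * (CaMKb + CaMKt) - bCaMK * CaMKt

    ENa = (1.0 / frt) * np.log(NAO / nai)
    EK = (1.0 / frt) * np.log(KO / ki)
    PKNa = 0.01833
    EKs = (1.0 / frt) * np.log((KO + PKNa * NAO) / (ki + PKNa * nai))

    # INa (PKA population: conductance factor on the phosphorylated share)
    mss = 1.0 / (1.0 + np.exp(-(v + 39.57) / 9.871))
    tm = 1.0 / (6.765 * np.exp((v + 11.64) / 34.77)
                + 8.552 * np.exp(-(v + 77.42) / 5.955))
    dm = (mss - m) / tm
    hss = 1.0 / (1.0 + np.exp((v + 82.90) / 6.086))
    thf = 1.0 / (1.432e-5 * np.exp(-(v + 1.196) / 6.285)
                 + 6.149 * np.exp((v + 0.5096) / 20.27))
    ths = 1.0 / (0.009794 * np.exp(-(v + 17.95) / 28.05)
                 + 0.3343 * np.exp((v + 5.730) / 56.66))
    Ahf = 0.99
    Ahs = 1.0 - Ahf
    dhf = (hss - hf) / thf
    dhs = (hss - hs) / ths
    h = Ahf * hf + Ahs * hs
    jss = hss
    tj = 2.038 + 1.0 / (0.02136 * np.exp(-(v + 100.6) / 8.281)
                        + 0.3052 * np.exp((v + 0.9941) / 38.45))
    dj = (jss - j) / tj
    hssp = 1.0 / (1.0 + np.exp((v + 89.1) / 6.086))
    thsp = 3.0 * ths
    dhsp = (hssp - hsp) / thsp
    hp = Ahf * hf + Ahs * hsp
    tjp = 1.46 * tj
    djp = (jss - jp) / tjp
    GNa = 75.0
    fINap = 1.0 / (1.0 + KmCaMK / CaMKa)
    ina_pka = 1.0 - pt + pt * p[P_INA_MULT]
    INa = ina_pka * GNa * (v - ENa) * m ** 3 \
        * ((1.0 - fINap) * h * j + fINap * hp * jp)

    # INaL
    mLss = 1.0 / (1.0 + np.exp(-(v + 42.85) / 5.264))
    dmL = (mLss - mL) / tm
    hLss = 1.0 / (1.0 + np.exp((v + 87.61) / 7.488))
    thL = 200.0
    dhL = (hLss - hL) / thL
    hLssp = 1.0 / (1.0 + np.exp((v + 93.81) / 7.488))
    thLp = 3.0 * thL
    dhLp = (hLssp - hLp) / thLp
    GNaL = 0.0075
    fINaLp = 1.0 / (1.0 + KmCaMK / CaMKa)
    INaL = GNaL * (v - ENa) * mL * ((1.0 - fINaLp) * hL + fINaLp * hLp)

    # Ito
    ass = 1.0 / (1.0 + np.exp(-(v - 14.34) / 14.82))
    ta = 1.0515 / (1.0 / (1.2089 * (1.0 + np.exp(-(v - 18.41) / 29.38)))
                   + 3.5 / (1.0 + np.exp((v + 100.0) / 29.38)))
    da = (ass - a) / ta
    iss = 1.0 / (1.0 + np.exp((v + 43.94) / 5.711))
    tiF = 4.562 + 1.0 / (0.3933 * np.exp(-(v + 100.0) / 100.0)
                         + 0.08004 * np.exp((v + 50.0) / 16.59))
    tiS = 23.62 + 1.0 / (0.001416 * np.exp(-(v + 96.52) / 59.05)
                         + 1.780e-8 * np.exp((v + 114.1) / 8.079))
    AiF = 1.0 / (1.0 + np.exp((v - 213.6) / 151.2))
    AiS = 1.0 - AiF
    diF = (iss - iF) / tiF
    diS = (iss - iS) / tiS
    i_gate = AiF * iF + AiS * iS
    assp = 1.0 / (1.0 + np.exp(-(v - 24.34) / 14.82))
    dap = (assp - ap) / ta
    dti_develop = 1.354 + 1.0e-4 / (np.exp((v - 167.4) / 15.89)
                                    + np.exp(-(v - 12.23) / 0.2154))
    dti_recover = 1.0 - 0.5 / (1.0 + np.exp((v + 70.0) / 20.0))
    tiFp = dti_develop * dti_recover * tiF
    tiSp = dti_develop * dti_recover * tiS
    diFp = (iss - iFp) / tiFp
    diSp = (iss - iSp) / tiSp
    ip = AiF * iFp + AiS * iSp
    Gto = 0.02
    fItop = 1.0 / (1.0 + KmCaMK / CaMKa)
    Ito = Gto * (v - EK) * ((1.0 - fItop) * a * i_gate + fItop * ap * ip)

    # ------------------------------------------------------------------
    # LTCC subpopulations
    # ------------------------------------------------------------------
    dss = 1.0 / (1.0 + np.exp(-(v + 3.940) / 4.230))
    td = 0.6 + 1.0 / (np.exp(-0.05 * (v + 6.0)) + np.exp(0.09 * (v + 14.0)))
    dd = (dss - d) / td
    # PKA-phosphorylated channels: activation shifted to more negative
    # potentials (classic beta-adrenergic effect on the L-type channel)
    vp = v + p[P_DSHIFT]
    dss_p = 1.0 / (1.0 + np.exp(-(vp + 3.940) / 4.230))
    td_p = 0.6 + 1.0 / (np.exp(-0.05 * (vp + 6.0)) + np.exp(0.09 * (vp + 14.0)))
    ddp = (dss_p - dp) / td_p
    fss = 1.0 / (1.0 + np.exp((v + 19.58) / 3.696))
    tff = 7.0 + 1.0 / (0.0045 * np.exp(-(v + 20.0) / 10.0)
                       + 0.0045 * np.exp((v + 20.0) / 10.0))
    tfs = 1000.0 + 1.0 / (0.000035 * np.exp(-(v + 5.0) / 4.0)
                          + 0.000035 * np.exp((v + 5.0) / 6.0))
    Aff = 0.6
    Afs = 1.0 - Aff
    dff = (fss - ff) / tff
    dfs = (fss - fs) / tfs
    f = Aff * ff + Afs * fs
    fcass = fss
    tfcaf = 7.0 + 1.0 / (0.04 * np.exp(-(v - 4.0) / 7.0)
                         + 0.04 * np.exp((v - 4.0) / 7.0))
    tfcas = 100.0 + 1.0 / (0.00012 * np.exp(-v / 3.0)
                           + 0.00012 * np.exp(v / 7.0))
    Afcaf = 0.3 + 0.6 / (1.0 + np.exp((v - 10.0) / 10.0))
    Afcas = 1.0 - Afcaf
    dfcaf = (fcass - fcaf) / tfcaf
    dfcas = (fcass - fcas) / tfcas
    fca = Afcaf * fcaf + Afcas * fcas
    tjca = 75.0
    djca = (fcass - jca) / tjca
    tffp = 2.5 * tff
    dffp = (fss - ffp) / tffp
    fp = Aff * ffp + Afs * fs
    tfcafp = 2.5 * tfcaf
    dfcafp = (fcass - fcafp) / tfcafp
    fcap = Afcaf * fcafp + Afcas * fcas
    Kmn = 0.002
    k2n = 1000.0
    km2n = jca * 1.0
    if km2n < 1.0e-12:      # guard: jca pinned to 0 in edge-case analyses
        km2n = 1.0e-12
    anca = 1.0 / (k2n / km2n + (1.0 + Kmn / cass) ** 4)
    dnca = anca * k2n - nca * km2n
    # surface channels: CaM-mode exit rate fixed at its diastolic value so
    # that mode occupancy is governed by the sensed (sub-sarcolemmal) Ca
    # rather than by the dyad-calibrated voltage coupling through jca
    km2n_sl = 0.2
    anca_sl = 1.0 / (k2n / km2n_sl + (1.0 + Kmn / casl) ** 4)
    dncasl = anca_sl * k2n - ncasl * km2n_sl

    expv2 = np.exp(2.0 * vfrt)
    expv1 = np.exp(vfrt)
    PhiCaL_ss = 4.0 * vffrt * (cass * expv2 - 0.341 * CAO) / (expv2 - 1.0)
    PhiCaL_sl = 4.0 * vffrt * (casl * expv2 - 0.341 * CAO) / (expv2 - 1.0)
    PhiCaNa_ss = vffrt * (0.75 * nass * expv1 - 0.75 * NAO) / (expv1 - 1.0)
    PhiCaNa_i = vffrt * (0.75 * nai * expv1 - 0.75 * NAO) / (expv1 - 1.0)
    PhiCaK_ss = vffrt * (0.75 * kss * expv1 - 0.75 * KO) / (expv1 - 1.0)
    PhiCaK_i = vffrt * (0.75 * ki * expv1 - 0.75 * KO) / (expv1 - 1.0)

    PCa = 0.0001
    PCap = 1.1 * PCa
    PCaNa = 0.00125 * PCa
    PCaK = 3.574e-4 * PCa
    PCaNap = 0.00125 * PCap
    PCaKp = 3.574e-4 * PCap

    # open-channel gating terms: per activation gate (d: unphosphorylated,
    # dp: PKA-phosphorylated), non-CaMK and CaMK-phosphorylated branches
    h_np_ss = f * (1.0 - nca) + jca * fca * nca
    h_p_ss = fp * (1.0 - nca) + jca * fcap * nca
    h_np_sl = f * (1.0 - ncasl) + jca * fca * ncasl
    h_p_sl = fp * (1.0 - ncasl) + jca * fcap * ncasl

    # subgroup weights split by PKA state
    w_np_tt = (p[P_WA] * (1.0 - p[P_PA]) + p[P_WB] * (1.0 - p[P_PB])
               + p[P_WC] * (1.0 - p[P_PC]))
    w_pka_tt = p[P_WA] * p[P_PA] + p[P_WB] * p[P_PB] + p[P_WC] * p[P_PC]
    w_np_sl = (p[P_WD] * (1.0 - p[P_PD]) + p[P_WE] * (1.0 - p[P_PE])
               + p[P_WF] * (1.0 - p[P_PF]))
    w_pka_sl = p[P_WD] * p[P_PD] + p[P_WE] * p[P_PE] + p[P_WF] * p[P_PF]

    # T-tubular channels: baseline dynamic CaMKII split
    fICaLp = 1.0 / (1.0 + KmCaMK / CaMKa)
    gate_tt = (w_np_tt * d + amp * w_pka_tt * dp)
    k_tt = (1.0 - fICaLp) * PCa * h_np_ss + fICaLp * PCap * h_p_ss
    k_tt_na = (1.0 - fICaLp) * PCaNa * h_np_ss + fICaLp * PCaNap * h_p_ss
    k_tt_k = (1.0 - fICaLp) * PCaK * h_np_ss + fICaLp * PCaKp * h_p_ss
    ical_ca_tt = gate_tt * PhiCaL_ss * k_tt
    ical_na_tt = gate_tt * PhiCaNa_ss * k_tt_na
    ical_k_tt = gate_tt * PhiCaK_ss * k_tt_k

    # surface channels: constant CaMKII-phosphorylated fraction
    c_sl = p[P_CAMK_SL]
    gate_sl = (w_np_sl * d + amp * w_pka_sl * dp)
    k_sl = (1.0 - c_sl) * PCa * h_np_sl + c_sl * PCap * h_p_sl
    k_sl_na = (1.0 - c_sl) * PCaNa * h_np_sl + c_sl * PCaNap * h_p_sl
    k_sl_k = (1.0 - c_sl) * PCaK * h_np_sl + c_sl * PCaKp * h_p_sl
    ical_ca_sl = gate_sl * PhiCaL_sl * k_sl
    ical_na_sl = gate_sl * PhiCaNa_i * k_sl_na
    ical_k_sl = gate_sl * PhiCaK_i * k_sl_k

    if zero_ca:
        ical_ca_tt = 0.0
        ical_ca_sl = 0.0

    # IKr
    xrss = 1.0 / (1.0 + np.exp(-(v + 8.337) / 6.789))
    txrf = 12.98 + 1.0 / (0.3652 * np.exp((v - 31.66) / 3.869)
                          + 4.123e-5 * np.exp(-(v - 47.78) / 20.38))
    txrs = 1.865 + 1.0 / (0.06629 * np.exp((v - 34.70) / 7.355)
                          + 1.128e-5 * np.exp(-(v - 29.74) / 25.94))
    Axrf = 1.0 / (1.0 + np.exp((v + 54.81) / 38.21))
    Axrs = 1.0 - Axrf
    dxrf = (xrss - xrf) / txrf
    dxrs = (xrss - xrs) / txrs
    xr = Axrf * xrf + Axrs * xrs
    rkr = 1.0 / (1.0 + np.exp((v + 55.0) / 75.0)) \
        * 1.0 / (1.0 + np.exp((v - 10.0) / 30.0))
    GKr = 0.046
    IKr = GKr * np.sqrt(KO / 5.4) * xr * rkr * (v - EK)

    # IKs (PKA population: conductance factor)
    xs1ss = 1.0 / (1.0 + np.exp(-(v + 11.60) / 8.932))
    txs1 = 817.3 + 1.0 / (2.326e-4 * np.exp((v + 48.28) / 17.80)
                          + 0.001292 * np.exp(-(v + 210.0) / 230.0))
    dxs1 = (xs1ss - xs1) / txs1
    xs2ss = xs1ss
    txs2 = 1.0 / (0.01 * np.exp((v - 50.0) / 20.0)
                  + 0.0193 * np.exp(-(v + 66.54) / 31.0))
    dxs2 = (xs2ss - xs2) / txs2
    KsCa = 1.0 + 0.6 / (1.0 + (3.8e-5 / cai) ** 1.4)
    GKs = 0.0034
    iks_pka = 1.0 - pt + pt * p[P_IKS_MULT]
    IKs = iks_pka * GKs * KsCa * xs1 * xs2 * (v - EKs)

    # IK1
    xk1ss = 1.0 / (1.0 + np.exp(-(v + 2.5538 * KO + 144.59)
                                / (1.5692 * KO + 3.8115)))
    txk1 = 122.2 / (np.exp(-(v + 127.2) / 20.36) + np.exp((v + 236.8) / 69.33))
    dxk1 = (xk1ss - xk1) / txk1
    rk1 = 1.0 / (1.0 + np.exp((v + 105.8 - 2.6 * KO) / 9.493))
    GK1 = 0.1908
    IK1 = GK1 * np.sqrt(KO) * rk1 * xk1 * (v - EK)

    # NCX pools: intact T-tubular organization keeps the baseline myoplasmic
    # and junctional components; the redistributed share senses casl
    INaCa_i = 0.8 * ftt * _ncx_core(v, vfrt, cai, nai)
    INaCa_ss = 0.2 * ftt * _ncx_core(v, vfrt, cass, nass)
    INaCa_sl = (1.0 - ftt) * _ncx_core(v, vfrt, casl, nai)
    if zero_ca:
        INaCa_i = 0.0
        INaCa_ss = 0.0
        INaCa_sl = 0.0

    # INaK (PKA population: Na-affinity shift on the phosphorylated share)
    INaK = (1.0 - pt) * _inak(v, vfrt, nai, ki, 1.0) \
        + pt * _inak(v, vfrt, nai, ki, p[P_INAK_KNAI_MULT])

    # background / pump currents
    xkb = 1.0 / (1.0 + np.exp(-(v - 14.48) / 18.34))
    GKb = 0.003
    ikb_pka = 1.0 - pt + pt * p[P_IKB_MULT]
    IKb = ikb_pka * GKb * xkb * (v - EK)
    PNab = 3.75e-10
    INab = PNab * vffrt * (nai * expv1 - NAO) / (expv1 - 1.0)
    PCab = 2.5e-8
    ICab = PCab * 4.0 * vffrt * (cai * expv2 - 0.341 * CAO) / (expv2 - 1.0)
    GpCa = 0.0005
    IpCa = GpCa * cai / (0.0005 + cai)
    if zero_ca:
        ICab = 0.0
        IpCa = 0.0

    # diffusion fluxes
    JdiffNa = (nass - nai) / 2.0
    JdiffK = (kss - ki) / 2.0
    Jdiff = (cass - cai) / 0.2
    Jdiffsl = (casl - cai) / p[P_TAU_CASL]

    # SR release: coupled RyRs triggered by the T-tubular (dyadic) LTCC Ca
    # current; orphaned RyRs by bulk cytosolic Ca
    ryr_pka = 1.0 - pt + pt * p[P_RYR_MULT]
    bt_rel = 4.75
    a_rel = 0.5 * bt_rel
    jsr_gate = 1.0 / (1.0 + (1.5 / cajsr) ** 8)
    Jrel_inf = ryr_pka * a_rel * (-ical_ca_tt) * jsr_gate
    tau_rel = bt_rel / (1.0 + 0.0123 / cajsr)
    if tau_rel < 0.001:
        tau_rel = 0.001
    dJrelnp = (Jrel_inf - Jrelnp) / tau_rel
    btp = 1.25 * bt_rel
    a_relp = 0.5 * btp
    Jrel_infp = ryr_pka * a_relp * (-ical_ca_tt) * jsr_gate
    tau_relp = btp / (1.0 + 0.0123 / cajsr)
    if tau_relp < 0.001:
        tau_relp = 0.001
    dJrelp = (Jrel_infp - Jrelp) / tau_relp
    fJrelp = 1.0 / (1.0 + KmCaMK / CaMKa)
    Jrel_c = (1.0 - fJrelp) * Jrelnp + fJrelp * Jrelp

    Korph = p[P_KORPH]
    # orphaned RyRs: regenerative CICR triggered by the bulk cytosolic Ca
    # transient (steep activation keeps the diastolic leak negligible)
    ca_ratio = (cai / Korph) ** 4
    Jrelo_inf = (1.0 - ftt) * p[P_AREL_ORPH] * ryr_pka * jsr_gate \
        * (ca_ratio / (1.0 + ca_ratio))
    dJrelo = (Jrelo_inf - Jrelo) / tau_rel

    # SR uptake: PKA population on phospholamban (SERCA Km)
    km_up = 0.00092
    km_up_p = km_up * p[P_PLB_KM_MULT]
    fJupp = 1.0 / (1.0 + KmCaMK / CaMKa)
    Jup_b = (1.0 - fJupp) * 0.004375 * cai / (cai + km_up) \
        + fJupp * 2.75 * 0.004375 * cai / (cai + km_up - 0.00017)
    Jup_pka = (1.0 - fJupp) * 0.004375 * cai / (cai + km_up_p) \
        + fJupp * 2.75 * 0.004375 * cai / (cai + km_up_p - 0.00017)
    Jleak = 0.0039375 * cansr / 15.0
    Jup = (1.0 - pt) * Jup_b + pt * Jup_pka - Jleak
    Jtr = (cansr - cajsr) / 100.0

    # buffers (TnI: PKA population on troponin Ca affinity)
    cmdnmax = 0.05
    kmcmdn = 0.00238
    trpnmax = 0.07
    kmtrpn = 0.0005
    kmtrpn_p = kmtrpn * p[P_TNI_KM_MULT]
    BSRmax = 0.047
    KmBSR = 0.00087
    BSLmax = 1.124
    KmBSL = 0.0087
    csqnmax = 10.0
    kmcsqn = 0.8

    ICaL_full_tt = ical_ca_tt + ical_na_tt + ical_k_tt
    ICaL_full_sl = ical_ca_sl + ical_na_sl + ical_k_sl
    INaCa_total = INaCa_i + INaCa_ss + INaCa_sl

    dv = -(INa + INaL + Ito + ICaL_full_tt + ICaL_full_sl + IKr + IKs + IK1
           + INaCa_total + INaK + INab + IKb + IpCa + ICab + ist)
    if p[P_CLAMP] > 0.5:
        dv = 0.0

    dnai = -(INa + INaL + 3.0 * INaCa_i + 3.0 * INaCa_sl + 3.0 * INaK
             + INab + ical_na_sl) * ACAP / (FDAY * VMYO) \
        + JdiffNa * vss / VMYO
    dnass = -(ical_na_tt + 3.0 * INaCa_ss) * ACAP / (FDAY * vss) - JdiffNa
    dki = -(Ito + IKr + IKs + IK1 + IKb + ist - 2.0 * INaK + ical_k_sl) \
        * ACAP / (FDAY * VMYO) + JdiffK * vss / VMYO
    dkss = -ical_k_tt * ACAP / (FDAY * vss) - JdiffK

    trpn_term = (1.0 - pt) * trpnmax * kmtrpn / (kmtrpn + cai) ** 2 \
        + pt * trpnmax * kmtrpn_p / (kmtrpn_p + cai) ** 2
    Bcai = 1.0 / (1.0 + cmdnmax * kmcmdn / (kmcmdn + cai) ** 2 + trpn_term)
    dcai_flux = -(IpCa + ICab - 2.0 * INaCa_i) * ACAP / (2.0 * FDAY * VMYO) \
        - Jup * VNSR / VMYO + Jdiff * vss / VMYO + Jrelo * VJSR / VMYO
    if sl_active:
        dcai_flux += Jdiffsl * vsl / VMYO
    dcai = Bcai * dcai_flux

    Bcass = 1.0 / (1.0 + BSRmax * KmBSR / (KmBSR + cass) ** 2
                   + BSLmax * KmBSL / (KmBSL + cass) ** 2)
    dcass = Bcass * (-(ical_ca_tt - 2.0 * INaCa_ss) * ACAP / (2.0 * FDAY * vss)
                     + Jrel_c * VJSR / vss - Jdiff)

    Bcasl = 1.0 / (1.0 + BSRmax * KmBSR / (KmBSR + casl) ** 2
                   + BSLmax * KmBSL / (KmBSL + casl) ** 2)
    if sl_active:
        dcasl = Bcasl * (-(ical_ca_sl - 2.0 * INaCa_sl) * ACAP
                         / (2.0 * FDAY * vsl) - Jdiffsl)
    else:
        # pool not distinguished from bulk myoplasm: track cai passively
        dcasl = -(casl - cai) / p[P_TAU_CASL]

    dcansr = Jup - Jtr * VJSR / VNSR
    Bcajsr = 1.0 / (1.0 + csqnmax * kmcsqn / (kmcsqn + cajsr) ** 2)
    dcajsr = Bcajsr * (Jtr - Jrel_c - Jrelo)

    dy = np.empty(N_STATES)
    dy[0] = dv
    dy[1] = dnai
    dy[2] = dnass
    dy[3] = dki
    dy[4] = dkss
    dy[5] = dcai
    dy[6] = dcass
    dy[7] = dcansr
    dy[8] = dcajsr
    dy[9] = dm
    dy[10] = dhf
    dy[11] = dhs
    dy[12] = dj
    dy[13] = dhsp
    dy[14] = djp
    dy[15] = dmL
    dy[16] = dhL
    dy[17] = dhLp
    dy[18] = da
    dy[19] = diF
    dy[20] = diS
    dy[21] = dap
    dy[22] = diFp
    dy[23] = diSp
    dy[24] = dd
    dy[25] = dff
    dy[26] = dfs
    dy[27] = dfcaf
    dy[28] = dfcas
    dy[29] = djca
    dy[30] = dnca
    dy[31] = dffp
    dy[32] = dfcafp
    dy[33] = dxrf
    dy[34] = dxrs
    dy[35] = dxs1
    dy[36] = dxs2
    dy[37] = dxk1
    dy[38] = dJrelnp
    dy[39] = dJrelp
    dy[40] = dCaMKt
    dy[41] = dcasl
    dy[42] = dncasl
    dy[43] = dJrelo
    dy[44] = ddp

    obs = np.empty(N_OBS)
    obs[0] = ICaL_full_tt
    obs[1] = ICaL_full_sl
    obs[2] = ICaL_full_tt + ICaL_full_sl
    obs[3] = ical_ca_tt + ical_ca_sl
    obs[4] = INaCa_total
    obs[5] = Jrel_c
    obs[6] = Jrelo
    obs[7] = Jrel_c + Jrelo
    obs[8] = cai
    obs[9] = cass
    obs[10] = casl
    obs[11] = cansr
    obs[12] = cajsr
    obs[13] = INa
    obs[14] = INaL
    obs[15] = Ito
    obs[16] = IKr
    obs[17] = IKs
    obs[18] = IK1
    obs[19] = INaK
    obs[20] = CaMKa
    obs[21] = v
    return dy, obs


@njit(cache=True)
def rhs_ext(y, p):
    dy, _ = _eval(y, p)
    return dy


@njit(cache=True)
def observables_ext(y, p):
    _, obs = _eval(y, p)
    return obs


# ------------------------------------------------------------------
# public domain types and operations
# ------------------------------------------------------------------

@dataclass(frozen=True)
class CellGeometry:
    """Volume partitions (fractions of cell volume) and membrane areas."""

    v_myo_frac: float = 0.68
    v_nsr_frac: float = 0.0552
    v_jsr_frac: float = 0.0048
    v_ss_frac: float = 0.02
    v_sl_frac: float = 0.02
    capacitance_per_area: float = 1.0   # uF/cm^2
    cell_volume_uL: float = VCELL
    a_cap_cm2: float = ACAP

    def __post_init__(self):
        for name in ("v_myo_frac", "v_nsr_frac", "v_jsr_frac", "v_ss_frac",
                     "v_sl_frac"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.v_ss_frac >= self.v_myo_frac or self.v_sl_frac >= self.v_myo_frac:
            raise ValueError(
                "dyadic and sub-sarcolemmal fractions must be much smaller "
                "than the myoplasmic fraction")


@dataclass(frozen=True)
class StimulusProtocol:
    """Current-clamp pacing protocol."""

    cycle_length_ms: float = 1000.0
    amplitude: float = -80.0        # uA/uF
    duration_ms: float = 0.5
    conditioning_beats: int = 1000  # cap; pacing stops early at steady state
    recorded_beats: int = 3

    def __post_init__(self):
        if not self.cycle_length_ms > self.duration_ms > 0:
            raise ValueError("need cycle length > stimulus duration > 0")
        if self.recorded_beats < 1 or self.conditioning_beats < 0:
            raise ValueError("beat counts must be non-negative (>=1 recorded)")


class MembraneState:
    """Named view over the extended state vector.

    Attribute access maps to entries of :data:`EXT_STATE_NAMES`; the raw
    vector is available as ``.y``.
    """

    __slots__ = ("y",)

    def __init__(self, y: np.ndarray | None = None):
        object.__setattr__(self, "y", initial_state() if y is None
                           else np.asarray(y, dtype=float).copy())
        if self.y.shape != (N_STATES,):
            raise ValueError(f"state vector must have length {N_STATES}")

    def __getattr__(self, name):
        try:
            return self.y[_IDX[name]]
        except KeyError:
            raise AttributeError(name) from None

    def __setattr__(self, name, value):
        if name in _IDX:
            self.y[_IDX[name]] = value
        else:
            raise AttributeError(name)

    def validate(self) -> None:
        """Raise ``ValueError`` naming the first field violating invariants."""
        for k, name in enumerate(EXT_STATE_NAMES):
            val = self.y[k]
            if not np.isfinite(val):
                raise ValueError(f"non-finite state entry: {name} = {val}")
        for name in GATE_NAMES:
            val = self.y[_IDX[name]]
            if not (-1e-9 <= val <= 1.0 + 1e-9):
                raise ValueError(f"gate {name} = {val} outside [0, 1]")
        for name in CONCENTRATION_NAMES:
            val = self.y[_IDX[name]]
            if val <= 0:
                raise ValueError(f"concentration {name} = {val} must be > 0")
        if not (-150.0 <= self.y[0] <= 80.0):
            raise ValueError(f"membrane potential v = {self.y[0]} mV outside "
                             "[-150, 80] mV")


def compute_rhs(state, t: float, stim: float, params: np.ndarray) -> np.ndarray:
    """Validated time derivative of the full state.

    ``state`` may be a :class:`MembraneState` or a raw vector; ``t`` is
    accepted for interface completeness (the model is autonomous apart from
    the externally scheduled stimulus ``stim``, uA/uF).
    """
    ms = state if isinstance(state, MembraneState) else MembraneState(state)
    ms.validate()
    p = np.asarray(params, dtype=float).copy()
    p[P_IST] = stim
    dy = rhs_ext(ms.y, p)
    if not np.all(np.isfinite(dy)):
        bad = EXT_STATE_NAMES[int(np.argmax(~np.isfinite(dy)))]
        raise FloatingPointError(f"non-finite derivative for state {bad}")
    return dy


def total_calcium(y: np.ndarray, p: np.ndarray) -> float:
    """Total cell Ca content (free + buffered, volume-weighted; nmol-scale
    units of mM*uL) over all compartments.

    Used by the conservation checks: with all sarcolemmal Ca fluxes zeroed
    this quantity is an invariant of the dynamics.
    """
    cai = y[_IDX["cai"]]
    cass = y[_IDX["cass"]]
    casl = y[_IDX["casl"]]
    cansr = y[_IDX["cansr"]]
    cajsr = y[_IDX["cajsr"]]
    pt = p[P_TARGETS]
    vsl = p[P_VSL_FRAC] * VCELL
    vss = VSS * max(p[P_FTT], 1.0e-3)

    cmdn = 0.05 * cai / (cai + 0.00238)
    kmtrpn = 0.0005
    kmtrpn_p = kmtrpn * p[P_TNI_KM_MULT]
    trpn = (1.0 - pt) * 0.07 * cai / (cai + kmtrpn) \
        + pt * 0.07 * cai / (cai + kmtrpn_p)

    def _bsr_bsl(ca):
        return 0.047 * ca / (ca + 0.00087) + 1.124 * ca / (ca + 0.0087)

    csqn = 10.0 * cajsr / (cajsr + 0.8)

    total = VMYO * (cai + cmdn + trpn) \
        + vss * (cass + _bsr_bsl(cass)) \
        + VNSR * cansr \
        + VJSR * (cajsr + csqn)
    if p[P_SL_ACTIVE] > 0.5:
        total += vsl * (casl + _bsr_bsl(casl))
    return total
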