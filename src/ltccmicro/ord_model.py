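"""Baseline human ventricular ionic model with microdomain-partitioned I_CaL.

The electrophysiology is the O'Hara–Rudy human ventricular formulation
(endo/epi variants), re-implemented from its public description, with one
structural change: the L-type Ca2+ current is split into two channel
populations,

- a **T-tubular (TT) population** (fraction ``f_tt`` of channels) facing
  the dyadic subspace — strong Ca-dependent inactivation, feeds ``ca_ss``
  and drives SR release;
- a **crest population** (fraction ``1 − f_tt``) on the surface
  sarcolemma facing bulk cytosolic Ca — weak Ca-dependent inactivation,
  feeds ``ca_i`` directly.

Disease knobs: ``ttd`` (T-tubule integrity, multiplies the TT-population
conductance), ``pka_fraction`` of TT channels with PKA-phosphorylated
gating (2.5x current, hyperpolarized activation/inactivation, slowed
voltage inactivation), ``camkii_crest`` fraction of crest channels locked
into the model's CaMKII-phosphorylated I_CaL gating, a whole-cell
``correction`` factor on I_CaL, and named scalings of the non-LTCC
currents for heart-failure remodeling.

Units: ms, mV, mM, µA/µF.  The integrator is fixed-step with
Rush-Larsen exponential updates for gating variables and forward Euler
for concentrations and voltage — the standard scheme for this model
family.
"""

from __future__ import annotations

import math

import numpy as np
from numba import njit

__all__ = [
    "N_STATES",
    "N_PARAMS",
    "default_params",
    "initial_state",
    "integrate",
    "P",
]

N_STATES = 48

# state indices
(IV, INAI, INASS, IKI, IKSS, ICAI, ICASS, ICANSR, ICAJSR,
 IM, IHF, IHS, IJ, IHSP, IJP, IML, IHL, IHLP,
 IA, IIF, IIS, IAP, IIFP, IISP,
 ID, IFF, IFS, IFCAF, IFCAS, IJCA, INCA, IFFP, IFCAFP,
 IXRF, IXRS, IXS1, IXS2, IXK1, IJRELNP, IJRELP, ICAMKT,
 IDPKA, IFFPKA, IFSPKA, INCAI, IFCAFPKA, IJCAPKA, IDCAMK) = range(N_STATES)


class P:
    """Parameter-vector indices."""

    CELLTYPE = 0  # 0 endo, 1 epi
    F_TT = 1
    TTD = 2
    PKA_FRACTION = 3
    CAMKII_CREST = 4
    PKA_CURRENT_FACTOR = 5
    CORRECTION = 6
    PKA_ACT_SHIFT = 7
    PKA_INACT_SHIFT = 8
    PKA_TAU_FACTOR = 9
    SERCA_SCALE = 10
    NCX_SCALE = 11
    GK1_SCALE = 12
    GTO_SCALE = 13
    GNAL_SCALE = 14
    GKR_SCALE = 15
    GKS_SCALE = 16
    PCA_SCALE = 17
    JREL_SCALE = 18
    CAMK_ACT_SHIFT = 19



# module-level aliases usable inside numba kernels
_CELLTYPE = P.CELLTYPE
_F_TT = P.F_TT
_TTD = P.TTD
_PKA_FRACTION = P.PKA_FRACTION
_CAMKII_CREST = P.CAMKII_CREST
_PKA_CURRENT_FACTOR = P.PKA_CURRENT_FACTOR
_CORRECTION = P.CORRECTION
_PKA_ACT_SHIFT = P.PKA_ACT_SHIFT
_PKA_INACT_SHIFT = P.PKA_INACT_SHIFT
_PKA_TAU_FACTOR = P.PKA_TAU_FACTOR
_SERCA_SCALE = P.SERCA_SCALE
_NCX_SCALE = P.NCX_SCALE
_GK1_SCALE = P.GK1_SCALE
_GTO_SCALE = P.GTO_SCALE
_GNAL_SCALE = P.GNAL_SCALE
_GKR_SCALE = P.GKR_SCALE
_GKS_SCALE = P.GKS_SCALE
_PCA_SCALE = P.PCA_SCALE
_JREL_SCALE = P.JREL_SCALE
_CAMK_ACT_SHIFT = P.CAMK_ACT_SHIFT

N_PARAMS = 20


def default_params(celltype: str = "endo") -> np.ndarray:
    """Healthy control parameter vector (all scalings 1)."""
    p = np.ones(N_PARAMS)
    p[_CELLTYPE] = {"endo": 0.0, "epi": 1.0}[celltype]
    p[_F_TT] = (25.8 / 10.3) / (1.0 + 25.8 / 10.3)  # control TT fraction from the occurrence ratio
    p[_TTD] = 1.0
    p[_PKA_FRACTION] = 0.0
    p[_CAMKII_CREST] = 0.0
    p[_PKA_CURRENT_FACTOR] = 2.5
    p[_CORRECTION] = 1.0
    p[_PKA_ACT_SHIFT] = -8.0
    p[_PKA_INACT_SHIFT] = -8.0
    p[_PKA_TAU_FACTOR] = 1.3
    p[_CAMK_ACT_SHIFT] = -6.0
    return p


def initial_state() -> np.ndarray:
    """Resting-state initial conditions (refined by pre-pacing)."""
    y = np.zeros(N_STATES)
    y[IV] = -87.5
    y[INAI] = 7.268
    y[INASS] = 7.268
    y[IKI] = 144.65
    y[IKSS] = 144.65
    y[ICAI] = 8.6e-5
    y[ICASS] = 8.49e-5
    y[ICANSR] = 1.61
    y[ICAJSR] = 1.56
    y[IM] = 0.00746
    y[IHF] = 0.6926
    y[IHS] = 0.6926
    y[IJ] = 0.6925
    y[IHSP] = 0.4485
    y[IJP] = 0.6924
    y[IML] = 0.000194
    y[IHL] = 0.4961
    y[IHLP] = 0.2659
    y[IA] = 0.001012
    y[IIF] = 0.9995
    y[IIS] = 0.5896
    y[IAP] = 0.000516
    y[IIFP] = 0.9995
    y[IISP] = 0.6419
    y[ID] = 2.43e-9
    y[IFF] = 1.0
    y[IFS] = 0.9107
    y[IFCAF] = 1.0
    y[IFCAS] = 0.9998
    y[IJCA] = 1.0
    y[INCA] = 0.00275
    y[IFFP] = 1.0
    y[IFCAFP] = 1.0
    y[IXRF] = 8.26e-6
    y[IXRS] = 0.4537
    y[IXS1] = 0.2705
    y[IXS2] = 0.000196
    y[IXK1] = 0.9968
    y[IJRELNP] = 2.5e-7
    y[IJRELP] = 3.12e-7
    y[ICAMKT] = 0.0124
    y[IDPKA] = 2.43e-9
    y[IFFPKA] = 1.0
    y[IFSPKA] = 0.9107
    y[INCAI] = 0.0
    y[IFCAFPKA] = 1.0
    y[IJCAPKA] = 1.0
    y[IDCAMK] = 2.43e-9
    return y


@njit(cache=True)
def _rl(x, ss, tau, dt):  # pragma: no cover - numba
    return ss - (ss - x) * math.exp(-dt / tau)


@njit(cache=True)
def _step(y, p, dt, istim, clamp, v_forced):  # pragma: no cover - numba
    """Advance the state one step of ``dt`` ms.  Returns I_CaL components
    (total Ca-carried current through LTCC per domain, µA/µF)."""
    # physical constants and geometry
    nao = 140.0
    cao = 1.8
    ko = 5.4
    R = 8314.0
    T = 310.0
    F = 96485.0
    L = 0.01
    rad = 0.0011
    vcell = 1000.0 * 3.14 * rad * rad * L
    Ageo = 2.0 * 3.14 * rad * rad + 2.0 * 3.14 * rad * L
    Acap = 2.0 * Ageo
    vmyo = 0.68 * vcell
    vnsr = 0.0552 * vcell
    vjsr = 0.0048 * vcell
    vss = 0.02 * vcell

    epi = p[_CELLTYPE] == 1.0

    if clamp:
        y[IV] = v_forced
    v = y[IV]
    nai = y[INAI]
    nass = y[INASS]
    ki = y[IKI]
    kss = y[IKSS]
    cai = y[ICAI]
    cass = y[ICASS]
    cansr = y[ICANSR]
    cajsr = y[ICAJSR]

    vfrt = v * F / (R * T)
    vffrt = v * F * F / (R * T)

    ENa = (R * T / F) * math.log(nao / nai)
    EK = (R * T / F) * math.log(ko / ki)
    PKNa = 0.01833
    EKs = (R * T / F) * math.log((ko + PKNa * nao) / (ki + PKNa * nai))

    # CaMK
    KmCaMK = 0.15
    aCaMK = 0.05
    bCaMK = 0.00068
    CaMKo = 0.05
    KmCaM = 0.0015
    CaMKb = CaMKo * (1.0 - y[ICAMKT]) / (1.0 + KmCaM / cass)
    CaMKa = CaMKb + y[ICAMKT]
    dCaMKt = aCaMK * CaMKb * (CaMKb + y[ICAMKT]) - bCaMK * y[ICAMKT]
    fphos = 1.0 / (1.0 + KmCaMK / CaMKa)  # CaMK-phosphorylated fraction

    # ------------------------------------------------------------------ INa
    mss = 1.0 / (1.0 + math.exp(-(v + 39.57) / 9.871))
    tm = 1.0 / (6.765 * math.exp((v + 11.64) / 34.77) + 8.552 * math.exp(-(v + 77.42) / 5.955))
    hss = 1.0 / (1.0 + math.exp((v + 82.90) / 6.086))
    thf = 1.0 / (1.432e-5 * math.exp(-(v + 1.196) / 6.285) + 6.149 * math.exp((v + 0.5096) / 20.27))
    ths = 1.0 / (0.009794 * math.exp(-(v + 17.95) / 28.05) + 0.3343 * math.exp((v + 5.730) / 56.66))
    Ahf = 0.99
    Ahs = 0.01
    jss = hss
    tj = 2.038 + 1.0 / (0.02136 * math.exp(-(v + 100.6) / 8.281) + 0.3052 * math.exp((v + 0.9941) / 38.45))
    hssp = 1.0 / (1.0 + math.exp((v + 89.1) / 6.086))
    thsp = 3.0 * ths
    tjp = 1.46 * tj
    h = Ahf * y[IHF] + Ahs * y[IHS]
    hp = Ahf * y[IHF] + Ahs * y[IHSP]
    fINap = fphos
    GNa = 75.0
    INa = GNa * (v - ENa) * y[IM] ** 3 * ((1.0 - fINap) * h * y[IJ] + fINap * hp * y[IJP])

    # ----------------------------------------------------------------- INaL
    mLss = 1.0 / (1.0 + math.exp(-(v + 42.85) / 5.264))
    tmL = tm
    hLss = 1.0 / (1.0 + math.exp((v + 87.61) / 7.488))
    thL = 200.0
    hLssp = 1.0 / (1.0 + math.exp((v + 93.81) / 7.488))
    thLp = 3.0 * thL
    GNaL = 0.0075 * p[_GNAL_SCALE]
    if epi:
        GNaL *= 0.6
    INaL = GNaL * (v - ENa) * y[IML] * ((1.0 - fphos) * y[IHL] + fphos * y[IHLP])

    # ------------------------------------------------------------------ Ito
    ass = 1.0 / (1.0 + math.exp(-(v - 14.34) / 14.82))
    ta = 1.0515 / (
        1.0 / (1.2089 * (1.0 + math.exp(-(v - 18.4099) / 29.3814)))
        + 3.5 / (1.0 + math.exp((v + 100.0) / 29.3814))
    )
    iss = 1.0 / (1.0 + math.exp((v + 43.94) / 5.711))
    if epi:
        delta_epi = 1.0 - 0.95 / (1.0 + math.exp((v + 70.0) / 5.0))
    else:
        delta_epi = 1.0
    tiF = 4.562 + 1.0 / (0.3933 * math.exp(-(v + 100.0) / 100.0) + 0.08004 * math.exp((v + 50.0) / 16.59))
    tiS = 23.62 + 1.0 / (0.001416 * math.exp(-(v + 96.52) / 59.05) + 1.780e-8 * math.exp((v + 114.1) / 8.079))
    tiF *= delta_epi
    tiS *= delta_epi
    AiF = 1.0 / (1.0 + math.exp((v - 213.6) / 151.2))
    AiS = 1.0 - AiF
    i_gate = AiF * y[IIF] + AiS * y[IIS]
    assp = 1.0 / (1.0 + math.exp(-(v - 24.34) / 14.82))
    dti_develop = 1.354 + 1.0e-4 / (math.exp((v - 167.4) / 15.89) + math.exp(-(v - 12.23) / 0.2154))
    dti_recover = 1.0 - 0.5 / (1.0 + math.exp((v + 70.0) / 20.0))
    tiFp = dti_develop * dti_recover * tiF
    tiSp = dti_develop * dti_recover * tiS
    ip_gate = AiF * y[IIFP] + AiS * y[IISP]
    Gto = 0.02 * p[_GTO_SCALE]
    if epi:
        Gto *= 4.0
    Ito = Gto * (v - EK) * ((1.0 - fphos) * y[IA] * i_gate + fphos * y[IAP] * ip_gate)

    # ----------------------------------------------------------------- ICaL
    dss = 1.0 / (1.0 + math.exp(-(v + 3.940) / 4.230))
    td = 0.6 + 1.0 / (math.exp(-0.05 * (v + 6.0)) + math.exp(0.09 * (v + 14.0)))
    fss = 1.0 / (1.0 + math.exp((v + 19.58) / 3.696))
    tff = 7.0 + 1.0 / (0.0045 * math.exp(-(v + 20.0) / 10.0) + 0.0045 * math.exp((v + 20.0) / 10.0))
    tfs = 1000.0 + 1.0 / (0.000035 * math.exp(-(v + 5.0) / 4.0) + 0.000035 * math.exp((v + 5.0) / 6.0))
    Aff = 0.6
    Afs = 1.0 - Aff
    f = Aff * y[IFF] + Afs * y[IFS]
    fcass = fss
    tfcaf = 7.0 + 1.0 / (0.04 * math.exp(-(v - 4.0) / 7.0) + 0.04 * math.exp((v - 4.0) / 7.0))
    tfcas = 100.0 + 1.0 / (0.00012 * math.exp(-v / 3.0) + 0.00012 * math.exp(v / 7.0))
    Afcaf = 0.3 + 0.6 / (1.0 + math.exp((v - 10.0) / 10.0))
    Afcas = 1.0 - Afcaf
    fca = Afcaf * y[IFCAF] + Afcas * y[IFCAS]
    tjca = 75.0
    tffp = 2.5 * tff
    tfcafp = 2.5 * tfcaf
    fp = Aff * y[IFFP] + Afs * y[IFS]
    fcap = Afcaf * y[IFCAFP] + Afcas * y[IFCAS]
    Kmn = 0.002
    k2n = 1000.0
    km2n = y[IJCA] * 1.0
    anca = 1.0 / (k2n / km2n + (1.0 + Kmn / cass) ** 4)
    anca_i = 1.0 / (k2n / km2n + (1.0 + Kmn / cai) ** 4)

    # PKA-phosphorylated gate laws (hyperpolarized activation/inactivation,
    # slowed voltage inactivation)
    dss_p = 1.0 / (1.0 + math.exp(-(v + 3.940 - p[_PKA_ACT_SHIFT]) / 4.230))
    dss_c = 1.0 / (1.0 + math.exp(-(v + 3.940 - p[_CAMK_ACT_SHIFT]) / 4.230))
    fss_p = 1.0 / (1.0 + math.exp((v + 19.58 - p[_PKA_INACT_SHIFT]) / 3.696))
    tff_p = tff * p[_PKA_TAU_FACTOR]
    tfs_p = tfs * p[_PKA_TAU_FACTOR]
    tfcaf_p = tfcaf * p[_PKA_TAU_FACTOR]
    tjca_p = tjca * p[_PKA_TAU_FACTOR]
    f_pka = Aff * y[IFFPKA] + Afs * y[IFSPKA]
    fca_pka = Afcaf * y[IFCAFPKA] + Afcas * y[IFCAS]

    vfrt_s = vfrt
    if -1e-7 < vfrt_s < 1e-7:
        vfrt_s = 1e-7
    e2v = math.exp(2.0 * vfrt_s)
    e1v = math.exp(vfrt_s)
    PhiCaL_ss = 4.0 * vffrt * (cass * e2v - 0.341 * cao) / (e2v - 1.0)
    PhiCaL_i = 4.0 * vffrt * (cai * e2v - 0.341 * cao) / (e2v - 1.0)
    PhiCaNa_ss = 1.0 * vffrt * (0.75 * nass * e1v - 0.75 * nao) / (e1v - 1.0)
    PhiCaNa_i = 1.0 * vffrt * (0.75 * nai * e1v - 0.75 * nao) / (e1v - 1.0)
    PhiCaK_ss = 1.0 * vffrt * (0.75 * kss * e1v - 0.75 * ko) / (e1v - 1.0)
    PhiCaK_i = 1.0 * vffrt * (0.75 * ki * e1v - 0.75 * ko) / (e1v - 1.0)

    PCa = 0.0001 * p[_PCA_SCALE]
    if epi:
        PCa *= 1.2
    PCaNa = 0.00125 * PCa
    PCaK = 3.574e-4 * PCa

    nca = y[INCA]
    nca_i = y[INCAI]
    O_base_ss = y[ID] * (f * (1.0 - nca) + y[IJCA] * fca * nca)
    O_camk_ss = y[ID] * (fp * (1.0 - nca) + y[IJCA] * fcap * nca)
    O_pka_ss = y[IDPKA] * (f_pka * (1.0 - nca) + y[IJCAPKA] * fca_pka * nca)
    O_base_i = y[ID] * (f * (1.0 - nca_i) + y[IJCA] * fca * nca_i)
    # crest CaMKII population: shifted activation plus the phosphorylated
    # (slowed) inactivation gate set
    O_camk_i = y[IDCAMK] * (fp * (1.0 - nca_i) + y[IJCA] * fcap * nca_i)

    pka = p[_PKA_FRACTION]
    camkii = p[_CAMKII_CREST]
    w_tt = p[_CORRECTION] * p[_TTD] * p[_F_TT]
    w_cr = p[_CORRECTION] * (1.0 - p[_F_TT])
    # 1.1 = permeability ratio of the CaMK-phosphorylated channel
    W_tt = w_tt * (
        (1.0 - pka) * ((1.0 - fphos) * O_base_ss + fphos * 1.1 * O_camk_ss)
        + pka * p[_PKA_CURRENT_FACTOR] * O_pka_ss
    )
    W_cr = w_cr * ((1.0 - camkii) * O_base_i + camkii * 1.1 * O_camk_i)

    ICaL_tt = PCa * PhiCaL_ss * W_tt
    ICaL_cr = PCa * PhiCaL_i * W_cr
    ICaNa_tt = PCaNa * PhiCaNa_ss * W_tt
    ICaNa_cr = PCaNa * PhiCaNa_i * W_cr
    ICaK_tt = PCaK * PhiCaK_ss * W_tt
    ICaK_cr = PCaK * PhiCaK_i * W_cr

    # ------------------------------------------------------------------ IKr
    xrss = 1.0 / (1.0 + math.exp(-(v + 8.337) / 6.789))
    txrf = 12.98 + 1.0 / (0.3652 * math.exp((v - 31.66) / 3.869) + 4.123e-5 * math.exp(-(v - 47.78) / 20.38))
    txrs = 1.865 + 1.0 / (0.06629 * math.exp((v - 34.70) / 7.355) + 1.128e-5 * math.exp(-(v - 29.74) / 25.94))
    Axrf = 1.0 / (1.0 + math.exp((v + 54.81) / 38.21))
    Axrs = 1.0 - Axrf
    xr = Axrf * y[IXRF] + Axrs * y[IXRS]
    rkr = 1.0 / ((1.0 + math.exp((v + 55.0) / 75.0)) * (1.0 + math.exp((v - 10.0) / 30.0)))
    GKr = 0.046 * p[_GKR_SCALE]
    if epi:
        GKr *= 1.3
    IKr = GKr * math.sqrt(ko / 5.4) * xr * rkr * (v - EK)

    # ------------------------------------------------------------------ IKs
    xs1ss = 1.0 / (1.0 + math.exp(-(v + 11.60) / 8.932))
    txs1 = 817.3 + 1.0 / (2.326e-4 * math.exp((v + 48.28) / 17.80) + 0.001292 * math.exp(-(v + 210.0) / 230.0))
    xs2ss = xs1ss
    txs2 = 1.0 / (0.01 * math.exp((v - 50.0) / 20.0) + 0.0193 * math.exp(-(v + 66.54) / 31.0))
    KsCa = 1.0 + 0.6 / (1.0 + (3.8e-5 / cai) ** 1.4)
    GKs = 0.0034 * p[_GKS_SCALE]
    if epi:
        GKs *= 1.4
    IKs = GKs * KsCa * y[IXS1] * y[IXS2] * (v - EKs)

    # ------------------------------------------------------------------ IK1
    xk1ss = 1.0 / (1.0 + math.exp(-(v + 2.5538 * ko + 144.59) / (1.5692 * ko + 3.8115)))
    txk1 = 122.2 / (math.exp(-(v + 127.2) / 20.36) + math.exp((v + 236.8) / 69.33))
    rk1 = 1.0 / (1.0 + math.exp((v + 105.8 - 2.6 * ko) / 9.493))
    GK1 = 0.1908 * p[_GK1_SCALE]
    if epi:
        GK1 *= 1.2
    IK1 = GK1 * math.sqrt(ko) * rk1 * y[IXK1] * (v - EK)

    # ---------------------------------------------------------------- INaCa
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
    hca = math.exp(qca * vfrt)
    hna = math.exp(qna * vfrt)
    Gncx = 0.0008 * p[_NCX_SCALE]
    if epi:
        Gncx *= 1.1
    KmCaAct = 150.0e-6
    zca = 2.0

    # myoplasmic exchanger
    h1 = 1.0 + nai / kna3 * (1.0 + hna)
    h2 = (nai * hna) / (kna3 * h1)
    h3 = 1.0 / h1
    h4 = 1.0 + nai / kna1 * (1.0 + nai / kna2)
    h5 = nai * nai / (h4 * kna1 * kna2)
    h6 = 1.0 / h4
    h7 = 1.0 + nao / kna3 * (1.0 + 1.0 / hna)
    h8 = nao / (kna3 * hna * h7)
    h9 = 1.0 / h7
    h10 = kasymm + 1.0 + nao / kna1 * (1.0 + nao / kna2)
    h11 = nao * nao / (h10 * kna1 * kna2)
    h12 = 1.0 / h10
    k1 = h12 * cao * kcaon
    k2 = kcaoff
    k3p_ = h9 * wca
    k3pp = h8 * wnaca
    k3 = k3p_ + k3pp
    k4p_ = h3 * wca / hca
    k4pp = h2 * wnaca
    k4 = k4p_ + k4pp
    k5 = kcaoff
    k6 = h6 * cai * kcaon
    k7 = h5 * h2 * wna
    k8 = h8 * h11 * wna
    x1 = k2 * k4 * (k7 + k6) + k5 * k7 * (k2 + k3)
    x2 = k1 * k7 * (k4 + k5) + k4 * k6 * (k1 + k8)
    x3 = k1 * k3 * (k7 + k6) + k8 * k6 * (k2 + k3)
    x4 = k2 * k8 * (k4 + k5) + k3 * k5 * (k1 + k8)
    E1 = x1 / (x1 + x2 + x3 + x4)
    E2 = x2 / (x1 + x2 + x3 + x4)
    E3 = x3 / (x1 + x2 + x3 + x4)
    E4 = x4 / (x1 + x2 + x3 + x4)
    allo = 1.0 / (1.0 + (KmCaAct / cai) ** 2)
    JncxNa = 3.0 * (E4 * k7 - E1 * k8) + E3 * k4pp - E2 * k3pp
    JncxCa = E2 * k2 - E1 * k1
    INaCa_i = 0.8 * Gncx * allo * (JncxNa + zca * JncxCa)

    # subspace exchanger
    h1 = 1.0 + nass / kna3 * (1.0 + hna)
    h2 = (nass * hna) / (kna3 * h1)
    h3 = 1.0 / h1
    h4 = 1.0 + nass / kna1 * (1.0 + nass / kna2)
    h5 = nass * nass / (h4 * kna1 * kna2)
    h6 = 1.0 / h4
    k6 = h6 * cass * kcaon
    k7 = h5 * h2 * wna
    k4p_ = h3 * wca / hca
    k4pp = h2 * wnaca
    k4 = k4p_ + k4pp
    x1 = k2 * k4 * (k7 + k6) + k5 * k7 * (k2 + k3)
    x2 = k1 * k7 * (k4 + k5) + k4 * k6 * (k1 + k8)
    x3 = k1 * k3 * (k7 + k6) + k8 * k6 * (k2 + k3)
    x4 = k2 * k8 * (k4 + k5) + k3 * k5 * (k1 + k8)
    E1 = x1 / (x1 + x2 + x3 + x4)
    E2 = x2 / (x1 + x2 + x3 + x4)
    E3 = x3 / (x1 + x2 + x3 + x4)
    E4 = x4 / (x1 + x2 + x3 + x4)
    allo = 1.0 / (1.0 + (KmCaAct / cass) ** 2)
    JncxNa = 3.0 * (E4 * k7 - E1 * k8) + E3 * k4pp - E2 * k3pp
    JncxCa = E2 * k2 - E1 * k1
    INaCa_ss = 0.2 * Gncx * allo * (JncxNa + zca * JncxCa)

    # ----------------------------------------------------------------- INaK
    k1p = 949.5
    k1m = 182.4
    k2p = 687.2
    k2m = 39.4
    k3p_nak = 1899.0
    k3m = 79300.0
    k4p_nak = 639.0
    k4m = 40.0
    Knai0 = 9.073
    Knao0 = 27.78
    delta = -0.1550
    Knai = Knai0 * math.exp(delta * vfrt / 3.0)
    Knao = Knao0 * math.exp((1.0 - delta) * vfrt / 3.0)
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
    Pfrac = eP / (1.0 + H / Khp + nai / Knap + ki / Kxkur)
    a1 = (k1p * (nai / Knai) ** 3) / ((1.0 + nai / Knai) ** 3 + (1.0 + ki / Kki) ** 2 - 1.0)
    b1 = k1m * MgADP
    a2 = k2p
    b2 = (k2m * (nao / Knao) ** 3) / ((1.0 + nao / Knao) ** 3 + (1.0 + ko / Kko) ** 2 - 1.0)
    a3 = (k3p_nak * (ko / Kko) ** 2) / ((1.0 + nao / Knao) ** 3 + (1.0 + ko / Kko) ** 2 - 1.0)
    b3 = (k3m * Pfrac * H) / (1.0 + MgATP / Kmgatp)
    a4 = (k4p_nak * MgATP / Kmgatp) / (1.0 + MgATP / Kmgatp)
    b4 = (k4m * (ki / Kki) ** 2) / ((1.0 + nai / Knai) ** 3 + (1.0 + ki / Kki) ** 2 - 1.0)
    x1 = a4 * a1 * a2 + b2 * b4 * b3 + a2 * b4 * b3 + b3 * a1 * a2
    x2 = b2 * b1 * b4 + a1 * a2 * a3 + a3 * b1 * b4 + a2 * a3 * b4
    x3 = a2 * a3 * a4 + b3 * b2 * b1 + b2 * b1 * a4 + a3 * a4 * b1
    x4 = b4 * b3 * b2 + a3 * a4 * a1 + b2 * a4 * a1 + b3 * b2 * a1
    E1 = x1 / (x1 + x2 + x3 + x4)
    E2 = x2 / (x1 + x2 + x3 + x4)
    E3 = x3 / (x1 + x2 + x3 + x4)
    E4 = x4 / (x1 + x2 + x3 + x4)
    JnakNa = 3.0 * (E1 * a3 - E2 * b3)
    JnakK = 2.0 * (E4 * b1 - E3 * a1)
    Pnak = 30.0
    if epi:
        Pnak *= 0.9
    INaK = Pnak * (JnakNa + JnakK)

    # ---------------------------------------------------------------- minor
    xkb = 1.0 / (1.0 + math.exp(-(v - 14.48) / 18.34))
    GKb = 0.003
    if epi:
        GKb *= 0.6
    IKb = GKb * xkb * (v - EK)
    PNab = 3.75e-10
    INab = PNab * vffrt * (nai * e1v - nao) / (e1v - 1.0)
    PCab = 2.5e-8
    ICab = PCab * 4.0 * vffrt * (cai * e2v - 0.341 * cao) / (e2v - 1.0)
    GpCa = 0.0005
    IpCa = GpCa * cai / (0.0005 + cai)

    # ---------------------------------------------------------------- fluxes
    JdiffNa = (nass - nai) / 2.0
    JdiffK = (kss - ki) / 2.0
    Jdiff = (cass - cai) / 0.2

    bt = 4.75
    a_rel = 0.5 * bt
    Jrel_inf = p[_JREL_SCALE] * a_rel * (-ICaL_tt) / (1.0 + (1.5 / cajsr) ** 8)
    tau_rel = bt / (1.0 + 0.0123 / cajsr)
    if tau_rel < 0.001:
        tau_rel = 0.001
    btp = 1.25 * bt
    a_relp = 0.5 * btp
    Jrel_infp = p[_JREL_SCALE] * a_relp * (-ICaL_tt) / (1.0 + (1.5 / cajsr) ** 8)
    tau_relp = btp / (1.0 + 0.0123 / cajsr)
    if tau_relp < 0.001:
        tau_relp = 0.001
    Jrel = (1.0 - fphos) * y[IJRELNP] + fphos * y[IJRELP]

    Jupnp = 0.004375 * cai / (cai + 0.00092)
    Jupp = 2.75 * 0.004375 * cai / (cai + 0.00092 - 0.00017)
    upScale = 1.3 if epi else 1.0
    Jleak = 0.0039375 * cansr / 15.0
    Jup = p[_SERCA_SCALE] * upScale * ((1.0 - fphos) * Jupnp + fphos * Jupp) - Jleak
    Jtr = (cansr - cajsr) / 100.0

    # ------------------------------------------------------------- membrane
    ICaL_total = ICaL_tt + ICaL_cr
    ICaNa_total = ICaNa_tt + ICaNa_cr
    ICaK_total = ICaK_tt + ICaK_cr
    Iion = (
        INa + INaL + Ito + ICaL_total + ICaNa_total + ICaK_total
        + IKr + IKs + IK1 + INaCa_i + INaCa_ss + INaK + INab + IKb + IpCa + ICab
    )
    if not clamp:
        y[IV] = v - dt * (Iion + istim)

    # ------------------------------------------------------ gate updates (RL)
    y[IM] = _rl(y[IM], mss, tm, dt)
    y[IHF] = _rl(y[IHF], hss, thf, dt)
    y[IHS] = _rl(y[IHS], hss, ths, dt)
    y[IJ] = _rl(y[IJ], jss, tj, dt)
    y[IHSP] = _rl(y[IHSP], hssp, thsp, dt)
    y[IJP] = _rl(y[IJP], jss, tjp, dt)
    y[IML] = _rl(y[IML], mLss, tmL, dt)
    y[IHL] = _rl(y[IHL], hLss, thL, dt)
    y[IHLP] = _rl(y[IHLP], hLssp, thLp, dt)
    y[IA] = _rl(y[IA], ass, ta, dt)
    y[IIF] = _rl(y[IIF], iss, tiF, dt)
    y[IIS] = _rl(y[IIS], iss, tiS, dt)
    y[IAP] = _rl(y[IAP], assp, ta, dt)
    y[IIFP] = _rl(y[IIFP], iss, tiFp, dt)
    y[IISP] = _rl(y[IISP], iss, tiSp, dt)
    y[ID] = _rl(y[ID], dss, td, dt)
    y[IFF] = _rl(y[IFF], fss, tff, dt)
    y[IFS] = _rl(y[IFS], fss, tfs, dt)
    y[IFCAF] = _rl(y[IFCAF], fcass, tfcaf, dt)
    y[IFCAS] = _rl(y[IFCAS], fcass, tfcas, dt)
    y[IJCA] = _rl(y[IJCA], fcass, tjca, dt)
    y[IFFP] = _rl(y[IFFP], fss, tffp, dt)
    y[IFCAFP] = _rl(y[IFCAFP], fcass, tfcafp, dt)
    y[IDPKA] = _rl(y[IDPKA], dss_p, td, dt)
    y[IFFPKA] = _rl(y[IFFPKA], fss_p, tff_p, dt)
    y[IFSPKA] = _rl(y[IFSPKA], fss_p, tfs_p, dt)
    y[IFCAFPKA] = _rl(y[IFCAFPKA], fcass, tfcaf_p, dt)
    y[IJCAPKA] = _rl(y[IJCAPKA], fcass, tjca_p, dt)
    y[IDCAMK] = _rl(y[IDCAMK], dss_c, td, dt)
    y[IXRF] = _rl(y[IXRF], xrss, txrf, dt)
    y[IXRS] = _rl(y[IXRS], xrss, txrs, dt)
    y[IXS1] = _rl(y[IXS1], xs1ss, txs1, dt)
    y[IXS2] = _rl(y[IXS2], xs2ss, txs2, dt)
    y[IXK1] = _rl(y[IXK1], xk1ss, txk1, dt)
    y[IJRELNP] = _rl(y[IJRELNP], Jrel_inf, tau_rel, dt)
    y[IJRELP] = _rl(y[IJRELP], Jrel_infp, tau_relp, dt)

    # nca relaxes to anca*k2n/km2n with rate km2n
    y[INCA] = anca * k2n / km2n - (anca * k2n / km2n - y[INCA]) * math.exp(-km2n * dt)
    y[INCAI] = anca_i * k2n / km2n - (anca_i * k2n / km2n - y[INCAI]) * math.exp(-km2n * dt)
    y[ICAMKT] += dt * dCaMKt

    # --------------------------------------------------- concentration Euler
    dnai = -(INa + INaL + 3.0 * INaCa_i + 3.0 * INaK + INab + ICaNa_cr) * Acap / (F * vmyo) \
        + JdiffNa * vss / vmyo
    dnass = -(ICaNa_tt + 3.0 * INaCa_ss) * Acap / (F * vss) - JdiffNa
    dki = -(Ito + IKr + IKs + IK1 + IKb + istim - 2.0 * INaK + ICaK_cr) * Acap / (F * vmyo) \
        + JdiffK * vss / vmyo
    dkss = -ICaK_tt * Acap / (F * vss) - JdiffK
    cmdnmax = 0.05 * (1.3 if epi else 1.0)
    kmcmdn = 0.00238
    trpnmax = 0.07
    kmtrpn = 0.0005
    BSRmax = 0.047
    KmBSR = 0.00087
    BSLmax = 1.124
    KmBSL = 0.0087
    csqnmax = 10.0
    kmcsqn = 0.8
    Bcai = 1.0 / (1.0 + cmdnmax * kmcmdn / (kmcmdn + cai) ** 2 + trpnmax * kmtrpn / (kmtrpn + cai) ** 2)
    dcai = Bcai * (
        -(IpCa + ICab - 2.0 * INaCa_i + ICaL_cr) * Acap / (2.0 * F * vmyo)
        - Jup * vnsr / vmyo + Jdiff * vss / vmyo
    )
    Bcass = 1.0 / (1.0 + BSRmax * KmBSR / (KmBSR + cass) ** 2 + BSLmax * KmBSL / (KmBSL + cass) ** 2)
    dcass = Bcass * (
        -(ICaL_tt - 2.0 * INaCa_ss) * Acap / (2.0 * F * vss) + Jrel * vjsr / vss - Jdiff
    )
    dcansr = Jup - Jtr * vjsr / vnsr
    Bcajsr = 1.0 / (1.0 + csqnmax * kmcsqn / (kmcsqn + cajsr) ** 2)
    dcajsr = Bcajsr * (Jtr - Jrel)

    y[INAI] += dt * dnai
    y[INASS] += dt * dnass
    y[IKI] += dt * dki
    y[IKSS] += dt * dkss
    y[ICAI] += dt * dcai
    y[ICASS] += dt * dcass
    y[ICANSR] += dt * dcansr
    y[ICAJSR] += dt * dcajsr
    if y[ICAI] < 1e-10:
        y[ICAI] = 1e-10
    if y[ICASS] < 1e-10:
        y[ICASS] = 1e-10

    return ICaL_tt, ICaL_cr


@njit(cache=True)
def _integrate(y, p, dt, t_end, record_every,
               stim_starts, stim_dur, stim_amp,
               clamp_mode, v_hold, v_step, t_on, t_off):  # pragma: no cover - numba
    n_steps = int(round(t_end / dt))
    n_rec = n_steps // record_every + 1
    t_rec = np.empty(n_rec)
    v_rec = np.empty(n_rec)
    itt_rec = np.empty(n_rec)
    icr_rec = np.empty(n_rec)
    r = 0
    for s in range(n_steps + 1):
        t = s * dt
        istim = 0.0
        if not clamp_mode:
            for k in range(stim_starts.size):
                if stim_starts[k] <= t < stim_starts[k] + stim_dur:
                    istim = stim_amp
        v_forced = v_hold
        if clamp_mode and t_on <= t < t_off:
            v_forced = v_step
        record = s % record_every == 0 and r < n_rec
        if record:
            t_rec[r] = t
            v_rec[r] = y[IV]
            r += 1
        itt, icr = _step(y, p, dt, istim, clamp_mode, v_forced)
        if record:
            # currents evaluated from the state at the recorded time
            itt_rec[r - 1] = itt
            icr_rec[r - 1] = icr
    return t_rec[:r], v_rec[:r], itt_rec[:r], icr_rec[:r]


def integrate(
    y: np.ndarray,
    p: np.ndarray,
    t_end: float,
    dt: float = 0.01,
    record_every: int = 10,
    stim_starts: np.ndarray | None = None,
    stim_dur: float = 0.5,
    stim_amp: float = -80.0,
    clamp: tuple[float, float, float, float] | None = None,
):
    """Integrate the model in place for ``t_end`` ms.

    ``clamp`` is ``(v_hold, v_step, t_on, t_off)`` for voltage-clamp mode;
    otherwise stimuli at ``stim_starts`` (ms) drive free-running pacing.
    Returns ``(t, V, i_cal_tt, i_cal_crest)`` sampled every
    ``record_every`` steps.
    """
    if stim_starts is None:
        stim_starts = np.empty(0)
    stim_starts = np.asarray(stim_starts, dtype=float)
    if clamp is None:
        return _integrate(y, p, dt, t_end, record_every, stim_starts,
                          stim_dur, stim_amp, False, 0.0, 0.0, 0.0, 0.0)
    v_hold, v_step, t_on, t_off = clamp
    return _integrate(y, p, dt, t_end, record_every, stim_starts,
                      stim_dur, stim_amp, True, v_hold, v_step, t_on, t_off)
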