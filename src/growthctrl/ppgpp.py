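"""RelA/SpoT ppGpp kinetics: synthesis, hydrolysis and their calibration.

RelA synthesizes ppGpp when bound to ribosomes carrying uncharged tRNA in
the A-site, with competitive adjustment across tRNA species.  SpoT provides
a constant basal synthesis and a first-order hydrolysis that is inhibited by
uncharged tRNA.  Per-species dissociation/inhibition constants are scaled by
tRNA prevalence so each species holds comparable control.  The SpoT rate
constants follow analytically from a measured decay half-life (30 s at
0.1 µM SpoT) and a RelA-knockout steady-state concentration (11.4 µM).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .charging import ChargingParams
from .errors import DomainError


@dataclass
class PpGppParams:
    k_RelA: float                   # 1/s
    K_D_RelA: np.ndarray            # µM, per species (prevalence-adjusted)
    k_SpoT_syn: float               # 1/s
    k_SpoT_deg: float               # 1/(µM s)
    K_I_SpoT: np.ndarray            # µM, per species (prevalence-adjusted)
    C_SpoT_ref: float = 0.1         # µM, calibration assumption
    ppgpp_ss_ref: float = 11.4      # µM, RelA-knockout steady state
    halflife_ref: float = 30.0      # s, decay half-life calibration

    def __post_init__(self):
        self.K_D_RelA = np.asarray(self.K_D_RelA, dtype=float)
        self.K_I_SpoT = np.asarray(self.K_I_SpoT, dtype=float)
        for name in ("k_RelA", "k_SpoT_syn", "k_SpoT_deg", "C_SpoT_ref",
                     "ppgpp_ss_ref", "halflife_ref"):
            if not getattr(self, name) > 0:
                raise DomainError(f"{name} must be > 0")
        if np.any(self.K_D_RelA <= 0) or np.any(self.K_I_SpoT <= 0):
            raise DomainError("per-species constants must be > 0")


@dataclass
class RibosomeOccupancy:
    """A-site occupancy decomposition per tRNA species."""

    C_rib: np.ndarray           # ribosomes with species i at the A-site, µM
    C_rib_tRNAu: np.ndarray     # of those, bound to uncharged tRNA, µM
    sigma: np.ndarray           # A-site charged-tRNA saturation in [0, 1]


def ribosome_occupancy(charging_params: ChargingParams, tRNA_charged: np.ndarray,
                       tRNA_uncharged: np.ndarray, v_elongation: np.ndarray,
                       k_rib: float) -> RibosomeOccupancy:
    """Back out per-species ribosome pools from elongation rates.

    sigma_i is the charged-tRNA A-site saturation; C_rib,i = v_el,i /
    (sigma_i * k_rib) with the 0/0 case mapped to 0; the uncharged-bound
    fraction follows from the same competitive binding terms.
    """
    if not k_rib > 0:
        raise DomainError(f"k_rib must be > 0, got {k_rib}")
    tc = np.maximum(np.asarray(tRNA_charged, dtype=float), 0.0)
    tu = np.maximum(np.asarray(tRNA_uncharged, dtype=float), 0.0)
    xc = tc / charging_params.K_D_tRNAc
    xu = tu / charging_params.K_D_tRNAu
    denom = 1.0 + xu + xc
    sigma = xc / denom
    v_el = np.asarray(v_elongation, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        c_rib = np.where((sigma > 0) & (v_el > 0), v_el / (sigma * k_rib), 0.0)
    c_rib_u = c_rib * xu / denom
    return RibosomeOccupancy(C_rib=c_rib, C_rib_tRNAu=c_rib_u, sigma=sigma)


def species_adjustments(total_tRNA_conc: np.ndarray, K_D_RelA_lit: float,
                        K_I_SpoT_lit: float) -> tuple[np.ndarray, np.ndarray]:
    """Prevalence-scale the literature constants per tRNA species.

    ratio_i = tRNA_i / sum(tRNA); adjustment_i = ratio_i / (mean ratio);
    each species' constant is the adjustment times the literature value, so
    abundant species get proportionally weaker per-molecule control and all
    species exert comparable total control.
    """
    trna = np.asarray(total_tRNA_conc, dtype=float)
    if np.any(trna <= 0):
        raise DomainError("total tRNA concentration must be > 0 for every species")
    ratio = trna / trna.sum()
    adjustment = ratio / ratio.mean()
    return adjustment * K_D_RelA_lit, adjustment * K_I_SpoT_lit


def rela_rate(params: PpGppParams, occupancy: RibosomeOccupancy,
              C_RelA: float) -> float:
    """RelA ppGpp synthesis rate, µM/s.

    Summed over species: each species' saturation term competes against the
    product over the other species' occupancy terms in its denominator.
    """
    x = occupancy.C_rib_tRNAu / params.K_D_RelA
    if np.all(x == 0):
        return 0.0
    total = 0.0
    prod_all = np.prod(1.0 + x)
    for i in range(len(x)):
        prod_others = prod_all / (1.0 + x[i])
        total += x[i] / (x[i] + prod_others)
    return params.k_RelA * C_RelA * total


def spot_rates(params: PpGppParams, C_SpoT: float, ppgpp_conc: float,
               tRNA_uncharged: np.ndarray) -> tuple[float, float]:
    """(synthesis, degradation) by SpoT, µM/s; hydrolysis inhibited by uncharged tRNA."""
    if ppgpp_conc < 0 or C_SpoT < 0:
        raise DomainError("concentrations must be >= 0")
    tu = np.maximum(np.asarray(tRNA_uncharged, dtype=float), 0.0)
    syn = params.k_SpoT_syn * C_SpoT
    inhibition = 1.0 + float(np.sum(tu / params.K_I_SpoT))
    deg = params.k_SpoT_deg * C_SpoT * ppgpp_conc / inhibition
    return syn, deg


def ppgpp_derivative(rela: float, spot: tuple[float, float]) -> float:
    """d[ppGpp]/dt = v_RelA + v_SpoT,syn - v_SpoT,deg."""
    syn, deg = spot
    return rela + syn - deg


def derive_spot_constants(halflife_ref: float = 30.0, C_SpoT_ref: float = 0.1,
                          ppgpp_ss_ref: float = 11.4) -> tuple[float, float]:
    """Analytic SpoT calibration: (k_SpoT_deg, k_SpoT_syn).

    k_deg = ln(2)/t_half / C_SpoT from exponential decay with synthesis off
    and uninhibited hydrolysis; k_syn = k_deg * C_ppGpp,SS from the
    RelA-knockout steady state.
    """
    if not (halflife_ref > 0 and C_SpoT_ref > 0 and ppgpp_ss_ref > 0):
        raise DomainError("calibration inputs must be > 0")
    k_deg = math.log(2.0) / halflife_ref / C_SpoT_ref
    k_syn = k_deg * ppgpp_ss_ref
    return k_deg, k_syn


def step_ppgpp(params: PpGppParams, ppgpp_conc: float, rela: float,
               C_SpoT: float, tRNA_uncharged: np.ndarray, dt: float) -> float:
    """Advance the ppGpp ODE by dt with occupancy held fixed.

    With fixed RelA rate and uncharged tRNA the ODE is linear,
    dC/dt = a - b C, and is advanced exactly: C(t+dt) = a/b + (C - a/b) e^{-b dt}.
    """
    if not dt > 0:
        raise DomainError(f"dt must be > 0, got {dt}")
    tu = np.maximum(np.asarray(tRNA_uncharged, dtype=float), 0.0)
    inhibition = 1.0 + float(np.sum(tu / params.K_I_SpoT))
    a = rela + params.k_SpoT_syn * C_SpoT
    b = params.k_SpoT_deg * C_SpoT / inhibition
    if b <= 0:
        return max(ppgpp_conc + a * dt, 0.0)
    c_inf = a / b
    return max(c_inf + (ppgpp_conc - c_inf) * math.exp(-b * dt), 0.0)
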