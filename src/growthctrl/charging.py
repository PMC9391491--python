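"""tRNA charging and ribosome elongation kinetics.

One tRNA species is tracked per amino acid.  Synthetases charge tRNA with a
random-order bi-substrate saturation form; ribosomes elongate at a shared
rate limited by A-site competition between charged and uncharged tRNA of
every species.  Within each simulation timestep the charged:uncharged ratio
is relaxed toward the charging/elongation steady state by stiff ODE
integration, optionally co-integrating the amino-acid pools so supply enters
on sub-timestep scales.  ppGpp competitively inhibits translational GTPases,
capping the maximum elongation rate with a Hill form.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Callable

import numpy as np
from scipy.integrate import solve_ivp

from .errors import DomainError, IntegrationError


@dataclass
class ChargingParams:
    """Kinetic constants; per-species entries are arrays over tRNA species."""

    k_S: float                      # synthetase turnover, 1/s
    K_M_tRNAu: np.ndarray           # µM, default 1 for uncurated species
    K_M_aa: np.ndarray              # µM, default 100 for uncurated species
    K_D_tRNAc: float                # ribosome A-site dissociation, µM
    K_D_tRNAu: float                # µM
    k_rib_max: float                # aa/s per ribosome
    K_I_GTPase: float               # µM ppGpp
    hill_H: float                   # Hill coefficient of GTPase inhibition

    def __post_init__(self):
        self.K_M_tRNAu = np.asarray(self.K_M_tRNAu, dtype=float)
        self.K_M_aa = np.asarray(self.K_M_aa, dtype=float)
        scalars = dict(k_S=self.k_S, K_D_tRNAc=self.K_D_tRNAc, K_D_tRNAu=self.K_D_tRNAu,
                       k_rib_max=self.k_rib_max, K_I_GTPase=self.K_I_GTPase, hill_H=self.hill_H)
        for name, v in scalars.items():
            if not v > 0:
                raise DomainError(f"{name} must be > 0, got {v}")
        if np.any(self.K_M_tRNAu <= 0) or np.any(self.K_M_aa <= 0):
            raise DomainError("Michaelis constants must be > 0")

    @classmethod
    def with_defaults(cls, n_species: int, **overrides) -> "ChargingParams":
        kwargs = dict(k_S=100.0, K_M_tRNAu=np.full(n_species, 1.0),
                      K_M_aa=np.full(n_species, 100.0), K_D_tRNAc=1.0, K_D_tRNAu=1.0,
                      k_rib_max=22.0, K_I_GTPase=75.0, hill_H=2.0)
        kwargs.update(overrides)
        return cls(**kwargs)


@dataclass
class ChargingState:
    """Pools driving the charging ODEs; all concentrations µM."""

    tRNA_charged: np.ndarray
    tRNA_uncharged: np.ndarray
    synthetase_conc: np.ndarray
    ribosome_conc: float
    aa_conc: np.ndarray
    codon_fraction: np.ndarray      # sums to 1

    def __post_init__(self):
        for name in ("tRNA_charged", "tRNA_uncharged", "synthetase_conc",
                     "aa_conc", "codon_fraction"):
            arr = np.asarray(getattr(self, name), dtype=float)
            setattr(self, name, arr)
            if np.any(arr < 0):
                raise DomainError(f"{name} must be >= 0")
        if not np.isclose(self.codon_fraction.sum(), 1.0, atol=1e-9):
            raise DomainError("codon fractions must sum to 1")

    @property
    def total_trna(self) -> np.ndarray:
        return self.tRNA_charged + self.tRNA_uncharged


def charging_rate(params: ChargingParams, tRNA_uncharged: np.ndarray,
                  aa_conc: np.ndarray, synthetase_conc: np.ndarray) -> np.ndarray:
    """Random-order bi-substrate synthetase rate, µM/s per species."""
    u = np.maximum(tRNA_uncharged, 0.0) / params.K_M_tRNAu
    a = np.maximum(aa_conc, 0.0) / params.K_M_aa
    return params.k_S * synthetase_conc * (u * a) / (1.0 + u + a + u * a)


def ribosome_rate_cap(params: ChargingParams, ppgpp_conc: float,
                      gtpase_inhibition_enabled: bool = True) -> float:
    """Max elongation rate, Hill-inhibited by ppGpp when enabled."""
    if ppgpp_conc < 0:
        raise DomainError(f"ppGpp concentration must be >= 0, got {ppgpp_conc}")
    if not gtpase_inhibition_enabled:
        return params.k_rib_max
    return params.k_rib_max / (1.0 + (ppgpp_conc / params.K_I_GTPase) ** params.hill_H)


def elongation_rate(params: ChargingParams, tRNA_charged: np.ndarray,
                    tRNA_uncharged: np.ndarray, codon_fraction: np.ndarray,
                    ribosome_conc: float, k_rib: float,
                    ) -> tuple[np.ndarray, bool]:
    """Per-species elongation rate and a starvation flag.

    All species share one denominator of A-site competition terms; when a
    species with codon demand has no charged tRNA that denominator diverges
    and elongation stalls entirely (the algebraic limit), which is flagged.
    """
    tc = np.maximum(tRNA_charged, 0.0)
    tu = np.maximum(tRNA_uncharged, 0.0)
    f = codon_fraction
    starved = bool(np.any((f > 0) & (tc <= 0)))
    if starved:
        return np.zeros_like(tc), True
    with np.errstate(divide="ignore"):
        terms = np.where(f > 0,
                         f * (params.K_D_tRNAc / np.where(tc > 0, tc, np.inf)
                              + np.where(tc > 0, tu / tc, 0.0)
                              * params.K_D_tRNAc / params.K_D_tRNAu),
                         0.0)
    denom = 1.0 + terms.sum()
    return f * k_rib * ribosome_conc / denom, False


def _rhs(t, y, params, state, k_rib, supply, couple_supply, n):
    tc = y[:n]
    total = state.total_trna
    tu = np.maximum(total - tc, 0.0)
    tc = np.minimum(np.maximum(tc, 0.0), total)
    if couple_supply:
        aa = np.maximum(y[n:2 * n], 0.0)
    else:
        aa = state.aa_conc
    v_chg = charging_rate(params, tu, aa, state.synthetase_conc)
    v_el, _ = elongation_rate(params, tc, tu, state.codon_fraction,
                              state.ribosome_conc, k_rib)
    dtc = v_chg - v_el
    out = [dtc]
    if couple_supply:
        v_sup = supply(aa)
        daa = v_sup - v_chg
        # keep amino acids nonnegative: no further drain at zero
        daa = np.where((y[n:2 * n] <= 0) & (daa < 0), 0.0, daa)
        out.append(daa)
    out.append(v_chg)   # cumulative integrals for time-averaged rates
    out.append(v_el)
    return np.concatenate(out)


def relax_to_steady_state(params: ChargingParams, state: ChargingState,
                          supply: Callable[[np.ndarray], np.ndarray],
                          dt: float, k_rib: float | None = None,
                          couple_supply: bool = False,
                          rtol: float = 1e-8, atol: float = 1e-10,
                          ) -> tuple[ChargingState, np.ndarray, np.ndarray]:
    """Integrate the charging ODEs over one timestep.

    Returns the updated state plus the time-averaged charging and elongation
    rates over ``dt``.  Per-species total tRNA is conserved by construction
    (uncharged = total - charged).  With ``couple_supply`` the amino-acid
    pools are co-integrated via d[AA]/dt = supply - charging; otherwise the
    amino-acid concentrations are held constant during the step and updated
    once afterwards from the time-averaged rates.
    """
    if not dt > 0:
        raise DomainError(f"dt must be > 0, got {dt}")
    if k_rib is None:
        k_rib = params.k_rib_max
    n = len(state.tRNA_charged)
    y0 = [state.tRNA_charged]
    if couple_supply:
        y0.append(state.aa_conc)
    y0.extend([np.zeros(n), np.zeros(n)])
    y0 = np.concatenate(y0)

    sol = solve_ivp(_rhs, (0.0, dt), y0, method="LSODA", rtol=rtol, atol=atol,
                    args=(params, state, k_rib, supply, couple_supply, n))
    if not sol.success:
        raise IntegrationError(f"charging relaxation failed: {sol.message}",
                               snapshot=state)
    y = sol.y[:, -1]
    total = state.total_trna
    tc = np.minimum(np.maximum(y[:n], 0.0), total)
    tu = total - tc
    off = 2 * n if couple_supply else n
    avg_charging = y[off:off + n] / dt
    avg_elongation = y[off + n:off + 2 * n] / dt
    if couple_supply:
        aa = np.maximum(y[n:2 * n], 0.0)
    else:
        aa = np.maximum(state.aa_conc + (supply(state.aa_conc) - avg_charging) * dt, 0.0)
    new_state = replace(state, tRNA_charged=tc, tRNA_uncharged=tu, aa_conc=aa)
    return new_state, avg_charging, avg_elongation
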