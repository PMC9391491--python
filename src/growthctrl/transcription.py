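"""ppGpp-RNAP binding and gene-level synthesis-probability parameterization.

ppGpp binds RNA polymerase with Hill coefficient 2; free and bound
polymerase drive different per-gene expression levels.  The binding constant
and aggregate expression rates are fitted to growth-law data (RNA mass
fraction, RNAP and ppGpp concentrations across doubling times).  Per-gene
free/bound expression pairs are solved from a measured induction fold change
plus basal expression, with negative solutions truncated at zero; adjusted
genes can instead be re-fitted across conditions by least squares after
subtracting the transcription-factor contribution.  During simulation the
basal recruitment becomes ppGpp-dependent, with transcription-factor effects
rescaled so basal-condition probabilities match the unregulated model.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy.interpolate import PchipInterpolator
from scipy.optimize import least_squares

from .errors import DomainError, FitError


@dataclass
class RnapBinding:
    """ppGpp-RNAP binding: Hill form with exponent fixed at 2."""

    K_M_ppgpp: float
    hill: float = 2.0

    def __post_init__(self):
        if not self.K_M_ppgpp > 0:
            raise DomainError("K_M_ppgpp must be > 0")
        if self.hill != 2.0:
            raise DomainError("the Hill exponent of ppGpp-RNAP binding is fixed at 2")


def fraction_bound(binding: RnapBinding, ppgpp_conc: float) -> float:
    """Fraction of RNAP bound to ppGpp: C^2 / (K_M^2 + C^2)."""
    if ppgpp_conc < 0:
        raise DomainError(f"ppGpp concentration must be >= 0, got {ppgpp_conc}")
    c2 = ppgpp_conc * ppgpp_conc
    return c2 / (binding.K_M_ppgpp ** 2 + c2)


@dataclass
class GrowthLawTable:
    """Population-level rows of (doubling time, RNA mass fraction, RNAP, ppGpp)."""

    doubling_time_min: np.ndarray
    rna_mass_fraction: np.ndarray
    rnap_conc: np.ndarray
    ppgpp_conc: np.ndarray

    def __post_init__(self):
        for name in ("doubling_time_min", "rna_mass_fraction", "rnap_conc", "ppgpp_conc"):
            setattr(self, name, np.asarray(getattr(self, name), dtype=float))
        if np.any(self.doubling_time_min <= 0):
            raise DomainError("doubling times must be > 0")
        n = len(self.doubling_time_min)
        if any(len(getattr(self, f)) != n for f in
               ("rna_mass_fraction", "rnap_conc", "ppgpp_conc")):
            raise DomainError("growth-law table columns must have equal length")

    def __len__(self):
        return len(self.doubling_time_min)


@dataclass
class KmRnapFit:
    K_M_ppgpp: float
    exp_free: float
    exp_ppgpp: float
    residual: float


def fit_km_rnap(table: GrowthLawTable, km_init: float = 50.0) -> KmRnapFit:
    """Nonlinear least squares of the RNA-fraction growth-law relation.

    RNA_fraction = C_RNAP * ((1-f)*exp_free + f*exp_ppgpp) with
    f = C^2/(K_M^2 + C^2); returns K_M plus the aggregate expression rates.
    """
    if len(table) < 3:
        raise FitError("growth-law fit needs at least 3 rows")
    if np.ptp(table.ppgpp_conc) == 0:
        raise FitError("degenerate growth-law table: constant ppGpp makes K_M unidentifiable")

    c2 = table.ppgpp_conc ** 2

    def resid(theta):
        km, ef, ep = theta
        f = c2 / (km * km + c2)
        return table.rnap_conc * ((1 - f) * ef + f * ep) - table.rna_mass_fraction

    scale = np.median(table.rna_mass_fraction / np.maximum(table.rnap_conc, 1e-12))
    sol = least_squares(resid, x0=[km_init, scale, scale],
                        bounds=([1e-9, 0.0, 0.0], [np.inf] * 3), xtol=1e-14, ftol=1e-14,
                        gtol=1e-14)
    if not sol.success:
        raise FitError(f"growth-law fit failed: {sol.message}")
    km, ef, ep = sol.x
    return KmRnapFit(K_M_ppgpp=float(km), exp_free=float(ef), exp_ppgpp=float(ep),
                     residual=float(np.linalg.norm(sol.fun)))


def solve_gene_expression(fc: Mapping[str, float | None], exp_basal: Mapping[str, float],
                          f_rich: float, f_basal: float,
                          reg_sign: Mapping[str, int] | None = None,
                          fc_plus: float | None = None, fc_minus: float | None = None,
                          ) -> tuple[dict[str, float], dict[str, float]]:
    """Per-gene (exp_free, exp_ppgpp) from fold change and basal expression.

    The induction fold change FC = log2(exp_ppgpp / ((1-f_rich)*exp_free +
    f_rich*exp_ppgpp)) and the basal relation exp_basal = (1-f_basal)*exp_free
    + f_basal*exp_ppgpp form a 2x2 linear system per gene.  Genes without a
    measured FC fall back to the sign-matched average fold change.  Negative
    exp_free solutions (large positive FC) are truncated at 0 and exp_ppgpp
    re-solved from the basal relation.
    """
    if not (0.0 <= f_basal <= 1.0 and 0.0 <= f_rich <= 1.0):
        raise DomainError("bound fractions must lie in [0, 1]")
    reg_sign = reg_sign or {}
    exp_free: dict[str, float] = {}
    exp_ppgpp: dict[str, float] = {}
    for gene, basal in exp_basal.items():
        if basal < 0:
            raise DomainError(f"negative basal expression for {gene!r}")
        fc_g = fc.get(gene)
        if fc_g is None:
            sign = reg_sign.get(gene, 0)
            fc_g = fc_plus if sign > 0 else fc_minus
            if fc_g is None:
                raise DomainError(f"gene {gene!r} has no fold change and no usable fallback")
        ratio = 2.0 ** fc_g
        # exp_ppgpp * (1 - ratio*f_rich) = ratio*(1-f_rich)*exp_free
        denom = 1.0 - ratio * f_rich
        if f_rich == 1.0:
            raise DomainError("f_rich = 1 with a finite fold change is unsolvable")
        if denom <= 0:
            # fold change unreachable even with exp_free = 0: truncate
            ef, ep = 0.0, _basal_only(basal, f_basal, gene)
        else:
            slope = ratio * (1.0 - f_rich) / denom     # exp_ppgpp = slope * exp_free
            ef = basal / ((1.0 - f_basal) + f_basal * slope)
            ep = slope * ef
            if ef < 0 or ep < 0:
                ef, ep = 0.0, _basal_only(basal, f_basal, gene)
        exp_free[gene] = ef
        exp_ppgpp[gene] = ep
    return exp_free, exp_ppgpp


def _basal_only(basal: float, f_basal: float, gene: str) -> float:
    if f_basal == 0:
        raise DomainError(f"cannot truncate {gene!r}: f_basal = 0 leaves exp_ppgpp unconstrained")
    return basal / f_basal


def condition_match(exp_cond: Mapping[str, Sequence[float]],
                    f_cond: Sequence[float],
                    tf_cond: Mapping[str, Sequence[float]] | None = None,
                    ) -> tuple[dict[str, float], dict[str, float]]:
    """Least-squares (exp_free, exp_ppgpp) per gene across >= 2 conditions.

    Design matrix rows are (1-f, f) per condition; the response is the
    per-condition target expression minus the transcription-factor
    contribution.  Raises on a rank-deficient design (identical f values).
    """
    f = np.asarray(f_cond, dtype=float)
    if len(f) < 2:
        raise FitError("condition match needs at least 2 conditions")
    F = np.column_stack([1.0 - f, f])
    if np.linalg.matrix_rank(F, tol=1e-12) < 2:
        raise FitError("rank-deficient condition design: condition f values are identical")
    tf_cond = tf_cond or {}
    exp_free, exp_ppgpp = {}, {}
    for gene, targets in exp_cond.items():
        e = np.asarray(targets, dtype=float) - np.asarray(
            tf_cond.get(gene, np.zeros(len(f))), dtype=float)
        r, *_ = np.linalg.lstsq(F, e, rcond=None)
        exp_free[gene] = float(r[0])
        exp_ppgpp[gene] = float(r[1])
    return exp_free, exp_ppgpp


def tf_contribution(exp_cond: float, delta_r_cond: float, p_cond: float) -> float:
    """Expected TF-driven expression share: exp * delta_r / p for one condition."""
    if p_cond == 0:
        raise DomainError("zero synthesis probability in tf_contribution")
    return exp_cond * delta_r_cond / p_cond


@dataclass
class GeneExpressionParams:
    """Per-gene expression decomposition and recruitment parameters."""

    genes: tuple[str, ...]
    exp_free: dict[str, float]
    exp_ppgpp: dict[str, float]
    alpha_o: dict[str, float]                       # reference basal recruitment
    delta_r: dict[tuple[str, str], float] = field(default_factory=dict)  # (TF, gene)
    P_T: dict[str, float] = field(default_factory=dict)                  # TF bound prob
    rna_halflife_s: dict[str, float] = field(default_factory=dict)
    gene_position: dict[str, float] = field(default_factory=dict)        # [0,1] from origin

    def __post_init__(self):
        for g in self.genes:
            if self.exp_free.get(g, 0.0) < 0 or self.exp_ppgpp.get(g, 0.0) < 0:
                raise DomainError(f"negative expression level for gene {g!r}")
        for tf, p in self.P_T.items():
            if not 0.0 <= p <= 1.0:
                raise DomainError(f"P_T[{tf!r}] must lie in [0, 1]")

    def tf_term(self, gene: str) -> float:
        return sum(self.P_T[tf] * dr for (tf, g), dr in self.delta_r.items() if g == gene)


def synth_probability(params: GeneExpressionParams, alpha: Mapping[str, float],
                      alpha_mode: str = "fixed",
                      clip_counter: dict | None = None) -> dict[str, float]:
    """Per-gene synthesis probability.

    fixed mode: v = alpha + sum(P_T * delta_r).  ppgpp mode: the TF term is
    scaled by alpha/alpha_o so transcription factors reduce expression by the
    same fraction regardless of the ppGpp-dependent basal recruitment.
    Negative outputs are clipped at 0 and counted.
    """
    if alpha_mode not in ("fixed", "ppgpp"):
        raise DomainError(f"unknown alpha_mode {alpha_mode!r}")
    out = {}
    for gene in params.genes:
        a = alpha[gene]
        tf = params.tf_term(gene)
        if alpha_mode == "fixed":
            v = a + tf
        else:
            a_o = params.alpha_o[gene]
            if a_o == 0 and tf != 0:
                raise DomainError(f"alpha_o = 0 with TF effects for gene {gene!r}")
            v = a + (a / a_o) * tf if a_o != 0 else a
        if v < 0:
            if clip_counter is not None:
                clip_counter[gene] = clip_counter.get(gene, 0) + 1
            else:
                warnings.warn(f"clipping negative synthesis probability for {gene!r}",
                              stacklevel=2)
            v = 0.0
        out[gene] = v
    return out


def tf_scale_correction(params: GeneExpressionParams, binding: RnapBinding,
                        basal_ppgpp: float,
                        alpha_fn) -> tuple[dict[str, float], dict[str, float]]:
    """Rescale (exp_free, exp_ppgpp) of TF-regulated genes.

    The scale is the ratio of the fixed-mode probability to the ppGpp-mode
    probability at the basal ppGpp concentration, applied to both expression
    levels so the two modes agree at the basal condition.
    """
    alpha_basal = alpha_fn(basal_ppgpp)
    v_fixed = synth_probability(params, {g: params.alpha_o[g] for g in params.genes},
                                alpha_mode="fixed")
    v_ppgpp = synth_probability(params, alpha_basal, alpha_mode="ppgpp")
    ef = dict(params.exp_free)
    ep = dict(params.exp_ppgpp)
    for gene in params.genes:
        if params.tf_term(gene) == 0:
            continue
        if v_ppgpp[gene] == 0:
            raise FitError(f"cannot rescale gene {gene!r}: zero ppGpp-mode probability")
        scale = v_fixed[gene] / v_ppgpp[gene]
        ef[gene] *= scale
        ep[gene] *= scale
    return ef, ep


def make_tau_interpolant(table: GrowthLawTable) -> PchipInterpolator:
    """Monotone piecewise-cubic doubling-time-vs-ppGpp interpolant (minutes)."""
    order = np.argsort(table.ppgpp_conc)
    return PchipInterpolator(table.ppgpp_conc[order], table.doubling_time_min[order],
                             extrapolate=False)


def gene_dosage(tau_min: float, position_frac: float, C_min: float = 40.0,
                D_min: float = 20.0) -> float:
    """Replication-driven copy number: 2^((C*(1-x) + D)/tau)."""
    if not 0.0 <= position_frac <= 1.0:
        raise DomainError("gene position must lie in [0, 1]")
    return 2.0 ** ((C_min * (1.0 - position_frac) + D_min) / tau_min)


def alpha_of_ppgpp(params: GeneExpressionParams, binding: RnapBinding,
                   ppgpp_conc: float, tau_interp, C_min: float = 40.0,
                   D_min: float = 20.0) -> dict[str, float]:
    """ppGpp-dependent basal recruitment per gene.

    exp_j = (1-f)*exp_free + f*exp_ppgpp; loss = ln2/tau + ln2/t_half
    (both in 1/s); alpha = exp_j * loss / n_genes with the replication
    dosage factor.
    """
    f = fraction_bound(binding, ppgpp_conc)
    tau = float(tau_interp(ppgpp_conc))
    if np.isnan(tau):
        raise DomainError(f"ppGpp {ppgpp_conc} µM outside the growth-law interpolation range")
    out = {}
    ln2 = np.log(2.0)
    for gene in params.genes:
        exp_j = (1.0 - f) * params.exp_free[gene] + f * params.exp_ppgpp[gene]
        t_half = params.rna_halflife_s.get(gene, np.inf)
        loss = ln2 / (tau * 60.0) + (ln2 / t_half if np.isfinite(t_half) else 0.0)
        n_genes = gene_dosage(tau, params.gene_position.get(gene, 0.5), C_min, D_min)
        out[gene] = exp_j * loss / n_genes
    return out
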