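"""Single-step amino-acid biosynthesis network: rate laws and parameter fitting.

The network abstracts every biosynthesis pathway to one reaction step per
amino acid, rooted at glutamate (treated as upstream of all pathways).
Synthesis is end-product inhibited and saturated by upstream amino acids;
each amino acid may additionally carry at most one loss reaction (a reverse
reaction or a degradation reaction).  Forward/loss rate constants and
environmental exchange rates are fitted jointly against two anchor
conditions (minimal and rich media) under steady-state mass balances.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .errors import DomainError, FitError, IdentifierError

LOSS_KINDS = ("none", "reverse", "degradation")


@dataclass(frozen=True)
class AANetwork:
    """Topology of the single-step amino-acid reaction network.

    ``upstream[i]`` holds the amino acids whose concentrations saturate the
    synthesis of ``i``; ``downstream`` is the exact inverse relation.  The
    forward edges must form a DAG reachable from ``root``.
    """

    amino_acids: tuple[str, ...]
    upstream: Mapping[str, frozenset[str]]
    root: str = "GLU"
    loss_kind: Mapping[str, str] = field(default_factory=dict)

    def __post_init__(self):
        ids = set(self.amino_acids)
        if self.root not in ids:
            raise IdentifierError(f"root {self.root!r} not among amino acids")
        for aa, ups in self.upstream.items():
            if aa not in ids:
                raise IdentifierError(f"unknown amino acid {aa!r} in upstream map")
            unknown = set(ups) - ids
            if unknown:
                raise IdentifierError(f"unknown upstream ids {sorted(unknown)} for {aa!r}")
        for aa, kind in self.loss_kind.items():
            if kind not in LOSS_KINDS:
                raise DomainError(f"loss_kind for {aa!r} must be one of {LOSS_KINDS}")
        self._check_dag()

    @property
    def downstream(self) -> dict[str, frozenset[str]]:
        down: dict[str, set[str]] = {aa: set() for aa in self.amino_acids}
        for aa, ups in self.upstream.items():
            for up in ups:
                down[up].add(aa)
        return {aa: frozenset(v) for aa, v in down.items()}

    def loss_of(self, aa: str) -> str:
        return self.loss_kind.get(aa, "none")

    def index(self, aa: str) -> int:
        try:
            return self.amino_acids.index(aa)
        except ValueError:
            raise IdentifierError(f"unknown amino acid {aa!r}") from None

    def _check_dag(self):
        # Kahn topological sort over forward (upstream -> downstream) edges.
        down = self.downstream
        indeg = {aa: len(self.upstream.get(aa, ())) for aa in self.amino_acids}
        queue = [aa for aa in self.amino_acids if indeg[aa] == 0]
        seen = 0
        order = []
        while queue:
            aa = queue.pop()
            order.append(aa)
            seen += 1
            for child in down[aa]:
                indeg[child] -= 1
                if indeg[child] == 0:
                    queue.append(child)
        if seen != len(self.amino_acids):
            raise DomainError("forward edges of the amino-acid network contain a cycle")
        object.__setattr__(self, "_topo_order", tuple(order))

    @property
    def topological_order(self) -> tuple[str, ...]:
        """Amino acids ordered so every upstream AA precedes its downstream AAs."""
        return self._topo_order  # type: ignore[attr-defined]


@dataclass
class AAKinetics:
    """Kinetic constants of the biosynthesis network (all µM / 1/s units).

    ``inhibition_scale`` multiplies the end-product inhibition constant;
    1.0 is wildtype and ``inf`` removes inhibition entirely.
    """

    kcat_f: dict[str, float]
    kcat_loss: dict[str, float]
    K_I: dict[str, float]
    K_M_up: dict[tuple[str, str], float]
    K_M_loss: dict[str, float]
    inhibition_scale: dict[str, float] = field(default_factory=dict)

    def __post_init__(self):
        for name, mapping in (("K_I", self.K_I), ("K_M_loss", self.K_M_loss)):
            for aa, v in mapping.items():
                if not v > 0:
                    raise DomainError(f"{name}[{aa!r}] must be > 0, got {v}")
        for key, v in self.K_M_up.items():
            if not v > 0:
                raise DomainError(f"K_M_up[{key!r}] must be > 0, got {v}")
        for name, mapping in (("kcat_f", self.kcat_f), ("kcat_loss", self.kcat_loss)):
            for aa, v in mapping.items():
                if v < 0:
                    raise DomainError(f"{name}[{aa!r}] must be >= 0, got {v}")
        for aa, s in self.inhibition_scale.items():
            if s < 1:
                raise DomainError(f"inhibition_scale[{aa!r}] must be >= 1, got {s}")

    def scale_of(self, aa: str) -> float:
        return self.inhibition_scale.get(aa, 1.0)


@dataclass
class ConditionTable:
    """Per-condition concentrations and literature anchors.

    Columns mirror the CSV interface: amino-acid concentration (µM), pooled
    enzyme concentration (µM), translation demand S (µM/s), literature
    exchange rate (µM/s) and literature kcat (1/s).
    """

    name: str
    aa_conc: dict[str, float]
    enzyme_conc: dict[str, float]
    demand: dict[str, float]
    v_exchange_lit: dict[str, float] = field(default_factory=dict)
    kcat_lit: dict[str, float] = field(default_factory=dict)

    def __post_init__(self):
        for label, mapping in (("aa_conc", self.aa_conc), ("enzyme_conc", self.enzyme_conc),
                               ("demand", self.demand)):
            for aa, v in mapping.items():
                if v < 0:
                    raise DomainError(f"{label}[{aa!r}] must be >= 0, got {v}")


def _saturation(conc: float, km: float) -> float:
    """Upstream saturation conc/(conc + K), algebraically 0 at conc = 0."""
    if conc == 0:
        return 0.0
    return conc / (conc + km)


def _inhibition(conc: float, ki: float, scale: float) -> float:
    """End-product inhibition factor 1/(1 + conc/(scale*K_I))."""
    if math.isinf(scale):
        return 1.0
    return 1.0 / (1.0 + conc / (scale * ki))


def synthesis_capacity(net: AANetwork, kin: AAKinetics, aa_conc: Mapping[str, float],
                       enzyme_conc: Mapping[str, float]) -> dict[str, float]:
    """Saturation-weighted enzyme capacity C_synth = v_synth / kcat_f per AA."""
    caps = {}
    for aa in net.amino_acids:
        conc = _get_conc(aa_conc, aa)
        e = _get_conc(enzyme_conc, aa)
        factor = _inhibition(conc, kin.K_I[aa], kin.scale_of(aa))
        for up in net.upstream.get(aa, ()):  # product over upstream saturations
            factor *= _saturation(_get_conc(aa_conc, up), kin.K_M_up[(aa, up)])
        caps[aa] = e * factor
    return caps


def loss_capacity(net: AANetwork, kin: AAKinetics, aa_conc: Mapping[str, float],
                  enzyme_conc: Mapping[str, float]) -> dict[str, float]:
    """Saturation-weighted enzyme capacity of the loss reaction, C_loss = v_loss / kcat_loss."""
    caps = {}
    for aa in net.amino_acids:
        if net.loss_of(aa) == "none":
            caps[aa] = 0.0
        else:
            caps[aa] = _get_conc(enzyme_conc, aa) * _saturation(
                _get_conc(aa_conc, aa), kin.K_M_loss[aa])
    return caps


def _get_conc(mapping: Mapping[str, float], aa: str) -> float:
    try:
        v = mapping[aa]
    except KeyError:
        raise IdentifierError(f"unknown amino acid {aa!r}") from None
    if v < 0:
        raise DomainError(f"negative concentration {v} for {aa!r}")
    return v


def synthesis_rate(net: AANetwork, kin: AAKinetics, aa_conc: Mapping[str, float],
                   enzyme_conc: Mapping[str, float]) -> dict[str, float]:
    """v_synth = kcat_f * E * inhibition(AA) * prod(upstream saturations), µM/s."""
    caps = synthesis_capacity(net, kin, aa_conc, enzyme_conc)
    return {aa: kin.kcat_f.get(aa, 0.0) * caps[aa] for aa in net.amino_acids}


def loss_rates(net: AANetwork, kin: AAKinetics, aa_conc: Mapping[str, float],
               enzyme_conc: Mapping[str, float], v_synth: Mapping[str, float]
               ) -> tuple[dict[str, float], dict[str, float]]:
    """Per-AA (v_down, v_loss).

    ``v_down`` sums the synthesis rates of the immediate downstream amino
    acids only; ``v_loss`` is the reverse-or-degradation Michaelis–Menten
    rate, zero when the amino acid carries no loss reaction.
    """
    down = net.downstream
    v_down = {aa: sum(v_synth[j] for j in down[aa]) for aa in net.amino_acids}
    caps = loss_capacity(net, kin, aa_conc, enzyme_conc)
    v_loss = {aa: kin.kcat_loss.get(aa, 0.0) * caps[aa] for aa in net.amino_acids}
    return v_down, v_loss


def supply_rate(net: AANetwork, kin: AAKinetics, aa_conc: Mapping[str, float],
                enzyme_conc: Mapping[str, float],
                v_exchange: Mapping[str, float] | None = None) -> dict[str, float]:
    """Net supply to translation: v_synth - v_down - v_loss + v_exchange (may be negative)."""
    v_synth = synthesis_rate(net, kin, aa_conc, enzyme_conc)
    v_down, v_loss = loss_rates(net, kin, aa_conc, enzyme_conc, v_synth)
    ex = v_exchange or {}
    return {aa: v_synth[aa] - v_down[aa] - v_loss[aa] + ex.get(aa, 0.0)
            for aa in net.amino_acids}


def assign_default_constants(net: AANetwork, minimal_conc: Mapping[str, float],
                             curated_K_M_up: Mapping[tuple[str, str], float] | None = None,
                             curated_K_M_loss: Mapping[str, float] | None = None,
                             curated_K_I_bounds: Mapping[str, tuple[float, float]] | None = None,
                             ) -> AAKinetics:
    """Fill in saturation constants from minimal-media concentrations.

    Uncurated upstream K_M values default to the minimal-media concentration
    (high dynamic range); uncurated loss K_M values default to 10x that
    concentration (limited loss at physiological levels).  K_I is the
    minimal-media concentration clamped to the curated bounds when present.
    """
    curated_K_M_up = dict(curated_K_M_up or {})
    curated_K_M_loss = dict(curated_K_M_loss or {})
    curated_K_I_bounds = dict(curated_K_I_bounds or {})
    for aa in net.amino_acids:
        if not _get_conc(minimal_conc, aa) > 0:
            raise DomainError(f"minimal-media concentration of {aa!r} must be > 0")

    K_M_up = {}
    for aa in net.amino_acids:
        for up in net.upstream.get(aa, ()):
            K_M_up[(aa, up)] = curated_K_M_up.get((aa, up), minimal_conc[up])
    K_M_loss = {}
    for aa in net.amino_acids:
        if net.loss_of(aa) != "none":
            K_M_loss[aa] = curated_K_M_loss.get(aa, 10.0 * minimal_conc[aa])
    K_I = {}
    for aa in net.amino_acids:
        conc = minimal_conc[aa]
        bounds = curated_K_I_bounds.get(aa)
        if bounds is None:
            K_I[aa] = conc
        else:
            lo, hi = bounds
            if lo > hi:
                raise DomainError(f"empty K_I bounds interval for {aa!r}: [{lo}, {hi}]")
            K_I[aa] = min(max(conc, lo), hi)
    return AAKinetics(kcat_f={}, kcat_loss={}, K_I=K_I, K_M_up=K_M_up, K_M_loss=K_M_loss)


@dataclass
class KcatFitResult:
    """Outcome of the joint kcat / exchange fit."""

    kcat_f: dict[str, float]
    kcat_loss: dict[str, float]
    v_exchange: dict[str, float]
    residuals: dict[str, dict[str, float]]  # per-AA balance violations per condition
    objective: float


def fit_kcats_and_exchange(net: AANetwork, kin: AAKinetics,
                           cond_minimal: ConditionTable, cond_rich: ConditionTable,
                           weight: float = 1000.0) -> KcatFitResult:
    """Fit nonnegative kcats and exchange rates against the two mass balances.

    At steady state each amino acid must satisfy, in minimal media,
    ``kcat_f*C_synth - kcat_loss*C_loss = S + v_down`` and in rich media the
    same balance minus the exchange rate.  Capacities are saturation-weighted
    enzyme concentrations evaluated at each condition's concentrations.  The
    objective trades a heavy penalty on departing from literature exchange
    rates against matching literature kcats and keeping loss kcats small:
    ``weight*||v_ex - v_ex_lit|| + ||kcat_f - kcat_lit|| + ||kcat_loss||``.

    Because ``v_down`` of an amino acid depends only on the fitted forward
    kcats of its immediate downstream amino acids, the problem decomposes
    exactly when solved in reverse topological order (leaves first); each
    per-AA subproblem is a one-dimensional piecewise-linear minimization in
    the exchange rate, solved exactly at its breakpoints.
    """
    caps_syn = {c.name: synthesis_capacity(net, kin, c.aa_conc, c.enzyme_conc)
                for c in (cond_minimal, cond_rich)}
    caps_loss = {c.name: loss_capacity(net, kin, c.aa_conc, c.enzyme_conc)
                 for c in (cond_minimal, cond_rich)}
    mname, rname = cond_minimal.name, cond_rich.name

    kcat_f: dict[str, float] = {}
    kcat_loss: dict[str, float] = {}
    v_exchange: dict[str, float] = {}
    objective = 0.0

    # children before parents: v_down needs fitted downstream kcat_f
    down = net.downstream
    for aa in reversed(net.topological_order):
        vdown_m = sum(kcat_f[j] * caps_syn[mname][j] for j in down[aa])
        vdown_r = sum(kcat_f[j] * caps_syn[rname][j] for j in down[aa])
        b_m = cond_minimal.demand[aa] + vdown_m
        b_r = cond_rich.demand[aa] + vdown_r
        cs_m, cs_r = caps_syn[mname][aa], caps_syn[rname][aa]
        cl_m, cl_r = caps_loss[mname][aa], caps_loss[rname][aa]
        kf_lit = cond_minimal.kcat_lit.get(aa, cond_rich.kcat_lit.get(aa, 1.0))
        ex_lit = cond_rich.v_exchange_lit.get(aa, cond_minimal.v_exchange_lit.get(aa, 0.0))

        try:
            kf, kl, ex, obj = _fit_single_aa(
                net.loss_of(aa) != "none", cs_m, cs_r, cl_m, cl_r, b_m, b_r,
                kf_lit, ex_lit, weight)
        except FitError as err:
            raise FitError(f"kcat fit infeasible for amino acid {aa!r}: {err}",
                           diagnostics={aa: {"b_minimal": b_m, "b_rich": b_r,
                                             "C_synth_minimal": cs_m, "C_synth_rich": cs_r}},
                           ) from err
        kcat_f[aa] = kf
        kcat_loss[aa] = kl
        v_exchange[aa] = ex
        objective += obj

    # residual report: balance violations at the fitted parameters
    fitted = AAKinetics(kcat_f=kcat_f, kcat_loss=kcat_loss, K_I=kin.K_I,
                        K_M_up=kin.K_M_up, K_M_loss=kin.K_M_loss,
                        inhibition_scale=dict(kin.inhibition_scale))
    residuals: dict[str, dict[str, float]] = {}
    for cond, use_ex in ((cond_minimal, False), (cond_rich, True)):
        ex = v_exchange if use_ex else {aa: 0.0 for aa in net.amino_acids}
        supply = supply_rate(net, fitted, cond.aa_conc, cond.enzyme_conc, ex)
        residuals[cond.name] = {aa: supply[aa] - cond.demand[aa] for aa in net.amino_acids}

    return KcatFitResult(kcat_f=kcat_f, kcat_loss=kcat_loss, v_exchange=v_exchange,
                         residuals=residuals, objective=objective)


def _fit_single_aa(has_loss: bool, cs_m: float, cs_r: float, cl_m: float, cl_r: float,
                   b_m: float, b_r: float, kf_lit: float, ex_lit: float,
                   weight: float) -> tuple[float, float, float, float]:
    """Exact solution of one per-AA subproblem.

    Constraints: kf*cs_m - kl*cl_m = b_m and kf*cs_r - kl*cl_r = b_r - ex
    with kf, kl >= 0 and ex free.  For fixed ex the kcats are affine in ex,
    so the objective weight*|ex - ex_lit| + |kf - kf_lit| + |kl| is convex
    piecewise linear in ex; evaluate it at all breakpoints and box edges.
    """
    if not has_loss:
        # kl fixed at 0: kf from the minimal balance, ex absorbs the rich slack.
        if cs_m <= 0:
            if b_m != 0:
                raise FitError("zero synthesis capacity in minimal media with nonzero demand")
            kf = max(kf_lit, 0.0)
        else:
            kf = b_m / cs_m
            if kf < 0:
                raise FitError("negative forward kcat required (net drain exceeds synthesis)")
        ex = b_r - kf * cs_r
        obj = weight * abs(ex - ex_lit) + abs(kf - kf_lit)
        return kf, 0.0, ex, obj

    det = -cs_m * cl_r + cs_r * cl_m
    if abs(det) < 1e-300:
        raise FitError("singular capacity system (proportional capacities across conditions)")
    # [kf; kl] = M^-1 [b_m; b_r - ex]  ->  affine in ex
    #   kf(ex) = (-cl_r*b_m + cl_m*(b_r - ex)) / det
    #   kl(ex) = (-cs_r*b_m + cs_m*(b_r - ex)) / det
    kf0 = (-cl_r * b_m + cl_m * b_r) / det
    kf1 = -cl_m / det
    kl0 = (-cs_r * b_m + cs_m * b_r) / det
    kl1 = -cs_m / det

    def interval(c0: float, c1: float) -> tuple[float, float]:
        # feasible ex range for c0 + c1*ex >= 0
        if c1 == 0:
            return (-math.inf, math.inf) if c0 >= -1e-12 else (math.nan, math.nan)
        bound = -c0 / c1
        return (bound, math.inf) if c1 > 0 else (-math.inf, bound)

    lo, hi = -math.inf, math.inf
    for c0, c1 in ((kf0, kf1), (kl0, kl1)):
        a, b = interval(c0, c1)
        if math.isnan(a):
            raise FitError("no nonnegative kcat solution for any exchange rate")
        lo, hi = max(lo, a), min(hi, b)
    if lo > hi:
        raise FitError("no nonnegative kcat solution for any exchange rate")

    def objective(ex: float) -> float:
        kf = kf0 + kf1 * ex
        kl = kl0 + kl1 * ex
        return weight * abs(ex - ex_lit) + abs(kf - kf_lit) + abs(kl)

    candidates = [ex_lit]
    if kf1 != 0:
        candidates.append((kf_lit - kf0) / kf1)  # kf == kf_lit breakpoint
        candidates.append(-kf0 / kf1)            # kf == 0
    if kl1 != 0:
        candidates.append(-kl0 / kl1)            # kl == 0
    candidates.extend(x for x in (lo, hi) if math.isfinite(x))
    feasible = [x for x in candidates if lo - 1e-12 <= x <= hi + 1e-12]
    if not feasible:
        raise FitError("empty candidate set for exchange rate")
    best = min(feasible, key=objective)
    best = min(max(best, lo), hi)
    kf = max(kf0 + kf1 * best, 0.0)
    kl = max(kl0 + kl1 * best, 0.0)
    return kf, kl, best, objective(best)
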