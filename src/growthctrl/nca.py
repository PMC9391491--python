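"""Topology-constrained factorization of an expression compendium.

Decomposes a log2 expression matrix E (genes x conditions) into interaction
strengths A (genes x regulators, sparsity fixed by a signed topology mask)
and regulator activities P (regulators x conditions) by alternating
constrained least squares.  Dual regulators are split into sign-homogeneous
rows beforehand, with ambiguous edges duplicated into both.  Regulator
fold changes on genes follow from the strength times the spread between
high- and low-activity condition sets.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence
import warnings

import numpy as np

from .errors import DomainError

POS_SUFFIX = ":+"
NEG_SUFFIX = ":-"


@dataclass
class TopologyMask:
    """Signed regulator -> gene sparsity pattern.

    ``signs[r, g]`` in {+1, -1} after preprocessing; raw masks may also
    contain 0 for ambiguous regulation.
    """

    regulators: tuple[str, ...]
    genes: tuple[str, ...]
    signs: dict[tuple[str, str], int] = field(default_factory=dict)

    def __post_init__(self):
        touched = {r: 0 for r in self.regulators}
        for (r, g), s in self.signs.items():
            if r not in touched:
                raise DomainError(f"unknown regulator {r!r} in mask")
            if g not in self.genes:
                raise DomainError(f"unknown gene {g!r} in mask")
            if s not in (-1, 0, 1):
                raise DomainError(f"mask sign must be -1, 0 or +1, got {s}")
            touched[r] += 1
        empty = [r for r, n in touched.items() if n == 0]
        if empty:
            raise DomainError(f"regulators without any edge: {empty}")

    def support_matrix(self) -> np.ndarray:
        """genes x regulators boolean support."""
        gi = {g: i for i, g in enumerate(self.genes)}
        ri = {r: i for i, r in enumerate(self.regulators)}
        m = np.zeros((len(self.genes), len(self.regulators)), dtype=bool)
        for (r, g) in self.signs:
            m[gi[g], ri[r]] = True
        return m

    def sign_matrix(self) -> np.ndarray:
        gi = {g: i for i, g in enumerate(self.genes)}
        ri = {r: i for i, r in enumerate(self.regulators)}
        m = np.zeros((len(self.genes), len(self.regulators)))
        for (r, g), s in self.signs.items():
            m[gi[g], ri[r]] = s if s != 0 else 1.0
        return m


def preprocess_topology(raw: TopologyMask) -> TopologyMask:
    """Split dual/ambiguous regulators into sign-homogeneous rows.

    A regulator with edges of both signs becomes two entries (":+"/":-"
    suffixes); ambiguous (0-signed) edges are duplicated into both entries.
    Sign-homogeneous regulators pass through unchanged.
    """
    if not raw.signs:
        raise DomainError("empty topology mask")
    regulators: list[str] = []
    signs: dict[tuple[str, str], int] = {}
    for reg in raw.regulators:
        edges = {g: s for (r, g), s in raw.signs.items() if r == reg}
        pos = {g for g, s in edges.items() if s > 0}
        neg = {g for g, s in edges.items() if s < 0}
        amb = {g for g, s in edges.items() if s == 0}
        if not amb and (not pos or not neg):
            # already sign-homogeneous
            regulators.append(reg)
            sign = 1 if pos else -1
            for g in edges:
                signs[(reg, g)] = sign
            continue
        pos_set = pos | amb
        neg_set = neg | amb
        if pos_set:
            name = reg + POS_SUFFIX
            regulators.append(name)
            for g in pos_set:
                signs[(name, g)] = 1
        if neg_set:
            name = reg + NEG_SUFFIX
            regulators.append(name)
            for g in neg_set:
                signs[(name, g)] = -1
    return TopologyMask(regulators=tuple(regulators), genes=raw.genes, signs=signs)


@dataclass
class Factorization:
    A: np.ndarray           # genes x regulators, zero off-support
    P: np.ndarray           # regulators x conditions
    residual: float
    residual_history: tuple[float, ...] = ()


def solve_nca(E: np.ndarray, mask: TopologyMask, max_iter: int = 200,
              tol: float = 1e-10, seed: int | None = 0) -> Factorization:
    """Alternating constrained least squares for min ||E - A P||^2, A in the mask support.

    The P-step is an unconstrained least squares given A; the A-step solves
    per-gene least squares restricted to that gene's support.  The residual
    is non-increasing across iterations; iteration stops when its relative
    improvement falls below ``tol``.  A is initialized to the mask signs
    plus a small seeded jitter -- pure sign initialization leaves regulators
    with identical supports collinear, trapping the alternating scheme in a
    low-rank subspace.  Deterministic given ``seed``.
    """
    E = np.asarray(E, dtype=float)
    if not np.all(np.isfinite(E)):
        raise DomainError("expression matrix must be finite")
    support = mask.support_matrix()
    if E.shape[0] != support.shape[0]:
        raise DomainError("expression matrix and mask gene dimensions differ")
    n_genes, n_regs = support.shape
    if np.linalg.matrix_rank(support.astype(float)) < n_regs:
        warnings.warn("topology mask may be non-identifiable (rank-deficient support)",
                      stacklevel=2)
    rng = np.random.default_rng(seed)
    A = mask.sign_matrix()
    A[support] *= 1.0 + 0.1 * rng.random(int(support.sum()))
    history: list[float] = []
    prev = np.inf
    P = np.zeros((n_regs, E.shape[1]))
    for _ in range(max_iter):
        P, *_ = np.linalg.lstsq(A, E, rcond=None)
        for g in range(n_genes):
            cols = support[g]
            if not cols.any():
                continue
            sol, *_ = np.linalg.lstsq(P[cols].T, E[g], rcond=None)
            A[g, cols] = sol
        res = float(np.linalg.norm(E - A @ P))
        history.append(res)
        if prev - res <= tol * max(res, 1.0):
            break
        prev = res
    return Factorization(A=A, P=P, residual=history[-1], residual_history=tuple(history))


def normalize_factorization(fact: Factorization) -> Factorization:
    """Standardize each P row to unit variance, absorbing the scale into A."""
    P = fact.P.copy()
    A = fact.A.copy()
    sd = P.std(axis=1)
    for j, s in enumerate(sd):
        if s > 0:
            P[j] /= s
            A[:, j] *= s
    return Factorization(A=A, P=P, residual=fact.residual,
                         residual_history=fact.residual_history)


def activity_extremes(p_row: np.ndarray, min_count: int = 10) -> tuple[float, float]:
    """Mean activity of the high and low condition sets for one regulator.

    The high set unions conditions strictly above mean + sd with the top
    ``min_count`` activities; the low set is the mirror image.
    """
    p = np.asarray(p_row, dtype=float)
    if len(p) < min_count:
        raise DomainError(f"activity extremes need >= {min_count} conditions, got {len(p)}")
    mean, sd = p.mean(), p.std()
    order = np.argsort(p)
    top = set(order[-min_count:].tolist())
    bottom = set(order[:min_count].tolist())
    high = {i for i in range(len(p)) if p[i] > mean + sd} | top
    low = {i for i in range(len(p)) if p[i] < mean - sd} | bottom
    return float(p[sorted(high)].mean()), float(p[sorted(low)].mean())


def fold_change(a_entry: float, p_high: float, p_low: float) -> float:
    """log2 fold change of a regulator on a gene: A_ij * (P_high - P_low)."""
    return a_entry * (p_high - p_low)


def extract_fold_changes(fact: Factorization, mask: TopologyMask,
                         min_count: int = 10) -> dict[tuple[str, str], float]:
    """All per-edge fold changes from a normalized factorization."""
    gi = {g: i for i, g in enumerate(mask.genes)}
    ri = {r: i for i, r in enumerate(mask.regulators)}
    extremes = {r: activity_extremes(fact.P[ri[r]], min_count) for r in mask.regulators}
    out = {}
    for (r, g) in mask.signs:
        hi, lo = extremes[r]
        out[(r, g)] = fold_change(fact.A[gi[g], ri[r]], hi, lo)
    return out
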