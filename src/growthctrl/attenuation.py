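"""Charged-tRNA-dependent transcriptional attenuation.

Termination at the attenuation site is a Poissonian stop event whose
probability rises with the charged tRNA pools of the regulating amino acids
(tRNA species per amino acid are summed and share one constant).  Strength
constants are back-calculated from repression fold changes at rich-media
charged-tRNA levels, basal recruitment probabilities are compensated upward
so expected completion matches the unattenuated parameterization, and
per-transcript termination is sampled from a seeded uniform stream.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping

import numpy as np

from .errors import DomainError


@dataclass
class AttenuationParams:
    """K[gene, amino_acid] attenuation constants (µM) over the attenuated genes."""

    K: dict[tuple[str, str], float]

    def __post_init__(self):
        for key, v in self.K.items():
            if not v > 0:
                raise DomainError(f"attenuation K{key!r} must be > 0, got {v}")

    @property
    def genes(self) -> frozenset[str]:
        return frozenset(g for g, _ in self.K)


def p_stop(params: AttenuationParams, charged_trna_by_aa: Mapping[str, float]
           ) -> dict[str, float]:
    """Per-gene stop probability 1 - exp(-sum_j tRNA_j / K_gene,j), in [0, 1)."""
    out: dict[str, float] = {}
    for (gene, aa), k in params.K.items():
        conc = charged_trna_by_aa[aa]
        if conc < 0:
            raise DomainError(f"negative charged tRNA pool for {aa!r}")
        out[gene] = out.get(gene, 0.0) + conc / k
    return {g: 1.0 - math.exp(-s) for g, s in out.items()}


def fit_K(fc: Mapping[tuple[str, str], float],
          trna_rich_by_aa: Mapping[str, float]) -> AttenuationParams:
    """Back-calculate K from repression fold changes at rich tRNA levels.

    FC is the read-through fraction at rich charged-tRNA levels relative to
    zero charged tRNA, so FC = exp(-tRNA_rich/K) and K = -tRNA_rich/ln(FC)
    (positive for repressing fold changes 0 < FC < 1).
    """
    K: dict[tuple[str, str], float] = {}
    for (gene, aa), fc_val in fc.items():
        if not 0.0 < fc_val < 1.0:
            raise DomainError(
                f"attenuation fold change for gene {gene!r} must lie in (0, 1), got {fc_val}")
        K[(gene, aa)] = -trna_rich_by_aa[aa] / math.log(fc_val)
    return AttenuationParams(K=K)


def adjust_basal(alpha: Mapping[str, float],
                 p_stop_expected: Mapping[str, float]) -> dict[str, float]:
    """Compensate basal recruitment for expected attenuation losses.

    alpha_adjusted = alpha / (1 - P_stop), so that
    (1 - P_stop) * alpha_adjusted == alpha exactly.
    """
    out = {}
    for gene, a in alpha.items():
        p = p_stop_expected.get(gene, 0.0)
        if not 0.0 <= p < 1.0:
            raise DomainError(f"expected P_stop for {gene!r} must lie in [0, 1), got {p}")
        out[gene] = a / (1.0 - p)
    return out


def sample_termination(p_stop_per_transcript: np.ndarray,
                       rng: np.random.Generator) -> np.ndarray:
    """Boolean stop flags: uniform draw below the stop probability terminates."""
    p = np.asarray(p_stop_per_transcript, dtype=float)
    return rng.random(p.shape) < p
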