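"""Phenomenological amino-acid supply, used when mechanistic supply is off.

Supply is a per-condition base rate scaled by a concentration-responsive
factor made of a constant base-synthesis term, an end-product-inhibited
synthesis term, a media-gated import constant and a saturating export term.
The four constants per amino acid follow in closed form from two anchor
fractions: f_I (inhibited-synthesis share at the basal concentration) and
f_M (export share at the rich concentration), chosen so the scaling factor
is exactly 1 at both anchor states.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

from .errors import DomainError, IdentifierError


@dataclass
class PhenoParams:
    c1: dict[str, float]
    c2: dict[str, float]
    K_I: dict[str, float]
    K_M: dict[str, float]
    f_I: float
    f_M: float
    # per condition name -> per-AA base supply rate (µM/s)
    v_supply_media: dict[str, dict[str, float]] = field(default_factory=dict)


def solve_pheno_params(f_I: float, f_M: float, basal_conc: Mapping[str, float],
                       rich_conc: Mapping[str, float],
                       v_supply_media: Mapping[str, Mapping[str, float]] | None = None,
                       ) -> PhenoParams:
    """Closed-form constants from the two anchor fractions.

    K_I = f_I*basal/(1-f_I); K_M = (1/f_M - 1)*rich;
    c1 = 1 - (f_I - basal/(K_M+basal));
    c2 = 1 - (c1 + 1/(1+rich/K_I) - f_M).
    """
    if not (0.0 < f_I < 1.0 and 0.0 < f_M < 1.0):
        raise DomainError(f"f_I and f_M must lie in (0, 1), got {f_I}, {f_M}")
    c1, c2, K_I, K_M = {}, {}, {}, {}
    for aa in basal_conc:
        basal = basal_conc[aa]
        rich = rich_conc[aa]
        if basal <= 0 or rich <= 0:
            raise DomainError(f"anchor concentrations for {aa!r} must be > 0")
        K_I[aa] = f_I * basal / (1.0 - f_I)
        K_M[aa] = (1.0 / f_M - 1.0) * rich
        c1[aa] = 1.0 - (f_I - basal / (K_M[aa] + basal))
        c2[aa] = 1.0 - (c1[aa] + 1.0 / (1.0 + rich / K_I[aa]) - f_M)
    media = {name: dict(rates) for name, rates in (v_supply_media or {}).items()}
    return PhenoParams(c1=c1, c2=c2, K_I=K_I, K_M=K_M, f_I=f_I, f_M=f_M,
                       v_supply_media=media)


def supply_scaling(params: PhenoParams, aa_conc: Mapping[str, float],
                   media: Mapping[str, bool]) -> dict[str, float]:
    """Dimensionless f_supply = c1 + inhibited synthesis + gated import - export."""
    out = {}
    for aa, conc in aa_conc.items():
        if conc < 0:
            raise DomainError(f"negative concentration {conc} for {aa!r}")
        f = params.c1[aa] + 1.0 / (1.0 + conc / params.K_I[aa])
        if media.get(aa, False):
            f += params.c2[aa]
        f -= conc / (params.K_M[aa] + conc)
        out[aa] = f
    return out


def pheno_supply_rate(params: PhenoParams, condition: str,
                      aa_conc: Mapping[str, float], media: Mapping[str, bool]
                      ) -> dict[str, float]:
    """v_supply = f_supply * v_supply_media for the active condition."""
    try:
        base = params.v_supply_media[condition]
    except KeyError:
        raise IdentifierError(f"unknown condition {condition!r}") from None
    scaling = supply_scaling(params, aa_conc, media)
    return {aa: scaling[aa] * base[aa] for aa in aa_conc}
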