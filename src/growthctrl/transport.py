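"""Mechanistic amino-acid import/export rate laws and their calibration.

Uptake is inhibited by the internal amino-acid concentration; export follows
Michaelis–Menten kinetics.  Multiple transporters for one amino acid are
pooled and share a single parameter set.  Import kcat and export kcat are
calibrated per amino acid from two anchor points: at rich-media internal
concentrations exchange equals the rate fitted by the biosynthesis module,
and at an internal concentration equal to the export K_M exchange is zero
(which is how curated export K_M values are defined).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping

from .errors import DomainError, FitError


@dataclass
class TransportParams:
    """Per-AA transport constants; ``importable`` is False for cysteine-like AAs."""

    kcat_im: dict[str, float]
    kcat_ex: dict[str, float]
    K_I_im: dict[str, float]
    K_M_ex: dict[str, float]
    importable: dict[str, bool] = field(default_factory=dict)

    def __post_init__(self):
        for name, mapping in (("kcat_im", self.kcat_im), ("kcat_ex", self.kcat_ex)):
            for aa, v in mapping.items():
                if v < 0:
                    raise DomainError(f"{name}[{aa!r}] must be >= 0, got {v}")
        for aa, flag in self.importable.items():
            if not flag and self.kcat_im.get(aa, 0.0) != 0.0:
                raise DomainError(f"{aa!r} is not importable but has kcat_im != 0")

    def is_importable(self, aa: str) -> bool:
        return self.importable.get(aa, True)


@dataclass
class TransporterPools:
    """Pooled importer/exporter concentrations (µM) per amino acid."""

    T_im: dict[str, float]
    T_ex: dict[str, float]

    def __post_init__(self):
        for name, mapping in (("T_im", self.T_im), ("T_ex", self.T_ex)):
            for aa, v in mapping.items():
                if v < 0:
                    raise DomainError(f"{name}[{aa!r}] must be >= 0, got {v}")


def import_rate(params: TransportParams, pools: TransporterPools,
                aa: str, conc: float, present_in_media: bool) -> float:
    """Inhibited uptake; zero when the AA is absent from media or not importable."""
    if conc < 0:
        raise DomainError(f"negative concentration {conc} for {aa!r}")
    if not present_in_media or not params.is_importable(aa):
        return 0.0
    kcat = params.kcat_im.get(aa, 0.0)
    return kcat * pools.T_im.get(aa, 0.0) / (1.0 + conc / params.K_I_im[aa])


def export_rate(params: TransportParams, pools: TransporterPools,
                aa: str, conc: float) -> float:
    """Michaelis–Menten export; algebraically 0 at zero internal concentration."""
    if conc < 0:
        raise DomainError(f"negative concentration {conc} for {aa!r}")
    kcat = params.kcat_ex.get(aa, 0.0)
    if conc == 0 or kcat == 0:
        return 0.0
    return kcat * pools.T_ex.get(aa, 0.0) * conc / (conc + params.K_M_ex[aa])


def exchange_rate(params: TransportParams, pools: TransporterPools,
                  aa_conc: Mapping[str, float], media: Mapping[str, bool]
                  ) -> dict[str, float]:
    """Net exchange (import - export) per amino acid, µM/s."""
    out = {}
    for aa, conc in aa_conc.items():
        v_im = import_rate(params, pools, aa, conc, media.get(aa, False))
        v_ex = export_rate(params, pools, aa, conc)
        out[aa] = v_im - v_ex
    return out


def estimate_missing_export_km(known_K_M: Mapping[str, float],
                               minimal_conc: Mapping[str, float]) -> dict[str, float]:
    """Impute missing export K_M values from the curated fold-over-concentration.

    factor = mean over curated AAs of K_M / minimal-media concentration;
    each missing K_M is factor times that AA's minimal-media concentration.
    """
    if not known_K_M:
        raise DomainError("at least one curated export K_M is required")
    ratios = [known_K_M[aa] / minimal_conc[aa] for aa in known_K_M]
    factor = sum(ratios) / len(ratios)
    out = dict(known_K_M)
    for aa, conc in minimal_conc.items():
        if aa not in out:
            out[aa] = factor * conc
    return out


def fit_transport_kcats(K_I_im: Mapping[str, float], K_M_ex: Mapping[str, float],
                        pools: TransporterPools, rich_conc: Mapping[str, float],
                        v_exchange_fit: Mapping[str, float],
                        importable: Mapping[str, bool] | None = None,
                        ) -> tuple[dict[str, float], dict[str, float]]:
    """Solve the per-AA 2x2 linear system for (kcat_im, kcat_ex).

    Anchor 1: at rich internal concentrations, exchange equals the fitted
    rate.  Anchor 2: at an internal concentration equal to the export K_M,
    exchange is zero.  Negative algebraic solutions are clipped to zero with
    a warning.  Non-importable amino acids get kcat_im = 0 and kcat_ex from
    anchor 1 alone.
    """
    importable = importable or {}
    kcat_im: dict[str, float] = {}
    kcat_ex: dict[str, float] = {}
    for aa, target in v_exchange_fit.items():
        conc_r = rich_conc[aa]
        km = K_M_ex[aa]
        t_im = pools.T_im.get(aa, 0.0)
        t_ex = pools.T_ex.get(aa, 0.0)
        sat_im_rich = 1.0 / (1.0 + conc_r / K_I_im[aa])
        sat_ex_rich = conc_r / (conc_r + km)

        if not importable.get(aa, True):
            kcat_im[aa] = 0.0
            if target == 0:
                kcat_ex[aa] = 0.0
                continue
            if t_ex * sat_ex_rich == 0:
                raise FitError(f"zero exporter pool for non-importable {aa!r} "
                               f"with nonzero target exchange")
            k = -target / (t_ex * sat_ex_rich)
            if k < 0:
                warnings.warn(f"clipping negative kcat_ex to 0 for {aa!r}", stacklevel=2)
                k = 0.0
            kcat_ex[aa] = k
            continue

        # rows: [T_im*sat_im_rich, -T_ex*sat_ex_rich] . [kim, kex] = target
        #       [T_im*sat_im_km,   -T_ex*0.5        ] . [kim, kex] = 0
        sat_im_km = 1.0 / (1.0 + km / K_I_im[aa])
        a11, a12 = t_im * sat_im_rich, -t_ex * sat_ex_rich
        a21, a22 = t_im * sat_im_km, -t_ex * 0.5
        det = a11 * a22 - a12 * a21
        if abs(det) < 1e-300:
            if target == 0:
                kcat_im[aa] = 0.0
                kcat_ex[aa] = 0.0
                continue
            raise FitError(f"singular transport system for {aa!r} (zero transporter pools?)")
        kim = a22 * target / det
        kex = -a21 * target / det
        for name, k in (("kcat_im", kim), ("kcat_ex", kex)):
            if k < -1e-15:
                warnings.warn(f"clipping negative {name} to 0 for {aa!r}", stacklevel=2)
        kcat_im[aa] = max(kim, 0.0)
        kcat_ex[aa] = max(kex, 0.0)
    return kcat_im, kcat_ex
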