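"""Synthetic fixture generators: every module is testable without downloads.

All generators are pure functions of a ``FixtureSpec`` (seed mandatory), so
fixtures document their own provenance and identical specs produce identical
outputs.  ``build_default_cell`` assembles a fully parameterized 4-amino-acid
host cell by running the package's own fitting pipeline end to end.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import attenuation as att
from . import biosynthesis as bio
from . import cell as cell_mod
from . import charging as chg
from . import nca
from . import pheno_supply as pheno
from . import ppgpp as ppg
from . import transcription as txn
from . import transport as trn
from .errors import DomainError


@dataclass(frozen=True)
class FixtureSpec:
    """Declarative description of a synthetic fixture."""

    seed: int
    n_aa: int = 3
    topology: str = "chain"             # "chain" | "branch"
    noise: float = 0.0
    n_conditions: int = 12
    n_genes: int = 20
    n_regulators: int = 4
    n_rows: int = 8                     # growth-law table rows

    def __post_init__(self):
        if self.topology not in ("chain", "branch"):
            raise DomainError(f"unknown topology {self.topology!r}")
        if self.n_aa < 2:
            raise DomainError("need at least 2 amino acids")


# ---------------------------------------------------------------------------
# toy amino-acid networks with self-consistent demands

def generate_toy_aa_network(spec: FixtureSpec
                            ) -> tuple[bio.AANetwork, bio.AAKinetics,
                                       bio.ConditionTable, bio.ConditionTable]:
    """Glutamate-rooted toy network with planted kcats and round-trippable demands.

    Demands and literature anchors are computed forward through the rate
    laws at both anchor conditions, so ``fit_kcats_and_exchange`` recovers
    the planted parameters exactly.
    """
    rng = np.random.default_rng(spec.seed)
    aas = ["GLU"] + [f"AA{i}" for i in range(1, spec.n_aa)]
    upstream: dict[str, frozenset[str]] = {"GLU": frozenset()}
    if spec.topology == "chain":
        for i in range(1, spec.n_aa):
            upstream[aas[i]] = frozenset({aas[i - 1]})
    else:  # branch: everything hangs off the root, except one chained leaf
        for i in range(1, spec.n_aa):
            parent = aas[0] if i < spec.n_aa - 1 else aas[1]
            upstream[aas[i]] = frozenset({parent})
    loss_cycle = ("none", "reverse", "degradation")
    loss_kind = {aa: loss_cycle[i % 3] for i, aa in enumerate(aas)}
    net = bio.AANetwork(amino_acids=tuple(aas), upstream=upstream, root="GLU",
                        loss_kind=loss_kind)

    minimal_conc = {aa: float(rng.uniform(50, 500)) for aa in aas}
    rich_conc = {aa: 2.0 * c for aa, c in minimal_conc.items()}
    kin = bio.assign_default_constants(net, minimal_conc)

    # plant positive minimal-media demands, then solve kcat_f forward so the
    # minimal balance holds by construction (children before parents, since
    # the parent's balance absorbs the children's fitted synthesis)
    enzyme = {aa: float(rng.uniform(5, 15)) for aa in aas}
    s_min = {aa: float(rng.uniform(5, 30)) for aa in aas}
    kcat_loss = {aa: (float(rng.uniform(0.05, 0.3)) if loss_kind[aa] != "none" else 0.0)
                 for aa in aas}
    caps_min = bio.synthesis_capacity(net, kin, minimal_conc, enzyme)
    closs_min = bio.loss_capacity(net, kin, minimal_conc, enzyme)
    kcat_f: dict[str, float] = {}
    down = net.downstream
    for aa in reversed(net.topological_order):
        vdown = sum(kcat_f[j] * caps_min[j] for j in down[aa])
        kcat_f[aa] = (s_min[aa] + vdown + kcat_loss[aa] * closs_min[aa]) / caps_min[aa]
    planted = bio.AAKinetics(kcat_f=kcat_f, kcat_loss=kcat_loss, K_I=kin.K_I,
                             K_M_up=kin.K_M_up, K_M_loss=kin.K_M_loss)

    # rich-media demands follow forward, with exchange chosen to keep them positive
    balance_rich = bio.supply_rate(net, planted, rich_conc, enzyme)
    v_exchange = {aa: max(float(rng.uniform(0, 20)), 1.0 - balance_rich[aa])
                  for aa in aas}
    s_rich = {aa: balance_rich[aa] + v_exchange[aa] for aa in aas}
    if any(v < 0 for v in s_rich.values()):
        raise DomainError("planted parameters produced a negative demand")
    cond_min = bio.ConditionTable(name="minimal", aa_conc=minimal_conc, enzyme_conc=enzyme,
                                  demand=s_min, v_exchange_lit={aa: 0.0 for aa in aas},
                                  kcat_lit=dict(kcat_f))
    cond_rich = bio.ConditionTable(name="rich", aa_conc=rich_conc, enzyme_conc=enzyme,
                                   demand=s_rich, v_exchange_lit=dict(v_exchange),
                                   kcat_lit=dict(kcat_f))
    return net, planted, cond_min, cond_rich


# ---------------------------------------------------------------------------
# growth-law table

def generate_growth_law_table(spec: FixtureSpec, K_M: float = 35.0,
                              exp_free: float = 0.05, exp_ppgpp: float = 0.005,
                              ) -> tuple[txn.GrowthLawTable, dict]:
    """Rows generated from planted (K_M, exp_free, exp_ppgpp) plus optional noise.

    Emulates the shape of population growth-law data: faster growth (shorter
    doubling time) pairs with lower ppGpp, more RNAP and a higher RNA mass
    fraction.
    """
    if spec.n_rows < 3:
        raise DomainError("growth-law table needs at least 3 rows")
    rng = np.random.default_rng(spec.seed)
    tau = np.linspace(24.0, 100.0, spec.n_rows)            # doubling times, min
    ppgpp = 10.0 + 0.9 * (tau - tau.min())                 # µM, rises with tau
    rnap = 8.0 - 0.05 * (tau - tau.min())                  # µM, falls with tau
    f = ppgpp ** 2 / (K_M ** 2 + ppgpp ** 2)
    rna_fraction = rnap * ((1 - f) * exp_free + f * exp_ppgpp)
    if spec.noise > 0:
        rna_fraction = rna_fraction * (1.0 + spec.noise * rng.standard_normal(spec.n_rows))
    table = txn.GrowthLawTable(doubling_time_min=tau, rna_mass_fraction=rna_fraction,
                               rnap_conc=rnap, ppgpp_conc=ppgpp)
    planted = {"K_M": K_M, "exp_free": exp_free, "exp_ppgpp": exp_ppgpp}
    return table, planted


# ---------------------------------------------------------------------------
# expression compendium with a planted factorization

def generate_expression_compendium(spec: FixtureSpec
                                   ) -> tuple[np.ndarray, nca.TopologyMask,
                                              nca.Factorization]:
    """E = A P (+ noise) with A respecting a random sparse signed mask."""
    if spec.n_conditions < 10:
        raise DomainError("activity-extreme extraction needs >= 10 conditions")
    rng = np.random.default_rng(spec.seed)
    genes = tuple(f"g{i}" for i in range(spec.n_genes))
    regs = tuple(f"tf{i}" for i in range(spec.n_regulators))
    signs: dict[tuple[str, str], int] = {}
    A = np.zeros((spec.n_genes, spec.n_regulators))
    for j, r in enumerate(regs):
        # each regulator touches a distinct anchor gene plus random extras,
        # keeping the support identifiable
        targets = {j % spec.n_genes}
        extra = rng.choice(spec.n_genes, size=max(2, spec.n_genes // 4), replace=False)
        targets.update(int(g) for g in extra)
        for g in targets:
            sign = 1 if rng.random() < 0.6 else -1
            signs[(r, genes[g])] = sign
            A[g, j] = sign * rng.uniform(0.5, 2.0)
    mask = nca.TopologyMask(regulators=regs, genes=genes, signs=signs)
    P = rng.standard_normal((spec.n_regulators, spec.n_conditions))
    E = A @ P
    if spec.noise > 0:
        E = E + spec.noise * rng.standard_normal(E.shape)
    planted = nca.Factorization(A=A, P=P, residual=0.0)
    return E, mask, planted


# ---------------------------------------------------------------------------
# the default host cell

#: reference geometry used to size the default cell's pools
_REF_PROTEIN_FG = 200.0
_REF_VOLUME_FL = 1.0

_MW = {
    "enzyme": 1.0e5, "transporter": 1.0e5, "synthetase": 1.0e5,
    "rnap": 4.0e5, "rela": 8.0e4, "spot": 8.0e4,
    "rprotein": 1.0e5, "other": 5.0e4,
    "ribosome": 1.5e6, "trna": 2.5e4, "nt": 3.3e2, "aa": 1.1e2,
}


def default_cell_config(seed: int = 0) -> tuple[cell_mod.CellParams, cell_mod.CellState]:
    """A fully parameterized 4-amino-acid toy cell plus a near-steady initial state.

    Every fitted constant is produced by the package's own parameterization
    pipeline: kcats and exchange from the two-condition mass-balance fit,
    transport kcats from the two-anchor calibration, the ppGpp-RNAP binding
    constant from a synthetic growth-law table, per-class expression pairs
    from fold-change/basal decomposition, SpoT constants from the half-life
    calibration, and attenuation constants from rich-media fold changes.
    """
    aas = ("GLU", "ALA", "VAL", "LEU")
    n = len(aas)
    upstream = {"GLU": frozenset(), "ALA": frozenset({"GLU"}),
                "VAL": frozenset({"ALA"}), "LEU": frozenset({"GLU"})}
    loss_kind = {"GLU": "none", "ALA": "reverse", "VAL": "none", "LEU": "degradation"}
    net = bio.AANetwork(amino_acids=aas, upstream=upstream, root="GLU",
                        loss_kind=loss_kind)

    minimal_conc = {"GLU": 1000.0, "ALA": 300.0, "VAL": 150.0, "LEU": 80.0}
    rich_conc = {aa: 2.0 * c for aa, c in minimal_conc.items()}
    # curated inhibition bounds sit below the expected concentrations, so the
    # clamp rule engages and end-product inhibition is active at steady state
    ki_bounds = {aa: (0.1 * c, 0.35 * c) for aa, c in minimal_conc.items()}
    kin = bio.assign_default_constants(net, minimal_conc, curated_K_I_bounds=ki_bounds)

    codon_fraction = np.array([0.35, 0.30, 0.15, 0.20])
    total_elong_min, total_elong_rich = 250.0, 600.0
    s_min = {aa: float(codon_fraction[i]) * total_elong_min for i, aa in enumerate(aas)}
    s_rich = {aa: float(codon_fraction[i]) * total_elong_rich for i, aa in enumerate(aas)}
    enzyme_min = {aa: 12.0 for aa in aas}
    enzyme_rich = {aa: 10.0 for aa in aas}
    ex_lit = {aa: 0.5 * s_rich[aa] for aa in aas}
    kcat_lit = {aa: 10.0 for aa in aas}
    cond_min = bio.ConditionTable(name="minimal", aa_conc=minimal_conc,
                                  enzyme_conc=enzyme_min, demand=s_min,
                                  v_exchange_lit={aa: 0.0 for aa in aas},
                                  kcat_lit=kcat_lit)
    cond_rich = bio.ConditionTable(name="rich", aa_conc=rich_conc,
                                   enzyme_conc=enzyme_rich, demand=s_rich,
                                   v_exchange_lit=ex_lit, kcat_lit=kcat_lit)
    fit = bio.fit_kcats_and_exchange(net, kin, cond_min, cond_rich)
    kinetics = bio.AAKinetics(kcat_f=fit.kcat_f, kcat_loss=fit.kcat_loss, K_I=kin.K_I,
                              K_M_up=kin.K_M_up, K_M_loss=kin.K_M_loss)

    # transport: curated export K_M for two AAs, rest imputed; calibrate kcats
    curated_km = {"GLU": 3.0 * minimal_conc["GLU"], "ALA": 3.0 * minimal_conc["ALA"]}
    K_M_ex = trn.estimate_missing_export_km(curated_km, minimal_conc)
    K_I_im = dict(rich_conc)
    transporter_per_aa = 5.0
    pools = trn.TransporterPools(T_im={aa: transporter_per_aa for aa in aas},
                                 T_ex={aa: transporter_per_aa for aa in aas})
    kcat_im, kcat_ex = trn.fit_transport_kcats(K_I_im, K_M_ex, pools, rich_conc,
                                               fit.v_exchange)
    transport = trn.TransportParams(kcat_im=kcat_im, kcat_ex=kcat_ex, K_I_im=K_I_im,
                                    K_M_ex=K_M_ex, importable={aa: True for aa in aas})

    # phenomenological supply anchored at the same conditions
    pheno_params = pheno.solve_pheno_params(
        0.25, 0.25, minimal_conc, rich_conc,
        v_supply_media={"minimal": s_min, "rich": s_rich})

    # charging kinetics
    charging = chg.ChargingParams.with_defaults(
        n, K_M_aa=np.full(n, 100.0), k_rib_max=24.0, K_I_GTPase=150.0, hill_H=2.0,
        K_D_tRNAc=1.0, K_D_tRNAu=1.0)

    # ppGpp kinetics: analytic SpoT calibration + prevalence adjustments
    k_deg, k_syn = ppg.derive_spot_constants()
    trna_total_ref = 300.0 * codon_fraction      # µM per species
    kd_rela, ki_spot = ppg.species_adjustments(trna_total_ref, K_D_RelA_lit=15.0,
                                               K_I_SpoT_lit=4000.0)
    ppgpp_params = ppg.PpGppParams(k_RelA=75.0, K_D_RelA=kd_rela, k_SpoT_syn=k_syn,
                                   k_SpoT_deg=k_deg, K_I_SpoT=ki_spot)

    # ppGpp-RNAP binding constant from a synthetic growth-law table
    table, _ = generate_growth_law_table(FixtureSpec(seed=seed, n_rows=8), K_M=35.0)
    binding = txn.RnapBinding(K_M_ppgpp=txn.fit_km_rnap(table).K_M_ppgpp)

    # per-class expression pairs from fold changes + basal weights
    basal_ppgpp, rich_ppgpp = 45.0, 22.0
    f_basal = txn.fraction_bound(binding, basal_ppgpp)
    f_rich = txn.fraction_bound(binding, rich_ppgpp)
    # mRNA-class weights are the target protein shares scaled by the mRNA
    # share of RNAP output, so protein composition converges onto the
    # intended pool sizes under balanced growth.
    mrna_output_share = 0.40
    protein_shares = {
        **{f"enzyme_{aa}": 0.006 for aa in aas},
        "transporter": 0.010, "synthetase": 0.004, "rnap": 0.012,
        "rela": 4e-5, "spot": 4e-5, "rprotein": 0.25,
    }
    protein_shares["other"] = 1.0 - sum(protein_shares.values())
    basal_weights = {
        "rrna": 0.50, "trna": 0.10,
        **{cls: share * mrna_output_share for cls, share in protein_shares.items()},
    }
    fc_by_class = {
        "rrna": -2.5, "trna": -2.0,
        **{f"enzyme_{aa}": 1.2 for aa in aas},
        "transporter": 0.4, "synthetase": -0.5,
        "rprotein": -1.5, "rnap": -1.0, "rela": 0.5, "spot": -0.5,
        "other": 0.0,
    }
    exp_free, exp_ppgpp = txn.solve_gene_expression(fc_by_class, basal_weights,
                                                    f_rich=f_rich, f_basal=f_basal)
    exp_pairs = {cls: (exp_free[cls], exp_ppgpp[cls]) for cls in basal_weights}

    # attenuation of the enzyme classes by their own charged tRNA pools
    tc_rich = 0.92 * trna_total_ref
    fc_att = {(f"enzyme_{aa}", aa): 0.6 for aa in aas}
    att_params = att.fit_K(fc_att, {aa: float(tc_rich[i]) for i, aa in enumerate(aas)})
    p_stop_ref = att.p_stop(att_params,
                            {aa: float(tc_rich[i]) for i, aa in enumerate(aas)})

    media = {
        "minimal": cell_mod.MediaCondition(name="minimal", amino_acids_present=frozenset(),
                                           ref_ppgpp=60.0, pheno_base_supply=s_min),
        "rich": cell_mod.MediaCondition(name="rich",
                                        amino_acids_present=frozenset(aas),
                                        ref_ppgpp=rich_ppgpp, pheno_base_supply=s_rich),
    }

    params = cell_mod.CellParams(
        network=net, kinetics=kinetics, transport=transport, pheno=pheno_params,
        charging=charging, ppgpp=ppgpp_params, binding=binding, exp_pairs=exp_pairs,
        attenuation=att_params, p_stop_ref=p_stop_ref, media=media,
        codon_fraction=codon_fraction, mw=dict(_MW), density_fg_per_fl=260.0,
        k_rnap=45.0, rnap_active_frac=0.6, mrna_halflife_s=240.0,
    )
    state = initial_state(params, media="rich")
    return params, state


def initial_state(params: cell_mod.CellParams, media: str = "rich") -> cell_mod.CellState:
    """Reference-geometry initial state consistent with the default pool targets."""
    v = _REF_VOLUME_FL
    aas = params.amino_acids
    cond = params.media[media]
    protein_shares = {
        **{f"enzyme_{aa}": 0.006 for aa in aas},
        "transporter": 0.010, "synthetase": 0.004, "rnap": 0.012,
        "rela": 4e-5, "spot": 4e-5, "rprotein": 0.25,
    }
    protein_shares["other"] = 1.0 - sum(protein_shares.values())
    protein_mass = {cls: share * _REF_PROTEIN_FG for cls, share in protein_shares.items()}

    rrna_mass = 48.0
    trna_mass = 7.5
    mrna_total = 4.0
    # mRNA composition mirrors the protein shares so translation keeps them
    mrna_mass = {cls: protein_shares[cls] * mrna_total for cls in protein_shares}

    conc = params.media[media].amino_acids_present
    aa_conc = np.array([
        (2.0 if aa in conc else 1.0) *
        {"GLU": 1000.0, "ALA": 300.0, "VAL": 150.0, "LEU": 80.0}[aa]
        for aa in aas])
    total_trna_conc = cell_mod.mass_to_conc(trna_mass, params.mw["trna"], v)
    per_species = total_trna_conc * params.codon_fraction
    charged_frac = 0.9
    state = cell_mod.CellState(
        time=0.0, mrna_mass=mrna_mass, rrna_mass=rrna_mass, trna_mass=trna_mass,
        protein_mass=protein_mass, aa_conc=aa_conc,
        trna_charged=charged_frac * per_species,
        trna_uncharged=(1 - charged_frac) * per_species,
        ppgpp=cond.ref_ppgpp, media=media)
    return state
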