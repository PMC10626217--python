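"""Toy-scale microbial community models and net-secretion FVA.

Builds joint stoichiometric models of a microbial community from per-species
genome-scale reconstructions, in the style of pan-species community modeling
pipelines: each microbe keeps its own compartmentalized reaction set, its
exchange reactions are rewired into lumen transfer (IEX) reactions feeding a
shared lumen compartment, the lumen connects to diet and fecal sink
reactions, a community biomass reaction weights the member biomasses by
relative abundance, and coupling constraints ``|IEX| <= kappa * bm`` tie each
microbe's exchanges to its biomass flux so absent or inactive microbes carry
no flux.

The net-secretion readout per lumen metabolite is obtained by flux
variability analysis at the community biomass optimum ``w``:

    maxProd = |maxFaecal + minDiet|,    maxUpt = |minFaecal + maxDiet|

with the diet sink using the uptake-negative sign convention (a diet sink
flux of -10 means up to 10 units enter from the diet).

All linear programs are solved with HiGHS via :func:`scipy.optimize.linprog`.
"""

from __future__ import annotations

import copy
import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import linprog

from .errors import (
    InfeasibleModelError,
    MissingModelError,
    ModelConstructionError,
    StoichiometryConflictError,
)

logger = logging.getLogger(__name__)

DEFAULT_COUPLING = 400.0
DEFAULT_BIOMASS_BOUNDS = (0.4, 1.0)
#: Fecal sink upper bound (the excretion side is otherwise unconstrained).
DEFAULT_FECAL_UPPER = 1000.0
#: LP feasibility/optimality tolerance handed to HiGHS.
LP_TOL = 1e-9
#: FVA fluxes below this magnitude are reported as exact zeros, so that the
#: absolute values in the net-secretion formula cannot flip sign on solver
#: noise.
FVA_ZERO_TOL = 1e-8


# ---------------------------------------------------------------------------
# Reconstructions
# ---------------------------------------------------------------------------

@dataclass
class Metabolite:
    id: str
    compartment: str = "c"  # 'c' internal, 'e' extracellular


@dataclass
class Reaction:
    id: str
    stoichiometry: dict[str, float]
    lower: float = 0.0
    upper: float = 1000.0


@dataclass
class Reconstruction:
    """A single genome-scale reconstruction (toy schema).

    ``exchange_reactions`` name the reactions of the form ``met[e] <-> {}``
    (single negative stoichiometric entry on an extracellular metabolite);
    positive flux is secretion out of the cell's surroundings, negative flux
    is uptake.
    """

    id: str
    metabolites: list[Metabolite]
    reactions: list[Reaction]
    biomass_reaction: str
    exchange_reactions: list[str] = field(default_factory=list)

    def validate(self) -> None:
        from .errors import ValidationError

        met_ids = {m.id for m in self.metabolites}
        rxn_ids = {r.id for r in self.reactions}
        if len(rxn_ids) != len(self.reactions):
            raise ValidationError(f"{self.id}: duplicate reaction ids")
        if self.biomass_reaction not in rxn_ids:
            raise ValidationError(
                f"{self.id}: biomass reaction {self.biomass_reaction!r} not in reactions"
            )
        for r in self.reactions:
            for m in r.stoichiometry:
                if m not in met_ids:
                    raise ValidationError(
                        f"{self.id}: reaction {r.id} references unknown metabolite {m!r}"
                    )
            if r.lower > r.upper:
                raise ValidationError(f"{self.id}: reaction {r.id} has lower > upper")
        for ex in self.exchange_reactions:
            if ex not in rxn_ids:
                raise ValidationError(f"{self.id}: exchange reaction {ex!r} not found")

    def reaction(self, rid: str) -> Reaction:
        for r in self.reactions:
            if r.id == rid:
                return r
        raise KeyError(rid)

    def compartment_of(self, met_id: str) -> str:
        for m in self.metabolites:
            if m.id == met_id:
                return m.compartment
        raise KeyError(met_id)


def build_pan_model(members: list[Reconstruction]) -> Reconstruction:
    """Merge strain reconstructions of one species into a pan-reconstruction.

    The reaction set is the union over members; a reaction id present in
    several members must have identical stoichiometry (bounds are merged to
    the widest interval).  The pan biomass is the arithmetic mean of the
    member biomass stoichiometries over all members (a precursor absent from
    some members averages toward zero).
    """
    if not members:
        raise ValueError("need at least one member reconstruction")
    for m in members:
        m.validate()
    biomass_id = members[0].biomass_reaction

    mets: dict[str, Metabolite] = {}
    rxns: dict[str, Reaction] = {}
    exchanges: list[str] = []
    biomass_stoichs: list[dict[str, float]] = []

    for member in members:
        for met in member.metabolites:
            mets.setdefault(met.id, Metabolite(met.id, met.compartment))
        for r in member.reactions:
            if r.id == member.biomass_reaction:
                biomass_stoichs.append(r.stoichiometry)
                continue
            if r.id in rxns:
                have = rxns[r.id]
                if have.stoichiometry != r.stoichiometry:
                    raise StoichiometryConflictError(
                        f"reaction {r.id!r} has conflicting stoichiometry across members"
                    )
                have.lower = min(have.lower, r.lower)
                have.upper = max(have.upper, r.upper)
            else:
                rxns[r.id] = Reaction(r.id, dict(r.stoichiometry), r.lower, r.upper)
        for ex in member.exchange_reactions:
            if ex not in exchanges and ex != member.biomass_reaction:
                exchanges.append(ex)

    pan_biomass: dict[str, float] = {}
    for stoich in biomass_stoichs:
        for met, coef in stoich.items():
            pan_biomass[met] = pan_biomass.get(met, 0.0) + coef / len(members)
    lo = min(m.reaction(m.biomass_reaction).lower for m in members)
    hi = max(m.reaction(m.biomass_reaction).upper for m in members)
    rxns[biomass_id] = Reaction(biomass_id, pan_biomass, lo, hi)

    pan = Reconstruction(
        id=members[0].id,
        metabolites=list(mets.values()),
        reactions=list(rxns.values()),
        biomass_reaction=biomass_id,
        exchange_reactions=exchanges,
    )
    pan.validate()
    return pan


# ---------------------------------------------------------------------------
# Community model
# ---------------------------------------------------------------------------

def _base_met(exchange: Reaction) -> str:
    """Metabolite id moved by a single-metabolite exchange reaction."""
    if len(exchange.stoichiometry) != 1:
        raise ModelConstructionError(
            f"exchange reaction {exchange.id!r} must move exactly one metabolite"
        )
    return next(iter(exchange.stoichiometry))


@dataclass
class CommunityModel:
    """Joint stoichiometric system of one sample's microbial community.

    Reactions and metabolites are stored with microbe-prefixed ids
    (``<microbe>__<id>``); lumen metabolites are ``<met>[u]``.  Diet and
    fecal compartments are realized as one sink reaction each per lumen
    metabolite (``EX_<met>[d]`` with bounds [-supply, 0], ``EX_<met>[fe]``
    with bounds [0, fecal_upper]); coupling constraints are the pairs
    ``v_iex - kappa*v_bm <= 0`` and ``-v_iex - kappa*v_bm <= 0``.
    """

    metabolites: list[str]
    reactions: list[Reaction]
    abundances: dict[str, float]
    community_biomass: str
    biomass_reactions: dict[str, str]  # microbe -> prefixed biomass rxn id
    diet_sinks: dict[str, str]  # lumen metabolite base -> diet sink rxn id
    fecal_sinks: dict[str, str]
    coupling: list[tuple[str, str]]  # (iex rxn id, biomass rxn id)
    coupling_coefficient: float = DEFAULT_COUPLING

    _rxn_index: dict[str, int] = field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        self._rxn_index = {r.id: i for i, r in enumerate(self.reactions)}

    @property
    def lumen_metabolites(self) -> list[str]:
        return sorted(self.diet_sinks)

    def reaction(self, rid: str) -> Reaction:
        return self.reactions[self._rxn_index[rid]]

    def matrices(self):
        """Assemble (S, bounds, A_coupling) for the LP layer."""
        met_index = {m: i for i, m in enumerate(self.metabolites)}
        n = len(self.reactions)
        S = np.zeros((len(self.metabolites), n))
        bounds = []
        for j, r in enumerate(self.reactions):
            for met, coef in r.stoichiometry.items():
                S[met_index[met], j] += coef
            bounds.append((r.lower, r.upper))
        A_c = np.zeros((2 * len(self.coupling), n))
        for i, (iex, bm) in enumerate(self.coupling):
            ji, jb = self._rxn_index[iex], self._rxn_index[bm]
            A_c[2 * i, ji] = 1.0
            A_c[2 * i, jb] = -self.coupling_coefficient
            A_c[2 * i + 1, ji] = -1.0
            A_c[2 * i + 1, jb] = -self.coupling_coefficient
        return S, bounds, A_c


def effective_community_stoichiometry(model: CommunityModel) -> dict[str, float]:
    """Community biomass stoichiometry with the biomass carriers composed out.

    The community biomass reaction consumes ``a_m`` units of each microbe's
    biomass carrier metabolite, and each carrier is produced 1:1 by that
    microbe's biomass reaction; eliminating the carriers yields the
    abundance-weighted sum of the member biomass stoichiometries.
    """
    out: dict[str, float] = {}
    for microbe, bm_id in model.biomass_reactions.items():
        a = model.abundances[microbe]
        carrier = f"{microbe}__biomass"
        for met, coef in model.reaction(bm_id).stoichiometry.items():
            if met == carrier:
                continue
            out[met] = out.get(met, 0.0) + a * coef
    return out


def build_community_model(
    abundances: dict[str, float],
    reconstructions: dict[str, Reconstruction],
    coupling_coefficient: float = DEFAULT_COUPLING,
    biomass_bounds: tuple[float, float] = DEFAULT_BIOMASS_BOUNDS,
    fecal_upper: float = DEFAULT_FECAL_UPPER,
) -> CommunityModel:
    """Join the present microbes' reconstructions through a shared lumen.

    Microbes with abundance exactly 0 are excluded from the model entirely
    (their reactions never enter the stoichiometric matrix), so a sample
    lacking a species and a sample carrying it at zero abundance yield the
    same model.
    """
    total = sum(abundances.values())
    if any(a < 0 for a in abundances.values()):
        raise ValueError("abundances must be nonnegative")
    if abs(total - 1.0) > 1e-9:
        raise ValueError(f"abundances must sum to 1 (got {total})")

    present = {m: a for m, a in abundances.items() if a > 0}
    for microbe in present:
        if microbe not in reconstructions:
            raise MissingModelError(f"no reconstruction for microbe {microbe!r}")

    metabolites: list[str] = []
    reactions: list[Reaction] = []
    biomass_reactions: dict[str, str] = {}
    coupling: list[tuple[str, str]] = []
    lumen: set[str] = set()

    for microbe, abundance in present.items():
        recon = reconstructions[microbe]
        recon.validate()
        exchange_ids = set(recon.exchange_reactions)
        prefix = f"{microbe}__"
        for met in recon.metabolites:
            metabolites.append(prefix + met.id)
        metabolites.append(prefix + "biomass")

        bm_id = prefix + recon.biomass_reaction
        biomass_reactions[microbe] = bm_id
        for r in recon.reactions:
            if r.id in exchange_ids:
                base = _base_met(r)
                lum = f"{base}[u]"
                lumen.add(base)
                # IEX: microbe extracellular <-> lumen; positive = secretion.
                iex = Reaction(
                    id=f"{prefix}IEX_{base}",
                    stoichiometry={prefix + base: -1.0, lum: 1.0},
                    lower=r.lower,
                    upper=r.upper,
                )
                reactions.append(iex)
                coupling.append((iex.id, bm_id))
            else:
                stoich = {prefix + met: coef for met, coef in r.stoichiometry.items()}
                if r.id == recon.biomass_reaction:
                    stoich[prefix + "biomass"] = stoich.get(prefix + "biomass", 0.0) + 1.0
                reactions.append(Reaction(prefix + r.id, stoich, r.lower, r.upper))

    metabolites.extend(f"{base}[u]" for base in sorted(lumen))

    diet_sinks: dict[str, str] = {}
    fecal_sinks: dict[str, str] = {}
    for base in sorted(lumen):
        lum = f"{base}[u]"
        d_id, fe_id = f"EX_{base}[d]", f"EX_{base}[fe]"
        # Diet sink: closed until a diet is applied (uptake-negative).
        reactions.append(Reaction(d_id, {lum: -1.0}, 0.0, 0.0))
        reactions.append(Reaction(fe_id, {lum: -1.0}, 0.0, fecal_upper))
        diet_sinks[base] = d_id
        fecal_sinks[base] = fe_id

    cm_stoich = {f"{m}__biomass": -a for m, a in present.items()}
    reactions.append(
        Reaction("communityBiomass", cm_stoich, biomass_bounds[0], biomass_bounds[1])
    )

    return CommunityModel(
        metabolites=metabolites,
        reactions=reactions,
        abundances=dict(present),
        community_biomass="communityBiomass",
        biomass_reactions=biomass_reactions,
        diet_sinks=diet_sinks,
        fecal_sinks=fecal_sinks,
        coupling=coupling,
        coupling_coefficient=coupling_coefficient,
    )


def apply_diet(model: CommunityModel, diet: dict[str, float]) -> CommunityModel:
    """Open diet sinks to ``[-supply, 0]``; unknown metabolites are skipped.

    Returns a new model; the input is not modified.  All diet sinks absent
    from ``diet`` stay closed at [0, 0].
    """
    for met, supply in diet.items():
        if supply < 0:
            raise ValueError(f"diet supply for {met!r} must be nonnegative")
    new = copy.deepcopy(model)
    for met, supply in diet.items():
        if met not in new.diet_sinks:
            logger.warning("diet metabolite %r not in the lumen; skipped", met)
            continue
        sink = new.reaction(new.diet_sinks[met])
        sink.lower, sink.upper = -float(supply), 0.0
    return new


# ---------------------------------------------------------------------------
# LP layer
# ---------------------------------------------------------------------------

def _solve_lp(model: CommunityModel, objective: np.ndarray, sense: str = "max",
              fixed: dict[str, tuple[float, float]] | None = None):
    """Solve one LP over the community polytope; return (status, value, x)."""
    S, bounds, A_c = model.matrices()
    if fixed:
        bounds = list(bounds)
        for rid, (lo, hi) in fixed.items():
            bounds[model._rxn_index[rid]] = (lo, hi)
    c = -objective if sense == "max" else objective
    res = linprog(
        c,
        A_eq=S,
        b_eq=np.zeros(S.shape[0]),
        A_ub=A_c if len(A_c) else None,
        b_ub=np.zeros(len(A_c)) if len(A_c) else None,
        bounds=bounds,
        method="highs",
        options={"primal_feasibility_tolerance": LP_TOL,
                 "dual_feasibility_tolerance": LP_TOL},
    )
    value = None
    if res.status == 0:
        value = -res.fun if sense == "max" else res.fun
    return res.status, value, res


def _constraint_report(model: CommunityModel) -> str:
    open_diet = [m for m in model.diet_sinks
                 if model.reaction(model.diet_sinks[m]).lower < 0]
    cm = model.reaction(model.community_biomass)
    return (
        f"community biomass bounds [{cm.lower}, {cm.upper}]; "
        f"{len(open_diet)} diet sinks open ({', '.join(sorted(open_diet)) or 'none'}); "
        f"{len(model.coupling)} coupling constraints"
    )


def solve_community_fba(model: CommunityModel) -> float:
    """Maximize the community biomass flux; return the optimum ``w``."""
    obj = np.zeros(len(model.reactions))
    obj[model._rxn_index[model.community_biomass]] = 1.0
    status, value, res = _solve_lp(model, obj, "max")
    if status == 2:
        raise InfeasibleModelError(
            "community FBA infeasible: " + _constraint_report(model)
        )
    if status == 3:
        raise ModelConstructionError("community FBA unbounded; check sink bounds")
    if status != 0:
        raise ModelConstructionError(f"LP solver failure: {res.message}")
    return float(value)


def fva_exchange_bounds(
    model: CommunityModel,
    metabolite: str,
    w: float,
    biomass_fraction: float = 1.0,
) -> tuple[float, float, float, float]:
    """FVA of the diet and fecal sinks of one metabolite at fixed biomass.

    The community biomass reaction is constrained to
    ``[biomass_fraction * w, w]`` (both bounds equal to ``w`` by default) and
    the four optima (minDiet, maxDiet, minFaecal, maxFaecal) are computed
    independently.  Values within ``FVA_ZERO_TOL`` of zero are reported as 0.
    """
    if metabolite not in model.diet_sinks:
        raise KeyError(f"metabolite {metabolite!r} not present in the lumen")
    out = []
    for rid in (model.diet_sinks[metabolite], model.fecal_sinks[metabolite]):
        obj = np.zeros(len(model.reactions))
        obj[model._rxn_index[rid]] = 1.0
        for sense in ("min", "max"):
            value = None
            for cm_lo in (biomass_fraction * w, biomass_fraction * w * (1 - 1e-6)):
                status, value, _ = _solve_lp(
                    model, obj, sense, fixed={model.community_biomass: (cm_lo, w)}
                )
                if status == 0:
                    break
            if value is None:
                raise InfeasibleModelError(
                    f"FVA infeasible for {rid} at community biomass {w}"
                )
            out.append(0.0 if abs(value) < FVA_ZERO_TOL else float(value))
    min_diet, max_diet, min_faecal, max_faecal = out
    return min_diet, max_diet, min_faecal, max_faecal


def net_secretion_capacity(
    min_diet: float, max_diet: float, min_faecal: float, max_faecal: float
) -> tuple[float, float]:
    """Net production and uptake capacity from the four sink FVA values.

    ``maxProd = |maxFaecal + minDiet|`` (fecal output beyond dietary input,
    diet uptake being negative) and ``maxUpt = |minFaecal + maxDiet|``.
    """
    if min_diet > max_diet or min_faecal > max_faecal:
        raise ValueError("FVA minima must not exceed maxima")
    return abs(max_faecal + min_diet), abs(min_faecal + max_diet)


# ---------------------------------------------------------------------------
# Population runs
# ---------------------------------------------------------------------------

def population_flux_profiles(
    abundance_table,
    reconstructions: dict[str, Reconstruction],
    diet: dict[str, float],
    metabolites: list[str] | None = None,
    coupling_coefficient: float = DEFAULT_COUPLING,
    biomass_bounds: tuple[float, float] = DEFAULT_BIOMASS_BOUNDS,
    biomass_fraction: float = 1.0,
):
    """Per-sample community modeling over an abundance table.

    ``abundance_table`` is a pandas DataFrame (samples x species, rows
    summing to 1); the same ``diet`` is applied to every sample so that
    community composition is the only source of flux variation.  Returns
    ``(flux_df, stats_df)``: the samples x metabolites matrix of maxProd
    values and a per-sample model-statistics table (n_reactions,
    n_metabolites, community biomass optimum ``w``).  Samples whose model
    fails are dropped with a logged reason.
    """
    import pandas as pd

    flux_rows, stats_rows, index = [], [], []
    for sample, row in abundance_table.iterrows():
        abunds = {sp: float(v) for sp, v in row.items() if v > 0}
        try:
            model = build_community_model(
                abunds, reconstructions,
                coupling_coefficient=coupling_coefficient,
                biomass_bounds=biomass_bounds,
            )
            model = apply_diet(model, diet)
            w = solve_community_fba(model)
            mets = metabolites if metabolites is not None else model.lumen_metabolites
            profile = {}
            for met in mets:
                if met not in model.diet_sinks:
                    profile[met] = 0.0
                    continue
                fva = fva_exchange_bounds(model, met, w, biomass_fraction)
                profile[met], _ = net_secretion_capacity(*fva)
        except Exception as exc:  # noqa: BLE001 - per-sample failures are data
            logger.warning("sample %s dropped: %s", sample, exc)
            continue
        flux_rows.append(profile)
        stats_rows.append({
            "n_reactions": len(model.reactions),
            "n_metabolites": len(model.metabolites),
            "w": w,
        })
        index.append(sample)

    flux_df = pd.DataFrame(flux_rows, index=index)
    stats_df = pd.DataFrame(stats_rows, index=index)
    return flux_df, stats_df


# ---------------------------------------------------------------------------
# Toy reconstructions (worked examples and test substrate)
# ---------------------------------------------------------------------------

def toy_m1() -> Reconstruction:
    """Single-microbe worked example: glucose in, butyrate out.

    With abundance 1, diet {glc: 10} and community biomass bounds [0.4, 1],
    the biomass optimum is w = 1 (one glucose per biomass unit) and butyrate
    FVA at w gives (minDiet, maxDiet, minFaecal, maxFaecal) = (0, 0, 0, 9):
    nine of the ten dietary glucoses can be fermented 1:1 to butyrate, hence
    maxProd = 9.
    """
    return Reconstruction(
        id="M1",
        metabolites=[
            Metabolite("glc", "e"),
            Metabolite("glc_c", "c"),
            Metabolite("but_c", "c"),
            Metabolite("but", "e"),
        ],
        reactions=[
            Reaction("EX_glc", {"glc": -1.0}, -1000.0, 1000.0),
            Reaction("T_glc", {"glc": -1.0, "glc_c": 1.0}, 0.0, 1000.0),
            Reaction("FERM", {"glc_c": -1.0, "but_c": 1.0}, 0.0, 1000.0),
            Reaction("T_but", {"but_c": -1.0, "but": 1.0}, 0.0, 1000.0),
            Reaction("EX_but", {"but": -1.0}, -1000.0, 1000.0),
            Reaction("BIOMASS", {"glc_c": -1.0}, 0.0, 1000.0),
        ],
        biomass_reaction="BIOMASS",
        exchange_reactions=["EX_glc", "EX_but"],
    )


def toy_reconstructions() -> dict[str, Reconstruction]:
    """Three toy species with overlapping but distinct metabolic capabilities.

    M1 ferments glucose to butyrate; M2 grows on glucose and secretes
    acetate; M3 grows on acetate (cross-feeding) and can consume butyrate.
    """
    m2 = Reconstruction(
        id="M2",
        metabolites=[
            Metabolite("glc", "e"),
            Metabolite("glc_c", "c"),
            Metabolite("ac_c", "c"),
            Metabolite("ac", "e"),
        ],
        reactions=[
            Reaction("EX_glc", {"glc": -1.0}, -1000.0, 1000.0),
            Reaction("T_glc", {"glc": -1.0, "glc_c": 1.0}, 0.0, 1000.0),
            Reaction("GLYC", {"glc_c": -1.0, "ac_c": 2.0}, 0.0, 1000.0),
            Reaction("T_ac", {"ac_c": -1.0, "ac": 1.0}, -1000.0, 1000.0),
            Reaction("EX_ac", {"ac": -1.0}, -1000.0, 1000.0),
            Reaction("BIOMASS", {"glc_c": -0.5, "ac_c": -0.5}, 0.0, 1000.0),
        ],
        biomass_reaction="BIOMASS",
        exchange_reactions=["EX_glc", "EX_ac"],
    )
    m3 = Reconstruction(
        id="M3",
        metabolites=[
            Metabolite("ac", "e"),
            Metabolite("ac_c", "c"),
            Metabolite("but", "e"),
            Metabolite("but_c", "c"),
        ],
        reactions=[
            Reaction("EX_ac", {"ac": -1.0}, -1000.0, 1000.0),
            Reaction("T_ac", {"ac": -1.0, "ac_c": 1.0}, 0.0, 1000.0),
            Reaction("EX_but", {"but": -1.0}, -1000.0, 1000.0),
            Reaction("T_but", {"but": -1.0, "but_c": 1.0}, -1000.0, 1000.0),
            Reaction("BUTOX", {"but_c": -1.0, "ac_c": 2.0}, 0.0, 1000.0),
            Reaction("BIOMASS", {"ac_c": -1.0}, 0.0, 1000.0),
        ],
        biomass_reaction="BIOMASS",
        exchange_reactions=["EX_ac", "EX_but"],
    )
    return {"M1": toy_m1(), "M2": m2, "M3": m3}
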