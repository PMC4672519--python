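"""Two-member community models with balanced-growth coupling.

Two member models are merged into a single stoichiometric system: internal
metabolites and reactions are namespaced with ``A__``/``B__`` prefixes,
extracellular metabolites are merged on their compartment-free base id into a
single shared pool, and exactly one community exchange reaction per shared
metabolite applies the medium's uptake bounds. Member transport reactions are
preserved, so each member feeds on (and secretes into) the common pool.

Balanced growth of a stable consortium requires both members to grow at the
same specific rate; this is encoded as a hard equality row
``v_biomass_A - v_biomass_B = 0`` appended to the stoichiometric matrix. The
community objective maximizes member A's biomass flux, which under the
coupling equals member B's.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import numpy as np

from .fba_core import StoichiometricSystem, build_system, solve_fba
from .model_io import (
    EXTRACELLULAR,
    Medium,
    MetabolicModel,
    ValidationError,
    _model_from_dict,
    _model_to_dict,
    validate_model,
)

logger = logging.getLogger(__name__)

COUPLING_ROW = "coupling__equal_growth"


@dataclass(frozen=True)
class SharedMetabolite:
    """One candidate cross-feeding direction for a shared extracellular pool."""

    base_id: str
    donor: str       # member model id able to secrete into the pool
    recipient: str   # member model id able to take up from the pool


@dataclass
class CommunityModel:
    members: tuple[MetabolicModel, MetabolicModel]
    system: StoichiometricSystem
    medium: Medium
    shared_metabolites: set[str]
    shared_directions: list[SharedMetabolite]
    biomass_cols: dict[str, str] = field(default_factory=dict)   # member id -> col
    transport_cols: dict[tuple[str, str], list[str]] = field(default_factory=dict)
    exchange_cols: dict[str, str] = field(default_factory=dict)  # base id -> col
    compound_names: dict[str, str] = field(default_factory=dict)

    @property
    def member_ids(self) -> tuple[str, str]:
        return (self.members[0].id, self.members[1].id)

    def transport_reactions_of(self, member_id: str, base_id: str) -> list[str]:
        """Namespaced system column ids of ``member_id``'s transports of a
        shared metabolite."""
        return list(self.transport_cols.get((member_id, base_id), []))


def _e_coefficient(rxn, met_map) -> dict[str, float]:
    """Net stoichiometric coefficient of each extracellular base id."""
    out: dict[str, float] = {}
    for mid, coef in rxn.stoichiometry.items():
        met = met_map[mid]
        if met.compartment == EXTRACELLULAR:
            out[met.base_id] = out.get(met.base_id, 0.0) + coef
    return out


def _can_secrete(coef: float, lb: float, ub: float) -> bool:
    return (coef > 0 and ub > 1e-12) or (coef < 0 and lb < -1e-12)


def _can_uptake(coef: float, lb: float, ub: float) -> bool:
    return (coef < 0 and ub > 1e-12) or (coef > 0 and lb < -1e-12)


def build_community(
    model_A: MetabolicModel, model_B: MetabolicModel, medium: Medium
) -> CommunityModel:
    """Merge two member models over a shared extracellular compartment and
    couple their growth rates with a hard equality constraint."""
    for model in (model_A, model_B):
        validate_model(model)
        if EXTRACELLULAR not in model.compartments:
            raise ValidationError(
                [f"member '{model.id}' declares no extracellular compartment"]
            )
        if model.objective_reaction_id is None:
            raise ValidationError([f"member '{model.id}' has no biomass reaction"])
    if model_A.id == model_B.id:
        raise ValidationError(["member models must have distinct ids"])

    prefixes = {"A": model_A, "B": model_B}
    rows: list[str] = []
    row_index: dict[str, int] = {}
    cols: list[str] = []
    entries: list[tuple[int, int, float]] = []
    lb: list[float] = []
    ub: list[float] = []
    biomass_cols: dict[str, str] = {}
    transport_cols: dict[tuple[str, str], list[str]] = {}
    compound_names: dict[str, str] = {}
    member_e_caps: dict[str, dict[str, dict[str, bool]]] = {
        model_A.id: {}, model_B.id: {}
    }

    def row(met_id: str) -> int:
        if met_id not in row_index:
            row_index[met_id] = len(rows)
            rows.append(met_id)
        return row_index[met_id]

    shared_e: set[str] = set()
    for prefix, model in prefixes.items():
        met_map = model.metabolite_map
        e_bases = set()
        for met in model.metabolites:
            if met.compartment == EXTRACELLULAR:
                base = met.base_id
                e_bases.add(base)
                row(f"{base}_{EXTRACELLULAR}")
                if met.annotation and base not in compound_names:
                    compound_names[base] = met.annotation
                elif met.name and base not in compound_names:
                    compound_names.setdefault(base, met.name)
            else:
                row(f"{prefix}__{met.id}")
        shared_e |= e_bases

        def remap(mid: str) -> str:
            met = met_map[mid]
            if met.compartment == EXTRACELLULAR:
                return f"{met.base_id}_{EXTRACELLULAR}"
            return f"{prefix}__{mid}"

        for rxn in model.reactions:
            if rxn.kind == "exchange":
                continue  # replaced by community exchanges
            cid = f"{prefix}__{rxn.id}"
            if cid in transport_cols:  # pragma: no cover - impossible by design
                raise RuntimeError(f"internal error: column collision '{cid}'")
            j = len(cols)
            cols.append(cid)
            lb.append(rxn.lower_bound)
            ub.append(rxn.upper_bound)
            for mid, coef in rxn.stoichiometry.items():
                entries.append((row(remap(mid)), j, coef))
            if rxn.id == model.objective_reaction_id:
                biomass_cols[model.id] = cid
            if rxn.kind == "transport":
                for base, coef in _e_coefficient(rxn, met_map).items():
                    if coef == 0:
                        continue
                    transport_cols.setdefault((model.id, base), []).append(cid)
                    caps = member_e_caps[model.id].setdefault(
                        base, {"secrete": False, "uptake": False}
                    )
                    caps["secrete"] |= _can_secrete(coef, rxn.lower_bound, rxn.upper_bound)
                    caps["uptake"] |= _can_uptake(coef, rxn.lower_bound, rxn.upper_bound)

    # one community exchange per extracellular metabolite
    exchange_cols: dict[str, str] = {}
    for base in sorted(shared_e):
        cid = f"EX_{base}_{EXTRACELLULAR}"
        j = len(cols)
        cols.append(cid)
        lb.append(-float(medium.uptake_bounds.get(base, 0.0)))
        ub.append(1000.0)
        entries.append((row(f"{base}_{EXTRACELLULAR}"), j, -1.0))
        exchange_cols[base] = cid
    for base in medium.uptake_bounds:
        if base not in shared_e:
            logger.warning(
                "medium component '%s' is not exchanged by either member", base
            )

    # balanced-growth coupling: v_bioA - v_bioB = 0 as an extra equality row
    coupling_row = row(COUPLING_ROW)
    entries.append((coupling_row, cols.index(biomass_cols[model_A.id]), 1.0))
    entries.append((coupling_row, cols.index(biomass_cols[model_B.id]), -1.0))

    S = np.zeros((len(rows), len(cols)))
    for i, j, coef in entries:
        S[i, j] += coef
    c = np.zeros(len(cols))
    c[cols.index(biomass_cols[model_A.id])] = 1.0

    system = StoichiometricSystem(
        S=S, lb=np.array(lb), ub=np.array(ub), c=c, row_ids=rows, col_ids=cols
    )

    # candidate cross-feeding directions: donor can secrete, recipient can uptake
    shared_pool = set()
    directions: list[SharedMetabolite] = []
    id_a, id_b = model_A.id, model_B.id
    for base in sorted(shared_e):
        caps_a = member_e_caps[id_a].get(base, {})
        caps_b = member_e_caps[id_b].get(base, {})
        if not caps_a or not caps_b:
            continue  # only one member transports this metabolite
        if caps_a.get("secrete") and caps_b.get("uptake"):
            directions.append(SharedMetabolite(base, donor=id_a, recipient=id_b))
            shared_pool.add(base)
        if caps_b.get("secrete") and caps_a.get("uptake"):
            directions.append(SharedMetabolite(base, donor=id_b, recipient=id_a))
            shared_pool.add(base)

    return CommunityModel(
        members=(model_A, model_B),
        system=system,
        medium=medium,
        shared_metabolites=shared_pool,
        shared_directions=directions,
        biomass_cols=biomass_cols,
        transport_cols=transport_cols,
        exchange_cols=exchange_cols,
        compound_names=compound_names,
    )


def mono_growth(model: MetabolicModel, medium: Medium) -> float:
    """FBA growth rate of a single model alone on the medium."""
    solution = solve_fba(build_system(model, medium))
    if not solution.optimal:
        return 0.0
    return solution.objective_value


def community_growth(community: CommunityModel):
    """Coupled FBA of the community; returns (mu_A, mu_B, solution)."""
    solution = solve_fba(community.system)
    if not solution.optimal:
        return 0.0, 0.0, solution
    mu = tuple(
        solution.fluxes[community.biomass_cols[mid]] for mid in community.member_ids
    )
    return mu[0], mu[1], solution


def list_shared_metabolites(community: CommunityModel) -> list[SharedMetabolite]:
    """Shared extracellular base ids tagged with candidate donor/recipient."""
    return list(community.shared_directions)


# ---------------------------------------------------------------------------
# serialization (JSON dialect with a coupling block)
# ---------------------------------------------------------------------------

def community_to_json(community: CommunityModel) -> str:
    payload = {
        "members": [_model_to_dict(m) for m in community.members],
        "medium": {
            "name": community.medium.name,
            "uptake_bounds": dict(community.medium.uptake_bounds),
        },
        "coupling": {
            "type": "equal_growth",
            "members": list(community.member_ids),
        },
    }
    return json.dumps(payload, indent=1) + "\n"


def write_community(community: CommunityModel, path) -> None:
    with open(path, "w") as fh:
        fh.write(community_to_json(community))


def read_community(path) -> CommunityModel:
    with open(path) as fh:
        payload = json.load(fh)
    model_A = _model_from_dict(payload["members"][0], source=str(path))
    model_B = _model_from_dict(payload["members"][1], source=str(path))
    medium = Medium(
        uptake_bounds={
            k: float(v) for k, v in payload["medium"]["uptake_bounds"].items()
        },
        name=payload["medium"].get("name", "medium"),
    )
    if payload.get("coupling", {}).get("type", "equal_growth") != "equal_growth":
        raise ValidationError(["unsupported coupling type"])
    return build_community(model_A, model_B, medium)
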