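"""Transport-knockout cross-feeding screen.

The headline analysis: starting from a growth-coupled two-member community at
its FBA optimum, knock out the transport reactions for each shared metabolite
and re-solve. A shared metabolite whose loss abolishes community growth is an
*essential* cross-feeding interaction; metabolites that are individually
dispensable may still belong to a *redundancy group* (an OR-group) that is
jointly essential — e.g. a set of alternative carbon sources or purine
precursors where the recipient needs at least one member.

Knockouts are recipient-side by default: disabling the consumer's uptake
transports isolates the recipient's dependence on the donated compound.
Donor-side knockouts (disabling the producer's secretion) are available for
sensitivity analysis.

Transfer directions are read from the parsimonious-FBA flux distribution and
cross-checked by flux variability analysis at 99.9 % of the optimum: a
direction is *robust* when the FVA interval of the recipient's net uptake
does not straddle zero, i.e. it is not an artefact of a degenerate optimum.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

from .community import CommunityModel, community_growth
from .fba_core import (
    GROWTH_EPSILON,
    TOLERANCE,
    fva,
    knockout,
    solve_fba,
    solve_pfba,
)
from .model_io import ValidationError

logger = logging.getLogger(__name__)

FVA_FRACTION = 0.999
MAX_SUBSETS = 2 ** 15
MAX_GROUP_SIZE = 3


class ScreenError(RuntimeError):
    pass


@dataclass
class InteractionRecord:
    """Machine twin of one row of the interaction table."""

    metabolite: str
    compound_name: str
    donor: str
    recipient: str
    transfer_flux: float
    essential: bool
    direction_robust: bool
    growth_after_knockout: float
    active: bool
    redundancy_group: str | None = None


@dataclass
class ScreenReport:
    records: list[InteractionRecord]
    baseline_growth: float
    mono_growth_A: float
    mono_growth_B: float
    groups_tested: list[tuple[frozenset, float]] = field(default_factory=list)


def _knockout_targets(
    community: CommunityModel, base_id: str, recipient: str, donor: str,
    side: str,
) -> list[str]:
    if side == "recipient":
        return community.transport_reactions_of(recipient, base_id)
    if side == "donor":
        return community.transport_reactions_of(donor, base_id)
    raise ValueError(f"knockout side must be 'recipient' or 'donor', got '{side}'")


def _net_uptake(community: CommunityModel, recipient: str, base_id: str,
                fluxes: dict[str, float]) -> float:
    """Recipient's net uptake of the shared pool species (positive = uptake)."""
    system = community.system
    row = system.row_index[f"{base_id}_e"]
    total = 0.0
    for cid in community.transport_reactions_of(recipient, base_id):
        coef = system.S[row, system.col_index[cid]]
        total += -coef * fluxes[cid]
    return total


def screen_interactions(
    community: CommunityModel,
    knockout_side: str = "recipient",
    fva_fraction: float = FVA_FRACTION,
) -> ScreenReport:
    """Single-metabolite knockout screen over all shared metabolites.

    For each shared metabolite and candidate direction: record the transfer
    flux at the pFBA optimum, knock out all of the recipient's transport
    reactions for it, re-solve, and mark it essential iff growth falls below
    GROWTH_EPSILON. Direction robustness comes from FVA at ``fva_fraction`` of
    the optimum. Records with zero transfer and no essentiality are retained
    but flagged inactive.
    """
    from .community import mono_growth

    mu_a, mu_b, baseline = community_growth(community)
    if not baseline.optimal or baseline.objective_value < GROWTH_EPSILON:
        raise ScreenError(
            "community baseline FBA is not optimal with positive growth; "
            f"status={baseline.status}"
        )
    pfba = solve_pfba(community.system)

    # FVA over every transport column involved in any candidate direction
    fva_cols = sorted(
        {
            cid
            for d in community.shared_directions
            for cid in community.transport_reactions_of(d.recipient, d.base_id)
        }
    )
    fva_ranges = fva(community.system, fva_cols, fva_fraction) if fva_cols else {}

    records: list[InteractionRecord] = []
    for direction in community.shared_directions:
        base = direction.base_id
        transfer = _net_uptake(community, direction.recipient, base, pfba.fluxes)

        # interval arithmetic over the recipient's transports
        system = community.system
        row = system.row_index[f"{base}_e"]
        lo = hi = 0.0
        for cid in community.transport_reactions_of(direction.recipient, base):
            coef = system.S[row, system.col_index[cid]]
            a, b = fva_ranges[cid]
            contrib = sorted((-coef * a, -coef * b))
            lo += contrib[0]
            hi += contrib[1]
        robust = not (lo < -TOLERANCE and hi > TOLERANCE)

        targets = _knockout_targets(
            community, base, direction.recipient, direction.donor, knockout_side
        )
        ko_solution = solve_fba(knockout(community.system, targets))
        mu_ko = ko_solution.objective_value if ko_solution.optimal else 0.0
        essential = mu_ko < GROWTH_EPSILON
        records.append(
            InteractionRecord(
                metabolite=base,
                compound_name=community.compound_names.get(base, base),
                donor=direction.donor,
                recipient=direction.recipient,
                transfer_flux=transfer,
                essential=essential,
                direction_robust=robust,
                growth_after_knockout=mu_ko,
                active=essential or transfer > TOLERANCE,
            )
        )
    records.sort(key=lambda r: (not r.essential, -r.transfer_flux, r.metabolite))
    return ScreenReport(
        records=records,
        baseline_growth=baseline.objective_value,
        mono_growth_A=mono_growth(community.members[0], community.medium),
        mono_growth_B=mono_growth(community.members[1], community.medium),
    )


def screen_groups(
    community: CommunityModel,
    groups: list[set[str]],
    knockout_side: str = "recipient",
) -> dict[frozenset, float]:
    """Community growth after jointly knocking out every metabolite in each
    group (recipient-side transports of all group members at once)."""
    unknown = {m for g in groups for m in g} - community.shared_metabolites
    if unknown:
        raise ValidationError(
            [f"'{m}' is not a shared metabolite" for m in sorted(unknown)]
        )
    out: dict[frozenset, float] = {}
    for group in groups:
        targets: set[str] = set()
        for direction in community.shared_directions:
            if direction.base_id in group:
                targets |= set(
                    _knockout_targets(
                        community, direction.base_id, direction.recipient,
                        direction.donor, knockout_side,
                    )
                )
        solution = solve_fba(knockout(community.system, sorted(targets)))
        out[frozenset(group)] = (
            solution.objective_value if solution.optimal else 0.0
        )
    return out


def auto_groups(
    community: CommunityModel,
    report: ScreenReport | None = None,
    max_size: int = MAX_GROUP_SIZE,
    knockout_side: str = "recipient",
) -> list[frozenset]:
    """Minimal jointly-essential metabolite sets among non-essential transfers.

    Enumerates subsets of the individually non-essential shared metabolites up
    to ``max_size`` in deterministic (size, lexicographic) order and returns
    the minimal sets whose joint knockout abolishes growth. Refuses when more
    than 2**15 subsets would be tested.
    """
    if report is None:
        report = screen_interactions(community, knockout_side=knockout_side)
    candidates = sorted({r.metabolite for r in report.records if not r.essential})
    n_subsets = sum(
        len(list(itertools.combinations(candidates, size)))
        for size in range(2, max_size + 1)
    )
    if n_subsets > MAX_SUBSETS:
        raise ScreenError(
            f"{n_subsets} candidate subsets exceed the cap of {MAX_SUBSETS}; "
            "pass groups explicitly via screen_groups"
        )
    minimal: list[frozenset] = []
    for size in range(2, max_size + 1):
        for combo in itertools.combinations(candidates, size):
            group = frozenset(combo)
            if any(found <= group for found in minimal):
                continue
            growth = screen_groups(community, [set(group)], knockout_side)[group]
            report.groups_tested.append((group, growth))
            if growth < GROWTH_EPSILON:
                minimal.append(group)
    return minimal


def annotate_groups(report: ScreenReport, groups: list[frozenset]) -> None:
    """Attach redundancy-group labels to the matching records in place."""
    for record in report.records:
        for group in groups:
            if record.metabolite in group:
                record.redundancy_group = "|".join(sorted(group))
                record.active = True
                break


def run_screen(
    community: CommunityModel,
    groups: list[set[str]] | None = None,
    discover_groups: bool = True,
    knockout_side: str = "recipient",
) -> tuple[ScreenReport, list[frozenset]]:
    """Full screen: singles, then OR-group discovery (or explicit groups),
    with redundancy-group labels attached to the report."""
    report = screen_interactions(community, knockout_side=knockout_side)
    found: list[frozenset] = []
    if groups is not None:
        tested = screen_groups(community, groups, knockout_side=knockout_side)
        report.groups_tested.extend(tested.items())
        found = [g for g, mu in tested.items() if mu < GROWTH_EPSILON]
    elif discover_groups:
        found = auto_groups(community, report, knockout_side=knockout_side)
    annotate_groups(report, found)
    return report, found


# ---------------------------------------------------------------------------
# table output
# ---------------------------------------------------------------------------

TABLE_COLUMNS = ["compound", "provides", "consumes", "essential", "robust",
                 "flux", "group"]


def interaction_table(report: ScreenReport) -> str:
    """TSV table of active interactions, essential-first then by flux."""
    rows = [
        r for r in report.records if r.active or r.redundancy_group is not None
    ]
    rows.sort(key=lambda r: (not r.essential, -r.transfer_flux, r.compound_name,
                             r.metabolite))
    lines = ["\t".join(TABLE_COLUMNS)]
    for r in rows:
        lines.append(
            "\t".join(
                [
                    r.compound_name,
                    r.donor,
                    r.recipient,
                    "yes" if r.essential else "no",
                    "yes" if r.direction_robust else "no",
                    f"{r.transfer_flux:.6f}",
                    r.redundancy_group or "-",
                ]
            )
        )
    return "\n".join(lines) + "\n"


def read_interaction_table(path_or_buffer):
    """Read an interaction TSV back into a DataFrame (round-trip partner of
    :func:`interaction_table`)."""
    import pandas as pd

    return pd.read_csv(path_or_buffer, sep="\t")
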