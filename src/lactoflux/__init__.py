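"""lactoflux: constraint-based community modelling for lactic acid bacteria.

Reconstruction of draft metabolic models by ortholog-based reaction transfer,
flux balance analysis (plain, parsimonious, variability), two-member
community models with balanced-growth coupling, and transport-knockout
screens that classify cross-feeding interactions between consortium members.
"""

from importlib import resources

from .model_io import (
    Medium,
    MetabolicModel,
    Metabolite,
    Reaction,
    ValidationError,
    read_medium,
    read_model,
    write_medium,
    write_model,
)
from .fba_core import (
    FluxSolution,
    StoichiometricSystem,
    build_system,
    fva,
    knockout,
    solve_fba,
    solve_pfba,
)
from .community import (
    CommunityModel,
    build_community,
    community_growth,
    list_shared_metabolites,
    mono_growth,
    read_community,
    write_community,
)
from .interaction_screen import (
    InteractionRecord,
    ScreenReport,
    auto_groups,
    interaction_table,
    run_screen,
    screen_groups,
    screen_interactions,
)
from .reconstruction import (
    OrthologPair,
    ProteinSet,
    add_non_gene_reactions,
    copy_subsystems,
    kmer_bbh,
    transfer_reactions,
)
from .synthetic_data import (
    GeneratorConfig,
    PlantedTruth,
    make_milk_fixture,
    make_milk_medium,
    make_rescue_medium,
    make_toy_genomes,
    make_toy_pair,
)
from .genome_summary import GenomeSummary, summarize_fasta

__version__ = "0.1.0"


def fixture_path(name: str):
    """Path to a packaged milk_consortium_mini fixture file (e.g. 'ST.json')."""
    return resources.files(__name__) / "data" / "milk_consortium_mini" / name


__all__ = [
    "Medium", "MetabolicModel", "Metabolite", "Reaction", "ValidationError",
    "read_model", "write_model", "read_medium", "write_medium",
    "FluxSolution", "StoichiometricSystem", "build_system", "solve_fba",
    "solve_pfba", "fva", "knockout",
    "CommunityModel", "build_community", "community_growth", "mono_growth",
    "list_shared_metabolites", "read_community", "write_community",
    "InteractionRecord", "ScreenReport", "screen_interactions",
    "screen_groups", "auto_groups", "run_screen", "interaction_table",
    "OrthologPair", "ProteinSet", "kmer_bbh", "transfer_reactions",
    "add_non_gene_reactions", "copy_subsystems",
    "GeneratorConfig", "PlantedTruth", "make_toy_pair", "make_milk_fixture",
    "make_milk_medium", "make_rescue_medium", "make_toy_genomes",
    "GenomeSummary", "summarize_fasta", "fixture_path",
]
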