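"""Synthetic model pairs, media, proteomes, and the curated milk fixture.

Everything here is generated code, not measured data. Two kinds of fixtures
are produced:

``make_milk_fixture``
    A hand-curated, deterministic two-member pair emulating the novel yoghurt
    consortium: a *Streptococcus thermophilus*-like member that grows in milk
    by itself (lactose catabolism via a lactose hydrolase, casein/peptide
    degradation via a cell-wall protease, full folate and purine
    biosynthesis) and a *Lactobacillus rhamnosus*-like member that cannot use
    lactose or casein and is auxotrophic for folate and purines. The
    streptococcal member obligately releases galactose (it ferments only the
    glucose moiety of lactose) and excretes succinate and glycerol as
    fermentation byproducts; the lactobacillus can grow on galactose,
    succinate or glycerol interchangeably and needs peptides, folate, and
    xanthine *or* guanine from its partner.

``make_toy_pair``
    A randomized generalization with a machine-readable planted ground truth
    (:class:`PlantedTruth`): which transfers are individually essential,
    which metabolite sets form jointly-but-not-individually essential
    OR-groups, and which shared metabolites are inactive. The transport
    knockout screen must recover this truth exactly; that recovery is the
    generator's core contract.

Biomass is a single lumped drain consuming one unit of a carbon currency,
pooled amino acids, and catalytic amounts of vitamins/cofactors. "Milk
peptides" are pooled into one pseudo-metabolite; water is carried in the
medium but has no stoichiometric role. Stoichiometry uses lumped currency
units rather than elemental balancing; no pathway creates mass from nothing
(every biomass precursor traces back to a medium uptake), so a closed medium
gives zero growth.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .model_io import Medium, MetabolicModel, Metabolite, Reaction, ValidationError

MILK_COMPONENTS = (
    "biotin",
    "lactose",
    "milk_peptides",
    "nicotinate",
    "pantothenate",
    "phosphate",
    "pyridoxamine",
    "riboflavin",
    "thiamin",
    "water",
)

_VITAMINS = (
    "biotin", "nicotinate", "pantothenate", "phosphate",
    "pyridoxamine", "riboflavin", "thiamin",
)


# ---------------------------------------------------------------------------
# small builder helper
# ---------------------------------------------------------------------------

class _Builder:
    def __init__(self, model_id: str):
        self.model = MetabolicModel(id=model_id, compartments={"c", "e"})
        self._mets: set[str] = set()

    def met(self, base: str, comp: str, name: str = "", annotation: str = ""):
        mid = f"{base}_{comp}"
        if mid not in self._mets:
            self._mets.add(mid)
            self.model.metabolites.append(
                Metabolite(id=mid, name=name or base, compartment=comp,
                           annotation=annotation)
            )
        return mid

    def rxn(self, rid: str, stoich: dict[str, float], lb: float = 0.0,
            ub: float = 1000.0, gene_rule: str | None = None,
            subsystem: str | None = None, kind: str = "internal",
            name: str = ""):
        self.model.reactions.append(
            Reaction(id=rid, name=name, stoichiometry=dict(stoich),
                     lower_bound=lb, upper_bound=ub, gene_rule=gene_rule,
                     subsystem=subsystem, kind=kind)
        )
        if gene_rule:
            from .reconstruction import gene_rule_ids

            self.model.genes |= gene_rule_ids(gene_rule)

    def exchange(self, base: str, name: str = "", annotation: str = ""):
        mid = self.met(base, "e", name=name, annotation=annotation)
        self.rxn(f"EX_{base}_e", {mid: -1.0}, lb=0.0, ub=1000.0, kind="exchange")
        return mid

    def biomass(self, rid: str, stoich: dict[str, float]):
        self.rxn(rid, stoich, lb=0.0, ub=1000.0, kind="biomass")
        self.model.objective_reaction_id = rid

    def build(self) -> MetabolicModel:
        from .model_io import validate_model

        validate_model(self.model)
        return self.model


def _biomass_drain(b: _Builder, extra: dict[str, float]) -> dict[str, float]:
    """Lumped biomass: 1 carbon unit + 1 amino-acid pool + cofactors."""
    stoich = {
        b.met("carbon", "c", "carbon units"): -1.0,
        b.met("amino_acids", "c", "pooled amino acids"): -1.0,
    }
    for vit in _VITAMINS:
        stoich[b.met(vit, "c")] = -0.01
    stoich.update(extra)
    return stoich


def _vitamin_uptake(b: _Builder, gene_prefix: str):
    for vit in _VITAMINS:
        ve = b.exchange(vit)
        vc = b.met(vit, "c")
        b.rxn(f"{vit.upper()}t", {ve: -1.0, vc: 1.0},
              gene_rule=f"{gene_prefix}{vit.capitalize()}T", kind="transport",
              subsystem="vitamin transport")


# ---------------------------------------------------------------------------
# the curated milk consortium fixture
# ---------------------------------------------------------------------------

def make_milk_medium() -> Medium:
    """The 10-component milk medium: lactose and casein-derived milk peptides
    as carbon/nitrogen sources plus B-vitamins, phosphate and water."""
    bounds = {comp: 1.0 for comp in MILK_COMPONENTS}
    bounds["lactose"] = 10.0
    bounds["milk_peptides"] = 10.0
    bounds["phosphate"] = 10.0
    bounds["water"] = 1000.0
    return Medium(uptake_bounds=bounds, name="milk")


def make_rescue_medium() -> Medium:
    """Milk supplemented the way a rich laboratory medium would be: free
    glucose, free amino acids, and a yeast-extract-like folate/purine source.
    Rescues the lactobacillus member's mono-culture growth."""
    medium = make_milk_medium()
    medium.uptake_bounds.update(
        {"glucose": 10.0, "amino_acids": 10.0, "folate": 1.0, "xanthine": 1.0}
    )
    medium.name = "milk_rescue"
    return medium


def _make_st_member() -> MetabolicModel:
    """Streptococcus-like member: proteolytic, lactose-positive, prototrophic;
    obligately releases galactose and excretes succinate + glycerol."""
    b = _Builder("ST_C106")

    lac_e = b.exchange("lactose", "Lactose")
    mp_e = b.exchange("milk_peptides", "Milk peptides (casein-derived)")
    pep_e = b.exchange("peptides", "Free peptides", annotation="Peptides")
    gal_e = b.exchange("galactose", "Galactose", annotation="Galactose")
    suc_e = b.exchange("succinate", "Succinate", annotation="Succinate")
    gly_e = b.exchange("glycerol", "Glycerol", annotation="Glycerol")
    fol_e = b.exchange("folate", "Folate", annotation="Folic acid")
    xan_e = b.exchange("xanthine", "Xanthine", annotation="Xanthine/Guanine")
    gua_e = b.exchange("guanine", "Guanine", annotation="Xanthine/Guanine")
    b.exchange("water", "Water")

    lac_c = b.met("lactose", "c")
    glc_c = b.met("glucose", "c")
    gal_c = b.met("galactose", "c")
    mp_c = b.met("milk_peptides", "c")
    pep_c = b.met("peptides", "c")
    aa_c = b.met("amino_acids", "c")
    car_c = b.met("carbon", "c")
    suc_c = b.met("succinate", "c")
    gly_c = b.met("glycerol", "c")
    fol_c = b.met("folate", "c")
    pur_c = b.met("purine", "c")
    xan_c = b.met("xanthine", "c")
    gua_c = b.met("guanine", "c")

    # lactose catabolism (lacAYZ-like): only the glucose moiety is fermented,
    # galactose is obligately released
    b.rxn("LACt", {lac_e: -1, lac_c: 1}, gene_rule="stLacS", kind="transport",
          subsystem="sugar transport", name="lactose permease")
    b.rxn("LACZ", {lac_c: -1, glc_c: 1, gal_c: 1}, gene_rule="stLacZ",
          subsystem="lactose catabolism", name="beta-galactosidase")
    b.rxn("GALts", {gal_c: -1, gal_e: 1}, gene_rule="stGalT", kind="transport",
          subsystem="sugar transport", name="galactose efflux")

    # fermentation: carbon units plus obligate succinate/glycerol byproducts
    b.rxn("FERM", {glc_c: -1, car_c: 2, suc_c: 2, gly_c: 2},
          gene_rule="stPyk or stLdh", subsystem="central fermentation",
          name="glucose fermentation (lumped)")
    b.rxn("SUCCts", {suc_c: -1, suc_e: 1}, kind="transport",
          subsystem="byproduct efflux")
    b.rxn("GLYCts", {gly_c: -1, gly_e: 1}, kind="transport",
          subsystem="byproduct efflux")

    # casein degradation (prtS) and peptide handling
    b.rxn("CASt", {mp_e: -1, mp_c: 1}, gene_rule="stPrtS", kind="transport",
          subsystem="proteolysis", name="cell-wall protease uptake (prtS)")
    b.rxn("PROT", {mp_c: -1, pep_c: 2}, gene_rule="stPrtS",
          subsystem="proteolysis", name="casein hydrolysis")
    b.rxn("PEPTt", {pep_c: -1, pep_e: 1}, lb=-1000.0, gene_rule="stOppA and stOppD",
          kind="transport", subsystem="proteolysis",
          name="peptide exchange (opp)")
    b.rxn("PEPDASE", {pep_c: -1, aa_c: 2}, gene_rule="stPepN",
          subsystem="proteolysis", name="peptidase")

    # folate and purine biosynthesis with efflux routes
    b.rxn("FOLS", {car_c: -1, fol_c: 1}, gene_rule="stFolK and stFolP",
          subsystem="folate biosynthesis")
    b.rxn("FOLts", {fol_c: -1, fol_e: 1}, gene_rule="stFolT", kind="transport",
          subsystem="folate biosynthesis")
    b.rxn("PURS", {car_c: -1, pur_c: 1}, gene_rule="stPurA",
          subsystem="purine biosynthesis")
    b.rxn("XANS", {pur_c: -1, xan_c: 1}, gene_rule="stXpt",
          subsystem="purine biosynthesis")
    b.rxn("GUAS", {pur_c: -1, gua_c: 1}, gene_rule="stGuaB",
          subsystem="purine biosynthesis")
    b.rxn("XANts", {xan_c: -1, xan_e: 1}, kind="transport",
          subsystem="purine biosynthesis")
    b.rxn("GUAts", {gua_c: -1, gua_e: 1}, kind="transport",
          subsystem="purine biosynthesis")

    _vitamin_uptake(b, "st")

    # cell-envelope detail carried over verbatim during reconstruction
    env_c = b.met("envelope", "c", "cell wall precursor pool")
    b.rxn("CWSYN", {car_c: -0.1, env_c: 0.1},
          gene_rule="stMurA", subsystem="cell wall")

    b.biomass(
        "BIOMASS_ST",
        _biomass_drain(b, {fol_c: -0.1, pur_c: -0.1}),
    )
    return b.build()


def _make_lr_member() -> MetabolicModel:
    """Lactobacillus-like member: lactose- and casein-negative, folate and
    purine auxotroph; grows on galactose, succinate or glycerol plus free
    peptides."""
    b = _Builder("LR_yoba2012")

    gal_e = b.exchange("galactose", "Galactose", annotation="Galactose")
    suc_e = b.exchange("succinate", "Succinate", annotation="Succinate")
    gly_e = b.exchange("glycerol", "Glycerol", annotation="Glycerol")
    glc_e = b.exchange("glucose", "Glucose")
    pep_e = b.exchange("peptides", "Free peptides", annotation="Peptides")
    aa_e = b.exchange("amino_acids", "Free amino acids")
    fol_e = b.exchange("folate", "Folate", annotation="Folic acid")
    xan_e = b.exchange("xanthine", "Xanthine", annotation="Xanthine/Guanine")
    gua_e = b.exchange("guanine", "Guanine", annotation="Xanthine/Guanine")

    gal_c = b.met("galactose", "c")
    suc_c = b.met("succinate", "c")
    gly_c = b.met("glycerol", "c")
    glc_c = b.met("glucose", "c")
    pep_c = b.met("peptides", "c")
    aa_c = b.met("amino_acids", "c")
    car_c = b.met("carbon", "c")
    fol_c = b.met("folate", "c")
    pur_c = b.met("purine", "c")
    xan_c = b.met("xanthine", "c")
    gua_c = b.met("guanine", "c")

    # alternative carbon sources (no lactose transporter, no protease)
    b.rxn("GALt", {gal_e: -1, gal_c: 1}, gene_rule="lrGalP", kind="transport",
          subsystem="sugar transport", name="galactose permease")
    b.rxn("GALK", {gal_c: -1, car_c: 1}, gene_rule="lrGalK",
          subsystem="galactose catabolism")
    b.rxn("SUCCt", {suc_e: -1, suc_c: 1}, gene_rule="lrDctA", kind="transport",
          subsystem="organic acid transport")
    b.rxn("SUCDH", {suc_c: -1, car_c: 1}, gene_rule="lrSdhA",
          subsystem="succinate catabolism")
    b.rxn("GLYCt", {gly_e: -1, gly_c: 1}, gene_rule="lrGlpF", kind="transport",
          subsystem="glycerol transport")
    b.rxn("GLPK", {gly_c: -1, car_c: 1}, gene_rule="lrGlpK",
          subsystem="glycerol catabolism")
    b.rxn("GLCt", {glc_e: -1, glc_c: 1}, gene_rule="lrPtsG", kind="transport",
          subsystem="sugar transport")
    b.rxn("GLK", {glc_c: -1, car_c: 2}, gene_rule="lrGlk",
          subsystem="glycolysis")

    # nitrogen: free peptides (opp/dtp) or free amino acids
    b.rxn("OPPt", {pep_e: -1, pep_c: 1}, gene_rule="lrOppA and lrOppD",
          kind="transport", subsystem="peptide transport",
          name="oligopeptide permease")
    b.rxn("PEPDASE", {pep_c: -1, aa_c: 2}, gene_rule="lrPepN",
          subsystem="proteolysis")
    b.rxn("AAt", {aa_e: -1, aa_c: 1}, gene_rule="lrLivJ", kind="transport",
          subsystem="amino acid transport")

    # folate/purine auxotrophies: uptake only, no biosynthesis
    b.rxn("FOLt", {fol_e: -1, fol_c: 1}, gene_rule="lrFolT", kind="transport",
          subsystem="folate salvage")
    b.rxn("XANt", {xan_e: -1, xan_c: 1}, kind="transport",
          subsystem="purine salvage")
    b.rxn("XPT", {xan_c: -1, pur_c: 1}, gene_rule="lrXpt",
          subsystem="purine salvage")
    b.rxn("GUAt", {gua_e: -1, gua_c: 1}, kind="transport",
          subsystem="purine salvage")
    b.rxn("HPT", {gua_c: -1, pur_c: 1}, gene_rule="lrHpt",
          subsystem="purine salvage")

    _vitamin_uptake(b, "lr")

    b.biomass(
        "BIOMASS_LR",
        _biomass_drain(b, {fol_c: -0.1, pur_c: -0.1}),
    )
    return b.build()


def make_milk_fixture() -> tuple[MetabolicModel, MetabolicModel, Medium]:
    """The curated deterministic mini consortium on the milk medium."""
    return _make_st_member(), _make_lr_member(), make_milk_medium()


# ---------------------------------------------------------------------------
# randomized planted-truth generator
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GeneratorConfig:
    n_extra_metabolites: int = 3
    n_redundant_paths: int = 2
    seed: int = 0
    noise_reactions: int = 2

    def __post_init__(self):
        bad = [
            f"{name} must be >= 0 (got {getattr(self, name)})"
            for name in ("n_extra_metabolites", "n_redundant_paths",
                         "noise_reactions")
            if getattr(self, name) < 0
        ]
        if bad:
            raise ValidationError(bad)


@dataclass
class PlantedTruth:
    essential_transfers: list[tuple[str, str, str]]  # (metabolite, donor, recipient)
    or_groups: list[frozenset]
    inactive_shared: list[str]


_N_ESSENTIAL = 2  # mirrors the curated consortium: one vitamin-like + one nitrogen-like


def make_toy_pair(
    config: GeneratorConfig,
) -> tuple[MetabolicModel, MetabolicModel, Medium, PlantedTruth]:
    """Random donor/recipient pair with planted cross-feeding ground truth.

    Member A catabolizes the medium's polymer substrate and can synthesize and
    secrete every transfer metabolite; member B cannot touch the polymer and
    requires each planted essential transfer plus one member of each planted
    OR-group. The same seed yields byte-identical serialized models.
    """
    rng = np.random.default_rng(config.seed)

    a = _Builder(f"toyA_s{config.seed}")
    bb = _Builder(f"toyB_s{config.seed}")

    medium = Medium(
        uptake_bounds={"polymer": 10.0, "mineral": 1.0, "water": 1000.0},
        name=f"toy_medium_s{config.seed}",
    )

    # --- member A: polymer catabolism into a currency pool
    pol_e = a.exchange("polymer")
    min_e_a = a.exchange("mineral")
    a.exchange("water")
    pol_c = a.met("polymer", "c")
    cur_a = a.met("currency", "c")
    min_c_a = a.met("mineral", "c")
    a.rxn("POLYt", {pol_e: -1, pol_c: 1}, gene_rule="aPolT", kind="transport")
    a.rxn("POLYCAT", {pol_c: -1, cur_a: 2}, gene_rule="aPolC")
    a.rxn("MINt", {min_e_a: -1, min_c_a: 1}, kind="transport")

    # --- member B scaffold
    min_e_b = bb.exchange("mineral")
    min_c_b = bb.met("mineral", "c")
    bb.rxn("MINt", {min_e_b: -1, min_c_b: 1}, kind="transport")
    b_biomass: dict[str, float] = {min_c_b: -0.01}

    essential: list[tuple[str, str, str]] = []
    for i in range(_N_ESSENTIAL):
        base = f"ess_met_{i}"
        me_a = a.exchange(base)
        mc_a = a.met(base, "c")
        a.rxn(f"SYN_{base}", {cur_a: -1, mc_a: 1}, gene_rule=f"aSyn{i}")
        a.rxn(f"SEC_{base}", {mc_a: -1, me_a: 1}, kind="transport")
        me_b = bb.exchange(base)
        mc_b = bb.met(base, "c")
        bb.rxn(f"UPT_{base}", {me_b: -1, mc_b: 1}, gene_rule=f"bUpt{i}",
               kind="transport")
        b_biomass[mc_b] = -0.1
        essential.append((base, a.model.id, bb.model.id))

    or_groups: list[frozenset] = []
    for g in range(config.n_redundant_paths):
        size = 2 + (g % 2)
        members = []
        pool_c = bb.met(f"pool_{g}", "c")
        for i in range(size):
            base = f"grp{g}_opt{i}"
            members.append(base)
            me_a = a.exchange(base)
            mc_a = a.met(base, "c")
            a.rxn(f"SYN_{base}", {cur_a: -1, mc_a: 1})
            a.rxn(f"SEC_{base}", {mc_a: -1, me_a: 1}, kind="transport")
            me_b = bb.exchange(base)
            mc_b = bb.met(base, "c")
            bb.rxn(f"UPT_{base}", {me_b: -1, mc_b: 1}, kind="transport")
            bb.rxn(f"CONV_{base}", {mc_b: -1, pool_c: 1})
        b_biomass[pool_c] = -0.1
        or_groups.append(frozenset(members))

    # a shared but unused metabolite: A can secrete it, B can import it,
    # but B has no consuming reaction so the transfer stays inactive
    idle_e_a = a.exchange("idle_met")
    idle_c_a = a.met("idle_met", "c")
    a.rxn("SYN_idle_met", {cur_a: -1, idle_c_a: 1})
    a.rxn("SEC_idle_met", {idle_c_a: -1, idle_e_a: 1}, kind="transport")
    idle_e_b = bb.exchange("idle_met")
    idle_c_b = bb.met("idle_met", "c")
    bb.rxn("UPT_idle_met", {idle_e_b: -1, idle_c_b: 1}, kind="transport")

    # decoy dead-end metabolites in A
    for i in range(config.n_extra_metabolites):
        xc = a.met(f"extra_{i}", "c")
        a.rxn(f"DIV_extra_{i}", {cur_a: -1, xc: 1})

    a.biomass("BIOMASS_A", {cur_a: -1.0, min_c_a: -0.01})
    bb.biomass("BIOMASS_B", b_biomass)

    model_a = a.build()
    model_b = bb.build()

    # noise reactions: random internal conversions in A, accepted only when
    # they leave mono and community growth unchanged (planted truth stays true)
    if config.noise_reactions:
        from .community import build_community, community_growth, mono_growth

        ref_a = mono_growth(model_a, medium)
        ref_b = mono_growth(model_b, medium)
        ref_mu, _, _ = community_growth(build_community(model_a, model_b, medium))
        internal = sorted(
            m.id for m in model_a.metabolites
            if m.compartment == "c" and m.id != "currency_c"
        )
        accepted = 0
        attempts = 0
        while accepted < config.noise_reactions and attempts < 20 * max(
            1, config.noise_reactions
        ):
            attempts += 1
            src, dst = rng.choice(internal, size=2, replace=False)
            candidate = model_a.copy()
            candidate.reactions.append(
                Reaction(
                    id=f"NOISE_{accepted}",
                    stoichiometry={src: -1.0, dst: 1.0},
                    lower_bound=0.0,
                    upper_bound=1000.0,
                    kind="internal",
                    subsystem="noise",
                )
            )
            mu_a = mono_growth(candidate, medium)
            mu_b = mono_growth(model_b, medium)
            mu_c, _, _ = community_growth(
                build_community(candidate, model_b, medium)
            )
            if (
                abs(mu_a - ref_a) < 1e-6
                and abs(mu_b - ref_b) < 1e-6
                and abs(mu_c - ref_mu) < 1e-6
            ):
                model_a = candidate
                accepted += 1

    truth = PlantedTruth(
        essential_transfers=essential,
        or_groups=or_groups,
        inactive_shared=["idle_met"],
    )
    return model_a, model_b, medium, truth


# ---------------------------------------------------------------------------
# toy proteomes for the reconstruction pipeline
# ---------------------------------------------------------------------------

_AA = "ACDEFGHIKLMNPQRSTVWY"


def make_toy_genomes(
    seed: int,
    n_genes: int = 5,
    mutation_rate: float = 0.1,
):
    """Reference proteome, a mutated query proteome plus decoys, and the true
    ortholog map ``{query_gene: reference_gene}``.

    Reference proteins are random sequences (length 80-150); query orthologs
    are per-residue point-mutated copies; decoys (one per two reference genes)
    are unrelated random sequences present only in the query.
    """
    from .reconstruction import ProteinSet

    if not 0.0 <= mutation_rate <= 0.5:
        raise ValueError("mutation_rate must lie in [0, 0.5]")
    rng = np.random.default_rng(seed)
    reference: dict[str, str] = {}
    query: dict[str, str] = {}
    truth: dict[str, str] = {}
    for i in range(n_genes):
        length = int(rng.integers(80, 151))
        seq = "".join(rng.choice(list(_AA), size=length))
        rid, qid = f"r{i:03d}", f"q{i:03d}"
        reference[rid] = seq
        mutated = [
            rng.choice(list(_AA)) if rng.random() < mutation_rate else ch
            for ch in seq
        ]
        query[qid] = "".join(mutated)
        truth[qid] = rid
    for i in range(n_genes // 2):
        length = int(rng.integers(80, 151))
        query[f"qdecoy{i:03d}"] = "".join(rng.choice(list(_AA), size=length))
    if n_genes == 0:
        return ProteinSet(entries={}), ProteinSet(entries={}), {}
    return ProteinSet(entries=query), ProteinSet(entries=reference), truth
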