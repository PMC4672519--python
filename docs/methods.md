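# Methods

This note documents the models, conventions, and design choices behind
`lactoflux`, in the order a user meets them: model representation, the LP
machinery, community coupling, the knockout screen, the synthetic fixtures,
reconstruction, and the genome summary utility.

## Model representation and formats

A metabolic model is a set of compartments (`"e"` is, by convention, the
extracellular compartment), metabolites with ids `<base>_<compartment>`,
reactions with signed stoichiometries and flux bounds
(mmol gDW⁻¹ h⁻¹ by convention), optional boolean gene rules (AND/OR over
gene ids), and one biomass objective. Reaction *kinds* — internal,
transport, exchange, biomass — are taken from files when present and
otherwise inferred: an exchange touches exactly one extracellular
metabolite; a transport spans ≥ 2 compartments. The compartment-free base id
is the join key that identifies "the same" compound across members of a
community; this is what makes "shared metabolite" well-defined.

Sign conventions: negative exchange flux is uptake into the system, positive
is secretion. Unspecified bounds default to [−1000, 1000] (reversible) or
[0, 1000] (irreversible) — the usual big-M convention.

Two dialects are supported. The JSON dialect round-trips every field; its
schema is exactly the keyword layout of `model_io._model_to_dict` (id,
compartments, metabolites, reactions, genes, objective). The SBML dialect is
a Level 3 core subset with the `fbc` version 2 package: flux bounds as
per-reaction parameter references, gene rules as gene-product associations,
the objective as an fbc flux objective. Units and annotations beyond a notes
field are deliberately out of scope. Validation checks every declared
invariant and reports *all* violations at once (k violations → k
diagnostics), which matters when fixing hand-edited models.

Media are TSV tables `metabolite → max_uptake` keyed by extracellular base
id; all bounds are ≥ 0 (they cap uptake; secretion is always open).

## LP machinery

All linear programs are solved with scipy's HiGHS backend
(`linprog(method="highs")`); the solver identity is recorded in run
manifests. Numerical choices:

- steady-state and bound tolerance: 1e-6 (asserted on every optimal solution
  in the test suite as a feasibility certificate);
- growth-abolition threshold: μ < 1e-6 h⁻¹ counts as "no growth";
- pFBA optimality slack: flux-norm minimization is constrained to
  c·v ≥ (1 − 1e-6) × optimum, with each reaction split into two nonnegative
  direction variables;
- FVA robustness fraction: 0.999. A transfer direction is *robust* when the
  FVA interval of the recipient's net uptake does not straddle zero — i.e.
  the direction holds across near-optimal alternative optima rather than
  being one solver's arbitrary pick among degenerate solutions.

Correctness of the FBA optimum is checked against an independent brute-force
oracle (vertex enumeration by fixing coordinate subsets at their bounds and
solving the remaining equality system) on seeded random systems of ≤ 6
reactions, and — on the curated fixture — against an independent
constraint-based toolbox reading this package's SBML output.

## Community model and coupling

Two members are merged by prefixing member-internal metabolites and
reactions with `A__`/`B__` and pooling extracellular metabolites on base id.
Member exchange reactions are replaced by exactly one community exchange per
extracellular metabolite, carrying the medium bounds; member transport
reactions are preserved unchanged. Balanced growth — required for a
consortium whose composition is stable over serial propagation — is encoded
as a hard equality row v_bio,A − v_bio,B = 0 appended to S. The community
objective maximizes v_bio,A, which equals v_bio,B under the coupling;
members are weighted 1:1 (the seed-culture context this emulates contains
equal cell counts of both strains, and nothing in the modelled scenario
justifies another ratio). A ratio or inequality coupling would be a
one-line change to the coupling row; hard equality is the simplest reading
of "equal growth rate" and is what ships.

A candidate cross-feeding direction exists for shared metabolite m when one
member has a transport reaction capable of secreting m (by sign and bounds)
and the other a transport capable of taking it up. Uptake-only metabolites
(e.g. vitamins both members import from the medium) are deliberately *not*
shared: nobody can donate them.

## The knockout screen

For each candidate direction, the screen records the recipient's net uptake
at the pFBA optimum, knocks out **all of the recipient's transport
reactions** for that metabolite, re-solves, and calls the transfer essential
iff μ < 1e-6. Recipient-side knockout is the default because it isolates the
consumer's dependence on the donation; donor-side knockout (disabling
secretion instead) is available via `knockout_side="donor"` for sensitivity
analysis. Records with zero transfer and no essentiality are retained but
flagged inactive.

OR-groups are discovered by exhaustive joint knockouts over the individually
non-essential metabolites, subsets of size 2 and 3 in deterministic
(size, lexicographic) order, keeping only minimal jointly-essential sets.
The size cap of 3 matches the largest redundancy structure the fixture
plants (three alternative carbon sources) and keeps the enumeration safe;
the enumerator refuses outright above 2¹⁵ subsets rather than silently
truncating. All orderings and tie-breaks are lexicographic, so reports are
byte-identical across runs.

One mass-balance subtlety: at a community optimum, a donor's secretion of m
equals the recipient's uptake *plus* net export through the community
exchange (S·v = 0 on the pool row). Donor secretion equals recipient uptake
only for metabolites with no system export; galactose is the standing
counterexample — the donor releases more than the recipient consumes and the
surplus accumulates in the medium. The test suite asserts the three-term
balance, not the two-term shortcut.

## Synthetic fixtures

### The curated milk consortium (`make_milk_fixture`)

Two hand-curated members (43 and 40 reactions) on a 10-component milk
medium: biotin, lactose, milk peptides, nicotinate, pantothenate, phosphate,
pyridoxamine, riboflavin, thiamin, water. Default uptake caps: 10 for the
two macro-substrates (lactose, milk peptides), 10 for phosphate, 1 for each
vitamin, 1000 for water — vitamin demand is catalytic (0.01 per unit
biomass), so these caps never bind at the fixture's scale. Water is carried
in the medium but has no stoichiometric role.

The streptococcal member imports lactose and hydrolyzes it to glucose +
galactose, ferments only the glucose moiety (galactose release is therefore
*obligatory*), and its lumped fermentation reaction co-produces succinate
and glycerol as obligate byproducts — which is why both appear as secreted
at the parsimonious optimum rather than depending on a solver whim. It
degrades casein-like milk peptides through a cell-wall protease into free
peptides (shared with the partner via a reversible peptide transporter) and
synthesizes folate and purines (xanthine/guanine efflux routes) from its
carbon pool. The lactobacillus member has no lactose transporter and no
protease; it imports galactose, succinate or glycerol (each convertible to
the same carbon currency, 1:1), free peptides (its only nitrogen source in
milk), folate (no biosynthesis — a strict auxotrophy) and xanthine or
guanine (interchangeable purine salvage). Biomass in both members is a
single lumped drain: 1 carbon unit + 1 amino-acid pool + 0.1 folate +
0.1 purine + 0.01 of each vitamin. Stoichiometry uses lumped currency units,
not elemental balancing; the construction guarantees no pathway creates mass
from nothing, so a fully closed medium yields zero growth in both members.

What the fixture does *not* emulate: genome-scale reaction counts, elemental
or energy (ATP/redox) bookkeeping, product inhibition (the experimental
observation that accumulated galactose inhibits the producer is kinetic, not
stoichiometric), pH and temperature effects, and any abundance dynamics.
Passing screens on this fixture demonstrate that the pipeline's logic
recovers the designed dependency structure — not that a particular real
strain pair has these exact interactions.

A supplemented variant (`make_rescue_medium`) adds free glucose, free amino
acids, and a yeast-extract-like folate + xanthine supplement; on it the
lactobacillus grows alone (10.0 h⁻¹ at the fixture's scale), mirroring the
fact that rich supplementation — not only a partner strain — can rescue its
growth. Glucose and amino acids alone would not suffice: the folate/purine
auxotrophies are strict by design, and real-world supplements of this type
(yeast extract) are folate and purine sources.

The fixture is versioned: the generator is the source of truth and the
shipped JSON/TSV copies under `src/lactoflux/data/milk_consortium_mini/` are
asserted byte-equivalent in tests. The classical yoghurt consortium's
interaction pattern ships there too, as a static annotation table only — it
is literature-derived background, not something this package computes.

### The planted-truth generator (`make_toy_pair`)

A randomized generalization used for property testing: member A catabolizes
a polymer substrate (10 uptake cap) into a currency pool; member B cannot.
Two transfers are always planted as individually essential (the fixed count
mirrors the two strict dependencies of the curated consortium — a
vitamin-like and a nitrogen-like donation); `n_redundant_paths` OR-groups of
sizes alternating 2, 3 are planted as jointly-but-not-individually
essential; one shared-but-unused metabolite is planted as inactive; decoy
dead-end metabolites and random internal noise reactions pad the structure.
Noise reactions are accepted only if they leave both mono-culture growth
values and the community optimum unchanged (checked by FBA at generation
time), so the planted truth remains true by construction. Identical seeds
produce byte-identical serialized models. The generator's core contract —
the screen recovers exactly the planted truth, precision = recall = 1 — is
exercised across 20 seeds in the acceptance suite.

### Toy proteomes (`make_toy_genomes`)

Reference proteins are uniform-random sequences (length 80–150); query
orthologs are per-residue point-mutated copies; decoys (one per two genes)
are unrelated random sequences. Real proteomes have paralogs, domain
shuffling, and compositional bias that uniform-random sequences lack, so
recovery rates here are upper bounds on real-data performance; the tests
therefore assert exact recovery only at mutation rate 0 and a monotone trend
elsewhere.

## Reconstruction choices

Ortholog detection is a k-mer Jaccard bidirectional best hit (defaults
k = 5, min_score = 0.3): deterministic, dependency-free, adequate at the
scale of curated fixtures; a TSV pair table from any external orthology tool
is accepted interchangeably. Under a partial map, unmapped reference genes
evaluate FALSE — conservative transfer: an AND-rule reaction is dropped
unless every subunit has an ortholog, an OR-rule survives on any one isozyme
— and surviving rules are rewritten to query gene ids with the dead branches
pruned. The biomass reaction is always carried over (drafts must be able to
grow; biomass composition is not orthology-transferable). Non-gene-associated
reactions (exchanges, spontaneous transports) are added afterwards,
deduplicated by id; whole subsystems (e.g. cell wall components, fatty acid
biosynthesis) can be copied verbatim when their detail is not the study's
focus. Transfer is monotone in the ortholog map, and the identity map plus
non-gene addition reproduces the reference reaction set exactly — both are
tested invariants.

## Genome summary

`summarize_fasta` reports contig count, total length in bp (ambiguous bases
included) and Mbp (2 decimals), and GC% (1 decimal) computed as
100·(G+C)/(A+C+G+T) case-insensitively with IUPAC ambiguity codes excluded
from numerator and denominator. Whether published GC figures include
ambiguous bases is rarely stated; at draft-genome ambiguity levels the two
conventions differ negligibly, and `gc_denominator="all"` switches to the
all-bases denominator for comparison.

## Problem sizes and determinism

All shipped analyses run at desk scale by design: fixture members are 40–45
reactions, random LP-oracle systems ≤ 6 reactions (20 seeds), the recovery
sweep 20 generated pairs, and the OR-group enumerator at most a few dozen
LPs per community — the full test suite and the acceptance script each
complete in seconds. Every random component is seeded through
`numpy.random.default_rng`; reports and serialized models are byte-stable
across runs with the same seed.

## Known limitations

Two members only; 1:1 abundance; reaction-level knockouts (no gene-level
deletion through GPR compilation); no MILP, thermodynamic, dynamic, or
kinetic extensions; SBML support is the fbc-flavoured subset needed here,
not the full specification.
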