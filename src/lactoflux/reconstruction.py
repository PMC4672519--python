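"""Orthology-driven draft reconstruction.

Builds a draft metabolic model for a query organism by transferring reactions
from a curated reference model through an ortholog map. The pipeline is the
classical comparative-genomics recipe for lactic acid bacteria: detect
orthologs between the query and reference proteomes, keep every
gene-associated reference reaction whose gene rule is satisfied by the mapped
genes, then top the draft up with the reference's non-gene-associated
reactions (exchanges, spontaneous transports) and, optionally, whole
subsystems (cell wall components, fatty acid biosynthesis) copied verbatim.

Ortholog detection here is a deterministic k-mer Jaccard bidirectional best
hit (BBH): two proteins are called orthologs when each is the other's unique
highest-similarity match and the similarity clears a threshold. Any external
orthology tool can be substituted by supplying a TSV pair table instead.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

from .model_io import MetabolicModel, Reaction, ValidationError

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# gene (GPR) rules: boolean expressions over gene ids with AND/OR/parens
# ---------------------------------------------------------------------------

class _RuleParser:
    """Recursive-descent parser for ``gA and (gB or gC)`` style rules."""

    def __init__(self, rule: str):
        self.tokens = self._tokenize(rule)
        self.pos = 0

    @staticmethod
    def _tokenize(rule: str) -> list[str]:
        tokens, cur = [], []
        for ch in rule:
            if ch in "()":
                if cur:
                    tokens.append("".join(cur))
                    cur = []
                tokens.append(ch)
            elif ch.isspace():
                if cur:
                    tokens.append("".join(cur))
                    cur = []
            else:
                cur.append(ch)
        if cur:
            tokens.append("".join(cur))
        return tokens

    def _peek(self):
        return self.tokens[self.pos] if self.pos < len(self.tokens) else None

    def parse(self):
        node = self._expr()
        if self._peek() is not None:
            raise ValueError(f"unexpected token '{self._peek()}' in gene rule")
        return node

    def _expr(self):
        terms = [self._term()]
        while self._peek() is not None and self._peek().lower() == "or":
            self.pos += 1
            terms.append(self._term())
        return ("or", terms) if len(terms) > 1 else terms[0]

    def _term(self):
        factors = [self._factor()]
        while self._peek() is not None and self._peek().lower() == "and":
            self.pos += 1
            factors.append(self._factor())
        return ("and", factors) if len(factors) > 1 else factors[0]

    def _factor(self):
        tok = self._peek()
        if tok is None:
            raise ValueError("gene rule ended unexpectedly")
        if tok == "(":
            self.pos += 1
            node = self._expr()
            if self._peek() != ")":
                raise ValueError("unbalanced parenthesis in gene rule")
            self.pos += 1
            return node
        if tok == ")" or tok.lower() in ("and", "or"):
            raise ValueError(f"unexpected token '{tok}' in gene rule")
        self.pos += 1
        return ("gene", tok)


def parse_gene_rule(rule: str):
    return _RuleParser(rule).parse()


def gene_rule_ids(rule: str) -> set[str]:
    """All gene ids mentioned in a rule."""
    out: set[str] = set()

    def walk(node):
        if node[0] == "gene":
            out.add(node[1])
        else:
            for child in node[1]:
                walk(child)

    walk(parse_gene_rule(rule))
    return out


def evaluate_gene_rule(rule: str, active_genes: set[str]) -> bool:
    """Evaluate a rule with listed genes TRUE and all others FALSE."""

    def ev(node):
        if node[0] == "gene":
            return node[1] in active_genes
        if node[0] == "and":
            return all(ev(c) for c in node[1])
        return any(ev(c) for c in node[1])

    return ev(parse_gene_rule(rule))


def _rewrite_rule(node, mapping: dict[str, list[str]]):
    """Substitute mapped reference genes by query genes; unmapped genes are
    FALSE and the expression is simplified. Returns an infix string or None
    when the whole rule evaluates FALSE."""
    if node[0] == "gene":
        repl = mapping.get(node[1])
        if not repl:
            return None
        return repl[0] if len(repl) == 1 else "(" + " or ".join(sorted(repl)) + ")"
    parts = [_rewrite_rule(c, mapping) for c in node[1]]
    if node[0] == "and":
        if any(p is None for p in parts):
            return None
        return " and ".join(f"({p})" if " or " in p and not p.startswith("(") else p
                            for p in parts)
    parts = [p for p in parts if p is not None]
    if not parts:
        return None
    return " or ".join(parts) if len(parts) > 1 else parts[0]


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class OrthologPair:
    query_gene: str
    reference_gene: str
    score: float

    def __post_init__(self):
        if not 0.0 <= self.score <= 1.0:
            raise ValidationError([f"ortholog score {self.score} outside [0, 1]"])


@dataclass
class ProteinSet:
    """Gene id -> amino-acid sequence (uppercase 20-letter alphabet plus X)."""

    entries: dict[str, str]

    def __post_init__(self):
        empty = [g for g, s in self.entries.items() if not s]
        if empty:
            raise ValidationError([f"empty sequence for gene '{g}'" for g in empty])


def read_fasta_proteins(path) -> ProteinSet:
    from Bio import SeqIO

    entries = {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}
    return ProteinSet(entries=entries)


def read_pair_table(path) -> list[OrthologPair]:
    """TSV with header ``query<TAB>reference<TAB>score``."""
    import pandas as pd

    table = pd.read_csv(path, sep="\t")
    return [
        OrthologPair(str(r["query"]), str(r["reference"]), float(r["score"]))
        for _, r in table.iterrows()
    ]


def write_pair_table(pairs: list[OrthologPair], path) -> None:
    with open(path, "w") as fh:
        fh.write("query\treference\tscore\n")
        for p in pairs:
            fh.write(f"{p.query_gene}\t{p.reference_gene}\t{p.score:.6f}\n")


# ---------------------------------------------------------------------------
# ortholog detection
# ---------------------------------------------------------------------------

def _kmers(seq: str, k: int) -> frozenset:
    return frozenset(seq[i : i + k] for i in range(len(seq) - k + 1))


def kmer_jaccard(a: str, b: str, k: int) -> float:
    """Jaccard index of the k-mer sets of two sequences."""
    ka, kb = _kmers(a, k), _kmers(b, k)
    if not ka and not kb:
        return 0.0
    union = len(ka | kb)
    return len(ka & kb) / union if union else 0.0


def kmer_bbh(
    query: ProteinSet,
    reference: ProteinSet,
    k: int = 5,
    min_score: float = 0.3,
) -> list[OrthologPair]:
    """Bidirectional-best-hit ortholog pairs under k-mer Jaccard similarity.

    A pair (q, r) is returned iff q's unique best reference hit is r, r's
    unique best query hit is q, and their similarity is >= ``min_score``.
    Output is sorted by descending score, ties broken by query gene id.
    """
    if k < 3:
        raise ValueError("k must be >= 3")
    if not 0.0 <= min_score <= 1.0:
        raise ValueError("min_score must lie in [0, 1]")
    qids = sorted(query.entries)
    rids = sorted(reference.entries)
    if not qids or not rids:
        return []
    sim = {
        q: {r: kmer_jaccard(query.entries[q], reference.entries[r], k) for r in rids}
        for q in qids
    }

    def unique_argmax(scores: dict[str, float]):
        best = max(scores.values())
        tops = [i for i, s in scores.items() if s == best]
        return tops[0] if len(tops) == 1 else None

    pairs = []
    for q in qids:
        r = unique_argmax(sim[q])
        if r is None or sim[q][r] < min_score:
            continue
        back = unique_argmax({qq: sim[qq][r] for qq in qids})
        if back == q:
            pairs.append(OrthologPair(q, r, sim[q][r]))
    pairs.sort(key=lambda p: (-p.score, p.query_gene))
    return pairs


# ---------------------------------------------------------------------------
# reaction transfer
# ---------------------------------------------------------------------------

def _carry_metabolites(target: MetabolicModel, source: MetabolicModel, rxn: Reaction):
    known = set(target.metabolite_map)
    smap = source.metabolite_map
    for mid in rxn.stoichiometry:
        if mid not in known:
            met = smap[mid]
            target.metabolites.append(
                type(met)(
                    id=met.id,
                    name=met.name,
                    compartment=met.compartment,
                    formula=met.formula,
                    annotation=met.annotation,
                )
            )
            target.compartments.add(met.compartment)


def transfer_reactions(
    reference_model: MetabolicModel,
    pairs: list[OrthologPair],
    query_id: str,
) -> MetabolicModel:
    """Transfer gene-associated reactions supported by the ortholog map.

    A reference reaction is kept iff its gene rule evaluates TRUE with mapped
    reference genes set true and all unmapped genes false; rules are rewritten
    to query gene ids. The biomass reaction is always carried over (biomass is
    not orthology-transferable but every draft must be able to grow).
    """
    unknown = {p.reference_gene for p in pairs} - reference_model.genes
    if unknown:
        raise ValidationError(
            [f"ortholog pair references unknown reference gene '{g}'"
             for g in sorted(unknown)]
        )
    mapping: dict[str, list[str]] = {}
    for p in pairs:
        mapping.setdefault(p.reference_gene, []).append(p.query_gene)
    for v in mapping.values():
        v.sort()

    draft = MetabolicModel(id=query_id)
    draft.genes = {q for qs in mapping.values() for q in qs}
    for rxn in reference_model.reactions:
        keep = False
        new_rule = None
        if rxn.id == reference_model.objective_reaction_id or rxn.kind == "biomass":
            keep = True
            new_rule = rxn.gene_rule
            if new_rule:
                draft.genes |= gene_rule_ids(new_rule)
        elif rxn.gene_rule:
            new_rule = _rewrite_rule(parse_gene_rule(rxn.gene_rule), mapping)
            keep = new_rule is not None
        if keep:
            new = rxn.copy()
            new.gene_rule = new_rule
            draft.reactions.append(new)
            _carry_metabolites(draft, reference_model, new)
    draft.objective_reaction_id = reference_model.objective_reaction_id
    logger.info(
        "transferred %d/%d reference reactions to draft '%s'",
        len(draft.reactions), len(reference_model.reactions), query_id,
    )
    return draft


def add_non_gene_reactions(
    draft: MetabolicModel, reference_model: MetabolicModel
) -> MetabolicModel:
    """Add every non-gene-associated reference reaction (exchanges,
    spontaneous transports) absent from the draft. Idempotent."""
    result = draft.copy()
    present = result.reaction_map
    for rxn in reference_model.reactions:
        if rxn.gene_rule:
            continue
        if rxn.id in present:
            if rxn.stoichiometry != present[rxn.id].stoichiometry:
                raise ValidationError(
                    [f"reaction id '{rxn.id}' already present with different "
                     "stoichiometry"]
                )
            continue
        new = rxn.copy()
        if new.kind == "biomass" and result.objective_reaction_id != new.id:
            new.kind = "internal"
        result.reactions.append(new)
        present[new.id] = new
        _carry_metabolites(result, reference_model, new)
    return result


def copy_subsystems(
    draft: MetabolicModel,
    reference_model: MetabolicModel,
    subsystems: list[str],
) -> MetabolicModel:
    """Copy all reactions of the named reference subsystems verbatim (gene
    rules included; their genes are added to the draft gene set)."""
    known = {r.subsystem for r in reference_model.reactions if r.subsystem}
    missing = [s for s in subsystems if s not in known]
    if missing:
        raise ValidationError(
            [f"unknown subsystem '{s}' (known: {sorted(known)})" for s in missing]
        )
    result = draft.copy()
    present = result.reaction_map
    for rxn in reference_model.reactions:
        if rxn.subsystem not in subsystems or rxn.id in present:
            continue
        new = rxn.copy()
        result.reactions.append(new)
        present[new.id] = new
        _carry_metabolites(result, reference_model, new)
        if new.gene_rule:
            result.genes |= gene_rule_ids(new.gene_rule)
    return result
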