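"""Two-criterion taxonomic identification of query OTUs.

A query OTU is accepted at species rank only when two independent criteria
agree: (1) its best-hit percent identity against the reference library
reaches the species threshold (default 98%), and (2) the query clusters
conclusively with references of a single species on a bootstrapped
neighbor-joining tree.  When the identity criterion fails, or the tree is
conclusive only at a higher rank, the OTU is identified at that higher rank
(genus, family, or order); when no supported clade is informative the OTU is
left unresolved.

"Conclusive clustering" is operationalized as monophyly of the query with
references of a single taxon at the candidate rank, on the tree rooted at
the outgroup edge, with bootstrap support at or above ``min_support``
(default 50%).
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping

from .phylo import BootstrapConfig, PhyloTree, align_star, bootstrap_supports
from .refdb import ASSIGNABLE_RANKS, Lineage, ReferenceDB, outgroup_candidates
from .seqops import (AlignmentParams, DEFAULT_PARAMS, IdentityResult, OTU,
                     rank_references)

__all__ = [
    "AssignmentConfig", "TaxonAssignment", "CladeRankResult",
    "clade_rank", "resolve_level", "assign_taxon", "assign_all",
    "label_genus_calls",
]

_RANK_ORDER = {r: i for i, r in enumerate(ASSIGNABLE_RANKS)}  # species=0 ... order=3


class AssignError(ValueError):
    pass


@dataclass(frozen=True)
class AssignmentConfig:
    species_identity_threshold: float = 98.0
    n_reference_hits: int = 10
    n_outgroups: int = 3
    min_support: float = 50.0
    bootstrap: BootstrapConfig = field(default_factory=BootstrapConfig)
    alignment: AlignmentParams = DEFAULT_PARAMS
    distance_model: str = "k2p"

    def __post_init__(self) -> None:
        if not 0 < self.species_identity_threshold <= 100:
            raise ValueError("species_identity_threshold must be in (0, 100]")


@dataclass(frozen=True)
class CladeRankResult:
    """Lowest rank at which the query clusters conclusively."""

    rank: str  # species | genus | family | order | unresolved
    supporting_clade: frozenset
    taxon: str = ""
    support: float = 0.0


@dataclass
class TaxonAssignment:
    otu_id: str
    assigned_taxon: str
    assigned_rank: str  # species | genus | family | order | unresolved
    identity_percent: float
    identity_pass: bool
    clade_conclusive_rank: str
    best_hit_accession: str = ""
    supporting_clade: frozenset = frozenset()
    tree_newick: str = ""
    error: str = ""


def _query_side_clades(tree: PhyloTree, query_leaf: str, outgroup_leaf: str
                       ) -> list[frozenset]:
    """Nested leaf sets containing the query, from the query pendant edge up
    to (but not including) the side facing the rooting outgroup."""
    leaves = {l.name: l for l in tree.root.leaves()}
    if query_leaf not in leaves:
        raise AssignError(f"query leaf {query_leaf!r} not in tree")
    if outgroup_leaf not in leaves:
        raise AssignError(f"outgroup leaf {outgroup_leaf!r} not in tree")
    # path from query to outgroup through the (arbitrary) rooted representation
    def ancestors(node):
        chain = []
        while node is not None:
            chain.append(node)
            node = node.parent
        return chain

    qa = ancestors(leaves[query_leaf])
    oa = ancestors(leaves[outgroup_leaf])
    qa_ids = {id(n): k for k, n in enumerate(qa)}
    meet = next(n for n in oa if id(n) in qa_ids)
    path = qa[: qa_ids[id(meet)] + 1] + list(
        reversed(oa[: next(k for k, n in enumerate(oa) if n is meet)])
    )
    # cutting each successive edge along the path yields the nested clades on
    # the query side
    all_names = frozenset(tree.labels)
    clades = []
    for a, b in zip(path[:-1], path[1:]):  # edge between consecutive nodes
        if a.parent is b:  # ascending: query side is a's subtree
            clades.append(a.leaf_names())
        else:  # descending: b is a child of a; query side excludes b's subtree
            clades.append(all_names - b.leaf_names())
    return clades


def clade_rank(tree: PhyloTree, query_leaf: str,
               lineages: Mapping[str, Lineage], min_support: float,
               outgroup_leaves: list[str]) -> CladeRankResult:
    """Most specific rank at which a supported clade unites the query with
    references of a single taxon.

    The tree is read as rooted on the edge to the first outgroup leaf; the
    nested clades containing the query are tested from the tips rootward.
    Clades containing any designated outgroup are skipped (outgroups only
    root the tree), as are clades below ``min_support`` bootstrap support.
    """
    if not outgroup_leaves:
        raise AssignError("no outgroup to root on")
    outset = set(outgroup_leaves)
    best: CladeRankResult | None = None
    for clade in _query_side_clades(tree, query_leaf, outgroup_leaves[0]):
        if clade & outset:
            continue
        refs = [l for l in clade if l != query_leaf and l in lineages]
        if not refs:
            continue
        support = tree.support_of(clade)
        if support < min_support:
            continue
        for rank in ASSIGNABLE_RANKS:
            names = {lineages[l].at(rank) for l in refs}
            if "" in names or len(names) != 1:
                continue
            cand = CladeRankResult(rank, clade, names.pop(), support)
            if best is None or _RANK_ORDER[rank] < _RANK_ORDER[best.rank]:
                best = cand
            break  # only the most specific rank of this clade matters
    if best is None:
        return CladeRankResult("unresolved", frozenset())
    return best


def resolve_level(identity_percent: float, threshold: float,
                  clade_conclusive_rank: str) -> str:
    """The decision rule combining the identity and tree criteria.

    Species rank requires both the identity threshold and a species-level
    conclusive clade; with a passing identity but a less specific clade the
    call is demoted to the clade rank; with a failing identity the call can
    never be species, so a species-level clade yields a genus-level call.
    """
    if clade_conclusive_rank == "unresolved":
        return "unresolved"
    if identity_percent >= threshold:
        return clade_conclusive_rank
    if clade_conclusive_rank == "species":
        return "genus"
    return clade_conclusive_rank


def _name_for(rank: str, best_lineage: Lineage, clade: CladeRankResult) -> str:
    if rank == "species":
        return best_lineage.species
    if rank == "unresolved":
        return ""
    if rank == "genus":
        genus = clade.taxon if clade.rank == "genus" else best_lineage.genus
        return f"{genus} sp."
    return clade.taxon or best_lineage.at(rank)


def assign_taxon(otu: OTU, db: ReferenceDB, cfg: AssignmentConfig) -> TaxonAssignment:
    """Identify one OTU: best hit, NJ+bootstrap tree, clade rank, decision rule.

    The tree is built over the query, its top ``n_reference_hits`` reference
    hits, and ``n_outgroups`` outgroups from the nearest other families.
    """
    if len(db) == 0:
        raise AssignError("empty reference library")
    if otu.representative is None:
        raise AssignError(f"{otu.otu_id}: no representative sequence")
    ranked = rank_references(otu.representative, db, cfg.alignment)
    best = ranked[0]
    otu.identity = best
    best_lineage = db.lineage_of(best.best_hit)
    outgroups = outgroup_candidates(db, best_lineage, cfg.n_outgroups)
    if not outgroups:
        raise AssignError(
            f"{otu.otu_id}: reference library has no outgroup family"
        )
    out_accs = {r.accession for r in outgroups}
    hits = [r for r in ranked if r.best_hit not in out_accs][: cfg.n_reference_hits]
    # anchor the star alignment on the best-hit reference
    seqs: dict[str, str] = {best.best_hit: db.by_accession[best.best_hit].sequence}
    seqs[otu.otu_id] = otu.representative
    for r in hits:
        seqs.setdefault(r.best_hit, db.by_accession[r.best_hit].sequence)
    for rec in outgroups:
        seqs[rec.accession] = rec.sequence
    msa = align_star(seqs, cfg.alignment)
    tree = bootstrap_supports(msa, cfg.bootstrap, model=cfg.distance_model)
    lineages = {acc: db.lineage_of(acc) for acc in seqs if acc != otu.otu_id}
    clade = clade_rank(tree, otu.otu_id, lineages, cfg.min_support,
                       [r.accession for r in outgroups])
    identity_pass = best.percent_identity >= cfg.species_identity_threshold
    effective_clade_rank = clade.rank
    if identity_pass and effective_clade_rank == "species":
        # ambiguous best hit: equal top identity to two different species
        top_species = {
            db.lineage_of(r.best_hit).species
            for r in ranked
            if r.percent_identity == best.percent_identity
        }
        if len(top_species) > 1:
            effective_clade_rank = "genus"
    rank = resolve_level(best.percent_identity, cfg.species_identity_threshold,
                         effective_clade_rank)
    assignment = TaxonAssignment(
        otu_id=otu.otu_id,
        assigned_taxon=_name_for(rank, best_lineage, clade),
        assigned_rank=rank,
        identity_percent=best.percent_identity,
        identity_pass=identity_pass,
        clade_conclusive_rank=clade.rank,
        best_hit_accession=best.best_hit,
        supporting_clade=clade.supporting_clade,
        tree_newick=tree.to_newick(),
    )
    otu.assignment = assignment
    return assignment


def label_genus_calls(assignments: list[TaxonAssignment]) -> None:
    """Number genus-level calls sharing a genus: 'Asellus sp. 1', 'Asellus sp. 2'.

    A genus with a single OTU keeps the plain '<Genus> sp.' label.
    """
    by_genus: dict[str, list[TaxonAssignment]] = {}
    for a in assignments:
        if a.assigned_rank == "genus" and a.assigned_taxon.endswith(" sp."):
            by_genus.setdefault(a.assigned_taxon, []).append(a)
    for base, group in by_genus.items():
        if len(group) > 1:
            for k, a in enumerate(group, start=1):
                a.assigned_taxon = f"{base} {k}"


def assign_all(otus: list[OTU], db: ReferenceDB, cfg: AssignmentConfig,
               seed: int = 0) -> list[TaxonAssignment]:
    """Assign every OTU with a per-OTU derived bootstrap seed; stable order.

    Per-OTU failures are captured in the assignment's ``error`` field (rank
    'unresolved') instead of aborting the batch.
    """
    out: list[TaxonAssignment] = []
    for k, otu in enumerate(otus):
        sub = replace(cfg, bootstrap=replace(
            cfg.bootstrap, seed=(seed * 100003 + 7919 * k + 1) % (2 ** 31)))
        try:
            out.append(assign_taxon(otu, db, sub))
        except Exception as exc:  # noqa: BLE001 - aggregate per-OTU errors
            out.append(TaxonAssignment(
                otu_id=otu.otu_id, assigned_taxon="", assigned_rank="unresolved",
                identity_percent=float("nan"), identity_pass=False,
                clade_conclusive_rank="unresolved", error=str(exc)))
    label_genus_calls(out)
    return out
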