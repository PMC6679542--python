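"""Flanking-gene contexts, synteny conservation, phylogenetic linking of
syntenies through intermediate species, and tandem gene-cluster resolution.

Conserved synteny here means shared flanking-gene *content*, not order
identity: genomes related by inversions and translocations still share
neighbors even when orientation and order differ, and that is the evidence
used to accept an orthology call.  When the query and target neighborhoods
have diverged beyond direct comparison, conservation can sometimes still be
established transitively through intermediate species, each of which must
both share synteny with its neighbors in the chain and align preferentially
back to the correct query locus.
"""

from __future__ import annotations

from collections import deque
from dataclasses import dataclass, field

import dendropy

from .alignment_io import GeneAnnotation

DEFAULT_FLANKING_K = 2


@dataclass
class SyntenyContext:
    """Ordered, oriented flanking genes around a focal locus.

    ``upstream`` and ``downstream`` are (symbol, strand) pairs in order of
    increasing distance from the focal gene; each list holds at most ``k``
    entries and excludes the focal gene.  ``scaffoldEdges`` flags sides cut
    short by the end of the scaffold.
    """

    gene: str
    upstream: list[tuple[str, str]]
    downstream: list[tuple[str, str]]
    k: int
    scaffoldEdges: dict[str, bool] = field(
        default_factory=lambda: {"upstream": False, "downstream": False}
    )

    def side_symbols(self, side: str) -> set[str]:
        return {sym for sym, _ in getattr(self, side)}

    def all_symbols(self) -> set[str]:
        return self.side_symbols("upstream") | self.side_symbols("downstream")


@dataclass
class SyntenyLink:
    """A chain of species linking the synteny of query and target."""

    speciesChain: list[str]
    verdict: str  # direct | phylo-linked | unresolved


def flanking_context(
    annotation: list[GeneAnnotation], gene: str, k: int = DEFAULT_FLANKING_K
) -> SyntenyContext:
    """The k nearest genes on each side of ``gene``, in increasing distance.

    Genes on the same seqid are totally ordered by start coordinate.  A
    side truncated by the scaffold end sets the corresponding
    ``scaffoldEdges`` flag.
    """
    focal = [a for a in annotation if a.gene == gene]
    if not focal:
        raise KeyError(f"gene {gene!r} not present in annotation")
    locus = focal[0]
    same_scaffold = sorted(
        (a for a in annotation if a.seqid == locus.seqid),
        key=lambda a: (a.start, a.end, a.gene),
    )
    idx = next(i for i, a in enumerate(same_scaffold) if a.gene == gene)
    upstream = [
        (a.gene, a.strand) for a in reversed(same_scaffold[max(0, idx - k) : idx])
    ]
    downstream = [(a.gene, a.strand) for a in same_scaffold[idx + 1 : idx + 1 + k]]
    edges = {
        "upstream": len(upstream) < k,
        "downstream": len(downstream) < k,
    }
    return SyntenyContext(gene, upstream, downstream, k, edges)


def synteny_conserved(ctx_a: SyntenyContext, ctx_b: SyntenyContext) -> str:
    """Compare two flanking contexts: ``direct``/``divergent``/``unresolvable``.

    Direct requires at least one shared flanking symbol on each side of
    *both* contexts (a side may match the other context's opposite side —
    inversions flip neighborhoods without breaking synteny).  Divergent
    means no shared symbol at all.  When the only unmatched sides are cut
    short by scaffold ends the comparison is unresolvable rather than
    negative.  Symmetric in its arguments.
    """
    if ctx_a.k != ctx_b.k:
        raise ValueError("contexts must be built with the same k")
    checks = []  # (has_match, prevented_by_edge)
    for ctx, other in ((ctx_a, ctx_b), (ctx_b, ctx_a)):
        pool = other.all_symbols()
        for side in ("upstream", "downstream"):
            symbols = ctx.side_symbols(side)
            has_match = bool(symbols & pool)
            prevented = not has_match and (
                ctx.scaffoldEdges.get(side, False) or not symbols
            )
            checks.append((has_match, prevented))
    if all(m for m, _ in checks):
        return "direct"
    if any(p for _, p in checks):
        return "unresolvable"
    if not any(m for m, _ in checks):
        return "divergent"
    return "divergent"  # partial sharing without edge interference


def link_via_phylogeny(
    gene: str,
    contexts_by_species: dict[str, SyntenyContext],
    back_hit_ok_by_species: dict[str, bool],
    query_species: str,
    target_species: str,
    tree: dendropy.Tree | None = None,
) -> SyntenyLink:
    """Link query and target syntenies through intermediate species.

    Breadth-first search for the shortest chain query -> ... -> target in
    which every consecutive species pair has directly conserved synteny and
    every *intermediate* species also aligns preferentially back to the
    correct query locus.  A direct query-target edge yields verdict
    ``direct`` regardless of intermediates; a longer chain yields
    ``phylo-linked``; no chain yields ``unresolved``.
    """
    if query_species not in contexts_by_species or target_species not in contexts_by_species:
        return SyntenyLink([], "unresolved")

    if (
        synteny_conserved(
            contexts_by_species[query_species], contexts_by_species[target_species]
        )
        == "direct"
    ):
        return SyntenyLink([query_species, target_species], "direct")

    # Deterministic expansion order: tree leaf order when available,
    # else sorted species names.
    if tree is not None:
        order = [lf.taxon.label for lf in tree.leaf_node_iter()]
        species = [s for s in order if s in contexts_by_species]
        species += sorted(set(contexts_by_species) - set(species))
    else:
        species = sorted(contexts_by_species)

    usable = [
        s
        for s in species
        if s in (query_species, target_species) or back_hit_ok_by_species.get(s, False)
    ]
    queue: deque[list[str]] = deque([[query_species]])
    seen = {query_species}
    while queue:
        chain = queue.popleft()
        here = contexts_by_species[chain[-1]]
        for nxt in usable:
            if nxt in seen:
                continue
            if synteny_conserved(here, contexts_by_species[nxt]) != "direct":
                continue
            new_chain = chain + [nxt]
            if nxt == target_species:
                return SyntenyLink(new_chain, "phylo-linked")
            seen.add(nxt)
            queue.append(new_chain)
    return SyntenyLink([], "unresolved")


# ---------------------------------------------------------------------------
# Tandem cluster resolution
# ---------------------------------------------------------------------------


@dataclass
class ClusterAssignment:
    mapping: dict[str, str]  # query gene symbol -> target locus name
    reversed_cluster: bool
    unassigned: list[str]


def _best_order_preserving(
    query_genes: list[str], target_names: list[str], pair_score
) -> tuple[float, dict[str, str]]:
    # Needleman-Wunsch-style DP: order-preserving injective assignment
    # maximizing total pair score; gaps are free (unassigned genes).
    nq, nt = len(query_genes), len(target_names)
    score = [[0.0] * (nt + 1) for _ in range(nq + 1)]
    for i in range(1, nq + 1):
        for j in range(1, nt + 1):
            pair = score[i - 1][j - 1] + pair_score(query_genes[i - 1], target_names[j - 1])
            score[i][j] = max(pair, score[i - 1][j], score[i][j - 1])
    # traceback (prefer matches, then skipping target, then query)
    mapping: dict[str, str] = {}
    i, j = nq, nt
    while i > 0 and j > 0:
        pair = score[i - 1][j - 1] + pair_score(query_genes[i - 1], target_names[j - 1])
        if score[i][j] == pair and pair_score(query_genes[i - 1], target_names[j - 1]) > 0:
            mapping[query_genes[i - 1]] = target_names[j - 1]
            i, j = i - 1, j - 1
        elif score[i][j] == score[i][j - 1]:
            j -= 1
        else:
            i -= 1
    return score[nq][nt], mapping


def resolve_cluster(
    cluster_genes: list[str],
    target_loci: list[str],
    pair_score=None,
) -> ClusterAssignment:
    """One-to-one assignment of tandem cluster members across species.

    Maximizes the summed pair score of an order-preserving assignment,
    trying the target cluster both forward and whole-cluster reversed (a
    common rearrangement); ties prefer the forward orientation.  The
    default score is 1 for a symbol match and 0.25 for any positional
    pairing, so labelled loci align by name and unlabelled ones by
    position.  Member-count mismatches leave the surplus genes unassigned.
    """
    if pair_score is None:

        def pair_score(gene: str, locus: str) -> float:
            return 1.0 if gene == locus else 0.25

    fwd_total, fwd_map = _best_order_preserving(cluster_genes, target_loci, pair_score)
    rev_total, rev_map = _best_order_preserving(
        cluster_genes, list(reversed(target_loci)), pair_score
    )
    if rev_total > fwd_total:
        mapping, reversed_cluster = rev_map, True
    else:
        mapping, reversed_cluster = fwd_map, False
    unassigned = [g for g in cluster_genes if g not in mapping]
    return ClusterAssignment(mapping, reversed_cluster, unassigned)
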