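"""Flanking contexts, conservation verdicts, phylogenetic linking, clusters."""

import itertools

import pytest

from genecomplement.alignment_io import GeneAnnotation, parse_tree
from genecomplement.synteny import (
    SyntenyContext,
    flanking_context,
    link_via_phylogeny,
    resolve_cluster,
    synteny_conserved,
)


def annotation(genes, species="sp", seqid="s1"):
    """[(symbol, strand), ...] -> evenly spaced annotations on one scaffold."""
    out = []
    for i, (g, strand) in enumerate(genes):
        out.append(
            GeneAnnotation(species, g, seqid, i * 10_000, i * 10_000 + 1000, strand)
        )
    return out


def ctx(gene, upstream, downstream, k=2, up_edge=False, down_edge=False):
    return SyntenyContext(
        gene, upstream, downstream, k,
        {"upstream": up_edge, "downstream": down_edge},
    )


class TestFlankingContext:
    def test_two_neighbors_each_side_in_distance_order(self):
        ann = annotation([("A", "+"), ("B", "-"), ("G", "+"), ("C", "+"), ("D", "+")])
        c = flanking_context(ann, "G", k=2)
        assert c.upstream == [("B", "-"), ("A", "+")]
        assert c.downstream == [("C", "+"), ("D", "+")]
        assert not c.scaffoldEdges["upstream"] and not c.scaffoldEdges["downstream"]

    def test_scaffold_edge_flagged(self):
        ann = annotation([("G", "+"), ("C", "+"), ("D", "+")])
        c = flanking_context(ann, "G", k=2)
        assert c.upstream == [] and c.scaffoldEdges["upstream"]
        assert c.downstream == [("C", "+"), ("D", "+")]

    def test_absent_gene_raises(self):
        with pytest.raises(KeyError):
            flanking_context(annotation([("A", "+")]), "Z")

    def test_matches_brute_force_scan(self, rng):
        genes = [(f"g{i}", "+" if rng.random() < 0.5 else "-") for i in range(50)]
        order = list(rng.permutation(range(50)))
        ann = annotation([genes[i] for i in order])
        for focal_idx in rng.choice(50, size=10, replace=False):
            focal = genes[order[int(focal_idx)]][0]
            c = flanking_context(ann, focal, k=3)
            pos = [a.gene for a in sorted(ann, key=lambda a: a.start)]
            i = pos.index(focal)
            assert [s for s, _ in c.upstream] == pos[max(0, i - 3) : i][::-1]
            assert [s for s, _ in c.downstream] == pos[i + 1 : i + 4]


class TestSyntenyConserved:
    def test_identical_contexts_direct(self):
        a = ctx("G", [("B", "-"), ("A", "+")], [("C", "+"), ("D", "+")])
        assert synteny_conserved(a, a) == "direct"

    def test_shared_neighbors_despite_orientation_changes(self):
        # the same three flanking genes around the focal locus, rearranged
        # and reoriented across the two species, still count as conserved
        a = ctx("SCN1B", [("BCL3", "+"), ("PSMC4", "-")], [("RBM42", "+"), ("X1", "+")])
        b = ctx("SCN1B", [("RBM42", "-"), ("X2", "+")], [("BCL3", "-"), ("PSMC4", "+")])
        assert synteny_conserved(a, b) == "direct"

    def test_disjoint_contexts_divergent(self):
        a = ctx("G", [("A", "+")], [("B", "+")])
        b = ctx("G", [("Y", "+")], [("Z", "+")])
        assert synteny_conserved(a, b) == "divergent"

    def test_scaffold_edge_makes_unresolvable(self):
        a = ctx("G", [], [("B", "+")], up_edge=True)
        b = ctx("G", [("Y", "+")], [("B", "+")])
        assert synteny_conserved(a, b) == "unresolvable"

    def test_symmetry(self, rng):
        pool = [f"n{i}" for i in range(8)]
        for _ in range(200):
            def rand_ctx():
                pick = lambda: [(pool[int(rng.integers(0, 8))], "+") for _ in range(int(rng.integers(0, 3)))]
                up, down = pick(), pick()
                return ctx(
                    "G", up, down,
                    up_edge=len(up) < 2 and rng.random() < 0.5,
                    down_edge=len(down) < 2 and rng.random() < 0.5,
                )
            a, b = rand_ctx(), rand_ctx()
            assert synteny_conserved(a, b) == synteny_conserved(b, a)

    def test_inversion_preserves_verdict_for_undisturbed_neighborhoods(self):
        """Genes whose k-neighborhood lies wholly inside or outside an
        inverted segment stay directly conserved; a gene moved to a random
        locus becomes divergent."""
        genes = [(f"g{i}", "+") for i in range(20)]
        ann_a = annotation(genes, species="A")
        # invert genes 8..13 in species B
        inverted = genes[:8] + [(g, "-") for g, _ in reversed(genes[8:14])] + genes[14:]
        ann_b = annotation(inverted, species="B")
        for focal in ["g2", "g10", "g11", "g17"]:  # deep outside / deep inside
            va = flanking_context(ann_a, focal, k=2)
            vb = flanking_context(ann_b, focal, k=2)
            assert synteny_conserved(va, vb) == "direct", focal
        # translocate g5 into a distant interior neighborhood in species C
        without = [g for g in inverted if g[0] != "g5"]
        moved = without[:16] + [("g5", "+")] + without[16:]
        ann_c = annotation(moved, species="C")
        assert (
            synteny_conserved(
                flanking_context(ann_a, "g5", k=2), flanking_context(ann_c, "g5", k=2)
            )
            == "divergent"
        )

    def test_mismatched_k_rejected(self):
        a = ctx("G", [], [], k=2, up_edge=True, down_edge=True)
        b = ctx("G", [], [], k=3, up_edge=True, down_edge=True)
        with pytest.raises(ValueError):
            synteny_conserved(a, b)


class TestLinkViaPhylogeny:
    tree = parse_tree("(query,(mid,target));")

    def test_direct_conservation_short_circuits(self):
        c = ctx("G", [("A", "+")], [("B", "+")])
        link = link_via_phylogeny(
            "G", {"query": c, "mid": c, "target": c}, {"mid": False},
            "query", "target", self.tree,
        )
        assert link.verdict == "direct"
        assert link.speciesChain == ["query", "target"]

    def _chain_contexts(self):
        # query shares neighbors with mid; mid shares different ones with target
        q = ctx("G", [("A", "+")], [("B", "+")])
        m = ctx("G", [("A", "+"), ("Y", "+")], [("B", "+"), ("Z", "+")])
        t = ctx("G", [("Y", "+")], [("Z", "+")])
        return {"query": q, "mid": m, "target": t}

    def test_one_intermediate_gives_phylo_linked(self):
        link = link_via_phylogeny(
            "G", self._chain_contexts(), {"mid": True}, "query", "target", self.tree
        )
        assert link.verdict == "phylo-linked"
        assert link.speciesChain == ["query", "mid", "target"]

    def test_intermediate_failing_back_alignment_unlinks(self):
        link = link_via_phylogeny(
            "G", self._chain_contexts(), {"mid": False}, "query", "target", self.tree
        )
        assert link.verdict == "unresolved" and link.speciesChain == []


class TestResolveCluster:
    def test_conserved_order_identity_assignment(self):
        genes = ["SCN1A", "SCN2A", "SCN3A", "SCN9A"]
        res = resolve_cluster(genes, genes)
        assert res.mapping == dict(zip(genes, genes))
        assert not res.reversed_cluster and res.unassigned == []

    def test_reversed_target_cluster_flagged(self):
        genes = ["SCN1A", "SCN2A", "SCN3A", "SCN9A"]
        res = resolve_cluster(genes, list(reversed(genes)))
        assert res.mapping == dict(zip(genes, genes))
        assert res.reversed_cluster

    def test_member_count_mismatch_leaves_unassigned(self):
        res = resolve_cluster(["a", "b", "c", "d"], ["L1", "L2", "L3"])
        assert len(res.mapping) == 3 and len(res.unassigned) == 1

    def test_matches_exhaustive_search_on_small_clusters(self, rng):
        """DP assignment equals brute force over all order-preserving
        injective assignments (forward or whole-cluster reversed)."""

        def brute(query, target, score):
            best = (-1.0, {})
            for orient, tgt in (("fwd", target), ("rev", list(reversed(target)))):
                # order-preserving assignments = choose equal-size subsequences
                for size in range(min(len(query), len(tgt)), -1, -1):
                    for qi in itertools.combinations(range(len(query)), size):
                        for ti in itertools.combinations(range(len(tgt)), size):
                            total = sum(
                                score(query[a], tgt[b]) for a, b in zip(qi, ti)
                            )
                            if total > best[0]:
                                best = (total, dict((query[a], tgt[b]) for a, b in zip(qi, ti)))
            return best[0]

        pool = ["u", "v", "w", "x", "y"]
        score = lambda g, l: 1.0 if g == l else 0.25
        for _ in range(20):
            nq = int(rng.integers(2, 6))
            nt = int(rng.integers(2, 6))
            query = list(rng.choice(pool, size=nq, replace=False))
            target = list(rng.choice(pool, size=nt, replace=False))
            res = resolve_cluster(query, target)
            got = sum(score(g, l) for g, l in res.mapping.items())
            assert got == pytest.approx(brute(query, target, score))
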