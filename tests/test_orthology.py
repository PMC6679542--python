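"""Hit scoring, significance, reciprocality, family checks, classification."""

import dataclasses

import pytest

from genecomplement.alignment_io import GenomicInterval
from genecomplement.orthology import (
    ContradictoryEvidenceError,
    GeneEvidence,
    HitScore,
    Marker,
    Status,
    blat_score,
    classify_gene,
    reciprocal_top_hit,
    significant_hits,
    verify_secondary_hits,
)
from conftest import random_alignment_record


def make_hit(rng, score=None, tname=None, tstart=None):
    rec = random_alignment_record(rng)
    if score is not None:
        # rebuild with exact score: matches=score, no penalties, single block
        rec = dataclasses.replace(
            rec,
            matches=score,
            misMatches=0,
            repMatches=0,
            nCount=0,
            qNumInsert=0,
            tNumInsert=0,
            blockSizes=(score,),
            qStarts=(0,),
            tStarts=(tstart if tstart is not None else rec.tStarts[0],),
            tStart=tstart if tstart is not None else rec.tStarts[0],
            tEnd=(tstart if tstart is not None else rec.tStarts[0]) + score,
            qStart=0,
            qEnd=score,
            qSize=max(score, rec.qSize),
            tName=tname or rec.tName,
        )
    return HitScore.from_record(rec)


class TestBlatScore:
    @pytest.mark.parametrize(
        "matches,rep,mis,qins,tins,expected",
        [(60, 0, 5, 2, 1, 52), (100, 0, 0, 0, 0, 100), (30, 0, 30, 0, 0, 0)],
    )
    def test_hand_computed_scores(self, rng, matches, rep, mis, qins, tins, expected):
        rec = random_alignment_record(rng)
        total = matches + mis + rep
        rec = dataclasses.replace(
            rec, matches=matches, misMatches=mis, repMatches=rep, nCount=0,
            qNumInsert=qins, tNumInsert=tins,
            blockSizes=(total,), qStarts=(0,), tStarts=(0,),
            qSize=max(total, rec.qSize),
        )
        assert blat_score(rec) == expected


class TestSignificantHits:
    def test_strictly_above_fifty(self, rng):
        hits = [make_hit(rng, s) for s in (52, 50, 49)]
        assert [h.score for h in significant_hits(hits)] == [52]

    def test_empty(self):
        assert significant_hits([]) == []

    def test_matches_brute_force_on_random_hits(self, rng):
        for _ in range(20):
            hits = [HitScore.from_record(random_alignment_record(rng)) for _ in range(50)]
            expected = sorted(
                (h for h in hits if h.score > 50),
                key=lambda h: (-h.score, h.record.tName, h.record.tStart),
            )
            assert significant_hits(hits) == expected


class TestReciprocalTopHit:
    def test_back_hit_at_own_locus(self, rng):
        locus = GenomicInterval("chrQ", 1000, 2000)
        back = [make_hit(rng, 200, "chrQ", 1500)]
        assert reciprocal_top_hit("g", [], back, locus).ok

    def test_paralog_top_hit_fails(self, rng):
        locus = GenomicInterval("chrQ", 1000, 2000)
        back = [
            make_hit(rng, 300, "chrQ", 50_000),  # paralog locus scores higher
            make_hit(rng, 200, "chrQ", 1500),
        ]
        res = reciprocal_top_hit("g", [], back, locus)
        assert not res.ok and res.reason == "top-hit-elsewhere"

    def test_no_back_hits(self):
        res = reciprocal_top_hit("g", [], [], GenomicInterval("chrQ", 0, 10))
        assert not res.ok and res.reason == "no-back-hit"

    def test_exact_tie_is_refused(self, rng):
        locus = GenomicInterval("chrQ", 1000, 2000)
        back = [make_hit(rng, 200, "chrQ", 1500), make_hit(rng, 200, "chrQ", 90_000)]
        res = reciprocal_top_hit("g", [], back, locus)
        assert not res.ok and res.reason == "tied-top-hit"


class TestVerifySecondaryHits:
    def test_secondary_hits_at_paralog_loci(self, rng):
        hits = [
            make_hit(rng, 300, "chr1", 100),
            make_hit(rng, 200, "chr1", 5000),
            make_hit(rng, 150, "chr2", 800),
        ]
        family = {GenomicInterval("chr1", 4900, 6000), GenomicInterval("chr2", 700, 900)}
        assert verify_secondary_hits(hits, family)

    def test_non_family_secondary_hit_flags_novel_paralog(self, rng):
        hits = [make_hit(rng, 300, "chr1", 100), make_hit(rng, 200, "chr3", 5000)]
        family = {GenomicInterval("chr1", 4900, 6000)}
        assert not verify_secondary_hits(hits, family)

    def test_chrUn_hits_are_excluded_as_allelic_variants(self, rng):
        hits = [make_hit(rng, 300, "chr1", 100), make_hit(rng, 200, "chrUn", 5000)]
        assert verify_secondary_hits(hits, set())
        hits = [make_hit(rng, 300, "chr1", 100), make_hit(rng, 200, "chr13_random", 5000)]
        assert verify_secondary_hits(hits, set())


def evidence(**kw) -> GeneEvidence:
    base = dict(
        gene="G",
        topHitLocus=GenomicInterval("chr3", 100, 5000),
        topHitScore=400,
        reciprocalOk=True,
        syntenyVerdict="direct",
        annotatedModels=["m1"],
    )
    base.update(kw)
    return GeneEvidence(**base)


class TestClassifyGene:
    def test_annotated_reciprocal_direct_is_clean_present(self):
        status = classify_gene(evidence(), completeness_flag=False)
        assert status.status is Status.PRESENT_ANNOTATED
        assert status.markers == frozenset()

    def test_longread_only_locus_with_phylo_linked_synteny(self):
        status = classify_gene(
            evidence(
                annotatedModels=[], hasPacbioLocus=True, syntenyVerdict="phylo-linked",
                scaffoldGapless=True,
            )
        )
        assert status.status is Status.PRESENT_PACBIO_ONLY
        assert status.markers == frozenset({Marker.DOLLAR})

    def test_tiny_aligned_fraction_on_gapless_scaffold_is_truncated(self):
        status = classify_gene(
            evidence(
                annotatedModels=[], hasPacbioLocus=True, scaffoldGapless=True,
                alignedFractionOfOrtholog=0.01,
            )
        )
        assert status.status is Status.TRUNCATED
        assert Marker.NABLA in status.markers

    def test_novel_models_add_caret(self):
        status = classify_gene(evidence(annotatedModels=[], novelModels=["m1", "m2"]))
        assert status.status is Status.PRESENT_NOVEL_MODEL
        assert Marker.CARET in status.markers

    def test_unresolved_synteny_adds_hash_diamond_from_found_via(self):
        status = classify_gene(
            evidence(syntenyVerdict="unresolved", foundVia="other-species-query")
        )
        assert status.markers == frozenset({Marker.HASH, Marker.DIAMOND})

    def test_missing_requires_adjacent_gapless_flanks(self):
        status = classify_gene(
            GeneEvidence(gene="G", topHitLocus=None, flanksAdjacentGapless=True)
        )
        assert status.status is Status.MISSING and status.markers == frozenset()
        status = classify_gene(
            GeneEvidence(gene="G", topHitLocus=None, flanksAdjacentGapless=False)
        )
        assert status.status is Status.UNRESOLVED

    def test_contradictory_evidence_raises(self):
        with pytest.raises(ContradictoryEvidenceError):
            classify_gene(evidence(flanksAdjacentGapless=True))

    def test_failed_reciprocal_or_divergent_synteny_is_unresolved(self):
        assert classify_gene(evidence(reciprocalOk=False)).status is Status.UNRESOLVED
        assert (
            classify_gene(evidence(syntenyVerdict="divergent")).status
            is Status.UNRESOLVED
        )

    def test_classification_is_a_pure_function(self, rng):
        verdicts = ["direct", "phylo-linked", "unresolved", "divergent"]
        vias = ["human-query", "other-species-query", "pacbio-only"]
        for _ in range(300):
            ev = GeneEvidence(
                gene="G",
                topHitLocus=GenomicInterval("c", 0, 100) if rng.random() < 0.8 else None,
                topHitScore=int(rng.integers(51, 1000)),
                reciprocalOk=bool(rng.random() < 0.8),
                syntenyVerdict=verdicts[int(rng.integers(0, 4))],
                foundVia=vias[int(rng.integers(0, 3))],
                scaffoldGapless=bool(rng.random() < 0.5),
                alignedFractionOfOrtholog=float(rng.random()),
                annotatedModels=["m"] * int(rng.integers(0, 3)),
                novelModels=["n"] * int(rng.integers(0, 3)),
                hasAssemblyLocus=bool(rng.random() < 0.5),
                hasPacbioLocus=bool(rng.random() < 0.5),
                flanksAdjacentGapless=None,
            )
            flag = bool(rng.random() < 0.3)
            assert classify_gene(ev, flag) == classify_gene(ev, flag)


class TestFixtureReproduction:
    """The classifier reproduces the packaged 94-row complement exactly."""

    def test_every_row_status_and_markers(self):
        from genecomplement.synthetic_data import load_paper_fixture

        rows = load_paper_fixture("table1")
        assert len(rows) == 94
        for row in rows:
            status = classify_gene(row.evidence, row.completeness_flag)
            assert status.markers == row.markers, row.gene
            assert status.status in (
                Status.PRESENT_ANNOTATED,
                Status.PRESENT_NOVEL_MODEL,
                Status.PRESENT_NO_MODEL,
                Status.PRESENT_PACBIO_ONLY,
                Status.TRUNCATED,
            ), row.gene
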