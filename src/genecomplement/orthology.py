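"""Hit significance, reciprocal top-hit, and family verification of
secondary alignments, routed to a per-gene evidence-tier classification.

The orthology call for a gene proceeds in five steps: score all alignments
of the query-species model against the target genome; keep the significant
hits (score strictly above 50); verify that the gene model at the top hit
aligns back preferentially to the querying locus; verify that secondary
alignments fall on known loci of the same gene family (otherwise they flag
candidate novel paralogs); and combine this with the synteny verdict and
model inventory into a final status with evidence markers.

Marker glossary (matching the conventional report symbols):

===========  ==============================================================
caret  (^)   locus model(s) annotated only as "novel gene" by the annotator
dollar ($)   synteny traced indirectly through phylogenetic relationships
hash   (#)   synteny could not be linked through phylogenetic relationships
diamond (◆)  a non-query-species ortholog was needed to find the locus
nabla  (▽)   highly partial or truncated remnant
star   (*)   model shorter than 90% of its post-recovery length
===========  ==============================================================
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum

from .alignment_io import AlignmentRecord, GenomicInterval

#: Significance cut-off for alignment scores; strictly-greater comparison.
DEFAULT_SCORE_MIN = 50

#: Aligned fraction of the ortholog below which a gap-free locus is called
#: a truncation.
DEFAULT_TRUNCATION_FRACTION = 0.25

#: Unplaced / unordered assembly fragments: hits there are treated as
#: allelic variants, never as paralogs, and never veto orthology.
UNPLACED_PREFIXES = ("chrUn",)
UNPLACED_SUFFIXES = ("_random",)


class Marker(str, Enum):
    CARET = "caret"
    DOLLAR = "dollar"
    HASH = "hash"
    DIAMOND = "diamond"
    NABLA = "nabla"
    STAR = "star"


class Status(str, Enum):
    PRESENT_ANNOTATED = "PRESENT_ANNOTATED"
    PRESENT_NOVEL_MODEL = "PRESENT_NOVEL_MODEL"
    PRESENT_NO_MODEL = "PRESENT_NO_MODEL"
    PRESENT_PACBIO_ONLY = "PRESENT_PACBIO_ONLY"
    TRUNCATED = "TRUNCATED"
    MISSING = "MISSING"
    UNRESOLVED = "UNRESOLVED"


#: Statuses that count toward the species' gene complement.
PRESENT_TIER = frozenset(
    {
        Status.PRESENT_ANNOTATED,
        Status.PRESENT_NOVEL_MODEL,
        Status.PRESENT_NO_MODEL,
        Status.PRESENT_PACBIO_ONLY,
        Status.TRUNCATED,
    }
)


class ContradictoryEvidenceError(ValueError):
    """Evidence asserts both a located hit and a verified empty locus."""


def is_unplaced(seqid: str) -> bool:
    """True for unplaced/unordered assembly fragments (chrUn, chr*_random)."""
    return seqid.startswith(UNPLACED_PREFIXES) or seqid.endswith(UNPLACED_SUFFIXES)


# ---------------------------------------------------------------------------
# Scoring and hit filtering
# ---------------------------------------------------------------------------


def blat_score(record: AlignmentRecord) -> int:
    """Web-BLAT alignment score.

    score = matches + repMatches - misMatches - qNumInsert - tNumInsert
    """
    return (
        record.matches
        + record.repMatches
        - record.misMatches
        - record.qNumInsert
        - record.tNumInsert
    )


@dataclass(frozen=True)
class HitScore:
    """An alignment record with its derived score."""

    record: AlignmentRecord
    score: int

    @classmethod
    def from_record(cls, record: AlignmentRecord) -> "HitScore":
        return cls(record=record, score=blat_score(record))

    def target_locus(self) -> GenomicInterval:
        return GenomicInterval(
            self.record.tName,
            self.record.tStart,
            self.record.tEnd,
            name=self.record.qName,
        )


def score_hits(records) -> list[HitScore]:
    return [HitScore.from_record(r) for r in records]


def significant_hits(
    hits: list[HitScore], score_min: int = DEFAULT_SCORE_MIN
) -> list[HitScore]:
    """Hits scoring strictly above ``score_min``, best first.

    Ties are broken by (tName, tStart) lexicographically so the ordering is
    deterministic.
    """
    kept = [h for h in hits if h.score > score_min]
    kept.sort(key=lambda h: (-h.score, h.record.tName, h.record.tStart))
    return kept


# ---------------------------------------------------------------------------
# Reciprocal top hit
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ReciprocalResult:
    ok: bool
    reason: str | None = None

    def __bool__(self) -> bool:
        return self.ok


def reciprocal_top_hit(
    gene: str,
    forward_hits: list[HitScore],
    back_hits: list[HitScore],
    expected_locus: GenomicInterval,
    score_min: int = DEFAULT_SCORE_MIN,
) -> ReciprocalResult:
    """Does the target-species model align preferentially back to the
    expected query locus?

    True iff the top significant back-alignment overlaps ``expected_locus``
    by at least one base.  An exact score tie between the top two back-hits
    is refused ("preferentially" is not established) so classification can
    fall to UNRESOLVED rather than guess.
    """
    back = significant_hits(back_hits, score_min)
    if not back:
        return ReciprocalResult(False, "no-back-hit")
    if len(back) > 1 and back[0].score == back[1].score:
        return ReciprocalResult(False, "tied-top-hit")
    if back[0].target_locus().overlaps(expected_locus):
        return ReciprocalResult(True)
    return ReciprocalResult(False, "top-hit-elsewhere")


def verify_secondary_hits(
    hits: list[HitScore],
    family_loci: set[GenomicInterval] | list[GenomicInterval],
    score_min: int = DEFAULT_SCORE_MIN,
) -> bool:
    """Do all significant non-top hits fall on known family-member loci?

    Hits on unplaced fragments (chrUn, chr*_random) are excluded before the
    check — they represent allelic variants, not paralogs.  A significant
    secondary hit outside every family locus means a candidate novel
    paralog and returns False (flag for review).
    """
    sig = significant_hits(hits, score_min)
    secondary = [h for h in sig[1:] if not is_unplaced(h.record.tName)]
    for hit in secondary:
        locus = hit.target_locus()
        if not any(locus.overlaps(fl) for fl in family_loci):
            return False
    return True


# ---------------------------------------------------------------------------
# Evidence and classification
# ---------------------------------------------------------------------------


@dataclass
class GeneEvidence:
    """All per-gene observations feeding the final classification.

    ``annotatedModels`` / ``novelModels`` split the locus model inventory
    by annotation quality; ``hasAssemblyLocus`` marks a verified locus with
    coordinates in the primary assembly but no model; ``hasPacbioLocus``
    marks a locus found (only, if the others are empty) in the gap-free
    long-read assembly.  ``flanksAdjacentGapless`` is the missing-locus
    evidence: both syntenic flanks adjacent on one gap-free scaffold with
    no significant intergenic hit.
    """

    gene: str
    querySpecies: str = "query"
    targetSpecies: str = "target"
    topHitLocus: GenomicInterval | None = None
    topHitScore: int = 0
    reciprocalOk: bool = False
    syntenyVerdict: str = "unresolved"  # direct | phylo-linked | unresolved | divergent
    secondaryHitsAreFamily: bool = True
    foundVia: str = "human-query"  # human-query | other-species-query | pacbio-only
    scaffoldGapless: bool = False
    alignedFractionOfOrtholog: float = 1.0
    annotatedModels: list[str] = field(default_factory=list)
    novelModels: list[str] = field(default_factory=list)
    hasAssemblyLocus: bool = False
    hasPacbioLocus: bool = False
    flanksAdjacentGapless: bool | None = None

    def __post_init__(self) -> None:
        if self.topHitLocus is not None and self.topHitScore <= DEFAULT_SCORE_MIN:
            raise ValueError(
                f"{self.gene}: topHitScore must exceed {DEFAULT_SCORE_MIN} "
                "when a top-hit locus is recorded"
            )
        if not 0.0 <= self.alignedFractionOfOrtholog <= 1.0:
            raise ValueError(f"{self.gene}: alignedFractionOfOrtholog outside [0,1]")


@dataclass(frozen=True)
class GeneStatus:
    gene: str
    status: Status
    markers: frozenset[Marker]

    def __post_init__(self) -> None:
        if self.status is Status.TRUNCATED and Marker.NABLA not in self.markers:
            raise ValueError(f"{self.gene}: TRUNCATED requires the nabla marker")
        if self.status is Status.MISSING and self.markers:
            raise ValueError(f"{self.gene}: MISSING carries no markers")


def classify_gene(
    evidence: GeneEvidence,
    completeness_flag: bool = False,
    truncation_fraction: float = DEFAULT_TRUNCATION_FRACTION,
) -> GeneStatus:
    """Route a gene's evidence to its final status and marker set.

    Deterministic routing:

    * no locus anywhere + flanks adjacent on a gap-free scaffold -> MISSING;
      no locus and weaker flank evidence -> UNRESOLVED;
    * aligned fraction below the truncation threshold on a gap-free
      scaffold -> TRUNCATED (nabla);
    * reciprocal alignment OK with usable synteny -> PRESENT tier by model
      inventory (annotated models > novel models > assembly coordinates
      only > long-read locus only);
    * anything else -> UNRESOLVED.

    Markers accumulate independently of the present-tier choice: caret for
    novel models, dollar/hash from the synteny verdict, diamond when a
    non-query-species ortholog found the locus, star when the completeness
    flag is set.
    """
    ev = evidence
    if ev.topHitLocus is None:
        if ev.flanksAdjacentGapless:
            return GeneStatus(ev.gene, Status.MISSING, frozenset())
        return GeneStatus(ev.gene, Status.UNRESOLVED, frozenset())

    if ev.flanksAdjacentGapless:
        raise ContradictoryEvidenceError(
            f"{ev.gene}: a top-hit locus and a verified empty locus cannot coexist"
        )

    markers: set[Marker] = set()
    if ev.novelModels:
        markers.add(Marker.CARET)
    if ev.syntenyVerdict == "phylo-linked":
        markers.add(Marker.DOLLAR)
    elif ev.syntenyVerdict == "unresolved":
        markers.add(Marker.HASH)
    if ev.foundVia == "other-species-query":
        markers.add(Marker.DIAMOND)
    if completeness_flag:
        markers.add(Marker.STAR)

    truncated = (
        ev.alignedFractionOfOrtholog < truncation_fraction and ev.scaffoldGapless
    )
    if truncated:
        markers.add(Marker.NABLA)
        return GeneStatus(ev.gene, Status.TRUNCATED, frozenset(markers))

    if not ev.reciprocalOk or ev.syntenyVerdict == "divergent":
        return GeneStatus(ev.gene, Status.UNRESOLVED, frozenset())

    if ev.annotatedModels and not ev.novelModels:
        status = Status.PRESENT_ANNOTATED
    elif ev.novelModels:
        status = Status.PRESENT_NOVEL_MODEL
    elif ev.hasAssemblyLocus:
        status = Status.PRESENT_NO_MODEL
    elif ev.hasPacbioLocus:
        status = Status.PRESENT_PACBIO_ONLY
    else:
        return GeneStatus(ev.gene, Status.UNRESOLVED, frozenset())

    return GeneStatus(ev.gene, status, frozenset(markers))
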