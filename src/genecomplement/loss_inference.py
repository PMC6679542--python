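"""Gene-loss and truncation calls, and Dollo placement of losses on a
species tree.

A locus is called *missing* only on positive evidence of absence: the two
syntenic flanking genes sit adjacent on a single gap-free scaffold and no
significant alignment is found in the intergenic interval.  Gaps in the
intergenic region, or flanks stranded at the ends of different scaffolds,
degrade the call to tentative or undetermined — an incomplete assembly can
hide a gene, so unknown is never treated as absent.

Loss placement follows a Dollo model (a gene is gained once and may be
lost on any branch, possibly independently in several clades): for each
maximal clade whose known states are all absent, the loss is placed on
that clade's stem branch.  Leaves with unknown state widen the candidate
set to every branch compatible with the observations; ambiguity can widen
the set but never drop the true branch.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import dendropy

from .orthology import DEFAULT_TRUNCATION_FRACTION, HitScore, significant_hits


@dataclass
class PhyloProfile:
    """Tri-state presence map over the leaves of a species tree.

    ``states`` maps leaf label -> ``present``/``absent``/``unknown``;
    ``evidenceQuality`` maps leaf label -> ``gapless``/``gappy``/
    ``fragmented`` describing the assembly behind an absence call.
    """

    gene: str
    states: dict[str, str]
    evidenceQuality: dict[str, str] = field(default_factory=dict)

    def leaves_in(self, state: str) -> set[str]:
        return {sp for sp, st in self.states.items() if st == state}


@dataclass
class LossPlacement:
    """Candidate loss branches (each a leaf set) for one gene."""

    gene: str
    lossBranches: set[frozenset[str]]
    confidence: str  # high | tentative

    def maximal_branches(self) -> list[frozenset[str]]:
        """Branches not contained in any other candidate branch."""
        return [
            b
            for b in self.lossBranches
            if not any(b < other for other in self.lossBranches)
        ]


# ---------------------------------------------------------------------------
# Missing-locus and truncation calls
# ---------------------------------------------------------------------------


@dataclass
class FlankPlacement:
    """Where the two syntenic flanking genes landed in the target assembly."""

    both_found: bool = True
    same_scaffold: bool = True
    adjacent: bool = True
    at_different_scaffold_ends: bool = False


def call_missing_locus(
    flanks: FlankPlacement,
    intergenic_hits: list[HitScore],
    gapless: bool,
    score_min: int = 50,
) -> tuple[str, str]:
    """Call a locus missing from the evidence around it.

    Returns (verdict, reason) with verdict one of ``missing-high``,
    ``missing-tentative``, ``undetermined``.
    """
    if not flanks.both_found:
        return "undetermined", "flanks-not-found"
    if flanks.at_different_scaffold_ends or not flanks.same_scaffold:
        return "undetermined", "flanks-on-different-scaffolds"
    if not flanks.adjacent:
        return "undetermined", "flanks-not-adjacent"
    if significant_hits(intergenic_hits, score_min):
        return "undetermined", "significant-intergenic-hit"
    if gapless:
        return "missing-high", "adjacent-gapless-no-hit"
    return "missing-tentative", "adjacent-but-gapped"


def call_truncation(
    aligned_fraction: float,
    gapless: bool,
    expression_evidence: bool,
    threshold: float = DEFAULT_TRUNCATION_FRACTION,
) -> str:
    """Distinguish pseudogenization from a merely partial gene model.

    A severely truncated remnant (aligned fraction below ``threshold``) on
    a gap-free scaffold with no expression evidence is a likely pseudogene;
    the same fraction with gaps nearby or with expression support is only a
    partial model (missing sequence could hide in the gaps).
    """
    if not 0.0 <= aligned_fraction <= 1.0:
        raise ValueError("aligned_fraction outside [0,1]")
    if aligned_fraction >= threshold:
        return "intact"
    if gapless and not expression_evidence:
        return "truncated-pseudogene"
    return "partial-model"


# ---------------------------------------------------------------------------
# Dollo placement
# ---------------------------------------------------------------------------


def place_loss(profile: PhyloProfile, tree: dendropy.Tree) -> LossPlacement:
    """Place the loss(es) of a gene on the species tree under Dollo parsimony.

    For each connected set of absent leaves, the candidate branches are all
    branches whose subtended leaves are only absent-or-unknown and include
    every absent leaf of that set; the maximal such branch (the stem of the
    maximal all-absent clade) is always included, and unknown leaves widen
    the set downward toward the absences.  Multiple independent losses are
    reported as multiple maximal absent clades.  Requires at least one
    present leaf; with no absent leaf the placement is empty.

    Confidence is ``high`` iff every absent leaf carries gap-free
    (``gapless``) evidence, else ``tentative``.
    """
    leaf_labels = {lf.taxon.label for lf in tree.leaf_node_iter()}
    unknown_extra = set(profile.states) - leaf_labels
    if unknown_extra:
        raise ValueError(f"{profile.gene}: species not in tree: {sorted(unknown_extra)}")

    def state(label: str) -> str:
        return profile.states.get(label, "unknown")

    present = {sp for sp in leaf_labels if state(sp) == "present"}
    absent = {sp for sp in leaf_labels if state(sp) == "absent"}
    if not present:
        raise ValueError(f"{profile.gene}: no present leaf; gene not placeable")
    if not absent:
        return LossPlacement(profile.gene, set(), "high")

    # Candidate branches: leaves only absent-or-unknown, at least one absent.
    candidates: list[frozenset[str]] = []
    for node in tree.preorder_node_iter():
        leaves = frozenset(lf.taxon.label for lf in node.leaf_iter())
        if leaves & present:
            continue
        if leaves & absent:
            candidates.append(leaves)

    # Group candidates into independent loss events: each maximal candidate
    # branch heads one event; a branch belongs to the event whose maximal
    # branch contains it and must cover all that event's absences to be a
    # single-loss explanation of them.
    maximal = [
        b for b in candidates if not any(b < other for other in candidates)
    ]
    loss_branches: set[frozenset[str]] = set()
    for head in maximal:
        event_absent = head & absent
        for b in candidates:
            if b <= head and event_absent <= b:
                loss_branches.add(b)

    confidence = "high" if all(
        profile.evidenceQuality.get(sp, "gapless") == "gapless" for sp in absent
    ) else "tentative"
    return LossPlacement(profile.gene, loss_branches, confidence)


# ---------------------------------------------------------------------------
# Reporting: map placements to clade-category labels
# ---------------------------------------------------------------------------


def loss_category(
    placement: LossPlacement, branch_labels: dict[frozenset[str], str]
) -> str:
    """Human-readable category for a placement: the label(s) of its maximal
    candidate branch(es), e.g. a named internal clade or a single species."""
    names = sorted(
        branch_labels.get(b, "clade(" + ",".join(sorted(b)) + ")")
        for b in placement.maximal_branches()
    )
    return " + ".join(names) if names else "none"
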