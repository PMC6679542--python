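"""Gene-model completeness: cross-species length ratios and alignment-block
subtraction ("sequence recovery").

Two complementary metrics flag incomplete gene models in a
lower-coverage assembly:

* the *length ratio* — target-species model length (longest transcript
  variant; split models summed) divided by the orthologous reference-model
  length; and
* the *percent of post-recovery length* — aligning the better-annotated
  sister-species model to the target genome, subtracting the blocks already
  covered by the target species' own model alignment, and asking what
  fraction of the augmented model the original model represents:
  ``modelLength / (modelLength + basesRecovered)``.

A model below 90% of its post-recovery length is flagged; the recovered
blocks are exported as a BED track so they can be inspected in a genome
browser.  All block arithmetic happens in target-genome coordinates after
per-model merging; overlap means at least one shared base, and threshold
comparisons are strict.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from .alignment_io import AlignmentRecord, GenomicInterval, write_bed

#: Strict completeness-flag threshold on percent of post-recovery length.
DEFAULT_COMPLETENESS_FLAG = 0.90


@dataclass
class CompletenessRecord:
    gene: str
    zfModelLength: int
    humanModelLength: int | None = None
    recoveredBlocks: list[GenomicInterval] = field(default_factory=list)
    flag_threshold: float = DEFAULT_COMPLETENESS_FLAG

    @property
    def lengthRatio(self) -> float | None:
        if not self.humanModelLength:
            return None
        return self.zfModelLength / self.humanModelLength

    @property
    def basesRecovered(self) -> int:
        return sum(len(b) for b in self.recoveredBlocks)

    @property
    def percentPostRecovery(self) -> float:
        return self.zfModelLength / (self.zfModelLength + self.basesRecovered)

    @property
    def flagged(self) -> bool:
        return self.percentPostRecovery < self.flag_threshold


def length_ratio(zf_lengths: Sequence[int], human_length: int) -> float:
    """Summed split-model length over the orthologous reference length.

    May exceed 1 (the target model can be longer than the reference).
    """
    if human_length <= 0:
        raise ValueError("reference model length must be positive")
    if not zf_lengths:
        raise ValueError("need at least one model length")
    return sum(zf_lengths) / human_length


def merge_intervals(blocks: Iterable[GenomicInterval]) -> list[GenomicInterval]:
    """Merge possibly-overlapping blocks into maximal disjoint intervals,
    sorted by (seqid, start).  Abutting blocks are coalesced."""
    by_seq: dict[str, list[GenomicInterval]] = {}
    for b in blocks:
        by_seq.setdefault(b.seqid, []).append(b)
    out: list[GenomicInterval] = []
    for seqid in sorted(by_seq):
        ivs = sorted(by_seq[seqid], key=lambda b: (b.start, b.end))
        cur_start, cur_end = ivs[0].start, ivs[0].end
        for b in ivs[1:]:
            if b.start <= cur_end:
                cur_end = max(cur_end, b.end)
            else:
                out.append(GenomicInterval(seqid, cur_start, cur_end))
                cur_start, cur_end = b.start, b.end
        out.append(GenomicInterval(seqid, cur_start, cur_end))
    return out


def subtract_blocks(
    reference_blocks: Iterable[GenomicInterval],
    target_model_blocks: Iterable[GenomicInterval],
) -> list[GenomicInterval]:
    """Merged reference blocks minus merged target blocks.

    Returns the set difference as maximal disjoint intervals sorted by
    (seqid, start): the reference-model sequence aligned to the genome that
    the target species' own model does not cover.
    """
    ref = merge_intervals(reference_blocks)
    tgt = merge_intervals(target_model_blocks)
    tgt_by_seq: dict[str, list[GenomicInterval]] = {}
    for b in tgt:
        tgt_by_seq.setdefault(b.seqid, []).append(b)

    out: list[GenomicInterval] = []
    for r in ref:
        cuts = tgt_by_seq.get(r.seqid, [])
        pos = r.start
        for c in cuts:
            if c.end <= pos or c.start >= r.end:
                continue
            if c.start > pos:
                out.append(GenomicInterval(r.seqid, pos, c.start))
            pos = max(pos, c.end)
            if pos >= r.end:
                break
        if pos < r.end:
            out.append(GenomicInterval(r.seqid, pos, r.end))
    return out


def recovery_stats(
    gene: str,
    ref_alignment: AlignmentRecord | None,
    zf_alignment: AlignmentRecord | None,
    zf_model_length: int,
    human_model_length: int | None = None,
    flag_threshold: float = DEFAULT_COMPLETENESS_FLAG,
) -> CompletenessRecord | None:
    """Per-gene recovery record from the two top-scoring model alignments.

    ``ref_alignment`` is the better-annotated sister-species model aligned
    to the target genome; ``zf_alignment`` the target species' own model
    (may be None when the locus has no model alignment).  A gene without a
    reference alignment is excluded from the analysis (returns None).
    """
    if ref_alignment is None:
        return None
    ref_blocks = ref_alignment.target_blocks()
    zf_blocks = zf_alignment.target_blocks() if zf_alignment is not None else []
    recovered = subtract_blocks(ref_blocks, zf_blocks)
    named = [
        GenomicInterval(b.seqid, b.start, b.end, name=f"{gene}_rec{i + 1}")
        for i, b in enumerate(recovered)
    ]
    return CompletenessRecord(
        gene=gene,
        zfModelLength=zf_model_length,
        humanModelLength=human_model_length,
        recoveredBlocks=named,
        flag_threshold=flag_threshold,
    )


def export_recovery_track(
    records: Iterable[CompletenessRecord], path: str | Path
) -> None:
    """Write all recovered blocks of all genes as a sorted BED6 track."""
    blocks: list[GenomicInterval] = []
    for rec in records:
        blocks.extend(rec.recoveredBlocks)
    write_bed(blocks, path)
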