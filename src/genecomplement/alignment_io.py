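"""Readers and writers for the standard formats the pipeline touches.

Formats: PSL (21-column BLAT output), BED6, gene-annotation TSV or GFF3
gene lines, Newick species trees, and TSV profile/expression matrices.

All coordinates are 0-based half-open internally.  BED output equals the
internal coordinates unchanged; 1-based source formats (GFF3) are converted
at the reader boundary.  For minus-strand PSL records the per-block target
starts are already target-forward in the format itself, so all downstream
interval arithmetic is strand-free.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import dendropy

logger = logging.getLogger("genecomplement")

PSL_HEADER_PREFIXES = ("psLayout", "match", "-----", "\t")
PSL_N_COLUMNS = 21


class PslError(ValueError):
    """Malformed PSL input (wrong column count or inconsistent block lists)."""


class AnnotationError(ValueError):
    """Malformed or contradictory gene-annotation input."""


class TreeError(ValueError):
    """Species-tree input that is not a single rooted Newick tree."""


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class AlignmentRecord:
    """One PSL hit with per-block coordinates.

    Field names follow the PSL column names.  ``blockSizes``, ``qStarts``
    and ``tStarts`` are equal-length tuples; target blocks are
    non-overlapping and sorted in target-forward coordinates, and block
    sizes sum to matches + misMatches + repMatches + nCount.
    """

    qName: str
    tName: str
    strand: str
    qSize: int
    tSize: int
    matches: int
    misMatches: int
    repMatches: int
    nCount: int
    qNumInsert: int
    tNumInsert: int
    qBaseInsert: int
    tBaseInsert: int
    qStart: int
    qEnd: int
    tStart: int
    tEnd: int
    blockSizes: tuple[int, ...]
    qStarts: tuple[int, ...]
    tStarts: tuple[int, ...]

    def __post_init__(self) -> None:
        if not (len(self.blockSizes) == len(self.qStarts) == len(self.tStarts)):
            raise PslError(
                f"{self.qName}->{self.tName}: block list lengths differ "
                f"({len(self.blockSizes)}, {len(self.qStarts)}, {len(self.tStarts)})"
            )
        prev_end = -1
        for size, t0 in zip(self.blockSizes, self.tStarts):
            if t0 < prev_end:
                raise PslError(
                    f"{self.qName}->{self.tName}: target blocks overlap or are unsorted"
                )
            prev_end = t0 + size
        total = self.matches + self.misMatches + self.repMatches + self.nCount
        if sum(self.blockSizes) != total:
            raise PslError(
                f"{self.qName}->{self.tName}: sum(blockSizes)={sum(self.blockSizes)} "
                f"!= matches+misMatches+repMatches+nCount={total}"
            )

    def target_blocks(self) -> list["GenomicInterval"]:
        """Aligned blocks as half-open intervals on the target genome."""
        return [
            GenomicInterval(self.tName, t0, t0 + size, name=self.qName)
            for size, t0 in zip(self.blockSizes, self.tStarts)
        ]

    def query_starts_forward(self) -> tuple[int, ...]:
        """Per-block query starts converted to query-forward coordinates.

        PSL stores minus-strand qStarts in reverse-complement coordinates;
        conversion makes interval math strand-free.
        """
        if self.strand.startswith("-"):
            return tuple(
                self.qSize - (q0 + size)
                for q0, size in zip(self.qStarts, self.blockSizes)
            )
        return self.qStarts


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A named, optionally stranded interval; 0-based half-open."""

    seqid: str
    start: int
    end: int
    name: str = ""
    strand: str | None = None

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval {self.seqid}:{self.start}-{self.end} "
                "(need 0 <= start < end)"
            )

    def __len__(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        """True iff the two intervals share at least one base."""
        return (
            self.seqid == other.seqid
            and self.start < other.end
            and other.start < self.end
        )


@dataclass
class GeneAnnotation:
    """One gene locus in one species.

    ``modelLength`` is the length of the longest transcript variant; for
    split models (multiple non-overlapping models at one locus) the lengths
    are summed.
    """

    species: str
    gene: str
    seqid: str
    start: int
    end: int
    strand: str
    modelIds: list[str] = field(default_factory=list)
    modelLength: int = 0

    def __post_init__(self) -> None:
        if self.modelIds and self.modelLength <= 0:
            raise AnnotationError(
                f"{self.species}/{self.gene}: modelLength must be > 0 when models exist"
            )


# ---------------------------------------------------------------------------
# PSL
# ---------------------------------------------------------------------------


def _split_int_list(text: str) -> tuple[int, ...]:
    # BLAT writes trailing commas in list columns; ignore them.
    return tuple(int(tok) for tok in text.strip().strip(",").split(",") if tok)


def _looks_like_psl_header(line: str) -> bool:
    # data lines always start with the integer `matches` column
    first = line.split("\t", 1)[0].strip()
    return not first.lstrip("-").isdigit()


def read_psl(path: str | Path) -> list[AlignmentRecord]:
    """Read a 21-column PSL file (with or without the 5-line header).

    Records are returned in file order and validated against the
    AlignmentRecord invariants; a malformed column count raises a
    :class:`PslError` naming the line number.
    """
    records: list[AlignmentRecord] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            if _looks_like_psl_header(line):
                continue
            cols = line.rstrip("\n").split("\t")
            if len(cols) != PSL_N_COLUMNS:
                raise PslError(
                    f"{path}: line {lineno}: expected {PSL_N_COLUMNS} columns, "
                    f"got {len(cols)}"
                )
            try:
                rec = AlignmentRecord(
                    matches=int(cols[0]),
                    misMatches=int(cols[1]),
                    repMatches=int(cols[2]),
                    nCount=int(cols[3]),
                    qNumInsert=int(cols[4]),
                    qBaseInsert=int(cols[5]),
                    tNumInsert=int(cols[6]),
                    tBaseInsert=int(cols[7]),
                    strand=cols[8],
                    qName=cols[9],
                    qSize=int(cols[10]),
                    qStart=int(cols[11]),
                    qEnd=int(cols[12]),
                    tName=cols[13],
                    tSize=int(cols[14]),
                    tStart=int(cols[15]),
                    tEnd=int(cols[16]),
                    blockSizes=_split_int_list(cols[18]),
                    qStarts=_split_int_list(cols[19]),
                    tStarts=_split_int_list(cols[20]),
                )
            except PslError as exc:
                raise PslError(f"{path}: line {lineno}: {exc}") from exc
            records.append(rec)
    return records


def write_psl(records: Iterable[AlignmentRecord], path: str | Path) -> None:
    """Write records as headerless 21-column PSL (lossless round trip)."""
    with open(path, "w") as fh:
        for r in records:
            fh.write(
                "\t".join(
                    str(v)
                    for v in (
                        r.matches,
                        r.misMatches,
                        r.repMatches,
                        r.nCount,
                        r.qNumInsert,
                        r.qBaseInsert,
                        r.tNumInsert,
                        r.tBaseInsert,
                        r.strand,
                        r.qName,
                        r.qSize,
                        r.qStart,
                        r.qEnd,
                        r.tName,
                        r.tSize,
                        r.tStart,
                        r.tEnd,
                        len(r.blockSizes),
                        ",".join(map(str, r.blockSizes)) + ",",
                        ",".join(map(str, r.qStarts)) + ",",
                        ",".join(map(str, r.tStarts)) + ",",
                    )
                )
                + "\n"
            )


# ---------------------------------------------------------------------------
# BED
# ---------------------------------------------------------------------------


def write_bed(intervals: Sequence[GenomicInterval], path: str | Path) -> None:
    """Write BED6, sorted by (seqid, start); 0-based half-open unchanged.

    An interval with start >= end cannot arise from a valid
    :class:`GenomicInterval`, but raw tuples are tolerated and refused with
    a log message rather than aborting the whole track.
    """
    rows = []
    for iv in intervals:
        if iv.start >= iv.end:
            logger.warning("write_bed: refusing invalid interval %r", iv)
            continue
        rows.append(iv)
    rows.sort(key=lambda iv: (iv.seqid, iv.start, iv.end, iv.name))
    with open(path, "w") as fh:
        for iv in rows:
            fh.write(
                f"{iv.seqid}\t{iv.start}\t{iv.end}\t{iv.name or '.'}\t0\t"
                f"{iv.strand or '.'}\n"
            )


def read_bed(path: str | Path) -> list[GenomicInterval]:
    """Read BED (>=3 columns) into intervals; strand from column 6 if present."""
    out: list[GenomicInterval] = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith(("track", "browser", "#")):
                continue
            cols = line.rstrip("\n").split("\t")
            name = cols[3] if len(cols) > 3 and cols[3] != "." else ""
            strand = cols[5] if len(cols) > 5 and cols[5] in "+-" else None
            out.append(
                GenomicInterval(cols[0], int(cols[1]), int(cols[2]), name, strand)
            )
    return out


# ---------------------------------------------------------------------------
# Gene annotations (TSV canonical; GFF3 adapter for gene lines)
# ---------------------------------------------------------------------------

ANNOTATION_COLUMNS = (
    "species",
    "gene",
    "seqid",
    "start",
    "end",
    "strand",
    "model_ids",
    "model_length",
)


def read_annotation(path: str | Path) -> list[GeneAnnotation]:
    """Read gene annotations from TSV (declared header) or GFF3 gene lines.

    Rows are grouped per (species, gene, seqid): multiple non-overlapping
    models at one locus ("split models") have their lengths summed and
    their model ids concatenated.  Duplicate identical rows are an error;
    rows lacking coordinates are skipped with a warning.
    """
    text_path = Path(path)
    first = ""
    with open(text_path) as fh:
        for line in fh:
            if line.strip() and not line.startswith("#"):
                first = line
                break
    if first.split("\t")[0] == "species":
        rows = _read_annotation_tsv(text_path)
    else:
        rows = _read_annotation_gff3(text_path)

    grouped: dict[tuple[str, str, str], GeneAnnotation] = {}
    seen_exact: set[tuple] = set()
    for ann in rows:
        exact = (ann.species, ann.gene, ann.seqid, ann.start, ann.end)
        if exact in seen_exact:
            raise AnnotationError(f"duplicate annotation row: {exact}")
        seen_exact.add(exact)
        key = (ann.species, ann.gene, ann.seqid)
        if key in grouped:
            prev = grouped[key]
            prev.start = min(prev.start, ann.start)
            prev.end = max(prev.end, ann.end)
            prev.modelIds.extend(ann.modelIds)
            prev.modelLength += ann.modelLength
        else:
            grouped[key] = ann
    return list(grouped.values())


def _read_annotation_tsv(path: Path) -> list[GeneAnnotation]:
    out: list[GeneAnnotation] = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        idx = {name: i for i, name in enumerate(header)}
        for lineno, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            cols = line.rstrip("\n").split("\t")
            try:
                start = int(cols[idx["start"]])
                end = int(cols[idx["end"]])
            except (ValueError, IndexError):
                logger.warning("%s: line %d: missing coordinates, skipped", path, lineno)
                continue
            model_ids = [
                m for m in cols[idx.get("model_ids", -1)].split(";") if m
            ] if "model_ids" in idx and len(cols) > idx["model_ids"] else []
            model_length = (
                int(cols[idx["model_length"]])
                if "model_length" in idx and cols[idx["model_length"]]
                else 0
            )
            out.append(
                GeneAnnotation(
                    species=cols[idx["species"]],
                    gene=cols[idx["gene"]],
                    seqid=cols[idx["seqid"]],
                    start=start,
                    end=end,
                    strand=cols[idx["strand"]],
                    modelIds=model_ids,
                    modelLength=model_length,
                )
            )
    return out


def _read_annotation_gff3(path: Path) -> list[GeneAnnotation]:
    # gene lines only; mRNA/exon lines ignored.  GFF3 is 1-based inclusive,
    # converted here to 0-based half-open.
    out: list[GeneAnnotation] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            cols = line.rstrip("\n").split("\t")
            if len(cols) < 9 or cols[2] != "gene":
                continue
            attrs = dict(
                kv.split("=", 1) for kv in cols[8].split(";") if "=" in kv
            )
            gene = attrs.get("Name") or attrs.get("gene_name") or attrs.get("ID", "")
            species = attrs.get("species", "unknown")
            try:
                start = int(cols[3]) - 1
                end = int(cols[4])
            except ValueError:
                logger.warning("%s: line %d: missing coordinates, skipped", path, lineno)
                continue
            out.append(
                GeneAnnotation(
                    species=species,
                    gene=gene,
                    seqid=cols[0],
                    start=start,
                    end=end,
                    strand=cols[6],
                    modelIds=[attrs["ID"]] if "ID" in attrs else [],
                    modelLength=end - start if "ID" in attrs else 0,
                )
            )
    return out


def write_annotation(annotations: Iterable[GeneAnnotation], path: str | Path) -> None:
    """Write annotations in the canonical TSV layout."""
    with open(path, "w") as fh:
        fh.write("\t".join(ANNOTATION_COLUMNS) + "\n")
        for a in sorted(annotations, key=lambda a: (a.species, a.seqid, a.start)):
            fh.write(
                f"{a.species}\t{a.gene}\t{a.seqid}\t{a.start}\t{a.end}\t{a.strand}\t"
                f"{';'.join(a.modelIds)}\t{a.modelLength}\n"
            )


# ---------------------------------------------------------------------------
# Newick species trees
# ---------------------------------------------------------------------------


def read_tree(path: str | Path) -> dendropy.Tree:
    """Read a single rooted Newick tree with unique leaf labels.

    Every internal branch is addressable by its subtended leaf set (see
    :func:`branch_leaf_sets`).
    """
    try:
        trees = dendropy.TreeList.get(
            path=str(path), schema="newick", preserve_underscores=True
        )
    except Exception as exc:  # dendropy's reader errors, incl. duplicate taxa
        raise TreeError(f"{path}: {exc}") from exc
    if len(trees) != 1:
        raise TreeError(f"{path}: expected exactly one tree, found {len(trees)}")
    tree = trees[0]
    tree.is_rooted = True
    labels = [leaf.taxon.label for leaf in tree.leaf_node_iter()]
    if len(labels) != len(set(labels)):
        raise TreeError(f"{path}: duplicate leaf labels")
    return tree


def parse_tree(newick: str) -> dendropy.Tree:
    """Parse a rooted Newick string (same checks as :func:`read_tree`)."""
    try:
        tree = dendropy.Tree.get(
            data=newick, schema="newick", preserve_underscores=True
        )
    except Exception as exc:
        raise TreeError(str(exc)) from exc
    tree.is_rooted = True
    labels = [leaf.taxon.label for leaf in tree.leaf_node_iter()]
    if len(labels) != len(set(labels)):
        raise TreeError("duplicate leaf labels")
    return tree


def branch_leaf_sets(tree: dendropy.Tree) -> dict[frozenset[str], str]:
    """Map each branch (as its subtended leaf set) to a branch label.

    The label is the internal node label where present, else the sole leaf
    label for terminal branches, else a deterministic ``clade(...)`` name.
    """
    out: dict[frozenset[str], str] = {}
    for node in tree.preorder_node_iter():
        leaves = frozenset(
            lf.taxon.label for lf in node.leaf_iter()
        )
        if node.is_leaf():
            out[leaves] = node.taxon.label
        else:
            label = node.label or "clade(" + ",".join(sorted(leaves)) + ")"
            out[leaves] = label
    return out


# ---------------------------------------------------------------------------
# TSV profile / expression matrices
# ---------------------------------------------------------------------------


def read_profile_matrix(path: str | Path):
    """Read a tri-state presence matrix: rows = genes, columns = species.

    Cell values are ``present`` / ``absent`` / ``unknown``, optionally
    suffixed ``:gapless`` / ``:gappy`` / ``:fragmented`` with the evidence
    quality of the underlying assembly.  Returns a pandas DataFrame of raw
    cell strings indexed by gene.
    """
    import pandas as pd

    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    return df
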