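import numpy as np
import pytest

from genecomplement.alignment_io import AlignmentRecord, GenomicInterval


def random_alignment_record(rng: np.random.Generator) -> AlignmentRecord:
    """A random but invariant-satisfying PSL record."""
    nblocks = int(rng.integers(1, 5))
    sizes = [int(rng.integers(10, 200)) for _ in range(nblocks)]
    total = sum(sizes)
    mis = int(rng.integers(0, total // 4 + 1))
    rep = int(rng.integers(0, total // 8 + 1))
    ncount = int(rng.integers(0, total // 10 + 1))
    matches = total - mis - rep - ncount
    tstarts, pos = [], int(rng.integers(0, 1000))
    for s in sizes:
        tstarts.append(pos)
        pos += s + int(rng.integers(0, 300))
    qstarts, qpos = [], 0
    for s in sizes:
        qstarts.append(qpos)
        qpos += s + int(rng.integers(0, 20))
    qsize = qpos + int(rng.integers(0, 100))
    strand = "+" if rng.random() < 0.7 else "-"
    return AlignmentRecord(
        qName=f"q{rng.integers(0, 100)}",
        tName=f"chr{rng.integers(1, 6)}",
        strand=strand,
        qSize=qsize,
        tSize=pos + 1000,
        matches=matches,
        misMatches=mis,
        repMatches=rep,
        nCount=ncount,
        qNumInsert=max(0, nblocks - 1),
        tNumInsert=max(0, nblocks - 1),
        qBaseInsert=qpos - total,
        tBaseInsert=tstarts[-1] + sizes[-1] - tstarts[0] - total,
        qStart=qstarts[0],
        qEnd=qstarts[-1] + sizes[-1],
        tStart=tstarts[0],
        tEnd=tstarts[-1] + sizes[-1],
        blockSizes=tuple(sizes),
        qStarts=tuple(qstarts),
        tStarts=tuple(tstarts),
    )


def random_interval(rng: np.random.Generator, max_coord: int = 10_000) -> GenomicInterval:
    start = int(rng.integers(0, max_coord - 1))
    end = int(rng.integers(start + 1, max_coord))
    return GenomicInterval(
        f"chr{rng.integers(1, 4)}", start, end, name=f"iv{rng.integers(0, 10_000)}"
    )


@pytest.fixture
def rng():
    return np.random.default_rng(20_240_901)
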