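"""Per-gene, per-song-nucleus differential-expression calls and the
reconciliation rule between microarray and in situ hybridization outcomes.

Calls are categorical: ``higher``, ``lower`` or ``nondifferential``
relative to the surrounding brain region, or ``not-assessed``.  When the
two assays disagree, the in situ hybridization call wins — it observes the
nucleus and its surround in the same section, whereas the microarray
contrast regions were dissected separately.  Genes without an in situ
probe fall back to the microarray call alone.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

import pandas as pd

SONG_NUCLEI = ("HVC", "RA", "AreaX", "LMAN", "nXIIts", "DLM", "Uva", "NIf")
CALLS = ("higher", "lower", "nondifferential", "not-assessed")
ASSAYS = ("microarray", "ish")


@dataclass(frozen=True)
class ExpressionCall:
    """One categorical call for (gene, nucleus, assay).

    ``sparsePopulation`` annotates in situ observations of strong signal in
    a sparse cell population; it is orthogonal to the nucleus-level call.
    """

    gene: str
    nucleus: str
    assay: str
    call: str
    sparsePopulation: bool = False

    def __post_init__(self) -> None:
        if self.nucleus not in SONG_NUCLEI:
            raise ValueError(f"unknown nucleus {self.nucleus!r}")
        if self.assay not in ASSAYS:
            raise ValueError(f"unknown assay {self.assay!r}")
        if self.call not in CALLS:
            raise ValueError(f"unknown call {self.call!r}")


def reconcile_call(microarray: str, ish: str) -> tuple[str, str]:
    """Combine the two assay outcomes into (final call, provenance).

    In-situ-dominant: an assessed in situ call is final regardless of the
    microarray; agreement of both assays is recorded as such; a gene
    assessed only on the array is ``microarray-only``; neither assay
    assessed leaves the cell ``not-assessed``.
    """
    for call in (microarray, ish):
        if call not in CALLS:
            raise ValueError(f"unknown call {call!r}")
    micro_ok = microarray != "not-assessed"
    ish_ok = ish != "not-assessed"
    if not micro_ok and not ish_ok:
        return "not-assessed", "not-assessed"
    if not ish_ok:
        return microarray, "microarray-only"
    if micro_ok and microarray == ish:
        return ish, "agreement"
    return ish, "ish"


@dataclass
class FinalCallMatrix:
    """Final calls and their provenance per gene x nucleus."""

    calls: pd.DataFrame  # genes x nuclei, final call strings
    provenance: pd.DataFrame  # genes x nuclei, provenance strings


def build_matrix(calls: Iterable[ExpressionCall]) -> FinalCallMatrix:
    """Reconcile a stream of per-assay calls into the final matrix.

    One call per (gene, nucleus, assay) is allowed; cells never observed by
    either assay are ``not-assessed``.
    """
    per_cell: dict[tuple[str, str], dict[str, str]] = {}
    for c in calls:
        cell = per_cell.setdefault((c.gene, c.nucleus), {})
        if c.assay in cell:
            raise ValueError(
                f"duplicate call for ({c.gene}, {c.nucleus}, {c.assay})"
            )
        cell[c.assay] = c.call

    genes = sorted({g for g, _ in per_cell})
    final = pd.DataFrame("not-assessed", index=genes, columns=list(SONG_NUCLEI))
    prov = pd.DataFrame("not-assessed", index=genes, columns=list(SONG_NUCLEI))
    for (gene, nucleus), cell in per_cell.items():
        call, provenance = reconcile_call(
            cell.get("microarray", "not-assessed"), cell.get("ish", "not-assessed")
        )
        final.loc[gene, nucleus] = call
        prov.loc[gene, nucleus] = provenance
    return FinalCallMatrix(final, prov)


def summarize_matrix(
    matrix: FinalCallMatrix, families: dict[str, str] | None = None
) -> dict[str, pd.DataFrame]:
    """Counts of higher/lower/nondifferential per nucleus (and per family).

    Not-assessed cells are excluded from all denominators.
    """
    directions = ("higher", "lower", "nondifferential")
    per_nucleus = pd.DataFrame(
        {
            d: (matrix.calls == d).sum(axis=0) for d in directions
        }
    )
    out = {"per_nucleus": per_nucleus}
    if families is not None:
        fam = pd.Series(
            {g: families.get(g, "unknown") for g in matrix.calls.index}
        )
        rows = {}
        for family in sorted(set(fam)):
            sub = matrix.calls.loc[fam[fam == family].index]
            rows[family] = {d: int((sub == d).sum().sum()) for d in directions}
        out["per_family"] = pd.DataFrame(rows).T
    return out


def write_matrix(matrix: FinalCallMatrix, path) -> None:
    """TSV heat-table: one row per gene, one column per nucleus, final call
    suffixed ``/provenance`` for cells where the assays disagreed."""
    df = matrix.calls.copy()
    disagree = matrix.provenance == "ish"
    df = df.where(~disagree, df + "/ish")
    df.to_csv(path, sep="\t")
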