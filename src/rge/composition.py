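"""GC content of intact ORFs and degraded remnant regions.

N and gap characters are excluded from both numerator and denominator, so
a remnant's GC is measured only on its determined bases.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .sequence_io import GeneMatrix
from .tables import ParameterTable


@dataclass
class GCResult:
    symbiont_id: str
    gene_id: str
    gc_fraction: float
    gc_percent: float
    n_counted: int
    n_excluded: int


def gc_content(seq: str) -> tuple[float, int, int]:
    """(gc_fraction, n_counted, n_excluded) for a DNA string over ACGTN-."""
    counted = excluded = gc = 0
    for c in seq:
        if c in "GC":
            gc += 1
            counted += 1
        elif c in "AT":
            counted += 1
        elif c in "N-":
            excluded += 1
        else:
            raise ValueError(f"unexpected character {c!r} in sequence")
    if counted == 0:
        raise ValueError("no countable bases (sequence is all gaps/N)")
    return gc / counted, counted, excluded


def gc_result(symbiont_id: str, gene_id: str, seq: str) -> GCResult:
    frac, counted, excluded = gc_content(seq)
    return GCResult(
        symbiont_id=symbiont_id,
        gene_id=gene_id,
        gc_fraction=frac,
        gc_percent=100.0 * frac,
        n_counted=counted,
        n_excluded=excluded,
    )


def gc_table(matrix: GeneMatrix) -> ParameterTable:
    """Genes x symbionts table of GC percent; absent genes -> NA."""
    values = pd.DataFrame(np.nan, index=matrix.gene_order, columns=matrix.symbiont_order)
    for (gene, sym), rec in matrix.records.items():
        if rec.status == "absent":
            continue
        frac, _, _ = gc_content(rec.sequence)
        values.at[gene, sym] = 100.0 * frac
    return ParameterTable(
        parameter="gc",
        values=values,
        status=matrix.status_frame(),
        clade_map=matrix.clade_map(),
    )
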