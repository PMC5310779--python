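"""Gene-by-symbiont parameter tables shared across the analysis modules."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

PARAMETERS = ("distance", "gc", "repeat_density", "dnds")


@dataclass
class ParameterTable:
    """One genetic parameter measured for every (gene, symbiont) cell.

    ``values`` is a genes x symbionts float DataFrame with NaN marking
    absent genes or failed measurements.  ``status`` mirrors its shape with
    the intact/degraded/absent call for each cell, and ``clade_map`` sends
    each symbiont column to "I", "II" or "outgroup".
    """

    parameter: str
    values: pd.DataFrame
    status: pd.DataFrame | None = None
    clade_map: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.parameter not in PARAMETERS:
            raise ValueError(
                f"unknown parameter {self.parameter!r}; expected one of {PARAMETERS}"
            )
        self.values = self.values.astype(float)
        if self.status is not None and not self.status.index.equals(self.values.index):
            raise ValueError("status table does not match values table dimensions")

    @property
    def genes(self) -> list[str]:
        return list(self.values.index)

    @property
    def symbionts(self) -> list[str]:
        return list(self.values.columns)

    def ingroup_symbionts(self) -> list[str]:
        return [s for s in self.symbionts if self.clade_map.get(s) != "outgroup"]

    def clade_members(self, clade: str) -> list[str]:
        return [s for s in self.symbionts if self.clade_map.get(s) == clade]


def write_parameter_table(table: ParameterTable, path, metadata: dict | None = None) -> None:
    """Write a TSV (genes as rows, symbionts as columns, missing cells "NA").

    Values are written with ``repr`` precision so a read-back reproduces
    them bit-exactly.  ``metadata`` key/value pairs go into "#"-prefixed
    header lines so spreadsheets still load the table unchanged.
    """
    lines = [f"# parameter: {table.parameter}"]
    for key, val in (metadata or {}).items():
        lines.append(f"# {key}: {val}")
    lines.append("\t".join(["gene"] + table.symbionts))
    for gene in table.genes:
        row = [gene]
        for sym in table.symbionts:
            v = table.values.at[gene, sym]
            row.append("NA" if pd.isna(v) else repr(float(v)))
        lines.append("\t".join(row))
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


def read_parameter_table(path, clade_map: dict[str, str] | None = None) -> ParameterTable:
    """Read a TSV written by :func:`write_parameter_table`."""
    parameter = None
    rows = []
    header = None
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            if line.startswith("#"):
                body = line.lstrip("# ")
                if body.startswith("parameter:"):
                    parameter = body.split(":", 1)[1].strip()
                continue
            if header is None:
                header = line.split("\t")
                continue
            rows.append(line.split("\t"))
    if header is None or not rows:
        raise ValueError(f"{path}: no table rows found")
    if parameter is None:
        raise ValueError(f"{path}: missing '# parameter:' header line")
    genes = [r[0] for r in rows]
    data = np.array(
        [[np.nan if c == "NA" else float(c) for c in r[1:]] for r in rows], dtype=float
    )
    values = pd.DataFrame(data, index=genes, columns=header[1:])
    return ParameterTable(parameter=parameter, values=values, clade_map=clade_map or {})
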