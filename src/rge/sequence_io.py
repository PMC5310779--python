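"""Read/write sequences and metadata and assemble the gene x symbiont panel.

Sequences are DNA over {A,C,G,T,N,-}; ambiguity codes beyond N are rejected
because the panel genes are finished Sanger sequences and the downstream
k-mer counting needs unambiguous bases.  Degraded remnants are stored
verbatim (gaps and frameshifts included); gap characters are stripped only
inside the computations that need contiguous sequence.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd
from Bio import SeqIO

VALID_CHARS = frozenset("ACGTN-")
CLADES = ("I", "II", "outgroup")
STATUSES = ("intact", "degraded", "absent")

STOP_CODONS = frozenset({"TAA", "TAG", "TGA"})


class SequenceDataError(ValueError):
    """Malformed sequence or metadata input."""


@dataclass
class GeneRecord:
    """One (symbiont, gene) sequence with its clade and intact/degraded call.

    Clade and status always come from the metadata table, never from the
    sequence itself.
    """

    symbiont_id: str
    gene_id: str
    sequence: str
    status: str
    clade: str

    def __post_init__(self) -> None:
        if self.status not in STATUSES:
            raise SequenceDataError(f"unknown status {self.status!r}")
        if self.clade not in CLADES:
            raise SequenceDataError(f"unknown clade {self.clade!r}")
        if self.status != "absent" and not self.sequence:
            raise SequenceDataError(
                f"{self.symbiont_id}|{self.gene_id}: empty sequence but status "
                f"is {self.status!r}"
            )
        bad = set(self.sequence) - VALID_CHARS
        if bad:
            raise SequenceDataError(
                f"{self.symbiont_id}|{self.gene_id}: non-IUPAC characters {sorted(bad)}"
            )

    @property
    def ungapped(self) -> str:
        return self.sequence.replace("-", "")

    def orf_ok(self) -> bool:
        """Frame-1 sanity flag for intact genes (not a hard failure).

        True when the gap-stripped sequence has length divisible by 3 and
        no internal stop codon in frame 1.  Degraded remnants are exempt
        and always return True.
        """
        if self.status != "intact":
            return True
        seq = self.ungapped
        if len(seq) % 3 != 0:
            return False
        for i in range(0, len(seq) - 3, 3):
            if seq[i : i + 3] in STOP_CODONS:
                return False
        return True


@dataclass
class GeneMatrix:
    """The gene x symbiont panel: at most one record per (gene, symbiont)."""

    records: dict[tuple[str, str], GeneRecord]
    gene_order: list[str]
    symbiont_order: list[str]
    outgroup_id: str

    def __post_init__(self) -> None:
        if self.outgroup_id not in self.symbiont_order:
            raise SequenceDataError(
                f"outgroup {self.outgroup_id!r} not among symbionts"
            )
        for (gene, sym), rec in self.records.items():
            if rec.gene_id != gene or rec.symbiont_id != sym:
                raise SequenceDataError(f"record key mismatch at ({gene}, {sym})")
        for rec in self.records.values():
            if rec.symbiont_id == self.outgroup_id and rec.clade != "outgroup":
                raise SequenceDataError(
                    f"outgroup {self.outgroup_id!r} has clade {rec.clade!r}"
                )

    def get(self, gene_id: str, symbiont_id: str) -> GeneRecord | None:
        return self.records.get((gene_id, symbiont_id))

    def clade_map(self) -> dict[str, str]:
        out = {}
        for rec in self.records.values():
            out[rec.symbiont_id] = rec.clade
        return out

    def status_frame(self) -> pd.DataFrame:
        frame = pd.DataFrame(
            "absent", index=self.gene_order, columns=self.symbiont_order
        )
        for (gene, sym), rec in self.records.items():
            frame.at[gene, sym] = rec.status
        return frame

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, GeneMatrix):
            return NotImplemented
        return (
            self.records == other.records
            and self.gene_order == other.gene_order
            and self.symbiont_order == other.symbiont_order
            and self.outgroup_id == other.outgroup_id
        )


def read_fasta(path) -> list[tuple[str, str]]:
    """Read a multi-record FASTA as (header, uppercased sequence) pairs.

    Headers keep the first token plus description verbatim; wrapped lines
    and CRLF endings are handled by the parser; record order is preserved.
    """
    out = []
    for rec in SeqIO.parse(str(path), "fasta"):
        header = rec.description
        seq = str(rec.seq).upper()
        bad_at = next((i for i, c in enumerate(seq) if c not in VALID_CHARS), None)
        if bad_at is not None:
            raise SequenceDataError(
                f"{path}: record {header!r} has non-IUPAC character "
                f"{seq[bad_at]!r} at offset {bad_at + 1}"
            )
        out.append((header, seq))
    if not out:
        raise SequenceDataError(f"{path}: no FASTA records found")
    return out


def write_fasta(records: list[tuple[str, str]], path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for header, seq in records:
            fh.write(f">{header}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def read_metadata(path) -> pd.DataFrame:
    """Read the metadata TSV (symbiont_id, gene_id, clade, status columns)."""
    meta = pd.read_csv(path, sep="\t", dtype=str, comment="#")
    required = {"symbiont_id", "gene_id", "clade", "status"}
    missing = required - set(meta.columns)
    if missing:
        raise SequenceDataError(f"{path}: metadata missing columns {sorted(missing)}")
    bad_clade = set(meta["clade"]) - set(CLADES)
    if bad_clade:
        raise SequenceDataError(f"{path}: unknown clade values {sorted(bad_clade)}")
    bad_status = set(meta["status"]) - set(STATUSES)
    if bad_status:
        raise SequenceDataError(f"{path}: unknown status values {sorted(bad_status)}")
    return meta


def build_matrix(
    fasta_records: list[tuple[str, str]],
    metadata: pd.DataFrame,
    delimiter: str = "|",
) -> GeneMatrix:
    """Join FASTA records to metadata rows via "symbiont_id|gene_id" headers.

    Metadata rows with status=absent need no FASTA entry (they become
    empty-sequence cells).  Duplicate keys and orphan FASTA records are
    errors.  The result is independent of FASTA record order.
    """
    seq_by_key: dict[tuple[str, str], str] = {}
    for header, seq in fasta_records:
        token = header.split()[0]
        parts = token.split(delimiter)
        if len(parts) != 2:
            raise SequenceDataError(
                f"FASTA header {header!r} does not follow the "
                f"'symbiont{delimiter}gene' convention"
            )
        sym, gene = parts
        key = (gene, sym)
        if key in seq_by_key:
            raise SequenceDataError(f"duplicate FASTA record for {sym}{delimiter}{gene}")
        seq_by_key[key] = seq

    records: dict[tuple[str, str], GeneRecord] = {}
    gene_order: list[str] = []
    symbiont_order: list[str] = []
    outgroup_ids = set()
    meta_keys = set()
    for row in metadata.itertuples(index=False):
        key = (row.gene_id, row.symbiont_id)
        if key in meta_keys:
            raise SequenceDataError(
                f"duplicate metadata row for {row.symbiont_id}{delimiter}{row.gene_id}"
            )
        meta_keys.add(key)
        seq = seq_by_key.pop(key, "")
        if not seq and row.status != "absent":
            raise SequenceDataError(
                f"no FASTA sequence for {row.symbiont_id}{delimiter}{row.gene_id} "
                f"(status {row.status})"
            )
        records[key] = GeneRecord(
            symbiont_id=row.symbiont_id,
            gene_id=row.gene_id,
            sequence=seq,
            status=row.status,
            clade=row.clade,
        )
        if row.gene_id not in gene_order:
            gene_order.append(row.gene_id)
        if row.symbiont_id not in symbiont_order:
            symbiont_order.append(row.symbiont_id)
        if row.clade == "outgroup":
            outgroup_ids.add(row.symbiont_id)

    if seq_by_key:
        orphans = ", ".join(f"{s}{delimiter}{g}" for g, s in sorted(seq_by_key))
        raise SequenceDataError(f"FASTA records with no metadata row: {orphans}")
    if len(outgroup_ids) != 1:
        raise SequenceDataError(
            f"expected exactly one outgroup symbiont, found {sorted(outgroup_ids)}"
        )
    return GeneMatrix(
        records=records,
        gene_order=gene_order,
        symbiont_order=symbiont_order,
        outgroup_id=outgroup_ids.pop(),
    )


# Parameter-table IO lives with the table type; re-exported here because the
# file-format surface of the package is defined in this module.
from .tables import ParameterTable, read_parameter_table, write_parameter_table  # noqa: E402,F401
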