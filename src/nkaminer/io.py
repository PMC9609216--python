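"""Readers and writers for the formats the pipeline touches.

Sequences travel as standard FASTA; taxonomic labels travel in a sidecar
TSV (id, group, isoform) so the FASTA stays plain.  Attribute tables are
TSV with a ``#inventory=<version>`` header comment that detects featurizer
drift between writer and reader.
"""

from __future__ import annotations

import io as _io
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Optional, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

log = logging.getLogger("nkaminer")

GROUPS = ("prokaryote", "Protista", "fungi", "invertebrate", "vertebrate")
ISOFORMS = ("a1", "a2", "a3", "a4")

#: 20 standard residues plus the ambiguity letters accepted on input.
STANDARD_AA = "ACDEFGHIKLMNPQRSTVWY"
AMBIGUOUS_AA = "BZXUO"
ALPHABET = frozenset(STANDARD_AA + AMBIGUOUS_AA)


class FastaError(ValueError):
    """Malformed or inconsistent FASTA input."""


class LabelError(ValueError):
    """Label table violates the record invariants."""


@dataclass(frozen=True)
class ProteinRecord:
    """One protein sequence with optional taxonomy labels.

    ``group`` is one of the five organism groups; ``isoform`` (a1..a4)
    may only be set for vertebrates.
    """

    id: str
    sequence: str
    description: str = ""
    group: Optional[str] = None
    isoform: Optional[str] = None

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("record id must be non-empty")
        if len(self.sequence) < 1:
            raise ValueError(f"{self.id}: empty sequence")
        bad = set(self.sequence) - ALPHABET
        if bad:
            raise ValueError(f"{self.id}: illegal residue letters {sorted(bad)}")
        if self.group is not None and self.group not in GROUPS:
            raise LabelError(f"{self.id}: unknown group {self.group!r}")
        if self.isoform is not None:
            if self.isoform not in ISOFORMS:
                raise LabelError(f"{self.id}: unknown isoform {self.isoform!r}")
            if self.group != "vertebrate":
                raise LabelError(
                    f"{self.id}: isoform set for non-vertebrate group {self.group!r}"
                )


def read_fasta(path) -> list[ProteinRecord]:
    """Read a protein FASTA into :class:`ProteinRecord` objects.

    Sequences are uppercased; entry order is preserved; duplicate ids are
    an error.
    """
    path = Path(path)
    records: list[ProteinRecord] = []
    seen: set[str] = set()
    try:
        parsed = list(SeqIO.parse(str(path), "fasta"))
    except (ValueError, FileNotFoundError) as exc:  # pragma: no cover - passthrough
        raise FastaError(f"{path}: {exc}") from exc
    if not parsed:
        raise FastaError(f"{path}: no FASTA entries found")
    for entry in parsed:
        if entry.id in seen:
            raise FastaError(f"{path}: duplicate sequence id {entry.id!r}")
        seen.add(entry.id)
        records.append(
            ProteinRecord(
                id=entry.id,
                sequence=str(entry.seq).upper(),
                description=entry.description,
            )
        )
    return records


def write_fasta(records: Iterable[ProteinRecord], path) -> None:
    seqrecs = [
        SeqRecord(Seq(r.sequence), id=r.id, description=r.description or "")
        for r in records
    ]
    with open(path, "w") as fh:
        SeqIO.write(seqrecs, fh, "fasta")


def read_labels(path) -> pd.DataFrame:
    """Read the sidecar label TSV (columns: id, group, optional isoform)."""
    df = pd.read_csv(path, sep="\t", dtype=str, comment="#").fillna("")
    required = {"id", "group"}
    if not required.issubset(df.columns):
        raise LabelError(f"{path}: label table needs columns {sorted(required)}")
    if "isoform" not in df.columns:
        df["isoform"] = ""
    return df[["id", "group", "isoform"]]


def write_labels(records: Iterable[ProteinRecord], path) -> None:
    rows = [
        {"id": r.id, "group": r.group or "", "isoform": r.isoform or ""}
        for r in records
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def join_labels(
    records: Sequence[ProteinRecord], labels: pd.DataFrame
) -> list[ProteinRecord]:
    """Attach group/isoform labels to records by id.

    Ids present in the table but absent from the records are reported via
    a warning (returned records keep input order).  An isoform given for a
    non-vertebrate row raises :class:`LabelError`.
    """
    by_id = {r.id: r for r in records}
    dup = labels["id"][labels["id"].duplicated()]
    if len(dup):
        raise LabelError(f"duplicate ids in label table: {sorted(set(dup))}")
    orphans = [i for i in labels["id"] if i not in by_id]
    if orphans:
        log.warning("label rows with no matching record: %s", ", ".join(orphans))
    out = {r.id: r for r in records}
    for _, row in labels.iterrows():
        rid = row["id"]
        if rid not in by_id:
            continue
        iso = row["isoform"] or None
        grp = row["group"] or None
        out[rid] = replace(by_id[rid], group=grp, isoform=iso)
    return [out[r.id] for r in records]


# ---------------------------------------------------------------------------
# Attribute tables


class InventoryMismatch(ValueError):
    """Attribute table written under a different attribute inventory."""


@dataclass
class AttributeTable:
    """Sequences x attributes matrix with labels carried alongside.

    ``data`` holds the numeric attribute matrix (row index = sequence id,
    columns in inventory order); ``labels`` holds the group/isoform columns
    for the same index.
    """

    data: pd.DataFrame
    labels: pd.DataFrame
    inventory_version: str
    provenance: dict = field(default_factory=dict)

    @property
    def ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def attributes(self) -> list[str]:
        return list(self.data.columns)

    def subset(self, attributes: Sequence[str]) -> "AttributeTable":
        return AttributeTable(
            data=self.data[list(attributes)].copy(),
            labels=self.labels,
            inventory_version=self.inventory_version,
            provenance=dict(self.provenance),
        )

    def rows(self, mask) -> "AttributeTable":
        return AttributeTable(
            data=self.data.loc[mask].copy(),
            labels=self.labels.loc[mask].copy(),
            inventory_version=self.inventory_version,
            provenance=dict(self.provenance),
        )


def write_attribute_table(table: AttributeTable, path) -> None:
    """Write an attribute table as TSV with an inventory-version header.

    Round-trips losslessly to 12 significant digits.
    """
    if table.data.shape[0] == 0:
        raise ValueError("refusing to write an empty attribute table")
    path = Path(path)
    joined = pd.concat([table.labels, table.data], axis=1)
    with open(path, "w") as fh:
        fh.write(f"#inventory={table.inventory_version}\n")
        for key, val in sorted(table.provenance.items()):
            fh.write(f"#{key}={val}\n")
        joined.to_csv(fh, sep="\t", index=True, index_label="id", float_format="%.12g")


def read_attribute_table(path, expected_version: Optional[str] = None) -> AttributeTable:
    path = Path(path)
    version = None
    provenance: dict[str, str] = {}
    body: list[str] = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("#"):
                key, _, val = line[1:].rstrip("\n").partition("=")
                if key == "inventory":
                    version = val
                else:
                    provenance[key] = val
            else:
                body.append(line)
    if version is None:
        raise InventoryMismatch(f"{path}: missing #inventory= header")
    if expected_version is not None and version != expected_version:
        raise InventoryMismatch(
            f"{path}: inventory {version!r} != expected {expected_version!r}"
        )
    df = pd.read_csv(_io.StringIO("".join(body)), sep="\t", index_col="id")
    df.index.name = None
    label_cols = [c for c in ("group", "isoform") if c in df.columns]
    labels = df[label_cols].fillna("").astype(str)
    data = df.drop(columns=label_cols).astype(float)
    return AttributeTable(
        data=data, labels=labels, inventory_version=version, provenance=provenance
    )
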