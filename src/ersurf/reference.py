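"""Protein catalogs: sequences, compartment annotation, hydropathy scales.

The catalog is the protein universe every downstream stage works on: each
protein carries a sequence (for hydropathy profiling) and a subcellular
compartment label (for subclass statistics and the fraction-composition
summary). Mitochondrial sub-compartments mirror the standard matrix /
inner membrane / intermembrane space / outer membrane taxonomy; the
non-mitochondrial classes are the ones relevant to an ER-vs-mitochondria
affinity-purification design.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

#: Closed set of compartment labels accepted by the annotation loader.
COMPARTMENTS = (
    "matrix",
    "inner_membrane",
    "IMS",
    "outer_membrane",
    "ER",
    "peroxisome",
    "nucleus",
    "other",
)

UNANNOTATED = "unannotated"

#: Mitochondrial sub-compartments (used for subclass breakdowns).
MITO_COMPARTMENTS = ("matrix", "inner_membrane", "IMS", "outer_membrane")

#: The 20 standard amino-acid one-letter codes.
STANDARD_RESIDUES = "ACDEFGHIKLMNPQRSTVWY"

# Kyte & Doolittle (1982) hydropathy values, one per standard residue.
_KD_VALUES = {
    "I": 4.5, "V": 4.2, "L": 3.8, "F": 2.8, "C": 2.5, "M": 1.9, "A": 1.8,
    "G": -0.4, "T": -0.7, "S": -0.8, "W": -0.9, "Y": -1.3, "P": -1.6,
    "H": -3.2, "E": -3.5, "Q": -3.5, "D": -3.5, "N": -3.5, "K": -3.9,
    "R": -4.5,
}


class ReferenceError(ValueError):
    """Raised for malformed catalogs, annotation tables or scales."""


@dataclass
class ProteinRecord:
    """One catalog entry.

    Parameters
    ----------
    id : str
        Unique identifier (first whitespace-delimited FASTA header token).
    sequence : str
        Amino-acid sequence, uppercase, standard 20-letter alphabet only.
    compartment : str
        One of :data:`COMPARTMENTS` or ``"unannotated"``.
    description : str
        Full FASTA header, retained as metadata.
    """

    id: str
    sequence: str
    compartment: str = UNANNOTATED
    description: str = ""

    def __post_init__(self) -> None:
        if not self.id:
            raise ReferenceError("protein id must be non-empty")
        if len(self.sequence) < 1:
            raise ReferenceError(f"protein {self.id!r}: empty sequence")
        bad = sorted(set(self.sequence) - set(STANDARD_RESIDUES))
        if bad:
            raise ReferenceError(
                f"protein {self.id!r}: non-standard residues {bad}; "
                "only the 20 standard amino-acid letters are accepted"
            )


@dataclass
class HydropathyScale:
    """Residue-letter → hydropathy score lookup (dimensionless)."""

    values: dict[str, float]
    name: str = "custom"

    def __post_init__(self) -> None:
        missing = set(STANDARD_RESIDUES) - set(self.values)
        extra = set(self.values) - set(STANDARD_RESIDUES)
        if missing or extra:
            raise ReferenceError(
                f"scale {self.name!r} must cover exactly the 20 standard "
                f"residues (missing={sorted(missing)}, extra={sorted(extra)})"
            )
        for res, v in self.values.items():
            if not math.isfinite(v):
                raise ReferenceError(f"scale {self.name!r}: non-finite score for {res}")


def kd_scale() -> HydropathyScale:
    """Return the canonical Kyte–Doolittle hydropathy scale."""
    return HydropathyScale(values=dict(_KD_VALUES), name="Kyte-Doolittle")


def load_scale(path) -> HydropathyScale:
    """Load a custom scale from a ``residue<TAB>score`` TSV (no header)."""
    table = pd.read_csv(path, sep="\t", header=None, names=["residue", "score"])
    return HydropathyScale(
        values={str(r): float(s) for r, s in zip(table["residue"], table["score"])},
        name=str(path),
    )


def load_fasta(path) -> list[ProteinRecord]:
    """Parse a FASTA file into a protein catalog.

    The id is the first whitespace-delimited header token; sequences are
    uppercased and validated against the 20-letter alphabet. Duplicate ids
    and non-standard residues are rejected (hydropathy is undefined for
    B/Z/X/U/O, and silently imputing values would bias the max-peak
    statistic).
    """
    records: list[ProteinRecord] = []
    seen: set[str] = set()
    for entry in SeqIO.parse(str(path), "fasta"):
        if entry.id in seen:
            raise ReferenceError(f"duplicate protein id {entry.id!r} in {path}")
        seen.add(entry.id)
        records.append(
            ProteinRecord(
                id=entry.id,
                sequence=str(entry.seq).upper(),
                description=entry.description,
            )
        )
    if not records:
        raise ReferenceError(f"no FASTA entries found in {path}")
    return records


def write_fasta(records: list[ProteinRecord], path) -> None:
    """Write a catalog back to FASTA (round-trips ids and sequences)."""
    SeqIO.write(
        (
            SeqRecord(Seq(r.sequence), id=r.id, description=r.description or r.id)
            for r in records
        ),
        str(path),
        "fasta",
    )


def load_annotation(path, records: list[ProteinRecord]) -> list[ProteinRecord]:
    """Apply a compartment annotation TSV (columns ``id``, ``compartment``).

    Records matching a table row get their compartment set in place;
    annotation rows without a matching record trigger a single warning with
    the unmatched count; records absent from the table stay unannotated.
    Unknown compartment labels are an error (the label set is closed).
    """
    table = pd.read_csv(path, sep="\t", dtype=str)
    for col in ("id", "compartment"):
        if col not in table.columns:
            raise ReferenceError(f"annotation table {path} lacks column {col!r}")
    bad_labels = sorted(set(table["compartment"]) - set(COMPARTMENTS))
    if bad_labels:
        raise ReferenceError(
            f"unknown compartment labels {bad_labels}; allowed: {list(COMPARTMENTS)}"
        )
    by_id = {r.id: r for r in records}
    unmatched = 0
    for pid, comp in zip(table["id"], table["compartment"]):
        rec = by_id.get(pid)
        if rec is None:
            unmatched += 1
        else:
            rec.compartment = comp
    if unmatched:
        warnings.warn(
            f"{unmatched} annotation row(s) had no matching protein record",
            stacklevel=2,
        )
    return records


def annotation_map(records: list[ProteinRecord]) -> pd.Series:
    """Compartment label per protein id, as a pandas Series."""
    return pd.Series({r.id: r.compartment for r in records}, name="compartment")


def write_annotation(records: list[ProteinRecord], path) -> None:
    """Write an ``id<TAB>compartment`` table for the annotated records."""
    pd.DataFrame(
        {"id": [r.id for r in records], "compartment": [r.compartment for r in records]}
    ).to_csv(path, sep="\t", index=False)
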