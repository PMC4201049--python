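"""Readers and writers for the formats the design engine touches.

Three input routes are supported, mirroring what a bench scientist actually
has at hand for a target protein:

* plain FASTA (one or many records),
* a UniProt/Swiss-Prot flat-text record, from which both the sequence and
  the annotated sequence features (PTM sites, transmembrane spans, variants,
  splice-isoform differences, ...) are extracted,
* a bare tab-separated feature table, for proteins with no curated record.

All coordinates are 1-based inclusive, the UniProt convention; peptide
windows downstream share it.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Union

from Bio import SeqIO, SwissProt
from Bio.SeqFeature import ExactPosition

logger = logging.getLogger("pepdesign")

PathLike = Union[str, Path]

#: Controlled vocabulary for feature kinds. Anything else maps to OTHER with
#: the original key preserved in the note.
FEATURE_KINDS = frozenset({
    "MOD_RES", "CARBOHYD", "LIPID", "DISULFID", "TRANSMEM", "TOPO_DOM",
    "SIGNAL", "DOMAIN", "VARIANT", "VAR_SEQ", "CONFLICT", "OTHER",
})

STANDARD_AA = frozenset("ACDEFGHIKLMNPQRSTVWY")


class FormatError(ValueError):
    """Malformed input file (bad FASTA, flat-text record, or feature table)."""


class ParameterError(ValueError):
    """Invalid run parameter (window length, epitope length, ...)."""


@dataclass(frozen=True)
class SequenceFeature:
    """One annotated interval on a protein, 1-based inclusive."""

    kind: str
    start: int
    end: int
    note: str = ""

    def __post_init__(self):
        if not (1 <= self.start <= self.end):
            raise FormatError(
                f"feature {self.kind} has invalid interval "
                f"[{self.start}, {self.end}] (need 1 <= start <= end)"
            )
        if self.kind not in FEATURE_KINDS:
            object.__setattr__(
                self, "note",
                f"{self.kind}: {self.note}" if self.note else self.kind,
            )
            object.__setattr__(self, "kind", "OTHER")


@dataclass
class ProteinRecord:
    """A protein sequence plus its attached features.

    The sequence is stored uppercase; the 20 standard letters plus
    B, Z, X, U, O are tolerated (downstream modules decide how the
    nonstandard ones score).
    """

    id: str
    sequence: str
    description: str = ""
    features: list[SequenceFeature] = field(default_factory=list)

    def __post_init__(self):
        if not self.sequence:
            raise FormatError(f"record {self.id!r} has an empty sequence")
        self.sequence = self.sequence.upper()
        if not self.sequence.isalpha():
            raise FormatError(
                f"record {self.id!r} contains non-letter sequence characters"
            )
        for f in self.features:
            self._check_feature(f)

    def _check_feature(self, f: SequenceFeature) -> None:
        if f.end > len(self.sequence):
            raise FormatError(
                f"feature {f.kind} [{f.start}, {f.end}] extends beyond "
                f"{self.id!r} (length {len(self.sequence)})"
            )

    def attach(self, features: Iterable[SequenceFeature]) -> None:
        for f in features:
            self._check_feature(f)
            self.features.append(f)

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass
class Proteome:
    """A set of protein records from one species."""

    records: list[ProteinRecord]
    species_label: str = ""

    def __post_init__(self):
        ids = [r.id for r in self.records]
        if len(ids) != len(set(ids)):
            dup = sorted({i for i in ids if ids.count(i) > 1})
            raise FormatError(f"duplicate record ids in proteome: {dup}")

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def read_fasta(path: PathLike) -> list[ProteinRecord]:
    """Read a multi-record FASTA file into ProteinRecords.

    The record id is the first whitespace-delimited token after '>'; the rest
    of the header line becomes the description. Record order is preserved.
    """
    path = Path(path)
    records: list[ProteinRecord] = []
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = str(rec.seq)
        if not seq:
            raise FormatError(f"{path}: record {rec.id!r} has an empty sequence")
        records.append(ProteinRecord(id=rec.id, sequence=seq,
                                     description=rec.description[len(rec.id):].strip()))
    if not records:
        raise FormatError(f"{path}: no FASTA records found")
    return records


def write_fasta(records: list[ProteinRecord], path: PathLike, width: int = 60) -> Path:
    """Write records as wrapped FASTA. Round-trips ids and sequences exactly."""
    if not records:
        raise ParameterError("cannot write an empty record list")
    path = Path(path)
    with open(path, "w") as fh:
        for r in records:
            header = f">{r.id}" + (f" {r.description}" if r.description else "")
            fh.write(header + "\n")
            for i in range(0, len(r.sequence), width):
                fh.write(r.sequence[i:i + width] + "\n")
    return path


# ---------------------------------------------------------------------------
# UniProt / Swiss-Prot flat text
# ---------------------------------------------------------------------------

_SQ_RE = re.compile(r"^SQ\s+SEQUENCE\s+(\d+)\s+AA;", re.MULTILINE)


def read_uniprot_text(path: PathLike) -> ProteinRecord:
    """Read a single Swiss-Prot flat-text record (modern FT qualifier style).

    The sequence comes from the SQ block; FT lines in the controlled
    vocabulary become SequenceFeatures. Features whose positions are unknown
    or uncertain ('?', '<', '>') are skipped with a logged warning.
    """
    path = Path(path)
    text = path.read_text()
    m = _SQ_RE.search(text)
    if m is None:
        raise FormatError(f"{path}: no SQ block found")
    declared_length = int(m.group(1))

    try:
        with open(path) as fh:
            sp = SwissProt.read(fh)
    except Exception as exc:  # biopython raises bare ValueError on bad records
        raise FormatError(f"{path}: cannot parse Swiss-Prot record: {exc}") from exc

    sequence = str(sp.sequence)
    if len(sequence) != declared_length:
        raise FormatError(
            f"{path}: SQ block declares {declared_length} aa but the "
            f"assembled sequence has {len(sequence)}"
        )

    accession = sp.accessions[0] if sp.accessions else sp.entry_name
    features: list[SequenceFeature] = []
    for ft in sp.features:
        loc = ft.location
        # UncertainPosition subclasses ExactPosition, so compare exact types
        if not (type(loc.start) is ExactPosition
                and type(loc.end) is ExactPosition):
            logger.warning("%s: skipping %s feature with unknown position", path, ft.type)
            continue
        # biopython locations are 0-based half-open; convert to 1-based inclusive
        start, end = int(loc.start) + 1, int(loc.end)
        if end > len(sequence):
            raise FormatError(
                f"{path}: feature {ft.type} [{start}, {end}] extends beyond "
                f"the {len(sequence)}-aa sequence"
            )
        if ft.type not in FEATURE_KINDS - {"OTHER"}:
            continue  # CHAIN, HELIX, STRAND etc. carry no design signal here
        note = str(ft.qualifiers.get("note", ""))
        features.append(SequenceFeature(kind=ft.type, start=start, end=end, note=note))

    return ProteinRecord(id=accession, sequence=sequence,
                         description=sp.entry_name, features=features)


# ---------------------------------------------------------------------------
# Tabular feature file
# ---------------------------------------------------------------------------

def read_feature_table(path: PathLike) -> list[SequenceFeature]:
    """Read a tab-separated feature table: kind, start, end, note.

    '#'-prefixed lines and blank lines are ignored. Kinds outside the
    controlled vocabulary map to OTHER with the original key kept in the note.
    """
    path = Path(path)
    features: list[SequenceFeature] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise FormatError(f"{path}:{lineno}: expected at least 3 "
                                  f"tab-separated columns, got {len(parts)}")
            kind = parts[0].strip()
            try:
                start, end = int(parts[1]), int(parts[2])
            except ValueError as exc:
                raise FormatError(
                    f"{path}:{lineno}: non-integer coordinates "
                    f"{parts[1]!r}, {parts[2]!r}") from exc
            note = parts[3].strip() if len(parts) > 3 else ""
            try:
                features.append(SequenceFeature(kind=kind, start=start, end=end, note=note))
            except FormatError as exc:
                raise FormatError(f"{path}:{lineno}: {exc}") from exc
    return features


def detect_and_read_target(path: PathLike) -> ProteinRecord:
    """Read a target protein from FASTA or Swiss-Prot flat text, by content.

    A file whose first non-blank character is '>' is FASTA (first record
    taken); anything else is treated as a flat-text record.
    """
    path = Path(path)
    with open(path) as fh:
        for line in fh:
            if line.strip():
                first = line.lstrip()[0]
                break
        else:
            raise FormatError(f"{path}: empty file")
    if first == ">":
        records = read_fasta(path)
        if len(records) > 1:
            logger.warning("%s: %d records; using the first as the target",
                           path, len(records))
        return records[0]
    return read_uniprot_text(path)
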