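"""Readers and writers for every external representation the pipeline touches.

Protein and nucleotide FASTA go through Biopython's ``SeqIO``; tabular hit
files use the standard 12-column format (query, subject, %identity, aln
length, mismatches, gap opens, qstart, qend, sstart, send, evalue, bitscore);
score and phenotype tables are headered TSV; melt plates are CSV with a
temperature column plus one column per well.

Sequences are upper-cased on input. Ambiguity letters (B, Z, X, U, O) are
accepted in protein records; downstream composition measures exclude them
from both numerators and denominators.
"""

from __future__ import annotations

import csv
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .errors import EmptyInputError, ValidationError
from .meltcurve import MeltCurve

STANDARD_AA = "ACDEFGHIKLMNPQRSTVWY"
AMBIGUOUS_AA = "BZXUO"
PROTEIN_ALPHABET = frozenset(STANDARD_AA + AMBIGUOUS_AA)
NUCLEOTIDE_ALPHABET = frozenset("ACGTN")


@dataclass
class ProteinRecord:
    """One protein sequence with its species tag.

    ``coding_seq``, when present, is the in-frame nucleotide sequence and
    must be exactly three times as long as the residue string.
    """

    id: str
    species: str
    residues: str
    coding_seq: str | None = None

    def __post_init__(self) -> None:
        if not self.residues:
            raise ValidationError(f"record {self.id!r}: empty residue string")
        if "-" in self.residues:
            raise ValidationError(f"record {self.id!r}: gap character in residues")
        if self.coding_seq is not None and len(self.coding_seq) != 3 * len(self.residues):
            raise ValidationError(
                f"record {self.id!r}: coding_seq length {len(self.coding_seq)} "
                f"!= 3 x {len(self.residues)} residues"
            )

    def __len__(self) -> int:
        return len(self.residues)


@dataclass(frozen=True)
class HitRecord:
    """One pairwise similarity hit between proteins of two species."""

    query_id: str
    subject_id: str
    query_species: str
    subject_species: str
    bitscore: float
    evalue: float


@dataclass
class PhenotypeTable:
    """Map species -> body temperature in degrees Celsius."""

    temperatures: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for sp, t in self.temperatures.items():
            if not (0.0 <= t <= 50.0):
                raise ValidationError(
                    f"species {sp!r}: body temperature {t} outside plausible 0-50 C"
                )

    def __len__(self) -> int:
        return len(self.temperatures)

    def __getitem__(self, species: str) -> float:
        return self.temperatures[species]


@dataclass
class ScoreTable:
    """Externally computed per-protein scores for one named measure.

    ``direction`` is +1 when larger scores indicate greater thermostability,
    -1 otherwise.
    """

    measure_name: str
    scores: dict[str, float]
    direction: int = 1

    def __post_init__(self) -> None:
        if self.direction not in (1, -1):
            raise ValidationError(f"direction must be +1 or -1, got {self.direction}")


def _validate_sequence(seq: str, alphabet: frozenset, record_id: str, kind: str) -> None:
    for pos, ch in enumerate(seq, start=1):
        if ch not in alphabet:
            raise ValidationError(
                f"record {record_id!r}: illegal {kind} character {ch!r} at position {pos}"
            )


def read_fasta(
    path: str | Path,
    alphabet: str = "protein",
    species: str | None = None,
    species_regex: str | None = None,
    allow_stop: bool = False,
) -> list[ProteinRecord]:
    """Read a FASTA file into :class:`ProteinRecord` objects, in file order.

    The species label is taken from ``species`` (one file per species, the
    default convention) or extracted from each header with ``species_regex``
    (first capture group). ``allow_stop`` retains ``'*'`` in protein records.
    """
    if alphabet not in ("protein", "nucleotide"):
        raise ValidationError(f"unknown alphabet {alphabet!r}")
    letters = PROTEIN_ALPHABET if alphabet == "protein" else NUCLEOTIDE_ALPHABET
    if allow_stop and alphabet == "protein":
        letters = letters | {"*"}
    records: list[ProteinRecord] = []
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = str(rec.seq).upper()
        _validate_sequence(seq, letters, rec.id, alphabet)
        if species_regex is not None:
            m = re.search(species_regex, rec.description)
            if m is None:
                raise ValidationError(
                    f"record {rec.id!r}: header does not match species regex"
                )
            sp = m.group(1)
        else:
            sp = species if species is not None else ""
        records.append(ProteinRecord(id=rec.id, species=sp, residues=seq))
    if not records:
        raise EmptyInputError(f"{path}: no FASTA records")
    return records


def write_fasta(records: Iterable[ProteinRecord], path: str | Path, coding: bool = False) -> None:
    """Write records as FASTA; ``coding=True`` writes the nucleotide sequences."""
    seqrecs = []
    for r in records:
        seq = r.coding_seq if coding else r.residues
        if seq is None:
            raise ValidationError(f"record {r.id!r}: no coding sequence to write")
        seqrecs.append(SeqRecord(Seq(seq), id=r.id, description=""))
    SeqIO.write(seqrecs, str(path), "fasta")


def read_hit_table(path: str | Path, id_to_species: dict[str, str]) -> list[HitRecord]:
    """Parse a 12-column tabular hit file.

    Only bitscore (column 12) and e-value (column 11) are consumed; species
    are resolved through ``id_to_species``. Lines starting with ``#`` are
    comments.
    """
    hits: list[HitRecord] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 12:
                raise ValidationError(
                    f"{path}:{lineno}: malformed row ({len(fields)} columns, need >= 12)"
                )
            qid, sid = fields[0], fields[1]
            for pid in (qid, sid):
                if pid not in id_to_species:
                    raise ValidationError(f"{path}:{lineno}: unknown id {pid!r}")
            try:
                evalue = float(fields[10])
                bitscore = float(fields[11])
            except ValueError as exc:
                raise ValidationError(f"{path}:{lineno}: malformed row: {exc}") from exc
            hits.append(
                HitRecord(
                    query_id=qid,
                    subject_id=sid,
                    query_species=id_to_species[qid],
                    subject_species=id_to_species[sid],
                    bitscore=bitscore,
                    evalue=evalue,
                )
            )
    return hits


def write_hit_table(hits: Iterable[HitRecord], path: str | Path) -> None:
    """Write hits in the 12-column tabular dialect (unused columns zeroed)."""
    with open(path, "w") as fh:
        for h in hits:
            fh.write(
                "\t".join(
                    [
                        h.query_id,
                        h.subject_id,
                        "0.0",
                        "0",
                        "0",
                        "0",
                        "0",
                        "0",
                        "0",
                        "0",
                        f"{h.evalue:g}",
                        f"{h.bitscore:g}",
                    ]
                )
                + "\n"
            )


def read_aligned_fasta(path: str | Path) -> list[tuple[str, str]]:
    """Read an aligned FASTA file as ``(id, gapped row)`` pairs.

    All rows must have equal length; a ragged alignment is an error naming
    the offending row.
    """
    rows = [(rec.id, str(rec.seq).upper()) for rec in SeqIO.parse(str(path), "fasta")]
    if not rows:
        raise EmptyInputError(f"{path}: no alignment rows")
    width = len(rows[0][1])
    for rid, row in rows:
        if len(row) != width:
            raise ValidationError(
                f"{path}: ragged alignment, row {rid!r} has length {len(row)} != {width}"
            )
    return rows


def write_aligned_fasta(rows: Sequence[tuple[str, str]], path: str | Path) -> None:
    seqrecs = [SeqRecord(Seq(row), id=rid, description="") for rid, row in rows]
    SeqIO.write(seqrecs, str(path), "fasta")


def read_score_table(
    path: str | Path, direction: int = 1, measure_name: str | None = None
) -> ScoreTable:
    """Read a two-column TSV (protein_id, score) with a header line.

    The measure name defaults to the second column's header.
    """
    scores: dict[str, float] = {}
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if len(header) < 2:
            raise ValidationError(f"{path}: score table needs >= 2 columns")
        name = measure_name or header[1]
        for lineno, line in enumerate(fh, start=2):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 2:
                raise ValidationError(f"{path}:{lineno}: malformed row")
            pid = fields[0]
            if pid in scores:
                raise ValidationError(f"{path}:{lineno}: duplicate protein id {pid!r}")
            scores[pid] = float(fields[1])
    return ScoreTable(measure_name=name, scores=scores, direction=direction)


def write_score_table(table: ScoreTable, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write(f"protein_id\t{table.measure_name}\n")
        for pid, score in table.scores.items():
            fh.write(f"{pid}\t{score:g}\n")


def read_phenotype_table(path: str | Path) -> PhenotypeTable:
    """Read a headered TSV mapping species to body temperature (C)."""
    temps: dict[str, float] = {}
    with open(path) as fh:
        fh.readline()  # header
        for lineno, line in enumerate(fh, start=2):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 2:
                raise ValidationError(f"{path}:{lineno}: malformed row")
            sp = fields[0]
            if sp in temps:
                raise ValidationError(f"{path}:{lineno}: duplicate species {sp!r}")
            temps[sp] = float(fields[1])
    return PhenotypeTable(temperatures=temps)


def read_melt_plate(path: str | Path) -> list[MeltCurve]:
    """Read a plate CSV: a ``temperature`` column plus one column per well."""
    with open(path) as fh:
        reader = csv.reader(fh)
        header = next(reader, None)
        if header is None:
            raise EmptyInputError(f"{path}: empty melt plate")
        if header[0].strip().lower() != "temperature":
            raise ValidationError(f"{path}: first column must be 'temperature'")
        wells = [h.strip() for h in header[1:]]
        temps: list[float] = []
        columns: list[list[float]] = [[] for _ in wells]
        for lineno, row in enumerate(reader, start=2):
            if not row:
                continue
            if len(row) != len(wells) + 1:
                raise ValidationError(f"{path}:{lineno}: malformed row")
            temps.append(float(row[0]))
            for i, val in enumerate(row[1:]):
                columns[i].append(float(val))
    t = np.asarray(temps, dtype=float)
    return [
        MeltCurve(temperatures=t, fluorescence=np.asarray(col, dtype=float), well_id=w)
        for w, col in zip(wells, columns)
    ]


def write_melt_plate(curves: Sequence[MeltCurve], path: str | Path) -> None:
    if not curves:
        raise EmptyInputError("no curves to write")
    t = curves[0].temperatures
    for c in curves[1:]:
        if not np.array_equal(c.temperatures, t):
            raise ValidationError("all wells must share the temperature grid")
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["temperature"] + [c.well_id for c in curves])
        for i in range(len(t)):
            writer.writerow([f"{t[i]:g}"] + [f"{c.fluorescence[i]:.6g}" for c in curves])
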