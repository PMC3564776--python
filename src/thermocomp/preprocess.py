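"""Protein-fragment extraction from translated transcripts and redundancy
reduction.

Transcript translations arrive as frames over the amino-acid alphabet plus
``'*'`` stop markers. Each frame is trimmed to its longest stop-free
fragment; a fragment downstream of a stop codon is scanned to the first
methionine (that becomes the protein start), and fragments shorter than a
minimum length (default 60 residues) are discarded. Proteomes are then
reduced with a deterministic greedy identity clustering (default 98%
identity, arbitrary length difference).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

from Bio.Align import PairwiseAligner
from Bio.Seq import Seq

from .errors import EmptyInputError, ParameterError, ValidationError
from .io_formats import NUCLEOTIDE_ALPHABET, ProteinRecord


@dataclass
class TranslatedFrame:
    """One reading-frame translation of a transcript."""

    source_id: str
    frame_seq: str

    def __post_init__(self) -> None:
        if not self.frame_seq:
            raise EmptyInputError(f"frame of {self.source_id!r} is empty")


def six_frame_translate(nt: str, source_id: str = "") -> list[TranslatedFrame]:
    """Translate all six reading frames with the standard genetic code.

    Incomplete trailing codons are dropped; reverse frames translate the
    reverse complement.
    """
    seq = nt.upper()
    if len(seq) < 3:
        raise ParameterError("nucleotide sequence shorter than one codon")
    for pos, ch in enumerate(seq, start=1):
        if ch not in NUCLEOTIDE_ALPHABET:
            raise ValidationError(f"illegal nucleotide {ch!r} at position {pos}")
    frames: list[TranslatedFrame] = []
    fwd = Seq(seq)
    rev = fwd.reverse_complement()
    for strand_label, strand in (("+", fwd), ("-", rev)):
        for offset in range(3):
            sub = strand[offset : len(strand) - (len(strand) - offset) % 3]
            if len(sub) < 3:
                continue
            frames.append(
                TranslatedFrame(
                    source_id=f"{source_id}|{strand_label}{offset + 1}",
                    frame_seq=str(sub.translate()),
                )
            )
    return frames


def extract_protein_fragment(
    frame: TranslatedFrame,
    min_len: int = 60,
    species: str = "",
    met_scan_before_selection: bool = False,
) -> ProteinRecord | None:
    """Trim a translated frame to its longest stop-free protein fragment.

    The frame is split on ``'*'`` and the longest fragment chosen (leftmost
    on ties). If the chosen fragment follows a stop codon, its start is
    advanced to the first methionine; a post-stop fragment with no
    methionine is discarded. Fragments shorter than ``min_len`` are
    discarded (returns ``None``).

    ``met_scan_before_selection=True`` applies the methionine rule to every
    post-stop fragment *before* picking the longest, the alternative reading
    of the trimming procedure.
    """
    seq = frame.frame_seq
    pieces = seq.split("*")
    candidates: list[str] = []
    for i, piece in enumerate(pieces):
        if met_scan_before_selection and i > 0:
            m = piece.find("M")
            piece = "" if m < 0 else piece[m:]
        candidates.append(piece)
    if not any(candidates):
        return None
    best_i = max(range(len(candidates)), key=lambda i: len(candidates[i]))
    fragment = candidates[best_i]
    if not met_scan_before_selection and best_i > 0:
        m = fragment.find("M")
        if m < 0:
            return None
        fragment = fragment[m:]
    if len(fragment) < min_len:
        return None
    return ProteinRecord(id=frame.source_id, species=species, residues=fragment)


def _identity_aligner() -> PairwiseAligner:
    # Only the identity fraction is consumed, so a minimal scoring scheme
    # (match +1, mismatch 0, linear gap -1) suffices; ties resolve toward
    # fewer gaps because gaps cost while mismatches are free.
    aligner = PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = 1.0
    aligner.mismatch_score = 0.0
    aligner.open_gap_score = -1.0
    aligner.extend_gap_score = -1.0
    return aligner


def pairwise_identity(a: str, b: str, aligner: PairwiseAligner | None = None) -> float:
    """Global-alignment identity: exact matches / aligned columns."""
    if aligner is None:
        aligner = _identity_aligner()
    aln = aligner.align(a, b)[0]
    counts = aln.counts()
    columns = counts.identities + counts.mismatches + counts.gaps
    return counts.identities / columns if columns else 0.0


def cluster_by_identity(
    records: Sequence[ProteinRecord], threshold: float = 0.98
) -> list[ProteinRecord]:
    """Greedy redundancy reduction of one species' proteome.

    Records are processed longest-first (ties by id); each record joins the
    first earlier representative it matches at >= ``threshold`` global
    identity, otherwise it becomes a new representative. Deterministic and
    idempotent.
    """
    if not (0.0 < threshold <= 1.0):
        raise ParameterError(f"identity threshold must be in (0, 1], got {threshold}")
    aligner = _identity_aligner()
    ordered = sorted(records, key=lambda r: (-len(r.residues), r.id))
    reps: list[ProteinRecord] = []
    for rec in ordered:
        placed = False
        for rep in reps:
            # identity <= shorter/longer: skip alignments that cannot reach
            # the threshold.
            lo, hi = sorted((len(rec.residues), len(rep.residues)))
            if lo / hi < threshold:
                continue
            if pairwise_identity(rec.residues, rep.residues, aligner) >= threshold:
                placed = True
                break
        if not placed:
            reps.append(rec)
    return reps
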