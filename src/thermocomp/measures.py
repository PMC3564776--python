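"""Sequence-composition thermostability measures and codon GC statistics.

The central quantity is the charged-versus-polar bias

    CvP = 100 * (N_charged - N_polar) / L

with charged = {E, D, K, R} and polar = {S, T, N, Q}; higher values are
associated with thermostable proteomes. Companion measures: the IVYWREL
content (fraction of I, V, Y, W, R, E, L), the (E+K)/(Q+H) count ratio,
serine content, charged content, mean hydrophobicity on a named scale, and
GARP versus FYMINK content (residues encoded by GC-rich versus AT-rich
codons, used to diagnose GC-content confounding).

Ambiguity letters (B, Z, X, U, O) and stop markers are excluded from both
numerators and denominators: ``L`` above is the *effective* length, so all
percentage measures stay comparable across records.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import (
    ConfigurationError,
    FrameError,
    ParameterError,
    UndefinedCompositionError,
)
from .io_formats import STANDARD_AA, ProteinRecord, ScoreTable

CHARGED = frozenset("EDKR")
POLAR = frozenset("STNQ")
IVYWREL_SET = frozenset("IVYWREL")
GARP_SET = frozenset("GARP")
FYMINK_SET = frozenset("FYMINK")

#: Kyte-Doolittle hydropathy values (positive = hydrophobic).
KYTE_DOOLITTLE = {
    "A": 1.8, "R": -4.5, "N": -3.5, "D": -3.5, "C": 2.5,
    "Q": -3.5, "E": -3.5, "G": -0.4, "H": -3.2, "I": 4.5,
    "L": 3.8, "K": -3.9, "M": 1.9, "F": 2.8, "P": -1.6,
    "S": -0.8, "T": -0.7, "W": -0.9, "Y": -1.3, "V": 4.2,
}

HYDROPHOBICITY_SCALES: dict[str, Mapping[str, float]] = {
    "kyte-doolittle": KYTE_DOOLITTLE,
}


def _effective_residues(seq: str | ProteinRecord) -> str:
    """Residues that enter composition statistics (standard 20 only)."""
    residues = seq.residues if isinstance(seq, ProteinRecord) else seq
    kept = [c for c in residues.upper() if c in STANDARD_AA]
    if not kept:
        raise UndefinedCompositionError(
            "sequence has no unambiguous standard residues; composition undefined"
        )
    return "".join(kept)


def effective_length(seq: str | ProteinRecord) -> int:
    return len(_effective_residues(seq))


def aa_frequencies(seq: str | ProteinRecord) -> dict[str, float]:
    """Percent content of each of the 20 standard residues (sums to 100)."""
    eff = _effective_residues(seq)
    n = len(eff)
    return {aa: 100.0 * eff.count(aa) / n for aa in STANDARD_AA}


def _set_percent(seq: str | ProteinRecord, residue_set: frozenset) -> float:
    eff = _effective_residues(seq)
    return 100.0 * sum(1 for c in eff if c in residue_set) / len(eff)


def cvp_bias(seq: str | ProteinRecord) -> float:
    """Charged-versus-polar bias: 100 * (N_EDKR - N_STNQ) / effective length."""
    eff = _effective_residues(seq)
    c = sum(1 for ch in eff if ch in CHARGED)
    p = sum(1 for ch in eff if ch in POLAR)
    return 100.0 * (c - p) / len(eff)


def ivywrel(seq: str | ProteinRecord) -> float:
    """Percent content of the thermophile-enriched residue set I,V,Y,W,R,E,L."""
    return _set_percent(seq, IVYWREL_SET)


def ek_qh_ratio(seq: str | ProteinRecord) -> float | None:
    """(E+K)/(Q+H) count ratio; ``None`` when the denominator is zero.

    The undefined value is carried as missing in rankings, never as infinity.
    """
    eff = _effective_residues(seq)
    num = eff.count("E") + eff.count("K")
    den = eff.count("Q") + eff.count("H")
    if den == 0:
        return None
    return num / den


def serine_content(seq: str | ProteinRecord) -> float:
    """Percent serine; low values weakly mark thermoadapted proteomes."""
    return _set_percent(seq, frozenset("S"))


def charged_content(seq: str | ProteinRecord) -> float:
    """Percent of charged residues D, E, K, R."""
    return _set_percent(seq, CHARGED)


def polar_content(seq: str | ProteinRecord) -> float:
    """Percent of polar residues S, T, N, Q."""
    return _set_percent(seq, POLAR)


def mean_hydrophobicity(seq: str | ProteinRecord, scale: str = "kyte-doolittle") -> float:
    """Mean per-residue hydrophobicity on a named scale (default Kyte-Doolittle)."""
    try:
        table = HYDROPHOBICITY_SCALES[scale]
    except KeyError:
        raise ParameterError(
            f"unknown hydrophobicity scale {scale!r}; "
            f"known: {sorted(HYDROPHOBICITY_SCALES)}"
        ) from None
    eff = _effective_residues(seq)
    return float(np.mean([table[c] for c in eff]))


def garp_fymink(seq: str | ProteinRecord) -> tuple[float, float]:
    """Percent content of GC-rich-codon residues (GARP) and AT-rich-codon
    residues (FYMINK)."""
    return _set_percent(seq, GARP_SET), _set_percent(seq, FYMINK_SET)


@dataclass
class CodonStats:
    """GC content (%) by codon position over the complete, unambiguous codons."""

    gc1: float
    gc2: float
    gc3: float
    gc_total: float
    n_codons: int


def gc_by_codon_position(coding_seq: str) -> CodonStats:
    """Positional GC content of an in-frame coding sequence.

    Codons containing ``N`` are excluded entirely; a length not divisible by
    three is a frame error.
    """
    seq = coding_seq.upper()
    if len(seq) % 3 != 0:
        raise FrameError(f"coding sequence length {len(seq)} not divisible by 3")
    counts = [0, 0, 0]
    n_codons = 0
    for i in range(0, len(seq), 3):
        codon = seq[i : i + 3]
        if "N" in codon:
            continue
        n_codons += 1
        for k in range(3):
            if codon[k] in "GC":
                counts[k] += 1
    if n_codons == 0:
        raise UndefinedCompositionError("no complete unambiguous codons")
    gc = [100.0 * c / n_codons for c in counts]
    return CodonStats(
        gc1=gc[0],
        gc2=gc[1],
        gc3=gc[2],
        gc_total=100.0 * sum(counts) / (3 * n_codons),
        n_codons=n_codons,
    )


@dataclass(frozen=True)
class Measure:
    """A registered per-protein measure with its thermophilic direction."""

    name: str
    func: Callable[[ProteinRecord], float | None]
    direction: int  # +1: larger is more thermostable; -1: smaller is

    def __post_init__(self) -> None:
        if self.direction not in (1, -1):
            raise ParameterError(f"measure {self.name!r}: direction must be +1 or -1")


def default_registry(hydrophobicity_scale: str = "kyte-doolittle") -> list[Measure]:
    """The built-in measure registry with field-standard orientations.

    CvP, IVYWREL, (E+K)/(Q+H), charged content and hydrophobicity point up
    (larger = more thermostable-looking); serine content and sequence length
    (compactness / shorter surface loops) point down.
    """
    return [
        Measure("cvp_bias", cvp_bias, +1),
        Measure("ivywrel", ivywrel, +1),
        Measure("ek_qh_ratio", ek_qh_ratio, +1),
        Measure("serine_content", serine_content, -1),
        Measure("charged_content", charged_content, +1),
        Measure(
            "hydrophobicity",
            lambda s: mean_hydrophobicity(s, hydrophobicity_scale),
            +1,
        ),
        Measure("length", lambda s: float(effective_length(s)), -1),
    ]


@dataclass
class MeasureTable:
    """Per-protein values for named measures plus each measure's direction."""

    values: pd.DataFrame  # index protein_id, one column per measure
    directions: dict[str, int]
    species: dict[str, str] = field(default_factory=dict)
    effective_lengths: dict[str, int] = field(default_factory=dict)

    def measure_names(self) -> list[str]:
        return list(self.values.columns)


def evaluate_measures(
    records: Sequence[ProteinRecord],
    registry: Sequence[Measure] | None = None,
    external: Iterable[ScoreTable] = (),
) -> MeasureTable:
    """Evaluate all built-in and external measures over a set of records.

    External score tables (e.g. disorder predictions or trained
    thermostability rankers computed elsewhere) are merged by protein id;
    proteins they do not score get missing values. An external measure whose
    name collides with a built-in is a configuration error.
    """
    if registry is None:
        registry = default_registry()
    builtin_names = {m.name for m in registry}
    directions = {m.name: m.direction for m in registry}
    rows: dict[str, dict[str, float]] = {}
    species: dict[str, str] = {}
    lengths: dict[str, int] = {}
    for rec in records:
        if rec.id in rows:
            raise ConfigurationError(f"duplicate protein id {rec.id!r}")
        row = {}
        for m in registry:
            v = m.func(rec)
            row[m.name] = np.nan if v is None else float(v)
        rows[rec.id] = row
        species[rec.id] = rec.species
        lengths[rec.id] = effective_length(rec)
    df = pd.DataFrame.from_dict(rows, orient="index")
    df = df.reindex([r.id for r in records])
    for table in external:
        if table.measure_name in builtin_names:
            raise ConfigurationError(
                f"external measure {table.measure_name!r} collides with a built-in"
            )
        unknown = set(table.scores) - set(df.index)
        if unknown:
            raise ConfigurationError(
                f"external measure {table.measure_name!r} scores unknown ids: "
                f"{sorted(unknown)[:3]}"
            )
        df[table.measure_name] = pd.Series(table.scores, dtype=float).reindex(df.index)
        directions[table.measure_name] = table.direction
    return MeasureTable(
        values=df, directions=directions, species=species, effective_lengths=lengths
    )
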