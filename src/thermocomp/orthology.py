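"""Reciprocal-best-hit ortholog detection across many species, and trimming
of ortholog alignments to their shared gap-free core.

An orthologous set is one protein per species such that, for every ordered
species pair (A, B), the best cross-species hit of the member from A in
species B is exactly the member from B — best-hit consistency over all
S*(S-1) directed relations. Alignments of each set (built externally) are
trimmed from both ends to the first and last columns free of gaps in every
row, so every species is represented by the same homologous fragment.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from .errors import ParameterError, UntrimmableAlignmentError
from .io_formats import HitRecord, ProteinRecord

GAP = "-"


@dataclass
class OrthologSet:
    """One protein per species, optionally with aligned and trimmed rows."""

    members: dict[str, str]  # species -> protein id
    records: dict[str, ProteinRecord] = field(default_factory=dict)
    aligned_rows: dict[str, str] | None = None
    trimmed_fragments: dict[str, str] | None = None
    trim_span: tuple[int, int] | None = None  # 1-based inclusive columns

    @property
    def seed_id(self) -> str:
        return min(self.members.values())


BestHitMap = dict[tuple[str, str], str]  # (query_id, target_species) -> subject_id


def best_hits(hits: Iterable[HitRecord]) -> BestHitMap:
    """Reduce a hit list to the best subject per (query, target species).

    Best = maximal bitscore; ties broken by lower e-value, then by
    lexicographically smallest subject id, so the result is deterministic.
    Same-species hits are ignored.
    """
    best: dict[tuple[str, str], HitRecord] = {}
    for h in hits:
        if h.query_species == h.subject_species:
            continue
        key = (h.query_id, h.subject_species)
        cur = best.get(key)
        if cur is None or _hit_rank(h) < _hit_rank(cur):
            best[key] = h
    return {key: h.subject_id for key, h in best.items()}


def _hit_rank(h: HitRecord) -> tuple[float, float, str]:
    return (-h.bitscore, h.evalue, h.subject_id)


def build_ortholog_sets(
    best: BestHitMap,
    species: Sequence[str],
    id_to_species: Mapping[str, str],
) -> list[OrthologSet]:
    """Assemble fully consistent best-hit cliques, one protein per species.

    Construction seeds from every protein of the first species in ``species``
    order: the candidate members are that protein's best hits in each other
    species, and the candidate is emitted only if *every* directed best hit
    between members stays inside the set. Output is sorted by seed protein
    id; each protein appears in at most one set.
    """
    if len(set(species)) != len(species):
        raise ParameterError("species list contains duplicates")
    if len(species) < 2:
        raise ParameterError("need at least two species")
    seed_species = species[0]
    seeds = sorted(
        {qid for (qid, _t) in best if id_to_species.get(qid) == seed_species}
    )
    sets: list[OrthologSet] = []
    used: set[str] = set()
    for seed in seeds:
        members = {seed_species: seed}
        ok = True
        for sp in species[1:]:
            subj = best.get((seed, sp))
            if subj is None:
                ok = False
                break
            members[sp] = subj
        if not ok:
            continue
        if not _consistent(members, species, best):
            continue
        if any(pid in used for pid in members.values()):
            continue
        used.update(members.values())
        sets.append(OrthologSet(members=members))
    sets.sort(key=lambda s: s.members[seed_species])
    return sets


def _consistent(members: Mapping[str, str], species: Sequence[str], best: BestHitMap) -> bool:
    for a in species:
        for b in species:
            if a == b:
                continue
            if best.get((members[a], b)) != members[b]:
                return False
    return True


def mutual_best_pairs(best: BestHitMap, id_to_species: Mapping[str, str]) -> set[frozenset]:
    """Laxer two-species view: unordered pairs that are each other's best hit."""
    pairs: set[frozenset] = set()
    for (qid, _tsp), sid in best.items():
        if best.get((sid, id_to_species[qid])) == qid:
            pairs.add(frozenset((qid, sid)))
    return pairs


def trim_alignment(
    aligned_rows: Mapping[str, str] | Sequence[tuple[str, str]],
) -> tuple[tuple[int, int], dict[str, str]]:
    """Trim an alignment from both ends to the first/last all-gap-free column.

    Returns the 1-based inclusive column span and, per row, the fragment over
    that span with remaining interior gaps removed (fragment lengths may
    therefore differ between rows).
    """
    rows = dict(aligned_rows)
    if len(rows) < 2:
        raise ParameterError("alignment needs at least two rows")
    widths = {len(r) for r in rows.values()}
    if len(widths) != 1:
        raise ParameterError("alignment rows have unequal lengths")
    width = widths.pop()
    gap_free = [all(row[c] != GAP for row in rows.values()) for c in range(width)]
    if not any(gap_free):
        raise UntrimmableAlignmentError("no column is gap-free in every row")
    first = gap_free.index(True)
    last = width - 1 - gap_free[::-1].index(True)
    fragments = {
        rid: row[first : last + 1].replace(GAP, "") for rid, row in rows.items()
    }
    return (first + 1, last + 1), fragments
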