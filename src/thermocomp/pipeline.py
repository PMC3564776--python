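"""End-to-end survey orchestration from a single run configuration.

Stages, in order: read per-species proteomes, optional redundancy clustering,
best-hit reduction of the all-vs-all hit table, reciprocal-best-hit ortholog
set construction, alignment trimming, measure evaluation on the trimmed
fragments, cumulative species ranking, and (when a phenotype table is given)
proteome-mean versus body-temperature correlations. Outputs are plain TSV and
JSON; reruns on identical inputs are byte-identical.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

from . import correlate, io_formats, orthology, preprocess, survey
from .errors import ThermocompError, UntrimmableAlignmentError
from .measures import MeasureTable, default_registry, evaluate_measures


class StageError(ThermocompError):
    """A pipeline stage failed; carries the stage name and offending input."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


@dataclass
class RunConfig:
    """Configuration of one survey run.

    ``species`` maps species labels to protein FASTA paths; ``hits`` is the
    12-column all-vs-all hit table; ``alignments`` a directory of aligned
    FASTA files, one per ortholog set. Defaults mirror the survey's standard
    parameters: 60-residue minimum fragment length and 98% identity
    clustering.
    """

    species: dict[str, str]
    hits: str
    alignments: str
    out_dir: str
    phenotype: str | None = None
    external_scores: list[dict] = field(default_factory=list)
    min_len: int = 60
    cluster_id: float = 0.98
    cluster: bool = False
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh)
        return cls(**raw)

    def validate(self) -> None:
        for sp, p in self.species.items():
            if not Path(p).exists():
                raise StageError("config", f"species {sp!r}: missing file {p}")
        for p in [self.hits, self.alignments] + [e["path"] for e in self.external_scores]:
            if not Path(p).exists():
                raise StageError("config", f"missing path {p}")
        if self.phenotype and not Path(self.phenotype).exists():
            raise StageError("config", f"missing phenotype table {self.phenotype}")


def run_survey(config: RunConfig) -> dict:
    """Execute the full survey and write per-stage tables plus a JSON summary.

    Returns the summary dictionary (also written to ``summary.json``).
    """
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    log: list[str] = [f"seed={config.seed}", f"min_len={config.min_len}",
                      f"cluster_id={config.cluster_id}", f"cluster={config.cluster}"]

    # Stage 1: proteomes
    proteomes: dict[str, list[io_formats.ProteinRecord]] = {}
    for sp in sorted(config.species):
        try:
            proteomes[sp] = io_formats.read_fasta(config.species[sp], species=sp)
        except ThermocompError as exc:
            raise StageError("proteomes", f"species {sp!r}: {exc}") from exc
        log.append(f"proteome {sp}: {len(proteomes[sp])} records")

    # Stage 2: optional redundancy clustering
    if config.cluster:
        for sp in sorted(proteomes):
            before = len(proteomes[sp])
            proteomes[sp] = preprocess.cluster_by_identity(
                proteomes[sp], threshold=config.cluster_id
            )
            log.append(f"cluster {sp}: {before} -> {len(proteomes[sp])}")

    id_to_species = {r.id: r.species for recs in proteomes.values() for r in recs}
    record_by_id = {r.id: r for recs in proteomes.values() for r in recs}

    # Stage 3-4: orthology
    try:
        hits = io_formats.read_hit_table(config.hits, id_to_species)
        best = orthology.best_hits(hits)
        species_order = sorted(proteomes)
        sets = orthology.build_ortholog_sets(best, species_order, id_to_species)
    except ThermocompError as exc:
        raise StageError("orthology", str(exc)) from exc
    log.append(f"orthology: {len(sets)} sets from {len(hits)} hits")

    # Stage 5: alignment trimming
    aln_by_ids: dict[frozenset, dict[str, str]] = {}
    for aln_path in sorted(Path(config.alignments).iterdir()):
        if aln_path.suffix not in (".afa", ".fasta", ".fa", ".aln"):
            continue
        rows = io_formats.read_aligned_fasta(aln_path)
        aln_by_ids[frozenset(rid for rid, _ in rows)] = dict(rows)
    n_untrimmable = 0
    usable_sets: list[orthology.OrthologSet] = []
    for s in sets:
        ids = frozenset(s.members.values())
        aln = aln_by_ids.get(ids)
        if aln is None:
            log.append(f"trim: no alignment for set seeded by {s.seed_id}; skipped")
            continue
        try:
            span, fragments = orthology.trim_alignment(aln)
        except UntrimmableAlignmentError:
            n_untrimmable += 1
            log.append(f"trim: set seeded by {s.seed_id} untrimmable; excluded")
            continue
        s.aligned_rows = aln
        s.trim_span = span
        s.trimmed_fragments = fragments
        usable_sets.append(s)
    log.append(f"trim: {len(usable_sets)} usable sets, {n_untrimmable} untrimmable")

    # Stage 6: measures on trimmed fragments
    external = [
        io_formats.read_score_table(
            e["path"], direction=e.get("direction", 1), measure_name=e.get("name")
        )
        for e in config.external_scores
    ]
    registry = default_registry()
    set_tables: list[MeasureTable] = []
    for s in usable_sets:
        members = []
        for sp, pid in sorted(s.members.items()):
            fragment = s.trimmed_fragments[pid]
            members.append(
                io_formats.ProteinRecord(id=pid, species=sp, residues=fragment)
            )
        ext_subset = [
            io_formats.ScoreTable(
                measure_name=t.measure_name,
                scores={pid: v for pid, v in t.scores.items() if pid in s.members.values()},
                direction=t.direction,
            )
            for t in external
        ]
        set_tables.append(evaluate_measures(members, registry, ext_subset))

    # Stage 7: cumulative ranking
    summaries = survey.cumulative_ranks(set_tables) if set_tables else []
    ranks_path = out / "cumulative_ranks.tsv"
    species_order = sorted(proteomes)
    with open(ranks_path, "w") as fh:
        fh.write("measure\tn_sets_used\t" + "\t".join(species_order) + "\n")
        for summ in summaries:
            row = [summ.measure_name, str(summ.n_sets_used)]
            row += [f"{summ.cumulative_rank.get(sp, float('nan')):g}" for sp in species_order]
            fh.write("\t".join(row) + "\n")

    # Stage 8: optional phenotype correlation on whole-proteome means
    correlations = {}
    if config.phenotype:
        phen = io_formats.read_phenotype_table(config.phenotype)
        whole = {
            sp: evaluate_measures(recs, registry) for sp, recs in proteomes.items()
        }
        for m in registry:
            try:
                res = correlate.proteome_mean_vs_phenotype(whole, phen, m.name)
            except ThermocompError as exc:
                log.append(f"correlate {m.name}: {exc}")
                continue
            correlations[m.name] = {"r": res.r, "p_value": res.p_value, "n": res.n}

    summary = {
        "n_species": len(proteomes),
        "species": species_order,
        "n_sets": len(sets),
        "n_usable_sets": len(usable_sets),
        "n_untrimmable": n_untrimmable,
        "cumulative_ranks": {
            s.measure_name: {
                "n_sets_used": s.n_sets_used,
                "ranks": {sp: s.cumulative_rank.get(sp) for sp in species_order},
            }
            for s in summaries
        },
        "correlations": correlations,
        "seed": config.seed,
    }
    with open(out / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
        fh.write("\n")
    with open(out / "run.log", "w") as fh:
        fh.write("\n".join(log) + "\n")
    return summary
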