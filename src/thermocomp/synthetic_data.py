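"""Synthetic inputs with the statistical structure the survey assumes.

Every pipeline stage can be exercised without external downloads:

* **Ortholog sets.** Each set derives from one ancestral sequence; species
  copies are produced by comonotone inverse-CDF sampling — every position
  carries one shared uniform variate, and each species maps it through its
  own residue distribution. Species with identical profiles therefore get
  identical residues, while a profile shift changes exactly the boundary
  positions, so within-set similarity stays high and each species' marginal
  composition is *exactly* its profile.

* **Thermophilic composition shift.** A fraction ``delta`` of probability
  mass is moved from the polar residues {S, T, N, Q} to the charged residues
  {E, D, K, R}. Charged content rises by ``delta`` and polar content falls by
  ``delta``, so the expected CvP-bias of a shifted species exceeds the
  unshifted baseline by exactly ``200 * delta`` percentage points — a
  closed-form oracle for the ranking and ROC stages.

* **Coding sequences** reverse-translate proteins with a Bernoulli
  preference for G/C third codon positions, planting a known GC3.

* **Melt curves** evaluate the Boltzmann sigmoid on the standard 20-80 C,
  0.2 C plate grid, plus seeded Gaussian noise.

All generators are pure functions of their seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from Bio.Data.CodonTable import standard_dna_table
from Bio.Seq import Seq

from .errors import ParameterError, ValidationError
from .io_formats import STANDARD_AA, HitRecord, ProteinRecord
from .meltcurve import MeltCurve, boltzmann_model

AA_ORDER = STANDARD_AA  # "ACDEFGHIKLMNPQRSTVWY"
_AA_INDEX = {aa: i for i, aa in enumerate(AA_ORDER)}
_CHARGED_IDX = [_AA_INDEX[a] for a in "EDKR"]
_POLAR_IDX = [_AA_INDEX[a] for a in "STNQ"]

#: Average residue frequencies of well-curated protein databases, used as the
#: mesophilic baseline composition (normalized to 1).
BASE_RESIDUE_FREQS = np.array(
    [
        0.0825, 0.0138, 0.0546, 0.0672, 0.0386, 0.0707, 0.0227, 0.0591,
        0.0580, 0.0965, 0.0241, 0.0406, 0.0474, 0.0393, 0.0553, 0.0663,
        0.0535, 0.0686, 0.0110, 0.0292,
    ]
)
BASE_RESIDUE_FREQS = BASE_RESIDUE_FREQS / BASE_RESIDUE_FREQS.sum()


@dataclass
class SpeciesProfile:
    """Residue composition of one synthetic species.

    ``thermo_shift`` is the probability mass moved from polar {S,T,N,Q} to
    charged {E,D,K,R}; the expected CvP-bias gain over the unshifted profile
    is ``200 * thermo_shift`` percentage points.
    """

    species: str
    residue_probs: np.ndarray = field(
        default_factory=lambda: BASE_RESIDUE_FREQS.copy()
    )
    thermo_shift: float = 0.0
    gc3_target: float = 0.5

    def __post_init__(self) -> None:
        self.residue_probs = np.asarray(self.residue_probs, dtype=float)
        if self.residue_probs.shape != (20,):
            raise ParameterError("residue_probs must have 20 entries")
        if abs(self.residue_probs.sum() - 1.0) > 1e-12:
            raise ParameterError("residue_probs must sum to 1")
        if np.any(self.residue_probs < 0):
            raise ParameterError("residue_probs must be non-negative")
        if not (0.0 <= self.thermo_shift <= 0.2):
            raise ParameterError("thermo_shift must lie in [0, 0.2]")
        if not (0.0 <= self.gc3_target <= 1.0):
            raise ParameterError("gc3_target must lie in [0, 1]")
        polar_mass = self.residue_probs[_POLAR_IDX].sum()
        if self.thermo_shift > polar_mass:
            raise ParameterError("thermo_shift exceeds available polar mass")

    def shifted_probs(self) -> np.ndarray:
        """The profile after the polar-to-charged mass transfer."""
        p = self.residue_probs.copy()
        d = self.thermo_shift
        if d > 0:
            polar = p[_POLAR_IDX].sum()
            charged = p[_CHARGED_IDX].sum()
            p[_POLAR_IDX] *= (polar - d) / polar
            p[_CHARGED_IDX] *= (charged + d) / charged
        return p

    def cdf(self) -> np.ndarray:
        return np.cumsum(self.shifted_probs())


_GARP_IDX = [_AA_INDEX[a] for a in "GARP"]
_FYMINK_IDX = [_AA_INDEX[a] for a in "FYMINK"]


def make_profiles(
    species: list[str],
    thermo_shifts: dict[str, float] | None = None,
    gc3_targets: dict[str, float] | None = None,
    jitter: float = 0.02,
    gc_coupling: float = 0.0,
    seed: int = 0,
) -> list[SpeciesProfile]:
    """Build per-species profiles around the mesophilic baseline.

    ``jitter`` applies a small seeded log-normal perturbation per species so
    mesophiles are similar but not identical, mimicking neutral composition
    drift between real proteomes. ``gc_coupling`` > 0 tilts composition with
    the species' GC3 target — GC-rich genomes gain residues from GC-rich
    codons (G, A, R, P) and lose residues from AT-rich codons (F, Y, M, I,
    N, K) — emulating the strong GC/composition dependence seen in real
    proteomes.
    """
    rng = np.random.default_rng(seed)
    thermo_shifts = thermo_shifts or {}
    gc3_targets = gc3_targets or {}
    profiles = []
    for sp in species:
        p = BASE_RESIDUE_FREQS.copy()
        if jitter > 0:
            p = p * np.exp(jitter * rng.standard_normal(20))
            p = p / p.sum()
        gc3 = gc3_targets.get(sp, 0.5)
        if gc_coupling > 0:
            charged0 = p[_CHARGED_IDX].sum()
            polar0 = p[_POLAR_IDX].sum()
            tilt = gc_coupling * 2.0 * (gc3 - 0.5)
            p[_GARP_IDX] *= 1.0 + tilt
            p[_FYMINK_IDX] *= max(1.0 - tilt, 0.05)
            # restore the charged and polar masses so the GC tilt is
            # CvP-neutral, then rebalance the remaining residues to sum to 1
            p[_CHARGED_IDX] *= charged0 / p[_CHARGED_IDX].sum()
            p[_POLAR_IDX] *= polar0 / p[_POLAR_IDX].sum()
            rest = [i for i in range(20) if i not in _CHARGED_IDX + _POLAR_IDX]
            p[rest] *= (1.0 - charged0 - polar0) / p[rest].sum()
        profiles.append(
            SpeciesProfile(
                species=sp,
                residue_probs=p,
                thermo_shift=thermo_shifts.get(sp, 0.0),
                gc3_target=gc3,
            )
        )
    return profiles


def _sample_from_cdf(cdf: np.ndarray, u: np.ndarray) -> np.ndarray:
    return np.searchsorted(cdf, u, side="right").clip(0, 19)


def _indices_to_seq(idx: np.ndarray) -> str:
    return "".join(AA_ORDER[i] for i in idx)


@dataclass
class SyntheticOrthologData:
    """Everything :func:`gen_ortholog_sets` plants: proteomes, the true
    alignments, the hit table, and id bookkeeping."""

    proteomes: dict[str, list[ProteinRecord]]
    alignments: list[dict[str, str]]  # per set: species -> gapped row
    hits: list[HitRecord]
    id_to_species: dict[str, str]
    set_ids: list[list[str]]  # per set: member protein ids


def gen_ortholog_sets(
    profiles: list[SpeciesProfile],
    n_sets: int = 100,
    len_range: tuple[int, int] = (100, 300),
    indel_rate: float = 0.0,
    n_decoys: int = 2,
    seed: int = 0,
) -> SyntheticOrthologData:
    """Generate orthologous sets with planted best-hit structure.

    Bitscores in the emitted hit table are pairwise identities scaled by 100
    (an identity proxy, not an alignment score); with a small ``indel_rate``
    the planted partners dominate the ``n_decoys`` random cross-set hits, so
    reciprocal-best-hit construction recovers the planted sets exactly.
    """
    if len(profiles) < 2:
        raise ParameterError("need at least two species profiles")
    if n_sets < 1:
        raise ParameterError("n_sets must be >= 1")
    if not (0.0 <= indel_rate < 1.0):
        raise ParameterError("indel_rate must lie in [0, 1)")
    rng = np.random.default_rng(seed)
    species = [p.species for p in profiles]
    cdfs = {p.species: p.cdf() for p in profiles}
    pmfs = {p.species: p.shifted_probs() for p in profiles}

    proteomes: dict[str, list[ProteinRecord]] = {sp: [] for sp in species}
    alignments: list[dict[str, str]] = []
    set_ids: list[list[str]] = []
    id_to_species: dict[str, str] = {}
    # per set and species: residue indices on ancestor coordinates (-1 = deleted)
    ancestor_rows: list[dict[str, np.ndarray]] = []

    for i in range(n_sets):
        length = int(rng.integers(len_range[0], len_range[1] + 1))
        u = rng.random(length)
        rows: dict[str, np.ndarray] = {}
        inserts: dict[str, list[list[int]]] = {}
        for sp in species:
            idx = _sample_from_cdf(cdfs[sp], u)
            if indel_rate > 0:
                deleted = rng.random(length) < indel_rate / 2.0
                idx = np.where(deleted, -1, idx)
                ins: list[list[int]] = []
                for _ in range(length):
                    if rng.random() < indel_rate / 2.0:
                        ins.append([int(rng.choice(20, p=pmfs[sp]))])
                    else:
                        ins.append([])
            else:
                ins = [[] for _ in range(length)]
            rows[sp] = idx
            inserts[sp] = ins
        # assemble gapped alignment: one column per ancestor position, plus
        # one column per inserted residue (species order after each position)
        aln: dict[str, list[str]] = {sp: [] for sp in species}
        for j in range(length):
            for sp in species:
                aln[sp].append("-" if rows[sp][j] < 0 else AA_ORDER[rows[sp][j]])
            for owner in species:
                for res_idx in inserts[owner][j]:
                    for sp in species:
                        aln[sp].append(AA_ORDER[res_idx] if sp == owner else "-")
        members = []
        aln_rows = {}
        for sp in species:
            row = "".join(aln[sp])
            seq = row.replace("-", "")
            pid = f"{sp}|set{i:04d}"
            proteomes[sp].append(ProteinRecord(id=pid, species=sp, residues=seq))
            id_to_species[pid] = sp
            members.append(pid)
            aln_rows[sp] = row
        alignments.append(aln_rows)
        set_ids.append(members)
        ancestor_rows.append(rows)

    hits = _build_hit_table(species, ancestor_rows, n_decoys, rng)
    return SyntheticOrthologData(
        proteomes=proteomes,
        alignments=alignments,
        hits=hits,
        id_to_species=id_to_species,
        set_ids=set_ids,
    )


def _ancestor_identity(a: np.ndarray, b: np.ndarray) -> float:
    """Fraction of ancestor positions both species retain and match on."""
    n = min(a.size, b.size)
    a, b = a[:n], b[:n]
    both = (a >= 0) & (b >= 0)
    if not both.any():
        return 0.0
    return float(np.mean(a[both] == b[both]))


def _build_hit_table(
    species: list[str],
    ancestor_rows: list[dict[str, np.ndarray]],
    n_decoys: int,
    rng: np.random.Generator,
) -> list[HitRecord]:
    n_sets = len(ancestor_rows)
    hits: list[HitRecord] = []

    def add(qsp: str, qi: int, ssp: str, si: int) -> None:
        ident = _ancestor_identity(ancestor_rows[qi][qsp], ancestor_rows[si][ssp])
        bitscore = round(100.0 * ident, 4)
        hits.append(
            HitRecord(
                query_id=f"{qsp}|set{qi:04d}",
                subject_id=f"{ssp}|set{si:04d}",
                query_species=qsp,
                subject_species=ssp,
                bitscore=bitscore,
                evalue=10.0 ** (-bitscore / 10.0),
            )
        )

    for qsp in species:
        for ssp in species:
            if qsp == ssp:
                continue
            for i in range(n_sets):
                add(qsp, i, ssp, i)
                if n_sets > 1 and n_decoys > 0:
                    others = [j for j in range(n_sets) if j != i]
                    k = min(n_decoys, len(others))
                    chosen = rng.choice(len(others), size=k, replace=False)
                    for c in chosen:
                        add(qsp, i, ssp, others[int(c)])
    return hits


def write_ortholog_inputs(data: SyntheticOrthologData, outdir) -> dict:
    """Write generated inputs in the formats the pipeline reads.

    Produces one protein FASTA per species, a 12-column hit table, and one
    aligned FASTA per planted set. Returns the paths, keyed for a run config.
    """
    from pathlib import Path

    from .io_formats import write_aligned_fasta, write_fasta, write_hit_table

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    species_paths = {}
    for sp, records in data.proteomes.items():
        path = outdir / f"{sp}.fasta"
        write_fasta(records, path)
        species_paths[sp] = str(path)
    hits_path = outdir / "hits.tsv"
    write_hit_table(data.hits, hits_path)
    aln_dir = outdir / "alignments"
    aln_dir.mkdir(exist_ok=True)
    for i, aln in enumerate(data.alignments):
        rows = [(f"{sp}|set{i:04d}", row) for sp, row in aln.items()]
        write_aligned_fasta(rows, aln_dir / f"set{i:04d}.afa")
    return {
        "species": species_paths,
        "hits": str(hits_path),
        "alignments": str(aln_dir),
    }


def gen_pair_dataset(
    n_pairs: int,
    delta_thermo: float,
    length: int = 300,
    seed: int = 0,
) -> list[tuple[ProteinRecord, ProteinRecord]]:
    """Homologous thermophile/mesophile sequence pairs.

    Both members of a pair share the positionwise uniforms of a common
    backbone; the thermophilic member samples through the composition-shifted
    profile. Returns ``(thermophile, mesophile)`` record pairs.
    """
    if n_pairs < 1:
        raise ParameterError("n_pairs must be >= 1")
    rng = np.random.default_rng(seed)
    meso = SpeciesProfile(species="mesophile")
    thermo = SpeciesProfile(species="thermophile", thermo_shift=delta_thermo)
    cdf_m, cdf_t = meso.cdf(), thermo.cdf()
    pairs = []
    for i in range(n_pairs):
        u = rng.random(length)
        t_seq = _indices_to_seq(_sample_from_cdf(cdf_t, u))
        m_seq = _indices_to_seq(_sample_from_cdf(cdf_m, u))
        pairs.append(
            (
                ProteinRecord(id=f"thermo{i:04d}", species="thermophile", residues=t_seq),
                ProteinRecord(id=f"meso{i:04d}", species="mesophile", residues=m_seq),
            )
        )
    return pairs


def _codon_choices() -> dict[str, tuple[list[str], list[str]]]:
    """Per residue: (codons with G/C third base, codons with A/T third base)."""
    table = standard_dna_table
    by_aa: dict[str, tuple[list[str], list[str]]] = {}
    for codon, aa in sorted(table.forward_table.items()):
        gc_list, at_list = by_aa.setdefault(aa, ([], []))
        (gc_list if codon[2] in "GC" else at_list).append(codon)
    return by_aa


_CODON_CHOICES = _codon_choices()


def gen_coding_sequences(
    records: list[ProteinRecord], gc3_target: float, seed: int = 0
) -> list[ProteinRecord]:
    """Reverse-translate proteins with a planted third-position GC preference.

    At each codon a Bernoulli(``gc3_target``) draw prefers a G/C-ending
    synonymous codon where the code offers one; the translation of the output
    equals the input protein exactly.
    """
    if not (0.0 <= gc3_target <= 1.0):
        raise ParameterError("gc3_target must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    out = []
    for rec in records:
        codons = []
        for pos, aa in enumerate(rec.residues, start=1):
            if aa not in _CODON_CHOICES:
                raise ValidationError(
                    f"record {rec.id!r}: residue {aa!r} at position {pos} "
                    "has no codon (ambiguity letters cannot be reverse-translated)"
                )
            gc_list, at_list = _CODON_CHOICES[aa]
            prefer_gc = rng.random() < gc3_target
            pool = gc_list if (prefer_gc and gc_list) else (at_list or gc_list)
            codons.append(pool[int(rng.integers(len(pool)))])
        coding = "".join(codons)
        assert str(Seq(coding).translate()) == rec.residues
        out.append(
            ProteinRecord(
                id=rec.id, species=rec.species, residues=rec.residues, coding_seq=coding
            )
        )
    return out


def gen_melt_curve(
    tm: float,
    slope_a: float = 1.5,
    f_low: float = 0.0,
    f_high: float = 100.0,
    noise_sd: float = 0.0,
    seed: int = 0,
    t_min: float = 20.0,
    t_max: float = 80.0,
    step: float = 0.2,
    well_id: str = "A1",
) -> MeltCurve:
    """A Boltzmann melt curve on the plate grid plus seeded Gaussian noise."""
    if not (t_min <= tm <= t_max):
        raise ParameterError(f"tm={tm} outside the temperature grid [{t_min}, {t_max}]")
    n = int(round((t_max - t_min) / step)) + 1
    t = t_min + step * np.arange(n)
    f = boltzmann_model(t, tm, slope_a, f_low, f_high)
    if noise_sd > 0:
        f = f + np.random.default_rng(seed).normal(0.0, noise_sd, size=n)
    return MeltCurve(temperatures=t, fluorescence=np.asarray(f), well_id=well_id)
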