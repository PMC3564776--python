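"""Published reference values used as inputs to the correlation analyses.

Two small published datasets are bundled as plain constants:

* per-species proteome means of four thermostability measures for ten
  homeothermic vertebrates, together with their body temperatures — the
  input for the proteome-mean versus body-temperature correlation;

* per-protein CvP-bias values and experimentally determined melting
  temperatures for seven orthologous protein pairs, each pairing a protein
  from a thermophilic eukaryote (the hydrothermal-vent annelid *Alvinella
  pompejana* or the thermophilic fungus *Chaetomium thermophilum*) with its
  mesophilic ortholog — the input for the sign-concordance analysis.

Melting temperatures reported as a range (collagen) keep the range in
``tm_range`` fields; the scalar used in computations is the midpoint.
"""

from __future__ import annotations

from .correlate import OrthologPairComparison
from .io_formats import PhenotypeTable

#: Proteome means for ten homeothermic vertebrates (UniProt species mnemonics).
#: Columns: number of sequences, mean CvP-bias, mean Tm-Index, mean IUPred
#: disorder, mean IVYWREL (%), body temperature (C).
VERTEBRATE_PROTEOME_MEANS: dict[str, dict[str, float]] = {
    "HUMAN": {"n_sequences": 50006, "cvp_bias": 0.93, "tm_index": 0.90, "iupred": 0.31, "ivywrel": 36.87, "body_temperature": 37.0},
    "MOUSE": {"n_sequences": 36368, "cvp_bias": 0.97, "tm_index": 0.93, "iupred": 0.29, "ivywrel": 37.16, "body_temperature": 37.0},
    "TURTR": {"n_sequences": 307, "cvp_bias": 0.99, "tm_index": 0.79, "iupred": 0.28, "ivywrel": 38.80, "body_temperature": 36.8},
    "RAT": {"n_sequences": 30926, "cvp_bias": 1.02, "tm_index": 0.97, "iupred": 0.28, "ivywrel": 37.17, "body_temperature": 37.0},
    "BOVIN": {"n_sequences": 23358, "cvp_bias": 1.34, "tm_index": 0.96, "iupred": 0.27, "ivywrel": 37.60, "body_temperature": 37.0},
    "CHICK": {"n_sequences": 19671, "cvp_bias": 1.42, "tm_index": 0.94, "iupred": 0.28, "ivywrel": 37.30, "body_temperature": 41.0},
    "CANFA": {"n_sequences": 24002, "cvp_bias": 1.43, "tm_index": 0.96, "iupred": 0.28, "ivywrel": 37.50, "body_temperature": 37.0},
    "PIG": {"n_sequences": 24692, "cvp_bias": 1.61, "tm_index": 0.98, "iupred": 0.28, "ivywrel": 37.43, "body_temperature": 37.0},
    "MELGA": {"n_sequences": 15899, "cvp_bias": 1.72, "tm_index": 0.94, "iupred": 0.27, "ivywrel": 37.66, "body_temperature": 41.0},
    "TAEGU": {"n_sequences": 16717, "cvp_bias": 2.32, "tm_index": 0.97, "iupred": 0.27, "ivywrel": 37.72, "body_temperature": 41.0},
}

#: Measures available in VERTEBRATE_PROTEOME_MEANS besides body temperature.
VERTEBRATE_MEASURES = ("cvp_bias", "tm_index", "iupred", "ivywrel")


def vertebrate_phenotypes() -> PhenotypeTable:
    """Body temperatures of the ten vertebrates as a :class:`PhenotypeTable`."""
    return PhenotypeTable(
        temperatures={
            sp: row["body_temperature"] for sp, row in VERTEBRATE_PROTEOME_MEANS.items()
        }
    )


def vertebrate_measure_means(measure: str) -> dict[str, float]:
    """Per-species proteome mean of one measure, in table order."""
    return {sp: row[measure] for sp, row in VERTEBRATE_PROTEOME_MEANS.items()}


def _pair(
    name: str,
    thermo_cvp: float,
    meso_cvp: float,
    thermo_tm,
    meso_tm,
) -> OrthologPairComparison:
    def scalar(x) -> float:
        return float(sum(x) / len(x)) if isinstance(x, tuple) else float(x)

    return OrthologPairComparison(
        protein_name=name,
        thermo_value=thermo_cvp,
        meso_value=meso_cvp,
        thermo_tm=scalar(thermo_tm),
        meso_tm=scalar(meso_tm),
        thermo_tm_range=thermo_tm if isinstance(thermo_tm, tuple) else None,
        meso_tm_range=meso_tm if isinstance(meso_tm, tuple) else None,
    )


#: Orthologous protein pairs with experimentally determined melting
#: temperatures: CvP-bias and Tm for the thermophilic member (A. pompejana or
#: C. thermophilum) and its mesophilic ortholog (human, S. cerevisiae or
#: T. reesei). Tm ranges are stored as tuples and used via their midpoint.
ORTHOLOG_PAIR_STABILITY: list[OrthologPairComparison] = [
    _pair("Rrp4", 0.408, 6.122, 38.0, 43.1),
    _pair("PolEta", 5.71, 3.67, 49.0, 43.0),
    _pair("Collagen", 8.696, 5.804, (45.0, 46.0), (38.0, 42.0)),
    _pair("U2AF65", 11.90, 5.68, 47.0, 43.0),
    _pair("Nup170", -1.13, -4.86, 57.0, 36.0),
    _pair("Nup192", 3.47, -3.33, 57.0, 36.0),
    _pair("Xylanase", -20.276, -22.523, 60.0, 50.0),
]
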