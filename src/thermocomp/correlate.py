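"""Correlation analyses: GC-confound regressions, proteome means versus body
temperature, and sign concordance of paired stability differences.

All correlations are ordinary Pearson product-moment coefficients with
two-sided p-values from the t transform on n - 2 degrees of freedom, plus an
ordinary-least-squares line with a 95% confidence band on the slope. The
paired comparison convention is fixed throughout: difference = mesophilic
value - thermophilic value, for both the measure and the melting
temperature, so a negative difference means the thermophilic member is
higher.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy import stats

from .errors import DegenerateInputError, InsufficientOverlapError
from .io_formats import PhenotypeTable
from .measures import MeasureTable


@dataclass
class CorrelationResult:
    """Pearson correlation with the associated least-squares line."""

    r: float
    p_value: float
    n: int
    slope: float
    intercept: float
    slope_stderr: float
    slope_ci95: tuple[float, float]


def pearson(x: Sequence[float], y: Sequence[float]) -> CorrelationResult:
    """Pearson r with two-sided p-value and OLS line.

    Requires equal-length vectors of size >= 3 with non-zero variance in
    both coordinates.
    """
    xa = np.asarray(x, dtype=float)
    ya = np.asarray(y, dtype=float)
    if xa.shape != ya.shape:
        raise DegenerateInputError("x and y lengths differ")
    n = xa.size
    if n < 3:
        raise DegenerateInputError(f"need >= 3 points, got {n}")
    if np.ptp(xa) == 0 or np.ptp(ya) == 0:
        raise DegenerateInputError("zero variance in one of the variables")
    res = stats.pearsonr(xa, ya)
    ols = stats.linregress(xa, ya)
    tcrit = stats.t.ppf(0.975, n - 2)
    return CorrelationResult(
        r=float(res.statistic),
        p_value=float(res.pvalue),
        n=n,
        slope=float(ols.slope),
        intercept=float(ols.intercept),
        slope_stderr=float(ols.stderr),
        slope_ci95=(
            float(ols.slope - tcrit * ols.stderr),
            float(ols.slope + tcrit * ols.stderr),
        ),
    )


def proteome_mean_vs_phenotype(
    species_means: Mapping[str, float] | Mapping[str, MeasureTable],
    phenotype: PhenotypeTable,
    measure_name: str | None = None,
) -> CorrelationResult:
    """Correlate per-species proteome means of a measure with body temperature.

    ``species_means`` may map species directly to a precomputed mean, or to a
    :class:`MeasureTable` from which the unweighted mean of ``measure_name``
    over proteins is taken. Species present in only one input are dropped;
    fewer than 3 shared species is an error.
    """
    means: dict[str, float] = {}
    for sp, val in species_means.items():
        if isinstance(val, MeasureTable):
            if measure_name is None:
                raise DegenerateInputError("measure_name required with MeasureTable input")
            col = val.values[measure_name]
            means[sp] = float(np.nanmean(col.to_numpy()))
        else:
            means[sp] = float(val)
    shared = [sp for sp in means if sp in phenotype.temperatures]
    if len(shared) < 3:
        raise InsufficientOverlapError(
            f"only {len(shared)} species shared between means and phenotypes"
        )
    x = [means[sp] for sp in shared]
    y = [phenotype[sp] for sp in shared]
    return pearson(x, y)


def measure_vs_gc3(
    species_measure_means: Mapping[str, float],
    species_gc3: Mapping[str, float],
) -> CorrelationResult:
    """Correlate per-species measure means against third-position GC content.

    Used to check whether an apparent thermostability signal is a GC-content
    artifact: GARP/FYMINK content tracks GC3 strongly, a genuine
    thermostability measure should not.
    """
    shared = sorted(set(species_measure_means) & set(species_gc3))
    if len(shared) < 3:
        raise InsufficientOverlapError(
            f"only {len(shared)} species shared between measure and GC3 tables"
        )
    return pearson(
        [species_measure_means[sp] for sp in shared],
        [species_gc3[sp] for sp in shared],
    )


@dataclass
class OrthologPairComparison:
    """One thermophile/mesophile ortholog pair with measure and Tm values.

    ``difference`` properties follow the mesophilic-minus-thermophilic
    convention.
    """

    protein_name: str
    thermo_value: float
    meso_value: float
    thermo_tm: float | None = None
    meso_tm: float | None = None
    thermo_tm_range: tuple[float, float] | None = None
    meso_tm_range: tuple[float, float] | None = None

    @property
    def difference(self) -> float:
        return self.meso_value - self.thermo_value

    @property
    def tm_difference(self) -> float | None:
        if self.thermo_tm is None or self.meso_tm is None:
            return None
        return self.meso_tm - self.thermo_tm


def sign_concordance(
    comparisons: Sequence[OrthologPairComparison],
) -> tuple[int, int]:
    """Count pairs where the measure difference and the Tm difference agree
    in sign (both mesophilic minus thermophilic).

    Pairs missing a Tm are skipped with a warning; an exactly zero
    difference counts as discordant and is flagged.
    """
    n_concordant = 0
    n_total = 0
    for cmp_ in comparisons:
        dtm = cmp_.tm_difference
        if dtm is None:
            warnings.warn(
                f"pair {cmp_.protein_name!r}: missing Tm, skipped", stacklevel=2
            )
            continue
        n_total += 1
        dval = cmp_.difference
        if dval == 0 or dtm == 0:
            warnings.warn(
                f"pair {cmp_.protein_name!r}: zero difference, counted discordant",
                stacklevel=2,
            )
            continue
        if math.copysign(1.0, dval) == math.copysign(1.0, dtm):
            n_concordant += 1
    return n_concordant, n_total
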