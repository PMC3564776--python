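"""Per-set species ranking, cumulative rank sums, and ROC discrimination.

Each orthologous set yields a within-set ranking of species by a measure
(rank 1 = most thermostable-looking under the measure's direction; ties get
average ranks). Summing ranks over all sets gives a cumulative rank per
species and measure: the lower the sum, the more consistently
"thermostable-looking" the species' sequences are.

Discrimination power on labeled thermophile/mesophile data is quantified by
the ROC AUC, computed with the rank (Mann-Whitney) pair-counting identity

    AUC = (#{(pos, neg): pos > neg} + 0.5 * #ties) / (n_pos * n_neg)

which equals the trapezoidal area under the empirical ROC curve.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy.stats import rankdata

from .errors import UndefinedRocError
from .measures import MeasureTable


@dataclass
class RankSummary:
    """Cumulative within-set ranks of each species for one measure."""

    measure_name: str
    cumulative_rank: dict[str, float]
    n_sets_used: int


def rank_set(
    set_values: Mapping[str, float | None], direction: int
) -> dict[str, float] | None:
    """Rank the species of one orthologous set under a measure.

    Rank 1 is the most thermostable under ``direction`` (+1: largest value
    first; -1: smallest first); ties receive the average of the tied
    positions. If any species has a missing value the whole set is skipped
    for that measure (returns ``None``) so cumulative sums stay comparable
    across species.
    """
    species = list(set_values)
    values = [set_values[sp] for sp in species]
    if any(v is None or (isinstance(v, float) and np.isnan(v)) for v in values):
        return None
    if len(values) < 2:
        return None
    arr = np.asarray(values, dtype=float)
    ranks = rankdata(-direction * arr, method="average")
    return dict(zip(species, ranks.tolist()))


def cumulative_ranks(
    set_tables: Sequence[MeasureTable],
    measure_names: Sequence[str] | None = None,
) -> list[RankSummary]:
    """Sum within-set species ranks over many orthologous sets.

    Each element of ``set_tables`` holds the measure values of one set's
    members (one protein per species). Sets with a missing value for a
    measure are excluded from that measure's sum; ``n_sets_used`` reports how
    many sets contributed. For every measure the column sum equals
    ``n_sets_used * S * (S + 1) / 2`` (average-rank ties preserve the total).
    """
    if not set_tables:
        return []
    if measure_names is None:
        measure_names = set_tables[0].measure_names()
    summaries: list[RankSummary] = []
    for name in measure_names:
        direction = set_tables[0].directions[name]
        totals: dict[str, float] = {}
        n_used = 0
        for table in set_tables:
            col = table.values[name]
            per_species = {
                table.species[pid]: (None if np.isnan(v) else float(v))
                for pid, v in col.items()
            }
            ranks = rank_set(per_species, direction)
            if ranks is None:
                continue
            n_used += 1
            for sp, r in ranks.items():
                totals[sp] = totals.get(sp, 0.0) + r
        summaries.append(
            RankSummary(measure_name=name, cumulative_rank=totals, n_sets_used=n_used)
        )
    return summaries


@dataclass
class RocResult:
    """ROC points and AUC for one scored, labeled dataset."""

    scores: list[tuple[float, str]]
    roc_points: list[tuple[float, float]]  # (FPR, TPR), (0,0) .. (1,1)
    auc: float
    positive_label: str = "thermophile"


def roc_auc(
    scores: Sequence[tuple[float, str]],
    positive: str = "thermophile",
    direction: int = 1,
) -> RocResult:
    """ROC curve and AUC for labeled scores.

    ``direction=-1`` orients measures where *smaller* values indicate the
    positive class. The curve is a threshold sweep over the unique oriented
    scores; the AUC is computed by pair counting (ties weighted 0.5) and
    equals the trapezoidal area under the returned points.
    """
    oriented = [(direction * v, lab) for v, lab in scores]
    pos = np.array([v for v, lab in oriented if lab == positive], dtype=float)
    neg = np.array([v for v, lab in oriented if lab != positive], dtype=float)
    if pos.size == 0 or neg.size == 0:
        raise UndefinedRocError("ROC needs both positive and negative examples")

    greater = np.sum(pos[:, None] > neg[None, :])
    ties = np.sum(pos[:, None] == neg[None, :])
    auc = float((greater + 0.5 * ties) / (pos.size * neg.size))

    thresholds = np.unique(np.concatenate([pos, neg]))[::-1]
    points = [(0.0, 0.0)]
    for th in thresholds:
        tpr = float(np.sum(pos >= th)) / pos.size
        fpr = float(np.sum(neg >= th)) / neg.size
        points.append((fpr, tpr))
    if points[-1] != (1.0, 1.0):
        points.append((1.0, 1.0))
    return RocResult(scores=list(scores), roc_points=points, auc=auc, positive_label=positive)


def trapezoid_area(points: Sequence[tuple[float, float]]) -> float:
    """Trapezoidal area under a ROC polyline (used to cross-check the AUC)."""
    xs = np.array([p[0] for p in points])
    ys = np.array([p[1] for p in points])
    return float(np.trapezoid(ys, xs))


def paired_concordance(
    pairs: Sequence[tuple[float, float]], direction: int = 1
) -> float:
    """Fraction of homolog pairs where the thermophile member scores higher.

    Each pair is (thermophile value, mesophile value); ties count 0.5;
    ``direction=-1`` flips the comparison for smaller-is-thermostable
    measures.
    """
    if not pairs:
        raise UndefinedRocError("no pairs given")
    score = 0.0
    for t, m in pairs:
        dt = direction * (t - m)
        if dt > 0:
            score += 1.0
        elif dt == 0:
            score += 0.5
    return score / len(pairs)
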