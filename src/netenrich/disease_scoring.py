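"""Geometric-mean combination of empirical p-values into per-disease scores.

The combined statistic is p_mean = (p1 x p2 x ... x pn)^(1/n) over all
interactome x disease-pathway cells, with exact zeros (and anything below
the floor) replaced by a zero floor before combining.  The sensitivity
index is 1/p_mean; diseases are ranked by descending index.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .enrichment import EnrichmentMatrix
from .io_formats import DiseaseCatalog

DEFAULT_ZERO_FLOOR = 1e-4
_REFERENCE_N_NULL = 1000


def default_zero_floor(n_null: int) -> float:
    """Floor one decade below the resampling resolution 1/n_null.

    Equals the canonical 1e-4 at the reference ensemble size of 1000 null
    sets and scales with the attainable resolution otherwise.
    """
    if n_null <= 0:
        return DEFAULT_ZERO_FLOOR
    return 1.0 / (10.0 * n_null)


def combine_pvalues(p_values: Sequence[float], zero_floor: float = DEFAULT_ZERO_FLOOR) -> float:
    """Geometric mean of the floored p-values, computed in log space."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        raise ValueError("p_values must be non-empty")
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    if not (0.0 < zero_floor <= 1.0):
        raise ValueError(f"zero_floor must be in (0, 1], got {zero_floor}")
    floored = np.maximum(p, zero_floor)
    return float(np.exp(np.mean(np.log(floored))))


def sensitivity_index(p_mean: float) -> float:
    if p_mean <= 0:
        raise ValueError(f"p_mean must be positive, got {p_mean}")
    if p_mean > 1:
        raise ValueError(f"p_mean must be <= 1, got {p_mean}")
    return 1.0 / p_mean


def format_p_mean(p_mean: float, decimals: int = 4) -> float:
    """Report-side rounding of p_mean (the index stays full precision)."""
    return round(p_mean, decimals)


@dataclass(frozen=True)
class CombinedScore:
    disease: str
    p_values: tuple[float, ...]
    p_mean: float
    sensitivity_index: float
    zero_floor: float

    @property
    def n(self) -> int:
        return len(self.p_values)


def score_disease(
    matrix: EnrichmentMatrix,
    disease: str,
    catalog: DiseaseCatalog,
    zero_floor: float | None = None,
) -> CombinedScore:
    """Combine the disease's block of empirical p-values into one score.

    Gathers every (interactome row) x (disease pathway column) cell, so
    n = #interactomes x #disease pathways.  ``zero_floor=None`` selects
    :func:`default_zero_floor` for the matrix's ensemble size.
    """
    if disease not in catalog:
        raise KeyError(f"unknown disease {disease!r}")
    if zero_floor is None:
        zero_floor = default_zero_floor(matrix.n_null)
    col_index = {c: j for j, c in enumerate(matrix.cols)}
    missing = [p for p in catalog.pathway_ids(disease) if p not in col_index]
    if missing:
        raise ValueError(f"disease {disease!r} has pathway(s) missing from the matrix: {missing}")
    cols = [col_index[p] for p in catalog.pathway_ids(disease)]
    block = matrix.empirical_p[:, cols]
    p_values = tuple(float(v) for v in block.ravel())
    p_mean = combine_pvalues(p_values, zero_floor)
    return CombinedScore(
        disease=disease,
        p_values=p_values,
        p_mean=p_mean,
        sensitivity_index=sensitivity_index(p_mean),
        zero_floor=zero_floor,
    )


def score_all_diseases(
    matrix: EnrichmentMatrix, catalog: DiseaseCatalog, zero_floor: float | None = None
) -> list[CombinedScore]:
    return [score_disease(matrix, d, catalog, zero_floor) for d in sorted(catalog.diseases)]


@dataclass(frozen=True)
class RankedDisease:
    rank: int
    disease: str
    category: str
    p_mean: float
    sensitivity_index: float


@dataclass
class DiseaseRanking:
    entries: list[RankedDisease]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                (e.disease, e.category, e.p_mean, e.sensitivity_index, e.rank)
                for e in self.entries
            ],
            columns=["disease", "category", "p_mean", "sensitivity_index", "rank"],
        )

    def to_report_frame(self) -> pd.DataFrame:
        """Human-facing table: p_mean rounded to 4 decimals, index full precision."""
        frame = self.to_frame()
        frame["p_mean"] = frame["p_mean"].map(format_p_mean)
        return frame

    def __len__(self) -> int:
        return len(self.entries)


def rank_diseases(scores: Sequence[CombinedScore], catalog: DiseaseCatalog) -> DiseaseRanking:
    """Rank by descending sensitivity index; ties break lexicographically."""
    if not scores:
        raise ValueError("scores must be non-empty")
    names = [s.disease for s in scores]
    if len(set(names)) != len(names):
        raise ValueError("duplicate disease names in scores")
    ordered = sorted(scores, key=lambda s: (-s.sensitivity_index, s.disease))
    entries = [
        RankedDisease(
            rank=i + 1,
            disease=s.disease,
            category=catalog.category(s.disease),
            p_mean=s.p_mean,
            sensitivity_index=s.sensitivity_index,
        )
        for i, s in enumerate(ordered)
    ]
    return DiseaseRanking(entries)


def category_summary(scores: Sequence[CombinedScore], catalog: DiseaseCatalog) -> pd.DataFrame:
    """Five-number summary of log10(sensitivity index) per category.

    Plot-ready table with columns: category, n, min, q1, median, q3, max.
    """
    by_category: dict[str, list[float]] = {}
    for s in scores:
        cat = catalog.category(s.disease)
        by_category.setdefault(cat, []).append(math.log10(s.sensitivity_index))
    records = []
    for cat in sorted(by_category):
        values = np.asarray(by_category[cat])
        records.append(
            (
                cat,
                values.size,
                float(values.min()),
                float(np.percentile(values, 25)),
                float(np.percentile(values, 50)),
                float(np.percentile(values, 75)),
                float(values.max()),
            )
        )
    return pd.DataFrame(records, columns=["category", "n", "min", "q1", "median", "q3", "max"])
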