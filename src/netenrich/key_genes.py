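"""Cross-section gene scoring: how often a gene sits in interactome-pathway overlaps.

For one disease, a gene's count is the number of (interactome, pathway)
pairs whose intersection contains it, over the disease's pathways; counts
are normalized by the disease's pathway count and summed across diseases.
"""

from __future__ import annotations

from typing import Mapping, Sequence

import pandas as pd

from .enrichment import EnrichmentMatrix
from .interactome import Interactome
from .io_formats import DiseaseCatalog, PathwayCollection


def cross_section_counts(
    interactomes: Sequence[Interactome],
    disease: str,
    catalog: DiseaseCatalog,
    pathways: PathwayCollection,
    matrix: EnrichmentMatrix | None = None,
    min_significance: float | None = None,
) -> dict[str, int]:
    """count(g) = #{(I, P): P is a disease pathway, g in I and g in P}.

    Genes with count 0 are omitted.  When ``min_significance`` is given
    (together with the enrichment matrix) only pairs with empirical
    p <= min_significance are counted.
    """
    if disease not in catalog:
        raise KeyError(f"unknown disease {disease!r}")
    if min_significance is not None and matrix is None:
        raise ValueError("min_significance requires the enrichment matrix")

    emp = matrix.empirical_frame() if matrix is not None else None
    counts: dict[str, int] = {}
    for pid in catalog.pathway_ids(disease):
        pathway_genes = pathways.genes(pid)
        for ia in interactomes:
            if min_significance is not None:
                if emp.loc[ia.name, pid] > min_significance:
                    continue
            for gene in ia.members & pathway_genes:
                counts[gene] = counts.get(gene, 0) + 1
    return counts


def normalize_counts(counts: Mapping[str, int], n_pathways: int) -> dict[str, float]:
    """Divide each count by the disease's pathway count."""
    if n_pathways < 1:
        raise ValueError(f"n_pathways must be >= 1, got {n_pathways}")
    return {gene: count / n_pathways for gene, count in counts.items()}


def gene_score_table(
    per_disease: Mapping[str, Mapping[str, float]],
    disease_order: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Assemble the per-disease normalized counts into one table with a Sum.

    Rows are the union of genes across diseases (missing values 0), sorted
    by descending Sum then gene name.  Sums are computed from unrounded
    values; exports round to 2 decimals at write time.
    """
    if not per_disease:
        raise ValueError("at least one disease is required")
    if disease_order is None:
        disease_order = list(per_disease)
    genes = sorted(set().union(*(set(m) for m in per_disease.values())))
    records = []
    for gene in genes:
        row = [per_disease[d].get(gene, 0.0) for d in disease_order]
        records.append([gene, *row, sum(row)])
    frame = pd.DataFrame(records, columns=["gene", *disease_order, "Sum"])
    frame = frame.sort_values(["Sum", "gene"], ascending=[False, True], kind="mergesort")
    return frame.reset_index(drop=True)


def score_key_genes(
    interactomes: Sequence[Interactome],
    catalog: DiseaseCatalog,
    pathways: PathwayCollection,
    matrix: EnrichmentMatrix | None = None,
    min_significance: float | None = None,
) -> pd.DataFrame:
    """Full cross-section scoring over every disease in the catalog."""
    disease_order = sorted(catalog.diseases)
    per_disease: dict[str, dict[str, float]] = {}
    for disease in disease_order:
        counts = cross_section_counts(
            interactomes, disease, catalog, pathways, matrix, min_significance
        )
        per_disease[disease] = normalize_counts(counts, len(catalog.pathway_ids(disease)))
    if not per_disease:
        return pd.DataFrame(columns=["gene", "Sum"])
    return gene_score_table(per_disease, disease_order)
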