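"""Domain types and file-format readers/writers.

All other modules exchange only the in-memory types defined here:
:class:`InteractionNetwork`, :class:`PathwayCollection` and
:class:`DiseaseCatalog`.  On-disk formats are plain TSV (tab or whitespace
delimited, ``.`` decimal separator), GMT for gene sets, and JSON for the run
configuration snapshot.
"""

from __future__ import annotations

import json
import logging
import math
import os
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Literal, Mapping

import networkx as nx
import pandas as pd

logger = logging.getLogger(__name__)

ScoreScale = Literal["auto", "unit", "string999"]


class ParseError(ValueError):
    """Raised for malformed input files; carries the offending line number."""

    def __init__(self, message: str, line_number: int | None = None):
        if line_number is not None:
            message = f"line {line_number}: {message}"
        super().__init__(message)
        self.line_number = line_number


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


class InteractionNetwork:
    """Undirected weighted gene network with per-edge confidence in [0, 1].

    Invariants: no self-loops, at most one edge per unordered pair, every
    edge endpoint is a node, confidences in [0, 1].  Nodes without edges are
    allowed (they still count toward the enrichment universe).
    """

    def __init__(self) -> None:
        self._g = nx.Graph()

    # -- construction -------------------------------------------------------

    @classmethod
    def from_edges(
        cls,
        edges: Iterable[tuple[str, str, float]],
        nodes: Iterable[str] = (),
    ) -> "InteractionNetwork":
        net = cls()
        for n in nodes:
            net.add_node(n)
        for a, b, c in edges:
            net.add_edge(a, b, c)
        return net

    def add_node(self, gene: str) -> None:
        if not gene:
            raise ValueError("gene symbol must be a non-empty string")
        self._g.add_node(gene)

    def add_edge(self, a: str, b: str, confidence: float) -> None:
        """Add an edge; an existing edge keeps the maximum confidence."""
        if not a or not b:
            raise ValueError("gene symbols must be non-empty strings")
        if a == b:
            raise ValueError(f"self-loop not allowed: {a!r}")
        if not (0.0 <= confidence <= 1.0):
            raise ValueError(f"confidence {confidence} outside [0, 1] for edge ({a}, {b})")
        if self._g.has_edge(a, b):
            confidence = max(confidence, self._g[a][b]["confidence"])
        self._g.add_edge(a, b, confidence=confidence)

    def set_edge(self, a: str, b: str, confidence: float) -> None:
        """Set an edge confidence, overwriting any existing value."""
        if a == b:
            raise ValueError(f"self-loop not allowed: {a!r}")
        if not (0.0 <= confidence <= 1.0):
            raise ValueError(f"confidence {confidence} outside [0, 1]")
        self._g.add_edge(a, b, confidence=confidence)

    def copy(self) -> "InteractionNetwork":
        out = InteractionNetwork()
        out._g = self._g.copy()
        return out

    # -- queries ------------------------------------------------------------

    @property
    def nodes(self) -> set[str]:
        return set(self._g.nodes)

    def __contains__(self, gene: str) -> bool:
        return gene in self._g

    @property
    def n_nodes(self) -> int:
        return self._g.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self._g.number_of_edges()

    def edges(self) -> Iterator[tuple[str, str, float]]:
        for a, b, d in self._g.edges(data="confidence"):
            yield a, b, d

    def edge_set(self) -> set[tuple[str, str, float]]:
        """Canonical (sorted-pair) edge set, usable for exact comparisons."""
        return {(min(a, b), max(a, b), c) for a, b, c in self.edges()}

    def confidence(self, a: str, b: str) -> float | None:
        if self._g.has_edge(a, b):
            return self._g[a][b]["confidence"]
        return None

    def neighbors(self, gene: str) -> Iterator[tuple[str, float]]:
        for nb, d in self._g[gene].items():
            yield nb, d["confidence"]

    def degree(self, gene: str) -> int:
        return self._g.degree(gene)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, InteractionNetwork):
            return NotImplemented
        return self.nodes == other.nodes and self.edge_set() == other.edge_set()


@dataclass(frozen=True)
class Pathway:
    description: str
    genes: frozenset[str]


@dataclass
class PathwayCollection:
    """Named gene sets, keyed by unique pathway id."""

    pathways: dict[str, Pathway] = field(default_factory=dict)

    def add(self, pathway_id: str, description: str, genes: Iterable[str]) -> None:
        if pathway_id in self.pathways:
            raise ValueError(f"duplicate pathway id {pathway_id!r}")
        gene_set = frozenset(genes)
        if not gene_set:
            raise ValueError(f"pathway {pathway_id!r} has an empty gene set")
        self.pathways[pathway_id] = Pathway(description, gene_set)

    def genes(self, pathway_id: str) -> frozenset[str]:
        return self.pathways[pathway_id].genes

    def ids(self) -> list[str]:
        return list(self.pathways)

    def __contains__(self, pathway_id: str) -> bool:
        return pathway_id in self.pathways

    def __len__(self) -> int:
        return len(self.pathways)


@dataclass
class DiseaseCatalog:
    """Disease -> pathway-id grouping plus a category label per disease."""

    diseases: dict[str, list[str]] = field(default_factory=dict)
    categories: dict[str, str] = field(default_factory=dict)

    def add(self, disease: str, category: str, pathway_id: str) -> None:
        if disease in self.categories and self.categories[disease] != category:
            raise ValueError(
                f"conflicting categories for disease {disease!r}: "
                f"{self.categories[disease]!r} vs {category!r}"
            )
        self.categories[disease] = category
        self.diseases.setdefault(disease, [])
        if pathway_id not in self.diseases[disease]:
            self.diseases[disease].append(pathway_id)

    def pathway_ids(self, disease: str) -> list[str]:
        return self.diseases[disease]

    def category(self, disease: str) -> str:
        return self.categories[disease]

    def __contains__(self, disease: str) -> bool:
        return disease in self.diseases

    def __len__(self) -> int:
        return len(self.diseases)


# ---------------------------------------------------------------------------
# Readers
# ---------------------------------------------------------------------------


def _is_number(token: str) -> bool:
    try:
        float(token)
    except ValueError:
        return False
    return True


def read_network(path: str | os.PathLike, score_scale: ScoreScale = "auto") -> InteractionNetwork:
    """Read a whitespace/tab-delimited ``geneA geneB score`` edge list.

    ``score_scale`` selects the score dialect: ``unit`` passes scores through,
    ``string999`` divides integer 0-999 scores by 1000, and ``auto`` picks
    ``string999`` iff every score is an integer > 1.  Duplicate pairs keep the
    maximum confidence; self-loops are dropped with a logged warning.  An
    optional header line is detected by a non-numeric third column.
    """
    if score_scale not in ("auto", "unit", "string999"):
        raise ValueError(f"unknown score_scale {score_scale!r}")
    rows: list[tuple[int, str, str, float]] = []
    with open(path, "rt", encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            fields = line.split()
            if len(fields) != 3:
                raise ParseError(
                    f"expected 3 columns (geneA geneB score), got {len(fields)}", lineno
                )
            a, b, score_str = fields
            if not _is_number(score_str):
                if lineno == 1:  # header line
                    continue
                raise ParseError(f"non-numeric score {score_str!r}", lineno)
            rows.append((lineno, a, b, float(score_str)))

    if score_scale == "auto":
        scores = [s for _, _, _, s in rows]
        string999 = bool(scores) and all(s > 1 and float(s).is_integer() for s in scores)
    else:
        string999 = score_scale == "string999"

    net = InteractionNetwork()
    n_self_loops = 0
    for lineno, a, b, score in rows:
        conf = score / 1000.0 if string999 else score
        if not (0.0 <= conf <= 1.0):
            raise ParseError(
                f"score {score} maps to confidence {conf} outside [0, 1]", lineno
            )
        if a == b:
            n_self_loops += 1
            continue
        net.add_edge(a, b, conf)  # duplicate pairs keep max confidence
    if n_self_loops:
        logger.warning("read_network: dropped %d self-loop line(s) from %s", n_self_loops, path)
    return net


def read_gmt(path: str | os.PathLike) -> PathwayCollection:
    """Read a GMT file (``id<TAB>description<TAB>gene1<TAB>gene2...``)."""
    collection = PathwayCollection()
    with open(path, "rt", encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip():
                continue
            fields = [f for f in line.split("\t")]
            # trailing empty cells from editors are tolerated
            while fields and fields[-1] == "":
                fields.pop()
            if len(fields) < 3:
                raise ParseError("GMT line needs id, description and >=1 gene", lineno)
            pathway_id, description, *genes = fields
            try:
                collection.add(pathway_id, description, genes)
            except ValueError as exc:
                raise ParseError(str(exc), lineno) from exc
    return collection


def read_disease_map(path: str | os.PathLike, pathways: PathwayCollection) -> DiseaseCatalog:
    """Read a ``disease<TAB>category<TAB>pathway_id`` TSV into a catalog.

    Referential integrity against *pathways* is enforced; an unknown pathway
    id raises an error naming the id and row.
    """
    catalog = DiseaseCatalog()
    with open(path, "rt", encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) != 3:
                raise ParseError(
                    f"expected 3 columns (disease, category, pathway_id), got {len(fields)}",
                    lineno,
                )
            disease, category, pathway_id = (f.strip() for f in fields)
            if pathway_id not in pathways:
                raise ParseError(
                    f"unknown pathway id {pathway_id!r} for disease {disease!r}", lineno
                )
            try:
                catalog.add(disease, category, pathway_id)
            except ValueError as exc:
                raise ParseError(str(exc), lineno) from exc
    return catalog


# ---------------------------------------------------------------------------
# Writers
# ---------------------------------------------------------------------------

# None -> pandas writes the shortest repr that round-trips float64 exactly
FLOAT_FMT = None


def write_network(net: InteractionNetwork, path: str | os.PathLike) -> None:
    """Write a unit-dialect edge list plus a ``<path>.nodes`` sidecar.

    Isolated nodes cannot be represented in a 3-column edge list, so a
    companion ``<path>.nodes`` file lists every node (one per line); reading
    both reconstructs the network exactly.
    """
    edges = sorted(net.edge_set())
    with open(path, "wt", encoding="utf-8") as fh:
        fh.write("gene_a\tgene_b\tcombined_score\n")
        for a, b, c in edges:
            fh.write(f"{a}\t{b}\t{c!r}\n")
    with open(f"{path}.nodes", "wt", encoding="utf-8") as fh:
        for n in sorted(net.nodes):
            fh.write(f"{n}\n")


def read_node_list(path: str | os.PathLike) -> list[str]:
    with open(path, "rt", encoding="utf-8") as fh:
        return [line.strip() for line in fh if line.strip()]


def write_gmt(collection: PathwayCollection, path: str | os.PathLike) -> None:
    with open(path, "wt", encoding="utf-8") as fh:
        for pid in sorted(collection.ids()):
            pw = collection.pathways[pid]
            genes = "\t".join(sorted(pw.genes))
            fh.write(f"{pid}\t{pw.description}\t{genes}\n")


def write_disease_map(catalog: DiseaseCatalog, path: str | os.PathLike) -> None:
    with open(path, "wt", encoding="utf-8") as fh:
        for disease in sorted(catalog.diseases):
            for pid in catalog.pathway_ids(disease):
                fh.write(f"{disease}\t{catalog.category(disease)}\t{pid}\n")


def _safe_filename(name: str) -> str:
    return "".join(c if c.isalnum() or c in "-_." else "_" for c in name)


def write_results(
    matrix,
    scores,
    genes: pd.DataFrame,
    outdir: str | os.PathLike,
    catalog: DiseaseCatalog | None = None,
    run_config: Mapping | None = None,
) -> list[str]:
    """Write the five result artifacts and return the written paths.

    * ``enrichment_long.tsv`` — interactome, pathway, overlap, uncorrected_p,
      empirical_p (long format);
    * ``heatmap_<disease>.tsv`` — one wide empirical-p matrix per disease
      (interactome rows x disease-pathway columns);
    * ``disease_scores.tsv`` — disease, category, p_mean, sensitivity_index,
      rank, full precision;
    * ``gene_scores.tsv`` — gene, one column per disease, Sum (2 decimals);
    * ``run_config.json`` — every parameter and seed of the run.
    """
    os.makedirs(outdir, exist_ok=True)
    written: list[str] = []

    long_path = os.path.join(outdir, "enrichment_long.tsv")
    matrix.to_long_frame().to_csv(long_path, sep="\t", index=False, float_format=FLOAT_FMT)
    written.append(long_path)

    if catalog is not None:
        emp = matrix.empirical_frame()
        for disease in sorted(catalog.diseases):
            cols = [p for p in catalog.pathway_ids(disease) if p in emp.columns]
            hm_path = os.path.join(outdir, f"heatmap_{_safe_filename(disease)}.tsv")
            emp[cols].to_csv(
                hm_path, sep="\t", index=True, index_label="interactome", float_format=FLOAT_FMT
            )
            written.append(hm_path)

    score_path = os.path.join(outdir, "disease_scores.tsv")
    scores.to_frame().to_csv(score_path, sep="\t", index=False, float_format=FLOAT_FMT)
    written.append(score_path)

    gene_path = os.path.join(outdir, "gene_scores.tsv")
    gene_out = genes.copy()
    for col in gene_out.columns:
        if col != "gene":
            gene_out[col] = gene_out[col].map(lambda v: f"{v:.2f}")
    gene_out.to_csv(gene_path, sep="\t", index=False)
    written.append(gene_path)

    config_path = os.path.join(outdir, "run_config.json")
    with open(config_path, "wt", encoding="utf-8") as fh:
        json.dump(dict(run_config or {}), fh, indent=2, sort_keys=True, default=str)
        fh.write("\n")
    written.append(config_path)
    return written


def read_interactomes_gmt(path: str | os.PathLike):
    """Read interactomes dumped in GMT form (name, spec-description, members)."""
    from .interactome import Interactome  # local import to avoid cycle

    collection = read_gmt(path)
    out = []
    for name in collection.ids():
        pw = collection.pathways[name]
        out.append(Interactome(name=name, members=pw.genes, spec=None, provenance=()))
    return out


def write_interactomes_gmt(interactomes, path: str | os.PathLike) -> None:
    with open(path, "wt", encoding="utf-8") as fh:
        for ia in sorted(interactomes, key=lambda i: i.name):
            desc = ia.describe_spec()
            genes = "\t".join(sorted(ia.members))
            fh.write(f"{ia.name}\t{desc}\t{genes}\n")


def values_close(a: float, b: float, sig_digits: int = 12) -> bool:
    """True when a and b agree to ``sig_digits`` significant digits."""
    if a == b:
        return True
    scale = max(abs(a), abs(b))
    return math.isclose(a, b, rel_tol=10 ** (1 - sig_digits), abs_tol=scale * 10 ** (-sig_digits))
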