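"""Seed-gene interactome extraction, size tuning and near-duplicate merging.

An interactome is the set of genes reachable from a seed gene within a fixed
number of hops, using only edges whose confidence meets a threshold.  The
threshold applies to *every* edge on a path, so a second-order member must be
reached through two qualifying edges.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Literal, NamedTuple, Sequence

from .io_formats import InteractionNetwork

logger = logging.getLogger(__name__)

DEFAULT_THRESHOLDS: tuple[float, ...] = (0.4, 0.5, 0.6, 0.7, 0.8, 0.9)
DEFAULT_ORDERS: tuple[int, ...] = (1, 2)
DEFAULT_SIZE_WINDOW: tuple[int, int] = (100, 600)
DEFAULT_JACCARD = 0.8


@dataclass(frozen=True)
class InteractomeSpec:
    """Extraction parameters: seed gene, confidence threshold, hop order."""

    seed_gene: str
    confidence_threshold: float
    order: int

    def __post_init__(self) -> None:
        if self.order not in (1, 2):
            raise ValueError(f"order must be 1 or 2, got {self.order}")
        if not (0.0 <= self.confidence_threshold <= 1.0):
            raise ValueError(
                f"confidence_threshold must be in [0, 1], got {self.confidence_threshold}"
            )


@dataclass(frozen=True)
class Interactome:
    name: str
    members: frozenset[str]
    spec: InteractomeSpec | Literal["merged"] | None
    provenance: tuple[InteractomeSpec, ...] = ()

    def __len__(self) -> int:
        return len(self.members)

    def describe_spec(self) -> str:
        if isinstance(self.spec, InteractomeSpec):
            s = self.spec
            return f"seed={s.seed_gene};threshold={s.confidence_threshold};order={s.order}"
        if self.spec == "merged":
            parts = ";".join(
                f"{p.seed_gene}:{p.confidence_threshold}:{p.order}" for p in self.provenance
            )
            return f"merged[{parts}]"
        return "unspecified"


def extract_interactome(network: InteractionNetwork, spec: InteractomeSpec) -> Interactome:
    """BFS from the seed up to ``spec.order`` hops over qualifying edges.

    Every traversed edge must have confidence >= ``spec.confidence_threshold``.
    The seed is always a member.
    """
    seed = spec.seed_gene
    if seed not in network:
        raise KeyError(f"seed gene {seed!r} not present in the network")
    members: set[str] = {seed}
    frontier: set[str] = {seed}
    for _ in range(spec.order):
        nxt: set[str] = set()
        for gene in frontier:
            for nb, conf in network.neighbors(gene):
                if conf >= spec.confidence_threshold and nb not in members:
                    nxt.add(nb)
        members |= nxt
        frontier = nxt
        if not frontier:
            break
    return Interactome(name=seed, members=frozenset(members), spec=spec)


class TuneResult(NamedTuple):
    spec: InteractomeSpec
    interactome: Interactome
    in_window: bool


def tune_interactome(
    network: InteractionNetwork,
    seed_gene: str,
    size_window: tuple[int, int] = DEFAULT_SIZE_WINDOW,
    thresholds: Sequence[float] = DEFAULT_THRESHOLDS,
    orders: Sequence[int] = DEFAULT_ORDERS,
) -> TuneResult:
    """Scan (threshold, order) candidates for a size inside ``size_window``.

    Among in-window candidates the preference order is: lower order, then
    higher threshold, then size closest to the window midpoint.  When no
    candidate lands inside the window the closest-to-midpoint candidate is
    returned flagged (``in_window=False``).
    """
    if not thresholds or not orders:
        raise ValueError("candidate threshold and order lists must be non-empty")
    lo, hi = size_window
    if lo > hi:
        raise ValueError(f"invalid size window {size_window}")
    midpoint = (lo + hi) / 2.0

    candidates: list[tuple[InteractomeSpec, Interactome]] = []
    for order in sorted(orders):
        for threshold in sorted(thresholds):
            spec = InteractomeSpec(seed_gene, threshold, order)
            candidates.append((spec, extract_interactome(network, spec)))

    in_window = [(s, ia) for s, ia in candidates if lo <= len(ia) <= hi]
    if in_window:
        spec, ia = min(
            in_window,
            key=lambda c: (c[0].order, -c[0].confidence_threshold, abs(len(c[1]) - midpoint)),
        )
        return TuneResult(spec, ia, True)
    spec, ia = min(
        candidates,
        key=lambda c: (abs(len(c[1]) - midpoint), c[0].order, -c[0].confidence_threshold),
    )
    logger.warning(
        "tune_interactome: seed %s has no candidate in window [%d, %d]; "
        "closest size is %d (threshold=%.2f, order=%d)",
        seed_gene, lo, hi, len(ia), spec.confidence_threshold, spec.order,
    )
    return TuneResult(spec, ia, False)


def jaccard(a: frozenset[str] | set[str], b: frozenset[str] | set[str]) -> float:
    union = len(a | b)
    if union == 0:
        return 1.0
    return len(a & b) / union


def merge_similar(
    interactomes: Sequence[Interactome], jaccard_threshold: float = DEFAULT_JACCARD
) -> list[Interactome]:
    """Single-linkage merge of interactomes with pairwise Jaccard >= threshold.

    Each linked group is replaced by the union of its members, named by the
    sorted source names joined with ``+``; provenance keeps every source
    spec.  Output is sorted by name.
    """
    if not (0.0 < jaccard_threshold <= 1.0):
        raise ValueError(f"jaccard_threshold must be in (0, 1], got {jaccard_threshold}")
    n = len(interactomes)
    parent = list(range(n))

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i in range(n):
        for j in range(i + 1, n):
            if jaccard(interactomes[i].members, interactomes[j].members) >= jaccard_threshold:
                parent[find(i)] = find(j)

    groups: dict[int, list[Interactome]] = {}
    for i in range(n):
        groups.setdefault(find(i), []).append(interactomes[i])

    merged: list[Interactome] = []
    for group in groups.values():
        if len(group) == 1:
            merged.append(group[0])
            continue
        group = sorted(group, key=lambda ia: ia.name)
        members = frozenset().union(*(ia.members for ia in group))
        provenance: list[InteractomeSpec] = []
        for ia in group:
            if isinstance(ia.spec, InteractomeSpec):
                provenance.append(ia.spec)
            provenance.extend(ia.provenance)
        merged.append(
            Interactome(
                name="+".join(ia.name for ia in group),
                members=members,
                spec="merged",
                provenance=tuple(provenance),
            )
        )
    return sorted(merged, key=lambda ia: ia.name)


@dataclass
class SeedSpec:
    """One row of a seeds config: fixed spec or auto-tune request."""

    gene: str
    threshold: float | None = None  # None -> auto
    order: int | None = None

    @property
    def auto(self) -> bool:
        return self.threshold is None or self.order is None


def read_seed_specs(path: str) -> list[SeedSpec]:
    """Read a seeds TSV: ``gene<TAB>threshold<TAB>order``; ``auto`` allowed.

    A header line starting with 'gene' is skipped.  Lines with only a gene
    symbol default to auto tuning.
    """
    from .io_formats import ParseError

    out: list[SeedSpec] = []
    with open(path, "rt", encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            fields = line.split("\t") if "\t" in line else line.split()
            if lineno == 1 and fields[0].lower() == "gene":
                continue
            if len(fields) == 1:
                out.append(SeedSpec(fields[0]))
                continue
            if len(fields) != 3:
                raise ParseError(
                    f"expected 'gene', or 'gene threshold order', got {len(fields)} fields",
                    lineno,
                )
            gene, thr, order = fields
            if thr.lower() == "auto" or order.lower() == "auto":
                out.append(SeedSpec(gene))
            else:
                out.append(SeedSpec(gene, float(thr), int(order)))
    return out


def build_interactomes(
    network: InteractionNetwork,
    seed_specs: Iterable[SeedSpec],
    size_window: tuple[int, int] = DEFAULT_SIZE_WINDOW,
    thresholds: Sequence[float] = DEFAULT_THRESHOLDS,
    orders: Sequence[int] = DEFAULT_ORDERS,
    jaccard_threshold: float = DEFAULT_JACCARD,
) -> list[Interactome]:
    """Extract (or tune) one interactome per seed spec, then merge near-duplicates."""
    extracted: list[Interactome] = []
    for ss in seed_specs:
        if ss.auto:
            result = tune_interactome(network, ss.gene, size_window, thresholds, orders)
            extracted.append(result.interactome)
        else:
            spec = InteractomeSpec(ss.gene, ss.threshold, ss.order)
            extracted.append(extract_interactome(network, spec))
    return merge_similar(extracted, jaccard_threshold)
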