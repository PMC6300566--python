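"""Fully in-memory study bundles with known planted signal.

Generates a sparse confidence-weighted gene network (Erdos-Renyi topology,
Beta-distributed edge confidences), random pathway collections, disease
groupings, and a set of seed genes.  Selected (seed gene, disease) "truth"
pairs receive planted direct edges from the seed to a fraction of each
disease pathway's members, creating recoverable excess overlap between that
seed's network neighborhood and the disease's pathways.

Sub-seeds for each component are derived from the master seed by fixed
offsets, so a bundle is reproducible bit-for-bit from its config.
"""

from __future__ import annotations

import math
from dataclasses import asdict, dataclass

import numpy as np

from .io_formats import DiseaseCatalog, InteractionNetwork, PathwayCollection

# fixed sub-seed offsets per component (avoids seed collisions)
_SEED_NETWORK = 1
_SEED_PATHWAYS = 2
_SEED_CATALOG = 3
_SEED_PLANT = 4


@dataclass(frozen=True)
class SyntheticConfig:
    """Knobs for :func:`generate_study`; defaults give minutes-scale tests."""

    n_genes: int = 2000
    mean_degree: float = 20.0
    confidence_beta_params: tuple[float, float] = (2.0, 2.0)
    n_pathways: int = 60
    pathway_size_range: tuple[int, int] = (20, 100)
    n_diseases: int = 20
    pathways_per_disease_range: tuple[int, int] = (1, 3)
    n_seeds: int = 10
    planted_fraction: float = 0.5
    planted_confidence: float = 0.9
    n_truth_pairs: int = 2
    n_truth_diseases: int = 2
    master_seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_genes", "n_pathways", "n_diseases", "n_seeds"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be positive")
        if not (0.0 <= self.planted_fraction <= 1.0):
            raise ValueError("planted_fraction must be in [0, 1]")
        if not (0.0 <= self.planted_confidence <= 1.0):
            raise ValueError("planted_confidence must be in [0, 1]")
        for name in ("pathway_size_range", "pathways_per_disease_range"):
            lo, hi = getattr(self, name)
            if lo > hi or lo < 1:
                raise ValueError(f"{name} must be a non-empty positive interval")
        a, b = self.confidence_beta_params
        if a <= 0 or b <= 0:
            raise ValueError("confidence_beta_params must be positive")
        if self.n_truth_pairs < 0 or self.n_truth_diseases < 0:
            raise ValueError("truth counts must be non-negative")
        if self.n_truth_pairs > 0:
            if self.n_truth_diseases < 1:
                raise ValueError("n_truth_diseases must be >= 1 when truth pairs exist")
            if self.n_truth_diseases > self.n_diseases:
                raise ValueError("n_truth_diseases exceeds n_diseases")
            if self.n_truth_pairs > self.n_seeds * self.n_truth_diseases:
                raise ValueError("n_truth_pairs exceeds n_seeds x n_truth_diseases")


@dataclass
class StudyBundle:
    network: InteractionNetwork
    pathways: PathwayCollection
    catalog: DiseaseCatalog
    seed_genes: list[str]
    truth: set[tuple[str, str]]  # (seed gene, disease)
    master_seed: int
    config: SyntheticConfig | None = None


def generate_universe(n_genes: int, seed: int = 0) -> list[str]:
    """Deterministic gene symbols G000001..; ``seed`` reserved for shuffling."""
    if n_genes < 1:
        raise ValueError(f"n_genes must be >= 1, got {n_genes}")
    return [f"G{i:06d}" for i in range(1, n_genes + 1)]


def generate_network(
    universe: list[str],
    mean_degree: float,
    confidence_beta_params: tuple[float, float] = (2.0, 2.0),
    seed: int = 0,
) -> InteractionNetwork:
    """Erdos-Renyi network over the universe with Beta-distributed confidences.

    Edge probability is mean_degree / (n_genes - 1); every universe gene is a
    node even when isolated.
    """
    n = len(universe)
    if n < 1:
        raise ValueError("universe must be non-empty")
    if mean_degree < 0:
        raise ValueError("mean_degree must be non-negative")
    if n > 1 and mean_degree >= n - 1:
        raise ValueError(f"mean_degree {mean_degree} infeasible for {n} genes")

    net = InteractionNetwork.from_edges([], nodes=universe)
    if n < 2 or mean_degree == 0:
        return net
    p = mean_degree / (n - 1)
    rng = np.random.default_rng(seed)
    iu, ju = np.triu_indices(n, k=1)
    mask = rng.random(iu.size) < p
    a_idx, b_idx = iu[mask], ju[mask]
    confs = rng.beta(*confidence_beta_params, size=a_idx.size)
    for ai, bi, c in zip(a_idx, b_idx, confs):
        net.set_edge(universe[ai], universe[bi], float(c))
    return net


def generate_pathways(
    universe: list[str],
    n_pathways: int,
    size_range: tuple[int, int] = (20, 100),
    seed: int = 0,
) -> PathwayCollection:
    """Uniform random gene subsets with sizes uniform on ``size_range``."""
    lo, hi = size_range
    if lo > hi or lo < 1:
        raise ValueError(f"size_range {size_range} must be a non-empty positive interval")
    if hi > len(universe):
        raise ValueError(f"size_range {size_range} exceeds universe of {len(universe)} genes")
    if n_pathways < 0:
        raise ValueError("n_pathways must be non-negative")
    rng = np.random.default_rng(seed)
    collection = PathwayCollection()
    for k in range(1, n_pathways + 1):
        size = int(rng.integers(lo, hi + 1))
        members = [universe[i] for i in rng.choice(len(universe), size=size, replace=False)]
        collection.add(f"PW{k:04d}", f"synthetic pathway {k}", members)
    return collection


def plant_signal(
    network: InteractionNetwork,
    seed_gene: str,
    pathway: frozenset[str] | set[str],
    planted_fraction: float,
    planted_confidence: float,
    seed: int = 0,
) -> InteractionNetwork:
    """Return a copy with direct seed->pathway edges added or raised.

    A uniformly chosen ceil(planted_fraction x |pathway|) subset of pathway
    members receives an edge from the seed at confidence
    max(existing, planted_confidence); all other edges are untouched.
    Planting twice with the same arguments is idempotent.
    """
    if seed_gene not in network:
        raise KeyError(f"seed gene {seed_gene!r} not present in the network")
    if not pathway:
        raise ValueError("pathway must be non-empty")
    if not (0.0 <= planted_fraction <= 1.0):
        raise ValueError("planted_fraction must be in [0, 1]")
    out = network.copy()
    if planted_fraction == 0:
        return out
    members = sorted(pathway)
    n_pick = math.ceil(planted_fraction * len(members))
    rng = np.random.default_rng(seed)
    chosen = [members[i] for i in rng.choice(len(members), size=n_pick, replace=False)]
    for gene in chosen:
        if gene == seed_gene:
            continue  # no self-loops
        if gene not in out:
            out.add_node(gene)
        existing = out.confidence(seed_gene, gene)
        conf = planted_confidence if existing is None else max(existing, planted_confidence)
        out.set_edge(seed_gene, gene, conf)
    return out


def generate_study(config: SyntheticConfig) -> StudyBundle:
    """Compose universe, network, pathways, catalog, seeds and planted truth.

    Diseases are assigned disjoint pathway groups.  The first
    ``n_truth_diseases`` diseases are category "nervous" and receive the
    planted signal; the remaining diseases alternate between "metabolic" and
    "null".  Truth pairs enumerate the (seed, nervous disease) grid
    disease-major, so n_truth_pairs = 2 x n_truth_diseases plants two
    distinct seeds into every nervous disease; every pathway of a truth
    disease is planted from its paired seed.
    """
    cfg = config
    ms = cfg.master_seed
    universe = generate_universe(cfg.n_genes, ms)
    network = generate_network(
        universe, cfg.mean_degree, cfg.confidence_beta_params, ms + _SEED_NETWORK
    )
    pathways = generate_pathways(
        universe, cfg.n_pathways, cfg.pathway_size_range, ms + _SEED_PATHWAYS
    )

    rng = np.random.default_rng(ms + _SEED_CATALOG)
    lo, hi = cfg.pathways_per_disease_range
    group_sizes = [int(rng.integers(lo, hi + 1)) for _ in range(cfg.n_diseases)]
    if sum(group_sizes) > cfg.n_pathways:
        raise ValueError(
            f"disease groups need {sum(group_sizes)} pathways but only "
            f"{cfg.n_pathways} exist; increase n_pathways"
        )
    pathway_ids = sorted(pathways.ids())
    order = rng.permutation(len(pathway_ids))
    cursor = 0
    catalog = DiseaseCatalog()
    disease_names = [f"D{k:04d}" for k in range(1, cfg.n_diseases + 1)]
    for k, (disease, size) in enumerate(zip(disease_names, group_sizes)):
        if k < cfg.n_truth_diseases and cfg.n_truth_pairs > 0:
            category = "nervous"
        else:
            category = "metabolic" if k % 2 == 0 else "null"
        for j in range(size):
            catalog.add(disease, category, pathway_ids[order[cursor + j]])
        cursor += size

    seed_genes = [universe[i] for i in rng.choice(len(universe), size=cfg.n_seeds, replace=False)]

    truth: set[tuple[str, str]] = set()
    for k in range(cfg.n_truth_pairs):
        # grid enumeration keeps pairs distinct up to n_seeds x n_truth_diseases
        seed_idx = k // cfg.n_truth_diseases
        disease_idx = k % cfg.n_truth_diseases
        truth.add((seed_genes[seed_idx], disease_names[disease_idx]))

    for idx, (seed_gene, disease) in enumerate(sorted(truth)):
        for pid in catalog.pathway_ids(disease):
            network = plant_signal(
                network,
                seed_gene,
                pathways.genes(pid),
                cfg.planted_fraction,
                cfg.planted_confidence,
                seed=ms + _SEED_PLANT + idx * 101 + _stable_index(pid),
            )

    return StudyBundle(
        network=network,
        pathways=pathways,
        catalog=catalog,
        seed_genes=seed_genes,
        truth=truth,
        master_seed=ms,
        config=cfg,
    )


def _stable_index(pathway_id: str) -> int:
    digits = "".join(ch for ch in pathway_id if ch.isdigit())
    return int(digits) if digits else 0


def config_to_dict(config: SyntheticConfig) -> dict:
    return asdict(config)


def config_from_dict(data: dict) -> SyntheticConfig:
    kwargs = dict(data)
    for key in ("confidence_beta_params", "pathway_size_range", "pathways_per_disease_range"):
        if key in kwargs and kwargs[key] is not None:
            kwargs[key] = tuple(kwargs[key])
    return SyntheticConfig(**kwargs)
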