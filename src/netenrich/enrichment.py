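"""Over-representation p-values calibrated against size-matched null ensembles.

The uncorrected statistic is the one-sided hypergeometric upper tail
(Fisher's exact over-representation side).  Calibration draws ``n_null``
random gene sets matched to each test set's size and reports, per pathway,
the fraction of null uncorrected p-values that are <= the observed one.
"""

from __future__ import annotations

import logging
import zlib
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.stats import hypergeom

from .interactome import Interactome
from .io_formats import PathwayCollection

logger = logging.getLogger(__name__)

DEFAULT_N_NULL = 1000


_TINY = 5e-324  # smallest positive float64; keeps p-values in (0, 1]


def _log_tail_table(universe: int, pathway: int, set_size: int) -> np.ndarray:
    """log P(X >= k) for k = 0..min(pathway, set_size), by reverse log-sum-exp.

    Accumulating the pmf in log space keeps far tails meaningful for
    universes up to 1e6 instead of cancelling against 1.
    """
    support = np.arange(0, min(pathway, set_size) + 1)
    logpmf = hypergeom.logpmf(support, universe, pathway, set_size)
    log_tail = np.logaddexp.accumulate(logpmf[::-1])[::-1]
    return np.minimum(log_tail, 0.0)


def overlap_pvalue(set_size: int, pathway_size: int, overlap: int, universe_size: int) -> float:
    """P(X >= overlap) for X ~ Hypergeometric(universe, pathway, set draws).

    Returns 1.0 when overlap == 0 (the certain event).  Computed by
    log-space accumulation of the pmf; results below float64 range are
    clamped to the smallest positive float so the value stays in (0, 1].
    """
    _validate_counts(set_size, pathway_size, overlap, universe_size)
    if overlap == 0:
        return 1.0
    log_tail = _log_tail_table(universe_size, pathway_size, set_size)
    return max(float(np.exp(log_tail[overlap])), _TINY)


def _validate_counts(set_size: int, pathway_size: int, overlap: int, universe_size: int) -> None:
    if universe_size < 1:
        raise ValueError(f"universe_size must be >= 1, got {universe_size}")
    if not (0 <= pathway_size <= universe_size):
        raise ValueError(f"pathway_size {pathway_size} outside [0, {universe_size}]")
    if not (0 <= set_size <= universe_size):
        raise ValueError(f"set_size {set_size} outside [0, {universe_size}]")
    if not (0 <= overlap <= min(pathway_size, set_size)):
        raise ValueError(
            f"overlap {overlap} outside [0, min({pathway_size}, {set_size})]"
        )
    # overlap cannot be smaller than forced by set sizes
    if overlap < set_size + pathway_size - universe_size:
        raise ValueError(
            f"overlap {overlap} below the forced minimum "
            f"{set_size + pathway_size - universe_size}"
        )


def sample_null_sets(
    universe: Sequence[str], set_size: int, n_sets: int, seed: int | np.random.SeedSequence
) -> list[frozenset[str]]:
    """Draw ``n_sets`` uniform without-replacement gene sets of ``set_size``."""
    if set_size > len(universe):
        raise ValueError(f"set_size {set_size} exceeds universe size {len(universe)}")
    if n_sets < 1:
        raise ValueError(f"n_sets must be >= 1, got {n_sets}")
    rng = np.random.default_rng(seed)
    universe = list(universe)
    return [
        frozenset(universe[i] for i in rng.choice(len(universe), size=set_size, replace=False))
        for _ in range(n_sets)
    ]


def empirical_pvalue(
    observed_p: float, null_p: Sequence[float], pseudocount: bool = False
) -> float:
    """Fraction of null p-values <= the observed p-value.

    With ``pseudocount=True`` returns (count+1)/(n+1) instead, which can
    never be exactly zero.  The default matches the literal <= rule, whose
    zeros are handled downstream by the zero floor.
    """
    null = np.asarray(null_p, dtype=float)
    if null.size == 0:
        raise ValueError("null_p must be non-empty")
    if np.any((null < 0) | (null > 1)):
        raise ValueError("null p-values must lie in [0, 1]")
    count = int(np.count_nonzero(null <= observed_p))
    if pseudocount:
        return (count + 1) / (null.size + 1)
    return count / null.size


def derive_subseed(master_seed: int, name: str) -> np.random.SeedSequence:
    """Deterministic per-interactome seed: master seed plus a CRC of the name."""
    return np.random.SeedSequence([int(master_seed), zlib.crc32(name.encode("utf-8"))])


@dataclass
class NullEnsemble:
    """Size-matched null sets and their per-pathway uncorrected p-values."""

    n_sets: int
    set_size: int
    seed: int
    null_p: dict[str, np.ndarray] = field(default_factory=dict)  # pathway id -> (n_sets,)


@dataclass
class EnrichmentMatrix:
    """Complete empirical/uncorrected p-value matrix over interactome x pathway."""

    rows: list[str]  # interactome names
    cols: list[str]  # pathway ids
    empirical_p: np.ndarray  # (n_rows, n_cols)
    uncorrected_p: np.ndarray
    overlap: np.ndarray  # integer overlap counts
    n_null: int
    seed: int
    null_ensembles: dict[str, NullEnsemble] = field(default_factory=dict)

    def empirical_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.empirical_p, index=self.rows, columns=self.cols)

    def uncorrected_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.uncorrected_p, index=self.rows, columns=self.cols)

    def to_long_frame(self) -> pd.DataFrame:
        records = []
        for i, name in enumerate(self.rows):
            for j, pid in enumerate(self.cols):
                records.append(
                    (name, pid, int(self.overlap[i, j]),
                     self.uncorrected_p[i, j], self.empirical_p[i, j])
                )
        return pd.DataFrame(
            records,
            columns=["interactome", "pathway", "overlap", "uncorrected_p", "empirical_p"],
        )

    @classmethod
    def from_long_frame(cls, frame: pd.DataFrame, n_null: int = 0, seed: int = 0):
        required = {"interactome", "pathway", "uncorrected_p", "empirical_p"}
        missing = required - set(frame.columns)
        if missing:
            raise ValueError(f"long matrix table missing column(s): {sorted(missing)}")
        rows = list(dict.fromkeys(frame["interactome"]))
        cols = list(dict.fromkeys(frame["pathway"]))
        shape = (len(rows), len(cols))
        emp = np.full(shape, np.nan)
        unc = np.full(shape, np.nan)
        ovl = np.zeros(shape, dtype=int)
        ri = {r: i for i, r in enumerate(rows)}
        ci = {c: j for j, c in enumerate(cols)}
        for rec in frame.itertuples(index=False):
            i, j = ri[rec.interactome], ci[rec.pathway]
            emp[i, j] = rec.empirical_p
            unc[i, j] = rec.uncorrected_p
            if hasattr(rec, "overlap"):
                ovl[i, j] = int(rec.overlap)
        if np.isnan(emp).any():
            raise ValueError("long matrix table does not cover the full row x column grid")
        return cls(rows, cols, emp, unc, ovl, n_null, seed)


def enrich_matrix(
    interactomes: Sequence[Interactome],
    pathways: PathwayCollection,
    universe: Sequence[str],
    n_null: int = DEFAULT_N_NULL,
    master_seed: int = 0,
    pseudocount: bool = False,
) -> EnrichmentMatrix:
    """Empirical p-value matrix over all interactome x pathway pairs.

    Each interactome gets its own size-matched null ensemble whose seed is
    derived from ``master_seed`` and the interactome name, so the result is
    independent of interactome ordering.  Genes outside the universe are
    dropped from both interactomes and pathways (with a logged count); an
    interactome left empty after restriction is an error.
    """
    universe_list = sorted(set(universe))
    uindex = {g: i for i, g in enumerate(universe_list)}
    m = len(universe_list)
    if m == 0:
        raise ValueError("universe must be non-empty")

    pathway_ids = sorted(pathways.ids())
    # pathway membership matrix over the universe
    pmat = np.zeros((len(pathway_ids), m), dtype=bool)
    n_dropped_pw = 0
    for j, pid in enumerate(pathway_ids):
        genes = pathways.genes(pid)
        kept = [uindex[g] for g in genes if g in uindex]
        n_dropped_pw += len(genes) - len(kept)
        pmat[j, kept] = True
    if n_dropped_pw:
        logger.info("enrich_matrix: dropped %d pathway gene(s) outside the universe", n_dropped_pw)
    pathway_sizes = pmat.sum(axis=1)

    names = [ia.name for ia in interactomes]
    if len(set(names)) != len(names):
        raise ValueError("interactome names must be unique")

    n_rows, n_cols = len(interactomes), len(pathway_ids)
    emp = np.zeros((n_rows, n_cols))
    unc = np.zeros((n_rows, n_cols))
    ovl = np.zeros((n_rows, n_cols), dtype=int)
    ensembles: dict[str, NullEnsemble] = {}

    for i, ia in enumerate(interactomes):
        kept_idx = np.array(sorted(uindex[g] for g in ia.members if g in uindex), dtype=int)
        n_dropped = len(ia.members) - kept_idx.size
        if n_dropped:
            logger.info(
                "enrich_matrix: interactome %s: dropped %d member(s) outside the universe",
                ia.name, n_dropped,
            )
        if kept_idx.size == 0:
            raise ValueError(f"interactome {ia.name!r} is empty after universe restriction")
        set_size = int(kept_idx.size)

        subseed = derive_subseed(master_seed, ia.name)
        rng = np.random.default_rng(subseed)
        null_idx = np.stack(
            [rng.choice(m, size=set_size, replace=False) for _ in range(n_null)]
        )  # (n_null, set_size)

        obs_overlap = pmat[:, kept_idx].sum(axis=1)  # (n_cols,)
        null_overlap = pmat[:, null_idx].sum(axis=2)  # (n_cols, n_null)

        ens = NullEnsemble(n_sets=n_null, set_size=set_size, seed=int(master_seed))
        for j in range(n_cols):
            k = int(pathway_sizes[j])
            p_both = _tail_p_vec(np.append(null_overlap[j], obs_overlap[j]), m, k, set_size)
            p_null, p_obs = p_both[:-1], float(p_both[-1])
            ens.null_p[pathway_ids[j]] = p_null
            unc[i, j] = p_obs
            ovl[i, j] = int(obs_overlap[j])
            emp[i, j] = empirical_pvalue(p_obs, p_null, pseudocount=pseudocount)
        ensembles[ia.name] = ens

    return EnrichmentMatrix(
        rows=names,
        cols=pathway_ids,
        empirical_p=emp,
        uncorrected_p=unc,
        overlap=ovl,
        n_null=n_null,
        seed=int(master_seed),
        null_ensembles=ensembles,
    )


def _tail_p_vec(overlaps: np.ndarray, universe: int, pathway: int, set_size: int) -> np.ndarray:
    """Tail p per overlap; shares the log-tail table so equal overlaps tie exactly."""
    log_tail = _log_tail_table(universe, pathway, set_size)
    p = np.maximum(np.exp(log_tail[np.asarray(overlaps, dtype=int)]), _TINY)
    p[np.asarray(overlaps) == 0] = 1.0
    return p
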