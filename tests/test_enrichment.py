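import itertools
import math

import numpy as np
import pytest
from scipy.stats import kstest

from netenrich.enrichment import (
    EnrichmentMatrix,
    derive_subseed,
    empirical_pvalue,
    enrich_matrix,
    overlap_pvalue,
    sample_null_sets,
)
from netenrich.interactome import Interactome
from netenrich.io_formats import PathwayCollection


def enumeration_tail(set_size, pathway_size, overlap, universe_size):
    """Exact P(X >= overlap) by enumerating every set_size-subset of the universe."""
    universe = list(range(universe_size))
    pathway = set(range(pathway_size))
    hits = total = 0
    for subset in itertools.combinations(universe, set_size):
        total += 1
        if len(pathway.intersection(subset)) >= overlap:
            hits += 1
    return hits / total


class TestOverlapPvalue:
    def test_four_of_five_in_ten(self):
        # 5/210 by enumeration of all 210 4-subsets of a 10-gene universe
        expected = enumeration_tail(4, 5, 4, 10)
        assert expected == pytest.approx(5 / 210)
        assert overlap_pvalue(4, 5, 4, 10) == pytest.approx(expected, rel=1e-10)

    def test_three_of_six_in_twenty(self):
        # C(6,3)C(14,2) + C(6,4)C(14,1) + C(6,5)C(14,0) over C(20,5) = 2036/15504
        assert overlap_pvalue(5, 6, 3, 20) == pytest.approx(2036 / 15504, rel=1e-10)

    def test_zero_overlap_is_certain(self):
        assert overlap_pvalue(10, 5, 0, 100) == 1.0

    def test_enumeration_oracle_small_universes(self):
        for universe in range(1, 10):
            for pathway in range(universe + 1):
                for set_size in range(universe + 1):
                    lo = max(0, set_size + pathway - universe)
                    hi = min(set_size, pathway)
                    for overlap in range(lo, hi + 1):
                        expected = enumeration_tail(set_size, pathway, overlap, universe)
                        got = overlap_pvalue(set_size, pathway, overlap, universe)
                        assert got == pytest.approx(expected, rel=1e-10), (
                            universe, pathway, set_size, overlap,
                        )

    def test_large_universe_stability(self):
        # far tails stay positive instead of cancelling against 1
        p = overlap_pvalue(300, 500, 60, 10**6)
        assert 0.0 < p < 1e-100
        # and deep underflow clamps to the smallest positive float, not 0
        assert overlap_pvalue(300, 500, 300, 10**6) > 0.0

    def test_matches_scipy_sf_at_moderate_scale(self):
        from scipy.stats import hypergeom

        for set_size, pathway, overlap, universe in [
            (300, 60, 12, 2000), (100, 500, 40, 10000), (50, 50, 5, 200),
        ]:
            expected = hypergeom.sf(overlap - 1, universe, pathway, set_size)
            assert overlap_pvalue(set_size, pathway, overlap, universe) == pytest.approx(
                expected, rel=1e-10
            )

    def test_invariant_violations(self):
        with pytest.raises(ValueError):
            overlap_pvalue(5, 4, 5, 10)  # overlap > pathway
        with pytest.raises(ValueError):
            overlap_pvalue(11, 5, 2, 10)  # set > universe
        with pytest.raises(ValueError):
            overlap_pvalue(6, 6, 1, 10)  # overlap below forced minimum of 2


class TestSampleNullSets:
    def test_full_universe_sets(self):
        universe = ["A", "B", "C"]
        sets = sample_null_sets(universe, 3, 5, seed=0)
        assert all(s == frozenset(universe) for s in sets)

    def test_sizes_and_membership(self):
        universe = [f"G{i}" for i in range(100)]
        sets = sample_null_sets(universe, 10, 20, seed=1)
        assert len(sets) == 20
        assert all(len(s) == 10 and s <= set(universe) for s in sets)

    def test_inclusion_frequency_binomial_oracle(self):
        # inclusion prob per gene = 300/2000 = 0.15; check within 4 SE over 1000
        # draws (fixed seed: the max over 2000 genes sits near 4 SE by design)
        universe = [f"G{i}" for i in range(2000)]
        n_sets, set_size = 1000, 300
        sets = sample_null_sets(universe, set_size, n_sets, seed=3)
        p = set_size / len(universe)
        se = math.sqrt(p * (1 - p) / n_sets)
        counts = {}
        for s in sets:
            for g in s:
                counts[g] = counts.get(g, 0) + 1
        freqs = np.array([counts.get(g, 0) / n_sets for g in universe])
        assert np.all(np.abs(freqs - p) <= 4 * se + 1e-12)

    def test_deterministic(self):
        universe = [f"G{i}" for i in range(50)]
        assert sample_null_sets(universe, 5, 10, seed=3) == sample_null_sets(
            universe, 5, 10, seed=3
        )

    def test_oversized_request_rejected(self):
        with pytest.raises(ValueError):
            sample_null_sets(["A"], 2, 1, seed=0)


class TestEmpiricalPvalue:
    def test_direct_count(self):
        assert empirical_pvalue(0.2, [0.1, 0.2, 0.3, 0.4]) == 0.5

    def test_observed_at_or_above_max(self):
        assert empirical_pvalue(0.9, [0.1, 0.2]) == 1.0

    def test_observed_below_min_is_zero(self):
        assert empirical_pvalue(0.001, [0.1, 0.2]) == 0.0

    def test_pseudocount_variant(self):
        assert empirical_pvalue(0.2, [0.1, 0.2, 0.3, 0.4], pseudocount=True) == 3 / 5
        assert empirical_pvalue(0.0, [0.1], pseudocount=True) == 0.5

    def test_empty_null_rejected(self):
        with pytest.raises(ValueError):
            empirical_pvalue(0.5, [])

    def test_monotone_in_observed(self):
        rng = np.random.default_rng(4)
        null = rng.random(200)
        obs = np.sort(rng.random(50))
        values = [empirical_pvalue(o, null) for o in obs]
        assert all(a <= b for a, b in zip(values, values[1:]))

    def test_resolution_bound(self):
        # nonzero empirical p is at least 1/n_null
        rng = np.random.default_rng(5)
        null = rng.random(250)
        for obs in rng.random(50):
            p = empirical_pvalue(obs, null)
            assert p == 0.0 or p >= 1 / 250


def _pathways(**kwargs):
    pc = PathwayCollection()
    for pid, genes in kwargs.items():
        pc.add(pid, pid, genes)
    return pc


class TestEnrichMatrix:
    def test_interactome_identical_to_pathway_floors_at_zero(self):
        universe = [f"G{i:04d}" for i in range(1000)]
        pathway_genes = universe[:50]
        pc = _pathways(P1=pathway_genes)
        ia = Interactome("I1", frozenset(pathway_genes), None)
        matrix = enrich_matrix([ia], pc, universe, n_null=1000, master_seed=0)
        assert matrix.empirical_p[0, 0] == 0.0
        assert matrix.uncorrected_p[0, 0] < 1e-50

    def test_disjoint_interactome_gives_p_one(self):
        universe = [f"G{i:04d}" for i in range(100)]
        pc = _pathways(P1=universe[:10])
        ia = Interactome("I1", frozenset(universe[50:60]), None)
        matrix = enrich_matrix([ia], pc, universe, n_null=100, master_seed=0)
        assert matrix.uncorrected_p[0, 0] == 1.0
        assert matrix.empirical_p[0, 0] == 1.0

    def test_deterministic_and_row_order_invariant(self):
        universe = [f"G{i:04d}" for i in range(200)]
        pc = _pathways(P1=universe[:20], P2=universe[30:70])
        ia1 = Interactome("I1", frozenset(universe[:30]), None)
        ia2 = Interactome("I2", frozenset(universe[10:45]), None)
        m_a = enrich_matrix([ia1, ia2], pc, universe, n_null=50, master_seed=9)
        m_b = enrich_matrix([ia1, ia2], pc, universe, n_null=50, master_seed=9)
        assert np.array_equal(m_a.empirical_p, m_b.empirical_p)
        # sub-seeds derive from names, so reordering rows permutes but preserves values
        m_c = enrich_matrix([ia2, ia1], pc, universe, n_null=50, master_seed=9)
        assert np.array_equal(m_c.empirical_p[::-1], m_a.empirical_p)

    def test_out_of_universe_members_dropped(self, caplog):
        universe = [f"G{i:04d}" for i in range(100)]
        pc = _pathways(P1=universe[:10])
        ia = Interactome("I1", frozenset(universe[:5] + ["ALIEN"]), None)
        with caplog.at_level("INFO"):
            matrix = enrich_matrix([ia], pc, universe, n_null=50, master_seed=0)
        assert "dropped 1 member" in caplog.text
        assert matrix.overlap[0, 0] == 5

    def test_empty_after_restriction_rejected(self):
        universe = [f"G{i:04d}" for i in range(100)]
        pc = _pathways(P1=universe[:10])
        ia = Interactome("I1", frozenset(["ALIEN"]), None)
        with pytest.raises(ValueError, match="empty after universe restriction"):
            enrich_matrix([ia], pc, universe, n_null=10, master_seed=0)

    def test_matrix_complete_and_bounded(self, tiny_bundle):
        universe = sorted(tiny_bundle.network.nodes)
        ia = Interactome("T", frozenset(universe[:40]), None)
        matrix = enrich_matrix([ia], tiny_bundle.pathways, universe, n_null=40, master_seed=1)
        assert matrix.empirical_p.shape == (1, len(tiny_bundle.pathways))
        assert np.all((matrix.empirical_p >= 0) & (matrix.empirical_p <= 1))
        nonzero = matrix.empirical_p[matrix.empirical_p > 0]
        assert np.all(nonzero >= 1 / 40 - 1e-12)

    def test_long_frame_round_trip(self):
        universe = [f"G{i:04d}" for i in range(100)]
        pc = _pathways(P1=universe[:10], P2=universe[20:40])
        ia = Interactome("I1", frozenset(universe[5:25]), None)
        matrix = enrich_matrix([ia], pc, universe, n_null=20, master_seed=2)
        back = EnrichmentMatrix.from_long_frame(matrix.to_long_frame(), n_null=20)
        assert back.rows == matrix.rows and back.cols == matrix.cols
        assert np.array_equal(back.empirical_p, matrix.empirical_p)
        assert np.array_equal(back.uncorrected_p, matrix.uncorrected_p)
        assert np.array_equal(back.overlap, matrix.overlap)

    def test_subseed_depends_on_name_and_master(self):
        assert derive_subseed(1, "A").entropy != derive_subseed(1, "B").entropy
        assert derive_subseed(1, "A").entropy != derive_subseed(2, "A").entropy


def test_null_calibration_ks(tiny_bundle):
    """Unplanted empirical p-values pool to ~Uniform[0,1].

    Independent (random set, pathway) pairs: one test set per pathway, each
    with its own null ensemble; sizes vary so discreteness atoms do not align.
    """
    universe = sorted(tiny_bundle.network.nodes)
    rng = np.random.default_rng(123)
    interactomes = []
    for i in range(len(tiny_bundle.pathways)):
        size = int(rng.integers(60, 180))
        members = sample_null_sets(universe, size, 1, seed=int(rng.integers(2**31)))[0]
        interactomes.append(Interactome(f"T{i:02d}", members, None))
    matrix = enrich_matrix(
        interactomes, tiny_bundle.pathways, universe, n_null=150, master_seed=77
    )
    pooled = np.diagonal(matrix.empirical_p)
    assert pooled.size >= 12
    _, p_value = kstest(pooled, "uniform")
    assert p_value > 0.01
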