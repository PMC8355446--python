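"""Enrichment statistics, empirical p-values, and the full pipeline."""

import numpy as np
import pytest

from proximatch.annotate import (GeneAnnotation, WindowSpec, annotate_snps,
                                 build_panel_index)
from proximatch.enrichment import (empirical_pvalue, gene_member_mask,
                                   nearest_null_counts, run_enrichment,
                                   run_sensitivity, stat_nearest, stat_window,
                                   window_null_counts)
from proximatch.io_formats import Classification, SnpRecord
from proximatch.matching import MatchCriteria, build_pools, sample_null_sets
from proximatch.simulate import SimConfig, simulate_inputs

from conftest import random_genes, random_snp


def brute_stats(prox, genes, w=None):
    """Double-loop oracle for both statistics."""
    n_snps, hit = 0, set()
    for p in prox:
        near = set()
        if w is None:
            if p.nearest_gene is not None:
                near = {p.nearest_gene}
        else:
            near = set(p.window_genes[w])
        inter = {g for g in near for target in genes if g == target}
        if inter:
            n_snps += 1
            hit |= inter
    return len(hit), n_snps


class TestStatistics:
    def test_empty_gene_set_gives_zero(self, rng, small_annotation):
        prox = annotate_snps([random_snp(rng, i) for i in range(5)],
                             small_annotation, WindowSpec((1_000,)))
        s = stat_nearest(prox, set())
        assert (s.n_genes, s.n_snps) == (0, 0)

    def test_gene_just_outside_window_not_counted(self):
        from proximatch.annotate import GeneRecord
        ann = GeneAnnotation([GeneRecord("G", "1", 1_102, 1_200)])
        prox = annotate_snps([SnpRecord("rs1", "1", 1_001, 0.2)], ann,
                             WindowSpec((100,)))
        s = stat_window(prox, {"G"}, 100)
        assert (s.n_genes, s.n_snps) == (0, 0)

    def test_missing_window_annotation_rejected(self, rng, small_annotation):
        prox = annotate_snps([random_snp(rng, 0)], small_annotation,
                             WindowSpec((1_000,)))
        with pytest.raises(ValueError):
            stat_window(prox, {"ALPHA"}, 5_000)

    def test_agrees_with_double_loop_on_random_fixtures(self, rng):
        windows = WindowSpec((500, 2_000))
        for _ in range(200):
            genes = random_genes(rng, int(rng.integers(1, 9)))
            ann = GeneAnnotation(genes)
            prox = annotate_snps([random_snp(rng, i) for i in range(6)],
                                 ann, windows)
            labels = {g.symbol for g in genes
                      if rng.random() < 0.4} | {"ABSENT"}
            s = stat_nearest(prox, labels)
            assert (s.n_genes, s.n_snps) == brute_stats(prox, labels)
            for w in windows.sizes:
                s = stat_window(prox, labels, w)
                assert (s.n_genes, s.n_snps) == brute_stats(prox, labels, w)

    def test_statistics_monotone_in_window_size(self, rng):
        windows = WindowSpec((200, 1_000, 4_000))
        for _ in range(50):
            genes = random_genes(rng, 6)
            ann = GeneAnnotation(genes)
            prox = annotate_snps([random_snp(rng, i) for i in range(8)],
                                 ann, windows)
            labels = {g.symbol for g in genes if rng.random() < 0.5}
            stats = [stat_window(prox, labels, w) for w in windows.sizes]
            for a, b in zip(stats, stats[1:]):
                assert a.n_genes <= b.n_genes
                assert a.n_snps <= b.n_snps


class TestEmpiricalPvalue:
    def test_half_of_nulls_at_least_observed(self):
        ep = empirical_pvalue(3, [1, 2, 3, 4])
        assert ep.p == 0.5

    def test_ties_count_toward_numerator(self):
        assert empirical_pvalue(2, [2, 2]).p == 1.0

    def test_all_nulls_reaching_observed_formats_as_one(self):
        ep = empirical_pvalue(0, [1] * 100)
        assert ep.p == 1.0
        assert ep.formatted == "1.00E+00"

    def test_zero_exceedances_floor_rendering(self):
        ep = empirical_pvalue(10, [0] * 10_000)
        assert ep.p == 0.0
        assert ep.formatted == "<1.00E-04"

    def test_single_list_degenerate(self):
        assert empirical_pvalue(5, [1]).formatted == "<1.00E+00"
        assert empirical_pvalue(0, [1]).p == 1.0

    def test_plus_one_estimator_never_zero(self):
        ep = empirical_pvalue(10, [0] * 999, estimator="plus_one")
        assert ep.p == pytest.approx(1 / 1000)
        assert ep.formatted == "1.00E-03"


class TestNullCountHelpers:
    def _setup(self, rng, n_panel=60, n_index=4):
        genes = random_genes(rng, 8, max_pos=50_000)
        ann = GeneAnnotation(genes)
        windows = WindowSpec((2_000, 8_000))
        panel = [random_snp(rng, i, max_pos=50_000) for i in range(n_panel)]
        pidx = build_panel_index(panel, ann, windows)
        matrix = rng.integers(0, n_panel, size=(30, n_index))
        labels = {g.symbol for g in genes if rng.random() < 0.5}
        member = gene_member_mask(ann, labels)
        return ann, pidx, matrix, labels, member

    def test_nearest_counts_match_per_row_statistics(self, rng):
        for _ in range(20):
            ann, pidx, matrix, labels, member = self._setup(rng)
            gc, sc = nearest_null_counts(matrix, pidx, member)
            for r in range(matrix.shape[0]):
                prox = [pidx.proximity(int(i)) for i in matrix[r]]
                s = stat_nearest(prox, labels)
                assert (gc[r], sc[r]) == (s.n_genes, s.n_snps)

    def test_window_counts_match_per_row_statistics(self, rng):
        for _ in range(20):
            ann, pidx, matrix, labels, member = self._setup(rng)
            for w in (2_000, 8_000):
                gc, sc = window_null_counts(matrix, pidx, w, member)
                for r in range(matrix.shape[0]):
                    prox = [pidx.proximity(int(i)) for i in matrix[r]]
                    s = stat_window(prox, labels, w)
                    assert (gc[r], sc[r]) == (s.n_genes, s.n_snps)


@pytest.fixture(scope="module")
def sim_null():
    cfg = SimConfig(n_chroms=4, chrom_length=20_000_000, n_genes=400,
                    n_panel_snps=20_000, n_index_snps=25,
                    planted_fraction=0.0, n_dd_genes=60, seed=11)
    return simulate_inputs(cfg)


class TestRunEnrichment:
    def test_deterministic_given_seed(self, sim_null):
        ann, panel, gl, index = sim_null
        windows = WindowSpec((50_000,))
        kwargs = dict(n_lists=200, seed=5, include_nearest=False)
        a = run_enrichment(index, ann, gl, panel, windows, **kwargs)
        b = run_enrichment(index, ann, gl, panel, windows, **kwargs)
        for ra, rb in zip(a, b):
            assert ra.p_genes.p == rb.p_genes.p
            assert np.array_equal(ra.p_genes.null_values, rb.p_genes.null_values)
            assert ra.p_snps.formatted == rb.p_snps.formatted

    def test_full_run_covers_all_lists_and_modes(self, sim_null):
        ann, panel, gl, index = sim_null
        windows = WindowSpec((50_000, 150_000))
        res = run_enrichment(index, ann, gl, panel, windows,
                             n_lists=100, seed=5)
        assert len(res) == 4 * 3  # 4 gene lists x (nearest + 2 windows)
        modes = {(r.mode, r.window) for r in res}
        assert modes == {("nearest", None), ("window", 50_000),
                         ("window", 150_000)}
        for r in res:
            assert 0.0 <= r.p_genes.p <= 1.0
            assert r.p_genes.null_values.size == 100

    def test_single_list_null_degenerate(self, sim_null):
        ann, panel, gl, index = sim_null
        res = run_enrichment(index, ann, gl, panel, WindowSpec((50_000,)),
                             n_lists=1, seed=5, include_nearest=False)
        for r in res:
            assert r.p_genes.p in (0.0, 1.0)
            if r.p_genes.p == 0.0:
                assert r.p_genes.formatted == "<1.00E+00"


class TestRunSensitivity:
    def test_noop_when_no_snp_is_unclassified(self, sim_null):
        ann, panel, gl, index = sim_null
        classified = [SnpRecord(s.rsid, s.chrom, s.pos, s.maf,
                                Classification.FETAL_ONLY) for s in index]
        windows = WindowSpec((50_000,))
        kwargs = dict(n_lists=100, seed=5, include_nearest=False)
        a = run_enrichment(classified, ann, gl, panel, windows, **kwargs)
        b = run_sensitivity(classified, ann, gl, panel, windows, **kwargs)
        for ra, rb in zip(a, b):
            assert ra.observed == rb.observed
            assert ra.p_genes.p == rb.p_genes.p

    def test_all_unclassified_rejected(self, sim_null):
        ann, panel, gl, index = sim_null
        unclassified = [SnpRecord(s.rsid, s.chrom, s.pos, s.maf,
                                  Classification.UNCLASSIFIED) for s in index]
        with pytest.raises(ValueError, match="no SNPs remain"):
            run_sensitivity(unclassified, ann, gl, panel, WindowSpec((50_000,)),
                            n_lists=10, seed=1)
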