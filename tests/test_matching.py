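"""Matched candidate pools and seeded null-set sampling."""

import numpy as np
import pytest

from proximatch.annotate import (GeneAnnotation, GeneRecord, WindowSpec,
                                 annotate_snps, build_panel_index)
from proximatch.io_formats import SnpRecord
from proximatch.matching import (MatchCriteria, MatchingFailure,
                                 build_pools, candidate_pool,
                                 read_null_sets_tsv, sample_null_sets,
                                 validate_null_sets, write_null_sets_tsv)


@pytest.fixture
def toy():
    """One gene; panel SNPs with hand-set positions/MAFs around it."""
    ann = GeneAnnotation([GeneRecord("G", "1", 10_000, 20_000)])
    windows = WindowSpec((1_000,))
    # nearest distances:   0      0      100    110     90    500
    positions = [15_000, 19_000, 20_100, 20_110, 9_910, 20_500]
    mafs = [0.20, 0.18, 0.22, 0.20, 0.179, 0.221]
    panel = [SnpRecord(f"p{i}", "1", pos, maf)
             for i, (pos, maf) in enumerate(zip(positions, mafs))]
    return ann, windows, panel, build_panel_index(panel, ann, windows)


def index_prox(ann, windows, chrom="1", pos=20_100, maf=0.20, rsid="idx"):
    (p,) = annotate_snps([SnpRecord(rsid, chrom, pos, maf)], ann, windows)
    return p


class TestCandidatePool:
    def test_maf_interval_is_closed_and_scaled(self, toy):
        ann, windows, panel, pidx = toy
        # index maf 0.20 -> interval [0.18, 0.22]; distance 100 -> [90, 110]
        idx = index_prox(ann, windows)
        pool = candidate_pool(idx, pidx, MatchCriteria(mode="nearest"))
        got = {panel[i].rsid for i in pool.candidates}
        # p2 excluded (self), p3 d=110 in, p4 d=90 in but maf 0.179 out,
        # p5 maf 0.221 out
        assert got == {"p3"}

    def test_distance_zero_matches_only_in_gene_snps(self, toy):
        ann, windows, panel, pidx = toy
        idx = index_prox(ann, windows, pos=15_500)  # inside gene, d = 0
        pool = candidate_pool(idx, pidx, MatchCriteria(mode="nearest"))
        got = {panel[i].rsid for i in pool.candidates}
        assert got == {"p0", "p1"}

    def test_hand_enumeration_of_toy_panel(self, toy):
        ann, windows, panel, pidx = toy
        idx = index_prox(ann, windows, pos=20_090, maf=0.2, rsid="other")
        # distance 90 -> [81, 99]: only p4 (d=90, maf 0.179? out!) -> empty
        with pytest.raises(MatchingFailure):
            candidate_pool(idx, pidx, MatchCriteria(mode="nearest"))

    def test_window_mode_requires_exact_count(self, toy):
        ann, windows, panel, pidx = toy
        idx = index_prox(ann, windows, pos=19_500, maf=0.2)  # 1 gene in 1 kb
        pool = candidate_pool(
            idx, pidx, MatchCriteria(mode="window", window=1_000))
        got = {panel[i].rsid for i in pool.candidates}
        counts = pidx.window_counts[1_000]
        assert got == {panel[i].rsid for i in np.flatnonzero(counts == 1)
                       if 0.18 <= panel[i].maf <= 0.22
                       and (panel[i].chrom, panel[i].pos) != ("1", 19_500)}

    def test_exclude_self_removes_same_position(self, toy):
        ann, windows, panel, pidx = toy
        idx = index_prox(ann, windows, pos=15_000, maf=0.20)  # == p0
        pool = candidate_pool(idx, pidx, MatchCriteria(mode="nearest"))
        assert {panel[i].rsid for i in pool.candidates} == {"p1"}
        pool2 = candidate_pool(
            idx, pidx, MatchCriteria(mode="nearest", exclude_self=False))
        assert {panel[i].rsid for i in pool2.candidates} == {"p0", "p1"}

    def test_empty_pool_raises_naming_snp_and_constraint(self, toy):
        ann, windows, panel, pidx = toy
        idx = index_prox(ann, windows, maf=0.45, rsid="lonely")
        with pytest.raises(MatchingFailure, match="lonely"):
            candidate_pool(idx, pidx, MatchCriteria(mode="nearest"))

    def test_relaxation_widens_maf_interval_with_warning(self, toy, caplog):
        ann, windows, panel, pidx = toy
        idx = index_prox(ann, windows, pos=20_100, maf=0.25, rsid="tight")
        crit = MatchCriteria(mode="nearest", relax_steps=2)
        pool = candidate_pool(idx, pidx, crit)
        assert len(pool) > 0
        assert any("RELAXATION" in r.message for r in caplog.records)

    def test_every_candidate_satisfies_criteria(self, rng, toy):
        ann, windows, panel, pidx = toy
        idx = index_prox(ann, windows)
        pool = candidate_pool(idx, pidx, MatchCriteria(mode="nearest"))
        for i in pool.candidates:
            assert 0.18 <= panel[i].maf <= 0.22
            d = pidx.nearest_dist[i]
            assert 90 <= d <= 110


def make_pools(toy, n_index=3):
    ann, windows, panel, pidx = toy
    prox = [index_prox(ann, windows, pos=15_000 + 200 * i, maf=0.2,
                       rsid=f"i{i}") for i in range(n_index)]
    return build_pools(prox, pidx, MatchCriteria(mode="nearest")), pidx


class TestSampleNullSets:
    def test_same_seed_gives_identical_matrix(self, toy):
        pools, pidx = make_pools(toy)
        a = sample_null_sets(pools, 50, seed=9)
        b = sample_null_sets(pools, 50, seed=9)
        assert np.array_equal(a.matrix, b.matrix)

    def test_different_seed_differs(self, toy):
        pools, pidx = make_pools(toy)
        a = sample_null_sets(pools, 200, seed=9)
        b = sample_null_sets(pools, 200, seed=10)
        assert not np.array_equal(a.matrix, b.matrix)

    def test_single_member_pools_give_identical_lists(self):
        ann = GeneAnnotation([GeneRecord("G", "1", 100, 200)])
        windows = WindowSpec((50,))
        panel = [SnpRecord("p0", "1", 150, 0.2), SnpRecord("p1", "1", 160, 0.4)]
        pidx = build_panel_index(panel, ann, windows)
        prox = index_prox(ann, windows, pos=155, maf=0.2)
        pools = build_pools([prox], pidx, MatchCriteria(mode="nearest"))
        assert len(pools[0]) == 1
        nulls = sample_null_sets(pools, 20, seed=1)
        assert np.all(nulls.matrix == nulls.matrix[0, 0])

    def test_selection_frequencies_binomial(self, toy):
        # one pool of 4 candidates sampled 10 000 times: each candidate's
        # frequency within 4 standard errors of 1/4
        ann, windows, panel, pidx = toy
        idx = index_prox(ann, windows, pos=15_500)
        crit = MatchCriteria(mode="nearest", maf_lower_factor=0.5,
                             maf_upper_factor=2.0)
        pool = candidate_pool(idx, pidx, crit)
        k = len(pool)
        nulls = sample_null_sets([pool], 10_000, seed=4)
        freqs = np.bincount(nulls.matrix[:, 0],
                            minlength=len(panel))[pool.candidates] / 10_000
        se = np.sqrt((1 / k) * (1 - 1 / k) / 10_000)
        assert np.all(np.abs(freqs - 1 / k) <= 4 * se)

    def test_unique_within_list_avoids_duplicates(self, toy):
        ann, windows, panel, pidx = toy
        # two index SNPs with identical pools (both inside the gene)
        prox = [index_prox(ann, windows, pos=15_400 + i, maf=0.2,
                           rsid=f"i{i}") for i in range(2)]
        pools = build_pools(prox, pidx, MatchCriteria(mode="nearest"))
        nulls = sample_null_sets(pools, 200, seed=3)
        assert all(len(set(row)) == len(row) for row in nulls.matrix.tolist())
        with_dups = sample_null_sets(pools, 200, seed=3,
                                     unique_within_list=False)
        assert any(len(set(row)) < len(row)
                   for row in with_dups.matrix.tolist())

    def test_invalid_n_lists_rejected(self, toy):
        pools, _ = make_pools(toy)
        with pytest.raises(ValueError):
            sample_null_sets(pools, 0, seed=1)


class TestValidateNullSets:
    def test_fresh_sample_has_zero_violations(self, toy):
        pools, pidx = make_pools(toy)
        nulls = sample_null_sets(pools, 100, seed=2)
        report = validate_null_sets(nulls, pidx)
        assert report.n_violations == 0

    def test_planted_corruption_detected(self, toy):
        ann, windows, panel, pidx = toy
        pools, _ = make_pools(toy)
        nulls = sample_null_sets(pools, 100, seed=2)
        # p5 (maf 0.221, d 500) is off-criteria for every pool
        nulls.matrix[7, 1] = 5
        report = validate_null_sets(nulls, pidx)
        assert report.n_violations == 1
        assert report.violations == ((7, 1),)


class TestNullSetCache:
    def test_roundtrip_with_checksum(self, tmp_path, toy):
        pools, pidx = make_pools(toy)
        nulls = sample_null_sets(pools, 10, seed=6)
        path = tmp_path / "cache.tsv"
        write_null_sets_tsv(nulls, pidx, path)
        rows, meta = read_null_sets_tsv(path, pidx)
        assert meta["seed"] == "6"
        assert len(rows) == 10
        expect = [[pidx.records[int(i)].rsid for i in row]
                  for row in nulls.matrix]
        assert rows == expect
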