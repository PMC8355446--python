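"""Shared fixtures and brute-force oracles.

The oracles are deliberately naive linear scans, independent of the
indexed implementations they check.
"""

from __future__ import annotations

import numpy as np
import pytest

from proximatch.annotate import GeneAnnotation, GeneRecord
from proximatch.io_formats import SnpRecord


def brute_nearest(snp: SnpRecord, genes: list[GeneRecord]
                  ) -> tuple[str, int] | None:
    """Nearest gene by exhaustive scan: (distance, symbol) lexicographic min."""
    best = None
    for g in genes:
        if g.chrom != snp.chrom:
            continue
        if g.start <= snp.pos <= g.end:
            d = 0
        else:
            d = min(abs(snp.pos - g.start), abs(snp.pos - g.end))
        key = (d, g.symbol)
        if best is None or key < best:
            best = key
    if best is None:
        return None
    return best[1], best[0]


def brute_window(snp: SnpRecord, genes: list[GeneRecord], w: int
                 ) -> frozenset[str]:
    """Genes overlapping the closed interval [pos - w, pos + w], by scan."""
    return frozenset(
        g.symbol for g in genes
        if g.chrom == snp.chrom and g.start <= snp.pos + w
        and g.end >= snp.pos - w
    )


def random_genes(rng: np.random.Generator, n: int, chroms=("1", "2"),
                 max_pos: int = 10_000) -> list[GeneRecord]:
    """Random (possibly overlapping) gene spans with distinct symbols."""
    genes = []
    for i in range(n):
        a, b = sorted(rng.integers(1, max_pos + 1, size=2))
        genes.append(GeneRecord(f"G{i:03d}", str(rng.choice(chroms)),
                                int(a), int(max(a, b))))
    return genes


def random_snp(rng: np.random.Generator, i: int, chroms=("1", "2"),
               max_pos: int = 10_000) -> SnpRecord:
    return SnpRecord(f"rs{i}", str(rng.choice(chroms)),
                     int(rng.integers(1, max_pos + 1)),
                     float(rng.uniform(0.001, 0.5)))


@pytest.fixture
def rng():
    return np.random.default_rng(20_240_901)


@pytest.fixture
def small_annotation():
    """Five genes on two chromosomes, hand-placed for distance arithmetic."""
    return GeneAnnotation([
        GeneRecord("ALPHA", "1", 1_000, 2_000),
        GeneRecord("BETA", "1", 2_500, 3_000),
        GeneRecord("GAMMA", "1", 10_000, 12_000),
        GeneRecord("DELTA", "2", 100, 200),
        GeneRecord("EPSILON", "2", 400, 500),
    ])
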