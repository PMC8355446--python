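"""Matched null SNP sets.

For each index SNP a pool of reference-panel SNPs is built that matches it
on MAF (within 0.9-1.1x) and on a proximity covariate: either the distance
to the nearest gene (within +/-10%) or the exact number of genes inside a
given window.  Seeded sampling from the pools yields n_lists matched SNP
lists, the substrate of the empirical null distribution.

All intervals are closed.  An empty pool is a hard error by default:
silently relaxing the criteria would invalidate the matching claim.  An
opt-in stepped relaxation widens the MAF factors by 0.05 per step, with a
prominent warning.
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Sequence

import numpy as np

from .annotate import PanelIndex, SnpProximity

logger = logging.getLogger(__name__)


class MatchingFailure(RuntimeError):
    """No panel SNP satisfies the matching criteria for an index SNP."""

    def __init__(self, rsid: str, constraint: str):
        self.rsid = rsid
        self.constraint = constraint
        super().__init__(
            f"no matched panel SNP for index SNP {rsid}: {constraint}"
        )


@dataclass(frozen=True)
class MatchCriteria:
    """Matching rules for building candidate pools.

    MAF of a matching SNP must lie in [maf_lower_factor * m,
    maf_upper_factor * m] for index MAF m.  In ``nearest`` mode the
    nearest-gene distance must lie within +/- ``distance_tolerance`` of the
    index SNP's; in ``window`` mode the gene count in ``window`` must match
    exactly.
    """

    maf_lower_factor: float = 0.9
    maf_upper_factor: float = 1.1
    distance_tolerance: float = 0.1
    mode: str = "nearest"  # nearest | window
    window: int | None = None
    n_lists: int = 10_000
    exclude_self: bool = True
    relax_steps: int = 0

    def __post_init__(self) -> None:
        if not (0 < self.maf_lower_factor <= 1 <= self.maf_upper_factor):
            raise ValueError("MAF factors must satisfy 0 < lower <= 1 <= upper")
        if not 0 <= self.distance_tolerance < 1:
            raise ValueError("distance_tolerance must be in [0, 1)")
        if self.mode not in ("nearest", "window"):
            raise ValueError(f"mode must be 'nearest' or 'window', got {self.mode!r}")
        if self.mode == "window" and self.window is None:
            raise ValueError("window mode requires a window size")
        if self.n_lists < 1:
            raise ValueError("n_lists must be positive")
        if self.relax_steps < 0:
            raise ValueError("relax_steps must be non-negative")


@dataclass(frozen=True)
class CandidatePool:
    """Panel SNPs (as indices into a PanelIndex) matched to one index SNP."""

    index_snp: SnpProximity
    candidates: np.ndarray  # panel indices, non-empty
    criteria: MatchCriteria

    def __len__(self) -> int:
        return len(self.candidates)


#: Relative slack applied to closed-interval bounds so that nominally
#: boundary-equal values (e.g. MAF 0.18 against 0.9 x 0.20) are not excluded
#: by floating-point representation error.
_REL_EPS = 1e-12


def _matching_indices(index: SnpProximity, panel: PanelIndex,
                      criteria: MatchCriteria) -> np.ndarray:
    m = index.snp.maf
    lo = criteria.maf_lower_factor * m * (1 - _REL_EPS)
    hi = criteria.maf_upper_factor * m * (1 + _REL_EPS)
    if criteria.mode == "nearest":
        if index.nearest_distance is None:
            raise MatchingFailure(index.snp.rsid,
                                  "index SNP has no nearest-gene distance")
        d = index.nearest_distance
        idx = panel.candidates_nearest(
            lo, hi, (1 - criteria.distance_tolerance) * d * (1 - _REL_EPS),
            (1 + criteria.distance_tolerance) * d * (1 + _REL_EPS))
    else:
        w = criteria.window
        count = index.window_counts.get(w)
        if count is None:
            raise MatchingFailure(index.snp.rsid,
                                  f"index SNP not annotated for window {w}")
        idx = panel.candidates_window(lo, hi, w, count)
    if criteria.exclude_self and len(idx):
        same = ((panel.chrom[idx] == index.snp.chrom)
                & (panel.pos[idx] == index.snp.pos))
        idx = idx[~same]
    return idx


def candidate_pool(index: SnpProximity, panel: PanelIndex,
                   criteria: MatchCriteria) -> CandidatePool:
    """Build the pool of panel SNPs matching one annotated index SNP.

    Raises :class:`MatchingFailure` naming the binding constraint when the
    pool is empty (after any configured relaxation steps).
    """
    crit = criteria
    idx = _matching_indices(index, panel, crit)
    step = 0
    while len(idx) == 0 and step < criteria.relax_steps:
        step += 1
        crit = replace(
            crit,
            maf_lower_factor=max(crit.maf_lower_factor - 0.05, 1e-9),
            maf_upper_factor=crit.maf_upper_factor + 0.05,
        )
        logger.warning(
            "RELAXATION: index SNP %s pool empty; widening MAF factors to "
            "[%.2f, %.2f] (step %d/%d)", index.snp.rsid,
            crit.maf_lower_factor, crit.maf_upper_factor, step,
            criteria.relax_steps)
        idx = _matching_indices(index, panel, crit)
    if len(idx) == 0:
        m = index.snp.maf
        n_maf = int(panel.mask_maf(criteria.maf_lower_factor * m,
                                   criteria.maf_upper_factor * m).sum())
        constraint = ("MAF interval alone is empty" if n_maf == 0 else
                      f"{criteria.mode} proximity constraint empties the "
                      f"{n_maf} MAF-matched SNPs")
        raise MatchingFailure(index.snp.rsid, constraint)
    return CandidatePool(index_snp=index, candidates=idx, criteria=crit)


def build_pools(prox: Sequence[SnpProximity], panel: PanelIndex,
                criteria: MatchCriteria) -> list[CandidatePool]:
    """Candidate pools for a list of annotated index SNPs."""
    return [candidate_pool(p, panel, criteria) for p in prox]


@dataclass(frozen=True)
class NullSets:
    """n_lists x n_index_snps matrix of matched panel SNP indices.

    A pure function of (pools, n_lists, seed): per-column generators are
    spawned deterministically from the top-level seed, so the result does
    not depend on evaluation order.
    """

    matrix: np.ndarray  # shape (n_lists, n_cols), panel indices
    pools: tuple[CandidatePool, ...]
    seed: int

    @property
    def n_lists(self) -> int:
        return self.matrix.shape[0]


def sample_null_sets(pools: Sequence[CandidatePool], n_lists: int,
                     seed: int, unique_within_list: bool = True) -> NullSets:
    """Sample the matched null lists: uniform per cell from each pool.

    By default a list never contains the same panel SNP twice
    (``unique_within_list``), mirroring the observed index SNPs, which are
    distinct loci.  Duplicates within a list would deflate the gene-level
    null statistic whenever candidate pools overlap, which matters at
    desk-scale panel sizes.  Uniqueness is enforced by synchronized
    redraw rounds from the per-column generators, so the result is still
    a pure function of (pools, n_lists, seed); cells whose pool holds a
    single SNP cannot be redrawn and may leave duplicates (warned).
    """
    if n_lists < 1:
        raise ValueError("n_lists must be positive")
    if not pools:
        raise ValueError("need at least one candidate pool")
    children = np.random.SeedSequence(seed).spawn(len(pools))
    rngs = [np.random.default_rng(ss) for ss in children]
    matrix = np.empty((n_lists, len(pools)), dtype=np.int64)
    for j, (pool, rng) in enumerate(zip(pools, rngs)):
        matrix[:, j] = pool.candidates[rng.integers(0, len(pool), size=n_lists)]
    if unique_within_list and len(pools) > 1:
        redrawable = np.array([len(p) > 1 for p in pools])
        for _round in range(64):
            order = np.argsort(matrix, axis=1, kind="stable")
            sortedm = np.take_along_axis(matrix, order, axis=1)
            dup_sorted = np.zeros_like(sortedm, dtype=bool)
            dup_sorted[:, 1:] = sortedm[:, 1:] == sortedm[:, :-1]
            dup = np.zeros_like(dup_sorted)
            np.put_along_axis(dup, order, dup_sorted, axis=1)
            dup &= redrawable[None, :]
            if not dup.any():
                break
            for j, (pool, rng) in enumerate(zip(pools, rngs)):
                rows = np.flatnonzero(dup[:, j])
                if rows.size:
                    matrix[rows, j] = pool.candidates[
                        rng.integers(0, len(pool), size=rows.size)]
        else:
            logger.warning(
                "sample_null_sets: duplicate panel SNPs remain within some "
                "lists after redraw rounds (overlapping near-degenerate pools)")
    return NullSets(matrix=matrix, pools=tuple(pools), seed=seed)


@dataclass(frozen=True)
class NullSetReport:
    n_entries: int
    n_violations: int
    violations: tuple[tuple[int, int], ...]  # (row, col) of offending entries


def validate_null_sets(nulls: NullSets, panel: PanelIndex) -> NullSetReport:
    """Re-check every sampled entry against its pool's criteria.

    Recomputes the admissible candidate set per column from the panel
    (not from the stored pool) and reports entries outside it.
    """
    bad: list[tuple[int, int]] = []
    for j, pool in enumerate(nulls.pools):
        admissible = _matching_indices(pool.index_snp, panel, pool.criteria)
        ok = np.isin(nulls.matrix[:, j], admissible)
        for i in np.flatnonzero(~ok):
            bad.append((int(i), j))
    return NullSetReport(n_entries=nulls.matrix.size,
                         n_violations=len(bad), violations=tuple(bad))


# ---------------------------------------------------------------------------
# Optional on-disk cache


def panel_checksum(panel: PanelIndex) -> str:
    h = hashlib.sha256()
    for rec in panel.records:
        h.update(f"{rec.rsid}\t{rec.chrom}\t{rec.pos}\t{rec.maf:.10g}\n".encode())
    return h.hexdigest()[:16]


def write_null_sets_tsv(nulls: NullSets, panel: PanelIndex, path) -> None:
    """Cache null sets as TSV: metadata header lines, then one row of rsids per list."""
    crit = nulls.pools[0].criteria
    lines = [
        f"#seed={nulls.seed}",
        f"#criteria=mode:{crit.mode},window:{crit.window},"
        f"maf:{crit.maf_lower_factor}-{crit.maf_upper_factor},"
        f"dist_tol:{crit.distance_tolerance},exclude_self:{crit.exclude_self}",
        f"#panel_checksum={panel_checksum(panel)}",
        "\t".join(p.index_snp.snp.rsid for p in nulls.pools),
    ]
    for row in nulls.matrix:
        lines.append("\t".join(panel.records[int(i)].rsid for i in row))
    Path(path).write_text("\n".join(lines) + "\n")


def read_null_sets_tsv(path, panel: PanelIndex) -> tuple[list[list[str]], dict]:
    """Read a cached null-set file; verifies the panel checksum.

    Returns (rows of rsids, metadata dict).  The rsid rows can be mapped
    back to panel indices by the caller if needed.
    """
    meta: dict[str, str] = {}
    rows: list[list[str]] = []
    header_seen = False
    for line in Path(path).read_text().splitlines():
        if line.startswith("#"):
            key, _, value = line[1:].partition("=")
            meta[key] = value
        elif not header_seen:
            header_seen = True  # index-SNP rsid header row
        else:
            rows.append(line.split("\t"))
    if meta.get("panel_checksum") != panel_checksum(panel):
        raise ValueError("null-set cache was built against a different panel")
    return rows, meta
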