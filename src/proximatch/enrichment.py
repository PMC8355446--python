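"""Enrichment statistics and empirical p-values.

Two statistics summarise how a SNP list relates to a gene list:

* gene-level: the number of distinct list genes proximal (nearest gene, or
  within a window) to at least one SNP;
* SNP-level: the number of SNPs with at least one list gene proximal.

The same statistics computed on each matched null SNP list form the
empirical distribution; the one-sided upper-tail empirical p-value is the
fraction of null lists whose statistic is at least the observed one (ties
count toward the numerator).  With zero exceedances the default "floor"
estimator renders the p-value as "<1/n_lists" (e.g. "<1.00E-04" for 10 000
lists); the (r+1)/(n+1) estimator is available behind a flag.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np

from .annotate import (DEFAULT_WINDOWS, GeneAnnotation, PanelIndex,
                       SnpProximity, WindowSpec, annotate_snps,
                       build_panel_index)
from .matching import MatchCriteria, build_pools, sample_null_sets

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class EnrichmentStat:
    """Observed (or null) gene-level and SNP-level proximity counts."""

    n_genes: int
    n_snps: int


@dataclass(frozen=True)
class EmpiricalP:
    observed: int
    null_values: np.ndarray
    p: float
    formatted: str
    estimator: str = "floor"


@dataclass(frozen=True)
class EnrichmentResult:
    gene_list_name: str
    mode: str               # "nearest" or "window"
    window: int | None      # half-width in bp when mode == "window"
    observed: EnrichmentStat
    p_genes: EmpiricalP
    p_snps: EmpiricalP


def stat_nearest(prox: Sequence[SnpProximity], genes: frozenset[str] | set[str]
                 ) -> EnrichmentStat:
    """Nearest-gene statistics against a gene list.

    SNP-level: SNPs whose nearest gene is in the list.  Gene-level:
    distinct list genes that are the nearest gene of at least one SNP.
    """
    hit_genes = set()
    n_snps = 0
    for p in prox:
        if p.nearest_gene is not None and p.nearest_gene in genes:
            n_snps += 1
            hit_genes.add(p.nearest_gene)
    return EnrichmentStat(n_genes=len(hit_genes), n_snps=n_snps)


def stat_window(prox: Sequence[SnpProximity], genes: frozenset[str] | set[str],
                w: int) -> EnrichmentStat:
    """Window statistics against a gene list at half-width ``w``.

    SNP-level: SNPs with at least one list gene in their window.
    Gene-level: distinct list genes inside the window of at least one SNP.
    """
    hit_genes: set[str] = set()
    n_snps = 0
    for p in prox:
        if w not in p.window_genes:
            raise ValueError(
                f"{p.snp.rsid}: not annotated for window {w}"
            )
        inter = p.window_genes[w] & genes
        if inter:
            n_snps += 1
            hit_genes |= inter
    return EnrichmentStat(n_genes=len(hit_genes), n_snps=n_snps)


def format_p(x: float) -> str:
    return f"{x:.2E}"


def empirical_pvalue(observed: int, null_values: Sequence[int] | np.ndarray,
                     estimator: str = "floor") -> EmpiricalP:
    """One-sided upper-tail empirical p-value against a null sample.

    ``floor``: p = #{null >= observed} / n, rendered "<1/n" when the count
    is zero.  ``plus_one``: p = (#{null >= observed} + 1) / (n + 1).
    """
    nv = np.asarray(null_values)
    if nv.size == 0:
        raise ValueError("null_values must be non-empty")
    n = nv.size
    count = int((nv >= observed).sum())
    if estimator == "floor":
        p = count / n
        formatted = f"<{format_p(1.0 / n)}" if count == 0 else format_p(p)
    elif estimator == "plus_one":
        p = (count + 1) / (n + 1)
        formatted = format_p(p)
    else:
        raise ValueError(f"unknown p estimator: {estimator!r}")
    return EmpiricalP(observed=observed, null_values=nv, p=p,
                      formatted=formatted, estimator=estimator)


# ---------------------------------------------------------------------------
# Vectorised null statistics over a NullSets matrix


def gene_member_mask(ann: GeneAnnotation, genes: frozenset[str] | set[str]
                     ) -> np.ndarray:
    """Boolean mask over annotation gene ids for membership in ``genes``."""
    mask = np.zeros(len(ann.symbols), dtype=bool)
    for g in genes:
        gid = ann.symbol_to_id.get(g)
        if gid is not None:
            mask[gid] = True
    return mask


def nearest_null_counts(matrix: np.ndarray, panel: PanelIndex,
                        member: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Per-list (gene-level, SNP-level) nearest-gene counts.

    Each matched SNP contributes its own nearest gene, exactly parallel to
    the observed computation.
    """
    n_lists, n_cols = matrix.shape
    g = member.size
    # id -1 (no gene on chromosome) indexes the appended False slot
    mem = np.append(member, False)
    sel_ids = panel.nearest_id[matrix]
    sel_mem = mem[sel_ids]
    snp_counts = sel_mem.sum(axis=1)
    rows = np.repeat(np.arange(n_lists, dtype=np.int64), n_cols)
    keep = sel_mem.ravel()
    keys = rows[keep] * g + sel_ids.ravel()[keep]
    gene_counts = np.bincount(np.unique(keys) // g, minlength=n_lists)
    return gene_counts, snp_counts


def window_null_counts(matrix: np.ndarray, panel: PanelIndex, w: int,
                       member: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Per-list (gene-level, SNP-level) window counts at half-width ``w``."""
    n_lists, n_cols = matrix.shape
    g = member.size
    indptr = panel.window_indptr[w]
    flat = panel.window_flat_ids[w]
    counts = indptr[1:] - indptr[:-1]
    sel = matrix.ravel()
    seg_len = counts[sel]
    total = int(seg_len.sum())
    if total == 0:
        zeros = np.zeros(n_lists, dtype=np.int64)
        return zeros, zeros.copy()
    seg_starts = np.cumsum(seg_len) - seg_len
    ramp = np.arange(total, dtype=np.int64) - np.repeat(seg_starts, seg_len)
    ids = flat[np.repeat(indptr[sel], seg_len) + ramp]
    memf = member[ids]
    cell_of = np.repeat(np.arange(sel.size, dtype=np.int64), seg_len)
    cell_hit = np.bincount(cell_of[memf], minlength=sel.size) > 0
    snp_counts = cell_hit.reshape(n_lists, n_cols).sum(axis=1)
    rows = cell_of // n_cols
    keys = rows[memf] * g + ids[memf]
    gene_counts = np.bincount(np.unique(keys) // g, minlength=n_lists)
    return gene_counts, snp_counts


# ---------------------------------------------------------------------------
# Orchestration


def _as_named_lists(gene_lists) -> dict[str, frozenset[str]]:
    if hasattr(gene_lists, "named_lists"):
        return gene_lists.named_lists()
    return {name: frozenset(g) for name, g in dict(gene_lists).items()}


def run_enrichment(
    snps: Sequence,
    annotation: GeneAnnotation,
    gene_lists,
    panel,
    windows: WindowSpec = DEFAULT_WINDOWS,
    *,
    criteria: MatchCriteria | None = None,
    n_lists: int | None = None,
    seed: int = 0,
    estimator: str = "floor",
    include_nearest: bool = True,
) -> list[EnrichmentResult]:
    """Run the full enrichment analysis.

    For the nearest-gene mode and each window: annotate the index SNPs,
    build matched candidate pools from the panel, sample the seeded null
    lists, and compute both empirical p-values for every gene list.  The
    null lists depend only on the matching covariates, so each mode's null
    sets are shared across gene lists.  Identical inputs and seed give
    identical output.
    """
    base = criteria if criteria is not None else MatchCriteria()
    nl = n_lists if n_lists is not None else base.n_lists
    panel_index = panel if isinstance(panel, PanelIndex) else \
        build_panel_index(panel, annotation, windows)
    named = _as_named_lists(gene_lists)
    prox = annotate_snps(snps, annotation, windows)

    modes: list[tuple[str, int | None]] = []
    if include_nearest:
        modes.append(("nearest", None))
    modes += [("window", w) for w in windows.sizes]
    mode_seeds = np.random.SeedSequence(seed).generate_state(len(modes))

    results: list[EnrichmentResult] = []
    for (mode, w), mode_seed in zip(modes, mode_seeds):
        if mode == "nearest":
            crit = replace(base, mode="nearest", window=None)
            usable = [p for p in prox if p.nearest_distance is not None]
            if len(usable) < len(prox):
                logger.warning(
                    "nearest-gene mode: %d SNPs without a nearest gene excluded",
                    len(prox) - len(usable))
        else:
            crit = replace(base, mode="window", window=w)
            usable = prox
        pools = build_pools(usable, panel_index, crit)
        nulls = sample_null_sets(pools, nl, int(mode_seed))
        for name, genes in named.items():
            member = gene_member_mask(annotation, genes)
            if mode == "nearest":
                observed = stat_nearest(usable, genes)
                gene_counts, snp_counts = nearest_null_counts(
                    nulls.matrix, panel_index, member)
            else:
                observed = stat_window(usable, genes, w)
                gene_counts, snp_counts = window_null_counts(
                    nulls.matrix, panel_index, w, member)
            results.append(EnrichmentResult(
                gene_list_name=name,
                mode=mode,
                window=w,
                observed=observed,
                p_genes=empirical_pvalue(observed.n_genes, gene_counts, estimator),
                p_snps=empirical_pvalue(observed.n_snps, snp_counts, estimator),
            ))
    return results


def run_sensitivity(snps: Sequence, annotation: GeneAnnotation, gene_lists,
                    panel, windows: WindowSpec = DEFAULT_WINDOWS,
                    **kwargs) -> list[EnrichmentResult]:
    """Enrichment after additionally dropping unclassified index SNPs.

    Unclassified loci may hide purely maternal effects; removing them
    trades power for specificity to direct fetal effects.
    """
    from .io_formats import Classification, select_lead_snps

    kept = select_lead_snps(
        snps,
        drop_classifications=(Classification.MATERNAL_ONLY,
                              Classification.UNCLASSIFIED),
    )
    if not kept:
        raise ValueError("no SNPs remain after dropping unclassified loci")
    return run_enrichment(kept, annotation, gene_lists, panel, windows, **kwargs)
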