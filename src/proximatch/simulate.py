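"""Synthetic genomes, reference panels, gene lists and index SNP sets.

The generator emulates the inputs the enrichment method consumes — an
imputation-panel-like reference SNP list, a curated disease-gene table
with allelic requirements, a gene annotation, and a set of GWAS lead
(index) SNPs — at a desk scale, with an optional planted proximity
enrichment.  Planting is positional: a configurable fraction of index
SNPs is placed within a maximum distance of a dominant-labelled gene.
The method only ever sees positions and MAFs, so positional planting is
the appropriate notion of effect.

Everything is reproducible from the single seed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np

from .annotate import GeneAnnotation, GeneRecord
from .io_formats import (Classification, DDGeneRow, GeneListSet, SnpRecord,
                         derive_gene_lists)

logger = logging.getLogger(__name__)

#: Fraction of curated genes carrying both a dominant and a recessive
#: disorder, mirroring the small dominant/recessive overlap seen in
#: clinician-curated gene lists.
P_BOTH = 0.036

#: Classification mix for simulated index SNPs, proportional to the
#: fetal-only : fetal-and-maternal : unclassified split reported for
#: birth-weight GWAS loci after maternal-only removal (62:35:62).
CLASS_PROBS = (
    (Classification.FETAL_ONLY, 62 / 159),
    (Classification.FETAL_AND_MATERNAL_SAME, 35 / 159),
    (Classification.UNCLASSIFIED, 62 / 159),
)


@dataclass(frozen=True)
class SimConfig:
    """Parameters of the synthetic input generator.

    Defaults emulate the study conditions at a tractable scale: 156 index
    SNPs and a gene/DD-gene density proportional to a ~20k-gene genome
    with ~7% curated disease genes (35% of them dominant), on a 400 Mb
    8-chromosome genome with a 50k-SNP panel standing in for the full
    imputation panel.
    """

    n_chroms: int = 8
    chrom_length: int = 50_000_000
    n_genes: int = 2600
    gene_length: tuple[int, int] = (5_000, 120_000)  # uniform min, max
    n_panel_snps: int = 50_000
    maf_beta: tuple[float, float] = (1.0, 3.0)  # Beta shape pair, folded
    n_index_snps: int = 156
    planted_fraction: float = 0.0
    planted_max_distance: int = 5_000
    n_dd_genes: int = 180
    fraction_dominant: float = 0.35
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_chroms", "chrom_length", "n_genes", "n_panel_snps",
                     "n_index_snps", "planted_max_distance", "n_dd_genes"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not 0 <= self.planted_fraction <= 1:
            raise ValueError("planted_fraction must be in [0, 1]")
        if not 0 <= self.fraction_dominant <= 1:
            raise ValueError("fraction_dominant must be in [0, 1]")
        if self.gene_length[0] < 1 or self.gene_length[1] < self.gene_length[0]:
            raise ValueError("gene_length must be (min, max) with 1 <= min <= max")
        if self.n_dd_genes > self.n_genes:
            raise ValueError("n_dd_genes cannot exceed n_genes")


def _place_genes(rng: np.random.Generator, config: SimConfig
                 ) -> list[GeneRecord]:
    """Place non-overlapping genes uniformly across chromosomes."""
    chroms = [str(i + 1) for i in range(config.n_chroms)]
    assignment = rng.integers(0, config.n_chroms, size=config.n_genes)
    lengths = rng.integers(config.gene_length[0], config.gene_length[1] + 1,
                           size=config.n_genes)
    genes: list[GeneRecord] = []
    counter = 0
    for ci, chrom in enumerate(chroms):
        idx = np.flatnonzero(assignment == ci)
        lens = lengths[idx]
        free = config.chrom_length - int(lens.sum())
        if free < 0:
            raise ValueError(
                f"infeasible packing: {len(idx)} genes totalling {lens.sum()} bp "
                f"exceed chromosome length {config.chrom_length}"
            )
        # gaps between consecutive genes via sorted uniform cut points
        cuts = np.sort(rng.integers(0, free + 1, size=len(idx)))
        pos = 1
        prev_cut = 0
        for L, cut in zip(lens, cuts):
            pos += int(cut - prev_cut)
            prev_cut = int(cut)
            counter += 1
            genes.append(GeneRecord(f"GENE{counter:05d}", chrom, pos,
                                    pos + int(L) - 1))
            pos += int(L)
    return genes


def _draw_mafs(rng: np.random.Generator, shape: tuple[float, float],
               n: int) -> np.ndarray:
    f = rng.beta(shape[0], shape[1], size=n)
    maf = np.minimum(f, 1.0 - f)
    return np.maximum(maf, 0.001)


def _draw_classifications(rng: np.random.Generator, n: int
                          ) -> list[Classification]:
    labels = [c for c, _ in CLASS_PROBS]
    probs = np.array([p for _, p in CLASS_PROBS])
    picks = rng.choice(len(labels), size=n, p=probs / probs.sum())
    return [labels[int(i)] for i in picks]


def simulate_inputs(config: SimConfig
                    ) -> tuple[GeneAnnotation, list[SnpRecord], GeneListSet,
                               list[SnpRecord]]:
    """Generate (annotation, panel, gene lists, index SNPs) from a config.

    Genes are non-overlapping and uniformly placed; panel positions are
    uniform with Beta-distributed folded MAFs floored at 0.001; planted
    index SNPs are placed uniformly within ``planted_max_distance`` of a
    uniformly chosen dominant-labelled gene, the rest are drawn from the
    panel without replacement.
    """
    rng = np.random.default_rng(config.seed)
    genes = _place_genes(rng, config)
    ann = GeneAnnotation(genes)

    # curated disease-gene table
    dd_idx = rng.choice(len(genes), size=config.n_dd_genes, replace=False)
    u = rng.random(config.n_dd_genes)
    dd_rows: list[DDGeneRow] = []
    for i, gi in enumerate(dd_idx):
        if u[i] < config.fraction_dominant:
            req = "monoallelic"
        elif u[i] < config.fraction_dominant + P_BOTH:
            req = "both"
        else:
            req = "biallelic"
        g = genes[int(gi)]
        dd_rows.append(DDGeneRow(g.symbol, req, g.chrom))
    gene_lists = derive_gene_lists(dd_rows, exclude_chroms=())

    # reference panel
    chrom_pick = rng.integers(0, config.n_chroms, size=config.n_panel_snps)
    pos = rng.integers(1, config.chrom_length + 1, size=config.n_panel_snps)
    mafs = _draw_mafs(rng, config.maf_beta, config.n_panel_snps)
    panel = [
        SnpRecord(f"panel{i + 1}", str(int(c) + 1), int(p), float(m))
        for i, (c, p, m) in enumerate(zip(chrom_pick, pos, mafs))
    ]

    # index SNPs: planted near dominant-flagged genes, rest from the panel
    n_planted = int(round(config.planted_fraction * config.n_index_snps))
    flagged = sorted(gene_lists.dominant)
    if n_planted > 0 and not flagged:
        raise ValueError("planting requested but no dominant-labelled genes")
    by_symbol = {g.symbol: g for g in genes}
    classifications = _draw_classifications(rng, config.n_index_snps)
    index: list[SnpRecord] = []
    planted_mafs = _draw_mafs(rng, config.maf_beta, n_planted)
    for i in range(n_planted):
        g = by_symbol[flagged[int(rng.integers(0, len(flagged)))]]
        lo = max(1, g.start - config.planted_max_distance)
        hi = min(config.chrom_length, g.end + config.planted_max_distance)
        index.append(SnpRecord(
            f"index{i + 1}", g.chrom, int(rng.integers(lo, hi + 1)),
            float(planted_mafs[i]), classifications[i]))
    rest = rng.choice(config.n_panel_snps,
                      size=config.n_index_snps - n_planted, replace=False)
    for j, pi in enumerate(rest):
        src = panel[int(pi)]
        index.append(SnpRecord(
            f"index{n_planted + j + 1}", src.chrom, src.pos, src.maf,
            classifications[n_planted + j]))
    return ann, panel, gene_lists, index


def negative_control_snps(panel: Sequence[SnpRecord], n: int,
                          seed: int) -> list[SnpRecord]:
    """Uniform sample of ``n`` panel SNPs without replacement (seeded).

    Mirrors the random-SNP negative-control design: a trait-free SNP set
    drawn from the same panel should show no proximity enrichment.
    """
    if n > len(panel):
        raise ValueError(f"cannot sample {n} SNPs from a panel of {len(panel)}")
    rng = np.random.default_rng(seed)
    idx = rng.choice(len(panel), size=n, replace=False)
    return [panel[int(i)] for i in idx]


def write_simulated_inputs(config: SimConfig, outdir: str | Path
                           ) -> dict[str, Path]:
    """Write the four simulated inputs in their on-disk dialects.

    Produces genes.bed, panel.tsv, dd_genes.tsv and index_snps.tsv under
    ``outdir`` and returns their paths.
    """
    from .io_formats import write_snp_table

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    ann, panel, gene_lists, index = simulate_inputs(config)

    paths = {
        "genes": outdir / "genes.bed",
        "panel": outdir / "panel.tsv",
        "dd_genes": outdir / "dd_genes.tsv",
        "index_snps": outdir / "index_snps.tsv",
    }
    with open(paths["genes"], "w") as fh:
        for g in ann.genes:
            fh.write(f"{g.chrom}\t{g.start - 1}\t{g.end}\t{g.symbol}\n")
    write_snp_table(panel, paths["panel"], include_classification=False)
    with open(paths["dd_genes"], "w") as fh:
        fh.write("symbol\tallelic_requirement\tchrom\n")
        by_symbol = {g.symbol: g for g in ann.genes}
        both = gene_lists.dominant & gene_lists.recessive
        for sym in sorted(gene_lists.all):
            if sym in both:
                req = "both"
            elif sym in gene_lists.dominant:
                req = "monoallelic"
            else:
                req = "biallelic"
            fh.write(f"{sym}\t{req}\t{by_symbol[sym].chrom}\n")
    write_snp_table(index, paths["index_snps"])
    return paths
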