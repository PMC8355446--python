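"""Packaged worked example: dominant disease genes near birth-weight SNPs.

The packaged table lists, for a published birth-weight GWAS analysis, the
dominant developmental-disorder genes that were the nearest gene to at
least one lead SNP or fell within the 19/94/138/258 kb window of one,
together with the rsids involved and per-window SNP counts.  It contains
no coordinates: it is a membership encoding, sufficient to drive the two
enrichment statistics and to serve as a ground-truth check of the
counting logic.

Two cells of the printed table are internally ambiguous (a window count
larger than the number of rsids printed for the row, and vice versa);
the encoding keeps them exactly as printed, so only the unambiguous
aggregates (gene-level counts at every window; SNP-level counts for the
nearest-gene mode and the largest window) should be asserted against it.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import pandas as pd

from .annotate import SnpProximity
from .io_formats import Classification, SnpRecord, parse_classification

#: Window half-widths of the worked example, in bp.
WINDOWS = (19_000, 94_000, 138_000, 258_000)

_COLUMNS = {19_000: "w19kb", 94_000: "w94kb", 138_000: "w138kb",
            258_000: "w258kb"}

#: Placeholder symbol for a nearest gene that is not in the table (the
#: table only lists dominant disease genes, not every nearest gene).
OTHER_GENE = "NOT_IN_LIST"


@dataclass(frozen=True)
class WorkedExampleRow:
    """One gene of the worked example: flags are per-window SNP counts."""

    gene: str
    inheritance: str
    rsids: tuple[str, ...]
    classifications: tuple[Classification, ...]
    nearest: int
    window_counts: dict[int, int]


def _load_rows() -> list[WorkedExampleRow]:
    with resources.files("proximatch.data").joinpath(
            "dominant_gene_worked_example.tsv").open() as fh:
        df = pd.read_csv(fh, sep="\t", dtype=str).fillna("")
    rows = []
    for r in df.itertuples(index=False):
        rows.append(WorkedExampleRow(
            gene=r.gene,
            inheritance=r.inheritance,
            rsids=tuple(s.strip() for s in r.rsids.split(";")),
            classifications=tuple(parse_classification(s)
                                  for s in r.classifications.split(";")),
            nearest=int(r.nearest or 0),
            window_counts={w: int(getattr(r, col) or 0)
                           for w, col in _COLUMNS.items()},
        ))
    return rows


def worked_example_fixture() -> tuple[list[WorkedExampleRow],
                                      list[SnpProximity], frozenset[str]]:
    """The worked example as (rows, per-SNP proximity encoding, gene set).

    The proximity encoding has one entry per distinct rsid.  Its nearest
    gene is the table gene flagged "nearest" for that rsid (or the
    :data:`OTHER_GENE` placeholder when the true nearest gene is not a
    listed dominant gene), and its per-window gene sets contain the table
    genes flagged at that window for the rsid.  Distances and coordinates
    are not encoded (``nearest_distance`` is None throughout).
    """
    rows = _load_rows()
    dominant = frozenset(r.gene for r in rows)

    rsid_class: dict[str, Classification] = {}
    nearest_of: dict[str, str] = {}
    window_of: dict[str, dict[int, set[str]]] = {}
    for row in rows:
        for i, rsid in enumerate(row.rsids):
            cls = (row.classifications[i] if i < len(row.classifications)
                   else row.classifications[0])
            rsid_class.setdefault(rsid, cls)
            wg = window_of.setdefault(rsid, {w: set() for w in WINDOWS})
            if row.nearest > 0:
                nearest_of.setdefault(rsid, row.gene)
            for w in WINDOWS:
                if row.window_counts[w] > 0:
                    wg[w].add(row.gene)

    prox = []
    for i, rsid in enumerate(sorted(window_of)):
        snp = SnpRecord(rsid=rsid, chrom="1", pos=i + 1, maf=0.25,
                        classification=rsid_class[rsid])
        prox.append(SnpProximity(
            snp=snp,
            nearest_gene=nearest_of.get(rsid, OTHER_GENE),
            nearest_distance=None,
            window_genes={w: frozenset(g) for w, g in window_of[rsid].items()},
        ))
    return rows, prox, dominant
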