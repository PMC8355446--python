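"""Input/output for SNP tables, gene annotations, gene lists and results.

All tables are plain text (TSV, BED, GTF, or sites-only VCF).  Coordinates
are held internally as 1-based inclusive; BED input is converted at the
boundary.  Minor allele frequencies are folded (f > 0.5 becomes 1 - f) with
a warning, since panel files commonly store the ALT-allele frequency.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from enum import Enum
from pathlib import Path
from typing import TYPE_CHECKING, Iterable, Sequence

import pandas as pd

from .annotate import GeneAnnotation, GeneRecord

if TYPE_CHECKING:  # pragma: no cover
    from .enrichment import EnrichmentResult

logger = logging.getLogger(__name__)

AUTOSOMES = frozenset(str(i) for i in range(1, 23))
ALLOWED_CHROMS = AUTOSOMES | {"X"}


class Classification(str, Enum):
    """Origin of a lead SNP's effect (fetal genome vs. maternal genome)."""

    FETAL_ONLY = "fetal_only"
    MATERNAL_ONLY = "maternal_only"
    FETAL_AND_MATERNAL_SAME = "fetal_and_maternal_same"
    FETAL_AND_MATERNAL_OPPOSITE = "fetal_and_maternal_opposite"
    UNCLASSIFIED = "unclassified"
    NONE = "none"


_CLASSIFICATION_ALIASES = {
    "fetal only": Classification.FETAL_ONLY,
    "fetal_only": Classification.FETAL_ONLY,
    "maternal only": Classification.MATERNAL_ONLY,
    "maternal_only": Classification.MATERNAL_ONLY,
    "fetal and maternal": Classification.FETAL_AND_MATERNAL_SAME,
    "fetal and maternal - same direction": Classification.FETAL_AND_MATERNAL_SAME,
    "fetal and maternal_-_same direction": Classification.FETAL_AND_MATERNAL_SAME,
    "fetal_and_maternal_same": Classification.FETAL_AND_MATERNAL_SAME,
    "fetal and maternal - opposite directions": Classification.FETAL_AND_MATERNAL_OPPOSITE,
    "fetal and maternal_-_opposite directions": Classification.FETAL_AND_MATERNAL_OPPOSITE,
    "fetal_and_maternal_opposite": Classification.FETAL_AND_MATERNAL_OPPOSITE,
    "unclassified": Classification.UNCLASSIFIED,
    "none": Classification.NONE,
    "": Classification.NONE,
}


def parse_classification(label: str | None) -> Classification:
    """Map a free-text effect-classification label onto the enum."""
    if label is None or (isinstance(label, float) and pd.isna(label)):
        return Classification.NONE
    key = str(label).strip().lower()
    try:
        return _CLASSIFICATION_ALIASES[key]
    except KeyError:
        raise ValueError(f"unknown SNP classification label: {label!r}") from None


def normalise_chrom(chrom: str) -> str:
    """Strip any 'chr' prefix and validate against autosomes + X."""
    c = str(chrom).strip()
    if c.lower().startswith("chr"):
        c = c[3:]
    if c not in ALLOWED_CHROMS:
        raise ValueError(f"chromosome {chrom!r} not in allowed set 1..22, X")
    return c


@dataclass(frozen=True)
class SnpRecord:
    """A lead or reference-panel SNP: identifier, position and MAF."""

    rsid: str
    chrom: str
    pos: int
    maf: float
    classification: Classification = Classification.NONE

    def __post_init__(self) -> None:
        if not self.rsid:
            raise ValueError("rsid must be non-empty")
        if self.chrom not in ALLOWED_CHROMS:
            raise ValueError(f"chromosome {self.chrom!r} not in allowed set")
        if self.pos < 1:
            raise ValueError(f"{self.rsid}: position must be >= 1, got {self.pos}")
        if not 0.0 < self.maf <= 0.5:
            raise ValueError(
                f"{self.rsid}: MAF must be in (0, 0.5], got {self.maf}"
            )


@dataclass(frozen=True)
class DDGeneRow:
    """One curated disease-gene entry: symbol, allelic requirement, chromosome."""

    symbol: str
    allelic_requirement: str  # monoallelic | biallelic | both
    chrom: str

    def __post_init__(self) -> None:
        if self.allelic_requirement not in ("monoallelic", "biallelic", "both"):
            raise ValueError(
                f"{self.symbol}: allelic requirement must be monoallelic, "
                f"biallelic or both, got {self.allelic_requirement!r}"
            )


#: Verbose allelic-requirement vocabulary (as used by curated clinical gene
#: databases) mapped onto the three-way scheme used here.
_ALLELIC_ALIASES = {
    "monoallelic": "monoallelic",
    "monoallelic_autosomal": "monoallelic",
    "dominant": "monoallelic",
    "biallelic": "biallelic",
    "biallelic_autosomal": "biallelic",
    "recessive": "biallelic",
    "both": "both",
    "monoallelic_and_biallelic": "both",
}


@dataclass(frozen=True)
class GeneListSet:
    """The four analysis gene lists, as disjoint/nested sets of symbols.

    ``dominant`` holds genes whose disorders follow a dominant (monoallelic)
    or dual mode of inheritance; ``recessive`` the biallelic or dual ones;
    ``recessive_only`` = recessive minus dominant; ``all`` their union.
    """

    all: frozenset[str]
    dominant: frozenset[str]
    recessive: frozenset[str]
    recessive_only: frozenset[str]

    def __post_init__(self) -> None:
        if self.recessive_only != self.recessive - self.dominant:
            raise ValueError("recessive_only must equal recessive \\ dominant")
        if self.all != self.dominant | self.recessive:
            raise ValueError("all must equal dominant | recessive")

    def named_lists(self) -> dict[str, frozenset[str]]:
        return {
            "all": self.all,
            "dominant": self.dominant,
            "recessive": self.recessive,
            "recessive_only": self.recessive_only,
        }


# ---------------------------------------------------------------------------
# Gene annotation readers


def _merge_spans(records: Iterable[GeneRecord]) -> list[GeneRecord]:
    """Collapse per-transcript records into one span per symbol (union)."""
    by_symbol: dict[str, GeneRecord] = {}
    for rec in records:
        prev = by_symbol.get(rec.symbol)
        if prev is None:
            by_symbol[rec.symbol] = rec
        else:
            if prev.chrom != rec.chrom:
                raise ValueError(
                    f"gene {rec.symbol} appears on chromosomes "
                    f"{prev.chrom} and {rec.chrom}"
                )
            by_symbol[rec.symbol] = GeneRecord(
                rec.symbol,
                rec.chrom,
                min(prev.start, rec.start),
                max(prev.end, rec.end),
            )
    return list(by_symbol.values())


def _parse_gtf_attributes(attrs: str) -> dict[str, str]:
    out: dict[str, str] = {}
    for item in attrs.strip().rstrip(";").split(";"):
        item = item.strip()
        if not item:
            continue
        key, _, value = item.partition(" ")
        out[key] = value.strip().strip('"')
    return out


def load_gene_annotation(
    path: str | Path,
    format: str = "bed",
    exclude_chroms: Sequence[str] = (),
) -> GeneAnnotation:
    """Read a gene annotation from BED4+ or GTF into one span per symbol.

    BED coordinates (0-based half-open) are converted to 1-based inclusive.
    GTF ``gene`` features are preferred; if none are present the union of
    all features carrying a ``gene_name`` (or ``gene_id``) is used.
    """
    path = Path(path)
    records: list[GeneRecord] = []
    exclude = {normalise_chrom(c) for c in exclude_chroms}
    with open(path) as fh:
        lines = fh.readlines()
    if format == "bed":
        for lineno, line in enumerate(lines, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 4:
                raise ValueError(
                    f"{path}:{lineno}: BED line has {len(fields)} fields, need >= 4"
                )
            try:
                chrom = normalise_chrom(fields[0])
                start0, end0 = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: {exc}") from None
            if end0 <= start0:
                raise ValueError(f"{path}:{lineno}: end <= start")
            records.append(GeneRecord(fields[3], chrom, start0 + 1, end0))
    elif format == "gtf":
        gene_rows: list[GeneRecord] = []
        any_rows: list[GeneRecord] = []
        for lineno, line in enumerate(lines, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 9:
                raise ValueError(
                    f"{path}:{lineno}: GTF line has {len(fields)} fields, need 9"
                )
            attrs = _parse_gtf_attributes(fields[8])
            symbol = attrs.get("gene_name") or attrs.get("gene_id")
            if not symbol:
                raise ValueError(f"{path}:{lineno}: no gene_name/gene_id attribute")
            try:
                chrom = normalise_chrom(fields[0])
                start, end = int(fields[3]), int(fields[4])
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: {exc}") from None
            rec = GeneRecord(symbol, chrom, start, end)
            any_rows.append(rec)
            if fields[2] == "gene":
                gene_rows.append(rec)
        records = gene_rows if gene_rows else any_rows
    else:
        raise ValueError(f"unknown gene annotation format: {format!r}")

    merged = _merge_spans(records)
    if exclude:
        n_before = len(merged)
        merged = [g for g in merged if g.chrom not in exclude]
        if n_before != len(merged):
            logger.info(
                "excluded %d genes on chromosomes %s", n_before - len(merged), exclude
            )
    if not merged:
        logger.warning("gene annotation %s is empty", path)
    return GeneAnnotation(merged)


# ---------------------------------------------------------------------------
# SNP tables


def _record_from_row(rsid: str, chrom: str, pos: int, maf: float,
                     classification: Classification) -> SnpRecord:
    if not 0.0 < maf < 1.0:
        raise ValueError(f"{rsid}: allele frequency must be in (0, 1), got {maf}")
    if maf > 0.5:
        logger.warning("%s: frequency %.4g folded to MAF %.4g", rsid, maf, 1 - maf)
        maf = 1.0 - maf
    return SnpRecord(str(rsid), normalise_chrom(chrom), int(pos), float(maf),
                     classification)


def load_snp_table(path: str | Path) -> list[SnpRecord]:
    """Read a headered TSV of SNPs (rsid, chrom, pos, maf[, classification])."""
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str, "rsid": str},
                     float_precision="round_trip")
    required = {"rsid", "chrom", "pos", "maf"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing required columns {sorted(missing)}")
    has_cls = "classification" in df.columns
    out = []
    for row in df.itertuples(index=False):
        cls = parse_classification(getattr(row, "classification", None)) if has_cls \
            else Classification.NONE
        out.append(_record_from_row(row.rsid, row.chrom, row.pos, row.maf, cls))
    return out


def load_reference_panel(
    path: str | Path,
    format: str = "tsv",
    min_maf: float = 0.001,
) -> list[SnpRecord]:
    """Read the reference SNP panel and drop SNPs with MAF below ``min_maf``.

    The default threshold (0.1%) mirrors the usual imputation-panel cut-off.
    VCF input is sites-only; the MAF is taken from INFO/AF and folded.
    """
    if not 0.0 <= min_maf <= 0.5:
        raise ValueError(f"min_maf must be in [0, 0.5], got {min_maf}")
    if format == "tsv":
        snps = load_snp_table(path)
    elif format == "vcf_sites":
        snps = _load_vcf_sites(path)
    else:
        raise ValueError(f"unknown panel format: {format!r}")
    kept = [s for s in snps if s.maf >= min_maf]
    if len(kept) != len(snps):
        logger.info("panel %s: excluded %d of %d SNPs below MAF %g",
                    path, len(snps) - len(kept), len(snps), min_maf)
    return kept


def _load_vcf_sites(path: str | Path) -> list[SnpRecord]:
    import pysam

    out: list[SnpRecord] = []
    with pysam.VariantFile(str(path)) as vcf:
        for i, rec in enumerate(vcf):
            af = rec.info.get("AF")
            if af is None:
                raise ValueError(f"{path}: record {rec.chrom}:{rec.pos} has no INFO/AF")
            af = af[0] if isinstance(af, tuple) else float(af)
            rsid = rec.id or f"{rec.chrom}:{rec.pos}"
            out.append(_record_from_row(rsid, rec.chrom, rec.pos, float(af),
                                        Classification.NONE))
    return out


def write_snp_table(snps: Sequence[SnpRecord], path: str | Path,
                    include_classification: bool = True) -> None:
    """Write SNPs as the headered TSV dialect read by :func:`load_snp_table`."""
    cols = {
        "rsid": [s.rsid for s in snps],
        "chrom": [s.chrom for s in snps],
        "pos": [s.pos for s in snps],
        "maf": [s.maf for s in snps],
    }
    if include_classification:
        cols["classification"] = [s.classification.value for s in snps]
    # %.17g guarantees MAFs survive a write/read round trip bit-exactly
    pd.DataFrame(cols).to_csv(path, sep="\t", index=False, float_format="%.17g")


# ---------------------------------------------------------------------------
# Gene lists


def load_dd_gene_table(path: str | Path) -> list[DDGeneRow]:
    """Read a curated gene list TSV (symbol, allelic_requirement, chrom).

    Verbose allelic-requirement labels ("monoallelic_autosomal", ...) are
    mapped onto {monoallelic, biallelic, both}.  A symbol listed twice with
    different requirements is merged to "both".
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"symbol", "allelic_requirement", "chrom"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing required columns {sorted(missing)}")
    merged: dict[str, DDGeneRow] = {}
    for row in df.itertuples(index=False):
        key = str(row.allelic_requirement).strip().lower()
        try:
            req = _ALLELIC_ALIASES[key]
        except KeyError:
            raise ValueError(
                f"{path}: unknown allelic requirement {row.allelic_requirement!r} "
                f"for gene {row.symbol}"
            ) from None
        chrom = normalise_chrom(row.chrom)
        prev = merged.get(row.symbol)
        if prev is not None and prev.allelic_requirement != req:
            req = "both"
        merged[row.symbol] = DDGeneRow(str(row.symbol), req, chrom)
    return list(merged.values())


def derive_gene_lists(
    rows: Sequence[DDGeneRow],
    exclude_chroms: Iterable[str] = ("X",),
) -> GeneListSet:
    """Split curated genes into all/dominant/recessive/recessive-only lists.

    Genes on excluded chromosomes (by default X, where dominant/recessive
    classification is ambiguous) are absent from every list.
    """
    exclude = {normalise_chrom(c) for c in exclude_chroms}
    kept = [r for r in rows if r.chrom not in exclude]
    dominant = frozenset(r.symbol for r in kept
                         if r.allelic_requirement in ("monoallelic", "both"))
    recessive = frozenset(r.symbol for r in kept
                          if r.allelic_requirement in ("biallelic", "both"))
    return GeneListSet(
        all=dominant | recessive,
        dominant=dominant,
        recessive=recessive,
        recessive_only=recessive - dominant,
    )


def select_lead_snps(
    snps: Sequence[SnpRecord],
    drop_classifications: Iterable[Classification] = (Classification.MATERNAL_ONLY,),
    drop_chroms: Iterable[str] = ("X",),
) -> list[SnpRecord]:
    """Filter lead SNPs, dropping unwanted effect classes and chromosomes.

    The default drops maternal-only loci (no direct fetal effect) and the X
    chromosome; sensitivity analyses additionally drop unclassified loci.
    Order is preserved.
    """
    drop_cls = set(drop_classifications)
    drop_chr = {normalise_chrom(c) for c in drop_chroms}
    kept, n_cls, n_chr = [], 0, 0
    for s in snps:
        if s.classification in drop_cls:
            n_cls += 1
        elif s.chrom in drop_chr:
            n_chr += 1
        else:
            kept.append(s)
    logger.info("select_lead_snps: kept %d of %d (dropped %d by classification, "
                "%d by chromosome)", len(kept), len(snps), n_cls, n_chr)
    return kept


# ---------------------------------------------------------------------------
# Results table


def _window_label(w: int) -> str:
    return f"{w // 1000}kb" if w % 1000 == 0 else f"{w}bp"


def write_results_table(results: Sequence["EnrichmentResult"],
                        path: str | Path) -> None:
    """Write enrichment results as a TSV, one row per gene list.

    Columns follow the nearest-then-windows layout: for each mode the
    observed gene-level count and p-value, then the SNP-level pair.
    """
    modes: list[tuple[str, int | None]] = []
    for r in results:
        key = (r.mode, r.window)
        if key not in modes:
            modes.append(key)
    gene_lists: list[str] = []
    for r in results:
        if r.gene_list_name not in gene_lists:
            gene_lists.append(r.gene_list_name)

    def mode_label(mode: str, window: int | None) -> str:
        return "nearest" if mode == "nearest" else _window_label(window)

    header = ["gene_list"]
    for mode, window in modes:
        lab = mode_label(mode, window)
        header += [f"n_genes_{lab}", f"p_genes_{lab}",
                   f"n_snps_{lab}", f"p_snps_{lab}"]
    by_cell = {(r.gene_list_name, r.mode, r.window): r for r in results}
    lines = ["\t".join(header)]
    for gl in gene_lists:
        row = [gl]
        for mode, window in modes:
            r = by_cell.get((gl, mode, window))
            if r is None:
                row += ["", "", "", ""]
            else:
                row += [str(r.observed.n_genes), r.p_genes.formatted,
                        str(r.observed.n_snps), r.p_snps.formatted]
        lines.append("\t".join(row))
    Path(path).write_text("\n".join(lines) + "\n")
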