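"""Nearest-gene annotation and data-driven window sizes.

Annotates a few SNPs against a small gene annotation and shows how window
half-widths can be derived from a vector of SNP-to-gene distances (their
lower quartile, median, mean and upper quartile).
"""

from proximatch import (GeneAnnotation, GeneRecord, SnpRecord, annotate_snps,
                        derive_window_sizes)

annotation = GeneAnnotation([
    GeneRecord("GRB10", "7", 50_600_000, 50_800_000),
    GeneRecord("IGF2BP3", "7", 23_300_000, 23_450_000),
    GeneRecord("KLF14", "7", 130_400_000, 130_420_000),
])
snps = [
    SnpRecord("rs_a", "7", 50_650_000, 0.21),   # inside GRB10
    SnpRecord("rs_b", "7", 23_500_000, 0.33),   # 50 kb past IGF2BP3
    SnpRecord("rs_c", "7", 130_000_000, 0.05),  # 400 kb before KLF14
]

windows = derive_window_sizes([12_000, 31_000, 87_000, 155_000,
                               60_000, 240_000, 95_000, 140_000])
print("derived window half-widths (bp):", windows.sizes)

for p in annotate_snps(snps, annotation, windows):
    genes = {w: sorted(g) for w, g in p.window_genes.items()}
    print(f"{p.snp.rsid}: nearest={p.nearest_gene} "
          f"at {p.nearest_distance} bp; window genes: {genes}")

print("\nDistance is 0 inside a gene span; a nearest gene can still lie "
      "outside the smallest window.")
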