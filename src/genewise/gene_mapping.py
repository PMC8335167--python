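"""SNP-to-gene assignment with a symmetric flanking window.

A SNP belongs to a gene iff it lies on the same chromosome within
``[start - flank, end + flank]``, both boundaries inclusive (the default
flank is 50 kb on each side).  A SNP inside several extended gene intervals
is assigned to every one of them — no nearest-gene tie-breaking.
"""

from __future__ import annotations

from bisect import bisect_left, bisect_right
from dataclasses import dataclass
from typing import Sequence

from .io_formats import GeneRegion, SnpAssocRecord

__all__ = ["GeneSnpAssignment", "assign_snps", "count_tested_genes", "DEFAULT_FLANK_BP"]

DEFAULT_FLANK_BP = 50_000


@dataclass
class GeneSnpAssignment:
    """A gene region together with the association-table indices of its SNPs."""

    gene: GeneRegion
    snp_indices: list[int]

    @property
    def n_snps(self) -> int:
        return len(self.snp_indices)


def assign_snps(
    snps: Sequence[SnpAssocRecord],
    genes: Sequence[GeneRegion],
    flank_bp: int = DEFAULT_FLANK_BP,
) -> list[GeneSnpAssignment]:
    """Assign every SNP to every gene whose flanked interval contains it.

    Returns one assignment per input gene, in gene order; genes with no
    assigned SNPs appear with ``n_snps == 0`` (downstream testing skips
    them).  ``snp_indices`` are ascending indices into ``snps``.
    """
    if flank_bp < 0:
        raise ValueError("flank_bp must be >= 0")

    by_chrom: dict[str, tuple[list[int], list[int]]] = {}
    for chrom in {s.chrom for s in snps}:
        order = sorted((i for i, s in enumerate(snps) if s.chrom == chrom),
                       key=lambda i: (snps[i].pos, i))
        by_chrom[chrom] = ([snps[i].pos for i in order], order)

    out: list[GeneSnpAssignment] = []
    for gene in genes:
        positions, order = by_chrom.get(gene.chrom, ([], []))
        lo = bisect_left(positions, gene.start - flank_bp)
        hi = bisect_right(positions, gene.end + flank_bp)
        out.append(GeneSnpAssignment(gene, sorted(order[lo:hi])))
    return out


def count_tested_genes(assignments: Sequence[GeneSnpAssignment]) -> int:
    """Number of genes carrying at least one SNP — the divisor of the
    per-method stringent Bonferroni threshold."""
    return sum(1 for a in assignments if a.n_snps >= 1)
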