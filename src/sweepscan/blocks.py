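"""Haplotype-block partitioning by the four-gamete test.

Under the infinite-sites assumption, a pair of SNPs exhibiting all four
two-locus gametes {00, 01, 10, 11} witnesses a historical recombination
between them.  Blocks are built greedily left to right per scaffold: a block
``[i..j]`` extends to ``j+1`` iff no site pair ``(k, j+1)``, ``k`` in the
block, shows all four gametes across the pooled samples.  The partition
therefore tiles each scaffold without gaps or overlaps, contains no
recombination witness inside any block, and — being computed on pooled
samples — is comparable across populations for spectrum plots.  Pairs are
evaluated over samples non-missing at both sites, so the partition can
bootstrap imputation.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .matrix import MISSING, HaplotypeMatrix
from .vcfio import GeneInterval

log = logging.getLogger(__name__)


@dataclass
class HaplotypeBlock:
    """Contiguous SNP interval with optional per-population spectrum."""

    scaffold: str
    start: int              # global site index, inclusive
    end: int                # global site index, inclusive
    start_bp: int
    end_bp: int
    spectra: dict[str, dict[str, int]] | None = None   # pop → haplotype string → count
    haplotype_ids: dict[str, str] | None = None        # haplotype string → stable id
    contains_selected: bool = False
    genic: bool | None = None
    genes: list[str] = field(default_factory=list)

    @property
    def n_snps(self) -> int:
        return self.end - self.start + 1

    @property
    def span_bp(self) -> int:
        return self.end_bp - self.start_bp + 1


def _four_gametes(col_block: np.ndarray, col_new: np.ndarray) -> np.ndarray:
    """Per block-column flag: does (column, new site) show all four gametes?

    ``col_block`` is (n_samples, width); missing calls drop the pair.
    """
    c = col_new[:, None]
    ok = (col_block != MISSING) & (c != MISSING)
    g00 = ((col_block == 0) & (c == 0) & ok).any(axis=0)
    g01 = ((col_block == 0) & (c == 1) & ok).any(axis=0)
    g10 = ((col_block == 1) & (c == 0) & ok).any(axis=0)
    g11 = ((col_block == 1) & (c == 1) & ok).any(axis=0)
    return g00 & g01 & g10 & g11


def partition_blocks(matrix: HaplotypeMatrix) -> list[HaplotypeBlock]:
    """Greedy maximal four-gamete blocks tiling every scaffold."""
    blocks: list[HaplotypeBlock] = []
    calls = matrix.calls
    for scaf in dict.fromkeys(matrix.scaffolds):
        sites = np.flatnonzero(matrix.scaffolds == scaf)
        start = int(sites[0])
        for j in sites[1:]:
            j = int(j)
            if _four_gametes(calls[:, start:j], calls[:, j]).any():
                blocks.append(_make_block(matrix, scaf, start, j - 1))
                start = j
        blocks.append(_make_block(matrix, scaf, start, int(sites[-1])))
    return blocks


def _make_block(matrix: HaplotypeMatrix, scaf, start: int, end: int) -> HaplotypeBlock:
    return HaplotypeBlock(
        scaffold=str(scaf),
        start=start,
        end=end,
        start_bp=int(matrix.positions_bp[start]),
        end_bp=int(matrix.positions_bp[end]),
    )


def block_spectrum(matrix: HaplotypeMatrix, block: HaplotypeBlock) -> dict[str, dict[str, int]]:
    """Per-population haplotype frequency table over the block's sites.

    Requires complete calls inside the block.  Haplotype identifiers are
    stable across populations: assigned by descending pooled frequency, ties
    broken lexicographically.  The result is stored on ``block.spectra``.
    """
    sub = matrix.calls[:, block.start:block.end + 1]
    if np.any(sub == MISSING):
        raise ValueError("block spectrum requires complete calls; run rescue_missing")
    strings = ["".join(str(int(c)) for c in row) for row in sub]
    pooled: dict[str, int] = {}
    for s in strings:
        pooled[s] = pooled.get(s, 0) + 1
    ordered = sorted(pooled, key=lambda s: (-pooled[s], s))
    block.haplotype_ids = {s: f"H{i+1}" for i, s in enumerate(ordered)}
    labels = matrix.population_labels
    spectra: dict[str, dict[str, int]] = {}
    for pop in matrix.population_names():
        spectra[pop] = {}
        for s, lab in zip(strings, labels):
            if lab == pop:
                spectra[pop][s] = spectra[pop].get(s, 0) + 1
    block.spectra = spectra
    return spectra


def blocks_containing(blocks: list[HaplotypeBlock], selected_sites) -> list[HaplotypeBlock]:
    """Blocks overlapping at least one selected SNP (by global site index)."""
    selected = np.asarray(sorted(set(int(s) for s in selected_sites)))
    hits: list[HaplotypeBlock] = []
    for b in blocks:
        inside = selected[(selected >= b.start) & (selected <= b.end)]
        b.contains_selected = inside.size > 0
        if b.contains_selected:
            hits.append(b)
    return hits


def annotate_blocks(
    blocks: list[HaplotypeBlock], gene_intervals: list[GeneInterval]
) -> list[HaplotypeBlock]:
    """Mark each block genic/intergenic by bp-span intersection with genes."""
    by_scaf: dict[str, list[GeneInterval]] = {}
    for g in gene_intervals:
        by_scaf.setdefault(g.scaffold, []).append(g)
    block_scafs = {b.scaffold for b in blocks}
    for scaf in by_scaf:
        if scaf not in block_scafs:
            log.warning("annotate_blocks: gene scaffold %r absent from blocks; skipped", scaf)
    for b in blocks:
        genes = [
            g.gene_id
            for g in by_scaf.get(b.scaffold, [])
            if g.start_bp <= b.end_bp and g.end_bp >= b.start_bp
        ]
        b.genes = genes
        b.genic = bool(genes)
    return blocks


def blocks_table(blocks: list[HaplotypeBlock]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "scaffold": [b.scaffold for b in blocks],
            "start_idx": [b.start for b in blocks],
            "end_idx": [b.end for b in blocks],
            "start_bp": [b.start_bp for b in blocks],
            "end_bp": [b.end_bp for b in blocks],
            "n_snps": [b.n_snps for b in blocks],
            "contains_selected": [b.contains_selected for b in blocks],
            "genic": [b.genic for b in blocks],
            "genes": [";".join(b.genes) for b in blocks],
        }
    )
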