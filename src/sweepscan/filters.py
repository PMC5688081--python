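"""Representation filters and missing-call rescue.

The scan's upstream filters are quality-agnostic: exclusion of blacklisted
regions (unplaced scaffolds, NUMTs) given as BED, restriction to biallelic
SNPs, and a pooled minor-allele-frequency cut.  All filters are idempotent
and never mutate surviving calls.  ``rescue_missing`` imputes missing haploid
calls from the nearest complete haplotype within each haplotype block.
"""
from __future__ import annotations

import logging
from typing import Sequence

import numpy as np

from .matrix import MISSING, HaplotypeMatrix
from .vcfio import BedInterval

log = logging.getLogger(__name__)


def exclude_regions(matrix: HaplotypeMatrix, regions: Sequence[BedInterval]) -> HaplotypeMatrix:
    """Drop sites falling inside any BED interval (0-based half-open).

    A site at 1-based position ``p`` is inside ``(start, end)`` iff
    ``start < p <= end`` after coordinate conversion, i.e. 0-based position
    ``p - 1`` lies in ``[start, end)``.
    """
    if not regions:
        return matrix.subset_sites(np.arange(matrix.n_sites))
    keep = np.ones(matrix.n_sites, dtype=bool)
    by_scaf: dict[str, list[BedInterval]] = {}
    for iv in regions:
        by_scaf.setdefault(iv.scaffold, []).append(iv)
    for scaf, ivs in by_scaf.items():
        mask = matrix.scaffolds == scaf
        if not mask.any():
            continue
        pos0 = matrix.positions_bp[mask] - 1  # 0-based
        inside = np.zeros(pos0.shape, dtype=bool)
        for iv in ivs:
            inside |= (pos0 >= iv.start) & (pos0 < iv.end)
        keep[np.flatnonzero(mask)[inside]] = False
    dropped = int((~keep).sum())
    if dropped:
        log.info("exclude_regions: removed %d of %d sites", dropped, matrix.n_sites)
    return matrix.subset_sites(keep)


def filter_biallelic(matrix: HaplotypeMatrix) -> HaplotypeMatrix:
    """Keep only sites with a single ALT allele."""
    multi = np.array(["," in str(a) for a in matrix.alt_allele])
    # calls with allele index > 1 also witness a multi-allelic record
    multi |= np.any(matrix.calls > 1, axis=0)
    removed = int(multi.sum())
    if removed:
        log.info("filter_biallelic: removed %d multi-allelic sites", removed)
    return matrix.subset_sites(~multi)


def filter_maf(matrix: HaplotypeMatrix, threshold: float = 0.05) -> HaplotypeMatrix:
    """Drop sites with pooled minor-allele frequency strictly below ``threshold``.

    Frequency is computed over non-missing calls pooled across all samples.
    Sites with zero non-missing calls are dropped and logged.
    """
    if not 0.0 <= threshold <= 0.5:
        raise ValueError("MAF threshold must be in [0, 0.5]")
    nonmiss = (matrix.calls != MISSING).sum(axis=0)
    alt = (matrix.calls == 1).sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        freq = alt / nonmiss
    maf = np.minimum(freq, 1.0 - freq)
    empty = nonmiss == 0
    if empty.any():
        log.info("filter_maf: dropped %d sites with no non-missing calls", int(empty.sum()))
    keep = ~empty & (maf >= threshold)
    log.info(
        "filter_maf: kept %d of %d sites at threshold %.3g",
        int(keep.sum()), matrix.n_sites, threshold,
    )
    return matrix.subset_sites(keep)


def rescue_missing(matrix: HaplotypeMatrix, blocks=None) -> HaplotypeMatrix:
    """Impute missing calls from the nearest complete haplotype per block.

    For every block (from :func:`sweepscan.blocks.partition_blocks`, computed
    on the fly when ``blocks`` is ``None``), candidate haplotypes are the
    distinct strings carried by samples with no missing call inside the block,
    ordered by descending pooled frequency then lexicographically.  A sample
    with missing calls takes, at each of them, the allele of the candidate
    minimising Hamming distance over the sample's non-missing sites in the
    block (ties → the lower-index, i.e. more frequent, candidate).  If a block
    has no complete haplotype, the nearest other sample (smallest mismatch
    fraction over mutually observed sites) that carries a call at the missing
    site donates its allele; a sample missing at every block site falls back
    to the per-site majority allele (logged).

    Non-missing calls are never altered.
    """
    if not matrix.has_missing():
        return matrix.copy()
    from .blocks import partition_blocks  # deferred: blocks module is downstream

    if blocks is None:
        blocks = partition_blocks(matrix)
    calls = matrix.calls.copy()
    n_majority = 0
    for block in blocks:
        cols = slice(block.start, block.end + 1)
        sub = calls[:, cols]
        miss_rows = np.flatnonzero((sub == MISSING).any(axis=1))
        if miss_rows.size == 0:
            continue
        complete = np.flatnonzero(~(sub == MISSING).any(axis=1))
        # per-site majority fallback (ref allele wins exact ties)
        maj = np.where(
            (sub == 1).sum(axis=0) > (sub == 0).sum(axis=0), 1, 0
        ).astype(np.int8)
        if complete.size == 0:
            # no complete haplotype in the block: donate from the nearest
            # sample over mutually observed sites, per missing site
            original = sub.copy()
            for i in miss_rows:
                row = sub[i]
                known_i = original[i] != MISSING
                if not known_i.any():
                    row[:] = maj
                    n_majority += 1
                    continue
                dists = np.full(original.shape[0], np.inf)
                for k in range(original.shape[0]):
                    if k == i:
                        continue
                    shared = known_i & (original[k] != MISSING)
                    if shared.any():
                        dists[k] = (original[k][shared] != original[i][shared]).mean()
                order = np.argsort(dists, kind="stable")
                for j in np.flatnonzero(original[i] == MISSING):
                    donor = next(
                        (k for k in order
                         if np.isfinite(dists[k]) and original[k, j] != MISSING),
                        None,
                    )
                    row[j] = maj[j] if donor is None else original[donor, j]
            continue
        # candidates by descending pooled frequency, then lexicographic string
        strings, counts = np.unique(
            sub[complete].astype(np.uint8), axis=0, return_counts=True
        )
        order = sorted(
            range(len(strings)),
            key=lambda k: (-counts[k], strings[k].tobytes()),
        )
        cands = strings[order].astype(np.int8)
        for i in miss_rows:
            row = sub[i]
            known = row != MISSING
            if not known.any():
                row[:] = maj
                n_majority += 1
                continue
            dists = (cands[:, known] != row[known]).sum(axis=1)
            best = cands[int(np.argmin(dists))]  # argmin takes the lowest index on ties
            row[~known] = best[~known]
    if n_majority:
        log.info(
            "rescue_missing: %d sample-blocks imputed by per-site majority", n_majority
        )
    out = matrix.copy()
    out.calls = calls
    assert not np.any(out.calls == MISSING)
    return out
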