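"""Planted-sweep recovery and null-calibration benchmarks.

These run the full pipeline on replicate simulations and score how often the
planted selected loci (or a close neighbour) land in the F_ST ∩ Rsb outlier
intersection, and what fraction of SNPs each metric flags when nothing is
selected.  They are the package's own yardstick for the scan's power at
desk-scale problem sizes.
"""
from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .filters import filter_maf, rescue_missing
from .matrix import HaplotypeMatrix
from .scan import run_scan
from .simulate import SimulationConfig, simulate_three_populations

#: study-shaped benchmark conditions: 30/30/30 samples, 2,000 SNPs, five
#: selected loci with s = 0.1, twelve post-founding generations
BENCHMARK_CONFIG = SimulationConfig()


@dataclass
class RecoveryReplicate:
    seed: int
    n_sites_scanned: int
    recovered: int                 # planted loci with an intersection hit nearby
    n_planted: int
    intersection_size: int


def _recovered_loci(
    matrix_scanned: HaplotypeMatrix,
    planted_positions: np.ndarray,
    selected_site_idx: np.ndarray,
    window: int,
) -> int:
    """Planted loci with a selected SNP within ``window`` scanned-site ordinals."""
    if selected_site_idx.size == 0:
        return 0
    pos = matrix_scanned.positions_bp
    hits = 0
    for p in planted_positions:
        ordinal = int(np.searchsorted(pos, p))
        lo, hi = ordinal - window, ordinal + window
        if np.any((selected_site_idx >= lo) & (selected_site_idx <= hi)):
            hits += 1
    return hits


def recovery_replicate(
    seed: int,
    config: SimulationConfig = BENCHMARK_CONFIG,
    window: int = 10,
    maf: float = 0.05,
    quantile: float = 0.99,
) -> RecoveryReplicate:
    """Simulate, filter, scan, and score one planted-sweep replicate."""
    cfg = replace(config, seed=seed)
    matrix, truth = simulate_three_populations(cfg)
    if matrix.has_missing():
        matrix = rescue_missing(matrix)
    planted_pos = matrix.positions_bp[np.array(truth.selected_site_indices, dtype=int)]
    matrix = filter_maf(matrix, maf)
    result = run_scan(matrix, quantile=quantile)
    recovered = _recovered_loci(
        matrix, planted_pos, result.selected_sites, window
    )
    return RecoveryReplicate(
        seed=seed,
        n_sites_scanned=matrix.n_sites,
        recovered=recovered,
        n_planted=len(truth.selected_site_indices),
        intersection_size=int(result.table["selected"].sum()),
    )


def recovery_benchmark(
    n_replicates: int = 20,
    base_seed: int = 1,
    config: SimulationConfig = BENCHMARK_CONFIG,
    window: int = 10,
    min_recovered: int = 3,
) -> tuple[float, list[RecoveryReplicate]]:
    """Fraction of replicates recovering ≥ ``min_recovered`` planted loci."""
    reps = [
        recovery_replicate(base_seed + i, config=config, window=window)
        for i in range(n_replicates)
    ]
    frac = float(np.mean([r.recovered >= min_recovered for r in reps]))
    return frac, reps


def null_outlier_rates(
    seed: int,
    config: SimulationConfig = BENCHMARK_CONFIG,
    maf: float = 0.05,
    quantile: float = 0.99,
) -> dict[str, float]:
    """Per-metric outlier fractions under s = 0 (no selection planted)."""
    cfg = replace(config, seed=seed, sel_coeff=0.0)
    matrix, _ = simulate_three_populations(cfg)
    if matrix.has_missing():
        matrix = rescue_missing(matrix)
    matrix = filter_maf(matrix, maf)
    result = run_scan(matrix, quantile=quantile)
    n_fst = int(np.isfinite(result.css_fst.css).sum())
    n_rsb = int(np.isfinite(result.css_rsb.css).sum())
    return {
        "fst_rate": float(result.table["outlier_fst"].sum() / n_fst),
        "rsb_rate": float(result.table["outlier_rsb"].sum() / n_rsb),
        "intersection_rate": float(
            result.table["selected"].sum() / min(n_fst, n_rsb)
        ),
        "n_sites": matrix.n_sites,
    }
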