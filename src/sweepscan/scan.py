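"""End-to-end triangulated selection scan.

Combines the three pairwise F_ST comparisons (with the negation contrast on
the focal-vs-reference pair), the two Rsb contrasts of the focal population
against each source population, composite scores per metric, 99th-percentile
outlier calls, and their intersection — the per-SNP "selection allele" set.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .css import CssResult, call_outliers, css_scores, intersect_metrics
from .ehh import RsbResult, rsb_scan
from .fst import FstResult, fst_contrast_vector, weir_haploid_fst
from .matrix import GeneticMap, HaplotypeMatrix


@dataclass
class ScanResult:
    """Per-SNP statistics, composite scores and outlier calls for one scan."""

    table: pd.DataFrame
    fst_results: dict[str, FstResult]
    rsb_results: dict[str, RsbResult]
    css_fst: CssResult
    css_rsb: CssResult

    @property
    def selected_sites(self) -> np.ndarray:
        """Site indices flagged by both metrics (the intersection)."""
        return np.flatnonzero(self.table["selected"].to_numpy())


def run_scan(
    matrix: HaplotypeMatrix,
    gmap: GeneticMap | None = None,
    focal: str = "gAHB",
    admixed: str = "AHB",
    reference: str = "EHB",
    quantile: float = 0.99,
    decay_threshold: float = 0.05,
) -> ScanResult:
    """Full scan on an imputed matrix; returns per-SNP table plus components.

    The F_ST composite uses the triple (θ_focal,admixed, θ_reference,admixed,
    −θ_focal,reference); the Rsb composite uses the standardized contrasts of
    the focal population against each of the other two.
    """
    if matrix.has_missing():
        raise ValueError("scan requires an imputed matrix; run rescue_missing first")
    f_fa = weir_haploid_fst(matrix, focal, admixed)
    f_ra = weir_haploid_fst(matrix, reference, admixed)
    f_fr = weir_haploid_fst(matrix, focal, reference)
    triple = fst_contrast_vector(f_fa, f_ra, f_fr)
    css_fst = css_scores(triple, metric="FST")
    out_fst = call_outliers(css_fst, quantile)

    ies_cache: dict[str, np.ndarray] = {}
    r_fa = rsb_scan(matrix, focal, admixed, gmap, decay_threshold, _ies_cache=ies_cache)
    r_fr = rsb_scan(matrix, focal, reference, gmap, decay_threshold, _ies_cache=ies_cache)
    css_rsb = css_scores(
        np.column_stack([r_fa.standardized, r_fr.standardized]), metric="RSB"
    )
    out_rsb = call_outliers(css_rsb, quantile)
    selected, _ = intersect_metrics(out_fst, out_rsb)

    table = pd.DataFrame(
        {
            "scaffold": matrix.scaffolds,
            "pos": matrix.positions_bp,
            f"theta_{focal}_{admixed}": f_fa.theta,
            f"theta_{reference}_{admixed}": f_ra.theta,
            f"theta_{focal}_{reference}": f_fr.theta,
            "css_fst": css_fst.css,
            f"rsb_{focal}_{admixed}": r_fa.rsb,
            f"rsb_{focal}_{reference}": r_fr.rsb,
            "css_rsb": css_rsb.css,
            "outlier_fst": out_fst,
            "outlier_rsb": out_rsb,
            "selected": selected,
        }
    )
    return ScanResult(
        table=table,
        fst_results={
            f"{focal}_vs_{admixed}": f_fa,
            f"{reference}_vs_{admixed}": f_ra,
            f"{focal}_vs_{reference}": f_fr,
        },
        rsb_results={r_fa.contrast: r_fa, r_fr.contrast: r_fr},
        css_fst=css_fst,
        css_rsb=css_rsb,
    )
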