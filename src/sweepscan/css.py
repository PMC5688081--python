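"""Composite selection score: rank → z → mean-z → −log10 p.

Each constituent statistic is reduced to fractional ranks ``rank/(n+1)``
(ascending, ties averaged), mapped through the standard normal quantile
function to a z-score, and the z-scores are averaged per SNP.  Under the
null the mean of m independent standard normals is N(0, 1/m), so the
one-sided upper-tail p-value is ``1 − Φ(z̄·√m)`` and CSS = −log10 p.  Being
rank-based, the score is invariant under any strictly monotone transform of
each constituent.  Outliers are SNPs whose CSS strictly exceeds the
empirical 99th percentile (linear interpolation), and the selection calls
of two metrics are combined by set intersection.
"""
from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

log = logging.getLogger(__name__)


def fractional_ranks(values: np.ndarray) -> np.ndarray:
    """Ascending fractional ranks in (0, 1): ``rank/(n+1)``, ties averaged.

    NaN entries are excluded from ranking and returned as NaN.
    """
    values = np.asarray(values, dtype=float)
    finite = np.isfinite(values)
    n = int(finite.sum())
    if n == 0:
        raise ValueError("all values are NA; nothing to rank")
    out = np.full(values.shape, np.nan)
    out[finite] = stats.rankdata(values[finite], method="average") / (n + 1)
    return out


@dataclass
class CssResult:
    """Per-SNP composite scores for one metric."""

    metric: str
    ranks: np.ndarray        # (n_sites, m)
    z: np.ndarray            # (n_sites, m)
    z_mean: np.ndarray
    pvalue: np.ndarray
    css: np.ndarray          # −log10 p
    outlier: np.ndarray | None = None

    def to_dataframe(self) -> pd.DataFrame:
        df = pd.DataFrame({"z_mean": self.z_mean, "pvalue": self.pvalue, "css": self.css})
        if self.outlier is not None:
            df["outlier"] = self.outlier
        return df


def css_scores(
    constituents: np.ndarray | list[np.ndarray],
    metric: str = "",
    empirical_null: bool = False,
) -> CssResult:
    """Composite score from ``m`` per-SNP constituent vectors.

    ``constituents`` is an ``(n_sites, m)`` array or list of m vectors sharing
    one SNP list.  A SNP with NA in any constituent gets an NA score.  With
    ``empirical_null`` the p-value is taken from the empirical upper-tail
    fraction of the z̄ distribution itself instead of the N(0, 1/m) null.
    """
    arr = np.column_stack(constituents) if isinstance(constituents, list) else np.asarray(constituents, dtype=float)
    if arr.ndim == 1:
        arr = arr[:, None]
    n, m = arr.shape
    if m < 1:
        raise ValueError("need at least one constituent statistic")
    ranks = np.column_stack([fractional_ranks(arr[:, k]) for k in range(m)])
    z = stats.norm.ppf(ranks)
    z_mean = z.mean(axis=1)  # NaN propagates for SNPs with any NA constituent
    if empirical_null:
        p = np.full(n, np.nan)
        finite = np.isfinite(z_mean)
        p[finite] = 1.0 - fractional_ranks(np.where(finite, z_mean, np.nan))[finite]
    else:
        p = stats.norm.sf(z_mean * np.sqrt(m))
    css = -np.log10(p)
    n_na = int(np.isnan(css).sum())
    if n_na:
        log.info("css_scores[%s]: %d SNPs with NA constituents", metric, n_na)
    return CssResult(metric=metric, ranks=ranks, z=z, z_mean=z_mean, pvalue=p, css=css)


def call_outliers(result: CssResult, quantile: float = 0.99) -> np.ndarray:
    """Flag SNPs with CSS strictly above the empirical ``quantile``.

    The threshold uses linear interpolation over finite scores; the flag
    array is also stored on ``result.outlier``.
    """
    if not 0.0 < quantile < 1.0:
        raise ValueError("quantile must be in (0, 1)")
    finite = np.isfinite(result.css)
    n = int(finite.sum())
    if n < 1.0 / (1.0 - quantile):
        warnings.warn(
            f"only {n} scores for quantile {quantile}; threshold is unstable"
        )
    threshold = float(np.quantile(result.css[finite], quantile))
    flags = np.where(finite, result.css > threshold, False)
    result.outlier = flags
    return flags


def intersect_metrics(outliers_a, outliers_b, site_ids=None):
    """Intersection of two metrics' outlier calls over one site universe.

    Accepts either two same-length boolean masks (optionally with explicit
    ``site_ids``) or two sets of site identifiers.  Returns ``(flags, table)``
    in the mask case — flags for the intersection plus a per-flagged-site
    provenance table — or the plain set intersection in the set case.
    """
    if isinstance(outliers_a, (set, frozenset)) or isinstance(outliers_b, (set, frozenset)):
        return set(outliers_a) & set(outliers_b)
    a = np.asarray(outliers_a, dtype=bool)
    b = np.asarray(outliers_b, dtype=bool)
    if a.shape != b.shape:
        raise ValueError("outlier masks cover different site universes")
    both = a & b
    ids = np.arange(a.size) if site_ids is None else np.asarray(site_ids)
    table = pd.DataFrame(
        {
            "site": ids[a | b],
            "metric_a": a[a | b],
            "metric_b": b[a | b],
            "both": both[a | b],
        }
    )
    return both, table
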