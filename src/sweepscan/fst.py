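"""Haploid Weir variance-component F_ST with permutation p-values.

The estimator is the two-population haploid form of Weir's method-of-moments
θ: each haploid individual contributes a single allele, so there is no
heterozygosity term.  With ``r = 2`` populations, ``n_i`` non-missing calls
and alt frequency ``p_i`` in population i, ``n_T = n_1 + n_2`` and
``p̄ = Σ n_i p_i / n_T``:

    MSP = Σ n_i (p_i − p̄)² / (r − 1)
    MSG = Σ n_i p_i (1 − p_i) / (n_T − r)
    n_c = (n_T − Σ n_i² / n_T) / (r − 1)
    θ   = (MSP − MSG) / (MSP + (n_c − 1) MSG)

θ is undefined where either population has fewer than two non-missing calls,
or the site is monomorphic in both (MSP = MSG = 0).  Negative θ is retained.
Significance comes from permuting population membership of the pooled
samples and counting permutation θ that equal or exceed the observed value.
"""
from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .matrix import MISSING, HaplotypeMatrix


@dataclass
class FstResult:
    """Per-SNP variance components and θ for one population pair."""

    pair: tuple[str, str]
    scaffolds: np.ndarray
    positions_bp: np.ndarray
    theta: np.ndarray
    msp: np.ndarray
    msg: np.ndarray
    n_c: np.ndarray
    n1: np.ndarray
    n2: np.ndarray
    p1: np.ndarray
    p2: np.ndarray
    p_bar: np.ndarray
    pvalues: np.ndarray | None = None

    def to_dataframe(self) -> pd.DataFrame:
        df = pd.DataFrame(
            {
                "scaffold": self.scaffolds,
                "pos": self.positions_bp,
                "n1": self.n1,
                "n2": self.n2,
                "p1": self.p1,
                "p2": self.p2,
                "theta": self.theta,
            }
        )
        if self.pvalues is not None:
            df["pvalue"] = self.pvalues
        return df


def _theta_components(n1, c1, n2, c2):
    """Vectorised straight application of the four formulas above.

    Inputs are per-site non-missing counts ``n`` and alt-allele counts ``c``.
    Returns (theta, msp, msg, n_c, p1, p2, p_bar) with NaN where undefined.
    """
    n1 = np.asarray(n1, dtype=float)
    n2 = np.asarray(n2, dtype=float)
    c1 = np.asarray(c1, dtype=float)
    c2 = np.asarray(c2, dtype=float)
    valid = (n1 >= 2) & (n2 >= 2)
    with np.errstate(invalid="ignore", divide="ignore"):
        p1 = np.where(n1 > 0, c1 / n1, np.nan)
        p2 = np.where(n2 > 0, c2 / n2, np.nan)
        n_t = n1 + n2
        p_bar = (c1 + c2) / n_t
        msp = n1 * (p1 - p_bar) ** 2 + n2 * (p2 - p_bar) ** 2
        msg = (n1 * p1 * (1 - p1) + n2 * p2 * (1 - p2)) / (n_t - 2)
        n_c = n_t - (n1**2 + n2**2) / n_t
        denom = msp + (n_c - 1) * msg
        theta = (msp - msg) / denom
    undefined = ~valid | ((msp == 0) & (msg == 0)) | (denom == 0)
    theta = np.where(undefined, np.nan, theta)
    return theta, msp, msg, n_c, p1, p2, p_bar


def _pool_counts(matrix: HaplotypeMatrix, pop_a: str, pop_b: str):
    known = set(matrix.population_names())
    for p in (pop_a, pop_b):
        if p not in known:
            raise ValueError(f"unknown population label {p!r}; have {sorted(known)}")
    ia = matrix.samples_for(pop_a)
    ib = matrix.samples_for(pop_b)
    return ia, ib


def weir_haploid_fst(matrix: HaplotypeMatrix, pop_a: str, pop_b: str) -> FstResult:
    """Per-SNP haploid Weir θ between two labelled populations."""
    ia, ib = _pool_counts(matrix, pop_a, pop_b)
    ca = matrix.calls[ia]
    cb = matrix.calls[ib]
    n1 = (ca != MISSING).sum(axis=0)
    n2 = (cb != MISSING).sum(axis=0)
    c1 = (ca == 1).sum(axis=0)
    c2 = (cb == 1).sum(axis=0)
    theta, msp, msg, n_c, p1, p2, p_bar = _theta_components(n1, c1, n2, c2)
    return FstResult(
        pair=(pop_a, pop_b),
        scaffolds=matrix.scaffolds.copy(),
        positions_bp=matrix.positions_bp.copy(),
        theta=theta, msp=msp, msg=msg, n_c=n_c,
        n1=n1.astype(int), n2=n2.astype(int),
        p1=p1, p2=p2, p_bar=p_bar,
    )


def multilocus_theta(result: FstResult) -> float:
    """Ratio-of-sums multi-locus Weir estimate over defined sites."""
    ok = np.isfinite(result.theta)
    num = np.sum(result.msp[ok] - result.msg[ok])
    den = np.sum(result.msp[ok] + (result.n_c[ok] - 1) * result.msg[ok])
    return float(num / den)


def permutation_pvalues(
    matrix: HaplotypeMatrix,
    pop_a: str,
    pop_b: str,
    n_perm: int = 10_000,
    seed: int = 0,
    shared_shuffles: bool = True,
    add_one: bool = False,
    tie_break: str = "ge",
    exhaustive: bool = False,
) -> FstResult:
    """Permutation p-values for haploid Weir θ.

    ``p = #{θ_perm ≥ θ_obs} / n_perm`` by default (``add_one`` appends the
    observed arrangement to both counts).  ``shared_shuffles`` applies one
    label shuffle per iteration to every SNP, preserving cross-SNP
    correlation under the null; per-SNP independent shuffles are used when
    it is False.  ``tie_break="randomized"`` returns the randomized p-value
    ``(#{>} + U·(#{=}+1)) / (n_perm+1)``, exactly U(0,1) under the null, for
    calibration checks.  ``exhaustive=True`` enumerates every assignment of
    the pooled samples into groups of the observed sizes (small pools only).
    """
    if tie_break not in ("ge", "randomized"):
        raise ValueError("tie_break must be 'ge' or 'randomized'")
    ia, ib = _pool_counts(matrix, pop_a, pop_b)
    observed = weir_haploid_fst(matrix, pop_a, pop_b)
    pooled = np.concatenate([ia, ib])
    calls = matrix.calls[pooled]
    n_a = ia.size
    n_pool = pooled.size
    is_alt = (calls == 1).astype(np.float64)
    non_miss = (calls != MISSING).astype(np.float64)
    theta_obs = observed.theta
    rng = np.random.default_rng(seed)

    def thetas_for(mask: np.ndarray) -> np.ndarray:
        # mask: boolean (n_pool,) or (n_pool, n_sites) selecting group A
        if mask.ndim == 1:
            sel = mask.astype(np.float64)
            n1 = sel @ non_miss
            c1 = sel @ is_alt
        else:
            n1 = (mask * non_miss).sum(axis=0)
            c1 = (mask * is_alt).sum(axis=0)
        n2 = non_miss.sum(axis=0) - n1
        c2 = is_alt.sum(axis=0) - c1
        return _theta_components(n1, c1, n2, c2)[0]

    if exhaustive:
        if n_pool > 20:
            raise ValueError("exhaustive enumeration limited to pools of <= 20 samples")
        ge = np.zeros(matrix.n_sites)
        total = 0
        for combo in itertools.combinations(range(n_pool), n_a):
            mask = np.zeros(n_pool, dtype=bool)
            mask[list(combo)] = True
            t = thetas_for(mask)
            ge += (t >= theta_obs) & np.isfinite(t)
            total += 1
        pvals = np.where(np.isfinite(theta_obs), ge / total, np.nan)
        observed.pvalues = pvals
        return observed

    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    ge = np.zeros(matrix.n_sites)
    gt = np.zeros(matrix.n_sites)
    eq = np.zeros(matrix.n_sites)
    tol = 0.0  # identical counts reproduce θ bitwise, so exact comparison is safe
    for _ in range(n_perm):
        if shared_shuffles:
            perm = rng.permutation(n_pool)
            mask = np.zeros(n_pool, dtype=bool)
            mask[perm[:n_a]] = True
        else:
            order = np.argsort(rng.random((n_pool, matrix.n_sites)), axis=0)
            mask = order < n_a  # independent shuffle per SNP column
        t = thetas_for(mask)
        finite = np.isfinite(t)
        ge += (t >= theta_obs - tol) & finite
        gt += (t > theta_obs + tol) & finite
        eq += (np.abs(t - theta_obs) <= tol) & finite
    if tie_break == "randomized":
        u = rng.random(matrix.n_sites)
        pvals = (gt + u * (eq + 1)) / (n_perm + 1)
    elif add_one:
        pvals = (ge + 1) / (n_perm + 1)
    else:
        pvals = ge / n_perm
    pvals = np.where(np.isfinite(theta_obs), pvals, np.nan)
    observed.pvalues = pvals
    return observed


def fst_contrast_vector(
    f_focal_vs_admixed: FstResult,
    f_reference_vs_admixed: FstResult,
    f_focal_vs_reference: FstResult,
) -> np.ndarray:
    """Three-way contrast for the composite score, shape ``(n_sites, 3)``.

    Columns are (θ_focal,admixed, θ_reference,admixed, −θ_focal,reference):
    a SNP scores high on all three when the focal population diverged from
    the admixed source while converging on the reference population.
    """
    a, b, c = f_focal_vs_admixed, f_reference_vs_admixed, f_focal_vs_reference
    for other in (b, c):
        if not (
            np.array_equal(a.scaffolds, other.scaffolds)
            and np.array_equal(a.positions_bp, other.positions_bp)
        ):
            raise ValueError("F_ST results computed on different site lists")
    return np.column_stack([a.theta, b.theta, -c.theta])
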