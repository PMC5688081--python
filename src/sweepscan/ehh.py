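"""Site extended haplotype homozygosity, its integral, and the Rsb contrast.

``EHH_S`` at a marker x flanking a core SNP is the probability that two
chromosomes drawn without replacement from one population are identical over
the interval [core..x]:

    EHH_S = Σ_h C(n_h, 2) / C(n, 2)

over distinct haplotype strings h with multiplicity n_h among n samples.  By
convention the profile starts at 1 at the core (a zero-width interval) and
is extended outwards until it decays below a threshold (that marker is kept)
or the scaffold ends.  ``iES`` integrates the profile against genetic
position (Morgans when a map is available, bp otherwise) by the trapezoid
rule, both sides summed.  ``Rsb`` compares haplotype decay between two
populations: the log-ratio of iES is median-centred, scaled, and
exponentiated so values above 1 flag slower decay — candidate selection —
in the numerator population.
"""
from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .matrix import MISSING, GeneticMap, HaplotypeMatrix

log = logging.getLogger(__name__)


@dataclass
class EhhProfile:
    """One core SNP's decay profile within one population.

    Marker arrays run outwards from the core on each side; the core itself is
    held separately with EHH_S fixed at 1.
    """

    core_index: int
    core_bp: int
    core_morgans: float | None
    left_index: np.ndarray
    left_bp: np.ndarray
    left_morgans: np.ndarray | None
    left_ehh: np.ndarray
    right_index: np.ndarray
    right_bp: np.ndarray
    right_morgans: np.ndarray | None
    right_ehh: np.ndarray
    truncation_left: str = "scaffold_end"   # "threshold" | "scaffold_end"
    truncation_right: str = "scaffold_end"


def _pair_homozygosity(group_ids: np.ndarray) -> float:
    counts = np.bincount(group_ids)
    n = group_ids.size
    return float((counts * (counts - 1)).sum() / (n * (n - 1)))


def _side(calls: np.ndarray, core: int, step: int, stop: int, threshold: float):
    """Extend haplotype grouping outwards; returns (indices, ehh, reason).

    Group ids are kept compact so each extension is O(n) via bincount.
    """
    n = calls.shape[0]
    groups = calls[:, core].astype(np.intp)
    idx: list[int] = []
    ehh: list[float] = []
    reason = "scaffold_end"
    denom = n * (n - 1)
    j = core + step
    while (j - stop) * step <= 0:
        merged = groups * 2 + calls[:, j]
        counts = np.bincount(merged, minlength=2 * n)
        value = float((counts * (counts - 1)).sum() / denom)
        relabel = np.cumsum(counts > 0) - 1
        groups = relabel[merged]
        idx.append(j)
        ehh.append(value)
        if value < threshold:
            reason = "threshold"
            break
        j += step
    return np.array(idx, dtype=int), np.array(ehh, dtype=float), reason


def ehh_s_profile(
    matrix_one_pop: HaplotypeMatrix,
    core_index: int,
    decay_threshold: float = 0.05,
    _scaffold_bounds: tuple[int, int] | None = None,
) -> EhhProfile:
    """Site-EHH profile around ``core_index`` for a single-population matrix.

    Haplotype strings always include the core column; extension stops at the
    first marker where EHH_S drops below ``decay_threshold`` (that marker is
    included) or at the scaffold end.
    """
    m = matrix_one_pop
    if m.n_samples < 2:
        raise ValueError("EHH requires at least 2 haplotypes")
    if not 0 <= core_index < m.n_sites:
        raise IndexError(f"core index {core_index} out of range")
    if _scaffold_bounds is None:
        if m.has_missing():
            raise ValueError("matrix contains missing calls; run rescue_missing first")
        scaf = m.scaffolds[core_index]
        on_scaf = np.flatnonzero(m.scaffolds == scaf)
        first, last = int(on_scaf[0]), int(on_scaf[-1])
    else:
        first, last = _scaffold_bounds
    calls = m.calls
    li, le, lreason = _side(calls, core_index, -1, first, decay_threshold)
    ri, re_, rreason = _side(calls, core_index, +1, last, decay_threshold)
    gp = m.genetic_pos
    return EhhProfile(
        core_index=core_index,
        core_bp=int(m.positions_bp[core_index]),
        core_morgans=None if gp is None else float(gp[core_index]),
        left_index=li,
        left_bp=m.positions_bp[li],
        left_morgans=None if gp is None else gp[li],
        left_ehh=le,
        right_index=ri,
        right_bp=m.positions_bp[ri],
        right_morgans=None if gp is None else gp[ri],
        right_ehh=re_,
        truncation_left=lreason,
        truncation_right=rreason,
    )


def integrate_ies(profile: EhhProfile, gmap: GeneticMap | None = None,
                  scaffold: str | None = None) -> float:
    """Trapezoid integral of the EHH_S profile over genetic distance.

    Positions come from the profile's Morgan coordinates, from ``gmap`` when
    given, or fall back to bp.  The core contributes height 1 at width 0;
    each side integrates outwards and the two sides are summed.
    """

    def coords(bp: np.ndarray, morgans) -> np.ndarray:
        if gmap is not None:
            if scaffold is None:
                raise ValueError("scaffold required when integrating against a map")
            return np.asarray(gmap.morgans(scaffold, bp), dtype=float)
        if morgans is not None:
            return np.asarray(morgans, dtype=float)
        return bp.astype(float)

    core_x = coords(np.array([profile.core_bp]), None if profile.core_morgans is None
                    else np.array([profile.core_morgans]))[0]
    total = 0.0
    for bp, morg, ehh in (
        (profile.left_bp, profile.left_morgans, profile.left_ehh),
        (profile.right_bp, profile.right_morgans, profile.right_ehh),
    ):
        if len(bp) == 0:
            continue
        x = coords(bp, morg)
        xs = np.concatenate([[core_x], x])
        ys = np.concatenate([[1.0], ehh])
        order = np.argsort(xs)
        total += float(np.trapezoid(ys[order], xs[order]))
    return total


@dataclass
class RsbResult:
    """Per-SNP standardized cross-population haplotype-decay contrast."""

    contrast: str                     # e.g. "gAHB_vs_AHB"
    scaffolds: np.ndarray
    positions_bp: np.ndarray
    ies_num: np.ndarray
    ies_den: np.ndarray
    ln_ratio: np.ndarray
    standardized: np.ndarray          # median-centred, scale-divided ln ratio
    rsb: np.ndarray                   # exp(standardized)
    units: str = "morgans"
    scale: str = "sd"

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "scaffold": self.scaffolds,
                "pos": self.positions_bp,
                "iES_num": self.ies_num,
                "iES_den": self.ies_den,
                "ln_ratio": self.ln_ratio,
                "std": self.standardized,
                "rsb": self.rsb,
            }
        )


def ies_scan(
    matrix_one_pop: HaplotypeMatrix,
    decay_threshold: float = 0.05,
) -> np.ndarray:
    """iES at every site for one population (Morgans if available, else bp)."""
    m = matrix_one_pop
    if m.has_missing():
        raise ValueError("matrix contains missing calls; run rescue_missing first")
    bounds: dict[str, tuple[int, int]] = {}
    for scaf in dict.fromkeys(m.scaffolds):
        on_scaf = np.flatnonzero(m.scaffolds == scaf)
        bounds[scaf] = (int(on_scaf[0]), int(on_scaf[-1]))
    out = np.empty(m.n_sites)
    for j in range(m.n_sites):
        profile = ehh_s_profile(
            m, j, decay_threshold, _scaffold_bounds=bounds[m.scaffolds[j]]
        )
        out[j] = integrate_ies(profile)
    return out


def standardize_ln_ratio(ln_ratio: np.ndarray, scale: str = "sd") -> np.ndarray:
    """Median-centre and scale-divide; degenerate spread → all zeros."""
    finite = np.isfinite(ln_ratio)
    centred = ln_ratio - np.median(ln_ratio[finite])
    if scale == "sd":
        spread = float(np.std(centred[finite]))
    elif scale == "mad":
        spread = float(np.median(np.abs(centred[finite]))) * 1.4826
    else:
        raise ValueError("scale must be 'sd' or 'mad'")
    if spread == 0.0:
        warnings.warn("degenerate ln(Rsb) spread; standardized values set to 0")
        return np.where(finite, 0.0, np.nan)
    return centred / spread


def rsb_scan(
    matrix: HaplotypeMatrix,
    pop_numerator: str,
    pop_denominator: str,
    gmap: GeneticMap | None = None,
    decay_threshold: float = 0.05,
    scale: str = "sd",
    _ies_cache: dict[str, np.ndarray] | None = None,
) -> RsbResult:
    """Standardized Rsb between two populations at every site.

    The numerator population is the focal one, so Rsb > 1 flags candidate
    selection there.  Sites where either iES is zero (no flanking markers)
    are set undefined and logged.  ``_ies_cache`` (population → iES vector)
    lets callers computing several contrasts reuse per-population scans.
    """

    def ies_for(pop: str) -> np.ndarray:
        if _ies_cache is not None and pop in _ies_cache:
            return _ies_cache[pop]
        sub = matrix.restrict_to_population(pop)
        if gmap is not None:
            sub = sub.attach_map(gmap)
        ies = ies_scan(sub, decay_threshold)
        if _ies_cache is not None:
            _ies_cache[pop] = ies
        return ies

    ies_num = ies_for(pop_numerator)
    ies_den = ies_for(pop_denominator)
    bad = (ies_num <= 0) | (ies_den <= 0)
    if bad.any():
        log.info("rsb_scan: %d sites undefined (zero iES)", int(bad.sum()))
    with np.errstate(divide="ignore", invalid="ignore"):
        # difference of logs, so swapping populations negates the ratio exactly
        ln_ratio = np.where(bad, np.nan, np.log(ies_num) - np.log(ies_den))
    standardized = standardize_ln_ratio(ln_ratio, scale=scale)
    units = "morgans" if (gmap is not None or matrix.genetic_pos is not None) else "bp"
    return RsbResult(
        contrast=f"{pop_numerator}_vs_{pop_denominator}",
        scaffolds=matrix.scaffolds.copy(),
        positions_bp=matrix.positions_bp.copy(),
        ies_num=ies_num,
        ies_den=ies_den,
        ln_ratio=ln_ratio,
        standardized=standardized,
        rsb=np.exp(standardized),
        units=units,
        scale=scale,
    )
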