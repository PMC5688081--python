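"""Diversity at the complementary sex determiner (csd) locus.

In honeybees, individuals homozygous at csd develop into sterile diploid
males, so csd allele diversity is under balancing selection and the chance
of producing diploid males is a diversity proxy.  An allele here is the
ordered tuple of calls at a designated set of non-synonymous coding SNPs.
For a focal population with allele counts ``h_i`` over its ``k`` alleles,
and ``K`` alleles present across all populations pooled, the diploid-male
likelihood is

    P(d) = Σ_{i=1..k} C(h_i, 2) / Σ_{i=1..K} C(h_i, 2)

with the denominator counts pooled across populations by default — the
reading that makes P(d) comparable across populations.  The literal
within-population denominator is kept behind a flag; it collapses to 1 for
any focal population (every focal pair is counted in both sums), which is
exactly why the pooled reading is the default.
"""
from __future__ import annotations

from dataclasses import dataclass
from math import comb
from typing import Sequence

import numpy as np
import pandas as pd

from .matrix import MISSING, HaplotypeMatrix


@dataclass
class CsdAlleleTable:
    """Per-population counts of csd alleles (call tuples at designated sites)."""

    alleles: list[tuple[int, ...]]
    counts: pd.DataFrame          # index: allele label, columns: populations
    site_indices: list[int]

    @property
    def populations(self) -> list[str]:
        return list(self.counts.columns)

    def k(self, population: str) -> int:
        """Number of alleles present in ``population``."""
        return int((self.counts[population] > 0).sum())

    @property
    def K(self) -> int:
        """Number of alleles present across all populations pooled."""
        return int((self.counts.sum(axis=1) > 0).sum())


def extract_csd_alleles(
    matrix: HaplotypeMatrix, nonsyn_sites: Sequence[int]
) -> CsdAlleleTable:
    """Tally allele (call-tuple) counts per population at the given sites."""
    sites = [int(j) for j in nonsyn_sites]
    if not sites:
        raise ValueError("empty non-synonymous site list")
    sub = matrix.calls[:, sites]
    if np.any(sub == MISSING):
        raise ValueError("missing calls at designated csd sites; run rescue_missing")
    tuples = [tuple(int(c) for c in row) for row in sub]
    labels = matrix.population_labels
    pops = matrix.population_names()
    alleles = sorted(set(tuples))
    data = {
        pop: [
            sum(1 for t, lab in zip(tuples, labels) if t == a and lab == pop)
            for a in alleles
        ]
        for pop in pops
    }
    counts = pd.DataFrame(data, index=[f"allele_{i+1}" for i in range(len(alleles))])
    return CsdAlleleTable(alleles=alleles, counts=counts, site_indices=sites)


def diploid_male_likelihood(
    table: CsdAlleleTable,
    focal_population: str,
    denominator: str = "pooled",
) -> float:
    """P(d): chance a within-population mating yields a csd homozygote.

    Numerator sums C(h_i, 2) over the focal population's own allele counts;
    the denominator sums C(h_i, 2) over all K alleles with counts pooled
    across populations (``denominator="pooled"``, default) or with the focal
    population's counts (``denominator="within"``, the literal reading).
    Undefined (NaN) when the denominator is zero.
    """
    if focal_population not in table.counts.columns:
        raise ValueError(f"population {focal_population!r} absent from table")
    if denominator not in ("pooled", "within"):
        raise ValueError("denominator must be 'pooled' or 'within'")
    focal = table.counts[focal_population]
    num = sum(comb(int(h), 2) for h in focal if h > 0)
    if denominator == "pooled":
        pooled = table.counts.sum(axis=1)
        den = sum(comb(int(h), 2) for h in pooled if h > 0)
    else:
        den = num
    if den == 0:
        return float("nan")
    return num / den


@dataclass
class CsdComparison:
    pd_values: dict[str, float]
    ratios: pd.DataFrame               # pairwise P(d) ratios, row/column
    spectra: pd.DataFrame              # allele frequencies per population

    def ratio(self, a: str, b: str) -> float:
        return float(self.ratios.loc[a, b])


def compare_populations(
    table: CsdAlleleTable, denominator: str = "pooled"
) -> CsdComparison:
    """P(d) per population, pairwise ratios, and allele-frequency spectra."""
    pops = table.populations
    if len(pops) < 2:
        raise ValueError("need at least two populations to compare")
    pd_values = {
        p: diploid_male_likelihood(table, p, denominator=denominator) for p in pops
    }
    ratios = pd.DataFrame(
        [[pd_values[a] / pd_values[b] if pd_values[b] else float("nan") for b in pops] for a in pops],
        index=pops, columns=pops,
    )
    totals = table.counts.sum(axis=0)
    spectra = table.counts / totals.replace(0, np.nan)
    return CsdComparison(pd_values=pd_values, ratios=ratios, spectra=spectra)
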