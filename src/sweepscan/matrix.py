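"""Core in-memory containers for haploid SNP data.

A :class:`HaplotypeMatrix` holds one allele per sample per site (the natural
representation for honeybee drones and other haploid genomes): ``0`` is the
reference allele, positive integers index alternate alleles, and ``MISSING``
(−1) marks a failed call.  Sites carry scaffold, physical position, allele
strings and optionally genetic-map (Morgan) coordinates.
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np

#: sentinel value for a missing haploid call
MISSING: int = -1


@dataclass
class HaplotypeMatrix:
    """Samples × biallelic-SNP matrix of haploid calls with site metadata.

    Parameters
    ----------
    sample_ids:
        Ordered sample identifiers (rows of ``calls``).
    populations:
        Mapping from sample id to population label (e.g. ``gAHB``/``AHB``/``EHB``).
    scaffolds:
        Per-site scaffold/chromosome identifier.
    positions_bp:
        Per-site 1-based physical position, strictly increasing within scaffold.
    ref_allele, alt_allele:
        Per-site allele strings.  Multi-allelic records read from a VCF keep a
        comma-joined ALT until :func:`sweepscan.filters.filter_biallelic` runs.
    calls:
        ``(n_samples, n_sites)`` integer array; 0 = ref, k ≥ 1 = k-th alt,
        :data:`MISSING` = no call.
    genetic_pos:
        Optional per-site genetic position in Morgans.
    """

    sample_ids: list[str]
    populations: dict[str, str]
    scaffolds: np.ndarray
    positions_bp: np.ndarray
    ref_allele: np.ndarray
    alt_allele: np.ndarray
    calls: np.ndarray
    genetic_pos: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.scaffolds = np.asarray(self.scaffolds, dtype=object)
        self.positions_bp = np.asarray(self.positions_bp, dtype=np.int64)
        self.ref_allele = np.asarray(self.ref_allele, dtype=object)
        self.alt_allele = np.asarray(self.alt_allele, dtype=object)
        self.calls = np.asarray(self.calls, dtype=np.int8)
        if self.genetic_pos is not None:
            self.genetic_pos = np.asarray(self.genetic_pos, dtype=float)

    # -- basic geometry -------------------------------------------------
    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_sites(self) -> int:
        return self.calls.shape[1]

    @property
    def population_labels(self) -> np.ndarray:
        """Population label per sample, aligned with ``sample_ids``."""
        return np.array([self.populations[s] for s in self.sample_ids], dtype=object)

    def population_names(self) -> list[str]:
        seen: dict[str, None] = {}
        for s in self.sample_ids:
            seen.setdefault(self.populations[s], None)
        return list(seen)

    def samples_for(self, population: str) -> np.ndarray:
        """Row indices of samples belonging to ``population``."""
        labels = self.population_labels
        idx = np.flatnonzero(labels == population)
        return idx

    # -- validation ------------------------------------------------------
    def validate(self) -> None:
        if self.calls.shape != (len(self.sample_ids), len(self.positions_bp)):
            raise ValueError(
                f"calls shape {self.calls.shape} does not match "
                f"{len(self.sample_ids)} samples × {len(self.positions_bp)} sites"
            )
        for arr, name in (
            (self.scaffolds, "scaffolds"),
            (self.ref_allele, "ref_allele"),
            (self.alt_allele, "alt_allele"),
        ):
            if len(arr) != self.n_sites:
                raise ValueError(f"{name} has length {len(arr)}, expected {self.n_sites}")
        if self.genetic_pos is not None and len(self.genetic_pos) != self.n_sites:
            raise ValueError("genetic_pos length mismatch")
        missing_pops = [s for s in self.sample_ids if s not in self.populations]
        if missing_pops:
            raise ValueError(f"samples without population label: {missing_pops[:5]}")
        if np.any(self.calls < MISSING):
            raise ValueError("calls contain values below the MISSING sentinel")
        # positions strictly increasing within each scaffold
        for scaf in dict.fromkeys(self.scaffolds):
            pos = self.positions_bp[self.scaffolds == scaf]
            if np.any(np.diff(pos) <= 0):
                raise ValueError(f"positions not strictly increasing on {scaf}")
            if self.genetic_pos is not None:
                gp = self.genetic_pos[self.scaffolds == scaf]
                if np.any(np.diff(gp) < 0):
                    raise ValueError(f"genetic positions decrease on {scaf}")

    # -- subsetting ------------------------------------------------------
    def subset_sites(self, index: np.ndarray) -> "HaplotypeMatrix":
        """New matrix restricted to the given site indices / boolean mask."""
        index = np.asarray(index)
        return replace(
            self,
            scaffolds=self.scaffolds[index],
            positions_bp=self.positions_bp[index],
            ref_allele=self.ref_allele[index],
            alt_allele=self.alt_allele[index],
            calls=self.calls[:, index],
            genetic_pos=None if self.genetic_pos is None else self.genetic_pos[index],
        )

    def subset_samples(self, index: np.ndarray) -> "HaplotypeMatrix":
        index = np.asarray(index)
        ids = [self.sample_ids[i] for i in np.arange(self.n_samples)[index]] \
            if index.dtype == bool else [self.sample_ids[i] for i in index]
        return replace(
            self,
            sample_ids=ids,
            populations={s: self.populations[s] for s in ids},
            calls=self.calls[index],
        )

    def restrict_to_population(self, population: str) -> "HaplotypeMatrix":
        idx = self.samples_for(population)
        if idx.size == 0:
            raise ValueError(f"no samples labelled {population!r}")
        return self.subset_samples(idx)

    def copy(self) -> "HaplotypeMatrix":
        return replace(
            self,
            sample_ids=list(self.sample_ids),
            populations=dict(self.populations),
            scaffolds=self.scaffolds.copy(),
            positions_bp=self.positions_bp.copy(),
            ref_allele=self.ref_allele.copy(),
            alt_allele=self.alt_allele.copy(),
            calls=self.calls.copy(),
            genetic_pos=None if self.genetic_pos is None else self.genetic_pos.copy(),
        )

    def equals(self, other: "HaplotypeMatrix") -> bool:
        """Exact equality of samples, sites and every call."""
        return (
            self.sample_ids == other.sample_ids
            and {s: self.populations[s] for s in self.sample_ids}
            == {s: other.populations.get(s) for s in other.sample_ids}
            and np.array_equal(self.scaffolds, other.scaffolds)
            and np.array_equal(self.positions_bp, other.positions_bp)
            and np.array_equal(self.ref_allele, other.ref_allele)
            and np.array_equal(self.alt_allele, other.alt_allele)
            and np.array_equal(self.calls, other.calls)
        )

    def has_missing(self) -> bool:
        return bool(np.any(self.calls == MISSING))

    def attach_map(self, gmap: "GeneticMap") -> "HaplotypeMatrix":
        """Return a copy with ``genetic_pos`` interpolated from ``gmap``."""
        gp = np.empty(self.n_sites, dtype=float)
        for scaf in dict.fromkeys(self.scaffolds):
            mask = self.scaffolds == scaf
            gp[mask] = gmap.morgans(scaf, self.positions_bp[mask])
        return replace(self, genetic_pos=gp)


@dataclass
class GeneticMap:
    """Piecewise-linear genetic map: bp → Morgans per scaffold.

    ``breakpoints`` maps scaffold → ``(bp, morgans)`` arrays with bp strictly
    increasing and morgans non-decreasing.
    """

    breakpoints: dict[str, tuple[np.ndarray, np.ndarray]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        clean: dict[str, tuple[np.ndarray, np.ndarray]] = {}
        for scaf, (bp, m) in self.breakpoints.items():
            bp = np.asarray(bp, dtype=np.int64)
            m = np.asarray(m, dtype=float)
            if np.any(np.diff(bp) <= 0):
                raise ValueError(f"map bp not strictly increasing on {scaf}")
            if np.any(np.diff(m) < 0):
                raise ValueError(f"map Morgans decrease on {scaf}")
            clean[scaf] = (bp, m)
        self.breakpoints = clean

    @classmethod
    def uniform(cls, scaffold: str, length_bp: int, rate_morgans_per_bp: float) -> "GeneticMap":
        """Uniform-rate map over ``[1, length_bp]``."""
        bp = np.array([1, length_bp], dtype=np.int64)
        m = (bp - 1) * rate_morgans_per_bp
        return cls({scaffold: (bp, m.astype(float))})

    def morgans(self, scaffold: str, bp: np.ndarray | int) -> np.ndarray | float:
        """Interpolated genetic position; raises if outside the mapped range."""
        if scaffold not in self.breakpoints:
            raise KeyError(f"scaffold {scaffold!r} absent from genetic map")
        xp, fp = self.breakpoints[scaffold]
        bp_arr = np.atleast_1d(np.asarray(bp))
        if bp_arr.min() < xp[0] or bp_arr.max() > xp[-1]:
            raise ValueError(
                f"position outside mapped range [{xp[0]}, {xp[-1]}] on {scaffold}"
            )
        out = np.interp(bp_arr, xp, fp)
        return out if np.ndim(bp) else float(out[0])

    def total_length(self, scaffold: str) -> float:
        xp, fp = self.breakpoints[scaffold]
        return float(fp[-1] - fp[0])
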