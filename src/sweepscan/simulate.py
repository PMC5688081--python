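"""Forward Wright–Fisher simulator for a three-population invasion scenario.

The demography mirrors the Africanized-honeybee story: an ancestral deme
splits into an African-like (A) and a European-like (E) lineage; an admixed
population (AHB) forms from the two; and a bottlenecked island population
(gAHB) is founded from AHB and then experiences multiplicative viability
selection on standing variation at a handful of loci.  Individuals are
haploid; reproduction draws two parents per offspring with a Poisson number
of crossovers given by the genetic-map length, so the output carries
realistic linkage structure for EHH-style statistics.

Everything is deterministic given the configuration seed, and planted truth
(selected sites, favoured alleles, realized trajectories) is emitted for
recovery benchmarking.
"""
from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from .matrix import MISSING, GeneticMap, HaplotypeMatrix

POPULATION_ORDER = ("gAHB", "AHB", "EHB")


@dataclass
class SimulationConfig:
    """Parameters of the three-population scenario.

    Times are forward generation indices: the ancestral deme evolves until
    ``t_split``, A- and E-like demes until ``t_admix`` (when the admixed AHB
    deme replaces pure A), AHB and E until ``t_invasion`` (when gAHB is founded
    from ``founder_size`` AHB haplotypes), and all three demes then run for
    ``generations_post_invasion`` generations, with selection confined to gAHB.
    ``sel_coeff`` is the per-copy multiplicative fitness advantage (1 + s) of
    the favoured allele.  Rates are per bp (recombination, Morgans/bp) or per
    site per generation (mutation).
    """

    n_sites: int = 2000
    chrom_length_bp: int = 1_000_000
    recomb_rate: float = 2.2e-7      # Morgans/bp, honeybee-like
    mut_rate: float = 1e-8
    pop_size_ancestral: int = 2000
    pop_size_A: int = 2000
    pop_size_E: int = 500
    t_split: int = 150
    t_admix: int = 165
    t_invasion: int = 205
    admix_prop_E: float = 0.3
    founder_size: int = 300
    n_selected_loci: int = 5
    sel_coeff: float = 0.1
    generations_post_invasion: int = 12
    sample_sizes: tuple[int, int, int] = (30, 30, 30)  # gAHB, AHB, EHB
    missing_rate: float = 0.0
    seed: int = 0
    standing_freq_range: tuple[float, float] = (0.05, 0.5)
    ancestral_freq: float | None = None   # None → per-site Uniform(0.05, 0.95)
    ancestral_haplotypes: int | None = None  # None → linkage-equilibrium init
    scaffold: str = "scaffold_1"
    csd_sites: tuple[int, ...] = ()       # site indices under balancing selection
    csd_balancing: float = 0.0            # strength of negative frequency dependence

    def validate(self) -> None:
        if min(self.recomb_rate, self.mut_rate, self.sel_coeff, self.csd_balancing) < 0:
            raise ValueError("rates and selection coefficients must be >= 0")
        if not 0.0 <= self.admix_prop_E <= 1.0:
            raise ValueError("admix_prop_E must be in [0, 1]")
        if not 0.0 <= self.missing_rate < 1.0:
            raise ValueError("missing_rate must be in [0, 1)")
        if self.founder_size > self.pop_size_A:
            raise ValueError("founder_size must not exceed pop_size_A")
        if not self.t_split <= self.t_admix <= self.t_invasion:
            raise ValueError("require t_split <= t_admix <= t_invasion")
        if self.n_sites < 1 or self.chrom_length_bp < self.n_sites:
            raise ValueError("need n_sites >= 1 and chrom_length_bp >= n_sites")
        lo, hi = self.standing_freq_range
        if not 0.0 <= lo <= hi <= 1.0:
            raise ValueError("standing_freq_range must be ordered within [0, 1]")

    @property
    def map_length_morgans(self) -> float:
        return self.recomb_rate * (self.chrom_length_bp - 1)


@dataclass
class SimulationTruth:
    """Planted ground truth for recovery benchmarks."""

    selected_site_indices: list[int]
    favoured_allele: list[int]            # 0 = ref, 1 = alt, per selected site
    sel_coeff: float
    trajectories: dict[str, list[list[float]]]  # pop → per-site frequency series
    seed: int

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=1))

    @classmethod
    def from_json(cls, path: str | Path) -> "SimulationTruth":
        return cls(**json.loads(Path(path).read_text()))


# -- reproduction machinery ---------------------------------------------

def _offspring(
    parents: np.ndarray,
    n_children: int,
    rng: np.random.Generator,
    map_length: float,
    positions: np.ndarray,
    chrom_length: int,
    weights: np.ndarray | None = None,
) -> np.ndarray:
    """One generation of haploid reproduction with recombination.

    Each child draws two parents (fitness-weighted when ``weights`` given) and
    a Poisson(``map_length``) number of crossovers placed uniformly in bp.
    """
    n_parents = parents.shape[0]
    if weights is None:
        mothers = rng.integers(0, n_parents, n_children)
        fathers = rng.integers(0, n_parents, n_children)
    else:
        p = weights / weights.sum()
        mothers = rng.choice(n_parents, n_children, p=p)
        fathers = rng.choice(n_parents, n_children, p=p)
    n_x = rng.poisson(map_length, n_children)
    children = np.empty((n_children, parents.shape[1]), dtype=np.int8)
    plain = n_x == 0
    children[plain] = parents[mothers[plain]]
    for i in np.flatnonzero(~plain):
        cuts = np.sort(rng.uniform(0, chrom_length, n_x[i]))
        seg = np.searchsorted(cuts, positions)
        start_with_mother = rng.integers(2)
        from_mother = (seg % 2) == start_with_mother
        children[i] = np.where(from_mother, parents[mothers[i]], parents[fathers[i]])
    return children


def _mutate(pop: np.ndarray, rng: np.random.Generator, mut_rate: float) -> None:
    """Flip 0↔1 at a Poisson number of random (individual, site) cells."""
    if mut_rate <= 0:
        return
    n_mut = rng.poisson(mut_rate * pop.size)
    if n_mut == 0:
        return
    rows = rng.integers(0, pop.shape[0], n_mut)
    cols = rng.integers(0, pop.shape[1], n_mut)
    pop[rows, cols] = 1 - pop[rows, cols]


def _mixed_offspring(
    pop_a: np.ndarray,
    pop_e: np.ndarray,
    prop_e: float,
    n_children: int,
    rng: np.random.Generator,
    map_length: float,
    positions: np.ndarray,
    chrom_length: int,
) -> np.ndarray:
    """Admixture pulse: each parent drawn from E with probability ``prop_e``."""
    pool = np.vstack([pop_a, pop_e])
    na, ne = pop_a.shape[0], pop_e.shape[0]
    p = np.concatenate([
        np.full(na, (1.0 - prop_e) / na),
        np.full(ne, prop_e / ne),
    ])
    return _offspring(pool, n_children, rng, map_length, positions, chrom_length, weights=p * len(p))


def _selection_weights(
    pop: np.ndarray,
    sel_idx: np.ndarray,
    favoured: np.ndarray,
    s: float,
    csd_sites: tuple[int, ...],
    csd_b: float,
) -> np.ndarray | None:
    w = None
    if s > 0 and sel_idx.size:
        n_fav = (pop[:, sel_idx] == favoured).sum(axis=1)
        w = (1.0 + s) ** n_fav
    if csd_b > 0 and csd_sites:
        hap = pop[:, list(csd_sites)]
        _, inverse, counts = np.unique(hap, axis=0, return_inverse=True, return_counts=True)
        freq = counts[inverse] / pop.shape[0]
        w_csd = np.exp(-csd_b * freq)  # rare csd alleles favoured
        w = w_csd if w is None else w * w_csd
    return w


def simulate_three_populations(
    config: SimulationConfig,
) -> tuple[HaplotypeMatrix, SimulationTruth]:
    """Run the full scenario; returns sampled haplotypes plus planted truth."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    L = config.n_sites
    chrom = config.chrom_length_bp
    positions = np.sort(
        rng.choice(np.arange(1, chrom + 1), size=L, replace=False)
    ).astype(np.int64)
    map_len = config.map_length_morgans

    def reproduce(pop, size, weights=None):
        children = _offspring(pop, size, rng, map_len, positions, chrom, weights)
        _mutate(children, rng, config.mut_rate)
        return children

    # ancestral deme
    if config.ancestral_haplotypes is not None:
        freqs = (
            np.full(L, config.ancestral_freq)
            if config.ancestral_freq is not None
            else rng.uniform(0.05, 0.95, L)
        )
        founders = (rng.random((config.ancestral_haplotypes, L)) < freqs).astype(np.int8)
        anc = founders[rng.integers(0, config.ancestral_haplotypes, config.pop_size_ancestral)]
    elif config.ancestral_freq is not None:
        anc = (rng.random((config.pop_size_ancestral, L)) < config.ancestral_freq).astype(np.int8)
    else:
        freqs = rng.uniform(0.05, 0.95, L)
        anc = (rng.random((config.pop_size_ancestral, L)) < freqs).astype(np.int8)

    for _ in range(config.t_split):
        anc = reproduce(anc, config.pop_size_ancestral)

    # split into A-like and E-like lineages
    pop_a = reproduce(anc, config.pop_size_A)
    pop_e = reproduce(anc, config.pop_size_E)
    del anc
    for _ in range(config.t_split + 1, config.t_admix):
        pop_a = reproduce(pop_a, config.pop_size_A)
        pop_e = reproduce(pop_e, config.pop_size_E)

    # admixture pulse: AHB replaces pure A
    pop_ahb = _mixed_offspring(
        pop_a, pop_e, config.admix_prop_E, config.pop_size_A, rng, map_len, positions, chrom
    )
    _mutate(pop_ahb, rng, config.mut_rate)
    del pop_a
    for _ in range(config.t_admix + 1, config.t_invasion):
        pop_ahb = reproduce(pop_ahb, config.pop_size_A)
        pop_e = reproduce(pop_e, config.pop_size_E)

    # gAHB founding: bottleneck sample without replacement from AHB
    founders_idx = rng.choice(config.pop_size_A, config.founder_size, replace=False)
    pop_g = pop_ahb[founders_idx].copy()

    # planted selection on standing variation: the favoured allele is the
    # AHB minor allele sitting in the standing-frequency window at founding
    ahb_freq = pop_ahb.mean(axis=0)           # alt-allele frequency
    minor = np.where(ahb_freq <= 0.5, 1, 0)   # minor allele code per site
    minor_freq = np.minimum(ahb_freq, 1.0 - ahb_freq)
    lo, hi = config.standing_freq_range
    eligible = np.flatnonzero((minor_freq >= lo) & (minor_freq <= hi))
    if eligible.size < config.n_selected_loci:
        raise ValueError(
            f"only {eligible.size} sites segregate in AHB at frequency "
            f"[{lo}, {hi}]; {config.n_selected_loci} selected loci requested"
        )
    # scenario: gAHB evolved toward the European-like profile, so prefer
    # standing alleles that are the majority allele in the E-like deme
    e_freq = pop_e.mean(axis=0)
    e_major = np.where(e_freq >= 0.5, 1, 0)
    preferred = eligible[e_major[eligible] == minor[eligible]]
    rest = eligible[e_major[eligible] != minor[eligible]]
    if preferred.size >= config.n_selected_loci:
        sel_idx = np.sort(rng.choice(preferred, config.n_selected_loci, replace=False))
    else:
        extra = rng.choice(rest, config.n_selected_loci - preferred.size, replace=False)
        sel_idx = np.sort(np.concatenate([preferred, extra]))
    favoured = minor[sel_idx].astype(np.int8)

    traj: dict[str, list[list[float]]] = {p: [] for p in POPULATION_ORDER}

    def record():
        for name, pop in (("gAHB", pop_g), ("AHB", pop_ahb), ("EHB", pop_e)):
            traj[name].append(
                [float((pop[:, j] == favoured[k]).mean()) for k, j in enumerate(sel_idx)]
            )

    record()
    size_g = config.founder_size
    for _ in range(config.generations_post_invasion):
        size_g = min(2 * size_g, config.pop_size_A)  # post-founding growth
        w = _selection_weights(
            pop_g, sel_idx, favoured, config.sel_coeff,
            config.csd_sites, config.csd_balancing,
        )
        pop_g = reproduce(pop_g, size_g, weights=w)
        pop_ahb = reproduce(pop_ahb, config.pop_size_A)
        pop_e = reproduce(pop_e, config.pop_size_E)
        record()

    # sampling without replacement
    n_g, n_a, n_e = config.sample_sizes
    for n_req, pop, name in ((n_g, pop_g, "gAHB"), (n_a, pop_ahb, "AHB"), (n_e, pop_e, "EHB")):
        if n_req > pop.shape[0]:
            raise ValueError(f"requested {n_req} samples from {name} deme of size {pop.shape[0]}")
    rows = [
        pop_g[rng.choice(pop_g.shape[0], n_g, replace=False)],
        pop_ahb[rng.choice(pop_ahb.shape[0], n_a, replace=False)],
        pop_e[rng.choice(pop_e.shape[0], n_e, replace=False)],
    ]
    calls = np.vstack(rows).astype(np.int8)

    sample_ids = (
        [f"gAHB_{i+1:03d}" for i in range(n_g)]
        + [f"AHB_{i+1:03d}" for i in range(n_a)]
        + [f"EHB_{i+1:03d}" for i in range(n_e)]
    )
    populations = {s: s.split("_")[0] for s in sample_ids}

    bases = np.array(["A", "C", "G", "T"])
    ref = bases[rng.integers(0, 4, L)]
    shift = rng.integers(1, 4, L)
    alt = bases[(np.searchsorted(bases, ref) + shift) % 4]

    matrix = HaplotypeMatrix(
        sample_ids=sample_ids,
        populations=populations,
        scaffolds=np.full(L, config.scaffold, dtype=object),
        positions_bp=positions,
        ref_allele=ref.astype(object),
        alt_allele=alt.astype(object),
        calls=calls,
        genetic_pos=(positions - 1) * config.recomb_rate,
    )
    if config.missing_rate > 0:
        matrix = inject_missingness(matrix, config.missing_rate, seed=int(rng.integers(2**31)))
    truth = SimulationTruth(
        selected_site_indices=[int(j) for j in sel_idx],
        favoured_allele=[int(a) for a in favoured],
        sel_coeff=config.sel_coeff,
        trajectories=traj,
        seed=config.seed,
    )
    return matrix, truth


def genetic_map_for(config: SimulationConfig) -> GeneticMap:
    """The uniform map implied by the configuration (emitted beside the VCF)."""
    return GeneticMap.uniform(config.scaffold, config.chrom_length_bp, config.recomb_rate)


def inject_missingness(matrix: HaplotypeMatrix, rate: float, seed: int) -> HaplotypeMatrix:
    """Set each call to MISSING independently with probability ``rate``."""
    if not 0.0 <= rate < 1.0:
        raise ValueError("missingness rate must be in [0, 1)")
    out = matrix.copy()
    if rate == 0.0:
        return out
    rng = np.random.default_rng(seed)
    mask = rng.random(out.calls.shape) < rate
    out.calls[mask] = MISSING
    return out
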