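"""Reading and writing the interchange formats around the scan.

VCF handling goes through :mod:`pysam`; calls are haploid (GT ``0``/``1``/``.``)
and a diploid genotype in the input is a hard error.  Auxiliary tables are
plain TSV: population membership (``sample<TAB>population``), genetic map
(``scaffold<TAB>bp<TAB>morgans``), and a ``scaffold:pos`` site list.  BED is
0-based half-open; GFF3 and gene BED intervals are normalised to 1-based
inclusive coordinates internally.
"""
from __future__ import annotations

import logging
from pathlib import Path
from typing import Iterable, NamedTuple

import numpy as np
import pysam

from .matrix import MISSING, GeneticMap, HaplotypeMatrix

log = logging.getLogger(__name__)


def read_vcf(
    path: str | Path,
    populations: dict[str, str] | None = None,
    info_bounds: dict[str, tuple[float | None, float | None]] | None = None,
) -> HaplotypeMatrix:
    """Parse a haploid VCF into a :class:`HaplotypeMatrix`.

    Multi-allelic records are tolerated here (ALT kept comma-joined, calls
    keep their allele index) and removed later by ``filter_biallelic``.
    Samples lacking an entry in ``populations`` are labelled ``"unknown"``.

    ``info_bounds`` optionally maps numeric INFO fields (or the special key
    ``"QUAL"``) to (min, max) bounds, either side ``None`` for open; records
    whose value falls outside the bounds are dropped, records lacking the
    field are kept.  Off by default — generic stand-ins for caller-specific
    site quality filters.
    """
    dropped_info = 0
    scaffolds: list[str] = []
    positions: list[int] = []
    ref: list[str] = []
    alt: list[str] = []
    columns: list[np.ndarray] = []
    with pysam.VariantFile(str(path)) as vf:
        samples = list(vf.header.samples)
        for rec in vf:
            if info_bounds and _fails_info_bounds(rec, info_bounds):
                dropped_info += 1
                continue
            col = np.empty(len(samples), dtype=np.int8)
            for i, s in enumerate(samples):
                gt = rec.samples[s]["GT"]
                if gt is None or len(gt) == 0 or (len(gt) == 1 and gt[0] is None):
                    col[i] = MISSING
                elif len(gt) > 1:
                    raise ValueError(
                        f"diploid genotype {gt} for sample {s} at "
                        f"{rec.chrom}:{rec.pos}; haploid calls required"
                    )
                else:
                    col[i] = gt[0]
            scaffolds.append(rec.chrom)
            positions.append(rec.pos)
            ref.append(rec.ref or "N")
            alt.append(",".join(rec.alts) if rec.alts else ".")
            columns.append(col)
    calls = (
        np.stack(columns, axis=1)
        if columns
        else np.empty((len(samples), 0), dtype=np.int8)
    )
    if dropped_info:
        log.info("read_vcf: %d records dropped by INFO bounds", dropped_info)
    pops = {s: (populations or {}).get(s, "unknown") for s in samples}
    m = HaplotypeMatrix(
        sample_ids=samples,
        populations=pops,
        scaffolds=np.array(scaffolds, dtype=object),
        positions_bp=np.array(positions, dtype=np.int64),
        ref_allele=np.array(ref, dtype=object),
        alt_allele=np.array(alt, dtype=object),
        calls=calls,
    )
    return m


def _fails_info_bounds(rec, info_bounds) -> bool:
    for field, (lo, hi) in info_bounds.items():
        if field == "QUAL":
            value = rec.qual
        else:
            value = rec.info.get(field)
        if value is None:
            continue
        if isinstance(value, (tuple, list)):
            value = value[0]
        value = float(value)
        if (lo is not None and value < lo) or (hi is not None and value > hi):
            return True
    return False


def write_vcf(matrix: HaplotypeMatrix, path: str | Path) -> None:
    """Write a haploid VCF such that ``read_vcf(write_vcf(m))`` equals ``m``."""
    header = pysam.VariantHeader()
    # contig lengths: at least the largest recorded position
    lengths: dict[str, int] = {}
    for scaf, pos in zip(matrix.scaffolds, matrix.positions_bp):
        lengths[scaf] = max(lengths.get(scaf, 0), int(pos))
    for scaf, length in lengths.items():
        header.contigs.add(scaf, length=length + 1)
    header.add_meta(
        "FORMAT",
        items=[("ID", "GT"), ("Number", "1"), ("Type", "String"), ("Description", "Genotype")],
    )
    for s in matrix.sample_ids:
        header.add_sample(s)
    with pysam.VariantFile(str(path), "w", header=header) as out:
        for j in range(matrix.n_sites):
            alts = tuple(str(matrix.alt_allele[j]).split(","))
            rec = out.new_record(
                contig=str(matrix.scaffolds[j]),
                start=int(matrix.positions_bp[j]) - 1,
                stop=int(matrix.positions_bp[j]),
                alleles=(str(matrix.ref_allele[j]),) + alts,
            )
            for i, s in enumerate(matrix.sample_ids):
                c = int(matrix.calls[i, j])
                rec.samples[s]["GT"] = (None,) if c == MISSING else (c,)
            out.write(rec)


# -- auxiliary tables ----------------------------------------------------

def read_populations(path: str | Path) -> dict[str, str]:
    """``sample<TAB>population`` table → mapping."""
    pops: dict[str, str] = {}
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line.strip() or line.startswith("#"):
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) < 2:
            raise ValueError(f"{path}:{lineno}: expected 'sample<TAB>population'")
        pops[parts[0]] = parts[1]
    return pops


def write_populations(populations: dict[str, str], path: str | Path) -> None:
    with open(path, "w") as fh:
        for s, p in populations.items():
            fh.write(f"{s}\t{p}\n")


def read_genetic_map(path: str | Path) -> GeneticMap:
    """``scaffold<TAB>bp<TAB>morgans`` breakpoint table → :class:`GeneticMap`."""
    per_scaf: dict[str, list[tuple[int, float]]] = {}
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line.strip() or line.startswith("#") or line.startswith("scaffold\t"):
            continue
        parts = line.split("\t")
        if len(parts) < 3:
            raise ValueError(f"{path}:{lineno}: expected 'scaffold<TAB>bp<TAB>morgans'")
        per_scaf.setdefault(parts[0], []).append((int(parts[1]), float(parts[2])))
    breakpoints = {}
    for scaf, rows in per_scaf.items():
        rows.sort()
        bp = np.array([r[0] for r in rows], dtype=np.int64)
        m = np.array([r[1] for r in rows], dtype=float)
        breakpoints[scaf] = (bp, m)
    return GeneticMap(breakpoints)


def write_genetic_map(gmap: GeneticMap, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("scaffold\tbp\tmorgans\n")
        for scaf, (bp, m) in gmap.breakpoints.items():
            for b, mm in zip(bp, m):
                fh.write(f"{scaf}\t{b}\t{mm:.10g}\n")


class BedInterval(NamedTuple):
    scaffold: str
    start: int  # 0-based inclusive
    end: int    # 0-based exclusive


def read_bed(path: str | Path) -> list[BedInterval]:
    """Parse a BED file (0-based half-open); malformed lines name their number."""
    out: list[BedInterval] = []
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line.strip() or line.startswith(("#", "track", "browser")):
            continue
        parts = line.split("\t")
        try:
            scaf, start, end = parts[0], int(parts[1]), int(parts[2])
        except (IndexError, ValueError) as exc:
            raise ValueError(f"{path}:{lineno}: malformed BED line: {line!r}") from exc
        if end < start:
            raise ValueError(f"{path}:{lineno}: BED end < start")
        out.append(BedInterval(scaf, start, end))
    return out


class GeneInterval(NamedTuple):
    scaffold: str
    start_bp: int  # 1-based inclusive
    end_bp: int    # 1-based inclusive
    gene_id: str


def read_gene_intervals(path: str | Path, feature_types: tuple[str, ...] = ("gene",)) -> list[GeneInterval]:
    """Gene spans from GFF3 (``feature_types`` rows) or from a named BED.

    Format is sniffed from the extension: ``.bed`` → 0-based half-open with the
    4th column as gene id; anything else is treated as GFF3 (1-based inclusive,
    ``ID=``/``Name=`` attribute as gene id).
    """
    path = Path(path)
    genes: list[GeneInterval] = []
    if path.suffix.lower() == ".bed":
        for iv_idx, line in enumerate(path.read_text().splitlines()):
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            name = parts[3] if len(parts) > 3 else f"gene{iv_idx + 1}"
            genes.append(GeneInterval(parts[0], int(parts[1]) + 1, int(parts[2]), name))
        return genes
    for lineno, line in enumerate(path.read_text().splitlines(), start=1):
        if not line.strip() or line.startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) < 9:
            raise ValueError(f"{path}:{lineno}: malformed GFF3 line")
        if parts[2] not in feature_types:
            continue
        attrs = dict(
            kv.split("=", 1) for kv in parts[8].strip().split(";") if "=" in kv
        )
        gene_id = attrs.get("ID") or attrs.get("Name") or f"gene_at_{parts[0]}:{parts[3]}"
        genes.append(GeneInterval(parts[0], int(parts[3]), int(parts[4]), gene_id))
    return genes


def read_site_list(path: str | Path) -> list[tuple[str, int]]:
    """One ``scaffold:pos`` per line → list of (scaffold, 1-based pos)."""
    sites: list[tuple[str, int]] = []
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line.strip() or line.startswith("#"):
            continue
        try:
            scaf, pos = line.strip().rsplit(":", 1)
            sites.append((scaf, int(pos)))
        except ValueError as exc:
            raise ValueError(f"{path}:{lineno}: expected 'scaffold:pos'") from exc
    return sites


def resolve_sites(matrix: HaplotypeMatrix, sites: Iterable[tuple[str, int]]) -> list[int]:
    """Map (scaffold, pos) pairs to site indices; unknown sites raise."""
    lookup = {
        (str(s), int(p)): j
        for j, (s, p) in enumerate(zip(matrix.scaffolds, matrix.positions_bp))
    }
    idx = []
    for key in sites:
        key = (str(key[0]), int(key[1]))
        if key not in lookup:
            raise KeyError(f"site {key[0]}:{key[1]} not present in matrix")
        idx.append(lookup[key])
    return idx
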