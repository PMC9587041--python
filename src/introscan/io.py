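"""Genotype containers, VCF/TSV/BED input-output, site filters, and block grids.

Internal coordinates are 0-based half-open; VCF positions stay 1-based at the
boundary. Genotypes are diploid ALT-allele dosages in {0, 1, 2} with
``MISSING`` (-1) for any genotype containing an unknown allele.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Sentinel dosage for a missing genotype.
MISSING: int = -1

SITE_COLUMNS = ("chrom", "pos", "ref", "alt")


class VCFParseError(ValueError):
    """Raised when a VCF cannot be parsed; carries the offending location."""


@dataclass(frozen=True)
class Block:
    """A 0-based half-open genomic interval, one tile of a block grid."""

    chrom: str
    start: int
    end: int
    index: int

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError(f"block end must exceed start: {self}")

    @property
    def length(self) -> int:
        return self.end - self.start

    def overlaps(self, chrom: str, start: int, end: int) -> bool:
        return self.chrom == chrom and self.start < end and start < self.end


@dataclass
class GroupMap:
    """Accession -> subpopulation assignment with a declared group order."""

    assignments: dict[str, str]
    group_order: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        seen: list[str] = list(self.group_order)
        for g in self.assignments.values():
            if g not in seen:
                seen.append(g)
        self.group_order = seen

    def members(self, group: str) -> list[str]:
        return [a for a, g in self.assignments.items() if g == group]

    def group_of(self, accession: str) -> str:
        return self.assignments[accession]

    def __contains__(self, accession: str) -> bool:
        return accession in self.assignments

    @property
    def groups(self) -> list[str]:
        return list(self.group_order)


@dataclass
class GenotypeMatrix:
    """Samples x biallelic sites dosage matrix with a sorted site table.

    Parameters
    ----------
    accession_ids
        Unique sample identifiers, one per dosage row.
    sites
        DataFrame with columns ``chrom, pos, ref, alt``; ``pos`` is the
        1-based VCF coordinate, sorted by (chrom, pos) with unique positions
        per chromosome.
    dosage
        ``(n_accessions, n_sites)`` int8 array of ALT dosages; ``MISSING``
        marks unknown genotypes.
    """

    accession_ids: list[str]
    sites: pd.DataFrame
    dosage: np.ndarray

    def __post_init__(self) -> None:
        self.dosage = np.asarray(self.dosage, dtype=np.int8)
        if len(self.accession_ids) != len(set(self.accession_ids)):
            raise ValueError("accession ids must be unique")
        if self.dosage.shape != (len(self.accession_ids), len(self.sites)):
            raise ValueError(
                f"dosage shape {self.dosage.shape} inconsistent with "
                f"{len(self.accession_ids)} accessions x {len(self.sites)} sites"
            )
        bad = ~np.isin(self.dosage, (0, 1, 2, MISSING))
        if bad.any():
            raise ValueError("dosage codes must be in {0, 1, 2, MISSING}")
        self.sites = self.sites.reset_index(drop=True)

    @property
    def n_accessions(self) -> int:
        return len(self.accession_ids)

    @property
    def n_sites(self) -> int:
        return len(self.sites)

    def accession_indices(self, ids) -> np.ndarray:
        lookup = {a: i for i, a in enumerate(self.accession_ids)}
        return np.array([lookup[a] for a in ids], dtype=np.intp)

    def take_sites(self, idx) -> "GenotypeMatrix":
        idx = np.asarray(idx)
        return GenotypeMatrix(
            list(self.accession_ids),
            self.sites.iloc[idx].reset_index(drop=True),
            self.dosage[:, idx],
        )

    def take_accessions(self, ids) -> "GenotypeMatrix":
        idx = self.accession_indices(ids)
        return GenotypeMatrix(list(ids), self.sites.copy(), self.dosage[idx])

    def allele_counts(self, accession_idx=None) -> tuple[np.ndarray, np.ndarray]:
        """Per-site (ALT-dosage sum, non-missing allele count) over a sample subset."""
        d = self.dosage if accession_idx is None else self.dosage[accession_idx]
        obs = d != MISSING
        alt = np.where(obs, d, 0).sum(axis=0).astype(np.int64)
        n_alleles = 2 * obs.sum(axis=0).astype(np.int64)
        return alt, n_alleles


def _sorted_sites(sites: pd.DataFrame) -> pd.DataFrame:
    sites = sites.sort_values(["chrom", "pos"], kind="mergesort").reset_index(drop=True)
    dup = sites.duplicated(["chrom", "pos"])
    if dup.any():
        raise ValueError("duplicate site positions within a chromosome")
    return sites


def read_vcf(path, skip_multiallelic: bool = True) -> GenotypeMatrix:
    """Read a VCF (GT field) into a :class:`GenotypeMatrix`.

    Dosage is the count of ALT alleles; any genotype containing a missing
    allele becomes ``MISSING``. Multiallelic records are skipped with a
    warning (or rejected when ``skip_multiallelic`` is False).
    """
    from cyvcf2 import VCF

    try:
        vcf = VCF(str(path))
    except Exception as exc:  # pragma: no cover - cyvcf2 error text varies
        raise VCFParseError(f"{path}: cannot open VCF: {exc}") from exc
    samples = list(vcf.samples)
    rows = []
    dosages = []
    n_multi = 0
    for rec_no, var in enumerate(vcf, start=1):
        if len(var.ALT) != 1:
            if not skip_multiallelic:
                raise VCFParseError(
                    f"{path}: record {rec_no} ({var.CHROM}:{var.POS}) is not biallelic"
                )
            n_multi += 1
            continue
        gts = var.genotype.array()
        a = gts[:, 0].astype(np.int16)
        b = gts[:, 1].astype(np.int16)
        dos = a + b
        dos[(a < 0) | (b < 0)] = MISSING
        rows.append((var.CHROM, var.POS, var.REF, var.ALT[0]))
        dosages.append(dos.astype(np.int8))
    vcf.close()
    if n_multi:
        logger.warning("%s: skipped %d multiallelic record(s)", path, n_multi)
    sites = _sorted_sites(pd.DataFrame(rows, columns=list(SITE_COLUMNS)))
    if dosages:
        mat = np.stack(dosages, axis=1)
        # re-order columns to match the sorted site table
        order = (
            pd.DataFrame(rows, columns=list(SITE_COLUMNS))
            .sort_values(["chrom", "pos"], kind="mergesort")
            .index.to_numpy()
        )
        mat = mat[:, order]
    else:
        mat = np.empty((len(samples), 0), dtype=np.int8)
    return GenotypeMatrix(samples, sites, mat)


def write_vcf(g: GenotypeMatrix, path, chrom_lengths: dict[str, int] | None = None) -> None:
    """Write a minimal VCF 4.2 with GT only; missing genotypes as ``./.``."""
    if chrom_lengths is None:
        chrom_lengths = (
            g.sites.groupby("chrom", sort=True)["pos"].max().astype(int).to_dict()
        )
    gt_codes = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        for chrom, length in chrom_lengths.items():
            fh.write(f"##contig=<ID={chrom},length={int(length)}>\n")
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(g.accession_ids)
            + "\n"
        )
        chroms = g.sites["chrom"].to_numpy()
        poss = g.sites["pos"].to_numpy()
        refs = g.sites["ref"].to_numpy()
        alts = g.sites["alt"].to_numpy()
        for j in range(g.n_sites):
            gts = "\t".join(gt_codes[int(d)] for d in g.dosage[:, j])
            fh.write(
                f"{chroms[j]}\t{int(poss[j])}\t.\t{refs[j]}\t{alts[j]}\t.\tPASS\t.\tGT\t{gts}\n"
            )


def filter_sites(
    g: GenotypeMatrix, maf_min: float = 0.05, missing_max: float = 0.40
) -> GenotypeMatrix:
    """Apply the standard site filters: MAF strictly above ``maf_min`` and
    missing fraction strictly below ``missing_max``.

    MAF is computed over non-missing alleles only; sites with all genotypes
    missing are dropped (their MAF is undefined). Both inequalities are
    strict, so a site at exactly the threshold is removed. The operation is
    idempotent.
    """
    if not (0 <= maf_min <= 0.5):
        raise ValueError("maf_min must be in [0, 0.5]")
    if not (0 <= missing_max <= 1):
        raise ValueError("missing_max must be in [0, 1]")
    obs = g.dosage != MISSING
    n_obs = obs.sum(axis=0)
    miss_frac = 1.0 - n_obs / g.n_accessions
    alt, n_alleles = g.allele_counts()
    with np.errstate(invalid="ignore", divide="ignore"):
        p = np.where(n_alleles > 0, alt / np.maximum(n_alleles, 1), np.nan)
    maf = np.minimum(p, 1.0 - p)
    keep = (n_alleles > 0) & (maf > maf_min) & (miss_frac < missing_max)
    return g.take_sites(np.flatnonzero(keep))


@dataclass
class BlockGrid:
    """Partition of the genome into fixed-width non-overlapping blocks.

    ``site_slices[i]`` is the half-open (lo, hi) range of rows of the site
    table falling in ``blocks[i]``; the site table is sorted, so ranges are
    contiguous and the blocks of one grid tile each chromosome exactly.
    """

    blocks: list[Block]
    site_slices: list[tuple[int, int]]
    block_size: int
    chrom_lengths: dict[str, int]

    @property
    def n_blocks(self) -> int:
        return len(self.blocks)

    def sites_in(self, block_index: int) -> np.ndarray:
        lo, hi = self.site_slices[block_index]
        return np.arange(lo, hi, dtype=np.intp)

    def n_sites_in(self, block_index: int) -> int:
        lo, hi = self.site_slices[block_index]
        return hi - lo

    def block_of_site(self, chrom: str, pos_1based: int) -> int:
        """Grid index of the block containing a site (1-based position)."""
        for b in self.blocks:
            if b.chrom == chrom and b.start <= pos_1based - 1 < b.end:
                return b.index
        raise KeyError(f"no block contains {chrom}:{pos_1based}")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "chrom": [b.chrom for b in self.blocks],
                "start": [b.start for b in self.blocks],
                "end": [b.end for b in self.blocks],
            }
        )


def slice_blocks(
    sites: pd.DataFrame, block_size_bp: int, chrom_lengths: dict[str, int]
) -> BlockGrid:
    """Tile each chromosome with ``block_size_bp`` half-open blocks.

    A site at 1-based position p belongs to block ``floor((p-1)/B)`` on its
    chromosome; the last block is truncated at the chromosome end. Chromosomes
    are laid out in the (sorted) order of ``chrom_lengths``.
    """
    if block_size_bp <= 0:
        raise ValueError("block_size_bp must be positive")
    B = int(block_size_bp)
    blocks: list[Block] = []
    slices: list[tuple[int, int]] = []
    chrom_arr = sites["chrom"].to_numpy()
    pos_arr = sites["pos"].to_numpy()
    idx = 0
    for chrom in sorted(chrom_lengths):
        length = int(chrom_lengths[chrom])
        on_chrom = np.flatnonzero(chrom_arr == chrom)
        pos0 = pos_arr[on_chrom] - 1  # 0-based
        for start in range(0, length, B):
            end = min(start + B, length)
            lo = int(np.searchsorted(pos0, start, side="left"))
            hi = int(np.searchsorted(pos0, end, side="left"))
            base = int(on_chrom[0]) if len(on_chrom) else 0
            blocks.append(Block(chrom, start, end, idx))
            slices.append((base + lo, base + hi))
            idx += 1
    covered = sum(hi - lo for lo, hi in slices)
    if covered != len(sites):
        warnings.warn(
            f"{len(sites) - covered} site(s) fall outside the declared "
            "chromosome lengths and are not assigned to any block",
            stacklevel=2,
        )
    return BlockGrid(blocks, slices, B, dict(chrom_lengths))


# ---------------------------------------------------------------------------
# plain-text tables


def read_groups(path) -> GroupMap:
    """Read an accession<TAB>group table."""
    df = pd.read_csv(path, sep="\t", header=None, names=["accession", "group"], comment="#")
    order: list[str] = []
    for grp in df["group"]:
        if grp not in order:
            order.append(grp)
    return GroupMap(dict(zip(df["accession"], df["group"])), order)


def write_groups(groups: GroupMap, path) -> None:
    with open(path, "w") as fh:
        for acc, grp in groups.assignments.items():
            fh.write(f"{acc}\t{grp}\n")


def read_phenotype(path) -> pd.Series:
    """Read an accession<TAB>value table into a float Series."""
    df = pd.read_csv(path, sep="\t", header=None, names=["accession", "value"], comment="#")
    return pd.Series(df["value"].to_numpy(float), index=df["accession"], name="phenotype")


def write_phenotype(pheno: pd.Series, path) -> None:
    with open(path, "w") as fh:
        for acc, val in pheno.items():
            fh.write(f"{acc}\t{val:.10g}\n")


def write_bed(intervals, path, names=None) -> None:
    """Write (chrom, start, end) triples as 0-based half-open BED."""
    with open(path, "w") as fh:
        for i, iv in enumerate(intervals):
            chrom, start, end = iv[0], iv[1], iv[2]
            line = f"{chrom}\t{int(start)}\t{int(end)}"
            if names is not None:
                line += f"\t{names[i]}"
            fh.write(line + "\n")


def read_bed(path) -> list[tuple[str, int, int]]:
    out = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            out.append((parts[0], int(parts[1]), int(parts[2])))
    return out
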