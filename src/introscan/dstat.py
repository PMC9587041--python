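"""Windowed ABBA-BABA D statistic with block-jackknife Z scores.

Four populations are assigned the roles P1, P2, P3 and outgroup O. With
per-site derived-allele frequencies p1..p4, each site contributes

    abba = (1 - p1) p2 p3 (1 - p4)
    baba = p1 (1 - p2) p3 (1 - p4)

and a window's D is (sum abba - sum baba) / (sum abba + sum baba). D > 0
indicates excess P2-P3 sharing, D < 0 excess P1-P3 sharing; with tropical
japonica as P1, temperate japonica as P2 and indica as P3, indica ->
tropical-japonica introgression drives D negative, and peaks are reported by
|D| / |Z|. A window with zero denominator reports D as NA, never 0.

ALT dosage is used as the derived allele by default; with a strongly
diverged, nearly fixed outgroup the (1 - p4) weight makes orientation matter
only through O. ``polarize_by_outgroup=True`` instead re-orients every site
so the outgroup's major allele is ancestral.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from introscan.io import BlockGrid, GenotypeMatrix, GroupMap

__all__ = [
    "RoleAssignment",
    "FrequencyTable",
    "DStatWindow",
    "group_allele_frequencies",
    "site_pattern_terms",
    "d_statistic",
    "jackknife_z_window",
    "genome_wide_d",
    "dstat_scan",
    "call_peaks",
]


@dataclass(frozen=True)
class RoleAssignment:
    """Mapping of the four D-statistic roles to group names."""

    p1: str
    p2: str
    p3: str
    outgroup: str

    def __post_init__(self) -> None:
        names = (self.p1, self.p2, self.p3, self.outgroup)
        if len(set(names)) != 4:
            raise ValueError("P1, P2, P3 and O must be four distinct groups")

    @property
    def ordered(self) -> tuple[str, str, str, str]:
        return (self.p1, self.p2, self.p3, self.outgroup)

    def swapped_p1_p2(self) -> "RoleAssignment":
        return RoleAssignment(self.p2, self.p1, self.p3, self.outgroup)


@dataclass
class FrequencyTable:
    """Per-site derived-allele frequencies in the four role populations.

    ``p`` is an (n_sites, 4) array ordered (P1, P2, P3, O); ``n_obs`` the
    matching non-missing accession counts; ``usable`` flags sites where every
    role has at least one non-missing genotype.
    """

    p: np.ndarray
    n_obs: np.ndarray
    usable: np.ndarray
    roles: RoleAssignment


def group_allele_frequencies(
    g: GenotypeMatrix,
    groups: GroupMap,
    roles: RoleAssignment,
    polarize_by_outgroup: bool = False,
) -> FrequencyTable:
    """ALT-allele frequency per site in each of the four role populations.

    p = ALT-dosage sum / (2 x non-missing accessions), computed over
    non-missing genotypes only; a site missing all data in any role is
    flagged unusable.
    """
    p = np.empty((g.n_sites, 4), dtype=float)
    n_obs = np.empty((g.n_sites, 4), dtype=np.int64)
    for col, group in enumerate(roles.ordered):
        members = [a for a in groups.members(group) if a in set(g.accession_ids)]
        if not members:
            raise ValueError(f"role group {group!r} has no accession in the matrix")
        idx = g.accession_indices(members)
        alt, n_alleles = g.allele_counts(idx)
        with np.errstate(invalid="ignore", divide="ignore"):
            p[:, col] = np.where(n_alleles > 0, alt / np.maximum(n_alleles, 1), np.nan)
        n_obs[:, col] = n_alleles // 2
    usable = (n_obs > 0).all(axis=1)
    if polarize_by_outgroup:
        flip = p[:, 3] > 0.5
        p[flip] = 1.0 - p[flip]
    return FrequencyTable(p, n_obs, usable, roles)


def site_pattern_terms(freqs: FrequencyTable) -> tuple[np.ndarray, np.ndarray]:
    """Per-site (abba, baba) weights; NaN at unusable sites."""
    p1, p2, p3, p4 = freqs.p.T
    abba = (1.0 - p1) * p2 * p3 * (1.0 - p4)
    baba = p1 * (1.0 - p2) * p3 * (1.0 - p4)
    abba = np.where(freqs.usable, abba, np.nan)
    baba = np.where(freqs.usable, baba, np.nan)
    return abba, baba


@dataclass
class DStatWindow:
    """ABBA/BABA sums and D for one window; ``d`` is NaN when the
    denominator is zero and ``z`` is +/-inf when the jackknife SE is zero."""

    block_index: int
    abba: float
    baba: float
    n_sites: int
    z: float | None = None

    @property
    def d(self) -> float:
        den = self.abba + self.baba
        if den <= 0 or self.n_sites == 0:
            return float("nan")
        return (self.abba - self.baba) / den


def d_statistic(
    freqs: FrequencyTable, site_indices: np.ndarray | None = None, block_index: int = -1
) -> DStatWindow:
    """D over a set of sites (all usable sites when ``site_indices`` is None)."""
    abba, baba = site_pattern_terms(freqs)
    if site_indices is not None:
        abba = abba[np.asarray(site_indices)]
        baba = baba[np.asarray(site_indices)]
    ok = ~np.isnan(abba)
    return DStatWindow(
        block_index,
        float(np.nansum(abba)),
        float(np.nansum(baba)),
        int(ok.sum()),
    )


def _jackknife(d_full: float, d_loo: np.ndarray) -> float:
    """Delete-one jackknife SE from leave-one-out estimates."""
    m = len(d_loo)
    mean = d_loo.mean()
    var = (m - 1) / m * np.sum((d_loo - mean) ** 2)
    return float(np.sqrt(var))


def jackknife_z_window(
    abba: np.ndarray, baba: np.ndarray, n_chunks: int | None = None
) -> float:
    """Per-window Z from a delete-one jackknife over site chunks.

    The window's usable sites are split, in genomic order, into ``n_chunks``
    nearly equal chunks (default: one chunk per site, appropriate when sites
    are effectively unlinked; pass a smaller count to damp local LD); each
    leave-one-out replicate recomputes D. Returns NaN when fewer than 10
    chunks have sites or the window's D is undefined; returns signed
    infinity when all replicates agree exactly (SE = 0).
    """
    ok = ~np.isnan(abba)
    a = abba[ok]
    b = baba[ok]
    if n_chunks is None:
        n_chunks = len(a)
    if n_chunks < 10 or len(a) < n_chunks:
        return float("nan")
    A, B = a.sum(), b.sum()
    den = A + B
    if den <= 0:
        return float("nan")
    d_full = (A - B) / den
    bounds = np.linspace(0, len(a), n_chunks + 1).astype(int)
    ca = np.add.reduceat(a, bounds[:-1])
    cb = np.add.reduceat(b, bounds[:-1])
    den_loo = (A - ca) + (B - cb)
    if np.any(den_loo <= 0):
        return float("nan")
    d_loo = ((A - ca) - (B - cb)) / den_loo
    se = _jackknife(d_full, d_loo)
    if se == 0.0:
        return float(np.copysign(np.inf, d_full)) if d_full != 0 else float("inf")
    return float(d_full / se)


def genome_wide_d(
    freqs: FrequencyTable,
    grid: BlockGrid,
    windows_per_jackknife_block: int = 5,
) -> tuple[float, float, float]:
    """Genome-wide D with SE and Z from a delete-one jackknife over blocks of
    ``windows_per_jackknife_block`` consecutive grid windows (2.5 Mb at the
    500 kb default)."""
    abba, baba = site_pattern_terms(freqs)
    block_a, block_b = [], []
    for start in range(0, grid.n_blocks, windows_per_jackknife_block):
        idx = np.concatenate(
            [grid.sites_in(b) for b in range(start, min(start + windows_per_jackknife_block, grid.n_blocks))]
        )
        a = np.nansum(abba[idx])
        b = np.nansum(baba[idx])
        if a + b > 0:
            block_a.append(a)
            block_b.append(b)
    if len(block_a) < 10:
        raise ValueError("need >= 10 jackknife blocks with usable sites")
    a = np.array(block_a)
    b = np.array(block_b)
    d_full = (a.sum() - b.sum()) / (a.sum() + b.sum())
    m = len(a)
    d_loo = np.array(
        [
            (a.sum() - a[i] - (b.sum() - b[i])) / (a.sum() - a[i] + b.sum() - b[i])
            for i in range(m)
        ]
    )
    se = _jackknife(d_full, d_loo)
    z = float("inf") if se == 0 else d_full / se
    return float(d_full), float(se), float(z)


def dstat_scan(
    g: GenotypeMatrix,
    grid: BlockGrid,
    groups: GroupMap,
    roles: RoleAssignment,
    n_jackknife_chunks: int | None = None,
    polarize_by_outgroup: bool = False,
) -> pd.DataFrame:
    """Per-window D and jackknife Z along the block grid.

    Returns a DataFrame with chrom, start, end, n_sites, abba, baba, D, Z;
    D and Z are NaN where undefined.
    """
    freqs = group_allele_frequencies(g, groups, roles, polarize_by_outgroup)
    abba, baba = site_pattern_terms(freqs)
    rows = []
    for b in grid.blocks:
        idx = grid.sites_in(b.index)
        win = d_statistic(freqs, idx, b.index)
        z = jackknife_z_window(abba[idx], baba[idx], n_jackknife_chunks)
        rows.append(
            (b.chrom, b.start, b.end, win.n_sites, win.abba, win.baba, win.d, z)
        )
    return pd.DataFrame(
        rows, columns=["chrom", "start", "end", "n_sites", "abba", "baba", "D", "Z"]
    )


def call_peaks(scan: pd.DataFrame, grid: BlockGrid, z_threshold: float = 3.0) -> pd.DataFrame:
    """Merge contiguous windows with |Z| >= threshold into peak regions.

    Direction is annotated by the sign of D: "P3->P1" for negative D (excess
    P1-P3 sharing), "P3->P2" for positive.
    """
    z = scan["Z"].to_numpy()
    d = scan["D"].to_numpy()
    passing = np.flatnonzero(np.abs(z) >= z_threshold)
    sign = {}
    for i in passing:
        sign[i] = "P3->P1" if d[i] < 0 else "P3->P2"
    regions: list[tuple[str, int, int, str]] = []
    for i in passing:
        blk = grid.blocks[int(i)]
        if (
            regions
            and regions[-1][0] == blk.chrom
            and blk.start <= regions[-1][2]
            and regions[-1][3] == sign[i]
        ):
            regions[-1] = (blk.chrom, regions[-1][1], blk.end, sign[i])
        else:
            regions.append((blk.chrom, blk.start, blk.end, sign[i]))
    return pd.DataFrame(regions, columns=["chrom", "start", "end", "direction"])


def peak_regions(peaks: pd.DataFrame) -> list[tuple[str, int, int]]:
    return [tuple(r) for r in peaks[["chrom", "start", "end"]].itertuples(index=False)]
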