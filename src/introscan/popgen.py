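"""Windowed nucleotide diversity and Hudson's Fst.

Diversity is pi with the small-sample correction, per base pair of block
length (no callability mask is modelled, so block length — not callable
length — is the denominator). Differentiation uses Hudson's estimator as a
ratio of averages across sites, which is robust to low-frequency sites and
unequal sample sizes.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from introscan.io import BlockGrid, GenotypeMatrix, GroupMap

__all__ = ["nucleotide_diversity", "hudson_fst"]


def _group_freqs(g: GenotypeMatrix, groups: GroupMap, group: str):
    members = [a for a in groups.members(group) if a in set(g.accession_ids)]
    idx = g.accession_indices(members)
    alt, n_alleles = g.allele_counts(idx)
    with np.errstate(invalid="ignore", divide="ignore"):
        p = np.where(n_alleles > 0, alt / np.maximum(n_alleles, 1), np.nan)
    return p, n_alleles, len(members)


def nucleotide_diversity(
    g: GenotypeMatrix, grid: BlockGrid, groups: GroupMap, group_names=None
) -> pd.DataFrame:
    """Per-block, per-group pi per base pair.

    Each site with n >= 2 observed alleles contributes 2 p (1-p) n/(n-1);
    the block sum is divided by block length. Blocks with no usable site for
    a group report NaN. Groups need at least 2 accessions.
    """
    if group_names is None:
        group_names = groups.groups
    rows = []
    for group in group_names:
        p, n_alleles, n_members = _group_freqs(g, groups, group)
        if n_members < 2:
            raise ValueError(f"group {group!r} needs >= 2 accessions for diversity")
        usable = n_alleles >= 2
        with np.errstate(invalid="ignore"):
            term = np.where(
                usable, 2.0 * p * (1.0 - p) * n_alleles / np.maximum(n_alleles - 1, 1), 0.0
            )
        for b in grid.blocks:
            idx = grid.sites_in(b.index)
            n_use = int(usable[idx].sum())
            pi = float(term[idx].sum()) / b.length if n_use > 0 else float("nan")
            rows.append((b.chrom, b.start, b.end, group, pi, n_use))
    return pd.DataFrame(
        rows, columns=["chrom", "start", "end", "group", "pi_per_bp", "n_sites"]
    )


def hudson_fst(
    g: GenotypeMatrix, grid: BlockGrid, groups: GroupMap, group_a: str, group_b: str
) -> pd.DataFrame:
    """Per-block Hudson Fst between two groups, as a ratio of averages.

    Per usable site (>= 2 observed alleles in each group):

        N = (pA - pB)^2 - pA(1-pA)/(nA-1) - pB(1-pB)/(nB-1)
        D = pA(1-pB) + pB(1-pA)

    with n the observed allele count; block Fst = sum N / sum D, NaN when
    the denominator sum is zero.
    """
    pa, na, ma = _group_freqs(g, groups, group_a)
    pb, nb, mb = _group_freqs(g, groups, group_b)
    if ma < 2 or mb < 2:
        raise ValueError("both groups need >= 2 accessions for Fst")
    usable = (na >= 2) & (nb >= 2)
    with np.errstate(invalid="ignore", divide="ignore"):
        num = (
            (pa - pb) ** 2
            - pa * (1 - pa) / np.maximum(na - 1, 1)
            - pb * (1 - pb) / np.maximum(nb - 1, 1)
        )
        den = pa * (1 - pb) + pb * (1 - pa)
    num = np.where(usable, num, 0.0)
    den = np.where(usable, den, 0.0)
    rows = []
    for b in grid.blocks:
        idx = grid.sites_in(b.index)
        dsum = float(den[idx].sum())
        fst = float(num[idx].sum()) / dsum if dsum > 0 else float("nan")
        n_use = int(usable[idx].sum())
        rows.append((b.chrom, b.start, b.end, f"{group_a}:{group_b}", fst, n_use))
    return pd.DataFrame(
        rows, columns=["chrom", "start", "end", "pair", "fst", "n_sites"]
    )
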