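"""Supervised local-ancestry estimation and admixture association mapping.

For each target accession and each block (200 kb by default), the donor
ancestry dosage q in [0, 1] maximizes the supervised two-panel binomial
likelihood

    prod_sites Binom(g_s; 2, q f_A,s + (1-q) f_B,s)

where f_A and f_B are the reference panels' allele frequencies (recomputed
leaving the target out when it belongs to a panel). The log-likelihood is
concave in q, so a golden-section search on [0, 1] finds the maximum to the
requested tolerance.

Association then regresses the phenotype on each block's q with an
always-included global mean-ancestry covariate controlling population
structure, reporting the dosage coefficient's two-sided t test and the
genomic-inflation factor lambda over all blocks.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from introscan.io import BlockGrid, GenotypeMatrix, GroupMap, MISSING

__all__ = ["estimate_block_ancestry", "associate", "AssociationResult"]

_EPS = 1e-6
_INVPHI = (np.sqrt(5.0) - 1.0) / 2.0


def _panel_freqs_loo(
    g: GenotypeMatrix, members: list[str], targets: list[str]
) -> tuple[np.ndarray, np.ndarray]:
    """Per-target per-site panel frequencies with leave-one-out for targets
    inside the panel. Returns (F, defined) of shape (n_targets, n_sites)."""
    midx = g.accession_indices(members)
    alt, n_alleles = g.allele_counts(midx)
    member_set = set(members)
    F = np.empty((len(targets), g.n_sites), dtype=float)
    defined = np.empty((len(targets), g.n_sites), dtype=bool)
    with np.errstate(invalid="ignore", divide="ignore"):
        base = np.where(n_alleles > 0, alt / np.maximum(n_alleles, 1), np.nan)
    base_def = n_alleles > 0
    for ti, t in enumerate(targets):
        if t in member_set:
            d_t = g.dosage[g.accession_indices([t])[0]]
            obs_t = d_t != MISSING
            alt_l = alt - np.where(obs_t, d_t, 0)
            n_l = n_alleles - np.where(obs_t, 2, 0)
            with np.errstate(invalid="ignore", divide="ignore"):
                F[ti] = np.where(n_l > 0, alt_l / np.maximum(n_l, 1), np.nan)
            defined[ti] = n_l > 0
        else:
            F[ti] = base
            defined[ti] = base_def
    return F, defined


def estimate_block_ancestry(
    g: GenotypeMatrix,
    grid: BlockGrid,
    groups: GroupMap,
    panel_a: str,
    panel_b: str,
    targets: list[str] | None = None,
    min_sites: int = 10,
    tol: float = 1e-4,
) -> pd.DataFrame:
    """Per-block panel-A ancestry dosage for each target accession.

    Returns a targets x blocks DataFrame of q in [0, 1]; a block with fewer
    than ``min_sites`` informative sites (panel frequencies defined and
    unequal) is NaN for all targets, as is any target with no usable site in
    a block.
    """
    members_a = [a for a in groups.members(panel_a) if a in set(g.accession_ids)]
    members_b = [a for a in groups.members(panel_b) if a in set(g.accession_ids)]
    if len(members_a) < 5 or len(members_b) < 5:
        raise ValueError("reference panels need >= 5 accessions each")
    if targets is None:
        targets = list(g.accession_ids)
    FA, defA = _panel_freqs_loo(g, members_a, targets)
    FB, defB = _panel_freqs_loo(g, members_b, targets)
    FA = np.clip(FA, _EPS, 1.0 - _EPS)
    FB = np.clip(FB, _EPS, 1.0 - _EPS)
    tidx = g.accession_indices(targets)
    G = g.dosage[tidx].astype(float)
    obs = G != MISSING
    # block-level informativeness from the full panels
    alt_a, na = g.allele_counts(g.accession_indices(members_a))
    alt_b, nb = g.allele_counts(g.accession_indices(members_b))
    with np.errstate(invalid="ignore", divide="ignore"):
        fa_full = np.where(na > 0, alt_a / np.maximum(na, 1), np.nan)
        fb_full = np.where(nb > 0, alt_b / np.maximum(nb, 1), np.nan)
    informative = (na > 0) & (nb > 0) & (np.abs(fa_full - fb_full) > 1e-12)
    q_out = np.full((len(targets), grid.n_blocks), np.nan)
    for b in range(grid.n_blocks):
        sidx = grid.sites_in(b)
        if informative[sidx].sum() < min_sites:
            continue
        s = sidx[informative[sidx]]
        w = obs[:, s] & defA[:, s] & defB[:, s]  # targets x sites weights
        usable_targets = w.any(axis=1)
        if not usable_targets.any():
            continue
        fa = FA[:, s]
        fb = FB[:, s]
        gb = np.where(w, G[:, s], 0.0)

        def loglik(q: np.ndarray) -> np.ndarray:
            m = np.clip(q[:, None] * fa + (1.0 - q[:, None]) * fb, _EPS, 1.0 - _EPS)
            ll = gb * np.log(m) + (2.0 - gb) * np.log(1.0 - m)
            return np.where(w, ll, 0.0).sum(axis=1)

        lo = np.zeros(len(targets))
        hi = np.ones(len(targets))
        while (hi - lo).max() > tol:
            x1 = hi - _INVPHI * (hi - lo)
            x2 = lo + _INVPHI * (hi - lo)
            f1 = loglik(x1)
            f2 = loglik(x2)
            take_hi = f1 < f2  # maximum lies right of x1
            lo = np.where(take_hi, x1, lo)
            hi = np.where(take_hi, hi, x2)
        q = 0.5 * (lo + hi)
        q_out[usable_targets, b] = q[usable_targets]
    return pd.DataFrame(q_out, index=list(targets), columns=range(grid.n_blocks))


@dataclass
class AssociationResult:
    """Per-block association table plus the genomic-inflation factor."""

    table: pd.DataFrame
    lambda_gc: float


def associate(
    ancestry: pd.DataFrame,
    phenotype: pd.Series,
    grid: BlockGrid,
    covariates: pd.DataFrame | None = None,
) -> AssociationResult:
    """OLS of phenotype on per-block ancestry dosage with structure control.

    Each block is tested with phenotype ~ intercept + block dosage + global
    mean ancestry (+ user covariates); the reported p is the two-sided t
    test on the dosage coefficient. Blocks with constant dosage or a
    rank-deficient design are NaN. lambda is median(t^2)/median(chi^2_1).
    """
    common = [a for a in ancestry.index if a in phenotype.index and np.isfinite(phenotype[a])]
    if len(common) < 10:
        raise ValueError("need >= 10 accessions with phenotype and ancestry")
    A = ancestry.loc[common]
    y = phenotype.loc[common].to_numpy(float)
    global_anc = np.nanmean(A.to_numpy(float), axis=1)
    cov = None
    if covariates is not None:
        cov = covariates.loc[common].to_numpy(float)
    rows = []
    for b in A.columns:
        q = A[b].to_numpy(float)
        ok = np.isfinite(q)
        blk = grid.blocks[int(b)]
        out = (blk.chrom, blk.start, blk.end, np.nan, np.nan, np.nan, np.nan, int(ok.sum()))
        if ok.sum() >= 10 and np.ptp(q[ok]) > 0:
            X = np.column_stack([q[ok], global_anc[ok]])
            if cov is not None:
                X = np.column_stack([X, cov[ok]])
            X = sm.add_constant(X, has_constant="add")
            if np.linalg.matrix_rank(X) < X.shape[1]:
                warnings.warn(f"block {b}: rank-deficient design", stacklevel=2)
            else:
                fit = sm.OLS(y[ok], X).fit()
                beta, se = fit.params[1], fit.bse[1]
                t, p = fit.tvalues[1], fit.pvalues[1]
                out = (blk.chrom, blk.start, blk.end, beta, se, t, p, int(ok.sum()))
        rows.append(out)
    table = pd.DataFrame(
        rows, columns=["chrom", "start", "end", "beta", "se", "t", "p", "n"]
    )
    tvals = table["t"].to_numpy(float)
    chi2 = tvals[np.isfinite(tvals)] ** 2
    lam = float(np.median(chi2) / stats.chi2.ppf(0.5, 1)) if len(chi2) else float("nan")
    return AssociationResult(table, lam)
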