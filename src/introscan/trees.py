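"""Phylogenetic-tree introgression detection.

The genome is tiled with fixed-width blocks (500 kb by default); within each
block a pairwise allele-sharing distance matrix feeds a neighbor-joining
tree, and an accession whose whole-genome group is A but whose nearest
leaves in the block tree belong to group B is called introgressed B -> A.
Per-block call counts are tested genome-wide against a permutation null that
preserves each accession's total introgression load, giving family-wise
error control via the max-count statistic.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from skbio import TreeNode

from introscan.io import Block, BlockGrid, GenotypeMatrix, GroupMap, MISSING

__all__ = [
    "DistanceMatrix",
    "NoSharedSitesError",
    "IntrogressionCall",
    "ScanResult",
    "SignificantRegions",
    "allele_sharing_distance",
    "nj_tree",
    "patristic_distances",
    "classify_introgression",
    "scan_blocks",
    "permutation_significant_regions",
    "direction_correlation",
    "enrichment_test",
]


class NoSharedSitesError(ValueError):
    """A pair of accessions has no jointly non-missing site in the block."""


@dataclass
class DistanceMatrix:
    """Symmetric allele-sharing distance matrix with pairwise site counts.

    d(i,j) = sum_s |g_i - g_j| / (2 * n shared non-missing sites); the
    complement 1 - d is the corresponding kinship.
    """

    ids: list[str]
    d: np.ndarray
    n_sites_used: np.ndarray

    def __post_init__(self) -> None:
        self.d = np.asarray(self.d, dtype=float)
        n = len(self.ids)
        if self.d.shape != (n, n):
            raise ValueError("distance matrix shape mismatch")
        if not np.allclose(self.d, self.d.T):
            raise ValueError("distance matrix must be symmetric")
        if np.any(np.diag(self.d) != 0):
            raise ValueError("distance matrix diagonal must be zero")

    @property
    def kinship(self) -> np.ndarray:
        return 1.0 - self.d


def allele_sharing_distance(
    g: GenotypeMatrix,
    site_indices: np.ndarray | None = None,
    accession_ids: list[str] | None = None,
) -> DistanceMatrix:
    """Pairwise allele-sharing distances over jointly non-missing sites.

    Raises :class:`NoSharedSitesError` if any accession pair shares no
    non-missing site (the caller then declares the block NO_CALL).
    """
    if accession_ids is None:
        accession_ids = list(g.accession_ids)
    acc_idx = g.accession_indices(accession_ids)
    X = g.dosage[acc_idx]
    if site_indices is not None:
        X = X[:, np.asarray(site_indices)]
    X = X.astype(np.float64)
    obs = X != MISSING
    Xz = np.where(obs, X, 0.0)
    n = len(accession_ids)
    # |gi - gj| summed over shared sites; broadcast is fine at block scale
    diff = np.abs(Xz[:, None, :] - Xz[None, :, :])
    shared = obs[:, None, :] & obs[None, :, :]
    num = np.where(shared, diff, 0.0).sum(axis=2)
    cnt = shared.sum(axis=2)
    off = ~np.eye(n, dtype=bool)
    if np.any(cnt[off] == 0):
        raise NoSharedSitesError("an accession pair shares no non-missing site")
    d = np.zeros((n, n))
    d[off] = num[off] / (2.0 * cnt[off])
    return DistanceMatrix(list(accession_ids), d, cnt)


# ---------------------------------------------------------------------------
# neighbor joining


def _min_leaf_names(nodes: list[TreeNode]) -> list[str]:
    out = []
    for node in nodes:
        if node.is_tip():
            out.append(node.name)
        else:
            out.append(min(t.name for t in node.tips()))
    return out


def _pick_pair(Q: np.ndarray, labels: list[str]) -> tuple[int, int]:
    """Argmin of Q with ties broken by the lexicographically smallest
    (sorted) pair of clade labels — fully deterministic."""
    n = Q.shape[0]
    iu = np.triu_indices(n, k=1)
    vals = Q[iu]
    m = vals.min()
    ties = np.flatnonzero(np.isclose(vals, m, rtol=0, atol=1e-12) & (vals <= m + 1e-12))
    best = None
    best_key = None
    for t in ties:
        i, j = int(iu[0][t]), int(iu[1][t])
        key = tuple(sorted((labels[i], labels[j])))
        if best_key is None or key < best_key:
            best_key, best = key, (i, j)
    return best


def nj_tree(dm: DistanceMatrix) -> TreeNode:
    """Saitou-Nei neighbor joining, returned as an unrooted skbio tree.

    Exact on additive distances. Negative branch lengths are clamped to zero
    with the deficit transferred to the sister branch (so the pair's summed
    length is preserved); remaining negatives after transfer are clamped.
    Ties in the Q criterion are broken by lexicographic clade labels.
    """
    n = len(dm.ids)
    if n < 3:
        raise ValueError("neighbor joining needs at least 3 leaves")
    D = dm.d.astype(float).copy()
    nodes: list[TreeNode] = [TreeNode(name=name) for name in dm.ids]
    while len(nodes) > 3:
        m = len(nodes)
        r = D.sum(axis=1)
        Q = (m - 2) * D - r[:, None] - r[None, :]
        np.fill_diagonal(Q, np.inf)
        i, j = _pick_pair(Q, _min_leaf_names(nodes))
        li = 0.5 * D[i, j] + (r[i] - r[j]) / (2.0 * (m - 2))
        lj = D[i, j] - li
        li, lj = _clamp_pair(li, lj)
        parent = TreeNode()
        nodes[i].length = li
        nodes[j].length = lj
        parent.append(nodes[i])
        parent.append(nodes[j])
        dnew = 0.5 * (D[i, :] + D[j, :] - D[i, j])
        keep = [k for k in range(m) if k not in (i, j)]
        D2 = np.empty((m - 1, m - 1))
        D2[:-1, :-1] = D[np.ix_(keep, keep)]
        D2[-1, :-1] = dnew[keep]
        D2[:-1, -1] = dnew[keep]
        D2[-1, -1] = 0.0
        D = D2
        nodes = [nodes[k] for k in keep] + [parent]
    # final three nodes around the central vertex (closed form)
    a, b, c = 0, 1, 2
    la = max(0.5 * (D[a, b] + D[a, c] - D[b, c]), 0.0)
    lb = max(0.5 * (D[a, b] + D[b, c] - D[a, c]), 0.0)
    lc = max(0.5 * (D[a, c] + D[b, c] - D[a, b]), 0.0)
    root = TreeNode()
    for node, length in zip(nodes, (la, lb, lc)):
        node.length = length
        root.append(node)
    return root


def _clamp_pair(li: float, lj: float) -> tuple[float, float]:
    if li < 0:
        lj += li
        li = 0.0
    if lj < 0:
        li += lj
        lj = 0.0
    return max(li, 0.0), max(lj, 0.0)


def patristic_distances(tree: TreeNode) -> tuple[list[str], np.ndarray]:
    """Leaf ids and the matrix of path-length (patristic) distances."""
    dm = tree.tip_tip_distances()
    return list(dm.ids), np.asarray(dm.data, dtype=float)


# ---------------------------------------------------------------------------
# introgression classification


@dataclass(frozen=True)
class IntrogressionCall:
    accession: str
    block: Block
    recipient_group: str
    donor_group: str


def classify_introgression(
    tree: TreeNode,
    groups: GroupMap,
    recipient: str,
    donor: str,
    k: int | None = None,
) -> set[str]:
    """Accessions of ``recipient`` that cluster with ``donor`` in the tree.

    An accession is called introgressed iff (i) strictly more than k/2 of
    its k nearest non-self leaves by patristic distance — restricted to
    donor and recipient members — belong to the donor group, and (ii) its
    mean patristic distance to the donor group is strictly smaller than to
    the rest of its own group (the displacement condition). Condition (ii)
    suppresses the mirror-image artifact of a pure nearest-neighbour rule:
    a donor-group accession surrounded by true carriers (which are
    genuinely donor-like inside the block) still sits close to its own
    group core and must not be called in the reverse direction. Distance
    ties are broken by leaf name, so the rule is deterministic. k defaults
    to min(5, donor group size in tree).
    """
    ids, pd_mat = patristic_distances(tree)
    return _classify_from_patristic(ids, pd_mat, groups, recipient, donor, k)


def _classify_from_patristic(
    ids: list[str],
    pd_mat: np.ndarray,
    groups: GroupMap,
    recipient: str,
    donor: str,
    k: int | None = None,
) -> set[str]:
    donor_leaves = [x for x in ids if x in groups and groups.group_of(x) == donor]
    rec_leaves = [x for x in ids if x in groups and groups.group_of(x) == recipient]
    if k is None:
        k = min(5, len(donor_leaves))
    if len(donor_leaves) < k or len(rec_leaves) < 2:
        raise ValueError(
            f"tree needs >= {k} {donor!r} and >= 2 {recipient!r} leaves "
            f"(found {len(donor_leaves)} and {len(rec_leaves)})"
        )
    pos = {x: i for i, x in enumerate(ids)}
    candidates = sorted(donor_leaves + rec_leaves)
    is_donor = {x: (x in set(donor_leaves)) for x in candidates}
    calls: set[str] = set()
    donor_idx = [pos[c] for c in donor_leaves]
    for x in rec_leaves:
        neigh = [c for c in candidates if c != x]
        neigh.sort(key=lambda c: (pd_mat[pos[x], pos[c]], c))
        donor_count = sum(is_donor[c] for c in neigh[:k])
        if 2 * donor_count <= k:
            continue
        own_idx = [pos[c] for c in rec_leaves if c != x]
        mean_donor = pd_mat[pos[x], donor_idx].mean()
        mean_own = pd_mat[pos[x], own_idx].mean()
        if mean_donor < mean_own:
            calls.add(x)
    return calls


# ---------------------------------------------------------------------------
# genome scan


@dataclass
class ScanResult:
    """Per-block introgression calls for a set of ordered (donor, recipient)
    group pairs, plus the NO_CALL mask for blocks lacking polymorphism."""

    grid: BlockGrid
    groups: GroupMap
    pairs: list[tuple[str, str]]
    no_call: np.ndarray
    calls: dict[tuple[str, str], pd.DataFrame] = field(default_factory=dict)
    trees: dict[int, str] = field(default_factory=dict)

    def counts(self, pair: tuple[str, str]) -> np.ndarray:
        """Per-block introgressed-accession counts (0 at NO_CALL blocks)."""
        return self.calls[pair].to_numpy().sum(axis=0)

    @property
    def called_blocks(self) -> np.ndarray:
        return np.flatnonzero(~self.no_call)

    def calls_table(self) -> pd.DataFrame:
        rows = []
        for (donor, recipient), mat in self.calls.items():
            for acc in mat.index:
                for b in np.flatnonzero(mat.loc[acc].to_numpy()):
                    blk = self.grid.blocks[int(b)]
                    rows.append(
                        (acc, blk.chrom, blk.start, blk.end, donor, recipient)
                    )
        return pd.DataFrame(
            rows,
            columns=["accession", "chrom", "start", "end", "donor", "recipient"],
        )

    def counts_table(self) -> pd.DataFrame:
        rows = []
        for pair in self.pairs:
            counts = self.counts(pair)
            for b in self.grid.blocks:
                rows.append(
                    (
                        b.chrom,
                        b.start,
                        b.end,
                        f"{pair[0]}->{pair[1]}",
                        int(counts[b.index]),
                        bool(self.no_call[b.index]),
                    )
                )
        return pd.DataFrame(
            rows, columns=["chrom", "start", "end", "pair", "count", "no_call"]
        )


def _polymorphic_count(X: np.ndarray) -> int:
    obs = X != MISSING
    any_obs = obs.any(axis=0)
    with np.errstate(invalid="ignore"):
        mx = np.where(obs, X, -10).max(axis=0)
        mn = np.where(obs, X, 10).min(axis=0)
    return int((any_obs & (mx != mn)).sum())


def scan_blocks(
    g: GenotypeMatrix,
    grid: BlockGrid,
    groups: GroupMap,
    pairs: list[tuple[str, str]],
    min_snps: int = 10,
    k: int | None = None,
    write_trees: bool = False,
) -> ScanResult:
    """Run distance -> NJ -> classification for every block and ordered pair.

    Blocks with fewer than ``min_snps`` polymorphic sites (or with an
    accession pair sharing no site) are NO_CALL and emit no calls. ``pairs``
    are ordered (donor, recipient) tuples; the tree for a block is built once
    over the union of all groups named in ``pairs``.
    """
    used_groups = sorted({grp for pair in pairs for grp in pair})
    accessions = [a for a in g.accession_ids if a in groups and groups.group_of(a) in used_groups]
    if len(accessions) < 3:
        raise ValueError("need at least 3 accessions across the scanned groups")
    no_call = np.zeros(grid.n_blocks, dtype=bool)
    calls = {
        pair: pd.DataFrame(
            False,
            index=groups.members(pair[1]),
            columns=range(grid.n_blocks),
            dtype=bool,
        )
        for pair in pairs
    }
    trees: dict[int, str] = {}
    acc_idx = g.accession_indices(accessions)
    for b in range(grid.n_blocks):
        site_idx = grid.sites_in(b)
        if len(site_idx) == 0:
            no_call[b] = True
            continue
        X = g.dosage[np.ix_(acc_idx, site_idx)]
        if _polymorphic_count(X) < min_snps:
            no_call[b] = True
            continue
        try:
            dm = allele_sharing_distance(g, site_idx, accessions)
        except NoSharedSitesError:
            no_call[b] = True
            continue
        tree = nj_tree(dm)
        if write_trees:
            trees[b] = str(tree)
        ids, pd_mat = patristic_distances(tree)
        for donor, recipient in pairs:
            called = _classify_from_patristic(ids, pd_mat, groups, recipient, donor, k)
            for acc in called:
                calls[(donor, recipient)].loc[acc, b] = True
    return ScanResult(grid, groups, list(pairs), no_call, calls, trees)


# ---------------------------------------------------------------------------
# permutation null


@dataclass
class SignificantRegions:
    regions: list[tuple[str, int, int]]
    threshold: float
    pvalues: pd.Series  # indexed by called block index
    significant_blocks: np.ndarray
    n_perm: int
    alpha: float


def permutation_significant_regions(
    scan: ScanResult,
    pair: tuple[str, str],
    n_perm: int = 1000,
    alpha: float = 0.05,
    seed: int = 0,
) -> SignificantRegions:
    """Max-count permutation test for blocks with excess introgression.

    The null permutes, independently for each recipient accession, its
    per-block call vector across all called blocks, preserving the
    accession's genome-wide introgression total. The genome-wide reference
    distribution is the max per-block count over permutations; a block is
    significant when (1 + #{perm max >= observed}) / (n_perm + 1) <= alpha.
    Contiguous significant blocks merge into regions.
    """
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100")
    if alpha < 1.0 / n_perm:
        raise ValueError(f"alpha={alpha} unattainable with n_perm={n_perm}")
    called = scan.called_blocks
    if len(called) == 0:
        raise ValueError("no called block to test")
    C = scan.calls[pair].to_numpy()[:, called]  # recipients x called blocks
    observed = C.sum(axis=0)
    rng = np.random.default_rng(seed)
    n_rec, n_blk = C.shape
    tiled = np.broadcast_to(C, (n_perm, n_rec, n_blk)).copy()
    permuted = rng.permuted(tiled, axis=2)
    max_null = permuted.sum(axis=1).max(axis=1)  # (n_perm,)
    pvals = (1 + (max_null[:, None] >= observed[None, :]).sum(axis=0)) / (n_perm + 1)
    sig_mask = pvals <= alpha
    threshold = float(np.quantile(max_null, 1.0 - alpha))
    sig_blocks = called[sig_mask]
    regions = merge_blocks([scan.grid.blocks[int(b)] for b in sig_blocks])
    return SignificantRegions(
        regions,
        threshold,
        pd.Series(pvals, index=called),
        sig_blocks,
        n_perm,
        alpha,
    )


def merge_blocks(blocks: list[Block]) -> list[tuple[str, int, int]]:
    """Merge grid-adjacent blocks (same chromosome, consecutive indices)."""
    regions: list[tuple[str, int, int]] = []
    for b in sorted(blocks, key=lambda x: x.index):
        if regions and regions[-1][0] == b.chrom and b.start <= regions[-1][2]:
            regions[-1] = (b.chrom, regions[-1][1], max(regions[-1][2], b.end))
        else:
            regions.append((b.chrom, b.start, b.end))
    return regions


# ---------------------------------------------------------------------------
# direction correlation and annotation enrichment


@dataclass
class DirectionCorrelation:
    r: float | None
    p: float | None
    slope: float | None
    intercept: float | None
    n_blocks: int
    reason: str | None = None


def direction_correlation(
    scan: ScanResult,
    pair_forward: tuple[str, str],
    pair_reverse: tuple[str, str] | None = None,
) -> DirectionCorrelation:
    """Pearson correlation and OLS slope between the two directions'
    per-block counts over called blocks."""
    if pair_reverse is None:
        pair_reverse = (pair_forward[1], pair_forward[0])
    called = scan.called_blocks
    if len(called) < 3:
        raise ValueError("need >= 3 called blocks")
    x = scan.counts(pair_forward)[called].astype(float)
    y = scan.counts(pair_reverse)[called].astype(float)
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return DirectionCorrelation(
            None, None, None, None, len(called), reason="zero variance"
        )
    r, p = stats.pearsonr(x, y)
    fit = stats.linregress(x, y)
    return DirectionCorrelation(float(r), float(p), float(fit.slope), float(fit.intercept), len(called))


@dataclass
class EnrichmentResult:
    table: np.ndarray
    statistic: float | None
    p: float | None
    reason: str | None = None


def enrichment_test(
    scan: ScanResult,
    pair: tuple[str, str],
    annotation: list[tuple[str, int, int]],
) -> EnrichmentResult:
    """Pearson chi-square (1 df, no continuity correction) for enrichment of
    introgression calls in annotated blocks.

    The 2x2 table crosses (calls, non-calls) with (blocks overlapping the
    annotation, other blocks), over called blocks only; a block overlaps when
    any base pair intersects.
    """
    called = scan.called_blocks
    counts = scan.counts(pair)
    n_rec = len(scan.calls[pair].index)
    in_annot = np.zeros(scan.grid.n_blocks, dtype=bool)
    for chrom, start, end in annotation:
        for b in scan.grid.blocks:
            if b.overlaps(chrom, start, end):
                in_annot[b.index] = True
    a = int(counts[called][in_annot[called]].sum())
    bq = int(counts[called][~in_annot[called]].sum())
    c = int((n_rec - counts[called][in_annot[called]]).sum())
    d = int((n_rec - counts[called][~in_annot[called]]).sum())
    table = np.array([[a, bq], [c, d]], dtype=float)
    if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
        return EnrichmentResult(table, None, None, reason="zero margin")
    chi2, p, _, _ = stats.chi2_contingency(table, correction=False)
    return EnrichmentResult(table, float(chi2), float(p))
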