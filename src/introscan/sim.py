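"""Synthetic multi-group genotype datasets with planted introgression tracts.

The generator follows the Balding-Nichols model on a fixed two-level
population tree: subpopulation allele frequencies are Beta-distributed around
an ancestral frequency with a per-branch drift parameter F, and nested
divergence (e.g. temperate vs tropical japonica inside a japonica branch) is
obtained by drawing the subgroup frequencies from the branch frequency rather
than from the root. Introgression is planted as whole-tract dosage
replacement — the selected recipient accessions' genotypes inside the tract
are redrawn from the donor group's allele frequencies, emulating a homozygous
introgressed segment.

There is no linkage disequilibrium beyond the tract structure itself and no
recombination: the downstream tree and D-statistic methods operate on
frequencies and distances and do not require realistic LD.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from introscan.io import Block, BlockGrid, GenotypeMatrix, GroupMap, MISSING

__all__ = [
    "SimulationConfig",
    "PlantedTract",
    "SimulatedDataset",
    "simulate_frequencies",
    "simulate_genotypes",
    "plant_introgression",
    "simulate_phenotype",
    "simulate_dataset",
    "truth_ancestry",
    "default_config",
]

#: Default panel: an African-rice-like outgroup, indica, and the two japonica
#: subgroups hanging off a shared japonica branch.
DEFAULT_GROUPS = ("african", "indica", "temperate_japonica", "tropical_japonica")
DEFAULT_FST = {
    "african": 0.5,
    "indica": 0.15,
    "japonica": 0.15,
    "temperate_japonica": 0.05,
    "tropical_japonica": 0.05,
}
DEFAULT_SUBTREES = {"japonica": ("temperate_japonica", "tropical_japonica")}

_FREQ_EPS = 1e-9


@dataclass
class SimulationConfig:
    """Parameters of the Balding-Nichols population simulation.

    ``fst_branch`` maps each leaf group — and each internal branch named in
    ``subtrees`` — to its drift parameter F in (0, 1). ``subtrees`` maps an
    internal branch name to the leaf groups drawn from it; groups not under
    any internal branch drift directly from the root.
    """

    n_per_group: dict[str, int] = field(
        default_factory=lambda: {g: 40 for g in DEFAULT_GROUPS}
    )
    n_chromosomes: int = 3
    chrom_length_bp: int = 5_000_000
    n_sites_per_chrom: int = 2_500
    fst_branch: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_FST))
    ancestral_beta: tuple[float, float] = (0.8, 0.8)
    missing_rate: float = 0.02
    seed: int = 0
    subtrees: dict[str, tuple[str, ...]] = field(
        default_factory=lambda: {k: tuple(v) for k, v in DEFAULT_SUBTREES.items()}
    )

    def __post_init__(self) -> None:
        if not self.n_per_group:
            raise ValueError("n_per_group must not be empty")
        for g, n in self.n_per_group.items():
            if n < 2:
                raise ValueError(f"group {g!r} needs >= 2 accessions, got {n}")
        branch_names = set(self.n_per_group) | set(self.subtrees)
        for name in branch_names:
            if name not in self.fst_branch:
                raise ValueError(f"no drift parameter F for branch {name!r}")
        for name, f in self.fst_branch.items():
            if not (0.0 < f < 1.0):
                raise ValueError(f"F for {name!r} must be strictly in (0,1), got {f}")
        if self.n_sites_per_chrom < 1:
            raise ValueError("n_sites_per_chrom must be >= 1")
        if self.n_sites_per_chrom > self.chrom_length_bp:
            raise ValueError("more sites than base pairs on a chromosome")
        if not (0.0 <= self.missing_rate < 1.0):
            raise ValueError("missing_rate must be in [0, 1)")
        a, b = self.ancestral_beta
        if a <= 0 or b <= 0:
            raise ValueError("ancestral_beta shapes must be positive")
        for branch, children in self.subtrees.items():
            for child in children:
                if child not in self.n_per_group:
                    raise ValueError(f"subtree {branch!r} names unknown group {child!r}")

    @property
    def groups(self) -> list[str]:
        return list(self.n_per_group)

    @property
    def n_sites(self) -> int:
        return self.n_chromosomes * self.n_sites_per_chrom

    def accession_ids(self) -> list[str]:
        return [f"{g}_{i:03d}" for g in self.n_per_group for i in range(self.n_per_group[g])]

    def group_map(self) -> GroupMap:
        return GroupMap(
            {f"{g}_{i:03d}": g for g in self.n_per_group for i in range(self.n_per_group[g])},
            list(self.n_per_group),
        )

    def chrom_lengths(self) -> dict[str, int]:
        return {f"chr{c + 1}": self.chrom_length_bp for c in range(self.n_chromosomes)}


@dataclass
class PlantedTract:
    """Ground-truth introgression tract copied from a donor group into a
    subset of one recipient group's accessions."""

    chrom: str
    start_bp: int
    end_bp: int
    donor_group: str
    recipient_group: str
    recipient_accessions: tuple[str, ...] = ()
    replacement_fraction: float = 0.3

    def __post_init__(self) -> None:
        if self.end_bp <= self.start_bp:
            raise ValueError("tract end must exceed start")
        if self.donor_group == self.recipient_group:
            raise ValueError("donor and recipient group must differ")
        if not (0.0 <= self.replacement_fraction <= 1.0):
            raise ValueError("replacement_fraction must be in [0, 1]")

    def site_mask(self, sites: pd.DataFrame) -> np.ndarray:
        pos0 = sites["pos"].to_numpy() - 1
        return (
            (sites["chrom"].to_numpy() == self.chrom)
            & (pos0 >= self.start_bp)
            & (pos0 < self.end_bp)
        )


@dataclass
class SimulatedDataset:
    """A simulated genotype matrix plus everything needed to score detectors."""

    genotypes: GenotypeMatrix
    groups: GroupMap
    truth_tracts: list[PlantedTract]
    frequencies: dict[str, np.ndarray]
    config: SimulationConfig
    phenotypes: pd.Series | None = None
    causal_block: Block | None = None

    def __post_init__(self) -> None:
        if (self.phenotypes is None) != (self.causal_block is None):
            raise ValueError("phenotypes and causal_block must be supplied together")


def _bn_draw(rng: np.random.Generator, p: np.ndarray, f: float) -> np.ndarray:
    """One Balding-Nichols drift step: Beta(p(1-F)/F, (1-p)(1-F)/F) per site."""
    p = np.clip(p, _FREQ_EPS, 1.0 - _FREQ_EPS)
    scale = (1.0 - f) / f
    return rng.beta(p * scale, (1.0 - p) * scale)


def simulate_frequencies(config: SimulationConfig) -> dict[str, np.ndarray]:
    """Per-group per-site allele frequencies under the nested drift model.

    Returns a dict mapping each leaf group to a length-``config.n_sites``
    frequency array; the ancestral frequencies are included under the key
    ``"__ancestral__"`` and internal branches under their branch names.
    """
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 0]))
    a, b = config.ancestral_beta
    p_anc = rng.beta(a, b, size=config.n_sites)
    freqs: dict[str, np.ndarray] = {"__ancestral__": p_anc}
    child_to_branch = {
        child: branch for branch, children in config.subtrees.items() for child in children
    }
    # internal branches first (deterministic order: sorted names)
    for branch in sorted(config.subtrees):
        freqs[branch] = _bn_draw(rng, p_anc, config.fst_branch[branch])
    for group in config.n_per_group:
        parent = freqs.get(child_to_branch.get(group, "__ancestral__"), p_anc)
        freqs[group] = _bn_draw(rng, parent, config.fst_branch[group])
    return freqs


def simulate_genotypes(
    freqs: dict[str, np.ndarray], config: SimulationConfig
) -> GenotypeMatrix:
    """Draw diploid dosages Binomial(2, p_group) and sprinkle missing calls.

    Site positions are uniform without replacement on each chromosome; the
    two alleles are written as A (ref) / T (alt).
    """
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 1]))
    rows = []
    for c in range(config.n_chromosomes):
        pos = np.sort(
            rng.choice(config.chrom_length_bp, size=config.n_sites_per_chrom, replace=False)
        )
        for p in pos:
            rows.append((f"chr{c + 1}", int(p) + 1, "A", "T"))
    sites = pd.DataFrame(rows, columns=["chrom", "pos", "ref", "alt"])
    n_acc = sum(config.n_per_group.values())
    dosage = np.empty((n_acc, config.n_sites), dtype=np.int8)
    row = 0
    for group, n in config.n_per_group.items():
        p = np.clip(freqs[group], 0.0, 1.0)
        dosage[row : row + n] = rng.binomial(2, p, size=(n, config.n_sites)).astype(np.int8)
        row += n
    if config.missing_rate > 0:
        miss = rng.random(dosage.shape) < config.missing_rate
        dosage[miss] = MISSING
    return GenotypeMatrix(config.accession_ids(), sites, dosage)


def plant_introgression(
    genotypes: GenotypeMatrix,
    tracts: list[PlantedTract],
    freqs: dict[str, np.ndarray],
    groups: GroupMap,
    seed: int = 0,
) -> tuple[GenotypeMatrix, list[PlantedTract]]:
    """Plant introgression tracts by whole-tract dosage replacement.

    For every carrier accession, dosages at all sites inside the tract are
    replaced by fresh Binomial(2, p_donor) draws from the donor group's
    frequencies (missing calls inside the tract are preserved). Tracts whose
    ``recipient_accessions`` is empty have carriers sampled from the
    recipient group at ``replacement_fraction``. Returns the modified matrix
    and the tracts with carriers filled in.
    """
    rng = np.random.default_rng(np.random.SeedSequence([seed, 2]))
    dosage = genotypes.dosage.copy()
    resolved: list[PlantedTract] = []
    for tract in tracts:
        if tract.donor_group not in freqs:
            raise ValueError(f"unknown donor group {tract.donor_group!r}")
        carriers = tuple(tract.recipient_accessions)
        if not carriers:
            members = groups.members(tract.recipient_group)
            n_carry = int(round(tract.replacement_fraction * len(members)))
            carriers = tuple(
                sorted(rng.choice(members, size=n_carry, replace=False))
            )
        for acc in carriers:
            if groups.group_of(acc) != tract.recipient_group:
                raise ValueError(
                    f"carrier {acc!r} is not in recipient group {tract.recipient_group!r}"
                )
        site_idx = np.flatnonzero(tract.site_mask(genotypes.sites))
        if len(site_idx) == 0:
            warnings.warn(
                f"tract {tract.chrom}:{tract.start_bp}-{tract.end_bp} overlaps no sites",
                stacklevel=2,
            )
        else:
            p_donor = np.clip(freqs[tract.donor_group][site_idx], 0.0, 1.0)
            acc_idx = genotypes.accession_indices(carriers)
            for i in acc_idx:
                missing = dosage[i, site_idx] == MISSING
                fresh = rng.binomial(2, p_donor).astype(np.int8)
                fresh[missing] = MISSING
                dosage[i, site_idx] = fresh
        resolved.append(
            PlantedTract(
                tract.chrom,
                tract.start_bp,
                tract.end_bp,
                tract.donor_group,
                tract.recipient_group,
                carriers,
                tract.replacement_fraction,
            )
        )
    out = GenotypeMatrix(list(genotypes.accession_ids), genotypes.sites.copy(), dosage)
    return out, resolved


def truth_ancestry(
    tracts: list[PlantedTract],
    grid: BlockGrid,
    accession_ids: list[str],
    donor_group: str | None = None,
) -> pd.DataFrame:
    """Accessions x blocks ground-truth donor-ancestry dosage (0/1).

    A block scores 1 for an accession when a planted tract (optionally
    restricted to ``donor_group``) overlaps the block and the accession is a
    carrier.
    """
    z = np.zeros((len(accession_ids), grid.n_blocks), dtype=float)
    lookup = {a: i for i, a in enumerate(accession_ids)}
    for tract in tracts:
        if donor_group is not None and tract.donor_group != donor_group:
            continue
        for b in grid.blocks:
            if b.overlaps(tract.chrom, tract.start_bp, tract.end_bp):
                for acc in tract.recipient_accessions:
                    if acc in lookup:
                        z[lookup[acc], b.index] = 1.0
    return pd.DataFrame(z, index=list(accession_ids), columns=range(grid.n_blocks))


def simulate_phenotype(
    ancestry_truth: pd.DataFrame,
    causal_block: int | Block,
    effect_size: float,
    noise_sd: float,
    seed: int = 0,
    confound_coef: float = 0.5,
) -> pd.Series:
    """Quantitative phenotype driven by local ancestry at one causal block.

    phenotype = effect_size * z(causal block)
              + confound_coef * mean ancestry across the genome (a global
                population-structure confounder)
              + Normal(0, noise_sd).
    """
    rng = np.random.default_rng(np.random.SeedSequence([seed, 3]))
    idx = causal_block.index if isinstance(causal_block, Block) else int(causal_block)
    if idx not in ancestry_truth.columns:
        raise ValueError(f"causal block {idx} not in ancestry matrix")
    z = ancestry_truth[idx].to_numpy(float)
    global_anc = ancestry_truth.to_numpy(float).mean(axis=1)
    y = (
        effect_size * z
        + confound_coef * global_anc
        + rng.normal(0.0, noise_sd, size=len(z))
    )
    return pd.Series(y, index=ancestry_truth.index, name="phenotype")


def default_config(**overrides) -> SimulationConfig:
    """The default desk-scale study configuration (4 groups x 40 accessions,
    3 chromosomes x 5 Mb x 2500 sites)."""
    return SimulationConfig(**overrides)


def simulate_dataset(
    config: SimulationConfig,
    tracts: list[PlantedTract] | None = None,
    causal_block: Block | None = None,
    grid: BlockGrid | None = None,
    effect_size: float = 1.0,
    noise_sd: float = 1.0,
    confound_coef: float = 0.5,
) -> SimulatedDataset:
    """Run the full generator: frequencies -> genotypes -> planted tracts
    (-> phenotype if a causal block is given)."""
    freqs = simulate_frequencies(config)
    geno = simulate_genotypes(freqs, config)
    groups = config.group_map()
    resolved: list[PlantedTract] = []
    if tracts:
        geno, resolved = plant_introgression(geno, tracts, freqs, groups, seed=config.seed)
    pheno = None
    if causal_block is not None:
        if grid is None:
            raise ValueError("a BlockGrid is required to simulate a phenotype")
        donor = resolved[0].donor_group if resolved else None
        truth = truth_ancestry(resolved, grid, geno.accession_ids, donor)
        pheno = simulate_phenotype(
            truth,
            causal_block,
            effect_size=effect_size,
            noise_sd=noise_sd,
            seed=config.seed,
            confound_coef=confound_coef,
        )
    return SimulatedDataset(geno, groups, resolved, freqs, config, pheno, causal_block)
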