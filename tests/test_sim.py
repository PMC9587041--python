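import numpy as np
import pytest

from introscan.io import MISSING, slice_blocks
from introscan.sim import (
    PlantedTract,
    SimulationConfig,
    plant_introgression,
    simulate_dataset,
    simulate_frequencies,
    simulate_genotypes,
    simulate_phenotype,
    truth_ancestry,
)
from introscan.trees import allele_sharing_distance


def two_group_config(**kw):
    base = dict(
        n_per_group={"a": 10, "b": 10},
        fst_branch={"a": 0.2, "b": 0.2},
        subtrees={},
        n_chromosomes=1,
        chrom_length_bp=1_000_000,
        n_sites_per_chrom=500,
        missing_rate=0.0,
        seed=11,
    )
    base.update(kw)
    return SimulationConfig(**base)


class TestConfigValidation:
    @pytest.mark.parametrize("bad_f", [0.0, 1.0, -0.2, 1.5])
    def test_f_outside_open_interval_rejected(self, bad_f):
        with pytest.raises(ValueError, match="strictly in"):
            two_group_config(fst_branch={"a": bad_f, "b": 0.2})

    def test_tiny_group_rejected(self):
        with pytest.raises(ValueError, match=">= 2"):
            two_group_config(n_per_group={"a": 1, "b": 10})

    def test_tract_validation(self):
        with pytest.raises(ValueError):
            PlantedTract("chr1", 100, 100, "a", "b")
        with pytest.raises(ValueError):
            PlantedTract("chr1", 0, 100, "a", "a")


class TestFrequencies:
    def test_no_drift_limit(self):
        cfg = two_group_config(fst_branch={"a": 1e-4, "b": 1e-4})
        freqs = simulate_frequencies(cfg)
        anc = freqs["__ancestral__"]
        assert np.max(np.abs(freqs["a"] - anc)) < 0.05
        assert np.mean(np.abs(freqs["a"] - anc)) < 0.01

    def test_extreme_drift_fixes_sites(self):
        cfg = two_group_config(
            fst_branch={"a": 0.99, "b": 0.99}, n_sites_per_chrom=10_000,
            chrom_length_bp=10_000_000,
        )
        freqs = simulate_frequencies(cfg)
        extreme = np.mean((freqs["a"] < 0.01) | (freqs["a"] > 0.99))
        assert extreme > 0.9

    def test_deterministic_under_seed(self):
        cfg = two_group_config()
        f1 = simulate_frequencies(cfg)
        f2 = simulate_frequencies(cfg)
        for key in f1:
            assert np.array_equal(f1[key], f2[key])

    def test_nested_groups_track_branch_not_root(self):
        cfg = SimulationConfig(
            n_per_group={"u": 5, "v": 5},
            fst_branch={"u": 0.01, "v": 0.01, "branch": 0.4},
            subtrees={"branch": ("u", "v")},
            n_chromosomes=1,
            chrom_length_bp=1_000_000,
            n_sites_per_chrom=2_000,
            seed=3,
        )
        freqs = simulate_frequencies(cfg)
        to_branch = np.mean(np.abs(freqs["u"] - freqs["branch"]))
        to_root = np.mean(np.abs(freqs["u"] - freqs["__ancestral__"]))
        assert to_branch < to_root


class TestGenotypes:
    def test_fixed_site_dosage(self):
        cfg = two_group_config(missing_rate=0.2)
        freqs = simulate_frequencies(cfg)
        freqs["a"][:] = 1.0
        g = simulate_genotypes(freqs, cfg)
        a_rows = g.dosage[:10]
        assert np.all(a_rows[a_rows != MISSING] == 2)

    def test_no_missing_when_rate_zero(self):
        cfg = two_group_config(missing_rate=0.0)
        g = simulate_genotypes(simulate_frequencies(cfg), cfg)
        assert not np.any(g.dosage == MISSING)

    def test_sample_frequency_tracks_population(self):
        cfg = SimulationConfig(
            n_per_group={"a": 2000},
            fst_branch={"a": 0.2},
            subtrees={},
            n_chromosomes=1,
            chrom_length_bp=10_000,
            n_sites_per_chrom=50,
            missing_rate=0.0,
            seed=13,
        )
        freqs = simulate_frequencies(cfg)
        freqs["a"][:] = 0.5
        g = simulate_genotypes(freqs, cfg)
        sample_freq = g.dosage.mean(axis=0) / 2.0
        assert np.all(np.abs(sample_freq - 0.5) < 0.03)

    def test_positions_unique_and_bit_identical(self):
        cfg = two_group_config()
        g1 = simulate_genotypes(simulate_frequencies(cfg), cfg)
        g2 = simulate_genotypes(simulate_frequencies(cfg), cfg)
        assert np.array_equal(g1.dosage, g2.dosage)
        pos = g1.sites["pos"].to_numpy()
        assert len(np.unique(pos)) == len(pos)
        assert pos.max() <= cfg.chrom_length_bp


class TestPlanting:
    def test_zero_fraction_leaves_genotypes_unchanged(self):
        cfg = two_group_config()
        freqs = simulate_frequencies(cfg)
        g = simulate_genotypes(freqs, cfg)
        tract = PlantedTract("chr1", 0, 500_000, "a", "b", replacement_fraction=0.0)
        g2, resolved = plant_introgression(g, [tract], freqs, cfg.group_map(), seed=1)
        assert np.array_equal(g.dosage, g2.dosage)
        assert resolved[0].recipient_accessions == ()

    def test_fixed_difference_replacement(self):
        cfg = two_group_config(n_sites_per_chrom=10, chrom_length_bp=1_000)
        freqs = simulate_frequencies(cfg)
        freqs["a"][:] = 1.0
        freqs["b"][:] = 0.0
        g = simulate_genotypes(freqs, cfg)
        carriers = ("b_000", "b_001")
        tract = PlantedTract("chr1", 0, 1_000, "a", "b", recipient_accessions=carriers)
        g2, _ = plant_introgression(g, [tract], freqs, cfg.group_map(), seed=1)
        idx = g2.accession_indices(carriers)
        assert np.all(g2.dosage[idx] == 2)

    def test_tract_with_no_sites_warns(self):
        cfg = two_group_config(n_sites_per_chrom=10, chrom_length_bp=10_000_000)
        freqs = simulate_frequencies(cfg)
        g = simulate_genotypes(freqs, cfg)
        lo = int(g.sites["pos"].max()) + 10
        tract = PlantedTract("chr1", lo, lo + 5, "a", "b", replacement_fraction=0.5)
        with pytest.warns(UserWarning, match="no sites"):
            g2, resolved = plant_introgression(g, [tract], freqs, cfg.group_map(), seed=1)
        assert np.array_equal(g.dosage, g2.dosage)
        assert len(resolved) == 1

    def test_carriers_closer_to_donor_inside_tract(self, planted_dataset):
        ds = planted_dataset
        tract = ds.truth_tracts[0]
        sites = np.flatnonzero(tract.site_mask(ds.genotypes.sites))
        dm = allele_sharing_distance(ds.genotypes, sites)
        pos = {a: i for i, a in enumerate(dm.ids)}
        donors = [pos[a] for a in ds.groups.members("indica")]
        own = [
            pos[a]
            for a in ds.groups.members("tropical_japonica")
            if a not in set(tract.recipient_accessions)
        ]
        for acc in tract.recipient_accessions:
            i = pos[acc]
            assert dm.d[i, donors].mean() < dm.d[i, own].mean()


class TestPhenotype:
    @pytest.fixture()
    def truth(self, planted_dataset, tree_grid):
        ds = planted_dataset
        grid = slice_blocks(ds.genotypes.sites, 200_000, ds.config.chrom_lengths())
        return truth_ancestry(ds.truth_tracts, grid, ds.genotypes.accession_ids, "indica")

    def test_zero_effect_uncorrelated(self, truth):
        ph = simulate_phenotype(truth, 10, 0.0, 1.0, seed=4, confound_coef=0.0)
        z = truth[10].to_numpy()
        r = np.corrcoef(ph.to_numpy(), z)[0, 1]
        assert abs(r) < 0.2

    def test_noiseless_affine(self, truth):
        ph = simulate_phenotype(truth, 10, 2.0, 0.0, seed=4, confound_coef=0.0)
        z = truth[10].to_numpy()
        # ancestry truth for a single tract is block-wise proportional to z
        assert abs(np.corrcoef(ph.to_numpy(), z)[0, 1] - 1.0) < 1e-12

    def test_variance_decomposition_regime(self, planted_dataset):
        ds = planted_dataset
        grid = slice_blocks(ds.genotypes.sites, 200_000, ds.config.chrom_lengths())
        rng = np.random.default_rng(0)
        z = rng.binomial(1, 0.3, size=300).astype(float)
        import pandas as pd

        truth = pd.DataFrame({0: z}, index=[f"t{i}" for i in range(300)])
        ph = simulate_phenotype(truth, 0, 1.0, 1.0, seed=9, confound_coef=0.0)
        r2 = np.corrcoef(ph.to_numpy(), z)[0, 1] ** 2
        assert 0.1 < r2 < 0.9


class TestDatasetAssembly:
    def test_dataset_deterministic(self):
        cfg = SimulationConfig(seed=21)
        tract = PlantedTract(
            "chr1", 2_000_000, 2_500_000, "indica", "tropical_japonica",
            replacement_fraction=0.3,
        )
        d1 = simulate_dataset(cfg, [tract])
        d2 = simulate_dataset(cfg, [tract])
        assert np.array_equal(d1.genotypes.dosage, d2.genotypes.dosage)
        assert d1.truth_tracts[0].recipient_accessions == d2.truth_tracts[0].recipient_accessions

    def test_truth_tracts_indexable_on_grid(self, planted_dataset, tree_grid):
        truth = truth_ancestry(
            planted_dataset.truth_tracts,
            tree_grid,
            planted_dataset.genotypes.accession_ids,
        )
        assert truth.to_numpy().sum() > 0
        # the 2.0-2.5 Mb tract on chr1 is exactly tree block 4
        assert set(np.flatnonzero(truth.to_numpy().any(axis=0))) == {4}
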