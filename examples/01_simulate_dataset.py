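"""Simulate a four-group rice-like panel with one planted introgression tract.

Builds the default Balding-Nichols panel (African-rice outgroup, indica,
temperate and tropical japonica; 40 accessions each), copies a 500 kb
indica segment into 30% of the tropical japonica accessions, and writes
VCF/TSV/BED files. The printed numbers are the dataset dimensions and the
ground-truth carriers every later scan should rediscover.
"""

from pathlib import Path

from introscan import SimulationConfig, PlantedTract, simulate_dataset, write_vcf
from introscan.io import write_bed, write_groups

out = Path("example_out/simulated")
out.mkdir(parents=True, exist_ok=True)

config = SimulationConfig(seed=1)
tract = PlantedTract(
    "chr1", 2_000_000, 2_500_000,
    donor_group="indica", recipient_group="tropical_japonica",
    replacement_fraction=0.3,
)
ds = simulate_dataset(config, [tract])

write_vcf(ds.genotypes, out / "panel.vcf", config.chrom_lengths())
write_groups(ds.groups, out / "groups.tsv")
write_bed(
    [(t.chrom, t.start_bp, t.end_bp) for t in ds.truth_tracts],
    out / "truth_tracts.bed",
)

print(f"accessions: {ds.genotypes.n_accessions}  sites: {ds.genotypes.n_sites}")
print(f"groups: {', '.join(ds.groups.groups)}")
t = ds.truth_tracts[0]
print(f"planted tract {t.chrom}:{t.start_bp}-{t.end_bp} ({t.donor_group} -> {t.recipient_group})")
print(f"carriers ({len(t.recipient_accessions)}): {', '.join(t.recipient_accessions[:4])}, ...")
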