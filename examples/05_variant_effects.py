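"""Score SNV effects on predicted editing outcomes at scanned PAM sites.

Builds a toy genome/exon/VCF fixture, scans exonic NGG sites on both strands,
predicts reference vs alternative outcome profiles for every (site, SNV)
window overlap, and ranks targets by SNV sensitivity (least variant first).
"""

import tempfile
from pathlib import Path

from editnas import (make_fixture_genome_and_vcf, rank_least_variant_targets,
                     scan_pam_sites, variant_effect_table)
from editnas.experiments import recovery_experiment
from editnas.variants import large_effect_report

res = recovery_experiment(seed=2, n=1500)
model = res["model"]

with tempfile.TemporaryDirectory() as tmp:
    fx = make_fixture_genome_and_vcf(seed=20, out_dir=Path(tmp))
    sites = scan_pam_sites(fx["fasta"], fx["bed"])
    table = variant_effect_table(model, sites, fx["vcf"])

print(f"scanned {len(sites)} exonic PAM sites "
      f"({fx['truth']['n_sites_forward']} forward, "
      f"{fx['truth']['n_sites_reverse']} reverse)")
print(f"(site, SNV) window overlaps: {len(table)} "
      f"(generator ground truth: {fx['truth']['n_pairs']})")

ranking = rank_least_variant_targets(table, all_sites=sites)
print("\nfive least-variant targets (low score = SNV-insensitive):")
print(ranking.head(5).to_string(index=False))

big = large_effect_report(table, task="ins1", min_effect=0.10)
print(f"\nSNVs shifting predicted 1 bp insertion by >= 0.10: {len(big)}")
if len(big):
    cols = ["site_id", "variant_id", "ref_ins1", "alt_ins1", "absdiff_ins1"]
    print(big[cols].head(5).round(3).to_string(index=False))
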