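"""Full congenic screen on synthetic data with known truth.

Simulates a three-strain congenic experiment (2 genotypes x 3 tissues x 4
replicates per strain), runs the differential-expression pipeline for one
strain (quantile normalization, present filtering, James-Stein shrinkage F,
pooled permutation p, BH q < 0.10), then the post-DE analyses: cis/trans
classification, donor-region enrichment, homogeneity along the region, IBD
test and candidate accounting. Because the data are synthetic, recovery of
the planted cis genes can be scored exactly.
"""

from congenic import analyze_congenic_strain
from congenic.diffexpr import run_strain_de
from congenic.simulate import (
    SimConfig,
    design_probes,
    probe_records,
    simulate_experiment,
    simulate_genome,
)

cfg = SimConfig(seed=11)
genome = simulate_genome(cfg)
probes = design_probes(genome.genes, genome.snps, cfg)
exp, truth = simulate_experiment(genome, probes, cfg)
print(
    f"simulated {len(genome.genes)} genes, {len(probes)} probes, "
    f"{exp.matrix.shape[1]} arrays"
)

strain = "HG2D"
records = probe_records(probes)
probe_to_gene = {r.probe_id: r.gene_id for r in records if not r.excluded}
table, de_genes = run_strain_de(exp, strain, probe_to_gene, n_perm=200, seed=11)
print(f"{strain}: {int(table['selected'].sum())} probes / {len(de_genes)} genes at q<0.10")

tg = truth.genes
cis = set(tg[(tg.strain == strain) & (tg.label == "cis")].gene_id)
trans = set(tg[(tg.strain == strain) & (tg.label == "trans_target")].gene_id)
print(
    f"planted: {len(cis)} cis, {len(trans)} trans targets; recovered "
    f"{len(cis & de_genes)} cis and {len(trans & de_genes)} trans "
    f"(sensitivity {len(cis & de_genes) / len(cis):.2f} for cis)"
)

report = analyze_congenic_strain(
    exp, records, genome.genes, genome.snps[genome.snps["known"]],
    genome.donor_regions[strain], de_genes,
    chrom_length=cfg.chrom_length, n_mc=200_000, seed=11,
)
acc = report["accounting"]
print(
    f"\naccounting: {acc.n_de_in_region}/{acc.n_candidates} region genes DE, "
    f"{acc.n_untested} untested -> raw reduction {acc.raw_reduction_pct:.1f}%, "
    f"effective {acc.effective_reduction_pct:.1f}%"
)
enr = report["donor_enrichment"]
print(
    f"donor-region enrichment of DE genes: OR {enr['odds_ratio']:.1f} "
    f"(p {enr['p']:.2g}) - cis candidates are preferentially selected"
)
print(
    f"homogeneity of DE along the region (2-Mb bins): p {report['homogeneity_p']:.2f} "
    "- no clustering beyond gene density"
)
ibd = report["ibd"]
if not ibd["degenerate"]:
    print(
        f"IBD: an IBD filter would discard {ibd['n_discarded']} DE genes "
        f"(non-IBD enrichment p {ibd['p']:.2g})"
    )
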