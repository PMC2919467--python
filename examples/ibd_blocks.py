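"""IBD block calling and genetic-map interpolation.

IBD (identical-by-descent) segments between two inbred strains carry
essentially no informative SNPs. Blocks are called by tiling a chromosome
into 10-kb windows and requiring >=10 uninformative SNPs and zero
informative ones per window; adjacent qualifying windows merge. The round
trip below plants IBD segments with a generator and recovers them. The
genetic-map interpolation converts cM positions (e.g. QTL confidence
limits) to bp.
"""

from congenic.genome import GeneticMap, SNPRecord, call_ibd_blocks, genetic_to_physical
from congenic.simulate import SimConfig, simulate_genome

cfg = SimConfig(
    seed=3, n_chromosomes=1, chrom_length=20_000_000, genes_per_chrom=10,
    strains=("HG2D",), donor_fractions={"HG2D": 0.5}, ibd_fraction=0.12,
)
genome = simulate_genome(cfg)
snps = genome.snps[genome.snps.chrom == "chr1"].sort_values("pos")
records = [
    SNPRecord("chr1", int(p), bool(i)) for p, i in zip(snps.pos, snps.informative)
]
blocks = call_ibd_blocks(records, cfg.chrom_length)

planted = sum(s.length for s in genome.ibd_segments)
recovered = sum(b.interval.length for b in blocks)
print(f"{len(snps)} SNPs ({int(snps.informative.sum())} informative) on chr1")
print(f"planted IBD: {planted/1e6:.2f} Mb in {len(genome.ibd_segments)} segments")
print(f"called IBD:  {recovered/1e6:.2f} Mb in {len(blocks)} blocks")
for b in blocks:
    print(
        f"  {b.interval.chrom}:{b.interval.start}-{b.interval.end} "
        f"({b.n_uninformative} uninformative SNPs)"
    )

gmap = GeneticMap(cM=[0.0, 12.0, 35.0, 60.0], bp=[0.0, 4e6, 11e6, 20e6])
for q in (6.0, 23.5, 80.0):
    print(f"QTL limit at {q} cM -> {genetic_to_physical(q, gmap)/1e6:.2f} Mb")
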