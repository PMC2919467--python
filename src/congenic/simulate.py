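"""Synthetic congenic-experiment generator with known truth.

Emulates the structure of a three-congenic-strain screen: strains HG2D, HG11
and HG17 each isolate a donor region on their own chromosome in an otherwise
shared background; 2 genotypes (background homozygote B vs congenic/donor
homozygote C) x 3 tissues x 4 replicates per strain; one or two probes per
gene designed on the background (reference) genome, so a SNP under a probe
depresses the signal of the congenic genotype by ``delta_snp`` log2 units —
the allelic-bias artifact. IBD segments inside donor regions are modeled as
stretches free of informative SNPs but with the genome-wide density of
uninformative ones, so the window-based IBD caller can recover them.

Planted truth (cis genes inside the donor region, sparse trans targets
elsewhere, artifact probes) is returned alongside the data, making
truth-conditional sensitivity and false-discovery proportions computable for
every run. All randomness derives from one seed; each stage draws from its
own deterministic substream.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

from .diffexpr import ExpressionExperiment, summarize_beads
from .genome import (
    DonorRegion,
    GeneAnnotation,
    GenomicInterval,
    ValidationError,
)
from .pipeline import ProbeRecord

#: Donor-region span as a fraction of the host chromosome, per strain. The
#: defaults put ~5.2/4.0/4.2% of all genes in the three regions.
DEFAULT_DONOR_FRACTIONS = {"HG2D": 0.26, "HG11": 0.20, "HG17": 0.21}


@dataclass(frozen=True)
class SimConfig:
    """Study-design knobs for the generator; defaults are the canonical
    desk-scale screen (~2,000 genes, 24 arrays per strain)."""

    seed: int = 0
    n_chromosomes: int = 5
    chrom_length: int = 50_000_000
    genes_per_chrom: int = 400
    strains: tuple[str, ...] = ("HG2D", "HG11", "HG17")
    donor_fractions: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_DONOR_FRACTIONS)
    )
    snp_density_non_ibd: float = 3.0  # informative SNPs / kb outside IBD
    snp_density_ibd: float = 0.0  # informative SNPs / kb inside IBD
    snp_density_uninformative: float = 2.0  # uninformative SNPs / kb, genome-wide
    ibd_fraction: float = 0.10  # of each donor region
    hidden_snp_fraction: float = 0.3  # SNPs absent from the "known" catalog
    probe_length: int = 50
    p_probe_snp_overlap: float = 0.15  # donor probes deliberately placed on a SNP
    multi_probe_fraction: float = 0.2  # genes with a second probe
    decoy_multimap_fraction: float = 0.02
    cis_fraction: float = 0.10  # of donor-region genes, per strain
    beta_cis: float = 1.0  # log2 effect of a cis gene
    n_trans: int = 20  # trans targets per strain
    beta_trans: float = 1.0
    delta_snp: float = 0.5  # log2 artifact per SNP-overlapping probe (C57-ward)
    noise_sd: float = 0.25  # residual log2 sd
    unexpressed_fraction: float = 0.10
    bead_outlier_rate: float = 0.01
    n_beads: int = 0  # 0 = emit the summarized matrix directly
    replicates: int = 4
    tissues: tuple[str, ...] = ("B", "F", "L")

    def __post_init__(self) -> None:
        for name in (
            "ibd_fraction",
            "hidden_snp_fraction",
            "p_probe_snp_overlap",
            "multi_probe_fraction",
            "decoy_multimap_fraction",
            "cis_fraction",
            "unexpressed_fraction",
            "bead_outlier_rate",
        ):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValidationError(f"{name} must lie in [0, 1], got {v}")
        if self.replicates < 2:
            raise ValidationError("need at least 2 replicates per group")
        for name in ("beta_cis", "beta_trans", "delta_snp", "noise_sd"):
            if not np.isfinite(getattr(self, name)):
                raise ValidationError(f"{name} must be finite")

    def with_seed(self, seed: int) -> "SimConfig":
        return replace(self, seed=seed)


@dataclass
class SimGenome:
    genes: list[GeneAnnotation]
    snps: pd.DataFrame  # chrom, pos, informative, known
    donor_regions: dict[str, DonorRegion]
    ibd_segments: list[GenomicInterval]


@dataclass
class SimTruth:
    """Planted labels: per (strain, gene) a {cis, trans_target, null} label
    with its log2 effect; per (strain, probe) whether the SNP artifact was
    applied."""

    genes: pd.DataFrame  # strain, gene_id, label, effect
    probes: pd.DataFrame  # strain, probe_id, artifact, n_snps_true


def _rng(config: SimConfig, stage: int) -> np.random.Generator:
    return np.random.default_rng([config.seed, stage])


def simulate_genome(config: SimConfig) -> SimGenome:
    """Place genes, SNPs, donor regions and IBD segments."""
    rng = _rng(config, 0)
    L = config.chrom_length
    if config.n_chromosomes < len(config.strains):
        raise ValidationError("need at least one chromosome per strain")

    donor_regions: dict[str, DonorRegion] = {}
    ibd_segments: list[GenomicInterval] = []
    for i, strain in enumerate(config.strains):
        chrom = f"chr{i + 1}"
        frac = config.donor_fractions.get(strain, 0.2)
        span = int(frac * L)
        start = (L - span) // 2
        region = GenomicInterval(chrom, start, start + span)
        donor_regions[strain] = DonorRegion(strain, region)
        ibd_segments.extend(_place_ibd_segments(region, config.ibd_fraction, rng))

    genes: list[GeneAnnotation] = []
    for c in range(config.n_chromosomes):
        chrom = f"chr{c + 1}"
        for i in range(config.genes_per_chrom):
            length = int(np.clip(rng.lognormal(np.log(20_000), 0.6), 2_000, 300_000))
            start = int(rng.integers(0, L - length))
            genes.append(
                GeneAnnotation(
                    gene_id=f"g{chrom}_{i:04d}",
                    chrom=chrom,
                    start=start,
                    end=start + length,
                    strand="+" if rng.random() < 0.5 else "-",
                )
            )
    genes.sort(key=lambda g: (g.chrom, g.start))

    snps = _simulate_snps(config, ibd_segments, rng)
    return SimGenome(genes, snps, donor_regions, ibd_segments)


def _place_ibd_segments(
    region: GenomicInterval, fraction: float, rng: np.random.Generator, window: int = 10_000
) -> list[GenomicInterval]:
    """Carve grid-aligned IBD segments covering ~``fraction`` of the region."""
    n_windows_total = int(fraction * region.length) // window
    if n_windows_total == 0:
        return []
    per_segment = max(1, n_windows_total // 2)
    segments: list[GenomicInterval] = []
    lo = -(-region.start // window)  # first full window inside the region
    hi = region.end // window
    occupied: set[int] = set()
    attempts = 0
    while n_windows_total > 0 and attempts < 100:
        attempts += 1
        k = min(per_segment, n_windows_total)
        if hi - lo <= k:
            break
        w0 = int(rng.integers(lo, hi - k))
        if any(w in occupied for w in range(w0 - 1, w0 + k + 1)):
            continue  # keep segments non-adjacent so merged blocks match
        occupied.update(range(w0, w0 + k))
        segments.append(
            GenomicInterval(region.chrom, w0 * window, (w0 + k) * window)
        )
        n_windows_total -= k
    return sorted(segments, key=lambda s: s.start)


def _simulate_snps(
    config: SimConfig,
    ibd_segments: list[GenomicInterval],
    rng: np.random.Generator,
) -> pd.DataFrame:
    rows = []
    L = config.chrom_length
    per_chrom_ibd: dict[str, list[GenomicInterval]] = {}
    for seg in ibd_segments:
        per_chrom_ibd.setdefault(seg.chrom, []).append(seg)

    for c in range(config.n_chromosomes):
        chrom = f"chr{c + 1}"
        segs = per_chrom_ibd.get(chrom, [])

        def in_ibd(pos: np.ndarray) -> np.ndarray:
            mask = np.zeros(pos.size, dtype=bool)
            for s in segs:
                mask |= (pos >= s.start) & (pos < s.end)
            return mask

        n_inf = rng.poisson(config.snp_density_non_ibd * L / 1_000)
        pos_inf = rng.integers(0, L, size=n_inf)
        pos_inf = pos_inf[~in_ibd(pos_inf)]
        for seg in segs:
            k = rng.poisson(config.snp_density_ibd * seg.length / 1_000)
            if k:
                pos_inf = np.concatenate(
                    [pos_inf, rng.integers(seg.start, seg.end, size=k)]
                )
        n_uninf = rng.poisson(config.snp_density_uninformative * L / 1_000)
        pos_uninf = rng.integers(0, L, size=n_uninf)

        pos = np.concatenate([pos_inf, pos_uninf])
        informative = np.concatenate(
            [np.ones(pos_inf.size, bool), np.zeros(pos_uninf.size, bool)]
        )
        order = np.argsort(pos, kind="mergesort")
        known = rng.random(pos.size) >= config.hidden_snp_fraction
        rows.append(
            pd.DataFrame(
                {
                    "chrom": chrom,
                    "pos": pos[order],
                    "informative": informative[order],
                    "known": known[order],
                }
            )
        )
    return pd.concat(rows, ignore_index=True)


def design_probes(
    genes: Sequence[GeneAnnotation], snps: pd.DataFrame, config: SimConfig
) -> pd.DataFrame:
    """Design one or two probes per gene on the reference genome.

    SNP overlap is determined by actual interval intersection against the
    full SNP set (``n_snps_true``) and against the known catalog only
    (``n_snps``, what a probe-filtering step can see). A fraction of donor
    probes is deliberately centered on a SNP so the artifact stratum is
    populated; a small fraction of decoy multi-mapped probes exercises the
    annotation filter.
    """
    if not genes:
        return pd.DataFrame(
            columns=[
                "probe_id", "gene_id", "chrom", "start", "end",
                "n_hits", "max_gap", "n_snps", "n_snps_true",
            ]
        )
    rng = _rng(config, 1)
    by_chrom_all = {
        chrom: np.sort(grp["pos"].to_numpy()) for chrom, grp in snps.groupby("chrom")
    }
    known = snps[snps["known"]]
    by_chrom_known = {
        chrom: np.sort(grp["pos"].to_numpy()) for chrom, grp in known.groupby("chrom")
    }

    def count(pos: dict[str, np.ndarray], chrom: str, s: int, e: int) -> int:
        arr = pos.get(chrom)
        if arr is None:
            return 0
        return int(np.searchsorted(arr, e) - np.searchsorted(arr, s))

    rows = []
    for g in genes:
        n_probes = 1 + (rng.random() < config.multi_probe_fraction)
        for k in range(n_probes):
            plen = min(config.probe_length, g.end - g.start)
            start = None
            if rng.random() < config.p_probe_snp_overlap:
                arr = by_chrom_all.get(g.chrom)
                if arr is not None:
                    lo = np.searchsorted(arr, g.start)
                    hi = np.searchsorted(arr, g.end)
                    if hi > lo:
                        snp = int(arr[rng.integers(lo, hi)])
                        start = int(
                            np.clip(snp - plen // 2, g.start, g.end - plen)
                        )
            if start is None:
                start = int(rng.integers(g.start, g.end - plen + 1))
            end = start + plen
            rows.append(
                {
                    "probe_id": f"p_{g.gene_id}_{k}",
                    "gene_id": g.gene_id,
                    "chrom": g.chrom,
                    "start": start,
                    "end": end,
                    "n_hits": 2 if rng.random() < config.decoy_multimap_fraction else 1,
                    "max_gap": 0,
                    "n_snps": count(by_chrom_known, g.chrom, start, end),
                    "n_snps_true": count(by_chrom_all, g.chrom, start, end),
                }
            )
    return pd.DataFrame(rows)


def probe_records(probe_table: pd.DataFrame) -> list[ProbeRecord]:
    """View a generated (or read-back) probe table as ProbeRecord objects.

    ``n_snps`` is the known-catalog count — what downstream filters see.
    """
    records = []
    for row in probe_table.itertuples(index=False):
        multi = int(row.n_hits) > 1
        records.append(
            ProbeRecord(
                probe_id=str(row.probe_id),
                gene_id=str(row.gene_id),
                alignment=GenomicInterval(str(row.chrom), int(row.start), int(row.end)),
                n_snps=int(row.n_snps),
                multi_mapped=multi,
                max_gap=int(row.max_gap),
                excluded=multi or int(row.max_gap) > 10_000,
            )
        )
    return records


def simulate_experiment(
    genome: SimGenome, probe_table: pd.DataFrame, config: SimConfig
) -> tuple[ExpressionExperiment, SimTruth]:
    """Generate the probes x samples log2 matrix, detection p-values and truth.

    log2 intensity = baseline + tissue effect + genotype effect (cis genes of
    the strain's donor region and its trans targets, congenic genotype only)
    - delta_snp for SNP-overlapping donor probes in the congenic genotype
    + N(0, noise_sd). With ``n_beads > 0`` the matrix entry is instead the
    3-MAD-summarized mean of simulated bead intensities around that value.
    """
    rng = _rng(config, 2)
    genes = {g.gene_id: g for g in genome.genes}
    probes = probe_table.reset_index(drop=True)
    n_probes = len(probes)

    sample_rows = []
    for strain in config.strains:
        for genotype in ("B", "C"):
            for tissue in config.tissues:
                for rep in range(1, config.replicates + 1):
                    sample_rows.append(
                        {
                            "sample_id": f"{strain}.{tissue}{genotype}{rep}",
                            "strain": strain,
                            "genotype": genotype,
                            "tissue": tissue,
                            "replicate": rep,
                        }
                    )
    samples = pd.DataFrame(sample_rows).set_index("sample_id")

    # planted truth per strain
    gene_truth_rows = []
    effects: dict[str, dict[str, float]] = {}
    for strain in config.strains:
        region = genome.donor_regions[strain].interval
        donor_gene_ids = [
            g.gene_id
            for g in genome.genes
            if g.chrom == region.chrom and region.start <= g.start and g.end <= region.end
        ]
        n_cis = int(round(config.cis_fraction * len(donor_gene_ids)))
        cis = set(
            rng.choice(donor_gene_ids, size=n_cis, replace=False)
        ) if n_cis else set()
        outside = [
            g.gene_id
            for g in genome.genes
            if not any(
                dr.interval.contains_interval(genes[g.gene_id].interval)
                for dr in genome.donor_regions.values()
            )
        ]
        n_trans = min(config.n_trans, len(outside))
        trans = set(
            rng.choice(outside, size=n_trans, replace=False)
        ) if n_trans else set()
        eff: dict[str, float] = {}
        for g in genome.genes:
            if g.gene_id in cis:
                label, effect = "cis", config.beta_cis * (1 if rng.random() < 0.5 else -1)
            elif g.gene_id in trans:
                label, effect = "trans_target", config.beta_trans * (
                    1 if rng.random() < 0.5 else -1
                )
            else:
                label, effect = "null", 0.0
            if label != "null":
                eff[g.gene_id] = effect
            gene_truth_rows.append(
                {"strain": strain, "gene_id": g.gene_id, "label": label, "effect": effect}
            )
        effects[strain] = eff

    baseline = rng.normal(8.0, 1.0, size=n_probes)
    expressed = rng.random(n_probes) >= config.unexpressed_fraction
    baseline[~expressed] = rng.normal(4.0, 0.3, size=(~expressed).sum())
    tissue_eff = {
        t: rng.normal(0.0, 0.5, size=n_probes) for t in config.tissues
    }

    probe_gene = probes["gene_id"].to_numpy()
    probe_chrom = probes["chrom"].to_numpy()
    probe_start = probes["start"].to_numpy()
    probe_end = probes["end"].to_numpy()
    has_true_snp = probes["n_snps_true"].to_numpy() >= 1

    artifact_rows = []
    artifact_by_strain: dict[str, np.ndarray] = {}
    for strain in config.strains:
        region = genome.donor_regions[strain].interval
        in_region = (
            (probe_chrom == region.chrom)
            & (probe_start >= region.start)
            & (probe_end <= region.end)
        )
        art = in_region & has_true_snp & expressed
        artifact_by_strain[strain] = art
        for i in range(n_probes):
            artifact_rows.append(
                {
                    "strain": strain,
                    "probe_id": probes.at[i, "probe_id"],
                    "artifact": bool(art[i]),
                    "n_snps_true": int(probes.at[i, "n_snps_true"]),
                }
            )

    matrix = np.empty((n_probes, len(samples)))
    detection = np.empty_like(matrix)
    for j, (sid, s) in enumerate(samples.iterrows()):
        mu = baseline + tissue_eff[s["tissue"]]
        if s["genotype"] == "C":
            eff = effects[s["strain"]]
            if eff:
                gene_effect = np.array([eff.get(g, 0.0) for g in probe_gene])
                mu = mu + np.where(expressed, gene_effect, 0.0)
            mu = mu - config.delta_snp * artifact_by_strain[s["strain"]]
        y = mu + rng.normal(0.0, config.noise_sd, size=n_probes)
        if config.n_beads > 0:
            y = _summarize_simulated_beads(y, config, rng)
        matrix[:, j] = y
        det = rng.uniform(0.0, 1.0, size=n_probes)
        det[expressed] = rng.uniform(0.0, 0.002, size=expressed.sum())
        detection[:, j] = det

    index = pd.Index(probes["probe_id"], name="probe_id")
    exp = ExpressionExperiment(
        matrix=pd.DataFrame(matrix, index=index, columns=samples.index),
        samples=samples,
        detection=pd.DataFrame(detection, index=index, columns=samples.index),
    )
    truth = SimTruth(
        genes=pd.DataFrame(gene_truth_rows),
        probes=pd.DataFrame(artifact_rows),
    )
    return exp, truth


def _summarize_simulated_beads(
    y: np.ndarray, config: SimConfig, rng: np.random.Generator
) -> np.ndarray:
    """Replace each log2 value with the 3-MAD summary of simulated beads."""
    out = np.empty_like(y)
    for i, target in enumerate(y):
        lin = 2.0**target
        beads = rng.normal(lin, 0.1 * lin, size=config.n_beads)
        outliers = rng.random(config.n_beads) < config.bead_outlier_rate
        beads[outliers] *= 8.0
        beads = np.maximum(beads, 1.0)
        mean, _, _ = summarize_beads(beads)
        out[i] = np.log2(mean)
    return out
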