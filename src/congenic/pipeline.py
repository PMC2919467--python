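"""Post-DE congenic analyses.

Everything downstream of differential expression for a congenic screen:
probe annotation filters (multi-mapping, large alignment gaps), removal of
donor-region probes that overlap SNPs between the strains, cis/trans
classification of DE genes against the donor region, donor-region and
IBD enrichment tests, a Monte-Carlo homogeneity test of DE rates along the
donor region, allelic-bias summaries of probe intensities, and the
candidate-accounting arithmetic that adds untested genes back to the
candidate list.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.special import gammaln
from scipy.stats import mannwhitneyu, ttest_ind

from .diffexpr import ExpressionExperiment, present_filter
from .enrichment import (
    ContingencyTable,
    fisher_exact_two_sided,
    odds_ratio_cmle,
)
from .genome import (
    DonorRegion,
    GeneAnnotation,
    GenomicInterval,
    IBDBlock,
    ValidationError,
    gene_in_ibd,
    gene_in_region,
)

logger = logging.getLogger(__name__)

MAX_ALIGNMENT_GAP = 10_000  # bp; larger gaps disqualify a probe's annotation


@dataclass
class ProbeRecord:
    """A microarray probe with its genomic alignment and annotation state."""

    probe_id: str
    gene_id: str | None
    alignment: GenomicInterval | None
    n_snps: int = 0
    multi_mapped: bool = False
    max_gap: int = 0
    excluded: bool = False

    def __post_init__(self) -> None:
        if self.n_snps < 0:
            raise ValidationError(f"{self.probe_id}: n_snps must be >= 0")


@dataclass(frozen=True)
class EqtlCall:
    gene_id: str
    strain_id: str
    classification: str  # "cis_candidate" or "trans"
    chrom: str


@dataclass(frozen=True)
class AccountingReport:
    """Candidate bookkeeping for one donor region.

    ``n_untested`` genes (no probe, or only SNP-overlapping probes) cannot be
    discarded and are added back, turning the raw reduction from DE testing
    into the smaller effective reduction.
    """

    strain_id: str
    n_candidates: int
    n_untested: int
    n_de_in_region: int

    def __post_init__(self) -> None:
        if self.n_untested + self.n_de_in_region > self.n_candidates:
            raise ValidationError(
                f"{self.strain_id}: untested + DE exceeds candidate count"
            )

    @property
    def n_tested(self) -> int:
        return self.n_candidates - self.n_untested

    @property
    def n_remaining(self) -> int:
        return self.n_de_in_region + self.n_untested

    @property
    def raw_reduction_pct(self) -> float:
        return 100.0 * (1.0 - self.n_de_in_region / self.n_candidates)

    @property
    def effective_reduction_pct(self) -> float:
        return 100.0 * (1.0 - self.n_remaining / self.n_candidates)

    def as_dict(self) -> dict:
        return {
            "strain_id": self.strain_id,
            "n_candidates": self.n_candidates,
            "n_untested": self.n_untested,
            "n_tested": self.n_tested,
            "n_de_in_region": self.n_de_in_region,
            "n_remaining": self.n_remaining,
            "raw_reduction_pct": round(self.raw_reduction_pct, 1),
            "effective_reduction_pct": round(self.effective_reduction_pct, 1),
        }


def annotate_probes(
    alignments: pd.DataFrame,
    gene_sources: Sequence[Sequence[GeneAnnotation]],
    snps: pd.DataFrame | None = None,
) -> list[ProbeRecord]:
    """Build probe records from alignment hits, gene sources and a SNP table.

    ``alignments`` needs columns probe_id, chrom, start, end, n_hits,
    max_gap. Probes with multiple genomic hits or an alignment gap over 10 kb
    are flagged excluded and left unannotated. Remaining probes are assigned
    the maximally overlapping gene from the first source (in the given
    priority order, e.g. curated transcripts before predicted ones) that
    overlaps them at all. ``snps`` (columns chrom, pos) fills ``n_snps``.
    """
    snp_pos: dict[str, np.ndarray] = {}
    if snps is not None and len(snps):
        for chrom, grp in snps.groupby("chrom"):
            snp_pos[str(chrom)] = np.sort(grp["pos"].to_numpy())

    records: list[ProbeRecord] = []
    for row in alignments.itertuples(index=False):
        multi = int(row.n_hits) > 1
        gap = int(row.max_gap)
        excluded = multi or gap > MAX_ALIGNMENT_GAP
        interval = GenomicInterval(str(row.chrom), int(row.start), int(row.end))
        gene_id = None
        if not excluded:
            gene_id = _assign_gene(interval, gene_sources)
        n_snps = 0
        if str(row.chrom) in snp_pos:
            pos = snp_pos[str(row.chrom)]
            n_snps = int(
                np.searchsorted(pos, interval.end, side="left")
                - np.searchsorted(pos, interval.start, side="left")
            )
        records.append(
            ProbeRecord(
                probe_id=str(row.probe_id),
                gene_id=gene_id,
                alignment=interval,
                n_snps=n_snps,
                multi_mapped=multi,
                max_gap=gap,
                excluded=excluded,
            )
        )
    return records


def _assign_gene(
    interval: GenomicInterval, gene_sources: Sequence[Sequence[GeneAnnotation]]
) -> str | None:
    for source in gene_sources:
        best, best_overlap = None, 0
        for g in source:
            if g.chrom != interval.chrom:
                continue
            ov = min(g.end, interval.end) - max(g.start, interval.start)
            if ov > best_overlap:
                best, best_overlap = g.gene_id, ov
        if best is not None:
            return best
    return None


def filter_snp_probes(
    probes: Iterable[ProbeRecord], donor: DonorRegion
) -> tuple[list[ProbeRecord], list[ProbeRecord]]:
    """Drop donor-region probes that overlap at least one SNP.

    Only probes whose alignment lies within the donor interval are touched —
    a mismatch artifact requires the sample to carry the non-reference
    allele, which outside the donor region it does not. Returns
    (kept, removed).
    """
    kept, removed = [], []
    for p in probes:
        in_region = p.alignment is not None and donor.interval.contains_interval(
            p.alignment
        )
        if in_region and p.n_snps >= 1:
            removed.append(p)
        else:
            kept.append(p)
    return kept, removed


def classify_cis_trans(
    de_genes: Iterable[GeneAnnotation], donor: DonorRegion
) -> tuple[list[EqtlCall], dict[str, int]]:
    """Partition DE genes into cis candidates (inside the donor region) and
    trans (everywhere else); also tally trans calls per chromosome."""
    calls: list[EqtlCall] = []
    trans_counts: dict[str, int] = {}
    for g in de_genes:
        cls = "cis_candidate" if gene_in_region(g, donor.interval) else "trans"
        calls.append(EqtlCall(g.gene_id, donor.strain_id, cls, g.chrom))
        if cls == "trans":
            trans_counts[g.chrom] = trans_counts.get(g.chrom, 0) + 1
    return calls, trans_counts


def donor_enrichment_test(
    n_de_in_region: int,
    n_de_total: int,
    n_array_genes_in_region: int,
    n_array_genes: int,
    or_method: str = "reference",
) -> tuple[float, float]:
    """Enrichment of DE genes inside the donor region against the array.

    2x2 of {DE, not DE} x {in region, outside}; returns (odds ratio, p).
    """
    t = ContingencyTable(
        a=n_de_in_region,
        b=n_de_total - n_de_in_region,
        c=n_array_genes_in_region - n_de_in_region,
        d=n_array_genes - n_de_total - n_array_genes_in_region + n_de_in_region,
    )
    return odds_ratio_cmle(t, method=or_method), fisher_exact_two_sided(t)


def _log_table_prob(de_counts: np.ndarray, expressed: np.ndarray) -> np.ndarray:
    """Log multivariate-hypergeometric probability of 2xK tables with both
    margins fixed: DE genes distributed over bins of expressed genes."""
    de_counts = np.atleast_2d(de_counts)
    lp = (
        gammaln(expressed + 1)
        - gammaln(de_counts + 1)
        - gammaln(expressed - de_counts + 1)
    ).sum(axis=1)
    total, n_de = int(expressed.sum()), int(de_counts[0].sum())
    lp -= gammaln(total + 1) - gammaln(n_de + 1) - gammaln(total - n_de + 1)
    return lp


def homogeneity_test(
    bins: pd.DataFrame,
    n_mc: int = 2_000_000,
    seed: int = 0,
    rel_tol: float = 1e-7,
    chunk: int = 200_000,
) -> float:
    """Monte-Carlo exact test of homogeneity of DE rates across bins.

    ``bins`` needs columns ``expressed`` and ``de`` (de <= expressed per
    bin); bins with zero expressed genes are dropped. Tables are sampled
    with both margins fixed (equivalent to permuting gene-to-bin labels) and
    the p-value is ``(1 + #{simulated table at most as probable as
    observed}) / (1 + n_mc)`` — conditional exact, conservative, and
    bit-reproducible for a given seed.
    """
    if not {"expressed", "de"} <= set(bins.columns):
        raise ValidationError("bins must have 'expressed' and 'de' columns")
    sub = bins[bins["expressed"] > 0]
    expressed = sub["expressed"].to_numpy(dtype=int)
    de = sub["de"].to_numpy(dtype=int)
    if np.any(de > expressed):
        raise ValidationError("de count exceeds expressed count in a bin")
    if len(expressed) < 2:
        return 1.0
    n_de = int(de.sum())
    if n_de == 0 or n_de == int(expressed.sum()):
        return 1.0
    lp_obs = float(_log_table_prob(de, expressed)[0])
    threshold = lp_obs + math.log1p(rel_tol)

    rng = np.random.default_rng(seed)
    n_le = 0
    remaining = n_mc
    while remaining > 0:
        m = min(chunk, remaining)
        sim = rng.multivariate_hypergeometric(expressed, n_de, size=m)
        n_le += int((_log_table_prob(sim, expressed) <= threshold).sum())
        remaining -= m
    return (1 + n_le) / (1 + n_mc)


def ibd_enrichment_test(
    de_genes: Iterable[GeneAnnotation],
    expressed_genes: Iterable[GeneAnnotation],
    ibd_blocks: Sequence[IBDBlock],
    or_method: str = "reference",
) -> dict:
    """Association between DE status and IBD membership among expressed
    donor-region genes.

    Returns a dict with odds_ratio (non-IBD enrichment of DE genes), p,
    n_discarded (DE genes an IBD filter would drop) and a ``degenerate``
    flag when no expressed gene lies in IBD. The filter itself is reported,
    never applied.
    """
    de_ids = {g.gene_id for g in de_genes}
    rows = [(g.gene_id in de_ids, gene_in_ibd(g, ibd_blocks)) for g in expressed_genes]
    n_de_ibd = sum(1 for de, ibd in rows if de and ibd)
    n_de_non = sum(1 for de, ibd in rows if de and not ibd)
    n_nd_ibd = sum(1 for de, ibd in rows if not de and ibd)
    n_nd_non = sum(1 for de, ibd in rows if not de and not ibd)
    if n_de_ibd + n_nd_ibd == 0:
        return {
            "degenerate": True,
            "odds_ratio": None,
            "p": None,
            "n_discarded": 0,
        }
    # orient the table so OR > 1 means DE genes favor non-IBD
    t = ContingencyTable(a=n_de_non, b=n_de_ibd, c=n_nd_non, d=n_nd_ibd)
    return {
        "degenerate": False,
        "odds_ratio": odds_ratio_cmle(t, method=or_method),
        "p": fisher_exact_two_sided(t),
        "n_discarded": n_de_ibd,
    }


def allelic_bias_summary(
    exp: ExpressionExperiment,
    probes: Iterable[ProbeRecord],
    donor: DonorRegion,
    linear_mean: bool = True,
    test: str = "ranksum",
    detection_alpha: float = 0.01,
    detection_min_samples: int = 4,
) -> tuple[pd.DataFrame, dict[str, float], dict[str, float]]:
    """Per-probe allelic bias log2(C57 mean / CAST mean), stratified.

    Intensities are averaged on the linear scale by default ("average
    intensity"; ``linear_mean=False`` averages the log2 values instead).
    Probes are restricted to those detected in at least one tissue of the
    strain's samples, and stratified donor/background x has_snp/no_snp.
    Stratum medians and pairwise two-sided p-values (Wilcoxon rank-sum by
    default, Welch t with ``test="t"``) are returned alongside the rows.
    """
    sub = exp.restrict_to_strain(donor.strain_id)
    mask = present_filter(
        sub.detection, sub.samples, detection_alpha, detection_min_samples
    )
    b_cols = sub.samples.index[sub.samples["genotype"] == "B"]
    c_cols = sub.samples.index[sub.samples["genotype"] == "C"]
    if linear_mean:
        lin = 2.0 ** sub.matrix
        log2fc = np.log2(lin[b_cols].mean(axis=1)) - np.log2(lin[c_cols].mean(axis=1))
    else:
        log2fc = sub.matrix[b_cols].mean(axis=1) - sub.matrix[c_cols].mean(axis=1)

    rows = []
    for p in probes:
        if p.probe_id not in log2fc.index or not mask.loc[p.probe_id, "any"]:
            continue
        location = (
            "donor"
            if p.alignment is not None
            and donor.interval.contains_interval(p.alignment)
            else "background"
        )
        snp = "has_snp" if p.n_snps >= 1 else "no_snp"
        rows.append(
            {
                "probe_id": p.probe_id,
                "stratum": f"{location}/{snp}",
                "location": location,
                "snp": snp,
                "log2fc": float(log2fc[p.probe_id]),
            }
        )
    table = pd.DataFrame(rows)
    medians = (
        table.groupby("stratum")["log2fc"].median().to_dict() if len(table) else {}
    )
    pvals: dict[str, float] = {}
    if len(table):
        pvals = _stratum_pvalues(table, test)
    return table, medians, pvals


def _stratum_pvalues(table: pd.DataFrame, test: str) -> dict[str, float]:
    def compare(x: np.ndarray, y: np.ndarray) -> float:
        if len(x) == 0 or len(y) == 0:
            return float("nan")
        if test == "ranksum":
            return float(mannwhitneyu(x, y, alternative="two-sided").pvalue)
        if test == "t":
            return float(ttest_ind(x, y, equal_var=False).pvalue)
        raise ValueError(f"unknown test {test!r}")

    out = {}
    donor = table[table["location"] == "donor"]
    background = table[table["location"] == "background"]
    out["donor_vs_background"] = compare(
        donor["log2fc"].to_numpy(), background["log2fc"].to_numpy()
    )
    for loc, grp in (("donor", donor), ("background", background)):
        out[f"{loc}_has_snp_vs_no_snp"] = compare(
            grp.loc[grp["snp"] == "has_snp", "log2fc"].to_numpy(),
            grp.loc[grp["snp"] == "no_snp", "log2fc"].to_numpy(),
        )
    return out


def candidate_accounting(
    region_genes: Iterable[GeneAnnotation],
    array_coverage: Mapping[str, str],
    de_genes: Iterable[str],
    strain_id: str = "",
) -> AccountingReport:
    """Account for every donor-region candidate.

    ``array_coverage`` maps each region gene to "covered", "snp_only" (only
    SNP-overlapping probes) or "absent"; genes in the last two classes were
    never tested and are added back to the candidate list.
    """
    region_ids = [g.gene_id for g in region_genes]
    missing = [g for g in region_ids if g not in array_coverage]
    if missing:
        raise ValidationError(
            f"coverage map missing {len(missing)} region genes, e.g. {missing[:5]}"
        )
    bad = {g: s for g, s in array_coverage.items() if s not in ("covered", "snp_only", "absent")}
    if bad:
        raise ValidationError(f"invalid coverage statuses: {bad}")
    de = set(de_genes)
    n_untested = sum(
        1 for g in region_ids if array_coverage[g] in ("snp_only", "absent")
    )
    n_de_in_region = sum(
        1 for g in region_ids if g in de and array_coverage[g] == "covered"
    )
    return AccountingReport(
        strain_id=strain_id,
        n_candidates=len(region_ids),
        n_untested=n_untested,
        n_de_in_region=n_de_in_region,
    )


def accounting_from_counts(
    n_candidates: int, n_de_in_region: int, n_untested: int, strain_id: str = ""
) -> AccountingReport:
    """Build an accounting report directly from published counts."""
    return AccountingReport(
        strain_id=strain_id,
        n_candidates=n_candidates,
        n_untested=n_untested,
        n_de_in_region=n_de_in_region,
    )


def array_coverage_map(
    region_genes: Iterable[GeneAnnotation],
    probes: Iterable[ProbeRecord],
    donor: DonorRegion,
) -> dict[str, str]:
    """Classify each region gene as covered / snp_only / absent.

    A gene is "absent" with no usable (non-excluded) probe, "snp_only" when
    every usable probe would be removed by the donor-region SNP filter, and
    "covered" otherwise.
    """
    by_gene: dict[str, list[ProbeRecord]] = {}
    for p in probes:
        if p.excluded or p.gene_id is None:
            continue
        by_gene.setdefault(p.gene_id, []).append(p)

    def snp_filtered(p: ProbeRecord) -> bool:
        return (
            p.alignment is not None
            and donor.interval.contains_interval(p.alignment)
            and p.n_snps >= 1
        )

    coverage = {}
    for g in region_genes:
        plist = by_gene.get(g.gene_id, [])
        if not plist:
            coverage[g.gene_id] = "absent"
        elif all(snp_filtered(p) for p in plist):
            coverage[g.gene_id] = "snp_only"
        else:
            coverage[g.gene_id] = "covered"
    return coverage


def analyze_congenic_strain(
    exp: ExpressionExperiment,
    probes: Sequence[ProbeRecord],
    genes: Sequence[GeneAnnotation],
    snps: pd.DataFrame,
    donor: DonorRegion,
    de_genes: set[str],
    ibd_blocks: Sequence[IBDBlock] | None = None,
    chrom_length: int | None = None,
    bin_width: int = 2_000_000,
    n_mc: int = 2_000_000,
    seed: int = 0,
    or_method: str = "reference",
) -> dict:
    """Run every post-DE analysis for one strain and return one report dict.

    ``snps`` is the known-SNP catalog (chrom, pos, informative); IBD blocks
    are called from it on the donor chromosome unless supplied. ``de_genes``
    is the gene set selected by the DE stage (already restricted to probes
    that survive the SNP filter upstream, if desired).
    """
    from .genome import bin_gene_counts, call_ibd_blocks
    from .genome import SNPRecord

    gene_by_id = {g.gene_id: g for g in genes}
    region_genes = [g for g in genes if gene_in_region(g, donor.interval)]

    coverage = array_coverage_map(region_genes, probes, donor)
    kept, removed = filter_snp_probes(
        [p for p in probes if not p.excluded], donor
    )

    # expressed = detected in >= 1 tissue through a kept probe
    sub = exp.restrict_to_strain(donor.strain_id)
    mask = present_filter(sub.detection, sub.samples)
    expressed_genes: set[str] = set()
    array_genes: set[str] = set()
    for p in kept:
        if p.gene_id is None:
            continue
        array_genes.add(p.gene_id)
        if p.probe_id in mask.index and mask.loc[p.probe_id, "any"]:
            expressed_genes.add(p.gene_id)

    de_annot = [gene_by_id[g] for g in sorted(de_genes) if g in gene_by_id]
    skipped = sorted(de_genes - set(gene_by_id))
    if skipped:
        logger.warning("%d DE genes lack coordinates; excluded", len(skipped))
    calls, trans_counts = classify_cis_trans(de_annot, donor)
    n_cis = sum(1 for c in calls if c.classification == "cis_candidate")

    array_in_region = {g.gene_id for g in region_genes} & array_genes
    enrich_or, enrich_p = donor_enrichment_test(
        n_de_in_region=len(de_genes & array_in_region),
        n_de_total=len(de_genes & array_genes),
        n_array_genes_in_region=len(array_in_region),
        n_array_genes=len(array_genes),
        or_method=or_method,
    )

    bins = bin_gene_counts(
        region_genes,
        {
            "on_array": array_in_region,
            "expressed": expressed_genes & array_in_region,
            "de": de_genes & expressed_genes & array_in_region,
        },
        donor.interval,
        width=bin_width,
    )
    homog_p = homogeneity_test(bins, n_mc=n_mc, seed=seed)

    if ibd_blocks is None:
        chrom_snps = snps[snps["chrom"] == donor.interval.chrom].sort_values("pos")
        length = chrom_length or int(chrom_snps["pos"].max()) + 1
        ibd_blocks = call_ibd_blocks(
            [
                SNPRecord(str(r.chrom), int(r.pos), bool(r.informative))
                for r in chrom_snps.itertuples(index=False)
            ],
            length,
        )
    expressed_region = [
        g for g in region_genes if g.gene_id in (expressed_genes & array_in_region)
    ]
    de_region = [g for g in expressed_region if g.gene_id in de_genes]
    ibd = ibd_enrichment_test(de_region, expressed_region, ibd_blocks, or_method)

    bias_rows, bias_medians, bias_p = allelic_bias_summary(exp, kept, donor)

    accounting = candidate_accounting(
        region_genes, coverage, de_genes, strain_id=donor.strain_id
    )

    return {
        "strain_id": donor.strain_id,
        "n_region_genes": len(region_genes),
        "n_probes_snp_removed": len(removed),
        "eqtl_calls": calls,
        "trans_counts": trans_counts,
        "n_cis_candidates": n_cis,
        "donor_enrichment": {"odds_ratio": enrich_or, "p": enrich_p},
        "homogeneity_p": homog_p,
        "ibd": ibd,
        "ibd_blocks": list(ibd_blocks),
        "allelic_bias": {
            "rows": bias_rows,
            "medians": bias_medians,
            "p": bias_p,
        },
        "accounting": accounting,
        "bins": bins,
    }
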