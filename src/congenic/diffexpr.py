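"""Differential-expression pipeline for a congenic-vs-background experiment.

The canonical design profiles one congenic strain against its background in
three tissues with four biological replicates per genotype (24 arrays per
strain). Stages, in order:

1. bead-level summarization with 3-MAD outlier removal,
2. quantile normalization across arrays,
3. detection ("present call") filtering per tissue,
4. a cell-means model ``y_ij = mu + mu_i + eps_ij`` over the six
   tissue-by-genotype groups of one strain,
5. per-tissue genotype contrasts scored by an F statistic whose denominator
   uses James-Stein-shrunken residual variances,
6. permutation p-values pooled across probes,
7. Benjamini-Hochberg FDR, selecting probes at q < 0.10 in any tissue and
   collapsing probes to genes.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.special import polygamma
from statsmodels.stats.multitest import multipletests

from .genome import ValidationError

logger = logging.getLogger(__name__)

MAD_SCALE = 1.4826  # normal-consistency factor
TISSUES = ("B", "F", "L")  # brain, fat, liver
GENOTYPES = ("B", "C")  # C57 background, CAST congenic


@dataclass
class ExpressionExperiment:
    """Probes x samples log2 expression with per-sample factors.

    ``samples`` is indexed by sample id with columns strain, genotype
    (B = background/C57, C = congenic/CAST homozygote), tissue (B/F/L) and
    replicate. ``detection`` holds per-probe per-sample detection p-values
    and shares the matrix's shape.
    """

    matrix: pd.DataFrame
    samples: pd.DataFrame
    detection: pd.DataFrame

    def __post_init__(self) -> None:
        if self.matrix.shape != self.detection.shape:
            raise ValidationError("matrix and detection must share shape")
        if list(self.matrix.columns) != list(self.samples.index):
            raise ValidationError("matrix columns must match sample sheet index")

    def restrict_to_strain(self, strain: str) -> "ExpressionExperiment":
        keep = self.samples.index[self.samples["strain"] == strain]
        if keep.empty:
            raise ValidationError(f"no samples for strain {strain!r}")
        return ExpressionExperiment(
            self.matrix[keep], self.samples.loc[keep], self.detection[keep]
        )

    @property
    def strains(self) -> list[str]:
        return sorted(self.samples["strain"].unique())


@dataclass
class ModelFit:
    """Cell-means fit: per-probe group means and residual variance."""

    group_means: pd.DataFrame  # probes x groups
    resid_var: np.ndarray
    df: int
    n_per_group: pd.Series

    @property
    def groups(self) -> list[str]:
        return list(self.group_means.columns)


@dataclass
class ContrastResult:
    contrast_id: str
    fs: pd.Series
    p_perm: pd.Series
    q: pd.Series


def summarize_beads(
    values: Sequence[float], n_mads: float = 3.0, scaled: bool = True
) -> tuple[float, float, int]:
    """Summarize one probe's bead intensities on one array.

    Beads farther than ``n_mads`` median absolute deviations from the median
    are dropped; the mean and sample variance of the survivors are returned
    along with the surviving count. The MAD is scaled by 1.4826 by default so
    the cut corresponds to ~3 sigma under normality (``scaled=False`` uses
    the raw MAD).
    """
    x = np.asarray(values, dtype=float)
    if x.size == 0:
        raise ValidationError("no bead values")
    med = np.median(x)
    mad = np.median(np.abs(x - med))
    if scaled:
        mad *= MAD_SCALE
    # a zero MAD keeps only beads at the median (half the beads at least)
    keep = np.abs(x - med) <= n_mads * mad
    if not keep.any():
        raise ValidationError("all beads removed as outliers (degenerate probe)")
    survivors = x[keep]
    var = float(survivors.var(ddof=1)) if survivors.size > 1 else 0.0
    return float(survivors.mean()), var, int(survivors.size)


def quantile_normalize(matrix: pd.DataFrame) -> pd.DataFrame:
    """Force every array (column) onto the mean empirical distribution.

    After the transform every column, sorted, equals the row-wise mean of the
    sorted input columns; within-column rank order is preserved, and ties
    within a column receive the mean of the reference values at their tied
    ranks.
    """
    if matrix.isna().any().any():
        raise ValidationError("quantile normalization requires a complete matrix")
    if matrix.shape[1] < 2:
        return matrix.copy()
    x = matrix.to_numpy(dtype=float)
    reference = np.sort(x, axis=0).mean(axis=1)
    out = np.empty_like(x)
    grid = np.arange(x.shape[0], dtype=float)
    for j in range(x.shape[1]):
        order = np.argsort(x[:, j], kind="mergesort")
        ranks = np.empty(x.shape[0], dtype=float)
        ranks[order] = grid
        # average ranks over ties so tied inputs map to the tied-rank mean
        col = x[:, j]
        _, inv, counts = np.unique(col, return_inverse=True, return_counts=True)
        sums = np.bincount(inv, weights=ranks)
        ranks = sums[inv] / counts[inv]
        out[:, j] = np.interp(ranks, grid, reference)
    return pd.DataFrame(out, index=matrix.index, columns=matrix.columns)


def present_filter(
    detection: pd.DataFrame,
    samples: pd.DataFrame,
    alpha: float = 0.01,
    min_samples: int = 4,
) -> pd.DataFrame:
    """Per-tissue detection mask plus an ``any`` column.

    A probe is retained for a tissue iff at least ``min_samples`` samples of
    that tissue detect it at p < ``alpha``; it enters analysis if retained in
    at least one tissue.
    """
    if ((detection < 0) | (detection > 1)).any().any():
        raise ValidationError("detection p-values must lie in [0, 1]")
    tissues = sorted(samples["tissue"].unique())
    mask = pd.DataFrame(index=detection.index)
    for t in tissues:
        cols = samples.index[samples["tissue"] == t]
        mask[t] = (detection[cols] < alpha).sum(axis=1) >= min_samples
    mask["any"] = mask[tissues].any(axis=1)
    return mask


def _group_labels(samples: pd.DataFrame) -> pd.Series:
    return samples["tissue"].astype(str) + "." + samples["genotype"].astype(str)


def fit_cell_means(
    matrix: pd.DataFrame, groups: pd.Series | Sequence[str]
) -> ModelFit:
    """Fit the cell-means model per probe: group means and pooled residual
    variance with df = n_samples - n_groups."""
    groups = pd.Series(np.asarray(groups), index=matrix.columns)
    counts = groups.value_counts()
    if (counts < 1).any():
        raise ValidationError("every group must be non-empty")
    names = sorted(counts.index)
    n = matrix.shape[1]
    df = n - len(names)
    if df < 1:
        raise ValidationError(f"non-positive residual df ({n} samples, {len(names)} groups)")
    x = matrix.to_numpy(dtype=float)
    indicator = np.column_stack(
        [(groups == g).to_numpy() / counts[g] for g in names]
    )
    means = x @ indicator
    nk = counts[names].to_numpy()
    rss = (x**2).sum(axis=1) - (means**2 * nk).sum(axis=1)
    rss = np.maximum(rss, 0.0)  # guard tiny negative round-off
    return ModelFit(
        group_means=pd.DataFrame(means, index=matrix.index, columns=names),
        resid_var=rss / df,
        df=df,
        n_per_group=counts[names],
    )


def shrink_variances(
    resid_var: np.ndarray, df: int, floor: float = 1e-12
) -> np.ndarray:
    """James-Stein shrinkage of per-probe residual variances on the log scale.

    With ``X_g = ln s2_g`` and ``V = trigamma(df/2)`` (the sampling variance
    of the log of a scaled chi-square variance estimate), the shrinkage
    factor is ``B = max(0, 1 - (G-3) V / sum (X_g - Xbar)^2)`` and the
    shrunken variances are ``exp(Xbar + B (X_g - Xbar))``. The additive
    sampling bias of the log (digamma(df/2) + ln(2/df)) is common to every
    probe, so it cancels in the deviations and a homogeneous input is
    returned unchanged.
    """
    s2 = np.maximum(np.asarray(resid_var, dtype=float), floor)
    G = s2.size
    if G < 4:
        raise ValidationError("shrinkage needs at least 4 probes")
    if df < 1:
        raise ValidationError("residual df must be >= 1")
    x = np.log(s2)
    xbar = x.mean()
    ss = ((x - xbar) ** 2).sum()
    V = float(polygamma(1, df / 2.0))
    B = max(0.0, 1.0 - (G - 3) * V / ss) if ss > 0 else 0.0
    return np.exp(xbar + B * (x - xbar))


def genotype_contrasts(groups: Sequence[str]) -> dict[str, np.ndarray]:
    """Per-tissue genotype contrasts (congenic minus background) over the
    given group names, e.g. L.Geno = L.C - L.B."""
    groups = list(groups)
    contrasts = {}
    tissues = sorted({g.split(".")[0] for g in groups})
    for t in tissues:
        c = np.zeros(len(groups))
        hi, lo = f"{t}.C", f"{t}.B"
        if hi in groups and lo in groups:
            c[groups.index(hi)] = 1.0
            c[groups.index(lo)] = -1.0
            contrasts[f"{t}.Geno"] = c
    return contrasts


def contrast_fs(
    fit: ModelFit, shrunk: np.ndarray, contrast: np.ndarray
) -> np.ndarray:
    """Shrinkage F statistic for one contrast: (c.mu)^2 / (s2_shrunk * sum c_k^2/n_k).

    With shrinkage disabled (``shrunk = fit.resid_var``) this is the
    classical 1-df F. A zero denominator yields NaN rather than an overflow.
    """
    c = np.asarray(contrast, dtype=float)
    if abs(c.sum()) > 1e-9:
        raise ValidationError("contrast coefficients must sum to 0")
    num = (fit.group_means.to_numpy() @ c) ** 2
    scale = float((c**2 / fit.n_per_group.to_numpy()).sum())
    den = np.asarray(shrunk, dtype=float) * scale
    with np.errstate(divide="ignore", invalid="ignore"):
        fs = np.where(den > 0, num / den, np.nan)
    return fs


def _permute_genotypes_within_tissue(
    samples: pd.DataFrame, rng: np.random.Generator
) -> pd.Series:
    geno = samples["genotype"].copy()
    for t in samples["tissue"].unique():
        idx = samples.index[samples["tissue"] == t]
        geno.loc[idx] = rng.permutation(geno.loc[idx].to_numpy())
    return geno


def _fs_for_labels(
    matrix: pd.DataFrame,
    samples: pd.DataFrame,
    genotype: pd.Series,
    contrasts: Mapping[str, np.ndarray] | None = None,
) -> tuple[dict[str, np.ndarray], ModelFit, np.ndarray]:
    relabeled = samples.copy()
    relabeled["genotype"] = genotype
    fit = fit_cell_means(matrix, _group_labels(relabeled))
    shrunk = shrink_variances(fit.resid_var, fit.df)
    if contrasts is None:
        contrasts = genotype_contrasts(fit.groups)
    fs = {name: contrast_fs(fit, shrunk, c) for name, c in contrasts.items()}
    return fs, fit, shrunk


def permutation_pvalues(
    matrix: pd.DataFrame,
    samples: pd.DataFrame,
    n_perm: int = 1000,
    seed: int = 0,
    within_tissue: bool = True,
    pool_contrasts: bool = False,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Pooled permutation p-values for the per-tissue genotype contrasts.

    Genotype labels are permuted (within tissue by default, preserving the
    tissue structure; globally if ``within_tissue=False``) and the full
    shrinkage-F pipeline is recomputed per permutation. The null is pooled
    across all probes and permutations — per contrast by default, across the
    three contrasts with ``pool_contrasts=True`` — and each probe's p-value
    is ``(1 + #{null >= fs}) / (1 + n_null)``, so p is never zero and
    identical seeds give identical output.

    Returns (fs, p) DataFrames, probes x contrasts.
    """
    if n_perm < 1:
        raise ValidationError("n_perm must be >= 1")
    rng = np.random.default_rng(seed)
    fs_obs, fit, _ = _fs_for_labels(matrix, samples, samples["genotype"])
    names = list(fs_obs)
    G = matrix.shape[0]

    n_distinct = _count_distinct_permutations(samples, within_tissue)
    if n_distinct < n_perm:
        logger.warning(
            "only %d distinct permutations available for %d requested; "
            "sampling with replacement",
            n_distinct,
            n_perm,
        )

    null = {name: np.empty((n_perm, G)) for name in names}
    for i in range(n_perm):
        if within_tissue:
            geno = _permute_genotypes_within_tissue(samples, rng)
        else:
            geno = pd.Series(
                rng.permutation(samples["genotype"].to_numpy()), index=samples.index
            )
        fs_perm, _, _ = _fs_for_labels(matrix, samples, geno)
        for name in names:
            null[name][i] = fs_perm[name]

    p = {}
    if pool_contrasts:
        pooled = np.sort(np.concatenate([null[n].ravel() for n in names]))
        for name in names:
            p[name] = _pooled_p(fs_obs[name], pooled)
    else:
        for name in names:
            p[name] = _pooled_p(fs_obs[name], np.sort(null[name].ravel()))

    fs_df = pd.DataFrame(fs_obs, index=matrix.index)[names]
    p_df = pd.DataFrame(p, index=matrix.index)[names]
    return fs_df, p_df


def _pooled_p(fs: np.ndarray, sorted_null: np.ndarray) -> np.ndarray:
    m = sorted_null.size
    n_ge = m - np.searchsorted(sorted_null, fs, side="left")
    return (1.0 + n_ge) / (1.0 + m)


def _count_distinct_permutations(samples: pd.DataFrame, within_tissue: bool) -> int:
    def arrangements(labels: pd.Series) -> int:
        n = len(labels)
        k = int((labels == "C").sum())
        return math.comb(n, k)

    if within_tissue:
        total = 1
        for t in samples["tissue"].unique():
            total *= arrangements(samples.loc[samples["tissue"] == t, "genotype"])
        return total
    return arrangements(samples["genotype"])


def fdr_adjust(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p
    if np.any((p <= 0) | (p > 1)):
        raise ValidationError("p-values must lie in (0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def select_de_genes(
    q: pd.DataFrame,
    probe_to_gene: Mapping[str, str],
    threshold: float = 0.10,
) -> tuple[pd.Series, set[str]]:
    """Select probes at q < threshold in any tissue contrast and collapse to
    genes (a gene is selected iff any of its probes is).

    Returns (per-probe boolean Series, set of selected gene ids). Probes
    missing from the mapping are logged and excluded from gene-level counts.
    """
    selected = (q < threshold).any(axis=1)
    genes: set[str] = set()
    unmapped = 0
    for probe in q.index[selected]:
        gene = probe_to_gene.get(probe)
        if gene is None:
            unmapped += 1
            continue
        genes.add(gene)
    if unmapped:
        logger.warning("%d selected probes had no gene mapping", unmapped)
    return selected, genes


def run_strain_de(
    exp: ExpressionExperiment,
    strain: str,
    probe_to_gene: Mapping[str, str],
    n_perm: int = 1000,
    seed: int = 0,
    fdr_threshold: float = 0.10,
    detection_alpha: float = 0.01,
    detection_min_samples: int = 4,
    normalize: bool = True,
    within_tissue: bool = True,
    pool_contrasts: bool = False,
) -> tuple[pd.DataFrame, set[str]]:
    """End-to-end DE screen for one strain: normalization, present filtering,
    shrinkage-F contrasts, pooled permutation p, BH q, gene collapsing.

    Returns the per-probe result table (fs/p/q per contrast plus a
    ``selected`` flag, restricted to detected probes) and the selected gene
    set.
    """
    sub = exp.restrict_to_strain(strain)
    matrix = quantile_normalize(sub.matrix) if normalize else sub.matrix
    mask = present_filter(
        sub.detection, sub.samples, detection_alpha, detection_min_samples
    )
    matrix = matrix.loc[mask["any"]]
    fs, p = permutation_pvalues(
        matrix,
        sub.samples,
        n_perm=n_perm,
        seed=seed,
        within_tissue=within_tissue,
        pool_contrasts=pool_contrasts,
    )
    q = p.apply(lambda col: pd.Series(fdr_adjust(col.to_numpy()), index=col.index))
    selected, genes = select_de_genes(q, probe_to_gene, fdr_threshold)
    table = pd.concat(
        {
            "fs": fs,
            "p": p,
            "q": q,
        },
        axis=1,
    )
    table.columns = [f"{stat}_{name}" for stat, name in table.columns]
    table["gene_id"] = [probe_to_gene.get(pr, "") for pr in table.index]
    table["selected"] = selected
    return table, genes
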