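"""Readers and writers for the interchange formats.

BED inputs are 0-based half-open (native). Gene TSV tables may carry a
``#coords: 1-based`` header pragma and are converted on read. All writers
are lossless round-trips for their readers at full precision; the
human-readable report rounds odds ratios to 2 decimals while the JSON report
keeps full precision.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import math
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
import yaml

from .diffexpr import ExpressionExperiment
from .enrichment import EnrichmentResult, StudyRecord
from .genome import (
    DonorRegion,
    GeneAnnotation,
    GenomicInterval,
    IBDBlock,
    ValidationError,
)

STUDY_COLUMNS = [
    "study_id",
    "species",
    "design",
    "n_candidates",
    "n_platform_probes",
    "n_selected_gw",
    "n_selected_qtl",
]


def packaged_study_table() -> Path:
    """Path to the packaged 20-study meta-analysis table."""
    return Path(__file__).parent / "data" / "qtl_microarray_studies.csv"


def read_study_table(path: str | Path) -> list[StudyRecord]:
    """Read the study-metadata CSV, validating row by row."""
    df = pd.read_csv(path)
    missing = [c for c in STUDY_COLUMNS if c not in df.columns]
    if missing:
        raise ValidationError(f"{path}: missing columns {missing}")
    records = []
    for i, row in df.iterrows():
        try:
            records.append(
                StudyRecord(
                    study_id=str(row["study_id"]),
                    species=str(row["species"]),
                    design=str(row["design"]),
                    n_candidates=int(row["n_candidates"]),
                    n_platform_probes=int(row["n_platform_probes"]),
                    n_selected_gw=int(row["n_selected_gw"]),
                    n_selected_qtl=int(row["n_selected_qtl"]),
                    phenotype=str(row.get("phenotype", "")),
                    platform=str(row.get("platform", "")),
                )
            )
        except (ValidationError, ValueError) as err:
            raise ValidationError(f"{path}, row {i + 2}: {err}") from err
    return records


# ---------------------------------------------------------------- genes/BED


def write_genes_bed(genes: Iterable[GeneAnnotation], path: str | Path) -> None:
    with open(path, "w") as fh:
        for g in genes:
            fh.write(f"{g.chrom}\t{g.start}\t{g.end}\t{g.gene_id}\t0\t{g.strand}\n")


def read_genes_bed(path: str | Path) -> list[GeneAnnotation]:
    genes = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 4:
                raise ValidationError(f"{path}: BED needs >= 4 columns")
            strand = fields[5] if len(fields) >= 6 else "+"
            genes.append(
                GeneAnnotation(
                    gene_id=fields[3],
                    chrom=fields[0],
                    start=int(fields[1]),
                    end=int(fields[2]),
                    strand=strand,
                )
            )
    return genes


def read_genes_tsv(path: str | Path) -> list[GeneAnnotation]:
    """Gene table TSV (gene_id, chrom, start, end, strand); honors a
    ``#coords: 1-based`` pragma on the first line."""
    offset = 0
    with open(path) as fh:
        first = fh.readline()
        if first.lstrip("#").strip().lower() == "coords: 1-based":
            offset = 1
            df = pd.read_csv(fh, sep="\t")
        else:
            fh.seek(0)
            df = pd.read_csv(fh, sep="\t", comment="#")
    return [
        GeneAnnotation(
            gene_id=str(r.gene_id),
            chrom=str(r.chrom),
            start=int(r.start) - offset,
            end=int(r.end),
            strand=str(getattr(r, "strand", "+")),
        )
        for r in df.itertuples(index=False)
    ]


def write_regions_bed(
    regions: Iterable[DonorRegion] | Iterable[IBDBlock], path: str | Path
) -> None:
    """BED3+name for donor regions (name = strain) or IBD blocks
    (name = uninformative-SNP count)."""
    with open(path, "w") as fh:
        for r in regions:
            if isinstance(r, DonorRegion):
                iv, name = r.interval, r.strain_id
            else:
                iv, name = r.interval, str(r.n_uninformative)
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{name}\n")


def read_donor_regions_bed(path: str | Path) -> dict[str, DonorRegion]:
    out: dict[str, DonorRegion] = {}
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            chrom, start, end, name = line.rstrip("\n").split("\t")[:4]
            if name in out:
                raise ValidationError(f"{path}: duplicate donor region for {name}")
            out[name] = DonorRegion(
                name, GenomicInterval(chrom, int(start), int(end))
            )
    return out


def read_ibd_blocks_bed(path: str | Path) -> list[IBDBlock]:
    blocks = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            chrom, start, end, name = line.rstrip("\n").split("\t")[:4]
            blocks.append(
                IBDBlock(GenomicInterval(chrom, int(start), int(end)), int(name))
            )
    return blocks


# ------------------------------------------------------------------- SNPs


def write_snps_tsv(snps: pd.DataFrame, path: str | Path) -> None:
    cols = [c for c in ("chrom", "pos", "informative", "known") if c in snps.columns]
    out = snps[cols].copy()
    for c in ("informative", "known"):
        if c in out.columns:
            out[c] = out[c].astype(int)
    out.to_csv(path, sep="\t", index=False)


def read_snps_tsv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    if not {"chrom", "pos", "informative"} <= set(df.columns):
        raise ValidationError(f"{path}: SNP TSV needs chrom, pos, informative")
    df["informative"] = df["informative"].astype(bool)
    if "known" in df.columns:
        df["known"] = df["known"].astype(bool)
    return df


# ------------------------------------------------------------- expression


def write_experiment(
    exp: ExpressionExperiment, outdir: str | Path, prefix: str = ""
) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    exp.matrix.to_csv(outdir / f"{prefix}expression.tsv", sep="\t")
    exp.detection.to_csv(outdir / f"{prefix}detection.tsv", sep="\t")
    exp.samples.to_csv(outdir / f"{prefix}samples.csv")


def read_experiment(
    expression: str | Path, samples: str | Path, detection: str | Path
) -> ExpressionExperiment:
    matrix = pd.read_csv(expression, sep="\t", index_col=0)
    det = pd.read_csv(detection, sep="\t", index_col=0)
    sheet = pd.read_csv(samples, index_col=0)
    return ExpressionExperiment(matrix=matrix, samples=sheet, detection=det)


def write_probe_table(probes: pd.DataFrame, path: str | Path) -> None:
    probes.to_csv(path, sep="\t", index=False)


def read_probe_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


# ---------------------------------------------------------------- reports


def _result_dict(r: EnrichmentResult) -> dict:
    return {
        "study_id": r.study_id,
        "reference": r.reference,
        "reference_size": r.reference_size,
        "odds_ratio": "Inf" if math.isinf(r.odds_ratio) else r.odds_ratio,
        "p_value": r.p_value,
    }


def write_report(
    results: Sequence[EnrichmentResult] | dict,
    path: str | Path,
    fmt: str = "tsv",
) -> None:
    """Serialize enrichment results (or any report dict) deterministically.

    TSV is the human report (odds ratios at 2 decimals); JSON keeps full
    precision and round-trips exactly, with infinite odds ratios written as
    the string sentinel ``"Inf"``.
    """
    if results is None:
        raise ValidationError("results must not be None")
    if fmt == "json":
        if isinstance(results, dict):
            payload = results
        else:
            payload = {"results": [_result_dict(r) for r in results]}
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1, sort_keys=True)
            fh.write("\n")
        return
    if fmt != "tsv":
        raise ValidationError(f"unknown report format {fmt!r}")
    if isinstance(results, dict):
        raise ValidationError("dict reports serialize as JSON only")
    with open(path, "w") as fh:
        fh.write("study_id\treference\treference_size\todds_ratio\tp_value\n")
        for r in results:
            orr = "Inf" if math.isinf(r.odds_ratio) else f"{r.odds_ratio:.2f}"
            fh.write(
                f"{r.study_id}\t{r.reference}\t{r.reference_size}\t{orr}\t{r.p_value:.3g}\n"
            )


def read_report_json(path: str | Path) -> list[EnrichmentResult]:
    with open(path) as fh:
        payload = json.load(fh)
    out = []
    for d in payload["results"]:
        orr = d["odds_ratio"]
        out.append(
            EnrichmentResult(
                study_id=d["study_id"],
                reference=d["reference"],
                reference_size=d["reference_size"],
                odds_ratio=math.inf if orr == "Inf" else float(orr),
                p_value=d["p_value"],
            )
        )
    return out


# ------------------------------------------------------------------ config


def dump_config_yaml(config, path: str | Path) -> None:
    payload = dataclasses.asdict(config) if dataclasses.is_dataclass(config) else dict(config)
    payload = {
        k: (list(v) if isinstance(v, tuple) else v) for k, v in payload.items()
    }
    with open(path, "w") as fh:
        yaml.safe_dump(payload, fh, sort_keys=True)


def load_config_yaml(path: str | Path) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh) or {}


def write_run_manifest(outdir: str | Path, settings: dict, seed: int | None) -> None:
    """Machine-readable manifest: settings, their hash, seed, versions."""
    import numpy, scipy  # local to keep import cost at call time

    from . import __version__

    payload = {
        "settings": {k: repr(v) for k, v in sorted(settings.items())},
        "seed": seed,
        "versions": {
            "congenic": __version__,
            "numpy": numpy.__version__,
            "scipy": scipy.__version__,
            "pandas": pd.__version__,
        },
    }
    payload["settings_sha1"] = hashlib.sha1(
        json.dumps(payload["settings"], sort_keys=True).encode()
    ).hexdigest()
    with open(Path(outdir) / "run_manifest.json", "w") as fh:
        json.dump(payload, fh, indent=1, sort_keys=True)
        fh.write("\n")
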