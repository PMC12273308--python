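"""Reading, aligning and writing the tabular/genomic inputs and result artifacts.

All tables are tab-delimited with a header row and a leading sample-id column;
genotypes may alternatively come from a VCF (dosage = count of alternate
alleles from GT, or the DS field when GT is absent).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger("rumenpred")


def setup_logging(level: str = "INFO") -> None:
    logging.basicConfig(
        level=getattr(logging, level.upper()),
        format="%(asctime)s %(name)s %(levelname)s %(message)s",
    )


def _check_unique(ids, what: str) -> None:
    seen = pd.Index(ids)
    if seen.has_duplicates:
        dups = seen[seen.duplicated()].unique().tolist()
        raise ValueError(f"duplicate {what}: {dups[:5]}")


@dataclass
class GenotypeMatrix:
    """SNP dosage matrix: ``dosages[i, k]`` counts alternate alleles (0..2)."""

    sample_ids: list[str]
    snp_ids: list[str]
    dosages: np.ndarray

    def __post_init__(self) -> None:
        self.dosages = np.asarray(self.dosages, dtype=float)
        _check_unique(self.sample_ids, "sample ids")
        _check_unique(self.snp_ids, "SNP ids")
        if self.dosages.shape != (len(self.sample_ids), len(self.snp_ids)):
            raise ValueError("dosage matrix shape inconsistent with id lists")
        if np.isnan(self.dosages).any():
            raise ValueError("missing dosages after load; configure imputation")
        if self.dosages.min() < 0 or self.dosages.max() > 2:
            raise ValueError("dosages must lie in [0, 2]")

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def subset(self, sample_ids: list[str]) -> "GenotypeMatrix":
        idx = pd.Index(self.sample_ids).get_indexer(sample_ids)
        if (idx < 0).any():
            raise KeyError("unknown sample ids in subset")
        return GenotypeMatrix(list(sample_ids), list(self.snp_ids), self.dosages[idx])


@dataclass
class MicrobiomeCounts:
    """Raw tag counts per sample (non-negative integers)."""

    sample_ids: list[str]
    tag_ids: list[str]
    counts: np.ndarray

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts)
        _check_unique(self.sample_ids, "sample ids")
        _check_unique(self.tag_ids, "tag ids")
        if counts.shape != (len(self.sample_ids), len(self.tag_ids)):
            raise ValueError("count matrix shape inconsistent with id lists")
        if np.isnan(counts.astype(float)).any():
            raise ValueError("missing counts")
        if (counts < 0).any():
            raise ValueError("counts must be non-negative")
        if not np.allclose(counts, np.round(counts.astype(float))):
            raise ValueError("counts must be integral")
        self.counts = counts.astype(np.int64)

    def subset(self, sample_ids: list[str]) -> "MicrobiomeCounts":
        idx = pd.Index(self.sample_ids).get_indexer(sample_ids)
        if (idx < 0).any():
            raise KeyError("unknown sample ids in subset")
        return MicrobiomeCounts(list(sample_ids), list(self.tag_ids), self.counts[idx])


@dataclass
class PhenoTable:
    """Phenotypes plus fixed-effect classes, covariates and cohort labels.

    ``table`` is indexed by sample id.  Column roles are declared explicitly so
    downstream code never guesses which columns are class factors.
    """

    table: pd.DataFrame
    traits: list[str]
    class_cols: list[str] = field(default_factory=list)
    covariate_cols: list[str] = field(default_factory=list)
    cohort_col: str = "cohort"
    year_col: str | None = None

    def __post_init__(self) -> None:
        _check_unique(self.table.index, "sample ids")
        missing = [
            c
            for c in self.traits + self.class_cols + self.covariate_cols + [self.cohort_col]
            if c not in self.table.columns
        ]
        if missing:
            raise ValueError(f"pheno table missing columns: {missing}")
        if self.table[self.cohort_col].isna().any():
            raise ValueError("every sample needs a cohort label")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.table.index)

    def subset(self, sample_ids: list[str]) -> "PhenoTable":
        return PhenoTable(
            self.table.loc[sample_ids].copy(),
            self.traits,
            self.class_cols,
            self.covariate_cols,
            self.cohort_col,
            self.year_col,
        )


@dataclass
class AlignedDataset:
    """Genotypes, counts and phenotypes restricted to a common, ordered sample set."""

    genotypes: GenotypeMatrix
    counts: MicrobiomeCounts
    pheno: PhenoTable

    def __post_init__(self) -> None:
        ids = self.genotypes.sample_ids
        if self.counts.sample_ids != ids or self.pheno.sample_ids != ids:
            raise ValueError("sample order differs between components")
        if not ids:
            raise ValueError("empty sample set")

    @property
    def sample_ids(self) -> list[str]:
        return self.genotypes.sample_ids

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)


# ---------------------------------------------------------------------------
# readers


def _read_numeric_table(path: str | Path, what: str) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index = df.index.astype(str)
    bad = df.columns[~df.apply(lambda c: pd.to_numeric(c, errors="coerce").notna() | c.isna()).all()]
    for col in df.columns:
        coerced = pd.to_numeric(df[col], errors="coerce")
        invalid = coerced.isna() & df[col].notna()
        if invalid.any():
            row = df.index[invalid.argmax()]
            raise ValueError(f"non-numeric {what} cell at row {row!r}, column {col!r}")
        df[col] = coerced
    del bad
    return df


def read_genotypes_tsv(path: str | Path, missing: str = "error") -> GenotypeMatrix:
    """Load a samples x SNPs dosage TSV; ``missing`` in {'error', 'mean'}."""
    df = _read_numeric_table(path, "dosage")
    if df.isna().any().any():
        if missing == "mean":
            df = df.fillna(df.mean())
            logger.info("mean-imputed missing dosages in %s", path)
        else:
            raise ValueError("missing dosages (set missing='mean' to impute)")
    gm = GenotypeMatrix(list(df.index), list(df.columns), df.to_numpy(float))
    logger.info("read %d samples x %d SNPs from %s", *gm.dosages.shape, path)
    return gm


def read_genotypes_vcf(path: str | Path, missing: str = "error") -> GenotypeMatrix:
    """Dosages from VCF: alternate-allele count from GT; DS used if GT absent."""
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    snp_ids: list[str] = []
    rows: list[np.ndarray] = []
    for var in vcf:
        vid = var.ID if var.ID not in (None, ".") else f"{var.CHROM}:{var.POS}"
        snp_ids.append(vid)
        gts = var.genotype.array() if var.genotype is not None else None
        if gts is not None and not (gts[:, :2] < 0).all():
            alleles = gts[:, :2].astype(float)
            alleles[alleles < 0] = np.nan
            dose = np.nansum(np.where(np.isnan(alleles), np.nan, (alleles > 0)), axis=1)
            dose[np.isnan(alleles).all(axis=1)] = np.nan
        else:
            ds = var.format("DS")
            if ds is None:
                raise ValueError(f"variant {vid}: neither GT nor DS present")
            dose = np.asarray(ds, float).reshape(-1)
        rows.append(dose)
    dosages = np.column_stack(rows) if rows else np.empty((len(samples), 0))
    if np.isnan(dosages).any():
        if missing == "mean":
            col_means = np.nanmean(dosages, axis=0)
            nan_idx = np.where(np.isnan(dosages))
            dosages[nan_idx] = np.take(col_means, nan_idx[1])
        else:
            raise ValueError("missing genotypes in VCF (set missing='mean')")
    gm = GenotypeMatrix(samples, snp_ids, dosages)
    logger.info("read %d samples x %d variants from %s", *gm.dosages.shape, path)
    return gm


def read_counts_tsv(path: str | Path) -> MicrobiomeCounts:
    df = _read_numeric_table(path, "count")
    if df.isna().any().any():
        raise ValueError("missing counts")
    mc = MicrobiomeCounts(list(df.index), list(df.columns), df.to_numpy())
    logger.info("read %d samples x %d tags from %s", *mc.counts.shape, path)
    return mc


def read_pheno_tsv(
    path: str | Path,
    traits: list[str],
    class_cols: list[str] | None = None,
    covariate_cols: list[str] | None = None,
    cohort_col: str = "cohort",
    year_col: str | None = None,
) -> PhenoTable:
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index = df.index.astype(str)
    pt = PhenoTable(df, traits, class_cols or [], covariate_cols or [], cohort_col, year_col)
    logger.info("read %d phenotype rows from %s", len(df), path)
    return pt


def load_dataset(
    genotype_path: str | Path,
    counts_path: str | Path,
    pheno_path: str | Path,
    *,
    traits: list[str],
    class_cols: list[str] | None = None,
    covariate_cols: list[str] | None = None,
    cohort_col: str = "cohort",
    year_col: str | None = None,
    genotype_format: str = "tsv",
    genotype_missing: str = "error",
    sample_order: list[str] | None = None,
) -> AlignedDataset:
    """Read the three sources and intersect them into one canonical sample order.

    Order is sorted by sample id unless ``sample_order`` is given explicitly.
    """
    if genotype_format == "vcf":
        geno = read_genotypes_vcf(genotype_path, missing=genotype_missing)
    else:
        geno = read_genotypes_tsv(genotype_path, missing=genotype_missing)
    counts = read_counts_tsv(counts_path)
    pheno = read_pheno_tsv(
        pheno_path, traits, class_cols, covariate_cols, cohort_col, year_col
    )
    return align(geno, counts, pheno, sample_order=sample_order)


def align(
    geno: GenotypeMatrix,
    counts: MicrobiomeCounts,
    pheno: PhenoTable,
    sample_order: list[str] | None = None,
) -> AlignedDataset:
    sets = {
        "genotypes": set(geno.sample_ids),
        "counts": set(counts.sample_ids),
        "phenotypes": set(pheno.sample_ids),
    }
    common = sets["genotypes"] & sets["counts"] & sets["phenotypes"]
    if not common:
        raise ValueError("no samples shared by genotypes, counts and phenotypes")
    for name, ids in sets.items():
        dropped = ids - common
        if dropped:
            logger.warning("%s: dropping %d samples absent elsewhere", name, len(dropped))
    if sample_order is not None:
        order = [s for s in sample_order if s in common]
        if set(order) != common:
            raise ValueError("explicit sample order does not cover the intersection")
    else:
        order = sorted(common)
    return AlignedDataset(geno.subset(order), counts.subset(order), pheno.subset(order))


# ---------------------------------------------------------------------------
# writers


def write_results(result_bundle: dict, out_dir: str | Path) -> dict[str, Path]:
    """Write GEBV/metric tables plus a machine-readable run summary.

    ``result_bundle`` keys (all optional): ``gebv`` (DataFrame indexed by
    sample id), ``metrics`` (DataFrame of per-fold metrics), ``varcomps``
    (dict), ``settings`` (dict), ``seed`` (int).
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    gebv = result_bundle.get("gebv")
    if gebv is not None and len(gebv):
        p = out / "gebv.tsv"
        gebv.to_csv(p, sep="\t", float_format="%.17g", index_label="sample_id")
        paths["gebv"] = p

    metrics = result_bundle.get("metrics")
    if metrics is not None and len(metrics):
        metrics = metrics.copy()
        num = metrics.select_dtypes("number")
        summary = pd.DataFrame(
            {c: [num[c].mean(), num[c].std(ddof=1)] for c in num.columns},
            index=["mean", "sd"],
        )
        table = pd.concat([metrics, summary])
        p = out / "metrics.tsv"
        table.to_csv(p, sep="\t", float_format="%.17g", index_label="fold")
        paths["metrics"] = p

    if not paths:
        logger.warning("empty result bundle: writing run summary only")

    summary_payload = {
        "varcomps": result_bundle.get("varcomps"),
        "settings": result_bundle.get("settings"),
        "seed": result_bundle.get("seed"),
        "tables": {k: str(v) for k, v in paths.items()},
    }
    p = out / "run_summary.json"
    p.write_text(json.dumps(summary_payload, indent=2, default=str))
    paths["summary"] = p
    return paths


def read_gebv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col="sample_id")
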