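"""File ingestion and result export.

Phenotype/covariate tables are TSV (or CSV) with a header row and one row per
individual; genotypes come either from a dosage TSV (individuals x variants,
entries 0/1/2) or from a biallelic VCF read through cyvcf2.  Ingestion
enforces two conventions stated in :mod:`wchc.data`: complete cases only for
phenotypes (dropped rows are counted, never imputed) and minor-allele
orientation for genotypes (dosages are flipped, with a log message, whenever
the counted allele has in-sample frequency above one half).
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .data import AssociationResult, CovariateMatrix, GenotypeVector, PhenotypeMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "read_phenotype_table",
    "read_covariate_table",
    "read_genotypes",
    "write_phenotype_table",
    "write_results",
]

MISSING_TSV = {"", "NA", "NaN", "nan", ".", "na"}


def _read_table(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    sep = "," if path.suffix.lower() == ".csv" else "\t"
    return pd.read_csv(path, sep=sep, na_values=list(MISSING_TSV), dtype=str)


def read_phenotype_table(
    path: str | Path,
    id_column: str | None = None,
    phenotype_columns: list[str] | None = None,
) -> PhenotypeMatrix:
    """Read a phenotype TSV/CSV into a complete-case :class:`PhenotypeMatrix`.

    Rows with any missing or non-numeric phenotype value are excluded; the
    exclusion count is logged and carried on the returned matrix.  ``id_column``
    defaults to the first column.
    """
    df = _read_table(path)
    if id_column is None:
        id_column = df.columns[0]
    if id_column not in df.columns:
        raise KeyError(f"id column {id_column!r} not found in {path}")
    if phenotype_columns is None:
        phenotype_columns = [c for c in df.columns if c != id_column]
    missing = [c for c in phenotype_columns if c not in df.columns]
    if missing:
        raise KeyError(f"phenotype columns {missing} not found in {path}")

    probe = df[phenotype_columns].apply(pd.to_numeric, errors="coerce")
    keep = probe.notna().all(axis=1)
    n_excluded = int((~keep).sum())
    if n_excluded:
        logger.info("%s: excluded %d incomplete rows", path, n_excluded)
    if int(keep.sum()) < 2:
        raise ValueError(f"{path}: fewer than 2 complete rows")
    # parse kept rows with numpy's correctly-rounded conversion (round-trip safe)
    vals = df.loc[keep, phenotype_columns].to_numpy(str).astype(np.float64)
    return PhenotypeMatrix(
        values=vals,
        phenotype_names=list(phenotype_columns),
        individual_ids=df.loc[keep, id_column].astype(str).tolist(),
        n_excluded=n_excluded,
    )


def read_covariate_table(
    path: str | Path,
    id_column: str | None = None,
    covariate_columns: list[str] | None = None,
    individual_ids: list[str] | None = None,
) -> CovariateMatrix:
    """Read covariates, dummy-encoding non-numeric columns.

    If ``individual_ids`` is given the rows are aligned to that order by id
    join; individuals without a complete covariate row raise, mirroring the
    complete-case policy.
    """
    df = _read_table(path)
    if id_column is None:
        id_column = df.columns[0]
    if covariate_columns is None:
        covariate_columns = [c for c in df.columns if c != id_column]
    sub = df.set_index(df[id_column].astype(str))[covariate_columns]
    if individual_ids is not None:
        absent = [i for i in individual_ids if i not in sub.index]
        if absent:
            raise ValueError(f"covariate rows missing for individuals {absent[:5]}")
        sub = sub.loc[individual_ids]
    num = sub.apply(pd.to_numeric, errors="coerce")
    cols = []
    names: list[str] = []
    for c in covariate_columns:
        if num[c].notna().all():
            cols.append(num[c].to_numpy(float))
            names.append(c)
        else:  # categorical -> dummy encode, dropping the first level
            dummies = pd.get_dummies(sub[c].astype(str), prefix=c, drop_first=True)
            for dc in dummies.columns:
                cols.append(dummies[dc].to_numpy(float))
                names.append(dc)
    values = np.column_stack(cols) if cols else np.empty((len(sub), 0))
    if not np.isfinite(values).all():
        raise ValueError(f"{path}: missing covariate values")
    return CovariateMatrix(values=values, covariate_names=names)


def _orient_minor(counts: np.ndarray, variant_id: str) -> np.ndarray:
    """Flip dosages so the counted allele is the in-sample minor allele."""
    if counts.mean() / 2.0 > 0.5:
        logger.info(
            "%s: counted allele is major in-sample; flipping to minor-allele dosage",
            variant_id,
        )
        counts = 2 - counts
    return counts


def _genotypes_from_tsv(
    path: Path, variant_ids: list[str] | None, individual_ids: list[str] | None
) -> list[GenotypeVector]:
    df = _read_table(path)
    id_col = df.columns[0]
    df = df.set_index(df[id_col].astype(str)).drop(columns=[id_col])
    if variant_ids is None:
        variant_ids = list(df.columns)
    unknown = [v for v in variant_ids if v not in df.columns]
    if unknown:
        raise KeyError(f"unknown variant ids {unknown} in {path}")
    out = []
    for vid in variant_ids:
        col = pd.to_numeric(df[vid], errors="coerce")
        if individual_ids is not None:
            col = col.reindex(individual_ids)
        keep = col.notna()
        vals = col[keep].to_numpy(float)
        if not np.isin(vals, (0, 1, 2)).all():
            raise ValueError(f"{path}:{vid}: dosage entries must be 0/1/2 or missing")
        counts = _orient_minor(vals.astype(np.int8), vid)
        out.append(
            GenotypeVector(
                counts=counts,
                variant_id=vid,
                individual_ids=list(col[keep].index.astype(str)),
            )
        )
    return out


def _genotypes_from_vcf(
    path: Path, variant_ids: list[str] | None, individual_ids: list[str] | None
) -> list[GenotypeVector]:
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = [str(s) for s in vcf.samples]
    wanted = set(variant_ids) if variant_ids is not None else None
    found: dict[str, GenotypeVector] = {}
    for rec in vcf:
        vid = rec.ID or f"{rec.CHROM}:{rec.POS}"
        if wanted is not None and vid not in wanted:
            continue
        if len(rec.ALT) != 1:
            raise ValueError(f"{path}:{vid}: non-biallelic record")
        alt_counts = np.full(len(samples), -1, dtype=np.int8)
        for i, gt in enumerate(rec.genotypes):
            a, b = gt[0], gt[1]
            if a < 0 or b < 0:
                continue  # missing; excluded for this variant only
            alt_counts[i] = int(a > 0) + int(b > 0)
        present = alt_counts >= 0
        ids = [s for s, p in zip(samples, present) if p]
        counts = _orient_minor(alt_counts[present], vid)
        gv = GenotypeVector(counts=counts, variant_id=vid, individual_ids=ids)
        found[vid] = gv
    if wanted is not None:
        unknown = sorted(wanted - set(found))
        if unknown:
            raise KeyError(f"unknown variant ids {unknown} in {path}")
        ordered = [found[v] for v in variant_ids]
    else:
        ordered = list(found.values())
    if individual_ids is not None:
        ordered = [_align(gv, individual_ids) for gv in ordered]
    return ordered


def _align(gv: GenotypeVector, individual_ids: list[str]) -> GenotypeVector:
    """Subset/reorder a genotype vector to the given individual order.

    Individuals missing a genotype are dropped pairwise for that variant.
    """
    pos = {s: i for i, s in enumerate(gv.individual_ids or [])}
    keep = [s for s in individual_ids if s in pos]
    idx = [pos[s] for s in keep]
    return GenotypeVector(
        counts=gv.counts[idx], variant_id=gv.variant_id, individual_ids=keep
    )


def read_genotypes(
    path: str | Path,
    variant_ids: list[str] | None = None,
    individual_ids: list[str] | None = None,
) -> list[GenotypeVector]:
    """Read genotype vectors from a dosage TSV or a VCF.

    VCF alternate-allele counts are flipped to minor-allele dosage when the
    alternate allele is the in-sample major allele.  When ``individual_ids``
    is supplied (typically the phenotype row order) vectors are aligned to it
    by id join; individuals without a called genotype are dropped for that
    variant only.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if path.suffix.lower() in {".vcf", ".gz", ".bcf"} or path.name.endswith(".vcf.gz"):
        return _genotypes_from_vcf(path, variant_ids, individual_ids)
    return _genotypes_from_tsv(path, variant_ids, individual_ids)


def write_phenotype_table(phenotypes: PhenotypeMatrix, path: str | Path) -> None:
    df = pd.DataFrame(
        phenotypes.values,
        columns=phenotypes.phenotype_names,
        index=pd.Index(phenotypes.individual_ids, name="individual_id"),
    )
    df.to_csv(path, sep="\t", float_format="%.17g")


def write_results(results: list[AssociationResult], path: str | Path) -> None:
    """Export association results to TSV, padding cluster p-value columns."""
    kmax = max(r.K for r in results)
    rows = []
    for r in results:
        row = {"variant_id": r.variant_id, "K": r.K}
        for k in range(kmax):
            row[f"p_{k + 1}"] = r.cluster_pvalues[k] if k < r.K else np.nan
        row.update(
            {"T_WCHC": r.t_wchc, "pvalue": r.pvalue, "B": r.B, "seed": r.seed}
        )
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False, float_format="%.10g")
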