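"""Core data containers, file readers/writers and dataset merging.

The pipeline operates on four aligned tables:

* a genotype matrix of minor-allele dosages (0/1/2, missing allowed),
* a subject table with case/control status and covariates,
* a SNP annotation mapping each SNP to a gene region,
* a pathway map allocating gene regions to one or more pathways.

Dosages are stored as a float DataFrame with ``NaN`` marking missing calls;
every analysis drops missing subjects listwise per SNP.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

__all__ = [
    "GenotypeMatrix",
    "SubjectTable",
    "SnpAnnotation",
    "PathwayMap",
    "Dataset",
    "MergeReport",
    "GenotypeParseError",
    "ValidationError",
    "read_genotypes",
    "write_genotypes",
    "read_subjects",
    "read_snp_annotation",
    "read_pathway_map",
    "merge_dataset",
    "write_results_table",
]


class GenotypeParseError(ValueError):
    """A genotype file cell could not be interpreted as a dosage."""


class ValidationError(ValueError):
    """A container invariant is violated (duplicates, misalignment, ...)."""


def _check_unique(ids: Iterable[str], what: str) -> pd.Index:
    idx = pd.Index(ids)
    if idx.has_duplicates:
        dups = idx[idx.duplicated()].unique().tolist()
        raise ValidationError(f"duplicate {what}: {dups[:5]}")
    return idx


@dataclasses.dataclass
class GenotypeMatrix:
    """Subjects x SNPs minor-allele dosage matrix.

    ``dosages`` is a float DataFrame indexed by subject id with SNP-id
    columns; entries are 0.0, 1.0, 2.0 or NaN (missing).
    """

    dosages: pd.DataFrame

    def __post_init__(self) -> None:
        _check_unique(self.dosages.index, "subject ids")
        _check_unique(self.dosages.columns, "snp ids")
        vals = self.dosages.to_numpy(dtype=float)
        bad = ~(np.isnan(vals) | np.isin(vals, (0.0, 1.0, 2.0)))
        if bad.any():
            i, j = map(int, np.argwhere(bad)[0])
            raise ValidationError(
                f"dosage out of range at subject {self.dosages.index[i]!r}, "
                f"SNP {self.dosages.columns[j]!r}: {vals[i, j]!r}"
            )

    @property
    def subject_ids(self) -> pd.Index:
        return self.dosages.index

    @property
    def snp_ids(self) -> pd.Index:
        return self.dosages.columns

    @property
    def shape(self) -> tuple[int, int]:
        return self.dosages.shape

    def values(self) -> np.ndarray:
        """Dosages as a float ndarray (NaN = missing)."""
        return self.dosages.to_numpy(dtype=float)


@dataclasses.dataclass
class SubjectTable:
    """Per-subject phenotype and covariates.

    Required columns: ``status`` (0=control, 1=case), ``sex`` ("F"/"M"),
    ``birth_year`` (integer). Optional: ``age`` (attained age for cases /
    referent age for controls; NaN until assigned), ``thyroiditis``
    (0/1/NaN) and arbitrary extra covariates.
    """

    table: pd.DataFrame
    birth_year_bounds: tuple[int, int] = (1900, 2010)

    REQUIRED = ("status", "sex", "birth_year")

    def __post_init__(self) -> None:
        _check_unique(self.table.index, "subject ids")
        missing = [c for c in self.REQUIRED if c not in self.table.columns]
        if missing:
            raise ValidationError(f"subject table missing columns: {missing}")
        status = self.table["status"]
        if not status.isin((0, 1)).all():
            raise ValidationError("status must be 0 (control) or 1 (case)")
        sex = self.table["sex"]
        if not sex.isin(("F", "M")).all():
            raise ValidationError("sex must be 'F' or 'M'")
        by = self.table["birth_year"]
        lo, hi = self.birth_year_bounds
        if ((by < lo) | (by > hi)).any():
            raise ValidationError(f"birth_year outside [{lo}, {hi}]")

    @property
    def subject_ids(self) -> pd.Index:
        return self.table.index

    def cases(self) -> pd.DataFrame:
        return self.table[self.table["status"] == 1]

    def controls(self) -> pd.DataFrame:
        return self.table[self.table["status"] == 0]


@dataclasses.dataclass
class SnpAnnotation:
    """SNP id -> gene region (plus optional band and 1-based position)."""

    table: pd.DataFrame

    def __post_init__(self) -> None:
        _check_unique(self.table.index, "snp ids")
        if "gene_region" not in self.table.columns:
            raise ValidationError("annotation requires a gene_region column")
        if self.table["gene_region"].isna().any():
            bad = self.table.index[self.table["gene_region"].isna()].tolist()
            raise ValidationError(f"SNPs without gene_region: {bad[:5]}")

    @property
    def snp_ids(self) -> pd.Index:
        return self.table.index

    def region_of(self, snp_id: str) -> str:
        return str(self.table.loc[snp_id, "gene_region"])

    def snps_by_region(self) -> dict[str, list[str]]:
        groups: dict[str, list[str]] = {}
        for snp, region in self.table["gene_region"].items():
            groups.setdefault(str(region), []).append(str(snp))
        return groups


# Pathway universe of the immune candidate-gene study; extensible.
DEFAULT_PATHWAYS = (
    "adhesion-extravasation-migration",
    "arachidonic acid metabolism/eicosanoid signaling",
    "complement and coagulation cascade",
    "cytokine signaling",
    "innate pathogen detection and antimicrobials",
    "leukocyte signaling",
    "TNF/NF-kB signaling",
    "other",
)


@dataclasses.dataclass
class PathwayMap:
    """Gene region -> non-empty set of pathways (multi-allocation allowed)."""

    mapping: dict[str, frozenset[str]]
    universe: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        clean: dict[str, frozenset[str]] = {}
        for region, pws in self.mapping.items():
            pws = frozenset(pws)
            if not pws:
                raise ValidationError(f"gene region {region!r} has no pathway")
            if self.universe is not None:
                unknown = pws - set(self.universe)
                if unknown:
                    raise ValidationError(
                        f"unknown pathways for {region!r}: {sorted(unknown)}"
                    )
            clean[region] = pws
        self.mapping = clean

    @property
    def regions(self) -> list[str]:
        return list(self.mapping)

    @property
    def pathways(self) -> list[str]:
        seen: list[str] = []
        for pws in self.mapping.values():
            for p in sorted(pws):
                if p not in seen:
                    seen.append(p)
        return seen

    def regions_by_pathway(self, drop_overlap: bool = False) -> dict[str, list[str]]:
        """Pathway -> member regions; ``drop_overlap`` removes multi-allocated
        regions from every pathway (the "without overlap" variant)."""
        out: dict[str, list[str]] = {}
        for region, pws in self.mapping.items():
            if drop_overlap and len(pws) > 1:
                continue
            for p in pws:
                out.setdefault(p, []).append(region)
        return out

    def multi_allocated(self) -> list[str]:
        return [r for r, pws in self.mapping.items() if len(pws) > 1]


@dataclasses.dataclass
class MergeReport:
    n_subjects_dropped: int
    n_snps_dropped: int
    dropped_subjects: list[str]
    dropped_snps: list[str]


@dataclasses.dataclass
class Dataset:
    """Index-aligned bundle of genotypes, subjects, annotation and pathways."""

    genotypes: GenotypeMatrix
    subjects: SubjectTable
    annotation: SnpAnnotation
    pathways: PathwayMap
    merge_report: MergeReport | None = None

    def __post_init__(self) -> None:
        if not self.genotypes.subject_ids.equals(self.subjects.subject_ids):
            raise ValidationError("genotype/subject ids are not aligned")
        if not self.genotypes.snp_ids.equals(self.annotation.snp_ids):
            raise ValidationError("genotype/annotation SNP ids are not aligned")
        regions = set(self.annotation.table["gene_region"].astype(str))
        unmapped = regions - set(self.pathways.mapping)
        if unmapped:
            raise ValidationError(
                f"gene regions with no pathway allocation: {sorted(unmapped)[:5]}"
            )

    @property
    def n_subjects(self) -> int:
        return self.genotypes.shape[0]

    @property
    def n_snps(self) -> int:
        return self.genotypes.shape[1]

    @property
    def status(self) -> np.ndarray:
        return self.subjects.table["status"].to_numpy(dtype=int)

    def snps_by_region(self) -> dict[str, list[str]]:
        return self.annotation.snps_by_region()


# ---------------------------------------------------------------------------
# readers / writers


def _parse_tsv_genotypes(path: Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype=str, index_col=0)
    out = pd.DataFrame(index=df.index, columns=df.columns, dtype=float)
    for col in df.columns:
        for row, cell in df[col].items():
            if cell is None or (isinstance(cell, float) and np.isnan(cell)) or cell == "NA":
                out.loc[row, col] = np.nan
            elif cell in ("0", "1", "2"):
                out.loc[row, col] = float(cell)
            else:
                raise GenotypeParseError(
                    f"invalid dosage {cell!r} at subject {row!r}, SNP {col!r}"
                )
    return out


def _fast_tsv_genotypes(path: Path) -> pd.DataFrame:
    # vectorised fast path; falls back to the cell-by-cell parser for the
    # error message naming the offending cell
    df = pd.read_csv(path, sep="\t", index_col=0, na_values=["NA"], keep_default_na=False)
    vals = df.to_numpy()
    try:
        vals = vals.astype(float)
    except (TypeError, ValueError):
        return _parse_tsv_genotypes(path)
    if not (np.isnan(vals) | np.isin(vals, (0.0, 1.0, 2.0))).all():
        return _parse_tsv_genotypes(path)
    return pd.DataFrame(vals, index=df.index.astype(str), columns=df.columns.astype(str))


def _read_vcf_genotypes(path: Path) -> pd.DataFrame:
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    snp_ids: list[str] = []
    cols: list[np.ndarray] = []
    for i, variant in enumerate(vcf):
        # gt_types: 0=hom-ref, 1=het, 3=hom-alt, 2=unknown
        gts = np.asarray(variant.gt_types, dtype=float)
        alt_dosage = np.where(gts == 0, 0.0, np.where(gts == 1, 1.0, np.where(gts == 3, 2.0, np.nan)))
        ok = ~np.isnan(alt_dosage)
        if ok.sum() == 0:
            alt_freq = 0.0
        else:
            alt_freq = alt_dosage[ok].sum() / (2.0 * ok.sum())
        # minor allele from the sample frequency; ties go to ALT
        dosage = alt_dosage if alt_freq <= 0.5 else 2.0 - alt_dosage
        snp_ids.append(variant.ID or f"{variant.CHROM}:{variant.POS}")
        cols.append(dosage)
    if not cols:
        return pd.DataFrame(index=pd.Index(samples), columns=pd.Index([]), dtype=float)
    mat = np.column_stack(cols)
    return pd.DataFrame(mat, index=pd.Index(samples), columns=pd.Index(snp_ids))


def read_genotypes(path: str | Path, format: str = "tsv") -> GenotypeMatrix:
    """Read a genotype matrix from TSV (subjects x SNPs, cells 0/1/2/NA)
    or VCF (diploid GT converted to minor-allele dosage, minor allele
    determined per site from the sample allele frequency, ties toward ALT).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format == "tsv":
        return GenotypeMatrix(_fast_tsv_genotypes(path))
    if format == "vcf":
        return GenotypeMatrix(_read_vcf_genotypes(path))
    raise ValueError(f"unknown genotype format {format!r}")


def write_genotypes(g: GenotypeMatrix, path: str | Path) -> None:
    df = g.dosages.copy()
    out = df.map(lambda v: "NA" if pd.isna(v) else str(int(v)))
    out.index.name = "subject_id"
    out.to_csv(path, sep="\t")


def read_subjects(path: str | Path, **kwargs) -> SubjectTable:
    df = pd.read_csv(path, sep="\t", index_col=0, dtype={"sex": str})
    df.index = df.index.astype(str)
    return SubjectTable(df, **kwargs)


def write_subjects(s: SubjectTable, path: str | Path) -> None:
    df = s.table.copy()
    df.index.name = "subject_id"
    df.to_csv(path, sep="\t")


def read_snp_annotation(path: str | Path) -> SnpAnnotation:
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    df.index = df.index.astype(str)
    if "position" in df.columns:
        df["position"] = pd.to_numeric(df["position"], errors="coerce")
    return SnpAnnotation(df)


def write_snp_annotation(a: SnpAnnotation, path: str | Path) -> None:
    df = a.table.copy()
    df.index.name = "snp_id"
    df.to_csv(path, sep="\t")


def read_pathway_map(path: str | Path, universe: tuple[str, ...] | None = None) -> PathwayMap:
    """Two-column TSV (gene_region, pathway), repeated rows for
    multi-allocation."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    if df.shape[1] < 2:
        raise ValidationError("pathway map needs gene_region and pathway columns")
    mapping: dict[str, set[str]] = {}
    for region, pathway in zip(df.iloc[:, 0], df.iloc[:, 1]):
        mapping.setdefault(str(region), set()).add(str(pathway))
    return PathwayMap({r: frozenset(p) for r, p in mapping.items()}, universe=universe)


def write_pathway_map(p: PathwayMap, path: str | Path) -> None:
    rows = [
        {"gene_region": region, "pathway": pw}
        for region, pws in p.mapping.items()
        for pw in sorted(pws)
    ]
    pd.DataFrame(rows, columns=["gene_region", "pathway"]).to_csv(path, sep="\t", index=False)


def merge_dataset(
    g: GenotypeMatrix,
    s: SubjectTable,
    a: SnpAnnotation,
    p: PathwayMap,
    how: str = "inner",
) -> Dataset:
    """Align the four components into a Dataset.

    ``how='inner'`` keeps the subject-id intersection (drop counts go in the
    merge report); ``how='strict'`` requires identical id sets.
    """
    g_ids, s_ids = g.subject_ids, s.subject_ids
    common = g_ids.intersection(s_ids)
    if len(common) == 0:
        raise ValidationError("no subjects in common between genotypes and subject table")
    if how == "strict" and (len(common) != len(g_ids) or len(common) != len(s_ids)):
        raise ValidationError("strict merge: subject id sets differ")
    if how not in ("inner", "strict"):
        raise ValueError(f"unknown merge policy {how!r}")

    keep_subjects = g_ids[g_ids.isin(common)]  # preserve genotype order
    dropped_subjects = sorted(set(g_ids).symmetric_difference(s_ids))

    annotated = g.snp_ids[g.snp_ids.isin(a.snp_ids)]
    un_annotated = [x for x in g.snp_ids if x not in set(a.snp_ids)]
    if un_annotated:
        raise ValidationError(f"SNPs with no gene_region annotation: {un_annotated[:5]}")
    dropped_snps: list[str] = sorted(set(a.snp_ids) - set(g.snp_ids))

    report = MergeReport(
        n_subjects_dropped=len(dropped_subjects),
        n_snps_dropped=len(dropped_snps),
        dropped_subjects=dropped_subjects,
        dropped_snps=dropped_snps,
    )
    return Dataset(
        genotypes=GenotypeMatrix(g.dosages.loc[keep_subjects, annotated]),
        subjects=SubjectTable(s.table.loc[keep_subjects], birth_year_bounds=s.birth_year_bounds),
        annotation=SnpAnnotation(a.table.loc[annotated]),
        pathways=p,
        merge_report=report,
    )


# ---------------------------------------------------------------------------
# result tables

_SNP_COLUMNS = [
    "gene_region", "snp_id", "genotype", "cases_n", "cases_pct",
    "controls_n", "controls_pct", "odds_ratio", "ci_lower", "ci_upper",
    "p_trend", "p_fdr",
]
_REGION_COLUMNS = ["gene_region", "chromosome_band", "n_snps", "p_region", "p_region_fdr"]
_PATHWAY_COLUMNS = [
    "pathway", "p_with_overlap", "n_genes_with_overlap",
    "p_without_overlap", "n_genes_without_overlap",
]


def write_results_table(rows: list[Mapping], path: str | Path, table_kind: str) -> None:
    """Write SNP / region / pathway result records as TSV mirroring the
    study's report layouts (three genotype rows with counts, OR, CI and a
    trend p per SNP; one row per region with the SNP count; one row per
    pathway with with/without-overlap p-values and gene counts)."""
    columns = {"snp": _SNP_COLUMNS, "region": _REGION_COLUMNS, "pathway": _PATHWAY_COLUMNS}.get(table_kind)
    if columns is None:
        raise ValueError(f"unknown table kind {table_kind!r}")
    df = pd.DataFrame(list(rows), columns=columns)
    df.to_csv(path, sep="\t", index=False)
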