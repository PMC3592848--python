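"""End-to-end orchestration: simulate/load -> QC -> association -> FDR ->
LD -> ARTP, with a manifest recording seeds, thresholds, row counts and
output checksums so a rerun with the same config is byte-identical."""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml

from . import association, data_model, ld, multiplicity, qc, synthetic_cohort
from .artp import TruncationSet, build_permutation_matrix, pathway_analysis
from .association import ModelSpec
from .data_model import Dataset, write_results_table

logger = logging.getLogger("pathassoc")

__all__ = ["RunConfig", "run_pipeline", "association_table", "load_run_config"]


@dataclasses.dataclass
class RunConfig:
    out_dir: Path
    seed: int = 0
    # either simulate (None paths) or load the four input files
    genotypes_path: Path | None = None
    subjects_path: Path | None = None
    annotation_path: Path | None = None
    pathway_map_path: Path | None = None
    simulate: bool = True
    qc_config: qc.QcConfig = dataclasses.field(default_factory=qc.QcConfig)
    model_spec: ModelSpec = dataclasses.field(default_factory=ModelSpec)
    fdr_m: int | None = None
    artp_B: int = 500
    artp_adjusted_in_permutations: bool = False
    ld_region: str | None = None
    log_level: str = "INFO"


def load_run_config(path: str | Path) -> RunConfig:
    raw: dict[str, Any] = yaml.safe_load(Path(path).read_text()) or {}
    qc_cfg = qc.QcConfig(**raw.pop("qc", {}))
    spec = ModelSpec(**raw.pop("model", {}))
    for key in ("genotypes_path", "subjects_path", "annotation_path", "pathway_map_path"):
        if key in raw and raw[key] is not None:
            raw[key] = Path(raw[key])
    raw["out_dir"] = Path(raw["out_dir"])
    return RunConfig(qc_config=qc_cfg, model_spec=spec, **raw)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _genotype_counts(dosage: np.ndarray, status: np.ndarray):
    out = {}
    for label, grp in (("cases", 1), ("controls", 0)):
        v = dosage[status == grp]
        v = v[~np.isnan(v)]
        counts = [int((v == k).sum()) for k in (0, 1, 2)]
        total = max(sum(counts), 1)
        out[label] = [(c, 100.0 * c / total) for c in counts]
    return out["cases"], out["controls"]


def association_table(dataset: Dataset, spec: ModelSpec, fdr_m: int | None = None) -> pd.DataFrame:
    """Per-SNP trend test + genotype-category ORs + BH-FDR, one tidy frame."""
    rows = []
    G = dataset.genotypes.dosages
    status = dataset.status
    for snp in G.columns:
        g = G[snp].to_numpy(dtype=float)
        or_allele, ci_allele, p_trend, _ = association.trend_test(g, dataset, spec)
        or_het, ci_het, or_hom, ci_hom, _ = association.genotype_category_or(g, dataset, spec)
        cases, controls = _genotype_counts(g, status)
        rows.append({
            "snp_id": snp,
            "gene_region": dataset.annotation.region_of(snp),
            "cases_counts": cases,
            "controls_counts": controls,
            "per_allele_or": or_allele,
            "per_allele_ci": ci_allele,
            "p_trend": p_trend,
            "or_het": or_het, "ci_het": ci_het,
            "or_hom": or_hom, "ci_hom": ci_hom,
        })
    df = pd.DataFrame(rows)
    ok = df["p_trend"].notna()
    q = np.full(len(df), np.nan)
    if ok.any():
        q[ok.to_numpy()] = multiplicity.bh_adjust(df.loc[ok, "p_trend"].to_numpy(), m=fdr_m)
    df["p_fdr"] = q
    return df


def _snp_records(df: pd.DataFrame) -> list[dict]:
    genotype_labels = ("common_hom", "het", "variant_hom")
    records = []
    for _, row in df.iterrows():
        ors = [(1.0, (None, None)), (row["or_het"], row["ci_het"]), (row["or_hom"], row["ci_hom"])]
        for gi, label in enumerate(genotype_labels):
            or_, ci = ors[gi]
            records.append({
                "gene_region": row["gene_region"],
                "snp_id": row["snp_id"],
                "genotype": label,
                "cases_n": row["cases_counts"][gi][0],
                "cases_pct": round(row["cases_counts"][gi][1], 1),
                "controls_n": row["controls_counts"][gi][0],
                "controls_pct": round(row["controls_counts"][gi][1], 1),
                "odds_ratio": or_,
                "ci_lower": None if ci is None or ci[0] is None else ci[0],
                "ci_upper": None if ci is None or ci[1] is None else ci[1],
                "p_trend": row["p_trend"] if gi == 2 else None,
                "p_fdr": row["p_fdr"] if gi == 2 else None,
            })
    return records


def run_pipeline(config: RunConfig) -> dict:
    """Run every stage and return the manifest (also written as
    manifest.json in the output directory)."""
    logging.basicConfig(level=config.log_level)
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict[str, Any] = {"seed": config.seed, "stages": [], "files": {}}

    def record(stage: str, **info):
        manifest["stages"].append({"stage": stage, **info})
        logger.info("stage %s done: %s", stage, info)

    def save(path: Path):
        manifest["files"][path.name] = _sha256(path)

    try:
        # 1. acquire data
        if config.simulate:
            cohort_cfg = synthetic_cohort.default_config()
            dataset = synthetic_cohort.simulate_cohort(cohort_cfg, seed=config.seed)
        else:
            g = data_model.read_genotypes(config.genotypes_path, format="tsv")
            s = data_model.read_subjects(config.subjects_path)
            a = data_model.read_snp_annotation(config.annotation_path)
            p = data_model.read_pathway_map(config.pathway_map_path)
            dataset = data_model.merge_dataset(g, s, a, p)
        record("data", n_subjects=dataset.n_subjects, n_snps=dataset.n_snps)

        # 2. QC
        dataset, qc_report = qc.apply_qc(dataset, config.qc_config)
        qc_path = out / "qc_report.tsv"
        qc_report.to_frame().to_csv(qc_path, sep="\t", index=False)
        save(qc_path)
        record("qc", n_subjects=dataset.n_subjects, n_snps=dataset.n_snps,
               exclusions=qc_report.counts())

        # 3. association + FDR
        assoc_df = association_table(dataset, config.model_spec, fdr_m=config.fdr_m)
        snp_path = out / "snp_results.tsv"
        write_results_table(_snp_records(assoc_df), snp_path, "snp")
        save(snp_path)
        record("association", n_snps=len(assoc_df))

        # 4. LD (first gene region by default)
        region = config.ld_region or sorted(dataset.snps_by_region())[0]
        ld_df = ld.pairwise_ld(dataset, region=region)
        ld_path = out / f"ld_{region}.tsv"
        ld_df.to_csv(ld_path, sep="\t", index=False)
        save(ld_path)
        record("ld", region=region, n_pairs=len(ld_df))

        # 5-6. ARTP with and without overlap, sharing one permutation layer
        M = build_permutation_matrix(
            dataset, B=config.artp_B, spec=config.model_spec, seed=config.seed,
            adjusted_in_permutations=config.artp_adjusted_in_permutations,
        )
        res_with = pathway_analysis(dataset, B=config.artp_B, seed=config.seed,
                                    spec=config.model_spec, overlap="with", snp_matrix=M)
        res_without = pathway_analysis(dataset, B=config.artp_B, seed=config.seed,
                                       spec=config.model_spec, overlap="without", snp_matrix=M)

        region_rows = []
        region_p = {r: res.p for r, res in res_with.region_results.items()}
        region_q = multiplicity.bh_adjust(list(region_p.values()))
        snps_by_region = dataset.snps_by_region()
        for (r, p_r), q_r in zip(region_p.items(), region_q):
            region_rows.append({
                "gene_region": r, "chromosome_band": "",
                "n_snps": len(snps_by_region[r]), "p_region": p_r, "p_region_fdr": q_r,
            })
        region_path = out / "region_results.tsv"
        write_results_table(region_rows, region_path, "region")
        save(region_path)
        record("artp_region", n_regions=len(region_rows))

        pathway_rows = []
        for pw in sorted(set(res_with.pathway_results) | set(res_without.pathway_results)):
            with_res = res_with.pathway_results.get(pw)
            wo_res = res_without.pathway_results.get(pw)
            pathway_rows.append({
                "pathway": pw,
                "p_with_overlap": None if with_res is None else with_res.p,
                "n_genes_with_overlap": res_with.n_genes_per_pathway.get(pw, 0),
                "p_without_overlap": None if wo_res is None else wo_res.p,
                "n_genes_without_overlap": res_without.n_genes_per_pathway.get(pw, 0),
            })
        pathway_rows.append({
            "pathway": "overall",
            "p_with_overlap": res_with.overall.p,
            "n_genes_with_overlap": sum(res_with.n_genes_per_pathway.values()),
            "p_without_overlap": res_without.overall.p,
            "n_genes_without_overlap": sum(res_without.n_genes_per_pathway.values()),
        })
        pathway_path = out / "pathway_results.tsv"
        write_results_table(pathway_rows, pathway_path, "pathway")
        save(pathway_path)
        record("artp_pathway", n_pathways=len(pathway_rows) - 1,
               overall_p_with=res_with.overall.p, overall_p_without=res_without.overall.p)
    except Exception as exc:
        manifest["error"] = {"stage": len(manifest["stages"]), "message": str(exc)}
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
        raise

    manifest["config"] = {
        "qc": dataclasses.asdict(config.qc_config),
        "model": dataclasses.asdict(config.model_spec),
        "artp_B": config.artp_B,
        "fdr_m": config.fdr_m,
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
    return manifest
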